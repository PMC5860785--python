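"""Derivative-chromosome path reconstruction and GCR classification.

The rearranged chromosome is reconstructed as a walk that starts at the
assay chromosome's centromeric anchor and proceeds telomere-ward,
consuming junctions; the walk ends at a reference telomere, a de novo
telomere, or is marked unresolved.  Each isolate is then assigned one of
five classes (precedence order below) and a PFGE group from predicted
size and hph-marker status.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .errors import ReconstructionError
from .events import Breakend

GCR_CLASSES = (
    "telomere_addition",
    "interstitial_deletion",
    "hairpin_inverted_duplication",
    "micro_nonhomology_translocation",
    "homology_translocation",
)


@dataclass
class PathStep:
    chrom: str
    start: int
    end: int
    orientation: str  # '+' forward in the derivative, '-' inverted

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GcrPath:
    steps: list  # ordered centromere-side first
    junctions_used: list
    terminal: str  # 'reference_telomere' | 'de_novo_telomere' | 'unresolved'
    centromere_count: int = 1
    predicted_length: Optional[int] = None
    telomere_call: Optional[object] = None
    orphan_junctions: list = field(default_factory=list)


@dataclass
class GcrCall:
    isolate_id: str
    event_class: Optional[str]
    group: Optional[int]
    hph_retained: Optional[bool]
    predicted_length: Optional[int]
    secondary_type: Optional[str] = None
    disomies: list = field(default_factory=list)
    path: Optional[GcrPath] = None
    flagged: bool = False
    low_confidence: bool = False
    notes: str = ""


def _segment_state(segments, chrom, pos) -> Optional[int]:
    for s in segments:
        if s.chrom == chrom and s.start <= pos < s.end:
            return s.copy_state
    return None


def reconstruct_path(
    segments: list,
    junctions: list,
    telomere_calls: list,
    ref,
    max_hops: int = 8,
    slop: int = 800,
) -> GcrPath:
    """Walk the junction graph from the assay centromere telomere-ward."""
    assay = ref.assay_chrom
    cen = ref.centromere(assay)
    kept = [j for j in junctions if j.kept]
    used: list = []
    steps: list = []
    chrom, pos, direction = assay, cen.start, -1
    terminal = "unresolved"
    telo_used = None

    for _ in range(max_hops):
        cands = []
        for j in kept:
            if j in used:
                continue
            for be, other in ((j.breakend_a, j.breakend_b), (j.breakend_b, j.breakend_a)):
                if be.chrom != chrom:
                    continue
                if direction == -1 and be.side == "retains_right" and be.pos <= pos + slop:
                    cands.append((j, be, other))
                elif direction == 1 and be.side == "retains_left" and be.pos >= pos - slop:
                    cands.append((j, be, other))
        telo = None
        for t in telomere_calls:
            if t.breakend.chrom == chrom and direction == -1 and t.breakend.pos <= pos + slop:
                telo = t
        # nearest event ahead in the direction of travel
        if direction == -1:
            cands.sort(key=lambda c: -c[1].pos)
            telo_closer = telo is not None and (
                not cands or telo.breakend.pos >= cands[0][1].pos
            )
        else:
            cands.sort(key=lambda c: c[1].pos)
            telo_closer = False

        if telo_closer:
            steps.append(PathStep(chrom, telo.breakend.pos, pos, "+"))
            terminal = "de_novo_telomere"
            telo_used = telo
            break
        if not cands:
            # run to the chromosome end (or to a coverage-supported boundary)
            if direction == -1:
                steps.append(PathStep(chrom, 0, pos, "+"))
                tel_feats = [f for f in ref.features_on(chrom, "telomere") if f.start == 0]
                terminal = "reference_telomere" if tel_feats else "unresolved"
            else:
                L = ref.chrom_len(chrom)
                steps.append(PathStep(chrom, pos, L, "-"))
                tel_feats = [f for f in ref.features_on(chrom, "telomere") if f.end == L]
                terminal = "reference_telomere" if tel_feats else "unresolved"
            break
        j, be, other = cands[0]
        if direction == -1:
            steps.append(PathStep(chrom, be.pos, pos, "+"))
        else:
            steps.append(PathStep(chrom, pos, be.pos, "-"))
        used.append(j)
        chrom, pos = other.chrom, other.pos
        direction = -1 if other.side == "retains_left" else 1
    else:
        raise ReconstructionError(
            "junction graph admits no terminating walk",
            [j for j in kept if j not in used],
        )

    # the centromere-to-right-telomere side of the assay chromosome
    steps.insert(0, PathStep(assay, cen.start, ref.chrom_len(assay), "+"))

    cen_count = 0
    for s in steps:
        for f in ref.features_on(s.chrom, "centromere"):
            if f.start >= s.start and f.end <= s.end:
                cen_count += 1
    inserted = sum(len(j.inserted_sequence or "") for j in used)
    seed = len(telo_used.seed_sequence) if telo_used else 0
    length = sum(s.length for s in steps) + inserted + seed
    orphans = [j for j in kept if j not in used]
    return GcrPath(
        steps=steps,
        junctions_used=used,
        terminal=terminal,
        centromere_count=cen_count,
        predicted_length=length,
        telomere_call=telo_used,
        orphan_junctions=orphans,
    )


def classify_gcr(
    path: GcrPath,
    ref,
    isolate_id: str = "isolate",
    secondary: Optional[object] = None,
    disomies: Optional[list] = None,
    homology_threshold: int = 50,
) -> GcrCall:
    """Assign one of the five GCR classes by precedence.

    1. de novo telomere terminal -> telomere_addition
    2. inverted self-duplication in the path -> hairpin_inverted_duplication
    3. cross-chromosome junction with repeat-family/segdup context or
       microhomology >= ``homology_threshold`` -> homology_translocation
    4. other cross-chromosome junction -> micro_nonhomology_translocation
    5. intra-chromosome deletion junction -> interstitial_deletion
    """
    from .hairpin import _repeat_family_at

    disomies = list(disomies or [])
    call = GcrCall(
        isolate_id=isolate_id,
        event_class=None,
        group=None,
        hph_retained=_hph_retained(path, ref),
        predicted_length=path.predicted_length,
        disomies=disomies,
        path=path,
    )
    if path.terminal == "unresolved":
        call.flagged = True
        call.notes = "unresolved path; class withheld"
        return call
    if path.terminal == "de_novo_telomere":
        call.event_class = "telomere_addition"
    elif any(s.orientation == "-" and s.chrom == ref.assay_chrom for s in path.steps):
        call.event_class = "hairpin_inverted_duplication"
        call.secondary_type = secondary.type if secondary is not None else None
    else:
        cross = [j for j in path.junctions_used if j.breakend_a.chrom != j.breakend_b.chrom]
        if cross:
            j = cross[0]
            fa = _repeat_family_at(ref, j.breakend_a)
            fb = _repeat_family_at(ref, j.breakend_b)
            homologous = (fa is not None and fa == fb) or (
                j.microhomology_len >= homology_threshold
            )
            call.event_class = (
                "homology_translocation" if homologous else "micro_nonhomology_translocation"
            )
            call.low_confidence = j.junction_sequence is None
        elif path.junctions_used:
            call.event_class = "interstitial_deletion"
            call.low_confidence = path.junctions_used[0].junction_sequence is None
        else:
            call.flagged = True
            call.notes = "no junction consumed; class withheld"
            return call
    call.group = assign_group(call, ref.chrom_len(ref.assay_chrom))
    return call


def _hph_retained(path: GcrPath, ref) -> bool:
    hph = ref.by_name("hph")
    for s in path.steps:
        if s.chrom == hph.chrom and s.start <= hph.start and hph.end <= s.end:
            return True
    return False


def assign_group(call: GcrCall, parent_length: int, size_margin: float = 0.02) -> int:
    """PFGE group: 1 = larger than the parent chromosome; else 2 (hph lost)
    or 3 (hph retained)."""
    if call.predicted_length is not None and call.predicted_length > parent_length * (
        1 + size_margin
    ):
        return 1
    return 3 if call.hph_retained else 2


def tabulate_spectrum(calls_by_genotype: dict) -> pd.DataFrame:
    """Counts of each GCR class per genotype, plus totals and fractions."""
    rows = []
    for genotype, calls in calls_by_genotype.items():
        row = {"genotype": genotype}
        for cls in GCR_CLASSES:
            row[cls] = sum(1 for c in calls if c.event_class == cls)
        row["unclassified"] = sum(1 for c in calls if c.event_class is None)
        row["total"] = len(calls)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("genotype")
    for cls in GCR_CLASSES:
        denom = df[list(GCR_CLASSES)].sum(axis=1)
        df["frac_" + cls] = (df[cls] / denom).where(denom > 0)
    return df
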