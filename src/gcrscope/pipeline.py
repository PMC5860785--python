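"""End-to-end orchestration: simulate -> map -> dedup -> depth -> junctions
-> hairpin -> classify -> rates.

``analyze_isolate`` is the per-sample core shared by the library, the CLI
and the tests; ``run_pipeline`` drives whole configurations and writes
reports.  All stages are deterministic for a fixed configuration and
seed (one integer seed fans out to per-stage independent streams).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from ._seq import complement, revcomp
from .classify import GcrCall, classify_gcr, reconstruct_path, tabulate_spectrum
from .depth import (
    build_depth_profiles,
    call_disomies,
    mappability_mask,
    scale_profile,
    segment_profile,
)
from .errors import GcrScopeError
from .events import Breakend, GcrEventSpec, implant_gcr
from .genome import GenomeConfig, ReferenceGenome, build_reference
from .hairpin import detect_foldback, infer_hairpin_intermediate, type_secondary_resolution
from .junctions import (
    cluster_discordant_pairs,
    collect_junction_sequencing_reads,
    derive_junction_sequence,
    detect_telomere_addition,
    filter_against_noise,
)
from .mapper import KmerIndex, MapperParams
from .pairs import classify_concordance, fit_insert_model, remove_duplicates
from .readsim import ReadSimConfig, simulate_read_pairs

logger = logging.getLogger(__name__)


@dataclass
class AnalysisParams:
    mapper: MapperParams = field(default_factory=MapperParams)
    min_pairs: int = 3
    noise_alpha: float = 0.01
    segment_window: int = 500
    min_segment: int = 1500
    homology_threshold: int = 50
    anchor_len: int = 350
    foldback_max_distance: int = 10_000
    insert_fallback: tuple = (200.0, 1000.0)


@dataclass
class IsolateResult:
    isolate_id: str
    pairs: list
    insert_model: object
    copy_number: object
    segments: list
    junctions: list
    telomere_calls: list
    foldbacks: list
    secondary: Optional[object]
    disomies: list
    path: Optional[object]
    call: Optional[GcrCall]

    @property
    def kept_junctions(self) -> list:
        return [j for j in self.junctions if j.kept]


class ReferenceContext:
    """Reference genome plus the reusable per-reference heavy artifacts
    (k-mer index and mappability mask)."""

    def __init__(self, ref: ReferenceGenome, params: Optional[AnalysisParams] = None,
                 read_len: int = 100):
        self.ref = ref
        self.params = params or AnalysisParams()
        self.index = KmerIndex(ref, self.params.mapper)
        self.mask = mappability_mask(ref, k=read_len)
        self.chrom_order = {c: i for i, c in enumerate(ref.sequences)}


def analyze_isolate(
    ctx: ReferenceContext,
    read_pairs: list,
    isolate_id: str = "isolate",
    mapped_pairs: Optional[list] = None,
) -> IsolateResult:
    """Run the full per-isolate analysis on raw read pairs (or pre-mapped
    pairs imported from SAM)."""
    ref, params = ctx.ref, ctx.params
    pairs = mapped_pairs if mapped_pairs is not None else ctx.index.map_pairs(read_pairs)
    pairs = remove_duplicates(pairs)
    model = fit_insert_model(pairs, fallback=params.insert_fallback)
    pairs = classify_concordance(pairs, model)

    read_depth, span_depth = build_depth_profiles(pairs, ref)
    conc_depth, _ = build_depth_profiles([p for p in pairs if p.concordant], ref)
    cnp = scale_profile(read_depth, conc_depth, ctx.mask)
    segments = segment_profile(cnp, params.segment_window, params.min_segment)

    candidates = cluster_discordant_pairs(pairs, model.upper, ref)
    junctions = filter_against_noise(
        candidates, pairs, span_depth, params.min_pairs, params.noise_alpha
    )
    for j in junctions:
        if j.kept:
            _sequence_and_refine(j, pairs, model, ref, params)

    telomere_calls = _find_telomere_additions(pairs, segments, junctions, model, ref)
    foldbacks = detect_foldback(
        junctions, cnp, ref, max_distance=params.foldback_max_distance
    )
    for fb in foldbacks:
        if fb.junction_sequence:
            infer_hairpin_intermediate(
                fb.junction_sequence, ref.sequences[fb.chrom], call=fb, noisy=True
            )
            if fb.stem_len is not None:
                fb.junction.breakend_a = Breakend(fb.chrom, fb.pivot, "retains_right", inverted=True)
                fb.junction.breakend_b = Breakend(
                    fb.chrom, fb.fold_point + fb.stem_len, "retains_right"
                )
    secondary = None
    for fb in foldbacks:
        secondary = type_secondary_resolution(fb, junctions, ref)
        if secondary is not None:
            break

    disomy_calls = call_disomies(cnp)
    disomies = [d.chrom for d in disomy_calls if d.disomic]

    kept = [j for j in junctions if j.kept]
    if not kept and not telomere_calls and not disomies:
        return IsolateResult(
            isolate_id, pairs, model, cnp, segments, junctions, [], foldbacks,
            None, [], None,
            GcrCall(isolate_id, None, None, True, None, notes="no rearrangement detected"),
        )
    path = reconstruct_path(segments, junctions, telomere_calls, ref)
    call = classify_gcr(
        path, ref, isolate_id, secondary=secondary, disomies=disomies,
        homology_threshold=params.homology_threshold,
    )
    return IsolateResult(
        isolate_id, pairs, model, cnp, segments, junctions, telomere_calls,
        foldbacks, secondary, disomies, path, call,
    )


# ----------------------------------------------------------------------
# junction sequencing + breakend refinement


def _near_repeat_or_marker(ref, be: Breakend, slop: int = 150) -> bool:
    for f in ref.features_at(be.chrom, be.pos, slop):
        if f.kind.startswith("repeat_") or f.kind in ("segdup", "marker_ura3_52", "cassette"):
            return True
    return False


def _sequence_and_refine(j, pairs, model, ref, params) -> None:
    read_sets = [collect_junction_sequencing_reads(j, pairs, model.upper)]
    if _near_repeat_or_marker(ref, j.breakend_a) or _near_repeat_or_marker(ref, j.breakend_b):
        read_sets.append(
            collect_junction_sequencing_reads(j, pairs, model.upper, include_mapped=True)
        )
    read_sets = [rs for rs in read_sets if len(rs) >= 2]
    j.n_sequencing_reads = max((len(rs) for rs in read_sets), default=0)
    if not read_sets:
        j.low_confidence = True
        return
    if j.breakend_a.side == j.breakend_b.side == "retains_right":
        # foldback geometry: derive the consensus leftward from the
        # forward-copy side by mirroring; stem/loop refinement is done by
        # the hairpin module.  The lower breakend sits nearest the pivot.
        be = min((j.breakend_a, j.breakend_b), key=lambda b: b.pos)
        for reads in read_sets:
            try:
                # the junction region is quasi-palindromic, so read
                # orientation is ambiguous there; disagreements around the
                # loop are expected and tolerated, the stem/loop scan
                # validates against the flanks only
                j.junction_sequence = _derive_mirror(
                    be, reads, ref, params, max_conflict=0.6
                )
                return
            except GcrScopeError:
                continue
        j.low_confidence = True
        return
    # anchor preference: retains_left flanks read forward into the junction;
    # on ambiguity (e.g. the partner locus is still present intact, as for
    # homology junctions) fall back to the other end, mirrored if needed.
    attempts = []
    for be, on_a in ((j.breakend_a, True), (j.breakend_b, False)):
        if be.side == "retains_left":
            attempts.append((be, on_a, "fwd"))
    for be, on_a in ((j.breakend_a, True), (j.breakend_b, False)):
        if be.side == "retains_right":
            attempts.append((be, on_a, "mirror"))
    last_err = None
    for (anchor_be, anchored_on_a, mode), reads in [
        (att, rs) for rs in read_sets for att in attempts
    ]:
        side_reads = [r for r in reads if r.anchor_side == ("a" if anchored_on_a else "b")]
        if len(side_reads) < 2:
            side_reads = reads
        try:
            if mode == "fwd":
                # trim the junction-proximal anchor edge: the cluster estimate
                # can overshoot the junction by a few read-mapping-tolerance bp
                a0 = max(0, anchor_be.pos - params.anchor_len)
                anchor = ref.sequences[anchor_be.chrom][a0 : max(a0, anchor_be.pos - 10)]
                if len(anchor) < 50:
                    continue
                cons, _ = derive_junction_sequence(anchor, side_reads)
                # reads past the anchor's far edge may have prepended content
                idx = cons.find(anchor)
                if idx < 0:
                    continue
                ok = _refine_breakends(
                    j, cons[idx:], anchor_be, anchored_on_a, "fwd", a0, ref
                )
            else:
                anchor_lo = anchor_be.pos + 10
                anchor_end = min(
                    len(ref.sequences[anchor_be.chrom]), anchor_be.pos + params.anchor_len
                )
                cons = _derive_mirror(anchor_be, side_reads, ref, params)
                anchor = ref.sequences[anchor_be.chrom][anchor_lo:anchor_end]
                idx = cons.find(anchor)
                if idx < 0:
                    continue
                ok = _refine_breakends(
                    j,
                    cons[: idx + len(anchor)],
                    anchor_be,
                    anchored_on_a,
                    "mirror",
                    anchor_end,
                    ref,
                )
            if ok:
                j.low_confidence = False
                j.repeat_entering = _consensus_enters_repeat(cons, ref)
                return
        except GcrScopeError as err:
            last_err = err
            continue
    j.low_confidence = True


def _derive_mirror(be, reads, ref, params, max_conflict: float = 0.20) -> str:
    """Consensus extending leftward from a retains_right anchor flank,
    returned in derivative-forward orientation (ends with the anchor)."""
    from .junctions import AnchoredRead

    chrom_seq = ref.sequences[be.chrom]
    anchor = chrom_seq[be.pos + 10 : be.pos + params.anchor_len]
    if len(anchor) < 50:
        raise GcrScopeError("anchor flank too short")
    rc_reads = [
        AnchoredRead(r.read_id, revcomp(r.seq), r.anchor_side, r.mapped_mate_pos)
        for r in reads
    ]
    rc_cons, _ = derive_junction_sequence(
        revcomp(anchor), rc_reads, max_conflict=max_conflict
    )
    return revcomp(rc_cons)


def _refine_breakends(j, cons, anchor_be, anchored_on_a, mode, anchor_coord, ref) -> bool:
    """Exact breakends + microhomology from a resolved consensus.

    Every flank alignment yields its maximal-extension EDGE (the
    junction-proximal reference coordinate with any shared block
    included).  The block is then assigned to the canonical first end:
    breakend_a reports its EDGE, breakend_b steps the block off
    (``EDGE - mh`` for a retains_left flank, ``EDGE + mh`` otherwise).

    ``anchor_coord``: reference coordinate of consensus position 0 in fwd
    mode, or of the consensus end in mirror mode.
    """
    A = ref.sequences[anchor_be.chrom]
    if mode == "fwd":
        matched_a = 0
        for x, y in zip(cons, A[anchor_coord:]):
            if x != y:
                break
            matched_a += 1
        edge_a = anchor_coord + matched_a
    else:
        matched_a = _walk_rev(cons, A, anchor_coord)
        edge_a = anchor_coord - matched_a
    other_be = j.breakend_b if anchored_on_a else j.breakend_a
    B = ref.sequences[other_be.chrom]
    inverted = j.same_strand_signature
    if mode == "fwd":
        hit = _suffix_alignment(cons, B, other_be, inverted)
    else:
        hit = _prefix_alignment(cons, B, other_be)
    if hit is None:
        return False
    edge_b, matched_b = hit
    gap = len(cons) - matched_a - matched_b
    if gap > 0:
        mh = 0
        if mode == "fwd":
            inserted = cons[matched_a : len(cons) - matched_b]
        else:
            inserted = cons[matched_b : len(cons) - matched_a]
    else:
        mh = -gap
        inserted = ""
    j.junction_sequence = cons
    j.microhomology_len = int(mh)
    j.inserted_sequence = inserted

    def exclude(edge, side):
        return edge - mh if side == "retains_left" else edge + mh

    if anchored_on_a:
        pa = edge_a
        pb = exclude(edge_b, j.breakend_b.side)
    else:
        pa = edge_b  # EDGE includes the block by construction
        pb = exclude(edge_a, j.breakend_b.side)
    j.breakend_a = replace(j.breakend_a, pos=int(pa))
    j.breakend_b = replace(j.breakend_b, pos=int(pb))
    return True


def _walk_rev(cons, A, anchor_end) -> int:
    """Length of the consensus suffix matching A ending at ``anchor_end``."""
    n = 0
    for i in range(1, min(len(cons), anchor_end) + 1):
        if cons[-i] != A[anchor_end - i]:
            break
        n += 1
    return n


def _prefix_alignment(cons, B, other_be, seed_len: int = 30, window: int = 3000):
    """Locate the consensus prefix in the partner flank (forward strand).

    Returns ``(edge, matched)`` with ``edge`` the junction-proximal
    (rightmost matched) coordinate, block included.
    """
    if len(cons) < seed_len:
        return None
    seed = cons[:seed_len]
    lo = max(0, other_be.pos - window)
    hi = min(len(B), other_be.pos + window)
    region = B[lo:hi]
    i = region.find(seed)
    if i < 0 or region.find(seed, i + 1) >= 0:
        return None
    start = lo + i
    qi = seed_len
    ci = start + seed_len
    while qi < len(cons) and ci < len(B) and cons[qi] == B[ci]:
        qi += 1
        ci += 1
    return ci, qi


def _suffix_alignment(cons, B, other_be, inverted, seed_len: int = 30, window: int = 3000):
    """Locate the consensus suffix in the partner flank.

    Returns ``(edge, b_match)`` where ``edge`` is the junction-proximal
    reference coordinate of the partner flank excluding any shared block
    (i.e. the maximal-extension limit), and ``b_match`` the matched
    length.  ``inverted`` means the partner flank enters the derivative
    reverse-complemented.
    """
    if len(cons) < seed_len:
        return None
    seed = cons[-seed_len:]
    lo = max(0, other_be.pos - window)
    hi = min(len(B), other_be.pos + window)
    region = B[lo:hi]
    if not inverted:
        i = region.find(seed)
        if i < 0 or region.find(seed, i + 1) >= 0:
            return None
        start = lo + i
        qi = len(cons) - seed_len - 1
        ci = start - 1
        while qi >= 0 and ci >= 0 and cons[qi] == B[ci]:
            qi -= 1
            ci -= 1
        b_match = len(cons) - 1 - qi
        return ci + 1, b_match
    rc_seed = revcomp(seed)
    i = region.find(rc_seed)
    if i < 0 or region.find(rc_seed, i + 1) >= 0:
        return None
    end = lo + i + seed_len  # B coordinate just past the seed image
    qi = len(cons) - seed_len - 1
    ci = end
    while qi >= 0 and ci < len(B) and cons[qi] == complement(B[ci]):
        qi -= 1
        ci += 1
    b_match = len(cons) - 1 - qi
    return ci, b_match


def _consensus_enters_repeat(cons, ref, probe_len: int = 60) -> bool:
    """Does the consensus end inside repeat-family sequence (annotated or
    hidden)?  Flags anchors that run into unannotated elements."""
    tail = cons[-probe_len:]
    for f in list(ref.features) + list(ref.hidden_features):
        if not (f.kind.startswith("repeat_") or f.kind == "segdup"):
            continue
        seq = ref.sequences[f.chrom][f.start : f.end]
        if tail in seq or revcomp(tail) in seq:
            return True
    return False


def _find_telomere_additions(pairs, segments, junctions, model, ref) -> list:
    """One-sided breakend discovery: terminal zero-copy segment on the
    assay chromosome with no two-sided junction nearby."""
    assay = ref.assay_chrom
    zero_end = None
    assay_segs = sorted((s for s in segments if s.chrom == assay), key=lambda s: s.start)
    if assay_segs and assay_segs[0].copy_state == 0:
        zero_end = assay_segs[0].end
    if zero_end is None:
        return []
    for j in junctions:
        if not j.kept:
            continue
        for be in (j.breakend_a, j.breakend_b):
            if be.chrom == assay and abs(be.pos - zero_end) <= 2 * model.upper:
                return []
    # refine the boundary from read starts (segmentation is window-quantised)
    lo, hi = zero_end - 2 * model.upper, zero_end + 2 * model.upper
    starts = [
        e.start
        for p in pairs
        if not p.duplicate
        for e in p.ends
        if e.status == "unique" and e.chrom == assay and lo <= e.start <= hi
    ]
    refined = min(starts) if starts else int(zero_end)
    be = Breakend(assay, int(refined) + 10, "retains_right")
    reads = collect_junction_sequencing_reads(_one_sided(be), pairs, model.upper)
    call = detect_telomere_addition(be, reads, ref.grammar, ref)
    return [call] if call else []


class _one_sided:
    """Adapter giving a lone breakend the JunctionCall read-collection API."""

    def __init__(self, be):
        self.breakend_a = be
        self.breakend_b = Breakend("*none*", -1, "retains_left")


# ----------------------------------------------------------------------
# configuration-driven runs


@dataclass
class PipelineConfig:
    mode: str = "end_to_end"  # 'simulate' | 'analyze' | 'fluctuation' | 'end_to_end'
    outdir: Optional[str] = None
    seed: int = 0
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    readsim: ReadSimConfig = field(default_factory=ReadSimConfig)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    events: list = field(default_factory=list)  # list[GcrEventSpec]
    sam_paths: list = field(default_factory=list)
    fluctuation_path: Optional[str] = None


@dataclass
class RunReport:
    calls: list
    spectrum: Optional[object]
    warnings: list = field(default_factory=list)
    seed: int = 0
    truth: list = field(default_factory=list)

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                d = dataclasses.asdict(o)
                d.pop("path", None)
                return d
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            return str(o)

        calls = []
        for c in self.calls:
            d = {
                "isolate_id": c.isolate_id,
                "event_class": c.event_class,
                "group": c.group,
                "hph_retained": c.hph_retained,
                "predicted_length": c.predicted_length,
                "secondary_type": c.secondary_type,
                "disomies": c.disomies,
                "flagged": c.flagged,
                "notes": c.notes,
            }
            calls.append(d)
        payload = {"seed": self.seed, "calls": calls, "warnings": self.warnings}
        if self.spectrum is not None:
            payload["spectrum"] = json.loads(self.spectrum.to_json())
        return json.dumps(payload, indent=2, default=enc, sort_keys=True)


def default_event_mixture(n: int, rng: np.random.Generator) -> list:
    """A mixture over the five junction-forming GCR classes.

    Weights follow the telomere-addition-dominated spectrum typical of a
    single-copy-sequence assay in a checkpoint-proficient background.
    """
    classes = [
        ("telomere_addition", 0.40),
        ("interstitial_deletion", 0.15),
        ("hairpin_inverted_duplication", 0.20),
        ("micro_nonhomology_translocation", 0.15),
        ("homology_translocation", 0.10),
    ]
    names = [c for c, _ in classes]
    probs = np.array([p for _, p in classes])
    out = []
    for _ in range(n):
        cls = names[int(rng.choice(len(names), p=probs))]
        out.append(random_event_spec(cls, rng))
    return out


def random_event_spec(cls: str, rng: np.random.Generator) -> GcrEventSpec:
    """Randomised but valid parameters for one event of class ``cls``."""
    break_pos = int(rng.integers(6_900, 11_800))
    params: dict = {}
    if cls == "telomere_addition":
        params["seed_len"] = int(rng.integers(150, 400))
    elif cls == "interstitial_deletion":
        params["microhomology_len"] = int(rng.integers(3, 9))
    elif cls == "micro_nonhomology_translocation":
        if rng.random() < 0.25:
            params["insertion_len"] = int(rng.integers(2, 6))
        else:
            params["microhomology_len"] = int(rng.integers(3, 9))
        params["target_pos"] = int(rng.integers(2_000, 10_000))
    elif cls == "homology_translocation":
        # direct (non-hairpin) homology donors on the assay arm are the
        # forward-orientation copies: the segdup and delta_V2
        params["family"] = ["segdup", "delta"][int(rng.integers(2))]
        params["crossover_frac"] = float(rng.uniform(0.35, 0.65))
    elif cls == "hairpin_inverted_duplication":
        site = [(7_600, 6, 4), (8_400, 8, 6), (9_200, 12, 10), (10_000, 20, 40)][
            int(rng.integers(4))
        ]
        break_pos = min(break_pos, site[0])
        params.update(
            stem_len=site[1],
            loop_len=site[2],
            secondary_resolution=["repeat_HR", "microhomology", "marker_HR"][
                int(rng.integers(3))
            ],
            family=["delta", "PAU", "Ty"][int(rng.integers(3))],
        )
    elif cls == "disomy":
        params["chrom"] = "chrIII"
    return GcrEventSpec(cls, break_pos, params)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the configured stages; outputs are reproducible per seed."""
    rng = np.random.default_rng(config.seed)
    ss = np.random.SeedSequence(config.seed)
    warnings_log: list = []

    ref = build_reference(config.genome)
    ctx = ReferenceContext(ref, config.analysis, read_len=config.readsim.read_len)

    calls = []
    truths = []
    if config.mode in ("end_to_end", "simulate"):
        events = config.events or default_event_mixture(
            10, np.random.default_rng(ss.spawn(1)[0])
        )
        child_seeds = ss.spawn(len(events) + 1)[1:]
        for i, (spec, child) in enumerate(zip(events, child_seeds)):
            iso = f"sim{i:03d}"
            srng = np.random.default_rng(child)
            genome, truth = implant_gcr(ref, spec, srng)
            truths.append(truth)
            sim_cfg = replace(
                config.readsim, rng_seed=int(child.generate_state(1)[0] % (2**31))
            )
            reads, _ = simulate_read_pairs(genome, sim_cfg)
            if config.mode == "simulate":
                continue
            result = analyze_isolate(ctx, reads, isolate_id=iso)
            calls.append(result.call)
    elif config.mode == "analyze":
        from .samio import import_sam

        for path in config.sam_paths:
            mapped = import_sam(path, ref)
            result = analyze_isolate(
                ctx, [], isolate_id=Path(path).stem, mapped_pairs=mapped
            )
            calls.append(result.call)

    spectrum = None
    real_calls = [c for c in calls if c is not None and c.event_class is not None]
    if real_calls:
        spectrum = tabulate_spectrum({"simulated": real_calls})

    report = RunReport(calls=calls, spectrum=spectrum, warnings=warnings_log, seed=config.seed, truth=truths)
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        if spectrum is not None:
            spectrum.to_csv(out / "spectrum.tsv", sep="\t")
    return report
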