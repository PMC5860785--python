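"""Implanting truth-annotated GCR events into a reference genome.

Each event class rewrites the assay chromosome into a derivative molecule
and records a :class:`TruthRecord` with the realized junction coordinates,
microhomology, expected classification, PFGE group and marker status.

Conventions
-----------
* A junction fuses a *left* flank ``LEFT[:b]`` to a *right* flank
  ``RIGHT[a:]``.  Engineered microhomology of length ``h`` means
  ``LEFT[b-h:b] == RIGHT[a-h:a]`` with mismatches immediately outside the
  block, so ``h`` is the exact maximal overlap.  Because the block is
  attributable to either flank, the placement of the breakpoint within it
  is a convention: reported breakend coordinates assign the block to the
  canonical first end (chromosome order in the reference, then position),
  which the junction caller applies identically.
* Hairpin-mediated inverted duplications follow the resection/foldback
  mechanism: a break is resected to a 3' overhang which anneals at a short
  inverted repeat (stem ``s``, loop ``l``) centromeric to the break at
  pivot ``p``; copy-back and replication yield the dicentric intermediate
  ``revcomp(assay[p:L]) + assay[p+2s+l:L]`` which a secondary rearrangement
  resolves to a monocentric product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._seq import random_dna, revcomp
from .errors import ConfigurationError, SimulationError
from .genome import Feature, ReferenceGenome

EVENT_CLASSES = (
    "telomere_addition",
    "interstitial_deletion",
    "hairpin_inverted_duplication",
    "micro_nonhomology_translocation",
    "homology_translocation",
    "disomy",
)

SECONDARY_TYPES = ("repeat_HR", "microhomology", "marker_HR")


@dataclass(frozen=True)
class Breakend:
    chrom: str
    pos: int
    side: str  # 'retains_left' | 'retains_right'
    inverted: bool = False  # flank enters the derivative in reverse orientation


@dataclass
class TruthJunction:
    breakend_a: Breakend  # left flank of the derivative
    breakend_b: Breakend  # right flank
    microhomology_len: int = 0
    inserted_sequence: str = ""
    kind: str = "junction"  # 'junction' | 'foldback' | 'secondary'
    junction_sequence: str = ""  # derivative context around the fusion


@dataclass
class GcrEventSpec:
    event_class: str
    break_pos: Optional[int] = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.event_class not in EVENT_CLASSES:
            raise ConfigurationError(f"unknown event class {self.event_class!r}")


@dataclass
class Molecule:
    name: str
    seq: str

    def __len__(self):
        return len(self.seq)


@dataclass
class RearrangedGenome:
    molecules: list  # list[Molecule]; the derivative replaces the assay chromosome

    def molecule(self, name: str) -> Molecule:
        for m in self.molecules:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def total_length(self) -> int:
        return sum(len(m) for m in self.molecules)


@dataclass
class TruthRecord:
    spec: GcrEventSpec
    event_class: str
    junctions: list = field(default_factory=list)
    hph_retained: bool = True
    group: Optional[int] = None
    derivative_length: Optional[int] = None
    deleted: list = field(default_factory=list)  # (chrom, start, end)
    duplicated: list = field(default_factory=list)  # (chrom, start, end)
    disomies: list = field(default_factory=list)
    telomere_seed: str = ""
    # hairpin-specific
    stem_len: Optional[int] = None
    loop_len: Optional[int] = None
    pivot: Optional[int] = None
    resection_end: Optional[int] = None
    secondary_type: Optional[str] = None
    intermediate_seq: Optional[str] = None  # dicentric, pre-resolution


# ----------------------------------------------------------------------
# junction-site search


def find_mh_pair(
    left_seq: str,
    left_range: tuple,
    right_seq: str,
    right_range: tuple,
    h: int,
    right_hint: Optional[int] = None,
    left_hint: Optional[int] = None,
):
    """Find ``(b, a)`` with exactly ``h`` bp of junction microhomology.

    Requires ``left_seq[b-h:b] == right_seq[a-h:a]`` and mismatches at both
    flanking positions so the maximal overlap is exactly ``h``.  Positions
    are searched nearest the hints first.  Raises SimulationError when no
    site exists in the allowed ranges.
    """

    def _order(lo, hi, hint):
        xs = list(range(lo, hi))
        if hint is not None:
            xs.sort(key=lambda x: abs(x - hint))
        return xs

    a_candidates = _order(*right_range, right_hint)
    if h == 0:
        for a in a_candidates:
            for b in _order(*left_range, left_hint):
                if left_seq[b - 1] != right_seq[a - 1] and left_seq[b] != right_seq[a]:
                    return b, a
        raise SimulationError("no zero-homology junction site found")

    index: dict = {}
    lo, hi = left_range
    for b in range(lo, hi):
        index.setdefault(left_seq[b - h : b], []).append(b)
    for a in a_candidates:
        word = right_seq[a - h : a]
        for b in sorted(index.get(word, []), key=lambda x: abs(x - (left_hint or x))):
            if (
                left_seq[b - h - 1] != right_seq[a - h - 1]
                and left_seq[b] != right_seq[a]
            ):
                return b, a
    raise SimulationError(
        f"no junction site with exactly {h} bp microhomology in the allowed ranges"
    )


def _junction_context(seq: str, pos: int, w: int = 150) -> str:
    return seq[max(0, pos - w) : pos + w]


def _natural_mh(left_seq: str, b: int, right_seq: str, a: int) -> int:
    """Maximal identical block at a fusion of LEFT[:b] + RIGHT[a:]."""
    i = 0
    while b - 1 - i >= 0 and a - 1 - i >= 0 and left_seq[b - 1 - i] == right_seq[a - 1 - i]:
        i += 1
    j = 0
    while b + j < len(left_seq) and a + j < len(right_seq) and left_seq[b + j] == right_seq[a + j]:
        j += 1
    return i + j


# ----------------------------------------------------------------------
# implanting


def _assay_window(ref: ReferenceGenome, break_pos: Optional[int], pad: int = 60) -> tuple:
    lo, hi = ref.breakpoint_region
    lo, hi = lo + pad, hi - pad
    if break_pos is not None and not (lo <= break_pos < hi):
        raise SimulationError(
            f"break_pos {break_pos} outside breakpoint region {ref.breakpoint_region}"
        )
    return lo, hi


def _group(derivative_len: int, parent_len: int, hph_retained: bool, margin: float = 0.02) -> int:
    if derivative_len > parent_len * (1 + margin):
        return 1
    return 3 if hph_retained else 2


def _other_molecules(ref: ReferenceGenome) -> list:
    return [
        Molecule(name, seq)
        for name, seq in ref.sequences.items()
        if name != ref.assay_chrom
    ]


def implant_gcr(
    ref: ReferenceGenome, spec: GcrEventSpec, rng: Optional[np.random.Generator] = None
) -> tuple:
    """Apply one GCR event; returns ``(RearrangedGenome, TruthRecord)``."""
    rng = rng if rng is not None else np.random.default_rng(0)
    handler = {
        "telomere_addition": _implant_telomere_addition,
        "interstitial_deletion": _implant_deletion,
        "micro_nonhomology_translocation": _implant_micro_translocation,
        "homology_translocation": _implant_homology_translocation,
        "hairpin_inverted_duplication": _implant_hairpin,
        "disomy": _implant_disomy,
    }[spec.event_class]
    return handler(ref, spec, rng)


def _finish(ref, derivative: str, truth: TruthRecord, extra: list = ()) -> tuple:
    parent_len = ref.chrom_len(ref.assay_chrom)
    truth.derivative_length = len(derivative)
    truth.group = _group(len(derivative), parent_len, truth.hph_retained)
    mols = [Molecule(ref.assay_chrom + "_GCR", derivative)] + _other_molecules(ref)
    mols.extend(extra)
    return RearrangedGenome(mols), truth


def _implant_telomere_addition(ref, spec, rng):
    assay = ref.sequences[ref.assay_chrom]
    lo, hi = _assay_window(ref, spec.break_pos)
    a = spec.break_pos if spec.break_pos is not None else (lo + hi) // 2
    seed_len = int(spec.params.get("seed_len", 250))
    if seed_len < 15:
        raise ConfigurationError("telomere seed length must be >= 15 bp")
    seed = ref.grammar.left_telomere(rng, seed_len)
    # keep the truth breakpoint unambiguous: the seed always ends in the
    # complement of the G-strand's leading T, so nudge the break position
    # until the retained flank does not extend the telomeric pattern
    while seed[-1] == assay[a - 1] and a < hi:
        a += 1
    if seed[-1] == assay[a - 1]:
        raise SimulationError("no unambiguous telomere-addition breakpoint found")
    derivative = seed + assay[a:]
    be = Breakend(ref.assay_chrom, a, "retains_right")
    truth = TruthRecord(
        spec=spec,
        event_class="telomere_addition",
        junctions=[
            TruthJunction(
                Breakend("*telomere*", 0, "retains_left"),
                be,
                kind="junction",
                junction_sequence=_junction_context(derivative, seed_len),
            )
        ],
        hph_retained=False,
        deleted=[(ref.assay_chrom, 0, a)],
        telomere_seed=seed,
    )
    return _finish(ref, derivative, truth)


def _implant_deletion(ref, spec, rng):
    assay = ref.sequences[ref.assay_chrom]
    lo, hi = _assay_window(ref, spec.break_pos)
    a_hint = spec.break_pos if spec.break_pos is not None else (lo + hi) // 2
    h = int(spec.params.get("microhomology_len", 5))
    ins_len = int(spec.params.get("insertion_len", 0))
    hph = ref.by_name("hph")
    cas = next(f for f in ref.features_on(ref.assay_chrom, "cassette"))
    d_range = (hph.end + 200, cas.start - 200)
    d_hint = int(spec.params.get("del_pos", sum(d_range) // 2))
    if ins_len:
        b, a = find_mh_pair(assay, d_range, assay, (lo, hi), 0, a_hint, d_hint)
        ins = random_dna(rng, ins_len)
        while ins[0] == assay[b] or ins[-1] == assay[a - 1]:
            ins = random_dna(rng, ins_len)
        derivative = assay[:b] + ins + assay[a:]
        mh = 0
    else:
        b, a = find_mh_pair(assay, d_range, assay, (lo, hi), h, a_hint, d_hint)
        ins = ""
        derivative = assay[:b] + assay[a:]
        mh = h
    truth = TruthRecord(
        spec=spec,
        event_class="interstitial_deletion",
        junctions=[
            TruthJunction(
                Breakend(ref.assay_chrom, b, "retains_left"),
                Breakend(ref.assay_chrom, a, "retains_right"),
                microhomology_len=mh,
                inserted_sequence=ins,
                junction_sequence=_junction_context(derivative, b + len(ins)),
            )
        ],
        hph_retained=True,
        deleted=[(ref.assay_chrom, b, a)],
    )
    return _finish(ref, derivative, truth)


def _implant_micro_translocation(ref, spec, rng):
    assay = ref.sequences[ref.assay_chrom]
    lo, hi = _assay_window(ref, spec.break_pos)
    a_hint = spec.break_pos if spec.break_pos is not None else (lo + hi) // 2
    target = spec.params.get("target_chrom", "chrIII")
    if target == ref.assay_chrom:
        raise SimulationError("translocation target must not be the assay chromosome")
    tseq = ref.sequences[target]
    cen = ref.centromere(target)
    b_range = (1_000, cen.start - 500)
    b_hint = int(spec.params.get("target_pos", sum(b_range) // 2))
    h = int(spec.params.get("microhomology_len", 5))
    ins_len = int(spec.params.get("insertion_len", 0))
    if ins_len:
        b, a = find_mh_pair(tseq, b_range, assay, (lo, hi), 0, a_hint, b_hint)
        ins = random_dna(rng, ins_len)
        while ins[0] == tseq[b] or ins[-1] == assay[a - 1]:
            ins = random_dna(rng, ins_len)
        derivative = tseq[:b] + ins + assay[a:]
        mh = 0
    else:
        b, a = find_mh_pair(tseq, b_range, assay, (lo, hi), h, a_hint, b_hint)
        ins = ""
        derivative = tseq[:b] + assay[a:]
        mh = h
    # canonical first end is the assay chromosome: assign the block to it
    truth = TruthRecord(
        spec=spec,
        event_class="micro_nonhomology_translocation",
        junctions=[
            TruthJunction(
                Breakend(target, b - mh, "retains_left"),
                Breakend(ref.assay_chrom, a - mh, "retains_right"),
                microhomology_len=mh,
                inserted_sequence=ins,
                junction_sequence=_junction_context(derivative, b + len(ins)),
            )
        ],
        hph_retained=False,
        deleted=[(ref.assay_chrom, 0, a)],
        duplicated=[(target, 0, b)],
    )
    return _finish(ref, derivative, truth)


def _pick_copies(ref, family: str, assay_strand: str):
    copies = ref.repeat_copies(family)
    assay_copies = [
        f
        for f in copies
        if f.chrom == ref.assay_chrom
        and f.strand == assay_strand
        and f.start > ref.breakpoint_region[0]
        and f.end < ref.centromere(ref.assay_chrom).start
    ]
    partners = [
        f
        for f in copies
        if f.chrom != ref.assay_chrom
        and f.strand == "+"
        and f.end < ref.centromere(f.chrom).start
    ]
    if not assay_copies or not partners:
        raise SimulationError(
            f"no usable {family} copy pair (assay strand {assay_strand!r}) for homology event"
        )
    return assay_copies[0], partners[0]


def _implant_homology_translocation(ref, spec, rng):
    assay = ref.sequences[ref.assay_chrom]
    family = spec.params.get("family", "segdup")
    frac = float(spec.params.get("crossover_frac", 0.5))
    acopy, pcopy = _pick_copies(ref, family, "+")
    c = int(min(acopy.length, pcopy.length) * frac)
    tseq = ref.sequences[pcopy.chrom]
    b, a = pcopy.start + c, acopy.start + c
    derivative = tseq[:b] + assay[a:]
    mh = _natural_mh(tseq, b, assay, a)
    truth = TruthRecord(
        spec=spec,
        event_class="homology_translocation",
        junctions=[
            TruthJunction(
                Breakend(pcopy.chrom, b, "retains_left"),
                Breakend(ref.assay_chrom, a, "retains_right"),
                microhomology_len=mh,
                kind="junction",
                junction_sequence=_junction_context(derivative, b),
            )
        ],
        hph_retained=False,
        deleted=[(ref.assay_chrom, 0, a)],
        duplicated=[(pcopy.chrom, 0, b)],
    )
    return _finish(ref, derivative, truth)


def _find_hairpin_site(ref, break_pos: int, stem: int, loop: int) -> int:
    """Leftmost usable inverted repeat at/centromeric of the break."""
    assay = ref.sequences[ref.assay_chrom]
    lo, hi = ref.breakpoint_region
    for p in range(max(break_pos, lo), hi - (2 * stem + loop)):
        arm1 = assay[p : p + stem]
        arm2 = assay[p + stem + loop : p + 2 * stem + loop]
        if arm1 == revcomp(arm2):
            return p
    raise SimulationError(
        f"no inverted repeat with stem {stem} / loop {loop} centromeric of {break_pos}"
    )


def _implant_hairpin(ref, spec, rng):
    assay = ref.sequences[ref.assay_chrom]
    L = len(assay)
    lo, hi = _assay_window(ref, spec.break_pos)
    break_pos = spec.break_pos if spec.break_pos is not None else lo
    stem = int(spec.params.get("stem_len", 8))
    loop = int(spec.params.get("loop_len", 6))
    if stem < 4:
        raise ConfigurationError("hairpin stem length must be >= 4 bp")
    secondary = spec.params.get("secondary_resolution", "repeat_HR")
    if secondary not in SECONDARY_TYPES:
        raise ConfigurationError(f"unknown secondary resolution {secondary!r}")
    p = _find_hairpin_site(ref, break_pos, stem, loop)
    pivot_gap = 2 * stem + loop
    intermediate = revcomp(assay[p:L]) + assay[p + pivot_gap : L]
    n1 = L - p  # length of the inverted copy within the intermediate
    cen = ref.centromere(ref.assay_chrom)

    # breakend_b marks where the forward copy resumes (one stem copy and the
    # loop appear only once, inside the inverted flank)
    foldback = TruthJunction(
        Breakend(ref.assay_chrom, p, "retains_right", inverted=True),
        Breakend(ref.assay_chrom, p + pivot_gap, "retains_right"),
        kind="foldback",
        junction_sequence=_junction_context(intermediate, n1),
    )

    def inv_coord(x):  # assay coordinate -> intermediate coordinate (inverted copy)
        return L - x

    duplicated_to = None
    if secondary == "repeat_HR":
        family = spec.params.get("family", "delta")
        acopy, pcopy = _pick_copies(ref, family, "-")
        c = int(min(acopy.length, pcopy.length) * 0.5)
        tseq = ref.sequences[pcopy.chrom]
        b = pcopy.start + c
        q = inv_coord(acopy.end) + c
        derivative = tseq[:b] + intermediate[q:]
        mh = _natural_mh(tseq, b, intermediate, q)
        sec_junction = TruthJunction(
            Breakend(pcopy.chrom, b, "retains_left"),
            Breakend(ref.assay_chrom, acopy.end - c, "retains_left", inverted=True),
            microhomology_len=mh,
            kind="secondary",
            junction_sequence=_junction_context(derivative, b),
        )
        hph_retained = False
        deleted = [(ref.assay_chrom, 0, p)]
        duplicated_to = acopy.end - c
        duplicated = [
            (ref.assay_chrom, p, duplicated_to),
            (pcopy.chrom, 0, b),
        ]
    elif secondary == "marker_HR":
        u = ref.by_name("ura3-52")
        cu0, cu1 = ref.cassette_ura3
        c = int(min(u.length, cu1 - cu0) * 0.5)
        b = cu0 + c
        q = inv_coord(u.end) + c
        derivative = assay[:b] + intermediate[q:]
        mh = _natural_mh(assay, b, intermediate, q)
        sec_junction = TruthJunction(
            Breakend(ref.assay_chrom, b, "retains_left"),
            Breakend(ref.assay_chrom, u.end - c, "retains_left", inverted=True),
            microhomology_len=mh,
            kind="secondary",
            junction_sequence=_junction_context(derivative, b),
        )
        hph_retained = True
        deleted = [(ref.assay_chrom, b, p)]
        duplicated_to = u.end - c
        duplicated = [(ref.assay_chrom, p, duplicated_to)]
    else:  # microhomology
        target = spec.params.get("target_chrom", "chrIII")
        tseq = ref.sequences[target]
        tcen = ref.centromere(target)
        h = int(spec.params.get("microhomology_len", 5))
        q_range = (inv_coord(cen.start) + 500, n1 - 500)
        b, q = find_mh_pair(
            tseq,
            (1_000, tcen.start - 500),
            intermediate,
            q_range,
            h,
            right_hint=(q_range[0] + q_range[1]) // 2,
        )
        derivative = tseq[:b] + intermediate[q:]
        mh = h
        # canonical first end (assay chromosome) takes the block
        sec_junction = TruthJunction(
            Breakend(target, b - mh, "retains_left"),
            Breakend(ref.assay_chrom, L - q + mh, "retains_left", inverted=True),
            microhomology_len=mh,
            kind="secondary",
            junction_sequence=_junction_context(derivative, b),
        )
        hph_retained = False
        deleted = [(ref.assay_chrom, 0, p)]
        duplicated_to = L - q
        duplicated = [(ref.assay_chrom, p, duplicated_to), (target, 0, b)]

    truth = TruthRecord(
        spec=spec,
        event_class="hairpin_inverted_duplication",
        junctions=[foldback, sec_junction],
        hph_retained=hph_retained,
        deleted=deleted,
        duplicated=duplicated,
        stem_len=stem,
        loop_len=loop,
        pivot=p,
        resection_end=p,
        secondary_type=secondary,
        intermediate_seq=intermediate,
    )
    return _finish(ref, derivative, truth)


def _implant_disomy(ref, spec, rng):
    chrom = spec.params.get("chrom", "chrIII")
    if chrom == ref.assay_chrom:
        raise SimulationError("disomy of the assay chromosome is not modelled")
    extra = Molecule(chrom + "_copy2", ref.sequences[chrom])
    truth = TruthRecord(
        spec=spec,
        event_class="disomy",
        hph_retained=True,
        disomies=[chrom],
        duplicated=[(chrom, 0, ref.chrom_len(chrom))],
    )
    derivative = ref.sequences[ref.assay_chrom]
    genome, truth = _finish(ref, derivative, truth, extra=[extra])
    truth.group = None  # no size/marker change on the assay chromosome
    return genome, truth


def count_centromeres(seq_or_molecule, ref: ReferenceGenome) -> int:
    """Number of centromere copies contained in a derivative sequence.

    Counts occurrences of each reference centromere sequence in either
    orientation; used to check mono/di-centricity of simulated products.
    """
    seq = seq_or_molecule.seq if isinstance(seq_or_molecule, Molecule) else seq_or_molecule
    n = 0
    for f in ref.features:
        if f.kind != "centromere":
            continue
        cen = ref.sequences[f.chrom][f.start : f.end]
        for probe in (cen, revcomp(cen)):
            start = 0
            while True:
                i = seq.find(probe, start)
                if i < 0:
                    break
                n += 1
                start = i + 1
    return n


def verify_truth_junctions(genome: RearrangedGenome, truth: TruthRecord) -> bool:
    """Round-trip check: recorded junction context occurs in the derivative."""
    derivative = genome.molecules[0].seq
    for j in truth.junctions:
        if j.junction_sequence and j.junction_sequence not in derivative:
            return False
    return True
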