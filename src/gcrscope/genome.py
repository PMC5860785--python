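"""Assay-like reference genomes for GCR simulation.

The genome emulates the geometry of a chromosome-V GCR selection assay:
a telomeric hygromycin-resistance marker (hph), a counter-selectable
CAN1/URA3 cassette placed telomeric to the most telomeric essential gene,
a breakpoint region of unique sequence between the cassette and that
essential gene, Ty/delta/PAU-family repeats and a diverged segmental
duplication providing homology donors, and a centromere.  One non-assay
chromosome additionally carries a full-length Ty copy that is deliberately
omitted from the feature table (flanked by a 5-bp target-site duplication)
so that anchor-based junction sequencing can be shown to discover
unannotated repeat elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._seq import complement, mutate, random_dna, revcomp
from .errors import ConfigurationError
from .telomere import DEFAULT_GRAMMAR, TelomereGrammar

FEATURE_KINDS = {
    "telomere",
    "marker_hph",
    "cassette",
    "repeat_Ty",
    "repeat_delta",
    "repeat_PAU",
    "marker_ura3_52",
    "essential",
    "centromere",
    "segdup",
}


@dataclass(frozen=True)
class Feature:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str
    kind: str
    name: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ConfigurationError(f"feature {self.name}: empty interval")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Feature") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class PlannedFeature:
    kind: str
    name: str
    chrom: str
    start: int
    length: int
    strand: str = "+"
    family: Optional[str] = None  # repeat family / segdup group
    hidden: bool = False  # omitted from the feature table (unannotated)

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class RepeatFamily:
    name: str
    consensus_len: int
    copies: int
    divergence: float  # expected pairwise divergence between copies


@dataclass
class GenomeConfig:
    n_chromosomes: int = 3
    chrom_names: tuple = ("chrV", "chrII", "chrIII")
    chrom_lengths: tuple = (30_000, 30_000, 20_000)
    assay_chrom: str = "chrV"
    feature_plan: list = field(default_factory=list)
    repeat_families: tuple = (
        RepeatFamily("delta", 330, 4, 0.05),
        RepeatFamily("PAU", 900, 2, 0.05),
        RepeatFamily("Ty", 1500, 3, 0.05),
    )
    segdup_divergence: float = 0.05
    gc_content: float = 0.40
    #: (position on assay chromosome, stem bp, loop bp) inverted repeats
    #: planted in the breakpoint region as hairpin annealing sites
    hairpin_sites: tuple = ((7_600, 6, 4), (8_400, 8, 6), (9_200, 12, 10), (10_000, 20, 40))
    telomere_len: int = 300
    grammar: TelomereGrammar = field(default_factory=lambda: DEFAULT_GRAMMAR)
    rng_seed: int = 0

    def __post_init__(self):
        if not self.feature_plan:
            self.feature_plan = default_feature_plan()
        if not (0 < self.gc_content < 1):
            raise ConfigurationError("gc_content must be in (0, 1)")
        if any(n <= 0 for n in self.chrom_lengths):
            raise ConfigurationError("chromosome lengths must be positive")
        if len(self.chrom_names) != self.n_chromosomes or len(self.chrom_lengths) != self.n_chromosomes:
            raise ConfigurationError("chrom_names/chrom_lengths must match n_chromosomes")
        if self.assay_chrom not in self.chrom_names:
            raise ConfigurationError(f"assay chromosome {self.assay_chrom!r} not in chrom_names")


def default_feature_plan() -> list:
    """Standard desk-scale layout mirroring the assay geometry.

    chrV (assay): telomere, hph, CAN1/URA3 cassette, breakpoint region,
    first essential gene, ura3-52 allele, repeat donors, segdup, centromere.
    chrII: repeat-family partners, segdup partner, hidden Ty.  chrIII:
    plain translocation/disomy target.
    """
    P = PlannedFeature
    return [
        # --- assay chromosome, telomere-to-centromere order ---
        P("telomere", "TEL05L", "chrV", 0, 300),
        P("marker_hph", "hph", "chrV", 1_000, 1_200),
        P("cassette", "CAN1_URA3", "chrV", 4_000, 2_800),
        # breakpoint region (derived): 6_800 .. 12_000
        P("essential", "PCM1", "chrV", 12_000, 1_200),
        P("marker_ura3_52", "ura3-52", "chrV", 13_600, 450, "-"),
        P("repeat_delta", "delta_V1", "chrV", 15_000, 330, "-", family="delta"),
        P("repeat_delta", "delta_V2", "chrV", 15_700, 330, "+", family="delta"),
        P("repeat_PAU", "PAU_V", "chrV", 16_500, 900, "-", family="PAU"),
        P("repeat_Ty", "Ty_V", "chrV", 17_800, 1_500, "-", family="Ty"),
        P("segdup", "segdup_V", "chrV", 19_500, 2_000, "+", family="segdup"),
        P("centromere", "CEN5", "chrV", 22_000, 120),
        P("telomere", "TEL05R", "chrV", 29_700, 300),
        # --- chrII: homology partners + hidden Ty ---
        P("telomere", "TEL02L", "chrII", 0, 300),
        P("repeat_delta", "delta_II1", "chrII", 2_000, 330, "+", family="delta"),
        P("repeat_PAU", "PAU_II", "chrII", 3_000, 900, "+", family="PAU"),
        P("repeat_Ty", "Ty_II", "chrII", 5_000, 1_500, "+", family="Ty"),
        P("segdup", "segdup_II", "chrII", 8_000, 2_000, "+", family="segdup"),
        P("repeat_Ty", "Ty_unannotated", "chrII", 12_000, 1_505, "+", family="Ty", hidden=True),
        P("centromere", "CEN2", "chrII", 18_000, 120),
        P("telomere", "TEL02R", "chrII", 29_700, 300),
        # --- chrIII: plain target ---
        P("telomere", "TEL03L", "chrIII", 0, 300),
        P("centromere", "CEN3", "chrIII", 12_000, 120),
        P("telomere", "TEL03R", "chrIII", 19_700, 300),
    ]


@dataclass
class ReferenceGenome:
    """Chromosome sequences plus the feature annotation used throughout.

    Coordinates are 0-based half-open.  ``hidden_features`` holds elements
    present in the sequence but absent from ``features`` (the unannotated
    Ty); they exist only so simulations and tests can know the truth.
    """

    sequences: dict
    features: list
    assay_chrom: str
    breakpoint_region: tuple  # (start, end) on the assay chromosome
    cassette_ura3: tuple  # URA3 portion of the cassette, (start, end)
    hairpin_sites: tuple  # (pos, stem, loop) planted inverted repeats
    hidden_features: list = field(default_factory=list)
    grammar: TelomereGrammar = field(default_factory=lambda: DEFAULT_GRAMMAR)
    config: Optional[GenomeConfig] = None

    def __len__(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    @property
    def chrom_names(self) -> list:
        return list(self.sequences)

    def chrom_len(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def centromere(self, chrom: str) -> Feature:
        for f in self.features:
            if f.chrom == chrom and f.kind == "centromere":
                return f
        raise KeyError(f"no centromere on {chrom}")

    def features_on(self, chrom: str, kind: Optional[str] = None) -> list:
        return [
            f
            for f in self.features
            if f.chrom == chrom and (kind is None or f.kind == kind)
        ]

    def by_name(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def repeat_copies(self, family: str, include_hidden: bool = False) -> list:
        kinds = {"repeat_" + family} if family != "segdup" else {"segdup"}
        out = [f for f in self.features if f.kind in kinds]
        if include_hidden:
            out += [f for f in self.hidden_features if f.kind in kinds]
        return out

    def features_at(self, chrom: str, pos: int, slop: int = 0) -> list:
        return [
            f
            for f in self.features
            if f.chrom == chrom and f.start - slop <= pos < f.end + slop
        ]


def _validate_plan(config: GenomeConfig) -> None:
    lengths = dict(zip(config.chrom_names, config.chrom_lengths))
    by_chrom: dict = {}
    for pf in config.feature_plan:
        if pf.kind not in FEATURE_KINDS:
            raise ConfigurationError(f"unknown feature kind {pf.kind!r} ({pf.name})")
        if pf.chrom not in lengths:
            raise ConfigurationError(f"feature {pf.name} on unknown chromosome {pf.chrom}")
        if pf.start < 0 or pf.end > lengths[pf.chrom]:
            raise ConfigurationError(f"feature {pf.name} outside {pf.chrom}")
        by_chrom.setdefault(pf.chrom, []).append(pf)
    for chrom, feats in by_chrom.items():
        feats = sorted(feats, key=lambda f: f.start)
        for a, b in zip(feats, feats[1:]):
            if b.start < a.end:
                raise ConfigurationError(
                    f"features {a.name} and {b.name} overlap on {chrom}"
                )
        n_cen = sum(f.kind == "centromere" for f in feats)
        if n_cen != 1:
            raise ConfigurationError(f"{chrom} must carry exactly one centromere (got {n_cen})")
    # assay chromosome ordering invariant, telomere -> centromere
    assay = sorted(
        (f for f in config.feature_plan if f.chrom == config.assay_chrom),
        key=lambda f: f.start,
    )
    order = {}
    for f in assay:
        order.setdefault(f.kind, f.start)
    required = ["telomere", "marker_hph", "cassette", "essential", "centromere"]
    for kind in required:
        if kind not in order:
            raise ConfigurationError(f"assay chromosome lacks a {kind} feature")
    starts = [order[k] for k in required]
    if starts != sorted(starts):
        raise ConfigurationError(
            "assay chromosome features out of telomere-to-centromere order"
        )


def _plant_hairpin_site(seq: bytearray, pos: int, stem: int, loop: int, rng) -> None:
    """Write a clean inverted repeat ``S loop S'`` at ``pos``.

    "Clean" means the stem cannot be extended outward or into the loop by
    chance base pairing, so the planted (stem, loop) is the unique maximal
    interpretation recovered by exhaustive scanning.
    """
    arm = random_dna(rng, stem)
    site = arm + random_dna(rng, loop) + revcomp(arm)
    seq[pos : pos + len(site)] = site.encode()
    # no outward extension: base before arm1 must not pair with base after arm2
    after = pos + 2 * stem + loop
    if pos > 0 and after < len(seq):
        while chr(seq[after]) == complement(chr(seq[pos - 1])):
            seq[after] = ord(random_dna(rng, 1))
    # no inward extension into the loop
    if loop >= 1:
        a, b = pos + stem, pos + stem + loop - 1
        while chr(seq[a]) == complement(chr(seq[b])) and a <= b:
            seq[b] = ord(random_dna(rng, 1))
            if a == b:
                break


def build_reference(config: Optional[GenomeConfig] = None) -> ReferenceGenome:
    """Build a deterministic assay-like reference genome.

    The same seed always yields byte-identical sequences.  Raises
    :class:`ConfigurationError` naming the colliding features when the
    feature plan is inconsistent.
    """
    config = config or GenomeConfig()
    _validate_plan(config)
    rng = np.random.default_rng(config.rng_seed)

    seqs = {
        name: bytearray(random_dna(rng, n, config.gc_content).encode())
        for name, n in zip(config.chrom_names, config.chrom_lengths)
    }

    fam_by_name = {f.name: f for f in config.repeat_families}
    consensus = {
        f.name: random_dna(rng, f.consensus_len, config.gc_content)
        for f in config.repeat_families
    }
    segdup_len = max(
        (pf.length for pf in config.feature_plan if pf.kind == "segdup"), default=0
    )
    if segdup_len:
        consensus["segdup"] = random_dna(rng, segdup_len, config.gc_content)

    features: list = []
    hidden: list = []
    cassette_ura3 = None
    ura3_seq = None

    # first pass: everything except ura3-52 (needs the cassette sequence)
    deferred = []
    for pf in sorted(config.feature_plan, key=lambda p: (p.chrom, p.start)):
        target = seqs[pf.chrom]
        if pf.kind == "telomere":
            if pf.start == 0:
                s = config.grammar.left_telomere(rng, pf.length)
            else:
                s = config.grammar.right_telomere(rng, pf.length)
            target[pf.start : pf.end] = s.encode()
        elif pf.kind == "cassette":
            s = random_dna(rng, pf.length, config.gc_content)
            target[pf.start : pf.end] = s.encode()
            # homology tract kept below the insert size so marker-HR
            # junctions still yield junction-defining discordant pairs
            ura3_len = min(450, pf.length // 2)
            cassette_ura3 = (pf.end - ura3_len, pf.end)
            ura3_seq = s[-ura3_len:]
        elif pf.kind == "marker_ura3_52":
            deferred.append(pf)
            continue
        elif pf.kind in ("repeat_Ty", "repeat_delta", "repeat_PAU", "segdup"):
            fam = pf.family or pf.kind.split("_")[-1]
            div = (
                config.segdup_divergence
                if fam == "segdup"
                else fam_by_name[fam].divergence
            )
            body_len = pf.length
            tsd = ""
            if pf.hidden and pf.kind == "repeat_Ty":
                # unannotated Ty with a 5-bp target-site duplication
                tsd = bytes(target[pf.start - 5 : pf.start]).decode()
                body_len = pf.length - len(tsd)
            core = consensus[fam][:body_len]
            if len(core) < body_len:
                core = core + random_dna(rng, body_len - len(core), config.gc_content)
            copy = mutate(core, rng, div / 2)
            if pf.strand == "-":
                copy = revcomp(copy)
            target[pf.start : pf.start + body_len] = copy.encode()
            if tsd:
                target[pf.start + body_len : pf.end] = tsd.encode()
        elif pf.kind in ("marker_hph", "essential", "centromere"):
            target[pf.start : pf.end] = random_dna(
                rng, pf.length, config.gc_content
            ).encode()
        feat = Feature(pf.chrom, pf.start, pf.end, pf.strand, pf.kind, pf.name)
        if pf.hidden:
            if pf.kind == "repeat_Ty":
                feat = Feature(pf.chrom, pf.start, pf.end - 5, pf.strand, pf.kind, pf.name)
            hidden.append(feat)
        else:
            features.append(feat)

    for pf in deferred:  # ura3-52: diverged, Ty-interrupted URA3 modelled as a copy
        if ura3_seq is None:
            raise ConfigurationError("marker_ura3_52 requires a cassette feature")
        copy = ura3_seq[: pf.length]
        if len(copy) < pf.length:
            copy = copy + random_dna(rng, pf.length - len(copy), config.gc_content)
        if pf.strand == "-":
            copy = revcomp(copy)
        seqs[pf.chrom][pf.start : pf.end] = copy.encode()
        features.append(Feature(pf.chrom, pf.start, pf.end, pf.strand, pf.kind, pf.name))

    # breakpoint region: between cassette end and first essential gene start
    assay_feats = sorted(
        (f for f in features if f.chrom == config.assay_chrom), key=lambda f: f.start
    )
    cas = next(f for f in assay_feats if f.kind == "cassette")
    ess = next(f for f in assay_feats if f.kind == "essential")
    bp_region = (cas.end, ess.start)

    for pos, stem, loop in config.hairpin_sites:
        if not (bp_region[0] <= pos and pos + 2 * stem + loop <= bp_region[1]):
            raise ConfigurationError(
                f"hairpin site at {pos} falls outside the breakpoint region {bp_region}"
            )
        _plant_hairpin_site(seqs[config.assay_chrom], pos, stem, loop, rng)

    features.sort(key=lambda f: (f.chrom, f.start))
    return ReferenceGenome(
        sequences={k: bytes(v).decode() for k, v in seqs.items()},
        features=features,
        assay_chrom=config.assay_chrom,
        breakpoint_region=bp_region,
        cassette_ura3=cassette_ura3,
        hairpin_sites=config.hairpin_sites,
        hidden_features=hidden,
        grammar=config.grammar,
        config=config,
    )
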