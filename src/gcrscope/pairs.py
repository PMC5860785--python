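"""Read-pair containers, PCR-duplicate removal and concordance classification."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import ConfigurationError


@dataclass
class EndAlignment:
    """One end of a sequenced fragment, mapped independently of its mate."""

    chrom: Optional[str]
    start: Optional[int]
    end: Optional[int]
    strand: Optional[str]
    status: str  # 'unique' | 'multi' | 'unmapped'
    mismatches: Optional[int]
    seq: str = ""
    reason: str = ""

    @property
    def mapped(self) -> bool:
        return self.status in ("unique", "multi")

    @property
    def outer_coord(self) -> Optional[int]:
        """5'-most reference coordinate (duplicate-marking key)."""
        if not self.mapped:
            return None
        return self.start if self.strand == "+" else self.end


@dataclass
class ReadPairAlignment:
    pair_id: str
    end1: EndAlignment
    end2: EndAlignment
    concordant: Optional[bool] = None
    duplicate: bool = False

    @property
    def both_unique(self) -> bool:
        return self.end1.status == "unique" and self.end2.status == "unique"

    @property
    def ends(self):
        return (self.end1, self.end2)

    def insert_size(self) -> Optional[int]:
        e1, e2 = self.end1, self.end2
        if not (e1.mapped and e2.mapped) or e1.chrom != e2.chrom:
            return None
        return max(e1.end, e2.end) - min(e1.start, e2.start)


def remove_duplicates(pairs: list) -> list:
    """Flag PCR duplicates; one representative per fragment signature.

    Pairs sharing both ends' (chrom, strand, outermost coordinate) are
    grouped; pairs with an unmapped end are grouped by the mapped end plus
    the mate's sequence.  Idempotent; the representative is the first pair
    in input order.
    """
    seen: set = set()
    out = []
    for p in pairs:
        e1, e2 = p.end1, p.end2
        if e1.mapped and e2.mapped:
            k1 = (e1.chrom, e1.strand, e1.outer_coord)
            k2 = (e2.chrom, e2.strand, e2.outer_coord)
            key = ("mm",) + tuple(sorted((k1, k2)))
        elif e1.mapped or e2.mapped:
            m, u = (e1, e2) if e1.mapped else (e2, e1)
            key = ("mu", m.chrom, m.strand, m.outer_coord, u.seq)
        else:
            key = ("uu", min(e1.seq, e2.seq), max(e1.seq, e2.seq))
        dup = key in seen
        seen.add(key)
        out.append(replace(p, duplicate=dup) if dup != p.duplicate else p)
    return out


@dataclass
class InsertModel:
    """Empirical insert-size model defining concordance bounds."""

    inserts: np.ndarray
    lower: float
    upper: float
    median: float
    orientation: str = "FR"

    @classmethod
    def from_bounds(cls, lower: float, upper: float) -> "InsertModel":
        return cls(np.array([]), lower, upper, (lower + upper) / 2)


def _inward(e1: EndAlignment, e2: EndAlignment) -> bool:
    if e1.strand == e2.strand:
        return False
    plus, minus = (e1, e2) if e1.strand == "+" else (e2, e1)
    return plus.start <= minus.end


def fit_insert_model(
    pairs: list,
    lower_pct: float = 0.1,
    upper_pct: float = 99.9,
    min_pairs: int = 1000,
    fallback: Optional[tuple] = None,
) -> InsertModel:
    """Percentile bounds on inward-facing same-chromosome unique inserts."""
    inserts = []
    for p in pairs:
        if p.duplicate or not p.both_unique:
            continue
        e1, e2 = p.end1, p.end2
        if e1.chrom == e2.chrom and _inward(e1, e2):
            inserts.append(p.insert_size())
    if len(inserts) < min_pairs:
        if fallback is not None:
            return InsertModel.from_bounds(*fallback)
        raise ConfigurationError(
            f"only {len(inserts)} usable pairs for the insert model "
            f"(need {min_pairs}) and no fallback bounds given"
        )
    arr = np.asarray(inserts)
    # robustify: junction-spanning pairs (deletions) inflate the upper tail;
    # restrict to the bulk around the median before taking percentiles
    med0 = np.median(arr)
    core = arr[arr <= 3 * med0]
    lo, med, hi = np.percentile(core, [lower_pct, 50, upper_pct])
    if not (lo < med < hi):
        lo, hi = med - 1, med + 1
    return InsertModel(arr, float(lo), float(hi), float(med))


def classify_concordance(pairs: list, model: InsertModel) -> list:
    """A pair is concordant iff both ends unique, same chromosome,
    opposite strands, inward-facing, and insert within the model bounds."""
    out = []
    for p in pairs:
        ok = False
        if p.both_unique:
            e1, e2 = p.end1, p.end2
            if e1.chrom == e2.chrom and _inward(e1, e2):
                ins = p.insert_size()
                ok = model.lower <= ins <= model.upper
        out.append(replace(p, concordant=ok))
    return out


def discordant_pairs(pairs: list) -> list:
    """Both-unique, deduplicated, non-concordant pairs (junction candidates)."""
    return [
        p
        for p in pairs
        if p.both_unique and not p.duplicate and p.concordant is False
    ]
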