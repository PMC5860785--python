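"""Minimal built-in unique mapper (exact k-mer seeds, ungapped extension).

Each end of a pair is mapped independently; pairing is applied afterwards
by the concordance classifier.  Reads crossing novel junctions fail
full-length extension on both flanks and stay unmapped - that is the
mechanism by which junction-sequencing reads are produced downstream, so
there is deliberately no split/gapped alignment here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from ._seq import revcomp
from .pairs import EndAlignment, ReadPairAlignment


@dataclass
class MapperParams:
    k: int = 31
    max_mismatches: int = 5
    unique_margin: int = 2  # next-best must have >= this many more mismatches
    n_seeds: int = 3


class KmerIndex:
    """Exact k-mer index over the forward reference strands."""

    def __init__(self, ref, params: Optional[MapperParams] = None):
        self.ref = ref
        self.params = params or MapperParams()
        k = self.params.k
        self.seqs = dict(ref.sequences)
        self._index: dict = {}
        for ci, (chrom, seq) in enumerate(self.seqs.items()):
            idx = self._index
            for p in range(len(seq) - k + 1):
                idx.setdefault(seq[p : p + k], []).append((ci, p))
        self.chrom_names = list(self.seqs)

    def _candidates(self, read: str):
        k = self.params.k
        n = len(read)
        offsets = sorted({0, max(0, (n - k) // 2), n - k})
        cands = set()
        for off in offsets[: self.params.n_seeds]:
            for ci, p in self._index.get(read[off : off + k], ()):
                start = p - off
                if start >= 0 and start + n <= len(self.seqs[self.chrom_names[ci]]):
                    cands.add((ci, start))
        return cands

    def map_read(self, read: str) -> EndAlignment:
        """Map one read end: unique / multi / unmapped."""
        pr = self.params
        if len(read) < pr.k:
            return EndAlignment(None, None, None, None, "unmapped", None, read, reason="read shorter than k")
        best: list = []  # (mismatches, chrom_idx, start, strand)
        best_mm = pr.max_mismatches + pr.unique_margin + 1
        for strand, seq in (("+", read), ("-", revcomp(read))):
            for ci, start in self._candidates(seq):
                ref_seq = self.seqs[self.chrom_names[ci]]
                mm = 0
                limit = best_mm
                window = ref_seq[start : start + len(seq)]
                for x, y in zip(seq, window):
                    if x != y:
                        mm += 1
                        if mm > limit:
                            break
                if mm <= best_mm:
                    best.append((mm, ci, start, strand))
                    if mm < best_mm:
                        best_mm = mm
        hits = sorted(h for h in best if h[0] <= pr.max_mismatches)
        if not hits:
            return EndAlignment(None, None, None, None, "unmapped", None, read)
        top = [h for h in hits if h[0] == hits[0][0]]
        others = sorted(h[0] for h in best if h[0] > hits[0][0])
        runner_up = others[0] if others else None
        mm, ci, start, strand = top[0]
        chrom = self.chrom_names[ci]
        if len(top) > 1:
            status = "multi"  # ties are never broken arbitrarily
        elif runner_up is not None and runner_up - mm < pr.unique_margin:
            status = "multi"
        else:
            status = "unique"
        return EndAlignment(chrom, start, start + len(read), strand, status, mm, read)

    def map_read_pair(self, pair) -> ReadPairAlignment:
        return ReadPairAlignment(
            pair.pair_id, self.map_read(pair.seq1), self.map_read(pair.seq2)
        )

    def map_pairs(self, pairs) -> list:
        return [self.map_read_pair(p) for p in pairs]


def brute_force_map(ref, read: str, max_mismatches: int = 5, margin: int = 2) -> EndAlignment:
    """All-positions Hamming search; oracle for the k-mer mapper."""
    hits = []
    for strand, seq in (("+", read), ("-", revcomp(read))):
        for chrom, ref_seq in ref.sequences.items():
            n = len(seq)
            for start in range(len(ref_seq) - n + 1):
                mm = sum(a != b for a, b in zip(seq, ref_seq[start : start + n]))
                if mm <= max_mismatches + margin:
                    hits.append((mm, chrom, start, strand))
    hits.sort(key=lambda h: h[0])
    good = [h for h in hits if h[0] <= max_mismatches]
    if not good:
        return EndAlignment(None, None, None, None, "unmapped", None, read)
    top = [h for h in good if h[0] == good[0][0]]
    runner = next((h[0] for h in hits if h[0] > good[0][0]), None)
    mm, chrom, start, strand = top[0]
    if len(top) > 1 or (runner is not None and runner - mm < margin):
        status = "multi"
    else:
        status = "unique"
    return EndAlignment(chrom, start, start + len(read), strand, status, mm, read)
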