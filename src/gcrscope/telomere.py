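"""Budding-yeast-style irregular telomeric repeats.

Yeast telomeres are irregular TG(1-3) repeats on the G-rich strand that
points 5'->3' toward the chromosome end.  Detection of de novo telomere
addition must therefore be pattern-driven rather than motif-matching a
fixed repeat unit.  The grammar here emits blocks ``T G{1..3}`` on the
G-strand; on the top strand a *left* telomere then reads as ``C{1..3} A``
blocks, a *right* telomere as ``T G{1..3}`` blocks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp


@dataclass(frozen=True)
class TelomereGrammar:
    """Configurable irregular-repeat grammar for telomeric sequence."""

    g_min: int = 1
    g_max: int = 3
    #: probability of each G-run length g_min..g_max on the G-strand
    weights: tuple = field(default=(0.4, 0.35, 0.25))

    def g_strand(self, rng: np.random.Generator, length: int) -> str:
        """Generate ``length`` bases of G-strand telomeric repeat."""
        runs = list(range(self.g_min, self.g_max + 1))
        out = []
        n = 0
        while n < length:
            k = int(rng.choice(runs, p=np.asarray(self.weights) / sum(self.weights)))
            block = "T" + "G" * k
            out.append(block)
            n += len(block)
        return "".join(out)[:length]

    def left_telomere(self, rng: np.random.Generator, length: int) -> str:
        """Top-strand sequence of a left chromosome end (C-rich)."""
        return revcomp(self.g_strand(rng, length))

    def right_telomere(self, rng: np.random.Generator, length: int) -> str:
        return self.g_strand(rng, length)

    # -- recognition ---------------------------------------------------

    def _patterns(self):
        lo, hi = self.g_min, self.g_max
        # arbitrary phase: allow a partial leading/trailing block
        tg = rf"G{{0,{hi}}}(?:TG{{{lo},{hi}}})*T?"
        ca = rf"C{{0,{hi}}}A?(?:C{{{lo},{hi}}}A)*C{{0,{hi}}}"
        return (re.compile(tg), re.compile(ca))

    def match_prefix(self, seq: str) -> int:
        """Longest prefix of ``seq`` consistent with the grammar (either strand)."""
        best = 0
        for pat in self._patterns():
            m = pat.match(seq)
            if m:
                best = max(best, m.end())
        return best

    def match_suffix(self, seq: str) -> int:
        """Longest suffix of ``seq`` consistent with the grammar (either strand)."""
        rev = seq[::-1]
        lo, hi = self.g_min, self.g_max
        # reversed TG-grammar reads (G{1,3} T)+, reversed CA reads (A C{1,3})+
        pats = (
            re.compile(rf"T?(?:G{{{lo},{hi}}}T)*G{{0,{hi}}}"),
            re.compile(rf"C{{0,{hi}}}(?:AC{{{lo},{hi}}})*A?C{{0,{hi}}}"),
        )
        best = 0
        for pat in pats:
            m = pat.match(rev)
            if m:
                best = max(best, m.end())
        return best

    def is_telomeric(self, seq: str, min_len: int = 15) -> bool:
        return len(seq) >= min_len and self.match_prefix(seq) >= min_len


DEFAULT_GRAMMAR = TelomereGrammar()
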