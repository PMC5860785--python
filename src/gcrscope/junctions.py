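"""Junction discovery from discordant read pairs.

Discordant pairs sharing an orientation signature and co-locating within
one insert length are clustered into candidate junctions; candidates are
filtered against the stray-discordant background using local span depth;
junction sequences are derived from junction-sequencing reads (unmapped
reads whose mates anchor next to a breakend) by greedy anchored overlap
layout; one-sided breakends whose consensus runs into telomeric-repeat
grammar are called as de novo telomere additions; microhomology is the
maximal fusion-point block attributable to either flank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from ._seq import revcomp
from .errors import AmbiguousConsensusError, ConfigurationError, GcrScopeError
from .events import Breakend


@dataclass
class JunctionCall:
    breakend_a: Breakend
    breakend_b: Breakend
    n_defining_pairs: int
    orientation: tuple = ("+", "-")  # strand signature after canonical ordering
    n_sequencing_reads: int = 0
    junction_sequence: Optional[str] = None
    microhomology_len: int = 0
    inserted_sequence: str = ""
    noise_pvalue: Optional[float] = None
    kept: bool = False
    pair_ids: list = field(default_factory=list)
    repeat_entering: bool = False  # consensus runs into repeat-family sequence
    low_confidence: bool = False  # classified without a junction sequence

    @property
    def same_chrom(self) -> bool:
        return self.breakend_a.chrom == self.breakend_b.chrom

    @property
    def same_strand_signature(self) -> bool:
        return self.orientation[0] == self.orientation[1]


@dataclass
class TelomereAdditionCall:
    breakend: Breakend
    seed_sequence: str
    n_supporting_reads: int


def _canonical_ends(p, chrom_order: dict):
    e1, e2 = p.end1, p.end2
    k1 = (chrom_order[e1.chrom], e1.start)
    k2 = (chrom_order[e2.chrom], e2.start)
    return (e1, e2) if k1 <= k2 else (e2, e1)


def cluster_discordant_pairs(pairs: list, slop: float, ref) -> list:
    """Cluster discordant pairs into candidate junction calls.

    ``pairs`` must already be deduplicated and concordance-classified;
    ``slop`` is typically the insert-model upper bound.
    """
    chrom_order = {c: i for i, c in enumerate(ref.sequences)}
    buckets: dict = {}
    for p in pairs:
        if not (p.both_unique and not p.duplicate and p.concordant is False):
            continue
        a, b = _canonical_ends(p, chrom_order)
        key = (a.chrom, b.chrom, a.strand, b.strand)
        buckets.setdefault(key, []).append((a, b, p.pair_id))
    calls = []
    for (ca, cb, sa, sb), items in sorted(buckets.items()):
        items.sort(key=lambda t: (t[0].start, t[1].start))
        clusters: list = []
        for a, b, pid in items:
            placed = False
            for cl in clusters:
                la, lb, _ = cl[-1]
                if abs(a.start - la.start) <= slop and abs(b.start - lb.start) <= slop:
                    cl.append((a, b, pid))
                    placed = True
                    break
            if not placed:
                clusters.append([(a, b, pid)])
        for cl in clusters:
            ends_a = [t[0] for t in cl]
            ends_b = [t[1] for t in cl]
            be_a = _cluster_breakend(ends_a, ca, sa)
            be_b = _cluster_breakend(ends_b, cb, sb)
            # same-chromosome inward clusters spanning less than one insert
            # length are insert-size outliers, not junctions: a deletion
            # below insert resolution cannot produce discordant pairs
            if (
                ca == cb
                and (sa, sb) == ("+", "-")
                and be_b.pos - be_a.pos <= slop
            ):
                continue
            calls.append(
                JunctionCall(
                    be_a,
                    be_b,
                    n_defining_pairs=len(cl),
                    orientation=(sa, sb),
                    pair_ids=[t[2] for t in cl],
                )
            )
    return calls


def _cluster_breakend(ends: list, chrom: str, strand: str) -> Breakend:
    # '+' reads point right: the junction lies just beyond the innermost
    # (rightmost) read edge; '-' reads point left, symmetric.
    if strand == "+":
        return Breakend(chrom, max(e.end for e in ends), "retains_left")
    return Breakend(chrom, min(e.start for e in ends), "retains_right")


def filter_against_noise(
    candidates: list,
    pairs: list,
    span_depth,
    min_pairs: int = 3,
    alpha: float = 0.01,
    window: int = 500,
) -> list:
    """Keep candidates whose support exceeds the stray-discordant background.

    A one-sided binomial test asks whether ``n_defining_pairs`` co-located
    discordant pairs are plausible given the local span depth and the
    genome-wide stray discordant fraction; kept iff the cluster has at
    least ``min_pairs`` pairs and the test rejects at ``alpha``.
    """
    if min_pairs < 1:
        raise ConfigurationError("min_pairs must be >= 1")
    usable = [p for p in pairs if p.both_unique and not p.duplicate]
    n_total = len(usable)
    n_disc = sum(1 for p in usable if p.concordant is False)
    p_bg = max(n_disc / n_total, 1e-9) if n_total else 1e-9
    out = []
    for cand in candidates:
        be = cand.breakend_a
        arr = span_depth.counts[be.chrom]
        lo, hi = max(0, be.pos - window), min(len(arr), be.pos + window)
        local = float(np.mean(arr[lo:hi])) if hi > lo else 0.0
        n_local = max(int(round(local)), cand.n_defining_pairs)
        pval = float(stats.binom.sf(cand.n_defining_pairs - 1, n_local, p_bg))
        cand.noise_pvalue = pval
        cand.kept = cand.n_defining_pairs >= min_pairs and pval < alpha
        out.append(cand)
    return out


# ----------------------------------------------------------------------
# junction-sequencing reads and anchored consensus


@dataclass
class AnchoredRead:
    read_id: str
    seq: str
    anchor_side: str  # 'a' or 'b'
    mapped_mate_pos: int


def collect_junction_sequencing_reads(
    junction: JunctionCall,
    pairs: list,
    insert_upper: float,
    include_mapped: bool = False,
) -> list:
    """Reads informative for the junction sequence.

    Returns mates of uniquely mapped "anchor" reads that sit within one
    insert length of a breakend and point toward it.  By default only
    unmapped mates are taken (the junction-sequencing reads proper); with
    ``include_mapped`` every anchor mate is returned, which is what the
    anchor strategy needs inside repeat elements where chimeric reads
    still map to a diverged copy.
    """
    out = []
    for p in pairs:
        if p.duplicate:
            continue
        for me, ue, tag in ((p.end1, p.end2, "1"), (p.end2, p.end1, "2")):
            if ue.status != "unique":
                continue
            for side, be in (("a", junction.breakend_a), ("b", junction.breakend_b)):
                if ue.chrom != be.chrom:
                    continue
                if be.side == "retains_left":
                    near = ue.strand == "+" and be.pos - insert_upper <= ue.start and ue.end <= be.pos + 50
                else:
                    near = ue.strand == "-" and ue.start >= be.pos - 50 and ue.end <= be.pos + insert_upper
                if not near:
                    continue
                # in include_mapped mode, mates of concordant pairs are still
                # excluded: where the partner locus also exists intact (repeat
                # or marker homology) they would vote the reference allele and
                # swamp the chimeric junction consensus
                if me.status == "unmapped" or (include_mapped and p.concordant is not True):
                    out.append(AnchoredRead(f"{p.pair_id}/{tag}", me.seq, side, ue.start))
    # deterministic order regardless of pair input ordering
    out.sort(key=lambda r: r.read_id)
    return out


def derive_junction_sequence(
    anchor: str,
    reads: list,
    min_overlap: int = 20,
    max_mismatch: int = 2,
    min_support: int = 2,
    max_conflict: float = 0.20,
) -> tuple:
    """Greedy anchored overlap layout; returns ``(consensus, support)``.

    The consensus starts as the known anchor flank and is extended to the
    right by reads overlapping its growing end; extension stops when read
    support drops below ``min_support``.  Columns where conflicting bases
    exceed ``max_conflict`` of the column raise
    :class:`AmbiguousConsensusError` naming the conflicting reads.
    """
    if len(reads) < 2:
        raise GcrScopeError("need at least 2 reads to derive a junction sequence")
    seqs = []
    for r in reads:
        rid, s = (r.read_id, r.seq) if hasattr(r, "seq") else (f"read{len(seqs)}", r)
        seqs.append((rid, s))

    cons = anchor
    offset0 = 0  # offset of consensus start relative to anchor start
    placements: dict = {}  # rid -> (offset, oriented_seq)

    def _try_place(rid, s):
        best = None
        for cand in (s, revcomp(s)):
            for i in range(0, max(1, len(cand) - min_overlap + 1), 7):
                seed = cand[i : i + min_overlap]
                if len(seed) < min_overlap:
                    break
                j = cons.find(seed)
                while j >= 0:
                    off = j - i
                    lo = max(0, -off)
                    hi = min(len(cand), len(cons) - off)
                    if hi - lo >= min_overlap:
                        mm = sum(
                            1
                            for x in range(lo, hi)
                            if cand[x] != cons[off + x]
                        )
                        if mm <= max_mismatch and (best is None or mm < best[0]):
                            best = (mm, off, cand)
                    j = cons.find(seed, j + 1)
        if best is not None:
            placements[rid] = (best[1], best[2])
            return True
        return False

    def _revote():
        # majority per column among placed reads, anchor as scaffold where
        # read support is thin; washes individual sequencing errors out of
        # the growing consensus so they cannot block later placements
        anchor_off = -offset0
        out = list(cons)
        counts = [dict() for _ in range(len(cons))]
        for _, (off, cand) in placements.items():
            for x, base in enumerate(cand):
                col = off + x
                if 0 <= col < len(cons):
                    counts[col][base] = counts[col].get(base, 0) + 1
        for col, cnt in enumerate(counts):
            if not cnt:
                continue
            ordered = sorted(cnt.items(), key=lambda kv: (-kv[1], kv[0]))
            in_anchor = anchor_off <= col < anchor_off + len(anchor)
            if in_anchor and ordered[0][1] < 2:
                continue
            out[col] = ordered[0][0]
        return "".join(out)

    changed = True
    while changed:
        changed = False
        for rid, s in seqs:
            if rid in placements:
                continue
            if _try_place(rid, s):
                # extend consensus with the read's right overhang
                off, cand = placements[rid]
                if off + len(cand) > len(cons):
                    cons = cons + cand[len(cons) - off :]
                if off < 0:
                    cons = cand[:-off] + cons
                    shift = -off
                    offset0 -= shift
                    placements = {
                        k: (o + shift, c) for k, (o, c) in placements.items()
                    }
                    placements[rid] = (0, cand)
                changed = True
        if changed:
            cons = _revote()

    # column-wise vote
    anchor_off = -offset0
    ncol = len(cons)
    counts = [dict() for _ in range(ncol)]
    for rid, (off, cand) in placements.items():
        for x, base in enumerate(cand):
            col = off + x
            if 0 <= col < ncol:
                counts[col][base] = counts[col].get(base, 0) + 1
    support = np.zeros(ncol, dtype=int)
    out = list(cons)
    conflicts = []
    anchor_hi = anchor_off + len(anchor)
    for col, cnt in enumerate(counts):
        tot = sum(cnt.values())
        support[col] = tot
        if not cnt:
            continue
        ordered = sorted(cnt.items(), key=lambda kv: (-kv[1], kv[0]))
        # inside the anchor the reference base stands unless >= 2 reads
        # agree otherwise: a single read's sequencing error must not
        # corrupt scaffold columns
        if anchor_off <= col < anchor_hi and ordered[0][1] < 2:
            pass
        else:
            out[col] = ordered[0][0]
        # one or two dissenting reads are sequencing errors (two reads
        # hitting the same column with the same wrong base happens at
        # 1% error rates); a genuine second haplotype brings more
        if (
            len(ordered) > 1
            and tot >= 4
            and ordered[1][1] >= 3
            and ordered[1][1] > max_conflict * tot
        ):
            conflicts.append(col)
    if conflicts:
        bad = sorted(
            rid
            for rid, (off, cand) in placements.items()
            if any(off <= c < off + len(cand) for c in conflicts)
        )
        raise AmbiguousConsensusError(
            f"irreconcilable overlaps at {len(conflicts)} columns", bad
        )
    # anchor region keeps reference support; extension requires min_support
    end = ncol
    for col in range(anchor_off + len(anchor), ncol):
        if support[col] < min_support:
            end = col
            break
    consensus = "".join(out[:end])
    return consensus, support[:end]


def measure_microhomology(junction_sequence: str, flank_a: str, flank_b: str) -> tuple:
    """Maximal fusion-point block attributable to either flank.

    ``flank_a`` is the reference sequence aligned at the start of the
    junction sequence (continuing past the fusion); ``flank_b`` is aligned
    at its end, extending backwards.  Returns
    ``(microhomology_len, inserted_sequence)``; a nonempty insertion
    implies zero microhomology.
    """
    j = junction_sequence
    a_match = 0
    for x, y in zip(j, flank_a):
        if x != y:
            break
        a_match += 1
    b_match = 0
    for x, y in zip(reversed(j), reversed(flank_b)):
        if x != y:
            break
        b_match += 1
    if a_match == 0 or b_match == 0:
        raise GcrScopeError("junction sequence does not contain either flank")
    if a_match + b_match >= len(j):
        return a_match + b_match - len(j), ""
    return 0, j[a_match : len(j) - b_match]


def detect_telomere_addition(
    breakend: Breakend,
    reads: list,
    grammar,
    ref,
    anchor_len: int = 300,
    min_seed: int = 15,
) -> Optional[TelomereAdditionCall]:
    """De novo telomere call from junction-sequencing reads.

    For a one-sided breakend retaining its right flank the consensus is
    derived leftward from the mapped anchor; a call is made iff the
    sequence beyond the breakend matches the telomeric grammar for at
    least ``min_seed`` nt.
    """
    if breakend.side != "retains_right" or len(reads) < 2:
        return None
    # keep only junction-crossing reads: reads lying wholly inside the new
    # telomeric repeat are self-similar and chain at shifted registers,
    # scrambling the assembly; a read anchored by >= 25 nt of unique flank
    # places unambiguously and still carries plenty of seed sequence
    reads = [
        r
        for r in reads
        if len(r.seq) - max(grammar.match_prefix(r.seq), grammar.match_suffix(r.seq))
        >= 25
    ]
    if len(reads) < 2:
        return None
    chrom_seq = ref.sequences[breakend.chrom]
    anchor = chrom_seq[breakend.pos : breakend.pos + anchor_len]
    # mirror: derive rightward on the reverse complement
    rc_reads = [
        AnchoredRead(r.read_id, revcomp(r.seq), r.anchor_side, r.mapped_mate_pos)
        for r in reads
    ]
    # telomeric repeats are self-similar, so some seed reads place
    # ambiguously; drop the conflicting ones and retry
    rc_cons = None
    for _ in range(4):
        try:
            rc_cons, _ = derive_junction_sequence(revcomp(anchor), rc_reads)
            break
        except AmbiguousConsensusError as err:
            bad = set(err.conflicting_reads)
            rc_reads = [r for r in rc_reads if r.read_id not in bad]
            if len(rc_reads) < 2:
                return None
        except GcrScopeError:
            return None
    if rc_cons is None:
        return None
    cons = revcomp(rc_cons)  # anchor inside; novel part on its left
    # reads overlapping the anchor's far edge may extend the consensus
    # beyond it, so locate the anchor rather than assuming it ends the string
    idx = cons.find(anchor)
    if idx < 0:
        return None
    novel_plus_ref = cons[:idx]
    # refine the breakpoint: walk left from the anchor while matching reference
    pos = breakend.pos
    i = len(novel_plus_ref)
    while i > 0 and pos > 0 and novel_plus_ref[i - 1] == chrom_seq[pos - 1]:
        i -= 1
        pos -= 1
    seed = novel_plus_ref[:i]
    run = grammar.match_suffix(seed)
    if run >= min_seed:
        return TelomereAdditionCall(
            Breakend(breakend.chrom, pos, "retains_right"),
            seed[len(seed) - run :],
            len(reads),
        )
    return None


def microhomology_oracle(junction_sequence: str, flank_a: str, flank_b: str) -> tuple:
    """Exhaustive-overlap reference implementation of microhomology.

    Enumerates every split of the junction sequence into a flank_a-prefix
    and flank_b-suffix and reports the maximal total overlap; independent
    of the incremental matcher above.
    """
    j = junction_sequence
    n = len(j)
    a_max = max(
        L for L in range(n + 1) if L <= len(flank_a) and j[:L] == flank_a[:L]
    )
    b_max = max(
        L
        for L in range(n + 1)
        if L <= len(flank_b) and (L == 0 or j[n - L :] == flank_b[len(flank_b) - L :])
    )
    if a_max == 0 or b_max == 0:
        raise GcrScopeError("junction sequence does not contain either flank")
    if a_max + b_max >= n:
        return a_max + b_max - n, ""
    return 0, j[a_max : n - b_max]
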