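"""Foldback detection and hairpin-intermediate reconstruction.

A hairpin-mediated inverted duplication leaves a same-chromosome,
same-strand junction whose centromeric side steps from 1n to 2n: the
broken arm was resected, folded back at a short inverted repeat, copied,
and replicated into a dicentric isoduplication later resolved to a
monocentric product by a secondary rearrangement (repeat-family HR,
engineered-marker HR, or microhomology-mediated fusion).

The stem/loop of the annealing site is recovered by aligning the junction
consensus to the chromosome in forward and reverse-complement orientation
around the pivot and exhaustively scanning the gap for the maximal
inverted repeat (ties: maximal stem, then smallest loop).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._seq import hamming, revcomp
from .junctions import JunctionCall


@dataclass
class FoldbackCall:
    chrom: str
    pivot: int  # start of the centromeric stem arm (= resection end)
    fold_point: int  # start of the inverted arm image (pivot + stem + loop)
    stem_len: Optional[int] = None  # None = undetermined
    loop_len: Optional[int] = None
    stem_arms: Optional[tuple] = None  # ((s1,e1),(s2,e2)) reference intervals
    resection_end: Optional[int] = None
    junction: Optional[JunctionCall] = None
    junction_sequence: Optional[str] = None


@dataclass
class SecondaryResolution:
    type: str  # 'repeat_HR' | 'marker_HR' | 'microhomology'
    partner_chrom: Optional[str]
    partner_pos: Optional[int]
    partner_name: Optional[str] = None  # repeat family / marker name
    junction: Optional[JunctionCall] = None
    microhomology_len: int = 0
    monocentric: bool = True


def detect_foldback(
    junctions: list,
    cnp,
    ref,
    max_distance: int = 10_000,
    window: int = 2_000,
    step_min: float = 0.75,
) -> list:
    """Label kept junctions that carry the foldback signature.

    Criteria: both breakends on one chromosome, same-strand orientation
    signature, separation below ``max_distance``, and a copy-number step
    to >= 1.5n on the centromeric side of the junction.
    """
    calls = []
    for j in junctions:
        if not (j.kept and j.same_chrom and j.same_strand_signature):
            continue
        pa, pb = sorted((j.breakend_a.pos, j.breakend_b.pos))
        if pb - pa > max_distance:
            continue
        chrom = j.breakend_a.chrom
        cen = ref.centromere(chrom)
        vals = cnp.values[chrom]
        if cen.start >= pb:  # centromere to the right
            cen_side = vals[pb : pb + window]
            tel_side = vals[max(0, pa - window) : pa]
        else:
            cen_side = vals[max(0, pa - window) : pa]
            tel_side = vals[pb : pb + window]
        c = np.nanmean(cen_side) if np.any(~np.isnan(cen_side)) else np.nan
        t = np.nanmean(tel_side) if np.any(~np.isnan(tel_side)) else 0.0
        t = 0.0 if np.isnan(t) else t
        if np.isnan(c) or c < 1.5 or c - t < step_min:
            continue
        calls.append(
            FoldbackCall(
                chrom=chrom,
                pivot=pa,
                fold_point=pb,
                junction=j,
                junction_sequence=j.junction_sequence,
            )
        )
    return calls


def infer_hairpin_intermediate(
    junction_sequence: str,
    chrom_seq: str,
    call: Optional[FoldbackCall] = None,
    max_stem: int = 50,
    min_stem: int = 4,
    max_loop: int = 250,
    stem_mismatches: int = 1,
    seed_len: int = 30,
    noisy: bool = False,
) -> FoldbackCall:
    """Recover pivot, stem and loop from a foldback junction consensus.

    The consensus spans the inversion point: its left flank is the
    reverse-complement image of ``chrom[p:...]`` and its right flank is
    ``chrom[p + 2s + l:]``.  Anchoring each flank to the chromosome pins
    the sum ``p + fold0`` (fold0 = p + 2s + l) exactly, independent of
    where the fold-adjacent columns stop matching — robust even when the
    loop columns of the consensus are noisy, as the junction region is
    quasi-palindromic and read orientation is locally ambiguous there.
    Candidate pivots are then scanned under that constraint; the stem is
    the maximal inverted repeat (ties: smallest loop), and each candidate
    is validated against the consensus outside its loop columns.
    """
    j = junction_sequence
    out = call or FoldbackCall(chrom="", pivot=0, fold_point=0)
    out.junction_sequence = j
    out.stem_len = None
    out.loop_len = None

    right = _anchor_flank(j, chrom_seq, seed_len, from_end=True)
    left = _anchor_flank(revcomp(j), chrom_seq, seed_len, from_end=True)
    if right is None or left is None:
        return out
    # a_R(col) = col + off_r maps consensus columns to the forward flank;
    # a_L(col) = c_sum - col maps columns to the reverse-complement image.
    off_r = right
    c_sum = left + (len(j) - 1)
    # p + fold0 is column-independent: a_L(J-1) + a_R(J) for any junction J
    total = c_sum + 1 + off_r
    # walk limits: leftmost column verified as forward-flank content and
    # rightmost column verified as reverse-image content.  The junction
    # column must fall between them (the walks overlap through the stem
    # and may stop short inside the quasi-palindromic core when the
    # consensus is read-derived).
    from ._seq import complement

    col_f = len(j)
    mism = 0
    for c in range(len(j) - 1, -1, -1):
        if c + off_r < 0 or c + off_r >= len(chrom_seq) or j[c] != chrom_seq[c + off_r]:
            mism += 1  # tolerate isolated consensus errors
            if mism > 2:
                break
        else:
            col_f = c
    col_r = -1
    mism = 0
    for c in range(len(j)):
        a = c_sum - c
        if a < 0 or a >= len(chrom_seq) or j[c] != complement(chrom_seq[a]):
            mism += 1
            if mism > 2:
                break
        else:
            col_r = c

    # exact stems first: with a mismatch allowance the maximal-stem
    # tie-break would systematically over-grow one base into the loop
    best = None
    p_hi = (total - 2 * min_stem) // 2
    p_lo = max(0, (total - (2 * max_stem + max_loop)) // 2)
    for allowed in range(stem_mismatches + 1):
        for p in range(p_lo, p_hi + 1):
            g = total - 2 * p
            for s in range(min(max_stem, g // 2), min_stem - 1, -1):
                loop = g - 2 * s
                if loop > max_loop:
                    break
                arm1 = chrom_seq[p : p + s]
                arm2 = chrom_seq[p + g - s : p + g]
                if len(arm2) < s or hamming(arm1, revcomp(arm2), allowed) > allowed:
                    continue
                J = g + p - off_r  # candidate junction column
                slack = (s + loop) if noisy else 0
                if not (col_f - 2 <= J <= col_r + 3 + slack):
                    continue
                score = _validate_candidate(j, chrom_seq, p, s, loop, off_r)
                if score is None:
                    continue
                key = (s, -loop, score)
                if best is None or key > best[0]:
                    best = (key, p, s, loop)
                break  # maximal stem found for this pivot
        if best is not None:
            break
    if best is None:
        return out
    _, p, s, loop = best
    out.pivot = p
    out.fold_point = p + s + loop
    out.resection_end = p
    out.stem_len = s
    out.loop_len = loop
    out.stem_arms = ((p, p + s), (p + s + loop, p + 2 * s + loop))
    return out


def _validate_candidate(j, chrom_seq, p, s, loop, off_r, flank: int = 30):
    """Check the consensus against the junction implied by (p, stem, loop).

    Compares the reverse-complement image columns left of the junction,
    skipping the loop image (orientation-ambiguous reads corrupt the
    quasi-palindromic core); returns a match score or None when the
    non-loop columns disagree.
    """
    fold0 = p + 2 * s + loop
    J = fold0 - off_r  # junction column in the consensus
    if not (0 < J <= len(j)):
        return None
    matches = 0
    checked = 0
    bad = 0
    from ._seq import complement

    for u in range(min(2 * s + loop + flank, J, len(chrom_seq) - p)):
        col = J - 1 - u
        if s <= u < s + loop:
            continue
        ok = j[col] == complement(chrom_seq[p + u])
        checked += 1
        if ok:
            matches += 1
        else:
            bad += 1
            if bad > 2:
                return None
    if checked < s + 5:
        return None
    return matches


def _anchor_flank(query: str, chrom_seq: str, seed_len: int, from_end: bool = True):
    """Map the query's right end onto the chromosome (forward strand).

    Returns the alignment offset ``off`` such that query column c
    corresponds to chromosome position c + off, or None when no unique
    seed is found.  Several seed offsets are tried so an isolated
    consensus error cannot break the anchoring.
    """
    n = len(query)
    for back in (0, seed_len, 2 * seed_len, 3 * seed_len):
        start = n - seed_len - back
        if start < 0:
            return None
        seed = query[start : start + seed_len]
        hit = chrom_seq.find(seed)
        if hit < 0 or chrom_seq.find(seed, hit + 1) >= 0:
            continue
        return hit - start
    return None


def exhaustive_inverted_repeat_scan(
    chrom_seq: str, lo: int, hi: int, min_stem: int = 4, max_stem: int = 50,
    max_loop: int = 200,
) -> list:
    """All inverted repeats in a region (oracle for stem/loop inference)."""
    found = []
    for p in range(lo, hi):
        for s in range(max_stem, min_stem - 1, -1):
            for l in range(0, max_loop + 1):
                e = p + 2 * s + l
                if e > hi:
                    continue
                arm1 = chrom_seq[p : p + s]
                arm2 = chrom_seq[p + s + l : e]
                if arm1 == revcomp(arm2):
                    found.append((p, s, l))
                    break
    return found


def type_secondary_resolution(
    foldback: FoldbackCall,
    junctions: list,
    ref,
    path=None,
) -> Optional[SecondaryResolution]:
    """Classify the event that resolved the dicentric isoduplication.

    Looks for a kept junction (other than the foldback itself) with one
    breakend on the duplicated, inverted side of the assay chromosome.
    Typed as repeat_HR when both breakends fall in annotated repeat
    features of one family, marker_HR when they pair the engineered URA3
    homologies, else microhomology.
    """
    chrom = foldback.chrom
    cen = ref.centromere(chrom)
    lo, hi = foldback.pivot, cen.start
    cands = []
    for j in junctions:
        if not j.kept or j is foldback.junction:
            continue
        for be, other in ((j.breakend_a, j.breakend_b), (j.breakend_b, j.breakend_a)):
            if be.chrom == chrom and lo - 500 <= be.pos <= hi + 500:
                cands.append((j, be, other))
                break
    if not cands:
        warnings.warn(
            "dicentric intermediate with no resolving junction found; "
            "product reported as an unresolved intermediate",
            stacklevel=2,
        )
        return None
    j, be, other = cands[0]
    fam_be = _repeat_family_at(ref, be)
    fam_other = _repeat_family_at(ref, other)
    if fam_be and fam_be == fam_other:
        partner_feat = _feature_at(ref, other)
        return SecondaryResolution(
            "repeat_HR",
            other.chrom,
            other.pos,
            partner_name=partner_feat.name if partner_feat else fam_other,
            junction=j,
            microhomology_len=j.microhomology_len,
        )
    kinds = {_marker_kind_at(ref, be), _marker_kind_at(ref, other)}
    if kinds == {"marker_ura3_52", "cassette"}:
        return SecondaryResolution(
            "marker_HR",
            other.chrom,
            other.pos,
            partner_name="URA3",
            junction=j,
            microhomology_len=j.microhomology_len,
        )
    return SecondaryResolution(
        "microhomology",
        other.chrom,
        other.pos,
        junction=j,
        microhomology_len=j.microhomology_len,
    )


def _feature_at(ref, be, slop: int = 120):
    for f in ref.features_at(be.chrom, be.pos, slop):
        if f.kind.startswith("repeat_") or f.kind == "segdup":
            return f
    return None


def _repeat_family_at(ref, be, slop: int = 120) -> Optional[str]:
    f = _feature_at(ref, be, slop)
    if f is None:
        return None
    return "segdup" if f.kind == "segdup" else f.kind.split("_", 1)[1]


def _marker_kind_at(ref, be, slop: int = 120) -> Optional[str]:
    for f in ref.features_at(be.chrom, be.pos, slop):
        if f.kind in ("marker_ura3_52", "cassette"):
            return f.kind
    return None
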