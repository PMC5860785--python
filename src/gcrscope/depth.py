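"""Read-depth and span-depth copy-number profiling.

Read depth counts, per base, how many times the base was read; span depth
additionally counts bases spanned by the unread interior of a pair's
fragment.  Only pairs in which both ends map uniquely contribute.  Read
depth is scaled by the median read depth of concordant pairs over
uniquely mappable territory to place the genome at 1n, then segmented by
a windowed-median changepoint merge.  Span depth feeds the junction noise
filter; whole-chromosome disomies are called from the scaled profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigurationError


@dataclass
class DepthProfile:
    kind: str  # 'read_depth' | 'span_depth'
    counts: dict  # chrom -> int array (per base)

    def chrom(self, name: str) -> np.ndarray:
        return self.counts[name]


@dataclass
class CopyNumberProfile:
    values: dict  # chrom -> float array; NaN where masked
    scaling_factor: float
    mask: dict  # chrom -> bool array; True = uniquely mappable

    def unmasked_values(self, chrom: Optional[str] = None) -> np.ndarray:
        chroms = [chrom] if chrom else list(self.values)
        parts = [self.values[c][self.mask[c]] for c in chroms]
        return np.concatenate(parts) if parts else np.array([])


@dataclass
class CopySegment:
    chrom: str
    start: int
    end: int
    copy_state: int
    mean_depth: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DisomyCall:
    chrom: str
    mean_copy: float
    fraction_2n: float
    disomic: bool


def _add_interval(diff: np.ndarray, start: int, end: int) -> None:
    n = len(diff) - 1
    s, e = max(0, start), min(n, end)
    if e > s:
        diff[s] += 1
        diff[e] -= 1


def build_depth_profiles(pairs: list, ref) -> tuple:
    """(read_depth, span_depth) from deduplicated both-unique pairs."""
    rd = {c: np.zeros(len(s) + 1, dtype=np.int32) for c, s in ref.sequences.items()}
    sd = {c: np.zeros(len(s) + 1, dtype=np.int32) for c, s in ref.sequences.items()}
    for p in pairs:
        if p.duplicate or not p.both_unique:
            continue
        e1, e2 = p.end1, p.end2
        for e in (e1, e2):
            _add_interval(rd[e.chrom], e.start, e.end)
        if e1.chrom == e2.chrom and e1.strand != e2.strand:
            plus, minus = (e1, e2) if e1.strand == "+" else (e2, e1)
            if plus.start <= minus.end:  # inward-facing: span the fragment
                _add_interval(sd[e1.chrom], min(e1.start, e2.start), max(e1.end, e2.end))
                continue
        for e in (e1, e2):
            _add_interval(sd[e.chrom], e.start, e.end)
    read_depth = DepthProfile("read_depth", {c: np.cumsum(a[:-1]) for c, a in rd.items()})
    span_depth = DepthProfile("span_depth", {c: np.cumsum(a[:-1]) for c, a in sd.items()})
    return read_depth, span_depth


def mappability_mask(ref, k: int = 100) -> dict:
    """Per-base uniquely-mappable territory from exact k-mer uniqueness.

    A k-mer is unique when it occurs once in the genome counting both
    strands; every base covered by at least one unique k-mer is mappable.
    """
    from ._seq import revcomp

    counts: dict = {}
    for chrom, seq in ref.sequences.items():
        for p in range(len(seq) - k + 1):
            w = seq[p : p + k]
            counts[w] = counts.get(w, 0) + 1
            rc = revcomp(w)
            if rc != w:
                counts[rc] = counts.get(rc, 0) + 1
    mask = {}
    for chrom, seq in ref.sequences.items():
        diff = np.zeros(len(seq) + 1, dtype=np.int32)
        for p in range(len(seq) - k + 1):
            if counts[seq[p : p + k]] == 1:
                diff[p] += 1
                diff[p + k] -= 1
        mask[chrom] = np.cumsum(diff[:-1]) > 0
    return mask


def scale_profile(
    read_depth: DepthProfile,
    concordant_depth: DepthProfile,
    mask: dict,
    smooth: int = 101,
) -> CopyNumberProfile:
    """Scale read depth by the median concordant read depth (1n = 1.0).

    The concordant median is taken on a lightly smoothed profile: per-base
    depths are integers, so the raw median is quantized to whole units
    (>2% granularity below ~50x) and a knife-edge distribution would make
    the 1n level flip by a full unit between samples.
    """
    kernel = np.ones(smooth) / smooth
    med_parts = [
        np.convolve(concordant_depth.counts[c].astype(float), kernel, mode="same")[mask[c]]
        for c in mask
    ]
    allv = np.concatenate(med_parts)
    factor = float(np.median(allv)) if allv.size else 0.0
    if factor <= 0:
        raise ConfigurationError("zero median concordant depth; cannot scale")
    values = {}
    for c, arr in read_depth.counts.items():
        v = arr.astype(float) / factor
        v[~mask[c]] = np.nan
        values[c] = v
    return CopyNumberProfile(values, factor, mask)


def segment_profile(
    cnp: CopyNumberProfile, window: int = 500, min_seg: int = 1500
) -> list:
    """Sliding-window median segmentation with changepoint merge.

    Adjacent windows with the same rounded copy state are merged; runs
    shorter than ``min_seg`` are absorbed into the neighbour with the
    closer mean.  Transition coordinates are reported at window resolution.
    """
    if min_seg < window:
        raise ConfigurationError("min_seg must be >= window")
    segments = []
    for chrom, v in cnp.values.items():
        n = len(v)
        nwin = max(1, n // window)
        states, means, bounds = [], [], []
        for w in range(nwin):
            s, e = w * window, min((w + 1) * window, n) if w < nwin - 1 else n
            vals = v[s:e]
            good = vals[~np.isnan(vals)]
            if good.size < (e - s) * 0.25:
                m = np.nan
            else:
                m = float(np.median(good))
            states.append(-1 if np.isnan(m) else int(round(m)))
            means.append(m)
            bounds.append((s, e))
        # fill no-data windows with the previous informative state
        last = next((s for s in states if s >= 0), 0)
        for i, s in enumerate(states):
            if s < 0:
                states[i] = last
            else:
                last = s
        # merge runs of equal state
        runs = []  # [state, start_w, end_w]
        for i, s in enumerate(states):
            if runs and runs[-1][0] == s:
                runs[-1][2] = i + 1
            else:
                runs.append([s, i, i + 1])
        # absorb short runs
        def run_len(r):
            return bounds[r[2] - 1][1] - bounds[r[1]][0]

        def run_mean(r):
            vals = [means[i] for i in range(r[1], r[2]) if not np.isnan(means[i])]
            return float(np.mean(vals)) if vals else float(r[0])

        changed = True
        while changed and len(runs) > 1:
            changed = False
            for i, r in enumerate(runs):
                if run_len(r) >= min_seg:
                    continue
                nbrs = [runs[j] for j in (i - 1, i + 1) if 0 <= j < len(runs)]
                tgt = min(nbrs, key=lambda nb: abs(run_mean(nb) - run_mean(r)))
                tgt[1] = min(tgt[1], r[1])
                tgt[2] = max(tgt[2], r[2])
                runs.pop(i)
                # re-merge equal neighbours
                j = 0
                while j < len(runs) - 1:
                    if runs[j][0] == runs[j + 1][0]:
                        runs[j][2] = runs[j + 1][2]
                        runs.pop(j + 1)
                    else:
                        j += 1
                changed = True
                break
        for s, w0, w1 in runs:
            seg_vals = v[bounds[w0][0] : bounds[w1 - 1][1]]
            good = seg_vals[~np.isnan(seg_vals)]
            segments.append(
                CopySegment(
                    chrom,
                    bounds[w0][0],
                    bounds[w1 - 1][1],
                    max(s, 0),
                    float(np.mean(good)) if good.size else float("nan"),
                )
            )
    return segments


def call_disomies(
    cnp: CopyNumberProfile,
    min_fraction: float = 0.95,
    band: tuple = (1.5, 2.5),
    mean_band: tuple = (1.8, 2.2),
    edge_trim: int = 1000,
) -> list:
    """Whole-chromosome 2n calls; bimodal GCR duplications are excluded.

    A chromosome is disomic iff >= ``min_fraction`` of its mappable bases
    lie in ``band`` and its mean scaled copy lies in ``mean_band``.
    ``edge_trim`` bases at each chromosome end are ignored: fragment
    sampling ramps down there and depresses the depth structurally.
    """
    calls = []
    for chrom in cnp.values:
        v = cnp.values[chrom]
        m = cnp.mask[chrom]
        sl = slice(edge_trim, max(edge_trim, len(v) - edge_trim))
        vals = v[sl][m[sl]]
        if vals.size == 0:
            continue
        frac = float(np.mean((vals >= band[0]) & (vals <= band[1])))
        mean = float(np.mean(vals))
        disomic = frac >= min_fraction and mean_band[0] <= mean <= mean_band[1]
        calls.append(DisomyCall(chrom, mean, frac, disomic))
    return calls
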