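"""Foldback detection and hairpin stem/loop inference."""

import warnings

import numpy as np
import pytest

from gcrscope._seq import complement, random_dna, revcomp
from gcrscope.events import Breakend
from gcrscope.hairpin import (
    FoldbackCall,
    detect_foldback,
    infer_hairpin_intermediate,
    type_secondary_resolution,
)
from gcrscope.junctions import JunctionCall


def make_foldback_sequence(rng, stem, loop, flank=400):
    """Error-free junction consensus across an implanted foldback.

    Returns ``(chrom_seq, junction_sequence, pivot)``: the chromosome
    carries a clean inverted repeat (no chance outward/inward stem
    extension) at ``pivot``; the consensus is the derivative
    ``revcomp(chrom[p:]) tail + chrom[p+2s+l:]`` segment.
    """
    while True:
        chrom = list(random_dna(rng, 2 * flank + 2 * stem + loop + 200))
        p = flank + 100
        arm = random_dna(rng, stem)
        site = arm + random_dna(rng, loop) + revcomp(arm)
        chrom[p : p + len(site)] = site
        # clean: no outward or into-loop extension by chance pairing
        after = p + 2 * stem + loop
        if chrom[after] == complement(chrom[p - 1]):
            chrom[after] = _other(chrom[after])
        if loop >= 1 and chrom[p + stem] == complement(chrom[p + stem + loop - 1]):
            chrom[p + stem + loop - 1] = _other(chrom[p + stem + loop - 1])
        chrom = "".join(chrom)
        jseq = revcomp(chrom[p : p + flank]) + chrom[after : after + flank]
        return chrom, jseq, p


def _other(base):
    return "A" if base != "A" else "C"


@pytest.mark.parametrize("stem", [4, 5, 8, 13, 21, 34, 50])
@pytest.mark.parametrize("loop", [0, 1, 6, 37, 118, 200])
def test_stem_loop_recovered_exactly(stem, loop):
    rng = np.random.default_rng(1000 + 7 * stem + loop)
    chrom, jseq, p = make_foldback_sequence(rng, stem, loop)
    call = infer_hairpin_intermediate(jseq, chrom)
    assert (call.stem_len, call.loop_len, call.pivot) == (stem, loop, p)
    assert call.resection_end == p


def test_palindromic_stem_zero_loop():
    """Loop 0: the annealing site is a perfect palindrome; the pivot sits
    at its centre and the loop is reported as zero."""
    rng = np.random.default_rng(77)
    chrom, jseq, p = make_foldback_sequence(rng, 12, 0)
    call = infer_hairpin_intermediate(jseq, chrom)
    assert (call.stem_len, call.loop_len) == (12, 0)


def test_exhaustive_scan_agrees_with_inference():
    """Independent oracle: scan every inverted repeat near the pivot."""
    from gcrscope.hairpin import exhaustive_inverted_repeat_scan

    rng = np.random.default_rng(5)
    chrom, jseq, p = make_foldback_sequence(rng, 10, 8)
    call = infer_hairpin_intermediate(jseq, chrom)
    found = exhaustive_inverted_repeat_scan(chrom, p - 5, p + 60, min_stem=8, max_stem=20)
    assert (p, 10, 8) in found
    best = max(found, key=lambda t: (t[1], -t[2]))
    assert (best[1], best[2]) == (call.stem_len, call.loop_len)


def test_no_stem_reported_as_undetermined():
    """No inverted repeat >= 4 bp at the pivot: arm alignments only.

    The background is rejection-sampled with an independent exhaustive
    scan so no chance inverted repeat satisfies the flank constraint.
    """
    from gcrscope._seq import hamming

    rng = np.random.default_rng(9)
    while True:
        chrom = random_dna(rng, 1000)
        # flank alignments pin p + fold0 = 900 (p = 400, gap = 100)
        if not any(
            hamming(chrom[400 : 400 + s], revcomp(chrom[500 - s : 500])) <= 1
            for s in range(4, 49)
        ):
            break
    jseq = revcomp(chrom[400:700]) + chrom[500:800]
    call = infer_hairpin_intermediate(jseq, chrom)
    assert call.stem_len is None


def test_detect_foldback_on_implanted_hairpin(analyzed):
    truth, res = analyzed["hairpin_repeat_HR"]
    assert len(res.foldbacks) == 1
    fb = res.foldbacks[0]
    assert (fb.stem_len, fb.loop_len) == (truth.stem_len, truth.loop_len)
    assert fb.pivot == truth.pivot
    assert fb.resection_end == truth.resection_end


def test_foldback_breakends_exact_after_inference(analyzed):
    truth, res = analyzed["hairpin_microhomology"]
    fbj = truth.junctions[0]
    fb = res.foldbacks[0]
    det = next(
        j for j in res.kept_junctions if j.same_chrom and j.same_strand_signature
    )
    assert {det.breakend_a.pos, det.breakend_b.pos} == {
        fbj.breakend_a.pos,
        fbj.breakend_b.pos,
    }


def test_translocation_is_not_foldback(analyzed, ref):
    _, res = analyzed["micro_translocation"]
    assert res.foldbacks == []


def test_no_copy_step_no_foldback(ref, unrearranged_result):
    """A same-strand junction without a 1n->2n step (reciprocal-style
    inversion) must not be labelled foldback."""
    cnp = unrearranged_result.copy_number  # flat 1n everywhere
    j = JunctionCall(
        Breakend("chrV", 8_000, "retains_right"),
        Breakend("chrV", 8_300, "retains_right"),
        n_defining_pairs=10,
        orientation=("-", "-"),
        kept=True,
    )
    assert detect_foldback([j], cnp, ref) == []


@pytest.mark.parametrize(
    "key,expected",
    [
        ("hairpin_repeat_HR", "repeat_HR"),
        ("hairpin_microhomology", "microhomology"),
    ],
)
def test_secondary_resolution_typing(analyzed, key, expected):
    truth, res = analyzed[key]
    assert truth.secondary_type == expected
    assert res.secondary is not None
    assert res.secondary.type == expected
    assert res.call.secondary_type == expected


def test_marker_hr_resolution(ref, ctx):
    from gcrscope.events import GcrEventSpec, implant_gcr
    from gcrscope.pipeline import analyze_isolate
    from gcrscope.readsim import ReadSimConfig, simulate_read_pairs

    spec = GcrEventSpec(
        "hairpin_inverted_duplication",
        8_400,
        {"stem_len": 8, "loop_len": 6, "secondary_resolution": "marker_HR"},
    )
    genome, truth = implant_gcr(ref, spec, np.random.default_rng(61))
    reads, _ = simulate_read_pairs(genome, ReadSimConfig(rng_seed=62))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = analyze_isolate(ctx, reads)
    assert res.secondary is not None and res.secondary.type == "marker_HR"
    assert res.call.event_class == "hairpin_inverted_duplication"
    assert res.call.hph_retained is True


def test_unresolved_dicentric_warns(analyzed, ref):
    _, res = analyzed["hairpin_repeat_HR"]
    fb = res.foldbacks[0]
    with pytest.warns(UserWarning, match="dicentric"):
        out = type_secondary_resolution(fb, [fb.junction], ref)
    assert out is None
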