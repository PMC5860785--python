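"""Junction discovery: clustering, noise filtering, anchored consensus,
telomere-addition detection and microhomology measurement."""

import numpy as np
import pytest

from gcrscope._seq import random_dna, revcomp
from gcrscope.errors import AmbiguousConsensusError, ConfigurationError, GcrScopeError
from gcrscope.junctions import (
    AnchoredRead,
    JunctionCall,
    cluster_discordant_pairs,
    derive_junction_sequence,
    filter_against_noise,
    measure_microhomology,
    microhomology_oracle,
)
from gcrscope.events import Breakend


# ----------------------------------------------------------------- clustering


def test_translocation_cluster(analyzed, ref):
    truth, res = analyzed["micro_translocation"]
    kept = res.kept_junctions
    assert len(kept) == 1
    j = kept[0]
    assert j.n_defining_pairs >= 5
    tpos = {
        (truth.junctions[0].breakend_a.chrom, truth.junctions[0].breakend_a.pos),
        (truth.junctions[0].breakend_b.chrom, truth.junctions[0].breakend_b.pos),
    }
    dpos = {(j.breakend_a.chrom, j.breakend_a.pos), (j.breakend_b.chrom, j.breakend_b.pos)}
    assert dpos == tpos  # exact: the junction sequence resolved
    assert j.microhomology_len == truth.junctions[0].microhomology_len
    assert j.noise_pvalue < 1e-6


def test_foldback_cluster_signature(analyzed):
    _, res = analyzed["hairpin_repeat_HR"]
    fb = [j for j in res.kept_junctions if j.same_chrom and j.same_strand_signature]
    assert len(fb) == 1
    assert fb[0].breakend_a.chrom == "chrV"


def test_singleton_candidate_filtered(clean_pairs, ref):
    pairs, model, _ = clean_pairs
    from gcrscope.depth import build_depth_profiles

    _, sd = build_depth_profiles(pairs, ref)
    cand = JunctionCall(
        Breakend("chrV", 5_000, "retains_left"),
        Breakend("chrII", 9_000, "retains_right"),
        n_defining_pairs=1,
    )
    out = filter_against_noise([cand], pairs, sd)
    assert not out[0].kept


def test_unrearranged_simulation_has_no_kept_junctions(unrearranged_result):
    assert unrearranged_result.kept_junctions == []
    assert unrearranged_result.call.event_class is None


def test_min_pairs_validation(clean_pairs, ref):
    pairs, _, _ = clean_pairs
    from gcrscope.depth import build_depth_profiles

    _, sd = build_depth_profiles(pairs, ref)
    with pytest.raises(ConfigurationError):
        filter_against_noise([], pairs, sd, min_pairs=0)


# ------------------------------------------------------------- consensus


def _shred(seq, rng, read_len=100, step=11, tag="r"):
    reads = []
    for i, start in enumerate(range(0, len(seq) - read_len + 1, step)):
        s = seq[start : start + read_len]
        if rng.random() < 0.5:
            s = revcomp(s)
        reads.append(AnchoredRead(f"{tag}{i:03d}", s, "a", start))
    return reads


def test_consensus_recovers_exact_junction(rng):
    rng = np.random.default_rng(17)
    left = random_dna(rng, 400)
    right = random_dna(rng, 400)
    derivative = left + right
    anchor = left[:300]
    reads = _shred(derivative[150:650], rng)
    cons, support = derive_junction_sequence(anchor, reads)
    assert cons == derivative[: len(cons)]
    assert len(cons) >= 550


def test_mixed_junction_reads_raise_ambiguity():
    """Reads from two junctions sharing an anchor but diverging sparsely
    beyond it both place, and their systematic disagreement is reported
    as an ambiguous consensus naming the conflicting reads."""
    rng = np.random.default_rng(18)
    left = random_dna(rng, 300)
    right = random_dna(rng, 300)
    d1 = left + right
    # plant one substitution every 60 bp beyond the shared flank
    alt = list(right)
    for pos in range(20, 280, 60):
        alt[pos] = "A" if alt[pos] != "A" else "C"
    d2 = left + "".join(alt)
    reads = _shred(d1[100:500], rng, tag="x") + _shred(d2[100:500], rng, tag="y")
    with pytest.raises(AmbiguousConsensusError) as exc:
        derive_junction_sequence(left[:280], reads)
    assert exc.value.conflicting_reads


def test_consensus_needs_two_reads():
    with pytest.raises(GcrScopeError):
        derive_junction_sequence("A" * 100, [])


def test_junction_sequencing_reads_recovered(analyzed):
    _, res = analyzed["interstitial_deletion"]
    j = res.kept_junctions[0]
    assert j.n_sequencing_reads >= 3
    assert j.junction_sequence is not None
    assert j.microhomology_len == 7  # the implanted block, measured exactly


def test_anchor_into_unannotated_ty_flagged(ref, ctx):
    """A junction whose consensus runs into the hidden Ty element is
    flagged repeat-entering (anchor-based discovery of unannotated
    repeats)."""
    from gcrscope.pipeline import _consensus_enters_repeat

    hidden = ref.hidden_features[0]
    cons = (
        ref.sequences["chrV"][8_000:8_200]
        + ref.sequences[hidden.chrom][hidden.start : hidden.start + 80]
    )
    assert _consensus_enters_repeat(cons, ref)
    plain = ref.sequences["chrV"][8_000:8_400]
    assert not _consensus_enters_repeat(plain, ref)


# -------------------------------------------------------- telomere addition


def test_telomere_addition_detected_at_truth_breakpoint(analyzed):
    truth, res = analyzed["telomere_addition"]
    assert len(res.telomere_calls) == 1
    call = res.telomere_calls[0]
    a = truth.junctions[0].breakend_b.pos
    assert abs(call.breakend.pos - a) <= 5
    assert len(call.seed_sequence) >= 15
    assert res.call.event_class == "telomere_addition"


def test_deletion_junction_is_not_telomere_addition(analyzed):
    _, res = analyzed["interstitial_deletion"]
    assert res.telomere_calls == []


def test_short_seed_below_threshold_rejected(ref):
    from gcrscope.junctions import detect_telomere_addition

    be = Breakend("chrV", 8_000, "retains_right")
    # reads carrying only 10 nt of telomeric sequence beyond the junction
    rng = np.random.default_rng(21)
    seed10 = ref.grammar.left_telomere(rng, 10)
    flank = ref.sequences["chrV"][8_000:8_300]
    derivative = seed10 + flank
    reads = [
        AnchoredRead(f"t{i}", derivative[i * 7 : i * 7 + 100], "a", 8_000)
        for i in range(20)
    ]
    call = detect_telomere_addition(be, reads, ref.grammar, ref)
    assert call is None


# ---------------------------------------------------------- microhomology


def test_microhomology_trivial_cases():
    # flanks sharing no overlap at the fusion
    j = "ACGT" + "TACG"
    assert measure_microhomology(j, "ACGTGGCC", "CCGGTACG") == (0, "")


def test_microhomology_error_when_flank_absent():
    with pytest.raises(GcrScopeError):
        measure_microhomology("AAAACCCC", "GGGG", "TTTT")


@pytest.mark.parametrize("h,ins", [(0, 0), (3, 0), (7, 0), (12, 0), (0, 3), (0, 8)])
def test_microhomology_matches_oracle(h, ins):
    """Incremental matcher equals the exhaustive-overlap oracle on
    engineered junctions."""
    rng = np.random.default_rng(100 + h * 10 + ins)
    for _ in range(50):
        jseq, fa, fb = make_junction(rng, h, ins)
        got = measure_microhomology(jseq, fa, fb)
        oracle = microhomology_oracle(jseq, fa, fb)
        assert got == oracle == (h, "" if h else jseq[60 : 60 + ins])


def _force_diff(base):
    return "A" if base != "A" else "C"


def make_junction(rng, h, ins_len, flank=60):
    """Engineer ``L + ins + rest`` with exactly ``h`` bp of fusion-point
    microhomology (mismatches planted just outside the block so the
    maximal overlap is unambiguous)."""
    assert not (h and ins_len)
    L = random_dna(rng, flank)
    rest = random_dna(rng, flank)
    ins = random_dna(rng, ins_len)
    fa_cont = list(random_dna(rng, 40))
    fb_pre = list(random_dna(rng, 40))
    jseq = L + ins + rest
    # block maximality: one mismatch immediately outside each flank match
    first_after_L = (ins + rest)[0]
    if fa_cont[0] == first_after_L:
        fa_cont[0] = _force_diff(first_after_L)
    last_unshared = ins[-1] if ins else L[-(h + 1)]
    if fb_pre[-1] == last_unshared:
        fb_pre[-1] = _force_diff(last_unshared)
    fa = L + "".join(fa_cont)
    fb = "".join(fb_pre) + (L[-h:] if h else "") + rest
    return jseq, fa, fb
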