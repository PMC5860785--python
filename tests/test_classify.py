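"""Path reconstruction, five-class assignment, PFGE groups, spectrum."""

import numpy as np
import pytest

from gcrscope.classify import GcrCall, assign_group, tabulate_spectrum


def test_translocation_path(analyzed, ref):
    truth, res = analyzed["micro_translocation"]
    path = res.path
    assert path.terminal == "reference_telomere"
    chroms = [s.chrom for s in path.steps]
    assert chroms[0] == "chrV" and chroms[-1] == "chrIII"
    assert path.centromere_count == 1
    assert path.predicted_length == truth.derivative_length


def test_telomere_addition_path(analyzed):
    truth, res = analyzed["telomere_addition"]
    assert res.path.terminal == "de_novo_telomere"
    assert len([s for s in res.path.steps if s.orientation == "-"]) == 0
    # the retained-reference part is exact; the de novo telomeric seed is
    # repetitive terminal sequence, recoverable only as far as individual
    # junction-crossing reads extend into it (a lower bound on its length)
    ref_part = truth.derivative_length - len(truth.telomere_seed)
    seed_part = res.path.predicted_length - ref_part
    assert 15 <= seed_part <= len(truth.telomere_seed)


def test_hairpin_path_contains_inverted_step(analyzed):
    truth, res = analyzed["hairpin_repeat_HR"]
    inverted = [s for s in res.path.steps if s.orientation == "-"]
    assert len(inverted) == 1
    assert inverted[0].chrom == "chrV"
    assert res.path.centromere_count == 1
    assert res.path.terminal == "reference_telomere"


def test_hairpin_microhomology_path_length_exact(analyzed):
    truth, res = analyzed["hairpin_microhomology"]
    assert res.path.predicted_length == truth.derivative_length


def test_deletion_path_length_exact(analyzed):
    truth, res = analyzed["interstitial_deletion"]
    assert res.path.predicted_length == truth.derivative_length


@pytest.mark.parametrize(
    "key",
    [
        "telomere_addition",
        "interstitial_deletion",
        "micro_translocation",
        "homology_translocation",
        "hairpin_repeat_HR",
        "hairpin_microhomology",
    ],
)
def test_classification_matches_truth(analyzed, key):
    truth, res = analyzed[key]
    assert res.call.event_class == truth.event_class
    assert res.call.group == truth.group
    assert res.call.hph_retained == truth.hph_retained


def test_hairpin_precedence_over_translocation(analyzed):
    """A hairpin resolved through a cross-chromosome microhomology junction
    is classed as hairpin, not translocation."""
    truth, res = analyzed["hairpin_microhomology"]
    assert res.call.event_class == "hairpin_inverted_duplication"
    assert res.call.secondary_type == "microhomology"


def test_group_rules():
    base = dict(isolate_id="x", event_class=None, group=None)
    telo = GcrCall(**base, hph_retained=False, predicted_length=22_000)
    assert assign_group(telo, 30_000) == 2
    keep = GcrCall(**base, hph_retained=True, predicted_length=25_000)
    assert assign_group(keep, 30_000) == 3
    big = GcrCall(**base, hph_retained=False, predicted_length=30_000 + 150_000)
    assert assign_group(big, 30_000) == 1
    # within the size margin: not group 1
    margin = GcrCall(**base, hph_retained=True, predicted_length=30_500)
    assert assign_group(margin, 30_000) == 3


def test_spectrum_fractions():
    calls = [
        GcrCall(f"i{k}", "telomere_addition", 2, False, 1) for k in range(8)
    ] + [GcrCall(f"d{k}", "interstitial_deletion", 3, True, 1) for k in range(2)]
    df = tabulate_spectrum({"wt": calls})
    assert df.loc["wt", "total"] == 10
    assert df.loc["wt", "frac_telomere_addition"] == pytest.approx(0.8)
    assert df.loc["wt", "frac_interstitial_deletion"] == pytest.approx(0.2)


def test_spectrum_empty_genotype_flagged():
    df = tabulate_spectrum({"empty": []})
    assert df.loc["empty", "total"] == 0
    assert np.isnan(df.loc["empty", "frac_telomere_addition"])


def test_spectrum_recovers_multinomial_mixture():
    rng = np.random.default_rng(3)
    classes = [
        "telomere_addition",
        "interstitial_deletion",
        "hairpin_inverted_duplication",
        "micro_nonhomology_translocation",
        "homology_translocation",
    ]
    probs = np.array([0.4, 0.1, 0.3, 0.1, 0.1])
    draws = rng.choice(classes, p=probs, size=100)
    calls = [GcrCall(str(i), c, 2, False, 1) for i, c in enumerate(draws)]
    df = tabulate_spectrum({"sim": calls})
    for cls, p in zip(classes, probs):
        frac = df.loc["sim", "frac_" + cls]
        se = np.sqrt(p * (1 - p) / 100)
        assert abs(frac - p) < 3.5 * se + 1e-9
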