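"""GCR implanting: truth-record consistency, conservation, monocentricity."""

import numpy as np
import pytest

from gcrscope.errors import ConfigurationError, SimulationError
from gcrscope.events import (
    GcrEventSpec,
    count_centromeres,
    find_mh_pair,
    implant_gcr,
    verify_truth_junctions,
)

ALL_CASES = [
    ("telomere_addition", {}),
    ("interstitial_deletion", {"microhomology_len": 7}),
    ("interstitial_deletion", {"insertion_len": 3}),
    ("micro_nonhomology_translocation", {"microhomology_len": 5}),
    ("micro_nonhomology_translocation", {"insertion_len": 4}),
    ("homology_translocation", {"family": "segdup"}),
    ("homology_translocation", {"family": "delta"}),
    ("hairpin_inverted_duplication", {"stem_len": 8, "loop_len": 6, "secondary_resolution": "repeat_HR"}),
    ("hairpin_inverted_duplication", {"stem_len": 12, "loop_len": 10, "secondary_resolution": "marker_HR"}),
    ("hairpin_inverted_duplication", {"stem_len": 6, "loop_len": 4, "secondary_resolution": "microhomology"}),
    ("disomy", {}),
]


@pytest.fixture(params=ALL_CASES, ids=lambda c: c[0] + "/" + "_".join(f"{k}={v}" for k, v in c[1].items()))
def implanted(request, ref):
    cls, params = request.param
    break_pos = 7600 if cls == "hairpin_inverted_duplication" else 8000
    spec = GcrEventSpec(cls, break_pos, dict(params))
    genome, truth = implant_gcr(ref, spec, np.random.default_rng(42))
    return genome, truth


def test_truth_junctions_roundtrip(implanted, ref):
    """Recorded junction context re-extracts exactly from the derivative."""
    genome, truth = implanted
    assert verify_truth_junctions(genome, truth)


def test_final_product_monocentric(implanted, ref):
    genome, truth = implanted
    assert count_centromeres(genome.molecules[0], ref) == 1


def test_dicentric_intermediate(ref):
    spec = GcrEventSpec(
        "hairpin_inverted_duplication",
        7600,
        {"stem_len": 8, "loop_len": 6, "secondary_resolution": "repeat_HR"},
    )
    _, truth = implant_gcr(ref, spec, np.random.default_rng(1))
    assert count_centromeres(truth.intermediate_seq, ref) == 2


def test_group_and_marker_rules(implanted, ref):
    genome, truth = implanted
    if truth.event_class == "telomere_addition":
        assert truth.group == 2 and not truth.hph_retained
    if truth.event_class == "interstitial_deletion":
        assert truth.group == 3 and truth.hph_retained
    if truth.group == 1:
        assert truth.derivative_length > ref.chrom_len(ref.assay_chrom) * 1.02


def test_deletion_length_conservation(ref):
    spec = GcrEventSpec("interstitial_deletion", 8000, {"microhomology_len": 5})
    genome, truth = implant_gcr(ref, spec, np.random.default_rng(3))
    (chrom, d, a) = truth.deleted[0]
    assert truth.derivative_length == ref.chrom_len(ref.assay_chrom) - (a - d)


def test_translocation_nonreciprocal(ref):
    """The target chromosome stays intact; its fragment is duplicated."""
    spec = GcrEventSpec(
        "micro_nonhomology_translocation", 8000, {"microhomology_len": 5}
    )
    genome, truth = implant_gcr(ref, spec, np.random.default_rng(4))
    assert genome.molecule("chrIII").seq == ref.sequences["chrIII"]
    (chrom, s, e) = truth.duplicated[0]
    assert chrom == "chrIII" and e > s
    assert genome.molecules[0].seq[: e - s] == ref.sequences["chrIII"][s:e]


def test_disomy_adds_exactly_one_copy(ref):
    genome, truth = implant_gcr(ref, GcrEventSpec("disomy", None, {}), np.random.default_rng(5))
    names = [m.name for m in genome.molecules]
    assert sum(1 for m in genome.molecules if m.seq == ref.sequences["chrIII"]) == 2
    assert truth.disomies == ["chrIII"]


def test_engineered_microhomology_is_exact(ref):
    assay = ref.sequences["chrV"]
    t = ref.sequences["chrIII"]
    b, a = find_mh_pair(t, (1_000, 11_000), assay, (7_000, 11_500), 7, 8_000)
    assert t[b - 7 : b] == assay[a - 7 : a]
    assert t[b - 8] != assay[a - 8] and t[b] != assay[a]


def test_hairpin_without_site_raises(ref):
    spec = GcrEventSpec(
        "hairpin_inverted_duplication",
        7_000,
        {"stem_len": 31, "loop_len": 7, "secondary_resolution": "repeat_HR"},
    )
    with pytest.raises(SimulationError, match="inverted repeat"):
        implant_gcr(ref, spec, np.random.default_rng(6))


def test_break_outside_region_rejected(ref):
    with pytest.raises(SimulationError, match="breakpoint region"):
        implant_gcr(ref, GcrEventSpec("telomere_addition", 3_000, {}), np.random.default_rng(7))


def test_unknown_class_rejected():
    with pytest.raises(ConfigurationError):
        GcrEventSpec("inversion", 8_000, {})
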