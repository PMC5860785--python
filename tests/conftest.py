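import warnings

import numpy as np
import pytest

from gcrscope.genome import build_reference
from gcrscope.pairs import classify_concordance, fit_insert_model, remove_duplicates
from gcrscope.pipeline import ReferenceContext
from gcrscope.readsim import ReadSimConfig, simulate_read_pairs

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def ref():
    return build_reference()


@pytest.fixture(scope="session")
def ctx(ref):
    return ReferenceContext(ref)


@pytest.fixture(scope="session")
def clean_pairs(ref, ctx):
    """Mapped, deduplicated, concordance-classified pairs from an
    unrearranged 50x simulation (1% error, 2% duplicates)."""
    reads, truth = simulate_read_pairs(ref.sequences, ReadSimConfig(rng_seed=77))
    pairs = remove_duplicates(ctx.index.map_pairs(reads))
    model = fit_insert_model(pairs, fallback=(200.0, 1000.0))
    return classify_concordance(pairs, model), model, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


CANONICAL_EVENTS = {
    "telomere_addition": ("telomere_addition", 8_000, {"seed_len": 250}),
    "interstitial_deletion": ("interstitial_deletion", 8_000, {"microhomology_len": 7}),
    "micro_translocation": (
        "micro_nonhomology_translocation",
        8_000,
        {"microhomology_len": 5},
    ),
    "homology_translocation": ("homology_translocation", None, {"family": "segdup"}),
    "hairpin_repeat_HR": (
        "hairpin_inverted_duplication",
        7_600,
        {"stem_len": 8, "loop_len": 6, "secondary_resolution": "repeat_HR"},
    ),
    "hairpin_microhomology": (
        "hairpin_inverted_duplication",
        9_200,
        {"stem_len": 12, "loop_len": 10, "secondary_resolution": "microhomology"},
    ),
    "disomy": ("disomy", None, {"chrom": "chrIII"}),
}


@pytest.fixture(scope="session")
def analyzed(ref, ctx):
    """Canonical implanted isolates run through the full analysis once."""
    from gcrscope.events import GcrEventSpec, implant_gcr
    from gcrscope.pipeline import analyze_isolate

    out = {}
    for i, (key, (cls, pos, params)) in enumerate(CANONICAL_EVENTS.items()):
        spec = GcrEventSpec(cls, pos, dict(params))
        genome, truth = implant_gcr(ref, spec, np.random.default_rng(400 + i))
        reads, _ = simulate_read_pairs(genome, ReadSimConfig(rng_seed=500 + i))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = analyze_isolate(ctx, reads, isolate_id=key)
        out[key] = (truth, result)
    return out


@pytest.fixture(scope="session")
def unrearranged_result(ref, ctx, clean_pairs):
    from gcrscope.pipeline import analyze_isolate
    from gcrscope.readsim import ReadSimConfig, simulate_read_pairs

    reads, _ = simulate_read_pairs(ref.sequences, ReadSimConfig(rng_seed=78))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze_isolate(ctx, reads, isolate_id="plain")
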