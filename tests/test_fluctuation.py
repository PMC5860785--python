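"""Method-of-the-median rate estimation and observed/expected comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gcrscope.cultures import CultureSimConfig, simulate_cultures
from gcrscope.errors import ConfigurationError
from gcrscope.fluctuation import (
    FluctuationExperiment,
    compare_observed_expected,
    fold_change,
    lc_median_rate,
    mann_whitney_enumeration,
    partition_rate,
    read_experiments,
    solve_lc_m,
    type_partitioned_rates,
)


def test_lea_coulson_closed_form():
    """r = 1.24 solves to m = 1 exactly (ln 1 = 0)."""
    assert solve_lc_m(1.24) == pytest.approx(1.0, abs=1e-9)


def test_solver_monotone():
    ms = [solve_lc_m(r) for r in (0.5, 2, 10, 100, 1000)]
    assert ms == sorted(ms)


def test_all_zero_counts_upper_bound():
    exp = FluctuationExperiment(np.zeros(8), np.array([1e8]))
    est = lc_median_rate(exp)
    assert est.upper_bound_only
    assert est.rate > 0 and est.ci_low == 0.0


def test_ci_brackets_rate():
    counts = simulate_cultures(CultureSimConfig(1e-7, 1e8, 16, rng_seed=4))
    est = lc_median_rate(FluctuationExperiment(counts, np.array([1e8])))
    assert est.ci_low <= est.rate <= est.ci_high


def test_estimator_recovers_known_rate():
    """Median-of-estimates within 20% of the simulated true rate."""
    rng = np.random.default_rng(8)
    ests = []
    for _ in range(200):
        counts = simulate_cultures(
            CultureSimConfig(1e-7, 1e8, 16, rng_seed=int(rng.integers(2**31)))
        )
        ests.append(lc_median_rate(FluctuationExperiment(counts, np.array([1e8]))).rate)
    assert abs(np.median(ests) - 1e-7) / 1e-7 < 0.2


def test_partition_linearity():
    est = lc_median_rate(
        FluctuationExperiment(np.array([10, 20, 30, 40, 50, 60]), np.array([1e8]))
    )
    half = partition_rate(est, 0.4)
    assert half.rate == pytest.approx(est.rate * 0.4)
    assert half.ci_low == pytest.approx(est.ci_low * 0.4)
    assert half.ci_high == pytest.approx(est.ci_high * 0.4)
    assert partition_rate(est, 1.0).rate == est.rate
    assert partition_rate(est, 0.0).rate == 0.0
    with pytest.raises(ConfigurationError):
        partition_rate(est, 1.5)


def test_partition_conserves_total():
    est = lc_median_rate(
        FluctuationExperiment(np.array([3, 8, 15, 21, 40, 7]), np.array([1e8]))
    )
    fracs = {"a": 0.5, "b": 0.3, "c": 0.2}
    parts = type_partitioned_rates(est, fracs, fracs)
    assert sum(p.observed.rate for p in parts) == pytest.approx(est.rate)


def test_mann_whitney_identical_samples():
    r = compare_observed_expected([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.p_value > 0.5 and r.stars == ""
    tied = compare_observed_expected([5.0, 5.0], [5.0, 5.0])
    assert tied.p_value == 1.0


def test_mann_whitney_separated_samples_exact_p():
    """{1,2,3} vs {10,20,30}: U = 0 and exact two-sided p = 0.1."""
    r = compare_observed_expected([1, 2, 3], [10, 20, 30])
    assert r.U == 0
    assert r.p_value == pytest.approx(0.1)


@given(
    n1=st.integers(2, 8),
    n2=st.integers(2, 8),
    seed=st.integers(0, 9999),
)
@settings(max_examples=25, deadline=None)
def test_exact_p_matches_full_enumeration(n1, n2, seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=n1)
    b = rng.normal(size=n2)
    p_scipy = compare_observed_expected(a, b).p_value
    p_enum = mann_whitney_enumeration(a, b)
    assert p_scipy == pytest.approx(p_enum, abs=1e-9)


def test_star_thresholds():
    from gcrscope.fluctuation import ComparisonResult

    assert ComparisonResult(0, 0.04).stars == "*"
    assert ComparisonResult(0, 0.0004).stars == "**"
    assert ComparisonResult(0, 0.2).stars == ""
    assert ComparisonResult(0, 0.05).stars == ""


def test_fold_change():
    est = lc_median_rate(
        FluctuationExperiment(np.array([5, 12, 9, 30, 2, 18]), np.array([1e8]))
    )
    fc = fold_change(est, est.rate)
    assert fc.rate == pytest.approx(1.0)
    fc30 = fold_change(est, est.rate / 30)
    assert fc30.rate == pytest.approx(30.0)
    with pytest.raises(ConfigurationError):
        fold_change(est, 0)


def test_read_experiments_tsv(tmp_path):
    path = tmp_path / "counts.tsv"
    path.write_text(
        "culture_id\tmutant_count\tviable_cells\tplating_fraction\tgenotype\tassay\n"
        + "".join(
            f"c{i}\t{c}\t1e8\t1.0\twild-type\tuGCR\n"
            for i, c in enumerate([4, 9, 1, 22, 7, 3, 15, 8])
        )
        + "".join(
            f"m{i}\t{c}\t1e8\t1.0\tmutant\tuGCR\n"
            for i, c in enumerate([40, 90, 10, 220, 70, 30, 150, 80])
        )
    )
    exps = read_experiments(path)
    assert len(exps) == 2
    by_geno = {e.genotype: e for e in exps}
    wt = lc_median_rate(by_geno["wild-type"])
    mut = lc_median_rate(by_geno["mutant"])
    assert mut.rate > wt.rate
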