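import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from pseudoscales import (
    ValidationError,
    cumulative_probability,
    kde_overlap,
    median_iqr,
    proportion_significant,
    rank_sum_test,
    sheather_jones_bandwidth,
    simulation_interval,
    size_or_correlation,
    summarize,
)


# ---------------------------------------------------------------------------
# Simulation intervals, medians, rank-sum
# ---------------------------------------------------------------------------

def test_simulation_interval_constant_and_full_level():
    assert simulation_interval([2.0, 2.0, 2.0]) == (2.0, 2.0)
    lo, hi = simulation_interval([1.0, 5.0, 3.0, 2.0], level=1.0)
    assert (lo, hi) == (1.0, 5.0)


def test_simulation_interval_sorted_array_oracle():
    values = np.arange(1000) / 1000
    lo, hi = simulation_interval(values)
    assert lo == pytest.approx(0.024975)  # type-7 interpolation, frozen
    assert hi == pytest.approx(0.974025)


def test_simulation_interval_width_nondecreasing_in_level():
    rng = np.random.default_rng(0)
    v = rng.normal(size=500)
    widths = [np.diff(simulation_interval(v, lv))[0] for lv in (0.5, 0.8, 0.95, 0.99)]
    assert all(np.diff(widths) >= 0)


def test_simulation_interval_rejects_degenerate_input():
    with pytest.raises(ValidationError):
        simulation_interval([1.0])


def test_median_iqr_type7_oracle():
    assert median_iqr([1.0, 2.0, 3.0, 4.0]) == (2.5, 1.5)
    assert median_iqr([3.0, 3.0, 3.0]) == (3.0, 0.0)
    sym = np.concatenate([np.linspace(-1, 1, 101)])
    med, _ = median_iqr(sym)
    assert med == pytest.approx(np.mean(sym), abs=1e-12)


def test_rank_sum_identical_samples_p_one():
    assert rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0, abs=1e-9)


def test_rank_sum_exact_enumeration_oracle():
    # 2 extreme orderings / C(6,3)=20 -> two-sided p = 0.1
    assert rank_sum_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0]) == pytest.approx(0.1)


def test_rank_sum_null_pvalues_roughly_uniform():
    rng = np.random.default_rng(1)
    pvals = [
        rank_sum_test(rng.normal(size=30), rng.normal(size=30)) for _ in range(400)
    ]
    assert stats.kstest(pvals, "uniform").pvalue > 0.001


def test_rank_sum_rejects_nan_input():
    with pytest.raises(ValidationError):
        rank_sum_test([1.0, np.nan], [2.0, 3.0])


# ---------------------------------------------------------------------------
# Sheather-Jones bandwidth and overlap
# ---------------------------------------------------------------------------

def test_sheather_jones_matches_reference_values():
    """Frozen oracle: R 4.3 stats::bw.SJ(x - min(x), method="ste") on the
    same deterministically generated samples."""
    rng = np.random.default_rng(42)
    x1 = rng.normal(0, 1, 500)
    x2 = rng.gamma(2, 1.5, 800)
    x3 = rng.normal(0, 1, 100_000)
    assert sheather_jones_bandwidth(x1) == pytest.approx(0.2864647, rel=5e-3)
    assert sheather_jones_bandwidth(x2) == pytest.approx(0.3528648, rel=5e-3)
    assert sheather_jones_bandwidth(x3) == pytest.approx(0.1043366, rel=5e-3)


def test_sheather_jones_location_scale_equivariance():
    rng = np.random.default_rng(6)
    x = rng.normal(size=1000)
    h = sheather_jones_bandwidth(x)
    assert sheather_jones_bandwidth(3 * x + 10) == pytest.approx(3 * h, rel=1e-6)


def test_sheather_jones_degenerate_sample_rejected():
    with pytest.raises(ValidationError):
        sheather_jones_bandwidth(np.ones(50))


def test_overlap_of_sample_with_itself_is_one():
    rng = np.random.default_rng(2)
    x = rng.normal(size=2000)
    assert kde_overlap(x, x) == pytest.approx(1.0, abs=0.01)


def test_overlap_of_disjoint_samples_is_zero():
    rng = np.random.default_rng(3)
    assert kde_overlap(rng.normal(0, 1, 500), rng.normal(1000, 1, 500)) < 0.01


def test_overlap_matches_gaussian_closed_form():
    # two unit-variance normals one SD apart overlap by 2*Phi(-1/2)
    rng = np.random.default_rng(4)
    a = rng.normal(0, 1, 100_000)
    b = rng.normal(1, 1, 100_000)
    assert kde_overlap(a, b) == pytest.approx(0.6170750774519738, abs=0.02)


def test_overlap_symmetric_and_shift_invariant():
    rng = np.random.default_rng(5)
    a = rng.normal(0, 1, 1500)
    b = rng.normal(0.7, 1.3, 1500)
    ov = kde_overlap(a, b)
    assert kde_overlap(b, a) == pytest.approx(ov, abs=1e-9)
    assert kde_overlap(5 + 2 * a, 5 + 2 * b) == pytest.approx(ov, abs=0.01)
    assert 0 <= ov <= 1


# ---------------------------------------------------------------------------
# Correlations, cumulative probability, significance proportions
# ---------------------------------------------------------------------------

def test_size_or_correlation_perfectly_linear():
    sizes = np.array([15, 40, 80, 120, 150], dtype=float)
    r, (lo, hi) = size_or_correlation((sizes, 1 + 0.001 * sizes))
    assert r == pytest.approx(1.0)
    assert lo <= 1.0 <= hi + 1e-12


def test_size_or_correlation_frozen_fisher_oracle():
    sizes = [15.0, 40.0, 60.0, 90.0, 120.0, 150.0]
    ors = [1.01, 1.04, 1.02, 1.08, 1.07, 1.12]
    r, (lo, hi) = size_or_correlation((sizes, ors))
    assert r == pytest.approx(0.9209988872285587)
    assert lo == pytest.approx(0.43332537580804664)
    assert hi == pytest.approx(0.9914807897500041)


def test_size_or_correlation_independent_inputs_near_zero():
    rng = np.random.default_rng(8)
    r, _ = size_or_correlation((rng.permutation(1000).astype(float), rng.normal(size=1000)))
    assert abs(r) < 0.1


def test_size_or_correlation_constant_sizes_rejected():
    with pytest.raises(ValidationError):
        size_or_correlation(([5.0] * 10, list(np.arange(10.0))))


def test_cumulative_probability_counting_oracle():
    pseudo = [1.0, 1.1, 1.2, 1.3, 1.4]
    assert cumulative_probability(2.0, pseudo) == 1.0
    assert cumulative_probability(0.5, pseudo) == 0.0
    # abs OR at the median of an odd-length sample: (n-1)/2n
    assert cumulative_probability(1.2, pseudo) == pytest.approx(2 / 5)


def _res(or_, p, converged=True):
    return {"or_per_sd": or_, "p_value": p, "converged": converged}


def test_proportion_significant_hand_counts():
    df = pd.DataFrame(
        [
            _res(1.2, 0.01),   # significant positive
            _res(1.1, 0.20),   # positive, not significant
            _res(0.8, 0.01),   # significant but negative
            _res(1.3, 0.04),   # significant positive
            _res(np.nan, np.nan, converged=False),  # excluded from denominator
        ]
    )
    assert proportion_significant(df) == pytest.approx(2 / 4)
    strong = pd.DataFrame([_res(1.5, 1e-6)] * 8)
    assert proportion_significant(strong) == 1.0


def test_proportion_significant_null_rate_is_half_alpha():
    """Null logistic fits: positive-and-significant at two-sided alpha
    occurs at ~alpha/2 (the positive tail only)."""
    from pseudoscales import fit_logistic

    rng = np.random.default_rng(9)
    rows = []
    for _ in range(300):
        x = rng.normal(size=2000)
        y = (rng.random(2000) < expit(-1.0)).astype(float)
        r = fit_logistic(pd.DataFrame({"burden": x}), y)
        rows.append(_res(r.or_per_sd, r.p_value, r.converged))
    rate = proportion_significant(pd.DataFrame(rows))
    se = np.sqrt(0.025 * 0.975 / 300)
    assert rate < 0.025 + 3 * se + 0.01


# ---------------------------------------------------------------------------
# Report assembly (golden values on a constructed results table)
# ---------------------------------------------------------------------------

def _row(scale_id, or_, p, mode, pool, template="", kind="pseudoscale", size=50):
    return {
        "scale_id": scale_id,
        "outcome": "death",
        "or_per_sd": or_,
        "ci_low": or_ * 0.9,
        "ci_high": or_ * 1.1,
        "p_value": p,
        "n_used": 1000,
        "scale_size": size,
        "kind": kind,
        "mode": mode,
        "pool": pool,
        "template_scale_id": template,
        "converged": True,
        "reason": "",
    }


def test_summarize_golden_fixture():
    rows = []
    gen = [1.00, 1.02, 1.04, 1.06]
    ant = [1.05, 1.07, 1.09, 1.11]
    for i, o in enumerate(gen):
        rows.append(_row(f"g{i}", o, 0.01, "across", "general", size=20 + 10 * i))
    for i, o in enumerate(ant):
        rows.append(_row(f"a{i}", o, 0.20, "across", "anticholinergic", size=20 + 10 * i))
    for i, o in enumerate([1.00, 1.02, 1.06, 1.10]):
        rows.append(_row(f"w{i}", o, 0.5, "within", "general", template="ABS1"))
    rows.append(_row("ABS1", 1.04, 0.001, "none", "none", kind="abs", size=30))
    report = summarize(pd.DataFrame(rows))
    death = report["outcomes"]["death"]
    g = death["across"]["general"]
    assert g["median_or"] == pytest.approx(np.median(gen))
    assert g["iqr_or"] == pytest.approx(0.03)
    assert g["si_low"] == pytest.approx(np.percentile(gen, 2.5))
    # OR exactly 1.00 is not a *positive* association (strict inequality)
    assert g["prop_significant"] == pytest.approx(3 / 4)
    assert death["across"]["anticholinergic"]["prop_significant"] == 0.0
    # ABS1 OR 1.04 beats 2 of its 4 matched within-sampling replicates
    assert death["abs"]["ABS1"]["cumulative_probability"]["general"] == pytest.approx(0.5)
    assert 0 <= death["rank_sum_p"] <= 1
    assert report["n_nonconverged"] == 0
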