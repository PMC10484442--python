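"""Bayesian dosage-adjustment model: posterior summaries (HDI, ROPE),
likelihood and gradient correctness, sampler calibration on known
targets, down-sampling and determinism."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dosepair.bayes_dosage_model import (
    DownsampleConfig,
    ModelSpec,
    build_design,
    fit_index_drug,
    hdi,
    log_binomial_pmf,
    rice_bins,
    rope_decision,
    rope_decision_fraction,
    sample_nuts,
    stratified_downsample,
)
from dosepair.episode_builder import MONOTHERAPY

from .oracles import shortest_window_hdi


# ---------------------------------------------------------------------------
# HDI

def test_hdi_constant_sample_zero_width():
    assert hdi([3.0] * 50) == (3.0, 3.0)


def test_hdi_uniform_grid_width():
    lo, hi = hdi(np.arange(1000.0), mass=0.89)
    assert hi - lo == 889.0
    assert (lo, hi) == shortest_window_hdi(np.arange(1000.0), 0.89)


def test_hdi_symmetric_sample_matches_central_interval():
    rng = np.random.default_rng(0)
    x = rng.normal(size=20000)
    lo, hi = hdi(x, 0.89)
    qlo, qhi = np.quantile(x, [0.055, 0.945])
    assert lo == pytest.approx(qlo, abs=0.08)
    assert hi == pytest.approx(qhi, abs=0.08)


@given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=200),
       st.floats(0.5, 0.99))
@settings(max_examples=80, deadline=None, derandomize=True)
def test_hdi_minimality_property(draws, mass):
    lo, hi = hdi(draws, mass)
    blo, bhi = shortest_window_hdi(draws, mass)
    assert hi - lo == pytest.approx(bhi - blo, rel=1e-12, abs=1e-12)
    assert lo < hi or len(set(draws)) == 1 or lo == hi


def test_hdi_rejects_tiny_samples():
    with pytest.raises(ValueError):
        hdi([1.0])


# ---------------------------------------------------------------------------
# ROPE

@pytest.mark.parametrize("interval, decision", [
    ((0.10, 0.30), "reject_null"),
    ((-0.30, -0.10), "reject_null"),
    ((-0.02, 0.03), "accept_null"),
    ((-0.01, 0.20), "undecided"),
    ((-0.05, 0.05), "accept_null"),   # boundary: containment is inclusive
    ((0.05001, 0.2), "reject_null"),
])
def test_rope_truth_table(interval, decision):
    assert rope_decision(interval) == decision


def test_rope_fraction_variant():
    rng = np.random.default_rng(1)
    inside = rng.uniform(-0.04, 0.04, size=1000)
    assert rope_decision_fraction(inside, (-0.05, 0.05)) == "accept_null"
    outside = rng.uniform(0.2, 0.4, size=1000)
    assert rope_decision_fraction(outside, (-0.05, 0.05)) == "reject_null"


# ---------------------------------------------------------------------------
# Rice's rule and likelihood

@pytest.mark.parametrize("n, k", [(1000, 21), (1, 3), (8, 5), (125, 11)])
def test_rice_bins(n, k):
    assert rice_bins(n) == k


def test_log_binomial_matches_scipy():
    rng = np.random.default_rng(3)
    n = rng.integers(1, 30, size=200)
    y = np.array([rng.integers(0, ni + 1) for ni in n])
    p = rng.uniform(0.01, 0.99, size=200)
    np.testing.assert_allclose(log_binomial_pmf(y, n, p),
                               stats.binom.logpmf(y, n, p), rtol=1e-10)
    # limiting behaviour: y=0, p->0 tends to log(1) = 0
    assert log_binomial_pmf(np.array([0]), np.array([5]),
                            np.array([1e-12]))[0] == pytest.approx(0.0, abs=1e-9)
    # p = 0.5: N log 0.5 + log C(N, y)
    val = log_binomial_pmf(np.array([2]), np.array([6]), np.array([0.5]))[0]
    assert val == pytest.approx(6 * math.log(0.5) + math.log(math.comb(6, 2)))


# ---------------------------------------------------------------------------
# posterior construction and sampler

def _episodes_frame(y, n, comed, patients):
    rows = []
    for i, (yi, ni, ci, pi) in enumerate(zip(y, n, comed, patients)):
        rows.append({
            "episode_id": f"E{i}", "patient_id": pi, "admission_id": f"A{i}",
            "index_drug": "A01AA01", "co_med": ci, "start": 0.0,
            "end": 1440.0, "N": ni, "y": yi, "discontinued": False,
            "complete": True, "add_values": ""})
    return pd.DataFrame(rows)


def _admissions_frame(episodes, rng):
    adm = episodes[["admission_id", "patient_id"]].drop_duplicates()
    n = len(adm)
    return adm.assign(
        start_min=0.0, end_min=7 * 1440.0,
        age=rng.normal(60, 10, n).round(1), sex=rng.integers(0, 2, n),
        hospital=np.take(["H1", "H2"], rng.integers(0, 2, n)),
        year=np.take([2010, 2011], rng.integers(0, 2, n)),
        icd10_chapter=np.take(["I", "II"], rng.integers(0, 2, n)),
        charlson=1, death=0, death_min=np.nan, n_unique_drugs=2)


def test_posterior_gradient_matches_finite_differences():
    rng = np.random.default_rng(5)
    n_ep = 60
    ep = _episodes_frame(
        y=rng.integers(0, 2, n_ep), n=rng.integers(2, 5, n_ep),
        comed=np.take([MONOTHERAPY, "B01BB01"], rng.integers(0, 2, n_ep)),
        patients=[f"P{i % 20}" for i in range(n_ep)])
    adm = _admissions_frame(ep, rng)
    for hier in (False, True):
        post, _, _ = build_design(ep, adm, ModelSpec(hierarchical=hier))
        th = 0.3 * rng.standard_normal(post.dim)
        _, g = post.logp_grad(th)
        for j in range(post.dim):
            e = np.zeros(post.dim)
            e[j] = 1e-6
            fd = (post.logp_grad(th + e)[0] - post.logp_grad(th - e)[0]) / 2e-6
            assert g[j] == pytest.approx(fd, rel=1e-4, abs=1e-5)


def test_nuts_recovers_correlated_gaussian():
    cov = np.array([[2.0, 0.9], [0.9, 1.0]])
    prec = np.linalg.inv(cov)

    def lg(t):
        return -0.5 * t @ prec @ t, -prec @ t

    d, st_ = sample_nuts(lg, np.zeros(2), 3000, 1000, np.random.default_rng(8))
    assert st_["divergent"].sum() == 0
    np.testing.assert_allclose(d.mean(0), [0, 0], atol=0.15)
    np.testing.assert_allclose(np.cov(d.T), cov, atol=0.3)


def test_intercept_matches_closed_form_mle_on_monotherapy():
    """All-monotherapy input: the intercept posterior sits within 3
    posterior SDs of the closed-form logit of the pooled change rate."""
    rng = np.random.default_rng(9)
    n_ep = 400
    n = rng.integers(2, 6, n_ep)
    p_true = 0.3
    y = rng.binomial(n - 1, p_true)
    ep = _episodes_frame(y, n, [MONOTHERAPY] * n_ep,
                         [f"P{i}" for i in range(n_ep)])
    adm = _admissions_frame(ep, rng)
    spec = ModelSpec(chains=2, iterations=800, warmup=400)
    res, diag = fit_index_drug(ep, adm, spec, seed=4)
    assert res == []  # no pair coefficients on all-monotherapy input
    coef = np.asarray(diag["coef_draws"])[:, :, 0].ravel()
    mle = math.log(y.sum() / ((n - 1).sum() - y.sum()))
    assert abs(np.median(coef) - mle) < 3 * coef.std()


def test_fit_determinism_same_seed():
    rng = np.random.default_rng(10)
    n_ep = 150
    ep = _episodes_frame(
        y=rng.integers(0, 2, n_ep), n=rng.integers(2, 5, n_ep),
        comed=np.take([MONOTHERAPY, "B01BB01"], rng.integers(0, 2, n_ep)),
        patients=[f"P{i % 60}" for i in range(n_ep)])
    adm = _admissions_frame(ep, rng)
    spec = ModelSpec(chains=2, iterations=600, warmup=300)
    r1, _ = fit_index_drug(ep, adm, spec, seed=77)
    r2, _ = fit_index_drug(ep, adm, spec, seed=77)
    assert round(r1[0].or_median, 6) == round(r2[0].or_median, 6)
    assert (r1[0].hdi_low, r1[0].hdi_high) == (r2[0].hdi_low, r2[0].hdi_high)


def test_unidentifiable_comed_flagged():
    """A co-medication present in every episode is collinear with the
    intercept and must be flagged, never significant."""
    rng = np.random.default_rng(11)
    n_ep = 80
    ep = _episodes_frame(
        y=rng.integers(0, 2, n_ep), n=[3] * n_ep, comed=["B01BB01"] * n_ep,
        patients=[f"P{i}" for i in range(n_ep)])
    adm = _admissions_frame(ep, rng)
    spec = ModelSpec(chains=2, iterations=400, warmup=200)
    res, _ = fit_index_drug(ep, adm, spec, seed=5)
    assert res[0].unidentifiable
    assert not res[0].significant


# ---------------------------------------------------------------------------
# stratified down-sampling

def _downsample_fixture(rng, n, frac_b):
    n_b = int(n * frac_b)
    comed = np.array(["B01BB01"] * (n - n_b) + ["C01CC01"] * n_b)
    ep = _episodes_frame(np.zeros(n, int), np.full(n, 2), comed,
                         [f"P{i}" for i in range(n)])
    adm = _admissions_frame(ep, rng)
    return ep, adm


def test_downsample_below_threshold_unchanged():
    rng = np.random.default_rng(12)
    ep, adm = _downsample_fixture(rng, 200, 0.1)
    cfg = DownsampleConfig(episode_threshold=500, top_comedications=10,
                           min_pair_patients=1)
    out = stratified_downsample(ep, adm, cfg, rng)
    assert out.equals(ep)


def test_downsample_preserves_stratum_proportions():
    rng = np.random.default_rng(13)
    ep, adm = _downsample_fixture(rng, 5000, 0.1)
    cfg = DownsampleConfig(episode_threshold=500, top_comedications=10,
                           min_pair_patients=1)
    out = stratified_downsample(ep, adm, cfg, np.random.default_rng(99))
    conc = out[out.co_med != MONOTHERAPY]
    assert len(conc) == 500
    prop_b = (conc["co_med"] == "C01CC01").mean()
    assert abs(prop_b - 0.1) < 0.03


def test_downsample_keeps_top_comedications_and_pair_minimum():
    rng = np.random.default_rng(14)
    n = 3000
    comed = np.array(["B01BB01"] * 2000 + ["C01CC01"] * 940 + ["D01DD01"] * 60)
    ep = _episodes_frame(np.zeros(n, int), np.full(n, 2), comed,
                         [f"P{i}" for i in range(n)])
    adm = _admissions_frame(ep, rng)
    cfg = DownsampleConfig(episode_threshold=600, top_comedications=2,
                           min_pair_patients=5)
    out = stratified_downsample(ep, adm, cfg, rng)
    assert set(out.loc[out.co_med != MONOTHERAPY, "co_med"]) == {"B01BB01", "C01CC01"}
    assert len(out[out.co_med != MONOTHERAPY]) == 600


def test_sensitivity_modes_produce_finite_fits():
    """The hierarchical-prior and trials=N sensitivity modes run end to
    end and give posteriors in the same neighbourhood as the default."""
    rng = np.random.default_rng(15)
    n_ep = 200
    ep = _episodes_frame(
        y=rng.integers(0, 2, n_ep), n=rng.integers(2, 6, n_ep),
        comed=np.take([MONOTHERAPY, "B01BB01"], rng.integers(0, 2, n_ep)),
        patients=[f"P{i % 80}" for i in range(n_ep)])
    adm = _admissions_frame(ep, rng)
    base, _ = fit_index_drug(ep, adm, ModelSpec(chains=2, iterations=600,
                                                warmup=300), seed=6)
    for spec in (ModelSpec(chains=2, iterations=600, warmup=300,
                           hierarchical=True),
                 ModelSpec(chains=2, iterations=600, warmup=300,
                           trials_mode="prescriptions")):
        res, diag = fit_index_drug(ep, adm, spec, seed=6)
        r = res[0]
        assert np.isfinite(r.or_median) and r.hdi_low < r.hdi_high
        assert abs(r.coef_median - base[0].coef_median) < 0.6


def test_modelspec_validation():
    with pytest.raises(ValueError):
        ModelSpec(iterations=100, warmup=100)
    with pytest.raises(ValueError):
        ModelSpec(rope=(0.01, 0.05))
    with pytest.raises(ValueError):
        ModelSpec(sigma_sex=0.0)
    with pytest.raises(ValueError):
        DownsampleConfig(episode_threshold=0)
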