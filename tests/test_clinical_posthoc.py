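"""Propensity matching and matched-cohort association analyses: matching
contracts and balance, planted-effect recovery, Bonferroni behaviour."""

import numpy as np
import pandas as pd
import pytest

from dosepair.clinical_posthoc import (
    AssociationResult,
    MatchingError,
    bonferroni,
    match_cohort,
    run_posthoc,
    standardized_mean_differences,
    test_discontinuation as discontinuation_assoc,
    test_enrichment as enrichment_assoc,
    test_outcomes as outcomes_assoc,
)
from dosepair.dosage_add import compute_add_frame
from dosepair.episode_builder import build_episodes, merge_readmissions
from dosepair.synthetic_cohort import (
    CohortConfig,
    OutcomeEffects,
    generate_cohort,
    make_drug_codes,
)


def _prepared(n_patients, seed, effects=None, **kw):
    drugs = make_drug_codes(8, np.random.default_rng(seed))
    cfg = CohortConfig(n_patients=n_patients, n_drugs=8, seed=seed,
                       planted_effects={(drugs[0], drugs[1]): 0.0},
                       outcome_effects=effects or OutcomeEffects(), **kw)
    c = generate_cohort(cfg)
    ep = build_episodes(c.prescriptions, compute_add_frame(c.prescriptions))
    ep = ep[ep.complete]
    adm = merge_readmissions(c.admissions)
    return c, ep, adm, (drugs[0], drugs[1])


@pytest.fixture(scope="module")
def null_setup():
    return _prepared(1200, seed=21)


def _episodes_for_pair(index_drug, co_meds, n_exposed, n_control, covs=None):
    """Hand-built episodes/admissions with one concomitant episode per
    admission."""
    rows, adms = [], []
    rng = np.random.default_rng(0)
    i = 0
    for arm, n_arm in (("E", n_exposed), ("C", n_control)):
        co = co_meds[0] if arm == "E" else co_meds[1]
        for _ in range(n_arm):
            aid, pid = f"A{i:04d}", f"P{i:04d}"
            rows.append({"episode_id": f"EP{i}", "patient_id": pid,
                         "admission_id": aid, "index_drug": index_drug,
                         "co_med": co, "start": 0.0, "end": 1440.0, "N": 2,
                         "y": 0, "discontinued": False, "complete": True,
                         "add_values": ""})
            cov = covs(i, arm) if covs else {}
            adms.append({"admission_id": aid, "patient_id": pid,
                         "start_min": 0.0, "end_min": 5 * 1440.0,
                         "age": cov.get("age", 60.0), "sex": cov.get("sex", 0),
                         "hospital": "H1", "year": 2010, "icd10_chapter": "I",
                         "charlson": cov.get("charlson", 1),
                         "death": 0, "death_min": np.nan, "n_unique_drugs": 2})
            i += 1
    return pd.DataFrame(rows), pd.DataFrame(adms)


def test_identical_pools_match_everyone():
    ep, adm = _episodes_for_pair("A01AA01", ("B01BB01", "C01CC01"), 10, 12)
    m = match_cohort(("A01AA01", "B01BB01"), ep, adm, seed=1)
    assert m.n_pairs == 10
    assert np.allclose(m.matches["exposed_score"], m.matches["control_score"])


def test_one_to_one_constraint_limits_pairs():
    ep, adm = _episodes_for_pair("A01AA01", ("B01BB01", "C01CC01"), 10, 5)
    m = match_cohort(("A01AA01", "B01BB01"), ep, adm, seed=1)
    assert m.n_pairs == 5
    assert m.matches["control_admission"].is_unique


def test_no_controls_raises():
    ep, adm = _episodes_for_pair("A01AA01", ("B01BB01", "B01BB01"), 5, 5)
    with pytest.raises(MatchingError):
        match_cohort(("A01AA01", "B01BB01"), ep, adm, seed=1)


def test_greedy_matches_sequential_brute_force():
    """Greedy nearest-neighbour equals an independent sequential
    minimal-distance assignment processed in the same seeded order."""
    def covs(i, arm):
        return {"age": 40.0 + 3.0 * i, "charlson": i % 3}
    ep, adm = _episodes_for_pair("A01AA01", ("B01BB01", "C01CC01"), 4, 4, covs)
    seed = 3
    m = match_cohort(("A01AA01", "B01BB01"), ep, adm, seed=seed)
    # oracle: replay with explicit loops over the same propensity scores
    scores = m.admissions.set_index("admission_id")["propensity"]
    exp_ids = sorted(a for a in m.matches["exposed_admission"])
    exp_rows = m.admissions[m.admissions.exposed == 1].sort_values("admission_id")
    ctl_rows = m.admissions[m.admissions.exposed == 0].sort_values("admission_id")
    order = np.random.default_rng(seed).permutation(len(exp_rows))
    taken, oracle = set(), {}
    for i in order:
        e = exp_rows.iloc[i]
        best, best_id = np.inf, None
        for _, c in ctl_rows.iterrows():
            if c["admission_id"] in taken:
                continue
            d = abs(e["propensity"] - c["propensity"])
            if d < best or (d == best and c["admission_id"] < best_id):
                best, best_id = d, c["admission_id"]
        taken.add(best_id)
        oracle[e["admission_id"]] = best_id
    got = dict(zip(m.matches["exposed_admission"], m.matches["control_admission"]))
    assert got == oracle


def test_matching_improves_balance():
    """With confounded exposure (older, sicker patients exposed) the
    post-match standardised mean differences shrink below pre-match."""
    rng = np.random.default_rng(31)

    def covs(i, arm):
        older = arm == "E"
        return {"age": float(rng.normal(64 if older else 56, 10)),
                "charlson": int(rng.poisson(2.2 if older else 1.2)),
                "sex": int(rng.integers(0, 2))}

    ep, adm = _episodes_for_pair("A01AA01", ("B01BB01", "C01CC01"),
                                 n_exposed=80, n_control=400, covs=covs)
    m = match_cohort(("A01AA01", "B01BB01"), ep, adm, seed=5)
    pre_rows = m.admissions
    pre = standardized_mean_differences(pre_rows, (pre_rows["exposed"] == 1).to_numpy())
    matched_ids = set(m.matches["exposed_admission"]) | set(m.matches["control_admission"])
    post_rows = pre_rows[pre_rows["admission_id"].isin(matched_ids)]
    post = standardized_mean_differences(post_rows, (post_rows["exposed"] == 1).to_numpy())
    assert post["age"] < pre["age"]
    assert post["charlson"] < pre["charlson"]
    assert post.max() < 0.3


def test_los_rate_ratio_recovery():
    eff = OutcomeEffects(los_lograte=np.log(2.0))
    c, ep, adm, pair = _prepared(2500, seed=23, effects=eff)
    m = match_cohort(pair, ep, adm, seed=2)
    res = {r.endpoint: r for r in outcomes_assoc(m, adm)}
    los = res["LOS"]
    assert los.estimable
    assert abs(los.effect - np.log(2.0)) < 2 * los.se


def test_mortality_hazard_recovery():
    eff = OutcomeEffects(mortality_loghr=np.log(3.0))
    c, ep, adm, pair = _prepared(3000, seed=24, effects=eff,
                                 baseline_mortality_30d=0.08)
    m = match_cohort(pair, ep, adm, seed=3)
    res = {r.endpoint: r for r in outcomes_assoc(m, adm)}
    mort = res["mortality_30d"]
    assert mort.estimable
    assert abs(mort.effect - np.log(3.0)) < 2.5 * mort.se


def test_conditional_cox_agrees_with_lifelines():
    """The pair-difference conditional partial likelihood matches a
    generic stratified Cox fitter on a clean matched fixture."""
    from dosepair.clinical_posthoc import _cox_result

    rng = np.random.default_rng(40)
    n_pairs = 250
    rows = []
    for i in range(n_pairs):
        for exp_ in (1, 0):
            age = rng.normal(60, 10)
            t = rng.exponential(60 / np.exp(0.8 * exp_ + 0.01 * (age - 60)))
            rows.append({"pair_id": f"M{i}", "exposure": exp_,
                         "age": age, "sex": int(rng.integers(0, 2)),
                         "charlson": 1, "n_unique_drugs": 2,
                         "icd10_chapter": "I",
                         "duration": min(t, 30.0), "event": t <= 30.0})
    df = pd.DataFrame(rows)
    dur = df.pop("duration").to_numpy()
    ev = df.pop("event").to_numpy()
    r_c = _cox_result(("A", "B"), "mortality_30d", df, dur, ev)
    r_lf = _cox_result(("A", "B"), "mortality_30d", df, dur, ev,
                       engine="lifelines")
    assert r_c.estimable and r_lf.estimable
    assert r_c.effect == pytest.approx(r_lf.effect, abs=0.02)
    assert r_c.se == pytest.approx(r_lf.se, rel=0.1)
    assert abs(r_c.effect - 0.8) < 2.5 * r_c.se


def test_discontinuation_odds_recovery():
    eff = OutcomeEffects(discontinuation_logodds=np.log(2.0))
    c, ep, adm, pair = _prepared(3000, seed=25, effects=eff,
                                 discontinuation_base_logit=-1.0)
    m = match_cohort(pair, ep, adm, seed=4)
    r = discontinuation_assoc(m, ep, adm)
    assert r.estimable
    assert r.direction > 0
    assert abs(r.effect - np.log(2.0)) < 2.5 * r.se


def test_enrichment_detects_planted_bloodtest_effect():
    """A planted abnormal-blood-test enrichment (odds ~3) reaches
    Bonferroni significance at about 2000 matched pairs."""
    eff = OutcomeEffects(bloodtest_logodds=np.log(3.0))
    c, ep, adm, pair = _prepared(7000, seed=26, effects=eff)
    m = match_cohort(pair, ep, adm, seed=6)
    assert m.n_pairs >= 1500
    res = enrichment_assoc(m, c.diagnoses, c.blood_tests, adm)
    res = bonferroni(res)
    target = [r for r in res if r.endpoint == "bloodtest:NPU_CREA"]
    assert target and target[0].p_bonferroni <= 0.05
    assert target[0].direction > 0


def test_enrichment_thresholds_and_all_normal(null_setup):
    c, ep, adm, pair = null_setup
    m = match_cohort(pair, ep, adm, seed=7)
    # a test present in fewer than the minimum patients is skipped
    res = enrichment_assoc(m, c.diagnoses, c.blood_tests, adm,
                           min_patients=10**6)
    assert res == []
    # an all-normal test yields no estimable coefficient
    bt = pd.DataFrame({"admission_id": c.admissions["admission_id"][:60],
                       "patient_id": c.admissions["patient_id"][:60],
                       "test_code": "NPU_X", "abnormal": 0})
    res2 = enrichment_assoc(m, c.diagnoses.iloc[:0], bt, adm, min_patients=10)
    assert all(not r.estimable for r in res2 if r.endpoint == "bloodtest:NPU_X")


def test_bonferroni_monotone_and_family_sizes():
    rs = [AssociationResult(("A", "B"), "diagnosis:X", 0.1, 0.1, 0.01),
          AssociationResult(("A", "B"), "diagnosis:Y", 0.1, 0.1, 0.04),
          AssociationResult(("A", "B"), "LOS", 0.1, 0.1, 0.04),
          AssociationResult(("A", "C"), "diagnosis:X", 0.1, 0.1, 0.9)]
    out = bonferroni(rs)
    assert out[0].p_bonferroni == pytest.approx(0.03)   # family of 3 diagnoses
    assert out[1].p_bonferroni == pytest.approx(0.12)
    assert out[2].p_bonferroni == pytest.approx(0.04)   # LOS family of 1
    assert out[3].p_bonferroni == 1.0
    assert all(r.p_bonferroni >= r.p_raw for r in out)


def test_run_posthoc_end_to_end(null_setup):
    c, ep, adm, pair = null_setup
    assoc, matched = run_posthoc([pair], ep, adm, c.diagnoses, c.blood_tests,
                                 seed=8)
    assert set(assoc["endpoint"]) >= {"discontinuation", "mortality_30d",
                                      "readmission_30d", "LOS"}
    assert (assoc.loc[assoc.estimable, "p_bonferroni"]
            >= assoc.loc[assoc.estimable, "p_raw"] - 1e-12).all()
    assert len(matched) > 0
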