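"""Clinical post-hoc characterisation of significant co-medication pairs.

For each dosage-adjusted pair, admissions exposed to the pair are matched
1:1 to control admissions that received the same index drug with a
different co-medication, by nearest-neighbour propensity-score matching
on age, sex, primary diagnosis chapter, weighted Charlson comorbidity
score and medication burden (unique drugs in the admission).  Only a
patient's first exposure is used.

On the matched cohort three analyses run:

* discontinuation of the index drug during concomitant treatment
  (logistic regression on exposure),
* clinical outcomes — 30-day post-admission all-cause mortality and
  30-day post-discharge readmission (Cox partial likelihood stratified by
  matched pair, Breslow ties) and length of stay (stratified Poisson,
  fitted through its exact conditional likelihood: within a 1:1 matched
  pair the Poisson counts conditioned on their total are binomial with
  logit equal to the exposure effect plus covariate differences),
* enrichment of diagnoses and abnormal blood tests present in >= 50
  patients (logistic regression; blood tests not taken count as within
  reference range).

All models adjust for age, sex, primary diagnosis, Charlson score and
medication burden; p-values are Bonferroni-corrected within one family
per endpoint type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter

from .episode_builder import MONOTHERAPY

logger = logging.getLogger(__name__)

MATCH_COVARIATES = ["age", "sex", "icd10_chapter", "charlson", "n_unique_drugs"]
MIN_CODE_PATIENTS = 50
MIN_PER_DAY = 24 * 60


@dataclass
class MatchedCohort:
    pair: tuple
    matches: pd.DataFrame  # pair_id, exposed/control admission ids, scores
    admissions: pd.DataFrame  # covariate rows for all matched admissions

    @property
    def n_pairs(self) -> int:
        return len(self.matches)


@dataclass
class AssociationResult:
    pair: tuple
    endpoint: str
    effect: float          # log-hazard, log-rate or log-odds
    se: float
    p_raw: float
    p_bonferroni: float = np.nan
    direction: int = 0
    n: int = 0
    estimable: bool = True


class MatchingError(RuntimeError):
    """No eligible controls for a pair."""


# ---------------------------------------------------------------------------
# matching

def _design_matrix(adm: pd.DataFrame) -> np.ndarray:
    """Numeric adjustment design from the matching covariates."""
    chap = pd.get_dummies(adm["icd10_chapter"], drop_first=True, dtype=float)
    X = np.column_stack([
        adm["age"].to_numpy(float),
        adm["sex"].to_numpy(float),
        adm["charlson"].to_numpy(float),
        adm["n_unique_drugs"].to_numpy(float),
    ] + ([chap.to_numpy()] if chap.shape[1] else []))
    return X


def propensity_scores(adm: pd.DataFrame, exposed: np.ndarray) -> np.ndarray:
    """Propensity of exposure from a logistic model on the matching
    covariates.  Falls back to the empirical rate under separation."""
    D = _design_matrix(adm)
    D = D[:, D.std(axis=0) > 0]          # constant covariates carry no signal
    X = sm.add_constant(D, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(exposed.astype(float), X).fit(disp=0, maxiter=200)
        return np.asarray(fit.predict(X), float)
    except Exception:  # perfect separation or singular design
        logger.warning("propensity model failed; using empirical rate")
        return np.full(len(adm), exposed.mean(), float)


def match_cohort(
    pair: tuple,
    episodes: pd.DataFrame,
    admissions: pd.DataFrame,
    seed: int,
) -> MatchedCohort:
    """1:1 greedy nearest-neighbour propensity matching for one pair.

    Exposed: first admission (per patient) with a concomitant episode of
    the pair.  Controls: first admission of patients never exposed to the
    pair whose admissions carry the same index drug with a different
    co-medication.  Greedy order is seeded-random; distance ties break on
    the lowest admission id.
    """
    index_drug, co_med = pair
    conc = episodes[(episodes["index_drug"] == index_drug)
                    & (episodes["co_med"] != MONOTHERAPY)]
    adm_start = admissions.set_index("admission_id")["start_min"]

    is_pair = conc["co_med"] == co_med
    exp_adm = conc.loc[is_pair, ["patient_id", "admission_id"]].drop_duplicates()
    exposed_patients = set(exp_adm["patient_id"])
    ctl_adm = conc.loc[~conc["patient_id"].isin(exposed_patients),
                       ["patient_id", "admission_id"]].drop_duplicates()
    if ctl_adm.empty or exp_adm.empty:
        raise MatchingError(f"pair {pair}: no exposed or no eligible controls")

    def first_per_patient(df: pd.DataFrame) -> pd.DataFrame:
        df = df.assign(start=df["admission_id"].map(adm_start))
        df = df.sort_values(["patient_id", "start", "admission_id"])
        return df.groupby("patient_id", as_index=False).first()

    exp_adm = first_per_patient(exp_adm)
    ctl_adm = first_per_patient(ctl_adm)

    ids = pd.concat([exp_adm["admission_id"], ctl_adm["admission_id"]])
    adm = admissions[admissions["admission_id"].isin(set(ids))].copy()
    adm = adm.sort_values("admission_id").reset_index(drop=True)
    exposed_flag = adm["admission_id"].isin(set(exp_adm["admission_id"])).to_numpy()
    adm["propensity"] = propensity_scores(adm, exposed_flag)
    adm["exposed"] = exposed_flag.astype(int)

    exp_rows = adm[adm["exposed"] == 1]
    ctl_rows = adm[adm["exposed"] == 0]

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(exp_rows))
    ctl_ids = ctl_rows["admission_id"].to_numpy()
    ctl_scores = ctl_rows["propensity"].to_numpy()
    used = np.zeros(len(ctl_rows), bool)
    rows = []
    for k, i in enumerate(order):
        erow = exp_rows.iloc[i]
        dist = np.abs(ctl_scores - erow["propensity"])
        dist[used] = np.inf
        if not np.isfinite(dist).any():
            break
        best = np.min(dist)
        cand = np.flatnonzero(dist == best)
        j = cand[np.argmin(ctl_ids[cand])]  # tie-break: lowest admission id
        used[j] = True
        rows.append({
            "pair_id": f"M{k:06d}",
            "exposed_admission": erow["admission_id"],
            "control_admission": ctl_ids[j],
            "exposed_score": float(erow["propensity"]),
            "control_score": float(ctl_scores[j]),
        })
    if not rows:
        raise MatchingError(f"pair {pair}: matching produced no pairs")
    return MatchedCohort(pair=pair, matches=pd.DataFrame(rows), admissions=adm)


def standardized_mean_differences(adm: pd.DataFrame,
                                  exposed: np.ndarray) -> pd.Series:
    """Absolute standardised mean differences of the numeric matching
    covariates between exposed and controls (balance diagnostic)."""
    out = {}
    for c in ("age", "sex", "charlson", "n_unique_drugs"):
        a = adm.loc[exposed, c].to_numpy(float)
        b = adm.loc[~exposed, c].to_numpy(float)
        s = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2) if len(a) > 1 and len(b) > 1 else 0.0
        out[c] = abs(a.mean() - b.mean()) / s if s > 0 else 0.0
    return pd.Series(out)


# ---------------------------------------------------------------------------
# outcome analyses

def _matched_long(matched: MatchedCohort, admissions: pd.DataFrame) -> pd.DataFrame:
    """One row per matched admission with pair_id and exposure."""
    m = matched.matches
    long = pd.concat([
        pd.DataFrame({"admission_id": m["exposed_admission"],
                      "pair_id": m["pair_id"], "exposure": 1}),
        pd.DataFrame({"admission_id": m["control_admission"],
                      "pair_id": m["pair_id"], "exposure": 0}),
    ], ignore_index=True)
    return long.merge(admissions, on="admission_id", how="left", validate="1:1")


def _adjusted_design(df: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame({
        "exposure": df["exposure"].to_numpy(float),
        "age": df["age"].to_numpy(float),
        "sex": df["sex"].to_numpy(float),
        "charlson": df["charlson"].to_numpy(float),
        "n_unique_drugs": df["n_unique_drugs"].to_numpy(float),
    })
    chap = pd.get_dummies(df["icd10_chapter"], prefix="chap", drop_first=True, dtype=float)
    return pd.concat([X, chap.reset_index(drop=True)], axis=1)


def _pair_difference_terms(data: pd.DataFrame, covariate_cols: list) -> np.ndarray:
    """Within-pair covariate differences carrying partial-likelihood
    information for 1:1-matched stratified Cox (Breslow ties).

    For a two-subject stratum the partial likelihood reduces to
    conditional-logistic terms log expit((x_event - x_other)' beta): one
    term when exactly one member has an event while the other is still at
    risk, one term for the earlier event when both fail at distinct
    times, and two mirrored terms when both fail simultaneously."""
    d = data.sort_values("pair_id", kind="stable")
    counts = d["pair_id"].value_counts()
    d = d[d["pair_id"].map(counts) == 2]
    a, b = d.iloc[0::2], d.iloc[1::2]
    t1, t2 = a["duration"].to_numpy(), b["duration"].to_numpy()
    e1, e2 = a["event"].to_numpy(bool), b["event"].to_numpy(bool)
    delta = a[covariate_cols].to_numpy(float) - b[covariate_cols].to_numpy(float)
    # member 1 fails while member 2 is in the risk set, and vice versa;
    # a tied double event contributes both mirrored terms (Breslow)
    pos = (e1 & e2 & (t1 <= t2)) | (e1 & ~e2 & (t2 >= t1))
    neg = (e1 & e2 & (t1 >= t2)) | (~e1 & e2 & (t1 >= t2))
    return np.vstack([delta[pos], -delta[neg]])


def _cox_result(pair, endpoint, df, durations, events,
                engine: str = "conditional") -> AssociationResult:
    data = _adjusted_design(df)
    cols = [c for c in data.columns if data[c].nunique() > 1 or c == "exposure"]
    data = data[cols]
    data["duration"] = np.maximum(durations, 1e-6)
    data["event"] = events.astype(int)
    data["pair_id"] = df["pair_id"].to_numpy()
    if data["event"].sum() == 0:
        return AssociationResult(pair, endpoint, np.nan, np.nan, np.nan,
                                 estimable=False)
    try:
        if engine == "lifelines":
            cph = CoxPHFitter()
            cph.fit(data, duration_col="duration", event_col="event",
                    strata=["pair_id"], robust=False)
            eff = float(cph.params_["exposure"])
            se = float(cph.standard_errors_["exposure"])
            p = float(cph.summary.loc["exposure", "p"])
        else:
            covariate_cols = [c for c in cols]
            diffs = _pair_difference_terms(data, covariate_cols)
            if len(diffs) < 2:
                raise ValueError("no informative pairs")
            X = pd.DataFrame(diffs, columns=covariate_cols)
            X = X.loc[:, (X != 0).any()]
            if "exposure" not in X.columns:
                raise ValueError("exposure constant within pairs")
            with np.errstate(all="ignore"):
                fit = sm.GLM(np.ones(len(X)), X,
                             family=sm.families.Binomial()).fit()
            eff = float(fit.params["exposure"])
            se = float(fit.bse["exposure"])
            p = float(fit.pvalues["exposure"])
        if not np.isfinite(eff) or not np.isfinite(se) or se > 50 or abs(eff) > 10:
            raise ValueError("non-finite or separated estimate")
        return AssociationResult(pair, endpoint, eff, se, p,
                                 direction=int(np.sign(eff)), n=len(df))
    except Exception as exc:
        logger.warning("%s Cox model inestimable for %s: %s", endpoint, pair, exc)
        return AssociationResult(pair, endpoint, np.nan, np.nan, np.nan,
                                 estimable=False)


def _logit_result(pair, endpoint, outcome, design) -> AssociationResult:
    y = np.asarray(outcome, float)
    if y.min() == y.max():
        return AssociationResult(pair, endpoint, np.nan, np.nan, np.nan,
                                 estimable=False)
    X = sm.add_constant(design, has_constant="add")
    X = X.loc[:, X.nunique() > 1] if isinstance(X, pd.DataFrame) else X
    X = sm.add_constant(X, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            try:
                fit = sm.Logit(y, X.astype(float)).fit(disp=0, maxiter=200)
            except Exception:
                fit = sm.Logit(y, X.astype(float)).fit(
                    disp=0, method="bfgs", maxiter=500)
        eff = float(fit.params["exposure"])
        se = float(fit.bse["exposure"])
        p = float(fit.pvalues["exposure"])
        if not np.isfinite(eff) or not np.isfinite(se) or se > 50 or abs(eff) > 10:
            raise ValueError("separation")
        return AssociationResult(pair, endpoint, eff, se, p,
                                 direction=int(np.sign(eff)), n=len(y))
    except Exception as exc:
        logger.warning("%s logistic model inestimable for %s: %s",
                       endpoint, pair, exc)
        return AssociationResult(pair, endpoint, np.nan, np.nan, np.nan,
                                 estimable=False)


def test_outcomes(matched: MatchedCohort, admissions: pd.DataFrame,
                  cox_engine: str = "conditional") -> list[AssociationResult]:
    """Mortality (30 d post-admission), readmission (30 d post-discharge)
    and length of stay on the matched cohort.

    ``cox_engine``: "conditional" (pair-difference partial likelihood,
    exact for 1:1 strata) or "lifelines" (generic stratified fitter)."""
    df = _matched_long(matched, admissions)
    results = []

    # 30-day post-admission mortality
    death_days = (df["death_min"] - df["start_min"]) / MIN_PER_DAY
    event = df["death"].astype(bool) & (death_days <= 30.0)
    duration = np.where(event, death_days, 30.0)
    results.append(_cox_result(matched.pair, "mortality_30d", df,
                               duration, event.to_numpy(), engine=cox_engine))

    # 30-day post-discharge readmission
    nxt = _next_admission_gap_days(df, admissions)
    event_r = nxt <= 30.0
    duration_r = np.where(event_r, nxt, 30.0)
    results.append(_cox_result(matched.pair, "readmission_30d", df,
                               duration_r, event_r, engine=cox_engine))

    # LOS via exact conditional (stratified) Poisson on pair totals
    results.append(_los_result(matched, df))
    return results


def _next_admission_gap_days(df: pd.DataFrame, admissions: pd.DataFrame) -> np.ndarray:
    adm = admissions.sort_values(["patient_id", "start_min"])
    nxt = adm.groupby("patient_id")["start_min"].shift(-1)
    gap = (nxt - adm["end_min"]) / MIN_PER_DAY
    gap_by_adm = pd.Series(gap.to_numpy(), index=adm["admission_id"])
    out = df["admission_id"].map(gap_by_adm).to_numpy(float)
    out[~np.isfinite(out)] = np.inf
    return out


def _los_result(matched: MatchedCohort, df: pd.DataFrame) -> AssociationResult:
    los = ((df["end_min"] - df["start_min"]) / MIN_PER_DAY).round().astype(int)
    df = df.assign(los=np.maximum(los, 1))
    wide = df.pivot_table(index="pair_id",
                          columns="exposure",
                          values=["los", "age", "sex", "charlson", "n_unique_drugs"])
    try:
        y1 = wide[("los", 1)].to_numpy(float)
        y0 = wide[("los", 0)].to_numpy(float)
    except KeyError:
        return AssociationResult(matched.pair, "LOS", np.nan, np.nan, np.nan,
                                 estimable=False)
    n = y1 + y0
    ok = n > 0
    if ok.sum() < 2:
        return AssociationResult(matched.pair, "LOS", np.nan, np.nan, np.nan,
                                 estimable=False)
    diffs = np.column_stack([
        wide[(c, 1)].to_numpy(float) - wide[(c, 0)].to_numpy(float)
        for c in ("age", "sex", "charlson", "n_unique_drugs")
    ])
    X = sm.add_constant(diffs[ok], has_constant="add")
    try:
        with np.errstate(all="ignore"):
            fit = sm.GLM(np.column_stack([y1[ok], y0[ok]]), X,
                         family=sm.families.Binomial()).fit()
        eff = float(fit.params[0])   # log rate ratio (exposure effect)
        se = float(fit.bse[0])
        p = float(fit.pvalues[0])
        return AssociationResult(matched.pair, "LOS", eff, se, p,
                                 direction=int(np.sign(eff)), n=int(ok.sum()))
    except Exception as exc:
        logger.warning("LOS model inestimable for %s: %s", matched.pair, exc)
        return AssociationResult(matched.pair, "LOS", np.nan, np.nan, np.nan,
                                 estimable=False)


def test_enrichment(
    matched: MatchedCohort,
    diagnoses: pd.DataFrame,
    blood_tests: pd.DataFrame,
    admissions: pd.DataFrame,
    min_patients: int = MIN_CODE_PATIENTS,
) -> list[AssociationResult]:
    """Diagnosis and abnormal-blood-test enrichment on the matched cohort.

    Codes present in fewer than ``min_patients`` matched patients are
    skipped; blood tests with no row for an admission are treated as
    within reference range (normal)."""
    df = _matched_long(matched, admissions)
    design = _adjusted_design(df)
    results = []

    dx = diagnoses[diagnoses["admission_id"].isin(set(df["admission_id"]))]
    pat_of_adm = df.set_index("admission_id")["patient_id"]
    for code, sub in dx.groupby("icd10"):
        n_pat = sub["admission_id"].map(pat_of_adm).nunique()
        if n_pat < min_patients:
            continue
        has = df["admission_id"].isin(set(sub["admission_id"])).astype(float)
        results.append(_logit_result(matched.pair, f"diagnosis:{code}", has, design))

    bt = blood_tests[blood_tests["admission_id"].isin(set(df["admission_id"]))]
    for code, sub in bt.groupby("test_code"):
        n_pat = sub["admission_id"].map(pat_of_adm).nunique()
        if n_pat < min_patients:
            continue
        abn = df["admission_id"].map(
            sub.set_index("admission_id")["abnormal"]).fillna(0).astype(float)
        results.append(_logit_result(matched.pair, f"bloodtest:{code}", abn, design))
    return results


def test_discontinuation(
    matched: MatchedCohort,
    episodes: pd.DataFrame,
    admissions: pd.DataFrame,
) -> AssociationResult:
    """Association of exposure with index-drug discontinuation during
    concomitant treatment, on the matched cohort."""
    index_drug, co_med = matched.pair
    df = _matched_long(matched, admissions)
    conc = episodes[(episodes["index_drug"] == index_drug)
                    & (episodes["co_med"] != MONOTHERAPY)]
    disc = conc.groupby("admission_id")["discontinued"].any()
    outcome = df["admission_id"].map(disc).fillna(False).astype(float)
    return _logit_result(matched.pair, "discontinuation", outcome,
                         _adjusted_design(df))


# ---------------------------------------------------------------------------
# multiple testing

def bonferroni(results: Sequence[AssociationResult]) -> list[AssociationResult]:
    """Bonferroni within one family per endpoint type; family sizes are
    the count of estimable tests of that type."""
    by_type: dict[str, int] = {}
    for r in results:
        t = r.endpoint.split(":")[0]
        if r.estimable:
            by_type[t] = by_type.get(t, 0) + 1
    for t, m in sorted(by_type.items()):
        logger.info("Bonferroni family %s: %d tests", t, m)
    for r in results:
        t = r.endpoint.split(":")[0]
        if r.estimable and np.isfinite(r.p_raw):
            r.p_bonferroni = min(1.0, r.p_raw * by_type.get(t, 1))
    return list(results)


def run_posthoc(
    significant_pairs: Sequence[tuple],
    episodes: pd.DataFrame,
    admissions: pd.DataFrame,
    diagnoses: pd.DataFrame,
    blood_tests: pd.DataFrame,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run all three post-hoc analyses for every significant pair.

    Returns (associations table, matched-pairs table)."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(max(len(significant_pairs), 1))
    all_results: list[AssociationResult] = []
    matched_rows = []
    for child, pair in zip(children, significant_pairs):
        pair = tuple(pair)
        try:
            matched = match_cohort(pair, episodes, admissions,
                                   int(child.generate_state(1)[0] % (2**31)))
        except MatchingError as exc:
            logger.warning("skipping %s: %s", pair, exc)
            continue
        m = matched.matches.assign(index_drug=pair[0], co_med=pair[1])
        matched_rows.append(m)
        all_results.append(test_discontinuation(matched, episodes, admissions))
        all_results.extend(test_outcomes(matched, admissions))
        all_results.extend(test_enrichment(matched, diagnoses, blood_tests, admissions))
    bonferroni(all_results)
    assoc = pd.DataFrame([{
        "index_drug": r.pair[0], "co_med": r.pair[1], "endpoint": r.endpoint,
        "effect": r.effect, "se": r.se, "p_raw": r.p_raw,
        "p_bonferroni": r.p_bonferroni, "direction": r.direction,
        "n": r.n, "estimable": r.estimable,
    } for r in all_results])
    matched_df = (pd.concat(matched_rows, ignore_index=True)
                  if matched_rows else pd.DataFrame())
    return assoc, matched_df
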