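"""Synthetic inpatient EHR cohort with planted dosage-adjustment effects.

Emulates the structure of timestamped inpatient prescription data:
admissions with covariates (age, sex, hospital, calendar year, primary
ICD-10 chapter, comorbidity score), per-admission drug courses made of
daily prescriptions with dosing regimens, plus diagnosis, blood-test,
drug-interaction (DDI), pharmacokinetic and literature co-mention
reference tables.

The generative model for dosage changes is the same binomial-logistic
model the inference stage fits, run forward: at each successive
prescription of a drug, the regimen is resampled (to a different menu
entry, so the ADD provably changes) with probability

    p = inv_logit(beta0 + sum_co beta_co + beta_age*age + beta_sex*sex
                  + hospital + diagnosis + year + gamma_patient)

where the beta_co sum runs over the *other drugs active at that
prescription's start*.  Co-medication activity intervals are aligned to
the index drug's daily prescription grid, so the exposure status used at
generation time is exactly the exposure the episode builder attributes to
the transition downstream.

All times are minutes since the cohort epoch (2008-01-01); intervals are
half-open [start, end).  A fixed seed makes every table byte-identical
under replay.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

MIN_PER_DAY = 24 * 60
EPOCH_YEAR = 2008
N_YEARS = 8

_ATC_LETTERS = "ABCDGHJLMNPRSV"
_CHAPTERS = ["I", "II", "IV", "VI", "IX", "X", "XI", "XIII", "XIV", "XIX"]
_HOSPITALS = ["H1", "H2", "H3", "H4"]

#: CYPs and transporters considered for shared pharmacokinetic activity
PK_PROTEINS = [
    "CYP1A2", "CYP2B6", "CYP2C8", "CYP2C9", "CYP2C19", "CYP2D6", "CYP2E1",
    "CYP3A4", "CYP3A5", "CYP3A7", "ABCB1", "BCRP", "MATE1", "MATE2K",
    "OAT1", "OAT3", "OCT1", "OCT2", "OATP1B1", "OATP1B3", "PSP",
]
PK_ROLES = ["inducer", "inhibitor", "substrate"]

#: default regimen menu — all entries have distinct numeric ADDs so a
#: resample is always a genuine dosage change
DEFAULT_REGIMEN_MENU = [
    (200.0, 3, 24.0, "mg"),   # ADD 600
    (400.0, 2, 24.0, "mg"),   # ADD 800
    (100.0, 3, 24.0, "mg"),   # ADD 300
    (250.0, 2, 24.0, "mg"),   # ADD 500
    (50.0, 3, 24.0, "mg"),    # ADD 150
]


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


@dataclass
class OutcomeEffects:
    """Planted clinical post-hoc effects applied to admissions exposed to
    ``effect_pair`` (log scale; 0 = null)."""

    mortality_loghr: float = 0.0
    readmission_loghr: float = 0.0
    los_lograte: float = 0.0
    discontinuation_logodds: float = 0.0
    bloodtest_logodds: float = 0.0
    diagnosis_logodds: float = 0.0


@dataclass
class CohortConfig:
    n_patients: int = 1000
    n_drugs: int = 8
    max_admissions_per_patient: int = 3
    #: ("lognormal", mu, sigma) of LOS in days, rounded up to whole days
    admission_los_distribution: tuple = ("lognormal", 1.5, 0.5)
    baseline_change_logit: float = -1.5
    #: (index_drug, co_med) -> log-odds effect on dosage change
    planted_effects: dict = field(default_factory=dict)
    #: scalar effect scales; categorical covariates get level effects
    #: spaced linearly in [-c, c]
    covariate_effects: dict = field(default_factory=lambda: {
        "age": 0.2, "sex": -0.1, "hospital": 0.1, "diagnosis": 0.15, "year": 0.05,
    })
    patient_sd: float = 0.3
    regimen_menu: list = field(default_factory=lambda: list(DEFAULT_REGIMEN_MENU))
    pn_vao_fraction: float = 0.05
    one_time_fraction_per_drug: dict = field(default_factory=dict)
    seed: int = 0

    # generator shape parameters (admission/drug-course structure)
    index_presence_prob: float = 0.8
    pair_comed_prob: float = 0.35
    filler_presence_prob: float = 0.10
    missing_dose_prob: float = 0.05
    baseline_mortality_30d: float = 0.04
    baseline_readmission_mean_days: float = 120.0
    bloodtest_base_logit: float = -2.0
    diagnosis_base_logit: float = -2.2
    discontinuation_base_logit: float = -2.0
    outcome_effects: OutcomeEffects = field(default_factory=OutcomeEffects)
    #: pair receiving the planted outcome effects (defaults to the first
    #: planted dosage effect pair, else (drug0, drug1))
    effect_pair: Optional[tuple] = None

    def validate(self, drugs: list[str]) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.patient_sd < 0:
            raise ConfigurationError("patient_sd must be >= 0")
        for p in (self.pn_vao_fraction, self.index_presence_prob,
                  self.pair_comed_prob, self.filler_presence_prob,
                  self.missing_dose_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability out of [0,1]: {p}")
        for q in self.one_time_fraction_per_drug.values():
            if not 0.0 <= q <= 1.0:
                raise ConfigurationError("one-time fraction out of [0,1]")
        kind = self.admission_los_distribution[0]
        if kind != "lognormal":
            raise ConfigurationError(f"unknown LOS distribution: {kind}")
        if self.admission_los_distribution[2] < 0:
            raise ConfigurationError("LOS sigma must be >= 0")
        universe = set(drugs)
        for a, b in self.planted_effects:
            if a not in universe or b not in universe:
                raise ConfigurationError(
                    f"planted effect pair ({a}, {b}) outside drug universe")


@dataclass
class SyntheticCohort:
    admissions: pd.DataFrame
    prescriptions: pd.DataFrame
    diagnoses: pd.DataFrame
    blood_tests: pd.DataFrame
    ddi_reference: pd.DataFrame
    pk_annotations: pd.DataFrame
    variants: pd.DataFrame
    comention_counts: pd.DataFrame
    truth: dict
    drugs: list
    config: CohortConfig


def make_drug_codes(n_drugs: int, rng: np.random.Generator) -> list[str]:
    """Synthetic ATC-like level-5 codes, unique and deterministic."""
    codes: list[str] = []
    seen = set()
    while len(codes) < n_drugs:
        a = _ATC_LETTERS[rng.integers(len(_ATC_LETTERS))]
        code = f"{a}{rng.integers(1, 17):02d}{_ATC_LETTERS[rng.integers(len(_ATC_LETTERS))]}" \
               f"{_ATC_LETTERS[rng.integers(len(_ATC_LETTERS))]}{rng.integers(1, 100):02d}"
        if code not in seen:
            seen.add(code)
            codes.append(code)
    return codes


def _level_effects(n_levels: int, scale: float) -> np.ndarray:
    """Centered categorical level effects spaced linearly in [-scale, scale]."""
    if n_levels == 1 or scale == 0:
        return np.zeros(n_levels)
    return np.linspace(-scale, scale, n_levels)


def _menu_index_resample(rng: np.random.Generator, current: int, k: int) -> int:
    j = int(rng.integers(k - 1))
    return j if j < current else j + 1


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort.  Deterministic for equal seeds."""
    rng = np.random.default_rng(config.seed)
    drugs = make_drug_codes(config.n_drugs, rng)
    config.validate(drugs)

    index_drug = drugs[0]
    pair_drug = drugs[1] if config.n_drugs > 1 else None
    filler_drugs = drugs[2:]
    effect_pair = config.effect_pair
    if effect_pair is None:
        effect_pair = next(iter(config.planted_effects), None)
    if effect_pair is None and pair_drug is not None:
        effect_pair = (index_drug, pair_drug)
    eff = config.outcome_effects

    cov_eff = {k: float(config.covariate_effects.get(k, 0.0))
               for k in ("age", "sex", "hospital", "diagnosis", "year")}
    hosp_eff = _level_effects(len(_HOSPITALS), cov_eff["hospital"])
    chap_eff = _level_effects(len(_CHAPTERS), cov_eff["diagnosis"])
    year_eff = _level_effects(N_YEARS, cov_eff["year"])
    menu = config.regimen_menu
    k_menu = len(menu)
    mort_rate_30d = -math.log(max(1e-12, 1.0 - config.baseline_mortality_30d)) / 30.0
    mu_los, sd_los = config.admission_los_distribution[1], config.admission_los_distribution[2]

    admissions, prescriptions, diagnoses, blood_tests = [], [], [], []
    rx_counter = itertools.count()
    adm_counter = itertools.count()

    for pid in range(config.n_patients):
        patient_id = f"P{pid:06d}"
        gamma_p = float(rng.normal(0.0, config.patient_sd))
        age = float(np.clip(rng.normal(62.0, 18.0), 18.0, 100.0))
        sex = int(rng.integers(2))
        n_adm = int(rng.integers(1, config.max_admissions_per_patient + 1))
        t = float(rng.uniform(0, (N_YEARS - 1) * 365.25)) * MIN_PER_DAY
        dead = False

        for _ in range(n_adm):
            if dead or t >= N_YEARS * 365.25 * MIN_PER_DAY:
                break
            admission_id = f"A{next(adm_counter):07d}"
            hosp = int(rng.integers(len(_HOSPITALS)))
            chap = int(rng.integers(len(_CHAPTERS)))
            year = min(EPOCH_YEAR + int(t / (365.25 * MIN_PER_DAY)), EPOCH_YEAR + N_YEARS - 1)
            charlson = int(rng.poisson(1.5))
            base_los = max(2, int(math.ceil(rng.lognormal(mu_los, sd_los))))

            # choose the admission's drug courses
            has_index = rng.random() < config.index_presence_prob
            has_pair = pair_drug is not None and rng.random() < config.pair_comed_prob
            fillers = [d for d in filler_drugs
                       if rng.random() < config.filler_presence_prob]
            exposed = bool(
                effect_pair is not None and has_index and has_pair
                and effect_pair == (index_drug, pair_drug)
            )
            # planted LOS effect scales the stay length
            los = max(2, int(round(base_los * math.exp(eff.los_lograte if exposed else 0.0))))

            age_std = (age - 62.0) / 18.0
            eta_base = (config.baseline_change_logit
                        + cov_eff["age"] * age_std + cov_eff["sex"] * sex
                        + hosp_eff[hosp] + chap_eff[chap]
                        + year_eff[year - EPOCH_YEAR] + gamma_p)

            # activity windows in whole days relative to admission start
            courses: dict[str, tuple[int, int]] = {}
            if has_index:
                courses[index_drug] = (0, los)
            if has_pair:
                a = int(rng.integers(0, los - 1))
                b = int(rng.integers(a + 1, los + 1))
                courses[pair_drug] = (a, b)
            for d in fillers:
                a = int(rng.integers(0, los))
                b = int(rng.integers(a + 1, los + 1))
                courses[d] = (a, b)

            # discontinuation: truncate the index course strictly inside a
            # co-medication's window (base rate for any co-medication, the
            # planted extra log-odds for the designated pair)
            if has_index:
                cands = [d for d, (a, b) in courses.items()
                         if d != index_drug and b - a >= 2 and b < los]
                if cands:
                    cand = pair_drug if (has_pair and pair_drug in cands) \
                        else cands[int(rng.integers(len(cands)))]
                    p_disc = _sigmoid(
                        config.discontinuation_base_logit
                        + (eff.discontinuation_logodds
                           if exposed and cand == pair_drug else 0.0))
                    if rng.random() < p_disc:
                        a, b = courses[cand]
                        stop = int(rng.integers(a + 1, b))
                        courses[index_drug] = (0, stop)

            def active_at(day: int, drug: str) -> list[str]:
                return [d for d, (s, e) in courses.items() if d != drug and s <= day < e]

            for drug, (s, e) in sorted(courses.items()):
                one_time_q = config.one_time_fraction_per_drug.get(drug, 0.0)
                if one_time_q > 0 and rng.random() < one_time_q:
                    day = int(rng.integers(s, e))
                    dose, freqn, interval, unit = menu[int(rng.integers(k_menu))]
                    prescriptions.append(_rx_row(
                        next(rx_counter), admission_id, patient_id, drug,
                        t + day * MIN_PER_DAY, t + (day + 1) * MIN_PER_DAY,
                        dose, unit, freqn, interval, "one-time"))
                    continue
                course_type = "scheduled"
                if drug != index_drug and rng.random() < config.pn_vao_fraction:
                    course_type = "PN" if rng.random() < 0.5 else "VAO"
                cur = int(rng.integers(k_menu))
                for day in range(s, e):
                    if day > s and course_type == "scheduled":
                        eta = eta_base + sum(
                            config.planted_effects.get((drug, other), 0.0)
                            for other in active_at(day, drug)
                        )
                        if rng.random() < _sigmoid(eta):
                            cur = _menu_index_resample(rng, cur, k_menu)
                    dose, freqn, interval, unit = menu[cur]
                    start = t + day * MIN_PER_DAY
                    end = t + (day + 1) * MIN_PER_DAY
                    if course_type == "scheduled" and rng.random() < config.missing_dose_prob:
                        # dose omitted; recoverable as strength x (default 1 volume)
                        prescriptions.append(_rx_row(
                            next(rx_counter), admission_id, patient_id, drug,
                            start, end, np.nan, unit, freqn, interval,
                            course_type, strength=dose))
                    else:
                        prescriptions.append(_rx_row(
                            next(rx_counter), admission_id, patient_id, drug,
                            start, end, dose, unit, freqn, interval, course_type))

            # clinical outcomes
            mort_rate = mort_rate_30d * math.exp(eff.mortality_loghr if exposed else 0.0)
            death_gap = rng.exponential(1.0 / mort_rate) if mort_rate > 0 else math.inf
            death = death_gap <= 365.0
            death_min = t + death_gap * MIN_PER_DAY if death else np.nan
            end_min = t + los * MIN_PER_DAY

            # diagnoses: primary chapter + possibly enriched secondary code
            diagnoses.append({"admission_id": admission_id, "patient_id": patient_id,
                              "icd10": f"CH_{_CHAPTERS[chap]}", "kind": "primary"})
            p_dx = _sigmoid(config.diagnosis_base_logit
                            + (eff.diagnosis_logodds if exposed else 0.0))
            if rng.random() < p_dx:
                diagnoses.append({"admission_id": admission_id, "patient_id": patient_id,
                                  "icd10": "E87", "kind": "secondary"})
            if rng.random() < 0.3:
                diagnoses.append({"admission_id": admission_id, "patient_id": patient_id,
                                  "icd10": f"Z{int(rng.integers(10, 99))}", "kind": "secondary"})

            # blood tests: binary in/out of reference range; untaken tests
            # are simply absent rows (downstream treats absent as normal)
            p_bt = _sigmoid(config.bloodtest_base_logit
                            + (eff.bloodtest_logodds if exposed else 0.0))
            if rng.random() < 0.8:  # test taken
                blood_tests.append({"admission_id": admission_id, "patient_id": patient_id,
                                    "test_code": "NPU_CREA",
                                    "abnormal": int(rng.random() < p_bt)})
            if rng.random() < 0.5:
                blood_tests.append({"admission_id": admission_id, "patient_id": patient_id,
                                    "test_code": "NPU_HB",
                                    "abnormal": int(rng.random() < 0.15)})

            admissions.append({
                "admission_id": admission_id, "patient_id": patient_id,
                "start_min": t, "end_min": end_min,
                "age": round(age, 1), "sex": sex, "hospital": _HOSPITALS[hosp],
                "year": year, "icd10_chapter": _CHAPTERS[chap],
                "charlson": charlson,
                "death": int(death), "death_min": death_min,
                "exposed_effect_pair": int(exposed),
                "n_unique_drugs": len(courses),
            })

            if death:
                dead = True
                break
            # gap to next admission carries the planted readmission effect
            gap_mean = config.baseline_readmission_mean_days * math.exp(
                -(eff.readmission_loghr if exposed else 0.0))
            gap_days = 1.05 + rng.exponential(gap_mean)
            t = end_min + gap_days * MIN_PER_DAY

    adm_df = pd.DataFrame(admissions)
    rx_df = pd.DataFrame(prescriptions)
    dx_df = pd.DataFrame(diagnoses, columns=["admission_id", "patient_id", "icd10", "kind"])
    bt_df = pd.DataFrame(blood_tests, columns=["admission_id", "patient_id", "test_code", "abnormal"])

    ddi_df = generate_ddi_reference(drugs, known_fraction=0.3,
                                    seed=int(rng.integers(2**31)))
    pk_df, var_df = _generate_pk_tables(drugs, rng)
    com_df = _generate_comentions(drugs, rng)

    return SyntheticCohort(
        admissions=adm_df, prescriptions=rx_df, diagnoses=dx_df,
        blood_tests=bt_df, ddi_reference=ddi_df, pk_annotations=pk_df,
        variants=var_df, comention_counts=com_df,
        truth=dict(config.planted_effects), drugs=drugs, config=config,
    )


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


def _rx_row(n, admission_id, patient_id, drug, start, end, dose, unit, freq,
            interval, rx_type, strength=np.nan, volume=np.nan) -> dict:
    return {
        "rx_id": f"R{n:08d}", "admission_id": admission_id,
        "patient_id": patient_id, "drug_atc": drug,
        "start": float(start), "end": float(end),
        "dose": dose, "unit": unit, "freq": freq,
        "interval_hours": interval, "rx_type": rx_type,
        "strength": strength, "volume": volume,
    }


def generate_ddi_reference(cohort_drugs: list[str], known_fraction: float,
                           seed: int) -> pd.DataFrame:
    """Symmetric binary DDI reference over all unordered drug pairs."""
    if not 0.0 <= known_fraction <= 1.0:
        raise ConfigurationError("known_fraction out of [0,1]")
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in itertools.combinations(sorted(cohort_drugs), 2):
        rows.append({"drug_a": a, "drug_b": b,
                     "has_ddi": int(rng.random() < known_fraction),
                     "source": "synthetic"})
    return pd.DataFrame(rows, columns=["drug_a", "drug_b", "has_ddi", "source"])


def _generate_pk_tables(drugs: list[str], rng: np.random.Generator):
    pk_rows, var_rows = [], []
    for d in drugs:
        n_prot = int(rng.integers(1, 4))
        prots = rng.choice(len(PK_PROTEINS), size=n_prot, replace=False)
        for p in prots:
            pk_rows.append({"drug": d, "protein": PK_PROTEINS[int(p)],
                            "role": PK_ROLES[int(rng.integers(3))]})
        if rng.random() < 0.3:
            p = int(rng.integers(len(PK_PROTEINS)))
            var_rows.append({"drug": d, "gene": f"{PK_PROTEINS[p]}_GENE",
                             "protein": PK_PROTEINS[p]})
    return (pd.DataFrame(pk_rows, columns=["drug", "protein", "role"]),
            pd.DataFrame(var_rows, columns=["drug", "gene", "protein"]))


def _generate_comentions(drugs: list[str], rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for a, b in itertools.combinations(sorted(drugs), 2):
        if rng.random() < 0.6:
            rows.append({"drug_a": a, "drug_b": b,
                         "n_articles": int(rng.geometric(0.08))})
    return pd.DataFrame(rows, columns=["drug_a", "drug_b", "n_articles"])


# ---------------------------------------------------------------------------
# persistence

_TABLES = {
    "admissions": "admissions.tsv",
    "prescriptions": "prescriptions.tsv",
    "diagnoses": "diagnoses.tsv",
    "blood_tests": "blood_tests.tsv",
    "ddi_reference": "ddi.tsv",
    "pk_annotations": "pk.tsv",
    "variants": "variants.tsv",
    "comention_counts": "comentions.tsv",
}


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write the cohort as a directory of TSV files plus truth and config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for attr, fname in _TABLES.items():
        getattr(cohort, attr).to_csv(outdir / fname, sep="\t", index=False)
    truth = pd.DataFrame(
        [{"index_drug": a, "co_med": b, "log_odds": v}
         for (a, b), v in sorted(cohort.truth.items())],
        columns=["index_drug", "co_med", "log_odds"],
    )
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    cfg = asdict(cohort.config)
    cfg["planted_effects"] = {f"{a}|{b}": v for (a, b), v in cohort.config.planted_effects.items()}
    cfg["one_time_fraction_per_drug"] = dict(cohort.config.one_time_fraction_per_drug)
    cfg["effect_pair"] = list(cohort.config.effect_pair) if cohort.config.effect_pair else None
    cfg["regimen_menu"] = [list(r) for r in cohort.config.regimen_menu]
    cfg["admission_los_distribution"] = list(cfg["admission_los_distribution"])
    (outdir / "config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True))
    (outdir / "data_dictionary.md").write_text(DATA_DICTIONARY)
    return outdir


def read_cohort_tables(indir: str | Path) -> dict[str, pd.DataFrame]:
    indir = Path(indir)
    return {attr: pd.read_csv(indir / fname, sep="\t")
            for attr, fname in _TABLES.items() if (indir / fname).exists()}


DATA_DICTIONARY = """\
# Cohort data dictionary

All times are minutes since the cohort epoch (2008-01-01); intervals are
half-open [start, end).

## admissions.tsv
admission_id, patient_id, start_min, end_min, age (years), sex (0/1),
hospital, year, icd10_chapter, charlson (weighted comorbidity score),
death (0/1), death_min (minutes; empty if alive),
exposed_effect_pair (0/1, generator bookkeeping), n_unique_drugs.

## prescriptions.tsv
rx_id, admission_id, patient_id, drug_atc, start, end (validity, minutes),
dose (per administration), unit, freq (administrations per interval),
interval_hours, rx_type (one-time|scheduled|PN|VAO), strength (package
label strength, used when dose missing), volume.

## diagnoses.tsv
admission_id, patient_id, icd10, kind (primary|secondary).

## blood_tests.tsv
admission_id, patient_id, test_code, abnormal (0/1). Tests not taken are
absent rows and are treated as within reference range downstream.

## ddi.tsv
drug_a, drug_b (unordered, drug_a < drug_b), has_ddi (0/1), source.

## pk.tsv
drug, protein (CYP/transporter), role (inducer|inhibitor|substrate).

## variants.tsv
drug, gene, protein — annotated gene variants mapping to a metabolising
or transporting protein.

## comentions.tsv
drug_a, drug_b, n_articles — literature co-mention counts; absent pair
means zero.

## truth.tsv
index_drug, co_med, log_odds — planted dosage-change effects.
"""
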