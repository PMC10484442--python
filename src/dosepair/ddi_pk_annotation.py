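"""Annotation of significant pairs with interaction and pharmacokinetic
evidence, and comparison of known-DDI vs unknown-DDI groups.

Each significant (index drug, co-medication) pair is annotated with:

* ``has_ddi`` — presence of the unordered pair in a curated binary
  drug-drug-interaction reference table,
* ``shared_cyp`` / ``shared_transporter`` — both drugs act (as inducer,
  inhibitor or substrate; role identity is not required) on a common CYP
  enzyme / transport protein from the regulatory-agency list,
* ``variant_link`` — an annotated gene variant of one drug maps to a
  protein that metabolises or transports the other,
* patient volume and literature co-mention count (absent pair = 0).

Pairs with and without DDI evidence are compared on patient volume,
co-mentions and odds ratio with the two-sided Mann-Whitney U test (exact
distribution when n1*n2 <= 400 and no ties, normal approximation with
tie and continuity correction otherwise); the effect size is
r = |z| / sqrt(n).  Distribution shape is checked with Shapiro-Wilk.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: CYP enzymes (shared_cyp) vs transport proteins (shared_transporter)
CYP_PREFIX = "CYP"

_ATC_RE = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")

#: conventional effect-size magnitude labels
EFFECT_SIZE_CUTS = {"small": 0.1, "moderate": 0.3, "large": 0.5}


@dataclass
class AnnotationRecord:
    index_drug: str
    co_med: str
    has_ddi: bool
    shared_cyp: bool
    shared_transporter: bool
    variant_link: bool
    n_patients: int
    n_comentions: int


@dataclass
class GroupComparison:
    variable: str
    group: str               # "all" or a therapeutic group
    n_ddi: int
    n_unknown: int
    u_statistic: float
    p_two_sided: float
    effect_size_r: float
    magnitude: str


def effect_magnitude(r: float) -> str:
    if r >= EFFECT_SIZE_CUTS["large"]:
        return "large"
    if r >= EFFECT_SIZE_CUTS["moderate"]:
        return "moderate"
    if r >= EFFECT_SIZE_CUTS["small"]:
        return "small"
    return "negligible"


def _valid_atc(code: str) -> bool:
    return bool(_ATC_RE.match(str(code)))


def _pair_key(a: str, b: str) -> tuple:
    return (a, b) if a <= b else (b, a)


def annotate_pairs(
    pairs: pd.DataFrame,
    ddi_table: pd.DataFrame,
    pk_table: pd.DataFrame,
    comention_table: pd.DataFrame,
    variants_table: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Annotate pairs (columns index_drug, co_med, n_patients) with DDI,
    shared-PK, variant and co-mention evidence.

    Malformed ATC codes are rejected with a log entry; annotation is
    symmetric in the two drugs for all evidence flags.
    """
    ddi_pairs = {
        _pair_key(a, b)
        for a, b, f in ddi_table[["drug_a", "drug_b", "has_ddi"]].itertuples(index=False)
        if f
    }
    com = {
        _pair_key(a, b): int(n)
        for a, b, n in comention_table[["drug_a", "drug_b", "n_articles"]]
        .itertuples(index=False)
    }
    prot_of: dict[str, set] = {}
    for d, p in pk_table[["drug", "protein"]].itertuples(index=False):
        prot_of.setdefault(d, set()).add(p)
    var_prot_of: dict[str, set] = {}
    if variants_table is not None and len(variants_table):
        for d, p in variants_table[["drug", "protein"]].itertuples(index=False):
            var_prot_of.setdefault(d, set()).add(p)

    records = []
    for row in pairs.itertuples(index=False):
        a, b = row.index_drug, row.co_med
        if not (_valid_atc(a) and _valid_atc(b)):
            logger.warning("malformed ATC code in pair (%s, %s); row rejected", a, b)
            continue
        shared = prot_of.get(a, set()) & prot_of.get(b, set())
        shared_cyp = any(p.startswith(CYP_PREFIX) for p in shared)
        shared_tr = any(not p.startswith(CYP_PREFIX) for p in shared)
        variant_link = bool(
            var_prot_of.get(a, set()) & prot_of.get(b, set())
            or var_prot_of.get(b, set()) & prot_of.get(a, set())
        )
        records.append({
            "index_drug": a, "co_med": b,
            "has_ddi": _pair_key(a, b) in ddi_pairs,
            "shared_cyp": shared_cyp,
            "shared_transporter": shared_tr,
            "variant_link": variant_link,
            "n_patients": int(getattr(row, "n_patients", 0)),
            "n_comentions": com.get(_pair_key(a, b), 0),
        })
    return pd.DataFrame.from_records(records, columns=[
        "index_drug", "co_med", "has_ddi", "shared_cyp",
        "shared_transporter", "variant_link", "n_patients", "n_comentions"])


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney U with effect size r = |z|/sqrt(n).

    Exact null distribution when n1*n2 <= 400 and there are no ties;
    otherwise the normal approximation with continuity and tie
    correction.  Returns (U, p, r)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = x.size, y.size
    ties = np.unique(np.concatenate([x, y])).size < n1 + n2
    method = "exact" if (n1 * n2 <= 400 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u = float(res.statistic)
    # tie-corrected z for the effect size (continuity-corrected)
    mu = n1 * n2 / 2.0
    all_v = np.concatenate([x, y])
    _, counts = np.unique(all_v, return_counts=True)
    n = n1 + n2
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u, float(res.pvalue), 0.0
    z = (u - mu - math_copysign_half(u - mu)) / np.sqrt(var)
    r = abs(z) / np.sqrt(n)
    return u, float(res.pvalue), float(r)


def math_copysign_half(d: float) -> float:
    """Continuity correction of 0.5 toward the null."""
    if d > 0:
        return 0.5
    if d < 0:
        return -0.5
    return 0.0


def shapiro_normality_p(values: Sequence[float]) -> float:
    """Shapiro-Wilk normality p-value (rationale for the rank test)."""
    return float(stats.shapiro(np.asarray(values, float)).pvalue)


def therapeutic_group(atc: str) -> str:
    """ATC level-2 therapeutic group, e.g. J01."""
    return str(atc)[:3]


def compare_groups(
    annotations: pd.DataFrame,
    posteriors: pd.DataFrame,
    min_group_size: int = 5,
) -> pd.DataFrame:
    """Mann-Whitney comparisons of known-DDI vs unknown-DDI pairs on
    patient volume, co-mentions and OR, overall and per therapeutic group
    of the index drug (groups with < ``min_group_size`` observations per
    DDI class are not reported)."""
    df = annotations.merge(
        posteriors[["index_drug", "co_med", "or_median"]],
        on=["index_drug", "co_med"], how="left", validate="1:1")
    rows = []

    def compare(sub: pd.DataFrame, label: str) -> None:
        g1 = sub[sub["has_ddi"]]
        g0 = sub[~sub["has_ddi"]]
        if len(g1) < min_group_size or len(g0) < min_group_size:
            if label != "all":
                return
            if len(g1) == 0 or len(g0) == 0:
                logger.warning("a DDI-evidence group is empty; comparison skipped")
                return
        for var in ("n_patients", "n_comentions", "or_median"):
            x = g1[var].dropna().to_numpy(float)
            y = g0[var].dropna().to_numpy(float)
            if x.size == 0 or y.size == 0:
                continue
            u, p, r = mann_whitney(x, y)
            rows.append({
                "variable": var, "group": label,
                "n_ddi": x.size, "n_unknown": y.size,
                "u_statistic": u, "p_two_sided": p,
                "effect_size_r": r, "magnitude": effect_magnitude(r),
            })

    compare(df, "all")
    for grp, sub in df.groupby(df["index_drug"].map(therapeutic_group)):
        compare(sub, str(grp))
    return pd.DataFrame(rows, columns=[
        "variable", "group", "n_ddi", "n_unknown", "u_statistic",
        "p_two_sided", "effect_size_r", "magnitude"])
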