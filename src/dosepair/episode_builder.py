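"""Treatment-episode construction and selection filters.

Within an admission, each drug's active timeline (the union of its
prescriptions' validity intervals, abutting intervals chained) is
partitioned into maximal sub-intervals over which the set of *other*
concurrently active drugs is constant.  A sub-interval with no other
active drug is a *monotherapy episode* of the index drug; a sub-interval
where co-medications are active yields one *concomitant episode* per
(index drug, co-medication) pair.  Monotherapy episodes are the reference
condition for the dosage-adjustment model.

Each episode carries the index drug's time-ordered prescriptions whose
validity intersects the episode interval; N is their count, and y counts
the lagged dosage changes — adjacent prescriptions whose ADD differs
after rounding to 6 significant digits.  Episodes whose ADD sequence is
not fully numeric (PN/VAO/one-time/incomputable members) are excluded.

All times are minutes since the cohort epoch; intervals are half-open
[start, end).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .dosage_add import ADD_SIG_DIGITS, round_sig

logger = logging.getLogger(__name__)

MONOTHERAPY = "MONOTHERAPY"

EPISODE_COLUMNS = [
    "episode_id", "patient_id", "admission_id", "index_drug", "co_med",
    "start", "end", "N", "y", "discontinued", "complete", "add_values",
]


@dataclass(frozen=True)
class TreatmentEpisode:
    patient_id: str
    admission_id: str
    index_drug: str
    co_med: str  # ATC code or MONOTHERAPY
    start: float
    end: float
    add_values: tuple[float, ...]
    N: int
    y: int
    discontinued: bool = False
    complete: bool = True

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("episode interval empty")
        if self.complete and not 0 <= self.y <= max(self.N - 1, 0):
            raise ValueError(f"y={self.y} outside [0, N-1] for N={self.N}")


@dataclass
class SelectionReport:
    drugs_considered: int = 0
    drugs_retained: int = 0
    pairs_considered: int = 0
    pairs_retained: int = 0
    exclusions: dict = field(default_factory=dict)

    def count(self, reason: str, n: int = 1) -> None:
        self.exclusions[reason] = self.exclusions.get(reason, 0) + n


def count_changes(add_values: Sequence[float]) -> int:
    """Number of lagged changes in an ordered numeric ADD sequence:
    adjacent pairs that differ after 6-significant-digit rounding."""
    vals = [round_sig(v, ADD_SIG_DIGITS) for v in add_values]
    return sum(1 for a, b in zip(vals, vals[1:]) if a != b)


def merge_intervals(intervals: Iterable[tuple[float, float]],
                    warn_label: Optional[str] = None) -> list[tuple[float, float]]:
    """Union of half-open intervals; abutting intervals chain into one.
    Overlapping duplicates are merged (with a warning when labelled)."""
    ivs = sorted(intervals)
    merged: list[list[float]] = []
    overlapped = False
    for s, e in ivs:
        if e <= s:
            continue
        if merged and s <= merged[-1][1]:
            if s < merged[-1][1]:
                overlapped = True
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    if overlapped and warn_label:
        logger.warning("overlapping duplicate prescriptions merged for %s", warn_label)
    return [(s, e) for s, e in merged]


def merge_readmissions(admissions: pd.DataFrame, gap_hours: float = 24.0) -> pd.DataFrame:
    """Combine a patient's re-admission within ``gap_hours`` of discharge
    into the preceding admission (ingest pre-pass).

    The merged record keeps the first admission's id and covariates and
    extends ``end_min``; a ``merged_into`` mapping column records which
    original admissions were absorbed.
    """
    gap = gap_hours * 60.0
    adm = admissions.sort_values(["patient_id", "start_min"]).reset_index(drop=True)
    keep_rows = []
    mapping: dict[str, str] = {}
    cur = None
    for row in adm.itertuples(index=False):
        r = row._asdict()
        if cur is not None and r["patient_id"] == cur["patient_id"] \
                and r["start_min"] - cur["end_min"] <= gap:
            cur["end_min"] = max(cur["end_min"], r["end_min"])
            cur["death"] = int(cur["death"] or r["death"]) if "death" in cur else cur.get("death")
            mapping[r["admission_id"]] = cur["admission_id"]
        else:
            if cur is not None:
                keep_rows.append(cur)
            cur = r
            mapping[r["admission_id"]] = r["admission_id"]
    if cur is not None:
        keep_rows.append(cur)
    out = pd.DataFrame(keep_rows, columns=list(adm.columns))
    out.attrs["admission_mapping"] = mapping
    return out


def _covering(intervals: list[tuple[float, float]], t: float) -> bool:
    for s, e in intervals:
        if s <= t < e:
            return True
        if s > t:
            return False
    return False


def build_episodes(prescriptions: pd.DataFrame, add_table: pd.DataFrame) -> pd.DataFrame:
    """Construct monotherapy and concomitant treatment episodes.

    ``prescriptions`` must carry PRESCRIPTION_COLUMNS; ``add_table`` is the
    output of :func:`dosepair.dosage_add.compute_add_frame`.  Returns one
    row per episode (EPISODE_COLUMNS).  Episodes with a non-numeric or
    unit-irreconcilable ADD sequence are emitted with ``complete=False``
    and must be dropped by the caller (the selection filter does this).
    """
    from .dosage_add import UNIT_TO_MG

    rx = prescriptions.merge(add_table, on="rx_id", how="left", validate="1:1")
    rx = rx.sort_values(["admission_id", "drug_atc", "start", "rx_id"],
                        kind="stable").reset_index(drop=True)

    adm_arr = rx["admission_id"].to_numpy(object)
    pat_arr = rx["patient_id"].to_numpy(object)
    drug_arr = rx["drug_atc"].to_numpy(object)
    start_arr = rx["start"].to_numpy(float)
    end_arr = rx["end"].to_numpy(float)
    numeric_arr = (rx["add_kind"].to_numpy(object) == "numeric")
    # ADD values on a common scale (mg), rounded for change comparison
    unit_arr = rx["add_unit"].to_numpy(object)
    factor = np.array([UNIT_TO_MG.get(u if u else "mg", np.nan) for u in unit_arr])
    val_arr = rx["add_value"].to_numpy(float) * factor
    ok = numeric_arr & np.isfinite(val_arr)
    val_arr[ok] = [round_sig(v) for v in val_arr[ok]]
    numeric_arr = ok

    n_rows = len(rx)
    # admission slice boundaries
    adm_change = np.flatnonzero(adm_arr[1:] != adm_arr[:-1]) + 1
    adm_slices = np.concatenate([[0], adm_change, [n_rows]])

    episodes: list[tuple] = []
    eid = 0

    for a0, a1 in zip(adm_slices[:-1], adm_slices[1:]):
        admission_id = str(adm_arr[a0])
        patient_id = str(pat_arr[a0])
        # drug slices within the admission (rows sorted by drug, start)
        dchange = np.flatnonzero(drug_arr[a0 + 1:a1] != drug_arr[a0:a1 - 1]) + 1 + a0 \
            if a1 - a0 > 1 else np.array([], dtype=int)
        dslices = np.concatenate([[a0], dchange, [a1]])

        timelines: dict[str, list[tuple[float, float]]] = {}
        rx_of: dict[str, tuple[int, int]] = {}
        for d0, d1 in zip(dslices[:-1], dslices[1:]):
            drug = drug_arr[d0]
            rx_of[drug] = (d0, d1)
            timelines[drug] = merge_intervals(
                zip(start_arr[d0:d1], end_arr[d0:d1]),
                warn_label=drug if d1 - d0 > 1 else None)
        drugs = sorted(timelines)
        bounds = np.unique(np.concatenate(
            [np.array(iv, float).ravel() for iv in timelines.values()]))

        for index_drug in drugs:
            own = timelines[index_drug]
            # last end of the index drug's activity, for discontinuation
            index_last_end = own[-1][1]
            segs: list[list] = []
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                mid = (lo + hi) / 2.0
                if not _covering(own, mid):
                    continue
                active = frozenset(
                    d for d in drugs
                    if d != index_drug and _covering(timelines[d], mid)
                )
                # merge with previous segment when contiguous and same set
                if segs and segs[-1][1] == lo and segs[-1][2] == active:
                    segs[-1][1] = hi
                else:
                    segs.append([lo, hi, active])

            d0, d1 = rx_of[index_drug]
            starts = start_arr[d0:d1]
            ends = end_arr[d0:d1]
            numerics = numeric_arr[d0:d1]
            vals = val_arr[d0:d1]

            for seg_start, seg_end, active in segs:
                mask = (starts < seg_end) & (ends > seg_start)
                n = int(mask.sum())
                numeric = bool(n) and bool(numerics[mask].all())
                if numeric:
                    seq = vals[mask]
                    y = int(np.count_nonzero(seq[1:] != seq[:-1]))
                    add_str = ",".join(f"{v:g}" for v in seq)
                else:
                    y, add_str = 0, ""
                co_meds = sorted(active) if active else [MONOTHERAPY]
                for co in co_meds:
                    disc = False
                    if co != MONOTHERAPY and seg_end == index_last_end:
                        # index stops here: discontinuation iff strictly
                        # inside the co-medication's activity (simultaneous
                        # end is not a discontinuation)
                        disc = any(s < index_last_end < e for s, e in timelines[co])
                    episodes.append((
                        f"E{eid:08d}", patient_id, admission_id, index_drug,
                        co, seg_start, seg_end, n, y, bool(disc),
                        bool(numeric), add_str))
                    eid += 1

    return pd.DataFrame(episodes, columns=EPISODE_COLUMNS)


def flag_discontinuation(episode: TreatmentEpisode,
                         index_intervals: list[tuple[float, float]],
                         co_intervals: list[tuple[float, float]]) -> bool:
    """True iff the index drug's last validity end falls strictly inside
    the co-medication's active interval (no later index prescription)."""
    if episode.co_med == MONOTHERAPY:
        raise ValueError("discontinuation applies to concomitant episodes")
    last_end = max(e for _, e in index_intervals)
    return any(s < last_end < e for s, e in co_intervals)


def one_time_fractions(prescriptions: pd.DataFrame) -> pd.Series:
    """Per-drug fraction of prescriptions that are one-time orders."""
    is_ot = prescriptions["rx_type"].eq("one-time")
    return is_ot.groupby(prescriptions["drug_atc"]).mean()


def apply_selection_filters(
    episodes: pd.DataFrame,
    prescriptions: pd.DataFrame,
    min_index_patients: int = 50,
    min_pair_patients: int = 50,
    one_time_max_fraction: float = 0.70,
) -> tuple[pd.DataFrame, SelectionReport]:
    """Cohort-level drug/pair selection.

    Retains index drugs with a monotherapy episode in at least
    ``min_index_patients`` patients and pairs present in at least
    ``min_pair_patients`` patients; drugs that are one-time orders in more
    than ``one_time_max_fraction`` of their prescriptions are dropped as
    co-medications (but kept as index drugs).  Episodes with incomplete
    ADD sequences are dropped first.
    """
    report = SelectionReport()
    ep = episodes
    n_incomplete = int((~ep["complete"]).sum())
    if n_incomplete:
        report.count("incomplete_add_sequence", n_incomplete)
    ep = ep[ep["complete"]].copy()

    report.drugs_considered = ep["index_drug"].nunique()
    pairs_all = ep.loc[ep["co_med"] != MONOTHERAPY, ["index_drug", "co_med"]].drop_duplicates()
    report.pairs_considered = len(pairs_all)

    # one-time co-medication rule
    frac = one_time_fractions(prescriptions)
    one_time_drugs = set(frac[frac > one_time_max_fraction].index)
    mask_ot = ep["co_med"].isin(one_time_drugs)
    if mask_ot.any():
        dropped_pairs = ep.loc[mask_ot, ["index_drug", "co_med"]].drop_duplicates()
        report.count("co_med_mostly_one_time", len(dropped_pairs))
        ep = ep[~mask_ot]

    # index drugs: >= min monotherapy patients
    mono = ep[ep["co_med"] == MONOTHERAPY]
    mono_patients = mono.groupby("index_drug")["patient_id"].nunique()
    keep_index = set(mono_patients[mono_patients >= min_index_patients].index)
    dropped_index = set(ep["index_drug"]) - keep_index
    if dropped_index:
        report.count("index_below_monotherapy_patient_minimum", len(dropped_index))
    ep = ep[ep["index_drug"].isin(keep_index)]

    # pairs: >= min patients
    conc = ep[ep["co_med"] != MONOTHERAPY]
    pair_patients = conc.groupby(["index_drug", "co_med"])["patient_id"].nunique()
    keep_pairs = set(pair_patients[pair_patients >= min_pair_patients].index)
    dropped_pairs = set(map(tuple, conc[["index_drug", "co_med"]].drop_duplicates().to_numpy())) - keep_pairs
    if dropped_pairs:
        report.count("pair_below_patient_minimum", len(dropped_pairs))
    keep_mask = (ep["co_med"] == MONOTHERAPY).to_numpy() | np.array(
        [(i, c) in keep_pairs for i, c in zip(ep["index_drug"], ep["co_med"])],
        dtype=bool)
    ep = ep[keep_mask].reset_index(drop=True)

    report.drugs_retained = ep["index_drug"].nunique()
    report.pairs_retained = len(
        ep.loc[ep["co_med"] != MONOTHERAPY, ["index_drug", "co_med"]].drop_duplicates()
    )
    return ep, report
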