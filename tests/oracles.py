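"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's interval algebra: activity is
materialised on a per-minute grid and episodes are read off as maximal
runs of constant active-drug sets.
"""

import numpy as np
import pandas as pd


def per_minute_episodes(prescriptions: pd.DataFrame):
    """Enumerate (index_drug, co_med, start, end) episodes per admission by
    scanning a per-minute activity grid.  Returns a set of tuples with
    co_med = 'MONOTHERAPY' for empty active sets, plus one tuple per
    active co-medication in multi-drug segments (mirroring the contract
    of the episode builder)."""
    out = set()
    for admission_id, group in prescriptions.groupby("admission_id"):
        t0 = int(group["start"].min())
        t1 = int(group["end"].max())
        drugs = sorted(group["drug_atc"].unique())
        grid = np.zeros((len(drugs), t1 - t0), dtype=bool)
        for row in group.itertuples(index=False):
            di = drugs.index(row.drug_atc)
            grid[di, int(row.start) - t0: int(row.end) - t0] = True
        for di, index_drug in enumerate(drugs):
            others = [j for j in range(len(drugs)) if j != di]
            # encode the active set of other drugs per minute
            code = np.full(t1 - t0, -1, dtype=np.int64)
            active_minutes = grid[di]
            if others:
                weights = (2 ** np.arange(len(others))).astype(np.int64)
                code_all = (grid[others].astype(np.int64).T @ weights)
            else:
                code_all = np.zeros(t1 - t0, dtype=np.int64)
            code[active_minutes] = code_all[active_minutes]
            # maximal runs of constant code among active minutes
            change = np.flatnonzero(np.diff(code) != 0) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [t1 - t0]])
            for s, e in zip(starts, ends):
                if code[s] < 0:
                    continue
                bits = code[s]
                co_set = [drugs[others[k]] for k in range(len(others))
                          if bits >> k & 1]
                span = (float(s + t0), float(e + t0))
                if co_set:
                    for co in co_set:
                        out.add((admission_id, index_drug, co) + span)
                else:
                    out.add((admission_id, index_drug, "MONOTHERAPY") + span)
    return out


def per_minute_change_counts(prescriptions: pd.DataFrame, add_values: dict):
    """For every oracle episode, count lagged ADD changes over the index
    drug's prescriptions intersecting it (time order by start)."""
    episodes = per_minute_episodes(prescriptions)
    counts = {}
    for adm, index_drug, co, s, e in episodes:
        sub = prescriptions[(prescriptions["admission_id"] == adm)
                            & (prescriptions["drug_atc"] == index_drug)]
        sub = sub[(sub["start"] < e) & (sub["end"] > s)].sort_values(
            ["start", "rx_id"])
        vals = [add_values[r] for r in sub["rx_id"]]
        y = sum(1 for a, b in zip(vals, vals[1:]) if a != b)
        counts[(adm, index_drug, co, s, e)] = (len(vals), y)
    return counts


def shortest_window_hdi(draws, mass):
    """Exhaustive search over all contiguous sorted windows."""
    x = np.sort(np.asarray(draws, float))
    n = x.size
    m = int(np.ceil(mass * n))
    best = (np.inf, None)
    for i in range(n - m + 1):
        w = x[i + m - 1] - x[i]
        if w < best[0]:
            best = (w, (x[i], x[i + m - 1]))
    return best[1]


def random_admission_fixture(rng, max_drugs=5, max_days=30):
    """Random multi-drug admission with arbitrary (minute-resolution)
    validity intervals and integer-valued ADDs."""
    n_drugs = int(rng.integers(1, max_drugs + 1))
    horizon = int(rng.integers(2, max_days + 1)) * 1440
    recs = []
    rid = 0
    for d in range(n_drugs):
        drug = f"D{d:02d}AA{d:02d}"
        n_rx = int(rng.integers(1, 6))
        t = int(rng.integers(0, horizon // 2))
        for _ in range(n_rx):
            length = int(rng.integers(60, horizon // 2))
            end = min(t + length, horizon)
            if end <= t:
                break
            recs.append({
                "rx_id": f"R{rid:05d}", "admission_id": "A1",
                "patient_id": "P1", "drug_atc": drug,
                "start": float(t), "end": float(end),
                "dose": float(rng.integers(1, 5) * 100), "unit": "mg",
                "freq": 1, "interval_hours": 24.0, "rx_type": "scheduled",
                "strength": np.nan, "volume": np.nan,
            })
            rid += 1
            # mostly abutting chains, sometimes gaps
            t = end if rng.random() < 0.7 else end + int(rng.integers(1, 600))
            if t >= horizon:
                break
    return pd.DataFrame(recs)
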