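"""Home-cage spatial-learning analysis from nosepoke event logs.

Animals co-housed in an automated home cage are each assigned one rewarded
port out of eight; the assignment is rotated through novel locations and
finally returned to the original port.  The daily error rate — the fraction
of nosepokes at non-assigned ports within a 24-h window — tracks spatial
learning, and rank correlations between a per-animal ablation covariate
(surviving terminal density) and late-session error rates dissociate the
acquisition of new locations from the retention of old ones.

Note on the error-rate definition: read literally, "ratio between nosepokes
to the assigned port and total" would define a success rate, yet a
"lower than 70%" criterion must indicate learning.  The default therefore
measures error = non-assigned / total; the literal reading is available via
``definition="literal"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import islice, permutations

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import SESSION_SCHEDULE

__all__ = [
    "SessionSchedule",
    "label_sessions",
    "daily_error_rate",
    "apply_exclusion",
    "group_learning_curve",
    "spearman_correlation",
    "ablation_performance_analysis",
]

SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class SessionSchedule:
    """Ordered sessions ``(label, start_day, n_days)``, day 0 = injection.

    The default mirrors the standard protocol: initial learning A (5 d,
    pre-injection), three novel rotations B/C/D (3 d each), return A* (5 d).
    """

    sessions: tuple[tuple[str, int, int], ...] = SESSION_SCHEDULE

    def __post_init__(self) -> None:
        prev_end = None
        for label, start, n in self.sessions:
            if n <= 0:
                raise ValueError(f"session {label} has non-positive length")
            if prev_end is not None and start < prev_end:
                raise ValueError("sessions overlap")
            prev_end = start + n

    def label_of_day(self, day: int) -> str | None:
        for label, start, n in self.sessions:
            if start <= day < start + n:
                return label
        return None

    @property
    def last_initial_day(self) -> int:
        """Last day of the initial learning period (day -1 by default)."""
        label, start, n = self.sessions[0]
        return start + n - 1


def label_sessions(
    log: pd.DataFrame, schedule: SessionSchedule | None = None
) -> pd.DataFrame:
    """Tag every nosepoke with its experimental day and session label.

    Days are 24-h windows anchored at the injection time (timestamp 0), so
    ``day = floor(timestamp_s / 86400)``.  Events outside the schedule get
    session label NaN and ``in_schedule = False``.
    """
    schedule = schedule or SessionSchedule()
    out = log.copy()
    out["day"] = np.floor(
        out["timestamp_s"] / SECONDS_PER_DAY
    ).astype(int)
    out["session_label"] = [
        schedule.label_of_day(d) for d in out["day"]
    ]
    out["in_schedule"] = out["session_label"].notna()
    return out


def daily_error_rate(
    log: pd.DataFrame, definition: str = "error"
) -> pd.DataFrame:
    """Per-animal, per-day error rate.

    ``definition="error"`` (default): non-assigned pokes / total pokes.
    ``definition="literal"``: assigned pokes / total pokes (the success
    rate).  Days with zero pokes are absent from the result.  Returns a
    tidy frame with columns ``animal_id, day, session_label, group,
    n_pokes, error_rate``.
    """
    if definition not in ("error", "literal"):
        raise ValueError("definition must be 'error' or 'literal'")
    if "day" not in log.columns:
        log = label_sessions(log)
    rows = []
    group_cols = ["animal_id", "day"]
    for (animal, day), grp in log.groupby(group_cols, sort=True):
        n = len(grp)
        correct = int((grp["port"] == grp["assigned_port"]).sum())
        rate = correct / n if definition == "literal" else 1.0 - correct / n
        rows.append(
            {
                "animal_id": animal,
                "day": day,
                "session_label": grp["session_label"].iloc[0],
                "group": grp["group"].iloc[0] if "group" in grp else "",
                "n_pokes": n,
                "error_rate": rate,
            }
        )
    return pd.DataFrame(rows)


def apply_exclusion(
    series: pd.DataFrame,
    threshold: float = 0.7,
    last_initial_day: int | None = None,
    schedule: SessionSchedule | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Exclude animals that never learned the initial port.

    Keeps animals whose error rate on the last day of the initial learning
    period is strictly below ``threshold``; animals with no pokes on that
    day are excluded with a logged reason.  Returns
    ``(included_animal_ids, diagnostics)``.
    """
    if last_initial_day is None:
        last_initial_day = (schedule or SessionSchedule()).last_initial_day
    included = []
    diag_rows = []
    for animal, grp in series.groupby("animal_id", sort=True):
        day_row = grp[grp["day"] == last_initial_day]
        if day_row.empty:
            diag_rows.append(
                {"animal_id": animal, "error_rate": float("nan"),
                 "included": False, "reason": "no pokes on criterion day"}
            )
            continue
        err = float(day_row["error_rate"].iloc[0])
        ok = err < threshold
        if ok:
            included.append(animal)
        diag_rows.append(
            {"animal_id": animal, "error_rate": err, "included": ok,
             "reason": "" if ok else f"error rate {err:.2f} >= {threshold}"}
        )
    return included, pd.DataFrame(diag_rows)


def group_learning_curve(
    series: pd.DataFrame, group: str | None = None
) -> pd.DataFrame:
    """Unweighted animal-level mean and SEM of the error rate per day."""
    if group is not None:
        series = series[series["group"] == group]
    if series["animal_id"].nunique() < 2:
        raise ValueError("need at least 2 animals for a group curve")
    rows = []
    for day, grp in series.groupby("day", sort=True):
        vals = grp["error_rate"].to_numpy(float)
        n = vals.size
        sem = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        rows.append(
            {"day": day, "session_label": grp["session_label"].iloc[0],
             "mean_error": float(vals.mean()), "sem": sem, "n_animals": n}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rank correlation
# ---------------------------------------------------------------------------

def _spearman_r(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx**2).sum() * (ry**2).sum()))
    return float((rx * ry).sum() / denom)


def spearman_correlation(
    x: np.ndarray,
    y: np.ndarray,
    alternative: str = "greater",
    exact_max_n: int = 10,
) -> tuple[float, float]:
    """Spearman rank correlation with a one-sided (default) p-value.

    Ties receive average ranks.  For ``n <= exact_max_n`` the p-value comes
    from full enumeration of the n! permutation null; otherwise from the
    t approximation with n - 2 degrees of freedom.  ``alternative`` is
    'greater', 'less' or 'two-sided'.  Constant input is undefined (NaN).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    r = _spearman_r(x, y)
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if n <= exact_max_n:
        null = _exact_null(stats.rankdata(x), stats.rankdata(y))
        eps = 1e-12
        if alternative == "greater":
            p = float((null >= r - eps).mean())
        elif alternative == "less":
            p = float((null <= r + eps).mean())
        else:
            p = float((np.abs(null) >= abs(r) - eps).mean())
    else:
        tstat = r * math.sqrt((n - 2) / max(1e-300, 1.0 - r * r))
        if alternative == "greater":
            p = float(stats.t.sf(tstat, n - 2))
        elif alternative == "less":
            p = float(stats.t.cdf(tstat, n - 2))
        else:
            p = float(2.0 * stats.t.sf(abs(tstat), n - 2))
    return r, min(p, 1.0)


def _exact_null(
    rx: np.ndarray, ry: np.ndarray, chunk: int = 200_000
) -> np.ndarray:
    """Correlation of rx with every permutation of ry (full n! null)."""
    n = rx.size
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float((rxc**2).sum() * (ryc**2).sum()))
    out = np.empty(math.factorial(n))
    it = permutations(ryc)
    pos = 0
    while True:
        block = np.fromiter(
            (v for perm in islice(it, chunk) for v in perm), dtype=float
        )
        if block.size == 0:
            break
        block = block.reshape(-1, n)
        out[pos:pos + block.shape[0]] = block @ rxc / denom
        pos += block.shape[0]
    return out[:pos]


def ablation_performance_analysis(
    error_series: pd.DataFrame,
    ablation_table: pd.DataFrame,
    novel_day: int = 8,
    familiar_day: int = 9,
    covariate: str = "surviving_density",
    group: str = "tmp",
) -> dict[str, tuple[float, float]]:
    """Rank-correlate surviving terminal density with late error rates.

    For the ablated group, the per-animal covariate (surviving relative
    terminal density) is correlated with the error rate on the last
    novel-session day (one-tailed for a negative association: more surviving
    input, better new learning) and on the first familiar-return day
    (one-tailed for a positive association: more surviving input, better
    forgetting of the old port, hence worse immediate return performance).

    Returns ``{"novel": (r_s, p), "familiar": (r_s, p)}``.
    """
    tbl = ablation_table
    if "group" in tbl.columns and group is not None:
        tbl = tbl[tbl["group"] == group]
    merged = error_series.merge(
        tbl[["animal_id", covariate]], on="animal_id", how="inner"
    )
    out = {}
    for name, day, alt in (
        ("novel", novel_day, "less"),
        ("familiar", familiar_day, "greater"),
    ):
        sel = merged[merged["day"] == day]
        if sel["animal_id"].nunique() < 3:
            raise ValueError(
                f"fewer than 3 animals with data on day {day}"
            )
        out[name] = spearman_correlation(
            sel[covariate].to_numpy(),
            sel["error_rate"].to_numpy(),
            alternative=alt,
        )
    return out
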