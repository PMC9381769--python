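"""Occupancy-normalized firing-rate maps and spatial information.

The single-unit spatial analysis: a speed filter (>3 cm/s) restricts both
dwell-time and spike counting to running periods, the arena is discretized
into an n x n grid (15 x 15 by default), rate maps are smoothed with a
Gaussian kernel of 1 bin SD, and spatial tuning is quantified with the
Skaggs information measure in bits per spike,

    SI = sum_x p_x (lambda_x / lambda) log2(lambda_x / lambda),

where p_x is the occupancy probability of bin x, lambda_x the mean rate in
that bin and lambda the occupancy-weighted mean rate.  A "literal" mode
computing the unweighted sum (1/sum P) * sum_x (lambda_x/lambda)
log2(lambda_x/lambda) is provided as well.  Quadrant-restricted SI supports
the three-session inside/outside-quadrant comparison under quadrant-confined
inhibition.

Unvisited bins are excluded from every sum and flagged NaN, never imputed
with zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter

from .core import ArenaConfig, SpikeTrain, Trajectory

__all__ = [
    "OccupancyMap",
    "RateMap",
    "QuadrantPartition",
    "SIResult",
    "SessionComparison",
    "compute_speed",
    "compute_occupancy",
    "compute_ratemap",
    "smooth_ratemap",
    "spatial_information",
    "quadrant_si",
    "score_unit",
    "apply_inclusion_filter",
    "rank_sum_test",
    "compare_sessions",
]

SPEED_MIN_DEFAULT = 3.0  # cm/s, strict ">" filter


# ---------------------------------------------------------------------------
# speed
# ---------------------------------------------------------------------------

def compute_speed(traj: Trajectory, smooth_window: float = 0.1) -> np.ndarray:
    """Instantaneous speed (cm/s) from centered finite differences.

    The displacement derivative is estimated with centered differences
    (one-sided at the endpoints) and boxcar-smoothed over ``smooth_window``
    seconds.
    """
    if len(traj) < 2:
        raise ValueError("need at least 2 samples to estimate speed")
    t, x, y = traj.t, traj.x, traj.y
    vx = np.gradient(x, t)
    vy = np.gradient(y, t)
    speed = np.hypot(vx, vy)
    dt = float(np.median(np.diff(t)))
    win = max(1, int(round(smooth_window / dt)))
    if win > 1:
        kernel = np.ones(win) / win
        # reflect-pad so the boxcar keeps length and does not bias the edges
        padded = np.pad(speed, (win // 2, win - 1 - win // 2), mode="edge")
        speed = np.convolve(padded, kernel, mode="valid")
    return speed


# ---------------------------------------------------------------------------
# occupancy and rate maps
# ---------------------------------------------------------------------------

@dataclass
class OccupancyMap:
    """Dwell time (s) per spatial bin over running periods."""

    dwell: np.ndarray  # (n, n) seconds, row = y bin, col = x bin
    arena: ArenaConfig
    speed_min: float = SPEED_MIN_DEFAULT

    @property
    def visited(self) -> np.ndarray:
        return self.dwell > 0

    @property
    def total_time(self) -> float:
        return float(self.dwell.sum())

    @property
    def probability(self) -> np.ndarray:
        """Occupancy probability per bin (NaN where unvisited)."""
        out = np.full_like(self.dwell, np.nan)
        tot = self.total_time
        if tot > 0:
            out[self.visited] = self.dwell[self.visited] / tot
        return out


@dataclass
class RateMap:
    """Firing rate (Hz) per spatial bin; NaN marks unvisited bins."""

    rate: np.ndarray
    occupancy: OccupancyMap
    unit_id: str = ""
    smoothed: bool = False
    n_spikes_used: int = 0
    n_spikes_dropped: int = 0

    @property
    def visited(self) -> np.ndarray:
        return np.isfinite(self.rate)


def _bin_index(values: np.ndarray, arena: ArenaConfig) -> np.ndarray:
    """Half-open bin membership [edge_i, edge_{i+1}); last bin closed."""
    edges = arena.bin_edges
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, arena.n_bins_per_side - 1)


def compute_occupancy(
    traj: Trajectory,
    arena: ArenaConfig | None = None,
    speed_min: float = SPEED_MIN_DEFAULT,
    speed: np.ndarray | None = None,
) -> OccupancyMap:
    """Accumulate dwell time per bin over samples moving faster than
    ``speed_min``.

    Each tracking sample contributes its sampling interval to the bin
    containing its position; samples at or below the speed threshold are
    discarded.  An all-zero map (animal never moving) is valid.
    """
    arena = arena or traj.arena
    if arena is None:
        raise ValueError("an ArenaConfig is required")
    speed = compute_speed(traj) if speed is None else np.asarray(speed)
    dts = np.diff(traj.t)
    dts = np.append(dts, np.median(dts))
    keep = speed > speed_min
    n = arena.n_bins_per_side
    dwell = np.zeros((n, n))
    if keep.any():
        ix = _bin_index(traj.x[keep], arena)
        iy = _bin_index(traj.y[keep], arena)
        np.add.at(dwell, (iy, ix), dts[keep])
    return OccupancyMap(dwell=dwell, arena=arena, speed_min=speed_min)


def compute_ratemap(
    spikes: SpikeTrain,
    traj: Trajectory,
    occupancy: OccupancyMap,
    speed_min: float = SPEED_MIN_DEFAULT,
    speed: np.ndarray | None = None,
) -> RateMap:
    """Raw (unsmoothed) firing-rate map: spike count / dwell time per bin.

    Spike positions are linearly interpolated from the tracking at spike
    times and spikes are speed-filtered with the same threshold as the
    occupancy.  Spikes outside the trajectory time range, or falling in a
    bin with zero dwell, are dropped and counted in ``n_spikes_dropped``.
    """
    arena = occupancy.arena
    speed = compute_speed(traj) if speed is None else np.asarray(speed)
    st = spikes.spike_times
    in_range = (st >= traj.t[0]) & (st <= traj.t[-1])
    dropped = int((~in_range).sum())
    st = st[in_range]
    sx = np.interp(st, traj.t, traj.x)
    sy = np.interp(st, traj.t, traj.y)
    sv = np.interp(st, traj.t, speed)
    keep = sv > speed_min
    sx, sy = sx[keep], sy[keep]
    n = arena.n_bins_per_side
    counts = np.zeros((n, n))
    if sx.size:
        np.add.at(counts, (_bin_index(sy, arena), _bin_index(sx, arena)), 1.0)
    rate = np.full((n, n), np.nan)
    visited = occupancy.visited
    rate[visited] = counts[visited] / occupancy.dwell[visited]
    dropped += int(counts[~visited].sum())
    used = int(counts[visited].sum())
    return RateMap(
        rate=rate,
        occupancy=occupancy,
        unit_id=spikes.unit_id,
        n_spikes_used=used,
        n_spikes_dropped=dropped,
    )


def smooth_ratemap(
    ratemap: RateMap, sigma_bins: float = 1.0, truncate: float = 4.0
) -> RateMap:
    """Gaussian-smooth a rate map, renormalizing the kernel over visited bins.

    Unvisited bins carry no weight (they are neither sources nor sinks of
    rate) and remain NaN in the output.
    """
    if sigma_bins <= 0:
        raise ValueError("sigma_bins must be positive")
    visited = ratemap.visited
    filled = np.where(visited, ratemap.rate, 0.0)
    num = gaussian_filter(
        filled, sigma_bins, mode="constant", cval=0.0, truncate=truncate
    )
    den = gaussian_filter(
        visited.astype(float), sigma_bins, mode="constant", cval=0.0,
        truncate=truncate,
    )
    out = np.full_like(filled, np.nan)
    out[visited] = num[visited] / den[visited]
    return RateMap(
        rate=out,
        occupancy=ratemap.occupancy,
        unit_id=ratemap.unit_id,
        smoothed=True,
        n_spikes_used=ratemap.n_spikes_used,
        n_spikes_dropped=ratemap.n_spikes_dropped,
    )


# ---------------------------------------------------------------------------
# spatial information
# ---------------------------------------------------------------------------

def spatial_information(
    rate: RateMap | np.ndarray,
    occupancy: OccupancyMap | np.ndarray,
    mode: str = "skaggs",
) -> float:
    """Spatial information in bits per spike.

    ``mode="skaggs"`` (default) is the standard occupancy-weighted form,
    ``SI = sum_x p_x (lam_x/lam) log2(lam_x/lam)`` with ``p_x`` the dwell
    fraction and ``lam`` the occupancy-weighted mean rate.  ``mode="literal"``
    drops the per-bin weight inside the sum,
    ``SI = (1/sum_x P_x) sum_x (lam_x/lam) log2(lam_x/lam)`` with the
    occupancies normalized to probabilities (so the prefactor is 1).

    Unvisited bins are excluded from all sums.  Returns NaN when the mean
    rate is zero (no spikes): the measure is undefined, not 0.
    """
    r = rate.rate if isinstance(rate, RateMap) else np.asarray(rate, float)
    d = (
        occupancy.dwell if isinstance(occupancy, OccupancyMap)
        else np.asarray(occupancy, float)
    )
    valid = np.isfinite(r) & (d > 0)
    if not valid.any():
        return float("nan")
    lam = r[valid]
    p = d[valid] / d[valid].sum()
    lam_bar = float((p * lam).sum())
    if lam_bar <= 0:
        return float("nan")
    ratio = lam / lam_bar
    terms = np.where(ratio > 0, ratio * np.log2(np.where(ratio > 0, ratio, 1.0)), 0.0)
    if mode == "skaggs":
        return float((p * terms).sum())
    if mode == "literal":
        return float(terms.sum())
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class QuadrantPartition:
    """Assignment of grid bins to four equal quadrants.

    For an odd grid (e.g. 15 x 15) the central row and column have bin
    centers exactly on the arena midlines and are excluded (label -1).
    Quadrants are numbered 2 * (upper half) + (right half): 0 lower-left,
    1 lower-right, 2 upper-left, 3 upper-right.
    """

    labels: np.ndarray  # (n, n) int, -1 = excluded
    target_quadrant: int | None = None

    @classmethod
    def for_grid(
        cls, n_bins: int, target_quadrant: int | None = None
    ) -> "QuadrantPartition":
        idx = np.arange(n_bins)
        if n_bins % 2 == 1:
            mid = n_bins // 2
            half = np.where(idx < mid, 0, np.where(idx > mid, 1, -1))
        else:
            half = (idx >= n_bins // 2).astype(int)
        labels = np.empty((n_bins, n_bins), dtype=int)
        for i in range(n_bins):
            for j in range(n_bins):
                if half[i] < 0 or half[j] < 0:
                    labels[i, j] = -1
                else:
                    labels[i, j] = 2 * half[i] + half[j]
        return cls(labels=labels, target_quadrant=target_quadrant)

    def mask(self, quadrant: int) -> np.ndarray:
        return self.labels == quadrant


def quadrant_si(
    rate: RateMap | np.ndarray,
    occupancy: OccupancyMap | np.ndarray,
    partition: QuadrantPartition,
    mode: str = "skaggs",
    mean_rate_scope: str = "quadrant",
) -> np.ndarray:
    """Spatial information computed separately within each quadrant.

    With ``mean_rate_scope="quadrant"`` (default) both the occupancy
    probabilities and the mean rate are renormalized within the quadrant, so
    the value equals the whole-map SI of the map restricted to that
    quadrant's bins.  ``"global"`` keeps the whole-map mean rate as the
    reference while renormalizing occupancies within the quadrant.
    Quadrants with no occupancy or no spikes are NaN.
    """
    r = rate.rate if isinstance(rate, RateMap) else np.asarray(rate, float)
    d = (
        occupancy.dwell if isinstance(occupancy, OccupancyMap)
        else np.asarray(occupancy, float)
    )
    out = np.full(4, np.nan)
    if mean_rate_scope not in ("quadrant", "global"):
        raise ValueError("mean_rate_scope must be 'quadrant' or 'global'")
    lam_global = None
    if mean_rate_scope == "global":
        valid = np.isfinite(r) & (d > 0)
        if not valid.any():
            return out
        p = d[valid] / d[valid].sum()
        lam_global = float((p * r[valid]).sum())
        if lam_global <= 0:
            return out
    for q in range(4):
        m = partition.mask(q)
        valid = m & np.isfinite(r) & (d > 0)
        if not valid.any():
            continue
        lam = r[valid]
        p = d[valid] / d[valid].sum()
        lam_bar = lam_global if lam_global is not None else float((p * lam).sum())
        if lam_bar <= 0:
            continue
        ratio = lam / lam_bar
        terms = np.where(
            ratio > 0, ratio * np.log2(np.where(ratio > 0, ratio, 1.0)), 0.0
        )
        if mode == "skaggs":
            out[q] = float((p * terms).sum())
        elif mode == "literal":
            out[q] = float(terms.sum())
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out


@dataclass
class SIResult:
    """Per-unit, per-session spatial-information summary."""

    unit_id: str
    session_label: str
    si_whole: float
    si_per_quadrant: np.ndarray  # length 4, NaN where undefined
    mean_rate: float  # Hz, whole-session unfiltered


def score_unit(
    spikes: SpikeTrain,
    traj: Trajectory,
    occupancy: OccupancyMap,
    partition: QuadrantPartition,
    session_label: str = "",
    sigma_bins: float = 1.0,
    mode: str = "skaggs",
    speed: np.ndarray | None = None,
) -> SIResult:
    """Full per-unit pipeline: rate map -> smoothing -> whole and quadrant SI."""
    rm = compute_ratemap(
        spikes, traj, occupancy, speed_min=occupancy.speed_min, speed=speed
    )
    sm = smooth_ratemap(rm, sigma_bins=sigma_bins)
    dur = traj.duration
    return SIResult(
        unit_id=spikes.unit_id,
        session_label=session_label,
        si_whole=spatial_information(sm, occupancy, mode=mode),
        si_per_quadrant=quadrant_si(sm, occupancy, partition, mode=mode),
        mean_rate=len(spikes) / dur if dur > 0 else float("nan"),
    )


# ---------------------------------------------------------------------------
# unit inclusion
# ---------------------------------------------------------------------------

def apply_inclusion_filter(
    units: list[SpikeTrain],
    t_start: float,
    t_stop: float,
    min_rate: float = 0.2,
    max_rate: float = 5.0,
    edge_window: float = 900.0,
) -> list[SpikeTrain]:
    """Keep putative pyramidal cells that were stably recorded.

    A unit is kept when its whole-session mean rate lies in
    ``[min_rate, max_rate]`` (inclusive) and its rate is at least
    ``min_rate`` in both the first and last ``edge_window`` seconds.
    Rates here use unfiltered spike counts (no speed filter).
    """
    dur = t_stop - t_start
    if dur < 2 * edge_window:
        raise ValueError(
            "session shorter than two edge windows; cannot apply the "
            "first/last-window stability rule"
        )
    out = []
    for u in units:
        st = u.spike_times
        st = st[(st >= t_start) & (st <= t_stop)]
        mean_rate = st.size / dur
        first = ((st >= t_start) & (st < t_start + edge_window)).sum()
        last = ((st > t_stop - edge_window) & (st <= t_stop)).sum()
        if (
            min_rate <= mean_rate <= max_rate
            and first / edge_window >= min_rate
            and last / edge_window >= min_rate
        ):
            out.append(u)
    return out


# ---------------------------------------------------------------------------
# session comparison
# ---------------------------------------------------------------------------

def rank_sum_test(
    a: np.ndarray, b: np.ndarray, exact_max_product: int = 400
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when ``len(a) * len(b)`` is at most
    ``exact_max_product`` and there are no ties; otherwise the normal
    approximation with continuity and tie correction.  Returns ``(U, p)``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        return float("nan"), float("nan")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = (
        "exact" if (a.size * b.size <= exact_max_product and not has_ties)
        else "asymptotic"
    )
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class SessionComparison:
    """Inside- vs outside-quadrant SI change across the three sessions."""

    unit_ids: list[str]
    delta_inside_s2: np.ndarray
    delta_outside_s2: np.ndarray
    delta_inside_s3: np.ndarray
    delta_outside_s3: np.ndarray
    p_s2: float = field(default=float("nan"))
    p_s3: float = field(default=float("nan"))
    n_dropped: int = 0

    @property
    def median_delta_inside_s2(self) -> float:
        return float(np.nanmedian(self.delta_inside_s2))

    @property
    def median_delta_outside_s2(self) -> float:
        return float(np.nanmedian(self.delta_outside_s2))


def compare_sessions(
    si_results: dict[str, list[SIResult]],
    target_quadrant: int,
) -> SessionComparison:
    """Per-unit SI change in the target quadrant vs the rest of the arena.

    ``si_results`` maps session labels 'S1', 'S2', 'S3' to per-unit
    :class:`SIResult` lists.  For each unit present in all three sessions,
    the inside change is ``SI_q(target, S) - SI_q(target, S1)`` and the
    outside change the difference of the mean SI over the other three
    quadrants; inside and outside changes are compared with a two-sided
    Mann-Whitney test for S2 and S3 separately.  Units missing a session
    are dropped and counted.
    """
    by_unit: dict[str, dict[str, SIResult]] = {}
    for label in ("S1", "S2", "S3"):
        for res in si_results.get(label, []):
            by_unit.setdefault(res.unit_id, {})[label] = res
    unit_ids, din2, dout2, din3, dout3 = [], [], [], [], []
    dropped = 0
    others = [q for q in range(4) if q != target_quadrant]
    for uid in sorted(by_unit):
        sess = by_unit[uid]
        if not all(k in sess for k in ("S1", "S2", "S3")):
            dropped += 1
            continue

        def _in(label: str) -> float:
            return float(sess[label].si_per_quadrant[target_quadrant])

        def _out(label: str) -> float:
            vals = sess[label].si_per_quadrant[others]
            return (
                float(np.nanmean(vals)) if np.isfinite(vals).any()
                else float("nan")
            )

        unit_ids.append(uid)
        din2.append(_in("S2") - _in("S1"))
        dout2.append(_out("S2") - _out("S1"))
        din3.append(_in("S3") - _in("S1"))
        dout3.append(_out("S3") - _out("S1"))
    din2 = np.asarray(din2)
    dout2 = np.asarray(dout2)
    din3 = np.asarray(din3)
    dout3 = np.asarray(dout3)
    _, p2 = rank_sum_test(din2, dout2)
    _, p3 = rank_sum_test(din3, dout3)
    return SessionComparison(
        unit_ids=unit_ids,
        delta_inside_s2=din2,
        delta_outside_s2=dout2,
        delta_inside_s3=din3,
        delta_outside_s3=dout3,
        p_s2=p2,
        p_s3=p3,
        n_dropped=dropped,
    )
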