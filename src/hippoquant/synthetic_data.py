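"""Synthetic-data generators with known ground truth.

Every input consumed by the analysis modules can be generated here: open-field
trajectories, place-field-tuned Poisson spike trains (optionally with a
quadrant-confined tuning degradation during the middle of three sessions),
two-channel punctum images at super-resolution pixel sizes, biexponential
EPSC trains with short-term depression, and multi-animal nosepoke logs with
exponential learning curves whose rates depend on a per-animal ablation
covariate.

All generators are pure functions of (parameters, seed).  Randomness is split
from the single seed with :class:`numpy.random.SeedSequence` children, so
sub-streams (per unit, per animal, ...) are independently reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .core import ArenaConfig, SpikeTrain, Trajectory

__all__ = [
    "MobilityParams",
    "PlaceCellParams",
    "InhibitionEffect",
    "PunctumFieldParams",
    "PunctumGroundTruth",
    "EPSCParams",
    "CohortParams",
    "SESSION_SCHEDULE",
    "generate_trajectory",
    "place_cell_rate",
    "simulate_spikes",
    "generate_punctum_image_pair",
    "generate_epsc_train",
    "default_stim_times",
    "generate_cohort_log",
]


def _rng(seed: int | np.random.SeedSequence, *key: int) -> np.random.Generator:
    """Child generator for stream ``key`` split off from ``seed``."""
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    return np.random.default_rng(
        np.random.SeedSequence(
            entropy=ss.entropy, spawn_key=tuple(key)
        )
    )


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MobilityParams:
    """Ornstein-Uhlenbeck velocity model for open-field locomotion.

    ``mean_speed`` is the target time-averaged speed (cm/s); ``persistence``
    is the velocity autocorrelation time constant (s).  With per-component
    stationary SD ``s``, the 2-D speed is Rayleigh with mean ``s*sqrt(pi/2)``,
    so ``s = mean_speed * sqrt(2/pi)``.
    """

    mean_speed: float = 8.0
    persistence: float = 1.0

    def __post_init__(self) -> None:
        if self.mean_speed < 0:
            raise ValueError("mean_speed must be >= 0")
        if self.persistence <= 0:
            raise ValueError("persistence must be positive")


def generate_trajectory(
    arena: ArenaConfig,
    duration: float,
    mobility: MobilityParams | None = None,
    seed: int = 0,
) -> Trajectory:
    """Simulate an open-field trajectory with reflecting walls.

    The velocity follows a 2-D Ornstein-Uhlenbeck process discretized exactly
    over the tracking interval ``arena.dt``; the free path is folded back at
    the walls (reflecting boundary), which preserves the speed distribution
    except at the rare wall-crossing steps.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    mobility = mobility or MobilityParams()
    rng = _rng(seed, 0)

    dt = arena.dt
    n = int(round(duration / dt))
    side = arena.side_length
    theta = mobility.persistence
    s = mobility.mean_speed * np.sqrt(2.0 / np.pi)

    a = np.exp(-dt / theta)
    b = s * np.sqrt(max(0.0, 1.0 - a * a))

    # start away from the walls, velocity from the stationary distribution
    start = rng.uniform(0.1 * side, 0.9 * side, size=2)
    v0 = rng.normal(0.0, s, size=2) if s > 0 else np.zeros(2)
    noise = rng.standard_normal((n, 2))

    pos = np.empty((n, 2))
    for k in range(2):
        # exact discretization of the OU recursion v_i = a v_{i-1} + b n_i
        vel, _ = lfilter([b], [1.0, -a], noise[:, k], zi=[a * v0[k]])
        free = start[k] + np.concatenate(([0.0], np.cumsum(vel[:-1] * dt)))
        # reflecting walls: fold the free path back into [0, side]
        folded = np.abs(np.mod(free, 2.0 * side))
        pos[:, k] = side - np.abs(folded - side)

    t = np.arange(n) * dt
    return Trajectory(t=t, x=pos[:, 0], y=pos[:, 1], arena=arena)


# ---------------------------------------------------------------------------
# place-cell spike trains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlaceCellParams:
    """Gaussian place-field tuning of a single unit."""

    field_center: tuple[float, float]
    field_width: float  # Gaussian sigma, cm
    peak_rate: float  # Hz
    baseline_rate: float = 0.0  # Hz

    def __post_init__(self) -> None:
        # equality gives a spatially untuned (homogeneous Poisson) unit
        if not self.peak_rate >= self.baseline_rate >= 0:
            raise ValueError("need peak_rate >= baseline_rate >= 0")
        if self.peak_rate <= 0:
            raise ValueError("peak_rate must be positive")
        if self.field_width <= 0:
            raise ValueError("field_width must be positive")


@dataclass(frozen=True)
class InhibitionEffect:
    """Quadrant-confined tuning degradation during session S2.

    ``degradation`` mixes the instantaneous rate toward the cell's own
    session-mean rate while the animal is inside ``target_quadrant``:
    lambda -> (1 - d) * lambda + d * mean(lambda).  This models a loss of
    spatial tuning with only a minimal change of the average firing rate.
    """

    target_quadrant: int
    degradation: float
    session_label: str = "S2"

    def __post_init__(self) -> None:
        if not 0 <= self.target_quadrant <= 3:
            raise ValueError("target_quadrant must be 0..3")
        if not 0.0 <= self.degradation <= 1.0:
            raise ValueError("degradation must be in [0, 1]")


def quadrant_of_position(
    x: np.ndarray, y: np.ndarray, side_length: float
) -> np.ndarray:
    """Quadrant index 0..3 per position.

    Quadrants are numbered 2 * (y >= mid) + (x >= mid): 0 lower-left,
    1 lower-right, 2 upper-left, 3 upper-right; points exactly on a midline
    belong to the upper/right half (same tie rule as the bin edges).
    """
    mid = side_length / 2.0
    return (2 * (np.asarray(y) >= mid).astype(int)
            + (np.asarray(x) >= mid).astype(int))


def place_cell_rate(
    cell: PlaceCellParams, x: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Instantaneous firing rate (Hz) at positions (x, y)."""
    cx, cy = cell.field_center
    d2 = (np.asarray(x) - cx) ** 2 + (np.asarray(y) - cy) ** 2
    return cell.baseline_rate + (
        cell.peak_rate - cell.baseline_rate
    ) * np.exp(-d2 / (2.0 * cell.field_width**2))


def simulate_spikes(
    trajectory: Trajectory,
    cells: list[PlaceCellParams],
    effect: InhibitionEffect | None = None,
    seed: int = 0,
    session_label: str = "S1",
) -> list[SpikeTrain]:
    """Inhomogeneous-Poisson spike trains for place-field-tuned units.

    The rate is piecewise-constant over the tracking interval and spikes are
    drawn by thinning a homogeneous Poisson process at the per-unit maximum
    rate.  When ``effect`` is given and ``session_label`` matches the
    effect's session, the rate is flattened toward the unit's session-mean
    rate inside the target quadrant.
    """
    if not cells:
        raise ValueError("cells must be non-empty")
    if trajectory.arena is None:
        raise ValueError("trajectory must carry an ArenaConfig")
    side = trajectory.arena.side_length
    t = trajectory.t
    if t.size < 2:
        raise ValueError("trajectory too short")
    t0, t1 = t[0], t[-1]
    span = t1 - t0

    in_target = None
    if effect is not None and session_label == effect.session_label:
        q = quadrant_of_position(trajectory.x, trajectory.y, side)
        in_target = q == effect.target_quadrant

    trains: list[SpikeTrain] = []
    for k, cell in enumerate(cells):
        lam = place_cell_rate(cell, trajectory.x, trajectory.y)
        if in_target is not None and effect.degradation > 0:
            lam_mean = lam.mean()
            lam = np.where(
                in_target,
                (1.0 - effect.degradation) * lam
                + effect.degradation * lam_mean,
                lam,
            )
        lam_max = float(lam.max())
        rng = _rng(seed, 1, k)
        if lam_max <= 0:
            trains.append(SpikeTrain(unit_id=f"u{k:03d}"))
            continue
        n_cand = rng.poisson(lam_max * span)
        cand = np.sort(rng.uniform(t0, t1, size=n_cand))
        idx = np.clip(np.searchsorted(t, cand, side="right") - 1, 0, t.size - 1)
        keep = rng.uniform(0.0, lam_max, size=n_cand) < lam[idx]
        times = np.unique(cand[keep])
        trains.append(SpikeTrain(unit_id=f"u{k:03d}", spike_times=times))
    return trains


# ---------------------------------------------------------------------------
# punctum images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PunctumFieldParams:
    """Two-channel synaptic punctum field at super-resolution pixel size.

    Densities are puncta per um^2; ``coloc_fraction`` of the A puncta are
    placed within ``coloc_radius`` (nm) of a B punctum.  Puncta are rendered
    as 2-D Gaussians of sigma ``punctum_sigma`` (nm) and peak
    ``peak_intensity``; Gaussian read noise of SD ``noise_sd`` is added.
    """

    image_size: tuple[int, int] = (500, 500)  # rows, cols (pixels)
    pixel_size: float = 40.0  # nm
    density_a: float = 0.25  # per um^2
    density_b: float = 0.25
    coloc_fraction: float = 0.15
    coloc_radius: float = 40.0  # nm
    punctum_sigma: float = 120.0  # nm
    peak_intensity: float = 1000.0
    noise_sd: float = 20.0

    def __post_init__(self) -> None:
        if self.density_a < 0 or self.density_b < 0:
            raise ValueError("densities must be >= 0")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must be in [0, 1]")
        if self.pixel_size <= 0 or self.punctum_sigma <= 0:
            raise ValueError("pixel_size and punctum_sigma must be positive")

    @property
    def area_um2(self) -> float:
        h, w = self.image_size
        return h * w * (self.pixel_size / 1000.0) ** 2


@dataclass
class PunctumGroundTruth:
    """True punctum centroids (um) and per-A colocalization labels."""

    centroids_a: np.ndarray  # (N_A, 2) um
    centroids_b: np.ndarray  # (N_B, 2) um
    coloc_label_a: np.ndarray  # (N_A,) bool


def _render_puncta(
    shape: tuple[int, int],
    centers_px: np.ndarray,
    sigma_px: float,
    peak: float,
) -> np.ndarray:
    img = np.zeros(shape, dtype=float)
    r = int(np.ceil(4.0 * sigma_px))
    h, w = shape
    for cx, cy in centers_px:  # cx: column, cy: row
        i0, i1 = int(np.floor(cy)) - r, int(np.floor(cy)) + r + 1
        j0, j1 = int(np.floor(cx)) - r, int(np.floor(cx)) + r + 1
        i0c, i1c = max(i0, 0), min(i1, h)
        j0c, j1c = max(j0, 0), min(j1, w)
        if i0c >= i1c or j0c >= j1c:
            continue
        ii = np.arange(i0c, i1c)[:, None]
        jj = np.arange(j0c, j1c)[None, :]
        img[i0c:i1c, j0c:j1c] += peak * np.exp(
            -((ii - cy) ** 2 + (jj - cx) ** 2) / (2.0 * sigma_px**2)
        )
    return img


def generate_punctum_image_pair(
    params: PunctumFieldParams, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, PunctumGroundTruth]:
    """Render a two-channel punctum field with known colocalization.

    Returns ``(image_a, image_b, ground_truth)``.  Punctum counts are
    deterministic, ``round(density * area)``; exactly
    ``round(coloc_fraction * N_A)`` A puncta are placed at distance
    ``U(0, coloc_radius)`` and uniform angle from a randomly chosen B
    punctum.  All centers stay >= 2 sigma from the borders.
    """
    if params.coloc_radius < params.pixel_size:
        warnings.warn(
            "coloc_radius below the pixel size: colocalized pairs are "
            "placed at sub-pixel offsets",
            stacklevel=2,
        )
    rng = _rng(seed, 2)
    h, w = params.image_size
    px_um = params.pixel_size / 1000.0
    sigma_px = params.punctum_sigma / params.pixel_size
    margin_px = 2.0 * sigma_px
    if w <= 2 * margin_px or h <= 2 * margin_px:
        raise ValueError("image too small for the punctum size")

    n_a = int(round(params.density_a * params.area_um2))
    n_b = int(round(params.density_b * params.area_um2))
    if (n_a > 0 or n_b > 0) and min(h, w) - 2 * margin_px < 1:
        raise ValueError("image too small to hold a punctum")

    def uniform_centers(n: int) -> np.ndarray:
        cx = rng.uniform(margin_px, w - margin_px, size=n)
        cy = rng.uniform(margin_px, h - margin_px, size=n)
        return np.column_stack([cx, cy])

    centers_b = uniform_centers(n_b)

    n_coloc = int(round(params.coloc_fraction * n_a)) if n_b > 0 else 0
    coloc_centers = np.empty((n_coloc, 2))
    radius_px = params.coloc_radius / params.pixel_size
    # distinct B partners while they last, so truth fraction 1 covers the
    # whole B population rather than a coupon-collector subset
    partners = rng.permutation(n_b)
    if n_coloc > n_b:
        partners = np.concatenate(
            [partners, rng.integers(n_b, size=n_coloc - n_b)]
        )
    for i in range(n_coloc):
        while True:
            d = rng.uniform(0.0, radius_px)
            ang = rng.uniform(0.0, 2.0 * np.pi)
            cand = centers_b[partners[i]] + d * np.array(
                [np.cos(ang), np.sin(ang)]
            )
            if (margin_px <= cand[0] <= w - margin_px
                    and margin_px <= cand[1] <= h - margin_px):
                coloc_centers[i] = cand
                break
    free_centers = uniform_centers(n_a - n_coloc)
    centers_a = np.vstack([coloc_centers, free_centers])
    labels = np.zeros(n_a, dtype=bool)
    labels[:n_coloc] = True

    img_a = _render_puncta((h, w), centers_a, sigma_px, params.peak_intensity)
    img_b = _render_puncta((h, w), centers_b, sigma_px, params.peak_intensity)
    if params.noise_sd > 0:
        img_a = img_a + rng.normal(0.0, params.noise_sd, size=(h, w))
        img_b = img_b + rng.normal(0.0, params.noise_sd, size=(h, w))

    truth = PunctumGroundTruth(
        centroids_a=centers_a * px_um,
        centroids_b=centers_b * px_um,
        coloc_label_a=labels,
    )
    return img_a, img_b, truth


# ---------------------------------------------------------------------------
# EPSC trains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EPSCParams:
    """Biexponential EPSC waveform and short-term-depression parameters.

    Amplitude is in pA and negative for inward currents; ``depression_ratio``
    scales the amplitude of each pulse relative to the previous one, so a
    value near 0 models nearly absolute short-term depression.
    """

    tau_rise: float = 2.0  # ms
    tau_decay: float = 50.0  # ms
    amplitude: float = -100.0  # pA
    onset_latency: float = 4.0  # ms
    depression_ratio: float = 0.05
    noise_sd: float = 0.0  # pA
    sample_rate: float = 20.0  # kHz

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("need 0 < tau_rise < tau_decay")
        if not 0.0 <= self.depression_ratio <= 1.0:
            raise ValueError("depression_ratio must be in [0, 1]")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")


def default_stim_times(
    n_pulses: int = 5, isi: float = 100.0, first: float = 100.0
) -> np.ndarray:
    """Stimulus onsets (ms) for a 10-Hz train of ``n_pulses`` pulses."""
    return first + isi * np.arange(n_pulses, dtype=float)


def biexp_kernel(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Unit-peak biexponential ``exp(-t/tau_decay) - exp(-t/tau_rise)``."""
    t = np.asarray(t, dtype=float)
    tp = np.where(t >= 0, t, 0.0)  # avoid huge exponents for t < 0
    raw = np.where(
        t >= 0, np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise), 0.0
    )
    t_peak = (
        np.log(tau_decay / tau_rise) / (1.0 / tau_rise - 1.0 / tau_decay)
    )
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    return raw / peak


def generate_epsc_train(
    params: EPSCParams,
    stim_times: np.ndarray | None = None,
    seed: int = 0,
    tail: float = 400.0,
    n_sweeps: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize a current trace ``(t_ms, i_pA)`` for a stimulus train.

    Pulse ``k`` (0-based) contributes
    ``amplitude * depression_ratio**k * kernel(t - stim_k - onset_latency)``;
    contributions sum linearly and Gaussian noise of SD ``noise_sd`` is
    added.  The trace starts at t = 0 and extends ``tail`` ms past the last
    stimulus.  ``n_sweeps > 1`` returns the average of that many identical
    sweeps with independent noise, mirroring how evoked responses are
    averaged before kinetic measurement.
    """
    stim = (
        default_stim_times() if stim_times is None
        else np.asarray(stim_times, dtype=float)
    )
    if stim.size and np.any(np.diff(stim) <= 0):
        raise ValueError("stim_times must be sorted and strictly increasing")
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    dt = 1.0 / params.sample_rate
    t = np.arange(0.0, stim.max() + tail + dt / 2, dt)
    i = np.zeros_like(t)
    for k, s in enumerate(stim):
        i += (
            params.amplitude
            * params.depression_ratio**k
            * biexp_kernel(t - s - params.onset_latency,
                           params.tau_rise, params.tau_decay)
        )
    if params.noise_sd > 0:
        rng = _rng(seed, 3)
        noise = rng.normal(
            0.0, params.noise_sd, size=(n_sweeps, t.size)
        ).mean(axis=0)
        i = i + noise
    return t, i


# ---------------------------------------------------------------------------
# nosepoke cohorts
# ---------------------------------------------------------------------------

#: (label, start_day, n_days) with day 0 = TMP/vehicle injection.  The
#: initial learning session A precedes the injection; the return session A*
#: reuses each animal's A port.
SESSION_SCHEDULE: tuple[tuple[str, int, int], ...] = (
    ("A", -5, 5),
    ("B", 0, 3),
    ("C", 3, 3),
    ("D", 6, 3),
    ("A*", 9, 5),
)

N_PORTS = 8


@dataclass(frozen=True)
class CohortParams:
    """Home-cage spatial-learning cohort with an ablation covariate.

    Each animal makes ``Poisson(pokes_per_day)`` nosepokes per day; the
    probability of choosing the assigned port follows
    ``p(t) = p_inf - (p_inf - p0) * exp(-t_session / tau_eff)`` with
    ``t_session`` in days.  Ablation (fraction of the projection removed)
    slows learning in the novel sessions B/C/D by inflating the time
    constant, ``tau_eff = learn_tau * (1 + ablation_coupling * ablation)``,
    and preserves the pre-manipulation port memory in the return session A*:
    the A* curve starts from
    ``p0 + retention * (p_end_A - p0)`` with
    ``retention = retention_base + (1 - retention_base) * ablation``.
    """

    n_animals_per_group: int = 12
    pokes_per_day: float = 120.0
    p0: float = 1.0 / N_PORTS
    p_inf: float = 0.75
    learn_tau: float = 0.8  # days
    ablation_fractions: tuple[float, ...] | None = None
    ablation_coupling: float = 6.0
    retention_base: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= self.p_inf <= 1.0:
            raise ValueError("need 0 <= p0 <= p_inf <= 1")
        if self.learn_tau <= 0:
            raise ValueError("learn_tau must be positive")

    def tmp_ablations(self) -> np.ndarray:
        if self.ablation_fractions is not None:
            return np.asarray(self.ablation_fractions, dtype=float)
        n = self.n_animals_per_group
        return np.linspace(0.25, 0.95, n)


def _port_rotation(rng: np.random.Generator) -> dict[str, int]:
    """Assign a port per session: A and A* share the original port."""
    ports = rng.permutation(N_PORTS)
    return {"A": int(ports[0]), "B": int(ports[1]), "C": int(ports[2]),
            "D": int(ports[3]), "A*": int(ports[0])}


def generate_cohort_log(
    params: CohortParams, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate nosepoke logs for a TMP (ablated) and a vehicle cohort.

    Returns ``(log, animals)``.  ``log`` has one row per nosepoke with
    columns ``animal_id, timestamp_s, port, assigned_port, session_label,
    group``; timestamps are seconds from day 0 (injection) so session-A
    events are negative.  ``animals`` lists per-animal group, ablation
    fraction and surviving relative terminal density (1 - ablation).
    """
    groups = (
        [("tmp", a) for a in params.tmp_ablations()]
        + [("vehicle", 0.0) for _ in range(params.n_animals_per_group)]
    )
    rows: list[dict] = []
    animal_rows: list[dict] = []
    for ai, (group, ablation) in enumerate(groups):
        rng = _rng(seed, 4, ai)
        animal = f"{group}_{ai:02d}"
        ports = _port_rotation(rng)
        tau_novel = params.learn_tau * (
            1.0 + params.ablation_coupling * ablation
        )
        p_end_a = params.p_inf - (params.p_inf - params.p0) * np.exp(
            -SESSION_SCHEDULE[0][2] / params.learn_tau
        )
        retention = params.retention_base + (
            1.0 - params.retention_base
        ) * ablation
        p0_return = params.p0 + retention * (p_end_a - params.p0)
        animal_rows.append(
            {"animal_id": animal, "group": group, "ablation": ablation,
             "surviving_density": 1.0 - ablation}
        )
        for label, start_day, n_days in SESSION_SCHEDULE:
            if label == "A":
                p_start, tau = params.p0, params.learn_tau
            elif label == "A*":
                p_start, tau = p0_return, tau_novel
            else:
                p_start, tau = params.p0, tau_novel
            assigned = ports[label]
            for day in range(n_days):
                n_pokes = rng.poisson(params.pokes_per_day)
                t_in = np.sort(rng.uniform(day, day + 1.0, size=n_pokes))
                p = params.p_inf - (params.p_inf - p_start) * np.exp(
                    -t_in / tau
                )
                correct = rng.uniform(size=n_pokes) < p
                other = rng.integers(0, N_PORTS - 1, size=n_pokes)
                other = np.where(other >= assigned, other + 1, other)
                chosen = np.where(correct, assigned, other)
                ts = (start_day + t_in) * 86400.0
                for tt, port in zip(ts, chosen):
                    rows.append(
                        {"animal_id": animal, "timestamp_s": tt,
                         "port": int(port), "assigned_port": assigned,
                         "session_label": label, "group": group}
                    )
    log = pd.DataFrame(
        rows, columns=["animal_id", "timestamp_s", "port",
                       "assigned_port", "session_label", "group"]
    )
    animals = pd.DataFrame(animal_rows)
    return log, animals
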