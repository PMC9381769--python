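"""End-to-end experiment drivers over the synthetic generators.

These functions wire the generators to the analysis modules for the three
recovery experiments the package is validated on: quadrant-confined tuning
degradation during the middle of three open-field sessions, punctum
colocalization-fraction recovery, and the ablation/learning dissociation in
the home-cage task.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import behavior, coloc, ratemaps, synthetic_data as synth
from .core import ArenaConfig
from .ratemaps import QuadrantPartition, SessionComparison

__all__ = [
    "make_place_cells",
    "run_quadrant_inhibition_experiment",
    "run_coloc_recovery",
    "run_cohort_experiment",
]


def make_place_cells(
    n_units: int,
    arena: ArenaConfig,
    seed: int,
    field_width: float = 6.0,
    peak_rate: float = 6.0,
    baseline_rate: float = 0.5,
) -> list[synth.PlaceCellParams]:
    """Place cells with uniformly scattered field centers.

    Defaults give a session-mean rate near 1 Hz, inside the 0.2-5 Hz
    putative-pyramidal inclusion band.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    lo, hi = 0.05 * arena.side_length, 0.95 * arena.side_length
    centers = rng.uniform(lo, hi, size=(n_units, 2))
    return [
        synth.PlaceCellParams(
            field_center=(float(cx), float(cy)),
            field_width=field_width,
            peak_rate=peak_rate,
            baseline_rate=baseline_rate,
        )
        for cx, cy in centers
    ]


def run_quadrant_inhibition_experiment(
    n_units: int = 100,
    degradation: float = 0.8,
    seed: int = 0,
    session_duration: float = 1800.0,
    target_quadrant: int = 0,
    n_recording_sessions: int = 20,
    arena: ArenaConfig | None = None,
) -> SessionComparison:
    """Three 30-min exposures with quadrant-confined tuning degradation in S2.

    The unit pool is split over ``n_recording_sessions`` independent
    recordings (animals/implant days), each with its own trajectory per
    exposure; the degradation acts in S2 only.  Each unit is scored per
    exposure (speed-filtered occupancy and rate map, 1-bin Gaussian
    smoothing, quadrant-restricted SI) and the inside- vs outside-quadrant
    SI changes are compared with the rank-sum test.

    Spreading units over many recordings keeps them approximately
    exchangeable: units that share one trajectory inherit a common
    occupancy-driven shift in their SI estimates, which invalidates a
    unit-level rank test (see the methods note).
    """
    arena = arena or ArenaConfig()
    effect = synth.InhibitionEffect(
        target_quadrant=target_quadrant, degradation=degradation
    )
    partition = QuadrantPartition.for_grid(
        arena.n_bins_per_side, target_quadrant
    )
    if n_units % n_recording_sessions:
        raise ValueError("n_units must divide over the recording sessions")
    per_session = n_units // n_recording_sessions
    si_results: dict[str, list[ratemaps.SIResult]] = {
        "S1": [], "S2": [], "S3": []
    }
    for rec in range(n_recording_sessions):
        cells = make_place_cells(per_session, arena, seed * 100 + rec)
        for si, label in enumerate(("S1", "S2", "S3")):
            traj = synth.generate_trajectory(
                arena, session_duration, seed=seed * 1000 + rec * 10 + si
            )
            trains = synth.simulate_spikes(
                traj, cells, effect=effect,
                seed=seed * 1000 + rec * 10 + si, session_label=label,
            )
            speed = ratemaps.compute_speed(traj)
            occ = ratemaps.compute_occupancy(traj, arena, speed=speed)
            for u in trains:
                res = ratemaps.score_unit(
                    u, traj, occ, partition, session_label=label,
                    speed=speed,
                )
                res.unit_id = f"r{rec:02d}_{u.unit_id}"
                si_results[label].append(res)
    return ratemaps.compare_sessions(si_results, target_quadrant)


def run_coloc_recovery(
    coloc_fraction: float,
    n_seeds: int = 20,
    seed: int = 0,
    noise_sd: float = 0.0,
    threshold: float = 65.0,
) -> np.ndarray:
    """Relative-density estimates over seeds at one ground-truth fraction.

    Images use the default punctum field (40-nm pixels); the threshold of
    65 intensity units (6.5% of the punctum peak) reproduces the mask
    footprint the densitometry was designed around.
    """
    params = synth.PunctumFieldParams(
        coloc_fraction=coloc_fraction, noise_sd=noise_sd
    )
    out = np.empty(n_seeds)
    for k in range(n_seeds):
        img_a, img_b, _ = synth.generate_punctum_image_pair(
            params, seed=seed * 1000 + k
        )
        res = coloc.coloc_pipeline(
            coloc.ChannelImage(img_a, params.pixel_size, "A"),
            coloc.ChannelImage(img_b, params.pixel_size, "B"),
            threshold_a=threshold,
            threshold_b=threshold,
        )
        out[k] = res.relative_density_a
    return out


@dataclass
class CohortAnalysis:
    """Analysis products of one synthetic home-cage cohort."""

    error_series: object  # tidy per-animal daily error-rate frame
    included: list[str]
    novel_r: float
    novel_p: float
    familiar_r: float
    familiar_p: float


def run_cohort_experiment(
    seed: int = 0,
    params: synth.CohortParams | None = None,
) -> CohortAnalysis:
    """Generate a cohort log and run the full behavioral analysis."""
    params = params or synth.CohortParams()
    log, animals = synth.generate_cohort_log(params, seed=seed)
    labeled = behavior.label_sessions(log)
    series = behavior.daily_error_rate(labeled)
    included, _ = behavior.apply_exclusion(series)
    series = series[series["animal_id"].isin(included)]
    res = behavior.ablation_performance_analysis(series, animals)
    return CohortAnalysis(
        error_series=series,
        included=included,
        novel_r=res["novel"][0],
        novel_p=res["novel"][1],
        familiar_r=res["familiar"][0],
        familiar_p=res["familiar"][1],
    )
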