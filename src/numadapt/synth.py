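"""Ground-truth synthetic datasets for exercising the full pipeline.

The generator emulates the statistical structure the analysis assumes:
mostly monotonic voxels whose response amplitude scales with the log
aggregate Fourier power of the displays, with condition-specific gain
(low adaptor > high adaptor, changing adaptor as control) and a
suppression gradient that grows along the visual hierarchy V1 -> V3A/B; a
minority of numerosity-tuned voxels in the later maps; voxels planted
outside the selection criteria (eccentric positions, negative slopes); and
additive Gaussian (optionally AR(1)) noise per run.  Every quantity the
pipeline estimates is emitted alongside as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .design import build_design, tuned_basis
from .hrf import HrfSpec
from .models import MAP_LABELS, VoxelRecord
from .stimuli import build_run_sequence, mean_power_table

__all__ = [
    "GroundTruthConfig",
    "generate_voxel_dataset",
    "generate_behavioral_dataset",
    "generate_reduction_examples",
]


def _default_fraction_tuned() -> dict[str, float]:
    return {"V1": 0.0, "V2": 0.0, "V3": 0.0, "hV4": 0.1,
            "LO1": 0.2, "LO2": 0.2, "V3AB": 0.2}


def _default_base_slope() -> dict[str, float]:
    # raw response amplitude falls off modestly along the hierarchy
    return {"V1": 1.0, "V2": 0.9, "V3": 0.8, "hV4": 0.7,
            "LO1": 0.6, "LO2": 0.6, "V3AB": 0.7}


@dataclass
class GroundTruthConfig:
    """Parameters of the synthetic fMRI dataset.

    ``reduction_base`` and ``hierarchy_gradient`` set the per-map true
    proportional slope reduction r_m = base + gradient * map_index (map
    order V1..V3A/B); condition gains are then g_changing = 1,
    g_low = 1 + r_m / 2, g_high = g_low - r_m, so the planted reduction is
    exactly r_m.  Explicit ``condition_gains`` override this.

    ``noise_fraction`` scales the per-run noise SD to the named fraction of
    each voxel's noiseless changing-condition signal SD; an absolute
    ``noise_sd`` (BOLD units) overrides it.
    """

    n_participants: int = 8
    hemispheres: tuple[str, ...] = ("L", "R")
    maps: tuple[str, ...] = MAP_LABELS
    voxels_per_map: int = 8
    fraction_tuned_by_map: dict[str, float] = field(default_factory=_default_fraction_tuned)
    base_slope_by_map: dict[str, float] = field(default_factory=_default_base_slope)
    reduction_base: float = 0.2
    hierarchy_gradient: float = 0.1
    condition_gains: dict[str, tuple[float, float, float]] | None = None
    noise_fraction: float = 0.1
    noise_sd: float | None = None
    noise_model: str = "white"  # or "ar1"
    ar1_rho: float = 0.3
    ecc_range: tuple[float, float] = (0.05, 1.4)
    fraction_negative_slope: float = 0.05
    slope_jitter_sd: float = 0.1
    runs_per_condition: dict[str, int] = field(
        default_factory=lambda: {"low": 3, "high": 3, "changing": 3}
    )
    tuned_pref_shift: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for m, f in self.fraction_tuned_by_map.items():
            if not 0 <= f <= 1:
                raise ValueError(f"fraction_tuned for {m} outside [0, 1]")
        if self.noise_model not in ("white", "ar1"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        for m, g in (self.condition_gains or {}).items():
            if any(x <= 0 for x in g):
                raise ValueError(f"condition gains for {m} must be positive")

    def true_reduction(self, map_label: str) -> float:
        if self.condition_gains is not None:
            gl, gh, gc = self.condition_gains[map_label]
            return (gl - gh) / gc
        return self.reduction_base + self.hierarchy_gradient * list(self.maps).index(map_label)

    def gains(self, map_label: str) -> tuple[float, float, float]:
        """(g_low, g_high, g_changing) for one map."""
        if self.condition_gains is not None:
            return self.condition_gains[map_label]
        r = self.true_reduction(map_label)
        g_low = 1.0 + r / 2.0
        g_high = g_low - r
        if g_high <= 0:
            raise ValueError(f"reduction {r} for {map_label} implies g_high <= 0")
        return (g_low, g_high, 1.0)


def _noise(rng: np.random.Generator, n: int, sd: float, model: str, rho: float) -> np.ndarray:
    e = rng.normal(0.0, 1.0, n)
    if model == "ar1":
        x = np.empty(n)
        x[0] = e[0] / np.sqrt(1 - rho**2)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + e[t]
        e = x * np.sqrt(1 - rho**2)  # unit marginal variance
    return sd * e


def generate_voxel_dataset(
    config: GroundTruthConfig,
    hrf: HrfSpec = HrfSpec(),
    mode: str = "log_power",
    power_table: Mapping[int, float] | None = None,
) -> tuple[list[VoxelRecord], pd.DataFrame]:
    """Draw a full synthetic dataset and its ground-truth table.

    Returns the voxel records (per-condition run time series plus spatial
    metadata) and a table with one row per voxel holding the generating
    class, parameters, gains and the planted per-map proportional
    reduction.  Fully determined by (config, seed).
    """
    rng = np.random.default_rng(config.seed)
    conditions = ("low", "high", "changing")
    sequences = {c: build_run_sequence(c) for c in conditions}
    if power_table is None and mode == "log_power":
        power_table = mean_power_table(seed=config.seed)
    stim_cols = {
        c: build_design(sequences[c], "monotonic", hrf=hrf, mode=mode,
                        power_table=power_table)["stimulus"].to_numpy()
        for c in conditions
    }
    bases = {c: tuned_basis(sequences[c], hrf) for c in conditions}

    voxels: list[VoxelRecord] = []
    truth_rows = []
    for p in range(config.n_participants):
        part = f"P{p + 1:02d}"
        for hemi in config.hemispheres:
            for map_label in config.maps:
                g_low, g_high, g_chg = config.gains(map_label)
                gains = {"low": g_low, "high": g_high, "changing": g_chg}
                frac_tuned = config.fraction_tuned_by_map.get(map_label, 0.0)
                for i in range(config.voxels_per_map):
                    vid = f"{part}_{hemi}_{map_label}_{i:03d}"
                    ecc = float(rng.uniform(*config.ecc_range))
                    polar = float(rng.uniform(0.0, 360.0))
                    is_tuned = rng.random() < frac_tuned
                    baseline = float(rng.uniform(-1.0, 1.0))
                    truth = {
                        "voxel_id": vid, "participant": part,
                        "hemisphere": hemi, "map_label": map_label,
                        "ecc_deg": ecc, "g_low": g_low, "g_high": g_high,
                        "g_changing": g_chg,
                        "true_reduction": config.true_reduction(map_label),
                    }
                    if is_tuned:
                        pref = float(rng.uniform(np.log(1.5), np.log(6.0)))
                        width = float(rng.uniform(0.3, 0.9))
                        amp = float(rng.uniform(0.8, 1.2))
                        prefs = {
                            "changing": pref,
                            "low": pref + config.tuned_pref_shift,
                            "high": pref - config.tuned_pref_shift,
                        }
                        clean = {}
                        for c in conditions:
                            b = bases[c]
                            a = np.exp(-0.5 * ((np.log(b.numerosities) - prefs[c]) / width) ** 2)
                            clean[c] = amp * gains[c] * (a @ b.C) + baseline
                        truth.update(true_class="tuned", true_slope=np.nan,
                                     true_pref_log=pref, true_width_log=width,
                                     true_amplitude=amp)
                    else:
                        base_slope = config.base_slope_by_map.get(map_label, 1.0)
                        slope = base_slope * (1.0 + rng.normal(0.0, config.slope_jitter_sd))
                        slope = max(slope, 0.1 * base_slope)
                        if rng.random() < config.fraction_negative_slope:
                            slope = -slope
                        clean = {
                            c: slope * gains[c] * stim_cols[c] + baseline
                            for c in conditions
                        }
                        truth.update(true_class="monotonic", true_slope=slope,
                                     true_pref_log=np.nan, true_width_log=np.nan,
                                     true_amplitude=np.nan)
                    if config.noise_sd is not None:
                        sd = config.noise_sd
                    else:
                        sd = config.noise_fraction * float(np.std(clean["changing"]))
                    ts = {
                        c: [
                            clean[c] + _noise(rng, len(clean[c]), sd,
                                              config.noise_model, config.ar1_rho)
                            for _ in range(config.runs_per_condition[c])
                        ]
                        for c in conditions
                    }
                    truth["noise_sd"] = sd
                    voxels.append(VoxelRecord(
                        voxel_id=vid, participant=part, hemisphere=hemi,
                        map_label=map_label, ecc_deg=ecc, polar_deg=polar,
                        timeseries=ts,
                    ))
                    truth_rows.append(truth)
    return voxels, pd.DataFrame(truth_rows)


DEFAULT_PSE_MEANS = {"low_adaptor": 12.0, "no_adaptor": 10.0, "high_adaptor": 8.0}


def generate_behavioral_dataset(
    effects: Mapping[str, float] | None = None,
    between_sd: float = 0.5,
    n_participants: int = 10,
    n_trials: int = 100,
    observer_sigma: float = 1.5,
    seed: int = 0,
    placement: str = "staircase",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the 2AFC adaptation experiment for a group of observers.

    Per participant and condition a true PSE is drawn around the condition
    mean (default repulsive pattern: low adaptor 12 > none 10 > high 8 test
    dots, between-subject SD 0.5), then ``n_trials`` answered trials are
    simulated.  Returns the trial table (with participant column) and the
    per-participant true-PSE table.
    """
    from .behavior import simulate_observer

    if effects is None:
        effects = DEFAULT_PSE_MEANS
    if between_sd <= 0 or observer_sigma <= 0:
        raise ValueError("standard deviations must be positive")
    rng = np.random.default_rng(seed)
    trials = []
    truths = []
    for p in range(n_participants):
        part = f"S{p + 1:02d}"
        for cond, mean_pse in effects.items():
            true_pse = float(rng.normal(mean_pse, between_sd))
            t = simulate_observer(
                true_pse, observer_sigma, n_trials,
                seed=rng, placement=placement, condition=cond,
            )
            t.insert(0, "participant", part)
            trials.append(t)
            truths.append({"participant": part, "condition": cond,
                           "true_pse": true_pse})
    return pd.concat(trials, ignore_index=True), pd.DataFrame(truths)


def generate_reduction_examples(
    n_participants: int = 8,
    maps: tuple[str, ...] = MAP_LABELS,
    hemispheres: tuple[str, ...] = ("L", "R"),
    reduction_base: float = 0.2,
    hierarchy_gradient: float = 0.1,
    participant_sd: float = 0.05,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a map-example proportional-reduction table directly.

    Generates reduction values at the map-example level (true per-map
    reduction + participant offset + noise) without simulating BOLD, for
    calibration studies of the group statistics (e.g. ANOVA type-I error
    over many replicates) where the full voxel pipeline would be needless.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        part = f"P{p + 1:02d}"
        offset = rng.normal(0.0, participant_sd)
        for hemi in hemispheres:
            for j, m in enumerate(maps):
                r = reduction_base + hierarchy_gradient * j
                rows.append({
                    "participant": part, "hemisphere": hemi, "map_label": m,
                    "proportional_reduction": r + offset + rng.normal(0.0, noise_sd),
                })
    return pd.DataFrame(rows)
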