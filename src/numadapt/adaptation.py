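"""Voxel selection, map-example aggregation and the adaptation metric.

The unit of group analysis is the *map example*: one visual field map in
one hemisphere.  Monotonic voxels are filtered by eccentricity, by a
positive slope in the control (changing-adaptor) condition, and by variance
explained; their slopes are averaged per map example and condition.  The
adaptation effect is summarised as the proportional slope reduction
(slope_low - slope_high) / slope_changing, a gain-invariant quantity that
can be compared across maps with very different raw response amplitudes.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "select_voxels",
    "aggregate_map_examples",
    "proportional_reduction",
    "add_proportional_reduction",
]

log = logging.getLogger(__name__)

ECC_MAX_DEG = 1.0
MIN_R2_CHANGING = 0.1
MIN_MAP_EXAMPLE_R2 = 0.1


def _wide_fits(fits: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long fits table to one row per voxel with per-condition
    slope/r2 columns."""
    meta_cols = ["voxel_id", "participant", "hemisphere", "map_label",
                 "ecc_deg", "model_class"]
    meta = fits[meta_cols].drop_duplicates("voxel_id").set_index("voxel_id")
    wide = fits.pivot(index="voxel_id", columns="condition",
                      values=["slope", "r2"])
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    return meta.join(wide).reset_index()


def select_voxels(
    fits: pd.DataFrame,
    ecc_max: float = ECC_MAX_DEG,
    min_r2: float = MIN_R2_CHANGING,
) -> pd.DataFrame:
    """Apply the three voxel-selection criteria to a long fits table.

    Keeps voxels that (1) prefer a visual field position with eccentricity
    below ``ecc_max`` degrees (their spatial receptive fields cover the
    stimulus area), (2) have a positive monotonic slope in the control
    (changing-adaptor) condition, and (3) explain at least ``min_r2`` of
    the changing-condition variance — and that are classified monotonic.
    Returns one row per retained voxel with per-condition slopes and R^2.
    """
    wide = _wide_fits(fits)
    keep = (
        (wide["model_class"] == "monotonic")
        & (wide["ecc_deg"] < ecc_max)
        & (wide["slope_changing"] > 0)
        & (wide["r2_changing"] >= min_r2)
    )
    return wide.loc[keep].reset_index(drop=True)


def aggregate_map_examples(
    selected: pd.DataFrame,
    min_example_r2: float = MIN_MAP_EXAMPLE_R2,
) -> pd.DataFrame:
    """Average selected voxels into map examples (map x hemisphere).

    Per participant x hemisphere x map: unweighted means of the
    per-condition slopes and of the low/high-condition R^2.  Examples whose
    mean variance explained falls below ``min_example_r2`` in *both* the
    low and high adaptor conditions show no clear response to those
    conditions and are flagged ``included = False``.  Map examples with no
    selected voxels are simply absent.
    """
    if selected.empty:
        return pd.DataFrame(
            columns=["participant", "hemisphere", "map_label", "n_voxels",
                     "mean_slope_low", "mean_slope_high", "mean_slope_changing",
                     "mean_r2_low", "mean_r2_high", "included"]
        )
    g = selected.groupby(["participant", "hemisphere", "map_label"],
                         observed=True, sort=True)
    out = g.agg(
        n_voxels=("voxel_id", "size"),
        mean_slope_low=("slope_low", "mean"),
        mean_slope_high=("slope_high", "mean"),
        mean_slope_changing=("slope_changing", "mean"),
        mean_r2_low=("r2_low", "mean"),
        mean_r2_high=("r2_high", "mean"),
    ).reset_index()
    out["included"] = ~(
        (out["mean_r2_low"] < min_example_r2)
        & (out["mean_r2_high"] < min_example_r2)
    )
    return out


def proportional_reduction(
    mean_slope_low: float, mean_slope_high: float, mean_slope_changing: float
) -> float:
    """Adaptation-effect strength of one map example.

    (slope_low - slope_high) / slope_changing: the drop in response
    amplitude from the weakest to the strongest adaptor, as a proportion of
    the control-condition amplitude.  Invariant to any global response gain,
    so comparable across visual field maps.  Undefined (NaN) when the
    control slope is not positive.
    """
    if not mean_slope_changing > 0:
        warnings.warn(
            "proportional reduction undefined for non-positive control slope",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return (mean_slope_low - mean_slope_high) / mean_slope_changing


def add_proportional_reduction(
    examples: pd.DataFrame, drop_undefined: bool = True
) -> pd.DataFrame:
    """Attach the proportional-reduction column to a map-example table.

    Examples flagged not included are dropped, as are (with a logged
    warning) examples whose control-condition slope is not positive.
    """
    out = examples.loc[examples["included"]].copy()
    bad = ~(out["mean_slope_changing"] > 0)
    if bad.any():
        log.warning(
            "dropping %d map example(s) with non-positive control slope",
            int(bad.sum()),
        )
        if drop_undefined:
            out = out.loc[~bad].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["proportional_reduction"] = (
            out["mean_slope_low"] - out["mean_slope_high"]
        ) / out["mean_slope_changing"]
    if drop_undefined:
        out = out.loc[np.isfinite(out["proportional_reduction"])]
    return out.reset_index(drop=True)
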