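"""Voxel-level response-model fitting, cross-validation and classification.

Two candidate models describe each voxel's BOLD time course:

* ``MonotonicResponseModel`` — a GLM whose stimulus regressor follows the
  log aggregate Fourier power (or log numerosity) of the displays; the
  fitted slope is the voxel's response amplitude per unit log predictor.
* ``TunedResponseModel`` — an exhaustive grid search over log-Gaussian
  numerosity tuning curves (preferred log numerosity x log width), with
  amplitude and baseline solved per candidate by least squares (amplitude
  clipped at zero) and the minimum-SSE candidate retained.

Model classes are assigned per voxel by odd/even-run cross-validation in
the changing-adaptor condition: each model is fit on one half and scored on
the other with a free non-negative amplitude rescale (halves may come from
different sessions with arbitrary signal scaling); the model with lower
summed cross-fold SSE wins, with tuned winners re-labelled monotonic when
their preferred numerosity exceeds 7.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .design import (
    TunedBasis,
    TunedGrid,
    TunedParams,
    build_design,
    make_tuned_grid,
    tuned_basis,
)
from .hrf import HrfSpec
from .stimuli import RunSequence

__all__ = [
    "VoxelRecord",
    "MonotonicResponseModel",
    "TunedResponseModel",
    "CrossvalResult",
    "fit_glm",
    "grid_fit_tuned",
    "crossval_compare",
    "classify_voxel",
    "fit_voxels",
]

MAP_LABELS = ("V1", "V2", "V3", "hV4", "LO1", "LO2", "V3AB")
HEMISPHERES = ("L", "R")

#: Tuned winners with preferred numerosity above this are treated as
#: monotonic responses (tuned preferences above 7 are rarely genuine).
PREFERENCE_RECLASSIFY_ABOVE = 7.0
#: Tuned-analysis inclusion requires at least this much variance explained
#: in the changing-adaptor condition.
TUNED_R2_EXCLUSION = 0.2


@dataclass
class VoxelRecord:
    """One recording site: per-condition run time series plus metadata."""

    voxel_id: str
    participant: str
    hemisphere: str
    map_label: str
    ecc_deg: float
    polar_deg: float
    timeseries: dict[str, list[np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be L or R, got {self.hemisphere!r}")
        if self.map_label not in MAP_LABELS:
            raise ValueError(
                f"unknown map label {self.map_label!r}; allowed: {MAP_LABELS}"
            )
        if self.ecc_deg < 0:
            raise ValueError("eccentricity must be non-negative")
        for cond, runs in self.timeseries.items():
            lengths = {len(r) for r in runs}
            if len(lengths) > 1:
                raise ValueError(
                    f"runs of condition {cond!r} have unequal lengths {lengths}"
                )

    def average(self, condition: str, runs: Sequence[int] | None = None) -> np.ndarray:
        """Mean time series over (a subset of) the condition's runs."""
        all_runs = self.timeseries[condition]
        chosen = all_runs if runs is None else [all_runs[i] for i in runs]
        if not chosen:
            raise ValueError("no runs to average")
        return np.mean(chosen, axis=0)


def _r2(y: np.ndarray, resid_ss: float) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0 if resid_ss > 0 else 1.0
    return 1.0 - resid_ss / ss_tot


class MonotonicResponseModel(BaseEstimator, RegressorMixin):
    """Ordinary-least-squares GLM of a voxel time series on a design matrix.

    Parameters
    ----------
    stimulus_column : name of the design column whose coefficient is the
        response slope (BOLD change per unit log predictor).

    Attributes (after fit)
    ----------------------
    slope_ : stimulus-column coefficient.
    baseline_ : constant-column coefficient.
    coef_ : all coefficients, in design-column order.
    r2_ : variance explained, 1 - SS_res / SS_tot.
    """

    def __init__(self, stimulus_column: str = "stimulus"):
        self.stimulus_column = stimulus_column

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "MonotonicResponseModel":
        y = np.asarray(y, dtype=float)
        M = np.asarray(X, dtype=float)
        if len(y) != M.shape[0]:
            raise ValueError(
                f"design has {M.shape[0]} timepoints but series has {len(y)}"
            )
        if np.linalg.matrix_rank(M) < M.shape[1]:
            raise ValueError("design matrix is rank deficient")
        coef, _, _, _ = np.linalg.lstsq(M, y, rcond=None)
        resid = y - M @ coef
        self.columns_ = list(X.columns)
        self.coef_ = coef
        self.slope_ = float(coef[self.columns_.index(self.stimulus_column)])
        self.baseline_ = (
            float(coef[self.columns_.index("constant")])
            if "constant" in self.columns_
            else 0.0
        )
        self.r2_ = _r2(y, float(resid @ resid))
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_

    def stimulus_component(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted response with the baseline removed (for rescaled CV)."""
        i = self.columns_.index(self.stimulus_column)
        return np.asarray(X, dtype=float)[:, i] * self.coef_[i]


class TunedResponseModel(BaseEstimator, RegressorMixin):
    """Grid-search fit of the log-Gaussian numerosity tuning model.

    ``fit`` takes a :class:`~numadapt.design.TunedBasis` (the HRF-convolved
    per-numerosity basis of one run sequence) and a voxel time series.  For
    every grid candidate the amplitude (clipped at zero: responses may
    rescale but not invert) and baseline are solved in closed form and the
    candidate with minimum SSE is kept; ties resolve to the lowest
    pref_log, then lowest width_log.

    Attributes (after fit): ``pref_log_``, ``width_log_``, ``amplitude_``,
    ``baseline_``, ``r2_``, ``sse_``, ``params_``.
    """

    def __init__(self, grid: TunedGrid | None = None):
        self.grid = grid

    def fit(self, X: TunedBasis, y: np.ndarray) -> "TunedResponseModel":
        basis = X
        grid = self.grid if self.grid is not None else make_tuned_grid()
        y = np.asarray(y, dtype=float)
        T = basis.n_timepoints
        if len(y) != T:
            raise ValueError(f"basis has {T} timepoints but series has {len(y)}")
        A, sum_x, sumsq_x = basis.candidate_moments(grid)
        sy = y.sum()
        syy_c = float(y @ y - sy**2 / T)
        t_k = A @ (basis.C @ y)
        sxy = t_k - sum_x * sy / T
        sxx = sumsq_x - sum_x**2 / T
        with np.errstate(divide="ignore", invalid="ignore"):
            amp = np.where(sxx > 1e-12, sxy / np.where(sxx > 1e-12, sxx, 1.0), 0.0)
        amp = np.maximum(amp, 0.0)
        sse = syy_c - 2.0 * amp * sxy + amp**2 * sxx
        # ties (within rounding of the total variance) resolve to the first
        # candidate in grid order: lowest pref_log, then lowest width_log
        tol = 1e-9 * max(abs(syy_c), 1.0)
        best = int(np.flatnonzero(sse <= sse.min() + tol)[0])
        self.grid_ = grid
        self.best_index_ = best
        self.pref_log_ = float(grid.pref_log[best])
        self.width_log_ = float(grid.width_log[best])
        self.amplitude_ = float(amp[best])
        self.baseline_ = float((sy - self.amplitude_ * sum_x[best]) / T)
        self.sse_ = float(sse[best])
        self.r2_ = _r2(y, self.sse_)
        self.params_ = TunedParams(self.pref_log_, self.width_log_)
        self._amplitudes_row = A[best]
        return self

    def predict(self, X: TunedBasis) -> np.ndarray:
        a = np.exp(
            -0.5
            * ((np.log(X.numerosities) - self.pref_log_) / self.width_log_) ** 2
        )
        return self.amplitude_ * (a @ X.C) + self.baseline_

    def stimulus_component(self, X: TunedBasis) -> np.ndarray:
        return self.predict(X) - self.baseline_


def fit_glm(y: np.ndarray, X: pd.DataFrame) -> MonotonicResponseModel:
    """OLS fit of a voxel time series on a design matrix (thin wrapper)."""
    return MonotonicResponseModel().fit(X, y)


def grid_fit_tuned(
    y: np.ndarray,
    seq: RunSequence,
    grid: TunedGrid | None = None,
    hrf: HrfSpec = HrfSpec(),
    basis: TunedBasis | None = None,
) -> TunedResponseModel:
    """Exhaustive tuned-model grid search on one voxel time series."""
    if basis is None:
        basis = tuned_basis(seq, hrf)
    return TunedResponseModel(grid=grid).fit(basis, y)


def _rescaled_sse(p: np.ndarray, y: np.ndarray, refit_baseline: bool = True) -> float:
    """SSE of y against amp * p + b with amp >= 0 (b free by default).

    The non-negative amplitude means predictions may rescale between data
    halves but never flip sign.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if refit_baseline:
        pc = p - p.mean()
        yc = y - y.mean()
    else:
        pc, yc = p, y
    spp = float(pc @ pc)
    amp = max(0.0, float(pc @ yc) / spp) if spp > 0 else 0.0
    r = yc - amp * pc
    return float(r @ r)


@dataclass
class CrossvalResult:
    """Odd/even cross-validated model comparison for one voxel."""

    model_class: str  # "monotonic" or "tuned" (pre-reclassification)
    sse: dict[str, float]
    cv_r2: dict[str, float]
    monotonic_fit: MonotonicResponseModel
    tuned_fit: TunedResponseModel
    condition: str = "changing"


def crossval_compare(
    voxel: VoxelRecord,
    condition: str = "changing",
    seq: RunSequence | None = None,
    hrf: HrfSpec = HrfSpec(),
    mode: str = "log_power",
    power_table: Mapping[int, float] | None = None,
    grid: TunedGrid | None = None,
    design: pd.DataFrame | None = None,
    basis: TunedBasis | None = None,
    refit_baseline: bool = True,
) -> CrossvalResult:
    """Compare monotonic vs tuned models by odd/even-run cross-validation.

    Odd-numbered and even-numbered runs (acquisition order, 1-based) are
    averaged separately.  Each model is fit on each half and its prediction
    scored on the complementary half with a free non-negative amplitude
    (and, by default, a re-fit baseline).  Summed SSE over both directions
    decides the winner; ties go to the simpler monotonic model.  The fits
    returned are on the average of *all* runs.

    cv_r2 is 1 - (summed cross-fold SSE) / (summed cross-fold SS_tot).
    """
    runs = voxel.timeseries.get(condition, [])
    if len(runs) < 2:
        raise ValueError(
            f"cross-validation needs >= 2 runs in condition {condition!r}, "
            f"got {len(runs)}"
        )
    if seq is None:
        from .stimuli import build_run_sequence

        seq = build_run_sequence(condition)
    if design is None:
        design = build_design(seq, "monotonic", hrf=hrf, mode=mode,
                              power_table=power_table)
    if basis is None:
        basis = tuned_basis(seq, hrf)

    odd = voxel.average(condition, list(range(0, len(runs), 2)))
    even = voxel.average(condition, list(range(1, len(runs), 2)))
    halves = [(odd, even), (even, odd)]

    sse = {"monotonic": 0.0, "tuned": 0.0}
    ss_tot = 0.0
    for fit_half, eval_half in halves:
        mono = MonotonicResponseModel().fit(design, fit_half)
        tuned = TunedResponseModel(grid=grid).fit(basis, fit_half)
        sse["monotonic"] += _rescaled_sse(
            mono.stimulus_component(design), eval_half, refit_baseline
        )
        sse["tuned"] += _rescaled_sse(
            tuned.stimulus_component(basis), eval_half, refit_baseline
        )
        ss_tot += float(np.sum((eval_half - eval_half.mean()) ** 2))

    cv_r2 = {
        m: (1.0 - s / ss_tot) if ss_tot > 0 else 0.0 for m, s in sse.items()
    }
    winner = "monotonic" if sse["monotonic"] <= sse["tuned"] else "tuned"

    y_all = voxel.average(condition)
    mono_full = MonotonicResponseModel().fit(design, y_all)
    mono_full.cv_r2_ = cv_r2["monotonic"]
    tuned_full = TunedResponseModel(grid=grid).fit(basis, y_all)
    tuned_full.cv_r2_ = cv_r2["tuned"]
    return CrossvalResult(
        model_class=winner,
        sse=sse,
        cv_r2=cv_r2,
        monotonic_fit=mono_full,
        tuned_fit=tuned_full,
        condition=condition,
    )


def classify_voxel(
    cv: CrossvalResult,
    tuned_fit: TunedResponseModel | None = None,
    preference_cutoff: float = PREFERENCE_RECLASSIFY_ABOVE,
    tuned_r2_threshold: float = TUNED_R2_EXCLUSION,
) -> str:
    """Assign a voxel's response class from its cross-validation outcome.

    Monotonic if cross-validation picked the monotonic model, or if the
    winning tuned model prefers a numerosity above ``preference_cutoff``
    (such fits almost always reflect monotonic responses).  Otherwise tuned,
    unless the tuned fit explains less than ``tuned_r2_threshold`` of the
    changing-condition variance, in which case the voxel is excluded from
    tuned-response analyses.
    """
    if tuned_fit is None:
        tuned_fit = cv.tuned_fit
    if cv.model_class == "monotonic":
        return "monotonic"
    if np.exp(tuned_fit.pref_log_) > preference_cutoff:
        return "monotonic"
    if tuned_fit.r2_ < tuned_r2_threshold:
        return "excluded"
    return "tuned"


def fit_voxels(
    voxels: Sequence[VoxelRecord],
    sequences: Mapping[str, RunSequence] | None = None,
    hrf: HrfSpec = HrfSpec(),
    mode: str = "log_power",
    power_table: Mapping[int, float] | None = None,
    grid: TunedGrid | None = None,
    conditions: Sequence[str] = ("low", "high", "changing"),
    fit_tuned_all_conditions: str = "tuned_only",
) -> pd.DataFrame:
    """Fit every voxel in every condition and classify response types.

    Returns a long-format table, one row per voxel x condition, with the
    monotonic fit (slope, baseline, r2), the changing-condition model class
    and cross-validated R^2 values, and tuned parameters where the tuned
    model was fit (always in the changing condition; in the other
    conditions for tuned/excluded voxels by default, or for all voxels with
    ``fit_tuned_all_conditions="all"``).
    """
    from .stimuli import build_run_sequence

    if sequences is None:
        sequences = {c: build_run_sequence(c) for c in conditions}
    if grid is None:
        grid = make_tuned_grid()
    if mode == "log_power" and power_table is None:
        from .stimuli import mean_power_table

        power_table = mean_power_table()
    designs = {
        c: build_design(sequences[c], "monotonic", hrf=hrf, mode=mode,
                        power_table=power_table)
        for c in conditions
    }
    bases = {c: tuned_basis(sequences[c], hrf) for c in conditions}

    rows = []
    for vox in voxels:
        cv = crossval_compare(
            vox,
            "changing",
            seq=sequences["changing"],
            hrf=hrf,
            mode=mode,
            power_table=power_table,
            grid=grid,
            design=designs["changing"],
            basis=bases["changing"],
        )
        vclass = classify_voxel(cv)
        want_tuned_everywhere = fit_tuned_all_conditions == "all" or vclass != "monotonic"
        for cond in conditions:
            y = vox.average(cond)
            mono = MonotonicResponseModel().fit(designs[cond], y)
            row = {
                "voxel_id": vox.voxel_id,
                "participant": vox.participant,
                "hemisphere": vox.hemisphere,
                "map_label": vox.map_label,
                "ecc_deg": vox.ecc_deg,
                "condition": cond,
                "model_class": vclass,
                "slope": mono.slope_,
                "baseline": mono.baseline_,
                "r2": mono.r2_,
                "cv_r2": cv.cv_r2["monotonic"] if cond == "changing" else np.nan,
                "pref_log": np.nan,
                "width_log": np.nan,
                "amplitude": np.nan,
                "tuned_r2": np.nan,
                "tuned_cv_r2": np.nan,
            }
            if cond == "changing":
                tf = cv.tuned_fit
            elif want_tuned_everywhere:
                tf = TunedResponseModel(grid=grid).fit(bases[cond], y)
            else:
                tf = None
            if tf is not None:
                row.update(
                    pref_log=tf.pref_log_,
                    width_log=tf.width_log_,
                    amplitude=tf.amplitude_,
                    tuned_r2=tf.r2_,
                    tuned_cv_r2=getattr(tf, "cv_r2_", np.nan),
                )
            rows.append(row)
    return pd.DataFrame(rows)
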