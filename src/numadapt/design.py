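"""Predictor (design-matrix) construction for the two voxel response models.

Monotonic model: the neural response to each display is proportional to the
log aggregate Fourier power of the display (or, in the alternate mode, to
log numerosity).  Tuned model: the neural response follows a log-Gaussian
numerosity tuning curve exp(-(ln n - p)^2 / (2 w^2)) with preferred log
numerosity p and log-space width w.

Each TR contains an adaptor display and a changing display; both are
modelled.  In the low/high conditions the adaptor numerosity is constant,
so its regressor is constant and absorbed by the GLM baseline.  In the
changing condition the adaptor regressor is identical to the
changing-numerosity regressor; to keep the GLM full rank the two are summed
into one column, doubling the predicted amplitude (and hence halving the
fitted scale relative to a changing-only design).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .hrf import HrfSpec, convolve_hrf
from .stimuli import RunSequence

__all__ = [
    "TunedParams",
    "TunedGrid",
    "TunedBasis",
    "monotonic_neural_timecourse",
    "tuned_neural_timecourse",
    "build_design",
    "make_tuned_grid",
    "tuned_basis",
]

PREF_LOG_RANGE = (0.007, 5.491)
PREF_LOG_STEP = 0.01
WIDTH_LOG_RANGE = (0.03, 3.0)
WIDTH_LOG_STEP = 0.0074
#: Candidates with pref_log more than two widths above log(14) only predict
#: responses to the 20-dot baseline and are excluded from the grid.
PREF_EXCLUSION_CENTRE = 2.64


@dataclass(frozen=True)
class TunedParams:
    """Log-Gaussian numerosity tuning: preferred log numerosity and width."""

    pref_log: float
    width_log: float

    def __post_init__(self) -> None:
        lo, hi = PREF_LOG_RANGE
        if not (lo <= self.pref_log <= hi):
            raise ValueError(f"pref_log {self.pref_log} outside [{lo}, {hi}]")
        wlo, whi = WIDTH_LOG_RANGE
        if not (wlo <= self.width_log <= whi):
            raise ValueError(f"width_log {self.width_log} outside [{wlo}, {whi}]")
        if self.pref_log > PREF_EXCLUSION_CENTRE + 2 * self.width_log:
            raise ValueError(
                "pref_log more than two widths above log(14): candidate only "
                "predicts responses to numerosity 20 and is not modelled"
            )

    @property
    def preferred_numerosity(self) -> float:
        return float(np.exp(self.pref_log))


class TunedGrid:
    """The exhaustive candidate set for the tuned-model grid search.

    Candidates are ordered pref-major, width-minor, both ascending, which
    fixes the deterministic tie-break (lowest pref_log, then lowest
    width_log) via first-argmin.
    """

    def __init__(self, pref_log: np.ndarray, width_log: np.ndarray):
        self.pref_log = np.asarray(pref_log, dtype=float)
        self.width_log = np.asarray(width_log, dtype=float)
        if self.pref_log.shape != self.width_log.shape:
            raise ValueError("pref_log and width_log must have equal length")
        if self.pref_log.size == 0:
            raise ValueError("empty tuned-model grid")
        self._amp_cache: dict[tuple, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.pref_log)

    def amplitudes(self, numerosities: np.ndarray) -> np.ndarray:
        """(n_candidates, n_levels) tuning amplitudes at the given counts."""
        key = tuple(np.asarray(numerosities, dtype=float))
        if key not in self._amp_cache:
            ln = np.log(np.asarray(key))
            z = (ln[None, :] - self.pref_log[:, None]) / self.width_log[:, None]
            self._amp_cache[key] = np.exp(-0.5 * z**2)
        return self._amp_cache[key]


def make_tuned_grid(
    pref_range: tuple[float, float] = PREF_LOG_RANGE,
    pref_step: float = PREF_LOG_STEP,
    width_range: tuple[float, float] = WIDTH_LOG_RANGE,
    width_step: float = WIDTH_LOG_STEP,
    exclusion_centre: float = PREF_EXCLUSION_CENTRE,
) -> TunedGrid:
    """Enumerate the (pref_log, width_log) candidate lattice.

    Preferred log numerosities from 0.007 (log 1.007) to 5.491 (log 242) in
    steps of 0.01; widths from 0.03 to 3 in steps of 0.0074; candidates with
    pref_log > exclusion_centre + 2 * width_log removed.
    """
    prefs = np.arange(pref_range[0], pref_range[1] + 1e-9, pref_step)
    widths = np.arange(width_range[0], width_range[1] + 1e-9, width_step)
    pp, ww = np.meshgrid(prefs, widths, indexing="ij")
    keep = pp <= exclusion_centre + 2 * ww
    return TunedGrid(pp[keep], ww[keep])


def _role_numerosities(seq: RunSequence, role: str) -> np.ndarray:
    if role == "changing":
        return seq.changing_n
    if role == "adaptor":
        return seq.adaptor_n
    raise ValueError(f"role must be 'changing' or 'adaptor', got {role!r}")


def monotonic_neural_timecourse(
    seq: RunSequence,
    role: str,
    mode: str = "log_power",
    power_table: Mapping[int, float] | None = None,
) -> np.ndarray:
    """Per-TR neural amplitude under the monotonic model.

    ``mode="log_power"`` maps each presented numerosity through
    ``log(power_table[n])``; ``mode="log_numerosity"`` through ``log(n)``.
    """
    ns = _role_numerosities(seq, role)
    if mode == "log_numerosity":
        return np.log(ns.astype(float))
    if mode == "log_power":
        if power_table is None:
            raise ValueError("log_power mode requires a power_table")
        missing = sorted(set(ns.tolist()) - set(int(k) for k in power_table))
        if missing:
            raise KeyError(f"power_table missing numerosities {missing}")
        return np.log(np.array([power_table[int(n)] for n in ns], dtype=float))
    raise ValueError(f"unknown mode {mode!r}")


def tuned_neural_timecourse(
    seq: RunSequence, role: str, params: TunedParams
) -> np.ndarray:
    """Per-TR neural amplitude under the log-Gaussian tuned model.

    Amplitude at a TR showing n dots is exp(-(ln n - p)^2 / (2 w^2)), so the
    peak amplitude 1 is attained exactly when ln n equals the preference.
    """
    ns = _role_numerosities(seq, role).astype(float)
    z = (np.log(ns) - params.pref_log) / params.width_log
    return np.exp(-0.5 * z**2)


def build_design(
    seq: RunSequence,
    model: str = "monotonic",
    params: TunedParams | None = None,
    hrf: HrfSpec = HrfSpec(),
    mode: str = "log_power",
    power_table: Mapping[int, float] | None = None,
) -> pd.DataFrame:
    """Assemble the GLM design matrix for one run sequence.

    Columns: ``stimulus`` (HRF-convolved neural series; merged with the
    adaptor column when the two are identical, i.e. the changing condition)
    and ``constant``.  A constant adaptor column (low/high conditions) is
    absorbed into the baseline and therefore dropped; the adaptor treatment
    is recorded in ``DataFrame.attrs["adaptor"]``.

    Raises
    ------
    ValueError
        If the adaptor column is collinear with, but not identical to, the
        stimulus column (a degenerate design this paradigm never produces).
    """
    if model == "monotonic":
        neural_c = monotonic_neural_timecourse(seq, "changing", mode, power_table)
        neural_a = monotonic_neural_timecourse(seq, "adaptor", mode, power_table)
    elif model == "tuned":
        if params is None:
            raise ValueError("tuned design requires TunedParams")
        neural_c = tuned_neural_timecourse(seq, "changing", params)
        neural_a = tuned_neural_timecourse(seq, "adaptor", params)
    else:
        raise ValueError(f"unknown model {model!r}")

    col_c = convolve_hrf(neural_c, hrf, seq.tr_seconds)
    col_a = convolve_hrf(neural_a, hrf, seq.tr_seconds)

    if np.allclose(col_a, col_a[0]):
        stimulus = col_c
        adaptor = "absorbed_constant"
    elif np.allclose(col_a, col_c):
        stimulus = col_c + col_a  # doubled amplitude, halves the fitted scale
        adaptor = "merged_identical"
    else:
        resid = col_a - col_a.mean()
        stim_c = col_c - col_c.mean()
        denom = np.linalg.norm(resid) * np.linalg.norm(stim_c)
        corr = float(resid @ stim_c / denom) if denom > 0 else 0.0
        if abs(corr) > 1 - 1e-10:
            raise ValueError(
                "adaptor regressor is collinear with but not identical to the "
                f"stimulus regressor (|r| = {abs(corr):.12f}); design is rank "
                "deficient"
            )
        X = pd.DataFrame(
            {"stimulus": col_c, "adaptor": col_a, "constant": np.ones(len(col_c))}
        )
        X.attrs.update(condition=seq.condition, model=model, adaptor="separate")
        return X

    X = pd.DataFrame({"stimulus": stimulus, "constant": np.ones(len(stimulus))})
    X.attrs.update(condition=seq.condition, model=model, adaptor=adaptor)
    return X


class TunedBasis:
    """Precomputed per-numerosity HRF-convolved indicator basis for one run.

    Any tuned-model prediction for this run is ``a @ C`` where ``a`` holds
    the candidate's tuning amplitudes at the run's distinct numerosities and
    ``C`` stacks the convolved indicator series of those numerosities
    (changing role plus, where not constant, the adaptor role).  The grid
    search over ~2e5 candidates then reduces to 8-dimensional quadratic
    forms, independent of the number of TRs.
    """

    def __init__(self, seq: RunSequence, hrf: HrfSpec = HrfSpec()):
        self.seq = seq
        self.hrf = hrf
        self.numerosities = np.unique(
            np.concatenate([seq.changing_n, seq.adaptor_n])
        ).astype(float)
        C_c = self._role_basis(seq.changing_n)
        adaptor_constant = np.all(seq.adaptor_n == seq.adaptor_n[0])
        if adaptor_constant:
            # constant adaptor -> constant regressor, absorbed by baseline
            self.C = C_c
            self.adaptor = "absorbed_constant"
        else:
            self.C = C_c + self._role_basis(seq.adaptor_n)
            self.adaptor = "merged_identical"
        self.n_timepoints = self.C.shape[1]
        # candidate-independent moments
        self.col_sums = self.C.sum(axis=1)
        self.gram = self.C @ self.C.T
        self._sumsq_cache: dict[int, np.ndarray] = {}
        self._sum_cache: dict[int, np.ndarray] = {}

    def _role_basis(self, ns: np.ndarray) -> np.ndarray:
        rows = []
        for u in self.numerosities:
            rows.append(convolve_hrf((ns == u).astype(float), self.hrf,
                                     self.seq.tr_seconds))
        return np.asarray(rows)

    def candidate_moments(self, grid: TunedGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(amplitudes A, per-candidate prediction sums, sums of squares)."""
        A = grid.amplitudes(self.numerosities)
        key = id(grid)
        if key not in self._sumsq_cache:
            self._sum_cache[key] = A @ self.col_sums
            self._sumsq_cache[key] = np.einsum("kj,ji,ki->k", A, self.gram, A)
        return A, self._sum_cache[key], self._sumsq_cache[key]


def tuned_basis(seq: RunSequence, hrf: HrfSpec = HrfSpec()) -> TunedBasis:
    """Build (or rebuild) the tuned-model prediction basis for a run."""
    return TunedBasis(seq, hrf)
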