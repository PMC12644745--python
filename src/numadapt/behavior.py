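"""Behavioural validation: 2AFC numerosity comparison and PSE analysis.

A simulated observer compares a variable test numerosity against a fixed
reference of 10 dots after adapting to a low (1-dot) or high (20-dot)
patch, or to nothing.  Numerosity adaptation is repulsive: a low adaptor
makes the adapted reference appear more numerous (raising the PSE measured
in test units), a high adaptor lowers it.  Responses follow a cumulative
Gaussian psychometric function; fitting it per condition yields the point
of subjective equality (PSE), and paired t-tests with Bonferroni correction
compare PSEs across adaptor conditions.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from scipy.stats import norm
from sklearn.base import BaseEstimator

__all__ = [
    "BEHAVIOR_CONDITIONS",
    "REFERENCE_NUMEROSITY",
    "simulate_observer",
    "PsychometricModel",
    "fit_psychometric",
    "compare_pse",
]

BEHAVIOR_CONDITIONS = ("low_adaptor", "high_adaptor", "no_adaptor")
REFERENCE_NUMEROSITY = 10

_SIGMA_BOUNDS = (0.05, 50.0)


def _p_more(test, pse, sigma):
    """P(respond 'test more numerous'); degenerates to a step as sigma -> 0."""
    test = np.asarray(test, dtype=float)
    if sigma <= 1e-12:
        return np.where(test > pse, 1.0, np.where(test < pse, 0.0, 0.5))
    return norm.cdf((test - pse) / sigma)


def simulate_observer(
    true_pse: float,
    sigma: float,
    n_trials: int,
    seed: int | np.random.Generator = 0,
    placement: str = "staircase",
    condition: str = "no_adaptor",
    levels: np.ndarray | None = None,
    no_response_rate: float = 0.0,
    reference: int = REFERENCE_NUMEROSITY,
) -> pd.DataFrame:
    """Simulate one observer's 2AFC trials in one adaptor condition.

    Responses are Bernoulli with P(test judged more numerous) =
    Phi((test - true_pse) / sigma).  Test numerosities are chosen either
    from a fixed grid of integer levels or by a greedy minimum-expected-
    entropy staircase: a posterior over a (pse, sigma) lattice is updated
    after every response, and the next test level is the one minimising the
    expected posterior entropy, which concentrates testing near the running
    PSE estimate.  Unanswered trials (probability ``no_response_rate``) are
    recorded and re-queued, so ``n_trials`` answered trials are returned
    plus any unanswered ones.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    if levels is None:
        levels = np.arange(max(1, reference - 8), reference + 9)
    levels = np.asarray(levels, dtype=int)

    if placement == "staircase":
        mu_lat = np.linspace(levels.min(), levels.max(), 41)
        sig_lat = np.geomspace(0.3, 8.0, 13)
        MU, SG = np.meshgrid(mu_lat, sig_lat, indexing="ij")
        post = np.full(MU.shape, 1.0 / MU.size)
        # P(more | lattice point, level): (n_mu, n_sigma, n_levels)
        pml = norm.cdf((levels[None, None, :] - MU[..., None]) / SG[..., None])
    elif placement != "fixed_grid":
        raise ValueError(f"unknown placement {placement!r}")

    rows = []
    answered = 0
    while answered < n_trials:
        if placement == "fixed_grid":
            test = int(rng.choice(levels))
        else:
            p_more_lvl = np.tensordot(post, pml, axes=([0, 1], [0, 1]))
            exp_ent = np.zeros(len(levels))
            for lik, resp_p in ((pml, p_more_lvl), (1 - pml, 1 - p_more_lvl)):
                w = post[..., None] * lik  # (n_mu, n_sigma, n_levels)
                tot = np.maximum(w.sum(axis=(0, 1)), 1e-300)
                wn = w / tot
                with np.errstate(divide="ignore", invalid="ignore"):
                    h = -np.where(wn > 0, wn * np.log(wn), 0.0).sum(axis=(0, 1))
                exp_ent += np.where(resp_p > 0, resp_p * h, 0.0)
            test = int(levels[int(np.argmin(exp_ent))])

        responded = rng.random() >= no_response_rate
        side = "left" if rng.random() < 0.5 else "right"
        if not responded:
            rows.append({"condition": condition, "test_numerosity": test,
                         "reference_numerosity": reference, "side": side,
                         "response_more": pd.NA, "responded": False})
            continue  # trial re-queued: does not count toward n_trials
        resp = bool(rng.random() < _p_more(test, true_pse, sigma))
        rows.append({"condition": condition, "test_numerosity": test,
                     "reference_numerosity": reference, "side": side,
                     "response_more": resp, "responded": True})
        answered += 1
        if placement == "staircase":
            j = int(np.where(levels == test)[0][0])
            post = post * (pml[..., j] if resp else 1 - pml[..., j])
            post /= post.sum()
    return pd.DataFrame(rows)


class PsychometricModel(BaseEstimator):
    """Cumulative-Gaussian psychometric function Phi((x - pse) / sigma).

    ``method="ml"`` (default) maximises the Bernoulli likelihood over the
    raw trials; ``method="ls_binned"`` least-squares fits the proportion
    judged more numerous per test-numerosity bin (the two agree closely on
    large samples).  No lapse-rate parameter is modelled.

    Attributes (after fit): ``pse_``, ``sigma_``, ``deviance_``,
    ``separation_flag_`` (True when responses are perfectly separable and
    sigma collapsed to its lower bound), ``pse_in_range_``.
    """

    def __init__(self, method: str = "ml"):
        self.method = method

    def fit(self, x, y) -> "PsychometricModel":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) != len(y):
            raise ValueError("x and y must have equal length")
        levels = np.unique(x)
        if len(levels) < 3:
            raise ValueError("need responses at >= 3 distinct test levels")
        # moment-based init from binned proportions
        props = np.array([y[x == l].mean() for l in levels])
        mu0 = float(np.interp(0.5, np.clip(props, 1e-3, 1 - 1e-3), levels))
        sig0 = max(0.5, (levels.max() - levels.min()) / 4)

        if self.method == "ml":
            def nll(theta):
                mu, log_sig = theta
                p = np.clip(_p_more(x, mu, np.exp(log_sig)), 1e-9, 1 - 1e-9)
                return -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))

            res = scipy.optimize.minimize(
                nll, [mu0, np.log(sig0)], method="L-BFGS-B",
                bounds=[(levels.min() - 10, levels.max() + 10),
                        (np.log(_SIGMA_BOUNDS[0]), np.log(_SIGMA_BOUNDS[1]))],
            )
            self.pse_ = float(res.x[0])
            self.sigma_ = float(np.exp(res.x[1]))
            self.deviance_ = float(2 * res.fun)
        elif self.method == "ls_binned":
            counts = np.array([np.sum(x == l) for l in levels])

            def ssq(theta):
                mu, log_sig = theta
                return np.sum(counts * (props - _p_more(levels, mu, np.exp(log_sig))) ** 2)

            res = scipy.optimize.minimize(
                ssq, [mu0, np.log(sig0)], method="Nelder-Mead")
            self.pse_ = float(res.x[0])
            self.sigma_ = float(np.exp(res.x[1]))
            self.deviance_ = float(res.fun)
        else:
            raise ValueError(f"unknown method {self.method!r}")

        self.separation_flag_ = self.sigma_ <= _SIGMA_BOUNDS[0] * 1.001
        self.pse_in_range_ = bool(levels.min() <= self.pse_ <= levels.max())
        if not self.pse_in_range_:
            warnings.warn("fitted PSE lies outside the tested numerosity range",
                          RuntimeWarning, stacklevel=2)
        return self

    def predict_proba(self, x) -> np.ndarray:
        return _p_more(x, self.pse_, self.sigma_)


def fit_psychometric(trials: pd.DataFrame, method: str = "ml") -> PsychometricModel:
    """Fit the psychometric function to one condition's answered trials."""
    t = trials.loc[trials["responded"].astype(bool)]
    return PsychometricModel(method=method).fit(
        t["test_numerosity"].to_numpy(dtype=float),
        t["response_more"].to_numpy(dtype=float),
    )


def compare_pse(fits: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Paired comparisons of PSEs across the three adaptor conditions.

    ``fits`` has columns participant, condition, pse.  For each of the
    three condition pairs: a Shapiro-Wilk normality check on the paired
    differences, a two-sided paired t-test, and a Bonferroni correction
    (x3, clipped at 1).  Participants missing a condition are dropped from
    the affected pairs.
    """
    wide = fits.pivot(index="participant", columns="condition", values="pse")
    pairs = list(combinations(BEHAVIOR_CONDITIONS, 2))
    rows = []
    for a, b in pairs:
        if a not in wide.columns or b not in wide.columns:
            raise ValueError(f"missing condition {a if a not in wide.columns else b!r}")
        sub = wide[[a, b]].dropna()
        n = len(sub)
        if n < 3:
            raise ValueError(
                f"paired comparison {a} vs {b} needs >= 3 complete participants"
            )
        diff = (sub[a] - sub[b]).to_numpy()
        if np.allclose(diff, diff[0]) and np.allclose(diff, 0):
            t_stat, p = 0.0, 1.0
            sw_p = float("nan")
        else:
            sw_p = float(scipy.stats.shapiro(diff).pvalue) if len(np.unique(diff)) > 1 else float("nan")
            t_stat, p = scipy.stats.ttest_rel(sub[a], sub[b])
        rows.append({
            "condition_a": a,
            "condition_b": b,
            "n": n,
            "mean_diff": float(np.mean(diff)),
            "direction": "a>b" if np.mean(diff) > 0 else ("a<b" if np.mean(diff) < 0 else "a=b"),
            "shapiro_p": sw_p,
            "t": float(t_stat),
            "p": float(p),
            "p_bonferroni": float(min(1.0, p * len(pairs))),
        })
    out = pd.DataFrame(rows)
    out["significant"] = out["p_bonferroni"] < alpha
    return out
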