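"""Critical spacing and crowding anisotropy from 4AFC trial tables.

Proportion correct per target-to-flanker spacing is fitted with a
maximum-likelihood cumulative-Weibull psychometric function,

    p(s) = gamma + (1 - gamma - lambda) * (1 - exp(-(s / theta)**beta)),

with guess rate gamma fixed at 0.25 (4AFC) and a small fixed lapse rate
lambda.  The critical spacing is the spacing at which the fitted function
reaches 68% correct; thresholds outside the tested spacing range are
flagged, never extrapolated.  Per training day, the radial and tangential
critical spacings C_r and C_t (averaged over that day's sub-block
estimates) combine into the crowding anisotropy index

    C_a = (C_r - C_t) / (C_r + C_t),

which is scale-invariant and lies in [-1, 1] for positive inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

GUESS_4AFC = 0.25
DEFAULT_LAPSE = 0.01
CRITERION = 0.68


@dataclass
class PsychometricFit:
    threshold: float      # Weibull scale theta (degrees)
    slope: float          # Weibull shape beta
    guess: float
    lapse: float
    method: str           # "weibull_ml" | "isotonic"
    converged: bool
    levels: np.ndarray
    n: np.ndarray
    k: np.ndarray
    # isotonic fallback keeps the monotone proportions for interpolation
    iso_props: np.ndarray | None = None

    def predict(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, float)
        if self.method == "isotonic":
            return np.interp(s, self.levels, self.iso_props)
        f = 1.0 - np.exp(-((s / self.threshold) ** self.slope))
        return self.guess + (1.0 - self.guess - self.lapse) * f


@dataclass
class CriticalSpacing:
    value: float          # NaN when undefined/out of range
    criterion: float
    flag: str             # "ok" | "out_of_range" | "undefined"


def proportion_correct(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-spacing trial counts and proportion correct.

    ``trials`` must already be sliced to one subject/day/orientation group
    and carry boolean ``correct`` values.
    """
    if len(trials) == 0:
        raise ValueError("empty trial group")
    g = trials.groupby("spacing")["correct"]
    out = pd.DataFrame(
        {"n": g.size(), "k": g.sum().astype(int)}
    ).reset_index()
    out["prop"] = out["k"] / out["n"]
    return out


def _nll(params: np.ndarray, s, n, k, guess, lapse) -> float:
    theta, beta = np.exp(params)
    f = 1.0 - np.exp(-((s / theta) ** beta))
    p = guess + (1.0 - guess - lapse) * f
    p = np.clip(p, 1e-9, 1.0 - 1e-9)
    return -float(np.sum(k * np.log(p) + (n - k) * np.log(1.0 - p)))


def fit_psychometric(
    props: pd.DataFrame,
    guess: float = GUESS_4AFC,
    lapse: float = DEFAULT_LAPSE,
) -> PsychometricFit:
    """Maximum-likelihood Weibull fit of proportion-correct data.

    Falls back to isotonic (monotone) interpolation of the observed
    proportions when the ML fit fails or lands absurdly far outside the
    data range (no admissible fit).
    """
    if len(props) < 3:
        raise ValueError("need at least 3 spacing levels")
    s = props["spacing"].to_numpy(float)
    n = props["n"].to_numpy(float)
    k = props["k"].to_numpy(float)
    order = np.argsort(s)
    s, n, k = s[order], n[order], k[order]

    x0 = np.log([np.median(s), 2.0])
    res = optimize.minimize(
        _nll, x0, args=(s, n, k, guess, lapse), method="Nelder-Mead",
        options={"maxiter": 500, "xatol": 1e-6, "fatol": 1e-9},
    )
    theta, beta = np.exp(res.x)
    admissible = np.isfinite(theta) and 0 < theta < 100 * s.max() and beta > 0
    if admissible:
        return PsychometricFit(
            float(theta), float(beta), guess, lapse, "weibull_ml",
            bool(res.success), s, n, k,
        )
    from sklearn.isotonic import IsotonicRegression

    iso = IsotonicRegression(y_min=0.0, y_max=1.0).fit_transform(s, k / n)
    return PsychometricFit(
        np.nan, np.nan, guess, lapse, "isotonic", False, s, n, k, iso_props=iso
    )


def critical_spacing(
    fit: PsychometricFit, criterion: float = CRITERION
) -> CriticalSpacing:
    """Spacing at which the fitted function reaches the criterion.

    The Weibull inverse is closed-form:
    s = theta * (-log(1 - F))**(1/beta) with
    F = (criterion - guess) / (1 - guess - lapse).  Values outside the
    tested spacing range are flagged ``out_of_range`` with NaN; criteria the
    function cannot attain (at or below the guess floor, or above the
    lapse ceiling) are ``undefined``.
    """
    lo, hi = fit.levels.min(), fit.levels.max()
    if fit.method == "isotonic":
        props = fit.iso_props
        if criterion <= fit.guess or criterion > props.max():
            return CriticalSpacing(np.nan, criterion, "undefined")
        idx = np.searchsorted(props, criterion)
        if idx == 0:
            return CriticalSpacing(np.nan, criterion, "out_of_range")
        x0, x1 = fit.levels[idx - 1], fit.levels[idx]
        y0, y1 = props[idx - 1], props[idx]
        value = x0 if y1 == y0 else x0 + (criterion - y0) * (x1 - x0) / (y1 - y0)
        return CriticalSpacing(float(value), criterion, "ok")
    f_target = (criterion - fit.guess) / (1.0 - fit.guess - fit.lapse)
    if not (0.0 < f_target < 1.0):
        return CriticalSpacing(np.nan, criterion, "undefined")
    value = fit.threshold * (-np.log(1.0 - f_target)) ** (1.0 / fit.slope)
    if not (lo <= value <= hi):
        return CriticalSpacing(np.nan, criterion, "out_of_range")
    return CriticalSpacing(float(value), criterion, "ok")


def critical_spacing_table(
    trials: pd.DataFrame,
    guess: float = GUESS_4AFC,
    lapse: float = DEFAULT_LAPSE,
    criterion: float = CRITERION,
    pool_subblocks: bool = False,
) -> pd.DataFrame:
    """Critical spacing per (subject, day, orientation[, sub_block]).

    By default each sub-block is fitted separately (its estimates are later
    averaged into the daily crowding index); ``pool_subblocks`` fits the
    day's pooled trials instead.
    """
    keys = ["subject", "day", "flanker_orientation"]
    if not pool_subblocks:
        keys = keys + ["sub_block"]
    rows = []
    for key, grp in trials.groupby(keys):
        fit = fit_psychometric(proportion_correct(grp), guess=guess, lapse=lapse)
        cs = critical_spacing(fit, criterion)
        rows.append(dict(zip(keys, key)) | {
            "critical_spacing": cs.value,
            "flag": cs.flag,
            "method": fit.method,
        })
    return pd.DataFrame(rows)


def crowding_indices(cs_table: pd.DataFrame) -> pd.DataFrame:
    """Daily crowding indices per subject: C_r, C_t and C_a.

    C_r / C_t are the mean critical spacings over that day's (sub-block)
    estimates for radial / tangential flankers; C_a = (C_r - C_t)/(C_r + C_t).
    A day missing one orientation yields NaN C_a.
    """
    valid = cs_table[cs_table["flag"] == "ok"]
    piv = (
        valid.groupby(["subject", "day", "flanker_orientation"])["critical_spacing"]
        .mean()
        .unstack("flanker_orientation")
    )
    out = piv.reset_index().rename(
        columns={"radial": "C_r", "tangential": "C_t"}
    )
    for col in ("C_r", "C_t"):
        if col not in out:
            out[col] = np.nan
    out["C_a"] = (out["C_r"] - out["C_t"]) / (out["C_r"] + out["C_t"])
    return out[["subject", "day", "C_r", "C_t", "C_a"]]
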