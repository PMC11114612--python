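"""Inferential statistics: paired t with BCa bootstrap, repeated-measures
ANOVA with Greenhouse-Geisser correction, and effect sizes.

``paired_t_bca`` tests paired differences (d = a - b) with the classic
paired t statistic and attaches a bias-corrected and accelerated (BCa) 95%
bootstrap confidence interval for t, resampling subject-level differences
with replacement (default B = 10,000).  The bias correction z0 is the
normal quantile of the fraction of bootstrap statistics below the observed
one; the acceleration a is the jackknife skewness of the statistic.

``rmanova_gg`` decomposes a complete balanced subject x A x B table into
within-subject sums of squares (each effect tested against its own
subject-by-effect interaction), computes the Greenhouse-Geisser epsilon per
within-subject effect from the covariance of orthonormal contrast scores,
and reports both uncorrected and epsilon-corrected p values together with
partial eta squared.  Shapiro-Wilk and Mauchly checks are attached as
advisory flags only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TestResult:
    t: float
    dof: int
    p: float
    ci_low: float
    ci_high: float
    cohens_d: float
    n: int
    B: int
    seed: int | None
    flags: list[str] = field(default_factory=list)


def cohens_d_paired(diff: np.ndarray) -> float:
    """mean(d) / sd(d) with sample (ddof=1) standard deviation."""
    diff = np.asarray(diff, float)
    sd = diff.std(ddof=1)
    return float(diff.mean() / sd) if sd > 0 else np.nan


def partial_eta_sq(ss_effect: float, ss_error: float) -> float:
    return ss_effect / (ss_effect + ss_error)


def _t_stat(d: np.ndarray) -> float:
    n = d.shape[-1]
    sd = d.std(ddof=1, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return d.mean(axis=-1) / (sd / np.sqrt(n))


def paired_t_bca(
    a: np.ndarray,
    b: np.ndarray,
    B: int = 10_000,
    seed: int | None = None,
    ci_level: float = 0.95,
    bias_correction: bool = True,
    acceleration: bool = True,
) -> TestResult:
    """Paired t-test of a vs b with a BCa bootstrap CI for the t value.

    Swapping the inputs negates t and mirrors the interval.  Degenerate
    inputs: identical pairs give t = 0, p = 1; constant nonzero differences
    give an undefined t, flagged.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("paired samples must share length >= 3")
    d = a - b
    n = d.size
    dof = n - 1
    flags: list[str] = []
    sw_p = sps.shapiro(d).pvalue if np.ptp(d) > 0 else np.nan
    if np.isfinite(sw_p) and sw_p < 0.05:
        flags.append("shapiro_non_normal")

    if d.std(ddof=1) == 0:
        if np.allclose(d, 0):
            return TestResult(0.0, dof, 1.0, 0.0, 0.0, np.nan, n, 0, seed,
                              flags + ["zero_variance"])
        return TestResult(np.nan, dof, np.nan, np.nan, np.nan, np.nan, n, 0,
                          seed, flags + ["zero_variance"])

    t_obs = float(_t_stat(d))
    p = float(2.0 * sps.t.sf(abs(t_obs), dof))

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    with np.errstate(invalid="ignore", divide="ignore"):
        t_boot = _t_stat(d[idx])
    bad = ~np.isfinite(t_boot)
    if bad.any():  # all-identical resamples: push to the matching extreme
        means = d[idx].mean(axis=1)
        t_boot[bad] = np.sign(means[bad]) * np.inf

    alpha = (1.0 - ci_level) / 2.0
    z_lo, z_hi = sps.norm.ppf([alpha, 1.0 - alpha])
    if bias_correction:
        frac = np.clip(np.mean(t_boot < t_obs), 1.0 / (B + 1), 1.0 - 1.0 / (B + 1))
        z0 = sps.norm.ppf(frac)
    else:
        z0 = 0.0
    if acceleration:
        jack = np.array([_t_stat(np.delete(d, i)) for i in range(n)])
        u = jack.mean() - jack
        denom = (u**2).sum() ** 1.5
        acc = float((u**3).sum() / (6.0 * denom)) if denom > 0 else 0.0
    else:
        acc = 0.0
    levels = sps.norm.cdf(
        z0 + (z0 + np.array([z_lo, z_hi])) / (1.0 - acc * (z0 + np.array([z_lo, z_hi])))
    )
    finite = np.where(np.isfinite(t_boot), t_boot,
                      np.nanmax(np.abs(t_boot[np.isfinite(t_boot)])) * 10
                      * np.sign(t_boot))
    ci_low, ci_high = np.quantile(finite, levels)
    return TestResult(
        t_obs, dof, p, float(ci_low), float(ci_high), cohens_d_paired(d), n, B,
        seed, flags,
    )


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast rows (Helmert, normalized)."""
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1.0)
        c[i] /= np.linalg.norm(c[i])
    return c


def _gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from subject x contrast scores.

    epsilon = (sum lambda)^2 / (m * sum lambda^2), with lambda the
    eigenvalues of the contrast-score covariance and m the number of
    contrasts; equals 1 exactly when m = 1.
    """
    m = scores.shape[1]
    if m == 1:
        return 1.0
    S = np.cov(scores, rowvar=False)
    lam = np.linalg.eigvalsh(S)
    lam = np.clip(lam, 0, None)
    denom = m * (lam**2).sum()
    return float(lam.sum() ** 2 / denom) if denom > 0 else 1.0


def mauchly_pvalue(scores: np.ndarray) -> float:
    """Mauchly sphericity test on subject x contrast scores (chi2 approx)."""
    n, m = scores.shape
    if m < 2 or n <= m:
        return np.nan
    S = np.cov(scores, rowvar=False)
    lam = np.clip(np.linalg.eigvalsh(S), 1e-300, None)
    W = np.prod(lam) / (lam.mean() ** m)
    df = m * (m + 1) // 2 - 1
    f = 1.0 - (2.0 * m**2 + m + 2.0) / (6.0 * m * (n - 1))
    chi2 = -(n - 1) * f * np.log(W)
    return float(sps.chi2.sf(chi2, df))


@dataclass
class AnovaResult:
    table: pd.DataFrame          # one row per effect
    factor_names: tuple[str, str]
    flags: dict = field(default_factory=dict)

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]


def rmanova_gg(
    data: np.ndarray, factor_names: tuple[str, str] = ("A", "B")
) -> AnovaResult:
    """Two-way repeated-measures ANOVA on an (n_subjects, a, b) array.

    Both factors are within-subject; missing cells are not allowed.  For a
    2-level factor the F statistic equals the squared paired t on the level
    difference and epsilon is exactly 1.
    """
    data = np.asarray(data, float)
    if data.ndim != 3:
        raise ValueError("data must be (n_subjects, a_levels, b_levels)")
    if np.isnan(data).any():
        raise ValueError("missing cells are not supported")
    n, a, b = data.shape
    if n < 2 or a < 2 or b < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels per factor")
    g = data.mean()
    m_s = data.mean(axis=(1, 2))
    m_a = data.mean(axis=(0, 2))
    m_b = data.mean(axis=(0, 1))
    m_ab = data.mean(axis=0)
    m_sa = data.mean(axis=2)
    m_sb = data.mean(axis=1)

    ss_a = n * b * ((m_a - g) ** 2).sum()
    ss_b = n * a * ((m_b - g) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + g) ** 2).sum()
    ss_s = a * b * ((m_s - g) ** 2).sum()
    ss_sa = b * ((m_sa - m_a[None, :] - m_s[:, None] + g) ** 2).sum()
    ss_sb = a * ((m_sb - m_b[None, :] - m_s[:, None] + g) ** 2).sum()
    ss_tot = ((data - g) ** 2).sum()
    ss_sab = ss_tot - ss_a - ss_b - ss_ab - ss_s - ss_sa - ss_sb

    ca = _orthonormal_contrasts(a)
    cb = _orthonormal_contrasts(b)
    cells = data.reshape(n, a * b)
    scores = {
        factor_names[0]: m_sa @ ca.T,
        factor_names[1]: m_sb @ cb.T,
        f"{factor_names[0]}*{factor_names[1]}": cells @ np.kron(ca, cb).T,
    }
    specs = [
        (factor_names[0], ss_a, a - 1, ss_sa, (a - 1) * (n - 1)),
        (factor_names[1], ss_b, b - 1, ss_sb, (b - 1) * (n - 1)),
        (f"{factor_names[0]}*{factor_names[1]}", ss_ab, (a - 1) * (b - 1),
         ss_sab, (a - 1) * (b - 1) * (n - 1)),
    ]
    rows = []
    flags = {}
    for name, ss_e, df_e, ss_err, df_err in specs:
        F = (ss_e / df_e) / (ss_err / df_err)
        eps = _gg_epsilon(scores[name])
        rows.append(
            {
                "effect": name,
                "ss_effect": ss_e,
                "ss_error": ss_err,
                "df_num": df_e,
                "df_den": df_err,
                "F": F,
                "p": float(sps.f.sf(F, df_e, df_err)),
                "gg_epsilon": eps,
                "df_num_gg": eps * df_e,
                "df_den_gg": eps * df_err,
                "p_gg": float(sps.f.sf(F, eps * df_e, eps * df_err)),
                "partial_eta_sq": partial_eta_sq(ss_e, ss_err),
            }
        )
        flags[f"mauchly_p_{name}"] = mauchly_pvalue(scores[name])
    return AnovaResult(pd.DataFrame(rows), factor_names, flags)
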