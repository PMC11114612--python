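"""Block-design GLM for the crowding-stimulus localizer (tROI definition).

The boxcar design (fixation = 0, stimulation = 1) is convolved with the
canonical HRF and regressed against every voxel's time series with an
intercept.  Stimulation-responsive voxels are retained at p <= 0.001
(boundary inclusive) with a positive stimulation beta, mirroring a
stimulation > fixation contrast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .hemodynamics import HRFSpec, convolve_bold

P_THRESHOLD = 0.001


def block_glm_tmap(
    observed: np.ndarray,
    design: np.ndarray,
    hrf: HRFSpec,
    tr: float,
    drift: bool = False,
) -> pd.DataFrame:
    """Per-voxel OLS t-map for a block design.

    Parameters
    ----------
    observed : (n_voxels, n_samples) BOLD matrix at TR resolution.
    design : boxcar sampled at TR (0/1), convolved here with the HRF.
    drift : include a linear-drift nuisance column.

    Returns a frame with columns voxel, beta_stim, t, p (two-sided), dof.
    """
    observed = np.atleast_2d(np.asarray(observed, float))
    design = np.asarray(design, float)
    n = design.size
    if observed.shape[1] != n:
        raise ValueError("observed and design lengths differ")
    if np.ptp(design) == 0:
        raise ValueError("design is constant; regressor degenerate")
    reg = convolve_bold(design, hrf, tr, frame_duration=tr)
    if np.ptp(reg) == 0:
        raise ValueError("convolved design regressor is constant")
    cols = [np.ones(n), reg]
    if drift:
        cols.append(np.linspace(-1, 1, n))
    X = np.column_stack(cols)
    dof = n - X.shape[1]
    XtX_inv = np.linalg.inv(X.T @ X)
    betas = observed @ X @ XtX_inv.T  # (n_vox, n_params)
    resid = observed - betas @ X.T
    sigma2 = (resid**2).sum(axis=1) / dof
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, betas[:, 1] / se, np.inf * np.sign(betas[:, 1]))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "voxel": np.arange(observed.shape[0]),
            "beta_stim": betas[:, 1],
            "t": t,
            "p": p,
            "dof": dof,
        }
    )


def threshold_rois(glm: pd.DataFrame, p_max: float = P_THRESHOLD) -> pd.DataFrame:
    """Voxels with p <= p_max (inclusive) and positive stimulation beta."""
    return glm[(glm["p"] <= p_max) & (glm["beta_stim"] > 0)]
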