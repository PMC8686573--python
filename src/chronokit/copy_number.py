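"""Post-hoc removal of copy-number bias from a gene-effect matrix.

CRISPR cutting toxicity depletes guides targeting amplified loci regardless
of the targeted gene, while high copy number of a truly essential gene
attenuates knockout and pulls its score up — the copy-number response
depends on both the copy number and the gene's mean effect, and is
non-monotone for essentials.  Rather than modeling the mechanism, the bias
is captured by a two-dimensional tensor-product cubic B-spline surface over
(copy number, mean gene effect), scaled per cell line by a weight
``w_c in (0, 1]``:

    y_cg = w_c * sum_k theta_k B_k(cn_cg, mean_g)

fitted by minimizing ``sum (r_cg - y_cg)^2 + X_w sum (ln w_c)^2`` with
alternating linear least squares (theta) and bounded scalar updates (w_c).
The residuals ``r_cg - y_cg`` are the corrected gene effects.  At least
three cell lines are required so the mean gene effect is meaningful.

Two refinements keep the removed surface a *bias*, not biology: the spline
is referenced to normal ploidy (``y = 0`` wherever ``cn = 1`` in log2(x+1)
units), and a separate smooth baseline in the mean-effect axis is fitted
alongside it so that the trivially strong dependence of scores on their own
gene mean is absorbed by the baseline instead of being subtracted.  Without
these, least squares would happily explain every gene's mean through the
effect axis and the "correction" would strip real signal even when scores
are independent of copy number.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import minimize_scalar

from .screen_data import GeneEffectMatrix, align_copy_number

logger = logging.getLogger("chronokit")

N_CN_KNOTS = 10
N_EFFECT_KNOTS = 5
SPLINE_DEGREE = 3
DEFAULT_X_W = 0.01
W_LOWER = 1e-3


def place_knots(
    cn_values: np.ndarray, gene_means: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Knot positions for the two spline axes.

    Copy-number knots: 10, linearly spaced over the observed range.  Effect
    knots: 5, exponentially spaced after shifting the axis so the first
    percentile of mean gene effects maps to 1 — strong negative effects,
    where the copy-number response changes fastest, get the densest coverage.
    """
    cn_values = np.asarray(cn_values, dtype=float).ravel()
    gene_means = np.asarray(gene_means, dtype=float).ravel()
    lo, hi = np.nanmin(cn_values), np.nanmax(cn_values)
    if not np.isfinite(lo) or hi <= lo:
        raise ValueError("copy number values are degenerate; cannot place knots")
    knots_cn = np.linspace(lo, hi, N_CN_KNOTS)

    e_lo, e_hi = np.nanmin(gene_means), np.nanmax(gene_means)
    if not np.isfinite(e_lo) or e_hi <= e_lo:
        raise ValueError(
            "mean gene effects are all equal; the effect axis is degenerate"
        )
    shift = 1.0 - np.nanquantile(gene_means, 0.01)
    lo_s = max(e_lo + shift, 1e-6)
    hi_s = e_hi + shift
    knots_effect = np.geomspace(lo_s, hi_s, N_EFFECT_KNOTS) - shift
    return knots_cn, knots_effect


def _axis_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Clamped cubic B-spline design matrix for one axis; inputs are clipped
    to the knot range so boundary basis functions absorb out-of-range points."""
    t = np.r_[[knots[0]] * SPLINE_DEGREE, knots, [knots[-1]] * SPLINE_DEGREE]
    x = np.clip(x, knots[0], knots[-1])
    # nudge the right boundary inside the half-open support of the last basis
    x = np.minimum(x, knots[-1] - 1e-12 * max(1.0, abs(knots[-1])))
    return BSpline.design_matrix(x, t, SPLINE_DEGREE).toarray()


#: copy number (log2(x+1)) of normal ploidy; the bias surface is pinned to 0 here
NORMAL_PLOIDY_CN = 1.0


@dataclasses.dataclass
class CNSplineModel:
    """Fitted 2D spline bias model.

    The bias surface is the tensor-product spline referenced to normal
    ploidy, ``D(cn, m) = S(cn, m) - S(1, m)``, so it vanishes where copy
    number is normal; a separate unpenalized 1D baseline in the mean-effect
    axis absorbs the (biological) dependence of scores on mean gene effect
    and is *not* part of the removed bias.
    """

    theta: np.ndarray  # tensor-product coefficients of S
    theta_baseline: np.ndarray  # 1D mean-effect baseline coefficients
    knots_cn: np.ndarray
    knots_effect: np.ndarray
    weights: pd.Series  # w_c per cell line, in (0, 1]
    fitted_bias: pd.DataFrame  # y_cg = w_c * D(cn_cg, mean_g) on the training matrix
    cost_history: list

    def predict(self, cn: pd.DataFrame, gene_means: pd.Series) -> pd.DataFrame:
        """Evaluate the removed bias w_c * D(cn, mean) on a line x gene grid."""
        means = gene_means.reindex(cn.columns).to_numpy(dtype=float)
        B = _tensor_design(cn.to_numpy(dtype=float), means, self.knots_cn, self.knots_effect)
        B_ref = _tensor_design(
            np.full(cn.shape, NORMAL_PLOIDY_CN), means, self.knots_cn, self.knots_effect
        )
        surf = ((B - B_ref) @ self.theta).reshape(cn.shape)
        w = self.weights.reindex(cn.index).to_numpy(dtype=float)[:, None]
        return pd.DataFrame(surf * w, index=cn.index, columns=cn.columns)


def _tensor_design(
    cn: np.ndarray, gene_means: np.ndarray, knots_cn, knots_effect
) -> np.ndarray:
    """Row-wise tensor product basis over flattened (line, gene) points."""
    n_lines, n_genes = cn.shape
    cn_flat = cn.ravel()
    eff_flat = np.tile(gene_means, n_lines)
    B_cn = _axis_design(cn_flat, np.asarray(knots_cn, dtype=float))
    B_eff = _axis_design(eff_flat, np.asarray(knots_effect, dtype=float))
    return (B_cn[:, :, None] * B_eff[:, None, :]).reshape(len(cn_flat), -1)


def fit_cn_model(
    gene_effect: GeneEffectMatrix | pd.DataFrame,
    copy_number: pd.DataFrame,
    x_w: float = DEFAULT_X_W,
    max_rounds: int = 100,
    tol: float = 1e-6,
    n_mean_updates: int = 3,
) -> CNSplineModel:
    """Fit the per-line-weighted 2D spline bias surface.

    Copy number is clipped to its [0.1, 99.9] percentile range before basis
    evaluation to stabilize the edges; genes absent from the copy-number
    matrix are imputed to normal ploidy (1 in log2(x+1) units).

    The effect axis should reflect the *biological* mean gene effect, but
    only biased means are observable before correction; ``n_mean_updates``
    outer passes therefore refit the original matrix with gene means
    re-estimated from the previous pass's residuals.
    """
    frame = getattr(gene_effect, "data", gene_effect)
    if frame.shape[0] < 3:
        raise ValueError(
            "copy number correction requires at least three cell lines to "
            "estimate mean gene effects"
        )
    cn = align_copy_number(copy_number, frame.index, frame.columns)
    cn_arr = cn.to_numpy(dtype=float)
    lo, hi = np.nanpercentile(cn_arr, [0.1, 99.9])
    cn_arr = np.clip(cn_arr, lo, hi)

    gene_means = frame.mean(axis=0, skipna=True)
    model = None
    for _ in range(max(1, n_mean_updates)):
        model = _fit_single(frame, cn_arr, gene_means, x_w, max_rounds, tol)
        gene_means = (frame - model.fitted_bias).mean(axis=0, skipna=True)
    return model


def _fit_single(
    frame: pd.DataFrame,
    cn_arr: np.ndarray,
    gene_means: pd.Series,
    x_w: float,
    max_rounds: int,
    tol: float,
) -> CNSplineModel:
    knots_cn, knots_effect = place_knots(cn_arr, gene_means.to_numpy())
    means_arr = gene_means.to_numpy()
    B_full = _tensor_design(cn_arr, means_arr, knots_cn, knots_effect)
    B_ref = _tensor_design(
        np.full(cn_arr.shape, NORMAL_PLOIDY_CN), means_arr, knots_cn, knots_effect
    )
    B_D = B_full - B_ref  # bias basis, exactly 0 at normal ploidy
    n_lines, n_genes = frame.shape
    B_h = np.tile(_axis_design(means_arr, knots_effect), (n_lines, 1))  # baseline
    r = frame.to_numpy(dtype=float).ravel()
    ok = np.isfinite(r)
    line_of_point = np.repeat(np.arange(n_lines), n_genes)

    w = np.ones(n_lines)
    n_h, n_d = B_h.shape[1], B_D.shape[1]
    theta_h = np.zeros(n_h)
    theta = np.zeros(n_d)
    history: list[float] = []
    prev = np.inf

    def _solve(design, target):
        sol, *_ = np.linalg.lstsq(design, target, rcond=None)
        if not np.all(np.isfinite(sol)):
            logger.warning("singular spline basis; adding ridge jitter 1e-8")
            gram = design.T @ design + 1e-8 * np.eye(design.shape[1])
            sol = np.linalg.solve(gram, design.T @ target)
        return sol

    for round_ in range(max_rounds):
        # theta step: joint linear least squares for baseline + weighted bias
        design = np.hstack([B_h[ok], B_D[ok] * w[line_of_point[ok], None]])
        sol = _solve(design, r[ok])
        theta_h, theta = sol[:n_h], sol[n_h:]
        f = B_D @ theta  # unweighted bias at each point
        baseline = B_h @ theta_h

        # w step: bounded scalar problem per line against the de-baselined target
        for c in range(n_lines):
            sel = ok & (line_of_point == c)
            fc, rc = f[sel], r[sel] - baseline[sel]

            def obj(wc, fc=fc, rc=rc):
                return np.sum((rc - wc * fc) ** 2) + x_w * np.log(wc) ** 2

            res = minimize_scalar(obj, bounds=(W_LOWER, 1.0), method="bounded")
            w[c] = float(res.x)

        resid = r[ok] - baseline[ok] - w[line_of_point[ok]] * f[ok]
        cost = float(np.sum(resid**2) + x_w * np.sum(np.log(w) ** 2))
        history.append(cost)
        if prev - cost < tol * max(abs(prev), 1.0):
            break
        prev = cost

    fitted = pd.DataFrame(
        (w[line_of_point] * f).reshape(n_lines, n_genes),
        index=frame.index,
        columns=frame.columns,
    )
    return CNSplineModel(
        theta=theta,
        theta_baseline=theta_h,
        knots_cn=knots_cn,
        knots_effect=knots_effect,
        weights=pd.Series(w, index=frame.index),
        fitted_bias=fitted,
        cost_history=history,
    )


def correct_copy_number(
    gene_effect: GeneEffectMatrix | pd.DataFrame,
    copy_number: pd.DataFrame,
    x_w: float = DEFAULT_X_W,
) -> tuple[GeneEffectMatrix, CNSplineModel]:
    """Remove the fitted copy-number bias; returns residuals and the model.

    The residuals ``r_cg - y_cg`` keep the input's scale (mean gene effects
    are approximately, not exactly, preserved).
    """
    frame = getattr(gene_effect, "data", gene_effect)
    model = fit_cn_model(frame, copy_number, x_w=x_w)
    corrected = frame - model.fitted_bias
    return GeneEffectMatrix(data=corrected, normalization="cn_corrected"), model
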