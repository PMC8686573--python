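"""Two-population growth model, NB2 readcount likelihood, and regularizers.

The generative picture: introducing sgRNA ``j`` (targeting gene ``g``) into
cell line ``c`` splits the infected population in two.  A fraction
``p_c * p_j`` achieves functional knockout and grows at the perturbed rate
``R_c (1 + r_cg)``; the rest keeps the unperturbed rate ``R_c``.  After the
phenotype-onset delay ``d_g`` the predicted relative sgRNA abundance is

    Z_cj(t) = nu_cj(0) * (1 + p_c p_j (exp(R_c r_cg (t - d_g)) - 1))
    nu_cj(t) = Z_cj(t) / sum_j Z_cj(t)

with ``Z_cj(t) = nu_cj(0)`` for ``t < d_g``.  Unperturbed-rate factors common
to both subpopulations cancel in the normalization, which is why ``r_cg``
(the fractional change in growth rate, per day with ``R_c`` constrained to
mean 1) is the only growth quantity that survives.

Observed readcounts are scored against predictions with the NB2 negative
binomial likelihood (variance ``mu + alpha mu^2``), keeping only
``mu``-dependent terms and shifting so the cost is exactly zero when the
observation equals the prediction.  Counts enter as reads per million, so
the cost is invariant to sequencing depth of a replicate.

The training objective adds five regularizers (see the ``penalty_*``
functions); :class:`CostEngine` evaluates the core cost and its analytic
gradients with respect to every free parameter on a fixed screen layout.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .preprocess import normalize_rpm
from .screen_data import ScreenData

logger = logging.getLogger("chronokit")

#: exponent clip guarding exp() against runaway parameters
EXPONENT_CLIP = 50.0
#: lower floor for the two-population mixture factor 1 + p(e^x - 1); the
#: exponent clip already bounds e^x >= e^-50, so this only guards exact zeros
MIXTURE_FLOOR = 1e-30


@dataclasses.dataclass
class Hyperparameters:
    """Every tunable constant of the model and optimizer, with defaults.

    Regularization weights: ``chi_rho`` (pDNA offsets), ``chi_p`` (top-2
    guide efficacy), ``chi_R`` (growth rates), ``chi_r1`` (global gene-effect
    mean), ``chi_h``/``chi_k``/``sigma`` (hierarchical kernel; ``sigma`` in
    gene-rank units).  ``d_g`` is the phenotype-onset delay in days.
    ``alpha_global`` is the NB2 overdispersion used when no per-line table is
    supplied.  The remaining fields control the optimizer schedule.
    """

    chi_rho: float = 1.0
    chi_p: float = 0.5
    chi_R: float = 0.01
    chi_r1: float = 0.1
    chi_h: float = 0.1
    chi_k: float = 0.25
    sigma: float = 5.0
    d_g: float = 3.0
    alpha_global: float = 0.05
    cell_efficacy_percentile: float = 0.99
    cell_efficacy_floor: float = 0.01
    time_scale: float = 0.1
    cost_rescale_target: float = 0.67
    lr_max: float = 0.02
    lr_initial: float = 1e-4
    burn_in_epochs: int = 50
    gene_effect_only_epochs: int = 100
    epochs: int = 801
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999

    def __post_init__(self) -> None:
        numeric = {
            f.name: getattr(self, f.name) for f in dataclasses.fields(self)
        }
        for name, value in numeric.items():
            if value <= 0:
                raise ValueError(f"hyperparameter {name} must be positive, got {value}")


@dataclasses.dataclass
class ModelParameters:
    """All free and fixed parameters of a fit.

    ``rho``: pDNA-batch x sgRNA initial-abundance offsets (log units, free;
    mean 0 over each gene's guides within a batch).
    ``guide_efficacy`` p_j in (0, 1] (free); ``cell_efficacy`` p_c in (0, 1]
    per (cell line, library) (fixed after direct estimation);
    ``growth_rate`` R_c > 0, mean 1 per library (free);
    ``gene_mean`` + ``delta`` decompose the gene effect r_cg (free);
    ``d_g`` delay in days and ``alpha`` overdispersion are fixed inputs.
    """

    rho: pd.DataFrame
    guide_efficacy: pd.Series
    cell_efficacy: pd.Series
    growth_rate: pd.Series
    gene_mean: pd.Series
    delta: pd.DataFrame
    guide_map: pd.Series  # sgRNA -> gene
    d_g: float = 3.0
    alpha: pd.Series | float = 0.05

    @property
    def gene_effect(self) -> pd.DataFrame:
        """r_cg = gene_mean_g + delta_cg, cell line x gene (per day)."""
        return self.delta.add(self.gene_mean, axis=1)

    def per_line(self, series: pd.Series) -> pd.Series:
        """Collapse a per-(line, library) series to per-line (single library)."""
        if isinstance(series.index, pd.MultiIndex):
            lines = series.index.get_level_values(0)
            if lines.duplicated().any():
                raise ValueError(
                    "per-line access is ambiguous with multiple libraries per line"
                )
            return pd.Series(series.to_numpy(), index=lines)
        return series

    def alpha_for(self, condition) -> float:
        if isinstance(self.alpha, pd.Series):
            return float(self.alpha.loc[condition])
        return float(self.alpha)


def center_rho(rho: pd.DataFrame, guide_map: pd.Series) -> pd.DataFrame:
    """Project rho to mean 0 over each gene's guide set, per batch."""
    genes = guide_map.reindex(rho.columns)
    means = rho.T.groupby(genes).transform("mean").T
    return rho - means


@dataclasses.dataclass
class PredictedAbundance:
    """Model-predicted relative sgRNA abundances on a (time, line, guide) grid."""

    days: np.ndarray
    cell_lines: pd.Index
    guides: pd.Index
    Z: np.ndarray  # unnormalized, shape (T, L, J)
    nu: np.ndarray  # rows sum to 1 over guides

    def frame(self, day: float) -> pd.DataFrame:
        t = int(np.nonzero(np.isclose(self.days, day))[0][0])
        return pd.DataFrame(self.nu[t], index=self.cell_lines, columns=self.guides)


def pdna_medians(data: ScreenData) -> pd.DataFrame:
    """Median measured relative abundance of each sgRNA per pDNA batch.

    Each pDNA sequence is converted to relative abundance (its row normalized
    to sum 1 over unmasked guides); the per-batch value is the median across
    that batch's pDNA sequences.  A guide with zero abundance in every
    measurement of a batch cannot seed the dynamics and raises an error.
    """
    pdna = data.pdna_map
    rel = normalize_rpm(data.counts.loc[pdna["sequence_ID"]]) / 1e6
    batches = pdna.set_index("sequence_ID")["pDNA_batch"].reindex(rel.index)
    med = rel.groupby(batches.to_numpy()).median()
    med.index.name = "pDNA_batch"
    zero = med.columns[(med.fillna(0.0) <= 0).any(axis=0)]
    if len(zero):
        raise ValueError(
            "sgRNAs with zero pDNA abundance in all measurements of a batch "
            f"cannot seed the dynamics: {zero[:5].tolist()}"
        )
    return med


def initial_abundance(data: ScreenData, rho: pd.DataFrame | None = None) -> pd.DataFrame:
    """nu(0): per-batch pDNA medians scaled by exp(rho), rho centered per gene."""
    med = pdna_medians(data)
    if rho is None:
        return med
    rho = center_rho(rho.reindex(index=med.index, columns=med.columns).fillna(0.0),
                     data.guide_genes())
    return med * np.exp(rho)


def _mixture_factors(
    pc: np.ndarray,
    pj: np.ndarray,
    exponent: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-population factor 1 + p_c p_j (e^x - 1) with overflow/underflow guards.

    Returns (factor, E, clipped) where ``E = exp(clip(x))`` and ``clipped``
    marks entries where either the exponent clip or the mixture floor was
    active (their gradients are zeroed).
    """
    clipped_exp = np.abs(exponent) >= EXPONENT_CLIP
    if clipped_exp.any():
        logger.warning(
            "clipping %d growth exponents at ±%g; parameters may be running away",
            int(clipped_exp.sum()),
            EXPONENT_CLIP,
        )
    E = np.exp(np.clip(exponent, -EXPONENT_CLIP, EXPONENT_CLIP))
    q = pc * pj
    factor = 1.0 + q * (E - 1.0)
    floored = factor < MIXTURE_FLOOR
    factor = np.maximum(factor, MIXTURE_FLOOR)
    return factor, E, clipped_exp | floored


def predicted_abundance(
    params: ModelParameters,
    nu0: pd.DataFrame | pd.Series,
    days,
) -> PredictedAbundance:
    """Forward-predict relative abundances at the given days (in days).

    ``nu0`` is either a per-guide Series (shared across lines) or a cell-line
    x guide DataFrame.  The growth exponent is ``R_c * r_cg * (t - d_g)``
    exactly — internal time rescaling (``time_scale``) multiplies time and
    divides the growth product, so predictions are invariant to it.
    """
    days = np.atleast_1d(np.asarray(days, dtype=float))
    if (days < 0).any():
        raise ValueError("days must be nonnegative")
    lines = params.delta.index
    if isinstance(nu0, pd.Series):
        guides = nu0.index
        nu0_arr = np.tile(nu0.to_numpy(dtype=float), (len(lines), 1))
    else:
        guides = nu0.columns
        nu0_arr = nu0.reindex(lines).to_numpy(dtype=float)
    genes = params.guide_map.reindex(guides)
    r = params.gene_effect.reindex(columns=params.gene_mean.index)
    r_guide = r.loc[:, genes.to_numpy()].to_numpy(dtype=float)  # (L, J)
    pc = params.per_line(params.cell_efficacy).reindex(lines).to_numpy(dtype=float)
    R = params.per_line(params.growth_rate).reindex(lines).to_numpy(dtype=float)
    pj = params.guide_efficacy.reindex(guides).to_numpy(dtype=float)

    T, L, J = len(days), len(lines), len(guides)
    Z = np.empty((T, L, J))
    nu = np.empty((T, L, J))
    for ti, t in enumerate(days):
        tau = max(t - params.d_g, 0.0)
        exponent = (R[:, None] * tau) * r_guide
        factor, _, _ = _mixture_factors(pc[:, None], pj[None, :], exponent)
        Zt = nu0_arr * factor
        Z[ti] = Zt
        nu[ti] = Zt / Zt.sum(axis=1, keepdims=True)
    return PredictedAbundance(days=days, cell_lines=lines, guides=guides, Z=Z, nu=nu)


# ---------------------------------------------------------------------------
# NB2 likelihood
# ---------------------------------------------------------------------------

def nb2_negative_log_likelihood(N, mu, alpha):
    """Shifted NB2 negative log likelihood, elementwise.

    lambda(N, mu) = (N + 1/alpha) ln(1 + alpha mu) - N ln(mu); the returned
    value is lambda(N, mu) - lambda(N, N), which is 0 at mu == N and
    nonnegative elsewhere (the N ln(mu) term is taken as 0 for N == 0).
    NaN observations propagate as NaN.
    """
    N = np.asarray(N, dtype=float)
    mu = np.asarray(mu, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("NB2 mean mu must be positive")
    if np.any(alpha <= 0):
        raise ValueError("NB2 overdispersion alpha must be positive")
    with np.errstate(invalid="ignore", divide="ignore"):
        inv_a = 1.0 / alpha
        out = (N + inv_a) * np.log1p(alpha * (mu - N) / (1.0 + alpha * N))
        ratio_term = N * np.log(np.where(N > 0, mu / np.where(N > 0, N, 1.0), 1.0))
        out = out - ratio_term
    if out.ndim == 0:
        return float(out)
    return out


def _nb2_dmu(N, mu, alpha):
    """d/dmu of the shifted NB2 cost (the shift is mu-independent)."""
    return (N * alpha + 1.0) / (1.0 + alpha * mu) - N / mu


# ---------------------------------------------------------------------------
# Cost engine: vectorized core cost and analytic gradients on a screen layout
# ---------------------------------------------------------------------------

class CostEngine:
    """Precomputed index arrays for evaluating the core NB2 cost and its
    gradients over every (replicate, time point, sgRNA) observation.

    Layout is fixed at construction: late sequences (rows), guides (columns),
    pDNA batches, and (cell line, library) conditions.  Parameters are read
    from a :class:`ModelParameters` whose labels must match the data.
    """

    def __init__(self, data: ScreenData, d_g: float = 3.0):
        self.d_g = float(d_g)
        self.guides = data.counts.columns
        genes_of_guides = data.guide_genes()
        self.genes = pd.Index(sorted(genes_of_guides.unique()))
        self.gene_codes = self.genes.get_indexer(genes_of_guides)

        late = data.replicate_map.reset_index(drop=True)
        self.sequence_ids = late["sequence_ID"].to_numpy()
        self.lines = pd.Index(sorted(late["cell_line_name"].unique()))
        self.line_idx = self.lines.get_indexer(late["cell_line_name"])
        cond = pd.MultiIndex.from_frame(late[["cell_line_name", "library"]])
        self.conditions = cond.unique().sortlevel()[0]
        self.cond_idx = self.conditions.get_indexer(cond)
        self.batches = pd.Index(sorted(late["pDNA_batch"].unique()))
        self.batch_idx = self.batches.get_indexer(late["pDNA_batch"])
        self.days = late["days"].to_numpy(dtype=float)
        self.tau = np.maximum(self.days - self.d_g, 0.0)

        # observed normalized counts (reads-per-million scale), NaN = masked
        rpm = normalize_rpm(data.counts.loc[self.sequence_ids])
        self.N = rpm.to_numpy(dtype=float)
        self.observed = ~np.isnan(self.N)

        med = pdna_medians(data).reindex(self.batches)
        self.pdna_median = med.to_numpy(dtype=float)
        self.guide_map = genes_of_guides

        # dense guide -> gene one-hot for gradient accumulation
        self._onehot = np.zeros((len(self.guides), len(self.genes)))
        self._onehot[np.arange(len(self.guides)), self.gene_codes] = 1.0

    # -- parameter gathering ---------------------------------------------
    def _gather(self, params: ModelParameters):
        rho = params.rho.reindex(index=self.batches, columns=self.guides)
        nu0_b = self.pdna_median * np.exp(rho.to_numpy(dtype=float))
        pj = params.guide_efficacy.reindex(self.guides).to_numpy(dtype=float)
        pc = params.cell_efficacy.reindex(self.conditions).to_numpy(dtype=float)
        R = params.growth_rate.reindex(self.conditions).to_numpy(dtype=float)
        r = (
            params.gene_effect.reindex(index=self.lines, columns=self.genes)
            .to_numpy(dtype=float)
        )
        if isinstance(params.alpha, pd.Series):
            alpha = params.alpha.reindex(self.conditions).to_numpy(dtype=float)
        else:
            alpha = np.full(len(self.conditions), float(params.alpha))
        return nu0_b, pj, pc, R, r, alpha

    def forward(self, params: ModelParameters):
        nu0_b, pj, pc, R, r, alpha = self._gather(params)
        r_guide = r[:, self.gene_codes]  # (L, J)
        nu0 = nu0_b[self.batch_idx]  # (K, J)
        exponent = (R[self.cond_idx] * self.tau)[:, None] * r_guide[self.line_idx]
        factor, E, clipped = _mixture_factors(
            pc[self.cond_idx][:, None], pj[None, :], exponent
        )
        Z = nu0 * factor
        S = Z.sum(axis=1, keepdims=True)
        nu = Z / S
        mu = 1e6 * nu
        return {
            "nu0": nu0, "factor": factor, "E": E, "clipped": clipped,
            "Z": Z, "S": S, "nu": nu, "mu": mu,
            "pj": pj, "pc": pc, "R": R, "r_guide": r_guide, "alpha": alpha,
        }

    def core_cost(self, params: ModelParameters, state=None) -> float:
        state = state or self.forward(params)
        alpha_k = state["alpha"][self.cond_idx][:, None]
        terms = nb2_negative_log_likelihood(
            np.where(self.observed, self.N, state["mu"]), state["mu"], alpha_k
        )
        return float(np.where(self.observed, terms, 0.0).sum())

    def gradients(self, params: ModelParameters, state=None, scale: float = 1.0):
        """Analytic gradients of ``scale * core_cost`` w.r.t. the free parameters.

        Returns a dict with ``rho`` (batch x guide), ``guide_efficacy``
        (guide,), ``growth_rate`` (condition,), and ``gene_effect``
        (line x gene); the caller splits the latter into gene_mean/delta.
        """
        state = state or self.forward(params)
        nu0, factor, E = state["nu0"], state["factor"], state["E"]
        Z, S, nu, mu = state["Z"], state["S"], state["nu"], state["mu"]
        pj, pc, R, alpha = state["pj"], state["pc"], state["R"], state["alpha"]
        alpha_k = alpha[self.cond_idx][:, None]
        pc_k = pc[self.cond_idx][:, None]
        live = ~state["clipped"]

        A = np.where(
            self.observed,
            1e6 * scale * _nb2_dmu(np.where(self.observed, self.N, mu), mu, alpha_k),
            0.0,
        )
        T = (A * nu).sum(axis=1, keepdims=True)
        dZ = (A - T) / S

        grad_rho = np.zeros((len(self.batches), len(self.guides)))
        np.add.at(grad_rho, self.batch_idx, dZ * factor * nu0)

        gq = dZ * nu0 * (E - 1.0) * live
        grad_pj = (gq * pc_k).sum(axis=0)

        gx = dZ * nu0 * (pc_k * pj[None, :]) * E * live
        Rtau = R[self.cond_idx] * self.tau
        per_line = np.zeros((len(self.lines), len(self.guides)))
        np.add.at(per_line, self.line_idx, gx * Rtau[:, None])
        grad_gene_effect = per_line @ self._onehot

        r_guide_k = state["r_guide"][self.line_idx]
        grad_R = np.zeros(len(self.conditions))
        np.add.at(grad_R, self.cond_idx, (gx * r_guide_k).sum(axis=1) * self.tau)

        return {
            "rho": grad_rho,
            "guide_efficacy": grad_pj,
            "growth_rate": grad_R,
            "gene_effect": grad_gene_effect,
        }


def core_cost(data: ScreenData, params: ModelParameters, engine: CostEngine | None = None) -> float:
    """Core NB2 cost of the data under the current parameters (no penalties)."""
    engine = engine or CostEngine(data, d_g=params.d_g)
    return engine.core_cost(params)


# ---------------------------------------------------------------------------
# Regularization penalties (values and gradients)
# ---------------------------------------------------------------------------

def penalty_rho(params: ModelParameters, hp: Hyperparameters) -> float:
    """chi_rho * mean(rho^2): keeps pDNA offsets small."""
    rho = params.rho.to_numpy(dtype=float)
    return float(hp.chi_rho * np.mean(rho**2))


def penalty_rho_grad(params: ModelParameters, hp: Hyperparameters) -> np.ndarray:
    rho = params.rho.to_numpy(dtype=float)
    return 2.0 * hp.chi_rho * rho / rho.size


def _top_two_mask(params: ModelParameters) -> np.ndarray:
    """Boolean mask of the two currently most efficacious guides per gene.

    Ties are broken by sgRNA label order (stable sort on descending efficacy
    of label-ordered guides).  Single-guide genes contribute their one guide.
    """
    pj = params.guide_efficacy
    genes = params.guide_map.reindex(pj.index)
    mask = np.zeros(len(pj), dtype=bool)
    frame = pd.DataFrame({"p": pj.to_numpy(), "gene": genes.to_numpy()},
                         index=pj.index).sort_index()
    pos_in_sorted = {label: i for i, label in enumerate(frame.index)}
    arr = frame["p"].to_numpy()
    orig_pos = pj.index.get_indexer(frame.index)
    for gene, labels in frame.groupby("gene", sort=False).groups.items():
        idx = np.array([pos_in_sorted[x] for x in labels])
        order = np.argsort(-arr[idx], kind="stable")
        chosen = idx[order[:2]]
        mask[orig_pos[chosen]] = True
    return mask


def penalty_guide_efficacy(params: ModelParameters, hp: Hyperparameters) -> float:
    """chi_p * mean over genes of sum of 1/p_j over the top-2 efficacious guides.

    Minimizing this forces at least two guides per gene toward efficacy 1, so
    a fit can never rest on a single (possibly off-target) sgRNA.
    """
    mask = _top_two_mask(params)
    pj = params.guide_efficacy.to_numpy(dtype=float)
    n_genes = params.guide_map.nunique()
    return float(hp.chi_p * np.sum(1.0 / pj[mask]) / n_genes)


def penalty_guide_efficacy_grad(params: ModelParameters, hp: Hyperparameters) -> np.ndarray:
    """Subgradient holding the top-2 indicator fixed at its current value."""
    mask = _top_two_mask(params)
    pj = params.guide_efficacy.to_numpy(dtype=float)
    n_genes = params.guide_map.nunique()
    grad = np.zeros_like(pj)
    grad[mask] = -hp.chi_p / (pj[mask] ** 2 * n_genes)
    return grad


def penalty_growth_rate(params: ModelParameters, hp: Hyperparameters) -> float:
    """chi_R * mean((ln R_c)^2): inert near the mean-1 constraint, strong as R -> 0."""
    R = params.growth_rate.to_numpy(dtype=float)
    return float(hp.chi_R * np.mean(np.log(R) ** 2))


def penalty_growth_rate_grad(params: ModelParameters, hp: Hyperparameters) -> np.ndarray:
    R = params.growth_rate.to_numpy(dtype=float)
    return 2.0 * hp.chi_R * np.log(R) / (R * R.size)


def penalty_gene_mean(params: ModelParameters, hp: Hyperparameters) -> float:
    """chi_r1 * (global mean of r_cg)^2: pins the overall effect scale at 0."""
    r = params.gene_effect.to_numpy(dtype=float)
    return float(hp.chi_r1 * np.mean(r) ** 2)


def penalty_gene_mean_grad(params: ModelParameters, hp: Hyperparameters) -> np.ndarray:
    """Gradient w.r.t. each r_cg entry (line x gene array)."""
    r = params.gene_effect.to_numpy(dtype=float)
    return np.full_like(r, 2.0 * hp.chi_r1 * np.mean(r) / r.size)


def kernel_weights(gene_means: pd.Series, hp: Hyperparameters) -> np.ndarray:
    """Gene x gene kernel kappa_{g-h} on the current mean-effect ranks.

    kappa = chi_h * delta_gh + chi_k * exp(-(rank_g - rank_h)^2 / 2 sigma^2) / b
    with support truncated at 3 sigma and ``b`` normalizing the full
    truncated window to sum 1.  Ranks are dense (ties broken by gene label
    order via a stable argsort).
    """
    means = gene_means.to_numpy(dtype=float)
    order = np.argsort(means, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(means))
    width = int(np.floor(3 * hp.sigma))
    offsets = np.arange(-width, width + 1)
    b = np.exp(-(offsets**2) / (2 * hp.sigma**2)).sum()
    d = ranks[:, None] - ranks[None, :]
    with np.errstate(over="ignore"):
        gauss = np.where(
            np.abs(d) <= width, np.exp(-(d.astype(float) ** 2) / (2 * hp.sigma**2)), 0.0
        )
    return hp.chi_h * np.eye(len(means)) + hp.chi_k * gauss / b


def penalty_kernel(
    params: ModelParameters, hp: Hyperparameters, weights: np.ndarray | None = None
) -> float:
    """Smoothed hierarchical shrinkage of r_cg toward nearby genes' means.

    (1/K) sum_{c,g,h in window} kappa_{g-h} (r_cg - rbar_h)^2 where rbar_h is
    the mean effect of gene h across lines and K counts the (c, g, h) terms.
    The delta part shrinks each line's effect toward its own gene mean; the
    Gaussian part couples genes of similar mean effect, smoothing the prior.
    """
    r = params.gene_effect.to_numpy(dtype=float)
    rbar = r.mean(axis=0)
    W = kernel_weights(pd.Series(rbar, index=params.gene_mean.index), hp) \
        if weights is None else weights
    L = r.shape[0]
    support = W > 0
    K = L * int(support.sum())
    S2 = (r**2).sum(axis=0)
    # sum_c (r_cg - rbar_h)^2 = S2_g - 2 L rbar_g rbar_h + L rbar_h^2
    total = (
        (W * S2[:, None]).sum()
        - 2.0 * L * rbar @ W @ rbar
        + L * (W.sum(axis=0) * rbar**2).sum()
    )
    return float(total / K)


def penalty_kernel_grad(
    params: ModelParameters, hp: Hyperparameters, weights: np.ndarray | None = None
) -> np.ndarray:
    """Gradient w.r.t. r_cg, including the dependence through rbar."""
    r = params.gene_effect.to_numpy(dtype=float)
    rbar = r.mean(axis=0)
    W = kernel_weights(pd.Series(rbar, index=params.gene_mean.index), hp) \
        if weights is None else weights
    L = r.shape[0]
    K = L * int((W > 0).sum())
    wrow = W.sum(axis=1)
    m1 = W @ rbar
    direct = (2.0 / K) * (r * wrow[None, :] - m1[None, :])
    wcol = W.sum(axis=0)
    colterm = -(2.0 / K) * (W.T @ rbar - rbar * wcol)
    return direct + colterm[None, :]


def total_cost(
    data: ScreenData,
    params: ModelParameters,
    hp: Hyperparameters | None = None,
    rescale: float = 1.0,
    engine: CostEngine | None = None,
) -> float:
    """Rescaled core cost plus all five penalties."""
    hp = hp or Hyperparameters()
    engine = engine or CostEngine(data, d_g=params.d_g)
    return (
        rescale * engine.core_cost(params)
        + penalty_rho(params, hp)
        + penalty_guide_efficacy(params, hp)
        + penalty_growth_rate(params, hp)
        + penalty_gene_mean(params, hp)
        + penalty_kernel(params, hp)
    )


# ---------------------------------------------------------------------------
# Direct cell-efficacy estimation
# ---------------------------------------------------------------------------

def estimate_cell_efficacy(
    lfc: pd.DataFrame,
    sequence_map: pd.DataFrame,
    percentile: float = 0.99,
    p_min: float = 0.01,
) -> pd.Series:
    """Estimate p_c per (cell line, library) from late-time-point depletion.

    Under the model, the most depleted guides (fully efficacious, lethal
    target) saturate at relative abundance 1 - p_c, so the fold change at the
    boundary of the most-depleted ``1 - percentile`` tail inverts to
    ``p_c = 1 - 2^q``.  ``q`` is the (1 - percentile) quantile of the mean
    LFC across a line's replicates at its last time point; the result is
    clipped to [p_min, 1].
    """
    if not 0 < percentile < 1:
        raise ValueError("percentile must be in (0, 1)")
    sm = sequence_map.copy()
    if "library" not in sm.columns:
        sm["library"] = "default"
    sm = sm[sm["sequence_ID"].isin(lfc.index)]
    sm = sm[(sm["cell_line_name"] != "pDNA") & (sm["days"] > 0)]
    if lfc.shape[1] < 100:
        logger.warning(
            "cell efficacy quantile estimated from only %d sgRNAs", lfc.shape[1]
        )
    out = {}
    for (line, lib), grp in sm.groupby(["cell_line_name", "library"], sort=True):
        last = grp["days"].max()
        rows = grp.loc[grp["days"] == last, "sequence_ID"]
        mean_lfc = lfc.loc[rows].mean(axis=0, skipna=True).to_numpy(dtype=float)
        q = np.nanquantile(mean_lfc, 1.0 - percentile)
        out[(line, lib)] = float(np.clip(1.0 - 2.0**q, p_min, 1.0))
    result = pd.Series(out)
    result.index = pd.MultiIndex.from_tuples(
        result.index, names=["cell_line_name", "library"]
    )
    return result
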