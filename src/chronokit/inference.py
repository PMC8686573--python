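"""Staged gradient-descent fitting of the population model.

Training minimizes ``rescale * core_cost + penalties`` with Adam on
full-batch analytic gradients.  The schedule follows four stabilizing
devices: (1) the core cost is rescaled once, at epoch 0, so its initial
value equals ``cost_rescale_target`` (0.67) — this keeps the penalty weights
meaningful across datasets of different size; (2) the learning rate ramps
geometrically from ``lr_initial`` to ``lr_max`` over ``burn_in_epochs``;
(3) only the gene effect (gene_mean + delta) is optimized during the first
``gene_effect_only_epochs`` epochs, a phase in which the core cost is convex;
(4) hard constraints (p_j in (0, 1], mean-1 positive growth rates, mean-0
pDNA offsets per gene) are reimposed by projection after every step.

Cell efficacy p_c is estimated directly from late-time-point fold changes
before training and held fixed throughout.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .preprocess import compute_lfc
from .population_model import (
    CostEngine,
    Hyperparameters,
    ModelParameters,
    center_rho,
    estimate_cell_efficacy,
    penalty_gene_mean,
    penalty_gene_mean_grad,
    penalty_growth_rate,
    penalty_growth_rate_grad,
    penalty_guide_efficacy,
    penalty_guide_efficacy_grad,
    penalty_kernel,
    penalty_kernel_grad,
    penalty_rho,
    penalty_rho_grad,
)
from .screen_data import GeneEffectMatrix, ScreenData

logger = logging.getLogger("chronokit")


@dataclasses.dataclass
class TrainingState:
    """Diagnostics of a completed (or aborted) fit."""

    params: ModelParameters
    epoch: int
    cost_history: list
    rescale_factor: float
    rng_seed: int


def learning_rate(epoch: int, hp: Hyperparameters) -> float:
    """Geometric ramp from lr_initial to lr_max over the burn-in, then constant."""
    if epoch < 0:
        raise ValueError("epoch must be nonnegative")
    if epoch >= hp.burn_in_epochs:
        return hp.lr_max
    frac = epoch / hp.burn_in_epochs
    return float(hp.lr_initial * (hp.lr_max / hp.lr_initial) ** frac)


def initialize(data: ScreenData, hp: Hyperparameters, seed: int = 0) -> ModelParameters:
    """Deterministic near-neutral starting point for all free parameters.

    rho = 0; p_j = 1 minus a small uniform offset on [0, 0.05]; R_c = 1 plus
    Gaussian(0, 0.01) noise, projected positive with mean exactly 1 per
    library; gene means and per-line deviations uniform on [-1e-4, 0.5e-4].
    Cell efficacy is a placeholder 1.0 until estimated.
    """
    rng = np.random.default_rng(seed)
    engine_guides = data.counts.columns
    genes = pd.Index(sorted(data.guide_map["gene"].unique()))
    lines = pd.Index(sorted(data.replicate_map["cell_line_name"].unique()))
    late = data.replicate_map
    conditions = (
        pd.MultiIndex.from_frame(late[["cell_line_name", "library"]])
        .unique()
        .sortlevel()[0]
    )
    batches = pd.Index(sorted(late["pDNA_batch"].unique()))

    rho = pd.DataFrame(0.0, index=batches, columns=engine_guides)
    pj = pd.Series(
        1.0 - rng.uniform(0.0, 0.05, size=len(engine_guides)), index=engine_guides
    )
    R_raw = 1.0 + rng.normal(0.0, 0.01, size=len(conditions))
    R = pd.Series(np.maximum(R_raw, 1e-6), index=conditions)
    for lib, grp in R.groupby(level=1):
        R.loc[grp.index] = grp / grp.mean()
    gene_mean = pd.Series(
        rng.uniform(-1e-4, 0.5e-4, size=len(genes)), index=genes
    )
    delta = pd.DataFrame(
        rng.uniform(-1e-4, 0.5e-4, size=(len(lines), len(genes))),
        index=lines,
        columns=genes,
    )
    return ModelParameters(
        rho=rho,
        guide_efficacy=pj,
        cell_efficacy=pd.Series(1.0, index=conditions),
        growth_rate=R,
        gene_mean=gene_mean,
        delta=delta,
        guide_map=data.guide_genes(),
        d_g=hp.d_g,
        alpha=hp.alpha_global,
    )


def project_constraints(params: ModelParameters) -> None:
    """Reimpose hard constraints in place after a gradient step."""
    params.guide_efficacy = params.guide_efficacy.clip(1e-6, 1.0)
    R = params.growth_rate.clip(lower=1e-6)
    for lib, grp in R.groupby(level=1):
        R.loc[grp.index] = grp / grp.mean()
    params.growth_rate = R
    params.rho = center_rho(params.rho, params.guide_map)


class _Adam:
    """Standard Adam with bias correction, one state per parameter group."""

    def __init__(self, beta1: float, beta2: float, eps: float = 1e-7):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t: dict[str, int] = {}

    def step(self, name: str, value: np.ndarray, grad: np.ndarray, lr: float) -> np.ndarray:
        if name not in self.m:
            self.m[name] = np.zeros_like(grad)
            self.v[name] = np.zeros_like(grad)
            self.t[name] = 0
        self.t[name] += 1
        t = self.t[name]
        self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * grad
        self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * grad**2
        m_hat = self.m[name] / (1 - self.beta1**t)
        v_hat = self.v[name] / (1 - self.beta2**t)
        return value - lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _penalty_sum(params: ModelParameters, hp: Hyperparameters) -> float:
    return (
        penalty_rho(params, hp)
        + penalty_guide_efficacy(params, hp)
        + penalty_growth_rate(params, hp)
        + penalty_gene_mean(params, hp)
        + penalty_kernel(params, hp)
    )


def fit(
    data: ScreenData,
    hp: Hyperparameters | None = None,
    seed: int = 0,
    cell_efficacy: pd.Series | None = None,
    alpha: pd.Series | float | None = None,
    epochs: int | None = None,
) -> tuple[GeneEffectMatrix, ModelParameters, TrainingState]:
    """Fit gene fitness effects to a preprocessed screen.

    Returns the raw (unnormalized) gene effect matrix, the full parameter
    set, and training diagnostics.  Deterministic given ``seed``.
    """
    hp = hp or Hyperparameters()
    n_epochs = hp.epochs if epochs is None else int(epochs)
    logger.info("fitting %d epochs with seed %d", n_epochs, seed)

    engine = CostEngine(data, d_g=hp.d_g)
    params = initialize(data, hp, seed)
    if alpha is not None:
        params.alpha = alpha
    if cell_efficacy is None:
        lfc = compute_lfc(data)
        cell_efficacy = estimate_cell_efficacy(
            lfc,
            data.sequence_map,
            percentile=hp.cell_efficacy_percentile,
            p_min=hp.cell_efficacy_floor,
        )
    params.cell_efficacy = cell_efficacy.reindex(engine.conditions)
    if params.cell_efficacy.isna().any():
        missing = params.cell_efficacy.index[params.cell_efficacy.isna()].tolist()
        raise ValueError(f"cell efficacy missing for conditions {missing[:5]}")

    state = engine.forward(params)
    core0 = engine.core_cost(params, state)
    rescale = hp.cost_rescale_target / core0 if core0 > 0 else 1.0
    logger.info("core cost rescale factor %.3g (initial core cost %.6g)", rescale, core0)

    adam = _Adam(hp.adam_beta1, hp.adam_beta2)
    cost_history: list[float] = []

    for epoch in range(n_epochs):
        try:
            cost = rescale * engine.core_cost(params, state) + _penalty_sum(params, hp)
        except (ValueError, FloatingPointError) as err:
            cost = np.nan
            logger.error("cost evaluation failed at epoch %d: %s", epoch, err)
        if not np.isfinite(cost):
            logger.error(
                "non-finite cost at epoch %d; parameter summary: p_j [%g, %g], "
                "R [%g, %g], r [%g, %g]",
                epoch,
                params.guide_efficacy.min(), params.guide_efficacy.max(),
                params.growth_rate.min(), params.growth_rate.max(),
                params.gene_effect.to_numpy().min(), params.gene_effect.to_numpy().max(),
            )
            raise RuntimeError(f"training diverged: non-finite cost at epoch {epoch}")
        cost_history.append(float(cost))

        grads = engine.gradients(params, state, scale=rescale)
        ge_grad = (
            grads["gene_effect"]
            + penalty_gene_mean_grad(params, hp)
            + penalty_kernel_grad(params, hp)
        )
        lr = learning_rate(epoch, hp)

        new_mean = adam.step("gene_mean", params.gene_mean.to_numpy(), ge_grad.sum(axis=0), lr)
        new_delta = adam.step("delta", params.delta.to_numpy(), ge_grad, lr)
        params.gene_mean = pd.Series(new_mean, index=params.gene_mean.index)
        params.delta = pd.DataFrame(
            new_delta, index=params.delta.index, columns=params.delta.columns
        )

        if epoch >= hp.gene_effect_only_epochs:
            grad_rho = grads["rho"] + penalty_rho_grad(params, hp)
            grad_pj = grads["guide_efficacy"] + penalty_guide_efficacy_grad(params, hp)
            grad_R = grads["growth_rate"] + penalty_growth_rate_grad(params, hp)
            params.rho = pd.DataFrame(
                adam.step("rho", params.rho.to_numpy(), grad_rho, lr),
                index=params.rho.index,
                columns=params.rho.columns,
            )
            params.guide_efficacy = pd.Series(
                adam.step("guide_efficacy", params.guide_efficacy.to_numpy(), grad_pj, lr),
                index=params.guide_efficacy.index,
            )
            params.growth_rate = pd.Series(
                adam.step("growth_rate", params.growth_rate.to_numpy(), grad_R, lr),
                index=params.growth_rate.index,
            )
        project_constraints(params)
        state = engine.forward(params)

    final_cost = rescale * engine.core_cost(params, state) + _penalty_sum(params, hp)
    cost_history.append(float(final_cost))
    lookback = min(100, len(cost_history) - 1)
    if lookback > 0 and cost_history[-1] > cost_history[-1 - lookback] * 1.001:
        logger.warning(
            "cost increased over the last %d epochs (%.6g -> %.6g)",
            lookback, cost_history[-1 - lookback], cost_history[-1],
        )

    gene_effect = GeneEffectMatrix(data=params.gene_effect, normalization="raw")
    training = TrainingState(
        params=params,
        epoch=n_epochs,
        cost_history=cost_history,
        rescale_factor=rescale,
        rng_seed=seed,
    )
    return gene_effect, params, training
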