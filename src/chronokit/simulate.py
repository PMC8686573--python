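"""Generative simulator of pooled CRISPR knockout screens with known truth.

Counts are generated from the same two-population mixture the fitter assumes:
cells that achieved knockout (probability ``p_c * p_j``) grow at
``R_c (1 + r_cg)`` after the delay ``d_g``, the rest at ``R_c``; relative
sgRNA abundances are the normalized population fractions and readcounts are
NB2 draws around ``depth * n_guides * nu`` (variance ``mu + alpha mu^2``).
Optional artifacts: clonal-outgrowth spikes (single entries multiplied by a
large factor, emulating a fitness-mutant clone expanding at the unperturbed
rate) and a copy-number bias acting as a knockout-independent growth-rate
offset for guides in amplified regions.

True gene effects follow a three-class mixture: neutral (r = 0), essential
(r ~ Normal(-1, 0.2) in every line, i.e. growth arrest on knockout), and
selective (essential in a random subset of lines).  Fifteen percent of genes
are non-neutral somewhere in every default scenario, echoing the prevalence
of true dependencies in large screening datasets.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .screen_data import GeneEffectMatrix, ScreenData


@dataclasses.dataclass
class SimulationScenario:
    """Complete description of a synthetic screen; counts are reproducible
    from ``seed`` alone."""

    name: str = "custom"
    n_lines: int = 3
    n_genes: int = 100
    guides_per_gene: int = 4
    n_replicates: int = 1  # replicates per (line, time point)
    time_points: tuple = (14.0, 21.0)
    depth: float = 500.0  # expected reads per sgRNA
    alpha: float = 0.05  # NB2 overdispersion
    noise: bool = True  # False -> counts equal their NB2 means exactly
    d_g: float = 3.0  # phenotype-onset delay, days
    # ground-truth generation
    essential_fraction: float = 0.15
    selective_fraction: float = 0.05
    selective_line_prob: float = 0.2
    essential_mean: float = -1.0
    essential_sd: float = 0.2
    guide_efficacy_beta: tuple = (6.0, 2.0)
    cell_efficacy_range: tuple = (0.7, 1.0)
    growth_rate_sd: float = 0.1
    pdna_sigma: float = 0.5  # lognormal spread of initial library abundance
    n_pdna_measurements: int = 2
    # artifacts
    outgrowth_rate: float = 0.0  # fraction of (replicate, sgRNA) entries spiked
    outgrowth_factor: float = 100.0
    cn_bias: bool = False
    cn_amplified_gene_fraction: float = 0.2
    cn_amplified_line_prob: float = 0.3
    cn_noise_sd: float = 0.05  # log2 jitter around normal ploidy
    cn_weight_range: tuple = (0.4, 1.0)  # per-line bias strength w_c
    cn_effect_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("sequencing depth must be positive")
        if self.n_lines < 1 or self.n_genes < 1 or self.guides_per_gene < 1:
            raise ValueError("scenario dimensions must be positive")
        if min(self.time_points) <= 0:
            raise ValueError("time points must be positive days")


@dataclasses.dataclass
class SimulationTruth:
    """Ground truth retained alongside simulated counts."""

    gene_effect: pd.DataFrame  # line x gene, per day
    guide_efficacy: pd.Series
    cell_efficacy: pd.Series  # per line
    growth_rate: pd.Series  # per line, mean 1
    pdna_abundance: pd.Series  # per guide, sums to 1
    essential_genes: list
    neutral_genes: list
    selective_genes: list
    outgrowths: pd.DataFrame  # (sequence_ID, sgrna) rows actually spiked
    copy_number: pd.DataFrame | None = None  # log2(x+1)
    cn_bias_surface: pd.DataFrame | None = None  # w_c * f(cn, mean), line x gene
    cn_weights: pd.Series | None = None


def _cn_bias_function(cn: np.ndarray, gene_mean: np.ndarray) -> np.ndarray:
    """Smooth planted bias surface f(cn, mean effect).

    Slope of the copy-number response flips sign with the gene's mean effect:
    amplified nonessential genes deplete (cutting toxicity), amplified
    essential genes score higher (incomplete knockout), and the essential
    response is non-monotone in copy number.
    """
    gate = np.tanh((gene_mean + 0.6) / 0.25)  # -1 essential .. +1 neutral
    slope = -0.05 - 0.35 * gate
    curvature = -0.15 * (1.0 - gate) / 2.0
    d = cn - 1.0  # log2(x+1) = 1 is normal ploidy
    return slope * d + curvature * d**2


def _draw_truth(sc: SimulationScenario, rng: np.random.Generator):
    genes = pd.Index([f"G{i:04d}" for i in range(sc.n_genes)], name="gene")
    guides = pd.Index(
        [f"{g}_sg{k}" for g in genes for k in range(sc.guides_per_gene)], name="sgrna"
    )
    lines = pd.Index([f"line{i:02d}" for i in range(sc.n_lines)], name="cell_line_name")

    neutral_frac = 1.0 - sc.essential_fraction - sc.selective_fraction
    klass = rng.choice(
        ["neutral", "essential", "selective"],
        size=sc.n_genes,
        p=[neutral_frac, sc.essential_fraction, sc.selective_fraction],
    )
    base = rng.normal(sc.essential_mean, sc.essential_sd, size=sc.n_genes)
    r = np.zeros((sc.n_lines, sc.n_genes))
    r[:, klass == "essential"] = base[klass == "essential"]
    sel_cols = np.nonzero(klass == "selective")[0]
    for g in sel_cols:
        hit = rng.random(sc.n_lines) < sc.selective_line_prob
        if not hit.any():
            hit[rng.integers(sc.n_lines)] = True
        r[hit, g] = base[g]

    a, b = sc.guide_efficacy_beta
    pj = pd.Series(rng.beta(a, b, size=len(guides)), index=guides)
    lo, hi = sc.cell_efficacy_range
    pc = pd.Series(rng.uniform(lo, hi, size=sc.n_lines), index=lines)
    R = 1.0 + rng.normal(0.0, sc.growth_rate_sd, size=sc.n_lines)
    R = np.maximum(R, 0.5)
    R = pd.Series(R / R.mean(), index=lines)
    abundance = rng.lognormal(0.0, sc.pdna_sigma, size=len(guides))
    abundance = pd.Series(abundance / abundance.sum(), index=guides)

    truth = SimulationTruth(
        gene_effect=pd.DataFrame(r, index=lines, columns=genes),
        guide_efficacy=pj,
        cell_efficacy=pc,
        growth_rate=R,
        pdna_abundance=abundance,
        essential_genes=genes[klass == "essential"].tolist(),
        neutral_genes=genes[klass == "neutral"].tolist(),
        selective_genes=genes[klass == "selective"].tolist(),
        outgrowths=pd.DataFrame(columns=["sequence_ID", "sgrna"]),
    )
    return genes, guides, lines, truth


def _draw_copy_number(sc: SimulationScenario, rng, lines, genes, gene_effect):
    cn = 1.0 + rng.normal(0.0, sc.cn_noise_sd, size=(len(lines), len(genes)))
    n_amp = int(round(sc.cn_amplified_gene_fraction * len(genes)))
    amp_genes = rng.choice(len(genes), size=n_amp, replace=False)
    for g in amp_genes:
        amp_lines = rng.random(len(lines)) < sc.cn_amplified_line_prob
        x = rng.uniform(2.0, 6.0, size=int(amp_lines.sum()))
        cn[amp_lines, g] = np.log2(x + 1.0)
    cn = np.maximum(cn, 0.0)
    cn_frame = pd.DataFrame(cn, index=lines, columns=genes)
    w = pd.Series(rng.uniform(*sc.cn_weight_range, size=len(lines)), index=lines)
    mean_effect = gene_effect.mean(axis=0).to_numpy()
    surface = _cn_bias_function(cn, mean_effect[None, :]) * w.to_numpy()[:, None]
    return cn_frame, pd.DataFrame(surface, index=lines, columns=genes), w, amp_genes


def _nb2_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB2 sample with mean mu and variance mu + alpha mu^2."""
    mu = np.maximum(mu, 1e-12)
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p).astype(float)


def simulate_screen(scenario: SimulationScenario) -> tuple[ScreenData, SimulationTruth]:
    """Generate a full synthetic screen and its ground truth."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    genes, guides, lines, truth = _draw_truth(sc, rng)
    J = len(guides)
    gene_codes = genes.get_indexer(pd.Index([g.rsplit("_sg", 1)[0] for g in guides]))

    bias_rate = None
    if sc.cn_bias:
        cn_frame, surface, w, _ = _draw_copy_number(
            sc, rng, lines, genes, truth.gene_effect
        )
        truth.copy_number = cn_frame
        truth.cn_bias_surface = surface
        truth.cn_weights = w
        bias_rate = surface.to_numpy()

    # pDNA measurements (shared single batch)
    a = truth.pdna_abundance.to_numpy()
    mu_pdna = sc.depth * J * a
    pdna_rows = {}
    for i in range(sc.n_pdna_measurements):
        counts = _nb2_draw(rng, mu_pdna, sc.alpha) if sc.noise else mu_pdna.copy()
        pdna_rows[f"pdna_{i}"] = np.maximum(counts, 1.0)

    r_guide = truth.gene_effect.to_numpy()[:, gene_codes]  # (L, J)
    pj = truth.guide_efficacy.to_numpy()
    pc = truth.cell_efficacy.to_numpy()
    R = truth.growth_rate.to_numpy()

    late_rows, seq_meta = {}, []
    for li, line in enumerate(lines):
        for t in sc.time_points:
            tau = max(t - sc.d_g, 0.0)
            E = np.exp(R[li] * r_guide[li] * tau)
            frac = a * (1.0 + pc[li] * pj * (E - 1.0))
            if bias_rate is not None:
                frac = frac * np.exp(R[li] * bias_rate[li][gene_codes] * tau)
            nu = frac / frac.sum()
            mu = sc.depth * J * nu
            for rep in range(sc.n_replicates):
                seq_id = f"{line}_d{int(t)}_r{rep}"
                counts = _nb2_draw(rng, mu, sc.alpha) if sc.noise else mu.copy()
                late_rows[seq_id] = counts
                seq_meta.append(
                    {
                        "sequence_ID": seq_id,
                        "cell_line_name": line,
                        "pDNA_batch": "batch0",
                        "days": float(t),
                    }
                )

    # clonal outgrowth spikes on late entries
    spiked = []
    if sc.outgrowth_rate > 0:
        for seq_id in late_rows:
            hits = np.nonzero(rng.random(J) < sc.outgrowth_rate)[0]
            for j in hits:
                late_rows[seq_id][j] = max(late_rows[seq_id][j], 1.0) * sc.outgrowth_factor
                spiked.append({"sequence_ID": seq_id, "sgrna": guides[j]})
    truth.outgrowths = pd.DataFrame(spiked, columns=["sequence_ID", "sgrna"])

    counts = pd.DataFrame({**pdna_rows, **late_rows}, index=guides).T
    counts.index.name = "sequence_ID"
    sequence_map = pd.DataFrame(
        [
            {
                "sequence_ID": f"pdna_{i}",
                "cell_line_name": "pDNA",
                "pDNA_batch": "batch0",
                "days": 0.0,
            }
            for i in range(sc.n_pdna_measurements)
        ]
        + seq_meta
    )
    guide_map = pd.DataFrame(
        {"sgrna": guides, "gene": [genes[c] for c in gene_codes]}
    )
    data = ScreenData(counts=counts, sequence_map=sequence_map, guide_map=guide_map)
    return data, truth


def simulate_cn_biased_gene_effects(
    scenario: SimulationScenario,
) -> tuple[GeneEffectMatrix, SimulationTruth]:
    """Plant a smooth copy-number bias directly on a gene-effect matrix.

    Returns ``truth_effect + w_c * f(cn, mean effect) + noise`` together with
    the truth bundle (including the planted surface and weights); used to
    exercise the post-hoc correction in isolation from fitting error.
    """
    sc = dataclasses.replace(scenario, cn_bias=True)
    rng = np.random.default_rng(sc.seed)
    genes, guides, lines, truth = _draw_truth(sc, rng)
    cn_frame, surface, w, _ = _draw_copy_number(sc, rng, lines, genes, truth.gene_effect)
    truth.copy_number = cn_frame
    truth.cn_bias_surface = surface
    truth.cn_weights = w
    noise = rng.normal(0.0, sc.cn_effect_noise_sd, size=surface.shape)
    biased = truth.gene_effect + surface + noise
    return GeneEffectMatrix(data=biased, normalization="raw"), truth


def plant_offtarget_guides(
    data: ScreenData,
    truth: SimulationTruth,
    genes: list,
    offtarget_efficacy: float = 0.8,
    offtarget_rate: float = -1.0,
    d_g: float = 3.0,
) -> tuple[ScreenData, list]:
    """Give the first guide of each listed gene an off-target fitness effect.

    The guide's counts are scaled by the two-population mixture it would show
    if it killed the cells carrying it (rate ``offtarget_rate``, knockout
    probability ``offtarget_efficacy * p_c``) — the realistic signature of a
    guide cutting at an unintended genomic site.  The targeted genes' true
    effects are untouched (they are expected to be null genes).  Returns the
    modified data and the list of planted guide labels.
    """
    planted = [f"{g}_sg0" for g in genes]
    missing = [g for g in planted if g not in data.counts.columns]
    if missing:
        raise ValueError(f"planted guides not in screen: {missing[:5]}")
    counts = data.counts.copy()
    R = truth.growth_rate
    pc = truth.cell_efficacy
    for _, row in data.replicate_map.iterrows():
        tau = max(float(row["days"]) - d_g, 0.0)
        line = row["cell_line_name"]
        p = offtarget_efficacy * pc[line]
        factor = (1.0 - p) + p * np.exp(R[line] * offtarget_rate * tau)
        counts.loc[row["sequence_ID"], planted] *= factor
    return (
        ScreenData(
            counts=counts, sequence_map=data.sequence_map, guide_map=data.guide_map
        ),
        planted,
    )


def default_scenarios() -> dict[str, SimulationScenario]:
    """Named study designs used throughout the test and acceptance suites."""
    return {
        "recovery_small": SimulationScenario(
            name="recovery_small", n_lines=3, n_genes=100, guides_per_gene=4,
            n_replicates=1, time_points=(7.0, 14.0, 21.0), depth=500.0,
        ),
        "recovery_standard": SimulationScenario(
            name="recovery_standard", n_lines=20, n_genes=250, guides_per_gene=4,
            n_replicates=2, time_points=(7.0, 14.0, 21.0), depth=500.0, alpha=0.05,
        ),
        "timecourse": SimulationScenario(
            name="timecourse", n_lines=1, n_genes=200, guides_per_gene=4,
            n_replicates=1,
            time_points=(7.0, 10.0, 13.0, 16.0, 19.0, 22.0, 25.0),
            depth=500.0,
        ),
        # enough lines that a per-gene correlation has a sampling floor well
        # below the planted-bias signal (|corr| floor ~ 1/sqrt(n_lines))
        "cn_bias": SimulationScenario(
            name="cn_bias", n_lines=100, n_genes=250, guides_per_gene=4,
            n_replicates=1, time_points=(14.0,), depth=500.0, cn_bias=True,
        ),
        "outgrowth": SimulationScenario(
            name="outgrowth", n_lines=25, n_genes=250, guides_per_gene=4,
            n_replicates=3, time_points=(14.0, 21.0), depth=500.0,
            outgrowth_rate=0.0002,
        ),
    }
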