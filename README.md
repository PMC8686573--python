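# chronokit

Gene fitness effects from pooled CRISPR knockout screens, inferred through
an explicit model of the cell population dynamics.

## The problem

A pooled knockout screen infects cells with a library of sgRNAs and tracks
each guide's relative abundance by sequencing.  Turning those readcounts
into per-gene fitness effects is confounded by variable guide efficacy,
incomplete knockout penetrance (cells that escape knockout keep growing at
the unperturbed rate, so depletion saturates), variable screen quality
across cell lines, copy-number-driven cutting toxicity, and occasional
clonal outgrowths.  chronokit addresses these jointly, for analysts of
single screens or multi-line panels, with or without multiple late time
points.

## The model

For sgRNA *j* (targeting gene *g*) in cell line *c*, a fraction
*p<sub>c</sub>·p<sub>j</sub>* of infected cells achieves knockout and grows
at rate *R<sub>c</sub>*(1 + *r<sub>cg</sub>*); the rest grow at
*R<sub>c</sub>*.  After an onset delay *d<sub>g</sub>* (default 3 days) the
predicted relative abundance is

    Z_cj(t) = ν_cj(0) · (1 + p_c p_j (e^{R_c r_cg (t−d_g)} − 1)),
    ν_cj(t) = Z_cj(t) / Σ_j Z_cj(t)

with *ν(0)* seeded from pDNA medians times free per-guide offsets.
Observed reads-per-million are scored with a shifted NB2 negative binomial
likelihood (variance μ + αμ²), and five regularizers make the model
identifiable — most importantly a top-2 guide-efficacy penalty that
prevents any gene score from resting on a single (possibly off-target)
sgRNA.  Training is staged Adam on hand-derived analytic gradients (no
autodiff dependency); *p<sub>c</sub>* is estimated directly from the
most-depleted LFC tail and held fixed.  The fitted gene-effect matrix
*r<sub>cg</sub>* can then be globally scaled to control genes
(nonessential → 0, essential → −1), corrected for copy-number bias with a
per-line-weighted 2D spline, and scored with standard screen QC metrics
(NNMD, unexpressed false-positive rate, precision-recall of essentials).
See `docs/methods.md` for the full model, defaults, and limitations.

## Worked example

Simulate a small 3-line screen with known ground truth, mask outgrowths,
fit, and check recovery:

```python
import numpy as np
from scipy.stats import pearsonr
import chronokit as ck

scenario = ck.default_scenarios()["recovery_small"]   # 3 lines x 100 genes
data, truth = ck.simulate_screen(scenario)
masked, report = ck.remove_clonal_outgrowths(data)
gene_effect, params, training = ck.fit(masked, seed=0)

for line in gene_effect.data.index:
    r = pearsonr(gene_effect.data.loc[line], truth.gene_effect.loc[line])[0]
    print(f"{line}: fitted-vs-true Pearson r = {r:.3f}")
print(f"cell efficacy estimates: {np.round(params.per_line(params.cell_efficacy).to_numpy(), 3)}")
print(f"true cell efficacies:    {np.round(truth.cell_efficacy.to_numpy(), 3)}")
print(f"final training cost: {training.cost_history[-1]:.4f}")
```

Output:

```
line00: fitted-vs-true Pearson r = 0.959
line01: fitted-vs-true Pearson r = 0.963
line02: fitted-vs-true Pearson r = 0.950
cell efficacy estimates: [0.849 0.812 0.934]
true cell efficacies:    [0.882 0.859 0.987]
final training cost: 1.1279
```

Per-line correlations with truth are ≈ 0.95–0.96 at sequencing depth 500;
cell efficacies are recovered to within a few percent (slightly
underestimated because the +1 LFC pseudocount damps extreme depletion).
The final cost is the rescaled NB2 likelihood plus all penalties — the
penalty floor alone is ≈ 1.0, so the data misfit term has shrunk from its
initial 0.67 to ≈ 0.1.

The same workflow runs from the shell:

```bash
screen-chronokit run --scenario recovery_small --seed 0 --out results/demo
screen-chronokit fit --counts counts.csv --sequence-map sequence_map.csv \
    --guide-map guide_map.csv --seed 0 --out results/fit
screen-chronokit correct-cn --gene-effect results/fit/gene_effect.csv \
    --copy-number copy_number.csv --out results/cn
screen-chronokit qc --gene-effect results/fit/gene_effect.csv \
    --essential essential.txt --nonessential nonessential.txt --out results/qc
```

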