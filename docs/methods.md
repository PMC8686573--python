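# Methods

## The model

A pooled CRISPR knockout screen infects a population of Cas9-positive cells
with a library of sgRNAs and reads out each guide's relative abundance by
sequencing, at one or more late time points, against the plasmid pool
(pDNA).  Knockout is stochastic: a cell that receives guide `j` (targeting
gene `g`) in line `c` either loses gene function — with probability
`p_c * p_j`, the product of a per-line and a per-guide efficacy in (0, 1] —
or retains it.  Knockout cells grow at `R_c (1 + r_cg)`, the rest at the
unperturbed rate `R_c`.  The quantity of interest is `r_cg`, the fractional
change in growth rate on knockout (0 = inert, −1 = growth arrest), reported
per day with `R_c` constrained to mean 1 per library.

Sequencing measures proportions, not cell numbers.  After the phenotype
onset delay `d_g` (default 3 days — inference of this delay has not proven
worthwhile, so it is a fixed hyperparameter), the predicted relative
abundance is

    Z_cj(t) = nu_cj(0) * (1 + p_c p_j (exp(R_c r_cg (t − d_g)) − 1)),
    nu_cj(t) = Z_cj(t) / Σ_j Z_cj(t),            Z_cj(t) = nu_cj(0) for t < d_g.

Unperturbed growth factors cancel in the normalization.  The initial
abundance `nu_cj(0)` is the median pDNA relative abundance of the batch
times `exp(rho_bj)`, where the free offsets `rho` absorb systematic pDNA
measurement error; `rho` is constrained to mean 0 over each gene's guides.
Guides annotated to multiple genes are rejected outright — joint-knockout
phenotypes are not additive, so no model of them is attempted.

Observed readcounts are scored with the NB2 negative binomial (variance
`mu + alpha mu^2`), keeping only the `mu`-dependent terms and shifting so a
perfect prediction costs exactly zero:

    lambda(N, mu) = (N + 1/alpha) ln(1 + alpha mu) − N ln mu,
    cost(N, mu) = lambda(N, mu) − lambda(N, N).

Counts enter as reads per million (so the cost ignores library size), with
NaN entries contributing nothing.  The overdispersion `alpha` is a fixed
input, global by default (0.05 per line and library, exposed as
`alpha_global`); external per-line estimates can be supplied but are not
estimated here, since data-driven estimates have a tendency to blow up for
some lines and silence their entire contribution.

### Units and time scaling

Gene effects and growth rates are in per-day units and the growth exponent
is exactly `R_c * r_cg * (t − d_g)` with `t` in days: the internal
`time_scale` constant (0.1, i.e. measuring time in 10-day units) enters the
exponent together with its exact reciprocal on the growth product, so
predictions are invariant to it.  The free optimization variables are also
kept in per-day units — with Adam, variable rescaling only changes the
effective per-parameter step size, and per-day variables converge within
the default epoch budget.  All penalties below are evaluated on the per-day
gene effects.

## Regularization

Five penalties make the model identifiable and robust (defaults in
parentheses):

- `C_rho = chi_rho * mean(rho^2)` (1.0) — keeps pDNA offsets small.
- `C_p = chi_p * mean_g Σ_{j in top-2 of g} 1/p_j` (0.5) — drives the two
  currently most efficacious guides of every gene toward efficacy 1 (the
  indicator is recomputed every evaluation; ties break by guide label).
  This is the guard against single off-target guides: a gene effect can
  never rest on one guide, because its best sibling is always forced to
  "agree" at full efficacy.
- `C_R = chi_R * mean((ln R_c)^2)` (0.01) — inert near the mean-1
  constraint, strong if a line's growth rate heads to 0.
- `C_r1 = chi_r1 * (mean r_cg)^2` (0.1) — pins the global mean effect at 0.
- `C_r2` — a smoothed hierarchical prior: with genes ranked by mean effect,
  `mean_{c,g,h} kappa_{g-h} (r_cg − rbar_h)^2` where
  `kappa = chi_h δ_gh + chi_k exp(−(rank_g − rank_h)^2 / 2 sigma^2)/b`
  (0.1, 0.25, sigma = 5 rank units), truncated at 3 sigma with `b`
  normalizing the full window to 1 (edge genes carry less Gaussian mass).
  The delta part shrinks a line's effect toward its own gene mean; the
  Gaussian part couples genes with similar mean effects.

The per-line efficacy `p_c` is deliberately *not* trained: with a single
late time point it is degenerate with `R_c` and `p_j`.  It is estimated
directly from the most-depleted tail of late-time-point log fold changes —
under the model a fully efficacious guide on a lethal gene saturates at
relative abundance `1 − p_c`, so the LFC quantile `q` at the 99th-percentile
depletion boundary inverts to `p_c = clip(1 − 2^q, 0.01, 1)`.  Whether the
99th percentile counts from the depleted or enriched end is ambiguous in
words; we take the boundary of the most-depleted 1% of guides.

## Fitting

Training minimizes `rescale * C + C_rho + C_p + C_R + C_r1 + C_r2` by Adam
(β = 0.9/0.999) on full-batch analytic gradients; no autodiff framework is
used — the gradients of every term are derived by hand and checked against
central finite differences in the test suite (relative error < 1e-4).
Four devices stabilize training:

1. the core cost is rescaled once, at epoch 0, to 0.67, so penalty weights
   mean the same thing for datasets of any size;
2. the learning rate ramps geometrically from 1e-4 to 0.02 over a 50-epoch
   burn-in (the exact ramp shape is not prescribed anywhere; geometric
   interpolation between the stated endpoints is used);
3. the first 100 epochs update the gene effect only (the core cost is
   convex in it), giving a stable basin before efficacies move;
4. after every step, hard constraints are re-imposed by projection:
   `p_j` clipped to [1e-6, 1], `R_c` clipped positive and divided by its
   per-library mean, `rho` re-centered per gene.

Default 801 epochs.  Growth exponents are clipped at ±50 with a warning
(runaway parameters); the two-population factor is floored at 1e-30 only to
guard exact zeros.  Fits are deterministic given the seed (default 0,
always logged).  Initialization: `rho = 0`; `p_j = 1 − U(0, 0.05)`;
`R_c = 1 + N(0, 0.01)` projected to positive mean-1; gene means and
per-line deviations uniform on [−1e-4, 0.5e-4].

The decomposition `r_cg = gene_mean_g + delta_cg` is redundant (only the
sum enters the cost); both parts are trained and only the sum is reported.

## Preprocessing

Log fold change is `log2(RPM + 1)` of a late sequence minus the same for
its pDNA batch, with multiple pDNA measurements summed per batch *before*
RPM normalization (NaNs count as 0 in the sum, with a logged warning).
Clonal outgrowths — single (replicate, guide) entries inflated by a fitness
mutant or artifact unrelated to the knockout — are masked when the entry's
LFC exceeds 2 *and* tops the next-highest LFC among the gene's guides in
that replicate by more than 2 (both log2 units, both configurable; no
published values exist for these thresholds, only the resulting masked
fraction on large datasets, ~0.02%, which our defaults reproduce on the
simulator's planted spikes).  Single-guide genes have no defined gap and
are never masked.  Masking is applied to raw counts, so every downstream
path sees it.

## Copy-number correction

Cutting toxicity depletes guides in amplified regions regardless of target,
while high copy number of an essential gene attenuates its knockout; the
response is non-monotone for essentials.  The bias is modeled post hoc, on
any gene-effect matrix with ≥ 3 cell lines, as a tensor-product cubic
B-spline surface over (copy number in log2(x+1) units, mean gene effect),
scaled per line by a weight `w_c ∈ (0, 1]`, minimizing
`Σ (r_cg − y_cg)^2 + X_w Σ (ln w_c)^2` (X_w = 0.01, configurable) by
alternating exact least squares in the spline coefficients and bounded
scalar updates in `w_c` (tolerance 1e-6, ≤ 100 rounds).  Knots: 10 linear
in copy number, 5 on the effect axis spaced exponentially after shifting so
the 1st-percentile mean effect maps to 1 (dense where effects are strongly
negative).  Copy number is clipped to its [0.1, 99.9] percentiles before
basis evaluation; genes without copy-number data are assigned normal ploidy
(value 1).

Two refinements keep the removed surface a bias rather than biology.
First, the surface is referenced to normal ploidy,
`y = w_c (S(cn, m) − S(1, m))`, so the correction vanishes exactly where
copy number is normal; second, a separate smooth 1D baseline in the
mean-effect axis is fitted jointly but never subtracted.  Without these,
least squares reproduces each gene's mean through the effect axis and the
"correction" strips real signal even when scores are independent of copy
number.  Because the effect axis should reflect biological means but only
biased means are observable, three outer passes refit the original matrix
with gene means re-estimated from the previous pass's residuals.  The
residuals are the corrected effects; correction is idempotent to well
under 1% of variance.

## Quality metrics and normalization

For interpretability a fitted matrix can be globally scaled — one affine
map for the whole matrix — so the median over lines of per-line control
medians is 0 for nonessential and −1 for essential reference genes.
Metrics: NNMD `(median(pos) − median(neg)) / MAD(neg)` with the raw
(unscaled) median absolute deviation; the unexpressed false-positive rate
(fraction of a line's unexpressed genes, expression < 0.01 in the caller's
units, ranked in its most-depleted 15% — 15% being the typical prevalence
of true dependencies); and precision-recall of essential controls against
the line's unexpressed genes, scored by negated gene effect, using standard
step-interpolated precision-recall semantics (average precision as the
area; ties share a threshold; recall at 90% precision is the best recall
among curve points with precision ≥ 0.9).  NNMD is the only metric here
that a rank-preserving transformation can change.

## The simulator

`simulate` generates screens from the same two-population mixture the
fitter assumes, which is the point: it provides ground truth for every
recovery, robustness and correction property, not a test of model
misspecification.  Defaults, chosen once as a realistic screen:

- true effects: 80% neutral, 15% essential (`r ~ N(−1, 0.2)`, i.e. growth
  arrest, matching the typical prevalence of true dependencies), 5%
  selective (essential in a random 20% of lines);
- reagents: `p_j ~ Beta(6, 2)` (mean 0.75, long left tail), `p_c ~ U(0.7, 1)`,
  `R_c ~ 1 + N(0, 0.1)` normalized to mean 1 per day;
- library: pDNA abundances lognormal (σ = 0.5), two pDNA measurements per
  batch, expected depth 500 reads per guide, NB2 noise with α = 0.05 (an
  exact-expectation mode exists for noise-free oracles);
- sampling days 7/14/21 with 2 replicates for the recovery designs: at
  per-day rates, essential-guide depletion saturates at the un-knocked
  floor `1 − p_c p_j` within ~2 weeks, so a recovery study must include a
  pre-saturation time point for magnitudes to be identifiable at all — the
  same reason multiple time points help the fitter;
- artifacts on demand: clonal spikes (default ×100 — a clone escaping its
  fitness cost regrows at the unperturbed rate, e^{R t}-fold over a screen,
  so ×100 is conservative) at a configurable entry rate, and a smooth
  copy-number bias surface `w_c f(cn, mean effect)` whose slope flips sign
  between neutral and essential genes and is non-monotone for essentials.

What the simulator does not emulate: guide-sequence-specific off-target
spectra, chromatin or cut-site effects, positional (genomic-coordinate)
correlation of the copy-number artifact, batch effects between libraries,
and real overdispersion heterogeneity.  Passing recovery tests therefore
demonstrates correctness of the inference machinery under the model's own
assumptions, not performance on any real dataset.

A note on reporting conventions for recovery metrics: guide efficacy is
statistically unidentifiable for guides whose target gene has no fitness
effect in any line (the likelihood is flat in `p_j` when `r_cg = 0`
everywhere), so efficacy recovery is summarized over guides of genes with
a true effect ≤ −0.25 in at least one line.  Where fitted matrices are
compared to truth by error magnitude, both are first aligned by the
control-based global normalization above, since single-time-point screens
identify effects only up to the scale degeneracies that normalization
absorbs.

## Known limitations

- A pDNA (or very early) measurement is required; late-only designs cannot
  be fitted.
- Conditions where most cells die (cytotoxic treatments) fall outside the
  model's assumption that untransduced growth dominates.
- Absolute effect magnitudes beyond the saturation floor are weakly
  identified from late time points; essential-gene magnitudes are reliable
  in rank but compressed in value unless early time points are included.
  Control-based normalization is the intended remedy.
- Multi-library fits share `r_cg` across libraries as the model implies,
  but this path is exercised far less than single-library fits.
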