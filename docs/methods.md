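# Methods

This note records the models, numerical choices and open design decisions
behind `phylodiv`, in the order the pipeline runs them.

## Study design and data model

The analysis contrasts fourteen sets of community phylogenies: seven barcode
supermatrices — R+M, R+I, R+I2, M+I, M+I2, R+M+I, R+M+I2, generated
programmatically from the rule {rbcL+matK} ∪ {each plastid × each ITS
variant} ∪ {both plastids × each ITS variant} — crossed with presence or
absence of a family-level backbone constraint.  Each condition carries five
0/1 indicators (rbcL, matK, ITS, ITS2, backbone) that later become the fixed
effects of the inference stage.  Diversity is estimated at the plot level on
every retained tree, giving a long table with one row per metric × tree ×
plot.

## Topology selection against the backbone

Unconstrained posterior samples are ranked by symmetric (Robinson–Foulds)
distance to the backbone and the top-*k* (default 500) kept, ties broken by
input order so the selection is reproducible.  RF is computed on unrooted,
non-trivial bipartitions.

The backbone lives at family level while the samples are species trees, and
no published rule says how to compare the two.  We condense each species
tree to its **clean family splits**: an internal edge contributes a split
if no family has members on both sides, expressed on the family label set.
A species tree on which every family is monophyletic and arranged like the
backbone reproduces exactly the backbone's splits (distance 0);
non-monophyletic families produce fewer clean splits and therefore larger
distances.  With singleton families this reduces to plain RF, which is how
the tests pin it down.  Backbone-constrained conditions skip ranking and
contribute a uniform random *k* trees, mirroring how constrained inference
already agrees with the backbone by construction.

## Ultrametric transformation

Branch lengths in substitutions/site are converted to relative time by
penalized rate smoothing.  Objective (node ages `t`, per-branch rates `r`,
observed lengths `x`, durations `d_b = t_parent − t_child`):

    F(t, r) = Σ_b (x_b − r_b d_b)² + λ Σ_(b,p∈ancestor pairs) (r_b − r_p)²

* λ defaults to 1000 — effectively a relaxed strict clock; small λ lets
  rates wander along the tree.
* Tips are fixed at age 0 and the root at age 1 (no fossil calibration is
  available, so all downstream branch lengths are relative time).
* For fixed ages, F is a positive-definite quadratic in the rates and is
  solved exactly by one linear solve; the outer problem over ages then uses
  L-BFGS-B with analytic gradients (envelope theorem).  Ages are
  parameterized as sigmoid-squashed fractions of the parent age, so
  monotonicity (and hence exact ultrametricity of the output) holds by
  construction.
* Initial ages are mean node-to-tip path lengths; restarts alternate
  between perturbing that initialization and fresh uniform age fractions.
  At λ ≥ ~10 the surface is effectively unimodal and one start suffices
  (the pipeline default); at small λ the surface is multimodal and
  `n_starts≈12` reliably reaches the optimum found by an independent
  grid-plus-polish search on small trees.
* Zero-length input branches degenerate the objective and are raised to
  1e-8 of tree height with a warning; negative lengths are an error, as is
  exhausting the iteration budget (the error carries the objective trace).

Note a consequence of root-age normalization: any *uniform* branch-length
multiplier cancels.  Condition effects that act purely as a global branch
scale are therefore invisible after smoothing; the parameter-recovery
experiment below runs the metric stage on raw generator trees (which are
ultrametric in expectation anyway), and `RunConfig.ultrametricize` exposes
the same choice to users.

## Diversity metrics

All metrics operate on a rooted tree plus one plot's abundances; communities
with fewer than two species yield NaN (flagged and logged) rather than an
exception so degenerate plots cannot kill a run.

* **PD** is root-inclusive (the spanning subtree includes the path to the
  root), the dominant ecological convention; it also keeps single-lineage
  communities defined.
* **MPD_ed** weights unordered pairs i<j by n_i·n_j; self-pairs are
  excluded (they would deflate the statistic by construction).  **MNTD_ed**
  weights each species' nearest-neighbour distance by n_i.
* **PAE** uses terminal branch lengths T_i measured on the community
  subtree with pass-through nodes suppressed (the "community phylogeny"
  reading); for a full-community plot these are simply the tree's pendant
  edges.  PAE = 1 exactly when all abundances are equal.
* **IAC** roots the community subtree at the MRCA of the present species,
  splits the community total N equally among the live daughters of every
  junction, and divides the summed absolute deviations by v, the number of
  junction nodes (≥ 2 live daughters) including the MRCA.  Polytomies split
  equally among all live daughters.
* The abundance-weighted nearest-taxon metric is reported as MNTD_ed
  (the name "MNND_ed" is treated as a synonym).

Patristic distances use d(i,j) = depth_i + depth_j − 2·depth_MRCA filled
per internal node, and are cross-checked in the tests against dendropy's
distance matrix; PD/MPD/MNTD/PAE/IAC are cross-checked against brute-force
path-enumeration oracles.

## Mixed-effects multi-model inference

Each metric's log-transformed values are fitted with all 24 subsets of the
five indicators (ITS and ITS2 mutually exclusive), always with a global
intercept and a plot random intercept.

* **ML, not REML**: models differing in fixed effects are compared by AICc,
  which REML likelihoods do not support.
* The random-intercept model is fitted exactly: fixed effects and residual
  variance are profiled out analytically, leaving a 1-D bounded search over
  the variance ratio σ²_plot/σ²_resid.  This reproduces statsmodels
  `MixedLM(reml=False)` to ~1e-6 in log-likelihood (test-verified) at a
  fraction of the cost, which is what makes the bootstrap × 24 models ×
  many seeds affordable.
* **AICc** uses k = fixed coefficients (incl. intercept) + 2 variance
  components, and n = number of rows in the metric's table.
* **R²** follows the variance-partition convention for mixed models:
  Rm² = σ²_fixed/(σ²_fixed+σ²_plot+σ²_resid), Rc² adds σ²_plot; σ²_fixed is
  the population variance of the fixed linear predictor over the data.
  Reported in percent.
* **Averaged standardized coefficients**: per term, AICc weights are
  renormalized to sum to 1 over the models containing the term, then β/SE
  is averaged with those weights.
* **Bootstrap**: records are resampled with replacement within each
  condition × plot cell (stratification preserves the balanced design; the
  source procedure says only "randomly resampled"), the full 24-model
  comparison is rerun per replicate, and 95% percentile intervals plus the
  fraction of replicates preserving the original top-ranked model are
  reported.
* Log-transform policy: values must be strictly positive; if zeros occur
  (possible for IAC, which is exactly 0 on perfectly balanced abundances),
  all values are offset by ε = half the smallest positive observation (the
  offset is configurable) with a warning.
* A term constant in the data (e.g. a single-condition table) is dropped
  from the design with a warning rather than producing a singular fit.
* All 24 models are fitted to the full 14-condition table (indicator
  coding); fitting to data subsets would confound the comparison.

## Synthetic-data generator

The generator reproduces the *structure* the analysis assumes, not any
particular empirical values:

* **True tree**: pure-birth (Yule) with 114 tips by default — fewer
  parameters than birth–death and closed-form expectations for testing
  (mean crown height Σ_{k=2}^{n−1} 1/k + 1/n at unit birth rate).
* **Families**: the tree is cut at the age where it has `n_families`
  (default 25) lineages; each tip's family is its lineage at the cut.  The
  backbone is the true tree condensed to those families.
* **Condition channels**: barcodes act through the two channels the study
  design contrasts — topology noise (Poisson-many NNI moves per tree, with
  expected count `base_intensity / Σ barcode information`, defaults 4.0 and
  info weights rbcL 1.0, matK 1.5, ITS 2.0, ITS2 1.0, so richer
  supermatrices sit closer to the truth) and branch-length multipliers
  (product of per-barcode factors, all 1.0 by default) with unit-mean
  lognormal jitter (σ = 0.15) per branch.  Backbone-constrained conditions
  restrict NNI moves to edges inside single-family clades, which
  guarantees family-level distance 0 to the backbone.
* **Communities**: two plots of 75 and 73 species sharing 34 (pooled 114,
  hence 41 and 39 unique), abundances i.i.d. geometric (p = 0.3, mean
  ≈ 3.3, support ≥ 1).
* All randomness flows from one root seed through named `SeedSequence`
  substreams; identical seeds give byte-identical outputs.

What the generator does **not** emulate: sequence-level evolution and
alignment artifacts, MCMC autocorrelation within posterior samples,
non-independence between the topology and branch-length channels, spatial
structure within plots, and detection/abundance error.  Passing tests
therefore demonstrate that the *pipeline* recovers effects injected through
the stated channels — not that real barcode data behave like the generator.

## Problem sizes used in checks

The test suite and the acceptance script scale the study down so the whole
chain stays cheap while keeping the design intact: the end-to-end recovery
experiment uses 100 trees per condition, two plots and 100 bootstrap
replicates per run (the full design otherwise); the scaled pipeline run in
the acceptance script uses 40 species, pools of 60 topologies reduced to
top-30, and 50 bootstrap replicates.  These sizes are package choices and
are recorded in each run's manifest.

## Known limitations

* The exact LMM profiling covers a single random intercept (plots); random
  slopes or crossed effects would need a different fitter.
* RF-based ranking treats trees as unrooted; a rooted backbone with fewer
  than four families carries no non-trivial splits and cannot rank
  topologies.
* With only two plots, the plot-variance component is weakly identified;
  ML estimates of σ²_plot frequently sit at 0 or inflate Rc², which is
  inherent to the two-plot design rather than to the fitter.
* The smoothing objective is least-squares, not the Poisson/penalized
  likelihood used by some chronogram tools; with λ = 1000 both approach a
  strict clock, but small-λ results are not interchangeable across tools.
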