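# phylodiv

How much do estimates of community phylogenetic diversity depend on *which*
DNA barcodes the community phylogeny was built from, and on whether tree
inference was constrained by a family-level backbone?  `phylodiv`
implements the full analysis chain for answering that question with
mixed-effects multi-model inference, for two forest plots whose species pool
was barcoded with the four core plant barcodes (*rbcL*, *matK*, ITS, ITS2).

The package is aimed at community phylogeneticists who have (or want to
emulate) posterior topology samples per barcode supermatrix and a plot ×
species abundance table, and want to quantify how barcode choice and
backbone constraints propagate into diversity metrics.

## What it computes

**Topology processing.** Posterior topology samples per condition are ranked
by Robinson–Foulds symmetric distance to an accepted family-level backbone
(species trees are condensed to "clean family splits" first), and the
top-*k* (default 500) are retained; backbone-constrained runs contribute a
random *k* instead.  Clade support is the frequency of each bipartition
across the retained sample.  Selected trees are made ultrametric by
penalized rate smoothing: minimize

    F(t, r) = Σ_b (x_b − r_b d_b)² + λ Σ_(b,p) (r_b − r_p)²

over node ages *t* and per-branch rates *r*, where `x_b` is the observed
branch length, `d_b` the branch duration implied by the ages, the penalty
runs over ancestor–descendant branch pairs and λ = 1000 by default (near
strict clock).  The root age is normalized to 1.

**Diversity metrics.** Per plot and per tree: Faith's PD (root-inclusive),
MPD and MNTD with presence/absence or abundance weighting (MPD_ed,
MNTD_ed), phylogenetic-abundance evenness

    PAE = [PD + Σ_i T_i (n_i − 1)] / [PD + (N/S − 1) Σ_i T_i],

and the imbalance of abundances among clades IAC = Σ_i |n_i − n̂_i| / v,
where n̂ splits the community total equally among daughter lineages at every
node of the community subtree and v counts its junction nodes.

**Inference.** Every log-transformed metric is modeled as

    log(diversity) = α + δ_plot + rbcL·β₁ + matK·β₂ + (ITS|ITS2)·β₃ + backbone·β₄

with a plot random intercept; all 24 term subsets (including the
intercept-only model, ITS and ITS2 never together) are fitted by exact
maximum likelihood and compared by AICc, Akaike weights and
marginal/conditional R².  Per-term standardized coefficients (β/SE) are
averaged across models with AICc weights renormalized over the models
containing the term; a stratified bootstrap (default 100 replicates) gives
95% CIs and a model-rank stability check.

**Synthetic data.** A seeded generator emulates the whole study: a Yule
species tree (default 114 species), families cut from it (default 25) plus
the condensed backbone, two plots (75 and 73 species, 34 shared) with
geometric abundances, and 14 condition-specific posterior sets in which
barcode combinations act through two channels — NNI topology noise
(less for more informative supermatrices) and branch-length multipliers.

## Worked example

Simulate a small study in which supermatrices containing ITS yield 1.3×
longer branches, then run the full pipeline (selection → metrics → 24-model
comparison) for PD and MPD:

```python
import phylodiv as pv

cfg = pv.RunConfig(
    synth=pv.SynthConfig(
        n_species=30, plot_richness=(20, 18), shared_species=10,
        n_families=8, posterior_size=40, trees_per_condition=20,
        length_multipliers={"rbcL": 1.0, "matK": 1.0, "ITS": 1.3, "ITS2": 1.0},
        seed=42,
    ),
    top_k=20, bootstrap=50, seed=42, metrics=("PD", "MPD"),
    ultrametricize=False, outdir="readme_demo",
)
out = pv.run_all(cfg)
print(out["results"]["PD"].summary(3))
```

prints

```
Multi-model inference for PD
  models fitted: 24, n = 560
  top model stable in 54% of bootstrap replicates

         model  k loglik    AICc dAICc wAICc   Rm2   Rc2
~B + M + R + I  7 1038.2 -2062.2   0.0 0.442 80.29 93.44
    ~B + R + I  6 1036.6 -2061.0   1.2 0.248 80.25 93.40
        ~B + I  5 1034.9 -2059.8   2.4 0.133 80.22 93.36

Averaged standardized coefficients (beta/SE):
    term          z  boot_mean     ci_low    ci_high
backbone  -2.514637  -2.469394  -3.831662  -0.852665
    matK  -1.666754  -1.636094  -3.035964  -0.447064
    rbcL  -2.188913  -2.278449  -4.206611  -0.755419
     ITS  81.515519  82.350154  76.919530  87.229301
    ITS2 -26.391406 -26.499216 -27.639228 -25.504673
```

The injected ITS effect dominates: every top-ranked model contains the ITS
term, the fixed effects explain ~80% of the variance in log PD (Rm²), and
the averaged standardized coefficient for ITS is large, positive, and its
bootstrap CI excludes zero.  (ITS2 picks up a strong negative contrast
because ITS2-supermatrices are exactly the ones lacking the ITS boost.)
`run_all` also writes the diversity table, per-metric model-comparison and
averaged-coefficient CSVs, clade supports, selected trees and a JSON
manifest to `outdir`.

The same stages are available from a shell:

```
phylodiv simulate --config cfg.yaml --seed 1 --out study/
phylodiv rank --trees study/pool_R+M.nwk --backbone study/backbone.nwk \
              --family-map study/family_map.csv --topk 500 --out sel.nwk
phylodiv ultrametricize --trees sel.nwk --lambda 1000 --out sel_ultra.nwk
phylodiv run-all --config cfg.yaml --out results/
```

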