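# Methods

## The analysis model

`mitofunnel` operates on normalised label-free protein abundances — the
output of upstream raw-MS processing, alignment and normalisation, which
this package deliberately does not reimplement. Abundances are assumed
strictly positive, finite and already comparable between samples within a
compartment; no additional between-sample normalisation is applied.
Because the two compartments are typically quantified as separate
experiments, **all cross-compartment comparisons use ratio-to-young
profiles** p(age)/p(young) rather than raw abundances; this removes the
per-experiment scale and makes young-age concordance exact by
construction.

The candidate funnel encodes a specific biological argument: proteins
changing the same way in synaptic and non-synaptic mitochondria track
organism-level ageing and are uninformative about synaptic vulnerability;
the interesting candidates are those whose synaptic trajectory breaks
away, particularly at old age. Hence the per-class symmetric-difference
subtraction, the concordant-then-divergent ("archetypal") profile
selection, and the final old-age fold filter.

## Statistical primitives

* **ANOVA** — one-way fixed-effects across the three age groups, per
  compartment, on ArcSinh-transformed abundances (a variance stabiliser
  behaving like log for large x but defined at 0). Degenerate
  conventions: zero within-group variance with separated means gives
  p = 0; fully constant data gives p = 1. "Zero" is judged at relative
  tolerance 1e-12 of the total sum of squares.
* **Post-hoc power** — P(F′ > F_crit(α)) under the noncentral F with
  λ = Σᵢ nᵢ(x̄ᵢ − x̄)²/MSE, clipped to [0, 1]. λ = 0 falls back to the
  central F (scipy's noncentral F is numerically unreliable at zero
  noncentrality). Zero within-variance gives power 1 when means differ,
  α when they do not. This is the standard observed-effect power of a
  fixed-effects one-way ANOVA; the upstream software that inspired the
  filter does not document its own formula.
* **Fold change** — max/min over the three group means, on the raw
  (untransformed) abundance scale.
* **Fisher exact / BH-FDR / t-tests** — delegated to scipy
  (`hypergeom.sf`, `ttest_ind`) and statsmodels (`multipletests`);
  the t-test is pooled-variance by default with Welch behind a flag.
* **Activation z** — (n_consistent − n_inconsistent)/√N against a
  user-supplied signed regulator→target network; no proprietary
  knowledge base is bundled, targets absent from the data are ignored,
  and z is reported as missing when no target is observed.

## Correlation graphs and MCL

Edges require Pearson r ≥ the threshold (default 0.96) on signed r, so
anti-correlated profiles never connect. Rows whose standard deviation is
below 1e-9 of their mean magnitude are treated as zero-variance
(constant rows computed from large baselines carry ~1e-16 relative
rounding noise), excluded from correlation with a warning, and kept as
isolated nodes — they become singleton clusters downstream.

MCL runs per connected component (MCL can never merge disconnected
components, and this keeps the dense iteration small). Per component:
self-loops at the node's maximum incident weight (1 for isolated nodes)
stabilise convergence; then expansion (matrix power 2), inflation
(elementwise power 2.2 + column renormalisation) and pruning (entries
< 1e-6 zeroed, renormalised) repeat until the maximum absolute change is
below 1e-8, with failure declared after 200 iterations. Clusters are read
off the limit matrix via attractors (nodes with positive diagonal);
attractors sharing mass merge into one system; every other node joins the
attractor holding the largest weight in its column, with exact ties
resolved to the system containing the smallest node index — deterministic
and seed-free. Correlation weights are the transition mass by default;
`mcl_weighted=False` gives the unweighted variant. Increasing inflation
usually, but not provably, refines the clustering; the test suite checks
the trend on average and logs individual reversals as a known MCL caveat.

One structural property worth knowing: under Pearson similarity, a
late-stage profile (1, 1, a) and a stronger late-stage profile (1, 1, b)
are *exactly* affinely related and therefore correlate at r = 1. On
noiseless data the planted divergent-at-old-age class consequently merges
with the late-stage class in the synaptic graph. This is a property of
correlation clustering, not an error; the funnel's subtraction and
divergence filters still separate the two classes exactly.

## Pipeline decisions

* **Filter direction** — the filters are applied as keep-rules:
  power ≥ 0.8 AND fold change ≥ 1.2 AND p ≤ 0.05 (feature filter);
  unique peptides ≥ 2 AND p ≤ 0.05 (protein filter). Boundaries are
  inclusive on the keep side.
* **Either-compartment retention** — a protein is retained when it passes
  the combined filter in *at least one* compartment. Candidates that
  diverge only in synaptic mitochondria are, by definition, unremarkable
  in the non-synaptic compartment; requiring both compartments to pass
  would delete exactly the proteins the funnel exists to find.
* **Trend granularity** — trends are classified at cluster level (each
  protein inherits its cluster's label), with a per-protein mode behind
  `per_protein_trends=True` since cluster granularity depends on MCL
  settings. The trend rule replaces by-eye cluster selection with a
  deterministic band rule (ε = 0.2, matching the 20% materiality
  threshold used elsewhere in the pipeline).
* **Subtraction scope** — per trend class by default ("altered in the
  same manner"); `pooled_subtraction=True` pools the four classes first.
* **Archetypal thresholds** — mid-age concordance band τ = log₂ 1.5;
  old-age demarcation is a fold threshold (> τ for archetypal, ≥ the
  2-fold `divergence_fold` for the final set), not a statistical test.
* **Ordering** — protein order follows the input everywhere; subtraction
  output is sorted by id; cluster and component lists are ordered by
  smallest member. Outputs are byte-reproducible given config + seed.

## The synthetic generator

The generator emulates the pooled-replicate study design: 2 compartments
× 3 ordered ages × 3 technical replicates (configurable). Baselines are
log-uniform over (1e3, 1e6), spanning the dynamic range of label-free
normalised abundances. Planted classes and their per-age mean
multipliers (effect size e = 1.5, divergent fold d = 2.5 by default):

| class          | non-synaptic  | synaptic            |
|----------------|---------------|---------------------|
| flat           | 1, 1, 1       | 1, 1, 1             |
| steady_up/down | 1, e, e² (or inverses) | same        |
| late_up/down   | 1, 1, e (or inverse)   | same        |
| divergent_old  | 1, 1, 1       | 1, 1, d (sign alternating by index) |

Noise is multiplicative log-normal, abundance = mean · exp(N(0, σ²)),
σ = 0.1 by default — label-free abundances are positive and
heteroscedastic, so a log-scale noise model is the natural choice.
Unique-peptide counts are uniform on 2–20 with a 5% single-peptide subset
to exercise the protein filter. Optional per-replicate "biological"
variance is off by default (the emulated design pools animals into
technical replicates). Class sizes use largest-remainder apportionment;
identical seeds give bit-identical output.

What the generator does **not** emulate: missing values, peptide-level
structure, retention-time artefacts, correlated noise between proteins,
or batch effects. Passing the recovery tests therefore demonstrates that
the funnel logic is correct and well-calibrated under its own
assumptions, not that real datasets will yield comparable sensitivity;
real-data cluster counts and funnel sizes depend on noise structure the
simulation does not model.

## Problem sizes and verification

The test suite verifies each primitive against an independent oracle
(scipy's one-way ANOVA, a 50,000-replicate Monte-Carlo power simulation,
a full hypergeometric tail-sum sweep over all enrichment tables with
background ≤ 60, a reference step-up FDR, and a separately coded
pure-Python MCL), checks exact recovery of planted structure on
noiseless data, and measures divergent-class sensitivity/precision ≥ 0.9
at the default study conditions (2,000 proteins, noise 0.1, 20 seeds).
`scripts/acceptance.py` recomputes all headline quantities at those same
sizes in well under a minute. Sizes were chosen so the full cycle runs
comfortably on a single CPU while keeping Monte-Carlo standard errors an
order of magnitude below the asserted tolerances.

## Known limitations

* The ANOVA is one-factor (age) per compartment; a two-factor
  age × compartment model is out of scope.
* MCL cluster counts are sensitive to pruning and self-loop choices;
  settings are recorded in the manifest but no attempt is made to match
  any particular historical cluster-count range on real data.
* The archetypal and fold filters act on point estimates of group means;
  replicate uncertainty is not propagated past the ANOVA stage.
* With three replicates per group the post-hoc power estimate is itself
  noisy; it is used as a screening heuristic, as in the original
  filtering convention, not as a design calculation.
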