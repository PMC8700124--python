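# mitofunnel

Temporal candidate prioritisation for mitochondrial subpopulation
proteomes.

Synapses are disproportionately vulnerable to ageing, and mitochondria
resident in presynaptic terminals age differently from those in the cell
body. Given label-free proteomic timecourses of **synaptic** and
**non-synaptic** mitochondria across three ordered ages (young, mid, old),
`mitofunnel` identifies proteins whose expression diverges *specifically*
in aged synaptic mitochondria — the candidates most likely to regulate
age-dependent synaptic stability. It is written for proteomics and systems
biologists who have normalised protein-abundance matrices (one per
compartment, replicates per age group) and want a reproducible,
parameterised version of the correlation-network candidate funnel.

## Method

Starting from the common proteins of the two compartments, the pipeline:

1. **Filters** proteins statistically: a one-way fixed-effects ANOVA
   across age groups on ArcSinh-transformed abundances
   (arcsinh x = ln(x + √(x²+1))), its post-hoc power from the noncentral
   F distribution with λ = Σᵢ nᵢ(x̄ᵢ − x̄)² / MSE, and the max/min
   group-mean fold change. Kept: power ≥ 0.8, fold change ≥ 1.2,
   p ≤ 0.05, and ≥ 2 unique peptides (in at least one compartment).
2. **Clusters** each compartment's protein co-expression graph — edges
   where Pearson r ≥ 0.96 — with an in-house **Markov Cluster (MCL)**
   implementation (expansion 2, inflation 2.2): alternating matrix
   squaring and elementwise inflation of a column-stochastic transition
   matrix until a near-idempotent limit whose attractors define disjoint
   clusters.
3. **Labels trends** from each cluster's mean (young, mid, old) profile:
   with r₁ = mid/young, r₂ = old/mid and band ε = 0.2, clusters are
   `steady_up/down` (both steps beyond 1±ε) or `late_up/down` (flat then
   a late step), else `other`.
4. **Subtracts** proteins altered in the same manner in both
   compartments (per-class symmetric difference): concordant changes are
   correlates of normal ageing, not synaptic vulnerability.
5. **Selects archetypal profiles** on ratio-to-young profiles
   p(age)/p(young): concordant across compartments at mid age
   (|log₂ ratio| ≤ log₂ 1.5) with a demarcation at old age, then applies
   a final **≥ 2-fold old-age** cross-compartment filter.

A synthetic-data generator plants these exact trend classes (plus a
`divergent_old` class that is flat in non-synaptic mitochondria and jumps
at old age in synaptic ones) under multiplicative log-normal noise, so
every stage can be validated against ground truth. QC statistics —
compartment-marker t-tests, Fisher-exact term over-representation with
BH-FDR, and signed-network activation z-scores — round out the toolkit.

## Worked example

```python
import mitofunnel as mf

cfg = mf.SimConfig(n_proteins=500, seed=3)           # 2 x 3 x 3 design
matrix, truth = mf.generate_dataset(cfg)
result = mf.run_funnel(
    matrix.subset_compartment("synaptic"),
    matrix.subset_compartment("non_synaptic"),
)
print(result.counts)
```

prints

```
{'input_synaptic': 500, 'input_non_synaptic': 500, 'common': 500,
 'retained': 210, 'trend_labelled': 209, 'subtracted': 59,
 'archetypal': 42, 'final': 42}
```

Of 500 simulated proteins, 210 pass the statistical filters (the planted
flat majority is removed), 59 survive the cross-compartment subtraction,
and 42 show the archetypal concordant-then-divergent profile with a
≥ 2-fold old-age divergence. Against the planted truth (45 divergent
proteins), that is sensitivity 0.93 at precision 1.00:

```python
planted = set(truth.index[truth["class"] == "divergent_old"])
final = set(result.final_candidates)
print(len(final & planted) / len(planted))   # 0.933...
```

The same pipeline runs from the shell:

```sh
mitofunnel run-all --simulate --n-proteins 500 --seed 3 --out run/
```

which writes the per-protein candidate table (`candidates.tsv`), filter
statistics, GraphML sample graphs, MCL memberships, a funnel summary and
a provenance manifest.

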