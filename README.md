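# bayescce

Semi-supervised estimation of cell-type composition from heterogeneous
DNA-methylation data, without sorted-cell reference methylomes.

## The problem

A methylation array measured on a complex tissue such as whole blood
yields a matrix **O** (m CpG sites × n samples) of beta values in
[0, 1].  Each observed value is a mixture of the cell-type-specific
methylation levels of the constituent cell types, weighted by the
sample's cell proportions:

    O_ji = M_j· R_iᵀ + S_j· X_iᵀ + ε_ji,   ε_ji ~ N(0, σ²)

with **M** (m × k) the cell-type-specific mean methylomes (entries in
[0, 1]), **R** (n × k) the cell proportions (rows on the probability
simplex), and optional covariate effects **S Xᵀ**.  Cell composition is
the dominant confounder in epigenome-wide association studies and is
interesting in its own right, but counting cells directly is costly and
often impossible for archived samples.

Reference-based deconvolution needs sorted-cell methylomes that exist
for few tissues and rarely match the study population.  Reference-free
factorizations (NNMF and relatives) are *non-identifiable*: for any
fitted (M̂, R̂) there is a transformed pair (M̂Q⁻ᵀ, R̂Q) with exactly
the same objective that still satisfies every constraint — so each
recovered component is some linear combination of cell types.  The
package ships an executable construction of this transform
(`construct_equivalent_solution`).

## The method

The estimator resolves the ambiguity with a weak, easily obtained piece
of prior knowledge: a Dirichlet distribution on cell composition,
fitted by maximum likelihood to cell counts from any previous study of
the tissue (no methylation needed; `fit_dirichlet_mle`).  Built-in
whole-blood priors cover six leukocyte types and a three-type
simplification.

Fitting works in a sparse low-rank basis: the t most
composition-informative sites are selected and their first d principal
components (loadings L, scores P) computed.  With a column of ones
appended to both factors, the estimator minimises

    (1/2σ²) ‖Õ − L_aug A (P_aug V)ᵀ − L_aug B Xᵀ‖²_F
        − Σ_h (α_h − 1) Σ_i log (P_aug V)_ih

over the small transformation matrices A, V, B, subject to every
proportion ≥ ε = 10⁻⁴, row sums within 5% of 1, and profile entries in
[0, 1].  The result is one component per cell type — correlated with
the true proportions, though without anchoring only up to affine scale.
When cell counts are measured for even ~15 samples, a two-stage convex
variant (`fit_bayescce_impute`) fixes the profiles from those samples
and ties their fitted rows to the measurements within a 1% slack,
making all estimates absolute and the cell-type assignment automatic.

## Worked example

`python examples/02_deconvolve_with_prior.py` simulates 300 whole-blood
samples at 2000 sites (three cell types, technical noise sd 0.01),
refits the prior from 50 external samples, and deconvolves:

```
prior refitted from 50 samples: Granulocytes=8.04, Monocytes=0.93, Lymphocytes=3.02
fit converged=True, objective 2040459 (started at 2134600), sigma2=1.31e-03
 component      |r|      MAE       R2
0->2         0.9868   0.2682   0.9974
1->1         0.9942   0.0078   0.9911
2->0         0.9974   0.2184   0.9980
      mean   0.9928   0.1648
mean absolute correlation with the truth (MAC): 0.993
raw principal components alone reach MAC 0.654
```

Each fitted component correlates |r| ≥ 0.987 with exactly one true cell
type (the `0->2` column shows the recovered assignment), versus 0.654
for the raw principal components, which mix cell types.  The large MAE
on two components reflects the unanchored scale; running
`examples/03_impute_cell_counts.py` adds measured counts for 15 of 300
samples and drops the held-out mean absolute error to 0.017 with every
anchored row within the 1% measurement slack.

The other examples cover simulation (`01`), imputation (`03`), the
non-identifiability transform (`04`) and prior fitting (`05`).  A thin
CLI wraps the same pipeline:

```sh
bayescce simulate --k 3 --m 2000 --n 300 --out sim/
bayescce fit --data sim/beta_values.tsv --prior sim/alpha_true.tsv \
             --k 3 --d 6 --truth sim/R_true.tsv --out fit/
```

Every run writes a JSON manifest with the configuration, seed and
SHA-256 checksums of all inputs and outputs; seeded runs are
bit-reproducible.

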