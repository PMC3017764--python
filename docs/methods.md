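# Methods

This note documents the statistical model, the estimation algorithms, the
synthetic data generator, and the numerical choices made in `mixde`.

## 1. Design and data model

A study comprises `n_chips` chips, each carrying `n_arrays_per_chip` arrays;
every array hybridises two samples labelled with a red and a green dye. A
*channel* is one (chip, array, dye) combination; the default 4 × 4 × 2 layout
yields 32 channels. Samples come from a roster of eleven animals (four
polled, three horned, four scurred; six male, five female), paired round-robin
so that no chip carries a single phenotype and each multiply-used animal sees
both dyes (dye swap). Each channel measures every probe once.

A spot reading consists of foreground mean and median and background mean
and SD. Quality control keeps a spot when

* signal-to-noise `s = (fg_mean − bg_mean) / bg_sd > 1` (strict), and
* mean–median agreement `r = min(fg_mean, fg_median) / max(fg_mean,
  fg_median) ≥ 0.85` (the boundary is kept by default; `r_strict=True`
  switches to a strict inequality), and
* the background-corrected intensity is positive (its log2 is the response).

A non-positive or zero-variance background fails the spot outright. Failed
spots are excluded from modelling; in written tables they are printed as 0.

## 2. Linear mixed model

For the log2 background-corrected intensity `y` of gene *g* in channel *c*:

```
y = C_c + G_g + AG_{a(c),g} + DG_{d(c),g} + HG_{h(c),g} + SG_{s(c),g} + e
```

* `C` — fixed comparison (channel) effects, 32 levels, cell-means coding
  (the grand mean is absorbed; it is reported as the mean of the channel
  effects, with per-channel deviations alongside).
* `G` — random gene effects, variance `var_g`.
* `AG` — array-position (1..`n_arrays_per_chip`) × gene, variance `var_ag`.
* `DG` — dye × gene, variance `var_dg`.
* `HG` — phenotype × gene (3 levels per gene), variance `var_hg`. The HG
  BLUPs are the phenotype expression profiles used downstream.
* `SG` — sex × gene, variance `var_sg`.
* `e` — residual, variance `var_e`.

All random factors are independent with homogeneous variances across genes.

### Estimation

Variance components are estimated by REML. Because every random effect is
gene-indexed, the mixed-model-equation coefficient matrix is an *arrowhead*:
32 fixed-effect columns coupled to independent per-gene blocks (1 + A + 2 +
3 + 2 = 12 rows per gene at defaults). Each solve forms the 32 × 32 Schur
complement `S = A − Σ_g B_g D_g⁻¹ B_gᵀ`, factorises it by Cholesky, and
back-substitutes per gene. The per-gene inverse blocks
`(M⁻¹)_gg = D_g⁻¹ + T_gᵀ S⁻¹ T_g` give exactly the traces needed by EM-REML
and the HG prediction-error covariance (PEV) blocks. Cost is linear in the
number of genes.

Each REML iteration computes two candidate updates — the EM-REML update
(guaranteed uphill) and an average-information (AI) Newton step built from
working vectors `f_k = Z_k u_k / σ²_k` — evaluates the restricted
log-likelihood of both, and accepts the better one. The accepted
log-likelihood path is therefore monotone while converging at Newton speed
near the optimum. Components are truncated at `min_variance = 1e-10`
(effectively zero; reported as boundary components). Convergence requires a
relative parameter change below `tol = 1e-6` or a log-likelihood change
below `1e-8`; the iteration cap is 200.

### Contrast statistics

For genes and a phenotype pair (A, B), the statistic is

```
t = (HG_A − HG_B) / sqrt(PEV_AA + PEV_BB − 2 PEV_AB)
```

using the per-gene HG PEV block. Under no differential expression these
statistics are approximately standard normal; shrinkage and the shared
`var_hg` nuisance variance make the null SD near — not exactly — one.

## 3. Two-component mixture and FDR

Per contrast, the statistics are modelled as a mixture of two normals fitted
by EM (tolerance 1e-8 on the log-likelihood, up to 2000 iterations). Five
starts are used: the first splits the data at the 90th percentile of the
absolute statistics; the rest jitter that split. Starts that collapse to a
degenerate component (vanishing weight or variance) are discarded; if all
collapse, a `MixtureConvergenceError` is raised. The component with mean
nearest zero (ties to the smaller variance) is labelled null.

Genes are ranked by the posterior probability of the non-null component; the
declared DE set is the largest prefix whose estimated FDR — the mean of
(1 − posterior) over the prefix — stays below the target (1% by default).
An empty selection is a valid outcome. Signed fold change is `2^d` for a
log2 difference `d ≥ 0` and `−2^(−d)` otherwise.

## 4. Probe annotation rules

Given probe alignments (0-based half-open intervals), bovine and human gene
models with exon structure, and best-hit BLAST names:

1. A probe overlapping a bovine **exon** of a non-provisional (not LOC/MGC)
   gene takes that gene's name; among several, the lowest accession wins
   (numeric comparison after the alphabetic prefix, lexicographic fallback).
2. Otherwise an overlapping human gene name is used (lowest accession on
   ties). A provisional bovine name with no human alternative is retained.
3. With no overlap at all, the nearest gene on the probe's chromosome is
   assigned (bovine models first; human models only when the chromosome has
   no bovine gene); ties in gap distance break by lowest accession.
4. A best BLAST hit disagreeing with a step-1/2 name flags the probe for
   manual curation (the overlap-derived name is retained). Step-3 names are
   never flagged: a nearest-gene guess carries no overlap evidence to
   contradict.

Strand is ignored throughout.

## 5. qPCR ΔΔCt model

Ct readings for one target and one reference gene in two phenotype groups
are fitted by ordinary least squares with cell-means coding of the four
(phenotype, gene) cells and no intercept. ΔΔCt is the contrast
`CE1 − CE2 − CE3 + CE4` (target cells minus reference cells, first phenotype
minus second); its SE and two-sided p-value come from the t-distribution of
the linear contrast. In a balanced design per-animal effects shared between
target and reference cancel exactly in this difference of differences.
Technical replicates enter as observations by default;
`average_technical=True` averages them per (animal, gene) first — the
estimate is unchanged in balanced designs, only the residual degrees of
freedom differ. Fold change is `2^(−ΔΔCt)`, negated-reciprocal below 1.

## 6. Synthetic data generator

The generator is a first-class component: it draws every model term from the
mixed model above, so the fitted model is correctly specified for its data.

Key `SimulationConfig` parameters (defaults define the reference study):

| parameter | default | role |
|---|---|---|
| `n_chips`, `n_arrays_per_chip`, `n_dyes` | 4, 4, 2 | 32-channel layout |
| `n_probes` | 2000 | genes per array |
| `mu` | 7.4 | grand mean log2 intensity |
| `c_effect_sd` | 0.3 | spread of fixed channel effects |
| `dye_bias` | 0.93 | green − red channel offset (split ± half) |
| `var_g`, `var_ag`, `var_dg`, `var_sg` | 1.0, 0.05, 0.05, 0.05 | random components |
| `var_hg` | 0.005 | phenotype×gene nuisance variance |
| `var_e` | 0.1 | residual variance |
| `de_fraction`, `de_effect_size` | 0.05, 1.5 | planted DE probes (one phenotype shifted ±1.5 log2, random sign) |
| `background_mean`, `background_sd_scale` | 80, 5 | spot background model |
| `bad_spot_fraction` | 0.05 | engineered QC failures |

Engineered failures alternate between inflated background SD (driving
`s = 0.5`) and a halved foreground median (driving `r = 0.5`), so both QC
rules are exercised. The truth table records each probe's per-phenotype
planted offsets and which of the three contrasts are affected.

`var_hg` was calibrated at design time: it is the variance of *real but
uninteresting* phenotype-by-gene differences shared by every gene, and its
default is set comparable to the per-contrast PEV so that planted 1.5-log2
effects are separable at the 1% FDR target. A much larger value would make
every gene genuinely phenotype-different, which blurs the notion of a
"null" gene rather than stressing the pipeline.

The qPCR generator draws per-animal effects (`animal_sd`, default 0.25)
shared between target and reference plus replicate noise (`noise_sd`,
default 0.3); the planted truth is a per-phenotype Ct offset on the target
gene, so the true ΔΔCt of a contrast is the offset difference. Annotation
fixtures are twelve deterministic probes covering every rule branch (plus
filler probes), with a seed-dependent coordinate shift that leaves all
branch decisions invariant.

### Validation-harness conditions

* REML recovery runs at `de_fraction = 0` so the generating model coincides
  with the fitted model (planted fixed-size effects would inflate `var_hg`
  by construction, as visible in the README example).
* ΔΔCt type-I calibration runs at `animal_sd = 0` because the minimal
  phenotype+gene+interaction GLM is nominally calibrated only under its own
  assumptions; the default generator keeps realistic animal effects.
* Mixture FDP control is assessed on directly simulated 90/10
  N(0,1)+N(4,1) statistics where per-observation truth is exact.

## 7. Numerical choices

* Arrowhead (Schur-complement) MME solves: exact, O(genes) per iteration,
  validated against a dense GLS solve to 1e-8 relative error.
* Log-determinants accumulate per-gene Cholesky factors plus the Schur
  complement factor; `−2 l_R = (n−p) ln σ²_e + Σ_k q_k ln σ²_k + ln|M| +
  y'Py` up to a constant.
* EM step guarantees monotonicity; AI step supplies quadratic convergence;
  acceptance is by explicit likelihood comparison, so the path is monotone.
* Mixture EM densities are floored at 1e-300 before logs; component
  variances are floored relative to the data variance to detect collapse
  rather than mask it. Constant input raises immediately.
* All randomness flows through `numpy.random.default_rng` seeds; the
  pipeline fans a single seed into fixed per-stage offsets, and same-seed
  runs are bit-identical (checksummed manifest).

## 8. Limitations

* The generator shares the fitted model's form; it does not simulate scanner
  artefacts, spatial correlation on the array, saturation, or
  intensity-dependent (banana-shaped) dye bias, so QC and normalisation are
  tested against clean parametric failure modes only.
* Variance components are homogeneous across genes; no gene-specific
  residual variances are modelled or estimated.
* The mixture is exactly two normal components per contrast; asymmetric DE
  (up and down) is captured only through a wider non-null component, and the
  null SD is near but not exactly 1 under shrinkage.
* The ΔΔCt model ignores amplification-efficiency differences between genes
  (the classical assumption of efficiency ≈ 1).
* Annotation operates on supplied interval tables at fixture scale with
  linear scans; it is not an interval-tree implementation for genome-scale
  inputs, and strand is deliberately ignored.
* Published genome-scale DE counts depend on unavailable raw scans and
  external databases and are out of scope; reproduction is limited to the
  validation arithmetic and property-based guarantees.
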