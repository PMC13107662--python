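# Methods

## Model and assumptions

The framework treats "is signature S activated or inhibited with respect to
the phenotype?" as a meta-analysis problem. Every (scorer × association
test) pipeline is regarded as one noisy, biased measurement of the same
directional hypothesis; no pipeline is trusted individually. Assumptions:

- expression matrices are complete (no missing values) and comparable
  within each dataset; cross-dataset calibration is *not* required because
  datasets are only combined at the p-value level;
- in differential mode each class has ≥ 2 samples; in correlative mode the
  state vector is non-constant and n ≥ 5;
- pipelines within a dataset are statistically dependent (they share the
  data). The combiners assume independence, so combined p-values are
  anti-conservative in absolute terms. The framework uses them as a
  *ranking* statistic (DI), not as calibrated significance claims — DI
  magnitudes are "orders of magnitude of accumulated one-sided evidence",
  comparable between signatures within a run, not family-wise error rates.

## Pipeline layer

**Unsupervised scorers (21).** Signature × sample score matrices. Contracts
worth noting:

- `zscore`: per-gene standardization, set sum / √n. `viper` is the
  one-tailed quantile-transform analogue (Φ⁻¹ of per-sample quantiles);
  gene sets carry no regulation modes or likelihoods, so this is a
  deliberately simplified aREA.
- `plage` / `pca`: first right singular vector (resp. first PC coordinate)
  of the standardized set submatrix. SVD signs are arbitrary, so both are
  oriented to correlate non-negatively with the set's mean expression
  profile — direction matters downstream.
- `ssgsea`: weighted KS running-sum with weight = rank^0.25 (rank value N
  for the highest-expressed gene), score = sum of the running difference,
  no cohort normalization by default. `gsva`: Gaussian-kernel ECDF per gene
  (bandwidth sd/4), symmetric rank statistic |N/2 − rank|, τ = 1, ES = max
  positive + max negative deviation (signed-sum convention).
- `aucell`: area under the set-recovery curve over the top ⌈0.05·N⌉ ranks
  (the top-5 % default used for sparse single-cell data), normalized by
  the maximal achievable area; ties broken by stable input order. `ucell`:
  Mann–Whitney U on ranks capped at 1500. `singscore`: mean set rank
  rescaled to [0, 1] by its theoretical extremes (unsigned-set convention).
- `ulm`/`mlm`: t-statistics of membership regression coefficients,
  univariate or joint; `udt`/`mdt`: unnormalized impurity reduction from
  depth-3 trees (min leaf 5). Joint methods (`mlm`, `mdt`) are auto-disabled
  when the membership design matrix has VIF > 10 (perfectly overlapping
  signatures make their coefficients unidentifiable).
- `wmean`/`wsum` and their permutation variants: unit weights; `norm_*` is
  a z-score against 100 seeded gene-label permutations; `corr_*` multiplies
  the statistic by −log10 of the permutation p (floored at 1/(n_perm+1)).

**Supervised methods (2).** Gene-level association statistics feed a signed
ranking, −log10(p) × log2FC in differential mode (log2FC = group mean
difference on an assumed-log2 scale; set `linear_scale: true` to apply
log2(x+1) first) and −log10(p) × r (slope for the linear model) in
correlative mode. `fgsea` runs the classic preranked walk (|stat| weights,
p = 1) against a same-size random gene-set null — enumerated exhaustively
when there are at most `n_perm_fgsea` distinct sets, which makes the toy
p-values exact. `ora` builds direction-specific top-k lists (k = 1000 by
default; ranked by ascending p per direction in differential mode, by
coefficient magnitude in correlative mode) and computes one-sided
hypergeometric tails directly, so it needs no two-to-one conversion.

**Registry count.** The scorer registry deliberately contains both `median`
and `mean` single-sample summaries; the arithmetic mean completes the
registry at 21 unsupervised + 2 supervised = 23, which is what the
138/230/368 pipeline arithmetic requires.

## Directional aggregation

Two-tailed p-values are split by effect sign (`two_to_one`); exact ties
(direction 0) are routed as non-negative, which returns the information-free
(0.5, 0.5) at p = 1. The identity p_act + p_inh = 1 holds exactly.

Combination order: each of the 12 combiners merges the per-direction lists
over all pipelines *within* a dataset; the per-combiner results are then
geometric-mean combined *across* datasets; the log transforms and the
average over combiners happen last. This keeps every combiner at the
dataset level and uses only the geometric mean where datasets meet.

Numerical choices:

- p-values are clamped to [1e−300, 1−1e−16] before combination and to
  [1e−300, 1] after, keeping every DI finite (a clamped one-sided p of
  1e−300 contributes at most 300 to ADI/|IDI|).
- `sump` (Edgington's additive method) uses the exact Irwin–Hall tail for
  k ≤ 30; beyond that the alternating sum is numerically catastrophic in
  float64 and the N(k/2, k/12) limit is used instead (its error is far
  below any tolerance at that k).
- `meanp` uses the stated normal form z = (0.5 − p̄)√(12k) for k ≥ 4 and
  falls back to the exact Irwin–Hall form for smaller k, where the normal
  approximation is badly calibrated (and k = 1 then reduces to the
  identity).
- `meanz` studentizes the normal scores (t with k−1 df); a degenerate
  sd = 0 resolves by the sign of the mean. Note the studentized form is
  *not* monotone in each input — decreasing one p can inflate the spread
  faster than the mean — so the monotonicity property asserted for the
  other combiners genuinely does not apply to it (nor to the step-function
  `votep`).
- `invt` uses ν = 100 df (effectively normal); `votep` counts p ≤ 0.5;
  `wilkinsonp` uses r = 1 (minimum p, Beta(1, k) tail). All configurable.
- the geometric mean is a descriptive summary, not a calibrated test, and
  is exempt from the null-uniformity property.

The moderated two-group test pools variances across the rows of whatever
matrix it is given (all signatures of one score matrix at the score level;
all genes at the gene level), using the standard empirical-Bayes scaled-F
prior fitted by method of moments; with fewer than 3 rows there is nothing
to pool and it reduces to the ordinary pooled t. Agreement with the
reference Bioconductor implementation on a 40 × 12 fixture: max |Δt| 0.045,
max |Δp| 0.005 (asserted in the suite via an Rscript oracle).

Rank ties in the final table break by ADI, then by signature name, making
output order deterministic. Determinism generally: every stochastic step
derives its seed from the run seed and stable string keys (CRC32), so
identical inputs + seed reproduce tables bit-identically and dataset order
is irrelevant.

## Robustness protocol

Seven scenarios plus an extreme stress test, each a seeded
perturb → rerun → Pearson-consistency loop against the unperturbed DI
vector: random exclusion of 3 datasets; removal of 30 % of genes
(independently per dataset); Gaussian noise (sd ~ U[0.05, 0.2], perturbed
fraction ~ U[0, 1], drawn per dataset; first half of repetitions additive,
second half multiplicative; zero-thresholded); removal of 30 % of scorers;
removal of 4 of the 12 combiners; per-scorer and per-combiner single-method
cycles; and the extreme scenario (remove 70 % of genes, then noise with
mean 1, sd ~ U[1, 2], fraction ~ U[0.5, 1]). The matched baseline runs each
scorer alone on one randomly chosen dataset under the same extreme
perturbation.

Robustness reruns disable the signature-coverage gate (`min_set_coverage`
is forced to 0): the protocol deliberately evaluates a *fixed* signature
panel on degraded data, and under 70 % gene loss every signature would
otherwise fall below any sensible coverage threshold, leaving nothing to
compare. In ordinary screening runs the gate defaults to 0.5 — signatures
with under half their genes present in a dataset are excluded from that
dataset and combined over the rest.

## Synthetic data

The cohort generator emulates the framework's training inputs: per dataset,
gene baselines N(μ_g, σ_g) with μ_g ~ U[2, 10], σ_g ~ U[0.5, 1.5]; planted
signatures occupy disjoint gene blocks shared across datasets; binary mode
shifts member genes by ±δ·σ_g in the activation group, continuous mode
gives them slope δ·σ_g per unit of a standardized latent state (emitted
with observation noise sd 0.1 as the annotation); optional Bernoulli
dropout zeroes entries for single-cell-like sparsity. Decoy signatures are
unshifted blocks. Gaussian gene noise is used throughout — matching the
additive/multiplicative Gaussian design of the robustness protocol — so
passing tests say nothing about negative-binomial count noise, batch
effects, or gene–gene correlation beyond the planted blocks; that is the
main gap between these fixtures and real cohorts.

The drug-panel generator plants, for each true drug, an exclusive gene
module responding (loading δ, default 2, protocol 3) to a per-line
susceptibility factor; sensitivity (IC50-like, higher = resistant) is a
decreasing monotone function of that factor plus noise (sd 0.1). The factor
is a standardized *evenly spaced grid* over the lines rather than a
Gaussian draw: the top-vs-bottom-quartile contrast is then a deterministic
≈ 2.6 sd, which makes derivation power reproducible across seeds. Baseline
dispersions are log-uniform on [0.25, 2.5] — a realistic spread that also
keeps the moderated test's variance prior diffuse, so the module's
factor-inflated variance is not shrunk into spuriously large t-statistics
under arbitrary contrasts. Decoy drugs get sensitivities independent of
expression; the median decoy's derived signatures overlap the planted
module at chance level.

**A structural caveat on consensus screening.** With 20 lines the
stratification uses 5-line extremes, and a random split aligns with the
planted susceptibility gradient strongly enough to lift module genes into a
decoy's top-100 lists with a few percent probability per decoy. Such a
"clone" decoy carries genuine module genes; its screen scores track the
true drug's almost perfectly across independent experiments, and no
downstream design can separate it (the benchmark records this: top-k
consensus sets contain the true drug in every seed but stay singleton in
only a minority). Suppressing clones entirely would require constraining
decoy sensitivities against the planted gradient — i.e. giving up their
independence. The package therefore reports both the consensus-contains and
consensus-equals rates.

## Drug screen

Per drug, lines with measurements (≥ 12 required) are ranked by descending
sensitivity; the top and bottom floor(0.25·n) (min 2) form the resistant
and sensitive strata — proportions of the ranking, never value thresholds,
so any monotone transform of the measurements leaves the result unchanged.
Moderated differential expression resistant-vs-sensitive yields Drug_R (top
100 up-regulated, ascending p, ties by |effect|) and Drug_S (top 100
down-regulated); the two lists are disjoint by construction. The screen
attaches single-sample ssGSEA scores of a phenotype signature as each
dataset's continuous state, runs the correlative screener over all
Drug_S/Drug_R signatures with a reduced registry (GSVA-, ssGSEA-, z-score
scorers × Pearson/Spearman/Kendall), and ranks drugs by
score = orientation · (DI(Drug_S) − DI(Drug_R)) — the symmetric statistic
honoring both required correlation signs; top-k defaults to 35. Consensus
over experiments is the intersection of top-k sets.

## Benchmark problem sizes

Fixed in `metascreener.protocols` so results are comparable across runs:
planted-signal recovery uses 5 datasets of 1000 genes × 100 samples, ten
30-gene signatures (one +, one −, eight decoys), δ = 2, with a
reduced-but-representative 9-scorer registry (rank-, standardization-,
summary- and model-based families plus both supervised methods) × 3
association tests per mode; the robustness comparison uses 3 datasets of
400 × 60 with a 4-scorer × 2-test registry and 10 repetitions; the drug
benchmark uses a 20-line, 50-drug panel on a 10 000-gene universe (the
large universe raises the top-100 selection threshold, which is what keeps
decoy signatures at chance overlap) and three screening experiments on
independent 30-sample cohorts keyed to overlapping 60-gene module windows.

## Known limitations

- Combined p-values ignore inter-pipeline dependence; DI is a ranking
  statistic, not an error rate (see above).
- VIPER is mode-less and one-tailed; GSVA uses the Gaussian kernel only (no
  Poisson kernel for raw counts); singscore handles unsigned sets only.
- Distance correlation and Hoeffding's D are non-negative; their direction
  is borrowed from the Pearson sign on the same data.
- The synthetic generators are Gaussian; negative-binomial count noise is
  out of scope.
- Runtime: the permutation-based correlation tests (distance, Hoeffding)
  dominate full-registry correlative runs; reduce `n_perm_assoc` or the
  registry for large cohorts.
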