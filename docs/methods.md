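# Methods

This note records the models implemented in `biogeo`, their assumptions,
the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Data model and contracts

A study is a taxa × samples integer count table, per-sample metadata
(subject, organ, site, sample type, covariates), an optional 7-rank
taxonomy, and an optional rooted phylogeny with branch lengths. Library
sizes are always derived as column sums, never stored. Identifiers are
case-sensitive after trimming; categorical metadata are normalized
(whitespace collapsed, lowercased) before validation against the organ and
sample-type vocabularies. TSV is the canonical interchange format; BIOM 1.0
JSON is read-only. Loading preserves order and round-trips bit-exactly for
integer counts.

## Contamination control

Three stages run in a fixed order: rarefy → rare-taxon filter → contaminant
scoring.

* **Rarefaction** draws exactly `target_depth` reads per sample *without*
  replacement (multivariate hypergeometric), the dominant reading of
  "reducing read counts to a common library size" in amplicon practice.
  Samples below the target are dropped with a logged warning, never
  up-sampled. Subsampling without replacement is unbiased for proportions
  (verified by simulation) and idempotent at a fixed depth and seed.
* **Rare-taxon filtering** discards a taxon only when its relative
  abundance is below the threshold (default 0.1%) in *every* sample;
  reaching the threshold anywhere retains it. The filter is monotone in the
  threshold.
* **Contaminant scoring** follows the prevalence logic of negative-control
  screening: per taxon, a 2×2 table of detection (count > 0 after
  rarefaction) in controls versus biological samples. The score is a
  one-sided p-value that control prevalence exceeds biological prevalence:
  chi-squared with continuity correction, replaced by the exact
  hypergeometric (Fisher) tail whenever any expected cell is below 5. A
  taxon is flagged when score < 0.5 *and* control prevalence ≥ biological
  prevalence. The direction guard is essential: without it, genuine taxa
  sparsely detected in controls would be flagged at the conventional 0.5
  cut. Under exact prevalence equality the flag rate is bounded by the
  threshold and in practice far lower (only the control-excess direction
  can flag). A `strict` mode instead removes every taxon detected in any
  control, for studies that take that harder line.

## Diversity and ordination

* Inverse Simpson `1/Σpᵢ²` is the effective number of equally abundant
  taxa. The "relative" variant divides by observed richness, giving an
  evenness measure in (0, 1]; both columns are always emitted because the
  bare term "relative inverse Simpson" is ambiguous in the literature.
* Rank collapse sums counts over identical lineage prefixes; taxa
  unclassified at the target rank pool into one `unclassified` bucket per
  parent lineage, so collapsing fine-then-coarse equals collapsing coarse
  directly (tested).
* UniFrac and PCoA delegate to scikit-bio. Unweighted UniFrac is the
  default (presence-driven, matching the presence-threshold ethos of the
  downstream analyses); the normalized weighted form is behind a flag.
  PCoA reports all eigenvalues but only produces axes for positive ones.
* **PERMANOVA with covariates** is implemented in-package because the
  stock implementations do not adjust for covariates. With Gower-centered
  `G = −½ J D² J` and hat matrices `H_cov` (intercept + covariates) and
  `H_full` (+ group dummies), the sequential-SS pseudo-F is
  `[(tr(H_full G) − tr(H_cov G))/df_g] / [(tr(G) − tr(H_full G))/df_res]`,
  and the p-value is `(1 + #{F_π ≥ F}) / (1 + n_perm)` under joint
  permutation of the distance matrix's rows and columns against the fixed
  design (raw-label permutation; Freedman–Lane residual permutation is
  deliberately not attempted — it is the simplest defensible reading of
  "adjusting for covariates", and the type-I error is nominal by
  construction for the no-covariate case). Without covariates the statistic
  reproduces scikit-bio's PERMANOVA to 1e-9 (tested), and the empirical
  type-I error over 1000 null datasets at α = 0.05 lies in [0.03, 0.07].

## Paired-niche enrichment regression

For one taxon at one site, counts `C` of depth `N` across the site's paired
lumen/mucosa samples follow a beta-binomial logistic model: `logit(p) = β₀
+ β_type·R_type + Σ β_k S_k` with `C ~ Binomial(N, p)`, `p ~ Beta(a, b)`,
and the mean/intra-class-correlation parameterization `a = p(1−ρ)/ρ`,
`b = (1−p)(1−ρ)/ρ`. One scalar ρ per taxon-site fit captures
between-sample overdispersion; ρ → 0 recovers the binomial likelihood.

Numerics: the log-likelihood is evaluated with log-gamma/Beta functions;
below ρ = 1e-8 the direct formula loses precision to log-gamma cancellation
(a, b ~ 1/ρ) and the binomial limit — then accurate to O((N−1)ρ/2) — is
used instead. The joint MLE of (β, logit ρ) uses L-BFGS-B with an analytic
gradient (digamma identities); standard errors come from the observed
information, obtained by central differences of the analytic gradient.
Starting values are a plain binomial GLM fit (pooled-proportion intercept
under separation) and ρ = 0.05. Separation or a singular information matrix
yields `converged=False`, infinite SE and p = 1 — never a crash. Taxa
detected in fewer than 4 pairs at a site are skipped: too thin for a
2+-parameter model.

Inference is a two-sided Wald test on β_type, with Benjamini–Hochberg FDR
applied within site by default (pooling across sites is behind a flag,
since published analyses are ambiguous on this point). Classification:
q < α and β_type > 0 → mucosa-enriched; q < α and β_type < 0 →
lumen-enriched; else ns. Fitting is per taxon per site; organ-level
enriched sets are unions over sites, compared across organs by Jaccard
percentage.

Calibration and power, verified by simulation from the model itself: null
Wald p-values are uniform (K-S p > 0.01 over 500 taxa at 40 pairs,
N = 10,000, ρ = 0.05); a planted β_type = 2 is recovered with |bias| ≤ 0.2
over 200 replicates; and in an 80/20 null/planted mixture BH at α = 0.05
achieves sensitivity ≥ 0.8 with false-discovery proportion ≤ 0.1.

**Known limitation.** The single-ρ beta-binomial absorbs *all*
between-sample variation. When subject-to-subject heterogeneity is large
and the number of pairs very small (the synthetic default uses 6 subjects),
the observed-information Wald test can be anticonservative and promote
heavily overdispersed null taxa; the calibration results above hold at
realistic pair counts (tens of subjects, as in body-site surveys). There is
also a structural compositional effect: shifting the planted taxa up in the
mucosa necessarily shifts every other taxon down slightly (the simplex
renormalization), so "lumen-enriched" calls in closed data are relative
statements, not absolute ones.

## SparCC correlation networks

Implemented from the algorithm's definition: counts + 1 pseudocount are
converted to fractions by Dirichlet resampling; pairwise log-ratio
variances `t_ij = var(log xᵢ/xⱼ)` relate to latent basis variances ωᵢ via
`t_ij = ωᵢ + ωⱼ − 2ρ_ij √(ωᵢωⱼ)`; under sparsity the ω solve the linear
system `diag(dᵢ) + A` over non-excluded pairs; correlations are
`ρ_ij = (ωᵢ + ωⱼ − t_ij) / 2√(ωᵢωⱼ)` clipped to [−1, 1]. The strongest
pair above the exclusion threshold (default 0.1) is iteratively removed and
the system re-solved (default 10 iterations); the reported matrix is the
median over 20 Dirichlet resamples; pseudo p-values permute each taxon's
samples independently (default 100 rounds, a SparCC convention — the source
analyses do not state their count) with BH across edges. At least 4 taxa
(the system is under-determined below that) and 10 samples are required.

Per organ, an edge is retained only when BH-significant at every site of
the organ *with the same sign everywhere*; its weight is the mean
correlation across sites. Organ-specificity follows two rules: (a) the
correlation differs by more than 0.6 from the edge's correlation in *every*
other organ carrying it, or (b) |correlation| > 0.6 and no other organ
carries the edge. An edge present in exactly one organ has no counterpart
to difference against, so singletons qualify only via rule (b) — otherwise
every unique edge would be vacuously "specific".

Verified behaviour: on 50 independent log-normal taxa across 200 samples
the median off-diagonal |ρ̂| stays below 0.1; a planted proportional pair
among 12 background taxa is recovered with ρ̂ > 0.9.

## Inter-organ translocation

Presence of a taxon in a (subject, organ) requires relative abundance
*strictly* above the threshold (default 0.1%) in at least one of the
subject's samples from that organ (an all-samples variant exists; organs
have multiple sites, and requiring one site matches how presence is read
off multi-site surveys). Species presence is the OR over member ASVs; the
multiplicity per (species, subject, organ) counts member ASVs meeting the
criterion; ASVs without a species rank become their own pseudo-species.
Prevalence per organ is the subject fraction with presence; "prevalent"
means strictly > 50%.

The inter-organ positive-correlation ratio takes, for each species
prevalent in either organ of a pair, the subject-level abundance (mean
relative abundance over the subject's samples in the organ) in both organs
and correlates them across subjects by Spearman, partial Spearman
(rank-residualized against age, sex and BMI — the covariates adjusted
elsewhere in the pipeline; the partial variant's covariate set is an
assumption) and Pearson. A species counts as positive when the coefficient
is > 0 with p < 0.05 — deliberately *uncorrected*, since the source
convention for this analysis uses raw p < 0.05; this is prominently a
per-species screen, not an FDR-controlled discovery set. The default
combination rule is "significant by at least one method" (`--combine all`
requires all three). Species with fewer than 5 subjects sampled in both
organs are skipped and excluded from the denominator, which is reported
next to every ratio.

Core species: for each (species, subject, organ-group), the call is `core`
when ≥ 1 ASV of the species is present in every organ of the group for
that subject, upgraded to `core_multi_asv` when ≥ 2 ASVs each satisfy this
(bounded by the minimum per-organ multiplicity). Upper/lower GI membership
is configurable (defaults: upper = esophagus + stomach, lower = small
intestine + appendix + large intestine; the oral cavity is an annotation,
not a group member).

## Synthetic-data generator

The generator emulates a body-wide 16S survey at desk scale. Default study
conditions: 6 subjects; organs oral cavity (2 sites, surface), esophagus
(2 sites, mucosa), stomach (2 sites, paired gastric juice + mucosa), small
and large intestine (3 sites each, paired lumen + mucosa) — 20 samples per
subject plus 3 negative controls; 120 taxa; library sizes uniform on
[20,000, 50,000] (real libraries vary more, but the pipeline rarefies to
10,000 anyway); overdispersion ρ = 0.02.

Latent model per (subject, site): organ base composition (log-normal
backbone plus organ offsets) perturbed by (i) core-species subject effects
— `√r·u_subject + √(1−r)·v_organ` in log space, realizing abundance
correlation r between the organs of the species' group, (ii) correlated
Gaussian pair noise for planted network edges (a Gaussian copula in log
space — precisely the structure SparCC is designed to detect; no generative
model is prescribed by the source analyses, so the simplest adequate one is
used), and (iii) i.i.d. log-space noise (sd 0.4). The vector is closed to
the simplex by softmax. The paired mucosa sample *shares the site's latent
community* and receives planted enrichment as an exact logit shift of the
affected taxa's proportions (the remaining taxa are rescaled to keep the
simplex), so β_type is exact by construction. Counts are drawn per taxon as
BetaBinomial(N, p, ρ) — independent thinning, so realized library sizes
scatter around the drawn N.

ρ = 0.02 deserves a note: with the mean/ICC parameterization the relative
overdispersion of a rare taxon scales like √(ρ/p), so even small ρ at
depth 10⁴ produces the zero-inflated, heavy-tailed counts familiar from
real amplicon data. The biological (between-subject) variation comes from
the latent log-normal layer, not from ρ.

Contaminant taxa have no biological source (zero base abundance); each is
present in a negative control with the configured prevalence (0.9) —
controls are composed of contaminant reads via a Dirichlet split of a
12–20k library — and leaks into biological samples at the carryover rate
(0.05) at 0.15–0.5% relative abundance. Planted-absent species have exactly
zero abundance in designated organs, making false core calls impossible by
construction. A random bifurcating tree with exponential branch lengths
covers all taxa (needed only for UniFrac). The `GroundTruth` object records
every planted parameter plus realized latent proportions and is JSON-
serializable, so each downstream stage is scored without re-reading the
config.

Two named scenarios support recovery experiments: `core_recovery_scenario`
(default design, 8–10 subjects, planted core and planted-absent species)
and `translocation_scenario` (two organs, 30 subjects, uniform base
composition, a configurable fraction — default 30% — of taxa given the
subject-level shared effect at r = 0.8, one species per ASV so the planted
fraction among tested species is exact). In the latter, the measured
positive-correlation ratio concentrates slightly *above* the planted 0.3
(≈ 0.34): near-unit power on planted species plus the expected α-level
positives among the independent 70%.

What passing these simulations does **not** show: robustness to taxonomic
misassignment, to uneven extraction efficiency between mucosa and lumen
(a real confounder of niche comparisons), to contaminants correlated with
biological covariates (the frequency/DNA-concentration mode of contaminant
screening is out of scope), or to the compositional coupling between many
simultaneously enriched taxa; the generator plants few, mostly independent
effects.

## Numerical conventions

Every randomized operation takes an explicit integer seed; fixed seed means
bit-identical output. Eigenvalue ties in PCoA are broken by stable ordering
on sample order. SparCC correlations are clipped to [−1, 1]; basis
variances are floored at 1e-12 before the correlation formula. PERMANOVA
p-values respect the attainable floor 1/(n_perm + 1). The enrichment
optimizer bounds logit ρ in [−30, logit(1 − 1e-9)].
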