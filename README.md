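# biogeo

Analysis pipeline for **multi-organ microbiome biogeography**: where do
bacteria live along the human body's surface organs (skin, oral cavity,
esophagus, stomach, small intestine, appendix, large intestine), which taxa
prefer the mucosa over the lumen of a gastrointestinal site, how do
taxon–taxon interaction networks differ between organs, and which species
co-exist across organs of the same individual — the signature of bacterial
translocation.

The package is written for microbiome researchers working with ASV-level
16S count tables plus per-sample metadata (subject, organ, site, sample
type, covariates). It ships a synthetic-study generator with full ground
truth, so every analytical stage is validated by parameter recovery rather
than by eyeballing.

## What it computes

1. **Contamination control** — rarefaction to a common depth (default
   10,000 reads, subsampling without replacement), removal of taxa below
   0.1% relative abundance in every sample, and prevalence-based
   contaminant scoring against negative controls (one-sided chi-squared /
   exact hypergeometric on the 2×2 presence table, flagging at score < 0.5).
2. **Diversity** — inverse Simpson index `1/Σpᵢ²` (plain and divided by
   observed richness), taxonomic rank collapse, unweighted/weighted UniFrac,
   classical PCoA, and PERMANOVA with covariate adjustment by sequential
   sums of squares (covariates entered before the grouping factor).
3. **Paired-niche enrichment** — the core model. For taxon *x* at one site,
   read count *C* out of depth *N* over paired lumen/mucosa samples:

   ```
   logit(p) = β₀ + β_type·R_type + β_k·S₁ + …
   C ~ Binomial(N, p),   p ~ Beta(a, b)
   a = p(1−ρ)/ρ,  b = (1−p)(1−ρ)/ρ
   ```

   with `R_type = 1` for mucosa, `S_i` subject covariates (age, sex, BMI by
   default), and one overdispersion ρ per fit. (β, ρ) are estimated by
   maximum likelihood with an analytic gradient; Wald tests plus
   Benjamini–Hochberg FDR within site classify taxa as mucosa- or
   lumen-enriched, and Jaccard overlap compares enriched sets across organs.
4. **Correlation networks** — SparCC compositional correlations per site
   (log-ratio variances `t_ij = var(log xᵢ/xⱼ)`, basis-variance linear
   system under sparsity, iterative exclusion of strong pairs, Dirichlet
   resampling, permutation p-values), kept per organ only when significant
   with a consistent sign across all the organ's sites, and annotated as
   organ-specific when the correlation differs by > 0.6 from every other
   organ or exceeds 0.6 in that organ alone.
5. **Translocation** — presence calling (> 0.1% relative abundance),
   species-level collapse with ASV multiplicity, per-organ prevalence
   (> 50% of subjects), inter-organ positive-correlation ratios among
   prevalent species (Spearman / partial Spearman / Pearson), and per-subject
   **core species**: a species whose ASV(s) are present in *every* organ of
   a group (e.g. upper GI) within the same individual.

## Worked example

```python
import biogeo as bg

bundle, truth = bg.generate_study(bg.default_config(seed=0))
cleaned, report = bg.decontaminate(bundle.count_table, bundle.samples)
print("flagged:", report.contaminants)

dm = bg.unifrac(cleaned, bundle.tree)
res = bg.permanova(dm, bundle.samples, "organ",
                   covariates=["age", "sex", "BMI"], n_perm=999, seed=0)
print(f"PERMANOVA organ: pseudo-F = {res.pseudo_F:.2f}, p = {res.p_value:.4g}")

fits = bg.classify_enrichment(
    bg.fit_organ(cleaned, bundle.samples, "small intestine"), alpha=0.05)
frame = bg.fits_to_frame(fits)
print(frame[frame["class"] != "ns"].sort_values("fdr_q").head(4)
      [["taxon_id", "site", "beta_type", "fdr_q", "class"]].to_string(index=False))
```

prints

```
flagged: ['ASV0115', 'ASV0116', 'ASV0117', 'ASV0118', 'ASV0119', 'ASV0120']
PERMANOVA organ: pseudo-F = 13.49, p = 0.001
taxon_id     site  beta_type        fdr_q           class
 ASV0046 duodenum  -3.283365 2.073084e-19  lumen_enriched
 ASV0007  jejunum   2.969528 5.040273e-13 mucosa_enriched
 ASV0002    ileum   2.743224 1.374263e-12 mucosa_enriched
 ASV0001    ileum   2.811944 1.502766e-11 mucosa_enriched
```

All six planted contaminants are flagged with no false flags; organs
separate overwhelmingly in UniFrac space (p at the permutation floor); and
the strongest enrichment calls include planted mucosa-enriched taxa
(ASV0001/0002/0007 were planted with β = +2 at small-intestine sites).
`beta_type` is the log-odds shift of the taxon's relative abundance in
mucosa versus lumen — e.g. +2.8 means ≈ 16-fold enrichment at the mucosa.
At this deliberately small scale (6 subjects) the Wald test can also
promote unplanted, heavily overdispersed taxa such as ASV0046; see
`docs/methods.md` for why, and for the calibration results at realistic
pair counts.

The same stages are scriptable from a shell:

```bash
biogeo simulate --out study --seed 0
biogeo validate --counts study/counts.tsv --meta study/meta.tsv
biogeo decontam --counts study/counts.tsv --meta study/meta.tsv --out clean --seed 0
biogeo enrich --counts clean/counts.tsv --meta study/meta.tsv \
    --organ "small intestine" --organ "large intestine" --out enriched
biogeo translocate --counts clean/counts.tsv --meta study/meta.tsv \
    --tax study/taxonomy.tsv --out translocation
```

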