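# methylotype

Analysis pipeline for Infinium-style DNA-methylation arrays, built around a
question from AML epigenomics: when a mutation (such as neomorphic *IDH1/2*)
is associated with genomic hypermethylation, is that a pathological
methylator phenotype, or does it simply reflect the methylome of the
less-differentiated cell state the mutation traps cells in? Answering it
takes five pieces of machinery, all provided here as a tested library:

* **Probe QC and harmonization** — detection-p filtering, removal of
  cross-reactive, SNP-overlapping and sex-chromosome probes, restriction to
  the 450K/EPIC chip intersection.
* **Differential methylation** — per-probe two-group comparison of beta
  values with empirical-Bayes variance moderation and Benjamini–Hochberg
  FDR control, plus feature stratification over CpG islands, shores,
  shelves and open sea (with optional LAD exclusion).
* **Methylation canyons** — calling of long (≥ 3.5 kb) hypomethylated
  regions from a per-CpG WGBS-style track, mapping of array probes into
  canyons, and size-normalized meta-profiles that show whether a
  methylation change is flat along the canyon or border-enriched.
* **Reference projection** — PCA fitted on sorted hematopoietic reference
  methylomes (CMP → GMP → PMC → PMN) and projection of patient samples onto
  that basis, placing each methylome on the normal differentiation axis;
  complete-linkage hierarchical clustering and FAB-class distributions.
* **Synthetic data with ground truth** — generators for two-group cohorts
  with planted hypermethylation, differentiation-gradient references, CpG
  tracks with planted canyons, and probe manifests, so every stage is
  testable end to end without external downloads.

## The statistics

For probe $g$ with group means $\bar\beta_{g1},\bar\beta_{g2}$, pooled
residual variance $s_g^2$ on $d_g=n_1+n_2-2$ degrees of freedom, the
variances are shrunk toward a scaled inverse-$\chi^2$ prior
$(d_0, s_0^2)$ fitted across probes by method of moments on $\log s_g^2$:

$$\tilde s_g^2=\frac{d_0 s_0^2 + d_g s_g^2}{d_0+d_g},\qquad
\tilde t_g=\frac{\bar\beta_{g2}-\bar\beta_{g1}}
{\tilde s_g\sqrt{1/n_1+1/n_2}}\sim t_{d_g+d_0}.$$

With $d_0=0$ this is exactly the classical pooled t-test; with
$d_0=\infty$ a z-like test against $s_0^2$. P-values are BH-adjusted;
probes with adj. p < 0.05 are differentially methylated, split into
hyper/hypo by the sign of $\Delta\beta$. Global comparisons use Welch's
t-test, probe-set overlaps the upper-tail hypergeometric test.

A canyon is a maximal chain of ≥ 5 consecutive covered CpGs with
methylation ratio ≤ 0.1, chains ≤ 1 kb apart merged, kept if spanning
≥ 3500 bp (only this floor is canonical; all parameters are configurable).

## Worked example

```python
import methylotype as mt

beta, detp, sheet, truth = mt.simulate_cohort(
    n_wt=28, n_mut=112, n_probes=10_000, frac_dmp=0.1, delta=0.2, seed=1)
manifest = mt.simulate_manifest(10_000, seed=2, sex_fraction=0.03,
    mask_fractions={"cross_reactive": 0.02, "snp_overlap": 0.02})

filtered, report = mt.filter_probes(beta, detp, manifest)
fit = mt.fit_groups(filtered, sheet["idh_status"])
table = mt.moderated_test(fit)
```

Running `python examples/01_cohort_differential_methylation.py` (the same
analysis) prints:

```
QC: 10000 -> 9315 probes, removed {'detection': 0, 'sex_chromosome': 329,
    'cross_reactive': 179, 'snp_overlap': 177, 'chip': 0}
prior: d0=10.7, s0^2=0.0019
975 significant probes; 948 hyper, 27 hypo
mean delta beta of significant hyper probes: 0.196
```

The cohort had a +0.2 beta shift planted at 10% of probes in the mutant
group: the moderated test finds it (948 of the significant probes are
hypermethylated, mean Δβ ≈ 0.196 against the planted 0.2), and the
feature stratification shows the shift in every island-relation category.
The other examples cover canyons (`02`, recovering a planted flat +0.014
canyon shift), reference projection (`03`, progenitor-like queries landing
at the progenitor end of PC1) and the full pipeline bundle (`04`).

A thin CLI mirrors the library:
`methylotype simulate|filter|dmp|canyons|pca|cluster|run-all`, e.g.

```sh
methylotype run-all --seed 7 --out bundle/
```

writes a fully reproducible results bundle (tables as TSV, reports as
JSON, canyons as BED) whose files are byte-identical across re-runs with
the same seed and config.

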