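# Methods

## Scope and data model

The package operates on beta values — per-probe methylation fractions
$\beta \in [0,1]$ — arranged probes × samples, with an aligned
detection-p matrix, a probe manifest (coordinates, CpG-island relation,
cross-reactive/SNP/LAD flags, 450K/EPIC membership) and a sample sheet
carrying mutation status and FAB class. It assumes normalized betas as
input: raw IDAT parsing and within-array normalization are upstream of
this pipeline and out of scope, as are multi-factor designs, batch
correction and region-level (DMR) calling. Coordinates are 0-based
half-open throughout; sequence names are normalized to a `chr` prefix;
sex chromosomes are {chrX, chrY}.

## Probe filtering

A probe is removed if (precedence order for reporting only): it fails
detection (p > 0.01) in more than `max_failing_fraction` of samples — the
default 0 is the strictest reading, where one failing sample removes the
probe; it lies on a sex chromosome; it is flagged cross-reactive; it
overlaps a SNP; or (optional) it is absent from either chip. The retained
set is independent of the precedence; the precedence only decides which
category a multiply-flagged probe is counted under, keeping the report's
categories disjoint and summing to the number removed. Filtering is
idempotent. Which published cross-reactive/SNP list to use is the
caller's choice: the filter consumes whatever flags the manifest carries.

## Moderated differential methylation

Betas are modelled directly (an M-value transform is deliberately not the
default, since effect sizes are reported as delta beta; the group-mean
fit applies unchanged to M-values if a caller transforms first). Per
probe, group means and the pooled residual variance $s^2$ on
$d = n_1 + n_2 - 2$ degrees of freedom are computed complete-case per
group; probes with fewer than two values in a group are dropped and
counted. The variance prior $(d_0, s_0^2)$ is fitted by method of moments
on $\log s^2$: under $s^2 \sim s_0^2 F(d, d_0)$, the mean and variance of
$\log s^2$ have closed forms in digamma/trigamma functions, and matching
empirical moments gives $d_0$ (via a Newton inversion of the trigamma
function) and $s_0^2$. When the empirical spread of $\log s^2$ does not
exceed what sampling alone implies, $d_0 = \infty$ and $s_0^2$ is the
mean sample variance; probes are then tested against $s_0^2$ with a
normal reference. The estimator is exposed separately (`estimate_prior`)
so it can be swapped. Zero-variance probes are excluded from prior
estimation but still tested, their variance fully shrunk to the prior.

Limits are exact by construction: $d_0 = 0$ reproduces the classical
pooled t-test (tested to 1e-10 against an independent implementation),
$d_0 = \infty$ the z-test. BH adjustment is delegated to statsmodels and
cross-checked in tests against a brute-force step-up enumeration. Probe
ranking for top-K selection is p ascending, ties by $|\Delta\beta|$
descending, then probe id — fully deterministic.

## Canyons

Calling: drop CpGs with coverage < 5; take maximal runs of ≥ 5
consecutive retained CpGs with ratio ≤ 0.1; chain-merge runs whose gap
(next run's first CpG minus previous run's end) is ≤ 1000 bp; keep merged
intervals spanning ≥ 3500 bp. Only the 3.5 kb floor is canonical for
canyons; the other defaults follow the canyon literature and are
configurable. An interval ends at the last qualifying CpG + 1: the caller
asserts nothing about unobserved sequence, which is why a planted canyon
is recovered to the nearest CpG (one spacing) rather than exactly.
Length is re-checked after merging only, so two sub-threshold runs can
legitimately merge into one canyon.

Probe mapping is binary search over the sorted non-overlapping intervals
per chromosome, half-open containment; probes with missing positions are
never assigned. The meta-profile maps each canyon affinely to $[0,1)$,
bins probes at $\lfloor B \cdot \text{rel} \rfloor$ (B = 50 by default),
and averages over all probes of all canyons per group; empty bins are
reported with count 0 rather than dropped.

## PCA and clustering

PCA is an SVD of the per-probe centered (optionally unit-scaled) samples
× probes matrix. Scaling defaults to off for within-cohort PCAs on betas;
the reference-projection use case can enable it — both modes are exposed
because the appropriate choice depends on whether probe-wise variance
differences are signal or nuisance. Basis vectors are sign-fixed (largest
magnitude element positive) so results are reproducible across runs and
BLAS builds. Projection applies the reference center/scale/basis to
query samples identified by probe id, so probe column order is
irrelevant and projecting the training data reproduces its scores.

Hierarchical clustering is euclidean complete linkage, implemented
in-package because the contract includes a deterministic tie-break
(smallest cluster-id pair) that library implementations do not promise;
scipy's linkage is the independent oracle in the tests. Flat clusters
come from cutting at a cluster count k, not at a height, which is
well-defined even with tied merge heights.

## Synthetic data: what it emulates, and what not

The generators reproduce the statistical structure the analysis relies
on, with ground-truth records for scoring:

* **Cohorts** — probe baselines from a bimodal low/high mixture (means
  ≈ 0.1 and ≈ 0.85, weight 0.5), mimicking the characteristic bimodal
  beta distribution of methylation arrays. Sample betas are
  Beta-distributed around the generating mean with shape $a = m\nu$,
  $b = (1-m)\nu$, $\nu = 1/\text{dispersion}$ (default dispersion 0.02,
  giving a within-group SD of ≈ 0.07 at intermediate methylation —
  realistic inter-patient spread for array cohorts; the true
  within-cohort variance of patient betas is not externally fixed, so
  this default is a free parameter of the generator). Dispersion 0 is the
  exact noise-free limit. Planted differential probes get their baseline
  from the intermediate band 0.25–0.6 and a +0.2 mutant shift by
  default, matching the observation that mutation-associated DMPs sit at
  intermediate wildtype methylation and gain on the order of 20%;
  default cohort size is 28 mutant vs 112 wildtype. Shifted means are
  clamped to [0.001, 0.999] to keep the Beta shapes non-degenerate.
* **References** — four stages (CMP, GMP, PMC, PMN) with strictly
  decreasing global methylation (default 0.8/0.7/0.5/0.4), shared
  per-probe offsets (zero-mean by construction, rescaled so every
  stage+offset stays in [0,1] — rescaling rather than clipping preserves
  the exact stage-mean contract) and Gaussian within-stage noise.
* **Tracks** — CpGs on a regular grid (default 100 bp), ratio 0.02 in
  planted canyons vs 0.85 outside, optional Gaussian noise, Poisson
  coverage.
* **Manifests** — categorical island relation, independent Bernoulli
  flags, probes on a regular genomic grid.

Not emulated: IDAT intensities, dye bias, batch effects, copy-number
artifacts, spatially correlated methylation outside canyons, probe-probe
correlation, or cohort substructure. Passing tests therefore demonstrate
the correctness and calibration of the machinery under the generative
model, not robustness to those real-data phenomena.

## Problem sizes and numerical choices

The test and acceptance workloads use 10,000 probes for cohort analyses
(28 vs 112 samples), 20 replicate seeds for calibration and canyon
round-trips, 2,000-probe references, and a 200 kb chromosome with 5
canyons for the coupled canyon cohort — sizes at which every property of
interest (FDR calibration, effect recovery within ±0.02, perfect canyon
round-trips, ≥95% projection accuracy) is already stable.

Ties and degenerate inputs: zero-delta probes get t = 0, p = 1; a Welch
test with two zero-variance groups returns p = 1 on equal means and p = 0
otherwise; empty feature categories yield NaN rows rather than errors; an
empty track yields an empty canyon set; pipeline bundles contain no
timestamps so fixed-seed re-runs are byte-identical (floats serialized
at 10 significant digits).
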