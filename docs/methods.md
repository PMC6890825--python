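# Methods

This note documents the statistical procedures implemented in
`regiontx`, the modeling assumptions behind them, the defaults and why,
and what the synthetic benchmarks do and do not establish.

## Regional differential expression

For one region of interest the model for each probe is ordinary least
squares on all atlas samples with an intercept, treatment-coded donor
indicators (lexicographically first donor as reference) and a single
binary region-of-interest indicator.  One model is fit per region of
interest rather than one model with a coefficient per region: the
contrast of interest is always region-vs-rest-of-brain, and separate
fits keep the design full-rank under unbalanced regional sampling.  The
design is shared by all probes, so the fit is vectorized: one
cross-product inverse serves every probe, and the unscaled standard
error √v of the region coefficient is a design constant.  Residual
degrees of freedom are n − n_donors − 1.  A donor whose samples all lie
inside the region of interest makes the design rank-deficient; this is
detected and reported with the confounded donor named rather than
silently dropped.

### Empirical-Bayes variance moderation

Per-probe variances are shrunk with the standard hierarchical model
s²_g | σ²_g ~ σ²_g χ²_d / d and σ²_g ~ s₀² d₀ / χ²_{d₀}.  With
e_g = log s²_g − ψ(d/2) + log(d/2), the prior parameters follow from the
marginal moments of e: the mean estimates log s₀² + ψ(d₀/2) − log(d₀/2)
and the excess of var(e) over ψ′(d/2) estimates ψ′(d₀/2), inverted by
bracketed root-finding on the strictly decreasing trigamma.  When the
observed dispersion does not exceed the sampling term, the prior df is
infinite and every moderated variance equals the arithmetic mean of the
observed variances; this matches the behavior of the reference
implementation in the limma package, which one test cross-checks through
Rscript (agreement to 1e-14 on t-statistics and p-values for a
finite-d₀ fixture).  In the infinite-d₀ case the moderated t is referred
to the standard normal; the reference implementation instead caps the
degrees of freedom at the pooled residual df, a difference of about 1e-4
in p on typical fixtures and zero once d₀ is finite.  Probes with zero
residual variance are excluded from estimation (their log is undefined)
but still shrunk toward the prior.  No variance trend or robust variant
is implemented.

### Gene summarization and ranking

Genes are represented by their lowest-p probe (ties by probe id).  A
gene is "up-regulated" only if its representative probe passes FDR <
0.05 **and** has positive effect; a gene whose best probe is negative
never enters an enriched list regardless of significance.  The signed
ranking key is sign(β)·(−log₁₀ p_min) with p floored at 1e-300 (atlas
rankings genuinely reach p ≈ 1e-209), ties broken by moderated t then
gene symbol so the order is a strict total order and byte-reproducible.
Raw p_min rather than the FDR-adjusted value drives the ranking; the
adjustment is monotone, so downstream AUROCs are unchanged.

## Gene-set enrichment and specificity

The AUROC of a set is computed from the rank-sum identity and equals
exhaustive (member, non-member) pair counting exactly (an acceptance
check runs 200 random fixtures against the brute-force oracle).
Significance uses the normal approximation to the one-sided
Mann–Whitney U with a 0.5 continuity correction; set sizes of 10–200
genes make the approximation adequate (agreement within 0.02 of exact
enumeration already at n₁ = 3, n₀ = 4, and empirical type-I error within
[0.03, 0.07] at α = 0.05).  Only up-regulation is tested: sets with
AUROC ≤ 0.5 are reported with p = 1 and flagged.  Gene sets are
intersected with the measured-gene universe and kept when the
intersected size lies in [10, 200], bounds inclusive.  The specificity
rank of a set for a region counts the other regions whose ranking gives
a strictly higher AUROC — ties do not count, so identical rankings give
rank 0.

## Overlap tests

The upper tail P(X ≥ k) of the hypergeometric distribution is summed in
log space via log-gamma, so log₁₀ p is exact even when p underflows
double precision (published configurations reach p < 10⁻¹³⁴).  The
universe defaults to the number of measured genes after probe filtering
(20,778 for the atlases that motivate the package) and is configurable.
The observed count is included in the tail (P(X ≥ k)), the standard
enrichment convention, and k at or below the minimum possible overlap
returns p = 1.

## Cell-type proportions (marker gene profiles)

Within each donor, marker-gene expression is centered per gene across
the donor's samples and the samples' scores on the first principal
component (covariance PCA via SVD, no per-gene variance scaling) are the
raw proportion estimates; the sign is fixed so PC1 correlates
non-negatively with mean marker expression.  Scores are averaged within
region, z-scored across regions within donor, averaged across donors and
densely ranked (1 = highest, ties by region name).  Probes are collapsed
to genes by the highest-mean probe beforehand.  Estimates are relative;
no sum-to-one deconvolution is attempted, and markers absent from the
data are dropped with a warning (at least two must remain).  Curated
marker lists are not bundled — a clearly synthetic example TSV shows the
format — so real-data runs require user-supplied markers.

## Region similarity

A reference region's signature is its top-20 ranking genes (20 gives a
specific rather than transcriptome-wide signal; configurable).  Every
region's ranking is scored for those markers by AUROC with the one-sided
Mann–Whitney p, BH-adjusted across regions within one dataset.  By
construction the reference scores exactly 1.0 against its own markers.
Cross-atlas scoring matches by gene symbol; markers missing from the
second atlas's universe raise unless explicitly allowed, in which case
they are dropped with a logged count.

## Atlas input conventions

Bundles follow the Allen file-layout convention (headerless expression
matrix keyed by probe id, probe/sample annotation CSVs, ontology CSV
with parent links, validated to be acyclic).  Per-donor bundles are
concatenated with samples re-keyed by donor so donors can be fit
jointly.  Gene symbols are whitespace-stripped and compared
case-sensitively; empty strings and NA spellings mean unmapped, and
unmapped probes are dropped before analysis.  Fetal region grouping
applies explicit merge rules first (dorsal+ventral claustrum →
claustrum; agranular insular samples → dysgranular insular cortex) and
can then walk fine cortical zone/layer dissections up the ontology to
the enclosing named region; the named-region list is user-overridable
and orphan samples are an error, not a silent drop.  Present/absent
detection flags in Allen bundles are ignored.

## Synthetic atlas generator

The generator emulates the statistical structure the DE model assumes:
log2 expression = gene baseline (Uniform(4, 12)) + per-probe offset
(N(0, 0.25²)) + additive donor effect (N(0, 0.5²)) + planted
region-specific shift δ + Gaussian noise (N(0, 0.5²)).  The default
scale — 2,000 genes × ~1.5 probes/gene, 8 regions, 4 donors, 4
samples/region/donor (~3,000 probes × 128 samples) — simulates and
analyzes in well under a second, which sets the problem sizes used by
the test suite and the acceptance script (20 null atlases, 2,000 random
rankings, 5,000-probe variance draws).  Default effect size is 2 log2
units with 20 planted markers, the regime in which recovery should be
essentially complete.  Randomness is hierarchical: one global seed
spawns per-component streams keyed by component name and region index,
so adding a region or a planted effect does not perturb unrelated draws,
and everything is bit-reproducible under a fixed seed.  A fetal
counterpart atlas reuses a configurable fraction of each region's
markers (exactly round(f·n), remainder drawn from non-marker genes so
fraction 0 is disjoint by construction).

What the generator does **not** emulate: spatial coordinates, batch and
array effects, intensity-dependent variance, probe cross-hybridization,
correlated gene programs beyond the planted markers, and the adult/fetal
global expression differences seen in real atlases.  Passing the
synthetic benchmarks therefore establishes the correctness and
calibration of the statistical machinery under its own model — not that
real-atlas conclusions are insensitive to those unmodeled features.

## Numerical choices

* p-values clamped strictly positive (smallest normal double) after the
  t tail; floored at 1e-300 before log₁₀ in the ranking key.
* Trigamma inversion by `brentq` on an adaptively widened bracket,
  tolerance 1e-12.
* BH adjustment delegates to statsmodels (`fdr_bh`).
* All tie-breaks (ranking, representative probe, region ranks) are
  deterministic and documented above; result tables are byte-identical
  across reruns with one seed.
* Degenerate inputs error loudly: all-zero variances, empty or
  full-universe set intersections, rank-deficient designs, impossible
  overlap configurations, orphan ontology walks.

## Known limitations

Only the one-region-vs-rest contrast is supported (no covariates or
surrogate variables); enrichment offers no permutation p-values or
GO-graph propagation; similarity does not include hierarchical
clustering or embedding methods (any external embedding can be applied
to the written tables); real-data reproduction of cell-type claims needs
user-supplied marker lists.
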