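# Methods

## Subcontext model

Every cytosine is classified by the trinucleotide starting at the C and
reading 5'→3' on the cytosine's own strand: the top-strand 3-mer for
plus-strand cytosines, the reverse complement of the top-strand 3-mer
ending at the position for minus-strand cytosines (where the reference
base is G). Sixteen subcontexts partition the classical classes — CGN (4),
CHG (3: CAG, CTG, CCG) and CHH (9). A 3-mer containing N or running off a
contig end is unclassifiable and excluded everywhere; no partial category
is invented. The vectorised scan is checked against a naive per-position
double-strand loop in the tests, and classification is
reverse-complement-invariant (the multiset of subcontexts of a sequence
equals that of its reverse complement — CG sites pair across strands).

Coordinates are 0-based half-open internally; cytosine reports keep their
1-based positions and are converted at ingestion. Contig names are matched
exactly, with an optional alias map for "Chr1"/"chr1" drift.

## Methylation estimators

The per-site level is mC/(mC+C), undefined at zero coverage. Aggregates
(bins, regions, profile bins) always carry both estimators:

- `site_mean` — unweighted mean of per-site levels over sites with
  coverage ≥ `min_depth` (default 1). Default for genome bins: sites are
  not weighted by their coverage.
- `pooled` — Σ methylated calls / Σ all calls. Invariant to splitting a
  site's calls across records; used within meta-profile position bins,
  where per-bin site counts are small and the site mean would be dominated
  by shot noise.

The wording "non-weighted" in methylome summaries is genuinely ambiguous
between these two readings, which is why both are always computed and
stored; analyses select one explicitly. Default bin sizes are 500 kb for
genomes under 250 Mb and 1 Mb otherwise, both overridable.

Per-site level histograms use 50 equal bins on [0, 1] (right-closed last
bin) over sites with coverage ≥ 8; the bimodality summary reports the mass
below 0.2, above 0.8, and between. A distribution is called bimodal when
both extreme masses exceed the central mass — this separates the
efficiently maintained CAG/CTG pattern (sites either methylated or not)
from the low-to-intermediate CCG pattern at the depths the histogram
filter admits.

## Conversion-rate control and correction

The conversion rate is 1 − pooled level over all cytosines of a named
unmethylated control contig (chloroplast-style), reported overall and per
subcontext; the per-subcontext spread is the control that apparent
subcontext bias is absent on unmethylated DNA. A conversion failure rate ε
biases every observed level upward: E[obs] = m + (1−m)ε. Recovery analyses
therefore apply the standard correction (obs − ε̂)/(1 − ε̂), with ε̂
estimated from the control contig, before comparing levels or forming
mutant/wt ratios — at arm-level CHH (~2%) the raw ratio of an nrpe1-like
mutant over wt would otherwise be ~0.3 instead of the true 0.15.

## Meta-profiles

Feature bodies are rescaled to `n_body_bins` (default 40) equal fractions;
flanks of `flank_bp` (default 1000) are split into `n_flank_bins` (default
20) fixed windows. Minus-strand features are flipped so bin 0 is 5'-most.
Features shorter than `min_feature_length` (default 200 bp) are skipped and
counted; a site under two features contributes to both. The defaults
resolve the edge-vs-body contrast at typical transposon sizes; they are
declared, not derived. Signature statistics: body bias = mean favored-CHH
level / mean of the remaining CHH over body bins (favored set is
species-style configuration: CAA/CTA for A. thaliana- and maize-like
genomes, CAA/CAT tomato-like, CTA rice-like); edge enrichment = all-CHH
pooled level in the first+last body bins over the central body bins. With
a 300-bp edge component and ~60-bp body bins the edge mass bleeds several
bins inward, so measured edge enrichment sits below the naive two-bin
expectation; tests assert calibrated bands rather than the naive value.

## Mutant comparisons

Ratio tracks divide mutant by wild-type levels bin-by-bin on identical
grids; bins with wt level below a floor (default 0.01) are masked as
missing rather than producing unstable ratios. Bias summaries:
ccg_bias = CCG / mean(CAG, CTG); chh_bias = mean(favored) / mean(rest).
The favored-set reading of the hyphenated "CAA-CTA" shorthand is a set
{CAA, CTA}, not a subtraction. Both ratios are scale-invariant. Bias
differences are reported descriptively; bootstrap CIs over bins are
available as a clearly optional extra.

## Small-RNA analysis

Size factors are median-of-ratios computed **only** on 20–22-nt loci with
all-positive counts (each sample's count over the locus geometric mean,
median over loci) and then applied to the 23–24-nt counts — the miRNA-rich
20–22-nt population anchors normalization when most 23–24-nt siRNA loci
collapse in RdDM mutants, exactly the situation where whole-library
normalization would be wrong.

The differential test is a deliberately simplified negative-binomial Wald
test, an approximation of the published shrinkage-estimator tools, not a
re-implementation: per-locus dispersion is estimated by method of moments
pooling both conditions' residual sums weighted by squared condition means
(so a collapsed mutant's 1-degree-of-freedom noise does not dominate), and
fully shrunk onto a trend a + b/mean fitted by least squares on estimates
winsorised at their 90th percentile — the raw moment estimates are heavy-
tailed at two replicates and an un-winsorised fit drags the trend up and
costs power genome-wide. Log-fold-change standard errors come from the
delta method with a 0.5 pseudocount; p-values are two-sided normal,
BH-adjusted across tested loci (adjustment method is an assumption — the
upstream convention says only "adjusted p-value"). Loci with mean
normalized count below 5 (configurable; the filter's existence is given,
its value is not) are excluded before testing. With a single replicate in
either condition the dispersion falls back to a fixed prior of 0.2 and the
output is flagged. Exact per-locus agreement with any published tool is
not claimed; the target is the headline down/up fractions.

## Synthetic data generator

The generator emulates the structure the analysis assumes, at desk scale:

- **Domains**: each chromosome has a pericentric heterochromatin span
  (central 20% in the A. thaliana-like preset) within euchromatic arms;
  an unmethylated control contig mimics the chloroplast.
- **Site models**: per domain and subcontext, per-site methylation
  probability follows a two-component beta mixture. Presets
  (heterochromatin): CG 0.85 strongly bimodal; CAG/CTG 0.40 bimodal
  (high component Beta(8, 1.5), low Beta(0.5, 10), weight solved for the
  mean); CCG unimodal Beta(3, 12), mean 0.20 — half of CAG/CTG;
  CAA/CTA 0.375 (the 35–40% heterochromatic range); CCC/CCT 0.05;
  remaining CHH 0.10. Arms: CG 0.25, CHG 0.08, all CHH 0.02. The mixture
  parameterisation is a modelling choice; only the bimodal-vs-unimodal
  shape and the means are treated as meaningful.
- **Features**: transposon families carry body signatures — the CMT-like
  family (heterochromatic, LINE/L1-style) re-uses the heterochromatic
  site models; the RdDM-like family (euchromatic, RathE1-style) has
  uniform moderate CHH (0.10) — plus a context-independent edge component
  A·exp(−d/300 bp) (A = 0.05 CMT-like, 0.35 RdDM-like). Genes carry a
  CHH-island component in their flanks only. The 300-bp decay is a
  declared scale for an edge-localised pattern whose true extent is not
  printed anywhere.
- **Observation**: coverage ~ Poisson(λ = 10); methylated calls ~
  Binomial(n, p + (1−p)ε) with ε = 0.005 — conversion failure produces
  false methylated calls only; failure to read true methylation is ignored
  (standard WGBS assumption). One record per cytosine per strand; no
  read-level simulation.
- **Genotypes**: multiplicative effects on the drawn per-site
  probabilities, keyed by (domain, subcontext/class): cmt2-like — CAA/CTA
  ×0.2, other CHH ×0.8 genome-wide, CHG ×0.75; nrpe1-like — euchromatic
  CHH ×0.15, edge and island amplitudes ×0.1, heterochromatin untouched.
- **Small RNA**: NB counts (dispersion 0.2) at two replicates per
  condition with per-sample library scales (1.0, 1.3, 0.8, 1.1); locus
  means lognormal (median 80, log-sd 1, floor 10); a configured fraction
  of 23–24-nt loci is reduced by the fold change (8×) in mutant samples;
  20–22-nt loci are undisturbed.

Fixed seed and configuration give byte-identical outputs; every stage
draws from an independently keyed generator so adding a genotype never
shifts another's stream.

Because edge and island components make raw domain means analytically
impure near features, the generator also emits "core" regions (domains
minus 2-kb neighborhoods of feature boundaries) where the expectation is
exactly the configured mean; recovery checks use cores, track-level
outputs use the full domains.

**What passing tests show — and do not.** The generator produces
independent sites with known mixtures, homogeneous domains with sharp
boundaries, i.i.d. nucleotides, and exact annotations. Real methylomes
have autocorrelated methylation, CpG-island-like composition structure,
mappability gaps, annotation errors and biological replicates. Passing
recovery tests therefore demonstrates correctness of the estimators and
pipeline plumbing under the stated model, not robustness to those
real-data pathologies; the track/profile machinery makes no smoothness
assumptions, but the differential test's calibration is only verified
under NB sampling.

## Problem sizes

Tests and the acceptance script run the methylome analyses on a 2-Mb
chromosome (~760k cytosine records per genotype, three genotypes) with a
120-kb control contig, and the small-RNA analyses on 300 + 1000 locus
tables — sizes at which every configured parameter is recoverable within
its sampling error while a full run stays around a minute. Binned-track
bin size is 100 kb at this genome size (the 500-kb default targets real
chromosome-scale inputs).

## Known limitations

- The differential test is asymptotic (Wald); at very low counts its
  p-values are approximate even under the NB model. The "sufficient
  counts" filter removes the worst cases.
- `site_mean` at min_depth 1 is noisy for shallow data; the pooled
  estimator or a higher depth threshold is preferable below ~5× coverage.
- Edge-enrichment statistics depend on body bin width relative to the
  edge decay scale; compare values only across profiles with the same
  layout.
- The perfect-alignment control on real reads is out of scope: reports
  produced under strict-alignment settings are simply another input, there
  is no re-alignment here.
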