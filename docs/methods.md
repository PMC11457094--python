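# Methods

`gcflux` analyses gene conversion between chromosomal inversion arrangements
segregating in one population. Because single crossovers in an inversion
heterokaryotype produce unbalanced gametes, genetic flux between arrangements
is dominated by gene conversion: short (hundreds of bp) non-reciprocal copies
of one arrangement's sequence into another. Accumulated conversion tracts
homogenize neutral sequence between arrangements; genes under
arrangement-specific selection resist this homogenization because conversion
tracts that import foreign alleles are removed by purifying selection. The
pipeline therefore (i) detects conversion tracts from an aligned haplotype
panel, (ii) fits a geometric tract-length model with a detection correction,
(iii) converts tracts to per-nucleotide coverage maps, and (iv) asks, with a
battery of permutation and classical tests, whether candidate selected
("outlier") genes receive significantly less conversion coverage than the
rest.

## Detection model

For an ordered (donor, recipient) pair of arrangements and a focal recipient
strain, each site is classified from arrangement-wise allele frequencies with
gap (`-`) and missing (`N`) chromosomes removed from every denominator:

* **informative** — the strain's allele has frequency `f_d` in the donor
  arrangement and `f_r` among the other strains of its own arrangement, with
  `f_d >= min_donor_freq` (default 0.5) and `f_d > f_r`. Its weight is
  `psi = f_d * (1 - f_r)`, which is 1 for a perfectly diagnostic site and
  decays as the frequency contrast weakens. The literature behind this
  statistic does not fix a unique closed form; this product form is monotone
  in both requirements (near-fixed in the donor, rare in the recipient) and
  is isolated behind `site_psi` so an alternative can be swapped in.
* **contradicting** — the strain's allele is absent from the donor but
  present in its own arrangement background: evidence the strain still sits
  on its own haplotype there.
* **neutral** — everything else, including sites identical between
  arrangements; converted segments legitimately contain such sites, so they
  never terminate a tract.

A tract is a maximal run of `>= 2` informative sites, within one syntenic
region, uninterrupted by a contradicting site. Its coordinates are the
outermost informative sites; its length excluding gaps subtracts the strain's
gap columns inside the span. Tracts never straddle syntenic-block boundaries
because inversion breakpoints interrupt pairing. Optional column chunking
(`chunk_size`, nominally 250 kb) exists only for memory parity; calls are
invariant to it by construction and by property test.

Redundancy is removed in two steps: overlapping detections in the same strain
collapse to one record (the variant with the most informative sites wins;
donor arrangements are unioned), and identical coordinates in several strains
of one arrangement — one ancestral event risen in frequency — collapse to the
alphabetically first strain. Overlap-collapse rather than exact-coordinate
matching was chosen for the first rule: it is the conservative reading (it
only lowers coverage). Polarity analyses use the subset with a single
candidate donor; the model fits use each tract in every donor group it was
detected under, mirroring the per-pair detection lists they summarize.

## Tract-length model and detection correction

True tract lengths are geometric, `P(L = l) = (1 - phi) phi^(l-1)`, so `phi`
is the per-nucleotide extension probability and the mean length is
`1/(1 - phi)` (e.g. `phi = 0.995` gives 200 bp, the scale reported for
*Drosophila* conversion tracts). Detection marks each nucleotide of a true
tract informative independently with probability `psi_bar`, the pooled mean
per-site psi of the (region, donor, recipient) group; an event is observed
when at least two sites are marked, and the observed span is the
outermost-marked distance. With `q = 1 - psi_bar`:

    P(detect)          = 1 - (1-phi) q / (1-phi q) - psi_bar (1-phi) / (1-phi q)^2
    P(span = d & det)  = psi_bar^2 (1-phi) phi^(d-1) / (1-phi q)^2,  d >= 2
    P(unobserved)      = 1 - P(detect)
    E(k_true)          = k_observed / (1 - P(unobserved))

These closed forms follow from geometric series and are verified against
brute-force simulation in the tests. `phi` is estimated by maximizing the
conditional span likelihood on a logit scale (bounded 1-D search, tolerance
1e-8, deterministic and order-invariant); the asymptotic variance is the
inverse negative second derivative of the log-likelihood at the optimum by
central differences. The tract-length interval is the endpoint
transformation `1/(1 - (phi_hat +/- 1.96 SE))` clipped to (0, inf) — chosen
over the delta method because it respects the (0, 1) domain of `phi`. When
every span equals the minimum the likelihood pushes `phi` to a boundary; the
fit warns rather than fails. Groups need at least two tracts.

## Coverage maps

Coverage counts the full span `[start, end]` of each non-redundant tract —
the converted segment is the span; informative sites merely mark its ends.
(`coverage_basis="nongap"` accumulates only the non-gap length instead.) The
histogram is exact: its mass equals the summed span lengths on every run.
Per-feature means divide summed coverage by feature length over a partition
of the chromosome into CDS, intron and intergenic classes with precedence
CDS > intron > intergenic for overlapping annotation. Transcript coverage is
the *unweighted* mean of per-exon means, deliberately not length-weighted.
Extreme features are flagged beyond two sample standard deviations of their
region's mean; because coverage is non-negative, a negative lower threshold
means no low flags are possible. Gap QC reports the fraction of `-`/`N`
cells per arrangement per region (the study's panels sit near 2%).

## Statistical battery

All permutation engines are seeded, bit-reproducible, and use add-one
empirical p-values `(b + 1)/(m + 1)` with ties counted on both sides, so
`p_lower + p_upper >= 1` and no finite run returns p = 0.

* **Outlier-label permutation** — reassigns outlier labels across genes;
  statistic: unweighted mean transcript coverage of outlier genes.
* **Tract shuffle** — re-places each observed tract uniformly within its
  syntenic region (length preserved); statistic: pooled mean coverage over
  outlier-CDS nucleotides. The within-region placement keeps the null
  comparable to the model-based null; `chromosome_wide=True` relaxes it.
* **Model-based null** — generates `ceil(E(k))` tracts per (region, donor)
  from the fitted geometric model, lengths rejection-sampled to fit the
  region and starts redrawn when a tract would cross a region edge.
* **Three-category classification** — genes fall below, within, or above the
  permutation null envelope; a 2 x 3 chi-square homogeneity test (df = 2)
  compares outlier and non-outlier genes, with a validity flag when an
  expected count drops below 1.
* **Polarity permutation** — each single-donor event independently receives
  a new ordered donor/recipient pair drawn uniformly from all non-self pairs,
  preserving its region. The uniform-per-event scheme is one of several
  readings of "permuting classifications under the non-self constraint"; it
  is documented here and seed-controlled.
* **Median tract-length permutation** — shuffles tracts across regions
  keeping per-region counts, recomputing regional medians.
* **Chi-square tests** — goodness of fit of tract counts against sampling
  proportions (df = k - 1) and region x arrangement homogeneity
  (df = (r-1)(c-1)); cells with standardized residual |(o - e)/sqrt(e)| > 2
  are flagged deficient/excess (the threshold 2 is this package's
  convention).
* **ANOVA with planned contrast** — one-way ANOVA of normalized per-gene
  coverage (values divided by the arrangement mean) across arrangement
  backgrounds, plus a single-df contrast of the focal arrangement against
  the unweighted mean of the remaining groups on the pooled error term.
* **Tajima's D** — computed per gene and arrangement with
  pairwise-complete site handling; significance uses the scaled-beta
  approximation over the theoretical range of D (swappable; degenerate for
  n = 3, where the variance constants vanish).
* **Heterokaryotype correlation** — Spearman rank correlation between
  per-pair event counts and maximum observed heterokaryotype frequency.

## Synthetic data generator

The generator emulates the statistical structure the detector consumes, not
a coalescent. Arrangements act as nearly isolated subpopulations, so
divergence is modelled directly as arrangement-diagnostic biallelic sites
(probability `divergence_rate` per site, owner drawn uniformly, fixed within
the owner), on top of a shared ancestral sequence, within-arrangement
polymorphism (`theta_site`, carrier frequency uniform on 0.1-0.6), and ~2%
alignment gaps. Conversion events per ordered arrangement pair are Poisson
(`events_per_pair`); each copies the current alleles of a uniformly chosen
donor strain onto a uniformly chosen recipient strain over a geometric
window that never straddles a region boundary. A purifying-selection veto
deletes, with probability `veto_probability`, any event overlapping an
outlier CDS of the recipient's own arrangement; every event is recorded in a
truth table with its survival flag. Outlier genes are interspersed (adjacent
runs capped), each assigned one background arrangement, optionally
restricted to focal arrangements so a single background carries the whole
outlier set.

Defaults are the desk-scale study conditions: five arrangements with sample
sizes (15, 8, 10, 9, 9), a 500 kb chromosome in 14 ordered syntenic regions,
`phi_true = 0.995` (200 bp mean tracts), gap rate 0.02, and
`events_per_pair = 625`, which gives each recipient arrangement roughly 1-2x
expected tract coverage — the coverage regime of the real chromosome. What
the generator does **not** reproduce: linkage disequilibrium from genealogy,
mutation-rate heterogeneity, breakpoint-proximity effects, and read-mapping
artefacts. Passing tests therefore demonstrate correctness of the method's
logic and calibration under its own assumptions, not robustness to every
property of real resequencing panels.

## Numerical and design notes

* Internal coordinates are 1-based inclusive everywhere; BED/BedGraph are
  converted exactly once at I/O.
* Multi-allelic sites reduce to focal-allele-vs-rest frequencies.
* Detection restricts computation to panel-wide polymorphic columns — exact,
  since monomorphic sites can be neither informative nor contradicting.
* Problem sizes in the test-suite simulations (500 kb chromosome, 50
  replicate analyses, 199-999 permutation replicates, 10^6-draw Monte-Carlo
  oracles) are the package's desk-scale verification conditions; the
  pipeline itself is linear in chromosome length and strain count.
* Known limitations: nearby events in one strain can be bridged into a
  single detected tract when no contradicting site falls between them
  (inflating spans slightly); detection power vanishes for tracts spanning
  fewer than two informative sites, which is exactly what the E(k)
  correction quantifies; the psi closed form is a documented convention, not
  a published formula.
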