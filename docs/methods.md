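# Methods

## Scope and substrate

All statistics operate on a `HaplotypeMatrix`: an n × m binary matrix of
phased haplotypes (0 = ancestral/reference, 1 = derived/alternate) over
strictly increasing 1-based bp positions. Strains are haploid-coded — the
panels the package targets are inbred lines, one haplotype per strain.
Missing genotypes must be resolved before matrix construction (the default
policy admits none); unphased diploid VCF records are rejected because every
haplotype statistic requires phase. Polarization treats the reference allele
as ancestral by default; callers with outgroup information can repolarize
before construction. Site filtering keeps SNPs with minor allele frequency
≥ 1/(2n) by default (comparison is ≥, keep-on-equal) and removes indel
records.

## The coalescent generator

The neutral simulator is a Kingman coalescent without recombination: waiting
times Exp(k(k−1)/2) in coalescent units, uniformly random topology, mutation
count Poisson(θ·L/2) with L the total branch length, each mutation placed on
a branch with probability proportional to its length. Infinite-sites
positions are drawn uniformly on [0, region_length), floored to integers, and
redrawn on collision, so sites are distinct integer bp. Under this model
E[S] = θ·Σ_{i<n} 1/i and E[π] = θ, which the test suite verifies within 3
standard errors at n = 10, θ = 5, 2000 replicates, alongside a cross-check of
mean S against msprime on the same parameters.

**No recombination** is a deliberate simplification: the focal region is
2 kb, where intra-window recombination is negligible in *D. melanogaster*.
Chromosome-scale background is supplied instead as many independent windows
(`simulate_background_windows`), each an independent genealogy — appropriate
for empirical-null construction, though it slightly understates the
autocorrelation a real sliding scan would see.

**The sweep model is a time-scaling surrogate, not forward selection.**
Carriers coalesce among themselves with waiting times multiplied by
`sweep_strength` ∈ (0, 1], forcing a recent common ancestor and long shared
haplotypes; the carrier ancestor then joins the neutral coalescent of the
non-carriers at the time it forms. At `sweep_strength = 1` the carrier
subsample is exactly a neutral Kingman coalescent (exchangeability), which
the suite verifies on carrier pairwise diversity. The construction is
sufficient for qualitative power analysis (does a statistic rank sweep
windows above neutral windows?); it does not model the fixation trajectory,
recombination off the sweep, or soft sweeps from recurrent mutation, so
measured AUCs should be read as properties of this surrogate, not as power
estimates for any natural population.

All generators draw from one explicit seed through
`numpy.random.SeedSequence` spawning, so identical seeds give bit-identical
output and nested simulations never share streams.

### Default study conditions

The insertion-panel generator mirrors the study design it emulates: each
strain receives at most one insertion allele by multinomial draw (focal
allele ~10%, the most common other allele ~13%, remaining alleles rare),
focal carriers get the sweep-structured genealogy in the 2-kb focal region,
and the scan partitions mirror the real sample sizes (on the order of 10
focal carriers vs 15 non-carriers). θ = 20 per 2-kb region (≈0.01/bp) is a
realistic autosomal diversity level for the species; the viability generator
uses 8–20 vials of 30 or 50 embryos in a balanced 2 × 2 condition × genotype
design, with cell means additive on the arcsine scale and counts binomial.

## Selection statistics

- **EHH** at extension site x is Σ_h C(c_h,2)/C(n_c,2) over identity classes
  of carrier haplotypes on the closed interval [core, x]. The walk truncates
  when EHH < 0.05 (`decay_cutoff`) or a gap > 200 kb is crossed — the default
  parameters of the scan tools standard in this field; both are arguments.
  The inner walk maintains identity classes incrementally (split by the new
  site's allele, compact relabel) and is JIT-compiled with numba; class ids
  stay below n so no sorting is needed.
- **iHH** integrates EHH against distance by the trapezoid rule, both
  directions summed. Profiles truncated by the data edge are integrated to
  the edge rather than dropped — on 2-kb desk-scale windows, dropping
  edge-truncated cores would empty the scan. Sites with fewer than 2 carriers
  of either allele, core MAF < 0.05, or a zero integral are dropped.
- **iHS/nSL standardization** uses 50 equal-width derived-frequency bins on
  [0, 1]; adjacent bins are merged left to right until each populated group
  holds ≥ 20 sites, with an undersized tail folding into the previous group.
  `FrequencyBins.fit` / `.apply` separates fitting the bin moments (on a
  mostly-neutral background, as a genome-wide scan does) from applying them
  to a window; `standardize_by_frequency` is the self-standardizing
  convenience form used within one scan. nSL is the identical pipeline with
  unit distance per segregating site and no bp-gap truncation.
- **XP-EHH** uses all haplotypes of each panel (no allele split) and
  standardizes over all scanned sites; positive values mean longer
  homozygosity in panel A. Panels must agree exactly on positions; the error
  names the first mismatching coordinate.
- **H12** groups exact haplotype strings over windows of 40 segregating
  sites (sliding step 1 by default). Ties in the sorted frequency vector are
  broken by (frequency desc, haplotype string asc) so results are
  deterministic.
- **Tajima's D** returns NaN with a warning at S = 0 rather than raising:
  a monomorphic carrier set is an expected, meaningful outcome (it is the
  strongest possible S signal), not an error.

## Empirical significance

S in a k-strain subset is compared against k-strain resampling draws (without
replacement) from the full panel; the default is 10,000 replicates for 1e-4
p-resolution, scaled down where a run computes hundreds of nulls. All other
statistics are compared against their empirical distribution over background
windows restricted to the same strain subset, with the same window width and
filters as the focal region. Tail assignments follow the directional
hypotheses — lower for S and D (reduced diversity, excess rare variants),
upper for H12, |iHS|, |nSL|, and XP-EHH with carriers as panel A — and are
overridable. P-values use (r+1)/(N+1), never exactly zero; nulls under 100
values warn about coarseness. For iHS/nSL in the partitioned scan the focal
window's sites are pooled with the background sites for standardization (one
window among dozens contaminates the bin moments negligibly, and pooling
preserves focal/background exchangeability under the null, which is what
makes the empirical p-value uniform — verified by the false-positive-rate
calibration at 150–200 neutral seeds).

## Annotation arithmetic

- **TSD detection** finds the decomposition absent = P+T+Q,
  present = P+T+E+T+Q maximizing |T|, leftmost on ties. With random flanks
  the planted duplication is sometimes extendable by chance adjacency
  (roughly half the time for 5-nt TSDs on uniform-random sequence); the
  detector then correctly reports the longer duplication, and the
  decomposition always reconstructs the present allele exactly. Tests assert
  exact recovery whenever the boundary is unambiguous plus the
  reconstruction identity always.
- **TSD logos** include only sequences of the modal length (a consensus
  built from the typical 5-nt duplications, excluding shorter outliers);
  consensus ties emit IUPAC ambiguity codes.
- **PWM scanning** builds log-odds from count matrices with a pseudocount of
  0.01 × background per cell (background uniform by default; JASPAR PFMs are
  parsed via Biopython). The relative score maps the best attainable window
  score to 1 and the worst to 0; hits are strictly above the threshold
  (0.995 in the intended promoter scans), and the reverse strand is scanned
  on the reverse complement with positions reported in forward coordinates.
- **The amplicon model** is calibrated to the four published product sizes
  (absent FL-R 638 bp, present FL-R 1066 = 638 + 428, L-R 616 bp, element
  428 bp); exact primer coordinates are not published. Element length is
  added *without* the 5-bp TSD by default because 1066 = 638 + 428 ignores
  it (a flag enables TSD-inclusive sizes). The L primer sits in the element
  near its 3' end in forward orientation, so L-R shifts by −offset and
  reverse orientation voids the product — the geometry that reproduces the
  published "only FL-R" class for the four reverse insertions. Band matching
  uses a ±20 bp gel-resolution tolerance (configurable); the +7 offset is
  therefore classified "present", matching the published table.
- **Transcript models**: the TE-initiated isoform (276-bp 5'-UTR, first
  50 bp inside the element at the reference allele) exists only for
  forward-oriented, gene-proximal elements flagged `te_internal_tss`; its
  UTR shrinks by the downstream offset (the +7 element gives 269 bp). The
  downstream-TSS isoform (201 bp) always exists.
- **Promoter proximity** is strand-aware 0-based half-open interval logic: a
  TE qualifies if it overlaps the 1-kb window upstream of a gene's 5' end or
  the 5'-most base itself.

## Phenotype statistics

The viability pipeline is proportions → arcsin√p → Kolmogorov–Smirnov
normality check → rank transform if rejected → two-way ANOVA, and the branch
taken is reported. The KS test uses Lilliefors critical values (parameters
estimated from the sample, via statsmodels); a zero-variance sample is
declared non-normal. The ANOVA is an OLS fit with sum-to-zero contrasts and
Type III sums of squares — on the balanced designs generated here the choice
is moot (verified against the sequential decomposition to 1e-10), but it
matches the convention of the statistical software the workflow emulates.
Replicate enters as a crossed fixed main effect; partial
η² = SS_term/(SS_term + SS_residual) with small/medium/large classes at
0.01/0.06/0.14. qPCR expression is E_t^(−Ct_t)/E_r^(−Ct_r) with
amplification factors in (1, 2] (a 99.1% primer efficiency gives
E = 1.991); biological replicates are averaged per sample before a Welch
two-sided t-test between genotype groups.

## What passing tests do and do not show

The generator produces panels with known truth under idealized conditions:
no recombination, no missing data, no genotyping error, equilibrium
demography, a surrogate sweep. Passing calibration and power tests therefore
shows the *implementations* are correct and internally calibrated; it does
not certify power or false-positive rates on real strain panels, where
demography, inbreeding artifacts and variant-calling error all intrude.
Quantities that depend on external panel genotypes or wet-lab measurements
(the published scan p-values, effect sizes, and population frequencies) are
out of reach of a synthetic rebuild and are not claimed.

## Simulation sizes

Default problem sizes were chosen once as the smallest that give stable
calibration: 2000 replicates for E[S], 1000 for mean Tajima's D, 200
windows for pooled iHS/nSL moments, 300–500 sweep/neutral pairs for AUCs,
150–200 neutral seeds × 40 background windows for the false-positive rate,
400–600 tables for ANOVA type-I error, 150–200 for power, 500 constructs
for TSD recovery. The acceptance script reports each measured value with the
problem size used.

## Known limitations

- The EHH family assumes dense, phased, error-free haplotypes; no missing-
  data handling inside the statistics.
- The sweep surrogate cannot distinguish hard from soft sweeps; H12's
  soft-sweep sensitivity is exercised only qualitatively.
- Background windows are independent rather than contiguous, so the
  empirical null ignores along-chromosome autocorrelation.
- The amplicon model is qualitative beyond the four calibrated sizes; it
  does not model primer thermodynamics or PCR failure.
- `build_tsd_logo` assumes a single modal length; bimodal TSD-length
  distributions would need explicit handling.
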