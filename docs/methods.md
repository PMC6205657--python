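# Methods

## The inference problem

A host insect population carries an intracellular bacterial symbiont.
Pooled resequencing of phenotypically contrasting host groups yields,
for each polymorphic site of the symbiont genome, read counts for the
reference (N) and alternative (S) alleles. If the population harbours
two clonal symbiont strains, three signatures co-occur: (i) all
diagnostic SNPs in a pool segregate at one shared frequency — the
S-strain fraction of that pool's symbiont chromosomes; (ii) windowed
F<sub>ST</sub> between a pool fixed for N and a mixed pool is flat at
that fraction across the genome; (iii) diagnostic SNPs are in complete
linkage disequilibrium. `symbiostrain` computes all three, then types
individuals and quantifies the strain's phenotypic association.

## Two-strain model and the synthetic generator

The generator assumes two clonal haplotypes with no within-strain
polymorphism, no indels, and no recombination — strain identity at one
site determines it at all others. Defaults are the study conditions of
the planthopper/*Arsenophonus* system the package was built around:

| parameter | default | meaning |
|---|---|---|
| `divergence_rate` | 0.65 /100 bp | fixed differences between haplotypes |
| resistant pool depth | 96× | mean reads per site (Poisson) |
| susceptible pool depth | 40× | " |
| susceptible `s_fraction` | 0.47 | S chromosomes in the pool |
| `error_rate` | 0 | symmetric per-base miscall probability |
| `cryptic_fraction` | 0 (opt-in 0.0859) | sub-chromatogram minor-strain titer |
| chromatogram `noise_sd` | 0.05 | multiplicative peak-height noise |
| bioassay layout | 5 doses × 3 × 20 | stem-dip assay scale |
| selection | 3 generations | class-specific survival |

Read sampling is per-site independent: depth ~ Poisson(mean), S-allele
count ~ Binomial(depth, f(1−e) + (1−f)e). Chromatogram peak heights are
titer shares times 1 + N(0, sd), truncated at 0, which keeps
minor/major ratios scale-free. Selection survival is binomial per
carrier class with multinomial refilling at survivor proportions; its
deterministic expectation f·s^g (renormalised) is exposed as
`expected_selection_frequencies` and used as the test oracle.

What the generator does *not* emulate: read-level errors correlated
along reads, mapping bias, copy-number variation of symbiont titer
across tissues, within-strain diversity, or unequal DNA contributions
of pooled individuals (the pool is treated as a well-mixed chromosome
population). Passing tests therefore demonstrate correctness of the
estimators under the stated sampling models, not robustness to
alignment artefacts.

## F<sub>ST</sub>

Per site, Hudson's estimator on pool frequencies:
num = H<sub>b</sub> − H<sub>w</sub>, den = H<sub>b</sub>, with
H<sub>w</sub> = (2p₁q₁ + 2p₂q₂)/2 and H<sub>b</sub> = p₁q₂ + p₂q₁.
Windows (5 kb, 1-kb step; half-open 0-based internally, BED on disk)
combine sites as Σnum/Σden (ratio of averages). Sites where both pools
are fixed for the same allele (den = 0) are undefined and excluded;
windows with no usable site are omitted and counted. The plain
frequency plug-in is used — with one pool fixed its expectation is
f + (1−f)/depth, a +0.01 inflation at 40×, accepted for transparency
rather than hiding a depth correction inside the estimator. A Weir &
Cockerham variant using pool depths as haploid sample sizes is provided
for comparison; its per-site estimates may be negative and are kept in
sums, clamped only in banded reporting. Genome summaries report the
window mean and band fractions (defaults: |F<sub>ST</sub>| < 0.005 "no
difference", [0.01, 0.30], remainder). The depth filter defaults to
min_depth = 10.

## Linkage disequilibrium

r² = D²/(p<sub>A</sub>p<sub>a</sub>p<sub>B</sub>p<sub>b</sub>) from
0/1 chromosome vectors (equivalently the squared Pearson correlation).
For unphased 0/1/2 genotypes, two-locus haplotype frequencies are
estimated by EM (50 iterations or Δ < 1e-8, initialised at linkage
equilibrium, deterministic): only the double heterozygote is
phase-ambiguous and is split between coupling and repulsion by the
current frequency estimates. When no double heterozygotes occur the EM
solution equals the phased computation exactly; a sample consisting
*only* of double heterozygotes is a known degenerate case (the
equilibrium initialisation is a stationary point) and is the reason
typing-based workflows should include homozygous carriers. LD is
computed from per-individual data, never from pooled frequencies —
pooled libraries carry no phase information, so co-segregation claims
are only defensible at the individual level.

The single-strain verdict requires (a) every scaffold's median window
mean-r² ≥ 0.33 (the observed lower bound in the motivating system;
configurable) and (b) the sd of diagnostic-site pool frequencies not
exceeding twice the binomial sd implied by the median depth — a
coherent mixture has one shared frequency, so any spread beyond read
sampling argues against a single second strain.

## Mixture estimation and chromatogram typing

The pooled-binomial MLE f̂ = Σs/Σd over passing sites, with a Wilson
score 95% interval on the pooled counts (chosen over Wald for its
behaviour near 0, the cryptic co-infection regime; empirical coverage
≥ 93% at depth ≥ 500 in the test suite). Per-site frequencies are
returned for heterogeneity inspection.

Chromatogram calls: ratio = minor/major peak height; ratio ≥ τ ⇒ Mix
(boundary inclusive), else the major peak's strain; τ defaults to 0.25
because Sanger secondary peaks below ~20–30% of the major peak are
routinely indistinguishable from baseline noise. Consensus per
individual is a majority vote in which any N/S discordance resolves to
Mix — under clonal strains, conflicting dominant calls at different
sites imply genuine co-infection, not error — and ties with Mix go to
Mix. Cross-amplicon consistency (all fragments of an individual agree)
is reported as a rate with the discordant individuals listed. Cohort
tables emit both the strict S frequency and S-or-Mix, since population
surveys differ in whether even co-infections count toward the novel
strain.

## Consequence annotation

Single-CDS bacterial gene models (1-based inclusive, ± strand, frame 0,
length divisible by 3 enforced). The affected codon is translated
before/after substitution under NCBI table 11; GTG/TTG are accepted
start codons translated as M at codon 1, and their loss (to a non-start
codon) is start_lost. A stop gained strictly before the annotated final
codon is a premature termination codon; summaries report both PTC SNPs
and PTC-carrying genes because either may be meant by a PTC tally.
Enrichment uses two-sided Fisher exact tests (minimum-likelihood
convention, via scipy) with Benjamini–Hochberg adjustment across all
tested terms. Correctness is checked against a whole-protein-diff
oracle on 1,000 random genes and a hypergeometric enumeration oracle.

## Bioassay statistics

The LC-P line Φ⁻¹(mortality) = α + β·log10(concentration) is fitted as
a binomial GLM with probit link (IRLS, ≤ 100 iterations, tolerance
1e-8); log10 follows entomological convention. Complete separation
(every dose at pooled 0% or 100% mortality) is rejected with advice to
add intermediate doses. Goodness of fit is the Pearson heterogeneity
χ² on per-dose pooled counts (df = doses − 2). LCq = 10^((Φ⁻¹(q)−α)/β);
95% limits come from Fieller's theorem on the ratio (z_q−α)/β using the
fitted covariance, falling back to the delta method (flagged) when the
Fieller quadratic is degenerate, i.e. the slope is not significantly
nonzero. An Abbott control-mortality correction is provided but off by
default. The "u-test" for cohort frequency change is the pooled-variance
two-proportion z-test, z = (p̂₁−p̂₂)/√(p̄(1−p̄)(1/n₁+1/n₂)), two-sided;
a pooled proportion of exactly 0 or 1 returns P = 1 with a degeneracy
flag.

## Pipeline, determinism and problem sizes

`run_discovery` composes the stages, writes every intermediate file
(TSV/VCF/FASTA/BED/CSV), a JSON report and a markdown summary, and logs
stage-by-stage to stderr and `run.log`. All randomness flows through
explicit seeds spawned from the config seed via `SeedSequence`; a fixed
config reproduces byte-identical reports.

The test suite and `scripts/acceptance.py` run at desk scale, chosen so
each statistic's Monte-Carlo error is well inside its assertion band:
~1 Mb of diagnostic sites (≈ 6,500 SNPs) for the FST/frequency checks,
5 × 50 kb scaffolds with 50 individuals for LD, ~2,000 sites at 100×
for the cryptic mixture, 200 replicates for coverage and unbiasedness
properties. Full suite ≈ 10 s on one core.

## Known limitations

- LD from pooled libraries is not attempted (no phase information);
  individual-level data are required for the co-segregation verdict.
- No indels, multi-nucleotide variants, or multi-exon gene models in
  consequence calling; terms are flat categories (no GO DAG
  propagation).
- The probit module offers no logit/Weibull alternatives or
  time-to-death models.
- The EM r² degenerates when every individual is a double heterozygote
  at both sites (all-Mix cohorts).
- Negative Hudson numerators can produce slightly negative window
  estimates in undifferentiated regions; they are retained in means and
  clamped only for band reporting.
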