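# Methods

## MLST diversity statistics

Marker alignments hold Sanger consensus sequences over
{A, C, G, T, R, Y, S, W, K, M, N, −}; a two-fold IUPAC code marks a
heterozygous position in one strain. Columns containing a gap or N in any
strain are excluded from every count — this is the only column-handling
convention under which heterozygous ≤ polymorphic ≤ total holds for all
loci, and it is applied uniformly. A column is *heterozygous* when at
least one strain carries an ambiguity code, and *polymorphic* when the
union of constituent alleles across strains (within-strain ambiguity
included) holds ≥ 2 bases; a column can be both. Percentages are rounded
half-up to two decimals, matching tabular reporting conventions.

Nucleotide diversity Π is the mean pairwise Hamming difference over all
C(2N, 2) pseudo-haplotype pairs after expanding each strain into two
haplotypes, computed per locus (a mean *number of differing sites*, which
can exceed 1); the per-site version is exposed as π per kb
(1000·Π/L_clean). Pseudo-haplotype phase is not identifiable from
consensus data; the alphabetically-first base goes to haplotype 1 at every
site. This choice is deterministic and invisible to every statistic
computed here (site counts, Π, F_IS, STRUCTURE export are all
phase-invariant).

## Inbreeding and selfing

F_IS uses the Weir & Cockerham (1984) single-population small-f estimator:
for each locus and allele with sample size n, allele frequency p and
observed heterozygote frequency Ho,

    c = Ho/2,   b = n/(n−1) · [p(1−p) − (2n−1)/(4n)·Ho],
    f = 1 − Σc / Σ(b+c)

with sums over alleles and loci (components summed before the ratio;
individuals missing a locus are dropped locus-wise). The simpler 1−Ho/He
estimator is available behind `method="ho-he"` for sensitivity checks.

Selfing from F_IS inverts the equilibrium F_IS = s/(2−s):
s = 2·F_IS/(1+F_IS), clamped to [0, 1]. A negative F_IS (heterozygote
excess) yields s = 0 with a warning rather than a negative rate.

Selfing from the heterozygosity profile maximizes the marginal likelihood
of the binary het matrix H under the model: individual i carries t_i
consecutive selfing generations with P(t) ∝ (1−s)·s^t truncated at t_max
(default 20, renormalized; at s = 1 the limit puts all mass at t_max), and
locus k is heterozygous with probability h0_k·2^(−t). Optimization is
L-BFGS-B over (s, h0_1..h0_K) with multi-start over s ∈ {0.1, …, 0.9} to
avoid boundary traps; the standard error is the numerical curvature of the
profile log-likelihood in s (h0 re-optimized at s ± 0.02). A panel with no
heterozygote anywhere returns the boundary ŝ = 1 with an undefined SE. The
moment diagnostic g2 (mean over locus pairs of ⟨H_k H_l⟩/⟨H_k⟩⟨H_l⟩ − 1)
is reported alongside; the ML estimate is primary.

STRUCTURE export encodes nucleotide alleles as A→0, C→1, G→2, T→3
(alphabetical; the two-digit range is fixed by the format but the mapping
is a package choice, configurable via the module dictionaries) and missing
as −9, two rows per individual.

## Synthetic-data model

The generator emulates the statistical structure the analyses assume, not
any particular organism's sequence:

- **Parental pair**: one uniform-random genome; the second differs by
  i.i.d. per-site substitutions at `divergence_rate` (uniform over the
  three alternative bases; no indels). The default 0.02/site is a
  configurable stand-in for a pair of closely related sister species — no
  published estimate is asserted.
- **Hybrid plan**: segments tile the genome with per-segment copy counts
  (0–4 per subgenome); copy "slots" persisting across adjacent segments
  form contiguous chromosome fragments. Heterozygous sites are planted as
  Poisson events per kb on exactly one uniformly chosen copy of the
  carrying subgenome, never inside LOH segments. With one carrying copy the
  planted site is a homozygous substitution — which is why a haploid
  subgenome shows (correctly) near-zero *called* heterozygosity.
- **Reads**: paired 2×150 bp with fixed 400-bp inserts (the library design
  the profiling targets), Poisson pair counts per fragment at `coverage`
  per copy, uniform substitution errors (default 0.001/base, a typical
  Illumina scale). No indel or quality-model simulation.
- **Selfing panels**: the t/2^(−t) model above, with two alleles per locus
  at frequency 1/2 (homozygotes pick one uniformly), so E[F_IS] = s/(2−s)
  holds by construction.
- **Flow events**: a two-component normal mixture at (g1, 2·g1) with a
  shared coefficient of variation; negatives are resampled.

What the generator does *not* emulate — indels and structural variants,
mapping biases around repeats, GC-coverage waves, PCR duplicates, base
quality structure, linkage between MLST loci — bounds what passing tests
show: recovery holds for the idealized error model, not for every artifact
of real libraries. The production path for real data is SAM/VCF import.

All randomness flows through `numpy.random.default_rng` (PCG64) from one
explicit seed per call; identical seeds give byte-identical FASTQ/TSV/BED.

## Read assignment and copy number

The built-in competitive assigner indexes exact 31-mers of each reference,
probes read k-mers at stride k (both orientations), and scores candidate
placements by Hamming distance (valid because simulated reads are
substitution-only; budget 8 mismatches per 150 bp read). The best score
per reference decides: strictly better on one side → unique; tie →
ambiguous (removed); no placement within budget → unmapped. SAM import
applies the same rule to mapped flags and alignment scores and assumes
deduplicated input. The built-in path exists so the full chain runs
without an external aligner; it is not a general-purpose mapper (no
indels, single scaffold per subgenome).

Window depth (1700 nt, non-overlapping; trailing short windows flagged and
excluded from summaries) is normalized by the 1n depth = summed mean
unique depth of both subgenomes / total ploidy. If the ploidy is not
supplied it is estimated as the P ∈ {2, 3, 4} minimizing the mean squared
rounding residual of window depth ratios, and flagged. Empty windows use a
pseudo-depth of 0.25 reads (half the minimum countable) for the log2
track. Copy number per window is the median-filtered (5 windows) depth
ratio rounded and capped at the total ploidy; windows whose smoothed ratio
sits > 0.25 from every integer are flagged, and a > 20% flagged fraction
marks the strain as a possible mixed cell population (non-integer coverage
plateaus are reported, not forced to integers).

## Variant calls, heterozygosity and allele balance

The pileup caller is deliberately simple (it stands in for a full
reassembly-based caller, and is documented as such): alleles reaching 15%
of depth at positions with depth ≥ 8 form the genotype; AD holds raw
counts. Quality annotations (QD, FS, SOR, MQ, rank sums) are only trusted
from VCF import; the built-in caller leaves them absent rather than
fabricating values, and a missing annotation simply skips that hard-filter
criterion. Hard-filter thresholds: QD < 5.0, FS > 55, SOR > 2.0, MQ < 40,
MQRankSum < −5.0, ReadPosRankSum < −5.0.

Allelic state: 0/1 genotypes are biallelic unconditionally (the
alternative reading, applying the 5% reference-read rule to 0/1 as well,
is switchable via `strict_ref_on_01`); 1/2 genotypes are biallelic when
reference reads are < 5% of depth, triallelic when the reference and both
alternatives are supported at ≥ 5%.

Heterozygous-SNP density uses 10-kb non-overlapping windows; the
genome-wide heterozygosity percent divides filtered biallelic heterozygous
sites by the reference subgenome length (pass a callable-site count to use
that denominator instead). LOH tracts are maximal runs of ≥ 5 consecutive
windows with ≤ 1 heterozygous SNP (both thresholds configurable; the
defaults resolve tracts ≥ 50 kb against a ≥ 2 SNP/kb background).
Minor-allele balance uses 2-kb windows; the global mode comes from a
Gaussian KDE of per-site minor fractions mirrored around 0.5, so an
even-balance population peaks at 0.5 exactly instead of just inside the
folding boundary. The three window sizes (1700 / 10 000 / 2000 nt) are
distinct per track and all overridable.

IBS0/IBS1 counts use multiset allele sharing per site on the
missing-data-free joint call set (IBS2 sites count in neither); for
haploid subgenomes only IBS0 is meaningful and IBS1 is suppressed. The
SNP PCA centers alternate-allele dosages and eigendecomposes via SVD;
variance fractions sum to 1 over all components.

## Flow cytometry

G1/G2 fitting: KDE modes initialize a two-component normal EM whose second
mean is projected into [1.7, 2.3]×G1 after every M-step (the 2× DNA-content
constraint relaxed by ±15%); 5 jittered restarts with a fixed seed. If no
secondary KDE mode exists in the band, G2 is reported absent. A
substantial KDE mode (≥ 10% of the main peak's density) far from both
fitted means raises the ambiguity flag — the signature of a population
with mixed genome content. Ploidy is called relative to a reference strain
of known ploidy from the G1 mean ratio; the distance to the nearest
integer is the confidence proxy. Input is a plain one-column event table
of gated intensities; binary FCS parsing is out of scope (convert with any
FCS reader upstream).

## Problem sizes in the test suite

Simulated genomes are 100–200 kb at 30× per copy with 2% parental
divergence — large enough that window statistics, LOH tracts ≥ 50 kb and
Monte-Carlo recoveries (selfing panels of 500 individuals × 5 loci, 20
replicates) behave as on full genomes, while a full run of the suite stays
fast. Chromosome structure is a single scaffold per subgenome by default;
multi-chromosome designs are expressed as repeated calls (scaffold
boundaries are cosmetic for all statistics computed here).

## Known limitations

- The assigner and read model exclude indels/SVs; real data should come in
  as SAM/VCF from a production aligner/caller.
- Π per locus depends on the gap/N column filter; loci with many gapped
  columns report over fewer sites.
- The profile-likelihood selfing model assumes equal h0 decay across loci
  and no population structure; strong structure inflates ŝ.
- Flow fitting assumes debris/doublet gating upstream and exactly one
  dominant cell population per sample (flagged, not modelled, otherwise).
- The 1n-depth normalization reproduces the expected 2:1 log2 patterns on
  simulation but is one convention among several used by coverage-profiling
  tools; absolute log2 values may shift by a constant between conventions.
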