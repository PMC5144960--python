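# Methods

## The drive model

Meiotic drive at the chromosome-2 locus acts only through the female
germline: a dam heterozygous at the locus (genotype Wa) transmits the
meiotic product that carries the driven (WSB/EiJ, "W") allele at the locus
point with probability τ ∈ [0.5, 1]; sires and homozygous dams transmit
each product with probability 1/2. Because the choice is made between whole
recombinant products, flanking material linked to the driven allele
hitchhikes with it — this is what produces the excess of the driven founder
across the non-selected portion of the drive chromosome in simulations, and
it falls out of the transmission model rather than being imposed.

Reported transmission ratios vary with genetic background; the package
models this (optionally) as a per-dam τ drawn once per mating from a
user-supplied sampler. The default is a fixed τ = 0.66, the
population-level estimate for the episode the package models. Copy-number
variation and modifier loci are deliberately not modelled: τ subsumes them.

Under Hardy–Weinberg proportions, one generation of drive with no
selection maps the allele frequency p to

    p' = [p² + 2p(1−p)τ + p] / 2,

the maternal gamete frequency under drive averaged with the Mendelian
paternal frequency. Its fixed points are {0, 1} for τ > 1/2 and p′ > p on
(0, 1), so any τ > 1/2 sweeps to fixation deterministically. From
p₀ = 0.125 at τ = 0.75 the recursion first exceeds 0.60 at generation 10
and reaches 0.726 by generation 12, consistent with the observed timing of
the sweep this package reconstructs.

## The purge algebra

Breeders are classified aa / Wa / WW at the locus; a mating type is the
ordered (dam, sire) pair, nine types. The purge policy discards WW × WW
outright, retains a fraction f of WW × Wa and Wa × WW (f = 0 by default —
the strictest reading of "only a fraction were retained"; f is exposed as a
parameter), and selects minimum-W progeny within retained matings.
Discarded mass is redistributed proportionally over retained matings,
mirroring the colony's replacement rule (another lineage supplies the
parents).

The deterministic one-generation expectation enumerates the nine types at
HWE: aa-capable matings (aa×aa, Wa×Wa, Wa×aa, aa×Wa) contribute aa
breeders in the infinite-litter idealization, forced-Wa matings (aa×WW,
WW×aa) contribute Wa. At p = 0.62, τ = 0.66, f = 0 this gives 0.1133 —
the "62% to below 15% in one generation" planning figure. A finite-litter
mode replaces the idealization with the exact distribution of the minimum
W count over n genotyped progeny per sex; with ~8 genotyped pups per sex
the correction is small (P(no aa pup in a Wa×Wa litter) ≈ 0.83⁸ ≈ 0.22 per
sex, raising the expectation to ~0.16), which is why the stochastic
simulator's first-generation outcome sits slightly above the idealized
figure.

## The breeding simulator

One generation proceeds as: (1) pair the lineages' selected breeders by a
random permutation, repaired by pair swaps until no dam meets her own
litter-mate or a full sibling (bounded retries; an error signals an
infeasible tiny population); (2) draw per-mating failure, then litter
sizes and pup sexes; (3) draw each pup's locus genotype from the exact
per-type progeny distribution; (4) select breeders (at random from the
first litter under the standard scheme; minimum-W across the genotyped
litters under a purge policy); (5) construct full genomes only for
selected pups, conditioning each gamete on the pup's drawn locus allele.
The conditioning is exact because crossover placement is independent of
which product is transmitted; litter-mates never selected exist only as
counts in the mating records. This lazy embodiment is what keeps
175-lineage, multi-replicate runs tractable on one CPU.

Meiosis uses Poisson crossover counts (chromosome genetic length in
Morgans) with positions uniform in map distance — no interference; the
model is the simplest defensible one and is isolated behind
`draw_crossovers` for future extension. Mitochondria follow the dam,
the Y follows the sire, and the offspring lineage follows the dam
(matrilineal bookkeeping), so with failures disabled the mito/Y haplogroup
multisets are conserved exactly each generation; failed matings trigger
replacement from another lineage and are the only mechanism that changes
them. A/B duplicate matings are modelled: the B dam/sire are full siblings
of the A pair, B progeny back up the A mating and are otherwise flagged
for distribution.

Founding (G0) individuals carry independent random founder mosaics
(default ~8 segments per chromosome, labels uniform) — a stand-in for
incipient-CC genomes whose funnel structure is not reproduced. When a
starting allele frequency is requested, the founder label at the locus is
overridden per homologue. Litter sizes are truncated negative binomial
(default mean 9.0, dispersion 50 — near-Poisson); heterozygous dams lose
`wa_dam_effect` pups (default 1.5, additive). No distribution or effect
size is reported for the real colony, so these are the package's own
realistic defaults; sire genotype never enters, by construction.

## Monitoring statistics

Founder frequencies condense 36-state unphased diplotype probabilities
(8 homozygous + 28 heterozygous states, (f,g) with f ≤ g) to dosages
dosage_f = 2P(f,f) + Σ_{g≠f} P(f,g); dosages sum to 2 per sample-marker
and cohort columns sum to 1. True mosaics can be counted directly and the
two paths agree exactly on indicator input. SNP information content is the
Shannon entropy H(q) = −q log₂ q − (1−q) log₂(1−q). The TRD test is a 1-df
chi-square against 1:1 without continuity correction — the default chosen
to match the printed p = 0.0018 at counts 159:108 (9.742 on 1 df); the
correction is exposed as an option. Litter-size ANOVA is scipy's one-way
F-test per litter and per parent sex, with group medians reported.

## Karyotype and haplogroup calling

Intensities are log-scale with copy-number-proportional means (two-copy 0,
one-copy −0.5, absent −2.0, Gaussian noise σ = 0.15 by default); decision
thresholds default to midpoints of those means and can instead be derived
from the cohort's nominal-sex reference distributions. XO requires: no Y
signal, mean X intensity (PAR excluded — the PAR is two-copy in every
karyotype but XO) below the one-copy midpoint, and X heterozygosity below
5%. Distal-X duplications are found by a run scan over robust X markers
proximal to the applicable pseudoautosomal boundary: a run of ≥5 markers
with two-copy-like intensity (single-marker gaps tolerated) containing ≥2
heterozygous calls. Breakpoints are reported at midpoints between the run
and its non-elevated neighbours, extending to the PAR boundary when the
run reaches the last scanned marker, so boundary accuracy is limited by
marker spacing (250 kb on the dense distal 10 Mb of the default panel's
X). For males carrying the CAST/EiJ Y, the boundary shifts 430 kb
proximal — heterozygosity confined to that extension reflects the
translocated X material on the CAST Y, not a duplication. X-to-Y
translocations are not distinguished from true X duplications; the call
means "distal-X gain".

Haplogroup assignment is linear discriminant analysis over small probe
panels (7 Y probes, 40 mitochondrial probes in the synthetic default;
6 Y classes, 5 mito classes). The pooled within-class covariance is shrunk
toward its diagonal with a variance floor, keeping the model well-posed
when training genotypes are perfectly concordant within class (the
empirical within-class variance is then exactly zero and standard
Ledoit–Wolf shrinkage degenerates). Missing probe calls are imputed with
training means; more than half missing is an error.

## The synthetic-data generator

The generator emulates MUGA-style array data: biallelic markers with
per-founder consensus alleles (a configurable fraction private to single
founders; default 0.3), genotyping error (default 0.5%), no-calls (0.2%),
and intensity noise as above. True diplotype probabilities are emitted as
indicators on the true unphased founder pair, with an optional uniform
admixture to exercise the probabilistic path. Injected XO samples get
one-copy X intensity, homozygized X calls, and silenced Y probes; injected
duplications get two-copy intensity plus heterozygous calls where a second
X haplotype — drawn to be distinguishable from the sample's own, since a
duplication of an identical haplotype is array-invisible — differs from it.
Class signatures for Y/mito probes are drawn with a minimum pairwise
Hamming distance (default 2) so classifier difficulty is tunable.

What the generator does not emulate: cluster-file artifacts, GC waves,
batch effects, platform differences between array generations, or real
linkage disequilibrium among founder haplotypes. Tests passing on this
generator show the algebra and detectors are correct under the stated
noise model, not that thresholds are tuned for real MUGA data.

## Problem sizes and numerical choices

Simulation-based checks run on a reduced map — the drive chromosome, one
further autosome, and X — because allele-frequency dynamics at a monitored
locus do not depend on how many unmonitored chromosomes are carried along;
the full 20-chromosome default map is used where genome-wide structure
matters. Stochastic checks use 20–50 replicates with fixed seeds and
3-standard-error bands. The purge-duration check uses 175 lineages and 20
replicates (median elimination generation 4–5 from p₀ = 0.62 at τ = 0.66);
the neutral martingale check uses 175 lineages × 10 generations × 20
replicates in the acceptance script. Coordinates are 0-based half-open
throughout; a segment owns its start, not its end. The drive locus is a
single point at chr2:85.65 Mb; the three flanking selection markers are
carried as metadata for genotyping emulation, with the locus genotype read
from the mosaic at the point itself (the markers are tightly linked
proxies).

## Known limitations

* The deterministic purge expectation reconstructs the published planning
  figure under stated assumptions (f = 0, infinite litters, proportional
  redistribution); the original computation's assumptions are not on
  record, so equivalence is not claimed.
* Genetic map lengths are fixture choices (~0.5 cM/Mb), not estimated DO
  map distances.
* The CC funnel structure of founding genomes, *R2d2* copy number, and
  modifier loci are out of scope; the rotational (HS-CC-style) breeding
  design is not implemented.
* Karyotype thresholds assume the synthetic intensity model's scale;
  applying the callers to real arrays requires re-deriving thresholds from
  the cohort (supported via `KaryotypeThresholds.from_cohort`).
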