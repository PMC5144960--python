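# dopop

Breeding simulation, marker-assisted selection, and colony monitoring for
Diversity Outbred (DO)-style multiparent mouse populations.

## The problem

The DO population is maintained as 175 matrilineal lineages bred by
randomized, sib-avoiding pairings so that each of its eight founder strains
(A/J, C57BL/6J, 129S1/SvImJ, NOD/ShiLtJ, NZO/HlLtJ, CAST/EiJ, PWK/PhJ,
WSB/EiJ — letters A–H) contributes ~1/8 of the genome everywhere. A meiotic
driver on chromosome 2 (*R2d2*) breaks this balance: heterozygous dams
transmit the WSB/EiJ ("W") allele with probability τ > 1/2, producing a
selfish sweep that threatens to fix one haplotype across a large region.
The remedy is marker-assisted selection: genotype every breeder pair at
markers flanking the locus, drop the worst mating types, and select the
progeny carrying the fewest W alleles.

`dopop` packages the quantitative machinery of this episode so the sweep,
the purge, and the colony-monitoring statistics can be simulated, predicted,
and tested end to end on synthetic data:

* **`dopop.genome`** — founder-mosaic chromosomes, genetic/physical maps,
  drive-locus genotype queries (aa / Wa / WW).
* **`dopop.breeding`** — forward simulation of the randomized breeding
  scheme: Poisson-crossover meiosis, maternal drive with hitchhiking of
  linked material, genotype-dependent litter sizes, A/B duplicate matings,
  mating failures with the replacement policy, matrilineal mitochondrial and
  patrilineal Y inheritance.
* **`dopop.purge`** — the mating-type algebra: 3×3 mating-type frequencies
  under Hardy–Weinberg, per-type progeny distributions under drive, the
  deterministic one-generation selection expectation, and the sweep
  recursion p′ = [p² + 2p(1−p)τ + p]/2.
* **`dopop.monitor`** — founder-frequency profiles from 36-state diplotype
  probabilities, SNP Shannon entropy, private-allele retention, the
  transmission-ratio-distortion (TRD) chi-square test, litter-size ANOVA.
* **`dopop.karyotype`** — XX/XY/XO calling and distal-X duplication
  detection from array intensities and heterozygosity; mito/Y haplogroup
  assignment by regularized linear discriminant analysis.
* **`dopop.synthetic`** — generators for every input the stack consumes:
  marker panels with per-founder consensus alleles, array calls and
  intensities with injectable anomalies, diplotype-probability arrays,
  breeding-record tables.

## Worked example

The planned intervention, starting from allele frequency p = 0.62 with
τ = 0.66:

```bash
$ dopop purge-plan --p 0.62 --tau 0.66
mating-type frequencies (dam rows x sire cols):
      WW     Wa     aa
WW 0.1477 0.1811 0.0555
Wa 0.1811 0.2220 0.0680
aa 0.0555 0.0680 0.0209
...
expected driven-allele frequency after one generation of selection: 0.1133 (11.33%)
```

Dropping WW×WW and WW×Wa/Wa×WW matings and selecting minimum-W progeny is
expected to bring the allele from 62% to ~11% among breeders in a single
generation. The TRD test on observed transmission counts:

```bash
$ dopop monitor trd --counts 159 108
{"chi2": 9.7416, "p_value": 0.001801, "ratio": 0.5955, "ci": [0.5366, 0.6544]}
```

i.e., 159:108 transmissions deviate from 1:1 at p ≈ 0.0018 with an
estimated transmission ratio of 0.60. A full stochastic colony run:

```python
from dopop import ColonyConfig, DriveParams, PurgePolicy, SchemeParams, simulate_colony
from dopop.genome import GenomeMap

cfg = ColonyConfig(scheme=SchemeParams(n_lineages=175),
                   drive=DriveParams(tau=0.66), generations=6,
                   seed=1, p_driven0=0.62,
                   purge_policy=PurgePolicy(), purge_start_generation=1)
res = simulate_colony(cfg, genome_map=GenomeMap.default(n_autosomes=2))
print(res.trajectory[["generation", "p_W"]])
```

which typically prints a breeder allele-frequency trajectory like
0.62 → 0.22 → 0.05 → 0.01 → 0.00: elimination of the driven allele in four
to five generations.

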