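"""Synthetic inputs for the full monitoring stack.

Generates every input the pipeline consumes with no external data:
marker panels with per-founder consensus alleles (a configurable
fraction private to single founders), array calls and log-scale
intensities for simulated individuals (with injectable XO and distal-X
duplication anomalies), true 36-state diplotype-probability arrays,
private-variant masks, and breeding-record tables from the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .breeding import Population
from .genome import FOUNDER_CODES, GenomeMap, Individual, MITO_CLASS, Y_CLASS, \
    MITO_CLASSES, Y_CLASSES
from .karyotype import NO_CALL, ArraySample, PARInfo
from .monitor import DIPLOTYPE_STATES, diplotype_state_index

PANEL_COLUMNS = ["marker", "chrom", "bp", "compartment", "robust", "private_founder"]


class SyntheticError(ValueError):
    pass


@dataclass
class NoiseModel:
    """Array noise: call errors, no-calls, and intensity dispersion.

    ``cn_means`` maps true copy number to the mean log-scale intensity
    (two-copy = 0 by convention; one-copy reduced; absent strongly
    negative; three-copy elevated).
    """

    error_rate: float = 0.005
    no_call_rate: float = 0.002
    sigma: float = 0.15
    cn_means: dict[int, float] = field(
        default_factory=lambda: {0: -2.0, 1: -0.5, 2: 0.0, 3: 0.4})

    def __post_init__(self) -> None:
        for r in (self.error_rate, self.no_call_rate):
            if not 0.0 <= r <= 1.0:
                raise SyntheticError("rates must be probabilities")
        if self.sigma <= 0:
            raise SyntheticError("sigma must be > 0")


@dataclass
class SyntheticPanel:
    """Marker annotation plus per-founder consensus alleles.

    ``markers`` has columns marker/chrom/bp/compartment/robust/
    private_founder (empty string = not private); ``consensus`` is
    (n_markers, 8) allele-B indicators per founder, with Y and
    mitochondrial probe rows holding the founder's haplogroup-class
    signature so all compartments share one lookup.
    """

    markers: pd.DataFrame
    consensus: np.ndarray

    def __post_init__(self) -> None:
        if len(self.markers) != self.consensus.shape[0] \
                or self.consensus.shape[1] != 8:
            raise SyntheticError("consensus must be (n_markers, 8)")
        for comp in ("Y", "mito"):
            if not (self.markers["compartment"] == comp).any():
                raise SyntheticError(f"panel needs {comp} probes")

    def probe_names(self, compartment: str) -> list[str]:
        return self.markers.loc[self.markers["compartment"] == compartment,
                                "marker"].tolist()

    def private_mask(self) -> pd.DataFrame:
        """Private-variant mask TSV layout: variant, chrom, bp, founder."""
        m = self.markers[self.markers["private_founder"] != ""]
        return pd.DataFrame({"variant": m["marker"], "chrom": m["chrom"],
                             "bp": m["bp"], "founder": m["private_founder"]
                             }).reset_index(drop=True)


def _class_signatures(classes: tuple[str, ...], n_probes: int,
                      rng: np.random.Generator, margin: int = 2) -> dict[str, np.ndarray]:
    """Binary probe signatures with pairwise Hamming distance >= margin."""
    if n_probes < len(classes):
        raise SyntheticError("need at least one probe per class")
    for _ in range(1000):
        sigs = {c: rng.integers(0, 2, size=n_probes) for c in classes}
        names = list(classes)
        ok = all(np.sum(sigs[a] != sigs[b]) >= margin
                 for i, a in enumerate(names) for b in names[i + 1:])
        if ok:
            return sigs
    # deterministic fallback: one-hot plus complement padding
    sigs = {}
    for k, c in enumerate(classes):
        v = np.zeros(n_probes, dtype=int)
        v[k % n_probes] = 1
        v[(k + 1) % n_probes] = 1 if k % 2 else 0
        sigs[c] = v
    return sigs


def generate_panel(genome_map: GenomeMap, private_fraction: float = 0.3,
                   n_y_probes: int = 7, n_mito_probes: int = 40,
                   robust_fraction: float = 0.95, seed: int = 0,
                   par: PARInfo | None = None,
                   signature_margin: int = 2) -> SyntheticPanel:
    """Biallelic consensus panel over the map's markers plus Y/mito probes.

    Each nuclear marker is private to a single founder with probability
    ``private_fraction`` (its minor allele carried by that founder
    only); other markers get a random non-monomorphic, non-private
    allele split. X markers distal to the standard PAR boundary are
    annotated compartment "PAR". Deterministic under ``seed``.
    """
    if par is None:
        par = PARInfo()
    rng = np.random.default_rng(seed)
    rows = []
    consensus = []
    for _, mk in genome_map.markers.iterrows():
        if mk["chrom"] == "X":
            comp = "PAR" if mk["bp"] >= par.standard_boundary_bp else "X"
        else:
            comp = "auto"
        private = ""
        if rng.random() < private_fraction:
            owner = FOUNDER_CODES[rng.integers(8)]
            alleles = np.zeros(8, dtype=int)
            alleles[FOUNDER_CODES.index(owner)] = 1
            private = owner
        else:
            while True:
                alleles = rng.integers(0, 2, size=8)
                s = alleles.sum()
                if s in (0, 8) or s == 1 or s == 7:
                    continue  # monomorphic or accidentally private
                break
        robust = rng.random() < robust_fraction
        rows.append((mk["marker"], mk["chrom"], int(mk["bp"]), comp,
                     robust, private))
        consensus.append(alleles)
    y_sigs = _class_signatures(Y_CLASSES, n_y_probes, rng, signature_margin)
    for j in range(n_y_probes):
        rows.append((f"Yp{j:02d}", "Y", 1_000_000 * (j + 1), "Y", True, ""))
        consensus.append(np.array([y_sigs[Y_CLASS[f]][j] for f in FOUNDER_CODES]))
    m_sigs = _class_signatures(MITO_CLASSES, n_mito_probes, rng, signature_margin)
    for j in range(n_mito_probes):
        rows.append((f"Mp{j:02d}", "MT", 100 * (j + 1), "mito", True, ""))
        consensus.append(np.array([m_sigs[MITO_CLASS[f]][j] for f in FOUNDER_CODES]))
    markers = pd.DataFrame(rows, columns=PANEL_COLUMNS)
    return SyntheticPanel(markers, np.asarray(consensus))


def _founder_indices(ind: Individual, panel: SyntheticPanel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker founder index of each homologue (and a haploid flag)."""
    n = len(panel.markers)
    f1 = np.zeros(n, dtype=int)
    f2 = np.zeros(n, dtype=int)
    haploid = np.zeros(n, dtype=bool)
    fidx = {f: i for i, f in enumerate(FOUNDER_CODES)}
    for chrom, grp in panel.markers.groupby("chrom"):
        rows = grp.index.to_numpy()
        if chrom == "Y":
            code = ind.y if ind.y is not None else "A"
            f1[rows] = f2[rows] = fidx[code]
            haploid[rows] = True
            continue
        if chrom == "MT":
            f1[rows] = f2[rows] = fidx[ind.mito]
            haploid[rows] = True
            continue
        homologues = ind.genome[chrom]
        pos = grp["bp"].to_numpy()
        a = [fidx[f] for f in homologues[0].founders_at(pos)]
        f1[rows] = a
        if len(homologues) == 2:
            f2[rows] = [fidx[f] for f in homologues[1].founders_at(pos)]
        else:
            f2[rows] = a
            haploid[rows] = True
    return f1, f2, haploid


def _copy_numbers(ind: Individual, panel: SyntheticPanel) -> np.ndarray:
    comp = panel.markers["compartment"].to_numpy()
    cn = np.full(len(comp), 2, dtype=int)
    if ind.sex == "M":
        cn[comp == "X"] = 1  # PAR stays two-copy (X + Y)
    if ind.karyotype == "XO":
        cn[(comp == "X") | (comp == "PAR")] = 1
        cn[comp == "Y"] = 0
    elif ind.sex == "F":
        cn[comp == "Y"] = 0
    return cn


def genotype_cohort(individuals, panel: SyntheticPanel, noise: NoiseModel,
                    seed: int = 0, return_diplotypes: bool = False):
    """Emulate array genotyping of simulated individuals.

    Returns a list of ArraySample (calls + intensities per marker, with
    error/no-call noise and copy-number-dependent intensity) and, when
    ``return_diplotypes`` is set, the true 36-state diplotype
    probabilities (indicator vectors) for every diploid autosomal/X
    marker as an (n_samples, n_markers, 36) array plus the marker
    subindex.
    """
    if isinstance(individuals, Population):
        individuals = individuals.all_individuals
    individuals = list(individuals)
    rng = np.random.default_rng(seed)
    comp = panel.markers["compartment"].to_numpy()
    n_mark = len(panel.markers)
    dip_rows = np.flatnonzero((comp == "auto") | (comp == "X") | (comp == "PAR"))
    samples = []
    dip_probs = (np.zeros((len(individuals), len(dip_rows), 36))
                 if return_diplotypes else None)
    for si, ind in enumerate(individuals):
        f1, f2, haploid = _founder_indices(ind, panel)
        a1 = panel.consensus[np.arange(n_mark), f1]
        a2 = panel.consensus[np.arange(n_mark), f2]
        calls = np.where(haploid, 2 * a1, a1 + a2).astype(np.int8)
        cn = _copy_numbers(ind, panel)
        absent = cn == 0
        calls[absent] = NO_CALL
        # genotyping error: flip to a random different genotype
        err = (rng.random(n_mark) < noise.error_rate) & ~absent
        if err.any():
            cur = calls[err]
            shift = rng.integers(1, 3, size=err.sum())
            calls[err] = ((cur + shift) % 3).astype(np.int8)
        nc = rng.random(n_mark) < noise.no_call_rate
        calls[nc] = NO_CALL
        means = np.vectorize(noise.cn_means.get)(cn)
        intensity = means + rng.normal(0.0, noise.sigma, size=n_mark)
        samples.append(ArraySample(ind.id, calls, intensity,
                                   nominal_sex=ind.sex,
                                   truth_karyotype=ind.karyotype))
        if return_diplotypes:
            for mj, row in enumerate(dip_rows):
                k = diplotype_state_index(FOUNDER_CODES[f1[row]],
                                          FOUNDER_CODES[f2[row]])
                dip_probs[si, mj, k] = 1.0
    if return_diplotypes:
        return samples, dip_probs, dip_rows
    return samples


def smooth_diplotypes(dip_probs: np.ndarray, weight: float,
                      ) -> np.ndarray:
    """Mix indicator diplotype probabilities with the uniform distribution."""
    if not 0.0 <= weight <= 1.0:
        raise SyntheticError("weight must be in [0, 1]")
    return (1 - weight) * dip_probs + weight / 36.0


def inject_anomaly(sample: ArraySample, kind: str, panel: SyntheticPanel,
                   noise: NoiseModel, rng: np.random.Generator,
                   par: PARInfo | None = None,
                   dup_length: int = 10_000_000) -> ArraySample:
    """Inject a sex-chromosome anomaly into an array sample (in place).

    ``XO`` (female samples): X intensities shift to the one-copy mean,
    X heterozygous calls are homozygized, Y probes are silenced.
    ``distal_dup`` (male samples): markers within ``dup_length`` of the
    standard PAR boundary get two-copy intensity, and heterozygous
    calls wherever a randomly drawn second X haplotype differs from the
    sample's own. A zero-length duplication leaves the sample unchanged.
    """
    if par is None:
        par = PARInfo()
    comp = panel.markers["compartment"].to_numpy()
    bp = panel.markers["bp"].to_numpy()
    one_step = noise.cn_means[1] - noise.cn_means[2]
    if kind == "XO":
        if sample.nominal_sex != "F":
            raise SyntheticError("XO is injected into female samples")
        x_all = (comp == "X") | (comp == "PAR")
        sample.intensity[x_all] += one_step
        het = x_all & (sample.calls == 1)
        sample.calls[het] = rng.choice([0, 2], size=int(het.sum())).astype(np.int8)
        y = comp == "Y"
        sample.intensity[y] = noise.cn_means[0] + rng.normal(
            0.0, noise.sigma, size=int(y.sum()))
        sample.calls[y] = NO_CALL
        sample.truth_karyotype = "XO"
    elif kind == "distal_dup":
        if sample.nominal_sex != "M":
            raise SyntheticError("distal_dup is injected into male samples")
        if dup_length <= 0:
            return sample
        lo = par.standard_boundary_bp - dup_length
        region = (comp == "X") & (bp >= lo) & (bp < par.standard_boundary_bp)
        if not region.any():
            return sample
        sample.intensity[region] -= one_step  # one-copy -> two-copy mean
        # second haplotype: a random founder distinguishable from the
        # sample's own X in the region (an identical haplotype would be
        # array-invisible, so the generator emulates the detectable case)
        own = sample.calls[region] // 2  # haploid allele (ignoring errors)
        diffs = (panel.consensus[np.flatnonzero(region), :] != own[:, None]).sum(0)
        need = max(2, int(0.2 * region.sum()))
        candidates = np.flatnonzero(diffs >= need)
        if candidates.size == 0:
            candidates = np.array([int(np.argmax(diffs))])
        f = int(rng.choice(candidates))
        other = panel.consensus[np.flatnonzero(region), f]
        het = np.flatnonzero(region)[other != own]
        sample.calls[het] = 1
        sample.truth_karyotype = "XY+dupX"
    else:
        raise SyntheticError(f"unknown anomaly kind {kind!r}")
    return sample


def anomaly_cohort(n_females: int, n_males: int, n_xo: int, n_dup: int,
                   seed: int = 0, genome_map: GenomeMap | None = None,
                   panel: SyntheticPanel | None = None,
                   noise: NoiseModel | None = None,
                   dup_length_range: tuple[int, int] = (5_000_000, 30_000_000),
                   par: PARInfo | None = None):
    """A genotyped cohort with injected sex-chromosome anomalies.

    Builds ``n_females + n_males`` individuals with random founder-mosaic
    genomes (Y haplogroups uniform over the six classes), genotypes them
    on a synthetic panel, injects ``n_xo`` XO females and ``n_dup``
    distal-X duplications in males (duplication lengths uniform in
    ``dup_length_range`` beyond the standard PAR boundary), and returns
    (female samples, male samples, panel, sample_id -> Y class).
    """
    from .breeding import random_mosaic

    if genome_map is None:
        genome_map = GenomeMap.default(n_autosomes=2, markers_per_chrom=60)
    if par is None:
        par = PARInfo()
    if panel is None:
        panel = generate_panel(genome_map, seed=seed, par=par)
    if noise is None:
        noise = NoiseModel()
    rng = np.random.default_rng(seed)
    y_codes = list(FOUNDER_CODES)

    def make(sex: str, i: int) -> Individual:
        genome = {}
        for chrom, c in genome_map.chromosomes.items():
            n = 1 if (chrom == "X" and sex == "M") else 2
            genome[chrom] = tuple(random_mosaic(chrom, c.length_bp, rng)
                                  for _ in range(n))
        return Individual(id=f"{sex}{i:04d}", sex=sex, generation=0, lineage=0,
                          genome=genome, mito=y_codes[rng.integers(8)],
                          y=y_codes[rng.integers(8)] if sex == "M" else None)

    inds = ([make("F", i) for i in range(n_females)]
            + [make("M", i) for i in range(n_males)])
    samples = genotype_cohort(inds, panel, noise, seed=seed + 1)
    females, males = samples[:n_females], samples[n_females:]
    y_class = {ind.id: ind.y_class for ind in inds[n_females:]}
    xo_idx = rng.choice(n_females, size=n_xo, replace=False)
    for i in xo_idx:
        inject_anomaly(females[i], "XO", panel, noise, rng, par=par)
    dup_idx = rng.choice(n_males, size=n_dup, replace=False)
    for i in dup_idx:
        length = int(rng.integers(*dup_length_range))
        inject_anomaly(males[i], "distal_dup", panel, noise, rng, par=par,
                       dup_length=length)
    return females, males, panel, y_class


def emit_breeding_records(result) -> pd.DataFrame:
    """File S1-style record table from a simulation result."""
    rec = result.records if hasattr(result, "records") else result
    return rec[["generation", "lineage", "group", "dam_id", "sire_id",
                "dam_geno", "sire_geno", "litter_index",
                "n_female", "n_male", "failed"]].copy()
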