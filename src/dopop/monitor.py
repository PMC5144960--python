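"""Colony-monitoring statistics.

Founder-frequency profiles from 36-state diplotype probabilities (or
from true simulated mosaics), per-SNP Shannon information content,
private-allele retention, the transmission-ratio-distortion chi-square
test, and the litter-size ANOVA by parental genotype at the drive
locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import FOUNDER_CODES, Individual

#: the 36 unphased diplotype states: 8 homozygous then 28 heterozygous,
#: ordered (f, g) with f <= g in founder-letter order.
DIPLOTYPE_STATES: tuple[tuple[str, str], ...] = tuple(
    (FOUNDER_CODES[i], FOUNDER_CODES[j])
    for i in range(8) for j in range(i, 8))

_STATE_INDEX = {s: k for k, s in enumerate(DIPLOTYPE_STATES)}

# dosage matrix D[36, 8]: dosage = probs @ D
_DOSAGE = np.zeros((36, 8))
for _k, (_f, _g) in enumerate(DIPLOTYPE_STATES):
    _DOSAGE[_k, FOUNDER_CODES.index(_f)] += 1.0
    _DOSAGE[_k, FOUNDER_CODES.index(_g)] += 1.0


class MonitorError(ValueError):
    pass


def diplotype_state_index(f: str, g: str) -> int:
    """Index of the unphased state {f, g} in the 36-vector."""
    return _STATE_INDEX[(f, g) if f <= g else (g, f)]


def condense_diplotypes(probs36: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Condense 36 diplotype probabilities to 8 founder dosages.

    dosage_f = 2 P(f,f) + sum_{g != f} P(f,g); dosages sum to 2 and
    dosage/2 is the founder-frequency contribution of the sample.
    Accepts any array whose last axis has length 36.
    """
    p = np.asarray(probs36, dtype=float)
    if p.shape[-1] != 36:
        raise MonitorError("last axis must hold the 36 diplotype states")
    if np.any(p < -tol):
        raise MonitorError("negative diplotype probability")
    sums = p.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > tol):
        raise MonitorError("diplotype probabilities must sum to 1")
    return p @ _DOSAGE


def founder_frequency_profile(
        samples: "Sequence[Individual] | np.ndarray",
        positions: np.ndarray | Sequence[int] | None = None,
        chrom: str | None = None) -> pd.DataFrame:
    """Founder-frequency matrix (8 founders x positions) over a cohort.

    Two input modes:

    * an array of diplotype probabilities shaped (samples, markers, 36):
      condensed to dosages and averaged (``positions`` labels columns);
    * a sequence of Individuals with mosaic genomes plus ``chrom`` and
      bp ``positions``: founder alleles are counted directly.

    Columns sum to 1 at every position.
    """
    if isinstance(samples, np.ndarray):
        if samples.ndim != 3 or samples.shape[-1] != 36:
            raise MonitorError("expected (samples, markers, 36) probabilities")
        if samples.shape[0] == 0:
            raise MonitorError("empty cohort")
        dos = condense_diplotypes(samples)  # (samples, markers, 8)
        freq = dos.mean(axis=0).T / 2.0  # (8, markers)
        cols = (list(positions) if positions is not None
                else list(range(samples.shape[1])))
    else:
        samples = list(samples)
        if not samples:
            raise MonitorError("empty cohort")
        if chrom is None or positions is None:
            raise MonitorError("mosaic input needs chrom and positions")
        pos = np.asarray(positions)
        counts = np.zeros((8, len(pos)))
        n_hap = 0
        for ind in samples:
            for mosaic in ind.genome[chrom]:
                fs = mosaic.founders_at(pos)
                for j, f in enumerate(fs):
                    counts[FOUNDER_CODES.index(f), j] += 1
            n_hap += len(ind.genome[chrom])
        freq = counts / n_hap
        cols = list(pos)
    return pd.DataFrame(freq, index=list(FOUNDER_CODES), columns=cols)


def snp_entropy(q: np.ndarray | float) -> np.ndarray | float:
    """Shannon entropy (bits) of a biallelic SNP at allele frequency q.

    H = -q log2 q - (1-q) log2(1-q), with 0 log 0 = 0; maximal (1.0)
    at q = 1/2, zero for monomorphic SNPs.
    """
    qa = np.asarray(q, dtype=float)
    if np.any((qa < 0) | (qa > 1)):
        raise MonitorError("allele frequency must be in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(np.where(qa > 0, qa * np.log2(qa), 0.0)
              + np.where(qa < 1, (1 - qa) * np.log2(1 - qa), 0.0))
    h = np.where((qa == 0) | (qa == 1), 0.0, h)
    return float(h) if np.isscalar(q) else h


def private_allele_retention(founder_freqs: pd.DataFrame, mask: pd.DataFrame,
                             region: tuple[int, int] | None = None,
                             chrom: str | None = None) -> float:
    """Fraction of private variants whose owning founder still segregates.

    ``founder_freqs`` is a profile as returned by
    founder_frequency_profile (8 founders x bp positions);
    ``mask`` has columns (variant, chrom, bp, founder). A private
    variant is retained iff its owning founder's frequency at the
    nearest profiled position is > 0.
    """
    if mask.empty:
        raise MonitorError("empty private-variant mask")
    m = mask
    if chrom is not None:
        m = m[m["chrom"] == chrom]
    if region is not None:
        m = m[(m["bp"] >= region[0]) & (m["bp"] < region[1])]
    if m.empty:
        raise MonitorError("no private variants in region")
    pos = np.asarray(founder_freqs.columns, dtype=float)
    idx = np.clip(np.searchsorted(pos, m["bp"].to_numpy(float)), 0, len(pos) - 1)
    # snap to nearest profiled position
    left = np.clip(idx - 1, 0, len(pos) - 1)
    idx = np.where(np.abs(pos[left] - m["bp"].to_numpy(float))
                   < np.abs(pos[idx] - m["bp"].to_numpy(float)), left, idx)
    freqs = founder_freqs.to_numpy()
    rows = [FOUNDER_CODES.index(f) for f in m["founder"]]
    retained = freqs[rows, idx] > 0.0
    return float(np.mean(retained))


@dataclass(frozen=True)
class TRDCounts:
    """Progeny counts by inherited allele at the drive locus."""

    n_driven: int
    n_other: int

    def __post_init__(self) -> None:
        if self.n_driven < 0 or self.n_other < 0:
            raise MonitorError("counts must be non-negative")
        if self.n_driven + self.n_other == 0:
            raise MonitorError("total count must be positive")


@dataclass(frozen=True)
class TRDResult:
    statistic: float
    p_value: float
    ratio: float
    ci_low: float
    ci_high: float


def trd_test(counts: TRDCounts, continuity_correction: bool = False,
             ci: str = "wald", alpha: float = 0.05) -> TRDResult:
    """Chi-square goodness-of-fit of transmission counts against 1:1.

    One degree of freedom, no continuity correction by default. The
    transmission-ratio estimate n_driven / n comes with a Wald or exact
    (Clopper-Pearson) confidence interval.
    """
    n = counts.n_driven + counts.n_other
    expected = n / 2.0
    if continuity_correction:
        dev = max(abs(counts.n_driven - expected) - 0.5, 0.0)
    else:
        dev = abs(counts.n_driven - expected)
    chi2 = 2.0 * dev * dev / expected
    p = float(stats.chi2.sf(chi2, df=1))
    ratio = counts.n_driven / n
    if ci == "wald":
        z = stats.norm.ppf(1 - alpha / 2)
        se = np.sqrt(ratio * (1 - ratio) / n)
        lo, hi = max(ratio - z * se, 0.0), min(ratio + z * se, 1.0)
    elif ci == "exact":
        res = stats.binomtest(counts.n_driven, n)
        interval = res.proportion_ci(confidence_level=1 - alpha)
        lo, hi = interval.low, interval.high
    else:
        raise MonitorError("ci must be 'wald' or 'exact'")
    return TRDResult(float(chi2), p, float(ratio), float(lo), float(hi))


def trd_counts_from_populations(populations, locus) -> TRDCounts:
    """Maternal transmission counts at the locus from simulated pedigrees.

    Scans consecutive populations for offspring of Wa dams mated to aa
    sires: such offspring carry a driven allele iff the maternal gamete
    did, so their genotypes are direct (unbiased, under random breeder
    selection) observations of the maternal transmission ratio.
    """
    from .genome import w_count as _w_count
    n_driven = n_other = 0
    for prev, cur in zip(populations[:-1], populations[1:]):
        parents = {ind.id: ind for ind in prev.all_individuals}
        for ind in cur.all_individuals:
            dam = parents.get(ind.dam_id)
            sire = parents.get(ind.sire_id)
            if dam is None or sire is None:
                continue
            if _w_count(dam, locus) == 1 and _w_count(sire, locus) == 0:
                if _w_count(ind, locus) >= 1:
                    n_driven += 1
                else:
                    n_other += 1
    return TRDCounts(n_driven, n_other)


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    group_medians: dict[str, float]
    group_sizes: dict[str, int]


def litter_anova(records: pd.DataFrame, by: str = "dam_geno",
                 litter_index: int | None = None) -> AnovaResult:
    """One-way ANOVA of litter size against parental genotype.

    ``by`` is "dam_geno" or "sire_geno"; ``litter_index`` restricts to
    one litter (the analyses are run separately per litter). Failed
    matings are excluded.
    """
    if by not in ("dam_geno", "sire_geno"):
        raise MonitorError("by must be dam_geno or sire_geno")
    tab = records[records["failed"] == 0].copy()
    if litter_index is not None:
        tab = tab[tab["litter_index"] == litter_index]
    tab["litter_size"] = tab["n_female"] + tab["n_male"]
    groups = {str(k): g["litter_size"].to_numpy(float)
              for k, g in tab.groupby(by) if len(g) >= 2}
    if len(groups) < 2:
        raise MonitorError("need at least two genotype groups with >= 2 litters")
    values = list(groups.values())
    if all(np.ptp(v) == 0 for v in values) and len({v[0] for v in values}) == 1:
        f, p = 0.0, 1.0  # identical constants: no variance anywhere
    else:
        f, p = stats.f_oneway(*values)
    return AnovaResult(float(f), float(p),
                       {k: float(np.median(v)) for k, v in groups.items()},
                       {k: int(len(v)) for k, v in groups.items()})
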