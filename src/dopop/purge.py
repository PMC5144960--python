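"""Marker-assisted purge algebra for a maternally driven allele.

Breeders are classified by carrier status at the drive locus: W = the
driven (WSB/EiJ) allele, a = any other founder allele; genotypes aa, Wa,
WW. A mating type is the ordered (dam, sire) genotype pair, nine types
in all. Under maternal meiotic drive a heterozygous dam transmits W with
probability tau (tau = 1/2 is Mendelian); sires and homozygotes are
unbiased.

The purge policy discards WW x WW matings outright, retains only a
fraction ``f`` of WW x Wa / Wa x WW matings (default 0), and within each
retained mating selects the progeny carrying the fewest W alleles.
This module gives the exact deterministic consequences of that policy:
mating-type frequencies at Hardy-Weinberg proportions, per-type progeny
genotype distributions under drive, the expected post-selection allele
frequency after one generation, and the generation-by-generation sweep
recursion with no selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GENOTYPES = ("aa", "Wa", "WW")  # index = W-allele count


class PurgeError(ValueError):
    pass


class DivergenceError(PurgeError):
    """A threshold cannot be reached under the given dynamics."""


@dataclass(frozen=True)
class MatingType:
    """Ordered (dam, sire) W-genotype pair; one of the nine types."""

    dam_w: int
    sire_w: int

    def __post_init__(self) -> None:
        if self.dam_w not in (0, 1, 2) or self.sire_w not in (0, 1, 2):
            raise PurgeError("genotypes must be in {0, 1, 2}")

    @property
    def label(self) -> str:
        return f"{GENOTYPES[self.dam_w]}x{GENOTYPES[self.sire_w]}"

    @property
    def produces_aa_possible(self) -> bool:
        """Can this mating produce progeny with no W allele?"""
        return self.dam_w <= 1 and self.sire_w <= 1

    @property
    def forced_wa(self) -> bool:
        """All progeny are obligate Wa (aa x WW or WW x aa)."""
        return {self.dam_w, self.sire_w} == {0, 2}

    @property
    def has_wa_parent(self) -> bool:
        """Progeny genotyping is required only when a parent is Wa."""
        return 1 in (self.dam_w, self.sire_w)


ALL_MATING_TYPES = tuple(MatingType(d, s) for d in (0, 1, 2) for s in (0, 1, 2))


def classify_mating(dam_w: int, sire_w: int,
                    policy: "PurgePolicy | None" = None) -> MatingType:
    mt = MatingType(dam_w, sire_w)
    return mt


@dataclass
class PurgePolicy:
    """Which matings are kept and how breeders are chosen from them.

    discard: mating types removed outright (default WW x WW).
    retained_fraction_ww_wa: fraction f of WW x Wa / Wa x WW matings kept.
    min_w_selection: choose the progeny with the fewest W alleles.
    litters_genotyped: how many litters feed the genotyped selection pool.
    """

    discard: frozenset[MatingType] = frozenset({MatingType(2, 2)})
    retained_fraction_ww_wa: float = 0.0
    min_w_selection: bool = True
    litters_genotyped: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.retained_fraction_ww_wa <= 1.0:
            raise PurgeError("retained fraction must be in [0, 1]")
        if not self.discard:
            raise PurgeError("an active purge needs a non-empty discard set")

    def retention(self, mt: MatingType) -> float:
        """Probability mass retained for a mating of this type."""
        if mt in self.discard:
            return 0.0
        if {mt.dam_w, mt.sire_w} == {1, 2}:
            return self.retained_fraction_ww_wa
        return 1.0

    def needs_genotyping(self, mt: MatingType) -> bool:
        return mt.has_wa_parent


@dataclass
class AlleleFrequencyState:
    """Genotype frequencies at the drive locus; defaults to HWE at p."""

    p: float
    genotype_freqs: tuple[float, float, float] | None = None  # (aa, Wa, WW)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise PurgeError("p must be in [0, 1]")
        if self.genotype_freqs is None:
            q = 1.0 - self.p
            self.genotype_freqs = (q * q, 2 * self.p * q, self.p * self.p)
        g = self.genotype_freqs
        if abs(sum(g) - 1.0) > 1e-9:
            raise PurgeError("genotype frequencies must sum to 1")
        if abs((g[2] + g[1] / 2) - self.p) > 1e-9:
            raise PurgeError("p inconsistent with genotype frequencies")


def mating_type_frequencies(state: AlleleFrequencyState) -> np.ndarray:
    """3x3 mating-type frequency table, dams in rows, sires in columns.

    Rows/columns are ordered (WW, Wa, aa) to match the conventional
    presentation; entries are the outer product of the dam and sire
    genotype frequencies and sum to 1.
    """
    aa, wa, ww = state.genotype_freqs
    g = np.array([ww, wa, aa])
    return np.outer(g, g)


def progeny_distribution(mtype: MatingType, tau: float) -> np.ndarray:
    """P(progeny genotype) as (aa, Wa, WW) under maternal drive.

    The maternal gamete carries W with probability tau iff the dam is
    heterozygous (0 or 1 deterministically otherwise); the paternal
    gamete is always Mendelian.
    """
    if not 0.0 <= tau <= 1.0:
        raise PurgeError("tau must be in [0, 1]")
    p_mat = {0: 0.0, 1: tau, 2: 1.0}[mtype.dam_w]
    p_pat = {0: 0.0, 1: 0.5, 2: 1.0}[mtype.sire_w]
    dist = np.array([
        (1 - p_mat) * (1 - p_pat),
        p_mat * (1 - p_pat) + (1 - p_mat) * p_pat,
        p_mat * p_pat,
    ])
    return dist


def min_w_genotype_distribution(mtype: MatingType, tau: float,
                                n_progeny: int) -> np.ndarray:
    """Distribution of the minimum W count among n iid progeny."""
    if n_progeny < 1:
        raise PurgeError("need at least one progeny")
    dist = progeny_distribution(mtype, tau)
    cdf = np.cumsum(dist)
    # P(min >= k) = P(no progeny below k)^n
    p_ge = np.array([1.0, (1 - cdf[0]) ** n_progeny, (1 - cdf[1]) ** n_progeny])
    return np.array([p_ge[0] - p_ge[1], p_ge[1] - p_ge[2], p_ge[2]])


def select_breeders(progeny: dict[str, list[int]], mtype: MatingType,
                    policy: PurgePolicy, rng: np.random.Generator):
    """Choose one female and one male breeder from a litter's genotypes.

    ``progeny`` maps sex ("F"/"M") to lists of W counts. Discarded
    mating types, non-retained WW x Wa matings, and litters missing a
    sex return ``None`` (a replacement request). Under the min-W policy
    the lowest-W individual of each sex is chosen, ties broken at
    random; matings with no Wa parent need no genotyping and the choice
    is uniform.
    """
    if policy.retention(mtype) == 0.0:
        return None
    if policy.retention(mtype) < 1.0 and rng.random() >= policy.retention(mtype):
        return None
    females = progeny.get("F", [])
    males = progeny.get("M", [])
    if not females or not males:
        return None

    def pick(pool: list[int]) -> int:
        if policy.min_w_selection and policy.needs_genotyping(mtype):
            lo = min(pool)
            idx = [i for i, g in enumerate(pool) if g == lo]
        else:
            idx = list(range(len(pool)))
        return pool[idx[rng.integers(len(idx))]]

    return pick(females), pick(males)


def expected_post_selection_frequency(
        state: AlleleFrequencyState, tau: float, policy: PurgePolicy | None = None,
        infinite_litter: bool = True, n_genotyped_per_sex: int = 8) -> float:
    """Expected driven-allele frequency among next-generation breeders.

    Exact enumeration over the nine mating types: discarded and
    non-retained mass is redistributed proportionally over retained
    matings. In the infinite-litter idealization every aa-capable mating
    contributes aa breeders (the minimum-W genotype is always
    obtainable) and forced-Wa matings contribute Wa; with
    ``infinite_litter=False`` the finite-litter expectation of the
    minimum-W genotype over ``n_genotyped_per_sex`` progeny per sex is
    used instead.
    """
    if policy is None:
        policy = PurgePolicy()
    aa, wa, ww = state.genotype_freqs
    gfreq = {0: aa, 1: wa, 2: ww}
    total_mass = 0.0
    w_alleles = 0.0
    for mt in ALL_MATING_TYPES:
        mass = gfreq[mt.dam_w] * gfreq[mt.sire_w] * policy.retention(mt)
        if mass == 0.0:
            continue
        total_mass += mass
        if infinite_litter:
            if mt.produces_aa_possible and policy.min_w_selection:
                exp_w = 0.0
            elif policy.min_w_selection:
                # minimum obtainable genotype: Wa for any type with a W
                # homozygote parent (forced Wa, or WW x Wa retained mass)
                exp_w = 1.0
            else:
                exp_w = float(progeny_distribution(mt, tau) @ np.arange(3))
        else:
            if policy.min_w_selection:
                dist = min_w_genotype_distribution(mt, tau, n_genotyped_per_sex)
            else:
                dist = progeny_distribution(mt, tau)
            exp_w = float(dist @ np.arange(3))
        w_alleles += mass * 2 * exp_w  # one female + one male breeder
    if total_mass == 0.0:
        raise PurgeError("all mating mass discarded; frequency undefined")
    return w_alleles / (4 * total_mass)  # 2 breeders x 2 alleles each


def drive_recursion(p: float, tau: float) -> float:
    """One generation of the deterministic maternal-drive recursion.

    p' = [p^2 + 2 p (1-p) tau + p] / 2: the maternal gamete frequency
    under drive at HWE, averaged with the Mendelian paternal frequency.
    """
    if not 0.0 <= p <= 1.0 or not 0.0 <= tau <= 1.0:
        raise PurgeError("p and tau must be in [0, 1]")
    return (p * p + 2 * p * (1 - p) * tau + p) / 2


def sweep_trajectory(p0: float, tau: float, generations: int) -> np.ndarray:
    """p across ``generations`` iterations of drive_recursion (incl. p0)."""
    traj = np.empty(generations + 1)
    traj[0] = p0
    for i in range(generations):
        traj[i + 1] = drive_recursion(traj[i], tau)
    return traj


def generations_to_threshold(p0: float, tau: float, threshold: float,
                             direction: str = "up",
                             policy: PurgePolicy | None = None,
                             max_iter: int = 1000) -> int:
    """Smallest generation count at which p passes the threshold.

    ``direction="up"`` iterates the no-selection drive recursion until
    p > threshold; ``direction="down"`` iterates the one-generation
    purge expectation (re-imposing HWE each generation) until
    p < threshold.
    """
    if not 0.0 < threshold < 1.0:
        raise PurgeError("threshold must be in (0, 1)")
    p = p0
    for n in range(1, max_iter + 1):
        if direction == "up":
            p = drive_recursion(p, tau)
            if p > threshold:
                return n
        elif direction == "down":
            p = expected_post_selection_frequency(AlleleFrequencyState(p), tau, policy)
            if p < threshold:
                return n
        else:
            raise PurgeError("direction must be 'up' or 'down'")
    raise DivergenceError(
        f"threshold {threshold} not reached in {max_iter} generations "
        f"(p0={p0}, tau={tau}, direction={direction})")
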