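"""Forward-in-time simulation of the DO randomized breeding scheme.

The colony is maintained as ``n_lineages`` matrilineal lineages. Each
generation one female and one male are selected from every lineage and
assigned to mating pairs at random with avoidance of sib mating; the
offspring lineage follows the dam. From G8 onward matings are made in
duplicate ("A" and "B" pairs, the B dam/sire being full siblings of the
A dam/sire), with B progeny used for distribution and as a backup when
the A mating fails.

Meiosis is modelled with Poisson crossover counts (no interference) and
uniform placement on the genetic map. Meiotic drive acts only in dams
heterozygous at the drive locus: the meiotic product that carries the
driven allele at the locus point is transmitted with probability tau,
so linked flanking material hitchhikes with it. Mitochondria follow the
matriline and the Y chromosome the patriline, so with no failed matings
their haplogroup counts are exactly conserved; failed matings trigger
the replacement policy (another lineage provides the parents) and are
the only route by which those frequencies can change.

For efficiency, litter-mates that are never selected as breeders exist
only as counts and drawn locus genotypes in the mating records; full
mosaic genomes are constructed for selected breeders only, with each
gamete conditioned on the pup's drawn allele at the drive locus. The
conditioning is exact because crossover placement is independent of
which meiotic product is transmitted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .genome import (
    FOUNDER_CODES,
    DriveLocus,
    FounderMosaic,
    GenomeMap,
    GENOTYPE_LABELS,
    Individual,
    w_count,
)
from .purge import PurgePolicy

RECORD_COLUMNS = [
    "generation", "lineage", "group", "dam_id", "sire_id",
    "dam_geno", "sire_geno", "litter_index", "n_female", "n_male", "failed",
]

PEDIGREE_COLUMNS = ["id", "dam", "sire", "sex", "generation", "lineage"]


class AssignmentError(RuntimeError):
    """No valid sib-avoiding mate assignment (or no replacement) found."""


@dataclass
class DriveParams:
    """Maternal transmission bias at the drive locus.

    tau is the probability that a heterozygous dam transmits the driven
    allele (0.5 = Mendelian). ``tau_sampler``, if given, draws a
    per-dam tau (background dependence); it is called once per mating.
    """

    tau: float = 0.66
    tau_sampler: Callable[[np.random.Generator], float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must be in [0, 1]")

    def sample_tau(self, rng: np.random.Generator) -> float:
        if self.tau_sampler is None:
            return self.tau
        t = float(self.tau_sampler(rng))
        return min(max(t, 0.0), 1.0)


@dataclass
class SchemeParams:
    """Breeding-scheme knobs of the randomized colony design."""

    n_lineages: int = 175
    ab_duplicates: bool = True
    failure_rate: float = 0.05
    litters_per_pair: int = 2
    sib_avoidance: bool = True
    max_pairing_retries: int = 200

    def __post_init__(self) -> None:
        if self.n_lineages < 2:
            raise ValueError("need at least two lineages")
        if not 0.0 <= self.failure_rate <= 1.0:
            raise ValueError("failure rate must be a probability")


@dataclass
class LitterModel:
    """Litter-size distribution: truncated negative binomial.

    Heterozygous (Wa) dams have reduced litters; the reduction is
    ``wa_dam_effect`` pups (additive) or a fractional reduction
    (multiplicative). Sire genotype never affects litter size.
    """

    base_mean: float = 9.0
    wa_dam_effect: float = 1.5
    effect_type: str = "additive"
    dispersion: float = 50.0

    def __post_init__(self) -> None:
        if self.base_mean < 0:
            raise ValueError("mean litter size must be >= 0")
        if self.effect_type not in ("additive", "multiplicative"):
            raise ValueError("effect_type must be additive or multiplicative")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")

    def mean_for(self, dam_w: int) -> float:
        if dam_w != 1:
            return self.base_mean
        if self.effect_type == "additive":
            return max(self.base_mean - self.wa_dam_effect, 0.0)
        return self.base_mean * max(1.0 - self.wa_dam_effect, 0.0)


def draw_litter(dam_w: int, model: LitterModel, rng: np.random.Generator) -> int:
    """Draw a non-negative litter size given the dam's locus genotype."""
    mean = model.mean_for(dam_w)
    if mean == 0.0:
        return 0
    theta = model.dispersion
    return int(rng.negative_binomial(theta, theta / (theta + mean)))


def draw_crossovers(genome_map: GenomeMap, chrom: str,
                    rng: np.random.Generator) -> list[int]:
    """Crossover bp positions for one meiosis: Poisson count, uniform in cM."""
    c = genome_map.chromosomes[chrom]
    n = rng.poisson(c.length_morgans)
    if n == 0:
        return []
    cm = rng.uniform(0.0, 100.0 * c.length_morgans, size=n)
    bp = np.sort(np.asarray(genome_map.cm_to_bp(chrom, cm), dtype=float))
    out = sorted({int(b) for b in bp if 0 < int(b) < c.length_bp})
    return out


def _recombine(m0: FounderMosaic, m1: FounderMosaic, crossovers: Sequence[int],
               start_strand: int) -> FounderMosaic:
    """The meiotic product that starts on ``start_strand`` at position 0."""
    if not crossovers:
        return m0 if start_strand == 0 else m1
    strands = (m0, m1)
    bounds = [0, *crossovers, m0.length]
    segs: list[tuple[int, int, str]] = []
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        src = strands[(start_strand + k) % 2]
        # sub-segments of src overlapping [lo, hi)
        i = np.searchsorted(np.asarray(src.starts), lo, side="right") - 1
        while i < len(src.starts) and src.starts[i] < hi:
            s = max(src.starts[i], lo)
            e = src.starts[i + 1] if i + 1 < len(src.starts) else src.length
            segs.append((s, min(e, hi), src.founders[i]))
            i += 1
    return FounderMosaic(m0.chrom, m0.length, segs)


def make_gamete(parent: Individual, genome_map: GenomeMap, locus: DriveLocus,
                drive: DriveParams, rng: np.random.Generator,
                force_w: bool | None = None,
                tau: float | None = None) -> dict[str, FounderMosaic]:
    """One gamete: a recombinant mosaic per chromosome of the parent.

    For a dam heterozygous at the drive locus the product carrying the
    driven allele at the locus point is transmitted with probability
    tau; sires and homozygous dams are unbiased. ``force_w`` conditions
    the gamete on carrying (True) or not carrying (False) the driven
    allele — used when the pup's genotype was drawn ahead of genome
    construction — and is ignored when the parent is homozygous there.
    """
    if tau is None:
        tau = drive.tau
    gamete: dict[str, FounderMosaic] = {}
    for chrom, homologues in parent.genome.items():
        if len(homologues) == 1:  # male X (or XO): transmitted intact
            gamete[chrom] = homologues[0]
            continue
        m0, m1 = homologues
        xs = draw_crossovers(genome_map, chrom, rng)
        if chrom == locus.chrom:
            k = int(np.searchsorted(np.asarray(xs), locus.pos, side="right"))
            f_at = ((m0, m1)[k % 2].founder_at(locus.pos),
                    (m0, m1)[(k + 1) % 2].founder_at(locus.pos))
            carries = tuple(f == locus.driven_founder for f in f_at)
            if force_w is not None and carries[0] != carries[1]:
                start = 0 if carries[0] == force_w else 1
            elif (parent.sex == "F" and carries[0] != carries[1]):
                w_start = 0 if carries[0] else 1
                start = w_start if rng.random() < tau else 1 - w_start
            else:
                start = int(rng.integers(2))
        else:
            start = int(rng.integers(2))
        gamete[chrom] = _recombine(m0, m1, xs, start)
    return gamete


def random_mosaic(chrom: str, length: int, rng: np.random.Generator,
                  expected_segments: float = 8.0) -> FounderMosaic:
    """A random founder mosaic with ~expected_segments segments."""
    n_break = rng.poisson(max(expected_segments - 1.0, 0.0))
    bps = sorted({int(b) for b in rng.integers(1, length, size=n_break)})
    bounds = [0, *bps, length]
    founders: list[str] = []
    for _ in range(len(bounds) - 1):
        if not founders:
            founders.append(FOUNDER_CODES[rng.integers(8)])
        else:
            others = [f for f in FOUNDER_CODES if f != founders[-1]]
            founders.append(others[rng.integers(7)])
    return FounderMosaic(chrom, length,
                         [(bounds[i], bounds[i + 1], founders[i])
                          for i in range(len(founders))])


def set_founder_at(mosaic: FounderMosaic, pos: int, founder: str) -> FounderMosaic:
    """Relabel the segment containing ``pos`` (used to seed G0 genotypes)."""
    segs = [(s, e, founder if s <= pos < e else f) for s, e, f in mosaic.segments]
    return FounderMosaic(mosaic.chrom, mosaic.length, segs)


@dataclass
class LineageSlot:
    """The breeders a lineage contributes to this generation's matings."""

    lineage: int
    a_female: Individual
    a_male: Individual
    b_female: Individual | None = None
    b_male: Individual | None = None


@dataclass
class Population:
    generation: int
    slots: list[LineageSlot]

    @property
    def breeders(self) -> list[Individual]:
        """A-group breeders (the core colony)."""
        out = []
        for s in self.slots:
            out.extend([s.a_female, s.a_male])
        return out

    @property
    def all_individuals(self) -> list[Individual]:
        out = []
        for s in self.slots:
            for ind in (s.a_female, s.a_male, s.b_female, s.b_male):
                if ind is not None:
                    out.append(ind)
        return out


def initial_population(genome_map: GenomeMap, scheme: SchemeParams,
                       rng: np.random.Generator, locus: DriveLocus | None = None,
                       p_driven: float | None = None,
                       expected_segments: float = 8.0,
                       generation: int = 0) -> Population:
    """A founding generation of random founder-mosaic individuals.

    Each chromosome is an independent random mosaic (a stand-in for
    incipient-CC genomes). If ``p_driven`` is given, each homologue of
    the drive chromosome carries the driven founder at the locus with
    that probability (other founders uniform), seeding the colony at a
    chosen drive-allele frequency.
    """
    if locus is None:
        locus = DriveLocus()
    counter = itertools.count()

    def make_individual(sex: str, lineage: int) -> Individual:
        genome: dict[str, tuple[FounderMosaic, ...]] = {}
        for chrom, c in genome_map.chromosomes.items():
            n_copies = 1 if (chrom == "X" and sex == "M") else 2
            mosaics = []
            for _ in range(n_copies):
                m = random_mosaic(chrom, c.length_bp, rng, expected_segments)
                if p_driven is not None and chrom == locus.chrom:
                    if rng.random() < p_driven:
                        m = set_founder_at(m, locus.pos, locus.driven_founder)
                    elif m.founder_at(locus.pos) == locus.driven_founder:
                        others = [f for f in FOUNDER_CODES
                                  if f != locus.driven_founder]
                        m = set_founder_at(m, locus.pos, others[rng.integers(7)])
                mosaics.append(m)
            genome[chrom] = tuple(mosaics)
        mito = FOUNDER_CODES[rng.integers(8)]
        y = FOUNDER_CODES[rng.integers(8)] if sex == "M" else None
        return Individual(id=f"G{generation}_{next(counter):05d}", sex=sex,
                          generation=generation, lineage=lineage, genome=genome,
                          mito=mito, y=y)

    slots = []
    for lin in range(scheme.n_lineages):
        slot = LineageSlot(lin, make_individual("F", lin), make_individual("M", lin))
        if scheme.ab_duplicates:
            slot.b_female = make_individual("F", lin)
            slot.b_male = make_individual("M", lin)
        slots.append(slot)
    return Population(generation, slots)


def _assign_pairs(slots: list[LineageSlot], scheme: SchemeParams,
                  rng: np.random.Generator) -> np.ndarray:
    """perm[i] = slot index providing the sire for slot i's dam.

    A random permutation is repaired by pair swaps until no dam is
    paired with her own slot's male (her litter-mate) or any full
    sibling; bounded retries guard against tiny populations where no
    valid assignment exists.
    """
    n = len(slots)

    def conflict(i: int, j: int) -> bool:
        """Would slot j's male conflict with slot i's dam?"""
        if not scheme.sib_avoidance:
            return False
        if i == j:
            return True
        dam, sire = slots[i].a_female, slots[j].a_male
        return (dam.dam_id is not None and dam.dam_id == sire.dam_id
                and dam.sire_id == sire.sire_id)

    for _ in range(scheme.max_pairing_retries):
        perm = rng.permutation(n)
        if not scheme.sib_avoidance:
            return perm
        for _ in range(10 * n):  # local repair by pair swaps
            bad = [i for i in range(n) if conflict(i, perm[i])]
            if not bad:
                return perm
            i = bad[rng.integers(len(bad))]
            k = int(rng.integers(n))
            if not conflict(i, perm[k]) and not conflict(k, perm[i]):
                perm[i], perm[k] = perm[k], perm[i]
    raise AssignmentError("no sib-avoiding pairing found "
                          f"in {scheme.max_pairing_retries} retries")


class _Mating:
    """Internal: one mated pair and its (lazily embodied) litters."""

    __slots__ = ("lineage", "group", "dam", "sire", "tau", "failed",
                 "litters", "taken")

    def __init__(self, lineage, group, dam, sire, tau, failed):
        self.lineage = lineage
        self.group = group
        self.dam = dam
        self.sire = sire
        self.tau = tau
        self.failed = failed
        # per litter: list of (sex, mat_w, pat_w) pup tuples
        self.litters: list[list[tuple[str, int, int]]] = []
        self.taken: set[tuple[int, int]] = set()

    def pool(self, sex: str, max_litters: int) -> list[tuple[int, int, int]]:
        """(litter_idx, pup_idx, w) for untaken pups of ``sex``."""
        out = []
        for li, litter in enumerate(self.litters[:max_litters]):
            for pi, (s, mw, pw) in enumerate(litter):
                if s == sex and (li, pi) not in self.taken:
                    out.append((li, pi, mw + pw))
        return out


def _gamete_probs(w: int, tau: float, maternal: bool) -> float:
    """P(gamete carries the driven allele) for a parent of W count w."""
    if w == 0:
        return 0.0
    if w == 2:
        return 1.0
    return tau if maternal else 0.5


def breed_generation(population: Population, scheme: SchemeParams,
                     litter_model: LitterModel, locus: DriveLocus,
                     drive: DriveParams, rng: np.random.Generator,
                     policy: PurgePolicy | None = None,
                     genome_map: GenomeMap | None = None,
                     ) -> tuple[Population, pd.DataFrame, pd.DataFrame]:
    """Breed one generation; returns (next population, records, pedigree).

    With ``policy=None`` breeders are selected at random from the first
    litter (second litter as fallback). With a purge policy, matings in
    the discard set (and non-retained WW x Wa mass) request replacement,
    genotyped progeny pools span ``policy.litters_genotyped`` litters,
    and minimum-W progeny are selected.
    """
    if genome_map is None:
        raise ValueError("genome_map is required")
    gen = population.generation + 1
    slots = population.slots
    perm = _assign_pairs(slots, scheme, rng)
    counter = itertools.count()
    records: list[tuple] = []
    pedigree: list[tuple] = []

    matings: dict[tuple[int, str], _Mating] = {}
    for i, slot in enumerate(slots):
        pairs = [("A", slot.a_female, slots[perm[i]].a_male)]
        if scheme.ab_duplicates and slot.b_female is not None \
                and slots[perm[i]].b_male is not None:
            pairs.append(("B", slot.b_female, slots[perm[i]].b_male))
        for group, dam, sire in pairs:
            tau = drive.sample_tau(rng)
            failed = rng.random() < scheme.failure_rate
            m = _Mating(slot.lineage, group, dam, sire, tau, failed)
            dam_w = w_count(dam, locus)
            sire_w = w_count(sire, locus)
            p_mat = _gamete_probs(dam_w, tau, maternal=True)
            p_pat = _gamete_probs(sire_w, 0.5, maternal=False)
            if failed:
                records.append((gen, slot.lineage, group, dam.id, sire.id,
                                GENOTYPE_LABELS[dam_w], GENOTYPE_LABELS[sire_w],
                                0, 0, 0, 1))
            else:
                for li in range(scheme.litters_per_pair):
                    size = draw_litter(dam_w, litter_model, rng)
                    pups = [("F" if rng.random() < 0.5 else "M",
                             int(rng.random() < p_mat), int(rng.random() < p_pat))
                            for _ in range(size)]
                    m.litters.append(pups)
                    records.append((gen, slot.lineage, group, dam.id, sire.id,
                                    GENOTYPE_LABELS[dam_w],
                                    GENOTYPE_LABELS[sire_w], li + 1,
                                    sum(1 for p in pups if p[0] == "F"),
                                    sum(1 for p in pups if p[0] == "M"), 0))
            matings[(i, group)] = m

    def mating_retained(m: _Mating) -> bool:
        if m.failed:
            return False
        if policy is None:
            return True
        from .purge import MatingType
        mt = MatingType(w_count(m.dam, locus), w_count(m.sire, locus))
        r = policy.retention(mt)
        if r == 0.0:
            return False
        if r < 1.0:
            return rng.random() < r
        return True

    retained: dict[tuple[int, str], bool] = {
        key: mating_retained(m) for key, m in matings.items()}

    def pick_pup(m: _Mating, sex: str) -> tuple[int, int, int] | None:
        max_litters = (policy.litters_genotyped if policy is not None
                       else scheme.litters_per_pair)
        if policy is None:
            # prefer first litter, fall back to later litters
            for nl in range(1, len(m.litters) + 1):
                pool = [p for p in m.pool(sex, nl)]
                if pool:
                    return pool[rng.integers(len(pool))]
            return None
        pool = m.pool(sex, max_litters)
        if not pool:
            return None
        if policy.min_w_selection:
            lo = min(p[2] for p in pool)
            pool = [p for p in pool if p[2] == lo]
        return pool[rng.integers(len(pool))]

    def embody(m: _Mating, sex: str, li: int, pi: int) -> Individual:
        _, mat_w, pat_w = m.litters[li][pi]
        m.taken.add((li, pi))
        dam_gam = make_gamete(m.dam, genome_map, locus, drive, rng,
                              force_w=bool(mat_w), tau=m.tau)
        sire_gam = make_gamete(m.sire, genome_map, locus, drive, rng,
                               force_w=bool(pat_w))
        genome: dict[str, tuple[FounderMosaic, ...]] = {}
        for chrom in genome_map.chromosomes:
            if chrom == "X":
                genome[chrom] = ((dam_gam["X"], sire_gam["X"]) if sex == "F"
                                 else (dam_gam["X"],))
            else:
                genome[chrom] = (dam_gam[chrom], sire_gam[chrom])
        ind = Individual(id=f"G{gen}_{next(counter):05d}", sex=sex,
                         generation=gen, lineage=m.dam.lineage, genome=genome,
                         mito=m.dam.mito, y=m.sire.y if sex == "M" else None,
                         dam_id=m.dam.id, sire_id=m.sire.id)
        pedigree.append((ind.id, m.dam.id, m.sire.id, sex, gen, ind.lineage))
        return ind

    roles = (["a_female", "a_male", "b_female", "b_male"]
             if scheme.ab_duplicates else ["a_female", "a_male"])
    new_slots: list[LineageSlot] = []
    unfilled: list[tuple[int, str]] = []
    for i, slot in enumerate(slots):
        chosen: dict[str, Individual] = {}
        for role in roles:
            sex = "F" if role.endswith("female") else "M"
            ind = None
            for group in ("A", "B"):
                key = (i, group)
                if key not in matings or not retained[key]:
                    continue
                hit = pick_pup(matings[key], sex)
                if hit is not None:
                    ind = embody(matings[key], sex, hit[0], hit[1])
                    break
            if ind is None:
                unfilled.append((i, role))
            chosen[role] = ind
        new_slots.append(LineageSlot(
            slot.lineage, chosen.get("a_female"), chosen.get("a_male"),
            chosen.get("b_female"), chosen.get("b_male")))

    # replacement policy: another lineage provides the missing breeder(s)
    if unfilled:
        donor_keys = [k for k, m in matings.items() if retained[k]]
        for i, role in unfilled:
            sex = "F" if role.endswith("female") else "M"
            ind = None
            order = rng.permutation(len(donor_keys))
            for j in order:
                m = matings[donor_keys[j]]
                hit = pick_pup(m, sex)
                if hit is not None:
                    ind = embody(m, sex, hit[0], hit[1])
                    break
            if ind is None:
                raise AssignmentError(
                    f"no replacement {sex} available for lineage {slots[i].lineage}")
            setattr(new_slots[i], role, ind)
        # slot lineage label follows the dam of its A female
        for i, _ in unfilled:
            new_slots[i].lineage = new_slots[i].a_female.lineage

    rec = pd.DataFrame(records, columns=RECORD_COLUMNS)
    ped = pd.DataFrame(pedigree, columns=PEDIGREE_COLUMNS)
    return Population(gen, new_slots), rec, ped


@dataclass
class ColonyConfig:
    """Everything simulate_colony needs, in named blocks."""

    scheme: SchemeParams = field(default_factory=SchemeParams)
    litter: LitterModel = field(default_factory=LitterModel)
    drive: DriveParams = field(default_factory=DriveParams)
    locus: DriveLocus = field(default_factory=DriveLocus)
    generations: int = 10
    seed: int = 0
    p_driven0: float | None = None
    purge_policy: PurgePolicy | None = None
    purge_start_generation: int | None = None
    expected_segments: float = 8.0

    @classmethod
    def from_dict(cls, d: dict) -> "ColonyConfig":
        kw: dict = {}
        if "scheme" in d:
            kw["scheme"] = SchemeParams(**d["scheme"])
        if "litter" in d:
            kw["litter"] = LitterModel(**d["litter"])
        if "drive" in d:
            kw["drive"] = DriveParams(**d["drive"])
        if "locus" in d:
            loc = dict(d["locus"])
            if "marker_positions" in loc:
                loc["marker_positions"] = tuple(loc["marker_positions"])
            kw["locus"] = DriveLocus(**loc)
        if "purge" in d and d["purge"] is not None:
            pg = dict(d["purge"])
            kw["purge_start_generation"] = pg.pop("start_generation", 1)
            kw["purge_policy"] = PurgePolicy(**pg) if pg else PurgePolicy()
        for k in ("generations", "seed", "p_driven0", "expected_segments"):
            if k in d:
                kw[k] = d[k]
        return cls(**kw)


@dataclass
class SimulationResult:
    trajectory: pd.DataFrame
    records: pd.DataFrame
    pedigree: pd.DataFrame
    population: Population
    populations: list[Population] | None = None


def _trajectory_row(pop: Population, locus: DriveLocus,
                    records: pd.DataFrame | None) -> dict:
    from .genome import MITO_CLASSES, Y_CLASSES
    breeders = pop.breeders
    n_hap = 0
    counts = dict.fromkeys(FOUNDER_CODES, 0)
    w_alleles = 0
    for ind in breeders:
        for m in ind.genome[locus.chrom]:
            f = m.founder_at(locus.pos)
            counts[f] += 1
            n_hap += 1
            if f == locus.driven_founder:
                w_alleles += 1
    row: dict = {"generation": pop.generation,
                 "p_W": w_alleles / n_hap if n_hap else np.nan}
    for f in FOUNDER_CODES:
        row[f"freq_{f}"] = counts[f] / n_hap if n_hap else np.nan
    for c in MITO_CLASSES:
        row[f"mito_{c}"] = sum(1 for s in pop.slots if s.a_female.mito_class == c)
    for c in Y_CLASSES:
        row[f"y_{c}"] = sum(1 for s in pop.slots if s.a_male.y_class == c)
    if records is not None and len(records):
        ok = records[records["failed"] == 0]
        row["mean_litter"] = float((ok["n_female"] + ok["n_male"]).mean()) \
            if len(ok) else np.nan
        row["failed_matings"] = int(
            records.drop_duplicates(["lineage", "group"])["failed"].sum())
    else:
        row["mean_litter"] = np.nan
        row["failed_matings"] = 0
    return row


def simulate_colony(config: ColonyConfig, genome_map: GenomeMap | None = None,
                    keep_populations: bool = False) -> SimulationResult:
    """Run the colony forward and log per-generation monitoring rows.

    The trajectory has one row per generation (including the founding
    one): driven-allele frequency among A-group breeders at the locus,
    founder frequencies at the locus, mito/Y haplogroup counts among
    lineage dams/sires, mean litter size and failed-mating count.
    """
    if genome_map is None:
        genome_map = GenomeMap.default()
    rng = np.random.default_rng(config.seed)
    pop = initial_population(genome_map, config.scheme, rng, config.locus,
                             p_driven=config.p_driven0,
                             expected_segments=config.expected_segments)
    rows = [_trajectory_row(pop, config.locus, None)]
    all_records: list[pd.DataFrame] = []
    all_ped: list[pd.DataFrame] = []
    pops = [pop] if keep_populations else None
    for g in range(1, config.generations + 1):
        policy = None
        if (config.purge_policy is not None
                and config.purge_start_generation is not None
                and g >= config.purge_start_generation):
            policy = config.purge_policy
        pop, rec, ped = breed_generation(pop, config.scheme, config.litter,
                                         config.locus, config.drive, rng,
                                         policy=policy, genome_map=genome_map)
        all_records.append(rec)
        all_ped.append(ped)
        rows.append(_trajectory_row(pop, config.locus, rec))
        if keep_populations:
            pops.append(pop)
    trajectory = pd.DataFrame(rows)
    records = (pd.concat(all_records, ignore_index=True) if all_records
               else pd.DataFrame(columns=RECORD_COLUMNS))
    pedigree = (pd.concat(all_ped, ignore_index=True) if all_ped
                else pd.DataFrame(columns=PEDIGREE_COLUMNS))
    return SimulationResult(trajectory, records, pedigree, pop, pops)
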