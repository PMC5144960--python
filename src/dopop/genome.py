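"""Core genome representation for an eight-founder outbred population.

Chromosomes are represented as founder mosaics: ordered runs of
0-based, half-open [start, end) intervals each labelled with the founder
strain that contributed the segment. Founder codes follow the standard
CC/DO letter convention:

    A = A/J          B = C57BL/6J     C = 129S1/SvImJ  D = NOD/ShiLtJ
    E = NZO/HlLtJ    F = CAST/EiJ     G = PWK/PhJ      H = WSB/EiJ

The meiotic-drive locus (*R2d2*) lives on chromosome 2; its driven
allele is the WSB/EiJ (H) haplotype.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

FOUNDER_CODES: tuple[str, ...] = ("A", "B", "C", "D", "E", "F", "G", "H")

FOUNDER_STRAINS: dict[str, str] = {
    "A": "A/J",
    "B": "C57BL/6J",
    "C": "129S1/SvImJ",
    "D": "NOD/ShiLtJ",
    "E": "NZO/HlLtJ",
    "F": "CAST/EiJ",
    "G": "PWK/PhJ",
    "H": "WSB/EiJ",
}

#: the founder whose allele drives at the default locus
DRIVEN_FOUNDER = "H"

# uniparental haplogroup classes distinguishable on the arrays
MITO_CLASS: dict[str, str] = {
    "A": "ABCD", "B": "ABCD", "C": "ABCD", "D": "ABCD",
    "E": "E", "F": "F", "G": "G", "H": "H",
}
Y_CLASS: dict[str, str] = {
    "A": "A", "B": "BCE", "C": "BCE", "D": "D",
    "E": "BCE", "F": "F", "G": "G", "H": "H",
}

MITO_CLASSES: tuple[str, ...] = ("ABCD", "E", "F", "G", "H")
Y_CLASSES: tuple[str, ...] = ("A", "BCE", "D", "F", "G", "H")


class CoordinateError(ValueError):
    """A position falls outside its chromosome."""


class MosaicError(ValueError):
    """A founder mosaic violates the tiling invariant."""


@dataclass(frozen=True)
class Chromosome:
    """One chromosome of the genome map."""

    name: str
    length_bp: int
    length_morgans: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"chromosome {self.name}: length_bp must be > 0")
        if self.length_morgans < 0:
            raise ValueError(f"chromosome {self.name}: genetic length must be >= 0")


class GenomeMap:
    """Physical and genetic map: chromosomes plus marker anchors.

    The cM<->bp relation on each chromosome is piecewise linear through
    the marker anchors (with the chromosome ends pinned at 0 and the
    chromosome lengths); with no markers it is uniform.
    """

    def __init__(self, chromosomes: Sequence[Chromosome],
                 markers: pd.DataFrame | None = None):
        self.chromosomes: dict[str, Chromosome] = {c.name: c for c in chromosomes}
        if len(self.chromosomes) != len(chromosomes):
            raise ValueError("duplicate chromosome names")
        if markers is None:
            markers = pd.DataFrame(columns=["marker", "chrom", "bp", "cM"])
        markers = markers.reset_index(drop=True)
        for chrom, grp in markers.groupby("chrom"):
            if chrom not in self.chromosomes:
                raise ValueError(f"marker chromosome {chrom!r} not in map")
            bp = grp["bp"].to_numpy()
            if not np.all(np.diff(bp) > 0):
                raise ValueError(f"marker bp positions not strictly increasing on {chrom}")
            c = self.chromosomes[chrom]
            if bp.min() < 0 or bp.max() >= c.length_bp:
                raise CoordinateError(f"marker outside chromosome {chrom}")
        self.markers = markers

    @property
    def chromosome_names(self) -> list[str]:
        return list(self.chromosomes)

    def _anchors(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        c = self.chromosomes[chrom]
        grp = self.markers[self.markers["chrom"] == chrom]
        bp = np.concatenate([[0.0], grp["bp"].to_numpy(float), [float(c.length_bp)]])
        cm = np.concatenate([[0.0], grp["cM"].to_numpy(float),
                             [100.0 * c.length_morgans]])
        # drop non-monotone anchor sets (degenerate fixtures) -> uniform map
        if not np.all(np.diff(cm) >= 0):
            bp = np.array([0.0, float(c.length_bp)])
            cm = np.array([0.0, 100.0 * c.length_morgans])
        return bp, cm

    def cm_to_bp(self, chrom: str, cm: np.ndarray | float) -> np.ndarray | float:
        bp, cmv = self._anchors(chrom)
        return np.interp(cm, cmv, bp)

    def bp_to_cm(self, chrom: str, pos: np.ndarray | float) -> np.ndarray | float:
        bp, cmv = self._anchors(chrom)
        return np.interp(pos, bp, cmv)

    @classmethod
    def from_tsv(cls, path, chromosomes: Sequence[Chromosome]) -> "GenomeMap":
        tab = pd.read_csv(path, sep="\t")
        return cls(chromosomes, tab[["marker", "chrom", "bp", "cM"]])

    def to_tsv(self, path) -> None:
        self.markers.to_csv(path, sep="\t", index=False)

    @classmethod
    def default(cls, n_autosomes: int = 19, markers_per_chrom: int = 100,
                include_x: bool = True) -> "GenomeMap":
        """A mouse-like default map: autosomes 1..n plus X, uniform markers.

        Physical lengths taper from ~195 Mb down; genetic lengths from
        ~0.98 M down, roughly 0.5 cM/Mb. The X is 171 Mb / 0.80 M with a
        denser marker grid (250 kb) on the distal 10 Mb, where the
        pseudoautosomal boundary and X-duplication calling live.
        """
        chroms = []
        rows = []
        for i in range(1, n_autosomes + 1):
            length = int(195e6 - (i - 1) * 7.5e6)
            gl = round(0.98 - (i - 1) * 0.025, 3)
            chroms.append(Chromosome(str(i), length, gl))
            pos = np.linspace(0, length, markers_per_chrom + 2, dtype=int)[1:-1]
            for j, bp in enumerate(pos):
                rows.append((f"chr{i}_m{j:03d}", str(i), int(bp),
                             round(100 * gl * bp / length, 4)))
        if include_x:
            length, gl = 171_031_299, 0.80
            chroms.append(Chromosome("X", length, gl))
            sparse = np.linspace(0, length - 11_000_000, markers_per_chrom + 1,
                                 dtype=int)[1:]
            dense = np.arange(length - 10_000_000, length - 50_000, 250_000, dtype=int)
            pos = np.unique(np.concatenate([sparse, dense]))
            for j, bp in enumerate(pos):
                rows.append((f"chrX_m{j:03d}", "X", int(bp),
                             round(100 * gl * bp / length, 4)))
        markers = pd.DataFrame(rows, columns=["marker", "chrom", "bp", "cM"])
        return cls(chroms, markers)


class FounderMosaic:
    """A chromosome as an ordered list of founder-labelled segments.

    Segments tile [0, chromosome length) with no gaps or overlaps and
    adjacent segments carry different founders; each segment owns its
    start but not its end (half-open convention).
    """

    __slots__ = ("chrom", "length", "starts", "founders")

    def __init__(self, chrom: str, length: int,
                 segments: Iterable[tuple[int, int, str]]):
        segs = list(segments)
        if not segs:
            raise MosaicError("empty mosaic")
        starts: list[int] = []
        founders: list[str] = []
        prev_end = 0
        for start, end, f in segs:
            if start != prev_end:
                raise MosaicError(f"gap/overlap at {start} (expected {prev_end})")
            if end <= start:
                raise MosaicError(f"empty segment [{start}, {end})")
            if f not in FOUNDER_STRAINS:
                raise MosaicError(f"unknown founder {f!r}")
            if founders and founders[-1] == f:
                # merge rather than reject: writers may emit mergeable runs
                prev_end = end
                continue
            starts.append(start)
            founders.append(f)
            prev_end = end
        if prev_end != length:
            raise MosaicError(f"segments end at {prev_end}, chromosome length {length}")
        self.chrom = chrom
        self.length = length
        self.starts = starts
        self.founders = founders

    @property
    def segments(self) -> list[tuple[int, int, str]]:
        ends = self.starts[1:] + [self.length]
        return list(zip(self.starts, ends, self.founders))

    def founder_at(self, pos: int) -> str:
        if not 0 <= pos < self.length:
            raise CoordinateError(
                f"position {pos} outside chromosome {self.chrom} [0, {self.length})")
        return self.founders[bisect_right(self.starts, pos) - 1]

    def founders_at(self, positions: np.ndarray) -> np.ndarray:
        """Vectorized founder lookup (positions must lie on the chromosome)."""
        pos = np.asarray(positions)
        if pos.size and (pos.min() < 0 or pos.max() >= self.length):
            raise CoordinateError("position outside chromosome")
        idx = np.searchsorted(np.asarray(self.starts), pos, side="right") - 1
        return np.asarray(self.founders, dtype=object)[idx]

    def __eq__(self, other) -> bool:
        return (isinstance(other, FounderMosaic)
                and self.chrom == other.chrom and self.length == other.length
                and self.starts == other.starts and self.founders == other.founders)

    def __repr__(self) -> str:
        return f"FounderMosaic({self.chrom}, {len(self.starts)} segments)"


def founder_at(mosaic: FounderMosaic, pos: int) -> str:
    """Founder of the unique segment whose half-open interval contains pos."""
    return mosaic.founder_at(pos)


@dataclass(frozen=True)
class DriveLocus:
    """The meiotic-drive locus and its flanking selection markers.

    Defaults place the locus at chr2:85.65 Mb (the responder element)
    with the three chromosome-2 selection-marker positions used to
    genotype W carrier status bracketing it.
    """

    chrom: str = "2"
    pos: int = 85_650_000
    driven_founder: str = DRIVEN_FOUNDER
    marker_positions: tuple[int, ...] = (83_000_000, 85_650_000, 88_500_000)

    def __post_init__(self) -> None:
        if self.driven_founder not in FOUNDER_STRAINS:
            raise ValueError(f"unknown founder {self.driven_founder!r}")
        if not self.marker_positions:
            raise ValueError("at least one selection marker required")


GENOTYPE_LABELS = {0: "aa", 1: "Wa", 2: "WW"}
LABEL_TO_COUNT = {v: k for k, v in GENOTYPE_LABELS.items()}


@dataclass
class Individual:
    """One mouse: sex, pedigree bookkeeping, and a founder-mosaic genome.

    ``genome`` maps chromosome name -> tuple of FounderMosaic (two for
    diploid chromosomes, one X for males and XO females). ``mito`` and
    ``y`` store the founder code of the uniparental compartments; mito
    follows the matriline and y the patriline.
    """

    id: str
    sex: str  # "F" or "M"
    generation: int
    lineage: int
    genome: dict[str, tuple[FounderMosaic, ...]] = field(default_factory=dict)
    mito: str = "B"
    y: str | None = None
    karyotype: str = ""  # XX, XY, XO, XY+dupX
    dam_id: str | None = None
    sire_id: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")
        if not self.karyotype:
            self.karyotype = "XX" if self.sex == "F" else "XY"
        if self.sex == "F":
            self.y = None
        if self.karyotype == "XO" and "X" in self.genome and len(self.genome["X"]) != 1:
            raise ValueError("XO individuals carry a single X mosaic")

    @property
    def mito_class(self) -> str:
        return MITO_CLASS[self.mito]

    @property
    def y_class(self) -> str | None:
        return None if self.y is None else Y_CLASS[self.y]


def w_count(individual: Individual, locus: DriveLocus) -> int:
    """Number of homologues carrying the driven founder at the locus (0/1/2)."""
    homologues = individual.genome[locus.chrom]
    return sum(1 for m in homologues if m.founder_at(locus.pos) == locus.driven_founder)


def w_label(individual: Individual, locus: DriveLocus) -> str:
    return GENOTYPE_LABELS[w_count(individual, locus)]
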