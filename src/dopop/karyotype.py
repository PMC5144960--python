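"""Sex-chromosome karyotype calling and uniparental haplogroup assignment.

Karyotypes are called from per-marker hybridization intensity (log-scale,
LRR-like, proportional to copy number) and heterozygosity:

* XY: Y-probe intensity consistent with a present Y chromosome;
* XO: no Y signal, X intensity reduced by about one copy relative to
  the XX reference (pseudoautosomal region excluded from the mean,
  since the PAR is two-copy in every karyotype but XO), and a complete
  lack of heterozygosity on X;
* distal-X duplication in males: a run of markers proximal to the
  pseudoautosomal boundary with female-like (two-copy) intensity and
  heterozygous calls. The CAST/EiJ Y carries an extended PAR whose
  boundary sits 430 kb proximal, so for males carrying that Y the
  extended boundary applies and heterozygosity confined to the
  extension is not evidence of a duplication.

Haplogroup assignment (six Y classes, five mitochondrial classes) uses
linear discriminant analysis on a small probe panel, with covariance
shrinkage because the probe count is tiny relative to class count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

NO_CALL = -1
HET = 1


class KaryotypeError(ValueError):
    pass


@dataclass
class ArraySample:
    """One genotyped sample: calls, intensities, and nominal sex.

    ``calls`` uses allele-B dosage coding: 0/2 homozygous, 1
    heterozygous, -1 no-call. ``intensity`` is log-scale normalized
    hybridization intensity (0 = two-copy). Both are indexed against a
    shared marker panel.
    """

    id: str
    calls: np.ndarray
    intensity: np.ndarray
    nominal_sex: str = ""
    truth_karyotype: str = ""  # synthetic provenance only; never used by callers

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.calls.shape != self.intensity.shape:
            raise KaryotypeError("calls and intensity must be index-aligned")
        if not np.all(np.isfinite(self.intensity)):
            raise KaryotypeError("intensities must be finite")


@dataclass(frozen=True)
class PARInfo:
    """Pseudoautosomal boundary positions on the X chromosome."""

    standard_boundary_bp: int = 168_750_000
    cast_offset_bp: int = 430_000

    @property
    def cast_boundary_bp(self) -> int:
        return self.standard_boundary_bp - self.cast_offset_bp

    def __post_init__(self) -> None:
        if self.cast_offset_bp <= 0:
            raise KaryotypeError("CAST boundary must be proximal to the standard one")

    def boundary_for(self, y_haplogroup: str | None) -> int:
        """Applicable boundary: extended (proximal) for a CAST (F) Y."""
        return (self.cast_boundary_bp if y_haplogroup == "F"
                else self.standard_boundary_bp)


@dataclass
class KaryotypeThresholds:
    """Decision thresholds on intensity means and X heterozygosity.

    Defaults are midpoints of the copy-number intensity means used by
    the synthetic intensity model (two-copy 0, one-copy -0.5, absent
    -2.0); ``from_cohort`` re-derives them from nominal-sex reference
    distributions instead.
    """

    y_presence: float = -1.25
    x_one_copy_max: float = -0.25
    xo_het_max: float = 0.05
    min_x_markers: int = 10
    min_y_markers: int = 3

    @classmethod
    def from_cohort(cls, samples, panel: pd.DataFrame) -> "KaryotypeThresholds":
        """Set thresholds midway between nominal-male and -female cohorts."""
        y_idx = panel.index[panel["compartment"] == "Y"].to_numpy()
        x_idx = panel.index[panel["compartment"] == "X"].to_numpy()
        y_f, y_m, x_f, x_m = [], [], [], []
        for s in samples:
            (y_f if s.nominal_sex == "F" else y_m).append(
                float(np.mean(s.intensity[y_idx])))
            (x_f if s.nominal_sex == "F" else x_m).append(
                float(np.mean(s.intensity[x_idx])))
        if not y_f or not y_m:
            raise KaryotypeError("cohort thresholds need both nominal sexes")
        return cls(y_presence=(np.median(y_f) + np.median(y_m)) / 2,
                   x_one_copy_max=(np.median(x_f) + np.median(x_m)) / 2)


def _x_stats(sample: ArraySample, panel: pd.DataFrame):
    x_idx = panel.index[panel["compartment"] == "X"].to_numpy()
    y_idx = panel.index[panel["compartment"] == "Y"].to_numpy()
    x_int = sample.intensity[x_idx]
    x_calls = sample.calls[x_idx]
    called = x_calls != NO_CALL
    het_frac = float(np.mean(x_calls[called] == HET)) if called.any() else np.nan
    return (len(x_idx), len(y_idx),
            float(np.mean(x_int)) if len(x_idx) else np.nan,
            float(np.mean(sample.intensity[y_idx])) if len(y_idx) else np.nan,
            het_frac)


def call_sex_karyotype(sample: ArraySample, panel: pd.DataFrame,
                       thresholds: KaryotypeThresholds | None = None) -> str:
    """Call XX / XY / XO for one sample ("NC" if markers are insufficient).

    Y presence is read from mean Y-probe intensity; XO additionally
    requires one-copy mean X intensity (PAR excluded — PAR markers are
    annotated with their own compartment) and near-zero X
    heterozygosity.
    """
    if thresholds is None:
        thresholds = KaryotypeThresholds()
    n_x, n_y, x_mean, y_mean, het = _x_stats(sample, panel)
    if n_x < thresholds.min_x_markers or n_y < thresholds.min_y_markers:
        return "NC"
    if y_mean > thresholds.y_presence:
        return "XY"
    if x_mean < thresholds.x_one_copy_max and het < thresholds.xo_het_max:
        return "XO"
    return "XX"


@dataclass
class DuplicationThresholds:
    """Run-scan parameters for distal-X duplication detection."""

    elevated: float = -0.25  # intensity above this = two-copy-like
    smooth_window: int = 1  # >1 averages neighbouring markers first
    min_markers: int = 5
    min_het: int = 2
    max_gap: int = 1  # tolerated non-elevated markers inside a run


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if len(x) == 0 or window <= 1:
        return x
    w = min(window, len(x))
    kernel = np.ones(w)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def detect_x_duplication(sample: ArraySample, panel: pd.DataFrame,
                         par: PARInfo | None = None,
                         y_haplogroup: str | None = None,
                         thresholds: DuplicationThresholds | None = None,
                         karyotype_thresholds: KaryotypeThresholds | None = None,
                         ) -> tuple[int, int] | None:
    """Scan a male's distal X for a duplicated (two-copy) interval.

    Returns the (start_bp, end_bp) of the maximal run of robust X
    markers outside the applicable PAR with elevated smoothed intensity
    and heterozygous calls, or None. Raises for non-male input (no Y
    signal).
    """
    if par is None:
        par = PARInfo()
    if thresholds is None:
        thresholds = DuplicationThresholds()
    kcall = call_sex_karyotype(sample, panel, karyotype_thresholds)
    if kcall != "XY":
        raise KaryotypeError(f"distal-X duplication is called in XY males only "
                             f"(sample {sample.id} called {kcall})")
    boundary = par.boundary_for(y_haplogroup)
    robust = panel["robust"] if "robust" in panel.columns else True
    mask = (panel["compartment"] == "X") & (panel["bp"] < boundary) & robust
    sub = panel[mask].sort_values("bp")
    idx = sub.index.to_numpy()
    bp = sub["bp"].to_numpy()
    smoothed = _smooth(sample.intensity[idx], thresholds.smooth_window)
    elevated = smoothed > thresholds.elevated
    # runs of elevated markers, tolerating up to max_gap interior drops
    runs: list[tuple[int, int]] = []
    hits = np.flatnonzero(elevated)
    for k in hits:
        if runs and k - runs[-1][1] <= thresholds.max_gap + 1:
            runs[-1] = (runs[-1][0], k)
        else:
            runs.append((k, k))
    best: tuple[int, int] | None = None
    for lo_k, hi_k in runs:
        n_markers = hi_k - lo_k + 1
        n_het = int(np.sum(sample.calls[idx[lo_k:hi_k + 1]] == HET))
        if n_markers >= thresholds.min_markers and n_het >= thresholds.min_het:
            if best is None or n_markers > (best[1] - best[0] + 1):
                best = (lo_k, hi_k)
    if best is None:
        return None
    lo_k, hi_k = best
    # breakpoints lie between the run and its non-elevated neighbours;
    # a run reaching the last scanned marker extends to the PAR boundary
    start = int((bp[lo_k] + bp[lo_k - 1]) / 2) if lo_k > 0 else int(bp[0])
    end = int((bp[hi_k] + bp[hi_k + 1]) / 2) if hi_k + 1 < len(bp) \
        else int(boundary)
    return start, end


@dataclass
class HaplogroupModel:
    """A trained linear-discriminant haplogroup classifier."""

    lda: LinearDiscriminantAnalysis
    classes: tuple[str, ...]
    probes: tuple[str, ...]
    probe_means: np.ndarray  # training means, for missing-call imputation

    def __post_init__(self) -> None:
        if not self.probes:
            raise KaryotypeError("probe list must be non-empty")


class _ShrunkFlooredCovariance:
    """Empirical covariance shrunk toward its diagonal, with a variance floor.

    Keeps the pooled within-class covariance positive definite even on
    tiny, perfectly concordant probe panels (where the empirical
    within-class variance is exactly zero and Ledoit-Wolf shrinkage
    degenerates to the zero matrix).
    """

    def __init__(self, alpha: float = 0.25, floor: float = 0.05):
        self.alpha = alpha
        self.floor = floor

    def fit(self, x: np.ndarray) -> "_ShrunkFlooredCovariance":
        x = np.asarray(x, dtype=float)
        xc = x - x.mean(axis=0)
        s = xc.T @ xc / max(len(x), 1)
        shrunk = (1 - self.alpha) * s + self.alpha * np.diag(np.diag(s))
        shrunk[np.diag_indices_from(shrunk)] += self.floor
        self.covariance_ = shrunk
        return self


def train_haplogroup_classifier(genotypes: pd.DataFrame, labels,
                                probes=None, shrinkage_alpha: float = 0.25,
                                variance_floor: float = 0.05,
                                ) -> HaplogroupModel:
    """Fit a regularized LDA on training samples with known haplogroups.

    ``genotypes`` is samples x probes (allele-dosage coding, -1 for
    no-call); shrinkage toward a floored diagonal covariance keeps the
    model well-posed on tiny probe panels.
    """
    labels = np.asarray(labels)
    if probes is not None:
        genotypes = genotypes[list(probes)]
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise KaryotypeError("training needs at least two haplogroup classes")
    x = genotypes.to_numpy(dtype=float)
    x[x == NO_CALL] = np.nan
    col_means = np.nanmean(x, axis=0)
    if np.any(np.isnan(col_means)):
        raise KaryotypeError("a probe has no called training genotypes")
    x = np.where(np.isnan(x), col_means, x)
    lda = LinearDiscriminantAnalysis(
        solver="lsqr",
        covariance_estimator=_ShrunkFlooredCovariance(shrinkage_alpha,
                                                      variance_floor))
    lda.fit(x, labels)
    return HaplogroupModel(lda, classes, tuple(genotypes.columns), col_means)


def assign_haplogroup(model: HaplogroupModel, calls: pd.Series | dict,
                      low_confidence: float = 0.8) -> tuple[str, float, bool]:
    """Assign the argmax-posterior class; returns (label, posterior, ok).

    Missing probes (absent or no-call) are imputed with training means;
    more than half missing is an error. ``ok`` is False when the
    posterior falls below ``low_confidence``.
    """
    if isinstance(calls, dict):
        calls = pd.Series(calls)
    x = np.full(len(model.probes), np.nan)
    for j, probe in enumerate(model.probes):
        if probe in calls.index and calls[probe] != NO_CALL:
            x[j] = float(calls[probe])
    n_missing = int(np.sum(np.isnan(x)))
    if n_missing > len(model.probes) / 2:
        raise KaryotypeError(
            f"{n_missing}/{len(model.probes)} model probes missing")
    x = np.where(np.isnan(x), model.probe_means, x)
    post = model.lda.predict_proba(x.reshape(1, -1))[0]
    k = int(np.argmax(post))
    label = str(model.lda.classes_[k])
    return label, float(post[k]), bool(post[k] >= low_confidence)
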