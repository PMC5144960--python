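"""Plain-text (TSV) readers and writers for every table the package uses.

All formats are wide or long TSV so fixtures stay human-readable:
breeding records (File S1-like layout), marker panels with founder
consensus alleles, array call/intensity matrices (markers x samples),
36-state diplotype probabilities (long layout), private-variant masks,
and simulation trajectories.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .breeding import RECORD_COLUMNS
from .genome import FOUNDER_CODES
from .karyotype import ArraySample
from .monitor import DIPLOTYPE_STATES
from .synthetic import PANEL_COLUMNS, SyntheticPanel


def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_records(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    missing = set(RECORD_COLUMNS) - set(tab.columns)
    if missing:
        raise ValueError(f"breeding records missing columns: {sorted(missing)}")
    return tab


def write_panel(panel: SyntheticPanel, path) -> None:
    tab = panel.markers.copy()
    for i, f in enumerate(FOUNDER_CODES):
        tab[f"allele_{f}"] = panel.consensus[:, i]
    tab.to_csv(path, sep="\t", index=False)


def read_panel(path) -> SyntheticPanel:
    tab = pd.read_csv(path, sep="\t", keep_default_na=False)
    consensus = tab[[f"allele_{f}" for f in FOUNDER_CODES]].to_numpy(int)
    markers = tab[PANEL_COLUMNS].copy()
    markers["robust"] = markers["robust"].astype(bool)
    markers["private_founder"] = markers["private_founder"].astype(str)
    return SyntheticPanel(markers, consensus)


def write_samples(samples: list[ArraySample], panel: SyntheticPanel,
                  calls_path, intensity_path) -> None:
    """Markers-x-samples wide TSVs for calls and intensities."""
    idx = panel.markers["marker"]
    calls = pd.DataFrame({s.id: s.calls for s in samples})
    calls.insert(0, "marker", idx.to_numpy())
    calls.to_csv(calls_path, sep="\t", index=False)
    inten = pd.DataFrame({s.id: np.round(s.intensity, 5) for s in samples})
    inten.insert(0, "marker", idx.to_numpy())
    inten.to_csv(intensity_path, sep="\t", index=False)


def read_samples(calls_path, intensity_path,
                 sexes: dict[str, str] | None = None) -> list[ArraySample]:
    calls = pd.read_csv(calls_path, sep="\t").set_index("marker")
    inten = pd.read_csv(intensity_path, sep="\t").set_index("marker")
    if list(calls.columns) != list(inten.columns) \
            or not calls.index.equals(inten.index):
        raise ValueError("calls and intensity files are not aligned")
    out = []
    for sid in calls.columns:
        sex = (sexes or {}).get(sid, "")
        out.append(ArraySample(sid, calls[sid].to_numpy(np.int8),
                               inten[sid].to_numpy(float), nominal_sex=sex))
    return out


def write_diplotypes(dip_probs: np.ndarray, sample_ids, marker_ids,
                     path) -> None:
    """Long-layout TSV: one row per (sample, marker), 36 state columns."""
    n_s, n_m, n_k = dip_probs.shape
    if n_k != 36:
        raise ValueError("diplotype array must have 36 states")
    state_cols = [f"{f}{g}" for f, g in DIPLOTYPE_STATES]
    flat = dip_probs.reshape(n_s * n_m, 36)
    tab = pd.DataFrame(flat, columns=state_cols)
    tab.insert(0, "marker", list(marker_ids) * n_s)
    tab.insert(0, "sample", np.repeat(list(sample_ids), n_m))
    tab.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_diplotypes(path) -> tuple[np.ndarray, list[str], list[str]]:
    tab = pd.read_csv(path, sep="\t")
    state_cols = [f"{f}{g}" for f, g in DIPLOTYPE_STATES]
    samples = list(dict.fromkeys(tab["sample"]))
    markers = list(dict.fromkeys(tab["marker"]))
    arr = tab[state_cols].to_numpy(float).reshape(len(samples), len(markers), 36)
    return arr, samples, markers


def write_mask(mask: pd.DataFrame, path) -> None:
    mask.to_csv(path, sep="\t", index=False)


def read_mask(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    need = {"variant", "chrom", "bp", "founder"}
    if not need <= set(tab.columns):
        raise ValueError("private-variant mask needs variant/chrom/bp/founder")
    return tab


def write_trajectory(trajectory: pd.DataFrame, path) -> None:
    trajectory.to_csv(path, sep="\t", index=False, float_format="%.6g")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
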