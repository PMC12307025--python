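"""File I/O: EEG readers/writers, tables and matrices.

Continuous EEG is read from BrainVision (``.vhdr``), EDF (``.edf``) via
MNE, or from a plain numeric channels-x-samples CSV matrix accompanied by
a JSON sidecar holding channel labels and the sampling rate.  Derived
outputs (band tables, connectivity matrices, metric and model tables) are
plain TSV/CSV so every stage's result is inspectable with standard tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .spectral import ContinuousEEG

__all__ = [
    "read_eeg",
    "write_eeg_matrix",
    "read_behaviour",
    "write_behaviour",
    "write_connectivity",
    "read_connectivity",
]

_BEHAVIOUR_COLS = ["subject_id", "age_group", "sex", "semantic_fluency",
                   "letter_fluency"]


def _check_nan(labels: list[str], data: np.ndarray) -> None:
    bad = ~np.isfinite(data)
    if bad.any():
        ch = int(np.argmax(bad.any(axis=1)))
        idx = np.flatnonzero(bad[ch])
        raise ValueError(
            f"non-finite samples in channel {labels[ch]!r}, sample range "
            f"{idx.min()}..{idx.max()}"
        )


def read_eeg(path: str | Path) -> ContinuousEEG:
    """Read a continuous recording from .vhdr, .edf or matrix CSV + sidecar."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".vhdr", ".edf"):
        import mne
        reader = (mne.io.read_raw_brainvision if suffix == ".vhdr"
                  else mne.io.read_raw_edf)
        raw = reader(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # MNE uses volts internally
        labels = list(raw.ch_names)
        _check_nan(labels, data)
        return ContinuousEEG(labels, float(raw.info["sfreq"]), data)
    if suffix in (".csv", ".txt", ".tsv"):
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(
                f"matrix input needs a JSON sidecar with channel labels and "
                f"sampling rate: {sidecar} not found"
            )
        meta = json.loads(sidecar.read_text())
        for key in ("channel_labels", "sampling_rate"):
            if key not in meta:
                raise KeyError(f"sidecar {sidecar} lacks {key!r}")
        sep = "\t" if suffix == ".tsv" else ","
        data = np.loadtxt(path, delimiter=sep, ndmin=2)
        labels = list(meta["channel_labels"])
        _check_nan(labels, data)
        return ContinuousEEG(labels, float(meta["sampling_rate"]), data,
                             meta.get("units", "µV"))
    raise ValueError(f"unsupported EEG format: {path.suffix}")


def write_eeg_matrix(eeg: ContinuousEEG, path: str | Path) -> Path:
    """Write a recording as CSV matrix plus JSON sidecar; returns the path."""
    path = Path(path)
    np.savetxt(path, eeg.data, delimiter=",", fmt="%.8g")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "channel_labels": list(eeg.channel_labels),
        "sampling_rate": eeg.sampling_rate,
        "units": eeg.units,
    }, indent=1))
    return path


def read_behaviour(path: str | Path) -> pd.DataFrame:
    """Read the behavioural table (TSV or CSV) and validate its columns."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _BEHAVIOUR_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"behavioural table lacks columns: {missing}")
    for col in ("semantic_fluency", "letter_fluency"):
        vals = df[col].dropna()
        if (vals < 0).any():
            raise ValueError(f"negative counts in {col!r}")
    return df


def write_behaviour(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_connectivity(matrix: ConnectivityMatrix, path: str | Path) -> Path:
    """Connectivity matrix as labelled CSV plus JSON metadata sidecar."""
    path = Path(path)
    frame = pd.DataFrame(matrix.weights, index=matrix.labels,
                         columns=matrix.labels)
    frame.to_csv(path, float_format="%.10g")
    path.with_suffix(".json").write_text(json.dumps({
        "band": matrix.band,
        "n_epochs_used": matrix.n_epochs_used,
    }, indent=1))
    return path


def read_connectivity(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    frame = pd.read_csv(path, index_col=0)
    meta = json.loads(path.with_suffix(".json").read_text())
    return ConnectivityMatrix(meta["band"], list(frame.columns),
                              frame.to_numpy(dtype=float),
                              int(meta["n_epochs_used"]))
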