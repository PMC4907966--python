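"""Plain-text interchange: spectra/design CSV, model JSON.

Spectra CSV layout: first column ``wavenumber_cm1``, one column per
spectrum named ``s<sample_id>_r<replicate>``. A sidecar labels CSV carries
``sample_id``, ``replicate`` and one ``<analyte>_mgL`` column per analyte.
All floats are written with 10 significant digits, which round-trips
read→write byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import WindowSet
from .plsr import PLSRModel
from .synth import DesignTable, SpectrumSet

__all__ = [
    "write_spectra_csv",
    "read_spectra_csv",
    "write_design_csv",
    "read_design_csv",
    "write_model_json",
    "read_model_json",
]

_FLOAT_FMT = "%.10g"
MODEL_SCHEMA_VERSION = 1


def write_spectra_csv(spectra: SpectrumSet, path: str | Path, labels_path: str | Path) -> None:
    """Write a spectrum set as a wide CSV plus a labels sidecar CSV."""
    cols = {"wavenumber_cm1": spectra.axis}
    for i, row in enumerate(spectra.labels.itertuples(index=False)):
        name = f"s{int(row.sample_id)}_r{int(getattr(row, 'replicate', 0))}"
        cols[name] = spectra.intensities[i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)
    spectra.labels.to_csv(labels_path, index=False, float_format=_FLOAT_FMT)


def read_spectra_csv(path: str | Path, labels_path: str | Path) -> SpectrumSet:
    """Read a spectrum set written by :func:`write_spectra_csv`.

    Rejects empty files, non-numeric cells (named by row/column) and a
    non-monotone wavenumber column.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty spectra file")
    frame = pd.read_csv(path)
    if frame.empty or frame.shape[1] < 2:
        raise ValueError(f"{path}: needs a wavenumber column plus at least one spectrum")
    for col in frame.columns:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric cell at data row {row + 1}, column {col!r}: "
                f"{frame[col].iloc[row]!r}"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise ValueError(f"{path}: missing value at data row {row + 1}, column {col!r}")
        frame[col] = numeric
    axis = frame.iloc[:, 0].to_numpy(dtype=float)
    if not np.all(np.diff(axis) > 0):
        row = int(np.flatnonzero(np.diff(axis) <= 0)[0])
        raise ValueError(
            f"{path}: wavenumber axis not strictly increasing at data rows {row + 1}-{row + 2}"
        )
    labels = pd.read_csv(labels_path)
    intensities = frame.iloc[:, 1:].to_numpy(dtype=float).T
    if len(labels) != intensities.shape[0]:
        raise ValueError(
            f"{labels_path}: {len(labels)} label rows for {intensities.shape[0]} spectra"
        )
    return SpectrumSet(axis=axis, intensities=intensities, labels=labels)


def write_design_csv(design: DesignTable, path: str | Path) -> None:
    design.table.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_design_csv(path: str | Path, replicates: int = 5) -> DesignTable:
    return DesignTable(table=pd.read_csv(path), replicates=replicates)


def write_model_json(model: PLSRModel, path: str | Path) -> None:
    """Serialize a fitted model (arrays, windows, metadata) to JSON."""
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "W": model.W.tolist(),
        "P": model.P.tolist(),
        "q": model.q.tolist(),
        "b": model.b.tolist(),
        "n_components": model.n_components,
        "wavenumbers": None if model.wavenumbers is None else model.wavenumbers.tolist(),
        "windows": None
        if model.windows is None
        else {"analyte": model.windows.analyte,
              "intervals": [list(iv) for iv in model.windows.intervals]},
        "meta": model.meta,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_model_json(path: str | Path) -> PLSRModel:
    path = Path(path)
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not valid model JSON ({exc})") from exc
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"{path}: unsupported model schema version {version!r} "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    windows = payload.get("windows")
    return PLSRModel(
        x_mean=np.asarray(payload["x_mean"], dtype=float),
        y_mean=float(payload["y_mean"]),
        W=np.asarray(payload["W"], dtype=float),
        P=np.asarray(payload["P"], dtype=float),
        q=np.asarray(payload["q"], dtype=float),
        b=np.asarray(payload["b"], dtype=float),
        n_components=int(payload["n_components"]),
        wavenumbers=None
        if payload.get("wavenumbers") is None
        else np.asarray(payload["wavenumbers"], dtype=float),
        windows=None
        if windows is None
        else WindowSet(windows["analyte"], tuple(tuple(iv) for iv in windows["intervals"])),
        meta=payload.get("meta", {}),
    )
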