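"""Replicate averaging and characteristic-peak window extraction.

Calibration models are built per analyte on the spectral channels inside
that analyte's characteristic peak sections only. A :class:`WindowSet`
holds those closed wavenumber intervals; :func:`extract_windows` turns a
spectrum set into the (X, y) feature matrix the regression consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import AnalyteLibrary, SpectrumSet

__all__ = [
    "WindowSet",
    "FeatureMatrix",
    "average_replicates",
    "windows_from_bands",
    "restrict_spectra",
    "extract_windows",
]


def _merge_intervals(intervals) -> tuple[tuple[float, float], ...]:
    ordered = sorted((float(lo), float(hi)) for lo, hi in intervals)
    merged: list[list[float]] = []
    for lo, hi in ordered:
        if lo >= hi:
            raise ValueError(f"window interval [{lo}, {hi}] has lo >= hi")
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return tuple((lo, hi) for lo, hi in merged)


@dataclass(frozen=True)
class WindowSet:
    """Closed wavenumber intervals defining one analyte's calibration channels.

    Intervals are sorted and overlapping ones merged on construction.
    """

    analyte: str
    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.intervals) == 0:
            raise ValueError(f"window set for {self.analyte!r} is empty")
        object.__setattr__(self, "intervals", _merge_intervals(self.intervals))

    def mask(self, axis: np.ndarray) -> np.ndarray:
        """Boolean channel membership; interval endpoints are inclusive."""
        axis = np.asarray(axis, dtype=float)
        mask = np.zeros(len(axis), dtype=bool)
        for lo, hi in self.intervals:
            mask |= (axis >= lo) & (axis <= hi)
        return mask


@dataclass
class FeatureMatrix:
    """Calibration-ready matrix: window channels x samples, plus the response.

    ``X`` is (n_samples, n_channels); ``wavenumbers`` labels the retained
    channels; ``y`` is the target analyte's true concentration per row.
    """

    X: np.ndarray
    wavenumbers: np.ndarray
    y: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids)
        if self.X.shape[0] != len(self.y) or len(self.y) != len(self.sample_ids):
            raise ValueError("rows of X, y and sample_ids must agree")
        if self.X.shape[1] != len(self.wavenumbers):
            raise ValueError("columns of X must match wavenumbers")


def average_replicates(spectra: SpectrumSet) -> SpectrumSet:
    """Channelwise mean over replicates: one spectrum per sample.

    Sample order follows first appearance in the set; labels keep sample_id
    and the true concentrations, with ``replicate`` recording how many
    spectra were averaged.
    """
    labels = spectra.labels
    if labels.empty:
        raise ValueError("cannot average an empty spectrum set")
    conc_cols = [f"{a}_mgL" for a in spectra.analytes]
    out_rows = []
    out_intensities = []
    for sample_id in labels["sample_id"].drop_duplicates():
        idx = np.flatnonzero((labels["sample_id"] == sample_id).to_numpy())
        out_intensities.append(spectra.intensities[idx].mean(axis=0))
        first = labels.iloc[idx[0]]
        out_rows.append(
            {"sample_id": int(sample_id), "replicate": len(idx)}
            | {c: float(first[c]) for c in conc_cols}
        )
    return SpectrumSet(
        axis=spectra.axis,
        intensities=np.vstack(out_intensities),
        labels=pd.DataFrame(out_rows),
        provenance=dict(spectra.provenance, averaged=True),
    )


def windows_from_bands(library: AnalyteLibrary, k: float = 3.0) -> WindowSet:
    """One interval per band, ``center ± k * hwhm``, merged where they touch."""
    if k <= 0:
        raise ValueError(f"half-width multiplier k must be > 0, got {k}")
    intervals = [(b.center - k * b.hwhm, b.center + k * b.hwhm) for b in library.bands]
    return WindowSet(analyte=library.name, intervals=intervals)


def restrict_spectra(spectra: SpectrumSet, windows: WindowSet) -> SpectrumSet:
    """Keep only the channels inside the window set (a projection)."""
    mask = windows.mask(spectra.axis)
    if not mask.any():
        raise ValueError(
            f"window set {windows.analyte!r} {list(windows.intervals)} selects no "
            f"channels on axis [{spectra.axis[0]}, {spectra.axis[-1]}]"
        )
    return SpectrumSet(
        axis=spectra.axis[mask],
        intensities=spectra.intensities[:, mask],
        labels=spectra.labels.copy(),
        provenance=dict(spectra.provenance),
    )


def extract_windows(
    spectra: SpectrumSet, windows: WindowSet, target: str
) -> FeatureMatrix:
    """Window-restricted feature matrix with the target analyte's response.

    Rows follow the spectrum set's order (one per averaged sample when the
    set has been averaged); channels are strictly increasing in wavenumber.
    """
    col = f"{target}_mgL"
    if col not in spectra.labels.columns:
        raise KeyError(f"target analyte {target!r} not labelled in spectrum set")
    restricted = restrict_spectra(spectra, windows)
    return FeatureMatrix(
        X=restricted.intensities,
        wavenumbers=restricted.axis,
        y=restricted.labels[col].to_numpy(dtype=float),
        sample_ids=restricted.labels["sample_id"].to_numpy(),
    )
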