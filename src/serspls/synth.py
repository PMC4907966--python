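"""Synthetic SERS spectrum generation.

The measured spectra behind the antiseptic calibration study are not
deposited, so this module generates spectra with the statistical structure
the downstream analysis assumes:

* each analyte contributes a fixed Lorentzian band profile scaled linearly
  (or, optionally, with Langmuir saturation) by its concentration;
* every spectrum carries one log-normal multiplicative enhancement factor,
  emulating site-to-site variability of the SERS substrate when replicate
  spectra are taken at random positions;
* additive Gaussian channel noise and an optional slowly varying polynomial
  baseline complete the measurement model.

The two concentration designs of the study — the 8-level single-analyte
series (0.3–10 mg/L potassium sorbate) and the 36-composition factorial of
potassium sorbate (PS) x sodium benzoate (SB) mixtures — are built here
exactly, with 5 replicate spectra per sample by default.

The default band libraries are synthetic stand-ins: the study shows the
characteristic peak sections of PS and SB only graphically, so the centers,
widths and relative amplitudes below are invented, chosen so that the
strongest PS and SB bands overlap the way the published spectra do.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Band",
    "AnalyteLibrary",
    "NoiseConfig",
    "DesignTable",
    "Spectrum",
    "SpectrumSet",
    "build_axis",
    "analyte_profile",
    "simulate_spectrum",
    "make_single_analyte_design",
    "make_mixture_design",
    "simulate_dataset",
    "default_libraries",
    "DEFAULT_AXIS_SPEC",
    "SINGLE_ANALYTE_LEVELS",
    "MIXTURE_LEVELS",
]

#: Fingerprint-region axis used throughout: 400–1800 cm⁻¹ in 2 cm⁻¹ steps.
DEFAULT_AXIS_SPEC = (400.0, 1800.0, 2.0)

#: Concentration levels (mg/L) of the single-analyte calibration series.
SINGLE_ANALYTE_LEVELS = (0.3, 0.5, 0.8, 1.0, 3.0, 5.0, 8.0, 10.0)

#: Per-analyte levels (mg/L) of the 36-composition mixture factorial.
MIXTURE_LEVELS = (0.0, 1.0, 5.0, 10.0, 50.0, 100.0)


@dataclass(frozen=True)
class Band:
    """One Lorentzian Raman band.

    Parameters
    ----------
    center : float
        Band center (cm⁻¹).
    hwhm : float
        Half-width at half-maximum (cm⁻¹); must be positive.
    amplitude : float
        Peak intensity per unit concentration (arbitrary units per mg/L).
    """

    center: float
    hwhm: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.hwhm <= 0:
            raise ValueError(f"band hwhm must be > 0, got {self.hwhm}")
        if self.amplitude < 0:
            raise ValueError(f"band amplitude must be >= 0, got {self.amplitude}")


@dataclass(frozen=True)
class AnalyteLibrary:
    """Named collection of bands describing one analyte's clean spectrum."""

    name: str
    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        if len(self.bands) == 0:
            raise ValueError(f"analyte {self.name!r} has no bands")
        centers = [b.center for b in self.bands]
        if len(set(centers)) != len(centers):
            raise ValueError(f"analyte {self.name!r} has duplicate band centers")


def default_libraries() -> dict[str, AnalyteLibrary]:
    """Synthetic default band libraries for PS and SB.

    These wavenumbers are invented (the study never prints them); they are
    chosen so that the PS 1640 cm⁻¹ and SB 1600 cm⁻¹ bands overlap once each
    is widened to its calibration window, mirroring the overlapping
    characteristic peak sections of the real analytes.
    """
    return {
        "PS": AnalyteLibrary(
            "PS",
            (Band(1640.0, 12.0, 1.0), Band(1380.0, 10.0, 0.6), Band(1140.0, 10.0, 0.4)),
        ),
        "SB": AnalyteLibrary(
            "SB",
            (Band(1600.0, 10.0, 1.0), Band(1026.0, 8.0, 0.5), Band(1002.0, 6.0, 0.9)),
        ),
    }


@dataclass(frozen=True)
class NoiseConfig:
    """Measurement-noise model parameters.

    Defaults are the reproduction configuration used for the end-to-end
    experiments: modest site-to-site enhancement variability, faint channel
    noise, no baseline, linear concentration response.

    Parameters
    ----------
    sigma_mult : float
        Standard deviation (log scale) of the per-spectrum log-normal
        multiplicative enhancement factor.
    sigma_add_frac : float
        Additive Gaussian noise s.d. expressed as a fraction of the maximum
        clean intensity over the design being simulated.
    baseline_amplitude : float
        Maximum magnitude of a slowly varying cubic baseline (intensity
        units); 0 disables the baseline.
    saturation_c50 : float or None
        Langmuir half-saturation concentration (mg/L). ``None`` keeps the
        concentration response exactly linear.
    """

    sigma_mult: float = 0.03
    sigma_add_frac: float = 0.005
    baseline_amplitude: float = 0.0
    saturation_c50: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_mult < 0:
            raise ValueError("sigma_mult must be >= 0")
        if self.sigma_add_frac < 0:
            raise ValueError("sigma_add_frac must be >= 0")
        if self.baseline_amplitude < 0:
            raise ValueError("baseline_amplitude must be >= 0")
        if self.saturation_c50 is not None and self.saturation_c50 <= 0:
            raise ValueError("saturation_c50 must be > 0 when present")

    @classmethod
    def zero(cls) -> "NoiseConfig":
        """Noise-free configuration (exact linear response)."""
        return cls(sigma_mult=0.0, sigma_add_frac=0.0, baseline_amplitude=0.0)


@dataclass
class DesignTable:
    """Concentration design: one row per sample, one column per analyte.

    ``table`` has a ``sample_id`` column plus one ``<analyte>_mgL`` column
    per analyte; ``replicates`` is the number of spectra simulated per row.
    """

    table: pd.DataFrame
    replicates: int = 5

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if "sample_id" not in self.table.columns:
            raise ValueError("design table needs a 'sample_id' column")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("sample_ids must be unique")
        conc = self.table[[c for c in self.table.columns if c.endswith("_mgL")]]
        if conc.empty:
            raise ValueError("design table needs at least one '<analyte>_mgL' column")
        if (conc.to_numpy() < 0).any():
            raise ValueError("concentrations must be non-negative")

    @property
    def analytes(self) -> list[str]:
        return [c[:-4] for c in self.table.columns if c.endswith("_mgL")]

    @property
    def n_samples(self) -> int:
        return len(self.table)

    def concentrations(self, sample_id: int) -> dict[str, float]:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"sample_id {sample_id} not in design")
        return {a: float(row[f"{a}_mgL"].iloc[0]) for a in self.analytes}


@dataclass
class Spectrum:
    """One measured (simulated) spectrum with its ground-truth labels."""

    axis: np.ndarray
    intensity: np.ndarray
    sample_id: int
    replicate: int
    concentrations: dict[str, float]

    def __post_init__(self) -> None:
        if len(self.axis) != len(self.intensity):
            raise ValueError("axis and intensity lengths differ")


@dataclass
class SpectrumSet:
    """A stack of spectra on one shared wavenumber axis.

    ``intensities`` is (n_spectra, n_channels); ``labels`` has one row per
    spectrum with columns ``sample_id``, ``replicate`` and ``<analyte>_mgL``.
    """

    axis: np.ndarray
    intensities: np.ndarray
    labels: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.intensities.shape[1] != len(self.axis):
            raise ValueError(
                f"intensity width {self.intensities.shape[1]} != axis length {len(self.axis)}"
            )
        if self.intensities.shape[0] != len(self.labels):
            raise ValueError("labels row count does not match number of spectra")

    @property
    def analytes(self) -> list[str]:
        return [c[:-4] for c in self.labels.columns if c.endswith("_mgL")]

    def __len__(self) -> int:
        return self.intensities.shape[0]

    def __iter__(self) -> Iterator[Spectrum]:
        for i, row in enumerate(self.labels.itertuples(index=False)):
            yield Spectrum(
                axis=self.axis,
                intensity=self.intensities[i],
                sample_id=int(getattr(row, "sample_id")),
                replicate=int(getattr(row, "replicate", 0)),
                concentrations={a: float(getattr(row, f"{a}_mgL")) for a in self.analytes},
            )


def build_axis(start: float, stop: float, step: float) -> np.ndarray:
    """Strictly increasing wavenumber axis from ``start`` to at most ``stop``.

    The axis starts exactly at ``start`` with uniform spacing ``step`` and
    includes ``stop`` when ``stop - start`` is a multiple of ``step``.
    """
    if step <= 0:
        raise ValueError(f"axis step must be > 0, got {step}")
    if start >= stop:
        raise ValueError(f"axis range inverted or empty: start={start}, stop={stop}")
    n = int(np.floor((stop - start) / step + 1e-9)) + 1
    return start + step * np.arange(n, dtype=float)


def analyte_profile(library: AnalyteLibrary, axis: np.ndarray) -> np.ndarray:
    """Clean unit-concentration spectrum of one analyte.

    Sum of Lorentzians: ``amplitude * hwhm² / ((nu - center)² + hwhm²)`` per
    band, so each band reaches exactly its amplitude at its center.
    """
    axis = np.asarray(axis, dtype=float)
    profile = np.zeros_like(axis)
    for b in library.bands:
        profile += b.amplitude * b.hwhm**2 / ((axis - b.center) ** 2 + b.hwhm**2)
    return profile


def _response(c: float, noise: NoiseConfig) -> float:
    # Linear by default; Langmuir-type saturation when c50 is configured.
    if noise.saturation_c50 is None:
        return c
    c50 = noise.saturation_c50
    return c * c50 / (c50 + c)


def _clean_spectrum(
    libraries: Mapping[str, AnalyteLibrary],
    concentrations: Mapping[str, float],
    noise: NoiseConfig,
    axis: np.ndarray,
) -> np.ndarray:
    clean = np.zeros(len(axis))
    for analyte, c in concentrations.items():
        if c < 0:
            raise ValueError(f"negative concentration for {analyte!r}: {c}")
        if analyte not in libraries:
            raise KeyError(f"no band library for analyte {analyte!r}")
        clean += _response(float(c), noise) * analyte_profile(libraries[analyte], axis)
    return clean


def simulate_spectrum(
    libraries: Mapping[str, AnalyteLibrary],
    concentrations: Mapping[str, float],
    noise: NoiseConfig,
    axis: np.ndarray,
    rng: np.random.Generator,
    add_sd: float | None = None,
) -> np.ndarray:
    """Simulate one spectrum's intensity vector.

    intensity = g * sum_a r(c_a) * profile_a + baseline + eps, with one
    log-normal enhancement factor ``g`` per spectrum and iid Gaussian
    channel noise ``eps``. ``add_sd`` fixes the absolute additive-noise
    standard deviation; when ``None`` it is ``sigma_add_frac`` times this
    spectrum's own clean maximum (dataset simulation passes the design-wide
    value instead, so faint samples get the same absolute noise floor).
    """
    axis = np.asarray(axis, dtype=float)
    clean = _clean_spectrum(libraries, concentrations, noise, axis)
    g = rng.lognormal(mean=0.0, sigma=noise.sigma_mult)
    if add_sd is None:
        add_sd = noise.sigma_add_frac * (clean.max() if clean.size else 0.0)
    baseline = np.zeros_like(axis)
    if noise.baseline_amplitude > 0:
        # Random cubic over the normalized axis, scaled to the configured peak.
        u = (axis - axis[0]) / max(axis[-1] - axis[0], 1.0)
        coeffs = rng.uniform(-1.0, 1.0, size=4)
        raw = np.polynomial.polynomial.polyval(u, coeffs)
        peak = np.abs(raw).max()
        if peak > 0:
            baseline = noise.baseline_amplitude * raw / peak
    eps = rng.normal(0.0, 1.0, size=len(axis)) * add_sd
    return g * clean + baseline + eps


def make_single_analyte_design(replicates: int = 5) -> DesignTable:
    """The 8-level PS calibration series: 0.3–10 mg/L, SB absent."""
    table = pd.DataFrame(
        {
            "sample_id": np.arange(1, len(SINGLE_ANALYTE_LEVELS) + 1),
            "PS_mgL": list(SINGLE_ANALYTE_LEVELS),
            "SB_mgL": 0.0,
        }
    )
    return DesignTable(table=table, replicates=replicates)


def make_mixture_design(replicates: int = 5) -> DesignTable:
    """The 36-composition PS x SB full factorial.

    Samples are numbered the way the study tabulates them: blocks of six
    with a fixed SB level (0, 1, 5, 10, 50, 100 mg/L) and PS ascending
    through the same levels within each block, so sample 1 is the blank and
    sample 36 is 100 mg/L of each.
    """
    rows = []
    n = 0
    for sb in MIXTURE_LEVELS:
        for ps in MIXTURE_LEVELS:
            n += 1
            rows.append({"sample_id": n, "PS_mgL": ps, "SB_mgL": sb})
    return DesignTable(table=pd.DataFrame(rows), replicates=replicates)


def simulate_dataset(
    design: DesignTable,
    libraries: Mapping[str, AnalyteLibrary],
    noise: NoiseConfig,
    axis: np.ndarray,
    seed: int,
) -> SpectrumSet:
    """Simulate ``replicates`` spectra for every design row, reproducibly.

    The additive-noise standard deviation is ``sigma_add_frac`` times the
    maximum clean intensity over the whole design, so every spectrum in the
    set sees the same absolute noise floor.
    """
    axis = np.asarray(axis, dtype=float)
    rng = np.random.default_rng(seed)
    analytes = design.analytes

    clean_max = 0.0
    per_row_conc: list[dict[str, float]] = []
    for row in design.table.itertuples(index=False):
        conc = {a: float(getattr(row, f"{a}_mgL")) for a in analytes}
        per_row_conc.append(conc)
        clean = _clean_spectrum(libraries, conc, noise, axis)
        clean_max = max(clean_max, float(clean.max()) if clean.size else 0.0)
    add_sd = noise.sigma_add_frac * clean_max

    intensities = np.empty((design.n_samples * design.replicates, len(axis)))
    label_rows = []
    i = 0
    for row, conc in zip(design.table.itertuples(index=False), per_row_conc):
        for rep in range(1, design.replicates + 1):
            intensities[i] = simulate_spectrum(
                libraries, conc, noise, axis, rng, add_sd=add_sd
            )
            label_rows.append(
                {"sample_id": int(row.sample_id), "replicate": rep}
                | {f"{a}_mgL": conc[a] for a in analytes}
            )
            i += 1
    labels = pd.DataFrame(label_rows)
    provenance = {
        "seed": int(seed),
        "noise": asdict(noise),
        "n_samples": design.n_samples,
        "replicates": design.replicates,
    }
    return SpectrumSet(axis=axis, intensities=intensities, labels=labels, provenance=provenance)
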