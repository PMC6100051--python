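"""Nuclear-ensemble (semiclassical) spectra with Lorentzian broadening.

A spectrum is the snapshot average of oscillator-strength-weighted Lorentzian
lines at the vertical transition energies:

    I(E) = (1/N_snap) * sum_records  f_i * L(E - dE_i; delta)

where L is a unit-area Lorentzian whose FWHM is the phenomenological
broadening ``delta`` (default 0.1 eV).  N_snap is the number of *distinct
snapshots*, so several states of one snapshot add without diluting each
other.  Intensities are relative (arbitrary units); an optional E^3 emission
prefactor is available but off by default, since spectra are compared by
shape after normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "ExcitationRecord",
    "SpectrumGrid",
    "lorentzian",
    "ensemble_spectrum",
    "ev_to_nm",
    "normalize",
    "find_bands",
    "EV_NM",
]

#: hc in eV*nm — lambda[nm] = EV_NM / E[eV]
EV_NM = 1239.841984


@dataclass
class ExcitationRecord:
    """One vertical electronic transition of one snapshot."""

    snapshot_id: int | str
    state: int
    energy_ev: float
    osc_strength: float
    kind: str = "absorption"  # or "emission"
    depth_nm: float | None = None
    tilt_deg: float | None = None

    def __post_init__(self) -> None:
        if self.energy_ev <= 0:
            raise ValueError(f"energy must be positive, got {self.energy_ev}")
        if self.osc_strength < 0:
            raise ValueError(f"oscillator strength must be >= 0, got {self.osc_strength}")
        if self.state < 1:
            raise ValueError("state index starts at 1")
        if self.kind not in ("absorption", "emission"):
            raise ValueError(f"kind must be absorption|emission, got {self.kind!r}")


@dataclass
class SpectrumGrid:
    axis: np.ndarray  # eV (or nm after conversion)
    intensity: np.ndarray
    broadening_ev: float
    kernel: str = "lorentzian"
    n_snapshots: int = 0
    axis_unit: str = "eV"

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.axis) != len(self.intensity):
            raise ValueError("axis and intensity lengths differ")
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError("axis must be strictly increasing")
        if np.any(self.intensity < -1e-12):
            raise ValueError("negative intensity")

    def integral(self) -> float:
        return float(np.trapezoid(self.intensity, self.axis))

    def to_frame(self) -> pd.DataFrame:
        col = "energy_eV" if self.axis_unit == "eV" else "wavelength_nm"
        return pd.DataFrame({col: self.axis, "intensity": self.intensity})

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, header=False)


def lorentzian(e: np.ndarray | float, e0: float, delta: float) -> np.ndarray | float:
    """Unit-area Lorentzian centred at ``e0`` with FWHM ``delta`` (all eV).

    L(E) = (1/pi) * (delta/2) / ((E - e0)^2 + (delta/2)^2), peak 2/(pi*delta).
    """
    if delta <= 0:
        raise ValueError("broadening delta must be positive")
    half = 0.5 * delta
    return (half / np.pi) / ((np.asarray(e, dtype=float) - e0) ** 2 + half**2)


def _records_to_arrays(records) -> tuple[np.ndarray, np.ndarray, np.ndarray, str]:
    if isinstance(records, pd.DataFrame):
        if len(records) == 0:
            raise ValueError("empty excitation ensemble")
        kinds = set(records["kind"].unique()) if "kind" in records.columns else {"absorption"}
        if len(kinds) > 1:
            raise ValueError(f"mixed record kinds {kinds} in one ensemble")
        return (
            records["energy_eV"].to_numpy(dtype=float),
            records["osc_strength"].to_numpy(dtype=float),
            records["snapshot_id"].to_numpy(),
            kinds.pop(),
        )
    records = list(records)
    if not records:
        raise ValueError("empty excitation ensemble")
    kinds = {r.kind for r in records}
    if len(kinds) > 1:
        raise ValueError(f"mixed record kinds {kinds} in one ensemble")
    return (
        np.array([r.energy_ev for r in records]),
        np.array([r.osc_strength for r in records]),
        np.array([r.snapshot_id for r in records]),
        kinds.pop(),
    )


def ensemble_spectrum(
    records,
    grid: np.ndarray | tuple[float, float, float] | None = None,
    delta: float = 0.1,
    emission_e3_prefactor: bool = False,
) -> SpectrumGrid:
    """Snapshot-averaged Lorentzian spectrum of an excitation ensemble.

    ``records`` is a list of :class:`ExcitationRecord` or a DataFrame with
    columns snapshot_id, energy_eV, osc_strength (and optionally kind).
    ``grid`` is an energy array or a (start, stop, step) triple; the default
    spans 2.0-6.0 eV for absorption and 1.5-4.5 eV for emission at 0.005 eV.
    """
    energies, fs, snaps, kind = _records_to_arrays(records)
    if np.any(energies <= 0) or np.any(fs < 0):
        raise ValueError("invalid records: energies must be > 0 and f >= 0")
    if grid is None:
        grid = (2.0, 6.0, 0.005) if kind == "absorption" else (1.5, 4.5, 0.005)
    if isinstance(grid, tuple):
        start, stop, step = grid
        axis = np.arange(start, stop + 0.5 * step, step)
    else:
        axis = np.asarray(grid, dtype=float)
    n_snap = len(pd.unique(snaps))
    weights = fs.copy()
    if emission_e3_prefactor and kind == "emission":
        weights = weights * energies**3
    half = 0.5 * delta
    # vectorised sum of Lorentzians: (n_records, n_grid)
    intensity = (
        (weights[:, None] * (half / np.pi) / ((axis[None, :] - energies[:, None]) ** 2 + half**2))
        .sum(axis=0)
        / n_snap
    )
    return SpectrumGrid(
        axis=axis, intensity=intensity, broadening_ev=delta, n_snapshots=n_snap
    )


def ev_to_nm(spectrum: SpectrumGrid, jacobian: bool = False) -> SpectrumGrid:
    """Re-express an energy-axis spectrum on a wavelength axis.

    Default is a plain remap I(lambda) = I(E(lambda)); with ``jacobian`` the
    intensity is multiplied by |dE/dlambda| = E^2 / (hc) so areas are
    preserved as spectral densities.
    """
    if spectrum.axis_unit != "eV":
        raise ValueError("spectrum is not on an energy axis")
    if np.any(spectrum.axis <= 0):
        raise ValueError("energies must be positive for wavelength conversion")
    lam = EV_NM / spectrum.axis
    inten = spectrum.intensity.copy()
    if jacobian:
        inten = inten * spectrum.axis**2 / EV_NM
    order = np.argsort(lam)
    return SpectrumGrid(
        axis=lam[order],
        intensity=inten[order],
        broadening_ev=spectrum.broadening_ev,
        kernel=spectrum.kernel,
        n_snapshots=spectrum.n_snapshots,
        axis_unit="nm",
    )


def normalize(spectrum: SpectrumGrid) -> SpectrumGrid:
    """Scale so the maximum intensity is 1 (shape comparison)."""
    peak = float(spectrum.intensity.max())
    if peak <= 0:
        raise ValueError("cannot normalise an all-zero spectrum")
    return SpectrumGrid(
        axis=spectrum.axis,
        intensity=spectrum.intensity / peak,
        broadening_ev=spectrum.broadening_ev,
        kernel=spectrum.kernel,
        n_snapshots=spectrum.n_snapshots,
        axis_unit=spectrum.axis_unit,
    )


def find_bands(
    spectrum: SpectrumGrid, prominence: float = 0.05
) -> list[tuple[float, float, float]]:
    """Local maxima of a (normalised) spectrum as (position, height, prominence).

    ``prominence`` is on the spectrum's own intensity scale; bands are sorted
    by axis position.  An all-zero spectrum has no bands.
    """
    if not spectrum.intensity.any():
        return []
    peaks, props = find_peaks(spectrum.intensity, prominence=prominence)
    bands = [
        (float(spectrum.axis[i]), float(spectrum.intensity[i]), float(p))
        for i, p in zip(peaks, props["prominences"])
    ]
    return sorted(bands, key=lambda b: b[0])
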