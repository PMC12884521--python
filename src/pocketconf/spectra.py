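"""Electronic-spectrum post-processing.

Stick spectra (wavelength, oscillator strength) are broadened with Gaussians
of fixed full width at half maximum in the wavelength domain, normalized to
unit peak, and compared between systems: position of the absorption maximum,
signed shift of the predominant transition (positive = bathochromic/red,
negative = hypsochromic/blue), relative intensity changes, and HOMO-LUMO gap
bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TransitionRecord",
    "Spectrum",
    "OrbitalEnergyTable",
    "read_transitions",
    "write_transitions",
    "broaden",
    "normalize",
    "lambda_max",
    "predominant",
    "shift",
    "percent_change",
    "homo_lumo_gap",
    "GAUSS_FWHM_FACTOR",
]

#: 4 ln 2, so that exp(-GAUSS_FWHM_FACTOR (x/fwhm)^2) has half-maxima fwhm apart
GAUSS_FWHM_FACTOR = 4.0 * math.log(2.0)

TRANSITION_COLUMNS = [
    "state",
    "lambda_nm",
    "f",
    "mu_tr_D",
    "assignment",
    "character",
    "percent",
]


@dataclass(frozen=True)
class TransitionRecord:
    """One electronic excitation S0 -> S_n."""

    state: int
    lambda_nm: float
    f: float
    mu_tr: float = 0.0
    assignment: str = ""
    character: tuple[str, ...] = ()
    weight_percent: float = 0.0
    predominant: bool = False

    def __post_init__(self) -> None:
        if self.lambda_nm <= 0:
            raise ValueError("transition wavelength must be positive")
        if self.f < 0 or self.mu_tr < 0:
            raise ValueError("oscillator strength and transition dipole are >= 0")


@dataclass
class Spectrum:
    """A broadened spectrum on a strictly increasing wavelength grid."""

    wavelengths: np.ndarray
    intensity: np.ndarray
    fwhm: float
    normalized: bool = False

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1D array")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.intensity.shape != self.wavelengths.shape:
            raise ValueError("intensity and wavelength grids must match")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class OrbitalEnergyTable:
    """Frontier orbital energies in eV, keyed by labels like 'HOMO', 'LUMO+1'."""

    energies: dict[str, float] = field(default_factory=dict)


def read_transitions(path: str | Path) -> list[TransitionRecord]:
    """Read a transition table (TSV with the Table-style column layout)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"state", "lambda_nm", "f"} - set(df.columns)
    if missing:
        raise ValueError(f"transition table is missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        character = tuple(
            t.strip() for t in str(row.get("character", "")).split(",") if t.strip()
        ) if "character" in df.columns and not pd.isna(row.get("character")) else ()
        records.append(
            TransitionRecord(
                state=int(row["state"]),
                lambda_nm=float(row["lambda_nm"]),
                f=float(row["f"]),
                mu_tr=float(row["mu_tr_D"]) if "mu_tr_D" in df.columns else 0.0,
                assignment=str(row["assignment"]) if "assignment" in df.columns and not pd.isna(row.get("assignment")) else "",
                character=character,
                weight_percent=float(row["percent"]) if "percent" in df.columns and not pd.isna(row.get("percent")) else 0.0,
                predominant=bool(row["predominant"]) if "predominant" in df.columns else False,
            )
        )
    if not records:
        raise ValueError(f"no transitions found in {path}")
    return records


def write_transitions(transitions: list[TransitionRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "state": [t.state for t in transitions],
            "lambda_nm": [t.lambda_nm for t in transitions],
            "f": [t.f for t in transitions],
            "mu_tr_D": [t.mu_tr for t in transitions],
            "assignment": [t.assignment for t in transitions],
            "character": [",".join(t.character) for t in transitions],
            "percent": [t.weight_percent for t in transitions],
            "predominant": [t.predominant for t in transitions],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def broaden(
    transitions: list[TransitionRecord],
    fwhm: float = 20.0,
    grid: np.ndarray | tuple[float, float, float] = (120.0, 400.0, 0.1),
) -> Spectrum:
    """Gaussian broadening in the wavelength domain.

    I(lam) = sum_k f_k exp(-4 ln2 (lam - lam_k)^2 / fwhm^2); peak amplitudes
    are proportional to the oscillator strengths, which is all a normalized
    spectrum needs.
    """
    if not transitions:
        raise ValueError("at least one transition is required")
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    if isinstance(grid, tuple):
        lo, hi, step = grid
        wavelengths = np.arange(lo, hi + 0.5 * step, step)
    else:
        wavelengths = np.asarray(grid, dtype=float)
    intensity = np.zeros_like(wavelengths)
    for t in transitions:
        if t.f == 0.0:
            continue
        intensity += t.f * np.exp(
            -GAUSS_FWHM_FACTOR * ((wavelengths - t.lambda_nm) / fwhm) ** 2
        )
    return Spectrum(wavelengths=wavelengths, intensity=intensity, fwhm=fwhm)


def normalize(spectrum: Spectrum) -> Spectrum:
    """Scale to unit maximum intensity (idempotent)."""
    peak = spectrum.intensity.max()
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return replace(
        spectrum, intensity=spectrum.intensity / peak, normalized=True
    )


def lambda_max(spectrum: Spectrum) -> float:
    """Wavelength of the global intensity maximum; ties resolve to the
    longest wavelength."""
    if spectrum.wavelengths.size == 0:
        raise ValueError("empty spectrum")
    peak = spectrum.intensity.max()
    at_peak = np.flatnonzero(spectrum.intensity >= peak - 1e-15 * max(peak, 1.0))
    return float(spectrum.wavelengths[at_peak[-1]])


def predominant(transitions: list[TransitionRecord]) -> TransitionRecord:
    """The designated predominant transition: an explicitly flagged row, or
    the highest oscillator strength otherwise."""
    if not transitions:
        raise ValueError("empty transition table has no predominant row")
    flagged = [t for t in transitions if t.predominant]
    if flagged:
        return flagged[0]
    return max(transitions, key=lambda t: t.f)


def shift(
    transitions_a: list[TransitionRecord],
    transitions_b: list[TransitionRecord],
    mode: str = "predominant",
) -> tuple[float, str]:
    """Signed wavelength displacement lambda(b) - lambda(a) of the
    predominant transitions; positive is bathochromic (red), negative
    hypsochromic (blue)."""
    if mode != "predominant":
        raise ValueError(f"unknown shift mode: {mode!r}")
    pa = predominant(transitions_a)
    pb = predominant(transitions_b)
    delta = pb.lambda_nm - pa.lambda_nm
    if delta > 0:
        label = "bathochromic"
    elif delta < 0:
        label = "hypsochromic"
    else:
        label = "unshifted"
    return delta, label


def percent_change(value_a: float, value_b: float) -> float:
    """100 (b - a) / a."""
    if value_a == 0:
        raise ValueError("percent change is undefined for a zero baseline")
    return 100.0 * (value_b - value_a) / value_a


def homo_lumo_gap(table: OrbitalEnergyTable) -> float:
    """E(LUMO) - E(HOMO) in eV; degenerate HOMO labels resolve to the
    highest-energy occupied entry, LUMO to the lowest-energy virtual."""
    homos = [v for k, v in table.energies.items() if k.upper().startswith("HOMO")]
    lumos = [v for k, v in table.energies.items() if k.upper().startswith("LUMO")]
    if not homos or not lumos:
        raise ValueError("orbital table must contain HOMO and LUMO entries")
    gap = min(lumos) - max(homos)
    if gap <= 0:
        raise ValueError("HOMO lies above LUMO; not a closed-shell ground state")
    return gap
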