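"""Bulk spectral ratio metrics.

77 K emission spectra resolve phycobilisome terminal emitters (~660 nm), PSII
(~695 nm) and PSI (~730 nm); the F730/F695 ratio tracks the PSI/PSII balance
and F660/F695 (or F650/F695) tracks phycobilisome energetic decoupling.  The
room-temperature absorbance ratio A630/A682 reports the PBS-to-chlorophyll
pigment balance.  All ratios are band means over a narrow window and are
invariant to uniform intensity rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: default band-reading wavelengths, nm
F_PSI_NM = 730.0
F_PSII_NM = 695.0
F_PBS_NM = 660.0
F_PBS_ALT_NM = 650.0
A_PBS_NM = 630.0
A_CHL_NM = 682.0
DEFAULT_WINDOW_NM = 1.0


@dataclass
class Spectrum:
    """A wavelength grid with intensities (emission or absorbance)."""

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    kind: str = "emission"

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength_nm.shape != self.intensity.shape:
            raise ValueError("wavelengths and intensities must have equal length")
        if not np.all(np.diff(self.wavelength_nm) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0 (baseline-correct first)")
        if self.kind not in ("emission", "absorbance"):
            raise ValueError("kind must be 'emission' or 'absorbance'")

    def scaled(self, k: float) -> "Spectrum":
        return Spectrum(self.wavelength_nm, self.intensity * k, self.kind)


def read_spectrum_csv(path: str | Path, kind: str = "emission") -> Spectrum:
    """Read a two-column (wavelength_nm, intensity) CSV."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("expected two columns: wavelength_nm, intensity")
    return Spectrum(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), kind)


def band_value(s: Spectrum, center_nm: float, window_nm: float = DEFAULT_WINDOW_NM) -> float:
    """Mean intensity over [center - window/2, center + window/2].

    Computed as the trapezoidal integral over the window divided by its width,
    with linear interpolation at the window edges; as the window shrinks this
    converges to the interpolated point value.
    """
    lo, hi = center_nm - window_nm / 2, center_nm + window_nm / 2
    wl = s.wavelength_nm
    if lo < wl[0] or hi > wl[-1]:
        raise ValueError(
            f"band [{lo:.1f}, {hi:.1f}] nm falls outside the grid [{wl[0]:.1f}, {wl[-1]:.1f}] nm"
        )
    if window_nm <= 0:
        return float(np.interp(center_nm, wl, s.intensity))
    inside = (wl > lo) & (wl < hi)
    xs = np.concatenate([[lo], wl[inside], [hi]])
    ys = np.interp(xs, wl, s.intensity)
    return float(np.trapezoid(ys, xs) / (hi - lo))


def emission_ratio(
    s: Spectrum, num_nm: float, den_nm: float, window_nm: float = DEFAULT_WINDOW_NM
) -> float:
    """band_value(num) / band_value(den); the PSI/PSII and PBS-decoupling metric."""
    den = band_value(s, den_nm, window_nm)
    if den <= 0:
        raise ValueError(f"denominator band at {den_nm} nm is zero")
    return band_value(s, num_nm, window_nm) / den


def psi_psii_ratio(s: Spectrum, window_nm: float = DEFAULT_WINDOW_NM) -> float:
    """F730/F695 — the PSI-to-PSII fluorescence balance."""
    return emission_ratio(s, F_PSI_NM, F_PSII_NM, window_nm)


def pbs_decoupling_ratio(
    s: Spectrum, numerator_nm: float = F_PBS_NM, window_nm: float = DEFAULT_WINDOW_NM
) -> float:
    """F660/F695 (or F650/F695 with ``numerator_nm=650``) — PBS decoupling."""
    return emission_ratio(s, numerator_nm, F_PSII_NM, window_nm)


def absorbance_ratio(
    s: Spectrum,
    pbs_nm: float = A_PBS_NM,
    chl_nm: float = A_CHL_NM,
    window_nm: float = DEFAULT_WINDOW_NM,
) -> float:
    """A630/A682 — phycobilisome-to-chlorophyll pigment balance."""
    if s.kind != "absorbance":
        raise ValueError("absorbance_ratio expects an absorbance spectrum")
    return emission_ratio(s, pbs_nm, chl_nm, window_nm)


def ratios_table(samples: dict[str, Spectrum], window_nm: float = DEFAULT_WINDOW_NM) -> pd.DataFrame:
    """Per-sample ratio summary for a batch of emission/absorbance spectra."""
    rows = []
    for name, s in samples.items():
        row: dict = {"sample": name, "kind": s.kind}
        if s.kind == "emission":
            row["f730_f695"] = psi_psii_ratio(s, window_nm)
            row["f660_f695"] = pbs_decoupling_ratio(s, window_nm=window_nm)
        else:
            row["a630_a682"] = absorbance_ratio(s, window_nm=window_nm)
        rows.append(row)
    return pd.DataFrame(rows)
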