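"""Pigment and spectral photometry.

* methanol-extract chlorophyll from OD at 665 nm (factor 12.7),
* whole-cell chlorophyll from the corrected absorbance
  ``A_Chl678 = 1.0162 A_678 - 0.0630 A_625`` and the molar absorption
  coefficient 68 mM^-1 cm^-1,
* 77 K fluorescence emission spectrum normalization to the mode-specific
  anchor peak (PSI emission near 720 nm for 435 nm excitation, phycocyanin
  emission near 655 nm for 600 nm excitation) after background subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "CHL_METHANOL_FACTOR",
    "CHL_ABS_COEFF_MM_CM",
    "ANCHOR_WINDOWS_NM",
    "WholeCellAbsorbance",
    "ChlWholeCellResult",
    "Spectrum77K",
    "chl_methanol",
    "chl_whole_cell",
    "normalize_77k",
]

CHL_METHANOL_FACTOR = 12.7  # extract units per OD_665 unit (90% methanol)
CHL_ABS_COEFF_MM_CM = 68.0  # mM^-1 cm^-1, chlorophyll a in whole cells

#: Anchor peak search windows per excitation mode, nm (+-10 nm around the
#: approximate emission maxima).
ANCHOR_WINDOWS_NM = {435: (710.0, 730.0), 600: (645.0, 665.0)}


@dataclass(frozen=True)
class WholeCellAbsorbance:
    """Whole-cell absorbance readings; A_750 is optional turbidity metadata."""

    a_678: float
    a_625: float
    a_750: float | None = None

    def __post_init__(self) -> None:
        for name in ("a_678", "a_625"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def a_chl678(self) -> float:
        return 1.0162 * self.a_678 - 0.0630 * self.a_625


@dataclass(frozen=True)
class ChlWholeCellResult:
    a_chl678: float
    concentration_mM: float
    flagged: bool  # negative corrected absorbance: inputs inconsistent


def chl_methanol(od665: float) -> float:
    """Chlorophyll in a 90% methanol extract: 12.7 x OD_665."""
    if od665 < 0:
        raise ValueError("od665 must be >= 0")
    return CHL_METHANOL_FACTOR * od665


def chl_whole_cell(
    absorbance: WholeCellAbsorbance,
    pathlength_cm: float = 1.0,
    *,
    subtract_turbidity: bool = False,
) -> ChlWholeCellResult:
    """Corrected chlorophyll absorbance and concentration from whole-cell
    readings: ``A_Chl678 = 1.0162 A_678 - 0.0630 A_625`` and
    ``c = A_Chl678 / (68 * pathlength)`` in mM.

    ``subtract_turbidity=True`` pre-subtracts the 750 nm reading from both
    absorbances (off by default; the formula expects raw readings).  A
    negative corrected absorbance is returned flagged rather than raised.
    """
    if pathlength_cm <= 0:
        raise ValueError("pathlength must be > 0")
    a678, a625 = absorbance.a_678, absorbance.a_625
    if subtract_turbidity:
        if absorbance.a_750 is None:
            raise ValueError("subtract_turbidity requires an A_750 reading")
        a678 = a678 - absorbance.a_750
        a625 = a625 - absorbance.a_750
    a_chl = 1.0162 * a678 - 0.0630 * a625
    conc = a_chl / (CHL_ABS_COEFF_MM_CM * pathlength_cm)
    return ChlWholeCellResult(a_chl, conc, flagged=a_chl < 0)


@dataclass(frozen=True)
class Spectrum77K:
    """Low-temperature emission spectrum on a strictly increasing
    wavelength grid; ``excitation_nm`` selects the normalization anchor."""

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    excitation_nm: int = 435
    background: float = 0.0  # value already subtracted, bookkeeping

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wl.shape != it.shape:
            raise ValueError("wavelengths and intensities must match in length")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.excitation_nm not in ANCHOR_WINDOWS_NM:
            raise ValueError(
                f"excitation mode must be one of {sorted(ANCHOR_WINDOWS_NM)}"
            )
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "intensities", it)


def normalize_77k(
    spectrum: Spectrum77K, *, background: float | str = 0.0
) -> Spectrum77K:
    """Background-subtract and scale so the anchor peak equals 1.

    ``background`` is a constant, or ``"min"`` for the spectrum minimum.
    The anchor is the maximum within the mode's window (710-730 nm for
    435 nm excitation, 645-665 nm for 600 nm excitation); a nonpositive
    anchor peak is an error.
    """
    wl = spectrum.wavelengths_nm
    it = spectrum.intensities
    bg = float(it.min()) if background == "min" else float(background)
    it = it - bg

    lo, hi = ANCHOR_WINDOWS_NM[spectrum.excitation_nm]
    window = (wl >= lo) & (wl <= hi)
    if not window.any():
        raise ValueError(
            f"anchor window {lo}-{hi} nm not covered by the wavelength grid"
        )
    peak = float(it[window].max())
    if peak <= 0:
        raise ValueError("anchor peak is not positive after background subtraction")
    return replace(
        spectrum,
        intensities=it / peak,
        background=spectrum.background + bg,
    )
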