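"""Peak finding, shift classification, synchronous spectra, and EEM taxonomy.

Ligand binding perturbs the microenvironment of a protein's intrinsic
fluorophores (tryptophan, tyrosine); the perturbation shows up as shifts of
the emission maximum (redshift = more polar surroundings, blueshift = more
hydrophobic) and as intensity changes.  This module extracts those features
from emission spectra and from excitation-emission matrices (EEMs):

* emission-peak location with sub-grid (3-point parabolic) refinement, so
  1-nm-scale shifts are resolvable on coarse grids;
* synchronous spectra — intensity along the constant-offset diagonal
  lambda_em = lambda_ex + delta, with delta = 15 nm reporting tyrosine and
  60 nm tryptophan;
* EEM peak taxonomy — Rayleigh (lambda_em = lambda_ex) and second-order
  (lambda_em = 2 lambda_ex) scattering ridges, plus the fluorophore peak
  (Peak I, excitation near 280 nm) and the polypeptide-backbone peak
  (Peak II, excitation near 230 nm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputDomainError, InsufficientDataError
from .titration import EEM, EmissionSpectrum

__all__ = [
    "PEAK1_EX_WINDOW",
    "PEAK2_EX_WINDOW",
    "Peak",
    "PeakShift",
    "EEMPeaks",
    "find_peak",
    "peak_shift",
    "synchronous_spectrum",
    "eem_peaks",
    "eem_peak_deltas",
]

#: Excitation windows (nm) classifying off-ridge EEM maxima.
PEAK1_EX_WINDOW = (260.0, 300.0)   # Trp/Tyr fluorophore region
PEAK2_EX_WINDOW = (210.0, 250.0)   # polypeptide backbone region


@dataclass(frozen=True)
class Peak:
    wavelength: float    # nm, parabola-refined
    intensity: float
    found: bool = True
    flag: str = ""       # "flat" or "boundary" when not a genuine peak


@dataclass(frozen=True)
class PeakShift:
    lambda_free: float           # nm
    lambda_bound: float          # nm
    shift: float                 # nm, bound - free
    direction: str               # redshift | blueshift | none
    intensity_change_pct: float  # % change at peak, bound vs free


@dataclass(frozen=True)
class EEMPeaks:
    rayleigh_ridge: tuple[tuple[float, float], ...]      # (lam_ex, lam_em) cells
    second_order_ridge: tuple[tuple[float, float], ...]  # lam_em = 2 lam_ex cells
    peak1: tuple[float, float, float] | None             # (lam_ex, lam_em, intensity)
    peak2: tuple[float, float, float] | None
    flag: str = ""


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Refine a grid maximum by the vertex of the parabola through 3 points."""
    if i == 0 or i == x.size - 1:
        return float(x[i]), float(y[i])
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (y0 - 2 * y1 + y2)
    if denom >= 0:  # not concave; keep the grid point
        return float(x1), float(y1)
    # uniform-spacing vertex formula generalized to the local spacing
    h = (x2 - x0) / 2.0
    delta = 0.5 * (y0 - y2) / denom
    xv = float(x1 + delta * h)
    yv = float(y1 - 0.25 * (y0 - y2) * delta)
    return xv, yv


def find_peak(spectrum: EmissionSpectrum, refine: bool = True) -> Peak:
    """Locate the emission maximum.

    Ties go to the lowest wavelength.  A flat spectrum or a maximum sitting
    on the grid boundary (monotone spectrum) is returned with
    ``found=False`` and an explanatory flag rather than as a peak.
    """
    wl = spectrum.wavelengths
    y = spectrum.intensities
    if wl.size < 3:
        raise InsufficientDataError("peak finding needs >= 3 points")
    if np.ptp(y) == 0:
        return Peak(wavelength=float(wl[0]), intensity=float(y[0]), found=False, flag="flat")
    i = int(np.argmax(y))  # argmax returns the first (lowest-wavelength) maximum
    if i == 0 or i == wl.size - 1:
        return Peak(wavelength=float(wl[i]), intensity=float(y[i]), found=False, flag="boundary")
    if refine:
        xv, yv = _parabolic_refine(wl, y, i)
    else:
        xv, yv = float(wl[i]), float(y[i])
    return Peak(wavelength=xv, intensity=yv, found=True)


def peak_shift(free: EmissionSpectrum, bound: EmissionSpectrum) -> PeakShift:
    """Shift of the emission maximum on binding (bound minus free).

    Positive shift is a redshift (more polar fluorophore microenvironment),
    negative a blueshift.  The intensity change is evaluated peak-to-peak.
    """
    lo = max(free.wavelengths[0], bound.wavelengths[0])
    hi = min(free.wavelengths[-1], bound.wavelengths[-1])
    if lo >= hi:
        raise InputDomainError("spectra have no overlapping wavelength range")
    p_free = find_peak(free)
    p_bound = find_peak(bound)
    shift = p_bound.wavelength - p_free.wavelength
    if shift > 0:
        direction = "redshift"
    elif shift < 0:
        direction = "blueshift"
    else:
        direction = "none"
    change = 100.0 * (p_bound.intensity - p_free.intensity) / p_free.intensity
    return PeakShift(
        lambda_free=p_free.wavelength,
        lambda_bound=p_bound.wavelength,
        shift=shift,
        direction=direction,
        intensity_change_pct=change,
    )


def synchronous_spectrum(eem: EEM, delta_lambda: float) -> EmissionSpectrum:
    """Sample an EEM along the diagonal lambda_em = lambda_ex + delta_lambda.

    Intensities are linearly interpolated between emission grid points; the
    returned spectrum is indexed by excitation wavelength.  delta = 0 is the
    Rayleigh ridge itself.
    """
    ex = eem.excitation_grid
    em = eem.emission_grid
    target = ex + delta_lambda
    valid = (target >= em[0]) & (target <= em[-1])
    if not np.any(valid):
        raise InputDomainError(
            f"delta_lambda={delta_lambda} nm leaves no excitation point with "
            f"lambda_ex + delta inside the emission grid"
        )
    rows = np.where(valid)[0]
    intensities = np.array(
        [np.interp(target[i], em, eem.intensity_matrix[i]) for i in rows]
    )
    return EmissionSpectrum(
        excitation_wavelength=float("nan"),
        wavelengths=ex[valid],
        intensities=intensities,
    )


def _ridge_cells(eem: EEM, order: int, tolerance: float) -> list[tuple[float, float]]:
    cells = []
    for lam_ex in eem.excitation_grid:
        for lam_em in eem.emission_grid:
            if abs(lam_em - order * lam_ex) <= tolerance:
                cells.append((float(lam_ex), float(lam_em)))
    return cells


def _ridge_mask(eem: EEM, tolerance: float) -> np.ndarray:
    ex = eem.excitation_grid[:, None]
    em = eem.emission_grid[None, :]
    return (np.abs(em - ex) <= tolerance) | (np.abs(em - 2 * ex) <= tolerance)


def _local_maxima(z: np.ndarray) -> np.ndarray:
    """Cells >= every 8-neighbour (ridge tails sloping toward the ridge fail)."""
    padded = np.pad(z, 1, mode="constant", constant_values=-np.inf)
    out = np.ones_like(z, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == dj == 0:
                continue
            out &= z >= padded[1 + di : 1 + di + z.shape[0],
                               1 + dj : 1 + dj + z.shape[1]]
    return out


def _window_peak(
    eem: EEM, off_ridge: np.ndarray, window: tuple[float, float]
) -> tuple[float, float, float] | None:
    ex = eem.excitation_grid
    in_win = (ex >= window[0]) & (ex <= window[1])
    usable = off_ridge & in_win[:, None] & _local_maxima(eem.intensity_matrix)
    if not np.any(usable):
        return None
    z = np.where(usable, eem.intensity_matrix, -np.inf)
    i, j = np.unravel_index(int(np.argmax(z)), z.shape)
    if not np.isfinite(z[i, j]) or z[i, j] <= 0:
        return None
    return float(ex[i]), float(eem.emission_grid[j]), float(eem.intensity_matrix[i, j])


def eem_peaks(eem: EEM, tolerance: float | None = None) -> EEMPeaks:
    """Locate scattering ridges and the two protein peaks in an EEM.

    ``tolerance`` (nm) bounds the distance from the exact ridge lines; the
    default is two emission grid steps.  Peak I / Peak II are the off-ridge
    maxima inside the excitation windows around 280 and 230 nm; when no
    positive off-ridge maximum exists the corresponding peak is None and a
    flag is set.
    """
    if tolerance is None:
        steps = np.diff(eem.emission_grid)
        tolerance = 2.0 * float(np.median(steps)) if steps.size else 2.0
    off_ridge = ~_ridge_mask(eem, tolerance)
    peak1 = _window_peak(eem, off_ridge, PEAK1_EX_WINDOW)
    peak2 = _window_peak(eem, off_ridge, PEAK2_EX_WINDOW)
    flag = "" if (peak1 or peak2) else "no off-ridge maxima"
    return EEMPeaks(
        rayleigh_ridge=tuple(_ridge_cells(eem, 1, tolerance)),
        second_order_ridge=tuple(_ridge_cells(eem, 2, tolerance)),
        peak1=peak1,
        peak2=peak2,
        flag=flag,
    )


def eem_peak_deltas(
    bound: EEM, free: EEM, tolerance: float | None = None
) -> dict[str, float | None]:
    """Intensity change (bound minus free) of Peak I and Peak II."""
    pb = eem_peaks(bound, tolerance)
    pf = eem_peaks(free, tolerance)
    out: dict[str, float | None] = {}
    for name, b, f in (("peak1", pb.peak1, pf.peak1), ("peak2", pb.peak2, pf.peak2)):
        out[name] = None if (b is None or f is None) else b[2] - f[2]
    return out
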