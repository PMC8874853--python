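"""Synthetic titrations, spectra and EEMs with known ground truth.

No raw fluorescence data accompany typical quenching studies, so every
analysis stage here is validated against generated data whose parameters
are known exactly.  The generator reproduces the standard experimental
design for a serum-albumin study: protein held at 1.5 uM, quencher stepped
over 0-27.5 uM, temperatures near physiological, an optional competing
ligand at fixed concentration, and optional inner-filter attenuation.

The generative model is deliberately the exact inverse of the linearized
analysis equations (not a mass-balance binding simulation), so recovery is
exact at zero noise:

* static mechanism — (F0 - F)/F = Kb_app [Q]^n with the competitive
  attenuation Kb_app = Kb / (1 + Kc [C]);
* dynamic mechanism — F0/F = 1 + Ksv(T) [Q], with Ksv rising linearly in
  temperature at a stated positive coefficient;
* noise — multiplicative Gaussian with a given coefficient of variation
  (an approximation to fluorescence shot/gain noise), deterministic under
  the seed;
* inner filter — the stated attenuation is applied in reverse
  (observed = true / exp((A_ex + A_em)/2)) so the correction recovers the
  noise-free truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InputDomainError
from .thermodynamics import GAS_CONSTANT
from .titration import EEM, MICROMOLAR_TO_MOLAR, EmissionSpectrum, TitrationSeries

__all__ = [
    "GroundTruth",
    "default_concentration_grid",
    "generate_titration",
    "generate_vant_hoff_set",
    "generate_emission_pair",
    "generate_eem",
    "generate_eem_pair",
]

#: Relative increase of a dynamic Ksv per kelvin above the reference 298 K.
DYNAMIC_KSV_TEMP_COEFF = 0.01


@dataclass(frozen=True)
class GroundTruth:
    """Parameters of a simulated titration."""

    mechanism: str = "static"       # static | dynamic
    kb: float = 2.07e4              # M^-n, binding constant (static)
    n: float = 1.0                  # stoichiometry
    ksv: float = 2.0e4              # M^-1 (dynamic mechanism)
    competitor_k: float = 0.0       # M^-1, competitor binding constant
    competitor_conc: float = 0.0    # uM
    noise_cv: float = 0.0           # relative multiplicative noise
    ife: tuple[float, float] | None = None  # constant (a_ex, a_em) per point
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in ("static", "dynamic"):
            raise InputDomainError(f"unknown mechanism {self.mechanism!r}")
        if self.kb <= 0 or self.ksv <= 0:
            raise InputDomainError("binding and quenching constants must be positive")
        if self.competitor_k < 0 or self.competitor_conc < 0:
            raise InputDomainError("competitor parameters must be non-negative")
        if self.noise_cv < 0:
            raise InputDomainError("noise_cv must be non-negative")

    @property
    def kb_apparent(self) -> float:
        """Kb attenuated by competitive inhibition: Kb / (1 + Kc [C])."""
        c_molar = self.competitor_conc * MICROMOLAR_TO_MOLAR
        return self.kb / (1.0 + self.competitor_k * c_molar)


def default_concentration_grid(n_points: int = 12, q_max: float = 27.5) -> np.ndarray:
    """Evenly spaced quencher grid 0..q_max uM including the mandatory zero."""
    return np.linspace(0.0, q_max, n_points)


def generate_titration(
    truth: GroundTruth,
    conc_grid: np.ndarray | None = None,
    f0: float = 1000.0,
    temperature: float = 298.0,
    label: str = "sim",
) -> tuple[TitrationSeries, GroundTruth]:
    """Generate one titration series under ``truth``.

    Returns the series together with the ground truth actually used (the
    input, unchanged), mirroring how a simulated experiment travels with
    its manifest.
    """
    if conc_grid is None:
        conc_grid = default_concentration_grid()
    conc_grid = np.asarray(conc_grid, dtype=float)
    if np.any(conc_grid < 0):
        raise InputDomainError("concentration grid must be non-negative")
    if conc_grid[0] != 0:
        raise InputDomainError("concentration grid must start at 0")
    q = conc_grid * MICROMOLAR_TO_MOLAR

    if truth.mechanism == "static":
        ratio = truth.kb_apparent * np.power(q, truth.n, where=q > 0, out=np.zeros_like(q))
        f = f0 / (1.0 + ratio)              # (F0-F)/F = Kb_app [Q]^n
    else:
        ksv_t = truth.ksv * (1.0 + DYNAMIC_KSV_TEMP_COEFF * (temperature - 298.0))
        f = f0 / (1.0 + ksv_t * q)          # F0/F = 1 + Ksv(T) [Q]

    if truth.noise_cv > 0:
        rng = np.random.default_rng(truth.seed)
        f = f * (1.0 + truth.noise_cv * rng.standard_normal(f.size))
        f = np.maximum(f, 1e-12)

    a_ex = a_em = None
    if truth.ife is not None:
        ax, am = truth.ife
        a_ex = np.full(conc_grid.size, float(ax))
        a_em = np.full(conc_grid.size, float(am))
        f = f / np.exp((a_ex + a_em) / 2.0)  # observed; correction inverts this

    competitor = None
    if truth.competitor_conc > 0:
        competitor = ("competitor", truth.competitor_conc)
    series = TitrationSeries(
        label=label,
        ligand_conc=conc_grid,
        intensity_obs=f,
        temperature=temperature,
        protein_conc=1.5,
        a_ex=a_ex,
        a_em=a_em,
        competitor=competitor,
    )
    return series, truth


def kb_at_temperature(delta_h: float, delta_s: float, temperature: float) -> float:
    """K(T) = exp(-dH/(R T) + dS/R), dH in kJ/mol, dS in J/mol/K."""
    return float(
        np.exp(-delta_h * 1000.0 / (GAS_CONSTANT * temperature) + delta_s / GAS_CONSTANT)
    )


def generate_vant_hoff_set(
    delta_h: float,
    delta_s: float,
    temps: list[float],
    truth: GroundTruth | None = None,
    conc_grid: np.ndarray | None = None,
    f0: float = 1000.0,
) -> list[tuple[TitrationSeries, float]]:
    """One titration per temperature with Kb following the van't Hoff law.

    ``delta_h`` in kJ/mol, ``delta_s`` in J/mol/K; per-temperature seeds are
    derived from ``truth.seed`` so replicates differ but remain
    deterministic.
    """
    if len(set(temps)) != len(temps):
        raise InputDomainError("temperatures must be distinct")
    base = truth if truth is not None else GroundTruth()
    out = []
    for i, t in enumerate(temps):
        k_t = kb_at_temperature(delta_h, delta_s, t)
        truth_t = replace(base, mechanism="static", kb=k_t, seed=base.seed + i)
        series, _ = generate_titration(
            truth_t, conc_grid=conc_grid, f0=f0, temperature=t, label=f"sim@{t:g}K"
        )
        out.append((series, k_t))
    return out


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def _gaussian(x: np.ndarray, center: float, width: float, amplitude: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((x - center) / width) ** 2)


def generate_emission_pair(
    peak_nm: float = 340.0,
    width_nm: float = 25.0,
    amplitude: float = 1000.0,
    shift_nm: float = 8.0,
    damping: float = 0.81,
    grid: tuple[float, float] = (300.0, 500.0),
) -> tuple[EmissionSpectrum, EmissionSpectrum]:
    """Free/bound Gaussian emission bands on a 1-nm grid.

    The bound spectrum is shifted by ``shift_nm`` (positive = redshift) and
    scaled by ``damping`` (0.81 emulates a 19% intensity loss on binding).
    """
    if width_nm <= 0:
        raise InputDomainError("width must be positive")
    wl = np.arange(grid[0], grid[1] + 1.0)
    free = EmissionSpectrum(280.0, wl, _gaussian(wl, peak_nm, width_nm, amplitude))
    bound = EmissionSpectrum(
        280.0, wl, _gaussian(wl, peak_nm + shift_nm, width_nm, amplitude * damping)
    )
    return free, bound


def generate_eem(
    peaks: tuple[tuple[float, float, float], ...] = ((280.0, 340.0, 1000.0), (230.0, 330.0, 600.0)),
    width_nm: float = 12.0,
    ridge_amplitude: float = 300.0,
    ex_range: tuple[float, float] = (200.0, 350.0),
    em_range: tuple[float, float] = (200.0, 500.0),
    step: float = 5.0,
) -> EEM:
    """Synthetic EEM: Gaussian peaks plus Rayleigh and second-order ridges.

    Each peak is (lambda_ex, lambda_em, amplitude); the default pair mimics
    a protein's fluorophore peak (Peak I) and backbone peak (Peak II).
    """
    ex = np.arange(ex_range[0], ex_range[1] + step, step)
    em = np.arange(em_range[0], em_range[1] + step, step)
    z = np.zeros((ex.size, em.size))
    for cx, cm, amp in peaks:
        z += np.outer(
            _gaussian(ex, cx, width_nm, 1.0), _gaussian(em, cm, width_nm, amp)
        )
    exg = ex[:, None]
    emg = em[None, :]
    for order in (1, 2):
        z += ridge_amplitude * np.exp(-0.5 * ((emg - order * exg) / (step / 2.0)) ** 2)
    return EEM(excitation_grid=ex, emission_grid=em, intensity_matrix=z)


def generate_eem_pair(damping: float = 0.7, **kwargs) -> tuple[EEM, EEM]:
    """Free/bound EEM pair; bound fluorophore peaks are damped, ridges kept."""
    free = generate_eem(**kwargs)
    peaks = kwargs.pop("peaks", ((280.0, 340.0, 1000.0), (230.0, 330.0, 600.0)))
    damped = [(cx, cm, amp * damping) for cx, cm, amp in peaks]
    bound = generate_eem(peaks=damped, **kwargs)
    return free, bound
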