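"""van't Hoff analysis, Gibbs energy, and interaction-force typing.

Binding constants measured at several temperatures are fitted to the linear
van't Hoff relation

    ln Kb = -dH / (R T) + dS / R

giving the binding enthalpy dH (kJ/mol, from the slope) and entropy dS
(J/mol/K, from the intercept); the Gibbs energy at any temperature follows
from dG = dH - T dS.  The signs of dH and dS type the dominant interaction
(Ross's rules): both negative points to van der Waals contacts and hydrogen
bonding, both positive to hydrophobic burial, negative enthalpy with
positive entropy to electrostatics.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError

__all__ = [
    "GAS_CONSTANT",
    "ThermoResult",
    "vant_hoff_fit",
    "gibbs",
    "classify_forces",
]

#: Universal gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314


@dataclass(frozen=True)
class ThermoResult:
    """van't Hoff fit with derived Gibbs energies and force typing."""

    delta_h: float                    # kJ/mol
    delta_s: float                    # J/mol/K
    delta_g: dict[float, float]       # K -> kJ/mol
    r: float                          # Pearson correlation of ln Kb vs 1/T
    force_label: str
    driving: str                      # enthalpy-driven | entropy-driven | both
    spontaneity: str                  # spontaneous | non-spontaneous
    temperatures: tuple[float, ...] = ()   # K, those used in the fit


def gibbs(delta_h: float, delta_s: float, t: float) -> float:
    """Gibbs free energy dG = dH - T dS, in kJ/mol.

    ``delta_h`` in kJ/mol, ``delta_s`` in J/mol/K; the factor 1000 reconciles
    the unit mix exactly once, here.
    """
    if t <= 0:
        raise ValueError("temperature must be positive (K)")
    return delta_h - t * delta_s / 1000.0


def classify_forces(
    delta_h: float, delta_s: float, t_ref: float = 298.0
) -> tuple[str, str, str]:
    """Type the dominant interaction force from the signs of dH and dS.

    Returns ``(force_label, driving, spontaneity)``; driving and
    spontaneity are judged at ``t_ref``.
    """
    if delta_h < 0 and delta_s < 0:
        force = "van der Waals + hydrogen bonding"
    elif delta_h > 0 and delta_s > 0:
        force = "hydrophobic"
    elif delta_h < 0 and delta_s > 0:
        force = "electrostatic"
    else:
        force = "unfavorable/other"

    if delta_h < 0 and t_ref * delta_s < 0:
        driving = "enthalpy-driven"
    elif delta_h >= 0 and delta_s > 0:
        driving = "entropy-driven"
    else:
        driving = "both"

    dg = gibbs(delta_h, delta_s, t_ref)
    spontaneity = "spontaneous" if dg < 0 else "non-spontaneous"
    return force, driving, spontaneity


def vant_hoff_fit(
    kb_values: Sequence[tuple[float, float]] | Mapping[float, float],
    eval_temps: Sequence[float] = (),
) -> ThermoResult:
    """Fit ln Kb against 1/T and evaluate dG at the requested temperatures.

    Parameters
    ----------
    kb_values
        ``(temperature K, Kb M^-1)`` pairs or a {T: Kb} mapping; at least
        two distinct temperatures with positive Kb.
    eval_temps
        Temperatures (K) at which to evaluate dG; defaults to the fitted
        temperatures when empty.

    Notes
    -----
    Duplicate temperatures with differing Kb do not abort the fit but a
    warning is emitted, since the line is then fit through replicate
    abscissae.
    """
    if isinstance(kb_values, Mapping):
        pairs = sorted(kb_values.items())
    else:
        pairs = sorted((float(t), float(k)) for t, k in kb_values)
    temps = np.array([t for t, _ in pairs], dtype=float)
    kbs = np.array([k for _, k in pairs], dtype=float)
    if np.any(kbs <= 0):
        raise ValueError("all Kb must be positive")
    if np.unique(temps).size < 2:
        raise InsufficientDataError("van't Hoff fit needs >= 2 distinct temperatures")
    if np.unique(temps).size < temps.size:
        _warnings.warn(
            "duplicate temperatures in van't Hoff input; fitting through replicates",
            stacklevel=2,
        )

    fit = stats.linregress(1.0 / temps, np.log(kbs))
    delta_h = -float(fit.slope) * GAS_CONSTANT / 1000.0   # kJ/mol
    delta_s = float(fit.intercept) * GAS_CONSTANT         # J/mol/K
    eval_at = tuple(eval_temps) if len(tuple(eval_temps)) else tuple(temps.tolist())
    delta_g = {float(t): gibbs(delta_h, delta_s, float(t)) for t in eval_at}
    force, driving, spontaneity = classify_forces(delta_h, delta_s)
    return ThermoResult(
        delta_h=delta_h,
        delta_s=delta_s,
        delta_g=delta_g,
        r=0.0 if np.isnan(fit.rvalue) else float(np.clip(fit.rvalue, -1.0, 1.0)),
        force_label=force,
        driving=driving,
        spontaneity=spontaneity,
        temperatures=tuple(temps.tolist()),
    )
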