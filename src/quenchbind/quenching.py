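"""Stern-Volmer quenching analysis and mechanism classification.

The Stern-Volmer relation for collisional or apparent quenching is

    F0 / F = 1 + Ksv [Q] = 1 + kq * tau0 * [Q]

with Ksv the Stern-Volmer constant (M^-1), kq the bimolecular quenching
constant (M^-1 s^-1) and tau0 the unquenched fluorophore lifetime, taken as
1e-8 s for biopolymers by default.  Two diagnostics separate static
(ground-state complex) from dynamic (collisional) quenching:

* temperature trend — Ksv falling as temperature rises points to static
  quenching (complex stability drops with T), rising Ksv to dynamic
  (faster diffusion);
* magnitude — kq above the diffusion-controlled ceiling of ~2e10 M^-1 s^-1
  cannot be collisional, so it indicates static quenching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError
from .titration import TitrationSeries

__all__ = [
    "DEFAULT_TAU0",
    "DEFAULT_KQ_THRESHOLD",
    "QuenchingResult",
    "MechanismCall",
    "stern_volmer_fit",
    "classify_mechanism",
    "quenching_percentage",
]

#: Unquenched fluorophore lifetime for biopolymers (s).
DEFAULT_TAU0 = 1e-8
#: Diffusion-controlled ceiling for collisional quenching (M^-1 s^-1).
DEFAULT_KQ_THRESHOLD = 2e10


@dataclass(frozen=True)
class QuenchingResult:
    """Stern-Volmer fit for one titration at one temperature."""

    ksv: float          # M^-1, slope of F0/F vs [Q]
    ksv_sd: float       # M^-1, standard error of the slope
    intercept: float    # dimensionless, fitted (not forced to 1)
    r: float            # Pearson correlation of the fit
    kq: float           # M^-1 s^-1, ksv / tau0
    tau0: float         # s
    temperature: float  # K
    label: str = ""
    n_points: int = 0
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.tau0 <= 0:
            raise ValueError("tau0 must be positive")
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("Pearson r out of [-1, 1]")


@dataclass(frozen=True)
class MechanismCall:
    """Static/dynamic/ambiguous verdict with per-criterion evidence."""

    label: str                               # static | dynamic | ambiguous
    evidence: tuple[tuple[str, str], ...]    # (criterion, outcome) pairs


def stern_volmer_fit(series: TitrationSeries, tau0: float = DEFAULT_TAU0) -> QuenchingResult:
    """Fit F0/F against [Q] (mol/L) by ordinary least squares.

    The intercept is fitted, not constrained to the theoretical value 1;
    a deviation beyond three standard errors is surfaced as a warning, as
    are any fluorescence-enhancement points (F >= F0), which are retained.

    Raises
    ------
    InsufficientDataError
        If fewer than three points with [Q] > 0 are available.
    """
    if tau0 <= 0:
        raise ValueError("tau0 must be positive")
    q = series.ligand_conc_molar
    f = series.intensity
    f0 = series.f0
    mask = q > 0
    if int(mask.sum()) < 3:
        raise InsufficientDataError(
            f"Stern-Volmer fit needs >= 3 points with [Q] > 0, got {int(mask.sum())}"
        )
    warnings: list[str] = []
    n_enhanced = int(np.sum(f[mask] >= f0))
    if n_enhanced:
        warnings.append(
            f"{n_enhanced} point(s) show F >= F0 (fluorescence enhancement); retained in fit"
        )
    fit = stats.linregress(q[mask], f0 / f[mask])
    r = float(np.clip(fit.rvalue, -1.0, 1.0))
    if np.isnan(fit.rvalue):  # constant F0/F: no correlation definable
        r = 0.0
        warnings.append("constant F0/F ratio; correlation undefined, reported as 0")
    if fit.intercept_stderr > 0 and abs(fit.intercept - 1.0) > 3 * fit.intercept_stderr:
        warnings.append(
            f"intercept {fit.intercept:.4g} deviates from 1 by more than 3 standard errors"
        )
    ksv = float(fit.slope)
    return QuenchingResult(
        ksv=ksv,
        ksv_sd=float(fit.stderr),
        intercept=float(fit.intercept),
        r=r,
        kq=ksv / tau0,
        tau0=tau0,
        temperature=series.temperature,
        label=series.label,
        n_points=int(mask.sum()),
        warnings=tuple(warnings),
    )


def classify_mechanism(
    results: Sequence[QuenchingResult],
    kq_threshold: float = DEFAULT_KQ_THRESHOLD,
) -> MechanismCall:
    """Vote on static vs dynamic quenching from one or more temperatures.

    Criterion A (needs >= 2 temperatures): Ksv strictly decreasing with
    temperature votes static; strictly increasing votes dynamic.
    Criterion B: every kq above ``kq_threshold`` votes static; every kq at
    or below it votes dynamic.  Agreement (or a single applicable
    criterion) decides the label; a conflict yields ``ambiguous`` with both
    outcomes recorded.
    """
    if not results:
        raise InsufficientDataError("mechanism classification needs at least one fit")
    results = sorted(results, key=lambda r: r.temperature)
    evidence: list[tuple[str, str]] = []
    votes: list[str] = []

    if len(results) >= 2:
        ksv = [r.ksv for r in results]
        if all(b < a for a, b in zip(ksv, ksv[1:])):
            votes.append("static")
            evidence.append(("Ksv temperature trend", "strictly decreasing -> static"))
        elif all(b > a for a, b in zip(ksv, ksv[1:])):
            votes.append("dynamic")
            evidence.append(("Ksv temperature trend", "strictly increasing -> dynamic"))
        else:
            evidence.append(("Ksv temperature trend", "non-monotonic -> no vote"))
    else:
        evidence.append(("Ksv temperature trend", "single temperature -> not applicable"))

    kq = [r.kq for r in results]
    if all(v > kq_threshold for v in kq):
        votes.append("static")
        evidence.append(
            ("kq magnitude", f"all kq > {kq_threshold:.3g} M^-1 s^-1 -> static")
        )
    elif all(v <= kq_threshold for v in kq):
        votes.append("dynamic")
        evidence.append(
            ("kq magnitude", f"all kq <= {kq_threshold:.3g} M^-1 s^-1 -> dynamic")
        )
    else:
        evidence.append(("kq magnitude", "kq straddles threshold -> no vote"))

    distinct = set(votes)
    if len(distinct) == 1:
        label = distinct.pop()
    else:
        label = "ambiguous"
    return MechanismCall(label=label, evidence=tuple(evidence))


def quenching_percentage(series: TitrationSeries) -> float:
    """Percent drop in intensity at the highest quencher concentration.

    100 * (F0 - F_last) / F0 — e.g. 19% for a series quenched from 100 to 81.
    """
    f = series.intensity
    return float(100.0 * (f[0] - f[-1]) / f[0])
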