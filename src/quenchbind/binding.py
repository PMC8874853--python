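"""Double-logarithmic estimation of binding constant and stoichiometry.

For static quenching through formation of a protein-ligand complex with
effective constant Kb and stoichiometry n, the bound/free intensity ratio
obeys

    log10((F0 - F) / F) = log10(Kb) + n * log10([Q])

so an ordinary least-squares line through the double-log plot yields Kb from
the intercept (Kb = 10^intercept, in M^-n when [Q] is in mol/L) and n from
the slope.  Points with F >= F0 leave the transform undefined; they are
excluded and counted, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError
from .titration import TitrationSeries

__all__ = ["BindingResult", "double_log_fit"]

LN10 = np.log(10.0)


@dataclass(frozen=True)
class BindingResult:
    """Double-log fit of one titration."""

    kb: float           # M^-n, 10^intercept
    n: float            # stoichiometry, slope
    kb_sd: float        # delta-method: kb * ln(10) * SE(intercept)
    n_sd: float         # standard error of the slope
    r: float            # Pearson correlation
    temperature: float  # K
    label: str = ""
    n_points: int = 0
    n_excluded: int = 0  # points with F >= F0 removed before the transform

    def __post_init__(self) -> None:
        if self.kb <= 0:
            raise ValueError("kb must be positive")
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("Pearson r out of [-1, 1]")


def double_log_fit(series: TitrationSeries) -> BindingResult:
    """OLS of log10((F0-F)/F) on log10([Q] in mol/L).

    Raises
    ------
    InsufficientDataError
        If fewer than three points with [Q] > 0 and F < F0 survive.
    """
    q = series.ligand_conc_molar
    f = series.intensity
    f0 = series.f0
    candidate = q > 0
    usable = candidate & (f < f0)
    n_excluded = int(candidate.sum() - usable.sum())
    if int(usable.sum()) < 3:
        raise InsufficientDataError(
            f"double-log fit needs >= 3 points with [Q] > 0 and F < F0, "
            f"got {int(usable.sum())} ({n_excluded} excluded)"
        )
    x = np.log10(q[usable])
    y = np.log10((f0 - f[usable]) / f[usable])
    fit = stats.linregress(x, y)
    kb = float(10.0 ** fit.intercept)
    return BindingResult(
        kb=kb,
        n=float(fit.slope),
        kb_sd=kb * LN10 * float(fit.intercept_stderr),
        n_sd=float(fit.stderr),
        r=0.0 if np.isnan(fit.rvalue) else float(np.clip(fit.rvalue, -1.0, 1.0)),
        temperature=series.temperature,
        label=series.label,
        n_points=int(usable.sum()),
        n_excluded=n_excluded,
    )
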