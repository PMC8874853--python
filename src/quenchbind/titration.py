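"""Titration domain types, inner-filter correction, and CSV readers/writers.

A fluorescence titration holds a protein at a fixed concentration while a
quencher (the ligand) is stepped up from zero; the emission-peak intensity
recorded at each step is the raw material for Stern-Volmer and double-log
binding analysis.  Concentrations are stored in the reporting unit (uM) and
converted to mol/L exactly once, at fit time, through
:attr:`TitrationSeries.ligand_conc_molar` so fitted constants carry M^-1.

When the absorbance of the sample at the excitation and emission wavelengths
is non-negligible, part of the exciting and emitted light is reabsorbed (the
inner filter effect).  The multiplicative correction

    F_cor = F_obs * exp((A_ex + A_em) / 2)

restores the intensity that would have been observed in a transparent
sample.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InputDomainError

__all__ = [
    "MICROMOLAR_TO_MOLAR",
    "TitrationSeries",
    "EmissionSpectrum",
    "EEM",
    "correct_inner_filter",
    "read_titration_csv",
    "write_titration_csv",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_eem_csv",
    "write_eem_csv",
    "write_report",
    "read_report",
]

#: uM -> mol/L.  Applied exactly once, inside ``ligand_conc_molar``.
MICROMOLAR_TO_MOLAR = 1e-6

REPORT_SECTIONS = (
    "quenching",
    "binding",
    "thermodynamics",
    "competition",
    "spectral_features",
)


def correct_inner_filter(f_obs, a_ex, a_em):
    """Correct fluorescence for the inner filter effect.

    Parameters
    ----------
    f_obs : float or array
        Observed intensity (arbitrary units), strictly positive.
    a_ex, a_em : float or array
        Absorbance at the excitation and emission wavelengths
        (dimensionless, >= 0).

    Returns
    -------
    float or ndarray
        ``f_obs * exp((a_ex + a_em) / 2)``; always >= ``f_obs``.
    """
    f_obs = np.asarray(f_obs, dtype=float)
    a_ex = np.asarray(a_ex, dtype=float)
    a_em = np.asarray(a_em, dtype=float)
    if np.any(f_obs <= 0):
        raise InputDomainError("observed intensity must be strictly positive")
    if np.any(a_ex < 0) or np.any(a_em < 0):
        raise InputDomainError("absorbances must be non-negative")
    out = f_obs * np.exp((a_ex + a_em) / 2.0)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class TitrationSeries:
    """One protein + ligand titration at a single temperature.

    ``ligand_conc`` is the quencher concentration [Q] in uM, strictly
    increasing with the mandatory [Q] = 0 point first; the intensity at that
    point defines F0.  ``intensity_obs`` is the as-measured intensity; when
    per-point absorbances are present, ``intensity`` is the inner-filter
    corrected series, otherwise the two coincide and ``ife_applied`` is
    False.
    """

    label: str
    ligand_conc: np.ndarray          # uM, first entry 0
    intensity_obs: np.ndarray        # arbitrary units
    temperature: float               # K
    protein_conc: float | None = None   # uM
    a_ex: np.ndarray | None = None
    a_em: np.ndarray | None = None
    competitor: tuple[str, float] | None = None  # (name, conc uM)

    def __post_init__(self) -> None:
        conc = np.asarray(self.ligand_conc, dtype=float)
        inten = np.asarray(self.intensity_obs, dtype=float)
        object.__setattr__(self, "ligand_conc", conc)
        object.__setattr__(self, "intensity_obs", inten)
        if conc.ndim != 1 or conc.size < 2:
            raise InputDomainError("need at least two titration points")
        if conc.size != inten.size:
            raise InputDomainError("concentration and intensity lengths differ")
        if conc[0] != 0.0:
            raise InputDomainError("first point must be [Q] = 0 (defines F0)")
        if np.any(np.diff(conc) <= 0):
            raise InputDomainError("ligand concentrations must be strictly increasing")
        if np.any(conc < 0):
            raise InputDomainError("ligand concentrations must be non-negative")
        if np.any(inten <= 0):
            raise InputDomainError("intensities must be strictly positive")
        if self.temperature <= 0:
            raise InputDomainError("temperature must be positive (K)")
        for name in ("a_ex", "a_em"):
            a = getattr(self, name)
            if a is not None:
                a = np.asarray(a, dtype=float)
                object.__setattr__(self, name, a)
                if a.size != conc.size:
                    raise InputDomainError(f"{name} length differs from titration length")
                if np.any(a < 0):
                    raise InputDomainError(f"{name} must be non-negative")
        if (self.a_ex is None) != (self.a_em is None):
            raise InputDomainError("a_ex and a_em must be supplied together")

    # -- derived views -------------------------------------------------

    @property
    def ife_applied(self) -> bool:
        """Whether per-point inner-filter correction is in effect."""
        return self.a_ex is not None

    @property
    def intensity(self) -> np.ndarray:
        """Inner-filter corrected intensities (== observed when no absorbances)."""
        if self.a_ex is None:
            return self.intensity_obs
        return correct_inner_filter(self.intensity_obs, self.a_ex, self.a_em)

    @property
    def f0(self) -> float:
        """Unquenched intensity F0, taken at the mandatory [Q] = 0 point."""
        return float(self.intensity[0])

    @property
    def ligand_conc_molar(self) -> np.ndarray:
        """[Q] in mol/L — the single authorized uM -> M conversion point."""
        return self.ligand_conc * MICROMOLAR_TO_MOLAR

    def n_points(self) -> int:
        return int(self.ligand_conc.size)


@dataclass(frozen=True)
class EmissionSpectrum:
    """Emission scan at one excitation wavelength."""

    excitation_wavelength: float     # nm
    wavelengths: np.ndarray          # nm, strictly increasing
    intensities: np.ndarray          # arbitrary units

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)
        if wl.size != it.size:
            raise InputDomainError("wavelength and intensity lengths differ")
        if wl.size >= 2 and np.any(np.diff(wl) <= 0):
            raise InputDomainError("wavelengths must be strictly increasing")


@dataclass(frozen=True)
class EEM:
    """Excitation-emission matrix; rows are excitation wavelengths."""

    excitation_grid: np.ndarray      # nm
    emission_grid: np.ndarray        # nm
    intensity_matrix: np.ndarray     # shape (n_ex, n_em)

    def __post_init__(self) -> None:
        ex = np.asarray(self.excitation_grid, dtype=float)
        em = np.asarray(self.emission_grid, dtype=float)
        z = np.asarray(self.intensity_matrix, dtype=float)
        object.__setattr__(self, "excitation_grid", ex)
        object.__setattr__(self, "emission_grid", em)
        object.__setattr__(self, "intensity_matrix", z)
        if np.any(np.diff(ex) <= 0) or np.any(np.diff(em) <= 0):
            raise InputDomainError("EEM grids must be strictly increasing")
        if z.shape != (ex.size, em.size):
            raise InputDomainError(
                f"intensity matrix shape {z.shape} does not match grids "
                f"({ex.size}, {em.size})"
            )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_TITRATION_REQUIRED = ("conc_uM", "F_obs")
_TITRATION_OPTIONAL = ("A_ex", "A_em")


def read_titration_csv(
    path: str | Path,
    *,
    temperature: float,
    label: str | None = None,
    protein_conc: float | None = None,
    competitor: tuple[str, float] | None = None,
) -> TitrationSeries:
    """Read a titration table (``conc_uM,F_obs[,A_ex,A_em]``).

    Comment lines start with ``#``.  Rows are sorted by concentration;
    duplicate concentrations and non-numeric cells raise :class:`FormatError`
    naming the offending row.  Absorbance columns, when present, switch on
    per-point inner-filter correction in the returned series.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in _TITRATION_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    has_abs = all(c in df.columns for c in _TITRATION_OPTIONAL)
    if any(c in df.columns for c in _TITRATION_OPTIONAL) and not has_abs:
        raise FormatError(f"{path}: A_ex and A_em must both be present or both absent")

    cols = list(_TITRATION_REQUIRED) + (list(_TITRATION_OPTIONAL) if has_abs else [])
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(np.argmax(coerced.isna().to_numpy())) + 2  # 1-based, after header
            raise FormatError(f"{path}: non-numeric or empty cell in column {col!r} at line {row}")
        df[col] = coerced

    df = df.sort_values("conc_uM", kind="mergesort").reset_index(drop=True)
    dup = df["conc_uM"].duplicated()
    if dup.any():
        row = int(np.argmax(dup.to_numpy())) + 2
        raise FormatError(
            f"{path}: duplicate concentration {df['conc_uM'][dup].iloc[0]} uM (row {row} after sorting)"
        )
    return TitrationSeries(
        label=label if label is not None else path.stem,
        ligand_conc=df["conc_uM"].to_numpy(),
        intensity_obs=df["F_obs"].to_numpy(),
        temperature=float(temperature),
        protein_conc=protein_conc,
        a_ex=df["A_ex"].to_numpy() if has_abs else None,
        a_em=df["A_em"].to_numpy() if has_abs else None,
        competitor=competitor,
    )


def write_titration_csv(series: TitrationSeries, path: str | Path) -> None:
    """Write a series back to the ``conc_uM,F_obs[,A_ex,A_em]`` layout."""
    data = {"conc_uM": series.ligand_conc, "F_obs": series.intensity_obs}
    if series.a_ex is not None:
        data["A_ex"] = series.a_ex
        data["A_em"] = series.a_em
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def read_spectrum_csv(path: str | Path, *, excitation_wavelength: float = float("nan")) -> EmissionSpectrum:
    """Read a ``wavelength_nm,intensity`` emission spectrum."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    for col in ("wavelength_nm", "intensity"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
        df[col] = pd.to_numeric(df[col], errors="raise")
    df = df.sort_values("wavelength_nm").reset_index(drop=True)
    return EmissionSpectrum(
        excitation_wavelength=excitation_wavelength,
        wavelengths=df["wavelength_nm"].to_numpy(),
        intensities=df["intensity"].to_numpy(),
    )


def write_spectrum_csv(spectrum: EmissionSpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "intensity": spectrum.intensities}
    ).to_csv(path, index=False, float_format="%.12g")


def read_eem_csv(path: str | Path) -> EEM:
    """Read an EEM table: first row = emission grid, first column = excitation grid."""
    path = Path(path)
    raw = pd.read_csv(path, comment="#", header=None).to_numpy(dtype=float)
    if raw.shape[0] < 2 or raw.shape[1] < 2:
        raise FormatError(f"{path}: EEM needs at least one excitation and one emission value")
    return EEM(
        excitation_grid=raw[1:, 0],
        emission_grid=raw[0, 1:],
        intensity_matrix=raw[1:, 1:],
    )


def write_eem_csv(eem: EEM, path: str | Path) -> None:
    n_ex, n_em = eem.intensity_matrix.shape
    out = np.empty((n_ex + 1, n_em + 1))
    out[0, 0] = np.nan
    out[0, 1:] = eem.emission_grid
    out[1:, 0] = eem.excitation_grid
    out[1:, 1:] = eem.intensity_matrix
    pd.DataFrame(out).to_csv(path, index=False, header=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Report serialization
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = {"_type": type(obj).__name__}
        for f in dataclasses.fields(obj):
            d[f.name] = _jsonable(getattr(obj, f.name))
        return d
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(results: Mapping[str, Sequence | Mapping | None], path: str | Path,
                 provenance: Mapping[str, object] | None = None) -> dict:
    """Serialize analysis results to a JSON report.

    ``results`` maps section names (a subset of ``quenching``, ``binding``,
    ``thermodynamics``, ``competition``, ``spectral_features``) to result
    dataclasses or lists thereof.  Missing sections are written as empty
    lists so the schema is stable.  Returns the document written.
    """
    unknown = set(results) - set(REPORT_SECTIONS)
    if unknown:
        raise InputDomainError(f"unknown report section(s): {sorted(unknown)}")
    doc: dict = {"provenance": _jsonable(dict(provenance or {}))}
    for section in REPORT_SECTIONS:
        value = results.get(section)
        if value is None:
            doc[section] = []
        elif isinstance(value, (list, tuple)):
            doc[section] = [_jsonable(v) for v in value]
        else:
            doc[section] = [_jsonable(value)]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return doc


def read_report(path: str | Path) -> dict:
    """Read back a JSON report written by :func:`write_report`."""
    with open(path) as fh:
        return json.load(fh)
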