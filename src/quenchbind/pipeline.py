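"""End-to-end orchestration: titrations in, full analysis report out.

``run_full_analysis`` composes the per-module operations — Stern-Volmer
fits and mechanism classification across temperatures, double-log binding
fits, van't Hoff thermodynamics when two or more temperatures are present,
binary-vs-ternary comparison when a competitor series is supplied, and
site-marker inference when marker series are supplied.  Any stage failure
is recorded with its stage name; partial results are still emitted.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .binding import BindingResult, double_log_fit
from .competition import (
    DEFAULT_SITE_THRESHOLD,
    compare_systems,
    site_marker_inference,
)
from .errors import QuenchBindError
from .quenching import (
    DEFAULT_KQ_THRESHOLD,
    DEFAULT_TAU0,
    classify_mechanism,
    quenching_percentage,
    stern_volmer_fit,
)
from .thermodynamics import vant_hoff_fit
from .titration import TitrationSeries, _jsonable

__all__ = ["AnalysisConfig", "run_full_analysis", "format_report_json", "summary_table"]

#: Default site map for the classical serum-albumin markers.
DEFAULT_MARKER_SITES = {"phenylbutazone": "Site I", "ibuprofen": "Site II"}


@dataclass(frozen=True)
class AnalysisConfig:
    tau0: float = DEFAULT_TAU0                    # s
    kq_threshold: float = DEFAULT_KQ_THRESHOLD    # M^-1 s^-1
    marker_site_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_SITES)
    )
    eval_temps: tuple[float, ...] = ()            # K; empty -> fitted temps
    site_threshold: float = DEFAULT_SITE_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau0 <= 0 or self.kq_threshold <= 0 or self.site_threshold <= 0:
            raise QuenchBindError("thresholds must be positive")
        if len(set(self.eval_temps)) != len(self.eval_temps):
            raise QuenchBindError("eval_temps must be distinct")


def run_full_analysis(
    config: AnalysisConfig,
    binary_series: Sequence[TitrationSeries],
    ternary_series: Sequence[TitrationSeries] = (),
    marker_series: Mapping[str, TitrationSeries] | None = None,
) -> dict:
    """Run the whole analysis and return a plain-dict report.

    ``binary_series`` are probe-only titrations, typically one per
    temperature; ``ternary_series`` add a competitor; ``marker_series``
    maps site-marker name to its titration.
    """
    if not binary_series:
        raise QuenchBindError("at least one binary titration is required")
    errors: list[dict] = []
    report: dict = {
        "quenching": [],
        "binding": [],
        "thermodynamics": [],
        "competition": [],
        "spectral_features": [],
        "site_assignment": [],
        "warnings": [],
        "errors": errors,
    }

    def _try(stage: str, label: str, fn):
        try:
            return fn()
        except QuenchBindError as exc:
            errors.append({"stage": stage, "input": label, "error": str(exc)})
            return None

    binary_series = sorted(binary_series, key=lambda s: (s.temperature, s.label))
    sv_results = []
    bind_results = []
    for s in binary_series:
        sv = _try("stern_volmer", s.label, lambda s=s: stern_volmer_fit(s, config.tau0))
        if sv is not None:
            sv_results.append(sv)
            report["quenching"].append(
                {**dataclasses.asdict(sv), "quench_pct": quenching_percentage(s)}
            )
        b = _try("double_log", s.label, lambda s=s: double_log_fit(s))
        if b is not None:
            bind_results.append(b)
            report["binding"].append(dataclasses.asdict(b))

    if sv_results:
        mech = _try(
            "mechanism", "all temperatures",
            lambda: classify_mechanism(sv_results, config.kq_threshold),
        )
        if mech is not None:
            report["mechanism"] = dataclasses.asdict(mech)

    temps = {b.temperature for b in bind_results}
    if len(temps) >= 2:
        thermo = _try(
            "vant_hoff", "binding constants",
            lambda: vant_hoff_fit(
                [(b.temperature, b.kb) for b in bind_results], config.eval_temps
            ),
        )
        if thermo is not None:
            report["thermodynamics"].append(dataclasses.asdict(thermo))
    else:
        report["warnings"].append(
            "thermodynamics skipped: needs binding constants at >= 2 temperatures"
        )

    if ternary_series:
        by_temp = {s.temperature: s for s in binary_series}
        for ts in ternary_series:
            bs = by_temp.get(ts.temperature)
            if bs is None:
                errors.append(
                    {
                        "stage": "competition",
                        "input": ts.label,
                        "error": f"no binary series at {ts.temperature} K",
                    }
                )
                continue
            comp = _try(
                "competition", ts.label,
                lambda bs=bs, ts=ts: compare_systems(
                    (stern_volmer_fit(bs, config.tau0), double_log_fit(bs), bs),
                    (stern_volmer_fit(ts, config.tau0), double_log_fit(ts), ts),
                ),
            )
            if comp is not None:
                report["competition"].append(dataclasses.asdict(comp))

    if marker_series:
        ref_temp = next(iter(marker_series.values())).temperature
        ref = next(
            (b for b in bind_results if b.temperature == ref_temp),
            bind_results[0] if bind_results else None,
        )
        if ref is None:
            errors.append(
                {"stage": "site_marker", "input": "markers",
                 "error": "no binary binding fit available as reference"}
            )
        else:
            kb_by_marker = {}
            for name, ms in marker_series.items():
                mb = _try("site_marker", name, lambda ms=ms: double_log_fit(ms))
                if mb is not None:
                    kb_by_marker[name] = mb.kb
            if kb_by_marker:
                assign = _try(
                    "site_marker", "inference",
                    lambda: site_marker_inference(
                        ref.kb, kb_by_marker, config.marker_site_map,
                        config.site_threshold,
                    ),
                )
                if assign is not None:
                    report["site_assignment"].append(dataclasses.asdict(assign))

    return report


def _round_sig(x: float, sig: int = 6) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def _round_tree(obj, sig: int = 6):
    if isinstance(obj, float):
        return _round_sig(obj, sig)
    if isinstance(obj, dict):
        return {k: _round_tree(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_tree(v, sig) for v in obj]
    return obj


def format_report_json(report: dict) -> str:
    """Deterministic JSON: sorted keys, floats at 6 significant digits."""
    return json.dumps(_round_tree(_jsonable(report)), indent=2, sort_keys=True) + "\n"


def summary_table(report: dict) -> str:
    """Human-readable summary mirroring the usual quenching/binding tables."""
    lines = []
    if report.get("quenching"):
        lines.append("Stern-Volmer quenching")
        lines.append(
            f"{'label':<16}{'T (K)':>8}{'R':>9}{'Ksv (M^-1)':>16}{'+/- SE':>10}"
            f"{'kq x10^12':>12}{'quench %':>10}"
        )
        for q in report["quenching"]:
            lines.append(
                f"{q['label']:<16}{q['temperature']:>8.0f}{q['r']:>9.4f}"
                f"{q['ksv']:>16,.2f}{q['ksv_sd']:>10.0f}{q['kq'] / 1e12:>12.2f}"
                f"{q.get('quench_pct', float('nan')):>10.1f}"
            )
    if report.get("binding"):
        lines.append("")
        lines.append("Double-log binding")
        lines.append(f"{'label':<16}{'T (K)':>8}{'Kb (M^-n)':>14}{'n':>8}{'R':>9}")
        for b in report["binding"]:
            lines.append(
                f"{b['label']:<16}{b['temperature']:>8.0f}{b['kb']:>14.4g}"
                f"{b['n']:>8.2f}{b['r']:>9.4f}"
            )
    for t in report.get("thermodynamics", []):
        lines.append("")
        lines.append("van't Hoff thermodynamics")
        lines.append(
            f"  dH = {t['delta_h']:.2f} kJ/mol, dS = {t['delta_s']:.2f} J/mol/K, "
            f"r = {t['r']:.4f}"
        )
        for temp, dg in sorted(t["delta_g"].items()):
            lines.append(f"  dG({float(temp):.0f} K) = {dg:.2f} kJ/mol")
        lines.append(f"  forces: {t['force_label']}; {t['driving']}; {t['spontaneity']}")
    if report.get("mechanism"):
        m = report["mechanism"]
        lines.append("")
        lines.append(f"Quenching mechanism: {m['label']}")
        for crit, outcome in m["evidence"]:
            lines.append(f"  {crit}: {outcome}")
    for c in report.get("competition", []):
        lines.append("")
        lines.append(
            f"Competition at {c['temperature']:.0f} K: Kb {c['kb_binary']:.4g} -> "
            f"{c['kb_ternary']:.4g} ({c['fold_change']:.4g}-fold); "
            f"quenching {c['quench_pct_binary']:.1f}% -> {c['quench_pct_ternary']:.1f}%"
        )
        lines.append(f"  {c['interpretation']}")
    for s in report.get("site_assignment", []):
        lines.append("")
        lines.append(f"Site assignment: {s['site']}")
        for m, e in sorted(s["marker_effects"].items()):
            lines.append(f"  {m}: relative Kb change {e:.2f}")
    return "\n".join(lines) + "\n"
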