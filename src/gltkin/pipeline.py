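"""End-to-end analysis of an initial-rate grid.

Reproduces the complete kinetic workflow from a rate table:

1. Michaelis-Menten fits to each aspartate-titration row (apparent
   aspartate vmax / K_M per fixed [Na+]);
2. Hill fits to each sodium-titration column (apparent sodium vmax,
   half-saturation and Hill coefficient per fixed [Asp]);
3. hyperbolic fit of the apparent sodium vmax versus [Asp], whose
   half-saturation estimates kcat/k3, and a hyperbolic fit of the
   apparent aspartate vmax versus [Na+], whose plateau estimates the
   maximal turnover rate;
4. log-log slopes of the apparent aspartate K_M versus [Na+] in the low
   and high sodium regimes (model predictions: -1 and 0);
5. derivation of kcat (plateau / 60), kcat/k3 and k3, cross-checking the
   two independent routes to k3 (vmax-saturation half-constant versus
   the high-[Na+] K_M plateau).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import __version__
from .fitting import (
    HIGH_NA_REGIME_MM,
    LOW_NA_REGIME_MM,
    ApparentProfile,
    DerivedConstants,
    FitError,
    FitResult,
    RateTable,
    compare_km_kd,
    derive_rate_constants,
    fit_hill,
    fit_michaelis_menten,
    fit_vmax_saturation,
    loglog_slope,
)

__all__ = [
    "AnalysisOptions", "AnalysisReport", "load_rate_table",
    "run_full_analysis", "export_report", "SYBODY_REFERENCE_FITS",
]

#: published apparent aspartate parameters measured with the right-side-out
#: population inactivated by 750 nM external sybody (two biological
#: replicates); useful as comparison constants for single-orientation data
SYBODY_REFERENCE_FITS = {
    10.0: {"vmax_per_min": 9.8, "vmax_se": 1.0, "km_uM": 4.9, "km_se": 1.4},
    100.0: {"vmax_per_min": 18.3, "vmax_se": 2.0, "km_uM": 0.97, "km_se": 0.36},
    200.0: {"vmax_per_min": 17.0, "vmax_se": 1.0, "km_uM": 0.65, "km_se": 0.13},
    300.0: {"vmax_per_min": 17.2, "vmax_se": 1.5, "km_uM": 0.63, "km_se": 0.17},
}


@dataclass
class AnalysisOptions:
    """Knobs of the grid analysis.

    The 1 mM sodium row is excluded by default: at that concentration
    the uptake signal is close to the assay noise floor and too few
    aspartate points are measurable for a stable saturation fit.
    """

    weighting: str = "none"
    low_regime_mM: Sequence[float] = LOW_NA_REGIME_MM
    high_regime_mM: Sequence[float] = HIGH_NA_REGIME_MM
    exclude_na_mM: Sequence[float] = (1.0,)
    kd_table: Sequence[tuple[float, float]] | None = None
    min_asp_points: int = 3
    min_na_points: int = 4


@dataclass
class AnalysisReport:
    """Serializable results of the full grid analysis."""

    row_fits: ApparentProfile
    column_fits: ApparentProfile
    vmax_na_saturation: FitResult
    vmax_asp_saturation: FitResult
    slopes: dict[str, tuple[float, float]]
    derived: DerivedConstants
    k3_routes: dict[str, float]
    km_kd: list[dict] | None = None
    skipped: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "row_fits": self.row_fits.to_dict(),
            "column_fits": self.column_fits.to_dict(),
            "vmax_na_saturation": self.vmax_na_saturation.to_dict(),
            "vmax_asp_saturation": self.vmax_asp_saturation.to_dict(),
            "slopes": {k: list(v) for k, v in self.slopes.items()},
            "derived": self.derived.to_dict(),
            "k3_routes": dict(self.k3_routes),
            "km_kd": self.km_kd,
            "skipped": dict(self.skipped),
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisReport":
        return cls(
            row_fits=ApparentProfile.from_dict(d["row_fits"]),
            column_fits=ApparentProfile.from_dict(d["column_fits"]),
            vmax_na_saturation=FitResult.from_dict(d["vmax_na_saturation"]),
            vmax_asp_saturation=FitResult.from_dict(d["vmax_asp_saturation"]),
            slopes={k: tuple(v) for k, v in d["slopes"].items()},
            derived=DerivedConstants.from_dict(d["derived"]),
            k3_routes=dict(d["k3_routes"]),
            km_kd=d.get("km_kd"),
            skipped=dict(d.get("skipped", {})),
            provenance=dict(d.get("provenance", {})),
        )

    def to_json(self, **kw) -> str:
        kw.setdefault("sort_keys", True)
        kw.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls.from_dict(json.loads(text))


def load_rate_table(path) -> RateTable:
    """Read and validate a rate-table CSV (malformed rows are reported
    with their line numbers)."""
    return RateTable.from_csv(path)


def run_full_analysis(table: RateTable,
                       options: AnalysisOptions | None = None,
                       ) -> AnalysisReport:
    """Run the complete row/column fitting and constant-derivation workflow.

    Analyses that the grid cannot support (too few points in a row or
    column, empty regimes) are skipped and recorded in
    ``report.skipped`` rather than aborting the whole report.
    """
    opt = options or AnalysisOptions()
    skipped: dict[str, str] = {}

    # -- row-wise aspartate saturation fits --------------------------------
    row_entries = []
    for na in table.na_levels:
        if any(np.isclose(na, x) for x in opt.exclude_na_mM):
            skipped[f"row_{na:g}mM"] = "excluded by options"
            continue
        cells = table.row(na)
        if cells.asp_uM.nunique() < opt.min_asp_points:
            skipped[f"row_{na:g}mM"] = "too few aspartate concentrations"
            continue
        fit = fit_michaelis_menten(cells.asp_uM, cells.rate_per_min,
                                   sems=cells.sem_per_min,
                                   weighting=opt.weighting)
        row_entries.append((float(na), fit))
    if not row_entries:
        raise FitError("no sodium row has enough aspartate points to fit")
    row_fits = ApparentProfile(varied="ASP", entries=row_entries)

    # -- column-wise sodium saturation fits --------------------------------
    col_entries = []
    for asp in table.asp_levels:
        cells = table.column(asp)
        keep = ~cells.na_mM.apply(
            lambda v: any(np.isclose(v, x) for x in opt.exclude_na_mM))
        cells = cells[keep]
        if cells.na_mM.nunique() < opt.min_na_points:
            skipped[f"column_{asp:g}uM"] = "too few sodium concentrations"
            continue
        fit = fit_hill(cells.na_mM, cells.rate_per_min,
                       sems=cells.sem_per_min, weighting=opt.weighting)
        col_entries.append((float(asp), fit))
    if not col_entries:
        raise FitError("no aspartate column has enough sodium points to fit")
    column_fits = ApparentProfile(varied="NA", entries=col_entries)

    # -- saturation of the apparent maximal rates --------------------------
    vmax_na_sat = fit_vmax_saturation(column_fits.fixed_concs,
                                      column_fits.param("vmax"),
                                      sems=column_fits.param_se("vmax"),
                                      weighting=opt.weighting)
    vmax_asp_sat = fit_vmax_saturation(row_fits.fixed_concs,
                                       row_fits.param("vmax"),
                                       sems=row_fits.param_se("vmax"),
                                       weighting=opt.weighting)

    # -- log-log regime slopes ---------------------------------------------
    slopes: dict[str, tuple[float, float]] = {}
    for regime in ("low_na", "high_na"):
        try:
            slopes[regime] = loglog_slope(row_fits, regime,
                                          low=opt.low_regime_mM,
                                          high=opt.high_regime_mM)
        except FitError as exc:
            skipped[f"slope_{regime}"] = str(exc)

    # -- intrinsic constants -----------------------------------------------
    # turnover number from the plateau of the apparent aspartate vmax
    # versus [Na+] (per-transporter min^-1 -> s^-1)
    kcat = vmax_asp_sat.estimates["vmax"] / 60.0
    kcat_se = vmax_asp_sat.standard_errors["vmax"] / 60.0

    # route A: half-saturation of vmax_Na(app) versus [Asp] (uM -> M)
    c_uM = vmax_na_sat.estimates["half_saturation"]
    c_se_uM = vmax_na_sat.standard_errors["half_saturation"]
    derived = derive_rate_constants(
        km_limit=c_uM * 1e-6, kcat=kcat,
        km_limit_se=c_se_uM * 1e-6, kcat_se=kcat_se,
        provenance={"kcat": "vmax_Asp(app) plateau / 60",
                    "kcat_over_k3": "vmax_Na(app) half-saturation"},
    )

    # route B: plateau of the apparent aspartate K_M at high [Na+]
    k3_routes = {"vmax_saturation_per_M_s": derived.k3}
    high_kms = [fit.estimates["km"] for na, fit in row_fits.entries
                if any(np.isclose(na, x) for x in opt.high_regime_mM)]
    if high_kms:
        km_plateau_uM = float(np.mean(high_kms))
        k3_b = kcat / (km_plateau_uM * 1e-6)
        k3_routes["km_plateau_per_M_s"] = k3_b
        k3_routes["km_plateau_uM"] = km_plateau_uM
        k3_routes["relative_disagreement"] = abs(derived.k3 - k3_b) / derived.k3
    else:
        skipped["k3_km_plateau"] = "no rows in the high-[Na+] regime"

    # -- optional K_M / K_D comparison --------------------------------------
    km_kd = None
    if opt.kd_table is not None:
        km_kd = compare_km_kd(row_fits, opt.kd_table)

    return AnalysisReport(
        row_fits=row_fits, column_fits=column_fits,
        vmax_na_saturation=vmax_na_sat, vmax_asp_saturation=vmax_asp_sat,
        slopes=slopes, derived=derived, k3_routes=k3_routes, km_kd=km_kd,
        skipped=skipped,
        provenance={"software": f"gltkin {__version__}",
                    "input": table.metadata.get("source", "<in-memory>"),
                    "weighting": opt.weighting,
                    "n_cells": len(table)},
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _markdown_report(report: AnalysisReport) -> str:
    lines = ["# Transport kinetics analysis", ""]
    lines += ["## Apparent aspartate saturation (per [Na+] row)", "",
              "| [Na+] (mM) | vmax_Asp(app) (min^-1) | K_M_Asp(app) (uM) |",
              "|---|---|---|"]
    for na, fit in report.row_fits.entries:
        lines.append(
            f"| {na:g} | {fit.estimates['vmax']:.1f} "
            f"± {fit.standard_errors['vmax']:.1f} "
            f"| {fit.estimates['km']:.3g} ± {fit.standard_errors['km']:.2g} |")
    lines += ["", "## Apparent sodium saturation (per [Asp] column)", "",
              "| [Asp] (uM) | vmax_Na(app) (min^-1) | K_M_Na(app) (mM) "
              "| n_Hill |", "|---|---|---|---|"]
    for asp, fit in report.column_fits.entries:
        lines.append(
            f"| {asp:g} | {fit.estimates['vmax']:.1f} "
            f"± {fit.standard_errors['vmax']:.1f} "
            f"| {fit.estimates['k']:.3g} ± {fit.standard_errors['k']:.2g} "
            f"| {fit.estimates['n']:.2f} ± {fit.standard_errors['n']:.2f} |")
    d = report.derived
    lines += ["", "## Derived constants", "",
              f"- kcat = {d.kcat:.3g} ± {d.kcat_se:.2g} s^-1",
              f"- kcat/k3 = {d.kcat_over_k3 * 1e6:.3g} "
              f"± {d.kcat_over_k3_se * 1e6:.2g} uM",
              f"- k3 = {d.k3:.3g} ± {d.k3_se:.2g} M^-1 s^-1"]
    if report.slopes:
        lines += ["", "## log-log K_M slopes"]
        for regime, (s, se) in sorted(report.slopes.items()):
            lines.append(f"- {regime}: {s:.2f} ± {se:.2f}")
    if "relative_disagreement" in report.k3_routes:
        lines += ["", f"- k3 route agreement: "
                  f"{report.k3_routes['relative_disagreement'] * 100:.1f}% "
                  f"difference between the vmax-saturation and K_M-plateau "
                  f"estimates"]
    if report.km_kd:
        lines += ["", "## K_M versus K_D", "",
                  "| [Na+] (mM) | K_M | K_D | ratio | class |",
                  "|---|---|---|---|---|"]
        for row in report.km_kd:
            lines.append(f"| {row['na_mM']:g} | {row['km']:.3g} "
                         f"| {row['kd']:.3g} | {row['ratio']:.2f} "
                         f"| {row['class']} |")
    if report.skipped:
        lines += ["", "## Skipped analyses", ""]
        for key, why in sorted(report.skipped.items()):
            lines.append(f"- {key}: {why}")
    return "\n".join(lines) + "\n"


def export_report(report: AnalysisReport, path, format: str = "json") -> None:
    """Write a report to disk as machine-readable JSON or markdown tables."""
    if format == "json":
        text = report.to_json()
    elif format == "markdown":
        text = _markdown_report(report)
    else:
        raise ValueError(f"unknown report format {format!r}")
    with open(path, "w") as fh:
        fh.write(text)
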