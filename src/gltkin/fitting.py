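"""Saturation-model fitting of initial-rate data and derived rate constants.

Implements the analysis applied to proteoliposome uptake measurements on
a [Na+] x [Asp] concentration grid:

* row-wise Michaelis-Menten fits (aspartate varied at fixed [Na+]) give
  the apparent vmax and K_M for aspartate;
* column-wise Hill fits (sodium varied at fixed [Asp]) give the apparent
  sodium vmax, half-saturation and Hill coefficient;
* the apparent sodium vmax values follow a rectangular hyperbola in
  [Asp] whose half-saturation constant equals kcat/k3 (kcat = turnover
  number, k3 = aspartate on-rate), so fitting it yields an intrinsic
  ratio of rate constants without knowing the transporter concentration;
* the apparent aspartate K_M plateaus at kcat/k3 in the high-[Na+]
  limit, providing an independent route to the same ratio.

Fits are unweighted least squares on replicate-mean rates by default
(matching an analysis of printed mean values); inverse-SEM^2 weighting is
available.  All fitters use a multi-start heuristic so that recovery of
generating parameters from clean data does not depend on initial guesses.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "FitError", "RateTable", "FitResult", "ApparentProfile", "DerivedConstants",
    "fit_michaelis_menten", "fit_hill", "fit_vmax_saturation", "loglog_slope",
    "derive_rate_constants", "specific_activity_to_kcat", "compare_km_kd",
    "LOW_NA_REGIME_MM", "HIGH_NA_REGIME_MM",
]

#: default log-log regime boundaries (mM): the apparent aspartate K_M is
#: strongly [Na+]-dependent up to ~50 mM and levels off above ~100 mM
LOW_NA_REGIME_MM = (5.0, 10.0, 25.0, 50.0)
HIGH_NA_REGIME_MM = (100.0, 200.0, 300.0)

REQUIRED_COLUMNS = ("na_mM", "asp_uM", "rate_per_min", "sem_per_min", "n_rep")


class FitError(ValueError):
    """Raised for malformed fitting inputs."""


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class RateTable:
    """Sparse grid of mean initial transport rates.

    Backed by a DataFrame with columns ``na_mM, asp_uM, rate_per_min,
    sem_per_min, n_rep`` (one row per populated grid cell; the grid need
    not be complete).  Rates are per-transporter turnovers per minute.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise FitError(f"missing required columns: {missing}")
        d = self.data
        bad = d.index[(d.na_mM <= 0) | (d.asp_uM <= 0)].tolist()
        if bad:
            raise FitError(f"non-positive concentrations at rows {bad}")
        bad = d.index[(d.rate_per_min < 0) | (d.sem_per_min < 0)].tolist()
        if bad:
            raise FitError(f"negative rate or SEM at rows {bad}")
        self.data = d.sort_values(["na_mM", "asp_uM"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def na_levels(self) -> np.ndarray:
        return np.sort(self.data.na_mM.unique())

    @property
    def asp_levels(self) -> np.ndarray:
        return np.sort(self.data.asp_uM.unique())

    def row(self, na_mM: float) -> pd.DataFrame:
        """All cells at one fixed [Na+] (aspartate series)."""
        return self.data[np.isclose(self.data.na_mM, na_mM)]

    def column(self, asp_uM: float) -> pd.DataFrame:
        """All cells at one fixed [Asp] (sodium series)."""
        return self.data[np.isclose(self.data.asp_uM, asp_uM)]

    @classmethod
    def from_csv(cls, path, metadata: dict | None = None) -> "RateTable":
        try:
            df = pd.read_csv(path, comment="#")
        except pd.errors.EmptyDataError as exc:
            raise FitError(f"{path}: empty rate-table file") from exc
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise FitError(f"{path}: missing required columns {missing}")
        for i, row in df.iterrows():
            # +2: one for the header line, one for 1-based numbering
            line = i + 2
            if not row.na_mM > 0 or not row.asp_uM > 0:
                raise FitError(f"{path}:{line}: non-positive concentration")
            if row.rate_per_min < 0:
                raise FitError(f"{path}:{line}: negative rate")
            if row.sem_per_min < 0:
                raise FitError(f"{path}:{line}: negative SEM")
        return cls(df, metadata=dict(metadata or {}, source=str(path)))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class FitResult:
    """Parameter estimates of one saturation-model fit."""

    model: str
    estimates: dict[str, float]
    standard_errors: dict[str, float]
    ssr: float
    converged: bool
    n_points: int

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "estimates": dict(self.estimates),
            "standard_errors": dict(self.standard_errors),
            "ssr": self.ssr,
            "converged": self.converged,
            "n_points": self.n_points,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(model=d["model"], estimates=dict(d["estimates"]),
                   standard_errors=dict(d["standard_errors"]), ssr=d["ssr"],
                   converged=d["converged"], n_points=d["n_points"])

    def to_json(self, **kw) -> str:
        kw.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kw)


@dataclass
class ApparentProfile:
    """Apparent-parameter fits versus the fixed co-ligand concentration."""

    varied: str  # ligand that was titrated in each underlying fit
    entries: list[tuple[float, FitResult]]

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: e[0])

    @property
    def fixed_concs(self) -> np.ndarray:
        return np.array([c for c, _ in self.entries])

    def param(self, name: str) -> np.ndarray:
        return np.array([f.estimates[name] for _, f in self.entries])

    def param_se(self, name: str) -> np.ndarray:
        return np.array([f.standard_errors[name] for _, f in self.entries])

    def to_dict(self) -> dict:
        return {"varied": self.varied,
                "entries": [[c, f.to_dict()] for c, f in self.entries]}

    @classmethod
    def from_dict(cls, d: dict) -> "ApparentProfile":
        return cls(varied=d["varied"],
                   entries=[(c, FitResult.from_dict(f)) for c, f in d["entries"]])


@dataclass
class DerivedConstants:
    """Intrinsic constants in SI units with delta-method uncertainties.

    kcat (s^-1), k3 (M^-1 s^-1) and their ratio kcat/k3 (M, the
    high-[Na+] plateau of the apparent aspartate K_M).
    """

    kcat: float
    k3: float
    kcat_over_k3: float
    kcat_se: float = 0.0
    k3_se: float = 0.0
    kcat_over_k3_se: float = 0.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("kcat", "k3", "kcat_over_k3"):
            if not getattr(self, name) > 0:
                raise FitError(f"{name} must be positive")
        if not math.isclose(self.kcat, self.k3 * self.kcat_over_k3,
                            rel_tol=1e-9):
            raise FitError("kcat != k3 * (kcat/k3): inconsistent constants")

    def to_dict(self) -> dict:
        return {
            "kcat_per_s": self.kcat, "kcat_se": self.kcat_se,
            "k3_per_M_s": self.k3, "k3_se": self.k3_se,
            "kcat_over_k3_M": self.kcat_over_k3,
            "kcat_over_k3_se": self.kcat_over_k3_se,
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DerivedConstants":
        return cls(kcat=d["kcat_per_s"], k3=d["k3_per_M_s"],
                   kcat_over_k3=d["kcat_over_k3_M"], kcat_se=d["kcat_se"],
                   k3_se=d["k3_se"], kcat_over_k3_se=d["kcat_over_k3_se"],
                   provenance=dict(d.get("provenance", {})))


# ---------------------------------------------------------------------------
# model functions and the generic fitter
# ---------------------------------------------------------------------------

def _michaelis_menten(s, vmax, km):
    return vmax * s / (km + s)


def _hill(s, vmax, k, n):
    s = np.asarray(s, dtype=float)
    return vmax / (1.0 + (k / s) ** n)


def _initial_half_saturation(concs: np.ndarray, rates: np.ndarray) -> float:
    """Log-interpolated concentration at half the maximal observed rate."""
    order = np.argsort(concs)
    c, r = concs[order], rates[order]
    half = r.max() / 2.0
    above = np.nonzero(r >= half)[0]
    i = above[0] if len(above) else len(c) - 1
    if i == 0:
        return float(c[0])
    lo, hi = i - 1, i
    if r[hi] == r[lo]:
        return float(c[hi])
    t = (half - r[lo]) / (r[hi] - r[lo])
    return float(10 ** (np.log10(c[lo]) + t * (np.log10(c[hi]) - np.log10(c[lo]))))


def _run_fit(model_name, fn, param_names, concs, rates, sems, weighting,
             starts, bounds) -> FitResult:
    concs = np.asarray(concs, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise FitError("rates must be non-negative")
    sigma = None
    if weighting == "inverse_sem_sq":
        if sems is None:
            raise FitError("SEM values required for inverse_sem_sq weighting")
        sigma = np.asarray(sems, dtype=float)
        if np.any(sigma <= 0):
            raise FitError("SEMs must be positive for weighting")
    elif weighting != "none":
        raise FitError(f"unknown weighting {weighting!r}")

    best = None
    for p0 in starts:
        try:
            popt, pcov = curve_fit(fn, concs, rates, p0=p0, sigma=sigma,
                                   bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        ssr = float(np.sum((rates - fn(concs, *popt)) ** 2))
        if best is None or ssr < best[2]:
            best = (popt, pcov, ssr)
    if best is None:
        nanpar = {n: float("nan") for n in param_names}
        return FitResult(model=model_name, estimates=nanpar,
                         standard_errors=dict(nanpar), ssr=float("nan"),
                         converged=False, n_points=len(concs))
    popt, pcov, ssr = best
    se = np.sqrt(np.diag(pcov))
    return FitResult(
        model=model_name,
        estimates={n: float(v) for n, v in zip(param_names, popt)},
        standard_errors={n: float(v) for n, v in zip(param_names, se)},
        ssr=ssr, converged=True, n_points=len(concs),
    )


def fit_michaelis_menten(concs, rates, sems=None, weighting: str = "none",
                         ) -> FitResult:
    """Fit v = vmax * [S] / (K_M + [S]).

    Parameters are reported in the units of the inputs (``vmax`` in the
    rate units, ``km`` in the concentration units).  Requires at least
    three distinct concentrations.
    """
    concs = np.asarray(concs, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if len(np.unique(concs)) < 3:
        raise FitError("Michaelis-Menten fit needs >= 3 distinct concentrations")
    v0 = max(rates.max(), 1e-12)
    k0 = _initial_half_saturation(concs, rates)
    starts = [(v0, k0), (v0, 0.2 * k0), (v0, 5 * k0), (1.5 * v0, k0),
              (1.5 * v0, 5 * k0)]
    return _run_fit("michaelis_menten", _michaelis_menten, ("vmax", "km"),
                    concs, rates, sems, weighting, starts, (0, np.inf))


def fit_hill(concs, rates, sems=None, weighting: str = "none") -> FitResult:
    """Fit v = vmax * [S]^n / (K^n + [S]^n).

    ``k`` is parameterized directly as the half-saturation concentration.
    The Hill coefficient ``n`` is unconstrained-positive (values below 1
    are legitimate fits).  Requires at least four distinct concentrations.
    """
    concs = np.asarray(concs, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if len(np.unique(concs)) < 4:
        raise FitError("Hill fit needs >= 4 distinct concentrations")
    v0 = max(rates.max(), 1e-12)
    k0 = _initial_half_saturation(concs, rates)
    starts = [(v0, k0, 1.0), (v0, k0, 1.7), (v0, 0.2 * k0, 1.0),
              (v0, 5 * k0, 1.0), (v0, k0, 0.8)]
    return _run_fit("hill", _hill, ("vmax", "k", "n"),
                    concs, rates, sems, weighting, starts, (0, np.inf))


def fit_vmax_saturation(asp_concs, vmax_apps, sems=None,
                        weighting: str = "none") -> FitResult:
    """Hyperbolic fit of apparent sodium vmax values versus [Asp].

    The rate law for a mechanism with one sodium ion binding after
    aspartate predicts vmax_Na(app) = vmax * [Asp] / (kcat/k3 + [Asp]),
    so the fitted half-saturation constant directly estimates kcat/k3
    (reported as ``half_saturation`` in the input concentration units).
    """
    asp_concs = np.asarray(asp_concs, dtype=float)
    vmax_apps = np.asarray(vmax_apps, dtype=float)
    if len(np.unique(asp_concs)) < 3:
        raise FitError("saturation fit needs >= 3 distinct concentrations")
    fit = fit_michaelis_menten(asp_concs, vmax_apps, sems, weighting)
    return FitResult(
        model="hyperbola",
        estimates={"vmax": fit.estimates["vmax"],
                   "half_saturation": fit.estimates["km"]},
        standard_errors={"vmax": fit.standard_errors["vmax"],
                         "half_saturation": fit.standard_errors["km"]},
        ssr=fit.ssr, converged=fit.converged, n_points=fit.n_points,
    )


# ---------------------------------------------------------------------------
# log-log regime slopes
# ---------------------------------------------------------------------------

def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = len(x)
    slope, intercept = np.polyfit(x, y, 1)
    if n <= 2:
        return float(slope), float("nan")
    resid = y - (slope * x + intercept)
    sxx = np.sum((x - x.mean()) ** 2)
    se = math.sqrt(float(np.sum(resid ** 2)) / (n - 2) / sxx)
    return float(slope), se


def loglog_slope(profile, regime: str,
                 low: Sequence[float] = LOW_NA_REGIME_MM,
                 high: Sequence[float] = HIGH_NA_REGIME_MM,
                 ) -> tuple[float, float]:
    """OLS slope of log10 K_M_Asp(app) versus log10 [Na+] in one regime.

    ``profile`` is either an :class:`ApparentProfile` of aspartate-varied
    Michaelis-Menten fits or a sequence of ``(na_mM, km)`` pairs.  The
    rate law predicts slope -1 as [Na+] -> 0 and slope 0 in the
    high-[Na+] plateau.  Returns ``(slope, standard_error)``.
    """
    if regime not in ("low_na", "high_na"):
        raise FitError(f"unknown regime {regime!r}")
    if isinstance(profile, ApparentProfile):
        pairs = list(zip(profile.fixed_concs, profile.param("km")))
    else:
        pairs = [(float(c), float(k)) for c, k in profile]
    wanted = low if regime == "low_na" else high
    sel = [(c, k) for c, k in pairs
           if any(np.isclose(c, w) for w in wanted)]
    if len(sel) < 2:
        raise FitError(f"fewer than 2 points in the {regime} regime")
    x = np.log10([c for c, _ in sel])
    y = np.log10([k for _, k in sel])
    return _ols_slope(x, y)


# ---------------------------------------------------------------------------
# intrinsic constants
# ---------------------------------------------------------------------------

def derive_rate_constants(km_limit: float, kcat: float | None = None,
                          k3: float | None = None,
                          km_limit_se: float = 0.0, kcat_se: float = 0.0,
                          k3_se: float = 0.0,
                          provenance: Mapping | None = None,
                          ) -> DerivedConstants:
    """Complete (kcat, k3) from the high-[Na+] K_M plateau and one of them.

    ``km_limit`` is the plateau value of the apparent aspartate K_M in
    molar; it equals kcat/k3, so either constant determines the other:
    kcat = k3 * km_limit.  Exactly one of ``kcat``/``k3`` must be given.
    Standard errors are propagated by the delta method.
    """
    if not km_limit > 0:
        raise FitError("km_limit must be positive")
    if (kcat is None) == (k3 is None):
        raise FitError("provide exactly one of kcat or k3")
    if kcat is not None:
        k3 = kcat / km_limit
        k3_se = math.hypot(kcat_se / km_limit,
                           kcat * km_limit_se / km_limit ** 2)
    else:
        kcat = k3 * km_limit
        kcat_se = math.hypot(k3_se * km_limit, k3 * km_limit_se)
    return DerivedConstants(
        kcat=float(kcat), k3=float(k3), kcat_over_k3=float(km_limit),
        kcat_se=float(kcat_se), k3_se=float(k3_se),
        kcat_over_k3_se=float(km_limit_se),
        provenance=dict(provenance or {}),
    )


def specific_activity_to_kcat(v: float, molar_mass: float) -> float:
    """Convert a specific activity to a per-monomer turnover number.

    ``v`` in nmol substrate per mg protein per minute, ``molar_mass`` in
    g/mol; returns kcat in s^-1 (v * M * 1e-6 / 60).
    """
    if v < 0 or molar_mass <= 0:
        raise FitError("specific activity must be >= 0 and molar mass > 0")
    return v * molar_mass * 1e-6 / 60.0


def compare_km_kd(profile, kd_table: Sequence[tuple[float, float]],
                  rel_tol: float = 0.25) -> list[dict]:
    """Ratio of transport K_M to equilibrium binding K_D versus [Na+].

    ``profile`` as in :func:`loglog_slope`; ``kd_table`` lists
    ``(na_mM, kd)`` with K_D in the same concentration units as the
    profile's K_M.  Sodium concentrations are matched within relative
    tolerance ``rel_tol``.  A ratio above 3 is classed ``KM>>KD``, below
    1/3 ``KM<<KD``, otherwise ``KM~=KD`` — under rapid-equilibrium
    kinetics the ratio would be 1 everywhere, so systematic departures
    flag a steady-state (turnover-limited) mechanism.
    """
    if isinstance(profile, ApparentProfile):
        pairs = list(zip(profile.fixed_concs, profile.param("km")))
    else:
        pairs = [(float(c), float(k)) for c, k in profile]
    out = []
    for na, kd in kd_table:
        matches = [(c, km) for c, km in pairs
                   if abs(c - na) <= rel_tol * na]
        if not matches:
            continue
        c, km = min(matches, key=lambda m: abs(m[0] - na))
        ratio = km / kd
        if ratio > 3:
            klass = "KM>>KD"
        elif ratio < 1 / 3:
            klass = "KM<<KD"
        else:
            klass = "KM~=KD"
        out.append({"na_mM": float(na), "km": float(km), "kd": float(kd),
                    "ratio": float(ratio), "class": klass})
    if not out:
        raise FitError("no overlapping [Na+] values between K_M and K_D tables")
    return out
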