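"""1:1 binding equilibrium and fast-exchange titration fitting.

A host H (protein) and guest G (ligand, here cognate DNA) form a 1:1 complex
HG with association constant ``K_a = [HG]/([H][G])`` (``K_d = 1/K_a``).  Under
fast chemical exchange the observed chemical shift of a host probe is the
population-weighted average of its free and bound values, so the shift change
relative to the free state is

    dd = d_HG * [HG] / [H]_0

where ``d_HG`` is the limiting (fully bound) shift change and ``[H]_0`` the
analytical host concentration.  ``[HG]`` follows from mass action on the
analytical concentrations, the textbook quadratic in ``[HG]``.  The quadratic
is evaluated here in a cancellation-safe rearrangement (see
:func:`complex_concentration`), and an independent bisection solver
(:func:`equilibrium_oracle`) is provided for verification.

Fitting works on :class:`TitrationSeries` tables, estimating ``log10(K_d)``
(positivity, near-symmetric errors) and one limiting shift per probe, with the
dissociation constant optionally shared across probes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "BindingParameters",
    "TitrationPoint",
    "TitrationSeries",
    "FitResult",
    "complex_concentration",
    "predicted_shift",
    "fit_titration",
    "equilibrium_oracle",
    "read_titration_csv",
    "write_titration_csv",
]

#: Factors converting the concentration units accepted at file interfaces to
#: molar, which is canonical everywhere inside the package.
_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9}


def _require_finite_nonneg(name: str, value: float, strict: bool = False) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if strict and value <= 0:
        raise ValueError(f"{name} must be > 0, got {value!r}")
    if not strict and value < 0:
        raise ValueError(f"{name} must be >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class BindingParameters:
    """Thermodynamic description of a 1:1 host--guest complex.

    Parameters
    ----------
    kd : float
        Dissociation constant in molar; must be strictly positive.
    delta_hg : float
        Limiting shift change of the probe in the fully bound complex, ppm.
        Signed: shifts may move either way on binding.
    host_label, guest_label : str
        Free-text labels for bookkeeping.
    """

    kd: float
    delta_hg: float = 0.0
    host_label: str = "host"
    guest_label: str = "guest"

    def __post_init__(self) -> None:
        _require_finite_nonneg("kd", self.kd, strict=True)
        if not math.isfinite(self.delta_hg):
            raise ValueError("delta_hg must be finite")

    @property
    def ka(self) -> float:
        """Association constant, per molar (``1/kd``)."""
        return 1.0 / self.kd


@dataclass(frozen=True)
class TitrationPoint:
    """One point of a titration: analytical concentrations plus observables.

    ``observed_shift`` is the signed shift change relative to the free state
    (guest_total = 0), in ppm; ``observed_intensity`` is an optional peak
    height in arbitrary units.
    """

    host_total: float
    guest_total: float
    observed_shift: float = 0.0
    observed_intensity: float | None = None

    def __post_init__(self) -> None:
        _require_finite_nonneg("host_total", self.host_total, strict=True)
        _require_finite_nonneg("guest_total", self.guest_total)


@dataclass
class TitrationSeries:
    """Observed titration curves, one list of points per probe."""

    points: dict[str, list[TitrationPoint]] = field(default_factory=dict)

    @property
    def probes(self) -> list[str]:
        return list(self.points)

    def add(self, probe: str, point: TitrationPoint) -> None:
        self.points.setdefault(probe, []).append(point)

    def n_points(self) -> int:
        return sum(len(v) for v in self.points.values())


@dataclass
class FitResult:
    """Outcome of a titration fit.

    ``params`` carries the fitted ``K_d`` and, per probe, the limiting shift;
    ``standard_errors`` are delta-method errors on the linear scale (the fit
    itself runs in log10 K_d).  Non-convergence and uninformative data are
    flagged, never raised.
    """

    kd: float
    kd_stderr: float | None
    delta_hg: dict[str, float]
    delta_hg_stderr: dict[str, float | None]
    residuals: np.ndarray
    converged: bool
    n_points: int
    n_params: int
    message: str = ""

    @property
    def params(self) -> dict[str, BindingParameters]:
        return {
            probe: BindingParameters(kd=self.kd, delta_hg=dhg, guest_label=probe)
            for probe, dhg in self.delta_hg.items()
        }

    def to_dict(self) -> dict:
        return {
            "kd_molar": self.kd,
            "ka_per_molar": 1.0 / self.kd if self.kd else None,
            "kd_stderr_molar": self.kd_stderr,
            "delta_hg_ppm": self.delta_hg,
            "delta_hg_stderr_ppm": self.delta_hg_stderr,
            "converged": self.converged,
            "n_points": self.n_points,
            "n_params": self.n_params,
            "message": self.message,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)


def complex_concentration(host_total: float, guest_total: float, ka: float) -> float:
    """Equilibrium complex concentration [HG] of a 1:1 association, molar.

    Solves mass action ``K_a = [HG] / (([H]0-[HG])([G]0-[HG]))`` for the
    physical root.  The standard quadratic solution subtracts two nearly equal
    numbers when binding is tight; with ``S = [G]0 + [H]0 + 1/K_a`` the
    algebraically identical form

        [HG] = 2 [H]0 [G]0 / (S + sqrt(S^2 - 4 [H]0 [G]0))

    is cancellation-safe for all parameter regimes.
    """
    host_total = _require_finite_nonneg("host_total", host_total, strict=True)
    guest_total = _require_finite_nonneg("guest_total", guest_total)
    ka = _require_finite_nonneg("ka", ka, strict=True)
    if guest_total == 0.0:
        return 0.0
    s = guest_total + host_total + 1.0 / ka
    disc = s * s - 4.0 * host_total * guest_total
    # disc >= (|H0-G0| + 1/Ka)^2 > 0 analytically; clip to guard rounding.
    root = math.sqrt(max(disc, 0.0))
    return 2.0 * host_total * guest_total / (s + root)


def predicted_shift(params: BindingParameters, point: TitrationPoint) -> float:
    """Fast-exchange observed shift change, ppm: ``d_HG * [HG]/[H]0``."""
    hg = complex_concentration(point.host_total, point.guest_total, params.ka)
    return params.delta_hg * hg / point.host_total


def equilibrium_oracle(
    host_total: float,
    guest_total: float,
    ka: float,
    rtol: float = 1e-13,
    max_iter: int = 1000,
) -> float:
    """[HG] by bracketed bisection on the free guest concentration.

    Independent check of :func:`complex_concentration`: with free guest ``g``,
    ``[HG] = K_a [H]0 g / (1 + K_a g)`` and the guest balance
    ``g + [HG] = [G]0`` is monotone in ``g``, so plain bisection on
    ``g in [0, [G]0]`` converges unconditionally.
    """
    host_total = _require_finite_nonneg("host_total", host_total, strict=True)
    guest_total = _require_finite_nonneg("guest_total", guest_total)
    ka = _require_finite_nonneg("ka", ka, strict=True)
    if guest_total == 0.0:
        return 0.0

    def balance(g: float) -> float:
        kag = ka * g
        return g + host_total * kag / (1.0 + kag) - guest_total

    lo, hi = 0.0, guest_total
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if mid <= lo or mid >= hi:  # bracket exhausted at float resolution
            break
        if balance(mid) > 0.0:
            hi = mid
        else:
            lo = mid
        # stop relative to the bracket itself: the free-guest root can sit
        # many orders of magnitude below guest_total under tight binding
        if hi - lo <= rtol * hi:
            break
    g = 0.5 * (lo + hi)
    kag = ka * g
    return host_total * kag / (1.0 + kag)


def _series_arrays(
    series: TitrationSeries,
) -> tuple[list[str], list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    probes, h0s, g0s, shifts = [], [], [], []
    for probe, pts in series.points.items():
        probes.append(probe)
        h0s.append(np.array([p.host_total for p in pts]))
        g0s.append(np.array([p.guest_total for p in pts]))
        shifts.append(np.array([p.observed_shift for p in pts]))
    return probes, h0s, g0s, shifts


def _hg_vector(h0: np.ndarray, g0: np.ndarray, ka: float) -> np.ndarray:
    return np.array(
        [complex_concentration(h, g, ka) if g > 0 else 0.0 for h, g in zip(h0, g0)]
    )


def fit_titration(
    series: TitrationSeries,
    init: BindingParameters | None = None,
    bounds: tuple[float, float] = (1e-9, 1e-1),
    share_kd: bool = True,
    min_signal: float = 1e-6,
) -> FitResult:
    """Least-squares fit of the 1:1 fast-exchange model to titration data.

    One ``K_d`` (shared across probes when ``share_kd``; the common case of a
    single probe is unaffected by the flag) and one limiting shift per probe
    are estimated.  The optimiser works in ``log10(K_d)`` so positivity is
    structural and the error distribution near the optimum is more symmetric;
    the reported ``kd_stderr`` is the delta-method transform of the
    log-scale Jacobian-covariance error.

    Degenerate input (all observed shifts ~ 0 within ``min_signal``) and
    optimiser failure are reported via ``converged=False`` with a message,
    never as an exception.
    """
    probes, h0s, g0s, shifts = _series_arrays(series)
    n_points = int(sum(len(s) for s in shifts))
    n_params = 1 + len(probes) if share_kd else 2 * len(probes)
    if not probes or n_points < 3:
        return FitResult(
            kd=math.nan, kd_stderr=None, delta_hg={}, delta_hg_stderr={},
            residuals=np.array([]), converged=False, n_points=n_points,
            n_params=n_params, message="need at least 3 titration points",
        )
    max_signal = max(float(np.max(np.abs(s))) for s in shifts)
    if max_signal < min_signal:
        return FitResult(
            kd=math.nan, kd_stderr=None,
            delta_hg={p: 0.0 for p in probes},
            delta_hg_stderr={p: None for p in probes},
            residuals=np.concatenate(shifts), converged=False,
            n_points=n_points, n_params=n_params,
            message="uninformative: all observed shifts are ~0",
        )

    if init is None:
        # mid-log of the bounds; limiting shift from the largest observed
        kd0 = 10 ** (0.5 * (math.log10(bounds[0]) + math.log10(bounds[1])))
    else:
        kd0 = min(max(init.kd, bounds[0]), bounds[1])

    pars = lmfit.Parameters()
    pars.add(
        "log_kd", value=math.log10(kd0),
        min=math.log10(bounds[0]), max=math.log10(bounds[1]),
    )
    names = [f"dhg_{i}" for i in range(len(probes))]
    for i, s in enumerate(shifts):
        guess = s[np.argmax(np.abs(s))] if len(s) else 1.0
        pars.add(names[i], value=float(guess) if guess != 0 else 0.1)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        ka = 10 ** (-p["log_kd"].value)
        out = []
        for i, (h0, g0, obs) in enumerate(zip(h0s, g0s, shifts)):
            hg = _hg_vector(h0, g0, ka)
            out.append(obs - p[names[i]].value * hg / h0)
        return np.concatenate(out)

    try:
        res = lmfit.minimize(residual, pars, method="least_squares")
    except Exception as exc:  # optimiser blow-up -> flagged result
        return FitResult(
            kd=kd0, kd_stderr=None,
            delta_hg={p: math.nan for p in probes},
            delta_hg_stderr={p: None for p in probes},
            residuals=np.concatenate(shifts), converged=False,
            n_points=n_points, n_params=n_params,
            message=f"optimiser failure: {exc}",
        )

    log_kd = res.params["log_kd"].value
    kd = 10 ** log_kd
    kd_err = None
    if res.params["log_kd"].stderr is not None:
        kd_err = math.log(10.0) * kd * res.params["log_kd"].stderr
    dhg = {p: res.params[names[i]].value for i, p in enumerate(probes)}
    dhg_err = {p: res.params[names[i]].stderr for i, p in enumerate(probes)}
    at_bound = (
        abs(log_kd - math.log10(bounds[0])) < 1e-6
        or abs(log_kd - math.log10(bounds[1])) < 1e-6
    )
    msg = "kd at bound" if at_bound else ""
    return FitResult(
        kd=kd, kd_stderr=kd_err, delta_hg=dhg, delta_hg_stderr=dhg_err,
        residuals=res.residual, converged=bool(res.success) and not at_bound,
        n_points=n_points, n_params=n_params, message=msg,
    )


def read_titration_csv(path) -> TitrationSeries:
    """Read a titration table (host_total, guest_total, probe, shift_ppm,
    intensity, unit) into a :class:`TitrationSeries`, converting to molar."""
    df = pd.read_csv(path)
    required = {"host_total", "guest_total", "probe", "shift_ppm", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"titration CSV missing columns: {sorted(missing)}")
    series = TitrationSeries()
    for _, row in df.iterrows():
        unit = str(row["unit"])
        if unit not in _UNIT_TO_MOLAR:
            raise ValueError(
                f"unknown concentration unit {unit!r}; use one of "
                f"{sorted(_UNIT_TO_MOLAR)}"
            )
        f = _UNIT_TO_MOLAR[unit]
        intensity = row.get("intensity")
        series.add(
            str(row["probe"]),
            TitrationPoint(
                host_total=float(row["host_total"]) * f,
                guest_total=float(row["guest_total"]) * f,
                observed_shift=float(row["shift_ppm"]),
                observed_intensity=None if pd.isna(intensity) else float(intensity),
            ),
        )
    return series


def write_titration_csv(series: TitrationSeries, path, unit: str = "M") -> None:
    f = _UNIT_TO_MOLAR[unit]
    rows = []
    for probe, pts in series.points.items():
        for p in pts:
            rows.append(
                {
                    "host_total": p.host_total / f,
                    "guest_total": p.guest_total / f,
                    "probe": probe,
                    "shift_ppm": p.observed_shift,
                    "intensity": p.observed_intensity,
                    "unit": unit,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
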