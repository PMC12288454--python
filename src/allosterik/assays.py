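"""Quantitative models for the binding and phenotype assays.

Two equilibrium binding models:

* Hill (gel-shift titrations of protein against operator DNA):
  f(P) = P^n / (K_D^n + P^n); f(K_D) = 1/2.
* Exact 1:1 isotherm (thermophoresis titrations of ligand at fixed protein),
  using the quadratic solution so protein depletion is handled:
  [PL] = ((P+L+K_D) − sqrt((P+L+K_D)² − 4PL)) / 2, f = [PL]/P.
  (At 500 nM protein the simple L/(K_D+L) form is adequate for the K_Ds seen
  here, but the exact form costs nothing and is the default.)

Growth kinetics are summarised by the maximal exponential rate (sliding
log-linear window), the doubling time ln2/rate, and a lag time.  Effector
release titrations are reduced to the lowest concentration achieving
(near-)complete release.

Fitting follows a Model/Results layout: construct a model from data, call
``fit()``, read estimates, standard errors and a ``summary()`` table off the
results object.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import DegenerateDataError, UnitMismatchError


@dataclass
class CurveData:
    """A titration or time series: strictly increasing x, unit-tagged."""

    x: np.ndarray
    y: np.ndarray
    x_unit: str = ""
    y_unit: str = ""
    replicate_id: str = ""
    truth: dict = field(default_factory=dict)  # generator ground truth, if synthetic
    model: str = ""

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x values must be strictly increasing")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, x: str = "x", y: str = "y", **kw):
        d = df.sort_values(x)
        return cls(d[x].to_numpy(), d[y].to_numpy(), **kw)

    def to_csv(self, path) -> None:
        pd.DataFrame({"x": self.x, "y": self.y}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Model functions
# ---------------------------------------------------------------------------

def hill_model(P, K_D: float, n: float = 1.0):
    """Hill fraction bound, f = P^n / (K_D^n + P^n)."""
    if K_D <= 0 or n <= 0:
        raise ValueError("K_D and n must be positive")
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("concentration must be non-negative")
    with np.errstate(divide="ignore"):
        r = np.where(P > 0, (P / K_D) ** n, 0.0)
    out = r / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def isotherm_model(P_total: float, L_total, K_D: float):
    """Exact 1:1 binding: fraction of protein bound at total ligand L_total."""
    if P_total <= 0:
        raise ValueError("P_total must be positive")
    if K_D < 0:
        raise ValueError("K_D must be non-negative")
    L = np.asarray(L_total, dtype=float)
    if np.any(L < 0):
        raise ValueError("ligand concentration must be non-negative")
    b = P_total + L + K_D
    disc = np.clip(b * b - 4.0 * P_total * L, 0.0, None)
    # rationalised root: 2PL/(b + sqrt(disc)) avoids cancellation when P ≪ L
    complex_ = np.where(b > 0, 2.0 * P_total * L / (b + np.sqrt(disc)), 0.0)
    out = np.clip(complex_ / P_total, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def simple_isotherm_model(L_total, K_D: float):
    """Depletion-free isotherm L/(K_D + L); limit of the quadratic as P→0."""
    L = np.asarray(L_total, dtype=float)
    out = L / (K_D + L)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Binding fits
# ---------------------------------------------------------------------------

@dataclass
class BindingResults:
    """Fitted binding parameters with Jacobian-based standard errors."""

    model: str
    params: dict
    bse: dict
    residual_norm: float
    converged: bool
    n_obs: int
    x_unit: str = ""
    data: CurveData | None = None

    @property
    def kd(self) -> float:
        return self.params["K_D"]

    @property
    def kd_se(self) -> float:
        return self.bse["K_D"]

    @property
    def hill_n(self) -> float | None:
        return self.params.get("n")

    def summary(self) -> str:
        lines = [
            f"{'Binding fit':<24}{self.model}",
            f"{'N observations':<24}{self.n_obs}",
            f"{'Converged':<24}{self.converged}",
            f"{'Residual norm':<24}{self.residual_norm:.4g}",
            "-" * 44,
            f"{'param':<10}{'estimate':>14}{'std err':>14}",
        ]
        for k in self.params:
            unit = f" {self.x_unit}" if k == "K_D" and self.x_unit else ""
            lines.append(f"{k:<10}{self.params[k]:>14.4g}{self.bse[k]:>14.4g}{unit}")
        return "\n".join(lines)

    def predict(self, x):
        if self.model == "hill":
            return hill_model(x, self.params["K_D"], self.params["n"])
        return isotherm_model(self.params["P_total"], x, self.params["K_D"])

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.data is not None:
            ax.plot(self.data.x, self.data.y, "o", label="data")
            xs = np.linspace(self.data.x.min(), self.data.x.max(), 200)
            ax.plot(xs, self.predict(xs), "-", label="fit")
        ax.set_xlabel(f"concentration ({self.x_unit})" if self.x_unit else "concentration")
        ax.set_ylabel("fraction bound")
        ax.legend()
        return ax


class BindingModel:
    """Nonlinear least-squares binding model (``hill`` or ``isotherm_1to1``).

    Initialisation is deterministic: K_D starts at the x whose response is
    closest to 0.5 and the Hill coefficient at 1, so repeated fits of the
    same data are bit-identical.
    """

    def __init__(
        self,
        data: CurveData,
        model: str = "hill",
        protein_total: float | None = None,
    ):
        if model not in ("hill", "isotherm_1to1"):
            raise ValueError(f"unknown binding model: {model}")
        if model == "isotherm_1to1" and protein_total is None:
            raise ValueError("isotherm_1to1 needs the fixed protein concentration")
        if len(data.x) < 5:
            raise ValueError("need at least 5 titration points")
        self.data = data
        self.model = model
        self.protein_total = protein_total

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, x: str = "x", y: str = "y", **kw):
        return cls(CurveData.from_dataframe(df, x, y), **kw)

    def fit(self) -> BindingResults:
        x, y = self.data.x, self.data.y
        if np.ptp(y) <= 0:
            raise DegenerateDataError("response is constant; nothing to fit")
        kd0 = float(x[np.argmin(np.abs(y - 0.5))])
        if kd0 <= 0:
            kd0 = float(x[x > 0].min()) if np.any(x > 0) else 1.0
        converged = True
        if self.model == "hill":
            fun = lambda xx, kd, n: hill_model(xx, kd, n)  # noqa: E731
            p0, names = [kd0, 1.0], ["K_D", "n"]
        else:
            P = self.protein_total
            fun = lambda xx, kd: isotherm_model(P, xx, kd)  # noqa: E731
            p0, names = [kd0], ["K_D"]
        lb = np.full(len(p0), 1e-12)
        try:
            popt, pcov = optimize.curve_fit(
                fun, x, y, p0=p0, bounds=(lb, np.inf), maxfev=20000
            )
        except RuntimeError:
            converged = False
            popt = np.asarray(p0, dtype=float)
            pcov = np.full((len(p0), len(p0)), np.nan)
            warnings.warn("binding fit did not converge", stacklevel=2)
        resid = y - fun(x, *popt)
        se = np.sqrt(np.diag(pcov))
        params = dict(zip(names, map(float, popt)))
        bse = dict(zip(names, map(float, se)))
        if self.model == "isotherm_1to1":
            params["P_total"] = float(self.protein_total)
            bse["P_total"] = 0.0
        return BindingResults(
            model=self.model,
            params=params,
            bse=bse,
            residual_norm=float(np.linalg.norm(resid)),
            converged=converged,
            n_obs=len(x),
            x_unit=self.data.x_unit,
            data=self.data,
        )


def fit_binding(
    curve: CurveData, model: str = "hill", protein_total: float | None = None
) -> BindingResults:
    """Functional wrapper: ``BindingModel(curve, model).fit()``."""
    return BindingModel(curve, model=model, protein_total=protein_total).fit()


# ---------------------------------------------------------------------------
# Fold ratios and release titrations
# ---------------------------------------------------------------------------

def fold_ratio(
    k_a: float, k_b: float, unit_a: str | None = None, unit_b: str | None = None
) -> tuple[float, int]:
    """Affinity ratio K_a/K_b and its nearest integer fold."""
    if k_a <= 0 or k_b <= 0:
        raise ValueError("dissociation constants must be positive")
    if unit_a is not None and unit_b is not None and unit_a != unit_b:
        raise UnitMismatchError(f"cannot compare {unit_a} with {unit_b}")
    ratio = k_a / k_b
    return ratio, round(ratio)


@dataclass
class ReleaseResult:
    released: bool
    concentration: float | None
    threshold: float

    def __str__(self):
        if self.released:
            return f"complete release at {self.concentration:g} (bound ≤ {self.threshold:g})"
        return "not released within the tested range"


def release_titration(
    series: CurveData, threshold: float = 0.05
) -> ReleaseResult:
    """Lowest tested effector concentration with bound fraction ≤ threshold.

    The series should be a release titration (bound fraction non-increasing
    with effector concentration); a clearly increasing series triggers a
    warning.
    """
    y = series.y
    if len(y) >= 2:
        slope = stats.linregress(series.x, y).slope
        if slope > 0 and y[-1] > y[0]:
            warnings.warn("series increases with concentration; not a release titration", stacklevel=2)
    hits = np.flatnonzero(y <= threshold)
    if len(hits) == 0:
        return ReleaseResult(False, None, threshold)
    return ReleaseResult(True, float(series.x[hits[0]]), threshold)


# ---------------------------------------------------------------------------
# Growth kinetics
# ---------------------------------------------------------------------------

@dataclass
class GrowthResults:
    doubling_time: float  # h; NaN when degenerate
    growth_rate: float  # 1/h
    lag_time: float  # h; NaN when never reached
    window: tuple  # (t_start, t_end) of the exponential window
    r_squared: float
    degenerate: bool = False

    def summary(self) -> str:
        return "\n".join(
            [
                f"{'Growth fit':<24}{'log-linear sliding window'}",
                f"{'Degenerate':<24}{self.degenerate}",
                f"{'Growth rate (1/h)':<24}{self.growth_rate:.4g}",
                f"{'Doubling time (h)':<24}{self.doubling_time:.4g}",
                f"{'Lag time (h)':<24}{self.lag_time:.4g}",
                f"{'Window (h)':<24}{self.window[0]:.3g}-{self.window[1]:.3g}",
                f"{'Window R²':<24}{self.r_squared:.4f}",
            ]
        )


class GrowthCurveModel:
    """Growth-curve kinetics from OD vs time.

    The maximal specific growth rate is the slope of ln(OD) over the sliding
    window (default 5 points) with the highest R²; the doubling time is
    ln2/rate.  The default lag estimate is the first time the (lightly
    smoothed) OD exceeds ``lag_factor`` × its initial value; a classic
    tangent-intercept estimate is available via ``lag_method="tangent"``.
    """

    def __init__(
        self,
        time,
        od,
        window: int = 5,
        lag_factor: float = 2.0,
        lag_method: str = "threshold",
    ):
        self.time = np.asarray(time, dtype=float)
        self.od = np.asarray(od, dtype=float)
        if len(self.time) < 8:
            raise ValueError("need at least 8 time points")
        if np.any(self.od <= 0):
            raise ValueError("OD values must be positive")
        if window < 3:
            raise ValueError("window must span at least 3 points")
        self.window = min(window, len(self.time))
        self.lag_factor = lag_factor
        if lag_method not in ("threshold", "tangent"):
            raise ValueError(f"unknown lag method: {lag_method}")
        self.lag_method = lag_method

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time: str = "time", od: str = "od", **kw):
        d = df.sort_values(time)
        return cls(d[time].to_numpy(), d[od].to_numpy(), **kw)

    def fit(self) -> GrowthResults:
        t, od = self.time, self.od
        ln_od = np.log(od)
        if np.ptp(od) <= 1e-12 * max(od.max(), 1.0):
            return GrowthResults(math.nan, 0.0, math.nan, (t[0], t[-1]), 0.0, True)
        w = self.window
        best = None
        for i in range(len(t) - w + 1):
            res = stats.linregress(t[i : i + w], ln_od[i : i + w])
            r2 = res.rvalue**2
            if best is None or r2 > best[0] + 1e-12:
                best = (r2, res.slope, i)
        r2, rate, i0 = best
        if rate <= 0:
            return GrowthResults(math.nan, float(rate), math.nan, (t[i0], t[i0 + w - 1]), float(r2), True)
        smooth = np.convolve(od, np.ones(3) / 3.0, mode="same")
        smooth[0], smooth[-1] = od[0], od[-1]
        if self.lag_method == "threshold":
            above = np.flatnonzero(smooth >= self.lag_factor * smooth[0])
            lag = float(t[above[0]]) if len(above) else math.nan
        else:
            # tangent through the max-rate window intersected with the baseline
            t_mid = t[i0 : i0 + w].mean()
            y_mid = ln_od[i0 : i0 + w].mean()
            lag = float(t_mid - (y_mid - ln_od[0]) / rate)
        return GrowthResults(
            doubling_time=float(math.log(2) / rate),
            growth_rate=float(rate),
            lag_time=lag,
            window=(float(t[i0]), float(t[i0 + w - 1])),
            r_squared=float(r2),
        )


def fit_growth(curve: CurveData, **kw) -> GrowthResults:
    """Functional wrapper: ``GrowthCurveModel(curve.x, curve.y).fit()``."""
    return GrowthCurveModel(curve.x, curve.y, **kw).fit()


def normalize_fluorescence(F, OD, background=None):
    """Per-sample fluorescence normalised to culture density, (F − F_bg)/OD."""
    F = np.asarray(F, dtype=float)
    OD = np.asarray(OD, dtype=float)
    if np.any(OD <= 0):
        raise ValueError("OD must be positive everywhere")
    if background is not None:
        F = F - np.asarray(background, dtype=float)
    out = F / OD
    return float(out) if out.ndim == 0 else out
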