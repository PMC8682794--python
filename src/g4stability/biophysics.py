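"""Thermal difference spectra and Langmuir binding kinetics.

Two in-vitro readouts of G-quadruplex formation:

* **TDS** — the UV absorbance spectrum above melting minus the spectrum
  below melting, normalised by the maximum low-temperature absorbance
  (A_max). Duplex and single-stranded DNA become hyperchromic everywhere
  on melting, so their TDS is non-negative across 220-320 nm; a
  G-quadruplex instead *loses* absorbance above 290 nm, producing a
  negative lobe and an isosbestic zero-crossing at ~290 nm, which is the
  classification signature used here.

* **Langmuir kinetics** — label-free biosensor binding curves sigma(t)
  (surface density of analyte on immobilised probes) under a step-wise
  rising concentration series. Under single-site Langmuir binding each
  step at concentration c relaxes exponentially toward
  sigma_max * c/(c + Kd) with observed rate k_obs = kon*c + koff, so a
  per-step exponential fit followed by a linear regression of k_obs on c
  yields kon (slope), koff (intercept) and Kd = koff/kon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import statsmodels.api as sm

__all__ = [
    "Spectrum",
    "TdsResult",
    "tds",
    "classify_g4",
    "BindingCurve",
    "KineticFit",
    "LangmuirModel",
    "langmuir_fit",
]


@dataclass
class Spectrum:
    """Absorbance spectrum at one temperature over an ascending nm grid."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    temperature: float

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.shape != self.absorbance.shape:
            raise ValueError("wavelength and absorbance vectors must match")
        if (np.diff(self.wavelengths) <= 0).any():
            raise ValueError("wavelengths must be strictly ascending")
        if not (self.wavelengths.min() <= 290 <= self.wavelengths.max()):
            raise ValueError("grid must span 290 nm")


@dataclass
class TdsResult:
    """Normalised thermal difference spectrum and its G4 classification."""

    wavelengths: np.ndarray
    values: np.ndarray           # (A_high - A_low) / A_max
    a_max: float
    zero_crossing_nm: float | None = None
    is_g4_signature: bool = False

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.wavelengths, self.values)
        ax.axhline(0, color="k", lw=0.5)
        ax.axvline(290, color="0.6", lw=0.5, ls="--")
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel(r"$\Delta A / A_{max}$")
        return ax


def tds(low: Spectrum, high: Spectrum) -> TdsResult:
    """Thermal difference spectrum, (A_high - A_low) / max(A_low).

    The high-temperature spectrum is linearly interpolated onto the
    low-temperature grid if the grids differ. Scale-invariant: multiplying
    both spectra by the same positive factor leaves the result unchanged.
    """
    a_low = low.absorbance
    if len(high.wavelengths) == len(low.wavelengths) and np.array_equal(high.wavelengths, low.wavelengths):
        a_high = high.absorbance
    else:
        a_high = np.interp(low.wavelengths, high.wavelengths, high.absorbance)
    a_max = float(a_low.max())
    if a_max <= 0:
        raise ValueError("maximum low-temperature absorbance must be positive")
    values = (a_high - a_low) / a_max
    result = TdsResult(wavelengths=low.wavelengths, values=values, a_max=a_max)
    result.is_g4_signature, result.zero_crossing_nm = classify_g4(result)
    return result


def classify_g4(
    tds_result: TdsResult,
    pivot_nm: float = 290.0,
    tolerance_nm: float = 3.0,
) -> tuple[bool, float | None]:
    """G4 signature test on a TDS: positive lobe below ~290 nm, negative above.

    The signature requires (i) the median TDS over [pivot+5, 320] to be
    negative, (ii) the median over [260, pivot-5] to be positive, and (iii)
    a sign change located within pivot +/- tolerance. Band medians rather
    than single-wavelength values make the call robust to grid placement
    and noise. Returns (is_signature, zero_crossing_nm).
    """
    w, v = tds_result.wavelengths, tds_result.values
    hi_band = v[(w >= pivot_nm + 5) & (w <= 320)]
    lo_band = v[(w >= 260) & (w <= pivot_nm - 5)]
    if len(hi_band) == 0 or len(lo_band) == 0:
        return False, None
    lobes_ok = (np.median(hi_band) < 0) and (np.median(lo_band) > 0)

    # locate the sign change near the pivot by a local linear fit: much more
    # robust to per-wavelength noise than interpolating raw sign flips
    crossing = None
    local = (w >= pivot_nm - 15) & (w <= pivot_nm + 15)
    if local.sum() >= 6:
        # quadratic absorbs the lobe curvature that biases a straight line
        coef = np.polyfit(w[local] - pivot_nm, v[local], 2)
        roots = [r.real + pivot_nm for r in np.roots(coef) if abs(r.imag) < 1e-9]
        roots = [r for r in roots if w.min() <= r <= w.max()]
        if roots:
            crossing = float(min(roots, key=lambda x: abs(x - pivot_nm)))
    else:  # sparse grid: interpolate the sign flip nearest the pivot
        sign = np.sign(v)
        flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
        xs = [float(w[i] - v[i] * (w[i + 1] - w[i]) / (v[i + 1] - v[i])) for i in flips]
        xs += [float(x) for x in w[v == 0]]
        if xs:
            crossing = min(xs, key=lambda x: abs(x - pivot_nm))
    sig = bool(lobes_ok and crossing is not None and abs(crossing - pivot_nm) <= tolerance_nm)
    return sig, crossing


# ---------------------------------------------------------------------------
# Langmuir binding kinetics

@dataclass
class BindingCurve:
    """Surface density sigma(t) under a step-wise concentration schedule.

    ``steps`` is a list of (start_time_s, concentration_nM) pairs with
    non-decreasing concentrations (rising spike series).
    """

    time: np.ndarray
    sigma: np.ndarray
    steps: list

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.time.shape != self.sigma.shape:
            raise ValueError("time and sigma vectors must match")
        if (np.diff(self.time) <= 0).any():
            raise ValueError("time must be strictly increasing")
        concs = [c for _, c in self.steps]
        if any(c < 0 for c in concs) or any(b < a for a, b in zip(concs, concs[1:])):
            raise ValueError("concentrations must be >= 0 and non-decreasing across spikes")


@dataclass
class KineticFit:
    """Langmuir kinetic constants from a step-series binding curve."""

    kon: float                     # 1/(nM s)
    koff: float                    # 1/s
    sigma_max: float
    steps: "object" = None         # per-step DataFrame: conc, k_obs, k_obs_se, plateau
    residual_ss: float = 0.0

    @property
    def Kd(self) -> float:
        """Equilibrium dissociation constant, koff / kon (nM)."""
        return self.koff / self.kon

    def summary(self) -> str:
        lines = [
            "Langmuir kinetic fit (per-step exponential + k_obs ~ c regression)",
            f"  kon       : {self.kon:.4g} 1/(nM s)",
            f"  koff      : {self.koff:.4g} 1/s",
            f"  Kd        : {self.Kd:.4g} nM",
            f"  sigma_max : {self.sigma_max:.4g}",
            f"  residual sum of squares: {self.residual_ss:.4g}",
        ]
        if self.steps is not None:
            for row in self.steps.itertuples(index=False):
                lines.append(
                    f"    c={row.conc:g} nM  k_obs={row.k_obs:.4g}/s  plateau={row.plateau:.4g}"
                )
        return "\n".join(lines)


def _fit_exponential(t, y):
    """Fit y = y_inf + (y0 - y_inf) exp(-k t) with t starting at 0.

    Initialised from log-linearised residuals against a provisional
    plateau; returns (y_inf, y0, k, k_se, rss).
    """
    y_inf0 = y[-1] + (y[-1] - y[0]) * 0.05
    resid = y_inf0 - y if y[-1] >= y[0] else y - y_inf0
    resid = np.maximum(np.abs(resid), 1e-12 * max(1.0, np.abs(y).max()))
    slope = np.polyfit(t, np.log(resid), 1)[0]
    k0 = max(-slope, 1e-6)

    def model(t, y_inf, y0, k):
        return y_inf + (y0 - y_inf) * np.exp(-k * t)

    with warnings.catch_warnings():
        # on noiseless data the fit is exact and the covariance is singular
        warnings.simplefilter("ignore", scipy.optimize.OptimizeWarning)
        popt, pcov = scipy.optimize.curve_fit(
            model, t, y, p0=(y_inf0, y[0], k0), maxfev=20_000
        )
    rss = float(np.sum((model(t, *popt) - y) ** 2))
    k_se = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.nan
    return popt[0], popt[1], popt[2], k_se, rss


class LangmuirModel:
    """Two-stage Langmuir fit of a step-series binding curve.

    Stage 1 fits sigma(t) = sigma_inf + (sigma_start - sigma_inf) *
    exp(-k_obs t) within each concentration step (>= ``min_points`` points
    required); stage 2 regresses k_obs on concentration (weighted by the
    inverse squared standard errors of k_obs when available): the slope is
    kon, the intercept koff. sigma_max comes from the plateau isotherm
    sigma_inf(c) = sigma_max * c / (c + Kd) with Kd = koff/kon.

    A step whose fitted k_obs is non-positive is excluded with a warning;
    fewer than two usable steps is an error.
    """

    def __init__(self, curve: BindingCurve, min_points: int = 10):
        if len(curve.steps) < 2:
            raise ValueError("need >= 2 concentration steps")
        self.curve = curve
        self.min_points = int(min_points)

    def fit(self) -> KineticFit:
        import pandas as pd

        t, y = self.curve.time, self.curve.sigma
        bounds = [s for s, _ in self.curve.steps] + [np.inf]
        rows = []
        rss_total = 0.0
        for (start, conc), stop in zip(self.curve.steps, bounds[1:]):
            sel = (t >= start) & (t < stop)
            if sel.sum() < self.min_points:
                warnings.warn(f"step at c={conc} nM has <{self.min_points} points; skipped")
                continue
            ts = t[sel] - t[sel][0]
            y_inf, y0, k, k_se, rss = _fit_exponential(ts, y[sel])
            rss_total += rss
            if k <= 0:
                warnings.warn(f"step at c={conc} nM fitted non-positive k_obs; excluded")
                continue
            rows.append((conc, k, k_se, y_inf))
        steps = pd.DataFrame(rows, columns=["conc", "k_obs", "k_obs_se", "plateau"])
        if len(steps) < 2:
            raise ValueError("fewer than 2 usable concentration steps")
        se = steps["k_obs_se"].to_numpy()
        w = 1.0 / se**2 if np.isfinite(se).all() and (se > 0).all() else np.ones(len(steps))
        X = sm.add_constant(steps["conc"].to_numpy())
        reg = sm.WLS(steps["k_obs"].to_numpy(), X, weights=w).fit()
        koff, kon = float(reg.params[0]), float(reg.params[1])
        if kon <= 0 or koff <= 0:
            raise ValueError(
                f"non-physical kinetic constants (kon={kon:.3g}, koff={koff:.3g});"
                " check step assignment and data quality"
            )
        kd = koff / kon
        x = steps["conc"].to_numpy() / (steps["conc"].to_numpy() + kd)
        plateaus = steps["plateau"].to_numpy()
        sigma_max = float(np.dot(x, plateaus) / np.dot(x, x))
        return KineticFit(kon=kon, koff=koff, sigma_max=sigma_max, steps=steps, residual_ss=rss_total)


def langmuir_fit(curve: BindingCurve, **kwargs) -> KineticFit:
    """Functional wrapper around :class:`LangmuirModel`."""
    return LangmuirModel(curve, **kwargs).fit()
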