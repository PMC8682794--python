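"""GC-bias correction of window counts by robust regression.

Sequencing depth depends systematically on local GC content. The model
here is deliberately simple and mirrors common read-depth CNV practice:
fit a robust linear relation count ~ gc (M-estimation with Huber
weighting), then rescale every window multiplicatively so that the fitted
expectation becomes flat. Correction factors are tabulated per GC bin, and
factor(w) = (mean fitted value over all windows) / (fitted value at gc(w)),
floored at 0.1 and capped at 10 so single extreme-GC windows cannot blow
up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .windows import WindowedCoverage

__all__ = ["GCBiasModel", "GCBiasResults", "fit_gc_model", "normalize"]

FACTOR_FLOOR = 0.1
FACTOR_CAP = 10.0


class GCBiasModel:
    """Robust linear model of window count on GC fraction.

    Parameters
    ----------
    counts : array-like
        Per-window read counts (one sample).
    gc : array-like
        Per-window GC fraction in [0, 1]; NaN windows are excluded from the
        fit and receive factor 1.
    bin_width : float
        Width of the GC bins used to tabulate the scaling factors.

    Examples
    --------
    >>> res = GCBiasModel(cov.counts, cov.gc).fit()
    >>> corrected = res.apply(cov)
    """

    def __init__(self, counts, gc, bin_width: float = 0.01):
        self.counts = np.asarray(counts, dtype=float)
        self.gc = np.asarray(gc, dtype=float)
        if self.counts.shape != self.gc.shape:
            raise ValueError("counts and gc must have the same length")
        self.bin_width = float(bin_width)
        self._ok = ~np.isnan(self.gc)
        if self._ok.sum() < 100:
            raise ValueError("need >= 100 windows with defined GC to fit the bias model")
        if not self.counts[self._ok].any():
            raise ValueError("all counts are zero; nothing to normalize")

    def fit(self, tuning: float = 1.345, maxiter: int = 50, tol: float = 1e-8) -> "GCBiasResults":
        """Fit by iteratively reweighted least squares (Huber M-estimator).

        Iterates to relative coefficient change < *tol* or *maxiter*
        iterations. If the fitted line goes non-positive at any observed GC,
        falls back to a robust fit on the log scale with a warning.
        """
        y = self.counts[self._ok]
        x = self.gc[self._ok]
        X = sm.add_constant(x)
        norm = sm.robust.norms.HuberT(t=tuning)
        res = sm.RLM(y, X, M=norm).fit(maxiter=maxiter, tol=tol, conv="coefs")
        fitted = res.params[0] + res.params[1] * x
        log_scale = False
        if (fitted <= 0).any():
            warnings.warn("fitted count non-positive at some observed GC; refitting on the log scale")
            res = sm.RLM(np.log(y + 0.5), X, M=norm).fit(maxiter=maxiter, tol=tol, conv="coefs")
            fitted = np.exp(res.params[0] + res.params[1] * x) - 0.5
            fitted = np.maximum(fitted, 1e-6)
            log_scale = True
        mean_fitted = float(np.mean(fitted))

        # tabulate factors per GC bin over the full [0, 1] range
        edges = np.arange(0.0, 1.0 + self.bin_width, self.bin_width)
        centers = 0.5 * (edges[:-1] + edges[1:])
        if log_scale:
            fit_at = np.maximum(np.exp(res.params[0] + res.params[1] * centers) - 0.5, 1e-6)
        else:
            fit_at = res.params[0] + res.params[1] * centers
        with np.errstate(divide="ignore", invalid="ignore"):
            factors = np.where(fit_at > 0, mean_fitted / fit_at, FACTOR_CAP)
        factors = np.clip(factors, FACTOR_FLOOR, FACTOR_CAP)
        return GCBiasResults(
            model=self,
            params=np.asarray(res.params, dtype=float),
            log_scale=log_scale,
            mean_fitted=mean_fitted,
            bin_edges=edges,
            scaling=factors,
            weighting=f"HuberT(t={tuning})",
        )


@dataclass
class GCBiasResults:
    """Fitted GC-bias correction: coefficients plus per-GC-bin factors."""

    model: GCBiasModel
    params: np.ndarray       # (intercept, slope), possibly on the log scale
    log_scale: bool
    mean_fitted: float
    bin_edges: np.ndarray
    scaling: np.ndarray      # multiplicative factor per GC bin, in (0.1, 10)
    weighting: str

    @property
    def slope(self) -> float:
        """Robust slope of count on GC (log-scale slope if fallback fired)."""
        return float(self.params[1])

    def factor(self, gc) -> np.ndarray:
        """Multiplicative correction factor for windows at GC *gc* (NaN -> 1)."""
        gc = np.asarray(gc, dtype=float)
        idx = np.clip(
            np.searchsorted(self.bin_edges, np.nan_to_num(gc, nan=0.5), side="right") - 1,
            0,
            len(self.scaling) - 1,
        )
        out = self.scaling[idx]
        return np.where(np.isnan(gc), 1.0, out)

    def apply(self, coverage: WindowedCoverage) -> WindowedCoverage:
        """Return a GC-corrected copy of *coverage* (raw counts preserved)."""
        if coverage.gc is None:
            raise ValueError("coverage has no GC vector attached")
        if len(coverage.counts) != len(self.model.counts):
            raise ValueError("window grid mismatch between model and coverage")
        corrected = coverage.counts * self.factor(coverage.gc)
        return WindowedCoverage(
            windows=coverage.windows,
            counts=corrected,
            sample_id=coverage.sample_id,
            total_mapped=float(corrected.sum()),
            gc=coverage.gc,
            raw_counts=np.array(coverage.counts, copy=True),
        )

    def to_dict(self) -> dict:
        return {
            "params": self.params.tolist(),
            "log_scale": self.log_scale,
            "weighting": self.weighting,
            "mean_fitted": self.mean_fitted,
            "bin_edges": self.bin_edges.tolist(),
            "scaling": self.scaling.tolist(),
        }

    def summary(self) -> str:
        lines = [
            "GC bias correction (robust linear fit)",
            f"  weighting     : {self.weighting}",
            f"  scale         : {'log' if self.log_scale else 'linear'}",
            f"  intercept     : {self.params[0]:.4f}",
            f"  slope         : {self.params[1]:.4f}",
            f"  mean fitted   : {self.mean_fitted:.3f}",
            f"  factor range  : [{self.scaling.min():.3f}, {self.scaling.max():.3f}]",
        ]
        return "\n".join(lines)


def robust_slope(counts, gc, tuning: float = 1.345) -> float:
    """Robust (Huber) slope of count on gc; NaN-GC windows excluded."""
    counts = np.asarray(counts, dtype=float)
    gc = np.asarray(gc, dtype=float)
    ok = ~np.isnan(gc)
    X = sm.add_constant(gc[ok])
    res = sm.RLM(counts[ok], X, M=sm.robust.norms.HuberT(t=tuning)).fit(conv="coefs", tol=1e-8, maxiter=50)
    return float(res.params[1])


def fit_gc_model(coverage: WindowedCoverage, gc=None, **kwargs) -> GCBiasResults:
    """Functional wrapper: fit the GC-bias model for one sample."""
    gc = coverage.gc if gc is None else gc
    if gc is None:
        raise ValueError("GC vector required (attach to coverage or pass explicitly)")
    return GCBiasModel(coverage.counts, gc, **kwargs).fit()


def normalize(coverage: WindowedCoverage, model: GCBiasResults) -> WindowedCoverage:
    """Apply a fitted GC model to a coverage track on the same grid."""
    return model.apply(coverage)
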