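"""Luria-Delbrueck fluctuation analysis by MSS maximum likelihood.

Parallel cultures grown from small inocula accumulate mutants in jackpots:
the mutant-count distribution is the Luria-Delbrueck distribution, fully
determined by m, the expected number of mutation events per culture. Its
pmf follows the Ma-Sandri-Sarkar (MSS) recursion

    p_0 = exp(-m),    p_r = (m / r) * sum_{i=0}^{r-1} p_i / (r - i + 1)

which is the Panjer recursion of a compound Poisson: N ~ Poisson(m)
mutation events, each founding a clone whose final size K has
P(K >= k) = 1/k. The distribution is heavy-tailed (p_r ~ m / r**2, so the
mean is infinite and the mass beyond a truncation point r_max is ~m/r_max);
likelihoods therefore right-censor extreme jackpot counts rather than
chasing the tail.

The MLE of m maximises sum_i log p_{r_i}(m); a 95% confidence interval
comes from the profile-likelihood drop of 1.92 log-units, and the mutation
rate is m / Nt with Nt the number of viable cells per culture. Partial
plating (a fraction f < 1 of each culture plated) is handled by binomial
thinning of the pmf, which is the exact likelihood for that design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.stats

__all__ = [
    "mss_pmf",
    "thin_pmf",
    "FluctuationExperiment",
    "FluctuationModel",
    "FluctuationResults",
    "mss_mle",
    "fold_enrichment",
    "FoldEnrichment",
]

_CHI2_95_HALF = 1.92072941  # qchisq(0.95, 1) / 2
DEFAULT_CENSOR_CAP = 10_000


def mss_pmf(m: float, r_max: int | None = None, tail: float = 1e-6, hard_cap: int = 200_000) -> np.ndarray:
    """Luria-Delbrueck pmf p_0..p_r_max by the MSS recursion.

    With ``r_max=None`` the support is extended until the residual tail
    mass falls below *tail* or *hard_cap* is reached. Because the tail
    decays only like m/r, very small *tail* targets are expensive:
    reaching 1e-6 for m=2 already needs r_max ~ 2e6.

    m = 0 gives a point mass at zero; p_0 = exp(-m) exactly for all m.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    n_out = (r_max + 1) if r_max is not None else None
    if m == 0:
        p = np.zeros(n_out or 1)
        p[0] = 1.0
        return p
    cap = r_max if r_max is not None else hard_cap
    p = np.zeros(cap + 1)
    p[0] = np.exp(-m)
    recip = 1.0 / np.arange(2, cap + 2)  # recip[j] = 1/(j + 2)
    total = p[0]
    for r in range(1, cap + 1):
        p[r] = (m / r) * np.dot(p[:r], recip[:r][::-1])
        total += p[r]
        if r_max is None and 1.0 - total < tail:
            return p[: r + 1]
    return p


def thin_pmf(p: np.ndarray, fraction: float) -> np.ndarray:
    """Binomial thinning of a count pmf: each mutant is plated w.p. *fraction*."""
    if not (0 < fraction <= 1):
        raise ValueError("plating fraction must be in (0, 1]")
    if fraction == 1:
        return p
    rmax = len(p) - 1
    ks = np.arange(rmax + 1)
    out = np.zeros(rmax + 1)
    for r in range(rmax + 1):
        out[: r + 1] += p[r] * scipy.stats.binom.pmf(ks[: r + 1], r, fraction)
    return out


@dataclass
class FluctuationExperiment:
    """One fluctuation test: mutant counts per culture plus culture size.

    ``Nt`` is the number of viable cells per culture (typically measured
    once per strain from permissive plates); per-culture Nt is supported by
    running one experiment per culture.
    """

    counts: np.ndarray
    Nt: float
    plating_fraction: float = 1.0
    strain: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or len(self.counts) < 1:
            raise ValueError("need a 1-d vector with at least one culture")
        if (self.counts < 0).any():
            raise ValueError("mutant counts must be non-negative")
        if self.Nt <= 0:
            raise ValueError("Nt must be positive")
        if not (0 < self.plating_fraction <= 1):
            raise ValueError("plating fraction must be in (0, 1]")


class FluctuationModel:
    """MSS maximum-likelihood estimation of the mutation number m.

    Parameters
    ----------
    experiment : FluctuationExperiment
    censor_cap : int
        Counts above this value contribute P(R >= cap) to the likelihood
        (right censoring). The exact value of an extreme jackpot carries
        almost no information about m, and censoring keeps the pmf
        recursion bounded.

    Examples
    --------
    >>> exp = FluctuationExperiment(counts, Nt=2e7, strain="vid22")
    >>> res = FluctuationModel(exp).fit()
    >>> res.m, res.rate, res.ci95
    """

    def __init__(self, experiment: FluctuationExperiment, censor_cap: int = DEFAULT_CENSOR_CAP):
        self.experiment = experiment
        self.censor_cap = int(censor_cap)
        counts = experiment.counts
        self._censored = counts >= self.censor_cap
        self._obs = np.minimum(counts, self.censor_cap)
        self._r_max = int(self._obs.max())

    def _pmf(self, m: float) -> np.ndarray:
        f = self.experiment.plating_fraction
        if f == 1:
            return mss_pmf(m, r_max=self._r_max)
        # thinning moves mass downward only; give the raw pmf headroom so
        # raw counts beyond the window that would thin into it are captured
        raw_max = min(int(np.ceil(self._r_max / f)) + 20, 4 * self.censor_cap)
        return thin_pmf(mss_pmf(m, r_max=raw_max), f)[: self._r_max + 1]

    def loglike(self, m: float) -> float:
        if m <= 0:
            return 0.0 if self._r_max == 0 else -np.inf
        p = self._pmf(m)
        ll = 0.0
        uncens = ~self._censored
        vals = p[self._obs[uncens]]
        if (vals <= 0).any():
            return -np.inf
        ll += float(np.sum(np.log(vals)))
        if self._censored.any():
            tail_mass = max(1.0 - float(p[: self.censor_cap].sum()), 1e-300)
            ll += float(self._censored.sum()) * np.log(tail_mass)
        return ll

    def fit(self) -> "FluctuationResults":
        exp = self.experiment
        n = len(exp.counts)
        if self._r_max == 0:
            # log-likelihood n * (-m * f_eff) is monotone decreasing in m:
            # boundary MLE at 0; one-sided upper CI from the 1.92 drop
            upper = _CHI2_95_HALF / n  # exp(-m)^n drop; thinning only widens
            return FluctuationResults(self, m=0.0, ci95=(0.0, float(upper)), llf=0.0)
        frac0 = max(float(np.mean(exp.counts == 0)), 1.0 / (2 * n + 2))
        m0 = -np.log(frac0)  # p0-method pilot estimate (pre-thinning scale)
        m_hi = max(2 * (m0 + 5), 2.0 * float(np.minimum(exp.counts, 100).mean()))
        res = scipy.optimize.minimize_scalar(
            lambda m: -self.loglike(m),
            bounds=(1e-9, m_hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        m_hat = float(res.x)
        llf = -float(res.fun)

        def drop(m):
            return self.loglike(m) - (llf - _CHI2_95_HALF)

        lo = 0.0
        if drop(1e-12) < 0:
            lo = float(scipy.optimize.brentq(drop, 1e-12, m_hat, xtol=1e-10))
        hi_bracket = max(m_hi, 2 * m_hat)
        while drop(hi_bracket) > 0:
            hi_bracket *= 2
            if hi_bracket > 1e8:
                raise RuntimeError("profile CI upper bound did not bracket")
        hi = float(scipy.optimize.brentq(drop, m_hat, hi_bracket, xtol=1e-10))
        return FluctuationResults(self, m=m_hat, ci95=(lo, hi), llf=llf)


@dataclass
class FluctuationResults:
    """MSS-MLE mutation number, rate per cell, and profile-likelihood CI."""

    model: FluctuationModel
    m: float
    ci95: tuple
    llf: float

    @property
    def rate(self) -> float:
        """Mutation rate per cell per generation-equivalent, m / Nt."""
        return self.m / self.model.experiment.Nt

    @property
    def rate_ci95(self) -> tuple:
        Nt = self.model.experiment.Nt
        return (self.ci95[0] / Nt, self.ci95[1] / Nt)

    def p0_estimate(self) -> float:
        """Independent cross-check: m = -ln(fraction of zero cultures)."""
        frac0 = float(np.mean(self.model.experiment.counts == 0))
        if frac0 == 0:
            return np.nan
        return -np.log(frac0)

    def summary(self) -> str:
        exp = self.model.experiment
        return (
            "Fluctuation test (MSS maximum likelihood){}\n"
            "  cultures       : {}\n"
            "  Nt             : {:.3g} cells/culture\n"
            "  m (MLE)        : {:.4g}   95% CI [{:.4g}, {:.4g}]\n"
            "  rate (m/Nt)    : {:.4g}   95% CI [{:.4g}, {:.4g}]\n"
            "  log-likelihood : {:.4f}".format(
                f" - {exp.strain}" if exp.strain else "",
                len(exp.counts),
                exp.Nt,
                self.m,
                *self.ci95,
                self.rate,
                *self.rate_ci95,
                self.llf,
            )
        )


def mss_mle(experiment: FluctuationExperiment, **kwargs) -> FluctuationResults:
    """Functional wrapper around :class:`FluctuationModel`."""
    return FluctuationModel(experiment, **kwargs).fit()


@dataclass
class FoldEnrichment:
    """Rate ratio between two strains, optionally per replicate pair."""

    numerator: str
    denominator: str
    fold: float
    replicate_folds: np.ndarray | None = None

    @property
    def mean_fold(self) -> float:
        if self.replicate_folds is None:
            return self.fold
        return float(np.mean(self.replicate_folds))


def fold_enrichment(a, b) -> FoldEnrichment:
    """Fold change of mutation rates, a over b.

    *a* and *b* are FluctuationResults or same-length lists of them
    (independent replicate tests, paired in order); with replicates the
    per-pair folds and their mean are reported. A zero numerator rate
    gives fold 0; a zero denominator rate is undefined and raises.
    """
    a_list = list(a) if isinstance(a, (list, tuple)) else [a]
    b_list = list(b) if isinstance(b, (list, tuple)) else [b]
    if len(a_list) != len(b_list):
        raise ValueError("replicate lists must pair up")
    folds = []
    for ra, rb in zip(a_list, b_list):
        if rb.rate == 0:
            raise ZeroDivisionError("denominator rate is zero; fold undefined")
        folds.append(ra.rate / rb.rate)
    folds = np.asarray(folds)
    name_a = a_list[0].model.experiment.strain or "a"
    name_b = b_list[0].model.experiment.strain or "b"
    return FoldEnrichment(
        numerator=name_a,
        denominator=name_b,
        fold=float(folds.mean()),
        replicate_folds=folds if len(folds) > 1 else None,
    )
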