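"""CNV detection by pairwise window tests against a control sample.

Pipeline: GC-normalise each sample independently, then for every window
compare the mutant count with the control count by a 1-df Pearson
chi-squared test on the 2x2 table

    [[wt_w, wt_total - wt_w],
     [mut_w, mut_total - mut_w]]

(window versus rest-of-library homogeneity; uses both library sizes; a
goodness-of-fit variant is available behind ``layout="gof"``).
Benjamini-Hochberg correction is applied across all tested windows of the
pair; significant windows of the same direction whose spans overlap or
adjoin are merged, and merged intervals are kept as calls iff the span
strictly exceeds ``min_span_bp`` and they contain at least ``min_windows``
supporting windows. Whole-chromosome duplications are flagged from
median depth ratios, and mitochondrial copy number from RPKM ratios
against single-copy nuclear genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .gcnorm import GCBiasModel
from .windows import WindowedCoverage

__all__ = [
    "test_windows",
    "merge_calls",
    "chromosome_ploidy",
    "mtdna_copy_number",
    "quantile_normalize",
    "CNVModel",
    "CNVResults",
]


def test_windows(
    wt: WindowedCoverage,
    mut: WindowedCoverage,
    fdr_cutoff: float = 0.05,
    layout: str = "window-vs-rest",
) -> pd.DataFrame:
    """Per-window chi-squared tests of the mutant against the control.

    Windows where both samples have zero counts are excluded (p, q = NaN,
    never significant). Returns a DataFrame aligned to the grid with
    columns wt, mut, ratio (mutant/control normalised coverage), p, q,
    significant.
    """
    if not wt.same_grid(mut):
        raise ValueError("wt and mut must share one window grid")
    wt_c = np.asarray(wt.counts, dtype=float)
    mut_c = np.asarray(mut.counts, dtype=float)
    wt_tot = float(wt_c.sum())
    mut_tot = float(mut_c.sum())
    if wt_tot <= 0 or mut_tot <= 0:
        raise ValueError("both samples need non-zero totals")

    tested = (wt_c + mut_c) > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (mut_c / mut_tot) / np.where(wt_c > 0, wt_c / wt_tot, np.nan)
    p = np.full(len(wt_c), np.nan)
    if layout == "window-vs-rest":
        # Pearson chi-squared on [[a, b], [c, d]], 1 df, no continuity corr.
        a, c = wt_c[tested], mut_c[tested]
        b, d = wt_tot - a, mut_tot - c
        n = a + b + c + d
        stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        p[tested] = scipy.stats.chi2.sf(stat, df=1)
    elif layout == "gof":
        # goodness of fit of the mutant count against the depth-scaled control
        a, c = wt_c[tested], mut_c[tested]
        expected = a * (mut_tot / wt_tot)
        ok = expected > 0
        stat = np.full(tested.sum(), np.inf)
        stat[ok] = (c[ok] - expected[ok]) ** 2 / expected[ok]
        p[tested] = scipy.stats.chi2.sf(stat, df=1)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    q = np.full(len(wt_c), np.nan)
    q[tested] = multipletests(p[tested], method="fdr_bh")[1]
    out = wt.windows[["chrom", "start", "end"]].copy()
    out["wt"] = wt_c
    out["mut"] = mut_c
    out["ratio"] = ratio
    out["p"] = p
    out["q"] = q
    out["significant"] = (q < fdr_cutoff) & tested
    out.attrs["layout"] = layout
    out.attrs["fdr_cutoff"] = fdr_cutoff
    return out


def merge_calls(
    tests: pd.DataFrame,
    min_span_bp: int = 500,
    min_windows: int = 3,
) -> pd.DataFrame:
    """Merge significant same-direction windows into CNV calls.

    Windows whose spans overlap or adjoin are merged; runs are broken at
    chromosome boundaries and at direction changes (a gain run adjacent to
    a loss run yields two candidate intervals). Merged intervals are kept
    iff span > min_span_bp (strict) and n_windows >= min_windows.
    """
    sig = tests[tests["significant"]].copy()
    if len(sig) == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "direction", "n_windows", "mean_ratio", "min_q"]
        )
    # a window with mutant coverage 0 has ratio 0 -> loss; ratio NaN can
    # only arise with wt == 0, an (infinite-ratio) gain
    direction = np.where(np.nan_to_num(sig["ratio"], nan=np.inf) > 1, "gain", "loss")
    sig["direction"] = direction
    sig = sig.sort_values(["chrom", "start"], kind="mergesort")
    calls = []
    cur = None
    for row in sig.itertuples(index=False):
        if (
            cur is not None
            and row.chrom == cur["chrom"]
            and row.direction == cur["direction"]
            and row.start <= cur["end"]
        ):
            cur["end"] = max(cur["end"], row.end)
            cur["n"] += 1
            cur["ratios"].append(row.ratio)
            cur["min_q"] = min(cur["min_q"], row.q)
        else:
            if cur is not None:
                calls.append(cur)
            cur = {
                "chrom": row.chrom,
                "start": row.start,
                "end": row.end,
                "direction": row.direction,
                "n": 1,
                "ratios": [row.ratio],
                "min_q": row.q,
            }
    calls.append(cur)
    rows = [
        (
            c["chrom"],
            c["start"],
            c["end"],
            c["direction"],
            c["n"],
            float(np.nanmean(np.asarray(c["ratios"], dtype=float))),
            c["min_q"],
        )
        for c in calls
        if (c["end"] - c["start"]) > min_span_bp and c["n"] >= min_windows
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "direction", "n_windows", "mean_ratio", "min_q"]
    )


def chromosome_ploidy(
    wt: WindowedCoverage,
    mut: WindowedCoverage,
    gain_threshold: float = 1.75,
    min_windows: int = 10,
) -> pd.DataFrame:
    """Per-chromosome depth ratios and whole-chromosome duplication flags.

    Each sample's per-chromosome median window count is rescaled by its
    genome-wide median (so a global depth difference between the samples
    cancels); the reported ratio is mutant over control. With a haploid
    baseline, a chromosome is flagged duplicated iff ratio >=
    gain_threshold. Chromosomes with fewer than *min_windows* windows get
    a ratio but a suppressed flag and a warning.
    """
    if not wt.same_grid(mut):
        raise ValueError("wt and mut must share one window grid")
    wt_med = float(np.median(wt.counts))
    mut_med = float(np.median(mut.counts))
    if wt_med <= 0 or mut_med <= 0:
        raise ValueError("genome-wide median coverage must be positive")
    rows = []
    for chrom, sub in wt.windows.groupby("chrom", sort=True):
        idx = sub.index.to_numpy()
        n = len(idx)
        wt_rel = np.median(wt.counts[idx]) / wt_med
        mut_rel = np.median(mut.counts[idx]) / mut_med
        ratio = mut_rel / wt_rel if wt_rel > 0 else np.nan
        flag = bool(ratio >= gain_threshold) if n >= min_windows and np.isfinite(ratio) else False
        if n < min_windows:
            warnings.warn(f"chromosome {chrom!r} has only {n} windows; duplication flag suppressed")
        rows.append((chrom, n, ratio, flag))
    return pd.DataFrame(rows, columns=["chrom", "n_windows", "ratio", "duplicated"])


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalise columns of a per-gene value matrix.

    Each column is replaced by the mean of the sorted columns at its rank
    (ties get the mean of the tied ranks). Offered as an optional pre-step
    for cross-sample mtDNA comparisons.
    """
    ranks = df.rank(method="average")
    sorted_means = pd.DataFrame(np.sort(df.to_numpy(), axis=0)).mean(axis=1).to_numpy()
    # interpolate mean profile at (possibly fractional) ranks
    grid = np.arange(1, len(df) + 1, dtype=float)
    out = {
        col: np.interp(ranks[col].to_numpy(), grid, sorted_means)
        for col in df.columns
    }
    return pd.DataFrame(out, index=df.index)


@dataclass
class MtCopyNumber:
    sample_id: str
    mt_rpkm: float
    nuclear_single_copy_mean_rpkm: float

    @property
    def copy_number(self) -> float:
        return self.mt_rpkm / self.nuclear_single_copy_mean_rpkm


def mtdna_copy_number(
    feature_counts: pd.DataFrame,
    total_mapped: float,
    sample_id: str = "sample",
    invert: bool = False,
) -> MtCopyNumber:
    """Mitochondrial copy number from RPKM ratios.

    *feature_counts* has one row per feature with columns ``length`` (bp),
    ``count`` (reads), ``is_mt`` (bool) and ``is_single_copy`` (bool,
    nuclear single-copy genes only). RPKM = count / (length_kb *
    total_mapped_millions); the copy number is mt RPKM over the mean RPKM
    of the single-copy nuclear set, so more mitochondria means a larger
    number (pass ``invert=True`` for the reciprocal convention). Relative
    copy number across samples is each sample's value divided by the
    control's.
    """
    if total_mapped <= 0:
        raise ValueError("total mapped reads must be positive")
    fc = feature_counts
    if (fc["length"] <= 0).any():
        raise ValueError("feature lengths must be positive")
    single = fc[fc["is_single_copy"] & ~fc["is_mt"]]
    mt = fc[fc["is_mt"]]
    if len(single) == 0:
        raise ValueError("single-copy nuclear gene set is empty")
    if len(mt) == 0:
        raise ValueError("no mitochondrial feature provided")
    rpkm = fc["count"] / ((fc["length"] / 1e3) * (total_mapped / 1e6))
    mt_rpkm = float(rpkm[mt.index].mean())
    nuc_rpkm = float(rpkm[single.index].mean())
    if invert:
        mt_rpkm, nuc_rpkm = nuc_rpkm, mt_rpkm
    return MtCopyNumber(sample_id=sample_id, mt_rpkm=mt_rpkm, nuclear_single_copy_mean_rpkm=nuc_rpkm)


class CNVModel:
    """Paired-sample CNV caller (control vs mutant) on a shared grid.

    Thin modelling facade over :func:`test_windows` / :func:`merge_calls`:
    optionally GC-normalises both samples (each with its own robust fit),
    runs the per-window tests with BH correction, and merges significant
    windows into calls.

    Parameters
    ----------
    wt, mut : WindowedCoverage
        Control and test sample on the identical window grid.
    normalize_gc : bool
        Fit and apply a per-sample GC model before testing (requires ``gc``
        attached to both coverages).
    fdr_cutoff, min_span_bp, min_windows
        Significance and call-filter settings.
    """

    def __init__(
        self,
        wt: WindowedCoverage,
        mut: WindowedCoverage,
        normalize_gc: bool = True,
        fdr_cutoff: float = 0.05,
        min_span_bp: int = 500,
        min_windows: int = 3,
        layout: str = "window-vs-rest",
    ):
        if not wt.same_grid(mut):
            raise ValueError("wt and mut must share one window grid")
        self.wt = wt
        self.mut = mut
        self.normalize_gc = normalize_gc
        self.fdr_cutoff = fdr_cutoff
        self.min_span_bp = min_span_bp
        self.min_windows = min_windows
        self.layout = layout

    def fit(self) -> "CNVResults":
        wt, mut = self.wt, self.mut
        gc_fits = {}
        if self.normalize_gc:
            for name in ("wt", "mut"):
                cov = getattr(self, name)
                res = GCBiasModel(cov.counts, cov.gc).fit()
                gc_fits[name] = res
            wt = gc_fits["wt"].apply(wt)
            mut = gc_fits["mut"].apply(mut)
        tests = test_windows(wt, mut, fdr_cutoff=self.fdr_cutoff, layout=self.layout)
        calls = merge_calls(tests, min_span_bp=self.min_span_bp, min_windows=self.min_windows)
        return CNVResults(model=self, wt=wt, mut=mut, window_tests=tests, calls=calls, gc_fits=gc_fits)


@dataclass
class CNVResults:
    """CNV calls plus the per-window evidence behind them."""

    model: CNVModel
    wt: WindowedCoverage
    mut: WindowedCoverage
    window_tests: pd.DataFrame
    calls: pd.DataFrame
    gc_fits: dict = field(default_factory=dict)

    def chromosome_ploidy(self, gain_threshold: float = 1.75) -> pd.DataFrame:
        return chromosome_ploidy(self.wt, self.mut, gain_threshold=gain_threshold)

    def summary(self) -> str:
        t = self.window_tests
        n_sig = int(t["significant"].sum())
        lines = [
            "Paired read-depth CNV comparison",
            f"  samples        : {self.wt.sample_id} (control) vs {self.mut.sample_id}",
            f"  windows tested : {int(t['p'].notna().sum())} / {len(t)}",
            f"  significant    : {n_sig} at FDR < {self.model.fdr_cutoff}",
            f"  CNV calls      : {len(self.calls)} "
            f"(span > {self.model.min_span_bp} bp, >= {self.model.min_windows} windows)",
        ]
        for row in self.calls.itertuples(index=False):
            lines.append(
                f"    {row.chrom}:{row.start}-{row.end}  {row.direction}"
                f"  n={row.n_windows}  ratio={row.mean_ratio:.2f}  q={row.min_q:.2e}"
            )
        return "\n".join(lines)

    def plot_ratio(self, chrom: str, ax=None):
        """Plot the per-window mutant/control ratio along one chromosome."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 2.5))
        sub = self.window_tests[self.window_tests["chrom"] == chrom]
        ax.plot(sub["start"], sub["ratio"], ".", ms=2, color="0.5")
        sig = sub[sub["significant"]]
        ax.plot(sig["start"], sig["ratio"], ".", ms=3, color="crimson")
        ax.axhline(1.0, color="k", lw=0.5)
        ax.set_xlabel(f"{chrom} position (bp)")
        ax.set_ylabel("coverage ratio")
        return ax
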