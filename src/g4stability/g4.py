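"""G-quadruplex motif scanning and CNV-G4 association statistics.

The scanner looks for the canonical intramolecular G4 motif: at least
``min_runs`` runs of >= ``min_run_len`` consecutive guanines separated by
loops of ``loop_min``..``loop_max`` nucleotides, on either strand (C-runs
on the forward strand are G-runs on the reverse). Overlapping matches are
merged into one motif per locus so nested matches do not inflate counts.

Association of a query interval set (e.g. CNV calls) with G4 elements is
measured two ways: (i) an exact 2x2 test classifying every window of a
genome-wide grid by overlap with the query and with G4s (Fisher two-sided
and one-sided hypergeometric upper tail), and (ii) an empirical
closer-than-expected test, comparing the observed distances to the nearest
G4 against replicates in which length-matched intervals are placed
uniformly at random genome-wide.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import IntervalSet, distance_to_nearest, merge_intervals, overlaps_any

__all__ = [
    "G4Motif",
    "scan_g4",
    "EnrichmentResult",
    "fisher_exact_2x2",
    "hypergeom_upper",
    "overlap_enrichment",
    "DistanceNull",
    "resample_null",
]


@dataclass
class G4Motif:
    """One G4-forming locus (possibly merging several raw matches)."""

    start: int
    end: int
    strand: str
    sequence: str
    g_runs: list = field(default_factory=list)   # run lengths, >= min_runs entries
    loops: list = field(default_factory=list)    # loop lengths between runs
    chrom: str | None = None


def _runs(seq: str, base: str, min_len: int) -> list[tuple[int, int]]:
    return [(m.start(), m.end()) for m in re.finditer(f"{base}{{{min_len},}}", seq)]


def _chain_runs(runs, min_runs, loop_min, loop_max):
    """Group maximal runs into chains whose inter-run gaps fit the loop bounds."""
    chains, cur = [], []
    for r in runs:
        if cur and not (loop_min <= r[0] - cur[-1][1] <= loop_max):
            if len(cur) >= min_runs:
                chains.append(cur)
            cur = []
        cur.append(r)
    if len(cur) >= min_runs:
        chains.append(cur)
    return chains


def scan_g4(
    sequence: str,
    min_run_len: int = 3,
    min_runs: int = 4,
    loop_min: int = 1,
    loop_max: int = 25,
    chrom: str | None = None,
) -> list[G4Motif]:
    """Scan a sequence for G4 motifs on both strands.

    Maximal G-runs (and C-runs, for the reverse strand) are chained left to
    right while consecutive runs are separated by loop_min..loop_max nt;
    every maximal chain of >= min_runs runs is one motif spanning the first
    to the last run. Motifs from the two strands that overlap are merged
    into a single locus (strand reported as ``+/-``).
    """
    if loop_max < loop_min:
        raise ValueError("loop_max must be >= loop_min")
    if loop_min < 1:
        raise ValueError("loop_min must be >= 1 (maximal runs cannot touch)")
    seq = sequence.upper()
    if re.search("[^ACGTN]", seq):
        raise ValueError("sequence must be over the alphabet {A,C,G,T,N}")
    raw = []
    for base, strand in (("G", "+"), ("C", "-")):
        for chain in _chain_runs(_runs(seq, base, min_run_len), min_runs, loop_min, loop_max):
            s, e = chain[0][0], chain[-1][1]
            raw.append((s, e, strand, chain))
    if not raw:
        return []
    raw.sort()
    motifs = []
    cur_s, cur_e, strands = raw[0][0], raw[0][1], {raw[0][2]}
    chains = [raw[0][3]]
    for s, e, strand, chain in raw[1:]:
        if s < cur_e:  # overlapping matches merge into one locus
            cur_e = max(cur_e, e)
            strands.add(strand)
            chains.append(chain)
        else:
            motifs.append((cur_s, cur_e, strands, chains))
            cur_s, cur_e, strands, chains = s, e, {strand}, [chain]
    motifs.append((cur_s, cur_e, strands, chains))
    out = []
    for s, e, strands, chains in motifs:
        chain = chains[0]
        g_runs = [b - a for a, b in chain]
        loops = [chain[i + 1][0] - chain[i][1] for i in range(len(chain) - 1)]
        out.append(
            G4Motif(
                start=s,
                end=e,
                strand="+/-" if len(strands) == 2 else next(iter(strands)),
                sequence=seq[s:e],
                g_runs=g_runs,
                loops=loops,
                chrom=chrom,
            )
        )
    return out


def scan_genome(sequences: dict, **kwargs) -> IntervalSet:
    """Scan every chromosome of a genome; motifs as an IntervalSet."""
    rows = []
    for chrom in sorted(sequences):
        for m in scan_g4(sequences[chrom], chrom=chrom, **kwargs):
            rows.append((chrom, m.start, m.end))
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


# ---------------------------------------------------------------------------
# exact overlap tests

def _hypergeom_pmf_support(a, b, c, d):
    """Hypergeometric pmf over the full support of a 2x2 table's margins."""
    from scipy.special import gammaln

    N = a + b + c + d
    K = a + b          # row-1 margin
    n = a + c          # column-1 margin
    k_min = max(0, K + n - N)
    k_max = min(K, n)
    ks = np.arange(k_min, k_max + 1)
    log_pmf = (
        gammaln(K + 1) - gammaln(ks + 1) - gammaln(K - ks + 1)
        + gammaln(N - K + 1) - gammaln(n - ks + 1) - gammaln(N - K - n + ks + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return ks, np.exp(log_pmf)


def fisher_exact_2x2(a, b, c, d) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums the probabilities of all tables with the same margins whose pmf
    does not exceed the observed pmf by more than a relative guard of 1e-7
    (the usual tie convention for two-sided exact tests).
    """
    ks, pmf = _hypergeom_pmf_support(a, b, c, d)
    if len(ks) == 1:
        return 1.0
    p_obs = pmf[np.searchsorted(ks, a)]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def hypergeom_upper(a, b, c, d) -> float:
    """One-sided (enrichment) hypergeometric upper-tail p, P(X >= a)."""
    ks, pmf = _hypergeom_pmf_support(a, b, c, d)
    return float(min(1.0, pmf[ks >= a].sum()))


@dataclass
class EnrichmentResult:
    """2x2 overlap classification of a window universe and its exact tests."""

    table: np.ndarray            # [[both, query only], [g4 only, neither]]
    odds_ratio: float
    p_fisher: float              # two-sided Fisher exact
    p_hypergeom: float           # one-sided upper tail (enrichment)
    unit: str = "windows"

    def summary(self) -> str:
        (a, b), (c, d) = self.table
        return (
            "G4 overlap enrichment (unit = {})\n"
            "  both={}  query_only={}  g4_only={}  neither={}\n"
            "  odds ratio      : {:.3g}\n"
            "  Fisher two-sided: {:.3g}\n"
            "  hypergeom upper : {:.3g}".format(
                self.unit, a, b, c, d, self.odds_ratio, self.p_fisher, self.p_hypergeom
            )
        )


def overlap_enrichment(
    query: IntervalSet,
    g4: IntervalSet,
    universe: pd.DataFrame,
) -> EnrichmentResult:
    """Exact tests for query/G4 co-occurrence over a window universe.

    Every window of *universe* (chrom/start/end grid covering both sets) is
    classified by whether it overlaps the query and whether it overlaps a
    G4 element; Fisher's exact two-sided p and the one-sided hypergeometric
    upper tail are computed on the resulting 2x2 table. The odds ratio uses
    a Haldane (+0.5) correction when any cell is zero.
    """
    chroms = universe["chrom"].to_numpy()
    starts = universe["start"].to_numpy()
    ends = universe["end"].to_numpy()
    in_q = overlaps_any(chroms, starts, ends, query)
    in_g = overlaps_any(chroms, starts, ends, g4)
    a = int((in_q & in_g).sum())
    b = int((in_q & ~in_g).sum())
    c = int((~in_q & in_g).sum())
    d = int((~in_q & ~in_g).sum())
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        warnings.warn("degenerate margins: all windows fall in one class; p set to 1")
        p2, p1 = 1.0, 1.0
    else:
        p2 = fisher_exact_2x2(a, b, c, d)
        p1 = hypergeom_upper(a, b, c, d)
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(
        table=np.array([[a, b], [c, d]]),
        odds_ratio=float(odds),
        p_fisher=p2,
        p_hypergeom=p1,
    )


# ---------------------------------------------------------------------------
# matched resampling null for distance-to-G4

@dataclass
class DistanceNull:
    """Observed nearest-G4 distances against a length-matched placement null."""

    observed: np.ndarray
    observed_summary: float
    replicate_summaries: np.ndarray
    n_reps: int
    seed: int
    p_value: float
    summary_stat: str = "mean"

    def summary(self) -> str:
        return (
            "Distance-to-G4 resampling null ({} of nearest distances)\n"
            "  observed {}   : {:.1f} bp\n"
            "  null mean      : {:.1f} bp over {} replicates\n"
            "  empirical p    : {:.4g} (closer than expected)".format(
                self.summary_stat,
                self.summary_stat,
                self.observed_summary,
                float(self.replicate_summaries.mean()),
                self.n_reps,
                self.p_value,
            )
        )


def _placeable(chrom_sizes: dict, length: int):
    chroms = [c for c, s in chrom_sizes.items() if s >= length]
    if not chroms:
        raise ValueError(f"interval of length {length} does not fit any chromosome")
    weights = np.array([chrom_sizes[c] - length + 1 for c in chroms], dtype=float)
    return chroms, weights / weights.sum()


def resample_null(
    query: IntervalSet,
    g4: IntervalSet,
    chrom_sizes: dict,
    n_reps: int = 1000,
    seed: int = 0,
    summary: str = "mean",
) -> DistanceNull:
    """Empirical p for the query lying closer to G4s than length-matched chance.

    Each replicate draws ``len(query)`` intervals, one per observed query
    interval with the identical length, placed uniformly at random
    genome-wide (chromosome chosen with probability proportional to the
    number of placeable start positions; replicated intervals may overlap
    each other). The chosen summary (mean or median) of nearest-G4
    distances is recorded per replicate and the one-sided empirical p is
    (1 + #{replicate summary <= observed summary}) / (n_reps + 1).
    """
    if summary not in ("mean", "median"):
        raise ValueError("summary must be 'mean' or 'median'")
    stat = np.mean if summary == "mean" else np.median
    obs = distance_to_nearest(query, g4)
    obs_summary = float(stat(obs))

    rng = np.random.default_rng(seed)
    lengths = query.lengths
    placements = [_placeable(chrom_sizes, int(L)) for L in lengths]
    g4_by_chrom = {
        chrom: (sub["start"].to_numpy(), sub["end"].to_numpy())
        for chrom, sub in merge_intervals(g4.df, adjoin=False).groupby("chrom")
    }
    # vectorised over replicates, one query interval at a time
    dmat = np.full((n_reps, len(lengths)), np.nan)
    for i, (L, (chroms, probs)) in enumerate(zip(lengths, placements)):
        L = int(L)
        ci = rng.choice(len(chroms), size=n_reps, p=probs)
        u = rng.random(n_reps)
        for k, chrom in enumerate(chroms):
            sel = np.nonzero(ci == k)[0]
            if len(sel) == 0:
                continue
            starts = np.floor(u[sel] * (chrom_sizes[chrom] - L + 1)).astype(np.int64)
            if chrom not in g4_by_chrom:
                continue  # distance undefined on this chromosome
            ms, me = g4_by_chrom[chrom]
            ends = starts + L
            j = np.searchsorted(ms, starts, side="right")
            right = np.full(len(sel), np.inf)
            valid = j < len(ms)
            right[valid] = np.maximum(ms[j[valid]] - ends[valid], 0)
            left = np.full(len(sel), np.inf)
            vj = j > 0
            left[vj] = np.where(me[j[vj] - 1] > starts[vj], 0, starts[vj] - me[j[vj] - 1])
            dmat[sel, i] = np.minimum(left, right)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rep_summaries = (np.nanmean if summary == "mean" else np.nanmedian)(dmat, axis=1)
    p = (1 + int((rep_summaries <= obs_summary).sum())) / (n_reps + 1)
    return DistanceNull(
        observed=obs,
        observed_summary=obs_summary,
        replicate_summaries=rep_summaries,
        n_reps=n_reps,
        seed=seed,
        p_value=float(p),
        summary_stat=summary,
    )
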