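"""Genomic interval primitives.

All coordinates are 0-based, half-open ``[start, end)`` — the BED convention.
Two intervals overlap iff ``s1 < e2 and s2 < e1``; touching intervals
(``e1 == s2``) do not overlap but *adjoin*, which matters for merging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IntervalSet",
    "merge_intervals",
    "intersect",
    "overlaps_any",
    "distance_to_nearest",
]


@dataclass
class IntervalSet:
    """A sorted set of genomic intervals with optional per-interval names.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``chrom`` (str), ``start`` (int), ``end`` (int) and
        optionally ``name``/``score``. Normalised (sorted by chrom, start)
        on construction.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end"]))

    def __post_init__(self):
        df = pd.DataFrame(self.df).reset_index(drop=True)
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"IntervalSet requires a '{col}' column")
        if len(df) and (df["start"] >= df["end"]).any():
            raise ValueError("intervals must satisfy start < end")
        self.df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)

    @classmethod
    def from_records(cls, records, names=None) -> "IntervalSet":
        """Build from an iterable of ``(chrom, start, end)`` tuples."""
        df = pd.DataFrame(records, columns=["chrom", "start", "end"])
        if names is not None:
            df["name"] = list(names)
        return cls(df)

    @classmethod
    def read_bed(cls, path) -> "IntervalSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        cols = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
        df.columns = cols + list(df.columns[len(cols):])
        return cls(df)

    def to_bed(self, path) -> None:
        cols = [c for c in ("chrom", "start", "end", "name", "score", "strand") if c in self.df.columns]
        self.df[cols].to_csv(path, sep="\t", header=False, index=False)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return iter(self.df[["chrom", "start", "end"]].itertuples(index=False, name=None))

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def merged(self) -> "IntervalSet":
        return IntervalSet(merge_intervals(self.df))


def merge_intervals(df: pd.DataFrame, adjoin: bool = True) -> pd.DataFrame:
    """Merge overlapping (and by default adjoining) intervals per chromosome."""
    if len(df) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    out = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            joined = s <= cur_e if adjoin else s < cur_e
            if joined:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def intersect(a: IntervalSet, b: IntervalSet) -> pd.DataFrame:
    """All overlapping pairs between two interval sets.

    Returns a DataFrame with the indices of the overlapping intervals in
    each input (``idx_a``, ``idx_b`` are positions within the normalised
    sets), their coordinates, and the overlap length in bp. Half-open
    semantics: touching intervals do not overlap. Symmetric in a and b up
    to column naming.
    """
    rows = []
    adf, bdf = a.df, b.df
    for chrom in sorted(set(adf["chrom"]) & set(bdf["chrom"])):
        asub = adf[adf["chrom"] == chrom]
        bsub = bdf[bdf["chrom"] == chrom]
        b_starts = bsub["start"].to_numpy()
        b_ends = bsub["end"].to_numpy()
        b_idx = bsub.index.to_numpy()
        # b is sorted by start; for each a, candidates have b.start < a.end
        order_hint = np.searchsorted(b_starts, asub["end"].to_numpy(), side="left")
        for (ia, s, e), hi in zip(asub[["start", "end"]].itertuples(name=None), order_hint):
            cand = slice(0, hi)
            mask = b_ends[cand] > s
            for j in np.nonzero(mask)[0]:
                ov = min(e, b_ends[j]) - max(s, b_starts[j])
                rows.append((ia, b_idx[j], chrom, s, e, b_starts[j], b_ends[j], ov))
    return pd.DataFrame(
        rows,
        columns=["idx_a", "idx_b", "chrom", "start_a", "end_a", "start_b", "end_b", "overlap_bp"],
    )


def _merged_arrays(iv: IntervalSet):
    m = merge_intervals(iv.df, adjoin=False)
    return {
        chrom: (sub["start"].to_numpy(), sub["end"].to_numpy())
        for chrom, sub in m.groupby("chrom")
    }


def overlaps_any(chroms, starts, ends, iv: IntervalSet) -> np.ndarray:
    """Boolean vector: does each query interval overlap any interval of *iv*?

    Vectorised via searchsorted against the merged representation of *iv*;
    intended for classifying large window grids.
    """
    chroms = np.asarray(chroms)
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    out = np.zeros(len(starts), dtype=bool)
    merged = _merged_arrays(iv)
    for chrom, (ms, me) in merged.items():
        sel = np.nonzero(chroms == chrom)[0]
        if len(sel) == 0:
            continue
        # merged intervals are disjoint and sorted; the only candidate for
        # overlap with [s, e) is the first merged interval with end > s
        j = np.searchsorted(me, starts[sel], side="right")
        valid = j < len(ms)
        hit = np.zeros(len(sel), dtype=bool)
        hit[valid] = ms[j[valid]] < ends[sel[valid]]
        out[sel] = hit
    return out


def distance_to_nearest(query: IntervalSet, subject: IntervalSet) -> np.ndarray:
    """Edge-to-edge gap (bp) from each query interval to its nearest subject.

    Zero if any subject interval overlaps (or touches) the query. Query
    intervals on chromosomes with no subject interval are excluded with a
    warning, mirroring how distances to an annotation are undefined off its
    chromosomes.
    """
    if len(subject) == 0:
        raise ValueError("subject interval set is empty")
    merged = _merged_arrays(subject)
    dists = []
    n_skipped = 0
    for chrom, s, e in query:
        if chrom not in merged:
            n_skipped += 1
            continue
        ms, me = merged[chrom]
        j = np.searchsorted(ms, s, side="right")
        best = np.inf
        if j < len(ms):  # first subject starting at/after s
            best = min(best, max(0, ms[j] - e))
        if j > 0:  # subject starting before s; may overlap or lie left
            if me[j - 1] > s:
                best = 0.0
            else:
                best = min(best, s - me[j - 1])
        # an overlapping subject always yields 0 through one of the branches
        if j < len(ms) and ms[j] < e:
            best = 0.0
        dists.append(best)
    if n_skipped:
        warnings.warn(
            f"{n_skipped} query interval(s) on chromosomes without any subject interval were excluded"
        )
    return np.asarray(dists, dtype=float)
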