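"""Sliding-window grid, per-window read counts and GC fraction.

The coverage grid follows the paired-genome comparison design: 200 bp
windows advanced by 100 bp, so each genomic position (away from chromosome
ends) is covered by two windows, and every sample is counted on the
*identical* grid. Trailing partial windows are dropped, not truncated, so
per-window counts and GC fractions remain directly comparable; this is an
explicit, configurable divergence from tools that emit trailing stubs.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "make_windows",
    "window_gc",
    "window_counts",
    "WindowedCoverage",
]

DEFAULT_WINDOW_BP = 200
DEFAULT_STEP_BP = 100


def make_windows(
    chrom_sizes: Mapping[str, int],
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
) -> pd.DataFrame:
    """Build the genome-wide sliding-window grid.

    Windows start at 0, step_bp, 2*step_bp, ...; only full-length windows
    are emitted, so a chromosome of length L yields
    ``floor((L - window_bp)/step_bp) + 1`` windows (0 if L < window_bp).

    Returns a DataFrame with columns chrom, start, end sorted by
    (chrom, start).
    """
    if not (1 <= step_bp <= window_bp):
        raise ValueError("require window_bp >= step_bp >= 1")
    frames = []
    for chrom in sorted(chrom_sizes):
        size = int(chrom_sizes[chrom])
        if size <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {size}")
        if size < window_bp:
            warnings.warn(f"chromosome {chrom!r} ({size} bp) is shorter than one window; emitting 0 windows")
            continue
        n = (size - window_bp) // step_bp + 1
        starts = np.arange(n, dtype=np.int64) * step_bp
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + window_bp}))
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(frames, ignore_index=True)


def _seq_to_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def window_gc(sequences: Mapping[str, str], windows: pd.DataFrame) -> np.ndarray:
    """Per-window GC fraction, (#G + #C) / (#A + #C + #G + #T).

    Ambiguous bases (N etc.) are excluded from both numerator and
    denominator. Windows with no unambiguous base get NaN and a warning:
    downstream stages must exclude them.
    """
    gc = np.full(len(windows), np.nan)
    for chrom, sub in windows.groupby("chrom", sort=False):
        if chrom not in sequences:
            raise KeyError(f"no sequence provided for chromosome {chrom!r}")
        b = _seq_to_bytes(sequences[chrom])
        if len(b) < sub["end"].max():
            raise ValueError(f"sequence for {chrom!r} shorter than window coordinates")
        is_gc = (b == ord("G")) | (b == ord("C"))
        is_acgt = is_gc | (b == ord("A")) | (b == ord("T"))
        cgc = np.concatenate([[0], np.cumsum(is_gc)])
        cok = np.concatenate([[0], np.cumsum(is_acgt)])
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        n_ok = cok[e] - cok[s]
        n_gc = cgc[e] - cgc[s]
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(n_ok > 0, n_gc / np.maximum(n_ok, 1), np.nan)
        gc[sub.index.to_numpy()] = vals
    if np.isnan(gc).any():
        warnings.warn(f"{int(np.isnan(gc).sum())} window(s) are entirely ambiguous; GC set to NaN")
    return gc


def _reads_to_window_counts(windows, chroms, starts, ends, window_bp, step_bp):
    counts = np.zeros(len(windows), dtype=np.int64)
    offsets = {}
    for chrom, sub in windows.groupby("chrom", sort=False):
        offsets[chrom] = (sub.index[0], len(sub))
    chroms = np.asarray(chroms)
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    for chrom in np.unique(chroms):
        if chrom not in offsets:
            raise KeyError(f"alignment references unknown chromosome {chrom!r}")
        off, n = offsets[chrom]
        sel = chroms == chrom
        rs, re = starts[sel], ends[sel]
        # window k spans [k*step, k*step + window); overlaps a read [rs, re)
        # iff k*step < re and k*step + window > rs
        k_lo = np.maximum(0, -(-(rs - window_bp + 1) // step_bp))
        k_hi = np.minimum(n - 1, (re - 1) // step_bp)
        max_span = int(np.max(k_hi - k_lo, initial=-1)) + 1
        for j in range(max_span):
            k = k_lo + j
            ok = k <= k_hi
            np.add.at(counts, off + k[ok], 1)
    return counts


def window_counts(
    source,
    windows: pd.DataFrame,
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
    read_length: int | None = None,
    skip_flags: int = 0x4 | 0x100 | 0x400,
):
    """Per-window read counts from alignments or a per-base depth track.

    Parameters
    ----------
    source
        One of:

        * a path to a SAM/BAM file (or an open :class:`pysam.AlignmentFile`):
          every mapped read increments every window its aligned span
          overlaps by >= 1 bp (at 200/100 windows a read shorter than the
          step lands in at most two windows); unmapped, secondary and
          duplicate records are skipped by default (``skip_flags``);
        * a DataFrame of per-base/bedGraph depth with columns
          ``chrom, start, end, depth`` (0-based half-open): the window
          value is the summed per-base depth over the window divided by
          ``read_length`` (required in this mode), rounded to integer.
    windows
        Grid from :func:`make_windows`, built with the same
        ``window_bp``/``step_bp``.

    Returns
    -------
    (counts, total_mapped)
        Integer count vector aligned to *windows*, and the number of input
        reads (alignment mode) or round(total depth / read_length) (depth
        mode). Because windows overlap, ``counts.sum()`` can exceed
        ``total_mapped``.
    """
    if isinstance(source, pd.DataFrame):
        if read_length is None:
            raise ValueError("depth mode requires read_length")
        counts = np.zeros(len(windows), dtype=np.int64)
        known = set(windows["chrom"].unique())
        unknown = set(source["chrom"].unique()) - known
        if unknown:
            raise KeyError(f"depth track references unknown chromosome(s): {sorted(unknown)}")
        total_depth = float((source["depth"] * (source["end"] - source["start"])).sum())
        for chrom, wsub in windows.groupby("chrom", sort=False):
            dsub = source[source["chrom"] == chrom]
            if len(dsub) == 0:
                continue
            size = int(max(wsub["end"].max(), dsub["end"].max()))
            per_base = np.zeros(size, dtype=float)
            for s, e, d in dsub[["start", "end", "depth"]].itertuples(index=False):
                per_base[s:e] += d
            cdepth = np.concatenate([[0.0], np.cumsum(per_base)])
            s = wsub["start"].to_numpy()
            e = wsub["end"].to_numpy()
            counts[wsub.index.to_numpy()] = np.rint((cdepth[e] - cdepth[s]) / read_length).astype(np.int64)
        return counts, int(round(total_depth / read_length))

    import pysam

    if isinstance(source, (str, os.PathLike)):
        handle = pysam.AlignmentFile(str(source), check_sq=False)
        close = True
    else:
        handle, close = source, False
    chroms, starts, ends = [], [], []
    try:
        for rec in handle:
            if rec.flag & skip_flags:
                continue
            if rec.reference_name is None:
                continue
            chroms.append(rec.reference_name)
            starts.append(rec.reference_start)
            ends.append(rec.reference_end if rec.reference_end is not None else rec.reference_start + 1)
    finally:
        if close:
            handle.close()
    if not chroms:
        return np.zeros(len(windows), dtype=np.int64), 0
    counts = _reads_to_window_counts(windows, chroms, starts, ends, window_bp, step_bp)
    return counts, len(chroms)


@dataclass
class WindowedCoverage:
    """Per-sample read counts on a shared window grid.

    ``counts`` is aligned to ``windows`` row for row. ``total_mapped`` is
    tracked independently of ``counts.sum()`` because with overlapping
    windows a read can be counted in up to two windows. ``gc`` is the
    per-window GC fraction (NaN where undefined) and ``raw_counts`` holds
    pre-normalisation counts after GC correction.
    """

    windows: pd.DataFrame
    counts: np.ndarray
    sample_id: str = "sample"
    total_mapped: int | None = None
    gc: np.ndarray | None = None
    raw_counts: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != len(self.windows):
            raise ValueError("counts length must equal number of windows")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.total_mapped is None:
            self.total_mapped = float(self.counts.sum())
        if self.gc is not None:
            self.gc = np.asarray(self.gc, dtype=float)
            if len(self.gc) != len(self.windows):
                raise ValueError("gc length must equal number of windows")

    def same_grid(self, other: "WindowedCoverage") -> bool:
        a, b = self.windows, other.windows
        return len(a) == len(b) and (a[["chrom", "start", "end"]].values == b[["chrom", "start", "end"]].values).all()

    def to_tsv(self, path) -> None:
        df = self.windows.copy()
        if self.gc is not None:
            df["gc"] = self.gc
        df[f"count_{self.sample_id}"] = self.counts
        with open(path, "w") as fh:
            fh.write(f"# total_mapped_{self.sample_id}={self.total_mapped}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "WindowedCoverage":
        total = None
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                total = float(first.strip().split("=")[-1])
            else:
                fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
        count_cols = [c for c in df.columns if c.startswith("count_")]
        if len(count_cols) != 1:
            raise ValueError("expected exactly one count_<sample> column")
        sample = count_cols[0][len("count_"):]
        return cls(
            windows=df[["chrom", "start", "end"]].copy(),
            counts=df[count_cols[0]].to_numpy(),
            sample_id=sample,
            total_mapped=total,
            gc=df["gc"].to_numpy() if "gc" in df.columns else None,
        )
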