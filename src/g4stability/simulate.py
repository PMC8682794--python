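"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its configuration and a seed, and
every planted feature (CNV intervals and multipliers, G4 motif
coordinates, mutation number m, kinetic constants, spectral shapes) is
returned in machine-readable form so recovery can be scored against
ground truth.

What is emulated, per stage:

* a small multi-chromosome genome with a smoothly varying GC landscape,
  planted canonical G4 motifs, a set of single-copy nuclear genes and one
  mitochondrial chromosome;
* per-window read counts with a GC-dependent bias curve and Poisson or
  negative-binomial noise, planted segmental CNVs and whole-chromosome
  duplications, and an independent mitochondrial depth multiplier;
* Luria-Delbrueck mutant-count vectors, sampled exactly through the
  compound-Poisson representation of the MSS distribution;
* paired low/high-temperature UV spectra with G4-like, duplex-like or
  single-strand-like thermal difference shapes;
* step-series Langmuir binding curves.

Read-level simulation (FASTQ, sequencing errors, alignment) is out of
scope: the pipeline consumes window counts or depth tracks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biophysics import BindingCurve, Spectrum
from .fluctuation import FluctuationExperiment
from .intervals import IntervalSet
from .windows import WindowedCoverage, make_windows, window_gc

__all__ = [
    "SimulatedGenome",
    "CnvTruth",
    "simulate_genome",
    "simulate_cnv_truth",
    "simulate_coverage",
    "simulate_fluctuation",
    "simulate_spectra",
    "simulate_binding",
    "default_gc_bias",
    "identity_bias",
]

DEFAULT_CHROM_SIZES = {"chrI": 120_000, "chrII": 200_000, "chrIII": 150_000}
DEFAULT_MT_SIZE = 30_000
MT_CHROM = "chrM"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def default_gc_bias(gc):
    """Unimodal quadratic depth bias peaking at GC 0.40, range [0.5, 1.0].

    An Illumina-like GC curve, deliberately strong enough that CNV calling
    without GC correction visibly degrades.
    """
    gc = np.asarray(gc, dtype=float)
    return np.clip(1.0 - 0.5 * ((gc - 0.40) / 0.17) ** 2, 0.5, 1.0)


def identity_bias(gc):
    return np.ones_like(np.asarray(gc, dtype=float))


@dataclass
class SimulatedGenome:
    """A synthetic genome with known GC landscape and planted G4 motifs."""

    chrom_sizes: dict
    sequences: dict
    gc_landscape: dict            # per-chrom per-base GC probability used
    planted_g4: IntervalSet
    single_copy_genes: IntervalSet
    mt_chrom: str | None = MT_CHROM

    @property
    def nuclear_chroms(self) -> list:
        return [c for c in self.chrom_sizes if c != self.mt_chrom]

    def write_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.sequences):
                fh.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")

    def truth(self) -> dict:
        return {
            "chrom_sizes": self.chrom_sizes,
            "mt_chrom": self.mt_chrom,
            "planted_g4": self.planted_g4.df.to_dict(orient="records"),
            "single_copy_genes": self.single_copy_genes.df.to_dict(orient="records"),
        }


def _g4_insert(rng, min_run_len=3, n_runs=4) -> str:
    """A canonical planted G4: n_runs G-runs of 3-4 with short A/T/C loops."""
    parts = []
    for i in range(n_runs):
        parts.append("G" * int(rng.integers(min_run_len, min_run_len + 2)))
        if i < n_runs - 1:
            loop_len = int(rng.integers(1, 8))
            parts.append("".join(rng.choice(list("ATC"), size=loop_len)))
    return "".join(parts)


def _gc_profile_values(profile, size, rng):
    """Per-base GC probability along one chromosome."""
    pos = np.arange(size)
    if profile is None:
        profile = ("sine", 0.42, 0.08, 50_000)
    kind = profile[0]
    if kind == "constant":
        return np.full(size, float(profile[1]))
    if kind == "sine":
        _, mean, amp, period = profile
        phase = rng.uniform(0, 2 * np.pi)
        return np.clip(mean + amp * np.sin(2 * np.pi * pos / period + phase), 0.05, 0.95)
    raise ValueError(f"unknown gc profile {profile!r}")


def simulate_genome(
    chrom_sizes: dict | None = None,
    gc_profile=None,
    g4_density: float = 1 / 25_000,
    n_single_copy_genes: int = 40,
    mt_size: int = DEFAULT_MT_SIZE,
    mask_accidental_runs: bool = False,
    seed: int = 0,
    window_bp: int = 200,
) -> SimulatedGenome:
    """Generate a genome with known GC landscape and planted G4 motifs.

    ``g4_density`` is motifs per bp on nuclear chromosomes (default one per
    25 kb, yeast-like); planted coordinates are recorded exactly. With
    ``mask_accidental_runs`` every background G/C run of >= 3 outside the
    planted motifs is broken, so the only scanner hits are planted ones;
    otherwise accidental motifs can occur and are simply not part of the
    recorded truth.
    """
    if chrom_sizes is None:
        chrom_sizes = dict(DEFAULT_CHROM_SIZES)
    if any(s <= 0 for s in chrom_sizes.values()):
        raise ValueError("chromosome sizes must be positive")
    if any(s < window_bp for s in chrom_sizes.values()):
        raise ValueError(f"all chromosomes must be at least one window ({window_bp} bp) long")
    rng = np.random.default_rng(seed)
    sizes = dict(chrom_sizes)
    if mt_size:
        sizes[MT_CHROM] = mt_size
    sequences, landscapes = {}, {}
    g4_rows, gene_rows = [], []
    for chrom in sorted(sizes):
        size = sizes[chrom]
        p_gc = _gc_profile_values(gc_profile, size, rng)
        # draw bases with P(G)=P(C)=p_gc/2, P(A)=P(T)=(1-p_gc)/2
        u = rng.random(size)
        seq = np.empty(size, dtype=np.uint8)
        seq[u < p_gc / 2] = ord("G")
        seq[(u >= p_gc / 2) & (u < p_gc)] = ord("C")
        seq[(u >= p_gc) & (u < p_gc + (1 - p_gc) / 2)] = ord("A")
        seq[u >= p_gc + (1 - p_gc) / 2] = ord("T")
        if mask_accidental_runs:
            for b in (ord("G"), ord("C")):
                run = (seq == b)
                # break every third consecutive occurrence
                streak = 0
                for i in range(size):
                    if run[i]:
                        streak += 1
                        if streak == 3:
                            seq[i] = ord("A") if b == ord("G") else ord("T")
                            streak = 0
                    else:
                        streak = 0
        if chrom != MT_CHROM and g4_density > 0:
            n_g4 = rng.poisson(g4_density * size)
            starts = np.sort(rng.integers(0, max(size - 100, 1), size=n_g4))
            last_end = -1
            for s in starts:
                ins = _g4_insert(rng)
                if s <= last_end:  # keep planted motifs disjoint
                    continue
                e = s + len(ins)
                if e > size:
                    continue
                seq[s:e] = np.frombuffer(ins.encode(), dtype=np.uint8)
                g4_rows.append((chrom, int(s), int(e)))
                last_end = e
        sequences[chrom] = seq.tobytes().decode("ascii")
        landscapes[chrom] = p_gc
    # single-copy nuclear genes: disjoint 1-2 kb intervals
    nuclear = [c for c in sorted(sizes) if c != MT_CHROM]
    per_chrom = max(1, n_single_copy_genes // max(len(nuclear), 1))
    for chrom in nuclear:
        size = sizes[chrom]
        cursor = int(0.05 * size)
        for _ in range(per_chrom):
            length = int(rng.integers(1000, 2001))
            gap = int(rng.integers(500, 2000))
            if cursor + length > size:
                break
            gene_rows.append((chrom, cursor, cursor + length))
            cursor += length + gap
    return SimulatedGenome(
        chrom_sizes=sizes,
        sequences=sequences,
        gc_landscape=landscapes,
        planted_g4=IntervalSet(pd.DataFrame(g4_rows, columns=["chrom", "start", "end"])),
        single_copy_genes=IntervalSet(pd.DataFrame(gene_rows, columns=["chrom", "start", "end"])),
        mt_chrom=MT_CHROM if mt_size else None,
    )


@dataclass
class CnvTruth:
    """Ground-truth copy-number state for one simulated sample."""

    intervals: IntervalSet
    copy_number: np.ndarray            # per-interval multiplier, >= 0
    whole_chrom_dups: list = field(default_factory=list)

    def __post_init__(self):
        self.copy_number = np.asarray(self.copy_number, dtype=float)
        if (self.copy_number < 0).any():
            raise ValueError("copy multipliers must be >= 0")
        if len(self.copy_number) != len(self.intervals):
            raise ValueError("one multiplier per interval required")
        df = self.intervals.df
        for chrom, sub in df.groupby("chrom"):
            e = sub.sort_values("start")
            if (e["start"].to_numpy()[1:] < e["end"].to_numpy()[:-1]).any():
                raise ValueError("truth intervals must not overlap within a sample")

    def to_json(self, path) -> None:
        payload = {
            "intervals": self.intervals.df.assign(copy=self.copy_number).to_dict(orient="records"),
            "whole_chrom_dups": list(self.whole_chrom_dups),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def simulate_cnv_truth(
    genome: SimulatedGenome,
    n_cnvs: int = 20,
    size_range: tuple = (800, 2000),
    multipliers: tuple = (0.0, 0.5, 2.0),
    whole_chrom_dups: list | None = None,
    min_gap: int = 2000,
    seed: int = 0,
) -> CnvTruth:
    """Plant segmental CNVs (and optional whole-chromosome duplications).

    Default sizes 800-2000 bp target the sub-2 kb event scale; events are
    disjoint, separated by >= min_gap, and never on the mitochondrial
    chromosome.
    """
    rng = np.random.default_rng(seed)
    chroms = genome.nuclear_chroms
    weights = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed = {c: [] for c in chroms}
    rows, mults = [], []
    attempts = 0
    while len(rows) < n_cnvs and attempts < 50 * n_cnvs:
        attempts += 1
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        length = int(rng.integers(size_range[0], size_range[1] + 1))
        size = genome.chrom_sizes[chrom]
        if size <= length + 2 * min_gap:
            continue
        s = int(rng.integers(min_gap, size - length - min_gap))
        e = s + length
        if any(s - min_gap < pe and ps < e + min_gap for ps, pe in placed[chrom]):
            continue
        placed[chrom].append((s, e))
        rows.append((chrom, s, e))
        mults.append(multipliers[len(rows) % len(multipliers)])
    if len(rows) < n_cnvs:
        raise RuntimeError("could not place all CNVs; genome too small for the requested layout")
    return CnvTruth(
        intervals=IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"])),
        copy_number=np.array(mults),
        whole_chrom_dups=list(whole_chrom_dups or []),
    )


def _window_copy(windows: pd.DataFrame, truth: CnvTruth | None, mt_chrom, mt_multiplier) -> np.ndarray:
    copy = np.ones(len(windows))
    if mt_chrom is not None:
        copy[(windows["chrom"] == mt_chrom).to_numpy()] = mt_multiplier
    if truth is None:
        return copy
    starts = windows["start"].to_numpy()
    ends = windows["end"].to_numpy()
    chroms = windows["chrom"].to_numpy()
    width = ends - starts
    for (chrom, s, e), mult in zip(truth.intervals, truth.copy_number):
        sel = (chroms == chrom) & (starts < e) & (ends > s)
        if sel.any():
            ov = np.minimum(ends[sel], e) - np.maximum(starts[sel], s)
            frac = ov / width[sel]
            copy[sel] = copy[sel] + (mult - 1.0) * frac  # partial windows blend
    for chrom in truth.whole_chrom_dups:
        copy[(chroms == chrom)] *= 2.0
    return copy


def simulate_coverage(
    genome: SimulatedGenome,
    truth: CnvTruth | None = None,
    depth: float = 100.0,
    gc_bias=default_gc_bias,
    noise: str = "negbin",
    dispersion: float = 0.1,
    mt_multiplier: float = 20.0,
    seed: int = 0,
    sample_id: str = "sample",
    windows: pd.DataFrame | None = None,
    gc: np.ndarray | None = None,
) -> WindowedCoverage:
    """Per-window read counts for one sample on the 200/100 grid.

    The expected count of window w is depth * copy(w) * gc_bias(gc(w));
    windows partially covered by a CNV get a proportionally blended copy
    number. Noise is Poisson or negative binomial; ``dispersion`` d is the
    fractional excess of the variance over the Poisson value
    (Var = (1 + d) * mu, i.e. NB size = mu/d), so d=0.1 means 10% extra
    variance. The mitochondrial chromosome carries an independent depth
    multiplier (default 20x, a yeast-like mtDNA copy number).

    Pass precomputed ``windows``/``gc`` to amortise grid construction
    across samples; they must come from this genome.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if noise == "negbin" and dispersion <= 0:
        raise ValueError("negative-binomial dispersion must be > 0")
    if windows is None:
        windows = make_windows(genome.chrom_sizes)
    if gc is None:
        gc = window_gc(genome.sequences, windows)
    bias = (identity_bias if gc_bias is None else gc_bias)(np.nan_to_num(gc, nan=0.5))
    if (np.asarray(bias) <= 0).any():
        raise ValueError("gc bias multiplier must be positive over [0, 1]")
    copy = _window_copy(windows, truth, genome.mt_chrom, mt_multiplier)
    mu = depth * copy * bias
    rng = np.random.default_rng(seed)
    counts = np.zeros(len(mu), dtype=np.int64)
    pos = mu > 0
    if noise == "poisson":
        counts[pos] = rng.poisson(mu[pos])
    elif noise == "negbin":
        size = mu[pos] / dispersion
        counts[pos] = rng.negative_binomial(size, 1.0 / (1.0 + dispersion))
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    return WindowedCoverage(
        windows=windows,
        counts=counts,
        sample_id=sample_id,
        total_mapped=int(counts.sum()),
        gc=gc,
    )


def simulate_fluctuation(
    m: float,
    n_cultures: int,
    Nt: float,
    seed: int = 0,
    plating_fraction: float = 1.0,
    strain: str = "",
) -> FluctuationExperiment:
    """Sample mutant counts from the Luria-Delbrueck (MSS) distribution.

    Exact sampling through the compound-Poisson representation: each
    culture receives N ~ Poisson(m) mutation events whose clones reach
    iid sizes K with P(K >= k) = 1/k (K = floor(1/U)); the mutant count is
    the clone-size sum, binomially thinned when only a fraction of the
    culture is plated. The Panjer recursion of this compound law is the
    MSS pmf, so the draw is exact in distribution with no truncation.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    if n_cultures < 1:
        raise ValueError("need at least one culture")
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_cultures, dtype=np.int64)
    if m > 0:
        n_mut = rng.poisson(m, size=n_cultures)
        for i, n in enumerate(n_mut):
            if n == 0:
                continue
            u = rng.random(n)
            counts[i] = int(np.floor(1.0 / u).sum())
    if plating_fraction < 1:
        counts = rng.binomial(counts, plating_fraction)
    return FluctuationExperiment(
        counts=counts, Nt=Nt, plating_fraction=plating_fraction, strain=strain
    )


@dataclass
class SimulatedSpectra:
    """Paired low/high-temperature spectra plus the noise-free TDS truth."""

    low: Spectrum
    high: Spectrum
    kind: str
    true_tds: np.ndarray


def simulate_spectra(
    kind: str = "g4",
    noise_sd: float = 0.0,
    seed: int = 0,
    wavelengths: np.ndarray | None = None,
) -> SimulatedSpectra:
    """Low/high-temperature UV spectra with a chosen melting signature.

    ``kind='g4'`` yields a thermal difference that is positive below
    290 nm, negative above, crossing zero at exactly 290 nm;
    ``'duplex'``/``'ss'`` yield non-negative (hyperchromic-only)
    differences. ``noise_sd`` is additive Gaussian noise in absorbance
    units applied independently to both spectra.
    """
    if wavelengths is None:
        wavelengths = np.arange(220.0, 321.0)
    w = np.asarray(wavelengths, dtype=float)
    a_low = np.exp(-((w - 258.0) / 18.0) ** 2)  # ~1 OD peak near 260 nm
    if kind == "g4":
        # hyperchromic below the 290 nm isosbestic point, hypochromic above
        delta = 0.015 * (290.0 - w) * np.exp(-((w - 278.0) / 25.0) ** 2)
    elif kind == "duplex":
        # broad hyperchromic hump, still clearly positive past 300 nm
        delta = 0.25 * np.exp(-((w - 270.0) / 30.0) ** 2)
    elif kind == "ss":
        delta = 0.15 * np.exp(-((w - 268.0) / 32.0) ** 2)
    else:
        raise ValueError(f"unknown spectrum kind {kind!r}")
    a_high = a_low + delta
    true_tds = delta / a_low.max()
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        a_low = a_low + rng.normal(0, noise_sd, size=len(w))
        a_high = a_high + rng.normal(0, noise_sd, size=len(w))
    return SimulatedSpectra(
        low=Spectrum(w, a_low, temperature=20.0),
        high=Spectrum(w, a_high, temperature=90.0),
        kind=kind,
        true_tds=true_tds,
    )


DEFAULT_CONC_SERIES = (0.08, 0.4, 2.0, 10.0, 50.0)  # nM spike series


def simulate_binding(
    kon: float = 1e-3,
    koff: float = 5e-3,
    sigma_max: float = 1.0,
    conc_steps: list | None = None,
    step_duration: float = 600.0,
    dt: float = 2.0,
    noise: float = 0.0,
    seed: int = 0,
) -> BindingCurve:
    """Langmuir binding curve under a step-wise rising concentration series.

    Within each step at concentration c, sigma relaxes exponentially from
    its value at the spike toward sigma_max * c/(c + Kd) at rate
    kon*c + koff, continuous across steps. ``conc_steps`` is a list of
    (start_time_s, concentration_nM); by default the five-spike series
    0.08, 0.4, 2, 10, 50 nM with ``step_duration`` seconds per step.
    ``noise`` is the multiplicative Gaussian noise fraction.
    """
    if kon <= 0 or koff <= 0:
        raise ValueError("kon and koff must be positive")
    if conc_steps is None:
        conc_steps = [(i * step_duration, c) for i, c in enumerate(DEFAULT_CONC_SERIES)]
    starts = [s for s, _ in conc_steps]
    if any(b <= a for a, b in zip(starts, starts[1:])):
        raise ValueError("step start times must be increasing")
    kd = koff / kon
    t_end = starts[-1] + step_duration
    time = np.arange(starts[0], t_end, dt)
    sigma = np.empty_like(time)
    s0 = 0.0
    bounds = starts[1:] + [np.inf]
    for (start, c), stop in zip(conc_steps, bounds):
        sel = (time >= start) & (time < stop)
        k_obs = kon * c + koff
        s_eq = sigma_max * c / (c + kd) if c > 0 else 0.0
        tt = time[sel] - start
        sigma[sel] = s_eq + (s0 - s_eq) * np.exp(-k_obs * tt)
        seg_len = (min(stop, t_end) - start)
        s0 = s_eq + (s0 - s_eq) * np.exp(-k_obs * seg_len)
    if noise > 0:
        rng = np.random.default_rng(seed)
        sigma = sigma * (1.0 + rng.normal(0, noise, size=len(sigma)))
    return BindingCurve(time=time, sigma=sigma, steps=list(conc_steps))
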