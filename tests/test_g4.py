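"""G4 motif scanning, interval ops, exact overlap tests and the distance null."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from g4stability import scan_g4
from g4stability.g4 import (
    fisher_exact_2x2,
    hypergeom_upper,
    overlap_enrichment,
    resample_null,
)
from g4stability.intervals import IntervalSet, distance_to_nearest, intersect
from g4stability.windows import make_windows

# the two G4-forming cassettes assayed for rearrangement induction, and
# their GGG->GCG / bold-G->C mutants that abolish G4 formation
GCR_G4 = "GGGTCCTCCAAGCGGTAAAACTTACATGGGATGGTGGGGTCACATGGG"
GCR_G4_MUT = "GGGTCCTCCAAGCGGTAAAACTTACATGCGATGGTGGCGTCACATGGG"
CHR8_G4 = "GGGTTTTGCTATAATAGGGATGCCATAAGTGAGGGCAGGG"
CHR8_G4_MUT = "GGGTTTTGCTATAATAGCGATGCCATAAGTGAGCGCAGGG"


class TestScanner:
    @pytest.mark.parametrize(
        "seq,n_expected",
        [
            (GCR_G4, 1),
            (GCR_G4_MUT, 0),
            (CHR8_G4, 1),
            (CHR8_G4_MUT, 0),
            ("A" * 200, 0),
            ("", 0),
        ],
    )
    def test_cassettes_and_mutants(self, seq, n_expected):
        motifs = scan_g4(seq)
        assert len(motifs) == n_expected

    def test_motif_structure_recorded(self):
        (m,) = scan_g4(CHR8_G4)
        assert len(m.g_runs) >= 4
        assert all(r >= 3 for r in m.g_runs)
        assert all(1 <= loop <= 25 for loop in m.loops)
        assert m.sequence == CHR8_G4[m.start:m.end]

    def test_reverse_strand_c_runs(self):
        fwd = scan_g4(CHR8_G4)
        # reverse complement: the same motif appears as C-runs
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        rc = "".join(comp[b] for b in reversed(CHR8_G4))
        rev = scan_g4(rc)
        assert len(rev) == len(fwd) == 1
        assert rev[0].strand == "-"

    def test_long_loop_breaks_motif(self):
        seq = "GGG" + "A" * 26 + "GGG" + "T" * 2 + "GGGTTGGG"
        assert len(scan_g4(seq)) == 0  # first run detached; only 3 chained runs

    def test_overlapping_matches_merge_to_one_locus(self):
        seq = "GGGAGGGAGGGAGGGAGGGAGGG"  # 6 runs: one locus, not 3 nested motifs
        motifs = scan_g4(seq)
        assert len(motifs) == 1
        assert len(motifs[0].g_runs) == 6

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            scan_g4("ACGT", loop_min=5, loop_max=2)
        with pytest.raises(ValueError):
            scan_g4("ACGU")


class TestIntervalOps:
    def test_touching_is_not_overlapping(self):
        a = IntervalSet.from_records([("c", 0, 100)])
        b = IntervalSet.from_records([("c", 100, 200)])
        assert len(intersect(a, b)) == 0

    def test_overlap_length(self):
        a = IntervalSet.from_records([("c", 0, 150)])
        b = IntervalSet.from_records([("c", 100, 200)])
        hits = intersect(a, b)
        assert len(hits) == 1 and hits["overlap_bp"].iloc[0] == 50

    def test_intersect_matches_quadratic_oracle(self, rng):
        def random_set(n):
            rows = []
            for _ in range(n):
                chrom = rng.choice(["c1", "c2"])
                s = int(rng.integers(0, 10_000))
                rows.append((chrom, s, s + int(rng.integers(1, 500))))
            return IntervalSet.from_records(rows)

        a, b = random_set(300), random_set(300)
        got = {
            (r.chrom, r.start_a, r.end_a, r.start_b, r.end_b)
            for r in intersect(a, b).itertuples(index=False)
        }
        expected = set()
        for ca, sa, ea in a:
            for cb, sb, eb in b:
                if ca == cb and sa < eb and sb < ea:
                    expected.add((ca, sa, ea, sb, eb))
        assert got == expected

    def test_distance_examples(self):
        q = IntervalSet.from_records([("c", 100, 200)])
        g = IntervalSet.from_records([("c", 300, 350)])
        assert distance_to_nearest(q, g)[0] == 100
        overlapping = IntervalSet.from_records([("c", 150, 400)])
        assert distance_to_nearest(q, overlapping)[0] == 0

    def test_distance_matches_quadratic_oracle(self, rng):
        q_rows = [("c", int(s), int(s) + 50) for s in rng.integers(0, 100_000, 200)]
        g_rows = [("c", int(s), int(s) + 30) for s in rng.integers(0, 100_000, 100)]
        q, g = IntervalSet.from_records(q_rows), IntervalSet.from_records(g_rows)
        got = distance_to_nearest(q, g)
        expected = []
        for _, s, e in q:
            best = math.inf
            for _, gs, ge in g:
                if s < ge and gs < e:
                    best = 0
                else:
                    best = min(best, gs - e if gs >= e else s - ge)
            expected.append(best)
        assert np.allclose(got, expected)

    def test_query_chrom_without_subject_excluded_with_warning(self):
        q = IntervalSet.from_records([("c1", 0, 10), ("c2", 0, 10)])
        g = IntervalSet.from_records([("c1", 50, 60)])
        with pytest.warns(UserWarning):
            d = distance_to_nearest(q, g)
        assert len(d) == 1


def _fisher_enumeration_oracle(a, b, c, d):
    """Exact two-sided and upper-tail p by explicit enumeration with lgamma."""
    N, K, n = a + b + c + d, a + b, a + c

    def log_pmf(k):
        return (
            math.lgamma(K + 1) - math.lgamma(k + 1) - math.lgamma(K - k + 1)
            + math.lgamma(N - K + 1) - math.lgamma(n - k + 1) - math.lgamma(N - K - n + k + 1)
            - (math.lgamma(N + 1) - math.lgamma(n + 1) - math.lgamma(N - n + 1))
        )

    ks = range(max(0, K + n - N), min(K, n) + 1)
    pmf = {k: math.exp(log_pmf(k)) for k in ks}
    p_obs = pmf[a]
    two = sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7))
    upper = sum(p for k, p in pmf.items() if k >= a)
    return min(two, 1.0), min(upper, 1.0)


class TestExactTests:
    def test_worked_table(self):
        p_two, p_up = _fisher_enumeration_oracle(10, 90, 5, 895)
        assert fisher_exact_2x2(10, 90, 5, 895) == pytest.approx(p_two, abs=1e-9)
        assert hypergeom_upper(10, 90, 5, 895) == pytest.approx(p_up, abs=1e-9)

    def test_enumeration_agreement_on_random_tables(self, rng):
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, 4))
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            p_two, p_up = _fisher_enumeration_oracle(a, b, c, d)
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(p_two, abs=1e-9)
            assert hypergeom_upper(a, b, c, d) == pytest.approx(p_up, abs=1e-9)

    def test_matches_scipy_two_sided(self, rng):
        import scipy.stats

        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 30, 4))
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            ref = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(ref, rel=1e-6, abs=1e-12)


class TestOverlapEnrichment:
    def test_perfect_association(self):
        universe = make_windows({"c": 10_000}, 200, 100)
        g4 = IntervalSet.from_records([("c", 1000, 1200), ("c", 5000, 5200)])
        res = overlap_enrichment(g4, g4, universe)
        assert res.table[0, 1] == 0 and res.table[1, 0] == 0
        assert res.odds_ratio > 100
        assert res.p_fisher < 1e-4 and res.p_hypergeom < 1e-4

    def test_degenerate_margins_warn_p_one(self):
        universe = make_windows({"c": 2_000}, 200, 100)
        everything = IntervalSet.from_records([("c", 0, 2_000)])
        g4 = IntervalSet.from_records([("c", 100, 200)])
        with pytest.warns(UserWarning, match="degenerate"):
            res = overlap_enrichment(everything, g4, universe)
        assert res.p_fisher == 1.0


class TestResampleNull:
    def test_planted_overlap_gives_minimal_p(self, small_genome):
        g4 = small_genome.planted_g4
        query = IntervalSet(g4.df.head(6))
        null = resample_null(query, g4, small_genome.chrom_sizes, n_reps=1000, seed=4)
        assert null.observed_summary == 0
        assert null.p_value == pytest.approx(1 / 1001)

    def test_fixed_seed_reproducible(self, small_genome):
        g4 = small_genome.planted_g4
        query = IntervalSet(g4.df.head(4))
        a = resample_null(query, g4, small_genome.chrom_sizes, n_reps=50, seed=9)
        b = resample_null(query, g4, small_genome.chrom_sizes, n_reps=50, seed=9)
        assert np.array_equal(a.replicate_summaries, b.replicate_summaries)
        assert a.p_value == b.p_value

    def test_placement_is_uniform(self):
        """Replicate start positions are uniform over the placeable range.

        With a single anchor interval at the chromosome start, the distance
        of one resampled length-100 interval equals its start minus the
        anchor end, so the replicate summaries expose the placement
        distribution directly; KS-test it against the uniform law.
        """
        import scipy.stats

        sizes = {"c": 100_000}
        g4 = IntervalSet.from_records([("c", 0, 1)])
        query = IntervalSet.from_records([("c", 50_000, 50_100)])
        null = resample_null(query, g4, sizes, n_reps=2000, seed=11)
        d = null.replicate_summaries
        ks = scipy.stats.kstest(d, "uniform", args=(0, 100_000 - 100))
        assert ks.pvalue > 0.01

    def test_interval_longer_than_every_chromosome_errors(self, small_genome):
        query = IntervalSet.from_records([("chrI", 0, 10_000_000)])
        g4 = small_genome.planted_g4
        with pytest.raises(ValueError, match="does not fit"):
            resample_null(query, g4, small_genome.chrom_sizes, n_reps=5, seed=0)
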