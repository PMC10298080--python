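"""Windowed ROH caller: window rule, hit fractions, segment calling,
and exhaustive-oracle equivalence."""

import numpy as np
import pytest

from rohscan.caller import (
    CallerParams,
    call_all,
    call_segments,
    snp_hit_fractions,
    validate_segments,
    window_passes,
)
from rohscan.io import GT
from rohscan.oracle import oracle_call_segments, oracle_hit_fractions

from conftest import make_matrix

P = CallerParams()


def random_instance(rng, max_snps=300):
    n = int(rng.integers(2, max_snps))
    spacing = int(rng.integers(2_000, 60_000))
    pos = np.cumsum(rng.integers(1, 2 * spacing, size=n)).astype(np.int64)
    calls = rng.choice([0, 1, 2, 3], size=n, p=[0.55, 0.15, 0.25, 0.05]).astype(np.int8)
    params = CallerParams(
        window_mode=("snp", "span")[int(rng.integers(0, 2))],
        window_snps=int(rng.integers(2, 80)),
        window_span_bp=int(rng.integers(100_000, 1_000_000)),
        het_allowed_per_window=int(rng.integers(0, 3)),
        missing_allowed_per_window=int(rng.integers(0, 6)),
        max_gap_bp=int(rng.integers(100_000, 1_500_000)),
        min_density_bp_per_snp=int(rng.integers(10_000, 100_000)),
        min_segment_length_bp=int(rng.integers(100_000, 1_000_000)),
        min_segment_snps=int(rng.integers(2, 30)),
        hit_fraction_threshold=float(rng.uniform(0.01, 1.0)),
        exclude_het_sites=bool(rng.integers(0, 2)),
    )
    return make_matrix(pos, calls), params


class TestWindowPasses:
    @pytest.mark.parametrize(
        "n_hom,n_het,n_mis,expected",
        [
            (40, 1, 0, True),  # one tolerated heterozygote
            (40, 0, 5, False),  # five missing exceeds the allowance of four
            (40, 0, 4, True),
            (40, 2, 0, False),
            (10, 0, 0, True),  # all homozygous
        ],
    )
    def test_het_and_missing_allowances(self, n_hom, n_het, n_mis, expected):
        calls = [GT.HOM_REF] * n_hom + [GT.HET] * n_het + [GT.MISSING] * n_mis
        assert window_passes(calls, P) is expected

    def test_empty_window_is_error(self):
        with pytest.raises(ValueError):
            window_passes([], P)


class TestHitFractions:
    def test_single_hom_snp_has_fraction_one(self):
        frac = snp_hit_fractions(np.array([1000]), np.array([GT.HOM_REF]), P)
        assert frac.tolist() == [1.0]

    def test_single_het_snp_tolerated_by_allowance(self):
        frac = snp_hit_fractions(np.array([1000]), np.array([GT.HET]), P)
        assert frac.tolist() == [1.0]

    def test_matches_exhaustive_enumeration_on_central_het_run(self):
        pos = np.arange(1, 101) * 10_000
        calls = np.full(100, GT.HOM_REF, dtype=np.int8)
        calls[49:52] = GT.HET
        fast = snp_hit_fractions(pos, calls, P)
        slow = oracle_hit_fractions(pos, calls, P)
        np.testing.assert_allclose(fast, slow)
        # the het cluster depresses the surrounding fractions
        assert fast[50] < 1.0 and fast[0] == 1.0

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            m, params = random_instance(rng, max_snps=120)
            pos = m.positions["1"]
            calls = m.calls["1"][:, 0]
            np.testing.assert_allclose(
                snp_hit_fractions(pos, calls, params),
                oracle_hit_fractions(pos, calls, params),
            )


class TestCallSegments:
    def test_all_het_chromosome_yields_nothing(self):
        m = make_matrix(np.arange(1, 201) * 10_000, np.full(200, GT.HET))
        assert call_segments(m, "s0", P) == []

    def test_long_homozygous_run_is_one_segment(self):
        m = make_matrix(np.arange(1, 201) * 10_000, np.full(200, GT.HOM_REF))
        segs = call_segments(m, "s0", P)
        assert len(segs) == 1
        (s,) = segs
        assert (s.start_bp, s.end_bp, s.n_snps) == (10_000, 2_000_000, 200)
        assert s.length_bp == 1_990_001
        assert segs == oracle_call_segments(m, "s0", P)

    @pytest.mark.parametrize("n_snps,expect_segment", [(60, True), (40, False)])
    def test_minimum_length_gate(self, n_snps, expect_segment):
        # 60 SNPs at 10 kb span 590,001 bp (passes the 500 kb floor);
        # 40 SNPs span 390,001 bp (fails it)
        m = make_matrix(np.arange(1, n_snps + 1) * 10_000, np.full(n_snps, GT.HOM_ALT))
        segs = call_segments(m, "s0", P)
        assert bool(segs) is expect_segment
        assert segs == oracle_call_segments(m, "s0", P)

    def test_run_splits_at_large_gap(self):
        pos = np.concatenate([np.arange(1, 101) * 10_000, 3_000_000 + np.arange(1, 101) * 10_000])
        m = make_matrix(pos, np.full(200, GT.HOM_REF))
        segs = call_segments(m, "s0", P)
        assert len(segs) == 2
        assert segs == oracle_call_segments(m, "s0", P)

    def test_unknown_sample_is_error(self):
        m = make_matrix([1000], [GT.HOM_REF])
        with pytest.raises(KeyError):
            call_segments(m, "nope", P)

    def test_identical_samples_get_identical_segments(self):
        rng = np.random.default_rng(3)
        pos = np.cumsum(rng.integers(1, 20_000, size=300)).astype(np.int64)
        col = rng.choice([0, 1, 2], size=300, p=[0.6, 0.05, 0.35]).astype(np.int8)
        m = make_matrix(pos, np.column_stack([col, col]), samples=["a", "b"])
        segs = call_all(m, P)
        a = [(s.chrom, s.start_bp, s.end_bp, s.n_snps) for s in segs if s.sample_id == "a"]
        b = [(s.chrom, s.start_bp, s.end_bp, s.n_snps) for s in segs if s.sample_id == "b"]
        assert a == b

    def test_empty_matrix_yields_empty_list(self):
        m = make_matrix([], np.empty((0, 1), dtype=np.int8), samples=["a"])
        assert call_all(m, P) == []


class TestOracleEquivalence:
    def test_random_instances_agree_exactly(self):
        rng = np.random.default_rng(2024)
        for _ in range(250):
            m, params = random_instance(rng)
            assert call_segments(m, "s0", params) == oracle_call_segments(m, "s0", params)

    def test_oracle_refuses_large_instances(self):
        m = make_matrix(np.arange(1, 602) * 1000, np.zeros(601, dtype=np.int8))
        with pytest.raises(ValueError, match="limited"):
            oracle_call_segments(m, "s0", P)


class TestInvariantsAndMonotonicity:
    def test_emitted_segments_satisfy_all_segment_invariants(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            m, params = random_instance(rng)
            segs = call_segments(m, "s0", params)
            validate_segments(segs, m, params)

    def test_raising_allowances_never_shrinks_called_length(self):
        # on dense instances where the density cap is slack, enlarging the
        # per-window allowances can only grow the eligible set and the runs
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = 400
            pos = np.cumsum(rng.integers(1, 8_000, size=n)).astype(np.int64)
            calls = rng.choice([0, 1, 2, 3], size=n, p=[0.55, 0.1, 0.3, 0.05]).astype(np.int8)
            m = make_matrix(pos, calls)
            totals = []
            for het, mis in [(0, 0), (1, 2), (2, 4), (3, 8)]:
                params = CallerParams(
                    het_allowed_per_window=het,
                    missing_allowed_per_window=mis,
                    min_density_bp_per_snp=1_000_000,
                )
                totals.append(sum(s.length_bp for s in call_segments(m, "s0", params)))
            assert totals == sorted(totals)

    def test_hit_fractions_monotone_in_allowances(self):
        rng = np.random.default_rng(23)
        m, params = random_instance(rng)
        pos, calls = m.positions["1"], m.calls["1"][:, 0]
        base = snp_hit_fractions(pos, calls, params)
        import dataclasses

        looser = dataclasses.replace(
            params,
            het_allowed_per_window=params.het_allowed_per_window + 1,
            missing_allowed_per_window=params.missing_allowed_per_window + 2,
        )
        assert np.all(snp_hit_fractions(pos, calls, looser) >= base)
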