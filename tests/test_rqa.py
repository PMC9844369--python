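import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rqa_oracle import oracle_embed, oracle_matrix, oracle_measures
from stepshape.rqa import (
    RQAParams,
    embed,
    recurrence_matrix,
    rqa_measures,
    run_arqa,
    run_crqa,
    run_mdrqa,
    select_delay,
    select_dim,
)


def assert_matches_oracle(r, lmin, theiler):
    got = rqa_measures(r, lmin, theiler)
    exp = oracle_measures(r.astype(int).tolist(), lmin, theiler)
    assert got.rec_pct == pytest.approx(exp["rec"], abs=1e-12)
    assert got.det_pct == pytest.approx(exp["det"], abs=1e-12)
    assert got.entropy == pytest.approx(exp["ent"], abs=1e-12)
    assert got.lmax == exp["lmax"]
    assert got.lam_pct == pytest.approx(exp["lam"], abs=1e-12)


class TestAgainstOracle:
    def test_alternating_series_cross_of_itself(self):
        # 0/1 alternating, dim 1, radius 0.5, LOI excluded: same-parity pairs
        # recur; off-diagonal recurrence 12/30
        emb = embed(np.array([0.0, 1, 0, 1, 0, 1]), 1, 0)
        r = recurrence_matrix(emb, emb, 0.5)
        m = rqa_measures(r, 2, 0)
        assert m.rec_pct == pytest.approx(40.0)
        assert m.det_pct == pytest.approx(100.0)
        assert m.lmax == 4
        assert m.entropy == pytest.approx(1.0)  # line lengths {4,4,2,2}
        assert_matches_oracle(r, 2, 0)

    def test_all_ones_theiler_one(self):
        # 6x6 all-ones: excluded band |i-j|<=1 leaves diagonals of lengths
        # 4,4,3,3,2,2,1,1; lines >= 2 give lmax 4 and entropy log2(3)
        r = np.ones((6, 6), dtype=bool)
        m = rqa_measures(r, 2, 1)
        assert m.rec_pct == 100.0
        assert m.lmax == 4
        assert m.entropy == pytest.approx(np.log2(3))
        assert_matches_oracle(r, 2, 1)

    def test_isolated_recurrences_have_no_determinism(self):
        # recurrent points only at even-even cells: no diagonal or vertical runs
        i, j = np.meshgrid(np.arange(8), np.arange(8), indexing="ij")
        r = (i % 2 == 0) & (j % 2 == 0)
        m = rqa_measures(r, 2, None)
        assert m.det_pct == 0.0 and m.lam_pct == 0.0 and m.lmax == 0
        assert_matches_oracle(r, 2, None)

    def test_checkerboard_matches_oracle(self):
        i, j = np.meshgrid(np.arange(6), np.arange(6), indexing="ij")
        assert_matches_oracle((i + j) % 2 == 1, 2, None)

    def test_single_vertical_run(self):
        r = np.zeros((5, 3), dtype=bool)
        r[:, 1] = True
        m = rqa_measures(r, 2, None)
        assert m.lam_pct == pytest.approx(100.0)
        assert m.det_pct == 0.0
        assert_matches_oracle(r, 2, None)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        n=st.integers(10, 60),
        lmin=st.integers(2, 4),
        theiler=st.sampled_from([None, 0, 1, 2]),
        dim=st.integers(1, 3),
    )
    def test_random_series_equal_oracle(self, seed, n, lmin, theiler, dim):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        delay = 2
        radius = float(rng.uniform(0.2, 2.0))
        emb = embed(x, dim, delay)
        r = recurrence_matrix(emb, None, radius)
        o = oracle_matrix(oracle_embed(x, dim, delay), oracle_embed(x, dim, delay), radius)
        assert np.array_equal(r, np.array(o, dtype=bool))
        assert_matches_oracle(r, lmin, theiler)


class TestMatrixProperties:
    def test_auto_matrix_symmetric_cross_not(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        ra = recurrence_matrix(embed(x, 2, 1), None, 1.0)
        assert np.array_equal(ra, ra.T)
        rc = recurrence_matrix(embed(x, 2, 1), embed(y, 2, 1), 1.0)
        assert not np.array_equal(rc, rc.T)

    def test_recurrence_monotone_in_radius(self, rng):
        x = rng.normal(size=80)
        emb = embed(x, 2, 1)
        rates = [
            rqa_measures(recurrence_matrix(emb, None, r), 2, 0).rec_pct
            for r in (0.2, 0.5, 1.0, 2.0)
        ]
        assert all(a <= b for a, b in zip(rates, rates[1:]))

    def test_affine_invariance_after_zscore(self, rng):
        x = rng.normal(size=300)
        m1, _ = run_arqa(x, RQAParams(delay=2, dim=3))
        m2, _ = run_arqa(4.2 * x - 17.0, RQAParams(delay=2, dim=3))
        assert m1 == m2

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            recurrence_matrix(rng.normal(size=(10, 2)), rng.normal(size=(10, 3)), 1.0)

    def test_tiny_radius_no_recurrence(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        r = recurrence_matrix(embed(x, 1, 0), embed(y, 1, 0), 1e-12)
        assert rqa_measures(r, 2, None).rec_pct == 0.0


class TestParameterSelection:
    def test_sine_delay_quarter_period(self, rng):
        # measured (noisy) sinusoid: AMI first minimum at the quarter period
        t = np.arange(2000)
        x = np.sin(2 * np.pi * t / 40) + rng.normal(0, 0.1, 2000)
        assert select_delay(x) == pytest.approx(10, abs=2)

    def test_white_noise_delay_one(self, rng):
        assert select_delay(rng.normal(size=2000)) == 1

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            select_delay(np.ones(500))
        with pytest.raises(ValueError):
            select_dim(np.ones(500), 1)

    def test_sine_dim_two(self):
        t = np.arange(3000)
        x = np.sin(2 * np.pi * t / 40)
        assert select_dim(x, 10) == 2

    def test_logistic_map_low_dim(self):
        x = np.empty(2000)
        x[0] = 0.4
        for i in range(1, 2000):
            x[i] = 3.99 * x[i - 1] * (1 - x[i - 1])
        assert select_dim(x, 1) <= 3

    def test_white_noise_hits_cap_with_warning(self, rng):
        with pytest.warns(UserWarning):
            m = select_dim(rng.normal(size=400), 1, max_dim=6)
        assert m == 6


class TestAnalyses:
    def test_periodic_arqa_highly_deterministic(self):
        t = np.arange(1200)
        x = np.sin(2 * np.pi * t / 60)
        m, params = run_arqa(x)
        assert m.det_pct >= 95.0
        assert params.theiler == params.delay * params.dim

    def test_noise_arqa_less_deterministic_than_periodic(self, rng):
        t = np.arange(800)
        m_per, _ = run_arqa(np.sin(2 * np.pi * t / 60), RQAParams(delay=15, dim=2))
        m_noise, _ = run_arqa(rng.normal(size=800), RQAParams(delay=15, dim=2))
        assert m_noise.det_pct < m_per.det_pct

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            run_arqa(np.ones(500))

    def test_crqa_identical_series(self, rng):
        x = np.cumsum(rng.normal(size=400))
        m, _ = run_crqa(x, x.copy(), RQAParams(delay=1, dim=2))
        # the line of identity itself recurs entirely
        assert m.lmax == 399  # full-length LOI of the embedded series
        assert m.det_pct > 95.0

    def test_crqa_shuffling_destroys_determinism(self, rng):
        t = np.arange(600)
        hip = np.sin(2 * np.pi * t / 60)
        knee = np.sin(2 * np.pi * t / 60 + 0.3)
        m_coupled, _ = run_crqa(knee, hip, RQAParams(delay=15, dim=2))
        m_shuffled, _ = run_crqa(rng.permutation(knee), hip, RQAParams(delay=15, dim=2))
        assert m_shuffled.det_pct < m_coupled.det_pct

    def test_crqa_antiphase_still_lines(self):
        t = np.arange(600)
        hip = np.sin(2 * np.pi * t / 60)
        m, _ = run_crqa(-hip, hip, RQAParams(delay=15, dim=2))
        assert m.lmax >= 2

    def test_mdrqa_identical_channels_match_arqa(self, rng):
        t = np.arange(500)
        x = np.sin(2 * np.pi * t / 50) + 0.05 * rng.normal(size=500)
        block = np.tile(x[:, None], (1, 7))
        # identical z-scored channels: distances scale by sqrt(7), so the
        # fractional radius selects exactly the same pairs as 1-D aRQA
        m_md, _ = run_mdrqa(block, RQAParams(theiler=1))
        m_a, _ = run_arqa(x, RQAParams(delay=0, dim=1, theiler=1))
        assert m_md == m_a

    def test_mdrqa_constant_block_rejected(self):
        with pytest.raises(ValueError):
            run_mdrqa(np.ones((100, 7)))

    def test_mdrqa_coupled_channels_longer_lines(self, rng):
        t = np.arange(600)
        base = np.sin(2 * np.pi * t / 60)
        coupled = np.column_stack([base * (1 + 0.05 * k) for k in range(7)])
        uncoupled = rng.normal(size=(600, 7))
        m_c, _ = run_mdrqa(coupled + 0.01 * rng.normal(size=coupled.shape))
        m_u, _ = run_mdrqa(uncoupled)
        assert m_c.lmax > m_u.lmax
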