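"""Insert tuple geometry, the product-limit estimator, and CDF distances.

Oracles: hand-worked KM values, the lifelines implementation, an exact
geometric identity (t_o = t_l + t_r - contig_length), and dense-grid
numeric integration for the Wasserstein distance.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqsentry.insert_size_km import (InsertTuple, StepCDF, build_tuples,
                                      distribution_distance, km_estimate,
                                      km_estimate_ipcw, naive_estimate)
from seqsentry.mini_aligner import AlignmentRecord, pair_and_flag


def _rec(name="p", contig=0, start=0, strand="+", mapped=True, mapq=60,
         length=150, is_read1=True):
    return AlignmentRecord(name, "A" * length, "I" * length, mapped=mapped,
                           contig=contig, start=start, strand=strand,
                           cigar=[("M", length)] if mapped else [],
                           mapq=mapq, is_read1=is_read1)


def observed(t_o, t_l=10_000, t_r=10_000):
    return InsertTuple(t_o, t_l, t_r)


def censored(t):
    return InsertTuple(None, t, None)


class TestInsertTuple:
    def test_observed_requires_bounds(self):
        with pytest.raises(ValueError):
            InsertTuple(500, 400, 600)  # t_o > t_l

    def test_single_end_needs_exactly_one(self):
        with pytest.raises(ValueError):
            InsertTuple(None, 100, 200)
        with pytest.raises(ValueError):
            InsertTuple(None, None, None)

    def test_censor_time(self):
        assert censored(321).censor_time == 321
        assert InsertTuple(None, None, 77).censor_time == 77


class TestBuildTuples:
    def test_proper_pair_geometry(self, small_world):
        """Contig 501, read1 fwd at 0, read2 rev ending at 400."""
        ref = small_world["ref"]
        ci = next(i for i, c in enumerate(ref.contigs) if len(c.seq) == 501)
        a1 = _rec(contig=ci, start=0, strand="+")
        a2 = _rec(contig=ci, start=250, strand="-", is_read1=False)
        pair = pair_and_flag(a1, a2)
        assert pair.proper and pair.t_o == 400
        (tup,) = build_tuples([pair], ref)
        assert tup.t_o == 400
        assert tup.t_l == 501      # leftmost base of fwd read to contig end
        assert tup.t_r == 400      # rightmost base of rev read to contig start

    def test_geometric_identity_oracle(self, small_world):
        """t_o = t_l + t_r - L for every proper pair, by construction."""
        ref = small_world["ref"]
        rng = np.random.default_rng(3)
        pairs = []
        for _ in range(100):
            ci = int(rng.integers(len(ref)))
            L = len(ref.contigs[ci].seq)
            s1 = int(rng.integers(0, L - 320))
            e2 = int(rng.integers(s1 + 301, L))
            a1 = _rec(contig=ci, start=s1, strand="+")
            a2 = _rec(contig=ci, start=e2 - 150, strand="-", is_read1=False)
            pairs.append(pair_and_flag(a1, a2))
        for pair, tup in zip(pairs, build_tuples(pairs, ref)):
            L = len(ref.contigs[pair.mate1.contig].seq)
            assert tup.t_o == tup.t_l + tup.t_r - L
            assert tup.t_o == pair.t_o

    def test_single_end_forward(self, small_world):
        ref = small_world["ref"]
        ci = next(i for i, c in enumerate(ref.contigs) if len(c.seq) == 501)
        a1 = _rec(contig=ci, start=100, strand="+")
        a2 = _rec(mapped=False, is_read1=False)
        (tup,) = build_tuples([pair_and_flag(a1, a2)], ref)
        assert tup.t_o is None and tup.t_l == 401 and tup.t_r is None

    def test_single_end_reverse(self, small_world):
        ref = small_world["ref"]
        ci = next(i for i, c in enumerate(ref.contigs) if len(c.seq) == 501)
        a1 = _rec(mapped=False)
        a2 = _rec(contig=ci, start=250, strand="-", is_read1=False)
        (tup,) = build_tuples([pair_and_flag(a1, a2)], ref)
        assert tup.t_o is None and tup.t_l is None and tup.t_r == 400

    def test_different_contigs_discarded(self, small_world):
        pair = pair_and_flag(_rec(contig=0), _rec(contig=1, strand="-",
                                                  is_read1=False))
        assert build_tuples([pair], small_world["ref"]) == []

    def test_low_mapq_single_end_discarded(self, small_world):
        a1 = _rec(mapq=5)
        a2 = _rec(mapped=False, is_read1=False)
        assert build_tuples([pair_and_flag(a1, a2)], small_world["ref"]) == []


class TestKmEstimate:
    def test_hand_worked_example(self):
        """Events {100, 200}, censored {150}: F(100)=1/3, F(199)=1/3, F(200)=1."""
        tuples = [observed(100), observed(200), censored(150)]
        curve = km_estimate(tuples)
        f = curve.cdf
        assert f(100) == pytest.approx(1 / 3)
        assert f(199) == pytest.approx(1 / 3)
        assert f(200) == pytest.approx(1.0)
        assert curve.risk.tolist() == [3, 2, 1]

    def test_no_censoring_equals_ecdf_exactly(self):
        rng = np.random.default_rng(1)
        vals = rng.integers(100, 600, size=200)
        tuples = [observed(int(v)) for v in vals]
        curve = km_estimate(tuples)
        ec = naive_estimate(tuples)
        grid = np.unique(vals).astype(float)
        np.testing.assert_allclose(curve.cdf(grid), ec(grid), rtol=0, atol=1e-15)

    def test_exact_rational_oracle(self):
        """Product-limit values match an exact-fraction reimplementation."""
        from fractions import Fraction

        ev = [100, 150, 150, 300, 420]
        ce = [120, 150, 360]
        tuples = [observed(v) for v in ev] + [censored(v) for v in ce]
        curve = km_estimate(tuples)
        times = sorted(set(ev + ce))
        s = Fraction(1)
        expected = []
        for t in times:
            o = ev.count(t)
            y = sum(1 for v in ev if v >= t) + sum(1 for v in ce if v >= t)
            s *= Fraction(y - o, y)
            expected.append(s)
        for got, exp in zip(curve.survival, expected):
            assert got == pytest.approx(float(exp), abs=1e-15)
        # and the zero-censoring case is exact ECDF as fractions
        tuples2 = [observed(v) for v in ev]
        curve2 = km_estimate(tuples2)
        n = len(ev)
        k = 0
        for t, srv in zip(curve2.times, curve2.survival):
            k += ev.count(t)
            assert srv == float(Fraction(n - k, n))

    def test_survival_monotone_and_risk_bound(self):
        rng = np.random.default_rng(2)
        tuples = [observed(int(v)) for v in rng.integers(100, 600, size=300)]
        tuples += [censored(int(v)) for v in rng.integers(100, 600, size=200)]
        curve = km_estimate(tuples)
        assert (np.diff(curve.survival) <= 1e-12).all()
        assert ((curve.risk >= curve.events + curve.censored)).all()
        assert curve.risk[0] == len(tuples)

    def test_zero_events_error(self):
        with pytest.raises(ValueError, match="no properly paired"):
            km_estimate([censored(100)])

    def test_against_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(12)
        ev = rng.integers(200, 500, size=400)
        ce = rng.integers(200, 500, size=300)
        tuples = [observed(int(v)) for v in ev] + [censored(int(v)) for v in ce]
        curve = km_estimate(tuples)
        kmf = lifelines.KaplanMeierFitter()
        durations = np.concatenate([ev, ce])
        event_flags = np.concatenate([np.ones(len(ev)), np.zeros(len(ce))])
        kmf.fit(durations, event_flags)
        ours = curve.survival
        theirs = kmf.survival_function_at_times(curve.times).to_numpy()
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_ipcw_reformulation_agrees(self):
        rng = np.random.default_rng(13)
        for trial in range(5):
            ev = rng.integers(100, 400, size=150)
            ce = rng.integers(100, 400, size=120)
            tuples = ([observed(int(v)) for v in ev]
                      + [censored(int(v)) for v in ce])
            km = km_estimate(tuples).cdf
            ipcw = km_estimate_ipcw(tuples)
            grid = np.unique(ev)
            np.testing.assert_allclose(km(grid), ipcw(grid), atol=1e-10)

    def test_defective_flag(self):
        curve = km_estimate([observed(100), censored(500)])
        assert curve.defective
        curve2 = km_estimate([observed(100), censored(50)])
        assert not curve2.defective

    def test_quantiles_interpolated(self):
        curve = km_estimate([observed(v) for v in (100, 200, 300, 400)])
        med = curve.quantile(0.5)
        assert 100 <= med <= 300


class TestNaive:
    def test_single_event_step(self):
        f = naive_estimate([observed(300)])
        assert f(299) == 0.0 and f(300) == 1.0

    def test_censoring_ignored(self):
        tuples = [observed(100), observed(300), censored(200)]
        f = naive_estimate(tuples)
        assert f(100) == pytest.approx(0.5)


class TestDistances:
    def test_identical_zero(self):
        f = StepCDF(np.array([1.0, 2.0]), np.array([0.5, 1.0]))
        assert distribution_distance(f, f) == (0.0, 0.0)

    def test_extreme_steps(self):
        f1 = StepCDF(np.array([0.0]), np.array([1.0]))
        f2 = StepCDF(np.array([1000.0]), np.array([1.0]))
        d, w = distribution_distance(f1, f2)
        assert d == 1.0 and w == pytest.approx(1.0)

    def test_against_dense_grid_oracle(self):
        f1 = StepCDF(np.array([10.0, 20.0, 40.0]), np.array([0.2, 0.7, 1.0]))
        f2 = StepCDF(np.array([15.0, 25.0, 35.0]), np.array([0.3, 0.6, 1.0]))
        d, w = distribution_distance(f1, f2)
        dense = np.linspace(0, 40, 400_001)
        v1, v2 = f1(dense), f2(dense)
        d_oracle = np.abs(v1 - v2).max()
        w_oracle = np.trapezoid(np.abs(v1 - v2), dense) / 40.0
        assert d == pytest.approx(d_oracle, abs=1e-9)
        assert w == pytest.approx(w_oracle, abs=1e-4)

    @given(st.lists(st.integers(min_value=1, max_value=1000), min_size=1,
                    max_size=30),
           st.lists(st.integers(min_value=1, max_value=1000), min_size=1,
                    max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_metric_properties(self, xs, ys):
        f1 = naive_estimate([observed(v) for v in xs])
        f2 = naive_estimate([observed(v) for v in ys])
        d12, w12 = distribution_distance(f1, f2)
        d21, w21 = distribution_distance(f2, f1)
        assert d12 == d21 and w12 == w21
        assert 0 <= d12 <= 1 and w12 >= 0


def geometry_sim(n_pairs, contig_len, rng, mu=350.0, sd=50.0, read_len=150):
    """Fragments dropped uniformly over an infinite tiling of one contig.

    Returns tuples as the pipeline would build them, plus true inserts.
    """
    inserts = rng.normal(mu, sd, size=n_pairs)
    while (inserts < 2 * read_len).any():
        bad = inserts < 2 * read_len
        inserts[bad] = rng.normal(mu, sd, size=int(bad.sum()))
    inserts = np.round(inserts).astype(int)
    # fragment left ends uniform relative to the contig start
    starts = rng.integers(-600, contig_len + 600, size=n_pairs)
    tuples = []
    for s, ins in zip(starts, inserts):
        e = s + ins
        left_in = s >= 0 and s + read_len <= contig_len
        right_in = e - read_len >= 0 and e <= contig_len
        if left_in and right_in:
            tuples.append(InsertTuple(int(ins), contig_len - int(s), int(e)))
        elif left_in:
            tuples.append(InsertTuple(None, contig_len - int(s), None))
        elif right_in:
            tuples.append(InsertTuple(None, None, int(e)))
    return tuples, inserts


class TestBiasRemoval:
    def test_km_beats_naive_under_censoring(self):
        """On short contigs the KM curve tracks truth; the ECDF is biased."""
        rng = np.random.default_rng(77)
        wins = 0
        n_rep = 20
        for _ in range(n_rep):
            tuples, inserts = geometry_sim(5000, 501, rng)
            truth = StepCDF(*np.unique(inserts, return_counts=True))
            truth = StepCDF(truth.times,
                            np.cumsum(truth.values) / truth.values.sum())
            km = km_estimate(tuples).cdf
            nv = naive_estimate(tuples)
            d_km, w_km = distribution_distance(km, truth)
            d_nv, w_nv = distribution_distance(nv, truth)
            if d_km < d_nv and w_km < w_nv:
                wins += 1
        assert wins >= int(0.95 * n_rep)

    def test_naive_stochastically_larger(self):
        rng = np.random.default_rng(88)
        tuples, inserts = geometry_sim(5000, 501, rng)
        km = km_estimate(tuples).cdf
        nv = naive_estimate(tuples)
        grid = np.arange(300, 550)
        assert (nv(grid) >= km(grid) - 1e-12).all()
        assert nv(grid).mean() > km(grid).mean()

    def test_consistency_with_n(self):
        rng = np.random.default_rng(99)
        errs = []
        for n in (500, 5000, 50_000):
            tuples, inserts = geometry_sim(n, 2001, rng)
            truth_x, truth_c = np.unique(inserts, return_counts=True)
            truth = StepCDF(truth_x.astype(float),
                            np.cumsum(truth_c) / truth_c.sum())
            km = km_estimate(tuples).cdf
            d, _ = distribution_distance(km, truth)
            errs.append(d)
        assert errs[2] < errs[0]
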