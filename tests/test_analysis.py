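"""Q statistics, free-energy profiles, TSE selection, φ, Δprob and h_p."""

import numpy as np
import pytest

from gofrust.analysis import (
    KEPT_LAMBDA,
    PhiProfile,
    QTrace,
    SelectionError,
    compare_phi,
    contact_kept,
    contact_probability_increase,
    find_two_peaks,
    free_energy_profile,
    h_p_table,
    kept_flags,
    phi_values,
    select_tse,
    two_state_summary,
)
from gofrust.structures import (
    ContactPair,
    InputError,
    NativeTopology,
    SecondaryStructureMap,
)


def _toy_topology(n=8, contacts=None):
    ca = np.zeros((n, 3))
    ca[:, 0] = 3.8 * np.arange(n)
    return NativeTopology(
        n_residues=n, ca0=ca,
        bond_r0=np.full(n - 1, 3.8),
        angle_theta0=np.full(n - 2, np.pi),
        dihedral_phi0=np.zeros(n - 3),
        contacts=contacts if contacts is not None else [
            ContactPair(1, 5, 5.0, 1.0),
            ContactPair(2, 6, 5.0, 1.0),
            ContactPair(1, 8, 6.0, 1.0),
            ContactPair(4, 8, 5.5, 1.0),
        ],
    )


class TestContactKept:
    def test_boundary_convention(self):
        assert contact_kept(5.0, 5.0)
        assert contact_kept(1.2 * 5.0, 5.0)          # boundary counts as kept
        assert not contact_kept(1.2 * 5.0 + 1e-9, 5.0)
        assert not contact_kept(10.0, 5.0)

    def test_vectorized(self):
        r = np.array([1.0, 1.19, 1.21]) * 5.0
        assert contact_kept(r, 5.0).tolist() == [True, True, False]

    def test_lambda_must_exceed_one(self):
        with pytest.raises(InputError):
            contact_kept(5.0, 5.0, lam=1.0)


class TestFreeEnergyProfile:
    def test_uniform_trace_is_flat(self):
        q = QTrace(np.repeat(np.arange(5), 20), nc=10)
        prof = free_energy_profile(q, t_avg=1.0)
        assert prof.f_values == pytest.approx(np.zeros(5), abs=1e-12)

    def test_hand_computed_three_level_profile(self):
        counts = [40, 10, 50]
        q = QTrace(np.repeat([10, 30, 55], counts), nc=60)
        prof = free_energy_profile(q, t_avg=1.0)
        assert prof.q_bins.tolist() == [10, 30, 55]
        # -ln(0.4, 0.1, 0.5) offset so the minimum is zero
        expected = -np.log([0.4, 0.1, 0.5])
        expected -= expected.min()
        assert prof.f_values == pytest.approx(expected, abs=1e-3)
        assert prof.f_values[0] == pytest.approx(0.223, abs=5e-4)
        assert prof.f_values[1] == pytest.approx(1.609, abs=5e-4)
        assert prof.f_values[2] == pytest.approx(0.0, abs=1e-12)

    def test_reconstruction_recovers_empirical_distribution(self, rng):
        qc = rng.integers(0, 21, size=5000)
        q = QTrace(qc, nc=20)
        t_avg = 0.37
        prof = free_energy_profile(q, t_avg)
        p_rec = np.exp(-prof.f_values / t_avg)
        p_rec /= p_rec.sum()
        p_emp = prof.counts / prof.counts.sum()
        assert p_rec == pytest.approx(p_emp, abs=1e-12)

    def test_temperature_scales_profile(self):
        q = QTrace(np.repeat([2, 9], [30, 10]), nc=10)
        p1 = free_energy_profile(q, t_avg=1.0)
        p2 = free_energy_profile(q, t_avg=2.0)
        assert p2.f_values == pytest.approx(2.0 * p1.f_values)


class TestTSESelection:
    @staticmethod
    def _bimodal_trace(rng, mu1=8, mu2=32, sigma=4.0, n=20000, nc=40):
        a = rng.normal(mu1, sigma, n // 2)
        b = rng.normal(mu2, sigma, n // 2)
        q = np.clip(np.round(np.concatenate([a, b])), 0, nc).astype(int)
        return QTrace(q, nc=nc)

    def test_window_brackets_the_density_minimum(self, rng):
        q = self._bimodal_trace(rng)
        tse = select_tse(q, t_avg=1.0)
        # analytic minimum of an equal two-Gaussian mixture: midpoint
        assert tse.q_window[0] < 20 < tse.q_window[1]
        assert abs(tse.valley - 20) <= 1
        assert tse.low_peak < tse.q_window[0]
        assert tse.high_peak > tse.q_window[1]

    def test_symmetric_mixture_window_centered(self, rng):
        q = self._bimodal_trace(rng, mu1=10, mu2=30)
        tse = select_tse(q, t_avg=1.0)
        center = 0.5 * (tse.q_window[0] + tse.q_window[1])
        assert center == pytest.approx(20, abs=1.5)

    def test_selected_snapshots_lie_in_window(self, rng):
        q = self._bimodal_trace(rng)
        tse = select_tse(q, t_avg=1.0)
        sel = q.q_counts[tse.indices]
        assert sel.min() >= tse.q_window[0]
        assert sel.max() <= tse.q_window[1]

    def test_all_folded_trace_fails(self, rng):
        q = QTrace(np.clip(np.round(rng.normal(35, 2, 5000)), 0, 40).astype(int), nc=40)
        with pytest.raises(SelectionError):
            select_tse(q, t_avg=1.0)

    def test_smaller_delta_narrows_window(self, rng):
        q = self._bimodal_trace(rng)
        wide = select_tse(q, t_avg=1.0, delta=1.0)
        narrow = select_tse(q, t_avg=1.0, delta=0.1)
        assert narrow.q_window[0] >= wide.q_window[0]
        assert narrow.q_window[1] <= wide.q_window[1]


class TestPhiValues:
    def test_native_snapshot_gives_phi_one(self):
        topo = _toy_topology()
        kept = np.ones((1, topo.n_contacts), dtype=bool)
        phi = phi_values(kept, topo)
        assert np.nanmax(phi.phi) == np.nanmin(phi.phi) == 1.0
        # residues without native contacts are undefined, not zero
        assert np.isnan(phi.phi[2])        # residue 3 has no contacts

    def test_fully_broken_gives_phi_zero(self):
        topo = _toy_topology()
        kept = np.zeros((3, topo.n_contacts), dtype=bool)
        phi = phi_values(kept, topo)
        defined = phi.defined
        assert np.all(phi.phi[defined] == 0.0)

    def test_three_snapshot_counting_oracle(self):
        topo = _toy_topology()
        kept = np.array([
            [1, 0, 1, 0],
            [1, 1, 0, 0],
            [0, 0, 0, 1],
        ], dtype=bool)
        phi = phi_values(kept, topo)
        # residue 1 participates in contacts (1,5) and (1,8):
        # snapshot sums 2,1,0 -> mean 1 over native 2
        assert phi.phi[0] == pytest.approx(1.0 / 2.0 * 1.0)
        # residue 8 in contacts (1,8) and (4,8): sums 1,0,1 -> 2/3 over 2
        assert phi.phi[7] == pytest.approx((2 / 3) / 2)
        # residue 2 in contact (2,6): 0,1,0 -> 1/3
        assert phi.phi[1] == pytest.approx(1 / 3)
        assert np.all((phi.phi[phi.defined] >= 0) & (phi.phi[phi.defined] <= 1))

    def test_empty_tse_rejected(self):
        topo = _toy_topology()
        with pytest.raises(InputError):
            phi_values(np.zeros((0, 4), dtype=bool), topo)

    def test_phi_bounds_property(self, rng):
        topo = _toy_topology()
        for _ in range(20):
            kept = rng.random((7, topo.n_contacts)) < rng.random()
            phi = phi_values(kept, topo)
            d = phi.defined
            assert np.all(phi.phi[d] >= 0) and np.all(phi.phi[d] <= 1)


class TestComparePhi:
    @staticmethod
    def _profile(values, native=None):
        v = np.asarray(values, dtype=float)
        n = np.asarray(native if native is not None else np.ones(len(v)),
                       dtype=np.int64)
        return PhiProfile(phi=np.where(n > 0, v, np.nan), native_counts=n,
                          tse_size=10)

    def test_identical_profiles(self):
        a = self._profile([0.1, 0.5, 0.9, 0.3])
        comp = compare_phi(a, a)
        assert comp.pearson_r == pytest.approx(1.0)
        assert comp.mean_increment == pytest.approx(0.0)

    def test_affine_shift(self):
        a = self._profile([0.1, 0.5, 0.9])
        b = self._profile([0.2, 0.6, 1.0])
        comp = compare_phi(a, b)
        assert comp.pearson_r == pytest.approx(1.0)
        assert comp.mean_increment == pytest.approx(0.10)
        assert comp.std_increment == pytest.approx(0.0, abs=1e-12)

    def test_matches_covariance_formula_on_random_profiles(self, rng):
        for _ in range(10):
            x = rng.random(50)
            y = rng.random(50)
            comp = compare_phi(self._profile(x), self._profile(y))
            xm, ym = x - x.mean(), y - y.mean()
            r_direct = (xm @ ym) / np.sqrt((xm @ xm) * (ym @ ym))
            assert comp.pearson_r == pytest.approx(r_direct, abs=1e-12)

    def test_undefined_residues_excluded_pairwise(self):
        a = self._profile([0.1, 0.5, 0.9, 0.7], native=[1, 1, 1, 0])
        b = self._profile([0.2, 0.6, 1.0, 0.1], native=[1, 1, 1, 1])
        comp = compare_phi(a, b)
        assert comp.n_defined == 3
        assert np.isnan(comp.increments[3])

    def test_too_few_defined_rejected(self):
        a = self._profile([0.1, 0.5], native=[1, 1])
        with pytest.raises(InputError):
            compare_phi(a, a)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            compare_phi(self._profile([0.1, 0.2, 0.3]),
                        self._profile([0.1, 0.2, 0.3, 0.4]))


class TestContactProbability:
    def test_identical_ensembles_give_zero(self, rng):
        topo = _toy_topology()
        kept = rng.random((10, 4)) < 0.6
        d = contact_probability_increase(kept, kept, topo)
        assert d == pytest.approx(np.zeros(4))

    def test_hand_arithmetic(self):
        topo = _toy_topology()
        a = np.zeros((10, 4), dtype=bool); a[:6, 0] = True
        b = np.zeros((10, 4), dtype=bool); b[:9, 0] = True
        d = contact_probability_increase(a, b, topo)
        assert d[0] == pytest.approx(0.3)
        assert d[1:] == pytest.approx(np.zeros(3))

    def test_counting_oracle(self, rng):
        topo = _toy_topology()
        a = rng.random((7, 4)) < 0.5
        b = rng.random((9, 4)) < 0.5
        d = contact_probability_increase(a, b, topo)
        for k in range(4):
            expected = b[:, k].sum() / 9 - a[:, k].sum() / 7
            assert d[k] == pytest.approx(expected, abs=1e-12)

    def test_empty_ensemble_rejected(self):
        topo = _toy_topology()
        with pytest.raises(InputError):
            contact_probability_increase(np.zeros((0, 4), dtype=bool),
                                         np.ones((3, 4), dtype=bool), topo)


class TestHpTable:
    @staticmethod
    def _ss(n=8):
        return SecondaryStructureMap(
            elements=[("Helix I", 1, 3), ("Coil I", 4, 5), ("Helix II", 6, 8)])

    def test_all_zero_dprob(self):
        topo = _toy_topology()
        table = h_p_table(np.zeros(4), topo, self._ss())
        for p in (0.05, 0.10):
            assert table.counts[p].sum() == 0

    def test_threshold_counting(self):
        # contacts: (1,5) H1-C1, (2,6) H1-H2, (1,8) H1-H2, (4,8) C1-H2
        topo = _toy_topology()
        dprob = np.array([0.12, 0.07, 0.03, -0.12])
        table = h_p_table(dprob, topo, self._ss(), thresholds=(0.05, 0.10))
        h1, c1, h2 = 0, 1, 2
        assert table.counts[0.05][h1, c1] == 1          # 0.12
        assert table.counts[0.05][h1, h2] == 1          # 0.07 (0.03 below)
        assert table.counts[0.10][h1, c1] == 1
        assert table.counts[0.10][h1, h2] == 0
        assert table.counts[0.05][c1, h2] == 0          # -0.12 not an increase
        assert table.signed[0.05][c1, h2] == -1         # signed reading
        assert table.signed[0.10][c1, h2] == -1

    def test_monotone_in_p_cellwise_and_totals(self, rng):
        topo = _toy_topology()
        for _ in range(25):
            dprob = rng.uniform(-0.3, 0.3, 4)
            ths = (0.02, 0.05, 0.10, 0.20)
            table = h_p_table(dprob, topo, self._ss(), thresholds=ths)
            for lo, hi in zip(ths, ths[1:]):
                assert np.all(table.counts[hi] <= table.counts[lo])
                assert np.all(table.totals(hi) <= table.totals(lo))

    def test_exhaustive_enumeration_oracle(self, rng):
        topo = _toy_topology()
        ss = self._ss()
        dprob = rng.uniform(-0.3, 0.3, 4)
        table = h_p_table(dprob, topo, ss, thresholds=(0.05,))
        pos = {lab: k for k, lab in enumerate(ss.labels)}
        expected = np.zeros((3, 3), dtype=int)
        for c, dp in zip(topo.contacts, dprob):
            if dp >= 0.05:
                ea, eb = pos[ss.element_of(c.i)], pos[ss.element_of(c.j)]
                lo, hi = min(ea, eb), max(ea, eb)
                expected[lo, hi] += 1
                if lo != hi:
                    expected[hi, lo] += 1
        assert np.array_equal(table.counts[0.05], expected)

    def test_bad_threshold_rejected(self):
        topo = _toy_topology()
        with pytest.raises(InputError):
            h_p_table(np.zeros(4), topo, self._ss(), thresholds=(0.0,))

    def test_map_must_cover_chain(self):
        topo = _toy_topology()
        short = SecondaryStructureMap(elements=[("Helix I", 1, 5)])
        with pytest.raises(InputError):
            h_p_table(np.zeros(4), topo, short)


class TestSecondaryStructureMap:
    def test_gaps_and_overlaps_rejected(self):
        with pytest.raises(InputError):
            SecondaryStructureMap(elements=[("A", 1, 3), ("B", 5, 8)])
        with pytest.raises(InputError):
            SecondaryStructureMap(elements=[("A", 1, 4), ("B", 3, 8)])

    def test_element_lookup(self):
        ss = SecondaryStructureMap(elements=[("A", 1, 3), ("B", 4, 8)])
        assert ss.element_of(1) == "A"
        assert ss.element_of(4) == "B"
        with pytest.raises(InputError):
            ss.element_of(9)


class TestTwoStateSummary:
    def test_positions_and_barrier_on_synthetic_mixture(self, rng):
        a = rng.normal(8, 2, 8000)
        b = rng.normal(32, 2, 8000)
        q = QTrace(np.clip(np.round(np.concatenate([a, b])), 0, 40).astype(int), nc=40)
        summ = two_state_summary(q, t_avg=1.0)
        assert summ.q_unfolded == pytest.approx(8 / 40, abs=0.05)
        assert summ.q_folded == pytest.approx(32 / 40, abs=0.05)
        assert summ.barrier_from_folded > 0
        assert summ.barrier_from_unfolded > 0


class TestHypothesisProperties:
    """Randomized invariants (derandomized by hypothesis's default seed)."""

    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.floats(-0.5, 0.5), min_size=4, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_h_p_monotone_for_any_dprob(self, dprob):
        topo = _toy_topology()
        ss = SecondaryStructureMap(
            elements=[("Helix I", 1, 3), ("Coil I", 4, 5), ("Helix II", 6, 8)])
        ths = (0.01, 0.05, 0.10, 0.25)
        table = h_p_table(np.asarray(dprob), topo, ss, thresholds=ths)
        for lo, hi in zip(ths, ths[1:]):
            assert np.all(table.counts[hi] <= table.counts[lo])

    @given(st.floats(0.1, 50.0), st.floats(1.01, 3.0), st.floats(0.0, 5.0))
    @settings(max_examples=100, deadline=None)
    def test_contact_kept_threshold_is_sharp(self, r0, lam, scale):
        r = scale * r0
        assert bool(contact_kept(r, r0, lam)) == (r <= lam * r0)
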