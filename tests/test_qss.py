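"""Quasi-steady-state reduction: dimer algebra, inversion, mass matrix."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from floralnet import (
    build_default_topology,
    mass_matrix,
    monomers_from_totals,
    qss_dimer,
    simulate_reduced,
    totals_from_monomers,
)
from floralnet.network import GENES
from floralnet.qss import qss_dimer_vector

concentrations = st.lists(
    st.floats(min_value=1.0, max_value=1.0e4), min_size=6, max_size=6
)


class TestQssDimer:
    def test_arithmetic(self):
        assert qss_dimer(0.0, 123.0, 0.5) == 0.0
        assert qss_dimer(10.0, 20.0, 0.1) == pytest.approx(20.0)
        assert qss_dimer(100.0, 100.0, 0.01) == pytest.approx(100.0)  # homodimer

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            qss_dimer(-1.0, 1.0, 0.1)


class TestTotals:
    def test_zero_maps_to_zero(self, topology):
        assert np.allclose(totals_from_monomers(np.zeros(6), topology), 0.0)

    def test_hand_balance_for_ap1(self):
        """AP1=100, SEP=50 with only the AP1 homo- and heterodimer active:
        total = 100 + 2*0.01*100^2 + 0.1*100*50 = 800 nM."""
        gamma = {n: 0.0 for n in ("[AG AG]", "[AG SEP]", "[AP3 PI]",
                                  "[SEP SEP]", "[SHP SEP]")}
        gamma["[AP1 AP1]"] = 0.01
        gamma["[AP1 SEP]"] = 0.1
        topo = build_default_topology(gamma=gamma)
        x = np.zeros(6)
        x[0], x[5] = 100.0, 50.0
        totals = totals_from_monomers(x, topo)
        assert totals[0] == pytest.approx(800.0)

    def test_monotone_in_monomers(self, topology):
        x = np.array([100.0, 50.0, 40.0, 30.0, 20.0, 60.0])
        base = totals_from_monomers(x, topology)
        for i in range(6):
            bumped = x.copy()
            bumped[i] *= 1.1
            assert (totals_from_monomers(bumped, topology) >= base - 1e-12).all()

    def test_totals_dominate_monomers(self, topology):
        x = np.array([100.0, 50.0, 40.0, 30.0, 20.0, 60.0])
        assert (totals_from_monomers(x, topology) >= x).all()


class TestInversion:
    def test_zero(self, topology):
        assert np.allclose(monomers_from_totals(np.zeros(6), topology), 0.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(concentrations)
    def test_round_trip(self, topology, x):
        x = np.asarray(x)
        totals = totals_from_monomers(x, topology)
        back = monomers_from_totals(totals, topology, tol=1e-12)
        assert np.allclose(back, x, rtol=1e-8)

    def test_homodimer_closed_form(self):
        """One gene with only its homodimer: T = x + 2*gamma*x^2 has the
        positive root x = (-1 + sqrt(1 + 8*gamma*T)) / (4*gamma)."""
        gamma_val = 0.02
        gamma = {n: 0.0 for n in build_default_topology().dimer_names}
        gamma["[AP1 AP1]"] = gamma_val
        topo = build_default_topology(gamma=gamma)
        T = np.zeros(6)
        T[0] = 5.0e3
        x = monomers_from_totals(T, topo, tol=1e-12)
        expected = (-1.0 + np.sqrt(1.0 + 8.0 * gamma_val * T[0])) / (4.0 * gamma_val)
        assert x[0] == pytest.approx(expected, rel=1e-10)
        assert np.allclose(x[1:], 0.0)

    def test_negative_totals_rejected(self, topology):
        with pytest.raises(ValueError):
            monomers_from_totals(np.full(6, -1.0), topology)


class TestMassMatrix:
    def test_identity_at_origin(self, topology):
        assert np.allclose(mass_matrix(np.zeros(6), topology), np.eye(6))

    def test_identity_without_dimers(self, topology):
        topo0 = topology.with_gamma({n: 0.0 for n in topology.dimer_names})
        x = np.array([100.0, 50.0, 40.0, 30.0, 20.0, 60.0])
        assert np.allclose(mass_matrix(x, topo0), np.eye(6))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(concentrations)
    def test_column_diagonal_dominance(self, topology, x):
        """M is strictly diagonally dominant by columns for x >= 0 (the
        column sums collect gamma_ij x_j, which the diagonal contains),
        guaranteeing invertibility."""
        M = mass_matrix(np.asarray(x), topology)
        for j in range(6):
            off = np.abs(M[:, j]).sum() - abs(M[j, j])
            assert abs(M[j, j]) > off

    def test_is_jacobian_of_forward_map(self, topology):
        x = np.array([100.0, 50.0, 40.0, 30.0, 20.0, 60.0])
        M = mass_matrix(x, topology)
        eps = 1e-4
        for j in range(6):
            dx = np.zeros(6)
            dx[j] = eps
            fd = (totals_from_monomers(x + dx, topology)
                  - totals_from_monomers(x - dx, topology)) / (2 * eps)
            assert np.allclose(fd, M[:, j], rtol=1e-6, atol=1e-8)


class TestSimulateReduced:
    def test_gamma_zero_is_pure_decay(self, schedule):
        """All affinities zero: no dimers, hence no production — each
        monomer decays exponentially (closed form)."""
        from floralnet.network import KineticParameters

        topo0 = build_default_topology(
            gamma={n: 0.0 for n in build_default_topology().dimer_names}
        )
        dc = {"AP1": 71.0, "AP3": 3.0, "PI": 48.0, "AG": 5.0, "SHP": 4.0, "SEP": 16.0}
        pars = KineticParameters(
            beta={g: tuple(1e-30 for _ in topo0.activators[g]) for g in GENES},
            km_act={g: tuple(100.0 for _ in topo0.activators[g]) for g in GENES},
            km_rep={g: tuple(100.0 for _ in topo0.repressors[g]) for g in GENES},
            dc=dc, p2_magnitude=1e-30, p4_magnitude=1e-30,
        )
        x0 = np.array([500.0, 400.0, 300.0, 200.0, 100.0, 600.0])
        t = np.linspace(0, 1, 6)
        traj = simulate_reduced(x0, (0, 1), 1, topo0, pars, schedule, t_eval=t,
                                solver_options={"rtol": 1e-10, "atol": 1e-12})
        expected = x0[None, :] * np.exp(
            -np.array([dc[g] for g in GENES])[None, :] * t[:, None]
        )
        assert np.allclose(traj.monomers, expected, rtol=1e-6, atol=1e-8)
        assert np.allclose(traj.dimers, 0.0)

    def test_dimer_block_is_qss(self, wild_type):
        traj = wild_type[3]
        for k in (0, len(traj.times) // 2, -1):
            assert np.allclose(traj.dimers[k],
                               qss_dimer_vector(traj.monomers[k], traj.topology))

    def test_steady_persistence_after_day_5(self, config, wild_type):
        """Advancing the day-5 wild-type state to day 8 leaves the
        expression pattern intact: no gene moves by more than 30% (the
        dimer buffering in the mass matrix stretches the slowest
        relaxation to several days) and the four organ calls survive."""
        from floralnet.experiments import classify_organs, reference_thresholds

        thresholds = reference_thresholds(wild_type)
        day8 = {}
        for w, traj in wild_type.items():
            x5 = traj.monomers[traj.at_time(5.0)]
            later = simulate_reduced(x5, (5.0, 8.0), w, config.topology,
                                     config.params, config.schedule,
                                     t_eval=np.array([5.0, 8.0]))
            x8 = later.monomers[-1]
            rel = np.abs(x8 - x5) / np.maximum(x5, 1.0)
            assert (rel < 0.30).all()
            day8[w] = later
        from floralnet.experiments import ThresholdPolicy

        calls = classify_organs(day8, thresholds, ThresholdPolicy(day=8.0))
        assert {w: c.label for w, c in calls.items()} == {
            1: "sepal", 2: "petal", 3: "stamen", 4: "carpel"
        }

    def test_koff_ladder_converges_to_reduced(self, config):
        """The full coupled model approaches the reduced model as the
        dissociation rate grows at fixed affinity ratio (QSS limit)."""
        from floralnet.network import build_default_topology, simulate_full
        from floralnet.synth import initial_monomers

        x0 = initial_monomers(config)
        t = np.arange(0.1, 5.0001, 0.05)
        red = simulate_reduced(x0, (0, 5), 3, config.topology, config.params,
                               config.schedule, t_eval=t)
        errors = []
        for koff in (144.0, 1440.0, 14400.0):
            topo = build_default_topology(koff=koff)
            d0 = qss_dimer_vector(x0, topo)
            full = simulate_full(np.concatenate([x0, d0]), (0, 5), 3, topo,
                                 config.params, config.schedule, t_eval=t)
            scale = np.maximum(full.monomers.max(axis=0), 1e-6)
            errors.append(
                float(np.max(np.abs(full.monomers - red.monomers) / scale))
            )
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 0.005
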