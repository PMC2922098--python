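"""Network topology, rate laws, triggers and the full coupled model."""

import numpy as np
import pytest

from floralnet import (
    DimerSpec,
    KineticParameters,
    TriggerSchedule,
    build_default_topology,
    coupled_rhs,
    production_rate,
    simulate_full,
    trigger_input,
)
from floralnet.network import GENES, GENE_INDEX
from floralnet.qss import qss_dimer_vector, simulate_reduced


def zero_dimers(topology):
    return {name: 0.0 for name in topology.dimer_names}


class TestTopology:
    def test_gene_index_bijection(self, topology):
        assert GENES == ("AP1", "AP3", "PI", "AG", "SHP", "SEP")
        assert [GENE_INDEX[g] for g in GENES] == [1, 2, 3, 4, 5, 6]

    def test_dimer_species(self, topology):
        expected = {"[AP1 SEP]", "[AG AG]", "[AG SEP]", "[AP3 PI]",
                    "[AP1 AP1]", "[SEP SEP]", "[SHP SEP]"}
        assert set(topology.dimer_names) == expected
        assert topology.n_states == 13

    def test_wiring(self, topology):
        assert set(topology.activators["AP3"]) == {"[AP1 SEP]", "[AG SEP]", "[AP3 PI]"}
        assert topology.repressors["AP3"] == ()
        assert topology.activators["SHP"] == ("[AG SEP]",)
        assert topology.repressors["SHP"] == ("[AP3 PI]",)
        assert set(topology.activators["SEP"]) == {"[AG SEP]", "[AP1 SEP]", "[SEP SEP]"}
        assert topology.repressors["SEP"] == ()
        # [SHP SEP] exists as a species but regulates nothing
        regulating = {d for v in topology.activators.values() for d in v}
        regulating |= {d for v in topology.repressors.values() for d in v}
        assert "[SHP SEP]" not in regulating

    def test_parameter_census(self, topology, params):
        assert topology.n_beta() == 13
        assert topology.n_km() == 16
        assert topology.free_parameter_count() == 37
        assert topology.total_parameter_count() == 51
        params.validate(topology)
        assert params.free_parameter_count() == 37

    def test_dimer_spec_invariants(self):
        d = DimerSpec(partners=("SEP", "AP1"), gamma=0.1, koff=1440.0)
        assert d.partners == ("AP1", "SEP")  # canonical gene-index order
        assert d.kon / d.koff == pytest.approx(d.gamma, rel=1e-12)
        assert DimerSpec(partners=("AG", "AG"), gamma=1.0).stoichiometry("AG") == 2
        with pytest.raises(ValueError):
            DimerSpec(partners=("AP1", "SEP"), gamma=-1.0)

    def test_gamma_override_and_scaling(self, topology):
        removed = topology.with_gamma({"[AP3 PI]": 0.0})
        assert removed.gamma("[AP3 PI]") == 0.0
        assert removed.gamma("[AG AG]") == topology.gamma("[AG AG]")
        doubled = topology.scaled_gamma("[AG SEP]", 2.0)
        assert doubled.gamma("[AG SEP]") == pytest.approx(2 * topology.gamma("[AG SEP]"))


class TestProductionRate:
    def test_zero_activation_limit(self, topology, params):
        conc = zero_dimers(topology)
        for g in GENES:
            assert production_rate(g, conc, params, topology) == 0.0

    def test_half_maximal_identity(self, topology, params):
        """SHP at [AG SEP] = Km and no repressor gives beta/2 = 205 nM/day."""
        conc = zero_dimers(topology)
        conc["[AG SEP]"] = params.km_act["SHP"][0]
        assert production_rate("SHP", conc, params, topology) == pytest.approx(2.05e2)

    def test_full_repression_limit(self, topology, params):
        conc = zero_dimers(topology)
        conc["[AG SEP]"] = params.km_act["SHP"][0]
        conc["[AP3 PI]"] = 1e12
        assert production_rate("SHP", conc, params, topology) < 1e-6

    def test_bounded_by_beta_sum(self, topology, params):
        conc = {name: 1e9 for name in topology.dimer_names}
        for g in GENES:
            rate = production_rate(g, dict(conc), params, topology)
            assert 0.0 <= rate <= sum(params.beta[g]) * (1 + 1e-12)

    def test_errors(self, topology, params):
        with pytest.raises(KeyError):
            production_rate("AP9", zero_dimers(topology), params, topology)
        with pytest.raises(KeyError):
            production_rate("SHP", {}, params, topology)


class TestTrigger:
    def test_magnitudes_inside_window(self, params, schedule):
        assert trigger_input("AP3", 1.5, 3, schedule, params) == 4.5e4
        assert trigger_input("AG", 1.5, 4, schedule, params) == 3.4e3

    def test_zero_outside_window_and_domain(self, params, schedule):
        assert trigger_input("AP3", 2.5, 3, schedule, params) == 0.0
        assert trigger_input("AP3", 2.0, 3, schedule, params) == 0.0  # half-open
        assert trigger_input("AP3", 1.5, 1, schedule, params) == 0.0
        assert trigger_input("AG", 1.5, 2, schedule, params) == 0.0
        assert trigger_input("AP1", 1.5, 2, schedule, params) == 0.0

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            TriggerSchedule(t_on=2.0, t_off=1.0)
        with pytest.raises(ValueError):
            TriggerSchedule(p2_whorls=frozenset({5}))


class TestCoupledRhs:
    def test_origin_is_fixed_point(self, topology, params, schedule):
        rhs = coupled_rhs(0.5, np.zeros(13), 1, topology, params, schedule)
        assert np.allclose(rhs, 0.0)

    def test_dimer_equilibrium(self, topology, params, schedule):
        """At the QSS values the dimer derivatives vanish identically."""
        x = np.array([100.0, 50.0, 40.0, 30.0, 20.0, 60.0])
        d = qss_dimer_vector(x, topology)
        rhs = coupled_rhs(0.5, np.concatenate([x, d]), 1, topology, params, schedule)
        assert np.allclose(rhs[6:], 0.0, atol=1e-8)

    def test_negative_state_rejected(self, topology, params, schedule):
        state = np.zeros(13)
        state[0] = -1.0
        with pytest.raises(ValueError):
            coupled_rhs(0.5, state, 1, topology, params, schedule)

    def test_stoichiometric_conservation(self, topology, schedule):
        """With production, decay and triggers off, each gene's total
        monomer + weighted dimer content is a conserved quantity."""
        tiny = 1e-30
        silent = KineticParameters(
            beta={g: tuple(tiny for _ in topology.activators[g]) for g in GENES},
            km_act={g: tuple(1.0 for _ in topology.activators[g]) for g in GENES},
            km_rep={g: tuple(1.0 for _ in topology.repressors[g]) for g in GENES},
            dc={g: tiny for g in GENES},
            p2_magnitude=tiny,
            p4_magnitude=tiny,
        )
        x0 = np.array([300.0, 150.0, 80.0, 120.0, 60.0, 200.0])
        init = np.concatenate([x0, np.zeros(7)])
        traj = simulate_full(init, (0.0, 1.0), 1, topology, silent, schedule,
                             t_eval=np.linspace(0, 1, 11),
                             solver_options={"rtol": 1e-10, "atol": 1e-8})
        totals = traj.totals()
        for i in range(6):
            assert np.allclose(totals[:, i], totals[0, i], rtol=1e-8)


class TestSimulateFull:
    def test_zero_initial_state_stays_zero(self, topology, params):
        quiet = TriggerSchedule(p2_whorls=frozenset(), p4_whorls=frozenset())
        traj = simulate_full(np.zeros(13), (0.0, 3.0), 2, topology, params, quiet,
                             t_eval=np.linspace(0, 3, 7))
        assert np.allclose(traj.monomers, 0.0, atol=1e-9)
        assert np.allclose(traj.dimers, 0.0, atol=1e-9)

    def test_pure_decay_closed_form(self, topology, schedule):
        """With all affinities zero, dimers vanish, production is zero and
        each monomer decays exponentially — an analytic oracle."""
        topo0 = topology.with_gamma({n: 0.0 for n in topology.dimer_names})
        dc = {"AP1": 71.0, "AP3": 3.0, "PI": 48.0, "AG": 5.0, "SHP": 4.0, "SEP": 16.0}
        pars = KineticParameters(
            beta={g: tuple(1e-30 for _ in topo0.activators[g]) for g in GENES},
            km_act={g: tuple(100.0 for _ in topo0.activators[g]) for g in GENES},
            km_rep={g: tuple(100.0 for _ in topo0.repressors[g]) for g in GENES},
            dc=dc, p2_magnitude=1e-30, p4_magnitude=1e-30,
        )
        x0 = np.array([500.0, 400.0, 300.0, 200.0, 100.0, 600.0])
        t = np.linspace(0, 1, 6)
        traj = simulate_full(np.concatenate([x0, np.zeros(7)]), (0.0, 1.0), 1,
                             topo0, pars, schedule, t_eval=t,
                             solver_options={"rtol": 1e-10, "atol": 1e-12})
        expected = x0[None, :] * np.exp(-np.array([dc[g] for g in GENES])[None, :]
                                        * t[:, None])
        assert np.allclose(traj.monomers, expected, rtol=1e-6, atol=1e-8)

    def test_invalid_initial_rejected(self, topology, params, schedule):
        with pytest.raises(ValueError):
            simulate_full(np.full(13, -1.0), (0, 1), 1, topology, params, schedule)
        with pytest.raises(ValueError):
            simulate_full(np.zeros(6), (0, 1), 1, topology, params, schedule)


class TestWildTypeDynamics:
    def test_non_negativity(self, wild_type):
        for traj in wild_type.values():
            assert (traj.monomers >= 0).all()
            assert (traj.dimers >= 0).all()

    def test_shp_rises_late_in_carpel_whorl(self, wild_type):
        """SHP (D function) builds up late and only in whorl 4: half of
        its day-5 level is reached only after the trigger window closes,
        and the day-5 level is well above the day-2 level."""
        traj = wild_type[4]
        shp = traj.gene("SHP", "total")
        day5 = shp[traj.at_time(5.0)]
        crossing = traj.times[shp >= 0.5 * day5]
        assert crossing.min() > 2.0
        assert day5 / shp[traj.at_time(2.0)] > 2.0
        # no other whorl reaches a comparable SHP level
        for w in (1, 2, 3):
            other = wild_type[w].gene("SHP", "total")
            assert other[wild_type[w].at_time(5.0)] < 0.5 * day5

    def test_trigger_locality(self, config):
        """Whorl 1 is blind to both trigger magnitudes; whorl 2 to P4."""
        from floralnet.synth import initial_monomers

        x0 = initial_monomers(config)
        t = np.linspace(0, 5, 26)
        boosted = config.params.copy()
        boosted.p4_magnitude *= 10.0
        for whorl, par in ((1, boosted), (2, boosted)):
            base = simulate_reduced(x0, (0, 5), whorl, config.topology,
                                    config.params, config.schedule, t_eval=t)
            pert = simulate_reduced(x0, (0, 5), whorl, config.topology,
                                    par, config.schedule, t_eval=t)
            assert np.allclose(base.monomers, pert.monomers, rtol=1e-6, atol=1e-6)
        boosted2 = config.params.copy()
        boosted2.p2_magnitude *= 10.0
        base = simulate_reduced(x0, (0, 5), 1, config.topology, config.params,
                                config.schedule, t_eval=t)
        pert = simulate_reduced(x0, (0, 5), 1, config.topology, boosted2,
                                config.schedule, t_eval=t)
        assert np.allclose(base.monomers, pert.monomers, rtol=1e-6, atol=1e-6)
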