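import math

import numpy as np
import pytest
from pgpkinetics.errors import InvalidInputError, InvalidStateError, MisuseError
from pgpkinetics.pgp_model import (
    ATP_CYT,
    N_COMPARTMENT_VARS,
    PGP_OFFSET,
    SUB_CYT,
    SUB_EXT,
    SUB_MEM,
    TKI_CYT,
    TKI_EXT,
    TKI_MEM,
    KineticParameters,
    NbdOccupant,
    PgpState,
    SbdOccupant,
    SystemState,
    build_network,
    enumerate_states,
    equilibrium_occupancy,
    n_variables,
    rhs,
)
from pgpkinetics.simulate import SolverSettings, integrate, steady_state

PARAMS = KineticParameters(Kd_P=1e-6, Kd_N=5e-7, Kd_A=1e-5, Kd_I=2e-9)


def random_state_vector(rng, params=PARAMS):
    y = rng.uniform(0.0, 1e-5, n_variables())
    return y


class TestStates:
    def test_nine_states(self):
        states = enumerate_states()
        assert len(states) == 9
        assert len(set(states)) == 9

    def test_first_state_is_empty_empty(self):
        assert enumerate_states()[0] == PgpState(SbdOccupant.EMPTY, NbdOccupant.EMPTY)

    def test_row_major_order(self):
        states = enumerate_states()
        for i, s in enumerate(states):
            assert s.index == i
            assert s.sbd.value == i // 3 and s.nbd.value == i % 3


class TestKineticParameters:
    def test_infinite_kd_allowed_for_tki_sites(self):
        p = KineticParameters(Kd_P=1e-6, Kd_N=math.inf, Kd_I=math.inf)
        assert math.isinf(p.Kd_N) and math.isinf(p.Kd_I)

    def test_infinite_kd_p_rejected(self):
        with pytest.raises(InvalidInputError):
            KineticParameters(Kd_P=math.inf, Kd_N=1e-6)

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(InvalidInputError):
            KineticParameters(Kd_P=1e-6, Kd_N=1e-6, k_on_sbd=0.0)

    def test_knockout(self):
        p = PARAMS.knockout("Kd_N")
        assert math.isinf(p.Kd_N) and p.Kd_I == PARAMS.Kd_I
        with pytest.raises(InvalidInputError):
            PARAMS.knockout("Kd_P")


class TestSystemState:
    def test_vector_round_trip(self, rng):
        y = random_state_vector(rng)
        s = SystemState.from_vector(y)
        assert np.allclose(s.to_vector(), y)

    def test_negative_rejected(self):
        y = np.zeros(16)
        y[SUB_CYT] = -1e-9
        with pytest.raises(InvalidStateError):
            SystemState.from_vector(y)

    def test_wrong_length_rejected(self):
        with pytest.raises(InvalidStateError):
            SystemState.from_vector(np.zeros(15))


class TestRhs:
    def test_empty_system_has_zero_derivative(self):
        y = np.zeros(16)
        y[PGP_OFFSET] = 1e-5  # all pump in (EMPTY, EMPTY), no drugs, no ATP
        d = rhs(SystemState.from_vector(y), PARAMS)
        assert np.allclose(d.to_vector(), 0.0)

    def test_pump_conservation_for_random_states(self, rng):
        net = build_network(PARAMS)
        for _ in range(25):
            y = random_state_vector(rng)
            dy = net.rhs(0.0, y)
            assert abs(dy[PGP_OFFSET:].sum()) < 1e-15 * np.abs(dy).sum() + 1e-30

    @pytest.mark.parametrize("k_cat", [0.0, 1.0])
    def test_drug_mole_balance(self, rng, k_cat):
        # volume-weighted totals of each drug have zero time derivative
        # (efflux only relocates the SBD occupant; no drug is destroyed)
        p = KineticParameters(
            Kd_P=1e-6, Kd_N=5e-7, Kd_A=1e-5, Kd_I=2e-9, k_cat=k_cat,
            extracellular_clamped=False, atp_clamped=False,
        )
        net = build_network(p)
        pac_states = [PGP_OFFSET + s.index for s in enumerate_states()
                      if s.sbd is SbdOccupant.PACLITAXEL]
        tki_states = [PGP_OFFSET + s.index for s in enumerate_states()
                      if s.sbd is SbdOccupant.TKI or s.nbd is NbdOccupant.TKI]
        # TKI bound at both sites of one pump counts twice
        tki_weights = {
            PGP_OFFSET + s.index: (s.sbd is SbdOccupant.TKI) + (s.nbd is NbdOccupant.TKI)
            for s in enumerate_states()
        }
        for _ in range(20):
            y = random_state_vector(rng)
            dy = net.rhs(0.0, y)
            pac_total = (
                p.V_ext * dy[SUB_EXT] + p.V_mem * dy[SUB_MEM] + p.V_cyt * dy[SUB_CYT]
                + p.V_mem * dy[pac_states].sum()
            )
            tki_total = (
                p.V_ext * dy[TKI_EXT] + p.V_mem * dy[TKI_MEM] + p.V_cyt * dy[TKI_CYT]
                + p.V_mem * sum(w * dy[i] for i, w in tki_weights.items())
            )
            scale = p.V_mem * np.abs(dy).max() + 1e-30
            assert abs(pac_total) < 1e-9 * scale
            assert abs(tki_total) < 1e-9 * scale

    def test_clamped_variables_have_zero_derivative(self, rng):
        net = build_network(PARAMS)  # ext + ATP clamped by default
        y = random_state_vector(rng)
        dy = net.rhs(0.0, y)
        assert dy[SUB_EXT] == 0.0 and dy[TKI_EXT] == 0.0 and dy[ATP_CYT] == 0.0

    def test_jacobian_matches_finite_differences(self, rng):
        net = build_network(PARAMS)
        y = random_state_vector(rng)
        J = net.jac(0.0, y)
        eps = 1e-9
        for j in range(net.n_vars):
            yp, ym = y.copy(), y.copy()
            yp[j] += eps
            ym[j] -= eps
            col = (net.rhs(0.0, yp) - net.rhs(0.0, ym)) / (2 * eps)
            assert np.allclose(J[:, j], col, rtol=1e-5, atol=1e-4)

    def test_infinite_kd_removes_fluxes_exactly(self, rng):
        p = PARAMS.knockout("Kd_N")
        net = build_network(p)
        y = random_state_vector(rng)
        dy = net.rhs(0.0, y)
        # TKI-in-SBD states are disconnected except via NBD exchange/efflux
        y2 = y.copy()
        tki_sbd = [PGP_OFFSET + s.index for s in enumerate_states()
                   if s.sbd is SbdOccupant.TKI]
        y2[tki_sbd] = 0.0
        dy2 = net.rhs(0.0, y2)
        assert np.allclose(dy2[tki_sbd], 0.0)

    def test_negative_state_rejected_by_wrapper(self):
        y = np.zeros(16)
        y[PGP_OFFSET] = 1e-6
        state = SystemState.from_vector(y)
        state.pac_membrane = -1.0
        with pytest.raises(InvalidStateError):
            rhs(state, PARAMS)


class TestEquilibrium:
    def test_no_ligands_all_empty(self):
        p = KineticParameters(Kd_P=1e-6, Kd_N=1e-6, k_cat=0.0)
        occ = equilibrium_occupancy(p, 0.0, 0.0, 0.0, 0.0)
        empty = PgpState(SbdOccupant.EMPTY, NbdOccupant.EMPTY)
        assert occ[empty] == 1.0

    def test_half_saturation_at_kd(self):
        p = KineticParameters(Kd_P=1e-6, Kd_N=math.inf, Kd_I=math.inf, k_cat=0.0)
        occ = equilibrium_occupancy(p, 1e-6, 0.0, 0.0, 0.0)
        sbd_pac = sum(v for s, v in occ.items() if s.sbd is SbdOccupant.PACLITAXEL)
        assert sbd_pac == pytest.approx(0.5)

    def test_fractions_sum_to_one(self):
        p = KineticParameters(Kd_P=1e-6, Kd_N=5e-7, Kd_A=1e-5, Kd_I=2e-9, k_cat=0.0)
        occ = equilibrium_occupancy(p, 2e-6, 1e-7, 1e-5, 5e-9)
        assert sum(occ.values()) == pytest.approx(1.0)

    def test_misuse_with_turnover(self):
        with pytest.raises(MisuseError):
            equilibrium_occupancy(PARAMS, 0.0, 0.0, 0.0, 0.0)

    def test_matches_ode_stationary_distribution(self):
        # oracle: long-time ODE integration with k_cat = 0 and the free
        # ligand pools clamped reproduces the closed-form lattice occupancy
        p = KineticParameters(Kd_P=1e-6, Kd_N=5e-7, Kd_A=1e-5, Kd_I=2e-9, k_cat=0.0)
        free = dict(pac_membrane=2e-6, tki_membrane=1e-7, atp_cytosol=1e-5, tki_cytosol=5e-9)
        extra = [SUB_MEM, TKI_MEM, TKI_CYT]
        net = build_network(p, extra_clamped=extra)
        y0 = np.zeros(16)
        y0[SUB_MEM] = free["pac_membrane"]
        y0[TKI_MEM] = free["tki_membrane"]
        y0[ATP_CYT] = free["atp_cytosol"]
        y0[TKI_CYT] = free["tki_cytosol"]
        total = 1e-6
        y0[PGP_OFFSET] = total
        sol = integrate(net, y0, (0.0, 1e5), SolverSettings())
        frac = sol.y[PGP_OFFSET:, -1] / total
        occ = equilibrium_occupancy(p, **free)
        expected = np.array([occ[s] for s in enumerate_states()])
        assert np.allclose(frac, expected, atol=1e-6)


class TestPartitionEquilibrium:
    def test_membrane_aqueous_ratio_equals_pc(self):
        p = KineticParameters(
            Kd_P=1e-6, Kd_N=1e-6, pc_sub=3467.0, pc_tki=100.0,
            extracellular_clamped=False, atp_clamped=False,
        )
        net = build_network(p)
        y0 = np.zeros(16)
        y0[SUB_EXT] = 3e-6
        y0[TKI_EXT] = 1e-6
        y = steady_state(net, y0, np.arange(PGP_OFFSET, 16), SolverSettings())
        assert y[SUB_MEM] / y[SUB_EXT] == pytest.approx(p.pc_sub, rel=1e-4)
        assert y[TKI_MEM] / y[TKI_EXT] == pytest.approx(p.pc_tki, rel=1e-4)
        assert y[SUB_CYT] == pytest.approx(y[SUB_EXT], rel=1e-4)


class TestTrajectoryInvariants:
    def test_conservation_and_nonnegativity_along_trajectory(self, drugs):
        from pgpkinetics.simulate import Scenario, initial_vector, scenario_params

        scn = Scenario(tki="nilotinib", tki_ext=1e-6, pgp_total=10e-6)
        net = build_network(scenario_params(scn, drugs))
        y0 = initial_vector(scn)
        st_ = SolverSettings()
        sol = integrate(net, y0, (0.0, 5e3), st_, t_eval=np.linspace(0, 5e3, 25))
        totals = sol.y[PGP_OFFSET:, :].sum(axis=0)
        assert np.allclose(totals, 10e-6, rtol=1e-7)
        assert sol.y.min() > -10 * st_.atol

    def test_clamped_variables_bit_identical(self, drugs):
        from pgpkinetics.simulate import Scenario, initial_vector, scenario_params

        scn = Scenario(tki="nilotinib", tki_ext=1e-6, pgp_total=1e-6)
        net = build_network(scenario_params(scn, drugs))
        y0 = initial_vector(scn)
        sol = integrate(net, y0, (0.0, 1e3), SolverSettings(), t_eval=[0, 500.0, 1e3])
        for idx in (SUB_EXT, TKI_EXT, ATP_CYT):
            assert np.all(sol.y[idx] == y0[idx])


class TestNoncompetitiveLattice:
    def test_twelve_states(self):
        assert n_variables(noncompetitive=True) == N_COMPARTMENT_VARS + 12

    def test_pump_conservation(self, rng):
        net = build_network(PARAMS, noncompetitive=True)
        y = rng.uniform(0, 1e-5, n_variables(noncompetitive=True))
        dy = net.rhs(0.0, y)
        assert abs(dy[PGP_OFFSET:].sum()) < 1e-15 * np.abs(dy).sum() + 1e-30

    def test_doubly_occupied_reachable(self):
        # with both ligands present the (SUB+TKI) states accumulate mass
        net = build_network(PARAMS, noncompetitive=True)
        y0 = np.zeros(n_variables(noncompetitive=True))
        y0[SUB_MEM] = 1e-6
        y0[TKI_MEM] = 1e-6
        y0[PGP_OFFSET] = 1e-6
        sol = integrate(net, y0, (0.0, 100.0), SolverSettings())
        assert sol.y[PGP_OFFSET + 9:, -1].sum() > 0  # (SUB,TKI) x NBD block
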