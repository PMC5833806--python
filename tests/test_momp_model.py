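"""Stress-dose model checks: network instantiation, binding kinetics from
K_D, pore read-out, bisection vs brute-force oracle, antagonist effects."""

import numpy as np
import pytest

from momp.momp_model import (
    Antagonist,
    MompConfig,
    ProteinProfile,
    binding_rates_from_kd,
    build_momp_network,
    compute_eta,
    eta_dose_curve,
    pore_timecourse,
)
from momp.reaction_engine import (
    NetworkValidationError,
    ProductionSchedule,
    ProductionStep,
    simulate,
)

WEHI539 = Antagonist("WEHI539", "BCLXL", kd=1.1)
ABT199 = Antagonist("ABT199", "BCL2", kd=0.01)
A1210477 = Antagonist("A1210477", "MCL1", kd=0.45)


class TestNetworkBuild:
    def test_default_build_has_catalogued_size(self, model_def, hcc1143):
        net = build_momp_network(hcc1143, model_def)
        assert len(net.reactions) == 126
        assert len(net.species) == 71

    def test_profile_sets_measured_initials(self, model_def, hcc1143):
        net = build_momp_network(hcc1143, model_def)
        state = net.initial_state
        assert state[net.index["BAK"]] == pytest.approx(3.173)
        assert state[net.index["BCL2"]] == pytest.approx(0.907)
        assert state[net.index["BAX"]] == pytest.approx(0.638)

    def test_bh3_species_start_at_model_defaults(self, model_def, hcc1143):
        net = build_momp_network(hcc1143, model_def)
        for sid in ("BIM", "PUMA", "NOXA"):
            assert net.initial_state[net.index[sid]] == 0.0

    def test_zero_dose_antagonist_is_identity(self, model_def, hcc1143):
        base = build_momp_network(hcc1143, model_def)
        with_zero = build_momp_network(hcc1143, model_def, {WEHI539: 0.0})
        assert [s.id for s in with_zero.species] == [s.id for s in base.species]
        assert len(with_zero.reactions) == len(base.reactions)

    def test_antagonist_adds_drug_species_at_effective_dose(self, model_def, hcc1143):
        net = build_momp_network(hcc1143, model_def, {WEHI539: 2.0})
        assert len(net.species) == 73  # drug + drug:target complex
        assert len(net.reactions) == 128
        assert net.initial_state[net.index["WEHI539"]] == pytest.approx(0.5 * 2.0)

    def test_negative_dose_rejected(self, model_def, hcc1143):
        with pytest.raises(NetworkValidationError, match="negative dose"):
            build_momp_network(hcc1143, model_def, {WEHI539: -1.0})

    def test_antagonist_target_missing_from_model(self, toy_model, toy_profile):
        with pytest.raises(NetworkValidationError, match="absent"):
            build_momp_network(toy_profile, toy_model, {WEHI539: 1.0})


class TestBindingRates:
    def test_kd_conversion_to_reverse_rate(self):
        kf, kr = binding_rates_from_kd(1000.0, reference_forward_rate=360.0)
        assert kf == 360.0
        assert kr == pytest.approx(1.0 * 360.0)  # 1000 nM == 1 uM

    def test_detailed_balance_exact(self):
        for kd_nm in (0.01, 1.1, 450.0):
            kf, kr = binding_rates_from_kd(kd_nm, 360.0)
            assert kr / kf == pytest.approx(kd_nm * 1e-3, rel=1e-12)

    def test_weak_binding_limit_leaves_target_free(self, model_def, hcc1143):
        weak = Antagonist("WEAKDRUG", "BCLXL", kd=1e7)  # 10 mM
        net = build_momp_network(hcc1143, model_def, {weak: 2.0})
        traj = simulate(net, 12.0)
        assert traj["WEAKDRUG_BCLXL"][-1] < 1e-3

    def test_lower_kd_gives_higher_occupancy(self, model_def, hcc1143):
        """Matches the single-site isotherm: occupancy ranks inversely with K_D."""
        occ = {}
        for kd_nm in (10.0, 1000.0):
            drug = Antagonist("PROBE", "BCLXL", kd=kd_nm, bioavailability_factor=1.0)
            net = build_momp_network(hcc1143, model_def, {drug: 1.0})
            traj = simulate(net, 100.0)
            occ[kd_nm] = traj["PROBE_BCLXL"][-1]
        assert occ[10.0] > occ[1000.0]

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            binding_rates_from_kd(0.0, 360.0)
        with pytest.raises(ValueError):
            binding_rates_from_kd(1.0, -1.0)


class TestPoreTimecourse:
    def test_no_stress_no_pores(self, model_def, hcc1143):
        net = build_momp_network(hcc1143, model_def)
        pores = pore_timecourse(simulate(net, 12.0), model_def)
        assert np.all(pores >= 0)
        assert pores.max() < model_def.pore_threshold

    def test_no_effectors_no_pores(self, model_def):
        profile = ProteinProfile("noeff", 1.0, 0.2, 0.0, 0.0, 0.5)
        net = build_momp_network(profile, model_def)
        sched = ProductionSchedule(
            ProductionStep(s, 0.2, 0, 12) for s in model_def.stress_species
        )
        pores = pore_timecourse(simulate(net, 12.0, sched), model_def)
        assert np.all(pores == 0.0)

    def test_max_pore_nondecreasing_in_stress_below_saturation(self, model_def, hcc1143):
        net = build_momp_network(hcc1143, model_def)
        peaks = []
        for dose in (0.0, 0.25, 0.5, 1.0, 2.0):
            per = dose / 12.0 / 3.0
            sched = ProductionSchedule(
                ProductionStep(s, per, 0, 12) for s in model_def.stress_species
            ) if dose else ProductionSchedule()
            peaks.append(pore_timecourse(simulate(net, 12.0, sched), model_def).max())
        assert np.all(np.diff(peaks) >= -1e-9)


class TestComputeEta:
    def test_zero_threshold_is_degenerate_zero(self, toy_model, toy_profile):
        sd = compute_eta(toy_profile, MompConfig(pore_threshold=0.0), model_def=toy_model)
        assert sd.eta == 0.0
        assert sd.status == "degenerate_threshold"

    def test_no_effectors_resistant_beyond_bound(self, model_def):
        profile = ProteinProfile("noeff", 1.0, 0.2, 0.0, 0.0, 0.5)
        sd = compute_eta(profile, model_def=model_def)
        assert sd.resistant
        assert sd.eta is None
        assert not sd.momp_reached

    def test_bisection_matches_grid_search_oracle(self, toy_model, toy_profile):
        """Bisection eta equals a brute-force 1000-point dose scan on the toy model."""
        cfg = MompConfig(eta_upper_bound=4.0, bisection_rel_tol=1e-4)
        sd = compute_eta(toy_profile, cfg, model_def=toy_model)
        assert sd.status == "converged"

        from momp.momp_model import _momp_indicator

        net = build_momp_network(toy_profile, toy_model)
        grid = np.linspace(0.0, 4.0, 1001)
        hits = [
            _momp_indicator(net, toy_model, cfg, toy_model.pore_threshold, float(d))
            for d in grid
        ]
        first = int(np.argmax(hits))
        assert hits[first], "grid search never reached MOMP"
        g_lo, g_hi = grid[first - 1], grid[first]
        # indicator must be monotone on the scan
        assert all(hits[first:]), "MOMP indicator non-monotone on the dose grid"
        assert g_lo - 1e-3 * sd.eta <= sd.eta <= g_hi + 1e-3 * sd.eta

    def test_eta_monotone_in_antiapoptotic_load(self, model_def, hcc1143):
        etas = [
            compute_eta(hcc1143.scaled(anti=lam), model_def=model_def).eta
            for lam in (1.0, 2.0, 5.0)
        ]
        assert etas[0] <= etas[1] <= etas[2]

    def test_eta_decreases_when_effectors_scale_up(self, model_def, hcc1143):
        base = compute_eta(hcc1143, model_def=model_def)
        more = compute_eta(hcc1143.scaled(pro=2.0), model_def=model_def)
        assert more.eta <= base.eta * (1 + 2e-3)


class TestEtaDoseCurve:
    def test_dose_zero_is_baseline(self, model_def, hcc1143):
        baseline = compute_eta(hcc1143, model_def=model_def)
        curve = eta_dose_curve(hcc1143, WEHI539, [0.0, 1.0], model_def=model_def)
        assert curve[0][1].eta == baseline.eta

    def test_expressed_target_curve_nonincreasing(self, model_def, hcc1143):
        curve = eta_dose_curve(hcc1143, WEHI539, [0.0, 0.5, 1.0, 2.0], model_def=model_def)
        etas = [sd.eta for _, sd in curve]
        tol = [sd.bracket[1] - sd.bracket[0] for _, sd in curve]
        for k in range(1, len(etas)):
            assert etas[k] <= etas[k - 1] + tol[k - 1] + tol[k]

    def test_zero_target_is_exact_no_op(self, model_def):
        profile = ProteinProfile("nomcl1", 2.0, 0.0, 2.0, 0.5, 1.0)
        base = compute_eta(profile, model_def=model_def)
        dosed = compute_eta(profile, antagonist_doses={A1210477: 3.0}, model_def=model_def)
        assert abs(dosed.eta - base.eta) < 1e-6

    def test_negative_dose_rejected(self, model_def, hcc1143):
        with pytest.raises(NetworkValidationError):
            eta_dose_curve(hcc1143, WEHI539, [-0.5, 1.0], model_def=model_def)


def test_eta_ranking_stable_under_solver_tolerance(model_def, table1_profiles):
    """The resistance ordering of the shipped panel does not depend on the
    integrator tolerance (one order of magnitude change)."""
    def ranking(rtol, atol):
        cfg = MompConfig(solver_rtol=rtol, solver_atol=atol)
        etas = {
            p.cell_line: compute_eta(p, cfg, model_def=model_def).eta
            for p in table1_profiles
        }
        return sorted(etas, key=etas.get)

    assert ranking(1e-6, 1e-6) == ranking(1e-7, 1e-7)


class TestProfileValidation:
    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            ProteinProfile("bad", -0.1, 0.0, 1.0, 1.0, 0.5)

    def test_antagonist_descriptor_invariants(self):
        with pytest.raises(ValueError):
            Antagonist("X", "BAD_TARGET", kd=1.0)
        with pytest.raises(ValueError):
            Antagonist("X", "BCL2", kd=-1.0)
        with pytest.raises(ValueError):
            Antagonist("X", "BCL2", kd=1.0, bioavailability_factor=0.0)
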