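import numpy as np
import pytest

import ptupbpk as pk


def total_volume(individual):
    return sum(o.volume for o in individual.organs.values())


class TestModelAssembly:
    def test_zero_dose_stays_zero(self, adult, compound):
        model = pk.build_model(adult, compound)
        res = pk.simulate(model, pk.SimulationConfig(dose=0.0))
        for conc in res.profiles.values():
            assert np.all(conc == 0.0)

    def test_missing_organ_kp_named(self, adult, compound, monkeypatch):
        import ptupbpk.pbpk_core as core

        def incomplete(comp, ind=None):
            kps = pk.partition_coefficients(comp, ind)
            kps.pop("spleen")
            return kps

        monkeypatch.setattr(core, "partition_coefficients", incomplete)
        with pytest.raises(KeyError, match="spleen"):
            core.build_model(adult, compound)

    def test_well_mixed_equilibrium(self, adult, compound):
        """Kp=1 everywhere, no elimination, iv bolus: every tissue converges
        to the plasma concentration."""
        model = pk.build_model(
            adult, compound, kp_override=1.0,
            brain_permeability_limited=False, elimination=False,
        )
        grid = tuple(np.linspace(0.0, 72.0, 73))
        res = pk.simulate(
            model, pk.SimulationConfig(dose=50.0, route="iv_bolus", duration=72.0,
                                       output_grid=grid)
        )
        finals = [conc[-1] for conc in res.profiles.values()]
        assert max(finals) == pytest.approx(min(finals), rel=1e-6)
        # and equal to dose over total volume
        assert max(finals) == pytest.approx(50000.0 / total_volume(adult), rel=1e-6)


class TestOneCompartmentCollapse:
    def test_matches_closed_form(self, adult, compound):
        """Lumped model vs analytic first-order-absorption solution."""
        model = pk.build_model(adult, compound, lumped=True)
        res = pk.simulate(model, pk.SimulationConfig(dose=50.0))
        v = total_volume(adult)
        cl = compound.clearance.CL_pls_total * adult.weight  # L/h
        ka, ke = model.ka, cl / v
        t = res.times
        closed = 50000.0 * ka / (v * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))
        num = res.profiles["central"]
        assert np.max(np.abs(num - closed)) <= 1e-3 * np.max(closed)


class TestSimulate:
    def test_adult_50mg_auc_in_qualification_window(self, adult_50mg_pk):
        auc = adult_50mg_pk.auc_t
        assert 0.5 * 3837.71 < auc < 2.0 * 3837.71

    def test_dose_linearity(self, adult, compound):
        model = pk.build_model(adult, compound)
        r50 = pk.simulate(model, pk.SimulationConfig(dose=50.0))
        r100 = pk.simulate(model, pk.SimulationConfig(dose=100.0))
        pk50 = pk.nca(r50.profile())
        pk100 = pk.nca(r100.profile())
        assert pk100.auc_t == pytest.approx(2 * pk50.auc_t, rel=1e-6)
        assert pk100.cmax == pytest.approx(2 * pk50.cmax, rel=1e-6)
        assert pk100.tmax == pk50.tmax

    @pytest.mark.parametrize("route", ["oral", "iv_bolus"])
    def test_mass_balance_ledger(self, adult, compound, route):
        model = pk.build_model(adult, compound)
        res = pk.simulate(pk.build_model(adult, compound),
                          pk.SimulationConfig(dose=50.0, route=route))
        totals = res.ledger[
            ["gut_ug", "body_ug", "elim_hepatic_ug", "elim_renal_ug"]
        ].sum(axis=1)
        assert np.max(np.abs(totals - 50000.0)) <= 0.001 * 50000.0

    def test_solver_tolerance_convergence(self, adult, compound, adult_50mg_pk):
        model = pk.build_model(adult, compound)
        tight = pk.simulate(model, pk.SimulationConfig(dose=50.0, rtol=5e-9, atol=5e-11))
        auc_tight = pk.nca(tight.profile()).auc_t
        assert abs(auc_tight - adult_50mg_pk.auc_t) / adult_50mg_pk.auc_t < 1e-4

    def test_non_negative_profiles(self, adult_50mg_result):
        for conc in adult_50mg_result.profiles.values():
            assert np.all(conc >= 0.0)

    def test_iv_renal_only_terminal_slope_tracks_cl_over_vss(self, adult, compound):
        """Terminal log-slope vs CL/Vss from moment analysis of the curve.

        The two agree only approximately in a multi-organ model (the slope
        is CL/Vbeta and Vbeta exceeds Vss); agreement is asserted at 5%.
        """
        renal_only = compound.with_(clearance=pk.ClearanceSpec(0.05, 0.0, 0.05))
        model = pk.build_model(adult, renal_only, brain_permeability_limited=False)
        grid = tuple(np.linspace(0.0, 96.0, 961))
        res = pk.simulate(
            model,
            pk.SimulationConfig(dose=50.0, route="iv_bolus", duration=96.0,
                                output_grid=grid),
        )
        c, t = res.profiles["venous_plasma"], res.times
        lam = -np.polyfit(t[-100:], np.log(c[-100:]), 1)[0]
        auc = np.trapezoid(c, t) + c[-1] / lam
        aumc = np.trapezoid(c * t, t) + c[-1] * t[-1] / lam + c[-1] / lam**2
        cl = 50000.0 / auc
        vss = cl * aumc / auc
        assert lam == pytest.approx(cl / vss, rel=0.05)

    def test_per_kg_dosing_resolves_with_subject_weight(self, compound):
        light = pk.reference_individual(6.5, 18.0, 115.0, "male")
        heavy = pk.reference_individual(6.5, 27.0, 125.0, "male")
        cfg = pk.SimulationConfig(dose_per_kg=4.0)
        assert cfg.resolve_dose_ug(light) == pytest.approx(4.0 * 18.0 * 1000.0)
        assert cfg.resolve_dose_ug(heavy) == pytest.approx(4.0 * 27.0 * 1000.0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            pk.SimulationConfig(dose=50.0, dose_per_kg=4.0)
        with pytest.raises(ValueError):
            pk.SimulationConfig()
        with pytest.raises(ValueError):
            pk.SimulationConfig(dose=50.0, duration=4.0, output_grid=(0.0, 6.0, 12.0))
        with pytest.raises(ValueError):
            pk.SimulationConfig(dose=50.0, output_grid=(0.0, 2.0, 1.0))


class TestPopulation:
    def test_identical_individuals_collapse_bands(self, adult, compound):
        pop = pk.simulate_population([adult] * 5, compound,
                                     pk.SimulationConfig(dose=50.0))
        for col in ("p2.5", "p97.5", "p5", "p95"):
            assert np.allclose(pop.bands[col], pop.bands["mean"])

    def test_percentiles_match_brute_force(self, compound):
        spec = pk.PopulationSpec(12, (18.0, 60.0), 0.5, "adult", seed=5)
        cohort = pk.generate_population(spec)
        pop = pk.simulate_population(cohort, compound, pk.SimulationConfig(dose=50.0))
        stack = np.vstack([r.profiles["venous_plasma"] for r in pop.results])
        assert np.allclose(pop.bands["p5"], np.percentile(stack, 5.0, axis=0))
        assert np.allclose(pop.bands["p97.5"], np.percentile(stack, 97.5, axis=0))
        lo, hi = stack.min(axis=0), stack.max(axis=0)
        assert np.all(pop.bands["mean"] >= lo - 1e-12)
        assert np.all(pop.bands["mean"] <= hi + 1e-12)


class TestTissueReport:
    def test_tissue_exposure_pattern(self, adult_50mg_result):
        """All tissue AUCs sit below plasma; liver peaks first (portal
        first-pass input), brain last (blood-brain-barrier lag)."""
        report = pk.tissue_report(adult_50mg_result)
        plasma_auc = report.loc["venous_plasma", "AUC_0-t"]
        tissues = report.drop("venous_plasma")
        assert (tissues["AUC_0-t"] < plasma_auc).all()
        assert tissues["Tmax"].idxmin() == "liver"
        assert tissues["Tmax"].idxmax() == "brain"

    def test_report_order(self, adult_50mg_result):
        report = pk.tissue_report(adult_50mg_result)
        assert list(report.index) == [
            "venous_plasma", "brain", "heart", "kidney", "liver",
            "lung", "muscle", "spleen", "stomach",
        ]
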