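import io

import numpy as np
import pandas as pd
import pytest

from modescope import energetics as en
from modescope import synthetic_data as sd

HEADER = "time_ps\tE_int\tE_ele\tE_vdw\tG_gb\tG_sa\tTS_trans\tTS_rot\tTS_vib"


def random_series(n, seed, label=""):
    rng = np.random.default_rng(seed)
    comp = {c: rng.normal(scale=10.0, size=n)
            for c in en.ENTHALPY_COLUMNS + en.ENTROPY_COLUMNS}
    return en.EnergySeries(times=np.arange(1.0, n + 1.0),
                           components=pd.DataFrame(comp), label=label)


class TestParsing:
    def test_well_formed_table(self):
        rows = "\n".join(
            f"{t}\t1\t2\t3\t4\t5\t0.1\t0.2\t0.3" for t in range(1, 11))
        series = en.parse_energy_table(io.StringIO(HEADER + "\n" + rows))
        assert series.n_frames == 10
        assert series.entropy_available()

    def test_missing_enthalpy_column_rejected(self):
        header = HEADER.replace("\tE_ele", "")
        with pytest.raises(en.EnergyTableError, match="E_ele"):
            en.parse_energy_table(io.StringIO(
                header + "\n1\t1\t3\t4\t5\t0.1\t0.2\t0.3\n"))

    def test_unknown_column_lists_accepted_names(self):
        with pytest.raises(en.EnergyTableError, match="E_int"):
            en.parse_energy_table(io.StringIO(
                HEADER + "\tbogus\n" + "1\t" + "\t".join(["1"] * 9) + "\n"))

    def test_non_monotone_time_rejected(self):
        rows = "1\t1\t1\t1\t1\t1\t1\t1\t1\n1\t1\t1\t1\t1\t1\t1\t1\t1\n"
        with pytest.raises(en.EnergyTableError, match="increasing"):
            en.parse_energy_table(io.StringIO(HEADER + "\n" + rows))

    def test_round_trip_preserves_values(self, tmp_path):
        series = random_series(20, seed=1, label="wt")
        path = tmp_path / "energy.tsv"
        en.write_energy_table(series, path)
        back = en.parse_energy_table(path, label="wt")
        pd.testing.assert_frame_equal(back.components, series.components,
                                      atol=1e-6, check_exact=False)

    def test_sparse_entropy_allowed_dense_enthalpy_required(self, tmp_path):
        series = random_series(20, seed=2)
        series.components.loc[5:15, "TS_vib"] = np.nan
        path = tmp_path / "sparse.tsv"
        en.write_energy_table(series, path)
        back = en.parse_energy_table(path)
        assert back.components["TS_vib"].isna().sum() == 11
        series.components.loc[3, "E_int"] = np.nan
        en.write_energy_table(series, path)
        with pytest.raises(en.EnergyTableError, match="E_int"):
            en.parse_energy_table(path)


class TestTotals:
    def test_known_component_sum(self):
        comp = pd.DataFrame({
            "E_int": [10.0], "E_ele": [-20.0], "E_vdw": [5.0],
            "G_gb": [-3.0], "G_sa": [1.0],
            "TS_trans": [2.0], "TS_rot": [1.0], "TS_vib": [1.0],
        })
        series = en.EnergySeries(times=np.array([1.0]), components=comp)
        totals = en.total_free_energy(series)
        assert totals["E_gas"][0] == -5.0
        assert totals["H"][0] == -7.0
        assert totals["G"][0] == -11.0

    def test_all_zero_components_give_zero(self):
        comp = pd.DataFrame({c: [0.0] * 3 for c in
                             en.ENTHALPY_COLUMNS + en.ENTROPY_COLUMNS})
        series = en.EnergySeries(times=np.arange(3.0) + 1, components=comp)
        assert (en.total_free_energy(series)["G"] == 0).all()

    def test_identity_g_plus_ts_minus_h_is_zero(self):
        series = random_series(50, seed=3)
        totals = en.total_free_energy(series)
        np.testing.assert_allclose(
            totals["G"] + totals["TS"] - totals["H"], 0.0, atol=1e-12)


class TestStraatsmaError:
    def test_iid_error_matches_sd_over_sqrt_n(self):
        x = sd.make_ar1_series(0.0, 1.0, 0.0, 100_000, seed=4)
        est = en.estimate_with_error(x)
        naive = x.std(ddof=1) / np.sqrt(len(x))
        assert est.error == pytest.approx(naive, rel=0.10)

    def test_ar1_error_matches_closed_form(self):
        x = sd.make_ar1_series(0.0, 2.0, 0.9, 100_000, seed=5)
        est = en.estimate_with_error(x)
        oracle = sd.ar1_standard_error(2.0, 0.9, 100_000)
        assert est.error == pytest.approx(oracle, rel=0.20)

    def test_constant_series_error_and_tau_zero(self):
        est = en.estimate_with_error(np.full(100, 3.5))
        assert est.error == 0.0
        assert est.tau == 0.0

    def test_positive_autocorrelation_inflates_error(self):
        x = sd.make_ar1_series(0.0, 1.0, 0.8, 20_000, seed=6)
        est = en.estimate_with_error(x)
        naive = x.std(ddof=1) / np.sqrt(len(x))
        assert est.error > naive

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            en.estimate_with_error(np.arange(5.0))


class TestStabilityChange:
    def test_identical_estimates_give_zero_with_sqrt2_error(self):
        est = en.free_energy_estimate(random_series(200, seed=7))
        change = en.stability_change(est, est)
        assert change.dG.value == pytest.approx(0.0)
        assert change.dG.error == pytest.approx(np.sqrt(2) * est.G.error)

    def test_three_four_five_quadrature(self):
        a = en.FreeEnergyEstimate(
            "mut", G=en.ScalarEstimate(-100.0, 3.0, 0, 10, 1),
            H=en.ScalarEstimate(0, 0, 0, 10, 0),
            TS=en.ScalarEstimate(0, 0, 0, 10, 0))
        b = en.FreeEnergyEstimate(
            "wt", G=en.ScalarEstimate(-110.0, 4.0, 0, 10, 1),
            H=en.ScalarEstimate(0, 0, 0, 10, 0),
            TS=en.ScalarEstimate(0, 0, 0, 10, 0))
        change = en.stability_change(a, b)
        assert change.dG.value == pytest.approx(10.0)
        assert change.dG.error == pytest.approx(5.0)

    def test_antisymmetry(self):
        a = en.free_energy_estimate(random_series(100, seed=8, label="a"))
        b = en.free_energy_estimate(random_series(100, seed=9, label="b"))
        fwd = en.stability_change(a, b)
        rev = en.stability_change(b, a)
        assert fwd.dG.value == pytest.approx(-rev.dG.value)
        assert fwd.dG.error == pytest.approx(rev.dG.error)


class TestBindingCycle:
    def _series_map(self, seed):
        rng = np.random.default_rng(seed)
        data = {}
        for form in ("wt", "mut"):
            for leg in ("complex", "receptor", "ligand"):
                data[(form, leg)] = random_series(
                    50, seed=rng.integers(1e6), label=f"{form}-{leg}")
        return data

    def test_additive_components_give_zero_binding(self):
        receptor = random_series(30, seed=10, label="receptor")
        ligand = random_series(30, seed=11, label="ligand")
        complex_ = en.EnergySeries(
            times=receptor.times,
            components=receptor.components + ligand.components,
            label="complex")
        series = {}
        for form in ("wt", "mut"):
            series[(form, "complex")] = complex_
            series[(form, "receptor")] = receptor
            series[(form, "ligand")] = ligand
        cycle = en.binding_cycle(series)
        for form in ("wt", "mut"):
            assert cycle.dG_bind[form].value == pytest.approx(0.0, abs=1e-9)
        assert cycle.ddG.value == pytest.approx(0.0, abs=1e-9)

    def test_identical_forms_give_zero_mutational_difference(self):
        series = self._series_map(seed=12)
        for leg in ("complex", "receptor", "ligand"):
            series[("mut", leg)] = series[("wt", leg)]
        cycle = en.binding_cycle(series)
        assert cycle.ddG.value == pytest.approx(0.0, abs=1e-12)

    def test_matches_spreadsheet_recomputation(self):
        """Independent recomputation of the cycle from the raw tables."""
        series = self._series_map(seed=13)
        cycle = en.binding_cycle(series)

        def mean_g(s):
            c = s.components
            h = (c["E_int"] + c["E_ele"] + c["E_vdw"]
                 + c["G_gb"] + c["G_sa"]).mean()
            ts = (c["TS_trans"] + c["TS_rot"] + c["TS_vib"]).mean()
            return h - ts

        expect = {}
        for form in ("wt", "mut"):
            expect[form] = (mean_g(series[(form, "complex")])
                            - mean_g(series[(form, "receptor")])
                            - mean_g(series[(form, "ligand")]))
        assert cycle.ddG.value == pytest.approx(
            expect["mut"] - expect["wt"], abs=1e-12)
        for form in ("wt", "mut"):
            assert cycle.dG_bind[form].value == pytest.approx(
                expect[form], abs=1e-12)

    def test_missing_leg_named_in_error(self):
        series = self._series_map(seed=14)
        del series[("mut", "ligand")]
        with pytest.raises(ValueError, match="ligand"):
            en.binding_cycle(series)

    def test_single_point_legs_get_zero_error(self):
        series = self._series_map(seed=15)
        one = random_series(50, seed=16)
        one.components = one.components.iloc[:1]
        one.times = one.times[:1]
        series[("wt", "ligand")] = one
        cycle = en.binding_cycle(series)
        assert cycle.legs[("wt", "ligand")].G.error == 0.0

    def test_ddh_decomposition_sums_to_ddh(self):
        series = self._series_map(seed=17)
        cycle = en.binding_cycle(series)
        total = sum(cycle.ddH_decomposition.values())
        assert total == pytest.approx(cycle.ddH.value, abs=1e-9)


class TestFragmentDecomposition:
    def test_fragment_ddg_sums_to_whole(self):
        """Component-wise additive fragment tables sum to the whole-region
        mutational binding difference."""
        rng = np.random.default_rng(18)
        frag_series = {}
        for form in ("wt", "mut"):
            receptor = random_series(40, seed=rng.integers(1e6))
            frags = [random_series(40, seed=rng.integers(1e6))
                     for _ in range(3)]
            whole = en.EnergySeries(
                times=receptor.times,
                components=sum(f.components for f in frags),
                label="whole")
            frag_series[form] = (receptor, frags, whole)

        def cycle_for(lig_key):
            series = {}
            for form in ("wt", "mut"):
                receptor, frags, whole = frag_series[form]
                ligand = whole if lig_key == "whole" else frags[lig_key]
                complex_ = en.EnergySeries(
                    times=receptor.times,
                    components=receptor.components + ligand.components)
                series[(form, "complex")] = complex_
                series[(form, "receptor")] = receptor
                series[(form, "ligand")] = ligand
            return en.binding_cycle(series).ddG.value

        whole_ddg = cycle_for("whole")
        frag_sum = sum(cycle_for(i) for i in range(3))
        assert frag_sum == pytest.approx(whole_ddg, abs=1e-9)
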