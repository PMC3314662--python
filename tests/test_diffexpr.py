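import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tlr4sim import diffexpr, synthetic
from tlr4sim.diffexpr import (bonferroni, ddct, fit_probe_set,
                              fit_single_probe_table, lowess_normalize,
                              volcano_table)
from tlr4sim.synthetic import (ProbeIntensityTable, SimulationSpec,
                               default_annotation, generate_intensities,
                               paired_design)


class TestLowessNormalize:
    def test_identical_arrays_stay_identical(self):
        table = generate_intensities(SimulationSpec(n_probes=100, seed=0))
        v = table.values.copy()
        for c in v.columns:
            v[c] = v.iloc[:, 0]
        norm = lowess_normalize(ProbeIntensityTable(v, table.design))
        arr = norm.values.to_numpy()
        assert np.allclose(arr, arr[:, [0]])

    def test_constant_log2_offset_removed(self):
        # doubling one array is a constant +1 shift on the log2 scale, which
        # the local fit captures exactly; oracle = subtracting the mean M
        table = generate_intensities(SimulationSpec(n_probes=300, seed=5))
        v = table.values.copy()
        v.iloc[:, 1] = v.iloc[:, 0] * 2
        norm = lowess_normalize(ProbeIntensityTable(v, table.design))
        m = norm.values.iloc[:, 1] - norm.values.iloc[:, 0]
        assert np.abs(m).max() < 1e-8

    def test_empty_and_nonpositive_rejected(self):
        table = generate_intensities(SimulationSpec(n_probes=5, seed=0))
        with pytest.raises(ValueError):
            lowess_normalize(ProbeIntensityTable(
                table.values.iloc[:0], table.design))
        with pytest.raises(ValueError):
            ProbeIntensityTable(table.values - table.values.max().max(),
                                table.design)


class TestFitProbeSet:
    def test_flat_values_give_zero_difference(self):
        design = paired_design(3)
        res = fit_probe_set(np.full((2, 6), 7.0), design)
        assert res.lsmean_diff == pytest.approx(0.0, abs=1e-12)
        assert res.p_raw == 1.0
        assert res.degenerate

    def test_balanced_design_matches_group_mean_difference(self):
        rng = np.random.default_rng(1)
        design = paired_design(3)
        vals = rng.normal(8, 0.5, size=(3, 6))
        res = fit_probe_set(vals, design)
        n = [i for i, d in enumerate(design) if d.condition == "non_inseminated"]
        y = [i for i, d in enumerate(design) if d.condition == "inseminated"]
        oracle = vals[:, n].mean() - vals[:, y].mean()
        assert res.lsmean_diff == pytest.approx(oracle, abs=1e-8)

    def test_planted_shift_recovered(self):
        # +1.0 planted N-Y shift = inseminated log2FC of -1.0
        spec = SimulationSpec(n_probes=40, noise_sd=0.05, seed=7,
                              planted_effects={"G": -1.0})
        ann = default_annotation(40, ["G"], probes_per_gene=2)
        table = generate_intensities(spec, ann)
        norm = lowess_normalize(table)
        res = fit_probe_set(norm.values.iloc[:2].to_numpy(), norm.design)
        assert 0.9 <= res.lsmean_diff <= 1.1

    def test_orientation_higher_in_embryo_is_negative(self):
        spec = SimulationSpec(n_probes=20, noise_sd=0.05, seed=3,
                              planted_effects={"G": 2.0})
        ann = default_annotation(20, ["G"], probes_per_gene=1)
        norm = lowess_normalize(generate_intensities(spec, ann))
        res = fit_probe_set(norm.values.iloc[[0]].to_numpy(), norm.design)
        assert res.lsmean_diff < 0
        assert res.direction == "up_in_embryo"

    def test_missing_condition_rejected(self):
        design = [d for d in paired_design(3) if d.condition == "inseminated"]
        with pytest.raises(ValueError):
            fit_probe_set(np.ones((1, 3)), design)

    def test_vectorized_path_matches_per_set_fit(self):
        table = generate_intensities(SimulationSpec(n_probes=30, seed=11))
        norm = lowess_normalize(table)
        fast = fit_single_probe_table(norm)
        for i, probe in enumerate(norm.probe_ids[:15]):
            slow = fit_probe_set(norm.values.loc[[probe]].to_numpy(), norm.design)
            assert fast["lsmean_diff"].iloc[i] == pytest.approx(slow.lsmean_diff,
                                                                abs=1e-10)
            assert fast["p_raw"].iloc[i] == pytest.approx(slow.p_raw, abs=1e-10)


class TestBonferroni:
    def test_adjustment_and_threshold(self):
        m = 24123
        p = np.full(m, 0.5)
        p[0] = 0.04 / m  # just under the per-test threshold alpha/m
        p[1] = 0.06 / m
        p_adj, flags = bonferroni(p, alpha=0.05)
        assert flags[0] and not flags[1]
        assert p_adj[0] == pytest.approx(0.04)
        assert (p_adj <= 1).all()

    @pytest.mark.parametrize("p,expected", [([1.0], 1.0), ([0.3], 0.3)])
    def test_edge_values(self, p, expected):
        p_adj, _ = bonferroni(p)
        assert p_adj[0] == pytest.approx(expected)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.5, 1.5])
        with pytest.raises(ValueError):
            bonferroni([])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2,
                    max_size=30))
    def test_monotone_and_bounded(self, p):
        p_adj, _ = bonferroni(p)
        order = np.argsort(p)
        assert (np.diff(np.asarray(p_adj)[order]) >= -1e-12).all()
        assert (p_adj <= 1.0).all() and (p_adj >= np.asarray(p) - 1e-12).all()


class TestVolcano:
    def test_flags_match_bonferroni(self):
        res = pd.DataFrame({"probe_set_id": ["a", "b", "c"],
                            "lsmean_diff": [1.0, -2.0, 0.1],
                            "p_raw": [0.001, 0.5, 0.049 / 3]})
        v = volcano_table(res, alpha=0.05)
        p_adj, flags = bonferroni(res["p_raw"], alpha=0.05)
        assert (v["significant"].to_numpy() == flags).all()
        assert v.loc["c", "significant"]  # p_adj = 0.049 < 0.05 boundary

    def test_planted_effects_detected_with_controlled_false_positives(self):
        # 2,000 probes in 11-probe probe sets (the array's layout), 10 sets
        # carrying a 2.0 log2 planted effect at noise 0.1
        n_per = 11
        genes = {f"G{i}": 2.0 for i in range(10)}
        ann, probe_sets, i = [], {}, 0
        for g in sorted(genes):
            ids = [f"probe_{i + j:05d}" for j in range(n_per)]
            ann += [synthetic.ProbeAnnotation(p, gene_symbol=g) for p in ids]
            probe_sets[g] = ids
            i += n_per
        ns = 0
        while i < 2002:
            ids = [f"probe_{i + j:05d}" for j in range(min(n_per, 2002 - i))]
            ann += [synthetic.ProbeAnnotation(p) for p in ids]
            probe_sets[f"null{ns}"] = ids
            ns += 1
            i += len(ids)
        spec = SimulationSpec(n_probes=2002, noise_sd=0.1, seed=21,
                              planted_effects=genes)
        norm = lowess_normalize(generate_intensities(spec, ann))
        de = diffexpr.fit_table(norm, probe_sets)
        v = volcano_table(de, alpha=0.05)
        hits = v.loc[sorted(genes), "significant"].sum()
        false_pos = v.drop(index=sorted(genes))["significant"].sum()
        assert hits >= 8
        assert false_pos <= 1


class TestDdct:
    def test_identical_groups_give_unit_fold(self):
        r = ddct({"inseminated": 20.0, "non_inseminated": 20.0},
                 {"inseminated": 15.0, "non_inseminated": 15.0})
        assert r.delta_delta_ct == 0.0
        assert r.fold_change == 1.0

    def test_known_arithmetic(self):
        # dCT1 = 5, dCT2 = 3 -> ddCT = 2 -> fold 0.25
        r = ddct({"inseminated": 25.0, "non_inseminated": 23.0},
                 {"inseminated": 20.0, "non_inseminated": 20.0})
        assert r.delta_delta_ct == pytest.approx(2.0)
        assert r.fold_change == pytest.approx(0.25)

    def test_unit_ddct_halves_expression(self):
        r = ddct({"inseminated": 21.0, "non_inseminated": 20.0},
                 {"inseminated": 15.0, "non_inseminated": 15.0})
        assert r.fold_change == pytest.approx(0.5)

    def test_missing_group_rejected(self):
        with pytest.raises(ValueError):
            ddct({"inseminated": 20.0}, {"inseminated": 15.0})
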