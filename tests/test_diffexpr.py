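import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncnet.core import ValidationError
from lncnet.diffexpr import collapse_to_genes, fold_change, screen, t_test
from lncnet.simulate import SimulationConfig, simulate_expression

from conftest import toy_matrix

# published worked-example rows: (control triplicate, case triplicate, FC, p, direction)
PUBLISHED_ROWS = [
    ((12.37, 12.85, 10.51), (14.53, 14.51, 15.32), 7.34, 0.02, "up"),
    ((5.35, 5.51, 5.75), (2.93, 3.09, 2.77), 6.09, 0.00, "down"),
    ((2.70, 4.54, 3.94), (6.32, 6.76, 6.83), 7.51, 0.01, "up"),
    ((6.73, 6.78, 7.11), (2.87, 4.72, 4.66), 6.94, 0.01, "down"),
    ((4.97, 7.33, 4.25), (9.98, 9.40, 9.18), 16.03, 0.01, "up"),
]


class TestFoldChange:
    @pytest.mark.parametrize("ctrl,case,fc,_p,direction", PUBLISHED_ROWS)
    def test_reproduces_published_fold_changes(self, ctrl, case, fc, _p, direction):
        delta, fc_abs, direc = fold_change(ctrl, case)
        assert fc_abs == pytest.approx(fc, abs=0.03)
        assert direc == direction
        assert fc_abs == pytest.approx(2.0 ** abs(delta))

    def test_identical_groups_give_unit_fc(self):
        delta, fc_abs, _ = fold_change([5.0, 6.0, 7.0], [5.0, 6.0, 7.0])
        assert delta == 0.0 and fc_abs == 1.0

    def test_single_value_group_rejected(self):
        with pytest.raises(ValidationError):
            fold_change([5.0], [1.0, 2.0])

    @given(
        ctrl=st.lists(st.floats(-20, 20), min_size=2, max_size=6),
        case=st.lists(st.floats(-20, 20), min_size=2, max_size=6),
    )
    @settings(max_examples=100, deadline=None)
    def test_antisymmetric_in_group_swap(self, ctrl, case):
        d1, fc1, dir1 = fold_change(ctrl, case)
        d2, fc2, dir2 = fold_change(case, ctrl)
        assert d1 == pytest.approx(-d2, abs=1e-9)
        assert fc1 == pytest.approx(fc2)
        if abs(d1) > 1e-9:
            assert {dir1, dir2} == {"up", "down"}


class TestTTest:
    @pytest.mark.parametrize("ctrl,case,_fc,p,_d", PUBLISHED_ROWS)
    def test_pooled_p_matches_published_rounding(self, ctrl, case, _fc, p, _d):
        _t, df, p_hat = t_test(ctrl, case, mode="pooled")
        assert df == 4
        assert round(p_hat, 2) == pytest.approx(p, abs=0.005)

    def test_identical_groups_give_p_one(self):
        t, _df, p = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_zero_variance_conventions(self):
        _t, _df, p = t_test([5.0, 5.0], [5.0, 5.0])
        assert p == 1.0
        _t, _df, p = t_test([5.0, 5.0], [7.0, 7.0])
        assert p == 0.0

    def test_paired_requires_equal_sizes(self):
        with pytest.raises(ValidationError):
            t_test([1.0, 2.0, 3.0], [1.0, 2.0], mode="paired")

    @given(shift=st.floats(-50, 50))
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_constant_shift(self, shift):
        ctrl = np.array([12.37, 12.85, 10.51])
        case = np.array([14.53, 14.51, 15.32])
        _t0, _df, p0 = t_test(ctrl, case)
        _t1, _df, p1 = t_test(ctrl + shift, case + shift)
        assert p1 == pytest.approx(p0, rel=1e-9)


class TestScreen:
    def test_worked_example_all_significant_with_matching_directions(self, worked_example):
        matrix, _ann, reference = worked_example
        results = screen(matrix).set_index("probe_id")
        assert results["significant"].all()
        for probe, row in reference.iterrows():
            got = results.loc[probe]
            assert got["fc_abs"] == pytest.approx(row["fc_abs"], abs=0.03)
            assert round(got["p_value"], 2) == pytest.approx(row["p"], abs=0.005)
            assert got["direction"] == row["regulation"]

    def test_ranking_is_fc_descending(self, worked_example):
        matrix, _, _ = worked_example
        results = screen(matrix)
        fc = results["fc_abs"].to_numpy()
        assert (np.diff(fc) <= 1e-12).all()

    def test_null_rate_compatible_with_permutation_control(self, null_sim):
        """With nothing planted, the joint FC+p rule's hit rate should match
        the rate estimated by relabeling the same data."""
        _cfg, (matrix, _ann, _truth) = null_sim
        observed = screen(matrix)["significant"].mean()
        # all 10 distinct balanced 3v3 relabelings; average their hit rates
        from itertools import combinations

        samples = matrix.sample_ids
        rates = []
        for ctrl in combinations(samples, 3):
            if samples[0] not in ctrl:
                continue  # halve: complement splits give the same two-sided test
            groups = {s: ("control" if s in ctrl else "case") for s in samples}
            relabeled = type(matrix)(matrix.values, groups)
            rates.append(screen(relabeled)["significant"].mean())
        perm_rate = float(np.mean(rates))
        n = len(matrix.probe_ids)
        se = np.sqrt(max(perm_rate, 1 / n) * (1 - perm_rate) / n)
        assert abs(observed - perm_rate) <= 3 * se + 1 / n

    def test_extreme_single_probe(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([
            10 + rng.normal(0, 0.01, 3), 20 + rng.normal(0, 0.01, 3)
        ]).reshape(1, 6)
        m = toy_matrix(vals, 3, 3)
        res = screen(m)
        assert res.loc[0, "significant"] and res.loc[0, "direction"] == "up"

    def test_sensitivity_and_fpr_on_planted_signal(self):
        """200 planted probes at a 2.5 log2 shift among 1800 nulls: the
        FC>=2 & p<0.05 rule should recover >=80% with FPR <=5%."""
        cfg = SimulationConfig(
            n_lncRNA=1000, n_mRNA=1000, n_de_lncRNA=100, n_de_mRNA=100,
            de_shift=2.5, noise_sd=0.5, n_modules=0, n_tf=0, seed=42,
        )
        matrix, _ann, truth = simulate_expression(cfg)
        res = screen(matrix)
        hits = set(res.loc[res["significant"], "probe_id"])
        planted = truth.de_ids()
        sensitivity = len(hits & planted) / len(planted)
        fpr = len(hits - planted) / (len(res) - len(planted))
        assert sensitivity >= 0.8
        assert fpr <= 0.05


class TestCollapseToGenes:
    @staticmethod
    def annotation_for(probes, symbols):
        from lncnet.core import ProbeAnnotation

        return ProbeAnnotation(pd.DataFrame({
            "probe_id": probes, "molecule_class": "mRNA", "gene_symbol": symbols,
        }))

    def test_keeps_max_fc_probe_per_symbol(self):
        res = pd.DataFrame({
            "probe_id": ["P1", "P2"], "mean_control": 0.0, "mean_case": 0.0,
            "delta": [np.log2(3), np.log2(5)], "fc_abs": [3.0, 5.0],
            "direction": "up", "t": 1.0, "p_value": [0.01, 0.02],
            "fdr": 0.05, "significant": True,
        })
        ann = self.annotation_for(["P1", "P2"], ["G", "G"])
        out = collapse_to_genes(res, ann)
        assert out["probe_id"].tolist() == ["P2"]

    def test_distinct_symbols_identity(self):
        res = pd.DataFrame({
            "probe_id": ["P1", "P2"], "mean_control": 0.0, "mean_case": 0.0,
            "delta": 1.0, "fc_abs": [4.0, 3.0], "direction": "up", "t": 1.0,
            "p_value": 0.01, "fdr": 0.05, "significant": True,
        })
        ann = self.annotation_for(["P1", "P2"], ["G1", "G2"])
        assert len(collapse_to_genes(res, ann)) == 2

    def test_shared_symbols_collapse_to_distinct_count(self):
        cfg = SimulationConfig(
            n_lncRNA=10, n_mRNA=200, n_de_lncRNA=0, n_de_mRNA=0, n_modules=0,
            n_tf=0, frac_shared_symbols=0.1, seed=2,
        )
        matrix, ann, _ = simulate_expression(cfg)
        res = screen(matrix)
        out = collapse_to_genes(res, ann)
        assert len(out) == len(set(ann.symbol_map().values()))
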