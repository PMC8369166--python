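import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmelearn import constants, synthetic, views
from tmelearn.io import LRDatabase
from tmelearn.views import (
    ViewError,
    ViewMatrix,
    assign_pairs_to_cc,
    cc_feature_names,
    compute_cc_view,
    compute_lr_frequencies,
    compute_lr_view,
    compute_pathway_activity,
    compute_tf_activity,
    deconvolve_cell_fractions,
    derive_tme_lr_pairs,
    group_lr_features,
    zscore_genes,
)
from conftest import make_expr


class TestViewMatrix:
    def test_features_with_missing_values_dropped(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, 1.0]}, index=["s1", "s2"])
        vm = ViewMatrix(view_name="external", values=df)
        assert vm.feature_ids == ["a"]
        assert vm.provenance["dropped_missing"] == ["b"]

    def test_duplicate_features_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], columns=["a", "a"], index=["s1"])
        with pytest.raises(ViewError):
            ViewMatrix(view_name="external", values=df)


@pytest.fixture(scope="module")
def signature():
    rng = np.random.default_rng(1)
    genes = [f"G{i}" for i in range(40)]
    return pd.DataFrame(rng.uniform(1, 100, size=(40, 3)), index=genes,
                        columns=["A", "B", "C"])


class TestDeconvolution:

    def test_noiseless_mixture_recovered(self, signature):
        mix = 0.3 * signature["A"] + 0.7 * signature["B"]
        expr = make_expr({g: [mix[g]] for g in signature.index})
        cf = deconvolve_cell_fractions(expr, signature, cd4_label="none")
        assert cf.values.loc["s0", "A"] == pytest.approx(0.3, abs=1e-8)
        assert cf.values.loc["s0", "B"] == pytest.approx(0.7, abs=1e-8)
        assert cf.values.loc["s0", "C"] == pytest.approx(0.0, abs=1e-8)
        assert cf.values.loc["s0", "Other"] == pytest.approx(0.0, abs=1e-8)

    def test_orthogonal_sample_all_other(self, signature):
        # expression only on genes outside the signature
        expr = make_expr({**{g: [0.0] for g in signature.index}, "ZZZ": [50.0]})
        cf = deconvolve_cell_fractions(expr, signature)
        assert cf.values.loc["s0", ["A", "B", "C"]].sum() == pytest.approx(0.0, abs=1e-10)
        assert cf.values.loc["s0", "Other"] == pytest.approx(1.0)

    def test_zero_overlap_errors(self, signature):
        expr = make_expr({"ZZZ": [1.0]})
        with pytest.raises(ViewError, match="overlap"):
            deconvolve_cell_fractions(expr, signature)

    def test_all_zero_sample_errors(self, signature):
        expr = make_expr({g: [0.0] for g in signature.index})
        with pytest.raises(ViewError, match="s0"):
            deconvolve_cell_fractions(expr, signature)

    def test_synthetic_recovery_with_noise(self, priors):
        expr, truth = synthetic.make_cohort(priors, n_samples=50, noise_sd=0.01, seed=3)
        cf = deconvolve_cell_fractions(expr, priors.cell_signature)
        est = cf.values
        for ct in priors.cell_signature.columns:
            true = truth.fractions[ct]
            got = est[ct]
            if ct == "CD4":  # reported as CD4 + Treg
                got = est["CD4"] - est["Treg"]
            rmse = float(np.sqrt(((got - true) ** 2).mean()))
            assert rmse < 0.05, ct

    def test_eleven_columns_and_sum_identity(self, priors, expr):
        cf = deconvolve_cell_fractions(expr, priors.cell_signature)
        assert cf.n_features == 11
        # other = 1 - sum of raw immune fractions; CD4 column includes Treg
        immune = list(priors.cell_signature.columns)
        raw_sum = cf.values[immune].sum(axis=1) - cf.values["Treg"]
        np.testing.assert_allclose(raw_sum + cf.values["Other"], 1.0, atol=1e-12)
        assert ((cf.values >= 0) & (cf.values <= 1)).all().all()


class TestPathwayActivity:
    def test_sample_at_gene_means_scores_zero(self):
        expr = make_expr({"G1": [1, 3, 2], "G2": [5, 1, 3]})
        model = pd.DataFrame({"P1": [1.0, 2.0]}, index=["G1", "G2"])
        vm = compute_pathway_activity(expr, model)
        # s2 sits at the mean of both genes on the log scale? use raw z check
        z = zscore_genes(expr.log2_tpm())
        expected = z.T.to_numpy() @ model.to_numpy()
        np.testing.assert_allclose(vm.values.to_numpy(), expected)

    def test_single_gene_weight_times_z(self):
        expr = make_expr({"G1": [0.0, 1.0, 3.0, 9.0]})
        model = pd.DataFrame({"P1": [2.0]}, index=["G1"])
        vm = compute_pathway_activity(expr, model)
        z = zscore_genes(expr.log2_tpm()).loc["G1"]
        np.testing.assert_allclose(vm.values["P1"].to_numpy(), 2.0 * z.to_numpy())
        assert vm.values["P1"].iloc[1] == pytest.approx(2.0 * z.iloc[1])

    def test_all_genes_excluded_gives_empty_view(self):
        expr = make_expr({"G1": [1, 2], "G2": [2, 3]})
        model = pd.DataFrame({"P1": [1.0, 1.0]}, index=["G1", "G2"])
        vm = compute_pathway_activity(expr, model, exclude_genes=["G1", "G2"])
        assert vm.n_features == 0

    def test_linearity_in_samples(self, priors, expr):
        vm = compute_pathway_activity(expr, priors.pathway_model)
        z = zscore_genes(expr.log2_tpm().loc[
            priors.pathway_model.index.intersection(expr.tpm.index)])
        # scoring the average of two z-profiles equals averaging their scores
        mean_z = (z.iloc[:, 0] + z.iloc[:, 1]) / 2
        model = priors.pathway_model.loc[z.index]
        direct = mean_z.to_numpy() @ model.to_numpy()
        np.testing.assert_allclose(
            direct, (vm.values.iloc[0] + vm.values.iloc[1]) / 2, atol=1e-9)


class TestTFActivity:
    def _toy_regulons(self):
        return pd.DataFrame({
            "tf": ["T1"] * 3,
            "target": ["G1", "G2", "G3"],
            "mor": [1, 1, -1],
            "confidence": ["A", "B", "A"],
        })

    def test_nes_matches_bruteforce_formula(self, rng):
        genes = [f"G{i}" for i in range(1, 11)]
        expr = make_expr({g: rng.uniform(0, 50, 3).tolist() for g in genes})
        reg = self._toy_regulons()
        vm = compute_tf_activity(expr, reg, min_targets=3)
        # independent evaluation of the stated formula
        log = expr.log2_tpm()
        for s in expr.sample_ids:
            ranks = stats.rankdata(log[s])
            q = (ranks - 0.5) / len(genes)
            z = dict(zip(genes, stats.norm.ppf(q)))
            nes = (z["G1"] + z["G2"] - z["G3"]) / np.sqrt(3)
            assert vm.values.loc[s, "T1"] == pytest.approx(nes, abs=1e-12)

    def test_mor_flip_negates_nes(self, rng):
        genes = [f"G{i}" for i in range(1, 11)]
        expr = make_expr({g: rng.uniform(0, 50, 4).tolist() for g in genes})
        reg = self._toy_regulons()
        flipped = reg.assign(mor=-reg["mor"])
        a = compute_tf_activity(expr, reg, min_targets=3).values
        b = compute_tf_activity(expr, flipped, min_targets=3).values
        np.testing.assert_allclose(a.to_numpy(), -b.to_numpy(), atol=1e-12)

    def test_top_ranked_targets_maximize_nes(self, rng):
        genes = [f"G{i}" for i in range(20)]
        vals = {g: [float(i)] for i, g in enumerate(genes)}
        expr = make_expr(vals)
        reg = pd.DataFrame({
            "tf": ["TOP"] * 5 + ["BOT"] * 5,
            "target": genes[-5:] + genes[:5],
            "mor": [1] * 10,
            "confidence": ["A"] * 10,
        })
        vm = compute_tf_activity(expr, reg)
        assert vm.values.loc["s0", "TOP"] == vm.values.max(axis=1).loc["s0"]

    def test_monotone_transform_invariance(self, rng):
        genes = [f"G{i}" for i in range(12)]
        base = {g: rng.uniform(0, 100, 3).tolist() for g in genes}
        expr1 = make_expr(base)
        expr2 = make_expr({g: (np.array(v) ** 2).tolist() for g, v in base.items()})
        reg = self._toy_regulons()
        a = compute_tf_activity(expr1, reg, min_targets=3).values
        b = compute_tf_activity(expr2, reg, min_targets=3).values
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_confidence_filter_and_min_targets(self):
        expr = make_expr({f"G{i}": [float(i), 1.0] for i in range(10)})
        reg = pd.DataFrame({
            "tf": ["T1"] * 5 + ["T2"] * 5,
            "target": [f"G{i}" for i in range(5)] + [f"G{i}" for i in range(5, 10)],
            "mor": [1] * 10,
            "confidence": ["A"] * 5 + ["C"] * 5,
        })
        vm = compute_tf_activity(expr, reg)
        assert vm.feature_ids == ["T1"]  # T2 filtered out at confidence C
        with pytest.raises(ViewError):
            compute_tf_activity(expr, reg[reg["confidence"] == "C"])


def _toy_db(ct_expr: pd.DataFrame, pairs) -> LRDatabase:
    amap = {c: c for c in ct_expr.index}
    return LRDatabase(pairs=pairs, celltype_expression=ct_expr,
                      aggregation_map=amap, aggregated_types=list(ct_expr.index))


class TestLRFilter:
    def test_low_ligand_dropped(self):
        ct = pd.DataFrame({"L1": [5.0, 2.0], "R1": [50.0, 50.0]}, index=["X", "Y"])
        db = _toy_db(ct, [("p1", ("L1",), ("R1",))])
        assert derive_tme_lr_pairs(db).pairs == []

    def test_autocrine_kept(self):
        ct = pd.DataFrame({"L1": [50.0, 1.0], "R1": [50.0, 1.0]}, index=["X", "Y"])
        db = _toy_db(ct, [("p1", ("L1",), ("R1",))])
        assert len(derive_tme_lr_pairs(db).pairs) == 1

    def test_unpaired_expression_dropped(self):
        # ligand only in X, receptor only in Y is fine (paracrine); but
        # ligand in X with receptor nowhere >= threshold must go
        ct = pd.DataFrame({"L1": [50.0, 1.0], "R1": [1.0, 50.0],
                           "L2": [50.0, 1.0], "R2": [9.0, 9.0]}, index=["X", "Y"])
        db = _toy_db(ct, [("p1", ("L1",), ("R1",)), ("p2", ("L2",), ("R2",))])
        kept = derive_tme_lr_pairs(db)
        assert [p[0] for p in kept.pairs] == ["p1"]

    def test_threshold_zero_keeps_everything(self):
        ct = pd.DataFrame({"L1": [0.0], "R1": [0.0]}, index=["X"])
        db = _toy_db(ct, [("p1", ("L1",), ("R1",))])
        assert len(derive_tme_lr_pairs(db, tpm_threshold=0).pairs) == 1

    def test_synthetic_bundle_keeps_all_pairs(self, priors):
        kept = derive_tme_lr_pairs(priors.lr_database)
        assert len(kept.pairs) == len(priors.lr_database.pairs)


class TestLRView:
    def test_min_log2_closed_form(self):
        ct = pd.DataFrame({"L1": [50.0], "R1": [50.0]}, index=["X"])
        db = _toy_db(ct, [("p1", ("L1",), ("R1",))])
        expr = make_expr({"L1": [3.0], "R1": [1.0]})
        vm = compute_lr_view(expr, db)
        assert vm.values.loc["s0", "p1"] == pytest.approx(1.0)  # min(log2 4, log2 2)

    def test_zero_tpm_gives_zero_weight(self):
        ct = pd.DataFrame({"L1": [50.0], "R1": [50.0]}, index=["X"])
        db = _toy_db(ct, [("p1", ("L1",), ("R1",))])
        expr = make_expr({"L1": [0.0], "R1": [64.0]})
        assert compute_lr_view(expr, db).values.loc["s0", "p1"] == 0.0

    def test_complex_pair_min_over_all_genes(self):
        ct = pd.DataFrame({"La": [50.0], "Lb": [50.0], "R1": [50.0]}, index=["X"])
        db = _toy_db(ct, [("p1", ("La", "Lb"), ("R1",))])
        expr = make_expr({"La": [7.0], "Lb": [3.0], "R1": [15.0]})
        assert compute_lr_view(expr, db).values.loc["s0", "p1"] == pytest.approx(2.0)

    def test_missing_gene_weight_zero(self):
        ct = pd.DataFrame({"L1": [50.0], "R1": [50.0]}, index=["X"])
        db = _toy_db(ct, [("p1", ("L1",), ("R1",))])
        expr = make_expr({"L1": [10.0], "OTHER": [1.0]})
        assert compute_lr_view(expr, db).values.loc["s0", "p1"] == 0.0

    def test_monotone_in_constituent_gene(self, rng):
        ct = pd.DataFrame({"L1": [50.0], "R1": [50.0]}, index=["X"])
        db = _toy_db(ct, [("p1", ("L1",), ("R1",))])
        lo = make_expr({"L1": [2.0], "R1": [8.0]})
        hi = make_expr({"L1": [4.0], "R1": [8.0]})
        assert compute_lr_view(hi, db).values.iloc[0, 0] >= \
            compute_lr_view(lo, db).values.iloc[0, 0]


class TestGroupLRFeatures:
    def _view(self, cols):
        return ViewMatrix(view_name="lrpairs",
                          values=pd.DataFrame(cols, index=["s0", "s1"]))

    def test_no_duplicates_unchanged(self):
        vm = self._view({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        out = group_lr_features(vm)
        assert sorted(out.feature_ids) == ["a", "b"]

    def test_shared_limiting_gene_merges(self):
        vm = self._view({"pB": [1.0, 3.0], "pA": [1.0, 3.0], "pC": [9.0, 9.0]})
        out = group_lr_features(vm)
        assert "pA_pB" in out.feature_ids
        np.testing.assert_allclose(out.values["pA_pB"], [1.0, 3.0])

    def test_three_identical_collapse_to_one(self):
        vm = self._view({"a": [1.0, 1.0], "b": [1.0, 1.0], "c": [1.0, 1.0]})
        out = group_lr_features(vm)
        assert out.n_features == vm.n_features - 2


class TestCCView:
    def test_canonical_list_gives_169_features(self):
        names = cc_feature_names(list(constants.AGGREGATED_CELL_TYPES))
        assert len(names) == 169

    def test_worked_example_score_six(self):
        ct = pd.DataFrame({"L1": [50.0, 1.0], "R1": [1.0, 50.0],
                           "L2": [50.0, 1.0], "R2": [1.0, 50.0]}, index=["A", "B"])
        db = _toy_db(ct, [("p1", ("L1",), ("R1",)), ("p2", ("L2",), ("R2",))])
        expr = make_expr({"L1": [20.0], "R1": [20.0], "L2": [20.0], "R2": [20.0]})
        vm = compute_cc_view(expr, db, {"p1": 0.5, "p2": 0.25})
        assert vm.values.loc["s0", "A->B"] == pytest.approx(6.0)

    def test_inactive_sample_scores_zero(self):
        ct = pd.DataFrame({"L1": [50.0], "R1": [50.0]}, index=["A"])
        db = _toy_db(ct, [("p1", ("L1",), ("R1",))])
        expr = make_expr({"L1": [1.0], "R1": [1.0]})
        vm = compute_cc_view(expr, db, {"p1": 0.5})
        assert (vm.values.to_numpy() == 0).all()

    def test_unit_frequencies_reduce_to_count(self, priors, expr):
        db = derive_tme_lr_pairs(priors.lr_database)
        freqs = {pid: 1.0 for pid in db.pair_ids}
        vm = compute_cc_view(expr, db, freqs)
        assignment = assign_pairs_to_cc(db)
        active = views.patient_active_pairs(expr, db)
        s = expr.sample_ids[0]
        for cc in ["Adipocytes->B cells", "B cells->B cells"]:
            count = sum(
                1 for pid, ccs in assignment.items()
                if tuple(cc.split("->")) in ccs and active.loc[s, pid]
            )
            assert vm.values.loc[s, cc] == pytest.approx(count)

    def test_scores_nonnegative_and_monotone(self, priors, expr):
        db = derive_tme_lr_pairs(priors.lr_database)
        freqs = compute_lr_frequencies(expr, db)
        vm = compute_cc_view(expr, db, freqs)
        assert (vm.values.to_numpy() >= 0).all()
        # dropping one pair never increases any score
        smaller = LRDatabase(pairs=db.pairs[1:], celltype_expression=db.celltype_expression,
                             aggregation_map=db.aggregation_map,
                             aggregated_types=db.aggregated_types)
        vm2 = compute_cc_view(expr, smaller, freqs)
        assert (vm.values.to_numpy() - vm2.values.to_numpy() >= -1e-12).all()

    def test_missing_aggregation_is_error(self):
        ct = pd.DataFrame({"L1": [50.0], "R1": [50.0]}, index=["A"])
        db = LRDatabase(pairs=[("p1", ("L1",), ("R1",))], celltype_expression=ct,
                        aggregation_map={}, aggregated_types=["A"])
        expr = make_expr({"L1": [20.0], "R1": [20.0]})
        with pytest.raises(ViewError, match="aggregation"):
            compute_cc_view(expr, db, {"p1": 1.0})

    def test_zero_frequency_pairs_excluded(self):
        ct = pd.DataFrame({"L1": [50.0], "R1": [50.0]}, index=["A"])
        db = _toy_db(ct, [("p1", ("L1",), ("R1",))])
        expr = make_expr({"L1": [20.0], "R1": [20.0]})
        vm = compute_cc_view(expr, db, {"p1": 0.0})
        assert (vm.values.to_numpy() == 0).all()
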