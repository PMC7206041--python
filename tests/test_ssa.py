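"""Single-subject analysis: normalization, fold changes, mixture, enrichment."""

import numpy as np
import pandas as pd
import pytest

from sololens.io import ConfigError, CountTable, DegTable, GeneSetCollection
from sololens.ssa import (
    FoldChangeProfile,
    GeneClassTable,
    NormalizationError,
    classify_genes,
    compute_fold_changes,
    enrichment_frame,
    fit_dysregulation_mixture,
    normalize_pair,
    pathway_fet,
    select_degs,
)


def make_pair(u, t, method="upper_quartile"):
    u, t = np.asarray(u), np.asarray(t)
    table = CountTable(
        gene_ids=[f"g{i}" for i in range(len(u))],
        sample_ids=["U", "T"],
        counts=np.column_stack([u, t]),
        condition_of_sample={"U": "untreated", "T": "treated"},
    )
    return normalize_pair(table, method=method)


class TestNormalization:
    def test_identical_columns_stay_equal(self):
        pair = make_pair([10, 0, 5, 30], [10, 0, 5, 30])
        assert pair.u_norm == pytest.approx(pair.t_norm)

    @pytest.mark.parametrize("method", ["upper_quartile", "total_count"])
    def test_pure_scaling_cancels(self, method):
        u = [10, 0, 5, 30, 100]
        pair = make_pair(u, [2 * x for x in u], method=method)
        assert pair.u_norm == pytest.approx(pair.t_norm)

    def test_none_is_identity(self):
        pair = make_pair([10, 0, 5], [1, 2, 3], method="none")
        assert pair.u_norm.tolist() == [10, 0, 5]
        assert pair.t_norm.tolist() == [1, 2, 3]

    def test_all_zero_sample_rejected(self):
        with pytest.raises(NormalizationError):
            make_pair([0, 0, 0], [1, 2, 3])

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigError):
            make_pair([1, 2], [3, 4], method="quantile")


class TestFoldChanges:
    def test_equal_expression_gives_zero(self):
        pair = make_pair([100, 100], [100, 100], method="none")
        prof = compute_fold_changes(pair)
        assert prof.lfc_signed == pytest.approx([0.0, 0.0])
        assert prof.lfc_abs == pytest.approx([0.0, 0.0])

    def test_fourfold_change_approaches_two(self):
        pair = make_pair([100], [400], method="none")
        prof = compute_fold_changes(pair, pseudocount=1e-9)
        assert prof.lfc_signed[0] == pytest.approx(2.0, abs=1e-6)

    def test_sign_symmetry_of_magnitude(self):
        up = compute_fold_changes(make_pair([100], [400], method="none"), 1e-9)
        down = compute_fold_changes(make_pair([400], [100], method="none"), 1e-9)
        assert down.lfc_signed[0] == pytest.approx(-up.lfc_signed[0])
        assert down.lfc_abs[0] == pytest.approx(up.lfc_abs[0])

    def test_nonpositive_pseudocount_rejected(self):
        with pytest.raises(ConfigError):
            compute_fold_changes(make_pair([1], [2], method="none"), pseudocount=0.0)


class TestMixture:
    def test_identical_values_fall_back_to_unaltered(self):
        fit = fit_dysregulation_mixture(np.full(200, 0.3))
        assert fit.degenerate
        assert np.all(fit.posterior_dysregulated == 0.0)

    def test_posteriors_lie_in_unit_interval(self):
        rng = np.random.default_rng(2)
        fit = fit_dysregulation_mixture(np.abs(rng.normal(0, 1, 1000)))
        assert np.all(fit.posterior_dysregulated >= 0.0)
        assert np.all(fit.posterior_dysregulated <= 1.0)

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([np.abs(rng.normal(0, 0.2, 900)),
                            np.abs(rng.normal(2.5, 0.4, 100))])
        fit = fit_dysregulation_mixture(x)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-9)
        assert fit.converged

    def test_recovers_generating_parameters(self):
        # 0.9*|N(0,0.2)| + 0.1*|N(2.5,0.4)|: the generating parameters are the oracle
        rng = np.random.default_rng(1)
        n = 5000
        is_dys = rng.random(n) < 0.1
        x = np.where(is_dys, np.abs(rng.normal(2.5, 0.4, n)),
                     np.abs(rng.normal(0.0, 0.2, n)))
        fit = fit_dysregulation_mixture(x)
        assert fit.weights[1] == pytest.approx(0.1, abs=0.03)
        assert fit.means[1] == pytest.approx(2.5, abs=0.2)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(4)
        x = np.abs(rng.normal(0, 1, 500))
        f1 = fit_dysregulation_mixture(x, seed=9)
        f2 = fit_dysregulation_mixture(x, seed=9)
        assert np.array_equal(f1.posterior_dysregulated, f2.posterior_dysregulated)


class TestClassification:
    def _profile(self, lfc):
        lfc = np.asarray(lfc, float)
        return FoldChangeProfile(
            gene_ids=[f"g{i}" for i in range(lfc.size)],
            lfc_signed=lfc, lfc_abs=np.abs(lfc), pseudocount=0.5,
        )

    def test_zero_lfc_stays_unaltered_despite_high_posterior(self):
        prof = self._profile([0.0, 3.0, -3.0])
        fit = fit_dysregulation_mixture(np.abs(np.r_[np.zeros(50), np.full(5, 3.0)]))
        fit.posterior_dysregulated = np.array([0.99, 0.99, 0.99])
        table = classify_genes(fit, prof)
        assert table.frame["gene_class"].tolist() == ["unaltered", "up", "down"]

    def test_classes_partition_universe(self):
        rng = np.random.default_rng(5)
        lfc = rng.normal(0, 1, 800)
        prof = self._profile(lfc)
        fit = fit_dysregulation_mixture(prof)
        table = classify_genes(fit, prof)
        counts = table.frame["gene_class"].value_counts()
        assert counts.sum() == 800

    def test_f1_against_truth_on_separated_mixture(self):
        rng = np.random.default_rng(1)
        n = 5000
        is_dys = rng.random(n) < 0.1
        mag = np.where(is_dys, np.abs(rng.normal(2.5, 0.4, n)),
                       np.abs(rng.normal(0.0, 0.2, n)))
        sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        prof = self._profile(sign * mag)
        fit = fit_dysregulation_mixture(prof)
        table = classify_genes(fit, prof)
        called = table.frame["gene_class"].isin(["up", "down"]).to_numpy()
        tp = np.sum(called & is_dys)
        f1 = 2 * tp / (2 * tp + np.sum(called & ~is_dys) + np.sum(~called & is_dys))
        assert f1 >= 0.9


def class_table(classes: dict[str, str]) -> GeneClassTable:
    genes = list(classes)
    return GeneClassTable(
        frame=pd.DataFrame(
            {
                "gene_id": genes,
                "gene_class": [classes[g] for g in genes],
                "posterior_dysregulated": [
                    0.9 if classes[g] != "unaltered" else 0.1 for g in genes
                ],
                "lfc_signed": [
                    2.0 if classes[g] == "up" else -2.0 if classes[g] == "down" else 0.0
                    for g in genes
                ],
                "lfc_abs": [2.0 if classes[g] != "unaltered" else 0.0 for g in genes],
            }
        )
    )


class TestPathwayFet:
    def test_handworked_hypergeometric_example(self):
        # 20-gene universe, 5 dysregulated; one 5-gene set holding 4 of them
        classes = {f"g{i}": "unaltered" for i in range(20)}
        for g in ["g0", "g1", "g2", "g3", "g10"]:
            classes[g] = "up"
        sets = GeneSetCollection(
            sets={"S": ("set", ["g0", "g1", "g2", "g3", "g4"])}
        )
        (res,) = pathway_fet(class_table(classes), sets)
        assert (res.a, res.b, res.c, res.d) == (4, 1, 1, 14)
        assert res.p_raw == pytest.approx(76 / 15504, rel=1e-12)
        assert res.n_up == 4 and res.n_down == 0

    def test_set_without_dysregulated_members_has_p_one(self):
        classes = {f"g{i}": "up" if i < 3 else "unaltered" for i in range(30)}
        sets = GeneSetCollection(sets={"S": ("s", [f"g{i}" for i in range(20, 28)])})
        (res,) = pathway_fet(class_table(classes), sets)
        assert res.p_raw == 1.0

    def test_all_genes_dysregulated_gives_p_one_everywhere(self):
        classes = {f"g{i}": "up" for i in range(30)}
        sets = GeneSetCollection(
            sets={
                "S1": ("s", [f"g{i}" for i in range(10)]),
                "S2": ("s", [f"g{i}" for i in range(5, 25)]),
            }
        )
        results = pathway_fet(class_table(classes), sets)
        assert [r.p_raw for r in results] == [1.0, 1.0]

    def test_small_sets_skipped(self):
        classes = {f"g{i}": "up" if i == 0 else "unaltered" for i in range(30)}
        sets = GeneSetCollection(
            sets={"tiny": ("s", ["g0", "g1"]), "big": ("s", [f"g{i}" for i in range(6)])}
        )
        results = pathway_fet(class_table(classes), sets, min_set_size=5)
        assert [r.set_id for r in results] == ["big"]

    def test_by_adjustment_applied_over_batch(self):
        classes = {f"g{i}": "up" if i < 10 else "unaltered" for i in range(40)}
        sets = GeneSetCollection(
            sets={f"S{j}": ("s", [f"g{(3 * j + k) % 40}" for k in range(8)]) for j in range(6)}
        )
        results = pathway_fet(class_table(classes), sets)
        frame = enrichment_frame(results)
        assert (frame["p_adj"] >= frame["p_raw"] - 1e-15).all()

    def test_zero_dysregulated_warns_and_returns_p_one(self, caplog):
        classes = {f"g{i}": "unaltered" for i in range(20)}
        sets = GeneSetCollection(sets={"S": ("s", [f"g{i}" for i in range(8)])})
        with caplog.at_level("WARNING"):
            (res,) = pathway_fet(class_table(classes), sets)
        assert res.p_raw == 1.0
        assert "dysregulated" in caplog.text


class TestSelectDegs:
    def test_permissive_thresholds_keep_all(self):
        table = DegTable(
            frame=pd.DataFrame(
                {"gene_id": ["g1", "g2"], "log2fc": [0.5, -3.0], "p_adj": [0.9, 0.99]}
            )
        )
        assert len(select_degs(table, lfc_threshold=0.0, p_adj_threshold=1.0)) == 2

    def test_default_rule_on_three_rows(self):
        table = DegTable(
            frame=pd.DataFrame(
                {
                    "gene_id": ["g1", "g2", "g3"],
                    "log2fc": [1.5, -1.5, 0.5],
                    "p_adj": [0.01, 0.2, 0.01],
                }
            )
        )
        assert select_degs(table).gene_ids == ["g1"]

    def test_random_table_matches_bruteforce_filter(self):
        rng = np.random.default_rng(6)
        frame = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(1000)],
                "log2fc": rng.normal(0, 1.5, 1000),
                "p_adj": rng.random(1000),
            }
        )
        kept = set(select_degs(DegTable(frame=frame)).gene_ids)
        expected = {
            row.gene_id
            for row in frame.itertuples()
            if abs(row.log2fc) > 1.0 and row.p_adj < 0.05
        }
        assert kept == expected

    def test_ssa_source_uses_class_and_magnitude(self):
        table = class_table({"g1": "up", "g2": "down", "g3": "unaltered"})
        table.frame.loc[table.frame.gene_id == "g2", ["lfc_signed", "lfc_abs"]] = [-0.5, 0.5]
        degs = select_degs(table)
        assert degs.gene_ids == ["g1"]  # g2 below |log2FC| threshold, g3 unaltered
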