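"""Stage assignment, RF taxon selection, weight screen, and clustering."""

import numpy as np
import pandas as pd
import pytest

from moltsucc.data_model import RelAbundTable, ValidationError
from moltsucc.staging import (
    assign_stages,
    cluster_panels,
    partition_clusters,
    rf_stage_selection,
    weight_association,
)

from conftest import make_meta


def _stage_dataset(n_per_stage=12, n_taxa=30, separating_taxon=True, seed=0):
    """Early/late samples where taxon a0 optionally separates stages."""
    rng = np.random.default_rng(seed)
    rows, metas = [], []
    for k in range(2 * n_per_stage):
        stage_late = k >= n_per_stage
        base = rng.dirichlet(np.ones(n_taxa)) * 0.9
        if separating_taxon:
            base[0] = 0.002 if not stage_late else 0.08
        base = base / base.sum()
        sid = f"s{k}"
        rows.append(base)
        metas.append(make_meta(sid, habitat="midgut",
                               time_h=12.0 if not stage_late else 60.0,
                               crab_weight=float(rng.lognormal(5, 0.1))))
    rel = RelAbundTable(pd.DataFrame(
        rows, index=[f"s{k}" for k in range(2 * n_per_stage)],
        columns=[f"a{j}" for j in range(n_taxa)]))
    return rel, metas


class TestAssignStages:
    def test_boundary_times_are_early(self):
        metas = [make_meta(f"s{i}", time_h=t) for i, t in enumerate((0, 12, 24))]
        metas.append(make_meta("late", time_h=48.0))
        stages = assign_stages(metas, 24.0)
        assert (stages.loc[["s0", "s1", "s2"]] == "early").all()
        assert stages.loc["late"] == "late"

    def test_ck_samples_excluded(self):
        metas = [make_meta("ck", ck=True), make_meta("e", time_h=0.0),
                 make_meta("l", time_h=72.0)]
        stages = assign_stages(metas, 24.0)
        assert "ck" not in stages.index

    def test_empty_side_is_error(self):
        metas = [make_meta(f"s{i}", time_h=float(i)) for i in range(3)]
        with pytest.raises(ValidationError):
            assign_stages(metas, 24.0)


class TestRfStageSelection:
    def test_perfect_separator_reaches_zero_error_at_one_taxon(self):
        rel, metas = _stage_dataset(separating_taxon=True)
        stages = assign_stages(metas, 24.0)
        model = rf_stage_selection(rel, stages, n_trees=100, cv_n_trees=50,
                                   k_folds=5, seed=0, cv_repeats=1)
        assert model.cv_curve.loc[1, "mean_error"] == pytest.approx(0.0)
        assert model.importance_ranking.index[0] == "a0"

    def test_selected_taxa_shrink_with_se_multiplier(self):
        rel, metas = _stage_dataset(separating_taxon=True, seed=1)
        stages = assign_stages(metas, 24.0)
        sizes = []
        for mult in (0.0, 1.0, 3.0):
            model = rf_stage_selection(rel, stages, n_trees=100, cv_n_trees=50,
                                       k_folds=5, seed=0, se_multiplier=mult)
            sizes.append(len(model.selected_taxa))
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_single_class_is_error(self):
        rel, metas = _stage_dataset()
        stages = pd.Series("early", index=rel.sample_ids)
        with pytest.raises(ValidationError):
            rf_stage_selection(rel, stages, n_trees=10)

    def test_fold_reduction_logged_for_small_classes(self, caplog):
        rel, metas = _stage_dataset(n_per_stage=4)
        stages = assign_stages(metas, 24.0)
        with caplog.at_level("WARNING", logger="moltsucc"):
            rf_stage_selection(rel, stages, n_trees=20, cv_n_trees=20,
                               k_folds=10, seed=0, cv_repeats=1)
        assert "reducing folds" in caplog.text


class TestWeightAssociation:
    def test_monotone_weight_taxon_detected(self):
        rel, metas = _stage_dataset(seed=2)
        w = rel.data["a1"] * 1000.0 + 50.0  # weight tracks taxon a1
        out = weight_association(rel, w, selected=["a1", "a2"])
        assert "a1" in out["significant"]
        assert "a1" in out["intersection"]

    def test_independent_weights_mostly_null(self):
        fractions = []
        for seed in range(10):
            rel, metas = _stage_dataset(seed=seed, separating_taxon=False)
            rng = np.random.default_rng(100 + seed)
            w = pd.Series(rng.lognormal(5, 0.2, len(rel.sample_ids)),
                          index=rel.sample_ids)
            out = weight_association(rel, w, selected=[])
            fractions.append(len(out["significant"]) / len(rel.asv_ids))
        assert np.mean(fractions) <= 0.05

    def test_empty_selected_gives_empty_intersection(self):
        rel, metas = _stage_dataset(seed=3)
        w = pd.Series(np.linspace(50, 150, len(rel.sample_ids)),
                      index=rel.sample_ids)
        out = weight_association(rel, w, selected=[])
        assert out["intersection"] == set()

    def test_constant_weights_rejected(self):
        rel, _ = _stage_dataset()
        w = pd.Series(100.0, index=rel.sample_ids)
        with pytest.raises(ValidationError):
            weight_association(rel, w, selected=[])


class TestPartitionClusters:
    def test_early_only_taxon_clusters_early(self):
        rel, metas = _stage_dataset(separating_taxon=False, seed=4)
        df = rel.data.copy()
        early_ids = [m.sample_id for m in metas if m.time_h <= 24]
        df["a0"] = 0.001
        df.loc[early_ids, "a0"] = 0.2
        rel2 = RelAbundTable(df.div(df.sum(axis=1), axis=0))
        stages = assign_stages(metas, 24.0)
        out = partition_clusters(rel2, stages, selected=["a0", "a1"])
        assert out.loc["a0", "cluster"] == "early"

    def test_clusters_partition_all_asvs(self):
        rel, metas = _stage_dataset(seed=5)
        stages = assign_stages(metas, 24.0)
        out = partition_clusters(rel, stages, selected=["a0", "a3", "a7"])
        assert set(out.index) == set(rel.asv_ids)
        assert out["cluster"].isin(["early", "late", "general"]).all()

    def test_empty_selection_rejected(self):
        rel, metas = _stage_dataset()
        stages = assign_stages(metas, 24.0)
        with pytest.raises(ValidationError):
            partition_clusters(rel, stages, selected=[])


class TestClusterPanels:
    def test_all_general_panel_matches_whole_community(self):
        rel, metas = _stage_dataset(seed=6)
        clusters = pd.Series("general", index=rel.asv_ids, name="cluster")
        out = cluster_panels(rel, clusters, metas)
        general = out.loc["general"]
        assert np.allclose(general["total_rel_abund_pct"].astype(float), 100.0)
        whole_rich = (rel.values > 0).sum(axis=1).mean()
        assert general["richness"].astype(float).mean() == pytest.approx(
            whole_rich, rel=0.01)

    def test_cluster_richness_bounded_by_cluster_size(self):
        rel, metas = _stage_dataset(seed=7)
        clusters = pd.Series("general", index=rel.asv_ids, name="cluster")
        clusters.iloc[:5] = "early"
        out = cluster_panels(rel, clusters, metas)
        early = out.loc["early"]
        assert (early["richness"].astype(float) <= 5 + 1e-9).all()

    def test_empty_cluster_emits_nulls_with_warning(self, caplog):
        rel, metas = _stage_dataset(seed=8)
        clusters = pd.Series("general", index=rel.asv_ids, name="cluster")
        with caplog.at_level("WARNING", logger="moltsucc"):
            out = cluster_panels(rel, clusters, metas)
        assert out.loc["early"]["stability_index"].isna().all()
        assert "empty" in caplog.text
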