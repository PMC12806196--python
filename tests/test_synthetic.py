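"""Generator contracts: determinism, planted-effect recoverability, nulls."""

import numpy as np
import pandas as pd
import pytest

import moltsucc as m
from moltsucc.data_model import ValidationError
from moltsucc.synthetic import SyntheticSpec, generate, generate_function_table
from moltsucc.turnover import classify_differential, classify_presence


def _null_spec(**kw):
    """Flat scenario: no drift, no planted taxa unless overridden."""
    base = dict(
        n_asvs=150, seq_depth=30_000, n_replicates=6,
        segments=("midgut",), breakpoint_h={"midgut": None},
        pre_slope=0.0, post_slope=0.0,
        n_emerged=0, n_lost=0, n_enriched=0, n_stage_discriminative=0,
        source_habitats=(), sink_mix={"unknown": 1.0}, seed=0,
    )
    base.update(kw)
    return SyntheticSpec(**base)


def _slice(table, metas, habitat, time_h):
    ids = [x.sample_id for x in metas
           if x.habitat == habitat and not x.is_premolt_ck and x.time_h == time_h]
    return table.select_samples(ids)


class TestGenerate:
    def test_deterministic_given_seed(self):
        spec = SyntheticSpec(n_asvs=60, seq_depth=5000, n_replicates=3,
                             n_emerged=8, n_lost=4, n_enriched=6,
                             n_stage_discriminative=4, seed=11)
        t1, m1, tax1, g1 = generate(spec)
        t2, m2, tax2, g2 = generate(spec)
        pd.testing.assert_frame_equal(t1.data, t2.data)
        assert [x.sample_id for x in m1] == [x.sample_id for x in m2]
        assert g1.emerged == g2.emerged

    def test_ground_truth_ids_exist_in_table(self):
        spec = SyntheticSpec(n_asvs=120, seq_depth=5000, n_replicates=3, seed=2,
                             n_emerged=15, n_lost=5, n_enriched=10,
                             n_stage_discriminative=4)
        table, _, tax, truth = generate(spec)
        universe = set(table.asv_ids)
        listed = (set(truth.emerged) | set(truth.lost) | set(truth.enriched)
                  | set(truth.stage_discriminative))
        assert listed <= universe
        assert set(tax.data.index) == universe

    def test_emerged_mean_is_exactly_zero_before_onset(self):
        spec = SyntheticSpec(n_asvs=120, seq_depth=50_000, n_replicates=6,
                             n_emerged=15, n_lost=5, n_enriched=10,
                             n_stage_discriminative=4,
                             emerged_onset_h=6.0, seed=3)
        table, metas, _, truth = generate(spec)
        for seg in spec.segments:
            for t in (0.0, 3.0):
                sl = _slice(table, metas, seg, t)
                assert (sl.data[list(truth.emerged)].to_numpy() == 0).all()

    def test_null_scenario_has_low_false_emergence(self):
        # no planted emergence, flat trajectories, depth 1e5: the presence
        # classifier should call (almost) nothing emerged
        rates = []
        for seed in range(3):
            spec = _null_spec(seq_depth=100_000, seed=seed)
            table, metas, _, _ = generate(spec)
            base = _slice(table, metas, "midgut", 0.0)
            grp = _slice(table, metas, "midgut", 24.0)
            calls = classify_presence(base, grp)
            rates.append((calls == "emerged").mean())
        assert np.mean(rates) < 0.01

    def test_breakpoint_displacement_rises_then_plateaus(self):
        spec = _null_spec(breakpoint_h={"midgut": 24.0}, pre_slope=0.02,
                          post_slope=0.0, seed=5)
        table, metas, _, _ = generate(spec)
        rel = m.to_relative(table)
        from moltsucc.tipping import dissimilarity_to_baseline

        ts, vs = dissimilarity_to_baseline(rel, metas)["midgut"]
        mean_at = {t: vs[ts == t].mean() for t in np.unique(ts)}
        assert mean_at[24.0] > mean_at[3.0]          # rising leg
        assert abs(mean_at[72.0] - mean_at[24.0]) < 0.5 * (
            mean_at[24.0] - mean_at[3.0])            # plateau leg

    def test_doubling_effect_size_does_not_hurt_enrichment_recall(self):
        recalls = []
        for effect in (2.0, 4.0, 8.0):
            per_seed = []
            for seed in range(3):
                spec = _null_spec(n_enriched=12, effect_size=effect,
                                  seq_depth=50_000, seed=seed,
                                  enriched_onset_h=24.0)
                table, metas, _, truth = generate(spec)
                rel = m.to_relative(table)
                base = rel.select_samples(
                    _slice(table, metas, "midgut", 0.0).sample_ids)
                grp = rel.select_samples(
                    _slice(table, metas, "midgut", 72.0).sample_ids)
                out = classify_differential(base, grp)
                hits = (out.loc[list(truth.enriched), "status"] == "enriched")
                per_seed.append(hits.mean())
            recalls.append(np.mean(per_seed))
        assert recalls[0] <= recalls[1] + 0.1
        assert recalls[1] <= recalls[2] + 0.1

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticSpec(n_asvs=40, n_emerged=30, n_lost=10,
                          n_enriched=10, n_stage_discriminative=5).validate()

    def test_breakpoint_outside_range_rejected(self):
        with pytest.raises(ValidationError):
            _null_spec(breakpoint_h={"midgut": 100.0}).validate()


class TestGenerateFunctionTable:
    def test_rows_sum_to_one(self):
        spec = _null_spec(n_enriched=5, seed=7)
        f, _ = generate_function_table(spec, n_pathways=20, n_linked=3)
        assert np.allclose(f.data.sum(axis=1), 1.0, atol=1e-9)

    def test_perfect_loading_without_noise_is_monotone(self):
        spec = _null_spec(n_enriched=5, seed=8)
        table, _, _, truth = generate(spec)
        f, truth = generate_function_table(
            spec, table=table, truth=truth, n_pathways=10, n_linked=1,
            loading=1.0, noise_sd=0.0)
        taxon, pathway, _ = truth.linked_pairs[0]
        rel = m.to_relative(table)
        from scipy.stats import spearmanr

        rho, _ = spearmanr(rel.data[taxon], f.data[pathway])
        assert rho == pytest.approx(1.0, abs=1e-9)

    def test_zero_loading_gives_calibrated_null(self):
        from moltsucc.stability import taxa_function_correlation

        fractions = []
        for seed in range(5):
            spec = _null_spec(n_enriched=5, seed=seed)
            table, _, _, truth = generate(spec)
            f, _ = generate_function_table(
                spec, table=table, truth=truth, n_pathways=20, loading=0.0)
            rel = m.to_relative(table)
            ids = [s for s in rel.sample_ids]
            screen = taxa_function_correlation(
                rel.select_samples(ids[:40]), f.select_samples(ids[:40]),
                taxa=rel.asv_ids[:25], alpha=0.05)
            fractions.append((screen["sign"] != "ns").mean())
        assert np.mean(fractions) <= 0.05
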