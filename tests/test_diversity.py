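"""Alpha diversity, Bray-Curtis, mixed-gut merging, and regressions."""

import numpy as np
import pandas as pd
import pytest

from moltsucc.data_model import CountTable, RelAbundTable, ValidationError
from moltsucc.diversity import (
    DissimilarityMatrix,
    alpha,
    bray_curtis,
    build_mixed_gut,
    distance_decay,
    segment_vs_reference,
)

from conftest import make_meta


class TestAlpha:
    def test_uniform_row_closed_form(self):
        t = CountTable(pd.DataFrame([[25, 25, 25, 25]], index=["s"],
                                    columns=list("abcd")))
        out = alpha(t)
        assert out.loc["s", "richness"] == 4
        assert out.loc["s", "shannon"] == pytest.approx(np.log(4), abs=1e-12)

    def test_single_taxon_row(self):
        t = CountTable(pd.DataFrame([[10, 0, 0]], index=["s"],
                                    columns=list("abc")))
        out = alpha(t)
        assert out.loc["s", "richness"] == 1
        assert out.loc["s", "shannon"] == 0.0

    def test_shannon_bounded_by_log_richness(self, small_counts):
        out = alpha(small_counts)
        assert (out["shannon"] <= np.log(out["richness"]) + 1e-12).all()


class TestBrayCurtis:
    def test_hand_cases(self):
        rel = RelAbundTable(pd.DataFrame(
            [[1.0, 0.0], [0.0, 1.0], [0.5, 0.5], [0.25, 0.75]],
            index=list("wxyz"), columns=["a", "b"]))
        d = bray_curtis(rel)
        assert d.get("w", "w") == 0.0
        assert d.get("w", "x") == pytest.approx(1.0)
        assert d.get("y", "z") == pytest.approx(0.25)

    def test_matches_double_loop_oracle(self, small_rel):
        d = bray_curtis(small_rel)
        x = small_rel.values
        for i in range(x.shape[0]):
            for j in range(x.shape[0]):
                expected = np.abs(x[i] - x[j]).sum() / (x[i] + x[j]).sum()
                assert d.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_validation_rejects_asymmetry(self):
        with pytest.raises(ValidationError):
            DissimilarityMatrix(("a", "b"),
                                np.array([[0.0, 0.2], [0.3, 0.0]]))


class TestBuildMixedGut:
    def _segment_data(self):
        rows, metas = [], []
        for seg, row in zip(("foregut", "midgut", "hindgut"),
                            ([1, 2], [3, 4], [5, 6])):
            sid = f"{seg}_c1"
            rows.append((sid, row))
            metas.append(make_meta(sid, habitat=seg, time_h=0.0,
                                   crab_id="c1"))
        t = CountTable(pd.DataFrame([r for _, r in rows],
                                    index=[s for s, _ in rows],
                                    columns=["a", "b"]))
        return t, metas

    def test_summation_before_rarefaction(self):
        t, metas = self._segment_data()
        mixed, mm = build_mixed_gut(t, metas)
        assert mixed.counts.tolist() == [[9, 12]]
        assert mm[0].habitat == "mixed_gut"

    def test_mixed_richness_at_least_max_segment(self):
        rng = np.random.default_rng(0)
        rows, metas = [], []
        for seg in ("foregut", "midgut", "hindgut"):
            row = rng.integers(0, 5, 12)
            row[0] += 1
            rows.append((f"{seg}_c1", row))
            metas.append(make_meta(f"{seg}_c1", habitat=seg, crab_id="c1"))
        t = CountTable(pd.DataFrame([r for _, r in rows],
                                    index=[s for s, _ in rows],
                                    columns=[f"a{i}" for i in range(12)]))
        mixed, _ = build_mixed_gut(t, metas)
        seg_rich = (t.counts > 0).sum(axis=1).max()
        assert (mixed.counts[0] > 0).sum() >= seg_rich

    def test_incomplete_triplet_skipped_with_warning(self, caplog):
        t, metas = self._segment_data()
        with caplog.at_level("WARNING", logger="moltsucc"):
            mixed, mm = build_mixed_gut(t, metas[:2])  # hindgut missing
        assert mixed is None and mm == []
        assert "hindgut" in caplog.text

    def test_commutes_with_column_permutation(self):
        t, metas = self._segment_data()
        mixed_ref, _ = build_mixed_gut(t, metas)
        perm = CountTable(t.data[["b", "a"]])
        mixed_perm, _ = build_mixed_gut(perm, metas)
        pd.testing.assert_frame_equal(mixed_perm.data[["a", "b"]],
                                      mixed_ref.data)


class TestDistanceDecay:
    def _setup(self, slope=0.004, noise=0.0, seed=0, n_t=6, reps=4):
        rng = np.random.default_rng(seed)
        times = np.repeat(np.arange(n_t) * 12.0, reps)
        ids = [f"s{i}" for i in range(times.size)]
        metas = [make_meta(s, habitat="midgut", time_h=t)
                 for s, t in zip(ids, times)]
        n = times.size
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    d[i, j] = min(1.0, slope * abs(times[i] - times[j])
                                  + 0.05 + noise * rng.random())
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        return DissimilarityMatrix(tuple(ids), d), metas

    def test_exactly_linear_gives_r2_one(self):
        d, metas = self._setup()
        slope, r2, p = distance_decay(d, metas, n_perm=99, seed=0)
        assert slope == pytest.approx(0.004, rel=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-9)
        assert p < 0.05

    def test_null_permutation_roughly_uniform(self):
        # label-shuffled inputs: rejection rate near alpha
        rng = np.random.default_rng(5)
        hits = 0
        n_runs = 100
        for k in range(n_runs):
            n = 24
            times = np.repeat([0.0, 12.0, 24.0, 48.0], 6)
            rng.shuffle(times)
            ids = [f"s{i}" for i in range(n)]
            metas = [make_meta(s, habitat="midgut", time_h=t)
                     for s, t in zip(ids, times)]
            m = rng.random((n, n)) * 0.3
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0.0)
            _, _, p = distance_decay(DissimilarityMatrix(tuple(ids), d),
                                     metas, n_perm=99, seed=k)
            hits += p < 0.05
        assert 0.01 <= hits / n_runs <= 0.10

    def test_too_few_pairs_is_error(self):
        d, metas = self._setup(n_t=3, reps=1)
        with pytest.raises(ValidationError):
            distance_decay(d, metas, n_perm=9, seed=0)


class TestSegmentVsReference:
    def test_identical_segment_wins_with_r2_one(self):
        t = pd.Index([0.0, 12.0, 24.0, 48.0])
        hind = pd.Series([1.0, 2.0, 3.0, 4.0], index=t)
        fore = pd.Series([4.0, 1.0, 3.5, 2.0], index=t)
        out = segment_vs_reference({"hindgut": hind, "foregut": fore},
                                   metric_reference=hind)
        assert out.index[0] == "hindgut"
        assert out.loc["hindgut", "r_squared"] == pytest.approx(1.0)

    def test_noise_dominated_reference_ranks_low(self):
        rng = np.random.default_rng(3)
        t = pd.Index(np.arange(8, dtype=float))
        seg = pd.Series(np.arange(8, dtype=float), index=t)
        ref = seg + rng.normal(0, 50.0, 8)
        noisy = pd.Series(rng.normal(0, 1, 8), index=t)
        out = segment_vs_reference({"clean": ref.copy(), "noisy": noisy},
                                   metric_reference=ref)
        assert out.index[0] == "clean"
        assert out.loc["clean", "r_squared"] == pytest.approx(1.0)

    def test_constant_series_is_error(self):
        t = pd.Index([0.0, 1.0, 2.0])
        with pytest.raises(ValidationError, match="constant"):
            segment_vs_reference(
                {"flat": pd.Series([1.0, 1.0, 1.0], index=t)},
                metric_reference=pd.Series([1.0, 2.0, 3.0], index=t))

    def test_too_few_points_is_error(self):
        t = pd.Index([0.0, 1.0])
        with pytest.raises(ValidationError):
            segment_vs_reference(
                {"x": pd.Series([1.0, 2.0], index=t)},
                metric_reference=pd.Series([1.0, 2.0], index=t))
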