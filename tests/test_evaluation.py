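import numpy as np
import pandas as pd
import pytest

from scmeth import (BinaryStateTable, SiteCatalog, auprc, downsample,
                    evaluate, filter_by_score, quality_score, quality_scores,
                    site_variability)
from scmeth.evaluation import UndefinedMetric, downsample_sites, read_bed_strata
from scmeth.model import PredictionMatrix
from oracles import auprc_bruteforce, quality_score_bruteforce


def _catalog(positions, chrom="s1"):
    n = len(positions)
    return SiteCatalog(np.array([chrom] * n, dtype=object),
                       np.asarray(positions),
                       np.array(["+"] * n, dtype=object))


class TestAuprc:
    def test_perfect_ranking(self):
        assert auprc([1, 0], [0.9, 0.1]) == 1.0

    def test_two_point_inverted_matches_oracle(self):
        labels, scores = [0, 1], [0.9, 0.1]
        assert auprc(labels, scores) == pytest.approx(
            auprc_bruteforce(labels, scores))

    def test_oracle_equivalence_with_ties(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 13))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            assert auprc(labels, scores) == pytest.approx(
                auprc_bruteforce(labels, scores), abs=1e-12)

    def test_no_skill_limit_is_positive_fraction(self, rng):
        n, pi = 20_000, 0.3
        labels = (rng.random(n) < pi).astype(int)
        scores = rng.random(n)
        assert auprc(labels, scores) == pytest.approx(pi, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetric):
            auprc([1, 1, 1], [0.1, 0.2, 0.3])


class TestSiteVariability:
    def _states(self, per_site_states, catalog):
        rows = []
        for s, states in enumerate(per_site_states):
            for i, v in enumerate(states):
                rows.append({"cell": f"c{i}", "chrom": "s1",
                             "pos": int(catalog.pos[s]), "strand": "+",
                             "state": v})
        return BinaryStateTable(pd.DataFrame(rows))

    def test_constant_and_balanced(self):
        cat = _catalog([10, 20, 30])
        states = self._states([[1, 1, 1, 1], [1, 1, 0, 0], [1]], cat)
        var = site_variability(states, cat)
        assert var[0] == 0.0
        assert var[1] == pytest.approx(0.25)
        assert np.isnan(var[2])  # single observation: unstratifiable

    def test_decile_partition_near_equal(self, rng):
        cat = _catalog((np.arange(200) + 1) * 10)
        frames = []
        for s in range(200):
            p = rng.random()
            states = (rng.random(20) < p).astype(int)
            frames.append(pd.DataFrame({
                "cell": [f"c{i}" for i in range(20)], "chrom": "s1",
                "pos": int(cat.pos[s]), "strand": "+", "state": states}))
        states = BinaryStateTable(pd.concat(frames, ignore_index=True))
        var = site_variability(states, cat)
        edges = np.quantile(var, np.linspace(0, 1, 11))
        counts, _ = np.histogram(var, bins=edges)
        assert counts.sum() == 200
        assert counts.min() >= 10  # near-equal deciles


class TestDownsample:
    @pytest.fixture
    def states(self, rng):
        rows = []
        for i in range(50):
            for s in range(20):
                if rng.random() < 0.99:
                    rows.append({"cell": f"c{i}", "chrom": "s1",
                                 "pos": (s + 1) * 10, "strand": "+",
                                 "state": int(rng.integers(0, 2))})
        return BinaryStateTable(pd.DataFrame(rows))

    def test_exact_count_and_subset(self, states):
        n = len(states)
        out = downsample(states, 0.1, seed=3)
        assert len(out) == round(0.1 * n)
        full = set(map(tuple, states.frame.to_numpy()))
        assert set(map(tuple, out.frame.to_numpy())) <= full

    def test_identity_at_rate_one(self, states):
        out = downsample(states, 1.0, seed=3)
        pd.testing.assert_frame_equal(
            out.frame.reset_index(drop=True),
            states.sorted().frame.reset_index(drop=True))

    def test_nested_chain_shared_seed(self, states):
        kept = {r: set(map(tuple, downsample(states, r, seed=11)
                           .frame.to_numpy()))
                for r in (0.01, 0.1, 0.5)}
        assert kept[0.01] <= kept[0.1] <= kept[0.5]

    def test_reproducible(self, states):
        a = downsample(states, 0.2, seed=5).frame
        b = downsample(states, 0.2, seed=5).frame
        pd.testing.assert_frame_equal(a, b)

    def test_per_site_mode_keeps_whole_sites(self, states):
        out = downsample_sites(states, 0.4, seed=2)
        kept_sites = set(map(tuple,
                             out.frame[["chrom", "pos"]].to_numpy()))
        all_sites = set(map(tuple,
                            states.frame[["chrom", "pos"]].to_numpy()))
        assert len(kept_sites) == round(0.4 * len(all_sites))
        # every kept site keeps all its entries
        full_counts = states.frame.groupby(["chrom", "pos"]).size()
        out_counts = out.frame.groupby(["chrom", "pos"]).size()
        for key, count in out_counts.items():
            assert count == full_counts[key]

    def test_bad_rate(self, states):
        from scmeth import ConfigError
        with pytest.raises(ConfigError):
            downsample(states, 0.0)


class TestQualityScore:
    def _pred(self, probs_rows, positions):
        cat = _catalog(positions)
        return PredictionMatrix([f"c{i}" for i in range(len(probs_rows))],
                                cat, np.asarray(probs_rows, dtype=float))

    def test_constant_neighborhood_scores_zero(self):
        pred = self._pred([np.full(11, 0.8)], (np.arange(11) + 1) * 10)
        assert quality_score(pred, "c0", 5) == 0.0

    def test_alternating_neighbors(self):
        probs = np.array([1, 0, 1, 0, 1, 1.0, 0, 1, 0, 1, 0])
        pred = self._pred([probs], (np.arange(11) + 1) * 10)
        # target p=1 at center; 5 upstream + 5 downstream alternate 0/1
        assert quality_score(pred, "c0", 5) == pytest.approx(0.5)

    def test_matches_bruteforce(self, rng):
        positions = np.sort(rng.choice(5000, size=30, replace=False)) + 1
        probs = rng.random((3, 30))
        pred = self._pred(probs, positions)
        table = quality_scores(pred)
        for cell_idx in range(3):
            by_pos = {int(p): probs[cell_idx, i]
                      for i, p in enumerate(positions)}
            for site in range(30):
                expected = quality_score_bruteforce(by_pos,
                                                    int(positions[site]))
                assert quality_score(pred, f"c{cell_idx}", site) == \
                    pytest.approx(expected)
                assert table[cell_idx, site] == pytest.approx(expected)


class TestFilter:
    @pytest.fixture
    def pred_scores(self, rng):
        pred = PredictionMatrix(["a", "b"], _catalog([10, 20, 30, 40]),
                                rng.random((2, 4)))
        scores = np.array([[0.0, 0.2, 0.5, 1.0], [0.05, 0.15, 0.35, 0.95]])
        return pred, scores

    def test_strict_inequality(self, pred_scores):
        pred, scores = pred_scores
        assert filter_by_score(pred, scores, 0.0).retained.sum() == 0
        kept = filter_by_score(pred, scores, 1.0).retained
        assert kept.sum() == 7  # the score-1.0 entry is dropped

    def test_monotone_nesting(self, pred_scores):
        pred, scores = pred_scores
        previous = None
        for t in (0.1, 0.2, 0.3, 0.4):
            kept = filter_by_score(pred, scores, t).retained
            if previous is not None:
                assert np.all(previous <= kept)
            previous = kept

    def test_nan_scores_retained_with_warning(self, pred_scores):
        pred, scores = pred_scores
        scores = scores.copy()
        scores[0, 0] = np.nan
        with pytest.warns(UserWarning, match="undefined"):
            kept = filter_by_score(pred, scores, 0.01).retained
        assert kept[0, 0]


class TestEvaluate:
    def _mixed_quality_fixture(self, rng, n_cells=24, n_sites=120):
        """Half the cells predict accurately and smoothly (low quality
        scores); half guess at random (high scores)."""
        positions = (np.arange(n_sites) + 1) * 7
        cat = _catalog(positions)
        block = np.repeat(rng.integers(0, 2, size=n_sites // 8 + 1), 8)[:n_sites]
        labels = np.tile(block, (n_cells, 1))
        probs = np.zeros((n_cells, n_sites))
        good = np.arange(n_cells) < n_cells // 2
        probs[good] = np.clip(labels[good] * 0.8 + 0.1
                              + rng.normal(0, 0.02, labels[good].shape), 0, 1)
        probs[~good] = rng.random(probs[~good].shape)
        pred = PredictionMatrix([f"c{i}" for i in range(n_cells)], cat, probs)
        rows = []
        for i in range(n_cells):
            for s in range(n_sites):
                rows.append({"cell": f"c{i}", "chrom": "s1",
                             "pos": int(positions[s]), "strand": "+",
                             "state": int(labels[i, s])})
        return pred, BinaryStateTable(pd.DataFrame(rows))

    def test_perfect_predictions_score_one(self, rng):
        pred, held = self._mixed_quality_fixture(rng)
        exact = PredictionMatrix(pred.cells, pred.catalog,
                                 held.dense(pred.cells, pred.catalog)[0]
                                 .astype(float))
        report = evaluate(exact, held)
        assert report.overall_auprc == 1.0
        assert report.n_entries == len(held)

    def test_filtering_improves_auprc_monotonically(self, rng):
        pred, held = self._mixed_quality_fixture(rng)
        report = evaluate(pred, held, thresholds=(0.4, 0.3, 0.2, 0.1))
        values = report.by_score_threshold.sort_values(
            "threshold", ascending=False)["auprc"].to_numpy()
        assert np.all(np.diff(values) > 0)
        assert values[-1] > report.overall_auprc

    def test_decile_report_covers_sites(self, rng):
        pred, held = self._mixed_quality_fixture(rng)
        report = evaluate(pred, held)
        assert len(report.by_variability_decile) <= 10
        assert report.by_variability_decile["n_entries"].sum() == len(held)

    def test_bed_strata_and_single_class_reported_nan(self, rng, tmp_path):
        pred, held = self._mixed_quality_fixture(rng)
        bed = tmp_path / "strata.bed"
        # stratum B covers nothing methylated=0/1 mixed? force single-class
        bed.write_text("s1\t0\t400\tA\ns1\t40000\t40100\tB\n")
        report = evaluate(pred, held, strata_bed=read_bed_strata(bed))
        frame = report.by_annotation.set_index("annotation")
        assert frame.loc["A", "n_entries"] > 0
        assert frame.loc["B", "n_entries"] == 0
        assert np.isnan(frame.loc["B", "auprc"])
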