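import itertools

import numpy as np
import pandas as pd
import pytest

import survmixer as sm


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------

class TestGradcam:
    def test_map_shape_z_and_nonnegativity(self, tiny_trained):
        model = tiny_trained["model"]
        x = tiny_trained["images"].images[:6]
        maps = sm.gradcam(model, x)
        g = model.layout.grid_side
        assert maps.maps.shape == (6, g, g)
        assert maps.z == g * g
        assert (maps.maps >= 0).all()
        assert maps.layer == model.stage_names()[-1]

    def test_channel_importances_match_finite_differences(self, tiny_trained):
        """Autodiff d(logit)/dA vs central finite differences on a 2-channel model."""
        images = tiny_trained["images"]
        cfg = sm.ModelConfig(channels=2, n_blocks=1, patch_kernel=2, patch_stride=2,
                             epochs=2, seed=5)
        model, _ = sm.train_model(images.images, tiny_trained["labels"], cfg, images.layout)
        x = images.images[:1]
        layer = model.stage_names()[-1]
        features, grads = model.gradient_at(x, layer)
        z = features.shape[2] * features.shape[3]
        alpha_auto = grads.sum(axis=(2, 3))[0] / z

        h = 1e-5
        alpha_fd = np.zeros(cfg.channels)
        for n in range(cfg.channels):
            for i in range(features.shape[2]):
                for j in range(features.shape[3]):
                    fp, fm = features.copy(), features.copy()
                    fp[0, n, i, j] += h
                    fm[0, n, i, j] -= h
                    yp = model.score_from(layer, fp)[0]
                    ym = model.score_from(layer, fm)[0]
                    alpha_fd[n] += (yp - ym) / (2 * h)
        alpha_fd /= z
        np.testing.assert_allclose(alpha_auto, alpha_fd, rtol=1e-3, atol=1e-9)

    def test_prerelu_map_is_linear_in_features(self, tiny_trained):
        # with importances held fixed, scaling all channel maps scales the map
        model = tiny_trained["model"]
        x = tiny_trained["images"].images[:2]
        features, grads = model.gradient_at(x, model.stage_names()[-1])
        z = features.shape[2] * features.shape[3]
        alpha = grads.sum(axis=(2, 3)) / z
        combo = np.einsum("nc,nchw->nhw", alpha, features)
        combo_scaled = np.einsum("nc,nchw->nhw", alpha, 3.0 * features)
        np.testing.assert_allclose(combo_scaled, 3.0 * combo, rtol=1e-12)

    def test_survival_class_flips_gradient_sign(self, tiny_trained):
        model = tiny_trained["model"]
        x = tiny_trained["images"].images[:3]
        death = sm.gradcam(model, x, target_class=1)
        surv = sm.gradcam(model, x, target_class=0)
        features, grads = model.gradient_at(x, model.stage_names()[-1])
        z = death.z
        raw = np.einsum("nc,nchw->nhw", grads.sum(axis=(2, 3)) / z, features)
        np.testing.assert_allclose(death.maps, np.maximum(raw, 0), atol=1e-12)
        np.testing.assert_allclose(surv.maps, np.maximum(-raw, 0), atol=1e-12)

    def test_unknown_layer_rejected(self, tiny_trained):
        with pytest.raises(sm.ModelError):
            sm.gradcam(tiny_trained["model"], tiny_trained["images"].images[:1],
                       layer="nope")


class TestPathwayActivations:
    def test_one_value_per_pathway(self, tiny_trained):
        model = tiny_trained["model"]
        maps = sm.gradcam(model, tiny_trained["images"].images[:4])
        act = sm.pathway_activations(maps, model.layout)
        assert act.shape == (4, len(model.layout.pathway_slots))
        assert list(act.columns) == list(model.layout.pathway_slots)

    def test_zero_maps_give_zero_activations(self, small_layout):
        maps = sm.ActivationMaps(np.zeros((3, 3, 3)), 1, "block1", 9)
        act = sm.pathway_activations(maps, small_layout)
        assert (act.to_numpy() == 0).all()

    def test_pathway_order_permutation_equivariance(self, rng):
        # permuting the collection permutes activation columns identically
        lists = [(f"pw{i}", [f"g{i}"]) for i in range(6)]
        c1 = sm.PathwayCollection.from_lists(lists)
        perm = [3, 0, 5, 1, 4, 2]
        c2 = sm.PathwayCollection.from_lists([lists[i] for i in perm])
        l1 = sm.build_layout(c1, patch_side=2, grid_side=3)
        l2 = sm.build_layout(c2, patch_side=2, grid_side=3)
        grids = rng.uniform(size=(5, 3, 3))
        # same physical grid values; only the name->slot map changes
        a1 = sm.pathway_activations(sm.ActivationMaps(grids, 1, "x", 9), l1)
        a2 = sm.pathway_activations(sm.ActivationMaps(grids, 1, "x", 9), l2)
        for new_pos, old_idx in enumerate(perm):
            name = f"pw{old_idx}"
            # pathway 'name' sits at slot new_pos in l2: value drawn from that slot
            r, c = l2.pathway_slots[name]
            np.testing.assert_array_equal(a2[name], grids[:, r, c])
        assert set(a1.columns) == set(a2.columns)


# ---------------------------------------------------------------------------
# Rank-sum tests + Bonferroni
# ---------------------------------------------------------------------------

def exact_rank_sum_p(a, b):
    """Enumeration oracle: two-sided p over all C(n+m, n) group assignments."""
    pooled = np.concatenate([a, b])
    n = len(a)
    ranks = pd.Series(pooled).rank().to_numpy()
    observed = ranks[:n].sum()
    mean = n * (len(pooled) + 1) / 2
    stats = []
    for combo in itertools.combinations(range(len(pooled)), n):
        stats.append(ranks[list(combo)].sum())
    stats = np.array(stats)
    p = np.mean(np.abs(stats - mean) >= abs(observed - mean) - 1e-12)
    return float(p)


class TestRankSum:
    def test_separated_groups_exact_p(self):
        # most extreme of C(6,3)=20 orderings, both tails: p = 2/20
        assert sm.rank_sum_p([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        assert sm.rank_sum_p([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            a = rng.normal(size=int(rng.integers(3, 7)))
            b = rng.normal(size=int(rng.integers(3, 7)))
            assert sm.rank_sum_p(a, b) == pytest.approx(exact_rank_sum_p(a, b), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(sm.InterpretationError):
            sm.rank_sum_p([], [1.0])


class TestWilcoxonKeyPathways:
    def test_bonferroni_correction_and_flag(self, rng):
        act = pd.DataFrame(rng.normal(size=(20, 40)),
                           columns=[f"pw{i}" for i in range(40)])
        labels = np.array([0] * 10 + [1] * 10)
        act.iloc[labels == 1, 0] += 10.0  # one hugely separated pathway
        report = sm.wilcoxon_keypathways(act, labels)
        assert report.loc["pw0", "significant"]
        np.testing.assert_allclose(
            report["corrected_p"], np.minimum(1.0, report["raw_p"] * 40)
        )
        # Bonferroni never decreases a p-value; corrected p stays in (0, 1]
        assert (report["corrected_p"] >= report["raw_p"] - 1e-15).all()
        assert (report["corrected_p"] <= 1.0).all()

    def test_raw_p_002_times_40_not_significant(self):
        # 0.002 * 40 = 0.08 >= 0.05 after correction over 40 pathways
        corrected = min(1.0, 0.002 * 40)
        assert corrected == pytest.approx(0.08)
        assert not corrected < 0.05

    def test_single_label_group_rejected(self, rng):
        act = pd.DataFrame(rng.normal(size=(5, 3)))
        with pytest.raises(sm.InterpretationError):
            sm.wilcoxon_keypathways(act, [1, 1, 1, 1, 1])


# ---------------------------------------------------------------------------
# GSVA
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def gsva_setup():
    rng = np.random.default_rng(0)
    genes = [f"G{i}" for i in range(60)]
    samples = [f"s{j}" for j in range(12)]
    values = rng.normal(size=(12, 60))
    coll = sm.PathwayCollection.from_lists(
        [("setA", genes[:8]), ("setB", genes[8:20])]
    )
    return genes, samples, values, coll


class TestGsvaScores:
    def test_rank_extreme_sample_scores_maximal(self, gsva_setup):
        genes, samples, values, coll = gsva_setup
        v = values.copy()
        v[0, :8] = 50.0   # sample s0: setA genes at the top...
        v[0, 8:] = -50.0  # ...all other genes at the bottom
        m = sm.ExpressionMatrix(samples, genes, v)
        scores = sm.gsva_scores(m, coll)
        assert scores.shape == (2, 12)
        assert scores.loc["setA"].idxmax() == "s0"

    def test_duplicated_sample_duplicates_score_column(self, gsva_setup):
        genes, samples, values, coll = gsva_setup
        ids = samples + ["s0_copy"]
        v = np.vstack([values, values[0]])
        scores = sm.gsva_scores(sm.ExpressionMatrix(ids, genes, v), coll)
        np.testing.assert_allclose(scores["s0_copy"], scores["s0"], atol=1e-9)

    def test_null_sets_center_near_zero(self):
        # random membership carries no coordinated signal
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(500)]
        samples = [f"s{j}" for j in range(15)]
        m = sm.ExpressionMatrix(samples, genes, rng.normal(size=(15, 500)))
        coll = sm.PathwayCollection.from_lists(
            [(f"null{k}", list(rng.choice(genes, size=20, replace=False)))
             for k in range(5)]
        )
        scores = sm.gsva_scores(m, coll)
        assert abs(scores.to_numpy().mean()) < 0.1

    def test_missing_genes_warned_and_empty_pathway_nan(self, gsva_setup):
        genes, samples, values, coll = gsva_setup
        coll2 = sm.PathwayCollection.from_lists(
            [("setA", list(coll.pathways[0].genes)), ("ghost", ["NOPE1", "NOPE2"])]
        )
        m = sm.ExpressionMatrix(samples, genes, values)
        with pytest.warns(UserWarning, match="no matched genes"):
            scores = sm.gsva_scores(m, coll2)
        assert scores.loc["ghost"].isna().all()
        assert not scores.loc["setA"].isna().any()

    def test_too_few_samples_rejected(self, gsva_setup):
        genes, samples, values, coll = gsva_setup
        m = sm.ExpressionMatrix(samples[:2], genes, values[:2])
        with pytest.raises(sm.InterpretationError):
            sm.gsva_scores(m, coll)


# ---------------------------------------------------------------------------
# Kaplan-Meier + log-rank
# ---------------------------------------------------------------------------

def logrank_oracle(t1, e1, t2, e2):
    """Observed-minus-expected over risk sets; returns (chi2, p)."""
    from scipy.stats import chi2 as chi2_dist

    times = np.concatenate([t1, t2])
    events = np.concatenate([e1, e2])
    group = np.concatenate([np.zeros(len(t1)), np.ones(len(t2))])
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e ** 2 / var
    return chi2, float(chi2_dist.sf(chi2, 1))


class TestKmLogrank:
    def _records(self, times, events):
        return [sm.SurvivalRecord(f"s{i}", float(t), int(e))
                for i, (t, e) in enumerate(zip(times, events))]

    def test_product_limit_worked_case(self):
        # 4 at risk, one death at t=1 and one at t=2: S(1)=0.75, S(2)=0.5
        curve = sm.km_curve(np.array([1.0, 2.0, 3.0, 4.0]), np.ones(4))
        s = dict(zip(curve["time"], curve["survival"]))
        assert s[1.0] == pytest.approx(0.75)
        assert s[2.0] == pytest.approx(0.5)

    def test_identical_groups_p_one(self):
        times = [1, 2, 3, 4, 5, 6, 1, 2, 3, 4, 5, 6]
        events = [1, 0, 1, 1, 0, 1] * 2
        records = self._records(times, events)
        scores = pd.Series(
            [0.0] * 6 + [1.0] * 6, index=[f"s{i}" for i in range(12)]
        )
        out = sm.km_logrank(scores, records)
        assert out["logrank_p"] == pytest.approx(1.0)

    def test_matches_risk_set_oracle_on_random_cohorts(self, rng):
        for trial in range(50):
            n = int(rng.integers(8, 24))
            times = rng.exponential(5.0, size=n).round(1) + 0.1
            events = rng.integers(0, 2, size=n)
            if events.sum() == 0:
                events[0] = 1
            scores = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
            records = self._records(times, events)
            try:
                out = sm.km_logrank(scores, records)
            except sm.InterpretationError:
                continue  # degenerate split; oracle comparison inapplicable
            hi = scores > scores.median()
            chi2, p = logrank_oracle(
                times[~hi.to_numpy()], events[~hi.to_numpy()],
                times[hi.to_numpy()], events[hi.to_numpy()],
            )
            assert out["logrank_statistic"] == pytest.approx(chi2, abs=1e-10)
            assert out["logrank_p"] == pytest.approx(p, abs=1e-10)

    def test_median_split_ties_go_low(self):
        scores = pd.Series([1.0, 2.0, 2.0, 3.0, 4.0, 5.0],
                           index=[f"s{i}" for i in range(6)])
        records = self._records([1, 2, 3, 4, 5, 6], [1] * 6)
        out = sm.km_logrank(scores, records)
        # median 2.5; scores <= 2.5 are low
        assert set(out["low_ids"]) == {"s0", "s1", "s2"}
        assert set(out["high_ids"]) == {"s3", "s4", "s5"}

    def test_constant_scores_rejected(self):
        scores = pd.Series([1.0] * 6, index=[f"s{i}" for i in range(6)])
        records = self._records([1, 2, 3, 4, 5, 6], [1] * 6)
        with pytest.raises(sm.InterpretationError, match="degenerate"):
            sm.km_logrank(scores, records)


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

def test_find_key_pathways_end_to_end(tmp_path, tiny_trained):
    report = sm.find_key_pathways(
        tiny_trained["model"],
        tiny_trained["images"].images,
        tiny_trained["labels"],
        tiny_trained["images"].sample_ids,
        tiny_trained["cohort"].expression,
        tiny_trained["collection"],
        tiny_trained["cohort"].records,
    )
    assert set(report.tests.index) == set(tiny_trained["collection"].names)
    assert (report.tests["corrected_p"] >= report.tests["raw_p"] - 1e-15).all()
    report.save(tmp_path)
    assert (tmp_path / "key_pathways.tsv").exists()
    assert (tmp_path / "key_pathways.json").exists()
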