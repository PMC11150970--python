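import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import myosig as ms
from myosig.derivation import PUBLISHED_GRID, PUBLISHED_THRESHOLDS, CandidateResult


def _annotation(labels, targets, obs_ids):
    return ms.ClusterAnnotation(pd.Series(labels, index=obs_ids), target_clusters=frozenset(targets))


class TestDetectionFraction:
    def test_counting(self):
        df = pd.DataFrame([[0, 2, 0]], index=["g"], columns=["a", "b", "c"])
        m = ms.CountMatrix(df)
        assert ms.detection_fraction(m, ["a", "b", "c"]).loc["g"] == pytest.approx(1 / 3)

    def test_boundaries(self):
        df = pd.DataFrame([[0, 0], [5, 1]], index=["zero", "full"], columns=["a", "b"])
        m = ms.CountMatrix(df)
        frac = ms.detection_fraction(m, ["a", "b"])
        assert frac.loc["zero"] == 0.0
        assert frac.loc["full"] == 1.0

    def test_matches_brute_force_on_sparse_random_matrix(self):
        rng = np.random.default_rng(5)
        vals = rng.poisson(0.3, size=(50, 200))
        m = ms.CountMatrix(pd.DataFrame(
            vals, index=[f"g{i}" for i in range(50)], columns=[f"c{i}" for i in range(200)]
        ))
        subset = [f"c{i}" for i in rng.choice(200, 80, replace=False)]
        got = ms.detection_fraction(m, subset)
        for gi in range(50):
            expect = sum(
                1 for c in subset if vals[gi, int(c[1:])] > 0
            ) / len(subset)
            assert got.iloc[gi] == pytest.approx(expect)

    def test_empty_subset_rejected(self, tiny_matrix):
        with pytest.raises(ValueError, match="non-empty"):
            ms.detection_fraction(tiny_matrix, [])


class TestMarkerStats:
    def test_fold_change_of_three(self, tiny_matrix):
        # equal library sizes, so normalization rescales both means identically
        ann = _annotation(["t"] * 3 + ["o"] * 3, ["t"], tiny_matrix.obs_ids)
        stats = ms.compute_marker_stats(tiny_matrix, ann, pseudocount=0.0)
        assert stats.table.loc["gA", "fold_change"] == pytest.approx(3.0)
        assert stats.table.loc["gB", "fold_change"] == pytest.approx(1 / 3)
        assert stats.table.loc["gC", "fold_change"] == pytest.approx(1.0)

    def test_null_gene_has_unit_fold_change_and_high_qvalue(self):
        rng = np.random.default_rng(2)
        vals = rng.poisson(5.0, size=(30, 200))
        obs = [f"c{i}" for i in range(200)]
        m = ms.CountMatrix(pd.DataFrame(vals, index=[f"g{i}" for i in range(30)], columns=obs))
        ann = _annotation(["t"] * 100 + ["o"] * 100, ["t"], obs)
        stats = ms.compute_marker_stats(m, ann)
        med_fc = stats.table["fold_change"].median()
        assert 0.9 < med_fc < 1.1
        assert stats.table["de_qvalue"].median() > 0.3

    def test_every_field_matches_per_gene_loop_oracle(self):
        rng = np.random.default_rng(9)
        n_genes, per = 40, 60
        vals = rng.poisson(1.0, size=(n_genes, 3 * per))
        vals[0, :per] = rng.poisson(4.0, size=per)  # planted marker in cluster A
        obs = [f"c{i}" for i in range(3 * per)]
        labels = ["A"] * per + ["B"] * per + ["C"] * per
        m = ms.CountMatrix(pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)], columns=obs))
        ann = _annotation(labels, ["A"], obs)
        pc = 0.01
        stats = ms.compute_marker_stats(m, ann, pseudocount=pc)

        libsize = vals.sum(axis=0)
        norm = vals / libsize * 1e4
        tmask = np.array([l == "A" for l in labels])
        for gi in range(n_genes):
            mt = norm[gi, tmask].mean()
            mr = norm[gi, ~tmask].mean()
            row = stats.table.iloc[gi]
            assert row["mean_target"] == pytest.approx(mt)
            assert row["mean_rest"] == pytest.approx(mr)
            assert row["fold_change"] == pytest.approx((mt + pc) / (mr + pc))
            assert row["detect_target"] == pytest.approx((vals[gi, tmask] > 0).mean())
            assert row["detect_global_other"] == pytest.approx((vals[gi, ~tmask] > 0).mean())
            per_cluster = [
                (vals[gi, [l == c for l in labels]] > 0).mean() for c in ("B", "C")
            ]
            assert row["detect_max_other_cluster"] == pytest.approx(max(per_cluster))
            p = scipy.stats.mannwhitneyu(
                norm[gi, tmask], norm[gi, ~tmask], alternative="two-sided"
            ).pvalue
            assert row["de_pvalue"] == pytest.approx(p)

    def test_global_detection_lies_within_cluster_range(self, sc_pair):
        m, ann, _, _, _ = sc_pair
        stats = ms.compute_marker_stats(m, ann, de_prefilter=False)
        other = [c for c in ann.clusters if c not in ann.target_clusters]
        detected = m.values.to_numpy() > 0
        labels = ann.labels.to_numpy()
        per_cluster = np.column_stack(
            [detected[:, labels == c].mean(axis=1) for c in other]
        )
        glob = stats.table["detect_global_other"].to_numpy()
        assert (glob >= per_cluster.min(axis=1) - 1e-12).all()
        assert (glob <= per_cluster.max(axis=1) + 1e-12).all()

    def test_single_cluster_is_an_error(self, tiny_matrix):
        ann = _annotation(["t"] * 6, ["t"], tiny_matrix.obs_ids)
        with pytest.raises(ValueError):
            ms.compute_marker_stats(tiny_matrix, ann)


def _stats_from_frame(df):
    return ms.MarkerStats(table=df, target_clusters=frozenset({"t"}), pseudocount=0.01)


def _stats_row(fc, glob, clus, q=0.0):
    return {
        "mean_target": 1.0, "mean_rest": 1.0, "fold_change": fc,
        "detect_target": 0.9, "detect_global_other": glob,
        "detect_max_other_cluster": clus, "de_pvalue": q, "de_qvalue": q,
    }


class TestApplyThresholds:
    def test_passing_gene_included(self):
        df = pd.DataFrame({"g1": _stats_row(2.0, 0.05, 0.10)}).T
        t = ms.SelectionThresholds(1.5, 0.10, 0.30)
        assert ms.apply_thresholds(_stats_from_frame(df), t) == ("g1",)

    @pytest.mark.parametrize(
        "fc,glob,clus",
        [
            (1.4, 0.05, 0.10),   # fold change below minimum
            (1.5, 0.05, 0.10),   # fold change exactly at minimum: strict
            (2.0, 0.10, 0.10),   # global detection at maximum: strict
            (2.0, 0.05, 0.30),   # cluster detection at maximum: strict
        ],
    )
    def test_boundaries_are_strict(self, fc, glob, clus):
        df = pd.DataFrame({"g1": _stats_row(fc, glob, clus)}).T
        t = ms.SelectionThresholds(1.5, 0.10, 0.30)
        assert ms.apply_thresholds(_stats_from_frame(df), t) == ()

    def test_de_filter_applies(self):
        df = pd.DataFrame({"g1": _stats_row(2.0, 0.05, 0.10, q=0.2)}).T
        t = ms.SelectionThresholds(1.5, 0.10, 0.30)
        assert ms.apply_thresholds(_stats_from_frame(df), t, de_alpha=0.05) == ()

    def test_matches_brute_force_predicate_and_ordering(self):
        rng = np.random.default_rng(3)
        rows = {}
        for i in range(200):
            rows[f"g{i}"] = _stats_row(
                float(rng.uniform(0.5, 4.0)),
                float(rng.uniform(0, 0.3)),
                float(rng.uniform(0, 0.6)),
                float(rng.uniform(0, 0.2)),
            )
        df = pd.DataFrame(rows).T
        t = ms.SelectionThresholds(1.5, 0.10, 0.30)
        got = ms.apply_thresholds(_stats_from_frame(df), t, de_alpha=0.05)
        expect = [
            g for g, r in df.iterrows()
            if r["de_qvalue"] < 0.05 and r["fold_change"] > 1.5
            and r["detect_global_other"] < 0.10 and r["detect_max_other_cluster"] < 0.30
        ]
        assert set(got) == set(expect)
        fcs = [df.loc[g, "fold_change"] for g in got]
        assert fcs == sorted(fcs, reverse=True)

    def test_monotone_in_each_threshold(self, sc_pair):
        """Tightening any single threshold never grows the selected set."""
        m, ann, _, _, _ = sc_pair
        stats = ms.compute_marker_stats(m, ann)
        grid = PUBLISHED_GRID
        sel = {
            t: set(ms.apply_thresholds(stats, t)) for t in ms.enumerate_grid(grid)
        }
        for t in sel:
            for u in sel:
                tighter = (
                    u.min_fold_change >= t.min_fold_change
                    and u.max_global_detection <= t.max_global_detection
                    and u.max_cluster_detection <= t.max_cluster_detection
                )
                if tighter:
                    assert sel[u] <= sel[t]


class TestEnumerateGrid:
    def test_published_grid_has_27_points(self):
        assert len(ms.enumerate_grid(PUBLISHED_GRID)) == 27

    def test_singletons_give_one(self):
        g = ms.SelectionGrid((1.5,), (0.1,), (0.3,))
        assert len(ms.enumerate_grid(g)) == 1

    def test_product_rule(self):
        g = ms.SelectionGrid((1.5, 2.0), (0.05, 0.1, 0.15), (0.3,))
        pts = ms.enumerate_grid(g)
        assert len(pts) == 6
        # fold change outermost, cluster detection innermost
        assert [p.min_fold_change for p in pts[:3]] == [1.5] * 3

    def test_deterministic_order(self):
        assert ms.enumerate_grid(PUBLISHED_GRID) == ms.enumerate_grid(PUBLISHED_GRID)


def _validation_matrix():
    """20 observations; genes a/b perfectly mark the first 8, gene c is noise."""
    rng = np.random.default_rng(0)
    n = 20
    labels = np.array([True] * 8 + [False] * 12)
    vals = rng.poisson(2.0, size=(6, n))
    vals[0, labels] += 30  # ga
    vals[1, labels] += 30  # gb
    vals[2, ~labels] += 30  # gc anti-marker
    df = pd.DataFrame(vals, index=["ga", "gb", "gc", "gd", "ge", "gf"],
                      columns=[f"v{i}" for i in range(n)])
    return ms.CountMatrix(df), labels


class TestSelectSignature:
    def test_highest_auc_wins(self):
        vm, labels = _validation_matrix()
        t = PUBLISHED_THRESHOLDS
        good = CandidateResult(t, ("ga", "gb"), True)
        bad = CandidateResult(t, ("gc", "gd"), True)
        sig, evaluated = ms.select_signature([bad, good], vm, labels, min_size=2)
        assert sig.genes == ("ga", "gb")
        aucs = {c.genes: c.validation_auc for c in evaluated}
        assert aucs[("ga", "gb")] > aucs[("gc", "gd")]

    def test_min_size_overrides_auc(self):
        vm, labels = _validation_matrix()
        t = PUBLISHED_THRESHOLDS
        small_sharp = CandidateResult(t, ("ga",), True)           # size 1, would win on AUC
        big = CandidateResult(t, ("gb", "gd", "ge", "gf"), True)  # size 4
        sig, _ = ms.select_signature([small_sharp, big], vm, labels, min_size=2)
        assert sig.genes == ("gb", "gd", "ge", "gf")

    def test_tie_broken_by_smaller_then_lexicographic(self):
        vm, labels = _validation_matrix()
        t = PUBLISHED_THRESHOLDS
        # ga and gb are identically constructed markers: equal AUC very likely
        a = CandidateResult(t, ("ga", "gb"), True)
        b = CandidateResult(t, ("gb", "ga", "gd"), True)
        sig, ev = ms.select_signature([b, a], vm, labels, min_size=2)
        by_genes = {c.genes: c.validation_auc for c in ev}
        if by_genes[("ga", "gb")] == by_genes[("gb", "ga", "gd")]:
            assert sig.genes == ("ga", "gb")  # smaller set wins the tie

    def test_permutation_invariant(self):
        vm, labels = _validation_matrix()
        t = PUBLISHED_THRESHOLDS
        cands = [
            CandidateResult(t, g, True)
            for g in [("ga", "gb"), ("gc", "gd"), ("ga", "gd"), ("gb", "ge")]
        ]
        picks = set()
        for perm in itertools.permutations(cands):
            sig, _ = ms.select_signature(list(perm), vm, labels, min_size=2)
            picks.add(sig.genes)
        assert len(picks) == 1

    def test_no_candidate_passing_min_size_is_an_error(self):
        vm, labels = _validation_matrix()
        t = PUBLISHED_THRESHOLDS
        with pytest.raises(ValueError, match="relax"):
            ms.select_signature([CandidateResult(t, ("ga",), False)], vm, labels, min_size=10)

    def test_provenance_records_winning_thresholds(self):
        vm, labels = _validation_matrix()
        t = ms.SelectionThresholds(1.75, 0.05, 0.2)
        sig, _ = ms.select_signature([CandidateResult(t, ("ga", "gb"), True)], vm, labels, min_size=2)
        assert sig.provenance["min_fold_change"] == 1.75
        assert sig.provenance["max_global_detection"] == 0.05


class TestDerivationModel:
    def test_planted_markers_recovered_without_false_positives(self, sc_pair):
        m, ann, truth, vm, vann = sc_pair
        model = ms.SignatureDerivation(m, ann)
        res = model.fit(vm, vann.target_mask(), name="satellite_synth")
        planted = set(truth["cluster_0"])
        got = set(res.signature.genes)
        assert got == planted
        assert res.signature.provenance["validation_auc"] > 0.99

    def test_candidates_frame_covers_grid(self, sc_pair):
        m, ann, truth, vm, vann = sc_pair
        res = ms.SignatureDerivation(m, ann).fit(vm, vann.target_mask())
        df = res.candidates_frame()
        assert len(df) == 27
        assert "Selected signature" in res.summary()

    def test_fixed_thresholds_mode_skips_grid(self, sc_pair):
        m, ann, truth, vm, vann = sc_pair
        model = ms.SignatureDerivation(m, ann, thresholds=PUBLISHED_THRESHOLDS)
        cands = model.candidates()
        assert len(cands) == 1
        assert cands[0].thresholds == PUBLISHED_THRESHOLDS
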