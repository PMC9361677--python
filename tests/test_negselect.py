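import warnings

import numpy as np
import pytest

from dtibalance import negselect, synthdata
from dtibalance.descriptors import PairFeatureMatrix, _recipe_names
from dtibalance.io_formats import InteractionSet, Label
from dtibalance.negselect import (
    DistanceTable,
    OneClassModelSpec,
    build_balanced_set,
    fit_one_class,
    select_negatives,
    signed_distances,
)


def fs3(x, start=0):
    """Embed an (n, d<=50) matrix into an FS3-shaped pair feature matrix."""
    x = np.asarray(x, dtype=float)
    full = np.zeros((x.shape[0], 50))
    full[:, : x.shape[1]] = x
    keys = [(f"D{start + i:05d}", "P0") for i in range(x.shape[0])]
    return PairFeatureMatrix("FS3", keys, full, _recipe_names("FS3"))


class TestSpec:
    def test_nu_bounds(self):
        with pytest.raises(ValueError):
            OneClassModelSpec(nu=0.0)
        with pytest.raises(ValueError):
            OneClassModelSpec(nu=1.5)

    def test_non_rbf_rejected(self):
        with pytest.raises(ValueError):
            OneClassModelSpec(kernel="linear")


class TestFitOneClass:
    def test_nu_bounds_heldout_recall(self):
        # nu upper-bounds the training-outlier fraction; held-out positives
        # from the same cluster are recognized as inliers at ~1-nu.
        # Explicit smooth bandwidth; see the nu-contract acceptance test.
        rng = np.random.default_rng(0)
        x = fs3(rng.normal(0, 1, (200, 5)))
        fitted = fit_one_class(x, OneClassModelSpec(nu=0.01, gamma=0.01),
                               folds=10, seed=0)
        recalls = [d.recall for d in fitted.fold_diagnostics]
        assert np.mean(recalls) >= 1 - 0.01 - 0.05

    def test_nu_near_one_rejects_nearly_all(self):
        # libsvm cannot solve nu=1.0 exactly (non-finite duals); 0.999
        # exercises the same bound: nu upper-bounds the inlier fraction.
        rng = np.random.default_rng(1)
        x = fs3(rng.normal(0, 1, (100, 5)))
        fitted = fit_one_class(x, OneClassModelSpec(nu=0.999), folds=10, seed=0)
        assert np.mean([d.recall for d in fitted.fold_diagnostics]) <= 0.1

    def test_duplicated_row_all_inside(self):
        x = fs3(np.tile([1.0, 2.0, 3.0], (50, 1)))
        fitted = fit_one_class(x, OneClassModelSpec(nu=0.01), folds=10, seed=0)
        table = signed_distances(fitted, x)
        assert (table.distances >= 0).all()

    def test_too_few_rows(self):
        x = fs3(np.random.default_rng(0).normal(size=(5, 3)))
        with pytest.raises(ValueError, match="at least 10"):
            fit_one_class(x, folds=10)

    def test_non_finite_rejected(self):
        x = fs3(np.full((20, 3), np.nan))
        with pytest.raises(ValueError, match="non-finite"):
            fit_one_class(x)


class TestSignedDistances:
    @pytest.fixture()
    def fitted(self):
        rng = np.random.default_rng(2)
        return fit_one_class(fs3(rng.normal(0, 1, (150, 4))), seed=0)

    def test_centroid_is_inlier(self, fitted):
        table = signed_distances(fitted, fs3(np.zeros((1, 4))))
        assert table.distances[0] > 0

    def test_far_candidate_is_outlier(self, fitted):
        table = signed_distances(fitted, fs3(np.full((1, 4), 100.0)))
        assert table.distances[0] < 0

    def test_empty_candidates(self, fitted):
        table = signed_distances(fitted, fs3(np.empty((0, 4))))
        assert table.pair_keys == []
        assert table.distances.size == 0

    def test_width_mismatch(self, fitted):
        bad = PairFeatureMatrix(
            "FS4", [("D0", "P0")], np.zeros((1, 430)), _recipe_names("FS4")
        )
        with pytest.raises(ValueError, match="width"):
            signed_distances(fitted, bad)


def make_tables(dist_by_set, keys):
    return {
        fs: DistanceTable(fs, list(keys), np.asarray(d, dtype=float))
        for fs, d in dist_by_set.items()
    }


class TestSelectNegatives:
    def test_empty_intersection(self):
        keys = [("D1", "P1"), ("D2", "P2")]
        tables = make_tables(
            {
                "FS1": [-1, -2],
                "FS2": [0.5, 0.1],  # all inside here
                "FS3": [-1, -2],
                "FS4": [-1, -2],
            },
            keys,
        )
        with pytest.warns(UserWarning):
            sel = select_negatives(tables, k=1, consensus="ALL_SETS")
        assert sel.selected == []
        assert sel.shortfall

    def test_dominant_candidate_first(self):
        keys = [("D1", "P1"), ("D2", "P2"), ("D3", "P3")]
        tables = make_tables(
            {
                "FS1": [-1, -2, -9],
                "FS2": [-1, -3, -8],
                "FS3": [-2, -1, -7],
                "FS4": [-1, -1, -9],
            },
            keys,
        )
        sel = select_negatives(tables, k=1)
        assert sel.selected == [("D3", "P3")]

    def test_brute_force_resort_oracle(self):
        rng = np.random.default_rng(9)
        n = 500
        keys = [(f"D{i:04d}", f"P{i:04d}") for i in range(n)]
        raw = {fs: rng.normal(0, 1 + i, n) for i, fs in
               enumerate(["FS1", "FS2", "FS3", "FS4"])}
        sel = select_negatives(make_tables(raw, keys), k=40)

        # Independent re-sort: z-score per set, average, filter, sort.
        cols = []
        for fs in ["FS1", "FS2", "FS3", "FS4"]:
            d = raw[fs]
            cols.append((d - d.mean()) / d.std())
        combined = np.mean(cols, axis=0)
        qualifies = np.all([raw[fs] < 0 for fs in raw], axis=0)
        expected = sorted(
            (i for i in range(n) if qualifies[i]),
            key=lambda i: (combined[i], keys[i]),
        )[:40]
        assert sel.selected == [keys[i] for i in expected]

    def test_prefix_monotonicity(self):
        rng = np.random.default_rng(4)
        n = 200
        keys = [(f"D{i:04d}", "P0") for i in range(n)]
        raw = {fs: rng.normal(-0.5, 1, n) for fs in ["FS1", "FS2", "FS3", "FS4"]}
        small = select_negatives(make_tables(raw, keys), k=10)
        large = select_negatives(make_tables(raw, keys), k=25)
        assert large.selected[:10] == small.selected

    def test_inconsistent_coverage_errors(self):
        t1 = DistanceTable("FS1", [("D1", "P1")], np.array([-1.0]))
        t2 = DistanceTable("FS2", [("D2", "P2")], np.array([-1.0]))
        with pytest.raises(ValueError, match="coverage"):
            select_negatives([t1, t2], k=1)

    def test_consensus_any_set(self):
        keys = [("D1", "P1"), ("D2", "P2")]
        tables = make_tables(
            {"FS1": [-1, 1], "FS2": [1, 1], "FS3": [1, 1], "FS4": [1, 1]}, keys
        )
        sel = select_negatives(tables, k=2, consensus="ANY_SET")
        assert sel.selected == [("D1", "P1")]

    def test_pair_order_alignment(self):
        # Same distances, different row order across tables: result invariant.
        keys = [("D1", "P1"), ("D2", "P2"), ("D3", "P3")]
        d = {"FS1": [-3, -1, -2], "FS2": [-3, -1, -2],
             "FS3": [-3, -1, -2], "FS4": [-3, -1, -2]}
        tables = make_tables(d, keys)
        shuffled = dict(tables)
        shuffled["FS2"] = DistanceTable(
            "FS2", [keys[2], keys[0], keys[1]], np.array([-2.0, -3.0, -1.0])
        )
        a = select_negatives(tables, k=3).selected
        b = select_negatives(shuffled, k=3).selected
        assert a == b == [("D1", "P1"), ("D3", "P3"), ("D2", "P2")]

    def test_recovery_of_planted_negatives(self):
        # PU-style recovery: ~100 planted negatives among ~1000 unknowns.
        cfg = synthdata.SynthConfig(
            n_drugs=33, n_proteins=33, positive_rate=0.05,
            negative_cluster_shift=3.0, seed=12, n_true_negatives=100,
        )
        data = synthdata.generate(cfg)
        pos_keys = data.positives.keys()
        unk_keys = data.interactions.with_label(Label.UNKNOWN)
        tables = {}
        for fs in negselect.FEATURE_SET_IDS:
            pm = synthdata.subset_features(data.features[fs], pos_keys)
            um = synthdata.subset_features(data.features[fs], unk_keys)
            fitted = fit_one_class(pm, OneClassModelSpec(nu=0.01), seed=12)
            tables[fs] = signed_distances(fitted, um)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = select_negatives(tables, k=100)
        planted = data.truth_pairs(synthdata.TRUTH_NEGATIVE)
        recovered = len(set(sel.selected) & planted)
        assert recovered >= 90

    def test_selected_subset_of_candidates(self):
        rng = np.random.default_rng(8)
        n = 100
        keys = [(f"D{i:03d}", "P0") for i in range(n)]
        raw = {fs: rng.normal(-1, 1, n) for fs in ["FS1", "FS2", "FS3", "FS4"]}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = select_negatives(make_tables(raw, keys), k=n)
        assert set(sel.selected) <= set(keys)


class TestBuildBalancedSet:
    def _selection(self, keys):
        return negselect.NegativeSelection(
            selected=list(keys),
            per_set_distance=np.zeros((len(keys), 4)),
            combined_score=np.zeros(len(keys)),
            k_requested=len(keys),
        )

    def test_balanced(self):
        pos = InteractionSet(
            [(f"D{i}", "P0", Label.POSITIVE) for i in range(50)]
        )
        sel = self._selection([(f"D{i}", "P1") for i in range(50)])
        labeled = build_balanced_set(pos, sel)
        assert len(labeled) == 100
        assert labeled.count(Label.POSITIVE) == labeled.count(
            Label.PREDICTED_NEGATIVE
        ) == 50

    def test_shortfall_warns(self):
        pos = InteractionSet(
            [(f"D{i}", "P0", Label.POSITIVE) for i in range(50)]
        )
        sel = self._selection([(f"D{i}", "P1") for i in range(30)])
        with pytest.warns(UserWarning, match="unbalanced"):
            labeled = build_balanced_set(pos, sel)
        assert len(labeled) == 80

    def test_overlap_errors(self):
        pos = InteractionSet([("D1", "P1", Label.POSITIVE)])
        sel = self._selection([("D1", "P1")])
        with pytest.raises(ValueError, match="overlap"):
            build_balanced_set(pos, sel)
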