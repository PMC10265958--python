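"""Grouping scheme, node training, tandem assembly, prediction and bundles."""

import numpy as np
import pandas as pd
import pytest

import woundage as wa
from woundage.peaktable import PeakTable
from woundage.tandem import (
    GroupScheme,
    LearnerSpec,
    PassthroughNode,
    build_tandem,
    default_scheme,
    default_specs,
    flat_baseline,
    load_bundle,
    predict,
    save_bundle,
    split_train_val,
    train_node,
)


class TestGroupScheme:
    def test_default_scheme_yields_seven_leaves(self, scheme):
        assert len(scheme.leaves) == 7
        assert scheme.leaves == ("4", "8", "12", "16-20", "24-32", "36-40", "44-48")
        assert scheme.groups == ("I", "II", "III")

    def test_label_routing_helpers(self, scheme):
        assert scheme.coarse_of(28) == "II"
        assert scheme.leaf_of("28") == "24-32"
        assert scheme.labels_of_group("I") == ("4", "8", "12")
        with pytest.raises(KeyError):
            scheme.coarse_of("99")

    def test_leaves_partition_coarse_groups(self, scheme):
        all_members = [m for leaf in scheme.leaves for m in scheme.leaf_members[leaf]]
        assert sorted(all_members) == sorted(scheme.coarse)

    def test_inconsistent_scheme_rejected(self):
        with pytest.raises(ValueError):
            GroupScheme(
                coarse={"4": "I", "8": "I"},
                fine={"I": ("4", "8")},
                leaf_members={"4": ("4",), "8": ("8", "4")},  # 4 in two leaves
            )

    def test_round_trips_through_dict(self, scheme):
        assert GroupScheme.from_dict(scheme.to_dict()) == scheme


class TestLearnerSpec:
    def test_study_hyperparameters_are_wired_in(self):
        params = {spec.kind: spec.build().get_params() for spec in default_specs(0)}
        assert params["LR"]["solver"] == "lbfgs"
        assert params["SVM"]["C"] == 1.5
        assert params["RF"]["n_estimators"] == 128
        mlp = params["MLP"]
        assert mlp["hidden_layer_sizes"] == (32, 32)
        assert mlp["solver"] == "adam"
        assert mlp["learning_rate"] == "adaptive"
        assert mlp["max_iter"] == 3000

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            LearnerSpec(kind="XGB")


def _toy_node_table(seed=0, n=20, sep=8.0):
    """Two linearly separable classes in a 4-feature log-area table."""
    rng = np.random.default_rng(seed)
    low = rng.normal(0.0, 0.3, (n, 4))
    high = rng.normal(0.0, 0.3, (n, 4)) + np.array([sep, sep, -sep, 0.0])
    rows = np.exp(np.vstack([low, high]) + 10.0)
    index = [f"s{i}" for i in range(2 * n)]
    areas = pd.DataFrame(rows, index=index, columns=list("abcd"))
    meta = pd.DataFrame({"label": ["4"] * n + ["8"] * n, "role": "study"}, index=index)
    return PeakTable(areas, meta)


class TestSplitTrainVal:
    def test_stratified_counts_within_one_sample(self, small_study):
        train, val = split_train_val(small_study, frac=0.7, seed=0)
        for label, count in train.meta["label"].value_counts().items():
            assert count in (6, 7)  # 9 per class, frac 0.7
        assert train.n_samples + val.n_samples == small_study.n_samples
        assert not set(train.sample_ids) & set(val.sample_ids)

    def test_full_fraction_rejected(self, small_study):
        with pytest.raises(ValueError):
            split_train_val(small_study, frac=1.0)

    def test_same_seed_reproduces_the_split(self, small_study):
        t1, v1 = split_train_val(small_study, seed=5)
        t2, v2 = split_train_val(small_study, seed=5)
        assert t1.sample_ids == t2.sample_ids
        assert v1.sample_ids == v2.sample_ids

    def test_single_sample_class_rejected(self):
        table = _toy_node_table(n=2)
        lone = table.subset_samples(table.sample_ids[1:])
        with pytest.raises(ValueError, match="single sample"):
            split_train_val(lone, frac=0.5)


class TestTrainNode:
    def test_separable_toy_reaches_perfect_accuracy_and_mlp_wins_ties(self):
        table = _toy_node_table()
        train, val = split_train_val(table, frac=0.7, seed=1)
        node = train_node(train, val, class_of=lambda l: l, name="toy")
        assert set(node.candidate_accuracies) == {"LR", "SVM", "RF", "MLP"}
        assert all(acc == 1.0 for acc in node.candidate_accuracies.values())
        assert node.spec.kind == "MLP"  # tie broken toward the deeper model

    def test_accuracies_lie_in_unit_interval(self, fitted_tandem):
        for node in [fitted_tandem.level1, *fitted_tandem.level2.values()]:
            if isinstance(node, PassthroughNode):
                continue
            assert all(0.0 <= a <= 1.0 for a in node.candidate_accuracies.values())
            assert set(node.candidate_accuracies) == {"LR", "SVM", "RF", "MLP"}

    def test_single_training_class_rejected(self):
        table = _toy_node_table()
        train, val = split_train_val(table, frac=0.7, seed=1)
        with pytest.raises(ValueError, match="single class"):
            train_node(train, val, class_of=lambda l: "same", name="bad")


class TestBuildTandem:
    def test_default_scheme_gives_seven_leaf_tandem(self, fitted_tandem):
        assert len(fitted_tandem.leaves) == 7
        assert set(fitted_tandem.level2) == {"I", "II", "III"}

    def test_single_coarse_group_degenerates_to_level2_node(self, small_study):
        labels = [str(t) for t in range(4, 13, 4)]
        scheme = GroupScheme(
            coarse={l: "only" for l in labels},
            fine={"only": ("4", "8", "12")},
            leaf_members={l: (l,) for l in labels},
        )
        study = small_study.subset_labels(labels + ["control"])
        tandem = build_tandem(study, scheme, seed=0)
        preds, routes = predict(tandem, study.subset_labels(labels))
        assert {r.coarse for r in routes} == {"only"}
        assert set(preds) <= {"4", "8", "12"}

    def test_passthrough_node_for_single_leaf_group(self, small_study):
        scheme = GroupScheme(
            coarse={"4": "A", "8": "A", "12": "B"},
            fine={"A": ("4", "8"), "B": ("12",)},
            leaf_members={"4": ("4",), "8": ("8",), "12": ("12",)},
        )
        study = small_study.subset_labels(["4", "8", "12", "control"])
        tandem = build_tandem(study, scheme, seed=3)
        assert isinstance(tandem.level2["B"], PassthroughNode)
        preds, routes = predict(tandem, study.subset_labels(["12"]))
        for r in routes:
            assert r.leaf in scheme.fine[r.coarse]

    def test_same_seed_builds_identical_tandem(self, small_study, scheme):
        contused = small_study.subset_labels(set(scheme.coarse))
        t1 = build_tandem(small_study, scheme, seed=7)
        t2 = build_tandem(small_study, scheme, seed=7)
        p1, _ = predict(t1, contused)
        p2, _ = predict(t2, contused)
        assert p1 == p2
        assert t1.panels.union == t2.panels.union
        assert t1.level1.spec.kind == t2.level1.spec.kind


class TestPredict:
    def test_routing_consistency_on_training_samples(self, fitted_tandem, small_study):
        contused = small_study.subset_labels(set(fitted_tandem.scheme.coarse))
        preds, routes = predict(fitted_tandem, contused)
        assert len(preds) == contused.n_samples
        for record in routes:
            assert record.leaf in fitted_tandem.scheme.fine[record.coarse]

    def test_noise_free_group_mean_sample_recovers_its_leaf(
        self, fitted_tandem, small_config
    ):
        from woundage.simdata import feature_names, _background_baselines, _log_means_for_label

        names = feature_names(small_config)
        bg = _background_baselines(small_config)
        for label in ("8", "28", "44"):
            mu = _log_means_for_label(label, small_config, bg)
            areas = pd.DataFrame([np.exp(mu)], index=["probe"], columns=names)
            meta = pd.DataFrame({"label": ["unknown"], "role": ["external"]}, index=["probe"])
            preds, _ = predict(fitted_tandem, PeakTable(areas, meta))
            assert preds == [fitted_tandem.scheme.leaf_of(label)]

    def test_empty_sample_set_gives_empty_output(self, fitted_tandem, small_study):
        empty = small_study.subset_samples([])
        preds, routes = predict(fitted_tandem, empty)
        assert preds == [] and routes == []

    def test_missing_panel_feature_error_names_it(self, fitted_tandem, small_study):
        reduced = small_study.subset_features(small_study.feature_ids[5:])
        contused = reduced.subset_labels(set(fitted_tandem.scheme.coarse))
        with pytest.raises(KeyError):
            predict(fitted_tandem, contused)


class TestFlatBaseline:
    def test_flat_models_share_tandem_split_and_panel(self, small_study, scheme):
        panels = wa.assemble_panels(small_study, scheme)
        flats = flat_baseline(small_study, seed=4, scheme=scheme, panels=panels)
        assert set(flats) == {"LR", "SVM", "RF", "MLP"}
        for kind, model in flats.items():
            assert model.node.panel == panels.union
        rerun = flat_baseline(small_study, seed=4, scheme=scheme, panels=panels)
        for kind in flats:
            assert (
                flats[kind].node.candidate_accuracies
                == rerun[kind].node.candidate_accuracies
            )


class TestBundle:
    def test_save_load_round_trip_preserves_predictions(
        self, fitted_tandem, small_study, tmp_path
    ):
        contused = small_study.subset_labels(set(fitted_tandem.scheme.coarse))
        before, _ = predict(fitted_tandem, contused)
        save_bundle(fitted_tandem, tmp_path / "bundle")
        loaded = load_bundle(tmp_path / "bundle")
        after, _ = predict(loaded, contused)
        assert before == after
        assert loaded.scheme == fitted_tandem.scheme
        assert loaded.panels.union == fitted_tandem.panels.union
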