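"""Grouped splitting, evaluation reports, and the Model/Results surface."""

import numpy as np
import pytest

import anurapam as ap
from anurapam.classify import (CnnArchitecture, build_model, encode_labels,
                               export_model, load_model)


class TestSplit:
    def test_one_in_five_origins_per_class(self, tiny_aug_manifest):
        train, test = ap.split_dataset(tiny_aug_manifest)
        # 5 origins per class -> exactly 1 origin (11 clips) per class in test
        test_origins = test.df[test.df.variant_tag == "original"]
        assert test_origins.groupby("label").size().eq(1).all()
        assert len(test) == 5 * 11
        assert len(train) + len(test) == len(tiny_aug_manifest)

    def test_no_origin_leakage(self, tiny_aug_manifest):
        train, test = ap.split_dataset(tiny_aug_manifest)
        assert not set(train.df.origin_id) & set(test.df.origin_id)

    def test_fraction_within_contract(self):
        counts = {"ec_standard": 30, "ec_chorus": 10, "ec_amplexus": 10,
                  "ao_standard": 40, "ao_distress": 5}
        m = ap.augment_dataset(ap.generate_dataset(counts, seed=0),
                               ap.AugmentationPlan())
        train, test = ap.split_dataset(m)
        frac = len(test) / len(m)
        assert 0.18 <= frac <= 0.22

    def test_deterministic(self, tiny_aug_manifest):
        t1 = ap.split_dataset(tiny_aug_manifest)[1]
        t2 = ap.split_dataset(tiny_aug_manifest)[1]
        assert t1.df.equals(t2.df)

    def test_incomplete_origin_rejected(self, tiny_aug_manifest):
        broken = ap.DatasetManifest(tiny_aug_manifest.df.iloc[:-1].copy())
        with pytest.raises(ValueError, match="11"):
            ap.split_dataset(broken)


class TestLabels:
    def test_merged_encoding_collapses_advertisement_classes(self):
        labels = ["ec_standard", "ec_chorus", "ao_distress"]
        y, names = encode_labels(labels, "merged")
        assert names == ap.MERGED_CLASS_NAMES
        assert y[0] == y[1] != y[2]

    def test_fine_encoding(self):
        y, names = encode_labels(list(ap.CLASS_NAMES), "fine")
        assert list(y) == [0, 1, 2, 3, 4]

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError):
            encode_labels([], "coarse")


class TestEvalReport:
    # held-out confusion matrix of the merged 4-class problem on the real
    # corpus; a useful worked example because it is self-consistent
    REF_4CLASS = [[775, 28, 0, 0],
                  [7, 136, 0, 0],
                  [11, 0, 902, 0],
                  [1, 0, 0, 43]]

    def test_overall_accuracy_is_trace_over_total(self):
        rep = ap.EvalReport.from_counts(self.REF_4CLASS,
                                        ap.MERGED_CLASS_NAMES)
        assert rep.total == 1903
        assert rep.accuracy_percent() == 97.53

    def test_per_class_error_rates(self):
        rep = ap.EvalReport.from_counts(self.REF_4CLASS,
                                        ap.MERGED_CLASS_NAMES)
        # 13 errors out of 143 amplexus clips -> 9.09 %
        counts5 = [[560, 6, 28, 0, 0], [10, 199, 0, 0, 0],
                   [13, 0, 130, 0, 0], [11, 0, 0, 902, 0],
                   [1, 0, 0, 0, 43]]
        rep5 = ap.EvalReport.from_counts(counts5, ap.CLASS_NAMES)
        assert rep5.per_class_error[2] == 9.09
        assert rep.per_class_error[1] == 4.90

    def test_perfect_predictor(self):
        rep = ap.EvalReport.from_counts(np.diag([5, 5, 5, 5]),
                                        ap.MERGED_CLASS_NAMES)
        assert rep.overall_accuracy == 1.0
        assert np.all(rep.per_class_error == 0.0)

    def test_row_percentages_normalize_rows(self):
        rep = ap.EvalReport.from_counts(self.REF_4CLASS,
                                        ap.MERGED_CLASS_NAMES)
        assert np.allclose(rep.row_percentages.sum(axis=1), 100.0, atol=0.02)
        assert rep.row_percentages[0, 0] == 96.51

    def test_merging_conserves_total(self):
        counts5 = [[560, 6, 28, 0, 0], [10, 199, 0, 0, 0],
                   [13, 0, 130, 0, 0], [11, 0, 0, 902, 0],
                   [1, 0, 0, 0, 43]]
        rep5 = ap.EvalReport.from_counts(counts5, ap.CLASS_NAMES)
        rep4 = rep5.merged(ap.calls.MERGED_LABEL, ap.MERGED_CLASS_NAMES)
        assert rep4.total == rep5.total
        # merged diagonal absorbs the standard<->chorus confusions
        assert rep4.counts[0, 0] == 560 + 6 + 10 + 199


class TestBuildModel:
    def test_output_class_count_guard(self):
        with pytest.raises(ValueError):
            build_model(CnnArchitecture(n_classes=3), (32, 54, 1))
        net = build_model(CnnArchitecture(n_classes=3), (32, 54, 1),
                          allow_any_k=True)
        assert net.n_classes == 3


@pytest.fixture(scope="module")
def fit_results(tiny_aug_manifest, tiny_features):
    clf = ap.CallClassifier(tiny_aug_manifest, task="fine", seed=0,
                            features=tiny_features)
    return clf.fit(epochs=3)


class TestModelSurface:
    def test_history_and_improvement(self, fit_results):
        h = fit_results.history
        assert len(h["loss"]) == 3
        assert h["accuracy"][-1] > h["accuracy"][0]

    def test_report_row_sums_match_test_sizes(self, fit_results):
        rep = fit_results.report
        assert rep.counts.sum() == fit_results.n_test == 55
        assert np.all(rep.counts.sum(axis=1) == 11)

    def test_summary_mentions_key_facts(self, fit_results):
        text = fit_results.summary()
        assert "Test accuracy" in text and "Confusion matrix" in text

    def test_merged_task_uses_four_classes(self, tiny_aug_manifest,
                                           tiny_features):
        clf = ap.CallClassifier(tiny_aug_manifest, task="merged", seed=0,
                                features=tiny_features)
        res = clf.fit(epochs=1)
        assert res.report.counts.shape == (4, 4)

    def test_refit_is_deterministic(self, tiny_aug_manifest, tiny_features,
                                    fit_results):
        clf = ap.CallClassifier(tiny_aug_manifest, task="fine", seed=0,
                                features=tiny_features)
        res = clf.fit(epochs=3)
        assert res.history["loss"] == fit_results.history["loss"]

    def test_export_roundtrip_and_size(self, fit_results, tmp_path):
        path, size = export_model(fit_results.net, tmp_path / "m")
        import os
        assert size == os.path.getsize(path) > 0
        loaded = load_model(path)
        x = np.random.default_rng(0).uniform(
            0, 1, (4, 32, 54, 1)).astype(np.float32)
        assert np.array_equal(loaded.predict(x), fit_results.net.predict(x))

    def test_predict_clip_returns_a_class_name(self, fit_results):
        clip = ap.generate_clip("ao_standard", seed=77)
        assert fit_results.predict_clip(clip) in ap.CLASS_NAMES
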