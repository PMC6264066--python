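"""Harness logic (LOO, temporal k-fold, sweep, transfer) with stub classifiers."""

import numpy as np
import pandas as pd
import pytest

from kinemap.cnn import ADHD, CONTROL
from kinemap.evaluation import (
    Cohort,
    CohortParticipant,
    GROUP_CONTROL,
    GROUP_MED,
    GROUP_NONMED,
    run_kfold4,
    run_loo,
    run_medicated_transfer,
    run_sweep_test,
)
from kinemap.imaging import ImageStack


def make_stack(pid, site, n_images, group, rng=None, marker=None):
    """A stack of synthetic images; `marker` stamps a class-identifying pixel."""
    pixels = np.zeros((n_images, 28, 28), dtype=np.uint8)
    pixels[:, 0, 0] = 1
    if marker is not None:
        pixels[:, marker, marker] = 1
    return ImageStack(
        pixels=pixels,
        center_index=np.arange(n_images) * 25 + 50,
        t_center=(np.arange(n_images) * 2.5 + 5.0),
        participant_id=pid,
        sensor_site=site,
        label=group,
    )


def make_cohort(n_pairs=3, n_images=60, n_med=0, marked=True):
    parts = []
    for k in range(n_pairs):
        for group, pid in ((GROUP_NONMED, f"a{k}"), (GROUP_CONTROL, f"c{k}")):
            marker = (5 if group == GROUP_NONMED else 20) if marked else None
            parts.append(CohortParticipant(
                participant_id=pid, group=group, pair_id=f"p{k}",
                snap_score=2.0 if group == GROUP_NONMED else 0.5,
                stacks={"wrist": make_stack(pid, "wrist", n_images, group, marker=marker)},
            ))
    for k in range(n_med):
        pid = f"m{k}"
        parts.append(CohortParticipant(
            participant_id=pid, group=GROUP_MED, pair_id=f"pm{k}", snap_score=2.0,
            stacks={"wrist": make_stack(pid, "wrist", n_images, GROUP_MED, marker=20)},
        ))
        parts.append(CohortParticipant(
            participant_id=f"cm{k}", group=GROUP_CONTROL, pair_id=f"pm{k}", snap_score=0.3,
            stacks={"wrist": make_stack(f"cm{k}", "wrist", n_images, GROUP_CONTROL,
                                        marker=20)},
        ))
    return Cohort(parts)


class OracleStub:
    """Reads the class marker pixel and reports it with high confidence."""

    def __init__(self, confidence=0.99):
        self.confidence = confidence
        self.seen_train = None

    def fit(self, images, labels):
        self.seen_train = (images.copy(), labels.copy())
        return self

    def predict_proba(self, images):
        p_adhd = np.where(images[:, 5, 5] == 1, self.confidence, 1 - self.confidence)
        return np.stack([p_adhd, 1 - p_adhd], axis=1)


class ConstantStub:
    """Indifferent classifier: p = (0.5, 0.5) for every image."""

    def fit(self, images, labels):
        return self

    def predict_proba(self, images):
        return np.full((len(images), 2), 0.5)


class RecordingFactory:
    """Wraps a stub class and records every training set it receives."""

    def __init__(self, stub_cls):
        self.stub_cls = stub_cls
        self.stubs = []

    def __call__(self, seed):
        stub = self.stub_cls()
        self.stubs.append(stub)
        return stub


class TestRunLoo:
    def test_oracle_stub_perfect_accuracy(self):
        cohort = make_cohort()
        report = run_loo(cohort, "wrist", lambda s: OracleStub(), seed=0)
        assert report.metrics.accuracy == 1.0
        assert len(report.predictions) == 6

    def test_constant_stub_all_control_by_tie_break(self):
        cohort = make_cohort()
        report = run_loo(cohort, "wrist", lambda s: ConstantStub(), seed=0)
        assert np.allclose(report.predictions["cl"], 0.0)
        assert (report.predictions["predicted"] == "control").all()
        assert report.metrics.sensitivity == 0.0
        assert report.metrics.specificity == 1.0

    def test_no_leakage_held_out_ids_absent_from_training(self):
        cohort = make_cohort()
        report = run_loo(cohort, "wrist", lambda s: OracleStub(), seed=0)
        for pid, train_ids in report.train_ids.items():
            assert pid not in train_ids
            assert len(train_ids) == 5

    def test_image_counts_preserved(self):
        cohort = make_cohort(n_images=45)
        report = run_loo(cohort, "wrist", lambda s: OracleStub(), seed=0)
        assert (report.predictions["n_images"] == 45).all()
        assert all(len(v) == 45 for v in report.image_labels.values())

    def test_too_few_participants_rejected(self):
        cohort = make_cohort(n_pairs=1)
        with pytest.raises(ValueError):
            run_loo(cohort, "wrist", lambda s: OracleStub(), seed=0)


class TestRunKfold4:
    def test_oracle_stub_perfect_in_every_fold(self):
        cohort = make_cohort(n_images=40)
        report = run_kfold4(cohort, "wrist", lambda s: OracleStub(), seed=0)
        assert report.metrics.accuracy == 1.0
        assert all(m.accuracy == 1.0 for m in report.fold_metrics)
        assert len(report.predictions) == 6 * 4

    def test_every_image_in_exactly_one_validation_fold(self):
        cohort = make_cohort(n_images=41)  # non-divisible: blocks of 11/10/10/10
        factory = RecordingFactory(OracleStub)
        report = run_kfold4(cohort, "wrist", factory, seed=0)
        # per fold, training images + validation images = all images
        n_total = 41 * 6
        for f, stub in enumerate(factory.stubs):
            n_train = len(stub.seen_train[0])
            n_val = int(report.predictions.query("fold == @f")["n_images"].sum())
            assert n_train + n_val == n_total
        assert int(report.predictions["n_images"].sum()) == n_total

    def test_blocks_are_consecutive_time_ranges(self):
        cohort = make_cohort(n_images=40)
        report = run_kfold4(cohort, "wrist", lambda s: OracleStub(), seed=0)
        assert report.schema == "kfold4"
        assert sorted(report.predictions["fold"].unique()) == [0, 1, 2, 3]

    def test_single_split_flag_one_fold_only(self):
        cohort = make_cohort(n_images=40)
        report = run_kfold4(cohort, "wrist", lambda s: OracleStub(), seed=0,
                            single_split=True)
        assert report.predictions["fold"].unique().tolist() == [3]
        assert len(report.predictions) == 6

    def test_session_too_short_rejected(self):
        cohort = make_cohort(n_images=3)
        with pytest.raises(ValueError):
            run_kfold4(cohort, "wrist", lambda s: OracleStub(), seed=0)


class TestRunSweepTest:
    def test_identical_label_sequences_p_one(self):
        labels = np.array((["ADHD"] * 7 + ["control"] * 13) * 3)
        image_labels = {pid: labels for pid in ("a0", "a1", "c0", "c1")}
        groups = {"a0": GROUP_NONMED, "a1": GROUP_NONMED,
                  "c0": GROUP_CONTROL, "c1": GROUP_CONTROL}
        table = run_sweep_test(image_labels, groups)
        assert (table["p_value"] == 1.0).all()

    def test_strong_group_difference_significant(self, rng):
        image_labels, groups = {}, {}
        for k in range(4):
            adhd_rate = rng.uniform(0.65, 0.75)
            ctrl_rate = rng.uniform(0.15, 0.25)
            image_labels[f"a{k}"] = np.where(rng.random(200) < adhd_rate, "ADHD", "control")
            image_labels[f"c{k}"] = np.where(rng.random(200) < ctrl_rate, "ADHD", "control")
            groups[f"a{k}"] = GROUP_NONMED
            groups[f"c{k}"] = GROUP_CONTROL
        table = run_sweep_test(image_labels, groups)
        assert (table.query("4 <= th <= 16")["p_value"] < 0.05).all()

    def test_p_vector_matches_independent_ttest(self, rng):
        from scipy import stats

        from kinemap.subject_inference import threshold_sweep

        image_labels, groups = {}, {}
        for k in range(3):
            image_labels[f"a{k}"] = rng.random(100) < 0.6
            image_labels[f"c{k}"] = rng.random(100) < 0.4
            groups[f"a{k}"] = GROUP_NONMED
            groups[f"c{k}"] = GROUP_CONTROL
        table = run_sweep_test(image_labels, groups)
        sweep = threshold_sweep(image_labels, n=20)
        for _, row in table.iterrows():
            th = int(row["th"])
            a = [sweep[f"a{k}"][th - 1] for k in range(3)]
            c = [sweep[f"c{k}"][th - 1] for k in range(3)]
            if np.var(a) == 0 and np.var(c) == 0:
                continue
            _, p = stats.ttest_ind(a, c)
            assert row["p_value"] == pytest.approx(p, abs=1e-12)

    def test_all_adhd_includes_medicated(self):
        labels_adhd = np.array(["ADHD"] * 40)
        labels_ctrl = np.array(["control"] * 40)
        image_labels = {"a0": labels_adhd, "a1": labels_adhd, "m0": labels_adhd,
                        "c0": labels_ctrl, "c1": labels_ctrl}
        groups = {"a0": GROUP_NONMED, "a1": GROUP_NONMED, "m0": GROUP_MED,
                  "c0": GROUP_CONTROL, "c1": GROUP_CONTROL}
        table = run_sweep_test(image_labels, groups, experiment_group="all_adhd")
        # perfect separation of 3 vs 2 -> p = 0 at every threshold
        assert (table["p_value"] == 0.0).all()


class TestMedicatedTransfer:
    def test_control_like_stub_classifies_all_control(self):
        cohort = make_cohort(n_pairs=2, n_med=2)
        # medicated stacks carry the control marker (20), which OracleStub
        # scores as control-like
        report = run_medicated_transfer(cohort, "wrist", lambda s: OracleStub(), seed=0)
        assert (report.predictions["predicted"] == "control").all()
        assert set(report.predictions["participant_id"]) == {"m0", "m1"}
        assert "snap_score" in report.predictions.columns

    def test_training_excludes_medicated(self):
        cohort = make_cohort(n_pairs=2, n_med=1)
        factory = RecordingFactory(OracleStub)
        run_medicated_transfer(cohort, "wrist", factory, seed=0)
        images, labels = factory.stubs[0].seen_train
        # 4 nonmed/control participants + 1 extra control pair-mate, 60 images each
        assert len(images) == 5 * 60
        assert set(np.unique(labels)) == {ADHD, CONTROL}

    def test_no_medicated_rejected(self):
        cohort = make_cohort(n_pairs=2)
        with pytest.raises(ValueError):
            run_medicated_transfer(cohort, "wrist", lambda s: OracleStub(), seed=0)


class TestCohortValidation:
    def test_pairing_must_be_bijection(self):
        parts = [
            CohortParticipant("a0", GROUP_NONMED, "p0", 2.0, {}),
            CohortParticipant("c0", GROUP_CONTROL, "p1", 0.5, {}),
        ]
        with pytest.raises(ValueError):
            Cohort(parts)

    def test_duplicate_ids_rejected(self):
        parts = [
            CohortParticipant("x", GROUP_NONMED, "p0", 2.0, {}),
            CohortParticipant("x", GROUP_CONTROL, "p0", 0.5, {}),
        ]
        with pytest.raises(ValueError):
            Cohort(parts)
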