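"""Cohort containers and the cross-validation / hypothesis-testing harnesses.

Four experiment schemas operate on per-participant acceleration-image stacks:

* ``run_loo`` — leave-one-participant-out: a fresh classifier per held-out
  child, trained on every other participant's images, so the evaluated child
  is never seen in training.
* ``run_kfold4`` — temporal cross-validation: each child's session is cut
  into 4 equal consecutive blocks; one block per child is held out per fold
  and the classifier trains on the remaining blocks of *all* children.  This
  bounds generalisation optimistically (every child contributes training
  data); a flag reproduces the single fixed consecutive train/validation
  split instead of rotating.
* ``run_sweep_test`` — the frame-count hypothesis test: per-image labels from
  the leave-one-out models feed a threshold sweep th = 1..20 and a two-sample
  t-test of the positive-frame fractions between groups.
* ``run_medicated_transfer`` — scores medicated participants with a model
  trained only on non-medicated ADHD and controls, to gauge how far
  medication shifts movement patterns toward the control class.

The classifier is injected as a factory ``seed -> object with
fit(images, labels) / predict_proba(images)`` so the harness logic is
testable with stub classifiers; :func:`cnn_factory` supplies the real CNN.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .cnn import ADHD, CLASSES, CONTROL, AccelCNN, ModelSpec, TrainConfig
from .imaging import ImageStack
from .subject_inference import (
    ConfusionMetrics,
    classify_subject,
    combined_likelihood,
    confusion_metrics,
    threshold_sweep,
    two_sample_ttest,
)

__all__ = [
    "GROUP_CONTROL",
    "GROUP_NONMED",
    "GROUP_MED",
    "CohortParticipant",
    "Cohort",
    "EvaluationReport",
    "CNNClassifier",
    "cnn_factory",
    "encode_cohort",
    "run_loo",
    "run_kfold4",
    "run_sweep_test",
    "run_medicated_transfer",
]

GROUP_CONTROL = "control"
GROUP_NONMED = "adhd_nonmed"
GROUP_MED = "adhd_med"
_GROUPS = (GROUP_CONTROL, GROUP_NONMED, GROUP_MED)


def is_adhd(group: str) -> bool:
    return group in (GROUP_NONMED, GROUP_MED)


@dataclass
class CohortParticipant:
    """One child: group membership, pairing, SNAP score and image stacks."""

    participant_id: str
    group: str
    pair_id: str
    snap_score: float
    stacks: dict[str, ImageStack] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in _GROUPS:
            raise ValueError(f"group must be one of {_GROUPS}, got {self.group!r}")


@dataclass
class Cohort:
    """A paired cohort of participants with encoded image stacks."""

    participants: list[CohortParticipant]

    def __post_init__(self) -> None:
        ids = [p.participant_id for p in self.participants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate participant ids")
        # pairing must be a bijection between ADHD and control members
        adhd_pairs = sorted(p.pair_id for p in self.participants if is_adhd(p.group))
        ctrl_pairs = sorted(p.pair_id for p in self.participants if not is_adhd(p.group))
        if adhd_pairs != ctrl_pairs:
            raise ValueError("pair ids do not form an ADHD/control bijection")

    def subset(self, groups: Iterable[str]) -> list[CohortParticipant]:
        groups = set(groups)
        return [p for p in self.participants if p.group in groups]

    def __iter__(self):
        return iter(self.participants)

    def __len__(self) -> int:
        return len(self.participants)


@dataclass
class EvaluationReport:
    """Outcome of one experiment harness run."""

    schema: str                      # loo | kfold4 | sweep | transfer
    predictions: pd.DataFrame
    metrics: ConfusionMetrics | None
    seed: int
    image_labels: dict[str, np.ndarray] = field(default_factory=dict)
    sweep_p_values: pd.DataFrame | None = None
    fold_metrics: list[ConfusionMetrics] | None = None
    train_ids: dict[str, list[str]] = field(default_factory=dict)
    config: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# classifier plumbing


class CNNClassifier:
    """The CNN behind the harness interface (fit / predict_proba)."""

    def __init__(self, spec: ModelSpec | None = None,
                 train_config: TrainConfig | None = None, seed: int = 0):
        self.model = AccelCNN(spec, seed)
        self.train_config = replace(train_config or TrainConfig(), seed=seed)

    def fit(self, images: np.ndarray, labels: np.ndarray) -> "CNNClassifier":
        self.model.fit(images, labels, self.train_config)
        return self

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(images)


def cnn_factory(spec: ModelSpec | None = None,
                train_config: TrainConfig | None = None) -> Callable[[int], CNNClassifier]:
    """Factory of seed-deterministic CNN classifiers for the harnesses."""

    def make(seed: int) -> CNNClassifier:
        return CNNClassifier(spec, train_config, seed)

    return make


def _child_seed(seed: int, index: int) -> int:
    """Deterministic per-model seed below 2**31 derived from the run seed."""
    return int(np.random.SeedSequence(entropy=[int(seed), int(index)]).generate_state(1)[0]
               % (2**31))


def _image_argmax_labels(probs: np.ndarray) -> np.ndarray:
    """Per-image hard labels; the exact tie p = (0.5, 0.5) goes to control."""
    return np.where(probs[:, ADHD] > probs[:, CONTROL], CLASSES[ADHD], CLASSES[CONTROL])


def _true_label(p: CohortParticipant) -> str:
    return CLASSES[ADHD] if is_adhd(p.group) else CLASSES[CONTROL]


def _train_arrays(parts: list[CohortParticipant], site: str,
                  exclude: set[str] | None = None) -> tuple[np.ndarray, np.ndarray, list[str]]:
    exclude = exclude or set()
    pix, lab, ids = [], [], []
    for p in parts:
        if p.participant_id in exclude:
            continue
        stack = p.stacks[site]
        if len(stack) == 0:
            continue
        pix.append(stack.pixels)
        lab.append(np.full(len(stack), ADHD if is_adhd(p.group) else CONTROL))
        ids.append(p.participant_id)
    if not pix:
        raise ValueError("no training images")
    return np.concatenate(pix), np.concatenate(lab), ids


# ---------------------------------------------------------------------------
# encoding


def encode_cohort(sim_cohort, config=None, interval=None,
                  sites: tuple[str, ...] | None = None) -> Cohort:
    """Encode raw simulated/loaded recordings into a :class:`Cohort` of stacks.

    ``sim_cohort`` needs a ``participants`` iterable whose items expose
    ``participant_id``/``group``/``pair_id``/``snap_score`` and a ``series``
    mapping site → :class:`~kinemap.signal_core.AccelSeries`.
    """
    from .imaging import session_to_images  # local import keeps module load light

    out = []
    for sp in sim_cohort.participants:
        use_sites = sites or tuple(sp.series.keys())
        stacks = {
            site: session_to_images(sp.series[site], config, interval, label=sp.group)
            for site in use_sites
        }
        out.append(CohortParticipant(
            participant_id=sp.participant_id,
            group=sp.group,
            pair_id=sp.pair_id,
            snap_score=sp.snap_score,
            stacks=stacks,
        ))
    return Cohort(out)


# ---------------------------------------------------------------------------
# harnesses


def run_loo(cohort: Cohort, site: str,
            factory: Callable[[int], object] | None = None,
            seed: int = 0,
            groups: tuple[str, ...] = (GROUP_NONMED, GROUP_CONTROL)) -> EvaluationReport:
    """Leave-one-participant-out evaluation on one sensor site.

    One classifier per held-out participant, trained on all other eligible
    participants' images (labels inherited from group membership).  The
    held-out child is scored by combined likelihood; per-image hard labels
    are kept for the threshold-sweep hypothesis test.
    """
    factory = factory or cnn_factory()
    eligible = cohort.subset(groups)
    n_adhd = sum(is_adhd(p.group) for p in eligible)
    n_ctrl = len(eligible) - n_adhd
    if n_adhd < 2 or n_ctrl < 2:
        raise ValueError("need at least 2 participants per class for leave-one-out")

    rows, image_labels, train_ids = [], {}, {}
    for k, held in enumerate(eligible):
        x, y, ids = _train_arrays(eligible, site, exclude={held.participant_id})
        if len(np.unique(y)) < 2:
            raise ValueError(f"training fold for {held.participant_id} lost a class")
        clf = factory(_child_seed(seed, k))
        clf.fit(x, y)
        probs = clf.predict_proba(held.stacks[site].pixels)
        cl = combined_likelihood(probs)
        rows.append({
            "participant_id": held.participant_id,
            "group": held.group,
            "true": _true_label(held),
            "n_images": len(probs),
            "cl": cl,
            "predicted": classify_subject(cl),
        })
        image_labels[held.participant_id] = _image_argmax_labels(probs)
        train_ids[held.participant_id] = ids

    pred = pd.DataFrame(rows)
    return EvaluationReport(
        schema="loo",
        predictions=pred,
        metrics=confusion_metrics(pred["true"], pred["predicted"]),
        seed=seed,
        image_labels=image_labels,
        train_ids=train_ids,
        config={"site": site, "groups": list(groups)},
    )


def run_kfold4(cohort: Cohort, site: str,
               factory: Callable[[int], object] | None = None,
               seed: int = 0,
               groups: tuple[str, ...] = (GROUP_NONMED, GROUP_CONTROL),
               n_folds: int = 4,
               single_split: bool = False) -> EvaluationReport:
    """Temporal cross-validation with consecutive within-session blocks.

    Each participant's image sequence is split into ``n_folds`` equal
    consecutive blocks (1.5 h out of 6 h at the defaults).  In fold f, block
    f of every participant is validation and all remaining blocks train one
    classifier; each participant receives a combined-likelihood decision per
    fold.  ``single_split=True`` evaluates only the last block (one fixed
    consecutive train/validation split).
    """
    factory = factory or cnn_factory()
    eligible = cohort.subset(groups)
    blocks: dict[str, list[np.ndarray]] = {}
    for p in eligible:
        k = len(p.stacks[site])
        if k < n_folds:
            raise ValueError(
                f"participant {p.participant_id} has {k} images; "
                f"cannot form {n_folds} consecutive blocks"
            )
        blocks[p.participant_id] = np.array_split(np.arange(k), n_folds)

    folds = [n_folds - 1] if single_split else list(range(n_folds))
    rows, fold_metrics = [], []
    for f in folds:
        pix, lab = [], []
        for p in eligible:
            train_idx = np.concatenate(
                [blocks[p.participant_id][g] for g in range(n_folds) if g != f]
            )
            pix.append(p.stacks[site].pixels[train_idx])
            lab.append(np.full(len(train_idx), ADHD if is_adhd(p.group) else CONTROL))
        clf = factory(_child_seed(seed, f))
        clf.fit(np.concatenate(pix), np.concatenate(lab))
        fold_rows = []
        for p in eligible:
            val_idx = blocks[p.participant_id][f]
            probs = clf.predict_proba(p.stacks[site].pixels[val_idx])
            cl = combined_likelihood(probs)
            fold_rows.append({
                "fold": f,
                "participant_id": p.participant_id,
                "group": p.group,
                "true": _true_label(p),
                "n_images": len(probs),
                "cl": cl,
                "predicted": classify_subject(cl),
            })
        fdf = pd.DataFrame(fold_rows)
        fold_metrics.append(confusion_metrics(fdf["true"], fdf["predicted"]))
        rows.extend(fold_rows)

    pred = pd.DataFrame(rows)
    return EvaluationReport(
        schema="kfold4",
        predictions=pred,
        metrics=confusion_metrics(pred["true"], pred["predicted"]),
        seed=seed,
        fold_metrics=fold_metrics,
        config={"site": site, "groups": list(groups), "n_folds": n_folds,
                "single_split": single_split},
    )


def run_sweep_test(image_labels: dict[str, np.ndarray],
                   participant_groups: dict[str, str],
                   experiment_group: str = "nonmed_only",
                   n: int = 20,
                   equal_var: bool = True) -> pd.DataFrame:
    """Threshold-sweep hypothesis test of frame-count positive fractions.

    For every threshold th = 1..n, the per-participant positive-frame
    fractions of the experiment group (non-medicated ADHD, or all ADHD) are
    compared with the controls' by a two-sample t-test.  Returns a table with
    columns ``th``, ``t`` and ``p_value``.
    """
    if experiment_group == "nonmed_only":
        exp_groups = {GROUP_NONMED}
    elif experiment_group == "all_adhd":
        exp_groups = {GROUP_NONMED, GROUP_MED}
    else:
        raise ValueError("experiment_group must be 'nonmed_only' or 'all_adhd'")

    exp_ids = [pid for pid, g in participant_groups.items()
               if g in exp_groups and pid in image_labels]
    ctrl_ids = [pid for pid, g in participant_groups.items()
                if g == GROUP_CONTROL and pid in image_labels]
    if len(exp_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError("need at least 2 labelled participants per group")

    sweep = threshold_sweep({pid: image_labels[pid] for pid in exp_ids + ctrl_ids}, n=n)
    exp = np.stack([sweep[pid] for pid in exp_ids])      # (n_exp, n)
    ctrl = np.stack([sweep[pid] for pid in ctrl_ids])
    rows = []
    for th in range(1, n + 1):
        a, b = exp[:, th - 1], ctrl[:, th - 1]
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() != b.mean():
            # perfectly separated groups: the t statistic diverges, p -> 0
            t, p = float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
        else:
            t, p = two_sample_ttest(a, b, equal_var=equal_var)
        rows.append({"th": th, "t": t, "p_value": p})
    return pd.DataFrame(rows)


def run_medicated_transfer(cohort: Cohort, site: str,
                           factory: Callable[[int], object] | None = None,
                           seed: int = 0) -> EvaluationReport:
    """Score medicated participants with a non-medicated + control model.

    One classifier is trained on all non-medicated ADHD and control images;
    each medicated child is then classified by combined likelihood, yielding
    a table of (participant, SNAP score, cl, classified-as).
    """
    factory = factory or cnn_factory()
    med = cohort.subset((GROUP_MED,))
    if not med:
        raise ValueError("cohort has no medicated participants")
    x, y, ids = _train_arrays(cohort.subset((GROUP_NONMED, GROUP_CONTROL)), site)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    clf = factory(_child_seed(seed, 0))
    clf.fit(x, y)

    rows, image_labels = [], {}
    for p in med:
        probs = clf.predict_proba(p.stacks[site].pixels)
        cl = combined_likelihood(probs)
        rows.append({
            "participant_id": p.participant_id,
            "snap_score": p.snap_score,
            "n_images": len(probs),
            "cl": cl,
            "predicted": classify_subject(cl),
        })
        image_labels[p.participant_id] = _image_argmax_labels(probs)

    pred = pd.DataFrame(rows)
    return EvaluationReport(
        schema="transfer",
        predictions=pred,
        metrics=None,
        seed=seed,
        image_labels=image_labels,
        train_ids={"_model": ids},
        config={"site": site},
    )
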