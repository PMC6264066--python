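"""Subject-level decision statistics built on per-image classifier outputs.

Two aggregation routes turn a stream of per-image outputs into one decision
per participant:

* **Frame counting** — the image stream is cut into disjoint runs ("frames")
  of n = 20 consecutive images (52.5 s of data); a frame is *positive* when at
  least ``th`` of its images were classified ADHD-like.  Sweeping th = 1..n
  and comparing the per-participant positive fractions between groups with a
  two-sample t-test gives a hypothesis test of group movement differences.

* **Combined likelihood** — ``cl = Σ_j (p_j(ADHD) − p_j(control))`` summed
  over all of a participant's images.  Since the two probabilities are
  complementary this equals ``2·Σ_j p_j(ADHD) − J``.  A participant is
  classified ADHD when cl exceeds 0; the exact tie cl = 0 goes to control, the
  conservative choice for a screening statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cnn import ADHD, CONTROL, CLASSES

__all__ = [
    "FrameConfig",
    "FrameResult",
    "SubjectScore",
    "ConfusionMetrics",
    "frame_positives",
    "threshold_sweep",
    "two_sample_ttest",
    "combined_likelihood",
    "classify_subject",
    "confusion_metrics",
]


@dataclass(frozen=True)
class FrameConfig:
    """Frame size ``n`` and decision threshold ``th`` (1 ≤ th ≤ n)."""

    n: int = 20
    th: int = 10

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("frame size n must be >= 1")
        if not 1 <= self.th <= self.n:
            raise ValueError(f"threshold must satisfy 1 <= th <= {self.n}")


@dataclass(frozen=True)
class FrameResult:
    """Outcome for one frame: ADHD-image count ``m`` and positivity ``m >= th``."""

    m: int
    positive: bool


@dataclass
class SubjectScore:
    """Aggregated decision statistics for one participant."""

    participant_id: str
    cl: float
    predicted: str
    n_images: int
    per_th_positive_fraction: np.ndarray | None = None


@dataclass(frozen=True)
class ConfusionMetrics:
    """Counts and proportions of a two-class confusion matrix (ADHD positive)."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def _as_adhd_indicator(image_labels) -> np.ndarray:
    """Coerce a label sequence ({'ADHD','control'}, class indices or bools)."""
    labels = np.asarray(image_labels)
    if labels.dtype.kind in "UO":
        known = set(CLASSES)
        bad = set(np.unique(labels)) - known
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}; expected {CLASSES}")
        return labels == CLASSES[ADHD]
    if labels.dtype.kind == "b":
        return labels
    return np.asarray(labels) == ADHD


def frame_positives(image_labels, config: FrameConfig) -> tuple[list[FrameResult], float]:
    """Cut an image-label sequence into disjoint frames and score each.

    Frames are consecutive, non-overlapping runs of ``config.n`` images; a
    trailing remainder shorter than ``n`` is dropped.  Returns the per-frame
    results and the fraction of positive frames.
    """
    ind = _as_adhd_indicator(image_labels)
    if len(ind) < config.n:
        raise ValueError(f"need at least n={config.n} images, got {len(ind)}")
    n_frames = len(ind) // config.n
    counts = ind[: n_frames * config.n].reshape(n_frames, config.n).sum(axis=1)
    results = [FrameResult(int(m), bool(m >= config.th)) for m in counts]
    fraction = float(np.mean([r.positive for r in results]))
    return results, fraction


def threshold_sweep(label_sequences: dict, n: int = 20) -> dict[str, np.ndarray]:
    """Positive-frame fraction per participant for every threshold th = 1..n.

    ``label_sequences`` maps participant id → per-image label sequence.  Each
    returned vector is monotonically non-increasing in th: raising the
    threshold can only demote frames.
    """
    out: dict[str, np.ndarray] = {}
    for pid, labels in label_sequences.items():
        ind = _as_adhd_indicator(labels)
        if len(ind) < n:
            raise ValueError(f"participant {pid!r} has fewer than n={n} images")
        n_frames = len(ind) // n
        counts = ind[: n_frames * n].reshape(n_frames, n).sum(axis=1)
        ths = np.arange(1, n + 1)
        out[pid] = (counts[:, None] >= ths[None, :]).mean(axis=0)
    return out


def two_sample_ttest(group_a, group_b, *, equal_var: bool = True) -> tuple[float, float]:
    """Two-sample t-test of group means; pooled-variance by default.

    ``equal_var=False`` selects the Welch variant.  Two degenerate cases are
    distinguished: if both groups have zero variance *and* equal means the
    samples are literally identical and the test returns ``(0.0, 1.0)``;
    zero variance with a mean difference leaves the statistic undefined and
    raises.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("degenerate zero-variance groups with different means")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def combined_likelihood(probs) -> float:
    """Combined likelihood ``cl = Σ_j (p_j(ADHD) − p_j(control))``.

    Accepts an (J, 2) array of class probabilities in the fixed (ADHD,
    control) order, or a 1-D array of p(ADHD) values (complement implied).
    Bounded in [−J, J]; positive values are ADHD-like.
    """
    p = np.asarray(probs, dtype=np.float64)
    if p.size == 0:
        raise ValueError("combined likelihood of an empty probability sequence")
    if p.ndim == 1:
        p_adhd = p
    elif p.ndim == 2 and p.shape[1] == 2:
        p_adhd = p[:, ADHD]
    else:
        raise ValueError(f"expected (J,) or (J, 2) probabilities, got {p.shape}")
    if np.any(p_adhd < 0) or np.any(p_adhd > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.sum(2.0 * p_adhd - 1.0))


def classify_subject(cl: float, threshold: float = 0.0) -> str:
    """ADHD iff cl strictly exceeds the threshold; ties go to control."""
    if not np.isfinite(cl):
        raise ValueError("combined likelihood must be finite")
    return CLASSES[ADHD] if cl > threshold else CLASSES[CONTROL]


def confusion_metrics(true_labels, predicted_labels) -> ConfusionMetrics:
    """Confusion counts and accuracy/sensitivity/specificity, ADHD positive."""
    t = _as_adhd_indicator(true_labels)
    p = _as_adhd_indicator(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label sequences differ in length")
    return ConfusionMetrics(
        tp=int(np.sum(t & p)),
        fn=int(np.sum(t & ~p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
    )
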