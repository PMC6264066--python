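"""Published per-participant validation outcomes of the originating study.

The method was originally validated on a cohort of 22 school-aged children
(11 with ADHD — 5 non-medicated, 6 medicated — and 11 paired controls), with
wrist and ankle recordings evaluated separately.  The study released its
subject-level "classified as" outcome tables but not the raw recordings, so
these tables are the only ground truth available for checking the metric
arithmetic of a re-implementation: confusion metrics computed from them must
reproduce the study's reported accuracy, sensitivity and specificity exactly.

Each table maps participant id → predicted class for one evaluation schema
(temporal 4-fold cross-validation or leave-one-participant-out) and one
sensor site.  The non-medicated evaluation covers 5 ADHD and 11 control
children; the medicated-transfer tables cover the 6 medicated children with
their SNAP severity scores.
"""

from __future__ import annotations

from .subject_inference import ConfusionMetrics, confusion_metrics

__all__ = [
    "NONMED_IDS",
    "CONTROL_IDS",
    "KFOLD_WRIST",
    "KFOLD_ANKLE",
    "LOO_WRIST",
    "LOO_ANKLE",
    "TRANSFER_WRIST",
    "TRANSFER_ANKLE",
    "outcome_metrics",
    "transfer_control_count",
]

NONMED_IDS = ("ADHD1", "ADHD3", "ADHD4", "ADHD10", "ADHD12")
CONTROL_IDS = (
    "Control1", "Control11", "Control2", "Control7", "Control5", "Control13",
    "Control6", "Control14", "Control15", "Control16", "Control8",
)

#: 4-fold temporal cross-validation, wrist sensor: one control misclassified.
KFOLD_WRIST = {
    **{pid: "ADHD" for pid in NONMED_IDS},
    **{pid: "control" for pid in CONTROL_IDS},
    "Control13": "ADHD",
}

#: 4-fold temporal cross-validation, ankle sensor: one ADHD child missed.
KFOLD_ANKLE = {
    **{pid: "ADHD" for pid in NONMED_IDS},
    **{pid: "control" for pid in CONTROL_IDS},
    "ADHD3": "control",
}

#: Leave-one-participant-out, wrist sensor: two ADHD children missed.
LOO_WRIST = {
    **{pid: "ADHD" for pid in NONMED_IDS},
    **{pid: "control" for pid in CONTROL_IDS},
    "ADHD1": "control",
    "ADHD12": "control",
}

#: Leave-one-participant-out, ankle sensor: one ADHD child missed.
LOO_ANKLE = {
    **{pid: "ADHD" for pid in NONMED_IDS},
    **{pid: "control" for pid in CONTROL_IDS},
    "ADHD12": "control",
}

#: Medicated transfer, wrist: (SNAP score, classified-as) per medicated child.
TRANSFER_WRIST = {
    "ADHD5": (1.77, "control"),
    "ADHD6": (3.0, "ADHD"),
    "ADHD9": (1.88, "ADHD"),
    "ADHD11": (2.11, "control"),
    "ADHD14": (1.66, "control"),
    "ADHD15": (2.0, "control"),
}

#: Medicated transfer, ankle.
TRANSFER_ANKLE = {
    "ADHD5": (1.77, "ADHD"),
    "ADHD6": (3.0, "ADHD"),
    "ADHD9": (1.88, "control"),
    "ADHD11": (2.11, "ADHD"),
    "ADHD14": (1.66, "control"),
    "ADHD15": (2.0, "ADHD"),
}


def outcome_metrics(outcomes: dict[str, str]) -> ConfusionMetrics:
    """Confusion metrics of one published outcome table (ADHD positive class)."""
    ids = sorted(outcomes)
    true = ["ADHD" if pid.startswith("ADHD") else "control" for pid in ids]
    pred = [outcomes[pid] for pid in ids]
    return confusion_metrics(true, pred)


def transfer_control_count(table: dict[str, tuple[float, str]]) -> int:
    """How many medicated children score as control-like in a transfer table."""
    return sum(1 for _, cls in table.values() if cls == "control")
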