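"""Structural-alert classification of azoles as aromatase agonists/antagonists.

An alert is a SMARTS substructure statistically associated with one activity
class.  Per-alert performance uses two statistics:

* accuracy  Acc = true predictions / all predictions by the alert;
* likelihood ratio  LR = (true/wrong) · (total antagonists / total agonists)
  for an agonist alert, with the class factor inverted for antagonist alerts;
  a perfect alert (zero wrong predictions) has LR = ∞.

A molecule matching several alerts is predicted by the alert with the highest
LR.  Model-level accuracy Q₂ is compared against the most probable random
accuracy Q₂rand = (P² + N²)/T² from the class marginals; their difference ΔQ₂
(at most 0.5) measures the real classification signal.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .chem import MolecularGraph, match_smarts


@dataclass(frozen=True)
class Alert:
    """One structural alert with its published statistics."""

    id: str
    name: str
    smarts: str
    activity: str  # "agonist" or "antagonist"
    lr: float  # math.inf for perfect classifiers
    accuracy: float
    reliability: str = ""


@dataclass(frozen=True)
class ClassTotals:
    """Dataset class marginals entering the LR class factor."""

    agonists: int
    antagonists: int

    @property
    def total(self) -> int:
        return self.agonists + self.antagonists


@dataclass
class ConfusionTable:
    """Binary confusion counts with agonist coded as the positive class."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def n_predicted(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class AlertSet:
    """Ordered alert collection plus the class totals of its training set."""

    alerts: list[Alert]
    totals: ClassTotals

    def __iter__(self):
        return iter(self.alerts)

    def __len__(self):
        return len(self.alerts)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "totals": asdict(self.totals),
            "alerts": [
                {**asdict(a), "lr": "inf" if math.isinf(a.lr) else a.lr}
                for a in self.alerts
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AlertSet":
        if isinstance(source, Path) or (isinstance(source, str) and "{" not in source):
            text = Path(source).read_text()
        else:
            text = str(source)
        d = json.loads(text)
        alerts = [
            Alert(**{**a, "lr": math.inf if a["lr"] == "inf" else float(a["lr"])})
            for a in d["alerts"]
        ]
        return cls(alerts=alerts, totals=ClassTotals(**d["totals"]))


#: class totals of the curated 78-compound active azole set
DEFAULT_TOTALS = ClassTotals(agonists=36, antagonists=42)

_BUILTIN = [
    # (id, name, SMARTS, class, LR, accuracy, reliability)
    ("SA1", "1,3-thiazoles", "c2cscn2", "agonist", math.inf, 1.0, "high"),
    ("SA2", "para-substituted chlorobenzenes", "Clc1ccc(CC)cc1", "antagonist",
     math.inf, 1.0, "high"),
    ("SA3", "1,2,4-triazoles", "n1cncn1", "antagonist", math.inf, 1.0, "high"),
    ("SA4", "carboxylic acids", "C(=O)O", "agonist", 12.83, 0.92, "high"),
    ("SA5", "ethyl(propyl)amine", "CCCN(CC)", "antagonist", 1.71, 0.67,
     "low to medium"),
    ("SA6", "benzylimidazoles", "c1cn(cn1)C(c1ccccc1)", "antagonist",
     math.inf, 1.0, "high"),
    ("SA7", "1-phenyl-1H-imidazoles", "c1c(cccc1)n1ccnc1", "antagonist",
     math.inf, 1.0, "high"),
    ("SA8", "amides", "C(=O)N", "agonist", 4.96, 0.81, "medium to high"),
    ("SA9", "chlorobenzenes", "Clc1cccc(c1)", "antagonist", 11.57, 0.93, "high"),
    ("SA10", "carbon chain", "CC", "antagonist", 1.67, 0.66, "low to medium"),
    ("SA11", "purines", "c1ncnc2c1ncn2", "agonist", 2.33, 0.67, "low to medium"),
]


def builtin_alerts() -> AlertSet:
    """The 11 published structural alerts with their printed LR and accuracy,
    four agonist and seven antagonist alerts, plus the 36/42 class totals."""
    return AlertSet(
        alerts=[Alert(*row) for row in _BUILTIN],
        totals=DEFAULT_TOTALS,
    )


def alert_accuracy(true_pred: int, total_pred: int) -> float:
    """Acc = true predictions / all predictions made by the alert."""
    if total_pred < 1:
        raise ValueError("alert made no predictions; accuracy undefined")
    if true_pred > total_pred or true_pred < 0:
        raise ValueError(f"invalid counts: {true_pred}/{total_pred}")
    return true_pred / total_pred


def alert_lr(true_pred: int, wrong_pred: int, totals: ClassTotals,
             activity: str) -> float:
    """Likelihood ratio with the activity-dependent class factor.

    Agonist alerts multiply by (antagonists/agonists); antagonist alerts invert
    the factor.  Zero wrong predictions gives ∞ (perfect classifier).
    """
    if true_pred < 0 or wrong_pred < 0:
        raise ValueError("counts must be non-negative")
    if true_pred == 0 and wrong_pred == 0:
        raise ValueError("alert made no predictions; LR undefined")
    if activity == "agonist":
        factor = totals.antagonists / totals.agonists
    elif activity == "antagonist":
        factor = totals.agonists / totals.antagonists
    else:
        raise ValueError(f"unknown alert activity {activity!r}")
    if wrong_pred == 0:
        return math.inf
    return (true_pred / wrong_pred) * factor


@dataclass
class Prediction:
    """Outcome of alert-based classification for one molecule."""

    label: str  # "agonist", "antagonist" or "no-prediction"
    matched: list[str] = field(default_factory=list)
    winning: str | None = None
    ambiguous: bool = False


def classify(g: MolecularGraph, alert_set: AlertSet) -> Prediction:
    """Predict the class of one molecule from the alert with the highest LR.

    Infinite LR outranks any finite value.  When alerts of opposite classes tie
    at the top LR the call is ambiguous: no-prediction, with a warning.
    """
    matched = [a for a in alert_set if match_smarts(g, a.smarts)[0]]
    if not matched:
        return Prediction(label="no-prediction")
    best_lr = max(a.lr for a in matched)
    winners = [a for a in matched if a.lr == best_lr]
    classes = {a.activity for a in winners}
    ids = [a.id for a in matched]
    if len(classes) > 1:
        warnings.warn(
            f"{g.id or 'molecule'}: opposite-class alerts tie at LR={best_lr}; "
            "no prediction",
            stacklevel=2,
        )
        return Prediction(label="no-prediction", matched=ids, ambiguous=True)
    win = winners[0]
    return Prediction(label=win.activity, matched=ids, winning=win.id)


def q2_random(agonists: int, antagonists: int) -> float:
    """Most probable random accuracy (P² + N²)/T² from the class marginals."""
    t = agonists + antagonists
    if t == 0:
        raise ValueError("empty dataset")
    return (agonists**2 + antagonists**2) / t**2


def q2_random_marginal(table: ConfusionTable) -> float:
    """Marginal-product random agreement
    [(TP+FP)(TP+FN) + (TN+FN)(TN+FP)]/N², for comparison with
    :func:`q2_random`."""
    n = table.n_predicted
    if n == 0:
        raise ValueError("no predictions")
    pos = (table.tp + table.fp) * (table.tp + table.fn)
    neg = (table.tn + table.fn) * (table.tn + table.fp)
    return (pos + neg) / n**2


@dataclass
class AlertPerformance:
    """Per-alert counts and statistics recomputed on a labeled dataset."""

    alert_id: str
    true_pred: int
    wrong_pred: int
    accuracy: float | None
    lr: float | None


@dataclass
class EvaluationResult:
    """Dataset-level classification performance of an alert set."""

    confusion: ConfusionTable
    q2: float
    q2_rand: float
    delta_q2: float
    n_no_prediction: int
    per_alert: list[AlertPerformance]


def evaluate(dataset, alert_set: AlertSet) -> EvaluationResult:
    """Classify every labeled molecule and score the alert model.

    ``dataset`` is an iterable of ``(MolecularGraph, label)`` with label
    "agonist" or "antagonist".  Molecules without any matching alert are
    excluded from Q₂'s denominator and reported separately; Q₂rand uses the
    actual class totals of the full dataset.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty dataset")
    table = ConfusionTable()
    n_nopred = 0
    per_alert_counts = {a.id: [0, 0] for a in alert_set}
    n_ag = sum(1 for _, lab in dataset if lab == "agonist")
    n_ant = len(dataset) - n_ag
    totals = ClassTotals(agonists=n_ag, antagonists=n_ant)
    for g, label in dataset:
        for a in alert_set:
            if match_smarts(g, a.smarts)[0]:
                if label == a.activity:
                    per_alert_counts[a.id][0] += 1
                else:
                    per_alert_counts[a.id][1] += 1
        pred = classify(g, alert_set)
        if pred.label == "no-prediction":
            n_nopred += 1
            continue
        if label == "agonist":
            if pred.label == "agonist":
                table.tp += 1
            else:
                table.fn += 1
        else:
            if pred.label == "antagonist":
                table.tn += 1
            else:
                table.fp += 1
    n_pred = table.n_predicted
    q2 = (table.tp + table.tn) / n_pred if n_pred else 0.0
    q2r = q2_random(n_ag, n_ant)
    per_alert = []
    for a in alert_set:
        t, w = per_alert_counts[a.id]
        if t + w == 0:
            per_alert.append(AlertPerformance(a.id, 0, 0, None, None))
        else:
            per_alert.append(
                AlertPerformance(
                    a.id, t, w,
                    accuracy=alert_accuracy(t, t + w),
                    lr=alert_lr(t, w, totals, a.activity),
                )
            )
    return EvaluationResult(
        confusion=table,
        q2=q2,
        q2_rand=q2r,
        delta_q2=q2 - q2r,
        n_no_prediction=n_nopred,
        per_alert=per_alert,
    )
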