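"""Classification and corruption-robustness metrics.

Accuracy, AUC-ROC and balanced error for binary, multi-class and multi-label
tasks, plus the reference-normalised robustness scores BE and rBE used by
corruption benchmarks:

* **balanced error** = 1 − mean over classes of per-class recall; insensitive
  to class imbalance.
* **BE**: per corruption, the model's severity-summed balanced error divided
  by the reference model's; BE is the mean of these ratios over corruptions
  (reference model = 1).
* **rBE**: the same construction applied to the *increase* in error over the
  clean test set, ``error − clean``.  rBE can legitimately be negative when
  a corruption reduces the model's error while increasing the reference's.

Both scores default to the raw ratio scale (reference = 1); ``scale_100``
multiplies by 100 for benchmarks that fix the reference at 100.  The default
aggregation sums severities within a corruption before taking the ratio (the
convention of the ImageNet-C family); a literal per-pair mean of the 55
individual ratios is available as ``aggregation="pair_mean"``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score, roc_auc_score

from .errors import UndefinedMetricError


@dataclass
class MetricReport:
    """Accuracy and AUC, with per-seed values when run-averaging is used.

    When ``n_runs > 1`` the headline ``accuracy``/``auc`` are means over the
    per-seed entries.
    """

    accuracy: float
    auc: float
    per_class_auc: list[float] | None = None
    per_seed: list[tuple[int, float, float]] = field(default_factory=list)
    n_runs: int = 1

    @classmethod
    def from_runs(cls, per_seed: list[tuple[int, float, float]]) -> "MetricReport":
        accs = [a for _, a, _ in per_seed]
        aucs = [u for _, _, u in per_seed]
        return cls(
            accuracy=float(np.mean(accs)),
            auc=float(np.mean(aucs)),
            per_seed=per_seed,
            n_runs=len(per_seed),
        )

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "auc": self.auc,
            "per_class_auc": self.per_class_auc,
            "per_seed": [list(t) for t in self.per_seed],
            "n_runs": self.n_runs,
        }


def _check_nonempty(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape[0] == 0:
        raise UndefinedMetricError("empty input")
    if a.shape[0] != b.shape[0]:
        raise UndefinedMetricError(f"misaligned inputs: {a.shape[0]} vs {b.shape[0]}")


def accuracy(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of correct predictions.

    Multi-label inputs (2-D 0/1 arrays) score each label decision
    independently: per-label binary accuracy averaged over labels.
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    _check_nonempty(predictions, labels)
    return float((predictions == labels).mean())


def auc_roc(scores: np.ndarray, labels: np.ndarray, task_type: str = "binary") -> float:
    """Area under the ROC curve.

    Binary: the probability that a random positive outranks a random
    negative, ties counting one half — ``(#(pos>neg) + 0.5*#ties) / (n_pos*n_neg)``.
    Multi-class: macro one-vs-rest over per-class scores.  Multi-label:
    per-label AUC, macro-averaged.  Single-class input raises
    :class:`UndefinedMetricError` rather than silently returning 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_nonempty(scores, labels)
    if task_type == "binary":
        if np.unique(labels).size < 2:
            raise UndefinedMetricError("AUC undefined: only one class present")
        s = scores[:, 1] if scores.ndim == 2 else scores
        return float(roc_auc_score(labels, s))
    if task_type == "multiclass":
        if np.unique(labels).size < 2:
            raise UndefinedMetricError("AUC undefined: only one class present")
        if np.unique(labels).size == 2:
            return float(roc_auc_score(labels, scores[:, 1]))
        return float(roc_auc_score(labels, scores, multi_class="ovr", average="macro"))
    if task_type == "multilabel":
        per_label = []
        for j in range(labels.shape[1]):
            if np.unique(labels[:, j]).size < 2:
                raise UndefinedMetricError(
                    f"AUC undefined: label {j} has a single class"
                )
            per_label.append(roc_auc_score(labels[:, j], scores[:, j]))
        return float(np.mean(per_label))
    raise ValueError(f"unknown task_type '{task_type}'")


def balanced_error(predictions: np.ndarray, labels: np.ndarray) -> float:
    """1 − mean per-class recall.  All classes must appear in ``labels``."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    _check_nonempty(predictions, labels)
    if labels.ndim == 2:  # multi-label: mean over per-label balanced errors
        return float(
            np.mean(
                [
                    balanced_error(predictions[:, j], labels[:, j])
                    for j in range(labels.shape[1])
                ]
            )
        )
    classes = np.unique(labels)
    if classes.size < 2:
        raise UndefinedMetricError(
            f"balanced error undefined: only class {classes[0]} present"
        )
    return float(1.0 - balanced_accuracy_score(labels, predictions))


def count_corruption_pairs(n_corruptions: int, n_severities: int) -> int:
    """Number of (corruption, severity) conditions: the plain product."""
    if n_corruptions < 1 or n_severities < 1:
        raise ValueError("counts must be positive")
    return n_corruptions * n_severities


@dataclass
class CorruptionErrorTable:
    """Balanced errors of a model and a reference under corruption.

    ``model_errors`` and ``ref_errors`` are ``(n_corruptions, n_severities)``
    matrices of balanced errors; ``model_clean`` / ``ref_clean`` are the
    errors on the uncorrupted test set.  The benchmark shape is 11x5 (55
    conditions) but any positive shape is accepted.
    """

    model_clean: float
    ref_clean: float
    model_errors: np.ndarray
    ref_errors: np.ndarray

    def __post_init__(self) -> None:
        self.model_errors = np.asarray(self.model_errors, dtype=float)
        self.ref_errors = np.asarray(self.ref_errors, dtype=float)
        if self.model_errors.shape != self.ref_errors.shape:
            raise ValueError("model and reference error matrices differ in shape")
        if self.model_errors.ndim != 2:
            raise ValueError("error matrices must be corruption x severity")
        for name, arr in (("model_errors", self.model_errors),
                          ("ref_errors", self.ref_errors)):
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError(f"{name} must lie in [0, 1]")
        for name, v in (("model_clean", self.model_clean),
                        ("ref_clean", self.ref_clean)):
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    def to_csv(self, path) -> None:
        """Write the table: two clean-error rows, then the per-condition CSV."""
        rows = []
        for c in range(self.model_errors.shape[0]):
            for s in range(self.model_errors.shape[1]):
                rows.append((c + 1, s + 1, self.model_errors[c, s],
                             self.ref_errors[c, s]))
        df = pd.DataFrame(rows, columns=["corruption", "severity",
                                         "model_error", "ref_error"])
        with open(path, "w") as fh:
            fh.write(f"model_clean,{self.model_clean}\n")
            fh.write(f"ref_clean,{self.ref_clean}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "CorruptionErrorTable":
        with open(path) as fh:
            clean = {}
            for _ in range(2):
                key, value = fh.readline().strip().split(",")
                clean[key] = float(value)
            df = pd.read_csv(io.StringIO(fh.read()))
        n_c = int(df["corruption"].max())
        n_s = int(df["severity"].max())
        model = np.full((n_c, n_s), np.nan)
        ref = np.full((n_c, n_s), np.nan)
        for _, row in df.iterrows():
            c, s = int(row["corruption"]) - 1, int(row["severity"]) - 1
            model[c, s] = row["model_error"]
            ref[c, s] = row["ref_error"]
        if np.isnan(model).any() or np.isnan(ref).any():
            raise ValueError(f"{path}: incomplete corruption x severity grid")
        return cls(model_clean=clean["model_clean"], ref_clean=clean["ref_clean"],
                   model_errors=model, ref_errors=ref)


def robustness_scores(
    table: CorruptionErrorTable,
    aggregation: str = "corruption_mean",
    scale_100: bool = False,
) -> tuple[float, float]:
    """Reference-normalised robustness scores ``(BE, rBE)``.

    ``corruption_mean`` (default): per corruption ``c``, the ratio of
    severity-summed errors ``sum_s model[c,s] / sum_s ref[c,s]``; BE is the
    mean ratio over corruptions.  rBE applies the same construction to
    ``error − clean``.  ``pair_mean`` instead averages the 55 individual
    per-condition ratios.  Negative rBE passes through unclamped.
    """
    if aggregation not in ("corruption_mean", "pair_mean"):
        raise ValueError(f"unknown aggregation '{aggregation}'")
    me, re_ = table.model_errors, table.ref_errors
    dm = me - table.model_clean
    dr = re_ - table.ref_clean
    if aggregation == "corruption_mean":
        ref_sums = re_.sum(axis=1)
        ref_delta_sums = dr.sum(axis=1)
        if (ref_sums == 0).any() or (ref_delta_sums == 0).any():
            raise ZeroDivisionError("reference error sums contain a zero denominator")
        be = float((me.sum(axis=1) / ref_sums).mean())
        rbe = float((dm.sum(axis=1) / ref_delta_sums).mean())
    else:
        if (re_ == 0).any() or (dr == 0).any():
            raise ZeroDivisionError("reference errors contain a zero denominator")
        be = float((me / re_).mean())
        rbe = float((dm / dr).mean())
    if scale_100:
        be, rbe = 100.0 * be, 100.0 * rbe
    return be, rbe
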