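"""Multi-class Gentle Boosting rule learner for phenotype classification.

The learner reproduces the CellProfiler-Analyst "Fast Gentle Boosting"
formulation: each boosting round fits a single shared regression stump (one
feature, one threshold) with a per-class score vector on symmetric
one-vs-rest +/-1 targets.  The stump scores are the weighted means of the
targets on each side of the split (the least-squares / gentle-AdaBoost
solution), weights are updated multiplicatively ``w <- w * exp(-y * h)``
and renormalised per class channel, and training stops once every class's
training accuracy - read from the confusion matrix - exceeds the target
(default 90%) or the rule budget (default 20) is exhausted.

Rules serialise to a line-oriented text dialect so a trained model can be
re-applied to new datasets without re-training::

    classes Round Spindle Spread
    IF (area > 412.5, [0.8, -0.3, -0.5], [-0.8, 0.3, 0.5])
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import CLASS_NAMES

__all__ = [
    "Rule",
    "BoostingModel",
    "ConfusionMatrix",
    "fit_weighted_stump",
    "train_gentle_boosting",
    "classify",
    "confusion_and_accuracy",
    "serialize_rules",
    "parse_rules",
]


@dataclass(frozen=True)
class Rule:
    """One threshold rule with per-class scores.

    ``score_above`` applies when feature > threshold, ``score_below``
    otherwise.
    """

    feature: str
    threshold: float
    score_above: tuple[float, ...]
    score_below: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.score_above) != len(self.score_below):
            raise ValueError("score vectors must have equal length")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


@dataclass
class ConfusionMatrix:
    counts: np.ndarray          # true class x predicted class
    class_names: tuple[str, ...]

    @property
    def per_class_accuracy(self) -> np.ndarray:
        row_sums = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            acc = np.diag(self.counts) / row_sums
        return np.where(row_sums > 0, acc, np.nan)

    @property
    def overall_accuracy(self) -> float:
        return float(np.diag(self.counts).sum() / self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.class_names),
                            columns=list(self.class_names))


@dataclass
class BoostingModel:
    """Ordered rule list with class names; applied additively."""

    rules: list[Rule]
    class_names: tuple[str, ...] = CLASS_NAMES
    training_confusion: ConfusionMatrix | None = None
    accuracy_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("model must contain at least one rule")
        if len(set(self.class_names)) != len(self.class_names) or not self.class_names:
            raise ValueError("class names must be nonempty and unique")

    @property
    def feature_names(self) -> list[str]:
        seen: list[str] = []
        for rule in self.rules:
            if rule.feature not in seen:
                seen.append(rule.feature)
        return seen


def _as_matrix(table, feature_names=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(table, pd.DataFrame):
        names = list(table.columns) if feature_names is None else list(feature_names)
        missing = [n for n in names if n not in table.columns]
        if missing:
            raise KeyError(f"missing feature column(s): {missing}")
        x = table[names].to_numpy(dtype=float)
    else:
        x = np.asarray(table, dtype=float)
        if x.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if feature_names is None:
            names = [f"f{i}" for i in range(x.shape[1])]
        else:
            names = list(feature_names)
    return x, names


def fit_weighted_stump(
    x: np.ndarray,
    targets: np.ndarray,
    weights: np.ndarray,
    feature_names: list[str] | None = None,
) -> Rule:
    """Least-squares regression stump shared across class channels.

    ``targets`` and ``weights`` have shape (n_samples, n_classes) with
    targets in {-1, +1}.  Every feature and every candidate threshold
    (midpoints of consecutive sorted unique values) is searched for the
    split minimising the total weighted squared error

        sum_c sum_i w_ci (y_ci - h_c(x_i))^2

    where h_c is the weighted mean of y_c on the side of the split.  Ties
    are broken by lowest feature index, then lowest threshold.  A constant
    feature matrix yields the degenerate rule whose two score vectors both
    equal the weighted class means.

    Because y^2 = 1 the error decomposes as
    ``W_tot - sum_side S_side^2 / W_side`` with S = sum(w*y), W = sum(w)
    per side, which the search exploits with cumulative sums.
    """
    x, names = _as_matrix(x, feature_names)
    y = np.asarray(targets, dtype=float)
    w = np.asarray(weights, dtype=float)
    if y.shape != w.shape or y.shape[0] != x.shape[0]:
        raise ValueError("targets/weights must align with the feature matrix")
    if (w <= 0).any():
        raise ValueError("weights must be positive")

    n, n_feat = x.shape
    w_tot = w.sum()
    wy = w * y
    w_class = w.sum(axis=0)              # per class channel
    s_class = wy.sum(axis=0)

    means = s_class / w_class
    best = None  # (error, feat_idx, threshold, above, below)
    for j in range(n_feat):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        xs = col[order]
        cw = np.cumsum(w[order], axis=0)      # (n, C) weight below-or-at i
        cs = np.cumsum(wy[order], axis=0)
        # candidate split after position i (0-based): below = [0..i]
        boundary = np.nonzero(xs[1:] > xs[:-1])[0]  # split between i and i+1
        if boundary.size == 0:
            continue
        w_below = cw[boundary]                # (B, C)
        s_below = cs[boundary]
        w_above = w_class[None, :] - w_below
        s_above = s_class[None, :] - s_below
        with np.errstate(divide="ignore", invalid="ignore"):
            gain = np.where(w_below > 0, s_below ** 2 / w_below, 0.0) + \
                   np.where(w_above > 0, s_above ** 2 / w_above, 0.0)
        errors = w_tot - gain.sum(axis=1)
        i_best = int(np.argmin(errors))       # argmin -> lowest threshold on ties
        err = float(errors[i_best])
        if best is None or err < best[0] - 1e-15:
            b = boundary[i_best]
            threshold = 0.5 * (xs[b] + xs[b + 1])
            above = s_above[i_best] / w_above[i_best]
            below = s_below[i_best] / w_below[i_best]
            best = (err, j, float(threshold), above, below)

    if best is None:  # constant matrix in every feature
        return Rule(names[0], float(x[0, 0]) if n else 0.0,
                    tuple(means), tuple(means))
    _, j, threshold, above, below = best
    return Rule(names[j], threshold, tuple(above), tuple(below))


def _score_matrix(model_rules: list[Rule], x: np.ndarray,
                  feature_index: dict[str, int]) -> np.ndarray:
    n = x.shape[0]
    n_classes = len(model_rules[0].score_above)
    scores = np.zeros((n, n_classes))
    for rule in model_rules:
        col = x[:, feature_index[rule.feature]]
        above = col > rule.threshold
        scores += np.where(above[:, None],
                           np.asarray(rule.score_above)[None, :],
                           np.asarray(rule.score_below)[None, :])
    return scores


def train_gentle_boosting(
    table,
    labels,
    max_rules: int = 20,
    accuracy_target: float = 0.90,
    class_names: tuple[str, ...] | None = None,
    feature_names: list[str] | None = None,
) -> BoostingModel:
    """Train the boosted rule list.

    Stops as soon as every class's training accuracy (from the confusion
    matrix of the model so far) exceeds ``accuracy_target``, or when
    ``max_rules`` stumps have been added.  The returned model carries its
    training confusion matrix and the per-iteration minimum class accuracy.
    """
    x, names = _as_matrix(table, feature_names)
    if not np.isfinite(x).all():
        bad = int(np.argwhere(~np.isfinite(x))[0][0])
        raise ValueError(f"non-finite feature value at row {bad}")
    labels = np.asarray(labels)
    present = pd.unique(labels)
    if len(present) < 2:
        raise ValueError("training requires at least two classes present")
    if class_names is None:
        if set(present) <= set(CLASS_NAMES):
            class_names = tuple(c for c in CLASS_NAMES if c in set(present))
        else:
            class_names = tuple(sorted(present))
    unknown = set(present) - set(class_names)
    if unknown:
        raise ValueError(f"labels outside the class set: {sorted(unknown)}")

    n = x.shape[0]
    n_classes = len(class_names)
    class_index = {c: i for i, c in enumerate(class_names)}
    y = -np.ones((n, n_classes))
    y[np.arange(n), [class_index[l] for l in labels]] = 1.0
    w = np.full((n, n_classes), 1.0 / n)

    feature_index = {name: i for i, name in enumerate(names)}
    rules: list[Rule] = []
    history: list[float] = []
    true_idx = np.array([class_index[l] for l in labels])
    for _ in range(max_rules):
        rule = fit_weighted_stump(x, y, w, feature_names=names)
        rules.append(rule)
        col = x[:, feature_index[rule.feature]]
        h = np.where((col > rule.threshold)[:, None],
                     np.asarray(rule.score_above)[None, :],
                     np.asarray(rule.score_below)[None, :])
        w = w * np.exp(-y * h)
        w /= w.sum(axis=0, keepdims=True)   # per class channel sums to 1

        scores = _score_matrix(rules, x, feature_index)
        predicted = scores.argmax(axis=1)
        cm = _confusion_from_indices(true_idx, predicted, class_names)
        min_acc = float(np.nanmin(cm.per_class_accuracy))
        history.append(min_acc)
        if min_acc > accuracy_target:
            break

    model = BoostingModel(rules=rules, class_names=tuple(class_names))
    model.training_confusion = cm
    model.accuracy_history = history
    return model


def classify(model: BoostingModel, table,
             feature_names: list[str] | None = None):
    """Apply a model: per-class additive scores and argmax labels.

    Ties are broken by class order (argmax keeps the first maximum).
    Returns ``(labels, scores)`` with scores shaped (n, n_classes).
    """
    needed = model.feature_names
    if isinstance(table, pd.DataFrame):
        missing = [f for f in needed if f not in table.columns]
        if missing:
            raise KeyError(f"missing feature column(s): {missing}")
        x, names = _as_matrix(table, list(table.columns))
    else:
        x, names = _as_matrix(table, feature_names)
        missing = [f for f in needed if f not in names]
        if missing:
            raise KeyError(f"missing feature column(s): {missing}")
    feature_index = {name: i for i, name in enumerate(names)}
    scores = _score_matrix(model.rules, x, feature_index)
    labels = np.asarray(model.class_names)[scores.argmax(axis=1)]
    return labels, scores


def _confusion_from_indices(true_idx, pred_idx, class_names) -> ConfusionMatrix:
    k = len(class_names)
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (true_idx, pred_idx), 1)
    return ConfusionMatrix(counts=counts, class_names=tuple(class_names))


def confusion_and_accuracy(predicted, true,
                           class_names: tuple[str, ...] | None = None
                           ) -> ConfusionMatrix:
    """Confusion matrix (true x predicted) with per-class accuracy."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError("predicted and true labels must have equal length")
    if class_names is None:
        observed = set(true) | set(predicted)
        if observed <= set(CLASS_NAMES):
            class_names = tuple(c for c in CLASS_NAMES if c in observed)
        else:
            class_names = tuple(sorted(observed))
    index = {c: i for i, c in enumerate(class_names)}
    try:
        t = np.array([index[v] for v in true])
        p = np.array([index[v] for v in predicted])
    except KeyError as exc:
        raise ValueError(f"label outside the class set: {exc.args[0]!r}") from exc
    return _confusion_from_indices(t, p, class_names)


_RULE_RE = re.compile(
    r"^IF \((?P<feature>[^,>]+?) > (?P<threshold>[^,]+), "
    r"\[(?P<above>[^\]]*)\], \[(?P<below>[^\]]*)\]\)$"
)


def serialize_rules(model: BoostingModel) -> str:
    """Rule list as the line-oriented text dialect (one rule per line)."""
    lines = ["classes " + " ".join(model.class_names)]
    for rule in model.rules:
        above = ", ".join(f"{v:.12g}" for v in rule.score_above)
        below = ", ".join(f"{v:.12g}" for v in rule.score_below)
        lines.append(
            f"IF ({rule.feature} > {rule.threshold:.12g}, [{above}], [{below}])"
        )
    return "\n".join(lines) + "\n"


def parse_rules(text: str) -> BoostingModel:
    """Parse the text dialect back into a model.

    Raises ``ValueError`` naming the offending line on malformed input.
    """
    lines = [l for l in (line.strip() for line in text.splitlines()) if l]
    if not lines:
        raise ValueError("empty rule file")
    header = lines[0]
    if not header.startswith("classes "):
        raise ValueError("line 1: expected 'classes <name> ...' header")
    class_names = tuple(header.split()[1:])
    if not class_names:
        raise ValueError("line 1: no class names in header")
    rules = []
    for lineno, line in enumerate(lines[1:], start=2):
        m = _RULE_RE.match(line)
        if m is None:
            raise ValueError(f"line {lineno}: malformed rule: {line!r}")
        try:
            threshold = float(m.group("threshold"))
            above = tuple(float(v) for v in m.group("above").split(","))
            below = tuple(float(v) for v in m.group("below").split(","))
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
        if len(above) != len(class_names) or len(below) != len(class_names):
            raise ValueError(
                f"line {lineno}: score vector length != number of classes"
            )
        rules.append(Rule(m.group("feature").strip(), threshold, above, below))
    if not rules:
        raise ValueError("rule file contains no rules")
    return BoostingModel(rules=rules, class_names=class_names)
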