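"""Linear-SVM decoding of heading and context from neural features.

All decoders share one engine: a linear maximum-margin binary classifier
(C = 1, no kernel tricks, no hyperparameter search) whose class priors are
the empirical class frequencies of the training trials (each training trial
weighs equally in the hinge loss), validated leave-one-out — one model per
held-out trial, accuracy = share of correct held-out predictions.

Feature sets:

* **heading from map alignment** — per-cell (sin, cos) of the trial's
  center-out angle, labels C vs G (or N vs F for error trials);
* **context / heading from firing rate** — per-cell mean firing rate per
  trial, labels context A vs B or dig side C vs G;
* **cross-day transfer** — the alignment features, fit once on a training
  day and evaluated on every trial of a test day, restricted to cells
  active on both days.

Cells missing a defined angle or rate on a trial contribute zeros by
default (an indicator-column policy is available).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from sklearn.svm import SVC

from .errors import DomainError


@dataclass
class TrialFeatureMatrix:
    """Feature rows per included trial, with labels and provenance."""

    X: np.ndarray
    y: np.ndarray                       # string labels, 2 classes
    trial_ids: list[int]
    feature_names: list[str] = field(default_factory=list)
    missing_policy: str = "zero"

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.y) or self.X.shape[0] != len(self.trial_ids):
            raise DomainError("one feature row per labeled trial is required")


def _fit_svm(X: np.ndarray, y: np.ndarray) -> SVC:
    # Unweighted hinge loss => class priors enter at their empirical
    # frequencies, which is the "empirical prior" wanted here.
    clf = SVC(kernel="linear", C=1.0)
    clf.fit(X, y)
    return clf


def loo_svm_accuracy(features: TrialFeatureMatrix) -> float:
    """Leave-one-out accuracy of the linear SVM on the given trials.

    Sessions where either class has fewer than two trials are excluded
    (raise), since leave-one-out could then face single-class training sets.
    """
    labels, counts = np.unique(features.y, return_counts=True)
    if len(labels) != 2:
        raise DomainError(f"need exactly 2 classes, got {list(labels)}")
    if counts.min() < 2:
        raise DomainError("each class needs >= 2 trials for leave-one-out")
    n = len(features.y)
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        clf = _fit_svm(features.X[mask], features.y[mask])
        correct += clf.predict(features.X[i:i + 1])[0] == features.y[i]
    return correct / n


def heading_features(
    angles: Mapping[int, Mapping[int, float | None]],
    trial_labels: Mapping[int, str],
    label_set: tuple[str, str] = ("C", "G"),
    missing_policy: Literal["zero", "zero+indicator"] = "zero",
) -> TrialFeatureMatrix:
    """Per-cell (sin, cos) of center-out angles for the labeled trials.

    ``angles[cell_id][trial_id]`` is the center-out angle in degrees or None
    when the cell had no field on that trial (imputed as (0, 0), optionally
    with an indicator column)."""
    cell_ids = sorted(angles)
    trial_ids = sorted(t for t, lab in trial_labels.items() if lab in label_set)
    if not trial_ids:
        raise DomainError(f"no trials labeled in {label_set}")
    rows, names = [], []
    for cid in cell_ids:
        names += [f"cell{cid}_sin", f"cell{cid}_cos"]
        if missing_policy == "zero+indicator":
            names.append(f"cell{cid}_defined")
    for t in trial_ids:
        row = []
        for cid in cell_ids:
            ang = angles[cid].get(t)
            if ang is None:
                row += [0.0, 0.0]
                if missing_policy == "zero+indicator":
                    row.append(0.0)
            else:
                a = np.deg2rad(ang)
                row += [np.sin(a), np.cos(a)]
                if missing_policy == "zero+indicator":
                    row.append(1.0)
        rows.append(row)
    return TrialFeatureMatrix(
        X=np.asarray(rows, float),
        y=np.asarray([trial_labels[t] for t in trial_ids]),
        trial_ids=trial_ids,
        feature_names=names,
        missing_policy=missing_policy,
    )


def predict_heading_from_alignment(
    angles: Mapping[int, Mapping[int, float | None]],
    trial_labels: Mapping[int, str],
    trial_filter: tuple[str, str] = ("C", "G"),
) -> float:
    """Session accuracy at predicting the dig side from map alignment.

    ``trial_filter`` selects the correct-axis digs ("C", "G") or the error
    digs ("N", "F")."""
    feats = heading_features(angles, trial_labels, label_set=trial_filter)
    return loo_svm_accuracy(feats)


def predict_heading_across_days(
    train_angles: Mapping[int, Mapping[int, float | None]],
    train_labels: Mapping[int, str],
    test_angles: Mapping[int, Mapping[int, float | None]],
    test_labels: Mapping[int, str],
    identity_map: Mapping[int, int],
    label_set: tuple[str, str] = ("C", "G"),
) -> float:
    """Cross-day transfer: fit once on the training day, score every test-day
    trial.  Only cells active on both days (present in ``identity_map`` and
    in both angle tables) are used, with the training day's cell identity as
    the shared feature space."""
    shared = sorted(c for c in train_angles
                    if c in identity_map and identity_map[c] in test_angles)
    if not shared:
        raise DomainError("no cells registered across the two days")
    train = heading_features({c: train_angles[c] for c in shared}, train_labels,
                             label_set=label_set)
    test = heading_features({identity_map[c]: test_angles[identity_map[c]]
                             for c in shared}, test_labels, label_set=label_set)
    labels, counts = np.unique(train.y, return_counts=True)
    if len(labels) != 2 or counts.min() < 1:
        raise DomainError("training day must contain both classes")
    if len(test.y) == 0:
        raise DomainError("no labeled test-day trials")
    clf = _fit_svm(train.X, train.y)
    return float(np.mean(clf.predict(test.X) == test.y))


def rate_features(
    rates: Mapping[int, Mapping[int, float | None]],
    trial_labels: Mapping[int, str],
    label_set: tuple[str, str],
    eligible_cells: Sequence[int] | None = None,
    log_scale: bool = False,
    standardize: bool = True,
) -> TrialFeatureMatrix:
    """Per-cell mean firing rate per trial (zero-imputed when undefined).

    Columns are z-scored by default.  Raw rates put the fixed-C maximum-
    margin classifier in an underfit regime where leave-one-out predictions
    collapse onto the training majority and chance-level sessions score
    systematically below 50%; standardization (a label-free transform)
    restores the 50% chance calibration and makes the decoder invariant to
    uniform rate rescaling.
    """
    cell_ids = sorted(eligible_cells if eligible_cells is not None else rates)
    if not cell_ids:
        raise DomainError("no eligible cells")
    trial_ids = sorted(t for t, lab in trial_labels.items() if lab in label_set)
    if not trial_ids:
        raise DomainError(f"no trials labeled in {label_set}")
    X = np.zeros((len(trial_ids), len(cell_ids)))
    for j, cid in enumerate(cell_ids):
        for i, t in enumerate(trial_ids):
            r = rates[cid].get(t)
            X[i, j] = 0.0 if r is None else (np.log1p(r) if log_scale else r)
    if standardize:
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    return TrialFeatureMatrix(
        X=X,
        y=np.asarray([trial_labels[t] for t in trial_ids]),
        trial_ids=trial_ids,
        feature_names=[f"cell{c}_rate" for c in cell_ids],
    )


def eligible_cells_by_fields(
    field_presence: Mapping[int, Mapping[int, bool]],
    contexts: Mapping[int, str],
    min_trials: int = 4,
    min_per_context: int = 2,
) -> list[int]:
    """Inclusion rule for rate decoding: a cell needs place fields in at
    least ``min_trials`` trials, ``min_per_context`` in each context."""
    out = []
    for cid, pres in field_presence.items():
        per_ctx = {"A": 0, "B": 0}
        for t, has in pres.items():
            if has and t in contexts:
                per_ctx[contexts[t]] += 1
        if sum(per_ctx.values()) >= min_trials and \
                all(v >= min_per_context for v in per_ctx.values()):
            out.append(cid)
    return sorted(out)


def predict_from_rates(
    rates: Mapping[int, Mapping[int, float | None]],
    contexts: Mapping[int, str],
    dig_labels: Mapping[int, str],
    target: Literal["context", "heading"],
    field_presence: Mapping[int, Mapping[int, bool]] | None = None,
    log_scale: bool = False,
) -> float:
    """Context (A/B) or heading (C/G dig side) decoding from mean rates.

    Only trials whose first dig was C or G enter; the context target labels
    them by chamber, the heading target by dig side.  Cell eligibility
    follows the fields-in-4-trials rule when ``field_presence`` is given."""
    cg_trials = {t: lab for t, lab in dig_labels.items() if lab in ("C", "G")}
    if not cg_trials:
        raise DomainError("no C/G trials")
    eligible = None
    if field_presence is not None:
        eligible = eligible_cells_by_fields(field_presence, contexts)
        if not eligible:
            raise DomainError("no cells meet the place-field inclusion rule")
    if target == "context":
        labels = {t: contexts[t] for t in cg_trials}
        label_set = ("A", "B")
    elif target == "heading":
        labels = cg_trials
        label_set = ("C", "G")
    else:
        raise DomainError(f"unknown target {target!r}")
    feats = rate_features(rates, labels, label_set, eligible_cells=eligible,
                          log_scale=log_scale)
    return loo_svm_accuracy(feats)


def shuffled_label_accuracy(features: TrialFeatureMatrix,
                            n_replicates: int,
                            rng: np.random.Generator | int = 0,
                            mode: Literal["permute", "relabel"] = "relabel",
                            ) -> np.ndarray:
    """Chance calibration: leave-one-out accuracy under label randomization.

    ``relabel`` draws fresh independent fair-coin labels per replicate — the
    null in which each held-out label is independent of everything the model
    sees, so any leak-free decoder is exactly 50% calibrated in expectation.
    ``permute`` shuffles the observed labels instead; fixing the class counts
    couples the held-out label to the training composition and biases
    leave-one-out accuracy below 50% for weakly informative features, so it
    is kept only as the classical permutation reference.  Replicates leaving
    either class with fewer than two members are redrawn (such sessions are
    excluded by the decoder's inclusion rule)."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    classes = np.unique(features.y)
    accs = np.empty(n_replicates)
    for k in range(n_replicates):
        for _ in range(1000):
            if mode == "permute":
                ylab = rng.permutation(features.y)
            else:
                ylab = classes[rng.integers(0, 2, size=len(features.y))]
            _, counts = np.unique(ylab, return_counts=True)
            if len(counts) == 2 and counts.min() >= 2:
                break
        shuffled = TrialFeatureMatrix(X=features.X, y=ylab,
                                      trial_ids=features.trial_ids)
        accs[k] = loo_svm_accuracy(shuffled)
    return accs
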