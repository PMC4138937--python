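"""Linear-SVM decoding of resting condition from fALFF patterns.

Samples are one fALFF feature vector per subject per condition,
labelled EC = +1 and EO = -1.  The split mirrors the modelled
procedure: each condition's samples are randomly halved (so one
subject's two recordings can land in different halves; a
subject-stratified split is available via ``by_subject=True`` because
the per-condition scheme leaks subject identity across the split).  A
soft-margin linear SVM (C = 1 by default, libsvm solver) is trained on
one half and evaluated on the other via percent accuracy and the ROC
curve of its decision values.

``run_criterion_comparison`` repeats the decode for each of the four
selection criteria.  By default the Z scores are computed from the
whole cohort before splitting — replicating the modelled analysis,
which is circular (the test half participates in feature selection and
accuracies are optimistic).  ``nested=True`` is the audit mode: a
subject-stratified split is drawn first and Z scores and patterns are
derived from the training subjects only, giving unbiased test accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.svm import SVC

from .selection import (
    DiscriminativePattern,
    RoiZScores,
    SelectionCriterion,
    score_all_rois,
    select_pattern,
    study_criteria,
)

LABEL_EC, LABEL_EO = 1, -1


@dataclass
class SampleSet:
    """Labelled feature matrix with optional train/test assignment."""

    features: np.ndarray
    labels: np.ndarray
    subject_ids: list[str]
    feature_names: list[str]
    split: np.ndarray | None = None  # 'train' / 'test' per sample

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.shape[0] != len(self.labels) or len(self.labels) != len(self.subject_ids):
            raise ValueError("misaligned SampleSet fields")
        if not set(np.unique(self.labels)) <= {LABEL_EC, LABEL_EO}:
            raise ValueError("labels must be +1 (EC) / -1 (EO)")

    def subset(self, which: str) -> "SampleSet":
        if self.split is None:
            raise ValueError("samples have not been split yet")
        m = self.split == which
        return SampleSet(self.features[m], self.labels[m],
                         [s for s, k in zip(self.subject_ids, m) if k],
                         self.feature_names)

    @property
    def train(self) -> "SampleSet":
        return self.subset("train")

    @property
    def test(self) -> "SampleSet":
        return self.subset("test")


def assemble_samples(table_ec: pd.DataFrame, table_eo: pd.DataFrame,
                     pattern: DiscriminativePattern) -> SampleSet:
    """Build the 2 x n_subjects sample set for one pattern.

    Feature columns follow the pattern's |Z|-descending ROI order.
    """
    if len(pattern) == 0:
        raise ValueError(f"pattern {pattern.criterion.label} is empty; nothing to decode")
    missing = set(table_ec.index).symmetric_difference(table_eo.index)
    if missing:
        raise ValueError(f"subject ids not present in both conditions: {sorted(missing)}")
    cols = pattern.roi_names
    ec = table_ec.loc[:, cols]
    eo = table_eo.loc[ec.index, cols]
    features = np.vstack([ec.to_numpy(dtype=float), eo.to_numpy(dtype=float)])
    labels = np.concatenate([np.full(len(ec), LABEL_EC), np.full(len(eo), LABEL_EO)])
    subjects = list(ec.index) + list(eo.index)
    return SampleSet(features, labels, subjects, list(cols))


def split_half(samples: SampleSet, seed: int, by_subject: bool = False) -> SampleSet:
    """Assign each sample to the train or test half.

    Default: each condition's samples are independently halved at
    random (the modelled scheme).  ``by_subject=True`` halves the
    subjects instead, keeping both of a subject's recordings together.
    """
    rng = np.random.default_rng(seed)
    split = np.empty(len(samples.labels), dtype=object)
    if by_subject:
        subjects = sorted(set(samples.subject_ids))
        if len(subjects) % 2:
            raise ValueError("subject-stratified split needs an even subject count")
        perm = rng.permutation(len(subjects))
        train_subj = {subjects[i] for i in perm[: len(subjects) // 2]}
        for i, s in enumerate(samples.subject_ids):
            split[i] = "train" if s in train_subj else "test"
    else:
        for lab in (LABEL_EC, LABEL_EO):
            idx = np.flatnonzero(samples.labels == lab)
            if len(idx) % 2:
                raise ValueError(f"odd sample count ({len(idx)}) for label {lab}")
            perm = rng.permutation(len(idx))
            half = len(idx) // 2
            split[idx[perm[:half]]] = "train"
            split[idx[perm[half:]]] = "test"
    return SampleSet(samples.features, samples.labels, samples.subject_ids,
                     samples.feature_names, split=split)


class StateDecoder(BaseEstimator, ClassifierMixin):
    """Soft-margin linear SVM with deterministic tie handling.

    A thin wrapper over the libsvm linear SVC: decision function
    d(x) = w.x + b, prediction sign(d) with d = 0 mapped to +1 (EC).
    Fitted attributes: ``coef_``, ``intercept_``, ``classes_``.
    """

    def __init__(self, C: float = 1.0):
        self.C = C

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both conditions")
        self._svc = SVC(kernel="linear", C=self.C)
        self._svc.fit(X, y)
        self.coef_ = self._svc.coef_.ravel().copy()
        self.intercept_ = float(self._svc.intercept_[0])
        self.classes_ = self._svc.classes_.copy()
        return self

    def decision_function(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        return np.where(d >= 0, LABEL_EC, LABEL_EO)


def train_linear_svm(train: SampleSet, regularization: float = 1.0) -> StateDecoder:
    """Fit the linear SVM on the training half."""
    return StateDecoder(C=regularization).fit(train.features, train.labels)


@dataclass
class DecodingResult:
    """Held-out performance of one trained pattern decoder."""

    accuracy: float  # percent correct
    auc: float
    decision_values: np.ndarray
    true_labels: np.ndarray
    roc_points: np.ndarray  # (n_thresholds, 2): FPR, TPR
    pattern: DiscriminativePattern | None = None
    split_seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 100.0:
            raise ValueError("accuracy is a percentage")


def evaluate(model: StateDecoder, test: SampleSet,
             pattern: DiscriminativePattern | None = None,
             split_seed: int | None = None) -> DecodingResult:
    """Accuracy, decision values, ROC points and trapezoidal AUC."""
    if len(test.labels) == 0:
        raise ValueError("empty test set")
    d = model.decision_function(test.features)
    pred = np.where(d >= 0, LABEL_EC, LABEL_EO)
    accuracy = 100.0 * float(np.mean(pred == test.labels))
    if len(np.unique(test.labels)) == 2:
        fpr, tpr, _ = _roc_curve(test.labels, d, pos_label=LABEL_EC)
        auc_val = float(_trapezoid_auc(fpr, tpr))
        roc = np.column_stack([fpr, tpr])
    else:  # single-class test set: ROC undefined
        roc = np.array([[0.0, 0.0], [1.0, 1.0]])
        auc_val = float("nan")
    return DecodingResult(accuracy=accuracy, auc=auc_val, decision_values=d,
                          true_labels=test.labels.copy(), roc_points=roc,
                          pattern=pattern, split_seed=split_seed)


def decode_pattern(table_ec: pd.DataFrame, table_eo: pd.DataFrame,
                   pattern: DiscriminativePattern, split_seed: int,
                   regularization: float = 1.0, by_subject: bool = False
                   ) -> DecodingResult:
    """assemble -> split -> train -> evaluate for one pattern."""
    samples = split_half(assemble_samples(table_ec, table_eo, pattern),
                         split_seed, by_subject=by_subject)
    model = train_linear_svm(samples.train, regularization)
    return evaluate(model, samples.test, pattern=pattern, split_seed=split_seed)


def run_criterion_comparison(table_ec: pd.DataFrame, table_eo: pd.DataFrame,
                             scores: RoiZScores | None = None,
                             criteria: list[SelectionCriterion] | None = None,
                             split_seeds: list[int] = (0,),
                             regularization: float = 1.0,
                             nested: bool = False
                             ) -> tuple[pd.DataFrame, dict[str, list[DecodingResult]]]:
    """Decode with each criterion's pattern; one row per criterion/seed.

    Returns ``(summary, results)``: the summary frame has columns
    criterion/n_rois/seed/accuracy/auc (NaN rows mark criteria whose
    pattern is empty); ``results`` maps criterion names to the
    per-seed :class:`DecodingResult` objects.

    ``nested=True`` runs the audit mode: for every seed a
    subject-stratified split is drawn first and the Z scores are
    recomputed from training subjects only.
    """
    criteria = list(criteria) if criteria is not None else study_criteria()
    if scores is None and not nested:
        scores = score_all_rois(table_ec, table_eo)
    rows, results = [], {c.name: [] for c in criteria}
    for seed in split_seeds:
        if nested:
            subjects = sorted(table_ec.index)
            if len(subjects) % 2:
                raise ValueError("nested mode needs an even subject count")
            rng = np.random.default_rng(seed)
            perm = rng.permutation(len(subjects))
            train_subj = [subjects[i] for i in perm[: len(subjects) // 2]]
            test_subj = [subjects[i] for i in perm[len(subjects) // 2:]]
            seed_scores = score_all_rois(table_ec.loc[train_subj], table_eo.loc[train_subj])
        else:
            seed_scores = scores
        for crit in criteria:
            pattern = select_pattern(seed_scores, crit)
            if len(pattern) == 0:
                rows.append({"criterion": crit.label, "n_rois": 0, "seed": seed,
                             "accuracy": np.nan, "auc": np.nan})
                continue
            if nested:
                samples = assemble_samples(table_ec, table_eo, pattern)
                split = np.array(["train" if s in set(train_subj) else "test"
                                  for s in samples.subject_ids], dtype=object)
                samples = SampleSet(samples.features, samples.labels,
                                    samples.subject_ids, samples.feature_names, split=split)
                model = train_linear_svm(samples.train, regularization)
                res = evaluate(model, samples.test, pattern=pattern, split_seed=seed)
            else:
                res = decode_pattern(table_ec, table_eo, pattern, seed, regularization)
            results[crit.name].append(res)
            rows.append({"criterion": crit.label, "n_rois": len(pattern), "seed": seed,
                         "accuracy": res.accuracy, "auc": res.auc})
    summary = pd.DataFrame(rows)
    return summary, results
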