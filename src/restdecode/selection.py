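"""Paired Wilcoxon signed-rank feature selection.

For every ROI, the per-subject eyes-closed minus eyes-open fALFF
differences are reduced to a signed standard-normal deviate Z via the
signed-rank test (normal approximation):

    W+ = sum of ranks of positive differences (midranks for ties)
    Z  = (W+ - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24 - sum(t^3 - t)/48)

with exact-zero differences dropped before ranking and no continuity
correction.  Positive Z means the eyes-closed median exceeds the
eyes-open one.  Discriminative patterns are ROI subsets passing one of
the four study criteria — |Z| > 1.96, Z > 1.96, Z > 2.25, Z < -1.96 —
with strict inequalities, ordered by descending |Z| (ties broken by
template order).

No multiple-testing correction is applied by default, matching the
procedure being modelled; ``fdr_threshold`` on :func:`select_pattern`
opts into Benjamini-Hochberg screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator, TransformerMixin

from .template import RoiTemplate

MIN_PAIRS = 5  # below this the normal approximation is meaningless


def _signed_rank_z(diffs: np.ndarray) -> tuple[float, int, bool]:
    """(z, n_pairs_used, degenerate) for one vector of paired diffs."""
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 1:
        raise ValueError("paired differences must be 1-D")
    if not np.all(np.isfinite(d)):
        raise ValueError("paired differences contain non-finite values")
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 0, True
    if n < MIN_PAIRS:
        raise ValueError(
            f"only {n} non-zero pairs; need >= {MIN_PAIRS} for the normal approximation"
        )
    ranks = scipy.stats.rankdata(np.abs(d))  # midranks
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_corr = float(((counts**3 - counts) / 48.0).sum())
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
    if var <= 0:
        return 0.0, n, True
    return (w_plus - mu) / np.sqrt(var), n, False


def wilcoxon_signed_rank_z(paired_diffs: np.ndarray) -> float:
    """Signed Z of the paired signed-rank test for one ROI.

    All-zero differences give Z = 0 (degenerate case); fewer than 5
    non-zero pairs is an error.
    """
    z, _, _ = _signed_rank_z(paired_diffs)
    return float(z)


@dataclass
class RoiZScores:
    """Per-ROI signed-rank Z scores for one paired cohort."""

    z: np.ndarray
    n_pairs: int
    roi_names: list[str]
    degenerate: np.ndarray
    modules: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.degenerate = np.asarray(self.degenerate, dtype=bool)
        if not np.all(np.isfinite(self.z)):
            raise ValueError("Z scores must be finite")
        if len(self.z) != len(self.roi_names) or len(self.z) != len(self.degenerate):
            raise ValueError("misaligned RoiZScores fields")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"roi": self.roi_names, "z": self.z, "degenerate": self.degenerate})
        if self.modules is not None:
            df.insert(1, "module", self.modules)
        for crit in study_criteria():
            df[f"selected_{crit.name}"] = crit.mask(self.z)
        return df

    @classmethod
    def from_template(cls, template: RoiTemplate, n_pairs: int = 0) -> "RoiZScores":
        """Scores carrying the template's companion (published) Z values."""
        z = template.z_values
        return cls(z=z, n_pairs=n_pairs, roi_names=template.roi_names,
                   degenerate=np.zeros(len(z), dtype=bool), modules=template.modules)


def score_all_rois(table_ec: pd.DataFrame, table_eo: pd.DataFrame,
                   template: RoiTemplate | None = None) -> RoiZScores:
    """One signed Z per ROI from per-condition subjects x ROIs tables.

    Subjects are paired by id (index), never by position; a mismatch in
    subject ids or ROI columns is an error naming the discrepancy.
    """
    missing = set(table_ec.index).symmetric_difference(table_eo.index)
    if missing:
        raise ValueError(f"subject ids not present in both conditions: {sorted(missing)}")
    if list(table_ec.columns) != list(table_eo.columns):
        raise ValueError("ROI columns differ between the two condition tables")
    eo = table_eo.loc[table_ec.index]
    diffs = table_ec.to_numpy(dtype=float) - eo.to_numpy(dtype=float)
    zs, degen = [], []
    for j in range(diffs.shape[1]):
        z, _, d = _signed_rank_z(diffs[:, j])
        zs.append(z)
        degen.append(d)
    modules = template.modules if template is not None else None
    if modules is not None and len(modules) != diffs.shape[1]:
        raise ValueError("template length does not match the feature tables")
    return RoiZScores(z=np.array(zs), n_pairs=diffs.shape[0],
                      roi_names=list(table_ec.columns),
                      degenerate=np.array(degen), modules=modules)


@dataclass(frozen=True)
class SelectionCriterion:
    """One of the four study selection rules (strict inequalities)."""

    name: str  # abs_gt | pos_gt | pos_gt_strict | neg_lt
    threshold: float

    _KINDS = ("abs_gt", "pos_gt", "pos_gt_strict", "neg_lt")

    def __post_init__(self) -> None:
        if self.name not in self._KINDS:
            raise ValueError(f"criterion name must be one of {self._KINDS}")
        if self.threshold <= 0:
            raise ValueError("threshold is given in positive standard-normal units")

    def mask(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if self.name == "abs_gt":
            return np.abs(z) > self.threshold
        if self.name in ("pos_gt", "pos_gt_strict"):
            return z > self.threshold
        return z < -self.threshold

    @property
    def label(self) -> str:
        if self.name == "abs_gt":
            return f"|Z| > {self.threshold:g}"
        if self.name == "neg_lt":
            return f"Z < -{self.threshold:g}"
        return f"Z > {self.threshold:g}"


def study_criteria() -> list[SelectionCriterion]:
    """The four criteria in published order."""
    return [
        SelectionCriterion("abs_gt", 1.96),
        SelectionCriterion("pos_gt", 1.96),
        SelectionCriterion("pos_gt_strict", 2.25),
        SelectionCriterion("neg_lt", 1.96),
    ]


@dataclass
class DiscriminativePattern:
    """ROI subset passing one criterion, ordered by descending |Z|."""

    criterion: SelectionCriterion
    roi_indices: np.ndarray
    roi_names: list[str]
    z_values: np.ndarray
    modules: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.roi_indices)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"roi_index": self.roi_indices, "roi": self.roi_names,
                           "z": self.z_values})
        if self.modules is not None:
            df["module"] = self.modules
        return df


def select_pattern(scores: RoiZScores, criterion: SelectionCriterion,
                   fdr_alpha: float | None = None) -> DiscriminativePattern:
    """Apply one criterion; empty selections are returned with a warning.

    ``fdr_alpha`` additionally requires the two-sided normal p-value to
    survive Benjamini-Hochberg at that level (off by default: the
    modelled procedure applies no multiplicity correction).
    """
    mask = criterion.mask(scores.z)
    if fdr_alpha is not None:
        p = 2.0 * scipy.stats.norm.sf(np.abs(scores.z))
        mask &= _bh_reject(p, fdr_alpha)
    idx = np.flatnonzero(mask)
    # descending |z|, stable on template order
    order = np.argsort(-np.abs(scores.z[idx]), kind="stable")
    idx = idx[order]
    if len(idx) == 0:
        import warnings

        warnings.warn(f"criterion {criterion.label} selects no ROI")
    return DiscriminativePattern(
        criterion=criterion,
        roi_indices=idx,
        roi_names=[scores.roi_names[i] for i in idx],
        z_values=scores.z[idx],
        modules=None if scores.modules is None else scores.modules[idx],
    )


def _bh_reject(p: np.ndarray, alpha: float) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, alpha=alpha, method="fdr_bh")[0]


def module_composition(pattern: DiscriminativePattern) -> pd.DataFrame:
    """Counts and percentages of template modules inside a pattern."""
    if len(pattern) == 0:
        raise ValueError("empty pattern has no module composition")
    if pattern.modules is None:
        raise ValueError("pattern carries no module labels")
    counts = pd.Series(pattern.modules).value_counts()
    df = pd.DataFrame({"count": counts})
    df["percent"] = 100.0 * df["count"] / len(pattern)
    df.index.name = "module"
    return df


class PairedWilcoxonSelector(BaseEstimator, TransformerMixin):
    """Feature selector over paired-difference input.

    ``fit(D)`` takes the subjects x ROIs matrix of paired (EC - EO)
    differences and stores per-ROI Z scores; ``transform(X)`` keeps the
    columns passing the criterion, ordered by descending |Z|.

    Attributes set by fit: ``z_``, ``support_`` (boolean mask in input
    order) and ``order_`` (selected column indices, |Z|-descending).
    """

    def __init__(self, criterion: str = "abs_gt", threshold: float = 1.96):
        self.criterion = criterion
        self.threshold = threshold

    def fit(self, X, y=None):
        D = np.asarray(X, dtype=float)
        if D.ndim != 2:
            raise ValueError("expected a 2-D subjects x ROIs difference matrix")
        crit = SelectionCriterion(self.criterion, self.threshold)
        zs = np.array([_signed_rank_z(D[:, j])[0] for j in range(D.shape[1])])
        self.z_ = zs
        self.support_ = crit.mask(zs)
        idx = np.flatnonzero(self.support_)
        self.order_ = idx[np.argsort(-np.abs(zs[idx]), kind="stable")]
        self.n_features_in_ = D.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.n_features_in_:
            raise ValueError("feature count differs from fit time")
        return X[..., self.order_]

    def get_support(self) -> np.ndarray:
        return self.support_.copy()
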