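"""Polygenic risk scores: log-OR weights, weighted allele sums, calibration.

The score for subject j is PRS_j = sum_i logOR_i * x_ij, where x_ij is the
risk-allele dosage (0/1/2) at SNP i and logOR_i the natural-log allelic odds
ratio. A one-feature logistic regression then maps the score to a case
probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from .assoc import allelic_association, _oriented_triple
from .genotype_data import GenotypeDataset, GenotypeMatrix

__all__ = ["PRSWeights", "PRSScore", "compute_weights", "compute_prs",
           "fit_prs_classifier", "PRSClassifier"]


@dataclass
class PRSWeights:
    """Ordered per-SNP natural-log odds-ratio weights."""

    snp_ids: list[str]
    log_or: np.ndarray

    def __post_init__(self) -> None:
        self.log_or = np.asarray(self.log_or, dtype=float)
        if self.log_or.shape != (len(self.snp_ids),):
            raise ValueError("one weight per SNP required")
        if not np.all(np.isfinite(self.log_or)):
            raise ValueError("weights must be finite")


@dataclass
class PRSScore:
    sample_id: str
    score: float


def compute_weights(
    dataset: GenotypeDataset,
    snp_ids: list[str],
    training_sample_ids: list[str] | None = None,
) -> PRSWeights:
    """Estimate log-OR weights on the training samples only (leakage guard).

    Re-runs the allelic association on the training subset and takes
    ln(OR); zero allele cells get the Haldane-Anscombe correction through
    the association routine. A SNP monomorphic in training gets weight 0
    with a warning. Pass ``training_sample_ids=None`` to estimate on the
    whole sample (the permissive variant).
    """
    if training_sample_ids is not None:
        idx = [dataset.sample_ids.index(s) for s in training_sample_ids]
        dataset = dataset.subset_samples(idx)
    sub = dataset.subset_snps(snp_ids)
    cases = sub.phenotypes == 1
    controls = sub.phenotypes == 0
    weights = np.zeros(len(snp_ids))
    for j, snp in enumerate(sub.snps):
        case_triple = _oriented_triple(sub, j, cases)
        ctrl_triple = _oriented_triple(sub, j, controls)
        # monomorphic in training: no risk-allele variation in either group
        total_risk = case_triple[1] + 2 * case_triple[2] + ctrl_triple[1] + 2 * ctrl_triple[2]
        total_nonrisk = 2 * case_triple[0] + case_triple[1] + 2 * ctrl_triple[0] + ctrl_triple[1]
        if total_risk == 0 or total_nonrisk == 0:
            warnings.warn(f"{snp.snp_id}: monomorphic in training data; weight set to 0")
            weights[j] = 0.0
            continue
        res = allelic_association(case_triple, ctrl_triple, snp_id=snp.snp_id)
        weights[j] = np.log(res.odds_ratio)
    return PRSWeights(list(snp_ids), weights)


def compute_prs(matrix: GenotypeMatrix, weights: PRSWeights) -> list[PRSScore]:
    """Exact weighted risk-allele sum per sample (no missing allowed)."""
    x = matrix.select(weights.snp_ids)
    if np.isnan(x).any():
        raise ValueError("matrix contains missing dosages; impute before scoring")
    scores = x @ weights.log_or
    return [PRSScore(sid, float(s)) for sid, s in zip(matrix.sample_ids, scores)]


class PRSClassifier:
    """One-feature logistic calibration of the PRS to case probability."""

    def __init__(self, model: LogisticRegression):
        self._model = model

    @property
    def slope(self) -> float:
        return float(self._model.coef_[0, 0])

    @property
    def intercept(self) -> float:
        return float(self._model.intercept_[0])

    def predict(self, scores) -> np.ndarray:
        """Case probability per sample from raw PRS values."""
        arr = np.asarray([s.score if isinstance(s, PRSScore) else s for s in scores],
                         dtype=float).reshape(-1, 1)
        return self._model.predict_proba(arr)[:, 1]


def fit_prs_classifier(train_scores, train_labels) -> PRSClassifier:
    """Fit the logistic score->probability map on training scores."""
    y = np.asarray(train_labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    x = np.asarray([s.score if isinstance(s, PRSScore) else s for s in train_scores],
                   dtype=float).reshape(-1, 1)
    model = LogisticRegression(C=1e6, solver="lbfgs", max_iter=2000)
    model.fit(x, y)
    return PRSClassifier(model)
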