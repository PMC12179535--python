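"""Median-split hypoxia metagene scoring and weak-label stratification.

The Buffa-style score of a sample is the sum over signature genes of +1 if
the sample's expression of that gene lies strictly above the cohort median
for that gene, else −1 (ties count as not-above).  With G signature genes
the score lies in [−G, +G] and has the parity of G.  Samples with a
positive score are labelled hypoxic; hypoxic samples are further split into
a low stratum (0 < score ≤ 20) and a high stratum (score > 20).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

__all__ = ["HypoxiaScore", "BuffaScorer", "buffa_score", "assign_stratum",
           "stratify_cohort"]

HIGH_CUTOFF = 20  # score > 20 → high stratum; 0 < score <= 20 → low


@dataclass
class HypoxiaScore:
    sample_id: str
    score: int
    binary_label: str  # 'hypoxic' | 'normoxic'
    stratum: str       # 'normoxic' | 'low' | 'high'


def assign_stratum(score: int) -> tuple:
    """Label map — a deterministic function of the score alone."""
    if score > HIGH_CUTOFF:
        return "hypoxic", "high"
    if score > 0:
        return "hypoxic", "low"
    return "normoxic", "normoxic"


class BuffaScorer(BaseEstimator, TransformerMixin):
    """Median-split ±1 metagene scorer (scikit-learn transformer).

    ``fit`` learns the per-gene cohort medians from a genes × samples
    expression DataFrame; ``transform`` scores samples against those
    medians.  Raising one signature gene's expression in one sample can
    never decrease that sample's score (each gene contributes ±1 through a
    monotone threshold).
    """

    def __init__(self, signature_genes):
        self.signature_genes = signature_genes

    def _validate(self, expr: pd.DataFrame):
        if not self.signature_genes:
            raise ValueError("signature gene list is empty")
        missing = [g for g in self.signature_genes if g not in expr.index]
        if missing:
            raise KeyError(
                f"signature genes missing from expression matrix: {missing}"
            )
        dupes = expr.index[expr.index.duplicated()].unique().tolist()
        if dupes:
            raise ValueError(f"duplicate gene identifiers in matrix: {dupes}")

    def fit(self, expr: pd.DataFrame, y=None):
        self._validate(expr)
        if expr.shape[1] < 2:
            raise ValueError("need at least 2 samples to define cohort medians")
        self.medians_ = expr.loc[list(self.signature_genes)].median(axis=1)
        return self

    def transform(self, expr: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "medians_")
        self._validate(expr)
        sig = expr.loc[list(self.signature_genes)]
        above = sig.gt(self.medians_, axis=0)  # strictly above; ties are -1
        scores = (2 * above.sum(axis=0) - len(self.signature_genes)).astype(int)
        rows = []
        for sample_id, score in scores.items():
            label, stratum = assign_stratum(int(score))
            rows.append({"sample_id": sample_id, "score": int(score),
                         "binary_label": label, "stratum": stratum})
        return pd.DataFrame(rows).set_index("sample_id")

    def fit_transform(self, expr: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(expr).transform(expr)


def buffa_score(expr: pd.DataFrame, signature) -> list:
    """Score a cohort; returns a list of :class:`HypoxiaScore` records."""
    table = BuffaScorer(list(signature)).fit_transform(expr)
    return [HypoxiaScore(sample_id=str(sid), score=int(r.score),
                         binary_label=r.binary_label, stratum=r.stratum)
            for sid, r in table.iterrows()]


def stratify_cohort(scores, n_splits: int = 3, train_frac: float = 0.75,
                    seed: int = 0, max_retries: int = 20) -> list:
    """Seeded independent train/test splits, stratified by binary label.

    Returns a list of ``{"train": [...], "test": [...]}`` manifests (sample
    IDs).  A split leaving a class absent from either side is redrawn; after
    ``max_retries`` redraws an error is raised.
    """
    if isinstance(scores, pd.DataFrame):
        ids = scores.index.to_numpy()
        labels = scores["binary_label"].to_numpy()
    else:
        ids = np.array([s.sample_id for s in scores])
        labels = np.array([s.binary_label for s in scores])
    if len(ids) < 8:
        raise ValueError(f"need at least 8 samples to split, got {len(ids)}")
    splits = []
    for k in range(n_splits):
        for attempt in range(max_retries):
            train_ids, test_ids, ytr, yte = train_test_split(
                ids, labels, train_size=train_frac,
                random_state=seed * 1000 + k * max_retries + attempt,
                stratify=labels,
            )
            if len(np.unique(ytr)) == 2 and len(np.unique(yte)) == 2:
                splits.append({"train": sorted(train_ids.tolist()),
                               "test": sorted(test_ids.tolist())})
                break
        else:
            raise RuntimeError(
                f"split {k}: a class was absent from one side after "
                f"{max_retries} redraws; cohort too small or too imbalanced"
            )
    return splits
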