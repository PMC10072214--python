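"""Feature-space reduction: log-rank screening and PCA components.

The stable feature pool is optionally screened by univariate survival
stratification — each feature dichotomized at its Youden-index cutoff,
groups compared by the two-group log-rank test, selection at p < alpha
with no multiplicity correction — and then projected onto the first
five principal components of the standardized features (RPC0..RPC4 for
radiomics, DPC0..DPC4 for dosiomics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .survival import SurvivalData, logrank_test

__all__ = ["PCModel", "ScreenResult", "youden_cutoff", "screen_features", "fit_pca"]


def youden_cutoff(values: np.ndarray, event: np.ndarray) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are midpoints between consecutive sorted unique values;
    a value above the cutoff predicts event = 1. Ties in J break toward
    the lower threshold.
    """
    values = np.asarray(values, dtype=float)
    event = np.asarray(event).astype(int)
    if values.shape != event.shape:
        raise ValueError("values and event must have the same length")
    if len(np.unique(event)) < 2:
        raise ValueError("Youden cutoff needs both event classes present")
    uniq = np.unique(values)
    if len(uniq) < 2:
        raise ValueError("all values identical: no valid split")
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    pos = event == 1
    n_pos, n_neg = pos.sum(), (~pos).sum()
    best_j, best_cut = -np.inf, cuts[0]
    for c in cuts:
        pred = values > c
        sens = (pred & pos).sum() / n_pos
        spec = (~pred & ~pos).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j:  # strict: first (lowest) cutoff wins ties
            best_j, best_cut = j, c
    return float(best_cut)


@dataclass
class ScreenResult:
    """Univariate log-rank screen over a feature table."""

    table: pd.DataFrame  # feature, cutoff, chi2, p, selected, reason
    alpha: float

    @property
    def selected(self) -> list[str]:
        return self.table.loc[self.table["selected"], "feature"].tolist()


def screen_features(
    features: pd.DataFrame, outcomes: SurvivalData, alpha: float = 0.05
) -> ScreenResult:
    """Select features that stratify survival at their Youden cutoff."""
    if not np.isfinite(features.to_numpy()).all():
        raise ValueError("feature table contains non-finite values")
    rows = []
    for feat in features.columns:
        vals = features[feat].to_numpy(dtype=float)
        rec = {"feature": feat, "cutoff": np.nan, "chi2": np.nan, "p": np.nan,
               "selected": False, "reason": ""}
        try:
            cut = youden_cutoff(vals, outcomes.event)
            hi = vals > cut
            if hi.all() or (~hi).all():
                raise ValueError("degenerate split: one group empty")
            chi2, p = logrank_test(outcomes.subset(hi), outcomes.subset(~hi))
            rec.update(cutoff=cut, chi2=chi2, p=p, selected=bool(p < alpha))
        except ValueError as exc:
            rec["reason"] = str(exc)
        rows.append(rec)
    return ScreenResult(pd.DataFrame(rows), alpha)


@dataclass
class PCModel:
    """Standardize-then-project PCA model with per-patient scores.

    Loadings are orthonormal rows ordered by explained variance; each
    loading's largest-magnitude entry is made positive so component
    signs are reproducible.
    """

    feature_names: list[str]
    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray  # (n_components, n_features)
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame  # patients x {prefix}{0..n-1}
    prefix: str

    def transform(self, features: pd.DataFrame) -> pd.DataFrame:
        """Project new patients with the stored means/scales/loadings."""
        x = features[self.feature_names].to_numpy(dtype=float)
        z = (x - self.means) / self.scales
        scores = z @ self.loadings.T
        cols = [f"{self.prefix}{i}" for i in range(self.loadings.shape[0])]
        return pd.DataFrame(scores, index=features.index, columns=cols)


def fit_pca(features: pd.DataFrame, n_components: int = 5, prefix: str = "PC") -> PCModel:
    """PCA of z-scored features, keeping the first ``n_components``.

    Constant features carry no variance and are dropped with a warning
    before standardization.
    """
    if len(features) < 2:
        raise ValueError("PCA needs at least 2 patients")
    x = features.to_numpy(dtype=float)
    sd = x.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant feature(s) before PCA",
            stacklevel=2,
        )
    names = [c for c, k in zip(features.columns, keep) if k]
    if len(names) < n_components:
        raise ValueError(
            f"only {len(names)} non-constant features for {n_components} components"
        )
    x = x[:, keep]
    means = x.mean(axis=0)
    scales = x.std(axis=0)
    z = (x - means) / scales
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(z)
    loadings = pca.components_.copy()
    # fix signs: largest-|entry| of each loading vector is positive
    for row in loadings:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1
    scores = z @ loadings.T
    cols = [f"{prefix}{i}" for i in range(n_components)]
    return PCModel(
        feature_names=names,
        means=means,
        scales=scales,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        scores=pd.DataFrame(scores, index=features.index, columns=cols),
        prefix=prefix,
    )
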