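"""Canonical correlation overview of descriptors vs physical properties.

Before CCorA the descriptor set is thinned with a pairwise-correlation
filter (|Pearson r| < 0.4 within one measurement method, < 0.3 for the
pooled all-method set), which also guarantees a full-rank descriptor block
with fewer columns than samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .descriptors import DescriptorTable

__all__ = ["CCorAResult", "correlation_filter", "ccora"]

#: Correlation caps: within one measurement method vs the pooled set.
R_MAX_PER_METHOD = 0.4
R_MAX_ALL = 0.3


@dataclass(frozen=True)
class CCorAResult:
    canonical_correlations: np.ndarray          # non-increasing, in [0, 1]
    property_scores: pd.DataFrame               # properties x axes
    descriptor_scores: pd.DataFrame             # descriptors x axes

    def __post_init__(self) -> None:
        c = np.asarray(self.canonical_correlations, dtype=float)
        if (np.diff(c) > 1e-9).any():
            raise ValueError("canonical correlations must be non-increasing")
        if c.min() < -1e-9 or c.max() > 1.0 + 1e-9:
            raise ValueError("canonical correlations must lie in [0, 1]")
        object.__setattr__(self, "canonical_correlations", np.clip(c, 0, 1))


def _greedy_filter(data: pd.DataFrame, r_max: float,
                   order: str) -> list[str]:
    variances = data.var(axis=0, ddof=1)
    constant = variances[variances <= 0].index
    if len(constant):
        warnings.warn(f"excluding constant descriptors: {list(constant)}")
    cols = [c for c in data.columns if variances[c] > 0]
    if order == "variance":
        cols = sorted(cols, key=lambda c: (-variances[c], c))
    elif order != "stored":
        raise ValueError("order must be 'stored' or 'variance'")
    corr = np.corrcoef(data[cols].to_numpy(dtype=float), rowvar=False)
    corr = np.atleast_2d(corr)
    kept_idx: list[int] = []
    for j in range(len(cols)):
        if all(abs(corr[j, i]) < r_max for i in kept_idx):
            kept_idx.append(j)
    return [cols[j] for j in kept_idx]


def correlation_filter(table: DescriptorTable, r_max: float | None = None,
                       scope: str = "all",
                       order: str = "stored") -> DescriptorTable:
    """Greedy forward pass keeping descriptors with all pairwise |r| < r_max.

    ``scope='per_method'`` applies the cap within each modality separately
    (default cap 0.4) and unions the survivors; ``scope='all'`` applies one
    pooled cap (default 0.3).  Constant descriptors are excluded with a
    warning.  The pass runs in stored column order by default
    (``order='variance'`` visits high-variance columns first).
    """
    if scope not in ("all", "per_method"):
        raise ValueError("scope must be 'all' or 'per_method'")
    if r_max is None:
        r_max = R_MAX_ALL if scope == "all" else R_MAX_PER_METHOD
    if not 0.0 < r_max < 1.0:
        raise ValueError("r_max must lie in (0, 1)")
    if scope == "all":
        kept = _greedy_filter(table.data, r_max, order)
    else:
        kept = []
        modalities = []
        for did in table.descriptor_ids:
            m = table.meta[did].modality
            if m not in modalities:
                modalities.append(m)
        for m in modalities:
            cols = [d for d in table.descriptor_ids
                    if table.meta[d].modality == m]
            kept.extend(_greedy_filter(table.data[cols], r_max, order))
    return table.subset(kept)


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    if (sd <= 0).any():
        raise ValueError("constant column; filter the table first")
    return (X - X.mean(axis=0)) / sd


def ccora(X, Y, x_names=None, y_names=None) -> CCorAResult:
    """Canonical correlation analysis of two standardized variable blocks.

    Canonical correlations are the singular values of Qx' Qy where Qx, Qy
    are orthonormal bases of the centered blocks.  Reported variable scores
    are the Pearson correlations of each variable with the canonical
    variates of its own block; each axis is oriented so that the property
    with the largest |score| is positive.
    """
    X = np.asarray(getattr(X, "to_numpy", lambda: X)(), dtype=float)
    Y = np.asarray(getattr(Y, "to_numpy", lambda: Y)(), dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("row mismatch between blocks")
    n_axes = min(X.shape[1], Y.shape[1], n - 1)
    if n <= max(X.shape[1], Y.shape[1]):
        warnings.warn("fewer samples than variables; canonical correlations "
                      "saturate — apply the correlation filter first")
    Xs, Ys = _standardize(X), _standardize(Y)
    qx, rx = np.linalg.qr(Xs)
    qy, ry = np.linalg.qr(Ys)
    if np.linalg.matrix_rank(ry) < Y.shape[1]:
        raise ValueError("rank-deficient property block")
    u, s, vt = np.linalg.svd(qx.T @ qy)
    s = s[:n_axes]
    cx = qx @ u[:, :n_axes]          # canonical variates (unit norm)
    cy = qy @ vt.T[:, :n_axes]

    def _scores(block: np.ndarray, variates: np.ndarray) -> np.ndarray:
        b = block / np.linalg.norm(block, axis=0)
        v = variates / np.linalg.norm(variates, axis=0)
        return b.T @ v

    prop_scores = _scores(Ys, cy)
    desc_scores = _scores(Xs, cx)
    flip = np.where(
        prop_scores[np.argmax(np.abs(prop_scores), axis=0),
                    np.arange(n_axes)] < 0, -1.0, 1.0)
    prop_scores *= flip
    desc_scores *= flip
    axes = [f"axis{k + 1}" for k in range(n_axes)]
    if x_names is None:
        x_names = [f"x{j + 1}" for j in range(X.shape[1])]
    if y_names is None:
        y_names = [f"y{j + 1}" for j in range(Y.shape[1])]
    return CCorAResult(
        canonical_correlations=np.clip(s, 0.0, 1.0),
        property_scores=pd.DataFrame(prop_scores, index=list(y_names),
                                     columns=axes),
        descriptor_scores=pd.DataFrame(desc_scores, index=list(x_names),
                                       columns=axes))
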