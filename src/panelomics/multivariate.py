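"""Autoscaling and principal component analysis of genotype means.

Multivariate overviews run on genotype means (one row per genotype, or per
genotype-stage cell for combined-stage runs), each trait centred and scaled
to unit variance first so that levels with very different measurement scales
contribute equally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


def autoscale(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Centre each column to mean 0 and scale to unit (sample) variance.

    Zero-variance columns are dropped with a warning — they carry no
    between-genotype information and would divide by zero.
    """
    m = matrix.astype(float)
    if m.shape[0] < 2:
        raise ValueError("autoscaling needs at least two rows")
    sd = m.std(axis=0, ddof=ddof)
    dead = sd[(sd == 0) | sd.isna()].index.tolist()
    if dead:
        warnings.warn(f"dropping {len(dead)} zero-variance column(s): {dead[:5]}")
        m = m.drop(columns=dead)
        sd = sd.drop(index=dead)
    return (m - m.mean(axis=0)) / sd


@dataclass
class PCAResult:
    """Scores (rows x components), loadings (traits x components) and the
    percentage of total variance each component explains."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def reconstruct(self) -> pd.DataFrame:
        """Back-project scores through loadings (identity at full rank)."""
        return pd.DataFrame(
            self.scores.to_numpy() @ self.loadings.to_numpy().T,
            index=self.scores.index, columns=self.loadings.index,
        )


def pca(matrix: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """Classical PCA of an autoscaled matrix via singular value decomposition.

    Input rows are observations (genotypes or genotype-stage cells); columns
    are traits, assumed already centred/scaled (see :func:`autoscale`).
    Columns containing any missing value are dropped with a warning.
    Loadings are orthonormal eigenvectors of the covariance matrix; the sign
    of each component is fixed so its largest-magnitude loading is positive.
    """
    m = matrix.astype(float)
    with_na = m.columns[m.isna().any()].tolist()
    if with_na:
        warnings.warn(f"dropping {len(with_na)} trait(s) with missing means: {with_na[:5]}")
        m = m.drop(columns=with_na)
    if m.shape[1] == 0:
        raise ValueError("no complete traits left for PCA")
    x = m.to_numpy()
    x = x - x.mean(axis=0)  # re-centre defensively; no-op on autoscaled input
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    k = rank if n_components is None else int(n_components)
    if k > rank:
        warnings.warn(f"n_components={k} exceeds rank {rank}; truncating")
        k = rank
    eigvals = s**2 / max(x.shape[0] - 1, 1)
    total = eigvals.sum()
    var_pct = 100.0 * eigvals[:k] / total if total > 0 else np.zeros(k)
    loadings = vt[:k].T.copy()
    scores = u[:, :k] * s[:k]
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(k):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=m.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=m.columns, columns=comp_names),
        variance_explained=var_pct,
    )
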