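"""Sparse partial least squares (sPLS) and similarity-network reconstruction.

sPLS in regression mode relates a predictor block X (here: protein-spot
volumes) to a response block Y (metabolites, enzyme activities, phenotypes),
both as autoscaled genotype-mean matrices with matched rows.  Each component
extracts a pair of unit-norm loading vectors (u, v) maximizing the
covariance between the latent variates t = X u and s = Y v, with
soft-thresholding that keeps only the ``keep_x`` (resp. ``keep_y``)
largest-magnitude loading entries — the sparsity that suppresses noise
variables when p, q far exceed the sample count.  After each component both
blocks are deflated on the X-variate (regression mode).

The network is rebuilt from the model through a similarity matrix
M[j, k] = sum_h cor(X_j, t_h) * cor(Y_k, t_h); entries with |M| at or above
a threshold (0.7 by default) become signed bipartite edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .multivariate import autoscale
from .network import Edge, TraitNetwork
from .panel import PanelError, TraitTable


class ConvergenceError(RuntimeError):
    """Raised when the power iterations of a component fail to converge."""


@dataclass
class SPLSModel:
    """Fitted sPLS model.

    ``x_weights``/``y_weights`` hold the sparse unit-norm loading vectors
    (variables x components); ``x_variates``/``y_variates`` the per-sample
    latent scores; ``keep_x``/``keep_y`` the retained-variable budget per
    component; ``n_iter`` the iterations each component used.
    """

    x_weights: pd.DataFrame
    y_weights: pd.DataFrame
    x_variates: pd.DataFrame
    y_variates: pd.DataFrame
    keep_x: list
    keep_y: list
    n_iter: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.x_weights.shape[1]


def _soft_keep(w: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold w so at most ``keep`` entries stay non-zero."""
    if keep >= len(w):
        return w.copy()
    if keep < 1:
        raise PanelError("keep must be >= 1")
    mags = np.abs(w)
    lam = np.partition(mags, len(w) - keep - 1)[len(w) - keep - 1]
    out = np.sign(w) * np.maximum(mags - lam, 0.0)
    return out


def _as_keep_list(keep, size: int, n_components: int, default: int) -> list:
    if keep is None:
        keep = default
    if np.isscalar(keep):
        keep = [int(keep)] * n_components
    keep = [min(int(k), size) for k in keep]
    if len(keep) != n_components:
        raise PanelError("keep list length must equal n_components")
    if any(k < 1 for k in keep):
        raise PanelError("keep counts must be >= 1")
    return keep


def spls_fit(X: pd.DataFrame, Y: pd.DataFrame, n_components: int = 3,
             keep_x=None, keep_y=None, max_iter: int = 500,
             tol: float = 1e-9) -> SPLSModel:
    """Fit a regression-mode sPLS model on matched autoscaled matrices.

    ``keep_x`` defaults to min(20, p) and ``keep_y`` to q (no sparsity on
    the response block); either may be a scalar or a per-component list.
    """
    if X.shape[0] != Y.shape[0] or not X.index.equals(Y.index):
        raise PanelError("X and Y must share an identical row (genotype) index")
    if X.shape[1] == 0 or Y.shape[1] == 0:
        raise PanelError("X and Y must each have at least one column")
    p, q = X.shape[1], Y.shape[1]
    keep_x = _as_keep_list(keep_x, p, n_components, default=min(20, p))
    keep_y = _as_keep_list(keep_y, q, n_components, default=q)

    Xd = X.to_numpy(dtype=float).copy()
    Yd = Y.to_numpy(dtype=float).copy()
    us, vs, ts, ss, iters = [], [], [], [], []
    for h in range(n_components):
        M = Xd.T @ Yd
        scale = np.linalg.norm(M)
        if scale <= 1e-12:
            raise PanelError(f"zero cross-covariance at component {h + 1}")
        # initialize from the dominant right singular vector of M
        _, _, vt = np.linalg.svd(M, full_matrices=False)
        v = vt[0]
        u = np.zeros(p)
        for it in range(1, max_iter + 1):
            u_new = _soft_keep(M @ v, keep_x[h])
            nu = np.linalg.norm(u_new)
            if nu <= 1e-15:
                raise ConvergenceError(f"component {h + 1}: X loading collapsed to zero")
            u_new /= nu
            v_new = _soft_keep(M.T @ u_new, keep_y[h])
            nv = np.linalg.norm(v_new)
            if nv <= 1e-15:
                raise ConvergenceError(f"component {h + 1}: Y loading collapsed to zero")
            v_new /= nv
            # sign-invariant change measure (power iterations may flip sign)
            du = min(np.abs(u_new - u).max(), np.abs(u_new + u).max())
            dv = min(np.abs(v_new - v).max(), np.abs(v_new + v).max())
            u, v = u_new, v_new
            if du < tol and dv < tol:
                break
        else:
            raise ConvergenceError(
                f"sPLS component {h + 1} did not converge in {max_iter} iterations")
        # fixed sign convention: largest-|entry| of the X loading positive
        i_max = int(np.argmax(np.abs(u)))
        if u[i_max] < 0:
            u, v = -u, -v
        t = Xd @ u
        s = Yd @ v
        tt = float(t @ t)
        if tt <= 1e-15:
            raise ConvergenceError(f"component {h + 1}: degenerate X variate")
        # regression-mode deflation: both blocks regressed on the X variate
        Xd = Xd - np.outer(t, (t @ Xd) / tt)
        Yd = Yd - np.outer(t, (t @ Yd) / tt)
        us.append(u); vs.append(v); ts.append(t); ss.append(s); iters.append(it)

    comp = [f"comp{h + 1}" for h in range(n_components)]
    return SPLSModel(
        x_weights=pd.DataFrame(np.column_stack(us), index=X.columns, columns=comp),
        y_weights=pd.DataFrame(np.column_stack(vs), index=Y.columns, columns=comp),
        x_variates=pd.DataFrame(np.column_stack(ts), index=X.index, columns=comp),
        y_variates=pd.DataFrame(np.column_stack(ss), index=X.index, columns=comp),
        keep_x=keep_x, keep_y=keep_y, n_iter=iters,
    )


def _safe_corr(matrix: np.ndarray, variates: np.ndarray) -> np.ndarray:
    """Column-wise correlations of matrix columns with each variate."""
    mc = matrix - matrix.mean(axis=0)
    vc = variates - variates.mean(axis=0)
    msd = np.sqrt((mc**2).sum(axis=0))
    vsd = np.sqrt((vc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (mc.T @ vc) / np.outer(msd, vsd)
    return np.nan_to_num(out)


def similarity_matrix(model: SPLSModel, X: pd.DataFrame, Y: pd.DataFrame) -> pd.DataFrame:
    """p x q signed similarity scores reconstructed from the latent variates.

    M[j, k] = sum over components h of cor(X_j, t_h) * cor(Y_k, t_h), with
    t_h the X-variates.  With one component every entry lies in [-1, 1].
    """
    t = model.x_variates.to_numpy(dtype=float)
    cx = _safe_corr(X.to_numpy(dtype=float), t)
    cy = _safe_corr(Y.to_numpy(dtype=float), t)
    return pd.DataFrame(cx @ cy.T, index=X.columns, columns=Y.columns)


def build_network(M: pd.DataFrame, threshold: float = 0.7,
                  x_levels: Mapping[str, str] | None = None,
                  y_levels: Mapping[str, str] | None = None) -> TraitNetwork:
    """Threshold a similarity matrix into a signed bipartite network.

    Edge (X_j, Y_k, M[j, k]) exists iff |M[j, k]| >= threshold; nodes
    without any edge are dropped.
    """
    x_levels = dict(x_levels or {})
    y_levels = dict(y_levels or {})
    edges = []
    arr = M.to_numpy(dtype=float)
    for j, xj in enumerate(M.index):
        for k, yk in enumerate(M.columns):
            w = arr[j, k]
            if abs(w) >= threshold:
                edges.append(Edge(str(xj), str(yk), float(w), "spls"))
    nodes = {}
    for e in edges:
        nodes[e.node_a] = x_levels.get(e.node_a, "protein_spot")
        nodes[e.node_b] = y_levels.get(e.node_b, "unknown")
    return TraitNetwork(nodes=nodes, edges=edges)


def spls_network(table: TraitTable, stage: str, x_level: str = "protein_spot",
                 y_levels: Sequence[str] = ("metabolite", "enzyme", "phenotype"),
                 x_traits: Sequence[str] | None = None,
                 y_traits: Sequence[str] | None = None,
                 threshold: float = 0.7, **fit_kwargs):
    """Within-stage convenience pipeline: means -> autoscale -> fit -> network.

    Returns (model, similarity matrix, network).
    """
    return lagged_network(table, stage, stage, x_level=x_level, y_levels=y_levels,
                          x_traits=x_traits, y_traits=y_traits,
                          threshold=threshold, **fit_kwargs)


def lagged_network(table: TraitTable, x_stage: str, y_stage: str,
                   x_level: str = "protein_spot",
                   y_levels: Sequence[str] = ("metabolite", "enzyme", "phenotype"),
                   x_traits: Sequence[str] | None = None,
                   y_traits: Sequence[str] | None = None,
                   threshold: float = 0.7, **fit_kwargs):
    """sPLS network with X taken at one stage and Y at another.

    With ``x_stage == y_stage`` this is the within-stage network; with
    ``x_stage='CE', y_stage='OR'`` it probes how early protein variation
    connects to later composition.  Genotype sets must match across stages.
    """
    x_ids = list(x_traits) if x_traits is not None else table.traits_at_level(x_level)
    y_ids = list(y_traits) if y_traits is not None else table.traits_at_level(list(y_levels))
    if not x_ids or not y_ids:
        raise PanelError("empty X or Y trait set for sPLS")
    mx = table.genotype_means(stage=x_stage, trait_ids=x_ids)
    my = table.genotype_means(stage=y_stage, trait_ids=y_ids)
    if not mx.index.equals(my.index):
        raise PanelError(f"genotype sets differ between stages {x_stage} and {y_stage}")
    X = autoscale(mx)
    Y = autoscale(my)
    model = spls_fit(X, Y, **fit_kwargs)
    M = similarity_matrix(model, X, Y)
    levels = table.traits.loc[:, "level"].to_dict()
    net = build_network(M, threshold=threshold, x_levels=levels, y_levels=levels)
    return model, M, net
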