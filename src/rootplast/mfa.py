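"""Multiple factor analysis (MFA) for grouped trait tables, from scratch.

MFA balances groups of variables before a joint ordination: each group's
standardized submatrix is divided by the square root of the first eigenvalue
of its own PCA, so no single high-dimensional or high-variance group can
dominate the global axes.  A global PCA (SVD) of the concatenated weighted
matrix then yields eigenvalues, observation scores, variable coordinates
(correlations with the axes), contributions and squared cosines, group
coordinates, and the RV and Lg association matrices between groups —
including each group's association with the consensus ("mean
configuration") of the global analysis.

Conventions (fixed and documented):

* active columns are centered and scaled to unit variance with the
  observation-count divisor n, so the first-eigenvalue normalization and the
  Lg coefficient are mutually consistent;
* each global axis is oriented so that its largest-magnitude variable
  loading is positive (SVD signs are otherwise arbitrary);
* categorical columns (genotype identity, P rate) are supplementary only:
  their levels are projected as barycenters of observation scores and never
  influence the axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .trait_data import PhenotypeTable

__all__ = [
    "MFAResult",
    "mfa_fit",
    "rv_coefficient",
    "lg_coefficient",
    "contribution_cutoff",
    "cell_mean_matrix",
]


@dataclass
class MFAResult:
    eigenvalues: np.ndarray            # all positive eigenvalues of the global PCA
    pct_variance: np.ndarray           # percent of total inertia, sums to 100
    row_scores: pd.DataFrame           # observations x retained dims
    variable_coords: pd.DataFrame      # variables x dims (correlation coords)
    variable_contrib: pd.DataFrame     # percent, sums to 100 per dim
    variable_cos2: pd.DataFrame
    group_coords: pd.DataFrame         # Lg(group, axis) per retained dim
    group_contrib: pd.DataFrame        # percent, sums to 100 per dim
    rv: pd.DataFrame                   # groups (+ "MFA" consensus) x groups
    lg: pd.DataFrame
    group_lambda1: dict[str, float]
    column_weights: pd.Series
    supplementary_coords: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def n_dims(self) -> int:
        return self.row_scores.shape[1]


def _standardize(X: np.ndarray) -> np.ndarray:
    """Center and unit-variance scale (divisor n) each column."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # ddof=0
    if np.any(sd == 0):
        raise ValueError("constant active column(s) after centering")
    return (X - mu) / sd


def _first_eigenvalue(X: np.ndarray) -> float:
    """Largest eigenvalue of the divisor-n covariance operator of X."""
    n = X.shape[0]
    s = np.linalg.svd(X, compute_uv=False)
    return float(s[0] ** 2 / n)


def rv_coefficient(X: np.ndarray, Y: np.ndarray) -> float:
    """RV similarity between two column-centered configurations, in [0, 1].

    RV = tr(W_X W_Y) / sqrt(tr(W_X^2) tr(W_Y^2)) with W = X X' the
    observation-space cross-product operator; invariant to rescaling either
    block.  A zero block is undefined and raises.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("row counts differ")
    cross = float(np.sum((X.T @ Y) ** 2))       # tr(WX WY) = ||X'Y||_F^2
    nx = float(np.sum((X.T @ X) ** 2))
    ny = float(np.sum((Y.T @ Y) ** 2))
    if nx == 0.0 or ny == 0.0:
        raise ValueError("RV undefined for a zero matrix")
    return cross / np.sqrt(nx * ny)


def lg_coefficient(
    X: np.ndarray,
    Y: np.ndarray,
    lambda1_X: float | None = None,
    lambda1_Y: float | None = None,
) -> float:
    """Lg link between two centered groups: tr(W_X W_Y)/(lambda1_X lambda1_Y).

    W is the divisor-n cross-product operator (1/n) X X'.  For a group with
    eigenvalues lambda_i, Lg(X, X) = sum_i (lambda_i/lambda_1)^2 >= 1, an
    indicator of the group's effective dimensionality.  The identity
    RV(X, Y) = Lg(X, Y)/sqrt(Lg(X, X) Lg(Y, Y)) holds by construction.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("row counts differ")
    n = X.shape[0]
    if lambda1_X is None:
        lambda1_X = _first_eigenvalue(X)
    if lambda1_Y is None:
        lambda1_Y = _first_eigenvalue(Y)
    if lambda1_X <= 0 or lambda1_Y <= 0:
        raise ValueError("first eigenvalues must be positive")
    cross = float(np.sum((X.T @ Y / n) ** 2))
    return cross / (lambda1_X * lambda1_Y)


def contribution_cutoff(n_items: int) -> float:
    """Uniform-contribution baseline 100/n_items percent.

    Contributions sum to 100 within a dimension, so an item contributing
    more than 100/n_items is an above-average contributor.
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    return 100.0 / n_items


def mfa_fit(
    X: pd.DataFrame,
    groups: Mapping[str, str],
    n_dims: int = 5,
    supplementary: pd.DataFrame | None = None,
) -> MFAResult:
    """Fit an MFA on an observations x variables table with grouped columns.

    ``groups`` maps every active column of ``X`` to its group label.
    ``supplementary`` optionally carries categorical columns (same rows as
    ``X``) whose levels are projected as barycenters.
    """
    cols = list(X.columns)
    missing = [c for c in cols if c not in groups]
    if missing:
        raise ValueError(f"columns without a group assignment: {missing}")
    if len(X) < 2:
        raise ValueError("need >= 2 observations")
    group_names = list(dict.fromkeys(groups[c] for c in cols))

    raw = X.to_numpy(dtype=float)
    n = raw.shape[0]
    sd = raw.std(axis=0)
    if np.any(sd == 0):
        bad = [c for c, s in zip(cols, sd) if s == 0]
        raise ValueError(f"constant active column(s): {bad}")
    Xs = _standardize(raw)

    # per-group first-eigenvalue weights
    col_idx = {gname: [i for i, c in enumerate(cols) if groups[c] == gname] for gname in group_names}
    lambda1: dict[str, float] = {}
    for gname, idx in col_idx.items():
        sub = Xs[:, idx]
        if not np.any(sub):
            raise ValueError(f"group {gname!r} is all-zero after centering")
        lambda1[gname] = _first_eigenvalue(sub)
    cw = np.array([1.0 / lambda1[groups[c]] for c in cols])  # column weights

    # global weighted PCA via SVD of (1/sqrt(n)) X diag(sqrt(cw))
    B = (Xs * np.sqrt(cw)) / np.sqrt(n)
    U, S, Vt = np.linalg.svd(B, full_matrices=False)
    pos = S > S[0] * 1e-12 if S[0] > 0 else S > 0
    U, S, Vt = U[:, pos], S[pos], Vt[pos]
    rank = S.size
    if n_dims > rank:
        import warnings

        warnings.warn(f"n_dims={n_dims} exceeds rank {rank}; truncating", RuntimeWarning)
        n_dims = rank

    # deterministic axis orientation: largest-|loading| positive
    V = Vt.T
    for s in range(rank):
        j = int(np.argmax(np.abs(V[:, s])))
        if V[j, s] < 0:
            V[:, s] = -V[:, s]
            U[:, s] = -U[:, s]

    eig = S**2
    pct = 100.0 * eig / eig.sum()
    dims = [f"dim{s + 1}" for s in range(rank)]

    F = np.sqrt(n) * U * S                   # observation scores, var(F_s) = eig_s
    G_full = (V * S) / np.sqrt(cw)[:, None]  # variable correlation coordinates
    contrib = 100.0 * V**2
    cos2 = G_full**2 / np.sum(G_full**2, axis=1, keepdims=True)

    # group coordinate on axis s = Lg(group, unit-variance axis s)
    #   = sum_{v in g} c_v * coord_vs^2 ; summed over groups it equals eig_s,
    # so group contributions (percent of the axis) are 100 * coord / eig.
    gcoord = np.zeros((len(group_names), rank))
    for gi, gname in enumerate(group_names):
        idx = col_idx[gname]
        gcoord[gi] = np.sum(cw[idx, None] * G_full[idx, :] ** 2, axis=0)
    gcontrib = 100.0 * gcoord / eig

    # RV / Lg matrices, with the weighted concatenation as consensus "MFA"
    blocks = {gname: Xs[:, col_idx[gname]] for gname in group_names}
    weighted_all = Xs * np.sqrt(cw)
    lam_all = _first_eigenvalue(weighted_all)
    names_ext = group_names + ["MFA"]
    blocks_ext = {**blocks, "MFA": weighted_all}
    lam_ext = {**lambda1, "MFA": lam_all}
    k = len(names_ext)
    rv = np.eye(k)
    lg = np.zeros((k, k))
    for i, a in enumerate(names_ext):
        for j in range(i, k):
            b = names_ext[j]
            lg_ij = lg_coefficient(blocks_ext[a], blocks_ext[b], lam_ext[a], lam_ext[b])
            lg[i, j] = lg[j, i] = lg_ij
            if i != j:
                rv[i, j] = rv[j, i] = rv_coefficient(blocks_ext[a], blocks_ext[b])

    result = MFAResult(
        eigenvalues=eig,
        pct_variance=pct,
        row_scores=pd.DataFrame(F[:, :n_dims], index=X.index, columns=dims[:n_dims]),
        variable_coords=pd.DataFrame(G_full[:, :n_dims], index=cols, columns=dims[:n_dims]),
        variable_contrib=pd.DataFrame(contrib[:, :n_dims], index=cols, columns=dims[:n_dims]),
        variable_cos2=pd.DataFrame(cos2[:, :n_dims], index=cols, columns=dims[:n_dims]),
        group_coords=pd.DataFrame(gcoord[:, :n_dims], index=group_names, columns=dims[:n_dims]),
        group_contrib=pd.DataFrame(gcontrib[:, :n_dims], index=group_names, columns=dims[:n_dims]),
        rv=pd.DataFrame(rv, index=names_ext, columns=names_ext),
        lg=pd.DataFrame(lg, index=names_ext, columns=names_ext),
        group_lambda1=lambda1,
        column_weights=pd.Series(cw, index=cols),
    )

    if supplementary is not None:
        if len(supplementary) != n:
            raise ValueError("supplementary rows must match X")
        for col in supplementary.columns:
            levels = supplementary[col].astype(str)
            bary = (
                pd.DataFrame(F[:, :n_dims], columns=dims[:n_dims])
                .assign(_lvl=levels.to_numpy())
                .groupby("_lvl")
                .mean()
            )
            bary.index.name = col
            result.supplementary_coords[col] = bary
    return result


def cell_mean_matrix(
    table: PhenotypeTable, traits: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotype x P-rate cell means (the MFA observations) plus the
    categorical identity columns as a supplementary frame."""
    wide = table.wide(index=("genotype", "p_rate"))
    if traits is not None:
        wide = wide.loc[:, list(traits)]
    supp = wide.index.to_frame(index=False)
    wide = wide.reset_index(drop=True)
    return wide, supp
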