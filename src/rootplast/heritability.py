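"""Variance components and broad-sense heritability for multi-run trials.

The observation model is fully random:

    y = mu + g + p + gp + pr + gpr + prb + gprb (+ run + g_run) + eps

fitted on plot means.  Two estimators are provided:

* ``anova_ems`` — equate observed ANOVA mean squares to their expected
  values and solve the resulting linear system.  The quadratic forms are
  built from the hierarchy of cell-mean projections, and the EMS
  coefficients are computed exactly as tr(A_t Z_k Z_k')/df_t, so the method
  is exact on balanced data (where it coincides with REML).
* ``em_reml`` — the classical EM iteration for residual maximum likelihood
  with an intercept-only fixed part:
  sigma2_k <- sigma2_k + sigma2_k^2/q_k * (y'P Z_k Z_k' P y - tr(Z_k' P Z_k)),
  where P is the REML projection of V^{-1} off the intercept.  The REML
  log-likelihood is nondecreasing across iterations; non-convergence is
  flagged, never silently returned.

Broad-sense heritability is H² = sigma2_g / sigma2_p with the phenotypic
variance on an entry-mean basis,

    sigma2_p = sigma2_g + sigma2_gxt / n + sigma2_eps / (r n),

where n is the number of trials (runs) and r the number of replicates per
trial.  The observation model contains no genotype-by-run term, so the
genotype-by-trial variance sigma2_gxt is mapped to a fitted ``g_run``
component by default (configurable to ``gpr``).  Negative component
estimates are truncated at zero and recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic_trial import TERM_FACTORS
from .trait_data import PhenotypeTable, aggregate

__all__ = [
    "DEFAULT_TERMS",
    "VarianceComponents",
    "HeritabilityEstimate",
    "estimate_varcomp",
    "phenotypic_variance",
    "heritability",
]

#: default random terms fitted in addition to the residual
DEFAULT_TERMS: tuple[str, ...] = ("g", "p", "gp", "g_run", "pr", "gpr", "prb", "gprb")


@dataclass
class VarianceComponents:
    """Estimated variances (trait units squared) for each random term."""

    sigma2: dict[str, float]
    method: str
    converged: bool = True
    n_iter: int = 0
    truncated: tuple[str, ...] = ()
    loglik: float | None = None

    def __getitem__(self, term: str) -> float:
        return self.sigma2[term]


@dataclass(frozen=True)
class HeritabilityEstimate:
    sigma2_g: float
    sigma2_gxt: float
    sigma2_eps: float
    n_trials: int
    n_reps: int
    sigma2_p: float
    h2: float | None  # None when sigma2_p == 0
    clipped: bool = False

    @property
    def defined(self) -> bool:
        return self.h2 is not None


def _design_columns(df: pd.DataFrame, term: str) -> np.ndarray:
    """0/1 incidence matrix of the term's cells (rows x levels)."""
    factors = TERM_FACTORS[term]
    labels = df[list(factors)].astype(str).agg("|".join, axis=1)
    return pd.get_dummies(labels, dtype=float).to_numpy()


def _plot_level(table: PhenotypeTable, trait: str) -> pd.DataFrame:
    if table.level in ("view", "plant"):
        table = aggregate(table, "plot")
    return table.select(trait).reset_index(drop=True)


def _ems_fit(y: np.ndarray, Z: dict[str, np.ndarray]) -> tuple[dict[str, float], list[str]]:
    """Equate observed to expected mean squares and solve for the variances."""
    n = y.size
    terms = list(Z)
    factor_sets = {t: set(TERM_FACTORS[t]) for t in terms}

    # projection onto each term's cell-mean space (includes the grand mean)
    proj: dict[str, np.ndarray] = {}
    for t, Zt in Z.items():
        counts = Zt.sum(axis=0)
        proj[t] = (Zt / counts) @ Zt.T

    ones = np.full((n, n), 1.0 / n)
    # ANOVA quadratic form of each term: its projection minus those of all
    # contained terms and the grand mean (projections commute on balanced data)
    A: dict[str, np.ndarray] = {}
    for t in sorted(terms, key=lambda t: len(factor_sets[t])):
        At = proj[t] - ones
        for s in terms:
            if s != t and factor_sets[s] < factor_sets[t]:
                At = At - A[s]
        A[t] = At
    # residual stratum: everything below the finest fitted cells
    maximal = max(terms, key=lambda t: len(factor_sets[t]))
    span = proj[maximal]
    if not all(factor_sets[t] <= factor_sets[maximal] for t in terms):
        # no single containing term: accumulate the span of all fitted cells
        M = np.hstack([Z[t] for t in terms] + [np.ones((n, 1))])
        q, _ = np.linalg.qr(M)
        span = q @ q.T
    A["eps"] = np.eye(n) - span

    ZZ = {k: Z[k] @ Z[k].T for k in terms}
    rows = []
    ms = []
    order = [*terms, "eps"]
    for t in order:
        df_t = float(np.trace(A[t]))
        if df_t < 0.5:
            raise ValueError(f"term {t!r} has zero degrees of freedom (confounded)")
        # tr(A Z Z') = sum(A * ZZ') for symmetric ZZ'
        coeffs = [float(np.sum(A[t] * ZZ[k])) / df_t for k in terms]
        rows.append(coeffs + [1.0])  # residual coefficient is always 1
        ms.append(float(y @ A[t] @ y) / df_t)
    C = np.array(rows)
    sol, *_ = np.linalg.lstsq(C, np.array(ms), rcond=None)
    est = dict(zip(order, sol))
    truncated = [t for t, v in est.items() if v < 0]
    for t in truncated:
        est[t] = 0.0
    return est, truncated


def _reml_loglik(y, X, V) -> float:
    n = y.size
    sign, logdetV = np.linalg.slogdet(V)
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    _, logdetX = np.linalg.slogdet(XtVX)
    P = Vinv - Vinv @ X @ np.linalg.solve(XtVX, X.T @ Vinv)
    return float(-0.5 * (logdetV + logdetX + y @ P @ y))


def _em_reml_fit(
    y: np.ndarray,
    Z: dict[str, np.ndarray],
    tol: float = 1e-6,
    max_iter: int = 500,
    loglik_trace: list | None = None,
) -> tuple[dict[str, float], bool, int, float]:
    n = y.size
    X = np.ones((n, 1))
    terms = list(Z)
    ZZ = {t: Z[t] @ Z[t].T for t in terms}
    q = {t: Z[t].shape[1] for t in terms}
    s2 = {t: float(np.var(y)) / (len(terms) + 1) for t in [*terms, "eps"]}
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        V = s2["eps"] * np.eye(n)
        for t in terms:
            V += s2[t] * ZZ[t]
        if loglik_trace is not None:
            loglik_trace.append(_reml_loglik(y, X, V))
        Vinv = np.linalg.inv(V)
        XtVX = X.T @ Vinv @ X
        P = Vinv - Vinv @ X @ np.linalg.solve(XtVX, X.T @ Vinv)
        Py = P @ y
        new = {}
        for t in terms:
            grad = float(Py @ ZZ[t] @ Py) - float(np.trace(P @ ZZ[t]))
            new[t] = max(s2[t] + (s2[t] ** 2 / q[t]) * grad, 0.0)
        grad_e = float(Py @ Py) - float(np.trace(P))
        new["eps"] = max(s2["eps"] + (s2["eps"] ** 2 / n) * grad_e, 1e-12)
        # convergence relative to the total variance: a per-component ratio
        # never triggers for components decaying to the zero boundary
        total = max(sum(new.values()), 1e-12)
        delta = max(abs(new[t] - s2[t]) for t in new) / total
        s2 = new
        if delta < tol:
            converged = True
            break
    V = s2["eps"] * np.eye(n)
    for t in terms:
        V += s2[t] * ZZ[t]
    ll = _reml_loglik(y, X, V)
    return s2, converged, it, ll


def estimate_varcomp(
    table: PhenotypeTable,
    trait: str,
    model_terms: Sequence[str] = DEFAULT_TERMS,
    method: str = "em_reml",
    tol: float = 1e-6,
    max_iter: int = 500,
) -> VarianceComponents:
    """Estimate the random-model variance components for one trait.

    ``model_terms`` are the non-residual components to fit (the residual is
    always included).  ``method`` is ``"em_reml"`` or ``"anova_ems"``; the
    two agree on balanced data.  Terms confounded with the residual raise.
    """
    df = _plot_level(table, trait)
    y = df["value"].to_numpy(dtype=float)
    y = y - y.mean()  # numerical centering only; the intercept is still fitted
    Z = {}
    n = y.size
    for t in model_terms:
        if t == "eps":
            continue
        if t not in TERM_FACTORS:
            raise ValueError(f"unknown model term {t!r}")
        Zt = _design_columns(df, t)
        if Zt.shape[1] >= n:
            raise ValueError(f"term {t!r} is confounded with the residual")
        Z[t] = Zt

    if method == "anova_ems":
        est, truncated = _ems_fit(y, Z)
        return VarianceComponents(
            sigma2={k: float(v) for k, v in est.items()},
            method=method,
            converged=True,
            n_iter=0,
            truncated=tuple(truncated),
        )
    if method == "em_reml":
        s2, converged, n_iter, ll = _em_reml_fit(y, Z, tol=tol, max_iter=max_iter)
        if not converged:
            warnings.warn(
                f"EM-REML did not converge in {n_iter} iterations for trait {trait!r}",
                RuntimeWarning,
            )
        return VarianceComponents(
            sigma2={k: float(v) for k, v in s2.items()},
            method=method,
            converged=converged,
            n_iter=n_iter,
            loglik=ll,
        )
    raise ValueError(f"method must be 'em_reml' or 'anova_ems', got {method!r}")


def phenotypic_variance(
    vc: VarianceComponents | Mapping[str, float],
    n_trials: int,
    n_reps: int,
    gxt_term: str = "g_run",
    strict_printed: bool = False,
) -> float:
    """Entry-mean phenotypic variance sigma2_g + sigma2_gxt/n + sigma2_eps/(rn).

    ``gxt_term`` selects which fitted component plays the genotype-by-trial
    role ("g_run" by default, "gpr" as the alternative mapping).  With
    ``strict_printed=True`` the genotypic term is omitted, reproducing the
    truncated published formula (documented as a typesetting loss; heritability
    is then unbounded and the mode exists only for comparison).
    """
    if n_trials < 1 or n_reps < 1:
        raise ValueError("n_trials and n_reps must be >= 1")
    s2 = vc.sigma2 if isinstance(vc, VarianceComponents) else dict(vc)
    g = float(s2.get("g", 0.0))
    gxt = float(s2.get(gxt_term, 0.0))
    eps = float(s2.get("eps", 0.0))
    if min(g, gxt, eps) < 0:
        raise ValueError("variance components must be nonnegative")
    base = gxt / n_trials + eps / (n_reps * n_trials)
    return base if strict_printed else g + base


def heritability(
    vc: VarianceComponents | Mapping[str, float],
    n_trials: int = 2,
    n_reps: int = 6,
    gxt_term: str = "g_run",
) -> HeritabilityEstimate:
    """Broad-sense heritability H² = sigma2_g / sigma2_p on an entry-mean basis.

    ``n_reps`` defaults to blocks x plots per run (2 x 3) for the reference
    design.  H² is clipped to [0, 1] with the clipping recorded; a zero
    phenotypic variance leaves H² undefined (``h2 is None``).
    """
    s2 = vc.sigma2 if isinstance(vc, VarianceComponents) else dict(vc)
    g = float(s2.get("g", 0.0))
    gxt = float(s2.get(gxt_term, 0.0))
    eps = float(s2.get("eps", 0.0))
    s2_p = phenotypic_variance(s2, n_trials, n_reps, gxt_term=gxt_term)
    if s2_p == 0.0:
        return HeritabilityEstimate(g, gxt, eps, n_trials, n_reps, 0.0, None)
    h2 = g / s2_p
    clipped = not 0.0 <= h2 <= 1.0
    h2 = float(min(max(h2, 0.0), 1.0))
    return HeritabilityEstimate(g, gxt, eps, n_trials, n_reps, float(s2_p), h2, clipped)
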