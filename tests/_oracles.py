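"""Independent brute-force oracles used by the test suite.

Everything here is written directly from the definitional formulas
(explicit loops, covariance eigendecompositions) and shares no code with
the package implementation it checks.
"""

from __future__ import annotations

import numpy as np


def rdpi_bruteforce(values_by_env: dict, env_pairs: list[tuple]) -> tuple[float, int]:
    """Mean relative distance by explicit double-loop enumeration."""
    total = 0.0
    n = 0
    for a, b in env_pairs:
        for x in values_by_env[a]:
            for y in values_by_env[b]:
                s = x + y
                if s > 0:
                    total += abs(x - y) / s
                    n += 1
    if n == 0:
        raise ValueError("no retained pairs")
    return total / n, n


def anova_bruteforce(df) -> dict:
    """Sums-of-squares partition via explicit marginal means on balanced data.

    df: columns genotype, p_rate, run, block, value; equal replication per
    (genotype, p_rate, block-unit) cell.
    """
    y = df["value"].to_numpy(dtype=float)
    grand = y.mean()
    n = y.size

    def marg(cols):
        means = df.groupby(cols, observed=True)["value"].mean()
        counts = df.groupby(cols, observed=True)["value"].count()
        return float(sum(c * (m - grand) ** 2 for m, c in zip(means, counts)))

    blk = df[["run", "block"]].astype(str).agg("-".join, axis=1)
    work = df.assign(_blk=blk)
    ss_blocks = float(
        sum(
            cnt * (m - grand) ** 2
            for m, cnt in zip(
                work.groupby("_blk")["value"].mean(), work.groupby("_blk")["value"].count()
            )
        )
    )
    ss_g = marg(["genotype"])
    ss_p = marg(["p_rate"])
    ss_cells = marg(["genotype", "p_rate"])
    ss_gxp = ss_cells - ss_g - ss_p
    ss_total = float(((y - grand) ** 2).sum())
    ss_resid = ss_total - ss_blocks - ss_cells
    df_g = df["genotype"].nunique() - 1
    df_p = df["p_rate"].nunique() - 1
    df_blk = work["_blk"].nunique() - 1
    df_gxp = df_g * df_p
    df_resid = n - 1 - df_blk - df_g - df_p - df_gxp
    ms_resid = ss_resid / df_resid
    return {
        "F_geno": (ss_g / df_g) / ms_resid,
        "F_p": (ss_p / df_p) / ms_resid,
        "F_gxp": (ss_gxp / df_gxp) / ms_resid,
        "ss": {
            "blocks": ss_blocks,
            "genotype": ss_g,
            "p_rate": ss_p,
            "gxp": ss_gxp,
            "residual": ss_resid,
            "total": ss_total,
        },
    }


def rv_bruteforce(X: np.ndarray, Y: np.ndarray) -> float:
    WX = X @ X.T
    WY = Y @ Y.T
    return float(
        np.trace(WX @ WY) / np.sqrt(np.trace(WX @ WX) * np.trace(WY @ WY))
    )


def lg_bruteforce(X: np.ndarray, Y: np.ndarray) -> float:
    n = X.shape[0]
    WX = X @ X.T / n
    WY = Y @ Y.T / n
    lam1x = np.linalg.eigvalsh(X.T @ X / n)[-1]
    lam1y = np.linalg.eigvalsh(Y.T @ Y / n)[-1]
    return float(np.trace(WX @ WY) / (lam1x * lam1y))


def mfa_bruteforce(X: np.ndarray, group_idx: list[list[int]]) -> dict:
    """Grouped-PCA ordination built from explicit covariance
    eigendecompositions of the definitional formulas."""
    n, p = X.shape
    Z = (X - X.mean(axis=0)) / X.std(axis=0)

    lam1 = []
    for idx in group_idx:
        C = Z[:, idx].T @ Z[:, idx] / n
        lam1.append(float(np.linalg.eigvalsh(C)[-1]))
    w = np.empty(p)
    for gi, idx in enumerate(group_idx):
        w[idx] = 1.0 / lam1[gi]

    Wt = Z * np.sqrt(w)
    C = Wt.T @ Wt / n
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > evals[0] * 1e-10
    evals, evecs = evals[keep], evecs[:, keep]
    for s in range(evals.size):
        j = int(np.argmax(np.abs(evecs[:, s])))
        if evecs[j, s] < 0:
            evecs[:, s] = -evecs[:, s]

    scores = Wt @ evecs  # divisor-n variance equals evals
    k = evals.size
    coords = np.empty((p, k))
    for v in range(p):
        for s in range(k):
            coords[v, s] = (Z[:, v] @ scores[:, s] / n) / np.sqrt(evals[s])
    contrib = 100.0 * w[:, None] * coords**2 / evals
    cos2 = coords**2 / (coords**2).sum(axis=1, keepdims=True)

    ngroups = len(group_idx)
    gcoord = np.empty((ngroups, k))
    for gi, idx in enumerate(group_idx):
        for s in range(k):
            z_s = scores[:, s] / np.sqrt(evals[s])
            gcoord[gi, s] = sum((Z[:, v] @ z_s / n) ** 2 for v in idx) / lam1[gi]

    blocks = [Z[:, idx] for idx in group_idx] + [Wt]
    lams = lam1 + [float(evals[0])]
    m = ngroups + 1
    rv = np.eye(m)
    lg = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            lg[i, j] = np.trace(
                (blocks[i] @ blocks[i].T / n) @ (blocks[j] @ blocks[j].T / n)
            ) / (lams[i] * lams[j])
            if i != j:
                rv[i, j] = rv_bruteforce(blocks[i], blocks[j])
    return {
        "eigenvalues": evals,
        "pct_variance": 100.0 * evals / evals.sum(),
        "variable_coords": coords,
        "variable_contrib": contrib,
        "variable_cos2": cos2,
        "group_coords": gcoord,
        "rv": rv,
        "lg": lg,
    }
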