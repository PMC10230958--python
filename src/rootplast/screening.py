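"""Trait screening: descriptive statistics, CoV and genotype filters,
factorial ANOVA, and trait correlations.

The screening cascade mirrors a progressive dimension reduction of a large
trait panel: (1) combine the two experimental runs and keep traits whose
coefficient of variation is at least 30%; (2) keep traits with a significant
genotype difference in a factorial ANOVA.  The analysis unit for ANOVA and
correlations is the plot mean — camera views are pseudoreplicates and plants
share a plot, so using them as error degrees of freedom would inflate
significance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trait_data import PhenotypeTable, aggregate

__all__ = [
    "TraitSummary",
    "summarize",
    "cov_from_summary",
    "cov_filter",
    "band_count",
    "anova_factorial",
    "genotype_filter",
    "correlation_matrix",
]


@dataclass(frozen=True)
class TraitSummary:
    """Descriptive statistics for one trait, runs combined."""

    trait: str
    n: int
    mean: float
    sd: float
    minimum: float
    maximum: float
    range: float
    cov_pct: float | None  # None when undefined (mean <= 0)

    @property
    def cov_defined(self) -> bool:
        return self.cov_pct is not None


def cov_from_summary(mean: float, sd: float) -> float:
    """Coefficient of variation in percent, 100*sd/mean."""
    if mean <= 0:
        raise ValueError("CoV undefined for nonpositive mean")
    return 100.0 * sd / mean


def summarize(table: PhenotypeTable, trait: str) -> TraitSummary:
    """Mean, sample SD (n-1), range and CoV% for one trait, all runs pooled."""
    values = table.select(trait)["value"].to_numpy(dtype=float)
    if values.size < 2:
        raise ValueError(f"trait {trait!r}: need >= 2 observations, have {values.size}")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    cov = 100.0 * sd / mean if mean > 0 else None
    return TraitSummary(
        trait=trait,
        n=int(values.size),
        mean=mean,
        sd=sd,
        minimum=float(values.min()),
        maximum=float(values.max()),
        range=float(values.max() - values.min()),
        cov_pct=cov,
    )


def _cov_values(rows) -> tuple[list, np.ndarray]:
    """Accept a DataFrame with a cov_pct column or an iterable of summaries."""
    if isinstance(rows, pd.DataFrame):
        items = [rows.iloc[[i]] for i in range(len(rows))]
        covs = rows["cov_pct"].to_numpy(dtype=float)
    else:
        items = list(rows)
        covs = np.array(
            [r.cov_pct if not isinstance(r, dict) else r["cov_pct"] for r in items],
            dtype=float,
        )
    if np.isnan(covs).any():
        raise ValueError("cov_pct undefined for some rows")
    return items, covs


def cov_filter(rows, threshold_pct: float = 30.0):
    """Partition rows into (kept, eliminated) by CoV >= threshold, order kept.

    ``rows`` may be a DataFrame carrying a ``cov_pct`` column (two DataFrames
    are returned) or any iterable of objects with a ``cov_pct`` attribute.
    """
    if isinstance(rows, pd.DataFrame):
        covs = rows["cov_pct"].to_numpy(dtype=float)
        if np.isnan(covs).any():
            raise ValueError("cov_pct undefined for some rows")
        keep = covs >= threshold_pct
        return rows[keep], rows[~keep]
    items, covs = _cov_values(rows)
    keep = covs >= threshold_pct
    kept = [r for r, k in zip(items, keep) if k]
    eliminated = [r for r, k in zip(items, keep) if not k]
    return kept, eliminated


def band_count(rows, lo_pct: float, hi_pct: float) -> int:
    """Count rows whose CoV falls in the reporting band [lo, hi+1).

    A band quoted as "30% to 59%" covers CoV values in [30, 60) at the
    printed 1-decimal resolution, hence the upper bound ``hi_pct + 1``.
    """
    if lo_pct > hi_pct:
        raise ValueError(f"lo_pct {lo_pct} > hi_pct {hi_pct}")
    _, covs = _cov_values(rows)
    upper = hi_pct + 1.0
    return int(np.count_nonzero((covs >= lo_pct) & (covs < upper)))


def anova_factorial(table: PhenotypeTable, trait: str) -> dict:
    """Factorial ANOVA for genotype, P rate and their interaction.

    Model: value ~ block stratum (run/block) + genotype * p_rate, fitted on
    plot means of a balanced table.  The sums of squares are computed from
    first principles (marginal-mean decomposition, exact on balanced data);
    F ratios use the plot-stratum residual mean square, p-values come from
    the F distribution.

    Returns ``{"genotype": {"F": ..., "p": ...}, "p_rate": ..., "gxp": ...,
    "ss": ..., "df": ...}``.
    """
    if table.level in ("view", "plant"):
        table = aggregate(table, "plot")
    df = table.select(trait).copy()
    df["blk"] = list(zip(df["run"], df["block"]))

    counts = df.groupby(["genotype", "p_rate", "blk"], observed=True)["value"].count()
    if counts.nunique() > 1:
        raise ValueError(
            f"trait {trait!r}: unbalanced table; aggregate to plot means on a "
            "balanced design before ANOVA"
        )

    y = df["value"].to_numpy(dtype=float)
    n = y.size
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    def _ss(groups: list[str]) -> float:
        m = df.groupby(groups, observed=True)["value"].agg(["mean", "count"])
        return float((m["count"] * (m["mean"] - grand) ** 2).sum())

    ss_blocks = _ss(["blk"])
    ss_geno = _ss(["genotype"])
    ss_p = _ss(["p_rate"])
    ss_cells = _ss(["genotype", "p_rate"])
    ss_gxp = ss_cells - ss_geno - ss_p
    ss_resid = ss_total - ss_blocks - ss_cells

    n_g = df["genotype"].nunique()
    n_p = df["p_rate"].nunique()
    n_blk = df["blk"].nunique()
    df_blocks = n_blk - 1
    df_geno = n_g - 1
    df_p = n_p - 1
    df_gxp = df_geno * df_p
    df_resid = n - 1 - df_blocks - df_geno - df_p - df_gxp
    if df_resid <= 0:
        raise ValueError(f"trait {trait!r}: zero residual degrees of freedom")

    ms_resid = ss_resid / df_resid
    out: dict = {
        "ss": {
            "blocks": ss_blocks,
            "genotype": ss_geno,
            "p_rate": ss_p,
            "gxp": ss_gxp,
            "residual": ss_resid,
            "total": ss_total,
        },
        "df": {
            "blocks": df_blocks,
            "genotype": df_geno,
            "p_rate": df_p,
            "gxp": df_gxp,
            "residual": df_resid,
        },
    }
    for name, ss, d in (
        ("genotype", ss_geno, df_geno),
        ("p_rate", ss_p, df_p),
        ("gxp", ss_gxp, df_gxp),
    ):
        F = (ss / d) / ms_resid
        out[name] = {"F": float(F), "p": float(stats.f.sf(F, d, df_resid))}
    return out


def genotype_filter(reports: dict[str, dict] | pd.DataFrame, alpha: float = 0.05):
    """Partition traits by genotype significance, kept iff p_geno < alpha.

    ``reports`` maps trait -> ANOVA result (as from :func:`anova_factorial`)
    or is a DataFrame carrying a ``p_geno`` column indexed/keyed by trait.
    """
    if isinstance(reports, pd.DataFrame):
        p = reports["p_geno"]
        if p.isna().any():
            raise ValueError("missing p_geno for some traits")
        keep = p < alpha
        return reports[keep], reports[~keep]
    kept, eliminated = [], []
    for trait, rep in reports.items():
        try:
            p = rep["genotype"]["p"]
        except (KeyError, TypeError):
            raise ValueError(f"trait {trait!r}: missing genotype p-value") from None
        (kept if p < alpha else eliminated).append(trait)
    return kept, eliminated


def correlation_matrix(
    table: PhenotypeTable, traits: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations between traits on plot means.

    Returns ``(r, p)`` DataFrames: symmetric, unit diagonal, two-sided
    p-values from the exact t transform.  Zero-variance traits yield NaN
    against every other trait (flagged by the caller via ``isna``).
    """
    if table.level in ("view", "plant"):
        table = aggregate(table, "plot")
    wide = table.wide(index=("genotype", "p_rate", "run", "block", "plot"))
    if traits is not None:
        wide = wide.loc[:, list(traits)]
    cols = list(wide.columns)
    if len(wide) < 3:
        raise ValueError("need >= 3 paired observations for correlations")
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    X = wide.to_numpy(dtype=float)
    sd = X.std(axis=0)
    for i in range(k):
        for j in range(i + 1, k):
            if sd[i] == 0 or sd[j] == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(X[:, i], X[:, j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )
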