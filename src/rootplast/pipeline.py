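"""One-shot pipeline: simulate/load -> screen -> heritability -> MFA -> RDPI.

Traits flow through the screening cascade in a fixed order: coefficient of
variation filter first, genotype-significance filter second; variance
components, heritability, the grouped ordination and the plasticity indices
are computed only for the surviving traits.  Every run writes human-readable
CSV/JSON stage outputs plus a machine-readable ``manifest.json`` that embeds
the configuration, its hash, the seed, and the trait counts at each stage.
Manifests contain no timestamps, so identical configuration + seed reruns
are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import mfa as mfa_mod
from . import plasticity as plast
from . import screening as screen_mod
from .heritability import estimate_varcomp as _estimate_varcomp
from .heritability import heritability as _heritability_fn
from .synthetic_trial import DesignSpec, DoseResponse, SimParams, simulate_trial
from .trait_data import (
    PhenotypeTable,
    TraitRegistry,
    load_table1_fixture,
    read_long_csv,
    table1_registry,
)

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "run_pipeline",
    "render_summary_table",
    "simulate_reference_panel",
]

log = logging.getLogger("rootplast")

#: shares of the *random* half of the log-scale variance budget (sum to 1);
#: the other half is the deterministic dose response (the reaction norm).
_VARIANCE_SHARES: dict[str, float] = {
    "g": 0.20,
    "gp": 0.10,
    "pr": 0.05,
    "gpr": 0.05,
    "prb": 0.05,
    "gprb": 0.05,
    "eps": 0.50,
}

#: relative reaction-norm amplitudes; the white genotype's steeper norm
#: makes it the more plastic one and also gives it the larger trait values,
#: as in the emulated trial.  The absolute scale is set per trait so the
#: cell-wise dose-pattern variance equals the random log-variance.
_DOSE_RATIO = {"red": 1.7, "white": 2.4}


class PipelineStageError(RuntimeError):
    """A stage failed; earlier stage outputs are preserved on disk."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    input_csv: str | None = None
    registry_csv: str | None = None
    cov_threshold_pct: float = 30.0
    alpha: float = 0.05
    mfa_dims: int = 3
    rdpi_baseline: float = 0.0
    h2_method: str = "em_reml"
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 <= self.cov_threshold_pct:
            raise ValueError("cov_threshold_pct must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.mfa_dims < 1:
            raise ValueError("mfa_dims must be >= 1")
        if self.h2_method not in ("em_reml", "anova_ems"):
            raise ValueError("h2_method must be 'em_reml' or 'anova_ems'")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        return cls(**payload)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _calibrate_trait(mean: float, cv: float, p_levels, c: float = 0.05):
    """Noise scale, intercept and dose amplitudes reproducing ``mean`` and
    ``cv`` in expectation for values exp(mu + dose(P) + noise).

    The dose pattern d_gj = kappa_g * s_n * (1 - exp(-c P_j)) is normalized
    so its cell-wise variance equals the random log-variance s_n^2 (an equal
    deterministic/stochastic split); s_n then solves
    E[X^2]/E[X]^2 = (M2/M1^2) * exp(s_n^2) = 1 + cv^2 with M_k the cell
    means of exp(k*d), and the intercept fixes E[X] = mean.
    """
    from scipy.optimize import brentq

    u = 1.0 - np.exp(-c * np.asarray(p_levels, dtype=float))
    ratios = np.array(list(_DOSE_RATIO.values()))
    d_unit = np.concatenate([r * u for r in ratios])  # cells at s_n = 1
    scale = 1.0 / d_unit.std()  # cell-variance of the pattern -> 1
    d_unit = d_unit * scale

    def excess(s_n: float) -> float:
        d = d_unit * s_n
        m1 = np.mean(np.exp(d))
        m2 = np.mean(np.exp(2.0 * d))
        return (m2 / m1**2) * math.exp(s_n**2) - (1.0 + cv * cv)

    s_n = brentq(excess, 1e-9, 4.0) if cv > 1e-9 else 0.0
    m1 = np.mean(np.exp(d_unit * s_n))
    mu_log = math.log(mean) - math.log(m1) - s_n**2 / 2.0
    amplitudes = {
        label: r * scale * s_n for label, r in _DOSE_RATIO.items()
    }
    return s_n, mu_log, amplitudes


def simulate_reference_panel(
    registry: TraitRegistry,
    seed: int = 0,
    design: DesignSpec | None = None,
) -> PhenotypeTable:
    """Simulate a full trait panel whose dispersion mirrors the published one.

    Each trait is strictly positive (exponentiated Gaussian, as ratio-based
    plasticity indices require) and calibrated so its expected mean and CoV
    equal the published values.  Half of the log-scale variance is a
    deterministic asymptotic P dose response — steeper for the white
    genotype, which therefore shows the higher plasticity and the larger
    trait values — and half is random, split across the model terms in
    fixed shares.
    """
    fixture = load_table1_fixture().set_index("acronym")
    design = design or DesignSpec(genotype_labels=("red", "white"))
    rng = np.random.default_rng(seed)
    tables = []
    for acronym in registry.acronyms:
        row = fixture.loc[acronym]
        cv = float(row["cov_pct"]) / 100.0
        s_n, mu_log, amplitudes = _calibrate_trait(float(row["mean"]), cv, design.p_levels)
        sigma2 = {k: share * s_n**2 for k, share in _VARIANCE_SHARES.items()}
        dose = {
            label: DoseResponse(A=a, B=a, c=0.05) for label, a in amplitudes.items()
        }
        params = SimParams(
            mu=mu_log, sigma2=sigma2, dose_response=dose, transform="exp"
        )
        tables.append(simulate_trial(design, params, [acronym], seed=rng))
    data = pd.concat([t.data for t in tables], ignore_index=True)
    return PhenotypeTable(data, design=design)


def _fmt_thousands(value: float, decimals: int) -> str:
    return f"{value:,.{decimals}f}"


def format_like_table1(value: float) -> str:
    """Magnitude-dependent rounding: >= 1000 whole numbers with thousands
    separators, below that one decimal."""
    if abs(value) >= 1000:
        return _fmt_thousands(value, 0)
    return f"{value:.1f}"


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def render_summary_table(
    summaries: Mapping[str, screen_mod.TraitSummary],
    anova: Mapping[str, dict],
    h2: Mapping[str, float],
    registry: TraitRegistry,
) -> pd.DataFrame:
    """Per-trait summary in the layout of a published trial table.

    One row per trait: acronym, group, mean, SD, range, CoV%, the three
    ANOVA p-values and H², with a dash where the trait was filtered out
    before the heritability stage.
    """
    rows = []
    for acronym in registry.acronyms:
        if acronym not in summaries:
            continue
        s = summaries[acronym]
        a = anova.get(acronym)
        rows.append(
            {
                "acronym": acronym,
                "group": registry[acronym].group,
                "mean": format_like_table1(s.mean),
                "sd": format_like_table1(s.sd),
                "range": format_like_table1(s.range),
                "cov_pct": f"{s.cov_pct:.1f}" if s.cov_defined else "-",
                "p_geno": _fmt_p(a["genotype"]["p"]) if a else "-",
                "p_p": _fmt_p(a["p_rate"]["p"]) if a else "-",
                "p_gxp": _fmt_p(a["gxp"]["p"]) if a else "-",
                "h2": f"{h2[acronym]:.2f}" if acronym in h2 else "-",
            }
        )
    return pd.DataFrame(rows)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                log.info("stage %s", name)
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage name must surface
                raise PipelineStageError(name, exc) from exc

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full cascade; returns the manifest (also written to disk)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": {},
        "outputs": [],
    }

    registry = (
        TraitRegistry.from_csv(config.registry_csv)
        if config.registry_csv
        else table1_registry()
    )
    if len(registry) == 0:
        raise PipelineStageError("load", ValueError("empty trait registry"))

    @_stage("load")
    def _load() -> PhenotypeTable:
        if config.input_csv:
            return read_long_csv(config.input_csv, registry)
        return simulate_reference_panel(registry, seed=config.seed)

    table = _load()
    plot_table = table.aggregate("plot")
    traits = [a for a in registry.acronyms if a in set(plot_table.traits)]
    manifest["stages"]["load"] = {"n_traits": len(traits), "n_rows": len(table)}

    @_stage("screening")
    def _screening():
        summaries = {t: screen_mod.summarize(plot_table, t) for t in traits}
        anova = {t: screen_mod.anova_factorial(plot_table, t) for t in traits}
        rows = pd.DataFrame(
            {
                "trait": traits,
                "mean": [summaries[t].mean for t in traits],
                "sd": [summaries[t].sd for t in traits],
                "range": [summaries[t].range for t in traits],
                "cov_pct": [summaries[t].cov_pct for t in traits],
                "F_geno": [anova[t]["genotype"]["F"] for t in traits],
                "p_geno": [anova[t]["genotype"]["p"] for t in traits],
                "p_p": [anova[t]["p_rate"]["p"] for t in traits],
                "p_gxp": [anova[t]["gxp"]["p"] for t in traits],
            }
        )
        kept_cov, dropped_cov = screen_mod.cov_filter(rows, config.cov_threshold_pct)
        kept_both, dropped_geno = screen_mod.genotype_filter(kept_cov, config.alpha)
        rows["kept_by_cov"] = rows["trait"].isin(kept_cov["trait"])
        rows["kept_by_genotype"] = rows["trait"].isin(kept_both["trait"])
        rows.to_csv(out / "screening.csv", index=False)
        return summaries, anova, rows, list(kept_both["trait"])

    summaries, anova, screening_rows, survivors = _screening()
    manifest["outputs"].append("screening.csv")
    manifest["stages"]["screening"] = {
        "cov_threshold_pct": config.cov_threshold_pct,
        "eliminated_by_cov": int((~screening_rows["kept_by_cov"]).sum()),
        "eliminated_by_genotype": int(
            (screening_rows["kept_by_cov"] & ~screening_rows["kept_by_genotype"]).sum()
        ),
        "surviving": len(survivors),
    }

    design = table.design
    n_trials = getattr(design, "n_runs", plot_table.data["run"].nunique())
    n_reps = getattr(design, "n_blocks", 2) * getattr(design, "n_plots", 3)

    @_stage("heritability")
    def _heritability():
        report = {}
        for t in survivors:
            vc = _estimate_varcomp(plot_table, t, method=config.h2_method)
            est = _heritability_fn(vc, n_trials=n_trials, n_reps=n_reps)
            report[t] = {
                "sigma2": vc.sigma2,
                "method": vc.method,
                "converged": vc.converged,
                "n_iter": vc.n_iter,
                "sigma2_p": est.sigma2_p,
                "h2": est.h2,
                "clipped": est.clipped,
            }
        (out / "heritability.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        return report

    h2_report = _heritability()
    manifest["outputs"].append("heritability.json")
    manifest["stages"]["heritability"] = {
        "n_traits": len(h2_report),
        "method": config.h2_method,
        "n_trials": int(n_trials),
        "n_reps": int(n_reps),
    }

    @_stage("mfa")
    def _mfa():
        X, supp = mfa_mod.cell_mean_matrix(plot_table, survivors)
        groups = {t: registry[t].group for t in survivors}
        res = mfa_mod.mfa_fit(X, groups, n_dims=config.mfa_dims, supplementary=supp)
        payload = {
            "eigenvalues": res.eigenvalues.tolist(),
            "pct_variance": res.pct_variance.tolist(),
            "variable_coords": res.variable_coords.to_dict(),
            "variable_contrib": res.variable_contrib.to_dict(),
            "variable_cos2": res.variable_cos2.to_dict(),
            "group_coords": res.group_coords.to_dict(),
            "group_contrib": res.group_contrib.to_dict(),
            "rv": res.rv.to_dict(),
            "lg": res.lg.to_dict(),
        }
        (out / "mfa.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
        return res

    mfa_res = _mfa()
    manifest["outputs"].append("mfa.json")
    manifest["stages"]["mfa"] = {
        "n_traits": len(survivors),
        "n_groups": len(mfa_res.group_lambda1),
        "pct_variance_dim1": float(mfa_res.pct_variance[0]),
        "pct_variance_dim2": float(mfa_res.pct_variance[1])
        if len(mfa_res.pct_variance) > 1
        else None,
    }

    genotypes = plot_table.genotypes

    @_stage("rdpi")
    def _rdpi():
        rows = []
        totals: dict[str, list] = {g: [] for g in genotypes}
        for t in survivors:
            per_geno = {}
            for g in genotypes:
                results = plast.rdpi_variants(plot_table, g, t, baseline=config.rdpi_baseline)
                per_geno[g] = results
                totals[g].append(next(r for r in results if r.variant == "Total"))
            pvals = {}
            if len(genotypes) == 2:
                g1, g2 = genotypes
                sets = []
                for g in (g1, g2):
                    levels = sorted(plot_table.p_levels)
                    ds = [
                        plast.relative_distances(plot_table, g, t, a, b)
                        for i, a in enumerate(levels)
                        for b in levels[i + 1 :]
                    ]
                    sets.append(plast.pooled_distance_set(ds))
                pvals["Total"] = plast.compare_genotypes(*sets)["p_value"]
            for g, results in per_geno.items():
                for r in results:
                    rows.append(
                        {
                            "genotype": g,
                            "trait": t,
                            "variant": r.variant,
                            "rdpi": r.rdpi,
                            "se": r.se,
                            "n_pairs": r.n_pairs,
                            "p_vs_other_genotype": pvals.get(r.variant, np.nan),
                        }
                    )
        df = pd.DataFrame(rows)
        df.to_csv(out / "rdpi.csv", index=False)
        contrast = None
        if len(genotypes) == 2:
            g1, g2 = genotypes
            contrast = plast.mean_rdpi_contrast(totals[g1], totals[g2])
        return df, contrast

    rdpi_df, contrast = _rdpi()
    manifest["outputs"].append("rdpi.csv")
    manifest["stages"]["rdpi"] = {
        "n_traits": len(survivors),
        "baseline": config.rdpi_baseline,
        "mean_total_contrast": contrast,
    }

    @_stage("summary")
    def _summary():
        h2_map = {t: rep["h2"] for t, rep in h2_report.items() if rep["h2"] is not None}
        df = render_summary_table(summaries, anova, h2_map, registry)
        df.to_csv(out / "summary_table.csv", index=False)
        return df

    _summary()
    manifest["outputs"].append("summary_table.csv")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
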