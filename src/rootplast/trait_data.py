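"""Trait registry and long-format phenotype tables.

The canonical data structure throughout the package is a *tidy* long table:
one row per (genotype, p_rate, run, block, plot, plant, view, trait) with a
single numeric ``value``.  Camera views are pseudoreplicates of one root
crown; plants nest in replicated plots, plots in blocks, blocks in
experimental runs.  Wide matrices (observations x traits) are derived views,
never the stored form.

The module also ships the published trial-summary table used as the trait
registry and as a self-contained arithmetic fixture (51 traits: 2 shoot +
49 root, eight trait groups).  In the printed source the header order of the
two dispersion columns contradicts the table's own coefficient-of-variation
arithmetic; the loader therefore maps the dispersion column that reproduces
the printed CoV (the third numeric column) to ``sd`` and the other to
``range`` while preserving both printed columns verbatim.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRAIT_GROUPS",
    "TraitMeta",
    "TraitRegistry",
    "PhenotypeTable",
    "LONG_COLUMNS",
    "read_long_csv",
    "write_long_csv",
    "aggregate",
    "load_table1_fixture",
    "table1_registry",
    "TABLE1_SHA256",
]

#: The eight trait groups used for grouped ordination.
TRAIT_GROUPS: tuple[str, ...] = (
    "angle",
    "area",
    "biomass",
    "diameter",
    "length",
    "number",
    "volume",
    "width",
)

#: Column order of the canonical long format.
LONG_COLUMNS: tuple[str, ...] = (
    "genotype",
    "p_rate",
    "run",
    "block",
    "plot",
    "plant",
    "view",
    "trait",
    "value",
)

#: Columns that uniquely identify an observation.
KEY_COLUMNS: tuple[str, ...] = LONG_COLUMNS[:-1]

TABLE1_SHA256 = "a50e0c3735b3d90cc160fc823a3cbd56e35c3a9dfb65a1ef468797625a9180b4"


@dataclass(frozen=True)
class TraitMeta:
    """Metadata for one measured trait."""

    name: str
    acronym: str
    group: str
    unit: str = ""
    mode: str = "image"  # {"manual", "image"}
    organ: str = "root"  # {"root", "shoot"}

    def __post_init__(self) -> None:
        if self.group not in TRAIT_GROUPS:
            raise ValueError(
                f"trait {self.acronym!r}: group {self.group!r} not one of {TRAIT_GROUPS}"
            )
        if self.mode not in ("manual", "image"):
            raise ValueError(f"trait {self.acronym!r}: mode must be 'manual' or 'image'")


class TraitRegistry:
    """Ordered collection of :class:`TraitMeta`, keyed by unique acronym."""

    def __init__(self, traits: Iterable[TraitMeta]):
        self._traits: dict[str, TraitMeta] = {}
        for t in traits:
            if t.acronym in self._traits:
                raise ValueError(f"duplicate trait acronym {t.acronym!r}")
            self._traits[t.acronym] = t

    def __contains__(self, acronym: object) -> bool:
        return acronym in self._traits

    def __getitem__(self, acronym: str) -> TraitMeta:
        return self._traits[acronym]

    def __iter__(self) -> Iterator[TraitMeta]:
        return iter(self._traits.values())

    def __len__(self) -> int:
        return len(self._traits)

    @property
    def acronyms(self) -> list[str]:
        return list(self._traits)

    def group_map(self) -> dict[str, str]:
        """acronym -> group, for grouped analyses."""
        return {t.acronym: t.group for t in self}

    def subset(self, acronyms: Sequence[str]) -> "TraitRegistry":
        missing = [a for a in acronyms if a not in self._traits]
        if missing:
            raise KeyError(f"unknown trait acronyms: {missing}")
        return TraitRegistry(self._traits[a] for a in acronyms)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TraitRegistry":
        cols = {"acronym", "name", "group"}
        if not cols.issubset(df.columns):
            raise ValueError(f"registry frame needs columns {sorted(cols)}")
        metas = []
        for _, row in df.iterrows():
            metas.append(
                TraitMeta(
                    name=str(row["name"]),
                    acronym=str(row["acronym"]),
                    group=str(row["group"]).lower(),
                    unit="" if pd.isna(row.get("unit", "")) else str(row.get("unit", "")),
                    mode=str(row.get("mode", "image")),
                    organ=str(row.get("organ", "root")),
                )
            )
        return cls(metas)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TraitRegistry":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "acronym": t.acronym,
                    "name": t.name,
                    "group": t.group,
                    "unit": t.unit,
                    "mode": t.mode,
                    "organ": t.organ,
                }
                for t in self
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class PhenotypeTable:
    """Long-format trait observations plus optional design metadata.

    ``data`` holds the nine canonical columns; ``design`` (if given) is the
    :class:`~rootplast.synthetic_trial.DesignSpec` the table conforms to.
    """

    data: pd.DataFrame
    design: object | None = None
    level: str = "view"  # finest index still present: view, plant, plot or cell

    def __post_init__(self) -> None:
        missing = [c for c in LONG_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns {missing}")
        self.data = self.data.loc[:, list(LONG_COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.data["genotype"].unique())

    @property
    def p_levels(self) -> list[float]:
        return sorted(self.data["p_rate"].unique())

    def validate(self, registry: TraitRegistry | None = None) -> None:
        """Check key uniqueness, finite values, and registry membership."""
        dup = self.data.duplicated(subset=list(KEY_COLUMNS))
        if dup.any():
            key = tuple(self.data.loc[dup.idxmax(), list(KEY_COLUMNS)])
            raise ValueError(f"duplicate observation key {key}")
        if not np.isfinite(self.data["value"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite trait values present")
        if registry is not None:
            unknown = sorted(set(self.data["trait"]) - set(registry.acronyms))
            if unknown:
                raise ValueError(f"unknown trait acronyms: {unknown}")

    def select(self, trait: str) -> pd.DataFrame:
        out = self.data[self.data["trait"] == trait]
        if out.empty:
            raise KeyError(f"trait {trait!r} not present in table")
        return out

    def wide(self, index: Sequence[str] = ("genotype", "p_rate")) -> pd.DataFrame:
        """Pivot to an observations x traits matrix of means over ``index``."""
        return (
            self.data.groupby([*index, "trait"], observed=True)["value"]
            .mean()
            .unstack("trait")
        )

    def aggregate(self, level: str, *, allow_unbalanced: bool = False) -> "PhenotypeTable":
        return aggregate(self, level, allow_unbalanced=allow_unbalanced)

    def to_csv(self, path: str | Path) -> None:
        write_long_csv(self, path)


#: index columns retained at each aggregation level (coarser levels drop more).
_LEVEL_KEYS: dict[str, tuple[str, ...]] = {
    "view": KEY_COLUMNS,
    "plant": ("genotype", "p_rate", "run", "block", "plot", "plant", "trait"),
    "plot": ("genotype", "p_rate", "run", "block", "plot", "trait"),
    "cell": ("genotype", "p_rate", "trait"),
}

_LEVEL_ORDER = ("view", "plant", "plot", "cell")


def aggregate(
    table: PhenotypeTable, level: str, *, allow_unbalanced: bool = False
) -> PhenotypeTable:
    """Average observations up to ``level`` ("plant", "plot" or "cell").

    Aggregation is the arithmetic mean over all finer indices (views into
    plants, plants into plots, plots into genotype x P-rate cells).  On
    balanced tables aggregation is associative: view->plant->plot equals
    view->plot directly.  Unequal group sizes are rejected unless
    ``allow_unbalanced`` is set, because means of unequal groups silently
    reweight the data.
    """
    if level not in _LEVEL_KEYS or level == "view":
        raise ValueError(f"level must be one of {'/'.join(_LEVEL_ORDER[1:])}, got {level!r}")
    if _LEVEL_ORDER.index(level) <= _LEVEL_ORDER.index(table.level):
        raise ValueError(f"table already at level {table.level!r}; cannot aggregate to {level!r}")
    keys = list(_LEVEL_KEYS[level])
    grouped = table.data.groupby(keys, observed=True, dropna=False)["value"]
    sizes = grouped.size()
    if sizes.empty or (sizes == 0).any():
        raise ValueError("empty aggregation group")
    if not allow_unbalanced and sizes.nunique() > 1:
        raise ValueError(
            "unbalanced table: group sizes differ; aggregate per level explicitly "
            "or pass allow_unbalanced=True"
        )
    out = grouped.mean().reset_index()
    for col in KEY_COLUMNS:
        if col not in out.columns:
            out[col] = 0
    out = out.loc[:, list(LONG_COLUMNS)]
    return PhenotypeTable(out, design=table.design, level=level)


def read_long_csv(path: str | Path, registry: TraitRegistry | None = None) -> PhenotypeTable:
    """Read a long-format observation CSV.

    Numeric parsing is locale-independent: period decimal separator, optional
    thousands separators (``24,059``) stripped.  Malformed rows raise with the
    offending file line number; trait acronyms absent from ``registry`` and
    duplicate observation keys are rejected.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in LONG_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    def _numeric(col: str, caster):
        series = raw[col].str.replace(",", "", regex=False).str.strip()
        out = pd.to_numeric(series, errors="coerce")
        bad = out.isna() | (series == "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(f"{path}: malformed {col!r} value {raw[col][bad.idxmax()]!r} at line {line}")
        return out.astype(caster)

    df = pd.DataFrame(
        {
            "genotype": raw["genotype"].str.strip(),
            "p_rate": _numeric("p_rate", float),
            "run": _numeric("run", int),
            "block": _numeric("block", int),
            "plot": _numeric("plot", int),
            "plant": _numeric("plant", int),
            "view": _numeric("view", int),
            "trait": raw["trait"].str.strip(),
            "value": _numeric("value", float),
        }
    )
    table = PhenotypeTable(df)
    table.validate(registry)
    return table


def write_long_csv(table: PhenotypeTable, path: str | Path) -> None:
    """Write the canonical long format, round-trippable to full precision."""
    table.data.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# packaged published-summary fixture


def _fixture_bytes() -> bytes:
    ref = resources.files("rootplast.data").joinpath("table1_summary.csv")
    return ref.read_bytes()


def _parse_p(series: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Parse printed p-values; '<0.001' maps to its numeric bound, flagged."""
    censored = series.str.startswith("<")
    numeric = pd.to_numeric(series.str.lstrip("<"), errors="raise")
    return numeric, censored


def load_table1_fixture() -> pd.DataFrame:
    """Published per-trait summary: mean, range, SD, CoV%, ANOVA p's, H².

    Returns one row per trait with canonical columns ``mean``, ``range``,
    ``sd``, ``cov_pct``, ``p_geno``/``p_p``/``p_gxp`` (numeric, with
    ``*_censored`` flags for values printed as "<0.001") and ``h2`` (NaN where
    the published table prints a dash).  The packaged file is bit-exact; a
    checksum mismatch raises.
    """
    payload = _fixture_bytes()
    digest = hashlib.sha256(payload).hexdigest()
    if digest != TABLE1_SHA256:
        raise ValueError(
            f"table1_summary.csv checksum mismatch: {digest} != {TABLE1_SHA256}"
        )
    import io

    raw = pd.read_csv(io.BytesIO(payload), dtype=str, keep_default_na=False)

    def _num(col: str) -> pd.Series:
        return pd.to_numeric(raw[col].str.replace(",", "", regex=False))

    out = pd.DataFrame(
        {
            "acronym": raw["acronym"],
            "name": raw["name"],
            "group": raw["group"].str.lower(),
            "mode": raw["mode"],
            "organ": raw["organ"],
            "unit": raw["unit"],
            "mean": _num("mean"),
            # printed column order is mean / dispersion-A / dispersion-B / CoV;
            # dispersion-B is the one whose 100*x/mean reproduces the printed CoV,
            # so it is the SD and dispersion-A is the range.
            "range": _num("sd_printed"),
            "sd": _num("range_printed"),
            "cov_pct": _num("cov_pct"),
        }
    )
    for col in ("p_geno", "p_p", "p_gxp"):
        numeric, censored = _parse_p(raw[col])
        out[col] = numeric
        out[f"{col}_censored"] = censored
    out["h2"] = pd.to_numeric(raw["h2"].replace("-", np.nan))
    if len(out) != 51:
        raise ValueError(f"expected 51 fixture rows, found {len(out)}")
    return out


def table1_registry() -> TraitRegistry:
    """The 51-trait registry (acronym, group, unit, extraction mode, organ)."""
    return TraitRegistry.from_frame(load_table1_fixture())
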