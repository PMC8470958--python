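"""Pair-structured twin phenotype data.

The sampling unit throughout the package is the *twin pair*, never the
individual.  A dataset is a wide table with one row per pair:

    pair_id, zygosity, age_1, age_2, sex_1, sex_2, <T>_1, <T>_2, ...

where ``<T>`` ranges over the phenotype (trait) names, suffix ``_1``/``_2``
distinguishes the two co-twins, sex is coded 0 = male / 1 = female, and a
missing value is an empty cell.  Zygosity is MZ (monozygotic) or DZ
(dizygotic); the MZ/DZ contrast is what identifies genetic versus
environmental variance in all downstream models.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Zygosity",
    "TwinPairRecord",
    "TwinDataset",
    "TwinCorrelations",
    "DataFormatError",
    "ValidationError",
    "EstimationError",
    "read_twin_csv",
    "write_twin_csv",
    "complete_case_filter",
    "twin_correlations",
]


class DataFormatError(ValueError):
    """A file does not follow the wide twin-pair CSV dialect."""


class ValidationError(ValueError):
    """Structurally well-formed input with invalid content."""


class EstimationError(RuntimeError):
    """Too little usable data to estimate the requested quantity."""


class Zygosity(str, enum.Enum):
    MZ = "MZ"
    DZ = "DZ"

    @classmethod
    def parse(cls, label: str) -> "Zygosity":
        try:
            return cls(str(label).strip().upper())
        except ValueError:
            raise ValidationError(
                f"unknown zygosity label {label!r}; expected MZ or DZ"
            ) from None


#: mandatory non-trait columns, in canonical order
META_COLUMNS = ("pair_id", "zygosity", "age_1", "age_2", "sex_1", "sex_2")


def _parse_float_column(series: pd.Series) -> pd.Series:
    """Exact float parsing: unparseable cells become missing.  Python's
    ``float`` is correctly rounded, so finite values survive a write/read
    round-trip bit-identically (pandas' fast parser does not guarantee
    that)."""
    if pd.api.types.is_numeric_dtype(series):
        return series.astype(float)

    def parse(v):
        if pd.isna(v):
            return np.nan
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan

    return series.map(parse).astype(float)


@dataclass(frozen=True)
class TwinPairRecord:
    """One twin pair: identifier, zygosity, per-twin covariates and traits."""

    pair_id: str
    zygosity: Zygosity
    age: np.ndarray  # shape (2,)
    sex: np.ndarray  # shape (2,), 0 = male, 1 = female
    phenotypes: np.ndarray  # shape (2, p), trait order fixed by the dataset


@dataclass
class TwinDataset:
    """Ordered collection of twin pairs sharing one trait ordering.

    ``table`` holds the wide representation (one row per pair); ``trait_names``
    fixes the trait order used by every array accessor and by the models.
    """

    table: pd.DataFrame
    trait_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.trait_names = tuple(self.trait_names)
        missing = [c for c in self.expected_columns() if c not in self.table.columns]
        if missing:
            raise DataFormatError(f"missing mandatory column(s): {', '.join(missing)}")
        if self.table["pair_id"].duplicated().any():
            dups = self.table.loc[self.table["pair_id"].duplicated(), "pair_id"]
            raise ValidationError(f"duplicate pair_id: {dups.iloc[0]!r}")
        zyg = self.table["zygosity"].map(lambda s: Zygosity.parse(s).value)
        table = self.table.loc[:, list(self.expected_columns())].copy()
        table["zygosity"] = zyg
        for col in table.columns[2:]:
            table[col] = _parse_float_column(table[col])
        self.table = table.reset_index(drop=True)
        opposite = (self.table["sex_1"] != self.table["sex_2"]) & np.isfinite(
            self.table[["sex_1", "sex_2"]]
        ).all(axis=1)
        if opposite.any():
            logger.warning(
                "%d opposite-sex pair(s) present; the models assume a same-sex design",
                int(opposite.sum()),
            )

    def expected_columns(self) -> tuple[str, ...]:
        trait_cols = [f"{t}_{j}" for t in self.trait_names for j in (1, 2)]
        return META_COLUMNS + tuple(trait_cols)

    # -- basic structure ---------------------------------------------------

    @property
    def n_pairs(self) -> int:
        return len(self.table)

    @property
    def n_mz(self) -> int:
        return int((self.table["zygosity"] == "MZ").sum())

    @property
    def n_dz(self) -> int:
        return int((self.table["zygosity"] == "DZ").sum())

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @property
    def records(self) -> list[TwinPairRecord]:
        y, ages, sexes, zyg = self.arrays()
        return [
            TwinPairRecord(
                pair_id=str(self.table["pair_id"].iloc[k]),
                zygosity=Zygosity(zyg[k]),
                age=ages[k],
                sex=sexes[k],
                phenotypes=y[k],
            )
            for k in range(self.n_pairs)
        ]

    # -- array accessors ---------------------------------------------------

    def arrays(
        self, traits: Sequence[str] | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return ``(y, ages, sexes, zygosity)`` with shapes
        ``(n, 2, p), (n, 2), (n, 2), (n,)``."""
        traits = self.trait_names if traits is None else tuple(traits)
        unknown = [t for t in traits if t not in self.trait_names]
        if unknown:
            raise ValidationError(f"unknown trait(s): {', '.join(unknown)}")
        n, p = self.n_pairs, len(traits)
        y = np.empty((n, 2, p))
        for i, t in enumerate(traits):
            y[:, 0, i] = self.table[f"{t}_1"].to_numpy(float)
            y[:, 1, i] = self.table[f"{t}_2"].to_numpy(float)
        ages = self.table[["age_1", "age_2"]].to_numpy(float)
        sexes = self.table[["sex_1", "sex_2"]].to_numpy(float)
        zyg = self.table["zygosity"].to_numpy(str)
        return y, ages, sexes, zyg

    def subset(self, mask: np.ndarray) -> "TwinDataset":
        return TwinDataset(self.table.loc[np.asarray(mask, bool)].copy(), self.trait_names)


@dataclass(frozen=True)
class TwinCorrelations:
    """Double-entry twin correlations for one trait, per zygosity group."""

    trait: str
    r_mz: float
    r_dz: float
    n_mz_pairs: int
    n_dz_pairs: int


# ---------------------------------------------------------------------------
# CSV I/O


def read_twin_csv(path, trait_names: Sequence[str] | None = None) -> TwinDataset:
    """Read the wide twin-pair CSV dialect.

    Trait columns are inferred as every ``T_1``/``T_2`` pair beyond the
    mandatory columns (header order preserved) unless ``trait_names`` is
    given, in which case exactly those columns are required.  Unparseable
    numeric cells become missing values; zygosity labels are matched
    case-insensitively.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    frame = frame.replace("", np.nan)
    for col in META_COLUMNS:
        if col not in frame.columns:
            raise DataFormatError(f"missing mandatory column(s): {col}")
    if trait_names is None:
        trait_names = []
        for col in frame.columns:
            if col in META_COLUMNS:
                continue
            if col.endswith("_1") and f"{col[:-2]}_2" in frame.columns:
                trait_names.append(col[:-2])
    else:
        for t in trait_names:
            for j in (1, 2):
                if f"{t}_{j}" not in frame.columns:
                    raise DataFormatError(f"missing mandatory column(s): {t}_{j}")
    return TwinDataset(frame, tuple(trait_names))


def write_twin_csv(dataset: TwinDataset, path) -> None:
    """Write ``dataset`` in the exact dialect :func:`read_twin_csv` consumes.

    Missing values become empty cells; finite values round-trip bit-identically
    (17 significant digits)."""
    out = dataset.table.copy()
    for col in out.columns[2:]:
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else np.format_float_positional(v, trim="0"))
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Filtering and correlations


def complete_case_filter(
    dataset: TwinDataset, traits: Sequence[str] | None = None
) -> TwinDataset:
    """Keep pairs where BOTH twins have finite values for all requested
    traits *and* for age and sex.  Idempotent; logs the exclusion count."""
    traits = dataset.trait_names if traits is None else tuple(traits)
    y, ages, sexes, _ = dataset.arrays(traits)
    ok = (
        np.isfinite(y).all(axis=(1, 2))
        & np.isfinite(ages).all(axis=1)
        & np.isfinite(sexes).all(axis=1)
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info(
            "complete_case_filter: excluded %d of %d pairs (traits: %s)",
            n_dropped,
            dataset.n_pairs,
            ", ".join(traits),
        )
    return dataset.subset(ok)


def twin_correlations(dataset: TwinDataset, trait: str) -> TwinCorrelations:
    """Double-entry Pearson twin correlation per zygosity group.

    Each complete pair contributes both orderings (y1, y2) and (y2, y1), so
    the estimate is exactly invariant to within-pair twin order.  Implemented
    through per-pair symmetric sums (y1 + y2, y1^2 + y2^2, y1*y2), which makes
    the invariance hold bit-for-bit.
    """
    y, _, _, zyg = dataset.arrays([trait])
    out = {}
    for group in ("MZ", "DZ"):
        yy = y[zyg == group, :, 0]
        yy = yy[np.isfinite(yy).all(axis=1)]
        n = len(yy)
        if n < 3:
            raise EstimationError(
                f"need >=3 complete {group} pairs for trait {trait!r}, got {n}"
            )
        y1, y2 = yy[:, 0], yy[:, 1]
        m = np.sum(y1 + y2) / (2 * n)
        var = np.sum(y1 * y1 + y2 * y2) / (2 * n) - m * m
        cov = np.sum(y1 * y2) / n - m * m
        if var <= 0:
            raise EstimationError(f"zero variance for trait {trait!r} in group {group}")
        out[group] = (float(cov / var), n)
    return TwinCorrelations(
        trait=trait,
        r_mz=out["MZ"][0],
        r_dz=out["DZ"][0],
        n_mz_pairs=out["MZ"][1],
        n_dz_pairs=out["DZ"][1],
    )
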