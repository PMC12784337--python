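"""Typed data model for mixed-measurement-level datasets.

A dataset couples a rectangular table (one row per participant) with a
metadata record per column assigning a role (predictor / response) and a
measurement level (numeric / binary / nominal / ordinal).  Responses may be
numeric, binary or ordinal; nominal variables are allowed on the predictor
side only.  Discrete variables are coded with 1-based integer category
codes in input files; binary responses use {0, 1}.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

ROLES = ("predictor", "response")
LEVELS = ("numeric", "binary", "nominal", "ordinal")


class ConfigError(ValueError):
    """Invalid variable metadata."""


class DataError(ValueError):
    """Invalid data table (missing cells, out-of-range codes, ...)."""


@dataclass(frozen=True)
class VariableSpec:
    """Role / level / category metadata for one column.

    ``n_categories`` is the number of categories C for discrete variables
    and 0 for numeric ones.  ``category_order`` optionally carries labels
    for ordinal categories, low to high.
    """

    name: str
    role: str
    level: str
    n_categories: int = 0
    category_order: tuple = ()

    def __post_init__(self):
        if self.role not in ROLES:
            raise ConfigError(f"{self.name}: unknown role {self.role!r}")
        if self.level not in LEVELS:
            raise ConfigError(f"{self.name}: unknown level {self.level!r}")
        if self.level == "numeric" and self.n_categories != 0:
            raise ConfigError(f"{self.name}: numeric implies n_categories=0")
        if self.level == "binary" and self.n_categories != 2:
            raise ConfigError(f"{self.name}: binary implies n_categories=2")
        if self.level in ("nominal", "ordinal") and self.n_categories < 2:
            raise ConfigError(
                f"{self.name}: {self.level} needs n_categories >= 2"
            )
        if self.role == "response" and self.level == "nominal":
            raise ConfigError(
                f"{self.name}: nominal level is not allowed for responses"
            )
        if self.category_order and len(self.category_order) != self.n_categories:
            raise ConfigError(
                f"{self.name}: category_order length != n_categories"
            )

    @property
    def is_discrete(self) -> bool:
        return self.level in ("binary", "nominal", "ordinal")


@dataclass
class Dataset:
    """Validated raw data: predictors X (N x P), responses Y (N x R).

    Numeric columns hold floats; discrete predictor columns hold integer
    codes 1..C; binary responses hold 0/1 and ordinal responses 1..C.
    """

    X: np.ndarray
    Y: np.ndarray
    predictor_specs: list = field(default_factory=list)
    response_specs: list = field(default_factory=list)

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def P(self) -> int:
        return self.X.shape[1]

    @property
    def R(self) -> int:
        return self.Y.shape[1]

    @property
    def specs(self) -> list:
        return list(self.predictor_specs) + list(self.response_specs)

    def response_families(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Boolean masks (numeric, binary, ordinal) over response columns."""
        lv = np.array([s.level for s in self.response_specs])
        return lv == "numeric", lv == "binary", lv == "ordinal"

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for j, s in enumerate(self.predictor_specs):
            col = self.X[:, j]
            cols[s.name] = col if s.level == "numeric" else col.astype(int)
        for j, s in enumerate(self.response_specs):
            col = self.Y[:, j]
            cols[s.name] = col if s.level == "numeric" else col.astype(int)
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class IndicatorMatrix:
    """0/1 indicator matrix G (N x C) with per-category counts."""

    G: np.ndarray
    frequencies: np.ndarray


def build_indicator(codes: Sequence[int], n_categories: int) -> IndicatorMatrix:
    """Indicator matrix for 1-based category codes.

    Every declared category must occur at least once; an empty category
    would make its quantification undefined.
    """
    codes = np.asarray(codes)
    if codes.size == 0:
        raise DataError("empty code vector")
    if np.any((codes < 1) | (codes > n_categories)):
        bad = sorted({int(c) for c in codes[(codes < 1) | (codes > n_categories)]})
        raise DataError(f"codes outside 1..{n_categories}: {bad}")
    idx = codes.astype(int) - 1
    freq = np.bincount(idx, minlength=n_categories)
    empty = np.flatnonzero(freq == 0)
    if empty.size:
        raise DataError(f"empty categories (1-based): {[int(c) for c in empty + 1]}")
    G = np.zeros((codes.size, n_categories))
    G[np.arange(codes.size), idx] = 1.0
    return IndicatorMatrix(G=G, frequencies=freq)


def standardize(values: Sequence[float]) -> np.ndarray:
    """Center and scale to mean 0, variance 1 (population, divide-by-N).

    The divide-by-N convention is used for every "variance 1" constraint in
    the package (numeric predictors and quantified variables alike).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DataError("need at least 2 values to standardize")
    sd = x.std()  # ddof=0
    if sd <= 0 or not np.isfinite(sd):
        raise DataError("constant column cannot be standardized")
    return (x - x.mean()) / sd


def _validate_discrete(col: pd.Series, spec: VariableSpec) -> np.ndarray:
    vals = col.to_numpy()
    if not np.all(np.isfinite(vals.astype(float))):
        raise DataError(f"{spec.name}: non-finite category code")
    codes = vals.astype(float)
    if np.any(codes != np.round(codes)):
        raise DataError(f"{spec.name}: non-integer category code")
    codes = codes.astype(int)
    if spec.role == "response" and spec.level == "binary":
        bad = set(codes) - {0, 1}
        if bad:
            raise DataError(f"{spec.name}: binary response codes must be 0/1, got {sorted(bad)}")
        return codes
    lo, hi = 1, spec.n_categories
    out = codes[(codes < lo) | (codes > hi)]
    if out.size:
        raise DataError(
            f"{spec.name}: code(s) {sorted({int(c) for c in out})} outside declared range 1..{hi}"
        )
    missing = sorted(set(range(lo, hi + 1)) - {int(c) for c in codes})
    if missing:
        raise DataError(f"{spec.name}: declared categories never observed: {missing}")
    return codes


def _parse_config(config) -> list[VariableSpec]:
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        try:
            entries = json.loads(text)
        except json.JSONDecodeError:
            entries = yaml.safe_load(text)
    else:
        entries = config
    if not isinstance(entries, list):
        raise ConfigError("config must be a list of variable entries")
    specs = []
    for i, e in enumerate(entries):
        if isinstance(e, VariableSpec):
            specs.append(e)
            continue
        if not isinstance(e, dict) or "name" not in e:
            raise ConfigError(f"config entry {i}: expected a mapping with a 'name'")
        try:
            specs.append(
                VariableSpec(
                    name=e["name"],
                    role=e.get("role", ""),
                    level=e.get("level", ""),
                    n_categories=int(e.get("n_categories", 0)),
                    category_order=tuple(e.get("order", e.get("category_order", ()))),
                )
            )
        except ConfigError:
            raise
        except Exception as exc:  # noqa: BLE001 - name the offending entry
            raise ConfigError(f"config entry {e.get('name', i)}: {exc}") from exc
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate variable names in config")
    return specs


def load_dataset(table, config) -> Dataset:
    """Load a delimited table plus variable metadata into a Dataset.

    ``table`` is a CSV path or a DataFrame; ``config`` is a JSON/YAML path
    or a list of spec mappings.  Columns present in the table but absent
    from the config are dropped with a warning; config entries without a
    matching column are an error.  Missing cells are rejected.
    """
    specs = _parse_config(config)
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table)
    by_name = {s.name: s for s in specs}
    missing_cols = [n for n in by_name if n not in df.columns]
    if missing_cols:
        raise ConfigError(f"config names not found in table: {missing_cols}")
    dropped = [c for c in df.columns if c not in by_name]
    if dropped:
        logger.warning("dropping columns not in config: %s", dropped)
    for name in by_name:
        col = df[name]
        if col.isna().any():
            row = int(col.index[col.isna()][0])
            raise DataError(f"missing cell at row {row}, column {name!r}")

    pred = [s for s in specs if s.role == "predictor"]
    resp = [s for s in specs if s.role == "response"]
    if not pred or not resp:
        raise ConfigError("need at least one predictor and one response")

    def extract(spec_list):
        cols = []
        for s in spec_list:
            if s.level == "numeric":
                cols.append(df[s.name].to_numpy(dtype=float))
            else:
                cols.append(_validate_discrete(df[s.name], s).astype(float))
        return np.column_stack(cols)

    return Dataset(
        X=extract(pred), Y=extract(resp),
        predictor_specs=pred, response_specs=resp,
    )


def save_dataset(dataset: Dataset, table_path, config_path) -> None:
    """Write the data table as CSV and the variable metadata as JSON."""
    dataset.to_frame().to_csv(table_path, index=False)
    entries = [
        {
            "name": s.name,
            "role": s.role,
            "level": s.level,
            "n_categories": s.n_categories,
            "order": list(s.category_order),
        }
        for s in dataset.specs
    ]
    Path(config_path).write_text(json.dumps(entries, indent=1))
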