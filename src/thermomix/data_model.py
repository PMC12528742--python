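"""Domain types and I/O for insect rearing datasets and fitted mixture models.

A rearing dataset holds one row per individual that completed development:
the development time ``D`` in days, the constant rearing temperature ``T``
in degrees Celsius, and optional covariates (sex, body length, body weight).
Individuals that died before reaching the landmark stage never appear as
rows; no censoring model is applied.

Datasets travel as UTF-8 CSV with canonical column names
``dev_time_days, temp_C, sex, length_mm, weight_mg``; fitted mixture models
travel as JSON (see :func:`write_model_json`).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical CSV column names.
REQUIRED_COLUMNS = ("dev_time_days", "temp_C")
OPTIONAL_COLUMNS = ("sex", "length_mm", "weight_mg")

VALID_SEX = frozenset({"M", "F", "unknown"})


class SchemaError(ValueError):
    """A required column is missing or a value violates the schema."""


class ParseError(ValueError):
    """A cell could not be parsed as the expected type."""


@dataclass(frozen=True)
class DevelopmentRecord:
    """One reared individual.

    Parameters
    ----------
    dev_time : float
        Development time D in days; must be positive.
    temp : float
        Rearing temperature T in degrees Celsius.
    sex : str
        One of ``"M"``, ``"F"`` or ``"unknown"``.
    length : float or None
        Body length in mm, if measured.
    weight : float or None
        Body weight in mg, if measured.
    """

    dev_time: float
    temp: float
    sex: str = "unknown"
    length: float | None = None
    weight: float | None = None

    def __post_init__(self) -> None:
        if not (self.dev_time > 0 and math.isfinite(self.dev_time)):
            raise ValueError(f"dev_time must be a positive finite number, got {self.dev_time}")
        if not math.isfinite(self.temp):
            raise ValueError(f"temp must be finite, got {self.temp}")
        if self.sex not in VALID_SEX:
            raise ValueError(f"sex must be one of {sorted(VALID_SEX)}, got {self.sex!r}")
        for name in ("length", "weight"):
            v = getattr(self, name)
            if v is not None and not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be positive when present, got {v}")


@dataclass
class Dataset:
    """An ordered collection of :class:`DevelopmentRecord`.

    All individuals together form the *combined population*; latent
    subgroups within it (component populations) are what the mixture
    model recovers.
    """

    records: list[DevelopmentRecord]
    species_label: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("Dataset must contain at least one record")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def dev_time(self) -> np.ndarray:
        return np.array([r.dev_time for r in self.records], dtype=float)

    @property
    def temp(self) -> np.ndarray:
        return np.array([r.temp for r in self.records], dtype=float)

    @property
    def length(self) -> np.ndarray:
        """Body lengths with NaN for absent measurements."""
        return np.array(
            [r.length if r.length is not None else np.nan for r in self.records], dtype=float
        )

    @property
    def sex(self) -> np.ndarray:
        return np.array([r.sex for r in self.records], dtype=object)

    def n_distinct_temps(self) -> int:
        return len(set(r.temp for r in self.records))

    def require_temperature_spread(self, n: int = 2) -> None:
        if self.n_distinct_temps() < n:
            raise ValueError(
                f"fitting requires at least {n} distinct temperatures, "
                f"dataset has {self.n_distinct_temps()}"
            )

    def to_frame(self) -> pd.DataFrame:
        """Canonical tabular view (column names match the CSV schema)."""
        return pd.DataFrame(
            {
                "dev_time_days": self.dev_time,
                "temp_C": self.temp,
                "sex": self.sex,
                "length_mm": self.length,
                "weight_mg": np.array(
                    [r.weight if r.weight is not None else np.nan for r in self.records]
                ),
            }
        )


def _resolve_columns(
    columns: Sequence[str], column_map: Mapping[str, str] | None
) -> dict[str, str]:
    """Map canonical names to actual CSV header names."""
    resolved: dict[str, str] = {}
    inverse = {v: k for k, v in (column_map or {}).items()}
    for canonical in REQUIRED_COLUMNS + OPTIONAL_COLUMNS:
        if canonical in columns:
            resolved[canonical] = canonical
        elif column_map and canonical in column_map and column_map[canonical] in columns:
            resolved[canonical] = column_map[canonical]
        elif canonical in inverse and inverse[canonical] in columns:
            resolved[canonical] = inverse[canonical]
    missing = [c for c in REQUIRED_COLUMNS if c not in resolved]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return resolved


def read_development_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    species_label: str = "",
) -> Dataset:
    """Read a rearing dataset from CSV.

    Rows with a missing development time or temperature are dropped (a
    warning counts them); row order is otherwise preserved.

    Parameters
    ----------
    path
        CSV file with a header row. Decimal separator is ``'.'``,
        field separator ``','``.
    column_map
        Optional mapping from canonical column names
        (``dev_time_days``, ``temp_C``, ...) to the names used in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty input file: {path}") from exc
    if df.empty:
        raise ValueError(f"no data rows in {path}")
    cols = _resolve_columns(list(df.columns), column_map)

    records: list[DevelopmentRecord] = []
    n_dropped = 0
    for idx, row in df.iterrows():
        raw_d = row[cols["dev_time_days"]]
        raw_t = row[cols["temp_C"]]
        if pd.isna(raw_d) or pd.isna(raw_t):
            n_dropped += 1
            continue
        try:
            d = float(raw_d)
            t = float(raw_t)
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"non-numeric dev_time/temp at data row {idx + 1}: "
                f"({raw_d!r}, {raw_t!r})"
            ) from exc
        sex = "unknown"
        if "sex" in cols and not pd.isna(row[cols["sex"]]):
            sex = str(row[cols["sex"]])
        length = None
        if "length_mm" in cols and not pd.isna(row[cols["length_mm"]]):
            length = float(row[cols["length_mm"]])
        weight = None
        if "weight_mg" in cols and not pd.isna(row[cols["weight_mg"]]):
            weight = float(row[cols["weight_mg"]])
        records.append(DevelopmentRecord(d, t, sex, length, weight))
    if n_dropped:
        logger.warning("dropped %d row(s) with missing dev_time or temp", n_dropped)
    if not records:
        raise ValueError(f"all {n_dropped} data rows were missing dev_time or temp")
    return Dataset(records, species_label=species_label)


def write_development_csv(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset in the canonical CSV schema (lossless round-trip)."""
    dataset.to_frame().to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Model JSON I/O. The MixtureModel type itself lives in weibull_mix; the
# (de)serialization is kept here with the rest of the artifact plumbing.
# ---------------------------------------------------------------------------

def write_model_json(model, path: str | Path) -> None:
    """Serialize a fitted mixture model to JSON at full float precision.

    Schema::

        {"components": [{"weight", "shape", "scale", "t0"}, ...],
         "meta": {"loglik", "n_obs", "n_iter", "converged", "seed"}}
    """
    model.validate()
    doc = {
        "components": [
            {"weight": c.weight, "shape": c.shape, "scale": c.scale, "t0": c.t0}
            for c in model.components
        ],
        "meta": {
            "loglik": model.loglik,
            "n_obs": model.n_obs,
            "n_iter": model.n_iter,
            "converged": model.converged,
            "seed": model.seed,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_model_json(path: str | Path):
    """Load a mixture model written by :func:`write_model_json`.

    Invariants (positive shapes/scales, weights summing to one) are
    re-validated on load.
    """
    from .weibull_mix import MixtureModel, WeibullComponent

    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed model JSON in {path}: {exc}") from exc
    try:
        comps = [
            WeibullComponent(
                weight=float(c["weight"]),
                shape=float(c["shape"]),
                scale=float(c["scale"]),
                t0=float(c["t0"]),
            )
            for c in doc["components"]
        ]
        meta = doc.get("meta", {})
        model = MixtureModel(
            components=comps,
            loglik=float(meta.get("loglik", float("nan"))),
            n_obs=int(meta.get("n_obs", 0)),
            n_iter=int(meta.get("n_iter", 0)),
            converged=bool(meta.get("converged", False)),
            seed=int(meta.get("seed", 0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"model JSON schema violation in {path}: {exc}") from exc
    model.validate()
    return model
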