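"""Reading and writing food-web sample tables and site configuration.

CSV dialect: comma-separated, UTF-8, header required, ``.`` decimal.
Missing values are written as empty cells; ``""`` and ``"NA"`` are both
accepted as missing on input.  Booleans are written lowercase
(``true``/``false``).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Optional, Union

import pandas as pd
import yaml
from pydantic import ValidationError

from .datamodel import BiotaSample, FoodWebDataset

#: Column order of the food-web CSV schema.
CSV_COLUMNS = [
    "sample_id",
    "species",
    "taxon_group",
    "endotherm",
    "tissue",
    "habitat",
    "d15n",
    "d13c",
    "d34s",
    "concentration",
    "basis",
    "lipid_fraction",
    "water_fraction",
    "detected",
    "detection_limit",
    "pool_size",
    "season",
    "location",
]

_REQUIRED_COLUMNS = ["sample_id", "species", "taxon_group", "d15n"]
_FLOAT_FIELDS = {
    "d15n",
    "d13c",
    "d34s",
    "concentration",
    "lipid_fraction",
    "water_fraction",
    "detection_limit",
}
_BOOL_FIELDS = {"endotherm", "detected"}
_MISSING_TOKENS = {"", "NA", "NaN", "nan"}


class SchemaError(ValueError):
    """The CSV header does not match the documented schema."""


class RowError(ValueError):
    """One or more rows failed parsing or validation."""


def _parse_cell(name: str, raw: Any, row: int):
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    text = str(raw).strip()
    if text in _MISSING_TOKENS:
        return None
    if name in _FLOAT_FIELDS:
        try:
            return float(text)
        except ValueError:
            raise RowError(f"row {row}: non-numeric value {text!r} in column {name!r}")
    if name in _BOOL_FIELDS:
        low = text.lower()
        if low in {"true", "1", "yes"}:
            return True
        if low in {"false", "0", "no"}:
            return False
        raise RowError(f"row {row}: non-boolean value {text!r} in column {name!r}")
    if name == "pool_size":
        try:
            return int(float(text))
        except ValueError:
            raise RowError(f"row {row}: non-integer value {text!r} in column {name!r}")
    return text


def read_foodweb_csv(
    path: Union[str, Path], config: Optional[dict[str, Any]] = None
) -> FoodWebDataset:
    """Read a food-web sample table and build a validated dataset.

    Parameters
    ----------
    path
        CSV file following :data:`CSV_COLUMNS`.
    config
        Dataset metadata (``baseline_species`` required; optional
        ``baseline_tl``, ``enrichment_factor``, ``ecosystem``,
        ``latitude_class``, ``sampling_window``), e.g. loaded with
        :func:`read_dataset_config`.

    Raises
    ------
    SchemaError
        if a required column is missing from the header.
    RowError
        if any row fails to parse or violates a sample invariant; the
        message names every offending row (1-based data rows).
    """
    config = dict(config or {})
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    samples: list[BiotaSample] = []
    errors: list[str] = []
    for i, record in enumerate(frame.to_dict(orient="records"), start=1):
        fields: dict[str, Any] = {}
        try:
            for name in CSV_COLUMNS:
                if name not in record:
                    continue
                value = _parse_cell(name, record[name], i)
                if value is not None:
                    fields[name] = value
            samples.append(BiotaSample(**fields))
        except RowError as exc:
            errors.append(str(exc))
        except ValidationError as exc:
            details = "; ".join(e["msg"] for e in exc.errors())
            errors.append(f"row {i}: {details}")
    if errors:
        raise RowError("invalid rows:\n" + "\n".join(errors))

    return FoodWebDataset(samples=samples, **config)


def _format_cell(value: Any) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if hasattr(value, "value"):  # enums
        return str(value.value)
    if isinstance(value, float):
        return repr(value)  # full round-trip precision
    return str(value)


def write_foodweb_csv(dataset: FoodWebDataset, path: Union[str, Path]) -> None:
    """Write the dataset's samples back to the CSV schema (lossless)."""
    rows = []
    for s in dataset.samples:
        d = s.model_dump()
        rows.append({c: _format_cell(d.get(c)) for c in CSV_COLUMNS})
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def dataset_config(dataset: FoodWebDataset) -> dict[str, Any]:
    """The site metadata of a dataset, as a plain config mapping."""
    return {
        "baseline_species": dataset.baseline_species,
        "baseline_tl": dataset.baseline_tl,
        "enrichment_factor": dataset.enrichment_factor,
        "ecosystem": dataset.ecosystem.value,
        "latitude_class": dataset.latitude_class.value,
        "sampling_window": dataset.sampling_window,
    }


def read_dataset_config(path: Union[str, Path]) -> dict[str, Any]:
    """Load dataset/site metadata from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return {k: v for k, v in data.items() if v is not None}
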