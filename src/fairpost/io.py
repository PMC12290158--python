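"""CSV + YAML-schema persistence for tabular datasets.

A dataset lives in a plain CSV (feature columns, a class column, one or
more protected-attribute columns) accompanied by a small YAML schema that
names the class column, the favorable label value, and for every protected
column its unprivileged value.  The loader maps arbitrary binary codings
(strings included) onto the internal convention: favorable label = 1,
unprivileged group = 0.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import EncodingError, SchemaError
from .synth import TabularDataset

__all__ = ["load_tabular", "save_tabular", "default_schema"]


def default_schema(dataset: TabularDataset) -> dict:
    """Schema describing a dataset already in internal coding."""
    return {
        "class_column": "y",
        "favorable_value": 1,
        "protected": {name: {"unprivileged_value": 0} for name in dataset.protected},
    }


def save_tabular(dataset: TabularDataset, path, schema_path=None) -> None:
    """Write the dataset CSV and (optionally) its sidecar YAML schema."""
    path = Path(path)
    dataset.to_frame().reset_index().to_csv(path, index=False)
    if schema_path is not None:
        Path(schema_path).write_text(yaml.safe_dump(default_schema(dataset)))


def _load_schema(schema) -> dict:
    if isinstance(schema, (str, Path)):
        schema = yaml.safe_load(Path(schema).read_text())
    if not isinstance(schema, dict):
        raise SchemaError("schema must be a mapping or a path to a YAML mapping")
    for key in ("class_column", "favorable_value", "protected"):
        if key not in schema:
            raise SchemaError(f"schema is missing required key {key!r}")
    return schema


def _binarize(col: pd.Series, one_value, name: str) -> np.ndarray:
    values = col.unique()
    if len(values) > 2:
        raise EncodingError(
            f"column {name!r} is not binary; offending values: {sorted(map(str, values))}"
        )
    if one_value not in values and len(values) == 2:
        raise EncodingError(
            f"column {name!r} never takes the declared value {one_value!r}; "
            f"observed: {sorted(map(str, values))}"
        )
    return (col == one_value).astype(int).to_numpy()


def load_tabular(path, schema) -> TabularDataset:
    """Load and validate a dataset from CSV against a YAML schema.

    ``schema`` is a mapping (or path to one) with ``class_column``,
    ``favorable_value`` and ``protected: {column: {unprivileged_value}}``.
    Feature columns are everything else numeric; an ``id`` column, if
    present, supplies the row identifiers.
    """
    schema = _load_schema(schema)
    df = pd.read_csv(path)
    class_col = schema["class_column"]
    if class_col not in df.columns:
        raise SchemaError(f"class column {class_col!r} not in CSV")
    labels = _binarize(df[class_col], schema["favorable_value"], class_col)
    protected = {}
    for name, spec in schema["protected"].items():
        if name not in df.columns:
            raise SchemaError(f"protected column {name!r} not in CSV")
        unpriv = spec["unprivileged_value"]
        col = df[name]
        values = col.unique()
        if len(values) > 2:
            raise EncodingError(
                f"protected column {name!r} is not binary; "
                f"offending values: {sorted(map(str, values))}"
            )
        if unpriv not in values and len(values) == 2:
            raise EncodingError(
                f"protected column {name!r} never takes the declared "
                f"unprivileged value {unpriv!r}; observed: {sorted(map(str, values))}"
            )
        protected[name] = (col != unpriv).astype(int).to_numpy()
    ids = df["id"].to_numpy() if "id" in df.columns else None
    feature_cols = [
        c
        for c in df.columns
        if c not in set(schema["protected"]) | {class_col, "id"}
    ]
    features = df[feature_cols].to_numpy(dtype=float)
    return TabularDataset(
        features=features,
        labels=labels,
        protected=protected,
        ids=ids,
        feature_names=feature_cols,
    )
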