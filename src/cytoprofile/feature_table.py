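"""Conventions for the per-cell feature table, the currency of the pipeline.

A feature table is a :class:`pandas.DataFrame` with three metadata columns
(``cell_id``, ``treatment``, ``replicate``) followed by one numeric column
per cytological parameter. Parameter values may be missing (NaN) upstream
of quality control; QC guarantees completeness downstream.
"""

from __future__ import annotations

import pandas as pd

METADATA_COLUMNS = ["cell_id", "treatment", "replicate"]


def parameter_columns(table: pd.DataFrame) -> list[str]:
    """Names of the parameter (non-metadata) columns, in table order."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check structural invariants; return the table unchanged.

    Raises ``ValueError`` on missing metadata columns, duplicate cell ids,
    or absence of parameter columns.
    """
    missing = [c for c in METADATA_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing metadata columns: {missing}")
    if table["cell_id"].duplicated().any():
        dupes = table.loc[table["cell_id"].duplicated(), "cell_id"].tolist()
        raise ValueError(f"duplicate cell_id values: {dupes[:5]}")
    params = parameter_columns(table)
    if not params:
        raise ValueError("feature table has zero parameter columns")
    return table


def parameter_matrix(table: pd.DataFrame):
    """Parameter block as a float ndarray (cells x parameters)."""
    return table[parameter_columns(table)].to_numpy(dtype=float)
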