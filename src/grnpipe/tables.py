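"""Sample metatable and matrix I/O with validation.

The metatable is a CSV with columns sample_id, file_name, description
(class or query-group annotation). Expression matrices are TSV with genes
in rows and sample ids as the header. Lines starting with '#' (used to
embed the run config hash) are ignored on read.
"""

from __future__ import annotations

import pandas as pd

REQUIRED_COLUMNS = ("sample_id", "file_name", "description")


def validate_sample_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"sample table missing column(s): {missing}")
    dup = table["sample_id"][table["sample_id"].duplicated()]
    if len(dup) > 0:
        raise ValueError(f"duplicate sample_id: {dup.iloc[0]!r}")
    for i, row in table.iterrows():
        for col in REQUIRED_COLUMNS:
            val = row[col]
            if pd.isna(val) or str(val) == "":
                raise ValueError(f"malformed row {i}: empty {col!r}")
    return table.reset_index(drop=True)


def read_sample_table(path) -> pd.DataFrame:
    """Read and validate a sample metatable CSV."""
    table = pd.read_csv(path, dtype=str, comment="#")
    return validate_sample_table(table)


def write_sample_table(table: pd.DataFrame, path) -> None:
    validate_sample_table(table).to_csv(path, index=False)


def read_expression(path) -> pd.DataFrame:
    """Read a gene-by-sample TSV matrix (first column = gene ids)."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_expression(expr: pd.DataFrame, path, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        expr.to_csv(fh, sep="\t")


def write_tsv(df: pd.DataFrame, path, config_hash: str | None = None, index=False):
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index)
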