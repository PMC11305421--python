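"""Small TSV I/O helpers shared across the pipeline.

All tabular output is UTF-8 TSV with ``.`` for missing values.  Files are
written atomically (temp file + rename) so a failing stage never leaves a
partial output behind, and optional ``# key = value`` header lines capture
the configuration that produced the table.
"""
from __future__ import annotations

import os
import tempfile
from pathlib import Path

import pandas as pd

MISSING_TOKEN = "."


def write_tsv(df: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None) -> None:
    path = Path(path)
    body = df.to_csv(sep="\t", index=False, na_rep=MISSING_TOKEN)
    text = "".join(f"# {line}\n" for line in header_lines or []) + body
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    # only "." marks a missing value: "NA" is a legitimate verdict label
    return pd.read_csv(path, sep="\t", na_values=[MISSING_TOKEN], keep_default_na=False,
                       comment="#", **kwargs)
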