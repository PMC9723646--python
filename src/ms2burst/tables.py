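"""Canonical table dialect: TSV, header row, UTF-8, '.' decimal."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a TSV table, checking the header for required columns."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse as TSV table: {exc}") from exc
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(
                f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
            )
    return df
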