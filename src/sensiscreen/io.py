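"""Table input/output conventions.

All tables are TSV with a header line, UTF-8, ``.`` decimal separator and
``NA`` for missing values, so that every intermediate product diffs cleanly
and round-trips losslessly through :func:`write_table` / :func:`read_table`.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["read_table", "write_table"]


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write ``df`` as a headered TSV with ``NA`` for missing values."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    return path


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], **kwargs)
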