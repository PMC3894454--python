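"""Long-format CSV output with reproducibility metadata.

All analysis results leave the package as comma-delimited long-format CSV:
a block of ``#``-prefixed metadata comment lines (command, seed, parameter
defaults), a header row, then one observation per line.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["write_long_csv", "read_long_csv", "aggregated_to_long"]


def write_long_csv(records: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a long-format table with leading ``#`` metadata comment lines.

    Metadata defaults to ``records.attrs['metadata']`` when present.
    """
    if metadata is None:
        metadata = records.attrs.get("metadata", {})
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, val in metadata.items():
            fh.write(f"# {key}: {val}\n")
        records.to_csv(fh, index=False)


def read_long_csv(path) -> pd.DataFrame:
    """Read a long-format CSV written by :func:`write_long_csv`.

    Metadata comment lines are parsed back into ``df.attrs['metadata']``
    as strings.
    """
    metadata = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, val = body.split(":", 1)
                    metadata[key.strip()] = val.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh)
    df.attrs["metadata"] = metadata
    return df


def aggregated_to_long(agg: pd.DataFrame) -> pd.DataFrame:
    """Flatten an aggregated (factors x yerr-units) table back to long format
    with columns (factor levels..., yerr unit, value)."""
    long = agg.stack(future_stack=True).rename("value").reset_index()
    return long
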