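"""Tab-delimited result tables with embedded metadata.

Tables are written as TSV with ``#``-prefixed header lines carrying the full
experiment metadata as JSON (grep-able without the library), and an optional
``.meta.json`` sidecar duplicating it machine-readably.  Floats are written
with shortest-round-trip precision, so write/read is lossless, including the
±inf sentinels that degenerate log-likelihoods can produce.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = ["write_table", "read_table", "TableParseError"]

_META_PREFIX = "# meta: "


class TableParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message}" + (f" (line {line})" if line else ""))


def write_table(df: pd.DataFrame, path, metadata: dict | None = None, sidecar: bool = True) -> None:
    """Write a numeric table as TSV with a ``#`` metadata header."""
    path = Path(path)
    lines = []
    if metadata:
        lines.append(_META_PREFIX + json.dumps(metadata, sort_keys=True))
    lines.append("\t".join(map(str, df.columns)))
    for row in df.itertuples(index=False):
        lines.append("\t".join(repr(v) if isinstance(v, float) else str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    if metadata and sidecar:
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(metadata, indent=2, sort_keys=True) + "\n"
        )


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a table written by :func:`write_table`; returns (frame, metadata)."""
    path = Path(path)
    metadata: dict = {}
    data_lines: list[str] = []
    header: list[str] | None = None
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        if raw.startswith(_META_PREFIX):
            try:
                metadata = json.loads(raw[len(_META_PREFIX):])
            except json.JSONDecodeError as e:
                raise TableParseError(f"bad metadata JSON: {e}", line=ln) from e
            continue
        if raw.startswith("#") or not raw.strip():
            continue
        if header is None:
            header = raw.split("\t")
            continue
        fields = raw.split("\t")
        if len(fields) != len(header):
            raise TableParseError(
                f"expected {len(header)} fields, got {len(fields)}", line=ln
            )
        data_lines.append(raw)
    if header is None:
        raise TableParseError("no header line found")
    if not data_lines:
        return pd.DataFrame(columns=header), metadata
    rows = [line.split("\t") for line in data_lines]
    df = pd.DataFrame(rows, columns=header)
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            pass
    return df, metadata
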