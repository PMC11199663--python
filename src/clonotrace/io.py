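"""Shared readers/writers: count tables (TSV/CSV, gzip transparent) and JSON reports."""

from __future__ import annotations

import dataclasses
import gzip
import hashlib
import json
import re
import warnings
from pathlib import Path
from typing import Any, Dict, Iterable, Optional

import numpy as np

from . import __version__
from .reads import CountTable

SCHEMA_VERSION = "1"
_SEQ_RE = re.compile(r"^[ACGTN]+$", re.IGNORECASE)


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode.replace("t", ""))


class CountTableParseError(ValueError):
    pass


def read_count_table(path, sample_id: Optional[str] = None) -> CountTable:
    """Read a (barcode, count) TSV/CSV; header optional, duplicates summed.

    Raises :class:`CountTableParseError` with the line number on non-integer
    or negative counts and on invalid nucleotide sequences.
    """
    counts: Dict[str, int] = {}
    dupes = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = re.split(r"[\t,]", line)
            if len(fields) < 2:
                raise CountTableParseError(f"{path}:{lineno}: expected 2 columns")
            seq, raw = fields[0].strip(), fields[1].strip()
            if lineno == 1 and not _SEQ_RE.match(seq):
                continue  # header row
            if not _SEQ_RE.match(seq):
                raise CountTableParseError(f"{path}:{lineno}: invalid sequence {seq!r}")
            try:
                count = int(raw)
            except ValueError:
                raise CountTableParseError(f"{path}:{lineno}: non-integer count {raw!r}")
            if count < 0:
                raise CountTableParseError(f"{path}:{lineno}: negative count {count}")
            if seq.upper() in counts:
                dupes += 1
            counts[seq.upper()] = counts.get(seq.upper(), 0) + count
    if dupes:
        warnings.warn(f"{path}: {dupes} duplicate barcode rows summed")
    return CountTable(counts=counts, sample_id=sample_id or Path(str(path)).stem)


def write_count_table(table: CountTable, path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("barcode\tcount\n")
        for seq, count in sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0])):
            fh.write(f"{seq}\t{count}\n")


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_report(
    result: Any,
    path,
    seed: Optional[int] = None,
    inputs: Optional[Iterable] = None,
) -> Dict[str, Any]:
    """JSON report with schema version, tool version, seed and input checksums."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "tool": "clonotrace",
        "version": __version__,
        "seed": seed,
        "input_checksums": {str(p): file_checksum(p) for p in (inputs or [])},
        "result": _jsonable(result),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
    return doc


def read_report(path) -> Dict[str, Any]:
    with open(path) as fh:
        return json.load(fh)
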