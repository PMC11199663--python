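"""Barcode library design: randomized N15 region plus fixed metadata positions.

A library barcode concatenates a randomized region (default 15 nt, the clone
label proper) with a block of fixed positions (default 10 nt) that encode cell
line metadata -- the campaign year, the CLD campaign number within that year,
the host cell line and the expressed molecule.  The metadata block uses a
fixed-width positional base-4 code over the ordered alphabet ACGT; the
codebook is a plain config object so sites can substitute their own layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np
import pandas as pd

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


class CodebookError(ValueError):
    """A metadata field is outside its codebook capacity or a code is unmappable."""


@dataclass(frozen=True)
class BarcodeSpec:
    """Structure of a library barcode: randomized region + metadata block."""

    random_length: int = 15
    meta_length: int = 10
    alphabet: str = ALPHABET

    def __post_init__(self) -> None:
        if self.random_length < 1:
            raise ValueError("random_length must be >= 1")
        if self.meta_length < 0:
            raise ValueError("meta_length must be >= 0")

    @property
    def total_length(self) -> int:
        return self.random_length + self.meta_length


@dataclass(frozen=True)
class MetadataTag:
    """Cell line metadata carried in the fixed barcode positions."""

    year: int
    cld_number: int
    host_id: int
    molecule_id: int


@dataclass(frozen=True)
class Codebook:
    """Fixed-width positional base-4 metadata code.

    Each field occupies ``widths[field]`` adjacent positions, most significant
    digit first, in the order year, cld_number, host_id, molecule_id.  Years
    are stored as an offset from ``base_year``.  The all-A code is the origin
    tag (base_year, 0, 0, 0).
    """

    base_year: int = 2020
    widths: Tuple[Tuple[str, int], ...] = (
        ("year", 2),
        ("cld_number", 3),
        ("host_id", 2),
        ("molecule_id", 3),
    )

    @property
    def meta_length(self) -> int:
        return sum(w for _, w in self.widths)

    def capacity(self, field_name: str) -> int:
        for name, w in self.widths:
            if name == field_name:
                return 4**w
        raise KeyError(field_name)

    @property
    def n_tags(self) -> int:
        """Number of distinct representable tags (product of field capacities)."""
        out = 1
        for _, w in self.widths:
            out *= 4**w
        return out

    def to_json(self) -> str:
        return json.dumps({"base_year": self.base_year, "widths": list(self.widths)})

    @classmethod
    def from_json(cls, text: str) -> "Codebook":
        obj = json.loads(text)
        return cls(
            base_year=obj["base_year"],
            widths=tuple((str(n), int(w)) for n, w in obj["widths"]),
        )


DEFAULT_CODEBOOK = Codebook()


def _field_values(tag: MetadataTag, codebook: Codebook) -> Dict[str, int]:
    return {
        "year": tag.year - codebook.base_year,
        "cld_number": tag.cld_number,
        "host_id": tag.host_id,
        "molecule_id": tag.molecule_id,
    }


def encode_metadata(
    tag: MetadataTag,
    spec: BarcodeSpec = BarcodeSpec(),
    codebook: Codebook = DEFAULT_CODEBOOK,
) -> str:
    """Encode a metadata tag into the fixed barcode positions.

    Raises :class:`CodebookError` naming the offending field when a value is
    outside its codebook capacity.
    """
    if codebook.meta_length != spec.meta_length:
        raise ValueError(
            f"codebook width {codebook.meta_length} != spec meta_length {spec.meta_length}"
        )
    values = _field_values(tag, codebook)
    out = []
    for name, width in codebook.widths:
        v = values[name]
        if not 0 <= v < 4**width:
            raise CodebookError(
                f"field {name!r} value {v} outside codebook capacity [0, {4**width})"
            )
        digits = []
        for _ in range(width):
            digits.append(ALPHABET[v % 4])
            v //= 4
        out.extend(reversed(digits))
    return "".join(out)


def decode_metadata(
    code: str,
    spec: BarcodeSpec = BarcodeSpec(),
    codebook: Codebook = DEFAULT_CODEBOOK,
) -> MetadataTag:
    """Inverse of :func:`encode_metadata`."""
    if len(code) != spec.meta_length:
        raise CodebookError(
            f"code length {len(code)} != meta_length {spec.meta_length}"
        )
    for ch in code:
        if ch not in _BASE_INDEX:
            raise CodebookError(f"letter {ch!r} outside alphabet {ALPHABET}")
    values: Dict[str, int] = {}
    pos = 0
    for name, width in codebook.widths:
        v = 0
        for ch in code[pos : pos + width]:
            v = 4 * v + _BASE_INDEX[ch]
        values[name] = v
        pos += width
    return MetadataTag(
        year=values["year"] + codebook.base_year,
        cld_number=values["cld_number"],
        host_id=values["host_id"],
        molecule_id=values["molecule_id"],
    )


@dataclass
class BarcodeLibrary:
    """Multiset of barcode sequences with abundances (plasmid library or pool)."""

    entries: Dict[str, int] = field(default_factory=dict)
    spec: BarcodeSpec = BarcodeSpec()

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.entries}
        if len(lengths) > 1:
            raise ValueError(f"mixed sequence lengths in library: {sorted(lengths)}")
        if any(c < 0 for c in self.entries.values()):
            raise ValueError("abundances must be non-negative")

    @property
    def total_abundance(self) -> int:
        return int(sum(self.entries.values()))

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"sequence": list(self.entries), "count": list(self.entries.values())}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, spec: BarcodeSpec | None = None) -> "BarcodeLibrary":
        df = pd.read_csv(path, sep="\t")
        entries = dict(zip(df["sequence"].astype(str), df["count"].astype(int)))
        if spec is None:
            length = len(next(iter(entries))) if entries else 15
            spec = BarcodeSpec(random_length=length, meta_length=0)
        return cls(entries=entries, spec=spec)


def library_uniformity(lib: BarcodeLibrary) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Per-position nucleotide frequencies and abundance-dispersion summary.

    Returns an (L x 4) frequency matrix (rows sum to 1, weighted by abundance)
    and a summary with the coefficient of variation and Gini coefficient of
    the abundances.  A well-made plasmid library shows near-uniform rows
    (~0.25 each) and low CV/Gini.
    """
    if not lib.entries or lib.total_abundance == 0:
        raise ValueError("empty library")
    seqs = list(lib.entries)
    counts = np.array([lib.entries[s] for s in seqs], dtype=float)
    length = len(seqs[0])
    mat = np.zeros((length, 4))
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), length)
    for j, base in enumerate(ALPHABET.encode()):
        mat[:, j] = ((arr == base) * counts[:, None]).sum(axis=0)
    freq = mat / counts.sum()
    df = pd.DataFrame(freq, columns=list(ALPHABET))
    df.index.name = "position"

    mean = counts.mean()
    cv = float(counts.std(ddof=0) / mean) if mean > 0 else float("nan")
    sorted_c = np.sort(counts)
    n = len(sorted_c)
    gini = float(
        (2 * np.arange(1, n + 1) - n - 1).dot(sorted_c) / (n * sorted_c.sum())
    )
    return df, {"cv": cv, "gini": gini, "n_barcodes": n, "total": float(counts.sum())}
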