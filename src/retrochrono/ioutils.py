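"""Readers and writers for the plain-text artifact formats.

Internal coordinates are 0-based half-open everywhere in the package; GFF3
output is 1-based inclusive, converted at the boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator


class FormatError(ValueError):
    """Malformed record; message carries the offending line number."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Parse FASTA into an ordered {id: sequence} mapping.

    Accepts wrapped or unwrapped sequence lines and CRLF line endings.
    """
    records: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, 1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(chunks)
                name = line[1:].split()[0] if line[1:].strip() else ""
                if not name:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                chunks = []
            else:
                if name is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence before first header"
                    )
                chunks.append(line.strip())
    if name is not None:
        records[name] = "".join(chunks)
    return records


def write_fasta(
    records: Iterable[tuple[str, str]] | dict[str, str],
    path: str | os.PathLike,
    width: int = 70,
) -> None:
    items = records.items() if isinstance(records, dict) else records
    with open(path, "w") as handle:
        for name, seq in items:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
            if not seq:
                handle.write("\n")


# ---------------------------------------------------------------------------
# FASTQ (paired, /1 and /2 suffixes)


def write_fastq_pairs(
    pairs: Iterable[tuple[str, str]],
    path1: str | os.PathLike,
    path2: str | os.PathLike,
    name_prefix: str = "read",
) -> None:
    with open(path1, "w") as h1, open(path2, "w") as h2:
        for i, (r1, r2) in enumerate(pairs):
            h1.write(f"@{name_prefix}{i}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            h2.write(f"@{name_prefix}{i}/2\n{r2}\n+\n{'I' * len(r2)}\n")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Return [(name, sequence)] from a FASTQ file."""
    out: list[tuple[str, str]] = []
    with open(path) as handle:
        lines = [ln.rstrip("\r\n") for ln in handle]
    lines = [ln for ln in lines if ln != ""]
    if len(lines) % 4:
        raise FormatError(f"{path}: truncated FASTQ (line count not multiple of 4)")
    for i in range(0, len(lines), 4):
        header = lines[i]
        if not header.startswith("@"):
            raise FormatError(f"{path}:{i + 1}: expected '@' header, got {header!r}")
        out.append((header[1:].split()[0], lines[i + 1]))
    return out


# ---------------------------------------------------------------------------
# GFF3


@dataclass
class GffRecord:
    seqid: str
    source: str
    type: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    score: str = "."
    strand: str = "+"
    phase: str = "."
    attributes: dict[str, str] = field(default_factory=dict)

    def to_line(self) -> str:
        attrs = ";".join(f"{k}={v}" for k, v in self.attributes.items()) or "."
        return "\t".join(
            [
                self.seqid,
                self.source,
                self.type,
                str(self.start),
                str(self.end),
                self.score,
                self.strand,
                self.phase,
                attrs,
            ]
        )


def write_gff3(records: Iterable[GffRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for rec in records:
            handle.write(rec.to_line() + "\n")


def read_gff3(path: str | os.PathLike) -> list[GffRecord]:
    records: list[GffRecord] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, 1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            attrs: dict[str, str] = {}
            if fields[8] != ".":
                for pair in fields[8].split(";"):
                    if not pair:
                        continue
                    key, _, value = pair.partition("=")
                    attrs[key] = value
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            records.append(
                GffRecord(
                    seqid=fields[0],
                    source=fields[1],
                    type=fields[2],
                    start=start,
                    end=end,
                    score=fields[5],
                    strand=fields[6],
                    phase=fields[7],
                    attributes=attrs,
                )
            )
    return records


# ---------------------------------------------------------------------------
# TSV


def write_tsv(
    rows: Iterable[dict[str, object]],
    path: str | os.PathLike,
    columns: list[str] | None = None,
) -> None:
    rows = list(rows)
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w") as handle:
        handle.write("\t".join(columns) + "\n")
        for row in rows:
            handle.write("\t".join(str(row.get(col, "")) for col in columns) + "\n")


def read_tsv(path: str | os.PathLike) -> list[dict[str, str]]:
    with open(path) as handle:
        lines = [ln.rstrip("\r\n") for ln in handle if ln.strip("\r\n")]
    if not lines:
        return []
    header = lines[0].split("\t")
    out = []
    for lineno, line in enumerate(lines[1:], 2):
        values = line.split("\t")
        if len(values) != len(header):
            raise FormatError(f"{path}:{lineno}: column count mismatch")
        out.append(dict(zip(header, values)))
    return out


# ---------------------------------------------------------------------------
# misc sequence helpers

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def ensure_dir(path: str | os.PathLike) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
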