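"""BED3+ reading, tab-separated writing, and per-run record accounting.

All readers accept a path, ``-`` for stdin, or an open text stream;
gzip-compressed files are detected by magic bytes.  Writers emit plain
tab-separated text with a trailing newline per record and the literal
``NA`` for missing values, so outputs are byte-stable across runs.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field, fields as dc_fields
from typing import IO, Iterable, Sequence

from .model import _open_text
from .records import SiteRecord

__all__ = ["BedParseError", "RunStats", "BedInput", "read_bed3plus", "write_table", "NA"]

NA = "NA"


class BedParseError(ValueError):
    """Malformed BED input; message carries the offending line number."""


@dataclass
class RunStats:
    """Per-record accounting for a liftover/annotate run.

    ``emitted`` plus the skip categories account for every input record
    exactly once; ``junction_spanning`` and ``non_numeric_filtered`` are
    advisory counts that do not remove records.
    """

    total: int = 0
    emitted: int = 0
    missing_transcript: int = 0
    out_of_range: int = 0
    junction_spanning: int = 0
    non_numeric_filtered: int = 0

    def summary(self) -> str:
        parts = [f"{f.name}={getattr(self, f.name)}" for f in dc_fields(self)]
        return " ".join(parts)


@dataclass
class BedInput:
    """Parsed BED3+ file: pass-through header lines plus site records."""

    records: list[SiteRecord] = field(default_factory=list)
    header: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def read_bed3plus(source) -> BedInput:
    """Read transcript-coordinate sites from BED3+ text.

    Column 1 is a transcript id, columns 2-3 are 0-based half-open
    transcript coordinates, and any further columns are preserved as
    opaque strings.  Lines starting with ``#`` or ``track``/``browser``
    are captured as pass-through header; blank lines are skipped.
    """
    handle = sys.stdin if source == "-" else _open_text(source)
    out = BedInput()
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#") or line.startswith(("track", "browser")):
            out.header.append(line)
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise BedParseError(f"line {lineno}: expected >=3 tab-separated columns, got {len(cols)}")
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError:
            raise BedParseError(f"line {lineno}: non-integer coordinates {cols[1]!r}/{cols[2]!r}") from None
        if start < 0 or start >= end:
            raise BedParseError(f"line {lineno}: invalid interval [{start}, {end})")
        out.records.append(SiteRecord(cols[0], start, end, tuple(cols[3:])))
    return out


def write_table(
    rows: Iterable[Sequence[str]],
    destination,
    header: Sequence[str] | None = None,
    extra_header_lines: Sequence[str] = (),
) -> None:
    """Write rows of pre-serialized cells as tab-separated text.

    ``header``, when given, is emitted as a single '#'-prefixed line after
    any pass-through ``extra_header_lines``.
    """
    own = not hasattr(destination, "write") and destination != "-"
    handle: IO[str]
    if destination == "-":
        handle = sys.stdout
    elif own:
        handle = open(destination, "w", encoding="utf-8")
    else:
        handle = destination
    try:
        for line in extra_header_lines:
            handle.write(line + "\n")
        if header is not None:
            handle.write("#" + "\t".join(header) + "\n")
        for row in rows:
            handle.write("\t".join(row) + "\n")
    finally:
        if own:
            handle.close()
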