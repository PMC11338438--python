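"""Transcript models built from GTF2 annotations.

A :class:`TranscriptModel` stores one isoform's exon chain in 5'->3'
(transcript) order together with its CDS span expressed in transcript
coordinates, and provides the bidirectional map between transcript and
genomic coordinates that the liftover and annotation steps rely on.

Coordinate conventions: GTF input is 1-based inclusive; everything held
in memory (and every BED coordinate) is 0-based half-open.
"""

from __future__ import annotations

import gzip
import io
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "TranscriptomeAnnotation",
    "GtfParseError",
    "CoordinateError",
    "AmbiguousIdError",
    "parse_gtf",
    "region_lengths",
    "tx_to_genomic",
    "genomic_to_tx",
    "lookup",
    "strip_version",
]


class GtfParseError(ValueError):
    """Malformed GTF input; message carries the offending line number."""


class CoordinateError(ValueError):
    """A transcript coordinate outside [0, transcript length)."""


class AmbiguousIdError(KeyError):
    """A version-stripped transcript id matches more than one model."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval on a single strand."""

    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """One isoform: exon chain, strand, CDS span, cumulative coordinate maps.

    ``exons`` are ordered 5'->3' along the transcript: ascending genomic
    start on '+', descending on '-'.  ``cum_lengths[i]`` is the summed
    length of exons 0..i, so the last entry is the transcript length and
    the prefix entries are the transcript coordinates of the first base
    after each exon-exon junction.

    ``cds_tx_start``/``cds_tx_end`` give the first and last base of the
    ORF in transcript coordinates (stop codon included), or ``None`` for
    noncoding isoforms.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    gene_name: str = ""
    transcript_biotype: str = ""
    cds_tx_start: int | None = None
    cds_tx_end: int | None = None
    cum_lengths: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        starts = [e.start for e in self.exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
        if not ordered or len(set(starts)) != len(starts):
            raise ValueError(f"{self.transcript_id}: exons not ordered 5'->3' for strand {self.strand}")
        acc, cum = 0, []
        for e in self.exons:
            acc += len(e)
            cum.append(acc)
        self.cum_lengths = tuple(cum)
        if (self.cds_tx_start is None) != (self.cds_tx_end is None):
            raise ValueError(f"{self.transcript_id}: partial CDS span")
        if self.cds_tx_start is not None:
            if not (0 <= self.cds_tx_start <= self.cds_tx_end < acc):
                raise ValueError(f"{self.transcript_id}: CDS span outside transcript")

    @property
    def tx_len(self) -> int:
        return self.cum_lengths[-1]

    @property
    def is_coding(self) -> bool:
        return self.cds_tx_start is not None

    @property
    def junctions(self) -> tuple[int, ...]:
        """Transcript coordinate of the first base downstream of each junction."""
        return self.cum_lengths[:-1]

    def tx_to_genomic(self, p: int) -> tuple[str, int, str]:
        """Map transcript base ``p`` to its 0-based genomic position.

        For '-' strand transcripts base 0 is the highest genomic
        coordinate of the 5'-most exon.
        """
        if not (0 <= p < self.tx_len):
            raise CoordinateError(
                f"{self.transcript_id}: position {p} outside [0, {self.tx_len})"
            )
        i = bisect_right(self.cum_lengths, p)
        offset = p - (self.cum_lengths[i - 1] if i else 0)
        exon = self.exons[i]
        if self.strand == "+":
            g = exon.start + offset
        else:
            g = exon.end - 1 - offset
        return self.chrom, g, self.strand

    def genomic_to_tx(self, g: int) -> int | None:
        """Inverse of :meth:`tx_to_genomic`; ``None`` for intronic/outside positions."""
        acc = 0
        for exon in self.exons:
            if exon.start <= g < exon.end:
                if self.strand == "+":
                    return acc + (g - exon.start)
                return acc + (exon.end - 1 - g)
            acc += len(exon)
        return None

    def region_lengths(self) -> tuple[int, int, int] | None:
        """(5'UTR, ORF, 3'UTR) lengths in nt; ``None`` for noncoding isoforms."""
        if self.cds_tx_start is None:
            return None
        utr5 = self.cds_tx_start
        orf = self.cds_tx_end - self.cds_tx_start + 1
        return utr5, orf, self.tx_len - utr5 - orf


_VERSION_RE = re.compile(r"\.\d+$")


def strip_version(tx_id: str) -> str:
    """Remove a trailing '.N' version suffix from a transcript id."""
    return _VERSION_RE.sub("", tx_id)


@dataclass
class TranscriptomeAnnotation:
    """Container of transcript models with optional version-tolerant lookup."""

    models: dict[str, TranscriptModel] = field(default_factory=dict)
    skipped: int = 0  # transcripts rejected during parsing

    def __post_init__(self) -> None:
        self._stripped: dict[str, list[str]] = {}
        for tx_id in self.models:
            self._stripped.setdefault(strip_version(tx_id), []).append(tx_id)

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.models.values())

    def lookup(self, tx_id: str, strip_versions: bool = False) -> TranscriptModel | None:
        model = self.models.get(tx_id)
        if model is not None or not strip_versions:
            return model
        candidates = self._stripped.get(strip_version(tx_id), [])
        if len(candidates) > 1:
            raise AmbiguousIdError(
                f"{tx_id}: version-stripped id matches {sorted(candidates)}"
            )
        return self.models[candidates[0]] if candidates else None


_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"')


def _open_text(source) -> IO[str]:
    if hasattr(source, "read"):
        return source
    with open(source, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(source, "rb"), encoding="utf-8")
    return open(source, "rt", encoding="utf-8")


def parse_gtf(gtf_source) -> TranscriptomeAnnotation:
    """Parse a GTF2 stream or path into a :class:`TranscriptomeAnnotation`.

    One model is built per transcript_id with at least one exon record.
    The ORF span is the union of CDS records extended by stop_codon
    records (Ensembl dialect, where CDS excludes the stop codon), so
    ``cds_tx_end`` is the last stop-codon base when one is annotated.
    Transcripts whose CDS falls outside their exons, or with zero-length
    exons, are skipped and counted in ``annotation.skipped``.
    """
    handle = _open_text(gtf_source)
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict[str, str]] = {}

    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
        if feature not in ("exon", "CDS", "stop_codon"):
            continue
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            raise GtfParseError(f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}") from None
        if start1 > end1:
            raise GtfParseError(f"line {lineno}: start {start1} > end {end1}")
        attributes = dict(_ATTR_RE.findall(attrs))
        tx_id = attributes.get("transcript_id")
        if tx_id is None:
            raise GtfParseError(f"line {lineno}: missing transcript_id attribute")
        interval = (start1 - 1, end1)  # to 0-based half-open
        if feature == "exon":
            exons.setdefault(tx_id, []).append(interval)
        else:
            cds.setdefault(tx_id, []).append(interval)
        info = meta.setdefault(tx_id, {"chrom": chrom, "strand": strand})
        for key in ("gene_id", "gene_name", "transcript_biotype", "transcript_type"):
            if key in attributes and key not in info:
                info[key] = attributes[key]

    models: dict[str, TranscriptModel] = {}
    skipped = 0
    for tx_id, tx_cds in cds.items():
        if tx_id not in exons:
            skipped += 1  # CDS without exons: cannot place on a transcript
    for tx_id, spans in exons.items():
        info = meta[tx_id]
        try:
            models[tx_id] = _build_model(tx_id, info, spans, cds.get(tx_id, []))
        except ValueError:
            skipped += 1
    return TranscriptomeAnnotation(models=models, skipped=skipped)


def _build_model(
    tx_id: str,
    info: dict[str, str],
    exon_spans: Iterable[tuple[int, int]],
    cds_spans: Iterable[tuple[int, int]],
) -> TranscriptModel:
    strand = info["strand"]
    if strand not in ("+", "-"):
        raise ValueError(f"{tx_id}: unstranded transcript")
    spans = sorted(set(exon_spans))
    for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
        if e1 > s2:
            raise ValueError(f"{tx_id}: overlapping exons")
    if strand == "-":
        spans.reverse()
    intervals = tuple(GenomicInterval(info["chrom"], s, e, strand) for s, e in spans)
    model = TranscriptModel(
        transcript_id=tx_id,
        gene_id=info.get("gene_id", ""),
        gene_name=info.get("gene_name", ""),
        transcript_biotype=info.get("transcript_biotype", info.get("transcript_type", "")),
        chrom=info["chrom"],
        strand=strand,
        exons=intervals,
    )
    cds_spans = list(cds_spans)
    if cds_spans:
        tx_positions = []
        for s, e in cds_spans:
            for g in (s, e - 1):
                p = model.genomic_to_tx(g)
                if p is None:
                    raise ValueError(f"{tx_id}: CDS base {g} outside exons")
                tx_positions.append(p)
        model.cds_tx_start = min(tx_positions)
        model.cds_tx_end = max(tx_positions)
        model.__post_init__()  # re-validate with the CDS span set
    return model


# -- thin functional wrappers matching the operation-level surface ----------

def region_lengths(model: TranscriptModel) -> tuple[int, int, int] | None:
    return model.region_lengths()


def tx_to_genomic(model: TranscriptModel, p: int) -> tuple[str, int, str]:
    return model.tx_to_genomic(p)


def genomic_to_tx(model: TranscriptModel, g: int) -> int | None:
    return model.genomic_to_tx(g)


def lookup(
    annotation: TranscriptomeAnnotation, tx_id: str, strip_versions: bool = False
) -> TranscriptModel | None:
    return annotation.lookup(tx_id, strip_versions=strip_versions)
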