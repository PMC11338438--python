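"""Transcript-to-genome liftover of BED3+ feature sites.

Each transcript-coordinate site is transposed to genomic coordinates by
walking its isoform's exon chain; the emitted record is standard BED6
(chrom, start, end, name, score, strand) with every original input
column appended verbatim, so the output has exactly ``n + 6`` columns
for an ``n``-column input and stripping the first six reconstructs the
input losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import RunStats
from .model import CoordinateError, TranscriptModel, TranscriptomeAnnotation
from .records import SiteRecord

__all__ = ["GenomicSite", "MissingTranscriptError", "lift_site", "liftover_stream", "LIFTOVER_COLUMNS"]

LIFTOVER_COLUMNS = ("chrom", "start", "end", "name", "score", "strand")


class MissingTranscriptError(KeyError):
    """A site references a transcript absent from the annotation (on_missing=fail)."""


@dataclass(frozen=True)
class GenomicSite:
    """A lifted site: BED6 genomic fields plus the preserved input columns."""

    chrom: str
    start: int
    end: int
    name: str
    score: str
    strand: str
    preserved: tuple[str, ...]

    @property
    def spans_junction(self) -> bool:
        """True when the genomic interval is wider than the transcript one,
        i.e. the feature crosses at least one intron."""
        tx_width = int(self.preserved[2]) - int(self.preserved[1])
        return (self.end - self.start) != tx_width

    def fields(self) -> tuple[str, ...]:
        return (
            self.chrom,
            str(self.start),
            str(self.end),
            self.name,
            self.score,
            self.strand,
        ) + self.preserved


def lift_site(model: TranscriptModel, site: SiteRecord) -> GenomicSite:
    """Lift one site to genomic coordinates on ``model``'s strand.

    The genomic interval spans from the minimum to the maximum genomic
    position of the site's first and last transcript bases, so a feature
    crossing an exon-exon junction yields one interval spanning the
    intervening intron(s).  Raises :class:`CoordinateError` when the site
    exceeds the transcript length.
    """
    if site.tx_end > model.tx_len:
        raise CoordinateError(
            f"{model.transcript_id}: site end {site.tx_end} exceeds transcript length {model.tx_len}"
        )
    chrom, g1, strand = model.tx_to_genomic(site.tx_start)
    _, g2, _ = model.tx_to_genomic(site.tx_end - 1)
    lo, hi = (g1, g2) if g1 <= g2 else (g2, g1)
    return GenomicSite(
        chrom=chrom,
        start=lo,
        end=hi + 1,
        name=site.tx_id,
        score=".",
        strand=strand,
        preserved=site.fields(),
    )


def liftover_stream(
    sites: Iterable[SiteRecord],
    annotation: TranscriptomeAnnotation,
    strip_versions: bool = False,
    on_missing: str = "skip",
) -> tuple[list[GenomicSite], RunStats]:
    """Lift a stream of sites, preserving input order.

    With ``on_missing='skip'``, records on transcripts absent from the
    annotation (or out of range) are dropped and counted in the returned
    :class:`RunStats`; with ``'fail'`` the first unmatched transcript
    aborts the run.
    """
    if on_missing not in ("skip", "fail"):
        raise ValueError(f"on_missing must be 'skip' or 'fail', got {on_missing!r}")
    stats = RunStats()
    out: list[GenomicSite] = []
    for site in sites:
        stats.total += 1
        model = annotation.lookup(site.tx_id, strip_versions=strip_versions)
        if model is None:
            if on_missing == "fail":
                raise MissingTranscriptError(f"transcript {site.tx_id!r} not in annotation")
            stats.missing_transcript += 1
            continue
        try:
            lifted = lift_site(model, site)
        except CoordinateError:
            if on_missing == "fail":
                raise
            stats.out_of_range += 1
            continue
        if lifted.spans_junction:
            stats.junction_spanning += 1
        out.append(lifted)
        stats.emitted += 1
    return out, stats
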