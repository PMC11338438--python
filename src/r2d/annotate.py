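"""Isoform-specific positional annotation of transcript-mapped sites.

For each site this module computes, against the site's own isoform:

* a metatranscript coordinate in [0, 3] — the position linearly rescaled
  within its region, 5'UTR -> [0, 1), ORF -> [1, 2), 3'UTR -> [2, 3)
  (``NA`` on noncoding isoforms);
* signed distances to the first and last ORF base (negative = 5' of the
  landmark);
* distances to the nearest upstream and downstream exon-exon junction
  (minimum 1 for a base immediately flanking a junction; ``NA`` on the
  side with no junction);
* distance to the transcript 3' end.

Together with the gene metadata carried by the transcript model these
form the 12 annotation columns appended to the input, giving an
``n + 12``-column output for an ``n``-column input.  A multi-base
feature is represented by its 5' base (``tx_start``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .io import NA, RunStats
from .liftover import MissingTranscriptError
from .model import CoordinateError, TranscriptModel, TranscriptomeAnnotation
from .records import SiteRecord

__all__ = [
    "AnnotatedSite",
    "ANNOTATION_COLUMNS",
    "metacoordinate",
    "junction_distances",
    "codon_distances",
    "annotate_site",
    "annotate_stream",
]

ANNOTATION_COLUMNS = (
    "gene_id",
    "gene_name",
    "transcript_biotype",
    "tx_len",
    "cds_tx_start",
    "cds_tx_end",
    "transcript_metacoordinate",
    "abs_cds_start",
    "abs_cds_end",
    "up_junc_dist",
    "down_junc_dist",
    "tx_end_dist",
)


def metacoordinate(region_lengths: tuple[int, int, int] | None, p: int) -> float | None:
    """Rescale transcript position ``p`` onto the 0-3 metatranscript axis.

    ``region_lengths`` is the (5'UTR, ORF, 3'UTR) triple; ``None`` (a
    noncoding isoform) yields ``None``.  Each region is mapped linearly
    onto its unit interval, so the first ORF base lands exactly on 1.0
    and the first 3'UTR base exactly on 2.0.
    """
    if region_lengths is None:
        return None
    l5, lc, l3 = region_lengths
    total = l5 + lc + l3
    if not (0 <= p < total):
        raise CoordinateError(f"position {p} outside transcript of length {total}")
    if p < l5:
        return p / l5
    if p < l5 + lc:
        return 1.0 + (p - l5) / lc
    return 2.0 + (p - l5 - lc) / l3


def junction_distances(model: TranscriptModel, p: int) -> tuple[int | None, int | None]:
    """Distances (nt) from ``p`` to the nearest junction on each side.

    Junction ``J`` is the transcript coordinate of the first base after
    the junction.  Upstream distance is ``p - J + 1`` over junctions with
    ``J <= p``; downstream is ``J - p`` over ``J > p``.  Either side is
    ``None`` when no junction exists there (both for single-exon
    transcripts).
    """
    if not (0 <= p < model.tx_len):
        raise CoordinateError(f"{model.transcript_id}: position {p} out of range")
    up = down = None
    for j in model.junctions:
        if j <= p:
            d = p - j + 1
            up = d if up is None or d < up else up
        else:
            d = j - p
            down = d if down is None or d < down else down
    return up, down


def codon_distances(model: TranscriptModel, p: int) -> tuple[int | None, int | None]:
    """Signed distances from ``p`` to the first and last ORF base.

    Negative values lie 5' of the landmark, positive 3'.  ``(None, None)``
    on noncoding isoforms.
    """
    if not (0 <= p < model.tx_len):
        raise CoordinateError(f"{model.transcript_id}: position {p} out of range")
    if model.cds_tx_start is None:
        return None, None
    return p - model.cds_tx_start, p - model.cds_tx_end


@dataclass(frozen=True)
class AnnotatedSite:
    """A site plus its 12 isoform-specific annotation values."""

    base: SiteRecord
    gene_id: str
    gene_name: str
    transcript_biotype: str
    tx_len: int
    cds_tx_start: int | None
    cds_tx_end: int | None
    meta: float | None
    abs_cds_start: int | None
    abs_cds_end: int | None
    up_junc_dist: int | None
    down_junc_dist: int | None
    tx_end_dist: int

    def annotation_fields(self) -> tuple[str, ...]:
        def s(v):
            return NA if v is None else str(v)

        meta = NA if self.meta is None else f"{self.meta:.4f}"
        return (
            self.gene_id,
            self.gene_name,
            self.transcript_biotype,
            str(self.tx_len),
            s(self.cds_tx_start),
            s(self.cds_tx_end),
            meta,
            s(self.abs_cds_start),
            s(self.abs_cds_end),
            s(self.up_junc_dist),
            s(self.down_junc_dist),
            str(self.tx_end_dist),
        )

    def fields(self) -> tuple[str, ...]:
        return self.base.fields() + self.annotation_fields()


def annotate_site(model: TranscriptModel, site: SiteRecord) -> AnnotatedSite:
    """Annotate one site against its isoform; the representative position
    is the site's 5' base."""
    if site.tx_end > model.tx_len:
        raise CoordinateError(
            f"{model.transcript_id}: site end {site.tx_end} exceeds transcript length {model.tx_len}"
        )
    p = site.tx_start
    up, down = junction_distances(model, p)
    d_start, d_end = codon_distances(model, p)
    return AnnotatedSite(
        base=site,
        gene_id=model.gene_id,
        gene_name=model.gene_name,
        transcript_biotype=model.transcript_biotype,
        tx_len=model.tx_len,
        cds_tx_start=model.cds_tx_start,
        cds_tx_end=model.cds_tx_end,
        meta=metacoordinate(model.region_lengths(), p),
        abs_cds_start=d_start,
        abs_cds_end=d_end,
        up_junc_dist=up,
        down_junc_dist=down,
        tx_end_dist=model.tx_len - 1 - p,
    )


def annotate_stream(
    sites: Iterable[SiteRecord],
    annotation: TranscriptomeAnnotation,
    strip_versions: bool = False,
    on_missing: str = "skip",
) -> tuple[list[AnnotatedSite], RunStats]:
    """Annotate a stream of sites, preserving input order; skip semantics
    mirror :func:`r2d.liftover.liftover_stream`."""
    if on_missing not in ("skip", "fail"):
        raise ValueError(f"on_missing must be 'skip' or 'fail', got {on_missing!r}")
    stats = RunStats()
    out: list[AnnotatedSite] = []
    for site in sites:
        stats.total += 1
        model = annotation.lookup(site.tx_id, strip_versions=strip_versions)
        if model is None:
            if on_missing == "fail":
                raise MissingTranscriptError(f"transcript {site.tx_id!r} not in annotation")
            stats.missing_transcript += 1
            continue
        try:
            out.append(annotate_site(model, site))
        except CoordinateError:
            if on_missing == "fail":
                raise
            stats.out_of_range += 1
            continue
        stats.emitted += 1
    return out, stats
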