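"""Seeded synthetic transcriptomes and site files with known ground truth.

The generator emulates the inputs of an isoform-resolved RNA-feature
study: a GTF2 annotation whose genes tile a virtual chromosome ``chrS``
(isoforms of a gene share exons but differ in UTR/CDS boundaries, so a
single genomic position can be CDS in one isoform and 3'UTR in another)
and a BED3+ site file mimicking transcript-centric modification calls,
with a ground-truth label in column 4 and a simulated stoichiometry
percentage in column 5.

Every positional quantity in the emitted truth table is computed by
naive per-base enumeration of the exon chain — independently of the
transcript-model coordinate maps — so the truth table doubles as the
brute-force oracle for the liftover and annotation tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import click
import numpy as np
import pandas as pd

from .model import GenomicInterval, TranscriptModel, TranscriptomeAnnotation

__all__ = [
    "FixtureSpec",
    "make_transcriptome",
    "make_sites",
    "naive_base_map",
    "naive_junction_distances",
    "naive_metacoordinate",
]

CHROM = "chrS"
INTERGENIC_GAP = 1000

TRUTH_COLUMNS = (
    "site",
    "transcript",
    "pos",
    "chrom",
    "genomic_pos",
    "strand",
    "region",
    "meta",
    "abs_cds_start",
    "abs_cds_end",
    "up_junc_dist",
    "down_junc_dist",
    "tx_end_dist",
    "label",
    "stoichiometry",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset; identical spec + seed gives
    byte-identical GTF and BED outputs.

    Site models: ``uniform`` places sites uniformly along transcripts
    with a flat positive rate; ``junction_depleted`` keeps uniform
    placement but suppresses the positive rate within ``zone_nt`` of any
    splice junction (``positive_rate_inside`` vs ``_outside``);
    ``codon_enriched`` draws positions normally around the start/stop
    codon at ``enrich_offset`` +/- ``enrich_sd`` and peaks the positive
    rate there.  Stoichiometry (column 5, percent) is drawn above
    ``sig_threshold`` for positives and below it for negatives.
    """

    n_genes: int = 50
    isoforms_per_gene: tuple[int, int] = (1, 3)
    exons_per_transcript: tuple[int, int] = (1, 10)
    exon_len: tuple[int, int] = (80, 300)
    intron_len: tuple[int, int] = (60, 2000)
    utr5_len: tuple[int, int] = (30, 300)
    utr3_len: tuple[int, int] = (50, 800)
    strand_probability: float = 0.5  # probability of '+' strand
    noncoding_fraction: float = 0.1
    n_sites: int = 1000
    site_model: str = "uniform"
    zone_nt: int = 200
    anchor: str = "stop"
    enrich_offset: int = 50
    enrich_sd: int = 30
    positive_rate_inside: float = 0.0
    positive_rate_outside: float = 0.3
    sig_threshold: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("isoforms_per_gene", "exons_per_transcript", "exon_len",
                     "intron_len", "utr5_len", "utr3_len"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name}: invalid range ({lo}, {hi})")
        if self.site_model not in ("uniform", "junction_depleted", "codon_enriched"):
            raise ValueError(f"unknown site_model {self.site_model!r}")
        if self.anchor not in ("start", "stop"):
            raise ValueError(f"anchor must be 'start' or 'stop', got {self.anchor!r}")


# ---------------------------------------------------------------------------
# brute-force oracle: naive per-base enumeration of the exon chain

def naive_base_map(exons: tuple[GenomicInterval, ...], strand: str) -> np.ndarray:
    """Genomic position of every transcript base, by plain concatenation
    of the exon chain ('-' strand exons contribute their bases high->low)."""
    parts = []
    for e in exons:
        block = np.arange(e.start, e.end, dtype=np.int64)
        parts.append(block[::-1] if strand == "-" else block)
    return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)


def naive_junction_distances(exon_lengths: list[int], p: int) -> tuple[int | None, int | None]:
    """Minimum over all junction coordinates, enumerated directly."""
    junctions = np.cumsum(exon_lengths)[:-1]
    ups = [p - j + 1 for j in junctions if j <= p]
    downs = [j - p for j in junctions if j > p]
    return (min(ups) if ups else None, min(downs) if downs else None)


def naive_metacoordinate(l5: int, lc: int, l3: int, p: int) -> float:
    """Per-region linear interpolation between the region's boundary values."""
    if p < l5:
        return np.interp(p, [0, l5], [0.0, 1.0])
    if p < l5 + lc:
        return np.interp(p - l5, [0, lc], [1.0, 2.0])
    return np.interp(p - l5 - lc, [0, l3], [2.0, 3.0])


# ---------------------------------------------------------------------------
# transcriptome generation

def _rint(rng: np.random.Generator, lohi: tuple[int, int]) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


def _pick_cds(rng: np.random.Generator, spec: FixtureSpec, tx_len: int) -> tuple[int, int] | None:
    """Choose a (cds_tx_start, cds_tx_end) span: ORF length a multiple of
    3 and >= 6 (codon + stop), flanked by UTRs drawn from the spec ranges."""
    if tx_len < 20:
        return None
    utr5 = min(_rint(rng, spec.utr5_len), max(0, tx_len - 9))
    utr3 = min(_rint(rng, spec.utr3_len), max(0, tx_len - utr5 - 6))
    orf = tx_len - utr5 - utr3
    orf -= orf % 3
    if orf < 6:
        return None
    return utr5, utr5 + orf - 1


def _shrink_orf(rng: np.random.Generator, cds: tuple[int, int], tx_len: int) -> tuple[int, int]:
    """Shorten an ORF in-frame so part of the old CDS becomes 3'UTR."""
    start, end = cds
    orf = end - start + 1
    max_cut = (orf - 6) // 3
    if max_cut < 1:
        return cds
    cut = int(rng.integers(1, max_cut + 1))
    return start, end - 3 * cut


def make_transcriptome(spec: FixtureSpec) -> tuple[TranscriptomeAnnotation, str]:
    """Generate the annotation and its GTF2 serialization.

    Genes tile ``chrS`` with 1 kb intergenic gaps.  The first two
    isoforms of any multi-isoform gene share the full exon chain but the
    second carries an in-frame-shortened ORF, guaranteeing genomic
    positions whose region (CDS vs 3'UTR) differs between isoforms.
    Later isoforms may additionally drop a terminal exon.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    models: dict[str, TranscriptModel] = {}
    gtf_lines = [f"#synthetic annotation; seed={spec.seed}"]
    cursor = INTERGENIC_GAP

    for g in range(spec.n_genes):
        gene_id = f"G{g:04d}"
        gene_name = f"SYN{g}"
        strand = "+" if rng.random() < spec.strand_probability else "-"
        n_exons = _rint(rng, spec.exons_per_transcript)
        exon_lens = [_rint(rng, spec.exon_len) for _ in range(n_exons)]
        intron_lens = [_rint(rng, spec.intron_len) for _ in range(n_exons - 1)]
        chain: list[tuple[int, int]] = []
        pos = cursor
        for i, el in enumerate(exon_lens):
            chain.append((pos, pos + el))
            pos += el + (intron_lens[i] if i < n_exons - 1 else 0)
        cursor = pos + INTERGENIC_GAP

        n_iso = _rint(rng, spec.isoforms_per_gene)
        base_cds: tuple[int, int] | None = None
        for iso in range(n_iso):
            tx_id = f"T{g:04d}_{iso + 1}"
            iso_chain = chain
            if iso >= 2 and len(chain) >= 3:
                iso_chain = chain[:-1] if rng.random() < 0.5 else chain[1:]
            ordered = iso_chain if strand == "+" else iso_chain[::-1]
            exons = tuple(GenomicInterval(CHROM, s, e, strand) for s, e in ordered)
            tx_len = sum(e - s for s, e in iso_chain)

            coding = rng.random() >= spec.noncoding_fraction
            cds = None
            if coding:
                if iso == 0:
                    cds = _pick_cds(rng, spec, tx_len)
                    base_cds = cds
                elif iso == 1 and base_cds is not None:
                    cds = _shrink_orf(rng, base_cds, tx_len)
                else:
                    cds = _pick_cds(rng, spec, tx_len)
            biotype = "protein_coding" if cds else "lncRNA"
            models[tx_id] = TranscriptModel(
                transcript_id=tx_id,
                gene_id=gene_id,
                gene_name=gene_name,
                transcript_biotype=biotype,
                chrom=CHROM,
                strand=strand,
                exons=exons,
                cds_tx_start=cds[0] if cds else None,
                cds_tx_end=cds[1] if cds else None,
            )
            gtf_lines.extend(_gtf_records(models[tx_id]))

    gtf_text = "\n".join(gtf_lines) + "\n"
    return TranscriptomeAnnotation(models=models), gtf_text


def _runs(sorted_positions: np.ndarray) -> list[tuple[int, int]]:
    """Group sorted genomic base positions into maximal half-open runs."""
    if len(sorted_positions) == 0:
        return []
    breaks = np.nonzero(np.diff(sorted_positions) != 1)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(sorted_positions) - 1]))
    return [(int(sorted_positions[s]), int(sorted_positions[e]) + 1) for s, e in zip(starts, ends)]


def _gtf_records(model: TranscriptModel) -> list[str]:
    attrs = (
        f'gene_id "{model.gene_id}"; transcript_id "{model.transcript_id}"; '
        f'gene_name "{model.gene_name}"; transcript_biotype "{model.transcript_biotype}";'
    )

    def line(feature: str, start0: int, end0: int) -> str:
        return "\t".join(
            [model.chrom, "synthetic", feature, str(start0 + 1), str(end0),
             ".", model.strand, ".", attrs]
        )

    out = [line("exon", e.start, e.end) for e in sorted(model.exons, key=lambda e: e.start)]
    if model.cds_tx_start is not None:
        bases = naive_base_map(model.exons, model.strand)
        orf = np.sort(bases[model.cds_tx_start : model.cds_tx_end + 1])
        stop = np.sort(bases[model.cds_tx_end - 2 : model.cds_tx_end + 1])
        cds_only = np.sort(bases[model.cds_tx_start : model.cds_tx_end - 2])
        out += [line("CDS", s, e) for s, e in _runs(cds_only)]
        out += [line("stop_codon", s, e) for s, e in _runs(stop)]
        del orf
    return out


# ---------------------------------------------------------------------------
# site generation with ground truth

def make_sites(
    annotation: TranscriptomeAnnotation, spec: FixtureSpec
) -> tuple[str, pd.DataFrame]:
    """Draw sites per the spec's site model and tabulate their ground truth.

    Returns the BED3+ text (columns: transcript, start, end, label,
    stoichiometry%) and a truth table whose positional columns are
    computed by naive per-base enumeration.
    """
    spec.validate()
    if len(annotation) == 0:
        raise ValueError("annotation is empty")
    rng = np.random.default_rng(spec.seed + 1)
    tx_ids = sorted(annotation.models)
    bed_lines = [f"#synthetic sites; model={spec.site_model}; seed={spec.seed}"]
    rows = []
    cache: dict[str, np.ndarray] = {}

    for i in range(spec.n_sites):
        model = annotation.models[tx_ids[int(rng.integers(len(tx_ids)))]]
        if spec.site_model == "codon_enriched":
            for _ in range(50):  # codon-anchored sites need a coding isoform
                if model.is_coding:
                    break
                model = annotation.models[tx_ids[int(rng.integers(len(tx_ids)))]]
        p = _draw_position(rng, spec, model)
        exon_lens = [len(e) for e in model.exons]
        up, down = naive_junction_distances(exon_lens, p)
        if model.is_coding:
            l5 = model.cds_tx_start
            lc = model.cds_tx_end - model.cds_tx_start + 1
            l3 = model.tx_len - l5 - lc
            meta = float(naive_metacoordinate(l5, lc, l3, p))
            d_start = p - model.cds_tx_start
            d_end = p - model.cds_tx_end
            region = "5utr" if p < l5 else ("orf" if p < l5 + lc else "3utr")
        else:
            meta = d_start = d_end = None
            region = "noncoding"
        rate = _positive_rate(spec, up, down, d_start, d_end)
        positive = bool(rng.random() < rate)
        if positive:
            stoich = spec.sig_threshold + rng.random() * (100.0 - spec.sig_threshold)
        else:
            stoich = rng.random() * spec.sig_threshold
        stoich = round(float(stoich), 2)
        label = "pos" if positive else "neg"
        bed_lines.append(f"{model.transcript_id}\t{p}\t{p + 1}\t{label}\t{stoich:.2f}")

        if model.transcript_id not in cache:
            cache[model.transcript_id] = naive_base_map(model.exons, model.strand)
        rows.append(
            {
                "site": i,
                "transcript": model.transcript_id,
                "pos": p,
                "chrom": model.chrom,
                "genomic_pos": int(cache[model.transcript_id][p]),
                "strand": model.strand,
                "region": region,
                "meta": meta,
                "abs_cds_start": d_start,
                "abs_cds_end": d_end,
                "up_junc_dist": up,
                "down_junc_dist": down,
                "tx_end_dist": model.tx_len - 1 - p,
                "label": label,
                "stoichiometry": stoich,
            }
        )
    truth = pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))
    return "\n".join(bed_lines) + "\n", truth


def _draw_position(rng: np.random.Generator, spec: FixtureSpec, model: TranscriptModel) -> int:
    if spec.site_model == "codon_enriched" and model.is_coding:
        landmark = model.cds_tx_start if spec.anchor == "start" else model.cds_tx_end
        p = int(round(rng.normal(landmark + spec.enrich_offset, spec.enrich_sd)))
        return int(np.clip(p, 0, model.tx_len - 1))
    return int(rng.integers(0, model.tx_len))


def _positive_rate(
    spec: FixtureSpec,
    up: int | None,
    down: int | None,
    d_start: int | None,
    d_end: int | None,
) -> float:
    if spec.site_model == "junction_depleted":
        nearest = min([d for d in (up, down) if d is not None], default=None)
        inside = nearest is not None and nearest <= spec.zone_nt
        return spec.positive_rate_inside if inside else spec.positive_rate_outside
    if spec.site_model == "codon_enriched":
        d = d_start if spec.anchor == "start" else d_end
        if d is None:
            return spec.positive_rate_outside
        bump = np.exp(-0.5 * ((d - spec.enrich_offset) / max(spec.enrich_sd, 1)) ** 2)
        return spec.positive_rate_outside + (
            spec.positive_rate_inside - spec.positive_rate_outside
        ) * float(bump)
    return spec.positive_rate_outside


# ---------------------------------------------------------------------------
# CLI

@click.command(name="r2d-fixtures")
@click.option("--spec", "spec_path", type=click.Path(exists=True, dir_okay=False),
              help="JSON file overriding FixtureSpec fields.")
@click.option("--out-dir", required=True, type=click.Path(file_okay=False))
@click.option("--seed", type=int, default=None, help="Override the spec seed.")
def main(spec_path: str | None, out_dir: str, seed: int | None) -> None:
    """Write annotation.gtf, sites.bed and truth.tsv for a synthetic dataset."""
    overrides = {}
    if spec_path:
        overrides = json.loads(Path(spec_path).read_text())
        for key, value in overrides.items():
            if isinstance(value, list):
                overrides[key] = tuple(value)
    spec = FixtureSpec(**overrides)
    if seed is not None:
        spec = replace(spec, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotation, gtf_text = make_transcriptome(spec)
    bed_text, truth = make_sites(annotation, spec)
    (out / "annotation.gtf").write_text(gtf_text)
    (out / "sites.bed").write_text(bed_text)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False, na_rep="NA")
    (out / "fixture_spec.json").write_text(json.dumps(asdict(spec), indent=2) + "\n")
    click.echo(f"wrote {len(annotation)} transcripts, {len(truth)} sites to {out}", err=True)


if __name__ == "__main__":
    main()
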