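# Methods

## Coordinate model

A transcript isoform is an ordered chain of genomic exon intervals
(5′→3′ in transcript orientation: ascending genomic starts on `+`,
descending on `-`), with cumulative exon lengths giving the transcript
length and the transcript coordinate of the first base after each
exon–exon junction. Transcript position `p` maps to the genome by
locating its exon through the cumulative lengths and offsetting within
it; on the `-` strand, transcript base 0 is the *highest* genomic
coordinate of the 5′-most exon. The inverse map is defined exactly on
exonic genomic positions and returns nothing for intronic or flanking
positions, giving the round-trip identity used throughout the tests.

Conventions: GTF input is 1-based inclusive; all in-memory and BED
coordinates are 0-based half-open. CDS records are taken in the Ensembl
dialect, where they exclude the stop codon; the ORF span is the union of
CDS records extended by `stop_codon` records, so the last ORF base is
the final stop-codon base and 5′UTR + ORF + 3′UTR lengths always sum to
the transcript length. Exon order in the file is not trusted: exons are
sorted by genomic coordinate and re-oriented by strand. Transcripts with
overlapping or zero-length exons, or a CDS falling outside their exons,
are skipped and counted rather than aborting the parse.

## Liftover and annotation contracts

Both commands are record-preserving streams: output order equals input
order, every input record is either emitted or counted under exactly one
skip category (missing transcript, out of range), and the original
columns are carried verbatim — liftover output is `n+6` columns (genomic
BED6 first), annotate output `n+12` (annotations appended). Input
transcript coordinates are treated as plus-strand by definition; a
strand column among the extra input columns is preserved but ignored.

A feature whose ends fall on different exons is lifted to a single
genomic interval spanning the intervening intron(s) and counted as
junction-spanning, keeping the one-in/one-out contract; blocked BED12
output is a deliberate non-goal since the motivating use case is
single-nucleotide sites, whose representative position is the 5′ base.

The 12 annotation columns, in order: `gene_id`, `gene_name`,
`transcript_biotype`, `tx_len`, `cds_tx_start`, `cds_tx_end`,
`transcript_metacoordinate`, `abs_cds_start`, `abs_cds_end`,
`up_junc_dist`, `down_junc_dist`, `tx_end_dist`. Missing values are the
literal `NA`: metacoordinate and codon distances on noncoding isoforms,
junction distances on the side with no junction (both on single-exon
transcripts). Junction distances are 1-anchored — a base immediately
flanking a junction on either side has distance 1 — keeping the two
sides symmetric. The metacoordinate maps each region linearly onto its
unit interval with floor(meta) identifying the region; the first ORF
base is exactly 1.0, the first 3′UTR base exactly 2.0, and the last
transcript base stays strictly below 3.0 (with 0-based positions the
right edge is never attained). Metacoordinates are serialized with 4
decimals so adjacent bases on long transcripts remain distinguishable;
other floats use 6 significant digits.

## Profiles and the LOESS trend

A profile bins sites along an axis and reports, per bin, the number of
sites passing a significance predicate (column, comparator, threshold —
covering cutoffs like "stoichiometry > 10") over all tested sites.
Records with non-numeric predicate values are excluded from numerator
and denominator and counted. Axes:

* metatranscript: 120 bins of width 0.025 over [0, 3] by default; bin
  index floor(meta/width) clamped to the last bin; plotted x is the bin
  midpoint;
* metajunction: 1-nt offsets, upstream side keyed by −up_junc_dist on
  [−window, −1] and downstream by down_junc_dist on [1, window]
  (default window 300 nt — wide enough to show context around a 200-nt
  effect); each site contributes at most one cell per side, at its
  nearest junction;
* metacodon: 1-nt signed offsets to the first or last ORF base on
  [−window, window], default window 100 nt.

Empty bins are kept with proportion `NA` so the axis stays complete and
strictly increasing.

The trend is a tricube-weighted local *linear* regression (classic
LOESS, degree 1) fitted at each profile point over the `span` fraction
of nearest neighbours — default span 0.3 for the metatranscript profile
and 0.5 for the sparser 1-nt profiles. Writing the fit as a linear
smoother `fit = L·y`, the pointwise standard error is
`se_i = σ·‖L_i‖` with `σ²` estimated from the residuals using the
smoother's approximate degrees of freedom (`n − 2·tr L + tr LLᵀ`), and
the 95% band is fit ± 1.96·se. For small tables a seeded case-resampling
bootstrap (200 replicates, percentile band) is available instead. The
displayed fit is clipped to [0, 1]; the raw fit is retained in the
returned table. Fewer than 10 non-missing rows skips the trend with a
warning and plots points only. The implementation is cross-checked in
the tests against statsmodels' `lowess` on smooth signals; statsmodels
provides no standard errors, which is why the smoother is implemented
in-package.

## Synthetic data generator

The generator emulates the inputs of an isoform-resolved modification
study. Genes tile a virtual chromosome `chrS` with 1-kb intergenic
gaps; per gene, an exon chain is drawn (defaults: 1–10 exons of
80–300 nt, introns 60–2000 nt, strand fair-coin) and isoforms share it —
the second isoform of a multi-isoform gene keeps the full chain but
carries an in-frame-shortened ORF, so shared genomic positions exist
whose region (CDS vs 3′UTR) differs between isoforms; later isoforms may
drop a terminal exon. ORFs are stop-codon-inclusive multiples of 3
(≥ 6 nt) flanked by UTRs drawn from 30–300 / 50–800 nt ranges; 10% of
isoforms are noncoding. Defaults of 50 genes and 1000 sites suit unit
tests; scale-up is a parameter.

Site files mimic transcript-centric m6A calls: column 4 a ground-truth
label, column 5 a stoichiometry percentage drawn above the significance
threshold (default 10%) for positives and below it for negatives — the
labels are therefore exactly recoverable by the `> threshold` predicate.
Site models: `uniform` (flat positive rate, default 0.3, matching a
plausible transcriptome-wide positive fraction); `junction_depleted`
(positive rate 0 within 200 nt of any junction, 0.3 outside — the
exclusion-zone geometry the junction profile must recover);
`codon_enriched` (positions and positive rate peaked at a configurable
offset from the start/stop codon). Every positional truth value —
genomic position, junction/codon distances, metacoordinate — is computed
by naive per-base enumeration of the exon chain, independently of the
package's coordinate maps, so the truth table doubles as the brute-force
oracle in the test suite.

What the generator does **not** model: real sequence (no FASTA, no DRACH
motif constraint), read-level error, coverage-dependent stoichiometry
uncertainty, overlapping genes, or annotation errors. Passing tests
therefore demonstrate the correctness of the coordinate arithmetic,
format contracts and profile statistics — not biological fidelity of any
particular dataset.

## Numerical and design choices

* Version-stripped transcript-id matching (`--strip-versions`) removes a
  trailing `.N` from both sides and refuses ambiguous matches rather
  than guessing.
* BED6 name/score columns are the source transcript id and `.`, safe
  for genome-browser display.
* Outputs are byte-stable across runs (plots excluded; their companion
  TSV tables included); logging goes to stderr only, and `-` selects
  stdin/stdout, so commands compose in pipelines.
* Problem sizes in the shipped checks — 100-transcript oracle sweeps,
  6000-site depletion recovery, a 5000-transcript / 10000-site
  end-to-end run — were chosen as the smallest scales at which the
  respective property is meaningfully exercised.

## Known limitations

Junction-spanning features are emitted as one intron-spanning interval,
not blocked BED12. Only GTF2 is parsed (no GFF3). Genome→transcriptome
liftover exists internally for round-trip testing but is not exposed as
a command. A single annotation is used per run; multi-GTF comparison and
two-condition differential profiles are out of scope.
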