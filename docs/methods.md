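# Methods

This note records the models, conventions and design choices behind
`asneo`, in the order the pipeline runs. It states no empirical number
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates, groups and conventions

All internal coordinates are 0-based half-open (the rMATS/BED convention);
GTF input/output is converted at the boundary (1-based inclusive on disk,
with CDS frame fields computed in coding order). Sample **group 1 is the
old cohort and group 2 the young cohort**, so ΔPSI = mean PSI(old) − mean
PSI(young) and "up-regulated" means higher isoform usage in old samples.
rMATS itself assigns groups arbitrarily, so this convention is stamped
into the event-summary metadata rather than assumed silently.

Both significance thresholds are strict inequalities (FDR < 0.05,
|ΔPSI| > 0.1): events sitting exactly on a threshold are excluded. The
same reading applies to the presentation cut (rank < 5%): a rank of
exactly 5.00 is not a binder. NetMHCpan's own strong/weak-binder bands
are deliberately not imported; the single 5% cut is the filter.

## Differential PSI and multiple testing

In synthetic mode the per-event statistic is a two-sided Welch t-test (or
rank-sum test) on per-sample PSI between groups; with real rMATS input the
tool's own PValue/FDR columns are consumed instead. "NA" inclusion levels
are dropped per sample, never imputed; events with fewer than two usable
samples in either group get missing p/FDR and are excluded from
correction. Benjamini–Hochberg is applied **jointly across all five event
types** — the conservative reading when a single significant-event count
is quoted for the pooled set. Two constant but different group vectors
are reported as p = 0 (separation is unambiguous and a variance-based test
is undefined there).

## Isoform surgery

An event is applied to a reference transcript by exon arithmetic: SE
keeps/removes the cassette between its flanks; MXE carries exon 1
(inclusion) or exon 2 (exclusion); A5SS/A3SS swap the long/short exon; RI
merges the flanking exon pair into the single retained-intron exon.
Flanking exons must match reference exons by exact coordinate equality —
anything else raises an incompatibility error carrying both coordinate
sets, and pipeline drivers skip such events with a logged reason. When a
gene has several annotated transcripts, the compatible one with the
longest annotated CDS is used (ties broken by transcript id); this is a
package decision for multi-isoform genes, not something the upstream
splicing tool prescribes.

The **aging-favored form is the inclusion form iff ΔPSI > 0**; the other
form plays the role of the unspliced reference isoform. Surgery keeps the
original annotated CDS span: if it removes the start codon, the pair is
classified non-coding and excluded from peptide work (no de-novo ORF
calling). Translation truncates at the first in-frame stop; sequence
beyond a premature stop contributes no peptides, and no NMD model is
applied — pre-stop peptides of frame-disrupting isoforms are kept.
Frame effect is the CDS length difference mod 3; the affected protein
interval is the residue span [⌊first_diff/3⌋, ⌈last_diff/3⌉) of the
aging-favored form (everything downstream under frame disruption), clipped
to the stop-truncated protein length. Domain intersection is plain
half-open interval overlap: abutting intervals do not overlap.

## Peptide subtraction and proteomic confirmation

Window length is fixed at k = 9 (MHC class I), exposed as a knob over
8–11. Windows containing X (a codon with non-ACGT bases) are dropped at
creation because they cannot be rank-scored; the translator maps *any*
codon containing such a base to X even when the ambiguity is synonymous,
keeping the rule simple and conservative. Subtraction removes windows
found in the other form of the same event **and** in the global background
library — both subtractions, in that order of thought but set-theoretically
commutative. Exact string matching replaces a blastp search for proteomic
confirmation: at 100% identity over full-length 9-mers the two coincide,
and exact matching has no e-value/word-size dialect. Gene symbols are
compared case-insensitively with no alias resolution.

## Presentation scoring

The external predictor is an **offline table adapter** over saved
NetMHCpan-style output (both the v4.0 and v4.1 header dialects), because
rank predictors of that family are license-restricted and runs must be
reproducible from their saved output; a missing (peptide, allele) pair is
a hard error, never a silent default. The mock predictor maps a keyed
BLAKE2b digest of `peptide|allele` uniformly onto (0, 100], so it is
deterministic across platforms without a seed file and its expected binder
fraction at threshold t is t/100 — a calibration the acceptance script
measures. Detection rate is reported under both plausible denominators
(carrier fraction of the cohort, and allele copies over 2N) because
published per-allele rates are ambiguous between them.

## Motif maps

Flank slots follow the motif-map tool layout: 250 bp intronic and 50 bp
exonic windows at each junction of the regulated exon(s), named in coding
orientation and clipped (with a flag) where an intron or exon is shorter
than nominal. Coverage marks every base under at least one match of the
degenerate pattern (bracket notation or IUPAC codes); density is the
50-bp sliding-window mean, averaged across regions at each offset, with
clipped regions contributing only to offsets they cover (regions align at
their coding-strand start). Significance per offset is a two-sided
rank-sum test of per-region densities, target vs background, with a
label-permutation test available as an option; no correction is applied
across offsets, matching the convention of reporting raw positional p
curves (offsets are strongly correlated through overlapping windows, so
per-offset correction would be neither independent nor interpretable).

## The synthetic cohort

The generator emulates a two-group blood cohort contrast: by default 40
old vs 40 young samples, eight signal and eight null events per type on
distinct transcripts, planted effect ΔPSI = ±0.3 (signs alternate within
each type so both directions occur) against per-sample Gaussian noise of
sd 0.05, clamped to [0, 1]. The config validator enforces
`delta_psi_effect > 2·psi_noise_sd`, so planted effects are recoverable by
construction. Junction counts are binomial at depth 100 per event and
sample with equal inclusion/skip form lengths, so count-derived PSI equals
IJC/(IJC+SJC) and matches the simulated PSI in expectation. Gene models
are placed without overlap on alternating strands; every CDS starts with
ATG, has length divisible by three and is written stop-free into the
genome. A small number of genes carry a 5' UTR spanning one internal
exon, hosting SE events that pass the significance filter but change no
coding sequence — exercising the non-coding branch end to end.

Ground truth for peptides is defined, for **every** signal event, as the
9-mers of the aging-favored protein absent from both the young-favored
protein and the background library; any frame-altering event generates
novel junction 9-mers, so recording only deliberately engineered inserts
would understate the truth. The background library contains every
unmodified transcript plus the young-favored isoform of each signal event
and **both** forms of each null event (a null event has no favored
direction — the young cohort expresses both), which guarantees that a null
event slipping past the filter contributes zero candidates. A designated
subset (up-regulated RI, down-regulated MXE) has its intron-junction or
alternative-exon content rejection-sampled (bounded at 1,000 draws) until
it contributes at least one library-disjoint 9-mer; frame class is
whatever the length arithmetic gives, since intron lengths are fixed at
gene construction. The proteomic list captures a configurable fraction of
the distinct planted peptides (ties rounded down) with correct gene
labels, plus decoy 9-mers guaranteed absent from the planted set.

Motif planting writes concrete realizations of the degenerate pattern into
the coding-upstream intron flank of SE events only: a Poisson(rate)
baseline count into every SE flank and Poisson(fold × rate) into
up-regulated signal flanks, so a fold of 1 is exactly the background —
distinguishability comes from the fold, not from planting per se. SE
introns are never part of either isoform, which keeps motif planting
independent of peptide truth. Placements never extend past the flank and
are recorded as (region id, coding offset).

Determinism: one integer seed drives independent named substreams per
stage, so identical configs reproduce every artifact byte for byte.

### What the generator does not emulate

No read-level simulation (junction counts are drawn, not aligned), no
realistic HLA population frequencies (a nine-allele toy pool), no
mass-spectrum simulation (peptide lists only), no multi-isoform genes, no
expression–PSI coupling (the expression matrix is independent noise, so
the correlation screen is exercised under its null), and no NMD. Passing
tests therefore demonstrate internal correctness of the event→peptide
logic and calibration of its statistics, not performance on real,
noisier annotation.

## Problem sizes and numerical choices

The test suite and acceptance script run the pipeline at sizes chosen to
make every property measurable while keeping a full run in seconds per
stage: 200 events for the surgery oracle (≥ 30 per type, both strands),
125 signal + 125 null events at 40/40 samples for filter recovery, the
default cohort for end-to-end peptide recovery, 10,000 (peptide, allele)
pairs for rank calibration, 20 SE signal + 20 SE null events for the
motif contrast, and 1,000 independent null events for the correlation
screen's calibration. Floating-point PSI values round-trip through the
emitted tables at six decimals; equality tests on ΔPSI therefore use
tolerances ≥ 5e-7.

## Known limitations

Real rMATS output occasionally contains events whose flanks match no
annotated transcript exactly (novel junctions); these are skipped with a
logged reason rather than rescued by approximate matching. The
correlation screen fits expression on PSI with a single univariate OLS per
event and makes no attempt at confounder adjustment. The package does not
run splicing quantification, HLA typing, domain search or binding
prediction itself — it consumes their outputs in the formats documented in
each module.
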