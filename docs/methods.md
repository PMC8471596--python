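# Methods

## Scope and data model

The package models the computational pipeline around a terminator
(3′UTR) screen in *Chlamydomonas reinhardtii*: genome-annotation
statistics, diurnal expression ranking, terminator-part selection and
Golden Gate domestication, and the statistics of an antibiotic/reporter
plate screen over serial subcultures. Annotations are taken as given
(no UTR inference from reads); FPKM matrices are inputs (no
quantification from reads); GFP calls enter as booleans (no image
processing, and no absolute expression levels — only threshold calls).

## Coordinates, lengths and size classes

All genomic arithmetic uses the GFF3 convention: 1-based, inclusive
ends, length = end − start + 1, summed over a feature's intervals.
Terminator size classes follow the screen's taxonomy: short < 100 bp,
medium 100–600 bp inclusive on both bounds, long > 600 bp; the three
classes partition the positive integers. Length histograms use
half-open bins `[i·binsize, (i+1)·binsize)` with a 100-bp default.

Medians use the lower-middle element for even n, keeping integer
samples integer-valued and reproducible; the interpolating convention
is available by flag. Genes lacking a UTR annotation are excluded from
UTR statistics (and counted), never treated as length 0.

Intergenic distances order genes by span start per chromosome,
regardless of strand; distance = downstream start − upstream end − 1,
so overlapping annotations give negative values, which are retained.
In `utr_to_utr` mode the boundary on each side is the genomic extent of
that gene's annotated UTRs; a gene with no UTR annotation contributes
its span boundary (the file records which genes that applies to via the
exclusion counts of `feature_lengths`). Representative transcripts
default to the longest by exonic length, ties broken lexicographically.

## Expression ranking

Genes are ranked by the unweighted arithmetic mean FPKM across all
timepoints of a 24-h series; SD is the sample SD across columns. Tied
means share the minimum rank of the tied block — a deterministic
convention that is conservative for downstream rank-cutoff filters.
"Highly expressed" means rank ≤ 350; named exceptions (e.g. a gene
induced only under nitrogen depletion) bypass the cutoff. Replicate
columns count individually unless a replicate map is supplied.

## Part engineering

Motif scanning is sense-strand only: polyadenylation signals act on the
transcript, so the strand-oriented extracted part is scanned for
`TGTAA` (all overlapping occurrences). Part trimming keeps the prefix
ending a configurable tail (default 33 bp) after the last motif
occurrence that allows the full tail.

Domestication removes BsaI/BpiI recognition sites on both strands by
single-base substitution: leftmost mutable position within the site not
covered by a protected interval (the poly(A) motifs are always
protected), transversions preferred, and an edit is accepted only if it
removes the site without creating a new site of any configured enzyme.
The procedure is idempotent and errors when a site admits no legal edit.
Parts here are non-coding, so no codon constraint applies; synonymous
CDS domestication is out of scope.

Assembly simulation checks that consecutive fusion sites (4-nt
overhangs) match, that the chain closes through the backbone, and that
no overhang serves two junctions (ligation ambiguity); each shared
overhang is counted once in the circular product length, and junction
coordinates are returned so a digestion can recover the input parts
exactly. Overhang assignments are part properties supplied by the user
or config — never hard-coded. Plasmid linearization treats positions
modulo the plasmid length; the flank is the shorter circular arc
between the unique out-of-cassette cut and the nearer cassette
boundary, with in-cassette or multiple cuts flagged rather than raised.

Candidate selection requires: rank ≤ 350 (or exception), annotated
3′UTR ≤ 1000 bp (longer elements hinder modular cloning), and at least
one sense-strand `TGTAA` in the extracted sequence. Extraction is
strand-aware (minus-strand UTRs reverse-complemented) and may extend
past the annotated UTR via `extend_3prime` (default 0).

## Screen statistics

* **Transformation efficiency**: per-plate rate = colonies/µg;
  technical replicates are averaged within an experiment first; mean
  and SEM (sd/√n) are taken over independent experiments. A single
  experiment yields SEM 0 with an `sem_undefined` flag.
* **Stability**: viability per line is a boolean per round, monotone
  non-increasing (violations raise, naming the line); the curve is the
  percentage of initially picked lines viable at each round.
* **GFP fraction**: denominator is the final-round viable lines — not
  the initially picked lines; unassessed viable lines are excluded and
  counted.
* **Mann–Whitney U**: implemented from scratch.
  U = Σ [xᵢ > yⱼ] + ½[xᵢ = yⱼ] via the rank-sum identity with midranks.
  The exact path builds the null distribution of U with the standard
  recurrence f(m, n, u) = f(m−1, n, u−n) + f(m, n−1, u) and doubles the
  lower tail (symmetric null); it requires tie-free samples and is the
  default up to C(nₓ+n_y, nₓ) ≤ 2×10⁶ combinations. Otherwise the
  normal approximation applies with tie-corrected variance
  σ²_U = nₓn_y/12·[(N+1) − Σ(t³−t)/(N(N−1))] and a 0.5 continuity
  correction. Degenerate variance (all values equal) gives p = 1.
  Tests against a baseline construct use per-experiment values,
  two-tailed, α = 0.05 with strict inequality; no multiplicity
  correction by default (Bonferroni/Benjamini–Hochberg behind a flag),
  matching the screen's reporting convention.

## Synthetic data

The generators target the statistical surface the analytics consume,
not the underlying biology — no integration genetics, silencing
mechanism or fluorescence physics is modelled.

* **Genome**: genes laid left to right with lognormal intergenic gaps
  (default median ≈ 3 kb, echoing the observed spacing); background GC
  0.64 as in the *C. reinhardtii* nuclear genome. 3′UTR lengths come
  from a three-component mixture with default weights 0.036/0.388/0.576
  (the short/medium/long proportions of the real annotation); one
  `TGTAA` is planted per UTR with probability 0.9 (default), ending
  10–20 nt upstream of the annotated UTR end, mirroring the observed
  spacing of poly(A) signals from cleavage sites. Minus-strand genes
  are placed reverse-complemented so strand-aware extraction recovers
  the sense motif. A truth table records every planted length, class
  and motif offset. Features are single-interval; multi-interval
  (spliced-UTR) gene models are exercised with hand-built fixtures in
  the tests instead.
* **FPKM**: log-normal gene baselines, per-gene sinusoidal diurnal
  component (amplitude U(0, 0.5), random phase) that averages to zero
  over an evenly spaced cycle, optional truncated Gaussian noise; the
  planted ranking is the baseline ranking.
* **Screen**: colonies ~ Poisson(efficiency · µg) per technical plate
  (negative-binomial overdispersion behind a flag); line viability is a
  product of per-round Bernoulli survivals, monotone by construction;
  GFP ~ Bernoulli(g) for final-round survivors only. Line fates are
  independent given the parameters — any line-level autocorrelation
  beyond the monotone constraint is unobservable from published
  summaries and is not modelled.

### Packaged presets

The packaged cw15/zeocin preset encodes the published screen outcomes:
RBCS2 2.47×10³ colonies/µg, 74% round-3 viability, 23% GFP⁺; CA1
5.50×10³ colonies/µg, 87% viability (13-point reduction), 81% GFP⁺;
PSAD 83% GFP⁺; no-3′UTR control 1.63×10³ colonies/µg, ~45% viability,
25% GFP⁺. Only marginal round-3 viability is published, so per-round
survival uses a geometric split (each round's conditional survival is
the cube root of the marginal) — a documented modelling choice, not a
published per-round claim. Entries for which only ranges were published
(PSAD/THI4/METE/NIT1 efficiencies; the 20–32% viability reductions and
15–35% / 60–70% GFP bands of the remaining constructs) carry mid-range
values and back no quantitative anchor. The deferred-selection preset
models three non-selective rounds with joint survival 95/96 followed by
two selective rounds ending at 49% overall viability.

Because the presets *are* the generating parameters, recovery tests
demonstrate estimator correctness and calibration at the study's sample
sizes (3 experiments × 96 lines; binomial/Poisson 95% CIs), not
anything about real transformants.

## Problem sizes and numerical choices

The default test and acceptance runs use synthetic genomes of 10–60
genes on single scaffolds, 200–5000-gene FPKM matrices, and screens of
3 × 96 lines — the screen dimensions are the study's own; the genome
sizes are chosen so planted-truth recovery is exact and fast. RNG is a
single named NumPy generator per run with the seed recorded in the
truth/metadata sidecars; identical seed and config reproduce files
byte-identically.

## Known limitations

* Gene models without an mRNA child are skipped rather than
  synthesised from bare gene records.
* The genome generator plants one motif per UTR; real UTRs may carry
  several, so motif-count statistics (as opposed to presence and
  position recovery) are not calibrated.
* The exact Mann–Whitney path refuses tied samples instead of
  enumerating the conditional permutation distribution; tied data fall
  back to the corrected normal approximation.
* Domestication edits one base per site; constructs needing multi-base
  or insertion/deletion edits are reported as having no legal edit.
* The published per-gene anchors for the reference annotation (e.g.
  median 3′UTR length of the real genome) require the externally
  distributed annotation and expression files; the package computes
  those statistics for any supplied GFF3/FPKM input but does not ship
  the data.
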