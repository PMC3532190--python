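# Methods

## Problem and model

Paired small-RNA libraries from cells and the extracellular vesicles (EVs)
they release are compared to decide, per miRNA, whether it is
preferentially packaged into EVs or retained in the cell. Because no
shared internal standard exists between the two compartments, both
libraries are closed compositions: each is normalized to reads per million
mapped (RPMM), and the per-miRNA statistic is the log2 ratio of EV RPMM
over cell RPMM. Under passive, non-selective packaging the ratios scatter
around zero; selective export shows up as a right-skewed ratio
distribution and a stable set of extreme miRNAs.

The estimand is descriptive — a normalized abundance ratio — but counts
are treated as Poisson/multinomial draws, which gives each log2 ratio a
delta-method standard error `sqrt(1/n_cell + 1/n_EV)/ln 2` reported
alongside the estimate. No per-miRNA significance test is performed; the
published analysis this package reimplements used ranked ratio lists, and
the lists are the deliverable.

## Pipeline stages and their parameters

**Adapter trimming** (`refio`). The 3' adapter is located by a
suffix-of-read / prefix-of-adapter Hamming scan — no indels, leftmost
acceptable position wins. Parameters: adapter sequence (default the
Illumina v1.5 small-RNA adapter; the original study used CLC defaults and
does not state one, so it is fully configurable), `min_overlap` 6 nt,
`max_adapter_mismatches` 1, `min_read_length` 16 nt (inserts must exceed
15 bp; the inequality is strict). Reads with no detectable adapter are
kept by default — the protocol does not prescribe discarding them — and a
`TrimSummary` reports every category. Quality strings are parsed and
ignored: no quality filtering is part of the procedure.

**Alignment and counting** (`quantify`). Reads are placed on hairpin
precursors by an exhaustive ungapped scan over every offset of every
hairpin (vectorized over unique sequences with numpy sliding windows),
keeping placements within 2 mismatches and then only those at the minimal
observed mismatch count. Ungapped-with-mismatch-cap is the conventional
model for ~22 nt reads; indels are not considered. A placement is assigned
to a mature arm when the read 5' end lies within ±3 nt of the arm's
annotated 5' end and the overlap is ≥ 16 nt — the upstream pipeline being
reproduced is a black box here, so both windows are exposed as parameters.
Reads assigned to several matures at equal mismatch count are split into
equal fractions (configurable: `split`/`discard`/`first-by-id`); splitting
keeps column totals equal to the number of assigned reads, which the
conservation tests rely on. IsomiR classes are keyed by (5' offset,
3' offset, mismatch count): end shifts define isomiRs, internal edit
positions do not. Reverse-complement placements are not searched (stranded
protocol).

**Normalization** (`normalize`). RPMM divides by the library's total
mature-assigned reads. The pseudocount rule operates on the count scale,
pre-normalization — "one read" then flows through the library's own
denominator — and only ever converts a lone cell-library zero of an
EV-ubiquitous miRNA to 1; it is idempotent. The symmetric EV-side variant
exists but is off by default, since only the cell-side rule is part of the
procedure being reproduced. Exclusion–renormalization drops the
overexpressed miRNA's rows and rescales each affected library back to
10^6; it preserves within-library pairwise ratios exactly (float tolerance
1e−9 relative) and equals de novo RPMM on the spike-free counts, which is
tested both ways. In `ExportAnalysis` the exclusion can be restricted to
chosen libraries (e.g. only the transfected pair), implemented by zeroing
those counts before normalization — the equivalent de novo computation.

**Export statistics** (`export`). `log2_ev_cell` is NaN, never zero, on
non-positive input. The classification band [−1, +1] is closed for class
labels; the *fraction similar* statistic uses the open interval (−1, +1)
by default, matching how that share is conventionally quoted — both are
selectable. The expressed flag uses raw reads (strictly more than 1000 by
default, in either compartment), not RPMM. Released/retained lists order
expressed miRNAs by descending/ascending ratio with lexicographic
tie-break for determinism. Report output rounds to 2 decimals, with a
1-decimal display mode matching the published table style. Library–library
correlations default to Pearson R² on log2(RPMM + 1); the raw-scale option
exists because the original figures do not state their scale — for the
same reason no specific published R² value is asserted anywhere.

**qPCR** (`qpcr`). Replicate Cts are averaged on the Ct scale before
differencing (the source protocol is silent; the arithmetic Ct mean is the
common choice), amplification efficiency is fixed at 2 with an
efficiency-corrected `E^-dCt` variant available, and undetermined wells
are missing data, not Ct 40. Both the replicate Ct spread and the derived
ratio are reported, so error bars can be drawn on either scale.

**Cross-dataset ranks** (`cross_dataset`). dCt is defined as
Ct(cells) − Ct(EVs), so larger always means more exported and qPCR
rankings coincide with ratio rankings. Ties get average ranks. Native
ranks are computed over each dataset's full detected set *before*
restriction to the reference miRNAs — the property that makes the rank
matrix meaningful — and decile bands (1–10) of the native rank stand in
for the red–green rendering of published heatmaps, which is a display
concern. A measured zero ratio participates in ranking; absence from a
platform is blank.

## The synthetic study

`simulate` generates the four-library design (cells/EVs ×
non-transfected/transfected) with known truth. Defaults, chosen once as a
realistic small study: 150 miRNAs on 80 nt hairpins with one 20–23 nt
mature arm each; cellular proportions log-normal with log-sd 2 (a handful
of miRNAs dominates, as in real libraries); export propensities e_i from a
mixture — baseline N(0, 1.5), a 12% strongly exported component
N(+5, 2) and a 5% retained component N(−2, 0.7) on the log2 scale; a
transfection spike at 32% of the cellular and 44% of the EV pool; 10^6
reads per library; canonical isomiR mass 0.5 over a small set of end
offsets; 0.1% per-base substitution error on 36 nt reads with the adapter
appended and the read truncated to that length.

EV proportions are the cellular proportions tilted by `2^e_i` and
renormalized. Renormalization makes the composition closed: realized
log2(EV/cell) ratios equal e_i minus a common constant, so recovery is
assessed after median-centering both sides. The generator knows every
read's source arm, end offsets and injected errors, so trimming, alignment
and assignment can be checked read by read.

The dataset panel generator perturbs true log2 ratios with Gaussian noise
(default sd 1.0) and applies detection dropout whose expected blank
fraction equals the `dropout` parameter, with low-abundance miRNAs
dropping out preferentially — no noise model for the heterogeneous public
datasets exists, so these are free, documented knobs. Ct tables are
derived as `baseline − log2(abundance) + noise` in triplicate wells, with
the reference (normalizer) miRNA chosen as an abundant miRNA with export
ratio near 1, mirroring how such normalizers are picked.

What the generator does *not* emulate: hairpin secondary structure,
ligation and PCR biases (abundances are clean multinomials), PCR
duplicates, per-base quality, indel sequencing errors, and non-miRNA small
RNA contamination. Passing tests therefore demonstrate correctness of the
computation under the stated sampling model, not robustness to every
artefact of real libraries.

## Numerical and design notes

* Aligner windows never span hairpin boundaries (explicit validity mask);
  non-ACGT read symbols mismatch every reference base. The test suite
  carries an independent exhaustive pure-Python oracle and compares
  placement lists exactly.
* Mature-assignment ambiguity (two arms qualifying) is broken by smallest
  5' offset, then larger overlap, then lexicographic id.
* RPMM conservation is validated at 1e−6 relative; exclusion preserves
  ratios at 1e−9 relative; both reflect pure float roundoff, not model
  tolerance.
* Simulation sizes in tests are scaled to the check at hand: read-level
  runs use 10^3–10^5 reads/library where per-read truth is compared;
  count-level runs use the full 10^6 reads/library default where only
  count statistics matter.
* The packaged published table reproduces two rows (mir-143, mir-720,
  transfected condition) whose printed log2 values are inconsistent with
  their printed RPMM pairs; they are kept verbatim and excluded from
  numeric checks rather than corrected.
* The published 19.5% similar-representation share requires the study's
  full supplementary expression table, which is not redistributed here;
  the statistic itself is exercised on the packaged table rows and on
  constructed data with known open/closed-interval counts.

## Known limitations

Single-end, stranded, mismatch-only alignment against hairpins — no
genome mapping, novel miRNA discovery or other small-RNA classes. The
mature-assignment window is a surrogate for an unpublished commercial
pipeline's behaviour. Cross-platform comparison is rank-only by design;
no intensity normalization across datasets is attempted, and meta-analytic
inference (combined p-values) is out of scope.
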