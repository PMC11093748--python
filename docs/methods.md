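# Methods

`sabrscreen` implements the computational workflow around pooled SABR-II
screens: a library of epitopes is displayed on MHC-II by reporter cells, TCR
binding drives the reporter, the top percentile of reporter-positive cells is
sorted, and sequencing of the integrated epitope cassette before and after the
sort reveals which epitopes a TCR recognizes. This note records the models,
defaults and design choices behind each stage, and what the bundled simulator
does and does not capture.

## Library design

**Curation.** Published epitope lists are trimmed to a configurable length
window (default 9–25 aa, the range presentable by MHC-II in this workflow) and
filtered on modification annotations. Only deamidation and hybrid insulin
peptides (HIPs) survive the filter by default, because both are expressible as
plain amino-acid sequence: deamidation is encoded directly as N→D / Q→E
substitution (the insert is genetically encoded, so a modification flag would
be meaningless), and a HIP is simply the fused peptide. Duplicate peptides
keep the first occurrence; entries with non-canonical residues are rejected
and logged rather than raised, so one bad record does not abort a 4,000-entry
curation.

**HIP enumeration.** The combinatorial HIP library is the full cross product
of "left" halves (insulin-C cleavage fragments) and "right" halves (secretory
granule protein fragments), keeping fusions of 12–25 aa total. Cleavage rules
are not modeled: fragments are user-supplied, with a helper that derives them
from a protein sequence plus declared cut positions. Junction indices are
0-based counts of left-derived residues. Junction-spanning validation
epitopes take the last *k* residues of the left context and the first *k* of
the right (default *k* = 7); at *k* = 7 no 9-mer of the 14-mer lies wholly in
either source protein, so any MHC-II binding register must span the fusion.

**Back-translation.** Codons are drawn per residue, weighted by mouse codon
usage, from a deterministic PCG64 stream; codons overlapping a forbidden
restriction motif (searched on both strands) are resampled, with a bounded
retry count so impossible constraints fail loudly. BsmBI (CGTCTC) is
forbidden by default because library cloning is Golden-Gate style through
BsmBI. Oligos are `flank5 + insert + flank3`; identical inserts from distinct
epitopes raise a collision report rather than silently synthesizing an
ambiguous pool. Per-epitope seeds are derived from a master seed plus library
position, so editing one epitope upstream does not reshuffle unrelated
inserts.

## TCR reconstruction

CDR3s follow the IMGT junction convention (conserved V cysteine through the
J-segment F/W of the FGXG motif), matching CellRanger vdj output. Anchors are
located at load time: for V, the last Cys within the C-terminal 15 residues
(with a per-allele override table for atypical segments); for J, the first
F/W opening an FGXG. Segments failing these invariants load but are flagged
unusable. The chain protein is
`V[:anchor] + CDR3 + J[anchor+1:] + C`.

Nucleotides maximize germline fidelity: the longest CDR3 prefix matching
germline V (from its anchor) and the longest suffix matching germline J (up to
its anchor) reuse germline codons; only the non-templated core is
back-translated. In the limit of a pure germline junction, the nucleotide
output is exactly the germline V+J+C concatenation. Constructs are
`EcoRI-flank + α + P2A + β`, with β truncated at (and including) the first
BlpI site in the β constant region — the downstream vector supplies the rest
of Cβ. Internal EcoRI sites inside the coding sequence are removed by
synonymous codon resampling so the cloning site stays unique. Leader peptides
are kept as present in the reference; no signal-peptide prediction is done.

## Read processing

Samples carry unique dual indexes (UDIs) parsed from Illumina-style header
comments (`1:N:0:I7+I5`). A read is assigned to the unique sample whose i7
and i5 are each within `tol` Hamming mismatches (default 1, common UDI
practice; the tolerance is configurable because no single value is canonical).
A sample sheet is refused up front if two samples' index pairs are both
within `2·tol`, the exact condition under which a read could satisfy the rule
for two samples. Indels in indexes are not handled.

The epitope insert is extracted between two constant anchors (vector-derived
amplicon sequence; ≥15 nt recommended — at that length, chance within-
tolerance matches inside inserts are negligible). Matching is nucleotide-
exact by default, since reads should reproduce the synthesized inserts; a
peptide mode translates in-frame inserts and matches on peptide, tolerating
synonymous variants. Read accounting is conserved at every stage:
`assigned + unmatched_insert` per sample plus global `unassigned_index`
equals the input read count. Only read 1 is searched for anchors; read 2
carries nothing the header does not. Phred scores are ignored (no quality
filter is part of the default workflow).

## Enrichment scoring

Counts are normalized to counts-per-million after adding a pseudocount
(default 0.5) to every cell; the pseudocount tames zero counts before
regression and is the only smoothing applied. For each sorted replicate an
ordinary least-squares model (with intercept) of that replicate's normalized
abundance on the mean normalized unsorted abundance yields the expected
abundance of every epitope; the enrichment score is the residual

    ES(e) = observed(e) − expected(e)   [CPM units]

Fitting per replicate (rather than pooling) lets each fit absorb
replicate-specific depth and scaling; a `studentize` option divides by the
fit's residual SD for unitless scores. A TCR's score per epitope is the mean
ES over the sorted replicates containing that TCR. ES is deliberately a raw
residual, not a p-value: hit calling uses calibrated thresholds, not tests.

**Confidence zones.** The thresholds are fractions (default 0.5 and 0.25,
recorded in output provenance) of the weakest control-cognate mean ES from a
positive-control TCR screened alongside. A control cognate with non-positive
ES indicates a failed screen and is an error, not a silent recalibration.
Hits are tiered high (≥ high threshold) or low (≥ low threshold), sorted by
descending mean ES then epitope id.

**Dropout deconvolution.** In a multiplexed leave-one-out design each sorted
replicate omits one TCR. A TCR's score is the mean ES over replicates
containing it; an optional contrast mode subtracts the mean over replicates
lacking it, which sharpens the assignment of an epitope to its owning TCR
(the cognate's score under every *other* TCR collapses, because the left-out
replicate of the owner is precisely where the epitope is not enriched).
Contrast mode requires every TCR to be absent from at least one replicate.

## Simulator

The simulator is the package's ground-truth generator, not a biophysical
model. Library abundances are log-normal (σ = 1 by default, reproducing the
strongly unequal representation seen in sequenced pools); each cell carries
one construct; reporter signal is N(0, 1) background plus an additive shift
(default 6 SD) for cells whose epitope is cognate to a present TCR; the
sorted sample is the exact top `gate_fraction` (default 2%) of cells by
signal; sequencing is a multinomial draw of `reads_per_sample` (default 10⁵)
from each sample's cell composition. Cognate epitopes can be pinned to a
fixed pre-sort cell frequency (default 0.05%), which reproduces the regime
where a strong signal shift saturates the gate and fold enrichment approaches
the reciprocal of the gate fraction (~50× at a 2% gate). Reads are emitted as
`anchor5 + insert + anchor3` with independent per-base substitution errors on
sequence and indexes; at zero error rates the read-processing stack recovers
the simulated counts exactly, which is the basis of the end-to-end tests.

Not modeled: reporter kinetics and co-staining, transduction multiplicity
(one construct per cell is assumed), cell growth between sort and sequencing,
PCR amplification bias, and sequencing indels. Passing tests therefore show
that the scoring machinery recovers planted signal under clean sampling
noise, not that it is robust to every artifact of real screens.

## Numerical choices and scales

Internal coordinates are 0-based half-open. All randomness flows through
explicit integer seeds (NumPy PCG64); derived seeds stay below 2³¹.
Simulation-based tests use 10⁴–10⁶ cells, 60–1,000 epitopes and 10³–10⁵
reads per sample — large enough that planted effects dominate sampling noise
by an order of magnitude, small enough that the whole suite runs in well
under a minute apart from the 100-seed sort-gate study (~15 s). Exact-ratio
assertions on gate enrichment use a 10⁻⁹ relative epsilon because the
frequency ratio (N/20000)/(N/10⁶) rounds below 50 in floating point for some
N.

## Known limitations

- The realized 2,561-epitope HIP library depends on an unpublished fragment
  set; the enumerator reproduces the construction rule, not the exact
  manifest, and the manifest-count check requires the original table.
- Anchored insert extraction handles substitutions but not indels; reads with
  indels inside an anchor are counted as unmatched rather than rescued.
- The expected-abundance model is a single linear regression on mean unsorted
  abundance; heteroscedasticity across the abundance range is absorbed only
  by the optional studentization, not modeled.
- The V-anchor heuristic (last Cys in the C-terminal 15 residues) covers
  standard mouse alleles; genuinely atypical segments need the override
  table.
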