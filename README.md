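# sabrscreen

Toolkit for pooled **SABR-II screens** — CD4⁺ T cell antigen discovery with
signaling and antigen-presenting bifunctional receptors. Reporter cells each
display one epitope of a pooled library on MHC-II; when a TCR binds its
displayed peptide the cell fires an NFAT reporter, the top 1–2% of
reporter-positive cells is sorted, and sequencing the integrated epitope
cassette before and after the sort reveals the TCR's cognate epitopes.

`sabrscreen` covers the computational workflow end to end:

- **`library_design`** — curate published epitope lists (9–25 aa, deamidation
  encoded as N→D/Q→E), enumerate combinatorial **hybrid insulin peptide
  (HIP)** libraries from insulin-C "left" halves × secretory-granule "right"
  halves (12–25 aa), build 7+7 junction-spanning validation epitopes, and
  back-translate peptides into synthesis-ready oligo pools with
  restriction-site (BsmBI) avoidance.
- **`tcr_reconstruction`** — rebuild full-length TCRα-2A-TCRβ constructs from
  V/J allele names + CDR3s against an IMGT-style germline reference, with
  EcoRI 5′ flank and BlpI-truncated Cβ, reusing germline codons wherever the
  CDR3 matches germline.
- **`read_processing`** — dual-index (UDI) demultiplexing with Hamming
  tolerance, anchored insert extraction, epitope counting, and merging into
  an epitope × sample count matrix with full read accounting.
- **`enrichment`** — per-replicate **enrichment scores** and two-tier hit
  calling: for each sorted replicate, OLS of normalized sorted abundance on
  mean unsorted abundance gives each epitope's expected abundance, and

  &nbsp;&nbsp;&nbsp;&nbsp;ES(e) = observed(e) − expected(e) (CPM),

  averaged over a TCR's replicates. High/low confidence zones are fractions
  (default 0.5/0.25) of the weakest positive-control cognate ES. Multiplexed
  **dropout (leave-one-out) screens** are deconvoluted by averaging ES over
  the replicates that contained each TCR.
- **`simulate`** — ground-truth screen simulation (log-normal library
  abundance, Gaussian reporter signal with a cognate shift, exact
  top-percentile gate, multinomial read sampling, FASTQ emission with index
  and read errors), so every stage is testable without external data.

## Worked example

Simulate a three-replicate screen of the BDC2.5 TCR against a 500-epitope
library (its cognate planted as `epi0042` at 0.05% pre-sort frequency), score
it, calibrate zones on the control cognate and call hits:

```python
from sabrscreen import (SimulationParams, ScreenDesign, simulate_screen,
                        compute_es, calibrate_zones, call_hits)

params = SimulationParams(
    n_epitopes=500, n_cells=200_000, reads_per_sample=100_000,
    gate_fraction=0.02, effect_size=6.0,
    cognate_map={"BDC2.5": "epi0042"}, seed=1,
)
replicates = {f"sorted_{i}": {"BDC2.5"} for i in (1, 2, 3)}
matrix, library, abundance, truth = simulate_screen(params, replicates)

design = ScreenDesign(
    unsorted=["unsorted_1", "unsorted_2", "unsorted_3"],
    sorted_tcrs=replicates,
    control_tcr="BDC2.5", control_cognates={"epi0042"},
)
scorer = compute_es(design, matrix)
zones = calibrate_zones(scorer.mean_es("BDC2.5"), ["epi0042"])
hits = call_hits(scorer.mean_es("BDC2.5"), zones)
print(hits.round(1))
print(f"zones: high >= {zones.high_threshold:.0f}, low >= {zones.low_threshold:.0f} CPM")
```

```
         mean_es  tier
epi0042  27290.8  high
zones: high >= 13645, low >= 6823 CPM
```

The planted cognate is the only hit: its mean ES of ~27,300 CPM says its
post-sort abundance exceeds the regression-expected abundance by ~2.7% of the
sample — consistent with 0.05% of cells being concentrated ~50-fold by a 2%
gate. Every other epitope's residual is sampling noise, orders of magnitude
below the low-confidence threshold.

The same workflow is available from the shell via the `sabr2` command
(`curate`, `hip`, `oligos`, `reconstruct`, `demux-count`, `merge`, `score`,
`simulate`); `sabr2 <cmd> --help` shows each command's options.

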