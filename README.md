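# epihet

Single-nucleus histone-modification heterogeneity analysis for tumor
progression studies.

Single-nucleus CUT&RUN-style assays profile histone marks (H3K4me3,
H3K27ac, H3K27me3) one cell at a time, which makes it possible to ask how a
tumor's chromatin landscape varies *within* a lesion — and whether a
primary tumor already contains small subpopulations whose epigenome is
"primed" toward a progressed state (metastatic or drug-resistant).
`epihet` implements the full analysis stack for this question:

1. **Per-cell QC** — unique fragment count (UMR), fraction of reads in
   peaks (FRiP), blacklist fraction, TSS enrichment, nucleosome signal;
   cells are excluded when UMR < 1000, UMR > 100 000, FRiP < 0.25,
   blacklist fraction > 0.01, nucleosome signal > 5, or TSS enrichment
   < 0.5 (strict inequalities).
2. **Cell×feature matrices** — 10 kb bin or peak matrices from fragment
   files, TF-IDF normalization `log(1 + TF·IDF·10⁴)`, LSI (truncated SVD,
   component 1 dropped), depth-equalized pseudobulks, and one-vs-rest
   Wilcoxon marker-peak detection with Benjamini–Hochberg correction.
3. **Chromatin-state segmentation** — pseudobulk mark tracks binarized per
   200 bp bin against a genome-wide Poisson background, then a K = 5 state
   HMM with independent Bernoulli emissions per mark is fit by Baum–Welch
   and decoded by forward–backward posteriors. States are labelled by
   their emission signature: E1 weak promoter (H3K4me3 only), E2 active
   promoter (H3K4me3⁺/H3K27ac⁺), E3 active enhancer (H3K27ac only), E4
   unmodified, E5 heterochromatin (H3K27me3 only). Transitions between
   two conditions are tabulated with the stable-unmodified (E4→E4) cell
   excluded from the reported table.
4. **CN × chromatin × expression integration** — each gene gets a promoter
   state (strand-oriented window −2000/+3000 bp around the TSS over the
   200 bp segmentation), the copy number of the segment containing its
   TSS (grouped 1 / 2 / 3 / 4+), and an expression Z-score; the CN effect
   on expression is quantified per state group by median (τ = 0.5)
   quantile regression of Z on CN ∈ {2, 3, 4+}.
5. **Module scores and ternary gating** — per condition, the top-50 marker
   peaks form a module; a chromVAR-style deviation Z-score per cell
   measures enrichment over accessibility-matched background peak sets;
   the three scores S_PRI, S_MET, S_PCR are shifted non-negative and
   normalized to sum to one (`Sx_norm = Sx / (S_PRI + S_MET + S_PCR)`),
   and a cell is called transitional (preMET / prePCR) when two of its
   ternary coordinates exceed 0.4.

A first-class synthetic-data generator (`epihet.simulate`) inverts these
models — hidden Markov chromatin landscape, per-cell fragment sampling with
CN scaling and planted peak modules, a planted transitional subpopulation,
and a linear CN × state expression model — so the entire pipeline is
testable offline with known ground truth.

## Worked example

```python
from epihet.config import PipelineConfig
from epihet.simulate import SimulationConfig, build_truth, simulate_cells, truth_peaks
from epihet.qc import compute_qc_table, filter_fragments
from epihet.pipeline import run_module_pipeline, attach_report
from epihet.io import GeneAnnotation
import pandas as pd

cfg, pcfg = SimulationConfig(), PipelineConfig()
truth = build_truth(cfg, seed=1)
fragments, labels = simulate_cells(truth, seed=2)
peaks = truth_peaks(truth)
qc = compute_qc_table(
    fragments, peaks,
    pd.DataFrame(list(cfg.blacklist), columns=["chrom", "start", "end"]),
    GeneAnnotation(truth.genes[["symbol", "chrom", "tss", "strand"]]), pcfg,
)
print(qc["pass"].sum(), "/", len(qc), "cells pass QC")
kept = filter_fragments(fragments, qc)
lab = labels.set_index("barcode")["condition"].loc[qc.loc[qc["pass"], "barcode"]]
res = run_module_pipeline(kept, peaks, lab, pcfg, seed=5, source="PRI", target="PCR")
res = attach_report(res, qc, lab, "PRI", "PCR")
print((res["gate"] != "none").sum(), "prePCR cells;",
      "ordering check:", res["report"]["ordering_check"])
```

prints

```
900 / 918 cells pass QC
30 prePCR cells; ordering check: True
```

i.e. the 18 planted QC-failure cells are excluded, and the ternary gate
recovers the 30 planted transitional cells (10 % of the 300 primary-tumor
cells): cells whose H3K27ac profile is a 50/50 mixture of the primary and
cisplatin-resistant rate profiles land near the PRI–PCR edge of the
simplex with both coordinates above 0.4. The report also confirms the
score ordering (remaining primary < transitional < progressed on the
progressed module) and that UMR/FRiP do not confound the gate.

## Command-line interface

`epihet simulate|qc|segment|integrate|modules`, each taking `--config`
(YAML/JSON overriding `PipelineConfig` defaults), `--seed` and `--outdir`;
see `epihet --help`. Outputs are plain text (TSV/BED/MTX/JSON/SVG).

## Scope

Alignment, deduplication, peak calling, RNA quantification, CN segment
estimation, UMAP, motif and pathway enrichment are out of scope: fragments
enter as 5-column TSV, peaks/blacklist as BED, copy number as segment
tables, expression as count tables.
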