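# cislnc

Analysis toolkit for **islet-enriched long non-coding RNAs (lncRNAs) in human
islet grafts**. The scientific setting: human pancreatic islets transplanted
into immunodeficient mice, with β-cell death induced by adoptive lymphocyte
transfer (ALT); bulk RNA-seq of isolated islets, PBS-treated grafts, and
ALT-treated grafts identifies lncRNAs whose deregulation tracks the loss of
β-cell function and survival. This package implements the post-alignment
analysis of that design as a tested, reusable library for transcriptomics
researchers: threshold-based differential-expression (DE) filtering,
genomic-distance screening of candidate *cis*-regulatory lncRNA–mRNA pairs,
tissue-specificity calling, ΔΔCt qPCR statistics, gene-set enrichment, and
apoptosis quantification — with a synthetic-data generator that plants known
ground truth so every stage is verifiable without access to raw reads.

## The core rules and statistics

- **DE filtering.** Per-transcript log2 fold change
  `log2FC = log2((mean_B + c) / (mean_A + c))` with pseudocount `c`, a
  two-sample Student *t*-test on log2(FPKM + c) replicates, and
  Benjamini–Hochberg *q*-values. Named threshold presets encode the
  inclusion rules verbatim: `rnaseq_de` (FC ≥ 2, q ≤ 0.05, status OK),
  `cis_screen` (|log2FC| > 1.5, p < 0.05), `ipa_upload` (FC > 1.5,
  p < 0.05), `plot_inclusion` (FC > 1.5 **or** p < 0.05).
- **Cis pairing.** A DE lncRNA is paired with a DE mRNA when the lncRNA lies
  within 50 kb of the mRNA transcription start site (TSS), computed per
  transcript isoform. Pairs are classified co-down / co-up / opposite by the
  signs of the two fold changes, and summarized with a Pearson correlation
  of the paired log2FCs.
- **Islet specificity.** A transcript is islet-specific when its islet
  expression strictly exceeds **twice** the highest expression in any other
  tissue of the panel (FPKM or 2^-ΔCt; the ratio is unit-free).
- **ΔΔCt.** ΔCt = Ct_target − mean(reference Cts) (geometric-mean
  normalization of reference quantities on the Ct scale), ΔΔCt against the
  calibrator-arm mean, fold change = mean 2^−ΔΔCt, Student *t*-test on the
  replicate 2^−ΔΔCt values, and fold regulation = −1/FC for FC < 1.
- **Apoptosis.** TUNEL⁺ β-cell percentages per islet with group *t*-tests,
  and Annexin-V/PI quadrant percentages with apoptotic rate = early + late.
- **Enrichment.** Right-tailed Fisher exact test (hypergeometric tail) of a
  DE set against named gene sets, reporting −log10(p).

## Worked example

The package ships a ten-isoform reference table of islet lncRNAs (locus,
strand, per-group FPKM, and the top-expressing other tissue from a public
body-map compilation). Applying the strict more-than-double rule:

```python
from cislnc.io import load_table1, table1_panel
from cislnc.specificity import specificity_calls, specificity_ratio_report

panel = table1_panel(load_table1())
for c in specificity_calls(panel, factor=2.0)[:3]:
    print(c.transcript_id, c.focal_expr, c.max_other_expr,
          round(c.ratio, 3), c.is_specific)
rep = specificity_ratio_report(panel,
                               exclude=("lnc-SCYL1-1:22", "lnc-POLG2-1:1"))
print("ratio range:", round(rep.min_ratio, 1), "-", round(rep.max_ratio, 1))
```

prints

```
lnc-SCYL1-1:22 321.526 100.17 3.21 True
lnc-POLG2-1:1 152.589 74.41 2.051 True
lnc-CTRB1-1:1 60.2895 0.069 873.761 True
ratio range: 172.1 - 3549.5
```

All ten isoforms pass the >2× rule (`is_specific=True`); outside the two
isoforms that clear it only narrowly (ratios 3.2 and 2.05), islet expression
is 172- to 3,550-fold above the strongest competing tissue.

The full synthetic pipeline runs from one command and recovers every planted
quantity at zero noise:

```sh
cislnc run --seed 1 --outdir runs/demo
```

writing `summary.json` with DE up/down counts, cis-pair pattern counts and
correlation, specificity and pattern calls, ΔΔCt fold changes, and apoptosis
rates, plus a JSON-lines provenance log sufficient to re-derive every
summary number.

## Layout

```
src/cislnc/
  simulate.py     synthetic fixtures with planted truth
  diffexpr.py     fold changes, t-test, presets, Fisher enrichment
  cis.py          locus parsing, TSS distances, 50-kb pair screen
  specificity.py  tissue specificity, graft patterns, detection calls
  qpcr.py         dCt/ddCt, fold regulation
  assays.py       TUNEL and flow-quadrant apoptosis
  pipeline.py     end-to-end orchestration     cli.py  `cislnc` commands
  io.py           GTF/BED/BEDPE/GMT/TSV/JSON   data/   reference table
```

See `docs/methods.md` for the modelling assumptions, parameter defaults,
and known limitations.
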