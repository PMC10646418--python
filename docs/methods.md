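# Methods

## Scope and stance

`cislnc` implements the post-alignment analysis of an islet-graft lncRNA
study: everything downstream of an expression matrix. Read alignment,
transcript assembly, and the original RNA-seq dispersion model are out of
scope; where the original workflow relied on external engines (a Cuffdiff
test, a curated pathway knowledge base, a genomic-region annotation service)
this package substitutes small, fully specified procedures and validates
them against planted synthetic truth rather than against a re-analysis of
the raw sequencing data.

## Differential expression

Fold change is the ratio of group means with a shared pseudocount
(default 1.0):
`log2FC = log2((mean_B + c) / (mean_A + c))`. With `c = 0` a zero mean
yields an explicit ±inf/NaN rather than a silent mask.

The significance stand-in is a **pooled-variance two-sample Student
t-test** on log2(FPKM + c) replicates, with Benjamini–Hochberg correction
applied within one comparison's OK-status tests. Pooled rather than
unequal-variance: the synthetic noise model is homoscedastic on the log2
scale, and at triplicate group sizes the pooled test holds its nominal 5%
size while the small-sample unequal-variance approximation is measurably
conservative (empirical size ≈ 3.7% at 3 vs 3). The calibration is asserted
in the suite: on 10,000 null transcripts (log2 noise sd 0.3, 3 vs 3) the
rejection rate at α = 0.05 must sit within 5% ± 1%.

Degenerate inputs follow fixed conventions: groups with < 2 replicates give
status LOWDATA (no p/q, excluded from BH); zero-variance rows give p = 1
when the groups are identical and p = 0 when two distinct constants are
compared.

Threshold presets encode each printed inclusion rule with its printed
operator (inclusive `≥/≤` for the RNA-seq rule, strict `>/<` for the cis
screen and pathway-upload rules). Two of the source rules genuinely differ —
one thresholds log2(FC) at 1.5 (FC ≈ 2.83), another thresholds FC itself at
1.5 — and both are kept as stated rather than reconciled. "Fold change ≥ 2"
is applied two-sidedly (|log2FC| ≥ 1), since both up- and downregulated
survivors are reported.

Gene-set enrichment is the right-tailed Fisher exact test: p = P(X ≥ k)
under the hypergeometric distribution, each gene set intersected with the
universe first, reported with −log10(p). The suite checks it against a
brute-force binomial-coefficient enumeration.

## Cis lncRNA–mRNA pairing

Coordinates are 0-based half-open internally; printed locus strings
(`chr11:65266530-65273915`, 1-based inclusive) round-trip through the
parser. The TSS is the 5′-most transcript base (start on +, end−1 on −).

A DE lncRNA and DE mRNA form a candidate cis pair when the lncRNA anchor is
within `max_distance` (default 50,000 bp) of the mRNA TSS, per isoform, with
duplicates from multiple isoforms deliberately kept. The default anchor is
the **nearest edge** of the lncRNA interval, treated as a closed segment on
the genomic line: distance 0 when the TSS is covered, otherwise the gap to
the closer end. An alternative `tss5p` anchor measures from the lncRNA's own
5′ end. Signs are reported in mRNA orientation — negative upstream of the
TSS, positive downstream — a convention the source material never fixes; the
screen itself uses only the magnitude. Antisense is flagged as
opposite-strand interval overlap; since no printed definition of an
antisense pair exists, the flag is descriptive and no antisense count is
asserted.

Pairs are classified by fold-change signs (co_down / co_up / opposite; a
zero fold change is a contract violation because the screen requires
|log2FC| > 1.5) and summarized with a Pearson correlation of the paired
log2FCs, two-tailed p from the t-distribution. Fewer than two pairs, or a
constant vector, flags the correlation undefined rather than raising.

## Tissue specificity and graft patterns

The islet-specificity rule is strict: focal expression must exceed
`factor × max(other tissues)` with factor 2 by default ("more than
double"); exactly double is not specific. A zero focal value is never
specific; an all-zero competitor set with positive focal expression is
specific with infinite ratio. The ratio report returns exact quotients and
skips undefined ratios (with a warning) from the min/max. Calls are scale
invariant, and raising the factor can only revoke specificity — both are
property-tested.

Graft patterns over (islet, PBS graft, ALT graft) are strict chains:
monotone_down (islet > PBS > ALT), monotone_up (the reverse), otherwise
`other`; ties always break the chain. Detection from replicate Cts is
"undetected" when all Cts are absent or at/above 40 cycles, or the
dissociation curve failed. Subcellular localization abstracts a
semi-quantitative gel readout into a two-signal fold rule (nuclear if
nuclear > 2× cytoplasmic, and vice versa, else "both").

## qPCR relative quantification

The reference normalization is the geometric mean of the reference-gene
quantities, implemented as the arithmetic mean of their Cts (the standard
reading; the two are identical on the quantity scale). Single-reference
mode covers designs where only one housekeeping gene is usable (e.g.
exosomal RNA). ΔΔCt is taken per treatment replicate against the mean
calibrator ΔCt; calibrator replicates are transformed against their own
mean (expected value 1) so both arms live on the 2^−ΔΔCt scale for the
t-test, paired or unpaired. A plate-wide Ct shift cancels exactly in every
ΔCt, ΔΔCt, and fold change (property-tested). Whether replicates are
technical wells or biological donors is left to the caller — both
aggregations pass through the same function.

## Apoptosis assays

TUNEL inputs are count tables (image analysis is out of scope):
100 · TUNEL⁺β / β per unit, group mean ± SE, t-test between groups. Units
with zero β cells are excluded with a warning.

Flow events are gated into fixed rectangular quadrants at the Annexin-V and
PI thresholds (default 1000 intensity units, calibrated to the generator's
two well-separated log-normal intensity populations; the instrument
thresholds of any real dataset must be supplied by the caller). Two quadrant
labelings are supported because the source material is internally
inconsistent about the A−/PI+ and A+/PI+ quadrants: the default `methods`
labeling uses early = A+/PI−, late = A+/PI+, necrotic = A−/PI+; the
`legend` labeling swaps late and necrotic. The apoptotic rate is
early + late in both. Threshold monotonicity (raising the Annexin threshold
never increases the rate) holds under the default labeling and is
property-tested there; under the `legend` labeling it provably does not
hold, which is one reason `methods` is the default.

## Synthetic data: what it emulates, and what it does not

The generator plants every quantity the downstream stages are asked to
recover:

- **Layout.** One synthetic chromosome; each transcript in its own 400-kb
  slot, so the only sub-50-kb lncRNA–mRNA proximities are the planted
  pairs. Pair lncRNAs sit at a drawn distance within
  `pair_distance_range` (default 1–40 kb) of their partner mRNA TSS,
  placed on the upstream side whenever the drawn gap could collide with the
  gene body; decoy lncRNAs sit 60–120 kb away (past the screen, nearest to
  that mRNA); optional antisense pairs overlap the partner TSS on the
  opposite strand. An explicit chromosome length that cannot hold the
  requested transcripts is an error.
- **Expression.** Log-normal FPKM: Gaussian log2 noise (sd 0.3 by default)
  around group means. Planted DE transcripts shift by the full effect
  (|log2FC| 2.5) in ALT vs Islet and half the effect in PBS — which also
  yields the monotone Islet > PBS > ALT (and reverse) graft patterns by
  construction. Baseline log2 abundance is drawn N(4, 1.5) and clipped to
  [2.5, 9]: the package models *expressed* transcripts, and within that
  range the default pseudocount of 1 cannot erode a planted fold change
  below the FC ≥ 2 gate. At zero noise every planted set is recovered
  exactly.
- **Tissue panel.** Planted islet-specific lncRNAs exceed every other
  tissue by more than `specificity_factor_planted` (default 4, comfortably
  above the 2× decision rule); non-specific rows get one tissue within 2×
  of islet so they cannot pass.
- **qPCR.** Ct = 35 − log2(abundance) + N(0, 0.15), detection limit 40
  cycles, triplicates; reference genes have equal abundance across groups.
- **Flow.** Multinomial over {viable, early, late, necrotic} (defaults
  0.85/0.10/0.03/0.02) with log-normal intensities separated ~100× across
  the threshold, so classification error is negligible and the drawn counts
  are the recoverable truth.

What the generator does **not** emulate: count-based overdispersion and
mean–variance coupling of real RNA-seq, library-size and batch effects,
isoform-level quantification uncertainty, amplification-efficiency
differences between primers, spectral compensation and gating artifacts in
flow cytometry, and any biological correlation structure between
transcripts. Passing tests therefore demonstrate correctness of the
decision rules and estimators under a clean noise model — not robustness to
the full messiness of real data, and no real-data DE or pair counts are
re-derived anywhere.

## Determinism and problem sizes

All randomness flows through seeded numpy generators with per-purpose salt
streams; identical configurations are byte-identical on rerun, including
the pipeline's `summary.json`. The suite's simulation sizes — 10,000 null
transcripts for the type-I calibration, 400 pairs for correlation recovery,
200 plates for ΔΔCt recovery, 10,000 flow events — were chosen so each
Monte-Carlo interval is decisively narrower than the tolerance it checks,
and the default synthetic study (40 mRNAs, 30 lncRNAs, 5 pairs + 3 decoys,
triplicates) keeps the end-to-end run near-instant.

## Known limitations

- The original study's printed DE and pair counts cannot be reproduced from
  first principles here (raw reads and the upstream quantification are out
  of scope); the package asserts their internal accounting identities and
  reproduces the reference-table results exactly, but everything else is
  planted-truth recovery.
- The basis on which the original analysis excluded one near-miss candidate
  isoform from its final specificity table is not numerically documented;
  no attempt is made to reproduce that exclusion.
- Both the pair-distance sign convention and the anchor choice are
  configurable because the source material does not pin them down; results
  that depend on either should report which was used.
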