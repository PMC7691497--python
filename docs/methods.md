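# Methods

This note documents the models, rules and numerical choices behind
`matdecay`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Decay clustering

All classification happens on the log2(FPKM + pseudocount) scale
(pseudocount 1.0). Maternal transcripts are genes with FPKM strictly
greater than 2 at the MII-oocyte stage; the boundary value 2.0 is
excluded. One margin δ (default 1 log2 unit, i.e. two-fold) drives every
inequality:

| cluster | meaning | rule |
|---|---|---|
| I | MII→2C degradation, then stable | `MII > 2C + δ` and `|2C − 4C| < δ` |
| II | stable, then 2C→4C degradation | `|MII − 2C| ≤ δ` and `2C > 4C + δ` |
| III | continuous degradation | `MII > 2C + δ` and `2C > 4C + δ` |

**Cluster-II repair.** Published statements of this scheme circulate with
a self-contradictory pair of inequalities for cluster II (simultaneously
requiring MII above and below the 2-cell level). The verbal definition —
no significant MII→2C change, strong 4-cell down-regulation — is
unambiguous, and the rule above implements it. The three rules are
mutually exclusive by construction: cluster I forbids the 2C/4C drop that
II and III require, and cluster II forbids the MII/2C drop that I and III
require. All comparisons are strict as written, so boundary profiles fall
into `none`.

**Dependence calls.** The knockdown (or DRB) series is compared against
the *control* start of each degradation leg: a cluster-I/III gene is
AGO2-dependent on the MII→2C leg when `log2 kd(2C) ≥ log2 ctrl(MII) − δ`
("increased or stable"); a cluster-II/III gene on the 2C→4C leg when
`log2 kd(4C) ≥ log2 ctrl(2C) − δ`; ZGA-dependence applies the same rule
with the DRB series on the 2C→4C leg. No published threshold exists for
"increased or stable", so the same δ is reused — one significance margin
throughout rather than a second free parameter. Differential-expression
testing (e.g. negative-binomial models with FDR control) is deliberately
not replicated; the log2-margin rules are the sole significance criterion.
Genes absent from a perturbed matrix are recorded as unassessable and
warned about, never silently defaulted.

## Antisense matcher

The endosiRNA→mRNA screen reimplements ungapped, end-to-end small-RNA
alignment with the report-all / mismatch-bound / multimap-suppression
semantics (`v` = 2 mismatches, `m` = 20 placements by default): every
placement of the query in both orientations with Hamming distance ≤ v is
enumerated; if the total across both orientations exceeds m the query is
suppressed entirely. "Antisense" means the reverse complement of the
query matches the transcript window; `N` never matches anything (it
always counts as a mismatch), which is conservative for hit counting.

The implementation is pigeonhole seed-and-verify: any placement with ≤ v
mismatches contains an exact match to one of v+1 disjoint seeds of the
query, so candidates come from an exact k-mer index (seed length
`len(query) // (v+1)`) and only candidates are Hamming-verified with
vectorized comparisons. Queries too short to seed fall back to a dense
scan. Output order is fixed to (transcript, start, orientation) for
reproducibility. The test suite certifies set-identity against an
independent brute-force sliding-window oracle on randomized instances
(100 transcripts × 500 nt, 200 queries, all v/m combinations).

Both orientations count toward the multimap cap, but only antisense hits
feed the downstream target map by default (`antisense_only`), since the
strand handling of the original screen is not stated. Hit *positions* are
reported on the transcript; a convention that pre-reverse-complements
queries would shift positions but not set membership.

The microRNA route is a declared stand-in: a transcript is a target iff
the exact reverse complement of the miRNA seed (positions 2–8) occurs in
it. It exists so the endosiRNA-vs-microRNA comparison can be exercised
offline and does **not** reproduce external target-prediction scores.

## CMR-lncRNA screen

"Alignment ratio" is interpreted as the fraction of lncRNA bases covered
by antisense-aligned blocks (denominator = lncRNA length); a pair is
reported when coverage exceeds `min_coverage` (0.9). Blocks are maximal
ungapped antisense runs of length ≥ `min_block` (20) with per-block
mismatch fraction ≤ `max_block_mismatch_frac` (0.05), found on
seed-flagged diagonals and chained greedily: a mismatch gap is absorbed
only when (a) it is no longer than the mismatch budget of a
minimum-length block (`⌊min_block · frac⌋`, i.e. isolated single-base
mismatches by default) and (b) the gap plus the following exact run is
itself within the mismatch bound. Both conditions matter numerically: a
purely global density bound lets one long near-perfect block "pay for"
arbitrary stretches of adjacent random sequence on the same diagonal,
inflating coverage past the threshold for true-negative pairs. The
selected blocks are a non-overlapping cover of the lncRNA maximizing
covered length (weighted interval scheduling).

Pairs are pre-screened by shared exact k-mers between the lncRNA and the
reverse-complemented mRNA with seed length
`(min_block − mb) // (mb + 1)`, `mb = ⌊min_block · frac⌋` (9 at the
defaults); any block satisfying the rules above contains an exact run at
least that long, so the pre-screen cannot drop a true hit (tested by
equivalence against a dense all-diagonal scan). Multiple mRNA partners
per lncRNA are allowed, one hit per qualifying pair.

The coding-potential filter is a declared ORF-length stand-in for
dedicated classifiers: sequences whose longest ORF (ATG→stop, six
frames; open-ended ORFs counted to the sequence end, the conservative
reading) reaches 100 codons are removed.

Genomic context uses majority rule over the locus span with per-base
priority coding exon > UTR exon > intron across overlapping genes;
`mixed` when no label exceeds 50%, `unplaced` (excluded from fractions)
when the lncRNA has no coordinates.

## saRNA screen

Candidates are small RNAs of 18–30 nt with RPM strictly above 1 at the
zygote *or* 2-cell stage. Promoter windows are strand-aware 1-kb
TSS-upstream sequences — `[TSS−1000, TSS)` on the plus strand,
`(TSS, TSS+1000]` reverse-complemented on the minus strand — so every
window reads 5'→3' toward the TSS; windows truncated by chromosome edges
are flagged. Scanning reuses the matcher with `v = 0` (exact match), the
conservative choice since no mismatch tolerance is published for this
step; both promoter strands are searched and the orientation recorded.
Offsets are measured from the TSS to the hit end nearest the TSS (offset
1 = adjacent to the TSS); the original convention is unstated, so this
one is fixed and documented. The positional histogram bins offsets into
`[k·100, (k+1)·100)` and its total equals the hit count.

## Kinetics and qPCR

Decay courses are fit to first-order decay by ordinary least squares of
ln(abundance) on time — closed-form, exact on noiseless exponentials —
with `T1/2 = ln 2 / k` (stored as the definitional identity, so
`t_half · k = ln 2` to machine precision). The model family is this
package's choice; the assays it models report only a generic
curve-fitting package. A linear-scale nonlinear refinement
(`nonlinear=True`) is available behind a flag. Fits with k ≤ 0 are
flagged and report an infinite half-life, which sorts as most stable in
comparisons. ΔCt aggregates multiple reference genes by the arithmetic
mean of their Cts (equivalently the geometric mean of linear
quantities); no amplification-efficiency correction is applied.

## Synthetic data

The generator emulates, with planted truth recorded for every stage:
log2-scale stage dynamics with planted cluster margins drawn uniformly
from 1.5–2.5 δ (and within-cluster drifts of ±0.3 δ, ±0.4 δ for `none`
genes), Gaussian measurement noise of 0.2 log2 units, 60%/50% planted
AGO2-/ZGA-dependent fractions; small-RNA pools half antisense-planted
with a 0.5/0.3/0.2 mismatch distribution over 0/1/2; lncRNAs with single
planted complementary blocks at coverages straddling the 0.9 threshold
(0.95/0.93 positive, 0.87/0.85 negative) plus composition-matched
scrambled decoys; a toy single-chromosome genome of uniform gene blocks
(1-kb promoter + 1.5-kb two-exon body with CDS) whose ZGA-gene promoters
carry planted saRNA matches, 70% of them 200–400 bp upstream of the TSS;
and log-normal (5% CV) first-order decay courses with mimic/control/
inhibitor rate constants in ratio 2 : 1 : 0.5 around k = ln 2 / 2 h⁻¹.
MII levels are anchored above the worst-case planted drop so no planted
value falls into the FPKM floor, planted lncRNA mismatches are kept ≥ 25
bp apart and from block ends so each is locally supported, and planted
lncRNAs are rejection-sampled to pass the ORF filter by construction.
One global seed fans out into per-component `SeedSequence` substreams, so
regenerating one component never perturbs the others.

Default scale — 2,000 genes, 5,000 small RNAs, 200 lncRNAs (+100
decoys), 300 ZGA genes, 200 kinetic replicates per condition — runs the
full pipeline in well under a minute on one CPU; unit tests use smaller
instances of the same generator.

**What passing tests do and do not show.** The generator plants clean,
isolated effects: uniform transcript base composition, independent
Gaussian/log-normal noise, single-block lncRNA complementarity, exact
promoter insertions. Real data add repeat content and shared sequence
families (which stress multimap suppression far harder), overdispersed
counts, partial and gapped complementarity, and annotation error. Perfect
planted recovery therefore certifies the *correctness of the rules as
specified*, not their biological error rate; the published per-dataset
counts (cluster sizes, 66,568 endosiRNAs, 82% RIP-bound, 37.8%/18.7%
context fractions, 701/208 overlaps) depend on the deposited sequencing
data and annotations and are not reproduction targets here.

## Other numerical choices

* Internal coordinates are 0-based half-open everywhere; GFF3 (1-based
  closed) is converted at the parse/serialize boundary only; BED passes
  through unchanged. TSS = span start (+) or span end − 1 (−).
* U→T normalization and upper-casing at parse time; all matching runs on
  the DNA alphabet.
* Pipeline outputs serialize floats at 6 significant digits; the
  round-trip expression writer uses full precision.
* Ties and orderings (hit sort order, block selection DP) are fixed
  deterministically; identical inputs and seeds give byte-identical
  outputs, checksummed in the run manifest.

## Limitations

* Ungapped matching only: no gapped alignment, no duplex thermodynamics,
  no genome-scale FM-index performance.
* The ORF-length and seed-match stand-ins are intentionally simple and
  are not calibrated against the external tools they replace.
* Group-comparison hypothesis testing (t-tests/ANOVA), GO/KEGG
  enrichment, and read-level processing (alignment, quantification) are
  out of scope; the pipeline starts from expression matrices and
  sequence tables.
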