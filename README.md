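# matdecay

Analysis toolkit for **maternal mRNA degradation (MRD)** during the mouse
maternal-to-zygotic transition (MZT). After fertilization the embryo clears
oocyte-deposited transcripts in waves — before, during and after zygotic
genome activation (ZGA) — and AGO2 loaded with endogenous siRNAs
(endosiRNAs) or guided by small activating RNAs (saRNAs) participates in
both the post-transcriptional and the transcription-coupled arms of this
program. `matdecay` implements the computational side of that analysis as
a tested, reusable pipeline that runs end-to-end on synthetic data with
planted ground truth:

* **Decay clustering** — maternal transcripts (FPKM > 2 in MII oocytes)
  are classified on the log2(FPKM + 1) scale with a single margin
  δ (default 1 log2 unit):
  - cluster I (MII/2C degradation): `MII > 2C + δ` and `|2C − 4C| < δ`
  - cluster II (2C/4C degradation): `|MII − 2C| ≤ δ` and `2C > 4C + δ`
  - cluster III (continuous): `MII > 2C + δ` and `2C > 4C + δ`
* **AGO2- and ZGA-dependence** — a degradation leg is AGO2-dependent when
  expression at the knockdown endpoint is increased-or-stable (not lower
  by more than δ) relative to the control start of the leg; ZGA-dependence
  applies the same rule to a DRB (transcription-blocked) series on the
  2C→4C leg, and the ZGA ∩ AGO2 overlap set is derived from the flags.
* **Antisense target mapping** — a native, exactly specified
  reimplementation of the classic ungapped small-RNA alignment screen:
  report *all* placements in both orientations with Hamming distance ≤ v
  (default 2), and suppress any query with more than m (default 20) total
  placements. A seed-and-verify k-mer index makes it fast; a brute-force
  sliding-window oracle in the test suite certifies it.
* **CMR-lncRNA screen** — lncRNAs whose antisense block coverage against
  an endosiRNA-targeted maternal mRNA exceeds 90% of the lncRNA length,
  with majority-rule genomic-context annotation (intron / coding exon /
  UTR exon / intergenic).
* **saRNA screen** — expressed 18–30-nt small RNAs (RPM > 1 at the zygote
  or 2-cell stage) matched into the 1-kb window upstream of ZGA-gene TSSs,
  with the positional histogram of hit offsets.
* **Kinetics and qPCR** — first-order decay fits N(t) = N₀·e^(−kt) with
  T₁/₂ = ln 2 / k for actinomycin-D time courses, and relative expression
  by the comparative-Ct method (2^−ΔΔCt).
* **Synthetic data** — a generator that emulates the statistical structure
  of the staged RNA-seq / small RNA-seq inputs and records every planted
  fact, so all of the above is scored against known truth.

## Worked example

```bash
matdecay simulate --seed 1 --out simdata
matdecay run-all --data simdata --out results
```

`results/decay_summary.tsv` then contains (seed 1, default scale of 2,000
genes with planted cluster proportions 0.25 / 0.2 / 0.15 / 0.4):

```
quantity                count
n_genes                 2000
cluster_I               499
cluster_II              401
cluster_III             297
cluster_none            803
ago2_dependent_MII_2C   485
ago2_dependent_2C_4C    436
zga_dependent           342
```

The cluster sizes recover the planted proportions (499/401/297/803 vs the
planted 500/400/300/800 at noise σ = 0.2), and the dependence counts
reflect the planted 60% AGO2-dependent and 50% ZGA-dependent fractions of
the eligible clusters. `results/` also holds the per-gene assignments, the
endosiRNA target map, CMR-lncRNA hits with genomic-context fractions, the
saRNA hit table and positional histogram, fitted half-lives, and a
`manifest.json` with parameters and SHA-256 checksums of every input and
output; rerunning with the same seed reproduces identical checksums.

Library use mirrors the CLI, e.g.:

```python
from matdecay import SynthConfig, gen_timecourses, fit_decay
courses, truth = gen_timecourses(SynthConfig(seed=1))
est = fit_decay(courses[0])
print(f"k = {est.k:.3f}/h, T1/2 = {est.t_half:.2f} h, R2 = {est.r_squared:.3f}")
# k = 0.349/h, T1/2 = 1.99 h, R2 = 1.000
```

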