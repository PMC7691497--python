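"""Synthetic datasets with recorded ground truth for every pipeline stage.

The generator emulates the statistical structure of staged embryo RNA-seq
and small RNA-seq: log2-scale stage dynamics with planted decay clusters
and dependence flags, small-RNA pools partly antisense to transcripts with
0-2 mismatches, lncRNAs carrying long complementary blocks straddling the
90% coverage threshold, a toy genome whose ZGA-gene promoters contain
planted 18-30 nt matches concentrated 200-400 bp upstream of the TSS, and
first-order decay time courses with multiplicative log-normal noise.

Every planted fact is recorded in truth tables so downstream stages can be
scored without re-deriving ground truth. One global seed fans out into
per-component substreams (numpy SeedSequence children), so regenerating
one component never perturbs the others.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    GeneModel,
    SequenceSet,
    StageExpressionMatrix,
    reverse_complement,
    write_expression_table,
    write_fasta,
    write_gene_models_gff3,
    write_tsv,
)
from .kinetics_qpcr import DecayTimecourse
from .smallrna_targeting import SmallRNARecord, write_smallrna_table
from .cmr_lncrna import longest_orf_codons

__all__ = [
    "SynthConfig",
    "gen_expression",
    "gen_sequences",
    "gen_timecourses",
    "simulate_all",
    "SynthSequences",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SynthConfig:
    """All knobs of the synthetic-data generator.

    Defaults are sized so that a full pipeline run finishes in minutes on
    one CPU (2,000 genes, 5,000 small RNAs, 200 lncRNAs, 300 ZGA genes)
    while keeping the planted effects at the margins the decay rules use
    (planted log2 margins >= 1.5 * delta).
    """

    seed: int = 0
    # expression / decay clustering
    n_genes: int = 2000
    cluster_proportions: dict = field(
        default_factory=lambda: {"I": 0.25, "II": 0.2, "III": 0.15, "none": 0.4}
    )
    log_delta: float = 1.0
    planted_margin_range: tuple[float, float] = (1.5, 2.5)  # in units of delta
    noise_sd: float = 0.2  # log2 scale
    ago2_dependent_fraction: float = 0.6
    zga_dependent_fraction: float = 0.5
    stages: tuple[str, str, str] = ("MII", "2C", "4C")
    # sequences / targeting
    transcript_length: int = 500
    n_smallrnas: int = 5000
    planted_antisense_fraction: float = 0.5
    mismatch_distribution: dict = field(
        default_factory=lambda: {0: 0.5, 1: 0.3, 2: 0.2}
    )
    smallrna_length_range: tuple[int, int] = (19, 24)
    smallrna_stages: tuple[str, ...] = ("MII", "zygote", "2C", "4C")
    n_mirnas: int = 50
    mirna_planted_fraction: float = 0.5
    # CMR-lncRNA
    n_lncrnas: int = 200
    lncrna_length: int = 300
    cmr_positive_coverages: tuple[float, ...] = (0.95, 0.93)
    cmr_negative_coverages: tuple[float, ...] = (0.87, 0.85)
    cmr_positive_fraction: float = 0.2
    cmr_negative_fraction: float = 0.2
    n_scrambled_decoys: int = 100
    max_orf_codons: int = 100
    lnc_context_fractions: dict = field(
        default_factory=lambda: {
            "intron": 0.4,
            "coding_exon": 0.2,
            "UTR_exon": 0.1,
            "intergenic": 0.3,
        }
    )
    # saRNA / genome
    n_zga_genes: int = 300
    zga_targeted_fraction: float = 0.6
    promoter_window: int = 1000
    sarna_band: tuple[int, int] = (200, 400)
    sarna_band_fraction: float = 0.7
    sarna_lengths: tuple[int, int] = (18, 30)
    # kinetics
    k_control: float = math.log(2) / 2.0  # T1/2 = 2 h
    k_mimic_factor: float = 2.0
    k_inhibitor_factor: float = 0.5
    timepoints: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0)
    kinetics_cv: float = 0.05
    n_replicates: int = 200

    def __post_init__(self):
        total = sum(self.cluster_proportions.values())
        if total > 1.0 + 1e-9 or any(v < 0 for v in self.cluster_proportions.values()):
            raise ValueError("cluster proportions must be >= 0 and sum to <= 1")
        if not (0 <= self.seed < 2**63):
            raise ValueError("seed out of range")

    def rng(self, component: int) -> np.random.Generator:
        """Deterministic substream for one generator component."""
        children = np.random.SeedSequence(self.seed).spawn(8)
        return np.random.default_rng(children[component])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, positions: np.ndarray) -> str:
    out = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


# ---------------------------------------------------------------------------
# Expression matrices with planted decay clusters
# ---------------------------------------------------------------------------


def gen_expression(
    cfg: SynthConfig,
) -> tuple[StageExpressionMatrix, StageExpressionMatrix, StageExpressionMatrix, pd.DataFrame]:
    """Control, knockdown and DRB matrices plus the planted truth table.

    Planted log2 dynamics (pseudocount scale): every gene is maternal
    (MII level uniform in [3, 8] log2 units); cluster genes carry drops of
    ``planted_margin_range`` x delta on their degrading legs and drifts
    within +/-0.3 delta (clusters) or +/-0.4 delta (none) elsewhere.
    AGO2-dependent genes hold their pre-decay level in the knockdown
    matrix; ZGA-dependent genes likewise under DRB. Gaussian noise of
    ``noise_sd`` log2 units is added independently per measurement.
    """
    rng = cfg.rng(0)
    n = cfg.n_genes
    mii_s, c2_s, c4_s = cfg.stages
    d = cfg.log_delta
    gene_ids = [f"gene_{i:05d}" for i in range(n)]

    labels = np.empty(n, dtype=object)
    counts = {
        c: int(round(p * n)) for c, p in cfg.cluster_proportions.items() if c != "none"
    }
    pos = 0
    for c in ("I", "II", "III"):
        k = counts.get(c, 0)
        labels[pos : pos + k] = c
        pos += k
    labels[pos:] = "none"
    rng.shuffle(labels)

    m1 = rng.uniform(*cfg.planted_margin_range, size=n) * d
    m2 = rng.uniform(*cfg.planted_margin_range, size=n) * d
    drift_small = rng.uniform(-0.3 * d, 0.3 * d, size=n)
    drift_none_1 = rng.uniform(-0.4 * d, 0.4 * d, size=n)
    drift_none_2 = rng.uniform(-0.4 * d, 0.4 * d, size=n)
    # anchor MII above the worst-case planted drop so no planted level falls
    # below ~1 log2 unit (the FPKM floor would otherwise erase margins)
    mii = 1.0 + m1 + m2 + rng.uniform(0.0, 4.0, size=n)

    c2 = np.where(
        np.isin(labels, ["I", "III"]),
        mii - m1,
        np.where(labels == "II", mii + drift_small, mii + drift_none_1),
    )
    c4 = np.where(
        np.isin(labels, ["II", "III"]),
        c2 - m2,
        np.where(labels == "I", c2 + drift_small, c2 + drift_none_2),
    )

    # dependence flags, only on legs where the gene actually degrades
    ago_m2 = np.isin(labels, ["I", "III"]) & (
        rng.random(n) < cfg.ago2_dependent_fraction
    )
    ago_24 = np.isin(labels, ["II", "III"]) & (
        rng.random(n) < cfg.ago2_dependent_fraction
    )
    zga = np.isin(labels, ["II", "III"]) & (rng.random(n) < cfg.zga_dependent_fraction)

    kd_c2 = np.where(ago_m2, mii, c2)
    kd_c4 = np.where(ago_24, c2, c4)
    drb_c4 = np.where(zga, c2, c4)

    def to_matrix(cols: dict, condition: str) -> StageExpressionMatrix:
        data = {}
        for stage, logvals in cols.items():
            noisy = logvals + rng.normal(0.0, cfg.noise_sd, size=n)
            data[stage] = np.maximum(2.0**noisy - 1.0, 0.0)
        df = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
        return StageExpressionMatrix(df, condition=condition)

    ctrl = to_matrix({mii_s: mii, c2_s: c2, c4_s: c4}, "control")
    kd = to_matrix({c2_s: kd_c2, c4_s: kd_c4}, "knockdown")
    drb = to_matrix({c4_s: drb_c4}, "DRB")

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "cluster": labels,
            "ago2_dependent_MII_2C": ago_m2,
            "ago2_dependent_2C_4C": ago_24,
            "zga_dependent": zga,
        }
    )
    return ctrl, kd, drb, truth


# ---------------------------------------------------------------------------
# Sequences: transcripts, small RNAs, lncRNAs, genome + gene models
# ---------------------------------------------------------------------------


@dataclass
class SynthSequences:
    """Everything sequence-shaped plus the planted truth tables."""

    transcripts: SequenceSet
    smallrnas: list[SmallRNARecord]
    mirnas: SequenceSet
    lncrnas: SequenceSet
    genome: SequenceSet
    gene_models: list[GeneModel]
    lnc_loci: dict[str, tuple[str, int, int]]
    zga_genes: list[str]
    planted_targets: pd.DataFrame  # smallrna_id, transcript_id, start, mismatches
    planted_mirna_targets: pd.DataFrame  # mirna_id, transcript_id
    planted_cmr: pd.DataFrame  # lncrna_id, mrna_id, coverage, is_positive
    scrambled_ids: list[str]
    planted_lnc_contexts: pd.DataFrame  # lncrna_id, context
    planted_sarna: pd.DataFrame  # smallrna_id, gene_id, offset_upstream
    sarna_targeted_genes: list[str]


def _smallrna_rpm(rng: np.random.Generator, stages: tuple[str, ...]) -> dict:
    """EndosiRNA-like stage profile: peak at zygote/2-cell, low at 4-cell."""
    base = {"MII": 2.0, "zygote": 8.0, "2C": 10.0, "4C": 1.0}
    return {
        s: float(max(rng.lognormal(math.log(base.get(s, 2.0)), 0.5), 0.0))
        for s in stages
    }


def gen_sequences(
    cfg: SynthConfig, target_pool: list[str] | None = None
) -> SynthSequences:
    """Generate transcripts, small-RNA pools, lncRNAs and a toy genome.

    ``target_pool`` optionally restricts which transcripts receive planted
    antisense small RNAs (e.g. the AGO2-dependent maternal set); default is
    all transcripts.
    """
    rng = cfg.rng(1)
    n_tx = cfg.n_genes
    tx_ids = [f"gene_{i:05d}" for i in range(n_tx)]
    transcripts = SequenceSet({}, kind="transcript")
    for tid in tx_ids:
        transcripts.add(tid, _random_seq(rng, cfg.transcript_length))
    pool = list(target_pool) if target_pool else tx_ids

    # --- small RNAs: planted antisense guides + random decoys -------------
    rng_sr = cfg.rng(2)
    n_planted = int(round(cfg.n_smallrnas * cfg.planted_antisense_fraction))
    mm_vals = np.array(sorted(cfg.mismatch_distribution))
    mm_p = np.array([cfg.mismatch_distribution[v] for v in mm_vals], dtype=float)
    mm_p = mm_p / mm_p.sum()
    smallrnas: list[SmallRNARecord] = []
    planted_rows = []
    lo_len, hi_len = cfg.smallrna_length_range
    for i in range(cfg.n_smallrnas):
        sid = f"sr_{i:05d}"
        if i < n_planted and pool:
            tid = pool[rng_sr.integers(0, len(pool))]
            tseq = transcripts[tid]
            k = int(rng_sr.integers(lo_len, hi_len + 1))
            if k > len(tseq):
                raise ValueError("planted window longer than transcript")
            start = int(rng_sr.integers(0, len(tseq) - k + 1))
            guide = reverse_complement(tseq[start : start + k])
            mm = int(rng_sr.choice(mm_vals, p=mm_p))
            if mm:
                positions = rng_sr.choice(k, size=mm, replace=False)
                guide = _mutate(rng_sr, guide, positions)
            planted_rows.append(
                {
                    "smallrna_id": sid,
                    "transcript_id": tid,
                    "start": start,
                    "mismatches": mm,
                }
            )
            seq = guide
        else:
            seq = _random_seq(rng_sr, int(rng_sr.integers(lo_len, hi_len + 1)))
        smallrnas.append(
            SmallRNARecord(
                id=sid,
                sequence=seq,
                rpm_by_stage=_smallrna_rpm(rng_sr, cfg.smallrna_stages),
            )
        )
    planted_targets = pd.DataFrame(
        planted_rows, columns=["smallrna_id", "transcript_id", "start", "mismatches"]
    )

    # --- microRNAs with planted exact seed sites --------------------------
    rng_mi = cfg.rng(3)
    mirnas = SequenceSet({}, kind="smallRNA")
    mirna_rows = []
    n_seeded = int(round(cfg.n_mirnas * cfg.mirna_planted_fraction))
    for i in range(cfg.n_mirnas):
        mid = f"mir_{i:03d}"
        if i < n_seeded and tx_ids:
            tid = tx_ids[rng_mi.integers(0, n_tx)]
            tseq = transcripts[tid]
            p = int(rng_mi.integers(0, len(tseq) - 7 + 1))
            site = tseq[p : p + 7]
            # seed occupies miRNA positions 2-8 (1-based)
            seq = _random_seq(rng_mi, 1) + reverse_complement(site) + _random_seq(
                rng_mi, 13
            )
            mirna_rows.append({"mirna_id": mid, "transcript_id": tid})
        else:
            seq = _random_seq(rng_mi, 21)
        mirnas.add(mid, seq)
    planted_mirna_targets = pd.DataFrame(
        mirna_rows, columns=["mirna_id", "transcript_id"]
    )

    # --- lncRNAs with planted complementary blocks ------------------------
    rng_ln = cfg.rng(4)
    lncrnas = SequenceSet({}, kind="lncRNA")
    cmr_rows = []
    scrambled_ids: list[str] = []
    n_pos = int(round(cfg.n_lncrnas * cfg.cmr_positive_fraction))
    n_neg = int(round(cfg.n_lncrnas * cfg.cmr_negative_fraction))
    L = cfg.lncrna_length

    def noncoding_seq(length: int) -> str:
        # reject sequences the ORF-length stand-in would call coding, so
        # planted lncRNAs survive the filter by construction
        for _ in range(200):
            s = _random_seq(rng_ln, length)
            if longest_orf_codons(s) < cfg.max_orf_codons:
                return s
        raise RuntimeError("could not draw a noncoding sequence")

    def plant_block(cov: float) -> tuple[str, str, float]:
        tid = pool[rng_ln.integers(0, len(pool))]
        tseq = transcripts[tid]
        blen = int(round(cov * L))
        if blen > len(tseq):
            raise ValueError("planted block longer than transcript")
        for _ in range(200):
            base = _random_seq(rng_ln, L)
            tstart = int(rng_ln.integers(0, len(tseq) - blen + 1))
            lstart = int(rng_ln.integers(0, L - blen + 1))
            block = reverse_complement(tseq[tstart : tstart + blen])
            # up to 2 isolated interior mismatches, kept >= 25 bp apart and
            # >= 25 bp from the block ends so each stays locally supported
            n_mm = int(rng_ln.integers(0, 3))
            if n_mm and blen > 60:
                for _mm_try in range(50):
                    positions = np.sort(
                        rng_ln.choice(
                            np.arange(25, blen - 25), size=n_mm, replace=False
                        )
                    )
                    if n_mm == 1 or np.all(np.diff(positions) >= 25):
                        break
                else:
                    positions = positions[:1]
                block = _mutate(rng_ln, block, positions)
            seq = base[:lstart] + block + base[lstart + blen :]
            if longest_orf_codons(seq) < cfg.max_orf_codons:
                return seq, tid, blen / L
        raise RuntimeError("could not plant a noncoding CMR block")

    for i in range(cfg.n_lncrnas):
        lid = f"lnc_{i:04d}"
        if i < n_pos:
            cov = cfg.cmr_positive_coverages[i % len(cfg.cmr_positive_coverages)]
            seq, tid, true_cov = plant_block(cov)
            cmr_rows.append(
                {
                    "lncrna_id": lid,
                    "mrna_id": tid,
                    "coverage": true_cov,
                    "is_positive": True,
                }
            )
        elif i < n_pos + n_neg:
            cov = cfg.cmr_negative_coverages[i % len(cfg.cmr_negative_coverages)]
            seq, tid, true_cov = plant_block(cov)
            cmr_rows.append(
                {
                    "lncrna_id": lid,
                    "mrna_id": tid,
                    "coverage": true_cov,
                    "is_positive": False,
                }
            )
        else:
            seq = noncoding_seq(L)
        lncrnas.add(lid, seq)
    # scrambled decoys: positives with shuffled bases (same composition)
    for j in range(cfg.n_scrambled_decoys):
        src = f"lnc_{j % max(n_pos, 1):04d}" if n_pos else None
        if src is None:
            seq = noncoding_seq(L)
        else:
            arr = np.frombuffer(lncrnas[src].encode(), dtype=np.uint8).copy()
            rng_ln.shuffle(arr)
            seq = arr.tobytes().decode()
            if longest_orf_codons(seq) >= cfg.max_orf_codons:
                seq = noncoding_seq(L)
        sid = f"scr_{j:04d}"
        lncrnas.add(sid, seq)
        scrambled_ids.append(sid)
    planted_cmr = pd.DataFrame(
        cmr_rows, columns=["lncrna_id", "mrna_id", "coverage", "is_positive"]
    )

    # --- toy genome, ZGA gene models, planted saRNAs, lncRNA loci ---------
    rng_g = cfg.rng(5)
    W = cfg.promoter_window
    body = 1500
    block = W + body
    chrom = "chr1"
    zga_genes = [f"zga_{i:04d}" for i in range(cfg.n_zga_genes)]
    n_targeted = int(round(cfg.n_zga_genes * cfg.zga_targeted_fraction))
    sarna_targeted = zga_genes[:n_targeted]

    # expressed, length-eligible small RNAs are the saRNA source pool
    lo_s, hi_s = cfg.sarna_lengths
    eligible = [
        r
        for r in smallrnas
        if lo_s <= len(r.sequence) <= hi_s
        and (
            r.rpm_by_stage.get("zygote", 0.0) > 1.0
            or r.rpm_by_stage.get("2C", 0.0) > 1.0
        )
    ]
    band_lo, band_hi = cfg.sarna_band
    sarna_rows = []
    promoter_seqs: list[str] = []
    gene_models: list[GeneModel] = []
    for gi, gid in enumerate(zga_genes):
        wseq = list(_random_seq(rng_g, W))
        occupied: list[tuple[int, int]] = []
        if gid in sarna_targeted and eligible:
            for _ in range(int(rng_g.integers(1, 3))):
                rec = eligible[rng_g.integers(0, len(eligible))]
                k = len(rec.sequence)
                for _try in range(50):
                    if rng_g.random() < cfg.sarna_band_fraction:
                        off = int(rng_g.integers(band_lo, band_hi))
                    else:
                        # outside the band, inside the window
                        lo_choices = np.concatenate(
                            [
                                np.arange(1, band_lo),
                                np.arange(band_hi, W - k + 2),
                            ]
                        )
                        off = int(lo_choices[rng_g.integers(0, len(lo_choices))])
                    s = W - off - k + 1
                    if s < 0:
                        continue
                    if all(e <= s or s + k <= b for b, e in occupied):
                        occupied.append((s, s + k))
                        wseq[s : s + k] = list(rec.sequence)
                        sarna_rows.append(
                            {
                                "smallrna_id": rec.id,
                                "gene_id": gid,
                                "offset_upstream": off,
                            }
                        )
                        break
        promoter_seqs.append("".join(wseq))

    # assemble the chromosome: [promoter][body] per gene, all + strand
    chrom_parts = []
    for gi, gid in enumerate(zga_genes):
        bstart = gi * block
        chrom_parts.append(promoter_seqs[gi])
        chrom_parts.append(_random_seq(rng_g, body))
        span = (bstart + W, bstart + W + body)
        s0 = span[0]
        gene_models.append(
            GeneModel(
                gene_id=gid,
                chrom=chrom,
                strand="+",
                span=span,
                exons=[(s0, s0 + 400), (s0 + 900, s0 + 1500)],
                cds=[(s0 + 100, s0 + 400), (s0 + 900, s0 + 1200)],
            )
        )
    genome = SequenceSet({chrom: "".join(chrom_parts)}, kind="transcript")
    planted_sarna = pd.DataFrame(
        sarna_rows, columns=["smallrna_id", "gene_id", "offset_upstream"]
    )

    # lncRNA genomic loci with planted context fractions
    rng_lc = cfg.rng(6)
    lnc_ids = [f"lnc_{i:04d}" for i in range(cfg.n_lncrnas)]
    context_counts = {
        c: int(round(f * cfg.n_lncrnas)) for c, f in cfg.lnc_context_fractions.items()
    }
    # span-local placements inside a gene block guaranteeing each label
    local = {
        "intron": (W + 450, W + 450 + L),  # inside intron [400, 900)
        "coding_exon": (W + 100, W + 100 + L),  # inside CDS of exon 1
        "UTR_exon": (W + 1200, W + 1200 + L),  # exon 2 past the CDS end
        "intergenic": (100, 100 + L),  # inside the promoter region
    }
    lnc_loci: dict[str, tuple[str, int, int]] = {}
    context_rows = []
    li = 0
    for label, count in context_counts.items():
        a, b = local[label]
        for _ in range(count):
            if li >= len(lnc_ids):
                break
            gi = int(rng_lc.integers(0, cfg.n_zga_genes))
            bstart = gi * block
            lnc_loci[lnc_ids[li]] = (chrom, bstart + a, bstart + b)
            context_rows.append({"lncrna_id": lnc_ids[li], "context": label})
            li += 1
    planted_lnc_contexts = pd.DataFrame(
        context_rows, columns=["lncrna_id", "context"]
    )

    return SynthSequences(
        transcripts=transcripts,
        smallrnas=smallrnas,
        mirnas=mirnas,
        lncrnas=lncrnas,
        genome=genome,
        gene_models=gene_models,
        lnc_loci=lnc_loci,
        zga_genes=zga_genes,
        planted_targets=planted_targets,
        planted_mirna_targets=planted_mirna_targets,
        planted_cmr=planted_cmr,
        scrambled_ids=scrambled_ids,
        planted_lnc_contexts=planted_lnc_contexts,
        planted_sarna=planted_sarna,
        sarna_targeted_genes=sorted({r["gene_id"] for r in sarna_rows}),
    )


# ---------------------------------------------------------------------------
# Decay time courses
# ---------------------------------------------------------------------------


def gen_timecourses(
    cfg: SynthConfig,
) -> tuple[list[DecayTimecourse], pd.DataFrame]:
    """First-order decay courses per condition with log-normal noise.

    Conditions: control (k_control), mimic (faster decay) and inhibitor
    (slower decay); abundance is renormalized to 1 at t = 0 after noise,
    matching how measured courses are expressed relative to time zero.
    """
    rng = cfg.rng(7)
    t = np.asarray(cfg.timepoints)
    sigma = math.sqrt(math.log(1.0 + cfg.kinetics_cv**2)) if cfg.kinetics_cv else 0.0
    ks = {
        "control": cfg.k_control,
        "mimic": cfg.k_control * cfg.k_mimic_factor,
        "inhibitor": cfg.k_control * cfg.k_inhibitor_factor,
    }
    courses = []
    for cond, k in ks.items():
        if k <= 0:
            raise ValueError(f"decay constant for {cond!r} must be > 0")
        for rep in range(cfg.n_replicates):
            clean = np.exp(-k * t)
            noise = np.exp(rng.normal(0.0, sigma, size=t.size)) if sigma else 1.0
            y = clean * noise
            courses.append(
                DecayTimecourse(
                    gene_id=f"tc_{cond}_{rep:04d}",
                    condition=cond,
                    timepoints=t.tolist(),
                    relative_abundance=y.tolist() if sigma else clean.tolist(),
                    normalize=True,
                )
            )
    truth = pd.DataFrame(
        [{"condition": c, "k": k, "t_half": math.log(2) / k} for c, k in ks.items()]
    )
    return courses, truth


# ---------------------------------------------------------------------------
# Full simulated dataset on disk
# ---------------------------------------------------------------------------


def simulate_all(cfg: SynthConfig, outdir: str | os.PathLike) -> dict[str, str]:
    """Write a complete synthetic dataset + truth tables; returns paths."""
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    def p(name: str) -> str:
        paths[name.split(".")[0]] = os.path.join(str(outdir), name)
        return paths[name.split(".")[0]]

    ctrl, kd, drb, truth_expr = gen_expression(cfg)
    write_expression_table(ctrl, p("control.tsv"))
    write_expression_table(kd, p("knockdown.tsv"))
    write_expression_table(drb, p("drb.tsv"))
    write_tsv(truth_expr, p("truth_expression.tsv"))

    seqs = gen_sequences(cfg)
    write_fasta(seqs.transcripts, p("transcripts.fa"))
    write_smallrna_table(seqs.smallrnas, p("smallrnas.tsv"))
    write_fasta(seqs.mirnas, p("mirnas.fa"))
    write_fasta(seqs.lncrnas, p("lncrnas.fa"))
    write_fasta(seqs.genome, p("genome.fa"))
    write_gene_models_gff3(seqs.gene_models, p("genes.gff3"))
    with open(p("lnc_loci.bed"), "w") as fh:
        for lid, (chrom, a, b) in sorted(seqs.lnc_loci.items()):
            fh.write(f"{chrom}\t{a}\t{b}\t{lid}\t0\t+\n")
    write_tsv(pd.DataFrame({"gene_id": seqs.zga_genes}), p("zga_genes.tsv"))
    write_tsv(seqs.planted_targets, p("truth_targets.tsv"))
    write_tsv(seqs.planted_mirna_targets, p("truth_mirna_targets.tsv"))
    write_tsv(seqs.planted_cmr, p("truth_cmr.tsv"))
    write_tsv(seqs.planted_lnc_contexts, p("truth_lnc_contexts.tsv"))
    write_tsv(seqs.planted_sarna, p("truth_sarna.tsv"))

    courses, truth_k = gen_timecourses(cfg)
    rows = []
    for tc in courses:
        for t, y in zip(tc.timepoints, tc.relative_abundance):
            rows.append(
                {
                    "gene_id": tc.gene_id,
                    "condition": tc.condition,
                    "time_h": t,
                    "relative_abundance": y,
                }
            )
    write_tsv(pd.DataFrame(rows), p("timecourses.tsv"))
    write_tsv(truth_k, p("truth_kinetics.tsv"))
    return paths
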