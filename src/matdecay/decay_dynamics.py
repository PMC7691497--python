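"""Maternal mRNA definition, decay clustering and dependence assignment.

Maternal transcripts are genes with FPKM > 2 in MII oocytes. Their decay
across MII -> 2-cell -> 4-cell is classified on the log2(FPKM + 1) scale
with a single log2 margin delta (default 1):

* cluster I   — MII/2C degradation:  MII > 2C + delta and |2C - 4C| < delta
* cluster II  — 2C/4C degradation:   |MII - 2C| <= delta and 2C > 4C + delta
* cluster III — continuous:          MII > 2C + delta and 2C > 4C + delta

The three label conditions are mutually exclusive by construction: cluster I
forbids the 2C/4C drop that clusters II and III require on their shared leg,
and cluster II forbids the MII/2C drop that I and III require. (The sources
describing this scheme print a self-contradictory pair of inequalities for
cluster II; the rule above is the repair consistent with its verbal
definition — no MII/2C change, strong 4C down-regulation. See
docs/methods.md.)

AGO2-dependence of a degradation leg means the drop disappears in the
Ago2-knockdown series: expression at the knockdown endpoint is "increased
or stable" relative to the control start of the leg, operationalized as not
lower by more than delta log2 units. ZGA-dependence applies the same rule
to the DRB (transcription-blocked) series for the 2C/4C leg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import StageExpressionMatrix

__all__ = [
    "ClassificationParams",
    "DecayAssignment",
    "define_maternal",
    "classify_decay",
    "kd_dependence",
    "zga_dependence",
    "bound_fraction",
    "assignments_frame",
    "cluster_summary",
]

logger = logging.getLogger(__name__)

CLUSTERS = ("I", "II", "III", "none")


@dataclass(frozen=True)
class ClassificationParams:
    """Thresholds for maternal definition and decay clustering.

    maternal_fpkm_threshold : linear FPKM floor at MII (strict >)
    log_delta : the log2 margin delta used by every inequality
    pseudocount : added to FPKM before log2
    """

    maternal_fpkm_threshold: float = 2.0
    log_delta: float = 1.0
    pseudocount: float = 1.0
    mii_stage: str = "MII"
    two_cell_stage: str = "2C"
    four_cell_stage: str = "4C"

    def __post_init__(self):
        if self.maternal_fpkm_threshold <= 0:
            raise ValueError("maternal_fpkm_threshold must be > 0")
        if self.log_delta <= 0:
            raise ValueError("log_delta must be > 0")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


@dataclass
class DecayAssignment:
    """Per-gene decay cluster plus dependence flags.

    The AGO2 flags are only meaningful on the legs where the gene actually
    degrades (MII->2C for clusters I/III, 2C->4C for II/III); ZGA-dependence
    only for genes with a 2C/4C degradation leg.
    """

    gene_id: str
    cluster: str = "none"
    ago2_dependent_MII_2C: bool = False
    ago2_dependent_2C_4C: bool = False
    zga_dependent: bool = False
    unassessable: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.cluster not in CLUSTERS:
            raise ValueError(f"unknown cluster label {self.cluster!r}")


def define_maternal(
    matrix: StageExpressionMatrix, params: ClassificationParams = ClassificationParams()
) -> set[str]:
    """Genes with MII FPKM strictly above the maternal threshold."""
    matrix.require_stages([params.mii_stage])
    mii = matrix.values[params.mii_stage]
    return set(mii.index[mii > params.maternal_fpkm_threshold])


def classify_decay(
    matrix: StageExpressionMatrix,
    maternal_set: set[str] | None = None,
    params: ClassificationParams = ClassificationParams(),
) -> dict[str, DecayAssignment]:
    """Assign each maternal gene to decay cluster I, II, III or none."""
    stages = [params.mii_stage, params.two_cell_stage, params.four_cell_stage]
    matrix.require_stages(stages)
    if maternal_set is None:
        maternal_set = define_maternal(matrix, params)
    log = matrix.log2(params.pseudocount)
    d = params.log_delta
    out: dict[str, DecayAssignment] = {}
    mii, c2, c4 = (log[s] for s in stages)
    for gid in matrix.gene_ids:
        if gid not in maternal_set:
            continue
        a, b, c = mii[gid], c2[gid], c4[gid]
        drop_m2 = a > b + d
        drop_24 = b > c + d
        if drop_m2 and drop_24:
            cluster = "III"
        elif drop_m2 and abs(b - c) < d:
            cluster = "I"
        elif abs(a - b) <= d and drop_24:
            cluster = "II"
        else:
            cluster = "none"
        out[gid] = DecayAssignment(gene_id=gid, cluster=cluster)
    return out


def _stable_under(
    series_log: pd.Series, reference_log: pd.Series, gid: str, delta: float
) -> bool | None:
    """True if expression is increased-or-stable (drop <= delta log2 units).

    Returns None when the gene is missing from the perturbed series.
    """
    if gid not in series_log.index:
        return None
    return bool(series_log[gid] >= reference_log[gid] - delta)


def kd_dependence(
    ctrl: StageExpressionMatrix,
    kd: StageExpressionMatrix,
    assignments: dict[str, DecayAssignment],
    params: ClassificationParams = ClassificationParams(),
) -> dict[str, DecayAssignment]:
    """Flag AGO2-dependent degradation legs from the knockdown series.

    A cluster-I/III gene is ``ago2_dependent_MII_2C`` when its knockdown
    2-cell level is increased-or-stable relative to the control MII level;
    a cluster-II/III gene is ``ago2_dependent_2C_4C`` when its knockdown
    4-cell level is increased-or-stable relative to the control 2-cell
    level. Genes absent from the knockdown matrix are recorded as
    unassessable with a warning. Mutates and returns ``assignments``.
    """
    ctrl.require_stages([params.mii_stage, params.two_cell_stage])
    kd.require_stages([params.two_cell_stage, params.four_cell_stage])
    ctrl_log = ctrl.log2(params.pseudocount)
    kd_log = kd.log2(params.pseudocount)
    d = params.log_delta
    n_missing = 0
    for gid, asg in assignments.items():
        if asg.cluster in ("I", "III"):
            stable = _stable_under(
                kd_log[params.two_cell_stage], ctrl_log[params.mii_stage], gid, d
            )
            if stable is None:
                asg.unassessable.add("ago2_MII_2C")
                n_missing += 1
            else:
                asg.ago2_dependent_MII_2C = stable
        if asg.cluster in ("II", "III"):
            stable = _stable_under(
                kd_log[params.four_cell_stage], ctrl_log[params.two_cell_stage], gid, d
            )
            if stable is None:
                asg.unassessable.add("ago2_2C_4C")
                n_missing += 1
            else:
                asg.ago2_dependent_2C_4C = stable
    if n_missing:
        logger.warning(
            "%d degradation legs unassessable: gene absent from knockdown matrix",
            n_missing,
        )
    return assignments


def zga_dependence(
    drb: StageExpressionMatrix,
    ctrl: StageExpressionMatrix,
    assignments: dict[str, DecayAssignment],
    params: ClassificationParams = ClassificationParams(),
    drb_stage: str | None = None,
) -> dict[str, DecayAssignment]:
    """Flag ZGA-dependent 2C/4C degradation from the DRB series.

    ``drb`` supplies post-treatment expression at the 4-cell-equivalent
    stage (``drb_stage``, defaulting to the 4C stage name, or the single
    stage of a one-column matrix). A cluster-II gene, or cluster-III gene
    on its 2C->4C leg, is ``zga_dependent`` when DRB expression is
    increased-or-stable relative to the control 2-cell level.
    """
    ctrl.require_stages([params.two_cell_stage])
    if drb_stage is None:
        drb_stage = (
            params.four_cell_stage
            if params.four_cell_stage in drb.stage_names
            else drb.stage_names[-1]
        )
    drb.require_stages([drb_stage])
    ctrl_log = ctrl.log2(params.pseudocount)
    drb_log = drb.log2(params.pseudocount)
    d = params.log_delta
    n_missing = 0
    for gid, asg in assignments.items():
        if asg.cluster not in ("II", "III"):
            continue
        stable = _stable_under(
            drb_log[drb_stage], ctrl_log[params.two_cell_stage], gid, d
        )
        if stable is None:
            asg.unassessable.add("zga")
            n_missing += 1
        else:
            asg.zga_dependent = stable
    if n_missing:
        logger.warning(
            "%d genes unassessable for ZGA-dependence: absent from DRB matrix",
            n_missing,
        )
    return assignments


def bound_fraction(target_smallrna_ids: set[str], rip_bound_ids: set[str]) -> float:
    """Fraction of targeting small RNAs recovered in a RIP-bound set."""
    if not target_smallrna_ids:
        raise ValueError("empty target small-RNA set")
    return len(target_smallrna_ids & rip_bound_ids) / len(target_smallrna_ids)


def assignments_frame(assignments: dict[str, DecayAssignment]) -> pd.DataFrame:
    """Tabular view of assignments for TSV export."""
    rows = [
        {
            "gene_id": a.gene_id,
            "cluster": a.cluster,
            "ago2_dependent_MII_2C": a.ago2_dependent_MII_2C,
            "ago2_dependent_2C_4C": a.ago2_dependent_2C_4C,
            "zga_dependent": a.zga_dependent,
        }
        for a in assignments.values()
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "cluster",
            "ago2_dependent_MII_2C",
            "ago2_dependent_2C_4C",
            "zga_dependent",
        ],
    ).sort_values("gene_id", ignore_index=True)


def cluster_summary(assignments: dict[str, DecayAssignment]) -> pd.DataFrame:
    """Cluster sizes and dependence/overlap counts (the headline sets)."""
    vals = list(assignments.values())
    zga = {a.gene_id for a in vals if a.zga_dependent}
    ago_24 = {a.gene_id for a in vals if a.ago2_dependent_2C_4C}
    rows = [
        ("n_genes", len(vals)),
        *((f"cluster_{c}", sum(a.cluster == c for a in vals)) for c in CLUSTERS),
        ("ago2_dependent_MII_2C", sum(a.ago2_dependent_MII_2C for a in vals)),
        ("ago2_dependent_2C_4C", len(ago_24)),
        ("zga_dependent", len(zga)),
        ("zga_and_ago2_2C_4C", len(zga & ago_24)),
    ]
    return pd.DataFrame(rows, columns=["quantity", "count"])
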