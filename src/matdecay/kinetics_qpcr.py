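"""Relative qPCR quantification (2^-ddCt) and first-order decay kinetics.

Relative expression follows the comparative-Ct method: dCt is the target
Ct minus the arithmetic mean of the reference-gene Cts (18S/5S rRNA in the
assays this models; averaging Cts equals a geometric mean of linear
quantities), ddCt subtracts the calibrator sample's dCt, and the fold
change is 2^-ddCt.

Decay time courses record relative abundance after transcription block
(actinomycin D at t = 0 h, abundance normalized to 1 at t = 0) and are fit
to first-order decay N(t) = N0 * exp(-k t) by least squares on the log
scale, giving a closed-form fit; the half-life is T1/2 = ln 2 / k. A
nonlinear linear-scale fit is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "QpcrMeasurement",
    "DecayTimecourse",
    "HalfLifeEstimate",
    "ddct",
    "delta_ct",
    "fit_decay",
    "compare_halflives",
]


@dataclass
class QpcrMeasurement:
    """One qPCR well: target Ct plus >= 1 reference-gene Cts."""

    sample_id: str
    group: str
    target_ct: float
    reference_cts: list[float] = field(default_factory=list)

    def __post_init__(self):
        if not self.reference_cts:
            raise ValueError("at least one reference Ct is required")
        for ct in [self.target_ct, *self.reference_cts]:
            if not math.isfinite(ct):
                raise ValueError(f"non-finite Ct value {ct!r}")
            if not (0 < ct < 50):
                raise ValueError(f"Ct value {ct} outside plausible (0, 50)")


def delta_ct(measurement: QpcrMeasurement) -> float:
    """dCt = target Ct - mean(reference Cts)."""
    return measurement.target_ct - float(np.mean(measurement.reference_cts))


def ddct(measurement: QpcrMeasurement, calibrator_delta_ct: float) -> float:
    """Relative expression 2^-(dCt - calibrator dCt)."""
    if not math.isfinite(calibrator_delta_ct):
        raise ValueError("non-finite calibrator dCt")
    return 2.0 ** -(delta_ct(measurement) - calibrator_delta_ct)


@dataclass
class DecayTimecourse:
    """Relative abundance over hours after transcription block.

    Timepoints must be strictly increasing with the first at 0 h;
    abundances are positive and normalized so abundance(0) = 1 (pass
    ``normalize=True`` to apply the normalization on construction).
    """

    gene_id: str
    condition: str
    timepoints: list[float]
    relative_abundance: list[float]
    normalize: bool = False

    def __post_init__(self):
        t = np.asarray(self.timepoints, dtype=float)
        y = np.asarray(self.relative_abundance, dtype=float)
        if t.size != y.size:
            raise ValueError("timepoints and abundances differ in length")
        if t.size == 0 or t[0] != 0:
            raise ValueError("first timepoint must be 0 h")
        if not np.all(np.diff(t) > 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(y <= 0) or not np.all(np.isfinite(y)):
            raise ValueError("abundances must be positive and finite")
        if self.normalize:
            y = y / y[0]
        elif not math.isclose(y[0], 1.0, rel_tol=1e-9):
            raise ValueError("abundance at t=0 must be 1 (or pass normalize=True)")
        self.timepoints = t.tolist()
        self.relative_abundance = y.tolist()


@dataclass
class HalfLifeEstimate:
    """First-order decay fit: rate constant k (/h), T1/2 = ln2/k, R^2."""

    k: float
    r_squared: float
    n0: float = 1.0
    flagged_no_decay: bool = False

    @property
    def t_half(self) -> float:
        if self.k <= 0:
            return math.inf
        return math.log(2) / self.k

    def __post_init__(self):
        if not (0.0 <= self.r_squared <= 1.0 or math.isnan(self.r_squared)):
            raise ValueError(f"R^2 {self.r_squared} outside [0, 1]")


def fit_decay(tc: DecayTimecourse, nonlinear: bool = False) -> HalfLifeEstimate:
    """Fit N(t) = N0 * exp(-k t).

    Default: ordinary least squares of ln(abundance) on time (closed form,
    exact on noiseless exponentials). ``nonlinear=True`` refines by
    linear-scale nonlinear least squares initialized at the log-fit.
    Non-decaying fits (k <= 0) report an infinite half-life, flagged.
    """
    t = np.asarray(tc.timepoints)
    y = np.asarray(tc.relative_abundance)
    if t.size < 3:
        raise ValueError("at least 3 timepoints required for a decay fit")
    ln_y = np.log(y)
    if np.allclose(ln_y, ln_y[0]):
        # constant course: k = 0 fits exactly
        return HalfLifeEstimate(k=0.0, r_squared=1.0, n0=float(y[0]),
                                flagged_no_decay=True)
    res = stats.linregress(t, ln_y)
    k = -res.slope
    n0 = float(np.exp(res.intercept))
    r2 = float(res.rvalue**2)
    if nonlinear:
        def model(tt, n0_, k_):
            return n0_ * np.exp(-k_ * tt)

        (n0, k), _ = optimize.curve_fit(model, t, y, p0=[n0, k], maxfev=10000)
        resid = y - model(t, n0, k)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        r2 = min(max(r2, 0.0), 1.0)
    return HalfLifeEstimate(
        k=float(k), r_squared=r2, n0=float(n0), flagged_no_decay=k <= 0
    )


def compare_halflives(
    est_a: HalfLifeEstimate, est_b: HalfLifeEstimate
) -> tuple[float, int]:
    """Half-life ratio a/b and stability ordering.

    Returns (ratio, order) with order -1 when a is less stable (shorter
    T1/2), +1 when more stable, 0 on ties. Infinite half-life counts as
    most stable; the ratio of two infinite half-lives is 1.
    """
    ta, tb = est_a.t_half, est_b.t_half
    if math.isinf(ta) and math.isinf(tb):
        ratio = 1.0
    elif math.isinf(tb):
        ratio = 0.0
    else:
        ratio = ta / tb
    order = -1 if ta < tb else (1 if ta > tb else 0)
    return ratio, order
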