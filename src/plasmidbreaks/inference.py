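"""Poisson inversion of plasmid conformation fractions into break yields.

Under the Poisson damage model, each plasmid accumulates single-strand
breaks (SSB) and double-strand breaks (DSB) as independent Poisson counts.
A plasmid with at least one DSB runs as linear (L); one with no DSB but at
least one SSB as open circular (OC); an untouched plasmid stays supercoiled
(SC).  Writing X_SSB and X_DSB for the per-plasmid means,

    F_L  = 1 - exp(-X_DSB)
    F_SC = exp(-(X_SSB + X_DSB))

which inverts to the two estimators implemented here:

    X_SSB = ln((1 - F_L) / F_SC)                     (exact)
    X_DSB = F_L / (1 - F_L)                          (first-order)

The X_DSB estimator is the first-order expansion of the exact inverse
-ln(1 - F_L); both are provided, the first-order form is the primary
estimator and the exact form is never silently substituted.  Dividing a
per-plasmid mean X by the number of decays each plasmid experienced, d,
gives the headline damage metric Y = X/d, breaks per plasmid per decay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .densitometry import FractionTriple

__all__ = [
    "NonDetectable",
    "BreakEstimate",
    "ReplicateSummary",
    "DmsoDecomposition",
    "ssb_mean",
    "dsb_mean",
    "exact_poisson_dsb",
    "yields",
    "detection_bound_yield",
    "replicate_summary",
    "dmso_decomposition",
    "estimate_breaks",
]


class NonDetectable:
    """Marker for an estimate that cannot be formed (e.g. SC band absent).

    Propagates through arithmetic-free code paths as a sentinel; it is never
    a number and never infinity.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NonDetectable"

    def __bool__(self) -> bool:
        return False


NON_DETECTABLE = NonDetectable()


@dataclass(frozen=True)
class BreakEstimate:
    """Per-plasmid break means and per-decay yields for one sample.

    ``x_ssb``/``y_ssb`` are ``None`` when the SC band was non-detectable
    (``ssb_nondetectable`` set).  When the L band is censored, ``x_dsb`` and
    ``y_dsb`` are zero point estimates and ``dsb_upper_bound`` carries the
    yield bound implied by the detection limit.
    """

    x_ssb: float | None
    x_dsb: float
    y_ssb: float | None = None
    y_dsb: float | None = None
    ssb_nondetectable: bool = False
    dsb_censored: bool = False
    dsb_upper_bound: float | None = None

    def __post_init__(self) -> None:
        for name in ("x_ssb", "x_dsb", "y_ssb", "y_dsb"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v!r}")


def ssb_mean(f: FractionTriple) -> float | NonDetectable:
    """Mean SSB per plasmid, ``ln((1 - F_L)/F_SC)``.

    Returns the :data:`NON_DETECTABLE` marker when the supercoiled band is
    absent or censored — the logarithm has no finite value and the assay
    carries no SSB information beyond "saturated".
    """
    eff = f.effective()
    if f.censored_sc or eff.f_sc == 0.0:
        return NON_DETECTABLE
    if eff.f_l >= 1.0:
        raise ValueError("F_L must be < 1 to estimate SSB")
    return math.log((1.0 - eff.f_l) / eff.f_sc)


def dsb_mean(f: FractionTriple) -> float:
    """Mean DSB per plasmid, ``F_L / (1 - F_L)`` (first-order estimator).

    A censored linear band gives a zero point estimate; the corresponding
    upper bound is available via :func:`detection_bound_yield`.
    """
    eff = f.effective()
    if eff.f_l >= 1.0:
        raise ValueError("F_L must be < 1 to estimate DSB")
    return eff.f_l / (1.0 - eff.f_l)


def exact_poisson_dsb(f: FractionTriple) -> float:
    """Exact Poisson inverse ``-ln(1 - F_L)``; always <= :func:`dsb_mean`."""
    eff = f.effective()
    if eff.f_l >= 1.0:
        raise ValueError("F_L must be < 1 to estimate DSB")
    return -math.log1p(-eff.f_l)


def yields(
    x: BreakEstimate,
    d: float,
    n_plasmid: float | None = None,
    total_decays: float | None = None,
    rtol: float = 1e-6,
) -> BreakEstimate:
    """Convert per-plasmid break means into per-decay yields, Y = X/d.

    When *n_plasmid* and *total_decays* are given they must satisfy
    ``d = total_decays / n_plasmid`` (within *rtol*); the equivalent route
    ``X * n_plasmid / total_decays`` is then computed as well and checked
    against the direct one to 1e-12 relative.
    """
    if not d > 0:
        raise ValueError(f"decays per plasmid must be positive, got {d!r}")
    if (n_plasmid is None) != (total_decays is None):
        raise ValueError("n_plasmid and total_decays must be given together")
    if n_plasmid is not None:
        implied = total_decays / n_plasmid
        if abs(implied - d) > rtol * d:
            raise ValueError(
                f"inconsistent normalisation: d={d} but total_decays/n_plasmid={implied}"
            )

    def _per_decay(val: float) -> float:
        direct = val / d
        if n_plasmid is not None:
            alt = val * n_plasmid / total_decays
            if abs(alt - direct) > 1e-12 * max(direct, 1.0):
                raise AssertionError("yield route mismatch beyond 1e-12")
        return direct

    return BreakEstimate(
        x_ssb=x.x_ssb,
        x_dsb=x.x_dsb,
        y_ssb=None if x.x_ssb is None else _per_decay(x.x_ssb),
        y_dsb=_per_decay(x.x_dsb),
        ssb_nondetectable=x.ssb_nondetectable,
        dsb_censored=x.dsb_censored,
        dsb_upper_bound=None if x.dsb_upper_bound is None else _per_decay(x.dsb_upper_bound),
    )


def detection_bound_yield(detection_limit: float, d: float) -> float:
    """Yield bound implied by an undetected linear band.

    Evaluates the first-order DSB estimator at the detection limit and
    divides by decays per plasmid: ``(limit/(1-limit))/d``.
    """
    if not (0.0 < detection_limit < 1.0):
        raise ValueError(f"detection_limit must lie in (0, 1), got {detection_limit!r}")
    if not d > 0:
        raise ValueError(f"decays per plasmid must be positive, got {d!r}")
    return (detection_limit / (1.0 - detection_limit)) / d


def estimate_breaks(
    f: FractionTriple, d: float | None = None
) -> BreakEstimate:
    """Full inversion of one fraction triple: X estimates, optional yields.

    Censoring and non-detectability flags on the triple propagate into the
    estimate; when *d* is given, per-decay yields and (for a censored linear
    band) the detection-limit yield bound are filled in.
    """
    x_ssb = ssb_mean(f)
    nondet = isinstance(x_ssb, NonDetectable)
    est = BreakEstimate(
        x_ssb=None if nondet else x_ssb,
        x_dsb=dsb_mean(f),
        ssb_nondetectable=nondet,
        dsb_censored=f.censored_l,
        dsb_upper_bound=(
            f.detection_limit / (1.0 - f.detection_limit) if f.censored_l else None
        ),
    )
    if d is not None:
        est = yields(est, d)
    return est


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean and sample SD (n-1 denominator) over replicate trials.

    ``n_excluded`` counts non-detectable trials removed before averaging;
    an all-excluded group yields a non-detectable summary (mean is None).
    """

    mean: float | None
    sd: float | None
    n: int
    n_excluded: int = 0

    @property
    def nondetectable(self) -> bool:
        return self.mean is None


def replicate_summary(values: Iterable[float | None | NonDetectable]) -> ReplicateSummary:
    """Summarise replicate estimates, excluding non-detectable entries."""
    vals = list(values)
    kept = [float(v) for v in vals if v is not None and not isinstance(v, NonDetectable)]
    n_excluded = len(vals) - len(kept)
    if not kept:
        return ReplicateSummary(mean=None, sd=None, n=0, n_excluded=n_excluded)
    n = len(kept)
    mean = sum(kept) / n
    if n == 1:
        sd = 0.0
    else:
        sd = math.sqrt(sum((v - mean) ** 2 for v in kept) / (n - 1))
    return ReplicateSummary(mean=mean, sd=sd, n=n, n_excluded=n_excluded)


@dataclass(frozen=True)
class DmsoDecomposition:
    """Split of a damage yield into direct and radical-mediated components.

    Incubation with the radical scavenger DMSO suppresses indirect damage by
    hydroxyl radicals from water radiolysis; the yield that survives DMSO is
    the direct component, the difference is the scavengeable indirect one.
    """

    y_direct: float
    y_indirect: float
    percent_reduction: float | None
    undefined: bool = False

    def __post_init__(self) -> None:
        if self.percent_reduction is not None and not (
            0.0 <= self.percent_reduction <= 100.0
        ):
            raise ValueError("percent_reduction must lie in [0, 100]")


def dmso_decomposition(y_minus: float, y_plus: float) -> DmsoDecomposition:
    """Decompose yields measured without (*y_minus*) and with (*y_plus*) DMSO.

    ``percent_reduction = 100 * (1 - y_plus/y_minus)`` floored at zero (a
    nominal increase under scavenging is sampling noise, not negative
    protection).  A zero baseline leaves the reduction undefined.
    """
    if y_minus < 0 or y_plus < 0:
        raise ValueError("yields must be >= 0")
    if y_minus == 0:
        return DmsoDecomposition(
            y_direct=y_plus, y_indirect=0.0, percent_reduction=None, undefined=True
        )
    reduction = max(0.0, 100.0 * (1.0 - y_plus / y_minus))
    return DmsoDecomposition(
        y_direct=y_plus,
        y_indirect=max(y_minus - y_plus, 0.0),
        percent_reduction=reduction,
    )
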