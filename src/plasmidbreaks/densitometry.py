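"""Lane densitometry: SC/OC/L fractions from 1-D gel intensity profiles.

A stained agarose gel separates the three conformations of a circular
plasmid — supercoiled (SC, intact), open circular (OC, at least one
single-strand break) and linear (L, at least one double-strand break) — into
three bands per lane.  This module turns a 1-D intensity trace along the
migration axis into the fraction of plasmid in each conformation: subtract a
background, integrate each band window, and normalise the three areas to sum
to one.  Bands whose normalised fraction falls below the detection limit are
flagged as censored rather than reported as point values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "CONFORMATIONS",
    "LaneProfile",
    "BandWindow",
    "FractionTriple",
    "subtract_background",
    "integrate_bands",
    "normalize_fractions",
    "quantify_lane",
]

#: Canonical conformation labels, in the default migration order (OC runs
#: slowest and sits at the top of the lane, SC fastest at the bottom).
CONFORMATIONS = ("OC", "L", "SC")

#: Fraction below which a band is reported as "< limit" rather than a value.
DEFAULT_DETECTION_LIMIT = 0.01


@dataclass
class LaneProfile:
    """A 1-D intensity trace along the migration axis of one gel lane."""

    positions: np.ndarray
    intensities: np.ndarray
    lane_id: str = ""
    background_method: str | None = None  # provenance of background removal

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.ndim != 1 or self.positions.size == 0:
            raise ValueError("positions must be a non-empty 1-D array")
        if self.positions.shape != self.intensities.shape:
            raise ValueError("positions and intensities must have equal length")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return self.positions.size


@dataclass(frozen=True)
class BandWindow:
    """Half-open position window ``[start, end)`` holding one conformation's band."""

    conformation: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.conformation not in CONFORMATIONS:
            raise ValueError(
                f"conformation must be one of {CONFORMATIONS}, got {self.conformation!r}"
            )
        if not self.start < self.end:
            raise ValueError(f"window start must precede end, got [{self.start}, {self.end})")

    def overlaps(self, other: "BandWindow") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class FractionTriple:
    """Fractions of supercoiled, open-circular and linear plasmid in one sample.

    Fractions are normalised to sum to one.  ``censored_l`` / ``censored_sc``
    mark bands below ``detection_limit``; a censored band is reported
    downstream as an upper bound ("< limit"), with its point estimate taken
    as zero and the remaining fractions renormalised.
    """

    f_sc: float
    f_oc: float
    f_l: float
    censored_l: bool = False
    censored_sc: bool = False
    detection_limit: float = DEFAULT_DETECTION_LIMIT

    def __post_init__(self) -> None:
        total = self.f_sc + self.f_oc + self.f_l
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total!r}")
        for name in ("f_sc", "f_oc", "f_l"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if not (0.0 < self.detection_limit < 1.0):
            raise ValueError("detection_limit must lie in (0, 1)")

    @classmethod
    def from_raw(
        cls,
        f_sc: float,
        f_oc: float,
        f_l: float,
        detection_limit: float = DEFAULT_DETECTION_LIMIT,
        **flags,
    ) -> "FractionTriple":
        """Build from possibly unnormalised non-negative values."""
        total = f_sc + f_oc + f_l
        if total <= 0:
            raise ValueError("at least one fraction must be positive")
        return cls(
            f_sc / total, f_oc / total, f_l / total,
            detection_limit=detection_limit, **flags,
        )

    def effective(self) -> "FractionTriple":
        """Point-estimate view: censored bands at zero, renormalised."""
        f_sc, f_oc, f_l = self.f_sc, self.f_oc, self.f_l
        if self.censored_l:
            f_l = 0.0
        if self.censored_sc:
            f_sc = 0.0
        return FractionTriple.from_raw(
            f_sc, f_oc, f_l,
            detection_limit=self.detection_limit,
            censored_l=self.censored_l, censored_sc=self.censored_sc,
        )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.f_sc, self.f_oc, self.f_l)


def subtract_background(profile: LaneProfile, method: str = "constant-minimum") -> LaneProfile:
    """Remove background from a lane profile.

    ``constant-minimum`` subtracts the profile minimum; ``linear-baseline``
    subtracts the straight line through the mean intensity of the first and
    last few samples (5% of the trace at each end).  Output intensities are
    clipped at zero and the method is recorded on the returned profile.
    """
    if method == "constant-minimum":
        baseline = np.full(len(profile), profile.intensities.min())
    elif method == "linear-baseline":
        k = max(1, len(profile) // 20)
        x0 = profile.positions[:k].mean()
        x1 = profile.positions[-k:].mean()
        y0 = profile.intensities[:k].mean()
        y1 = profile.intensities[-k:].mean()
        slope = (y1 - y0) / (x1 - x0) if x1 != x0 else 0.0
        baseline = y0 + slope * (profile.positions - x0)
    else:
        raise ValueError(f"unknown background method {method!r}")
    corrected = np.clip(profile.intensities - baseline, 0.0, None)
    return LaneProfile(
        positions=profile.positions.copy(),
        intensities=corrected,
        lane_id=profile.lane_id,
        background_method=method,
    )


def _check_windows(windows: Iterable[BandWindow], profile: LaneProfile) -> list[BandWindow]:
    windows = list(windows)
    lo, hi = profile.positions[0], profile.positions[-1]
    for w in windows:
        if w.start < lo or w.end > hi + 1e-12:
            raise ValueError(
                f"window {w.conformation} [{w.start}, {w.end}) lies outside the "
                f"profile range [{lo}, {hi}]"
            )
    for i, a in enumerate(windows):
        for b in windows[i + 1:]:
            if a.overlaps(b):
                raise ValueError(
                    f"band windows {a.conformation} and {b.conformation} overlap"
                )
    return windows


def integrate_bands(
    profile: LaneProfile, windows: Iterable[BandWindow]
) -> dict[str, float]:
    """Trapezoidal integral of intensity over each band window.

    Windows are half-open ``[start, end)`` so a shared edge belongs to the
    downstream window only.  Windows must be pairwise disjoint and inside
    the profile's position range.
    """
    windows = _check_windows(windows, profile)
    areas: dict[str, float] = {}
    for w in windows:
        mask = (profile.positions >= w.start) & (profile.positions < w.end)
        if mask.sum() < 2:
            areas[w.conformation] = 0.0
            continue
        areas[w.conformation] = float(
            np.trapezoid(profile.intensities[mask], profile.positions[mask])
        )
    return areas


def normalize_fractions(
    intensities: Mapping[str, float],
    detection_limit: float = DEFAULT_DETECTION_LIMIT,
) -> FractionTriple:
    """Normalise per-conformation band intensities so SC+OC+L = 1.

    The lane total is taken as the whole signal, so the three fractions sum
    to one by construction.  A conformation whose fraction falls below
    *detection_limit* is flagged censored; SC and L carry flags (OC censoring
    never occurs in practice because the OC band is the damage readout).
    """
    vals = {c: float(intensities.get(c, 0.0)) for c in CONFORMATIONS}
    if any(v < 0 for v in vals.values()):
        raise ValueError("band intensities must be non-negative")
    total = sum(vals.values())
    if total <= 0:
        raise ValueError("all band intensities are zero; lane has no signal")
    f = {c: v / total for c, v in vals.items()}
    return FractionTriple(
        f_sc=f["SC"],
        f_oc=f["OC"],
        f_l=f["L"],
        censored_l=f["L"] < detection_limit,
        censored_sc=f["SC"] < detection_limit,
        detection_limit=detection_limit,
    )


def quantify_lane(
    profile: LaneProfile,
    windows: Iterable[BandWindow],
    background: str = "constant-minimum",
    detection_limit: float = DEFAULT_DETECTION_LIMIT,
) -> FractionTriple:
    """Background-subtract, integrate and normalise one lane in one call."""
    corrected = subtract_background(profile, background)
    return normalize_fractions(integrate_bands(corrected, windows), detection_limit)
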