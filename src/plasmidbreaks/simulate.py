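"""Forward simulation of the plasmid nicking assay.

Generates synthetic data with exactly the statistical structure the Poisson
inversion assumes: per-plasmid Poisson SSB/DSB counts at given per-decay
yields, conformation classification (any DSB -> linear; else any SSB -> open
circular; else supercoiled), multinomial sampling noise on observed
fractions, activity series in which the decays-per-plasmid normalisation
scales with cumulative decays, and gel lanes rendered as Gaussian bands on
a noisy baseline in the standard OC < L < SC migration order.

Randomness is seeded through ``numpy.random.SeedSequence``: one root seed
spawns one child stream per replicate, so replicate sets are reproducible
and statistically independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decay import IncubationSetup, decays_per_plasmid
from .densitometry import BandWindow, FractionTriple, LaneProfile

__all__ = [
    "SimulationConfig",
    "GelRenderConfig",
    "ConformationCounts",
    "analytic_fractions",
    "simulate_conformations",
    "sample_observed_fractions",
    "activity_series",
    "render_lane",
    "simulate_replicates",
]

#: Default simulated plasmid count per sample: the assay's 6.88e10 molecules
#: scaled by 1e-6, giving ~0.2% sampling error per fraction.
DEFAULT_N_PLASMIDS = 68_800


@dataclass(frozen=True)
class SimulationConfig:
    """True yields and sampling sizes for one simulated experiment."""

    y_ssb_true: float
    y_dsb_true: float
    decays_per_plasmid: float = 6.37
    n_plasmids: int = DEFAULT_N_PLASMIDS
    n_replicates: int = 3
    detection_limit: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.y_ssb_true < 0 or self.y_dsb_true < 0:
            raise ValueError("true yields must be >= 0")
        if not self.decays_per_plasmid >= 0:
            raise ValueError("decays_per_plasmid must be >= 0")
        if self.n_plasmids < 1:
            raise ValueError("n_plasmids must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def replicate_rngs(self) -> list[np.random.Generator]:
        """One child generator per replicate, derived from the root seed."""
        root = np.random.SeedSequence(self.seed)
        return [np.random.default_rng(s) for s in root.spawn(self.n_replicates)]


@dataclass(frozen=True)
class GelRenderConfig:
    """Geometry and noise of a rendered synthetic gel lane.

    Band centers follow the default migration order OC < L < SC (open
    circular runs slowest).  ``amplitude`` is the peak height of a band
    holding the whole lane signal; band area scales with the conformation's
    fraction.
    """

    centers: dict = field(
        default_factory=lambda: {"OC": 30.0, "L": 55.0, "SC": 80.0}
    )
    widths: dict = field(default_factory=lambda: {"OC": 2.5, "L": 2.5, "SC": 2.5})
    amplitude: float = 1000.0
    baseline: float = 50.0
    noise_sd: float = 0.0
    n_points: int = 512
    x_min: float = 0.0
    x_max: float = 100.0
    window_half_width_sigmas: float = 4.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_points < 8:
            raise ValueError("n_points must be >= 8")
        self.band_windows()  # validates disjointness

    def band_windows(self) -> list[BandWindow]:
        """Integration windows at +/- a few sigma around each band center."""
        windows = [
            BandWindow(
                conformation=c,
                start=self.centers[c] - self.window_half_width_sigmas * self.widths[c],
                end=self.centers[c] + self.window_half_width_sigmas * self.widths[c],
            )
            for c in ("OC", "L", "SC")
        ]
        for i, a in enumerate(windows):
            for b in windows[i + 1:]:
                if a.overlaps(b):
                    raise ValueError(
                        f"band windows {a.conformation} and {b.conformation} overlap; "
                        "move centers apart or narrow the bands"
                    )
        return windows


def analytic_fractions(
    x_ssb: float, x_dsb: float, detection_limit: float = 0.01
) -> FractionTriple:
    """Exact conformation fractions under the Poisson damage model.

    ``F_L = 1 - exp(-X_DSB)``; ``F_SC = exp(-(X_SSB + X_DSB))``; OC is the
    remainder.  This is the forward map the fraction-to-break estimators
    invert.
    """
    if x_ssb < 0 or x_dsb < 0:
        raise ValueError("break means must be >= 0")
    f_l = -math.expm1(-x_dsb)
    f_sc = math.exp(-(x_ssb + x_dsb))
    f_oc = max(0.0, 1.0 - f_l - f_sc)
    return FractionTriple.from_raw(f_sc, f_oc, f_l, detection_limit=detection_limit)


@dataclass(frozen=True)
class ConformationCounts:
    """Classified plasmid counts from one simulated sample.

    ``n_multi_dsb`` counts plasmids with two or more DSB: the assay reads
    them as a single linear molecule, so the approximation is inspectable.
    """

    n_sc: int
    n_oc: int
    n_l: int
    n_multi_dsb: int = 0

    @property
    def n_total(self) -> int:
        return self.n_sc + self.n_oc + self.n_l

    def fractions(self, detection_limit: float = 0.01) -> FractionTriple:
        return FractionTriple.from_raw(
            self.n_sc, self.n_oc, self.n_l, detection_limit=detection_limit
        )


def simulate_conformations(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> ConformationCounts:
    """Draw per-plasmid Poisson break counts and classify conformations.

    Each plasmid draws ``n_dsb ~ Poisson(Y_DSB * d)`` and
    ``n_ssb ~ Poisson(Y_SSB * d)`` independently; it is linear if it has at
    least one DSB, else open circular if at least one SSB, else supercoiled.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    d = config.decays_per_plasmid
    n = config.n_plasmids
    n_dsb = rng.poisson(config.y_dsb_true * d, size=n)
    n_ssb = rng.poisson(config.y_ssb_true * d, size=n)
    is_l = n_dsb >= 1
    is_oc = ~is_l & (n_ssb >= 1)
    n_l = int(is_l.sum())
    n_oc = int(is_oc.sum())
    return ConformationCounts(
        n_sc=n - n_l - n_oc,
        n_oc=n_oc,
        n_l=n_l,
        n_multi_dsb=int((n_dsb >= 2).sum()),
    )


def sample_observed_fractions(
    f: FractionTriple, n_observed: int, rng: np.random.Generator | int | None = None
) -> FractionTriple:
    """Multinomial measurement noise: observe *n_observed* plasmids from *f*."""
    if n_observed < 1:
        raise ValueError("n_observed must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    counts = rng.multinomial(n_observed, [f.f_sc, f.f_oc, f.f_l])
    return FractionTriple.from_raw(
        counts[0], counts[1], counts[2], detection_limit=f.detection_limit
    )


def simulate_replicates(config: SimulationConfig) -> pd.DataFrame:
    """Simulate ``n_replicates`` independent samples; one fraction row each.

    Returns the shared fraction-table schema (columns ``replicate``,
    ``F_SC``, ``F_OC``, ``F_L``, ``censored_L``, ``censored_SC``) plus the
    multi-DSB diagnostic count.
    """
    rows = []
    for i, rng in enumerate(config.replicate_rngs(), start=1):
        counts = simulate_conformations(config, rng)
        f = counts.fractions(config.detection_limit)
        rows.append(
            {
                "replicate": i,
                "F_SC": f.f_sc,
                "F_OC": f.f_oc,
                "F_L": f.f_l,
                "censored_L": f.f_l < config.detection_limit,
                "censored_SC": f.f_sc < config.detection_limit,
                "n_plasmids": counts.n_total,
                "n_multi_dsb": counts.n_multi_dsb,
            }
        )
    return pd.DataFrame(rows)


def activity_series(
    activities_mbq: list[float],
    setup: IncubationSetup,
    y_ssb: float,
    y_dsb: float,
) -> pd.DataFrame:
    """Analytic conformation fractions across an activity series.

    For each activity the decays-per-plasmid normalisation is recomputed
    from cumulative decays (linear in activity at fixed duration), the break
    means are ``X = Y * d`` and the fractions follow the Poisson forward
    map.  The supercoiled fraction is strictly decreasing in activity
    whenever either yield is positive.
    """
    if any(a <= 0 for a in activities_mbq):
        raise ValueError("activities must be positive")
    if y_ssb < 0 or y_dsb < 0:
        raise ValueError("yields must be >= 0")
    rows = []
    for a in activities_mbq:
        res = setup.with_activity(a).decay_result()
        d = res.decays_per_plasmid
        f = analytic_fractions(y_ssb * d, y_dsb * d)
        rows.append(
            {
                "activity_MBq": a,
                "decays_per_plasmid": d,
                "F_SC": f.f_sc,
                "F_OC": f.f_oc,
                "F_L": f.f_l,
            }
        )
    return pd.DataFrame(rows)


def render_lane(
    f: FractionTriple,
    g: GelRenderConfig | None = None,
    rng: np.random.Generator | int | None = None,
    lane_id: str = "",
) -> LaneProfile:
    """Render a fraction triple as a synthetic gel lane intensity trace.

    The lane is the sum of three Gaussian bands whose areas are proportional
    to the conformation fractions, on a constant baseline with optional
    additive Gaussian noise.  Same seed, same profile, bit for bit.
    """
    if g is None:
        g = GelRenderConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    x = np.linspace(g.x_min, g.x_max, g.n_points)
    y = np.full_like(x, g.baseline)
    for conf, frac in (("SC", f.f_sc), ("OC", f.f_oc), ("L", f.f_l)):
        c, w = g.centers[conf], g.widths[conf]
        y = y + frac * g.amplitude * np.exp(-0.5 * ((x - c) / w) ** 2)
    if g.noise_sd > 0:
        y = y + rng.normal(0.0, g.noise_sd, size=x.size)
    y = np.clip(y, 0.0, None)
    return LaneProfile(positions=x, intensities=y, lane_id=lane_id)
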