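"""Plain-text I/O: lane profiles, band windows, fraction tables, configs.

Lane profiles travel as two-column delimited text (position, intensity);
band windows and incubation setups as small YAML mappings; fraction tables
as CSV in the shared schema (``compound, activity_MBq, dmso, replicate,
F_SC, F_OC, F_L, censored_L, censored_SC``).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .decay import NuclideSpec, IncubationSetup
from .densitometry import BandWindow, LaneProfile

__all__ = [
    "read_lane_profile",
    "write_lane_profile",
    "read_band_windows",
    "write_band_windows",
    "read_fraction_table",
    "write_fraction_table",
    "read_setup",
    "write_setup",
    "file_digest",
]


def read_lane_profile(path, lane_id: str | None = None) -> LaneProfile:
    """Read a two-column (position, intensity) whitespace/comma text file."""
    path = Path(path)
    try:
        arr = np.loadtxt(path, delimiter=None, comments="#", ndmin=2)
    except ValueError:
        arr = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    if arr.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns, got {arr.shape[1]}")
    return LaneProfile(
        positions=arr[:, 0],
        intensities=arr[:, 1],
        lane_id=lane_id if lane_id is not None else path.stem,
    )


def write_lane_profile(profile: LaneProfile, path) -> None:
    header = f"lane {profile.lane_id}\nposition\tintensity"
    np.savetxt(
        path,
        np.column_stack([profile.positions, profile.intensities]),
        fmt="%.10g",
        delimiter="\t",
        header=header,
    )


def read_band_windows(path) -> list[BandWindow]:
    """Read band windows from YAML: ``{OC: [start, end], L: [...], SC: [...]}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of conformation -> [start, end]")
    return [
        BandWindow(conformation=c, start=float(se[0]), end=float(se[1]))
        for c, se in raw.items()
    ]


def write_band_windows(windows: list[BandWindow], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {w.conformation: [w.start, w.end] for w in windows}, fh, sort_keys=False
        )


def read_fraction_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("F_SC", "F_OC", "F_L") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: fraction table lacks columns {missing}")
    return df


def write_fraction_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_setup(path) -> IncubationSetup:
    """Read an incubation setup from YAML.

    Keys: ``nuclide`` (name), ``half_life_h``, ``activity_MBq``,
    ``duration_h``, ``dna_mass_ng``, ``plasmid_length_bp``, and optional
    ``bp_molar_mass``, ``site_spacing_bp``, ``carrier_ratio``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    nuclide = NuclideSpec(raw.get("nuclide", "99mTc"), float(raw["half_life_h"]))
    kwargs = dict(
        nuclide=nuclide,
        activity_mbq=float(raw["activity_MBq"]),
        duration_h=float(raw["duration_h"]),
        dna_mass_ng=float(raw["dna_mass_ng"]),
        plasmid_length_bp=int(raw["plasmid_length_bp"]),
    )
    for opt in ("bp_molar_mass", "site_spacing_bp", "carrier_ratio"):
        if opt in raw:
            kwargs[opt] = float(raw[opt])
    return IncubationSetup(**kwargs)


def write_setup(setup: IncubationSetup, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "nuclide": setup.nuclide.name,
                "half_life_h": setup.nuclide.half_life_h,
                "activity_MBq": setup.activity_mbq,
                "duration_h": setup.duration_h,
                "dna_mass_ng": setup.dna_mass_ng,
                "plasmid_length_bp": setup.plasmid_length_bp,
                "bp_molar_mass": setup.bp_molar_mass,
                "site_spacing_bp": setup.site_spacing_bp,
                "carrier_ratio": setup.carrier_ratio,
            },
            fh,
            sort_keys=False,
        )


def file_digest(path) -> str:
    """SHA-256 of a file, for run manifests."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
        fh.write("\n")
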