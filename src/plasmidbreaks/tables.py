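"""Reference fraction tables for the ⁹⁹ᵐTc plasmid-damage assay.

Published mean OC/L percentages (three trials each, SD in the ``*_sd``
columns) for pUC 19 plasmid incubated 24 h with five ⁹⁹ᵐTc species at
15 MBq, with and without 0.2 M DMSO, plus the radical-scavenging control
series at 3 and 15 MBq of pertechnetate.  Linear bands below the 1%
detection limit are encoded with ``censored_L = True`` and ``l_pct = 0``.
The supercoiled percentage is the remainder to 100; where OC + L already
reach 100 the SC band was non-detectable.

These tables are the golden inputs for the fraction-to-yield inversion:
they are data, entered once, and never recomputed.
"""

from __future__ import annotations

import pandas as pd

from .densitometry import FractionTriple

__all__ = [
    "compound_fractions",
    "scavenger_fractions",
    "fixture_tables",
    "row_to_triple",
]

PERTECHNETATE = "TcO4-"
DETECTION_LIMIT = 0.01

# Mean OC/L percentages at 15 MBq, +/- 0.2 M DMSO (five species, n=3 each).
_COMPOUND_ROWS = [
    # compound, dmso, oc_pct, oc_sd, l_pct, l_sd, censored_L
    (PERTECHNETATE, False, 89.0, 1.0, 10.0, 1.0, False),
    (PERTECHNETATE, True, 9.0, 1.0, 0.0, None, True),
    ("Ia", False, 84.0, 3.0, 16.0, 3.0, False),
    ("Ia", True, 37.0, 8.0, 12.0, 5.0, False),
    ("Ib", False, 64.0, 5.0, 23.0, 4.0, False),
    ("Ib", True, 61.0, 2.0, 22.0, 7.0, False),
    ("II", False, 7.0, 4.0, 0.0, None, True),
    ("II", True, 8.0, 2.0, 0.0, None, True),
    ("III", False, 5.0, 1.0, 0.0, None, True),
    ("III", True, 4.0, 1.0, 0.0, None, True),
]

# Scavenging controls: pertechnetate alone vs. with DMSO or a ground-state
# (non-radioactive) Tc-pyrene derivative, at 3 and 15 MBq.
_SCAVENGER_ROWS = [
    # compound, activity_MBq, oc_pct, oc_sd, l_pct, l_sd, censored_L
    (PERTECHNETATE, 3.0, 57.0, 3.0, 3.0, 1.0, False),
    (PERTECHNETATE, 15.0, 89.0, 1.0, 10.0, 1.0, False),
    (PERTECHNETATE + " + DMSO", 3.0, 3.0, 1.0, 0.0, None, True),
    (PERTECHNETATE + " + DMSO", 15.0, 9.0, 1.0, 0.0, None, True),
    (PERTECHNETATE + " + Tc-Ia", 3.0, 6.0, 2.0, 0.0, None, True),
    (PERTECHNETATE + " + Tc-Ia", 15.0, 9.0, 1.0, 0.0, None, True),
    (PERTECHNETATE + " + Tc-Ib", 3.0, 5.0, 3.0, 0.0, None, True),
    (PERTECHNETATE + " + Tc-Ib", 15.0, 6.0, 1.0, 0.0, None, True),
    (PERTECHNETATE + " + Tc-II", 3.0, 8.0, 3.0, 0.0, None, True),
    (PERTECHNETATE + " + Tc-II", 15.0, 7.0, 2.0, 0.0, None, True),
    (PERTECHNETATE + " + Tc-III", 3.0, 6.0, 2.0, 0.0, None, True),
    (PERTECHNETATE + " + Tc-III", 15.0, 10.0, 2.0, 0.0, None, True),
]


def _finish(df: pd.DataFrame) -> pd.DataFrame:
    df["sc_pct"] = 100.0 - df["oc_pct"] - df["l_pct"]
    df["censored_SC"] = df["sc_pct"] < 100.0 * DETECTION_LIMIT
    df["F_SC"] = df["sc_pct"] / 100.0
    df["F_OC"] = df["oc_pct"] / 100.0
    df["F_L"] = df["l_pct"] / 100.0
    return df


def compound_fractions() -> pd.DataFrame:
    """Mean fractions for the five species at 15 MBq, with/without DMSO."""
    df = pd.DataFrame(
        _COMPOUND_ROWS,
        columns=["compound", "dmso", "oc_pct", "oc_sd", "l_pct", "l_sd", "censored_L"],
    )
    df.insert(1, "activity_MBq", 15.0)
    return _finish(df)


def scavenger_fractions() -> pd.DataFrame:
    """Radical-scavenging control series at 3 and 15 MBq pertechnetate."""
    df = pd.DataFrame(
        _SCAVENGER_ROWS,
        columns=["compound", "activity_MBq", "oc_pct", "oc_sd", "l_pct", "l_sd", "censored_L"],
    )
    df.insert(2, "dmso", df["compound"].str.contains("DMSO"))
    return _finish(df)


def fixture_tables() -> dict[str, pd.DataFrame]:
    """Both reference tables keyed by short name."""
    return {
        "compound_fractions": compound_fractions(),
        "scavenger_fractions": scavenger_fractions(),
    }


def row_to_triple(row: pd.Series, detection_limit: float = DETECTION_LIMIT) -> FractionTriple:
    """Convert one fraction-table row into a :class:`FractionTriple`."""
    return FractionTriple.from_raw(
        float(row["F_SC"]),
        float(row["F_OC"]),
        float(row["F_L"]),
        detection_limit=detection_limit,
        censored_l=bool(row.get("censored_L", False)),
        censored_sc=bool(row.get("censored_SC", False)),
    )
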