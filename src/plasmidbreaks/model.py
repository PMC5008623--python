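"""Model/Results objects tying fractions, decay accounting and inversion together.

:class:`PlasmidBreakModel` is built from a fraction table (one row per gel
lane / trial) and an :class:`~plasmidbreaks.decay.IncubationSetup`; its
:meth:`~PlasmidBreakModel.fit` returns a :class:`PlasmidBreakResults`
carrying per-condition break means, per-decay yields, replicate mean ± SD,
censoring markers and detection-limit bounds, with a ``summary()`` table
formatted like the assay's published yield tables (two significant figures).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decay import IncubationSetup
from .densitometry import FractionTriple
from .inference import (
    detection_bound_yield,
    dmso_decomposition,
    estimate_breaks,
    replicate_summary,
)
from .simulate import SimulationConfig, simulate_replicates
from .tables import row_to_triple

__all__ = ["PlasmidBreakModel", "PlasmidBreakResults", "round_sig"]

#: Columns a fraction table must provide.
REQUIRED_COLUMNS = ("F_SC", "F_OC", "F_L")
#: Grouping columns used when present, in precedence order.
GROUP_COLUMNS = ("compound", "dmso", "activity_MBq")


def round_sig(x: float | None, sig: int = 2) -> float | None:
    """Round to *sig* significant figures (display convention of the assay)."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return x
    if x == 0:
        return 0.0
    return round(x, sig - 1 - math.floor(math.log10(abs(x))))


class PlasmidBreakModel:
    """Poisson strand-break model for plasmid conformation fractions.

    Parameters
    ----------
    fractions : pandas.DataFrame
        One row per trial with columns ``F_SC``, ``F_OC``, ``F_L`` (summing
        to one; renormalised if not) and optional ``compound``, ``dmso``,
        ``activity_MBq``, ``replicate``, ``censored_L``, ``censored_SC``.
    setup : IncubationSetup, optional
        Decay/stoichiometry context.  When given, decays per plasmid are
        computed from it (per-row activity respected via ``activity_MBq``);
        otherwise pass ``decays_per_plasmid`` directly.
    decays_per_plasmid : float, optional
        Fixed normalisation overriding the setup-derived one.
    detection_limit : float
        Fraction below which a band counts as censored (default 1%).
    """

    def __init__(
        self,
        fractions: pd.DataFrame,
        setup: IncubationSetup | None = None,
        decays_per_plasmid: float | None = None,
        detection_limit: float = 0.01,
    ) -> None:
        if setup is None and decays_per_plasmid is None:
            raise ValueError("provide either setup or decays_per_plasmid")
        missing = [c for c in REQUIRED_COLUMNS if c not in fractions.columns]
        if missing:
            raise ValueError(f"fraction table lacks required columns: {missing}")
        self.fractions = fractions.reset_index(drop=True).copy()
        self.setup = setup
        self._fixed_d = decays_per_plasmid
        self.detection_limit = detection_limit

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_table(
        cls,
        path,
        setup: IncubationSetup | None = None,
        sep: str = ",",
        **kwargs,
    ) -> "PlasmidBreakModel":
        """Build from a delimited fraction table on disk."""
        return cls(pd.read_csv(path, sep=sep), setup=setup, **kwargs)

    @classmethod
    def from_simulation(
        cls, config: SimulationConfig, **kwargs
    ) -> "PlasmidBreakModel":
        """Forward-simulate replicates at known yields, then model them."""
        df = simulate_replicates(config)
        return cls(
            df,
            decays_per_plasmid=config.decays_per_plasmid,
            detection_limit=config.detection_limit,
            **kwargs,
        )

    # -- internals --------------------------------------------------------

    def _d_for_row(self, row: pd.Series) -> float:
        if self._fixed_d is not None:
            return self._fixed_d
        if "activity_MBq" in row.index and not pd.isna(row["activity_MBq"]):
            return (
                self.setup.with_activity(float(row["activity_MBq"]))
                .decay_result()
                .decays_per_plasmid
            )
        return self.setup.decay_result().decays_per_plasmid

    def _triple_for_row(self, row: pd.Series) -> FractionTriple:
        return row_to_triple(row, detection_limit=self.detection_limit)

    # -- fitting ----------------------------------------------------------

    def fit(self) -> "PlasmidBreakResults":
        """Invert every trial, then aggregate replicates per condition.

        Yields are computed per trial first and averaged afterwards (mean ±
        sample SD), matching how replicate assays are reported; trials with
        a non-detectable supercoiled band are excluded from the SSB summary
        and counted in ``n_excluded_ssb``.
        """
        per_trial = []
        for _, row in self.fractions.iterrows():
            d = self._d_for_row(row)
            est = estimate_breaks(self._triple_for_row(row), d)
            rec = {c: row[c] for c in GROUP_COLUMNS if c in row.index}
            rec.update(
                {
                    "decays_per_plasmid": d,
                    "X_SSB": est.x_ssb,
                    "X_DSB": est.x_dsb,
                    "Y_SSB": est.y_ssb,
                    "Y_DSB": est.y_dsb,
                    "ssb_nondetectable": est.ssb_nondetectable,
                    "dsb_censored": est.dsb_censored,
                    "dsb_upper_bound": est.dsb_upper_bound,
                }
            )
            per_trial.append(rec)
        trial_df = pd.DataFrame(per_trial)

        group_cols = [c for c in GROUP_COLUMNS if c in trial_df.columns]
        if group_cols:
            groups = trial_df.groupby(group_cols, sort=False, dropna=False)
        else:
            groups = [((), trial_df)]

        rows = []
        for key, g in groups:
            if not isinstance(key, tuple):
                key = (key,)
            rec = dict(zip(group_cols, key))
            for quantity in ("X_SSB", "X_DSB", "Y_SSB", "Y_DSB"):
                summ = replicate_summary(
                    None if pd.isna(v) else v for v in g[quantity]
                )
                rec[f"{quantity}_mean"] = summ.mean
                rec[f"{quantity}_sd"] = summ.sd
                rec[f"{quantity}_n"] = summ.n
                if quantity == "Y_SSB":
                    rec["n_excluded_ssb"] = summ.n_excluded
            rec["ssb_nondetectable"] = bool(g["ssb_nondetectable"].all())
            rec["dsb_censored"] = bool(g["dsb_censored"].all())
            bounds = g["dsb_upper_bound"].dropna()
            rec["dsb_upper_bound"] = float(bounds.max()) if len(bounds) else None
            rows.append(rec)
        return PlasmidBreakResults(
            model=self, table=pd.DataFrame(rows), per_trial=trial_df
        )


@dataclass
class PlasmidBreakResults:
    """Fitted break means and yields per experimental condition.

    ``table`` holds one row per (compound, dmso, activity) condition with
    replicate means, SDs, n, censoring markers and detection-limit bounds;
    ``per_trial`` keeps every individual inversion for inspection.
    """

    model: PlasmidBreakModel
    table: pd.DataFrame
    per_trial: pd.DataFrame

    # -- access -----------------------------------------------------------

    def condition(self, compound: str | None = None, dmso: bool | None = None) -> pd.Series:
        """The single summary row matching the given condition labels."""
        mask = pd.Series(True, index=self.table.index)
        if compound is not None:
            mask &= self.table["compound"] == compound
        if dmso is not None:
            mask &= self.table["dmso"] == dmso
        sub = self.table[mask]
        if len(sub) != 1:
            raise KeyError(
                f"condition (compound={compound!r}, dmso={dmso!r}) matched "
                f"{len(sub)} rows, expected exactly 1"
            )
        return sub.iloc[0]

    def dmso_decomposition(self, compound: str, metric: str = "Y_SSB"):
        """Direct/indirect split of *metric* for one compound.

        Compares the condition without DMSO against the one with the
        radical scavenger present; the surviving yield is the direct
        (Auger-electron) component.
        """
        minus = self.condition(compound, dmso=False)[f"{metric}_mean"]
        plus = self.condition(compound, dmso=True)[f"{metric}_mean"]
        if pd.isna(minus) or pd.isna(plus):
            raise ValueError(
                f"{metric} is non-detectable in one arm for {compound!r}"
            )
        return dmso_decomposition(float(minus), float(plus))

    def detection_bound(self) -> float:
        """Yield bound at the model's detection limit and mean normalisation."""
        d = float(self.per_trial["decays_per_plasmid"].mean())
        return detection_bound_yield(self.model.detection_limit, d)

    # -- presentation -----------------------------------------------------

    def display_table(self, sig: int = 2) -> pd.DataFrame:
        """Summary table rounded for display; censored/non-detectable entries
        rendered as "<bound" and em-dash markers."""
        out = []
        for _, r in self.table.iterrows():
            rec = {c: r[c] for c in r.index if not c.endswith(("_mean", "_sd", "_n"))
                   and c not in ("ssb_nondetectable", "dsb_censored", "dsb_upper_bound",
                                 "n_excluded_ssb")}
            if r.get("ssb_nondetectable", False):
                rec["Y_SSB"] = "—"
            else:
                rec["Y_SSB"] = round_sig(r["Y_SSB_mean"], sig)
            if r.get("dsb_censored", False) and pd.notna(r.get("dsb_upper_bound")):
                rec["Y_DSB"] = f"<{round_sig(r['dsb_upper_bound'], sig)}"
            else:
                rec["Y_DSB"] = round_sig(r["Y_DSB_mean"], sig)
            rec["n"] = r["Y_DSB_n"]
            out.append(rec)
        return pd.DataFrame(out)

    def summary(self, sig: int = 2) -> str:
        """Human-readable report of per-decay SSB/DSB yields per condition."""
        lines = [
            "Plasmid strand-break yields per plasmid per decay",
            "=" * 58,
        ]
        if self.model.setup is not None:
            res = self.model.setup.decay_result()
            lines.append(
                f"nuclide {self.model.setup.nuclide.name}, "
                f"{self.model.setup.activity_mbq:g} MBq, "
                f"{self.model.setup.duration_h:g} h -> "
                f"{res.decays_per_plasmid:.2f} decays/plasmid"
            )
        lines.append("-" * 58)
        lines.append(self.display_table(sig).to_string(index=False))
        lines.append("-" * 58)
        lines.append(
            f"detection limit {self.model.detection_limit:.0%}; "
            "'—' marks a non-detectable supercoiled band"
        )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def plot_fractions(self, ax=None):
        """Fraction-vs-activity plot when the table spans several activities."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.model.fractions
        if "activity_MBq" not in df.columns:
            raise ValueError("fraction table has no activity_MBq column to plot against")
        for col, label in (("F_SC", "SC"), ("F_OC", "OC"), ("F_L", "L")):
            ax.plot(df["activity_MBq"], df[col], "o-", label=label)
        ax.set_xlabel("activity (MBq)")
        ax.set_ylabel("plasmid fraction")
        ax.set_ylim(0, 1)
        ax.legend()
        return ax
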