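"""Combined baseline-burden + early-response prognostic model.

Patients are cross-classified by baseline metabolic tumour volume
(MTV-0 < 400 vs >= 400 cm^3) and interim Deauville score (1-3 vs 4-5) into
four groups, collapsed clinically into three tiers:

* good          — MTV-0 < 400 (either Deauville split),
* intermediate  — MTV-0 >= 400 with Deauville 1-3,
* poor          — MTV-0 >= 400 with Deauville 4-5.

:class:`PrognosticModel` is the statsmodels-style entry point: build it from
a cohort DataFrame (or :class:`~petdlbcl.records.PatientRecord` list), call
:meth:`PrognosticModel.fit`, and read estimates off the returned
:class:`PrognosticResults` (per-group sizes, event counts, Kaplan-Meier
5-year PFS, Cox hazard ratios versus the low-MTV/low-DS reference group, and
a text ``summary()``).  Alternative groupings substitute the response axis
(ΔSUVmax with the 66 % reduction cut-off) or the baseline axis (TLG-0, IPI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import CoxFit, KMCurve, cox_fit, km_estimate, logrank

__all__ = [
    "Cutoffs",
    "GROUPS",
    "TIERS",
    "TIER_OF_GROUP",
    "stratify_mtv_ds",
    "stratify_alt",
    "stratify_dataframe",
    "bulk_concordance",
    "ConcordanceTable",
    "PrognosticModel",
    "PrognosticResults",
    "ModelSummary",
    "summarise_model",
]

#: Four-way group labels, reference group first.
GROUPS = ("lowMTV_DS13", "lowMTV_DS45", "highMTV_DS13", "highMTV_DS45")
TIERS = ("good", "intermediate", "poor")
TIER_OF_GROUP = {
    "lowMTV_DS13": "good",
    "lowMTV_DS45": "good",
    "highMTV_DS13": "intermediate",
    "highMTV_DS45": "poor",
}

#: Generic labels for alternative groupings (baseline split x response split).
ALT_GROUPS = ("lowBase_goodResp", "lowBase_poorResp", "highBase_goodResp", "highBase_poorResp")


@dataclass(frozen=True)
class Cutoffs:
    """Dichotomisation cut-offs (rounded clinical defaults).

    ``roc_optimal`` switches MTV-0/TLG-0 to the exact ROC optima instead of
    the rounded clinical values.
    """

    mtv0: float = 400.0          # cm^3; >= is "high burden"
    tlg0: float = 4500.0         # cm^3·SUV
    mtv2: float = 1.8            # cm^3
    tlg2: float = 5.6
    suvmax2: float = 3.0
    delta_suvmax: float = -66.0  # %; reduction strictly greater than 66 % is "good response"
    delta_mtv: float = -99.8     # %
    delta_tlg: float = -99.9     # %
    mtd_bulk: float = 10.0       # cm; >= is "bulky"
    ipi_split: int = 2           # IPI >= 2 is "high risk"
    ds_split: int = 3            # Deauville <= 3 is CMR

    def __post_init__(self) -> None:
        for name in ("mtv0", "tlg0", "mtv2", "tlg2", "suvmax2", "mtd_bulk"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cutoff {name} must be positive")

    @classmethod
    def roc_optimal(cls) -> "Cutoffs":
        return cls(mtv0=396.0, tlg0=4541.0, delta_mtv=-99.76, delta_tlg=-99.9)


def stratify_mtv_ds(mtv0: float, ds: int, cutoffs: Cutoffs = Cutoffs()) -> tuple[str, str]:
    """Classify one patient into the four-way group and the three-way tier.

    ``mtv0`` exactly at the cut-off counts as high burden (the >= 400
    convention defines the model groups).
    """
    if not np.isfinite(mtv0) or not 1 <= int(ds) <= 5:
        raise ValueError(f"need finite mtv0 and Deauville 1-5, got {mtv0!r}, {ds!r}")
    low = mtv0 < cutoffs.mtv0
    cmr = int(ds) <= cutoffs.ds_split
    group = GROUPS[(0 if low else 2) + (0 if cmr else 1)]
    return group, TIER_OF_GROUP[group]


def stratify_alt(
    record: dict | pd.Series, mode: str, cutoffs: Cutoffs = Cutoffs()
) -> str:
    """Four-way classification for the alternative model variants.

    mode ``"mtv_dsuv"``: MTV-0 split with ΔSUVmax response (good iff the
    reduction exceeds 66 %, i.e. ``delta_suvmax < -66``); ``"tlg_ds"``:
    TLG-0 split with Deauville response; ``"ipi_ds"``: IPI 0-1 vs 2-5 with
    Deauville response.
    """
    if mode == "mtv_dsuv":
        base_low = record["mtv0"] < cutoffs.mtv0
        good = record["delta_suvmax"] < cutoffs.delta_suvmax
    elif mode == "tlg_ds":
        base_low = record["tlg0"] < cutoffs.tlg0
        good = int(record["ds"]) <= cutoffs.ds_split
    elif mode == "ipi_ds":
        base_low = int(record["ipi"]) < cutoffs.ipi_split
        good = int(record["ds"]) <= cutoffs.ds_split
    else:
        raise ValueError(f"unknown alternative grouping mode {mode!r}")
    return ALT_GROUPS[(0 if base_low else 2) + (0 if good else 1)]


def stratify_dataframe(
    df: pd.DataFrame, mode: str = "mtv_ds", cutoffs: Cutoffs = Cutoffs()
) -> pd.Series:
    """Vectorised stratification; rows with missing inputs are skipped with a warning.

    Returns a Series of group labels indexed like ``df`` (skipped rows absent).
    """
    if mode == "mtv_ds":
        needed = ["mtv0", "ds"]
    elif mode == "mtv_dsuv":
        needed = ["mtv0", "delta_suvmax"]
    elif mode == "tlg_ds":
        needed = ["tlg0", "ds"]
    elif mode == "ipi_ds":
        needed = ["ipi", "ds"]
    else:
        raise ValueError(f"unknown grouping mode {mode!r}")
    ok = df[needed].notna().all(axis=1)
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} record(s) skipped: missing {needed}", stacklevel=2
        )
    sub = df.loc[ok]
    if mode == "mtv_ds":
        labels = [
            stratify_mtv_ds(m, int(d), cutoffs)[0] for m, d in zip(sub["mtv0"], sub["ds"])
        ]
    else:
        labels = [stratify_alt(row, mode, cutoffs) for _, row in sub.iterrows()]
    return pd.Series(labels, index=sub.index, name="group")


# ---------------------------------------------------------------------------
# Bulk vs MTV-0 concordance


@dataclass(frozen=True)
class ConcordanceTable:
    """2x2 cross-classification of bulky disease (MTD >= 10 cm) vs high MTV-0."""

    counts: pd.DataFrame  # index: bulk low/high; columns: mtv0 low/high
    n: int
    concordance_pct: float
    discordant_low_bulk_high_mtv_pct: float
    discordant_high_bulk_low_mtv_pct: float

    @property
    def discordance_pct(self) -> float:
        return 100.0 - self.concordance_pct


def bulk_concordance(df: pd.DataFrame, cutoffs: Cutoffs = Cutoffs()) -> ConcordanceTable:
    """Agreement between anatomical bulk (MTD) and metabolic burden (MTV-0)."""
    ok = df[["mtd", "mtv0"]].notna().all(axis=1)
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} record(s) skipped: missing mtd/mtv0", stacklevel=2)
    sub = df.loc[ok]
    bulk = np.where(sub["mtd"].to_numpy(float) >= cutoffs.mtd_bulk, "high", "low")
    mtv = np.where(sub["mtv0"].to_numpy(float) >= cutoffs.mtv0, "high", "low")
    counts = (
        pd.crosstab(pd.Series(bulk, name="bulk"), pd.Series(mtv, name="mtv0"))
        .reindex(index=["low", "high"], columns=["low", "high"], fill_value=0)
    )
    n = int(counts.to_numpy().sum())
    conc = counts.loc["low", "low"] + counts.loc["high", "high"]
    return ConcordanceTable(
        counts=counts,
        n=n,
        concordance_pct=100.0 * conc / n,
        discordant_low_bulk_high_mtv_pct=100.0 * counts.loc["low", "high"] / n,
        discordant_high_bulk_low_mtv_pct=100.0 * counts.loc["high", "low"] / n,
    )


# ---------------------------------------------------------------------------
# Model / Results


class PrognosticModel:
    """Prognostic stratification model over a patient cohort.

    Parameters
    ----------
    data : DataFrame
        One row per patient.  Required columns: ``time_years`` (PFS time,
        years), ``event`` (bool) plus the grouping inputs (``mtv0`` and
        ``ds`` for the primary model).
    grouping : str
        ``"mtv_ds"`` (primary), ``"mtv_dsuv"``, ``"tlg_ds"`` or ``"ipi_ds"``.
    cutoffs : Cutoffs
    """

    def __init__(
        self, data: pd.DataFrame, grouping: str = "mtv_ds", cutoffs: Cutoffs | None = None
    ):
        for col in ("time_years", "event"):
            if col not in data.columns:
                raise ValueError(f"cohort table lacks required column {col!r}")
        self.data = data
        self.grouping = grouping
        self.cutoffs = cutoffs if cutoffs is not None else Cutoffs()
        self._group_order = GROUPS if grouping == "mtv_ds" else ALT_GROUPS

    @classmethod
    def from_records(cls, records, **kwargs) -> "PrognosticModel":
        """Build from a list of :class:`~petdlbcl.records.PatientRecord`."""
        from .records import records_to_dataframe

        return cls(records_to_dataframe(records), **kwargs)

    def fit(self, landmark_years: float = 5.0) -> "PrognosticResults":
        """Stratify, estimate per-group survival and hazard ratios."""
        groups = stratify_dataframe(self.data, self.grouping, self.cutoffs)
        sub = self.data.loc[groups.index]
        t = sub["time_years"].to_numpy(float)
        e = sub["event"].to_numpy(bool)
        g = groups.to_numpy()

        present = [lv for lv in self._group_order if (g == lv).any()]
        curves: dict[str, KMCurve] = {}
        rows = []
        total_events = int(e.sum())
        for lv in self._group_order:
            sel = g == lv
            n = int(sel.sum())
            if n == 0:
                rows.append(
                    {"group": lv, "n": 0, "share_pct": 0.0, "events": 0,
                     "km_landmark_pfs_pct": np.nan}
                )
                continue
            curve = km_estimate(t[sel], e[sel])
            curves[lv] = curve
            rows.append(
                {
                    "group": lv,
                    "n": n,
                    "share_pct": 100.0 * n / len(sub),
                    "events": int(e[sel].sum()),
                    "km_landmark_pfs_pct": 100.0 * curve.at(landmark_years),
                }
            )
        table = pd.DataFrame(rows).set_index("group")

        cox: CoxFit | None = None
        if len(present) >= 2 and e.sum() > 0:
            order = {lv: i for i, lv in enumerate(self._group_order)}
            cox = cox_fit(t, e, np.array([order[x] for x in g]))
            for lv in present:
                hr, lo, hi = cox.hazard_ratios[order[lv]]
                table.loc[lv, "HR"] = hr
                table.loc[lv, "CI95_low"] = lo
                table.loc[lv, "CI95_high"] = hi
        chi2 = p = np.nan
        if len(present) >= 2:
            chi2, p = logrank([(t[g == lv], e[g == lv]) for lv in present])

        worst = self._group_order[-1]
        worst_events = int(e[g == worst].sum())
        return PrognosticResults(
            model=self,
            group_table=table,
            curves=curves,
            cox=cox,
            logrank_chi2=float(chi2),
            logrank_p=float(p),
            landmark_years=landmark_years,
            n=len(sub),
            n_skipped=len(self.data) - len(sub),
            total_events=total_events,
            worst_group_event_share_pct=(
                100.0 * worst_events / total_events if total_events else np.nan
            ),
        )


@dataclass
class PrognosticResults:
    """Fitted stratification: group table, KM curves, Cox HRs, tier mapping."""

    model: PrognosticModel
    group_table: pd.DataFrame
    curves: dict[str, KMCurve]
    cox: CoxFit | None
    logrank_chi2: float
    logrank_p: float
    landmark_years: float
    n: int
    n_skipped: int
    total_events: int
    worst_group_event_share_pct: float

    @property
    def tier_table(self) -> pd.DataFrame:
        """Three-tier collapse (primary grouping only)."""
        if self.model.grouping != "mtv_ds":
            raise ValueError("tiers are defined for the mtv_ds grouping only")
        tiers = self.group_table.copy()
        tiers["tier"] = [TIER_OF_GROUP[g] for g in tiers.index]
        agg = tiers.groupby("tier", sort=False).agg(
            n=("n", "sum"), events=("events", "sum"), share_pct=("share_pct", "sum")
        )
        return agg.reindex(TIERS)

    def survival_at(self, years: float, group: str) -> float:
        """KM survival probability for a group at a time point."""
        return self.curves[group].at(years)

    def summary(self) -> str:
        """Human-readable summary table."""
        lines = [
            f"Prognostic stratification ({self.model.grouping}), "
            f"n = {self.n} ({self.n_skipped} skipped), events = {self.total_events}",
            f"log-rank chi2 = {self.logrank_chi2:.2f} (p = {self.logrank_p:.2g}); "
            f"KM read-out at {self.landmark_years:g} years",
            "",
            self.group_table.round(3).to_string(),
        ]
        if self.model.grouping == "mtv_ds":
            lines += ["", "Tiers:", self.tier_table.round(3).to_string()]
        lines += [
            "",
            f"worst-group share of events: {self.worst_group_event_share_pct:.1f} %",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "grouping": self.model.grouping,
            "n": self.n,
            "n_skipped": self.n_skipped,
            "total_events": self.total_events,
            "landmark_years": self.landmark_years,
            "logrank_chi2": self.logrank_chi2,
            "logrank_p": self.logrank_p,
            "worst_group_event_share_pct": self.worst_group_event_share_pct,
            "groups": self.group_table.reset_index().to_dict(orient="records"),
        }
        if self.model.grouping == "mtv_ds":
            out["tiers"] = self.tier_table.reset_index().to_dict(orient="records")
        return out

    def plot_km(self, ax=None):
        """Kaplan-Meier step plot per group (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for lv, curve in self.curves.items():
            ax.step(curve.times, curve.survival, where="post", label=lv)
        ax.set_xlabel("years from diagnosis")
        ax.set_ylabel("progression-free survival")
        ax.set_ylim(0, 1.02)
        ax.legend()
        return ax


#: Spec-facing alias: the fitted summary object.
ModelSummary = PrognosticResults


def summarise_model(
    data: pd.DataFrame,
    grouping: str = "mtv_ds",
    cutoffs: Cutoffs | None = None,
    landmark_years: float = 5.0,
) -> PrognosticResults:
    """Functional wrapper: fit :class:`PrognosticModel` on a cohort table."""
    return PrognosticModel(data, grouping=grouping, cutoffs=cutoffs).fit(landmark_years)
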