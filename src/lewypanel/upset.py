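"""Contrast-membership (UpSet) partitioning of significant proteins.

Proteins nominally significant in the DLB-vs-CON contrast are partitioned by
their behavior in DLB-vs-AD and AD-vs-CON:

* significant vs AD but not AD-vs-CON  -> ``dlb_unique``
* not significant vs AD                -> ``general_dementia``
* significant vs AD and AD-vs-CON      -> ``shared_divergent``

Assays failing the DLB-vs-CON gate are ``unclassified``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from lewypanel.errors import DataError

SUBSET_LABELS = ("dlb_unique", "general_dementia", "shared_divergent")


def categorize(sig_dlb_con: bool, sig_dlb_ad: bool, sig_ad_con: bool) -> str:
    """Subset label from the three nominal-significance flags."""
    if not sig_dlb_con:
        return "unclassified"
    if not sig_dlb_ad:
        return "general_dementia"
    return "dlb_unique" if not sig_ad_con else "shared_divergent"


@dataclass
class UpSetPartition:
    """Membership flags, labels and per-contrast directions per assay."""

    table: pd.DataFrame  # columns: sig_dlb_con, sig_dlb_ad, sig_ad_con,
    #                       subset, dir_dlb_con, dir_dlb_ad, dir_ad_con

    @property
    def classified(self) -> pd.DataFrame:
        return self.table[self.table["subset"] != "unclassified"]

    def membership_matrix(self) -> pd.DataFrame:
        """0/1 membership matrix consumable by UpSet plotting tools."""
        return self.table[["sig_dlb_con", "sig_dlb_ad", "sig_ad_con"]].astype(int)


def build_partition(
    dlb_con: pd.DataFrame,
    dlb_ad: pd.DataFrame,
    ad_con: pd.DataFrame,
    sig_col: str = "sig_p05",
) -> UpSetPartition:
    """Partition from three contrast tables (as built by ``contrast_table``).

    Membership uses nominal significance (``sig_p05``) by default.
    Direction is the sign of beta (0 when beta is exactly 0 or missing).
    """
    tabs = {}
    for name, tab in (("dlb_con", dlb_con), ("dlb_ad", dlb_ad), ("ad_con", ad_con)):
        tabs[name] = tab.set_index("assay_id")
    assays = tabs["dlb_con"].index
    for name, t in tabs.items():
        if not assays.equals(t.index):
            missing = assays.difference(t.index).tolist()
            raise DataError(f"contrast {name} lacks assays: {missing[:5]}")
    rows = {}
    for key in ("dlb_con", "dlb_ad", "ad_con"):
        rows[f"sig_{key}"] = tabs[key][sig_col].astype(bool)
        rows[f"dir_{key}"] = np.sign(tabs[key]["beta"].fillna(0.0)).astype(int)
    table = pd.DataFrame(rows, index=assays)
    table["subset"] = [
        categorize(a, b, c)
        for a, b, c in zip(
            table["sig_dlb_con"], table["sig_dlb_ad"], table["sig_ad_con"]
        )
    ]
    return UpSetPartition(table)


def upset_counts(partition: UpSetPartition) -> pd.DataFrame:
    """Subset sizes and integer percentages of the sig-DLB-vs-CON total.

    Percentages are 100*count/total rounded half-up; an empty partition
    yields zero counts and percentages.
    """
    counts = {label: int((partition.table["subset"] == label).sum())
              for label in SUBSET_LABELS}
    total = sum(counts.values())
    pct = {
        label: _round_half_up(100.0 * c / total) if total else 0
        for label, c in counts.items()
    }
    return pd.DataFrame(
        {
            "subset": list(SUBSET_LABELS),
            "count": [counts[s] for s in SUBSET_LABELS],
            "percent": [pct[s] for s in SUBSET_LABELS],
            "total": total,
        }
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def subset_direction_summary(
    partition: UpSetPartition,
    dlb_con: pd.DataFrame,
    ad_con: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Median member fold-change with bootstrap percentile 95% CI per subset.

    Summaries are computed for both the DLB-vs-CON and AD-vs-CON contrasts.
    Subsets with fewer than 3 members report a missing CI.
    """
    rng = np.random.default_rng(seed)
    fc = {
        "DLB_vs_CON": dlb_con.set_index("assay_id")["fold_change"],
        "AD_vs_CON": ad_con.set_index("assay_id")["fold_change"],
    }
    rows = []
    for label in SUBSET_LABELS:
        members = partition.table.index[partition.table["subset"] == label]
        for contrast, series in fc.items():
            vals = series.reindex(members).dropna().to_numpy()
            if vals.size == 0:
                rows.append(
                    {"subset": label, "contrast": contrast, "n": 0,
                     "median_fc": np.nan, "ci_low": np.nan, "ci_high": np.nan}
                )
                continue
            med = float(np.median(vals))
            if vals.size < 3:
                lo = hi = np.nan
            else:
                boots = np.median(
                    rng.choice(vals, size=(n_boot, vals.size), replace=True), axis=1
                )
                lo, hi = np.percentile(boots, [2.5, 97.5])
            rows.append(
                {"subset": label, "contrast": contrast, "n": vals.size,
                 "median_fc": med, "ci_low": float(lo), "ci_high": float(hi)}
            )
    return pd.DataFrame(rows)
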