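"""Perinatal, stillbirth, neonatal and late-neonatal rates and death timing.

Conventions: days are completed days since birth (0-based).  Perinatal
mortality = stillbirths + live-born deaths on days 0-6, per 1000 total
births.  Neonatal mortality = live-born deaths on days 0-27, per 1000
live births; late neonatal = days 7-27.  "Within 24 hours" is
operationalized as death day 0-1 (plus stillbirths for the perinatal
share), matching the day-bin labelling of the source register.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = ["RateSummary", "rate_summary", "timing_distribution", "annual_trends"]


@dataclass
class RateSummary:
    total_births: int
    live_births: int
    stillbirths: int
    deaths_day0_1: int
    deaths_day2_6: int
    deaths_day7_27: int
    pmr: float            # per 1000 total births
    sbr: float            # per 1000 total births
    nmr: float            # per 1000 live births
    late_nmr: float       # per 1000 live births
    share_24h_of_perinatal: float
    share_24h_of_neonatal: float

    @property
    def deaths_by_bin(self):
        return {
            "day0_1": self.deaths_day0_1,
            "day2_6": self.deaths_day2_6,
            "day7_27": self.deaths_day7_27,
        }

    def to_dict(self):
        return {
            "total_births": self.total_births,
            "live_births": self.live_births,
            "stillbirths": self.stillbirths,
            **self.deaths_by_bin,
            "pmr": self.pmr,
            "sbr": self.sbr,
            "nmr": self.nmr,
            "late_nmr": self.late_nmr,
            "share_24h_of_perinatal": self.share_24h_of_perinatal,
            "share_24h_of_neonatal": self.share_24h_of_neonatal,
        }


def _counts(df):
    dd = pd.to_numeric(df["death_day"], errors="coerce")
    sb = int((df["stillbirth"].astype(float) == 1).sum())
    total = len(df)
    d01 = int(((dd >= 0) & (dd <= 1)).sum())
    d26 = int(((dd >= 2) & (dd <= 6)).sum())
    d727 = int(((dd >= 7) & (dd <= 27)).sum())
    return total, sb, d01, d26, d727


def rate_summary(df) -> RateSummary:
    """Counts, rates per 1000 and 24-hour shares for one cohort."""
    df = df.df if isinstance(df, Cohort) else df
    if len(df) == 0:
        raise ValueError("empty cohort")
    total, sb, d01, d26, d727 = _counts(df)
    live = total - sb
    early = d01 + d26
    neonatal = early + d727
    perinatal = sb + early
    pmr = 1000.0 * perinatal / total
    sbr = 1000.0 * sb / total
    if live == 0:
        warnings.warn("no live births; neonatal rates undefined")
        nmr = late_nmr = float("nan")
    else:
        nmr = 1000.0 * neonatal / live
        late_nmr = 1000.0 * d727 / live
    return RateSummary(
        total_births=total,
        live_births=live,
        stillbirths=sb,
        deaths_day0_1=d01,
        deaths_day2_6=d26,
        deaths_day7_27=d727,
        pmr=pmr,
        sbr=sbr,
        nmr=nmr,
        late_nmr=late_nmr,
        share_24h_of_perinatal=(sb + d01) / perinatal if perinatal else float("nan"),
        share_24h_of_neonatal=d01 / neonatal if neonatal else float("nan"),
    )


def timing_distribution(df):
    """Death-timing shares: perinatal over (stillbirth + day 0-1, day 2-6),
    neonatal over (day 0-1, day 2-6, day 7-27)."""
    df = df.df if isinstance(df, Cohort) else df
    total, sb, d01, d26, d727 = _counts(df)
    perinatal = sb + d01 + d26
    if perinatal == 0:
        raise ValueError("no events")
    out = {
        "perinatal": {
            "stillbirth_day0_1": (sb + d01) / perinatal,
            "day2_6": d26 / perinatal,
        }
    }
    neonatal = d01 + d26 + d727
    out["neonatal"] = (
        {
            "day0_1": d01 / neonatal,
            "day2_6": d26 / neonatal,
            "day7_27": d727 / neonatal,
        }
        if neonatal
        else {"day0_1": float("nan"), "day2_6": float("nan"),
              "day7_27": float("nan")}
    )
    return out


def annual_trends(df) -> pd.DataFrame:
    """Per-year rate table (pmr, sbr, nmr, late_nmr, observed LBW %)."""
    df = df.df if isinstance(df, Cohort) else df
    rows = []
    for year, grp in df.groupby("year", sort=True):
        if len(grp) == 0:  # pragma: no cover - groupby omits empty groups
            warnings.warn(f"year {year} has no births; row omitted")
            continue
        s = rate_summary(grp)
        w = grp["birth_weight_kg"].astype(float)
        observed = w.notna()
        lbw_pct = (
            100.0 * float((w[observed] < 2.5).mean()) if observed.any()
            else float("nan")
        )
        rows.append(
            {
                "year": int(year),
                "total_births": s.total_births,
                "live_births": s.live_births,
                "stillbirths": s.stillbirths,
                "pmr": s.pmr,
                "sbr": s.sbr,
                "nmr": s.nmr,
                "late_nmr": s.late_nmr,
                "lbw_pct": lbw_pct,
            }
        )
    return pd.DataFrame(rows)
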