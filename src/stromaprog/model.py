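"""End-to-end prognostic stratification model over a quantified cohort.

:class:`SipLipStratification` takes a cohort table carrying per-patient
stroma and lymphocyte fractions (SIP, LIP) with overall-survival follow-up
and fits the full stratification in one call: a two-threshold (X-tile
style) SIP cutpoint search, a maximally-selected-rank-statistic LIP
cutpoint, the SIP-LH merge, the combined three-group risk classification,
Kaplan–Meier summaries with log-rank comparison and group-1 hazard-ratio
contrasts, and the univariate → multivariate (p < 0.05 carry-forward) Cox
screen including SIP and LIP as binary predictors.

The fitted :class:`SipLipResults` carries all estimates and a
``summary()`` report, in the spirit of statsmodels results objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cutpoints, survival


@dataclass
class SipLipResults:
    """Estimates and diagnostics from a fitted stratification."""

    data: pd.DataFrame  # cohort with sip_group3/sip_group/lip_group/combined_group
    sip_cutpoints: cutpoints.CutpointResult
    lip_cutpoint: cutpoints.CutpointResult
    group_comparison: dict  # from survival.compare_groups on combined_group
    cox_univariate: pd.DataFrame
    cox_multivariate: pd.DataFrame | None
    n_filtered: int

    @property
    def sip_cuts(self) -> tuple[float, float]:
        return self.sip_cutpoints.cut_values

    @property
    def lip_cut(self) -> float:
        return self.lip_cutpoint.cut_values[0]

    @property
    def hr_table(self) -> pd.DataFrame:
        return self.group_comparison["hr_table"]

    def summary(self) -> str:
        lines = [
            "SIP/LIP prognostic stratification",
            "=" * 48,
            f"patients analysed: {len(self.data)} "
            f"(excluded by filtering: {self.n_filtered})",
            f"SIP cuts (low | intermediate | high): "
            f"{self.sip_cuts[0]:.4f}, {self.sip_cuts[1]:.4f} "
            f"(chi2 = {self.sip_cutpoints.max_statistic:.2f})",
            f"LIP cut (low vs high): {self.lip_cut:.4f} "
            f"(|Z| = {self.lip_cutpoint.max_statistic:.2f}, "
            f"p = {self.lip_cutpoint.p_value:.3g})",
            "",
            "combined groups (1 = SIP-intermediate & LIP-high, "
            "3 = SIP-LH & LIP-low):",
        ]
        for g, summ in sorted(self.group_comparison["groups"].items()):
            med = "not reached" if not summ.median_reached else (
                f"{summ.median_os:.1f} months "
                f"(95% CI {summ.median_ci[0]:.1f}-{summ.median_ci[1]:.1f})"
            )
            lines.append(f"  group {g}: n = {summ.n}, median OS {med}")
        lines.append(
            f"log-rank across groups: chi2 = "
            f"{self.group_comparison['logrank_chi2']:.2f}, "
            f"p = {self.group_comparison['logrank_p']:.3g}"
        )
        lines.append("")
        lines.append("hazard-ratio contrasts (group 1 as reference):")
        for _, row in self.hr_table.iterrows():
            lines.append(
                f"  {row['variable']}: HR = {row['hr']:.2f} "
                f"(95% CI {row['ci_low']:.2f}-{row['ci_high']:.2f}), "
                f"p = {row['p']:.3g}"
            )
        if self.cox_multivariate is not None and len(self.cox_multivariate):
            lines.append("")
            lines.append("multivariate Cox (variables with univariate p < 0.05):")
            for _, row in self.cox_multivariate.iterrows():
                flag = " [independent predictor]" if row["independent_predictor"] else ""
                lines.append(
                    f"  {row['variable']}: HR = {row['hr']:.2f} "
                    f"(95% CI {row['ci_low']:.2f}-{row['ci_high']:.2f}), "
                    f"p = {row['p']:.3g}{flag}"
                )
        return "\n".join(lines)


class SipLipStratification:
    """Prognostic stratification of a cohort by SIP and LIP cutpoints.

    Parameters
    ----------
    data : cohort table with survival follow-up and marker columns.
    covariates : additional covariate columns to include in the Cox screen
        (SIP and LIP binary groups are always screened).
    min_group_frac : minimum group size for both cutpoint searches, as a
        fraction of the cohort.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        time_col: str = "os_months",
        event_col: str = "event",
        sip_col: str = "sip",
        lip_col: str = "lip",
        covariates: list[str] | None = None,
        min_group_frac: float = 0.10,
    ):
        for col in (time_col, event_col, sip_col, lip_col):
            if col not in data.columns:
                raise ValueError(f"column {col!r} missing from cohort table")
        self.data = data
        self.time_col = time_col
        self.event_col = event_col
        self.sip_col = sip_col
        self.lip_col = lip_col
        self.covariates = list(covariates or [])
        self.min_group_frac = min_group_frac

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "SipLipStratification":
        return cls(data, **kwargs)

    def fit(self, filter_perioperative: bool = True) -> SipLipResults:
        df = self.data.rename(
            columns={self.time_col: "os_months", self.event_col: "event"}
        )
        n0 = len(df)
        if filter_perioperative:
            df = survival.filter_cohort(df)
        t = df["os_months"].to_numpy(float)
        e = df["event"].to_numpy(int)

        sip_res = cutpoints.xtile_two_cut(
            df[self.sip_col], t, e, self.min_group_frac
        )
        lip_res = cutpoints.maxstat_binary(
            df[self.lip_col], t, e, self.min_group_frac
        )
        df = df.copy()
        df["sip_group3"] = sip_res.group_labels
        df["sip_group"] = cutpoints.merge_sip_lh(sip_res.group_labels)
        df["lip_group"] = lip_res.group_labels
        df["combined_group"] = cutpoints.combined_groups(
            df["sip_group"], df["lip_group"]
        )

        comparison = survival.compare_groups(df, "combined_group")

        # Cox screen: binary SIP/LIP indicators (protective direction) first
        df["sip_intermediate"] = (df["sip_group"] == "intermediate").astype(float)
        df["lip_high"] = (df["lip_group"] == "high").astype(float)
        screen = ["sip_intermediate", "lip_high"] + self.covariates
        uni = survival.cox_univariate(df, screen)
        selected = list(dict.fromkeys(
            row["source"] for _, row in uni.iterrows()
            if row["converged"] and row["p"] < 0.05
        ))
        multi = (
            survival.cox_multivariate(df, selected) if len(selected) >= 1 else None
        )
        return SipLipResults(
            data=df,
            sip_cutpoints=sip_res,
            lip_cutpoint=lip_res,
            group_comparison=comparison,
            cox_univariate=uni,
            cox_multivariate=multi,
            n_filtered=n0 - len(df),
        )
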