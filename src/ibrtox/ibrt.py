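"""Threshold-based Integrative Biomarker Response (IBR-T) index.

The index condenses a panel of oxidative-stress biomarkers into one score per
(tissue, day, treatment) group:

1. Within each (tissue, day) stratum, the control group defines, per
   biomarker b, a reference R_b (control median) and a threshold T_b
   (control 95th percentile), both by linear interpolation on order
   statistics (position h = (n-1)p + 1, numpy's default).
2. For each treatment t, the log-ratio L_t = ln(mean_t / R_b) of the
   treatment mean to the reference is standardised by the sample SD (n-1) of
   {L_t} across all treatments including the control: z_t = L_t / sd(L).
   If sd(L) = 0 all z are 0 by convention.
3. A biomarker is *included* for treatment t when its mean strictly exceeds
   T_b — i.e. when it is induced beyond the control's upper tail. Decreases
   never count as induction (a symmetric lower-tail option exists but is off
   by default).
4. The IBR-T score is the mean of |z_b| over included biomarkers, and 0 when
   none is included, so every group (the control included) carries a score.

The natural log is used; any base cancels after the SD standardisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TREATMENTS, summarize_groups


class InsufficientControlError(ValueError):
    """Fewer than 2 control values in a stratum cell."""


class MissingControlError(ValueError):
    """A (tissue, day) stratum lacks a control group entirely."""


def control_reference(control_values) -> tuple[float, float]:
    """Reference (median) and threshold (95th percentile) of a control sample.

    Percentiles use linear interpolation on order statistics, so e.g. values
    1..20 give median 10.5 and 95th percentile 19.05.
    """
    x = np.asarray(control_values, dtype=float)
    if x.size < 2:
        raise InsufficientControlError(
            f"need >= 2 control values to set reference/threshold, got {x.size}"
        )
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("control values must be finite and strictly positive")
    return float(np.median(x)), float(np.percentile(x, 95))


def standardized_log_ratios(
    group_means: pd.Series | dict,
    reference: float,
    threshold: float,
    *,
    symmetric: bool = False,
) -> pd.DataFrame:
    """Standardise per-treatment means of one biomarker against the control.

    Parameters
    ----------
    group_means : mapping treatment -> mean
        Must contain at least two treatments (the control among them).
    reference, threshold : float
        Control median and 95th percentile for this (tissue, day, biomarker).
    symmetric : bool
        If True, a mean below the control 5th-percentile-mirrored threshold
        ``reference**2 / threshold`` also counts as included (suppression
        treated like induction). Off by default: only induction counts.

    Returns
    -------
    DataFrame indexed by treatment with columns ``mean``, ``log_ratio``,
    ``sd_log_ratio``, ``z``, ``included``.
    """
    means = pd.Series(group_means, dtype=float)
    if len(means) < 2:
        raise ValueError("need >= 2 treatment means")
    if np.any(means.to_numpy() <= 0):
        bad = means.index[means <= 0].tolist()
        raise ValueError(f"nonpositive treatment mean(s) for {bad}")
    log_ratio = np.log(means / reference)
    sd = float(log_ratio.std(ddof=1))
    z = log_ratio / sd if sd > 0 else pd.Series(0.0, index=means.index)
    included = means > threshold
    if symmetric:
        included = included | (means < reference**2 / threshold)
    return pd.DataFrame(
        {
            "mean": means,
            "log_ratio": log_ratio,
            "sd_log_ratio": sd,
            "z": z,
            "included": included,
        }
    )


def ibrt_score(z, included) -> float:
    """Mean |z| over included biomarkers; 0 when none is included."""
    z = np.asarray(z, dtype=float)
    included = np.asarray(included, dtype=bool)
    if z.shape != included.shape:
        raise ValueError("z and inclusion flags must align")
    if not included.any():
        return 0.0
    return float(np.mean(np.abs(z[included])))


class IBRT:
    """IBR-T model over a long-format biomarker table.

    Parameters
    ----------
    data : DataFrame
        Long table with columns tissue, treatment, day, biomarker, value
        (as produced by :func:`ibrtox.data.read_biomarker_table` or the
        generator). Every (tissue, day) stratum must contain the control.
    pool_days : bool
        If True, references/thresholds are computed from controls pooled
        over both sampling days instead of per day.
    symmetric_threshold : bool
        Passed through to :func:`standardized_log_ratios`.
    control : str
        Label of the control group.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        *,
        pool_days: bool = False,
        symmetric_threshold: bool = False,
        control: str = "CTRL",
    ):
        self.data = data
        self.pool_days = pool_days
        self.symmetric_threshold = symmetric_threshold
        self.control = control
        strata = data[["tissue", "day"]].drop_duplicates()
        ctrl = data[data["treatment"] == control][["tissue", "day"]].drop_duplicates()
        merged = strata.merge(ctrl, how="left", indicator=True)
        missing = merged[merged["_merge"] == "left_only"]
        if len(missing):
            t, d = missing.iloc[0][["tissue", "day"]]
            raise MissingControlError(f"no {control} group in stratum (tissue={t}, day={d})")

    def fit(self) -> "IBRTResults":
        summaries = summarize_groups(self.data)
        thresh_rows = []
        detail_frames = []
        for (tissue, day), stratum in self.data.groupby(["tissue", "day"], sort=True):
            if self.pool_days:
                ctrl_pool = self.data[
                    (self.data["tissue"] == tissue) & (self.data["treatment"] == self.control)
                ]
            else:
                ctrl_pool = stratum[stratum["treatment"] == self.control]
            cell_means = summaries[(summaries["tissue"] == tissue) & (summaries["day"] == day)]
            for biomarker, ctrl_cell in ctrl_pool.groupby("biomarker", sort=True, observed=True):
                reference, threshold = control_reference(ctrl_cell["value"])
                thresh_rows.append((tissue, day, biomarker, reference, threshold))
                means = (
                    cell_means[cell_means["biomarker"] == biomarker]
                    .set_index("treatment")["mean"]
                )
                detail = standardized_log_ratios(
                    means, reference, threshold, symmetric=self.symmetric_threshold
                )
                detail.insert(0, "tissue", tissue)
                detail.insert(1, "day", day)
                detail.insert(2, "biomarker", biomarker)
                detail_frames.append(detail.rename_axis("treatment").reset_index())
        thresholds = pd.DataFrame(
            thresh_rows, columns=["tissue", "day", "biomarker", "reference", "threshold"]
        )
        details = pd.concat(detail_frames, ignore_index=True)
        score_rows = []
        for (tissue, day, treatment), cell in details.groupby(
            ["tissue", "day", "treatment"], sort=True
        ):
            score_rows.append(
                (
                    tissue,
                    day,
                    treatment,
                    ibrt_score(cell["z"], cell["included"]),
                    int(cell["included"].sum()),
                )
            )
        scores = pd.DataFrame(
            score_rows, columns=["tissue", "day", "treatment", "score", "n_included"]
        )
        order = {t: i for i, t in enumerate(TREATMENTS)}
        scores = scores.sort_values(
            ["tissue", "day", "treatment"],
            key=lambda c: c.map(order) if c.name == "treatment" else c,
        ).reset_index(drop=True)
        return IBRTResults(self, thresholds, details, scores)


@dataclass
class IBRTResults:
    """Fitted IBR-T index: thresholds, per-biomarker details and scores."""

    model: IBRT
    thresholds: pd.DataFrame
    details: pd.DataFrame
    scores: pd.DataFrame

    @property
    def settings(self) -> dict:
        """Methodological choices recorded alongside the scores."""
        return {
            "reference": "control median (per tissue and day)",
            "threshold": "control 95th percentile, linear interpolation",
            "log_base": "e",
            "sd_across": "treatment log-ratios, sample SD (ddof=1)",
            "inclusion": "treatment mean strictly above threshold"
            + (" or below mirrored lower threshold" if self.model.symmetric_threshold else ""),
            "pool_days": self.model.pool_days,
        }

    def summary(self) -> str:
        lines = ["IBR-T index", "=" * 55]
        for key, val in self.settings.items():
            lines.append(f"  {key}: {val}")
        lines.append("")
        lines.append(
            self.scores.to_string(
                index=False, float_format=lambda v: f"{v:.4f}"
            )
        )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Grouped bar chart of scores per tissue/day, one bar per treatment."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        pivot = self.scores.pivot_table(
            index=["tissue", "day"], columns="treatment", values="score", observed=True
        )
        pivot = pivot.reindex(columns=[t for t in TREATMENTS if t in pivot.columns])
        pivot.plot.bar(ax=ax, rot=30)
        ax.set_ylabel("IBR-T score")
        ax.set_xlabel("(tissue, day)")
        return ax


def compute_ibrt(data: pd.DataFrame, **kwargs) -> IBRTResults:
    """One-call convenience: ``IBRT(data, **kwargs).fit()``."""
    return IBRT(data, **kwargs).fit()
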