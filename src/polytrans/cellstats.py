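"""Group effect sizes for per-cell fluorescence and per-axon ribosome density.

Metabolic labelling (AHA incorporation) gives a mean fluorescence intensity
per neuron; electron microscopy gives ribosome counts and areas per axon
profile.  Both are summarised as a percent decrease of the case-group mean
relative to control, with a Student's t test.  For intensities two units of
analysis are reported side by side: pooled cells (cells from all
preparations pooled per genotype, the default) and replicate means (one
value per preparation), acknowledging the pseudo-replication debate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

CELL_COLUMNS = ("replicate_id", "genotype", "cell_id", "mean_intensity")
AXON_COLUMNS = ("mouse_id", "genotype", "axon_id", "ribosome_count", "axon_area")


@dataclass
class CellIntensityTable:
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CELL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"cell intensity table missing columns {missing}")
        if (self.data["mean_intensity"] < 0).any():
            raise ValueError("intensities must be >= 0")


@dataclass
class AxonCountTable:
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in AXON_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"axon count table missing columns {missing}")
        counts = self.data["ribosome_count"]
        if (counts < 0).any() or not np.allclose(counts, counts.round()):
            raise ValueError("ribosome counts must be nonnegative integers")
        if (self.data["axon_area"] <= 0).any():
            raise ValueError("axon areas must be > 0")


def percent_decrease(ctrl_values: Sequence[float], case_values: Sequence[float]) -> float:
    """100 * (1 - mean(case) / mean(ctrl))."""
    ctrl = np.asarray(list(ctrl_values), dtype=float)
    case = np.asarray(list(case_values), dtype=float)
    if len(ctrl) == 0 or len(case) == 0:
        raise ValueError("both groups must be non-empty")
    m = ctrl.mean()
    if m <= 0:
        raise ValueError("control mean must be positive")
    return float(100.0 * (1.0 - case.mean() / m))


@dataclass
class GroupComparison:
    estimate_pct: float
    t: float
    df: float
    p: float
    n_ctrl: int
    n_case: int


@dataclass
class IntensityEffect:
    """Percent-decrease effect under both units of analysis."""

    pooled: GroupComparison
    replicate_means: GroupComparison
    per_replicate: pd.DataFrame   # replicate_id, genotype, n, mean, sem
    default_pooling: str = "pooled_cells"

    @property
    def estimate_pct(self) -> float:
        return self.pooled.estimate_pct


def _ttest(ctrl: np.ndarray, case: np.ndarray) -> GroupComparison:
    res = stats.ttest_ind(ctrl, case, equal_var=True)
    return GroupComparison(
        estimate_pct=percent_decrease(ctrl, case),
        t=float(res.statistic), df=float(res.df), p=float(res.pvalue),
        n_ctrl=len(ctrl), n_case=len(case))


def compare_intensities(table: CellIntensityTable,
                        ctrl_label: str = "control",
                        case_label: str = "SMA",
                        pooling: str = "pooled_cells") -> IntensityEffect:
    """Percent decrease in mean per-cell intensity, case vs control.

    Both pooling modes are always computed; `pooling` only selects which is
    the headline estimate.
    """
    if pooling not in ("pooled_cells", "replicate_means"):
        raise ValueError(f"unknown pooling {pooling!r}")
    df = table.data
    for label in (ctrl_label, case_label):
        if label not in set(df["genotype"]):
            raise ValueError(f"genotype {label!r} absent from table")
    ctrl = df.loc[df["genotype"] == ctrl_label, "mean_intensity"].to_numpy(float)
    case = df.loc[df["genotype"] == case_label, "mean_intensity"].to_numpy(float)
    if len(ctrl) < 2 or len(case) < 2:
        raise ValueError("need at least 2 cells per genotype")
    pooled = _ttest(ctrl, case)

    per_rep = (df.groupby(["genotype", "replicate_id"])["mean_intensity"]
                 .agg(n="count", mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)))
                 .reset_index())
    rep_ctrl = per_rep.loc[per_rep["genotype"] == ctrl_label, "mean"].to_numpy(float)
    rep_case = per_rep.loc[per_rep["genotype"] == case_label, "mean"].to_numpy(float)
    if len(rep_ctrl) >= 2 and len(rep_case) >= 2:
        rep = _ttest(rep_ctrl, rep_case)
    else:
        # with a single preparation per genotype only the estimate is defined
        rep = GroupComparison(
            estimate_pct=percent_decrease(rep_ctrl, rep_case),
            t=float("nan"), df=float("nan"), p=float("nan"),
            n_ctrl=len(rep_ctrl), n_case=len(rep_case))
    return IntensityEffect(pooled=pooled, replicate_means=rep,
                           per_replicate=per_rep, default_pooling=pooling)


@dataclass
class DensityEffect:
    densities: pd.DataFrame       # per-axon densities with genotype
    mean_ctrl: float
    mean_case: float
    estimate_pct: float
    t: float
    df: float
    p: float


def ribosome_density(table: AxonCountTable,
                     ctrl_label: str = "control",
                     case_label: str = "SMA") -> DensityEffect:
    """Per-axon ribosome density (count/area), percent decrease and t test."""
    df = table.data.copy()
    df["density"] = df["ribosome_count"] / df["axon_area"]
    ctrl = df.loc[df["genotype"] == ctrl_label, "density"].to_numpy(float)
    case = df.loc[df["genotype"] == case_label, "density"].to_numpy(float)
    if len(ctrl) < 2 or len(case) < 2:
        raise ValueError("need at least 2 axons per genotype")
    res = stats.ttest_ind(ctrl, case, equal_var=True)
    return DensityEffect(
        densities=df[["mouse_id", "genotype", "axon_id", "density"]],
        mean_ctrl=float(ctrl.mean()), mean_case=float(case.mean()),
        estimate_pct=percent_decrease(ctrl, case),
        t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


@dataclass
class BackgroundCheck:
    at_background: bool
    p: float
    mean_treated: float
    mean_background: float
    alpha: float


def background_control(treated: Sequence[float], background: Sequence[float],
                       alpha: float = 0.05) -> BackgroundCheck:
    """Is a treated intensity distribution indistinguishable from background?

    Used for translation-inhibitor controls (e.g. anisomycin abolishing AHA
    signal): a two-sample t test that fails to reject at `alpha` flags the
    treated signal as at background level.
    """
    t = np.asarray(list(treated), dtype=float)
    b = np.asarray(list(background), dtype=float)
    if len(b) == 0:
        raise ValueError("background set is empty")
    if len(t) == 0:
        raise ValueError("treated set is empty")
    if t.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        p = 1.0 if t.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(t, b, equal_var=True).pvalue)
    return BackgroundCheck(at_background=p >= alpha, p=p,
                           mean_treated=float(t.mean()),
                           mean_background=float(b.mean()), alpha=alpha)
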