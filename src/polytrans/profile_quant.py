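"""Quantification of polysome profiles.

A sucrose-gradient absorbance trace (A254 vs. gradient position) is turned
into per-region areas — RNP, 40S, 60S, 80S and polysomes — and the FRP
statistic, the fraction of ribosomes engaged on polysomes:

    FRP = AUC(polysomes) / (AUC(polysomes) + AUC(80S))

Lighter species (RNP, 40S, 60S) are excluded from the denominator by
definition: they contain no assembled ribosome.  Downstream helpers compare
FRP between groups (Student's t), correlate FRP with phenotype (Pearson and
Spearman), normalise phenotypes to stage-matched controls, and cluster
animals on standardized (FRP, relative weight, relative righting time) with
Euclidean distances and the Ward.D agglomeration rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.cluster.hierarchy import fcluster

#: canonical region order on a gradient, light to heavy
REGIONS = ("RNP", "40S", "60S", "80S", "POLYSOMES")

#: species carrying assembled ribosomes, used by the FRP denominator
RIBOSOMAL_REGIONS = ("80S", "POLYSOMES")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PolysomeProfile:
    """An A254 absorbance trace with per-point fraction assignment.

    positions are in arbitrary gradient coordinates (monotone with sucrose
    density, light to heavy); absorbance in absorbance units; fraction_index
    is 1-based, mirroring fraction numbering on collected gradients.
    """

    positions: np.ndarray
    absorbance: np.ndarray
    fraction_index: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.fraction_index = np.asarray(self.fraction_index, dtype=int)
        n = len(self.positions)
        if not (len(self.absorbance) == len(self.fraction_index) == n):
            raise ValueError("positions, absorbance and fraction_index must have equal length")
        diffs = np.diff(self.positions)
        if np.any(diffs <= 0):
            row = int(np.argmax(diffs <= 0)) + 1
            raise ValueError(f"positions must be strictly increasing (first violation at row {row})")
        if np.any(np.diff(self.fraction_index) < 0):
            row = int(np.argmax(np.diff(self.fraction_index) < 0)) + 1
            raise ValueError(f"fraction_index must be nondecreasing (first violation at row {row})")

    def __len__(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.positions, "absorbance": self.absorbance,
             "fraction_index": self.fraction_index}
        )


@dataclass
class PeakSegmentation:
    """Region boundaries over a profile, in trace coordinates.

    regions maps region name -> (start, end); regions are ordered,
    non-overlapping and the 80S region precedes POLYSOMES.
    """

    regions: dict
    detected_peak_positions: list
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -math.inf
        for name, (start, end) in self.regions.items():
            if end < start:
                raise ValueError(f"region {name} has end < start")
            if start < prev_end:
                raise ValueError(f"region {name} overlaps preceding region")
            prev_end = end
        names = list(self.regions)
        if "80S" in names and "POLYSOMES" in names:
            if names.index("80S") > names.index("POLYSOMES"):
                raise ValueError("80S region must precede POLYSOMES")


@dataclass
class RegionAreas:
    """Trapezoidal AUC per region on the baseline-corrected trace."""

    area: dict
    baseline_model: dict = field(default_factory=dict)
    qc_flags: list = field(default_factory=list)


@dataclass
class FRPResult:
    """Fraction of ribosomes in polysomes for one sample."""

    frp: float
    metadata: dict = field(default_factory=dict)
    qc_flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.frp <= 1.0):
            raise ValueError(f"FRP must lie in [0, 1], got {self.frp}")


@dataclass
class PhenotypeRecord:
    """Per-mouse phenotype: body weight and righting-reflex time.

    Righting time is capped at 30 s — the assay is terminated when a pup
    takes longer than 30 s to right itself.
    """

    mouse_id: str
    genotype: str
    stage: str
    treatment: str
    weight: float
    righting_time: float
    relative_weight: float | None = None
    relative_righting: float | None = None

    def __post_init__(self) -> None:
        if self.righting_time > 30.0:
            raise ValueError("righting_time exceeds the 30 s assay cap")
        if self.righting_time <= 0:
            raise ValueError("righting_time must be positive")


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    tails: str
    flags: list = field(default_factory=list)


@dataclass
class CorrelationResult:
    pearson_r: float | None
    pearson_p: float | None
    spearman_rho: float | None
    spearman_p: float | None
    n: int


@dataclass
class ClusteringResult:
    """Ward.D tree: scipy-style linkage matrix plus flat labels."""

    linkage: np.ndarray           # (n-1, 4): id_a, id_b, height, size
    labels: np.ndarray            # flat cluster labels at `k`
    k: int
    mouse_ids: list
    standardized: pd.DataFrame


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

PROFILE_COLUMNS = ("position", "absorbance", "fraction_index")


def read_profile(path: str | Path, dialect: str = "tsv",
                 metadata: Mapping | None = None) -> PolysomeProfile:
    """Read a 3-column profile table (position, absorbance, fraction_index)."""
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return PolysomeProfile(
        positions=df["position"].to_numpy(),
        absorbance=df["absorbance"].to_numpy(),
        fraction_index=df["fraction_index"].to_numpy(),
        metadata=dict(metadata or {}),
    )


def write_profile(profile: PolysomeProfile, path: str | Path,
                  dialect: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    profile.to_frame().to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# trace processing
# ---------------------------------------------------------------------------

def correct_baseline(profile: PolysomeProfile,
                     anchors: Sequence[float] | None = None,
                     window_frac: float = 0.02) -> PolysomeProfile:
    """Subtract a linear baseline anchored at flat ends of the trace.

    A line through the median absorbance of two anchor windows (by default
    the first and last 2% of points) is removed.  Negative residuals are
    preserved; clamping is deferred to region integration so that noise is
    not rectified before averaging.
    """
    n = len(profile)
    if n < 10:
        raise ValueError("trace too short for baseline correction (need >= 10 points)")
    pos, absb = profile.positions, profile.absorbance
    if anchors is None:
        w = max(2, int(round(window_frac * n)))
        idx_lo = np.arange(w)
        idx_hi = np.arange(n - w, n)
    else:
        if len(anchors) != 2:
            raise ValueError("anchors must be two positions")
        lo, hi = sorted(anchors)
        if lo < pos[0] or hi > pos[-1]:
            raise ValueError("anchor positions outside trace bounds")
        half = window_frac * (pos[-1] - pos[0]) / 2
        idx_lo = np.where(np.abs(pos - lo) <= half)[0]
        idx_hi = np.where(np.abs(pos - hi) <= half)[0]
        if len(idx_lo) == 0 or len(idx_hi) == 0:
            raise ValueError("anchor windows contain no trace points")
    x0, y0 = np.median(pos[idx_lo]), np.median(absb[idx_lo])
    x1, y1 = np.median(pos[idx_hi]), np.median(absb[idx_hi])
    slope = (y1 - y0) / (x1 - x0)
    baseline = y0 + slope * (pos - x0)
    meta = dict(profile.metadata)
    meta["baseline_model"] = {"slope": float(slope), "intercept": float(y0 - slope * x0),
                              "anchors": (float(x0), float(x1))}
    return PolysomeProfile(pos.copy(), absb - baseline, profile.fraction_index.copy(), meta)


def segment_peaks(profile: PolysomeProfile,
                  expected_species: Sequence[str] = ("RNP", "40S", "60S", "80S"),
                  min_prominence: float | None = None,
                  smooth_window: int | None = None) -> PeakSegmentation:
    """Assign detected maxima to species and place boundaries at valleys.

    The first len(expected_species) local maxima (light to heavy) are
    assigned in order; each boundary sits at the absorbance minimum between
    adjacent assigned peaks.  Everything from the valley after the last
    expected species (normally 80S) to the end of the trace is the
    POLYSOMES region.  When no maximum is detected past the last species the
    POLYSOMES region has zero width at the trace end.

    Detection and valley location run on a Savitzky-Golay smoothed copy of
    the trace (window auto-sized to ~1% of the trace, disable with
    ``smooth_window=0``) so detector noise does not spawn spurious maxima;
    reported boundaries are positions on the original grid.
    """
    pos = profile.positions
    raw = profile.absorbance
    n = len(raw)
    if smooth_window is None:
        smooth_window = min(max(5, (n // 100) | 1), n - 1 if (n - 1) % 2 else n - 2)
    if smooth_window and smooth_window >= 5:
        absb = signal.savgol_filter(raw, smooth_window, polyorder=3)
    else:
        absb = raw
    if min_prominence is None:
        span = float(absb.max() - absb.min())
        min_prominence = 0.02 * span if span > 0 else 0.0
    peaks, props = signal.find_peaks(absb, prominence=min_prominence)
    if len(peaks) == 0:
        raise ValueError("no peaks detected in trace")
    k = len(expected_species)
    if len(peaks) < k:
        detected = [float(pos[i]) for i in peaks]
        raise ValueError(
            f"expected {k} species {list(expected_species)} but detected only "
            f"{len(peaks)} peaks at positions {detected}")

    flags: list[str] = []
    species_peaks = peaks[:k]
    regions: dict[str, tuple[float, float]] = {}
    start_idx = 0
    for i, name in enumerate(expected_species):
        if i + 1 < k:
            nxt = species_peaks[i + 1]
        elif len(peaks) > k:
            nxt = peaks[k]          # first polysomal peak
        else:
            nxt = None
        if nxt is not None:
            valley = int(species_peaks[i] + np.argmin(absb[species_peaks[i]:nxt + 1]))
            if absb[species_peaks[i]] - absb[valley] < min_prominence:
                flags.append(f"shallow_valley_after_{name}")
            regions[name] = (float(pos[start_idx]), float(pos[valley]))
            start_idx = valley
        else:
            regions[name] = (float(pos[start_idx]), float(pos[-1]))
            start_idx = len(pos) - 1
    if nxt is not None:
        regions["POLYSOMES"] = (float(pos[start_idx]), float(pos[-1]))
    else:
        regions["POLYSOMES"] = (float(pos[-1]), float(pos[-1]))
        flags.append("polysome_region_empty")
    return PeakSegmentation(regions=regions,
                            detected_peak_positions=[float(pos[i]) for i in peaks],
                            flags=flags)


def integrate_regions(profile: PolysomeProfile,
                      segmentation: PeakSegmentation) -> RegionAreas:
    """Trapezoidal AUC per segmented region.

    Negative areas (noisy tails dipping below baseline) are clamped to zero
    and flagged rather than rejected.
    """
    pos, absb = profile.positions, profile.absorbance
    areas: dict[str, float] = {}
    flags: list[str] = []
    for name, (start, end) in segmentation.regions.items():
        if start < pos[0] - 1e-12 or end > pos[-1] + 1e-12:
            raise ValueError(f"region {name} [{start}, {end}] outside trace bounds")
        mask = (pos >= start) & (pos <= end)
        if mask.sum() < 2:
            areas[name] = 0.0
            continue
        a = float(np.trapezoid(absb[mask], pos[mask]))
        if a < 0:
            flags.append(f"negative_area_clamped_{name}")
            a = 0.0
        areas[name] = a
    return RegionAreas(area=areas,
                       baseline_model=profile.metadata.get("baseline_model", {}),
                       qc_flags=flags)


def compute_frp(areas: RegionAreas) -> FRPResult:
    """FRP = polysome AUC / (polysome AUC + 80S AUC)."""
    for region in RIBOSOMAL_REGIONS:
        if region not in areas.area:
            raise ValueError(f"region areas missing {region}")
    a_poly = areas.area["POLYSOMES"]
    a_80s = areas.area["80S"]
    denom = a_poly + a_80s
    if denom == 0:
        raise ValueError("FRP undefined: polysome and 80S areas are both zero")
    return FRPResult(frp=a_poly / denom, qc_flags=list(areas.qc_flags))


def polysome_monosome_ratio(areas: RegionAreas) -> float:
    """P/M ratio variant (polysome AUC / 80S AUC); not used by FRP."""
    a_80s = areas.area["80S"]
    if a_80s == 0:
        raise ValueError("P/M ratio undefined: 80S area is zero")
    return areas.area["POLYSOMES"] / a_80s


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def _frp_values(group: Iterable) -> np.ndarray:
    vals = [g.frp if isinstance(g, FRPResult) else float(g) for g in group]
    return np.asarray(vals, dtype=float)


def compare_frp(group_a: Iterable, group_b: Iterable,
                tails: str = "two") -> TTestResult:
    """Student's t test on FRP values.

    ``tails="one"`` tests the alternative mean(group_a) > mean(group_b);
    order the arguments accordingly.  Two groups with zero variance and
    equal means return p = 1 with a flag instead of NaN.
    """
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    a, b = _frp_values(group_a), _frp_values(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    flags: list[str] = []
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        return TTestResult(t=0.0, df=len(a) + len(b) - 2, p=1.0,
                           mean_a=float(a.mean()), mean_b=float(b.mean()),
                           tails=tails, flags=["zero_variance_equal_means"])
    alternative = "two-sided" if tails == "two" else "greater"
    res = stats.ttest_ind(a, b, equal_var=True, alternative=alternative)
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue),
                       mean_a=float(a.mean()), mean_b=float(b.mean()),
                       tails=tails, flags=flags)


def correlate_phenotype(frp: Sequence[float] | Mapping[str, float],
                        phenotype: Sequence[float] | Mapping[str, float],
                        method: str = "both") -> CorrelationResult:
    """Pearson and Spearman correlation between FRP and a phenotype."""
    if isinstance(frp, Mapping) and isinstance(phenotype, Mapping):
        ids = sorted(set(frp) & set(phenotype))
        if len(ids) < len(frp) or len(ids) < len(phenotype):
            missing = sorted(set(frp) ^ set(phenotype))
            raise ValueError(f"unmatched ids between FRP and phenotype: {missing}")
        x = np.array([frp[i] for i in ids], dtype=float)
        y = np.array([phenotype[i] for i in ids], dtype=float)
    else:
        x = np.asarray(list(frp), dtype=float)
        y = np.asarray(list(phenotype), dtype=float)
        if len(x) != len(y):
            raise ValueError("FRP and phenotype vectors differ in length")
    if len(x) < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method not in ("pearson", "spearman", "both"):
        raise ValueError(f"unknown method {method!r}")
    pr = pp = sr = sp = None
    if method in ("pearson", "both"):
        r = stats.pearsonr(x, y)
        pr, pp = float(r.statistic), float(r.pvalue)
    if method in ("spearman", "both"):
        r = stats.spearmanr(x, y)
        sr, sp = float(r.statistic), float(r.pvalue)
    return CorrelationResult(pearson_r=pr, pearson_p=pp,
                             spearman_rho=sr, spearman_p=sp, n=len(x))


def relative_phenotype(records: Sequence[PhenotypeRecord],
                       control_selector=lambda r: r.genotype == "control",
                       ) -> list[PhenotypeRecord]:
    """Fill relative_weight / relative_righting vs stage-matched control means."""
    by_stage: dict[str, list[PhenotypeRecord]] = {}
    for r in records:
        by_stage.setdefault(r.stage, []).append(r)
    out: list[PhenotypeRecord] = []
    for stage, recs in by_stage.items():
        controls = [r for r in recs if control_selector(r)]
        if not controls:
            raise ValueError(f"no control records in stage {stage!r}")
        w_mean = float(np.mean([r.weight for r in controls]))
        t_mean = float(np.mean([r.righting_time for r in controls]))
        for r in recs:
            out.append(PhenotypeRecord(
                mouse_id=r.mouse_id, genotype=r.genotype, stage=r.stage,
                treatment=r.treatment, weight=r.weight,
                righting_time=r.righting_time,
                relative_weight=r.weight / w_mean,
                relative_righting=r.righting_time / t_mean,
            ))
    return out


# ---------------------------------------------------------------------------
# hierarchical clustering (Ward.D)
# ---------------------------------------------------------------------------

def ward_d_linkage(points: np.ndarray) -> np.ndarray:
    """Agglomerate with the Ward.D rule on *unsquared* Euclidean distances.

    This is the Lance-Williams Ward update applied directly to the raw
    Euclidean distance matrix (the behaviour of the method named "Ward.D",
    as opposed to "Ward.D2" which squares distances first — the variant
    scipy's ``linkage(..., 'ward')`` implements).  Returns a scipy-style
    linkage matrix.  O(n^3); intended for cohort-sized inputs.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 2:
        raise ValueError("need at least 2 points")
    # active cluster id -> (current index bookkeeping)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d[i, j]
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    Z = np.zeros((n - 1, 4))
    next_id = n

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    for step in range(n - 1):
        # ties broken by smallest pair of cluster ids, deterministically
        best = min(((get(i, j), i, j) for i in active for j in active if i < j),
                   key=lambda t: (t[0], t[1], t[2]))
        h, a, b = best
        na, nb = sizes[a], sizes[b]
        for c in active:
            if c in (a, b):
                continue
            nc = sizes[c]
            tot = na + nb + nc
            new = ((na + nc) / tot * get(a, c)
                   + (nb + nc) / tot * get(b, c)
                   - nc / tot * h)
            key = (min(a, c), max(a, c))
            dist[key] = new
        active.discard(a)
        active.discard(b)
        # reuse slot `a` keyed distances under the new id via remap
        for c in list(active):
            key_old = (min(a, c), max(a, c))
            dist[(min(next_id, c), max(next_id, c))] = dist.pop(key_old)
            dist.pop((min(b, c), max(b, c)), None)
        sizes[next_id] = na + nb
        active.add(next_id)
        Z[step] = (min(a, b), max(a, b), h, na + nb)
        next_id += 1
    return Z


def cluster_mice(table: pd.DataFrame, k: int = 2,
                 variables: Sequence[str] = ("frp", "relative_weight", "relative_righting"),
                 ) -> ClusteringResult:
    """Ward.D/Euclidean clustering of mice on standardized variables.

    Each variable is rescaled to zero mean and unit standard deviation so
    FRP (a fraction) and phenotypes (grams, seconds) weigh equally.
    """
    missing_cols = [v for v in variables if v not in table.columns]
    if missing_cols:
        raise ValueError(f"table missing variables {missing_cols}")
    sub = table.loc[:, list(variables)]
    bad = sub.index[sub.isna().any(axis=1)].tolist()
    if bad:
        raise ValueError(f"missing values for mice {bad}")
    if len(sub) < 3:
        raise ValueError("need at least 3 mice to cluster")
    std = sub.std(ddof=1)
    if (std == 0).any():
        zero = std.index[std == 0].tolist()
        raise ValueError(f"constant variables cannot be standardized: {zero}")
    z = (sub - sub.mean()) / std
    Z = ward_d_linkage(z.to_numpy())
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusteringResult(linkage=Z, labels=labels, k=k,
                            mouse_ids=list(sub.index), standardized=z)
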