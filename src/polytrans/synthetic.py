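"""Synthetic inputs with analytically known ground truth.

Every table the analysis modules consume can be generated here: gradient
absorbance traces (Gaussian peaks for RNP, 40S, 60S, 80S and polysomes on a
linear baseline), mouse cohorts with FRP-coupled phenotypes, per-fraction
co-sedimentation lanes, paired polysomal/total count matrices with planted
TE shifts, qPCR Ct tables, per-cell fluorescence intensities and per-axon
ribosome counts.  Each generator records the quantities a perfect analysis
would recover (region areas in closed form, the true FRP, planted effect
sizes and log2 dTE values) so estimator accuracy can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from polytrans.cellstats import AxonCountTable, CellIntensityTable
from polytrans.cosedimentation import CosedTable, default_fraction_regions
from polytrans.profile_quant import PhenotypeRecord, PolysomeProfile, REGIONS

SQRT_2PI = np.sqrt(2.0 * np.pi)

#: species assigned to the leading peaks, light to heavy; any further peak
#: is polysomal (consistent with the FRP denominator using 80S + polysomes)
LEADING_SPECIES = ("RNP", "40S", "60S", "80S")


# ---------------------------------------------------------------------------
# gradient model
# ---------------------------------------------------------------------------

@dataclass
class GradientModel:
    """Parametric A254 profile: Gaussian peaks on a linear baseline.

    The first four peaks are RNP, 40S, 60S and 80S; remaining peaks are
    polysomal (at least two, emulating di-/tri-/higher-order polysomes).
    Positions are in arbitrary gradient units spanning [0, length], with
    light material at low positions as on a linear 15%-50% sucrose
    gradient read top-down.
    """

    peak_centers: tuple = (1.0, 2.2, 3.0, 3.9, 5.2, 6.2, 7.2, 8.3)
    peak_widths: tuple = (0.30, 0.18, 0.20, 0.25, 0.28, 0.30, 0.32, 0.35)
    peak_amplitudes: tuple = (0.90, 0.35, 0.45, 1.20, 1.00, 0.70, 0.45, 0.30)
    baseline_slope: float = 0.02
    baseline_offset: float = 0.05
    noise_sd: float = 0.0
    n_points: int = 2000
    fraction_count: int = 12
    length: float = 10.0
    exponential_tail: float = 0.0   # optional skew (0 = symmetric, default)

    def __post_init__(self) -> None:
        k = len(self.peak_centers)
        if len(self.peak_widths) != k or len(self.peak_amplitudes) != k:
            raise ValueError("peak_centers, peak_widths, peak_amplitudes must have equal length")
        if k < len(LEADING_SPECIES) + 2:
            raise ValueError("need RNP/40S/60S/80S plus at least 2 polysome peaks")
        if any(a < 0 for a in self.peak_amplitudes):
            raise ValueError("amplitudes must be >= 0")
        if any(w <= 0 for w in self.peak_widths):
            raise ValueError("widths must be > 0")
        if any(c2 <= c1 for c1, c2 in zip(self.peak_centers, self.peak_centers[1:])):
            raise ValueError("peak centers must be strictly increasing")
        if self.fraction_count < 4:
            raise ValueError("fraction_count must be >= 4")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def species(self) -> list:
        k = len(self.peak_centers)
        return list(LEADING_SPECIES) + [f"P{i + 1}" for i in range(k - len(LEADING_SPECIES))]

    def overlapping_pairs(self) -> list:
        """Adjacent peaks closer than the sum of their widths."""
        out = []
        for i in range(len(self.peak_centers) - 1):
            gap = self.peak_centers[i + 1] - self.peak_centers[i]
            if gap < self.peak_widths[i] + self.peak_widths[i + 1]:
                out.append((self.species[i], self.species[i + 1]))
        return out

    def noiseless_trace(self, positions: np.ndarray) -> np.ndarray:
        y = self.baseline_offset + self.baseline_slope * positions
        for c, w, a in zip(self.peak_centers, self.peak_widths, self.peak_amplitudes):
            g = a * np.exp(-0.5 * ((positions - c) / w) ** 2)
            if self.exponential_tail > 0:
                # exponentially modified peak: convolution surrogate via skew
                g = a * np.exp(-0.5 * ((positions - c) / w) ** 2) \
                    * (1 + self.exponential_tail * np.clip(positions - c, 0, None) / w)
            y = y + g
        return y


@dataclass
class GroundTruth:
    """Analytic quantities the estimators should recover."""

    true_region_areas: dict = field(default_factory=dict)
    true_frp: float | None = None
    true_effect_sizes: dict = field(default_factory=dict)   # contrast -> percent
    true_te_shifts: dict = field(default_factory=dict)      # gene -> log2 units
    per_sample_frp: dict = field(default_factory=dict)      # mouse -> frp
    flags: list = field(default_factory=list)


def _gaussian_area(amplitude: float, sigma: float) -> float:
    return amplitude * sigma * SQRT_2PI


def _ground_truth_areas(model: GradientModel) -> dict:
    areas = dict.fromkeys(REGIONS, 0.0)
    for name, w, a in zip(model.species, model.peak_widths, model.peak_amplitudes):
        region = name if name in LEADING_SPECIES else "POLYSOMES"
        areas[region] += _gaussian_area(a, w)
    return areas


def simulate_profile(model: GradientModel, seed: int = 0,
                     metadata: Mapping | None = None
                     ) -> tuple[PolysomeProfile, GroundTruth]:
    """Sample one absorbance trace and its closed-form ground truth.

    The trace is baseline + sum of Gaussians + N(0, noise_sd); region areas
    in the ground truth are exact Gaussian integrals (amplitude * sigma *
    sqrt(2 pi)), valid as long as peaks sit well inside the trace span.
    Identical model and seed give byte-identical output.
    """
    rng = np.random.default_rng(seed)
    positions = np.linspace(0.0, model.length, model.n_points)
    y = model.noiseless_trace(positions)
    if model.noise_sd > 0:
        y = y + rng.normal(0.0, model.noise_sd, size=model.n_points)
    # 1-based equal-width fractions spanning the trace
    frac = np.minimum(
        (positions / model.length * model.fraction_count).astype(int) + 1,
        model.fraction_count)
    areas = _ground_truth_areas(model)
    flags = []
    for pair in model.overlapping_pairs():
        flags.append(f"overlapping_peaks_{pair[0]}_{pair[1]}")
    denom = areas["POLYSOMES"] + areas["80S"]
    if denom == 0:
        frp = None
        flags.append("frp_undefined")
    else:
        frp = areas["POLYSOMES"] / denom
    profile = PolysomeProfile(positions, y, frac, metadata=dict(metadata or {}))
    return profile, GroundTruth(true_region_areas=areas, true_frp=frp, flags=flags)


def model_with_frp(base: GradientModel, target_frp: float) -> GradientModel:
    """Rescale polysome amplitudes of `base` so true FRP equals `target_frp`."""
    if not (0.0 < target_frp < 1.0):
        raise ValueError("target FRP must be in (0, 1)")
    areas = _ground_truth_areas(base)
    a80, apoly = areas["80S"], areas["POLYSOMES"]
    if a80 == 0 or apoly == 0:
        raise ValueError("base model needs nonzero 80S and polysome peaks")
    scale = (target_frp / (1.0 - target_frp)) * a80 / apoly
    n_lead = len(LEADING_SPECIES)
    amps = tuple(a if i < n_lead else a * scale
                 for i, a in enumerate(base.peak_amplitudes))
    return replace(base, peak_amplitudes=amps)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortGroupSpec:
    """Distribution of true FRP in a group and its phenotype couplings.

    weight  = weight_intercept  + weight_slope  * FRP + N(0, weight_noise_sd)
    righting = righting_intercept + righting_slope * FRP + N(0, righting_noise_sd),
    capped at the 30 s assay termination (after noise) and floored just
    above zero.  Defaults emulate neonatal SMA-model litters: healthy pups
    right in a few seconds at normal weight, affected pups are lighter and
    slower with lower FRP.
    """

    frp_mean: float
    frp_sd: float
    genotype: str = "control"
    stage: str = "late"
    treatment: str = "none"
    weight_intercept: float = 1.5
    weight_slope: float = 6.0          # g per unit FRP
    weight_noise_sd: float = 0.3
    righting_intercept: float = 33.0
    righting_slope: float = -38.0      # s per unit FRP
    righting_noise_sd: float = 2.0


def default_cohort_specs() -> dict:
    """Late-symptomatic two-group design: control vs SMA."""
    return {
        "control": CohortGroupSpec(frp_mean=0.75, frp_sd=0.04, genotype="control"),
        "SMA": CohortGroupSpec(frp_mean=0.55, frp_sd=0.06, genotype="SMA"),
    }


def simulate_cohort(group_specs: Mapping[str, CohortGroupSpec] | None = None,
                    n_per_group: Mapping[str, int] | int = 6,
                    seed: int = 0,
                    base_model: GradientModel | None = None,
                    profile_noise_sd: float = 0.01,
                    allow_large_groups: bool = False,
                    ) -> tuple[list, list, GroundTruth]:
    """Simulate per-mouse profiles and FRP-coupled phenotypes.

    Group sizes default to the replicate range used for tissue profiling
    (3-9 per group); pass allow_large_groups=True to override.  Per-mouse
    true FRP is drawn from the group distribution truncated to (0, 1); the
    mouse's profile is the base gradient model rescaled to that FRP.
    """
    specs = dict(group_specs) if group_specs is not None else default_cohort_specs()
    if isinstance(n_per_group, int):
        n_per_group = {g: n_per_group for g in specs}
    for g, n in n_per_group.items():
        if n <= 0:
            raise ValueError(f"group {g!r} has nonpositive size {n}")
        if not allow_large_groups and not (3 <= n <= 9):
            raise ValueError(
                f"group {g!r} size {n} outside the replicate range 3-9 "
                "(set allow_large_groups=True to override)")
    base = base_model if base_model is not None else GradientModel()
    rng = np.random.default_rng(seed)
    profiles: list[PolysomeProfile] = []
    records: list[PhenotypeRecord] = []
    per_sample_frp: dict[str, float] = {}
    for gname in sorted(specs):
        spec = specs[gname]
        for i in range(n_per_group[gname]):
            mouse = f"{gname}_{i + 1:02d}"
            frp = float(np.clip(rng.normal(spec.frp_mean, spec.frp_sd), 1e-3, 1 - 1e-3))
            model = replace(model_with_frp(base, frp), noise_sd=profile_noise_sd)
            prof, _ = simulate_profile(
                model, seed=int(rng.integers(0, 2**31 - 1)),
                metadata={"sample": mouse, "genotype": spec.genotype,
                          "stage": spec.stage, "treatment": spec.treatment})
            weight = spec.weight_intercept + spec.weight_slope * frp \
                + rng.normal(0.0, spec.weight_noise_sd)
            righting = spec.righting_intercept + spec.righting_slope * frp \
                + rng.normal(0.0, spec.righting_noise_sd)
            righting = float(np.clip(righting, 0.5, 30.0))
            records.append(PhenotypeRecord(
                mouse_id=mouse, genotype=spec.genotype, stage=spec.stage,
                treatment=spec.treatment, weight=max(weight, 0.1),
                righting_time=righting))
            profiles.append(prof)
            per_sample_frp[mouse] = frp
    return profiles, records, GroundTruth(per_sample_frp=per_sample_frp)


# ---------------------------------------------------------------------------
# co-sedimentation
# ---------------------------------------------------------------------------

def simulate_cosed(region_distribution: Mapping[str, Mapping[str, float]],
                   lane_noise_cv: float = 0.0,
                   fraction_count: int = 12,
                   seed: int = 0,
                   sample: str = "s1",
                   total_signal: float = 100.0) -> CosedTable:
    """Per-fraction densitometry lanes from per-region signal shares.

    Each protein's share of a region is spread uniformly over that region's
    fractions, then multiplied by lognormal lane noise with coefficient of
    variation `lane_noise_cv` (multiplicative, so intensities stay >= 0).
    """
    rng = np.random.default_rng(seed)
    regions = default_fraction_regions(fraction_count)
    frac_of_region: dict[str, list[int]] = {}
    for f, r in regions.items():
        frac_of_region.setdefault(r, []).append(f)
    rows = []
    for protein in sorted(region_distribution):
        shares = region_distribution[protein]
        if any(v < 0 for v in shares.values()):
            raise ValueError(f"negative share for protein {protein!r}")
        total = sum(shares.values())
        if total == 0:
            raise ValueError(f"all-zero shares for protein {protein!r}")
        for f in range(1, fraction_count + 1):
            region = regions[f]
            share = shares.get(region, 0.0) / total
            mean_int = total_signal * share / len(frac_of_region[region])
            if lane_noise_cv > 0:
                s2 = np.log1p(lane_noise_cv**2)
                noise = rng.lognormal(-s2 / 2, np.sqrt(s2))
            else:
                noise = 1.0
            rows.append((protein, sample, f, mean_int * noise))
    df = pd.DataFrame(rows, columns=["protein", "sample", "fraction_index", "intensity"])
    return CosedTable(data=df, fraction_regions=regions)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def simulate_counts(n_genes: int = 1000,
                    n_samples_per_group: int = 4,
                    baseline_log2_mean_range: tuple = (3.0, 10.0),
                    dispersion: float = 0.1,
                    te_shift_spec: Mapping[str, float] | None = None,
                    library_size_range: tuple = (0.8, 1.2),
                    seed: int = 0):
    """Paired POL/TOT negative-binomial count matrices with planted TE shifts.

    Total-RNA means are shared across groups (no transcriptional change);
    polysomal means equal the total means except that genes in
    `te_shift_spec` have their case-group polysomal mean multiplied by
    2**log2dTE.  Returns (CountMatrixPair, GroundTruth).
    """
    from polytrans.translatome import CountMatrixPair  # local import, no cycle at module load

    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    lo, hi = library_size_range
    if lo <= 0 or hi <= 0:
        raise ValueError("library sizes must be > 0")
    te_shift_spec = dict(te_shift_spec or {})
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    unknown = set(te_shift_spec) - set(genes)
    if unknown:
        raise ValueError(f"te_shift_spec genes outside the gene set: {sorted(unknown)}")
    base_mean = 2.0 ** rng.uniform(*baseline_log2_mean_range, size=n_genes)

    groups = ["control"] * n_samples_per_group + ["SMA"] * n_samples_per_group
    samples = [f"{g}_{i % n_samples_per_group + 1}" for i, g in enumerate(groups)]
    lib = rng.uniform(lo, hi, size=len(samples))

    shift = np.zeros(n_genes)
    for g, d in te_shift_spec.items():
        shift[genes.index(g)] = d

    r = 1.0 / dispersion

    def _nb(mu: np.ndarray) -> np.ndarray:
        p = r / (r + mu)
        return rng.negative_binomial(r, p)

    pol = np.empty((n_genes, len(samples)), dtype=int)
    tot = np.empty_like(pol)
    for j, grp in enumerate(groups):
        mu_tot = base_mean * lib[j]
        mu_pol = base_mean * lib[j] * (2.0 ** shift if grp == "SMA" else 1.0)
        tot[:, j] = _nb(mu_tot)
        pol[:, j] = _nb(mu_pol)

    pair = CountMatrixPair(
        pol=pd.DataFrame(pol, index=genes, columns=samples),
        tot=pd.DataFrame(tot, index=genes, columns=samples),
        groups=pd.Series(groups, index=samples))
    return pair, GroundTruth(true_te_shifts=te_shift_spec)


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def simulate_qpcr(true_fold_changes: Mapping[str, Mapping[str, float]],
                  ct_noise_sd: float = 0.0,
                  reference_genes: Sequence[str] = ("Actb", "Ppia"),
                  n_biological: int = 3,
                  n_technical: int = 3,
                  seed: int = 0):
    """Ct tables with planted case-vs-control fold changes per compartment.

    Ct = base_ct(gene) - log2(relative expression) + N(0, ct_noise_sd);
    the case group's relative expression is the planted fold change,
    reference genes have fold change 1 by construction.
    """
    from polytrans.translatome import CtTable

    if n_biological < 1 or n_technical < 1:
        raise ValueError("need at least 1 biological and 1 technical replicate")
    for gene, by_comp in true_fold_changes.items():
        for comp, fc in by_comp.items():
            if fc <= 0:
                raise ValueError(f"fold change must be > 0 ({gene}, {comp})")
    rng = np.random.default_rng(seed)
    genes = sorted(set(true_fold_changes) | set(reference_genes))
    base_ct = {g: rng.uniform(18.0, 26.0) for g in genes}
    rows = []
    for comp in ("POL", "TOT"):
        for group in ("control", "SMA"):
            for b in range(1, n_biological + 1):
                sample = f"{group}_{comp}_b{b}"
                for gene in genes:
                    if gene in reference_genes:
                        fc = 1.0
                    else:
                        fc = true_fold_changes[gene].get(comp, 1.0)
                    expr = fc if group == "SMA" else 1.0
                    true_ct = base_ct[gene] - np.log2(expr)
                    for t in range(1, n_technical + 1):
                        noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                        rows.append((gene, sample, group, comp, t, true_ct + noise))
    df = pd.DataFrame(rows, columns=["gene", "sample", "group", "compartment",
                                     "technical_replicate", "ct"])
    return CtTable(data=df)


# ---------------------------------------------------------------------------
# cell intensities and axon counts
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    s2 = np.log1p(cv**2)
    return np.log(mean) - s2 / 2, np.sqrt(s2)


def simulate_cell_intensities(percent_decrease: float,
                              n_per_replicate_ctrl: Sequence[int],
                              n_per_replicate_case: Sequence[int],
                              lognormal_cv: float = 0.4,
                              seed: int = 0,
                              ctrl_mean: float = 100.0) -> CellIntensityTable:
    """Per-cell lognormal AHA intensities with a planted mean decrease.

    The case-group mean is ctrl_mean * (1 - percent_decrease/100); each
    preparation (replicate) contributes the listed number of cells.
    """
    if not (0.0 <= percent_decrease < 100.0):
        raise ValueError("percent_decrease must be in [0, 100)")
    if len(n_per_replicate_ctrl) == 0 or len(n_per_replicate_case) == 0:
        raise ValueError("replicate lists must be non-empty")
    rng = np.random.default_rng(seed)
    case_mean = ctrl_mean * (1.0 - percent_decrease / 100.0)
    rows = []
    for genotype, mean, ns in (("control", ctrl_mean, n_per_replicate_ctrl),
                               ("SMA", case_mean, n_per_replicate_case)):
        mu, sig = _lognormal_params(mean, lognormal_cv)
        for r, n in enumerate(ns, start=1):
            vals = rng.lognormal(mu, sig, size=int(n))
            for c, v in enumerate(vals, start=1):
                rows.append((f"prep{r}", genotype, f"{genotype}_r{r}_c{c}", v))
    df = pd.DataFrame(rows, columns=["replicate_id", "genotype", "cell_id",
                                     "mean_intensity"])
    return CellIntensityTable(data=df)


def simulate_axon_counts(control_density: float = 50.0,
                         percent_decrease: float = 27.0,
                         area_mean: float = 1.0,
                         area_cv: float = 0.3,
                         n_axons_per_group: int = 30,
                         n_mice_per_group: int = 3,
                         seed: int = 0) -> AxonCountTable:
    """Poisson ribosome counts over lognormal axon areas.

    Per-axon count ~ Poisson(density * area); case-group density is
    control_density * (1 - percent_decrease/100).  Axons are split evenly
    across mice for bookkeeping only.
    """
    if control_density <= 0:
        raise ValueError("control_density must be > 0")
    if not (0.0 <= percent_decrease < 100.0):
        raise ValueError("percent_decrease must be in [0, 100)")
    if area_mean <= 0:
        raise ValueError("axon areas must be positive")
    rng = np.random.default_rng(seed)
    mu, sig = _lognormal_params(area_mean, area_cv)
    rows = []
    for genotype, density in (("control", control_density),
                              ("SMA", control_density * (1 - percent_decrease / 100.0))):
        areas = rng.lognormal(mu, sig, size=n_axons_per_group)
        counts = rng.poisson(density * areas)
        for i, (a, c) in enumerate(zip(areas, counts)):
            mouse = f"{genotype}_m{i % n_mice_per_group + 1}"
            rows.append((mouse, genotype, f"{genotype}_a{i + 1}", int(c), float(a)))
    df = pd.DataFrame(rows, columns=["mouse_id", "genotype", "axon_id",
                                     "ribosome_count", "axon_area"])
    return AxonCountTable(data=df)
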