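"""Translation efficiency from paired polysomal/total expression.

Translation efficiency (TE) of a transcript is its polysomal abundance
relative to its total cytoplasmic abundance; a change in TE between
conditions (log2 dTE) indicates altered ribosome engagement independent of
transcription.  Two routes are implemented:

* sequencing-style: paired count matrices (POL, TOT) are depth-normalized,
  log2TE = log2((pol + pseudo) / (tot + pseudo)) per gene and sample, and
  differential TE is assessed by a paired label-permutation test on the
  difference of group-mean log2TE (labels permuted jointly across both
  compartments so POL/TOT pairing is preserved), with BH FDR;

* qPCR: fold changes via the delta-delta-Ct method with two reference
  genes aggregated as the geometric mean of their expression (equivalently
  the arithmetic mean of their Ct values), and
  log2 dTE = log2(FC_polysomal) - log2(FC_total).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

CT_COLUMNS = ("gene", "sample", "group", "compartment", "technical_replicate", "ct")
COMPARTMENTS = ("POL", "TOT")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrixPair:
    """Matched polysomal and total count matrices (genes x samples)."""

    pol: pd.DataFrame
    tot: pd.DataFrame
    groups: pd.Series                      # sample -> group label
    gene_lengths: pd.Series | None = None  # in base pairs

    def __post_init__(self) -> None:
        if not self.pol.index.equals(self.tot.index):
            raise ValueError("POL and TOT matrices must share the same gene set/order")
        if not self.pol.columns.equals(self.tot.columns):
            raise ValueError("POL and TOT matrices must share the same sample pairing")
        for name, m in (("POL", self.pol), ("TOT", self.tot)):
            if (m.to_numpy() < 0).any():
                raise ValueError(f"{name} matrix contains negative counts")
        missing = set(self.pol.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")


@dataclass
class CtTable:
    """Long-format qPCR cycle thresholds.

    A sample is one biological replicate of one group; technical replicates
    are separate rows.  Every target gene must be co-measured with both
    reference genes in every sample where it appears.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"Ct table missing columns {missing}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be > 0")
        bad = set(self.data["compartment"]) - set(COMPARTMENTS)
        if bad:
            raise ValueError(f"unknown compartments {sorted(bad)}")


@dataclass
class TEResult:
    """Per-gene differential-TE table."""

    table: pd.DataFrame   # gene, log2TE_ctrl, log2TE_case, log2dTE, p, fdr, direction
    n_permutations: int
    exhaustive: bool

    def significant(self, alpha: float = 0.05, use_fdr: bool = False) -> pd.DataFrame:
        col = "fdr" if use_fdr else "p"
        return self.table[self.table[col] < alpha]


# ---------------------------------------------------------------------------
# normalization and TE
# ---------------------------------------------------------------------------

def normalize_expression(pair: CountMatrixPair, method: str = "cpm"
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Depth-normalize both compartments.

    ``cpm``: counts per million mapped.  ``length_scaled``: cpm further
    divided by gene length in kb (an FPKM-like quantity); requires
    gene_lengths.
    """
    if method not in ("cpm", "length_scaled"):
        raise ValueError(f"unknown method {method!r}")
    if method == "length_scaled" and pair.gene_lengths is None:
        raise ValueError("length_scaled normalization requires gene_lengths")

    def _norm(m: pd.DataFrame) -> pd.DataFrame:
        lib = m.sum(axis=0)
        if (lib <= 0).any():
            empty = lib.index[lib <= 0].tolist()
            raise ValueError(f"library size <= 0 for samples {empty}")
        out = m / lib * 1e6
        if method == "length_scaled":
            kb = pair.gene_lengths.reindex(m.index) / 1e3
            out = out.div(kb, axis=0)
        return out

    return _norm(pair.pol), _norm(pair.tot)


def compute_te(pol_norm: pd.DataFrame, tot_norm: pd.DataFrame,
               pseudo: float = 0.5) -> pd.DataFrame:
    """log2((pol + pseudo) / (tot + pseudo)), per gene and sample."""
    if (pol_norm.to_numpy() < 0).any() or (tot_norm.to_numpy() < 0).any():
        raise ValueError("normalized expression must be nonnegative")
    if not pol_norm.columns.equals(tot_norm.columns):
        raise ValueError("sample columns must match between compartments")
    return np.log2(pol_norm + pseudo) - np.log2(tot_norm + pseudo)


# ---------------------------------------------------------------------------
# permutation test for differential TE
# ---------------------------------------------------------------------------

def test_delta_te(te: pd.DataFrame, groups: Mapping[str, str] | pd.Series,
                  case: str = "SMA", control: str = "control",
                  n_permutations: int = 10_000,
                  seed: int | None = None,
                  max_exhaustive: int = 10_000) -> TEResult:
    """Permutation test on the per-gene difference of group-mean log2TE.

    The observed statistic is mean(log2TE over case samples) minus
    mean(over control samples).  The null distribution permutes the sample
    group labels; since log2TE is already the paired POL/TOT contrast, a
    single label permutation applies jointly to both compartments.  When
    the number of distinct label assignments is at most `max_exhaustive`
    they are enumerated exactly (the p-value is then the exact permutation
    p); otherwise `n_permutations` random permutations are drawn and an
    add-one correction keeps p > 0.
    """
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    samples = list(te.columns)
    labels = groups.reindex(samples)
    if labels.isna().any():
        raise ValueError(f"samples without group label: {labels.index[labels.isna()].tolist()}")
    case_idx = np.where(labels.to_numpy() == case)[0]
    ctrl_idx = np.where(labels.to_numpy() == control)[0]
    if len(case_idx) == 0 or len(ctrl_idx) == 0:
        raise ValueError(f"both groups {case!r} and {control!r} must be present")
    if len(case_idx) < 3 or len(ctrl_idx) < 3:
        warnings.warn("fewer than 3 samples per group: permutation p-values are coarse",
                      stacklevel=2)
    if n_permutations < 100:
        warnings.warn("n_permutations < 100 gives very coarse p-values", stacklevel=2)

    X = te.to_numpy(dtype=float)
    n = len(samples)
    k = len(case_idx)
    w = np.zeros(n)
    w[case_idx] = 1.0 / k
    w[ctrl_idx] = -1.0 / len(ctrl_idx)
    obs = X @ w

    pool = np.concatenate([case_idx, ctrl_idx])
    n_pool = len(pool)
    total_assignments = math.comb(n_pool, k)
    exhaustive = total_assignments <= max_exhaustive
    if exhaustive:
        W = np.empty((n, total_assignments))
        for j, combo in enumerate(combinations(range(n_pool), k)):
            wj = np.zeros(n)
            sel = pool[list(combo)]
            rest = np.setdiff1d(pool, sel)
            wj[sel] = 1.0 / k
            wj[rest] = -1.0 / len(rest)
            W[:, j] = wj
        null = X @ W                         # genes x assignments
        exceed = (np.abs(null) >= np.abs(obs)[:, None] - 1e-12).sum(axis=1)
        p = exceed / total_assignments       # identity assignment included
        n_used = total_assignments
    else:
        rng = np.random.default_rng(seed)
        W = np.empty((n, n_permutations))
        for j in range(n_permutations):
            perm = rng.permutation(pool)
            wj = np.zeros(n)
            wj[perm[:k]] = 1.0 / k
            wj[perm[k:]] = -1.0 / (n_pool - k)
            W[:, j] = wj
        null = X @ W
        exceed = (np.abs(null) >= np.abs(obs)[:, None] - 1e-12).sum(axis=1)
        p = (exceed + 1) / (n_permutations + 1)
        n_used = n_permutations

    fdr = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({
        "log2TE_ctrl": X[:, ctrl_idx].mean(axis=1),
        "log2TE_case": X[:, case_idx].mean(axis=1),
        "log2dTE": obs,
        "p": p,
        "fdr": fdr,
        "direction": np.where(obs >= 0, "up", "down"),
    }, index=te.index)
    return TEResult(table=out, n_permutations=n_used, exhaustive=exhaustive)


test_delta_te.__test__ = False   # a library function, not a pytest case


# ---------------------------------------------------------------------------
# qPCR delta-delta-Ct
# ---------------------------------------------------------------------------

def _mean_ct(ct: CtTable, compartment: str) -> pd.DataFrame:
    """Average technical replicates: one Ct per gene x sample."""
    sub = ct.data[ct.data["compartment"] == compartment]
    return (sub.groupby(["gene", "sample", "group"])["ct"].mean().reset_index())


def qpcr_fold_change(ct: CtTable, target_gene: str,
                     reference_genes: Sequence[str],
                     compartment: str,
                     case: str = "SMA", control: str = "control") -> float:
    """Fold change of a target vs control group by the delta-delta-Ct method.

    Per sample: dCt = Ct(target) - mean(Ct(references)); the arithmetic
    mean of reference Cts corresponds to the geometric mean of reference
    expression.  ddCt = mean dCt(case) - mean dCt(control); FC = 2^(-ddCt).
    Technical replicates are averaged before biological aggregation.
    """
    if compartment not in COMPARTMENTS:
        raise ValueError(f"compartment must be one of {COMPARTMENTS}")
    means = _mean_ct(ct, compartment)
    wide = means.pivot_table(index=["sample", "group"], columns="gene", values="ct")
    if target_gene not in wide.columns:
        raise ValueError(f"target gene {target_gene!r} not measured in {compartment}")
    target_samples = wide.index[wide[target_gene].notna()]
    for ref in reference_genes:
        if ref not in wide.columns:
            raise ValueError(f"reference gene {ref!r} absent from the table")
        missing = [s for (s, g) in target_samples if pd.isna(wide.loc[(s, g), ref])]
        if missing:
            raise ValueError(
                f"reference gene {ref!r} missing in sample(s) {missing} ({compartment})")
    sub = wide.loc[target_samples]
    dct = sub[target_gene] - sub[list(reference_genes)].mean(axis=1)
    by_group = dct.groupby(level="group").mean()
    for g in (case, control):
        if g not in by_group.index:
            raise ValueError(f"group {g!r} has no measurements of {target_gene!r}")
    ddct = by_group[case] - by_group[control]
    return float(2.0 ** (-ddct))


def qpcr_delta_te(fc_pol: float, fc_tot: float) -> float:
    """log2 dTE = log2(FC_polysomal) - log2(FC_total)."""
    if fc_pol <= 0 or fc_tot <= 0:
        raise ValueError("fold changes must be > 0")
    return float(np.log2(fc_pol) - np.log2(fc_tot))


def qpcr_delta_te_raw(fc_pol: float, fc_tot: float) -> float:
    """Raw-difference variant: FC_polysomal - FC_total (not log-scale)."""
    if fc_pol <= 0 or fc_tot <= 0:
        raise ValueError("fold changes must be > 0")
    return float(fc_pol - fc_tot)


# ---------------------------------------------------------------------------
# DEG overlap
# ---------------------------------------------------------------------------

@dataclass
class DEGOverlap:
    shared: set
    transcriptome_only: set
    translatome_only: set
    overlap_pct: float            # 100 * |shared| / |union of DEG lists|
    pct_of_transcriptome: float
    pct_of_translatome: float
    contingency: pd.DataFrame


def classify_degs(transcriptome_degs: Sequence[str],
                  translatome_degs: Sequence[str],
                  universe: Sequence[str]) -> DEGOverlap:
    """Overlap between transcriptome-level and translatome-level DEG sets."""
    uni = set(universe)
    a, b = set(transcriptome_degs), set(translatome_degs)
    if not a <= uni or not b <= uni:
        raise ValueError("DEG lists contain genes outside the shared universe")
    shared = a & b
    union = a | b
    overlap_pct = 100.0 * len(shared) / len(union) if union else 0.0
    cont = pd.DataFrame(
        [[len(shared), len(a - b)], [len(b - a), len(uni - union)]],
        index=["translatome_DEG", "translatome_nonDEG"],
        columns=["transcriptome_DEG", "transcriptome_nonDEG"])
    return DEGOverlap(
        shared=shared, transcriptome_only=a - b, translatome_only=b - a,
        overlap_pct=overlap_pct,
        pct_of_transcriptome=100.0 * len(shared) / len(a) if a else 0.0,
        pct_of_translatome=100.0 * len(shared) / len(b) if b else 0.0,
        contingency=cont)
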