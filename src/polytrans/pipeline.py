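"""Config-driven orchestration: simulate a cohort, quantify FRP, relate it
to phenotype and cluster animals, with full seed provenance.

A run is described by a YAML config (stage list + per-stage parameter
blocks + one global seed).  The global seed is fanned out deterministically
(seed + stage index) so any stage can be re-run in isolation and reproduce
byte-identical output; the manifest records every artifact with a sha256
checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from polytrans import profile_quant as pq
from polytrans import synthetic

logger = logging.getLogger("polytrans")

KNOWN_STAGES = ("simulate_cohort", "frp", "phenotype", "cluster")
KNOWN_KEYS = {"stages", "seed", "out_dir", "params", "log_level"}


@dataclass
class RunConfig:
    stages: list
    seed: int = 0
    out_dir: str = "polytrans_run"
    params: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in KNOWN_STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; known: {list(KNOWN_STAGES)}")
        bad = set(self.params) - set(KNOWN_STAGES)
        if bad:
            raise ValueError(f"parameter blocks for unknown stages: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError("config must be a YAML mapping")
        unknown = set(raw) - KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    return (seed + KNOWN_STAGES.index(stage)) % (2**31 - 1)


def _quantify_profile(profile: pq.PolysomeProfile) -> pq.FRPResult:
    corrected = pq.correct_baseline(profile)
    seg = pq.segment_peaks(corrected)
    areas = pq.integrate_regions(corrected, seg)
    res = pq.compute_frp(areas)
    res.metadata.update(profile.metadata)
    return res


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest: dict = {"seed": config.seed, "stages": {}, "artifacts": {}}

    def record(path: Path, stage: str) -> None:
        manifest["artifacts"][str(path)] = {"sha256": _sha256(path), "stage": stage}

    state: dict = {}
    for stage in config.stages:
        params = dict(config.params.get(stage, {}))
        sseed = _stage_seed(config.seed, stage)
        manifest["stages"][stage] = {"seed": sseed, "params": params}
        logger.info("stage %s (seed %d)", stage, sseed)
        try:
            if stage == "simulate_cohort":
                specs = None
                if "groups" in params:
                    specs = {name: synthetic.CohortGroupSpec(genotype=name, **blk)
                             for name, blk in params.pop("groups").items()}
                profiles, records, truth = synthetic.simulate_cohort(
                    group_specs=specs, seed=sseed, **params)
                pdir = out / "profiles"
                pdir.mkdir(exist_ok=True)
                for prof in profiles:
                    p = pdir / f"{prof.metadata['sample']}.tsv"
                    pq.write_profile(prof, p)
                    record(p, stage)
                pheno = pd.DataFrame([vars(r) for r in records])
                ppath = out / "phenotypes.tsv"
                pheno.to_csv(ppath, sep="\t", index=False)
                record(ppath, stage)
                gt = out / "ground_truth.json"
                gt.write_text(json.dumps({"per_sample_frp": truth.per_sample_frp}, indent=1))
                record(gt, stage)
                state["profiles"] = profiles
                state["records"] = records
            elif stage == "frp":
                profiles = state.get("profiles")
                if profiles is None:
                    pdir = Path(params.get("profiles", out / "profiles"))
                    profiles = [pq.read_profile(p, metadata={"sample": p.stem})
                                for p in sorted(pdir.glob("*.tsv"))]
                results = [_quantify_profile(p) for p in profiles]
                df = pd.DataFrame({
                    "sample": [r.metadata.get("sample") for r in results],
                    "genotype": [r.metadata.get("genotype") for r in results],
                    "frp": [r.frp for r in results],
                    "qc": [";".join(r.qc_flags) for r in results]})
                fpath = out / "frp_results.tsv"
                df.to_csv(fpath, sep="\t", index=False)
                record(fpath, stage)
                state["frp"] = df
            elif stage == "phenotype":
                frp = state.get("frp")
                if frp is None:
                    frp = pd.read_csv(params.get("frp", out / "frp_results.tsv"), sep="\t")
                records = state.get("records")
                if records is None:
                    pheno = pd.read_csv(params.get("phenotypes", out / "phenotypes.tsv"), sep="\t")
                    records = [pq.PhenotypeRecord(
                        mouse_id=r.mouse_id, genotype=r.genotype, stage=r.stage,
                        treatment=r.treatment, weight=r.weight,
                        righting_time=r.righting_time) for r in pheno.itertuples()]
                records = pq.relative_phenotype(records)
                rel = pd.DataFrame([vars(r) for r in records])
                merged = frp.merge(rel, left_on="sample", right_on="mouse_id")
                groups = sorted(merged["genotype_x"].unique())
                tests = []
                if len(groups) == 2:
                    a = merged.loc[merged["genotype_x"] == groups[0], "frp"]
                    b = merged.loc[merged["genotype_x"] == groups[1], "frp"]
                    t = pq.compare_frp(a, b)
                    tests.append({"contrast": f"{groups[0]}_vs_{groups[1]}",
                                  "t": t.t, "df": t.df, "p": t.p})
                pd.DataFrame(tests).to_csv(out / "group_tests.tsv", sep="\t", index=False)
                record(out / "group_tests.tsv", stage)
                corrs = []
                for var in ("weight", "righting_time"):
                    c = pq.correlate_phenotype(merged["frp"], merged[var])
                    corrs.append({"phenotype": var, "pearson_r": c.pearson_r,
                                  "pearson_p": c.pearson_p, "spearman_rho": c.spearman_rho,
                                  "spearman_p": c.spearman_p, "n": c.n})
                pd.DataFrame(corrs).to_csv(out / "correlations.tsv", sep="\t", index=False)
                record(out / "correlations.tsv", stage)
                state["merged"] = merged
            elif stage == "cluster":
                merged = state.get("merged")
                if merged is None:
                    raise ValueError("cluster stage requires the phenotype stage")
                table = merged.set_index("mouse_id")[
                    ["frp", "relative_weight", "relative_righting"]]
                res = pq.cluster_mice(table, k=int(params.get("k", 2)))
                cpath = out / "clustering.json"
                cpath.write_text(json.dumps({
                    "merges": res.linkage[:, :2].astype(int).tolist(),
                    "heights": res.linkage[:, 2].tolist(),
                    "labels": {m: int(l) for m, l in zip(res.mouse_ids, res.labels)},
                    "k": res.k}, indent=1))
                record(cpath, stage)
        except Exception as exc:
            manifest["failed_stage"] = stage
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return manifest


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

_SCHEMAS = {
    "profile": ("position", "absorbance", "fraction_index"),
    "phenotype": ("mouse_id", "genotype", "stage", "treatment", "weight", "righting_time"),
    "counts": None,   # gene x sample matrix: first column gene ids, rest numeric
    "ct": ("gene", "sample", "group", "compartment", "technical_replicate", "ct"),
    "cosed": ("protein", "sample", "fraction_index", "intensity"),
    "cells": ("replicate_id", "genotype", "cell_id", "mean_intensity"),
    "axons": ("mouse_id", "genotype", "axon_id", "ribosome_count", "axon_area"),
}


def _guess_kind(path: Path) -> str | None:
    name = path.name.lower()
    for kind in _SCHEMAS:
        if kind in name:
            return kind
    if "pheno" in name:
        return "phenotype"
    return None


def validate_inputs(paths, schemas: dict | None = None) -> list:
    """Report-only validation of input tables; never raises on bad data."""
    report = []
    for item in paths:
        path = Path(item)
        kind = (schemas or {}).get(str(path)) or _guess_kind(path)
        entry = {"path": str(path), "kind": kind, "ok": True, "errors": []}
        try:
            df = pd.read_csv(path, sep="\t")
        except Exception as exc:
            entry["ok"] = False
            entry["errors"].append(f"parse failure: {exc}")
            report.append(entry)
            continue
        if kind is None:
            # fall back to schema inference from the columns present
            for cand, cols in _SCHEMAS.items():
                if cols is not None and set(cols) <= set(df.columns):
                    kind = entry["kind"] = cand
                    break
        if kind is None:
            entry["errors"].append("unknown table kind; schema not checked")
        else:
            cols = _SCHEMAS[kind]
            if cols is not None:
                missing = [c for c in cols if c not in df.columns]
                if missing:
                    entry["ok"] = False
                    entry["errors"].append(f"missing columns {missing}")
            if kind == "profile" and "position" in df.columns:
                diffs = np.diff(df["position"].to_numpy(dtype=float))
                if (diffs <= 0).any():
                    row = int(np.argmax(diffs <= 0)) + 1
                    entry["ok"] = False
                    entry["errors"].append(f"non-monotone positions at row {row}")
            if kind == "phenotype" and "righting_time" in df.columns:
                over = df.index[df["righting_time"] > 30].tolist()
                if over:
                    entry["ok"] = False
                    entry["errors"].append(f"righting_time > 30 s at rows {over}")
        report.append(entry)
    return report
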