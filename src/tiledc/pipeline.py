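"""End-to-end pipeline driver.

Mirrors the analysis order of a targeted-3C study: each replicate is
balanced individually before replicates are merged per condition; all
balanced matrices are scaled to the mean total interactions; then
viewpoint profiles, domain insulation, boundary contacts, E-P
quantification, PCA ordination, and rank-based group tests are computed
and written as tidy tables.  A run is fully described by one YAML
config and emits a summary JSON listing every output, so identical
config + inputs reproduce identical results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .domains import DomainSet, boundary_bin_sets, boundary_contacts, ep_contacts, insulation_table
from .genome import BinGrid, FeatureSet, GenomicInterval, read_bed
from .matrix import (
    ContactMatrix,
    SampleMeta,
    ice_balance,
    merge,
    percentile_cap,
    read_triplets,
    scale_to_mean_total,
    total_interactions,
    write_triplets,
)
from .profiles import (
    aggregate_replicates,
    normalize_profile,
    subtract_profiles,
    virtual_capture,
    write_bedgraph,
)
from .stats import dunn_test, kruskal_wallis, log_normalize, normality_check, pca, size_factors

__all__ = ["PipelineConfig", "PipelineError", "contact_count_table", "run_pipeline"]


def contact_count_table(
    matrices: dict[str, ContactMatrix], min_count: float = 0
) -> pd.DataFrame:
    """Cells-by-samples count table over the union of supports.

    Rows are canonical cell ids (``i * n_bins + j``); ``min_count``
    drops cells whose smallest per-sample count falls below it, the
    usual pre-filter before log transformation and ordination.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    n = next(iter(matrices.values())).grid.n_bins
    support: set[int] = set()
    for m in matrices.values():
        support.update((m.bins1 * n + m.bins2).tolist())
    idx = np.array(sorted(support), dtype=np.int64)
    columns = {}
    for name, m in matrices.items():
        col = np.zeros(idx.size)
        col[np.searchsorted(idx, m.bins1 * n + m.bins2)] = m.values
        columns[name] = col
    table = pd.DataFrame(columns, index=idx)
    if min_count > 0:
        table = table[table.min(axis=1) >= min_count]
    return table

DEFAULT_ANALYSES = ("profiles", "insulation", "boundary", "ep", "pca", "tests")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage and offending sample."""

    def __init__(self, stage: str, sample: str | None, cause: Exception):
        self.stage = stage
        self.sample = sample
        where = f" (sample {sample})" if sample else ""
        super().__init__(f"stage {stage!r}{where}: {cause}")


@dataclass
class SampleSpec:
    path: str
    state: str
    replicate: str
    genotype: str = "WT"


@dataclass
class PipelineConfig:
    grid: BinGrid
    samples: list[SampleSpec]
    outdir: Path
    domains: dict[str, tuple[int, int]] = field(default_factory=dict)
    ctcf_bed: str | None = None
    enhancer_bed: str | None = None
    viewpoints: dict[str, int] = field(default_factory=dict)
    analyses: tuple[str, ...] = DEFAULT_ANALYSES
    adjust: str = "holm"
    percentile: float = 94.0
    boundary_k: int = 4
    boundary_domain: str = "main_TAD"
    low_cov_fraction: float = 0.02
    pca_min_count: float = 5.0
    pca_top_n: int | None = 500
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        g = raw["grid"]
        grid = BinGrid(GenomicInterval(g["chrom"], g["start"], g["end"]), g["bin_size"])
        base = Path(path).parent
        samples = [
            SampleSpec(
                path=str((base / s["path"])),
                state=s["state"],
                replicate=str(s["replicate"]),
                genotype=s.get("genotype", "WT"),
            )
            for s in raw["samples"]
        ]
        feats = raw.get("features", {}) or {}
        viewpoints = {}
        for vp in raw.get("viewpoints", []) or []:
            if "bin" in vp:
                viewpoints[vp["name"]] = int(vp["bin"])
            else:
                viewpoints[vp["name"]] = grid.coord_to_bin(int(vp["pos"]))
        return cls(
            grid=grid,
            samples=samples,
            outdir=Path(raw["outdir"]),
            domains={k: (int(v[0]), int(v[1])) for k, v in (raw.get("domains") or {}).items()},
            ctcf_bed=str(base / feats["ctcf"]) if "ctcf" in feats else None,
            enhancer_bed=str(base / feats["enhancers"]) if "enhancers" in feats else None,
            viewpoints=viewpoints,
            analyses=tuple(raw.get("analyses", DEFAULT_ANALYSES)),
            adjust=raw.get("adjust", "holm"),
            percentile=float(raw.get("percentile", 94.0)),
            boundary_k=int(raw.get("boundary_k", 4)),
            boundary_domain=raw.get("boundary_domain", "main_TAD"),
            low_cov_fraction=float(raw.get("low_cov_fraction", 0.02)),
            pca_min_count=float(raw.get("pca_min_count", 5.0)),
            pca_top_n=raw.get("pca_top_n", 500),
            seed=int(raw.get("seed", 0)),
        )


def _group_tests(values_by_state: dict[str, list[float]], adjust: str) -> dict:
    """KW omnibus + Dunn post hoc on per-state value distributions."""
    groups = {s: np.asarray(v, dtype=np.float64) for s, v in values_by_state.items() if len(v)}
    if len(groups) < 2:
        return {"error": "fewer than 2 non-empty groups"}
    pooled = np.concatenate(list(groups.values()))
    try:
        shapiro_p = normality_check(pooled[:5000])
    except ValueError:
        shapiro_p = None
    kw = kruskal_wallis(groups)
    dunn = dunn_test(groups, adjust=adjust)
    return {
        "shapiro_p": shapiro_p,
        "kw_H": kw.H,
        "kw_df": kw.df,
        "kw_p": kw.p,
        "posthoc_warranted": dunn.posthoc_warranted,
        "dunn": dunn.table.to_dict(orient="records"),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every requested analysis; returns the summary report bundle."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    summary: dict = {
        "version": __version__,
        "parameters": {
            "grid": config.grid.to_dict(),
            "analyses": list(config.analyses),
            "adjust": config.adjust,
            "percentile": config.percentile,
            "boundary_k": config.boundary_k,
            "low_cov_fraction": config.low_cov_fraction,
            "seed": config.seed,
        },
        "samples": [vars(s) for s in config.samples],
    }

    def declare(path: Path) -> Path:
        outputs.append(str(path.relative_to(out)))
        return path

    # ---- per-replicate: read, balance -----------------------------------
    raw_by_key: dict[tuple[str, str], ContactMatrix] = {}
    balanced: list[ContactMatrix] = []
    balance_info = []
    states: list[str] = []
    for s in config.samples:
        if s.state not in states:
            states.append(s.state)
        try:
            m = read_triplets(s.path, config.grid)
        except Exception as exc:
            raise PipelineError("read_triplets", f"{s.state}/{s.replicate}", exc) from exc
        m = m.with_meta(SampleMeta(state=s.state, replicate=s.replicate, genotype=s.genotype))
        raw_by_key[(s.state, s.replicate)] = m
        try:
            b, res = ice_balance(m, low_cov_fraction=config.low_cov_fraction)
        except Exception as exc:
            raise PipelineError("ice_balance", f"{s.state}/{s.replicate}", exc) from exc
        balanced.append(b)
        balance_info.append(
            {
                "state": s.state,
                "replicate": s.replicate,
                "total": total_interactions(m),
                "masked_bins": len(res.masked_bins),
                "iterations": res.iterations,
                "converged": res.converged,
            }
        )
    summary["balancing"] = balance_info

    # ---- scale per-replicate matrices to the mean total -----------------
    try:
        scaled = scale_to_mean_total(balanced)
    except Exception as exc:
        raise PipelineError("scale_to_mean_total", None, exc) from exc
    summary["mean_total"] = float(np.mean([total_interactions(b) for b in balanced]))

    # ---- per condition: merge raw replicates, balance, export capped ----
    merged_scaled: dict[str, ContactMatrix] = {}
    for state in states:
        reps = [m for (st, _), m in raw_by_key.items() if st == state]
        try:
            mg = merge(reps)
            mgb, _ = ice_balance(mg, low_cov_fraction=config.low_cov_fraction)
        except Exception as exc:
            raise PipelineError("merge", state, exc) from exc
        merged_scaled[state] = mgb
    merged_list = scale_to_mean_total(list(merged_scaled.values()))
    merged_scaled = dict(zip(merged_scaled.keys(), merged_list))
    for state, m in merged_scaled.items():
        capped = percentile_cap(m, config.percentile)
        write_triplets(capped, declare(out / f"{state}.merged.capped.tsv"))

    domains = DomainSet(
        config.grid,
        {k: range(a, b) for k, (a, b) in config.domains.items()},
    ) if config.domains else None

    tests: dict[str, dict] = {}

    # ---- viewpoint profiles ---------------------------------------------
    if "profiles" in config.analyses and config.viewpoints:
        by_state: dict[str, dict[str, list]] = {vp: {} for vp in config.viewpoints}
        for m in scaled:
            for vp_name, vp_bin in config.viewpoints.items():
                try:
                    prof = normalize_profile(virtual_capture(m, vp_bin), m)
                except Exception as exc:
                    raise PipelineError(
                        "virtual_capture", f"{m.meta.state}/{m.meta.replicate}", exc
                    ) from exc
                by_state[vp_name].setdefault(m.meta.state, []).append(prof)
        for vp_name, groups in by_state.items():
            aggs = {}
            for state, profs in groups.items():
                agg = aggregate_replicates(profs)
                aggs[state] = agg
                write_bedgraph(agg.mean, config.grid,
                               declare(out / f"profile.{vp_name}.{state}.mean.bedgraph"))
                write_bedgraph(agg.sd, config.grid,
                               declare(out / f"profile.{vp_name}.{state}.sd.bedgraph"))
            for a, b in zip(states, states[1:]):
                if a in aggs and b in aggs:
                    diff = subtract_profiles(aggs[b], aggs[a])
                    write_bedgraph(diff, config.grid,
                                   declare(out / f"profile.{vp_name}.{b}-minus-{a}.bedgraph"))

    # ---- insulation ------------------------------------------------------
    if "insulation" in config.analyses and domains is not None:
        try:
            table = insulation_table(scaled, domains)
        except Exception as exc:
            raise PipelineError("insulation", None, exc) from exc
        table.to_csv(declare(out / "insulation.tsv"), sep="\t", index=False)
        if "tests" in config.analyses:
            for name in domains.ranges:
                sub = table[table["domain"] == name]
                tests[f"insulation:{name}"] = _group_tests(
                    {st: sub[sub["state"] == st]["ratio"].tolist() for st in states},
                    config.adjust,
                )

    # ---- boundary contacts ----------------------------------------------
    if (
        "boundary" in config.analyses
        and domains is not None
        and config.ctcf_bed
        and config.boundary_domain in (domains.ranges if domains else {})
    ):
        ctcf = read_bed(config.ctcf_bed, category="ctcf")
        try:
            set_a, set_b = boundary_bin_sets(
                ctcf, domains[config.boundary_domain], config.grid, k=config.boundary_k
            )
        except Exception as exc:
            raise PipelineError("boundary_bin_sets", None, exc) from exc
        rows = []
        for m in scaled:
            for v in boundary_contacts(m, set_a, set_b):
                rows.append({"state": m.meta.state, "replicate": m.meta.replicate,
                             "value": float(v)})
        bt = pd.DataFrame(rows)
        bt.to_csv(declare(out / "boundary_contacts.tsv"), sep="\t", index=False)
        summary["boundary_bins"] = {"A": set_a, "B": set_b}
        if "tests" in config.analyses:
            tests["boundary"] = _group_tests(
                {st: bt[bt["state"] == st]["value"].tolist() for st in states},
                config.adjust,
            )

    # ---- enhancer-promoter quantification -------------------------------
    if "ep" in config.analyses and config.enhancer_bed and config.viewpoints:
        enhancers = read_bed(config.enhancer_bed, category="enhancer")
        rows = []
        for m in scaled:
            for vp_name, vp_bin in config.viewpoints.items():
                try:
                    res = ep_contacts(m, vp_bin, enhancers, config.grid, promoter_name=vp_name)
                except Exception as exc:
                    raise PipelineError(
                        "ep_contacts", f"{m.meta.state}/{m.meta.replicate}", exc
                    ) from exc
                for b, v in res.per_bin.items():
                    rows.append({"state": m.meta.state, "replicate": m.meta.replicate,
                                 "promoter": vp_name, "bin": b, "value": v})
                rows.append({"state": m.meta.state, "replicate": m.meta.replicate,
                             "promoter": vp_name, "bin": -1, "value": res.total})
        et = pd.DataFrame(rows)
        et.to_csv(declare(out / "ep_contacts.tsv"), sep="\t", index=False)
        if "tests" in config.analyses:
            for vp_name in config.viewpoints:
                sub = et[(et["promoter"] == vp_name) & (et["bin"] >= 0)]
                tests[f"ep:{vp_name}"] = _group_tests(
                    {st: sub[sub["state"] == st]["value"].tolist() for st in states},
                    config.adjust,
                )

    # ---- PCA ordination --------------------------------------------------
    if "pca" in config.analyses and len(raw_by_key) >= 2:
        counts = contact_count_table(
            {f"{state}/{rep}": m for (state, rep), m in raw_by_key.items()},
            min_count=config.pca_min_count,
        )
        try:
            factors = size_factors(counts)
            normed = log_normalize(counts, factors)
            res = pca(normed, top_n=config.pca_top_n)
        except Exception as exc:
            raise PipelineError("pca", None, exc) from exc
        coords = res.coordinates.copy()
        coords.insert(0, "sample", coords.index)
        coords.to_csv(declare(out / "pca_coordinates.tsv"), sep="\t", index=False)
        pd.DataFrame({
            "component": [f"PC{i + 1}" for i in range(res.explained.size)],
            "variance_fraction": res.explained,
        }).to_csv(declare(out / "pca_variance.tsv"), sep="\t", index=False)
        summary["pca_explained"] = res.explained[:5].tolist()

    if tests:
        (out / "tests.json").write_text(json.dumps(tests, indent=1) + "\n")
        declare(out / "tests.json")
        summary["tests"] = tests

    summary["outputs"] = outputs
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str) + "\n")
    return summary
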