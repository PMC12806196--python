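"""End-to-end pipeline: orchestrates the analysis stages over the four input
tables and writes plain TSV/JSON artifacts plus a machine-readable report.

Every stage reads and writes flat files so any stage can be re-run
standalone; ``--resume`` skips stages whose config and inputs are unchanged
(per-stage hash files)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import (
    CountTable,
    GUT_HABITATS,
    SOURCE_HABITATS,
    ValidationError,
    meta_frame,
    read_count_table,
    read_function_table,
    read_metadata,
    read_taxonomy,
    to_relative,
)
from .diversity import alpha, bray_curtis, build_mixed_gut, distance_decay
from .network import build_network, full_metrics
from .sourcetrack import pooled_source_profiles, track_subset
from .stability import (
    functional_stability,
    multifunctionality,
    stability_series,
    taxa_function_correlation,
)
from .staging import (
    assign_stages,
    cluster_panels,
    partition_clusters,
    rf_stage_selection,
)
from .tipping import dissimilarity_to_baseline, fit_breakpoint
from .turnover import classify_differential, classify_presence, turnover_summary

log = logging.getLogger("moltsucc")


@dataclass
class RunConfig:
    """All pipeline inputs, thresholds, and output location."""

    counts: str
    metadata: str
    taxonomy: str | None = None
    functions: str | None = None
    outdir: str = "moltsucc_out"
    baseline_time_h: float = 0.0
    rarefy_depth: int | None = None
    # turnover
    min_count: int = 2
    min_prevalence: float = 0.5
    alpha: float = 0.05
    min_fold: float = 2.0
    # tipping
    grid_step_h: float = 0.1
    n_boot: int = 199
    # network
    rho_threshold: float = 0.6
    q_threshold: float = 0.05
    network_min_prevalence: float = 1 / 3
    removal_fraction: float = 0.5
    n_removal_trials: int = 100
    # staging
    tipping_mark_h: float = 24.0
    n_trees: int = 400
    cv_n_trees: int = 80
    cv_repeats: int = 1
    k_folds: int = 10
    max_head: int | None = 34
    # source tracking
    source_time_h: float | None = 48.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("counts", "metadata"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")
        for name in ("taxonomy", "functions"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")
        if not 0 < self.alpha < 1 or not 0 < self.q_threshold < 1:
            raise ValidationError("alpha/q_threshold must lie in (0, 1)")
        if not 0 <= self.rho_threshold <= 1:
            raise ValidationError("rho_threshold must lie in [0, 1]")
        if not 0 < self.removal_fraction < 1:
            raise ValidationError("removal_fraction must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage_hash(config: RunConfig, checksums: dict) -> str:
    payload = json.dumps(
        {"config": dataclasses.asdict(config), "inputs": checksums,
         "version": __version__},
        sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def run_all(config: RunConfig, resume: bool = False) -> dict:
    """Execute the full pipeline; returns (and writes) the run report.

    Stage order: load -> turnover -> diversity/mixed gut -> tipping ->
    staging/clusters -> networks -> stability/function -> source tracking.
    Any stage failure aborts with the stage name and cause; artifacts written
    so far are retained.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    checksums = {
        name: _sha256(getattr(config, name))
        for name in ("counts", "metadata", "taxonomy", "functions")
        if getattr(config, name) is not None
    }
    run_hash = _stage_hash(config, checksums)
    hash_file = outdir / "run.hash"
    report_file = outdir / "report.json"
    if resume and hash_file.exists() and hash_file.read_text() == run_hash \
            and report_file.exists():
        log.info("run_all: config and inputs unchanged, reusing %s", report_file)
        return json.loads(report_file.read_text())

    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "input_checksums": checksums,
        "stages": {},
        "artifacts": [],
    }

    def _emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t")
        report["artifacts"].append(str(path))

    def _emit_json(name: str, payload) -> None:
        path = outdir / name
        path.write_text(json.dumps(payload, indent=2, default=str))
        report["artifacts"].append(str(path))

    stage = "load"
    try:
        t0 = time.time()
        table = read_count_table(config.counts)
        metas = read_metadata(config.metadata)
        taxonomy = (read_taxonomy(config.taxonomy)
                    if config.taxonomy else None)
        functions = (read_function_table(config.functions)
                     if config.functions else None)
        if config.rarefy_depth:
            from .data_model import rarefy
            table = rarefy(table, config.rarefy_depth, config.seed)
            kept = set(table.sample_ids)
            metas = [m for m in metas if m.sample_id in kept]
        by_id = {m.sample_id: m for m in metas}
        missing = [s for s in table.sample_ids if s not in by_id]
        if missing:
            raise ValidationError(f"samples without metadata: {missing[:5]}")
        rel = to_relative(table)
        gut_segments = [h for h in ("foregut", "midgut", "hindgut")
                        if any(m.habitat == h for m in metas)]
        times = sorted({m.time_h for m in metas
                        if m.habitat in gut_segments and m.time_h is not None})
        report["stages"][stage] = {"seconds": round(time.time() - t0, 2),
                                   "n_samples": len(table.sample_ids),
                                   "n_asvs": len(table.asv_ids)}

        def _ids(habitat, time_h=None, ck=False):
            return [m.sample_id for m in metas
                    if m.habitat == habitat and m.is_premolt_ck == ck
                    and (ck or m.time_h == time_h)
                    and m.sample_id in table.data.index]

        # ---- turnover ---------------------------------------------------
        stage = "turnover"
        t0 = time.time()
        turnover_rows = []
        emerged_by_seg: dict[str, pd.Series] = {}
        for seg in gut_segments:
            base_ids = _ids(seg, config.baseline_time_h)
            if not base_ids:
                continue
            base_slice = table.select_samples(base_ids)
            base_rel = rel.select_samples(base_ids)
            comparisons = [(f"{t:g}h", _ids(seg, t)) for t in times
                           if t != config.baseline_time_h]
            ck_ids = _ids(seg, ck=True)
            if ck_ids:
                comparisons.append(("CK", ck_ids))
            for label, ids in comparisons:
                if len(ids) < 3:
                    continue
                grp = table.select_samples(ids)
                grp_rel = rel.select_samples(ids)
                presence_label = "lost" if label == "CK" else "emerged"
                pres = classify_presence(
                    base_slice, grp, config.min_count, config.min_prevalence,
                    label=presence_label)
                diff = classify_differential(
                    base_rel, grp_rel, config.alpha, config.min_fold)
                if label == "CK":
                    # higher in premolt CK than at 0 h = depleted by molting
                    diff = diff.copy()
                    remap = {"enriched": "depleted", "depleted": "gained_at_0h"}
                    diff["status"] = diff["status"].replace(remap)
                summary = turnover_summary(pres, grp_rel)
                for st, row in summary.iterrows():
                    turnover_rows.append({
                        "segment": seg, "comparison": label, "status": st,
                        "n_asvs": row["n_asvs"],
                        "total_rel_abund_pct": row["total_rel_abund_pct"],
                    })
                dsum = turnover_summary(diff, grp_rel)
                for st, row in dsum.iterrows():
                    turnover_rows.append({
                        "segment": seg, "comparison": label, "status": st,
                        "n_asvs": row["n_asvs"],
                        "total_rel_abund_pct": row["total_rel_abund_pct"],
                    })
                if label != "CK":
                    prev = emerged_by_seg.get(seg)
                    cur = pres == "emerged"
                    emerged_by_seg[seg] = cur if prev is None else (prev | cur)
        _emit("turnover_summary.tsv",
              pd.DataFrame(turnover_rows).set_index(["segment", "comparison"]))
        report["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

        # ---- diversity & mixed gut -------------------------------------
        stage = "diversity"
        t0 = time.time()
        adiv = alpha(table)
        _emit("alpha_diversity.tsv", adiv)
        mixed, mixed_meta = build_mixed_gut(table, metas)
        if mixed is not None:
            _emit("mixed_gut_counts.tsv", mixed.data)
            _emit("mixed_gut_metadata.tsv", meta_frame(mixed_meta))
        gut_ids = [m.sample_id for m in metas if m.habitat in gut_segments
                   and m.sample_id in rel.data.index]
        bc = bray_curtis(rel.select_samples(gut_ids))
        _emit("bray_curtis_gut.tsv", bc.to_frame())
        try:
            slope, r2, p = distance_decay(bc, metas, n_perm=199, seed=config.seed)
            decay = {"slope_per_h": slope, "r_squared": r2, "p_perm": p}
        except ValidationError as err:
            decay = {"skipped": str(err)}
        _emit_json("distance_decay.json", decay)
        report["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

        # ---- tipping points --------------------------------------------
        stage = "tipping"
        t0 = time.time()
        trajectories = dissimilarity_to_baseline(
            rel.select_samples(gut_ids), metas, config.baseline_time_h)
        fits = {}
        for hab, (ts, vs) in trajectories.items():
            try:
                fit = fit_breakpoint(ts, vs, config.grid_step_h,
                                     config.n_boot, config.seed)
                fits[hab] = dataclasses.asdict(fit)
            except ValidationError as err:
                fits[hab] = {"skipped": str(err)}
        _emit_json("tipping.json", fits)
        report["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

        # ---- staging & clusters ----------------------------------------
        stage = "staging"
        t0 = time.time()
        staging_out = {}
        for seg in gut_segments:
            try:
                stages = assign_stages(metas, config.tipping_mark_h, habitat=seg)
            except ValidationError as err:
                staging_out[seg] = {"skipped": str(err)}
                continue
            seg_ids = [s for s in stages.index if s in rel.data.index]
            seg_rel = rel.select_samples(seg_ids)
            model = rf_stage_selection(
                seg_rel, stages, n_trees=config.n_trees,
                cv_n_trees=config.cv_n_trees, cv_repeats=config.cv_repeats,
                k_folds=config.k_folds, seed=config.seed,
                max_head=config.max_head)
            clusters = partition_clusters(seg_rel, stages,
                                          model.selected_taxa, config.alpha)
            panels = cluster_panels(seg_rel, clusters, metas, habitat=seg,
                                    alpha=config.alpha)
            _emit(f"clusters_{seg}.tsv", clusters)
            _emit(f"cluster_panels_{seg}.tsv", panels)
            staging_out[seg] = {
                "n_selected": len(model.selected_taxa),
                "selected_taxa": list(model.selected_taxa),
                "cv_curve": model.cv_curve.reset_index().to_dict("records"),
            }
        _emit_json("staging.json", staging_out)
        report["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

        # ---- co-occurrence networks ------------------------------------
        stage = "network"
        t0 = time.time()
        net_metrics = {}
        for seg in gut_segments + (["mixed_gut"] if mixed is not None else []):
            if seg == "mixed_gut":
                ids = [m.sample_id for m in mixed_meta]
                seg_rel = to_relative(mixed)
            else:
                ids = [m.sample_id for m in metas if m.habitat == seg
                       and not m.is_premolt_ck and m.sample_id in rel.data.index]
                seg_rel = rel.select_samples(ids)
            if len(ids) < 5:
                net_metrics[seg] = {"skipped": "fewer than 5 samples"}
                continue
            net = build_network(seg_rel, config.rho_threshold,
                                config.q_threshold,
                                config.network_min_prevalence)
            metrics = full_metrics(net, config.removal_fraction,
                                   config.n_removal_trials, config.seed)
            net_metrics[seg] = dataclasses.asdict(metrics)
            _emit(f"network_edges_{seg}.tsv", net.edge_list())
        _emit_json("network_metrics.json", net_metrics)
        report["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

        # ---- stability & function --------------------------------------
        stage = "stability"
        t0 = time.time()
        stab_rows = []
        for seg in gut_segments:
            groups = {f"{t:g}h": _ids(seg, t) for t in times if len(_ids(seg, t)) >= 3}
            if not groups:
                continue
            series = stability_series(rel, groups)
            for gid, row in series.iterrows():
                stab_rows.append({"habitat": seg, "group": gid, **row.to_dict()})
        if stab_rows:
            _emit("community_stability.tsv",
                  pd.DataFrame(stab_rows).set_index(["habitat", "group"]))
        if functions is not None:
            shared = [s for s in functions.sample_ids if s in rel.data.index]
            fsub = functions.select_samples(shared)
            mf = multifunctionality(fsub)
            _emit("multifunctionality.tsv", mf.to_frame())
            for seg in gut_segments:
                groups = {f"{t:g}h": [s for s in _ids(seg, t) if s in shared]
                          for t in times}
                groups = {k: v for k, v in groups.items() if len(v) >= 3}
                if groups:
                    fs = functional_stability(fsub, groups)
                    _emit(f"functional_stability_{seg}.tsv", fs)
            seg = gut_segments[0] if "midgut" not in gut_segments else "midgut"
            seg_ids = [m.sample_id for m in metas
                       if m.habitat == seg and m.sample_id in shared]
            if len(seg_ids) >= 5:
                screen = taxa_function_correlation(
                    rel.select_samples(seg_ids), fsub.select_samples(seg_ids),
                    alpha=config.alpha)
                _emit("taxa_function_correlation.tsv", screen.set_index(
                    ["taxon", "pathway"]))
        report["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

        # ---- source tracking -------------------------------------------
        stage = "sourcetrack"
        t0 = time.time()
        st_out = {}
        source_habs = [h for h in SOURCE_HABITATS
                       if any(m.habitat == h for m in metas)]
        if source_habs and emerged_by_seg:
            profiles = pooled_source_profiles(table, metas, source_habs,
                                              time_h=config.source_time_h)
            for seg, emerged_mask in emerged_by_seg.items():
                if not emerged_mask.any():
                    continue
                sink_ids = _ids(seg, config.source_time_h) or \
                    _ids(seg, times[-1])
                if not sink_ids:
                    continue
                pooled_sink = table.data.loc[sink_ids].sum(axis=0)
                labeling = pd.Series(
                    np.where(emerged_mask, "emerged", "neither"),
                    index=emerged_mask.index)
                sink_table = CountTable(pooled_sink.to_frame(f"{seg}_pooled").T)
                estimates = track_subset(sink_table, labeling, "emerged",
                                         profiles, seed=config.seed)
                st_out[seg] = {sid: est.proportions
                               for sid, est in estimates.items()}
        _emit_json("source_tracking.json", st_out)
        report["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

    except Exception as err:
        report["failed_stage"] = stage
        report["error"] = f"{type(err).__name__}: {err}"
        report_file.write_text(json.dumps(report, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    report_file.write_text(json.dumps(report, indent=2, default=str))
    hash_file.write_text(run_hash)
    return report
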