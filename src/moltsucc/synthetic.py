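"""Synthetic postmolt communities with planted, machine-readable ground truth.

The generator emulates the study design this package analyzes: foregut,
midgut, and hindgut bacterial communities sampled at fixed hours after a crab
molts (plus a premolt "CK" control), with candidate source habitats (carapace
surface, rearing water, gill, hepatopancreas) sampled alongside.  Planted
structure:

* a continuous piecewise-linear drift of each segment's mean composition away
  from its 0 h baseline, with a hinge at a known breakpoint (the true
  "tipping point");
* *emerged* ASVs with exactly zero mean abundance before an onset time, fed
  by the source habitats in known mixing proportions (plus an unknown pool);
* *lost* ASVs present only in the premolt CK community;
* *enriched* ASVs whose mean abundance is multiplied by a fold change after
  an onset time;
* *stage-discriminative* ASVs elevated in either the early (<= 24 h) or late
  (>= 48 h) stage;
* pathway tables whose designated pathways are monotone functions of
  designated taxon abundances, so taxon-function correlations exist by
  construction.

Replicate noise is Dirichlet-multinomial so overdispersion resembles amplicon
data.  Everything is deterministic for a given seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    RANKS,
    CountTable,
    FunctionTable,
    SampleMeta,
    TaxonomyTable,
    ValidationError,
    to_relative,
)

_PHYLA = (
    "Proteobacteria", "Bacteroidota", "Firmicutes", "Actinobacteriota",
    "Desulfobacterota", "Verrucomicrobiota", "Planctomycetota", "Cyanobacteria",
)
_GENERA = (
    "Pseudomonas", "Maritalea", "Brevundimonas", "Achromobacter",
    "Lysinibacillus", "Acinetobacter", "Vibrio", "Shewanella",
    "Flavobacterium", "Sulfitobacter", "Roseobacter", "Marinomonas",
)


def _default_breakpoints() -> dict:
    return {"foregut": None, "midgut": 24.0, "hindgut": 21.3}


def _default_sink_mix() -> dict:
    return {
        "carapace": 0.30,
        "water": 0.20,
        "gill": 0.05,
        "hepatopancreas": 0.05,
        "unknown": 0.40,
    }


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study design.

    Defaults describe the desk-scale scenario: 8 postmolt sampling hours plus
    a premolt CK group, 6 replicate crabs, three gut segments, four candidate
    source habitats, and Dirichlet-multinomial sequencing noise.
    """

    n_asvs: int = 300
    timepoints: tuple = (0.0, 3.0, 6.0, 9.0, 12.0, 24.0, 48.0, 72.0)
    n_replicates: int = 6
    segments: tuple = ("foregut", "midgut", "hindgut")
    base_concentration: float = 0.3         # Dirichlet sparsity of base composition
    replicate_concentration: float = 300.0  # Dirichlet-multinomial overdispersion
    breakpoint_h: Mapping[str, float | None] = field(default_factory=_default_breakpoints)
    pre_slope: float = 0.02    # displacement fraction per hour before breakpoint
    post_slope: float = 0.0    # and after
    n_emerged: int = 50
    n_lost: int = 20
    n_enriched: int = 30
    n_stage_discriminative: int = 10
    effect_size: float = 4.0
    emerged_onset_h: float = 6.0
    enriched_onset_h: float = 24.0
    emerged_total_abundance: float = 0.10
    lost_total_abundance: float = 0.05
    # planted biomarkers (enriched / stage-discriminative) get controlled
    # moderate baseline abundances in this range, mirroring key taxa that are
    # detectable but not dominant
    planted_abundance_range: tuple = (4e-3, 1.2e-2)
    # each stage indicator is elevated in a given sample of its stage with
    # probability stage_colonization_prob (host-to-host colonization
    # variability: single indicators are partial stage markers, the panel is
    # a strong one).  stage_lottery=True instead marks each stage sample with
    # exactly one rotating indicator (an extreme lottery regime).
    stage_lottery: bool = False
    stage_colonization_prob: float = 0.65
    source_habitats: tuple = ("carapace", "water", "gill", "hepatopancreas")
    n_source_replicates: int = 6
    source_time_h: float = 48.0
    sink_mix: Mapping[str, float] = field(default_factory=_default_sink_mix)
    seq_depth: int = 50_000
    seed: int = 0

    def validate(self) -> None:
        n_planted = (self.n_emerged + self.n_lost + self.n_enriched
                     + self.n_stage_discriminative)
        if n_planted > self.n_asvs // 2:
            raise ValidationError(
                f"{n_planted} planted taxa exceed half of n_asvs={self.n_asvs}; "
                "leave room for the ordinary community"
            )
        if self.n_replicates < 1 or self.n_asvs < 10:
            raise ValidationError("need n_replicates >= 1 and n_asvs >= 10")
        if len(self.timepoints) < 2 or sorted(self.timepoints) != list(self.timepoints):
            raise ValidationError("timepoints must be increasing, length >= 2")
        mix = dict(self.sink_mix)
        if abs(sum(mix.values()) - 1.0) > 1e-8:
            raise ValidationError("sink_mix proportions must sum to 1")
        unknown_names = set(mix) - set(self.source_habitats) - {"unknown"}
        if unknown_names:
            raise ValidationError(f"sink_mix names not among sources: {unknown_names}")
        lo, hi = self.timepoints[0], self.timepoints[-1]
        for seg, bp in dict(self.breakpoint_h).items():
            if bp is not None and not (lo < bp < hi):
                raise ValidationError(
                    f"breakpoint {bp} for {seg!r} must lie strictly inside "
                    f"({lo}, {hi})"
                )
        if self.seq_depth <= 0:
            raise ValidationError("seq_depth must be positive")


@dataclass
class GroundTruth:
    """Planted structure of a generated dataset, keyed by ASV / segment ids."""

    emerged: dict        # asv_id -> onset hour
    lost: list           # asv ids present only premolt
    enriched: dict       # asv_id -> onset hour
    stage_discriminative: dict   # asv_id -> "early" | "late"
    true_breakpoints: dict       # segment -> hour or None
    true_sink_mixtures: dict     # segment -> {source or "unknown": proportion}
    linked_pairs: list = field(default_factory=list)  # (asv_id, pathway_id, loading)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["linked_pairs"] = [tuple(p) for p in d.get("linked_pairs", [])]
        return cls(**d)


def _dirichlet(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    """Dirichlet draw tolerating zero concentrations (exact zeros kept)."""
    out = np.zeros_like(alpha, dtype=float)
    pos = alpha > 0
    out[pos] = rng.dirichlet(alpha[pos])
    return out


def _dm_sample(rng: np.random.Generator, mean: np.ndarray, conc: float,
               depth: int) -> np.ndarray:
    """One Dirichlet-multinomial draw around ``mean`` (zeros stay zero)."""
    p = _dirichlet(rng, conc * mean)
    return rng.multinomial(depth, p)


def _displacement(t: float, bp: float | None, pre: float, post: float) -> float:
    # bp None = no planted regime change: the segment stays at its baseline
    # (the foregut case: no community displacement over the postmolt window)
    if bp is None:
        return 0.0
    d = pre * min(t, bp) + post * max(t - bp, 0.0)
    return float(np.clip(d, 0.0, 0.9))


def generate(spec: SyntheticSpec) -> tuple[CountTable, list[SampleMeta],
                                           TaxonomyTable, GroundTruth]:
    """Generate counts, metadata, taxonomy, and the planted ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_asvs
    asv_ids = [f"ASV{i + 1:04d}" for i in range(n)]

    # role blocks (deterministic layout; downstream code is permutation-safe)
    i0 = 0
    idx_emerged = np.arange(i0, i0 + spec.n_emerged); i0 += spec.n_emerged
    idx_lost = np.arange(i0, i0 + spec.n_lost); i0 += spec.n_lost
    idx_enriched = np.arange(i0, i0 + spec.n_enriched); i0 += spec.n_enriched
    idx_stage = np.arange(i0, i0 + spec.n_stage_discriminative)
    i0 += spec.n_stage_discriminative
    idx_core = np.arange(i0, n)  # ordinary taxa
    core_support = np.concatenate([idx_enriched, idx_stage, idx_core])

    stage_dir = {}
    for k, i in enumerate(idx_stage):
        stage_dir[asv_ids[i]] = "early" if k % 2 == 0 else "late"

    # source-habitat profiles over the emerged block: near-disjoint sub-blocks
    # (one per source plus an unknown pool) so mixtures are identifiable.
    # Block sizes follow the sink mixing proportions, which keeps per-taxon
    # emerged masses roughly even across pools.
    pools = list(spec.source_habitats) + ["unknown"]
    mix = dict(spec.sink_mix)
    emerged_pool_profiles: dict[str, np.ndarray] = {}
    if spec.n_emerged > 0:
        shares = np.array([max(mix.get(p, 0.0), 1e-9) for p in pools])
        sizes = np.maximum(
            np.round(spec.n_emerged * shares / shares.sum()).astype(int), 1)
        while sizes.sum() > spec.n_emerged:
            sizes[np.argmax(sizes)] -= 1
        while sizes.sum() < spec.n_emerged:
            sizes[np.argmax(shares)] += 1
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        for k, pool in enumerate(pools):
            block = idx_emerged[bounds[k]:bounds[k + 1]]
            alpha = np.full(spec.n_emerged, 0.02)
            alpha[block - idx_emerged[0]] = 5.0
            prof = np.zeros(n)
            prof[idx_emerged] = rng.dirichlet(alpha)
            emerged_pool_profiles[pool] = prof
    phi_sink = np.zeros(n)
    for pool in pools:
        if spec.n_emerged > 0:
            phi_sink += mix.get(pool, 0.0) * emerged_pool_profiles[pool]
    if phi_sink.sum() > 0:
        phi_sink /= phi_sink.sum()

    # per-segment base and drift-target compositions over the core support
    def _core_comp() -> np.ndarray:
        comp = np.zeros(n)
        alpha = np.full(core_support.size, spec.base_concentration)
        comp[core_support] = rng.dirichlet(alpha)
        planted = np.concatenate([idx_enriched, idx_stage])
        if planted.size:
            lo, hi = spec.planted_abundance_range
            comp[planted] = rng.uniform(lo, hi, size=planted.size)
            comp /= comp.sum()
        return comp

    seg_base = {seg: _core_comp() for seg in spec.segments}
    seg_target = {seg: _core_comp() for seg in spec.segments}
    lost_profile = np.zeros(n)
    if spec.n_lost > 0:
        lost_profile[idx_lost] = rng.dirichlet(np.full(spec.n_lost, 2.0))

    breakpoints = {seg: dict(spec.breakpoint_h).get(seg) for seg in spec.segments}

    def _mean_at(seg: str, t: float | None) -> np.ndarray:
        """Mean composition for a segment at postmolt hour t (None = CK)."""
        base = seg_base[seg]
        if t is None:  # premolt CK: baseline community plus the lost taxa
            p = (1.0 - spec.lost_total_abundance) * base
            p = p + spec.lost_total_abundance * lost_profile
            return p / p.sum()
        delta = _displacement(t, breakpoints[seg], spec.pre_slope, spec.post_slope)
        p = (1.0 - delta) * base + delta * seg_target[seg]
        if spec.n_enriched > 0 and t >= spec.enriched_onset_h:
            p = p.copy()
            p[idx_enriched] *= spec.effect_size
        return p / p.sum()

    early_taxa = [i for i in idx_stage if stage_dir[asv_ids[i]] == "early"]
    late_taxa = [i for i in idx_stage if stage_dir[asv_ids[i]] == "late"]
    lottery_counter = {}

    def _finish_mean(p: np.ndarray, t: float, seg: str) -> np.ndarray:
        """Per-sample stage colonization and the emerged overlay."""
        stage = "early" if t <= 24.0 else ("late" if t >= 48.0 else None)
        eligible = (early_taxa if stage == "early"
                    else late_taxa if stage == "late" else [])
        if eligible:
            if spec.stage_lottery:
                # exactly one indicator per sample, rotating: lottery
                # colonization across individual hosts
                key = (seg, stage)
                k = lottery_counter.get(key, 0)
                lottery_counter[key] = k + 1
                chosen = [eligible[k % len(eligible)]]
            else:
                mask = rng.random(len(eligible)) < spec.stage_colonization_prob
                chosen = [i for i, hit in zip(eligible, mask) if hit]
            if chosen:
                p = p.copy()
                p[chosen] *= spec.effect_size
                p = p / p.sum()
        if spec.n_emerged > 0 and t >= spec.emerged_onset_h:
            e = spec.emerged_total_abundance
            p = (1.0 - e) * p + e * phi_sink
        return p

    # gut samples (postmolt time series + premolt CK), shared crabs per time
    counts_rows: list[np.ndarray] = []
    sample_ids: list[str] = []
    metas: list[SampleMeta] = []
    weights = {}
    for t in list(spec.timepoints) + ["CK"]:
        for r in range(spec.n_replicates):
            weights[(t, r)] = float(np.round(rng.lognormal(np.log(150.0), 0.15), 1))
    for seg in spec.segments:
        for t in spec.timepoints:
            mean = _mean_at(seg, t)
            for r in range(spec.n_replicates):
                sid = f"{seg}_t{t:g}_r{r + 1}"
                counts_rows.append(
                    _dm_sample(rng, _finish_mean(mean, t, seg),
                               spec.replicate_concentration, spec.seq_depth))
                sample_ids.append(sid)
                metas.append(SampleMeta(
                    sample_id=sid, habitat=seg, time_h=float(t),
                    replicate=f"r{r + 1}", crab_weight=weights[(t, r)],
                    crab_id=f"crab_t{t:g}_r{r + 1}",
                ))
        mean_ck = _mean_at(seg, None)
        for r in range(spec.n_replicates):
            sid = f"{seg}_CK_r{r + 1}"
            counts_rows.append(
                _dm_sample(rng, mean_ck, spec.replicate_concentration, spec.seq_depth))
            sample_ids.append(sid)
            metas.append(SampleMeta(
                sample_id=sid, habitat=seg, time_h=None, is_premolt_ck=True,
                replicate=f"r{r + 1}", crab_weight=weights[("CK", r)],
                crab_id=f"crab_CK_r{r + 1}",
            ))

    # source habitats: habitat-specific background block + own emerged pool
    n_src = len(spec.source_habitats)
    if n_src > 0 and idx_core.size >= n_src:
        bg_blocks = np.array_split(idx_core, n_src)
        for h, block in zip(spec.source_habitats, bg_blocks):
            bg = np.zeros(n)
            bg[block] = rng.dirichlet(np.full(block.size, 1.0))
            prof = 0.5 * bg
            if spec.n_emerged > 0:
                prof = prof + 0.5 * emerged_pool_profiles[h]
            else:
                prof = bg
            prof = prof / prof.sum()
            for r in range(spec.n_source_replicates):
                sid = f"{h}_t{spec.source_time_h:g}_r{r + 1}"
                counts_rows.append(
                    _dm_sample(rng, prof, spec.replicate_concentration,
                               spec.seq_depth))
                sample_ids.append(sid)
                metas.append(SampleMeta(
                    sample_id=sid, habitat=h, time_h=float(spec.source_time_h),
                    replicate=f"r{r + 1}", crab_id=f"env_{h}_r{r + 1}",
                ))

    table = CountTable(pd.DataFrame(
        np.asarray(counts_rows, dtype=np.int64), index=sample_ids, columns=asv_ids))

    taxonomy = _synthetic_taxonomy(rng, asv_ids)

    truth = GroundTruth(
        emerged={asv_ids[i]: spec.emerged_onset_h for i in idx_emerged},
        lost=[asv_ids[i] for i in idx_lost],
        enriched={asv_ids[i]: spec.enriched_onset_h for i in idx_enriched},
        stage_discriminative=stage_dir,
        true_breakpoints=dict(breakpoints),
        true_sink_mixtures={seg: dict(mix) for seg in spec.segments},
    )
    return table, metas, taxonomy, truth


def _synthetic_taxonomy(rng: np.random.Generator,
                        asv_ids: Sequence[str]) -> TaxonomyTable:
    rows = []
    for _ in asv_ids:
        phylum = _PHYLA[rng.integers(len(_PHYLA))]
        genus = _GENERA[rng.integers(len(_GENERA))]
        rows.append({
            "kingdom": "Bacteria", "phylum": phylum,
            "class": f"{phylum}_c", "order": f"{phylum}_o",
            "family": f"{genus}aceae", "genus": genus, "species": "",
        })
    df = pd.DataFrame(rows, index=list(asv_ids))[list(RANKS)]
    return TaxonomyTable(df)


def generate_function_table(
    spec: SyntheticSpec,
    seed: int | None = None,
    table: CountTable | None = None,
    truth: GroundTruth | None = None,
    n_pathways: int = 60,
    n_linked: int = 10,
    loading: float = 1.0,
    noise_sd: float = 0.25,
) -> tuple[FunctionTable, GroundTruth]:
    """Pathway table driven by designated taxon abundances.

    Each designated (taxon, pathway) pair multiplies the pathway's baseline
    weight by ``(x / mean(x)) ** loading`` where x is the taxon's relative
    abundance, plus lognormal noise; rows are then renormalized.  With
    positive loading and no noise the designated pathway is an exactly
    monotone function of its taxon, so Spearman rho = 1 downstream.
    With ``loading=0`` the table is a pure null for calibration runs.

    Designated taxa are the first ``n_linked`` planted enriched ASVs (they
    vary over time, so the correlation is detectable); falls back to the
    first ordinary taxa if none are planted.
    """
    if table is None or truth is None:
        table, _, _, truth = generate(spec)
    rng = np.random.default_rng(spec.seed + 10007 if seed is None else seed)
    rel = to_relative(table)
    pathway_ids = [f"PWY{k + 1:04d}" for k in range(n_pathways)]

    linked_taxa = list(truth.enriched)[:n_linked]
    if not linked_taxa:
        linked_taxa = list(rel.asv_ids)[-n_linked:]
    linked_taxa = linked_taxa[:min(n_linked, n_pathways)]

    baseline = rng.dirichlet(np.full(n_pathways, 5.0))
    eps = rng.normal(0.0, noise_sd, size=(len(rel.sample_ids), n_pathways))
    w = baseline[None, :] * np.exp(eps)
    pairs = []
    for k, taxon in enumerate(linked_taxa):
        x = rel.data[taxon].to_numpy() + 1e-6
        factor = (x / x.mean()) ** loading
        w[:, k] = w[:, k] * factor
        if loading > 0:
            pairs.append((taxon, pathway_ids[k], float(loading)))
    df = pd.DataFrame(w, index=rel.sample_ids, columns=pathway_ids)
    truth.linked_pairs = pairs
    return FunctionTable.from_raw(df), truth


def write_dataset(spec: SyntheticSpec, outdir: str | Path,
                  with_functions: bool = True) -> dict:
    """Materialize a synthetic dataset as the four TSVs plus ground truth."""
    from .data_model import (write_count_table, write_function_table,
                             write_metadata, write_taxonomy)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, metas, taxonomy, truth = generate(spec)
    paths = {
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    if with_functions:
        functions, truth = generate_function_table(spec, table=table, truth=truth)
        paths["functions"] = outdir / "functions.tsv"
        write_function_table(functions, paths["functions"])
    write_count_table(table, paths["counts"])
    write_metadata(metas, paths["metadata"])
    write_taxonomy(taxonomy, paths["taxonomy"])
    truth.to_json(paths["ground_truth"])
    return {k: str(v) for k, v in paths.items()}
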