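"""Microbial source tracking: EM mixture of named sources plus "unknown".

A sink's counts are modeled as multinomial with composition
``sum_s alpha_s * theta_s + alpha_u * theta_u`` where the ``theta_s`` are
smoothed source profiles (pooled replicate counts, pseudo-count 1e-6 on the
relative scale) and ``theta_u`` is an unknown-source profile re-estimated in
each M-step from the sink's unexplained mass.  The unknown profile carries a
symmetric Dirichlet prior (total prior mass defaulting to the sink depth):
an entirely free profile would make the model degenerate (the unknown
component alone can reproduce any sink exactly), whereas the smoothed update
lets the unknown component absorb mass only where the named sources
genuinely fail.  The reported likelihood trace is the EM objective
(log-likelihood plus the prior term) and is non-decreasing at every
iteration.

Single-ASV attribution is handled separately: a one-taxon multinomial
mixture is unidentifiable, so the attribution is the ASV's mean relative
abundance per habitat normalized over the habitats where it occurs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import CountTable, RelAbundTable, ValidationError

PSEUDO = 1e-6


@dataclass(frozen=True)
class SourceEstimate:
    """Mixing proportions over named sources plus "unknown" for one sink."""

    sink_id: str
    proportions: dict          # source name (incl. "unknown") -> fraction
    log_likelihood: tuple      # EM objective trace, non-decreasing
    n_iter: int
    converged: bool

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-8:
            raise ValidationError(f"proportions sum to {total}, not 1")


def _smooth_profiles(sources: pd.DataFrame) -> np.ndarray:
    rel = sources.to_numpy(float)
    totals = rel.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValidationError("a source profile has zero total abundance")
    rel = rel / totals
    rel = rel + PSEUDO
    return rel / rel.sum(axis=1, keepdims=True)


def em_source_track(
    sink: np.ndarray | pd.Series,
    sources: pd.DataFrame,
    tol: float = 1e-8,
    max_iter: int = 2000,
    seed: int = 0,
    n_restarts: int = 3,
    unknown: bool = True,
    unknown_prior_mass: float | None = None,
    effective_depth: float | None = 1000.0,
    sink_id: str = "sink",
) -> SourceEstimate:
    """EM estimate of source mixing proportions for one sink count vector.

    ``sources`` holds one row per named source (index = source names,
    columns aligned with the sink vector).  Restarts perturb the uniform
    initialization; the best-objective run is kept.  With ``unknown=False``
    the model reduces to a plain fixed-component mixture and fails hard if
    the sources cannot cover the sink support.

    ``effective_depth`` caps the information content of the sink: amplicon
    counts are overdispersed relative to multinomial sampling (replicates
    share community-level noise), so a sink pooled to 1e5 reads does not
    carry 1e5 independent observations.  The sink vector is rescaled to this
    total before the likelihood is formed, which leaves the maximizing
    proportions of the fixed-source part unchanged but keeps the adaptive
    unknown component from soaking up ordinary profile noise.  ``None``
    disables the cap.
    """
    x = (sink.to_numpy(float) if isinstance(sink, pd.Series)
         else np.asarray(sink, float))
    if x.ndim != 1 or x.sum() <= 0:
        raise ValidationError("sink must be a 1-D count vector with positive total")
    if sources.shape[0] < 1:
        raise ValidationError("need at least one source")
    if sources.shape[1] != x.size:
        raise ValidationError("sink and source profiles have mismatched taxa")
    names = [str(s) for s in sources.index]
    theta = _smooth_profiles(sources)
    n_src = theta.shape[0]
    if effective_depth is not None and x.sum() > effective_depth:
        x = x * (effective_depth / x.sum())
    total = x.sum()
    support = x > 0
    if not unknown and np.any(theta[:, support].sum(axis=0) <= n_src * PSEUDO * 2):
        # smoothing technically covers everything; flag true non-overlap
        raw = sources.to_numpy(float)
        if np.any((raw[:, support].sum(axis=0) == 0)):
            raise ValidationError(
                "sink support not covered by any source and unknown is disabled"
            )
    lam = (total / x.size if unknown_prior_mass is None
           else unknown_prior_mass / x.size)

    rng = np.random.default_rng(seed)
    best = None
    for restart in range(max(1, n_restarts)):
        k = n_src + (1 if unknown else 0)
        alpha = np.full(k, 1.0 / k)
        if restart > 0:
            alpha = rng.dirichlet(np.full(k, 5.0))
        theta_u = np.full(x.size, 1.0 / x.size)
        trace = []
        converged = False
        for it in range(max_iter):
            comp = np.vstack([theta, theta_u[None, :]]) if unknown else theta
            p = alpha @ comp
            np.clip(p, 1e-300, None, out=p)
            obj = float(x @ np.log(p))
            if unknown:
                obj += float(lam * np.log(theta_u).sum())
            trace.append(obj)
            resp = alpha[:, None] * comp / p[None, :]   # (k, J)
            weighted = resp * x[None, :]
            alpha_new = weighted.sum(axis=1) / total
            alpha_new = alpha_new / alpha_new.sum()
            if unknown:
                theta_u = weighted[-1] + lam
                theta_u = theta_u / theta_u.sum()
            delta = np.max(np.abs(alpha_new - alpha))
            alpha = alpha_new
            if delta < tol:
                converged = True
                break
        comp = np.vstack([theta, theta_u[None, :]]) if unknown else theta
        p = np.clip(alpha @ comp, 1e-300, None)
        obj = float(x @ np.log(p))
        if unknown:
            obj += float(lam * np.log(theta_u).sum())
        trace.append(obj)
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], alpha, tuple(trace), converged, len(trace) - 1)

    _, alpha, trace, converged, n_iter = best
    proportions = {name: float(a) for name, a in zip(names, alpha[:n_src])}
    if unknown:
        proportions["unknown"] = float(alpha[-1])
    # exact renormalization guards accumulated float error
    s = sum(proportions.values())
    proportions = {k: v / s for k, v in proportions.items()}
    return SourceEstimate(sink_id, proportions, trace, n_iter, converged)


def pooled_source_profiles(
    table: CountTable,
    metas: Sequence,
    source_habitats: Sequence[str],
    time_h: float | None = None,
) -> pd.DataFrame:
    """Pool replicate counts per source habitat (optionally at one time)."""
    rows = {}
    for hab in source_habitats:
        ids = [m.sample_id for m in metas
               if m.habitat == hab and not m.is_premolt_ck
               and (time_h is None or m.time_h == time_h)
               and m.sample_id in table.data.index]
        if not ids:
            continue
        rows[hab] = table.data.loc[ids].sum(axis=0)
    if not rows:
        raise ValidationError(
            f"no source samples found for habitats {list(source_habitats)}"
        )
    return pd.DataFrame(rows).T


def track_subset(
    sink_table: CountTable,
    labeling: pd.Series | pd.DataFrame,
    status: str,
    sources: pd.DataFrame,
    **em_kwargs,
) -> dict:
    """Source-track each sink restricted to one turnover status set.

    Sink counts and source profiles are restricted to the ASVs carrying
    ``status`` (e.g. "emerged" or "enriched") and renormalized before EM.
    Sinks whose restricted vector is empty are skipped with a warning.
    """
    import logging

    log = logging.getLogger("moltsucc")
    col = labeling["status"] if isinstance(labeling, pd.DataFrame) else labeling
    members = [a for a in col.index[col == status] if a in sink_table.data.columns]
    if not members:
        raise ValidationError(f"status {status!r} selects no ASVs")
    sub_sources = sources.loc[:, members]
    covered = sub_sources.sum(axis=1) > 0
    dropped = [str(s) for s in sub_sources.index[~covered]]
    if dropped and covered.any():
        log.warning("track_subset: sources %s carry no %s ASVs and get "
                    "proportion 0", dropped, status)
        sub_sources = sub_sources.loc[covered]
    elif dropped:
        # the subset is absent from every source: everything is unexplained,
        # so the attribution is trivially all-unknown
        log.warning("track_subset: no source carries any %s ASV; "
                    "attributing everything to the unknown source", status)
        out = {}
        for sid in sink_table.sample_ids:
            vec = sink_table.data.loc[sid, members].to_numpy(float)
            if vec.sum() == 0:
                continue
            theta_u = vec / vec.sum()
            ll = float(vec[vec > 0] @ np.log(theta_u[vec > 0]))
            proportions = {str(s): 0.0 for s in sources.index}
            proportions["unknown"] = 1.0
            out[sid] = SourceEstimate(sid, proportions, (ll,), 0, True)
        return out
    out = {}
    for sid in sink_table.sample_ids:
        vec = sink_table.data.loc[sid, members].to_numpy()
        if vec.sum() == 0:
            log.warning("track_subset: sink %r has no %s reads, skipped",
                        sid, status)
            continue
        est = em_source_track(vec, sub_sources, sink_id=sid, **em_kwargs)
        for name in dropped:
            est.proportions[name] = 0.0
        out[sid] = est
    return out


def track_single_asv(
    asv_id: str,
    tables_by_habitat: Mapping[str, CountTable | RelAbundTable],
) -> dict:
    """Degenerate single-taxon attribution.

    The proportion assigned to habitat h is the ASV's mean relative
    abundance over h's samples, normalized across the habitats where the ASV
    occurs.  Raises if the ASV is absent everywhere.
    """
    means = {}
    for hab, t in tables_by_habitat.items():
        df = t.data
        if asv_id not in df.columns:
            means[hab] = 0.0
            continue
        rel = df.div(df.sum(axis=1), axis=0) if isinstance(t, CountTable) else df
        means[hab] = float(rel[asv_id].mean())
    total = sum(means.values())
    if total <= 0:
        raise ValidationError(f"ASV {asv_id!r} absent from every habitat")
    return {h: v / total for h, v in means.items()}
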