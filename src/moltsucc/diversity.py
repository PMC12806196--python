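"""Alpha diversity, Bray-Curtis dissimilarity, mixed-gut construction,
distance-decay regression, and segment-versus-whole linear relationships."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .data_model import (
    CountTable,
    RelAbundTable,
    SampleMeta,
    ValidationError,
    rarefy,
)

log = logging.getLogger("moltsucc")


def alpha(t: CountTable) -> pd.DataFrame:
    """Observed richness and Shannon entropy (natural log) per sample."""
    counts = t.counts.astype(float)
    richness = (counts > 0).sum(axis=1)
    p = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    return pd.DataFrame(
        {"richness": richness.astype(int), "shannon": shannon},
        index=t.data.index,
    )


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities in [0, 1] with zero diagonal."""

    sample_ids: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValidationError("dissimilarity matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("dissimilarity matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValidationError("dissimilarity matrix diagonal must be zero")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValidationError("dissimilarities must lie in [0, 1]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)

    def get(self, i: str, j: str) -> float:
        a, b = self.sample_ids.index(i), self.sample_ids.index(j)
        return float(self.values[a, b])


def bray_curtis(rel: RelAbundTable) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis: d(x, y) = sum|x - y| / sum(x + y)."""
    d = squareform(pdist(rel.values, metric="braycurtis"))
    return DissimilarityMatrix(tuple(rel.sample_ids), d)


def build_mixed_gut(
    t: CountTable,
    metas: Sequence[SampleMeta],
    segments: tuple = ("foregut", "midgut", "hindgut"),
    depth: int | None = None,
    seed: int = 0,
) -> tuple[CountTable | None, list[SampleMeta]]:
    """Merge each crab's segment samples into a mock whole-gut sample.

    For every (crab_id, time point) with all three segment samples present,
    the mixed sample is the element-wise sum of segment counts (the
    count-level equivalent of merging sequencing reads).  Incomplete triplets
    are skipped with a logged warning.  If ``depth`` is given the merged
    table is rarefied to it so mixed and segment samples stay
    depth-comparable.
    """
    by_key: dict[tuple, dict[str, SampleMeta]] = {}
    for m in metas:
        if m.habitat in segments:
            key = (m.crab_id, "CK" if m.is_premolt_ck else m.time_h)
            by_key.setdefault(key, {})[m.habitat] = m
    rows, ids, out_meta = [], [], []
    for key in sorted(by_key, key=str):
        found = by_key[key]
        if set(found) != set(segments):
            log.warning(
                "build_mixed_gut: skipping crab %s at %s (missing %s)",
                key[0], key[1], sorted(set(segments) - set(found)),
            )
            continue
        member_ids = [found[s].sample_id for s in segments]
        rows.append(t.data.loc[member_ids].sum(axis=0).to_numpy())
        ref = found[segments[0]]
        sid = f"mixed_{key[0]}_{key[1]}"
        ids.append(sid)
        out_meta.append(SampleMeta(
            sample_id=sid, habitat="mixed_gut",
            time_h=None if ref.is_premolt_ck else ref.time_h,
            is_premolt_ck=ref.is_premolt_ck, replicate=ref.replicate,
            crab_weight=ref.crab_weight, crab_id=ref.crab_id,
        ))
    if not rows:
        return None, []
    mixed = CountTable(pd.DataFrame(
        np.asarray(rows, dtype=np.int64), index=ids, columns=t.data.columns))
    if depth is not None:
        mixed = rarefy(mixed, depth, seed)
        kept = set(mixed.sample_ids)
        out_meta = [m for m in out_meta if m.sample_id in kept]
    return mixed, out_meta


def distance_decay(
    d: DissimilarityMatrix,
    metas: Sequence[SampleMeta],
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float, float]:
    """OLS of within-habitat pairwise dissimilarity on |Delta t|.

    Returns ``(slope, r_squared, p_perm)``.  Significance comes from
    permuting sample time labels within habitat (``n_perm`` permutations,
    +1 smoothing on the count of |slope*| >= |slope|).  Premolt CK samples
    carry no time and are excluded.
    """
    by_id = {m.sample_id: m for m in metas}
    idx, times, habs = [], [], []
    for k, sid in enumerate(d.sample_ids):
        m = by_id.get(sid)
        if m is not None and not m.is_premolt_ck and m.time_h is not None:
            idx.append(k)
            times.append(m.time_h)
            habs.append(m.habitat)
    times = np.asarray(times, float)
    habs = np.asarray(habs)
    idx = np.asarray(idx, int)
    if len(np.unique(times)) < 3:
        raise ValidationError("distance decay needs >= 3 distinct time points")
    ii, jj = np.triu_indices(len(idx), k=1)
    same = habs[ii] == habs[jj]
    ii, jj = ii[same], jj[same]
    if ii.size < 10:
        raise ValidationError(f"only {ii.size} usable within-habitat pairs (< 10)")
    y = d.values[np.ix_(idx, idx)][ii, jj]

    def _slope_r2(tvec: np.ndarray) -> tuple[float, float]:
        x = np.abs(tvec[ii] - tvec[jj])
        x_c = x - x.mean()
        y_c = y - y.mean()
        sxx = float(x_c @ x_c)
        if sxx == 0:
            return 0.0, 0.0
        slope = float(x_c @ y_c) / sxx
        syy = float(y_c @ y_c)
        r2 = 0.0 if syy == 0 else (float(x_c @ y_c) ** 2) / (sxx * syy)
        return slope, r2

    slope, r2 = _slope_r2(times)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = times.copy()
        for h in np.unique(habs):  # permute time labels within habitat
            sel = np.flatnonzero(habs == h)
            perm[sel] = perm[rng.permutation(sel)]
        s_perm, _ = _slope_r2(perm)
        if abs(s_perm) >= abs(slope) - 1e-15:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return slope, r2, p


def segment_vs_reference(
    metric_by_segment: Mapping[str, pd.Series],
    metric_reference: pd.Series,
) -> pd.DataFrame:
    """Per-segment simple linear regression of a reference metric time series
    on each segment's series, ranked by r-squared (descending).

    Series are aligned on their (time) index; a segment with fewer than 3
    aligned points or zero variance is a hard error — such a fit is
    meaningless, not merely weak.
    """
    rows = []
    for seg, series in metric_by_segment.items():
        joined = pd.concat([series, metric_reference], axis=1, join="inner").dropna()
        if len(joined) < 3:
            raise ValidationError(
                f"segment {seg!r}: only {len(joined)} aligned points (< 3)"
            )
        x = joined.iloc[:, 0].to_numpy(float)
        yref = joined.iloc[:, 1].to_numpy(float)
        if np.ptp(x) == 0:
            raise ValidationError(f"segment {seg!r}: constant metric series")
        fit = stats.linregress(x, yref)
        rows.append({
            "segment": seg,
            "slope": fit.slope,
            "r_squared": fit.rvalue ** 2,
            "p_value": fit.pvalue,
            "n": len(joined),
        })
    out = pd.DataFrame(rows).set_index("segment")
    return out.sort_values("r_squared", ascending=False)
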