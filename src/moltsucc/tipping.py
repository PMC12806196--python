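"""Tipping-point detection on dissimilarity-to-baseline trajectories.

The community's displacement from its 0 h baseline is summarized per sample
as the mean Bray-Curtis dissimilarity to all baseline replicates of the same
habitat.  A continuous two-segment ("hinge") linear model

    y = a + b * t + c * max(t - tau, 0)

is fitted by exhaustive grid search over the breakpoint tau; the estimate is
continuous (not snapped to sampling times).  Because tau is estimated, the
classical F null does not apply: significance against the single-line model
comes from a residual bootstrap under the null, and the breakpoint
confidence interval from a percentile bootstrap of the hinge fit.  Residuals
are inflated by sqrt(n / (n - p)) before resampling (the usual degrees-of-
freedom correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import RelAbundTable, SampleMeta, ValidationError
from .diversity import bray_curtis


@dataclass(frozen=True)
class BreakpointFit:
    """Two-segment continuous fit of dissimilarity-to-baseline vs time."""

    tau: float
    slope_pre: float
    slope_post: float
    intercept: float
    rss_segmented: float
    rss_linear: float
    p_value: float
    ci_tau: tuple
    significant: bool
    n: int


def _hinge_qs(t: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Stack of thin-QR orthonormal bases of [1, t, (t - tau)_+] per tau."""
    n = t.size
    qs = np.empty((grid.size, n, 3))
    for g, tau in enumerate(grid):
        x = np.column_stack([np.ones(n), t, np.maximum(t - tau, 0.0)])
        q, _ = np.linalg.qr(x)
        qs[g] = q
    return qs


def _rss_all(qs: np.ndarray, y: np.ndarray) -> np.ndarray:
    """RSS of every grid model for every response column.

    qs: (G, n, 3); y: (n, B) -> (G, B).
    """
    proj = np.einsum("gnk,nb->gkb", qs, y)
    return np.sum(y * y, axis=0)[None, :] - np.sum(proj * proj, axis=1)


def fit_breakpoint(
    times: Sequence[float],
    values: Sequence[float],
    grid_step: float = 0.1,
    n_boot: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> BreakpointFit:
    """Fit the hinge model and test it against a single straight line.

    The breakpoint grid runs from the 2nd to the penultimate distinct time
    in steps of ``grid_step`` hours.  With ``n_boot=0`` only the point
    estimate is computed (p = NaN, CI = (NaN, NaN), significant = False).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValidationError("times and values must be equal-length vectors")
    if not np.all(np.isfinite(y)):
        raise ValidationError("values must be finite")
    distinct = np.unique(t)
    if distinct.size < 4:
        raise ValidationError(
            f"need >= 4 distinct time points, got {distinct.size}"
        )
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    lo, hi = distinct[1], distinct[-2]
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid.size == 0:
        raise ValidationError("empty breakpoint grid")
    n = t.size

    qs = _hinge_qs(t, grid)
    rss_grid = _rss_all(qs, y[:, None])[:, 0]
    best = int(np.argmin(rss_grid))
    tau = float(grid[best])
    x_best = np.column_stack([np.ones(n), t, np.maximum(t - tau, 0.0)])
    coef, *_ = np.linalg.lstsq(x_best, y, rcond=None)
    yhat_seg = x_best @ coef
    rss_seg = float(np.sum((y - yhat_seg) ** 2))

    x_lin = np.column_stack([np.ones(n), t])
    coef_lin, *_ = np.linalg.lstsq(x_lin, y, rcond=None)
    yhat_lin = x_lin @ coef_lin
    rss_lin = float(np.sum((y - yhat_lin) ** 2))
    rss_seg = min(rss_seg, rss_lin)  # nested models, guard numerics

    p_value = float("nan")
    ci = (float("nan"), float("nan"))
    significant = False
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        q_lin, _ = np.linalg.qr(x_lin)

        # null: straight line + resampled (df-inflated) linear residuals
        resid_lin = (y - yhat_lin) * np.sqrt(n / max(n - 2, 1))
        idx = rng.integers(0, n, size=(n, n_boot))
        yb = yhat_lin[:, None] + resid_lin[idx]
        rss_lin_b = np.sum(yb * yb, axis=0) - np.sum((q_lin.T @ yb) ** 2, axis=0)
        rss_seg_b = _rss_all(qs, yb).min(axis=0)
        null_gain = rss_lin_b - rss_seg_b
        obs_gain = rss_lin - rss_seg
        p_value = float((np.sum(null_gain >= obs_gain - 1e-12) + 1) / (n_boot + 1))
        significant = p_value < alpha

        # percentile bootstrap of tau under the hinge fit
        resid_seg = (y - yhat_seg) * np.sqrt(n / max(n - 3, 1))
        idx2 = rng.integers(0, n, size=(n, n_boot))
        yb2 = yhat_seg[:, None] + resid_seg[idx2]
        tau_b = grid[np.argmin(_rss_all(qs, yb2), axis=0)]
        ci = (float(np.percentile(tau_b, 2.5)), float(np.percentile(tau_b, 97.5)))

    return BreakpointFit(
        tau=tau,
        slope_pre=float(coef[1]),
        slope_post=float(coef[1] + coef[2]),
        intercept=float(coef[0]),
        rss_segmented=rss_seg,
        rss_linear=rss_lin,
        p_value=p_value,
        ci_tau=ci,
        significant=significant,
        n=int(n),
    )


def dissimilarity_to_baseline(
    rel: RelAbundTable,
    metas: Sequence[SampleMeta],
    baseline_time: float = 0.0,
) -> dict:
    """Per habitat: (times, values) of mean Bray-Curtis to the 0 h baseline.

    For each non-baseline postmolt sample the value is the mean Bray-Curtis
    dissimilarity to every baseline replicate of the same habitat.  Habitats
    without baseline samples are skipped with a warning.  CK samples are not
    part of the postmolt trajectory.
    """
    import logging

    log = logging.getLogger("moltsucc")
    by_id = {m.sample_id: m for m in metas}
    d = bray_curtis(rel)
    pos = {sid: k for k, sid in enumerate(d.sample_ids)}
    habitats = sorted({m.habitat for m in metas
                       if m.sample_id in pos and not m.is_premolt_ck})
    out = {}
    for hab in habitats:
        base_idx = [pos[m.sample_id] for m in metas
                    if m.habitat == hab and not m.is_premolt_ck
                    and m.time_h == baseline_time and m.sample_id in pos]
        if not base_idx:
            log.warning("dissimilarity_to_baseline: no baseline for %r", hab)
            continue
        ts, vs = [], []
        for m in metas:
            if (m.habitat != hab or m.is_premolt_ck or m.time_h is None
                    or m.time_h == baseline_time or m.sample_id not in pos):
                continue
            row = d.values[pos[m.sample_id], base_idx]
            ts.append(m.time_h)
            vs.append(float(np.mean(row)))
        out[hab] = (np.asarray(ts, float), np.asarray(vs, float))
    return out
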