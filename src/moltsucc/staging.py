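"""Random-forest staging: early/late discrimination, cross-validated taxon
selection, crab-weight association, and early/late/general clustering.

The tipping-point analysis motivates a stage mark (24 h by default): samples
at or before the mark are "early", later ones "late", and the premolt CK
control is excluded.  A random-forest classifier ranks taxa by importance;
the ten-fold cross-validation error curve over increasing importance-ranked
panels (re-ranked inside each training fold, so the curve is leakage-free)
picks the panel size at the cross-validated error minimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .data_model import RelAbundTable, SampleMeta, ValidationError
from .stability import avd_stability, group_compare

log = logging.getLogger("moltsucc")


def assign_stages(
    metas: Sequence[SampleMeta],
    tipping_mark_h: float = 24.0,
    habitat: str | None = None,
) -> pd.Series:
    """Early/late stage labels from the tipping mark (CK excluded).

    time <= mark -> "early"; time > mark -> "late".  Raises if either side
    would be empty.
    """
    labels = {}
    for m in metas:
        if m.is_premolt_ck or m.time_h is None:
            continue
        if habitat is not None and m.habitat != habitat:
            continue
        labels[m.sample_id] = "early" if m.time_h <= tipping_mark_h else "late"
    s = pd.Series(labels, name="stage")
    if (s == "early").sum() == 0 or (s == "late").sum() == 0:
        raise ValidationError(
            f"tipping mark {tipping_mark_h} h leaves an empty stage "
            f"(early={(s == 'early').sum()}, late={(s == 'late').sum()})"
        )
    return s


@dataclass(frozen=True)
class StageModel:
    """Importance ranking, CV error curve, and the selected taxon panel."""

    importance_ranking: pd.Series      # taxon -> importance, descending
    cv_curve: pd.DataFrame             # index n_taxa; mean_error, se
    selected_taxa: tuple
    seed: int
    k_folds: int
    stages: pd.Series = field(repr=False, default=None)


def _head_sizes(n_features: int, max_head: int | None = None) -> list[int]:
    sizes, a, b = [], 1, 2
    limit = n_features if max_head is None else min(max_head, n_features)
    while a <= limit:
        sizes.append(a)
        a, b = b, a + b
    if sizes and sizes[-1] != n_features:
        sizes.append(n_features)
    return sizes


def _rank_features(clf: RandomForestClassifier, columns: pd.Index) -> np.ndarray:
    # stable sort so importance ties break by column position
    return np.argsort(-clf.feature_importances_, kind="stable")


def rf_stage_selection(
    rel: RelAbundTable,
    stages: pd.Series,
    n_trees: int = 1000,
    k_folds: int = 10,
    seed: int = 0,
    max_head: int | None = None,
    se_multiplier: float = 0.0,
    cv_n_trees: int | None = None,
    cv_repeats: int = 2,
) -> StageModel:
    """Forest importance ranking plus leakage-free CV error curve.

    The final ranking is fitted on all data; the error at each panel size n
    (Fibonacci-style grid 1, 2, 3, 5, 8, ... capped at the taxon count) is
    estimated by stratified k-fold CV where the importance ranking is
    recomputed inside each training fold before truncating to its top n.
    The selected panel is the smallest n whose mean CV error is within
    ``se_multiplier`` standard errors of the minimum; the default multiplier
    of 0 picks the error-curve minimum itself (ties toward fewer taxa), and a
    positive multiplier trades panel size for parsimony in the usual
    1-standard-error fashion.  ``cv_n_trees`` (default ``n_trees``) sizes the
    in-fold forests, which are refit dozens of times, and ``cv_repeats``
    repeats the whole k-fold split with fresh shuffles to smooth the error
    curve against fold-assignment noise.
    """
    common = [s for s in rel.sample_ids if s in stages.index]
    x = rel.data.loc[common]
    y = stages.loc[common].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 3:
        raise ValidationError(
            f"need two stages with >= 3 samples each, got {dict(zip(classes, counts))}"
        )
    k = min(k_folds, int(counts.min()))
    if k < k_folds:
        log.warning("rf_stage_selection: reducing folds from %d to %d "
                    "(smallest class has %d samples)", k_folds, k, counts.min())
    if k < 2:
        raise ValidationError("cannot stratify: a stage has fewer than 2 samples")

    cv_trees = n_trees if cv_n_trees is None else cv_n_trees
    full = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    full.fit(x.to_numpy(), y)
    order = _rank_features(full, x.columns)
    ranking = pd.Series(full.feature_importances_[order],
                        index=x.columns[order], name="importance")

    heads = _head_sizes(x.shape[1], max_head)
    if cv_repeats > 1:
        skf = RepeatedStratifiedKFold(n_splits=k, n_repeats=cv_repeats,
                                      random_state=seed)
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    n_iter = k * cv_repeats
    errors = np.zeros((n_iter, len(heads)))
    xv = x.to_numpy()
    for f, (tr, te) in enumerate(skf.split(xv, y)):
        if len(np.unique(y[tr])) < 2:
            raise ValidationError("degenerate single-class training fold")
        ranker = RandomForestClassifier(
            n_estimators=cv_trees, random_state=seed + 1000 + f, n_jobs=1)
        ranker.fit(xv[tr], y[tr])
        fold_order = _rank_features(ranker, x.columns)
        for h, n_top in enumerate(heads):
            cols = fold_order[:n_top]
            clf = RandomForestClassifier(
                n_estimators=cv_trees, random_state=seed + 2000 + f, n_jobs=1)
            clf.fit(xv[np.ix_(tr, cols)], y[tr])
            errors[f, h] = float(np.mean(clf.predict(xv[np.ix_(te, cols)]) != y[te]))
    mean_err = errors.mean(axis=0)
    se = errors.std(axis=0, ddof=1) / np.sqrt(n_iter)
    curve = pd.DataFrame({"mean_error": mean_err, "se": se},
                         index=pd.Index(heads, name="n_taxa"))
    best = int(np.argmin(mean_err))
    threshold = mean_err[best] + se_multiplier * se[best]
    n_selected = next(h for h, m in zip(heads, mean_err) if m <= threshold + 1e-12)
    selected = tuple(ranking.index[:n_selected])
    return StageModel(ranking, curve, selected, seed, k, stages.loc[common])


def weight_association(
    rel: RelAbundTable,
    weights: pd.Series,
    selected: Sequence[str],
    alpha: float = 0.05,
) -> dict:
    """Spearman taxon-vs-crab-weight screen with BH correction.

    Returns the significant taxon set, its intersection with the selected
    stage panel, and the full statistics frame.
    """
    common = [s for s in rel.sample_ids if s in weights.index
              and not pd.isna(weights.loc[s])]
    if len(common) < 5:
        raise ValidationError("need >= 5 samples with crab weights")
    w = weights.loc[common].to_numpy(float)
    if np.ptp(w) == 0:
        raise ValidationError("constant crab weights")
    x = rel.data.loc[common]
    rho = np.zeros(x.shape[1])
    p = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        col = x.iloc[:, j].to_numpy()
        if np.ptp(col) == 0:
            rho[j], p[j] = np.nan, 1.0
        else:
            rho[j], p[j] = stats.spearmanr(col, w)
    q = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame({"rho": rho, "p_value": p, "q_value": q},
                         index=x.columns)
    significant = set(table.index[table["q_value"] < alpha])
    return {
        "significant": significant,
        "intersection": significant & set(selected),
        "table": table,
    }


def partition_clusters(
    rel: RelAbundTable,
    stages: pd.Series,
    selected: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Partition every ASV into early / late / general clusters.

    A selected taxon is "early" when its mean relative abundance is higher
    in the early stage with rank-sum BH q < alpha ("late" symmetric);
    selected taxa failing significance, and all non-selected taxa, are
    "general".  Clusters therefore partition the ASV universe exactly once.
    """
    if len(selected) == 0:
        raise ValidationError("selected taxon set is empty")
    common = [s for s in rel.sample_ids if s in stages.index]
    x = rel.data.loc[common]
    y = stages.loc[common]
    early = x.loc[y == "early"]
    late = x.loc[y == "late"]
    sel = [t for t in selected if t in x.columns]
    pvals, means_e, means_l = [], [], []
    for t in sel:
        a, b = early[t].to_numpy(), late[t].to_numpy()
        if np.ptp(np.concatenate([a, b])) == 0:
            pvals.append(1.0)
        else:
            pvals.append(stats.mannwhitneyu(a, b, alternative="two-sided")[1])
        means_e.append(a.mean())
        means_l.append(b.mean())
    qvals = multipletests(pvals, method="fdr_bh")[1] if sel else np.array([])
    cluster = pd.Series("general", index=rel.data.columns, name="cluster")
    stats_rows = pd.DataFrame(
        {"mean_early": np.nan, "mean_late": np.nan, "q_value": np.nan},
        index=rel.data.columns)
    n_demoted = 0
    for t, q, me, ml in zip(sel, qvals, means_e, means_l):
        stats_rows.loc[t] = [me, ml, q]
        if q < alpha:
            cluster.loc[t] = "early" if me > ml else "late"
        else:
            n_demoted += 1
    if n_demoted:
        log.info("partition_clusters: %d selected taxa lacked stage "
                 "significance and fall back to 'general'", n_demoted)
    out = stats_rows
    out.insert(0, "cluster", cluster)
    return out


def cluster_panels(
    rel: RelAbundTable,
    clusters: pd.DataFrame | pd.Series,
    metas: Sequence[SampleMeta],
    habitat: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per (cluster x time point): AVD stability, total relative abundance,
    and richness, with compact-letter groups across time points.

    Empty clusters yield rows of nulls with a warning.  Letters compare the
    per-replicate values across time points within each cluster and panel.
    """
    cl = clusters["cluster"] if isinstance(clusters, pd.DataFrame) else clusters
    by_time: dict[float, list[str]] = {}
    for m in metas:
        if m.is_premolt_ck or m.time_h is None:
            continue
        if habitat is not None and m.habitat != habitat:
            continue
        if m.sample_id in rel.data.index:
            by_time.setdefault(m.time_h, []).append(m.sample_id)
    times = sorted(by_time)
    all_ids = [sid for t in times for sid in by_time[t]]
    rows = []
    for name in ("early", "late", "general"):
        members = list(cl.index[cl == name])
        if not members:
            log.warning("cluster_panels: cluster %r is empty", name)
            for t in times:
                rows.append({"cluster": name, "time_h": t, "stability_index":
                             None, "total_rel_abund_pct": None, "richness": None})
            continue
        sub_all = rel.data.loc[all_ids, members]
        abund_values, rich_values = {}, {}
        for t in times:
            sub = rel.data.loc[by_time[t], members]
            abund_values[t] = sub.sum(axis=1).to_numpy() * 100.0
            rich_values[t] = (sub > 0).sum(axis=1).to_numpy()
        abund_letters = group_compare(
            {str(t): abund_values[t] for t in times}, alpha)
        rich_letters = group_compare(
            {str(t): rich_values[t].astype(float) for t in times}, alpha)
        for t in times:
            try:
                _, stab = avd_stability(rel.data.loc[by_time[t], members],
                                        reference=sub_all)
            except ValidationError:
                stab = None
            rows.append({
                "cluster": name,
                "time_h": t,
                "stability_index": stab,
                "total_rel_abund_pct": float(np.mean(abund_values[t])),
                "richness": float(np.mean(rich_values[t])),
                "abund_letters": abund_letters.loc[str(t), "letters"],
                "richness_letters": rich_letters.loc[str(t), "letters"],
            })
    return pd.DataFrame(rows).set_index(["cluster", "time_h"])
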