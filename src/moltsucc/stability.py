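"""Community and functional stability, multifunctionality, and
taxon-function correlation screening.

Stability uses the average variation degree (AVD): for every taxon with
nonzero variance over a reference sample set, each replicate contributes the
standardized absolute deviation |x - mu| / sigma, and AVD is the mean over
(taxa x replicates).  Lower AVD means a more stable community; the reported
stability index 1 / (1 + AVD) maps it to (0, 1].  Multifunctionality is the
averaging flavor: the per-sample mean of column-standardized pathway
abundances.
"""

from __future__ import annotations

import itertools
import logging
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import FunctionTable, RelAbundTable, ValidationError

log = logging.getLogger("moltsucc")


def avd_stability(
    values: RelAbundTable | FunctionTable | pd.DataFrame,
    feature_subset: Sequence[str] | None = None,
    reference: pd.DataFrame | None = None,
) -> tuple[float, float]:
    """Average variation degree and stability index of a replicate slice.

    Deviations are centered on the slice's own per-feature mean (so identical
    replicates give AVD 0 exactly) and scaled by the population standard
    deviation of ``reference`` — by default the slice itself, but passing the
    habitat's full sample set keeps per-time-point AVD values on a common
    scale along a succession series.  Features with zero reference variance
    are excluded; if nothing survives, that is a hard error.  Returns
    ``(avd, 1/(1+avd))``.
    """
    df = values if isinstance(values, pd.DataFrame) else values.data
    if feature_subset is not None:
        missing = [f for f in feature_subset if f not in df.columns]
        if missing:
            raise ValidationError(f"unknown features in subset: {missing[:5]}")
        df = df.loc[:, list(feature_subset)]
    if df.shape[0] < 2:
        raise ValidationError(f"need >= 2 replicates, got {df.shape[0]}")
    ref = df if reference is None else reference.loc[:, df.columns]
    mu = df.mean(axis=0).to_numpy()
    sigma = ref.std(axis=0, ddof=0).to_numpy()
    ok = sigma > 0
    if not np.any(ok):
        raise ValidationError("all features have zero variance in the reference set")
    dev = np.abs(df.to_numpy()[:, ok] - mu[ok]) / sigma[ok]
    avd = float(dev.mean())
    return avd, 1.0 / (1.0 + avd)


def stability_series(
    rel: RelAbundTable | FunctionTable,
    groups: Mapping[str, Sequence[str]],
    feature_subset: Sequence[str] | None = None,
    shared_reference: bool = True,
) -> pd.DataFrame:
    """AVD stability per group of replicate sample ids.

    With ``shared_reference`` the mean/sd baseline is the union of all
    grouped samples, so entries are comparable across the series.
    """
    df = rel.data
    all_ids = [sid for ids in groups.values() for sid in ids]
    ref = df.loc[all_ids] if shared_reference else None
    if feature_subset is not None:
        ref = None if ref is None else ref.loc[:, list(feature_subset)]
    rows = []
    for gid, ids in groups.items():
        sub = df.loc[list(ids)]
        if feature_subset is not None:
            sub = sub.loc[:, list(feature_subset)]
        avd, stab = avd_stability(
            sub, reference=df.loc[all_ids] if shared_reference else None)
        rows.append({"group": gid, "n": len(ids), "avd": avd,
                     "stability_index": stab})
    return pd.DataFrame(rows).set_index("group")


def multifunctionality(f: FunctionTable) -> pd.Series:
    """Per-sample mean of pathway z-scores (averaging multifunctionality).

    Zero-variance pathways are dropped with a warning; if every pathway is
    degenerate the input cannot be scored.  The scores average to 0 over the
    standardization sample set by construction.
    """
    df = f.data
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValidationError("need >= 2 samples and >= 2 pathways")
    sd = df.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = list(df.columns[~keep])
    if dropped:
        log.warning("multifunctionality: dropping %d zero-variance pathways",
                    len(dropped))
    if not keep.any():
        raise ValidationError("every pathway has zero variance across samples")
    z = (df.loc[:, keep] - df.loc[:, keep].mean(axis=0)) / sd[keep]
    return z.mean(axis=1).rename("multifunctionality")


def functional_stability(
    f: FunctionTable,
    groups: Mapping[str, Sequence[str]],
    shared_reference: bool = True,
) -> pd.DataFrame:
    """AVD stability of the pathway table per group (see avd_stability)."""
    return stability_series(f, groups, shared_reference=shared_reference)


def taxa_function_correlation(
    rel: RelAbundTable,
    f: FunctionTable,
    taxa: Sequence[str] | None = None,
    pathways: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman screen over a (taxon x pathway) grid with BH correction.

    Returns one row per tested pair: rho, p, q, and sign ("positive" /
    "negative" / "ns").  Sample sets must be aligned (same ids, same order
    after reindexing).
    """
    if set(rel.sample_ids) != set(f.sample_ids):
        raise ValidationError("taxon and pathway tables cover different samples")
    fx = f.data.loc[rel.data.index]
    taxa = list(rel.asv_ids) if taxa is None else list(taxa)
    pathways = list(f.pathway_ids) if pathways is None else list(pathways)
    missing = [t for t in taxa if t not in rel.data.columns]
    missing += [p for p in pathways if p not in fx.columns]
    if missing:
        raise ValidationError(f"unknown ids in screen: {missing[:5]}")
    xt = rel.data[taxa].to_numpy()
    xp = fx[pathways].to_numpy()
    rows = []
    for i, taxon in enumerate(taxa):
        for j, pwy in enumerate(pathways):
            rho, p = stats.spearmanr(xt[:, i], xp[:, j])
            rows.append({"taxon": taxon, "pathway": pwy,
                         "rho": float(rho), "p_value": float(p)})
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out["p_value"].fillna(1.0), method="fdr_bh")[1]
    out["sign"] = np.where(
        out["q_value"] < alpha,
        np.where(out["rho"] > 0, "positive", "negative"),
        "ns",
    )
    return out


def significant_pathway_counts(screen: pd.DataFrame) -> pd.DataFrame:
    """Per taxon: number of significantly positive / negative pathways."""
    sig = screen[screen["sign"] != "ns"]
    counts = (sig.groupby(["taxon", "sign"]).size().unstack(fill_value=0)
              .reindex(columns=["positive", "negative"], fill_value=0))
    return counts


def group_compare(
    values_by_group: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Kruskal-Wallis omnibus + pairwise rank-sum/BH compact letter display.

    Letters come from the maximal cliques of the non-significance graph
    (groups in insertion order; cliques ordered by their first member), so
    every non-significant pair shares at least one letter and no significant
    pair shares any.  A non-significant omnibus test, or a single group,
    yields a single shared letter.
    """
    groups = list(values_by_group)
    if len(groups) == 0:
        raise ValidationError("no groups")
    arrays = {g: np.asarray(values_by_group[g], float) for g in groups}
    for g, v in arrays.items():
        if len(groups) > 1 and v.size < 3:
            raise ValidationError(f"group {g!r} has fewer than 3 values")
    order = {g: k for k, g in enumerate(groups)}
    if len(groups) == 1:
        return pd.DataFrame({"letters": ["a"]}, index=groups)
    try:
        _, omnibus_p = stats.kruskal(*arrays.values())
    except ValueError:  # all values identical across every group
        omnibus_p = 1.0
    if not np.isfinite(omnibus_p) or omnibus_p >= alpha:
        return pd.DataFrame({"letters": ["a"] * len(groups)}, index=groups)
    pairs = list(itertools.combinations(groups, 2))
    pvals = []
    for a, b in pairs:
        _, p = stats.mannwhitneyu(arrays[a], arrays[b],
                                  alternative="two-sided")
        pvals.append(p)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    ns_graph = nx.Graph()
    ns_graph.add_nodes_from(groups)
    for (a, b), q in zip(pairs, qvals):
        if q >= alpha:
            ns_graph.add_edge(a, b)
    cliques = [sorted(c, key=order.get) for c in nx.find_cliques(ns_graph)]
    cliques.sort(key=lambda c: [order[g] for g in c])
    letters = {g: "" for g in groups}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for k, clique in enumerate(cliques):
        letter = alphabet[k % len(alphabet)] * (k // len(alphabet) + 1)
        for g in clique:
            letters[g] += letter
    return pd.DataFrame({"letters": [letters[g] for g in groups]}, index=groups)
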