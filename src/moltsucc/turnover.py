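"""ASV turnover relative to the 0 h postmolt baseline.

Two complementary classifications per comparison group:

* presence/absence ("emerged" in a postmolt group, "lost" when the group is
  the premolt CK control): absent in every baseline replicate yet present in
  enough group replicates, or the mirror image;
* differential relative abundance ("enriched"/"depleted"): two-sided
  Wilcoxon rank-sum per ASV with Benjamini-Hochberg correction and a fold
  filter.  With two groups the rank-sum test is the two-sample equivalent of
  the Kruskal-Wallis test used for multi-group panels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import CountTable, RelAbundTable, ValidationError

PSEUDO_FRACTION = 1e-6  # added to mean relative abundances before fold ratios


def _check_same_asvs(a, b) -> None:
    if list(a.data.columns) != list(b.data.columns):
        if set(a.data.columns) != set(b.data.columns):
            raise ValidationError("baseline and group tables carry different ASV sets")
        raise ValidationError(
            "baseline and group tables carry the same ASVs in different order"
        )


def classify_presence(
    baseline: CountTable,
    group: CountTable,
    min_count: int = 2,
    min_prevalence: float = 0.5,
    label: str = "emerged",
) -> pd.Series:
    """Label ASVs absent at baseline but present in the comparison group.

    An ASV is ``label`` (default "emerged") when it has zero counts in every
    baseline replicate and at least ``min_count`` reads in at least
    ``min_prevalence`` of the group replicates; otherwise "neither".  Pass
    ``label="lost"`` when the comparison group is the premolt CK control
    (taxa present premolt but absent at/after 0 h).
    """
    if label not in ("emerged", "lost"):
        raise ValueError("label must be 'emerged' or 'lost'")
    _check_same_asvs(baseline, group)
    if baseline.counts.shape[0] == 0 or group.counts.shape[0] == 0:
        raise ValidationError("baseline and group slices must be non-empty")
    absent_baseline = np.all(baseline.counts == 0, axis=0)
    prevalence = np.mean(group.counts >= min_count, axis=0)
    hit = absent_baseline & (prevalence >= min_prevalence)
    return pd.Series(
        np.where(hit, label, "neither"), index=baseline.data.columns, name="status"
    )


def classify_differential(
    baseline: RelAbundTable,
    group: RelAbundTable,
    alpha: float = 0.05,
    min_fold: float = 2.0,
) -> pd.DataFrame:
    """Rank-sum + BH classification into enriched / depleted / unchanged.

    ASVs absent from every replicate on both sides are not tested (status
    "unchanged", p = q = NaN).  The exact null distribution is used when both
    sides have at most 8 replicates.  ``fold`` is the ratio of group to
    baseline mean relative abundance with a pseudo-fraction guard for zero
    baselines; "enriched" requires q < alpha and fold >= min_fold, "depleted"
    q < alpha and fold <= 1/min_fold.
    """
    _check_same_asvs(baseline, group)
    xb, xg = baseline.values, group.values
    nb, ng = xb.shape[0], xg.shape[0]
    if nb < 3 or ng < 3:
        raise ValidationError(
            f"need >= 3 replicates per side (got baseline {nb}, group {ng})"
        )
    asvs = list(baseline.data.columns)
    tested = (xb.sum(axis=0) + xg.sum(axis=0)) > 0
    p = np.full(len(asvs), np.nan)
    if np.any(tested):
        method = "exact" if max(nb, ng) <= 8 else "asymptotic"
        res = stats.mannwhitneyu(
            xg[:, tested], xb[:, tested], axis=0,
            alternative="two-sided", method=method,
        )
        p[tested] = np.atleast_1d(res.pvalue)
    q = np.full(len(asvs), np.nan)
    if np.any(tested):
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]
    mean_b = xb.mean(axis=0) + PSEUDO_FRACTION
    mean_g = xg.mean(axis=0) + PSEUDO_FRACTION
    fold = mean_g / mean_b
    status = np.full(len(asvs), "unchanged", dtype=object)
    sig = tested & (q < alpha)
    status[sig & (fold >= min_fold)] = "enriched"
    status[sig & (fold <= 1.0 / min_fold)] = "depleted"
    return pd.DataFrame(
        {
            "status": status,
            "fold_change": fold,
            "p_value": p,
            "q_value": q,
            "group_prevalence": np.mean(xg > 0, axis=0),
        },
        index=asvs,
    )


def turnover_summary(labeling: pd.DataFrame | pd.Series,
                     rel: RelAbundTable) -> pd.DataFrame:
    """Counts and total relative abundance per status.

    ``rel`` is the comparison-group slice; the total relative abundance of a
    status set is the sum of group-mean relative abundances of its members
    (reported as a percentage of the community).
    """
    status = labeling["status"] if isinstance(labeling, pd.DataFrame) else labeling
    if not set(status.index).issubset(set(rel.data.columns)):
        raise ValidationError("labeling refers to ASVs absent from the table")
    means = rel.data.mean(axis=0)
    rows = []
    for s in sorted(status.unique()):
        members = status.index[status == s]
        rows.append({
            "status": s,
            "n_asvs": int(len(members)),
            "total_rel_abund_pct": float(means.loc[members].sum() * 100.0),
        })
    return pd.DataFrame(rows).set_index("status")
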