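"""Group-level temporal structure of the drought and recovery responses.

DEG calls from individual genotypes are pooled to the tolerant/susceptible
group level, split into common and group-specific sets, tested for
group-different fold changes, clustered into temporal modes over the five
drought time points, compared across groups by profile correlation, and
classified into the eight recovery regulation modes defined by the
(W5 -> D5, D5 -> R) transition pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .data_model import DROUGHT_TIMEPOINTS, RECOVERY_TIMEPOINT, ValidationError
from .tolerance import welch_t

__all__ = [
    "GROUPS",
    "RECOVERY_MODES",
    "pool_group_sets",
    "group_mean_log2fc",
    "ts_different_test",
    "ts_different_table",
    "cluster_temporal",
    "cross_group_similarity",
    "assign_recovery_mode",
    "recovery_mode_table",
]

GROUPS = ("tolerant", "susceptible")

#: Fixed enumeration of the eight recovery modes as (W5->D5, D5->R) pairs;
#: the doubly-unchanged combination is not a recovery-related pattern.
RECOVERY_MODES: tuple[tuple[str, str], ...] = (
    ("up", "up"),
    ("up", "unchanged"),
    ("up", "down"),
    ("unchanged", "up"),
    ("unchanged", "down"),
    ("down", "up"),
    ("down", "unchanged"),
    ("down", "down"),
)


def pool_group_sets(calls: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Pool final calls to group x timepoint DEG sets with set labels.

    A gene belongs to a group's set at t iff it is a final DEG in at least
    one of the group's genotypes at t. Per (gene, timepoint): label
    ``common`` when both groups carry it, else ``tolerant-specific`` /
    ``susceptible-specific``; labels partition the union. ``mean_log2fc_*``
    is the mean over all of the group's genotypes' fold changes.
    """
    for group in GROUPS:
        if not (groups == group).any():
            raise ValidationError(f"empty group {group!r}")
    calls = calls.copy()
    calls["group"] = calls["genotype"].map(groups)
    deg = calls[calls["is_deg"]]
    membership = (
        deg.groupby(["gene", "timepoint"], observed=True)["group"]
        .agg(lambda s: frozenset(s))
        .rename("in_groups")
        .reset_index()
    )
    mean_fc = (
        calls.pivot_table(
            index=["gene", "timepoint"], columns="group", values="log2fc", aggfunc="mean",
            observed=True,
        )
        .rename(columns={g: f"mean_log2fc_{g}" for g in GROUPS})
        .reset_index()
    )
    out = membership.merge(mean_fc, on=["gene", "timepoint"], how="left")

    def label(in_groups: frozenset[str]) -> str:
        if in_groups == frozenset(GROUPS):
            return "common"
        return f"{next(iter(in_groups))}-specific"

    out["set_label"] = out["in_groups"].map(label)
    out["in_tolerant"] = out["in_groups"].map(lambda s: "tolerant" in s)
    out["in_susceptible"] = out["in_groups"].map(lambda s: "susceptible" in s)
    return out.drop(columns="in_groups")


def group_mean_log2fc(
    calls: pd.DataFrame, groups: pd.Series, timepoints=DROUGHT_TIMEPOINTS
) -> dict[str, pd.DataFrame]:
    """Genes x timepoints mean-log2FC matrix per group (all genes in calls)."""
    calls = calls.copy()
    calls["group"] = calls["genotype"].map(groups)
    out = {}
    for group in GROUPS:
        sub = calls[calls["group"] == group]
        mat = sub.pivot_table(
            index="gene", columns="timepoint", values="log2fc", aggfunc="mean",
            observed=True,
        )
        out[group] = mat.reindex(columns=list(timepoints))
    return out


def ts_different_test(tolerant_fc, susceptible_fc) -> dict:
    """Welch t on per-genotype log2FC between the groups at one time point."""
    tol = np.asarray(tolerant_fc, float)
    sus = np.asarray(susceptible_fc, float)
    tol = tol[~np.isnan(tol)]
    sus = sus[~np.isnan(sus)]
    if len(tol) < 2 or len(sus) < 2:
        return dict(p=np.nan, flagged=False, larger_group=None, testable=False)
    t, p = welch_t(tol, sus)
    larger = "tolerant" if abs(tol.mean()) >= abs(sus.mean()) else "susceptible"
    return dict(p=p, flagged=bool(p < 0.05), larger_group=larger, testable=True)


def ts_different_table(calls: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Group-different test for every final-DEG (gene, timepoint)."""
    calls = calls.copy()
    calls["group"] = calls["genotype"].map(groups)
    deg_keys = calls.loc[calls["is_deg"], ["gene", "timepoint"]].drop_duplicates()
    fc = calls.pivot_table(
        index=["gene", "timepoint"], columns=["group", "genotype"], values="log2fc",
        observed=True,
    )
    rows = []
    for gene, tp in deg_keys.itertuples(index=False):
        row = fc.loc[(gene, tp)]
        res = ts_different_test(
            row.get("tolerant", pd.Series(dtype=float)).to_numpy(float),
            row.get("susceptible", pd.Series(dtype=float)).to_numpy(float),
        )
        rows.append(dict(gene=gene, timepoint=tp, **res))
    return pd.DataFrame(rows)


def cluster_temporal(profiles: pd.DataFrame, k: int = 16) -> pd.Series:
    """Agglomerative temporal clustering of mean-log2FC profiles.

    Euclidean distance, average linkage, tree cut at ``k`` clusters
    (reduced with a warning when fewer profiles exist). Cluster ids are
    1..k ordered by descending size, ties broken by the smallest member
    gene id; the result is invariant to the row order of ``profiles``.
    """
    mat = profiles.dropna()
    n = len(mat)
    if n == 0:
        return pd.Series(dtype=int)
    if n < k:
        warnings.warn(f"only {n} profiles; reducing k from {k}")
        k = n
    # sort rows for order invariance of tie-broken merges
    mat = mat.sort_index()
    if k == n:
        raw = np.arange(1, n + 1)
    else:
        linkage = hierarchy.linkage(pdist(mat.to_numpy(float)), method="average")
        raw = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=mat.index)
    order = sorted(
        labels.unique(), key=lambda c: (-(labels == c).sum(), labels.index[labels == c].min())
    )
    remap = {c: i + 1 for i, c in enumerate(order)}
    return labels.map(remap).rename("cluster")


def cross_group_similarity(
    profile_t, profile_s, band: float = 0.4
) -> tuple[float, str]:
    """Pearson correlation of the two group profiles with a 3-way class.

    ``similar`` above +band, ``contrary`` below -band, else ``neither``;
    zero-variance profiles give (nan, 'neither').
    """
    a = np.asarray(profile_t, float)
    b = np.asarray(profile_s, float)
    if len(a) != len(b):
        raise ValidationError("profile length mismatch")
    if len(a) < 3:
        raise ValidationError("profiles need length >= 3")
    if np.isnan(a).any() or np.isnan(b).any() or a.std() == 0 or b.std() == 0:
        return float("nan"), "neither"
    pcc = float(np.corrcoef(a, b)[0, 1])
    if pcc > band:
        return pcc, "similar"
    if pcc < -band:
        return pcc, "contrary"
    return pcc, "neither"


def _transition(log2fc: float, threshold: float) -> str:
    if log2fc >= threshold:
        return "up"
    if log2fc <= -threshold:
        return "down"
    return "unchanged"


def assign_recovery_mode(
    log2fc_w5d5: float, log2fc_d5r: float, threshold: float = 1.0
) -> tuple[int, str, str] | None:
    """Recovery regulation mode from the (W5->D5, D5->R) transition pair.

    Each transition is up (>= threshold), down (<= -threshold) or
    unchanged. The doubly-unchanged pair is not a recovery pattern and
    returns None; the remaining 8 combinations map to mode ids 1..8 in the
    fixed :data:`RECOVERY_MODES` order.
    """
    t1 = _transition(float(log2fc_w5d5), threshold)
    t2 = _transition(float(log2fc_d5r), threshold)
    if t1 == t2 == "unchanged":
        return None
    return RECOVERY_MODES.index((t1, t2)) + 1, t1, t2


def recovery_mode_table(
    calls: pd.DataFrame, groups: pd.Series, threshold: float = 1.0
) -> pd.DataFrame:
    """Recovery modes for every recovery-related gene per group.

    The W5 -> D5 transition is the group-mean log2FC at T5 (D vs W); the
    D5 -> R transition is the difference between the group-mean recovery
    and T5 fold changes (both contrasts share the W baseline, so their
    difference tracks the D-field move from D5 to R).
    """
    mats = group_mean_log2fc(
        calls, groups, timepoints=DROUGHT_TIMEPOINTS + (RECOVERY_TIMEPOINT,)
    )
    rrg = calls.copy()
    rrg["group"] = rrg["genotype"].map(groups)
    rows = []
    for group in GROUPS:
        mat = mats[group]
        genes = sorted(
            set(rrg.loc[(rrg["group"] == group) & rrg["is_rrg"], "gene"])
        )
        for gene in genes:
            fc_d5 = mat.at[gene, DROUGHT_TIMEPOINTS[-1]]
            fc_r = mat.at[gene, RECOVERY_TIMEPOINT]
            if np.isnan(fc_d5) or np.isnan(fc_r):
                continue
            mode = assign_recovery_mode(fc_d5, fc_r - fc_d5, threshold)
            if mode is None:
                continue
            mode_id, t1, t2 = mode
            rows.append(
                dict(gene=gene, group=group, transition1=t1, transition2=t2, mode=mode_id)
            )
    return pd.DataFrame(rows, columns=["gene", "group", "transition1", "transition2", "mode"])
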