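"""Unsigned weighted coexpression network, modules, hubs and cross-talk.

Adjacency between DRGs is ``a_ij = |PCC(x_i, x_j)|^beta`` (unsigned, soft
power beta = 6 by default) over log2 expression of the drought-field
samples. Topological overlap smooths adjacency with shared neighbors:

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with connectivity ``k_i = sum_{u != i} a_iu`` and unit diagonal. The edge
cutoff tau is either fixed or chosen where the network density — computed
over the nodes retained at that tau (those with at least one
supra-threshold edge) — attains its minimum on a grid. Modules come from
average-linkage clustering of 1 - TOM with small-cluster merging; each
module is summarized by its eigengene (first principal component across
samples) and its top-15%-connectivity hub genes. Candidate tolerance genes
are hubs that correlate with a tolerance trait, annotate to a
tolerance-featured biological process, and avoid the tradeoff regions.

Phytohormone cross-talk is the mean pairwise Pearson correlation between
the temporal fold-change profiles of DRGs annotated to each pathway pair.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .data_model import HORMONES, ValidationError

__all__ = [
    "build_network",
    "select_cutoff",
    "detect_modules",
    "eigengene",
    "module_eigengenes",
    "module_trait_association",
    "intramodular_connectivity",
    "hub_genes",
    "hub_and_candidates",
    "hormone_crosstalk",
]


def build_network(expr: pd.DataFrame, beta: float = 6.0):
    """Unsigned adjacency and TOM from a genes x samples matrix.

    Constant genes are excluded with a warning (their correlation is
    undefined). Returns ``(adjacency, tom)`` as DataFrames with unit
    diagonals, symmetric, entries in [0, 1].
    """
    if expr.shape[0] < 3 or expr.shape[1] < 4:
        raise ValidationError("network needs >= 3 genes and >= 4 samples")
    sd = expr.std(axis=1)
    constant = sd[sd == 0].index
    if len(constant):
        warnings.warn(f"excluding {len(constant)} constant genes from the network")
        expr = expr.drop(index=constant)
    genes = expr.index
    corr = np.corrcoef(expr.to_numpy(float))
    adj = np.abs(corr) ** beta
    np.fill_diagonal(adj, 1.0)
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    adjacency = pd.DataFrame(adj, index=genes, columns=genes)
    tom_df = pd.DataFrame(tom, index=genes, columns=genes)
    return adjacency, tom_df


def _edge_mask(tom: np.ndarray, tau: float) -> np.ndarray:
    mask = tom >= tau
    np.fill_diagonal(mask, False)
    return mask


def select_cutoff(
    tom: pd.DataFrame,
    grid: np.ndarray | None = None,
    fixed: float | None = None,
):
    """Edge cutoff by the density-minimum rule (or a fixed override).

    For each tau on the grid, nodes with at least one edge of TOM >= tau
    are retained and density = 2E / (n_ret (n_ret - 1)) is computed over
    them; tau* is the first grid point attaining the minimal density.
    Returns ``(tau, scan)`` where ``scan`` tabulates the grid.
    """
    t = tom.to_numpy(float)
    if fixed is not None:
        mask = _edge_mask(t, fixed)
        retained = mask.any(axis=1)
        n_ret = int(retained.sum())
        edges = int(mask[np.ix_(retained, retained)].sum() // 2)
        dens = 2 * edges / (n_ret * (n_ret - 1)) if n_ret >= 2 else np.nan
        scan = pd.DataFrame(
            [dict(tau=fixed, n_retained=n_ret, n_edges=edges, density=dens)]
        )
        return float(fixed), scan
    if grid is None:
        grid = np.round(np.arange(0.01, 0.501, 0.01), 2)
    rows = []
    for tau in grid:
        mask = _edge_mask(t, tau)
        retained = mask.any(axis=1)
        n_ret = int(retained.sum())
        if n_ret < 2:
            rows.append(dict(tau=float(tau), n_retained=n_ret, n_edges=0, density=np.nan))
            continue
        edges = int(mask.sum() // 2)
        rows.append(
            dict(
                tau=float(tau),
                n_retained=n_ret,
                n_edges=edges,
                density=2 * edges / (n_ret * (n_ret - 1)),
            )
        )
    scan = pd.DataFrame(rows)
    valid = scan.dropna(subset=["density"])
    if not len(valid):
        raise ValidationError("no cutoff leaves >= 2 retained nodes; supply a fixed tau")
    tau_star = float(valid.loc[valid["density"].idxmin(), "tau"])
    return tau_star, scan


def detect_modules(tom: pd.DataFrame, tau: float, min_size: int = 30) -> pd.Series:
    """Module labels from the retained subnetwork.

    Retained genes (>= 1 edge with TOM >= tau) are clustered by average
    linkage on 1 - TOM; the tree is cut at 0.99 x the maximal merge
    height, then clusters below ``min_size`` are iteratively merged into
    their nearest cluster by mean inter-cluster TOM. Unretained genes are
    labeled ``unassigned``. Labels M1, M2, ... are ordered by descending
    module size (ties by smallest member gene id); the partition is
    invariant to gene order.
    """
    t = tom.to_numpy(float)
    mask = _edge_mask(t, tau)
    retained = tom.index[mask.any(axis=1)]
    labels = pd.Series("unassigned", index=tom.index, name="module")
    if len(retained) == 0:
        return labels
    sub = tom.loc[retained, retained].sort_index().sort_index(axis=1)
    genes = sub.index
    n = len(genes)
    if n == 1:
        return labels
    dist = 1.0 - sub.to_numpy(float)
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    cut_height = 0.99 * link[-1, 2]
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for idx, c in enumerate(raw):
        clusters.setdefault(int(c), []).append(idx)
    # merge small clusters into the nearest (highest mean inter-cluster TOM)
    tom_sub = sub.to_numpy(float)
    while len(clusters) > 1:
        small = [c for c in clusters if len(clusters[c]) < min_size]
        if not small:
            break
        c = min(small, key=lambda cc: (len(clusters[cc]), min(clusters[cc])))
        members = clusters.pop(c)
        best, best_sim = None, -np.inf
        for other, omembers in clusters.items():
            sim = tom_sub[np.ix_(members, omembers)].mean()
            if sim > best_sim:
                best, best_sim = other, sim
        clusters[best] = sorted(clusters[best] + members)
    ordered = sorted(clusters.values(), key=lambda m: (-len(m), m[0]))
    for mi, members in enumerate(ordered, start=1):
        labels[genes[members]] = f"M{mi}"
    return labels


def eigengene(sub_expr: pd.DataFrame) -> pd.Series:
    """First-principal-component sample score of a module.

    Gene profiles are standardized; the first right-singular direction is
    scaled to zero mean and unit variance over samples and sign-aligned to
    correlate positively with the mean member profile.
    """
    if sub_expr.shape[0] < 2 or sub_expr.shape[1] < 3:
        raise ValidationError("eigengene needs >= 2 genes and >= 3 samples")
    x = sub_expr.to_numpy(float)
    sd = x.std(axis=1, ddof=0)
    if (sd == 0).all():
        raise ValidationError("rank-0 module submatrix")
    x = x[sd > 0]
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=0, keepdims=True)
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    e = (e - e.mean()) / e.std(ddof=0)
    mean_profile = z.mean(axis=0)
    if np.corrcoef(e, mean_profile)[0, 1] < 0:
        e = -e
    return pd.Series(e, index=sub_expr.columns, name="eigengene")


def module_eigengenes(expr: pd.DataFrame, modules: pd.Series) -> pd.DataFrame:
    """Samples x modules eigengene matrix (skips 'unassigned')."""
    out = {}
    for module in sorted(modules.unique()):
        if module == "unassigned":
            continue
        members = modules.index[modules == module]
        members = [g for g in members if g in expr.index]
        if len(members) < 2:
            continue
        out[module] = eigengene(expr.loc[members])
    return pd.DataFrame(out)


def module_trait_association(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r and p per module x trait over matched samples.

    Pairwise-complete: samples missing a trait value are dropped for that
    trait, with the effective n recorded.
    """
    rows = []
    for module in eigengenes.columns:
        for trait in traits.columns:
            joined = pd.concat([eigengenes[module], traits[trait]], axis=1).dropna()
            n = len(joined)
            if n < 3:
                rows.append(dict(module=module, trait=trait, r=np.nan, p=np.nan, n=n))
                continue
            r, p = stats.pearsonr(joined.iloc[:, 0], joined.iloc[:, 1])
            rows.append(dict(module=module, trait=trait, r=float(r), p=float(p), n=n))
    return pd.DataFrame(rows)


def intramodular_connectivity(adjacency: pd.DataFrame, modules: pd.Series) -> pd.Series:
    """k_i = sum of adjacency to same-module members (diagonal excluded)."""
    k = pd.Series(0.0, index=modules.index, name="k_intra")
    for module in modules.unique():
        if module == "unassigned":
            continue
        members = [g for g in modules.index[modules == module] if g in adjacency.index]
        if len(members) < 2:
            continue
        block = adjacency.loc[members, members].to_numpy(float).copy()
        np.fill_diagonal(block, 0.0)
        k[members] = block.sum(axis=1)
    return k


def hub_genes(modules: pd.Series, k_intra: pd.Series, fraction: float = 0.15) -> pd.Series:
    """Top ceil(fraction x size) genes by intramodular connectivity per module.

    Ties broken by gene id; modules smaller than 2 yield no hubs.
    """
    is_hub = pd.Series(False, index=modules.index, name="is_hub")
    for module in modules.unique():
        if module == "unassigned":
            continue
        members = modules.index[modules == module]
        if len(members) < 2:
            continue
        n_hubs = math.ceil(fraction * len(members))
        ranked = sorted(members, key=lambda g: (-k_intra[g], g))
        is_hub[ranked[:n_hubs]] = True
    return is_hub


def hub_and_candidates(
    modules: pd.Series,
    k_intra: pd.Series,
    correlations: pd.DataFrame,
    regions: pd.Series,
    term_types: pd.DataFrame,
    gene_to_goterms: dict[str, frozenset[str]],
    hub_fraction: float = 0.15,
) -> pd.DataFrame:
    """Hub flags plus candidate selection for tolerance breeding targets.

    A hub is a candidate iff it (a) is significantly correlated with at
    least one tolerance trait (DTIB, osmotic potential or H2O2), (b) is
    annotated to a term of temporal type II or IV (tolerance-featured
    processes), and (c) does not sit in tradeoff region III or VII (no
    expected productivity penalty).
    """
    is_hub = hub_genes(modules, k_intra, hub_fraction)
    featured_terms = set(
        term_types.loc[term_types["type"].isin(["II", "IV"]), "term"]
    ) if len(term_types) else set()
    rows = []
    for gene in modules.index:
        if not is_hub[gene]:
            continue
        sig_cols = [c for c in ("sig_dtib", "sig_osmotic", "sig_h2o2") if c in correlations.columns]
        if gene in correlations.index:
            crow = correlations.loc[gene]
            trait_ok = any(bool(crow[c]) for c in sig_cols)
        else:
            trait_ok = False
        gene_terms = gene_to_goterms.get(gene, frozenset())
        term_ok = bool(gene_terms & featured_terms)
        region = regions.get(gene)
        region_ok = region not in ("III", "VII")
        rows.append(
            dict(
                gene=gene,
                module=modules[gene],
                k_intra=float(k_intra[gene]),
                trait_correlated=trait_ok,
                tolerance_featured=term_ok,
                region=region,
                no_tradeoff=region_ok,
                candidate=trait_ok and term_ok and region_ok,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "module", "k_intra", "trait_correlated",
            "tolerance_featured", "region", "no_tradeoff", "candidate",
        ],
    )


def hormone_crosstalk(
    profiles: pd.DataFrame,
    gene_to_hormone: dict[str, str],
    drg_genes: set[str] | None = None,
) -> pd.DataFrame:
    """8 x 8 mean pairwise PCC between pathway DRG temporal profiles.

    ``profiles`` is genes x timepoints (group-mean log2FC over T1..T5 and
    R). Entry (A, B) averages PCC over all cross pairs of distinct genes;
    the diagonal averages within-pathway distinct pairs. Pathways with
    fewer than two usable DRGs yield NaN entries.
    """
    members: dict[str, list[str]] = {h: [] for h in HORMONES}
    for gene, hormone in gene_to_hormone.items():
        if drg_genes is not None and gene not in drg_genes:
            continue
        if gene in profiles.index and hormone in members:
            members[hormone].append(gene)
    usable = {
        h: [g for g in gs if profiles.loc[g].std() > 0]
        for h, gs in members.items()
    }
    out = pd.DataFrame(np.nan, index=list(HORMONES), columns=list(HORMONES))
    corr_cache = profiles.T.corr()
    for i, a in enumerate(HORMONES):
        for b in HORMONES[i:]:
            ga, gb = usable[a], usable[b]
            if len(ga) < 2 or len(gb) < 2:
                continue
            vals = [
                corr_cache.loc[x, y]
                for x in ga
                for y in gb
                if x != y
            ]
            if not vals:
                continue
            m = float(np.mean(vals))
            out.loc[a, b] = out.loc[b, a] = m
    return out
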