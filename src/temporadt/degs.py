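"""Per-genotype differential-expression calling with time-course filters.

The caller contrasts drought (D) against well-watered (W) FPKM at each time
point within each genotype, on log2(FPKM + c):

* replicated libraries: two-sided Welch t-test per gene, Benjamini-Hochberg
  FDR across expressed genes, DEG iff FDR < 0.05 and |log2FC| >= 1;
* single (pooled) libraries: a z-test whose gene-wise null spread is
  estimated from that genotype's adjacent well-watered time-point
  log-ratios, DEG iff p < 0.05 and |log2FC| >= 1.

Two bespoke exclusions then clean the per-genotype sets:

* development-dependent genes — significant between any two *adjacent*
  well-watered time points (drought delays development, so stage effects
  masquerade as drought responses) — are removed per genotype;
* low-frequency calls — a (gene, timepoint) DEG seen in fewer than two
  genotypes — are removed panel-wide.

Surviving DEGs at T1..T5 are drought-responsive genes (DRGs); DEGs at the
recovery point R are recovery-related genes (RRGs). The labels are not
mutually exclusive.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import (
    DROUGHT_TIMEPOINTS,
    RECOVERY_TIMEPOINT,
    TIMEPOINTS,
    ExperimentSet,
    ValidationError,
)

__all__ = [
    "compute_log2fc",
    "call_degs",
    "call_all_degs",
    "flag_development_dependent",
    "frequency_filter",
    "label_drg_rrg",
    "final_deg_calls",
    "summarize_genotypes",
    "drg_sets",
]

PSEUDOCOUNT = 0.01  # one decade below the expressed floor


def compute_log2fc(mean_w, mean_d, pseudocount: float = PSEUDOCOUNT):
    """log2 fold change D vs W on pseudocounted means.

    ``log2((mean_D + c) / (mean_W + c))``; both-zero means give exactly 0.
    """
    mean_w = np.asarray(mean_w, float)
    mean_d = np.asarray(mean_d, float)
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    if (mean_w < 0).any() or (mean_d < 0).any():
        raise ValidationError("abundances must be non-negative")
    out = np.log2((mean_d + pseudocount) / (mean_w + pseudocount))
    return out if out.ndim else float(out)


def _contrast(
    expr: pd.DataFrame,
    cols_w: list[str],
    cols_d: list[str],
    expressed: pd.Series,
    pseudocount: float,
    fdr_level: float,
    p_level: float,
    fc_threshold: float,
    single_sd: pd.Series | None,
) -> pd.DataFrame:
    """Shared machinery for any W-like vs D-like column contrast."""
    logw = np.log2(expr[cols_w].to_numpy(float) + pseudocount)
    logd = np.log2(expr[cols_d].to_numpy(float) + pseudocount)
    log2fc = logd.mean(axis=1) - logw.mean(axis=1)
    ex = expressed.to_numpy(bool)
    p = np.full(len(expr), np.nan)
    fdr = np.full(len(expr), np.nan)
    if len(cols_w) >= 2 and len(cols_d) >= 2:
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p_all = stats.ttest_ind(logd, logw, axis=1, equal_var=False)
        # identical constant replicates produce NaN; no evidence -> p = 1
        p_all = np.where(np.isnan(p_all), 1.0, p_all)
        p[ex] = p_all[ex]
        if ex.any():
            fdr[ex] = multipletests(p[ex], method="fdr_bh")[1]
        is_deg = ex & (fdr < fdr_level) & (np.abs(log2fc) >= fc_threshold)
    else:
        if single_sd is None:
            raise ValidationError("single-library contrast needs a noise-sd estimate")
        sd = single_sd.to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = log2fc / sd
        p_all = 2 * stats.norm.sf(np.abs(z))
        p[ex] = p_all[ex]
        is_deg = ex & (p < p_level) & (np.abs(log2fc) >= fc_threshold)
    return pd.DataFrame(
        {
            "gene": expr.index,
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "direction": np.where(log2fc >= 0, "up", "down"),
            "is_deg": is_deg,
        }
    )


def single_library_sd(
    es: ExperimentSet, genotype: str, pseudocount: float = PSEUDOCOUNT
) -> pd.Series:
    """Gene-wise null spread for pooled libraries.

    Uses the standard deviation of the genotype's adjacent well-watered
    time-point log-ratios — biological-stage drift plus technical noise —
    as the null scale for a D-vs-W log-ratio. Degenerate (zero/NaN) gene
    estimates fall back to the genotype-wide median sd.
    """
    ratios = []
    for t0, t1 in zip(DROUGHT_TIMEPOINTS[:-1], DROUGHT_TIMEPOINTS[1:]):
        c0 = es.sample_ids(genotype, "W", t0)
        c1 = es.sample_ids(genotype, "W", t1)
        if not c0 or not c1:
            continue
        m0 = es.expression[c0].mean(axis=1)
        m1 = es.expression[c1].mean(axis=1)
        ratios.append(np.log2((m1 + pseudocount) / (m0 + pseudocount)))
    if not ratios:
        raise ValidationError(f"no adjacent W time points for genotype {genotype!r}")
    mat = np.column_stack(ratios)
    sd = mat.std(axis=1, ddof=1) if mat.shape[1] >= 2 else np.abs(mat[:, 0])
    sd = pd.Series(sd, index=es.expression.index)
    fallback = float(np.nanmedian(sd[sd > 0])) if (sd > 0).any() else 1.0
    return sd.where(sd > 0, fallback)


def call_degs(
    es: ExperimentSet,
    genotype: str,
    timepoint: str,
    fdr_level: float = 0.05,
    p_level: float = 0.05,
    fc_threshold: float = 1.0,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Differential calls for one genotype at one time point (D vs W).

    At the recovery point the drought-field R samples are contrasted against
    the well-watered R samples when those exist, else against the T5
    well-watered baseline. Falls back to single-library mode (with a
    warning) when either side has fewer than two replicates.
    """
    cols_d = es.sample_ids(genotype, "D", timepoint)
    if timepoint == RECOVERY_TIMEPOINT:
        cols_w = es.sample_ids(genotype, "W", RECOVERY_TIMEPOINT) or es.sample_ids(
            genotype, "W", DROUGHT_TIMEPOINTS[-1]
        )
    else:
        cols_w = es.sample_ids(genotype, "W", timepoint)
    if not cols_w or not cols_d:
        raise ValidationError(f"missing W or D samples for {genotype}/{timepoint}")
    single_sd = None
    if min(len(cols_w), len(cols_d)) < 2:
        if max(len(cols_w), len(cols_d)) >= 2:
            warnings.warn(
                f"{genotype}/{timepoint}: one side has a single library; "
                "falling back to single-library mode"
            )
        single_sd = single_library_sd(es, genotype, pseudocount)
    out = _contrast(
        es.expression, cols_w, cols_d, es.expressed, pseudocount,
        fdr_level, p_level, fc_threshold, single_sd,
    )
    out.insert(1, "genotype", genotype)
    out.insert(2, "timepoint", timepoint)
    return out


def flag_development_dependent(
    es: ExperimentSet,
    genotype: str,
    fdr_level: float = 0.05,
    p_level: float = 0.05,
    fc_threshold: float = 1.0,
    pseudocount: float = PSEUDOCOUNT,
) -> frozenset[str]:
    """Genes meeting the DEG criteria between any adjacent W time points.

    Applies the same test and thresholds as :func:`call_degs` to each
    adjacent well-watered pair (W1-W2 ... W4-W5); a hit in any pair flags
    the gene for exclusion from this genotype's final DEG set.
    """
    flagged: set[str] = set()
    pairs = list(zip(DROUGHT_TIMEPOINTS[:-1], DROUGHT_TIMEPOINTS[1:]))
    tested_any = False
    for t0, t1 in pairs:
        c0 = es.sample_ids(genotype, "W", t0)
        c1 = es.sample_ids(genotype, "W", t1)
        if not c0 or not c1:
            continue
        tested_any = True
        single_sd = None
        if min(len(c0), len(c1)) < 2:
            single_sd = single_library_sd(es, genotype, pseudocount)
        res = _contrast(
            es.expression, c0, c1, es.expressed, pseudocount,
            fdr_level, p_level, fc_threshold, single_sd,
        )
        flagged.update(res.loc[res["is_deg"], "gene"])
    if not tested_any:
        warnings.warn(f"{genotype}: fewer than two W time points; no development flags")
    return frozenset(flagged)


def call_all_degs(es: ExperimentSet, **kwargs) -> pd.DataFrame:
    """Raw calls for every genotype x time point plus development flags."""
    frames = []
    for genotype in es.genotypes:
        dev = flag_development_dependent(es, genotype, **kwargs)
        for timepoint in TIMEPOINTS:
            if not es.sample_ids(genotype, "D", timepoint):
                continue
            calls = call_degs(es, genotype, timepoint, **kwargs)
            calls["dev_dependent"] = calls["gene"].isin(dev)
            frames.append(calls)
    return pd.concat(frames, ignore_index=True)


def frequency_filter(calls: pd.DataFrame, min_freq: int = 2) -> pd.DataFrame:
    """Drop (gene, timepoint) DEGs seen in fewer than ``min_freq`` genotypes.

    Frequency is counted over post-development-filter calls; ``freq`` is
    recorded on every row. Idempotent: filtering twice changes nothing.
    """
    if min_freq < 1:
        raise ValidationError("min_freq must be >= 1")
    calls = calls.copy()
    dev = (
        calls["dev_dependent"].astype(bool)
        if "dev_dependent" in calls
        else pd.Series(False, index=calls.index)
    )
    eligible = calls["is_deg"] & ~dev
    freq = (
        calls[eligible]
        .groupby(["gene", "timepoint"], observed=True)["genotype"]
        .nunique()
    )
    key = pd.MultiIndex.from_frame(calls[["gene", "timepoint"]])
    calls["freq"] = freq.reindex(key).fillna(0).astype(int).to_numpy()
    calls["is_deg"] = eligible & (calls["freq"] >= min_freq)
    return calls


def final_deg_calls(
    calls: pd.DataFrame, min_freq: int = 2, dev_exclusion: str = "panel"
) -> pd.DataFrame:
    """Development exclusion + frequency filter + DRG/RRG labels.

    ``dev_exclusion``: ``panel`` (default) treats a gene flagged
    development-dependent in any genotype as developmentally regulated and
    excludes it everywhere — stage effects replicated across the panel are
    a property of the gene, not of one genotype; ``genotype`` restricts the
    exclusion to the flagging genotype's calls.
    """
    if dev_exclusion not in ("panel", "genotype"):
        raise ValidationError(f"unknown dev_exclusion mode {dev_exclusion!r}")
    calls = calls.copy()
    if dev_exclusion == "panel" and "dev_dependent" in calls:
        flagged_genes = set(calls.loc[calls["dev_dependent"].astype(bool), "gene"])
        calls["dev_dependent"] = calls["gene"].isin(flagged_genes)
    return label_drg_rrg(frequency_filter(calls, min_freq=min_freq))


def label_drg_rrg(calls: pd.DataFrame) -> pd.DataFrame:
    """Tag each call row as drought- and/or recovery-responsive.

    ``is_drg``: final DEG at any of T1..T5 for that genotype;
    ``is_rrg``: final DEG at R. A gene may carry both labels.
    """
    unknown = set(calls["timepoint"]) - set(TIMEPOINTS)
    if unknown:
        raise ValidationError(f"unknown timepoint tags: {sorted(unknown)}")
    calls = calls.copy()
    calls["is_drg"] = calls["is_deg"] & calls["timepoint"].isin(DROUGHT_TIMEPOINTS)
    calls["is_rrg"] = calls["is_deg"] & (calls["timepoint"] == RECOVERY_TIMEPOINT)
    return calls


def drg_sets(calls: pd.DataFrame) -> dict[str, frozenset[str]]:
    """Per-genotype DRG sets from labeled final calls."""
    out = {}
    for genotype, sub in calls.groupby("genotype"):
        out[genotype] = frozenset(sub.loc[sub["is_drg"], "gene"])
    return out


def summarize_genotypes(calls: pd.DataFrame):
    """Per-genotype DRG summaries plus panel-level structure.

    Returns ``(summary, shared, presence, linkage)``:

    * ``summary`` — genotype, n_drg, pct_up (gene direction = sign of its
      mean log2FC over the time points where it is a DEG; NaN when n_drg=0);
    * ``shared`` — symmetric Jaccard matrix of DRG-set overlap;
    * ``presence`` — genes x genotypes 0/1 DRG matrix;
    * ``linkage`` — scipy linkage (Euclidean, average) of genotypes on the
      0/1 vectors, or None with < 2 genotypes.
    """
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import pdist

    sets = drg_sets(calls)
    genotypes = sorted(sets)
    rows = []
    drg_calls = calls[calls["is_drg"]]
    mean_fc = drg_calls.groupby(["genotype", "gene"], observed=True)["log2fc"].mean()
    for g in genotypes:
        n = len(sets[g])
        if n:
            signs = mean_fc.loc[g]
            pct_up = 100.0 * float((signs > 0).mean())
        else:
            pct_up = np.nan
        rows.append(dict(genotype=g, n_drg=n, pct_up=pct_up))
    summary = pd.DataFrame(rows)

    shared = pd.DataFrame(1.0, index=genotypes, columns=genotypes)
    for i, a in enumerate(genotypes):
        for b in genotypes[i + 1:]:
            union = sets[a] | sets[b]
            j = len(sets[a] & sets[b]) / len(union) if union else 1.0
            shared.loc[a, b] = shared.loc[b, a] = j

    all_genes = sorted(set().union(*sets.values())) if sets else []
    presence = pd.DataFrame(
        [[int(g in sets[geno]) for geno in genotypes] for g in all_genes],
        index=all_genes,
        columns=genotypes,
    )
    linkage = None
    if len(genotypes) >= 2 and len(all_genes) >= 1:
        linkage = hierarchy.linkage(
            pdist(presence.T.to_numpy(float), metric="euclidean"), method="average"
        )
    return summary, shared, presence, linkage
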