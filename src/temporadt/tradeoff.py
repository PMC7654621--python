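"""Gene-trait correlations and the nine-region tolerance/productivity map.

Each drought-responsive gene is correlated across the genotype panel with

* tolerance: Pearson r between its per-genotype mean drought log2FC
  (mean over T1..T5) and DTIB;
* productivity: Pearson r between its per-genotype mean well-watered
  expression (mean FPKM over W1..W5) and biomass under W;

both significant when |r| exceeds the exact correlation threshold at the
panel size (0.576 for 12 genotypes, alpha 0.05, strict inequality). Jointly
the two calls place a gene into one of nine regions: I/III/V/VII are the
both-significant quadrants (III and VII are the tradeoff regions, where
tolerance and growth pull in opposite directions), II/VI tolerance-only,
IV/VIII productivity-only, IX neither.

Physiology couplings (osmotic potential, H2O2) are correlated per gene over
all drought-field samples; significance there is |r| > 0.4 and p < 0.001.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DROUGHT_TIMEPOINTS, ExperimentSet, ValidationError
from .tolerance import critical_pcc

__all__ = [
    "REGIONS",
    "pearson_rows",
    "correlate_gene_traits",
    "classify_region",
    "classify_regions",
    "trait_correlated_sets",
]

REGIONS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX")


def pearson_rows(matrix: pd.DataFrame, vector: pd.Series) -> pd.DataFrame:
    """Pearson r and two-sided p of every matrix row against a vector.

    Pairwise-complete over the shared columns; rows (or the vector) with
    zero variance give r = NaN.
    """
    cols = [c for c in matrix.columns if c in vector.index and not np.isnan(vector[c])]
    x = matrix[cols].to_numpy(float)
    y = vector[cols].to_numpy(float)
    n = len(cols)
    xm = x - x.mean(axis=1, keepdims=True)
    ym = y - y.mean()
    sx = np.sqrt((xm**2).sum(axis=1))
    sy = np.sqrt((ym**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xm @ ym) / (sx * sy)
    r[(sx == 0)] = np.nan
    if sy == 0:
        r[:] = np.nan
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return pd.DataFrame({"r": r, "p": p, "n": n}, index=matrix.index)


def _mean_drought_fc(calls: pd.DataFrame) -> pd.DataFrame:
    """Genes x genotypes mean log2FC over the drought time points."""
    drought = calls[calls["timepoint"].isin(DROUGHT_TIMEPOINTS)]
    return drought.pivot_table(
        index="gene", columns="genotype", values="log2fc", aggfunc="mean", observed=True
    )


def _mean_w_expression(es: ExperimentSet, genes) -> pd.DataFrame:
    """Genes x genotypes mean FPKM over the well-watered drought-period samples."""
    cols = {}
    for genotype in es.genotypes:
        ids = [
            s
            for tp in DROUGHT_TIMEPOINTS
            for s in es.sample_ids(genotype, "W", tp)
        ]
        cols[genotype] = es.expression.loc[genes, ids].mean(axis=1)
    return pd.DataFrame(cols)


def correlate_gene_traits(
    calls: pd.DataFrame,
    es: ExperimentSet,
    profiles: pd.DataFrame,
    genes: list[str] | None = None,
    alpha: float = 0.05,
    physiology_r: float = 0.4,
    physiology_p: float = 1e-3,
) -> pd.DataFrame:
    """Per-gene correlations with tolerance, productivity and physiology.

    ``profiles`` is the DTIB table from :func:`temporadt.tolerance.tolerance_profiles`;
    the biomass-W vector comes from ``es.traits``. Physiology traits in
    ``es.trait_measurements`` (osmotic_potential, h2o2) are correlated over
    all drought-field samples, matching trait replicate to expression
    replicate. Genes with undefined correlations keep NaN and are excluded
    from region classification downstream.
    """
    fc = _mean_drought_fc(calls)
    if genes is not None:
        fc = fc.reindex([g for g in genes if g in fc.index])
    if fc.shape[1] < 4:
        raise ValidationError("need >= 4 genotypes for gene-trait correlations")
    dtib = profiles.set_index("genotype")["dti"]
    res_dtib = pearson_rows(fc, dtib)
    r_crit = critical_pcc(int(res_dtib["n"].iloc[0]), alpha) if len(res_dtib) else np.nan

    expr_w = _mean_w_expression(es, fc.index)
    biomass = es.traits.set_index("genotype")["biomass_W"]
    res_bio = pearson_rows(expr_w, biomass)
    r_crit_bio = critical_pcc(int(res_bio["n"].iloc[0]), alpha) if len(res_bio) else np.nan

    out = pd.DataFrame(index=fc.index)
    out["r_dtib"] = res_dtib["r"]
    out["p_dtib"] = res_dtib["p"]
    out["n_dtib"] = res_dtib["n"]
    out["sig_dtib"] = res_dtib["r"].abs() > r_crit
    out["r_biomass"] = res_bio["r"]
    out["p_biomass"] = res_bio["p"]
    out["n_biomass"] = res_bio["n"]
    out["sig_biomass"] = res_bio["r"].abs() > r_crit_bio

    # physiology: per drought-field sample, replicate-matched trait values
    if es.trait_measurements is not None:
        meas = es.trait_measurements
        d_samples = es.samples[es.samples["condition"] == "D"]
        key = list(
            zip(d_samples["genotype"], d_samples["timepoint"], d_samples["replicate"])
        )
        for trait, col in (("osmotic_potential", "osmotic"), ("h2o2", "h2o2")):
            tm = meas[(meas["trait"] == trait) & (meas["condition"] == "D")]
            lookup = {
                (g, t, r): v
                for g, t, r, v in zip(
                    tm["genotype"], tm["timepoint"], tm["replicate"], tm["value"]
                )
            }
            vec = pd.Series(
                [lookup.get(k, np.nan) for k in key], index=d_samples.index, dtype=float
            )
            if vec.notna().sum() < 4:
                continue
            mat = es.expression.loc[fc.index, d_samples.index]
            res = pearson_rows(mat, vec)
            out[f"r_{col}"] = res["r"]
            out[f"p_{col}"] = res["p"]
            out[f"sig_{col}"] = (res["r"].abs() > physiology_r) & (
                res["p"] < physiology_p
            )
    out.index.name = "gene"
    return out


def classify_region(
    r_biomass: float, sig_biomass: bool, r_dtib: float, sig_dtib: bool
) -> str | None:
    """Nine-region call from the two correlation results.

    Returns None for undefined correlations. IX when neither significant;
    II/VI tolerance-only (sign of r_dtib); VIII/IV productivity-only (sign
    of r_biomass); both significant -> quadrant I (+,+), III (-biomass,
    +dtib), V (-,-), VII (+biomass, -dtib).
    """
    if np.isnan(r_biomass) or np.isnan(r_dtib):
        return None
    if not sig_biomass and not sig_dtib:
        return "IX"
    if sig_dtib and not sig_biomass:
        return "II" if r_dtib > 0 else "VI"
    if sig_biomass and not sig_dtib:
        return "VIII" if r_biomass > 0 else "IV"
    if r_biomass > 0:
        return "I" if r_dtib > 0 else "VII"
    return "III" if r_dtib > 0 else "V"


def classify_regions(correlations: pd.DataFrame) -> pd.Series:
    """Region per gene; genes with undefined correlations are dropped."""
    regions = {}
    for gene, row in correlations.iterrows():
        region = classify_region(
            row["r_biomass"], bool(row["sig_biomass"]), row["r_dtib"], bool(row["sig_dtib"])
        )
        if region is not None:
            regions[gene] = region
    out = pd.Series(regions, name="region")
    out.index.name = "gene"
    return out


def trait_correlated_sets(correlations: pd.DataFrame) -> dict[str, frozenset[str]]:
    """Significant gene sets per trait x sign, plus pairwise overlaps.

    Keys look like ``dtib+``, ``biomass-``, ``osmotic+`` ...; additionally
    ``overlap:<a>&<b>`` entries hold intersections of same-trait-pair sets.
    """
    sets: dict[str, frozenset[str]] = {}
    for trait in ("dtib", "biomass", "osmotic", "h2o2"):
        rcol, scol = f"r_{trait}", f"sig_{trait}"
        if rcol not in correlations.columns:
            continue
        sig = correlations[correlations[scol].fillna(False).astype(bool)]
        sets[f"{trait}+"] = frozenset(sig.index[sig[rcol] > 0])
        sets[f"{trait}-"] = frozenset(sig.index[sig[rcol] < 0])
    names = sorted(k for k in sets if ":" not in k)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            inter = sets[a] & sets[b]
            if inter:
                sets[f"overlap:{a}&{b}"] = inter
    return sets
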