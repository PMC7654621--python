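"""Drought-tolerance indices, genotype grouping and trait-level statistics.

The drought-tolerance index weighs a genotype's own stability under stress by
its performance relative to the panel:

    DTI = (P_d / P_W) * (P_d / P_ad)

where ``P_W`` and ``P_d`` are the trait values (biomass -> DTIB, yield ->
DTIY) under the well-watered and drought fields and ``P_ad`` is the panel
mean of the drought-field values. Genotypes are split into contrasting
tolerant / susceptible groups by the median of DTIB.

Trait-level statistics mirror the field-trial conventions: Welch independent
t-tests between groups at each time point, and one-way ANOVA with
Student-Newman-Keuls (SNK) stepwise letters across the drought time course.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ValidationError

__all__ = [
    "compute_dti",
    "tolerance_profiles",
    "assign_groups",
    "critical_pcc",
    "welch_t",
    "snk_letters",
    "compare_trait_groups",
]


def compute_dti(p_w: float, p_d: float, p_ad: float) -> float:
    """Drought-tolerance index ``(P_d/P_W) * (P_d/P_ad)``.

    All three inputs must be strictly positive trait values on a common
    scale; the index is unitless and invariant to rescaling every
    genotype's trait by a common positive constant.
    """
    if p_w <= 0 or p_d <= 0 or p_ad <= 0:
        raise ValidationError("DTI inputs must be strictly positive")
    return (p_d / p_w) * (p_d / p_ad)


def tolerance_profiles(traits: pd.DataFrame, basis: str = "biomass") -> pd.DataFrame:
    """Per-genotype DTI profile from a trait table.

    ``basis`` selects the trait pair (``biomass`` -> DTIB, ``yield`` ->
    DTIY); ``P_ad`` is the mean of the drought-field column over all
    genotypes in the table.
    """
    if basis not in ("biomass", "yield"):
        raise ValidationError(f"unknown DTI basis {basis!r}")
    col_w, col_d = f"{basis}_W", f"{basis}_D"
    p_ad = float(traits[col_d].mean())
    out = pd.DataFrame(
        {
            "genotype": traits["genotype"].to_numpy(),
            "P_W": traits[col_w].to_numpy(float),
            "P_d": traits[col_d].to_numpy(float),
            "P_ad": p_ad,
            "trait_basis": basis,
        }
    )
    out["dti"] = [compute_dti(w, d, p_ad) for w, d in zip(out["P_W"], out["P_d"])]
    return out


def assign_groups(
    profiles: pd.DataFrame,
    dti_yield: pd.Series | None = None,
    labels: dict[str, str] | None = None,
) -> pd.Series:
    """Tolerant/susceptible labels per genotype (index = genotype).

    Default rule: the top half of genotypes by DTIB is tolerant, the bottom
    half susceptible. Exact ties at the median are broken by DTIY (when
    supplied) then by genotype id. ``labels`` overrides everything.
    """
    genotypes = list(profiles["genotype"])
    if labels is not None:
        missing = set(genotypes) - set(labels)
        if missing:
            raise ValidationError(f"explicit labels missing genotypes {sorted(missing)}")
        return pd.Series({g: labels[g] for g in genotypes}, name="group")
    n = len(genotypes)
    if n < 4 or n % 2:
        raise ValidationError(
            "median split needs an even number of genotypes >= 4; supply explicit labels"
        )
    dtib = profiles.set_index("genotype")["dti"]
    dtiy = (
        dti_yield.reindex(genotypes)
        if dti_yield is not None
        else pd.Series(0.0, index=genotypes)
    )
    order = sorted(genotypes, key=lambda g: (-dtib[g], -dtiy[g], g))
    out = pd.Series("susceptible", index=pd.Index(genotypes, name="genotype"), name="group")
    out[order[: n // 2]] = "tolerant"
    return out


def critical_pcc(n: int, alpha: float = 0.05) -> float:
    """Two-sided significance threshold for a Pearson correlation at size n.

    Inverts the correlation t-test: returns r* with
    ``t = r* sqrt(n-2) / sqrt(1-r*^2)`` equal to the two-sided t critical
    value at ``alpha`` on ``n-2`` degrees of freedom. For a panel of 12
    genotypes at alpha = 0.05 this is 0.576.
    """
    if n < 3:
        raise ValidationError("critical_pcc needs n >= 3")
    df = n - 2
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    return float(t_crit / np.sqrt(df + t_crit**2))


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch t-test returning (statistic, p).

    Degenerate case: both samples constant with equal means -> p = 1 by
    convention (no evidence of difference, not an error).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


@dataclass
class SnkResult:
    means: pd.Series            # group means, original group order
    letters: pd.Series          # compact letter display per group
    f_statistic: float
    p_anova: float


def snk_letters(groups: dict[str, np.ndarray], alpha: float = 0.05) -> SnkResult:
    """One-way ANOVA with Student-Newman-Keuls stepwise letters.

    The SNK procedure sorts the group means and tests ranges with the
    studentized-range statistic at span-dependent critical values, never
    testing inside a range already declared non-significant. Unbalanced
    cells use the harmonic mean n. Groups sharing a letter are pairwise
    non-significant at ``alpha``.
    """
    names = list(groups)
    arrays = [np.asarray(groups[g], float) for g in names]
    if any(len(a) < 2 for a in arrays):
        raise ValidationError("SNK needs >= 2 observations per group")
    k = len(names)
    means = np.array([a.mean() for a in arrays])
    ns = np.array([len(a) for a in arrays])
    df_err = int(ns.sum() - k)
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_err
    f_stat, p_anova = stats.f_oneway(*arrays) if k > 1 else (0.0, 1.0)

    order = np.argsort(means)  # ascending
    sorted_means = means[order]
    n_h = k / (1.0 / ns).sum()  # harmonic mean n
    se = np.sqrt(mse / n_h)

    # nonsig[i][j] True if the range of sorted groups i..j is non-significant.
    nonsig = np.zeros((k, k), bool)
    if mse == 0:
        # zero within-group variance: equal means share letters, others differ
        for i in range(k):
            for j in range(i, k):
                nonsig[i, j] = sorted_means[j] == sorted_means[i]
    else:
        # stepwise: start from the full range; sub-ranges of a non-significant
        # range are non-significant without testing.
        stack = [(0, k - 1)]
        tested = set()
        while stack:
            i, j = stack.pop()
            if (i, j) in tested or i >= j:
                continue
            tested.add((i, j))
            span = j - i + 1
            q_obs = (sorted_means[j] - sorted_means[i]) / se
            q_crit = stats.studentized_range.ppf(1 - alpha, span, df_err)
            if q_obs > q_crit:
                stack.append((i, j - 1))
                stack.append((i + 1, j))
            else:
                for a in range(i, j + 1):
                    for b in range(a, j + 1):
                        nonsig[a, b] = True
        for i in range(k):
            nonsig[i, i] = True

    # compact letter display: one letter per maximal non-significant range
    ranges = []
    for i in range(k):
        j = i
        while j + 1 < k and nonsig[i, j + 1]:
            j += 1
        ranges.append((i, j))
    maximal = [r for r in ranges if not any(o[0] <= r[0] and r[1] <= o[1] and o != r for o in ranges)]
    seen = []
    for r in maximal:
        if r not in seen:
            seen.append(r)
    alphabet = string.ascii_lowercase
    letters_sorted = ["" for _ in range(k)]
    for li, (i, j) in enumerate(sorted(seen)):
        for pos in range(i, j + 1):
            letters_sorted[pos] += alphabet[li % 26]
    letters = ["" for _ in range(k)]
    for pos, orig in enumerate(order):
        letters[orig] = letters_sorted[pos]
    return SnkResult(
        means=pd.Series(means, index=names),
        letters=pd.Series(letters, index=names),
        f_statistic=float(f_stat),
        p_anova=float(p_anova),
    )


def compare_trait_groups(
    measurements: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Trait statistics across the tolerant/susceptible contrast.

    For every trait x timepoint (drought field): Welch t between the two
    groups' genotype-level values. For every trait x group x field series:
    one-way ANOVA across the drought time points with SNK letters.

    ``measurements`` is the long table (genotype, condition, timepoint,
    replicate, trait, value); ``groups`` maps genotype -> label. Returns a
    tidy frame with one row per test; cells with insufficient n are flagged
    (``tested = False``) and carry no p.
    """
    rows = []
    meas = measurements.copy()
    meas["group"] = meas["genotype"].map(groups)
    # between-group Welch t per trait x timepoint (drought field)
    for (trait, tp), cell in meas[meas["condition"] == "D"].groupby(["trait", "timepoint"]):
        tol = cell.loc[cell["group"] == "tolerant", "value"].to_numpy(float)
        sus = cell.loc[cell["group"] == "susceptible", "value"].to_numpy(float)
        if len(tol) >= 2 and len(sus) >= 2:
            t, p = welch_t(tol, sus)
            rows.append(
                dict(trait=trait, timepoint=tp, test="independent-t", statistic=t,
                     p=p, letters="", tested=True)
            )
        else:
            rows.append(
                dict(trait=trait, timepoint=tp, test="independent-t", statistic=np.nan,
                     p=np.nan, letters="", tested=False)
            )
    # within-series ANOVA + SNK across drought timepoints
    drought = meas[meas["timepoint"] != "R"]
    for (trait, group, cond), cell in drought.groupby(["trait", "group", "condition"]):
        series = {
            tp: sub["value"].to_numpy(float)
            for tp, sub in cell.groupby("timepoint")
        }
        series = {tp: v for tp, v in series.items() if len(v) >= 2}
        if len(series) < 2:
            continue
        res = snk_letters(series, alpha=alpha)
        for tp in series:
            rows.append(
                dict(trait=trait, timepoint=tp, test=f"ANOVA-SNK[{group},{cond}]",
                     statistic=res.f_statistic, p=res.p_anova,
                     letters=res.letters[tp], tested=True)
            )
    return pd.DataFrame(rows)
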