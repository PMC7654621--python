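"""GO-BP over-representation, temporal typing of terms, and ordinations.

Enrichment is the one-sided hypergeometric tail (study hits at least as
extreme as observed, against the expressed-gene background) with
Benjamini-Hochberg control across tested terms. A term's drought timeline —
its enrichment presence per group over D1..D5 — is classified into six
temporal types:

  I   same temporal pattern in both groups
  II  tolerant-only (DT-specific)
  III susceptible-only
  IV  initiated earlier and/or lasting longer in the tolerant group
  V   initiated earlier and/or lasting longer in the susceptible group
  VI  any other between-group difference

plus a recovery-specific flag for terms enriched only at R. Ordinations:
principal coordinates analysis (PCoA, Gower double-centering) and
correspondence analysis of classification x condition-cell count tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .data_model import DROUGHT_TIMEPOINTS, RECOVERY_TIMEPOINT, ValidationError

__all__ = [
    "TEMPORAL_TYPES",
    "enrich",
    "classify_temporal_type",
    "flag_recovery_specific",
    "build_term_timelines",
    "count_classifications",
    "pcoa",
    "correspondence_analysis",
]

TEMPORAL_TYPES = ("I", "II", "III", "IV", "V", "VI")


def enrich(
    study: set[str],
    population: set[str],
    gene_to_goterms: dict[str, frozenset[str]],
    correction: str = "fdr_bh",
) -> pd.DataFrame:
    """Hypergeometric over-representation of terms in a study set.

    p = P[X >= x] with X ~ Hypergeom(N population, K term genes, n study);
    ``correction`` is ``fdr_bh`` or ``bonferroni``, applied across tested
    terms (terms with at least one study hit are tested; terms with zero
    study count have p = 1 by the tail identity and are reported too).
    """
    if not study <= population:
        raise ValidationError("study set must be contained in the population")
    if not study:
        return pd.DataFrame(
            columns=["term", "study_count", "study_n", "pop_count", "pop_n", "p", "fdr"]
        )
    n_pop = len(population)
    n_study = len(study)
    pop_counts: dict[str, int] = {}
    study_counts: dict[str, int] = {}
    for gene in population:
        for term in gene_to_goterms.get(gene, ()):
            pop_counts[term] = pop_counts.get(term, 0) + 1
            if gene in study:
                study_counts[term] = study_counts.get(term, 0) + 1
    terms = sorted(pop_counts)
    rows = []
    for term in terms:
        big_k = pop_counts[term]
        x = study_counts.get(term, 0)
        p = float(stats.hypergeom.sf(x - 1, n_pop, big_k, n_study))
        rows.append((term, x, n_study, big_k, n_pop, p))
    out = pd.DataFrame(
        rows, columns=["term", "study_count", "study_n", "pop_count", "pop_n", "p"]
    )
    if len(out):
        method = "fdr_bh" if correction == "fdr_bh" else "bonferroni"
        out["fdr"] = multipletests(out["p"].to_numpy(), method=method)[1]
    else:
        out["fdr"] = []
    return out


def classify_temporal_type(presence_t, presence_s) -> str:
    """Six-way temporal type from the two groups' presence vectors.

    ``presence_t``/``presence_s``: booleans over D1..D5. "Initiated
    earlier" means a smaller first-enriched index; "lasted longer" means
    more enriched time points; when the two groups each win one of the
    predicates the term falls into type VI.
    """
    t = np.asarray(presence_t, bool)
    s = np.asarray(presence_s, bool)
    if not (t.any() or s.any()):
        raise ValidationError("term enriched in neither group; nothing to classify")
    if np.array_equal(t, s):
        return "I"
    if t.any() and not s.any():
        return "II"
    if s.any() and not t.any():
        return "III"
    first_t = int(np.argmax(t))
    first_s = int(np.argmax(s))
    earlier_t = first_t < first_s
    longer_t = t.sum() > s.sum()
    earlier_s = first_s < first_t
    longer_s = s.sum() > t.sum()
    if (earlier_t or longer_t) and not (earlier_s or longer_s):
        return "IV"
    if (earlier_s or longer_s) and not (earlier_t or longer_t):
        return "V"
    return "VI"


def flag_recovery_specific(presence_t, presence_s, at_r_t: bool, at_r_s: bool) -> bool:
    """True iff enriched at R in some group and never during D1..D5."""
    drought_any = bool(np.asarray(presence_t, bool).any() or np.asarray(presence_s, bool).any())
    return (bool(at_r_t) or bool(at_r_s)) and not drought_any


def build_term_timelines(
    enrichments: dict[tuple[str, str], pd.DataFrame],
    criterion: str = "fdr",
    level: float = 0.05,
) -> pd.DataFrame:
    """Assemble per-term presence vectors and assign temporal types.

    ``enrichments`` maps (group, timepoint) -> :func:`enrich` result.
    ``criterion`` selects the presence rule: ``fdr`` (corrected, used for
    typing) or ``p`` (raw, used for the focal classifications). Terms
    enriched at any drought point get a type; recovery-specific terms get
    the flag and type ``None``.
    """
    presence: dict[str, dict[tuple[str, str], bool]] = {}
    for (group, tp), res in enrichments.items():
        if not len(res):
            continue
        hits = res.loc[res[criterion] < level, "term"]
        for term in hits:
            presence.setdefault(term, {})[(group, tp)] = True
    rows = []
    for term in sorted(presence):
        cell = presence[term]
        vec_t = [bool(cell.get(("tolerant", tp))) for tp in DROUGHT_TIMEPOINTS]
        vec_s = [bool(cell.get(("susceptible", tp))) for tp in DROUGHT_TIMEPOINTS]
        at_r_t = bool(cell.get(("tolerant", RECOVERY_TIMEPOINT)))
        at_r_s = bool(cell.get(("susceptible", RECOVERY_TIMEPOINT)))
        rec = flag_recovery_specific(vec_t, vec_s, at_r_t, at_r_s)
        ttype = (
            classify_temporal_type(vec_t, vec_s) if (any(vec_t) or any(vec_s)) else None
        )
        rows.append(
            dict(
                term=term,
                **{f"T_{tp}": v for tp, v in zip(DROUGHT_TIMEPOINTS, vec_t)},
                **{f"S_{tp}": v for tp, v in zip(DROUGHT_TIMEPOINTS, vec_s)},
                at_R_tolerant=at_r_t,
                at_R_susceptible=at_r_s,
                type=ttype,
                recovery_specific=rec,
            )
        )
    return pd.DataFrame(rows)


def count_classifications(
    enriched_terms: dict[str, set[str]],
    goterm_to_classification: dict[str, frozenset[str]],
) -> pd.DataFrame:
    """Contingency table of enriched-term classifications per cell.

    ``enriched_terms`` maps a cell label (e.g. ``tolerant:T3``) to its
    enriched term set. A term carrying several classifications is counted
    once under each (the classification-counter convention); unmapped terms
    count under ``unclassified``.
    """
    cells = sorted(enriched_terms)
    classes: set[str] = set()
    counts: dict[tuple[str, str], int] = {}
    for cell in cells:
        for term in enriched_terms[cell]:
            for cls in goterm_to_classification.get(term, frozenset({"unclassified"})):
                classes.add(cls)
                counts[(cls, cell)] = counts.get((cls, cell), 0) + 1
    table = pd.DataFrame(0, index=sorted(classes), columns=cells, dtype=int)
    for (cls, cell), n in counts.items():
        table.loc[cls, cell] = n
    table.index.name = "classification"
    return table


def pcoa(
    data: pd.DataFrame, distance: str = "jaccard"
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal coordinates analysis of objects x features data.

    Computes the pairwise distance matrix (``jaccard`` on booleans or
    ``euclidean``), Gower-centers the squared distances and
    eigendecomposes. Coordinates are eigenvectors scaled by sqrt(lambda)
    for positive eigenvalues; negative eigenvalues are returned in the
    spectrum but contribute no axes.
    """
    if len(data) < 3:
        raise ValidationError("PCoA needs >= 3 objects")
    x = data.to_numpy(float)
    if distance == "jaccard":
        d = squareform(pdist(x.astype(bool), metric="jaccard"))
        d = np.nan_to_num(d)  # all-zero object pairs: distance 0
    elif distance == "euclidean":
        d = squareform(pdist(x, metric="euclidean"))
    else:
        raise ValidationError(f"unknown distance {distance!r}")
    n = len(d)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    pos = eigvals > 1e-10 * max(abs(eigvals[0]), 1.0)
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    coords_df = pd.DataFrame(
        coords, index=data.index, columns=[f"PCo{i+1}" for i in range(coords.shape[1])]
    )
    return coords_df, eigvals


def correspondence_analysis(table: pd.DataFrame, n_axes: int = 2):
    """Correspondence analysis of a non-negative contingency table.

    SVD of the standardized (Pearson) residual matrix of the independence
    model divided by sqrt(grand total); total inertia equals chi^2 / n and
    the squared singular values sum to it. Returns (row principal
    coordinates, column principal coordinates, inertia, singular values).
    All-zero rows/columns are pruned first.
    """
    if (table.to_numpy(float) < 0).any():
        raise ValidationError("contingency table must be non-negative")
    t = table.loc[(table.sum(axis=1) > 0), table.columns[table.sum(axis=0) > 0]]
    x = t.to_numpy(float)
    n = x.sum()
    if n <= 0:
        raise ValidationError("contingency table must have a positive grand total")
    p = x / n
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    expected = np.outer(r, c)
    s = (p - expected) / np.sqrt(expected)
    u, sv, vt = np.linalg.svd(s, full_matrices=False)
    inertia = float((sv**2).sum())
    keep = min(n_axes, int((sv > 1e-12).sum()))
    row_coords = (u[:, :keep] * sv[:keep]) / np.sqrt(r)[:, None]
    col_coords = (vt[:keep].T * sv[:keep]) / np.sqrt(c)[:, None]
    rows = pd.DataFrame(
        row_coords, index=t.index, columns=[f"CA{i+1}" for i in range(keep)]
    )
    cols = pd.DataFrame(
        col_coords, index=t.columns, columns=[f"CA{i+1}" for i in range(keep)]
    )
    return rows, cols, inertia, sv
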