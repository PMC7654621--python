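"""Shared domain types, readers, writers and validators.

The pipeline's single input bundle is an :class:`ExperimentSet`: an FPKM-scale
expression matrix (genes x samples), a sample sheet describing the two-field
(well-watered ``W`` / drought ``D``) time-course design, per-genotype agronomic
traits, per-sample physiological measurements, and the annotation maps
(gene->GO-BP, GO term->classification, gene->phytohormone pathway,
photosynthesis gene set).

Native on-disk dialect is tab-separated text with optional ``#`` comment
lines; genes are rows, samples are columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "DROUGHT_TIMEPOINTS",
    "RECOVERY_TIMEPOINT",
    "TIMEPOINTS",
    "HORMONES",
    "TemporadtError",
    "SchemaError",
    "ConsistencyError",
    "ValidationError",
    "ConfigError",
    "ExperimentSet",
    "read_table",
    "read_expression",
    "read_samples",
    "read_traits",
    "read_trait_measurements",
    "read_gene_map",
    "read_gene_sets",
    "read_experiment",
    "write_experiment",
    "write_results",
]

CONDITIONS = ("W", "D")
DROUGHT_TIMEPOINTS = ("T1", "T2", "T3", "T4", "T5")
RECOVERY_TIMEPOINT = "R"
TIMEPOINTS = DROUGHT_TIMEPOINTS + (RECOVERY_TIMEPOINT,)

#: The eight phytohormone pathway labels used throughout.
HORMONES = ("ABA", "auxin", "BR", "cytokinin", "ethylene", "SA", "GA", "JA")

#: FPKM floor below which a gene is flagged not-expressed (a flag, not a filter).
EXPRESSION_FLOOR = 0.001


class TemporadtError(Exception):
    """Base class for all typed errors raised by this package."""


class SchemaError(TemporadtError):
    """A required column or file is missing or malformed."""


class ConsistencyError(TemporadtError):
    """Cross-file identifiers disagree (e.g. sample in matrix but not sheet)."""


class ValidationError(TemporadtError):
    """A value violates a domain invariant (negative FPKM, duplicate id, ...)."""


class ConfigError(TemporadtError):
    """An analysis or simulation configuration is invalid."""


SAMPLE_COLUMNS = ("sample_id", "genotype", "condition", "timepoint", "replicate")
TRAIT_COLUMNS = (
    "genotype",
    "dead_leaf_ratio",
    "biomass_W",
    "biomass_D",
    "yield_W",
    "yield_D",
)
MEASUREMENT_COLUMNS = ("genotype", "condition", "timepoint", "replicate", "trait", "value")


@dataclass
class ExperimentSet:
    """Validated bundle of everything one analysis run consumes.

    Parameters
    ----------
    expression
        Genes x samples FPKM matrix (non-negative; index = gene ids).
    samples
        Sample sheet indexed by ``sample_id`` with columns ``genotype``,
        ``condition`` (W/D), ``timepoint`` (T1..T5, R) and ``replicate``.
    traits
        Per-genotype agronomic table (biomass/yield under W and D,
        dead-leaf ratio). Optional for expression-only analyses.
    trait_measurements
        Long-format physiological measurements (osmotic potential, H2O2)
        per genotype x condition x timepoint x replicate. Optional.
    gene_to_goterms
        Many-to-many gene -> GO-BP term map.
    goterm_to_classification
        GO term -> coarse classification label(s); terms absent from the map
        fall into an ``unclassified`` bucket downstream.
    gene_to_hormone
        Gene -> one of the eight phytohormone pathway labels.
    photosynthesis_genes
        Gene set annotated to the photosynthesis processes.
    """

    expression: pd.DataFrame
    samples: pd.DataFrame
    traits: pd.DataFrame | None = None
    trait_measurements: pd.DataFrame | None = None
    gene_to_goterms: dict[str, frozenset[str]] = field(default_factory=dict)
    goterm_to_classification: dict[str, frozenset[str]] = field(default_factory=dict)
    gene_to_hormone: dict[str, str] = field(default_factory=dict)
    photosynthesis_genes: frozenset[str] = frozenset()
    expression_floor: float = EXPRESSION_FLOOR

    def __post_init__(self) -> None:
        validate_expression(self.expression)
        validate_samples(self.samples)
        matrix_samples = set(self.expression.columns)
        sheet_samples = set(self.samples.index)
        missing = matrix_samples - sheet_samples
        if missing:
            raise ConsistencyError(
                f"samples present in matrix but absent from sheet: {sorted(missing)[:5]}"
            )
        if self.traits is not None:
            validate_traits(self.traits)

    @property
    def genes(self) -> pd.Index:
        return self.expression.index

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.samples["genotype"].unique())

    @property
    def expressed(self) -> pd.Series:
        """Boolean per gene: FPKM above the floor in at least one sample."""
        return (self.expression > self.expression_floor).any(axis=1)

    def sample_ids(
        self,
        genotype: str | None = None,
        condition: str | None = None,
        timepoint: str | None = None,
    ) -> list[str]:
        """Sample ids matching the given design cell, replicate-ordered."""
        sel = self.samples
        if genotype is not None:
            sel = sel[sel["genotype"] == genotype]
        if condition is not None:
            sel = sel[sel["condition"] == condition]
        if timepoint is not None:
            sel = sel[sel["timepoint"] == timepoint]
        return list(sel.sort_values("replicate").index)


# ---------------------------------------------------------------------------
# validators


def validate_expression(expr: pd.DataFrame) -> None:
    if expr.index.has_duplicates:
        dup = expr.index[expr.index.duplicated()][:5].tolist()
        raise ValidationError(f"duplicate gene ids: {dup}")
    if expr.columns.has_duplicates:
        dup = expr.columns[expr.columns.duplicated()][:5].tolist()
        raise ValidationError(f"duplicate sample ids: {dup}")
    values = expr.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError("expression matrix must be numeric")
    if np.isnan(values).any():
        raise ValidationError("expression matrix contains NaN")
    if (values < 0).any():
        gene = expr.index[np.where(values < 0)[0][0]]
        raise ValidationError(f"negative abundance for gene {gene!r}")


def validate_samples(samples: pd.DataFrame) -> None:
    for col in SAMPLE_COLUMNS[1:]:
        if col not in samples.columns:
            raise SchemaError(f"sample sheet is missing column {col!r}")
    if samples.index.has_duplicates:
        raise ValidationError("duplicate sample ids in sheet")
    bad_cond = set(samples["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValidationError(f"unknown condition labels: {sorted(bad_cond)}")
    bad_tp = set(samples["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise ValidationError(f"unknown timepoint labels: {sorted(bad_tp)}")
    if (samples["replicate"].astype(int) < 1).any():
        raise ValidationError("replicate numbers must be positive integers")
    key = samples[["genotype", "condition", "timepoint", "replicate"]]
    if key.duplicated().any():
        raise ValidationError("duplicate (genotype, condition, timepoint, replicate)")


def validate_traits(traits: pd.DataFrame) -> None:
    for col in TRAIT_COLUMNS:
        if col not in traits.columns:
            raise SchemaError(f"trait table is missing column {col!r}")
    for col in ("biomass_W", "biomass_D", "yield_W", "yield_D"):
        if (traits[col] <= 0).any():
            raise ValidationError(f"{col} must be strictly positive")
    dlr = traits["dead_leaf_ratio"]
    if ((dlr < 0) | (dlr > 1)).any():
        raise ValidationError("dead_leaf_ratio must lie in [0, 1]")
    if traits["genotype"].duplicated().any():
        raise ValidationError("duplicate genotype in trait table")


# ---------------------------------------------------------------------------
# readers


def read_table(path: str | Path, index_col: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#")
    if index_col is not None:
        if index_col not in df.columns:
            raise SchemaError(f"{path.name} is missing column {index_col!r}")
        df = df.set_index(index_col)
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    expr = read_table(path, index_col="gene_id")
    validate_expression(expr)
    return expr


def read_samples(path: str | Path) -> pd.DataFrame:
    sheet = read_table(path)
    if "sample_id" not in sheet.columns:
        raise SchemaError(f"{Path(path).name} is missing column 'sample_id'")
    sheet = sheet.set_index("sample_id")
    validate_samples(sheet)
    return sheet


def read_traits(path: str | Path) -> pd.DataFrame:
    traits = read_table(path)
    validate_traits(traits)
    return traits


def read_trait_measurements(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    for col in MEASUREMENT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{Path(path).name} is missing column {col!r}")
    return df


def read_gene_map(path: str | Path, value_col: str) -> dict[str, frozenset[str]]:
    """Read a two-column many-to-many map: gene_id <TAB> value."""
    df = read_table(path)
    for col in ("gene_id", value_col):
        if col not in df.columns:
            raise SchemaError(f"{Path(path).name} is missing column {col!r}")
    out: dict[str, set[str]] = {}
    for gene, value in zip(df["gene_id"].astype(str), df[value_col].astype(str)):
        out.setdefault(gene, set()).add(value)
    return {g: frozenset(v) for g, v in out.items()}


def read_gene_sets(path: str | Path) -> frozenset[str]:
    """One gene id per line (``#`` comments allowed)."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    genes = [
        line.strip()
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return frozenset(genes)


STANDARD_FILES = {
    "expression": "expression.tsv",
    "samples": "samples.tsv",
    "traits": "traits.tsv",
    "trait_measurements": "trait_measurements.tsv",
    "gene2go": "gene2go.tsv",
    "go2class": "go2class.tsv",
    "gene2hormone": "gene2hormone.tsv",
    "photosynthesis": "photosynthesis_genes.txt",
}


def read_experiment(directory: str | Path) -> ExperimentSet:
    """Read an :class:`ExperimentSet` from a directory of standard TSV files.

    Only ``expression.tsv`` and ``samples.tsv`` are mandatory; traits,
    measurements and annotation maps are loaded when present.
    """
    directory = Path(directory)
    expr = read_expression(directory / STANDARD_FILES["expression"])
    samples = read_samples(directory / STANDARD_FILES["samples"])

    def optional(name: str, reader, default):
        path = directory / STANDARD_FILES[name]
        return reader(path) if path.exists() else default

    go2class = optional(
        "go2class", lambda p: read_gene_map_generic(p, "go_term", "classification"), {}
    )
    gene2hormone_multi = optional("gene2hormone", lambda p: read_gene_map(p, "hormone"), {})
    gene2hormone = {g: sorted(v)[0] for g, v in gene2hormone_multi.items()}
    return ExperimentSet(
        expression=expr,
        samples=samples,
        traits=optional("traits", read_traits, None),
        trait_measurements=optional("trait_measurements", read_trait_measurements, None),
        gene_to_goterms=optional("gene2go", lambda p: read_gene_map(p, "go_term"), {}),
        goterm_to_classification=go2class,
        gene_to_hormone=gene2hormone,
        photosynthesis_genes=optional("photosynthesis", read_gene_sets, frozenset()),
    )


def read_gene_map_generic(path: str | Path, key_col: str, value_col: str) -> dict[str, frozenset[str]]:
    df = read_table(path)
    for col in (key_col, value_col):
        if col not in df.columns:
            raise SchemaError(f"{Path(path).name} is missing column {col!r}")
    out: dict[str, set[str]] = {}
    for key, value in zip(df[key_col].astype(str), df[value_col].astype(str)):
        out.setdefault(key, set()).add(value)
    return {k: frozenset(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# writers


def _map_to_frame(mapping: dict[str, frozenset[str]], key: str, value: str) -> pd.DataFrame:
    rows = [(k, v) for k in sorted(mapping) for v in sorted(mapping[k])]
    return pd.DataFrame(rows, columns=[key, value])


def write_experiment(es: ExperimentSet, out_dir: str | Path, overwrite: bool = False) -> dict:
    """Write every component of the bundle in the standard dialect."""
    tables = {
        STANDARD_FILES["expression"]: es.expression.rename_axis("gene_id").reset_index(),
        STANDARD_FILES["samples"]: es.samples.rename_axis("sample_id").reset_index(),
    }
    if es.traits is not None:
        tables[STANDARD_FILES["traits"]] = es.traits
    if es.trait_measurements is not None:
        tables[STANDARD_FILES["trait_measurements"]] = es.trait_measurements
    if es.gene_to_goterms:
        tables[STANDARD_FILES["gene2go"]] = _map_to_frame(es.gene_to_goterms, "gene_id", "go_term")
    if es.goterm_to_classification:
        tables[STANDARD_FILES["go2class"]] = _map_to_frame(
            es.goterm_to_classification, "go_term", "classification"
        )
    if es.gene_to_hormone:
        tables[STANDARD_FILES["gene2hormone"]] = pd.DataFrame(
            sorted(es.gene_to_hormone.items()), columns=["gene_id", "hormone"]
        )
    manifest = write_results(tables, out_dir, overwrite=overwrite)
    if es.photosynthesis_genes:
        path = Path(out_dir) / STANDARD_FILES["photosynthesis"]
        path.write_text("\n".join(sorted(es.photosynthesis_genes)) + "\n")
        manifest["files"][STANDARD_FILES["photosynthesis"]] = len(es.photosynthesis_genes)
    return manifest


def write_results(
    tables: dict[str, pd.DataFrame], out_dir: str | Path, overwrite: bool = False
) -> dict:
    """Write result tables as TSV with deterministic column order.

    Returns a manifest (also written as ``manifest.json``) listing every file
    with its row count. Refuses to clobber existing files unless ``overwrite``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not overwrite:
        clashes = [name for name in tables if (out_dir / name).exists()]
        if clashes:
            raise ValidationError(
                f"refusing to overwrite existing files {clashes}; pass overwrite=True"
            )
    manifest: dict = {"out_dir": str(out_dir), "files": {}}
    for name in sorted(tables):
        df = tables[name]
        df.to_csv(out_dir / name, sep="\t", index=False, lineterminator="\n")
        manifest["files"][name] = int(len(df))
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
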