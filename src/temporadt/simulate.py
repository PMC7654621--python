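"""Synthetic experiment generator with planted ground truth.

Emulates the study conditions of a two-field rice drought trial: twelve
genotypes (six tolerant, six susceptible), five drought time points plus a
recovery point, replicated FPKM expression, agronomic and physiological
traits coupled to planted gene programs, GO-term structure realizing each
temporal enrichment type, disjoint phytohormone pathway sets, and a planted
tolerance/productivity tradeoff.

Expression is log-normal with additive effects on the log2 scale, so every
planted log2 fold change is exact and recovery is directly testable:

    log2 x = baseline_gene + genotype effect + condition x time effect
             + development stage effect + module latent factor + noise

Gene classes partition the panel: ``null``, ``common`` (drought-responsive
in both groups, subdivided into the temporal-type programs I/IV/V/VI),
``tolerant_specific`` (type II program), ``susceptible_specific`` (type
III), ``rrg_only`` (responsive only at recovery) and ``dev_dependent``
(stage-driven; drought samples lag one stage behind well-watered ones, so
the D-vs-W contrast shows a spurious difference that the adjacent-W filter
must catch).

Latent genotype tolerance ``u`` drives the trait block: drought biomass and
yield retention rise with ``u``, dead-leaf ratio falls with it, osmotic
potential follows the tolerance gene program and H2O2 the acclimation
program. Tradeoff-coupled genes additionally shift their well-watered
baseline with the genotype's biomass (negatively for the tolerance program,
positively for the acclimation program), which places them in the
contradictory-correlation regions III and VII.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import (
    DROUGHT_TIMEPOINTS,
    HORMONES,
    RECOVERY_TIMEPOINT,
    TIMEPOINTS,
    ConfigError,
    ExperimentSet,
)

__all__ = ["SimulationConfig", "GroundTruth", "generate"]

# kernels: multiplier of the effect size per drought time point, plus the
# recovery-point multiplier. Chosen so the temporal-type programs realize
# distinct first-enrichment / duration patterns.
KERNELS: dict[str, tuple[tuple[float, ...], float]] = {
    "zero": ((0, 0, 0, 0, 0), 0.0),
    "early": ((1, 1, 1, 1, 1), 0.4),
    "late": ((0, 0, 1, 1, 1), 0.6),
    "transient": ((0, 1, 1, 1, 0), 0.0),
    "early_short": ((1, 1, 1, 0, 0), 0.0),
    "late_long": ((0, 1, 1, 1, 1), 0.6),
    "monotone": ((0.25, 0.5, 0.75, 1, 1), 0.5),
    "recovery_only": ((0, 0, 0, 0, 0), 1.0),
}

# per-group kernels of each planted temporal-type program
PROGRAM_KERNELS: dict[str, tuple[str, str]] = {
    "I": ("early", "early"),
    "II": ("early", "zero"),
    "III": ("zero", "transient"),
    "IV": ("early", "late"),
    "V": ("late", "early"),
    "VI": ("early_short", "late_long"),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the generator (defaults = the trial design)."""

    n_genotypes: int = 12
    n_tolerant: int = 6
    n_genes: int = 2000
    n_replicates: int = 3
    seed: int = 0

    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 1.5
    genotype_sd: float = 0.15
    replicate_sd: float = 0.15
    module_latent_sd: float = 2.0

    # planted gene-class fractions (remainder is null)
    frac_common: float = 0.10
    frac_tolerant_specific: float = 0.05
    frac_susceptible_specific: float = 0.08
    frac_rrg_only: float = 0.03
    frac_dev_dependent: float = 0.02
    frac_unexpressed: float = 0.01

    #: |log2FC| grid planted genes draw from
    effect_sizes: tuple[float, ...] = (1.25, 1.5, 2.0, 3.0)
    prob_up: float = 0.6
    #: development stage step between adjacent W time points (= 2x DEG threshold)
    dev_step: float = 2.0
    #: fraction of each specific program carrying the tradeoff coupling
    tradeoff_fraction: float = 0.5
    #: log2 W-baseline shift per sd of biomass for tradeoff genes
    tradeoff_coupling: float = 0.8

    # GO structure
    terms_per_type: int = 6
    term_size: int = 25
    term_program_genes: int = 20
    n_background_terms: int = 30
    n_recovery_terms: int = 3
    n_classifications: int = 6

    hormone_set_size: int = 12

    def validate(self) -> None:
        fracs = (
            self.frac_common
            + self.frac_tolerant_specific
            + self.frac_susceptible_specific
            + self.frac_rrg_only
            + self.frac_dev_dependent
            + self.frac_unexpressed
        )
        if fracs > 1:
            raise ConfigError("planted fractions sum to more than 1")
        for name in ("baseline_log2_sd", "replicate_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_tolerant * 2 != self.n_genotypes:
            raise ConfigError("genotypes must split evenly into two groups")
        min_pool = self.frac_tolerant_specific * self.n_genes
        if self.frac_common > 0 and min_pool and min_pool < self.term_program_genes:
            raise ConfigError(
                "n_genes too small to realize the planted term structure"
            )


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream recovery tests."""

    genes: pd.DataFrame          # class, program, effect, kernels, tradeoff, module
    genotypes: pd.DataFrame      # group, u (latent tolerance), biomass/yield
    terms: pd.DataFrame          # term, planted type ('' for background), program
    config: SimulationConfig
    #: per-genotype effect multiplier (genes x genotypes)
    multiplier: pd.DataFrame = field(repr=False, default=None)

    def true_log2fc(self, genotype: str) -> pd.DataFrame:
        """Exact planted log2FC (D vs W) per gene x timepoint for a genotype."""
        group = self.genotypes.loc[genotype, "group"]
        kcol = "kernel_tolerant" if group == "tolerant" else "kernel_susceptible"
        mat = np.zeros((len(self.genes), len(TIMEPOINTS)))
        for i, (eff, kname) in enumerate(zip(self.genes["effect"], self.genes[kcol])):
            drought, rec = KERNELS[kname]
            mat[i] = np.array(list(drought) + [rec]) * eff * self.multiplier.iloc[i][genotype]
        return pd.DataFrame(mat, index=self.genes.index, columns=list(TIMEPOINTS))

    def planted_groups(self) -> pd.Series:
        return self.genotypes["group"]


def _partition_classes(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_genes
    genes = [f"gene{i:05d}" for i in range(n)]
    counts = {
        "common": int(round(cfg.frac_common * n)),
        "tolerant_specific": int(round(cfg.frac_tolerant_specific * n)),
        "susceptible_specific": int(round(cfg.frac_susceptible_specific * n)),
        "rrg_only": int(round(cfg.frac_rrg_only * n)),
        "dev_dependent": int(round(cfg.frac_dev_dependent * n)),
        "unexpressed": int(round(cfg.frac_unexpressed * n)),
    }
    if sum(counts.values()) > n:
        raise ConfigError("n_genes too small to realize the planted fractions")
    labels = np.array(["null"] * n, dtype=object)
    perm = rng.permutation(n)
    pos = 0
    for cls, cnt in counts.items():
        labels[perm[pos : pos + cnt]] = cls
        pos += cnt
    df = pd.DataFrame(index=pd.Index(genes, name="gene"))
    df["class"] = labels

    # common genes split across the four both-group temporal programs
    df["program"] = ""
    common_idx = df.index[df["class"] == "common"]
    programs = ["I", "IV", "V", "VI"]
    for i, gene in enumerate(common_idx):
        df.loc[gene, "program"] = programs[i % 4]
    df.loc[df["class"] == "tolerant_specific", "program"] = "II"
    df.loc[df["class"] == "susceptible_specific", "program"] = "III"

    df["kernel_tolerant"] = "zero"
    df["kernel_susceptible"] = "zero"
    for prog, (kt, ks) in PROGRAM_KERNELS.items():
        sel = df["program"] == prog
        df.loc[sel, "kernel_tolerant"] = kt
        df.loc[sel, "kernel_susceptible"] = ks
    rrg = df["class"] == "rrg_only"
    df.loc[rrg, "kernel_tolerant"] = "recovery_only"
    df.loc[rrg, "kernel_susceptible"] = "recovery_only"

    planted = df["class"].isin(
        ["common", "tolerant_specific", "susceptible_specific", "rrg_only"]
    )
    sign = np.where(rng.random(n) < cfg.prob_up, 1.0, -1.0)
    magnitude = rng.choice(cfg.effect_sizes, size=n)
    df["effect"] = np.where(planted, sign * magnitude, 0.0)

    # tradeoff coupling on a subset of each specific program, forced
    # up-regulated so the correlation signs land in regions III / VII
    df["tradeoff"] = "none"
    for cls, label in (
        ("tolerant_specific", "tolerance"),
        ("susceptible_specific", "acclimation"),
    ):
        members = list(df.index[df["class"] == cls])
        k = int(round(cfg.tradeoff_fraction * len(members)))
        chosen = rng.choice(members, size=k, replace=False) if k else []
        df.loc[chosen, "tradeoff"] = label
        df.loc[chosen, "effect"] = np.abs(df.loc[chosen, "effect"])

    # planted coexpression modules: the group-specific programs, except
    # that growth-coupled (tradeoff) genes of both programs share one
    # biomass-driven module — under an unsigned similarity their common
    # baseline coupling makes them one coherent (anti-)correlated block
    df["module"] = ""
    df.loc[df["class"] == "tolerant_specific", "module"] = "tolerance_program"
    df.loc[df["class"] == "susceptible_specific", "module"] = "acclimation_program"
    df.loc[df["tradeoff"] != "none", "module"] = "growth_coupled"
    return df


def _genotype_table(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_tol = cfg.n_tolerant
    n_sus = cfg.n_genotypes - n_tol
    names = [f"G{i+1:02d}" for i in range(cfg.n_genotypes)]
    u = np.concatenate(
        [np.linspace(0.95, 0.65, n_tol), np.linspace(0.35, 0.05, n_sus)]
    )
    group = ["tolerant"] * n_tol + ["susceptible"] * n_sus
    biomass_w = 20.0 * np.exp(rng.normal(0, 0.15, cfg.n_genotypes))
    biomass_d = biomass_w * (0.25 + 0.55 * u) * np.exp(rng.normal(0, 0.05, cfg.n_genotypes))
    yield_w = 0.45 * biomass_w * np.exp(rng.normal(0, 0.10, cfg.n_genotypes))
    yield_d = yield_w * (0.08 + 0.65 * u) * np.exp(rng.normal(0, 0.10, cfg.n_genotypes))
    dead_leaf = np.clip(0.55 - 0.30 * u + rng.normal(0, 0.03, cfg.n_genotypes), 0.05, 0.95)
    return pd.DataFrame(
        {
            "group": group,
            "u": u,
            "biomass_W": biomass_w,
            "biomass_D": biomass_d,
            "yield_W": yield_w,
            "yield_D": yield_d,
            "dead_leaf_ratio": dead_leaf,
        },
        index=pd.Index(names, name="genotype"),
    )


def _build_terms(
    cfg: SimulationConfig, genes: pd.DataFrame, rng: np.random.Generator
):
    """Planted GO terms per temporal type plus background and recovery terms."""
    all_genes = list(genes.index)
    gene2go: dict[str, set[str]] = {}
    term_rows = []
    counter = 1

    def add_term(members: list[str], ttype: str, program: str):
        nonlocal counter
        term = f"GO:{counter:07d}"
        counter += 1
        for g in members:
            gene2go.setdefault(g, set()).add(term)
        term_rows.append(dict(term=term, planted_type=ttype, program=program))
        return term

    for prog in ["I", "II", "III", "IV", "V", "VI"]:
        pool = list(genes.index[genes["program"] == prog])
        if len(pool) < cfg.term_program_genes:
            continue
        for _ in range(cfg.terms_per_type):
            members = list(rng.choice(pool, size=cfg.term_program_genes, replace=False))
            n_bg = cfg.term_size - cfg.term_program_genes
            background = [x for x in all_genes if x not in set(members)]
            members += list(rng.choice(background, size=n_bg, replace=False))
            add_term(members, prog, prog)
    rec_pool = list(genes.index[genes["class"] == "rrg_only"])
    if len(rec_pool) >= cfg.term_program_genes:
        for _ in range(cfg.n_recovery_terms):
            members = list(rng.choice(rec_pool, size=cfg.term_program_genes, replace=False))
            background = [x for x in all_genes if x not in set(members)]
            members += list(
                rng.choice(background, size=cfg.term_size - cfg.term_program_genes, replace=False)
            )
            add_term(members, "recovery", "recovery")
    for _ in range(cfg.n_background_terms):
        members = list(rng.choice(all_genes, size=cfg.term_size, replace=False))
        add_term(members, "", "")

    terms = pd.DataFrame(term_rows).set_index("term")
    classifications = [f"class_{i+1}" for i in range(cfg.n_classifications)]
    go2class: dict[str, frozenset[str]] = {}
    for i, term in enumerate(terms.index):
        if terms.loc[term, "planted_type"] == "" and i % 5 == 0:
            continue  # some terms stay unclassified
        labels = {classifications[i % cfg.n_classifications]}
        if i % 10 == 0:
            labels.add(classifications[(i + 1) % cfg.n_classifications])
        go2class[term] = frozenset(labels)
    gene2go_frozen = {g: frozenset(t) for g, t in gene2go.items()}
    return gene2go_frozen, go2class, terms


def _hormone_sets(
    cfg: SimulationConfig, genes: pd.DataFrame, rng: np.random.Generator
) -> dict[str, str]:
    drg_pool = list(
        genes.index[genes["class"].isin(["common", "tolerant_specific", "susceptible_specific"])]
    )
    null_pool = list(genes.index[genes["class"] == "null"])
    rng.shuffle(drg_pool)
    rng.shuffle(null_pool)
    half = cfg.hormone_set_size // 2
    gene_to_hormone: dict[str, str] = {}
    # half responsive, half background per pathway; degrade gracefully when
    # a pool is too small (e.g. an all-null configuration)
    di = ni = 0
    for hormone in HORMONES:
        take = drg_pool[di : di + half]
        di += len(take)
        need = cfg.hormone_set_size - len(take)
        extra = null_pool[ni : ni + need]
        ni += len(extra)
        for g in take + extra:
            gene_to_hormone[g] = hormone
    return gene_to_hormone


def generate(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[ExperimentSet, GroundTruth]:
    """Generate one synthetic experiment; the seed fixes the full output."""
    cfg = config or SimulationConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genes = _partition_classes(cfg, rng)
    genotypes = _genotype_table(cfg, rng)
    gene2go, go2class, terms = _build_terms(cfg, genes, rng)
    gene_to_hormone = _hormone_sets(cfg, genes, rng)

    n = cfg.n_genes
    gnames = list(genotypes.index)
    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, n)
    baseline[genes["class"].to_numpy() == "unexpressed"] = -15.0
    genotype_eff = rng.normal(0, cfg.genotype_sd, size=(n, cfg.n_genotypes))

    # tradeoff W-baseline coupling to standardized biomass
    z_biomass = (
        genotypes["biomass_W"] - genotypes["biomass_W"].mean()
    ) / genotypes["biomass_W"].std(ddof=0)
    offset = np.zeros((n, cfg.n_genotypes))
    trade = genes["tradeoff"].to_numpy()
    offset[trade == "tolerance"] = -cfg.tradeoff_coupling * z_biomass.to_numpy()
    offset[trade == "acclimation"] = cfg.tradeoff_coupling * z_biomass.to_numpy()

    # per-genotype effect multiplier: 1 everywhere except tradeoff genes,
    # whose drought response scales with the genotype's latent tolerance
    u = genotypes["u"].to_numpy()
    mult = np.ones((n, cfg.n_genotypes))
    mult[trade == "tolerance"] = 0.5 + u
    mult[trade == "acclimation"] = 1.5 - u
    multiplier = pd.DataFrame(mult, index=genes.index, columns=gnames)

    # kernel matrices per gene over T1..T5 + R, per group
    def kernel_matrix(col: str) -> np.ndarray:
        mat = np.zeros((n, len(TIMEPOINTS)))
        for i, kname in enumerate(genes[col]):
            drought, rec = KERNELS[kname]
            mat[i] = list(drought) + [rec]
        return mat

    kmat = {
        "tolerant": kernel_matrix("kernel_tolerant"),
        "susceptible": kernel_matrix("kernel_susceptible"),
    }
    effect = genes["effect"].to_numpy()

    # development stage profile: alternating steps of dev_step between
    # adjacent W time points; drought samples lag one stage behind
    stage = np.array([0.0, cfg.dev_step, 0.0, cfg.dev_step, 0.0])
    is_dev = (genes["class"] == "dev_dependent").to_numpy()

    # module latent factors: one value per (module, genotype), applied to
    # every sample of the genotype so they cancel exactly in the D-vs-W and
    # adjacent-W contrasts while still correlating module members across
    # the sample axis
    module_names = [m for m in genes["module"].unique() if m]
    # orthogonalize the module activity vectors against the constant, the
    # group contrast, the biomass axis and each other: with only twelve
    # genotypes, raw independent draws carry sizable chance correlations
    # that would blur the planted module boundaries
    group_ind = (genotypes["group"] == "tolerant").to_numpy(float)
    basis = [np.ones(cfg.n_genotypes), group_ind, z_biomass.to_numpy()]
    latent: dict[str, np.ndarray] = {}
    for m in sorted(module_names):
        v = rng.normal(0, 1.0, cfg.n_genotypes)
        for b in basis:
            bn = b - b.mean() if b.std() > 0 else b
            denom = (bn * bn).sum()
            if denom > 0:
                v = v - (v @ bn) / denom * bn
        sd_v = v.std()
        v = v / sd_v * cfg.module_latent_sd if sd_v > 0 else v
        latent[m] = v
        basis.append(v)
    module_of = genes["module"].to_numpy()
    # each member tracks the program's activity with its own response sign
    # (repressed members fall when the program is active); growth-coupled
    # genes cohere through the biomass baseline shift instead
    latent_load = np.where(genes["effect"].to_numpy() < 0, -1.0, 1.0)
    latent_load[genes["module"].to_numpy() == "growth_coupled"] = 0.0
    module_names = [m for m in module_names if m != "growth_coupled"]

    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    for gi, genotype in enumerate(gnames):
        group = genotypes.loc[genotype, "group"]
        for ti, tp in enumerate(TIMEPOINTS):
            for condition in ("W", "D"):
                base = baseline + genotype_eff[:, gi] + offset[:, gi]
                for m in module_names:
                    base = base + np.where(module_of == m, latent_load * latent[m][gi], 0.0)
                if condition == "D":
                    base = base + effect * kmat[group][:, ti] * mult[:, gi]
                # development stage: W tracks the stage profile, D lags one
                if tp != RECOVERY_TIMEPOINT:
                    stage_idx = ti if condition == "W" else max(ti - 1, 0)
                    base = base + np.where(is_dev, stage[stage_idx], 0.0)
                else:
                    base = base + np.where(is_dev, stage[-1], 0.0)
                for rep in range(1, cfg.n_replicates + 1):
                    sample = f"{genotype}_{condition}_{tp}_r{rep}"
                    noise = rng.normal(0, cfg.replicate_sd, n)
                    columns[sample] = 2.0 ** (base + noise)
                    sheet_rows.append(
                        dict(
                            sample_id=sample,
                            genotype=genotype,
                            condition=condition,
                            timepoint=tp,
                            replicate=rep,
                        )
                    )
    expression = pd.DataFrame(columns, index=genes.index)
    samples = pd.DataFrame(sheet_rows).set_index("sample_id")

    traits = genotypes.reset_index()[
        ["genotype", "dead_leaf_ratio", "biomass_W", "biomass_D", "yield_W", "yield_D"]
    ]

    # physiology coupled to the planted programs: osmotic potential follows
    # the tolerance program, H2O2 the acclimation program
    meas_rows = []
    log_expr = np.log2(expression.to_numpy() + 0.01)
    prog_idx = {
        "osmotic_potential": np.where(genes["class"].to_numpy() == "tolerant_specific")[0],
        "h2o2": np.where(genes["class"].to_numpy() == "susceptible_specific")[0],
    }
    prog_base = {
        t: log_expr[idx].mean() if len(idx) else 0.0 for t, idx in prog_idx.items()
    }
    scale = {"osmotic_potential": (500.0, 60.0, 12.0), "h2o2": (0.30, 0.06, 0.02)}
    col_pos = {s: i for i, s in enumerate(expression.columns)}
    for sample_id, row in samples.iterrows():
        for trait_name in ("osmotic_potential", "h2o2"):
            base_v, coef, noise_sd = scale[trait_name]
            idx = prog_idx[trait_name]
            if row["condition"] == "D" and len(idx):
                signal = log_expr[idx, col_pos[sample_id]].mean() - prog_base[trait_name]
            else:
                signal = 0.0
            meas_rows.append(
                dict(
                    genotype=row["genotype"],
                    condition=row["condition"],
                    timepoint=row["timepoint"],
                    replicate=row["replicate"],
                    trait=trait_name,
                    value=base_v + coef * signal + rng.normal(0, noise_sd),
                )
            )
    trait_measurements = pd.DataFrame(meas_rows)

    es = ExperimentSet(
        expression=expression,
        samples=samples,
        traits=traits,
        trait_measurements=trait_measurements,
        gene_to_goterms=gene2go,
        goterm_to_classification=go2class,
        gene_to_hormone=gene_to_hormone,
        # photosynthesis regulation is an acclimation response: draw the
        # planted photosynthesis set from the acclimation program
        photosynthesis_genes=frozenset(
            genes.index[genes["program"] == "III"][:40]
        ),
    )
    truth = GroundTruth(
        genes=genes,
        genotypes=genotypes,
        terms=terms,
        config=cfg,
        multiplier=multiplier,
    )
    return es, truth


def two_block_network(
    n_per_block: int = 60,
    n_samples: int = 80,
    noise_sd: float = 0.35,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Expression with two planted coexpression blocks (module fixture).

    Each block follows its own latent sample factor with gene loadings of
    random sign plus independent noise; the two factors are orthogonalized
    so the blocks are uncorrelated by construction. Returns (genes x
    samples expression on the log2 scale, true block labels).
    """
    rng = np.random.default_rng(seed)
    f1 = rng.normal(0, 1, n_samples)
    f2 = rng.normal(0, 1, n_samples)
    f2 = f2 - (f2 @ f1) / (f1 @ f1) * f1
    f2 = f2 / f2.std() if f2.std() > 0 else f2
    f1 = f1 / f1.std()
    rows, labels = [], []
    for b, f in (("B1", f1), ("B2", f2)):
        for _ in range(n_per_block):
            load = rng.choice([-1.0, 1.0])
            rows.append(load * f + rng.normal(0, noise_sd, n_samples))
            labels.append(b)
    genes = [f"g{i:03d}" for i in range(2 * n_per_block)]
    expr = pd.DataFrame(rows, index=pd.Index(genes, name="gene"),
                        columns=[f"s{j:03d}" for j in range(n_samples)])
    return expr, pd.Series(labels, index=expr.index, name="block")
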