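"""Synthetic multi-batch cohorts with planted immune-phenotype structure.

The generator emulates the statistical structure the pipeline is designed
to detect, with full ground truth, so that every stage is testable offline:

* three latent phenotypes per sample (immune-active / immune-desert /
  stroma-rich) driving per-cell-type abundances (immune-active: high
  activated-adaptive infiltration; immune-desert: low everything;
  stroma-rich: high stromal/innate but low activated-adaptive);
* bulk log-scale expression in which each cell type's signature genes are
  elevated linearly in that cell's abundance, plus additive per-batch
  shifts and Gaussian noise;
* mutation indicator tables whose per-gene mutation probability follows a
  per-sample burden that is higher in the immune-active phenotype
  (burden-subtype confounding, emulating dMMR/MSI-H enrichment), with a
  configurable set of genuinely differential genes on top;
* thresholded CNV tables with a higher alteration rate in stroma-rich;
* clonotype tables with the lowest richness in immune-desert;
* exponential survival with a planted stroma-rich hazard ratio and
  independent uniform censoring;
* single-cell UMI counts whose cell-type mix depends on the phenotype.

All draws come from one seeded generator, so a config reproduces its
cohort exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmwrite
from scipy.sparse import csr_matrix

from .infiltration import SignatureRegistry, default_cell_groups
from .io_preprocess import ExpressionMatrix, write_expression

__all__ = ["GeneratorConfig", "SyntheticCohort", "generate_cohort", "write_cohort"]

PHENOTYPES = ("immune-active", "immune-desert", "stroma-rich")

#: Group-level abundance offsets per phenotype (log2-abundance units). The
#: activated-adaptive and stromal axes discriminate most strongly, as the
#: phenotypes are defined by them.
DEFAULT_ABUNDANCE_OFFSETS: dict[str, dict[str, float]] = {
    "immune-active": {"activated_adaptive": 2.5, "adaptive": 1.0, "innate": 1.0, "stromal": -1.0},
    "immune-desert": {"activated_adaptive": -1.0, "adaptive": -1.0, "innate": -1.0, "stromal": -1.0},
    "stroma-rich": {"activated_adaptive": -0.5, "adaptive": 1.0, "innate": 1.0, "stromal": 2.5},
}

#: Mean log2 burden (non-silent mutation count) per phenotype; the
#: immune-active excess emulates dMMR/MSI-H hypermutation.
DEFAULT_BURDEN_MEAN = {"immune-active": 8.5, "immune-desert": 6.5, "stroma-rich": 6.5}

#: Per-unit CNV alteration probability per phenotype (stroma-rich highest).
DEFAULT_CNV_RATE = {"immune-active": 0.08, "immune-desert": 0.08, "stroma-rich": 0.20}

#: Mean clonotype richness per phenotype (immune-desert lowest).
DEFAULT_RICHNESS = {"immune-active": 100, "immune-desert": 15, "stroma-rich": 60}

#: Major-cell-type proportions per phenotype for the single-cell mix.
DEFAULT_SC_PROPORTIONS = {
    "immune-active": {"T_cell": 0.35, "B_cell": 0.15, "myeloid": 0.20, "stromal": 0.10, "epithelial": 0.20},
    "immune-desert": {"T_cell": 0.05, "B_cell": 0.05, "myeloid": 0.10, "stromal": 0.10, "epithelial": 0.70},
    "stroma-rich": {"T_cell": 0.15, "B_cell": 0.05, "myeloid": 0.15, "stromal": 0.40, "epithelial": 0.25},
}


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic cohort. Defaults are sized so the
    full pipeline runs in minutes on one CPU while leaving each planted
    effect comfortably detectable at n=300."""

    seed: int
    n_samples: int = 300
    n_genes: int = 2000
    phenotype_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    # expression model
    signature_size: int = 10
    effect_size: float = 1.0  # log2 expression units per abundance unit
    noise_sd: float = 0.5
    abundance_sd: float = 0.3
    # per-sample latent "overall infiltration level" loading on the
    # non-activated adaptive and innate cells: real cohorts vary
    # continuously in global immune content within each phenotype
    infiltration_factor_sd: float = 0.55
    mixed_fraction: float = 0.0  # samples intermediate between two archetypes
    baseline_mean: float = 6.0
    baseline_sd: float = 1.5
    n_batches: int = 3
    batch_shift_sd: float = 0.5
    abundance_offsets: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_ABUNDANCE_OFFSETS
    )

    # mutation model
    burden_log2_mean: Mapping[str, float] = field(default_factory=lambda: DEFAULT_BURDEN_MEAN)
    burden_log2_sd: float = 1.0
    n_null_genes: int = 500
    n_differential_genes: int = 25
    differential_log_or: float = 2.0  # odds ratio ~7.4 in the target phenotype
    differential_target: str = "immune-active"
    mutation_intercept: float = -2.5
    mutation_burden_slope: float = 0.8
    burden_center: float = 7.5

    # CNV model
    n_cnv_units: int = 200
    cnv_rate: Mapping[str, float] = field(default_factory=lambda: DEFAULT_CNV_RATE)
    cnv_deep_fraction: float = 0.3

    # clonotype model
    richness_mean: Mapping[str, float] = field(default_factory=lambda: DEFAULT_RICHNESS)
    clonotype_geometric_p: float = 0.35

    # survival model
    baseline_hazard: float = 0.015  # events per month
    stroma_rich_hr: float = 2.3
    censor_low: float = 6.0
    censor_high: float = 120.0

    # single-cell model
    n_sc_samples: int = 12
    cells_per_sample: int = 60
    umis_per_cell: int = 1500
    sc_marker_boost: float = 8.0
    sc_proportions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_SC_PROPORTIONS
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        w = np.asarray(self.phenotype_weights, dtype=float)
        if len(w) != 3 or (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError("phenotype_weights must be 3 non-negative values summing to 1")
        for mapping in (self.cnv_rate,):
            for v in mapping.values():
                if not 0 <= v <= 1:
                    raise ValueError("probabilities must be in [0, 1]")
        if self.n_sc_samples > self.n_samples:
            raise ValueError("n_sc_samples exceeds n_samples")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "GeneratorConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass
class SyntheticCohort:
    """A generated cohort with its ground truth."""

    expression: ExpressionMatrix
    signatures: SignatureRegistry
    abundances: pd.DataFrame  # cell types x samples
    mutations: pd.DataFrame  # samples x genes 0/1
    mutation_counts: pd.Series  # per-sample non-silent totals
    cnv: pd.DataFrame  # samples x units in {-2..2}
    clonotypes: pd.DataFrame  # long: sample_id, clonotype_id, count
    clinical: pd.DataFrame
    sc_counts: pd.DataFrame  # genes x cells
    sc_meta: pd.DataFrame
    truth: pd.DataFrame  # sample_id-indexed: phenotype, batch, burden, ...
    differential_genes: list[str]
    config: GeneratorConfig


def _cell_types_and_offsets(cfg: GeneratorConfig):
    """The 31 cell types with their per-phenotype abundance offsets, using
    group precedence activated_adaptive > adaptive > innate > stromal."""
    groups = default_cell_groups()
    ordered = list(dict.fromkeys(groups["adaptive"] + groups["innate"] + groups["stromal"]))
    precedence = ("activated_adaptive", "adaptive", "innate", "stromal")
    offsets = {}
    for phen in PHENOTYPES:
        per_group = cfg.abundance_offsets[phen]
        row = {}
        for ct in ordered:
            for g in precedence:
                if ct in groups[g]:
                    row[ct] = float(per_group[g])
                    break
        offsets[phen] = row
    return ordered, offsets, groups


def generate_cohort(cfg: GeneratorConfig) -> SyntheticCohort:
    """Draw a complete cohort from the configured generative model."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]

    phen = rng.choice(len(PHENOTYPES), size=n, p=np.asarray(cfg.phenotype_weights))
    phenotypes = np.array(PHENOTYPES)[phen]
    batches = np.array([f"batch{b + 1}" for b in rng.integers(0, cfg.n_batches, size=n)])

    cell_types, offsets, groups = _cell_types_and_offsets(cfg)

    # --- abundances and signatures -------------------------------------
    mean_ab = np.array([[offsets[p][ct] for p in phenotypes] for ct in cell_types])
    # a configurable minority of samples sit between their phenotype and a
    # random other archetype, as intermediate tumors do in real cohorts
    mixed = rng.random(n) < cfg.mixed_fraction
    for i in np.flatnonzero(mixed):
        other = PHENOTYPES[rng.choice([j for j in range(3) if PHENOTYPES[j] != phenotypes[i]])]
        w = rng.uniform(0.3, 0.7)
        other_col = np.array([offsets[other][ct] for ct in cell_types])
        mean_ab[:, i] = w * mean_ab[:, i] + (1.0 - w) * other_col
    # latent per-sample infiltration level: loads on the non-activated
    # adaptive and innate cells, sparing the cell types that discriminate
    # the phenotypes most (activated-adaptive, stromal)
    act = set(groups["activated_adaptive"])
    infil_load = np.array(
        [
            0.0 if (ct in act or ct in groups["stromal"]) else 1.0
            for ct in cell_types
        ]
    )
    infil_factor = rng.normal(0.0, cfg.infiltration_factor_sd, size=n)
    abundance = (
        mean_ab
        + infil_load[:, None] * infil_factor[None, :]
        + rng.normal(0.0, cfg.abundance_sd, size=mean_ab.shape)
    )
    abundances = pd.DataFrame(abundance, index=cell_types, columns=sample_ids)

    sig_size = cfg.signature_size
    needed = (len(cell_types) + 1) * sig_size  # +1 for the exhausted set
    if needed > cfg.n_genes:
        raise ValueError("n_genes too small for the signature layout")
    sets: dict[str, list[str]] = {}
    for i, ct in enumerate(cell_types):
        sets[ct] = gene_ids[i * sig_size : (i + 1) * sig_size]
    exhausted_genes = gene_ids[len(cell_types) * sig_size : needed]
    sets["Exhausted T cell"] = exhausted_genes
    immune_members = groups["adaptive"] + groups["innate"]
    sets["ESTIMATE immune"] = [g for ct in immune_members for g in sets[ct]]
    sets["ESTIMATE stromal"] = [g for ct in groups["stromal"] for g in sets[ct]]
    provenance = {ct: "TME-cell" for ct in cell_types}
    provenance["Exhausted T cell"] = "exhaustion"
    provenance["ESTIMATE immune"] = "estimate-immune"
    provenance["ESTIMATE stromal"] = "estimate-stromal"
    registry = SignatureRegistry(sets=sets, provenance=provenance)

    exhausted_ab = 0.8 * abundance[cell_types.index("Activated CD8 T cell")] + rng.normal(
        0.0, 0.5 * cfg.abundance_sd, size=n
    )

    # --- bulk expression (log2 scale) ----------------------------------
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    expr = np.tile(baseline[:, None], (1, n))
    for i, ct in enumerate(cell_types):
        rows = slice(i * sig_size, (i + 1) * sig_size)
        expr[rows] += cfg.effect_size * abundance[i][None, :]
    expr[len(cell_types) * sig_size : needed] += cfg.effect_size * exhausted_ab[None, :]
    batch_shift = rng.normal(0.0, cfg.batch_shift_sd, size=(cfg.n_genes, cfg.n_batches))
    batch_idx = np.array([int(b[5:]) - 1 for b in batches])
    expr += batch_shift[:, batch_idx]
    expr += rng.normal(0.0, cfg.noise_sd, size=expr.shape)
    expression = ExpressionMatrix(
        pd.DataFrame(expr, index=gene_ids, columns=sample_ids),
        log_scale=True,
        batch=pd.Series(batches, index=sample_ids, name="batch"),
    )

    # --- mutations ------------------------------------------------------
    burden_mu = np.array([cfg.burden_log2_mean[p] for p in phenotypes])
    burden_latent = rng.normal(burden_mu, cfg.burden_log2_sd)
    n_nonsilent = np.maximum(np.round(2.0**burden_latent).astype(int), 1)
    load = np.log2(n_nonsilent + 1.0)

    n_mut = cfg.n_null_genes + cfg.n_differential_genes
    mut_genes = [f"MUT{i + 1:04d}" for i in range(n_mut)]
    differential = mut_genes[cfg.n_null_genes :]
    logit = cfg.mutation_intercept + cfg.mutation_burden_slope * (load - cfg.burden_center)
    probs = np.tile(1.0 / (1.0 + np.exp(-logit))[:, None], (1, n_mut))
    if cfg.n_differential_genes:
        in_target = phenotypes == cfg.differential_target
        boost = 1.0 / (
            1.0 + np.exp(-(logit[in_target, None] + cfg.differential_log_or))
        )
        probs[np.ix_(in_target, np.arange(cfg.n_null_genes, n_mut))] = boost
    mutations = pd.DataFrame(
        (rng.random(probs.shape) < probs).astype(int), index=sample_ids, columns=mut_genes
    )
    mutation_counts = pd.Series(n_nonsilent, index=sample_ids, name="n_nonsilent")

    # --- CNV -------------------------------------------------------------
    units = [f"CB{i + 1:03d}" for i in range(cfg.n_cnv_units)]
    rate = np.array([cfg.cnv_rate[p] for p in phenotypes])
    altered = rng.random((n, cfg.n_cnv_units)) < rate[:, None]
    prefer_gain = np.arange(cfg.n_cnv_units) % 2 == 0  # fixed per-unit direction bias
    use_pref = rng.random((n, cfg.n_cnv_units)) < 0.8
    gain = np.where(use_pref, prefer_gain[None, :], ~prefer_gain[None, :])
    deep = rng.random((n, cfg.n_cnv_units)) < cfg.cnv_deep_fraction
    calls = np.where(altered, np.where(gain, 1, -1) * np.where(deep, 2, 1), 0)
    cnv = pd.DataFrame(calls, index=sample_ids, columns=units)

    # --- clonotypes ------------------------------------------------------
    rich_mu = np.array([cfg.richness_mean[p] for p in phenotypes])
    richness = np.maximum(rng.poisson(rich_mu), 1)
    rows = []
    for s, r in zip(sample_ids, richness):
        counts = rng.geometric(cfg.clonotype_geometric_p, size=int(r))
        rows.extend(
            {"sample_id": s, "clonotype_id": f"{s}_c{i + 1}", "count": int(c)}
            for i, c in enumerate(counts)
        )
    clonotypes = pd.DataFrame(rows)

    # --- survival and clinical ------------------------------------------
    hr = np.where(phenotypes == "stroma-rich", cfg.stroma_rich_hr, 1.0)
    os_hazard = cfg.baseline_hazard * hr
    os_t = rng.exponential(1.0 / os_hazard)
    os_c = rng.uniform(cfg.censor_low, cfg.censor_high, size=n)
    dfs_t = rng.exponential(1.0 / (os_hazard * 1.3))
    dfs_c = rng.uniform(cfg.censor_low, cfg.censor_high, size=n)
    msi_p = np.where(phenotypes == "immune-active", 0.35, 0.05)
    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "os_time": np.minimum(os_t, os_c),
            "os_event": (os_t <= os_c).astype(int),
            "dfs_time": np.minimum(dfs_t, dfs_c),
            "dfs_event": (dfs_t <= dfs_c).astype(int),
            "age": np.clip(np.round(rng.normal(65, 10, size=n)), 30, 95).astype(int),
            "sex": rng.choice(["F", "M"], size=n),
            "stage": rng.choice(["I", "II", "III", "IV"], size=n, p=(0.15, 0.35, 0.35, 0.15)),
            "msi_status": np.where(rng.random(n) < msi_p, "MSI-H", "MSS"),
            "batch": batches,
        }
    ).set_index("sample_id")

    # --- single cell -----------------------------------------------------
    majors = {
        "T_cell": [ct for ct in groups["adaptive"] if "B cell" not in ct],
        "B_cell": [ct for ct in groups["adaptive"] if "B cell" in ct],
        "myeloid": groups["innate"],
        "stromal": groups["stromal"],
        "epithelial": [],
    }
    background = gene_ids[needed : needed + 50]  # epithelial marker stand-in
    marker_genes = {
        m: ([g for ct in cts for g in sets[ct]] if cts else list(background))
        for m, cts in majors.items()
    }
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    sc_sample_ids = sample_ids[: cfg.n_sc_samples]
    sc_cells, sc_types, sc_samples = [], [], []
    counts_rows = []
    base_w = np.ones(cfg.n_genes)
    for s in sc_sample_ids:
        p_row = cfg.sc_proportions[phenotypes[sample_ids.index(s)]]
        names = list(p_row)
        pvals = np.asarray([p_row[m] for m in names], dtype=float)
        pvals = pvals / pvals.sum()
        for c in range(cfg.cells_per_sample):
            major = names[rng.choice(len(names), p=pvals)]
            w = base_w.copy()
            w[[gene_pos[g] for g in marker_genes[major]]] *= cfg.sc_marker_boost
            counts_rows.append(rng.multinomial(cfg.umis_per_cell, w / w.sum()))
            sc_cells.append(f"{s}_cell{c + 1:03d}")
            sc_types.append(major)
            sc_samples.append(s)
    sc_counts = pd.DataFrame(
        np.asarray(counts_rows, dtype=np.int64).T, index=gene_ids, columns=sc_cells
    )
    sc_meta = pd.DataFrame(
        {"cell_id": sc_cells, "sample_id": sc_samples, "cell_type": sc_types}
    )

    truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "phenotype": phenotypes,
            "mixed": mixed,
            "batch": batches,
            "n_nonsilent": n_nonsilent,
            "mutation_load": load,
            "richness": richness,
        }
    ).set_index("sample_id")

    return SyntheticCohort(
        expression=expression,
        signatures=registry,
        abundances=abundances,
        mutations=mutations,
        mutation_counts=mutation_counts,
        cnv=cnv,
        clonotypes=clonotypes,
        clinical=clinical,
        sc_counts=sc_counts,
        sc_meta=sc_meta,
        truth=truth,
        differential_genes=list(differential),
        config=cfg,
    )


def write_cohort(c: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write every interface format of the cohort to ``outdir``:
    expression TSV, generating-signature GMT, mutation TSV + toy MAF, CNV
    TSV, clonotype TSV, clinical TSV, ground-truth TSV, and single-cell
    MTX + gene list + cell metadata. Returns the written paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["expression"] = out / "expression.tsv"
    write_expression(c.expression, paths["expression"])
    paths["sample_metadata"] = out / "sample_metadata.tsv"
    pd.DataFrame({"batch": c.expression.batch}).rename_axis("sample_id").to_csv(
        paths["sample_metadata"], sep="\t"
    )
    paths["signatures"] = out / "signatures.gmt"
    c.signatures.to_gmt(paths["signatures"])
    paths["mutations"] = out / "mutations.tsv"
    c.mutations.rename_axis("sample_id").to_csv(paths["mutations"], sep="\t")
    paths["maf"] = out / "mutations.maf"
    long = c.mutations.stack()
    long = long[long == 1]
    maf = pd.DataFrame(
        {
            "Tumor_Sample_Barcode": long.index.get_level_values(0),
            "Hugo_Symbol": long.index.get_level_values(1),
            "Variant_Classification": "Missense_Mutation",
        }
    )
    maf.to_csv(paths["maf"], sep="\t", index=False)
    paths["cnv"] = out / "cnv.tsv"
    c.cnv.rename_axis("sample_id").to_csv(paths["cnv"], sep="\t")
    paths["clonotypes"] = out / "clonotypes.tsv"
    c.clonotypes.to_csv(paths["clonotypes"], sep="\t", index=False)
    paths["clinical"] = out / "clinical.tsv"
    c.clinical.to_csv(paths["clinical"], sep="\t")
    paths["truth"] = out / "ground_truth.tsv"
    c.truth.to_csv(paths["truth"], sep="\t")

    sc_dir = out / "sc"
    sc_dir.mkdir(exist_ok=True)
    paths["sc_matrix"] = sc_dir / "matrix.mtx"
    mmwrite(str(paths["sc_matrix"]), csr_matrix(c.sc_counts.to_numpy()))
    paths["sc_genes"] = sc_dir / "genes.tsv"
    pd.Series(c.sc_counts.index).to_csv(paths["sc_genes"], sep="\t", index=False, header=False)
    paths["sc_cells"] = sc_dir / "cells.tsv"
    c.sc_meta.to_csv(paths["sc_cells"], sep="\t", index=False)
    return paths
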