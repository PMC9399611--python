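"""Per-sample infiltration scoring of TME cell types.

Single-sample gene-set enrichment (ssGSEA) turns a log-scale expression
profile into one enrichment score per cell-type signature: genes are ranked
within each sample and the score is the accumulated difference between a
rank-weighted in-set cumulative distribution and a uniform out-of-set one.
Because only ranks enter, the score is invariant to any strictly monotone
per-sample transform of expression.

On top of the raw scores the module derives the characterization battery:
ESTIMATE-style immune/stromal scores with a cosine tumor-purity transform,
macrophage M1/M2, Th17/Treg and Th1/Th2 ratios, grouped aggregate scores
(adaptive / activated-adaptive / innate / stromal), and exhausted-T-cell
scoring with its ratio to CD8 T cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import rankdata

from .io_preprocess import ExpressionMatrix, read_gmt, write_gmt

__all__ = [
    "SignatureRegistry",
    "InfiltrationMatrix",
    "ssgsea_score",
    "cohort_minmax",
    "normalize_scores",
    "estimate_scores",
    "derived_ratios",
    "characterize",
    "load_default_signatures",
    "default_cell_groups",
    "PURITY_INTERCEPT",
    "PURITY_SLOPE",
]

# Coefficients of the cosine purity transform applied to the combined
# immune + stromal score: purity = cos(a + b * combined).
PURITY_INTERCEPT = 0.6049872018
PURITY_SLOPE = 0.0001467884

#: Default numerator/denominator cell types for the characterization ratios.
DEFAULT_RATIOS: dict[str, tuple[str, str]] = {
    "m1_m2_ratio": ("Macrophage M1", "Macrophage M2"),
    "th17_treg_ratio": ("Type 17 T helper cell", "Regulatory T cell"),
    "th1_th2_ratio": ("Type 1 T helper cell", "Type 2 T helper cell"),
    "exhausted_to_cd8_ratio": ("Exhausted T cell", "Activated CD8 T cell"),
}


@dataclass
class SignatureRegistry:
    """Named gene sets with a provenance tag per set.

    Tags distinguish the TME cell-type signatures proper ("TME-cell") from
    the auxiliary sets (ESTIMATE-style immune/stromal, exhaustion,
    cytolytic). Membership is stored de-duplicated, insertion-ordered.
    """

    sets: dict[str, list[str]]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"empty gene set: {name!r}")
            self.sets[name] = list(dict.fromkeys(genes))
        for name in self.sets:
            self.provenance.setdefault(name, "TME-cell")

    @classmethod
    def from_gmt(cls, path: str | Path) -> "SignatureRegistry":
        sets, desc = read_gmt(path)
        return cls(sets=sets, provenance=desc)

    def to_gmt(self, path: str | Path) -> None:
        write_gmt(self.sets, path, self.provenance)

    def subset(self, names: Sequence[str]) -> "SignatureRegistry":
        return SignatureRegistry(
            sets={n: list(self.sets[n]) for n in names},
            provenance={n: self.provenance[n] for n in names},
        )

    def by_provenance(self, tag: str) -> list[str]:
        return [n for n, t in self.provenance.items() if t == tag]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class InfiltrationMatrix:
    """Cell types x samples enrichment scores.

    ``stages`` records the normalization stages applied ("minmax",
    "zscore"); ``constant_rows`` lists cell types whose scores were constant
    across the cohort and therefore skipped z-scaling.
    """

    scores: pd.DataFrame
    normalized: bool = False
    stages: tuple[str, ...] = ()
    constant_rows: list[str] = field(default_factory=list)

    @property
    def cell_types(self) -> pd.Index:
        return self.scores.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.scores.columns

    def to_tsv(self, path: str | Path) -> None:
        self.scores.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "InfiltrationMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0), **kwargs)


def load_default_signatures() -> SignatureRegistry:
    """Load the bundled TME signature collection.

    The bundled GMT is a synthetic stand-in: 31 named TME cell types plus
    auxiliary immune/stromal/exhaustion/cytolytic sets, each populated with
    plausible, editable marker genes. Curate your own GMT for real analyses.
    """
    ref = resources.files("tmephenotype.data") / "tme_signatures_synthetic.gmt"
    with resources.as_file(ref) as path:
        return SignatureRegistry.from_gmt(path)


def default_cell_groups() -> dict[str, list[str]]:
    """Functional grouping of the 31 cell types (adaptive, activated_adaptive,
    innate, stromal) used for aggregate scores and cluster naming."""
    ref = resources.files("tmephenotype.data") / "cell_groups.yaml"
    with resources.as_file(ref) as path:
        return yaml.safe_load(Path(path).read_text())


def ssgsea_score(
    m: ExpressionMatrix,
    sig: SignatureRegistry,
    alpha: float = 0.25,
) -> InfiltrationMatrix:
    """Single-sample GSEA enrichment scores, one per (gene set, sample).

    For each sample, genes are ordered by decreasing expression (average
    ranks for ties). Walking down that ordering, the in-set cumulative
    distribution weighted by rank**alpha is compared with the uniform
    out-of-set cumulative distribution, and the enrichment score is the sum
    of their differences over all positions.

    Sets with no gene present in the matrix are dropped with a warning;
    all-constant sample columns are scored with averaged ranks (warned).
    """
    X = m.values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if not m.log_scale:
        warnings.warn("scoring a matrix not flagged as log scale", stacklevel=2)
    const_cols = m.sample_ids[(X.max(axis=0) - X.min(axis=0)) == 0].tolist()
    if const_cols:
        warnings.warn(
            f"all-constant sample column(s) {const_cols[:5]}; ties averaged",
            stacklevel=2,
        )

    ranks = rankdata(X, method="average", axis=0)  # highest expression -> rank n_genes
    order = np.argsort(-X, axis=0, kind="stable")
    w = ranks**alpha
    w_ord = np.take_along_axis(w, order, axis=0)

    rows: list[np.ndarray] = []
    kept: list[str] = []
    gene_pos = {g: i for i, g in enumerate(m.gene_ids)}
    for name, genes in sig.sets.items():
        idx = [gene_pos[g] for g in genes if g in gene_pos]
        if not idx:
            warnings.warn(f"gene set {name!r} has no overlap with the matrix; dropped", stacklevel=2)
            continue
        mask = np.zeros(n_genes, dtype=bool)
        mask[idx] = True
        mask_ord = mask[order]  # (genes, samples) in per-sample rank order
        in_w = np.where(mask_ord, w_ord, 0.0)
        p_in = np.cumsum(in_w, axis=0) / in_w.sum(axis=0)
        n_out = n_genes - len(idx)
        if n_out == 0:
            p_out = np.zeros_like(p_in)
        else:
            p_out = np.cumsum(~mask_ord, axis=0) / n_out
        rows.append((p_in - p_out).sum(axis=0))
        kept.append(name)
    if not kept:
        raise ValueError("no gene set overlaps the expression matrix")
    scores = pd.DataFrame(np.vstack(rows), index=kept, columns=m.sample_ids)
    return InfiltrationMatrix(scores)


def cohort_minmax(scores: pd.DataFrame) -> pd.DataFrame:
    """Global min-max normalization over the whole matrix (idempotent)."""
    lo = scores.to_numpy().min()
    hi = scores.to_numpy().max()
    if hi == lo:
        return scores - lo  # all-constant matrix -> all zeros
    return (scores - lo) / (hi - lo)


def normalize_scores(im: InfiltrationMatrix) -> InfiltrationMatrix:
    """Cohort min-max normalization followed by per-cell-type z-scaling.

    Stage 1 maps the whole matrix onto [0, 1]; stage 2 centers and scales
    each cell type across samples (sd with ddof=1). Constant rows skip
    stage 2 and are flagged in ``constant_rows``.
    """
    mm = cohort_minmax(im.scores)
    mu = mm.mean(axis=1)
    sd = mm.std(axis=1, ddof=1)
    constant = sd == 0
    z = mm.sub(mu, axis=0)
    z.loc[~constant] = z.loc[~constant].div(sd[~constant], axis=0)
    z.loc[constant] = mm.loc[constant]
    return InfiltrationMatrix(
        z,
        normalized=True,
        stages=("minmax", "zscore"),
        constant_rows=im.cell_types[constant].tolist(),
    )


def estimate_scores(
    m: ExpressionMatrix,
    sig: SignatureRegistry,
    *,
    immune_set: str = "ESTIMATE immune",
    stromal_set: str = "ESTIMATE stromal",
    alpha: float = 0.25,
    affine: tuple[float, float] = (1.0, 0.0),
) -> pd.DataFrame:
    """ESTIMATE-style immune/stromal scores and cosine tumor purity.

    Immune and stromal scores are ssGSEA scores on the dedicated sets,
    optionally rescaled by the affine map ``a * ES + b`` (default identity;
    purity values are therefore internally consistent rather than
    ESTIMATE-identical, see the methods note). Purity is
    ``cos(0.6049872018 + 0.0001467884 * (immune + stromal))`` with the
    argument clipped to [0, pi/2] and purity to (0, 1]; clipping is flagged
    in the ``purity_clipped`` column.
    """
    for s in (immune_set, stromal_set):
        if s not in sig:
            raise ValueError(f"required gene set missing from registry: {s!r}")
    es = ssgsea_score(m, sig.subset([immune_set, stromal_set]), alpha=alpha).scores
    a, b = affine
    immune = a * es.loc[immune_set] + b
    stromal = a * es.loc[stromal_set] + b
    combined = immune + stromal
    arg = PURITY_INTERCEPT + PURITY_SLOPE * combined
    clipped = (arg < 0) | (arg > np.pi / 2)
    if clipped.any():
        warnings.warn(
            f"purity argument clipped to [0, pi/2] for {int(clipped.sum())} sample(s)",
            stacklevel=2,
        )
    purity = np.cos(np.clip(arg, 0.0, np.pi / 2))
    purity = np.clip(purity, np.nextafter(0, 1), 1.0)
    return pd.DataFrame(
        {
            "immune_score": immune,
            "stromal_score": stromal,
            "estimate_combined": combined,
            "tumor_purity": purity,
            "purity_clipped": clipped,
        }
    ).rename_axis("sample_id")


def derived_ratios(
    im: InfiltrationMatrix,
    *,
    groups: Mapping[str, Sequence[str]] | None = None,
    ratios: Mapping[str, tuple[str, str]] | None = None,
    eps: float = 0.01,
) -> pd.DataFrame:
    """Characterization ratios and grouped aggregate scores per sample.

    Ratios (M1/M2, Th17/Treg, Th1/Th2, exhausted/CD8) are computed on the
    cohort min-max-normalized (hence non-negative) scores as
    ``(num + eps) / (den + eps)``. Aggregate scores are means of the
    min-max + z-scaled scores over each group's member cell types. Pass the
    raw (un-normalized) score matrix. Missing cell types yield NaN columns
    with a warning naming them.
    """
    groups = default_cell_groups() if groups is None else groups
    ratios = DEFAULT_RATIOS if ratios is None else ratios
    mm = cohort_minmax(im.scores)
    z = normalize_scores(im).scores

    out = pd.DataFrame(index=im.sample_ids).rename_axis("sample_id")
    for col, (num, den) in ratios.items():
        if num not in mm.index or den not in mm.index:
            missing = [c for c in (num, den) if c not in mm.index]
            warnings.warn(f"{col}: missing cell type(s) {missing}; set undefined", stacklevel=2)
            out[col] = np.nan
            continue
        out[col] = (mm.loc[num] + eps) / (mm.loc[den] + eps)
    for group, members in groups.items():
        present = [c for c in members if c in z.index]
        if not present:
            warnings.warn(f"aggregate {group!r}: no member cell type present", stacklevel=2)
            out[f"{group}_score"] = np.nan
            continue
        out[f"{group}_score"] = z.loc[present].mean(axis=0)
    return out


def characterize(
    m: ExpressionMatrix,
    im: InfiltrationMatrix,
    sig: SignatureRegistry,
    *,
    groups: Mapping[str, Sequence[str]] | None = None,
    eps: float = 0.01,
    alpha: float = 0.25,
) -> pd.DataFrame:
    """Full per-sample characterization table: ESTIMATE-style scores and
    purity joined with ratios, aggregates, and the exhausted-T-cell score."""
    est = estimate_scores(m, sig, alpha=alpha)
    rat = derived_ratios(im, groups=groups, eps=eps)
    out = est.join(rat)
    if "Exhausted T cell" in im.scores.index:
        out["exhausted_t_score"] = im.scores.loc["Exhausted T cell"]
    return out
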