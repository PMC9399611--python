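"""Expression I/O, count transformation, and cross-cohort batch calibration.

This module handles the plumbing that precedes infiltration scoring: loading
genes x samples expression tables (TSV/CSV) and GMT gene-set files, a
voom-style log2-CPM transform of raw counts, and a parametric empirical-Bayes
location/scale batch adjustment (ComBat-type) used to merge cohorts profiled
on different platforms before rank-based enrichment scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionLoadError",
    "ExpressionMatrix",
    "BatchModel",
    "read_expression",
    "write_expression",
    "read_sample_metadata",
    "read_gmt",
    "write_gmt",
    "log_cpm_transform",
    "combat_adjust",
]

_SEPS = {"tsv": "\t", "csv": ","}


class ExpressionLoadError(ValueError):
    """An expression table violates the matrix contract (duplicates,
    non-numeric cells, missing values, or empty content)."""


def _check_unique(index: pd.Index, kind: str) -> None:
    if index.duplicated().any():
        dupes = index[index.duplicated()].unique().tolist()
        shown = ", ".join(str(d) for d in dupes[:5])
        raise ExpressionLoadError(f"duplicate {kind} identifier(s): {shown}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with optional per-sample batch labels.

    Parameters
    ----------
    values
        Numeric DataFrame, genes in rows, samples in columns.
    log_scale
        Whether ``values`` is already on log2 scale. Raw matrices must be
        non-negative.
    batch
        Optional per-sample batch label, indexed by sample id.
    """

    values: pd.DataFrame
    log_scale: bool = False
    batch: pd.Series | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.size == 0:
            raise ExpressionLoadError("empty expression matrix")
        _check_unique(v.index, "gene")
        _check_unique(v.columns, "sample")
        bad_cols = [c for c in v.columns if not np.issubdtype(v[c].dtype, np.number)]
        if bad_cols:
            raise ExpressionLoadError(f"non-numeric sample column(s): {bad_cols[:5]}")
        if v.isna().to_numpy().any():
            bad = v.columns[v.isna().any(axis=0)].tolist()
            raise ExpressionLoadError(f"missing values in sample(s): {bad[:5]}")
        if not self.log_scale and (v.to_numpy() < 0).any():
            raise ExpressionLoadError("negative values in a raw (non-log) matrix")
        if self.batch is not None:
            b = pd.Series(self.batch)
            b = b.reindex(v.columns)
            if b.isna().any():
                missing = b.index[b.isna()].tolist()
                raise ExpressionLoadError(f"batch label missing for sample(s): {missing[:5]}")
            self.batch = b

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(),
            log_scale=self.log_scale,
            batch=None if self.batch is None else self.batch.copy(),
        )


def read_expression(
    path: str | Path,
    dialect: str = "tsv",
    *,
    log_scale: bool = False,
    batch: pd.Series | None = None,
) -> ExpressionMatrix:
    """Read a genes x samples table. First column holds gene ids, the header
    row holds sample ids. Raises :class:`ExpressionLoadError` naming the
    offending row/column on malformed input."""
    sep = _SEPS[dialect]
    raw = pd.read_csv(path, sep=sep, index_col=0)
    if raw.empty:
        raise ExpressionLoadError(f"empty expression matrix in {path}")
    for col in raw.columns:
        if np.issubdtype(raw[col].dtype, np.number):
            continue
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = raw.index[coerced.isna() & raw[col].notna()]
        if len(bad):
            raise ExpressionLoadError(
                f"non-numeric value in column {col!r}, row {bad[0]!r}"
            )
        raw[col] = coerced
    return ExpressionMatrix(raw, log_scale=log_scale, batch=batch)


def write_expression(m: ExpressionMatrix, path: str | Path, dialect: str = "tsv") -> None:
    m.values.to_csv(path, sep=_SEPS[dialect])


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata TSV with a ``sample_id`` column (plus e.g.
    ``batch`` and clinical columns); returns a frame indexed by sample_id."""
    meta = pd.read_csv(path, sep="\t")
    if "sample_id" not in meta.columns:
        raise ExpressionLoadError("sample metadata must contain a 'sample_id' column")
    _check_unique(pd.Index(meta["sample_id"]), "sample")
    return meta.set_index("sample_id")


def read_gmt(path: str | Path) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Parse a GMT file (name, description, member genes per tab-separated
    line). Returns ``(sets, descriptions)``; membership is de-duplicated
    preserving order."""
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need name, description, genes): {line[:60]!r}")
        name = fields[0]
        if name in sets:
            raise ValueError(f"duplicate gene-set name in GMT: {name!r}")
        genes = list(dict.fromkeys(g for g in fields[2:] if g))
        if not genes:
            raise ValueError(f"empty gene set in GMT: {name!r}")
        sets[name] = genes
        desc[name] = fields[1]
    if not sets:
        raise ValueError(f"no gene sets found in {path}")
    return sets, desc


def write_gmt(
    sets: Mapping[str, list[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    lines = []
    for name, genes in sets.items():
        d = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, d, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def log_cpm_transform(m: ExpressionMatrix, prior_count: float = 0.5) -> ExpressionMatrix:
    """Voom-style log2 counts-per-million.

    out[g, s] = log2((count[g, s] + prior) / (libsize[s] + 2 * prior) * 1e6)

    The prior count damps the variance of low-count genes; the doubled prior
    in the denominator keeps the transformed values bounded by log2(1e6).
    """
    if m.log_scale:
        raise ValueError("matrix is already on log scale")
    if prior_count <= 0:
        raise ValueError("prior_count must be positive")
    arr = m.values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("negative values in count matrix")
    lib = arr.sum(axis=0)
    denom = lib + 2.0 * prior_count
    if (denom <= 0).any():
        bad = m.sample_ids[denom <= 0].tolist()
        raise ValueError(f"zero effective library size for sample(s): {bad[:5]}")
    out = np.log2((arr + prior_count) / denom * 1e6)
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids),
        log_scale=True,
        batch=m.batch,
    )


@dataclass
class BatchModel:
    """Fitted parameters of the empirical-Bayes batch adjustment.

    ``gamma_star`` / ``delta_star`` are the shrunken per-(gene, batch)
    additive shifts and multiplicative variance factors (on the standardized
    scale); ``hyper`` holds per-batch prior parameters
    (gamma_bar, tau2, a_prior, b_prior)."""

    batches: list
    gamma_hat: pd.DataFrame
    delta_hat2: pd.DataFrame
    gamma_star: pd.DataFrame
    delta_star2: pd.DataFrame
    hyper: dict = field(default_factory=dict)
    grand_mean: pd.Series | None = None
    pooled_var: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.delta_star2.to_numpy() <= 0).any():
            raise ValueError("variance scale factors must be strictly positive")


def combat_adjust(
    m: ExpressionMatrix,
    *,
    tol: float = 1e-6,
    max_iter: int = 100,
    return_model: bool = False,
):
    """Parametric empirical-Bayes location/scale batch calibration.

    Standardizes each gene to pooled mean/variance, estimates per-batch
    gene-wise shifts and scales, shrinks them toward batch-level normal /
    inverse-gamma priors by iterated conditional modes, removes them, and
    restores the pooled location/scale. Genes with zero pooled variance are
    passed through unchanged (with a warning). A single batch (or no batch
    labels) is a no-op.
    """
    if m.batch is None or m.batch.nunique() <= 1:
        out = m.copy()
        return (out, None) if return_model else out
    if not m.log_scale:
        raise ValueError("batch adjustment expects a log-scale matrix")

    X = m.values.to_numpy(dtype=float)
    n_genes, n_total = X.shape
    levels = list(pd.unique(m.batch))
    idx_by_batch = {b: np.flatnonzero((m.batch == b).to_numpy()) for b in levels}
    for b, idx in idx_by_batch.items():
        if len(idx) < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")
    n_i = np.array([len(idx_by_batch[b]) for b in levels], dtype=float)

    batch_means = np.column_stack([X[:, idx_by_batch[b]].mean(axis=1) for b in levels])
    grand = batch_means @ (n_i / n_total)
    fitted = np.zeros_like(X)
    for j, b in enumerate(levels):
        fitted[:, idx_by_batch[b]] = batch_means[:, [j]]
    pooled_var = ((X - fitted) ** 2).sum(axis=1) / n_total

    # constant genes yield variance ~0 up to accumulation error
    var_floor = np.finfo(float).eps * max(np.abs(X).max() ** 2, 1.0)
    keep = pooled_var > var_floor
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} zero-variance gene(s) passed through un-scaled",
            stacklevel=2,
        )
    sd = np.sqrt(pooled_var[keep])
    Z = (X[keep] - grand[keep, None]) / sd[:, None]

    gamma_hat = np.empty((Z.shape[0], len(levels)))
    delta_hat2 = np.empty_like(gamma_hat)
    gamma_star = np.empty_like(gamma_hat)
    delta_star2 = np.empty_like(gamma_hat)
    hyper: dict = {}
    for j, b in enumerate(levels):
        zb = Z[:, idx_by_batch[b]]
        g_hat = zb.mean(axis=1)
        d_hat2 = zb.var(axis=1, ddof=1)
        gamma_hat[:, j] = g_hat
        delta_hat2[:, j] = d_hat2

        g_bar = g_hat.mean()
        tau2 = g_hat.var(ddof=1)
        m_ = d_hat2.mean()
        s2 = d_hat2.var(ddof=1)
        if s2 > 0:
            a_prior = (2.0 * s2 + m_**2) / s2
            b_prior = (m_ * s2 + m_**3) / s2
        else:  # degenerate prior (e.g. duplicated batches): no shrinkage
            a_prior = np.inf
            b_prior = np.inf
        hyper[b] = {"gamma_bar": g_bar, "tau2": tau2, "a_prior": a_prior, "b_prior": b_prior}

        n_b = float(len(idx_by_batch[b]))
        g_star = g_hat.copy()
        d_star2 = np.maximum(d_hat2, 1e-12)
        if s2 > 0 and tau2 > 0:
            for _ in range(max_iter):
                g_new = (n_b * tau2 * g_hat + d_star2 * g_bar) / (n_b * tau2 + d_star2)
                sse = ((zb - g_new[:, None]) ** 2).sum(axis=1)
                d_new = (b_prior + 0.5 * sse) / (n_b / 2.0 + a_prior - 1.0)
                change = max(
                    np.abs(g_new - g_star).max() / max(np.abs(g_star).max(), 1e-12),
                    np.abs(d_new - d_star2).max() / max(np.abs(d_star2).max(), 1e-12),
                )
                g_star, d_star2 = g_new, np.maximum(d_new, 1e-12)
                if change < tol:
                    break
        gamma_star[:, j] = g_star
        delta_star2[:, j] = d_star2

    Z_adj = np.empty_like(Z)
    for j, b in enumerate(levels):
        idx = idx_by_batch[b]
        Z_adj[:, idx] = (Z[:, idx] - gamma_star[:, [j]]) / np.sqrt(delta_star2[:, [j]])

    out = X.copy()
    out[keep] = Z_adj * sd[:, None] + grand[keep, None]

    adjusted = ExpressionMatrix(
        pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids),
        log_scale=True,
        batch=m.batch.copy(),
    )
    if not return_model:
        return adjusted
    kept_genes = m.gene_ids[keep]
    model = BatchModel(
        batches=levels,
        gamma_hat=pd.DataFrame(gamma_hat, index=kept_genes, columns=levels),
        delta_hat2=pd.DataFrame(delta_hat2, index=kept_genes, columns=levels),
        gamma_star=pd.DataFrame(gamma_star, index=kept_genes, columns=levels),
        delta_star2=pd.DataFrame(delta_star2, index=kept_genes, columns=levels),
        hyper=hyper,
        grand_mean=pd.Series(grand, index=m.gene_ids),
        pooled_var=pd.Series(pooled_var, index=m.gene_ids),
    )
    return adjusted, model
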