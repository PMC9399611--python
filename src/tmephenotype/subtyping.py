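"""Consensus-NMF subtyping of samples into immune phenotypes.

Scaled infiltration profiles are folded into a non-negative matrix
(positive and negative parts as separate rows), factorized by KL-divergence
multiplicative updates at a range of ranks with repeated seeded restarts,
and summarized per rank by a consensus (co-clustering) matrix. The rank kept
is the highest one before the largest drop of the cophenetic correlation
coefficient; at rank 3 the clusters are named immune-active, immune-desert
and stroma-rich from their aggregate infiltration profiles.

The module also aggregates single-cell UMI counts to sample-level
pseudo-bulk so the same bulk pipeline applies to single-cell cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .infiltration import InfiltrationMatrix, default_cell_groups, normalize_scores
from .io_preprocess import ExpressionMatrix

__all__ = [
    "NMFRun",
    "SubtypingResult",
    "PseudoBulkMatrix",
    "PHENOTYPES",
    "nmf_factorize",
    "posneg_fold",
    "consensus_from_assignments",
    "cophenetic_coefficient",
    "consensus_cluster",
    "select_rank",
    "assign_and_name",
    "pseudobulk_aggregate",
    "read_single_cell",
    "phenotype_pipeline",
]

logger = logging.getLogger(__name__)

PHENOTYPES = ("immune-active", "immune-desert", "stroma-rich")

_EPS = 1e-12


@dataclass
class NMFRun:
    """One non-negative factorization X ~ W @ H with its objective trace."""

    W: np.ndarray
    H: np.ndarray
    objective_trace: list[float]
    seed: int
    converged: bool

    def assignments(self) -> np.ndarray:
        """Hard cluster per sample: argmax over the coefficient rows."""
        return np.argmax(self.H, axis=0)


@dataclass
class SubtypingResult:
    """Per-rank consensus matrices and cophenetic coefficients, the selected
    rank, and (after naming) per-sample cluster indices and phenotype names.

    ``data`` keeps the non-negative matrix the consensus was computed on so
    that the final full-cohort factorization can be (re)fit at the selected
    rank; ``best_runs`` caches that factorization per rank."""

    consensus: dict[int, pd.DataFrame]
    cophenetic: dict[int, float]
    ranks: list[int]
    data: pd.DataFrame | None = None
    seed: int = 0
    n_runs: int = 30
    best_runs: dict[int, NMFRun] = field(default_factory=dict)
    selected_rank: int | None = None
    labels: pd.Series | None = None
    phenotypes: pd.Series | None = None
    cluster_names: dict[int, str] = field(default_factory=dict)


def _kl_divergence(X: np.ndarray, WH: np.ndarray) -> float:
    WH = np.maximum(WH, _EPS)
    pos = X > 0
    val = float((X[pos] * np.log(X[pos] / WH[pos])).sum() - X.sum() + WH.sum())
    return val


def nmf_factorize(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
    objective: str = "kl",
    connectivity_stop: int | None = None,
) -> NMFRun:
    """Multiplicative-update NMF of a non-negative matrix.

    The default minimizes the generalized KL divergence D(X || WH) with the
    Brunet update rules; ``objective="frobenius"`` switches to the
    Lee-Seung Euclidean updates. Iteration stops when the relative
    objective decrease falls below ``tol`` or after ``max_iter`` sweeps.
    The objective is recorded every sweep and must never increase (an
    increase beyond 1e-8 relative indicates an update bug and raises).

    ``connectivity_stop=m`` switches to the membership-based stopping rule
    of the classic consensus-NMF protocol: stop once the hard sample
    assignment has not changed for ``m`` consecutive sweeps. Consensus
    clustering uses this mode; stopping at membership stability (rather
    than polishing the objective to convergence) is what preserves the
    run-to-run variability that the cophenetic rank diagnostic measures.
    """
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError("NMF input must be non-negative")
    if X.ndim != 2:
        raise ValueError("NMF input must be a matrix")
    if (X.sum(axis=0) == 0).any():
        raise ValueError("NMF input has an all-zero column")
    n, m = X.shape
    if k >= min(n, m):
        raise ValueError(f"rank k={k} must be < min(matrix dims)={min(n, m)}")
    if objective not in ("kl", "frobenius"):
        raise ValueError(f"unknown objective {objective!r}")

    rng = np.random.default_rng(seed)
    W = rng.random((n, k)) + _EPS
    H = rng.random((k, m)) + _EPS

    def obj() -> float:
        WH = W @ H
        if objective == "kl":
            return _kl_divergence(X, WH)
        return float(((X - WH) ** 2).sum())

    trace = [obj()]
    converged = False
    stable_sweeps = 0
    last_assign = np.argmax(H, axis=0)
    for _ in range(max_iter):
        if objective == "kl":
            WH = np.maximum(W @ H, _EPS)
            H *= (W.T @ (X / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
            WH = np.maximum(W @ H, _EPS)
            W *= ((X / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        else:
            H *= (W.T @ X) / np.maximum(W.T @ W @ H, _EPS)
            W *= (X @ H.T) / np.maximum(W @ H @ H.T, _EPS)
        current = obj()
        previous = trace[-1]
        if current > previous * (1 + 1e-8) + 1e-8:
            raise RuntimeError(
                f"objective increased ({previous:.6g} -> {current:.6g}): update bug"
            )
        trace.append(current)
        if connectivity_stop is not None:
            assign = np.argmax(H, axis=0)
            if np.array_equal(assign, last_assign):
                stable_sweeps += 1
                if stable_sweeps >= connectivity_stop:
                    converged = True
                    break
            else:
                stable_sweeps = 0
                last_assign = assign
        elif previous - current < tol * max(abs(previous), _EPS):
            converged = True
            break
    return NMFRun(W=W, H=H, objective_trace=trace, seed=seed, converged=converged)


def posneg_fold(Z: np.ndarray | pd.DataFrame):
    """Fold a real matrix into a non-negative one by doubling rows: for each
    row z, emit max(z, 0) and max(-z, 0). The sum of the two halves equals
    |z| elementwise, so no information is lost and no global shift is
    introduced."""
    if isinstance(Z, pd.DataFrame):
        pos = Z.clip(lower=0.0)
        neg = (-Z).clip(lower=0.0)
        pos.index = [f"{i}+" for i in Z.index]
        neg.index = [f"{i}-" for i in Z.index]
        return pd.concat([pos, neg], axis=0)
    Z = np.asarray(Z, dtype=float)
    return np.vstack([np.maximum(Z, 0.0), np.maximum(-Z, 0.0)])


def consensus_from_assignments(
    assignments: Iterable[np.ndarray],
) -> np.ndarray:
    """Co-clustering frequency matrix: entry (s, t) is the fraction of runs
    in which samples s and t share a cluster. Permutation-equivariant in the
    sample order of the assignment vectors."""
    assignments = [np.asarray(a) for a in assignments]
    if not assignments:
        raise ValueError("no assignments given")
    n = len(assignments[0])
    C = np.zeros((n, n))
    for a in assignments:
        if len(a) != n:
            raise ValueError("assignment vectors differ in length")
        C += a[:, None] == a[None, :]
    return C / len(assignments)


def cophenetic_coefficient(C: np.ndarray | pd.DataFrame) -> float:
    """Cophenetic correlation of a consensus matrix: Pearson correlation
    between the off-diagonal consensus dissimilarities (1 - C) and the
    cophenetic distances of their average-linkage hierarchical clustering.
    A constant dissimilarity structure is perfectly reproduced by the tree
    and scored 1."""
    arr = np.asarray(C, dtype=float)
    d = 1.0 - arr
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    cond = squareform(d, checks=False)
    if cond.std() == 0:
        return 1.0
    Z = linkage(cond, method="average")
    coeff, _ = cophenet(Z, cond)
    if np.isnan(coeff):
        return 0.0
    return float(coeff)


def consensus_cluster(
    X: np.ndarray | pd.DataFrame,
    ranks: Sequence[int] = (2, 3, 4, 5, 6),
    n_runs: int = 30,
    seed: int = 0,
    *,
    subsample: float | None = 0.8,
    max_iter: int = 600,
    tol: float = 1e-6,
    objective: str = "kl",
    connectivity_stop: int | None = None,
) -> SubtypingResult:
    """Consensus NMF over a range of ranks.

    For each rank, ``n_runs`` seeded factorizations are hard-assigned by
    coefficient argmax and summarized as a consensus matrix with its
    cophenetic coefficient. By default each run factorizes a random
    ``subsample`` fraction of the samples, and the consensus entry for a
    sample pair is its co-assignment frequency among the runs where both
    were drawn; perturbing the data is what exposes the instability of
    over-fitted ranks, which repeated restarts on the full matrix do not
    (``subsample=None`` restores plain restart consensus over all samples).
    Runs that leave a cluster empty are kept and logged. Deterministic
    given ``seed``.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if subsample is not None and not 0.0 < subsample <= 1.0:
        raise ValueError("subsample must be in (0, 1]")
    if isinstance(X, pd.DataFrame):
        sample_ids = X.columns
        arr = X.to_numpy(dtype=float)
        data = X
    else:
        arr = np.asarray(X, dtype=float)
        sample_ids = pd.RangeIndex(arr.shape[1])
        data = pd.DataFrame(arr, columns=sample_ids)
    n = arr.shape[1]
    n_sub = n if subsample is None else max(2, int(round(subsample * n)))

    root = np.random.SeedSequence(seed)
    rank_seqs = root.spawn(len(ranks))
    consensus: dict[int, pd.DataFrame] = {}
    cophenetic: dict[int, float] = {}
    for k, seq in zip(ranks, rank_seqs):
        run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seq.spawn(n_runs)]
        hits = np.zeros((n, n))
        drawn = np.zeros((n, n))
        for rs in run_seeds:
            if n_sub < n:
                idx = np.sort(np.random.default_rng(rs).choice(n, n_sub, replace=False))
            else:
                idx = np.arange(n)
            run = nmf_factorize(
                arr[:, idx], k, seed=rs, max_iter=max_iter, tol=tol,
                objective=objective, connectivity_stop=connectivity_stop,
            )
            a = run.assignments()
            if len(np.unique(a)) < k:
                logger.info("rank %d seed %d: run produced an empty cluster", k, rs)
            drawn[np.ix_(idx, idx)] += 1
            hits[np.ix_(idx, idx)] += a[:, None] == a[None, :]
        with np.errstate(invalid="ignore"):
            C = np.where(drawn > 0, hits / np.maximum(drawn, 1), 0.0)
        np.fill_diagonal(C, 1.0)
        consensus[k] = pd.DataFrame(C, index=sample_ids, columns=sample_ids)
        cophenetic[k] = cophenetic_coefficient(C)
    return SubtypingResult(
        consensus=consensus,
        cophenetic=cophenetic,
        ranks=list(ranks),
        data=data,
        seed=seed,
        n_runs=n_runs,
    )


def select_rank(rho: Mapping[int, float]) -> int:
    """Rank selection by the cophenetic-drop rule: the highest rank before
    the largest decrease of the cophenetic coefficient, i.e. the k
    maximizing rho[k] - rho[k+1] over consecutive rank pairs. Ties break
    toward the smaller k."""
    ranks = sorted(rho)
    if len(ranks) < 2:
        raise ValueError("need at least two consecutive ranks")
    pairs = [(k, rho[k] - rho[k + 1]) for k in ranks[:-1] if k + 1 in rho]
    if not pairs:
        raise ValueError("ranks are not consecutive")
    drops = [d for _, d in pairs]
    return pairs[int(np.argmax(drops))][0]  # argmax takes the first maximum


def assign_and_name(
    result: SubtypingResult,
    im: InfiltrationMatrix,
    *,
    groups: Mapping[str, Sequence[str]] | None = None,
    rank: int | None = None,
) -> SubtypingResult:
    """Final per-sample assignment and phenotype naming.

    Labels come from the coefficient argmax of the best-objective run at the
    selected rank. With exactly 3 clusters, the cluster with the highest
    mean activated-adaptive aggregate score is named immune-active, the
    highest stromal aggregate among the remaining is stroma-rich, and the
    last is immune-desert; if one cluster tops both aggregates it takes the
    label with the larger margin (logged). Any other rank gets generic
    ``cluster-i`` names.
    """
    k = rank if rank is not None else result.selected_rank
    if k is None:
        k = select_rank(result.cophenetic)
    if k not in result.best_runs:
        if result.data is None:
            raise ValueError(f"no factorization stored for rank {k} and no data kept")
        # final assignment: best-objective of n_runs full-cohort factorizations
        arr = result.data.to_numpy(dtype=float)
        seqs = np.random.SeedSequence([result.seed, k]).spawn(result.n_runs)
        runs = [
            nmf_factorize(arr, k, seed=int(s.generate_state(1)[0] % (2**31)))
            for s in seqs
        ]
        result.best_runs[k] = min(runs, key=lambda r: r.objective_trace[-1])
    run = result.best_runs[k]
    sample_ids = result.consensus[k].index
    labels = pd.Series(run.assignments() + 1, index=sample_ids, name="cluster")

    result.selected_rank = k
    result.labels = labels
    if k != 3:
        result.cluster_names = {c: f"cluster-{c}" for c in range(1, k + 1)}
        result.phenotypes = labels.map(result.cluster_names).rename("phenotype")
        return result

    groups = default_cell_groups() if groups is None else groups
    z = im.scores if im.normalized else normalize_scores(im).scores
    z = z.reindex(columns=sample_ids)

    def group_mean(group: str) -> pd.Series:
        members = [c for c in groups[group] if c in z.index]
        if not members:
            raise ValueError(f"no cell types of group {group!r} present in scores")
        return z.loc[members].mean(axis=0)

    act = group_mean("activated_adaptive").groupby(labels).mean()
    stro = group_mean("stromal").groupby(labels).mean()

    act_sorted = act.sort_values(ascending=False)
    stro_sorted = stro.sort_values(ascending=False)
    act_top = act_sorted.index[0]
    stro_top = stro_sorted.index[0]
    names: dict[int, str] = {}
    if act_top == stro_top:
        act_margin = act_sorted.iloc[0] - act_sorted.iloc[1]
        stro_margin = stro_sorted.iloc[0] - stro_sorted.iloc[1]
        logger.warning(
            "cluster %s tops both aggregates (margins: activated %.3f, stromal %.3f)",
            act_top, act_margin, stro_margin,
        )
        if act_margin >= stro_margin:
            names[act_top] = "immune-active"
            names[stro_sorted.index[1]] = "stroma-rich"
        else:
            names[stro_top] = "stroma-rich"
            names[act_sorted.index[1]] = "immune-active"
    else:
        names[act_top] = "immune-active"
        remaining_stro = stro.drop(index=act_top).sort_values(ascending=False)
        names[remaining_stro.index[0]] = "stroma-rich"
    leftover = [c for c in act.index if c not in names]
    names[leftover[0]] = "immune-desert"

    result.cluster_names = names
    result.phenotypes = labels.map(names).rename("phenotype")
    return result


@dataclass
class PseudoBulkMatrix:
    """Gene x sample summed UMI counts with per-sample cell counts."""

    values: pd.DataFrame
    cells_per_sample: pd.Series

    def mean_expression(self) -> ExpressionMatrix:
        """Per-sample mean counts (sum / number of cells), raw scale, ready
        for the log-CPM transform."""
        avg = self.values.div(self.cells_per_sample, axis=1)
        return ExpressionMatrix(avg, log_scale=False)


def pseudobulk_aggregate(
    counts: pd.DataFrame,
    cell_meta: pd.DataFrame,
    min_total_reads: int = 50,
) -> PseudoBulkMatrix:
    """Sum single-cell UMI counts to sample-level pseudo-bulk.

    ``counts`` is genes x cells; ``cell_meta`` must map every cell id to a
    ``sample_id``. Genes whose grand total across samples is below
    ``min_total_reads`` (default 50) are removed after summation.
    """
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("single-cell counts must be integers")
        arr = arr.astype(np.int64)
    if (arr < 0).any():
        raise ValueError("single-cell counts must be non-negative")
    meta = cell_meta.set_index("cell_id") if "cell_id" in cell_meta.columns else cell_meta
    unknown = [c for c in counts.columns if c not in meta.index]
    if unknown:
        raise ValueError(f"cell(s) with no sample id in metadata: {unknown[:5]}")
    samples = meta.loc[counts.columns, "sample_id"]
    sums = (
        pd.DataFrame(arr, index=counts.index, columns=counts.columns)
        .T.groupby(samples.values, sort=False)
        .sum()
        .T
    )
    cells = samples.groupby(samples.values, sort=False).size()
    keep = sums.sum(axis=1) >= min_total_reads
    return PseudoBulkMatrix(values=sums.loc[keep], cells_per_sample=cells)


def read_single_cell(
    mtx_path: str | Path,
    genes_path: str | Path,
    meta_path: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a MatrixMarket genes x cells count matrix with its gene list and
    cell metadata (columns cell_id, sample_id, optional cell_type)."""
    from scipy.io import mmread

    mat = mmread(str(mtx_path)).toarray().astype(np.int64)
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].tolist()
    meta = pd.read_csv(meta_path, sep="\t")
    counts = pd.DataFrame(mat, index=genes, columns=meta["cell_id"].tolist())
    return counts, meta


def phenotype_pipeline(
    expr: ExpressionMatrix,
    sig,
    *,
    alpha: float = 0.25,
    ranks: Sequence[int] = (2, 3, 4, 5, 6),
    n_runs: int = 30,
    seed: int = 0,
    batch_adjust: bool = True,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> tuple[InfiltrationMatrix, SubtypingResult]:
    """End-to-end phenotyping: optional batch calibration, ssGSEA scoring,
    normalization, pos/neg folding, consensus NMF, rank selection and
    cluster naming. Returns the raw infiltration matrix and the named
    subtyping result."""
    from .infiltration import ssgsea_score
    from .io_preprocess import combat_adjust

    if batch_adjust and expr.batch is not None and expr.batch.nunique() > 1:
        expr = combat_adjust(expr)
    im = ssgsea_score(expr, sig, alpha=alpha)
    # clustering uses the TME cell-type signatures only; auxiliary sets
    # (ESTIMATE-style unions, exhaustion) are characterization scores
    cell_sets = [n for n in im.scores.index if sig.provenance.get(n) == "TME-cell"]
    im_cells = InfiltrationMatrix(im.scores.loc[cell_sets])
    scaled = normalize_scores(im_cells)
    folded = posneg_fold(scaled.scores)
    result = consensus_cluster(folded, ranks=ranks, n_runs=n_runs, seed=seed)
    result.selected_rank = select_rank(result.cophenetic)
    result = assign_and_name(result, im, groups=groups)
    return im, result
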