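"""Per-sample genomic scoring and burden-adjusted differential genomics.

Scores: mutation load log2(n + 1), SCNV load (% altered cytobands),
cytolytic activity (geometric mean of GZMA and PRF1), and TCR/BCR repertoire
diversity (richness, Shannon entropy, evenness).

Differential testing between two immune subtypes models the subtype as a
logistic function of the per-sample burden plus the per-gene event
indicator, so that a gene is called differential only if it separates the
subtypes beyond what their overall mutation (or CNV) burden difference
already explains. Genes with an overall event rate below 2.5% are excluded
up front. For CNV comparisons, gains/amplifications and losses/deletions
are tested separately with opposite-direction calls zeroed out.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import entropy
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "mutation_load",
    "scnv_load",
    "cyt_score",
    "repertoire_diversity",
    "DifferentialResult",
    "burden_adjusted_test",
    "direction_events",
    "cnv_differential",
    "read_maf",
    "read_mutation_table",
    "read_cnv_table",
    "read_clonotypes",
    "kruskal_dunn",
]

logger = logging.getLogger(__name__)

#: MAF Variant_Classification values counted as non-silent.
NONSILENT_CLASSES = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Nonstop_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "In_Frame_Del",
    "In_Frame_Ins",
    "Splice_Site",
    "Translation_Start_Site",
)

CNV_LEVELS = (-2, -1, 0, 1, 2)


def mutation_load(n_nonsilent):
    """Mutation load: log2(non-silent mutation count + 1). Accepts scalars
    or arrays of non-negative integers."""
    n = np.asarray(n_nonsilent)
    if (n < 0).any():
        raise ValueError("mutation count must be non-negative")
    out = np.log2(n + 1.0)
    return float(out) if np.isscalar(n_nonsilent) else out


def scnv_load(calls, *, deep_only: bool = False):
    """SCNV load: percentage of genomic units with a non-neutral call.

    ``calls`` is one sample's vector of thresholded calls in {-2..2}, or a
    samples x units DataFrame (returns a per-sample Series). "Altered"
    counts |call| >= 1 by default; ``deep_only`` restricts to |call| = 2.
    """
    if isinstance(calls, pd.DataFrame):
        return calls.apply(lambda row: scnv_load(row, deep_only=deep_only), axis=1)
    arr = np.asarray(calls)
    if arr.size == 0:
        raise ValueError("empty CNV call vector")
    if not np.isin(arr, CNV_LEVELS).all():
        raise ValueError("CNV calls must be in {-2, -1, 0, 1, 2}")
    altered = np.abs(arr) >= (2 if deep_only else 1)
    return 100.0 * altered.sum() / arr.size


def cyt_score(gzma, prf1, offset: float = 0.01):
    """Cytolytic activity: log2-scale geometric mean of GZMA and PRF1
    (linear-scale expression), i.e. 0.5 * (log2(gzma + o) + log2(prf1 + o)).
    The geometric mean itself is 2**score."""
    g = np.asarray(gzma, dtype=float)
    p = np.asarray(prf1, dtype=float)
    if (g < 0).any() or (p < 0).any():
        raise ValueError("expression values must be non-negative")
    out = 0.5 * (np.log2(g + offset) + np.log2(p + offset))
    return float(out) if out.ndim == 0 else out


def repertoire_diversity(counts) -> tuple[int, float, float]:
    """Clonotype diversity of one sample: (richness, Shannon entropy in
    nats, evenness = H / ln(richness), defined as 1 for a single
    clonotype)."""
    arr = np.asarray(list(counts) if not isinstance(counts, np.ndarray) else counts, dtype=float)
    if arr.size == 0:
        raise ValueError("at least one clonotype required")
    if (arr <= 0).any():
        raise ValueError("clonotype counts must be positive")
    richness = int(arr.size)
    h = float(entropy(arr))  # normalizes to probabilities internally
    evenness = 1.0 if richness == 1 else h / np.log(richness)
    return richness, h, evenness


@dataclass
class DifferentialResult:
    """Per-gene burden-adjusted comparison between two subtypes.

    ``table`` columns: coef (log-odds of the event term), p (Wald, or
    likelihood-ratio on non-convergence), q (BH), direction (+1 events
    enriched in ``group_b``), prevalence per group and overall, converged
    flag. Genes failing the prevalence filter are listed in ``excluded``.
    """

    table: pd.DataFrame
    group_a: str
    group_b: str
    excluded: list[str] = field(default_factory=list)

    def significant(self, alpha: float = 0.05, use_q: bool = False) -> pd.DataFrame:
        col = "q" if use_q else "p"
        return self.table[self.table[col] < alpha]


def _fit_gene_logit(y: np.ndarray, burden: np.ndarray | None, event: np.ndarray):
    """Logistic fit of subtype on (burden, event); returns
    (coef, p, converged)."""
    cols = [np.ones_like(event, dtype=float)]
    if burden is not None:
        cols.append(burden)
    cols.append(event.astype(float))
    Xd = np.column_stack(cols)
    model = sm.Logit(y, Xd)
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=100)
        converged = bool(res.mle_retvals.get("converged", True))
        coef = float(res.params[-1])
        pval = float(res.pvalues[-1])
        if not np.isfinite(pval) or abs(coef) > 15:
            converged = False
    except (PerfectSeparationError, np.linalg.LinAlgError):
        converged = False
        res = None
        coef = np.nan
    if not converged:
        # separation or a singular design: the Wald test collapses, fall
        # back to a likelihood-ratio p (gradient-based fits avoid the
        # singular Hessian); an unfittable gene gets p = 1
        from scipy.stats import chi2

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                null_res = sm.Logit(y, Xd[:, :-1]).fit(
                    disp=0, maxiter=200, method="bfgs"
                )
                full_llf = (
                    res.llf
                    if res is not None
                    else sm.Logit(y, Xd).fit(disp=0, maxiter=200, method="bfgs").llf
                )
            lr = max(2.0 * (full_llf - null_res.llf), 0.0)
            pval = float(chi2.sf(lr, df=1))
        except Exception:  # degenerate design even for the gradient fit
            pval = 1.0
        logger.info("non-convergent logistic fit; likelihood-ratio fallback p=%.3g", pval)
    return coef, pval, converged


def burden_adjusted_test(
    labels: pd.Series,
    events: pd.DataFrame,
    burden: pd.Series,
    min_prevalence: float = 0.025,
) -> DifferentialResult:
    """Burden-adjusted differential event test between two subtypes.

    For each gene/unit with overall event rate >= ``min_prevalence``, fits
    the logistic regression ``subtype ~ burden + event`` and reports the
    Wald p-value of the event coefficient (the paper-convention call is
    p < 0.05 unadjusted; BH q-values are reported alongside).

    ``labels`` must take exactly two values; ``events`` is samples x genes
    in {0, 1}; ``burden`` is the per-sample load covariate (dropped
    automatically if constant).
    """
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"exactly two subtypes required, got {list(groups)}")
    if not (0 < min_prevalence < 1):
        raise ValueError("min_prevalence must be in (0, 1)")
    events = events.loc[labels.index]
    ev_arr = events.to_numpy()
    if not np.isin(ev_arr, (0, 1)).all():
        raise ValueError("event indicators must be 0/1")
    burden = burden.loc[labels.index].astype(float)
    if not np.isfinite(burden).all():
        raise ValueError("burden must be finite")

    group_a, group_b = groups[0], groups[1]
    y = (labels == group_b).to_numpy(dtype=float)
    rate = events.mean(axis=0)
    keep = rate >= min_prevalence
    excluded = events.columns[~keep].tolist()

    b_arr = burden.to_numpy()
    if np.ptp(b_arr) == 0:
        b_use = None  # constant burden carries no information and breaks the design
    else:
        b_use = b_arr

    records = []
    for gene in events.columns[keep]:
        ev = events[gene].to_numpy()
        coef, pval, converged = _fit_gene_logit(y, b_use, ev)
        records.append(
            {
                "gene": gene,
                "coef": coef,
                "p": pval,
                "direction": int(np.sign(coef)) if np.isfinite(coef) else 0,
                f"prevalence_{group_a}": float(ev[y == 0].mean()),
                f"prevalence_{group_b}": float(ev[y == 1].mean()),
                "prevalence": float(ev.mean()),
                "converged": converged,
            }
        )
    table = pd.DataFrame(records).set_index("gene") if records else pd.DataFrame(
        columns=["coef", "p", "direction", "prevalence", "converged"]
    )
    if len(table):
        p_clipped = table["p"].clip(lower=np.nextafter(0, 1), upper=1.0)
        table["p"] = p_clipped
        table["q"] = multipletests(p_clipped.to_numpy(), method="fdr_bh")[1]
    return DifferentialResult(
        table=table, group_a=str(group_a), group_b=str(group_b), excluded=excluded
    )


def direction_events(cnv: pd.DataFrame, direction: str) -> pd.DataFrame:
    """Binary event matrix for one CNV direction: calls of 1/2 under
    ``gain_amp`` (or -1/-2 under ``loss_del``) become 1, everything else --
    including opposite-direction calls -- becomes 0."""
    if direction == "gain_amp":
        return (cnv > 0).astype(int)
    if direction == "loss_del":
        return (cnv < 0).astype(int)
    raise ValueError(f"direction must be 'gain_amp' or 'loss_del', got {direction!r}")


def cnv_differential(
    labels: pd.Series,
    cnv: pd.DataFrame,
    direction: str,
    min_prevalence: float = 0.025,
    *,
    deep_only_burden: bool = False,
) -> DifferentialResult:
    """Burden-adjusted CNV comparison between two subtypes for one
    direction. Events are direction-specific calls (opposite-direction
    calls set to zero); the adjustment covariate is each sample's SCNV
    load."""
    cnv = cnv.loc[labels.index]
    events = direction_events(cnv, direction)
    burden = scnv_load(cnv, deep_only=deep_only_burden)
    return burden_adjusted_test(labels, events, burden, min_prevalence=min_prevalence)


def read_maf(
    path: str | Path,
    nonsilent_classes: Sequence[str] = NONSILENT_CLASSES,
) -> tuple[pd.DataFrame, pd.Series]:
    """Minimal MAF reader: collapses (Tumor_Sample_Barcode, Hugo_Symbol,
    Variant_Classification) rows to a samples x genes 0/1 indicator matrix
    of non-silent mutation plus a per-sample non-silent count."""
    maf = pd.read_csv(path, sep="\t", comment="#")
    required = {"Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"}
    missing = required - set(maf.columns)
    if missing:
        raise ValueError(f"MAF is missing column(s): {sorted(missing)}")
    ns = maf[maf["Variant_Classification"].isin(nonsilent_classes)]
    counts = ns.groupby("Tumor_Sample_Barcode").size().rename("n_nonsilent")
    indicators = (
        ns.assign(v=1)
        .pivot_table(index="Tumor_Sample_Barcode", columns="Hugo_Symbol", values="v", fill_value=0)
        .astype(int)
    )
    indicators.index.name = "sample_id"
    return indicators, counts


def read_mutation_table(path: str | Path) -> pd.DataFrame:
    """Read a samples x genes 0/1 mutation indicator TSV."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    if not np.isin(table.to_numpy(), (0, 1)).all():
        raise ValueError("mutation indicators must be 0/1")
    return table.astype(int)


def read_cnv_table(path: str | Path) -> pd.DataFrame:
    """Read a samples x units thresholded CNV TSV with values in {-2..2}."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    if not np.isin(table.to_numpy(), CNV_LEVELS).all():
        raise ValueError("CNV calls must be in {-2, -1, 0, 1, 2}")
    return table.astype(int)


def read_clonotypes(path: str | Path) -> pd.DataFrame:
    """Read a long-format clonotype TSV (sample_id, clonotype_id, count)."""
    table = pd.read_csv(path, sep="\t")
    required = {"sample_id", "clonotype_id", "count"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"clonotype table missing column(s): {sorted(missing)}")
    if (table["count"] <= 0).any():
        raise ValueError("clonotype counts must be positive")
    return table


def kruskal_dunn(values: pd.Series, groups: pd.Series) -> tuple[float, pd.DataFrame]:
    """Kruskal-Wallis test across groups followed by Dunn's pairwise
    post-hoc z-tests (BH-adjusted). Intended for externally supplied
    per-sample columns (neoantigen load, CTA, HRD, ITH). Returns the
    Kruskal-Wallis p and a pairwise table."""
    from itertools import combinations

    from scipy.stats import kruskal, norm, rankdata, tiecorrect

    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g].dropna().to_numpy() for g in levels]
    kw_p = float(kruskal(*samples).pvalue)

    pooled = np.concatenate(samples)
    ranks = rankdata(pooled)
    n = len(pooled)
    tie = tiecorrect(ranks)
    splits = np.cumsum([len(s) for s in samples])[:-1]
    mean_ranks = [r.mean() for r in np.split(ranks, splits)]
    sizes = [len(s) for s in samples]
    rows = []
    for (i, a), (j, b) in combinations(enumerate(levels), 2):
        se = np.sqrt(tie * n * (n + 1) / 12.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        rows.append({"group_a": a, "group_b": b, "z": z, "p": 2 * norm.sf(abs(z))})
    pairwise = pd.DataFrame(rows)
    pairwise["q"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    return kw_p, pairwise
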