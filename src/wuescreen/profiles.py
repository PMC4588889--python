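"""Expression-profile characterization of candidate genes.

Fold changes compare the arithmetic mean FPKM at the semiarid site (QG) to
the native site (JH); on the log2 scale +1/-1 mark 2-fold up/down regulation.
Differential expression uses Welch's t-test when both site groups pass a
Shapiro-Wilk normality gate and the Wilcoxon rank-sum test otherwise, with
Benjamini-Hochberg control of the FDR across the tested gene set.  Profiles
are normalized by dividing each gene's FPKM vector by its pooled-sample
standard deviation (n-1 denominator) and grouped by average-linkage
agglomerative clustering under Pearson correlation distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionTable

_UNCHANGED_EPS = 1e-12  # |log2 ratio| below this is reported as 'unchanged'


@dataclass(frozen=True)
class FoldChangeRecord:
    gene_id: str
    mean_fpkm_jh: float
    mean_fpkm_qg: float
    ratio: float  # mean_QG / mean_JH; NaN when mean_JH == 0
    log2_ratio: float
    fc_class: str  # up2 / up / down / down2 / unchanged / undefined


def _fc_class(log2_ratio: float) -> str:
    if np.isnan(log2_ratio):
        return "undefined"
    if abs(log2_ratio) < _UNCHANGED_EPS:
        return "unchanged"
    if log2_ratio > 1.0:
        return "up2"
    if log2_ratio > 0.0:
        return "up"
    if log2_ratio >= -1.0:
        return "down"
    return "down2"


def fold_change(
    expr: ExpressionTable, genes: list[str] | None = None
) -> list[FoldChangeRecord]:
    """Per-gene QG/JH fold change of mean FPKM with 2-fold classification.

    Genes with zero mean at JH get an undefined ratio and are excluded from
    class counts downstream; a zero QG mean over a positive JH mean maps to
    log2 ratio of -inf and class ``down2``.
    """
    sub = expr if genes is None else expr.subset_genes(genes)
    jh = sub.values[sub.sample_ids("JH")].mean(axis=1)
    qg = sub.values[sub.sample_ids("QG")].mean(axis=1)
    out = []
    for gene in sub.gene_ids:
        mj, mq = float(jh.loc[gene]), float(qg.loc[gene])
        if mj == 0.0:
            ratio = log2 = float("nan")
        else:
            ratio = mq / mj
            log2 = np.log2(ratio) if ratio > 0 else float("-inf")
        out.append(FoldChangeRecord(gene, mj, mq, ratio, log2, _fc_class(log2)))
    return out


def fold_change_fractions(records: list[FoldChangeRecord]) -> dict[str, float]:
    """Percentages of up/down and >2-fold genes among defined-ratio records.

    'up' / 'down' aggregate all up- or down-regulated genes (any magnitude);
    'up2' / 'down2' count only those beyond 2-fold.
    """
    defined = [r for r in records if r.fc_class not in ("undefined", "unchanged")]
    n = len(defined)
    if n == 0:
        raise ValueError("no genes with a defined, non-tied fold change")
    count = lambda *classes: sum(r.fc_class in classes for r in defined)
    return {
        "up": 100.0 * count("up", "up2") / n,
        "down": 100.0 * count("down", "down2") / n,
        "up2": 100.0 * count("up2") / n,
        "down2": 100.0 * count("down2") / n,
    }


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    test_used: str  # "t" or "wilcoxon"
    raw_p: float
    adj_p: float
    direction: str  # up / down / none
    significant: bool


def de_test(
    expr: ExpressionTable,
    genes: list[str] | None = None,
    alpha_normality: float = 0.05,
    alpha: float = 0.05,
) -> list[DEResult]:
    """Site-contrast differential expression over a gene set.

    Per gene: Shapiro-Wilk on each site's FPKM; if both groups look normal
    (p >= ``alpha_normality``) a Welch two-sample t-test is used, otherwise
    the Wilcoxon rank-sum test.  Raw p-values are BH-adjusted across the
    tested set; direction is the sign of mean(QG) - mean(JH).
    """
    sub = expr if genes is None else expr.subset_genes(genes)
    jh_ids, qg_ids = sub.sample_ids("JH"), sub.sample_ids("QG")
    if len(jh_ids) < 3 or len(qg_ids) < 3:
        raise ValueError("need at least 3 samples per site")
    rows = []
    for gene in sub.gene_ids:
        a = sub.values.loc[gene, jh_ids].to_numpy(float)
        b = sub.values.loc[gene, qg_ids].to_numpy(float)
        if np.ptp(a) == 0.0 and np.ptp(b) == 0.0 and a[0] == b[0]:
            rows.append((gene, "t", 1.0, "none"))
            continue
        normal = _looks_normal(a, alpha_normality) and _looks_normal(b, alpha_normality)
        if normal:
            p = float(stats.ttest_ind(b, a, equal_var=False).pvalue)
            test = "t"
        else:
            p = float(stats.ranksums(b, a).pvalue)
            test = "wilcoxon"
        if np.isnan(p):
            p = 1.0
        diff = float(b.mean() - a.mean())
        direction = "up" if diff > 0 else "down" if diff < 0 else "none"
        rows.append((gene, test, p, direction))
    adj = multipletests([r[2] for r in rows], method="fdr_bh")[1]
    return [
        DEResult(gene, test, raw, float(q), direction, bool(q < alpha))
        for (gene, test, raw, direction), q in zip(rows, adj)
    ]


def _looks_normal(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0.0:
        return False  # constant group: Shapiro undefined, treat as non-normal
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(x).pvalue) >= alpha


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    return multipletests(np.asarray(p_values, float), method="fdr_bh")[1]


def normalize_profiles(
    expr: ExpressionTable, genes: list[str] | None = None, center: bool = False
) -> pd.DataFrame:
    """Scale each gene's FPKM vector by its pooled-sample SD (n-1 denominator).

    Mean-centering before scaling is optional and off by default.  Genes with
    zero SD carry no profile information and are dropped with a warning.
    """
    sub = expr if genes is None else expr.subset_genes(genes)
    values = sub.values.astype(float)
    sd = values.std(axis=1, ddof=1)
    flat = sd[sd == 0.0].index.tolist()
    if flat:
        warnings.warn(f"dropping constant-profile genes: {flat}", stacklevel=2)
        values = values.drop(index=flat)
        sd = sd.drop(index=flat)
    if center:
        values = values.sub(values.mean(axis=1), axis=0)
    return values.div(sd, axis=0)


@dataclass(frozen=True)
class ClusterAssignment:
    gene_id: str
    cluster_index: int  # 1..k


def hier_cluster(profiles: pd.DataFrame, k: int = 4) -> list[ClusterAssignment]:
    """Average-linkage hierarchical clustering under Pearson correlation
    distance d = 1 - r, cut into exactly ``k`` clusters.

    Deterministic for a fixed row order; distance ties are resolved by the
    merge order of the underlying linkage (lowest index first).  Constant
    rows have no defined correlation and are rejected.
    """
    if k < 1 or k > profiles.shape[0]:
        raise ValueError(f"k must be in 1..{profiles.shape[0]}")
    x = profiles.to_numpy(float)
    if (x.std(axis=1) == 0.0).any():
        raise ValueError("constant profile rows have undefined correlation distance")
    d = pdist(x, metric="correlation")
    labels = fcluster(linkage(d, method="average"), t=k, criterion="maxclust")
    return [
        ClusterAssignment(gene, int(lbl)) for gene, lbl in zip(profiles.index, labels)
    ]
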