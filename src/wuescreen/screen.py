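"""Cross-environment ratio matrices and the Spearman Mantel screen.

The screen asks, gene by gene, whether cross-site *plasticity* in expression
tracks cross-site plasticity in the trait.  For a quantity measured on n_QG
individuals at the stress site and n_JH individuals at the native site, the
ratio matrix holds every pairwise ratio QG_i / JH_j.  The trait (WUE) ratio
matrix is compared with each gene's FPKM ratio matrix by a Mantel-style
permutation test on the Spearman rank correlation of the flattened cells.

The null distribution is generated by relabeling one matrix's axes.  Because
rows and columns index *disjoint* sets of individuals, the default scheme
permutes rows and columns independently; a ``joint`` scheme (one shared
permutation on both axes, requiring a square matrix) is provided for
comparison with distance-matrix Mantel implementations.

Genes whose median FPKM over all samples is zero are removed before
screening; zero denominators in surviving genes are masked cells by default
(a pseudocount policy is available for heavily zero-inflated data).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionTable, TraitTable


class DegenerateGeneError(ValueError):
    """Raised when a gene's ratio matrix cannot support the test."""


@dataclass
class RatioMatrix:
    """All-pairs QG/JH ratio matrix for one quantity.

    ``values[i, j] = value(QG individual i) / value(JH individual j)``;
    ``mask`` is True where the cell is defined (nonzero denominator).
    """

    row_ids: list[str]  # QG individuals
    col_ids: list[str]  # JH individuals
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        expect = (len(self.row_ids), len(self.col_ids))
        if self.values.shape != expect or self.mask.shape != expect:
            raise ValueError("ratio matrix shape mismatch")

    @property
    def n_defined(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class ScreenConfig:
    """Settings of the permutation screen.

    n_perm=10000 and alpha=0.01 reproduce the published screening protocol;
    the smallest attainable p is 1/(n_perm+1).
    """

    n_perm: int = 10000
    alpha: float = 0.01
    tail: str = "upper"  # or "two_sided"
    permutation_scheme: str = "independent_rows_cols"  # or "joint"
    seed: int = 0
    zero_policy: str = "mask"  # or "pseudocount"
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.tail not in ("upper", "two_sided"):
            raise ValueError(f"unknown tail {self.tail!r}")
        if self.permutation_scheme not in ("independent_rows_cols", "joint"):
            raise ValueError(f"unknown scheme {self.permutation_scheme!r}")
        if self.zero_policy not in ("mask", "pseudocount"):
            raise ValueError(f"unknown zero_policy {self.zero_policy!r}")


@dataclass(frozen=True)
class ScreenResult:
    gene_id: str
    r: float  # NaN for degenerate genes
    p: float  # NaN for degenerate genes
    n_perm: int
    n_cells_used: int
    is_candidate: bool


def median_zero_filter(
    expr: ExpressionTable,
) -> tuple[ExpressionTable, list[str]]:
    """Drop genes whose median FPKM over all samples (both sites pooled) is 0.

    Returns the surviving table (gene order preserved) and the removed ids.
    """
    med = expr.values.median(axis=1)
    removed = list(expr.values.index[med == 0.0])
    kept = expr.values.loc[med != 0.0]
    return ExpressionTable(kept, list(expr.samples)), removed


def build_ratio_matrix(
    values_qg: np.ndarray,
    values_jh: np.ndarray,
    row_ids: list[str] | None = None,
    col_ids: list[str] | None = None,
    zero_policy: str = "mask",
    pseudocount: float = 0.5,
) -> RatioMatrix:
    """Build the all-pairs QG/JH ratio matrix for one quantity.

    Under the ``mask`` policy cells with a zero denominator are flagged
    undefined; under ``pseudocount`` every value gets ``pseudocount`` added to
    numerator and denominator and all cells are defined.
    """
    qg = np.asarray(values_qg, float)
    jh = np.asarray(values_jh, float)
    if qg.ndim != 1 or jh.ndim != 1:
        raise ValueError("inputs must be vectors")
    if (qg < 0).any() or (jh < 0).any():
        raise ValueError("ratio matrix inputs must be non-negative")
    row_ids = row_ids if row_ids is not None else [f"QG{i}" for i in range(len(qg))]
    col_ids = col_ids if col_ids is not None else [f"JH{j}" for j in range(len(jh))]
    if zero_policy == "pseudocount":
        if pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        qg = qg + pseudocount
        jh = jh + pseudocount
        mask = np.ones((len(qg), len(jh)), bool)
        values = qg[:, None] / jh[None, :]
    else:
        mask = np.broadcast_to(jh[None, :] != 0.0, (len(qg), len(jh))).copy()
        with np.errstate(divide="ignore", invalid="ignore"):
            values = qg[:, None] / np.where(jh == 0.0, np.nan, jh)[None, :]
        values = np.where(mask, values, np.nan)
    if not mask.any():
        raise DegenerateGeneError("gene unusable: all ratio cells undefined")
    return RatioMatrix(row_ids, col_ids, values, mask)


def _check_aligned(m1: RatioMatrix, m2: RatioMatrix) -> None:
    if m1.row_ids != m2.row_ids or m1.col_ids != m2.col_ids:
        raise ValueError("ratio matrices must share row/col individual order")


def _spearman_flat(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rho of two 1-D vectors (average ranks for ties)."""
    ra = rankdata(a)
    rb = rankdata(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = math.sqrt((ra @ ra) * (rb @ rb))
    if denom == 0.0:
        raise DegenerateGeneError("degenerate gene: zero rank variance")
    return float((ra @ rb) / denom)


def mantel_spearman(
    m1: RatioMatrix, m2: RatioMatrix, config: ScreenConfig, rng: np.random.Generator | None = None
) -> tuple[float, float]:
    """Spearman Mantel test between two aligned ratio matrices.

    Only cells defined in *both* matrices are used.  ``m2`` is the matrix
    whose axes are relabeled to generate the null; with the trait matrix as
    ``m1`` and a gene matrix as ``m2``, positive r means the gene's
    expression plasticity tracks trait plasticity.

    Returns (r, p) with the add-one permutation p-value
    ``p = (1 + #{r_perm >= r_obs}) / (n_perm + 1)`` for the upper tail
    (absolute values for ``two_sided``).
    """
    _check_aligned(m1, m2)
    if config.permutation_scheme == "joint" and len(m1.row_ids) != len(m1.col_ids):
        raise ValueError("joint permutation scheme needs a square matrix")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    joint = m1.mask & m2.mask
    if joint.sum() < 3:
        raise DegenerateGeneError("fewer than 3 jointly defined cells")

    full = bool(joint.all())
    n_rows, n_cols = joint.shape
    r_obs = _spearman_flat(m1.values[joint], m2.values[joint])

    exceed = 0
    if full:
        # Fast path: with no masked cells a row/column relabeling of m2 only
        # permutes its (precomputed) ranks, so each permutation reduces to a
        # gather plus a dot product.
        r1 = _centered_unit_ranks(m1.values.ravel()).reshape(joint.shape)
        r2 = _centered_unit_ranks(m2.values.ravel()).reshape(joint.shape)
        stat = lambda rows, cols: float((r1 * r2[np.ix_(rows, cols)]).sum())
        s_obs = stat(np.arange(n_rows), np.arange(n_cols))
        for _ in range(config.n_perm):
            rows, cols = _draw_permutation(rng, n_rows, n_cols, config.permutation_scheme)
            s = stat(rows, cols)
            if _tail_hit(s, s_obs, config.tail):
                exceed += 1
    else:
        for _ in range(config.n_perm):
            rows, cols = _draw_permutation(rng, n_rows, n_cols, config.permutation_scheme)
            m = m1.mask & m2.mask[np.ix_(rows, cols)]
            if m.sum() < 3:
                continue  # conservatively not counted as an exceedance
            v2 = m2.values[np.ix_(rows, cols)]
            try:
                s = _spearman_flat(m1.values[m], v2[m])
            except DegenerateGeneError:
                continue
            if _tail_hit(s, r_obs, config.tail):
                exceed += 1
    p = (1 + exceed) / (config.n_perm + 1)
    return r_obs, p


def mantel_spearman_exact(
    m1: RatioMatrix, m2: RatioMatrix, tail: str = "upper", max_relabelings: int = 50000
) -> tuple[float, float]:
    """Exact Mantel p by exhaustive enumeration of all row x column
    relabelings of ``m2`` (n_rows! x n_cols! pairs, identity included).

    Only practical for tiny matrices; used as the oracle for the sampled test.
    """
    _check_aligned(m1, m2)
    joint = m1.mask & m2.mask
    if not joint.all():
        raise ValueError("exact enumeration requires fully defined matrices")
    n_rows, n_cols = joint.shape
    total = math.factorial(n_rows) * math.factorial(n_cols)
    if total > max_relabelings:
        raise ValueError(f"{total} relabelings exceed limit {max_relabelings}")
    r1 = _centered_unit_ranks(m1.values.ravel()).reshape(joint.shape)
    r2 = _centered_unit_ranks(m2.values.ravel()).reshape(joint.shape)
    r_obs = float((r1 * r2).sum())
    hits = 0
    for rows in itertools.permutations(range(n_rows)):
        sub = r2[list(rows), :]
        for cols in itertools.permutations(range(n_cols)):
            s = float((r1 * sub[:, list(cols)]).sum())
            if _tail_hit(s, r_obs, tail):
                hits += 1
    return r_obs, hits / total


def _centered_unit_ranks(v: np.ndarray) -> np.ndarray:
    """Ranks centered and scaled to unit norm, so the Spearman rho of two
    such vectors is their plain dot product."""
    r = rankdata(v)
    r = r - r.mean()
    norm = math.sqrt(r @ r)
    if norm == 0.0:
        raise DegenerateGeneError("degenerate gene: zero rank variance")
    return r / norm


def _draw_permutation(
    rng: np.random.Generator, n_rows: int, n_cols: int, scheme: str
) -> tuple[np.ndarray, np.ndarray]:
    if scheme == "joint":
        p = rng.permutation(n_rows)
        return p, p
    return rng.permutation(n_rows), rng.permutation(n_cols)


_TIE_EPS = 1e-12  # float-noise guard when comparing permuted statistics


def _tail_hit(s: float, s_obs: float, tail: str) -> bool:
    if tail == "two_sided":
        return abs(s) >= abs(s_obs) - _TIE_EPS
    return s >= s_obs - _TIE_EPS


def trait_ratio_matrix(
    expr: ExpressionTable, trait: TraitTable, config: ScreenConfig
) -> RatioMatrix:
    """Build the WUE ratio matrix over the expression table's samples."""
    qg_ids = expr.sample_ids("QG")
    jh_ids = expr.sample_ids("JH")
    missing = [s for s in qg_ids + jh_ids if s not in trait.values.index]
    if missing:
        raise ValueError(f"trait table missing samples: {missing}")
    return build_ratio_matrix(
        trait.wue(qg_ids), trait.wue(jh_ids), qg_ids, jh_ids,
        zero_policy=config.zero_policy, pseudocount=config.pseudocount,
    )


def screen_all_genes(
    expr: ExpressionTable, trait: TraitTable, config: ScreenConfig | None = None
) -> list[ScreenResult]:
    """Run the Mantel screen for every gene in ``expr``.

    ``expr`` should already be median-zero filtered.  The trait ratio matrix
    is built once; each gene draws its permutations from an independent
    substream of ``config.seed`` keyed by the gene's rank in the sorted id
    list, so per-gene results are identical whatever the row or processing
    order.  Degenerate genes (all-zero
    expression in one site, too few defined cells, tied ranks everywhere) are
    reported with r = p = NaN and never flagged as candidates.

    Results are sorted by descending r, degenerate genes last.
    """
    if config is None:
        config = ScreenConfig()
    trait_m = trait_ratio_matrix(expr, trait, config)
    qg_ids = trait_m.row_ids
    jh_ids = trait_m.col_ids
    qg_vals = expr.values[qg_ids].to_numpy(float)
    jh_vals = expr.values[jh_ids].to_numpy(float)

    substream = {g: k for k, g in enumerate(sorted(expr.gene_ids))}
    results: list[ScreenResult] = []
    for idx, gene in enumerate(expr.gene_ids):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(substream[gene],))
        )
        try:
            gene_m = build_ratio_matrix(
                qg_vals[idx], jh_vals[idx], qg_ids, jh_ids,
                zero_policy=config.zero_policy, pseudocount=config.pseudocount,
            )
            r, p = mantel_spearman(trait_m, gene_m, config, rng=rng)
            n_used = int((trait_m.mask & gene_m.mask).sum())
            results.append(
                ScreenResult(gene, r, p, config.n_perm, n_used, bool(p < config.alpha))
            )
        except DegenerateGeneError:
            results.append(
                ScreenResult(gene, float("nan"), float("nan"), config.n_perm, 0, False)
            )
    results.sort(
        key=lambda s: (math.isnan(s.r), -s.r if not math.isnan(s.r) else 0.0, s.gene_id)
    )
    return results


def results_to_frame(results: list[ScreenResult]) -> pd.DataFrame:
    cols = ["gene_id", "r", "p", "n_perm", "n_cells_used", "is_candidate"]
    return pd.DataFrame(
        [[getattr(s, c) for c in cols] for s in results], columns=cols
    )
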