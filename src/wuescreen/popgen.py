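"""Nucleotide diversity and genotype x environment analysis.

Haplotypes — the concatenated alleles at a gene's SNP positions — are treated
as alleles, and an individual's genotype is its unordered haplotype pair.
Nucleotide diversity uses the small-sample-corrected (Nei) estimator

    pi = n/(n-1) * sum_{i<j} 2 x_i x_j d_ij / L

with x_i the haplotype frequencies among the n = 2N copies carried by the
individuals considered, d_ij the number of differing SNP positions, and L the
transcript length in bp (per-base scaling; per-SNP scaling available).

Expression variation across the two field sites is partitioned by a two-step
two-way fixed-effects ANOVA on FPKM: the full model
FPKM ~ genotype + environment + genotype:environment is fitted first (type-II
sums of squares, the genotype groups being unbalanced across sites); if the
interaction is not significant the additive model is refitted and the gene is
classified by its main effects.  Only genotype groups carried by at least
``min_n`` individuals (default 3) enter the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import ExpressionTable

ANOVA_CLASSES = ("none", "E", "G", "G+E", "GEI")


@dataclass
class GenotypePanel:
    """Per-gene haplotype pairs for a set of individuals.

    ``genotypes`` maps individual id -> unordered haplotype pair (stored
    sorted); every haplotype is a string with one character per SNP position.
    """

    gene_id: str
    transcript_length: int
    snp_positions: list[int]
    genotypes: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        if self.transcript_length <= 0:
            raise ValueError("transcript_length must be > 0")
        n_snp = len(self.snp_positions)
        fixed = {}
        for ind, pair in self.genotypes.items():
            h1, h2 = pair
            if len(h1) != n_snp or len(h2) != n_snp:
                raise ValueError(
                    f"{self.gene_id}/{ind}: haplotype length != #SNPs ({n_snp})"
                )
            fixed[ind] = tuple(sorted((h1, h2)))
        self.genotypes = fixed

    def haplotype_copies(self, individuals: Iterable[str] | None = None) -> list[str]:
        inds = self.genotypes if individuals is None else individuals
        copies: list[str] = []
        for ind in inds:
            h1, h2 = self.genotypes[ind]
            copies.extend((h1, h2))
        return copies


def _hamming(a: str, b: str) -> int:
    return sum(c1 != c2 for c1, c2 in zip(a, b))


def nucleotide_diversity(
    panel: GenotypePanel,
    individuals: Iterable[str] | None = None,
    per_bp: bool = True,
) -> float:
    """Nei nucleotide diversity over the haplotype copies of ``individuals``
    (all individuals in the panel by default, e.g. those of one site).

    With ``per_bp`` (default) the average pairwise difference is divided by
    the transcript length; otherwise by the number of SNP positions.
    """
    copies = panel.haplotype_copies(individuals)
    n = len(copies)
    if n < 2:
        raise ValueError("need at least 2 haplotype copies")
    L = panel.transcript_length if per_bp else len(panel.snp_positions)
    if L <= 0:
        raise ValueError("zero-length scaling denominator")
    haps, counts = np.unique(copies, return_counts=True)
    x = counts / n
    acc = 0.0
    for i in range(len(haps)):
        for j in range(i + 1, len(haps)):
            acc += 2.0 * x[i] * x[j] * _hamming(haps[i], haps[j])
    return (n / (n - 1)) * acc / L


@dataclass(frozen=True)
class GxEResult:
    gene_id: str
    p_G: float
    p_E: float
    p_GEI: float
    model_used: str  # "full" or "additive"
    anova_class: str  # one of ANOVA_CLASSES
    genotypes_used: tuple[tuple[str, int, int], ...]  # (genotype key, n_JH, n_QG)


@dataclass
class GenotypeGrouping:
    """Retained genotype groups for one gene: genotype key -> individual ids."""

    gene_id: str
    groups: dict[str, list[str]]
    dropped: dict[str, list[str]]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def genotype_of(self) -> dict[str, str]:
        return {ind: key for key, inds in self.groups.items() for ind in inds}


class InsufficientGenotypesError(ValueError):
    """Gene lacks >= 2 genotype groups of the required size."""


def group_genotypes(
    panel: GenotypePanel,
    individuals: Iterable[str] | None = None,
    min_n: int = 3,
) -> GenotypeGrouping:
    """Group individuals by identical unordered haplotype pair and retain only
    groups with at least ``min_n`` members.

    Raises :class:`InsufficientGenotypesError` when fewer than two groups
    survive, in which case the gene cannot enter the G x E ANOVA.
    """
    inds = list(panel.genotypes if individuals is None else individuals)
    by_key: dict[str, list[str]] = {}
    for ind in inds:
        h1, h2 = panel.genotypes[ind]
        by_key.setdefault(f"{h1}/{h2}", []).append(ind)
    groups = {k: v for k, v in sorted(by_key.items()) if len(v) >= min_n}
    dropped = {k: v for k, v in sorted(by_key.items()) if len(v) < min_n}
    if len(groups) < 2:
        raise InsufficientGenotypesError(
            f"{panel.gene_id}: only {len(groups)} genotype group(s) with n >= {min_n}"
        )
    return GenotypeGrouping(panel.gene_id, groups, dropped)


def genotype_means(
    grouping: GenotypeGrouping, values: pd.Series, site_of: Mapping[str, str]
) -> pd.DataFrame:
    """Per-genotype mean FPKM per site (the reaction-norm endpoints)."""
    rows = []
    for key, inds in grouping.groups.items():
        for site in ("JH", "QG"):
            sub = [i for i in inds if site_of[i] == site]
            rows.append(
                (key, site, len(sub), float(values.loc[sub].mean()) if sub else np.nan)
            )
    return pd.DataFrame(rows, columns=["genotype", "site", "n", "mean_fpkm"])


def gxe_anova(
    values: pd.Series,
    grouping: GenotypeGrouping,
    site_of: Mapping[str, str],
    alpha: float = 0.05,
    log_transform: bool = False,
) -> GxEResult:
    """Two-step genotype/environment ANOVA for one gene.

    ``values`` holds the gene's FPKM indexed by individual id (raw scale by
    default).  Step 1 fits the full two-way model with interaction; if the
    interaction is significant at ``alpha`` the gene is classified GEI.
    Otherwise the additive model is refitted and the gene is classified G+E,
    G, E or none from its main effects.  An empty genotype x site cell makes
    the interaction inestimable; the gene then falls back to the additive
    model with a warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    genotype_of = grouping.genotype_of()
    inds = [i for inds in grouping.groups.values() for i in inds]
    df = pd.DataFrame(
        {
            "x": values.loc[inds].to_numpy(float),
            "genotype": [genotype_of[i] for i in inds],
            "site": [site_of[i] for i in inds],
        }
    )
    if log_transform:
        df["x"] = np.log(df["x"] + 1.0)
    counts = df.groupby(["genotype", "site"], observed=True).size().unstack(fill_value=0)
    for site in ("JH", "QG"):
        if site not in counts.columns:
            counts[site] = 0
    used = tuple(
        (g, int(counts.loc[g, "JH"]), int(counts.loc[g, "QG"])) for g in sorted(grouping.groups)
    )

    if float(np.var(df["x"].to_numpy())) == 0.0:
        return GxEResult(grouping.gene_id, 1.0, 1.0, 1.0, "additive", "none", used)

    p_gei = np.nan
    full_ok = (counts[["JH", "QG"]].to_numpy() > 0).all()
    if full_ok:
        fit = smf.ols("x ~ C(genotype) * C(site)", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        p_gei = float(tab.loc["C(genotype):C(site)", "PR(>F)"])
        if np.isnan(p_gei):
            full_ok = False  # saturated/deficient fit: interaction inestimable
    else:
        warnings.warn(
            f"{grouping.gene_id}: empty genotype x site cell, "
            "falling back to the additive model",
            stacklevel=2,
        )

    if full_ok and p_gei < alpha:
        p_g = float(tab.loc["C(genotype)", "PR(>F)"])
        p_e = float(tab.loc["C(site)", "PR(>F)"])
        return GxEResult(grouping.gene_id, p_g, p_e, p_gei, "full", "GEI", used)

    fit = smf.ols("x ~ C(genotype) + C(site)", data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    p_g = float(tab.loc["C(genotype)", "PR(>F)"])
    p_e = float(tab.loc["C(site)", "PR(>F)"])
    p_g = 1.0 if np.isnan(p_g) else p_g
    p_e = 1.0 if np.isnan(p_e) else p_e
    sig_g, sig_e = p_g < alpha, p_e < alpha
    cls = "G+E" if (sig_g and sig_e) else "G" if sig_g else "E" if sig_e else "none"
    return GxEResult(grouping.gene_id, p_g, p_e, p_gei, "additive", cls, used)


def classify_gene_set(results: Iterable[GxEResult]) -> dict[str, object]:
    """Tally ANOVA classes over a gene set; order-invariant.

    Returns ``{"counts": {class: int}, "members": {class: sorted gene ids}}``
    with every class present even when empty.
    """
    results = list(results)
    if not results:
        raise ValueError("empty result set")
    counts = {c: 0 for c in ANOVA_CLASSES}
    members: dict[str, list[str]] = {c: [] for c in ANOVA_CLASSES}
    for r in results:
        counts[r.anova_class] += 1
        members[r.anova_class].append(r.gene_id)
    return {"counts": counts, "members": {c: sorted(m) for c, m in members.items()}}


def read_haplotype_panels(path: str | Path) -> dict[str, GenotypePanel]:
    """Read haplotype panels from TSV with columns gene_id, individual_id,
    hap1, hap2, transcript_length, snp_positions (comma-separated)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    panels: dict[str, GenotypePanel] = {}
    for gene, sub in df.groupby("gene_id", sort=False):
        lengths = sub["transcript_length"].astype(int).unique()
        positions = sub["snp_positions"].unique()
        if len(lengths) != 1 or len(positions) != 1:
            raise ValueError(f"{gene}: inconsistent length/positions across rows")
        snp_positions = [int(x) for x in positions[0].split(",")]
        genotypes = {
            row.individual_id: (row.hap1, row.hap2) for row in sub.itertuples(index=False)
        }
        panels[gene] = GenotypePanel(gene, int(lengths[0]), snp_positions, genotypes)
    return panels


def write_haplotype_panels(panels: Iterable[GenotypePanel], path: str | Path) -> None:
    rows = []
    for p in panels:
        pos = ",".join(str(x) for x in p.snp_positions)
        for ind, (h1, h2) in sorted(p.genotypes.items()):
            rows.append((p.gene_id, ind, h1, h2, p.transcript_length, pos))
    pd.DataFrame(
        rows,
        columns=["gene_id", "individual_id", "hap1", "hap2", "transcript_length", "snp_positions"],
    ).to_csv(path, sep="\t", index=False)
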