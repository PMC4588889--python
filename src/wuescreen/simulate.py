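"""Synthetic two-site expression/trait/genotype data generator.

The generator emulates the study design the screen was built for: 39
individuals per field site drawn from 14 source populations, log-normal FPKM
with additive genotype (G), environment (E) and genotype-by-environment (GE)
effects on the log scale, a WUE-like trait loaded on a designated causal gene
subset, and optional zero inflation so the median-zero filter and the
zero-denominator policy are exercised.

For gene g and individual i at site s the latent log expression is

    log x_gi = mu_g + G_g(genotype_gi) + E_g * 1[s=QG] + GE_g(genotype_gi) * 1[s=QG] + eps_gi

with G_g(.) ~ N(0, sigma_g^2) per genotype class, E_g ~ N(0, sigma_e^2),
GE_g(.) ~ N(0, sigma_gxe^2) and eps ~ N(0, sigma_noise^2).  FPKM is
exp(log x) with a ``zero_inflation`` fraction of entries zeroed uniformly at
random.  The trait of individual i is

    WUE_i = beta0 + effect_size * sum_{g causal} z_gi + N(0, sigma_trait^2)

where z_gi is the individual's latent log expression of causal gene g,
standardized over all individuals (both sites pooled), truncated to stay
positive.  Causal genes therefore carry trait signal through both their
environmental shift and their individual-level variation, which is exactly
the structure the ratio-matrix screen targets.

``causal_cor`` makes the causal genes co-expressed by routing that fraction
of their noise variance through a shared per-individual latent factor, the
way genes of one regulated pathway covary.  This is what creates a genuinely
strong per-gene trait association: with n_c independent causal genes each
gene's trait correlation is capped at 1/sqrt(n_c) no matter how large
``effect_size`` is, whereas co-expressed causal genes can individually
explain most of the trait variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ExpressionTable, SampleMeta, TraitTable
from .popgen import GenotypePanel

_HAP_ALPHABET = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the field design the screen assumes: 39 individuals per
    site, multiplicative environment shifts (sigma_e on the log scale), a
    handful of causal genes, and a baseline trait level in the range of
    leaf-level WUE (umol CO2 per mmol H2O).
    """

    n_genes: int
    n_per_site: int = 39
    n_causal: int = 10
    effect_size: float = 1.0
    sigma_g: float = 0.3
    sigma_e: float = 0.5
    sigma_gxe: float = 0.2
    sigma_noise: float = 0.5
    zero_inflation: float = 0.0
    n_genotypes_per_gene: int = 4
    seed: int = 0
    causal_cor: float = 0.0
    beta0: float = 3.6
    sigma_trait: float = 0.2
    n_populations: int = 14
    n_snps_per_gene: int = 6
    transcript_length: int = 1601

    def __post_init__(self) -> None:
        if self.n_per_site < 2:
            raise ValueError("n_per_site must be >= 2")
        if not 0 <= self.n_causal <= self.n_genes:
            raise ValueError("need 0 <= n_causal <= n_genes")
        for name in ("sigma_g", "sigma_e", "sigma_gxe", "sigma_noise", "sigma_trait"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.zero_inflation < 1.0:
            raise ValueError("zero_inflation must be in [0, 1)")
        if not 0.0 <= self.causal_cor <= 1.0:
            raise ValueError("causal_cor must be in [0, 1]")
        if self.n_genotypes_per_gene < 1:
            raise ValueError("n_genotypes_per_gene must be >= 1")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    causal_gene_ids: list[str]
    effect_class: dict[str, str]  # gene -> none / E / G / G+E / GEI
    genotype_assignments: pd.DataFrame  # genes x individuals, int class labels


def _effect_class(sigma_g: float, sigma_e: float, sigma_gxe: float) -> str:
    if sigma_gxe > 0:
        return "GEI"
    if sigma_g > 0 and sigma_e > 0:
        return "G+E"
    if sigma_g > 0:
        return "G"
    if sigma_e > 0:
        return "E"
    return "none"


def _sample_frame(config: SimConfig) -> list[SampleMeta]:
    samples = []
    for site in ("JH", "QG"):
        for i in range(config.n_per_site):
            pop = f"pop{(i % config.n_populations) + 1:02d}"
            samples.append(SampleMeta(f"{site}_{i + 1:02d}", site, pop))
    return samples


def _haplotype_pairs(n_classes: int, n_snps: int, rng: np.random.Generator):
    """Distinct unordered haplotype pairs, one per genotype class."""
    n_haps = 2
    while n_haps * (n_haps + 1) // 2 < n_classes:
        n_haps += 1
    haps: list[str] = []
    seen = set()
    while len(haps) < n_haps:
        h = "".join(rng.choice(_HAP_ALPHABET, size=n_snps))
        if h not in seen:
            seen.add(h)
            haps.append(h)
    pairs = [
        tuple(sorted((haps[a], haps[b])))
        for a in range(n_haps)
        for b in range(a, n_haps)
    ]
    order = rng.permutation(len(pairs))[:n_classes]
    return [pairs[k] for k in order]


def simulate(
    config: SimConfig,
) -> tuple[ExpressionTable, TraitTable, dict[str, GenotypePanel], SimTruth]:
    """Generate one synthetic dataset; bitwise reproducible for a fixed seed."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    samples = _sample_frame(config)
    sample_ids = [s.sample_id for s in samples]
    is_qg = np.array([s.site == "QG" for s in samples])
    n_ind = len(samples)
    gene_ids = [f"SIM{g + 1:05d}" for g in range(config.n_genes)]

    mu = rng.normal(2.5, 1.0, size=config.n_genes)
    env_shift = rng.normal(0.0, config.sigma_e, size=config.n_genes)
    genotype = rng.integers(0, config.n_genotypes_per_gene, size=(config.n_genes, n_ind))
    g_eff = rng.normal(0.0, config.sigma_g, size=(config.n_genes, config.n_genotypes_per_gene))
    ge_eff = rng.normal(0.0, config.sigma_gxe, size=(config.n_genes, config.n_genotypes_per_gene))
    eps = rng.normal(0.0, config.sigma_noise, size=(config.n_genes, n_ind))

    causal_idx = rng.choice(config.n_genes, size=config.n_causal, replace=False)
    causal_idx.sort()
    if config.causal_cor > 0 and config.n_causal and config.sigma_noise > 0:
        # co-expression: route part of the causal genes' noise variance
        # through a shared per-individual latent factor
        latent = rng.normal(0.0, config.sigma_noise, size=n_ind)
        eps[causal_idx] = (
            math.sqrt(config.causal_cor) * latent[None, :]
            + math.sqrt(1.0 - config.causal_cor) * eps[causal_idx]
        )

    rows = np.arange(config.n_genes)[:, None]
    log_x = (
        mu[:, None]
        + g_eff[rows, genotype]
        + env_shift[:, None] * is_qg[None, :]
        + ge_eff[rows, genotype] * is_qg[None, :]
        + eps
    )
    fpkm = np.exp(log_x)
    if config.zero_inflation > 0:
        fpkm = np.where(rng.random(fpkm.shape) < config.zero_inflation, 0.0, fpkm)

    trait = np.full(n_ind, config.beta0)
    if config.n_causal:
        z = log_x[causal_idx]
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1, keepdims=True)
        trait = trait + config.effect_size * z.sum(axis=0)
    trait = trait + rng.normal(0.0, config.sigma_trait, size=n_ind)
    trait = np.maximum(trait, 0.05)  # WUE is a positive ratio

    expr = ExpressionTable(
        pd.DataFrame(fpkm, index=gene_ids, columns=sample_ids), samples
    )
    trait_tab = TraitTable(pd.DataFrame({"wue": trait}, index=pd.Index(sample_ids, name="sample_id")))

    snp_positions = list(range(100, 100 + 10 * config.n_snps_per_gene, 10))
    panels: dict[str, GenotypePanel] = {}
    for g, gene in enumerate(gene_ids):
        pairs = _haplotype_pairs(config.n_genotypes_per_gene, config.n_snps_per_gene, rng)
        panels[gene] = GenotypePanel(
            gene,
            config.transcript_length,
            snp_positions,
            {sample_ids[i]: pairs[genotype[g, i]] for i in range(n_ind)},
        )

    cls = _effect_class(config.sigma_g, config.sigma_e, config.sigma_gxe)
    truth = SimTruth(
        causal_gene_ids=[gene_ids[i] for i in causal_idx],
        effect_class={g: cls for g in gene_ids},
        genotype_assignments=pd.DataFrame(genotype, index=gene_ids, columns=sample_ids),
    )
    return expr, trait_tab, panels, truth


def perturb_trait(trait: TraitTable, fraction: float, seed: int) -> TraitTable:
    """Permute a fraction of trait values among individuals within each site.

    Site membership is inferred from the 'JH'/'QG' prefix of the sample id
    when present; otherwise all samples are shuffled as one block.  With
    ``fraction=1`` this is the standard negative control: any trait-expression
    association within sites is destroyed while the between-site trait shift
    is preserved.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    values = trait.values.copy()
    ids = list(values.index)
    blocks: dict[str, list[str]] = {}
    for sid in ids:
        blocks.setdefault(sid.split("_")[0], []).append(sid)
    wue = values["wue"].copy()
    for _, members in sorted(blocks.items()):
        k = int(round(fraction * len(members)))
        if k < 2:
            continue
        chosen = rng.choice(len(members), size=k, replace=False)
        chosen.sort()
        picked = [members[i] for i in chosen]
        perm = rng.permutation(k)
        wue.loc[picked] = wue.loc[[picked[j] for j in perm]].to_numpy()
    values["wue"] = wue
    return TraitTable(values)


def simulate_class_panel(
    template: dict[str, int],
    n_per_site: int = 39,
    n_genotypes: int = 3,
    effect: float = 3.0,
    sigma_noise: float = 1.0,
    baseline: float = 20.0,
    seed: int = 0,
) -> tuple[ExpressionTable, dict[str, "GenotypeGrouping"], dict[str, str]]:
    """Simulate genes built to specified ANOVA classes, for classifier checks.

    ``template`` maps class name (none/E/G/G+E/GEI) to a gene count.  Effects
    are additive on the raw FPKM scale, matching the ANOVA that consumes
    them; GEI genes get crossing site effects of opposite sign per genotype.
    Returns the expression table, per-gene genotype groupings (all groups of
    size >= 3 by construction when n_per_site/n_genotypes >= 3) and the true
    class per gene.
    """
    from .popgen import GenotypeGrouping

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    samples = []
    for site in ("JH", "QG"):
        for i in range(n_per_site):
            samples.append(SampleMeta(f"{site}_{i + 1:02d}", site, f"pop{(i % 14) + 1:02d}"))
    sample_ids = [s.sample_id for s in samples]
    is_qg = np.array([s.site == "QG" for s in samples])
    n_ind = len(samples)

    gene_rows = []
    gene_ids: list[str] = []
    truth: dict[str, str] = {}
    groupings: dict[str, GenotypeGrouping] = {}
    counter = 0
    for cls in ("none", "E", "G", "G+E", "GEI"):
        for _ in range(template.get(cls, 0)):
            counter += 1
            gene = f"CLS{counter:03d}_{cls.replace('+', 'p')}"
            # balanced genotype layout so every group clears the n >= 3 rule
            geno = np.tile(np.arange(n_genotypes), math.ceil(n_ind / n_genotypes))[:n_ind]
            x = baseline + rng.normal(0.0, sigma_noise, size=n_ind)
            if cls in ("E", "G+E"):
                x = x + effect * is_qg
            if cls in ("G", "G+E"):
                x = x + effect * geno
            if cls == "GEI":
                # crossing reaction norms: site effect of opposite sign by genotype
                sign = np.where(geno % 2 == 0, 1.0, -1.0)
                x = x + effect * sign * is_qg
            x = np.maximum(x, 0.0)
            gene_rows.append(x)
            gene_ids.append(gene)
            truth[gene] = cls
            groups: dict[str, list[str]] = {}
            for i, sid in enumerate(sample_ids):
                groups.setdefault(f"g{geno[i]}", []).append(sid)
            groupings[gene] = GenotypeGrouping(gene, dict(sorted(groups.items())), {})
    expr = ExpressionTable(
        pd.DataFrame(np.array(gene_rows), index=gene_ids, columns=sample_ids), samples
    )
    return expr, groupings, truth
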