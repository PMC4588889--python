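"""Domain types and tabular I/O.

The study design this package serves compares two field sites: JH, near the
species' native wet habitat, and QG, the semiarid target site.  Expression is
bulk RNA-Seq quantified as FPKM (fragments per kilobase of exon per million
mapped fragments); the physiological trait is instantaneous water use
efficiency, WUE = A/E, the ratio of CO2 assimilation rate A (umol m-2 s-1) to
transpiration rate E (mmol m-2 s-1).

All tables are plain TSV/CSV: UTF-8, tab separated (CSV for the trait table),
'.' decimal, no quoting, first column ``gene_id`` for gene-indexed tables.
Lines starting with '#' are comments.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SITES = ("JH", "QG")

CATEGORIES = (
    "Photosynthesis",
    "StomatalRegulation",
    "AbioticStress",
    "ProteinMetabolism",
    "Others",
)


@dataclass(frozen=True)
class SampleMeta:
    """One sequenced individual: its id, field site and source population."""

    sample_id: str
    site: str
    population_id: str

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(
                f"sample {self.sample_id!r}: site must be one of {SITES}, "
                f"got {self.site!r}"
            )


@dataclass
class ExpressionTable:
    """Genes x samples FPKM matrix with per-sample site metadata.

    ``values`` is a DataFrame indexed by gene id with one column per sample,
    in the same order as ``samples``.
    """

    values: pd.DataFrame
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        self.values.index.name = "gene_id"
        if list(self.values.columns) != [s.sample_id for s in self.samples]:
            raise ValueError("column order must match sample metadata order")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        vals = self.values.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("non-finite FPKM values")
        if (vals < 0).any():
            raise ValueError("negative FPKM values")
        for site in SITES:
            if not any(s.site == site for s in self.samples):
                raise ValueError(f"no samples from site {site}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def sample_ids(self, site: str | None = None) -> list[str]:
        if site is None:
            return [s.sample_id for s in self.samples]
        return [s.sample_id for s in self.samples if s.site == site]

    def site_of(self) -> dict[str, str]:
        return {s.sample_id: s.site for s in self.samples}

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionTable":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in table: {missing}")
        return ExpressionTable(self.values.loc[list(gene_ids)], list(self.samples))


@dataclass
class TraitTable:
    """Per-sample trait values (WUE, umol CO2 per mmol H2O), optionally with
    the raw gas-exchange rates A and E."""

    values: pd.DataFrame  # index sample_id; columns: wue [, A, E]

    def __post_init__(self) -> None:
        if "wue" not in self.values.columns:
            raise ValueError("trait table needs a 'wue' column")
        wue = self.values["wue"].to_numpy(float)
        if not np.isfinite(wue).all() or (wue <= 0).any():
            raise ValueError("WUE values must be finite and > 0")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate sample ids in trait table")
        if {"A", "E"} <= set(self.values.columns):
            ratio = self.values["A"].to_numpy(float) / self.values["E"].to_numpy(float)
            if not np.allclose(ratio, wue, rtol=1e-9, atol=0.0):
                raise ValueError("wue column inconsistent with A/E")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def wue(self, sample_ids: Iterable[str] | None = None) -> np.ndarray:
        if sample_ids is None:
            return self.values["wue"].to_numpy(float)
        return self.values["wue"].loc[list(sample_ids)].to_numpy(float)


@dataclass(frozen=True)
class CandidateFixture:
    """One screened candidate gene with its published screen statistics."""

    gene_id: str
    coefficient: float
    p_value: float
    category: str
    de_direction: str = "none"  # up / down / none
    de_adj_p: float | None = None
    annotation: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.de_direction not in ("up", "down", "none"):
            raise ValueError(f"bad de_direction {self.de_direction!r}")


def read_expression_table(path: str | Path, meta_path: str | Path) -> ExpressionTable:
    """Read a genes x samples FPKM TSV plus a sample-metadata TSV.

    The expression file has a header of sample ids with first column
    ``gene_id``; the metadata file has columns sample_id, site, population_id.
    Every expression column must be described in the metadata; metadata rows
    for absent samples are ignored.  Sample order follows the expression file.
    """
    expr = pd.read_csv(path, sep="\t", comment="#", index_col="gene_id")
    meta = pd.read_csv(meta_path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "site", "population_id"}
    if not required <= set(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    meta = meta.set_index("sample_id")
    orphans = [c for c in expr.columns if c not in meta.index]
    if orphans:
        raise ValueError(f"samples missing from metadata: {orphans}")
    samples = [
        SampleMeta(c, meta.loc[c, "site"], meta.loc[c, "population_id"])
        for c in expr.columns
    ]
    expr = expr.astype(float)
    return ExpressionTable(expr, samples)


def write_expression_table(
    expr: ExpressionTable, path: str | Path, meta_path: str | Path
) -> None:
    _write_table(expr.values.reset_index(), path)
    meta = pd.DataFrame(
        [(s.sample_id, s.site, s.population_id) for s in expr.samples],
        columns=["sample_id", "site", "population_id"],
    )
    _write_table(meta, meta_path)


def read_trait_table(path: str | Path) -> TraitTable:
    """Read a per-sample trait CSV with columns sample_id, wue [, A, E]."""
    df = pd.read_csv(path, comment="#", index_col="sample_id")
    return TraitTable(df)


def write_trait_table(trait: TraitTable, path: str | Path) -> None:
    trait.values.rename_axis("sample_id").reset_index().to_csv(
        path, index=False, float_format="%.10g"
    )


def write_results(results, path: str | Path) -> None:
    """Write any tabular result set as TSV.

    Accepts a DataFrame or a sequence of dataclass records; column order is
    the DataFrame's (or the dataclass field order) and is stable across runs.
    Floats are rendered with 10 significant digits so a read-back round-trip
    is exact well beyond 1e-9.  Empty results are an error.
    """
    df = _as_frame(results)
    if df.shape[0] == 0:
        raise ValueError("refusing to write an empty result table")
    _write_table(df, path)


def _as_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    records = list(results)
    if records and hasattr(records[0], "__dataclass_fields__"):
        cols = list(records[0].__dataclass_fields__)
        return pd.DataFrame([[getattr(r, c) for c in cols] for r in records], columns=cols)
    return pd.DataFrame(records)


def _write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("wuescreen").joinpath("data", name))


def load_candidate_fixture() -> list[CandidateFixture]:
    """Load the packaged table of the 48 published WUE candidate genes.

    Each record carries the gene's Mantel coefficient and permutation P value,
    its functional category, and its differential-expression call between the
    two sites (15 genes significant at adjusted P < 0.05: 10 up, 5 down in QG
    relative to JH).  See the fixture file header for the category-name
    mapping and known id discrepancies.
    """
    df = pd.read_csv(_data_path("candidate_genes.tsv"), sep="\t", comment="#")
    df = df.where(df.notna(), None)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            CandidateFixture(
                gene_id=row.gene_id,
                coefficient=float(row.mantel_r),
                p_value=float(row.p_value),
                category=row.category,
                de_direction=row.de_direction,
                de_adj_p=None if row.de_adj_p is None else float(row.de_adj_p),
                annotation=row.annotation or "",
                note=row.note or "",
            )
        )
    if len(out) != 48:
        raise RuntimeError(f"candidate fixture corrupt: {len(out)} rows")
    return out


def load_genetic_variation_fixture() -> pd.DataFrame:
    """Load the packaged per-gene SNP/haplotype/genotype counts and per-site
    nucleotide diversity (pi x 1000) for the 19 candidates with SNPs."""
    return pd.read_csv(_data_path("genetic_variation.tsv"), sep="\t", comment="#")
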