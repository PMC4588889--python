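"""Summary statistics and plain-text reporting over screened candidates.

Aggregates a candidate set (packaged fixture records or screen output joined
with annotations) into the headline descriptive statistics of the study:
coefficient range, per-category mean Mantel coefficients, category fractions,
fold-change class fractions, per-category significant-up fractions, and the
correlation between fold change and screen coefficient.

Means are rounded half-up to 3 decimals and percentages to 2 decimals to
match conventional reporting; half-up (rather than banker's) rounding is
deliberate and only matters at exact .0005 boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import CATEGORIES, CandidateFixture
from .profiles import DEResult, FoldChangeRecord, fold_change_fractions


def round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SummaryReport:
    n_candidates: int
    coefficient_range: tuple[float, float]
    category_mean_r: dict[str, float]  # 3 decimals, half-up
    category_counts: dict[str, int]
    category_fractions: dict[str, float]  # percent, 2 decimals
    fc_range: tuple[float, float] | None = None
    fc_fractions: dict[str, float] | None = None  # percents up/down/up2/down2
    de_up_fraction_by_category: dict[str, float] | None = None
    fc_r_correlation: float | None = None


def summarize_candidates(
    candidates: Sequence[CandidateFixture],
    fold_changes: Sequence[FoldChangeRecord] | None = None,
    de: Sequence[DEResult] | None = None,
) -> SummaryReport:
    """Compute the summary statistics of a candidate set.

    ``candidates`` must carry coefficients and categories.  Differential-
    expression calls come from ``de`` when given, falling back to the
    candidates' own ``de_direction`` fields (as in the packaged fixture).
    Fold-change statistics are computed only when ``fold_changes`` is given.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate set")
    n = len(candidates)
    coeffs = np.array([c.coefficient for c in candidates])
    by_cat: dict[str, list[CandidateFixture]] = {c: [] for c in CATEGORIES}
    for c in candidates:
        by_cat[c.category].append(c)

    category_mean_r = {
        cat: round_half_up(float(np.mean([c.coefficient for c in members])), 3)
        for cat, members in by_cat.items()
        if members
    }
    category_counts = {cat: len(members) for cat, members in by_cat.items() if members}
    category_fractions = {
        cat: round_half_up(100.0 * cnt / n, 2) for cat, cnt in category_counts.items()
    }

    up_by_gene: dict[str, bool]
    if de is not None:
        up_by_gene = {r.gene_id: (r.significant and r.direction == "up") for r in de}
    else:
        up_by_gene = {c.gene_id: c.de_direction == "up" for c in candidates}
    de_up_fraction_by_category = {}
    for cat, members in by_cat.items():
        if not members:
            continue
        k = sum(up_by_gene.get(c.gene_id, False) for c in members)
        de_up_fraction_by_category[cat] = round_half_up(100.0 * k / len(members), 2)

    fc_range = fc_fractions = fc_r_correlation = None
    if fold_changes is not None:
        defined = [r for r in fold_changes if np.isfinite(r.ratio)]
        if defined:
            ratios = np.array([r.ratio for r in defined])
            fc_range = (round_half_up(float(ratios.min()), 2), round_half_up(float(ratios.max()), 2))
            fc_fractions = {
                k: round_half_up(v, 2) for k, v in fold_change_fractions(defined).items()
            }
            coeff_of = {c.gene_id: c.coefficient for c in candidates}
            paired = [(r.ratio, coeff_of[r.gene_id]) for r in defined if r.gene_id in coeff_of]
            if len(paired) >= 3:
                fc, rr = np.array(paired).T
                fc_r_correlation = round_half_up(float(np.corrcoef(fc, rr)[0, 1]), 3)

    return SummaryReport(
        n_candidates=n,
        coefficient_range=(float(coeffs.min()), float(coeffs.max())),
        category_mean_r=category_mean_r,
        category_counts=category_counts,
        category_fractions=category_fractions,
        fc_range=fc_range,
        fc_fractions=fc_fractions,
        de_up_fraction_by_category=de_up_fraction_by_category,
        fc_r_correlation=fc_r_correlation,
    )


def render_report(report: SummaryReport, path: str | Path) -> None:
    """Write the report as deterministic plain text with TSV-style sections;
    identical input produces identical bytes."""
    lines: list[str] = []
    lines.append("# Candidate-gene summary")
    lines.append(f"candidates\t{report.n_candidates}")
    lo, hi = report.coefficient_range
    lines.append(f"coefficient_range\t{lo:.3f}\t{hi:.3f}")
    lines.append("")
    lines.append("# Per-category mean screen coefficient")
    for cat in CATEGORIES:
        if cat in report.category_mean_r:
            lines.append(f"{cat}\t{report.category_mean_r[cat]:.3f}")
    lines.append("")
    lines.append("# Category composition (count, percent)")
    for cat in CATEGORIES:
        if cat in report.category_counts:
            lines.append(
                f"{cat}\t{report.category_counts[cat]}\t{report.category_fractions[cat]:.2f}"
            )
    lines.append("")
    lines.append("# Fold-change statistics (QG/JH)")
    if report.fc_range is not None and report.fc_fractions is not None:
        lines.append(f"fc_range\t{report.fc_range[0]:.2f}\t{report.fc_range[1]:.2f}")
        for key in ("up", "down", "up2", "down2"):
            lines.append(f"fc_percent_{key}\t{report.fc_fractions[key]:.2f}")
    else:
        lines.append("not computed")
    lines.append("")
    lines.append("# Significantly up-regulated fraction per category (percent)")
    if report.de_up_fraction_by_category:
        for cat in CATEGORIES:
            if cat in report.de_up_fraction_by_category:
                lines.append(f"{cat}\t{report.de_up_fraction_by_category[cat]:.2f}")
    else:
        lines.append("not computed")
    lines.append("")
    lines.append("# Fold-change vs coefficient correlation")
    if report.fc_r_correlation is not None:
        lines.append(f"fc_r_correlation\t{report.fc_r_correlation:.3f}")
    else:
        lines.append("not computed")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
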