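"""Cohort-level aggregation of per-genome enrichment verdicts.

Three summaries over a cohort of genomes:

* significance frequencies — how many genomes reject homogeneity of the
  2x26 category table at each p-value threshold;
* cumulative overrepresentation — per category, in how many genomes the
  indicator fell to the small (resp. large) cluster;
* per-phylum ratios — within each phylum retained by the >10-genome
  filter, the small-wins and large-wins counts per category on the
  tie-excluded denominator (genomes whose indicator pair is (0,0) for
  that category do not count toward either side), plus a cross-phylum
  consistency classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .cog_enrichment import COG_CATEGORIES

logger = logging.getLogger(__name__)


@dataclass
class GenomeVerdictRow:
    """One genome's contribution to cohort tallies."""

    genome_id: str
    phylum: str
    p_value: float
    indicators: dict[str, tuple[int, int]]  # category -> (indicator_small, indicator_large)

    def __post_init__(self) -> None:
        missing = set(COG_CATEGORIES) - set(self.indicators)
        if missing:
            raise ValueError(f"{self.genome_id}: missing indicator pairs for {sorted(missing)}")
        for cat, pair in self.indicators.items():
            if tuple(pair) not in {(1, 0), (0, 1), (0, 0)}:
                raise ValueError(f"{self.genome_id}: invalid indicator pair {pair} for {cat}")


def _pct(count: int, total: int) -> tuple[float, str]:
    """Percentage at 2 decimal places, numeric and formatted."""
    pct = round(100.0 * count / total, 2)
    return pct, f"{pct:.2f}%"


def significance_summary(
    rows: list[GenomeVerdictRow], thresholds: tuple[float, ...] = (0.05, 0.01)
) -> pd.DataFrame:
    """Count genomes below / at-or-above each chi-squared p threshold.

    One row per threshold with counts and frequencies (percent of the
    cohort, 2 decimal places).
    """
    if not rows:
        raise ValueError("empty cohort")
    n = len(rows)
    out = []
    for t in thresholds:
        below = sum(1 for r in rows if r.p_value < t)
        above = n - below
        pct_b, fmt_b = _pct(below, n)
        pct_a, fmt_a = _pct(above, n)
        out.append(
            {
                "threshold": t,
                "n_significant": below,
                "n_not_significant": above,
                "freq_significant_pct": pct_b,
                "freq_not_significant_pct": pct_a,
                "freq_significant": fmt_b,
                "freq_not_significant": fmt_a,
            }
        )
    return pd.DataFrame(out)


def cumulative_overrepresentation(rows: list[GenomeVerdictRow]) -> pd.DataFrame:
    """Cohort-wide per-category overrepresented-genome tallies.

    Per category: number of genomes whose indicator went to the small
    cluster, to the large cluster, or to neither (tie), with frequencies
    over the cohort size.
    """
    if not rows:
        raise ValueError("empty cohort")
    n = len(rows)
    out = []
    for cat in COG_CATEGORIES:
        n_small = sum(r.indicators[cat][0] for r in rows)
        n_large = sum(r.indicators[cat][1] for r in rows)
        n_tie = n - n_small - n_large
        pct_s, fmt_s = _pct(n_small, n)
        pct_l, fmt_l = _pct(n_large, n)
        out.append(
            {
                "category": cat,
                "n_small": n_small,
                "n_large": n_large,
                "n_tie": n_tie,
                "freq_small_pct": pct_s,
                "freq_large_pct": pct_l,
                "freq_small": fmt_s,
                "freq_large": fmt_l,
            }
        )
    return pd.DataFrame(out)


def phylum_ratios(rows: list[GenomeVerdictRow], min_genomes: int = 10) -> pd.DataFrame:
    """Per-phylum per-category overrepresentation ratios, ties excluded.

    Phyla with ``min_genomes`` genomes or fewer are excluded (the filter
    is strictly more-than). Within a retained phylum, for each category,
    ratio_small = small-wins / (small-wins + large-wins); genomes whose
    pair is (0,0) shrink the denominator. If no genome decides the
    category, both ratios are 0.
    """
    by_phylum: dict[str, list[GenomeVerdictRow]] = {}
    for r in rows:
        by_phylum.setdefault(r.phylum, []).append(r)
    retained = {ph: rs for ph, rs in by_phylum.items() if len(rs) > min_genomes}
    if not retained:
        logger.warning(
            "no phylum has more than %d genomes; phylum-level output is empty", min_genomes
        )
    out = []
    for ph in sorted(retained):
        rs = retained[ph]
        for cat in COG_CATEGORIES:
            n_small = sum(r.indicators[cat][0] for r in rs)
            n_large = sum(r.indicators[cat][1] for r in rs)
            n_tie = len(rs) - n_small - n_large
            decided = n_small + n_large
            ratio_small = n_small / decided if decided else 0.0
            ratio_large = n_large / decided if decided else 0.0
            out.append(
                {
                    "phylum": ph,
                    "category": cat,
                    "n_genomes": len(rs),
                    "n_small_wins": n_small,
                    "n_large_wins": n_large,
                    "n_ties": n_tie,
                    "ratio_small": ratio_small,
                    "ratio_large": ratio_large,
                    "ratio_small_pct": round(100 * ratio_small, 2),
                    "ratio_large_pct": round(100 * ratio_large, 2),
                }
            )
    columns = [
        "phylum", "category", "n_genomes", "n_small_wins", "n_large_wins", "n_ties",
        "ratio_small", "ratio_large", "ratio_small_pct", "ratio_large_pct",
    ]
    return pd.DataFrame(out, columns=columns)


def consistency_matrix(ratios: pd.DataFrame) -> pd.DataFrame:
    """Classify each category's cross-phylum behaviour.

    ``consistent-large`` when ratio_large > ratio_small in every retained
    phylum where the category was decided at least once, ``consistent-small``
    symmetrically, else ``mixed`` (including categories never decided).
    Requires at least two retained phyla.
    """
    if ratios.empty or ratios["phylum"].nunique() < 2:
        raise ValueError("consistency classification requires >= 2 retained phyla")
    out = []
    for cat in COG_CATEGORIES:
        sub = ratios[ratios["category"] == cat]
        decided = sub[(sub["n_small_wins"] + sub["n_large_wins"]) > 0]
        if decided.empty:
            cls = "mixed"
        elif (decided["ratio_large"] > decided["ratio_small"]).all():
            cls = "consistent-large"
        elif (decided["ratio_small"] > decided["ratio_large"]).all():
            cls = "consistent-small"
        else:
            cls = "mixed"
        out.append({"category": cat, "classification": cls, "n_phyla_decided": len(decided)})
    return pd.DataFrame(out)
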