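"""COG functional-category enrichment between the SMALL and LARGE clusters.

Genes carry one or more of the 26 one-letter COG categories. For one
genome, the per-category gene counts in the two clusters form a 2x26
contingency table tested by Pearson's chi-squared (no continuity
correction). Per category P, the proportions

    F(P_small) = N(P_small) / N(small),   F(P_large) = N(P_large) / N(large)

are compared: if the larger proportion exceeds the smaller by more than
the threshold (by default 5% of the lower value), the cluster holding
the larger proportion receives indicator 1 and the other 0; otherwise,
including exact equality, both get 0.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

SMALL = "SMALL"
LARGE = "LARGE"

#: The 4 COG super-categories and their one-letter categories.
SUPER_CATEGORIES: dict[str, str] = {
    "information storage and processing": "JKLAB",
    "cellular processes and signaling": "DYVTMNZWUOX",
    "metabolism": "CGEFHIPQ",
    "poorly characterized": "RS",
}

#: All 26 category letters, grouped by super-category.
COG_CATEGORIES: str = "".join(SUPER_CATEGORIES.values())
assert len(COG_CATEGORIES) == 26 and len(set(COG_CATEGORIES)) == 26

_COG_FIELD_RE = re.compile(r"^(?:COG|cog)\d+([A-Za-z]*)$")
_PTT_LOCATION_RE = re.compile(r"^\d+\.\.\d+$")


@dataclass
class CategoryCounts:
    """Per-category annotated gene counts for one cluster."""

    cluster: str  # SMALL or LARGE
    counts: dict[str, int]
    total: int  # N(small) or N(large): annotated genes (first_letter) or increments (all_letters)


@dataclass
class ChiSquareResult:
    statistic: float
    dof: int
    p_value: float
    dropped_categories: list[str]
    min_expected: float


@dataclass
class EnrichmentVerdict:
    category: str
    F_small: float
    F_large: float
    indicator_small: int
    indicator_large: int


@dataclass
class CategoryEnrichmentReport:
    """Everything the enrichment stage reports for one genome."""

    genome_id: str
    counts_small: CategoryCounts
    counts_large: CategoryCounts
    chi2: ChiSquareResult
    verdicts: dict[str, EnrichmentVerdict]
    policy: str = "first_letter"
    threshold_mode: str = "relative"
    threshold: float = 0.05
    n_unclustered: int = 0

    def indicator_pairs(self) -> dict[str, tuple[int, int]]:
        return {c: (v.indicator_small, v.indicator_large) for c, v in self.verdicts.items()}


def _parse_cog_field(cog_field: str, where: str) -> list[str]:
    """Extract the trailing category letters from a COG accession field."""
    m = _COG_FIELD_RE.match(cog_field)
    if not m:
        raise ValueError(f"{where}: unparseable COG field {cog_field!r}")
    letters = list(m.group(1).upper())
    for letter in letters:
        if letter not in COG_CATEGORIES:
            raise ValueError(f"{where}: unknown COG category letter {letter!r}")
    return letters


def read_cog_annotation(path: str | Path, dialect: str = "tsv") -> dict[str, list[str]]:
    """Read a gene -> COG-category-letters map.

    ``tsv`` dialect: two columns, gene_id <TAB> letters (e.g. ``g7  KL``).
    ``ptt`` dialect: NCBI protein table — tab-separated data rows whose
    first field is a ``start..end`` location; the gene id is the Synonym
    column (index 5) and the COG column (index 7) carries an accession
    with trailing category letters, e.g. ``COG0583K``, or ``-`` for
    unannotated. Genes without category letters are absent from the map.
    Letters outside the 26-letter alphabet raise; structurally broken
    rows are skipped with a warning and counted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    if dialect not in ("tsv", "ptt"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")

    annotation: dict[str, list[str]] = {}
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            where = f"{path.name}:{lineno}"
            fields = line.split("\t")
            if dialect == "tsv":
                if len(fields) != 2 or not fields[0]:
                    n_skipped += 1
                    logger.warning("%s: skipping unparseable row", where)
                    continue
                gene_id, letters_str = fields
                letters = list(letters_str.strip().upper())
                for letter in letters:
                    if letter not in COG_CATEGORIES:
                        raise ValueError(f"{where}: unknown COG category letter {letter!r}")
                if letters:
                    annotation[gene_id] = letters
            else:  # ptt
                if not _PTT_LOCATION_RE.match(fields[0]):
                    continue  # description / count / header line
                if len(fields) < 8:
                    n_skipped += 1
                    logger.warning("%s: skipping short ptt row", where)
                    continue
                gene_id, cog_field = fields[5], fields[7]
                if cog_field in ("-", ""):
                    continue
                letters = _parse_cog_field(cog_field, where)
                if letters:
                    annotation[gene_id] = letters
    if n_skipped:
        logger.warning("%s: skipped %d unparseable row(s)", path.name, n_skipped)
    return annotation


def count_categories(
    labels: Mapping[str, str],
    annotation: Mapping[str, list[str]],
    policy: str = "first_letter",
) -> tuple[CategoryCounts, CategoryCounts]:
    """Tally annotated genes per category in each cluster.

    Under ``first_letter`` (default) each gene increments exactly one
    category, so cluster totals equal annotated gene counts and the 2x26
    table is well-formed; under ``all_letters`` each carried letter
    increments. Annotated genes with no cluster label are reported as
    unclustered; genes without annotation never enter the totals.
    """
    if policy not in ("first_letter", "all_letters"):
        raise ValueError(f"unknown category policy {policy!r}")
    counts = {SMALL: dict.fromkeys(COG_CATEGORIES, 0), LARGE: dict.fromkeys(COG_CATEGORIES, 0)}
    totals = {SMALL: 0, LARGE: 0}
    n_unclustered = 0
    n_counted = 0
    for gene_id, letters in annotation.items():
        cluster = labels.get(gene_id)
        if cluster is None:
            n_unclustered += 1
            continue
        use = letters[:1] if policy == "first_letter" else letters
        for letter in use:
            counts[cluster][letter] += 1
            totals[cluster] += 1
        n_counted += 1
    if n_counted == 0:
        raise ValueError("no gene is both clustered and COG-annotated")
    if n_unclustered:
        logger.warning("%d annotated gene(s) had no cluster label", n_unclustered)
    return (
        CategoryCounts(cluster=SMALL, counts=counts[SMALL], total=totals[SMALL]),
        CategoryCounts(cluster=LARGE, counts=counts[LARGE], total=totals[LARGE]),
    )


def chi_square_2xC(
    counts_small: CategoryCounts, counts_large: CategoryCounts
) -> ChiSquareResult:
    """Pearson chi-squared on the 2 x 26 cluster-by-category table.

    Categories with a zero column total are dropped (dof reduced
    accordingly); no continuity correction is applied. A minimum expected
    count below 5 is warned about but does not alter the statistic.
    """
    cats = list(COG_CATEGORIES)
    table = np.array(
        [[counts_small.counts.get(c, 0) for c in cats], [counts_large.counts.get(c, 0) for c in cats]],
        dtype=float,
    )
    col_totals = table.sum(axis=0)
    keep = col_totals > 0
    dropped = [c for c, k in zip(cats, keep) if not k]
    table = table[:, keep]
    if table.shape[1] < 2:
        raise ValueError("test undefined: fewer than 2 categories with nonzero totals")
    if table.sum(axis=1).min() == 0:
        raise ValueError("test undefined: one cluster has no annotated genes")
    stat, p, dof, expected = stats.chi2_contingency(table, correction=False)
    min_exp = float(expected.min())
    if min_exp < 5:
        logger.warning("chi-squared: minimum expected count %.2f < 5", min_exp)
    return ChiSquareResult(
        statistic=float(stat), dof=int(dof), p_value=float(p),
        dropped_categories=dropped, min_expected=min_exp,
    )


def category_proportions(counts: CategoryCounts, category: str) -> float:
    """F(P_cluster) = N(P_cluster) / N(cluster)."""
    if counts.total <= 0:
        raise ValueError(f"cluster {counts.cluster} has no annotated genes")
    return counts.counts.get(category, 0) / counts.total


def overrepresentation_indicator(
    F_small: float,
    F_large: float,
    threshold_mode: str = "relative",
    threshold: float = 0.05,
) -> tuple[int, int]:
    """The 1/0 overrepresentation assignment for one category.

    ``relative`` mode (default): the difference is significant when it
    exceeds ``threshold`` times the lower of the two proportions.
    ``absolute`` mode: when it exceeds ``threshold`` outright. The
    cluster with the larger proportion gets 1 and the other 0; a
    sub-threshold difference or exact equality yields (0, 0).
    """
    if threshold_mode not in ("relative", "absolute"):
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    diff = abs(F_small - F_large)
    if threshold_mode == "relative":
        significant = diff > threshold * min(F_small, F_large)
    else:
        significant = diff > threshold
    if not significant or F_small == F_large:
        return (0, 0)
    return (1, 0) if F_small > F_large else (0, 1)


def enrichment_report(
    labels: Mapping[str, str],
    annotation: Mapping[str, list[str]],
    genome_id: str = "",
    policy: str = "first_letter",
    threshold_mode: str = "relative",
    threshold: float = 0.05,
) -> CategoryEnrichmentReport:
    """Run the full per-genome enrichment stage: counts, chi-squared, verdicts."""
    counts_small, counts_large = count_categories(labels, annotation, policy=policy)
    chi2 = chi_square_2xC(counts_small, counts_large)
    verdicts: dict[str, EnrichmentVerdict] = {}
    for cat in COG_CATEGORIES:
        fs = category_proportions(counts_small, cat)
        fl = category_proportions(counts_large, cat)
        ind_s, ind_l = overrepresentation_indicator(fs, fl, threshold_mode, threshold)
        verdicts[cat] = EnrichmentVerdict(
            category=cat, F_small=fs, F_large=fl,
            indicator_small=ind_s, indicator_large=ind_l,
        )
    return CategoryEnrichmentReport(
        genome_id=genome_id,
        counts_small=counts_small,
        counts_large=counts_large,
        chi2=chi2,
        verdicts=verdicts,
        policy=policy,
        threshold_mode=threshold_mode,
        threshold=threshold,
    )
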