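"""End-to-end wiring: per-genome runs and cohort runs.

``run_genome`` takes a CDS FASTA (plus optional COG annotation) to a
report bundle: frequency table, cluster assignments, silhouette profile
and — when annotation is present — the enrichment report. ``run_cohort``
maps that over a directory of genomes and then aggregates. Every output
file carries the tool version and a hash of the configuration that
produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .codon_stats import genome_frequency_table, points_from_table, read_cds_fasta, write_frequency_table
from .clustering import cluster_genome
from .cog_enrichment import COG_CATEGORIES, CategoryEnrichmentReport, enrichment_report, read_cog_annotation
from .cohort_aggregation import (
    GenomeVerdictRow,
    consistency_matrix,
    cumulative_overrepresentation,
    phylum_ratios,
    significance_summary,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, with their documented defaults."""

    drop_terminal_stop: bool = False
    min_genes: int = 50
    k_min: int = 2
    k_max: int = 9
    seed: int = 20170326
    n_restarts: int = 50
    silhouette_subsample_cap: int | None = None
    threshold_mode: str = "relative"  # Eq.-style 5%-of-lower-proportion rule
    threshold: float = 0.05
    category_policy: str = "first_letter"
    min_genomes_per_phylum: int = 10
    annotation_dialect: str = "tsv"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    @property
    def provenance(self) -> str:
        return f"codonclust v{__version__} config={self.config_hash}"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)

    def k_range(self) -> range:
        return range(self.k_min, self.k_max + 1)


def _report_to_json_dict(report: CategoryEnrichmentReport, config: PipelineConfig) -> dict:
    return {
        "genome_id": report.genome_id,
        "tool": config.provenance,
        "config": config.to_dict(),
        "policy": report.policy,
        "threshold_mode": report.threshold_mode,
        "threshold": report.threshold,
        "n_small": report.counts_small.total,
        "n_large": report.counts_large.total,
        "chi2": {
            "statistic": report.chi2.statistic,
            "dof": report.chi2.dof,
            "p_value": report.chi2.p_value,
            "dropped_categories": report.chi2.dropped_categories,
            "min_expected": report.chi2.min_expected,
        },
        "categories": {
            c: {
                "n_small": report.counts_small.counts[c],
                "n_large": report.counts_large.counts[c],
                "F_small": v.F_small,
                "F_large": v.F_large,
                "ind_small": v.indicator_small,
                "ind_large": v.indicator_large,
            }
            for c, v in report.verdicts.items()
        },
    }


def run_genome(
    fasta_path: str | Path,
    annotation_path: str | Path | None,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    genome_id: str | None = None,
) -> dict:
    """Run frequencies -> clustering -> (optional) enrichment for one genome.

    Writes frequencies.tsv, clusters.tsv, silhouette.json and, with
    annotation, enrichment.json + enrichment.tsv under ``out_dir``.
    Returns a summary dict (gene counts, optimal K, p-value).
    """
    config = config or PipelineConfig()
    fasta_path = Path(fasta_path)
    genome_id = genome_id or fasta_path.parent.name or fasta_path.stem
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genes = read_cds_fasta(fasta_path, genome_id=genome_id)
    table = genome_frequency_table(
        genes, drop_terminal_stop=config.drop_terminal_stop, min_genes=config.min_genes
    )
    write_frequency_table(table, out_dir / "frequencies.tsv", header_comment=config.provenance)

    points, gene_ids = points_from_table(table)
    result = cluster_genome(
        points,
        gene_ids,
        genome_id=genome_id,
        k_range=config.k_range(),
        seed=config.seed,
        n_restarts=config.n_restarts,
        subsample_cap=config.silhouette_subsample_cap,
    )
    clusters = pd.DataFrame({"gene_id": gene_ids, "cluster": result.two_cluster_labels})
    with open(out_dir / "clusters.tsv", "w") as fh:
        fh.write(f"# {config.provenance}\n")
        fh.write(
            f"# centroid_small_fA2={result.centroid_small[0]:.6f}"
            f" centroid_small_fT2={result.centroid_small[1]:.6f}"
            f" centroid_large_fA2={result.centroid_large[0]:.6f}"
            f" centroid_large_fT2={result.centroid_large[1]:.6f}\n"
        )
        clusters.to_csv(fh, sep="\t", index=False)
    sil = result.silhouette_profile.to_dict() if result.silhouette_profile else {}
    sil["tool"] = config.provenance
    with open(out_dir / "silhouette.json", "w") as fh:
        json.dump(sil, fh, indent=1, sort_keys=True)

    summary = {
        "genome_id": genome_id,
        "n_genes": len(genes),
        "n_clustered": len(gene_ids),
        "optimal_k": result.optimal_k,
        "small_size": result.small_size,
        "large_size": result.large_size,
        "p_value": None,
    }
    logger.info(
        "%s: %d genes, %d clustered, optimal K=%d, small/large=%d/%d",
        genome_id, len(genes), len(gene_ids), result.optimal_k,
        result.small_size, result.large_size,
    )
    if annotation_path is not None:
        annotation = read_cog_annotation(annotation_path, dialect=config.annotation_dialect)
        labels = dict(zip(gene_ids, result.two_cluster_labels))
        report = enrichment_report(
            labels,
            annotation,
            genome_id=genome_id,
            policy=config.category_policy,
            threshold_mode=config.threshold_mode,
            threshold=config.threshold,
        )
        with open(out_dir / "enrichment.json", "w") as fh:
            json.dump(_report_to_json_dict(report, config), fh, indent=1, sort_keys=True)
        flat = pd.DataFrame(
            [
                {
                    "category": c,
                    "n_small": report.counts_small.counts[c],
                    "n_large": report.counts_large.counts[c],
                    "F_small": v.F_small,
                    "F_large": v.F_large,
                    "ind_small": v.indicator_small,
                    "ind_large": v.indicator_large,
                }
                for c, v in report.verdicts.items()
            ]
        )
        with open(out_dir / "enrichment.tsv", "w") as fh:
            fh.write(f"# {config.provenance}\n")
            flat.to_csv(fh, sep="\t", index=False)
        summary["p_value"] = report.chi2.p_value
        logger.info("%s: chi2 p=%.3g", genome_id, report.chi2.p_value)
    else:
        logger.warning("%s: no annotation given; enrichment stage skipped", genome_id)
    return summary


def verdict_row_from_report_json(path: str | Path, phylum: str) -> GenomeVerdictRow:
    """Rebuild a cohort tally row from a written enrichment.json."""
    with open(path) as fh:
        data = json.load(fh)
    indicators = {
        c: (int(d["ind_small"]), int(d["ind_large"])) for c, d in data["categories"].items()
    }
    return GenomeVerdictRow(
        genome_id=data["genome_id"],
        phylum=phylum,
        p_value=float(data["chi2"]["p_value"]),
        indicators=indicators,
    )


def run_cohort(
    cohort_dir: str | Path,
    metadata_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    fasta_name: str = "genes.fna",
    annotation_name: str = "annotation.tsv",
) -> dict:
    """Run every genome under ``cohort_dir`` and aggregate the cohort.

    ``metadata_path`` is a two-column TSV (genome_id, phylum) covering
    every genome directory; genomes that fail (too few genes, undefined
    test) are recorded in the skipped list without aborting the cohort.
    """
    config = config or PipelineConfig()
    cohort_dir = Path(cohort_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = pd.read_csv(metadata_path, sep="\t")
    if not {"genome_id", "phylum"} <= set(meta.columns):
        raise ValueError("metadata must have genome_id and phylum columns")
    phylum_of = dict(zip(meta["genome_id"], meta["phylum"]))

    genome_dirs = sorted(d for d in cohort_dir.iterdir() if d.is_dir() and (d / fasta_name).exists())
    orphans = [d.name for d in genome_dirs if d.name not in phylum_of]
    if orphans:
        raise ValueError(f"genomes missing from metadata: {orphans}")

    rows: list[GenomeVerdictRow] = []
    skipped: list[dict] = []
    for gdir in genome_dirs:
        ann = gdir / annotation_name
        try:
            run_genome(
                gdir / fasta_name,
                ann if ann.exists() else None,
                out_dir / gdir.name,
                config=config,
                genome_id=gdir.name,
            )
            report_path = out_dir / gdir.name / "enrichment.json"
            if report_path.exists():
                rows.append(verdict_row_from_report_json(report_path, phylum_of[gdir.name]))
            else:
                skipped.append({"genome_id": gdir.name, "reason": "no annotation"})
        except (ValueError, FileNotFoundError) as exc:
            logger.warning("skipping genome %s: %s", gdir.name, exc)
            skipped.append({"genome_id": gdir.name, "reason": str(exc)})

    summary: dict = {
        "tool": config.provenance,
        "n_genomes_run": len(rows),
        "skipped": skipped,
    }
    if rows:
        sig = significance_summary(rows)
        cum = cumulative_overrepresentation(rows)
        ratios = phylum_ratios(rows, min_genomes=config.min_genomes_per_phylum)
        for name, df in [
            ("significance_summary.tsv", sig),
            ("cumulative_overrepresentation.tsv", cum),
            ("phylum_ratios.tsv", ratios),
        ]:
            with open(out_dir / name, "w") as fh:
                fh.write(f"# {config.provenance}\n")
                df.to_csv(fh, sep="\t", index=False)
        if not ratios.empty and ratios["phylum"].nunique() >= 2:
            cons = consistency_matrix(ratios)
            with open(out_dir / "consistency.tsv", "w") as fh:
                fh.write(f"# {config.provenance}\n")
                cons.to_csv(fh, sep="\t", index=False)
    with open(out_dir / "cohort_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
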