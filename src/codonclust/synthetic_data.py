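"""Synthetic genomes with the two-component second-position structure.

Real prokaryotic genomes show two unequal gene clusters in
(f(A2), f(T2)) space: a large cluster with A2 >= T2 and a small one with
much higher T2, and the two clusters favour different COG categories.
The generator emulates exactly that statistical structure: each gene is
drawn from one of two (or more) components, each component fixing a
per-codon-position base distribution and a 26-category COG distribution.
Codons are i.i.d. within a gene, so the within-component spread of
(f(A2), f(T2)) is the multinomial sampling noise sqrt(p(1-p)/n_codons),
about 0.02-0.03 at the default median gene length of 300 codons.

Emitted genes are legal CDSs: no internal in-frame stop codon, and the
final codon is forced to a stop. Stop avoidance redraws codon positions
1 and 3 only, so the position-2 marginals — the clustering features —
match ``base_probs`` exactly; the position-1/3 marginals are perturbed
by at most the stop probability mass.

Every gene's true component and category letters go to a truth ledger so
recovery rates can be scored downstream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codon_stats import BASES, GeneRecord
from .cog_enrichment import COG_CATEGORIES

_A, _C, _G, _T = 0, 1, 2, 3  # indices into BASES
#: Stop codons as index triples: TAA, TAG, TGA.
_STOPS = np.array([[_T, _A, _A], [_T, _A, _G], [_T, _G, _A]])


@dataclass
class ComponentSpec:
    """One mixture component: where its genes live in base-frequency space
    and which functional categories they favour."""

    name: str
    weight: float
    base_probs: np.ndarray  # (3, 4): row = codon position, col = A,C,G,T
    cog_probs: np.ndarray  # (26,), order = COG_CATEGORIES
    annotation_rate: float = 0.9

    def __post_init__(self) -> None:
        self.base_probs = np.asarray(self.base_probs, dtype=float)
        self.cog_probs = np.asarray(self.cog_probs, dtype=float)
        if self.base_probs.shape != (3, 4):
            raise ValueError("base_probs must be 3 positions x 4 bases")
        if not np.allclose(self.base_probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each position's base probabilities must sum to 1")
        if self.cog_probs.shape != (26,):
            raise ValueError("cog_probs must cover the 26 COG categories")
        if not np.isclose(self.cog_probs.sum(), 1.0, atol=1e-9):
            raise ValueError("cog_probs must sum to 1")
        if not (0 < self.weight < 1):
            raise ValueError("weight must lie in (0, 1)")
        if not (0 <= self.annotation_rate <= 1):
            raise ValueError("annotation_rate must lie in [0, 1]")


@dataclass
class SyntheticCohortSpec:
    """Reproducible recipe for a multi-phylum cohort of synthetic genomes."""

    phyla: dict[str, int]  # phylum name -> number of genomes
    genes_per_genome: int
    components: list[ComponentSpec]
    codon_median: float = 300.0  # lognormal median codons per gene
    codon_log_sigma: float = 0.3
    min_codons: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        w = sum(c.weight for c in self.components)
        if not np.isclose(w, 1.0, atol=1e-9):
            raise ValueError(f"component weights must sum to 1, got {w}")


@dataclass
class SyntheticGenome:
    """In-memory genome plus its ground-truth ledger."""

    genome_id: str
    records: list[GeneRecord]
    annotation: dict[str, list[str]]
    truth: pd.DataFrame = field(repr=False)  # gene_id, component, letters


# --- paper-like preset -------------------------------------------------------

#: Position-1 / position-3 base compositions shared by both components
#: (A, C, G, T). Position 1 favours G/A as in typical prokaryotic CDSs;
#: position 3 is uniform.
_POS1 = np.array([0.26, 0.23, 0.35, 0.16])
_POS3 = np.array([0.25, 0.25, 0.25, 0.25])
#: Position-2 compositions placing the large component near
#: (f(A2), f(T2)) = (0.32, 0.27) and the small near (0.22, 0.45).
_POS2_LARGE = np.array([0.32, 0.21, 0.20, 0.27])
_POS2_SMALL = np.array([0.22, 0.18, 0.15, 0.45])

#: Baseline 26-category COG distribution (order = COG_CATEGORIES), a
#: rounded typical prokaryotic profile with every category >= 0.01 so
#: expected chi-squared cell counts stay healthy at realistic totals.
BASELINE_COG_PROBS = np.array([
    0.055, 0.060, 0.055, 0.010, 0.010,               # J K L A B
    0.020, 0.010, 0.025, 0.040, 0.055, 0.020,        # D Y V T M N
    0.010, 0.010, 0.025, 0.040, 0.015,               # Z W U O X
    0.055, 0.060, 0.080, 0.020, 0.040, 0.025, 0.050, 0.025,  # C G E F H I P Q
    0.095, 0.090,                                    # R S
])
assert np.isclose(BASELINE_COG_PROBS.sum(), 1.0)


def _boost(probs: np.ndarray, letters: str, factor: float) -> np.ndarray:
    out = probs.copy()
    for letter in letters:
        out[COG_CATEGORIES.index(letter)] *= factor
    return out / out.sum()


def paper_like_components(
    small_weight: float = 0.15,
    annotation_rate: float = 0.9,
    small_boost: str = "PUVSG",
    large_boost: str = "JKL",
    boost_factor: float = 2.0,
) -> list[ComponentSpec]:
    """The default two-component preset.

    Large component (weight 1 - small_weight) near (0.32, 0.27) with
    J/K/L boosted; small component near (0.22, 0.45) with P/U/V/S/G
    boosted — echoing the empirical pattern of informational genes in the
    large cluster and transport/defence categories in the small one.
    """
    large = ComponentSpec(
        name="large",
        weight=1 - small_weight,
        base_probs=np.vstack([_POS1, _POS2_LARGE, _POS3]),
        cog_probs=_boost(BASELINE_COG_PROBS, large_boost, boost_factor),
        annotation_rate=annotation_rate,
    )
    small = ComponentSpec(
        name="small",
        weight=small_weight,
        base_probs=np.vstack([_POS1, _POS2_SMALL, _POS3]),
        cog_probs=_boost(BASELINE_COG_PROBS, small_boost, boost_factor),
        annotation_rate=annotation_rate,
    )
    return [large, small]


def paper_like_cohort_spec(
    phyla: dict[str, int] | None = None,
    genes_per_genome: int = 600,
    seed: int = 0,
    **component_kwargs,
) -> SyntheticCohortSpec:
    if phyla is None:
        phyla = {"Alphaexempla": 12, "Betaexempla": 12, "Gammaexempla": 12}
    return SyntheticCohortSpec(
        phyla=phyla,
        genes_per_genome=genes_per_genome,
        components=paper_like_components(**component_kwargs),
        seed=seed,
    )


# --- emission ---------------------------------------------------------------

def _fix_stops(codons: np.ndarray, base_probs: np.ndarray, rng: np.random.Generator) -> None:
    """Redraw positions 1/3 of internal in-frame stop codons, in place.

    Keeps the position-2 draw untouched so position-2 marginals stay
    exact. If a degenerate base distribution cannot avoid a stop within
    100 rounds, position 3 is forced to C (TAA/TAG -> TAC, TGA -> TGC).
    """
    internal = codons[:-1]
    for _ in range(100):
        is_stop = (internal[:, None, :] == _STOPS[None, :, :]).all(axis=2).any(axis=1)
        if not is_stop.any():
            return
        n = int(is_stop.sum())
        internal[is_stop, 0] = rng.choice(4, size=n, p=base_probs[0])
        internal[is_stop, 2] = rng.choice(4, size=n, p=base_probs[2])
    is_stop = (internal[:, None, :] == _STOPS[None, :, :]).all(axis=2).any(axis=1)
    internal[is_stop, 2] = _C


def _draw_stop(base_probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Pick the terminal stop codon, weighted by the component's own
    base probabilities restricted to TAA/TAG/TGA (uniform fallback)."""
    w = np.array([base_probs[0, s[0]] * base_probs[1, s[1]] * base_probs[2, s[2]] for s in _STOPS])
    w = w / w.sum() if w.sum() > 0 else np.full(3, 1 / 3)
    return _STOPS[rng.choice(3, p=w)]


def emit_gene(
    component: ComponentSpec, n_codons: int, rng: np.random.Generator
) -> tuple[str, list[str] | None]:
    """Emit one CDS of ``n_codons`` codons (stop included) and its COG letters.

    Returns (sequence, letters); letters is None when the annotation coin
    (probability ``annotation_rate``) comes up unannotated.
    """
    if n_codons < 2:
        raise ValueError("a gene needs at least 2 codons (one coding + stop)")
    codons = np.empty((n_codons, 3), dtype=np.int64)
    for pos in range(3):
        codons[:, pos] = rng.choice(4, size=n_codons, p=component.base_probs[pos])
    _fix_stops(codons, component.base_probs, rng)
    codons[-1] = _draw_stop(component.base_probs, rng)
    seq = "".join(BASES[i] for i in codons.ravel())
    letters: list[str] | None = None
    if rng.random() < component.annotation_rate:
        letters = [COG_CATEGORIES[rng.choice(26, p=component.cog_probs)]]
    return seq, letters


def generate_genome(
    components: list[ComponentSpec],
    n_genes: int,
    genome_id: str,
    seed: int,
    codon_median: float = 300.0,
    codon_log_sigma: float = 0.3,
    min_codons: int = 60,
) -> SyntheticGenome:
    """Draw a genome: genes assigned to components by weight, lognormal lengths."""
    rng = np.random.default_rng(seed)
    weights = np.array([c.weight for c in components])
    comp_idx = rng.choice(len(components), size=n_genes, p=weights)
    n_codons = np.maximum(
        min_codons,
        np.round(rng.lognormal(np.log(codon_median), codon_log_sigma, size=n_genes)).astype(int),
    )
    width = max(4, len(str(n_genes)))
    records, annotation, truth_rows = [], {}, []
    for i in range(n_genes):
        comp = components[comp_idx[i]]
        seq, letters = emit_gene(comp, int(n_codons[i]), rng)
        gene_id = f"{genome_id}_g{i:0{width}d}"
        records.append(GeneRecord(gene_id=gene_id, sequence=seq, genome_id=genome_id))
        if letters:
            annotation[gene_id] = letters
        truth_rows.append(
            {"gene_id": gene_id, "component": comp.name, "letters": "".join(letters or [])}
        )
    return SyntheticGenome(
        genome_id=genome_id,
        records=records,
        annotation=annotation,
        truth=pd.DataFrame(truth_rows),
    )


def write_genome(genome: SyntheticGenome, out_dir: str | Path) -> dict[str, Path]:
    """Write genes.fna, annotation.tsv and truth.tsv in the pipeline's dialects."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "genes.fna"
    with open(fasta, "w") as fh:
        for rec in genome.records:
            fh.write(f">{rec.gene_id} synthetic component gene\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")
    ann = out_dir / "annotation.tsv"
    with open(ann, "w") as fh:
        for gene_id, letters in genome.annotation.items():
            fh.write(f"{gene_id}\t{''.join(letters)}\n")
    truth = out_dir / "truth.tsv"
    genome.truth.to_csv(truth, sep="\t", index=False)
    return {"fasta": fasta, "annotation": ann, "truth": truth}


def derive_seed(master_seed: int, *tokens: str | int) -> int:
    """Stable child seed below 2**31 from a master seed and context tokens."""
    h = zlib.crc32(repr((master_seed, *tokens)).encode())
    return int(h % (2**31))


def generate_cohort(spec: SyntheticCohortSpec, out_dir: str | Path) -> Path:
    """Write one genome directory per (phylum, index) plus metadata.tsv.

    Child seeds are derived from (seed, phylum, index), so every genome is
    distinct and the whole cohort is reproducible from the spec alone.
    Returns the metadata path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for phylum, n_genomes in spec.phyla.items():
        for i in range(n_genomes):
            genome_id = f"{phylum}_{i:03d}"
            child = derive_seed(spec.seed, phylum, i)
            genome = generate_genome(
                spec.components,
                spec.genes_per_genome,
                genome_id,
                seed=child,
                codon_median=spec.codon_median,
                codon_log_sigma=spec.codon_log_sigma,
                min_codons=spec.min_codons,
            )
            write_genome(genome, out_dir / genome_id)
            meta_rows.append({"genome_id": genome_id, "phylum": phylum})
    meta = out_dir / "metadata.tsv"
    pd.DataFrame(meta_rows).to_csv(meta, sep="\t", index=False)
    return meta
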