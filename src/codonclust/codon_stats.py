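"""Per-gene nucleotide frequencies at the three codon positions.

For a coding sequence split into consecutive in-frame triplets, f(X_n) is
the frequency of base X in {A, C, G, T} at codon position n in {1, 2, 3}.
The pair (f(A2), f(T2)) — the A and T frequencies at the second codon
position — is the feature space in which genes of a genome separate into
two unequal clusters downstream.

Frequencies are computed on the DNA alphabet (T, not U). A trailing
partial codon is trimmed; codons carrying an ambiguity code at a given
position are excluded from that position's denominator only, so a single
N does not discard the whole gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Canonical base order used for every 4-vector / 4x3 matrix in this package.
BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# Quality flags attached to a GeneFrequencyProfile.
PARTIAL_CODON_TRIMMED = "PARTIAL_CODON_TRIMMED"
AMBIGUOUS_BASES_SKIPPED = "AMBIGUOUS_BASES_SKIPPED"
TOO_SHORT = "TOO_SHORT"

#: Column order of the 12 frequency columns in genome_frequency_table.
FREQ_COLUMNS = [f"f{b}{n}" for n in (1, 2, 3) for b in "ATCG"]


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene: an id unique within its genome and its CDS."""

    gene_id: str
    sequence: str
    genome_id: str = ""

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"gene {self.gene_id!r}: sequence must be non-empty")


@dataclass
class GeneFrequencyProfile:
    """Base frequencies of one gene at each codon position.

    ``freq[i, n]`` is the frequency of base ``BASES[i]`` at codon position
    ``n + 1``; ``counted_codons[n]`` is the denominator used at that
    position (codons with an ambiguous base there are excluded).
    """

    gene_id: str
    freq: np.ndarray  # shape (4, 3)
    counted_codons: np.ndarray  # shape (3,), int
    flags: set[str] = field(default_factory=set)

    def f(self, base: str, position: int) -> float:
        """f(X_n): frequency of ``base`` at codon ``position`` (1-based)."""
        return float(self.freq[_BASE_INDEX[base], position - 1])

    @property
    def f_A2(self) -> float:
        return self.f("A", 2)

    @property
    def f_T2(self) -> float:
        return self.f("T", 2)

    @property
    def usable(self) -> bool:
        return TOO_SHORT not in self.flags


def read_cds_fasta(path: str | Path, genome_id: str = "") -> list[GeneRecord]:
    """Read a multi-FASTA of nucleotide CDS records.

    The gene id is the first whitespace-delimited token of the header.
    Sequences are uppercased and U is mapped to T. Duplicate ids raise;
    an empty file yields an empty list with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"CDS FASTA not found: {path}")
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id {gene_id!r} in {path}")
        seen.add(gene_id)
        seq = str(rec.seq).upper().replace("U", "T")
        records.append(GeneRecord(gene_id=gene_id, sequence=seq, genome_id=genome_id))
    if not records:
        logger.warning("FASTA %s contains no records", path)
    return records


def compute_frequency_profile(
    gene: GeneRecord, drop_terminal_stop: bool = False
) -> GeneFrequencyProfile:
    """Tally base frequencies per codon position for one gene.

    The sequence is split into consecutive non-overlapping triplets from
    its first base. A trailing partial codon is discarded
    (PARTIAL_CODON_TRIMMED). If ``drop_terminal_stop`` and the final
    complete codon is TAA/TAG/TGA it is excluded from counting. At each
    position, codons whose base there is not one of A/C/G/T are excluded
    from that position's denominator (AMBIGUOUS_BASES_SKIPPED). A gene
    with no countable codon gets TOO_SHORT and all-zero denominators.
    """
    flags: set[str] = set()
    seq = gene.sequence
    n_codons = len(seq) // 3
    if len(seq) % 3 != 0:
        flags.add(PARTIAL_CODON_TRIMMED)
    if drop_terminal_stop and n_codons >= 1 and seq[3 * (n_codons - 1) : 3 * n_codons] in STOP_CODONS:
        n_codons -= 1

    freq = np.zeros((4, 3))
    counted = np.zeros(3, dtype=int)
    if n_codons > 0:
        arr = np.frombuffer(seq[: 3 * n_codons].encode("ascii"), dtype="S1").reshape(
            n_codons, 3
        )
        base_bytes = np.array([b.encode("ascii") for b in BASES], dtype="S1")
        for pos in range(3):
            col = arr[:, pos]
            hits = (col[:, None] == base_bytes[None, :]).sum(axis=0)  # counts per base
            n_valid = int(hits.sum())
            counted[pos] = n_valid
            if n_valid < n_codons:
                flags.add(AMBIGUOUS_BASES_SKIPPED)
            if n_valid > 0:
                freq[:, pos] = hits / n_valid
    if counted.sum() == 0:
        flags.add(TOO_SHORT)
    return GeneFrequencyProfile(
        gene_id=gene.gene_id, freq=freq, counted_codons=counted, flags=flags
    )


def genome_frequency_table(
    genes: Iterable[GeneRecord],
    drop_terminal_stop: bool = False,
    min_genes: int = 50,
) -> pd.DataFrame:
    """Build the per-gene frequency table a genome's clustering runs on.

    One row per usable gene, in input order, with columns ``gene_id``, the
    12 frequencies (``fA1`` ... ``fG3``), ``counted_codons_1..3`` and a
    comma-joined ``flags`` column. Genes flagged TOO_SHORT are dropped
    with a warning; fewer than ``min_genes`` surviving genes is an error
    because silhouette analysis is meaningless on tiny gene sets.
    """
    rows = []
    n_dropped = 0
    for gene in genes:
        prof = compute_frequency_profile(gene, drop_terminal_stop=drop_terminal_stop)
        if not prof.usable:
            n_dropped += 1
            continue
        row: dict[str, object] = {"gene_id": prof.gene_id}
        for n in (1, 2, 3):
            for b in "ATCG":
                row[f"f{b}{n}"] = prof.f(b, n)
        for n in (1, 2, 3):
            row[f"counted_codons_{n}"] = int(prof.counted_codons[n - 1])
        row["flags"] = ",".join(sorted(prof.flags))
        rows.append(row)
    if n_dropped:
        logger.warning("dropped %d gene(s) with no countable codons", n_dropped)
    if len(rows) < min_genes:
        raise ValueError(
            f"genome too small to cluster: {len(rows)} usable genes < min_genes={min_genes}"
        )
    columns = ["gene_id", *FREQ_COLUMNS, "counted_codons_1", "counted_codons_2", "counted_codons_3", "flags"]
    return pd.DataFrame(rows, columns=columns)


def write_frequency_table(table: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """Write the frequency table as TSV, frequencies at 6-decimal fixed point."""
    out = table.copy()
    for col in FREQ_COLUMNS:
        out[col] = out[col].map(lambda v: f"{v:.6f}")
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, sep="\t", index=False)


def points_from_table(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Extract the (f(A2), f(T2)) matrix and gene ids for clustering."""
    pts = table[["fA2", "fT2"]].to_numpy(dtype=float)
    return pts, table["gene_id"].tolist()
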