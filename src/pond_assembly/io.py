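"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTQ (Phred+33) and FASTA go through Biopython; OTU tables, metadata and
distance matrices are TSV with a header row; trees are Newick read into
scikit-bio ``TreeNode``.  All round-trips are lossless.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix, TreeNode

from .amplicon import Genotype, ReadRecord

# Phred+33 Illumina scores top out around 41-45; anything far above that with
# no low scores is the signature of a Phred+64 file
_MAX_PLAUSIBLE_PHRED33 = 45


def read_fastq(path: str | Path) -> list[ReadRecord]:
    reads: list[ReadRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate read id {rec.id!r} (record {i + 1})")
        seen.add(rec.id)
        quals = rec.letter_annotations["phred_quality"]
        if quals and min(quals) > 30 and max(quals) > _MAX_PLAUSIBLE_PHRED33:
            raise ValueError(
                f"{path}: quality scores up to {max(quals)} look like Phred+64 "
                "encoding; only Phred+33 is supported"
            )
        reads.append(ReadRecord(id=rec.id, bases=str(rec.seq).upper(), qualities=list(quals)))
    return reads


def write_fastq(reads: list[ReadRecord], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_genotypes_fasta(genotypes: list[Genotype], path: str | Path) -> None:
    """Genotype FASTA with total read counts carried in the headers."""
    records = [
        SeqRecord(Seq(g.bases), id=f"g{i:04d};size={g.total_count}", description="")
        for i, g in enumerate(genotypes)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=index_col)
    return table


def read_otu_table(path: str | Path) -> pd.DataFrame:
    """OTU count table, OTUs as rows, integer cells; negatives rejected."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    if (table.values < 0).any():
        raise ValueError(f"{path}: OTU table contains negative counts")
    if table.index.has_duplicates or table.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate OTU or sample ids")
    return table.astype(int)


def write_table(table: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    table.to_csv(path, sep="\t", index_label=index_label)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise ValueError(f"{path}: metadata needs a sample_id column")
    if meta["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in metadata")
    return meta


def read_newick(path: str | Path, require_branch_lengths: bool = False) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    if require_branch_lengths:
        missing = [
            n.name for n in tree.traverse(include_self=False) if n.length is None
        ]
        if missing:
            raise ValueError(
                f"{path}: tree lacks branch lengths on {len(missing)} edges; "
                "betaNTI requires branch lengths"
            )
    return tree


def write_distance_matrix(dm: DistanceMatrix | pd.DataFrame, path: str | Path) -> None:
    if isinstance(dm, DistanceMatrix):
        dm = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    dm.to_csv(path, sep="\t", index_label="id")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=list(df.columns))


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)
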