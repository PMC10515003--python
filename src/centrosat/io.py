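"""Readers/writers for the plain-text formats the pipeline exchanges."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(sequences: dict, path, seed: int | None = None) -> None:
    """Write sequences as FASTA; the simulation seed is recorded in headers."""
    desc = f"rng_seed={seed}" if seed is not None else ""
    records = [SeqRecord(Seq(seq), id=name, description=desc)
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(gene_truth: dict, path) -> None:
    """Gene intervals as GFF3 ``gene`` features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seq_id in sorted(gene_truth):
            for i, (start, end) in enumerate(gene_truth[seq_id], 1):
                fh.write("\t".join([
                    seq_id, "centrosat_sim", "gene", str(start + 1), str(end),
                    ".", "+", ".", f"ID=gene_{seq_id}_{i:04d}"]) + "\n")


def read_gff3_genes(path) -> dict:
    genes: dict = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if f[2] == "gene":
            genes.setdefault(f[0], []).append((int(f[3]) - 1, int(f[4])))
    return genes


def write_bed(intervals: dict, path) -> None:
    """Truth intervals as BED (0-based half-open). Values are (start, end)
    or (start, end, name-ish extras)."""
    with open(path, "w") as fh:
        for seq_id in sorted(intervals):
            ivs = intervals[seq_id]
            if isinstance(ivs, tuple):
                ivs = [ivs]
            for iv in ivs:
                extras = [str(x) for x in iv[2:]]
                fh.write("\t".join([seq_id, str(iv[0]), str(iv[1])] + extras) + "\n")


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_json(truth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_jsonable(), indent=1))
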