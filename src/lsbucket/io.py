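"""File formats: TSV pair datasets, FASTA sequences, code tables, manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqsim import CategoryDataset, LabeledPair

__all__ = [
    "write_pairs_tsv",
    "read_pairs_tsv",
    "write_fasta",
    "read_sequences",
    "write_codes_tsv",
    "write_manifest",
]


def write_pairs_tsv(dataset: CategoryDataset, path: str | Path) -> None:
    """Pair dataset as TSV with columns seq1, seq2, edit_distance."""
    rows = [(p.s, p.t, p.d) for p in dataset.all_pairs()]
    pd.DataFrame(rows, columns=["seq1", "seq2", "edit_distance"]).to_csv(
        path, sep="\t", index=False
    )


def read_pairs_tsv(path: str | Path) -> CategoryDataset:
    df = pd.read_csv(path, sep="\t", dtype={"seq1": str, "seq2": str})
    if not {"seq1", "seq2", "edit_distance"} <= set(df.columns):
        raise ValueError("pair TSV needs columns seq1, seq2, edit_distance")
    if df.empty:
        raise ValueError("empty pair dataset")
    n = len(df.iloc[0]["seq1"])
    ds = CategoryDataset(n=n)
    for row in df.itertuples(index=False):
        d = int(row.edit_distance)
        ds.categories.setdefault(d, []).append(LabeledPair(row.seq1, row.seq2, d))
    return ds


def write_fasta(seqs: list[str], path: str | Path, prefix: str = "seq") -> None:
    records = [
        SeqRecord(Seq(s), id=f"{prefix}{i}", description="")
        for i, s in enumerate(seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_sequences(path: str | Path) -> list[str]:
    """Sequences from FASTA (by extension) or plain one-per-line text."""
    path = Path(path)
    if path.suffix.lower() in (".fa", ".fasta", ".fna"):
        return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
    return [line.strip().upper() for line in path.read_text().splitlines() if line.strip()]


def write_codes_tsv(ids: list[str], codes: np.ndarray, path: str | Path) -> None:
    """Hash-codes as TSV: id + k whitespace-separated bitstrings of length m."""
    codes = np.asarray(codes, dtype=np.uint8)
    with open(path, "w") as fh:
        for i, name in enumerate(ids):
            bits = ["".join(str(b) for b in code) for code in codes[i]]
            fh.write(name + "\t" + "\t".join(bits) + "\n")


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    subcommand: str,
    config: dict,
    seed: int | None,
    inputs: list[str | Path] = (),
) -> None:
    """Provenance record: config snapshot, seed, package version, input digests."""
    from . import __version__

    manifest = {
        "subcommand": subcommand,
        "config": config,
        "seed": seed,
        "version": __version__,
        "inputs": {str(p): _digest(p) for p in inputs},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
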