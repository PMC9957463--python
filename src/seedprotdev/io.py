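"""Readers for the tabular and FASTA input formats.

Formats match the synthetic generators: proteome FASTA; signal-peptide
annotation TSV (protein_id, signal_start, signal_end); detection TSV
(protein_id, cultivar, stage, replicate, n_peptides, score, p_value); GO
TSV (protein_id, go_id, aspect).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .digest import ProteinRecord


def read_proteome(
    path,
    signal_tsv=None,
    go_tsv=None,
    source_set: str = "target",
) -> list[ProteinRecord]:
    """Read a FASTA into :class:`ProteinRecord` objects.

    Lowercase residues are uppercased (gel and database exports disagree on
    case); signal spans and GO ids are attached when annotation TSVs are
    given.
    """
    signal = {}
    if signal_tsv is not None:
        sdf = pd.read_csv(signal_tsv, sep="\t")
        signal = {
            str(r.protein_id): (int(r.signal_start), int(r.signal_end))
            for r in sdf.itertuples()
        }
    go: dict[str, set[str]] = {}
    if go_tsv is not None:
        gdf = pd.read_csv(go_tsv, sep="\t")
        for r in gdf.itertuples():
            go.setdefault(str(r.protein_id), set()).add(str(r.go_id))
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                signal_span=signal.get(rec.id),
                go_ids=frozenset(go.get(rec.id, ())),
                source_set=source_set,
            )
        )
    return records


def read_detections(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_go_annotations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_detections(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_go_annotations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def sha256_of(path) -> str:
    import hashlib

    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
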