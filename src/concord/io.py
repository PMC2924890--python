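"""File formats: FASTA, TSV tables, the packaged fold-change fixture.

All tables are TSV (protein descriptions contain commas), written with a
stable column order and a fixed float format so that identical inputs
produce byte-identical files.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .concordance import PAIR_COLUMNS
from .errors import InputError

#: sha256 of the packaged fold-change table; guards against silent edits.
TABLE1_SHA256 = "71ab08d3a47f07fdc7972d7076033be4c54c7c58a9dd45ddc64261540fd6097b"


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read FASTA records; headers parse as 'accession description'.

    Errors on an empty file, duplicate ids, or a record with no sequence.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise InputError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            raise InputError(f"record {rec.id!r} has no sequence")
        if not str(rec.seq).replace("*", "").isalpha():
            raise InputError(f"record {rec.id!r} has illegal characters")
    return records


def write_fasta(records, path: str | Path) -> None:
    """Write records (SeqRecord or (id, seq) pairs) as wrapped FASTA."""
    recs = []
    for r in records:
        if isinstance(r, SeqRecord):
            recs.append(r)
        else:
            rid, seq = r
            recs.append(SeqRecord(Seq(str(seq)), id=rid, description=""))
    SeqIO.write(recs, str(path), "fasta")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV output (header row, empty string for NaN)."""
    df.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _fixture_bytes() -> bytes:
    return resources.files("concord.data").joinpath("table1.tsv").read_bytes()


def load_table1_fixture(verify: bool = True) -> pd.DataFrame:
    """The packaged goldfish dopamine-agonist protein/mRNA table.

    A literal transcription of the published 42-protein fold-change table
    (one row per protein/EST pairing, 45 rows; blank cells are absent
    values, asterisked duplicate rows carry ``starred=True``). The sha256
    of the packaged file is checked unless ``verify=False``.
    """
    raw = _fixture_bytes()
    if verify:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != TABLE1_SHA256:
            raise InputError(
                f"fixture checksum mismatch: {digest} != {TABLE1_SHA256}")
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), sep="\t")
    df["starred"] = df["starred"].astype(bool)
    df["mrna_acc"] = df["mrna_acc"].fillna("")
    df["mrna_name"] = df["mrna_name"].fillna("")
    for col in ("prot_fc_skf", "prot_fc_ly", "mrna_fc_skf", "mrna_fc_ly"):
        df[col] = pd.to_numeric(df[col], errors="raise")
        if (df[col].abs() < 1).any():
            raise InputError(f"fixture column {col} violates |FC| >= 1")
    return df[PAIR_COLUMNS]


def write_pair_table(table: pd.DataFrame, path: str | Path) -> None:
    write_table(table[PAIR_COLUMNS], path)


def read_pair_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"pair table missing columns {sorted(missing)}")
    df["starred"] = df["starred"].astype(bool)
    df["mrna_acc"] = df["mrna_acc"].fillna("")
    df["mrna_name"] = df["mrna_name"].fillna("")
    df["protein_name"] = df["protein_name"].fillna("")
    return df[PAIR_COLUMNS]


def frame_to_records(df: pd.DataFrame, id_col: str, seq_col: str):
    """Iterate (id, sequence) pairs from a DataFrame."""
    for _, row in df.iterrows():
        yield str(row[id_col]), str(row[seq_col])


def nan_to_none(obj):
    """Recursively convert NaN to None for JSON serialisation."""
    if isinstance(obj, dict):
        return {k: nan_to_none(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [nan_to_none(v) for v in obj]
    if isinstance(obj, (float, np.floating)) and np.isnan(obj):
        return None
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
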