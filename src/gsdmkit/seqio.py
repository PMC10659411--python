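"""FASTA and TSV input/output.

FASTA headers may carry record metadata as ``>id taxon=..;clade=..``;
plain headers simply yield empty metadata.  Metadata can alternatively be
supplied as a TSV table with columns ``id``, ``taxon``, ``clade``.
All files are plain text; FASTA output wraps sequence lines at 60
characters.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .records import ProteinRecord, SequenceError, check_unique_ids

_WRAP = 60


def _parse_metadata(description: str) -> dict[str, str]:
    # description is the full header; metadata lives after the first whitespace
    parts = description.split(None, 1)
    meta: dict[str, str] = {}
    if len(parts) == 2:
        for item in parts[1].split(";"):
            if "=" in item:
                key, value = item.split("=", 1)
                meta[key.strip()] = value.strip()
    return meta


def read_fasta(path: str | os.PathLike) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    The token before the first whitespace becomes the record id; the rest
    of the header is parsed as ``key=value`` pairs separated by ``;`` when
    present.  Duplicate ids and illegal sequence characters raise
    :class:`~gsdmkit.records.SequenceError`.
    """
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(os.fspath(path), "fasta"):
        meta = _parse_metadata(entry.description)
        records.append(
            ProteinRecord(
                id=entry.id,
                sequence=str(entry.seq),
                taxon=meta.get("taxon", ""),
                clade=meta.get("clade", ""),
            )
        )
    check_unique_ids(records)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | os.PathLike) -> None:
    """Write records as wrapped FASTA, embedding taxon/clade metadata."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.taxon or rec.clade:
                header += f" taxon={rec.taxon};clade={rec.clade}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), _WRAP):
                fh.write(rec.sequence[i : i + _WRAP] + "\n")


def read_metadata_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read an ``id``/``taxon``/``clade`` table."""
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"id", "taxon", "clade"}
    missing = required - set(table.columns)
    if missing:
        raise SequenceError(f"metadata table missing columns: {sorted(missing)}")
    return table


def write_metadata_tsv(records: Iterable[ProteinRecord], path: str | os.PathLike) -> None:
    rows = [{"id": r.id, "taxon": r.taxon, "clade": r.clade} for r in records]
    pd.DataFrame(rows, columns=["id", "taxon", "clade"]).to_csv(path, sep="\t", index=False)


def apply_metadata(records: list[ProteinRecord], table: pd.DataFrame) -> list[ProteinRecord]:
    """Return records with taxon/clade filled in from a metadata table."""
    lookup = {row["id"]: (row["taxon"], row["clade"]) for _, row in table.iterrows()}
    out = []
    for rec in records:
        taxon, clade = lookup.get(rec.id, (rec.taxon, rec.clade))
        out.append(ProteinRecord(rec.id, rec.sequence, taxon=taxon, clade=clade))
    return out
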