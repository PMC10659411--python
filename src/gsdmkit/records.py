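"""Core record type for protein sequences with taxon/clade metadata.

Every stage of the pipeline (curation, HMM scanning, motif extraction,
clade summaries) operates on :class:`ProteinRecord` objects.  Sequences
are amino-acid strings over the 20 standard residues plus ``X`` for
unknown/ambiguous positions; they are validated and uppercased at
construction time so downstream code never has to re-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


class SequenceError(ValueError):
    """Raised for malformed sequences or malformed sequence collections."""


@dataclass
class ProteinRecord:
    """One protein sequence plus its taxon and clade labels.

    ``clade`` is free-form metadata (e.g. ``"bird"``, ``"reptile"``,
    ``"decoy"``); it is not derived from any tree.
    """

    id: str
    sequence: str
    taxon: str = ""
    clade: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be nonempty")
        seq = self.sequence.upper()
        if not seq:
            raise SequenceError(f"record {self.id!r}: sequence must be nonempty")
        for pos, ch in enumerate(seq, start=1):
            if ch not in VALID_RESIDUES:
                raise SequenceError(
                    f"record {self.id!r}: illegal character {ch!r} at position {pos}"
                )
        self.sequence = seq

    def __len__(self) -> int:
        return len(self.sequence)


def check_unique_ids(records: list[ProteinRecord]) -> None:
    """Raise :class:`SequenceError` naming the first duplicated id, if any."""
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise SequenceError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
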