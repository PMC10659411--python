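"""Linker delimitation and caspase cleavage-site tetrapeptide analysis.

Gasdermins are two-domain proteins: an N-terminal pore-forming domain
held inactive by a C-terminal domain, joined by a cleavable linker
(structurally, the region between strand β11 and helix α5).  Proteases
activate a gasdermin by cutting after a linker aspartate (the P1
residue); caspase specificity is conventionally described by the
P4-P3-P2-P1 tetrapeptide ending at that aspartate, with the P1'/P2'
residues immediately downstream also informative (caspase-1 prefers a
bulky P4 and small P1', classically YVAD or FASD/FVSD with glycine at
P1' and proline at P2'; caspase-3 prefers DxxD, e.g. DEVD/DAVD).

This module projects reference structural boundaries through a family
alignment to delimit each member's linker, extracts one tetrapeptide
site per linker aspartate, classifies sites by caspase-1/-3 preference
rules, measures YVAD-likeness by BLOSUM62 similarity, summarizes sites
per clade, builds sequence-logo frequency/information matrices, and
computes Kyte–Doolittle hydropathy profiles (used to compare the
α7'–α8 interhelix region that mammal GSDMD uses as a caspase-1 exosite).

Coordinates are 1-based inclusive throughout, matching the standard
"FASD with P1 at residue 244" style of site notation.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align import GAP, MultipleAlignment, substitution_score
from .records import AMINO_ACIDS, ProteinRecord, SequenceError

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

BULKY_P4 = frozenset("FWYLIVM")
SMALL_P1_PRIME = frozenset("GAS")
DEFAULT_YVAD_THRESHOLD = 15.0

CASPASE1_LIKE = "caspase1_like"
CASPASE3_LIKE = "caspase3_like"
OTHER_ASP = "other_asp"

#: documented α7'–α8 interhelix ranges for the exosite hydropathy comparison
#: (1-based inclusive residue coordinates in the respective full-length protein)
HUMAN_GSDMD_ALPHA7P_ALPHA8 = (347, 380)
CHICKEN_GSDMA_ALPHA7P_ALPHA8 = (314, 347)

#: Kyte & Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


class MotifError(ValueError):
    pass


@dataclass
class ReferenceBoundaries:
    """Structural boundary annotation on one reference sequence.

    ``beta11_end`` and ``alpha5_start`` delimit the linker (exclusive on
    both sides); ``alpha7p_alpha8_range`` optionally marks the exosite
    interhelix region for hydropathy comparison, and ``nterm_range`` the
    window scanned for caspase-3 DxxD inactivation sites.
    """

    reference_id: str
    beta11_end: int
    alpha5_start: int
    alpha7p_alpha8_range: tuple[int, int] | None = None
    nterm_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.beta11_end >= self.alpha5_start:
            raise MotifError("beta11_end must precede alpha5_start")
        if self.beta11_end < 1:
            raise MotifError("boundaries are 1-based")
        for rng in (self.alpha7p_alpha8_range, self.nterm_range):
            if rng is not None and not 1 <= rng[0] <= rng[1]:
                raise MotifError(f"invalid range {rng}")


@dataclass
class LinkerAnnotation:
    """The interdomain linker of one sequence, in its own 1-based coordinates."""

    sequence_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise MotifError(f"invalid linker interval for {self.sequence_id!r}")


@dataclass
class TetrapeptideSite:
    """One P4..P1 window ending at an aspartate, with downstream context."""

    sequence_id: str
    tetrapeptide: str
    p1_position: int
    p1_prime: str = "X"
    p2_prime: str = "X"
    site_class: str = OTHER_ASP
    score: int = 0
    yvad_like: bool = False

    def __post_init__(self) -> None:
        if len(self.tetrapeptide) != 4 or self.tetrapeptide[-1] != "D":
            raise MotifError(
                f"tetrapeptide {self.tetrapeptide!r} must be 4 residues ending in D"
            )
        if self.p1_position < 1:
            raise MotifError("p1_position is 1-based")


@dataclass
class SequenceLogo:
    """Per-position residue frequencies and information content (bits)."""

    position_labels: list[str]
    frequency_matrix: np.ndarray  # (positions, 20)
    information_content: np.ndarray  # (positions,)
    n_sequences: int

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "position_labels": self.position_labels,
            "alphabet": AMINO_ACIDS,
            "frequency_matrix": self.frequency_matrix.tolist(),
            "information_content": self.information_content.tolist(),
            "n_sequences": self.n_sequences,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class CladeSummary:
    """Per-clade counts of caspase-1-like and YVAD-like carriers."""

    clade: str
    n_sequences: int
    n_with_caspase1_like: int
    n_yvad_like: int
    fraction_yvad_like: float


def project_boundaries(
    msa: MultipleAlignment, ref: ReferenceBoundaries
) -> dict[str, LinkerAnnotation | None]:
    """Project the reference linker boundaries onto every alignment row.

    The alignment columns holding the reference's ``beta11_end`` and
    ``alpha5_start`` residues are located; each row's linker is its
    ungapped residues strictly between those two columns, reported in
    that row's own 1-based coordinates.  Rows with no residue in the
    window map to ``None`` (reported, never an error).
    """
    try:
        ref_row = msa.row(ref.reference_id)
    except KeyError:
        raise MotifError(f"reference row {ref.reference_id!r} missing from alignment")
    residue = 0
    col_beta11 = col_alpha5 = None
    for col, ch in enumerate(ref_row):
        if ch != GAP:
            residue += 1
            if residue == ref.beta11_end:
                col_beta11 = col
            if residue == ref.alpha5_start:
                col_alpha5 = col
    if col_beta11 is None or col_alpha5 is None:
        raise MotifError("reference boundaries exceed the reference length")
    out: dict[str, LinkerAnnotation | None] = {}
    for rid, row in zip(msa.row_ids, msa.rows):
        before = sum(1 for ch in row[: col_beta11 + 1] if ch != GAP)
        inside = sum(1 for ch in row[col_beta11 + 1 : col_alpha5] if ch != GAP)
        if inside == 0:
            out[rid] = None
        else:
            out[rid] = LinkerAnnotation(rid, before + 1, before + inside)
    return out


def find_tetrapeptide_sites(
    record: ProteinRecord, linker: LinkerAnnotation
) -> list[TetrapeptideSite]:
    """One site per aspartate in the linker, ordered by P1 position.

    The tetrapeptide is the four residues ending at the aspartate,
    left-padded with ``X`` when the aspartate sits within the first
    three residues of the protein; P1'/P2' are read from the full
    sequence (``X`` past the C terminus), so sites at the linker's
    C-edge get their true downstream context.
    """
    seq = record.sequence
    if linker.end > len(seq):
        raise MotifError(f"linker exceeds sequence length for {record.id!r}")
    sites = []
    for pos in range(linker.start, linker.end + 1):  # 1-based
        if seq[pos - 1] != "D":
            continue
        window = seq[max(pos - 4, 0) : pos]
        tetra = "X" * (4 - len(window)) + window
        p1p = seq[pos] if pos < len(seq) else "X"
        p2p = seq[pos + 1] if pos + 1 < len(seq) else "X"
        sites.append(
            TetrapeptideSite(record.id, tetra, pos, p1_prime=p1p, p2_prime=p2p)
        )
    return sites


def classify_site(site: TetrapeptideSite) -> TetrapeptideSite:
    """Assign a caspase class and preference score to a site (in place).

    DxxD (aspartate at P4) is caspase-3-like; otherwise a bulky P4
    (F/W/Y/L/I/V/M) is caspase-1-like; anything else is a plain
    aspartate.  The score ranks caspase-1 plausibility from the
    P4/P1'/P2' preferences and is reported for ranking only — the class
    call is purely rule-based.
    """
    tetra = site.tetrapeptide
    if len(tetra) != 4 or tetra[-1] != "D":
        raise MotifError(f"malformed tetrapeptide {tetra!r}")
    p4 = tetra[0]
    if p4 == "D":
        site.site_class = CASPASE3_LIKE
    elif p4 in BULKY_P4:
        site.site_class = CASPASE1_LIKE
    else:
        site.site_class = OTHER_ASP
    score = 0
    if p4 in BULKY_P4:
        score += 2
    if site.p1_prime in SMALL_P1_PRIME:
        score += 2
    if site.p1_prime == "G":
        score += 1
    if site.p2_prime == "P":
        score += 1
    site.score = score
    site.yvad_like = is_yvad_like(site)
    return site


def yvad_similarity(tetrapeptide: str) -> float:
    """Summed BLOSUM62 similarity of a P4..P1 window against YVAD."""
    return sum(substitution_score(a, b) for a, b in zip(tetrapeptide, "YVAD"))


def is_yvad_like(
    site: TetrapeptideSite, threshold: float = DEFAULT_YVAD_THRESHOLD
) -> bool:
    """YVAD-likeness: BLOSUM62 similarity to YVAD >= ``threshold``.

    YVAD scores 21 against itself; the default cut of 15 admits close
    variants (e.g. YIAD at 20) while excluding FASD/FVSD-type sites.
    """
    return yvad_similarity(site.tetrapeptide) >= threshold


def scan_caspase3_nterm(
    record: ProteinRecord, nterm_range: tuple[int, int]
) -> list[TetrapeptideSite]:
    """DxxD tetrapeptides whose window lies inside ``nterm_range``.

    These model the caspase-3 inactivation site within the pore-forming
    N-terminal domain; the class is forced to caspase-3-like.
    """
    lo, hi = nterm_range
    seq = record.sequence
    if not 1 <= lo <= hi <= len(seq):
        raise MotifError(f"nterm_range {nterm_range} outside sequence {record.id!r}")
    sites = []
    for p4 in range(lo, hi - 2):  # 1-based position of P4; window is p4..p4+3
        window = seq[p4 - 1 : p4 + 3]
        if window[0] == "D" and window[3] == "D":
            pos = p4 + 3
            p1p = seq[pos] if pos < len(seq) else "X"
            p2p = seq[pos + 1] if pos + 1 < len(seq) else "X"
            site = TetrapeptideSite(
                record.id, window, pos, p1_prime=p1p, p2_prime=p2p,
                site_class=CASPASE3_LIKE,
            )
            sites.append(site)
    return sites


def build_logo(
    sites: Sequence[TetrapeptideSite], small_sample_correction: bool = True
) -> SequenceLogo:
    """Sequence logo over the P4..P1 positions of a site collection.

    Information content per position is ``log2(20) - H`` (Shannon
    entropy in bits) minus, when enabled, the small-sample correction
    ``e_n = (s - 1) / (2 ln 2 n)`` with s = 20; floored at zero.
    ``X`` placeholders are excluded from the frequency counts.
    """
    if not sites:
        raise MotifError("cannot build a logo from zero sites")
    n = len(sites)
    freq = np.zeros((4, 20))
    for site in sites:
        for pos, ch in enumerate(site.tetrapeptide):
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                freq[pos, idx] += 1.0
    totals = freq.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    freq = freq / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    entropy = -plogp.sum(axis=1)
    correction = (20 - 1) / (2 * math.log(2) * n) if small_sample_correction else 0.0
    ic = np.maximum(math.log2(20) - entropy - correction, 0.0)
    return SequenceLogo(["P4", "P3", "P2", "P1"], freq, ic, n)


def hydropathy_profile(sequence: str, window: int = 9) -> list[float]:
    """Sliding-window mean Kyte–Doolittle hydropathy.

    ``window`` must be odd and no longer than the sequence; ``X``
    contributes 0 (neutral).  Output length is ``len - window + 1``.
    """
    if window % 2 == 0 or window < 1:
        raise MotifError("window must be a positive odd integer")
    if window > len(sequence):
        raise MotifError("window longer than sequence")
    values = [KYTE_DOOLITTLE.get(ch, 0.0) for ch in sequence.upper()]
    out = []
    for i in range(len(values) - window + 1):
        out.append(sum(values[i : i + window]) / window)
    return out


def clade_summary(
    records: Sequence[ProteinRecord],
    sites_by_record: dict[str, Sequence[TetrapeptideSite]],
) -> list[CladeSummary]:
    """Per-clade counts; a record with several qualifying sites counts once."""
    clades: dict[str, list[ProteinRecord]] = {}
    for rec in records:
        clades.setdefault(rec.clade, []).append(rec)
    summaries = []
    for clade in sorted(clades):
        members = clades[clade]
        n_c1 = n_yvad = 0
        for rec in members:
            sites = sites_by_record.get(rec.id, [])
            if any(s.site_class == CASPASE1_LIKE for s in sites):
                n_c1 += 1
            if any(s.yvad_like for s in sites):
                n_yvad += 1
        n = len(members)
        summaries.append(
            CladeSummary(clade, n, n_c1, n_yvad, n_yvad / n if n else 0.0)
        )
    return summaries


def read_boundaries_yaml(path: str | os.PathLike) -> ReferenceBoundaries:
    """Load a structural-boundary annotation from flat YAML key-values."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    def _range(prefix: str):
        lo, hi = raw.get(f"{prefix}_start"), raw.get(f"{prefix}_end")
        return (int(lo), int(hi)) if lo and hi else None

    return ReferenceBoundaries(
        reference_id=raw["reference_id"],
        beta11_end=int(raw["beta11_end"]),
        alpha5_start=int(raw["alpha5_start"]),
        alpha7p_alpha8_range=_range("alpha7p_alpha8"),
        nterm_range=_range("nterm"),
    )


def write_boundaries_yaml(ref: ReferenceBoundaries, path: str | os.PathLike) -> None:
    import yaml

    raw: dict = {
        "reference_id": ref.reference_id,
        "beta11_end": ref.beta11_end,
        "alpha5_start": ref.alpha5_start,
    }
    if ref.alpha7p_alpha8_range:
        raw["alpha7p_alpha8_start"], raw["alpha7p_alpha8_end"] = ref.alpha7p_alpha8_range
    if ref.nterm_range:
        raw["nterm_start"], raw["nterm_end"] = ref.nterm_range
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# tabular output


def sites_to_frame(
    sites: Iterable[TetrapeptideSite], clades: dict[str, str] | None = None
) -> pd.DataFrame:
    rows = [
        {
            "sequence_id": s.sequence_id,
            "clade": (clades or {}).get(s.sequence_id, ""),
            "tetrapeptide": s.tetrapeptide,
            "p1_position": s.p1_position,
            "p1_prime": s.p1_prime,
            "p2_prime": s.p2_prime,
            "site_class": s.site_class,
            "score": s.score,
            "yvad_like": s.yvad_like,
        }
        for s in sites
    ]
    columns = [
        "sequence_id", "clade", "tetrapeptide", "p1_position", "p1_prime",
        "p2_prime", "site_class", "score", "yvad_like",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_sites_tsv(
    sites: Iterable[TetrapeptideSite],
    path: str | os.PathLike,
    clades: dict[str, str] | None = None,
) -> None:
    sites_to_frame(sites, clades).to_csv(path, sep="\t", index=False)


def write_clade_summaries_tsv(
    summaries: Sequence[CladeSummary], path: str | os.PathLike
) -> None:
    rows = [
        {
            "clade": s.clade,
            "n_sequences": s.n_sequences,
            "n_with_caspase1_like": s.n_with_caspase1_like,
            "n_yvad_like": s.n_yvad_like,
            "fraction_yvad_like": s.fraction_yvad_like,
        }
        for s in summaries
    ]
    columns = [
        "clade", "n_sequences", "n_with_caspase1_like", "n_yvad_like",
        "fraction_yvad_like",
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
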