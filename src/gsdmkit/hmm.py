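"""Profile hidden Markov models for gasdermin family detection.

A profile HMM is built from a curated family alignment (match/insert/
delete states with background-weighted pseudocounts) and scored against
candidate proteins in local mode: flanking residues outside the matched
core are emitted from the background at zero log-odds cost, entry is
allowed into any match state (uniform entry probability), and exit is
free from any match state.  Scores are log-odds bits against the
background distribution (uniform 1/20 by default), so an unrelated
sequence scores near or below zero while family members score high.

Nucleotide contigs are screened by translating all six reading frames,
splitting at stop codons, and scanning every ORF above a minimum length
— a desk-scale replacement for a TBLASTn/exonerate genome screen.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Seq import Seq
from numba import njit

from .align import GAP, MultipleAlignment
from .records import AMINO_ACIDS, ProteinRecord, SequenceError

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_NEG = -1.0e30

DEFAULT_GAP_THRESHOLD = 0.5
DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_BITS_THRESHOLD = 20.0
SCHEMA_VERSION = 1

NUCLEOTIDES = frozenset("ACGTN")


class HmmError(ValueError):
    pass


def assign_match_columns(msa: MultipleAlignment, gap_threshold: float = DEFAULT_GAP_THRESHOLD) -> list[int]:
    """Columns whose gap fraction is <= ``gap_threshold`` become match states."""
    if not 0.0 < gap_threshold < 1.0:
        raise HmmError("gap threshold must be in (0, 1)")
    fractions = msa.gap_fractions()
    columns = [j for j in range(msa.column_count) if fractions[j] <= gap_threshold]
    if not columns:
        raise HmmError("no match columns at this gap threshold")
    return columns


@dataclass
class ProfileHmm:
    """Match/insert/delete profile with log-odds scoring against a background.

    Transition arrays are indexed by source state; index 0 of the
    match-source arrays is the begin state, index ``n_match`` the final
    match state (whose M->M probability is the exit to the end state).
    """

    n_match: int
    match_emissions: np.ndarray  # (n_match, 20)
    insert_emissions: np.ndarray  # (n_match + 1, 20)
    background: np.ndarray  # (20,)
    t_mm: np.ndarray  # (n_match + 1,)  M_j -> M_{j+1} (j=0 is begin; j=k is exit)
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray  # (n_match + 1,)  I_j -> M_{j+1}
    t_ii: np.ndarray
    t_dm: np.ndarray  # (n_match + 1,)  D_j -> M_{j+1} (index 0 unused)
    t_dd: np.ndarray

    def __post_init__(self) -> None:
        if self.n_match < 1:
            raise HmmError("n_match must be >= 1")
        for name in ("match_emissions", "insert_emissions", "background"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if np.any(arr <= 0):
                raise HmmError(f"{name} must be strictly positive after pseudocounts")
        if np.max(np.abs(self.match_emissions.sum(axis=1) - 1.0)) > 1e-9:
            raise HmmError("match emission rows must sum to 1")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise HmmError("background must sum to 1")
        for name in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        sums = self.t_mm + self.t_mi + self.t_md
        if np.max(np.abs(sums - 1.0)) > 1e-9:
            raise HmmError("match-source transitions must sum to 1")
        if np.max(np.abs(self.t_im + self.t_ii - 1.0)) > 1e-9:
            raise HmmError("insert-source transitions must sum to 1")
        if np.max(np.abs((self.t_dm + self.t_dd)[1:] - 1.0)) > 1e-9:
            raise HmmError("delete-source transitions must sum to 1")

    # -- scoring helpers -------------------------------------------------
    def match_lod(self) -> np.ndarray:
        """(n_match, 20) log2-odds match emission scores."""
        return np.log2(self.match_emissions / self.background[None, :])

    def emission_scores(self, seq: str) -> np.ndarray:
        """(L, n_match) per-residue match scores; ``X`` scores 0 everywhere."""
        lod = self.match_lod()
        out = np.zeros((len(seq), self.n_match))
        for i, ch in enumerate(seq):
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                out[i, :] = lod[:, idx]
        return out

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "n_match": self.n_match,
            "alphabet": AMINO_ACIDS,
            "match_emissions": self.match_emissions.tolist(),
            "insert_emissions": self.insert_emissions.tolist(),
            "background": self.background.tolist(),
            "transitions": {
                name: getattr(self, name).tolist()
                for name in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd")
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "ProfileHmm":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("schema_version") != SCHEMA_VERSION:
            raise HmmError("unsupported profile schema version")
        return cls(
            n_match=payload["n_match"],
            match_emissions=np.array(payload["match_emissions"]),
            insert_emissions=np.array(payload["insert_emissions"]),
            background=np.array(payload["background"]),
            **{k: np.array(v) for k, v in payload["transitions"].items()},
        )


@dataclass
class HmmHit:
    """One scored segment: log-odds bits plus 1-based residue coordinates.

    ``frame`` is 0 for protein input, otherwise the reading frame
    (+1..+3 forward, -1..-3 reverse complement) of the translated ORF;
    coordinates are then in ORF amino-acid space.
    """

    sequence_id: str
    bit_score: float
    start: int
    end: int
    frame: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 1:
            raise HmmError("invalid hit coordinates")
        if not math.isfinite(self.bit_score):
            raise HmmError("non-finite bit score")


def build_profile(
    msa: MultipleAlignment,
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray | None = None,
) -> ProfileHmm:
    """Estimate a profile HMM from an alignment.

    Emissions are (counts + pseudocount * background) normalized;
    transitions are (counts + pseudocount) normalized over the allowed
    moves from each source state.  The background defaults to uniform
    1/20.
    """
    if background is None:
        background = np.full(20, 1.0 / 20.0)
    background = np.asarray(background, dtype=float)
    match_cols = assign_match_columns(msa, gap_threshold)
    k = len(match_cols)
    match_set = set(match_cols)
    em_counts = np.zeros((k, 20))
    ins_counts = np.zeros((k + 1, 20))
    c_mm = np.zeros(k + 1)
    c_mi = np.zeros(k + 1)
    c_md = np.zeros(k + 1)
    c_im = np.zeros(k + 1)
    c_ii = np.zeros(k + 1)
    c_dm = np.zeros(k + 1)
    c_dd = np.zeros(k + 1)
    col_to_state = {col: s + 1 for s, col in enumerate(match_cols)}
    for row in msa.rows:
        # walk the row as a state path: begin (M_0) .. end (M_{k+1})
        prev = ("M", 0)
        for j, ch in enumerate(row):
            if j in match_set:
                state = ("M", col_to_state[j]) if ch != GAP else ("D", col_to_state[j])
                if state[0] == "M" and ch in _AA_INDEX:
                    em_counts[state[1] - 1, _AA_INDEX[ch]] += 1
            else:
                if ch == GAP:
                    continue
                # insert state indexed by the last core state passed
                state = ("I", prev[1])
                if ch in _AA_INDEX:
                    ins_counts[state[1], _AA_INDEX[ch]] += 1
            src, dst = prev, state
            if src[0] == "M" and dst[0] == "M":
                c_mm[src[1]] += 1
            elif src[0] == "M" and dst[0] == "I":
                c_mi[src[1]] += 1
            elif src[0] == "M" and dst[0] == "D":
                c_md[src[1]] += 1
            elif src[0] == "I" and dst[0] == "M":
                c_im[src[1]] += 1
            elif src[0] == "I" and dst[0] == "I":
                c_ii[src[1]] += 1
            elif src[0] == "I" and dst[0] == "D":
                c_im[src[1]] += 1  # fold I->D into I->M (no I<->D transitions)
            elif src[0] == "D" and dst[0] == "M":
                c_dm[src[1]] += 1
            elif src[0] == "D" and dst[0] == "D":
                c_dd[src[1]] += 1
            elif src[0] == "D" and dst[0] == "I":
                c_dm[src[1]] += 1  # fold D->I into D->M
            prev = state
        # exit to end state
        if prev[0] == "M":
            c_mm[prev[1]] += 1
        elif prev[0] == "I":
            c_im[prev[1]] += 1
        else:
            c_dm[prev[1]] += 1

    pc = pseudocount
    match_em = em_counts + pc * background[None, :]
    match_em = match_em / match_em.sum(axis=1, keepdims=True)
    insert_em = ins_counts + pc * background[None, :]
    insert_em = insert_em / insert_em.sum(axis=1, keepdims=True)
    t_m = np.stack([c_mm + pc, c_mi + pc, c_md + pc])
    # the final match state cannot transition to a delete
    t_m[2, k] = 0.0
    t_m = t_m / t_m.sum(axis=0, keepdims=True)
    t_i = np.stack([c_im + pc, c_ii + pc])
    t_i = t_i / t_i.sum(axis=0, keepdims=True)
    t_d = np.stack([c_dm + pc, c_dd + pc])
    t_d[1, k] = 0.0
    with np.errstate(invalid="ignore"):
        t_d = t_d / t_d.sum(axis=0, keepdims=True)
    t_d[:, 0] = [1.0, 0.0]  # index 0 unused (no delete before the first column)
    return ProfileHmm(
        n_match=k,
        match_emissions=match_em,
        insert_emissions=insert_em,
        background=background,
        t_mm=t_m[0],
        t_mi=t_m[1],
        t_md=t_m[2],
        t_im=t_i[0],
        t_ii=t_i[1],
        t_dm=t_d[0],
        t_dd=t_d[1],
    )


def consensus(hmm: ProfileHmm) -> str:
    """Max-probability residue per match state (ties: alphabetical)."""
    return "".join(AMINO_ACIDS[int(i)] for i in np.argmax(hmm.match_emissions, axis=1))


# ---------------------------------------------------------------------------
# Viterbi / forward kernels


@njit(cache=True)
def _viterbi_kernel(emsc, lmm, lmi, lmd, lim, lii, ldm, ldd, entry):  # pragma: no cover
    L, k = emsc.shape
    M = np.full((L + 1, k + 1), _NEG)
    I = np.full((L + 1, k + 1), _NEG)
    D = np.full((L + 1, k + 1), _NEG)
    ptr_m = np.zeros((L + 1, k + 1), dtype=np.int8)  # 0 entry, 1 M, 2 I, 3 D
    ptr_i = np.zeros((L + 1, k + 1), dtype=np.int8)  # 0 M, 1 I
    ptr_d = np.zeros((L + 1, k + 1), dtype=np.int8)  # 0 M, 1 D
    best = _NEG
    best_i = 0
    best_j = 0
    for i in range(1, L + 1):
        for j in range(1, k + 1):
            score = entry
            choice = 0
            if j > 1:
                v = M[i - 1, j - 1] + lmm[j - 1]
                if v > score:
                    score = v
                    choice = 1
                v = I[i - 1, j - 1] + lim[j - 1]
                if v > score:
                    score = v
                    choice = 2
                v = D[i - 1, j - 1] + ldm[j - 1]
                if v > score:
                    score = v
                    choice = 3
            M[i, j] = emsc[i - 1, j - 1] + score
            ptr_m[i, j] = choice
            if M[i, j] > best:
                best = M[i, j]
                best_i = i
                best_j = j
            # insert after j (emission at background: score 0)
            vm = M[i - 1, j] + lmi[j]
            vi = I[i - 1, j] + lii[j]
            if vm >= vi:
                I[i, j] = vm
                ptr_i[i, j] = 0
            else:
                I[i, j] = vi
                ptr_i[i, j] = 1
            # delete state j (no emission), reachable from the left in-row
            if j > 1:
                vm = M[i, j - 1] + lmd[j - 1]
                vd = D[i, j - 1] + ldd[j - 1]
                if vm >= vd:
                    D[i, j] = vm
                    ptr_d[i, j] = 0
                else:
                    D[i, j] = vd
                    ptr_d[i, j] = 1
    return best, best_i, best_j, ptr_m, ptr_i, ptr_d


@njit(cache=True)
def _forward_kernel(emsc, lmm, lmi, lmd, lim, lii, ldm, ldd, entry):  # pragma: no cover
    L, k = emsc.shape
    M = np.full((L + 1, k + 1), _NEG)
    I = np.full((L + 1, k + 1), _NEG)
    D = np.full((L + 1, k + 1), _NEG)
    total = _NEG
    ln2 = 0.6931471805599453
    for i in range(1, L + 1):
        for j in range(1, k + 1):
            acc = entry
            if j > 1:
                for v in (M[i - 1, j - 1] + lmm[j - 1],
                          I[i - 1, j - 1] + lim[j - 1],
                          D[i - 1, j - 1] + ldm[j - 1]):
                    if v > _NEG / 2:
                        if v > acc:
                            acc = v + math.log1p(2.0 ** (acc - v)) / ln2
                        else:
                            acc = acc + math.log1p(2.0 ** (v - acc)) / ln2
            M[i, j] = emsc[i - 1, j - 1] + acc
            a = M[i - 1, j] + lmi[j]
            b = I[i - 1, j] + lii[j]
            if a >= b:
                I[i, j] = a + math.log1p(2.0 ** (b - a)) / ln2
            else:
                I[i, j] = b + math.log1p(2.0 ** (a - b)) / ln2
            if j > 1:
                a = M[i, j - 1] + lmd[j - 1]
                b = D[i, j - 1] + ldd[j - 1]
                if a >= b:
                    D[i, j] = a + math.log1p(2.0 ** (b - a)) / ln2
                else:
                    D[i, j] = b + math.log1p(2.0 ** (a - b)) / ln2
            v = M[i, j]
            if v > total:
                total = v + math.log1p(2.0 ** (total - v)) / ln2
            else:
                total = total + math.log1p(2.0 ** (v - total)) / ln2
    return total


def _transition_scores(hmm: ProfileHmm):
    with np.errstate(divide="ignore"):
        return tuple(
            np.log2(arr, out=np.full_like(arr, _NEG), where=arr > 0)
            for arr in (hmm.t_mm, hmm.t_mi, hmm.t_md, hmm.t_im, hmm.t_ii, hmm.t_dm, hmm.t_dd)
        )


def _traceback(ptr_m, ptr_i, ptr_d, best_i: int, best_j: int) -> list[tuple[str, int, int]]:
    """Recover the optimal core path ending at match cell (best_i, best_j).

    Returns (state, match-state index, residue position) triples in path
    order; delete states carry residue position 0.
    """
    path: list[tuple[str, int, int]] = []
    state, i, j = "M", best_i, best_j
    while True:
        path.append((state, j, i if state != "D" else 0))
        if state == "M":
            choice = int(ptr_m[i, j])
            if choice == 0:  # entry from the flank: path starts here
                break
            state = {1: "M", 2: "I", 3: "D"}[choice]
            i -= 1
            j -= 1
        elif state == "I":
            state = "M" if ptr_i[i, j] == 0 else "I"
            i -= 1
        else:  # D[i, j] came from M/D at (i, j-1); no residue consumed
            state = "M" if ptr_d[i, j] == 0 else "D"
            j -= 1
    path.reverse()
    return path


def viterbi(seq: str, hmm: ProfileHmm) -> tuple[float, list[tuple[str, int, int]]]:
    """Best local path; returns (bit score, path).

    The path is a list of (state, match-state index, residue position)
    triples covering the matched core; flanking residues are emitted from
    the background at zero cost and are not part of the path.
    """
    if not seq:
        raise HmmError("empty sequence")
    emsc = hmm.emission_scores(seq)
    entry = math.log2(1.0 / hmm.n_match)
    score, best_i, best_j, ptr_m, ptr_i, ptr_d = _viterbi_kernel(
        emsc, *_transition_scores(hmm), entry
    )
    return float(score), _traceback(ptr_m, ptr_i, ptr_d, best_i, best_j)


def forward(seq: str, hmm: ProfileHmm) -> float:
    """Log2 sum over all local paths (bits vs background); >= viterbi score."""
    if not seq:
        raise HmmError("empty sequence")
    emsc = hmm.emission_scores(seq)
    entry = math.log2(1.0 / hmm.n_match)
    return float(_forward_kernel(emsc, *_transition_scores(hmm), entry))


def _best_hit(seq_id: str, seq: str, hmm: ProfileHmm, frame: int = 0) -> HmmHit:
    emsc = hmm.emission_scores(seq)
    entry = math.log2(1.0 / hmm.n_match)
    score, best_i, best_j, ptr_m, ptr_i, ptr_d = _viterbi_kernel(
        emsc, *_transition_scores(hmm), entry
    )
    path = _traceback(ptr_m, ptr_i, ptr_d, best_i, best_j)
    start = path[0][2]  # entry is always into a match state
    return HmmHit(seq_id, float(score), max(start, 1), max(best_i, 1), frame)


def scan_proteins(
    hmm: ProfileHmm,
    records: Sequence[ProteinRecord],
    bits_threshold: float = DEFAULT_BITS_THRESHOLD,
) -> list[HmmHit]:
    """Best hit per record with bit score >= threshold, best first."""
    hits = []
    for rec in records:
        hit = _best_hit(rec.id, rec.sequence, hmm)
        if hit.bit_score >= bits_threshold:
            hits.append(hit)
    hits.sort(key=lambda h: (-h.bit_score, h.sequence_id))
    return hits


def six_frame_orfs(contig: str, min_orf_aa: int) -> list[tuple[str, int, str]]:
    """(orf_id_suffix, frame, peptide) for all six-frame ORFs >= min length."""
    contig = contig.upper()
    bad = set(contig) - NUCLEOTIDES
    if bad:
        raise HmmError(f"non-nucleotide characters in contig: {sorted(bad)}")
    orfs = []
    rc = str(Seq(contig).reverse_complement())
    for frame in (1, 2, 3, -1, -2, -3):
        source = contig if frame > 0 else rc
        offset = abs(frame) - 1
        sub = source[offset:]
        sub = sub[: len(sub) - len(sub) % 3]
        if not sub:
            continue
        peptide = str(Seq(sub).translate(table=1))
        for n, piece in enumerate(peptide.split("*")):
            if len(piece) >= min_orf_aa:
                orfs.append((f"frame{frame:+d}|orf{n}", frame, piece))
    return orfs


def six_frame_scan(
    contig_id: str,
    contig: str,
    hmm: ProfileHmm,
    min_orf_aa: int = 50,
    bits_threshold: float = DEFAULT_BITS_THRESHOLD,
) -> list[HmmHit]:
    """Scan all six reading frames of a nucleotide contig.

    ORFs (runs between stop codons) of at least ``min_orf_aa`` residues
    are scored; hit coordinates are in ORF amino-acid space with the
    reading frame recorded on the hit.
    """
    hits = []
    for suffix, frame, peptide in six_frame_orfs(contig, min_orf_aa):
        hit = _best_hit(f"{contig_id}|{suffix}", peptide, hmm, frame=frame)
        if hit.bit_score >= bits_threshold:
            hits.append(hit)
    hits.sort(key=lambda h: (-h.bit_score, h.sequence_id))
    return hits


def write_hits_tsv(hits: Sequence[HmmHit], path: str | os.PathLike) -> None:
    import pandas as pd

    rows = [
        {
            "sequence_id": h.sequence_id,
            "bit_score": h.bit_score,
            "start": h.start,
            "end": h.end,
            "frame": h.frame,
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=["sequence_id", "bit_score", "start", "end", "frame"]).to_csv(
        path, sep="\t", index=False
    )
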