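"""Dataset curation: redundancy clustering, 1-to-1 orthology, partial-row trimming.

Mirrors the standard comparative-genomics pre-processing of a protein
family catalog: CD-HIT-style greedy identity clustering to remove
redundant isoforms, reciprocal-best-hit (RBH) pairing to keep one
sequence per species pair, and trimAl-style removal of partial rows from
an alignment (rows covering less than half the alignment, or more than
half gaps; rows at exactly 50% are retained).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .align import GAP, MultipleAlignment, global_align, local_align
from .records import ProteinRecord, SequenceError

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY_THRESHOLD = 0.95
DEFAULT_RBH_MIN_SCORE = 50.0


@dataclass
class SequenceCluster:
    """One redundancy cluster; the representative is its longest member."""

    representative_id: str
    member_ids: list[str]


@dataclass
class OrthologPair:
    """A reciprocal-best-hit pair with its local-alignment score."""

    id_a: str
    id_b: str
    score: float


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical positions in the global alignment.

    The denominator is the length of the shorter sequence (the CD-HIT
    convention), so a perfect substring scores 1.0.
    """
    if not a or not b:
        raise SequenceError("pairwise_identity requires nonempty sequences")
    result = global_align(a, b)
    matches = sum(
        1
        for x, y in zip(result.aligned_a, result.aligned_b)
        if x == y and x != GAP
    )
    return matches / min(len(a), len(b))


def greedy_cluster(
    records: Sequence[ProteinRecord],
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> list[SequenceCluster]:
    """Greedy incremental clustering, longest sequence first.

    Each record joins the first existing cluster whose representative it
    matches at >= ``identity_threshold`` identity, else founds a new
    cluster.  Deterministic: sorting is by (length desc, id asc).
    """
    if not records:
        raise SequenceError("no records to cluster")
    if not 0.0 < identity_threshold <= 1.0:
        raise SequenceError("identity threshold must be in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    clusters: list[SequenceCluster] = []
    reps: list[ProteinRecord] = []
    for rec in ordered:
        placed = False
        for cluster, rep in zip(clusters, reps):
            if pairwise_identity(rec.sequence, rep.sequence) >= identity_threshold:
                cluster.member_ids.append(rec.id)
                placed = True
                break
        if not placed:
            clusters.append(SequenceCluster(rec.id, [rec.id]))
            reps.append(rec)
    return clusters


def reciprocal_best_hits(
    set_a: Sequence[ProteinRecord],
    set_b: Sequence[ProteinRecord],
    min_score: float = DEFAULT_RBH_MIN_SCORE,
) -> list[OrthologPair]:
    """1-to-1 ortholog pairs by mutual best local-alignment score.

    A pair (a, b) is emitted iff b is a's best hit in ``set_b`` and vice
    versa, and the score is >= ``min_score`` (a raw-score stand-in for a
    BLAST e-value cut).  Score ties are broken by lexicographic id and
    logged.
    """
    if not set_a or not set_b:
        return []
    scores: dict[tuple[str, str], float] = {}
    for rec_a in set_a:
        for rec_b in set_b:
            scores[(rec_a.id, rec_b.id)] = local_align(rec_a.sequence, rec_b.sequence).score

    def best_for(query_id: str, pool: Sequence[ProteinRecord], flip: bool) -> str:
        candidates = []
        for other in pool:
            key = (other.id, query_id) if flip else (query_id, other.id)
            candidates.append((-scores[key], other.id))
        candidates.sort()
        if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
            logger.info(
                "RBH tie for %s between %s and %s; choosing %s",
                query_id,
                candidates[0][1],
                candidates[1][1],
                candidates[0][1],
            )
        return candidates[0][1]

    best_a = {rec.id: best_for(rec.id, set_b, flip=False) for rec in set_a}
    best_b = {rec.id: best_for(rec.id, set_a, flip=True) for rec in set_b}
    pairs = []
    for rec in set_a:
        partner = best_a[rec.id]
        if best_b[partner] == rec.id and scores[(rec.id, partner)] >= min_score:
            pairs.append(OrthologPair(rec.id, partner, scores[(rec.id, partner)]))
    return pairs


def trim_partial(msa: MultipleAlignment) -> MultipleAlignment:
    """Remove partial rows from an alignment.

    A row is removed when its non-gap residue count is < 50% of the
    alignment length, or its gap fraction is > 50% (equivalent criteria,
    both strict, so the exact-50% boundary is retained).  Columns are
    left untouched.
    """
    width = msa.column_count
    keep_ids = []
    for rid, row in zip(msa.row_ids, msa.rows):
        residues = sum(1 for ch in row if ch != GAP)
        gap_fraction = (width - residues) / width
        if residues < 0.5 * width or gap_fraction > 0.5:
            logger.info("trim_partial: removing %s (%.0f%% gaps)", rid, 100 * gap_fraction)
            continue
        keep_ids.append(rid)
    if not keep_ids:
        raise SequenceError("empty alignment after trimming")
    return msa.subset_rows(keep_ids)


def write_clusters_tsv(clusters: Sequence[SequenceCluster], path: str | os.PathLike) -> None:
    rows = [
        {"representative_id": c.representative_id, "member_id": m}
        for c in clusters
        for m in c.member_ids
    ]
    pd.DataFrame(rows, columns=["representative_id", "member_id"]).to_csv(
        path, sep="\t", index=False
    )


def write_ortholog_pairs_tsv(pairs: Sequence[OrthologPair], path: str | os.PathLike) -> None:
    rows = [{"id_a": p.id_a, "id_b": p.id_b, "score": p.score} for p in pairs]
    pd.DataFrame(rows, columns=["id_a", "id_b", "score"]).to_csv(path, sep="\t", index=False)
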