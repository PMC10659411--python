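"""Worked example on synthetic stand-in sequences.

Chicken GSDMA is cleaved by caspase-1 after the P1 aspartate of its
linker FASD tetrapeptide (residue 244, mutating which — D244A —
abolishes cleavage); human GSDMD is cleaved after the P1 aspartate of
FLTD at residue 275.  The real proteins are NCBI records (chicken GSDMA
NP_001026532.1, human GSDMD NP_001159709.1) which this package does not
ship; instead, SYNTHETIC stand-ins are generated here with the same
coordinate structure: a pore-forming N-terminal domain, a linker whose
only caspase-1-compatible aspartate carries the documented tetrapeptide
at the documented position with the preferred downstream context, and a
C-terminal domain.  The point of the example is the machinery: a small
family is aligned, reference structural boundaries are projected
through the alignment, tetrapeptide sites are extracted and classified,
and the reported P1 coordinate must land exactly where the cleavage
site sits.
"""

from __future__ import annotations

import numpy as np

from .align import progressive_align
from .motifs import (
    CASPASE1_LIKE,
    ReferenceBoundaries,
    TetrapeptideSite,
    classify_site,
    find_tetrapeptide_sites,
    project_boundaries,
)
from .records import ProteinRecord
from .synthetic import _fill, _has_unplanted_bulky_p4_site, mutate_point

#: (name, N-domain length, pre-motif filler, tetrapeptide, context, post filler,
#:  C-domain length); P1 position = nterm + pre + 4
_SPECS = {
    "GgGSDMA_synthetic": (235, 5, "FASD", "GP", 19, 165),  # P1 at residue 244
    "HsGSDMD_synthetic": (265, 6, "FLTD", "GV", 18, 189),  # P1 at residue 275
}


def _build_standin(name: str, rng: np.random.Generator) -> tuple[ProteinRecord, ReferenceBoundaries]:
    nterm_len, pre, motif, context, post, cterm_len = _SPECS[name]
    nterm = _fill(nterm_len, rng)
    for _ in range(1000):
        linker = _fill(pre, rng) + motif + context + _fill(post, rng)
        planted_p1 = pre + len(motif)
        if not _has_unplanted_bulky_p4_site(nterm[-3:], linker, planted_p1):
            break
    cterm = _fill(cterm_len, rng)
    record = ProteinRecord(name, nterm + linker + cterm, taxon=name, clade="standin")
    boundaries = ReferenceBoundaries(
        reference_id=name,
        beta11_end=nterm_len,
        alpha5_start=nterm_len + len(linker) + 1,
    )
    return record, boundaries


def make_worked_example(
    seed: int = 0, n_relatives: int = 3, divergence: float = 0.04
) -> dict[str, tuple[list[ProteinRecord], ReferenceBoundaries]]:
    """Small synthetic families around the two stand-ins.

    Relatives are point-mutated copies with the tetrapeptide and its
    downstream context restored (the conserved feature of real linkers).
    """
    rng = np.random.default_rng(seed)
    out = {}
    for name in _SPECS:
        record, boundaries = _build_standin(name, rng)
        nterm_len, pre, motif, context, _post, _c = _SPECS[name]
        family = [record]
        for i in range(n_relatives):
            seq = mutate_point(record.sequence, divergence, rng)
            lo = nterm_len + pre
            seq = seq[:lo] + motif + context + seq[lo + len(motif) + len(context):]
            family.append(
                ProteinRecord(f"{name}_rel{i + 1}", seq, taxon=name, clade="standin")
            )
        out[name] = (family, boundaries)
    return out


def top_caspase1_site(
    family: list[ProteinRecord], boundaries: ReferenceBoundaries
) -> TetrapeptideSite:
    """Align the family, project the linker, return the reference's best
    caspase-1-like site (highest preference score, then smallest P1)."""
    msa = progressive_align(family)
    linkers = project_boundaries(msa, boundaries)
    reference = next(r for r in family if r.id == boundaries.reference_id)
    linker = linkers[reference.id]
    sites = [classify_site(s) for s in find_tetrapeptide_sites(reference, linker)]
    candidates = [s for s in sites if s.site_class == CASPASE1_LIKE]
    if not candidates:
        raise ValueError("no caspase-1-like site found")
    return sorted(candidates, key=lambda s: (-s.score, s.p1_position))[0]


def run_worked_example(seed: int = 0) -> dict[str, dict]:
    """Returns, per stand-in, the scanned P1 coordinate and tetrapeptide."""
    results = {}
    for name, (family, boundaries) in make_worked_example(seed).items():
        site = top_caspase1_site(family, boundaries)
        results[name] = {
            "p1_position": site.p1_position,
            "tetrapeptide": site.tetrapeptide,
            "p1_prime": site.p1_prime,
            "p2_prime": site.p2_prime,
            "site_class": site.site_class,
        }
    return results
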