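"""Synthetic gasdermin-like families with known ground truth.

The generator emulates the input universe of a genome screen at desk
scale: a clade-structured species tree (pure-birth within clades, long
stems between them), two-domain proteins whose conserved N- and
C-terminal domains evolve along the tree under a 20-state Jukes–Cantor
analog, a poorly conserved variable-length linker re-drawn per leaf,
clade-specific caspase tetrapeptides (e.g. YVAD in one bird sub-clade,
FASD/FVSD elsewhere) planted at a clade-constant linker position and
followed by the preferred Gly-Pro downstream context, unrelated decoy
proteins, and optional nucleotide contigs embedding back-translated
family members in known reading frames.

Every random draw flows from a single seeded generator, so a fixed
config + seed reproduces the bundle byte for byte.  Filler linkers are
rejection-sampled so they never contain an unplanted bulky-P4 aspartate
tetrapeptide: scanner precision against the truth tables is exact.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio.Data import CodonTable

from .motifs import BULKY_P4
from .phylo import write_newick
from .records import AMINO_ACIDS, ProteinRecord
from .seqio import write_fasta, write_metadata_tsv

MOTIF_CONTEXT = "GP"  # preferred P1'/P2' context planted after each motif

#: extra margin, in residues, for the aspartate-free junction zones flanking
#: the linker.  The structured boundary elements around the linker are
#: modelled without aspartates over a window of (linker-length spread +
#: margin) residues: alignment-based boundary projection can smear by up to
#: the difference in linker lengths, and keeping that zone aspartate-free
#: makes every caspase-compatible aspartate near a linker a planted one, so
#: scanner precision is exactly measurable against the truth tables.
JUNCTION_MARGIN = 2


def junction_buffer(linker_length_range: tuple[int, int]) -> int:
    lo, hi = linker_length_range
    return (hi - lo) + JUNCTION_MARGIN


class SyntheticError(ValueError):
    pass


@dataclass
class CladeSpec:
    """One clade: taxon count, its planted tetrapeptide, and carrier fraction."""

    name: str
    n_taxa: int
    planted_motif: str
    planted_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise SyntheticError("planted_fraction must be in [0, 1]")
        if self.n_taxa < 2:
            raise SyntheticError("each clade needs >= 2 taxa")
        if self.planted_motif[-1] != "D":
            raise SyntheticError("planted motifs must end in the P1 aspartate")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the observed gasdermin architecture: an N-terminal
    pore domain of ~230 residues (placing the linker near residue 240,
    as in chicken GSDMA), a 20-40 residue low-conservation linker, a
    ~180 residue C-terminal domain, and three caspase-1-cleavable
    clades carrying YVAD (bird), FASD (reptile) and FVSD (amphibian)
    tetrapeptides.  ``branch_scale`` converts tree time to expected
    substitutions per site.
    """

    seed: int = 0
    clades: list[CladeSpec] = field(
        default_factory=lambda: [
            CladeSpec("bird", 12, "YVAD", 1.0),
            CladeSpec("reptile", 12, "FASD", 1.0),
            CladeSpec("amphibian", 8, "FVSD", 1.0),
        ]
    )
    birth_rate: float = 1.0
    branch_scale: float = 0.3
    clade_stem_length: float = 3.0
    nterm_length: int = 230
    linker_length_range: tuple[int, int] = (20, 40)
    cterm_length: int = 180
    n_decoys: int = 20
    decoy_length_range: tuple[int, int] = (150, 400)
    include_orthologs: bool = True
    ortholog_sub_rate: float = 0.05
    include_contigs: bool = False
    contig_pad_range: tuple[int, int] = (30, 90)
    min_linker_for_motif: int = 8

    def __post_init__(self) -> None:
        if self.nterm_length <= 0 or self.cterm_length <= 0:
            raise SyntheticError("domain lengths must be positive")
        lo, hi = self.linker_length_range
        if lo < 1 or hi < lo:
            raise SyntheticError("invalid linker length range")
        for spec in self.clades:
            if len(spec.planted_motif) + len(MOTIF_CONTEXT) > lo:
                raise SyntheticError(
                    f"motif {spec.planted_motif!r} (+context) longer than the "
                    f"shortest allowed linker ({lo})"
                )


@dataclass
class PlantedSite:
    sequence_id: str
    p1_position: int
    tetrapeptide: str
    clade: str


@dataclass
class SyntheticTruth:
    """Ground truth for one generated dataset."""

    true_tree: dendropy.Tree
    family_ids: set[str]
    ortholog_pairs: list[tuple[str, str]]
    planted_sites: list[PlantedSite]
    linker_intervals: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for site in self.planted_sites:
            start, end = self.linker_intervals[site.sequence_id]
            if not start <= site.p1_position <= end:
                raise SyntheticError(
                    f"planted site for {site.sequence_id} outside its linker"
                )


def simulate_yule_tree(
    n_taxa: int,
    birth_rate: float,
    rng: np.random.Generator,
    labels: list[str] | None = None,
) -> dendropy.Tree:
    """Pure-birth (Yule) tree with exponential waiting times.

    Starting from two lineages at the root, each interval with k
    lineages lasts Exp(k * birth_rate); one uniformly chosen lineage
    then splits, until n_taxa lineages exist (the last interval runs at
    rate n_taxa * birth_rate).  Expected root-to-tip depth is
    sum_{k=2..n} 1 / (k * birth_rate).
    """
    if n_taxa < 2:
        raise SyntheticError("need at least two taxa")
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_taxa)]
    if len(labels) != n_taxa:
        raise SyntheticError("label count must equal n_taxa")
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    active = []
    for _ in range(2):
        child = dendropy.Node()
        child.edge.length = 0.0
        root.add_child(child)
        active.append(child)
    k = 2
    while True:
        wait = rng.exponential(1.0 / (k * birth_rate))
        for node in active:
            node.edge.length += wait
        if k == n_taxa:
            break
        idx = int(rng.integers(0, k))
        parent = active.pop(idx)
        for _ in range(2):
            child = dendropy.Node()
            child.edge.length = 0.0
            parent.add_child(child)
            active.append(child)
        k += 1
    order = rng.permutation(n_taxa)
    for node, pos in zip(active, order):
        node.taxon = taxa.get_taxon(labels[int(pos)])
    return tree


def jc20_p(t: float) -> float:
    """Expected site difference under the 20-state Jukes–Cantor analog."""
    return (19.0 / 20.0) * (1.0 - math.exp(-20.0 * t / 19.0))


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def evolve_protein(
    root_sequence: str,
    tree: dendropy.Tree,
    branch_scale: float,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Evolve a sequence down a tree; returns {leaf label: sequence}.

    Along a branch of substitution length t each site changes with
    probability p(t) = (19/20)(1 - exp(-20 t / 19)), replacement uniform
    over the 19 alternative residues.
    """
    sequences: dict[int, str] = {id(tree.seed_node): root_sequence.upper()}
    leaves: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = sequences[id(node.parent_node)]
        t = (node.edge.length or 0.0) * branch_scale
        p = jc20_p(t)
        seq = list(parent_seq)
        if p > 0:
            hits = np.nonzero(rng.random(len(seq)) < p)[0]
            for i in hits:
                current = seq[i]
                choices = [aa for aa in AMINO_ACIDS if aa != current]
                seq[i] = choices[int(rng.integers(0, 19))]
        child_seq = "".join(seq)
        sequences[id(node)] = child_seq
        if node.is_leaf():
            leaves[node.taxon.label] = child_seq
    return leaves


def simulate_clade_tree(config: SimulationConfig, rng: np.random.Generator) -> dendropy.Tree:
    """Clade-structured species tree: Yule within clades, long stems between."""
    labels = []
    subtree_newicks = []
    for spec in config.clades:
        clade_labels = [f"{spec.name}_t{i + 1:02d}" for i in range(spec.n_taxa)]
        labels.extend(clade_labels)
        sub = simulate_yule_tree(spec.n_taxa, config.birth_rate, rng, clade_labels)
        newick = write_newick(sub).replace("[&U] ", "").rstrip(";").strip()
        subtree_newicks.append(f"{newick}:{config.clade_stem_length}")
    combined = "(" + ",".join(subtree_newicks) + ");"
    tree = dendropy.Tree.get(data=combined, schema="newick")
    tree.is_rooted = True
    return tree


def _fill(length: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def _has_unplanted_bulky_p4_site(
    nterm_tail: str, linker: str, planted_p1_in_linker: int | None
) -> bool:
    """Any bulky-P4 aspartate tetrapeptide in the linker besides the planted one?

    The P4 lookback may extend into the last residues of the N domain.
    """
    context = nterm_tail + linker
    offset = len(nterm_tail)
    for i, ch in enumerate(linker):
        if ch != "D":
            continue
        if planted_p1_in_linker is not None and i == planted_p1_in_linker - 1:
            continue
        p4_index = offset + i - 3
        if p4_index >= 0 and context[p4_index] in BULKY_P4:
            return True
    return False


def plant_gasdermin(
    leaf_sequences: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[ProteinRecord], list[PlantedSite], dict[str, tuple[int, int]]]:
    """Assemble family proteins: evolved domains + drawn linker + planted motif.

    Leaf sequences must have length nterm_length + cterm_length; the
    linker is inserted between the two domains.  With probability
    ``planted_fraction`` the clade motif plus "GP" context is placed at
    a clade-constant offset; other linkers are rejection-sampled fillers
    with no bulky-P4 aspartate tetrapeptide at all.
    """
    nt, ct = config.nterm_length, config.cterm_length
    lo, hi = config.linker_length_range
    records: list[ProteinRecord] = []
    sites: list[PlantedSite] = []
    intervals: dict[str, tuple[int, int]] = {}
    clade_of = {
        f"{spec.name}_t{i + 1:02d}": spec
        for spec in config.clades
        for i in range(spec.n_taxa)
    }
    # clade-constant motif offset within the linker
    clade_offset: dict[str, int] = {}
    for spec in config.clades:
        max_pre = lo - len(spec.planted_motif) - len(MOTIF_CONTEXT)
        clade_offset[spec.name] = int(rng.integers(0, max_pre + 1))
    for label in sorted(leaf_sequences):
        seq = leaf_sequences[label]
        if len(seq) != nt + ct:
            raise SyntheticError(
                f"leaf sequence {label!r} has length {len(seq)}, expected {nt + ct}"
            )
        spec = clade_of[label]
        # aspartate-free junction zones (see junction_buffer)
        buffer = junction_buffer(config.linker_length_range)
        lo_zone = seq[nt - buffer : nt].replace("D", "E")
        hi_zone = seq[nt : nt + buffer].replace("D", "E")
        seq = seq[: nt - buffer] + lo_zone + hi_zone + seq[nt + buffer :]
        motif = spec.planted_motif
        length = int(rng.integers(lo, hi + 1))
        planted = bool(rng.random() < spec.planted_fraction)
        for _attempt in range(1000):
            if planted:
                pre = clade_offset[spec.name]
                post = length - pre - len(motif) - len(MOTIF_CONTEXT)
                linker = _fill(pre, rng) + motif + MOTIF_CONTEXT + _fill(post, rng)
                planted_p1 = pre + len(motif)
            else:
                linker = _fill(length, rng)
                planted_p1 = None
            if not _has_unplanted_bulky_p4_site(seq[nt - 3 : nt], linker, planted_p1):
                break
        else:  # pragma: no cover - rejection sampling virtually never exhausts
            raise SyntheticError("could not sample a clean linker")
        protein = seq[:nt] + linker + seq[nt:]
        records.append(
            ProteinRecord(label, protein, taxon=label, clade=spec.name)
        )
        intervals[label] = (nt + 1, nt + len(linker))
        if planted:
            sites.append(PlantedSite(label, nt + planted_p1, motif, spec.name))
    return records, sites, intervals


def make_decoys(
    n: int, length_range: tuple[int, int], rng: np.random.Generator
) -> list[ProteinRecord]:
    """Unrelated i.i.d. uniform-composition proteins, clade "decoy"."""
    lo, hi = length_range
    return [
        ProteinRecord(
            f"decoy_{i + 1:03d}",
            random_protein(int(rng.integers(lo, hi + 1)), rng),
            taxon="decoy",
            clade="decoy",
        )
        for i in range(n)
    ]


def mutate_point(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    hits = np.nonzero(rng.random(len(out)) < rate)[0]
    for i in hits:
        choices = [aa for aa in AMINO_ACIDS if aa != out[i]]
        out[i] = choices[int(rng.integers(0, 19))]
    return "".join(out)


def make_ortholog_sets(
    records: list[ProteinRecord], sub_rate: float, rng: np.random.Generator
) -> tuple[list[ProteinRecord], list[tuple[str, str]]]:
    """A mutated mirror of the family (ids suffixed ``_b``) plus truth pairs."""
    set_b = []
    pairs = []
    for rec in records:
        mutated = mutate_point(rec.sequence, sub_rate, rng)
        set_b.append(
            ProteinRecord(f"{rec.id}_b", mutated, taxon=rec.taxon, clade=rec.clade)
        )
        pairs.append((rec.id, f"{rec.id}_b"))
    return set_b, pairs


# ---------------------------------------------------------------------------
# nucleotide contigs

_CODON_FOR: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_FOR:
        table = CodonTable.unambiguous_dna_by_id[1]
        for codon, aa in sorted(table.forward_table.items()):
            _CODON_FOR.setdefault(aa, codon)  # alphabetically first codon wins
    return _CODON_FOR


def back_translate(protein: str) -> str:
    """Deterministic back-translation (alphabetically first codon per residue)."""
    table = _codon_table()
    return "".join(table[aa] for aa in protein)


def _random_nt(length: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def make_contig(
    record: ProteinRecord,
    frame: int,
    rng: np.random.Generator,
    pad_range: tuple[int, int] = (30, 90),
) -> str:
    """Embed a back-translated protein in random sequence at a known frame."""
    if frame not in (1, 2, 3, -1, -2, -3):
        raise SyntheticError("frame must be in +-1..3")
    cds = back_translate(record.sequence)
    lo, hi = pad_range
    pad5 = int(rng.integers(lo, hi + 1))
    pad5 += (abs(frame) - 1 - pad5) % 3  # align the CDS to the requested frame
    pad3 = int(rng.integers(lo, hi + 1))
    contig = _random_nt(pad5, rng) + cds + _random_nt(pad3, rng)
    if frame < 0:
        from Bio.Seq import Seq

        contig = str(Seq(contig).reverse_complement())
    return contig


# ---------------------------------------------------------------------------
# the bundle


def generate_dataset(
    config: SimulationConfig, out_dir: str | os.PathLike | None = None
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Generate records + truth; optionally write the full file bundle.

    The bundle contains proteins.fasta (family + decoys), metadata.tsv,
    truth_sites.tsv, truth_linkers.tsv, truth_orthologs.tsv + the
    mirrored ortholog FASTA (when enabled), true_tree.nwk, contigs.fasta
    (when enabled) and manifest.json echoing the config and seed.
    """
    rng = np.random.default_rng(config.seed)
    tree = simulate_clade_tree(config, rng)
    root = random_protein(config.nterm_length + config.cterm_length, rng)
    leaves = evolve_protein(root, tree, config.branch_scale, rng)
    family, planted, intervals = plant_gasdermin(leaves, config, rng)
    decoys = make_decoys(config.n_decoys, config.decoy_length_range, rng)
    ortho_b: list[ProteinRecord] = []
    pairs: list[tuple[str, str]] = []
    if config.include_orthologs:
        ortho_b, pairs = make_ortholog_sets(family, config.ortholog_sub_rate, rng)
    contigs: list[tuple[str, int, str]] = []
    if config.include_contigs:
        frames = [1, 2, 3, -1, -2, -3]
        for i, rec in enumerate(family):
            frame = frames[i % 6]
            contigs.append(
                (f"contig_{rec.id}", frame, make_contig(rec, frame, rng, config.contig_pad_range))
            )
    truth = SyntheticTruth(
        true_tree=tree,
        family_ids={r.id for r in family},
        ortholog_pairs=pairs,
        planted_sites=planted,
        linker_intervals=intervals,
    )
    records = family + decoys
    if out_dir is not None:
        _write_bundle(config, records, ortho_b, contigs, truth, out_dir)
    return records, truth


def _write_bundle(config, records, ortho_b, contigs, truth, out_dir) -> None:
    import pandas as pd

    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    write_fasta(records, os.path.join(out, "proteins.fasta"))
    write_metadata_tsv(records, os.path.join(out, "metadata.tsv"))
    family = [r for r in records if r.id in truth.family_ids]
    write_fasta(family, os.path.join(out, "seed_family.fasta"))
    pd.DataFrame(
        [dataclasses.asdict(s) for s in truth.planted_sites],
        columns=["sequence_id", "p1_position", "tetrapeptide", "clade"],
    ).to_csv(os.path.join(out, "truth_sites.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [
            {"sequence_id": sid, "start": start, "end": end}
            for sid, (start, end) in sorted(truth.linker_intervals.items())
        ],
        columns=["sequence_id", "start", "end"],
    ).to_csv(os.path.join(out, "truth_linkers.tsv"), sep="\t", index=False)
    with open(os.path.join(out, "true_tree.nwk"), "w") as fh:
        fh.write(write_newick(truth.true_tree) + "\n")
    if ortho_b:
        write_fasta(ortho_b, os.path.join(out, "orthologs_b.fasta"))
        pd.DataFrame(
            truth.ortholog_pairs, columns=["id_a", "id_b"]
        ).to_csv(os.path.join(out, "truth_orthologs.tsv"), sep="\t", index=False)
    if contigs:
        with open(os.path.join(out, "contigs.fasta"), "w") as fh:
            for cid, frame, seq in contigs:
                fh.write(f">{cid} frame={frame}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
    manifest = {
        "tool": "gsdmkit",
        "seed": config.seed,
        "config": _config_dict(config),
        "n_records": len(records),
        "n_family": len(truth.family_ids),
        "n_planted_sites": len(truth.planted_sites),
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _config_dict(config: SimulationConfig) -> dict:
    raw = dataclasses.asdict(config)
    return json.loads(json.dumps(raw, default=list))
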