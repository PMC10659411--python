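# Methods

This note documents the models, rules, parameters and numerical choices in
`gsdmkit`, and what its synthetic-data validation does and does not show.

## Scope and design stance

The package reimplements, at desk scale, the analytic core of a
comparative-genomics study of the gasdermin family: curating a protein
catalog, detecting family members with a profile HMM, placing them on a
tree, delimiting the interdomain linker, and classifying the caspase
cleavage tetrapeptides found there.  Heavy inference surrounding that core
is deliberately replaced by standard desk-scale surrogates: neighbor joining
on corrected distances instead of maximum-likelihood/Bayesian tree building
(so all phylogenetic claims are topology-level — monophyly, Robinson–Foulds
— never divergence times or posterior supports), a progressive profile
aligner instead of Clustal Omega/MAFFT (downstream code only needs a
reasonable family alignment), and raw local-alignment score thresholds
instead of BLAST e-values (e-value calibration is out of scope).

## Curation rules

- **Identity clustering.** Greedy incremental clustering, longest sequence
  first; a record joins the first cluster whose representative it matches at
  ≥ 0.95 identity (configurable).  Identity = exact matches in the global
  alignment divided by the shorter sequence's length (the CD-HIT
  convention), so fragments of a longer sequence cluster with it.
- **Reciprocal best hits.** Local-alignment scores (BLOSUM62, affine gaps);
  a pair is kept iff each member is the other's best cross-set hit and the
  score is ≥ 50 (configurable).  Ties break lexicographically and are
  logged.
- **Partial-row trimming.** A row is removed when its residue count is
  < 50% of the alignment length or its gap fraction is > 50%.  Both
  inequalities are strict: a row at exactly 50% is retained.  Trimming
  never touches columns and is idempotent.

## Alignment

Pairwise global/local alignment is Biopython's `PairwiseAligner` with
BLOSUM62; `X` scores 0 against everything.  A gap of length L costs
`open + L·extend` with open = 11, extend = 1 (BLAST-like defaults,
configurable).  The multiple aligner builds a UPGMA guide tree from 3-mer
distances (`1 − shared/min` on k-mer sets) and merges profiles in
post-order; profile columns are scored by average-linkage expected
substitution score (residue frequencies excluding gaps), with the same
affine gap costs and a fixed diagonal > up > left traceback tie-break.
Every construction asserts that de-gapping a row reproduces its source
sequence.

## Profile HMM

Match columns are alignment columns with gap fraction ≤ 0.5.  Emissions are
`(counts + pseudocount × background)` normalized (pseudocount 1.0,
background uniform 1/20 for testability; both configurable); transitions are
`(counts + pseudocount)` normalized over the allowed moves (M→M/I/D, I→M/I,
D→M/D; the rare I↔D moves are folded into I→M / D→M).  Scoring is
local-mode log2-odds against the background: flanking residues cost 0,
entry into any match state costs `log2(1/n_match)`, exit from any match
state is free, and insert emissions equal the background (cost 0, transition
costs still apply).  Viterbi and forward share one kernel structure
(max vs log-sum-exp); both are verified against exhaustive path enumeration
on small models, and `forward ≥ viterbi` holds by construction.  The default
reporting threshold is 20 bits; on default synthetic conditions family
members score several hundred bits and decoys below zero, so the threshold
is not delicate.  Contigs are screened by translating all six frames
(standard code), splitting at stops, and scanning every ORF of ≥ 50
residues; hit coordinates are reported in ORF amino-acid space with the
frame recorded.  HMMER file-format compatibility and e-value calibration are
non-goals.

## Phylogenetics

Distances: `d = −ln(1 − p)` with p the mismatch fraction over pairwise
ungapped columns (gapped columns excluded pairwise, not listwise); p is
capped at 0.95, logged when applied, to keep distances finite.  Under the
generator's 20-state substitution model this Poisson correction
underestimates long paths slightly (about −3.5% at one substitution/site),
which stays inside the 5% recovery tolerance the validation asserts.
Neighbor joining follows Saitou–Nei with the Studier–Keppler Q criterion;
ties pick the lowest index pair, and negative branch lengths are clamped to
zero with the deficit logged.  Midpoint rooting locates the diameter path
explicitly so that a midpoint falling exactly on an internal node still
yields a bifurcating root.  Monophyly requires a rooted tree and an exact
leaf-set match at some node.

## Linker and tetrapeptide analysis

Reference boundaries (the β11-end and α5-start residue indices of one
reference sequence) are configuration inputs, not hard-coded: structural
boundaries come from per-structure modeling and are supplied per dataset.
The α7′–α8 interhelix ranges used for hydropathy comparison default to
human GSDMD residues 347–380 and chicken GSDMA residues 314–347.  The
reference's boundary residues are located in alignment columns; every other
row's linker is its ungapped residues strictly between those columns,
reported in that row's own 1-based coordinates (rows with an empty window
get a null annotation, never an error).

For every linker aspartate: the tetrapeptide is the four residues ending at
the aspartate (left-padded with `X` when within three residues of the N
terminus, preserving the one-site-per-aspartate invariant), and P1′/P2′ are
read from the full protein so sites at the linker's C-edge get true
downstream context.  Classification is rule-based and total over the 8,000
D-terminal tetrapeptides:

- P4 = D → caspase-3-like (DxxD);
- else P4 ∈ {F, W, Y, L, I, V, M} → caspase-1-like (bulky P4; M and W are
  included with the aromatics/branched aliphatics by physicochemical class,
  configurable);
- else → plain aspartate.

A separate integer score (2·[bulky P4] + 2·[P1′ ∈ {G,A,S}] + 1·[P1′ = G] +
1·[P2′ = P]) ranks caspase-1 plausibility for reporting; it never changes
the class.  "YVAD-like" is operationalized as summed BLOSUM62 similarity to
YVAD ≥ 15 (YVAD itself scores 21, YIAD 20, FVSD 14), with the threshold
exposed in configuration and output so sensitivity can be explored.
Caspase-3 inactivation-site scanning looks for DxxD windows inside a
configured N-terminal range.  Logos report per-position frequencies and
`IC = log2(20) − H − e_n`, with the small-sample correction
`e_n = (s−1)/(2·ln2·n)`, s = 20, floored at zero; `X` placeholders are
excluded from counts.  Clade summaries count each record once regardless of
how many qualifying sites it carries; clade labels are metadata, not
tree-derived.

## Synthetic data generator

The generator emulates the study's input universe at desk scale with exact
ground truth:

- **Tree.** One pure-birth (Yule) tree per clade (exponential waiting times,
  rate k·λ with k current lineages; expected root-to-tip depth
  Σ_{k=2..n} 1/(kλ)), joined by stems of 3.0 time units; branch lengths
  convert to substitutions via `branch_scale` (default 0.3/unit).
- **Substitution model.** 20-state Jukes–Cantor analog: along a branch of
  length t each site differs from its parent with probability
  `p(t) = (19/20)(1 − e^(−20t/19))`, replacement uniform over the 19
  alternatives.  Chosen over WAG/LG because the closed form makes every
  statistical check analytic; the generator tests pipeline correctness, not
  empirical realism.
- **Architecture.** Conserved N-domain (230 aa) and C-domain (180 aa) evolve
  along the tree; the linker (uniform 20–40 aa) is re-drawn per leaf to
  mimic observed low linker conservation, placing the linker near residue
  240 as in chicken GSDMA.  Default clades: bird (12 taxa, YVAD), reptile
  (12, FASD), amphibian (8, FVSD), all with planting fraction 1.0, matching
  the observation that these clades carry caspase-1-compatible linker
  tetrapeptides.
- **Planting.** With probability `planted_fraction` the clade motif plus the
  preferred Gly-Pro context is inserted at a clade-constant linker offset
  and recorded in the truth tables; other linkers are rejection-sampled so
  they contain no bulky-P4 aspartate tetrapeptide at all.  The structured
  boundary elements flanking the linker are additionally modelled
  aspartate-free over a window equal to the linker-length spread plus two
  residues on each side: alignment-based boundary projection can smear by up
  to the difference in linker lengths, and an aspartate-free junction zone
  guarantees that every caspase-compatible aspartate near a linker is a
  planted one, making scanner precision exactly measurable.
- **Decoys and contigs.** Decoys are i.i.d. uniform-composition proteins
  (20 by default, 150–400 aa).  Optional contigs embed back-translated
  family members (alphabetically first codon per residue, for determinism)
  in random nucleotide padding at recorded reading frames.
- **Determinism.** All draws flow from one `numpy` generator seeded by the
  config; a fixed config + seed reproduces the output bundle byte for byte.

What passing on this generator does **not** show: robustness to indels
within domains (not simulated), to empirically realistic substitution
processes, to gene duplication/loss, or to the annotation noise of real
genome screens.  The generator's clean domain–linker junctions in
particular mean real-data precision will depend on boundary-projection
quality that is only exercised here under smear of a few residues.

## Validation experiments and problem sizes

`gsdmkit.evaluation` runs the actual pipeline against generator truth.  The
multi-seed sweeps use a scaled-down configuration (domains 60/50 aa, linkers
10–20 aa, clades of 6/6/4, 20 seeds) — the package's chosen validation
conditions, keeping a full sweep under a minute while preserving clade
structure, branch scale and planting.  Measured on these conditions: clade
monophyly recovered in 20/20 seeds, planted-site recall 320/320 with zero
false caspase-1 calls, and Poisson-distance bias under 5% for paths up to
one substitution/site (10,000 sites, five replicates).  The YVAD-fraction
experiment plants YVAD in 30% of a 100-species bird clade simulated as a
radiation (birth rate 10, keeping within-clade domain divergence modest, as
for real bird gasdermin domains — a single-clade Yule tree at rate 1 would
be ~4 substitutions/site deep and saturate the domains) and aggregates five
replicate clades; the recovered YVAD-like fraction is compared against the
95% binomial interval of 0.30.

## Known limitations

- The aligner is O(L²) per merge and intended for ≤ ~200 sequences.
- Forward/Viterbi operate on whole sequences; there is no multi-hit
  (domain-repeat) decomposition.
- NJ is consistent on additive matrices but offers no support values.
- Boundary projection assumes the reference's domain flanks align reliably;
  heavily saturated alignments degrade linker delimitation before they
  degrade classification.
- The caspase rules are sequence-level preferences; they deliberately do not
  model exosite-driven cleavage (mammal GSDMD's tetrapeptide-independent
  recognition by caspase-1), which is a structural phenomenon outside a
  sequence scanner's reach.
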