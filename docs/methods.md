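# Methods

## Scope and record model

`plasmidnet` characterizes small circular replicons. Coordinates are 1-based
inclusive throughout; a span with `start > end` runs forward through the
sequence origin and is legal only on circular records (a REP module written
`2,670–2,399` on a 3,124-bp plasmid is one 2,854-bp forward fragment).
Sequences are uppercased on read and restricted to `{A,C,G,T,N}`, failing
fast on alphabet errors. GenBank and FASTA IO go through Biopython; an
origin-spanning CDS `join` is folded into a single feature with
`start > end`. Deposited translations are never silently recomputed.

## Iteron detection

The *oriV* of theta-replicating Rep_3 plasmids carries a tandem array of
iterons (direct repeats, typically ~20–22 bp, usually four copies) bound by
the Rep initiator. The detector scans a window (default 500 bp) immediately
5′ of the *rep* start codon on the coding strand, wrapping through the
origin when needed.

For every unit length in `unit_range` (default 18–24 bp) and every start
position, an array is grown greedily to the right, accepting the next
adjacent copy while every copy stays within
`floor(max_mismatch_frac · unit_length)` mismatches of the column-majority
consensus (majority ties break alphabetically). Defaults: `min_copies = 3`
(one fewer than the canonical four, so degraded arrays still surface — copy
count is in the output for filtering), `max_mismatch_frac = 0.15`,
`max_spacer = 0` ("tandem" means adjacent; a spacer up to 10 bp can be
allowed). Reported arrays are maximal — not extendable by another
qualifying copy on either side — and overlapping candidates are resolved
deterministically: highest copy count, then lowest mean mismatch fraction,
then smallest unit, then leftmost. Candidate units with fewer than three
distinct bases are suppressed as low-complexity (homopolymers and
dinucleotide repeats otherwise flood the output). Both strands are
searched; because the reverse complement of a tandem array is itself a
tandem array, a minus-strand call overlapping a plus-strand call is
collapsed to the plus-strand one.

Each array is summarized as a degenerate consensus: per column, the set of
observed bases ordered by descending count then alphabetically, rendered as
the plain base for invariant columns and `(X/Y)` for variable ones.
Rendering and parsing are exact inverses, and the expanded length always
equals the unit length.

At 5% per-base noise on four 22-bp copies, the probability that one copy
exceeds the 3-mismatch budget is ≈1.5%, so exact recovery of (unit length,
copy count) plateaus near 95% — the detector is at its information-theoretic
ceiling there, not under-tuned.

## Restriction screening

Recognition sites are matched by exact IUPAC expansion on both strands;
minus-strand hits are reported at the plus-strand start of the
reverse-complemented site, so the 13 default palindromic six-cutters yield
one position per physical site. A circular scan appends the first
`|site|−1` bases to catch origin-spanning sites; positions stay within the
fragment. The default panel (BamHI, EcoRI, EcoRV, HindIII, KpnI, NcoI,
NheI, PstI, SacI, SalI, SphI, XbaI, XhoI) is the set of six-cutters common
in vector multiple-cloning sites; a user TSV overrides it.

A module screen extracts the (possibly wrapping) region from the circular
plasmid and then scans the fragment as **linear** DNA: a module cloned into
a vector is interrupted at its ends, so a site spanning the junction would
not exist in the construct. The enzyme panel is partitioned into cutting
(with 1-based fragment positions) and non-cutting; the non-cutting count is
the module's "availability" for vector design.

## Protein comparison and the similarity network

Pairwise comparison is optimal gapped local alignment (Smith–Waterman) under
BLOSUM62 with BLAST-style affine gaps: a gap of length k costs
`gap_open + k·gap_extend` (defaults 11/1). The engine is Biopython's
`PairwiseAligner`; the test suite cross-checks its scores exactly against an
independent hand-written Gotoh dynamic program on hundreds of short pairs.
Statistics are taken from the single best-scoring HSP — no HSP tiling, the
simplest faithful reading of per-HSP coverage:

- **identity** — identical aligned pairs / aligned columns;
- **positives** — aligned pairs with positive substitution score / aligned
  columns (what BLAST prints as "similarity"); positives ≥ identity by
  construction;
- **coverage** — aligned span of the shorter protein / its length. The
  denominator choice is symmetric, matching the reciprocated-edge
  semantics; per-direction query and subject coverage are stored alongside.
- **E-value** — Karlin–Altschul `E = K·m·n·exp(−λS)` with the published
  gapped BLOSUM62/11/1 parameters λ = 0.267, K = 0.041. It is a similarity
  filter here, not a database-search statistic, so no edge-effect or
  composition corrections are applied; both parameters are configurable.

The network joins *p* and *q* iff **both** directed hits pass E ≤ 1e-10,
identity ≥ 0.30 and coverage ≥ 0.90 (thresholds apply per direction), with
edge weight the mean over directions of identity × coverage — under the
defaults every edge weight lies in [0.27, 1]. Since the local alignment and
the min-length coverage are symmetric, the two directions coincide up to
E-value bookkeeping, but both are checked as specified. Components are
connected components of the edge set; singleton proteins remain singleton
components. Classification assigns a query the label of its best-scoring
reference hit at E ≤ 1e-2 (ties: higher identity, then lexicographic
reference id), or "unclassified". Graphs export to GraphML or an edge TSV
for external layout (e.g. Gephi); no layout is computed here.

## Synthetic data: what it emulates and what it does not

The generator assembles circular plasmids from i.i.d. background DNA at a
requested GC (realized within about ±2 points at kb scale), planting: a rep
ORF (ATG + non-stop codons + TAA; stop codons hit during sampling have only
their third base resampled, keeping composition on target) with an upstream
tandem iteron array (explicit or random unit, per-copy substitution
probability), a mob ORF, recognition sites at recorded positions, and
optionally a REP region scrubbed free of an enzyme panel's sites. All
randomness flows from one explicitly seeded NumPy generator per call;
identical inputs and seed give byte-identical output. Ground truth
(iteron coordinates and copies, planted sites, module regions, family
labels) is serializable to JSON and suffices to score every detector.

Protein families descend from independent random ancestors (or, when a
between-family identity above the ~5% random background is requested, from
a common root). Two lineages that independently substitute a fraction *d*
of positions retain pairwise identity ≈ (1−d)², so per-lineage divergence
for a pairwise target *t* is d = 1 − √t. `mutate_to_identity` applies an
exact substitution count `round((1−t)·L)`; its `mode="similarity"` variant
draws replacements only from residues scoring ≤ 0 against the original in
BLOSUM62, so the target governs percent positives instead — used to plant
relaxase pairs at published reciprocal-similarity levels (87% / 74%).

The generator deliberately omits indels, recombination, codon bias and
repeat-rich backgrounds. Passing tests therefore demonstrate correctness of
the detectors' logic and calibration under their own model assumptions, not
robustness to rearranged or compositionally skewed natural sequence. In
particular, synthetic REP modules are random-background DNA, so their
restriction-site counts follow Poisson statistics (~7–9 of 13 enzymes
available on kb-scale modules) rather than the site-poor character of real
AT-rich replicon modules.

## Pipeline and packaged study data

`run_characterization` chains classification → iteron hunt → restriction
screen → network and emits a per-replicon table (id, size, GC, gene count,
modules), a screen table, an iteron table and a network summary, all
deterministic for fixed inputs; per-replicon stage failures are recorded in
provenance, never fatal. Screen regions come from a user file when given,
else each rep-annotated gene ± 300 bp. Family counts are per *plasmid*: a
composite replicon with two replication systems counts once in each family.

Published values for the *Psychrobacter* sp. ANT_H3 plasmid set — per-plasmid
size/GC/gene counts, the origin-wrapping REP-module coordinates, and the
eight oriV iteron consensus strings (six 22-bp, one 21-bp, one 20-bp) — ship
as small packaged TSVs. `build_ant_h3_like_set` turns the table into eleven
synthetic look-alike records for pipeline exercises at the study's scale.

## Problem sizes and numerical choices

Test and acceptance workloads are sized for a single CPU: the planted-array
recovery statistic uses 60 seeded 3-kb plasmids; the alignment oracle check
200 short pairs; the network oracle ≤10 proteins of 250 residues; family
recovery 4×5 proteins of 300 residues; restriction oracles three 3-kb
fragments × 4 enzymes × both topologies. GC is reported to one decimal with
N bases excluded from numerator and denominator (all-N input is an error).
All tie-breaks (consensus base order, overlap resolution, classification)
are total orders, making every output deterministic.

## Known limitations

- No HSP tiling: a pair similar over two disjoint segments but not one HSP
  fails the 90% coverage filter.
- The E-value estimator ignores finite-size edge corrections; near-threshold
  decisions can differ from BLAST's, and shuffled-sequence queries pass the
  lenient 1e-2 classification filter at a ~1% rate.
- Iteron detection assumes substitution-only divergence between copies;
  copies with indels (spacer insertions) fragment an array unless
  `max_spacer` is raised.
- Whether a cloned module screen should treat the fragment as linear is a
  modeling choice (adopted here for the vector-construction use case);
  whole-plasmid scans support circular topology explicitly.
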