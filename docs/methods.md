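# Methods

## Model

`xtalface` decides whether a chain–chain interface in a protein crystal is
a biological contact or a packing artifact. The decision rests on three
indicators that are computed independently and then voted:

* **Core size (geometry).** Interface residues are those that lose
  accessible surface area (BSA = ASA_u − ASA_c > 0) when the pairwise
  complex forms. A residue burying more than 95 % of its uncomplexed ASA
  is a core residue; an interface with strictly more than 6 core residues
  (summed over both sides) is called biological. The underlying
  assumption is that fully buried residues are the energetic determinants
  of real interfaces, while packing contacts, even large ones, rarely
  bury residues completely.
* **Core–rim entropy ratio (evolution).** If an interface is functional,
  its buried core should be under stronger purifying selection than its
  solvent-exposed rim. Conservation is measured as Shannon entropy of
  multiple-alignment columns counted over a reduced 10-class amino-acid
  alphabet (hydrophobics {LVIM} pooled, etc.), in nats. For statistical
  robustness the scoring core uses a relaxed 70 % burial criterion and is
  required to exceed 8 residues with defined entropies; the score is
  mean(core entropies)/mean(rim entropies), biological below 0.75.
* **Core–surface Z-score (evolution).** The core's conservation is also
  compared to a surface baseline. Because real surfaces are heterogeneous
  (binding sites, active sites), the baseline is estimated by random
  pooling: 10 000 pools of N surface residues (N = scoring-core size),
  drawn without replacement within each pool from residues engaged in no
  crystal interface. The score is
  (mean core entropy − mean of pool means)/std of pool means; biological
  below −1.0. The pool restriction and the pooling itself reduce bias
  from conserved surface patches.

Votes combine 2-of-3 with overrides applied first: a wild-type
cross-interface disulfide (Sγ–Sγ within 1.8–2.5 Å, neither cysteine
mismatching its reference sequence) forces biological; areas above
2200 Å² force biological and below 400 Å² force crystal (the low limit
exempts protein–peptide interfaces, peptide = chain of fewer than 30
residues). With both evolutionary criteria unavailable the geometric call
stands; a lone evolutionary call beats a disagreeing geometric one. The
override order (disulfide, then hard limits, then vote) reflects that the
special cases are stated unconditionally; it only matters for interfaces
that trigger several overrides at once.

## Lattice reconstruction

Space-group operators are taken from gemmi's symmetry tables keyed by the
Hermann–Mauguin symbol in the coordinate file. Each chain is imaged by
every operator combined with unit-cell shifts in {−1,0,1}³; images whose
inflated bounding box (contact cutoff + 3 Å margin) cannot reach an
identity chain are pruned. Interfaces are pairs with any cross-pair atom
distance ≤ 6 Å (exact KD-tree search; validated against a brute-force
all-pairs scan in the tests). Symmetry produces each physical contact
several times; duplicates are collapsed by a fingerprint — the multiset of
contacting residue/atom identities with distances rounded to 0.01 Å,
pair-order canonicalized — keeping the first occurrence. Interfaces with
more than 5 atom clashes (< 1.5 Å) are flagged as suspicious but still
reported. Files without a cell/space group are analyzed as non-crystal
models over the given chains only.

Parsing keeps polymer protein chains; waters and non-polymer ligands are
excluded from the interface-bearing atom set, hydrogens are ignored, and
only the highest-occupancy alternate conformer of each atom is kept
(ties: first in file). Residues are identified by author chain id,
residue number and insertion code.

## Surface areas

ASA uses an in-package Shrake–Rupley implementation: a deterministic
golden-section spiral of 960 points per atom (configurable; at least 92),
probe radius 1.4 Å, and a fixed element radius table (C 1.70, N 1.55,
O 1.52, S 1.80 Å, default 1.70 Å). 960 points keep per-residue quadrature
error under 1 % for multi-atom residues; single-atom residues (as in the
synthetic fixtures) are the worst case at ≈ 1.2 % because no intra-residue
error cancellation occurs. The point set is fixed in the laboratory frame,
so areas are exactly translation-invariant but carry small (≪ 1 %)
rotation-dependent quadrature noise. The interface area is
½ Σ(ASA_u − ASA_c) over both sides — one shared surface, not two — while
per-residue burial fractions use the unhalved BSA/ASA_u. Surface residues
are those exposing more than 5 Å² in the isolated chain. A residue with
ASA_u = 0 (buried in the monomer) has burial ratio defined as 0: it can
never be core and is not surface either.

The relative-accessibility (rASA) core definition needs a per-residue-type
reference; we ship the published theoretical Gly-X-Gly extended-tripeptide
maxima (Tien et al. 2013) as the default table rather than recomputing
them, since generating chemically correct tripeptide conformers would
drag in a template library without changing the classification logic; the
table is a plain dict and can be swapped by the caller.

## Sequence handling

The evolutionary criteria consume, per chain, either a ready multiple
sequence alignment or a set of homolog hits (FASTA + optional
id/identity/coverage TSV). External search and alignment tools are
deliberately out of the package: the offline core is testable without
network or databases. Hits pass a coverage ≥ 0.80 filter, then an
identity cutoff starting at 0.60 and relaxing in 0.05 steps to 0.50 until
at least 10 survive (otherwise: no evolutionary prediction). Survivors
are redundancy-reduced by single-linkage clustering at 98 % identity,
lowering the threshold 1 % at a time while more than 100 representatives
remain; each cluster is represented by its member closest to the query
(ties: lexicographically smallest id), which makes the reduction
deterministic and input-order independent.

Identities are computed from global pairwise alignments (Biopython
PairwiseAligner, BLOSUM62, gap open/extend −11/−1, free terminal gaps) as
identical pairs over aligned query positions; for homolog–homolog
clustering the denominator is the longer sequence, making the measure
symmetric. The structure sequence is mapped onto its reference sequence
(a stand-in for the database reference) the same way; mappings below 60 %
identity or 80 % coverage yield a "no-reference" status that disables the
evolutionary criteria, and aligned-but-differing positions are recorded
as engineering mismatches. When homolog hits come with an explicit
reference, only the reference subsequence covered by the structure is
used as the query. Entropy columns with fewer than two counted symbols
(gaps and non-standard residues are never counted) are undefined;
undefined entropies simply drop a residue from scoring. Natural
logarithms are used throughout — the ratio and the Z-score are
base-invariant, only reported raw entropies depend on it.

Per-interface surface sampling is seeded as SeedSequence([seed,
interface_id]), so a single base seed reproduces every score while
interfaces stay independent.

## Synthetic data

The generator builds the statistical situation the classifier assumes,
not realistic protein chemistry. A chain is a compact slab of
single-atom (Cα) poly-alanine residues on a 3.5 Å cubic lattice — tight
enough that interior residues are fully occluded — and a second chain
faces it at a configurable closest-approach gap inside a padded P1 cell.
At the 4.5 Å default gap the face interior buries ≈ 93 % of its area
(scoring core under the 70 % criterion, but below the strict 95 % core
cutoff), the interface measures ≈ 490 Å², and both the 6 Å contact rule
and the clash flag can be exercised by moving the gap. Ground truth
(closest approach, brute-force contact and clash counts) is emitted
alongside the coordinates.

Synthetic alignments start from the all-alanine query; homologs mutate
free positions to representatives of other reduced-alphabet classes, at
per-homolog rates planted to yield query identities in a configured range
(default 0.60–0.95, matching the selection window), with every free
position guaranteed mutated somewhere so the conserved mask round-trips
through empirical entropies. Twenty percent of the non-contact surface is
conserved in *every* flavor, emulating the functional surface patches
(active sites, other interfaces) whose existence motivates the random
pooling; without them the core–surface null would be artificially
centered in a way real surfaces are not. The "biological" flavor
additionally conserves the contact-face interior; the "crystal" flavor
lets it mutate like the rest. Everything is derived from one seeded
generator: identical spec + seed gives byte-identical files.

What passing these tests shows: the pipeline recovers planted
differential selection pressure and respects all the stated decision
rules. What it does not show: performance on real structures, where
side-chain packing, alignment errors, paralog contamination and
non-idealized surfaces matter.

## Numerical and design choices

* Strict inequalities at every published threshold (> 0.95, > 6, > 8,
  < 0.75, < −1.0, > 2200, < 400, > 5 Å²), so boundary values never flip a
  call upward.
* "Fully buried atom" uses ASA_c < 0.01 Å² (exact zero is
  quadrature-fragile); rim-mean degeneracy below 10⁻⁶ nats and pool-mean
  spread below 10⁻¹² yield no-prediction instead of dividing by ≈ 0.
* The 27-cell neighborhood suffices for contact search at typical cell
  sizes; bounding-box pruning keeps it cheap.
* The geometric threshold compares the two-side total core size, and
  side-resolved counts are reported separately.
* The engineering veto threshold (mismatches exceeding 10 % of scored
  residues) is our choice; chimera-like multi-reference cases map to the
  same veto.
* Problem sizes in the test-suite and acceptance script (72-residue
  chains, 50 homologs, 50–100 generator seeds, 10 000 surface pools) were
  chosen to make every Monte-Carlo margin decisive at desk scale.

## Known limitations

* No NCS handling beyond the coordinate file, no biological-unit record
  interpretation, no assembly inference from the pairwise calls.
* Quaternary-structure benchmarking against curated PDB datasets requires
  the full structure sets plus era-specific sequence databases and is out
  of scope for the repository; `scripts/golden_pdb.py` covers the
  published per-entry reference values when downloads are possible.
* The ASA engine ignores hydrogens and uses a fixed radius table;
  absolute areas can differ by a few percent from engines with
  per-atom-type radii, which is why published comparison values carry a
  ±2 % tolerance.
* Homolog acquisition quality (search depth, taxon sampling) dominates
  real-world performance and is entirely delegated to the caller.
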