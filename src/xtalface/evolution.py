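"""Evolutionary signal: homolog selection, sequence entropies, interface scores.

The selection pressure acting on an interface is estimated from the Shannon
entropies of multiple-sequence-alignment columns, counted over a reduced
10-class amino-acid alphabet.  Homologs are admitted conservatively: a soft
sequence-identity cutoff of 60% is relaxed in 5% steps down to a hard floor
of 50% until at least 10 homologs pass, with an 80% coverage requirement and
a redundancy reduction to at most 100 representatives.  Two scores follow:

* core-rim ratio: mean entropy of the scoring core (interface residues
  burying more than 70% of their accessible area) over mean rim entropy;
  values below 0.75 indicate a biological interface.
* core-surface score: a Z-like distance of the mean core entropy from the
  distribution of mean entropies of 10,000 equally sized random pools of
  non-interface surface residues; values below -1.0 indicate biological.

Both require strictly more than 8 scoring-core residues, otherwise no
evolutionary prediction is made (NOPRED).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .accessibility import BurialRecord
from .constants import MURPHY10, STANDARD_AA
from .geometry import BIO, NOPRED, SCORING_CUTOFF, XTAL

SOFT_IDENTITY = 0.60
HARD_IDENTITY = 0.50
RELAX_STEP = 0.05
MIN_HOMOLOGS = 10
MIN_COVERAGE = 0.80
MAX_SEQUENCES = 100
CLUSTER_START_IDENTITY = 0.98
CR_CUTOFF = 0.75
CS_CUTOFF = -1.0
MIN_SCORING_CORE = 8          # strictly more than this many are required
N_SURFACE_SAMPLES = 10000
REF_MIN_IDENTITY = 0.60       # reference mapping acceptance
REF_MIN_COVERAGE = 0.80


@dataclass(frozen=True)
class SelectionParams:
    soft_identity: float = SOFT_IDENTITY
    hard_identity: float = HARD_IDENTITY
    relax_step: float = RELAX_STEP
    min_homologs: int = MIN_HOMOLOGS
    min_coverage: float = MIN_COVERAGE
    max_sequences: int = MAX_SEQUENCES
    cluster_start_identity: float = CLUSTER_START_IDENTITY

    def __post_init__(self):
        if self.hard_identity > self.soft_identity:
            raise ValueError("hard cutoff must not exceed soft cutoff")
        if self.relax_step <= 0:
            raise ValueError("relax_step must be positive")


@dataclass(frozen=True)
class HomologHit:
    id: str
    sequence: str
    identity: float         # fraction vs the query
    coverage: float         # fraction of the query matched


@dataclass
class FilterResult:
    accepted: list[HomologHit]
    effective_cutoff: float | None
    sufficient: bool


@dataclass
class ReferenceMapping:
    """Alignment of a structure chain sequence onto its reference sequence."""

    identity: float
    coverage: float
    mapping: dict[int, int]          # structure residue index -> reference index
    mismatches: set[int]             # structure indices aligned but differing
    ok: bool                         # False -> no-reference status

    @classmethod
    def identity_map(cls, length: int) -> "ReferenceMapping":
        return cls(identity=1.0, coverage=1.0,
                   mapping={i: i for i in range(length)},
                   mismatches=set(), ok=True)


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    al.mode = "global"
    # do not penalize terminal gaps: fragments align to their region
    try:
        al.end_insertion_score = 0.0
        al.end_deletion_score = 0.0
    except AttributeError:      # older Biopython naming
        al.target_end_gap_score = 0.0
        al.query_end_gap_score = 0.0
    return al


def _sanitize(seq: str) -> str:
    return "".join(c if c in STANDARD_AA else "X" for c in seq.upper())


def _align_stats(query: str, subject: str) -> tuple[float, float, dict[int, int], set[int]]:
    """Global alignment of query vs subject.

    Returns (identity, coverage, query->subject position map, mismatch query
    positions).  Identity = identical pairs / aligned query positions;
    coverage = aligned query positions / query length.
    """
    aln = _aligner().align(_sanitize(query), _sanitize(subject))[0]
    mapping: dict[int, int] = {}
    mismatches: set[int] = set()
    matches = 0
    for (qs, qe), (ss, se) in zip(*aln.aligned):
        for off in range(qe - qs):
            qi, si = qs + off, ss + off
            mapping[qi] = si
            if query[qi].upper() == subject[si].upper():
                matches += 1
            else:
                mismatches.add(qi)
    aligned = len(mapping)
    if aligned == 0:
        return 0.0, 0.0, {}, set()
    return matches / aligned, aligned / len(query), mapping, mismatches


def pairwise_identity(seq1: str, seq2: str) -> float:
    """Identity of a global alignment, normalized by the longer sequence."""
    aln = _aligner().align(_sanitize(seq1), _sanitize(seq2))[0]
    matches = 0
    for (qs, qe), (ss, se) in zip(*aln.aligned):
        for off in range(qe - qs):
            if seq1[qs + off].upper() == seq2[ss + off].upper():
                matches += 1
    return matches / max(len(seq1), len(seq2))


def map_reference(structure_seq: str, reference_seq: str,
                  min_identity: float = REF_MIN_IDENTITY,
                  min_coverage: float = REF_MIN_COVERAGE) -> ReferenceMapping:
    """Map structure residues onto the reference sequence by global alignment.

    Falls back to a "no-reference" status (``ok=False``) when identity or
    coverage are below threshold; the evolutionary criteria are then
    disabled and classification relies on geometry only.
    """
    if not structure_seq or not reference_seq:
        return ReferenceMapping(0.0, 0.0, {}, set(), ok=False)
    identity, coverage, mapping, mismatches = _align_stats(
        structure_seq, reference_seq)
    ok = identity >= min_identity and coverage >= min_coverage
    return ReferenceMapping(identity=identity, coverage=coverage,
                            mapping=mapping if ok else {},
                            mismatches=mismatches if ok else set(), ok=ok)


def filter_homologs(hits: list[HomologHit],
                    params: SelectionParams = SelectionParams()) -> FilterResult:
    """Identity/coverage filtering with the soft-to-hard cutoff relaxation.

    Coverage >= ``min_coverage`` is applied first.  Hits with identity at or
    above the cutoff are accepted, starting from the soft cutoff and
    relaxing stepwise down to the hard cutoff until at least
    ``min_homologs`` pass; if the floor still leaves fewer, the result is
    flagged insufficient.
    """
    covered = [h for h in hits if h.coverage >= params.min_coverage]
    cutoff = params.soft_identity
    while True:
        accepted = [h for h in covered if h.identity >= cutoff]
        if len(accepted) >= params.min_homologs:
            return FilterResult(accepted, cutoff, True)
        next_cutoff = cutoff - params.relax_step
        if cutoff <= params.hard_identity + 1e-9:
            return FilterResult(accepted, cutoff, False)
        cutoff = max(next_cutoff, params.hard_identity)


def reduce_redundancy(hits: list[HomologHit],
                      params: SelectionParams = SelectionParams(),
                      identity_fn=pairwise_identity) -> list[HomologHit]:
    """Greedy single-linkage redundancy reduction to at most ``max_sequences``.

    Sequences are clustered by single linkage at a pairwise-identity
    threshold starting at 98%; each cluster is represented by its member
    with the highest identity to the query (ties broken by lexicographic
    id).  While more representatives than the hard maximum remain, the
    threshold is lowered by 1% and clustering repeats.  Deterministic and
    independent of input order.
    """
    if not hits:
        return []
    hits = sorted(hits, key=lambda h: h.id)
    n = len(hits)
    pair_id = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pair_id[i, j] = pair_id[j, i] = identity_fn(
                hits[i].sequence, hits[j].sequence)

    def cluster_at(threshold: float) -> list[HomologHit]:
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                if pair_id[i, j] >= threshold:
                    parent[find(i)] = find(j)
        clusters: dict[int, list[HomologHit]] = {}
        for i, h in enumerate(hits):
            clusters.setdefault(find(i), []).append(h)
        reps = [max(members, key=lambda h: (h.identity, _neg_id(h.id)))
                for members in clusters.values()]
        return sorted(reps, key=lambda h: h.id)

    threshold = params.cluster_start_identity
    reps = cluster_at(threshold)
    while len(reps) > params.max_sequences and threshold > 0.0:
        threshold = round(threshold - 0.01, 10)
        reps = cluster_at(threshold)
    return reps[:params.max_sequences]


class _neg_id(str):
    """Reverse-order string so max() prefers the lexicographically smaller id."""

    def __lt__(self, other):
        return str.__gt__(self, other)


def column_entropy(column, alphabet: dict[str, int] | None = None) -> float:
    """Shannon entropy (nats) of an alignment column over residue classes.

    Gaps and non-standard symbols are excluded from the counts; a column
    with fewer than 2 counted symbols has undefined entropy (NaN).
    """
    table = MURPHY10 if alphabet is None else alphabet
    counts: dict[int, int] = {}
    for sym in column:
        cls = table.get(sym.upper())
        if cls is not None:
            counts[cls] = counts.get(cls, 0) + 1
    total = sum(counts.values())
    if total < 2:
        return float("nan")
    return -sum((c / total) * math.log(c / total) for c in counts.values())


@dataclass
class EntropyProfile:
    """Per-structure-residue conservation entropies mapped from an MSA."""

    entropies: np.ndarray                 # (n_residues,), NaN where undefined
    alignment: list[tuple[str, str]] = field(default_factory=list, repr=False)
    query_id: str = ""

    def defined(self, index: int) -> bool:
        return bool(np.isfinite(self.entropies[index]))


def entropy_profile(alignment: list[tuple[str, str]],
                    query_id: str,
                    n_residues: int,
                    mapping: ReferenceMapping | None = None,
                    alphabet: dict[str, int] | None = None) -> EntropyProfile:
    """Compute per-column entropies and map them onto structure residues.

    ``alignment`` is a list of (id, aligned sequence with gaps); the row
    named ``query_id`` is the reference/query.  ``mapping`` translates
    structure residue indices to ungapped query positions (identity if
    omitted).  Residues aligned to nothing get NaN.
    """
    rows = dict(alignment)
    if query_id not in rows:
        raise KeyError(f"query row {query_id!r} absent from alignment")
    query_row = rows[query_id]
    width = len(query_row)
    if any(len(seq) != width for seq in rows.values()):
        raise ValueError("alignment rows have unequal lengths")

    col_entropy = np.array([
        column_entropy([seq[c] for seq in rows.values()], alphabet)
        for c in range(width)])

    # ungapped query position -> column index
    pos_to_col: dict[int, int] = {}
    pos = 0
    for c, sym in enumerate(query_row):
        if sym != "-" and sym != ".":
            pos_to_col[pos] = c
            pos += 1

    if mapping is None:
        mapping = ReferenceMapping.identity_map(n_residues)
    ent = np.full(n_residues, np.nan)
    for res_idx, ref_pos in mapping.mapping.items():
        if res_idx < n_residues and ref_pos in pos_to_col:
            ent[res_idx] = col_entropy[pos_to_col[ref_pos]]
    return EntropyProfile(entropies=ent, alignment=alignment, query_id=query_id)


@dataclass
class EvolScores:
    cr_ratio: float | None
    cs_score: float | None
    n_scoring_core: int
    call_cr: str
    call_cs: str


def scoring_partition(burials: list[BurialRecord],
                      profiles: dict[str, EntropyProfile],
                      scoring_cutoff: float = SCORING_CUTOFF
                      ) -> tuple[list[float], list[float]]:
    """Split interface residues into scoring core and rim entropy lists.

    The scoring core uses the relaxed 70% burial criterion; only residues
    with a defined entropy are scored.
    """
    core, rim = [], []
    for rec in burials:
        if not rec.is_interface:
            continue
        profile = profiles.get(rec.side)
        if profile is None:
            continue
        e = profile.entropies[rec.residue_index]
        if not np.isfinite(e):
            continue
        (core if rec.burial_ratio > scoring_cutoff else rim).append(float(e))
    return core, rim


def core_rim_score(core_entropies: list[float], rim_entropies: list[float],
                   cr_cutoff: float = CR_CUTOFF,
                   min_core: int = MIN_SCORING_CORE,
                   eps: float = 1e-6) -> tuple[float | None, str]:
    """Mean core entropy over mean rim entropy; BIO iff strictly below cutoff.

    NOPRED when the scoring core is not larger than ``min_core``, the rim is
    empty, or the rim mean is degenerate (~0).
    """
    if len(core_entropies) <= min_core or not rim_entropies:
        return None, NOPRED
    rim_mean = float(np.mean(rim_entropies))
    if rim_mean <= eps:
        return None, NOPRED
    ratio = float(np.mean(core_entropies)) / rim_mean
    return ratio, (BIO if ratio < cr_cutoff else XTAL)


def core_surface_score(core_entropies: list[float],
                       surface_entropies: list[float],
                       n_samples: int = N_SURFACE_SAMPLES,
                       seed: int | np.random.SeedSequence = 0,
                       cs_cutoff: float = CS_CUTOFF,
                       min_core: int = MIN_SCORING_CORE) -> tuple[float | None, str]:
    """Z-like distance of the mean core entropy from random surface pools.

    ``n_samples`` pools of N residues (N = scoring-core size) are drawn
    without replacement from the surface residues that belong to no
    interface; the score is (mean core entropy - mean of pool means) /
    standard deviation of pool means.  The lower the score, the stronger
    the indication of a biological interface; BIO iff strictly below
    ``cs_cutoff``.  NOPRED when the core is too small, the surface pool is
    smaller than N, or the pool-mean spread vanishes.
    """
    n_core = len(core_entropies)
    if n_core <= min_core:
        return None, NOPRED
    pool = np.asarray(surface_entropies, dtype=float)
    if len(pool) < n_core:
        return None, NOPRED
    rng = np.random.default_rng(seed)
    # vectorized sampling without replacement within each pool
    keys = rng.random((n_samples, len(pool)))
    idx = np.argpartition(keys, n_core - 1, axis=1)[:, :n_core]
    pool_means = pool[idx].mean(axis=1)
    spread = float(pool_means.std())
    if spread < 1e-12:
        return None, NOPRED
    score = (float(np.mean(core_entropies)) - float(pool_means.mean())) / spread
    return score, (BIO if score < cs_cutoff else XTAL)


def evaluate_evolution(burials: list[BurialRecord],
                       profiles: dict[str, EntropyProfile],
                       surface_entropies: list[float],
                       scoring_cutoff: float = SCORING_CUTOFF,
                       cr_cutoff: float = CR_CUTOFF,
                       cs_cutoff: float = CS_CUTOFF,
                       n_samples: int = N_SURFACE_SAMPLES,
                       seed: int | np.random.SeedSequence = 0) -> EvolScores:
    """Run both evolutionary criteria for one interface."""
    core, rim = scoring_partition(burials, profiles, scoring_cutoff)
    cr, call_cr = core_rim_score(core, rim, cr_cutoff)
    cs, call_cs = core_surface_score(core, surface_entropies,
                                     n_samples=n_samples, seed=seed,
                                     cs_cutoff=cs_cutoff)
    return EvolScores(cr_ratio=cr, cs_score=cs, n_scoring_core=len(core),
                      call_cr=call_cr, call_cs=call_cs)
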