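"""End-to-end analysis: from a structure file to per-interface verdicts.

This is the orchestration layer.  It enumerates the lattice interfaces,
computes burials and region assignments, builds per-chain entropy profiles
from user-supplied alignments or homolog sets, and emits one
:class:`~xtalface.classifier.InterfaceVerdict` per interface, together with
a tabular report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accessibility import (AsaParameters, BurialRecord, compute_burial,
                            interface_area, shrake_rupley)
from .classifier import (MAX_MISMATCH_FRACTION, PEPTIDE_MAX_RESIDUES,
                         EngineeringResult, HardLimits, InterfaceVerdict,
                         combine, detect_interface_disulfide,
                         engineering_check)
from .evolution import (CR_CUTOFF, CS_CUTOFF, N_SURFACE_SAMPLES,
                        EntropyProfile, EvolScores, HomologHit,
                        ReferenceMapping, SelectionParams, entropy_profile,
                        evaluate_evolution, filter_homologs, map_reference,
                        reduce_redundancy)
from .geometry import (NOPRED, GeometryParams, RegionAssignment,
                       classify_chakrabarti, classify_levy, classify_scharer,
                       geometry_call)
from .structure import (CONTACT_CUTOFF, CrystalStructure, Interface,
                        enumerate_interfaces, parse_structure)


@dataclass
class AnalysisParams:
    contact_cutoff: float = CONTACT_CUTOFF
    asa: AsaParameters = field(default_factory=AsaParameters)
    geometry: GeometryParams = field(default_factory=GeometryParams)
    selection: SelectionParams = field(default_factory=SelectionParams)
    cr_cutoff: float = CR_CUTOFF
    cs_cutoff: float = CS_CUTOFF
    n_samples: int = N_SURFACE_SAMPLES
    limits: HardLimits = field(default_factory=HardLimits)
    peptide_max_residues: int = PEPTIDE_MAX_RESIDUES
    max_mismatch_fraction: float = MAX_MISMATCH_FRACTION


@dataclass
class ChainEvolution:
    """Evolutionary context prepared once per source chain."""

    profile: EntropyProfile | None
    mapping: ReferenceMapping | None
    status: str                        # "ok" | "no-data" | "no-reference" | ...
    surface_pool: list[float] = field(default_factory=list)


@dataclass
class InterfaceResult:
    interface: Interface
    burials: list[BurialRecord]
    scharer: RegionAssignment
    chakrabarti: RegionAssignment
    levy: RegionAssignment
    scores: EvolScores
    verdict: InterfaceVerdict

    @property
    def area(self) -> float:
        return self.interface.area


@dataclass
class CrystalAnalysis:
    structure: CrystalStructure
    results: list[InterfaceResult]
    chain_status: dict[str, str]

    @property
    def verdicts(self) -> list[InterfaceVerdict]:
        return [r.verdict for r in self.results]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            iface, v = r.interface, r.verdict
            rows.append({
                "interface_id": v.interface_id,
                "chain_a": iface.side_a.chain.chain_id,
                "op_a": _op_label(iface.side_a),
                "chain_b": iface.side_b.chain.chain_id,
                "op_b": _op_label(iface.side_b),
                "area": round(v.area, 2),
                "core_scharer_a": r.scharer.core_size_a,
                "core_scharer_b": r.scharer.core_size_b,
                "core_chakrabarti_total": r.chakrabarti.core_size,
                "core_levy_total": r.levy.core_size,
                "call_geom": v.call_geometry,
                "cr_ratio": _round(r.scores.cr_ratio),
                "call_cr": v.call_core_rim,
                "cs_score": _round(r.scores.cs_score),
                "call_cs": v.call_core_surface,
                "final": v.final,
                "decision_path": v.decision_path,
                "warnings": ";".join(v.warnings),
            })
        return pd.DataFrame(rows, columns=REPORT_COLUMNS)

    def to_json(self) -> str:
        return json.dumps(self.to_frame().to_dict(orient="records"), indent=2)


REPORT_COLUMNS = [
    "interface_id", "chain_a", "op_a", "chain_b", "op_b", "area",
    "core_scharer_a", "core_scharer_b", "core_chakrabarti_total",
    "core_levy_total", "call_geom", "cr_ratio", "call_cr", "cs_score",
    "call_cs", "final", "decision_path", "warnings",
]


def _op_label(instance) -> str:
    i, j, k = instance.cell_shift
    return f"{instance.operator_index}({i},{j},{k})"


def _round(x: float | None, ndigits: int = 4):
    return None if x is None else round(x, ndigits)


def _ungap(seq: str) -> str:
    return seq.replace("-", "").replace(".", "")


def _pick_query_row(alignment: list[tuple[str, str]], chain_id: str) -> str:
    ids = [rid for rid, _ in alignment]
    for candidate in (chain_id, "query", "QUERY", "__query__"):
        if candidate in ids:
            return candidate
    return ids[0]


def _stack_homolog_alignment(query_id: str, query_seq: str,
                             hits: list[HomologHit]) -> list[tuple[str, str]]:
    """Trivial alignment for ungapped same-length homolog sets."""
    if any(len(h.sequence) != len(query_seq) for h in hits):
        raise ValueError(
            "homolog sequences differ in length from the query; provide a "
            "precomputed multiple sequence alignment instead")
    return [(query_id, query_seq)] + [(h.id, h.sequence) for h in hits]


def prepare_chain_evolution(structure: CrystalStructure,
                            alignments: dict[str, list[tuple[str, str]]] | None,
                            references: dict[str, str] | None,
                            homologs: dict[str, list[HomologHit]] | None,
                            params: AnalysisParams) -> dict[str, ChainEvolution]:
    """Build the per-chain entropy profile and reference mapping.

    A chain with no sequence input at all gets status "no-data" and the
    classification for its interfaces is geometry-only, as prescribed for
    low-coverage cases.
    """
    alignments = alignments or {}
    references = references or {}
    homologs = homologs or {}
    out: dict[str, ChainEvolution] = {}
    for chain in structure.chains:
        cid = chain.chain_id
        chain_seq = chain.sequence
        msa = alignments.get(cid)
        hits = homologs.get(cid)
        explicit_ref = references.get(cid)

        if msa is None and hits is None:
            out[cid] = ChainEvolution(None, None, "no-data")
            continue

        if msa is not None:
            query_id = _pick_query_row(msa, cid)
            ref_seq = explicit_ref or _ungap(dict(msa)[query_id])
            mapping = map_reference(chain_seq, ref_seq)
            if not mapping.ok:
                out[cid] = ChainEvolution(None, mapping, "no-reference")
                continue
            # the profile is indexed through the MSA query row; when an
            # explicit reference differs from it, remap onto the row
            row_seq = _ungap(dict(msa)[query_id])
            if ref_seq != row_seq:
                mapping_profile = map_reference(chain_seq, row_seq)
                if not mapping_profile.ok:
                    out[cid] = ChainEvolution(None, mapping, "no-reference")
                    continue
            else:
                mapping_profile = mapping
            profile = entropy_profile(msa, query_id, len(chain.residues),
                                      mapping=mapping_profile)
            out[cid] = ChainEvolution(profile, mapping, "ok")
            continue

        # homolog-hit route: filter, reduce redundancy, stack an alignment
        if explicit_ref is None:
            mapping = ReferenceMapping.identity_map(len(chain.residues))
            query_seq = chain_seq
        else:
            mapping = map_reference(chain_seq, explicit_ref)
            if not mapping.ok:
                out[cid] = ChainEvolution(None, mapping, "no-reference")
                continue
            # only the matching subsequence of the reference is the query
            lo = min(mapping.mapping.values())
            hi = max(mapping.mapping.values())
            query_seq = explicit_ref[lo:hi + 1]
            mapping = ReferenceMapping(
                identity=mapping.identity, coverage=mapping.coverage,
                mapping={k: v - lo for k, v in mapping.mapping.items()},
                mismatches=mapping.mismatches, ok=True)
        selected = filter_homologs(hits, params.selection)
        if not selected.sufficient:
            out[cid] = ChainEvolution(None, mapping, "insufficient-homologs")
            continue
        reps = reduce_redundancy(selected.accepted, params.selection)
        msa = _stack_homolog_alignment("__query__", query_seq, reps)
        profile = entropy_profile(msa, "__query__", len(chain.residues),
                                  mapping=mapping)
        out[cid] = ChainEvolution(profile, mapping, "ok")
    return out


def analyze_crystal(structure: CrystalStructure | str,
                    alignments: dict[str, list[tuple[str, str]]] | None = None,
                    references: dict[str, str] | None = None,
                    homologs: dict[str, list[HomologHit]] | None = None,
                    params: AnalysisParams | None = None,
                    seed: int = 0) -> CrystalAnalysis:
    """Classify every interface of a crystal as biological or crystal packing.

    Parameters
    ----------
    structure
        A parsed :class:`CrystalStructure` or PDB/mmCIF file text.
    alignments
        Optional per-chain multiple sequence alignments, each a list of
        (id, aligned sequence) rows; the row named like the chain (or
        "query", else the first row) is the reference.
    references
        Optional per-chain reference sequences (stand-ins for the UniProt
        reference) used for mismatch/engineering checks.
    homologs
        Optional per-chain homolog hit sets; selection and redundancy
        reduction are applied before entropy computation.
    seed
        Base seed for the surface-pool sampling; each interface derives its
        own child generator, so results are reproducible.
    """
    if isinstance(structure, str):
        structure = parse_structure(structure)
    params = params or AnalysisParams()

    interfaces = enumerate_interfaces(structure, params.contact_cutoff)

    # isolated-chain ASA is invariant under the rigid symmetry placement,
    # so compute it once per source chain and reuse for every instance
    chain_atom_asa = {ch.chain_id: shrake_rupley(ch.coords, ch.radii, params.asa)
                      for ch in structure.chains}

    burials_by_iface: dict[int, list[BurialRecord]] = {}
    for iface in interfaces:
        pre = (chain_atom_asa[iface.side_a.chain.chain_id],
               chain_atom_asa[iface.side_b.chain.chain_id])
        burials = compute_burial(iface, params.asa, precomputed_u=pre)
        iface.area = interface_area(burials)
        burials_by_iface[iface.id] = burials

    # rank by descending buried area
    interfaces.sort(key=lambda f: (-f.area, f.side_a.label, f.side_b.label))
    old_burials = burials_by_iface
    burials_by_iface = {}
    for rank, iface in enumerate(interfaces, start=1):
        burials_by_iface[rank] = old_burials[iface.id]
        iface.id = rank

    evolution = prepare_chain_evolution(structure, alignments, references,
                                        homologs, params)
    mappings = {cid: ev.mapping for cid, ev in evolution.items()
                if ev.mapping is not None}

    # residues engaged in any interface, per source chain
    engaged: dict[str, set[int]] = {ch.chain_id: set()
                                    for ch in structure.chains}
    for iface in interfaces:
        for rec in burials_by_iface[iface.id]:
            if rec.is_interface:
                cid = (iface.side_a if rec.side == "A"
                       else iface.side_b).chain.chain_id
                engaged[cid].add(rec.residue_index)

    # surface pool per chain: surface residues in none of the interfaces,
    # restricted to defined entropies
    for chain in structure.chains:
        ev = evolution[chain.chain_id]
        if ev.profile is None:
            continue
        per_res = np.bincount(chain.atom_residue,
                              weights=chain_atom_asa[chain.chain_id],
                              minlength=len(chain.residues))
        surf = {int(i) for i in
                np.nonzero(per_res > params.asa.surface_min_asa)[0]}
        pool = []
        for ri in sorted(surf - engaged[chain.chain_id]):
            e = ev.profile.entropies[ri]
            if np.isfinite(e):
                pool.append(float(e))
        ev.surface_pool = pool

    results: list[InterfaceResult] = []
    for iface in interfaces:
        burials = burials_by_iface[iface.id]
        scharer = classify_scharer(burials, params.geometry.scharer_cutoff)
        chakrabarti = classify_chakrabarti(burials)
        levy = classify_levy(burials, cutoff=params.geometry.levy_rasa_cutoff)
        call_geom = geometry_call(scharer, params.geometry.core_size_threshold)

        cid_a = iface.side_a.chain.chain_id
        cid_b = iface.side_b.chain.chain_id
        profiles = {}
        if evolution[cid_a].profile is not None:
            profiles["A"] = evolution[cid_a].profile
        if evolution[cid_b].profile is not None:
            profiles["B"] = evolution[cid_b].profile

        warnings: list[str] = []
        if iface.is_suspicious:
            warnings.append(
                f"{iface.clash_count} atom clashes across the interface; "
                "possibly an artifact")
        for cid in dict.fromkeys((cid_a, cid_b)):
            status = evolution[cid].status
            if status not in ("ok", "no-data"):
                warnings.append(f"chain {cid}: {status}; "
                                "evolutionary criteria unavailable")

        scored = [((iface.side_a if rec.side == "A" else iface.side_b)
                   .chain.chain_id,
                   rec.residue_index,
                   f"{rec.residue.res_type}{rec.residue.seq_num}")
                  for rec in burials if rec.is_interface]
        eng: EngineeringResult = engineering_check(
            scored, mappings, params.max_mismatch_fraction)
        warnings.extend(eng.warnings)

        if eng.veto or not profiles:
            scores = EvolScores(None, None, 0, NOPRED, NOPRED)
        else:
            pool = []
            for cid in dict.fromkeys((cid_a, cid_b)):
                pool.extend(evolution[cid].surface_pool)
            scores = evaluate_evolution(
                burials, profiles, pool,
                scoring_cutoff=params.geometry.scoring_cutoff,
                cr_cutoff=params.cr_cutoff, cs_cutoff=params.cs_cutoff,
                n_samples=params.n_samples,
                seed=np.random.SeedSequence([seed, iface.id]))

        disulfide = detect_interface_disulfide(iface, mappings)
        is_peptide = (len(iface.side_a.chain.residues) < params.peptide_max_residues
                      or len(iface.side_b.chain.residues) < params.peptide_max_residues)
        verdict = combine(call_geom, scores.call_cr, scores.call_cs,
                          area=iface.area, disulfide=disulfide,
                          limits=params.limits,
                          is_peptide_partner=is_peptide,
                          interface_id=iface.id, warnings=warnings)
        results.append(InterfaceResult(
            interface=iface, burials=burials, scharer=scharer,
            chakrabarti=chakrabarti, levy=levy, scores=scores,
            verdict=verdict))

    return CrystalAnalysis(structure=structure, results=results,
                           chain_status={cid: ev.status
                                         for cid, ev in evolution.items()})
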