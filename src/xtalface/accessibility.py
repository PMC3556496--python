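"""Accessible surface areas, burial upon complexation, and interface area.

ASA is computed with the Shrake-Rupley rolling-probe quadrature: each atom
is wrapped in a deterministic spiral point set on its solvent-extended
sphere and the accessible fraction is the fraction of points not occluded
by any neighbor's extended sphere.  Buried surface area (BSA) per residue
is ASA_uncomplexed - ASA_complexed; the interface area is half the summed
BSA of both sides, so that one shared surface is not counted twice.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from .structure import ChainInstance, Interface, ResidueRecord

PROBE_RADIUS = 1.4       # A, water-sized probe
N_SPHERE_POINTS = 960
SURFACE_MIN_ASA = 5.0    # A^2; residues exposing more than this are surface


@dataclass(frozen=True)
class AsaParameters:
    probe_radius: float = PROBE_RADIUS
    n_sphere_points: int = N_SPHERE_POINTS
    surface_min_asa: float = SURFACE_MIN_ASA

    def __post_init__(self):
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.n_sphere_points < 92:
            raise ValueError("n_sphere_points must be at least 92")


@dataclass
class BurialRecord:
    """Per-residue accessibility bookkeeping for one side of an interface."""

    side: str                    # "A" or "B"
    residue_index: int           # index into the source chain's residues
    residue: ResidueRecord
    asa_u: float                 # A^2, isolated chain instance
    asa_c: float                 # A^2, in the pairwise complex
    atom_asa_u: np.ndarray       # per-atom ASA, isolated
    atom_asa_c: np.ndarray       # per-atom ASA, complexed

    @property
    def bsa(self) -> float:
        return self.asa_u - self.asa_c

    @property
    def burial_ratio(self) -> float:
        """bsa / asa_u clipped to [0, 1]; 0 for residues buried in the monomer."""
        if self.asa_u <= 1e-9:
            return 0.0
        return float(np.clip(self.bsa / self.asa_u, 0.0, 1.0))

    @property
    def is_interface(self) -> bool:
        return self.bsa > 0.0


@lru_cache(maxsize=8)
def unit_sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral point set on the unit sphere."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    pts.flags.writeable = False
    return pts


def shrake_rupley(coords: np.ndarray, radii: np.ndarray,
                  params: AsaParameters = AsaParameters()) -> np.ndarray:
    """Per-atom solvent accessible surface area in A^2."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    ext = np.asarray(radii, dtype=float) + params.probe_radius
    pts = unit_sphere_points(params.n_sphere_points)
    tree = cKDTree(coords)
    max_ext = ext.max()
    asa = np.empty(n)
    for i in range(n):
        cand = tree.query_ball_point(coords[i], ext[i] + max_ext)
        delta = coords[cand] - coords[i]
        d2 = np.einsum("ij,ij->i", delta, delta)
        keep = (d2 < (ext[i] + ext[cand]) ** 2) & (d2 > 1e-12)
        neigh = np.asarray(cand)[keep]
        sphere_area = 4.0 * np.pi * ext[i] ** 2
        if len(neigh) == 0:
            asa[i] = sphere_area
            continue
        surface = coords[i] + ext[i] * pts
        diff = surface[:, None, :] - coords[neigh][None, :, :]
        dist2 = np.einsum("ijk,ijk->ij", diff, diff)
        buried = (dist2 < (ext[neigh] ** 2)[None, :]).any(axis=1)
        asa[i] = sphere_area * (1.0 - buried.mean())
    return asa


def compute_asa(atoms, params: AsaParameters = AsaParameters()) -> np.ndarray:
    """Per-atom ASA for a list of :class:`AtomRecord`."""
    if not atoms:
        return np.zeros(0)
    coords = np.asarray([a.coords for a in atoms], dtype=float)
    radii = np.asarray([a.vdw_radius for a in atoms], dtype=float)
    return shrake_rupley(coords, radii, params)


def residue_asa(instance: ChainInstance,
                params: AsaParameters = AsaParameters(),
                atom_asa: np.ndarray | None = None) -> np.ndarray:
    """Per-residue ASA of an isolated chain instance."""
    if atom_asa is None:
        atom_asa = shrake_rupley(instance.coords, instance.chain.radii, params)
    n_res = len(instance.chain.residues)
    return np.bincount(instance.chain.atom_residue, weights=atom_asa,
                       minlength=n_res)


def compute_burial(interface: Interface,
                   params: AsaParameters = AsaParameters(),
                   precomputed_u: tuple[np.ndarray, np.ndarray] | None = None
                   ) -> list[BurialRecord]:
    """Burial records for every residue of both interface sides.

    ``asa_u`` comes from each isolated chain instance, ``asa_c`` from the
    two-chain complex.  ``precomputed_u`` may carry the per-atom isolated
    ASA of (side_a, side_b) when already known (it is invariant under the
    rigid placement of the instance).
    """
    a, b = interface.side_a, interface.side_b
    if precomputed_u is not None:
        asa_u_a, asa_u_b = precomputed_u
    else:
        asa_u_a = shrake_rupley(a.coords, a.chain.radii, params)
        asa_u_b = shrake_rupley(b.coords, b.chain.radii, params)
    coords = np.vstack([a.coords, b.coords])
    radii = np.concatenate([a.chain.radii, b.chain.radii])
    asa_c = shrake_rupley(coords, radii, params)
    asa_c_a, asa_c_b = asa_c[:len(a.coords)], asa_c[len(a.coords):]

    records: list[BurialRecord] = []
    for side, inst, u, c in (("A", a, asa_u_a, asa_c_a),
                             ("B", b, asa_u_b, asa_c_b)):
        ch = inst.chain
        for ri, res in enumerate(ch.residues):
            mask = ch.atom_residue == ri
            records.append(BurialRecord(
                side=side, residue_index=ri, residue=res,
                asa_u=float(u[mask].sum()), asa_c=float(c[mask].sum()),
                atom_asa_u=u[mask], atom_asa_c=c[mask]))
    return records


def interface_area(burials: list[BurialRecord]) -> float:
    """Total buried area of the interface: half-sum of both sides' BSA."""
    return max(0.0, 0.5 * sum(rec.bsa for rec in burials))


def surface_residues(instance: ChainInstance,
                     params: AsaParameters = AsaParameters(),
                     per_res_asa: np.ndarray | None = None) -> set[int]:
    """Indices of residues exposing more than ``surface_min_asa`` when isolated."""
    if per_res_asa is None:
        per_res_asa = residue_asa(instance, params)
    return {int(i) for i in np.nonzero(per_res_asa > params.surface_min_asa)[0]}
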