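"""Volume-overlap shape similarity and alignment search.

Shape similarity between two superposed molecules A and B is the ratio of
jointly occupied volume to total volume,

    Sim(A, B) = V(A ∩ B) / V(A ∪ B)  in [0, 1],

with molecular volume measured on a boolean occupancy lattice: a voxel is
occupied when its center lies within the van der Waals radius (Bondi set,
heavy atoms only) of any atom. The same 0.5 Å lattice underlies the
voxelized QSAR fields, so one rasterizer serves both stages.

The alignment search seeds each conformer-pair superposition from centroids
plus principal axes (four proper axis-flip hypotheses) and refines the six
rigid degrees of freedom with Nelder-Mead to maximize Sim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .chem import ConformerSet

__all__ = [
    "BONDI_RADII",
    "VolumeGrid",
    "Alignment",
    "ShapeHit",
    "rasterize",
    "overlap_volumes",
    "shape_similarity",
    "best_alignments",
    "typed_similarity",
    "screen_library",
]

# Bondi van der Waals radii (Å); hydrogens are ignored throughout.
BONDI_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "Cl": 1.75,
    "Br": 1.85, "I": 1.98, "S": 1.80, "P": 1.80, "B": 1.92,
}
DEFAULT_SPACING = 0.5
_FLIPS = [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]


def radii_for(elements) -> np.ndarray:
    return np.array([BONDI_RADII.get(e, 1.70) for e in elements], dtype=float)


@dataclass
class VolumeGrid:
    """Boolean occupancy lattice over one conformer at fixed spacing.

    ``occupancy`` marks voxels whose centers fall inside an atom and drives
    the fast alignment search; volumes are measured on a subsampled
    refinement of the same lattice (27 sub-centers per voxel), which keeps
    the discretization error of a van der Waals sphere under ~1% at 0.5 Å.
    """

    origin: np.ndarray            # (3,) Å, center of voxel [0,0,0]
    spacing: float                # Å
    occupancy: np.ndarray         # bool, shape (nx, ny, nz)
    coords: np.ndarray            # heavy-atom coordinates that were rasterized
    radii: np.ndarray             # per-atom VdW radii (Å)

    @property
    def voxel_volume(self) -> float:
        return self.spacing ** 3

    @property
    def volume(self) -> float:
        """Occupied volume in Å³ (subsampled estimate)."""
        fine = _fine_occupancy(self.origin, self.occupancy.shape, self.spacing,
                               self.coords, self.radii)
        return float(fine.sum()) * (self.spacing / _SUBSAMPLE) ** 3


def _rasterize_on(origin, shape, spacing, coords, radii) -> np.ndarray:
    """Occupancy on a given lattice: voxel centers within radius of any atom."""
    occ = np.zeros(shape, dtype=bool)
    for xyz, r in zip(coords, radii):
        lo = np.floor((xyz - r - origin) / spacing).astype(int)
        hi = np.ceil((xyz + r - origin) / spacing).astype(int) + 1
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, shape)
        if np.any(lo >= hi):
            continue
        ix = np.arange(lo[0], hi[0])
        iy = np.arange(lo[1], hi[1])
        iz = np.arange(lo[2], hi[2])
        dx = origin[0] + ix * spacing - xyz[0]
        dy = origin[1] + iy * spacing - xyz[1]
        dz = origin[2] + iz * spacing - xyz[2]
        d2 = (dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2)
        occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= r * r
    return occ


_SUBSAMPLE = 3  # sub-centers per voxel edge for volume measurement


def _fine_occupancy(origin, shape, spacing, coords, radii) -> np.ndarray:
    """Occupancy on the subsampled lattice (_SUBSAMPLE**3 sub-centers/voxel)."""
    s = _SUBSAMPLE
    fine_origin = np.asarray(origin, dtype=float) - spacing * (s - 1) / (2 * s)
    fine_shape = tuple(s * n for n in shape)
    return _rasterize_on(fine_origin, fine_shape, spacing / s, coords, radii)


def rasterize(coords: np.ndarray, elements, spacing: float = DEFAULT_SPACING) -> VolumeGrid:
    """Rasterize one conformer (heavy-atom coords + element symbols) to a grid.

    The grid bounds pad the molecule by the largest atomic radius plus one
    voxel so no occupied voxel is clipped.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ValueError("cannot rasterize an empty molecule")
    radii = radii_for(elements)
    pad = radii.max() + spacing
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    shape = tuple(np.ceil((hi - lo) / spacing).astype(int) + 1)
    occ = _rasterize_on(lo, shape, spacing, coords, radii)
    return VolumeGrid(origin=lo, spacing=spacing, occupancy=occ, coords=coords, radii=radii)


def overlap_volumes(a: VolumeGrid, b: VolumeGrid) -> tuple[float, float]:
    """(V_intersect, V_union) in Å³ on a common frame covering both grids."""
    if abs(a.spacing - b.spacing) > 1e-12:
        raise ValueError("grids must share one spacing")
    spacing = a.spacing
    pad = max(a.radii.max(initial=1.7), b.radii.max(initial=1.7)) + spacing
    lo = np.minimum(a.coords.min(axis=0), b.coords.min(axis=0)) - pad
    hi = np.maximum(a.coords.max(axis=0), b.coords.max(axis=0)) + pad
    shape = tuple(np.ceil((hi - lo) / spacing).astype(int) + 1)
    occ_a = _fine_occupancy(lo, shape, spacing, a.coords, a.radii)
    occ_b = _fine_occupancy(lo, shape, spacing, b.coords, b.radii)
    v = (spacing / _SUBSAMPLE) ** 3
    inter = float(np.logical_and(occ_a, occ_b).sum()) * v
    union = float(np.logical_or(occ_a, occ_b).sum()) * v
    return inter, union


def shape_similarity(a: VolumeGrid, b: VolumeGrid) -> float:
    """Sim(A, B) = V∩ / V∪, symmetric, in [0, 1]."""
    inter, union = overlap_volumes(a, b)
    if union == 0.0:
        raise ValueError("both grids are empty; similarity undefined")
    return inter / union


@dataclass
class Alignment:
    """Rigid map x -> x @ R.T + t taking query coordinates into the reference frame."""

    rotation: np.ndarray
    translation: np.ndarray
    query_conformer: int = 0
    ref_conformer: int = 0

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class ShapeHit:
    query: str
    reference: str
    sim: float
    typed_sims: dict = field(default_factory=dict)
    alignment: Alignment | None = None


# Gaussian-density surrogate for alignment optimization (hard-sphere volumes
# remain the reported similarity). Each atom is a spherical Gaussian whose
# amplitude/width reproduce its VdW sphere volume; the Gaussian Tanimoto is
# smooth in the 6 rigid DOF, which makes the search landscape tractable.
_GAUSS_P = 2.7
_GAUSS_KAPPA = 2.41798793102


def _gauss_alpha(radii: np.ndarray) -> np.ndarray:
    return _GAUSS_KAPPA / radii ** 2


def _gauss_cross(A: np.ndarray, aA: np.ndarray, B: np.ndarray, aB: np.ndarray) -> float:
    d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(-1)
    s = aA[:, None] + aB[None, :]
    return float((_GAUSS_P ** 2 * (np.pi / s) ** 1.5
                  * np.exp(-(aA[:, None] * aB[None, :] / s) * d2)).sum())


def gaussian_tanimoto(coords_a, radii_a, coords_b, radii_b) -> float:
    """Smooth shape Tanimoto under the Gaussian-density volume model."""
    aA, aB = _gauss_alpha(np.asarray(radii_a)), _gauss_alpha(np.asarray(radii_b))
    A, B = np.asarray(coords_a, float), np.asarray(coords_b, float)
    vaa = _gauss_cross(A, aA, A, aA)
    vbb = _gauss_cross(B, aB, B, aB)
    vab = _gauss_cross(A, aA, B, aB)
    return vab / (vaa + vbb - vab)


def _principal_frame(coords: np.ndarray):
    """Centroid and right-handed principal-axes matrix (columns = axes)."""
    c = coords.mean(axis=0)
    x = coords - c
    cov = x.T @ x / len(x)
    w, v = np.linalg.eigh(cov)
    v = v[:, ::-1]  # descending variance
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return c, v


def _pair_sim(ref_grid: VolumeGrid, ref_volume: float, q_coords: np.ndarray,
              q_radii: np.ndarray, q_volume: float) -> float:
    """Fast coarse Sim for a transformed query against a fixed reference grid.

    The intersection lives inside the reference molecular volume, so it is
    counted on the reference lattice; the query's own volume was precomputed
    on its fitted lattice. V∪ follows from inclusion-exclusion. All terms
    use the coarse (voxel-center) estimator; final hit scores are recomputed
    with the subsampled estimator.
    """
    occ_q = _rasterize_on(ref_grid.origin, ref_grid.occupancy.shape,
                          ref_grid.spacing, q_coords, q_radii)
    inter = float(np.logical_and(ref_grid.occupancy, occ_q).sum()) * ref_grid.voxel_volume
    union = ref_volume + q_volume - inter
    return inter / union if union > 0 else 0.0


def _seed_alignments(q_coords: np.ndarray, r_coords: np.ndarray) -> list[Alignment]:
    cq, vq = _principal_frame(q_coords)
    cr, vr = _principal_frame(r_coords)
    seeds = []
    for flip in _FLIPS:
        rot = vr @ np.diag(flip) @ vq.T
        seeds.append(Alignment(rotation=rot, translation=cr - rot @ cq))
    return seeds


def _refine(align: Alignment, ref_grid: VolumeGrid, q_coords, q_radii, q_volume,
            maxiter: int = 120, n_restarts: int = 8, restart_sigma: float = 0.8,
            rng: np.random.Generator | None = None) -> tuple[Alignment, float]:
    """Multi-start Nelder-Mead over 6 rigid DOF (rotation vector + translation).

    The boolean-overlap objective is rugged, so one run from the seed is
    complemented by ``n_restarts`` runs from seeded random perturbations
    (sigma in radians / Å); the best result wins. Deterministic for a fixed rng.
    """
    r0, t0 = align.rotation, align.translation
    if rng is None:
        rng = np.random.default_rng(0)

    def assemble(p):
        rot = Rotation.from_rotvec(p[:3]).as_matrix() @ r0
        return Alignment(rot, t0 + p[3:], align.query_conformer, align.ref_conformer)

    ref_volume = float(ref_grid.occupancy.sum()) * ref_grid.voxel_volume

    def objective(p):
        a = assemble(p)
        return -_pair_sim(ref_grid, ref_volume, a.apply(q_coords), q_radii, q_volume)

    starts = [np.zeros(6)]
    for _ in range(n_restarts):
        starts.append(rng.normal(0.0, restart_sigma, size=6))
    best_p, best_f = np.zeros(6), objective(np.zeros(6))
    for p0 in starts:
        res = minimize(objective, p0, method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 0.01, "fatol": 1e-4,
                                "initial_simplex": p0 + np.vstack(
                                    [np.zeros(6), np.eye(6) * 0.2])})
        if res.fun < best_f:
            best_p, best_f = res.x, res.fun
    return assemble(best_p), -float(best_f)


def _gauss_optimize_pair(qc: np.ndarray, rc: np.ndarray, aQ, aR, vqq: float,
                         vrr: float, rng: np.random.Generator,
                         n_restarts: int, restart_sigma: float,
                         maxiter: int) -> tuple[float, Alignment]:
    """Best Gaussian-Tanimoto alignment for one conformer pair.

    Runs Nelder-Mead from the four principal-axes seeds and from
    ``n_restarts`` random perturbations of the best seed.
    """
    seeds = _seed_alignments(qc, rc)

    def tan(qt):
        vab = _gauss_cross(qt, aQ, rc, aR)
        return vab / (vqq + vrr - vab)

    seeds.sort(key=lambda s: -tan(s.apply(qc)))
    starts = [(s, np.zeros(6)) for s in seeds]
    for _ in range(n_restarts):
        starts.append((seeds[0], rng.normal(0.0, restart_sigma, size=6)))

    best_val, best_align = -1.0, seeds[0]
    for seed, p0 in starts:
        r0, t0 = seed.rotation, seed.translation

        def objective(p):
            rot = Rotation.from_rotvec(p[:3]).as_matrix() @ r0
            return -tan(qc @ rot.T + t0 + p[3:])

        res = minimize(objective, p0, method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 0.01, "fatol": 1e-5,
                                "initial_simplex": p0 + np.vstack(
                                    [np.zeros(6), np.eye(6) * 0.2])})
        if -res.fun > best_val:
            rot = Rotation.from_rotvec(res.x[:3]).as_matrix() @ r0
            best_val = -float(res.fun)
            best_align = Alignment(rot, t0 + res.x[3:])
    return best_val, best_align


def best_alignments(query: ConformerSet, ref: ConformerSet, n_align: int = 4,
                    spacing: float = DEFAULT_SPACING, refine_top: int = 6,
                    refine_maxiter: int = 120, n_restarts: int = 6,
                    restart_sigma: float = 0.8, rng_seed: int = 2020) -> list[ShapeHit]:
    """Top ``n_align`` distinct conformer-pair superpositions by Sim, descending.

    Every conformer x conformer pair is optimized on the smooth Gaussian
    Tanimoto surrogate (principal-axes seeds plus seeded random restarts);
    the ``refine_top`` best pairs are then polished against the voxel-grid
    objective and finally scored with the subsampled hard-sphere estimator.
    Deterministic for fixed ``rng_seed``; ties break lexicographically on
    (query conformer, reference conformer).
    """
    if len(query) == 0 or len(ref) == 0:
        raise ValueError("both conformer sets must be non-empty")
    q_elems = query.heavy_elements()
    q_radii = radii_for(q_elems)
    r_elems = ref.heavy_elements()
    r_radii = radii_for(r_elems)
    aQ, aR = _gauss_alpha(q_radii), _gauss_alpha(r_radii)

    q_coords = [query.heavy_coords(i) for i in range(len(query))]
    r_coords = [ref.heavy_coords(i) for i in range(len(ref))]
    vqq = [_gauss_cross(c, aQ, c, aQ) for c in q_coords]
    vrr = [_gauss_cross(c, aR, c, aR) for c in r_coords]

    candidates: list[tuple[float, int, int, Alignment]] = []
    for qi, qc in enumerate(q_coords):
        for ri, rc in enumerate(r_coords):
            rng = np.random.default_rng((rng_seed + 7919 * qi + 104729 * ri) & 0x7FFFFFFF)
            val, align = _gauss_optimize_pair(qc, rc, aQ, aR, vqq[qi], vrr[ri], rng,
                                              n_restarts, restart_sigma,
                                              maxiter=refine_maxiter)
            align.query_conformer, align.ref_conformer = qi, ri
            candidates.append((val, qi, ri, align))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))

    refined: list[tuple[float, int, int, Alignment]] = []
    for val, qi, ri, a in candidates[:max(refine_top, n_align)]:
        qc = q_coords[qi]
        ref_grid = rasterize(r_coords[ri], r_elems, spacing)
        qg = rasterize(qc, q_elems, spacing)
        q_vol = float(qg.occupancy.sum()) * qg.voxel_volume
        rng = np.random.default_rng((rng_seed + 31 + 7919 * qi + 104729 * ri) & 0x7FFFFFFF)
        a2, _ = _refine(a, ref_grid, qc, q_radii, q_vol, maxiter=refine_maxiter,
                        n_restarts=0, rng=rng)
        # final score with the accurate (subsampled) estimator; keep the better
        # of the polished and unpolished placements
        best_s, best_a = -1.0, a
        for cand in (a, a2):
            gq = rasterize(cand.apply(qc), q_elems, spacing)
            s = shape_similarity(ref_grid, gq)
            if s > best_s:
                best_s, best_a = s, cand
        refined.append((best_s, qi, ri, best_a))
    refined.sort(key=lambda t: (-t[0], t[1], t[2]))

    hits = []
    for s, qi, ri, a in refined[:n_align]:
        hits.append(ShapeHit(query=query.molecule.name, reference=ref.molecule.name,
                             sim=float(min(s, 1.0)), alignment=a))
    return hits


def typed_similarity(query: ConformerSet, ref: ConformerSet, hit: ShapeHit,
                     mode: str = "pharmacophore",
                     spacing: float = DEFAULT_SPACING) -> dict[str, float]:
    """Per-class Sim over subgrids of atoms of one class, at a fixed alignment.

    ``mode='pharmacophore'`` types atoms as donor / acceptor / hydrophobic /
    aromatic / halogen; ``mode='element'`` types by element symbol. A class
    absent from both molecules is omitted; absent from one side only gives 0.
    """
    from .pharmacophore import atom_classes

    a = hit.alignment
    q_all = a.apply(query.heavy_coords(a.query_conformer))
    r_all = ref.heavy_coords(a.ref_conformer)
    q_elems = query.heavy_elements()
    r_elems = ref.heavy_elements()

    if mode == "element":
        q_cls = {e: [i for i, x in enumerate(q_elems) if x == e] for e in set(q_elems)}
        r_cls = {e: [i for i, x in enumerate(r_elems) if x == e] for e in set(r_elems)}
    elif mode == "pharmacophore":
        q_cls = atom_classes(query.molecule)
        r_cls = atom_classes(ref.molecule)
    else:
        raise ValueError(f"unknown typing mode {mode!r}")

    out: dict[str, float] = {}
    for cls in sorted(set(q_cls) | set(r_cls)):
        qi = q_cls.get(cls, [])
        ri = r_cls.get(cls, [])
        if not qi and not ri:
            continue
        if not qi or not ri:
            out[cls] = 0.0
            continue
        ga = rasterize(r_all[ri], [r_elems[i] for i in ri], spacing)
        gb = rasterize(q_all[qi], [q_elems[i] for i in qi], spacing)
        out[cls] = shape_similarity(ga, gb)
    return out


def screen_library(library: list[ConformerSet], reference: ConformerSet,
                   cutoff: float = 0.7, n_align: int = 4,
                   spacing: float = DEFAULT_SPACING, typed: bool = True,
                   refine_top: int = 6, refine_maxiter: int = 120,
                   n_restarts: int = 8, rng_seed: int = 2020):
    """Shape-screen a conformer library against a reference ensemble.

    Keeps at most ``n_align`` alignments per ligand, drops every hit with
    Sim below ``cutoff``, and ranks ligands by their best Sim, descending.
    Returns a pandas DataFrame (one row per retained hit).
    """
    import pandas as pd

    if not library:
        raise ValueError("library must be non-empty")
    rows = []
    for confs in library:
        hits = best_alignments(confs, reference, n_align=n_align, spacing=spacing,
                               refine_top=refine_top, refine_maxiter=refine_maxiter,
                               n_restarts=n_restarts, rng_seed=rng_seed)
        hits = [h for h in hits if h.sim >= cutoff]
        for rank_in_ligand, h in enumerate(hits):
            row = {"query": h.query, "reference": h.reference, "sim": round(h.sim, 4),
                   "alignment_rank": rank_in_ligand + 1,
                   "query_conformer": h.alignment.query_conformer,
                   "ref_conformer": h.alignment.ref_conformer}
            if typed:
                for cls, s in typed_similarity(confs, reference, h).items():
                    row[f"sim_{cls}"] = round(s, 4)
            rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    best = df.groupby("query")["sim"].transform("max")
    df = df.assign(_best=best).sort_values(
        ["_best", "query", "alignment_rank"], ascending=[False, True, True]
    ).drop(columns="_best").reset_index(drop=True)
    ranks = {q: i + 1 for i, q in enumerate(dict.fromkeys(df["query"]))}
    df.insert(0, "rank", df["query"].map(ranks))
    return df
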