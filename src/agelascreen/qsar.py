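"""Voxelized 3D-QSAR: field construction, NIPALS PLS, statistics, maps.

Aligned conformers are voxelized on a shared 0.5 Å lattice into three field
blocks — electrostatic (partial charge smeared over atomic volumes),
hydrophobic (occupancy by nonpolar carbons), and H-bond donor (occupancy at
idealized donor-H tips). The unfolded, variance-filtered voxel descriptors
feed a partial-least-squares regression (NIPALS, mean-centered, unscaled)
against activity; back-projected coefficients give per-voxel, per-class
contribution maps exportable as OpenDX grids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import Molecule
from .pharmacophore import atom_classes
from .shape import radii_for

__all__ = [
    "GridFrame",
    "VoxelField",
    "QsarModel",
    "FitStats",
    "make_frame",
    "build_field",
    "fit_pls",
    "fit_statistics",
    "predict_activity",
    "contribution_map",
    "choose_components",
    "export_dx",
]

FIELD_CLASSES = ("electrostatic", "hydrophobic", "donor")
DONOR_TIP_LENGTH = 1.0   # Å along the idealized donor-H direction
DONOR_TIP_RADIUS = 1.0   # Å capture radius around the tip


@dataclass(frozen=True)
class GridFrame:
    """A shared lattice frame: origin, spacing, and integer shape."""

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def contains(self, coords: np.ndarray, margin: float = 0.0) -> bool:
        o = np.asarray(self.origin)
        hi = o + (np.asarray(self.shape) - 1) * self.spacing
        return bool(np.all(coords >= o - margin) and np.all(coords <= hi + margin))


@dataclass
class VoxelField:
    """Per-class real-valued lattices over one aligned conformer."""

    frame: GridFrame
    blocks: dict[str, np.ndarray]
    name: str = ""

    def unfold(self) -> np.ndarray:
        return np.concatenate([self.blocks[c].ravel() for c in FIELD_CLASSES])


@dataclass
class FitStats:
    r2: float
    sd: float
    rmse: float
    pearson: float


@dataclass
class QsarModel:
    """A fitted voxel-field PLS model."""

    frame: GridFrame
    n_components: int
    x_mean: np.ndarray
    y_mean: float
    col_mask: np.ndarray          # retained (non-zero-variance) columns
    weights: np.ndarray           # W (p_kept, k)
    x_loadings: np.ndarray        # P (p_kept, k)
    y_loadings: np.ndarray        # c (k,)
    scores: np.ndarray            # T (n, k)
    coef: np.ndarray              # regression vector on kept columns
    stats: FitStats | None = None
    training_names: list[str] = dc_field(default_factory=list)

    def coefficient_field(self) -> dict[str, np.ndarray]:
        """Back-projected coefficients as one signed lattice per class."""
        full = np.zeros(self.col_mask.size)
        full[self.col_mask] = self.coef
        out, off = {}, 0
        n = int(np.prod(self.frame.shape))
        for cls in FIELD_CLASSES:
            out[cls] = full[off:off + n].reshape(self.frame.shape)
            off += n
        return out


def make_frame(coord_sets: list[np.ndarray], spacing: float = 0.5,
               pad: float = 3.0) -> GridFrame:
    """Smallest frame covering every coordinate set, padded by ``pad`` Å."""
    allc = np.vstack(coord_sets)
    lo = allc.min(axis=0) - pad
    hi = allc.max(axis=0) + pad
    shape = tuple(int(x) for x in np.ceil((hi - lo) / spacing) + 1)
    return GridFrame(origin=tuple(lo), spacing=spacing, shape=shape)


def _voxel_centers(frame: GridFrame):
    o = np.asarray(frame.origin)
    axes = [o[d] + np.arange(frame.shape[d]) * frame.spacing for d in range(3)]
    return axes


def _sphere_mask(frame: GridFrame, center: np.ndarray, radius: float):
    """Indices of voxels whose centers lie within radius of center."""
    o = np.asarray(frame.origin)
    lo = np.maximum(np.floor((center - radius - o) / frame.spacing).astype(int), 0)
    hi = np.minimum(np.ceil((center + radius - o) / frame.spacing).astype(int) + 1,
                    frame.shape)
    if np.any(lo >= hi):
        return None
    ax = _voxel_centers(frame)
    dx = ax[0][lo[0]:hi[0]] - center[0]
    dy = ax[1][lo[1]:hi[1]] - center[1]
    dz = ax[2][lo[2]:hi[2]] - center[2]
    d2 = dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
    return (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2])), d2 <= radius ** 2


def _heavy_gasteiger_charges(mol: Molecule) -> np.ndarray:
    """Gasteiger charges per heavy atom, hydrogens folded into their heavy
    neighbor so the vector sums to the molecular net charge."""
    molH = Chem.AddHs(Chem.Mol(mol.rdmol))
    AllChem.ComputeGasteigerCharges(molH)
    heavy = [a for a in molH.GetAtoms() if a.GetAtomicNum() > 1]
    charges = []
    for a in heavy:
        q = float(a.GetDoubleProp("_GasteigerCharge"))
        for nb in a.GetNeighbors():
            if nb.GetAtomicNum() == 1:
                q += float(nb.GetDoubleProp("_GasteigerCharge"))
        charges.append(q)
    return np.nan_to_num(np.array(charges), nan=0.0)


def _donor_tips(mol: Molecule, conformer: np.ndarray) -> list[np.ndarray]:
    """Idealized donor-H tip positions: 1.0 Å from each donor heavy atom,
    directed away from the mean of its heavy neighbors."""
    m = mol.rdmol
    heavy = [a.GetIdx() for a in m.GetAtoms() if a.GetAtomicNum() > 1]
    remap = {idx: i for i, idx in enumerate(heavy)}
    tips = []
    for i in atom_classes(mol).get("donor", []):
        atom = m.GetAtomWithIdx(heavy[i])
        nbrs = [remap[nb.GetIdx()] for nb in atom.GetNeighbors()
                if nb.GetAtomicNum() > 1]
        pos = conformer[i]
        if nbrs:
            u = pos - conformer[nbrs].mean(axis=0)
            norm = np.linalg.norm(u)
            u = u / norm if norm > 1e-8 else np.array([0.0, 0.0, 1.0])
        else:
            u = np.array([0.0, 0.0, 1.0])
        tips.append(pos + DONOR_TIP_LENGTH * u)
    return tips


def build_field(mol: Molecule, conformer: np.ndarray, frame: GridFrame) -> VoxelField:
    """Voxelize one aligned conformer into the three field blocks.

    Electrostatic: each heavy atom's partial charge spread uniformly over the
    voxels inside its VdW radius (block total equals molecular net charge).
    Hydrophobic: boolean occupancy by nonpolar carbons. Donor: occupancy
    within 1.0 Å of each idealized donor-H tip.
    """
    conformer = np.asarray(conformer, dtype=float)
    if not frame.contains(conformer, margin=0.5):
        raise ValueError(f"conformer for {mol.name!r} lies outside the training frame")
    elems = [a.GetSymbol() for a in mol.rdmol.GetAtoms() if a.GetAtomicNum() > 1]
    radii = radii_for(elems)
    charges = _heavy_gasteiger_charges(mol)

    elec = np.zeros(frame.shape)
    for pos, r, q in zip(conformer, radii, charges):
        hit = _sphere_mask(frame, pos, r)
        if hit is None:
            continue
        sl, mask = hit
        n = mask.sum()
        if n:
            elec[sl] += q * mask / n

    hydro = np.zeros(frame.shape)
    for i in atom_classes(mol).get("hydrophobic", []):
        hit = _sphere_mask(frame, conformer[i], radii[i])
        if hit is not None:
            sl, mask = hit
            hydro[sl] = np.maximum(hydro[sl], mask.astype(float))

    donor = np.zeros(frame.shape)
    for tip in _donor_tips(mol, conformer):
        hit = _sphere_mask(frame, tip, DONOR_TIP_RADIUS)
        if hit is not None:
            sl, mask = hit
            donor[sl] = np.maximum(donor[sl], mask.astype(float))

    return VoxelField(frame=frame, blocks={"electrostatic": elec, "hydrophobic": hydro,
                                           "donor": donor}, name=mol.name)


def _nipals_pls1(X: np.ndarray, y: np.ndarray, k: int):
    """Single-response NIPALS PLS on centered data. Returns W, P, c, T, coef."""
    n, p = X.shape
    Xr, yr = X.copy(), y.copy()
    W = np.zeros((p, k))
    P = np.zeros((p, k))
    c = np.zeros(k)
    T = np.zeros((n, k))
    for a in range(k):
        w = Xr.T @ yr
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            W, P, c, T = W[:, :a], P[:, :a], c[:a], T[:, :a]
            break
        w /= nw
        t = Xr @ w
        tt = t @ t
        if tt < 1e-14:
            W, P, c, T = W[:, :a], P[:, :a], c[:a], T[:, :a]
            break
        pv = Xr.T @ t / tt
        ca = (yr @ t) / tt
        Xr = Xr - np.outer(t, pv)
        yr = yr - ca * t
        W[:, a], P[:, a], c[a], T[:, a] = w, pv, ca, t
    coef = W @ np.linalg.solve(P.T @ W, c) if W.shape[1] else np.zeros(p)
    return W, P, c, T, coef


def fit_pls(fields: list[VoxelField], activity, n_components: int = 2,
            names: list[str] | None = None) -> QsarModel:
    """Fit a PLS model on unfolded, variance-filtered voxel descriptors.

    Columns with zero variance across training molecules are dropped;
    descriptors are mean-centered but not scaled. Deterministic.
    """
    y = np.asarray(activity, dtype=float)
    n = len(fields)
    if n < 3:
        raise ValueError("need at least 3 training molecules")
    if not np.all(np.isfinite(y)) or len(y) != n:
        raise ValueError("activities must be finite, one per field")
    if n_components >= n:
        raise ValueError("n_components must be < number of training molecules")
    frame = fields[0].frame
    if any(f.frame != frame for f in fields):
        raise ValueError("all fields must share one frame")

    X_full = np.vstack([f.unfold() for f in fields])
    var = X_full.var(axis=0)
    mask = var > 1e-14
    X = X_full[:, mask]
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, c, T, coef = _nipals_pls1(X - x_mean, y - y_mean, n_components)

    model = QsarModel(frame=frame, n_components=W.shape[1], x_mean=x_mean,
                      y_mean=y_mean, col_mask=mask, weights=W, x_loadings=P,
                      y_loadings=c, scores=T, coef=coef,
                      training_names=names or [f.name for f in fields])
    model.stats = fit_statistics(model, fields, y)
    return model


def predict_activity(model: QsarModel, field: VoxelField) -> float:
    """Linear form <coefficients, descriptors> + intercept."""
    if field.frame != model.frame:
        raise ValueError("field frame does not match the training frame")
    x = field.unfold()[model.col_mask]
    return float((x - model.x_mean) @ model.coef + model.y_mean)


def fit_statistics(model: QsarModel, fields: list[VoxelField], activity) -> FitStats:
    """R², residual SD (n-1), RMSE, and Pearson r of predictions vs activity."""
    y = np.asarray(activity, dtype=float)
    if np.var(y) < 1e-14:
        raise ValueError("zero activity variance; statistics undefined")
    yhat = np.array([predict_activity(model, f) for f in fields])
    resid = y - yhat
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    sd = float(np.std(resid, ddof=1)) if len(y) > 1 else 0.0
    rmse = float(np.sqrt(ss_res / len(y)))
    denom = np.std(yhat) * np.std(y)
    pearson = float(np.corrcoef(yhat, y)[0, 1]) if denom > 1e-14 else 0.0
    return FitStats(r2=r2, sd=sd, rmse=rmse, pearson=pearson)


def choose_components(fields: list[VoxelField], activity, max_components: int = 7,
                      gain_tol: float = 0.01) -> int:
    """Smallest component count at the training-R² plateau.

    Components are added while each one improves training R² by at least
    ``gain_tol``, up to ``max_components`` (and always < n_training).
    """
    y = np.asarray(activity, dtype=float)
    cap = min(max_components, len(fields) - 1)
    best_k, last_r2 = 1, -np.inf
    for k in range(1, cap + 1):
        m = fit_pls(fields, y, n_components=k)
        if m.stats.r2 - last_r2 < gain_tol and k > 1:
            break
        best_k, last_r2 = k, m.stats.r2
    return best_k


def export_dx(lattice: np.ndarray, frame: GridFrame, path) -> None:
    """Write one scalar lattice as an OpenDX grid (.dx)."""
    nx, ny, nz = lattice.shape
    o = frame.origin
    d = frame.spacing
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {o[0]:.4f} {o[1]:.4f} {o[2]:.4f}\n")
        fh.write(f"delta {d:.4f} 0 0\ndelta 0 {d:.4f} 0\ndelta 0 0 {d:.4f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {lattice.size} data follows\n")
        flat = lattice.ravel()
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "field" class field\n')
        fh.write('component "positions" value 1\ncomponent "connections" value 2\n')
        fh.write('component "data" value 3\n')


def contribution_map(model: QsarModel, out_dir=None, top_n: int = 20):
    """Per-class signed coefficient lattices, optionally exported.

    When ``out_dir`` is given, writes one OpenDX grid per class plus a JSON
    summary of the ``top_n`` voxels by |coefficient|. Returns the lattices
    and the summary list.
    """
    fields = model.coefficient_field()
    summary = []
    for cls, lat in fields.items():
        flat = np.abs(lat.ravel())
        order = np.argsort(-flat)
        for idx in order[:top_n]:
            if flat[idx] == 0.0:
                break
            ijk = np.unravel_index(idx, lat.shape)
            pos = [model.frame.origin[d] + ijk[d] * model.frame.spacing for d in range(3)]
            summary.append({"class": cls, "voxel": [int(v) for v in ijk],
                            "position": [round(float(p), 3) for p in pos],
                            "coefficient": float(lat[ijk])})
    summary.sort(key=lambda r: -abs(r["coefficient"]))
    summary = summary[:top_n]
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        for cls, lat in fields.items():
            export_dx(lat, model.frame, os.path.join(out_dir, f"coef_{cls}.dx"))
        with open(os.path.join(out_dir, "top_voxels.json"), "w") as fh:
            json.dump(summary, fh, indent=1)
    return fields, summary
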