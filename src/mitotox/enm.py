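"""Anisotropic elastic-network model and perturbation response scanning.

A structure is coarse-grained to nodes (Cα atoms of the receptor, heavy
atoms of a ligand) joined by harmonic springs.  The 3N×3N Hessian is built
from 3×3 super-elements: for connected pairs,

    H_ij = −(γ/s_ij²) (r_j − r_i)(r_j − r_i)ᵀ        (cutoff mode)
    H_ij = −(1/s_ij^(p+2)) (r_j − r_i)(r_j − r_i)ᵀ   (distance-weighted mode)

and diagonal blocks H_ii = −Σ_{j≠i} H_ij.  Its pseudo-inverse (excluding
the six rigid-body modes) is the fluctuation covariance of the network.
Perturbation response scanning applies localized forces at each node in
turn and reads off the displacement magnitude everywhere else, giving the
N×N local perturbation-response (LPRS) map used to compare unbound and
ligand-bound receptor states.

The published cutoff default is 4 Å with γ = 0.5, far below the 12–15 Å
conventional for Cα networks (consecutive Cα sit near 3.8 Å); disconnected
networks therefore warn rather than fail, and 13 Å is the suggested
alternative.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import GeometryError, PDBFormatError

CONVENTIONAL_CUTOFF = 13.0  # Å, typical anisotropic-network choice


@dataclass
class ElasticNetwork:
    """Coarse-grained harmonic network over 3D nodes."""

    coords: np.ndarray                 # N×3, Å
    labels: tuple[str, ...] = ()
    gamma: float = 0.5
    cutoff: float = 4.0
    p_exponent: int = 2
    mode: str = "cutoff"               # "cutoff" | "distance_weighted"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise GeometryError("coords must be N×3")
        if self.coords.shape[0] < 2:
            raise GeometryError("an elastic network needs at least 2 nodes")
        if not np.all(np.isfinite(self.coords)):
            raise GeometryError("coordinates must be finite")
        if self.gamma <= 0 or self.cutoff <= 0:
            raise GeometryError("gamma and cutoff must be positive")
        if self.mode not in ("cutoff", "distance_weighted"):
            raise GeometryError(f"unknown mode {self.mode!r}")
        if not self.labels:
            self.labels = tuple(f"node{i}" for i in range(len(self.coords)))
        if len(self.labels) != len(self.coords):
            raise GeometryError("one label per node required")

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]


def build_hessian(net: ElasticNetwork) -> np.ndarray:
    """The 3N×3N anisotropic Hessian of the network.

    Symmetric positive semi-definite; a connected network has exactly six
    zero eigenvalues (rigid translations and rotations).
    """
    r = net.coords
    n = net.n_nodes
    diff = r[None, :, :] - r[:, None, :]           # diff[i,j] = r_j - r_i
    s2 = np.sum(diff**2, axis=-1)
    tiny = s2 + np.eye(n)                          # silence the diagonal
    if np.any(tiny[~np.eye(n, dtype=bool)] < 1e-12):
        raise GeometryError("coincident nodes (distance < 1e-6 Å)")
    if net.mode == "cutoff":
        k = np.where(np.sqrt(s2) < net.cutoff, net.gamma / tiny, 0.0)
    else:
        s = np.sqrt(tiny)
        k = 1.0 / s ** (net.p_exponent + 2)
    np.fill_diagonal(k, 0.0)

    blocks = -k[:, :, None, None] * (diff[:, :, :, None] * diff[:, :, None, :])
    # diagonal super-elements: negative sum of the row's off-diagonals
    idx = np.arange(n)
    blocks[idx, idx] = -np.sum(blocks, axis=1)
    return blocks.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)


def contact_count(net: ElasticNetwork) -> int:
    """Number of springs under the network's connection rule."""
    d = np.linalg.norm(net.coords[None] - net.coords[:, None], axis=-1)
    if net.mode != "cutoff":
        n = net.n_nodes
        return n * (n - 1) // 2
    mask = (d < net.cutoff) & ~np.eye(net.n_nodes, dtype=bool)
    return int(mask.sum()) // 2


def is_connected(net: ElasticNetwork) -> bool:
    """Whether the spring graph is a single component."""
    import networkx as nx

    d = np.linalg.norm(net.coords[None] - net.coords[:, None], axis=-1)
    if net.mode != "cutoff":
        return True
    g = nx.from_numpy_array((d < net.cutoff) & ~np.eye(net.n_nodes, dtype=bool))
    return nx.is_connected(g)


def covariance_from_hessian(hessian: np.ndarray, zero_mode_rtol: float = 1e-8) -> np.ndarray:
    """Moore–Penrose pseudo-inverse of the Hessian over its non-null modes.

    Eigenvalues below ``zero_mode_rtol`` times the largest are treated as
    rigid-body (zero) modes and excluded.  More than six such modes means
    the network is disconnected; a warning is issued and the pseudo-inverse
    is still returned.
    """
    w, v = np.linalg.eigh(hessian)
    thresh = zero_mode_rtol * np.max(np.abs(w))
    null = w < thresh
    if null.sum() > 6:
        warnings.warn(
            f"{int(null.sum())} near-zero modes (expected 6): network is disconnected",
            stacklevel=2,
        )
    inv_w = np.where(null, 0.0, np.divide(1.0, w, out=np.zeros_like(w), where=~null))
    return (v * inv_w) @ v.T


def count_zero_modes(hessian: np.ndarray, zero_mode_rtol: float = 1e-8) -> int:
    w = np.linalg.eigvalsh(hessian)
    return int(np.sum(w < zero_mode_rtol * np.max(np.abs(w))))


@dataclass(frozen=True)
class PRSMap:
    """N×N perturbation-response map: entry (i, j) is the mean displacement
    magnitude of node j when node i is perturbed."""

    response: np.ndarray
    labels: tuple[str, ...]
    condition_label: str = "unbound"
    normalization: str = "none"

    def normalized(self, how: str = "row") -> "PRSMap":
        r = self.response
        if how == "row":
            denom = r.sum(axis=1, keepdims=True)
            denom[denom == 0] = 1.0
            r = r / denom
        elif how == "global":
            peak = r.max()
            r = r / peak if peak > 0 else r
        else:
            raise ValueError(f"unknown normalization {how!r}")
        return PRSMap(r, self.labels, self.condition_label, how)

    def submap(self, keep: np.ndarray) -> "PRSMap":
        keep = np.asarray(keep)
        labels = tuple(np.asarray(self.labels, dtype=object)[keep])
        return PRSMap(self.response[np.ix_(keep, keep)], labels,
                      self.condition_label, self.normalization)


def _force_directions(n_forces: int, seed: int | None) -> np.ndarray:
    """Coordinate axes plus seeded random unit directions."""
    dirs = [np.eye(3)]
    if n_forces:
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(n_forces, 3))
        dirs.append(v / np.linalg.norm(v, axis=1, keepdims=True))
    return np.vstack(dirs)


def prs_map(net: ElasticNetwork, n_forces: int = 7, seed: int | None = None,
            condition_label: str = "unbound", covariance: np.ndarray | None = None) -> PRSMap:
    """Perturbation response scanning over all nodes.

    Unit forces along the 3 coordinate axes plus ``n_forces`` seeded random
    unit directions are applied at each node i in turn; the response of
    node j is the root-mean-square over forces of ‖C_ji f‖ with C the
    covariance.  The RMS aggregation makes the axes-only response equal to
    ‖C_ji‖_F/√3, which is exactly invariant under rigid rotation of the
    structure (an arithmetic mean over a fixed frame is not).
    """
    if n_forces < 0:
        raise ValueError("n_forces must be >= 0")
    if covariance is None:
        covariance = covariance_from_hessian(build_hessian(net))
    n = net.n_nodes
    forces = _force_directions(n_forces, seed)          # F×3
    c = covariance.reshape(n, 3, n, 3)
    # disp[i, j, f] = ||C[j, :, i, :] @ force_f||
    prod = np.einsum("jaib,fb->ijfa", c, forces)
    response = np.sqrt((np.linalg.norm(prod, axis=-1) ** 2).mean(axis=2))
    return PRSMap(response, net.labels, condition_label)


def bound_condition(net: ElasticNetwork, ligand_coords: np.ndarray,
                    ligand_labels: tuple[str, ...] | None = None,
                    contact_cutoff: float | None = None) -> ElasticNetwork:
    """Augment a receptor network with coarse-grained ligand nodes.

    Springs between all node pairs (receptor–receptor, receptor–ligand,
    ligand–ligand) follow the same connection rule; receptor labels are
    preserved so the receptor-only submap can be compared with the unbound
    condition.  Warns when the ligand makes no receptor contact.
    """
    ligand_coords = np.atleast_2d(np.asarray(ligand_coords, dtype=float))
    if ligand_coords.shape[0] < 1 or ligand_coords.shape[1] != 3:
        raise GeometryError("ligand_coords must be M×3 with M >= 1")
    if ligand_labels is None:
        ligand_labels = tuple(f"ligand{i}" for i in range(len(ligand_coords)))
    cutoff = contact_cutoff if contact_cutoff is not None else net.cutoff
    d = np.linalg.norm(net.coords[:, None] - ligand_coords[None], axis=-1)
    if net.mode == "cutoff" and not np.any(d < cutoff):
        warnings.warn("ligand makes no contact with the receptor: bound map will equal unbound",
                      stacklevel=2)
    return replace(
        net,
        coords=np.vstack([net.coords, ligand_coords]),
        labels=tuple(net.labels) + tuple(ligand_labels),
        cutoff=cutoff,
    )


def receptor_mask(bound_net: ElasticNetwork, n_receptor: int) -> np.ndarray:
    return np.arange(bound_net.n_nodes) < n_receptor


def _resolve_altloc(atom):
    """Altloc 'A' preferred, else the first alternative."""
    if not atom.is_disordered():
        return atom
    ids = atom.disordered_get_id_list()
    return atom.disordered_get("A" if "A" in ids else sorted(ids)[0])


def read_calpha_pdb(path, heavy_atoms: bool = False) -> tuple[np.ndarray, tuple[str, ...]]:
    """Node coordinates and labels from PDB ATOM/HETATM records.

    One node per residue at its Cα by default (``heavy_atoms=True`` keeps
    every non-hydrogen atom).  Altloc 'A' or blank wins; insertion codes
    are kept in the label.  Raises PDBFormatError (with the offending line
    number, via the strict parser) on malformed records, and when no
    suitable atoms exist.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    path = Path(path)
    try:
        structure = PDBParser(PERMISSIVE=0, QUIET=True).get_structure(path.stem, path)
    except PDBConstructionException as exc:
        raise PDBFormatError(f"{path.name}: {exc}") from exc
    coords: list[np.ndarray] = []
    labels: list[str] = []
    model = next(iter(structure), None)
    if model is not None:
        for chain in model:
            chain_id = chain.id.strip() or "_"
            for res in chain:
                _, seq, icode = res.get_id()
                key = f"{chain_id}:{res.get_resname()}{seq}{icode.strip()}"
                if heavy_atoms:
                    for atom in res:
                        atom = _resolve_altloc(atom)
                        if (atom.element or "").upper() == "H":
                            continue
                        coords.append(atom.get_coord())
                        labels.append(f"{key}:{atom.get_name()}")
                elif "CA" in res:
                    coords.append(_resolve_altloc(res["CA"]).get_coord())
                    labels.append(key)
    if not coords:
        raise PDBFormatError(f"{path.name}: no usable CA/heavy atoms found")
    return np.asarray(coords, dtype=float), tuple(labels)


def export_map(m: PRSMap, out_dir, stem: str, net: ElasticNetwork | None = None,
               seed: int | None = None) -> dict:
    """Write a PRS map as CSV, 8-bit grayscale PNG (min–max scaled) and a
    sidecar JSON recording the scaling and run parameters."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    np.savetxt(csv_path, m.response, delimiter=",")
    lo, hi = float(m.response.min()), float(m.response.max())
    scale = (m.response - lo) / (hi - lo) if hi > lo else np.zeros_like(m.response)
    img = Image.fromarray((scale * 255).round().astype(np.uint8), mode="L")
    png_path = out_dir / f"{stem}.png"
    img.save(png_path)
    meta = {
        "condition": m.condition_label,
        "normalization": m.normalization,
        "min": lo,
        "max": hi,
        "n_nodes": int(m.response.shape[0]),
        "seed": seed,
    }
    if net is not None:
        meta.update({"gamma": net.gamma, "cutoff": net.cutoff,
                     "mode": net.mode, "p_exponent": net.p_exponent})
    (out_dir / f"{stem}.json").write_text(json.dumps(meta, indent=2))
    return meta
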