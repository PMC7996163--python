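"""Synthetic inputs for every pipeline stage — no downloads required.

Generators are pure functions of their configuration and seed: ideal
α-helix Cα traces (stand-ins for a receptor structure), random ligand
blobs, exactly-known fractal images (line, filled square, Sierpinski
carpet) and linear-model QSTR datasets with known coefficients for
parameter-recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import cos, radians, sin, sqrt

import numpy as np
import pandas as pd

from .qstr import QstrDataset

#: descriptor sampling ranges matching realistic nanotube descriptor scales
DESCRIPTOR_RANGES = {
    "GNar": (1.0, 3.0),
    "MAXDP": (0.0, 30.0),
    "PW5": (0.0, 1.0),
    "LOC": (0.0, 4.0),
}

#: default generating coefficients for synthetic QSTR responses, loosely
#: shaped like the pristine-tube model
DEFAULT_QSTR_COEFFS = {"GNar": -8.0, "MAXDP": 0.6, "PW5": -5.0, "LOC": -2.0}
DEFAULT_QSTR_INTERCEPT = -3.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for every generator; a fixed seed makes all outputs bitwise
    reproducible."""

    seed: int = 7
    n_residues: int = 30
    helix_rise: float = 1.5       # Å per residue
    helix_radius: float = 2.3     # Å
    helix_twist: float = 100.0    # degrees per residue
    qstr_n: int = 45
    qstr_sigma: float = 0.5
    qstr_coefficients: dict = field(default_factory=lambda: dict(DEFAULT_QSTR_COEFFS))
    qstr_intercept: float = DEFAULT_QSTR_INTERCEPT

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise ValueError("need at least 4 residues")


def helix_coords(cfg: SyntheticConfig) -> np.ndarray:
    """Ideal α-helix Cα trace.

    Consecutive Cα distance is the constant chord
    sqrt(rise² + (2 r sin(twist/2))²) ≈ 3.83 Å at canonical parameters.
    """
    i = np.arange(cfg.n_residues)
    theta = np.radians(cfg.helix_twist) * i
    return np.column_stack([
        cfg.helix_radius * np.cos(theta),
        cfg.helix_radius * np.sin(theta),
        cfg.helix_rise * i,
    ])


def helix_ca_distance(cfg: SyntheticConfig) -> float:
    """Closed-form consecutive-Cα chord length of the ideal helix."""
    chord = 2.0 * cfg.helix_radius * sin(radians(cfg.helix_twist) / 2.0)
    return sqrt(cfg.helix_rise**2 + chord**2)


def helix_pdb(cfg: SyntheticConfig, chain: str = "A") -> str:
    """The helix serialized as a single-chain poly-alanine Cα-only PDB."""
    lines = []
    for i, (x, y, z) in enumerate(helix_coords(cfg), start=1):
        lines.append(
            f"ATOM  {i:5d}  CA  ALA {chain}{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f" C  "
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_helix_structure(cfg: SyntheticConfig, path=None) -> tuple[np.ndarray, str]:
    """Coordinates plus PDB text; optionally written to ``path``."""
    coords = helix_coords(cfg)
    text = helix_pdb(cfg)
    if path is not None:
        from pathlib import Path

        Path(path).write_text(text)
    return coords, text


def make_ligand_blob(cfg: SyntheticConfig, center, n_atoms: int = 8,
                     radius: float = 3.0) -> np.ndarray:
    """Seeded uniform points inside a sphere around ``center`` — a
    coarse-grained stand-in for a docked ligand."""
    if n_atoms < 1:
        raise ValueError("need at least one ligand atom")
    rng = np.random.default_rng(cfg.seed)
    pts = np.empty((n_atoms, 3))
    filled = 0
    while filled < n_atoms:
        cand = rng.uniform(-radius, radius, size=(2 * n_atoms, 3))
        keep = cand[np.linalg.norm(cand, axis=1) <= radius]
        take = min(len(keep), n_atoms - filled)
        pts[filled:filled + take] = keep[:take]
        filled += take
    return pts + np.asarray(center, dtype=float)


def _sierpinski(level: int) -> np.ndarray:
    cell = np.ones((1, 1), dtype=bool)
    for _ in range(level):
        n = cell.shape[0]
        nxt = np.zeros((3 * n, 3 * n), dtype=bool)
        for bi in range(3):
            for bj in range(3):
                if bi == 1 and bj == 1:
                    continue
                nxt[bi * n:(bi + 1) * n, bj * n:(bj + 1) * n] = cell
        cell = nxt
    return cell


def make_fractal_image(kind: str, level: int = 5) -> np.ndarray:
    """Exactly-known test sets for the box counter.

    ``line``: one foreground row of a 2^level square (dimension 1).
    ``square``: a filled 2^level square (dimension 2).
    ``sierpinski_carpet``: the level-k carpet on a 3^k grid with 8^k
    foreground pixels (dimension log 8 / log 3 ≈ 1.8928).
    """
    if kind == "line":
        size = 2**level
        img = np.zeros((size, size), dtype=bool)
        img[size // 2, :] = True
        return img
    if kind == "square":
        size = 2**level
        return np.ones((size, size), dtype=bool)
    if kind == "sierpinski_carpet":
        if level < 3:
            raise ValueError("carpet needs level >= 3")
        return _sierpinski(level)
    raise ValueError(f"unknown fractal kind {kind!r}")


def make_qstr_dataset(cfg: SyntheticConfig) -> QstrDataset:
    """Descriptor table with a known linear response plus Gaussian noise.

    Descriptors are sampled uniformly over realistic ranges; the true
    coefficients and intercept are stored on the dataset for recovery
    tests.
    """
    if cfg.qstr_n < 10:
        raise ValueError("need at least 10 rows")
    rng = np.random.default_rng(cfg.seed)
    names = list(cfg.qstr_coefficients)
    cols = {}
    for name in names:
        lo, hi = DESCRIPTOR_RANGES.get(name, (0.0, 1.0))
        cols[name] = rng.uniform(lo, hi, size=cfg.qstr_n)
    table = pd.DataFrame(cols)
    response = cfg.qstr_intercept + sum(
        cfg.qstr_coefficients[name] * table[name] for name in names)
    response = response + rng.normal(0.0, cfg.qstr_sigma, size=cfg.qstr_n)
    table.insert(0, "label", [f"synthetic {i}" for i in range(cfg.qstr_n)])
    table["observed"] = response
    return QstrDataset(table, dict(cfg.qstr_coefficients), cfg.qstr_intercept)
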