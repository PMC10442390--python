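"""Sphere-probe pore-radius profiling and two-tier constriction detection.

A simplified, deterministic HOLE-style profiler: along the (auto-detected or
supplied) pore axis, each axial slab's radius is the largest sphere centred in
that plane that touches no atom, found by a coarse in-plane grid search plus
local refinement.  Paired radius minima one α-helix turn (~5.4 Å) apart are
reported as two-tier constriction candidates -- the geometry of the double
hydrophobic ring that forms the fast-inactivation gate at the bottom of the
S6 helices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.signal import find_peaks

__all__ = ["AtomSet", "PoreProfile", "VDW_RADII", "load_structure",
           "radius_profile", "find_constrictions"]

# Bondi van der Waals radii (Å); fallback 1.7 for unlisted elements
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}
DEFAULT_VDW = 1.70
RADIUS_CUTOFF = 15.0  # Å; slabs wider than this are treated as unbounded


@dataclass
class AtomSet:
    """Coordinates plus van der Waals radii and residue metadata."""

    coords: np.ndarray  # (n, 3) Å
    radii: np.ndarray  # (n,) Å
    elements: list[str]
    residues: list[tuple[str, int, str]]  # (chain, seq id, residue name)
    source: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.coords) == 0:
            raise ValueError("empty atom selection")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.radii <= 0):
            raise ValueError("van der Waals radii must be > 0")

    def __len__(self) -> int:
        return len(self.coords)


def load_structure(path: str, include_hetero: bool = False) -> AtomSet:
    """Load protein atoms from a PDB or mmCIF file with Bondi radii.

    Hetero records (detergents, lipids, waters) are excluded by default,
    since non-protein densities lodged in the pore confound the profile.
    For altloc duplicates the highest-occupancy conformer is kept.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    coords, radii, elements, residues = [], [], [], []
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            if het and not include_hetero:
                continue
            if res.is_water() and not include_hetero:
                continue
            best: dict[str, "gemmi.Atom"] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                el = atom.element.name.upper()
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                radii.append(VDW_RADII.get(el, DEFAULT_VDW))
                elements.append(el)
                residues.append((chain.name, res.seqid.num, res.name))
    if not coords:
        raise ValueError(f"no atoms selected from {path} "
                         f"(include_hetero={include_hetero})")
    return AtomSet(coords=np.asarray(coords, float),
                   radii=np.asarray(radii, float),
                   elements=elements, residues=residues,
                   source={"path": str(path), "include_hetero": include_hetero})


@dataclass
class PoreProfile:
    """Radius along the permeation pathway.

    ``s`` increases from the extracellular toward the intracellular end;
    ``z`` is the same coordinate in the (rotated) structure frame.
    """

    s: np.ndarray  # axial coordinate, Å, strictly increasing, fixed step
    radius: np.ndarray  # Å
    centers: np.ndarray  # (n, 2) in-plane center path
    axis: np.ndarray  # unit vector in the original frame
    z: np.ndarray | None = None  # same positions in the rotated frame
    truncated: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"s": self.s, "z": self.z, "radius": self.radius,
                             "cx": self.centers[:, 0], "cy": self.centers[:, 1]})


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    c = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    axis = vt[0]
    return axis / np.linalg.norm(axis)


def _rotate_to_axis(coords: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Rotate so that ``axis`` maps to +z."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    c = float(np.dot(axis, z))
    if s < 1e-12:
        return coords if c > 0 else coords * np.array([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    return coords @ R.T


def _clearance(c_xy: np.ndarray, z: float, coords: np.ndarray,
               radii: np.ndarray) -> float:
    d = np.sqrt((coords[:, 0] - c_xy[0]) ** 2 + (coords[:, 1] - c_xy[1]) ** 2
                + (coords[:, 2] - z) ** 2)
    return float(np.min(d - radii))


def radius_profile(atoms: AtomSet, axis: np.ndarray | str = "auto",
                   step: float = 0.25, coarse: float = 0.5,
                   pad: float = 2.0) -> PoreProfile:
    """Pore-radius profile along the axis by largest-inscribed-sphere search.

    Per axial slab the pore radius is max over in-plane centers c of
    min_i(|c - x_i| - vdw_i), located by a coarse grid (default 0.5 Å) then
    Nelder-Mead refinement; center-path continuity is enforced (at most 1 Å
    of in-plane drift per step after the first slab).  Slabs whose radius
    exceeds 15 Å truncate the profile with a flag.
    """
    if isinstance(axis, str):
        if axis != "auto":
            raise ValueError("axis must be 'auto' or a 3-vector")
        ax = _principal_axis(atoms.coords)
    else:
        ax = np.asarray(axis, float)
        ax = ax / np.linalg.norm(ax)
    xyz = _rotate_to_axis(atoms.coords, ax)
    radii = atoms.radii
    z_lo, z_hi = xyz[:, 2].min() + pad, xyz[:, 2].max() - pad
    n_steps = int(np.floor((z_hi - z_lo) / step))
    if n_steps < 2:
        raise ValueError("structure too thin along the pore axis")
    z_grid = z_lo + step * np.arange(n_steps + 1)

    center0 = xyz[:, :2].mean(axis=0)
    s_vals, r_vals, c_vals = [], [], []
    prev_c = None
    truncated = False
    grid_1d = np.arange(-6.0, 6.0 + coarse / 2, coarse)
    for z in z_grid:
        # coarse grid around the previous center (continuity <= 1 Å/step)
        if prev_c is None:
            offsets = np.stack(np.meshgrid(grid_1d, grid_1d), axis=-1).reshape(-1, 2)
            cands = center0 + offsets
        else:
            local = np.arange(-1.0, 1.0 + coarse / 2, coarse / 2)
            offsets = np.stack(np.meshgrid(local, local), axis=-1).reshape(-1, 2)
            cands = prev_c + offsets
        vals = np.array([_clearance(c, z, xyz, radii) for c in cands])
        best = cands[int(np.argmax(vals))]
        res = minimize(lambda c: -_clearance(c, z, xyz, radii), best,
                       method="Nelder-Mead",
                       options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 200})
        c_best = res.x
        if prev_c is not None and np.linalg.norm(c_best - prev_c) > 1.0:
            c_best = prev_c + (c_best - prev_c) / np.linalg.norm(c_best - prev_c)
        r = max(_clearance(c_best, z, xyz, radii), 0.0)
        if r > RADIUS_CUTOFF:
            truncated = True
            break
        s_vals.append(z)
        r_vals.append(r)
        c_vals.append(c_best)
        prev_c = c_best

    z_arr = np.asarray(s_vals)
    # report s increasing extracellular -> intracellular: the rotated +z end
    # is taken as extracellular, so flip the coordinate (z kept alongside)
    s = z_arr.max() - z_arr
    order = np.argsort(s)
    return PoreProfile(s=s[order], radius=np.asarray(r_vals)[order],
                       centers=np.asarray(c_vals)[order], axis=ax,
                       z=z_arr[order], truncated=truncated)


@dataclass
class Constriction:
    s: float
    radius: float
    prominence: float
    nearest_residue: tuple[str, int, str] | None = None


@dataclass
class TwoTierPair:
    top: Constriction
    bottom: Constriction

    @property
    def separation(self) -> float:
        return abs(self.bottom.s - self.top.s)


def find_constrictions(profile: PoreProfile, helix_turn: float = 5.4,
                       tol: float = 1.5, prominence: float = 0.2,
                       atoms: AtomSet | None = None,
                       ) -> tuple[list[Constriction], list[TwoTierPair]]:
    """Ranked radius minima and paired two-tier constriction candidates.

    Minima are located on the discrete profile with the given prominence
    (Å); pairs separated by one helix turn within ``tol`` are reported as
    two-tier barriers, annotated with the nearest residue when structure
    metadata is available.
    """
    step = profile.s[1] - profile.s[0]
    if (profile.s[-1] - profile.s[0]) < 2 * helix_turn:
        raise ValueError("profile shorter than two helix turns")
    idx, props = find_peaks(-profile.radius, prominence=prominence)
    minima = []
    for i, p in zip(idx, props["prominences"]):
        near = None
        if atoms is not None:
            xyz = _rotate_to_axis(atoms.coords, profile.axis)
            z_struct = profile.z[i] if profile.z is not None else profile.s[i]
            center = profile.centers[i]
            d = np.sqrt((xyz[:, 0] - center[0]) ** 2 + (xyz[:, 1] - center[1]) ** 2
                        + (xyz[:, 2] - z_struct) ** 2) - atoms.radii
            near = atoms.residues[int(np.argmin(d))]
        minima.append(Constriction(s=float(profile.s[i]),
                                   radius=float(profile.radius[i]),
                                   prominence=float(p), nearest_residue=near))
    minima.sort(key=lambda m: m.radius)
    pairs = []
    for a in range(len(minima)):
        for b in range(a + 1, len(minima)):
            sep = abs(minima[a].s - minima[b].s)
            if helix_turn - tol <= sep <= helix_turn + tol:
                top, bot = sorted((minima[a], minima[b]), key=lambda m: m.s)
                pairs.append(TwoTierPair(top=top, bottom=bot))
    pairs.sort(key=lambda p: min(p.top.radius, p.bottom.radius))
    return minima, pairs
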