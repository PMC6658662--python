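"""Channel pore profile and binding-site geometry.

The pore is profiled slice-by-slice along a user-given axis (the channel is
axis-aligned after PBC cleanup and centering): in each z-slice the largest
circle inscribed among the vdW spheres of the protein is found by a coarse
grid search refined with a simplex optimiser. The profile yields a surface
point cloud whose bounding-box extents along Z and X summarise pore size.

Site geometry reduces four labelled side-chain oxygens to their XY
projection: quadrilateral side lengths, diagonals, diagonal ratio and
crossing angle — the descriptors that distinguish a rectangular from a
diamond-like arrangement of the Mg²⁺-site asparagines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .structure import kabsch_superpose
from .trajio import Frame, IndexGroup, SelectionError, Topology

__all__ = [
    "PoreProfile",
    "SiteGeometry",
    "pore_profile",
    "site_geometry",
    "gate_distance",
    "helix_align_rmsd",
]


@dataclass
class PoreProfile:
    z: np.ndarray              # slice centers, nm
    center_xy: np.ndarray      # (n, 2) nm
    radius: np.ndarray         # nm
    surface: np.ndarray        # (m, 3) point cloud, nm
    extent_z: float            # nm
    extent_x: float            # nm

    @property
    def min_radius(self) -> float:
        return float(self.radius.min()) if len(self.radius) else np.nan

    @property
    def min_radius_z(self) -> float:
        return float(self.z[np.argmin(self.radius)]) if len(self.radius) else np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"z_nm": self.z, "cx_nm": self.center_xy[:, 0],
             "cy_nm": self.center_xy[:, 1], "radius_nm": self.radius}
        )


@dataclass
class SiteGeometry:
    positions: np.ndarray        # (4, 3) nm, input order
    projections: np.ndarray      # (4, 2) nm, ordered by polar angle
    sides_A: np.ndarray          # (4,) Å, consecutive around the quadrilateral
    diagonals_A: np.ndarray      # (2,) Å
    diagonal_ratio: float        # shorter / longer, in (0, 1]
    crossing_angle_deg: float    # acute angle between the diagonals
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "sides_A": [float(s) for s in self.sides_A],
            "diagonals_A": [float(d) for d in self.diagonals_A],
            "diagonal_ratio": float(self.diagonal_ratio),
            "crossing_angle_deg": float(self.crossing_angle_deg),
            "degenerate": bool(self.degenerate),
        }


def _slice_clearance(p_xy, pos_xy, radii):
    d = np.sqrt(((pos_xy - p_xy) ** 2).sum(axis=1))
    return float((d - radii).min())


def pore_profile(
    frame: Frame,
    topology: Topology,
    protein_group: IndexGroup,
    z_range: tuple[float, float],
    slice_thickness: float = 0.1,
    n_azimuth: int = 36,
    search_halfwidth: float = 0.5,
    slab_halfwidth: float | None = None,
) -> PoreProfile:
    """Maximal-inscribed-circle pore profile along the z axis.

    Per slice, atoms within a z-slab (half-width
    ``max(slice_thickness, 0.2)`` nm unless given) bound the largest
    inscribed circle: the center maximises the lateral clearance
    r(p) = min_i (|p − atom_i|_xy − vdW_i), searched on a coarse grid
    around the previous slice's center and refined with Nelder–Mead.
    Slices with no atoms within 2 nm of the running center truncate the
    profile with a warning.
    """
    idx = protein_group.indices(topology)
    pos = frame.coordinates[idx]
    radii = topology.vdw_radii[idx]
    z0, z1 = z_range
    z_slices = np.arange(z0 + slice_thickness / 2.0, z1, slice_thickness)
    if len(z_slices) == 0:
        warnings.warn("empty z range; empty pore profile")
        return PoreProfile(np.array([]), np.zeros((0, 2)), np.array([]),
                           np.zeros((0, 3)), 0.0, 0.0)
    center = pos[:, :2].mean(axis=0)
    if slab_halfwidth is None:
        slab_halfwidth = max(slice_thickness, 0.2)
    zs, centers, rads, surface = [], [], [], []
    phis = np.linspace(0.0, 2.0 * np.pi, n_azimuth, endpoint=False)
    for z in z_slices:
        near = np.abs(pos[:, 2] - z) <= slab_halfwidth
        sub, sub_r = pos[near, :2], radii[near]
        if len(sub) == 0 or np.sqrt(
            ((sub - center) ** 2).sum(axis=1)
        ).min() > 2.0:
            warnings.warn(f"pore profile truncated at z={z:.2f} nm (no atoms nearby)")
            break
        # coarse grid around the running center
        g = np.linspace(-search_halfwidth, search_halfwidth, 21)
        gx, gy = np.meshgrid(center[0] + g, center[1] + g, indexing="ij")
        pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
        d = np.sqrt(((pts[:, None, :] - sub[None, :, :]) ** 2).sum(-1))
        clear = (d - sub_r[None, :]).min(axis=1)
        best = pts[np.argmax(clear)]
        anchor = center.copy()

        def objective(pxy):
            # keep the refinement inside the slice search box: the largest
            # inscribed circle is only meaningful while confined to the pore
            overshoot = max(0.0, np.abs(pxy - anchor).max() - search_halfwidth)
            return -(_slice_clearance(pxy, sub, sub_r) - 10.0 * overshoot)

        res = minimize(
            objective, best, method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
        )
        c = np.clip(res.x, anchor - search_halfwidth, anchor + search_halfwidth)
        r = max(_slice_clearance(c, sub, sub_r), 0.0)
        zs.append(z)
        centers.append(c)
        rads.append(r)
        surface.append(
            np.stack([c[0] + r * np.cos(phis), c[1] + r * np.sin(phis),
                      np.full(n_azimuth, z)], axis=1)
        )
        center = c
    if not zs:
        return PoreProfile(np.array([]), np.zeros((0, 2)), np.array([]),
                           np.zeros((0, 3)), 0.0, 0.0)
    cloud = np.concatenate(surface)
    return PoreProfile(
        z=np.array(zs),
        center_xy=np.array(centers),
        radius=np.array(rads),
        surface=cloud,
        extent_z=float(cloud[:, 2].max() - cloud[:, 2].min()),
        extent_x=float(cloud[:, 0].max() - cloud[:, 0].min()),
    )


def site_geometry(frame: Frame, topology: Topology, group: IndexGroup) -> SiteGeometry:
    """Quadrilateral geometry of four labelled atoms projected on XY.

    Vertices are ordered by polar angle about the projection centroid, so
    sides and diagonals are well defined whatever the input order; all
    lengths are reported in Å.
    """
    idx = group.indices(topology)
    if len(idx) != 4:
        raise SelectionError(f"site selection must resolve exactly 4 atoms, got {len(idx)}")
    xyz = frame.coordinates[idx]
    xy = xyz[:, :2]
    centroid = xy.mean(axis=0)
    angles = np.arctan2(xy[:, 1] - centroid[1], xy[:, 0] - centroid[0])
    order = np.argsort(angles)
    q = xy[order]
    sides = np.array([np.linalg.norm(q[(i + 1) % 4] - q[i]) for i in range(4)]) * 10.0
    d1 = q[2] - q[0]
    d2 = q[3] - q[1]
    diags = np.array([np.linalg.norm(d1), np.linalg.norm(d2)]) * 10.0
    degenerate = False
    for combo in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)):
        a, b, c = (q[i] for i in combo)
        u, v = b - a, c - a
        if abs(u[0] * v[1] - u[1] * v[0]) < 1e-9:
            degenerate = True
    if diags.min() < 1e-12:
        ratio, angle = 0.0, np.nan
        degenerate = True
    else:
        ratio = float(diags.min() / diags.max())
        cosang = abs(np.dot(d1, d2)) / (np.linalg.norm(d1) * np.linalg.norm(d2))
        angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return SiteGeometry(
        positions=xyz,
        projections=q,
        sides_A=sides,
        diagonals_A=diags,
        diagonal_ratio=ratio,
        crossing_angle_deg=angle,
        degenerate=degenerate,
    )


def gate_distance(
    frame: Frame,
    topology: Topology,
    residue_number: int = 299,
    chains: tuple[str, str] = ("A", "C"),
    atom_name: str = "CA",
    threshold_A: float = 28.0,
    group: IndexGroup | None = None,
) -> tuple[float, str]:
    """Distance (Å) between the two gate Cα atoms, with an open/closed label.

    The pair is selected by residue number and chain ids, or supplied
    directly as a two-atom index group (file-based workflows where chain
    identity lives in an NDX file). Label is "open" when the distance is
    ≥ the threshold (boundary counts as open); the raw distance always
    accompanies the label.
    """
    from .trajio import select

    if group is not None:
        if len(group) != 2:
            raise SelectionError("gate group must contain exactly 2 atoms")
        picks = list(group.indices(topology))
    else:
        picks = []
        for ch in chains:
            g = select(topology, name=atom_name, chain=ch,
                       residue_number=residue_number)
            if len(g) != 1:
                raise SelectionError(
                    f"expected one {atom_name} for residue {residue_number} "
                    f"chain {ch}, got {len(g)}"
                )
            picks.append(g.indices(topology)[0])
    d = float(np.linalg.norm(
        frame.coordinates[picks[0]] - frame.coordinates[picks[1]]
    )) * 10.0
    return d, ("open" if d >= threshold_A else "closed")


def helix_align_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """RMSD (Å) between two equal-size backbone selections after optimal
    superposition."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise SelectionError("helix selections differ in atom count")
    _, _, rmsd_nm = kabsch_superpose(a, b, None)
    return rmsd_nm * 10.0
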