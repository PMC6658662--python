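"""Synthetic membrane–channel systems with analytic ground truth.

The generator emulates the *statistical structure* the analysis pipeline
probes — not molecular dynamics. A system consists of:

* a four-chain channel placeholder spanning a bilayer slab, its TMD Cα
  atoms lying on an analytic pore-radius profile, with residue names and
  numbers chosen so the standard selectors (gate-residue Cα, the four
  Mg²⁺-site asparagine OD1 atoms, every-5th-Cα references) all resolve;
* two leaflets of united-atom lipids whose acyl tails are rigid all-anti
  zig-zags tilted at a fixed angle β from the bilayer normal with uniform
  random tilt azimuth and spin, so every reconstructed C–H vector is
  exactly perpendicular to the chain axis and the ensemble order parameter
  is S_ch = −P₂(cos β)/2 per carbon — β is solved from the requested
  target (feasible range −0.5 < S ≤ 0.25);
* a bulk water bath, uniform except inside a cylindrical TMD shell where
  the density is multiplied by (1 − dehydration); the displaced waters are
  relocated to a reservoir slab at the bottom of the box, far from every
  RDF reference, so local bulk density and the global target density both
  stay equal to the control's;
* monatomic gas, each atom placed in the inter-leaflet gap slab with
  probability f_gap and in the bulk (outside the gap) otherwise, with
  hard-core rejection at the LJ contact distance.

Frames are independent redraws of a stationary ensemble — there is no
time correlation. Identical spec + seed reproduces byte-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .order import ChainDefinition
from .trajio import Atom, Frame, Topology, Trajectory

__all__ = [
    "SynthSpec",
    "PackingError",
    "build_system",
    "ground_truth",
    "chain_definitions",
    "standard_groups",
]

GAS_SIGMA_NM = 0.256        # LJ contact distance used for hard-core rejection
CC_BOND_NM = 0.153
# each C-C bond sits at half the tetrahedral supplement from the chain axis
ZIGZAG_HALF_ANGLE = (np.pi - np.arccos(-1.0 / 3.0)) / 2.0


class PackingError(Exception):
    pass


@dataclass
class SynthSpec:
    """Full ground-truth description of a generated system."""

    box: tuple[float, float, float] = (8.0, 8.0, 24.0)
    # bilayer
    bilayer_center: float = 12.0
    leaflet_offset: float = 1.5          # phosphate planes at center ± offset
    gap_half_width: float = 0.8          # inter-leaflet gas slab half-width
    n_lipids: int = 128                  # split evenly between leaflets
    tail_carbons: int = 16
    target_order: float = 0.20           # S_ch per carbon, in (-0.5, 0.25]
    # channel placeholder
    n_res_per_chain: int = 60
    channel_top_z: float = 23.0
    tmd_z: tuple[float, float] = (10.5, 13.5)
    ecd_radius: float = 2.2              # Cα ring radius outside the TMD
    pore_radius_max: float = 0.8
    pore_pinch_radius: float = 0.3
    pore_pinch_width: float = 0.3
    gate_residue: int = 299
    gate_residue_index: int = 10         # 0-based index along each GluN1 chain
    site_residue_index: int = 52         # OD1-bearing residue, all chains
    site_half_diagonals: tuple[float, float] = (0.55, 0.45)
    site_z_offset: float = 0.6           # OD1 plane above the bilayer center
    # solvent and gas
    n_water: int = 5000
    tmd_dehydration: float = 0.0         # water density × (1 − d) in the shell
    shell_radius: float = 10.0           # ≥ half the box diagonal: whole cross-section
    shell_z_pad: float = 3.5
    reservoir_z: tuple[float, float] = (4.0, 6.5)
    n_gas: int = 2000
    f_gap: float = 0.9
    # trajectory
    n_frames: int = 20
    frame_dt: float = 2.0                # ps
    protein_jitter: float = 0.02         # per-frame Gaussian sigma, nm
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.f_gap <= 1.0):
            raise ValueError("f_gap must be in [0, 1]")
        if not (0.0 <= self.tmd_dehydration <= 1.0):
            raise ValueError("tmd_dehydration must be in [0, 1]")
        if not (-0.5 < self.target_order <= 0.25):
            raise ValueError(
                "target_order must lie in (-0.5, 0.25] for a tilted rigid chain"
            )
        if min(self.n_lipids, self.n_water, self.n_gas, self.n_frames) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def tilt_beta(self) -> float:
        """Chain tilt (rad) giving S_ch = −P₂(cos β)/2 = target_order."""
        cos2 = (1.0 - 4.0 * self.target_order) / 3.0
        return float(np.arccos(np.sqrt(cos2)))

    @property
    def gap_z(self) -> tuple[float, float]:
        return (self.bilayer_center - self.gap_half_width,
                self.bilayer_center + self.gap_half_width)

    def pore_radius(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        dip = (self.pore_radius_max - self.pore_pinch_radius) * np.exp(
            -((z - self.bilayer_center) / self.pore_pinch_width) ** 2
        )
        return self.pore_radius_max - dip

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def chain_definitions(spec: SynthSpec) -> dict[str, ChainDefinition]:
    """Tail definitions (Sn-1 = 'A' suffix, Sn-2 = 'B') for generated lipids."""
    out = {}
    for tail, suffix in (("sn1", "A"), ("sn2", "B")):
        names = [f"C{i + 1}{suffix}" for i in range(spec.tail_carbons)]
        sp2 = frozenset({f"C9{suffix}", f"C10{suffix}"} & set(names))
        out[tail] = ChainDefinition(carbon_names=names, sp2_carbons=sp2)
    return out


# ---------------------------------------------------------------------------
# topology layout

@dataclass
class _Layout:
    atoms: list[Atom] = field(default_factory=list)
    protein_slice: slice = field(default_factory=lambda: slice(0, 0))
    lipid_tables: np.ndarray | None = None   # (n_lipids, 1 + 2*tail_carbons)
    water_slice: slice = field(default_factory=lambda: slice(0, 0))
    gas_slice: slice = field(default_factory=lambda: slice(0, 0))
    ca_info: list[tuple[int, int]] = field(default_factory=list)  # (atom, chain idx)
    protein_atoms: list[tuple[int, int, int, str]] = field(default_factory=list)
    # (atom index, chain index, residue ordinal, atom name)


_CHAINS = ("A", "B", "C", "D")
_GLUN1 = ("A", "C")


def _residue_number(spec: SynthSpec, chain: str, i: int) -> tuple[int, str]:
    if chain in _GLUN1 and i == spec.gate_residue_index:
        return spec.gate_residue, "GLU"
    if i == spec.site_residue_index:
        return (606 if chain in _GLUN1 else 598), "ASN"
    return i + 1, "ALA"


def _build_layout(spec: SynthSpec) -> _Layout:
    lay = _Layout()
    serial = 1

    def add(name, resname, resnum, chain, element="", mass=0.0):
        nonlocal serial
        lay.atoms.append(Atom(serial=serial, name=name, residue_name=resname,
                              residue_number=resnum, chain_id=chain,
                              element=element, mass=mass))
        serial += 1
        return serial - 2          # 0-based index

    p0 = serial - 1
    n = spec.n_res_per_chain
    z_top, z_bot = spec.channel_top_z, spec.tmd_z[0]
    for ci, chain in enumerate(_CHAINS):
        for i in range(n):
            resnum, resname = _residue_number(spec, chain, i)
            ai = add("CA", resname, resnum, chain, element="C", mass=13.019)
            lay.ca_info.append((ai, ci))
            lay.protein_atoms.append((ai, ci, i, "CA"))
            z = z_top - (z_top - z_bot) * i / (n - 1)
            if spec.tmd_z[0] <= z <= spec.tmd_z[1]:
                # sidechain pseudo-atoms thicken the pore wall so the
                # largest inscribed circle is confined, as in a real TMD
                for name in ("CB", "CG"):
                    bi = add(name, resname, resnum, chain, element="C",
                             mass=14.027)
                    lay.protein_atoms.append((bi, ci, i, name))
            if resname == "ASN":
                oi = add("OD1", resname, resnum, chain, element="O")
                lay.protein_atoms.append((oi, ci, i, "OD1"))
    lay.protein_slice = slice(p0, serial - 1)

    tables = []
    for li in range(spec.n_lipids):
        row = [add("P8", "DOPC", li + 1, "M", element="P")]
        for suffix in ("A", "B"):
            for k in range(spec.tail_carbons):
                row.append(add(f"C{k + 1}{suffix}", "DOPC", li + 1, "M",
                               element="C", mass=14.027))
        tables.append(row)
    lay.lipid_tables = np.array(tables, dtype=int) if tables else np.zeros((0, 1), int)

    w0 = serial - 1
    for wi in range(spec.n_water):
        add("OW", "SOL", wi + 1, "W", element="O", mass=18.015)
    lay.water_slice = slice(w0, serial - 1)

    g0 = serial - 1
    for gi in range(spec.n_gas):
        add("HE", "HE", gi + 1, "G", element="HE")
    lay.gas_slice = slice(g0, serial - 1)
    return lay


# ---------------------------------------------------------------------------
# per-frame coordinate draws

def _protein_base(spec: SynthSpec, lay: _Layout) -> np.ndarray:
    """Mean protein coordinates (jitter is added per frame)."""
    cx, cy = spec.box[0] / 2.0, spec.box[1] / 2.0
    coords = np.zeros((lay.protein_slice.stop, 3))
    azimuths = np.deg2rad([45.0, 135.0, 225.0, 315.0])
    z_top, z_bot = spec.channel_top_z, spec.tmd_z[0]
    n = spec.n_res_per_chain
    half_dx, half_dy = spec.site_half_diagonals
    od1_xy = {  # rectangle corners; GluN1 pair on one diagonal
        "A": (half_dx, half_dy), "C": (-half_dx, -half_dy),
        "B": (-half_dx, half_dy), "D": (half_dx, -half_dy),
    }
    atoms = lay.atoms
    for (ai, ci, i, name) in lay.protein_atoms:
        if name == "OD1":
            dx, dy = od1_xy[atoms[ai].chain_id]
            coords[ai] = (cx + dx, cy + dy,
                          spec.bilayer_center + spec.site_z_offset)
            continue
        z = z_top - (z_top - z_bot) * i / (n - 1)
        in_tmd = spec.tmd_z[0] <= z <= spec.tmd_z[1]
        radius = (spec.pore_radius(z) + 0.17) if in_tmd else spec.ecd_radius
        # stagger azimuths along the chain so neighbouring rings interleave
        # and the pore wall reads as a surface, not four isolated columns
        phi = azimuths[ci] + np.deg2rad(40.0) * i
        if name == "CB":
            radius, phi = radius + 0.35, phi + np.deg2rad(25.0)
        elif name == "CG":
            radius, phi = radius + 0.70, phi - np.deg2rad(25.0)
        coords[ai] = (cx + radius * np.cos(phi), cy + radius * np.sin(phi), z)
    return coords[lay.protein_slice.start : lay.protein_slice.stop]


def _draw_tail(rng, spec: SynthSpec, start: np.ndarray, downward: bool) -> np.ndarray:
    beta = spec.tilt_beta
    psi = rng.uniform(0.0, 2.0 * np.pi)     # tilt azimuth
    chi = rng.uniform(0.0, 2.0 * np.pi)     # spin about the chain axis
    sz = -1.0 if downward else 1.0
    a = np.array([np.sin(beta) * np.cos(psi), np.sin(beta) * np.sin(psi),
                  sz * np.cos(beta)])
    helper = np.array([0.0, 0.0, 1.0])
    if abs(a[2]) > 0.99:
        helper = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(a, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    m = e1 * np.cos(chi) + e2 * np.sin(chi)
    k = np.arange(spec.tail_carbons)
    along = CC_BOND_NM * np.cos(ZIGZAG_HALF_ANGLE) * k
    across = CC_BOND_NM * np.sin(ZIGZAG_HALF_ANGLE) * (k % 2)
    return start + along[:, None] * a + across[:, None] * m


def _draw_gas(rng, spec: SynthSpec) -> np.ndarray:
    """Sequential hard-core insertion with a periodic cell list.

    Gap/bulk membership is drawn first (exact Bernoulli(f_gap) statistics);
    each atom is then inserted by rejection against the already-placed
    atoms at the LJ contact distance.
    """
    box = np.array(spec.box)
    z0, z1 = spec.gap_z
    n = spec.n_gas
    in_gap = rng.random(n) < spec.f_gap
    below, above = z0, box[2] - z1

    cell = GAS_SIGMA_NM
    ncell = np.maximum((box / cell).astype(int), 1)
    cells: dict[tuple[int, int, int], list[np.ndarray]] = {}

    def conflicts(p) -> bool:
        c = (p / box * ncell).astype(int) % ncell
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    key = ((c[0] + dx) % ncell[0], (c[1] + dy) % ncell[1],
                           (c[2] + dz) % ncell[2])
                    for q in cells.get(key, ()):
                        d = p - q
                        d -= np.round(d / box) * box
                        if (d @ d) < GAS_SIGMA_NM ** 2:
                            return True
        return False

    pos = np.zeros((n, 3))
    for i in range(n):
        for _ in range(500):
            x = rng.uniform(0, box[0])
            y = rng.uniform(0, box[1])
            if in_gap[i]:
                z = rng.uniform(z0, z1)
            else:
                u = rng.uniform(0, below + above)
                z = u if u < below else z1 + (u - below)
            p = np.array([x, y, z])
            if not conflicts(p):
                break
        else:
            raise PackingError(
                f"gas hard-core insertion failed for atom {i} after 500 tries"
            )
        pos[i] = p
        key = tuple((p / box * ncell).astype(int) % ncell)
        cells.setdefault(key, []).append(p)
    return pos


def _draw_water(rng, spec: SynthSpec) -> np.ndarray:
    box = np.array(spec.box)
    n = spec.n_water
    pos = np.column_stack([rng.uniform(0, box[d], n) for d in range(3)])
    d = spec.tmd_dehydration
    if d > 0:
        cx, cy = box[0] / 2.0, box[1] / 2.0
        sz0 = spec.tmd_z[0] - spec.shell_z_pad
        sz1 = spec.tmd_z[1] + spec.shell_z_pad
        lateral = (pos[:, 0] - cx) ** 2 + (pos[:, 1] - cy) ** 2
        in_shell = (lateral <= spec.shell_radius ** 2) & \
                   (pos[:, 2] >= sz0) & (pos[:, 2] <= sz1)
        move = in_shell & (rng.random(n) < d)
        k = int(move.sum())
        # displaced water goes to the bottom reservoir, far from every
        # RDF reference, keeping both local bulk density and the global
        # target density equal to the control's
        pos[move, 0] = rng.uniform(0, box[0], k)
        pos[move, 1] = rng.uniform(0, box[1], k)
        pos[move, 2] = rng.uniform(*spec.reservoir_z, k)
    return pos


def build_system(spec: SynthSpec) -> tuple[Topology, Trajectory]:
    """Generate the synthetic system; deterministic for a fixed spec + seed."""
    lay = _build_layout(spec)
    top = Topology(lay.atoms)
    rng = np.random.default_rng(spec.seed)
    base_protein = _protein_base(spec, lay)
    box = np.array(spec.box)

    # lipid head lattice, split between leaflets
    per_leaf = spec.n_lipids // 2
    heads = []
    for leaf, count in ((0, per_leaf), (1, spec.n_lipids - per_leaf)):
        if count == 0:
            continue
        side = int(np.ceil(np.sqrt(count)))
        xs = (np.arange(side) + 0.5) * box[0] / side
        ys = (np.arange(side) + 0.5) * box[1] / side
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        pts = np.stack([gx.ravel(), gy.ravel()], axis=1)[:count]
        z = spec.bilayer_center + (spec.leaflet_offset if leaf else -spec.leaflet_offset)
        heads.append((pts, z, leaf == 1))
    frames = []
    n_atoms = top.n_atoms
    for fi in range(spec.n_frames):
        coords = np.zeros((n_atoms, 3))
        coords[lay.protein_slice] = base_protein + rng.normal(
            0.0, spec.protein_jitter, base_protein.shape
        )
        li = 0
        for pts, z_head, downward in heads:
            for (hx, hy) in pts:
                row = lay.lipid_tables[li]
                head = np.array([hx, hy, z_head])
                coords[row[0]] = head + rng.normal(0.0, 0.02, 3)
                tc = spec.tail_carbons
                for t in range(2):
                    start = head + np.array([0.12 * (t * 2 - 1), 0.0,
                                             -0.12 if downward else 0.12])
                    tail = _draw_tail(rng, spec, start, downward)
                    coords[row[1 + t * tc: 1 + (t + 1) * tc]] = tail
                li += 1
        if spec.n_water:
            coords[lay.water_slice] = _draw_water(rng, spec)
        if spec.n_gas:
            coords[lay.gas_slice] = _draw_gas(rng, spec)
        frames.append(Frame(fi * spec.frame_dt, coords, box.copy()))
    return top, Trajectory(top, frames)


def standard_groups(spec: SynthSpec, topology: Topology) -> list:
    """Canonical NDX groups so file-based workflows keep chain identity.

    GRO files carry no chain column, so selections that need chains (gate
    Cα pair, site OD1 quadrilateral, per-chain every-5th-Cα references) are
    exported as named index groups alongside the trajectory.
    """
    from .trajio import IndexGroup, select

    groups = [select(topology, name="CA", group_name="protein_ca")]
    for ch in _CHAINS:
        groups.append(select(topology, name="CA", chain=ch,
                             group_name=f"ca_{ch}"))
        groups.append(select(topology, name="CA", chain=ch, stride=5,
                             group_name=f"every5_ca_{ch}"))
    gate = [
        s for ch in _GLUN1
        for s in select(topology, name="CA", chain=ch,
                        residue_number=spec.gate_residue).atom_serials
    ]
    groups.append(IndexGroup("gate_ca", tuple(gate)))
    groups.append(select(topology, name="OD1", group_name="site_od1"))
    for name, kwargs in (("water", {"name": "OW"}),
                         ("gas", {"residue_name": "HE"}),
                         ("dopc", {"residue_name": "DOPC"}),
                         ("phosphates", {"name": "P8"})):
        try:
            groups.append(select(topology, group_name=name, **kwargs))
        except Exception:
            pass
    return groups


def ground_truth(spec: SynthSpec) -> dict:
    """Analytic expectations every estimator is tested against."""
    n = spec.n_res_per_chain
    z_top, z_bot = spec.channel_top_z, spec.tmd_z[0]
    z_of = lambda i: z_top - (z_top - z_bot) * i / (n - 1)
    shell_lo = spec.tmd_z[0] - spec.shell_z_pad + 3.4
    shell_hi = spec.tmd_z[1] + spec.shell_z_pad - 3.4
    rows = list(range(0, n, 5))
    tmd_rows, bulk_rows = [], []
    for r in rows:
        z = z_of(r)
        if shell_lo <= z <= shell_hi:
            tmd_rows.append(r)
        elif z >= spec.tmd_z[1] + spec.shell_z_pad + 3.4:
            bulk_rows.append(r)
    zq = np.linspace(*spec.tmd_z, 101)
    pr = spec.pore_radius(zq)
    gap = spec.gap_z
    return {
        "gap_z": gap,
        "expected_gap_gas": spec.n_gas * spec.f_gap,
        "gap_gas_sd": float(np.sqrt(spec.n_gas * spec.f_gap * (1 - spec.f_gap))),
        "slab_volume_nm3": float(spec.box[0] * spec.box[1] * (gap[1] - gap[0])),
        "order_parameter": spec.target_order,
        "tmd_water_ratio": 1.0 - spec.tmd_dehydration,
        "bulk_water_ratio": 1.0,
        "tmd_row_ordinals": tmd_rows,    # 0-based residue ordinals along a chain
        "bulk_row_ordinals": bulk_rows,
        "pore_min_radius": float(pr.min()),
        "pore_min_radius_z": float(zq[np.argmin(pr)]),
        "gate_distance_A": float(2.0 * spec.ecd_radius * 10.0),
        # OD1 corners (±dx, ±dy): rectangle with sides 2dx / 2dy, equal
        # diagonals 2√(dx²+dy²), hence diagonal ratio 1
        "site_sides_A": [2.0 * spec.site_half_diagonals[0] * 10.0,
                         2.0 * spec.site_half_diagonals[1] * 10.0],
        "site_diagonal_A": float(
            2.0 * np.hypot(*spec.site_half_diagonals) * 10.0
        ),
        "site_diagonal_ratio": 1.0,
    }
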