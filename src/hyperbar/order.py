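"""Acyl-chain orientational order parameters for united-atom lipids.

United-atom force fields carry no aliphatic hydrogens, so the two geminal
hydrogens of each chain CH2 are reconstructed from the positions of three
consecutive carbons and labelled by prochirality (pro-R / pro-S). The order
parameter per carbon and label is

    S_ch = <3 cos^2 theta - 1> / 2,

theta being the angle between the reconstructed C-H direction and the
bilayer normal: 1 = perfectly aligned, 0 = isotropic, -0.5 = perpendicular.

Prochirality convention: with u = C_prev - C and v = C_next - C, the
hydrogen with positive scalar triple product det[u, v, H - C] is labelled
pro-R. The convention is internal but self-consistent: mirroring the input
coordinates swaps the two labels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajio import Topology, Trajectory

__all__ = [
    "ChainDefinition",
    "OrderProfile",
    "GeometryError",
    "reconstruct_hydrogens",
    "order_parameter",
]

CH_BOND_NM = 0.109          # exported H coordinates only; S_ch uses direction
_COS_TETRA = -1.0 / 3.0     # cos(109.471 deg), ideal H-C-C target angle


class GeometryError(Exception):
    pass


@dataclass
class ChainDefinition:
    """One acyl tail: ordered carbon atom names, sp² pair, bilayer normal."""

    carbon_names: list[str]
    sp2_carbons: frozenset = field(default_factory=frozenset)
    normal_axis: int = 2
    lipid_residue_name: str = "DOPC"

    def __post_init__(self):
        self.sp2_carbons = frozenset(self.sp2_carbons)
        sp2_idx = sorted(
            i for i, n in enumerate(self.carbon_names) if n in self.sp2_carbons
        )
        if sp2_idx and not all(b - a == 1 for a, b in zip(sp2_idx, sp2_idx[1:])):
            raise ValueError("sp2 carbons must form an adjacent pair")


@dataclass
class OrderProfile:
    carbon_names: list[str]       # interior carbons (terminal ones excluded)
    proR_mean: np.ndarray
    proR_se: np.ndarray
    proS_mean: np.ndarray
    proS_se: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "carbon": self.carbon_names,
                "proR_mean": self.proR_mean,
                "proR_se": self.proR_se,
                "proS_mean": self.proS_mean,
                "proS_se": self.proS_se,
            }
        )


def _reconstruct_batch(
    c_prev: np.ndarray, c: np.ndarray, c_next: np.ndarray, sp2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised H reconstruction; returns unit pro-R and pro-S directions."""
    u = c_prev - c
    v = c_next - c
    un = u / np.linalg.norm(u, axis=-1, keepdims=True)
    vn = v / np.linalg.norm(v, axis=-1, keepdims=True)
    cross = np.cross(un, vn)
    cross_norm = np.linalg.norm(cross, axis=-1, keepdims=True)
    if np.any(cross_norm < 1e-8):
        raise GeometryError("collinear carbon triplet")
    p = cross / cross_norm
    bis = -(un + vn)
    bis /= np.linalg.norm(bis, axis=-1, keepdims=True)
    # each C-H at the tetrahedral angle from both C-C bonds, whatever the
    # local C-C-C angle: cos(phi) = |cos(tetra)| / cos(gamma/2)
    cos_half = np.sqrt(np.clip((1.0 + (un * vn).sum(-1)) / 2.0, 1e-12, 1.0))
    cos_phi = np.clip(-_COS_TETRA / cos_half, 0.0, 1.0)[..., None]
    sin_phi = np.sqrt(1.0 - cos_phi ** 2)
    h_plus = bis * cos_phi + p * sin_phi    # det[u, v, h_plus] > 0 -> pro-R
    h_minus = bis * cos_phi - p * sin_phi
    sp2 = np.asarray(sp2, dtype=bool)
    if sp2.any():
        # single in-plane hydrogen on the exterior bisector; both labels
        # report the same vector
        h_plus = np.where(sp2[..., None], bis, h_plus)
        h_minus = np.where(sp2[..., None], bis, h_minus)
    return h_plus, h_minus


def reconstruct_hydrogens(
    c_prev: np.ndarray, c: np.ndarray, c_next: np.ndarray, kind: str = "sp3"
) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct the geminal hydrogen position(s) of one chain carbon.

    Returns ``(H_proR, H_proS)`` positions at C-H length 0.109 nm. For sp²
    carbons the single in-plane hydrogen is returned under both labels.
    """
    if kind not in ("sp3", "sp2"):
        raise ValueError("kind must be 'sp3' or 'sp2'")
    c_prev, c, c_next = (np.asarray(x, dtype=float) for x in (c_prev, c, c_next))
    hr, hs = _reconstruct_batch(
        c_prev[None], c[None], c_next[None], np.array([kind == "sp2"])
    )
    return c + CH_BOND_NM * hr[0], c + CH_BOND_NM * hs[0]


def _carbon_index_table(topology: Topology, chain_def: ChainDefinition) -> np.ndarray:
    """(n_lipids, n_carbons) atom indices for the tail carbons of each lipid."""
    resname = chain_def.lipid_residue_name
    lipid_mask = topology.residue_names == resname
    lipid_ids = np.unique(topology.residue_numbers[lipid_mask])
    if len(lipid_ids) == 0:
        raise ValueError(f"no lipids with residue name {resname!r}")
    name_pos = {n: k for k, n in enumerate(chain_def.carbon_names)}
    table = np.full((len(lipid_ids), len(chain_def.carbon_names)), -1, dtype=int)
    rid_pos = {int(r): i for i, r in enumerate(lipid_ids)}
    for ai in np.nonzero(lipid_mask)[0]:
        k = name_pos.get(topology.names[ai])
        if k is not None:
            table[rid_pos[int(topology.residue_numbers[ai])], k] = ai
    bad = np.argwhere(table < 0)
    if len(bad):
        li, ci = bad[0]
        raise ValueError(
            f"lipid residue {int(lipid_ids[li])} is missing chain atom "
            f"{chain_def.carbon_names[ci]!r}"
        )
    return table


def order_parameter(trajectory: Trajectory, chain_def: ChainDefinition) -> OrderProfile:
    """S_ch per interior chain carbon and prochiral label.

    Averages run over frames and lipids; the standard error (n−1) is taken
    across lipids of their per-lipid time averages. Terminal carbons (no
    neighbour on one side) are excluded.
    """
    top = trajectory.topology
    table = _carbon_index_table(top, chain_def)
    n_lip, n_c = table.shape
    if n_c < 3:
        raise ValueError("a tail needs at least 3 carbons")
    interior = list(range(1, n_c - 1))
    sp2 = np.array(
        [chain_def.carbon_names[k] in chain_def.sp2_carbons for k in interior]
    )
    axis = chain_def.normal_axis
    acc_r = np.zeros((n_lip, len(interior)))
    acc_s = np.zeros((n_lip, len(interior)))
    for fr in trajectory.frames:
        xyz = fr.coordinates[table]                     # (n_lip, n_c, 3)
        hr, hs = _reconstruct_batch(
            xyz[:, :-2], xyz[:, 1:-1], xyz[:, 2:], np.broadcast_to(sp2, (n_lip, len(interior)))
        )
        acc_r += 0.5 * (3.0 * hr[..., axis] ** 2 - 1.0)
        acc_s += 0.5 * (3.0 * hs[..., axis] ** 2 - 1.0)
    acc_r /= trajectory.n_frames
    acc_s /= trajectory.n_frames
    if n_lip > 1:
        sqn = np.sqrt(n_lip)
        se_r = acc_r.std(axis=0, ddof=1) / sqn
        se_s = acc_s.std(axis=0, ddof=1) / sqn
    else:  # a single lipid has no across-lipid spread
        se_r = np.full(len(interior), np.nan)
        se_s = np.full(len(interior), np.nan)
    return OrderProfile(
        carbon_names=[chain_def.carbon_names[k] for k in interior],
        proR_mean=acc_r.mean(axis=0),
        proR_se=se_r,
        proS_mean=acc_s.mean(axis=0),
        proS_se=se_s,
    )
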