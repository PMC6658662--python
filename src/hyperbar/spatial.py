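"""Mass-density profiles along the membrane normal and RDF "layouts".

The layout machinery summarises solvation/gas structure along a protein
chain: around every 5th Cα of the chain a radial distribution function is
computed per sampling window, averaged over 0–3.4 nm (roughly the linear
length of a 10-residue peptide), and tabulated as mean ± standard error
across windows. Condition layouts are normalised row-wise to a control
layout to expose hydration/dehydration transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajio import IndexGroup, SelectionError, Trajectory, select

__all__ = [
    "DensityProfile",
    "RDFCurve",
    "RDFLayout",
    "density_profile",
    "rdf",
    "rdf_layout",
    "normalize_layout",
    "sampling_windows",
]

AMU_KG = 1.66053906660e-27
NM3_M3 = 1e-27


@dataclass
class DensityProfile:
    bin_centers: np.ndarray   # nm along Z
    density: np.ndarray       # kg m^-3
    group: str
    bin_width: float          # nm
    xy_area: float            # nm^2

    def total_mass_kg(self) -> float:
        """Integral density × slab volume — equals the group mass (kg)."""
        return float((self.density * self.bin_width * self.xy_area * NM3_M3).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z_nm": self.bin_centers, "kg_m3": self.density})


@dataclass
class RDFCurve:
    r: np.ndarray             # nm, bin centers
    g: np.ndarray             # dimensionless
    reference: str
    target: str

    def mean_over(self, r_min: float, r_max: float) -> float:
        """Unweighted mean of g(r) over bins with centers in [r_min, r_max]."""
        sel = (self.r >= r_min) & (self.r <= r_max)
        return float(self.g[sel].mean())


@dataclass
class RDFLayout:
    residue_numbers: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    chain: str
    species: str
    flagged: np.ndarray = field(default=None)  # rows with undefined ratio

    def __post_init__(self):
        if self.flagged is None:
            self.flagged = np.zeros(len(self.mean), dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": self.residue_numbers,
                "mean": self.mean,
                "se": self.se,
                "flagged": self.flagged,
            }
        )


def density_profile(
    trajectory: Trajectory,
    group: IndexGroup,
    n_bins: int = 100,
    axis: int = 2,
) -> DensityProfile:
    """Mass density (kg/m³) of a group binned along an axis of the box.

    Atom positions are wrapped into [0, box) along the axis; each atom's
    mass accumulates into its bin. Per-frame histograms are averaged and
    converted to kg/m³ using the slab volume (bin width × box cross-section,
    averaged over frames).
    """
    if len(group) == 0:
        raise SelectionError("empty group")
    top = trajectory.topology
    idx = group.indices(top)
    masses = top.masses[idx]
    L = np.mean([fr.box[axis] for fr in trajectory.frames])
    other = [i for i in range(3) if i != axis]
    area = np.mean([fr.box[other[0]] * fr.box[other[1]] for fr in trajectory.frames])
    if L <= 0 or area <= 0:
        raise ValueError("degenerate box")
    edges = np.linspace(0.0, L, n_bins + 1)
    acc = np.zeros(n_bins)
    for fr in trajectory.frames:
        z = fr.coordinates[idx, axis] % fr.box[axis]
        # rescale in case the frame box differs slightly from the mean
        z = z * (L / fr.box[axis])
        hist, _ = np.histogram(z, bins=edges, weights=masses)
        acc += hist
    acc /= trajectory.n_frames
    bin_width = L / n_bins
    slab_vol_m3 = bin_width * area * NM3_M3
    density = acc * AMU_KG / slab_vol_m3
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(centers, density, group.name, bin_width, area)


def _min_image_dists(ref_xyz: np.ndarray, tgt_xyz: np.ndarray, box: np.ndarray) -> np.ndarray:
    """(n_ref, n_tgt) image-minimum distances in a rectangular box."""
    delta = ref_xyz[:, None, :] - tgt_xyz[None, :, :]
    delta -= np.round(delta / box) * box
    return np.sqrt((delta ** 2).sum(axis=-1))


def rdf(
    trajectory: Trajectory,
    reference_group: IndexGroup,
    target_group: IndexGroup,
    r_max: float,
    bin_width: float = 0.02,
    frame_indices: np.ndarray | None = None,
) -> RDFCurve:
    """Radial distribution function g(r) of target atoms around references.

    g(r) = ⟨shell count⟩ / (4πr²dr · ρ_target), with image-minimum distances
    and ρ_target = N_target / V averaged over frames. Atoms common to both
    groups are self-excluded. ``r_max`` must not exceed half the smallest
    box edge — no silent truncation.
    """
    top = trajectory.topology
    ref_idx = reference_group.indices(top)
    tgt_idx = target_group.indices(top)
    if frame_indices is None:
        frame_indices = np.arange(trajectory.n_frames)
    frames = [trajectory.frames[int(i)] for i in frame_indices]
    if not frames:
        raise ValueError("no frames selected")
    min_half_edge = min(fr.box.min() for fr in frames) / 2.0
    if r_max > min_half_edge + 1e-12:
        raise ValueError(
            f"r_max {r_max} exceeds half the smallest box edge {min_half_edge:.3f}"
        )
    n_bins = int(np.ceil(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    shared = np.intersect1d(ref_idx, tgt_idx)
    counts = np.zeros(n_bins)
    rho_sum = 0.0
    for fr in frames:
        d = _min_image_dists(fr.coordinates[ref_idx], fr.coordinates[tgt_idx], fr.box)
        if len(shared):
            ri = {int(a): k for k, a in enumerate(ref_idx)}
            ti = {int(a): k for k, a in enumerate(tgt_idx)}
            for a in shared:
                d[ri[int(a)], ti[int(a)]] = np.inf
        hist, _ = np.histogram(d[d < r_max], bins=edges)
        counts += hist
        rho_sum += len(tgt_idx) / float(np.prod(fr.box))
    counts /= len(frames) * len(ref_idx)
    rho = rho_sum / len(frames)
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * np.pi * centers ** 2 * bin_width
    g = counts / (shell * rho)
    return RDFCurve(centers, g, reference_group.name, target_group.name)


def sampling_windows(
    t_start: float, t_end: float, width: float, gap: float
) -> list[tuple[float, float]]:
    """Sampling intervals of ``width`` separated by ``gap`` within [t_start, t_end].

    E.g. 50–100 ns with 5 ns windows and 10 ns gaps gives [50,55], [65,70],
    [80,85], [95,100] ns.
    """
    windows = []
    t = t_start
    while t + width <= t_end + 1e-9:
        windows.append((t, t + width))
        t += width + gap
    return windows


def rdf_layout(
    trajectory: Trajectory,
    chain: str,
    species_group: IndexGroup,
    windows: list[tuple[float, float]],
    r_range: tuple[float, float] = (0.0, 3.4),
    bin_width: float = 0.02,
    residue_stride: int = 5,
    reference_group: IndexGroup | None = None,
) -> RDFLayout:
    """Per-residue RDF summary along a protein chain.

    For every ``residue_stride``-th Cα of the chain (starting from the first
    resolved residue), one RDF of the species is computed per sampling
    window; g is averaged (plain mean over bins) over ``r_range``; the row
    reports mean ± standard error (n−1) across windows. An explicit
    ``reference_group`` (e.g. an every-5th-Cα NDX group) overrides the
    chain selection.
    """
    if len(windows) < 2:
        raise ValueError("at least 2 windows are required for a standard error")
    top = trajectory.topology
    ca = (reference_group if reference_group is not None
          else select(top, name="CA", chain=chain, stride=residue_stride))
    times = trajectory.times
    window_frames = []
    for (t0, t1) in windows:
        sel = np.nonzero((times >= t0) & (times <= t1))[0]
        if len(sel) == 0:
            raise ValueError(f"window ({t0}, {t1}) contains no frames")
        window_frames.append(sel)
    rows = []
    resnums = []
    for serial in ca.atom_serials:
        ref = IndexGroup(f"ca{serial}", (serial,))
        resnums.append(int(top.residue_numbers[serial - 1]))
        per_window = [
            rdf(trajectory, ref, species_group, r_max=r_range[1],
                bin_width=bin_width, frame_indices=fi).mean_over(*r_range)
            for fi in window_frames
        ]
        rows.append(per_window)
    rows = np.array(rows)
    mean = rows.mean(axis=1)
    se = rows.std(axis=1, ddof=1) / np.sqrt(rows.shape[1])
    return RDFLayout(
        residue_numbers=np.array(resnums),
        mean=mean,
        se=se,
        chain=chain,
        species=species_group.name,
    )


def normalize_layout(
    condition: RDFLayout, control: RDFLayout, eps: float = 1e-9
) -> RDFLayout:
    """Row-wise ratio of a condition layout to the control layout.

    Standard errors propagate to first order:
    SE(a/b) = |a/b| √((SEa/a)² + (SEb/b)²). Rows whose control mean falls
    below ``eps`` are flagged and reported as NaN rather than divided.
    """
    if not np.array_equal(condition.residue_numbers, control.residue_numbers):
        raise ValueError("layouts index different residues")
    ratio = np.full(len(condition.mean), np.nan)
    se = np.full(len(condition.mean), np.nan)
    flagged = np.abs(control.mean) < eps
    ok = ~flagged
    ratio[ok] = condition.mean[ok] / control.mean[ok]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.sqrt(
            (condition.se[ok] / condition.mean[ok]) ** 2
            + (control.se[ok] / control.mean[ok]) ** 2
        )
    se[ok] = np.abs(ratio[ok]) * rel
    return RDFLayout(
        residue_numbers=condition.residue_numbers.copy(),
        mean=ratio,
        se=se,
        chain=condition.chain,
        species=condition.species,
        flagged=flagged,
    )
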