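"""Wrapping-mode analysis: 2D free-energy profiles and subunit occupancy.

The wrapped ssDNA's location is projected onto the X-Y plane of a local
frame fixed to the protein (principal axes of the native structure); a 2D
histogram of those projections gives a potential of mean force in k_BT, and
per-frame subunit-contact counts summarise how many subunits the chain
occupies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cgtop import BeadTopology

__all__ = [
    "LocalFrame",
    "PMF2D",
    "OccupancyProfile",
    "local_frame",
    "project_dna",
    "pmf2d",
    "subunit_occupancy",
    "occupancy_profile",
]


@dataclass
class LocalFrame:
    origin: np.ndarray  # (3,)
    rotation: np.ndarray  # (3,3), rows = axes; det = +1

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords) - self.origin) @ self.rotation.T


@dataclass
class PMF2D:
    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray  # k_BT, NaN where unsampled, min over sampled = 0
    counts: np.ndarray

    @property
    def minimum_location(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.nanargmin(self.free_energy), self.free_energy.shape)
        return (
            float(0.5 * (self.x_edges[i] + self.x_edges[i + 1])),
            float(0.5 * (self.y_edges[j] + self.y_edges[j + 1])),
        )


@dataclass
class OccupancyProfile:
    per_frame: np.ndarray  # occupied-subunit count per frame
    n_subunits: int

    @property
    def distribution(self) -> np.ndarray:
        """P(occupancy = 0..n_subunits); sums to 1."""
        return np.bincount(self.per_frame, minlength=self.n_subunits + 1) / self.per_frame.size

    @property
    def mean(self) -> float:
        return float(self.per_frame.mean())


def local_frame(
    protein_coords: np.ndarray, orient_toward: np.ndarray | None = None
) -> LocalFrame:
    """Origin at the centre of geometry, axes = principal axes.

    Axes are ordered by decreasing spatial extent and sign-fixed so the
    first two point toward ``orient_toward`` (e.g. the anchored subunit's
    centroid); determinant is forced to +1.  Raises on degenerate inertia.
    """
    coords = np.asarray(protein_coords, dtype=float)
    if coords.shape[0] < 3:
        raise ValueError("need >= 3 beads")
    origin = coords.mean(axis=0)
    x = coords - origin
    cov = x.T @ x / x.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] < 1e-10 * evals[-1] or np.linalg.matrix_rank(cov, tol=1e-8) < 2:
        raise ValueError("degenerate inertia tensor (collinear beads)")
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order].T  # rows
    ref = (
        np.asarray(orient_toward, dtype=float) - origin
        if orient_toward is not None
        else x[0]
    )
    for i in range(2):
        if np.dot(axes[i], ref) < 0:
            axes[i] = -axes[i]
    axes[2] = np.cross(axes[0], axes[1])  # right-handed, det +1
    return LocalFrame(origin=origin, rotation=axes)


def project_dna(
    frames: np.ndarray, frame: LocalFrame, bead_selection: np.ndarray
) -> np.ndarray:
    """(n_frames * n_selected, 2) X-Y samples of the selected beads."""
    frames = np.asarray(frames, dtype=float)
    sel = np.asarray(bead_selection, dtype=np.int64).ravel()
    if sel.size == 0:
        raise ValueError("empty bead selection")
    if frames.ndim == 2:
        frames = frames[None]
    local = frame.apply(frames[:, sel, :].reshape(-1, 3))
    return local[:, :2]


def pmf2d(samples: np.ndarray, bin_width: float = 2.0, extent: float | None = None) -> PMF2D:
    """F(bin) = -ln(count / max count) in k_BT; unsampled bins are NaN."""
    samples = np.asarray(samples, dtype=float)
    if samples.shape[0] < 1000:
        raise ValueError("need >= 1000 samples for a meaningful PMF")
    if extent is None:
        extent = float(np.max(np.abs(samples))) + bin_width
    edges = np.arange(-extent, extent + bin_width, bin_width)
    counts, xe, ye = np.histogram2d(samples[:, 0], samples[:, 1], bins=(edges, edges))
    if np.count_nonzero(counts) == 1:
        warnings.warn("all samples fall in a single bin; PMF is flat", stacklevel=2)
    with np.errstate(divide="ignore"):
        fe = -np.log(counts / counts.max())
    fe[counts == 0] = np.nan
    return PMF2D(x_edges=xe, y_edges=ye, free_energy=fe, counts=counts)


def subunit_occupancy(
    coords: np.ndarray,
    topology: BeadTopology,
    cutoff: float = 10.0,
    min_nt: int = 3,
) -> int:
    """Number of subunits contacted by the ssDNA in one frame.

    A subunit counts as occupied when at least ``min_nt`` nucleotides have
    any bead within ``cutoff`` of any of that subunit's residues.
    """
    coords = np.asarray(coords, dtype=float)
    dna = np.flatnonzero(topology.molecule == 1)
    occupied = 0
    for s in range(topology.n_subunits):
        sub = np.flatnonzero((topology.molecule == 0) & (topology.subunit == s))
        d = np.linalg.norm(coords[dna][:, None, :] - coords[sub][None, :, :], axis=-1)
        close = d.min(axis=1) <= cutoff
        nts = np.unique(topology.resid[dna][close])
        if nts.size >= min_nt:
            occupied += 1
    return occupied


def occupancy_profile(
    frames: np.ndarray,
    topology: BeadTopology,
    cutoff: float = 10.0,
    min_nt: int = 3,
) -> OccupancyProfile:
    """Per-frame occupancy over a trajectory."""
    frames = np.asarray(frames, dtype=float)
    counts = np.array(
        [subunit_occupancy(f, topology, cutoff, min_nt) for f in frames], dtype=int
    )
    return OccupancyProfile(per_frame=counts, n_subunits=topology.n_subunits)
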