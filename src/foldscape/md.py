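"""Trajectory post-processing: superposition, RMSD/RMSF, PCA and FEL.

Essential-dynamics analysis of Calpha coordinates: frames are least-squares
superposed (Kabsch) onto an iteratively refined mean structure, the Cartesian
covariance C_ij = <(X_i - <X_i>)(X_j - <X_j>)> is diagonalized, frames are
projected onto the eigenvectors, and the free-energy landscape over the first
two principal components is built by Boltzmann inversion of the projection
histogram, G = -kT ln(P/Pmax), with the occupied-bin minimum anchored at 0.
No mass weighting is applied (Calpha-only, uniform mass).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import R_KCAL, ROOM_TEMPERATURE

__all__ = [
    "Trajectory",
    "PCAResult",
    "FELGrid",
    "PorcupineField",
    "superpose",
    "align_trajectory",
    "rmsd_series",
    "rmsf_profile",
    "pca",
    "fel",
    "porcupine",
]


@dataclass
class Trajectory:
    """A Calpha coordinate trajectory (frames x atoms x 3, angstrom)."""

    coordinates: np.ndarray
    frame_interval: float = 20.0  # ps
    atom_labels: list[str] | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if self.coordinates.shape[0] < 2:
            raise ValueError("trajectory needs at least 2 frames")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if self.atom_labels is None:
            self.atom_labels = ["CA"] * self.coordinates.shape[1]

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


def superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, float]:
    """Kabsch least-squares rigid-body superposition.

    Returns the aligned mobile structure and the minimal RMSD (angstrom).
    A proper rotation (det = +1) is enforced; collinear geometries are
    rejected.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[0] < 3:
        raise ValueError("need two equal (N>=3, 3) coordinate arrays")
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    if np.linalg.matrix_rank(rc, tol=1e-8) < 2 or np.linalg.matrix_rank(mc, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) geometry")
    h = mc.T @ rc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    aligned = mc @ rot.T + reference.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - reference) ** 2, axis=1))))
    return aligned, rmsd


def rmsd_series(traj: Trajectory, reference: np.ndarray) -> np.ndarray:
    """Per-frame superposed RMSD against a reference structure."""
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (traj.n_atoms, 3):
        raise ValueError("reference atom count does not match trajectory")
    return np.array([superpose(f, reference)[1] for f in traj.coordinates])


def align_trajectory(
    traj: Trajectory, n_iter: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose all frames onto an iteratively refined mean structure.

    Two refinement passes: align to the current mean, recompute the mean.
    Returns (aligned frames, mean structure).
    """
    frames = traj.coordinates.copy()
    mean = frames[0]
    for _ in range(n_iter):
        frames = np.array([superpose(f, mean)[0] for f in frames])
        mean = frames.mean(axis=0)
    return frames, mean


@dataclass
class PCAResult:
    """Eigendecomposition of the Cartesian Calpha covariance matrix."""

    mean_structure: np.ndarray  # (atoms, 3)
    eigenvalues: np.ndarray  # descending, angstrom^2
    eigenvectors: np.ndarray  # (n_components, 3N), orthonormal rows
    projections: np.ndarray  # (frames, n_components)

    def __post_init__(self):
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be descending")


def pca(traj: Trajectory, n_components: int | None = None) -> PCAResult:
    """Principal component analysis of Cartesian Calpha coordinates.

    Frames are aligned with the same two-pass mean-refinement protocol as
    the RMSF computation, so eigenvalue sums and RMSF^2 sums agree exactly.
    The sign convention makes each eigenvector's largest-magnitude element
    positive.
    """
    frames, mean = align_trajectory(traj)
    n3 = traj.n_atoms * 3
    if n_components is None:
        n_components = n3
    if n_components > n3:
        raise ValueError("n_components exceeds 3N")
    if traj.n_frames < n_components:
        warnings.warn(
            "fewer frames than requested components; covariance is rank-deficient",
            RuntimeWarning,
        )
    x = frames.reshape(traj.n_frames, n3) - mean.reshape(-1)
    cov = x.T @ x / traj.n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_components]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T
    for i, v in enumerate(evecs):
        if v[np.argmax(np.abs(v))] < 0:
            evecs[i] = -v
    proj = x @ evecs.T
    return PCAResult(
        mean_structure=mean,
        eigenvalues=evals,
        eigenvectors=evecs,
        projections=proj,
    )


def rmsf_profile(traj: Trajectory) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the refined mean, angstrom."""
    frames, mean = align_trajectory(traj)
    d2 = np.sum((frames - mean) ** 2, axis=2)  # (frames, atoms)
    return np.sqrt(d2.mean(axis=0))


@dataclass
class FELGrid:
    """Binned 2D free-energy surface over principal-component projections."""

    pc1_edges: np.ndarray
    pc2_edges: np.ndarray
    free_energy: np.ndarray  # occupied bins; NaN where masked
    mask: np.ndarray  # True where the bin is empty
    temperature: float  # K
    units: str  # "kT" or "kcal/mol"

    def __post_init__(self):
        occ = self.free_energy[~self.mask]
        if occ.size and (abs(occ.min()) > 1e-12 or np.any(occ < 0)):
            raise ValueError("occupied-bin minimum must be exactly 0")


def fel(
    projections: np.ndarray,
    temperature: float = ROOM_TEMPERATURE,
    bins: int = 50,
    units: str = "kT",
) -> FELGrid:
    """Free-energy landscape by Boltzmann inversion of a 2D histogram.

    G = -kT ln(P/Pmax) over occupied bins; empty bins are masked rather
    than imputed (the logarithm is undefined there and imputation distorts
    barrier heights).  ``units`` 'kT' gives dimensionless multiples of kT;
    'kcal/mol' multiplies by RT.
    """
    p = np.asarray(projections, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("projections must have shape (frames, 2)")
    if p.shape[0] < 100:
        raise ValueError("need at least 100 frames")
    if bins < 5:
        raise ValueError("need at least 5 bins per axis")
    counts, e1, e2 = np.histogram2d(p[:, 0], p[:, 1], bins=bins)
    if np.count_nonzero(counts) == 1:
        warnings.warn("all frames fall in one bin; degenerate landscape", RuntimeWarning)
    mask = counts == 0
    g = np.full_like(counts, np.nan)
    cmax = counts.max()
    occ = ~mask
    g[occ] = -np.log(counts[occ] / cmax)
    if units == "kcal/mol":
        g = g * R_KCAL * temperature
    elif units != "kT":
        raise ValueError("units must be 'kT' or 'kcal/mol'")
    return FELGrid(
        pc1_edges=e1,
        pc2_edges=e2,
        free_energy=g,
        mask=mask,
        temperature=temperature,
        units=units,
    )


@dataclass
class PorcupineField:
    """Per-atom displacement arrows for one principal component."""

    vectors: np.ndarray  # (atoms, 3), angstrom
    anchor: np.ndarray  # (atoms, 3): structure at the minimum projection
    component: int

    def __post_init__(self):
        if self.vectors.shape != self.anchor.shape:
            raise ValueError("vectors and anchor must have matching shapes")


def porcupine(
    pca_result: PCAResult, component: int, traj: Trajectory | None = None
) -> PorcupineField:
    """Collective-motion arrows between the extreme projections of a PC.

    Each atom's vector is the difference between the structures
    reconstructed at the maximum and minimum observed projection along the
    component: (p_max - p_min) * eigenvector.
    """
    if not (0 <= component < len(pca_result.eigenvalues)):
        raise ValueError("component index out of range")
    proj = pca_result.projections[:, component]
    evec = pca_result.eigenvectors[component]
    n_atoms = pca_result.mean_structure.shape[0]
    p_min, p_max = float(proj.min()), float(proj.max())
    vectors = ((p_max - p_min) * evec).reshape(n_atoms, 3)
    anchor = pca_result.mean_structure + (p_min * evec).reshape(n_atoms, 3)
    return PorcupineField(vectors=vectors, anchor=anchor, component=component)
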