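"""Dynamic cross-correlation maps and essential dynamics (trajectory PCA).

DCC here is the normalised covariance of per-residue Cα *displacement
vectors* (full 3D dot products, not per-coordinate):

    C_ij = <Δr_i · Δr_j> / sqrt(<|Δr_i|²> <|Δr_j|²>),   Δr_i = r_i − <r_i>

Essential dynamics diagonalises the 3n×3n coordinate covariance; the
top mode (PC1) is the dominant collective motion, and the porcupine field
renders it as per-residue displacement arrows with a magnitude cutoff
(3.5 Å by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InsufficientFramesError
from .trajectory import Trajectory

_ZERO_VAR_TOL = 1e-12


@dataclass
class CorrelationMatrix:
    """Symmetric per-residue DCC matrix with unit diagonal."""

    residues: list[tuple[str, int]]
    C: np.ndarray
    zero_variance: np.ndarray = field(default=None)  # bool mask of frozen residues

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        n = len(self.residues)
        if self.C.shape != (n, n):
            raise ValueError("correlation matrix shape mismatch")
        if self.zero_variance is None:
            self.zero_variance = np.zeros(n, dtype=bool)

    @property
    def n(self) -> int:
        return len(self.residues)

    def to_tsv(self, path: str | Path, long_form: bool = False) -> None:
        labels = [f"{c}{r}" for c, r in self.residues]
        if long_form:
            rows = [
                (labels[i], labels[j], self.C[i, j])
                for i in range(self.n)
                for j in range(i, self.n)
            ]
            pd.DataFrame(rows, columns=["resi", "resj", "C"]).to_csv(
                path, sep="\t", index=False
            )
        else:
            pd.DataFrame(self.C, index=labels, columns=labels).to_csv(path, sep="\t")

    def plot(self, ax=None):
        """Heatmap of the DCC map (blue = anticorrelated, red = correlated)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.C, vmin=-1, vmax=1, cmap="RdBu_r", origin="lower")
        ax.set_xlabel("residue index")
        ax.set_ylabel("residue index")
        ax.figure.colorbar(im, ax=ax, label="C_ij")
        return ax


def dcc(traj: Trajectory) -> CorrelationMatrix:
    """Dynamic cross-correlation of a (superposed) Cα trajectory.

    Residues whose displacement variance is numerically zero get diagonal 1
    and zero off-diagonals by convention; they are flagged in
    ``zero_variance``.
    """
    if traj.n_frames < 2:
        raise InsufficientFramesError("DCC needs at least 2 frames")
    disp = traj.coords - traj.coords.mean(axis=0)
    cov = np.einsum("fik,fjk->ij", disp, disp) / traj.n_frames
    var = np.diag(cov).copy()
    frozen = var <= _ZERO_VAR_TOL * max(var.max(), 1.0)
    safe = np.where(frozen, 1.0, var)
    C = cov / np.sqrt(np.outer(safe, safe))
    C[frozen, :] = 0.0
    C[:, frozen] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip(0.5 * (C + C.T), -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return CorrelationMatrix(traj.residues, C, frozen)


def dcc_from_covariance(
    sigma: np.ndarray, residues: list[tuple[str, int]] | None = None
) -> CorrelationMatrix:
    """Analytic DCC from a 3n×3n displacement covariance.

    C_ij = tr Σ_ij / sqrt(tr Σ_ii · tr Σ_jj) over the 3×3 blocks.  Used as the
    exact counterpart of :func:`dcc` when the covariance is known (e.g. from
    the elastic-network generator).
    """
    sigma = np.asarray(sigma, dtype=float)
    n = sigma.shape[0] // 3
    blocks = sigma.reshape(n, 3, n, 3)
    tr = np.einsum("iaja->ij", blocks)
    var = np.diag(tr).copy()
    frozen = var <= _ZERO_VAR_TOL * max(var.max(), 1.0)
    safe = np.where(frozen, 1.0, var)
    C = tr / np.sqrt(np.outer(safe, safe))
    C[frozen, :] = 0.0
    C[:, frozen] = 0.0
    np.fill_diagonal(C, 1.0)
    if residues is None:
        residues = [("A", i + 1) for i in range(n)]
    return CorrelationMatrix(residues, np.clip(C, -1, 1), frozen)


def interdomain_coupling(
    cmat: CorrelationMatrix,
    domain_labels: list[str] | np.ndarray,
    by_chain: bool = False,
    chains: list[str] | None = None,
) -> pd.DataFrame:
    """Mean and max |C| per domain-pair block (e.g. the DBD×EO coupling).

    With ``by_chain=True`` blocks are keyed by (chain, domain), separating
    within-monomer from cross-monomer coupling.  Diagonal entries are excluded
    from within-block statistics.
    """
    labels = np.asarray(domain_labels, dtype=object)
    if len(labels) != cmat.n:
        raise ValueError("domain label list does not match matrix size")
    unlabeled = [i for i, l in enumerate(labels) if not l]
    if unlabeled:
        raise ValueError(f"unlabeled residues at indices {unlabeled}")
    if by_chain:
        if chains is None:
            chains = [c for c, _ in cmat.residues]
        keys = np.array([f"{c}:{d}" for c, d in zip(chains, labels)], dtype=object)
    else:
        keys = labels
    absC = np.abs(cmat.C)
    uniq = sorted(set(keys))
    rows = []
    for a_i, a in enumerate(uniq):
        ia = np.flatnonzero(keys == a)
        for b in uniq[a_i:]:
            ib = np.flatnonzero(keys == b)
            block = absC[np.ix_(ia, ib)]
            if a == b:
                mask = ~np.eye(len(ia), dtype=bool)
                vals = block[mask]
            else:
                vals = block.ravel()
            if vals.size == 0:
                continue
            rows.append((a, b, float(vals.mean()), float(vals.max()), vals.size))
    return pd.DataFrame(
        rows, columns=["domain_a", "domain_b", "mean_abs_c", "max_abs_c", "n_pairs"]
    )


@dataclass
class EssentialModes:
    """Eigenstructure of the coordinate covariance (descending eigenvalues, Å²)."""

    eigenvalues: np.ndarray  # (k,)
    modes: np.ndarray  # (3n, k), orthonormal columns
    mean_structure: np.ndarray  # (n, 3)
    projections: np.ndarray  # (n_frames, k)
    total_variance: float
    residues: list[tuple[str, int]] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.eigenvalues)

    def explained_fraction(self, mode_index: int = 1) -> float:
        if self.total_variance <= 0:
            return 0.0
        return float(self.eigenvalues[mode_index - 1] / self.total_variance)


def essential_dynamics(traj: Trajectory, k: int = 5) -> EssentialModes:
    """PCA of the 3n×3n coordinate covariance of a superposed trajectory.

    Eigenvector signs follow a fixed convention (the largest-magnitude
    component of each mode is made positive) so downstream porcupine arrows
    are reproducible.
    """
    n3 = 3 * traj.n_atoms
    if k > n3:
        raise ValueError(f"k={k} exceeds 3n={n3}")
    if traj.n_frames < k + 1:
        raise InsufficientFramesError(f"need at least {k + 1} frames for k={k} modes")
    X = traj.coords.reshape(traj.n_frames, n3)
    mu = X.mean(axis=0)
    Xc = X - mu
    cov = (Xc.T @ Xc) / traj.n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:k]
    evals = np.clip(evals[order], 0.0, None)
    modes = evecs[:, order]
    for j in range(modes.shape[1]):
        i = np.argmax(np.abs(modes[:, j]))
        if modes[i, j] < 0:
            modes[:, j] = -modes[:, j]
    proj = Xc @ modes
    return EssentialModes(
        eigenvalues=evals,
        modes=modes,
        mean_structure=mu.reshape(-1, 3),
        projections=proj,
        total_variance=float(np.trace(cov)),
        residues=traj.residues,
    )


@dataclass
class PorcupineField:
    """Per-residue displacement arrows along one essential mode."""

    vectors: np.ndarray  # (n, 3), Å
    magnitudes: np.ndarray  # (n,)
    kept_mask: np.ndarray  # bool, |v| >= cutoff
    cutoff: float
    mode_index: int
    residues: list[tuple[str, int]] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        chains = [c for c, _ in self.residues]
        resids = [r for _, r in self.residues]
        pd.DataFrame(
            {
                "chain": chains,
                "resid": resids,
                "dx": self.vectors[:, 0],
                "dy": self.vectors[:, 1],
                "dz": self.vectors[:, 2],
                "magnitude": self.magnitudes,
                "kept": self.kept_mask.astype(int),
            }
        ).to_csv(path, sep="\t", index=False)


def porcupine(
    modes: EssentialModes,
    mode_index: int = 1,
    cutoff: float = 3.5,
    scale: float | None = None,
) -> PorcupineField:
    """Displacement arrows along a mode, masked at a magnitude cutoff (Å).

    Arrows are the mode vector scaled by the observed projection range
    (max − min along that mode), i.e. the full excursion of the trajectory
    along the PC; an explicit ``scale`` overrides this.
    """
    if not 1 <= mode_index <= modes.k:
        raise ValueError(f"mode {mode_index} not available (k={modes.k})")
    v = modes.modes[:, mode_index - 1].reshape(-1, 3)
    if scale is None:
        p = modes.projections[:, mode_index - 1]
        scale = float(p.max() - p.min()) if len(p) else 0.0
    vec = v * scale
    mag = np.linalg.norm(vec, axis=1)
    return PorcupineField(
        vectors=vec,
        magnitudes=mag,
        kept_mask=mag >= cutoff,
        cutoff=cutoff,
        mode_index=mode_index,
        residues=modes.residues,
    )
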