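"""Trajectory containers, I/O, rigid-body superposition and stability metrics.

The in-memory model is deliberately small: a :class:`Trajectory` is a
``(n_frames, n_atoms, 3)`` coordinate array in Å plus a per-atom metadata
table (serial, atom name, 1-based residue index, residue name, chain id and
an optional domain label).  A :class:`StructureModel` is a single frame with
the same metadata.  All dynamics analyses in this package operate on Cα-only
models, which is also all the synthetic generators emit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import TrajectoryFormatError

ATOM_COLUMNS = ["serial", "atom_name", "resid", "resname", "chain", "domain"]


def _check_atoms(atoms: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ATOM_COLUMNS if c not in atoms.columns]
    if missing:
        raise ValueError(f"atom table missing columns: {missing}")
    return atoms.reset_index(drop=True)


@dataclass
class StructureModel:
    """Single-frame structure: reference coordinates plus atom metadata."""

    atoms: pd.DataFrame
    coords: np.ndarray  # (n_atoms, 3), Å

    def __post_init__(self):
        self.atoms = _check_atoms(self.atoms)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise ValueError("coords shape does not match atom table")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        key = list(zip(self.atoms["chain"], self.atoms["resid"]))
        if len(set(key)) != len(key):
            raise ValueError("duplicate (chain, resid) in structure")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residues(self) -> list[tuple[str, int]]:
        return list(zip(self.atoms["chain"], self.atoms["resid"].astype(int)))


@dataclass
class Trajectory:
    """Multi-frame Cα trajectory with shared atom metadata."""

    atoms: pd.DataFrame
    coords: np.ndarray  # (n_frames, n_atoms, 3), Å

    def __post_init__(self):
        self.atoms = _check_atoms(self.atoms)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != len(self.atoms):
            raise ValueError("coords must be (n_frames, n_atoms, 3) matching atom table")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def residues(self) -> list[tuple[str, int]]:
        return list(zip(self.atoms["chain"], self.atoms["resid"].astype(int)))

    def frame(self, i: int) -> StructureModel:
        return StructureModel(self.atoms.copy(), self.coords[i].copy())

    def mean_structure(self) -> StructureModel:
        return StructureModel(self.atoms.copy(), self.coords.mean(axis=0))


@dataclass
class StabilityProfile:
    """Per-frame RMSD and per-residue RMSF (both Å, both ≥ 0)."""

    rmsd_per_frame: np.ndarray
    rmsf_per_residue: np.ndarray
    residues: list[tuple[str, int]] = field(default_factory=list)

    def to_tsv(self, rmsd_path: str | Path, rmsf_path: str | Path) -> None:
        pd.DataFrame(
            {"frame": np.arange(len(self.rmsd_per_frame)), "rmsd": self.rmsd_per_frame}
        ).to_csv(rmsd_path, sep="\t", index=False)
        chains = [c for c, _ in self.residues] or [""] * len(self.rmsf_per_residue)
        resids = [r for _, r in self.residues] or list(range(len(self.rmsf_per_residue)))
        pd.DataFrame(
            {"chain": chains, "resid": resids, "rmsf": self.rmsf_per_residue}
        ).to_csv(rmsf_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_pdb(traj: Trajectory | StructureModel, path: str | Path) -> None:
    """Write a (multi-model) PDB file via biotite; 3-decimal coordinate precision."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if isinstance(traj, StructureModel):
        coords = traj.coords[None, :, :]
        atoms = traj.atoms
    else:
        coords = traj.coords
        atoms = traj.atoms
    n = len(atoms)
    template = struc.AtomArray(n)
    template.chain_id = np.asarray(atoms["chain"], dtype="U4")
    template.res_id = np.asarray(atoms["resid"], dtype=int)
    template.res_name = np.asarray(atoms["resname"], dtype="U5")
    template.atom_name = np.asarray(atoms["atom_name"], dtype="U6")
    template.element = np.array(["C"] * n, dtype="U2")
    template.hetero = np.zeros(n, dtype=bool)
    stack = struc.AtomArrayStack(coords.shape[0], n)
    for ann in ("chain_id", "res_id", "res_name", "atom_name", "element", "hetero"):
        stack.set_annotation(ann, template.get_annotation(ann))
    stack.coord = np.asarray(coords, dtype=np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def _precheck_multimodel_pdb(path: Path) -> None:
    """Reject PDBs whose MODEL blocks disagree in atom count, naming the model."""
    counts: list[int] = []
    current = 0
    saw_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec.startswith("MODEL"):
                saw_model = True
                current = 0
            elif rec in ("ATOM  ", "HETATM"):
                current += 1
            elif rec.startswith("ENDMDL"):
                counts.append(current)
                current = 0
    if not saw_model and current:
        counts.append(current)
    elif saw_model and current:
        counts.append(current)  # unterminated final MODEL block
    if len(counts) > 1:
        for i, c in enumerate(counts, start=1):
            if c != counts[0]:
                raise TrajectoryFormatError(
                    f"model {i} has {c} atoms, expected {counts[0]}"
                )


def read_trajectory(
    path: str | Path,
    fmt: str = "pdb",
    topology: str | Path | None = None,
    domain_labels: dict[tuple[str, int], str] | None = None,
) -> Trajectory:
    """Read a trajectory from multi-model PDB, XYZ, or DCD (+ PDB topology).

    Residue indexing is kept 1-based as in the source file.  ``domain_labels``
    optionally maps ``(chain, resid)`` to a domain label; unknown residues get
    an empty label.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise TrajectoryFormatError(f"empty or missing trajectory file: {path}")
    fmt = fmt.lower()
    if fmt == "pdb":
        _precheck_multimodel_pdb(path)
        from biotite.structure.io.pdb import PDBFile

        try:
            stack = PDBFile.read(str(path)).get_structure(model=None)
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise TrajectoryFormatError(f"cannot parse PDB {path}: {exc}") from exc
        if stack.array_length() == 0:
            raise TrajectoryFormatError(f"no atoms in {path}")
        atoms = pd.DataFrame(
            {
                "serial": np.arange(1, stack.array_length() + 1),
                "atom_name": stack.atom_name,
                "resid": stack.res_id.astype(int),
                "resname": stack.res_name,
                "chain": stack.chain_id,
                "domain": "",
            }
        )
        coords = np.asarray(stack.coord, dtype=float)
        if coords.ndim == 2:
            coords = coords[None, :, :]
    elif fmt == "xyz":
        coords = _read_xyz(path)
        n = coords.shape[1]
        atoms = pd.DataFrame(
            {
                "serial": np.arange(1, n + 1),
                "atom_name": "CA",
                "resid": np.arange(1, n + 1),
                "resname": "GLY",
                "chain": "A",
                "domain": "",
            }
        )
    elif fmt == "dcd":
        if topology is None:
            raise TrajectoryFormatError("DCD input requires a PDB topology")
        import MDAnalysis as mda

        u = mda.Universe(str(topology), str(path))
        sel = u.atoms
        atoms = pd.DataFrame(
            {
                "serial": sel.ids,
                "atom_name": sel.names,
                "resid": sel.resids.astype(int),
                "resname": sel.resnames,
                "chain": [s or "A" for s in sel.segids],
                "domain": "",
            }
        )
        coords = np.array([sel.positions.copy() for _ in u.trajectory], dtype=float)
    else:
        raise TrajectoryFormatError(f"unknown trajectory format: {fmt}")

    if domain_labels:
        atoms["domain"] = [
            domain_labels.get((c, int(r)), "")
            for c, r in zip(atoms["chain"], atoms["resid"])
        ]
    return Trajectory(atoms, coords)


def _read_xyz(path: Path) -> np.ndarray:
    frames = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise TrajectoryFormatError(f"bad XYZ atom count at line {i + 1}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise TrajectoryFormatError("truncated XYZ frame")
        frames.append([[float(v) for v in ln.split()[1:4]] for ln in block])
        i += 2 + n
    if not frames:
        raise TrajectoryFormatError(f"no frames in {path}")
    return np.asarray(frames, dtype=float)


def select_ca(traj: Trajectory) -> Trajectory:
    """Cα-only view (copy) of a trajectory."""
    mask = (traj.atoms["atom_name"] == "CA").to_numpy()
    return Trajectory(traj.atoms[mask].reset_index(drop=True), traj.coords[:, mask, :])


# ---------------------------------------------------------------------------
# Superposition and stability metrics
# ---------------------------------------------------------------------------

def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal proper rotation R with target ≈ mobile @ R.T (both pre-centred)."""
    H = mobile.T @ target
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def _resolve_selection(traj_atoms: pd.DataFrame, selection) -> np.ndarray:
    if selection is None:
        idx = np.arange(len(traj_atoms))
    elif isinstance(selection, str):
        if selection.lower() in ("ca", "calpha"):
            idx = np.flatnonzero((traj_atoms["atom_name"] == "CA").to_numpy())
        else:
            raise ValueError(f"unknown selection string: {selection}")
    else:
        idx = np.asarray(selection, dtype=int)
    return idx


def superpose(
    traj: Trajectory,
    reference: StructureModel,
    selection=None,
    iterate_mean: bool = False,
    max_iter: int = 10,
) -> Trajectory:
    """Rigid-body least-squares superposition of every frame onto a reference.

    Only proper rotations are used (chirality preserved).  With
    ``iterate_mean=True`` the target is refined to the trajectory mean until
    convergence; the default single-pass fit onto the supplied reference is
    deterministic.
    """
    idx = _resolve_selection(traj.atoms, selection)
    if len(idx) < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    target = reference.coords[idx]
    coords = traj.coords.copy()
    for _ in range(max_iter if iterate_mean else 1):
        tc = target.mean(axis=0)
        for f in range(coords.shape[0]):
            sel = coords[f, idx]
            fc = sel.mean(axis=0)
            R = kabsch_rotation(sel - fc, target - tc)
            coords[f] = (coords[f] - fc) @ R.T + tc
        if not iterate_mean:
            break
        new_target = coords[:, idx, :].mean(axis=0)
        if np.max(np.abs(new_target - target)) < 1e-9:
            break
        target = new_target
    return Trajectory(traj.atoms.copy(), coords)


def rmsd_rmsf(
    traj: Trajectory,
    reference: StructureModel,
    selection=None,
    frame_slice: slice | None = None,
) -> StabilityProfile:
    """RMSD per frame against the reference and RMSF per residue about the mean.

    RMSF_i = sqrt(<|r_i - <r_i>|^2>) over frames; RMSD_t is over the selected
    atoms.  ``frame_slice`` optionally discards an equilibration window; by
    default all frames are used.
    """
    idx = _resolve_selection(traj.atoms, selection)
    coords = traj.coords if frame_slice is None else traj.coords[frame_slice]
    sel = coords[:, idx, :]
    ref = reference.coords[idx]
    rmsd = np.sqrt(np.mean(np.sum((sel - ref) ** 2, axis=2), axis=1))
    mean = sel.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((sel - mean) ** 2, axis=2), axis=0))
    residues = [
        (traj.atoms["chain"].iloc[i], int(traj.atoms["resid"].iloc[i])) for i in idx
    ]
    return StabilityProfile(rmsd, rmsf, residues)
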