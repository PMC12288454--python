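"""Synthetic inputs for every pipeline stage, with exact ground truth.

Real study data for this system — microsecond-scale all-atom trajectories of
a repressor dimer and a panel of sequenced natural isolates — are not
distributable, so every downstream stage is exercised on generated inputs
whose statistics are known exactly:

* **Toy dimer trajectories.**  A two-chain Cα bead model (α-helical geometry,
  ~3.8 Å consecutive spacing) carries an elastic network (springs between
  beads within a cutoff, plus planted extra springs).  Frames are drawn from
  the zero-mean Gaussian over displacements with covariance proportional to
  the pseudo-inverse of the network Hessian — the stationary distribution of
  the harmonic model — so the analytic covariance is returned alongside the
  trajectory and serves as the oracle for DCC/PCA/network tests.  Planted
  cross-domain springs emulate effector binding at the C-terminal domain
  allosterically modulating the N-terminal DNA-binding domain.
* **Ligand-state suites.**  Four trajectories per variant (APO, effector-
  bound E, DNA-bound D, doubly bound ED) differing only in the planted
  coupling scheme: E adds effector springs rigidifying the EO domains, D adds
  DNA-clamp springs rigidifying the DBDs, ED adds both.  APO, with no planted
  springs, is the loosest construction.
* **Isolate sequence panels.**  A reference protein plus homologs carrying
  planted substitutions at known positions with known carrier sets; the
  packaged default reproduces the published census dimensions (340 isolates,
  12 unique substitutions carried by 42 isolates).  Per-variant carrier
  counts are a documented fixture, not data.
* **Binding and growth curves.**  Hill, exact 1:1 isotherm, and
  lag+exponential growth curves with multiplicative Gaussian noise
  (responses are positive), truth stored alongside.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assays import CurveData, hill_model, isotherm_model
from .exceptions import DegenerateModelError, SpecificationError
from .trajectory import StructureModel, Trajectory

STATES = ("APO", "E", "D", "ED")

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: The 12 published substitutions in the 229-aa repressor with packaged
#: per-variant carrier counts (only the total, 42, is published; the split is
#: a fixture).  Disjoint carrier sets ⇒ 42 carrier isolates.
DEFAULT_VARIANT_TABLE: tuple[tuple[str, int], ...] = (
    ("L3F", 2),
    ("K15R", 6),
    ("H19Q", 3),
    ("P24L", 2),
    ("R71C", 4),
    ("P92L", 2),
    ("A128S", 5),
    ("A152E", 6),
    ("T180S", 4),
    ("A186V", 3),
    ("S220C", 2),
    ("T222I", 3),
)


def parse_variant(name: str) -> tuple[int, str, str]:
    """Parse e.g. ``"A152E"`` into ``(152, "A", "E")``."""
    return int(name[1:-1]), name[0], name[-1]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

def _default_domain_ranges(n: int) -> tuple[tuple[str, int, int], ...]:
    """Scale the 229-residue map (DBD 1-63, linker 64-79, EO 80-229) to n."""
    if n == 229:
        return (("DBD", 1, 63), ("linker", 64, 79), ("EO", 80, 229))
    dbd_end = max(1, round(n * 63 / 229))
    linker_end = max(dbd_end + 1, round(n * 79 / 229))
    linker_end = min(linker_end, n - 1)
    return (("DBD", 1, dbd_end), ("linker", dbd_end + 1, linker_end), ("EO", linker_end + 1, n))


@dataclass(frozen=True)
class ToyDimerSpec:
    """Geometry of a two-chain Cα bead dimer with per-residue domain labels."""

    residues_per_monomer: int = 229
    domain_map: tuple = None  # ((label, start, end), ...) per monomer
    geometry_seed: int = 0
    chain_separation: float = 11.0  # Å between helical axes

    def __post_init__(self):
        if self.residues_per_monomer < 2:
            raise SpecificationError("need at least 2 residues per monomer")
        dm = self.domain_map or _default_domain_ranges(self.residues_per_monomer)
        dm = tuple(tuple(s) for s in dm)
        object.__setattr__(self, "domain_map", dm)
        prev = 0
        for label, start, end in dm:
            if start != prev + 1 or end < start:
                raise SpecificationError(
                    f"domain ranges must be disjoint, ordered and contiguous; bad {label} {start}-{end}"
                )
            prev = end
        if prev != self.residues_per_monomer:
            raise SpecificationError("domain ranges must cover 1..residues_per_monomer")

    def domain_of(self, resid: int) -> str:
        for label, start, end in self.domain_map:
            if start <= resid <= end:
                return label
        raise ValueError(f"residue {resid} outside domain map")


@dataclass(frozen=True)
class ENMTrajectorySpec:
    """Elastic-network Gaussian trajectory specification."""

    spec: ToyDimerSpec
    contact_cutoff: float = 12.0  # Å
    spring_constant: float = 1.0  # energy/Å²
    extra_couplings: tuple = ()  # ((res_i, res_j, k), ...) global 1-based indices
    n_frames: int = 1000
    temperature_scale: float = 1.0  # Å² variance scale
    state_label: str = "APO"
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 10:
            raise SpecificationError("n_frames must be ≥ 10")
        if self.contact_cutoff <= 0:
            raise SpecificationError("contact_cutoff must be positive")
        if self.state_label not in STATES:
            raise SpecificationError(f"state_label must be one of {STATES}")
        object.__setattr__(
            self, "extra_couplings", tuple(tuple(c) for c in self.extra_couplings)
        )


@dataclass(frozen=True)
class PanelSpec:
    """Isolate sequence panel with planted substitutions."""

    reference_length: int = 229
    planted_variants: tuple = ()  # ((position, ref_aa, alt_aa, n_carriers), ...)
    total_sequences: int = 340
    seed: int = 0

    def __post_init__(self):
        pv = tuple(tuple(v) for v in self.planted_variants)
        object.__setattr__(self, "planted_variants", pv)
        seen: dict[int, str] = {}
        total = 0
        for pos, ref_aa, alt_aa, n in pv:
            if not 1 <= pos <= self.reference_length:
                raise SpecificationError(f"position {pos} outside reference")
            if ref_aa == alt_aa:
                raise SpecificationError(f"ref and alt identical at {pos}")
            if pos in seen and seen[pos] != ref_aa:
                raise SpecificationError(f"conflicting reference residues at {pos}")
            seen[pos] = ref_aa
            total += n
        if total > self.total_sequences:
            raise SpecificationError("carrier counts exceed panel size")

    @classmethod
    def default_dgor_panel(cls, seed: int = 0) -> "PanelSpec":
        """The packaged 340-isolate panel with the 12 published substitutions."""
        planted = tuple(
            (*parse_variant(name), n) for name, n in DEFAULT_VARIANT_TABLE
        )
        return cls(229, planted, 340, seed)


@dataclass(frozen=True)
class CurveSpec:
    """Synthetic assay curve specification."""

    model: str  # hill | isotherm_1to1 | growth_lag_exp
    true_params: tuple  # (("K_D", 494.0), ...) — mapping also accepted
    x_values: tuple
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.model not in ("hill", "isotherm_1to1", "growth_lag_exp"):
            raise SpecificationError(f"unknown curve model: {self.model}")
        tp = dict(self.true_params) if not isinstance(self.true_params, dict) else dict(self.true_params)
        object.__setattr__(self, "true_params", tuple(sorted(tp.items())))
        x = tuple(float(v) for v in self.x_values)
        object.__setattr__(self, "x_values", x)
        if any(v < 0 for v in x) or any(b <= a for a, b in zip(x, x[1:])):
            raise SpecificationError("x_values must be strictly increasing and non-negative")
        if self.noise_cv < 0:
            raise SpecificationError("noise_cv must be ≥ 0")

    @property
    def params(self) -> dict:
        return dict(self.true_params)


# ---------------------------------------------------------------------------
# Structure and trajectory generation
# ---------------------------------------------------------------------------

def generate_toy_dimer(spec: ToyDimerSpec) -> StructureModel:
    """Reference Cα coordinates for a two-chain bead dimer.

    Each monomer is laid out on an α-helical curve (rise 1.5 Å, 100° twist,
    radius 2.3 Å ⇒ ~3.8 Å consecutive Cα spacing, with near-in-sequence
    spatial contacts); the second chain is the first translated by the chain
    separation.  A small seeded jitter (0.02 Å) breaks exact symmetry.
    """
    n = spec.residues_per_monomer
    rng = np.random.default_rng(spec.geometry_seed)
    i = np.arange(n)
    theta = np.deg2rad(100.0) * i
    helix = np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])
    coords = np.vstack([helix, helix + np.array([spec.chain_separation, 0.0, 0.0])])
    coords = coords + rng.normal(0.0, 0.02, coords.shape)
    atoms = pd.DataFrame(
        {
            "serial": np.arange(1, 2 * n + 1),
            "atom_name": "CA",
            "resid": np.concatenate([i + 1, i + 1]),
            "resname": "ALA",
            "chain": ["A"] * n + ["B"] * n,
            "domain": [spec.domain_of(r + 1) for r in i] * 2,
        }
    )
    return StructureModel(atoms, coords)


def _enm_hessian(coords: np.ndarray, cutoff: float, k: float, extra) -> tuple[np.ndarray, list]:
    n = coords.shape[0]
    springs: list[tuple[int, int, float]] = []
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=2)
    cut2 = cutoff * cutoff
    for i in range(n):
        for j in range(i + 1, n):
            if d2[i, j] <= cut2:
                springs.append((i, j, k))
    for ri, rj, kk in extra:
        i, j = ri - 1, rj - 1
        if not (0 <= i < n and 0 <= j < n) or i == j:
            raise SpecificationError(f"bad extra coupling ({ri}, {rj})")
        springs.append((min(i, j), max(i, j), kk))
    H = np.zeros((3 * n, 3 * n))
    for i, j, kk in springs:
        dv = coords[j] - coords[i]
        dist2 = float(dv @ dv)
        if dist2 <= 0:
            continue
        block = kk * np.outer(dv, dv) / dist2
        si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        H[si, si] += block
        H[sj, sj] += block
        H[si, sj] -= block
        H[sj, si] -= block
    return H, springs


def sample_enm_trajectory(
    spec: ENMTrajectorySpec,
) -> tuple[Trajectory, np.ndarray]:
    """Sample a Gaussian elastic-network trajectory and its analytic covariance.

    Displacements are drawn from N(0, Σ) with Σ = temperature_scale × H⁺
    (pseudo-inverse with relative tolerance 1e-8, removing the six rigid-body
    modes) and added to the reference coordinates.  Returns the trajectory
    and the exact Σ (3n×3n) used.  Seeded runs are bit-reproducible.
    """
    structure = generate_toy_dimer(spec.spec)
    coords = structure.coords
    n = coords.shape[0]
    H, springs = _enm_hessian(
        coords, spec.contact_cutoff, spec.spring_constant, spec.extra_couplings
    )
    evals, evecs = np.linalg.eigh(H)
    tol = 1e-8 * max(evals.max(), 1.0)
    zero = evals <= tol
    if zero.sum() > 6:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from((i, j) for i, j, _ in springs)
        comps = sorted(nx.connected_components(g), key=len, reverse=True)
        isolated = sorted(r + 1 for comp in comps[1:] for r in comp)
        raise DegenerateModelError(
            f"elastic network is disconnected ({zero.sum()} near-zero modes); "
            f"isolated residues: {isolated}"
        )
    inv = np.where(zero, 0.0, 1.0 / np.where(zero, 1.0, evals))
    sigma = spec.temperature_scale * (evecs * inv) @ evecs.T
    rng = np.random.default_rng(spec.seed)
    nz = ~zero
    L = evecs[:, nz] * np.sqrt(spec.temperature_scale * inv[nz])
    z = rng.standard_normal((spec.n_frames, int(nz.sum())))
    disp = z @ L.T
    frames = coords[None, :, :] + disp.reshape(spec.n_frames, n, 3)
    traj = Trajectory(structure.atoms.copy(), frames)
    return traj, sigma


def _domain_clamp(
    spec: ToyDimerSpec, domain: str, k: float
) -> tuple[tuple[int, int, float], ...]:
    """Rigidifying springs for one domain (global 1-based residue indices).

    Within each monomer every even-separation residue pair of the domain is
    tied; every second residue is additionally tied to its counterpart in the
    other monomer (the ligand bridging the dimer interface).
    """
    from itertools import combinations

    n = spec.residues_per_monomer
    seg = next(s for s in spec.domain_map if s[0] == domain)
    res = list(range(seg[1], seg[2] + 1))
    springs: list[tuple[int, int, float]] = []
    for off in (0, n):
        for i, j in combinations(res, 2):
            if (j - i) % 2 == 0:
                springs.append((i + off, j + off, k))
    for i in res[::2]:
        springs.append((i, i + n, k))
    return tuple(springs)


def _state_couplings(
    spec: ToyDimerSpec, state: str, k_extra: float
) -> tuple[tuple[int, int, float], ...]:
    """Planted springs for a ligand state.

    Ligand binding is emulated as internal rigidification of the domain it
    engages — effector (E) clamps the EO domains, operator DNA (D) clamps the
    DBDs, ED clamps both.  In a superposed Gaussian model, rigidifying a
    domain concentrates the dimer's fluctuations into coherent inter-domain
    motion, which *raises* the DBD×EO correlation block — the planted
    direction downstream stages must recover.  APO plants nothing and is the
    loosest construction.
    """
    springs: tuple[tuple[int, int, float], ...] = ()
    if state in ("E", "ED"):
        springs += _domain_clamp(spec, "EO", k_extra)
    if state in ("D", "ED"):
        springs += _domain_clamp(spec, "DBD", k_extra)
    return tuple(sorted(set(springs)))


def generate_state_suite(
    base: ENMTrajectorySpec, k_extra: float | None = None
) -> dict[str, tuple[Trajectory, np.ndarray]]:
    """The four ligand-state trajectories (APO, E, D, ED) for one variant.

    State seeds are ``base.seed + state index`` so suites from different base
    seeds never share draws.  Planted couplings are added on top of any the
    base spec already carries.
    """
    if k_extra is None:
        k_extra = 20.0 * base.spring_constant
    out: dict[str, tuple[Trajectory, np.ndarray]] = {}
    for idx, state in enumerate(STATES):
        extra = tuple(base.extra_couplings) + _state_couplings(base.spec, state, k_extra)
        spec = ENMTrajectorySpec(
            spec=base.spec,
            contact_cutoff=base.contact_cutoff,
            spring_constant=base.spring_constant,
            extra_couplings=extra,
            n_frames=base.n_frames,
            temperature_scale=base.temperature_scale,
            state_label=state,
            seed=base.seed + idx,
        )
        out[state] = sample_enm_trajectory(spec)
    return out


# ---------------------------------------------------------------------------
# Sequence panels
# ---------------------------------------------------------------------------

@dataclass
class PanelResult:
    reference_id: str
    reference: str
    records: list  # [(id, seq), ...]
    truth: pd.DataFrame  # columns: variant, position, ref, alt, carrier_id

    def write_fasta(self, panel_path: str | Path, reference_path: str | Path) -> None:
        _write_fasta([(self.reference_id, self.reference)], reference_path)
        _write_fasta(self.records, panel_path)

    def write_truth(self, path: str | Path) -> None:
        obj = {
            "reference_id": self.reference_id,
            "variants": [
                {
                    "variant": v,
                    "carriers": sorted(g["carrier_id"].tolist()),
                }
                for v, g in self.truth.groupby("variant", sort=True)
            ],
        }
        Path(path).write_text(json.dumps(obj, indent=2))


def _write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def generate_sequence_panel(spec: PanelSpec) -> PanelResult:
    """Panel of isolate sequences with planted substitutions and a truth table.

    The reference is a seeded random protein (methionine first) carrying the
    stated reference residue at every planted position.  Carrier sets are
    disjoint and drawn without replacement from a seeded shuffle, so each
    carrier differs from the reference at exactly its one planted position.
    """
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(AA_ALPHABET))
    ref = rng.choice(aa, size=spec.reference_length)
    ref[0] = "M"
    for pos, ref_aa, _, _ in spec.planted_variants:
        ref[pos - 1] = ref_aa
    reference = "".join(ref)

    ids = [f"iso_{i + 1:04d}" for i in range(spec.total_sequences)]
    order = rng.permutation(spec.total_sequences)
    records = {i: reference for i in ids}
    rows = []
    cursor = 0
    for pos, ref_aa, alt_aa, n_carriers in spec.planted_variants:
        name = f"{ref_aa}{pos}{alt_aa}"
        for _ in range(n_carriers):
            carrier = ids[order[cursor]]
            cursor += 1
            s = list(records[carrier])
            s[pos - 1] = alt_aa
            records[carrier] = "".join(s)
            rows.append(
                {"variant": name, "position": pos, "ref": ref_aa, "alt": alt_aa, "carrier_id": carrier}
            )
    truth = pd.DataFrame(rows, columns=["variant", "position", "ref", "alt", "carrier_id"])
    return PanelResult("reference", reference, [(i, records[i]) for i in ids], truth)


# ---------------------------------------------------------------------------
# Assay curves
# ---------------------------------------------------------------------------

def growth_lag_exp_model(t, lag: float, rate: float, od0: float, plateau: float):
    """Lag + exponential growth capped at a plateau OD."""
    t = np.asarray(t, dtype=float)
    od = od0 * np.exp(rate * np.clip(t - lag, 0.0, None))
    return np.minimum(od, plateau)


def generate_curve(spec: CurveSpec) -> CurveData:
    """Noisy assay curve: y = model(x; truth) × (1 + ε), ε ~ N(0, noise_cv)."""
    x = np.asarray(spec.x_values)
    p = spec.params
    if spec.model == "hill":
        y0 = hill_model(x, p["K_D"], p.get("n", 1.0))
        units = ("nM", "fraction bound")
    elif spec.model == "isotherm_1to1":
        y0 = isotherm_model(p["P_total"], x, p["K_D"])
        units = ("nM", "fraction bound")
    else:
        rate = p["rate"] if "rate" in p else np.log(2) / p["doubling_time"]
        y0 = growth_lag_exp_model(x, p.get("lag", 0.0), rate, p["od0"], p.get("plateau", np.inf))
        units = ("h", "OD")
    rng = np.random.default_rng(spec.seed)
    y = y0 * (1.0 + rng.normal(0.0, spec.noise_cv, size=len(x))) if spec.noise_cv > 0 else y0.copy()
    return CurveData(
        x=x, y=y, x_unit=units[0], y_unit=units[1], truth=dict(p), model=spec.model
    )
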