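"""End-to-end orchestration: synthetic suite → dynamics → networks → report.

Runs are configured by a small YAML/dict schema, execute single-process with
stages communicating through files, and emit a JSON manifest recording the
verbatim configuration, the seed of every stochastic stage, package version
and a content hash of every output — rerunning a config reproduces all
deterministic outputs bit-identically (the manifest timestamp aside).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import yaml

from . import __version__
from .assays import BindingModel, CurveData, GrowthCurveModel
from .correlation import dcc, essential_dynamics, interdomain_coupling, porcupine
from .exceptions import PipelineError
from .network import PathQuery, build_network, detect_communities, path_statistics, suboptimal_paths
from .synthetic import (
    STATES,
    ENMTrajectorySpec,
    PanelSpec,
    ToyDimerSpec,
    generate_sequence_panel,
    generate_state_suite,
)
from .trajectory import rmsd_rmsf, superpose, write_pdb
from .variants import DEFAULT_DOMAIN_MAP, DomainMap, read_fasta, tabulate_panel

log = logging.getLogger("allosterik")


@dataclass(frozen=True)
class StudyDesign:
    """Variants × ligand states making up a simulation study."""

    variants: tuple
    states: tuple = STATES

    def __post_init__(self):
        object.__setattr__(self, "variants", tuple(self.variants))
        object.__setattr__(self, "states", tuple(self.states))
        if not self.variants or not self.states:
            raise ValueError("design must list at least one variant and one state")
        unknown = [s for s in self.states if s not in STATES]
        if unknown:
            raise ValueError(f"unknown state labels: {unknown}")


def enumerate_systems(design: StudyDesign) -> list[tuple[str, str]]:
    """Deterministic Cartesian product of variants and states."""
    return list(product(design.variants, design.states))


@dataclass
class RunConfig:
    kind: str  # dynamics | scan | curves
    seed: int = 0
    out_dir: str = "run_out"
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            kind=raw["kind"],
            seed=int(raw.get("seed", 0)),
            out_dir=raw.get("out_dir", "run_out"),
            params=raw.get("params", {}) or {},
        )

    def to_dict(self) -> dict:
        return {"kind": self.kind, "seed": self.seed, "out_dir": self.out_dir, "params": self.params}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, config: RunConfig, outputs: list[Path]) -> Path:
    manifest = {
        "package": "allosterik",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": config.to_dict(),
        "outputs": {str(p.relative_to(out_dir)): _sha256(p) for p in sorted(outputs)},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute a configured run; returns the manifest as a dict.

    Stage failures raise :class:`PipelineError` naming the stage; outputs
    written before the failure are preserved for inspection.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    runner = {"dynamics": _run_dynamics, "scan": _run_scan, "curves": _run_curves}.get(config.kind)
    if runner is None:
        raise PipelineError("configure", f"unknown run kind '{config.kind}'")
    outputs = runner(config, out_dir)
    manifest_path = _write_manifest(out_dir, config, outputs)
    return json.loads(manifest_path.read_text())


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _variant_couplings(variant: str, spec: ToyDimerSpec, k: float) -> tuple:
    """Local rigidification around a variant site, mapped onto the toy dimer.

    Named variants (e.g. R71C) stiffen contacts around the (scaled) mutated
    position in both monomers — a cartoon of a local packing change, enough
    to differentiate suites.  "WT" plants nothing.
    """
    if variant.upper() in ("WT", "WILDTYPE"):
        return ()
    try:
        pos = int("".join(ch for ch in variant if ch.isdigit()))
    except ValueError:
        return ()
    n = spec.residues_per_monomer
    p = max(2, min(n - 1, round(pos * n / 229)))
    springs = []
    for offset in (0, n):  # both monomers
        springs.append((p - 1 + offset, p + 1 + offset, 3.0 * k))
    return tuple(springs)


def _run_dynamics(config: RunConfig, out_dir: Path) -> list[Path]:
    p = config.params
    design = StudyDesign(
        variants=tuple(p.get("variants", ("WT",))),
        states=tuple(p.get("states", STATES)),
    )
    n_res = int(p.get("residues_per_monomer", 20))
    n_frames = int(p.get("n_frames", 1000))
    dimer = ToyDimerSpec(residues_per_monomer=n_res, geometry_seed=config.seed)
    outputs: list[Path] = []
    ensembles = {}
    systems = enumerate_systems(design)
    log.info("dynamics run: %d systems (%s)", len(systems), systems)
    for vi, variant in enumerate(design.variants):
        stage = f"simulate[{variant}]"
        try:
            base = ENMTrajectorySpec(
                spec=dimer,
                n_frames=n_frames,
                extra_couplings=_variant_couplings(variant, dimer, 1.0),
                seed=config.seed + 100 * (vi + 1),
            )
            suite = generate_state_suite(base)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc
        for state in design.states:
            traj, _sigma = suite[state]
            sysdir = out_dir / f"{variant}_{state}"
            sysdir.mkdir(exist_ok=True)
            try:
                ref = traj.frame(0)
                sup = superpose(traj, ref)
                prof = rmsd_rmsf(sup, ref)
                prof.to_tsv(sysdir / "rmsd.tsv", sysdir / "rmsf.tsv")
                cmat = dcc(sup)
                cmat.to_tsv(sysdir / "dcc.tsv")
                coupling = interdomain_coupling(cmat, list(traj.atoms["domain"]))
                coupling.to_csv(sysdir / "interdomain.tsv", sep="\t", index=False)
                modes = essential_dynamics(sup, k=min(5, 3 * traj.n_atoms))
                field_ = porcupine(modes, cutoff=float(p.get("porcupine_cutoff", 3.5)))
                field_.to_tsv(sysdir / "porcupine.tsv")
                net = build_network(
                    sup,
                    cmat,
                    contact_cutoff=float(p.get("contact_cutoff", 8.0)),
                    occupancy_min=float(p.get("occupancy_min", 0.75)),
                    corr_min=float(p.get("corr_min", 0.01)),
                )
                net.to_tsv(sysdir / "network.tsv")
                part = detect_communities(net)
                (sysdir / "communities.json").write_text(
                    json.dumps(
                        {
                            "n_communities": part.n_communities,
                            "modularity": part.modularity,
                            "membership": {f"{c}{r}": cid for (c, r), cid in part.membership.items()},
                        },
                        indent=2,
                        sort_keys=True,
                    )
                )
                sources = [node for node, dom in zip(traj.residues, traj.atoms["domain"]) if dom == "DBD"]
                sinks = [node for node, dom in zip(traj.residues, traj.atoms["domain"]) if dom == "EO"]
                ens = suboptimal_paths(
                    net,
                    PathQuery(sources, sinks, delta=p.get("delta"), max_paths=int(p.get("max_paths", 100_000))),
                )
                ens.to_tsv(sysdir / "paths.tsv")
                ensembles[(variant, state)] = ens
                if p.get("write_pdb", False):
                    write_pdb(sup, sysdir / "trajectory.pdb")
                outputs.extend(sorted(sysdir.iterdir()))
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"analyse[{variant}/{state}]", str(exc)) from exc
    try:
        comparison = path_statistics(ensembles)
        comp_path = out_dir / "path_comparison.json"
        comp_path.write_text(json.dumps(comparison.to_json(), indent=2, sort_keys=True))
        comparison.table.to_csv(out_dir / "path_comparison.tsv", sep="\t", index=False)
        outputs += [comp_path, out_dir / "path_comparison.tsv"]
    except ValueError:
        pass  # single-system runs have nothing to compare
    return outputs


def _run_scan(config: RunConfig, out_dir: Path) -> list[Path]:
    p = config.params
    domain_map = DEFAULT_DOMAIN_MAP
    if "domains" in p:
        domain_map = DomainMap(tuple(tuple(s) for s in p["domains"]))
    if "panel_fasta" in p:
        panel_path = Path(p["panel_fasta"])
        ref_path = Path(p.get("reference_fasta", ""))
        if not panel_path.exists():
            raise PipelineError("scan", f"missing input path: {panel_path}")
        if not ref_path.exists():
            raise PipelineError("scan", f"missing input path: {ref_path}")
        panel = read_fasta(panel_path)
        reference = read_fasta(ref_path)[0][1]
    else:
        spec = PanelSpec.default_dgor_panel(seed=config.seed)
        result = generate_sequence_panel(spec)
        result.write_fasta(out_dir / "panel.fasta", out_dir / "reference.fasta")
        result.write_truth(out_dir / "panel_truth.json")
        panel, reference = result.records, result.reference
    report = tabulate_panel(panel, reference, domain_map)
    report.to_tsv(out_dir / "variants.tsv")
    report.to_json(out_dir / "variants.json")
    return [q for q in out_dir.iterdir() if q.is_file() and q.name != "manifest.json"]


def _run_curves(config: RunConfig, out_dir: Path) -> list[Path]:
    import pandas as pd

    p = config.params
    fits = []
    for entry in p.get("curves", []):
        path = Path(entry["csv"])
        if not path.exists():
            raise PipelineError("curves", f"missing input path: {path}")
        df = pd.read_csv(path)
        model = entry.get("model", "hill")
        if model == "growth":
            res = GrowthCurveModel(df["x"].to_numpy(), df["y"].to_numpy()).fit()
            fits.append({"csv": str(path), "model": model, "doubling_time": res.doubling_time,
                         "growth_rate": res.growth_rate, "lag_time": res.lag_time,
                         "r_squared": res.r_squared, "degenerate": res.degenerate})
        else:
            curve = CurveData.from_dataframe(df)
            res = BindingModel(curve, model=model, protein_total=entry.get("protein_total")).fit()
            fits.append({"csv": str(path), "model": model, **res.params,
                         "se": res.bse, "converged": res.converged})
    out = out_dir / "fits.json"
    out.write_text(json.dumps(fits, indent=2, sort_keys=True))
    return [out]
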