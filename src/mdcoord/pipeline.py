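"""Run-configuration handling and the end-to-end comparative pipeline.

A run configuration (YAML) names one or more systems — each a topology PDB,
a list of replica trajectories, domain definitions and tagged atoms — plus
analysis parameters, an output directory and a global seed.  The pipeline
validates every path and selection before any compute (fail-fast), runs the
per-system analyses (distance fluctuations, RMSF, essential dynamics,
generalized correlations, descriptors, stacking, contacts, clustering,
GNM), writes CSV/TSV/JSON outputs plus cross-system DF difference matrices,
and emits a JSON manifest (parameters, file digests, versions) from which
the run can be reconstructed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core import (DomainDefinition, Selection, StructureModel, Trajectory,
                   read_structure, read_trajectory, resolve_selection,
                   superpose_trajectory)
from .clustering import gromos_cluster
from .distfluct import df_matrix, rmsf_profile
from .essdyn import fit_pca, project_trajectory, split_half_diagnostics
from .geometry import (hbond_saltbridge_occupancy, histogram_series,
                       interdomain_torsion_series, pair_distance_series,
                       radius_of_gyration, stacking_series)
from .gnm import collectivity_sensitivity, gnm_modes, slow_mode_mobility_fraction
from .mutinfo import generalized_correlation_matrix

logger = logging.getLogger("mdcoord")

__all__ = ["SystemConfig", "RunConfig", "load_config", "run_pipeline",
           "ALL_STAGES"]

ALL_STAGES = ("df", "rmsf", "ed", "lmi", "geom", "stack", "contacts",
              "cluster", "gnm")


@dataclass
class SystemConfig:
    name: str
    topology: Path
    trajectories: list[Path]
    domains: list[DomainDefinition] = field(default_factory=list)
    ca_selection: str = "name CA"
    pair_distances: list[dict] = field(default_factory=list)
    aromatic_pairs: list[dict] = field(default_factory=list)
    hbond_pairs: list[tuple] = field(default_factory=list)
    interface: tuple[str, str] | None = None
    torsion_domains: tuple[str, str] | None = None
    cluster_region: DomainDefinition | None = None


@dataclass
class RunConfig:
    systems: list[SystemConfig]
    output: Path
    seed: int = 0
    reference_system: str | None = None
    params: dict = field(default_factory=dict)

    def get_param(self, stage: str, key: str, default):
        return self.params.get(stage, {}).get(key, default)


def _domain_from_dict(d: dict) -> DomainDefinition:
    return DomainDefinition(d["name"], str(d["chain"]),
                            tuple((int(a), int(b)) for a, b in d["intervals"]))


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; relative paths are resolved against
    the config file's directory."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    base = path.parent

    def _p(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    systems = []
    for name, sc in raw.get("systems", {}).items():
        cluster_region = sc.get("cluster_region")
        systems.append(SystemConfig(
            name=name,
            topology=_p(sc["topology"]),
            trajectories=[_p(t) for t in sc.get("trajectories", [])],
            domains=[_domain_from_dict(d) for d in sc.get("domains", [])],
            ca_selection=sc.get("ca_selection", "name CA"),
            pair_distances=sc.get("pair_distances", []),
            aromatic_pairs=sc.get("aromatic_pairs", []),
            hbond_pairs=[tuple(p) for p in sc.get("hbond_pairs", [])],
            interface=tuple(sc["interface"]) if sc.get("interface") else None,
            torsion_domains=(tuple(sc["torsion_domains"])
                             if sc.get("torsion_domains") else None),
            cluster_region=(_domain_from_dict(cluster_region)
                            if cluster_region else None)))
    if not systems:
        raise ValueError("config defines no systems")
    return RunConfig(systems=systems,
                     output=_p(raw.get("output", "results")),
                     seed=int(raw.get("seed", 0)),
                     reference_system=raw.get("reference_system"),
                     params=raw.get("analysis", {}))


# --------------------------------------------------------------------------
# Validation and loading
# --------------------------------------------------------------------------

def _validate(config: RunConfig) -> None:
    errors = []
    for sys_cfg in config.systems:
        if not sys_cfg.topology.exists():
            errors.append(f"{sys_cfg.name}: topology {sys_cfg.topology} missing")
        for t in sys_cfg.trajectories:
            if not t.exists():
                errors.append(f"{sys_cfg.name}: trajectory {t} missing")
        if not sys_cfg.trajectories:
            errors.append(f"{sys_cfg.name}: no trajectories")
    if config.reference_system is not None:
        if config.reference_system not in [s.name for s in config.systems]:
            errors.append(f"reference system '{config.reference_system}' "
                          f"not among systems")
    if errors:
        raise ValueError("configuration invalid:\n  " + "\n  ".join(errors))


def _load_system(sys_cfg: SystemConfig):
    structure = read_structure(sys_cfg.topology)
    ca = resolve_selection(structure, sys_cfg.ca_selection)
    trajs = [read_trajectory(structure, t, replica=f"replica-{i + 1}")
             for i, t in enumerate(sys_cfg.trajectories)]
    # selections referenced by analyses must resolve before compute starts
    for dom in sys_cfg.domains:
        resolve_selection(structure, dom)
    return structure, ca, trajs


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def _stage_df(out, cfg, sys_cfg, structure, ca, fitted):
    dfm = df_matrix(fitted, ca)
    dfm.write_tsv(out / f"{sys_cfg.name}_df.tsv")
    dfm.to_long().to_csv(out / f"{sys_cfg.name}_df_long.csv", index=False)
    return dfm


def _stage_rmsf(out, cfg, sys_cfg, structure, ca, fitted):
    prof = rmsf_profile(fitted, ca, structure)
    prof.to_frame().to_csv(out / f"{sys_cfg.name}_rmsf.csv", index=False)
    return prof


def _stage_ed(out, cfg, sys_cfg, structure, ca, fitted):
    n_modes = int(cfg.get_param("ed", "n_modes", 2))
    ed = fit_pca(fitted, ca, structure)
    proj = project_trajectory(fitted, ed, modes=list(range(n_modes)))
    np.savetxt(out / f"{sys_cfg.name}_ed_eigenvalues.csv",
               ed.eigenvalues[:50], delimiter=",",
               header="eigenvalue_A2", comments="")
    import pandas as pd
    pd.DataFrame(proj, columns=[f"mode{k + 1}" for k in range(n_modes)]) \
        .to_csv(out / f"{sys_cfg.name}_ed_projections.csv", index=False)
    diag = split_half_diagnostics(fitted, ca, n_modes=n_modes)
    (out / f"{sys_cfg.name}_ed_diagnostics.json").write_text(json.dumps({
        "split_half_overlap": diag.split_half_overlap,
        "cosine_contents": diag.cosine_contents.tolist(),
        "variance_fractions": ed.variance_fractions[:n_modes].tolist()},
        indent=2))
    return ed


def _stage_lmi(out, cfg, sys_cfg, structure, ca, fitted):
    k = int(cfg.get_param("lmi", "k", 6))
    stride = cfg.get_param("lmi", "stride", None)
    max_frames = int(cfg.get_param("lmi", "max_frames", 500))
    lmi = generalized_correlation_matrix(fitted, ca, k=k, stride=stride,
                                         max_frames=max_frames)
    lmi.write_tsv(out / f"{sys_cfg.name}_lmi.tsv")
    return lmi


def _stage_geom(out, cfg, sys_cfg, structure, ca, fitted):
    results = {}
    for traj in fitted:
        rg = radius_of_gyration(traj, ca)
        results.setdefault("rg", []).append(rg)
        histogram_series(rg).to_csv(
            out / f"{sys_cfg.name}_{traj.replica}_rg_hist.csv", index=False)
        for pd_spec in sys_cfg.pair_distances:
            series = pair_distance_series(traj, pd_spec["a"], pd_spec["b"])
            name = pd_spec.get("name", series.name)
            series.to_frame().to_csv(
                out / f"{sys_cfg.name}_{traj.replica}_{name}.csv", index=False)
            results.setdefault(name, []).append(series)
        if sys_cfg.torsion_domains:
            doms = {d.name: d for d in sys_cfg.domains}
            da = resolve_selection(structure, doms[sys_cfg.torsion_domains[0]],
                                   atom_filter="CA")
            db = resolve_selection(structure, doms[sys_cfg.torsion_domains[1]],
                                   atom_filter="CA")
            tor = interdomain_torsion_series(traj, da, db)
            tor.to_frame().to_csv(
                out / f"{sys_cfg.name}_{traj.replica}_torsion.csv", index=False)
            results.setdefault("torsion", []).append(tor)
    return results


def _stage_stack(out, cfg, sys_cfg, structure, ca, fitted):
    results = []
    for traj in fitted:
        for pair in sys_cfg.aromatic_pairs:
            res_a = (str(pair["a"][0]), int(pair["a"][1]))
            res_b = (str(pair["b"][0]), int(pair["b"][1]))
            sg = stacking_series(traj, res_a, res_b)
            sg.to_frame().to_csv(
                out / f"{sys_cfg.name}_{traj.replica}_stack_"
                      f"{sg.pair[0].replace(':', '')}_"
                      f"{sg.pair[1].replace(':', '')}.csv", index=False)
            results.append(sg)
    return results


def _stage_contacts(out, cfg, sys_cfg, structure, ca, fitted):
    interface = None
    if sys_cfg.interface:
        interface = (resolve_selection(structure, sys_cfg.interface[0]),
                     resolve_selection(structure, sys_cfg.interface[1]))
    if not sys_cfg.hbond_pairs and interface is None:
        return []
    contacts = hbond_saltbridge_occupancy(
        fitted, hbond_pairs=sys_cfg.hbond_pairs or None, interface=interface,
        min_occupancy=float(cfg.get_param("contacts", "min_occupancy", 1.0)))
    import pandas as pd
    pd.DataFrame([{"donor": c.donor, "acceptor": c.acceptor, "kind": c.kind,
                   "occupancy_pct": c.occupancy} for c in contacts]) \
        .to_csv(out / f"{sys_cfg.name}_contacts.tsv", sep="\t", index=False)
    return contacts


def _stage_cluster(out, cfg, sys_cfg, structure, ca, fitted):
    region = sys_cfg.cluster_region
    if region is None:
        sel = ca
    else:
        sel = resolve_selection(structure, region)
    cutoff = float(cfg.get_param("cluster", "cutoff_A", 2.0))
    stride = cfg.get_param("cluster", "stride", None)
    results = []
    for traj in fitted:
        cr = gromos_cluster(traj, sel, cutoff=cutoff, stride=stride)
        cr.to_frame().to_csv(
            out / f"{sys_cfg.name}_{traj.replica}_clusters.csv", index=False)
        (out / f"{sys_cfg.name}_{traj.replica}_clusters.json").write_text(
            cr.summary().to_json(orient="records"))
        results.append(cr)
    return results


def _stage_gnm(out, cfg, sys_cfg, structure, ca, fitted):
    cutoff = float(cfg.get_param("gnm", "cutoff_A", 10.0))
    res = gnm_modes(structure, ca, cutoff=cutoff)
    table = res.mode_table(n_modes=10)
    table["mobility_fraction_2_slowest"] = slow_mode_mobility_fraction(res, 2)
    table.to_csv(out / f"{sys_cfg.name}_gnm_modes.csv", index=False)
    collectivity_sensitivity(structure, ca).to_csv(
        out / f"{sys_cfg.name}_gnm_cutoff_sensitivity.csv", index=False)
    return res


_STAGE_FUNCS = {"df": _stage_df, "rmsf": _stage_rmsf, "ed": _stage_ed,
                "lmi": _stage_lmi, "geom": _stage_geom, "stack": _stage_stack,
                "contacts": _stage_contacts, "cluster": _stage_cluster,
                "gnm": _stage_gnm}


# --------------------------------------------------------------------------
# Driver
# --------------------------------------------------------------------------

def run_pipeline(config: RunConfig,
                 stages: tuple[str, ...] = ALL_STAGES) -> dict:
    """Validate, run the requested stages per system, write outputs and the
    manifest.  Any stage failure aborts with the stage name; outputs from
    completed stages are retained and flagged in the manifest."""
    _validate(config)
    out = Path(config.output)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed,
                "parameters": config.params, "systems": {}, "stages": {},
                "inputs": {}}
    results: dict = {}
    df_by_system = {}
    for sys_cfg in config.systems:
        logger.info("loading system %s", sys_cfg.name)
        structure, ca, trajs = _load_system(sys_cfg)
        manifest["inputs"][sys_cfg.name] = {
            "topology": str(sys_cfg.topology),
            "topology_sha256": _sha256(sys_cfg.topology),
            "trajectories": {str(t): _sha256(t)
                             for t in sys_cfg.trajectories}}
        fitted = [superpose_trajectory(t, structure, ca) for t in trajs]
        sys_results = {}
        for stage in stages:
            logger.info("system %s: stage %s", sys_cfg.name, stage)
            try:
                sys_results[stage] = _STAGE_FUNCS[stage](
                    out, config, sys_cfg, structure, ca, fitted)
                manifest["stages"].setdefault(stage, {})[sys_cfg.name] = "ok"
            except Exception as exc:
                manifest["stages"].setdefault(stage, {})[sys_cfg.name] = \
                    f"failed: {exc}"
                (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
                raise RuntimeError(
                    f"stage '{stage}' failed for system '{sys_cfg.name}': "
                    f"{exc}") from exc
        results[sys_cfg.name] = sys_results
        if "df" in sys_results:
            df_by_system[sys_cfg.name] = sys_results["df"]
        manifest["systems"][sys_cfg.name] = {
            "n_replicas": len(trajs),
            "n_frames": [t.n_frames for t in trajs],
            "n_atoms": structure.n_atoms, "n_ca": len(ca)}
    # cross-system DF difference matrices where selections are commensurate
    names = list(df_by_system)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            A, B = df_by_system[a], df_by_system[b]
            if A.matrix.shape == B.matrix.shape:
                np.savetxt(out / f"delta_df_{a}_vs_{b}.tsv",
                           A.matrix - B.matrix, delimiter="\t")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results
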