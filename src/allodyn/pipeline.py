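"""Configuration-driven orchestration of the comparative workflow.

A study is a set of ligand states, each with replica trajectories over a
shared topology.  ``run_study`` aligns each replica on the Cα atoms of its
starting conformation, filters it through the top principal components,
computes replica-averaged distance-fluctuation matrices with rigidity
maps, strain-based mobility profiles, significance-filtered state
difference histograms, persistent H-bond networks from the ligand toward
the target segment, and GROMOS clusters — writing every artifact as
tab-delimited text under a run directory with a JSON manifest at its root.

All numeric defaults are the analysis constants used throughout the
package (10 components, 0.3 Å² rigidity, d0 = 7 Å, 30% persistence,
5 Å / 2 Å cluster cutoffs, 0.4 / 2 Å² flexibility bands).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import cluster as _cluster
from . import fluctuation as _fluct
from . import hbond as _hbond
from . import strain as _strain
from .core import Ensemble, Selection, select, write_matrix, ResidueMatrix
from .ed import align, filter_trajectory, fit_ed
from .io import read_ensemble

__all__ = ["StudyConfig", "StudyReport", "run_study", "compare_states"]

log = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Declarative description of a comparative study."""

    topology: str
    states: dict                     # label -> list of trajectory paths
    selection: str = "CA"
    fit_selection: str = "CA"
    ligand: str | None = None        # selection expression; None = auto-detect
    target_range: tuple | None = None
    site_residues: str | None = None
    n_components: int = 10
    rigidity_threshold: float = _fluct.RIGIDITY_THRESHOLD
    d0: float = 7.0
    width: float = 0.5
    persistence_threshold: float = _hbond.PERSISTENCE_THRESHOLD
    cluster_cutoff: float = _cluster.DOMAIN_CUTOFF
    site_cutoff: float = _cluster.SITE_CUTOFF
    flex_low: float = _strain.FLEX_LOW
    flex_high: float = _strain.FLEX_HIGH
    error_multiplier: float = 1.0
    unit_hint: str | None = None
    max_network_depth: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        """Load a config; relative paths resolve against the YAML's directory."""
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "target_range" in raw and raw["target_range"] is not None:
            raw["target_range"] = tuple(raw["target_range"])
        base = Path(path).resolve().parent
        raw["topology"] = str((base / raw["topology"])) if not Path(raw["topology"]).is_absolute() else raw["topology"]
        raw["states"] = {s: [str(base / p) if not Path(p).is_absolute() else p for p in ps]
                         for s, ps in raw["states"].items()}
        return cls(**raw)

    def validate(self) -> None:
        if not self.states:
            raise ValueError("config declares no states")
        if not Path(self.topology).exists():
            raise FileNotFoundError(f"topology not found: {self.topology}")
        for label, paths in self.states.items():
            if not paths:
                raise ValueError(f"state {label!r} has no replica trajectories")
            for p in paths:
                if not Path(p).exists():
                    raise FileNotFoundError(f"state {label!r}: replica file not found: {p}")


@dataclass
class StudyReport:
    config: StudyConfig
    outdir: Path
    fluctuation: dict = field(default_factory=dict)   # state -> FluctuationMatrix (averaged)
    rigidity: dict = field(default_factory=dict)      # state -> ResidueMatrix
    mobility: dict = field(default_factory=dict)      # state -> MobilityProfile
    networks: dict = field(default_factory=dict)      # state -> HBondGraph
    clusters: dict = field(default_factory=dict)      # state -> ClusterSet
    differences: dict = field(default_factory=dict)   # (a, b) -> MobilityDifference
    manifest: dict = field(default_factory=dict)


def _write_profile(path, mob: "_strain.MobilityProfile") -> None:
    with open(path, "w") as fh:
        fh.write(f"# units: A^2\n# state: {mob.state}\n# replicas: {','.join(mob.replicas)}\n")
        runs = "\t".join(f"run_{r or i + 1}" for i, r in enumerate(mob.replicas))
        fh.write(f"resid\t{runs}\tmean\tse\n")
        se = mob.se
        for i, resid in enumerate(mob.resids):
            vals = "\t".join(f"{v:.10g}" for v in mob.per_run[:, i])
            fh.write(f"{resid}\t{vals}\t{mob.mean[i]:.10g}\t{se[i]:.10g}\n")


def _write_difference(path, diff: "_strain.MobilityDifference") -> None:
    with open(path, "w") as fh:
        fh.write(f"# units: A^2\n# states: {diff.states[0]} - {diff.states[1]}\n"
                 f"# error_multiplier: {diff.k}\n")
        fh.write("resid\tdelta\terror\tretained\tfiltered\n")
        filt = diff.filtered
        for i, resid in enumerate(diff.resids):
            fh.write(f"{resid}\t{diff.delta[i]:.10g}\t{diff.error[i]:.10g}\t"
                     f"{int(not diff.mask[i])}\t{filt[i]:.10g}\n")


def _write_clusters(path, cs: "_cluster.ClusterSet") -> None:
    with open(path, "w") as fh:
        fh.write(f"# cutoff_A: {cs.cutoff}\n# selection: {cs.selection}\n"
                 f"# tie_break: earliest frame index\n")
        fh.write("frame\tcluster\n")
        for f, c in enumerate(cs.assignments):
            fh.write(f"{f}\t{c}\n")
        fh.write("# cluster\tcenter_frame\tpopulation\n")
        for c, (ctr, pop) in enumerate(zip(cs.centers, cs.populations)):
            fh.write(f"# {c}\t{ctr}\t{pop:.6f}\n")


def _write_network(path_tsv, path_gml, net: "_hbond.HBondGraph", topology) -> None:
    with open(path_tsv, "w") as fh:
        fh.write(f"# persistence_threshold: {net.threshold}\n"
                 f"# target_range: {net.target_range}\n"
                 f"# target_reached: {net.target_reached}\n"
                 f"# target_depth: {net.target_depth}\n")
        fh.write("residue_a\tresidue_b\tpersistence\tlevel\tper_replica\n")
        for row in net.edge_table(topology):
            reps = ",".join(f"{x:.4f}" for x in row["per_replica"])
            fh.write(f"{row['residue_a']}\t{row['residue_b']}\t"
                     f"{row['persistence']:.6f}\t{row['level']}\t{reps}\n")
    import networkx as nx
    g = net.graph.copy()
    for _, _, d in g.edges(data=True):
        d["per_replica"] = ",".join(f"{x:.4f}" for x in d.get("per_replica", []))
    nx.write_gml(g, path_gml)


def _concatenate(ensembles: list[Ensemble]) -> Ensemble:
    coords = np.concatenate([e.coords for e in ensembles], axis=0)
    return Ensemble(topology=ensembles[0].topology, coords=coords,
                    state=ensembles[0].state, replica="concat")


def run_study(config: StudyConfig, outdir) -> StudyReport:
    """Execute the full comparative workflow and write the artifact bundle."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = StudyReport(config=config, outdir=outdir)
    manifest: dict = {"parameters": {k: (list(v) if isinstance(v, tuple) else v)
                                     for k, v in asdict(config).items() if k != "states"},
                      "states": {s: list(map(str, ps)) for s, ps in config.states.items()},
                      "artifacts": {}}

    def record(name: str, path: Path, **params) -> None:
        manifest["artifacts"][name] = {"path": str(path.relative_to(outdir)), **params}

    params = _strain.StrainParams(d0=config.d0, w=config.width)
    for state, paths in config.states.items():
        log.info("state %s: %d replica(s)", state, len(paths))
        raw, aligned, filtered, strains, flucts = [], [], [], [], []
        for i, p in enumerate(paths):
            ens = read_ensemble(config.topology, p, unit_hint=config.unit_hint,
                                state=state, replica=str(i + 1))
            sel = select(ens.topology, config.selection)
            fit_sel = select(ens.topology, config.fit_selection)
            al = align(ens, fit_sel)
            model = fit_ed(al, sel, n_components=config.n_components)
            fl = filter_trajectory(al, model, sel, k=min(config.n_components,
                                                         model.eigenvalues.size))
            raw.append(ens)
            aligned.append(al)
            filtered.append(fl)
            flucts.append(_fluct.distance_fluctuations(fl, sel,
                                                       n_components=config.n_components))
            strains.append(_strain.geometric_strain(al, sel, params))

        avg = _fluct.average_over_replicas(flucts)
        report.fluctuation[state] = avg
        p_fluct = outdir / f"fluctuations_{state}.tsv"
        write_matrix(avg.matrix, p_fluct)
        record(f"fluctuations_{state}", p_fluct, n_components=config.n_components)

        rmap = _fluct.rigidity_map(avg, threshold=config.rigidity_threshold)
        report.rigidity[state] = rmap
        p_rig = outdir / f"rigidity_{state}.tsv"
        write_matrix(rmap, p_rig)
        record(f"rigidity_{state}", p_rig, threshold_A2=config.rigidity_threshold)

        mob = _strain.mobility(strains)
        report.mobility[state] = mob
        p_mob = outdir / f"mobility_{state}.tsv"
        _write_profile(p_mob, mob)
        record(f"mobility_{state}", p_mob, d0_A=config.d0, width_A=config.width)

        ligand = None
        if config.ligand:
            ligand = select(raw[0].topology, config.ligand)
        elif raw[0].topology.ligand is not None:
            ligand = raw[0].topology.ligand
        if ligand is not None:
            net = _hbond.propagate_network(raw, ligand, target_range=config.target_range,
                                           threshold=config.persistence_threshold,
                                           max_depth=config.max_network_depth)
            report.networks[state] = net
            p_net = outdir / f"network_{state}.tsv"
            p_gml = outdir / f"network_{state}.gml"
            _write_network(p_net, p_gml, net, raw[0].topology)
            record(f"network_{state}", p_net, threshold=config.persistence_threshold,
                   target_reached=net.target_reached)
            record(f"network_{state}_gml", p_gml)
        else:
            log.info("state %s: no ligand declared or detected; network skipped", state)

        concat = _concatenate(aligned)
        sel = select(concat.topology, config.selection)
        cs = _cluster.gromos_cluster(concat, sel, cutoff=config.cluster_cutoff)
        report.clusters[state] = cs
        p_cl = outdir / f"clusters_{state}.tsv"
        _write_clusters(p_cl, cs)
        record(f"clusters_{state}", p_cl, cutoff_A=config.cluster_cutoff)
        if config.site_residues:
            cs_site = _cluster.binding_site_cluster(concat, config.site_residues,
                                                    cutoff=config.site_cutoff)
            p_site = outdir / f"clusters_site_{state}.tsv"
            _write_clusters(p_site, cs_site)
            record(f"clusters_site_{state}", p_site, cutoff_A=config.site_cutoff,
                   site=config.site_residues)

    labels = list(config.states)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            diff = _strain.mobility_difference(report.mobility[a], report.mobility[b],
                                               k=config.error_multiplier)
            report.differences[(a, b)] = diff
            p_diff = outdir / f"mobility_diff_{a}_vs_{b}.tsv"
            _write_difference(p_diff, diff)
            record(f"mobility_diff_{a}_vs_{b}", p_diff, k=config.error_multiplier)

    report.manifest = manifest
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return report


def compare_states(report: StudyReport, state_a: str, state_b: str,
                   k: float | None = None):
    """Mobility difference plus the rigidity-classification flip set.

    Returns (MobilityDifference, flips) where flips is the set of residue
    pairs whose rigid/mobile classification differs between the two
    states' rigidity maps; the set is symmetric in the arguments.
    """
    for s in (state_a, state_b):
        if s not in report.mobility:
            raise KeyError(f"state {s!r} not in report")
    diff = _strain.mobility_difference(report.mobility[state_a], report.mobility[state_b],
                                       k=report.config.error_multiplier if k is None else k)
    ra, rb = report.rigidity[state_a], report.rigidity[state_b]
    flips = set()
    n = ra.values.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if ra.values[i, j] != rb.values[i, j]:
                flips.add((int(ra.resids[i]), int(ra.resids[j])))
    return diff, flips
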