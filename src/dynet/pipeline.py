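"""End-to-end pipeline: coordinates -> correlation network -> communities
-> regulation pathways -> perturbation -> report.

``run_pipeline`` executes one system (one :class:`~dynet.config.RunConfig`)
and returns a :class:`ReportBundle`; ``compare_systems`` lines several
bundles up against a declared reference system and scores each one's
efficiency of information transfer.  All randomness flows from the
single config seed, so equal configs produce identical reports.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import analysis, corrnet, interactions as inter, structure, synth
from .config import RunConfig


@dataclass
class ReportBundle:
    """Everything one pipeline run produced, JSON-serializable."""

    label: str
    config_hash: str
    seed: int
    n_replicates: int
    summary: dict
    communities: dict
    paths: dict                      # source label -> path/SPL record
    weakened: dict | None = None
    interactions: list = field(default_factory=list)
    networks: list = field(default_factory=list)       # per-replicate nets
    consensus: "corrnet.CorrelationNetwork | None" = None
    sink_labels: list = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "label": self.label,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "n_replicates": self.n_replicates,
            "sink": self.sink_labels,
            "summary": self.summary,
            "communities": self.communities,
            "paths": self.paths,
            "weakened": self.weakened,
            "interactions": self.interactions,
        }

    @property
    def spl_sum(self) -> float:
        """Sum over sources of the replicate-mean SPLs."""
        return float(sum(p["spl_mean"] for p in self.paths.values()))

    def write(self, out_dir: "str | Path") -> dict[str, Path]:
        """Write the machine report (JSON), a human summary (Markdown),
        the consensus edge table (TSV), community assignments (TSV) and
        the consensus network (GraphML)."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["report"] = out_dir / "report.json"
        paths["report"].write_text(
            json.dumps(self.to_json_dict(), indent=1, sort_keys=True) + "\n"
        )
        paths["markdown"] = out_dir / "report.md"
        paths["markdown"].write_text(self._markdown())
        if self.consensus is not None:
            paths["edges"] = out_dir / "edges.tsv"
            self.consensus.edge_table().to_csv(paths["edges"], sep="\t", index=False)
            paths["graphml"] = out_dir / "network.graphml"
            self.consensus.write_graphml(paths["graphml"])
            rows = [
                {
                    "node": self.consensus.label(i),
                    "community": self.communities["membership"][str(i)],
                }
                for i in sorted(self.consensus.graph.nodes)
            ]
            paths["communities"] = out_dir / "communities.tsv"
            pd.DataFrame(rows).to_csv(paths["communities"], sep="\t", index=False)
        return paths

    def _markdown(self) -> str:
        s = self.summary
        lines = [
            f"# {self.label}",
            "",
            f"seed {self.seed}, config {self.config_hash}, "
            f"{self.n_replicates} replicate(s)",
            "",
            "## Network parameters",
            "",
            "| parameter | value |",
            "|---|---|",
        ]
        lines += [f"| {k} | {v} |" for k, v in s.items()]
        lines += [
            "",
            "## Communities",
            "",
            f"{self.communities['n_communities']} communities, "
            f"{self.communities['n_isolated']} isolated cluster(s), "
            f"modularity {self.communities['modularity']:.3f}",
            "",
            "## Regulation pathways",
            "",
            "| source | pathway | nodes | SPL |",
            "|---|---|---|---|",
        ]
        for src, rec in self.paths.items():
            spl = (
                f"{rec['spl_mean']:.2f} ± {rec['spl_sd']:.2f}"
                if math.isfinite(rec["spl_mean"])
                else "unreachable"
            )
            lines.append(
                f"| {src} | {rec['consensus_path'] or '—'} | "
                f"{rec['n_intermediate'] if rec['n_intermediate'] is not None else '—'} | {spl} |"
            )
        if self.weakened is not None:
            lines += [
                "",
                "## After weakening " + ", ".join(self.weakened["ligands"]),
                "",
                f"{self.weakened['n_communities']} communities, "
                f"{self.weakened['n_isolated']} isolated cluster(s); "
                f"edges {self.weakened['n_edges']} (was {s['edges']})",
            ]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _load_trajectories(config: RunConfig):
    if config.synthetic is not None:
        kwargs = dict(config.synthetic)
        kwargs.setdefault("seed", config.seed)
        spec = synth.PlantedSpec(**kwargs)
        geometry = synth.build_geometry(spec)
        trajs = synth.sample_trajectory(spec, geometry)
        return trajs, geometry.node_map, spec
    node_map = structure.read_topology(config.topology)
    window = tuple(config.window) if isinstance(config.window, list) else config.window
    trajs = structure.read_trajectory(
        config.trajectories,
        node_map,
        topology=config.topology,
        stride=config.stride,
        window=window,
    )
    return trajs, node_map, None


def run_pipeline(config: RunConfig) -> ReportBundle:
    trajs, node_map, spec = _load_trajectories(config)
    do_fit = config.superpose is True or (
        config.superpose == "auto" and config.synthetic is None
    )
    if do_fit:
        trajs = [structure.superpose(t) for t in trajs]

    thr = config.thresholds
    nets = []
    for traj in trajs:
        corr = corrnet.correlation_matrix(traj)
        occ = corrnet.contact_occupancy(traj, cutoff=thr.contact_cutoff)
        nets.append(
            corrnet.build_network(corr, occ, node_map, occ_threshold=thr.occupancy)
        )
    consensus = corrnet.consensus_network(nets) if len(nets) > 1 else nets[0]

    summary = corrnet.network_summary(consensus, degree_cutoff=thr.degree_report)
    partition = analysis.girvan_newman(consensus)

    sources = list(config.sources)
    sinks = list(config.sinks)
    if spec is not None and not sources and spec.pathway:
        sources = [node_map.nodes[spec.source].label]
    if spec is not None and not sinks and spec.pathway:
        sinks = [node_map.nodes[spec.sink].label]

    paths: dict[str, dict] = {}
    for src in sources:
        summ = analysis.average_spl(nets, src, sinks, consensus=consensus)
        cpath = summ.consensus_path
        paths[src] = {
            "spl_mean": summ.mean,
            "spl_sd": summ.sd,
            "replicate_spls": summ.lengths,
            "consensus_path": "-".join(cpath.labels) if cpath and cpath.reachable else None,
            "n_intermediate": cpath.n_intermediate if cpath and cpath.reachable else None,
        }

    weakened = None
    if config.weaken:
        weak_net = analysis.weaken_ligand(consensus, config.weaken)
        weak_part = analysis.girvan_newman(weak_net)
        weakened = {
            "ligands": list(config.weaken),
            "n_edges": weak_net.n_edges,
            "n_communities": weak_part.n_communities,
            "n_isolated": weak_part.n_isolated,
            "paths": {
                src: analysis.shortest_path(weak_net, src, sinks).total_length
                if sinks
                else None
                for src in sources
            },
        }

    records = []
    if config.interactions:
        pooled = trajs[0]
        if len(trajs) > 1:
            import numpy as np

            pooled = trajs[0].with_coords(
                np.concatenate([t.coords for t in trajs], axis=0)
            )
        recs = inter.all_interactions(pooled)
        records = [
            {
                "pair": f"{r.label_i}|{r.label_j}",
                "type": r.kind,
                "population": round(r.population, 6),
                "mean_distance": round(r.mean_distance, 4),
            }
            for r in inter.filter_strong(recs, thr.population)
        ]

    return ReportBundle(
        label=config.label,
        config_hash=config.config_hash(),
        seed=config.seed,
        n_replicates=len(trajs),
        summary=summary.as_dict(),
        communities={
            "n_communities": partition.n_communities,
            "n_isolated": partition.n_isolated,
            "modularity": partition.modularity,
            "membership": {str(k): v for k, v in sorted(partition.membership.items())},
        },
        paths=paths,
        weakened=weakened,
        interactions=records,
        networks=nets,
        consensus=consensus,
        sink_labels=sinks,
    )


# ---------------------------------------------------------------------------
# cross-system comparison
# ---------------------------------------------------------------------------

def compare_systems(
    reports: "list[ReportBundle]", reference: str
) -> pd.DataFrame:
    """Side-by-side network parameters and transfer efficiencies.

    All reports must share the sink definition; the declared reference
    system scores 100 % and every system's efficiency is
    ``100 * spl_sum(reference) / spl_sum(system)``.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    by_label = {r.label: r for r in reports}
    if reference not in by_label:
        raise KeyError(f"reference system {reference!r} not among the reports")
    sink0 = reports[0].sink_labels
    if any(r.sink_labels != sink0 for r in reports):
        raise ValueError("reports disagree on the sink definition")
    ref_spls = [p["spl_mean"] for p in by_label[reference].paths.values()]
    rows = []
    for rep in reports:
        sys_spls = [p["spl_mean"] for p in rep.paths.values()]
        eff = analysis.transfer_efficiency(ref_spls, sys_spls)
        rows.append(
            {
                "system": rep.label,
                "nodes": rep.summary["nodes"],
                "edges": rep.summary["edges"],
                "avg_degree": rep.summary["avg_degree"],
                "communities": rep.communities["n_communities"],
                "isolated": rep.communities["n_isolated"],
                "spl_sum": sum(sys_spls),
                "efficiency_pct": eff,
            }
        )
    return pd.DataFrame(rows)
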