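"""File formats and the end-to-end pipeline.

Network definition files are plain-text, tab-separated, with three sections::

    [nodes]
    name    basal   role        # role: input | output | internal
    ...
    [links]
    source  target  weight      # nonzero integer weight
    ...
    [metadata]
    death_readout   CASP3
    version 1

Lines starting with ``#`` are comments.  Exactly one node must carry the
``output`` role and it must agree with the ``death_readout`` metadata entry.

Alteration-profile tables are delimited text with columns ``sample_id``,
``source`` (``cell_line`` or ``patient``) and ``alterations``
(semicolon-separated alteration ids); gene-node maps have columns
``alteration_id``, ``node``, ``status`` (A or I).

:func:`run_pipeline` strings the stages together (map -> sweep -> screen ->
stratify) from a serialisable :class:`RunConfig`, writing delimited artifacts
plus a manifest with the seed, a config hash and per-file checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .model import (
    CONTROL_PROFILE,
    Link,
    NetworkDefinition,
    NetworkSchemaError,
    SimulationConfig,
    StatusProfile,
    Target,
)

__all__ = [
    "load_network",
    "write_network",
    "read_profiles",
    "write_profiles",
    "read_gene_node_map",
    "write_gene_node_map",
    "write_unique_networks",
    "read_unique_networks",
    "RunConfig",
    "run_pipeline",
]

PROFILE_SOURCES = ("cell_line", "patient")


# ---------------------------------------------------------------------------
# network definition files
# ---------------------------------------------------------------------------


def load_network(path: str | Path) -> NetworkDefinition:
    """Parse and validate a network-definition file."""
    path = Path(path)
    section = None
    nodes: list[tuple[str, int, str]] = []
    links: list[Link] = []
    meta: dict[str, str] = {}
    header_skipped = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            header_skipped = False
            if section not in ("nodes", "links", "metadata"):
                raise NetworkSchemaError(f"{path}:{lineno}: unknown section {section!r}")
            continue
        fields = [f.strip() for f in line.split("\t")]
        if section is None:
            raise NetworkSchemaError(f"{path}:{lineno}: content before any section header")
        if not header_skipped and section in ("nodes", "links"):
            # optional column-header row
            if fields[0] in ("name", "source"):
                header_skipped = True
                continue
            header_skipped = True
        try:
            if section == "nodes":
                name, basal, role = fields
                nodes.append((name, int(basal), role))
            elif section == "links":
                src, tgt, weight = fields
                links.append(Link(src, tgt, int(weight)))
            else:
                key, value = fields
                meta[key] = value
        except (ValueError, TypeError) as exc:
            raise NetworkSchemaError(f"{path}:{lineno}: malformed record {line!r}") from exc
    net = NetworkDefinition(tuple(nodes), tuple(links))
    declared = meta.get("death_readout")
    if declared is None:
        raise NetworkSchemaError(f"{path}: metadata must declare a death_readout")
    if declared != net.death_readout:
        raise NetworkSchemaError(
            f"{path}: death_readout {declared!r} does not match the output node "
            f"{net.death_readout!r}"
        )
    return net


def write_network(net: NetworkDefinition, path: str | Path, version: str = "1") -> None:
    lines = ["[nodes]", "name\tbasal\trole"]
    lines += [f"{n}\t{b}\t{r}" for n, b, r in net.nodes]
    lines += ["", "[links]", "source\ttarget\tweight"]
    lines += [f"{lk.source}\t{lk.target}\t{lk.weight}" for lk in net.links]
    lines += ["", "[metadata]", f"death_readout\t{net.death_readout}", f"version\t{version}"]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# delimited tables
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_profiles(path: str | Path):
    """Read an alteration-profile table into AlterationProfile objects."""
    from .genomics import AlterationProfile

    df = _read_table(path, ["sample_id", "source", "alterations"])
    out = []
    for i, row in df.iterrows():
        if row["source"] not in PROFILE_SOURCES:
            raise ValueError(
                f"{path}: line {i + 2}: unknown source tag {row['source']!r}"
            )
        alts = frozenset(a for a in str(row["alterations"]).split(";") if a)
        out.append(AlterationProfile(row["sample_id"], row["source"], alts))
    return out


def write_profiles(profiles, path: str | Path, header: str | None = None) -> None:
    rows = [
        {
            "sample_id": p.sample_id,
            "source": p.source,
            "alterations": ";".join(sorted(p.alterations)),
        }
        for p in profiles
    ]
    _write_table(pd.DataFrame(rows, columns=["sample_id", "source", "alterations"]), path, header)


def read_gene_node_map(path: str | Path):
    from .genomics import GeneNodeMap

    df = _read_table(path, ["alteration_id", "node", "status"])
    entries = {}
    for i, row in df.iterrows():
        if row["status"] not in ("A", "I"):
            raise ValueError(f"{path}: line {i + 2}: status must be A or I")
        entries[row["alteration_id"]] = (row["node"], row["status"])
    return GeneNodeMap(entries)


def write_gene_node_map(gene_map, path: str | Path, header: str | None = None) -> None:
    rows = [
        {"alteration_id": a, "node": n, "status": s}
        for a, (n, s) in sorted(gene_map.entries.items())
    ]
    _write_table(pd.DataFrame(rows, columns=["alteration_id", "node", "status"]), path, header)


def write_unique_networks(networks, path: str | Path, header: str | None = None) -> None:
    rows = [
        {
            "network_id": nw.network_id,
            "statuses": ";".join(f"{n}={s}" for n, s in nw.profile.entries),
            "members": ";".join(nw.members),
        }
        for nw in networks
    ]
    _write_table(
        pd.DataFrame(rows, columns=["network_id", "statuses", "members"]), path, header
    )


def read_unique_networks(path: str | Path):
    from .genomics import UniqueNetwork

    df = _read_table(path, ["network_id", "statuses", "members"])
    out = []
    for _, row in df.iterrows():
        entries = tuple(
            tuple(kv.split("=", 1)) for kv in str(row["statuses"]).split(";") if kv
        )
        out.append(
            UniqueNetwork(
                network_id=row["network_id"],
                profile=StatusProfile(entries),
                members=tuple(m for m in str(row["members"]).split(";") if m),
            )
        )
    return out


def _write_table(df: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Serializable description of a full run; a run is reproducible from it."""

    network_file: str
    profile_table: str
    gene_node_map: str
    out_dir: str
    target_nodes: tuple[str, ...] = ()
    scenario: dict = field(default_factory=lambda: {})  # input node -> 0/1
    seed: int = 0
    n_replicates: int = 1
    transient_steps: int = 100
    steady_steps: int = 100
    basin_cutoff: float = 0.5
    max_networks: int | None = None  # cap screened networks (scaled-down runs)

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            transient_steps=self.transient_steps,
            steady_steps=self.steady_steps,
            input_clamp=dict(self.scenario),
            seed=self.seed,
            n_replicates=self.n_replicates,
        )

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, stage: str = "all") -> dict:
    """Run map / sweep / screen / stratify stages and write artifacts.

    Returns the manifest dict (also written to ``manifest.json``).  Stages
    build on each other; ``all`` runs the full chain.  Every artifact begins
    with a comment header recording the seed and the config hash.
    """
    from . import genomics as _gen
    from .categorize import ThresholdConfig, triangle_map as _triangle_map
    from .dose import dose_sweep, normalize_curve, curve_frame
    from .stratify import stratification_report as _stratification_report

    stages = ("map", "sweep", "screen", "stratify")
    if stage not in stages + ("all",):
        raise ValueError(f"unknown stage {stage!r}")
    wanted = stages if stage == "all" else stages[: stages.index(stage) + 1]

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"seed={config.seed} config_hash={config.config_hash()}"
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    net = load_network(config.network_file)
    profiles = read_profiles(config.profile_table)
    gene_map = read_gene_node_map(config.gene_node_map)
    gene_map.validate_against(net)
    sim = config.simulation_config()
    th = ThresholdConfig()
    targets = tuple(config.target_nodes) or tuple(
        n for n, _, r in net.nodes if r == "internal"
    )[:2]

    # -- map: alteration profiles -> unique networks, basin filter ---------
    pairs = [(p, _gen.alterations_to_status(p, gene_map)) for p in profiles]
    unique = _gen.dedupe_profiles(pairs)
    # basin filter in the unstimulated scenario (all inputs OFF)
    basin_cfg = dataclasses.replace(sim, input_clamp={})
    kept, audit = _gen.filter_by_basin(unique, net, basin_cfg, cutoff=config.basin_cutoff)
    write_unique_networks(unique, out / "unique_networks.tsv", header)
    _write_table(audit, out / "basin_audit.tsv", header)
    manifest["stages"]["map"] = {
        "unique_networks": len(unique),
        "kept_after_basin_filter": len(kept),
    }
    artifacts = ["unique_networks.tsv", "basin_audit.tsv"]
    if "sweep" in wanted:
        # -- sweep: dose-response curves for single-node targets -----------
        frames = []
        screen_nets = kept[: config.max_networks] if config.max_networks else kept
        for nw in screen_nets:
            for node in targets:
                curve = normalize_curve(
                    dose_sweep(net, nw.profile, [Target.of_node(node)], sim)
                )
                df = curve_frame(curve)
                df.insert(0, "network_id", nw.network_id)
                df.insert(1, "target", node)
                frames.append(df)
        sweep_df = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["network_id", "target", "dose", "value"])
        )
        _write_table(sweep_df, out / "dose_response.tsv", header)
        manifest["stages"]["sweep"] = {"curves": len(frames)}
        artifacts.append("dose_response.tsv")
    if "screen" in wanted:
        # -- screen: (S,O) categories per kept network ----------------------
        rows = []
        screen_nets = kept[: config.max_networks] if config.max_networks else kept
        for nw in screen_nets:
            tm = _triangle_map(net, nw.profile, CONTROL_PROFILE, targets, sim, th)
            df = tm.to_frame()
            df.insert(0, "network_id", nw.network_id)
            rows.append(df)
        screen_df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
        _write_table(screen_df, out / "categories.tsv", header)
        manifest["stages"]["screen"] = {"networks": len(rows)}
        artifacts.append("categories.tsv")
    if "stratify" in wanted:
        # -- stratify: determinants + per-sample predictions ----------------
        from .model import Perturbation

        pert = Perturbation.single(Target.of_node(targets[0]))
        result = _stratification_report(
            net, gene_map, profiles, pert, sim, th, subset_cap=8
        )
        _write_table(result.determinant_table, out / "determinants.tsv", header)
        _write_table(result.prediction_table, out / "predictions.tsv", header)
        manifest["stages"]["stratify"] = {
            "determinants": len(result.determinant_table),
            "samples": len(result.prediction_table),
        }
        artifacts += ["determinants.tsv", "predictions.tsv"]

    manifest["artifacts"] = {a: _checksum(out / a) for a in artifacts}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
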