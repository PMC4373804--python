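"""End-to-end orchestration: config, structured logging, CLI.

The pipeline chains simulate -> haplotypes -> network -> metrics -> report;
every stage is also exposed as its own subcommand so external datasets can
enter at any point (an alignment + metadata, a bare incidence matrix, or a
species summary table).  All outputs are UTF-8 tab-separated text with
deterministic (sorted) row order, so re-running an identical config yields
byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import click
import yaml

from . import __version__
from .errors import HapcolError, InputError
from .haplotypes import (DEFAULT_ISLAND_ALIASES, collapse_haplotypes,
                         read_alignment, read_incidence, read_metadata,
                         trim_alignment)
from .metrics import (DEFAULT_RULE, ColonizationRecord, compute_metrics,
                      read_species_table, report_to_markdown, species_report)
from .network import (ancestrality_rank, build_network, classification_frame,
                      write_edgelist, write_graphml)
from .simulate import galapagos_like, simulate_colonization


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run.

    Input can be (exactly one of) a simulator parameter block, an
    alignment+metadata pair, or an incidence matrix; a species summary
    table may be given in addition (or alone, for report-only runs).
    """

    outdir: str = "hapcol-out"
    seed: int = 0
    # inputs (mutually exclusive primary input)
    simulate: dict | None = None  # SimulationParams overrides, or {} preset
    alignment: str | None = None
    metadata: str | None = None
    incidence: str | None = None
    species_table: str | None = None
    # analysis options
    drop_leading: int = 0
    drop_trailing: int = 0
    ambiguity_policy: str = "exclude"
    island_aliases: dict = field(
        default_factory=lambda: dict(DEFAULT_ISLAND_ALIASES))
    max_steps: int | None = None
    rule: str = DEFAULT_RULE
    species: str = "unknown species"
    archipelago: str = ""
    n_archipelago_islands: int | None = None

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise InputError(f"config file not found: {path}")
        data = yaml.safe_load(path.read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def validate_paths(self) -> None:
        for name in ("alignment", "metadata", "incidence", "species_table"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise InputError(f"{name} file not found: {value}")
        primary = [x for x in (self.simulate, self.alignment, self.incidence)
                   if x is not None]
        if len(primary) > 1:
            raise InputError(
                "choose one primary input: simulate, alignment or incidence")
        if self.alignment is not None and self.metadata is None:
            raise InputError("an alignment input requires a metadata table")
        if not primary and self.species_table is None:
            raise InputError("config declares no inputs")


class RunLog:
    """Line-delimited JSON log, one structured record per stage."""

    def __init__(self, path):
        self.path = Path(path)
        self.records = []

    def stage(self, name: str, n_in: int, n_out: int, **extra) -> None:
        rec = {"stage": name, "n_in": n_in, "n_out": n_out, **extra}
        self.records.append(rec)

    def error(self, stage: str, message: str) -> None:
        self.records.append({"stage": stage, "error": message})

    def flush(self) -> None:
        self.path.parent.mkdir(parents=True, exist_ok=True)
        with open(self.path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages the config enables; returns artifact name -> path.

    On any stage error the partial outputs are retained next to a
    ``run.partial`` marker naming the failed stage, and the error is
    re-raised (the CLI maps it to a nonzero exit).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = RunLog(outdir / "run.log")
    marker = outdir / "run.partial"
    artifacts: dict[str, Path] = {}
    stage = "configure"
    try:
        config.validate_paths()
        table = None
        n_islands_for_metrics = config.n_archipelago_islands

        if config.simulate is not None:
            stage = "simulate"
            params = galapagos_like(seed=config.seed, **config.simulate)
            ds = simulate_colonization(params)
            artifacts.update(ds.write(outdir))
            log.stage("simulate", n_in=0, n_out=len(ds.alignment),
                      n_events=len(ds.event_log), seed=params.seed)
            aln, meta = ds.alignment, ds.metadata
        elif config.alignment is not None:
            stage = "read"
            aln = read_alignment(config.alignment)
            meta = read_metadata(config.metadata,
                                 island_aliases=config.island_aliases)
            log.stage("read", n_in=len(aln), n_out=len(aln))
        else:
            aln = meta = None

        if aln is not None:
            stage = "haplotypes"
            if config.drop_leading or config.drop_trailing:
                aln = trim_alignment(aln, config.drop_leading,
                                     config.drop_trailing)
            table = collapse_haplotypes(
                aln, meta, ambiguity_policy=config.ambiguity_policy)
            path = outdir / "haplotypes.tsv"
            table.write_tsv(path)
            artifacts["haplotypes"] = path
            path = outdir / "incidence.tsv"
            table.write_incidence(path)
            artifacts["incidence"] = path
            log.stage("haplotypes", n_in=len(aln),
                      n_out=table.n_haplotypes,
                      total_samples=table.total_samples)
        elif config.incidence is not None:
            stage = "haplotypes"
            table = read_incidence(config.incidence)
            path = outdir / "incidence.tsv"
            table.write_incidence(path)
            artifacts["incidence"] = path
            log.stage("haplotypes", n_in=table.n_haplotypes,
                      n_out=table.n_haplotypes,
                      total_samples=table.total_samples)

        if table is not None and table.has_sequences:
            stage = "network"
            net = build_network(table, max_steps=config.max_steps)
            path = outdir / "network_edges.tsv"
            write_edgelist(net, path)
            artifacts["network_edges"] = path
            path = outdir / "network.graphml"
            write_graphml(net, path)
            artifacts["network_graphml"] = path
            path = outdir / "classification.tsv"
            classification_frame(net).to_csv(path, sep="\t", index=False)
            artifacts["classification"] = path
            report = ancestrality_rank(net, table)
            path = outdir / "ancestrality.tsv"
            report.frame.to_csv(path, sep="\t")
            artifacts["ancestrality"] = path
            log.stage("network", n_in=table.n_haplotypes,
                      n_out=net.graph.number_of_nodes(),
                      n_edges=net.graph.number_of_edges())

        if table is not None:
            stage = "metrics"
            n_arch = n_islands_for_metrics or len(table.islands)
            record = ColonizationRecord.from_table(
                config.species, table, n_archipelago_islands=n_arch,
                archipelago=config.archipelago)
            result = compute_metrics(record, headline_rule=config.rule)
            payload = {
                "species": record.species,
                "n_islands_occupied": record.n_islands_occupied,
                "n_archipelago_islands": n_arch,
                "n_haplotypes": record.n_haplotypes,
                "chorological_min": result.chorological_min,
                "max_potential": result.max_potential,
                "inferred_events": result.inferred_events,
                "success": {r: {"value": s.value, "rounded": s.rounded}
                            for r, s in result.success.items()},
                "headline_rule": result.headline_rule,
            }
            path = outdir / "metrics.json"
            path.write_text(json.dumps(payload, indent=2, sort_keys=True)
                            + "\n")
            artifacts["metrics"] = path
            log.stage("metrics", n_in=record.n_haplotypes, n_out=1)

        if config.species_table is not None:
            stage = "report"
            records = read_species_table(config.species_table)
            frame = species_report(records, headline_rule=config.rule)
            path = outdir / "species_report.tsv"
            frame.to_csv(path, sep="\t", index=False)
            artifacts["species_report"] = path
            path = outdir / "species_report.md"
            path.write_text(report_to_markdown(frame))
            artifacts["species_report_md"] = path
            log.stage("report", n_in=len(records), n_out=len(frame))

        stage = "manifest"
        manifest = {
            "hapcol_version": __version__,
            "python": sys.version.split()[0],
            "seed": config.seed,
            "config": config.to_dict(),
            "config_hash": config.digest(),
            "artifacts": {k: str(v) for k, v in sorted(artifacts.items())},
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        artifacts["manifest"] = outdir / "manifest.json"
        if marker.exists():
            marker.unlink()
        log.flush()
        return {k: Path(v) for k, v in artifacts.items()}
    except Exception as exc:
        log.error(stage, str(exc))
        log.flush()
        marker.write_text(json.dumps(
            {"failed_stage": stage, "error": str(exc)}, sort_keys=True)
            + "\n")
        raise


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
@click.version_option(__version__)
def main():
    """Haplotype networks and island colonization metrics."""


@main.command()
@click.option("--config", "config_path", required=True,
              type=click.Path(), help="YAML/JSON pipeline config.")
def pipeline(config_path):
    """Run the full pipeline described by a config file."""
    _run(lambda: run_pipeline(PipelineConfig.from_file(config_path)))


@main.command()
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--preset", type=click.Choice(["galapagos-like"]),
              default="galapagos-like", show_default=True)
@click.option("--migration-prob", type=float, default=None)
@click.option("--mutation-rate", type=float, default=None)
@click.option("--out", "outdir", required=True, type=click.Path())
def simulate(seed, preset, migration_prob, mutation_rate, outdir):
    """Generate a synthetic archipelago dataset with ground truth."""
    overrides = {}
    if migration_prob is not None:
        overrides["migration_prob"] = migration_prob
    if mutation_rate is not None:
        overrides["mutation_rate"] = mutation_rate

    def go():
        ds = simulate_colonization(galapagos_like(seed=seed, **overrides))
        paths = ds.write(outdir)
        click.echo(f"samples: {len(ds.alignment)}  "
                   f"migration events: {len(ds.event_log)}")
        return paths

    _run(go)


@main.command()
@click.option("--alignment", required=True, type=click.Path())
@click.option("--metadata", required=True, type=click.Path())
@click.option("--drop-leading", type=int, default=0, show_default=True)
@click.option("--drop-trailing", type=int, default=0, show_default=True)
@click.option("--ambiguity-policy", default="exclude", show_default=True,
              type=click.Choice(["exclude", "collapse-compatible"]))
@click.option("--out", "outdir", required=True, type=click.Path())
def haplotypes(alignment, metadata, drop_leading, drop_trailing,
               ambiguity_policy, outdir):
    """Collapse an alignment into a haplotype table + incidence matrix."""
    cfg = PipelineConfig(outdir=outdir, alignment=alignment,
                         metadata=metadata, drop_leading=drop_leading,
                         drop_trailing=drop_trailing,
                         ambiguity_policy=ambiguity_policy)
    _run(lambda: run_pipeline(cfg))


@main.command()
@click.option("--alignment", required=True, type=click.Path())
@click.option("--metadata", required=True, type=click.Path())
@click.option("--max-steps", type=int, default=None,
              help="Connection limit in substitutions (default unlimited).")
@click.option("--out", "outdir", required=True, type=click.Path())
def network(alignment, metadata, max_steps, outdir):
    """Build the haplotype network and ancestrality report."""
    cfg = PipelineConfig(outdir=outdir, alignment=alignment,
                         metadata=metadata, max_steps=max_steps)
    _run(lambda: run_pipeline(cfg))


@main.command()
@click.option("--incidence", required=True, type=click.Path())
@click.option("--species", default="unknown species", show_default=True)
@click.option("--archipelago-islands", "n_arch", type=int, default=None,
              help="Number of archipelago islands considered "
                   "(default: islands in the matrix).")
@click.option("--out", "outdir", required=True, type=click.Path())
def metrics(incidence, species, n_arch, outdir):
    """Colonization metrics from a haplotype x island incidence matrix."""
    cfg = PipelineConfig(outdir=outdir, incidence=incidence,
                         species=species, n_archipelago_islands=n_arch)

    def go():
        paths = run_pipeline(cfg)
        click.echo((Path(paths["metrics"])).read_text().rstrip())
        return paths

    _run(go)


@main.command()
@click.option("--species-table", required=True, type=click.Path())
@click.option("--out", "outdir", required=True, type=click.Path())
def report(species_table, outdir):
    """Cross-species colonization-success comparison table."""
    cfg = PipelineConfig(outdir=outdir, species_table=species_table)

    def go():
        paths = run_pipeline(cfg)
        click.echo(Path(paths["species_report_md"]).read_text().rstrip())
        return paths

    _run(go)


def _run(fn):
    try:
        fn()
    except HapcolError as exc:
        click.echo(f"error: {exc}", err=True)
        sys.exit(1)
    except FileNotFoundError as exc:
        click.echo(f"error: {exc}", err=True)
        sys.exit(1)


if __name__ == "__main__":  # pragma: no cover
    main()
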