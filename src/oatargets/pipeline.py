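"""End-to-end orchestration: curation -> expression -> diffusion.

A single :class:`RunConfig` (loadable from YAML) names the input files and
parameters; :func:`run_pipeline` executes whichever stages have inputs,
writes intermediate tables to the output directory and returns a
JSON-serialisable :class:`RunReport`.  Stages whose inputs are absent are
skipped with an explicit notice rather than failing the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from .curation import (
    Consensus,
    consistency_report,
    gene_summaries,
    read_observations,
    summary_counts,
    write_gene_summaries,
)
from .diffusion import (
    candidates_to_frame,
    count_oa_interactions,
    cross_validate,
    diffuse,
    prioritise,
    rank_genes,
    rank_significance,
    read_edge_list,
)
from .expression import (
    map_to_human,
    overlap_effect_matrix,
    read_de_table,
    read_ortholog_map,
    significant_gene_sets,
)

log = logging.getLogger("oatargets")

__all__ = ["RunConfig", "RunReport", "StageFailure", "run_pipeline"]


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


@dataclass
class RunConfig:
    """Paths, thresholds and flags for one pipeline run."""

    # inputs (any may be None -> dependent stages are skipped)
    curation_table: str | None = None
    de_tables: list[str] = field(default_factory=list)
    network_edges: str | None = None
    ortholog_map: str | None = None
    protein_coding: str | None = None
    tractability: str | None = None

    # thresholds
    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    min_de: int = 3
    min_interactions: int = 4

    # diffusion parameters
    restart_probability: float = 0.3
    tol: float = 1e-8
    max_iter: int = 1000
    cv_folds: int = 5
    cv_repeats: int = 10
    rng_seed: int = 0

    # flags
    fc_scale: str = "log2"
    consistency_method: str = "consensus"
    wilcoxon_flavour: str = "signed_rank"
    seed_set: str = "any_effect"  # or "directional"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("curation_table", "network_edges", "ortholog_map",
                     "protein_coding", "tractability"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name}: {value} does not exist")
        for path in self.de_tables:
            if not Path(path).exists():
                raise FileNotFoundError(f"de_tables entry {path} does not exist")
        if not self.fc_threshold >= 1:
            raise ValueError("fc_threshold must be >= 1")
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")
        if not 0 < self.restart_probability <= 1:
            raise ValueError("restart_probability must be in (0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    package_version: str
    started: str
    finished: str = ""
    stages: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def run_pipeline(config: RunConfig, outdir: str | Path) -> RunReport:
    """Run all configured stages, writing outputs under ``outdir``."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        config_hash=config.config_hash(),
        package_version=__version__,
        started=datetime.now(timezone.utc).isoformat(),
    )
    (outdir / "config.yaml").write_text(yaml.safe_dump(asdict(config)))

    summaries = None
    consensus = {}

    # ---- curation ---------------------------------------------------------
    if config.curation_table is None:
        report.stages["curation"] = {"status": "skipped", "reason": "no curation_table"}
        log.info("curation stage skipped (no input table)")
    else:
        try:
            observations = read_observations(config.curation_table)
            summaries = gene_summaries(observations)
            counts = summary_counts(observations)
            consistency = consistency_report(
                observations, method=config.consistency_method
            )
            write_gene_summaries(summaries, outdir / "gene_summaries.tsv")
            consistency.to_json(outdir / "consistency.json")
            consensus = {g: s.consensus for g, s in summaries.items()}
            report.stages["curation"] = {
                "status": "ok",
                "summary_counts": counts.to_dict(),
                "consistency": consistency.to_dict(),
            }
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise StageFailure("curation", str(exc)) from exc

    # restrict consensus to protein-coding genes when a list is supplied
    if config.protein_coding and consensus:
        coding = {
            line.strip().upper()
            for line in Path(config.protein_coding).read_text().splitlines()
            if line.strip()
        }
        consensus = {g: c for g, c in consensus.items() if g in coding}

    # ---- expression -------------------------------------------------------
    de_sets = []
    de_counts: dict[str, int] = {}
    if not config.de_tables:
        report.stages["expression"] = {"status": "skipped", "reason": "no de_tables"}
        log.info("expression stage skipped (no DE tables)")
    elif not consensus:
        report.stages["expression"] = {
            "status": "skipped",
            "reason": "no consensus labels (curation skipped)",
        }
    else:
        try:
            ortho = (
                read_ortholog_map(config.ortholog_map)
                if config.ortholog_map
                else None
            )
            for path in config.de_tables:
                table = read_de_table(
                    path, fc_scale=config.fc_scale,
                    dataset_id=Path(path).stem,
                )
                sets = significant_gene_sets(
                    table, config.fc_threshold, config.p_threshold
                )
                sets = type(sets)(
                    up=frozenset(map_to_human(sets.up, ortho)),
                    down=frozenset(map_to_human(sets.down, ortho)),
                    universe=frozenset(map_to_human(sets.universe, ortho)),
                    dataset_id=sets.dataset_id,
                )
                de_sets.append(sets)
                for gene in sets.up | sets.down:
                    de_counts[gene] = de_counts.get(gene, 0) + 1
            matrix = overlap_effect_matrix(de_sets, consensus)
            matrix.to_csv(outdir / "overlap_matrix.tsv", sep="\t", index=False)
            report.stages["expression"] = {
                "status": "ok",
                "n_datasets": len(de_sets),
                "n_significant_cells": int(matrix["significant"].sum()),
            }
        except Exception as exc:  # noqa: BLE001
            raise StageFailure("expression", str(exc)) from exc

    # ---- diffusion --------------------------------------------------------
    if config.network_edges is None:
        report.stages["diffusion"] = {"status": "skipped", "reason": "no network_edges"}
        log.info("diffusion stage skipped (no network)")
    elif not consensus:
        report.stages["diffusion"] = {
            "status": "skipped",
            "reason": "no consensus labels (curation skipped)",
        }
    else:
        try:
            network = read_edge_list(config.network_edges)
            directional = {Consensus.PROTECTIVE, Consensus.DETRIMENTAL}
            wanted = (
                directional
                if config.seed_set == "directional"
                else directional | {Consensus.AMBIGUOUS, Consensus.MIXED}
            )
            seeds = sorted(
                g for g, c in consensus.items() if c in wanted and g in network
            )
            if not seeds:
                raise ValueError("no seed genes present in the network")
            cv = cross_validate(
                network,
                seeds,
                k=config.cv_folds,
                repeats=config.cv_repeats,
                r=config.restart_probability,
                rng_seed=config.rng_seed,
                tol=config.tol,
                max_iter=config.max_iter,
            )
            n_candidates = network.n_nodes - (
                len(seeds) - len(seeds) // config.cv_folds
            )
            rank_p = rank_significance(
                cv.heldout_ranks[: min(len(cv.heldout_ranks), 200)],
                n_candidates,
                flavour=config.wilcoxon_flavour,
            )
            (outdir / "cv_result.json").write_text(json.dumps(cv.to_dict()))
            scores = diffuse(
                network,
                seeds,
                r=config.restart_probability,
                tol=config.tol,
                max_iter=config.max_iter,
            )
            ranks = rank_genes(scores, exclude=seeds)
            interactions = {
                g: count_oa_interactions(network, g, seeds) for g in ranks
            }
            tract = (
                read_ortholog_map(config.tractability)
                if config.tractability
                else None
            )
            candidates = prioritise(
                ranks,
                de_counts,
                interactions,
                known=set(consensus),
                min_de=config.min_de,
                min_interactions=config.min_interactions,
                tractability=tract,
            )
            frame = candidates_to_frame(candidates)
            frame.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
            ranked = (
                scores.as_series().sort_values(ascending=False).rename("score")
            )
            ranked.to_csv(outdir / "diffusion_scores.tsv", sep="\t")
            report.stages["diffusion"] = {
                "status": "ok",
                "n_network_nodes": network.n_nodes,
                "n_seeds": len(seeds),
                "cv_summary": cv.summary(),
                "rank_test_p": rank_p,
                "n_candidates": len(candidates),
            }
        except StageFailure:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageFailure("diffusion", str(exc)) from exc

    report.finished = datetime.now(timezone.utc).isoformat()
    report.to_json(outdir / "report.json")
    return report
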