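"""Synthetic curation tables, DE tables and planted-module networks.

Every pipeline stage can be exercised without downloads: these generators
emit files in exactly the formats the readers consume, together with a
:class:`SyntheticTruth` record of the ground truth used to make them, so
tests can check recovery against a known answer.

The defaults mimic the structure of the real curated corpus: most genes are
observed once or twice, roughly 60% of observations are genetic, surgical
and spontaneous models dominate, and repeated studies of a gene agree about
80% of the time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .curation import ActivityChange, Approach, Effect, Model
from .expression import DETable

__all__ = [
    "SyntheticTruth",
    "synth_observations",
    "synth_network",
    "synth_de_tables",
    "write_edge_list",
]

DEFAULT_APPROACH_MIX: dict[str, float] = {"genetic": 0.63, "exogenous": 0.37}
DEFAULT_MODEL_MIX: dict[str, float] = {
    "surgical": 0.47,
    "spontaneous": 0.26,
    "chemical": 0.09,
    "high_fat_diet": 0.06,
    "mechanical": 0.05,
    "genetic_susceptibility": 0.04,
    "other": 0.03,
}
# corpus-like marginal frequencies of true gene effects: directional effects
# dominate, a minority of genes genuinely do nothing
DEFAULT_EFFECT_MIX: dict[str, float] = {
    "protective": 0.40,
    "detrimental": 0.45,
    "no_effect": 0.15,
}


@dataclass
class SyntheticTruth:
    """Ground truth and full parameter record for one generator call."""

    true_gene_effects: dict[str, str] = field(default_factory=dict)
    planted_module: list[str] = field(default_factory=list)
    de_enriched_sets: dict[str, list[str]] = field(default_factory=dict)
    generator_params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "true_gene_effects": self.true_gene_effects,
                    "planted_module": self.planted_module,
                    "de_enriched_sets": self.de_enriched_sets,
                    "generator_params": self.generator_params,
                },
                indent=2,
                sort_keys=True,
            )
        )


def _normalise(mix: Mapping[str, float]) -> tuple[list[str], np.ndarray]:
    keys = list(mix)
    probs = np.asarray([mix[k] for k in keys], dtype=float)
    if (probs < 0).any() or probs.sum() <= 0:
        raise ValueError("mixture weights must be non-negative and sum > 0")
    return keys, probs / probs.sum()


def synth_observations(
    n_genes: int = 500,
    obs_per_gene_mean: float = 2.0,
    consistency_rate: float = 0.8,
    approach_mix: Mapping[str, float] | None = None,
    model_mix: Mapping[str, float] | None = None,
    effect_mix: Mapping[str, float] | None = None,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a curated-observation table with known per-gene true effects.

    Each gene gets a true effect and a geometric number of observations with
    mean ``obs_per_gene_mean`` (most genes observed once, mirroring the
    literature).  ``consistency_rate`` is the per-gene probability that all
    of its observations report the true effect; a discordant gene instead
    reports the two opposite directions alternately within each approach
    stratum, so among genes observed more than once within an approach the
    expected consistent fraction equals ``consistency_rate`` exactly.
    """
    if not 0 <= consistency_rate <= 1:
        raise ValueError("consistency_rate must be in [0, 1]")
    if obs_per_gene_mean < 1:
        raise ValueError("obs_per_gene_mean must be >= 1")
    rng = np.random.default_rng(rng_seed)
    app_keys, app_p = _normalise(approach_mix or DEFAULT_APPROACH_MIX)
    mod_keys, mod_p = _normalise(model_mix or DEFAULT_MODEL_MIX)
    eff_keys, eff_p = _normalise(effect_mix or DEFAULT_EFFECT_MIX)

    genes = [f"SYNG{i:04d}" for i in range(n_genes)]
    truth = SyntheticTruth(
        generator_params={
            "generator": "synth_observations",
            "n_genes": n_genes,
            "obs_per_gene_mean": obs_per_gene_mean,
            "consistency_rate": consistency_rate,
            "approach_mix": dict(approach_mix or DEFAULT_APPROACH_MIX),
            "model_mix": dict(model_mix or DEFAULT_MODEL_MIX),
            "effect_mix": dict(effect_mix or DEFAULT_EFFECT_MIX),
            "rng_seed": rng_seed,
        }
    )
    rows = []
    pmid_counter = 10_000_000
    for gene in genes:
        true_effect = Effect(eff_keys[rng.choice(len(eff_keys), p=eff_p)])
        truth.true_gene_effects[gene] = true_effect.value
        n_obs = int(rng.geometric(1.0 / obs_per_gene_mean))
        concordant = rng.random() < consistency_rate
        if true_effect is Effect.NO_EFFECT:
            dir_a, dir_b = Effect.PROTECTIVE, Effect.DETRIMENTAL
        else:
            dir_a = true_effect
            dir_b = (
                Effect.DETRIMENTAL
                if true_effect is Effect.PROTECTIVE
                else Effect.PROTECTIVE
            )
        stratum_count = {Approach.GENETIC: 0, Approach.EXOGENOUS: 0}
        for _ in range(n_obs):
            approach = Approach(app_keys[rng.choice(len(app_keys), p=app_p)])
            model = Model(mod_keys[rng.choice(len(mod_keys), p=mod_p)])
            activity = (
                ActivityChange.DECREASE
                if rng.random() < 0.7
                else ActivityChange.INCREASE
            )
            if concordant:
                reported = true_effect
            else:
                # alternate the two directions within each approach stratum so
                # any stratum with >=2 observations is internally conflicted
                reported = (
                    dir_a if stratum_count[approach] % 2 == 0 else dir_b
                )
            stratum_count[approach] += 1
            # choose the observed phenotype so that inference recovers the
            # reported gene-level effect under this activity change
            if reported is Effect.NO_EFFECT:
                observed = Effect.NO_EFFECT
            elif activity is ActivityChange.INCREASE:
                observed = reported
            else:
                observed = (
                    Effect.DETRIMENTAL
                    if reported is Effect.PROTECTIVE
                    else Effect.PROTECTIVE
                )
            pmid_counter += 1
            intervention = (
                ("Knockout" if approach is Approach.GENETIC else "Inhibitor")
                if activity is ActivityChange.DECREASE
                else (
                    "Overexpression"
                    if approach is Approach.GENETIC
                    else "Agonist"
                )
            )
            rows.append(
                {
                    "gene": gene,
                    "pmid": str(pmid_counter),
                    "intervention": intervention,
                    "activity_change": activity.value,
                    "approach": approach.value,
                    "model": model.value,
                    "observed_effect": observed.value,
                    "specificity": "Global",
                    "species": "Mouse",
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "pmid",
            "intervention",
            "activity_change",
            "approach",
            "model",
            "observed_effect",
            "specificity",
            "species",
        ],
    )
    return table, truth


def synth_network(
    n_nodes: int = 2000,
    attachment: int = 3,
    module_size: int = 50,
    intra_module_edge_prob: float = 0.5,
    rng_seed: int = 0,
) -> tuple[list[tuple[str, str]], SyntheticTruth]:
    """Scale-free-like graph with a planted, densely connected module.

    A Barabasi-Albert preferential-attachment graph (``attachment`` edges per
    new node) provides the background topology; ``module_size`` nodes are
    then chosen at random and each missing intra-module edge is added with
    probability ``intra_module_edge_prob``.  With probability 0 the module is
    topologically invisible (negative control).  The output is connected by
    construction (BA graphs are connected; extra edges cannot disconnect).
    """
    if not 0 < module_size < n_nodes:
        raise ValueError("module_size must be in (0, n_nodes)")
    if not 0 <= intra_module_edge_prob <= 1:
        raise ValueError("intra_module_edge_prob must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    g = nx.barabasi_albert_graph(
        n_nodes, attachment, seed=int(rng.integers(2**31 - 1))
    )
    module_idx = rng.choice(n_nodes, size=module_size, replace=False)
    for i, a in enumerate(module_idx):
        for b in module_idx[i + 1 :]:
            if a != b and not g.has_edge(a, b):
                if rng.random() < intra_module_edge_prob:
                    g.add_edge(int(a), int(b))
    name = {i: f"NODE{i:05d}" for i in g.nodes}
    edges = [(name[a], name[b]) for a, b in g.edges]
    truth = SyntheticTruth(
        planted_module=sorted(name[int(i)] for i in module_idx),
        generator_params={
            "generator": "synth_network",
            "n_nodes": n_nodes,
            "attachment": attachment,
            "module_size": module_size,
            "intra_module_edge_prob": intra_module_edge_prob,
            "rng_seed": rng_seed,
        },
    )
    return edges, truth


def synth_de_tables(
    n_datasets: int = 5,
    universe: Sequence[str] | None = None,
    enriched_set: Sequence[str] = (),
    enrichment_odds: float = 10.0,
    effect_size_log2fc: float = 1.5,
    noise_sd: float = 0.3,
    base_signal_rate: float = 0.05,
    enriched_direction: str = "up",
    rng_seed: int = 0,
) -> tuple[list[DETable], SyntheticTruth]:
    """SkeletalVis-style DE result tables with a planted enriched gene set.

    Every gene is "significant" with a base probability; genes in
    ``enriched_set`` have their odds of significance multiplied by
    ``enrichment_odds`` (odds of 1 reduces them to nulls — the calibration
    control).  Null genes draw adjusted p uniformly on [0, 1] and a small
    centred log2 fold change; significant genes draw a Beta-skewed adjusted p
    near 0 and |log2FC| = ``effect_size_log2fc`` + half-normal noise, signed
    ``enriched_direction`` for planted genes and at random otherwise.
    """
    if enrichment_odds < 1:
        raise ValueError("enrichment_odds must be >= 1")
    if enriched_direction not in ("up", "down"):
        raise ValueError("enriched_direction must be 'up' or 'down'")
    rng = np.random.default_rng(rng_seed)
    if universe is None:
        universe = [f"SYNG{i:04d}" for i in range(1000)]
    universe = [str(g).upper() for g in universe]
    enriched = {str(g).upper() for g in enriched_set}
    if not enriched <= set(universe):
        raise ValueError("enriched_set must be a subset of the universe")

    base_odds = base_signal_rate / (1 - base_signal_rate)
    enriched_rate = (base_odds * enrichment_odds) / (
        1 + base_odds * enrichment_odds
    )
    sign = 1.0 if enriched_direction == "up" else -1.0

    tables: list[DETable] = []
    truth = SyntheticTruth(
        generator_params={
            "generator": "synth_de_tables",
            "n_datasets": n_datasets,
            "n_universe": len(universe),
            "enriched_set_size": len(enriched),
            "enrichment_odds": enrichment_odds,
            "effect_size_log2fc": effect_size_log2fc,
            "noise_sd": noise_sd,
            "base_signal_rate": base_signal_rate,
            "enriched_direction": enriched_direction,
            "rng_seed": rng_seed,
        }
    )
    for d in range(n_datasets):
        dataset_id = f"synthDE{d:02d}"
        rows = []
        for gene in universe:
            rate = enriched_rate if gene in enriched else base_signal_rate
            if rng.random() < rate:
                adj_p = float(rng.beta(1, 50))
                magnitude = effect_size_log2fc + abs(rng.normal(0, noise_sd))
                direction = (
                    sign if gene in enriched else (1.0 if rng.random() < 0.5 else -1.0)
                )
                log2fc = direction * magnitude
            else:
                adj_p = float(rng.uniform())
                log2fc = float(rng.normal(0, noise_sd / 2))
            rows.append({"gene": gene, "log2fc": log2fc, "adj_p": adj_p})
        tables.append(
            DETable(pd.DataFrame(rows), dataset_id=dataset_id, species="human")
        )
        truth.de_enriched_sets[dataset_id] = sorted(enriched)
    return tables, truth


def write_edge_list(edges: Sequence[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(edges).to_csv(path, sep="\t", header=False, index=False)
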