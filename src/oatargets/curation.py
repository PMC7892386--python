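"""Curated gene-perturbation observations and per-gene consensus effects.

Animal-model osteoarthritis (OA) experiments modulate a gene (knockout,
overexpression, drug, antibody ...) and score the resulting joint damage.
Each experiment is recorded as an :class:`Observation`.  Combining the
direction of the modulation (did protein activity go up or down?) with the
observed change in OA severity yields an inferred *gene* effect: a gene whose
removal worsens OA is protective, a gene whose removal improves OA is
detrimental — the same logic as tumour suppressor versus oncogene.

The module parses observation tables, infers per-experiment effects, folds
them into per-gene consensus labels (with ``ambiguous`` marking directional
conflicts and ``no_effect`` superseded by any directional observation), and
computes corpus-level summary and consistency statistics.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ActivityChange",
    "Approach",
    "Model",
    "Effect",
    "Consensus",
    "Observation",
    "GeneSummary",
    "ConsistencyReport",
    "SummaryCounts",
    "SchemaError",
    "RowError",
    "read_observations",
    "infer_effect",
    "consensus_effect",
    "gene_summaries",
    "consistency_report",
    "summary_counts",
    "write_gene_summaries",
]


class ActivityChange(str, Enum):
    """Direction of the perturbation's effect on protein product/activity."""

    INCREASE = "increase"
    DECREASE = "decrease"


class Approach(str, Enum):
    """Genetic (germline/conditional) versus exogenous (drug, protein, virus)."""

    GENETIC = "genetic"
    EXOGENOUS = "exogenous"


class Model(str, Enum):
    """Broad OA-induction model category."""

    SURGICAL = "surgical"
    SPONTANEOUS = "spontaneous"
    HIGH_FAT_DIET = "high_fat_diet"
    CHEMICAL = "chemical"
    MECHANICAL = "mechanical"
    GENETIC_SUSCEPTIBILITY = "genetic_susceptibility"
    OTHER = "other"


class Effect(str, Enum):
    """Observed or inferred per-experiment effect on OA severity."""

    PROTECTIVE = "protective"
    DETRIMENTAL = "detrimental"
    NO_EFFECT = "no_effect"
    MIXED = "mixed"


class Consensus(str, Enum):
    """Per-gene label combining all experiment-level inferred effects."""

    PROTECTIVE = "protective"
    DETRIMENTAL = "detrimental"
    AMBIGUOUS = "ambiguous"
    NO_EFFECT = "no_effect"
    MIXED = "mixed"


class SchemaError(ValueError):
    """A mandatory column is missing from an observation table."""


class RowError(ValueError):
    """A data row holds a value that cannot be mapped to the expected enum."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


@dataclass(frozen=True)
class Observation:
    """One curated gene-perturbation experiment.

    ``gene`` is the human symbol (uppercased), ``model_subtype`` carries the
    free-text refinement such as "DMM" for surgical destabilisation of the
    medial meniscus.
    """

    gene: str
    pmid: str
    intervention: str
    activity_change: ActivityChange
    approach: Approach
    model: Model
    observed_effect: Effect
    model_subtype: str = ""
    specificity: str = ""
    species: str = ""

    def __post_init__(self):
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")

    @property
    def inferred_effect(self) -> Effect:
        return infer_effect(self.activity_change, self.observed_effect)


@dataclass
class GeneSummary:
    gene: str
    consensus: Consensus
    n_genetic: int
    n_exogenous: int
    n_publications: int
    models_studied: frozenset[Model]


@dataclass
class ConsistencyReport:
    """(consistent, total) pairs over four strata of the observation corpus.

    ``genetic_multi`` / ``exogenous_multi``: genes with >=2 observations of
    that approach whose directional inferred effects never conflict.
    ``cross_approach``: genes studied both genetically and exogenously whose
    per-approach consensus labels agree.  ``cross_model``: genes with a
    directional per-model consensus in both spontaneous and surgical models
    whose labels agree.
    """

    genetic_multi: tuple[int, int]
    exogenous_multi: tuple[int, int]
    cross_approach: tuple[int, int]
    cross_model: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "genetic_multi": list(self.genetic_multi),
            "exogenous_multi": list(self.exogenous_multi),
            "cross_approach": list(self.cross_approach),
            "cross_model": list(self.cross_model),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass
class SummaryCounts:
    n_publications: int
    n_unique_genes: int
    n_genetic_observations: int
    n_genetic_genes: int
    n_exogenous_observations: int
    n_exogenous_genes: int
    per_model_counts: dict[Model, int] = field(default_factory=dict)
    per_gene_study_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_publications": self.n_publications,
            "n_unique_genes": self.n_unique_genes,
            "n_genetic_observations": self.n_genetic_observations,
            "n_genetic_genes": self.n_genetic_genes,
            "n_exogenous_observations": self.n_exogenous_observations,
            "n_exogenous_genes": self.n_exogenous_genes,
            "per_model_counts": {m.value: c for m, c in self.per_model_counts.items()},
            "per_gene_study_counts": dict(self.per_gene_study_counts),
        }


# ---------------------------------------------------------------------------
# Parsing

DEFAULT_SCHEMA: dict[str, str] = {
    "gene": "gene",
    "pmid": "pmid",
    "intervention": "intervention",
    "activity_change": "activity_change",
    "approach": "approach",
    "model": "model",
    "observed_effect": "observed_effect",
    "model_subtype": "model_subtype",
    "specificity": "specificity",
    "species": "species",
}

MANDATORY_FIELDS = (
    "gene",
    "pmid",
    "intervention",
    "activity_change",
    "approach",
    "model",
    "observed_effect",
)

# Accepted spellings for each enum, lowercased.  "removal"/"inhibition" style
# values come from tables that record the effect on the protein product.
_ACTIVITY_ALIASES = {
    "increase": ActivityChange.INCREASE,
    "increased": ActivityChange.INCREASE,
    "overexpression": ActivityChange.INCREASE,
    "activation": ActivityChange.INCREASE,
    "decrease": ActivityChange.DECREASE,
    "decreased": ActivityChange.DECREASE,
    "removal": ActivityChange.DECREASE,
    "inhibition": ActivityChange.DECREASE,
    "knockdown": ActivityChange.DECREASE,
    "deficiency": ActivityChange.DECREASE,
}

_EFFECT_ALIASES = {
    "protective": Effect.PROTECTIVE,
    "detrimental": Effect.DETRIMENTAL,
    "no_effect": Effect.NO_EFFECT,
    "no effect": Effect.NO_EFFECT,
    "none": Effect.NO_EFFECT,
    "mixed": Effect.MIXED,
}

_APPROACH_ALIASES = {
    "genetic": Approach.GENETIC,
    "exogenous": Approach.EXOGENOUS,
}

_MODEL_ALIASES = {
    "surgical": Model.SURGICAL,
    "spontaneous": Model.SPONTANEOUS,
    "ageing": Model.SPONTANEOUS,
    "aging": Model.SPONTANEOUS,
    "high_fat_diet": Model.HIGH_FAT_DIET,
    "high fat diet": Model.HIGH_FAT_DIET,
    "chemical": Model.CHEMICAL,
    "mechanical": Model.MECHANICAL,
    "genetic_susceptibility": Model.GENETIC_SUSCEPTIBILITY,
    "genetic susceptibility": Model.GENETIC_SUSCEPTIBILITY,
    "other": Model.OTHER,
}


def load_intervention_map(path: str | Path | None = None) -> dict[str, ActivityChange]:
    """Load an intervention -> activity-change dictionary from YAML.

    Without ``path`` the editable default shipped with the package is used
    (knockout/siRNA/antibody/... -> decrease; overexpression/agonist/... ->
    increase).  Keys are matched case-insensitively against the whole
    intervention string.
    """
    import yaml

    if path is None:
        path = Path(__file__).parent / "data" / "interventions.yaml"
    raw = yaml.safe_load(Path(path).read_text())
    mapping: dict[str, ActivityChange] = {}
    for direction, names in raw.items():
        change = ActivityChange(direction)
        for name in names:
            mapping[str(name).strip().lower()] = change
    return mapping


def _map_enum(value: str, aliases: Mapping[str, Enum], what: str, row: int):
    key = str(value).strip().lower()
    if key not in aliases:
        raise RowError(row, f"cannot map {what} value {value!r}")
    return aliases[key]


def _split_model(raw: str, row: int) -> tuple[Model, str]:
    """Split "surgical/DMM" or "Surgical - DMM" into (category, subtype)."""
    text = str(raw).strip()
    # dash variants first: subtype text may itself contain "/" (e.g. STR/ort)
    for sep in ("−", "–", "-", "/"):
        if sep in text:
            head, _, tail = text.partition(sep)
            return _map_enum(head, _MODEL_ALIASES, "model", row), tail.strip()
    return _map_enum(text, _MODEL_ALIASES, "model", row), ""


def read_observations(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    sep: str | None = None,
    intervention_map: Mapping[str, ActivityChange] | None = None,
) -> list[Observation]:
    """Read a curated observation table (CSV or TSV, header required).

    ``schema`` remaps logical field names to the file's column names.  The
    delimiter is sniffed from the extension unless ``sep`` is given.
    Rows with an empty ``activity_change`` cell fall back to
    ``intervention_map`` (see :func:`load_intervention_map`) keyed on the
    intervention text.  Missing mandatory columns raise :class:`SchemaError`;
    unmappable enum values raise :class:`RowError` carrying the (1-based)
    data row number.
    """
    path = Path(path)
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    missing = [f for f in MANDATORY_FIELDS if colmap[f] not in frame.columns]
    if missing:
        raise SchemaError(
            "missing mandatory column(s): "
            + ", ".join(colmap[f] for f in missing)
        )

    observations: list[Observation] = []
    for i, rec in enumerate(frame.to_dict("records"), start=1):
        def get(fld: str) -> str:
            col = colmap[fld]
            return str(rec.get(col, "")).strip()

        gene = get("gene").upper()
        if not gene:
            raise RowError(i, "empty gene symbol")
        model, subtype = _split_model(get("model"), i)
        explicit_subtype = get("model_subtype")
        raw_activity = get("activity_change")
        if not raw_activity and intervention_map is not None:
            key = get("intervention").strip().lower()
            if key not in intervention_map:
                raise RowError(i, f"intervention {key!r} not in intervention map")
            activity = ActivityChange(intervention_map[key])
        else:
            activity = _map_enum(
                raw_activity, _ACTIVITY_ALIASES, "activity_change", i
            )
        observations.append(
            Observation(
                gene=gene,
                pmid=get("pmid"),
                intervention=get("intervention"),
                activity_change=activity,
                approach=_map_enum(get("approach"), _APPROACH_ALIASES, "approach", i),
                model=model,
                observed_effect=_map_enum(
                    get("observed_effect"), _EFFECT_ALIASES, "observed_effect", i
                ),
                model_subtype=explicit_subtype or subtype,
                specificity=get("specificity"),
                species=get("species"),
            )
        )
    return observations


# ---------------------------------------------------------------------------
# Effect inference and consensus

def infer_effect(activity_change: ActivityChange, observed_effect: Effect) -> Effect:
    """Infer the gene's effect on OA severity from one experiment.

    Decreasing a gene and seeing worse OA means the gene protects the joint;
    decreasing it and seeing milder OA means it drives damage.  Increasing a
    gene leaves the observed direction unchanged.  ``no_effect`` and ``mixed``
    observations propagate unchanged.
    """
    activity_change = ActivityChange(activity_change)
    observed_effect = Effect(observed_effect)
    if observed_effect in (Effect.NO_EFFECT, Effect.MIXED):
        return observed_effect
    if activity_change is ActivityChange.INCREASE:
        return observed_effect
    # decrease: flip the direction
    return (
        Effect.PROTECTIVE
        if observed_effect is Effect.DETRIMENTAL
        else Effect.DETRIMENTAL
    )


def consensus_effect(inferred: Sequence[Effect]) -> Consensus:
    """Combine per-experiment inferred effects into one per-gene label.

    Directional conflict (both protective and detrimental present) gives
    ``ambiguous``.  A single direction wins, superseding any ``no_effect``
    entries.  With no directional evidence, any ``mixed`` observation gives
    ``mixed``; otherwise everything was ``no_effect``.
    """
    if not inferred:
        raise ValueError("consensus_effect requires at least one inferred effect")
    values = {Effect(e) for e in inferred}
    has_prot = Effect.PROTECTIVE in values
    has_detr = Effect.DETRIMENTAL in values
    if has_prot and has_detr:
        return Consensus.AMBIGUOUS
    if has_prot:
        return Consensus.PROTECTIVE
    if has_detr:
        return Consensus.DETRIMENTAL
    if Effect.MIXED in values:
        return Consensus.MIXED
    return Consensus.NO_EFFECT


def _by_gene(observations: Iterable[Observation]) -> dict[str, list[Observation]]:
    groups: dict[str, list[Observation]] = defaultdict(list)
    for obs in observations:
        groups[obs.gene].append(obs)
    return groups


def gene_summaries(observations: Iterable[Observation]) -> dict[str, GeneSummary]:
    """Per-gene consensus labels with supporting observation counts."""
    summaries: dict[str, GeneSummary] = {}
    for gene, group in _by_gene(observations).items():
        summaries[gene] = GeneSummary(
            gene=gene,
            consensus=consensus_effect([o.inferred_effect for o in group]),
            n_genetic=sum(o.approach is Approach.GENETIC for o in group),
            n_exogenous=sum(o.approach is Approach.EXOGENOUS for o in group),
            n_publications=len({o.pmid for o in group}),
            models_studied=frozenset(o.model for o in group),
        )
    return summaries


def _directional(effects: Iterable[Effect]) -> set[Effect]:
    return {e for e in effects if e in (Effect.PROTECTIVE, Effect.DETRIMENTAL)}


def _is_consistent(effects: Sequence[Effect]) -> bool:
    # consistent = directional effects never conflict; genes with only
    # no_effect (or mixed) observations count as consistent
    directions = _directional(effects)
    return not (Effect.PROTECTIVE in directions and Effect.DETRIMENTAL in directions)


def consistency_report(
    observations: Iterable[Observation],
    method: str = "consensus",
) -> ConsistencyReport:
    """Quantify agreement between repeated studies of the same gene.

    ``method`` controls the cross-approach comparison: ``"consensus"``
    compares per-approach consensus labels, ``"observations"`` asks whether
    the pooled directional inferred effects across both approaches conflict.
    """
    if method not in ("consensus", "observations"):
        raise ValueError("method must be 'consensus' or 'observations'")
    groups = _by_gene(observations)

    def multi(approach: Approach) -> tuple[int, int]:
        total = consistent = 0
        for group in groups.values():
            effects = [
                o.inferred_effect for o in group if o.approach is approach
            ]
            if len(effects) < 2:
                continue
            total += 1
            consistent += _is_consistent(effects)
        return consistent, total

    cross_approach_total = cross_approach_consistent = 0
    for group in groups.values():
        genetic = [o.inferred_effect for o in group if o.approach is Approach.GENETIC]
        exogenous = [
            o.inferred_effect for o in group if o.approach is Approach.EXOGENOUS
        ]
        if not genetic or not exogenous:
            continue
        cross_approach_total += 1
        if method == "consensus":
            cross_approach_consistent += consensus_effect(
                genetic
            ) == consensus_effect(exogenous)
        else:
            cross_approach_consistent += _is_consistent(genetic + exogenous)

    cross_model_total = cross_model_consistent = 0
    for group in groups.values():
        labels = {}
        for model in (Model.SPONTANEOUS, Model.SURGICAL):
            effects = [o.inferred_effect for o in group if o.model is model]
            if not effects:
                break
            label = consensus_effect(effects)
            if label not in (Consensus.PROTECTIVE, Consensus.DETRIMENTAL):
                break
            labels[model] = label
        if len(labels) == 2:
            cross_model_total += 1
            cross_model_consistent += (
                labels[Model.SPONTANEOUS] == labels[Model.SURGICAL]
            )

    return ConsistencyReport(
        genetic_multi=multi(Approach.GENETIC),
        exogenous_multi=multi(Approach.EXOGENOUS),
        cross_approach=(cross_approach_consistent, cross_approach_total),
        cross_model=(cross_model_consistent, cross_model_total),
    )


def summary_counts(observations: Iterable[Observation]) -> SummaryCounts:
    """Corpus-level counts of publications, genes, observations and models."""
    observations = list(observations)
    genetic = [o for o in observations if o.approach is Approach.GENETIC]
    exogenous = [o for o in observations if o.approach is Approach.EXOGENOUS]
    per_gene_pubs = {
        gene: len({o.pmid for o in group})
        for gene, group in _by_gene(observations).items()
    }
    return SummaryCounts(
        n_publications=len({o.pmid for o in observations}),
        n_unique_genes=len({o.gene for o in observations}),
        n_genetic_observations=len(genetic),
        n_genetic_genes=len({o.gene for o in genetic}),
        n_exogenous_observations=len(exogenous),
        n_exogenous_genes=len({o.gene for o in exogenous}),
        per_model_counts=dict(Counter(o.model for o in observations)),
        per_gene_study_counts=per_gene_pubs,
    )


def write_gene_summaries(
    summaries: Mapping[str, GeneSummary], path: str | Path
) -> None:
    """Write per-gene consensus labels and counts as TSV."""
    rows = [
        {
            "gene": s.gene,
            "consensus": s.consensus.value,
            "n_genetic": s.n_genetic,
            "n_exogenous": s.n_exogenous,
            "n_publications": s.n_publications,
            "models_studied": ";".join(sorted(m.value for m in s.models_studied)),
        }
        for s in sorted(summaries.values(), key=lambda s: s.gene)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
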