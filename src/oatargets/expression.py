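"""Differential-expression gene sets and their overlap with curated OA genes.

Takes SkeletalVis-style differential-expression result tables (gene, log2
fold change, adjusted p), thresholds them into up/down human-symbol gene
sets, and tests (a) whether curated OA genes are over-represented in those
sets (one-sided Fisher exact with Benjamini-Hochberg correction across
datasets) and (b) whether protective and detrimental OA genes appear in the
overlaps in different proportions (2x2 chi-square, BH-corrected across
dataset x direction cells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .curation import Consensus

__all__ = [
    "DETable",
    "DEGeneSets",
    "OverlapTestResult",
    "ProportionTestResult",
    "read_de_table",
    "read_ortholog_map",
    "significant_gene_sets",
    "map_to_human",
    "fisher_overlap",
    "bh_adjust",
    "effect_proportion_test",
    "overlap_effect_matrix",
]

MIRNA_PREFIXES = ("MIR", "MIR-", "HSA-MIR", "LET-7")


@dataclass
class DETable:
    """One differential-expression comparison.

    ``data`` has columns ``gene``, ``log2fc``, ``adj_p``; duplicated genes are
    collapsed to the row with the largest absolute fold change.
    """

    data: pd.DataFrame
    dataset_id: str = ""
    species: str = ""
    tissue: str = ""
    condition: str = ""

    def __post_init__(self):
        required = {"gene", "log2fc", "adj_p"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"DETable missing column(s): {sorted(missing)}")
        df = self.data.copy()
        df["gene"] = df["gene"].astype(str).str.strip().str.upper()
        df["adj_p"] = df["adj_p"].astype(float)
        df["log2fc"] = df["log2fc"].astype(float)
        if ((df["adj_p"] < 0) | (df["adj_p"] > 1)).any():
            raise ValueError("adjusted p-values must lie in [0, 1]")
        # keep the strongest row per gene
        df = (
            df.assign(_abs=df["log2fc"].abs())
            .sort_values("_abs", ascending=False)
            .drop_duplicates("gene")
            .drop(columns="_abs")
            .reset_index(drop=True)
        )
        self.data = df


@dataclass
class DEGeneSets:
    """Thresholded up/down gene sets plus the measured universe."""

    up: frozenset[str]
    down: frozenset[str]
    universe: frozenset[str]
    dataset_id: str = ""

    def __post_init__(self):
        if self.up & self.down:
            raise ValueError("up and down sets overlap")
        if not (self.up | self.down) <= self.universe:
            raise ValueError("up/down sets must be subsets of the universe")


@dataclass
class OverlapTestResult:
    k_overlap: int
    n_set: int
    n_reference: int
    n_universe: int
    odds_ratio: float
    p: float
    p_adj: float = math.nan


@dataclass
class ProportionTestResult:
    """2x2 chi-square of effect class against differential-expression status."""

    chi2: float
    p: float
    testable: bool
    table: np.ndarray = field(repr=False, default=None)


def read_de_table(
    path: str | Path,
    gene_col: str = "gene",
    fc_col: str = "log2fc",
    p_col: str = "adj_p",
    fc_scale: str = "log2",
    sep: str = "\t",
    **metadata,
) -> DETable:
    """Read a TSV differential-expression export.

    ``fc_scale`` declares the fold-change column dialect: ``"log2"`` (default)
    or ``"linear"`` (signed linear fold changes, converted to log2 preserving
    sign, e.g. -2.0 -> -1.0).
    """
    df = pd.read_csv(path, sep=sep)
    df = df.rename(columns={gene_col: "gene", fc_col: "log2fc", p_col: "adj_p"})
    if fc_scale == "linear":
        fc = df["log2fc"].astype(float)
        df["log2fc"] = np.sign(fc) * np.log2(np.abs(fc).clip(lower=np.finfo(float).tiny))
    elif fc_scale != "log2":
        raise ValueError("fc_scale must be 'log2' or 'linear'")
    return DETable(df[["gene", "log2fc", "adj_p"]], **metadata)


def read_ortholog_map(path: str | Path, sep: str = "\t") -> dict[str, str]:
    """Read a two-column source-symbol -> human-symbol table."""
    df = pd.read_csv(path, sep=sep, header=0, dtype=str)
    src, dst = df.columns[:2]
    return {
        str(a).strip(): str(b).strip().upper()
        for a, b in zip(df[src], df[dst])
        if str(a).strip() and str(b).strip()
    }


def significant_gene_sets(
    table: DETable,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
) -> DEGeneSets:
    """Threshold a DE table into up/down sets (inclusive boundaries).

    ``fc_threshold`` is on the linear fold-change scale (default 1.5, i.e.
    |log2FC| >= log2 1.5); ``p_threshold`` applies to the adjusted p-value.
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1 (linear scale)")
    df = table.data
    log2_cut = math.log2(fc_threshold)
    sig = df["adj_p"] <= p_threshold
    up = frozenset(df.loc[sig & (df["log2fc"] >= log2_cut), "gene"])
    down = frozenset(df.loc[sig & (df["log2fc"] <= -log2_cut), "gene"])
    return DEGeneSets(
        up=up,
        down=down,
        universe=frozenset(df["gene"]),
        dataset_id=table.dataset_id,
    )


def map_to_human(
    symbols: Iterable[str],
    ortholog_map: Mapping[str, str] | None = None,
    drop_mirna: bool = True,
    mirna_prefixes: Sequence[str] = MIRNA_PREFIXES,
) -> set[str]:
    """Map symbols to human symbols; drop unmapped entries and miRNAs.

    Without an ortholog map symbols are simply uppercased (human identity
    mapping).  miRNA identifiers are removed by prefix match (case
    insensitive) because small-RNA datasets are absent from the expression
    compendium being compared against.
    """
    out: set[str] = set()
    for sym in symbols:
        sym = str(sym).strip()
        if not sym:
            continue
        if ortholog_map is not None:
            if sym not in ortholog_map:
                continue
            mapped = ortholog_map[sym].upper()
        else:
            mapped = sym.upper()
        if drop_mirna and any(
            mapped.startswith(p.upper()) for p in mirna_prefixes
        ):
            continue
        out.add(mapped)
    return out


def fisher_overlap(
    query: Iterable[str],
    reference: Iterable[str],
    universe: Iterable[str],
) -> OverlapTestResult:
    """One-sided (enrichment) Fisher exact test of two gene sets' overlap.

    The 2x2 table partitions the universe by membership in ``query`` and in
    ``reference``; p is the upper hypergeometric tail P(X >= k).  The odds
    ratio is the sample (cross-product) ratio, with 0.5 added to every cell
    only when some cell is zero.
    """
    query, reference, universe = set(query), set(reference), set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    if not query <= universe or not reference <= universe:
        raise ValueError("query and reference must be subsets of the universe")
    k = len(query & reference)
    a = k
    b = len(query) - k
    c = len(reference) - k
    d = len(universe) - len(query) - len(reference) + k
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    if min(a, b, c, d) == 0:
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        odds = a * d / (b * c)
    return OverlapTestResult(
        k_overlap=k,
        n_set=len(query),
        n_reference=len(reference),
        n_universe=len(universe),
        odds_ratio=odds,
        p=float(p),
    )


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order-preserving, capped at 1."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh").tolist()


def effect_proportion_test(
    de_set: Iterable[str],
    protective: Iterable[str],
    detrimental: Iterable[str],
) -> ProportionTestResult:
    """Chi-square test of effect class (protective/detrimental) vs DE status.

    Builds the 2x2 table of protective/detrimental genes in and out of
    ``de_set`` and tests independence without continuity correction (1 df).
    A zero row or column margin makes the test undefined; the result is
    flagged ``testable=False`` with NaN statistic and p rather than a silent
    p of 1.
    """
    de_set, protective, detrimental = (
        set(de_set),
        set(protective),
        set(detrimental),
    )
    if protective & detrimental:
        raise ValueError("protective and detrimental sets must be disjoint")
    table = np.array(
        [
            [len(protective & de_set), len(protective - de_set)],
            [len(detrimental & de_set), len(detrimental - de_set)],
        ],
        dtype=float,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return ProportionTestResult(math.nan, math.nan, False, table)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ProportionTestResult(float(chi2), float(p), True, table)


def overlap_effect_matrix(
    datasets: Sequence[DEGeneSets],
    consensus: Mapping[str, Consensus],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-dataset, per-direction overlap composition with significance flags.

    For every dataset x {up, down} cell, counts the overlapping genes in each
    consensus class and tests whether protective and detrimental genes are
    differentially represented in that DE set (chi-square against the
    non-DE remainder of the dataset's universe).  Chi-square p-values are
    BH-adjusted across all cells; ``significant`` marks p_adj <= ``alpha``.
    """
    if not datasets:
        raise ValueError("at least one dataset required")
    protective = {g for g, c in consensus.items() if c is Consensus.PROTECTIVE}
    detrimental = {g for g, c in consensus.items() if c is Consensus.DETRIMENTAL}
    classes = [c.value for c in Consensus]

    rows = []
    for ds in datasets:
        for direction in ("up", "down"):
            genes = getattr(ds, direction)
            labelled = {g: consensus[g] for g in genes if g in consensus}
            row: dict = {
                "dataset": ds.dataset_id,
                "direction": direction,
            }
            for cls in classes:
                row[f"n_{cls}"] = sum(
                    1 for c in labelled.values() if c.value == cls
                )
            universe_labelled_prot = protective & ds.universe
            universe_labelled_detr = detrimental & ds.universe
            test = effect_proportion_test(
                genes, universe_labelled_prot, universe_labelled_detr
            )
            row["chi2"] = test.chi2
            row["p"] = test.p
            row["testable"] = test.testable
            rows.append(row)

    out = pd.DataFrame(rows)
    testable = out["testable"].to_numpy()
    p_adj = np.full(len(out), np.nan)
    if testable.any():
        p_adj[testable] = bh_adjust(out.loc[testable, "p"].tolist())
    out["p_adj"] = p_adj
    out["significant"] = (out["p_adj"] <= alpha).fillna(False)
    return out


def plot_overlap_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Export a basic heatmap of overlap counts (stars mark significance)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    count_cols = [c for c in matrix.columns if c.startswith("n_")]
    labels = matrix["dataset"].astype(str) + ":" + matrix["direction"]
    data = matrix[count_cols].to_numpy(dtype=float)
    fig, ax = plt.subplots(
        figsize=(2 + 0.6 * len(count_cols), 1 + 0.35 * len(matrix))
    )
    im = ax.imshow(data, aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(count_cols)), [c[2:] for c in count_cols], rotation=45)
    starred = [
        f"{lab} *" if sig else lab
        for lab, sig in zip(labels, matrix["significant"])
    ]
    ax.set_yticks(range(len(matrix)), starred, fontsize=7)
    fig.colorbar(im, ax=ax, label="overlap count")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
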