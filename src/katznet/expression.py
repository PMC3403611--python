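"""Cross-platform differential-expression screening and seed assembly.

Two-platform case/control expression is integrated onto the genes common to
all platforms (probe values averaged per gene), then each dataset goes
through a two-stage screen: a fold-change filter on the ratio of group
means (keep ratio <= 0.67 or >= 1.5), followed by a Wilcoxon rank-sum test
on within-sample ranks with Benjamini-Hochberg control at FDR 0.10.  The
union of per-dataset selections, together with causative genes and a
proteomics-derived list, forms the provenance-tagged seed collection used
for network propagation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionDataset",
    "SeedCollection",
    "IntegrationError",
    "harmonize_platforms",
    "fold_change_filter",
    "rank_transform",
    "wilcoxon_rank_sum",
    "fdr_adjust",
    "de_table",
    "select_de_genes",
    "assemble_seeds",
]

GROUP_LABELS = ("case", "control")


class IntegrationError(ValueError):
    """Platforms could not be joined onto a common gene universe."""


@dataclass
class ExpressionDataset:
    """One case/control expression matrix (rows: probes or genes; cols: samples)."""

    platform_id: str
    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.values.columns[self.groups.isna()])
            raise ValueError(f"samples without group labels: {missing[:5]}")
        bad = set(self.groups.unique()) - set(GROUP_LABELS)
        if bad:
            raise ValueError(f"group labels must be in {GROUP_LABELS}, got {sorted(bad)}")
        for label in GROUP_LABELS:
            if not (self.groups == label).any():
                raise ValueError(f"dataset {self.platform_id!r} has no {label} samples")
        if self.values.index.duplicated().any():
            raise ValueError("row identifiers must be unique")

    @property
    def case_columns(self) -> list[str]:
        return list(self.groups.index[self.groups == "case"])

    @property
    def control_columns(self) -> list[str]:
        return list(self.groups.index[self.groups == "control"])


def _map_to_genes(dataset: ExpressionDataset, probe_map: pd.DataFrame) -> pd.DataFrame:
    """Average probe rows per gene; probe_map has columns (probe, gene)."""
    pm = probe_map.set_index("probe")["gene"]
    unmapped = dataset.values.index.difference(pm.index)
    if len(unmapped):
        raise IntegrationError(
            f"platform {dataset.platform_id!r}: {len(unmapped)} probe rows "
            f"have no gene mapping (e.g. {list(unmapped[:3])})"
        )
    genes = pm.reindex(dataset.values.index)
    return dataset.values.groupby(genes.values).mean().sort_index()


def harmonize_platforms(
    datasets: Sequence[ExpressionDataset],
    probe_maps: Mapping[str, pd.DataFrame] | None = None,
) -> list[ExpressionDataset]:
    """Map probes to genes and restrict all datasets to the common genes.

    ``probe_maps`` keys platform ids to (probe, gene) tables; platforms
    without a map are taken to be gene-indexed already.  The output gene
    universe is the intersection of the distinct platforms' mapped genes
    (datasets from the same platform share one gene set).
    """
    if not datasets:
        raise ValueError("no datasets given")
    probe_maps = probe_maps or {}
    gene_level: list[pd.DataFrame] = []
    for ds in datasets:
        if ds.platform_id in probe_maps:
            gene_level.append(_map_to_genes(ds, probe_maps[ds.platform_id]))
        else:
            gene_level.append(ds.values.sort_index())
    platform_genes: dict[str, set[str]] = {}
    for ds, mat in zip(datasets, gene_level):
        platform_genes.setdefault(ds.platform_id, set()).update(mat.index)
    common: set[str] | None = None
    for genes in platform_genes.values():
        common = genes if common is None else common & genes
    assert common is not None
    if not common:
        counts = {p: len(g) for p, g in platform_genes.items()}
        raise IntegrationError(
            f"no genes common to all platforms; per-platform gene counts: {counts}"
        )
    universe = sorted(common)
    return [
        ExpressionDataset(
            platform_id=ds.platform_id,
            values=mat.loc[universe],
            groups=ds.groups,
        )
        for ds, mat in zip(datasets, gene_level)
    ]


def group_mean_ratio(dataset: ExpressionDataset) -> pd.Series:
    """Per-gene ratio of case group mean over control group mean."""
    case_mean = dataset.values[dataset.case_columns].mean(axis=1)
    ctrl_mean = dataset.values[dataset.control_columns].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = case_mean / ctrl_mean
    return ratio


def fold_change_filter(
    dataset: ExpressionDataset, low: float = 0.67, high: float = 1.5
) -> set[str]:
    """Genes whose case/control mean ratio is <= low or >= high.

    Ratios strictly inside (low, high) are filtered out.  A zero control
    mean with nonzero case mean gives ratio +inf (retained, with a
    warning); a gene flat at zero in both groups has no defined ratio and
    is dropped.
    """
    ratio = group_mean_ratio(dataset)
    inf_genes = ratio.index[np.isinf(ratio)]
    if len(inf_genes):
        warnings.warn(
            f"{len(inf_genes)} genes have zero control mean (ratio=+inf); retained",
            stacklevel=2,
        )
    keep = (ratio <= low) | (ratio >= high)
    return set(ratio.index[keep.fillna(False)])


def rank_transform(dataset: ExpressionDataset) -> pd.DataFrame:
    """Replace each sample column by within-column ranks (average-rank ties)."""
    ranked = dataset.values.apply(lambda col: stats.rankdata(col, method="average"), axis=0)
    ranked.index = dataset.values.index
    return ranked


def wilcoxon_rank_sum(case_values: Sequence[float], control_values: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null enumeration when min(n1, n2) <= 8 and the pooled values are
    tie-free; otherwise the normal approximation with tie correction.
    """
    case = np.asarray(case_values, dtype=float)
    ctrl = np.asarray(control_values, dtype=float)
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([case, ctrl])
    if np.ptp(pooled) == 0:
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(case.size, ctrl.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(case, ctrl, alternative="two-sided", method=method)
    return float(min(1.0, res.pvalue))


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_table(
    dataset: ExpressionDataset,
    fdr_level: float = 0.10,
    low: float = 0.67,
    high: float = 1.5,
) -> pd.DataFrame:
    """Two-stage differential-expression screen for one harmonized dataset.

    Stage 1: fold filter on the ratio of raw group means.  Stage 2: on the
    genes that pass, a Wilcoxon rank-sum test of case vs control using
    within-sample ranks over the common genes, BH-adjusted within this
    dataset.  Returns a table with columns gene, mean_ratio, p_value,
    q_value, selected (p and q are NaN for genes removed at stage 1).
    """
    ratio = group_mean_ratio(dataset)
    passed = fold_change_filter(dataset, low=low, high=high)
    ranks = rank_transform(dataset)
    case_cols, ctrl_cols = dataset.case_columns, dataset.control_columns
    genes = list(dataset.values.index)
    p = pd.Series(np.nan, index=genes)
    for g in genes:
        if g in passed:
            p[g] = wilcoxon_rank_sum(ranks.loc[g, case_cols], ranks.loc[g, ctrl_cols])
    q = pd.Series(np.nan, index=genes)
    tested = p.dropna()
    if len(tested):
        q[tested.index] = fdr_adjust(tested.values)
    selected = q.le(fdr_level).fillna(False)
    return pd.DataFrame(
        {
            "gene": genes,
            "mean_ratio": ratio.values,
            "p_value": p.values,
            "q_value": q.values,
            "selected": selected.values,
        }
    )


def select_de_genes(
    datasets: Sequence[ExpressionDataset],
    fdr_level: float = 0.10,
    low: float = 0.67,
    high: float = 1.5,
    pooled_fdr: bool = False,
) -> set[str]:
    """Union over datasets of genes passing the two-stage screen.

    ``pooled_fdr`` switches to a single BH adjustment over the tested genes
    of all datasets instead of per-dataset control.
    """
    if not datasets:
        raise ValueError("no datasets given")
    if not pooled_fdr:
        out: set[str] = set()
        for ds in datasets:
            tab = de_table(ds, fdr_level=fdr_level, low=low, high=high)
            out |= set(tab.loc[tab["selected"], "gene"])
        return out
    # pooled mode: collect per-dataset stage-2 p-values, adjust jointly
    entries: list[tuple[str, float]] = []
    for ds in datasets:
        tab = de_table(ds, fdr_level=1.1, low=low, high=high)  # keep all tested
        tested = tab.dropna(subset=["p_value"])
        entries += list(zip(tested["gene"], tested["p_value"]))
    if not entries:
        return set()
    qvals = fdr_adjust([p for _, p in entries])
    return {g for (g, _), q in zip(entries, qvals) if q <= fdr_level}


@dataclass
class SeedCollection:
    """Disease-active genes tagged by provenance."""

    omim: frozenset[str]
    proteomics: frozenset[str]
    microarray: frozenset[str]

    @property
    def union(self) -> frozenset[str]:
        return self.omim | self.proteomics | self.microarray

    def sources_of(self, gene: str) -> tuple[str, ...]:
        return tuple(
            name
            for name, genes in (
                ("omim", self.omim),
                ("proteomics", self.proteomics),
                ("microarray", self.microarray),
            )
            if gene in genes
        )

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "source": src}
            for src, genes in (
                ("omim", self.omim),
                ("proteomics", self.proteomics),
                ("microarray", self.microarray),
            )
            for g in sorted(genes)
        ]
        return pd.DataFrame(rows, columns=["gene", "source"])


def assemble_seeds(
    omim_genes: Iterable[str],
    proteomics_genes: Iterable[str],
    de_genes: Iterable[str],
) -> SeedCollection:
    """Combine causative, proteomics and microarray-derived genes.

    Overlap between sources is structurally allowed; the union counts each
    gene once (disjoint lists of sizes 7, 42 and 119 give a 168-gene pool).
    """
    return SeedCollection(
        omim=frozenset(omim_genes),
        proteomics=frozenset(proteomics_genes),
        microarray=frozenset(de_genes),
    )
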