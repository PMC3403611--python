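"""Synthetic inputs with planted ground truth for the whole pipeline.

The generators emulate the statistical structure of the study's real
inputs — a weighted interactome with a dense high-confidence disease
module, two-platform case/control expression with fold-change effects at
planted genes, locus tables placing held-out causative genes among ~100
chromosomal neighbors, and annotation collections containing one term
drawn from the planted module — without imitating any real database's
idiosyncrasies.  Every generator is driven by per-stage child streams of
one scenario seed, so outputs are bit-for-bit reproducible and independent
of the order in which generators are called.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import sparse

from .enrich import GeneSetCollection
from .expression import ExpressionDataset
from .prioritize import WeightedNetwork

__all__ = [
    "SyntheticScenario",
    "GroundTruthManifest",
    "PlatformExpression",
    "generate_network",
    "generate_expression",
    "generate_loci",
    "generate_annotations",
    "generate_abundance",
    "generate_reference_sets",
    "write_scenario_inputs",
]

# rng stream tags, one per generator stage
_STREAM_LAYOUT = 0
_STREAM_NETWORK = 1
_STREAM_EXPRESSION = 2
_STREAM_LOCI = 3
_STREAM_ANNOTATIONS = 4
_STREAM_ABUNDANCE = 5
_STREAM_REFERENCE = 6


@dataclass
class SyntheticScenario:
    """Ground-truth description of one synthetic study.

    Defaults are the reference conditions used throughout the test suite:
    a 2000-gene universe with a 50-gene planted disease module, 5 held-out
    causative genes and 25 seeds (10 proteomics-like, 15 expression-like),
    2-fold expression effects at the expression-derived seeds with
    lognormal noise (sd 0.3 on the log scale), 12 cases vs 12 controls per
    platform, module edges at density 0.6 with weights U(0.6, 1.0) against
    a U(0.1, 0.5)-weighted background at density 0.01 (so the 0.5
    confidence floor separates module from background nontrivially).
    """

    n_genes: int = 2000
    n_module: int = 50
    n_omim: int = 5
    n_proteomics: int = 10
    n_microarray: int = 15
    within_module_weight: tuple[float, float] = (0.6, 1.0)
    background_weight: tuple[float, float] = (0.1, 0.5)
    edge_density_in: float = 0.6
    edge_density_out: float = 0.01
    de_effect: float = 2.0
    n_case: int = 12
    n_control: int = 12
    noise_sd: float = 0.3
    platform_overlap: float = 0.9
    probes_per_gene_max: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.edge_density_out <= 1 and 0 <= self.edge_density_in <= 1):
            raise ValueError("edge densities must lie in [0, 1]")
        if self.edge_density_in <= self.edge_density_out:
            raise ValueError("edge_density_in must exceed edge_density_out")
        if self.n_module > self.n_genes:
            raise ValueError("planted module larger than the gene universe")
        if self.n_module < 2:
            raise ValueError("planted module needs at least 2 genes")
        if self.n_omim + self.n_proteomics + self.n_microarray > self.n_module:
            raise ValueError("source splits exceed the module size")
        if self.de_effect < 1:
            raise ValueError("de_effect must be >= 1 (fold-change multiplier)")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 case and 2 control samples")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for lo, hi in (self.within_module_weight, self.background_weight):
            if not (0 <= lo <= hi <= 1):
                raise ValueError("weight distribution bounds must satisfy 0 <= lo <= hi <= 1")
        if not 0 < self.platform_overlap <= 1:
            raise ValueError("platform_overlap must lie in (0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.rng_seed), stream])

    @cached_property
    def genes(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    @cached_property
    def _layout(self) -> dict[str, tuple[str, ...]]:
        rng = self.rng(_STREAM_LAYOUT)
        module = rng.choice(self.n_genes, size=self.n_module, replace=False)
        module_genes = tuple(self.genes[i] for i in np.sort(module))
        shuffled = list(module_genes)
        rng.shuffle(shuffled)
        a, b = self.n_omim, self.n_omim + self.n_proteomics
        c = b + self.n_microarray
        return {
            "module": module_genes,
            "omim": tuple(sorted(shuffled[:a])),
            "proteomics": tuple(sorted(shuffled[a:b])),
            "microarray": tuple(sorted(shuffled[b:c])),
        }

    @property
    def module_genes(self) -> tuple[str, ...]:
        return self._layout["module"]

    @property
    def omim_genes(self) -> tuple[str, ...]:
        """Held-out causative genes (excluded from the seeds until after calibration)."""
        return self._layout["omim"]

    @property
    def proteomics_genes(self) -> tuple[str, ...]:
        return self._layout["proteomics"]

    @property
    def microarray_genes(self) -> tuple[str, ...]:
        """Module genes carrying the planted expression effect."""
        return self._layout["microarray"]

    @property
    def seed_genes(self) -> tuple[str, ...]:
        return tuple(sorted(self.proteomics_genes + self.microarray_genes))


@dataclass
class GroundTruthManifest:
    """What was planted, for checking recovery downstream."""

    scenario: SyntheticScenario
    held_out_disease_genes: frozenset[str]
    enriched_term_ids: frozenset[str]
    de_gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.held_out_disease_genes & set(self.scenario.seed_genes):
            raise ValueError("held-out disease genes must be disjoint from the seeds")


def generate_network(scenario: SyntheticScenario) -> WeightedNetwork:
    """Planted-module weighted network.

    Module gene pairs connect at ``edge_density_in`` with weights from the
    within-module distribution; all other pairs at ``edge_density_out``
    with background weights.  The matrix is symmetric with zero diagonal.
    """
    rng = scenario.rng(_STREAM_NETWORK)
    n = scenario.n_genes
    gene_index = {g: i for i, g in enumerate(scenario.genes)}
    module_idx = np.array([gene_index[g] for g in scenario.module_genes])
    in_module = np.zeros(n, dtype=bool)
    in_module[module_idx] = True

    iu, ju = np.triu_indices(n, k=1)
    pair_in = in_module[iu] & in_module[ju]
    u = rng.random(iu.size)
    lo_in, hi_in = scenario.within_module_weight
    lo_bg, hi_bg = scenario.background_weight
    w = rng.uniform(lo_bg, hi_bg, size=iu.size)
    w[pair_in] = rng.uniform(lo_in, hi_in, size=int(pair_in.sum()))
    density = np.where(pair_in, scenario.edge_density_in, scenario.edge_density_out)
    keep = u < density
    rows, cols, vals = iu[keep], ju[keep], w[keep]
    W = sparse.csr_array(
        (
            np.concatenate([vals, vals]),
            (np.concatenate([rows, cols]), np.concatenate([cols, rows])),
        ),
        shape=(n, n),
    )
    return WeightedNetwork(genes=list(scenario.genes), W=W)


@dataclass
class PlatformExpression:
    """Probe-level expression for one platform plus its probe-to-gene map."""

    dataset: ExpressionDataset
    probe_map: pd.DataFrame  # columns: probe, gene


def generate_expression(scenario: SyntheticScenario) -> list[PlatformExpression]:
    """Two platform-tagged probe-level expression matrices.

    Each gene's control-group level is lognormal; planted genes (the
    expression-derived seed subset) are multiplied by ``de_effect`` in
    cases.  Every probe observes its gene's per-sample level under
    multiplicative lognormal noise, and genes carry 1..probes_per_gene_max
    probes.  The two platforms share the module genes plus a
    ``platform_overlap`` fraction of the remaining genes; leftover genes
    are split between the platforms, so the common-gene intersection is a
    strict subset of either platform when overlap < 1.
    """
    rng = scenario.rng(_STREAM_EXPRESSION)
    genes = list(scenario.genes)
    module = set(scenario.module_genes)
    de_genes = set(scenario.microarray_genes)

    others = [g for g in genes if g not in module]
    n_shared_others = int(np.floor(scenario.platform_overlap * len(others)))
    perm = rng.permutation(len(others))
    shared = sorted(module | {others[i] for i in perm[:n_shared_others]})
    leftover = [others[i] for i in perm[n_shared_others:]]
    extras = (leftover[0::2], leftover[1::2])

    baseline = pd.Series(rng.lognormal(mean=5.0, sigma=1.0, size=len(genes)), index=genes)
    out: list[PlatformExpression] = []
    for p, extra in enumerate(extras, start=1):
        platform = f"platform{p}"
        covered = sorted(set(shared) | set(extra))
        samples = [f"{platform}_case{i+1}" for i in range(scenario.n_case)] + [
            f"{platform}_ctrl{i+1}" for i in range(scenario.n_control)
        ]
        groups = pd.Series(
            ["case"] * scenario.n_case + ["control"] * scenario.n_control, index=samples
        )
        n_probes = rng.integers(1, scenario.probes_per_gene_max + 1, size=len(covered))
        probe_ids, probe_genes = [], []
        for g, np_g in zip(covered, n_probes):
            for a in range(int(np_g)):
                probe_ids.append(f"{platform}_{g}_p{a+1}")
                probe_genes.append(g)
        effect = np.array(
            [scenario.de_effect if g in de_genes else 1.0 for g in probe_genes]
        )
        base = baseline[probe_genes].to_numpy()
        n_s = len(samples)
        is_case = (groups == "case").to_numpy()
        true_level = np.outer(base, np.ones(n_s))
        true_level[:, is_case] *= effect[:, None]
        noise = (
            np.exp(rng.normal(0.0, scenario.noise_sd, size=true_level.shape))
            if scenario.noise_sd > 0
            else 1.0
        )
        values = pd.DataFrame(true_level * noise, index=probe_ids, columns=samples)
        out.append(
            PlatformExpression(
                dataset=ExpressionDataset(platform_id=platform, values=values, groups=groups),
                probe_map=pd.DataFrame({"probe": probe_ids, "gene": probe_genes}),
            )
        )
    return out


def generate_loci(
    scenario: SyntheticScenario,
    held_out_genes: Iterable[str] | None = None,
    genes_per_locus: int = 100,
) -> pd.DataFrame:
    """BED-like locus table placing each held-out gene among ~N neighbors.

    Each held-out gene gets its own chromosome with ``genes_per_locus - 1``
    neighbors sampled (without replacement across loci) from the rest of
    the universe, at strictly increasing coordinates; the disease gene sits
    mid-region.  Loci therefore never overlap.
    """
    rng = scenario.rng(_STREAM_LOCI)
    held_out = list(held_out_genes) if held_out_genes is not None else list(scenario.omim_genes)
    if not held_out:
        raise ValueError("held_out_genes is empty")
    if genes_per_locus < 1:
        raise ValueError("genes_per_locus must be >= 1")
    pool = [g for g in scenario.genes if g not in set(held_out)]
    needed = len(held_out) * (genes_per_locus - 1)
    if needed > len(pool):
        raise ValueError(
            f"universe too small: need {needed} neighbor genes, have {len(pool)}"
        )
    chosen = rng.choice(len(pool), size=needed, replace=False)
    rows = []
    for li, gene in enumerate(held_out):
        neighbors = [pool[i] for i in chosen[li * (genes_per_locus - 1):(li + 1) * (genes_per_locus - 1)]]
        locus_genes = neighbors[: (genes_per_locus - 1) // 2] + [gene] + neighbors[(genes_per_locus - 1) // 2:]
        for pos, g in enumerate(locus_genes):
            start = 1000 * pos
            rows.append({"chrom": f"chr{li + 1}", "start": start, "end": start + 500, "gene": g})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def generate_annotations(
    scenario: SyntheticScenario,
    n_terms: int = 50,
    term_size_range: tuple[int, int] = (10, 200),
    planted_term_size: int | None = None,
) -> tuple[GeneSetCollection, GroundTruthManifest]:
    """Gene-set collection with one term planted inside the disease module.

    The planted term (id ``TERM0000``) is drawn entirely from module genes
    (by default all of them); the remaining ``n_terms - 1`` terms are
    uniform draws from the whole universe with sizes uniform on
    ``term_size_range``.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    lo, hi = term_size_range
    if not 1 <= lo <= hi <= scenario.n_genes:
        raise ValueError("term sizes must satisfy 1 <= lo <= hi <= n_genes")
    rng = scenario.rng(_STREAM_ANNOTATIONS)
    module = list(scenario.module_genes)
    size0 = planted_term_size if planted_term_size is not None else len(module)
    if not 1 <= size0 <= len(module):
        raise ValueError("planted_term_size must be within the module size")
    planted = sorted(rng.choice(module, size=size0, replace=False)) if size0 < len(module) else module
    terms: dict[str, tuple[str, frozenset[str]]] = {
        "TERM0000": ("planted disease-module term", frozenset(planted))
    }
    for t in range(1, n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(scenario.n_genes, size=size, replace=False)
        terms[f"TERM{t:04d}"] = (
            f"background term {t}",
            frozenset(scenario.genes[i] for i in members),
        )
    collection = GeneSetCollection(terms=terms)
    manifest = GroundTruthManifest(
        scenario=scenario,
        held_out_disease_genes=frozenset(scenario.omim_genes),
        enriched_term_ids=frozenset({"TERM0000"}),
        de_gene_ids=frozenset(scenario.microarray_genes),
    )
    return collection, manifest


def generate_abundance(
    scenario: SyntheticScenario, coverage: float = 0.75
) -> dict[str, str]:
    """Tissue-abundance table over a random ``coverage`` fraction of genes.

    Covered genes get a level on the four-level scale with weights
    (0.25 negative, 0.35 weak, 0.25 moderate, 0.15 strong), loosely shaped
    like a single-tissue protein-abundance profile.
    """
    if not 0 <= coverage <= 1:
        raise ValueError("coverage must lie in [0, 1]")
    rng = scenario.rng(_STREAM_ABUNDANCE)
    n_cov = int(round(coverage * scenario.n_genes))
    covered = rng.choice(scenario.n_genes, size=n_cov, replace=False)
    levels = rng.choice(
        ["negative", "weak", "moderate", "strong"],
        size=n_cov,
        p=[0.25, 0.35, 0.25, 0.15],
    )
    return {scenario.genes[i]: lv for i, lv in zip(sorted(covered), levels)}


def generate_reference_sets(
    scenario: SyntheticScenario,
    background_fraction: float = 0.10,
    n_drug_targets: int = 10,
) -> dict[str, tuple[str, ...]]:
    """Reference gene sets enriched in the planted module.

    ``innate_like``: all module genes plus a ``background_fraction`` sample
    of the rest (emulates an immune-reference network whose members
    over-represent the disease module).  ``drug_target_like``: half module,
    half background genes.
    """
    rng = scenario.rng(_STREAM_REFERENCE)
    module = set(scenario.module_genes)
    others = [g for g in scenario.genes if g not in module]
    n_bg = int(round(background_fraction * len(others)))
    bg = rng.choice(len(others), size=n_bg, replace=False)
    innate = tuple(sorted(module | {others[i] for i in bg}))
    half = n_drug_targets // 2
    targets_mod = rng.choice(sorted(module), size=min(half, len(module)), replace=False)
    targets_bg = rng.choice(others, size=n_drug_targets - len(targets_mod), replace=False)
    return {
        "innate_like": innate,
        "drug_target_like": tuple(sorted(set(targets_mod) | set(targets_bg))),
    }


def write_scenario_inputs(
    scenario: SyntheticScenario,
    out_dir,
    genes_per_locus: int = 100,
    n_terms: int = 50,
) -> "object":
    """Materialize every pipeline input for a scenario and return a ready config.

    Writes the STRING-style edge list, per-platform expression/probe-map/
    group TSVs, the locus BED, GMT annotations, seed-source gene lists,
    abundance and reference tables, the ground-truth manifest, and a
    ``config.yaml`` wired to all of them.
    """
    from pathlib import Path

    import yaml

    from . import io
    from .config import PipelineConfig, PlatformPaths

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    net = generate_network(scenario)
    io.write_weighted_network(net, out / "network.tsv")

    platform_paths = []
    for pe in generate_expression(scenario):
        pid = pe.dataset.platform_id
        io.write_expression(pe.dataset, out / f"expr_{pid}.tsv", out / f"groups_{pid}.tsv")
        pe.probe_map.to_csv(out / f"probemap_{pid}.tsv", sep="\t", index=False)
        platform_paths.append(
            PlatformPaths(
                platform_id=pid,
                values=str(out / f"expr_{pid}.tsv"),
                groups=str(out / f"groups_{pid}.tsv"),
                probe_map=str(out / f"probemap_{pid}.tsv"),
            )
        )

    loci = generate_loci(scenario, genes_per_locus=genes_per_locus)
    io.write_loci(loci, out / "loci.bed")

    collection, manifest = generate_annotations(scenario, n_terms=n_terms)
    io.write_gmt(collection, out / "annotations.gmt")

    io.write_gene_list(sorted(scenario.omim_genes), out / "omim.txt")
    io.write_gene_list(sorted(scenario.proteomics_genes), out / "proteomics.txt")

    abundance = generate_abundance(scenario)
    io.write_abundance_table(abundance, out / "abundance.tsv")
    refs = generate_reference_sets(scenario)
    io.write_gene_list(refs["innate_like"], out / "reference_innate.txt")
    io.write_gene_list(refs["drug_target_like"], out / "drug_targets.txt")

    truth = {
        "held_out_disease_genes": sorted(manifest.held_out_disease_genes),
        "enriched_term_ids": sorted(manifest.enriched_term_ids),
        "de_gene_ids": sorted(manifest.de_gene_ids),
        "module_genes": sorted(scenario.module_genes),
        "seed_genes": sorted(scenario.seed_genes),
        "rng_seed": scenario.rng_seed,
    }
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)

    config = PipelineConfig(
        network_path=str(out / "network.tsv"),
        expression=platform_paths,
        omim_path=str(out / "omim.txt"),
        proteomics_path=str(out / "proteomics.txt"),
        loci_path=str(out / "loci.bed"),
        gmt_path=str(out / "annotations.gmt"),
        abundance_path=str(out / "abundance.tsv"),
        reference_network_path=str(out / "reference_innate.txt"),
        drug_targets_path=str(out / "drug_targets.txt"),
        out_dir=str(out / "results"),
        n_candidates=genes_per_locus,
        rng_seed=scenario.rng_seed,
    )
    config.to_yaml(out / "config.yaml")
    return config
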