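"""Synthetic study generator with the statistical structure the pipeline assumes.

A generated study emulates a two-cohort biomarker-discovery design:

* a *test cohort* of two EF-defined groups (default 16 vs 16) profiled on a
  ~25,000-gene two-channel array (log2 ratios, missing completely at random),
  with a planted differentially expressed subset whose per-gene fold changes
  start at the calling threshold (default 1.3);
* an angiogenesis-style annotation list (default 494 genes) overlapping the
  planted DE set by a configured amount (default 28, split 20 up-in-low /
  8 up-in-high);
* a sparse protein-interaction network (default 441 nodes) with planted
  near-clique modules, the first of which contains a planted predictive trio
  of strongly DE genes (2 noise-SD shift), mirroring the shape of a
  three-gene prognostic panel sitting inside one interaction cluster;
* a *validation cohort* (default 115 patients, 61 low EF / 54 high EF) whose
  clinical covariates and a designated biomarker are tied to EF through a
  Gaussian copula at the configured Spearman targets.

Everything is reproducible from ``config.seed``; stage-specific generators
use fixed offsets from it so individual operations are independently
re-runnable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .de import GeneSet

# fixed seed offsets so each stage is individually reproducible
_EXPR_OFF, _ANNOT_OFF, _NET_OFF, _CLIN_OFF = 0, 1, 2, 3

DEFAULT_CLINICAL_TARGETS = MappingProxyType({
    "age": -0.35,
    "sex": 0.20,
    "time_to_reperfusion": -0.26,
    "tnt": -0.25,
    "cpk": -0.25,
    "biomarker": -0.28,
})


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design constants for one synthetic study.

    Defaults encode the emulated study design: 16 + 16 test-cohort patients,
    25,000 genes with 525 planted DE genes at >= 1.3 linear fold change
    (299 up in the low-EF group), a 494-gene annotation overlapping the DE
    set by 28 (20 up-in-low / 8 up-in-high), a 441-node interactome with
    planted dense modules, a 3-gene predictive trio at a 2-SD expression
    shift, and a 115-patient validation cohort (61 low / 54 high EF) with
    Spearman-anchored clinical covariates.
    """

    n_genes: int = 25000
    n_high: int = 16
    n_low: int = 16
    n_de: int = 525
    fold_change: float = 1.3
    de_effect_log2_max: float = 1.0
    de_up_in_low_frac: float = 299 / 525
    noise_sd: float = 0.4
    missing_rate: float = 0.05
    n_annotated: int = 494
    n_overlap: int = 28
    overlap_direction: tuple | None = (20, 8)
    n_nodes: int = 441
    module_sizes: tuple = (16, 12, 9)
    module_edge_prob: float = 0.95
    background_edge_prob: float = 0.0025
    plant_trio: bool = True
    trio_effect_sd: float = 2.0
    n_validation_low: int = 61
    n_validation_high: int = 54
    clinical_targets: dict = field(default_factory=lambda: dict(DEFAULT_CLINICAL_TARGETS))
    seed: int = 0

    def __post_init__(self):
        if self.n_high < 1 or self.n_low < 1:
            raise ValueError("group sizes must be positive")
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must lie in [0, 1]")
        if not 0 <= self.background_edge_prob <= 1:
            raise ValueError("background_edge_prob must lie in [0, 1]")
        if not 0 <= self.module_edge_prob <= 1:
            raise ValueError("module_edge_prob must lie in [0, 1]")
        if self.n_de > self.n_genes:
            raise ValueError("n_de exceeds n_genes")
        if self.n_annotated > self.n_genes:
            raise ValueError("n_annotated exceeds n_genes")
        if self.n_overlap > min(self.n_de, self.n_annotated):
            raise ValueError("n_overlap exceeds min(n_de, n_annotated)")
        if self.overlap_direction is not None and sum(self.overlap_direction) != self.n_overlap:
            raise ValueError("overlap_direction must sum to n_overlap")
        if sum(self.module_sizes) > self.n_nodes:
            raise ValueError("module sizes exceed the number of network nodes")
        if self.n_nodes > self.n_genes:
            raise ValueError("n_nodes exceeds n_genes")
        for name, rho in self.clinical_targets.items():
            if abs(rho) >= 1:
                raise ValueError(f"|target correlation| for {name!r} must be < 1")

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index([f"G{i:05d}" for i in range(self.n_genes)], name="gene_id")

    def _trio_planted(self) -> bool:
        n_up = self._n_de_up_in_low()
        return (self.plant_trio and n_up >= 3 and self.n_de >= 3
                and len(self.module_sizes) > 0 and self.module_sizes[0] >= 3)

    def _n_de_up_in_low(self) -> int:
        return int(round(self.n_de * self.de_up_in_low_frac))


@dataclass
class StudyTruth:
    """Planted ground truth, sufficient to score recovery downstream."""

    de: pd.DataFrame  # index gene_id; columns direction, effect_log2
    trio: list
    modules: list
    annotation_overlap: list


@dataclass
class SyntheticStudy:
    """One generated study: expression, cohorts, annotation, network, truth."""

    config: SimulationConfig
    expression: pd.DataFrame
    samples: pd.DataFrame
    annotation: GeneSet
    network: nx.Graph
    validation: pd.DataFrame
    truth: StudyTruth


# ---------------------------------------------------------------------------
# expression + test cohort
# ---------------------------------------------------------------------------

def _plant_de(config: SimulationConfig, rng: np.random.Generator) -> StudyTruth:
    genes = config.gene_ids
    de_genes = rng.choice(config.n_genes, size=config.n_de, replace=False)
    de_genes = genes[np.sort(de_genes)]
    n_up = config._n_de_up_in_low()
    direction = np.array(["up-in-low"] * n_up + ["up-in-high"] * (config.n_de - n_up))
    lo = np.log2(config.fold_change)
    hi = max(lo, config.de_effect_log2_max)
    effects = lo + rng.random(config.n_de) * (hi - lo)
    trio: list = []
    if config._trio_planted():
        trio = list(de_genes[:3])
        effects[:3] = config.trio_effect_sd * config.noise_sd
    de = pd.DataFrame({"direction": direction, "effect_log2": effects}, index=de_genes)
    return StudyTruth(de=de, trio=trio, modules=[], annotation_overlap=[])


def simulate_expression(config: SimulationConfig, seed: int | None = None):
    """Genes x samples log2-ratio matrix plus the test-cohort sample table.

    Non-DE genes have class-independent mean 0; each planted gene's class
    means are shifted apart by its effect (split +/- half between classes,
    signed by its direction).  Entries go missing independently at
    ``missing_rate``.  EF is uniform within the class ranges 45-73 % (high)
    and 20-40 % (low).

    Returns ``(expression, samples, truth)``.
    """
    rng = np.random.default_rng(config.seed + _EXPR_OFF if seed is None else seed)
    truth = _plant_de(config, rng)
    n = config.n_high + config.n_low
    x = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n))
    low_cols = np.arange(config.n_low)  # low-EF samples first
    high_cols = np.arange(config.n_low, n)

    genes = config.gene_ids
    pos = pd.Series(np.arange(config.n_genes), index=genes)
    de_rows = pos[truth.de.index].to_numpy()
    sign = np.where(truth.de["direction"].to_numpy() == "up-in-low", 1.0, -1.0)
    half = 0.5 * sign * truth.de["effect_log2"].to_numpy()
    x[np.ix_(de_rows, low_cols)] += half[:, None]
    x[np.ix_(de_rows, high_cols)] -= half[:, None]

    if config.missing_rate > 0:
        x[rng.random(x.shape) < config.missing_rate] = np.nan

    sample_ids = ([f"T{i:02d}_low" for i in range(config.n_low)]
                  + [f"T{i:02d}_high" for i in range(config.n_high)])
    ef = np.concatenate([
        rng.uniform(20.0, 40.0, size=config.n_low),
        rng.uniform(45.0, 73.0, size=config.n_high),
    ])
    samples = pd.DataFrame(
        {
            "ef_percent": ef,
            "ef_class": ["low"] * config.n_low + ["high"] * config.n_high,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    expression = pd.DataFrame(x, index=genes, columns=samples.index)
    return expression, samples, truth


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimulationConfig, truth: StudyTruth,
                        seed: int | None = None) -> GeneSet:
    """Annotation gene set of size ``n_annotated`` with a planted DE overlap.

    The overlap honours ``overlap_direction`` (counts up-in-low / up-in-high)
    when set, and always includes the planted trio; the remaining members are
    sampled from non-DE genes.  Records the overlap in ``truth``.
    """
    rng = np.random.default_rng(config.seed + _ANNOT_OFF if seed is None else seed)
    de = truth.de
    up_low = [g for g in de.index if de.loc[g, "direction"] == "up-in-low"]
    up_high = [g for g in de.index if de.loc[g, "direction"] == "up-in-high"]

    if config.overlap_direction is not None:
        want_low, want_high = config.overlap_direction
    else:
        want_low = min(len(up_low), config.n_overlap)
        want_high = config.n_overlap - want_low
    if want_low > len(up_low) or want_high > len(up_high):
        raise ValueError("requested overlap direction counts exceed planted DE genes")

    chosen_low = list(truth.trio)
    pool_low = [g for g in up_low if g not in chosen_low]
    extra = want_low - len(chosen_low)
    if extra < 0:
        raise ValueError("overlap too small to contain the planted trio")
    chosen_low += [str(g) for g in rng.choice(pool_low, size=extra, replace=False)] if extra else []
    chosen_high = [str(g) for g in rng.choice(up_high, size=want_high, replace=False)] if want_high else []
    overlap = chosen_low + chosen_high

    non_de = config.gene_ids.difference(de.index)
    n_rest = config.n_annotated - len(overlap)
    if n_rest > len(non_de):
        raise ValueError("not enough non-DE genes to fill the annotation set")
    rest = [str(g) for g in rng.choice(non_de.to_numpy(), size=n_rest, replace=False)] if n_rest else []
    truth.annotation_overlap = sorted(overlap)
    return GeneSet(name="angiogenesis", genes=frozenset(overlap) | frozenset(rest),
                   description="synthetic annotation gene set")


# ---------------------------------------------------------------------------
# interactome
# ---------------------------------------------------------------------------

def simulate_interactome(config: SimulationConfig, gene_ids, truth: StudyTruth | None = None,
                         annotation: GeneSet | None = None, seed: int | None = None) -> nx.Graph:
    """Sparse background interactome with planted near-clique modules.

    The first planted module contains the predictive trio; the remaining
    module members are drawn from annotated non-DE genes when an annotation
    is supplied (interaction partners need not be differentially expressed),
    else from arbitrary genes.  Module membership is recorded in ``truth``.
    """
    rng = np.random.default_rng(config.seed + _NET_OFF if seed is None else seed)
    gene_ids = pd.Index(gene_ids)
    if max(config.module_sizes, default=0) > len(gene_ids):
        raise ValueError("module sizes exceed the number of genes")
    truth = truth if truth is not None else StudyTruth(
        de=pd.DataFrame(columns=["direction", "effect_log2"]), trio=[], modules=[],
        annotation_overlap=[])

    de_set = set(truth.de.index)
    if annotation is not None:
        member_pool = [g for g in sorted(annotation.genes) if g not in de_set]
    else:
        member_pool = [g for g in gene_ids if g not in de_set]

    modules = []
    used: set = set(truth.trio)
    for i, size in enumerate(config.module_sizes):
        members = list(truth.trio) if (i == 0 and truth.trio) else []
        pool = [g for g in member_pool if g not in used]
        need = size - len(members)
        if need > len(pool):
            raise ValueError("not enough genes to fill planted modules")
        members += [str(g) for g in rng.choice(pool, size=need, replace=False)] if need else []
        used.update(members)
        modules.append(sorted(members))
    truth.modules = modules

    node_set = set().union(*modules) if modules else set()
    node_set |= set(truth.annotation_overlap)
    fill_pool = [g for g in gene_ids if g not in node_set]
    n_fill = config.n_nodes - len(node_set)
    if n_fill < 0:
        raise ValueError("n_nodes smaller than the planted/overlap genes")
    nodes = sorted(node_set) + ([str(g) for g in rng.choice(fill_pool, size=n_fill, replace=False)]
                                if n_fill else [])
    nodes = sorted(nodes)

    g = nx.Graph()
    g.add_nodes_from(nodes)
    arr = np.array(nodes, dtype=object)
    n = len(arr)
    if config.background_edge_prob > 0 and n > 1:
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(len(iu)) < config.background_edge_prob
        g.add_edges_from(zip(arr[iu[mask]], arr[ju[mask]]))
    for members in modules:
        marr = np.array(members, dtype=object)
        iu, ju = np.triu_indices(len(marr), k=1)
        mask = rng.random(len(iu)) < config.module_edge_prob
        g.add_edges_from(zip(marr[iu[mask]], marr[ju[mask]]))
    return g


# ---------------------------------------------------------------------------
# validation cohort (clinical covariates via a Gaussian copula)
# ---------------------------------------------------------------------------

def _latent_from_spearman(rho_s: float) -> float:
    """Latent Pearson correlation reproducing a Spearman target (continuous margins)."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)

def _binary_inflation(p: float) -> float:
    """Attenuation correction for a thresholded (binary) copula margin."""
    c = sps.norm.ppf(1.0 - p)
    return float(np.sqrt(p * (1.0 - p)) / sps.norm.pdf(c))


def _truncated_lognorm_ppf(u, sigma, scale, lower, upper):
    lo = sps.lognorm.cdf(lower, s=sigma, scale=scale)
    hi = sps.lognorm.cdf(upper, s=sigma, scale=scale)
    return sps.lognorm.ppf(lo + u * (hi - lo), s=sigma, scale=scale)


_P_FEMALE = 0.15  # ~85 % male, as in both cohorts

# marginal shapes for the validation cohort (medians/ranges motivate the scales)
_MARGINALS = {
    "age": lambda u: sps.truncnorm.ppf(u, (32 - 60) / 12, (90 - 60) / 12, loc=60, scale=12),
    "time_to_reperfusion": lambda u: _truncated_lognorm_ppf(u, 0.6, 3.5, 0.25, 12.0),
    "tnt": lambda u: _truncated_lognorm_ppf(u, 1.2, 4.76, 0.03, 26.1),
    "cpk": lambda u: _truncated_lognorm_ppf(u, 0.8, 1978.0, 602.0, 9383.0),
    "biomarker": lambda u: sps.lognorm.ppf(u, s=0.5, scale=1.0),
}


def simulate_clinical(config: SimulationConfig, n: int | None = None,
                      seed: int | None = None) -> pd.DataFrame:
    """Validation-style sample table with Spearman-anchored covariates.

    EF and the covariates share a Gaussian copula whose latent correlations
    are chosen so the observed Spearman correlations with EF approximate
    ``config.clinical_targets`` (binary sex gets an analytic attenuation
    correction).  EF values are assigned rank-monotonically: the lowest
    ``n_low`` latent ranks get EF in [15, 40] and the rest in (40, 86], so
    class counts are exact.
    """
    rng = np.random.default_rng(config.seed + _CLIN_OFF if seed is None else seed)
    base_low, base_high = config.n_validation_low, config.n_validation_high
    if n is None:
        n_low, n_high = base_low, base_high
    else:
        n_low = int(round(n * base_low / (base_low + base_high)))
        n_high = n - n_low
    n_tot = n_low + n_high
    if n_low < 1 or n_high < 1:
        raise ValueError("both EF classes must be non-empty")

    names = list(config.clinical_targets)
    latent = []
    for name in names:
        rho = config.clinical_targets[name]
        if name == "sex":
            r = np.clip(rho * _binary_inflation(_P_FEMALE), -0.99, 0.99)
        else:
            r = _latent_from_spearman(rho)
        latent.append(r)
    k = len(names) + 1
    corr = np.eye(k)
    corr[0, 1:] = latent
    corr[1:, 0] = latent
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n_tot, k)) @ chol.T

    # EF: rank-monotone mixture of the two class ranges
    order = np.argsort(np.argsort(z[:, 0], kind="stable"), kind="stable")
    ef_low = np.sort(rng.uniform(15.0, 40.0, size=n_low))
    ef_high = np.sort(rng.uniform(40.0 + 1e-9, 86.0, size=n_high))
    ef_sorted = np.concatenate([ef_low, ef_high])
    ef = ef_sorted[order]

    data = {"ef_percent": ef,
            "ef_class": np.where(ef <= 40.0, "low", "high")}
    for j, name in enumerate(names, start=1):
        u = sps.norm.cdf(z[:, j])
        if name == "sex":
            data["sex"] = np.where(u > 1.0 - _P_FEMALE, "female", "male")
        else:
            data[name] = _MARGINALS[name](u)
    return pd.DataFrame(data, index=pd.Index([f"V{i:03d}" for i in range(n_tot)],
                                             name="sample_id"))


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a complete study (expression, annotation, network, validation)."""
    expression, samples, truth = simulate_expression(config)
    annotation = simulate_annotation(config, truth)
    network = simulate_interactome(config, expression.index, truth, annotation)
    validation = simulate_clinical(config)
    return SyntheticStudy(config=config, expression=expression, samples=samples,
                          annotation=annotation, network=network,
                          validation=validation, truth=truth)
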