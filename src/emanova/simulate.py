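"""Synthetic microbiome studies: sparse tables, trees, outcomes, replicates.

The generator emulates the statistical structure of a 16S/WGS case study:
a random birth-death phylogeny on K OTUs, sparse compositional abundance
tables from a zero-inflated Dirichlet-multinomial (lognormal base
composition, overdispersed per-sample Dirichlet draws, lognormal library
sizes, dropout calibrated to a target zero fraction), and outcomes tied to
the standardized aggregate abundance of an associated OTU set A:

    continuous:  y_i = 0.5 X1_i + 0.5 X2_i + beta * f(scale(sum_{k in A} Z_ik)) + eps_i
    binary:      logit(p_i) = 0.5 X1_i + 0.5 X2_i + beta * f(scale(sum_{k in A} Z_ik))

with f the identity (S1, S2), the real signed cube root (S3, diminishing
effect) or the sine (S4, periodic effect).  Scenarios S1/S3 pick A as a
phylogenetic cluster (20 average-linkage clusters of the patristic distance
matrix); S2/S4 pick the most abundant OTUs.  ``beta = 0`` defines the null.
"""

from __future__ import annotations

import random as _pyrandom
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import expit

from .ensemble import DEFAULT_D, DEFAULT_R, emanova
from .io_formats import AbundanceTable, PhyloTree, read_newick

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "StudyResult",
    "scale",
    "simulate_tree",
    "simulate_table",
    "select_associated_otus",
    "simulate_outcome_continuous",
    "simulate_outcome_binary",
    "simulate_dataset",
    "replicate_study",
]

SCENARIO_LINKS = {"S1": "identity", "S2": "identity", "S3": "cbrt", "S4": "sin"}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    Defaults reproduce the desk conditions: n=100 samples, K=330 OTUs,
    ~70% zero entries, 20 phylogenetic clusters, associated set of 10% of
    OTUs for the abundance-ranked scenarios, correlation 0.5 for the
    correlated-covariate mode.
    """

    n: int = 100
    K: int = 330
    scenario: str = "S1"
    beta: float = 0.0
    covariate_mode: str = "independent"
    n_clusters: int = 20
    assoc_fraction: float = 0.10  # |A| / K for S2/S4
    rho: float = 0.5  # X2 ~ aggregate correlation in correlated mode
    target_zero_fraction: float = 0.80
    dirichlet_theta: float = 20.0  # per-sample Dirichlet concentration
    log_sigma: float = 1.5  # lognormal spread of the base composition
    mean_depth: float = 1e4  # median library size (reads)
    depth_log_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIO_LINKS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.covariate_mode not in ("independent", "correlated"):
            raise ValueError(f"unknown covariate mode {self.covariate_mode!r}")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if self.scenario in ("S1", "S3") and self.K < self.n_clusters:
            raise ValueError("K must be at least n_clusters for S1/S3")

    @property
    def link(self) -> str:
        return SCENARIO_LINKS[self.scenario]


@dataclass
class SimulatedDataset:
    """One replicate: table, tree, associated set, covariates, outcome."""

    table: AbundanceTable
    tree: PhyloTree
    A: np.ndarray
    X1: np.ndarray
    X2: np.ndarray
    y: np.ndarray
    config: SimulationConfig = field(repr=False, default=None)


def scale(x: np.ndarray) -> np.ndarray:
    """Standardize to zero mean, unit (population) variance."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant aggregate")
    return (x - x.mean()) / sd


def _link_fn(name: str):
    if name == "identity":
        return lambda x: x
    if name == "cbrt":
        return np.cbrt  # real signed cube root: cbrt(-8) = -2
    if name == "sin":
        return np.sin
    raise ValueError(f"unknown link {name!r}")


def simulate_tree(K: int, seed: int) -> PhyloTree:
    """Random birth-death tree (birth 1, death 0) on K leaves, OTU labels."""
    from dendropy.simulate import treesim

    rng = _pyrandom.Random(int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=int(K), rng=rng
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"OTU{i + 1:04d}"
    newick = tree.as_string(schema="newick", suppress_rooting=True)
    return read_newick(newick)


def simulate_table(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    tree: PhyloTree | None = None,
) -> tuple[AbundanceTable, PhyloTree]:
    """Sparse compositional table from a zero-inflated Dirichlet-multinomial.

    Pipeline: lognormal base composition -> per-sample Dirichlet
    (concentration ``theta * base``) -> multinomial counts at lognormal
    depth -> dropout topping sparsity up to ``target_zero_fraction``
    (each row's largest entry is protected, so no sample degenerates) ->
    row normalization.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if tree is None:
        tree = simulate_tree(config.K, int(rng.integers(2**31 - 1)))
    n, K = config.n, config.K

    base = rng.lognormal(mean=0.0, sigma=config.log_sigma, size=K)
    base /= base.sum()
    # gamma representation of the Dirichlet; shapes < ~1e-3 underflow to
    # exact zeros, which is a realistic source of structural sparsity
    g = rng.gamma(shape=config.dirichlet_theta * base, scale=1.0, size=(n, K))
    g_sum = g.sum(axis=1)
    g_sum[g_sum == 0] = 1.0
    props = g / g_sum[:, None]
    depths = rng.lognormal(np.log(config.mean_depth), config.depth_log_sigma, n)
    counts = np.empty((n, K))
    for i in range(n):
        counts[i] = rng.multinomial(max(int(depths[i]), 100), props[i])

    counts = _calibrate_zeros(counts, config.target_zero_fraction, rng)
    ids = [f"S{i + 1:04d}" for i in range(n)]
    table = AbundanceTable.from_values(counts, ids, list(tree.leaf_labels[:K]))
    return table, tree


def _calibrate_zeros(
    counts: np.ndarray, target: float, rng: np.random.Generator
) -> np.ndarray:
    """Top sparsity up to the target zero fraction by random dropout.

    Nonzero entries (except each sample's most abundant OTU, kept to
    preserve a valid composition) are zeroed with the probability that
    makes the expected overall zero fraction equal the target.
    """
    zero_frac = float((counts == 0).mean())
    if zero_frac >= target:
        return counts
    q = (target - zero_frac) / (1.0 - zero_frac)
    drop = (rng.random(counts.shape) < q) & (counts > 0)
    drop[np.arange(counts.shape[0]), counts.argmax(axis=1)] = False
    out = counts.copy()
    out[drop] = 0
    return out


def select_associated_otus(
    table: AbundanceTable,
    tree: PhyloTree | None,
    scenario: str,
    rng: np.random.Generator | None = None,
    n_clusters: int = 20,
    assoc_fraction: float = 0.10,
) -> np.ndarray:
    """Pick the associated OTU index set A for a scenario.

    S1/S3: average-linkage clustering of the patristic distance matrix into
    ``n_clusters`` groups, then a seeded random draw of one cluster with
    probability proportional to its mean aggregate abundance (clusters with
    constant aggregate are ineligible).  S2/S4: the top
    ``assoc_fraction * K`` OTUs by mean relative abundance.
    """
    mean_ab = table.values.mean(axis=0)
    if scenario in ("S2", "S4"):
        m = max(1, int(round(assoc_fraction * table.n_otus)))
        order = np.argsort(mean_ab)[::-1]
        return np.sort(order[:m])
    if scenario not in ("S1", "S3"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if tree is None:
        raise ValueError("scenarios S1/S3 require a tree")
    if rng is None:
        rng = np.random.default_rng(0)

    labels = _tree_clusters(tree, list(table.otu_ids), n_clusters)
    weights = np.zeros(labels.max())
    for c in range(1, labels.max() + 1):
        members = np.flatnonzero(labels == c)
        agg = table.values[:, members].sum(axis=1)
        if agg.std() > 0:
            weights[c - 1] = mean_ab[members].sum()
    if weights.sum() == 0:
        raise ValueError("no cluster with a non-constant aggregate abundance")
    chosen = 1 + rng.choice(len(weights), p=weights / weights.sum())
    A = np.flatnonzero(labels == chosen)
    if A.size == 0:
        raise ValueError("empty cluster selection")
    return np.sort(A)


def _tree_clusters(
    tree: PhyloTree, otu_ids: list[str], n_clusters: int
) -> np.ndarray:
    """Average-linkage clusters of the patristic distances (cached per tree)."""
    key = (tuple(otu_ids), n_clusters)
    cache = getattr(tree, "_cluster_cache", None)
    if cache is not None and cache[0] == key:
        return cache[1]
    dist = tree.tree.tip_tip_distances(otu_ids)
    Z = linkage(squareform(dist.data, checks=False), method="average")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    tree._cluster_cache = (key, labels)
    return labels


def _covariates(
    dataset_agg: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n = config.n
    X1 = rng.binomial(1, 0.5, size=n).astype(float)
    noise = rng.standard_normal(n)
    if config.covariate_mode == "correlated":
        X2 = config.rho * scale(dataset_agg) + np.sqrt(1 - config.rho**2) * noise
    else:
        X2 = noise
    return X1, X2


def simulate_outcome_continuous(
    aggregate: np.ndarray,
    X1: np.ndarray,
    X2: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    eps: np.ndarray | None = None,
) -> np.ndarray:
    """Continuous outcome: linear covariate effects plus the OTU signal."""
    f = _link_fn(config.link)
    if eps is None:
        eps = rng.standard_normal(config.n)
    return 0.5 * X1 + 0.5 * X2 + config.beta * f(scale(aggregate)) + eps


def simulate_outcome_binary(
    aggregate: np.ndarray,
    X1: np.ndarray,
    X2: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binary outcome from the logistic model on the same linear predictor."""
    f = _link_fn(config.link)
    eta = 0.5 * X1 + 0.5 * X2 + config.beta * f(scale(aggregate))
    return rng.binomial(1, expit(eta)).astype(float)


def simulate_dataset(
    config: SimulationConfig,
    binary: bool = False,
    tree: PhyloTree | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedDataset:
    """Generate one full replicate: table, associated set, covariates, outcome."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    table, tree = simulate_table(config, rng=rng, tree=tree)
    A = select_associated_otus(
        table, tree, config.scenario, rng=rng,
        n_clusters=config.n_clusters, assoc_fraction=config.assoc_fraction,
    )
    aggregate = table.values[:, A].sum(axis=1)
    if aggregate.std() == 0:
        raise ValueError("associated aggregate is constant")
    X1, X2 = _covariates(aggregate, config, rng)
    if binary:
        y = simulate_outcome_binary(aggregate, X1, X2, config, rng)
    else:
        y = simulate_outcome_continuous(aggregate, X1, X2, config, rng)
    return SimulatedDataset(table=table, tree=tree, A=A, X1=X1, X2=X2, y=y,
                            config=config)


@dataclass
class StudyResult:
    """Rejection rate over replicates with its binomial standard error."""

    pvalues: np.ndarray
    alpha: float
    n_reps: int

    @property
    def rejection_rate(self) -> float:
        return float((self.pvalues <= self.alpha).mean())

    @property
    def standard_error(self) -> float:
        r = self.rejection_rate
        return float(np.sqrt(r * (1 - r) / self.n_reps))


def analyze_dataset(
    ds: SimulatedDataset,
    D_set=DEFAULT_D,
    R_set=DEFAULT_R,
    alpha_unifrac: float = 0.5,
):
    """Test outcome ~ microbiome adjusting for both simulated covariates."""
    y = ds.y - ds.y.mean()
    X2 = np.column_stack([ds.X1 - ds.X1.mean(), ds.X2 - ds.X2.mean()])
    return emanova(ds.table, ds.tree, y[:, None], X2, D_set=D_set, R_set=R_set,
                   alpha_unifrac=alpha_unifrac)


def replicate_study(
    config: SimulationConfig,
    n_reps: int,
    alpha: float = 0.05,
    binary: bool = False,
    D_set=DEFAULT_D,
    R_set=DEFAULT_R,
    share_tree: bool = True,
    progress: bool = False,
) -> StudyResult:
    """Run the ensemble test over seeded replicates; report the rejection rate.

    The phylogeny is generated once per study by default (replicates share
    the template tree, as when simulating from one reference dataset);
    tables, covariates and outcomes are redrawn per replicate from seeds
    spawned off ``config.seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    ss = np.random.SeedSequence(config.seed)
    tree_seed, reps_seed = ss.spawn(2)
    tree = None
    if share_tree:
        tree = simulate_tree(config.K, int(tree_seed.generate_state(1)[0] % (2**31 - 1)))
    pvals = np.empty(n_reps)
    for i, child in enumerate(reps_seed.spawn(n_reps)):
        rng = np.random.default_rng(child)
        ds = simulate_dataset(config, binary=binary, tree=tree, rng=rng)
        try:
            pvals[i] = analyze_dataset(ds, D_set=D_set, R_set=R_set).P
        except ValueError:
            # a pathological replicate (degenerate design/null) counts as
            # a non-rejection rather than aborting the study
            warnings.warn(f"replicate {i} degenerate; recorded p=1", stacklevel=2)
            pvals[i] = 1.0
        if progress and (i + 1) % 50 == 0:
            print(f"  replicate {i + 1}/{n_reps}", flush=True)
    return StudyResult(pvalues=pvals, alpha=alpha, n_reps=n_reps)


def power_curve(
    config: SimulationConfig,
    betas,
    n_reps: int,
    alpha: float = 0.05,
    binary: bool = False,
    **kwargs,
) -> dict[float, StudyResult]:
    """Rejection rate at each effect size (shared base seed per study)."""
    return {
        float(b): replicate_study(
            replace(config, beta=float(b)), n_reps, alpha=alpha, binary=binary,
            **kwargs,
        )
        for b in betas
    }
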