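"""Dirichlet-multinomial simulation study: data generators and the
type-I-error / power experiments that validate the tests.

The generators emulate an infant-gut 16S profile after abundance
filtering: p = 71 OTUs for n = 100 subjects, library sizes drawn from a
negative binomial with mean 300 and size 10, and counts from a
Dirichlet-multinomial whose proportion means follow a rank-abundance
power law (pi_j proportional to 1/j, so the top OTU holds ~21% of reads
and the rarest retained OTU ~0.3%) with overdispersion theta = 0.02 — a
typical stool-community value.  A random rooted binary tree with
exponential branch lengths stands in for the real phylogeny.

Outcomes follow a generalized linear model whose linear predictor is
0.5*scale(X1+X2) + sum_{j in Lam} beta_j*scale(Z_ij): X1 ~ Bernoulli(0.5),
X2 either independent N(0,1) or correlated with the associated OTUs, and
the associated set Lam chosen by one of four scenarios (top/random/bottom
10% by abundance, or one PAM cluster of the cophenetic distances).
Effects beta are Uniform(0, c) in same-direction mode and Uniform(-c, c)
in mixed mode, c in {1, 2, 3}.  Setting beta = 0 gives the null used for
type-I-error estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from skbio import TreeNode

from . import assoc, kernels as kmod, nullmodel
from .io import InputError, OtuTable, StudyDesign, validate_tree

SCENARIOS = ("top10", "random10", "bottom10", "pam_cluster")

#: Dimensions of the default synthetic community.
DEFAULT_P = 71
DEFAULT_N = 100
#: Default Dirichlet-multinomial overdispersion.
DEFAULT_THETA = 0.02
#: Library-size negative binomial (mean, size).
DEFAULT_LIBRARY_MEAN = 300.0
DEFAULT_LIBRARY_SIZE = 10.0


# ---------------------------------------------------------------------------
# Dirichlet-multinomial parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DMParams:
    """Proportion means and overdispersion of a Dirichlet-multinomial.

    theta follows the common dispersion convention: the Dirichlet
    concentration vector is pi * (1 - theta) / theta, so theta -> 0
    degenerates to a plain multinomial and larger theta inflates
    between-sample compositional variance by a factor
    1 + (N - 1) * theta for library size N.
    """

    pi: np.ndarray
    theta: float

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        if pi.ndim != 1 or (pi < 0).any() or not np.isclose(pi.sum(), 1.0):
            raise InputError("pi must be a probability vector summing to 1")
        if not 0 <= self.theta < 1:
            raise InputError("theta must lie in [0, 1)")

    @property
    def n_otus(self) -> int:
        return self.pi.shape[0]


def default_dm_params(p: int = DEFAULT_P, theta: float = DEFAULT_THETA) -> DMParams:
    """Rank-abundance power-law proportion means: pi_j proportional to 1/j."""
    ranks = np.arange(1, p + 1, dtype=float)
    pi = (1.0 / ranks) / (1.0 / ranks).sum()
    return DMParams(pi, theta)


def estimate_dm_params(otu: OtuTable) -> DMParams:
    """Weighted method-of-moments estimator for (pi, theta).

    pi_j is the pooled-count proportion; theta uses the Mosimann-style
    moment estimator on weighted between/within mean squares of the
    per-sample proportions.
    """
    counts = otu.counts
    n = counts.shape[0]
    if n < 2:
        raise InputError("need at least 2 samples to estimate dispersion")
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        raise InputError("zero-total sample in table")
    N = totals.sum()
    pi = counts.sum(axis=0) / N
    props = counts / totals[:, None]
    # between-sample (S) and within-sample (G) weighted mean squares
    S = (totals[:, None] * (props - pi) ** 2).sum(axis=0) / (n - 1)
    G = (totals[:, None] * props * (1 - props)).sum(axis=0) / (N - n)
    nc = (N - (totals ** 2).sum() / N) / (n - 1)
    denom = (S + (nc - 1) * G).sum()
    theta = float((S - G).sum() / denom) if denom > 0 else 0.0
    return DMParams(pi, float(np.clip(theta, 0.0, 1 - 1e-12)))


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _as_rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def otu_names(p: int) -> list:
    return [f"OTU{j + 1:03d}" for j in range(p)]


def synth_tree(p: int, seed=0) -> TreeNode:
    """Random rooted binary tree over p leaves with exponential branch lengths.

    Built by repeated random pairwise joins (a coalescent-style topology);
    identical seeds give identical Newick strings.
    """
    if p < 2:
        raise InputError("need at least 2 leaves")
    rng = _as_rng(seed)
    nodes = [f"{name}:{rng.exponential(0.1) + 0.01:.6f}" for name in otu_names(p)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        length = 0.0 if len(nodes) == 0 else rng.exponential(0.1) + 0.01
        nodes.append(f"({left},{right}):{length:.6f}")
    tree = TreeNode.read([nodes[0] + ";"])
    return validate_tree(tree)


def sample_library_sizes(n: int, mean: float = DEFAULT_LIBRARY_MEAN,
                         size: float = DEFAULT_LIBRARY_SIZE, seed=0) -> np.ndarray:
    """Negative-binomial library sizes (zero draws are redrawn)."""
    if mean <= 0 or size <= 0:
        raise InputError("mean and size must be positive")
    rng = _as_rng(seed)
    prob = size / (size + mean)
    totals = rng.negative_binomial(size, prob, n)
    while (totals == 0).any():
        zero = totals == 0
        totals[zero] = rng.negative_binomial(size, prob, int(zero.sum()))
    return totals


def sample_dm(params: DMParams, totals, seed=0) -> OtuTable:
    """Dirichlet-multinomial counts: per sample, a Dirichlet composition
    then multinomial counts of the supplied total."""
    rng = _as_rng(seed)
    totals = np.asarray(totals, dtype=int)
    n, p = totals.shape[0], params.n_otus
    counts = np.zeros((n, p))
    if params.theta == 0:
        for i, t in enumerate(totals):
            counts[i] = rng.multinomial(t, params.pi)
    else:
        conc = params.pi * (1 - params.theta) / params.theta
        if (conc <= 0).any():
            raise InputError("pi must be strictly positive to sample with theta > 0")
        comps = rng.dirichlet(conc, size=n)
        for i, t in enumerate(totals):
            counts[i] = rng.multinomial(t, comps[i])
    return OtuTable(counts, [f"S{i + 1:03d}" for i in range(n)], otu_names(p))


# ---------------------------------------------------------------------------
# PAM clustering of the cophenetic distances
# ---------------------------------------------------------------------------

def cophenetic_matrix(tree: TreeNode) -> tuple:
    """Tip-to-tip path-length matrix and the tip-name order."""
    dm = tree.tip_tip_distances()
    return np.asarray(dm.data), tuple(dm.ids)


def pam(D: np.ndarray, k: int) -> np.ndarray:
    """Classic deterministic PAM (build + swap) on a precomputed distance
    matrix; ties broken toward the lowest index.  Returns cluster labels."""
    D = np.asarray(D, dtype=float)
    m = D.shape[0]
    if not 1 <= k <= m:
        raise InputError("k must lie in [1, n_points]")
    # build
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        nearest = D[:, medoids].min(axis=1)
        gains = np.array([
            np.maximum(nearest - D[:, c], 0.0).sum() if c not in medoids else -1.0
            for c in range(m)
        ])
        medoids.append(int(np.argmax(gains)))
    # swap
    improved = True
    while improved:
        improved = False
        cost = D[:, medoids].min(axis=1).sum()
        best = None
        for mi, med in enumerate(medoids):
            for c in range(m):
                if c in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = c
                tc = D[:, trial].min(axis=1).sum()
                if tc < cost - 1e-12:
                    cost, best = tc, (mi, c)
        if best is not None:
            medoids[best[0]] = best[1]
            improved = True
    medoids = sorted(medoids)
    return np.argmin(D[:, medoids], axis=1)


def pam_clusters(tree: TreeNode, k: int = 5) -> dict:
    """Partition the tree's tips into k PAM clusters of cophenetic distance."""
    D, ids = cophenetic_matrix(tree)
    labels = pam(D, k)
    return {name: int(c) for name, c in zip(ids, labels)}


def synth_taxonomy(otu_ids, clusters, genus_size: int = 2) -> pd.DataFrame:
    """Synthetic 7-rank taxonomy nesting the PAM clusters.

    Each cluster becomes one phylum (and one class/order/family inside
    it), clusters are chopped into genera of ``genus_size`` OTUs, and
    every OTU is its own species — so the scan exercises multi-OTU taxa,
    small taxa and single-OTU taxa at once.  Returns a DataFrame shaped
    like :func:`omiat.io.read_taxonomy` output.
    """
    from .io import taxonomy_from_lineages

    lineages = {}
    per_cluster = {}
    for o in otu_ids:
        c = clusters[o]
        i = per_cluster.get(c, 0)
        per_cluster[c] = i + 1
        lineages[o] = (
            f"k__Bacteria; p__P{c}; c__C{c}; o__O{c}; f__F{c}; "
            f"g__G{c}.{i // genus_size}; s__{o}"
        )
    return taxonomy_from_lineages(lineages)


# ---------------------------------------------------------------------------
# Scenarios and outcome simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """Which OTUs carry effects and how strong the effects are."""

    selector: str            # one of SCENARIOS
    direction: str = "same"  # 'same' -> U(0,c); 'mixed' -> U(-c,c)
    c: float = 1.0

    def __post_init__(self):
        if self.selector not in SCENARIOS:
            raise InputError(f"unknown scenario {self.selector!r}")
        if self.direction not in ("same", "mixed"):
            raise InputError("direction must be 'same' or 'mixed'")
        if self.c <= 0:
            raise InputError("effect scale c must be positive")


def select_associated(scenario, otu: OtuTable, clusters=None, seed=0) -> np.ndarray:
    """Index set Lam of associated OTUs for one replicate.

    top10/bottom10 take round(0.1 p) (minimum 1) OTUs by mean-proportion
    rank; random10 draws the same number uniformly; pam_cluster picks one
    cluster uniformly at random per replicate.
    """
    selector = scenario.selector if isinstance(scenario, Scenario) else scenario
    rng = _as_rng(seed)
    p = otu.n_otus
    m = max(1, round(0.1 * p))
    if selector == "pam_cluster":
        if clusters is None:
            raise InputError("pam_cluster scenario needs a cluster assignment")
        labels = np.array([clusters[o] for o in otu.otu_ids])
        chosen = rng.integers(0, labels.max() + 1)
        return np.flatnonzero(labels == chosen)
    if selector == "random10":
        return np.sort(rng.choice(p, size=m, replace=False))
    mean_prop = nullmodel.to_composition(otu).mean(axis=0)
    order = np.argsort(-mean_prop, kind="stable")
    return np.sort(order[:m] if selector == "top10" else order[-m:])


def draw_effects(scenario: Scenario, lam: np.ndarray, seed=0) -> np.ndarray:
    rng = _as_rng(seed)
    lo = 0.0 if scenario.direction == "same" else -scenario.c
    return rng.uniform(lo, scenario.c, size=lam.shape[0])


def _scale(x: np.ndarray) -> np.ndarray:
    Z, _ = nullmodel.scale_columns(x if x.ndim == 2 else x[:, None])
    return Z if x.ndim == 2 else Z[:, 0]


def simulate_outcome(otu: OtuTable, lam, beta, trait: str = "continuous",
                     x2_mode: str = "independent", seed=0,
                     max_redraws: int = 100) -> StudyDesign:
    """Simulate the outcome and covariates given the associated set.

    Linear predictor: 0.5*scale(X1+X2) + sum_{j in Lam} beta_j*scale(Z_ij)
    with the 'scale' standardization applied to raw counts.  Continuous
    traits add N(0,1) noise; binary traits draw Bernoulli(expit(.)).  A
    single-class binary draw (possible at small n) is redrawn.
    """
    rng = _as_rng(seed)
    n = otu.n_samples
    lam = np.asarray(lam, dtype=int)
    beta = np.asarray(beta, dtype=float)
    Zs = _scale(otu.counts[:, lam]) if lam.size else np.zeros((n, 0))
    signal = Zs @ beta if lam.size else np.zeros(n)
    X1 = rng.binomial(1, 0.5, n).astype(float)
    if x2_mode == "correlated":
        X2 = Zs.sum(axis=1) + rng.normal(size=n)
    elif x2_mode == "independent":
        X2 = rng.normal(size=n)
    else:
        raise InputError("x2_mode must be 'independent' or 'correlated'")
    eta = 0.5 * _scale(X1 + X2) + signal
    X = np.column_stack([X1, X2])
    if trait == "continuous":
        return StudyDesign(eta + rng.normal(size=n), X, "continuous")
    for _ in range(max_redraws):
        y = rng.binomial(1, expit(eta)).astype(float)
        if 0 < y.sum() < n:
            return StudyDesign(y, X, "binary")
    raise InputError("could not draw a two-class binary outcome")


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentResult:
    """Rejection rates with Monte-Carlo bookkeeping.

    ``rates`` maps a cell label to the rejection proportion at ``alpha``;
    ``pvalues`` maps the same label to the per-replicate p-value arrays
    (method -> ndarray).
    """

    rates: pd.DataFrame
    alpha: float
    reps: int
    pvalues: dict = field(default_factory=dict, compare=False, repr=False)

    def mc_se(self, rate: float) -> float:
        return float(np.sqrt(rate * (1 - rate) / self.reps))


def _replicate_pvalues(rng, params, tindex, trait, x2_mode, scenario,
                       clusters, n, n_perm, grid, alphas, null=False):
    """One simulation replicate: data, outcome, all four headline tests.

    Under ``null=True`` the OTU effects are zeroed but the associated set
    still defines the OTU-correlated covariate when ``x2_mode`` is
    'correlated' (the covariate-confounding null).
    """
    totals = sample_library_sizes(n, seed=rng)
    otu = sample_dm(params, totals, seed=rng)
    if scenario is None:
        lam, beta = np.array([], dtype=int), np.array([])
    else:
        lam = select_associated(scenario, otu, clusters, seed=rng)
        beta = np.zeros(lam.shape[0]) if null else draw_effects(scenario, lam, seed=rng)
    design = simulate_outcome(otu, lam, beta, trait, x2_mode, seed=rng)
    fit = nullmodel.fit_null(design)
    P = nullmodel.to_composition(otu)
    Z = nullmodel.standardize_composition(P)
    kernels, degenerate = kmod.candidate_kernels(P, tindex, alphas)
    if degenerate:
        kernels = {"bray_curtis": kernels["bray_curtis"]}
    perms = assoc.make_permutations(n, n_perm, int(rng.integers(2 ** 31)))
    return assoc.community_test_suite(fit, Z, kernels, perms, grid)


def _run_cells(cells, reps, n, p, n_perm, seed, alpha, theta, grid, alphas,
               null=False):
    from zlib import crc32

    params = default_dm_params(p, theta)
    tree = synth_tree(p, seed=seed)
    tindex = kmod.TreeIndex(tree, otu_names(p))
    clusters = pam_clusters(tree, k=5)
    records, pvals = [], {}
    for label, trait, x2_mode, scenario in cells:
        rng = np.random.default_rng([seed, crc32(label.encode())])
        cell = {m: np.empty(reps) for m in ("omiat", "optimal_mirkat",
                                            "aspu", "aggregate")}
        for r in range(reps):
            out = _replicate_pvalues(rng, params, tindex, trait, x2_mode,
                                     scenario, clusters, n, n_perm, grid,
                                     alphas, null=null)
            for m in cell:
                cell[m][r] = out[m]
        pvals[label] = cell
        rec = {"cell": label, "trait": trait, "x2": x2_mode}
        for m, v in cell.items():
            rec[m] = float((v <= alpha).mean())
        records.append(rec)
    return pd.DataFrame(records), pvals


def run_type1_experiment(reps: int = 2000, n_perm: int = 1000,
                         n: int = DEFAULT_N, p: int = DEFAULT_P,
                         traits=("continuous", "binary"),
                         x2_modes=("independent", "correlated"),
                         alpha: float = 0.05, theta: float = DEFAULT_THETA,
                         seed: int = 0, grid=assoc.DEFAULT_GAMMA_GRID,
                         alphas=kmod.DEFAULT_ALPHAS) -> ExperimentResult:
    """Empirical type-I error of the four tests under beta = 0.

    With a correlated X2, the associated set (a random 10% of OTUs per
    replicate) still drives the covariate even though the OTU effects are
    zero, so the null exercises covariate adjustment.
    """
    cells = [(f"{trait}/{x2}", trait, x2,
              Scenario("random10") if x2 == "correlated" else None)
             for trait in traits for x2 in x2_modes]
    rates, pvals = _run_cells(cells, reps, n, p, n_perm, seed, alpha,
                              theta, grid, alphas, null=True)
    return ExperimentResult(rates, alpha, reps, pvals)


def run_power_experiment(scenarios, reps: int = 500, n_perm: int = 1000,
                         n: int = DEFAULT_N, p: int = DEFAULT_P,
                         trait: str = "continuous",
                         x2_mode: str = "independent", alpha: float = 0.05,
                         theta: float = DEFAULT_THETA, seed: int = 0,
                         grid=assoc.DEFAULT_GAMMA_GRID,
                         alphas=kmod.DEFAULT_ALPHAS) -> ExperimentResult:
    """Empirical power across scenario cells (each a :class:`Scenario`)."""
    cells = [(f"{s.selector}/{s.direction}/c={s.c:g}", trait, x2_mode, s)
             for s in scenarios]
    rates, pvals = _run_cells(cells, reps, n, p, n_perm, seed, alpha,
                              theta, grid, alphas)
    return ExperimentResult(rates, alpha, reps, pvals)
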