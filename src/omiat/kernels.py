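"""Ecological distance measures and kernel-machine score statistics.

The candidate set holds seven beta-diversity measures: Bray-Curtis
dissimilarity (abundance only) and the UniFrac family (phylogeny-aware):
unweighted, weighted (normalized) and generalized UniFrac with parameter
alpha in {0, 0.25, 0.5, 0.75}.  Each distance matrix D is turned into a
kernel by Gower double-centering of the element-wise square,

    K = -1/2 (I - 11'/n) D^2 (I - 11'/n),

followed by eigenvalue clipping to restore positive semidefiniteness, and
the kernel-machine variance-component score statistic is

    Q = (1 / 2 Phi) r' K r

with r the null-model residuals and Phi the null dispersion.

UniFrac computations run on branch profiles: for every edge e with length
b_e, the per-sample aggregated proportion p_e of all OTUs descending from
that edge.  The leaf-to-edge incidence is computed once per tree and reused
across samples, permutations and replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from .io import InputError
from .nullmodel import NullFit

#: Generalized UniFrac exponents in the default candidate set.
DEFAULT_ALPHAS = (0.0, 0.25, 0.5, 0.75)

#: Labels of the seven candidate distance measures, in reporting order.
CANDIDATE_MEASURES = ("bray_curtis", "u_unifrac", "w_unifrac",
                      "g_unifrac_0", "g_unifrac_0.25", "g_unifrac_0.5",
                      "g_unifrac_0.75")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise sample distances in [0, 1] with a measure label.

    ``degenerate`` is set when some pairwise denominator was zero (the
    measure carries no information for that pair; the distance is defined
    as 0 there).
    """

    values: np.ndarray
    measure: str
    degenerate: bool = False

    def __post_init__(self):
        V = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", V)
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise InputError("distance matrix must be square")


@dataclass(frozen=True)
class KernelMatrix:
    """Double-centered kernel, PSD-repaired by eigenvalue clipping."""

    values: np.ndarray
    measure: str
    repaired: bool = False


@dataclass(frozen=True)
class BranchProfile:
    """Per-edge branch lengths and per-sample descendant-proportion sums."""

    lengths: np.ndarray          # (n_edges,)
    profiles: np.ndarray         # (n_samples, n_edges)


class TreeIndex:
    """Leaf-to-edge incidence of a rooted tree, cached for reuse.

    ``incidence[j, e]`` is 1 when OTU column j descends through edge e.
    The (virtual) root edge is excluded; every other edge of the tree is a
    row of the profile, including edges leading only to tips absent from
    the OTU set (their profiles are identically zero).
    """

    def __init__(self, tree: TreeNode, otu_ids):
        otu_ids = [str(o) for o in otu_ids]
        col = {o: j for j, o in enumerate(otu_ids)}
        tip_names = {t.name for t in tree.tips()}
        missing = [o for o in otu_ids if o not in tip_names]
        if missing:
            raise InputError(f"OTUs absent from the tree: {missing[:10]}")
        lengths, rows = [], []
        masks = {}
        for node in tree.postorder(include_self=True):
            if node.is_tip():
                m = np.zeros(len(otu_ids))
                if node.name in col:
                    m[col[node.name]] = 1.0
            else:
                m = np.zeros(len(otu_ids))
                for child in node.children:
                    m += masks[id(child)]
            masks[id(node)] = m
            if node is not tree:  # the root has no edge above it
                lengths.append(float(node.length or 0.0))
                rows.append(m)
        self.otu_ids = tuple(otu_ids)
        self.lengths = np.asarray(lengths)
        self.incidence = np.asarray(rows).T  # (n_otus, n_edges)

    @property
    def n_edges(self) -> int:
        return self.lengths.shape[0]

    def profiles(self, P: np.ndarray) -> BranchProfile:
        P = np.asarray(P, dtype=float)
        if P.shape[1] != len(self.otu_ids):
            raise InputError("proportion matrix does not match tree index")
        return BranchProfile(self.lengths, P @ self.incidence)


def branch_profiles(P: np.ndarray, tree: TreeNode, otu_ids) -> BranchProfile:
    """Aggregate per-sample proportions onto every edge of the tree."""
    return TreeIndex(tree, otu_ids).profiles(P)


# ---------------------------------------------------------------------------
# Distance measures
# ---------------------------------------------------------------------------

def _ratio(num: np.ndarray, den: np.ndarray, measure: str) -> DistanceMatrix:
    zero = den <= 0
    degenerate = bool(np.any(zero & (np.abs(num) > 0))) or bool(
        np.any(zero[np.triu_indices_from(zero, k=1)]))
    if degenerate:
        warnings.warn(f"{measure}: zero denominator for some sample pair; "
                      "distance defined as 0 there")
    D = np.where(zero, 0.0, num / np.where(zero, 1.0, den))
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 1.0)
    return DistanceMatrix(D, measure, degenerate)


def bray_curtis(P: np.ndarray) -> DistanceMatrix:
    """Bray-Curtis dissimilarity D_ij = sum|P_i - P_j| / sum(P_i + P_j)."""
    P = np.asarray(P, dtype=float)
    num = squareform(pdist(P, metric="cityblock"))
    s = P.sum(axis=1)
    den = s[:, None] + s[None, :]
    return _ratio(num, den, "bray_curtis")


def unweighted_unifrac(bp: BranchProfile) -> DistanceMatrix:
    """Presence-based UniFrac: unshared branch length over covered length."""
    A = (bp.profiles > 0).astype(float)
    num = squareform(pdist(A, metric="cityblock", w=bp.lengths))
    s = A @ bp.lengths
    Aw = A * np.sqrt(bp.lengths)
    shared = Aw @ Aw.T
    den = s[:, None] + s[None, :] - shared  # sum of b over (present_i OR present_j)
    return _ratio(num, den, "u_unifrac")


def weighted_unifrac(bp: BranchProfile) -> DistanceMatrix:
    """Normalized weighted UniFrac: sum b|p_i-p_j| / sum b(p_i+p_j)."""
    num = squareform(pdist(bp.profiles, metric="cityblock", w=bp.lengths))
    s = bp.profiles @ bp.lengths
    den = s[:, None] + s[None, :]
    return _ratio(num, den, "w_unifrac")


def _generalized_family(bp: BranchProfile, alphas) -> dict:
    """Generalized UniFrac for several alphas sharing one pair expansion.

    Works on the condensed upper triangle; the per-edge log of the
    abundance sum is computed once and re-exponentiated per alpha.
    """
    P = bp.profiles
    n = P.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    Pi, Pj = P[iu], P[ju]
    S = Pi + Pj
    pos = S > 0
    ratio = np.abs(Pi - Pj)
    np.divide(ratio, S, out=ratio, where=pos)
    ratio[~pos] = 0.0
    # S^alpha via square-root chains for the standard alphas (cheaper than
    # a general power); S = 0 entries stay 0 for alpha > 0
    powers = {}

    def _pow(a):
        if a in powers:
            return powers[a]
        if a == 0.0:
            v = pos.astype(float)
        elif a == 1.0:
            v = S
        elif a == 0.5:
            v = np.sqrt(S)
        elif a == 0.25:
            v = np.sqrt(_pow(0.5))
        elif a == 0.75:
            v = _pow(0.5) * _pow(0.25)
        else:
            v = S ** a
        powers[a] = v
        return v

    out = {}
    for alpha in alphas:
        if not 0 <= alpha <= 1:
            raise InputError("alpha must lie in [0, 1]")
        W = _pow(float(alpha)) * bp.lengths
        num_c = (W * ratio).sum(axis=-1)
        den_c = W.sum(axis=-1)
        num = np.zeros((n, n))
        den = np.full((n, n), 1.0)
        num[iu, ju] = num[ju, iu] = num_c
        den[iu, ju] = den[ju, iu] = den_c
        out[alpha] = _ratio(num, den, f"g_unifrac_{alpha:g}")
    return out


def generalized_unifrac(bp: BranchProfile, alpha: float) -> DistanceMatrix:
    """Generalized UniFrac with abundance-weighting exponent ``alpha``.

    D_ij = sum_e b_e (p_ei+p_ej)^alpha |p_ei-p_ej|/(p_ei+p_ej)
           / sum_e b_e (p_ei+p_ej)^alpha,

    with edges where p_ei + p_ej = 0 skipped.  alpha = 1 reproduces the
    normalized weighted UniFrac.
    """
    return _generalized_family(bp, (alpha,))[alpha]


def candidate_distances(P: np.ndarray, tree_index: TreeIndex,
                        alphas=DEFAULT_ALPHAS) -> tuple:
    """The seven candidate distance matrices for one OTU group.

    Returns ``(distances, unifrac_degenerate)`` where ``distances`` maps
    measure label to :class:`DistanceMatrix`.  ``unifrac_degenerate`` is
    True when the group shows no phylogenetic disparity for some sample
    pair (a zero UniFrac denominator, or an all-zero UniFrac matrix) —
    downstream tests then fall back to the Bray-Curtis kernel alone.
    """
    bp = tree_index.profiles(P)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = {"bray_curtis": bray_curtis(P),
               "u_unifrac": unweighted_unifrac(bp),
               "w_unifrac": weighted_unifrac(bp)}
        fam = _generalized_family(bp, alphas)
        for a in alphas:
            out[f"g_unifrac_{a:g}"] = fam[a]
    degenerate = any(
        d.degenerate or not d.values.any()
        for name, d in out.items() if name != "bray_curtis"
    )
    return out, degenerate


# ---------------------------------------------------------------------------
# Kernels and the variance-component statistic
# ---------------------------------------------------------------------------

def gower_center(D: np.ndarray) -> np.ndarray:
    """-1/2 J D^2 J with J = I - 11'/n (no PSD repair)."""
    A = -0.5 * np.asarray(D, dtype=float) ** 2
    row = A.mean(axis=1, keepdims=True)
    col = A.mean(axis=0, keepdims=True)
    return A - row - col + A.mean()


def distance_to_kernel(D, psd_tol: float = 1e-10) -> KernelMatrix:
    """Double-center the squared distances and clip negative eigenvalues."""
    if isinstance(D, DistanceMatrix):
        V, measure = D.values, D.measure
    else:
        V, measure = np.asarray(D, dtype=float), "custom"
    if not np.allclose(V, V.T) or not np.allclose(np.diag(V), 0):
        raise InputError("distance matrix must be symmetric with zero diagonal")
    K = gower_center(V)
    w, Q = np.linalg.eigh(K)
    if w.min() < -psd_tol * max(1.0, w.max()):
        K = (Q * np.clip(w, 0.0, None)) @ Q.T
        K = (K + K.T) / 2.0
        return KernelMatrix(K, measure, repaired=True)
    return KernelMatrix(K, measure, repaired=False)


def candidate_kernels(P: np.ndarray, tree_index: TreeIndex,
                      alphas=DEFAULT_ALPHAS) -> tuple:
    """Kernels of the seven candidate measures; see :func:`candidate_distances`."""
    dists, degenerate = candidate_distances(P, tree_index, alphas)
    return {name: distance_to_kernel(d) for name, d in dists.items()}, degenerate


def mirkat_statistic(fit: NullFit, K) -> float:
    """Variance-component score statistic Q = r' K r / (2 Phi)."""
    V = K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    r = fit.residuals
    if V.shape[0] != r.shape[0]:
        raise InputError("kernel and residual dimensions disagree")
    return float(r @ V @ r / (2.0 * fit.phi))
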