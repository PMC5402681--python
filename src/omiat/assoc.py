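"""Permutation-based score tests: SPU, aSPU, MiRKAT, Optimal MiRKAT, the
pooled min-P combination, the aggregate comparator and the single-OTU test.

All inference is permutation-based and every statistic shares a single
:class:`PermutationSet` of sample-index permutations: the observed residual
vector r and its B permuted versions r^(b) are reused by every candidate
statistic of every taxon in a scan.  P-values use the add-one estimator

    p = (1 + #{b : s^(b) >= s_obs}) / (B + 1),

comparing by absolute value for sign-bearing statistics (SPU with any
gamma, aggregate, single-OTU) and one-sided for the non-negative kernel
statistic Q.

Adaptive tests (aSPU over the gamma grid, Optimal MiRKAT over the kernel
set, and the full min-P combination over both pools) use a single-layer
leave-one-out construction: each permutation's minimum pseudo p-value is
computed against the remaining permutations of the same set, so no nested
resampling is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .io import InputError
from .kernels import KernelMatrix
from .nullmodel import NullFit, StandardizedComposition

#: Default SPU exponent grid; math.inf denotes the max-|component| statistic.
DEFAULT_GAMMA_GRID = (1, 2, 3, 4, 5, 6, 7, 8, math.inf)


@dataclass(frozen=True)
class PermutationSet:
    """B seeded permutations of {0..n-1}, shared across all statistics."""

    indices: np.ndarray  # (B, n) int
    seed: int

    @property
    def B(self) -> int:
        return self.indices.shape[0]

    @property
    def n(self) -> int:
        return self.indices.shape[1]

    def permuted_residuals(self, fit: NullFit) -> np.ndarray:
        """Residual vector re-indexed by every stored permutation, (B, n)."""
        if fit.n_samples != self.n:
            raise InputError("permutation set built for a different sample count")
        return fit.residuals[self.indices]


def make_permutations(n: int, B: int, seed: int) -> PermutationSet:
    """Draw B uniformly random permutations of n indices, reproducibly."""
    if B < 1:
        raise InputError("need at least one permutation")
    rng = np.random.default_rng(seed)
    idx = np.tile(np.arange(n), (B, 1))
    idx = rng.permuted(idx, axis=1)
    return PermutationSet(idx, seed)


@dataclass(frozen=True)
class TestResult:
    """Outcome of one association test."""

    method: str
    statistic: float
    pvalue: float
    B: int
    component_pvalues: dict = field(default_factory=dict)
    flags: tuple = ()


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def spu_statistic(U: np.ndarray, gamma) -> float:
    """Sum of powered scores: sum_j U_j^gamma, or max_j |U_j| for gamma=inf."""
    U = np.asarray(U, dtype=float)
    if U.size == 0:
        raise InputError("empty score vector")
    if gamma == math.inf:
        return float(np.abs(U).max())
    if gamma < 1 or int(gamma) != gamma:
        raise InputError("gamma must be a positive integer or inf")
    return float((U ** gamma).sum())


def perm_pvalue(observed: float, permuted_values, two_sided_by_abs: bool = False) -> float:
    """Add-one permutation p-value; ties count as exceedances."""
    perm = np.asarray(permuted_values, dtype=float)
    if two_sided_by_abs:
        observed, perm = abs(observed), np.abs(perm)
    B = perm.shape[0]
    return float((1 + (perm >= observed).sum()) / (B + 1))


# ---------------------------------------------------------------------------
# Candidate-pool machinery (shared by every adaptive test)
# ---------------------------------------------------------------------------

def _pool_pvalues(obs: np.ndarray, perm: np.ndarray, abs_mask: np.ndarray) -> tuple:
    """Per-candidate p-values and leave-one-out pseudo p-values.

    ``obs`` (m,), ``perm`` (B, m).  For each candidate, p_obs uses the
    add-one estimator against all B permutations; pseudo p-values rank each
    permutation against the set including itself (the self-exceedance plays
    the add-one role), giving the null sample of the min-P statistic.
    """
    o = np.where(abs_mask, np.abs(obs), obs)
    V = np.where(abs_mask, np.abs(perm), perm)
    B = V.shape[0]
    p_obs = (1 + (V >= o).sum(axis=0)) / (B + 1)
    ranks = rankdata(V, axis=0, method="min")  # 1 + #{strictly smaller}
    pseudo = (B - ranks + 1) / B               # #{ >= } / B, self included
    return p_obs, pseudo


def _minp_pvalue(p_obs: np.ndarray, pseudo: np.ndarray) -> tuple:
    """Min-P combination over a candidate pool under the shared null."""
    minp_obs = float(p_obs.min())
    minp_b = pseudo.min(axis=1)
    B = pseudo.shape[0]
    p = float((1 + (minp_b <= minp_obs).sum()) / (B + 1))
    return minp_obs, p


def _spu_stat_matrix(U: np.ndarray, U_perm: np.ndarray, grid) -> tuple:
    """Observed and permuted SPU statistics over the gamma grid.

    Integer powers are built by iterated multiplication, reusing the
    running power across grid entries (the grid is sorted internally; the
    output column order matches the given grid).
    """
    obs = np.array([spu_statistic(U, g) for g in grid])
    cols = {}
    finite = sorted({int(g) for g in grid if g != math.inf})
    if finite:
        power = np.ones_like(U_perm)
        k = 0
        for g in finite:
            while k < g:
                power = power * U_perm
                k += 1
            cols[g] = power.sum(axis=1)
    if math.inf in grid:
        cols[math.inf] = np.abs(U_perm).max(axis=1)
    return obs, np.column_stack([cols[g if g == math.inf else int(g)]
                                 for g in grid])


def _mirkat_stat_matrix(fit: NullFit, kernels: dict, R: np.ndarray) -> tuple:
    """Observed and permuted Q for each kernel; columns follow kernel order."""
    r = fit.residuals
    obs, cols = [], []
    for K in kernels.values():
        V = K.values if isinstance(K, KernelMatrix) else np.asarray(K)
        obs.append(r @ V @ r / (2.0 * fit.phi))
        cols.append(((R @ V) * R).sum(axis=1) / (2.0 * fit.phi))
    return np.array(obs), np.column_stack(cols)


# ---------------------------------------------------------------------------
# Public tests
# ---------------------------------------------------------------------------

def _zvalues(Z) -> np.ndarray:
    return Z.values if isinstance(Z, StandardizedComposition) else np.asarray(Z, float)


def aspu_test(fit: NullFit, Z_std, perms: PermutationSet,
              grid=DEFAULT_GAMMA_GRID) -> TestResult:
    """Adaptive SPU: min-P over the gamma grid on one permutation set."""
    if len(grid) == 0:
        raise InputError("empty gamma grid")
    Zv = _zvalues(Z_std)
    R = perms.permuted_residuals(fit)
    U = fit.residuals @ Zv
    obs, perm = _spu_stat_matrix(U, R @ Zv, grid)
    abs_mask = np.ones(len(grid), dtype=bool)
    p_obs, pseudo = _pool_pvalues(obs, perm, abs_mask)
    stat, p = _minp_pvalue(p_obs, pseudo)
    comps = {f"spu_{g:g}": float(pc) for g, pc in zip(grid, p_obs)}
    return TestResult("aspu", stat, p, perms.B, comps)


def mirkat_test(fit: NullFit, K, perms: PermutationSet) -> TestResult:
    """Single-kernel variance-component score test (one-sided)."""
    R = perms.permuted_residuals(fit)
    measure = K.measure if isinstance(K, KernelMatrix) else "custom"
    obs, perm = _mirkat_stat_matrix(fit, {measure: K}, R)
    p = perm_pvalue(obs[0], perm[:, 0])
    return TestResult(f"mirkat_{measure}", float(obs[0]), p, perms.B,
                      {f"mirkat_{measure}": p})


def optimal_mirkat_test(fit: NullFit, kernels: dict, perms: PermutationSet) -> TestResult:
    """Min-P over the candidate kernels on the shared permutation set."""
    if not kernels:
        raise InputError("need at least one kernel")
    R = perms.permuted_residuals(fit)
    obs, perm = _mirkat_stat_matrix(fit, kernels, R)
    abs_mask = np.zeros(len(kernels), dtype=bool)
    p_obs, pseudo = _pool_pvalues(obs, perm, abs_mask)
    stat, p = _minp_pvalue(p_obs, pseudo)
    comps = {f"mirkat_{k}": float(pc) for k, pc in zip(kernels, p_obs)}
    return TestResult("optimal_mirkat", stat, p, perms.B, comps)


def omiat_test(fit: NullFit, Z_std, kernels: dict, perms: PermutationSet,
               grid=DEFAULT_GAMMA_GRID) -> TestResult:
    """Min-P combination over the pooled SPU and MiRKAT candidates.

    The candidate pool is the gamma grid (9 SPU statistics, compared by
    absolute value) together with the candidate kernels (one-sided Q each).
    The reported statistic is the observed minimum per-candidate p-value;
    the final p-value calibrates it against the same permutation set.  The
    component p-values include the two intermediate adaptive tests, keyed
    ``aspu`` and ``optimal_mirkat``.  An empty kernel dict degenerates to
    aSPU (used when UniFrac is uninformative and no fallback kernel is
    supplied).
    """
    Zv = _zvalues(Z_std)
    R = perms.permuted_residuals(fit)
    U = fit.residuals @ Zv
    spu_obs, spu_perm = _spu_stat_matrix(U, R @ Zv, grid)
    if kernels:
        k_obs, k_perm = _mirkat_stat_matrix(fit, kernels, R)
        obs = np.concatenate([spu_obs, k_obs])
        perm = np.column_stack([spu_perm, k_perm])
    else:
        obs, perm = spu_obs, spu_perm
    abs_mask = np.concatenate([np.ones(len(grid), bool),
                               np.zeros(len(kernels), bool)])
    p_obs, pseudo = _pool_pvalues(obs, perm, abs_mask)
    stat, p = _minp_pvalue(p_obs, pseudo)
    comps = {f"spu_{g:g}": float(pc) for g, pc in zip(grid, p_obs[:len(grid)])}
    comps.update({f"mirkat_{k}": float(pc)
                  for k, pc in zip(kernels, p_obs[len(grid):])})
    _, comps["aspu"] = _minp_pvalue(p_obs[:len(grid)], pseudo[:, :len(grid)])
    if kernels:
        _, comps["optimal_mirkat"] = _minp_pvalue(p_obs[len(grid):],
                                                  pseudo[:, len(grid):])
    return TestResult("omiat", stat, p, perms.B, comps)


def aggregate_test(fit: NullFit, Z_std, perms: PermutationSet) -> TestResult:
    """Aggregate-based comparator: per-sample sum of standardized columns.

    The per-sample predictor a_i = sum_j Zstd_ij collapses the group to a
    single variable, so components in opposite effect directions cancel —
    the failure mode the adaptive tests avoid.
    """
    Zv = _zvalues(Z_std)
    if Zv.shape[1] < 1:
        raise InputError("aggregate test needs at least one OTU column")
    a = Zv.sum(axis=1)
    obs = float(fit.residuals @ a)
    R = perms.permuted_residuals(fit)
    p = perm_pvalue(obs, R @ a, two_sided_by_abs=True)
    return TestResult("aggregate", obs, p, perms.B)


def single_otu_test(fit: NullFit, z_column, perms: PermutationSet) -> TestResult:
    """Score test for a taxon holding exactly one OTU (two-sided)."""
    z = np.asarray(z_column, dtype=float).ravel()
    if not z.any():
        return TestResult("single_otu", 0.0, 1.0, perms.B, flags=("zero_variance",))
    obs = float(fit.residuals @ z)
    R = perms.permuted_residuals(fit)
    p = perm_pvalue(obs, R @ z, two_sided_by_abs=True)
    return TestResult("single_otu", obs, p, perms.B)


def community_test_suite(fit: NullFit, Z_std, kernels: dict,
                         perms: PermutationSet,
                         grid=DEFAULT_GAMMA_GRID) -> dict:
    """All headline p-values for one OTU group in a single pass.

    Returns {'omiat', 'aspu', 'optimal_mirkat', 'aggregate'} p-values,
    sharing one permuted-residual matrix (used by the simulation studies,
    where the same group is tested by every method).
    """
    res = omiat_test(fit, Z_std, kernels, perms, grid)
    agg = aggregate_test(fit, Z_std, perms)
    out = {"omiat": res.pvalue, "aspu": res.component_pvalues["aspu"],
           "aggregate": agg.pvalue}
    out["optimal_mirkat"] = res.component_pvalues.get("optimal_mirkat", float("nan"))
    return out
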