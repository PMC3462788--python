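"""Within- and between-population diversity, neutrality tests and AMOVA.

The statistics here operate on haplotype counts and on matrices of pairwise
sequence distances.  AMOVA partitions the total sum of squared pairwise
distances into hierarchical variance components (among groups, among
populations within groups, within populations) following the classical
molecular-variance framework, with permutation tests for the Phi-statistics:

* Phi_CT — permute whole populations among groups;
* Phi_SC — permute individuals among populations within their group;
* Phi_ST — permute individuals among all populations.

Undefined statistics (zero total variance, no segregating sites) are returned
as ``None`` markers, never silent zeros; Fu's Fs may legitimately be +/-inf
when the Ewens tail probability saturates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._errors import DegenerateInputError, InsufficientSampleError, ValidationError
from .alignment import Alignment, PopulationAssignment, complete_site_mask

__all__ = [
    "DistanceMatrix",
    "DiversityStats",
    "AmovaResult",
    "haplotype_diversity",
    "nucleotide_diversity",
    "mean_pairwise_differences",
    "segregating_sites",
    "tajimas_D",
    "fus_Fs",
    "raw_difference_matrix",
    "haplotype_indicator_matrix",
    "read_distance_matrix",
    "write_distance_matrix",
    "pairwise_phist",
    "nm_from_fst",
    "amova",
    "best_grouping_search",
    "diversity_stats",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative pairwise distances between samples."""

    sample_ids: list[str]
    matrix: np.ndarray
    metric: str = "raw_differences"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValidationError("distance matrix shape does not match sample_ids")
        finite = np.isfinite(m)
        if not np.allclose(m[finite], m.T[finite]):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(m[finite] < -1e-12):
            raise ValidationError("negative distances")
        if not np.allclose(np.diag(m), 0.0):
            raise ValidationError("nonzero diagonal")
        self.matrix = m

    def submatrix(self, sample_ids: list[str]) -> "DistanceMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.matrix[np.ix_(rows, rows)], self.metric)


@dataclass
class DiversityStats:
    """Per-group summary: n, H, Hd, pi, S, Tajima's D, Fu's Fs."""

    n: int
    H: int
    Hd: float
    pi: float
    S: int
    tajima_D: float | None
    fu_Fs: float | None


@dataclass
class AmovaResult:
    sigma2_a: float | None  # among groups
    sigma2_b: float | None  # among populations within groups
    sigma2_c: float | None  # within populations
    phi_CT: float | None
    phi_SC: float | None
    phi_ST: float | None
    p_CT: float | None = None
    p_SC: float | None = None
    p_ST: float | None = None
    df: tuple[int, int, int] | None = None
    ssd: tuple[float, float, float] | None = None  # among-group, among-pop-within, within-pop


# ---------------------------------------------------------------------------
# diversity


def haplotype_diversity(counts) -> float:
    """Nei's unbiased haplotype diversity Hd = n/(n-1) * (1 - sum p_i^2)."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValidationError("negative haplotype counts")
    n = c.sum()
    if n < 2:
        raise InsufficientSampleError(f"need at least 2 samples, got {int(n)}")
    p = c / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p**2)))


def _numeric_matrix(aln: Alignment, site_policy: str) -> np.ndarray:
    """Encode A,C,G,T as 0..3 and gap/N as -1; complete_sites drops masked columns."""
    lut = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1, "-": -1}
    num = np.vectorize(lut.get, otypes=[np.int8])(aln.matrix) if aln.n_sites else np.empty(
        (aln.n_samples, 0), dtype=np.int8
    )
    if site_policy == "complete_sites":
        keep = complete_site_mask(aln)
        num = num[:, keep]
    elif site_policy != "pairwise":
        raise ValueError(f"unknown site_policy: {site_policy!r}")
    return num


def _pairwise_diff_counts(num: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(differences, compared sites) per unordered pair, ignoring -1 cells."""
    n = num.shape[0]
    diffs = np.zeros((n, n))
    comp = np.zeros((n, n))
    valid = num >= 0
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        d = (num[i] != num[i + 1 :]) & both
        diffs[i, i + 1 :] = d.sum(axis=1)
        comp[i, i + 1 :] = both.sum(axis=1)
    diffs += diffs.T
    comp += comp.T
    return diffs, comp


def mean_pairwise_differences(aln: Alignment, site_policy: str = "complete_sites") -> float:
    """k_hat: mean number of differences over all unordered sequence pairs."""
    if aln.n_samples < 2:
        raise InsufficientSampleError("need at least 2 sequences")
    num = _numeric_matrix(aln, site_policy)
    diffs, comp = _pairwise_diff_counts(num)
    iu = np.triu_indices(aln.n_samples, 1)
    if np.any(comp[iu] == 0):
        raise DegenerateInputError("a sequence pair has no comparable sites")
    return float(diffs[iu].mean())


def nucleotide_diversity(aln: Alignment, site_policy: str = "complete_sites") -> float:
    """pi: mean pairwise differences per compared site."""
    if aln.n_samples < 2:
        raise InsufficientSampleError("need at least 2 sequences")
    num = _numeric_matrix(aln, site_policy)
    diffs, comp = _pairwise_diff_counts(num)
    iu = np.triu_indices(aln.n_samples, 1)
    if np.any(comp[iu] == 0):
        raise DegenerateInputError("a sequence pair has no comparable sites")
    return float((diffs[iu] / comp[iu]).mean())


def segregating_sites(aln: Alignment, site_policy: str = "complete_sites") -> int:
    num = _numeric_matrix(aln, site_policy)
    S = 0
    for j in range(num.shape[1]):
        col = num[:, j]
        states = set(col[col >= 0].tolist())
        if len(states) >= 2:
            S += 1
    return S


# ---------------------------------------------------------------------------
# neutrality tests


def tajimas_D(S: int, n: int, k_hat: float) -> float | None:
    """Tajima's D from segregating sites S, sample size n and mean pairwise
    differences k_hat.  Returns None when S == 0 (statistic undefined)."""
    if n < 4:
        raise InsufficientSampleError("Tajima's D requires n >= 4")
    if S < 0:
        raise ValidationError("S must be non-negative")
    if S == 0:
        return None
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    return float((k_hat - S / a1) / math.sqrt(var))


def _log_stirling_first_unsigned(n: int) -> np.ndarray:
    """Row n of log |s(n, k)| for k = 0..n via the triangular recurrence."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |s(0,0)| = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        # |s(m,k)| = (m-1)|s(m-1,k)| + |s(m-1,k-1)|
        with np.errstate(divide="ignore"):
            grow = row + math.log(m - 1) if m > 1 else np.full(n + 1, -np.inf)
        new[1:] = np.logaddexp(grow[1:], row[:-1])
        if m == 1:
            new[1] = 0.0
        row = new
    return row


def fus_Fs(n: int, theta: float, k0: int) -> float:
    """Fu's Fs = ln(S'/(1-S')) with S' = Pr(K >= k0 | theta) under the Ewens
    sampling distribution.  Returns +inf when S' == 1 (k0 == 1) and -inf when
    S' underflows to 0; computed entirely in log space."""
    if n < 2:
        raise InsufficientSampleError("Fu's Fs requires n >= 2")
    if theta <= 0:
        raise ValidationError("theta must be positive")
    if not 1 <= k0 <= n:
        raise ValidationError("k0 must lie in [1, n]")
    if k0 == 1:
        return math.inf
    log_stirl = _log_stirling_first_unsigned(n)
    log_theta = math.log(theta)
    log_rising = sum(math.log(theta + i) for i in range(n))
    ks = np.arange(1, n + 1)
    log_probs = log_stirl[1:] + ks * log_theta - log_rising
    from scipy.special import logsumexp

    log_upper = logsumexp(log_probs[k0 - 1 :])  # Pr(K >= k0)
    log_lower = logsumexp(log_probs[: k0 - 1])  # Pr(K < k0)
    # S' saturating at 0 or 1 within double precision is signalled as +/-inf
    if math.exp(log_upper) == 0.0:
        return -math.inf
    if math.exp(log_lower) == 0.0:
        return math.inf
    return float(log_upper - log_lower)


# ---------------------------------------------------------------------------
# distances and AMOVA


def raw_difference_matrix(
    aln: Alignment, site_policy: str = "complete_sites"
) -> DistanceMatrix:
    """Pairwise raw difference counts (the classical AMOVA substrate)."""
    num = _numeric_matrix(aln, site_policy)
    diffs, comp = _pairwise_diff_counts(num)
    iu = np.triu_indices(aln.n_samples, 1)
    if aln.n_samples >= 2 and np.any(comp[iu] == 0):
        raise DegenerateInputError("a sequence pair has no comparable sites")
    return DistanceMatrix(list(aln.sample_ids), diffs, "raw_differences")


def haplotype_indicator_matrix(
    aln: Alignment, site_policy: str = "complete_sites"
) -> DistanceMatrix:
    """0/1 distances (same haplotype or not): AMOVA on this matrix yields the
    conventional frequency-based F_ST rather than the distance-weighted
    Phi_ST."""
    from .alignment import collapse_haplotypes

    table = collapse_haplotypes(aln, site_policy=site_policy)
    h = np.array([table.assignment[s] for s in aln.sample_ids])
    mat = (h[:, None] != h[None, :]).astype(float)
    return DistanceMatrix(list(aln.sample_ids), mat, "haplotype_indicator")


def _ssd(d2: np.ndarray, index_sets: list[np.ndarray]) -> float:
    """Sum over sets of (1 / 2n_s) * sum_{i,j in s} d2[i, j] (ordered pairs)."""
    total = 0.0
    for idx in index_sets:
        if len(idx) == 0:
            continue
        total += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return total


def _two_level_components(d2: np.ndarray, pop_indices: list[np.ndarray]) -> tuple:
    """Variance components for populations-only AMOVA.

    Returns (sigma2_a, sigma2_c, phi_ST, df_a, df_c, ssd_a, ssd_c)."""
    N = d2.shape[0]
    P = len(pop_indices)
    all_idx = np.arange(N)
    ssd_total = _ssd(d2, [all_idx])
    ssd_wp = _ssd(d2, pop_indices)
    ssd_ap = ssd_total - ssd_wp
    df_a, df_c = P - 1, N - P
    sizes = np.array([len(i) for i in pop_indices], dtype=float)
    sigma2_c = ssd_wp / df_c if df_c > 0 else 0.0
    n_c = (N - (sizes**2).sum() / N) / df_a
    sigma2_a = (ssd_ap / df_a - sigma2_c) / n_c
    denom = sigma2_a + sigma2_c
    phi = sigma2_a / denom if denom > 0 else None
    return sigma2_a, sigma2_c, phi, df_a, df_c, ssd_ap, ssd_wp


def _check_pops(dm: DistanceMatrix, pops: PopulationAssignment) -> dict[str, np.ndarray]:
    index = {s: i for i, s in enumerate(dm.sample_ids)}
    missing = [s for s in dm.sample_ids if s not in pops.sample_to_pop]
    if missing:
        raise ValidationError(f"samples without population: {missing}")
    by_pop: dict[str, list[int]] = {}
    for s in dm.sample_ids:
        by_pop.setdefault(pops.sample_to_pop[s], []).append(index[s])
    return {p: np.asarray(v) for p, v in by_pop.items()}


def pairwise_phist(
    dm: DistanceMatrix,
    pops: PopulationAssignment,
    n_perm: int = 10_000,
    seed: int | None = None,
    truncate_negative: bool = False,
) -> dict[tuple[str, str], tuple[float | None, float | None, float | None]]:
    """Pairwise Phi_ST with permutation p-values and Nm for every population pair.

    Returns {(popA, popB): (phi_ST, p, Nm)}.  The permutation scheme shuffles
    individuals between the two populations only; p uses the add-one rule
    (count + 1) / (n_perm + 1).
    """
    by_pop = _check_pops(dm, pops)
    pops_list = list(by_pop)
    if len(pops_list) < 2:
        raise InsufficientSampleError("need at least two populations")
    for p, idx in by_pop.items():
        if len(idx) < 2:
            raise InsufficientSampleError(f"population '{p}' has fewer than 2 samples")
    rng = np.random.default_rng(seed)
    d2 = dm.matrix**2
    out: dict[tuple[str, str], tuple] = {}
    for a in range(len(pops_list)):
        for b in range(a + 1, len(pops_list)):
            pa, pb = pops_list[a], pops_list[b]
            ia, ib = by_pop[pa], by_pop[pb]
            phi = _pair_phi(d2, ia, ib, truncate_negative)
            if phi is None:
                out[(pa, pb)] = (None, None, None)
                continue
            pooled = np.concatenate([ia, ib])
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(pooled)
                phi_p = _pair_phi(d2, perm[: len(ia)], perm[len(ia) :], truncate_negative)
                if phi_p is not None and phi_p >= phi - 1e-12:
                    count += 1
            p_val = (count + 1.0) / (n_perm + 1.0)
            out[(pa, pb)] = (phi, p_val, nm_from_fst(phi))
    return out


def _pair_phi(d2, ia, ib, truncate_negative=False) -> float | None:
    s2a, s2c, phi, *_ = _two_level_components(d2, [ia, ib])
    if phi is None:
        return None
    if truncate_negative:
        s2a = max(s2a, 0.0)
        denom = s2a + s2c
        phi = s2a / denom if denom > 0 else None
    return phi


def nm_from_fst(fst: float) -> float:
    """Migrants per generation under the haploid/maternal island-model
    convention Nm = (1 - F_ST) / (2 F_ST)."""
    if fst is None:
        return None
    if fst <= 0:
        return math.inf
    if fst >= 1:
        return 0.0
    return (1.0 - fst) / (2.0 * fst)


def amova(
    dm: DistanceMatrix,
    pops: PopulationAssignment,
    n_perm: int = 20_000,
    seed: int | None = None,
    truncate_negative: bool = False,
) -> AmovaResult:
    """Hierarchical AMOVA (groups / populations / individuals).

    With a single group (or no group layer) a two-level AMOVA is returned with
    the among-group fields set to None.  Negative variance components are
    reported as computed unless ``truncate_negative``.
    """
    by_pop = _check_pops(dm, pops)
    d2 = dm.matrix**2
    N = d2.shape[0]
    pop_names = list(by_pop)
    P = len(pop_names)

    if pops.pop_to_group is None or len(set(pops.pop_to_group.values())) < 2:
        # two-level: among populations / within populations
        idx_sets = [by_pop[p] for p in pop_names]
        s2a, s2c, phi, df_a, df_c, ssd_a, ssd_c = _two_level_components(d2, idx_sets)
        if truncate_negative:
            s2a = max(s2a, 0.0)
            phi = s2a / (s2a + s2c) if (s2a + s2c) > 0 else None
        p_st = _perm_p_individuals(d2, idx_sets, phi, n_perm, seed) if phi is not None else None
        return AmovaResult(
            sigma2_a=None, sigma2_b=s2a, sigma2_c=s2c,
            phi_CT=None, phi_SC=None, phi_ST=phi,
            p_CT=None, p_SC=None, p_ST=p_st,
            df=(0, df_a, df_c), ssd=(0.0, ssd_a, ssd_c),
        )

    uncovered = sorted(set(pop_names) - set(pops.pop_to_group))
    if uncovered:
        raise ValidationError(f"populations without group: {uncovered}")
    group_of = {p: pops.pop_to_group[p] for p in pop_names}
    groups = list(dict.fromkeys(group_of[p] for p in pop_names))

    comp = _three_level_components(d2, by_pop, group_of, groups, truncate_negative)
    (s2a, s2b, s2c, phis, dfs, ssds) = comp
    phi_ct, phi_sc, phi_st = phis

    rng = np.random.default_rng(seed)
    p_ct = p_sc = p_st = None
    if phi_st is not None:
        p_st = _perm_p_individuals(d2, [by_pop[p] for p in pop_names], phi_st, n_perm,
                                   rng.integers(2**31), statistic="phi_st",
                                   by_pop=by_pop, group_of=group_of, groups=groups,
                                   truncate=truncate_negative)
    if phi_sc is not None:
        p_sc = _perm_p_within_groups(d2, by_pop, group_of, groups, phi_sc, n_perm,
                                     rng.integers(2**31), truncate_negative)
    if phi_ct is not None:
        p_ct = _perm_p_pops_among_groups(d2, by_pop, group_of, groups, phi_ct, n_perm,
                                         rng.integers(2**31), truncate_negative)
    return AmovaResult(s2a, s2b, s2c, phi_ct, phi_sc, phi_st, p_ct, p_sc, p_st, dfs, ssds)


def _three_level_components(d2, by_pop, group_of, groups, truncate=False):
    pop_names = list(by_pop)
    N = d2.shape[0]
    P = len(pop_names)
    G = len(groups)
    pops_in_g = {g: [p for p in pop_names if group_of[p] == g] for g in groups}
    group_idx = {g: np.concatenate([by_pop[p] for p in pops_in_g[g]]) for g in groups}

    ssd_total = _ssd(d2, [np.arange(N)])
    ssd_wp = _ssd(d2, [by_pop[p] for p in pop_names])
    ssd_wg = _ssd(d2, [group_idx[g] for g in groups])
    ssd_ap = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg
    df_a, df_b, df_c = G - 1, P - G, N - P

    sizes = {p: float(len(by_pop[p])) for p in pop_names}
    n_g = {g: float(len(group_idx[g])) for g in groups}
    sum_sq_over_g = sum(sum(sizes[p] ** 2 for p in pops_in_g[g]) / n_g[g] for g in groups)
    sum_sq_total = sum(sizes[p] ** 2 for p in pop_names) / N

    sigma2_c = ssd_wp / df_c if df_c > 0 else 0.0
    if df_b > 0:
        n1 = (N - sum_sq_over_g) / df_b
        sigma2_b = (ssd_ap / df_b - sigma2_c) / n1
    else:
        sigma2_b = 0.0
    n2 = (sum_sq_over_g - sum_sq_total) / df_a
    n3 = (N - sum(v**2 for v in n_g.values()) / N) / df_a
    sigma2_a = (ssd_ag / df_a - sigma2_c - n2 * sigma2_b) / n3

    if truncate:
        sigma2_a = max(sigma2_a, 0.0)
        sigma2_b = max(sigma2_b, 0.0)

    total = sigma2_a + sigma2_b + sigma2_c
    phi_ct = sigma2_a / total if total > 0 else None
    phi_sc = sigma2_b / (sigma2_b + sigma2_c) if (sigma2_b + sigma2_c) > 0 else None
    phi_st = (sigma2_a + sigma2_b) / total if total > 0 else None
    return (
        sigma2_a, sigma2_b, sigma2_c,
        (phi_ct, phi_sc, phi_st),
        (df_a, df_b, df_c),
        (ssd_ag, ssd_ap, ssd_wp),
    )


def _perm_p_individuals(d2, idx_sets, observed, n_perm, seed, statistic="two_level",
                        by_pop=None, group_of=None, groups=None, truncate=False):
    """Permute individuals among all populations; recompute the statistic."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate(idx_sets)
    sizes = [len(s) for s in idx_sets]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        new_sets, start = [], 0
        for sz in sizes:
            new_sets.append(perm[start : start + sz])
            start += sz
        if statistic == "two_level":
            stat = _two_level_components(d2, new_sets)[2]
        else:  # phi_st within the three-level design
            new_by_pop = dict(zip(by_pop.keys(), new_sets))
            stat = _three_level_components(d2, new_by_pop, group_of, groups, truncate)[3][2]
        if stat is not None and stat >= observed - 1e-12:
            count += 1
    return (count + 1.0) / (n_perm + 1.0)


def _perm_p_within_groups(d2, by_pop, group_of, groups, observed, n_perm, seed, truncate):
    """Permute individuals among populations within each group (Phi_SC null)."""
    rng = np.random.default_rng(seed)
    pop_names = list(by_pop)
    count = 0
    for _ in range(n_perm):
        new_by_pop = {}
        for g in groups:
            g_pops = [p for p in pop_names if group_of[p] == g]
            pooled = np.concatenate([by_pop[p] for p in g_pops])
            perm = rng.permutation(pooled)
            start = 0
            for p in g_pops:
                sz = len(by_pop[p])
                new_by_pop[p] = perm[start : start + sz]
                start += sz
        stat = _three_level_components(d2, new_by_pop, group_of, groups, truncate)[3][1]
        if stat is not None and stat >= observed - 1e-12:
            count += 1
    return (count + 1.0) / (n_perm + 1.0)


def _perm_p_pops_among_groups(d2, by_pop, group_of, groups, observed, n_perm, seed, truncate):
    """Permute whole populations among groups, keeping pops-per-group counts."""
    rng = np.random.default_rng(seed)
    pop_names = list(by_pop)
    n_per_group = [sum(1 for p in pop_names if group_of[p] == g) for g in groups]
    count = 0
    for _ in range(n_perm):
        perm_pops = list(rng.permutation(pop_names))
        new_group_of, start = {}, 0
        for g, k in zip(groups, n_per_group):
            for p in perm_pops[start : start + k]:
                new_group_of[p] = g
            start += k
        stat = _three_level_components(d2, by_pop, new_group_of, groups, truncate)[3][0]
        if stat is not None and stat >= observed - 1e-12:
            count += 1
    return (count + 1.0) / (n_perm + 1.0)


def best_grouping_search(
    dm: DistanceMatrix,
    pops: PopulationAssignment,
    candidate_groupings: list[dict[str, str]],
    n_perm: int = 1000,
    seed: int | None = None,
) -> list[dict]:
    """Run AMOVA per candidate pop->group map; rank by Phi_CT descending.

    Ties break toward fewer groups, then input order; candidates whose AMOVA
    fails or yields an undefined Phi_CT sink to the bottom (error recorded,
    search never aborts).  Each entry: {grouping, phi_CT, p_CT, error}.
    """
    if not candidate_groupings:
        raise ValidationError("no candidate groupings supplied")
    rng = np.random.default_rng(seed)
    rows = []
    for order, grouping in enumerate(candidate_groupings):
        entry = {"grouping": grouping, "phi_CT": None, "p_CT": None, "error": None}
        try:
            res = amova(dm, pops.with_groups(grouping), n_perm=n_perm,
                        seed=int(rng.integers(2**31)))
            entry["phi_CT"], entry["p_CT"] = res.phi_CT, res.p_CT
        except Exception as exc:  # record and continue the search
            entry["error"] = str(exc)
        entry["_order"] = order
        entry["_ngroups"] = len(set(grouping.values()))
        rows.append(entry)
    rows.sort(
        key=lambda e: (
            0 if e["phi_CT"] is not None else 1,
            -(e["phi_CT"] if e["phi_CT"] is not None else 0.0),
            e["_ngroups"],
            e["_order"],
        )
    )
    for e in rows:
        e.pop("_order")
        e.pop("_ngroups")
    return rows


# ---------------------------------------------------------------------------
# distance-matrix TSV interface


def read_distance_matrix(path, metric: str = "raw_differences") -> DistanceMatrix:
    """Square TSV with a header row and leading column of sample IDs."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValidationError("row and column sample IDs differ")
    return DistanceMatrix([str(s) for s in df.index], df.to_numpy(dtype=float), metric)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    import pandas as pd

    pd.DataFrame(dm.matrix, index=dm.sample_ids, columns=dm.sample_ids).to_csv(
        path, sep="\t"
    )


# ---------------------------------------------------------------------------
# per-group summaries


def diversity_stats(aln: Alignment, site_policy: str = "complete_sites") -> DiversityStats:
    """n, H, Hd, pi, S, Tajima's D and Fu's Fs for one sample of sequences.

    Haplotypes, S and k_hat are all computed on the same retained-site set so
    the statistics are mutually consistent.  Fu's Fs uses theta = k_hat.
    """
    from .alignment import collapse_haplotypes

    n = aln.n_samples
    table = collapse_haplotypes(aln, site_policy=site_policy)
    H = table.n_haplotypes
    Hd = haplotype_diversity(table.total_counts()) if n >= 2 else 0.0
    pi = nucleotide_diversity(aln, site_policy)
    S = segregating_sites(aln, site_policy)
    k_hat = mean_pairwise_differences(aln, site_policy)
    D = tajimas_D(S, n, k_hat) if n >= 4 else None
    Fs = fus_Fs(n, k_hat, H) if k_hat > 0 else None
    return DiversityStats(n=n, H=H, Hd=Hd, pi=pi, S=S, tajima_D=D, fu_Fs=Fs)
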