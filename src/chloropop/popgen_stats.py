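"""Diversity, differentiation and ordination statistics on haploid calls.

Implements windowed nucleotide diversity (pi), the Weir-Cockerham (1984)
weighted FST estimator reduced to its haploid one-level ANOVA form,
Tajima's (1989) D, and PCA / classical MDS ordinations of the sample
panel.  All statistics use per-site denominators so that missing calls
shrink the local sample size rather than biasing the estimate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .variant_io import MISSING, GenotypeMatrix, PopulationMap


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class WindowStat:
    group: str
    start: int          # 1-based inclusive
    end: int
    length: int
    pi: float           # per-site diversity; NaN when undefined
    n_variants: int


@dataclass
class FstResult:
    group_a: str
    group_b: str
    fst: float
    per_site: list[tuple[int, float, float]]  # (pos, a=among, b=within)


@dataclass
class TajimaResult:
    group: str
    S: int
    n: int
    pi_total: float
    constants: dict[str, float]
    D: float            # NaN when S == 0


@dataclass
class OrdinationResult:
    method: str                              # "PCA" | "MDS"
    coordinates: dict[str, np.ndarray]       # sample -> first k axis values
    explained: np.ndarray | None = None      # PCA only


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

def site_diversity(m: GenotypeMatrix, sample_idx: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity h_i = n/(n-1) (1 - sum p_a^2).

    Sites with fewer than two non-missing calls get NaN.  Equals the mean
    pairwise difference at the site, so summing over a window and dividing
    by window length gives pi.
    """
    out = np.full(m.n_sites, np.nan)
    for i in range(m.n_sites):
        counts = m.allele_counts(i, sample_idx)
        n = counts.sum()
        if n < 2:
            continue
        p = counts / n
        out[i] = n / (n - 1) * (1.0 - float(np.sum(p * p)))
    return out


def nucleotide_diversity(m: GenotypeMatrix, samples: Sequence[str] | None = None,
                         window: int = 1000, step: int = 500,
                         group: str = "all") -> list[WindowStat]:
    """Sliding-window nucleotide diversity per site.

    Windows are anchored at position 1 and tile 1..genome_length; the
    terminal window may be shorter and is reported with its true length.
    pi divides by window length (invariant positions included), matching
    the conventional per-site scale.
    """
    if not (window >= step >= 1):
        raise ValueError("need window >= step >= 1")
    idx = m.sample_indices(samples)
    if idx.size < 2:
        raise ValueError("need at least 2 samples for diversity")
    h = site_diversity(m, idx)
    pos = m.positions
    out: list[WindowStat] = []
    start = 1
    while start <= m.genome_length:
        end = min(start + window - 1, m.genome_length)
        length = end - start + 1
        in_win = (pos >= start) & (pos <= end)
        h_win = h[in_win]
        n_var = int(np.sum(in_win))
        defined = h_win[~np.isnan(h_win)]
        if n_var > 0 and defined.size == 0:
            pi = float("nan")  # variants present but nowhere callable
        else:
            pi = float(np.sum(defined)) / length
        out.append(WindowStat(group, start, end, length, pi, n_var))
        if end == m.genome_length:
            break
        start += step
    return out


def mean_diversity(m: GenotypeMatrix, samples: Sequence[str] | None = None) -> float:
    """Genome-wide pi: summed site diversity over genome length."""
    idx = m.sample_indices(samples)
    if idx.size < 2:
        raise ValueError("need at least 2 samples for diversity")
    h = site_diversity(m, idx)
    return float(np.nansum(h)) / m.genome_length


# ---------------------------------------------------------------------------
# Weir-Cockerham FST (haploid)
# ---------------------------------------------------------------------------

def _wc_site_components(counts_a: np.ndarray, counts_b: np.ndarray
                        ) -> tuple[float, float] | None:
    """Haploid Weir-Cockerham variance components for one site.

    With haploid data the 1984 hierarchy collapses to a one-level ANOVA on
    allele indicators: for each allele, MSP (among populations) and MSG
    (within, i.e. between genes within populations) give
    a = (MSP - MSG)/n_c and b = MSG.  Components are summed over alleles.
    Returns None when the site is unusable (a group with < 2 calls) or
    monomorphic across both groups.
    """
    n_a, n_b = counts_a.sum(), counts_b.sum()
    if n_a < 2 or n_b < 2:
        return None
    width = max(len(counts_a), len(counts_b))
    ca = np.zeros(width); ca[: len(counts_a)] = counts_a
    cb = np.zeros(width); cb[: len(counts_b)] = counts_b
    total = ca + cb
    if np.count_nonzero(total) < 2:
        return None  # monomorphic across both groups
    r = 2
    n_sum = n_a + n_b
    n_c = (n_sum - (n_a**2 + n_b**2) / n_sum) / (r - 1)
    a_tot = b_tot = 0.0
    for allele in range(width):
        if total[allele] == 0:
            continue
        p_a, p_b = ca[allele] / n_a, cb[allele] / n_b
        p_bar = total[allele] / n_sum
        msp = (n_a * (p_a - p_bar) ** 2 + n_b * (p_b - p_bar) ** 2) / (r - 1)
        msg = (n_a * p_a * (1 - p_a) + n_b * p_b * (1 - p_b)) / (n_sum - r)
        a_tot += (msp - msg) / n_c
        b_tot += msg
    return a_tot, b_tot


def weir_cockerham_fst(m: GenotypeMatrix, pm: PopulationMap,
                       group_a: str, group_b: str) -> FstResult:
    """Weighted Weir-Cockerham FST between two groups.

    The weighted estimator is the ratio of summed among-group variance
    components to summed total components across sites (not a mean of
    per-site ratios), the combination the estimator's authors recommend
    for multi-locus data.
    """
    idx_a = m.sample_indices(pm.members(group_a))
    idx_b = m.sample_indices(pm.members(group_b))
    per_site: list[tuple[int, float, float]] = []
    num = den = 0.0
    for i in range(m.n_sites):
        comp = _wc_site_components(m.allele_counts(i, idx_a),
                                   m.allele_counts(i, idx_b))
        if comp is None:
            continue
        a, b = comp
        per_site.append((int(m.records[i].pos), a, b))
        num += a
        den += a + b
    if den == 0.0:
        raise ValueError(
            f"no usable polymorphic sites between {group_a!r} and {group_b!r}"
        )
    return FstResult(group_a, group_b, num / den, per_site)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    """The 1989 normalizing constants a1..e2 for sample size n."""
    if n < 2:
        raise ValueError("need n >= 2 sequences")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(m: GenotypeMatrix, samples: Sequence[str] | None = None,
              window: int | None = None, step: int = 500,
              group: str = "all") -> TajimaResult | list[TajimaResult]:
    """Tajima's D for a sample subset, whole-genome or windowed.

    D = (pi_total - S/a1) / sqrt(e1 S + e2 S (S-1)).  S counts sites
    polymorphic among the subset's non-missing calls; pi_total is the mean
    pairwise difference (summed unbiased site heterozygosity).  n for the
    constants is the subset size.  S = 0 yields NaN with a warning.
    """
    idx = m.sample_indices(samples)
    n = int(idx.size)
    if n < 2:
        raise ValueError("need at least 2 sequences")

    def _one(site_ids: np.ndarray, start: int, end: int) -> TajimaResult:
        S = 0
        pi_total = 0.0
        for i in site_ids:
            counts = m.allele_counts(int(i), idx)
            tot = counts.sum()
            if tot < 2 or np.count_nonzero(counts) < 2:
                continue
            S += 1
            p = counts / tot
            pi_total += tot / (tot - 1) * (1.0 - float(np.sum(p * p)))
        consts = tajima_constants(n)
        if S == 0:
            warnings.warn(f"no segregating sites in {group} "
                          f"[{start},{end}]; Tajima's D undefined", stacklevel=3)
            D = float("nan")
        else:
            var = consts["e1"] * S + consts["e2"] * S * (S - 1)
            D = (pi_total - S / consts["a1"]) / math.sqrt(var)
        return TajimaResult(group, S, n, pi_total, consts, D)

    all_sites = np.arange(m.n_sites)
    if window is None:
        return _one(all_sites, 1, m.genome_length)
    pos = m.positions
    out = []
    start = 1
    while start <= m.genome_length:
        end = min(start + window - 1, m.genome_length)
        out.append(_one(all_sites[(pos >= start) & (pos <= end)], start, end))
        if end == m.genome_length:
            break
        start += step
    return out


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

def _allele_count_matrix(m: GenotypeMatrix, idx: np.ndarray) -> np.ndarray:
    """Samples x sites matrix of allele indexes, missing imputed to site mean."""
    X = m.calls_matrix()[:, idx].astype(float).T  # samples x sites
    miss = X == MISSING
    X[miss] = np.nan
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    ii, jj = np.where(miss)
    X[ii, jj] = col_mean[jj]
    return X


def pca(m: GenotypeMatrix, samples: Sequence[str] | None = None,
        k: int = 2) -> OrdinationResult:
    """PCA of the mean-centered allele-count matrix (missing -> site mean)."""
    from sklearn.decomposition import PCA

    idx = m.sample_indices(samples)
    names = [m.samples[i] for i in idx]
    if idx.size < k + 1:
        raise ValueError(f"need at least k+1={k + 1} samples")
    X = _allele_count_matrix(m, idx)
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("all sites monomorphic in subset; PCA undefined")
    model = PCA(n_components=min(k, idx.size - 1, X.shape[1]))
    coords = model.fit_transform(X)
    return OrdinationResult(
        "PCA",
        {name: coords[i] for i, name in enumerate(names)},
        explained=model.explained_variance_ratio_,
    )


def hamming_distance_matrix(m: GenotypeMatrix,
                            samples: Sequence[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Pairwise normalized allele-mismatch distances.

    Missing-containing pairs of calls are excluded per pair; the distance
    is the mismatch fraction over the pair's complete sites (0 when no
    complete site exists).
    """
    idx = m.sample_indices(samples)
    names = [m.samples[i] for i in idx]
    X = m.calls_matrix()[:, idx]
    ns = idx.size
    D = np.zeros((ns, ns))
    for i in range(ns):
        for j in range(i + 1, ns):
            ok = (X[:, i] != MISSING) & (X[:, j] != MISSING)
            n_ok = int(np.sum(ok))
            d = float(np.sum(X[ok, i] != X[ok, j])) / n_ok if n_ok else 0.0
            D[i, j] = D[j, i] = d
    return D, names


def mds(m: GenotypeMatrix, samples: Sequence[str] | None = None,
        k: int = 2) -> OrdinationResult:
    """Classical metric scaling (principal coordinates) of Hamming distances."""
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.ordination import pcoa

    idx = m.sample_indices(samples)
    if idx.size < 3:
        raise ValueError("need at least 3 samples for MDS")
    D, names = hamming_distance_matrix(m, samples)
    if np.allclose(D, 0.0):
        warnings.warn("all pairwise distances zero; samples collapse to one point",
                      stacklevel=2)
        return OrdinationResult("MDS", {n: np.zeros(k) for n in names})
    res = pcoa(DistanceMatrix(D, ids=names), number_of_dimensions=min(k, len(names) - 1))
    coords = res.samples.to_numpy()
    if coords.shape[1] < k:  # pad degenerate axes with zeros
        coords = np.hstack([coords, np.zeros((coords.shape[0], k - coords.shape[1]))])
    return OrdinationResult("MDS", {n: coords[i, :k] for i, n in enumerate(names)})
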