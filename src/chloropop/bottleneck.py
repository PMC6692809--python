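"""Heterozygosity-excess bottleneck tests (IAM / TPM / SMM).

After a recent contraction in effective population size, rare alleles are
lost faster than gene diversity decays, so the observed diversity at a
locus exceeds the equilibrium expectation for its allele count.  The test
simulates, per locus, the equilibrium gene-diversity distribution from
neutral coalescent genealogies conditioned on the observed number of
alleles k and sample size n under one of three mutation models:

* IAM — infinite alleles: every mutation creates a novel allele;
* SMM — strict stepwise: every mutation moves one step on an integer
  allele ladder;
* TPM — two-phase: single-step with probability ``p_single``, otherwise a
  geometric multi-step jump (variance ``tpm_variance``).

The scaled mutation rate is tuned so the expected allele count matches k
(Ewens' formula for IAM, stochastic search otherwise), and replicates are
accepted only when exactly k alleles are observed.  Per-locus
standardized deviations DH = (He_obs - Heq_mean)/Heq_sd feed a sign test
(against the simulation-estimated expected excess proportion) and a
one-tailed Wilcoxon signed-rank test for heterozygosity excess.

SNP-type chloroplast loci are not microsatellites; SMM and TPM assume a
stepwise allele ladder that SNP alleles do not possess.  Both are
implemented to complete the classical three-model design, with IAM being
the model whose assumptions actually match this data type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .variant_io import MISSING, GenotypeMatrix, PopulationMap

MODELS = ("IAM", "TPM", "SMM")

#: Two-phase model defaults (the classical program's exposed knobs).
TPM_P_SINGLE: float = 0.70
TPM_VARIANCE: float = 30.0


@dataclass
class BottleneckLocus:
    site: int                 # position (bp)
    k: int
    n: int
    he_obs: float
    heq_mean: float
    heq_sd: float
    dh: float
    excess: bool


@dataclass
class BottleneckResult:
    group: str
    model: str
    loci: list[BottleneckLocus]
    p_sign: float
    p_wilcoxon: float
    reps: int
    expected_excess_proportion: float


# ---------------------------------------------------------------------------
# Observed gene diversity
# ---------------------------------------------------------------------------

def unbiased_heterozygosity(counts: np.ndarray) -> float:
    """Nei's unbiased gene diversity n/(n-1) (1 - sum p^2)."""
    n = counts.sum()
    if n < 2:
        raise ValueError("need >= 2 genes")
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p * p)))


def prefilter_loci(m: GenotypeMatrix, min_maf: float = 0.05,
                   pm: PopulationMap | None = None,
                   group: str | None = None) -> GenotypeMatrix:
    """Retain loci with MAF >= min_maf and >= 2 alleles (in the tested group).

    Removal is strict "< min_maf", so a locus exactly at the threshold
    stays.
    """
    idx = (m.sample_indices(pm.members(group))
           if pm is not None and group is not None else None)
    keep = []
    for i in range(m.n_sites):
        counts = m.allele_counts(i, idx)
        total = counts.sum()
        if total < 2 or np.count_nonzero(counts) < 2:
            continue
        order = np.sort(counts)[::-1]
        maf = order[1] / total
        if not (maf < min_maf):
            keep.append(i)
    if not keep:
        raise ValueError("no loci survive the bottleneck pre-filter")
    return m.subset_sites(keep)


# ---------------------------------------------------------------------------
# Coalescent simulation conditioned on allele count
# ---------------------------------------------------------------------------

def _genealogy_alleles(n: int, theta: float, model: str, rng: np.random.Generator,
                       p_single: float, tpm_p_geom: float) -> np.ndarray:
    """Allele states of n genes under one coalescent genealogy.

    Builds a Kingman genealogy (pairwise coalescence at rate j(j-1)/2),
    drops Poisson(theta/2 * branch length) mutations on each branch, and
    propagates allele states root-to-leaf per the mutation model.
    """
    # children[v] = (left, right); leaves are 0..n-1
    children: dict[int, tuple[int, int]] = {}
    node_time = [0.0] * n
    active = list(range(n))
    next_id = n
    t = 0.0
    while len(active) > 1:
        j = len(active)
        t += rng.exponential(2.0 / (j * (j - 1)))
        i1, i2 = rng.choice(j, size=2, replace=False)
        a, b = active[i1], active[i2]
        children[next_id] = (a, b)
        node_time.append(t)
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1

    root = active[0]
    states = np.empty(next_id, dtype=np.int64)
    states[root] = 0
    new_allele = 1
    # iterative pre-order traversal
    stack = [root]
    while stack:
        v = stack.pop()
        if v not in children:
            continue
        for child in children[v]:
            blen = node_time[v] - node_time[child]
            n_mut = rng.poisson(theta / 2.0 * blen)
            state = states[v]
            for _ in range(n_mut):
                if model == "IAM":
                    state = new_allele
                    new_allele += 1
                elif model == "SMM":
                    state += rng.choice((-1, 1))
                else:  # TPM
                    step = 1 if rng.random() < p_single else int(rng.geometric(tpm_p_geom))
                    state += int(rng.choice((-1, 1))) * step
            states[child] = state
            stack.append(child)
    return states[:n]


def _ewens_theta(k: int, n: int) -> float:
    """theta with Ewens expected allele count k in a sample of n (IAM)."""
    if k == n:
        return float(n * n)  # effectively every gene distinct

    def expected_k(theta: float) -> float:
        return sum(theta / (theta + i) for i in range(n))

    return float(optimize.brentq(lambda t: expected_k(t) - k, 1e-6, 1e6))


def _tune_theta(k: int, n: int, model: str, rng: np.random.Generator,
                p_single: float, tpm_p_geom: float) -> float:
    """theta with simulated mean allele count ~ k for ladder models.

    Starts from the Ewens value (an underestimate under homoplasy) and
    performs a short multiplicative stochastic search.
    """
    theta = _ewens_theta(k, n)
    if model == "IAM" or k == 2:
        # for k=2 homoplasy barely shifts E[K]; Ewens start is adequate
        return theta

    def mean_k(th: float, reps: int = 150) -> float:
        ks = [len(np.unique(_genealogy_alleles(n, th, model, rng,
                                               p_single, tpm_p_geom)))
              for _ in range(reps)]
        return float(np.mean(ks))

    lo = hi = theta
    mk = mean_k(theta)
    for _ in range(12):
        if abs(mk - k) < 0.15:
            return theta
        if mk < k:
            lo = theta
            theta *= 1.6
            hi = theta
        else:
            hi = theta
            theta /= 1.6
            lo = theta
        mk = mean_k(theta)
    # final bisection passes
    for _ in range(6):
        mid = math.sqrt(lo * hi)
        if mean_k(mid) < k:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def simulate_heq(k: int, n: int, model: str, reps: int = 1000,
                 seed: int | None = None,
                 p_single: float = TPM_P_SINGLE,
                 tpm_variance: float = TPM_VARIANCE,
                 rng: np.random.Generator | None = None
                 ) -> tuple[float, float, np.ndarray]:
    """Equilibrium gene-diversity distribution conditioned on k alleles.

    Returns (mean, sd, accepted He samples) over ``reps`` replicates that
    produced exactly k alleles in n genes.  Raises if acceptance falls
    below 1%.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if not (2 <= k <= n):
        raise ValueError("need 2 <= k <= n")
    if reps < 100:
        raise ValueError("need reps >= 100 for a stable Heq distribution")
    if rng is None:
        rng = np.random.default_rng(seed)
    # geometric step distribution with the requested variance: var = (1-p)/p^2
    p_geom = (math.sqrt(1.0 + 4.0 * tpm_variance) - 1.0) / (2.0 * tpm_variance)
    theta = _tune_theta(k, n, model, rng, p_single, p_geom)

    accepted = np.empty(reps)
    got = 0
    attempts = 0
    max_attempts = reps * 100
    while got < reps and attempts < max_attempts:
        attempts += 1
        alleles = _genealogy_alleles(n, theta, model, rng, p_single, p_geom)
        _, counts = np.unique(alleles, return_counts=True)
        if len(counts) != k:
            continue
        accepted[got] = unbiased_heterozygosity(counts)
        got += 1
    if got < reps:
        raise RuntimeError(
            f"acceptance rate {got / attempts:.2%} below 1% for k={k}, n={n}, "
            f"{model}; widen the theta search"
        )
    return float(accepted.mean()), float(accepted.std(ddof=1)), accepted


# ---------------------------------------------------------------------------
# The test
# ---------------------------------------------------------------------------

def het_excess_test(m: GenotypeMatrix, pm: PopulationMap | None, group: str | None,
                    model: str = "IAM", reps: int = 1000,
                    seed: int | None = None, min_maf: float = 0.05,
                    p_single: float = TPM_P_SINGLE,
                    tpm_variance: float = TPM_VARIANCE) -> BottleneckResult:
    """Heterozygosity-excess bottleneck test for one group and model.

    Loci passing the MAF pre-filter are each compared with their
    simulated equilibrium distribution (shared across loci with the same
    (k, n)); significance comes from a one-tailed Wilcoxon signed-rank on
    the per-locus deviations and a binomial sign test whose reference
    excess proportion is estimated from the same simulations.
    """
    filtered = prefilter_loci(m, min_maf=min_maf, pm=pm, group=group)
    idx = (m.sample_indices(pm.members(group))
           if pm is not None and group is not None else None)
    rng = np.random.default_rng(seed)

    cache: dict[tuple[int, int], tuple[float, float, np.ndarray]] = {}
    loci: list[BottleneckLocus] = []
    pe_sum = 0.0
    for i in range(filtered.n_sites):
        counts = filtered.allele_counts(i, idx)
        counts = counts[counts > 0]
        k, n = len(counts), int(counts.sum())
        key = (k, n)
        if key not in cache:
            cache[key] = simulate_heq(k, n, model, reps=reps, rng=rng,
                                      p_single=p_single, tpm_variance=tpm_variance)
        mean, sd, samples = cache[key]
        he = unbiased_heterozygosity(counts)
        dh = (he - mean) / sd if sd > 0 else 0.0
        loci.append(BottleneckLocus(int(filtered.records[i].pos), k, n,
                                    he, mean, sd, dh, he > mean))
        pe_sum += float(np.mean(samples > mean))
    if len(loci) < 2:
        raise ValueError("need >= 2 testable loci")

    dhs = np.array([l.dh for l in loci])
    n_excess = int(sum(l.excess for l in loci))
    pe = pe_sum / len(loci)
    p_sign = float(stats.binomtest(n_excess, len(loci), pe,
                                   alternative="greater").pvalue)
    nonzero = dhs[dhs != 0]
    if nonzero.size == 0:
        p_wilcoxon = 1.0
    else:
        p_wilcoxon = float(stats.wilcoxon(nonzero, alternative="greater").pvalue)
    return BottleneckResult(group or "all", model, loci, p_sign, p_wilcoxon,
                            reps, pe)
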