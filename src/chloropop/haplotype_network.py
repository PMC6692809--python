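"""Haplotype collapsing and statistical-parsimony (TCS-style) networks.

The chloroplast does not recombine, so each accession carries its variant
alleles as a single haplotype.  Samples with identical allele vectors over
the retained sites collapse into one haplotype; haplotypes are then
connected into a network by single mutational steps, agglomeratively in
increasing distance order, up to a parsimony connection limit: the
largest number of observed differences that can be attributed to
non-superimposed mutations with a given confidence (95% by default).

The connection-limit probability is computed from a neutral-pair model:
the number of mutations separating two sequences is geometric (its mean
moment-matched to the observed differences), mutations fall uniformly and
independently over the sites, and the limit is the largest difference
count j for which the posterior probability that the j differences
involved no repeated site exceeds the confidence level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .variant_io import MISSING, GenotypeMatrix


@dataclass
class Haplotype:
    hap_id: str
    key: tuple[int, ...]          # allele vector over retained sites
    members: list[str]
    group_counts: dict[str, int] = field(default_factory=dict)

    @property
    def frequency(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph               # nodes carry {"haplotype": Haplotype | None}
    limit: int

    @property
    def sampled_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["haplotype"] is not None]

    @property
    def intermediate_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["haplotype"] is None]

    @property
    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]


# ---------------------------------------------------------------------------
# Collapsing
# ---------------------------------------------------------------------------

def collapse_haplotypes(m: GenotypeMatrix, samples: Sequence[str] | None = None,
                        pm=None, missing_policy: str = "exclude",
                        snps_only: bool = False) -> list[Haplotype]:
    """Group samples sharing an allele vector over the retained sites.

    ``missing_policy="exclude"`` (default) drops samples with any MISSING
    call at a retained site; ``"pairwise"`` keeps them and treats MISSING
    as matching nothing, which can create non-transitive identity and is
    therefore off by default.  ``snps_only`` restricts the vector to SNP
    sites.  Haplotype ids are assigned H1, H2, ... by decreasing frequency.
    """
    idx = m.sample_indices(samples)
    if idx.size == 0:
        raise ValueError("need at least one sample")
    site_ids = [i for i, r in enumerate(m.records)
                if not snps_only or r.vclass == "SNP"]
    if not site_ids:
        raise ValueError("empty retained-site set")
    X = m.calls_matrix()[np.array(site_ids)][:, idx]  # sites x subset

    buckets: dict[tuple[int, ...], list[str]] = {}
    n_excluded = 0
    for col, sample_i in enumerate(idx):
        vec = X[:, col]
        if missing_policy == "exclude" and np.any(vec == MISSING):
            n_excluded += 1
            continue
        buckets.setdefault(tuple(int(v) for v in vec), []).append(m.samples[sample_i])
    if missing_policy == "pairwise":
        # exact-vector grouping still applies; MISSING is its own state
        pass
    if n_excluded:
        import logging
        logging.getLogger("chloropop").info(
            "excluded %d samples with missing calls from haplotyping", n_excluded)
    if not buckets:
        raise ValueError("no complete samples left after missing-data exclusion")

    ordered = sorted(buckets.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    haps = []
    for rank, (key, members) in enumerate(ordered, start=1):
        counts: dict[str, int] = {}
        if pm is not None:
            for s in members:
                g = pm.group_of(s)
                counts[g] = counts.get(g, 0) + 1
        haps.append(Haplotype(f"H{rank}", key, members, counts))
    return haps


# ---------------------------------------------------------------------------
# Parsimony connection limit
# ---------------------------------------------------------------------------

def parsimony_probability(j: int, seq_length: int, tail: int = 200) -> float:
    """Posterior probability that j observed differences are parsimonious.

    Likelihood P(D=j | M=k) — the chance that k uniform mutations on
    ``seq_length`` sites hit exactly j distinct sites — follows the
    occupancy recurrence L(k,j) = L(k-1,j) j/m + L(k-1,j-1) (m-j+1)/m.
    The mutation count M is geometric with mean j (neutral pair,
    moment-matched), and the returned value is P(M = j | D = j).
    """
    if j == 0:
        return 1.0
    m = float(seq_length)
    kmax = j + tail
    # occupancy probabilities for exactly j occupied sites, k = 0..kmax
    L_prev = np.zeros(j + 1)  # L(k, 0..j)
    L_prev[0] = 1.0
    like = np.zeros(kmax + 1)
    occupied = np.arange(j + 1)
    gain = (m - occupied + 1) / m  # prob of hitting a fresh site from j-1 occupied
    for k in range(1, kmax + 1):
        L = L_prev * (occupied / m)
        L[1:] += L_prev[:-1] * gain[1:]
        like[k] = L[j]
        L_prev = L
    theta = float(j)
    ratio = theta / (1.0 + theta)
    weights = ratio ** np.arange(kmax + 1)  # geometric prior, constant dropped
    denom = float(np.sum(weights * like))
    if denom == 0.0:
        return 0.0
    return float(weights[j] * like[j] / denom)


def parsimony_limit(seq_length: int, confidence: float = 0.95,
                    max_steps: int = 1000) -> int:
    """Largest difference count connectable with the given confidence.

    Monotone non-decreasing in ``seq_length``; saturates at ``max_steps``
    (relevant only for confidence levels near zero).
    """
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must be in (0, 1)")
    limit = 0
    for j in range(1, min(max_steps, seq_length) + 1):
        if parsimony_probability(j, seq_length) > confidence:
            limit = j
        else:
            break
    return limit


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def hamming(a: Sequence[int], b: Sequence[int]) -> int:
    return int(sum(x != y for x, y in zip(a, b)))


def build_tcs_network(haps: list[Haplotype], limit: int) -> HaplotypeNetwork:
    """Agglomerative statistical-parsimony network.

    Haplotype pairs are joined in increasing Hamming-distance order
    (ties: larger haplotype frequency first, then lower node index); a
    join at distance d inserts d-1 unsampled intermediate nodes so every
    edge spans exactly one mutational step.  Pairs farther apart than
    ``limit`` never join, leaving separate components.
    """
    if not haps:
        raise ValueError("need at least one haplotype")
    g = nx.Graph()
    for h in haps:
        g.add_node(h.hap_id, haplotype=h)

    pairs = []
    for i in range(len(haps)):
        for j in range(i + 1, len(haps)):
            d = hamming(haps[i].key, haps[j].key)
            fi, fj = haps[i].frequency, haps[j].frequency
            pairs.append((d, -max(fi, fj), -min(fi, fj), i, j))
    pairs.sort()

    parent = list(range(len(haps)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    n_intermediate = 0
    for d, _, _, i, j in pairs:
        if d > limit:
            break
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        parent[ri] = rj
        chain = [haps[i].hap_id]
        for _step in range(d - 1):
            n_intermediate += 1
            node = f"M{n_intermediate}"
            g.add_node(node, haplotype=None)
            chain.append(node)
        chain.append(haps[j].hap_id)
        for u, v in zip(chain, chain[1:]):
            g.add_edge(u, v, steps=1)
    return HaplotypeNetwork(g, limit)


def haplotype_table(haps: list[Haplotype]):
    """Haplotype summary DataFrame: id, size, per-group counts."""
    import pandas as pd

    groups = sorted({g for h in haps for g in h.group_counts})
    rows = []
    for h in haps:
        row = {"haplotype": h.hap_id, "size": h.frequency}
        for gname in groups:
            row[gname] = h.group_counts.get(gname, 0)
        rows.append(row)
    return pd.DataFrame(rows)
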