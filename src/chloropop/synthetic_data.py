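"""Synthetic haploid chloroplast-like datasets with known truth.

Every statistic in the package is exercised against data whose generating
parameters are known: within-group variation from a neutral infinite-sites
coalescent (Kingman genealogy, Poisson mutations at rate theta/2 per unit
branch length), planted fixed differences between a designated group
pair, planted private sites at chosen frequencies, uniform missingness,
and optional InDel-format emission.  Variant positions are unique integer
coordinates drawn uniformly over a circular ~134.5-kb genome so windowed
statistics see realistic spacing.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .variant_io import (DEFAULT_GENOME_LENGTH, MISSING, GenotypeMatrix,
                         PopulationMap, VariantRecord, classify_variant,
                         write_vcf)

_NUC = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Generator settings; groups are (label, n_samples) pairs.

    ``theta`` may be one value for all groups or a per-label dict.
    ``private`` maps a label to the derived-allele frequencies of its
    planted private polymorphic sites.
    """

    groups: list[tuple[str, int]]
    theta: float | dict[str, float] = 5.0
    genome_length: int = DEFAULT_GENOME_LENGTH
    n_fixed_diff: int = 0
    fixed_pair: tuple[str, str] | None = None
    private: dict[str, list[float]] = field(default_factory=dict)
    missing_rate: float = 0.0
    indel_fraction: float = 0.0
    seed: int = 0

    def theta_of(self, label: str) -> float:
        if isinstance(self.theta, dict):
            return float(self.theta.get(label, 0.0))
        return float(self.theta)


@dataclass
class CoalescentSample:
    n: int
    theta: float
    branches: list[tuple[frozenset, float]]  # (descendant leaves, length)
    total_branch_length: float
    site_carriers: list[frozenset]           # derived-allele carriers per site
    matrix: GenotypeMatrix


# ---------------------------------------------------------------------------
# Genealogy machinery
# ---------------------------------------------------------------------------

def _kingman_branches(n: int, rng: np.random.Generator
                      ) -> list[tuple[frozenset, float]]:
    """Branches of a Kingman genealogy as (leaf set, branch length)."""
    active: list[tuple[frozenset, float]] = [(frozenset([i]), 0.0) for i in range(n)]
    branches: list[tuple[frozenset, float]] = []
    t = 0.0
    while len(active) > 1:
        j = len(active)
        t += rng.exponential(2.0 / (j * (j - 1)))
        i1, i2 = sorted(rng.choice(j, size=2, replace=False))
        (sa, ta), (sb, tb) = active[i2], active[i1]
        branches.append((sa, t - ta))
        branches.append((sb, t - tb))
        del active[i2], active[i1]
        active.append((sa | sb, t))
    return branches


def _draw_positions(n_sites: int, genome_length: int, rng: np.random.Generator,
                    taken: set[int] | None = None) -> list[int]:
    """Unique 1-based coordinates, uniform over the genome."""
    taken = set() if taken is None else taken
    if n_sites + len(taken) > genome_length:
        raise ValueError("more sites requested than genome positions")
    out: set[int] = set()
    while len(out) < n_sites:
        need = n_sites - len(out)
        draws = rng.integers(1, genome_length + 1, size=2 * need + 8)
        for p in draws:
            p = int(p)
            if p not in taken and p not in out:
                out.add(p)
                if len(out) == n_sites:
                    break
    return sorted(out)


def _make_records(positions: Sequence[int], carriers: Sequence[np.ndarray],
                  n_samples: int, rng: np.random.Generator,
                  indel_fraction: float = 0.0,
                  missing_rate: float = 0.0) -> list[VariantRecord]:
    """Biallelic records with random allele strings and optional missingness."""
    records = []
    for pos, carrier_idx in zip(positions, carriers):
        calls = np.zeros(n_samples, dtype=np.int16)
        calls[carrier_idx] = 1
        if missing_rate > 0:
            calls[rng.random(n_samples) < missing_rate] = MISSING
        if rng.random() < indel_fraction:
            ref = str(rng.choice(_NUC))
            alts = (ref + str(rng.choice(_NUC)),)  # single-base insertion
        else:
            ref, alt = rng.choice(_NUC, size=2, replace=False)
            ref, alts = str(ref), (str(alt),)
        vclass, subst = classify_variant(ref, alts)
        records.append(VariantRecord("chloroplast", int(pos), ref, alts, calls,
                                     vclass, subst))
    return records


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def simulate_coalescent(n: int, theta: float, seed: int | None = None,
                        genome_length: int = DEFAULT_GENOME_LENGTH,
                        sample_prefix: str = "s", n_loci: int = 1,
                        rng: np.random.Generator | None = None) -> CoalescentSample:
    """Neutral infinite-sites coalescent sample of n sequences.

    With ``n_loci = 1`` (default) every site descends from one shared
    genealogy — the non-recombining chloroplast case.  ``n_loci > 1``
    splits theta over that many independent genealogies and pools their
    sites, emulating unlinked loci (the assumption behind the bottleneck
    test's locus-wise null).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if theta <= 0:
        raise ValueError("need theta > 0")
    if n_loci < 1:
        raise ValueError("need n_loci >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    branches = []
    carriers: list[frozenset] = []
    total_len = 0.0
    for _locus in range(n_loci):
        locus_branches = _kingman_branches(n, rng)
        branches.extend(locus_branches)
        total_len += sum(l for _, l in locus_branches)
        for leaves, length in locus_branches:
            if len(leaves) == n:
                continue  # mutation above the root is invisible
            for _ in range(rng.poisson(theta / n_loci / 2.0 * length)):
                carriers.append(leaves)
    rng.shuffle(carriers)
    positions = _draw_positions(len(carriers), genome_length, rng)
    carrier_arrays = [np.fromiter(c, dtype=np.intp) for c in carriers]
    records = _make_records(positions, carrier_arrays, n, rng)
    records.sort(key=lambda r: r.pos)
    samples = [f"{sample_prefix}{i}" for i in range(n)]
    matrix = GenotypeMatrix(records, samples, genome_length=genome_length)
    return CoalescentSample(n, theta, branches, total_len, carriers, matrix)


def simulate_structured(cfg: SimConfig) -> tuple[GenotypeMatrix, PopulationMap, dict]:
    """Multi-group dataset with planted structure; returns truth as well.

    Within-group polymorphism comes from independent coalescents (one per
    group with theta > 0); planted fixed differences separate
    ``cfg.fixed_pair`` (first member keeps the reference allele);
    ``cfg.private`` plants extra sites at explicit derived frequencies.
    The truth dict records every planted position and parameter.
    """
    if not cfg.groups:
        raise ValueError("config lists no groups")
    if cfg.n_fixed_diff > 0 and cfg.fixed_pair is None:
        raise ValueError("n_fixed_diff > 0 requires fixed_pair")
    rng = np.random.default_rng(cfg.seed)
    labels = [g for g, _ in cfg.groups]
    sizes = dict(cfg.groups)
    offsets: dict[str, int] = {}
    samples: list[str] = []
    for label, n in cfg.groups:
        offsets[label] = len(samples)
        samples.extend(f"{label}_{i}" for i in range(n))
    n_total = len(samples)
    pm = PopulationMap({s: label for label, n in cfg.groups
                        for s in [f"{label}_{i}" for i in range(n)]})

    taken: set[int] = set()
    positions: list[int] = []
    carriers: list[np.ndarray] = []
    truth: dict = {"seed": cfg.seed, "groups": dict(cfg.groups),
                   "theta": {g: cfg.theta_of(g) for g in labels},
                   "fixed_diff_positions": [], "private_positions": {}}

    # within-group coalescent variation
    for label, n in cfg.groups:
        theta = cfg.theta_of(label)
        if theta <= 0 or n < 2:
            continue
        branches = _kingman_branches(n, rng)
        group_carriers: list[np.ndarray] = []
        for leaves, length in branches:
            if len(leaves) == n:
                continue
            base = np.fromiter(leaves, dtype=np.intp) + offsets[label]
            for _ in range(rng.poisson(theta / 2.0 * length)):
                group_carriers.append(base)
        pos = _draw_positions(len(group_carriers), cfg.genome_length, rng, taken)
        taken.update(pos)
        positions.extend(pos)
        carriers.extend(group_carriers)

    # planted fixed differences: second member of the pair carries the
    # derived allele at frequency 1, everyone else stays reference
    if cfg.n_fixed_diff > 0:
        _, derived_label = cfg.fixed_pair
        if derived_label not in sizes:
            raise ValueError(f"unknown group {derived_label!r} in fixed_pair")
        base = np.arange(sizes[derived_label], dtype=np.intp) + offsets[derived_label]
        pos = _draw_positions(cfg.n_fixed_diff, cfg.genome_length, rng, taken)
        taken.update(pos)
        positions.extend(pos)
        carriers.extend([base] * cfg.n_fixed_diff)
        truth["fixed_diff_positions"] = [int(p) for p in pos]

    # planted private polymorphic sites
    for label, freqs in cfg.private.items():
        if label not in sizes:
            raise ValueError(f"unknown group {label!r} in private spec")
        n = sizes[label]
        pos = _draw_positions(len(freqs), cfg.genome_length, rng, taken)
        taken.update(pos)
        for p, f in zip(pos, freqs):
            n_carry = max(1, round(f * n))
            picked = rng.choice(n, size=min(n_carry, n), replace=False)
            positions.append(p)
            carriers.append(np.asarray(picked, dtype=np.intp) + offsets[label])
        truth["private_positions"][label] = [int(p) for p in pos]

    records = _make_records(positions, carriers, n_total, rng,
                            indel_fraction=cfg.indel_fraction,
                            missing_rate=cfg.missing_rate)
    records.sort(key=lambda r: r.pos)
    matrix = GenotypeMatrix(records, samples, genome_length=cfg.genome_length)
    return matrix, pm, truth


def simulate_bottleneck_dataset(n: int, theta_pre: float, severity: float,
                                seed: int | None = None,
                                genome_length: int = DEFAULT_GENOME_LENGTH,
                                n_loci: int = 1) -> GenotypeMatrix:
    """Neutral sample with its frequency spectrum distorted bottleneck-style.

    A contraction removes rare alleles faster than gene diversity, so
    relative to allele counts the surviving loci look too diverse.  That
    signature is emulated by pruning each polymorphic site with a
    probability that grows as its minor-allele frequency shrinks: a site
    with minor-allele frequency ``maf`` is kept with probability
    ``(2 maf)^severity``.  ``severity`` in (0, 1]; as severity -> 0 the
    spectrum is untouched and the dataset reduces to the neutral sample.
    """
    if not (0.0 <= severity <= 1.0):
        raise ValueError("severity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sample = simulate_coalescent(n, theta_pre, genome_length=genome_length,
                                 n_loci=n_loci, rng=rng)
    m = sample.matrix
    keep = []
    for i in range(m.n_sites):
        counts = m.allele_counts(i)
        maf = float(np.sort(counts)[::-1][1] / counts.sum()) if np.count_nonzero(counts) > 1 else 0.0
        if severity == 0.0 or rng.random() < (2.0 * maf) ** severity:
            keep.append(i)
    return m.subset_sites(keep)


def write_outputs(matrix: GenotypeMatrix, pm: PopulationMap,
                  out_dir: str | Path, truth: dict | None = None) -> dict[str, Path]:
    """Emit VCF v4.2 + groups TSV (+ truth JSON) into a directory."""
    if not pm.assignments:
        raise ValueError("empty group assignment")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"vcf": out_dir / "variants.vcf", "groups": out_dir / "groups.tsv"}
    write_vcf(matrix, paths["vcf"])
    pm.to_tsv(paths["groups"])
    if truth is not None:
        paths["truth"] = out_dir / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=1)
    return paths
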