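"""Subgroup-specific allele-frequency scan for introgression.

A site whose derived (non-reference) allele is nearly fixed in one
cultivated subgroup (frequency > 0.95) and nearly absent in the other
(< 0.05) is diagnostic for that subgroup.  An accession of one subgroup
carrying many alleles diagnostic for the other is a candidate
introgressant; pure subgroups yield none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .variant_io import MISSING, GenotypeMatrix, PopulationMap


@dataclass
class IntrogressionSite:
    pos: int
    freq_a: float                 # derived-allele frequency in group_a
    freq_b: float
    freq_wild: float              # NaN when no wild group supplied
    status: str                   # a_specific | b_specific | shared | none
    wild_presence: bool


@dataclass
class AccessionProfile:
    sample: str
    group: str
    n_a_specific_carried: int
    n_b_specific_carried: int
    opposite_fraction: float      # NaN when no opposite-type site exists
    verdict: str                  # none | candidate_introgressant


def group_allele_freq(m: GenotypeMatrix, pm: PopulationMap,
                      group: str) -> np.ndarray:
    """Per-site derived (non-reference) allele frequency in a group.

    Computed among non-missing calls; sites with none are NaN.  For
    multiallelic sites all non-reference alleles pool as derived.
    """
    idx = m.sample_indices(pm.members(group))
    out = np.full(m.n_sites, np.nan)
    for i in range(m.n_sites):
        calls = m.records[i].calls[idx]
        calls = calls[calls != MISSING]
        if calls.size:
            out[i] = float(np.mean(calls != 0))
    return out


def classify_specific_sites(m: GenotypeMatrix, freq_a: np.ndarray,
                            freq_b: np.ndarray,
                            freq_wild: np.ndarray | None = None,
                            high: float = 0.95, low: float = 0.05
                            ) -> list[IntrogressionSite]:
    """Label each site by which group its derived allele is diagnostic for.

    ``b_specific`` iff freq_b > high and freq_a < low (strict, so a
    frequency of exactly 0.95 is not specific); ``a_specific`` mirrored;
    ``shared`` when high in both.  Wild presence of the derived allele is
    annotated, not filtered, since the scan restricts to alleles absent
    from wild rice only optionally.
    """
    if len(freq_a) != m.n_sites or len(freq_b) != m.n_sites:
        raise ValueError("frequency vectors must align with sites")
    out = []
    for i in range(m.n_sites):
        fa, fb = float(freq_a[i]), float(freq_b[i])
        fw = float(freq_wild[i]) if freq_wild is not None else float("nan")
        if math.isnan(fa) or math.isnan(fb):
            status = "none"
        elif fa > high and fb < low:
            status = "a_specific"
        elif fb > high and fa < low:
            status = "b_specific"
        elif fa > high and fb > high:
            status = "shared"
        else:
            status = "none"
        wild_presence = (not math.isnan(fw)) and fw > 0.0
        out.append(IntrogressionSite(int(m.records[i].pos), fa, fb, fw,
                                     status, wild_presence))
    return out


def joint_frequency_table(freq_a: np.ndarray, freq_b: np.ndarray,
                          bins: int = 10) -> np.ndarray:
    """bins x bins counts of sites by (freq_a bin, freq_b bin).

    Bin edges are [0, 1/bins), ..., [1-1/bins, 1]; only sites with both
    frequencies defined contribute, so the table total equals their count.
    """
    if bins < 2:
        raise ValueError("need bins >= 2")
    ok = ~(np.isnan(freq_a) | np.isnan(freq_b))
    edges = np.linspace(0.0, 1.0, bins + 1)
    table, _, _ = np.histogram2d(freq_a[ok], freq_b[ok], bins=[edges, edges])
    return table.astype(int)


def accession_allele_profile(m: GenotypeMatrix, sites: list[IntrogressionSite],
                             pm: PopulationMap, group_a: str, group_b: str,
                             threshold: float = 0.10,
                             exclude_wild_alleles: bool = False
                             ) -> list[AccessionProfile]:
    """Count group-diagnostic alleles carried by each accession.

    An accession of group_a (resp. group_b) is a candidate introgressant
    when it carries the derived allele at more than ``threshold`` of the
    sites diagnostic for the opposite group.  Accessions outside the two
    groups are profiled with verdict "none".
    """
    if not sites:
        raise ValueError("need at least one classified site")
    use = [s for s in sites if not (exclude_wild_alleles and s.wild_presence)]
    pos_to_idx = {int(r.pos): i for i, r in enumerate(m.records)}
    a_sites = [pos_to_idx[s.pos] for s in use if s.status == "a_specific"]
    b_sites = [pos_to_idx[s.pos] for s in use if s.status == "b_specific"]
    X = m.calls_matrix()

    out = []
    for col, sample in enumerate(m.samples):
        group = pm.assignments.get(sample, "NA")
        n_a = int(sum(X[i, col] > 0 for i in a_sites))
        n_b = int(sum(X[i, col] > 0 for i in b_sites))
        if group == group_a:
            opp_carried, opp_total = n_b, len(b_sites)
        elif group == group_b:
            opp_carried, opp_total = n_a, len(a_sites)
        else:
            opp_carried, opp_total = 0, 0
        frac = opp_carried / opp_total if opp_total else float("nan")
        verdict = ("candidate_introgressant"
                   if opp_total and frac > threshold else "none")
        out.append(AccessionProfile(sample, group, n_a, n_b, frac, verdict))
    return out
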