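"""Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction.

Counting method: each codon position contributes a synonymous-site
fraction equal to the share of its three possible single-nucleotide
changes that preserve the amino acid (so n + s = 3 per codon); observed
differences in codons that differ at several positions are averaged over
all orderings of single steps, excluding pathways through stop codons.
Proportions are distance-corrected with the Jukes-Cantor formula
d = -(3/4) ln(1 - (4/3) p), and omega = Ka/Ks feeds the selection
classification: omega > 1 accelerated, < 1 purifying, = 1 neutral, with
omega > 5 treated as an outlier (unreliable estimate) and removed from
biological interpretation.

Chloroplast genes use the standard genetic code; the codon table is
configurable for other compartments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from pathlib import Path
from typing import Iterator

from Bio.Data import CodonTable

_BASES = "ACGT"


def _code(table_id: int = 1) -> tuple[dict[str, str], frozenset]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return dict(table.forward_table), frozenset(table.stop_codons)


@dataclass
class CodonAlignment:
    gene: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.gene}: unequal sequence lengths {sorted(lengths)}")
        (self.length,) = lengths or {0}
        if self.length % 3 != 0:
            raise ValueError(f"{self.gene}: length {self.length} not a multiple of 3")

    @classmethod
    def from_fasta(cls, path: str | Path, gene: str | None = None) -> "CodonAlignment":
        from Bio import SeqIO

        path = Path(path)
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        if not seqs:
            raise ValueError(f"no sequences in {path}")
        return cls(gene or path.stem, seqs)

    def codons(self, name: str) -> Iterator[str]:
        seq = self.sequences[name]
        for i in range(0, len(seq), 3):
            yield seq[i:i + 3]


@dataclass
class KaKsResult:
    gene: str
    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    Ka: float                 # NaN when the JC correction is undefined
    Ks: float
    omega: float              # NaN when Ks == 0 or rates undefined
    classification: str


# ---------------------------------------------------------------------------
# Site and difference counting
# ---------------------------------------------------------------------------

def count_sites(codon: str, table_id: int = 1) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts of one sense codon.

    Per position, the synonymous fraction is the share of the three
    single-base changes that keep the amino acid; changes creating a stop
    codon count as nonsynonymous.  Always n + s = 3.
    """
    forward, stops = _code(table_id)
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    if codon in stops:
        raise ValueError(f"stop codon {codon} ends the counting region")
    aa = forward[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in stops and forward[alt] == aa:
                syn += 1
        s += syn / 3.0
    return 3.0 - s, s


def _diff_positions(a: str, b: str) -> list[int]:
    return [i for i in range(3) if a[i] != b[i]]


def count_differences(a: str, b: str, table_id: int = 1) -> tuple[float, float]:
    """(nonsynonymous, synonymous) differences between two sense codons.

    Codons differing at d positions are compared along every ordering of
    the d single-base steps; pathways passing through a stop codon are
    excluded, and the per-step classifications are averaged over the
    remaining pathways (standard NG86 practice).  If every pathway hits a
    stop, all d differences count as nonsynonymous.
    """
    forward, stops = _code(table_id)
    diffs = _diff_positions(a, b)
    if not diffs:
        return 0.0, 0.0
    path_counts = []
    for order in permutations(diffs):
        cur = a
        nd = sd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in stops:
                ok = False
                break
            if forward[cur] == forward[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            path_counts.append((nd, sd))
    if not path_counts:
        return float(len(diffs)), 0.0
    nd = sum(p[0] for p in path_counts) / len(path_counts)
    sd = sum(p[1] for p in path_counts) / len(path_counts)
    return nd, sd


# ---------------------------------------------------------------------------
# Pairwise and per-gene rates
# ---------------------------------------------------------------------------

def jukes_cantor(p: float) -> float:
    """JC69 distance; NaN when p >= 3/4 (correction undefined)."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return float("nan")
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def classify_selection(omega: float) -> str:
    """Selection class from omega; outlier (> 5) overrides accelerated."""
    if omega is None or (isinstance(omega, float) and math.isnan(omega)):
        return "undefined"
    if omega < 0:
        raise ValueError("omega must be >= 0")
    if omega > 5.0:
        return "outlier"
    if omega > 1.0:
        return "accelerated"
    if omega < 1.0:
        return "purifying"
    return "neutral"


def pairwise_kaks(seq_a: str, seq_b: str, gene: str = "pair",
                  table_id: int = 1) -> KaKsResult:
    """NG86 Ka/Ks between two codon-aligned sequences.

    Site counts are averaged over the two sequences; codons containing a
    gap (or an uncallable/stop codon in either sequence) are skipped.
    Symmetric in its arguments.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be codon-aligned to equal length")
    if len(seq_a) % 3:
        raise ValueError("alignment length must be a multiple of 3")
    _, stops = _code(table_id)
    N = S = Nd = Sd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3].upper(), seq_b[i:i + 3].upper()
        if any(x not in _BASES for x in ca + cb):
            continue  # gaps / ambiguity
        if ca in stops or cb in stops:
            continue
        na, sa = count_sites(ca, table_id)
        nb, sb = count_sites(cb, table_id)
        N += (na + nb) / 2.0
        S += (sa + sb) / 2.0
        nd, sd = count_differences(ca, cb, table_id)
        Nd += nd
        Sd += sd
    if N == 0 or S == 0:
        raise ValueError("no comparable codons between the sequences")
    pN, pS = Nd / N, Sd / S
    ka, ks = jukes_cantor(pN), jukes_cantor(pS)
    if math.isnan(ka) or math.isnan(ks) or ks == 0.0:
        omega = float("nan")
    else:
        omega = ka / ks
    return KaKsResult(gene, N, S, Nd, Sd, pN, pS, ka, ks, omega,
                      classify_selection(omega))


def gene_kaks(aln: CodonAlignment, table_id: int = 1) -> KaKsResult:
    """Gene-level NG86 summary: counts pooled over all sequence pairs.

    N, S, Nd, Sd are averaged across pairs before the proportions and the
    JC correction, which keeps the estimate defined even when individual
    pairs are identical.
    """
    names = list(aln.sequences)
    if len(names) < 2:
        raise ValueError(f"{aln.gene}: need >= 2 sequences")
    N = S = Nd = Sd = 0.0
    n_pairs = 0
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = pairwise_kaks(aln.sequences[names[i]], aln.sequences[names[j]],
                              gene=aln.gene, table_id=table_id)
            N += r.N; S += r.S; Nd += r.Nd; Sd += r.Sd
            n_pairs += 1
    N /= n_pairs; S /= n_pairs; Nd /= n_pairs; Sd /= n_pairs
    pN, pS = Nd / N, Sd / S
    ka, ks = jukes_cantor(pN), jukes_cantor(pS)
    omega = float("nan") if (math.isnan(ka) or math.isnan(ks) or ks == 0.0) else ka / ks
    return KaKsResult(aln.gene, N, S, Nd, Sd, pN, pS, ka, ks, omega,
                      classify_selection(omega))


def kaks_table(alignments: list[CodonAlignment], table_id: int = 1):
    """Per-gene DataFrame of NG86 results."""
    import pandas as pd

    rows = []
    for aln in alignments:
        r = gene_kaks(aln, table_id)
        rows.append({"gene": r.gene, "N": r.N, "S": r.S, "Nd": r.Nd, "Sd": r.Sd,
                     "Ka": r.Ka, "Ks": r.Ks, "omega": r.omega,
                     "classification": r.classification})
    return pd.DataFrame(rows)
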