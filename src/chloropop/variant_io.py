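"""Reading, classifying and filtering chloroplast variants.

The chloroplast genome is effectively haploid (maternally inherited, no
recombination), but resequencing pipelines often emit diploid-coded
genotypes.  This module collapses such calls onto a haploid allele index,
applies the quality filters used throughout the package (site missingness
and minor-allele frequency), classifies variants (SNP/InDel,
transition/transversion), and annotates coding/non-coding regions from a
GFF3 gene annotation.

The central container is :class:`GenotypeMatrix`: an ordered list of
:class:`VariantRecord` over a fixed sample panel, backed by an integer
call matrix with ``MISSING = -1``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("chloropop")

#: Sentinel for a missing haploid call.
MISSING: int = -1

#: Length of the Nipponbare chloroplast reference (bp).
DEFAULT_GENOME_LENGTH: int = 134525

_NUCLEOTIDES = frozenset("ACGT")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


# ---------------------------------------------------------------------------
# Records and matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRecord:
    """One variant site: alleles plus per-sample haploid calls.

    ``calls`` holds, per sample, the index of the carried allele
    (0 = reference, 1.. = alternates) or :data:`MISSING`.
    """

    chrom: str
    pos: int                      # 1-based reference coordinate
    ref: str
    alts: tuple[str, ...]
    calls: np.ndarray             # int16, shape (n_samples,)
    vclass: str = "SNP"           # "SNP" | "InDel"
    subst: str = "NA"             # "transition" | "transversion" | "NA"
    region: str = "NA"            # "coding" | "noncoding" | "NA"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        calls = np.asarray(self.calls, dtype=np.int16)
        n_alleles = 1 + len(self.alts)
        bad = (calls != MISSING) & ((calls < 0) | (calls >= n_alleles))
        if bad.any():
            raise ValueError(
                f"call indexes out of range at pos {self.pos}: "
                f"{np.unique(calls[bad]).tolist()} with {n_alleles} alleles"
            )
        object.__setattr__(self, "calls", calls)

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref, *self.alts)

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1


@dataclass
class GenotypeMatrix:
    """Sites x samples haploid allele calls with a missing sentinel.

    Records are kept strictly increasing by position; every statistic in
    the package consumes this container.
    """

    records: list[VariantRecord]
    samples: list[str]
    genome_length: int = DEFAULT_GENOME_LENGTH

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        pos = [r.pos for r in self.records]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("records must be strictly increasing by position")
        for r in self.records:
            if r.calls.shape != (len(self.samples),):
                raise ValueError(
                    f"record at pos {r.pos} has {r.calls.shape[0]} calls "
                    f"for {len(self.samples)} samples"
                )

    # -- basic geometry ----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.records)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def positions(self) -> np.ndarray:
        return np.array([r.pos for r in self.records], dtype=np.int64)

    def calls_matrix(self) -> np.ndarray:
        """Dense (n_sites, n_samples) int16 call matrix."""
        if not self.records:
            return np.empty((0, self.n_samples), dtype=np.int16)
        return np.stack([r.calls for r in self.records])

    def sample_indices(self, samples: Sequence[str] | None) -> np.ndarray:
        """Column indexes for a sample subset (None = all samples)."""
        if samples is None:
            return np.arange(self.n_samples)
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in samples], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    # -- per-site summaries ------------------------------------------------
    def missing_rate(self, site: int) -> float:
        calls = self.records[site].calls
        return float(np.mean(calls == MISSING))

    def allele_counts(self, site: int, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Counts of each allele (0..n_alleles-1) among non-missing calls."""
        rec = self.records[site]
        calls = rec.calls if sample_idx is None else rec.calls[sample_idx]
        calls = calls[calls != MISSING]
        return np.bincount(calls, minlength=1 + len(rec.alts))

    def maf(self, site: int) -> float:
        """Minor-allele frequency among non-missing calls.

        For multiallelic sites this is the frequency of the second most
        common allele; 0 when fewer than two alleles are observed.
        """
        counts = self.allele_counts(site)
        total = counts.sum()
        if total == 0:
            return 0.0
        order = np.sort(counts)[::-1]
        if len(order) < 2 or order[1] == 0:
            return 0.0
        return float(order[1] / total)

    def subset_sites(self, keep: Sequence[int]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            records=[self.records[i] for i in keep],
            samples=list(self.samples),
            genome_length=self.genome_length,
        )


@dataclass
class PopulationMap:
    """sample id -> subgroup label."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        if not isinstance(self.assignments, dict):
            self.assignments = dict(self.assignments)

    def group_of(self, sample: str) -> str:
        try:
            return self.assignments[sample]
        except KeyError:
            raise KeyError(f"sample {sample!r} has no group assignment") from None

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sample, label in self.assignments.items():
            out.setdefault(label, []).append(sample)
        return out

    def members(self, label: str) -> list[str]:
        members = self.groups().get(label)
        if members is None:
            raise KeyError(f"unknown group label {label!r}")
        return members

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PopulationMap":
        """Two-column TSV: sample<TAB>group (header optional)."""
        assignments: dict[str, str] = {}
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{i + 1}: expected 2 columns")
                if i == 0 and parts[0].lower() in {"sample", "sample_id", "id"}:
                    continue
                if parts[0] in assignments:
                    raise ValueError(f"duplicate sample id {parts[0]!r}")
                assignments[parts[0]] = parts[1]
        return cls(assignments)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tgroup\n")
            for sample, label in self.assignments.items():
                fh.write(f"{sample}\t{label}\n")


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_variant(ref: str, alts: Sequence[str]) -> tuple[str, str]:
    """Classify (ref, alts) as SNP/InDel and transition/transversion.

    A site is a SNP iff every allele has length 1.  The substitution class
    is defined only for biallelic SNPs: transition iff both alleles are
    purines or both pyrimidines.  Symmetric in ref/alt.
    """
    alleles = [ref, *alts]
    if not alleles or any(not a for a in alleles):
        raise ValueError("empty allele string")
    for a in alleles:
        if set(a) - _NUCLEOTIDES:
            raise ValueError(f"non-nucleotide characters in allele {a!r}")
    if all(len(a) == 1 for a in alleles):
        vclass = "SNP"
        if len(alts) == 1:
            pair = {ref, alts[0]}
            subst = (
                "transition"
                if pair <= _PURINES or pair <= _PYRIMIDINES
                else "transversion"
            )
        else:
            subst = "NA"
    else:
        vclass, subst = "InDel", "NA"
    return vclass, subst


# ---------------------------------------------------------------------------
# VCF input / output
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, het_policy: str = "missing",
             genome_length: int = DEFAULT_GENOME_LENGTH) -> GenotypeMatrix:
    """Read a multi-sample VCF into a haploid :class:`GenotypeMatrix`.

    Diploid-coded homozygous genotypes collapse to one haploid allele.
    Heterozygous genotypes are artifacts on the haploid chloroplast and
    become MISSING under the default policy (``het_policy="missing"``);
    with ``het_policy="major"`` the lower allele index is kept.
    """
    from cyvcf2 import VCF

    if het_policy not in {"missing", "major"}:
        raise ValueError(f"unknown het_policy {het_policy!r}")
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise VcfParseError(f"VCF {path} has zero samples")

    records: list[VariantRecord] = []
    chroms: set[str] = set()
    n_het = 0
    for lineno, var in enumerate(vcf, start=1):
        chroms.add(var.CHROM)
        alts = tuple(var.ALT)
        calls = np.full(len(samples), MISSING, dtype=np.int16)
        # genotypes: rows [allele_a, (allele_b,) phased]
        for j, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a is not None]
            alleles = [a for a in alleles if a >= 0]
            if not alleles:
                continue
            if len(set(alleles)) == 1:
                calls[j] = alleles[0]
            elif het_policy == "major":
                calls[j] = min(alleles)
                n_het += 1
            else:
                n_het += 1  # stays MISSING
        try:
            vclass, subst = classify_variant(var.REF, alts)
        except ValueError:
            vclass, subst = ("SNP" if len(var.REF) == 1 and all(len(a) == 1 for a in alts) else "InDel", "NA")
        try:
            records.append(VariantRecord(var.CHROM, var.POS, var.REF, alts, calls,
                                         vclass, subst))
        except ValueError as exc:
            raise VcfParseError(f"{path} record {lineno} (pos {var.POS}): {exc}") from exc
    if len(chroms) > 1:
        warnings.warn(
            f"expected a single reference sequence, found {sorted(chroms)}",
            stacklevel=2,
        )
    if n_het:
        logger.info("collapsed %d heterozygous diploid calls (policy=%s)",
                    n_het, het_policy)
    records.sort(key=lambda r: (r.chrom, r.pos))
    return GenotypeMatrix(records, samples, genome_length=genome_length)


def write_vcf(m: GenotypeMatrix, path: str | Path, chrom: str | None = None) -> None:
    """Write a haploid VCF v4.2 (one allele index per genotype field)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if m.records:
            contig = chrom or m.records[0].chrom
            fh.write(f"##contig=<ID={contig},length={m.genome_length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(m.samples) + "\n")
        for rec in m.records:
            gts = ["." if c == MISSING else str(int(c)) for c in rec.calls]
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{','.join(rec.alts) or '.'}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterResult:
    matrix: GenotypeMatrix
    n_retained: int
    n_removed: int


def filter_variants(m: GenotypeMatrix, max_missing: float = 0.20,
                    min_maf: float = 0.01) -> FilterResult:
    """High-quality variant filter.

    Removes sites with missing-call rate strictly greater than
    ``max_missing`` or minor-allele frequency strictly below ``min_maf``
    (so a site at exactly the MAF threshold is retained).  Order is
    preserved.
    """
    if m.n_sites == 0:
        raise ValueError("cannot filter an empty matrix")
    if not (0.0 <= max_missing <= 1.0):
        raise ValueError("max_missing must be in [0, 1]")
    if not (0.0 <= min_maf <= 0.5):
        raise ValueError("min_maf must be in [0, 0.5]")
    keep = [
        i for i in range(m.n_sites)
        if m.missing_rate(i) <= max_missing and not (m.maf(i) < min_maf)
    ]
    out = m.subset_sites(keep)
    return FilterResult(out, len(keep), m.n_sites - len(keep))


def tstv_ratio(m: GenotypeMatrix) -> float:
    """Transition/transversion ratio over biallelic SNPs.

    Returns ``inf`` when transversions are absent; raises if the matrix
    contains no biallelic SNP.
    """
    ts = sum(1 for r in m.records if r.subst == "transition")
    tv = sum(1 for r in m.records if r.subst == "transversion")
    if ts + tv == 0:
        raise ValueError("no biallelic SNPs in matrix")
    if tv == 0:
        return float("inf")
    return ts / tv


# ---------------------------------------------------------------------------
# Region annotation & density
# ---------------------------------------------------------------------------

def _intervals_from_gff(path: str | Path, feature: str = "gene") -> list[tuple[int, int]]:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    return [(f.start, f.end) for f in db.features_of_type(feature)]


def annotate_regions(m: GenotypeMatrix,
                     gff: str | Path | Iterable[tuple[int, int]],
                     feature: str = "gene") -> GenotypeMatrix:
    """Mark each variant coding/noncoding from gene intervals.

    ``gff`` is a GFF3 path or an iterable of 1-based inclusive
    (start, end) intervals.  A variant is coding iff its position lies in
    any interval.
    """
    if isinstance(gff, (str, Path)):
        intervals = _intervals_from_gff(gff, feature=feature)
    else:
        intervals = list(gff)
    for start, end in intervals:
        if end < start:
            raise ValueError(f"interval end {end} < start {start}")
    if intervals:
        starts = np.array([s for s, _ in intervals])
        ends = np.array([e for _, e in intervals])
    records = []
    for rec in m.records:
        if intervals and bool(np.any((starts <= rec.pos) & (rec.pos <= ends))):
            region = "coding"
        else:
            region = "noncoding"
        records.append(replace(rec, region=region))
    return GenotypeMatrix(records, list(m.samples), genome_length=m.genome_length)


def variant_density(m: GenotypeMatrix, samples: Sequence[str] | None = None) -> float:
    """Polymorphic sites per kb within a sample subset."""
    if m.genome_length <= 0:
        raise ValueError("genome_length must be positive")
    idx = m.sample_indices(samples)
    if idx.size == 0:
        raise ValueError("empty sample subset")
    n_poly = 0
    for i in range(m.n_sites):
        counts = m.allele_counts(i, idx)
        if np.count_nonzero(counts) >= 2:
            n_poly += 1
    return n_poly / (m.genome_length / 1000.0)


def summary_table(m: GenotypeMatrix):
    """Per-site summary as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    rows = []
    for i, rec in enumerate(m.records):
        rows.append({
            "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref,
            "alt": ",".join(rec.alts), "class": rec.vclass, "subst": rec.subst,
            "region": rec.region, "missing_rate": m.missing_rate(i),
            "maf": m.maf(i),
        })
    return pd.DataFrame(rows)
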