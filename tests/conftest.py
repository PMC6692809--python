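import numpy as np
import pytest

from chloropop.variant_io import GenotypeMatrix, PopulationMap, VariantRecord


def make_matrix(calls, positions=None, genome_length=10_000, samples=None,
                refs=None, alts=None):
    """Build a GenotypeMatrix from a sites x samples array of allele indexes.

    Defaults to biallelic A>G transitions at evenly spaced positions.
    """
    calls = np.asarray(calls, dtype=np.int16)
    n_sites, n_samples = calls.shape
    if positions is None:
        positions = [10 * (i + 1) for i in range(n_sites)]
    if samples is None:
        samples = [f"s{j}" for j in range(n_samples)]
    from chloropop import classify_variant

    records = []
    for i in range(n_sites):
        ref = refs[i] if refs else "A"
        alt = alts[i] if alts else ("G",)
        n_alleles = 1 + len(alt)
        needed = int(calls[i][calls[i] >= 0].max(initial=0)) + 1
        if needed > n_alleles:
            alt = tuple("CGT"[: needed - 1])
        vclass, subst = classify_variant(ref, list(alt))
        records.append(VariantRecord("cp", positions[i], ref, tuple(alt),
                                     calls[i], vclass, subst))
    return GenotypeMatrix(records, list(samples), genome_length=genome_length)


@pytest.fixture
def two_group_map():
    return PopulationMap({f"s{j}": ("a" if j < 2 else "b") for j in range(4)})
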