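import io

import numpy as np
import pytest

from mitopanel.alignment import ReferenceAlignment, read_msa
from mitopanel.panel import MISSING, VariantPanel
from mitopanel.synthetic import simulate_population


def make_alignment(rows: dict[str, str], rcrs_id: str = "rCRS", projected: bool = False):
    """Build a ReferenceAlignment from id -> sequence strings."""
    ids = list(rows)
    matrix = np.array([list(s) for s in rows.values()], dtype="<U1")
    positions = (
        np.arange(1, matrix.shape[1] + 1, dtype=np.int64) if projected else None
    )
    return ReferenceAlignment(
        sequence_ids=ids, matrix=matrix, rcrs_id=rcrs_id, column_positions=positions
    )


def fasta_of(rows: dict[str, str]) -> io.StringIO:
    return io.StringIO("".join(f">{k}\n{v}\n" for k, v in rows.items()))


def random_panel(rng: np.random.Generator, biallelic: bool = False,
                 allow_missing: bool = True) -> VariantPanel:
    """Random small panel for round-trip and property tests."""
    n_sites = int(rng.integers(1, 13))
    n_samples = int(rng.integers(1, 9))
    positions = np.sort(rng.choice(np.arange(1, 16570), size=n_sites, replace=False))
    bases = np.array(list("ACGT"))
    refs, alts, rows = [], [], []
    for _ in range(n_sites):
        perm = rng.permutation(4)
        ref = str(bases[perm[0]])
        n_alt = 1 if biallelic else int(rng.integers(1, 4))
        alt = tuple(str(bases[p]) for p in perm[1 : 1 + n_alt])
        row = rng.integers(0, n_alt + 1, size=n_samples).astype(np.int8)
        if allow_missing:
            row[rng.random(n_samples) < 0.2] = MISSING
        refs.append(ref)
        alts.append(alt)
        rows.append(row)
    return VariantPanel(
        positions=positions,
        ref_alleles=refs,
        alt_alleles=alts,
        haplotypes=np.array(rows, dtype=np.int8),
        sample_ids=[f"s{j}" for j in range(n_samples)],
    )


@pytest.fixture(scope="session")
def population():
    return simulate_population(seed=11)


@pytest.fixture(scope="session")
def truth_panel(population):
    from mitopanel.panel import extract_variant_sites

    return extract_variant_sites(population.to_alignment())


@pytest.fixture(scope="session")
def target_ids(population):
    # spread targets across clades (every 4th sample)
    return population.sample_ids[::4][:50]


@pytest.fixture(scope="session")
def reference_panel(truth_panel, target_ids):
    keep = [s for s in truth_panel.sample_ids if s not in set(target_ids)]
    return truth_panel.subset_samples(keep)
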