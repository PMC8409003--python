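"""Seeded simulation of clade-structured haplotype populations.

The generator emulates the structure an imputation reference panel
relies on: a phylogeny of clades (haplogroups), each defined by a
private set of diagnostic substitutions accumulated along the tree,
plus per-haplotype private mutations.  It deliberately does not model
realistic mutation spectra, indel evolution or coalescent genealogies —
controllable clade-defining variants are the point, so that planted
truth (haplogroup labels, QC failures, chip content) can be recovered
exactly by the other modules.

Clade labels follow haplogroup-style nomenclature (letters and digits
alternating: A, A1, A1a, ...) so that macro-collapsing a leaf label
yields its top-level clade letter.  The letter L is never used as a
top-level label because L-lineages have two-character macrohaplogroups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import ReferenceAlignment
from .chip_sim import ChipDefinition
from .haplogroup import HaplogroupEntry, HaplogroupTable
from .panel import VariantPanel

BASES = np.array(list("ACGT"))
AMBIGUITY_CODES = np.array(list("NRYWSKM"))
#: Top-level clade letters ('L' omitted: L-lineage macros are two characters).
MACRO_LETTERS = "ABCDEFGHIJKMNOPQRSTUVWXYZ"

DEFAULT_SEQ_LENGTH = 2000
RCRS_STANDIN_ID = "rCRS"


@dataclass
class SyntheticPopulation:
    """A simulated clade-structured haplotype population."""

    root_seq: str
    haplotypes: np.ndarray           # (n_haplotypes, length), dtype '<U1'
    sample_ids: list[str]
    truth_labels: dict[str, str]     # sample id -> leaf clade label
    clade_defining: dict[str, list[tuple[int, str]]]  # label -> (pos, allele)
    clade_parents: dict[str, str | None]
    seed: int | None

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def length(self) -> int:
        return self.haplotypes.shape[1]

    def to_alignment(self, rcrs_id: str = RCRS_STANDIN_ID) -> ReferenceAlignment:
        """Population plus the root sequence as a projected alignment.

        The root plays the part of the rCRS coordinate anchor; the
        alignment is gap-free, so column *i* is position *i* and the
        alignment is already in projected form.
        """
        matrix = np.vstack([np.array(list(self.root_seq)), self.haplotypes])
        return ReferenceAlignment(
            sequence_ids=[rcrs_id] + list(self.sample_ids),
            matrix=matrix,
            rcrs_id=rcrs_id,
            column_positions=np.arange(1, self.length + 1, dtype=np.int64),
        )

    def haplogroup_table(self) -> HaplogroupTable:
        """Table of the planted clades and their defining variants."""
        entries = {
            label: HaplogroupEntry(
                label=label,
                parent=self.clade_parents[label],
                defining_variants=frozenset(self.clade_defining[label]),
            )
            for label in self.clade_defining
        }
        return HaplogroupTable(entries)

    def write_fasta(self, path) -> None:
        self.to_alignment().write_fasta(path)

    def write_truth_labels(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#sample_id\thaplogroup\n")
            for sid in self.sample_ids:
                fh.write(f"{sid}\t{self.truth_labels[sid]}\n")


def _child_labels(label: str, n: int) -> list[str]:
    if label[-1].isdigit():
        return [label + chr(ord("a") + i) for i in range(n)]
    return [label + str(i + 1) for i in range(n)]


def _grow_subtree(
    label: str, n_leaves: int, rng: np.random.Generator,
    parents: dict[str, str | None], leaves: list[str],
) -> None:
    """Random bifurcation of *n_leaves* leaf slots below *label*."""
    if n_leaves == 1:
        leaves.append(label)
        return
    left = int(rng.integers(1, n_leaves))
    for child, size in zip(_child_labels(label, 2), (left, n_leaves - left)):
        parents[child] = label
        _grow_subtree(child, size, rng, parents, leaves)


def simulate_population(
    n_clades: int = 8,
    n_per_clade: int = 25,
    n_defining: int = 12,
    private_mutation_rate: float = 3.0,
    seq_length: int = DEFAULT_SEQ_LENGTH,
    seed: int | None = None,
    n_macros: int | None = None,
) -> SyntheticPopulation:
    """Simulate a clade-structured haploid population.

    ``n_clades`` leaf clades are spread over ``n_macros`` top-level
    clades (default: up to 4) and connected by random bifurcating
    subtrees.  Every tree node carries ``n_defining`` defining
    substitutions, drawn without positional collision across the whole
    tree; every haplotype additionally carries Poisson-distributed
    private mutations at non-defining positions, so planted clade
    labels remain exactly recoverable from complete data.
    """
    if n_clades < 1 or n_per_clade < 1 or seq_length < 1:
        raise ValueError("n_clades, n_per_clade and seq_length must be positive")
    if n_defining < 0 or private_mutation_rate < 0:
        raise ValueError("n_defining and private_mutation_rate must be >= 0")
    rng = np.random.default_rng(seed)
    m = n_macros if n_macros is not None else min(4, n_clades)
    if not 1 <= m <= min(n_clades, len(MACRO_LETTERS)):
        raise ValueError("n_macros out of range")

    # partition leaf slots over macros (each non-empty)
    sizes = np.ones(m, dtype=int)
    for _ in range(n_clades - m):
        sizes[rng.integers(0, m)] += 1

    parents: dict[str, str | None] = {}
    leaves: list[str] = []
    for letter, size in zip(MACRO_LETTERS, sizes):
        parents[letter] = None
        _grow_subtree(letter, int(size), rng, parents, leaves)

    n_nodes = len(parents)
    if n_nodes * n_defining > seq_length:
        raise ValueError(
            f"{n_nodes} clades x {n_defining} defining mutations exceed "
            f"sequence length {seq_length}"
        )

    root = BASES[rng.integers(0, 4, size=seq_length)]
    defining_pos = rng.choice(seq_length, size=n_nodes * n_defining, replace=False)
    clade_defining: dict[str, list[tuple[int, str]]] = {}
    for k, label in enumerate(parents):
        muts = []
        for p in defining_pos[k * n_defining : (k + 1) * n_defining]:
            current = root[p]
            derived = rng.choice(BASES[BASES != current])
            muts.append((int(p) + 1, str(derived)))
        clade_defining[label] = muts

    path_cache: dict[str, dict[int, str]] = {}

    def _path_mutations(label: str) -> dict[int, str]:
        if label not in path_cache:
            own = dict()
            if parents[label] is not None:
                own.update(_path_mutations(parents[label]))
            own.update({p: a for p, a in clade_defining[label]})
            path_cache[label] = own
        return path_cache[label]

    non_defining = np.setdiff1d(np.arange(seq_length), defining_pos)
    haplotypes = []
    sample_ids: list[str] = []
    truth: dict[str, str] = {}
    for leaf in leaves:
        base = root.copy()
        for p, a in _path_mutations(leaf).items():
            base[p - 1] = a
        for i in range(n_per_clade):
            seq = base.copy()
            k = rng.poisson(private_mutation_rate)
            if k > 0 and non_defining.size:
                k = min(k, non_defining.size)
                for p in rng.choice(non_defining, size=k, replace=False):
                    seq[p] = rng.choice(BASES[BASES != seq[p]])
            sid = f"{leaf}_{i:03d}"
            sample_ids.append(sid)
            truth[sid] = leaf
            haplotypes.append(seq)

    return SyntheticPopulation(
        root_seq="".join(root),
        haplotypes=np.array(haplotypes),
        sample_ids=sample_ids,
        truth_labels=truth,
        clade_defining=clade_defining,
        clade_parents=parents,
        seed=seed,
    )


def inject_noise(
    population: SyntheticPopulation,
    n_bad_ambiguous: int,
    n_bad_gapped: int,
    seed: int | None = None,
    n_ambiguous_chars: int = 5,
    n_gap_chars: int = 8,
) -> tuple[ReferenceAlignment, dict[str, list[str]]]:
    """Plant QC-failing sequences and return the alignment plus manifest.

    Exactly ``n_bad_ambiguous`` haplotypes receive ``n_ambiguous_chars``
    ambiguity codes and ``n_bad_gapped`` distinct haplotypes receive
    ``n_gap_chars`` gap characters (defaults sit exactly on the removal
    thresholds).  The manifest maps ``"ambiguous"``/``"gapped"`` to the
    planted sequence ids.
    """
    n_bad = n_bad_ambiguous + n_bad_gapped
    if n_bad > population.n_haplotypes:
        raise ValueError("more planted-bad sequences requested than population size")
    rng = np.random.default_rng(seed)
    aln = population.to_alignment()
    victims = rng.choice(population.n_haplotypes, size=n_bad, replace=False)
    manifest = {"ambiguous": [], "gapped": []}
    for v_idx, victim in enumerate(victims):
        row = victim + 1  # row 0 is the rCRS stand-in
        sid = aln.sequence_ids[row]
        if v_idx < n_bad_ambiguous:
            cols = rng.choice(population.length, size=n_ambiguous_chars, replace=False)
            aln.matrix[row, cols] = rng.choice(AMBIGUITY_CODES, size=n_ambiguous_chars)
            manifest["ambiguous"].append(sid)
        else:
            cols = rng.choice(population.length, size=n_gap_chars, replace=False)
            aln.matrix[row, cols] = "-"
            manifest["gapped"].append(sid)
    return aln, manifest


def make_chip_definition(
    panel: VariantPanel,
    n_sites: int,
    bias: float = 0.0,
    seed: int | None = None,
    chip_name: str = "synthetic-chip",
) -> ChipDefinition:
    """Seeded subsample of panel positions as an in-silico chip.

    ``bias > 0`` weights selection towards high-MAF sites (mimicking
    commercial array design) via Gumbel-top-k sampling on
    ``bias * log(MAF)``; ``bias = 0`` is a uniform subsample and a very
    large bias converges on the top-MAF sites.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    if n_sites > panel.n_sites:
        raise ValueError(f"requested {n_sites} sites but panel has {panel.n_sites}")
    rng = np.random.default_rng(seed)
    keys = bias * np.log(panel.maf + 1e-12) + rng.gumbel(size=panel.n_sites)
    chosen = np.argsort(keys)[::-1][:n_sites]
    return ChipDefinition(
        chip_name=chip_name,
        positions=panel.positions[np.sort(chosen)],
        source="synthetic",
    )
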