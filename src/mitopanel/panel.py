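"""Variant panel extraction and minor-allele-frequency stratification.

A :class:`VariantPanel` is the imputation reference: the variable sites
of a projected, QC-filtered alignment as a haploid allele-index matrix.
Gap and ambiguous character states are coded as missing, invariant sites
(fewer than two distinct alleles among non-missing entries) are dropped,
and each site's reference allele is the rCRS base at that position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment import GAP, UNAMBIGUOUS, ReferenceAlignment

#: Allele-index code for a missing (gap or ambiguous) haploid call.
MISSING = -1


@dataclass
class VariantPanel:
    """Variant sites plus a haploid allele-index matrix.

    Attributes
    ----------
    positions : ndarray of shape (n_sites,)
        1-based rCRS positions, strictly increasing.
    ref_alleles : list of str
        Per-site reference allele (the rCRS base).
    alt_alleles : list of tuple of str
        Per-site alternate alleles ordered by descending observed count
        (ties broken alphabetically).
    haplotypes : ndarray of shape (n_sites, n_samples), dtype int8
        Allele index per site per sample: 0 = ref, 1.. = alts in order,
        :data:`MISSING` for missing.
    sample_ids : list of str
    collapsed : ndarray of bool or None
        Marks sites where a multiallelic one-vs-rest collapse was
        applied (see :meth:`to_biallelic`).
    """

    positions: np.ndarray
    ref_alleles: list[str]
    alt_alleles: list[tuple[str, ...]]
    haplotypes: np.ndarray
    sample_ids: list[str]
    collapsed: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape != (len(self.positions), len(self.sample_ids)):
            raise ValueError("haplotype matrix shape does not match sites x samples")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("site positions must be strictly increasing")
        if len(self.ref_alleles) != len(self.positions) or len(self.alt_alleles) != len(
            self.positions
        ):
            raise ValueError("per-site allele lists must match number of positions")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def site_alleles(self, i: int) -> tuple[str, ...]:
        """All alleles at site *i*: (ref, alt1, alt2, ...)."""
        return (self.ref_alleles[i], *self.alt_alleles[i])

    @property
    def maf(self) -> np.ndarray:
        """Per-site minor allele frequency over non-missing haplotypes.

        MAF = 1 - frequency of the most common observed allele, capped
        at 0.5 (the cap only matters for multiallelic sites).
        """
        out = np.zeros(self.n_sites)
        H = self.haplotypes
        nonmissing = H != MISSING
        for i in range(self.n_sites):
            alleles = H[i][nonmissing[i]]
            if alleles.size == 0:
                continue
            counts = np.bincount(alleles)
            out[i] = (alleles.size - counts.max()) / alleles.size
        return np.minimum(out, 0.5)

    def position_index(self) -> dict[int, int]:
        return {int(p): i for i, p in enumerate(self.positions)}

    def subset_sites(self, mask: np.ndarray) -> "VariantPanel":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return VariantPanel(
            positions=self.positions[idx],
            ref_alleles=[self.ref_alleles[i] for i in idx],
            alt_alleles=[self.alt_alleles[i] for i in idx],
            haplotypes=self.haplotypes[idx],
            sample_ids=list(self.sample_ids),
            collapsed=None if self.collapsed is None else self.collapsed[idx],
        )

    def subset_samples(self, sample_ids: list[str]) -> "VariantPanel":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in sample_ids]
        return VariantPanel(
            positions=self.positions.copy(),
            ref_alleles=list(self.ref_alleles),
            alt_alleles=list(self.alt_alleles),
            haplotypes=self.haplotypes[:, cols],
            sample_ids=list(sample_ids),
            collapsed=None if self.collapsed is None else self.collapsed.copy(),
        )

    def to_biallelic(self) -> "VariantPanel":
        """One-vs-rest collapse of multiallelic sites to (ref, top alt).

        At collapsed sites any allele other than the most frequent
        alternate is recoded as reference; collapsed sites are flagged.
        """
        H = self.haplotypes.copy()
        alt = [alts[:1] for alts in self.alt_alleles]
        flags = np.array([len(alts) > 1 for alts in self.alt_alleles])
        multi = H > 1
        H[multi] = 0
        return VariantPanel(
            positions=self.positions.copy(),
            ref_alleles=list(self.ref_alleles),
            alt_alleles=[tuple(a) for a in alt],
            haplotypes=H,
            sample_ids=list(self.sample_ids),
            collapsed=flags,
        )

    def allele_map(self, sample_id: str) -> dict[int, str]:
        """Position -> base for one sample; missing sites omitted."""
        j = self.sample_ids.index(sample_id)
        out: dict[int, str] = {}
        for i, pos in enumerate(self.positions):
            code = self.haplotypes[i, j]
            if code == MISSING:
                continue
            out[int(pos)] = self.site_alleles(i)[code]
        return out

    def allele_characters(self) -> np.ndarray:
        """Decode the allele-index matrix to base characters ('.' = missing)."""
        out = np.full(self.haplotypes.shape, ".", dtype="<U1")
        for i in range(self.n_sites):
            alleles = self.site_alleles(i)
            for code, base in enumerate(alleles):
                out[i][self.haplotypes[i] == code] = base
        return out


def extract_variant_sites(aln: ReferenceAlignment) -> VariantPanel:
    """Extract variable sites from a projected, QC-filtered alignment.

    Gaps and ambiguity codes become missing; sites with fewer than two
    distinct non-missing alleles are dropped; the rCRS row anchors each
    site's reference allele and is excluded from the sample set.
    """
    if not aln.is_projected():
        raise ValueError("alignment must be projected to rCRS coordinates first")
    rcrs_i = aln.rcrs_index
    sample_rows = [i for i in range(aln.n_sequences) if i != rcrs_i]
    sample_ids = [aln.sequence_ids[i] for i in sample_rows]
    M = aln.matrix[sample_rows]
    specified = np.isin(M, sorted(UNAMBIGUOUS))

    positions: list[int] = []
    refs: list[str] = []
    alts: list[tuple[str, ...]] = []
    rows: list[np.ndarray] = []
    for c in range(aln.n_columns):
        col = M[:, c]
        ok = specified[:, c]
        observed = col[ok]
        if observed.size == 0:
            continue
        bases, counts = np.unique(observed, return_counts=True)
        if len(bases) < 2:
            continue
        ref = str(aln.rcrs_row[c])
        # alts ordered by descending count, alphabetic on ties
        order = sorted(range(len(bases)), key=lambda k: (-counts[k], bases[k]))
        alt = tuple(str(bases[k]) for k in order if bases[k] != ref)
        coding = {ref: 0}
        for a in alt:
            coding[a] = len(coding)
        row = np.full(len(sample_ids), MISSING, dtype=np.int8)
        for base, code in coding.items():
            row[(col == base) & ok] = code
        positions.append(int(aln.column_positions[c]))
        refs.append(ref)
        alts.append(alt)
        rows.append(row)

    if not positions:
        warnings.warn("no variant sites found; returning empty panel")
        return VariantPanel(
            positions=np.empty(0, dtype=np.int64),
            ref_alleles=[],
            alt_alleles=[],
            haplotypes=np.empty((0, len(sample_ids)), dtype=np.int8),
            sample_ids=sample_ids,
        )
    return VariantPanel(
        positions=np.array(positions, dtype=np.int64),
        ref_alleles=refs,
        alt_alleles=alts,
        haplotypes=np.array(rows, dtype=np.int8),
        sample_ids=sample_ids,
    )


def filter_maf(panel: VariantPanel, threshold: float) -> VariantPanel:
    """Retain sites with minor allele frequency strictly above *threshold*.

    The thresholds of interest in practice are 0.01, 0.005 and 0.001
    (MAF > 1%, > 0.5%, > 0.1%); the comparison is strict, so a site at
    exactly the threshold is removed.
    """
    if not 0 <= threshold < 0.5:
        raise ValueError("MAF threshold must be in [0, 0.5)")
    return panel.subset_sites(panel.maf > threshold)
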