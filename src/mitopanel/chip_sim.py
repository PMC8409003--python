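"""In-silico microarray simulation.

A genotyping chip is reduced to the set of mitochondrial positions it
probes, parsed from an Oxford-style strand file.  Masking a truth panel
to a chip hides every site the chip does not probe and copies the
observed alleles verbatim at probed sites — masking is purely
information-losing, no genotyping error is introduced here.

Strand orientation is parsed but deliberately ignored: panels and chips
in this toolkit share rCRS plus-strand coordinates.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass

import numpy as np

from .panel import MISSING, VariantPanel

logger = logging.getLogger(__name__)

#: Chromosome labels accepted as mitochondrial.
MT_CHROMOSOMES = {"MT", "M", "26", "chrM", "chrMT"}

#: rCRS length; valid positions are 1..16569.
RCRS_LENGTH = 16569

MISSING_CHAR = "."


@dataclass
class ChipDefinition:
    """Site content of a microarray: sorted unique rCRS positions."""

    chip_name: str
    positions: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        pos = np.unique(np.asarray(self.positions, dtype=np.int64))
        if pos.size and (pos[0] < 1 or pos[-1] > RCRS_LENGTH):
            raise ValueError("chip positions must lie within [1, 16569]")
        self.positions = pos

    @property
    def n_sites(self) -> int:
        return len(self.positions)


@dataclass
class TypedGenotypes:
    """Observed alleles at chip-typed sites, per target sample.

    ``alleles`` is an (n_sites, n_samples) character matrix with
    :data:`MISSING_CHAR` marking missing observations.
    """

    sample_ids: list[str]
    positions: np.ndarray
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype="<U1")
        if self.alleles.shape != (len(self.positions), len(self.sample_ids)):
            raise ValueError("allele matrix shape does not match sites x samples")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def allele_map(self, sample_id: str) -> dict[int, str]:
        """Position -> observed base for one sample, missing omitted."""
        j = self.sample_ids.index(sample_id)
        return {
            int(p): str(a)
            for p, a in zip(self.positions, self.alleles[:, j])
            if a != MISSING_CHAR
        }


def parse_strand_file(path) -> ChipDefinition:
    """Parse an Oxford-style strand file into a :class:`ChipDefinition`.

    Expects whitespace-delimited rows of at least (id, chromosome,
    position); rows on non-mitochondrial chromosomes are dropped,
    positions are deduplicated, unparsable rows are skipped with a
    warning.  A strand column, if present, is ignored.
    """
    chip_name = os.path.splitext(os.path.basename(str(path)))[0]
    positions: list[int] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 3:
                n_skipped += 1
                logger.warning("%s line %d: too few columns, skipped", path, lineno)
                continue
            chrom, pos_str = fields[1], fields[2]
            if chrom not in MT_CHROMOSOMES:
                continue
            try:
                pos = int(pos_str)
            except ValueError:
                n_skipped += 1
                logger.warning("%s line %d: bad position %r, skipped", path, lineno, pos_str)
                continue
            positions.append(pos)
    if not positions:
        warnings.warn(f"strand file {path} contains no mitochondrial sites")
    return ChipDefinition(
        chip_name=chip_name,
        positions=np.array(positions, dtype=np.int64),
        source=str(path),
    )


def write_strand_file(chip: ChipDefinition, path) -> None:
    """Write a minimal strand-file-dialect site list (id, chrom, pos, strand)."""
    with open(path, "w") as fh:
        for p in chip.positions:
            fh.write(f"MT{p}\tMT\t{p}\t+\n")


def mask_to_chip(
    truth: VariantPanel,
    chip: ChipDefinition,
    target_ids: list[str],
) -> TypedGenotypes:
    """Restrict truth haplotypes to chip site content.

    Typed sites are the intersection of chip positions with the truth
    panel's variant positions; observed alleles are copied verbatim
    (missing stays missing).  Chip positions absent from the panel are
    dropped with a log note.
    """
    unknown = [s for s in target_ids if s not in truth.sample_ids]
    if unknown:
        raise ValueError(f"target ids not in truth panel: {unknown}")
    panel_pos = truth.position_index()
    site_idx = [panel_pos[int(p)] for p in chip.positions if int(p) in panel_pos]
    n_dropped = chip.n_sites - len(site_idx)
    if n_dropped:
        logger.info(
            "chip %s: %d of %d positions absent from panel, dropped",
            chip.chip_name, n_dropped, chip.n_sites,
        )
    if not site_idx:
        warnings.warn(f"chip {chip.chip_name}: no overlap with panel sites")
    sub = truth.subset_sites(np.array(site_idx, dtype=np.int64)).subset_samples(target_ids)
    chars = sub.allele_characters()
    chars[sub.haplotypes == MISSING] = MISSING_CHAR
    return TypedGenotypes(
        sample_ids=list(target_ids),
        positions=sub.positions,
        alleles=chars,
    )
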