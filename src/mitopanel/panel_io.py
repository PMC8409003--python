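"""Readers and writers between :class:`VariantPanel` and exchange formats.

Supported formats: haploid VCF 4.2 (single-allele GT, missing '.',
contig "MT"), the IMPUTE2 quartet .hap/.legend/.sample/.gen, and a
zero-rate recombination map.  Round-trips are bit-faithful on the
genotype matrix: ``read(write(panel))`` reproduces sites, samples and
alleles exactly.

The .gen probability dialect is the two-column haploid pair
(P(a0), P(a1)) per sample; typed or certain calls are degenerate (1, 0)
or (0, 1) and a missing observation is written as (0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam

from .chip_sim import MISSING_CHAR, TypedGenotypes
from .imputation import ImputationResult
from .panel import MISSING, VariantPanel

#: Chromosome labels accepted when reading; "MT" is written.
_READ_CHROMS = {"MT", "M", "26", "chrM", "chrMT"}

HAP_MISSING = "?"


@dataclass
class RecombinationMap:
    """Per-site recombination map; all rates are zero for mtDNA."""

    positions: np.ndarray
    rates: np.ndarray
    cumulative: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.rates = np.asarray(self.rates, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if np.any(self.rates != 0.0) or np.any(self.cumulative != 0.0):
            raise ValueError("mitochondrial recombination map must be all zeros")


# ---------------------------------------------------------------------------
# VCF


def write_vcf(panel: VariantPanel, path) -> None:
    """Write a panel as a haploid VCF (GT is a single allele index)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=MT,length=16569>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        for i in range(panel.n_sites):
            alt = ",".join(panel.alt_alleles[i]) if panel.alt_alleles[i] else "."
            gts = "\t".join(
                "." if g == MISSING else str(int(g)) for g in panel.haplotypes[i]
            )
            fh.write(
                f"MT\t{panel.positions[i]}\t.\t{panel.ref_alleles[i]}\t{alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path) -> VariantPanel:
    """Read a haploid VCF into a :class:`VariantPanel`."""
    try:
        vcf = pysam.VariantFile(str(path))
    except Exception as exc:  # pragma: no cover - pysam error text varies
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    sample_ids = list(vcf.header.samples)
    positions: list[int] = []
    refs: list[str] = []
    alts: list[tuple[str, ...]] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        if rec.chrom not in _READ_CHROMS:
            raise ValueError(
                f"malformed VCF {path}: unexpected chromosome {rec.chrom!r} "
                f"at position {rec.pos}"
            )
        positions.append(rec.pos)
        refs.append(rec.ref)
        alts.append(tuple(rec.alts) if rec.alts else ())
        row = np.full(len(sample_ids), MISSING, dtype=np.int8)
        for j, sid in enumerate(sample_ids):
            gt = rec.samples[sid]["GT"]
            allele = gt[0] if gt else None
            if allele is not None:
                row[j] = allele
        rows.append(row)
    vcf.close()
    return VariantPanel(
        positions=np.array(positions, dtype=np.int64),
        ref_alleles=refs,
        alt_alleles=alts,
        haplotypes=(
            np.array(rows, dtype=np.int8)
            if rows
            else np.empty((0, len(sample_ids)), dtype=np.int8)
        ),
        sample_ids=sample_ids,
    )


def panel_to_typed(panel: VariantPanel) -> TypedGenotypes:
    """View a panel's samples as typed genotypes at the panel's sites."""
    chars = panel.allele_characters()
    chars[panel.haplotypes == MISSING] = MISSING_CHAR
    return TypedGenotypes(
        sample_ids=list(panel.sample_ids),
        positions=panel.positions.copy(),
        alleles=chars,
    )


def typed_to_panel(typed: TypedGenotypes, panel: VariantPanel) -> VariantPanel:
    """Represent typed genotypes as a panel using *panel*'s site alleles.

    Sites absent from *panel* are dropped; observed alleles outside the
    site's allele set become missing.
    """
    pos_index = panel.position_index()
    keep = [t for t, p in enumerate(typed.positions) if int(p) in pos_index]
    positions, refs, alts, rows = [], [], [], []
    for t in keep:
        i = pos_index[int(typed.positions[t])]
        alleles = panel.site_alleles(i)
        coding = {a: c for c, a in enumerate(alleles)}
        row = np.array(
            [coding.get(a, MISSING) for a in typed.alleles[t]], dtype=np.int8
        )
        positions.append(int(typed.positions[t]))
        refs.append(panel.ref_alleles[i])
        alts.append(panel.alt_alleles[i])
        rows.append(row)
    return VariantPanel(
        positions=np.array(positions, dtype=np.int64),
        ref_alleles=refs,
        alt_alleles=alts,
        haplotypes=(
            np.array(rows, dtype=np.int8)
            if rows
            else np.empty((0, typed.n_samples), dtype=np.int8)
        ),
        sample_ids=list(typed.sample_ids),
    )


# ---------------------------------------------------------------------------
# IMPUTE2 .hap / .legend / .sample


def write_impute2(panel: VariantPanel, out_prefix, collapse: bool = False) -> None:
    """Write .hap/.legend/.sample files for a biallelic-coded panel.

    With ``collapse=True`` multiallelic sites are collapsed one-vs-rest
    first; otherwise they raise.
    """
    if panel.n_sites == 0:
        raise ValueError("refusing to write an empty panel to IMPUTE2 files")
    if any(len(a) > 1 for a in panel.alt_alleles):
        if not collapse:
            raise ValueError(
                "panel has multiallelic sites; pass collapse=True to collapse them"
            )
        panel = panel.to_biallelic()
    prefix = str(out_prefix)
    with open(prefix + ".legend", "w") as fh:
        fh.write("id position a0 a1\n")
        for i in range(panel.n_sites):
            a1 = panel.alt_alleles[i][0] if panel.alt_alleles[i] else "."
            fh.write(f"MT{panel.positions[i]} {panel.positions[i]} {panel.ref_alleles[i]} {a1}\n")
    with open(prefix + ".hap", "w") as fh:
        for i in range(panel.n_sites):
            fh.write(
                " ".join(
                    HAP_MISSING if g == MISSING else str(int(g))
                    for g in panel.haplotypes[i]
                )
                + "\n"
            )
    with open(prefix + ".sample", "w") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for sid in panel.sample_ids:
            fh.write(f"{sid} {sid} 0\n")


def read_impute2(prefix) -> VariantPanel:
    """Read .hap/.legend/.sample files back into a :class:`VariantPanel`."""
    prefix = str(prefix)
    with open(prefix + ".legend") as fh:
        header = fh.readline().split()
        if header[:4] != ["id", "position", "a0", "a1"]:
            raise ValueError(f"{prefix}.legend: unexpected header {header}")
        legend = [line.split() for line in fh if line.strip()]
    with open(prefix + ".sample") as fh:
        fh.readline()
        fh.readline()
        sample_ids = [line.split()[0] for line in fh if line.strip()]
    rows: list[np.ndarray] = []
    with open(prefix + ".hap") as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if len(fields) != len(sample_ids):
                raise ValueError(
                    f"{prefix}.hap line {lineno}: {len(fields)} haplotypes, "
                    f"expected {len(sample_ids)}"
                )
            rows.append(
                np.array(
                    [MISSING if f == HAP_MISSING else int(f) for f in fields],
                    dtype=np.int8,
                )
            )
    if len(rows) != len(legend):
        raise ValueError(
            f"{prefix}: .hap has {len(rows)} sites but .legend has {len(legend)}"
        )
    return VariantPanel(
        positions=np.array([int(r[1]) for r in legend], dtype=np.int64),
        ref_alleles=[r[2] for r in legend],
        alt_alleles=[(r[3],) if r[3] != "." else () for r in legend],
        haplotypes=(
            np.array(rows, dtype=np.int8)
            if rows
            else np.empty((0, len(sample_ids)), dtype=np.int8)
        ),
        sample_ids=sample_ids,
    )


# ---------------------------------------------------------------------------
# .gen and recombination map


def write_gen(obj, path, panel: VariantPanel | None = None) -> None:
    """Write per-sample haploid probability pairs in .gen layout.

    *obj* is an :class:`ImputationResult` (posterior pairs) or
    :class:`TypedGenotypes` (degenerate pairs; requires *panel* for the
    site alleles).  Missing observations are written as ``0 0``.
    """
    if isinstance(obj, ImputationResult):
        rows = zip(obj.positions, obj.ref_alleles, obj.alt_alleles)
        probs = obj.p_alt
        if np.any((probs < 0) | (probs > 1)):
            raise ValueError("posterior probabilities outside [0, 1]")
        with open(path, "w") as fh:
            for i, (pos, a0, a1) in enumerate(rows):
                pairs = " ".join(
                    f"{1.0 - p:.5f} {p:.5f}" for p in probs[i]
                )
                fh.write(f"MT{pos} MT{pos} {pos} {a0} {a1} {pairs}\n")
        return
    if isinstance(obj, TypedGenotypes):
        if panel is None:
            raise ValueError("writing TypedGenotypes to .gen requires the panel")
        coded = typed_to_panel(obj, panel.to_biallelic())
        with open(path, "w") as fh:
            for i in range(coded.n_sites):
                a1 = coded.alt_alleles[i][0] if coded.alt_alleles[i] else "."
                pairs = " ".join(
                    "0 0" if g == MISSING else ("0 1" if g == 1 else "1 0")
                    for g in coded.haplotypes[i]
                )
                fh.write(
                    f"MT{coded.positions[i]} MT{coded.positions[i]} "
                    f"{coded.positions[i]} {coded.ref_alleles[i]} {a1} {pairs}\n"
                )
        return
    raise TypeError(f"cannot write {type(obj).__name__} as .gen")


def write_map(panel: VariantPanel, path) -> RecombinationMap:
    """Write the zero-rate recombination map for a panel's sites."""
    rmap = RecombinationMap(
        positions=panel.positions.copy(),
        rates=np.zeros(panel.n_sites),
        cumulative=np.zeros(panel.n_sites),
    )
    with open(path, "w") as fh:
        fh.write("position COMBINED_rate(cM/Mb) Genetic_Map(cM)\n")
        for p in rmap.positions:
            fh.write(f"{p} 0 0\n")
    return rmap
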