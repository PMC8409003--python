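"""Table-driven mitochondrial haplogroup calling.

A haplogroup table lists lineage labels, their parent in the
mitochondrial phylogeny, and each lineage's defining variants as
(position, derived allele) pairs.  A sample is scored against a label
as the fraction of the label's *typed* defining variants at which the
sample carries the derived allele; the call is the most specific
(deepest) label whose score reaches the threshold.

This is a deliberate simplification of full PhyloTree nomenclature and
of HaploGrep-style quality scoring: it supports concordance evaluation
on panels whose clade structure is known, not fine-grained lineage
assignment on arbitrary real genomes.

Macro-collapsing reduces a label to its macrohaplogroup: the deep L
lineages keep their first major sub-haplogroup (L0–L6), HV and JT are
treated as macrohaplogroups of their own, and every other label
collapses to its first letter.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chip_sim import RCRS_LENGTH

#: Labels treated as macrohaplogroups by longest-prefix match.
DEFAULT_MACRO_PREFIXES = (
    "L0", "L1", "L2", "L3", "L4", "L5", "L6", "HV", "JT",
)


@dataclass
class HaplogroupEntry:
    label: str
    parent: str | None
    defining_variants: frozenset[tuple[int, str]]


@dataclass
class HaplogroupTable:
    """Validated lineage table: unique labels, acyclic parent graph."""

    entries: dict[str, HaplogroupEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("haplogroup table is empty")
        for entry in self.entries.values():
            if entry.parent is not None and entry.parent not in self.entries:
                raise ValueError(
                    f"haplogroup {entry.label!r} has unknown parent {entry.parent!r}"
                )
            for pos, allele in entry.defining_variants:
                if not 1 <= pos <= RCRS_LENGTH:
                    raise ValueError(
                        f"defining variant {pos}{allele} of {entry.label!r} "
                        f"outside [1, {RCRS_LENGTH}]"
                    )
        for label in self.entries:
            self.depth(label)  # raises on cycles

    def depth(self, label: str) -> int:
        """Length of the ancestor chain above *label* (root = 0)."""
        d = 0
        seen = {label}
        node = self.entries[label]
        while node.parent is not None:
            if node.parent in seen:
                raise ValueError(f"cycle in haplogroup table at {node.parent!r}")
            seen.add(node.parent)
            node = self.entries[node.parent]
            d += 1
        return d

    @property
    def labels(self) -> list[str]:
        return list(self.entries)


@dataclass
class HaplogroupCall:
    """Best-matching haplogroup for one sample.

    ``label`` is None when no lineage reached the score threshold;
    ``score`` is the fraction of the label's typed defining variants
    carrying the derived allele.
    """

    sample_id: str
    label: str | None
    score: float
    n_typed_defining: int

    def macro(self, prefixes=DEFAULT_MACRO_PREFIXES) -> str | None:
        return None if self.label is None else macro_collapse(self.label, prefixes)


def _parse_variant(token: str) -> tuple[int, str]:
    token = token.strip()
    pos, allele = token[:-1], token[-1].upper()
    if not pos.isdigit() or allele not in "ACGT":
        raise ValueError(f"malformed defining variant {token!r} (expected e.g. 73G)")
    return int(pos), allele


def load_haplogroup_table(path) -> HaplogroupTable:
    """Load a TSV haplogroup table.

    Columns: ``label``, ``parent`` ('-' or empty for roots), and a
    comma-separated list of defining variants like ``73G,263G``.  Lines
    starting with '#' are ignored.
    """
    entries: dict[str, HaplogroupEntry] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path} line {lineno}: expected 3 tab-separated columns")
            label, parent, variants = fields[0], fields[1], fields[2]
            if label in entries:
                raise ValueError(f"{path} line {lineno}: duplicate label {label!r}")
            parent_or_none = None if parent in ("", "-", ".") else parent
            defs = frozenset(
                _parse_variant(tok) for tok in variants.split(",") if tok.strip()
            )
            entries[label] = HaplogroupEntry(label, parent_or_none, defs)
    return HaplogroupTable(entries)


def write_haplogroup_table(table: HaplogroupTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("#label\tparent\tdefining_variants\n")
        for e in table.entries.values():
            variants = ",".join(
                f"{p}{a}" for p, a in sorted(e.defining_variants)
            )
            fh.write(f"{e.label}\t{e.parent or '-'}\t{variants}\n")


def call_haplogroup(
    alleles: dict[int, str],
    table: HaplogroupTable,
    sample_id: str = "",
    min_score: float = 0.9,
) -> HaplogroupCall:
    """Call the best-matching haplogroup for one sample.

    *alleles* maps rCRS position to the observed base; untyped
    positions are simply absent.  Among labels with at least one typed
    defining variant and score >= *min_score*, the deepest label wins;
    ties break on higher score, then lexicographic label.  If no label
    qualifies the call is unassigned (label None, score 0).
    """
    best: tuple[int, float, str] | None = None
    for label, entry in table.entries.items():
        typed = [(p, a) for p, a in entry.defining_variants if p in alleles]
        if not typed:
            continue
        score = sum(alleles[p] == a for p, a in typed) / len(typed)
        if score < min_score:
            continue
        key = (table.depth(label), score, label)
        if best is None or (key[0], key[1], _lex_inverse(key[2])) > (
            best[0], best[1], _lex_inverse(best[2])
        ):
            best = key
    if best is None:
        return HaplogroupCall(sample_id=sample_id, label=None, score=0.0, n_typed_defining=0)
    depth, score, label = best
    n_typed = sum(1 for p, _ in table.entries[label].defining_variants if p in alleles)
    return HaplogroupCall(
        sample_id=sample_id, label=label, score=score, n_typed_defining=n_typed
    )


class _lex_inverse(str):
    """Orders strings so that the lexicographically *smaller* wins a max()."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def macro_collapse(label: str, prefixes=DEFAULT_MACRO_PREFIXES) -> str:
    """Collapse a haplogroup label to its macrohaplogroup.

    Longest-prefix match against *prefixes* (by default L0–L6, HV, JT);
    otherwise the label's first alphabetic character.
    """
    if not label or not label[0].isalpha():
        raise ValueError(f"haplogroup label must start with a letter: {label!r}")
    hits = [p for p in prefixes if label.startswith(p)]
    if hits:
        return max(hits, key=len)
    return label[0]


def call_samples(
    allele_maps: dict[str, dict[int, str]],
    table: HaplogroupTable,
    min_score: float = 0.9,
) -> dict[str, HaplogroupCall]:
    """Call haplogroups for a batch of samples."""
    return {
        sid: call_haplogroup(alleles, table, sample_id=sid, min_score=min_score)
        for sid, alleles in allele_maps.items()
    }
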