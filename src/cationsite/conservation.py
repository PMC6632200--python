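"""Alignment-column conservation at positions of a reference sequence.

Reads an aligned FASTA (any upstream aligner), maps 1-based ungapped
reference positions to alignment columns, and reports per-column
identity percentages, residue-class percentages (e.g. negative = {D,E})
and the full composition. Gaps count in the denominator by default
(conservative); phylogenetic rate-based grades are *not* recomputed —
externally supplied grades can be passed through for display only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import AlignIO

from .errors import ConfigurationError

GAP_CHARS = "-."

#: Default residue classes for class-conservation percentages.
DEFAULT_CLASSES: dict[str, frozenset[str]] = {
    "negative": frozenset("DE"),
    "positive": frozenset("KRH"),
}


@dataclass
class Alignment:
    """Equal-length named sequences with a designated reference."""

    names: list[str]
    seqs: list[str]
    reference: str

    def __post_init__(self) -> None:
        if len(self.names) != len(self.seqs):
            raise ConfigurationError("names and sequences differ in number")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ConfigurationError("aligned sequences have unequal lengths")
        if self.reference not in self.names:
            raise ConfigurationError(f"reference {self.reference!r} not in alignment")

    @property
    def n_sequences(self) -> int:
        return len(self.seqs)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def reference_row(self) -> str:
        return self.seqs[self.names.index(self.reference)]

    def column(self, col: int) -> list[str]:
        """Characters of a 1-based alignment column."""
        if not 1 <= col <= self.length:
            raise ConfigurationError(f"column {col} out of range 1..{self.length}")
        return [s[col - 1] for s in self.seqs]


def read_alignment(path, reference: str) -> Alignment:
    aln = AlignIO.read(str(path), "fasta")
    return Alignment(names=[r.id for r in aln],
                     seqs=[str(r.seq).upper() for r in aln],
                     reference=reference)


@dataclass
class ConservationEntry:
    ref_pos: int
    column: int  # 1-based alignment column
    ref_residue: str
    identity_pct: float
    class_pct: dict[str, float] = field(default_factory=dict)
    composition_pct: dict[str, float] = field(default_factory=dict)
    ignore_gaps: bool = False


def map_position(aln: Alignment, ref_pos: int) -> int:
    """Alignment column (1-based) of the ``ref_pos``-th ungapped reference
    character."""
    ref = aln.reference_row
    if ref_pos < 1:
        raise ConfigurationError("ref_pos is 1-based and must be >= 1")
    count = 0
    for col0, ch in enumerate(ref):
        if ch not in GAP_CHARS:
            count += 1
            if count == ref_pos:
                return col0 + 1
    raise ConfigurationError(
        f"ref_pos {ref_pos} beyond ungapped reference length {count}")


def unmap_column(aln: Alignment, column: int) -> int | None:
    """Inverse of :func:`map_position`; None when the reference is gapped
    at that column."""
    ref = aln.reference_row
    if ref[column - 1] in GAP_CHARS:
        return None
    return sum(1 for ch in ref[:column] if ch not in GAP_CHARS)


def column_conservation(aln: Alignment, column: int,
                        classes: dict[str, frozenset[str]] | None = None,
                        ignore_gaps: bool = False) -> ConservationEntry:
    """Identity/class percentages and composition of one alignment column.

    The denominator is all sequences by default (gaps count as
    mismatches); with ``ignore_gaps`` it is the non-gap sequences only.
    """
    classes = DEFAULT_CLASSES if classes is None else classes
    chars = aln.column(column)
    ref_char = aln.reference_row[column - 1]
    denom_chars = [c for c in chars if c not in GAP_CHARS] if ignore_gaps else chars
    denom = len(denom_chars)
    if denom == 0:
        raise ConfigurationError(f"column {column} is all gaps")

    def pct(pred) -> float:
        return 100.0 * sum(1 for c in denom_chars if pred(c)) / denom

    comp: dict[str, float] = {}
    for c in denom_chars:
        key = "-" if c in GAP_CHARS else c
        comp[key] = comp.get(key, 0.0) + 100.0 / denom
    return ConservationEntry(
        ref_pos=unmap_column(aln, column) or 0,
        column=column,
        ref_residue=ref_char,
        identity_pct=pct(lambda c: c == ref_char),
        class_pct={name: pct(lambda c, s=s: c in s) for name, s in classes.items()},
        composition_pct=comp,
        ignore_gaps=ignore_gaps,
    )


def conservation_profile(aln: Alignment, positions: list[int],
                         classes: dict[str, frozenset[str]] | None = None,
                         ignore_gaps: bool = False) -> list[ConservationEntry]:
    """Conservation entries for 1-based ungapped reference positions."""
    return [column_conservation(aln, map_position(aln, p), classes, ignore_gaps)
            for p in positions]


def profile_table(entries: list[ConservationEntry],
                  grades: dict[int, int] | None = None):
    """Flat table; externally computed grades are passed through untouched."""
    import pandas as pd

    rows = []
    for e in entries:
        row = {"ref_pos": e.ref_pos, "column": e.column,
               "ref_residue": e.ref_residue, "identity_pct": e.identity_pct}
        for name, v in e.class_pct.items():
            row[f"{name}_pct"] = v
        comp = sorted(e.composition_pct.items(), key=lambda kv: -kv[1])
        row["composition"] = ";".join(f"{k}:{v:.1f}" for k, v in comp)
        if grades and e.ref_pos in grades:
            row["grade"] = grades[e.ref_pos]
        rows.append(row)
    return pd.DataFrame(rows)
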