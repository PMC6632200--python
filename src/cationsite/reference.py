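"""Published reference values for the OsHKT2;2 coordination-site region.

Two small datasets a user needs to reproduce the wild-type analysis
without re-running molecular dynamics or sequence retrieval:

* the wild-type ion-residue contact-frequency table for residues around
  the extracellular coordination site (pooled over three 100 ns
  replicates; per-species absolute counts with the published combined
  columns kept separately so the across-species arithmetic can be
  recomputed and checked);
* the HKT-family alignment-column compositions at the four
  coordination-site positions (P71, D75, D501, K504) over the 20-member
  characterized-channel alignment, plus the externally computed
  conservation grades displayed alongside (grades are pass-through
  only, never recomputed here).

The frame total of the pooled trajectories was not stated with the
table; 60,700 frames is inferred from the absolute/relative ratios and
reproduces every published 2-decimal relative frequency.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .conservation import Alignment
from .contacts import ContactParameters, ContactTable

#: Inferred pooled frame count behind the published contact table.
REFERENCE_N_FRAMES = 60700

#: (residue_seq, one-letter, Na abs, Na rel%, K abs, K rel%,
#:  published sum abs, published sum rel%, forms_site)
CONTACT_ROWS = [
    (69, "F", 28, 0.05, 48, 0.08, 76, 0.13, False),
    (70, "K", 306, 0.50, 273, 0.45, 579, 0.95, False),
    (71, "P", 1117, 1.84, 156, 0.26, 1273, 2.10, True),
    (72, "G", 690, 1.14, 134, 0.22, 824, 1.36, False),
    (73, "Y", 12, 0.02, 0, 0.00, 12, 0.02, False),
    (74, "I", 528, 0.87, 39, 0.06, 567, 0.93, False),
    (75, "D", 819, 1.35, 43, 0.07, 862, 1.42, True),
    (76, "M", 0, 0.00, 0, 0.00, 0, 0.00, False),
    (77, "L", 0, 0.00, 0, 0.00, 0, 0.00, False),
    (499, "W", 74, 0.12, 213, 0.35, 287, 0.47, False),
    (500, "S", 97, 0.16, 322, 0.53, 419, 0.69, False),
    (501, "D", 1105, 1.82, 307, 0.51, 1412, 2.33, True),
    (502, "E", 2125, 3.50, 5042, 8.31, 7167, 11.81, False),
    (503, "G", 0, 0.00, 12, 0.02, 12, 0.02, False),
    (504, "K", 900, 1.48, 125, 0.21, 1025, 1.69, True),
    (505, "L", 0, 0.00, 0, 0.00, 0, 0.00, False),
    (506, "L", 0, 0.00, 1, 0.00, 1, 0.00, False),
]

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def reference_contact_counts() -> tuple[ContactTable, pd.DataFrame]:
    """The wild-type per-species counts as a :class:`ContactTable` plus a
    frame holding the published combined columns for comparison.

    The returned table carries only the per-species absolute counts (the
    raw measurements); the combined columns are what
    :func:`cationsite.contacts.combine_species` recomputes.
    """
    index = pd.MultiIndex.from_tuples(
        [("A", seq, _ONE_TO_THREE[aa]) for seq, aa, *_ in CONTACT_ROWS],
        names=["chain", "residue_seq", "residue_name"])
    counts = pd.DataFrame(
        {"K": [r[4] for r in CONTACT_ROWS], "Na": [r[2] for r in CONTACT_ROWS]},
        index=index)[["K", "Na"]]
    table = ContactTable(counts=counts, n_frames=REFERENCE_N_FRAMES,
                         params=ContactParameters(),
                         replicate_ids=("rep1", "rep2", "rep3"))
    published = pd.DataFrame(
        {"na_rel": [r[3] for r in CONTACT_ROWS],
         "k_rel": [r[5] for r in CONTACT_ROWS],
         "sum_abs": [r[6] for r in CONTACT_ROWS],
         "sum_rel": [r[7] for r in CONTACT_ROWS],
         "forms_site": [r[8] for r in CONTACT_ROWS]},
        index=index)
    return table, published


#: Residue composition (counts out of 20 sequences) of the HKT-family
#: alignment columns at the coordination-site positions.
SITE_COLUMN_COMPOSITION: dict[int, dict[str, int]] = {
    71: {"P": 18, "K": 1, "S": 1},
    75: {"D": 20},
    501: {"D": 12, "E": 3, "N": 2, "P": 1, "K": 1, "W": 1},
    504: {"K": 20},
}

#: Externally computed 1-9 conservation grades, display pass-through only.
SITE_GRADES: dict[int, int] = {71: 8, 75: 9, 501: 4, 504: 9}

SITE_POSITIONS = (71, 75, 501, 504)

REFERENCE_NAME = "OsHKT2;2"


def synthetic_family_alignment(seed: int = 0, length: int = 520,
                               n_gap_cols: int = 3) -> Alignment:
    """A synthetic 20-sequence HKT-family-like alignment.

    This is a constructed stand-in, not the real family alignment: the
    columns at the coordination-site positions carry exactly the
    compositions in :data:`SITE_COLUMN_COMPOSITION` (with the reference
    sequence holding P71/D75/D501/K504), other columns are scaffold with
    mild random variation, and ``n_gap_cols`` insertion columns are
    placed before position 71 so reference positions and alignment
    columns differ. Useful for exercising position mapping and the
    column-conservation arithmetic at the published compositions.
    """
    rng = np.random.default_rng(seed)
    n_seq = 20
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

    cols: list[list[str]] = []
    for pos in range(1, length + 1):
        if pos in SITE_COLUMN_COMPOSITION:
            comp = SITE_COLUMN_COMPOSITION[pos]
            ref_char = {71: "P", 75: "D", 501: "D", 504: "K"}[pos]
            others = []
            for aa, count in comp.items():
                others.extend([aa] * count)
            others.remove(ref_char)  # reference takes one copy
            others = list(rng.permutation(others))
            cols.append([ref_char] + others)
        else:
            consensus = str(rng.choice(alphabet))
            col = [consensus] * n_seq
            for i in rng.choice(n_seq, size=rng.integers(0, 4), replace=False):
                col[i] = str(rng.choice(alphabet))
            cols.append(list(col))

    # insertion columns present only in a few non-reference sequences,
    # so the reference is gapped there and ref_pos != column downstream
    insert_at = 40
    for g in range(n_gap_cols):
        col = ["-"] * n_seq
        for i in (3, 7, 11):
            col[i] = str(rng.choice(alphabet))
        cols.insert(insert_at + g, col)

    names = [REFERENCE_NAME] + [f"synthHKT{i:02d}" for i in range(1, n_seq)]
    seqs = ["".join(col[i] for col in cols) for i in range(n_seq)]
    return Alignment(names=names, seqs=seqs, reference=REFERENCE_NAME)


def write_alignment_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(aln.names, aln.seqs):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
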