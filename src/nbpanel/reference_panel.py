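"""Published census of the anti-SpCas9 VHH discovery campaign.

These small tables record the reported characterization of the campaign's
51-clone library and its 15 selected, biotinylation-suitable clones: the
per-clone somatic mutation census (nucleotide mutations and amino-acid
changes from the inferred unmutated common ancestor, plus framework
lysine counts) and the library-wide germline gene usage.  They serve as
worked-example inputs for :func:`nbpanel.repertoire.mutation_summary` and
:func:`nbpanel.repertoire.gene_usage`-style arithmetic, and as the layout
the synthetic generators emulate.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "selected_clone_census",
    "library_gene_usage_counts",
    "EPITOPE_BINS",
    "PANEL_EC50_NM",
    "MP_PEAKS_KDA",
]

# clone, V-region nt mutations, aa changes, non-CDR3 lysines
_SELECTED = [
    ("C1", 33, 20, 3),
    ("C7", 37, 21, 5),
    ("F9", 35, 20, 5),
    ("D9", 14, 7, 5),
    ("G7", 10, 6, 5),
    ("E6", 8, 5, 5),
    ("F8", 10, 6, 5),
    ("F1", 7, 3, 5),
    ("G10", 10, 6, 5),
    ("D5", 41, 20, 5),
    ("F6", 10, 5, 5),
    ("A6", 44, 23, 5),
    ("G5", 32, 17, 5),
    ("D8", 12, 6, 5),
    ("E4", 9, 4, 5),
]

# segment, gene, clone count (V/J denominators: 51 clones; D: clones with
# an identifiable D segment)
_GENE_USAGE = [
    ("V", "IGHV3S66", 26),
    ("V", "IGHV3S53", 12),
    ("V", "IGHV3S65", 11),
    ("V", "IGHV3S1", 1),
    ("V", "IGHV3S61", 1),
    ("D", "IGHD3", 7),
    ("D", "IGHD5", 2),
    ("D", "IGHD6", 1),
    ("D", "IGHD2", 1),
    ("D", "IGHD1", 1),
    ("J", "IGHJ4", 39),
    ("J", "IGHJ6", 8),
    ("J", "IGHJ7", 4),
]

# Reported epitope partition of the nine well-expressing binders.
EPITOPE_BINS: dict[str, tuple[str, ...]] = {
    "bin1": ("C1",),
    "bin2": ("F9", "C7"),
    "bin3": ("E6", "F1", "F8", "G10", "G7", "D9"),
}

# Reported EC50s (nM) of the nine binders against apo SpCas9.
PANEL_EC50_NM: dict[str, float] = {
    "C1": 2.0,
    "D9": 4.5,
    "F9": 6.6,
    "C7": 7.1,
    "G7": 9.1,
    "F8": 18.5,
    "F1": 21.0,
    "E6": 37.0,
    "G10": 63.4,
}

# Reported stepwise mass-photometry peaks (kDa): SpCas9 alone, +C1,
# +C1+D9, +C1+D9+F9.
MP_PEAKS_KDA: tuple[float, ...] = (160.0, 180.0, 190.0, 209.0)


def selected_clone_census() -> pd.DataFrame:
    """Per-clone mutation/lysine census of the 15 selected clones."""
    return pd.DataFrame(
        _SELECTED,
        columns=["clone", "v_nt_mutations", "aa_changes", "non_cdr3_lysines"],
    )


def library_gene_usage_counts() -> pd.DataFrame:
    """Library-wide germline gene usage counts by segment class."""
    return pd.DataFrame(_GENE_USAGE, columns=["segment", "gene", "count"])
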