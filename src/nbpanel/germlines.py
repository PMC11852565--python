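"""Germline V/D/J reference sets for VHH (single-domain antibody) annotation.

A :class:`GermlineSet` holds named nucleotide sequences for the three
rearranging segment classes plus, for every V gene, fixed region anchors on
the germline *translation* in the style of a fixed-position numbering scheme:
the three CDR intervals, from which the four framework regions follow.  The
reference is user-supplied (FASTA plus a sidecar anchor table); nothing is
bundled from any germline database.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = ["RegionAnchors", "GermlineSet", "load_germline_set", "write_germline_set"]

REGION_NAMES = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")


@dataclass(frozen=True)
class RegionAnchors:
    """CDR intervals on a germline V translation (aa coordinates).

    ``cdr3`` spans from the start of CDR3 to the end of the V translation;
    the true CDR3 end of a rearranged clone is set by its J segment.
    """

    cdr1: tuple[int, int]
    cdr2: tuple[int, int]
    cdr3: tuple[int, int]

    def __post_init__(self) -> None:
        ivs = (self.cdr1, self.cdr2, self.cdr3)
        flat = [x for iv in ivs for x in iv]
        if flat != sorted(flat) or any(s >= e for s, e in ivs):
            raise ValueError(f"CDR anchors must be ascending, non-overlapping: {ivs}")

    def as_row(self) -> list[int]:
        return [*self.cdr1, *self.cdr2, *self.cdr3]


@dataclass
class GermlineSet:
    """Named germline V/D/J nucleotide sequences with V-gene region anchors.

    Parameters
    ----------
    v_genes, d_genes, j_genes
        Mapping of gene name to nucleotide sequence. V genes are expected
        in-frame (frame 0). D genes may be absent entirely.
    v_anchors
        Per-V-gene :class:`RegionAnchors` on the V translation.
    j_fr4_start
        Per-J-gene aa offset into the J translation at which FR4 begins
        (the tryptophan of the W-G-x-G motif). CDR3 of a rearranged clone
        ends there.
    """

    v_genes: dict[str, str]
    d_genes: dict[str, str] = field(default_factory=dict)
    j_genes: dict[str, str] = field(default_factory=dict)
    v_anchors: dict[str, RegionAnchors] = field(default_factory=dict)
    j_fr4_start: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.v_genes:
            raise ValueError("germline set needs at least one V gene")
        for name in self.v_genes:
            if name not in self.v_anchors:
                raise ValueError(f"V gene {name!r} has no region anchors")
            aa_len = len(self.v_aa(name))
            if self.v_anchors[name].cdr3[1] > aa_len:
                raise ValueError(f"anchors of {name!r} exceed its translation")

    def v_aa(self, name: str) -> str:
        """Translation of a V gene (frame 0, stops not expected)."""
        nt = self.v_genes[name]
        return str(Seq(nt[: len(nt) - len(nt) % 3]).translate())

    def j_aa(self, name: str) -> str:
        nt = self.j_genes[name]
        return str(Seq(nt[: len(nt) - len(nt) % 3]).translate())


def load_germline_set(fasta_path: str | Path, anchors_path: str | Path) -> GermlineSet:
    """Read a germline set from FASTA plus a TSV anchor table.

    FASTA record ids must be ``<segment>|<gene name>`` with segment one of
    ``V``/``D``/``J``.  The anchor table has columns
    ``gene  segment  b1 b2 b3 b4 b5 b6``: for V rows the six boundaries are
    CDR1 start/end, CDR2 start/end, CDR3 start/end (aa, 0-based half-open on
    the V translation); for J rows only ``b1`` is used, as the FR4 start
    offset within the J translation.
    """
    segments: dict[str, dict[str, str]] = {"V": {}, "D": {}, "J": {}}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        try:
            seg, name = rec.id.split("|", 1)
        except ValueError as exc:
            raise ValueError(f"germline id {rec.id!r} not of form SEGMENT|NAME") from exc
        if seg not in segments:
            raise ValueError(f"unknown segment class {seg!r} in {rec.id!r}")
        if name in segments[seg]:
            raise ValueError(f"duplicate {seg} gene name {name!r}")
        segments[seg][name] = str(rec.seq).upper()

    v_anchors: dict[str, RegionAnchors] = {}
    j_fr4: dict[str, int] = {}
    with open(anchors_path, newline="") as fh:
        for row in csv.DictReader(
            (ln for ln in fh if not ln.startswith("#")), delimiter="\t"
        ):
            if row["segment"] == "V":
                b = [int(row[f"b{i}"]) for i in range(1, 7)]
                v_anchors[row["gene"]] = RegionAnchors((b[0], b[1]), (b[2], b[3]), (b[4], b[5]))
            elif row["segment"] == "J":
                j_fr4[row["gene"]] = int(row["b1"])
    return GermlineSet(
        v_genes=segments["V"],
        d_genes=segments["D"],
        j_genes=segments["J"],
        v_anchors=v_anchors,
        j_fr4_start=j_fr4,
    )


def write_germline_set(gs: GermlineSet, fasta_path: str | Path, anchors_path: str | Path) -> None:
    """Inverse of :func:`load_germline_set`."""
    with open(fasta_path, "w") as fh:
        for seg, genes in (("V", gs.v_genes), ("D", gs.d_genes), ("J", gs.j_genes)):
            for name, nt in genes.items():
                fh.write(f">{seg}|{name}\n{nt}\n")
    with open(anchors_path, "w") as fh:
        fh.write("gene\tsegment\tb1\tb2\tb3\tb4\tb5\tb6\n")
        for name, anc in gs.v_anchors.items():
            fh.write(f"{name}\tV\t" + "\t".join(map(str, anc.as_row())) + "\n")
        for name, off in gs.j_fr4_start.items():
            fh.write(f"{name}\tJ\t{off}\t0\t0\t0\t0\t0\n")
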