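"""Repertoire census of a VHH (nanobody) clone panel.

Covers the sequence-analysis arm of a nanobody discovery campaign:

* reading-frame detection and translation,
* deduplication at nucleotide or protein level,
* germline V/D/J assignment by pairwise alignment against a user-supplied
  reference, with somatic nucleotide-mutation and amino-acid-change counts,
* CDR/framework region annotation by anchor transfer from the best V gene,
* the lysine census used to pick clones that tolerate NHS-ester
  biotinylation (no CDR3 lysines, several framework lysines),
* gene-usage and mutation summaries,
* the pairwise percent-identity matrix and a neighbor-joining cladogram.

Alignment is delegated to ``Bio.Align.PairwiseAligner``; trees to
``skbio.tree.nj``.  All coordinates are 0-based half-open on ``aa_seq``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .germlines import GermlineSet

__all__ = [
    "GermlineCall",
    "LysineCensus",
    "NanobodyRecord",
    "SelectionCriteria",
    "UntranslatableError",
    "UnassignableError",
    "translate_and_frame",
    "deduplicate",
    "assign_germline",
    "annotate",
    "count_lysines",
    "select_candidates",
    "gene_usage",
    "mutation_summary",
    "identity_matrix",
    "build_cladogram",
]


class UntranslatableError(ValueError):
    """No reading frame yields a sufficiently long stop-free translation."""


class UnassignableError(ValueError):
    """No germline V gene aligns above the identity/length floor."""


@dataclass
class GermlineCall:
    """Inferred germline origin of one clone.

    ``v_nt_mutations`` counts nucleotide mismatches plus gapped columns in
    the V alignment; ``aa_changes`` counts residue differences in the
    codon-aligned V translation, so silent and multi-hit codons make the
    two counts diverge (typically 2-3x).
    """

    v_gene: str
    j_gene: str | None
    d_gene: str | None
    v_identity: float
    v_nt_mutations: int
    aa_changes: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.v_identity <= 100.0:
            raise ValueError("v_identity must lie in [0, 100]")


@dataclass(frozen=True)
class LysineCensus:
    cdr3_lysines: int
    non_cdr3_lysines: int

    @property
    def total(self) -> int:
        return self.cdr3_lysines + self.non_cdr3_lysines


@dataclass(frozen=True)
class SelectionCriteria:
    """Biotinylation-suitability filter.

    The campaign's stated rule is "no lysines in CDR3, more than three
    elsewhere", but its own selected panel contains a clone with exactly
    three framework lysines, so the comparator defaults to ``at_least``.
    """

    max_cdr3_lysines: int = 0
    min_non_cdr3_lysines: int = 3
    comparator: str = "at_least"  # or "strict_greater"

    def __post_init__(self) -> None:
        if self.comparator not in ("at_least", "strict_greater"):
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if self.max_cdr3_lysines < 0 or self.min_non_cdr3_lysines < 0:
            raise ValueError("lysine thresholds must be non-negative")

    def accepts(self, census: LysineCensus) -> bool:
        if census.cdr3_lysines > self.max_cdr3_lysines:
            return False
        if self.comparator == "at_least":
            return census.non_cdr3_lysines >= self.min_non_cdr3_lysines
        return census.non_cdr3_lysines > self.min_non_cdr3_lysines


@dataclass
class NanobodyRecord:
    """One clone: nucleotide sequence plus derived annotation."""

    clone_id: str
    nt_seq: str
    aa_seq: str | None = None
    frame_offset: int | None = None
    regions: dict[str, tuple[int, int]] | None = None
    germline: GermlineCall | None = None

    @classmethod
    def from_nt(cls, clone_id: str, nt_seq: str) -> "NanobodyRecord":
        aa, off = translate_and_frame(nt_seq)
        return cls(clone_id=clone_id, nt_seq=nt_seq.upper(), aa_seq=aa, frame_offset=off)

    @property
    def cdr3(self) -> str:
        if self.regions is None or "CDR3" not in self.regions:
            raise ValueError(f"{self.clone_id}: CDR3 not annotated")
        s, e = self.regions["CDR3"]
        return self.aa_seq[s:e]


MIN_TRANSLATION_AA = 30


def translate_and_frame(nt_seq: str) -> tuple[str, int]:
    """Pick the reading frame with the longest stop-free translation.

    Returns the translation from that frame, truncated at the first stop
    codon (if any), and the 0-based frame offset.  Ties go to the smallest
    offset.  Raises :class:`UntranslatableError` when no frame yields at
    least 30 stop-free residues.
    """
    nt = nt_seq.upper().replace("U", "T")
    if len(nt) < 90:
        raise UntranslatableError(f"sequence too short ({len(nt)} nt)")
    if set(nt) - set("ACGTN"):
        raise UntranslatableError(f"non-ACGTN symbols: {sorted(set(nt) - set('ACGTN'))}")
    best: tuple[int, int] | None = None  # (stop-free length, -frame)
    best_aa, best_frame = "", 0
    for frame in (0, 1, 2):
        sub = nt[frame:]
        aa = str(Seq(sub[: len(sub) - len(sub) % 3]).translate())
        stem = aa.split("*", 1)[0]
        key = (len(stem), -frame)
        if best is None or key > best:
            best, best_aa, best_frame = key, stem, frame
    if len(best_aa) < MIN_TRANSLATION_AA:
        raise UntranslatableError(
            f"no stop-free frame of >= {MIN_TRANSLATION_AA} aa (best {len(best_aa)})"
        )
    return best_aa, best_frame


def deduplicate(records: list[NanobodyRecord], level: str = "aa") -> list[list[NanobodyRecord]]:
    """Partition records into identical-sequence groups.

    ``level`` selects exact nucleotide or exact protein identity.  Groups
    preserve first-occurrence order, so the operation is idempotent and
    moving from ``nt`` to ``aa`` can only merge groups.
    """
    if not records:
        raise ValueError("no records to deduplicate")
    if level not in ("nt", "aa"):
        raise ValueError(f"level must be 'nt' or 'aa', got {level!r}")
    groups: dict[str, list[NanobodyRecord]] = {}
    for rec in records:
        key = rec.nt_seq if level == "nt" else rec.aa_seq
        if key is None:
            raise ValueError(f"{rec.clone_id}: not translated")
        groups.setdefault(key, []).append(rec)
    return list(groups.values())


def _v_aligner() -> Align.PairwiseAligner:
    # Semi-global: the germline segment aligns as an infix of the clone,
    # end gaps on the germline side are free.
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = 0
    a.open_gap_score = -10
    a.extend_gap_score = -1
    a.end_deletion_score = 0
    a.end_insertion_score = -10
    return a


def _aa_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = 0
    a.open_gap_score = -10
    a.extend_gap_score = -1
    return a


def _alignment_stats(aln) -> tuple[int, int, int, int]:
    """(identities, mismatches, internal gap columns, aligned span columns)."""
    c = aln.counts()
    internal_gaps = c.internal_insertions + c.internal_deletions
    return c.identities, c.mismatches, internal_gaps, c.aligned + internal_gaps


def _query_to_target_map(aln) -> dict[int, int]:
    """Map query (germline) positions to target (clone) positions."""
    mapping: dict[int, int] = {}
    t_blocks, q_blocks = aln.aligned
    for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks, strict=True):
        for dt in range(t1 - t0):
            mapping[q0 + dt] = t0 + dt
    return mapping


def _best_semiglobal(clone_nt: str, genes: dict[str, str]):
    """Best-identity semi-global hit of each gene against the clone.

    Returns (name, alignment, identity_fraction) sorted winner; ties on
    identity break lexicographically on gene name.
    """
    aligner = _v_aligner()
    best: tuple[float, str, object] | None = None
    for name in sorted(genes):  # lexicographic tie-break: first win is kept
        aln = aligner.align(clone_nt, genes[name])[0]
        ident, _mism, _gaps, span = _alignment_stats(aln)
        frac = ident / span if span else 0.0
        if best is None or frac > best[0]:
            best = (frac, name, aln)
    if best is None:
        return None
    return best[1], best[2], best[0]


def assign_germline(
    record: NanobodyRecord,
    germline_set: GermlineSet,
    *,
    min_v_identity: float = 60.0,
    min_d_length: int = 8,
    min_d_identity: float = 0.8,
) -> GermlineCall:
    """Assign germline V, J and (when alignable) D genes to one clone.

    V and J are chosen by highest pairwise-alignment identity over the
    aligned span (semi-global, so the germline aligns as an infix of the
    clone).  ``v_nt_mutations`` = mismatches + gapped columns within the V
    alignment; ``aa_changes`` = mismatched residues between the codon-aligned
    clone V region and the germline V translation.  D is searched only in
    the junction between the V and J footprints and left absent when no D
    gene reaches the length/identity floor — short or heavily trimmed D
    segments are genuinely unidentifiable, as is common for VHH clones.
    """
    if record.aa_seq is None or record.frame_offset is None:
        raise ValueError(f"{record.clone_id}: translate before germline assignment")
    nt = record.nt_seq.upper()

    hit = _best_semiglobal(nt, germline_set.v_genes)
    if hit is None:
        raise UnassignableError(f"{record.clone_id}: empty V reference")
    v_name, v_aln, v_frac = hit
    if 100.0 * v_frac < min_v_identity:
        raise UnassignableError(
            f"{record.clone_id}: best V identity {100 * v_frac:.1f}% below floor {min_v_identity}%"
        )
    ident, mism, gaps, span = _alignment_stats(v_aln)
    v_nt_mutations = mism + gaps
    v_map = _query_to_target_map(v_aln)

    # codon-aligned amino-acid changes over the germline V translation
    v_nt = germline_set.v_genes[v_name]
    aa_changes = 0
    for codon_idx in range(len(v_nt) // 3):
        qs = 3 * codon_idx
        tpos = [v_map.get(qs + k) for k in range(3)]
        if None in tpos or tpos[2] - tpos[0] != 2:
            if any(p is not None for p in tpos) and not all(p is not None for p in tpos):
                aa_changes += 1  # codon disrupted by an indel
            continue
        g_aa = str(Seq(v_nt[qs : qs + 3]).translate())
        c_aa = str(Seq(nt[tpos[0] : tpos[0] + 3]).translate())
        if g_aa != c_aa:
            aa_changes += 1

    v_t_end = max(v_map.values()) + 1 if v_map else 0

    j_name = None
    j_hit = _best_semiglobal(nt[v_t_end:], germline_set.j_genes) if germline_set.j_genes else None
    if j_hit is not None and j_hit[2] >= 0.5:
        j_name = j_hit[0]
    j_t_start = len(nt)
    if j_name is not None:
        j_map = _query_to_target_map(j_hit[1])
        if j_map:
            j_t_start = v_t_end + min(j_map.values())

    d_name = None
    junction = nt[max(v_t_end - 3, 0) : min(j_t_start + 3, len(nt))]
    if germline_set.d_genes and len(junction) >= min_d_length:
        local = Align.PairwiseAligner()
        local.mode = "local"
        local.match_score = 1
        local.mismatch_score = -1
        local.open_gap_score = -5
        local.extend_gap_score = -2
        best_d = None
        for name in sorted(germline_set.d_genes):
            alns = local.align(junction, germline_set.d_genes[name])
            if len(alns) == 0:
                continue
            aln = alns[0]
            ident_d, mism_d, gaps_d, span_d = _alignment_stats(aln)
            if span_d >= min_d_length and span_d and ident_d / span_d >= min_d_identity:
                key = (ident_d / span_d, span_d)
                if best_d is None or key > best_d[0]:
                    best_d = (key, name)
        if best_d is not None:
            d_name = best_d[1]

    return GermlineCall(
        v_gene=v_name,
        j_gene=j_name,
        d_gene=d_name,
        v_identity=100.0 * v_frac,
        v_nt_mutations=v_nt_mutations,
        aa_changes=aa_changes,
    )


def annotate(
    record: NanobodyRecord,
    germline_set: GermlineSet,
    **assign_kwargs,
) -> NanobodyRecord:
    """Translate (if needed), assign germline, and transfer region anchors.

    CDR1/2 boundaries and the CDR3 start come from the best V gene's
    anchors mapped through the V alignment; the CDR3 end comes from the
    assigned J gene's FR4-start anchor.  Region intervals are clamped to
    the clone translation and stored on the record.
    """
    if record.aa_seq is None:
        record.aa_seq, record.frame_offset = translate_and_frame(record.nt_seq)
    call = assign_germline(record, germline_set, **assign_kwargs)
    record.germline = call

    nt = record.nt_seq.upper()
    aligner = _v_aligner()
    v_aln = aligner.align(nt, germline_set.v_genes[call.v_gene])[0]
    v_map = _query_to_target_map(v_aln)
    off = record.frame_offset
    n_aa = len(record.aa_seq)

    def clone_aa_pos(germ_aa_pos: int, default: int) -> int:
        t = v_map.get(3 * germ_aa_pos)
        if t is None:
            return default
        return min(max((t - off) // 3, 0), n_aa)

    anc = germline_set.v_anchors[call.v_gene]
    c1s = clone_aa_pos(anc.cdr1[0], 0)
    c1e = clone_aa_pos(anc.cdr1[1], c1s)
    c2s = clone_aa_pos(anc.cdr2[0], c1e)
    c2e = clone_aa_pos(anc.cdr2[1], c2s)
    c3s = clone_aa_pos(anc.cdr3[0], c2e)

    c3e = n_aa
    if call.j_gene is not None:
        v_t_end = max(v_map.values()) + 1 if v_map else 0
        j_aln = aligner.align(nt[v_t_end:], germline_set.j_genes[call.j_gene])[0]
        j_map = _query_to_target_map(j_aln)
        fr4_nt = 3 * germline_set.j_fr4_start.get(call.j_gene, 0)
        t = j_map.get(fr4_nt)
        if t is not None:
            c3e = min(max((v_t_end + t - off) // 3, c3s), n_aa)

    record.regions = {
        "FR1": (0, c1s),
        "CDR1": (c1s, c1e),
        "FR2": (c1e, c2s),
        "CDR2": (c2s, c2e),
        "FR3": (c2e, c3s),
        "CDR3": (c3s, c3e),
        "FR4": (c3e, n_aa),
    }
    return record


def count_lysines(record: NanobodyRecord) -> LysineCensus:
    """Split the clone's lysine count into CDR3 vs everywhere else."""
    if record.regions is None or "CDR3" not in record.regions:
        raise ValueError(f"{record.clone_id}: CDR3 annotation required")
    s, e = record.regions["CDR3"]
    inside = record.aa_seq[s:e].count("K")
    total = record.aa_seq.count("K")
    return LysineCensus(cdr3_lysines=inside, non_cdr3_lysines=total - inside)


def select_candidates(
    records: list[NanobodyRecord],
    criteria: SelectionCriteria | None = None,
) -> list[NanobodyRecord]:
    """Deterministically filter clones suitable for NHS-biotinylation."""
    criteria = criteria or SelectionCriteria()
    return [rec for rec in records if criteria.accepts(count_lysines(rec))]


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def gene_usage(records: list[NanobodyRecord]) -> pd.DataFrame:
    """Per-segment-class gene usage table (gene, count, percent).

    Percent denominators: V and J over all records, D over records with an
    assigned D (unassignable D segments are excluded, not counted as a
    category).  Percents are rounded to one decimal, half-up.
    """
    if any(rec.germline is None for rec in records):
        raise ValueError("all records need germline calls")
    rows = []
    for seg, getter in (
        ("V", lambda c: c.v_gene),
        ("D", lambda c: c.d_gene),
        ("J", lambda c: c.j_gene),
    ):
        names = [getter(rec.germline) for rec in records]
        names = [n for n in names if n is not None]
        denom = len(names)
        counts = pd.Series(names).value_counts() if names else pd.Series(dtype=int)
        for gene, count in counts.sort_values(ascending=False).items():
            rows.append(
                {
                    "segment": seg,
                    "gene": gene,
                    "count": int(count),
                    "percent": _round1(100.0 * count / denom),
                }
            )
    return pd.DataFrame(rows, columns=["segment", "gene", "count", "percent"])


def mutation_summary(records: list[NanobodyRecord]) -> dict[str, dict[str, float | int]]:
    """Mean (1 decimal, half-up) and exact min/max of the mutation census."""
    if not records:
        raise ValueError("empty record list")
    if any(rec.germline is None for rec in records):
        raise ValueError("all records need germline calls")
    out = {}
    for key, attr in (("nt_mutations", "v_nt_mutations"), ("aa_changes", "aa_changes")):
        vals = [getattr(rec.germline, attr) for rec in records]
        out[key] = {"mean": _round1(sum(vals) / len(vals)), "min": min(vals), "max": max(vals)}
    return out


def identity_matrix(records: list[NanobodyRecord]) -> pd.DataFrame:
    """Symmetric pairwise percent-identity matrix from global aa alignment.

    identity = 100 * matches / alignment length (columns, gaps included);
    the diagonal is exactly 100.
    """
    if len(records) < 2:
        raise ValueError("need at least two records")
    ids = [rec.clone_id for rec in records]
    if len(set(ids)) != len(ids):
        raise ValueError("clone ids must be unique")
    aligner = _aa_aligner()
    n = len(records)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(records[i].aa_seq, records[j].aa_seq)[0]
            ident = aln.counts().identities
            mat[i, j] = mat[j, i] = 100.0 * ident / aln.length
    return pd.DataFrame(mat, index=ids, columns=ids)


def build_cladogram(matrix: pd.DataFrame) -> TreeNode:
    """Neighbor-joining tree on distance = 100 - percent identity.

    Negative NJ branch lengths (a known artifact on noisy matrices) are
    clamped to zero.  The returned tree serializes to Newick via
    ``str(tree)`` or ``tree.write``.
    """
    if matrix.shape[0] < 3:
        raise ValueError("cladogram needs at least three leaves")
    if not np.allclose(matrix.values, matrix.values.T):
        raise ValueError("identity matrix must be symmetric")
    dist = 100.0 - matrix.values
    np.fill_diagonal(dist, 0.0)
    tree = nj(DistanceMatrix(dist, ids=list(matrix.index)))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree
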