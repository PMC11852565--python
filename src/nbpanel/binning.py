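"""Sandwich-ELISA epitope binning from corrected dose-response areas.

In a capture experiment the antigen is immobilized by one *unbiotinylated*
nanobody and titrated with every *biotinylated* analyte, including the
capture clone's own biotinylated version.  For each analyte the statistic
is

    corrected_auc(analyte) = AUC(analyte) - AUC(capture's biotinylated self)
    percent_binding        = 100 * corrected_auc / max_analyte corrected_auc

clamped to [0, 100].  An analyte that shares the capture clone's epitope is
blocked and scores low (< ``same_max``, default 25%); an analyte binding a
different epitope scores high (> ``diff_min``, default 60%); the interval
between is reported as indeterminate rather than forced to a side.

Bins are the connected components of the graph whose edges are
same-epitope calls from any experiment in either direction; conflicting
evidence keeps the edge but is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .dose_response import DoseResponseCurve, auc

__all__ = [
    "Thresholds",
    "CompetitionExperiment",
    "CompetitionScore",
    "BinAssignment",
    "score_competition",
    "infer_bins",
    "infer_bins_from_percent",
    "bins_from_scores",
    "binning_report",
]

SAME, DIFFERENT, INDETERMINATE = "same_epitope", "different_epitope", "indeterminate"


@dataclass(frozen=True)
class Thresholds:
    """Percent-binding classification cut-offs."""

    same_max: float = 25.0
    diff_min: float = 60.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.same_max < self.diff_min <= 100.0:
            raise ValueError("need 0 <= same_max < diff_min <= 100")

    def classify(self, percent: float) -> str:
        if percent < self.same_max:
            return SAME
        if percent > self.diff_min:
            return DIFFERENT
        return INDETERMINATE


@dataclass
class CompetitionExperiment:
    """One capture clone with dose-response curves for every analyte."""

    capture_clone: str
    analyte_curves: dict[str, DoseResponseCurve]

    def __post_init__(self) -> None:
        if self.capture_clone not in self.analyte_curves:
            raise ValueError(
                f"capture clone {self.capture_clone!r} must appear among analytes "
                "(its biotinylated self is the correction baseline)"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **curve_kwargs) -> list["CompetitionExperiment"]:
        """Split a long-format competition plate into experiments.

        Expected columns: ``capture_clone, analyte_clone, concentration,
        conc_unit, a450, blank`` (plus optional ``replicate``).
        """
        out = []
        for capture, sub in df.groupby("capture_clone", sort=False):
            curves = {}
            for analyte, rows in sub.groupby("analyte_clone", sort=False):
                rows = rows.rename(columns={"analyte_clone": "clone_id"})
                rows = rows.assign(antigen_id=f"captured-by-{capture}")
                curves[str(analyte)] = DoseResponseCurve.from_dataframe(rows, **curve_kwargs)
            out.append(cls(capture_clone=str(capture), analyte_curves=curves))
        return out


@dataclass(frozen=True)
class CompetitionScore:
    capture: str
    analyte: str
    corrected_auc: float
    percent_binding: float
    classification: str
    usable: bool = True


def score_competition(
    exp: CompetitionExperiment,
    thresholds: Thresholds | None = None,
    *,
    blockade_level: float = 0.15,
    min_dynamic_range: float = 0.1,
) -> list[CompetitionScore]:
    """Corrected-AUC percent-binding scores for one capture experiment.

    The self analyte scores exactly 0 (same epitope by construction).
    A flat experiment — corrected areas spanning less than
    ``min_dynamic_range`` of the largest raw area — is interpreted by its
    absolute signal: when the mean net absorbance stays below
    ``blockade_level`` AU no analyte bound, i.e. the capture clone blocks
    every epitope probed, and all analytes are called same-epitope; when
    the signal is high the capture failed to block even its own
    biotinylated twin and the experiment carries no competition
    information (flagged unusable).
    """
    thresholds = thresholds or Thresholds()
    self_auc = auc(exp.analyte_curves[exp.capture_clone])
    raw = {a: auc(c) for a, c in exp.analyte_curves.items()}
    corrected = {a: v - self_auc for a, v in raw.items()}
    max_corr = max(corrected.values())
    max_raw = max(raw.values())
    some_curve = exp.analyte_curves[exp.capture_clone]
    decades = float(np.log10(some_curve.concentration.max()
                             / some_curve.concentration.min())) or 1.0
    mean_net = max_raw / decades
    flat = max_corr <= min_dynamic_range * max_raw or max_corr <= 0
    all_blocked = flat and mean_net < blockade_level
    usable = (not flat) or all_blocked
    scores = []
    for analyte, corr in corrected.items():
        if analyte == exp.capture_clone:
            pct, cls = 0.0, SAME
        elif all_blocked:
            pct, cls = 0.0, SAME
        elif not flat:
            pct = min(max(100.0 * corr / max_corr, 0.0), 100.0)
            cls = thresholds.classify(pct)
        else:
            pct, cls = 0.0, INDETERMINATE
        scores.append(
            CompetitionScore(
                capture=exp.capture_clone,
                analyte=analyte,
                corrected_auc=0.0 if analyte == exp.capture_clone else corr,
                percent_binding=pct,
                classification=cls,
                usable=usable,
            )
        )
    return scores


@dataclass
class BinAssignment:
    """Epitope partition with the evidence graph behind it.

    ``conflicts`` lists unordered pairs called both same- and
    different-epitope across experiments (the same-epitope edge is kept
    for connectivity, the conflict is surfaced).  ``inferred_by_transitivity``
    lists intra-bin pairs never directly assayed as same-epitope.
    """

    bins: dict[str, int]
    graph: nx.Graph
    scores: list[CompetitionScore]
    conflicts: list[tuple[str, str]] = field(default_factory=list)
    indeterminate_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return len(set(self.bins.values()))

    def members(self) -> dict[int, frozenset[str]]:
        out: dict[int, set[str]] = {}
        for clone, b in self.bins.items():
            out.setdefault(b, set()).add(clone)
        return {b: frozenset(m) for b, m in out.items()}

    @property
    def inferred_by_transitivity(self) -> list[tuple[str, str]]:
        pairs = []
        for comp in nx.connected_components(self.graph):
            comp = sorted(comp)
            for i, a in enumerate(comp):
                for b in comp[i + 1 :]:
                    if not self.graph.has_edge(a, b):
                        pairs.append((a, b))
        return pairs


def infer_bins(
    experiments: list[CompetitionExperiment],
    thresholds: Thresholds | None = None,
) -> BinAssignment:
    """Infer epitope bins as connected components of same-epitope calls.

    The clone universe is the union of captures and analytes; clones with
    no same-epitope evidence form singleton bins.  Bin labels are assigned
    in order of each bin's lexicographically smallest member.
    """
    if not experiments:
        raise ValueError("need at least one competition experiment")
    thresholds = thresholds or Thresholds()
    universe: set[str] = set()
    all_scores: list[CompetitionScore] = []
    for exp in experiments:
        universe.add(exp.capture_clone)
        universe.update(exp.analyte_curves)
        all_scores.extend(score_competition(exp, thresholds))
    return bins_from_scores(all_scores, universe)


def infer_bins_from_percent(
    matrix: pd.DataFrame,
    thresholds: Thresholds | None = None,
) -> BinAssignment:
    """Bin inference directly from a percent-binding matrix.

    ``matrix`` has one row per capture clone and one column per analyte,
    cells holding percent binding (NaN for unassayed pairs).  This is the
    entry point for encoding an already-summarized competition outcome —
    e.g. a published capture-ELISA summary — without raw plate curves.
    """
    thresholds = thresholds or Thresholds()
    scores = []
    for capture in matrix.index:
        for analyte in matrix.columns:
            pct = matrix.loc[capture, analyte]
            if pd.isna(pct):
                continue
            pct = float(pct)
            cls = SAME if analyte == capture else thresholds.classify(pct)
            scores.append(CompetitionScore(
                capture=str(capture), analyte=str(analyte), corrected_auc=float("nan"),
                percent_binding=pct, classification=cls,
            ))
    universe = set(map(str, matrix.index)) | set(map(str, matrix.columns))
    return bins_from_scores(scores, universe)


def bins_from_scores(
    all_scores: list[CompetitionScore],
    universe: set[str],
) -> BinAssignment:
    """Connected-component partition from pre-computed competition scores."""
    calls: dict[tuple[str, str], set[str]] = {}
    for sc in all_scores:
        if not sc.usable or sc.analyte == sc.capture:
            continue
        pair = tuple(sorted((sc.capture, sc.analyte)))
        calls.setdefault(pair, set()).add(sc.classification)

    graph = nx.Graph()
    graph.add_nodes_from(sorted(universe))
    conflicts, indeterminate = [], []
    for pair, verdicts in sorted(calls.items()):
        if SAME in verdicts:
            graph.add_edge(*pair)
            if DIFFERENT in verdicts:
                conflicts.append(pair)
        elif verdicts == {INDETERMINATE}:
            indeterminate.append(pair)

    components = sorted(nx.connected_components(graph), key=min)
    bins = {clone: i + 1 for i, comp in enumerate(components) for clone in sorted(comp)}
    return BinAssignment(
        bins=bins,
        graph=graph,
        scores=all_scores,
        conflicts=conflicts,
        indeterminate_pairs=indeterminate,
    )


def binning_report(assignment: BinAssignment) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percent-binding matrix (capture x analyte) plus a bin table.

    Matrix cells hold percent binding rounded to one decimal; cells for
    unassayed capture/analyte pairs are NaN.  Self cells are 0 by
    construction.
    """
    captures = sorted({sc.capture for sc in assignment.scores})
    analytes = sorted({sc.analyte for sc in assignment.scores})
    matrix = pd.DataFrame(index=captures, columns=analytes, dtype=float)
    for sc in assignment.scores:
        matrix.loc[sc.capture, sc.analyte] = round(sc.percent_binding, 1)
    bin_table = pd.DataFrame(
        [(clone, b) for clone, b in sorted(assignment.bins.items())],
        columns=["clone", "bin"],
    ).sort_values(["bin", "clone"], ignore_index=True)
    return matrix, bin_table
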