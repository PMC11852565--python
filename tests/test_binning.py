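"""Corrected-AUC competition statistic and graph bin inference."""

import numpy as np
import pandas as pd
import pytest

from nbpanel import synthetic
from nbpanel.binning import (
    CompetitionExperiment,
    Thresholds,
    binning_report,
    infer_bins,
    infer_bins_from_percent,
    score_competition,
)


def _experiments(epitope_map, affinities=None, noise=0.0, seed=0, **kwargs):
    if affinities is None:
        affinities = {c: 5e-9 for c in epitope_map}
    df, _ = synthetic.gen_competition(epitope_map, affinities, noise_sd=noise,
                                      seed=seed, **kwargs)
    return CompetitionExperiment.from_dataframe(df)


def _partitions(items):
    """All set partitions (exhaustive oracle for small clone sets)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


class TestScoring:
    def test_self_analyte_scores_exactly_zero(self, epitope_map, panel_affinities):
        for exp in _experiments(epitope_map, panel_affinities, noise=0.02, seed=1):
            by_analyte = {s.analyte: s for s in score_competition(exp)}
            self_score = by_analyte[exp.capture_clone]
            assert self_score.corrected_auc == 0.0
            assert self_score.percent_binding == 0.0
            assert self_score.classification == "same_epitope"

    def test_percent_invariant_under_uniform_absorbance_rescaling(self):
        emap = {"a": "e1", "b": "e2", "c": "e1"}
        df, _ = synthetic.gen_competition(emap, {c: 5e-9 for c in emap}, noise_sd=0.0, seed=0)
        scaled = df.assign(a450=df.a450 * 3.7, blank=df.blank * 3.7)
        s1 = score_competition(CompetitionExperiment.from_dataframe(df)[0])
        s2 = score_competition(CompetitionExperiment.from_dataframe(scaled)[0])
        for a, b in zip(s1, s2):
            assert b.percent_binding == pytest.approx(a.percent_binding, abs=1e-9)

    def test_no_blocking_leaves_scores_unusable(self):
        emap = {"a": "e1", "b": "e1"}
        exps = _experiments(emap, eps_block=1.0)
        scores = score_competition(exps[0])
        assert all(not s.usable for s in scores)

    def test_capture_must_be_among_analytes(self, dose_grid):
        from nbpanel.dose_response import DoseResponseCurve

        curve = DoseResponseCurve("b", "x", dose_grid, np.ones(len(dose_grid)))
        with pytest.raises(ValueError, match="capture"):
            CompetitionExperiment(capture_clone="a", analyte_curves={"b": curve})


class TestBinInference:
    def test_published_competition_pattern_gives_three_bins(self):
        """Encoding the reported capture-ELISA outcomes for the nine-binder
        panel (three captures) must yield {C1} | {F9, C7} | {E6 clade}."""
        analytes = ["C1", "C7", "D9", "E6", "F1", "F8", "F9", "G10", "G7"]
        low, high = 10.0, 80.0
        rows = {
            "E6": {"F1": low, "F8": low, "G10": low, "G7": low, "D9": low,
                   "C1": high, "F9": high, "C7": high, "E6": 0.0},
            "F9": {"F1": high, "F8": high, "G10": high, "G7": high, "D9": high,
                   "E6": high, "C7": 4.1, "C1": 90.6, "F9": 0.0},
            "C1": {a: (0.0 if a == "C1" else high) for a in analytes},
        }
        matrix = pd.DataFrame(rows).T[analytes]
        assignment = infer_bins_from_percent(matrix)
        members = sorted(map(sorted, assignment.members().values()))
        assert members == [["C1"], ["C7", "F9"], ["D9", "E6", "F1", "F8", "G10", "G7"]]
        assert assignment.n_bins == 3
        assert not assignment.conflicts

    def test_all_different_gives_singletons(self):
        emap = {"a": "e1", "b": "e2", "c": "e3"}
        assignment = infer_bins(_experiments(emap))
        assert assignment.n_bins == 3
        assert all(len(m) == 1 for m in assignment.members().values())

    def test_exhaustive_small_epitope_maps_recovered_noiselessly(self):
        """Every partition of 3 and 4 clones, complete capture coverage,
        noise 0: inferred bins must equal the planted partition."""
        for clones in (["a", "b", "c"], ["a", "b", "c", "d"]):
            for partition in _partitions(clones):
                emap = {c: f"e{i}" for i, grp in enumerate(partition) for c in grp}
                assignment = infer_bins(_experiments(emap))
                got = sorted(map(sorted, assignment.members().values()))
                assert got == sorted(map(sorted, partition)), emap

    def test_conflicting_calls_keep_edge_and_flag(self):
        matrix = pd.DataFrame(
            {"a": [0.0, 80.0], "b": [10.0, 0.0]},
            index=["a", "b"],
        )
        assignment = infer_bins_from_percent(matrix)
        assert assignment.bins["a"] == assignment.bins["b"]
        assert assignment.conflicts == [("a", "b")]

    def test_transitivity_flags_unassayed_intra_bin_pairs(self):
        # a-b same, b-c same, a-c never assayed -> one bin, pair (a,c) inferred
        matrix = pd.DataFrame(
            {"a": [0.0, 10.0, np.nan], "b": [10.0, 0.0, 10.0], "c": [np.nan, 10.0, 0.0]},
            index=["a", "b", "c"],
        )
        assignment = infer_bins_from_percent(matrix)
        assert assignment.n_bins == 1
        assert ("a", "c") in assignment.inferred_by_transitivity

    def test_indeterminate_zone_makes_no_edge(self):
        matrix = pd.DataFrame({"a": [0.0, 40.0], "b": [40.0, 0.0]}, index=["a", "b"])
        assignment = infer_bins_from_percent(matrix)
        assert assignment.n_bins == 2
        assert assignment.indeterminate_pairs == [("a", "b")]

    def test_thresholds_validated(self):
        with pytest.raises(ValueError):
            Thresholds(same_max=70.0, diff_min=60.0)


class TestReport:
    def test_matrix_shape_and_self_cells(self, epitope_map, panel_affinities):
        exps = _experiments(epitope_map, panel_affinities, noise=0.01, seed=2)
        assignment = infer_bins(exps)
        matrix, bins = binning_report(assignment)
        assert matrix.shape == (9, 9)
        for clone in matrix.index:
            assert matrix.loc[clone, clone] == 0.0
        assert set(bins.columns) == {"clone", "bin"}
        assert len(bins) == 9

    def test_monotone_in_generator_occupancy(self):
        """Raising an analyte's affinity (occupancy at every dose) must not
        lower its percent binding on noiseless plates."""
        emap = {"a": "e1", "b": "e2"}
        pcts = []
        for ec50 in (50e-9, 5e-9):  # weaker then stronger analyte b
            df, _ = synthetic.gen_competition(emap, {"a": 5e-9, "b": ec50},
                                              capture_set=["a"], noise_sd=0.0, seed=0)
            exp = CompetitionExperiment.from_dataframe(df)[0]
            pct = {s.analyte: s.percent_binding for s in score_competition(exp)}
            pcts.append(pct["b"])
        assert pcts[1] >= pcts[0]
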