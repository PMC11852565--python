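"""Synthetic data generators with recorded ground truth.

Every input the analysis pipeline consumes can be generated here —
somatically mutated VHH repertoires from known germlines, 4PL-shaped
ELISA plates, sandwich-ELISA competition plates driven by a planted
epitope map, Gaussian mass-photometry event lists, and first-order
cleavage gels — so that each downstream stage can be tested against known
truth without any external data.  All generators are deterministic given
(config, seed).

The module-level ``panel_*`` helpers reproduce the layout of the
anti-SpCas9 campaign this package was built around: nine binders in three
epitope bins, a nanomolar EC50 ladder, a twelve-point three-fold dilution
series, and the 160/180/190/209 kDa stepwise mass-photometry peak set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .dose_response import DEFAULT_NANOBODY_KDA, four_pl, to_molar
from .germlines import GermlineSet, RegionAnchors
from .cleavage import GelLane
from .reference_panel import EPITOPE_BINS, MP_PEAKS_KDA, PANEL_EC50_NM, selected_clone_census
from .repertoire import NanobodyRecord

__all__ = [
    "SyntheticTruth",
    "example_germline_set",
    "gen_repertoire",
    "gen_dose_response",
    "gen_competition",
    "gen_mp_events",
    "gen_mp_titration",
    "gen_gel",
    "panel_epitope_map",
    "panel_dose_grid",
    "panel_affinities_molar",
]

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


@dataclass
class SyntheticTruth:
    """Ground-truth bundle emitted by every generator."""

    seed: int
    kind: str
    data: dict[str, Any] = field(default_factory=dict)

    def to_json(self, path) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o).__name__)

        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "kind": self.kind, "data": self.data}, fh,
                      indent=1, default=default)


# ---------------------------------------------------------------------------
# germline reference
# ---------------------------------------------------------------------------

def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """Random stop-free in-frame nucleotide sequence."""
    codons = []
    while len(codons) < n_codons:
        codon = "".join(rng.choice(list(_BASES), 3))
        if codon not in _STOP_CODONS:
            codons.append(codon)
    return "".join(codons)


def example_germline_set(seed: int = 20240) -> GermlineSet:
    """A synthetic 5V / 5D / 3J reference emulating a constrained VHH locus.

    Gene names follow the camelid heavy-chain nomenclature of the
    campaign's reported gene usage; the sequences themselves are random
    stop-free open reading frames (this is a synthetic stand-in for a
    curated germline database, which is a user-supplied input).  V genes
    are 98 codons with CDR1 = [26, 34), CDR2 = [50, 58) and CDR3 starting
    at 96; J genes encode a short CDR3 tail followed by the W-G-Q-G
    framework-4 motif.
    """
    rng = np.random.default_rng(seed)
    v_names = ["IGHV3S66", "IGHV3S53", "IGHV3S65", "IGHV3S1", "IGHV3S61"]
    base_v = _random_orf(rng, 98)
    v_genes, v_anchors = {}, {}
    for name in v_names:
        nt = list(base_v)
        # diversify each V away from the shared scaffold at ~10% of codons
        for codon_idx in rng.choice(98, size=10, replace=False):
            pos = 3 * int(codon_idx) + int(rng.integers(3))
            for _ in range(10):
                alt = rng.choice([b for b in _BASES if b != nt[pos]])
                trial = nt.copy()
                trial[pos] = alt
                codon = "".join(trial[3 * int(codon_idx): 3 * int(codon_idx) + 3])
                if codon not in _STOP_CODONS:
                    nt = trial
                    break
        v_genes[name] = "".join(nt)
        v_anchors[name] = RegionAnchors(cdr1=(26, 34), cdr2=(50, 58), cdr3=(96, 98))

    d_genes = {name: _random_orf(rng, 5) for name in ["IGHD1", "IGHD2", "IGHD3", "IGHD5", "IGHD6"]}

    j_tail_aa = {"IGHJ4": "VDY", "IGHJ6": "MDL", "IGHJ7": "ADF"}
    fr4_aa = "WGQGTQVTVSS"
    codon_for = {
        "A": "GCT", "D": "GAT", "F": "TTT", "G": "GGT", "L": "CTG", "M": "ATG",
        "Q": "CAG", "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
    }
    j_genes, j_fr4 = {}, {}
    for name, tail in j_tail_aa.items():
        j_genes[name] = "".join(codon_for[a] for a in tail + fr4_aa)
        j_fr4[name] = len(tail)

    return GermlineSet(v_genes=v_genes, d_genes=d_genes, j_genes=j_genes,
                       v_anchors=v_anchors, j_fr4_start=j_fr4)


# ---------------------------------------------------------------------------
# repertoire
# ---------------------------------------------------------------------------

def _mutate_v(
    rng: np.random.Generator,
    v_nt: str,
    n_mut: int,
    silent_fraction: float,
) -> tuple[str, list[int]]:
    """Plant ``n_mut`` point substitutions, stop-free, at distinct positions."""
    nt = list(v_nt)
    positions = sorted(int(p) for p in rng.choice(len(nt), size=n_mut, replace=False))
    for pos in positions:
        codon_start = 3 * (pos // 3)
        want_silent = rng.random() < silent_fraction
        ref_aa = str(Seq(v_nt[codon_start:codon_start + 3]).translate())
        candidates = []
        for alt in _BASES:
            if alt == nt[pos]:
                continue
            trial = nt[codon_start:codon_start + 3].copy()
            trial[pos - codon_start] = alt
            codon = "".join(trial)
            if codon in _STOP_CODONS:
                continue
            silent = str(Seq(codon).translate()) == ref_aa
            candidates.append((alt, silent))
        preferred = [a for a, s in candidates if s == want_silent] or [a for a, _ in candidates]
        nt[pos] = preferred[int(rng.integers(len(preferred)))]
    return "".join(nt), positions


def gen_repertoire(
    germline_set: GermlineSet,
    n: int,
    mutation_rate: float = 0.05,
    silent_fraction: float = 0.3,
    seed: int = 0,
    *,
    planted_counts: list[int] | None = None,
    v_weights: dict[str, float] | None = None,
    d_probability: float = 0.6,
    clone_ids: list[str] | None = None,
) -> tuple[list[NanobodyRecord], SyntheticTruth]:
    """Generate clones as V(+D)+J concatenations with planted substitutions.

    Mutations are substitution-only (keeps the mutation-count oracle
    exact) and restricted to the V segment, matching how the census is
    counted.  ``planted_counts`` overrides the binomial draw with an exact
    per-clone mutation count.  Truth records, per clone, the source genes,
    the mutated positions, and the realized nucleotide/amino-acid change
    counts from direct position-wise comparison with the source germline.
    """
    if not 0.0 <= mutation_rate <= 0.2:
        raise ValueError("mutation_rate must lie in [0, 0.2]")
    rng = np.random.default_rng(seed)
    v_names = sorted(germline_set.v_genes)
    if v_weights is None:
        probs = np.full(len(v_names), 1.0 / len(v_names))
    else:
        probs = np.array([v_weights.get(v, 0.0) for v in v_names], dtype=float)
        probs = probs / probs.sum()
    j_names = sorted(germline_set.j_genes)
    d_names = sorted(germline_set.d_genes)

    records, truth_clones = [], {}
    for i in range(n):
        cid = clone_ids[i] if clone_ids else f"SYN{i + 1:03d}"
        v = v_names[int(rng.choice(len(v_names), p=probs))]
        j = j_names[int(rng.integers(len(j_names)))] if j_names else None
        use_d = bool(d_names) and rng.random() < d_probability
        d = d_names[int(rng.integers(len(d_names)))] if use_d else None

        v_nt = germline_set.v_genes[v]
        n_mut = planted_counts[i] if planted_counts else int(rng.binomial(len(v_nt), mutation_rate))
        mut_v, positions = _mutate_v(rng, v_nt, n_mut, silent_fraction)
        nt = mut_v + (germline_set.d_genes[d] if d else "") + (germline_set.j_genes[j] if j else "")

        germ_aa = str(Seq(v_nt).translate())
        mut_aa = str(Seq(mut_v).translate())
        n_aa_changes = sum(a != b for a, b in zip(germ_aa, mut_aa))

        records.append(NanobodyRecord.from_nt(cid, nt))
        truth_clones[cid] = {
            "v_gene": v, "d_gene": d, "j_gene": j,
            "mutated_positions": positions,
            "n_nt_mutations": n_mut,
            "n_aa_changes": n_aa_changes,
        }
    truth = SyntheticTruth(seed=seed, kind="repertoire", data={"clones": truth_clones})
    return records, truth


# ---------------------------------------------------------------------------
# ELISA plates
# ---------------------------------------------------------------------------

def panel_dose_grid() -> np.ndarray:
    """Twelve-point three-fold dilution series, ~80 ug/mL down, in molar."""
    top = to_molar(80.0, "ug/mL", DEFAULT_NANOBODY_KDA)
    return top / 3.0 ** np.arange(12)[::-1]


def panel_affinities_molar() -> dict[str, float]:
    """The nine-binder EC50 ladder (nM -> molar)."""
    return {c: v * 1e-9 for c, v in PANEL_EC50_NM.items()}


def panel_epitope_map() -> dict[str, str]:
    """Clone -> epitope label for the nine-binder, three-epitope layout."""
    return {clone: label for label, clones in EPITOPE_BINS.items() for clone in clones}


def gen_dose_response(
    params: dict[tuple[str, str], tuple[float, float, float, float]],
    dose_grid: np.ndarray,
    noise_sd: float = 0.02,
    replicates: int = 1,
    seed: int = 0,
    *,
    blank: float = 0.05,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Long-format direct-ELISA plate from planted 4PL parameters.

    ``params`` maps (clone_id, antigen_id) to (bottom, top, ec50_molar,
    hill) of the blank-subtracted response.  Absorbances get additive
    Gaussian noise and are floored at zero.
    """
    rng = np.random.default_rng(seed)
    dose_grid = np.asarray(dose_grid, dtype=float)
    rows = []
    for (clone, antigen), (bottom, top, ec50, hill) in params.items():
        for rep in range(replicates):
            signal = four_pl(dose_grid, bottom, top, ec50, hill)
            a450 = np.maximum(signal + blank + rng.normal(0.0, noise_sd, len(dose_grid)), 0.0)
            for conc, y in zip(dose_grid, a450):
                rows.append((clone, antigen, rep, conc, "M", y, blank))
    df = pd.DataFrame(rows, columns=["clone_id", "antigen_id", "replicate",
                                     "concentration", "conc_unit", "a450", "blank"])
    truth = SyntheticTruth(seed=seed, kind="dose_response", data={
        "params": {f"{c}|{a}": list(p) for (c, a), p in params.items()},
        "noise_sd": noise_sd, "blank": blank,
    })
    return df, truth


def gen_competition(
    epitope_map: dict[str, str],
    affinities: dict[str, float],
    capture_set: list[str] | None = None,
    dose_grid: np.ndarray | None = None,
    noise_sd: float = 0.02,
    seed: int = 0,
    *,
    eps_block: float = 0.05,
    top_signal: float = 1.8,
    blank: float = 0.05,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Sandwich-ELISA competition plates from a planted epitope map.

    Occupancy of a biotinylated analyte follows its own 4PL (hill 1);
    when the analyte shares the capture clone's epitope the accessible
    signal is scaled by ``eps_block`` (epitope already occupied by the
    capture clone; ``eps_block`` < 0.25 for a realistic blockade, 1 means
    no blocking at all).  Truth is the epitope map itself.
    """
    if not (0.0 <= eps_block < 0.25 or eps_block == 1.0):
        raise ValueError("eps_block must lie in [0, 0.25) (or exactly 1 to disable blocking)")
    rng = np.random.default_rng(seed)
    if capture_set is None:
        capture_set = sorted(epitope_map)
    if dose_grid is None:
        dose_grid = panel_dose_grid()
    rows = []
    for capture in capture_set:
        for analyte in sorted(epitope_map):
            occ = four_pl(dose_grid, 0.0, 1.0, affinities[analyte], 1.0)
            scale = eps_block if epitope_map[analyte] == epitope_map[capture] else 1.0
            a450 = np.maximum(
                top_signal * occ * scale + blank + rng.normal(0.0, noise_sd, len(dose_grid)), 0.0
            )
            for conc, y in zip(dose_grid, a450):
                rows.append((capture, analyte, conc, "M", y, blank))
    df = pd.DataFrame(rows, columns=["capture_clone", "analyte_clone",
                                     "concentration", "conc_unit", "a450", "blank"])
    truth = SyntheticTruth(seed=seed, kind="competition", data={
        "epitope_map": dict(epitope_map), "eps_block": eps_block, "noise_sd": noise_sd,
    })
    return df, truth


# ---------------------------------------------------------------------------
# mass photometry and gels
# ---------------------------------------------------------------------------

def gen_mp_events(
    components: list[float] | None = None,
    weights: list[float] | None = None,
    sd: float | list[float] = 12.0,
    n: int = 10_000,
    seed: int = 0,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Draw landing-event masses from a Gaussian mixture.

    Defaults reproduce the campaign's four-peak stepwise-binding pattern
    (160/180/190/209 kDa) at equal weights.
    """
    if components is None:
        components = list(MP_PEAKS_KDA)
    if weights is None:
        weights = [1.0 / len(components)] * len(components)
    weights = np.asarray(weights, dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    sds = np.broadcast_to(np.asarray(sd, dtype=float), (len(components),))
    rng = np.random.default_rng(seed)
    which = rng.choice(len(components), size=n, p=weights)
    events = rng.normal(np.asarray(components)[which], sds[which])
    truth = SyntheticTruth(seed=seed, kind="mp_events", data={
        "means": list(components), "sds": sds.tolist(), "weights": weights.tolist(), "n": n,
    })
    return events, truth


def gen_mp_titration(
    antigen_mass: float = 160.0,
    nanobody_masses: dict[str, float] | None = None,
    sd: float = 12.0,
    n_per_step: int = 10_000,
    carryover: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, np.ndarray]], SyntheticTruth]:
    """One event set per incubation step of a stepwise-binding series.

    Step 0 is the bare antigen; step i adds the i-th nanobody, shifting
    the dominant complex mass by that nanobody's mass.  ``carryover`` is
    the fraction of events left at the previous step's mass (incomplete
    complexation; 0 with excess nanobody).  Defaults mirror the reported
    SpCas9 series: 160 then +C1/+D9/+F9 to 180/190/209 kDa.
    """
    if nanobody_masses is None:
        nanobody_masses = {"C1": 20.0, "D9": 10.0, "F9": 19.0}
    if not 0.0 <= carryover < 0.5:
        raise ValueError("carryover must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    labels, masses = ["antigen"], [antigen_mass]
    for name, m in nanobody_masses.items():
        labels.append(labels[-1] + f"+{name}")
        masses.append(masses[-1] + m)
    series = []
    for i, (label, mass) in enumerate(zip(labels, masses)):
        means = [mass] if i == 0 or carryover == 0.0 else [masses[i - 1], mass]
        weights = [1.0] if len(means) == 1 else [carryover, 1.0 - carryover]
        which = rng.choice(len(means), size=n_per_step, p=weights)
        events = rng.normal(np.asarray(means)[which], sd)
        series.append((label, events))
    truth = SyntheticTruth(seed=seed, kind="mp_titration", data={
        "labels": labels, "masses": masses, "sd": sd,
        "carryover": carryover, "n_per_step": n_per_step,
        "nanobody_masses": dict(nanobody_masses), "antigen_mass": antigen_mass,
    })
    return series, truth


def gen_gel(
    k_per_condition: dict[str, float],
    times: list[float] = (1.0, 5.0, 10.0, 60.0),
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
    *,
    total_intensity: float = 1000.0,
    product_split: tuple[float, ...] = (0.6, 0.4),
) -> tuple[list[GelLane], SyntheticTruth]:
    """Gel lanes from first-order cleavage, fraction cut = 1 - exp(-k t).

    Band intensities get multiplicative Gaussian noise (densitometry
    error scales with band size); a once-cut linear substrate yields two
    product bands split ``product_split``.
    """
    rng = np.random.default_rng(seed)
    lanes = []
    for condition, k in k_per_condition.items():
        if k < 0:
            raise ValueError("rate constants must be non-negative")
        for rep in range(replicates):
            for t in times:
                frac = 1.0 - np.exp(-k * t) if np.isfinite(k) else 1.0
                uncut = total_intensity * (1.0 - frac)
                bands = [uncut] + [total_intensity * frac * s for s in product_split]
                noisy = [max(b * (1.0 + rng.normal(0.0, noise_sd)), 0.0) for b in bands]
                lanes.append(GelLane(condition=condition, time_min=float(t),
                                     uncut=noisy[0], products=tuple(noisy[1:]), replicate=rep))
    truth = SyntheticTruth(seed=seed, kind="gel", data={
        "k": dict(k_per_condition), "times": list(times), "noise_sd": noise_sd,
    })
    return lanes, truth
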