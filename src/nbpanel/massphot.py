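"""Mass-photometry analysis: calibration, mixture fitting, complex calls.

Single-molecule landing events give one calibrated mass (or raw
interferometric contrast) each; populations of species appear as roughly
Gaussian peaks.  This module

* fits the linear contrast-to-mass calibration from protein standards,
* deconvolves an event list into Gaussian components (EM via
  scikit-learn, quantile-spaced initial means, BIC model selection with a
  minimum component weight),
* tests whether fitted peak masses are explained by an antigen plus a
  subset of candidate nanobodies bound simultaneously — the stepwise
  10-20 kDa mass-shift logic used to confirm non-overlapping epitopes.

Events below a noise floor (default 40 kDa) are discarded before fitting:
free 12-14 kDa nanobodies sit below the detection limit of the technique.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import linregress
from sklearn.mixture import GaussianMixture

__all__ = [
    "CalibrationFit",
    "calibrate",
    "GaussianComponent",
    "MassMixtureModel",
    "MassMixtureResults",
    "fit_components",
    "ComplexAssignment",
    "assign_complexes",
    "stepwise_shift_report",
]


@dataclass(frozen=True)
class CalibrationFit:
    """Linear contrast -> mass (kDa) map from protein standards."""

    slope: float
    intercept: float
    r_squared: float
    n_standards: int

    def to_mass(self, contrast) -> np.ndarray:
        return self.slope * np.asarray(contrast, dtype=float) + self.intercept


def calibrate(contrast_values, standard_masses) -> CalibrationFit:
    """Least-squares line through (contrast, known mass) standard pairs."""
    c = np.asarray(contrast_values, dtype=float)
    m = np.asarray(standard_masses, dtype=float)
    if c.shape != m.shape or len(c) < 2:
        raise ValueError("calibration needs >= 2 (contrast, mass) pairs")
    res = linregress(c, m)
    if res.slope <= 0:
        raise ValueError("calibration slope must be positive")
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_standards=len(c),
    )


@dataclass(frozen=True)
class GaussianComponent:
    mean: float  # kDa
    sd: float
    weight: float
    n_events: int


@dataclass
class MassMixtureResults:
    """Gaussian mixture fit of a landing-event mass distribution."""

    model: "MassMixtureModel"
    components: list[GaussianComponent]
    bic: float
    n_events: int

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.components])

    @property
    def dominant(self) -> GaussianComponent:
        """The highest-weight component (the acquisition's main species)."""
        return max(self.components, key=lambda c: c.weight)

    def summary(self) -> str:
        lines = [
            "Mass-photometry Gaussian mixture",
            "=" * 44,
            f"events (after {self.model.mass_floor:g} kDa floor): {self.n_events}",
            f"components: {self.k}   BIC: {self.bic:.1f}",
            "-" * 44,
            f"{'mean kDa':>10s} {'sd':>8s} {'weight':>8s} {'events':>8s}",
        ]
        for c in self.components:
            lines.append(f"{c.mean:10.1f} {c.sd:8.1f} {c.weight:8.3f} {c.n_events:8d}")
        return "\n".join(lines)


class MassMixtureModel:
    """Gaussian mixture over event masses with BIC order selection.

    For each candidate component count k = 1..``max_components`` an EM fit
    is started from quantile-spaced means (deterministic given ``seed``);
    the best BIC wins.  Fits with any component weight below
    ``min_weight`` or sd below ``sd_floor`` are rejected and the order is
    reduced, so spurious slivers cannot be selected.

    Populations separated by less than roughly 1.5 peak widths are not
    resolvable by mixture likelihood at realistic event counts and merge
    into one component; analyze titration steps as separate acquisitions
    (one event set per incubation) rather than pooling them.
    """

    def __init__(
        self,
        events,
        *,
        mass_floor: float = 40.0,
        min_weight: float = 0.05,
        sd_floor: float = 1.0,
        seed: int = 0,
    ) -> None:
        events = np.asarray(events, dtype=float)
        if events.ndim != 1:
            raise ValueError("events must be a 1-D mass array (kDa)")
        events = events[events >= mass_floor]
        if len(events) < 100:
            raise ValueError(f"need >= 100 events above the mass floor, got {len(events)}")
        self.events = np.sort(events)
        self.mass_floor = mass_floor
        self.min_weight = min_weight
        self.sd_floor = sd_floor
        self.seed = seed

    def _fit_k(self, k: int) -> tuple[GaussianMixture, float] | None:
        x = self.events[:, None]
        means_init = np.quantile(self.events, (np.arange(k) + 0.5) / k)[:, None]
        gm = GaussianMixture(
            n_components=k,
            covariance_type="diag",
            means_init=means_init,
            random_state=self.seed,
            n_init=1,
            max_iter=500,
            reg_covar=1e-3,
        ).fit(x)
        sds = np.sqrt(gm.covariances_.ravel())
        if np.any(gm.weights_ < self.min_weight) or np.any(sds < self.sd_floor):
            return None
        return gm, float(gm.bic(x))

    def fit(self, max_components: int = 6) -> MassMixtureResults:
        best: tuple[float, GaussianMixture] | None = None
        for k in range(1, max_components + 1):
            fitted = self._fit_k(k)
            if fitted is None:
                continue
            gm, bic = fitted
            if best is None or bic < best[0]:
                best = (bic, gm)
        if best is None:  # degenerate data: fall back to a single component
            gm = GaussianMixture(1, covariance_type="diag", random_state=self.seed).fit(
                self.events[:, None]
            )
            best = (float(gm.bic(self.events[:, None])), gm)
        bic, gm = best
        labels = gm.predict(self.events[:, None])
        order = np.argsort(gm.means_.ravel())
        components = []
        for idx in order:
            components.append(
                GaussianComponent(
                    mean=float(gm.means_.ravel()[idx]),
                    sd=float(np.sqrt(gm.covariances_.ravel()[idx])),
                    weight=float(gm.weights_[idx]),
                    n_events=int(np.sum(labels == idx)),
                )
            )
        return MassMixtureResults(model=self, components=components, bic=bic, n_events=len(self.events))


def fit_components(events, max_k: int = 6, **kwargs) -> list[GaussianComponent]:
    """Convenience wrapper returning just the fitted components."""
    return MassMixtureModel(events, **kwargs).fit(max_components=max_k).components


@dataclass(frozen=True)
class ComplexAssignment:
    """Best stoichiometry hypothesis for one fitted peak."""

    peak_mass: float
    bound_nanobodies: tuple[str, ...]
    expected_mass: float
    delta: float  # observed - expected, kDa
    within_tolerance: bool


def assign_complexes(
    components: list[GaussianComponent] | list[float],
    antigen_mass: float,
    nanobody_masses: dict[str, float],
    tolerance: float = 8.0,
) -> list[ComplexAssignment]:
    """Assign each fitted peak the nanobody subset best explaining its mass.

    Every subset of the candidate nanobodies (including the empty set =
    bare antigen) is scored by |antigen + sum(subset) - peak|; the
    minimizer wins, ties preferring fewer bound nanobodies then
    lexicographic order, so the result is independent of input ordering.
    Peaks farther than ``tolerance`` from every hypothesis are reported
    unassigned (empty subset, ``within_tolerance=False``).
    """
    if antigen_mass <= 0 or any(m <= 0 for m in nanobody_masses.values()):
        raise ValueError("masses must be positive")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    peaks = [c.mean if isinstance(c, GaussianComponent) else float(c) for c in components]
    names = sorted(nanobody_masses)
    hypotheses = []
    for r in range(len(names) + 1):
        for subset in combinations(names, r):
            hypotheses.append((subset, antigen_mass + sum(nanobody_masses[n] for n in subset)))
    out = []
    for peak in peaks:
        subset, expected = min(hypotheses, key=lambda h: (abs(peak - h[1]), len(h[0]), h[0]))
        delta = peak - expected
        out.append(
            ComplexAssignment(
                peak_mass=peak,
                bound_nanobodies=subset,
                expected_mass=expected,
                delta=float(delta),
                within_tolerance=abs(delta) <= tolerance,
            )
        )
    return out


def stepwise_shift_report(
    peaks: list[float],
    *,
    window: tuple[float, float] = (10.0, 20.0),
) -> list[dict[str, float | bool]]:
    """Per-addition mass shifts between successively larger peaks.

    Titration series that add one nanobody at a time should step the
    complex mass by roughly one nanobody (the ``window``, default
    10-20 kDa, matches tag-inclusive VHH masses).
    """
    peaks = sorted(peaks)
    lo, hi = window
    return [
        {"from": a, "to": b, "delta": b - a, "in_window": lo <= b - a <= hi}
        for a, b in zip(peaks, peaks[1:])
    ]
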