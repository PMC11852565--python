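"""Four-parameter logistic (4PL) dose-response analysis for plate ELISAs.

The signal model on a dilution series is

    A450(x) = bottom + (top - bottom) / (1 + (ec50 / x)^hill)

with ``x`` the analyte concentration.  Fitting is ordinary least squares on
the log10-dose axis via ``scipy.optimize.least_squares`` with a fixed,
data-driven initialization, so results are deterministic.  The module also
computes the log-dose trapezoid AUC that feeds the epitope-binning
statistic, compares apo-antigen vs RNP affinities, and calls
cross-reactivity against off-target antigens.

Concentrations are stored in molar units internally; mass-per-volume
inputs are converted with a per-clone molecular mass (default 14 kDa, a
typical tagged VHH).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseCurve",
    "FourPLModel",
    "FourPLResults",
    "fit_4pl",
    "auc",
    "compare_apo_vs_rnp",
    "cross_reactivity",
]

DEFAULT_NANOBODY_KDA = 14.0

_MOLAR_PER_UNIT = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}


def to_molar(values, unit: str, molecular_mass_kda: float = DEFAULT_NANOBODY_KDA):
    """Convert a concentration array to molar.

    Mass/volume units (``ug/mL``, ``ng/uL``, ``ng/mL``, ``pg/uL``) use the
    molecular mass; molar units pass through.
    """
    values = np.asarray(values, dtype=float)
    if unit in _MOLAR_PER_UNIT:
        return values * _MOLAR_PER_UNIT[unit]
    grams_per_liter = {"ug/mL": 1e-3, "ng/uL": 1e-3, "ng/mL": 1e-6, "pg/uL": 1e-6}
    if unit not in grams_per_liter:
        raise ValueError(f"unknown concentration unit {unit!r}")
    return values * grams_per_liter[unit] / (molecular_mass_kda * 1e3)


@dataclass
class DoseResponseCurve:
    """One clone/antigen dilution series with per-plate blank.

    ``concentration`` is molar; ``replicate`` groups repeated series for
    per-replicate AUC averaging (fits pool all points).
    """

    clone_id: str
    antigen_id: str
    concentration: np.ndarray
    a450: np.ndarray
    blank: float = 0.0
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.a450 = np.asarray(self.a450, dtype=float)
        if self.concentration.shape != self.a450.shape:
            raise ValueError("concentration and a450 must have equal length")
        if np.any(self.concentration <= 0):
            raise ValueError("concentrations must be strictly positive")
        if self.replicate is None:
            self.replicate = np.zeros(len(self.a450), dtype=int)
        else:
            self.replicate = np.asarray(self.replicate, dtype=int)
        for rep in np.unique(self.replicate):
            c = np.sort(self.concentration[self.replicate == rep])
            if np.any(np.diff(c) <= 0):
                raise ValueError(f"replicate {rep}: concentrations must be distinct")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        *,
        molecular_mass_kda: float = DEFAULT_NANOBODY_KDA,
    ) -> "DoseResponseCurve":
        """Build from long-format plate rows.

        Expected columns: ``clone_id, antigen_id, concentration, conc_unit,
        a450, blank`` and optionally ``replicate``.  The frame must contain
        a single (clone, antigen) pair.
        """
        clones = df["clone_id"].unique()
        antigens = df["antigen_id"].unique()
        if len(clones) != 1 or len(antigens) != 1:
            raise ValueError("frame must hold exactly one clone/antigen pair")
        units = df["conc_unit"].unique()
        if len(units) != 1:
            raise ValueError("mixed concentration units in one curve")
        return cls(
            clone_id=str(clones[0]),
            antigen_id=str(antigens[0]),
            concentration=to_molar(df["concentration"].to_numpy(), str(units[0]), molecular_mass_kda),
            a450=df["a450"].to_numpy(dtype=float),
            blank=float(df["blank"].iloc[0]) if "blank" in df else 0.0,
            replicate=df["replicate"].to_numpy(dtype=int) if "replicate" in df else None,
        )

    @property
    def n_distinct_concentrations(self) -> int:
        return len(np.unique(self.concentration))

    def net_signal(self) -> np.ndarray:
        return self.a450 - self.blank


def four_pl(x, bottom, top, ec50, hill):
    """The 4PL response function."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / x) ** hill)


@dataclass
class FourPLResults:
    """Fitted 4PL parameters with diagnostics.

    ``flags`` may contain ``no_response`` (flat series, parameters are
    placeholders), ``not_converged`` and ``extrapolated_ec50`` (EC50 more
    than a decade outside the dosed range).
    """

    model: "FourPLModel"
    bottom: float
    top: float
    ec50: float
    hill: float
    converged: bool
    residual_sse: float
    flags: tuple[str, ...] = ()
    bse: dict[str, float] = field(default_factory=dict)

    @property
    def ec50_nm(self) -> float:
        return self.ec50 * 1e9

    @property
    def params(self) -> dict[str, float]:
        return {"bottom": self.bottom, "top": self.top, "ec50": self.ec50, "hill": self.hill}

    def predict(self, x) -> np.ndarray:
        return four_pl(x, self.bottom, self.top, self.ec50, self.hill)

    def summary(self) -> str:
        c = self.model.curve
        lines = [
            "Four-parameter logistic fit",
            "=" * 45,
            f"clone / antigen : {c.clone_id} / {c.antigen_id}",
            f"n points        : {len(c.a450)}  ({c.n_distinct_concentrations} doses)",
            f"converged       : {self.converged}   flags: {', '.join(self.flags) or '-'}",
            "-" * 45,
        ]
        for name, val in self.params.items():
            shown = f"{self.ec50_nm:.3g} nM" if name == "ec50" else f"{val:.4g}"
            se = self.bse.get(name)
            lines.append(f"{name:>8s} : {shown:<14s}" + (f"(se {se:.3g})" if se is not None else ""))
        lines.append(f"residual SSE    : {self.residual_sse:.4g}")
        return "\n".join(lines)


class FourPLModel:
    """Least-squares 4PL model for one dose-response curve.

    Parameters
    ----------
    curve : DoseResponseCurve
    min_response : float
        Blank-subtracted signal span below which the series is declared
        flat ("no response") instead of being fitted, default 0.02 AU.
    """

    def __init__(self, curve: DoseResponseCurve, *, min_response: float = 0.02) -> None:
        if curve.n_distinct_concentrations < 4:
            raise ValueError("4PL fit needs >= 4 distinct concentrations")
        if not np.all(np.isfinite(curve.a450)):
            raise ValueError("non-finite absorbance values")
        self.curve = curve
        self.min_response = min_response

    def _initial_params(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        bottom, top = float(np.min(y)), float(np.max(y))
        half = 0.5 * (bottom + top)
        ec50 = float(x[np.argmin(np.abs(y - half))])
        return np.array([bottom, top, np.log10(ec50), 1.0])

    def fit(self) -> FourPLResults:
        x = self.curve.concentration
        y = self.curve.net_signal()
        span = float(np.max(y) - np.min(y))
        if span < self.min_response:
            return FourPLResults(
                model=self,
                bottom=float(np.mean(y)),
                top=float(np.mean(y)),
                ec50=float(np.median(x)),
                hill=0.0,
                converged=False,
                residual_sse=float(np.sum((y - np.mean(y)) ** 2)),
                flags=("no_response",),
            )

        def residuals(theta):
            bottom, top, log_ec50, hill = theta
            return four_pl(x, bottom, top, 10.0**log_ec50, hill) - y

        res = least_squares(residuals, self._initial_params(x, y), method="lm", max_nfev=20000)
        bottom, top, log_ec50, hill = res.x
        if hill < 0:  # equivalent curve with swapped asymptotes; canonicalize
            bottom, top, hill = top, bottom, -hill
        if top < bottom:
            bottom, top = top, bottom
        ec50 = float(10.0**log_ec50)
        sse = float(np.sum(res.fun**2))

        flags: list[str] = []
        if not res.success:
            flags.append("not_converged")
        if not (np.min(x) / 10.0 <= ec50 <= np.max(x) * 10.0):
            flags.append("extrapolated_ec50")

        bse: dict[str, float] = {}
        dof = len(y) - 4
        if dof > 0:
            try:
                jtj_inv = np.linalg.inv(res.jac.T @ res.jac)
                se = np.sqrt(np.maximum(np.diag(jtj_inv) * sse / dof, 0.0))
                bse = dict(zip(("bottom", "top", "ec50", "hill"), se))
                # delta method: se on log10(ec50) -> se on ec50
                bse["ec50"] = bse["ec50"] * np.log(10.0) * ec50
            except np.linalg.LinAlgError:
                pass

        return FourPLResults(
            model=self,
            bottom=float(bottom),
            top=float(top),
            ec50=ec50,
            hill=float(hill),
            converged=res.success,
            residual_sse=sse,
            flags=tuple(flags),
            bse=bse,
        )


def fit_4pl(curve: DoseResponseCurve, **kwargs) -> FourPLResults:
    """Convenience wrapper: ``FourPLModel(curve).fit()``."""
    return FourPLModel(curve, **kwargs).fit()


def auc(curve: DoseResponseCurve) -> float:
    """Trapezoid area under blank-subtracted A450 over log10 concentration.

    Negative blank-subtracted values are clamped to zero before
    integration (the area feeds a ratio statistic and must be
    non-negative).  With replicates, the per-replicate areas are averaged.
    """
    areas = []
    for rep in np.unique(curve.replicate):
        mask = curve.replicate == rep
        x = curve.concentration[mask]
        y = np.maximum(curve.net_signal()[mask], 0.0)
        order = np.argsort(x)
        x, y = x[order], y[order]
        if len(x) < 2:
            raise ValueError("AUC needs at least two points per replicate")
        areas.append(float(np.trapezoid(y, np.log10(x))))
    return float(np.mean(areas))


@dataclass(frozen=True)
class AffinityComparison:
    fold_difference: float
    similar: bool
    threshold: float


def compare_apo_vs_rnp(
    fit_apo: FourPLResults,
    fit_rnp: FourPLResults,
    *,
    fold_threshold: float = 3.0,
) -> AffinityComparison:
    """EC50 fold-difference (larger/smaller) with a "similar" verdict.

    Used to decide whether a clone binds the guide-RNA-loaded RNP as well
    as apo antigen.
    """
    if not (fit_apo.converged and fit_rnp.converged):
        raise ValueError("both fits must have converged")
    a, b = fit_apo.ec50, fit_rnp.ec50
    fold = max(a, b) / min(a, b)
    return AffinityComparison(fold_difference=fold, similar=fold <= fold_threshold, threshold=fold_threshold)


def cross_reactivity(
    curves: dict[str, DoseResponseCurve],
    *,
    blank_sd: float = 0.01,
    k: float = 3.0,
) -> dict[str, bool]:
    """Per-antigen reactivity calls for one clone against several antigens.

    Reactive iff the maximum blank-subtracted signal reaches ``k`` times
    the blank standard deviation AND a 4PL fit converges with an EC50
    inside the dosed range (tenfold margin).  Noise-only series fail both
    conditions.
    """
    verdict: dict[str, bool] = {}
    for antigen, curve in curves.items():
        strong = float(np.max(curve.net_signal())) >= k * blank_sd
        reactive = False
        if strong:
            fit = FourPLModel(curve, min_response=k * blank_sd).fit()
            reactive = fit.converged and "extrapolated_ec50" not in fit.flags
        verdict[antigen] = reactive
    return verdict
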