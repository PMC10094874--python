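"""Unit-safe potency handling.

Canonical internal unit for mass concentration is g/L; every other accepted
unit is converted at the boundary.  Potency is carried both ways: IC50
(g/L, small = potent) and its reciprocal EDV50 (L/g, large = potent), the
half-maximal effective dilution volume — the volume of water 1 g of material
can be diluted into while still producing half-maximal activity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from biopotency.errors import DomainError, UnitError

__all__ = [
    "Censoring",
    "PotencyEstimate",
    "DoseResponsePlate",
    "HillFit",
    "Edv50Uncertainty",
    "parse_concentration",
    "ic50_to_edv50",
    "edv50_to_ic50",
    "fit_dose_response",
    "potency_uncertainty_to_edv50",
    "CONCENTRATION_UNITS",
]

# factor to g/L, keyed by normalized token (lower-case, micro sign -> "u",
# whitespace stripped)
CONCENTRATION_UNITS = {
    "ug/ml": 1e-3,
    "mg/l": 1e-3,
    "mg/ml": 1.0,
    "g/l": 1.0,
}


def _normalize_unit(unit: str) -> str:
    return (
        unit.strip()
        .lower()
        .replace("µ", "u")  # micro sign
        .replace("μ", "u")  # greek mu
        .replace(" ", "")
    )


def parse_concentration(value: float, unit: str) -> float:
    """Convert a mass concentration to canonical g/L.

    Accepted units: ``µg/mL``, ``mg/L``, ``mg/mL``, ``g/L`` (case and
    whitespace tolerant; ``ug/ml`` is accepted for µg/mL).

    Raises
    ------
    DomainError
        If ``value`` is not strictly positive.
    UnitError
        If the unit token is not recognized.
    """
    if not math.isfinite(value) or value <= 0:
        raise DomainError(f"concentration must be a positive finite number, got {value!r}")
    key = _normalize_unit(unit)
    try:
        factor = CONCENTRATION_UNITS[key]
    except KeyError:
        raise UnitError(
            f"unknown concentration unit {unit!r}; expected one of µg/mL, mg/L, mg/mL, g/L"
        ) from None
    return value * factor


def ic50_to_edv50(ic50: float) -> float:
    """Reciprocal transform IC50 (g/L) -> EDV50 (L/g).

    Strictly decreasing: more potent material (lower IC50) has a larger
    effective dilution volume.
    """
    if not math.isfinite(ic50) or ic50 <= 0:
        raise DomainError(f"ic50 must be a positive finite number, got {ic50!r}")
    return 1.0 / ic50


def edv50_to_ic50(edv50: float) -> float:
    """Inverse of :func:`ic50_to_edv50`: EDV50 (L/g) -> IC50 (g/L)."""
    if not math.isfinite(edv50) or edv50 <= 0:
        raise DomainError(f"edv50 must be a positive finite number, got {edv50!r}")
    return 1.0 / edv50


class Censoring(str, Enum):
    """Censoring status of a potency estimate."""

    NONE = "none"
    #: IC50 exceeds the highest tested concentration; only a bound is known.
    RIGHT = "right"


@dataclass(frozen=True)
class PotencyEstimate:
    """An IC50/EC50 in canonical g/L together with its EDV50 view.

    Parameters
    ----------
    ic50 : float
        Half-maximal inhibitory concentration in g/L, > 0.
    ic50_sd : float, optional
        Standard deviation of ``ic50``, same units.
    n_replicates : int, optional
        Number of replicates behind the estimate.
    censored : Censoring
        ``RIGHT`` when the IC50 exceeds the highest tested concentration.
    assay_label : str
        Free-text assay description.
    sd_source : str, optional
        Which procedure produced ``ic50_sd`` (e.g. ``"fit_se"``,
        ``"replicate_sd"``, ``"reported"``); recorded, never guessed.
    """

    ic50: float
    ic50_sd: Optional[float] = None
    n_replicates: Optional[int] = None
    censored: Censoring = Censoring.NONE
    assay_label: str = ""
    sd_source: Optional[str] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.ic50) or self.ic50 <= 0:
            raise DomainError(f"ic50 must be positive and finite, got {self.ic50!r}")
        if self.ic50_sd is not None and (not math.isfinite(self.ic50_sd) or self.ic50_sd < 0):
            raise DomainError(f"ic50_sd must be >= 0, got {self.ic50_sd!r}")
        if not isinstance(self.censored, Censoring):
            object.__setattr__(self, "censored", Censoring(self.censored))

    @property
    def edv50(self) -> float:
        """Half-maximal effective dilution volume, L/g (= 1/ic50)."""
        return ic50_to_edv50(self.ic50)

    @classmethod
    def from_value(
        cls,
        value: float,
        unit: str,
        sd: Optional[float] = None,
        **kwargs,
    ) -> "PotencyEstimate":
        """Build from a value in any accepted unit; ``sd`` shares the unit."""
        ic50 = parse_concentration(value, unit)
        ic50_sd = None if sd is None else sd * (ic50 / value)
        return cls(ic50=ic50, ic50_sd=ic50_sd, **kwargs)


@dataclass(frozen=True)
class DoseResponsePlate:
    """Serial-dilution inhibition readouts feeding the curve fitter.

    ``points`` are ``(concentration g/L, response % inhibition, replicate_id)``
    tuples; responses live on a 0–100 scale (values slightly outside are
    tolerated as assay noise).
    """

    points: Tuple[Tuple[float, float, str], ...]
    max_tested_concentration: float
    dilution_note: str = ""

    def __post_init__(self) -> None:
        pts = tuple((float(c), float(r), str(rep)) for c, r, rep in self.points)
        object.__setattr__(self, "points", pts)
        for c, _, _ in pts:
            if not math.isfinite(c) or c <= 0:
                raise DomainError(f"all concentrations must be > 0, got {c!r}")
        if pts and self.max_tested_concentration < max(c for c, _, _ in pts):
            raise DomainError(
                "max_tested_concentration must be >= every point's concentration"
            )

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _, _ in self.points], dtype=float)

    @property
    def responses(self) -> np.ndarray:
        return np.array([r for _, r, _ in self.points], dtype=float)

    @property
    def n_distinct_concentrations(self) -> int:
        return len({c for c, _, _ in self.points})


@dataclass(frozen=True)
class HillFit:
    """Result of a logistic dose–response fit."""

    ic50: float
    hill_slope: float
    top: float
    bottom: float
    residual_sse: float
    converged: bool
    ic50_se: Optional[float] = None
    model: str = "4PL"
    warnings: Tuple[str, ...] = field(default_factory=tuple)


def _four_pl(c: np.ndarray, bottom: float, top: float, log10_ic50: float, h: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + (c / 10.0**log10_ic50) ** h)


def fit_dose_response(
    plate: DoseResponsePlate,
    model: Literal["4PL", "3PL"] = "4PL",
) -> Tuple[HillFit, PotencyEstimate]:
    """Least-squares logistic fit of ``response(c) = bottom + (top-bottom)/(1+(c/ic50)^h)``.

    ``3PL`` fixes ``bottom = 0``.  IC50 is fitted on a log10 scale for
    numerical stability; its standard error is transported back by the delta
    method.  A fitted IC50 above the plate's highest tested concentration is
    flagged ``censored=RIGHT``.  Non-convergence never yields a silent
    number: the returned :class:`HillFit` carries ``converged=False`` plus a
    warning record (also emitted via :mod:`warnings`).
    """
    if model not in ("4PL", "3PL"):
        raise ValueError(f"unknown model {model!r}; expected '4PL' or '3PL'")
    if plate.n_distinct_concentrations < 4:
        raise DomainError(
            f"fitting requires >= 4 distinct concentrations, got {plate.n_distinct_concentrations}"
        )
    c = plate.concentrations
    y = plate.responses
    if not np.all(np.isfinite(y)):
        raise DomainError("responses must be finite numbers")

    logc = np.log10(c)
    # initialize ic50 at the geometric mid-concentration
    log_ic50_0 = 0.5 * (logc.min() + logc.max())
    top0 = float(np.clip(y.max(), 50.0 + 1e-9, 120.0))
    bot0 = float(np.clip(y.min(), -10.0, 40.0))
    # generous ic50 bounds: two decades beyond the tested range either side
    lo_ic, hi_ic = logc.min() - 2.0, logc.max() + 2.0

    fit_warnings: list[str] = []
    if model == "4PL":
        p0 = [bot0, top0, log_ic50_0, 1.0]
        bounds = ([-10.0, 50.0, lo_ic, 0.1], [40.0, 120.0, hi_ic, 10.0])
        fun = _four_pl
    else:
        p0 = [top0, log_ic50_0, 1.0]
        bounds = ([50.0, lo_ic, 0.1], [120.0, hi_ic, 10.0])

        def fun(cc, top, log10_ic50, h):  # bottom pinned at 0
            return _four_pl(cc, 0.0, top, log10_ic50, h)

    try:
        popt, pcov = optimize.curve_fit(
            fun, c, y, p0=p0, bounds=bounds, maxfev=20000, method="trf"
        )
        converged = bool(np.all(np.isfinite(popt)))
    except (RuntimeError, optimize.OptimizeWarning, ValueError) as exc:
        msg = f"dose-response fit did not converge: {exc}"
        warnings.warn(msg, stacklevel=2)
        fit = HillFit(
            ic50=float("nan"), hill_slope=float("nan"), top=float("nan"),
            bottom=float("nan"), residual_sse=float("nan"), converged=False,
            model=model, warnings=(msg,),
        )
        # fall back to the initial guess as a clearly-flagged placeholder
        est = PotencyEstimate(
            ic50=10.0**log_ic50_0, censored=Censoring.NONE,
            assay_label="UNCONVERGED FIT", sd_source=None,
        )
        return fit, est

    if model == "4PL":
        bottom, top, log10_ic50, h = popt
        ic50_idx = 2
    else:
        top, log10_ic50, h = popt
        bottom = 0.0
        ic50_idx = 1

    ic50 = float(10.0**log10_ic50)
    resid = y - fun(c, *popt)
    sse = float(np.dot(resid, resid))

    ic50_se: Optional[float] = None
    if np.all(np.isfinite(pcov)):
        se_log = float(np.sqrt(pcov[ic50_idx, ic50_idx]))
        ic50_se = math.log(10.0) * ic50 * se_log
        if not math.isfinite(ic50_se):
            ic50_se = None

    censored = Censoring.RIGHT if ic50 > plate.max_tested_concentration else Censoring.NONE
    if censored is Censoring.RIGHT:
        fit_warnings.append(
            "fitted IC50 exceeds the highest tested concentration; estimate is right-censored"
        )

    if top <= bottom:
        converged = False
        msg = "degenerate fit: top <= bottom"
        fit_warnings.append(msg)
        warnings.warn(msg, stacklevel=2)

    fit = HillFit(
        ic50=ic50, hill_slope=float(h), top=float(top), bottom=float(bottom),
        residual_sse=sse, converged=converged, ic50_se=ic50_se, model=model,
        warnings=tuple(fit_warnings),
    )
    est = PotencyEstimate(
        ic50=ic50, ic50_sd=ic50_se, censored=censored, sd_source="fit_se",
    )
    return fit, est


@dataclass(frozen=True)
class Edv50Uncertainty:
    """Uncertainty of an EDV50 derived from the IC50's standard deviation.

    ``available`` is False when the source potency carried no uncertainty —
    an explicit "no uncertainty" answer rather than a silent zero.
    """

    available: bool
    edv50_sd: Optional[float] = None  # delta-method value, L/g
    edv50_sd_mc: Optional[float] = None  # Monte-Carlo value when requested
    method: str = "delta"
    n_draws: Optional[int] = None
    seed: Optional[int] = None
    divergent: bool = False  # delta vs MC disagree by > 15%


# relative disagreement between delta method and Monte Carlo beyond which the
# result is flagged divergent (delta linearization breaks down at large CV)
_MC_DIVERGENCE_TOL = 0.15


def potency_uncertainty_to_edv50(
    p: PotencyEstimate,
    method: Literal["delta", "monte-carlo"] = "delta",
    n_draws: int = 10_000,
    seed: Optional[int] = None,
) -> Edv50Uncertainty:
    """Propagate ``ic50_sd`` to the EDV50 scale.

    Delta method: ``edv50_sd = ic50_sd / ic50**2``.  The Monte-Carlo
    alternative resamples the IC50 from a lognormal with matching mean and
    SD (seeded) and reports the empirical SD of the reciprocal; when the two
    disagree by more than 15% the result is flagged ``divergent``.
    """
    if p.ic50_sd is None:
        return Edv50Uncertainty(available=False, method=method)
    delta_sd = p.ic50_sd / (p.ic50**2)
    if method == "delta":
        return Edv50Uncertainty(available=True, edv50_sd=delta_sd, method="delta")
    if method != "monte-carlo":
        raise ValueError(f"unknown method {method!r}")
    if p.ic50_sd == 0.0:
        return Edv50Uncertainty(
            available=True, edv50_sd=delta_sd, edv50_sd_mc=0.0,
            method="monte-carlo", n_draws=n_draws, seed=seed,
        )
    rng = np.random.default_rng(seed)
    cv = p.ic50_sd / p.ic50
    sigma2 = math.log1p(cv**2)
    mu = math.log(p.ic50) - 0.5 * sigma2
    draws = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n_draws)
    mc_sd = float(np.std(1.0 / draws, ddof=1))
    divergent = abs(mc_sd - delta_sd) / delta_sd > _MC_DIVERGENCE_TOL
    return Edv50Uncertainty(
        available=True, edv50_sd=delta_sd, edv50_sd_mc=mc_sd,
        method="monte-carlo", n_draws=n_draws, seed=seed, divergent=divergent,
    )
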