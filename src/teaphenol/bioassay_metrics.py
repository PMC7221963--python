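"""Antioxidant-assay mathematics: inhibition %, ID50, TEAC, ORAC AUC and TE.

Covers the arithmetic of four cell-free antioxidant assays:

* DPPH / ABTS radical-decolorization and TBARS lipid-peroxidation inhibition,
  reported as percent response vs. a blank; the dose producing a 50% response
  (ID50, µg/mL) is estimated from the dose–response curve.
* TEAC: the potency ratio ID50(Trolox) / ID50(sample); larger is more potent.
* ORAC: fluorescein-decay curves are normalized to the blank's starting
  fluorescence, integrated as AUC = Σ fi/f0 over the reading grid, and
  referenced to Trolox through the ratio of net-AUC-vs-concentration
  regression slopes.

ID50 is found by linear interpolation of response against log10(dose) between
the doses bracketing 50% (the dose grids in this kind of screen are sparse —
five points over ~16-fold — so a parametric fit is optional, not the default);
a four-parameter logistic fit is available as ``method="4pl"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "DoseResponse",
    "Id50Estimate",
    "OracCurve",
    "OracResult",
    "percent_inhibition",
    "estimate_id50",
    "teac",
    "orac_normalize",
    "orac_auc",
    "orac_trolox_equivalents",
    "load_assay_panel",
]

ASSAYS = ("DPPH", "ABTS", "TBARS")


@dataclass
class DoseResponse:
    """Mean percent response at each dose for one sample in one assay."""

    sample_id: str
    assay: str
    doses: np.ndarray
    responses: np.ndarray
    sds: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.assay not in ASSAYS:
            raise ValueError(f"assay must be one of {ASSAYS}")
        if self.doses.ndim != 1 or self.doses.shape != self.responses.shape:
            raise ValueError("doses and responses must be 1-D and equal length")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be positive")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")
        if self.sds is not None:
            self.sds = np.asarray(self.sds, dtype=float)
            if self.sds.shape != self.doses.shape:
                raise ValueError("sds must match doses in length")


@dataclass(frozen=True)
class Id50Estimate:
    value: float
    method: str
    bracketed: bool

    def __post_init__(self) -> None:
        if self.bracketed and not self.value > 0:
            raise ValueError("bracketed ID50 must be positive")


def percent_inhibition(signal_sample: float, signal_blank: float) -> float:
    """Percent reduction of the blank signal: (1 − sample/blank) × 100."""
    if signal_blank <= 0:
        raise ValueError("blank signal must be positive")
    return (1.0 - signal_sample / signal_blank) * 100.0


def _isotonic_cleanup(doses: np.ndarray, responses: np.ndarray,
                      max_violation_frac: float = 0.05) -> np.ndarray:
    """Project responses onto a non-decreasing sequence.

    Small ordering violations (noise) are repaired; violations larger than
    ``max_violation_frac`` of the response range indicate a genuinely
    non-monotone curve and raise.
    """
    diffs = np.diff(responses)
    worst = -diffs.min() if diffs.size and diffs.min() < 0 else 0.0
    span = responses.max() - responses.min()
    if span > 0 and worst > max_violation_frac * span:
        raise ValueError(
            f"non-monotone dose-response (violation {worst:.3g} exceeds "
            f"{max_violation_frac:.0%} of range {span:.3g})")
    if worst == 0.0:
        return responses
    iso = IsotonicRegression(increasing=True)
    return iso.fit_transform(np.log10(doses), responses)


def _four_pl(d, top, bottom, id50, hill):
    return bottom + (top - bottom) / (1.0 + (id50 / d) ** hill)


def estimate_id50(dr: DoseResponse, *, method: str = "interp",
                  target: float = 50.0) -> Id50Estimate:
    """Estimate the dose giving a 50% response.

    ``method="interp"`` (default): the response is treated as locally linear
    in log10(dose). When at least three doses fall in the quasi-linear 20-80%
    response band, an OLS line through those points is solved at the target
    (this pools replicate-level noise across doses); otherwise plain linear
    interpolation between the bracketing pair is used. Small ordering
    violations are repaired isotonically first. If the target is never
    crossed the estimate is extrapolated from the two nearest doses and
    flagged ``bracketed=False``.

    ``method="4pl"``: four-parameter logistic fit; the returned value is the
    dose at which the fitted curve crosses the target.
    """
    if dr.doses.size < 2:
        raise ValueError("need at least 2 dose points")
    if method == "4pl":
        p0 = (100.0, 0.0, float(np.median(dr.doses)), 1.0)
        bounds = ([0.0, -50.0, 1e-9, 0.05], [200.0, 50.0, 1e6, 10.0])
        popt, _ = optimize.curve_fit(_four_pl, dr.doses, dr.responses, p0=p0,
                                     bounds=bounds, maxfev=20000)
        top, bottom, id50_fit, hill = popt
        if not (min(top, bottom) < target < max(top, bottom)):
            return Id50Estimate(float(id50_fit), "4pl", False)
        dose = id50_fit * ((target - bottom) / (top - target)) ** (1.0 / hill)
        bracketed = dr.responses.min() <= target <= dr.responses.max()
        return Id50Estimate(float(dose), "4pl", bool(bracketed))
    if method != "interp":
        raise ValueError("method must be 'interp' or '4pl'")

    responses = _isotonic_cleanup(dr.doses, dr.responses)
    logd = np.log10(dr.doses)
    exact = np.flatnonzero(responses == target)
    if exact.size:
        return Id50Estimate(float(dr.doses[exact[0]]), "interp", True)
    above = responses >= target
    band = (responses >= 20.0) & (responses <= 80.0)
    if band.sum() >= 3 and above.any() and not above.all():
        slope, intercept = np.polyfit(logd[band], responses[band], 1)
        if slope > 0:
            return Id50Estimate(float(10 ** ((target - intercept) / slope)),
                                "interp", True)
    if above.all() or not above.any():
        # extrapolate from the two points nearest the target response
        order = np.argsort(np.abs(responses - target))[:2]
        i, j = sorted(order)
        if responses[j] == responses[i]:
            return Id50Estimate(float(dr.doses[i]), "interp", False)
        logdose = logd[i] + (target - responses[i]) * (logd[j] - logd[i]) / (
            responses[j] - responses[i])
        return Id50Estimate(float(10 ** logdose), "interp", False)
    k = int(np.argmax(above))  # first index at/above target; k-1 is below
    r0, r1 = responses[k - 1], responses[k]
    logdose = logd[k - 1] + (target - r0) * (logd[k] - logd[k - 1]) / (r1 - r0)
    return Id50Estimate(float(10 ** logdose), "interp", True)


def teac(id50_trolox: float, id50_sample: float) -> float:
    """Trolox-equivalent antioxidant capacity: ID50(Trolox) / ID50(sample)."""
    if id50_trolox <= 0:
        raise ValueError("Trolox ID50 must be positive")
    if id50_sample <= 0:
        raise ValueError("sample ID50 must be positive")
    return id50_trolox / id50_sample


@dataclass
class OracCurve:
    """Fluorescein fluorescence readings on a uniform time grid."""

    sample_id: str
    concentration: float
    times: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.shape != self.fluorescence.shape or self.times.ndim != 1:
            raise ValueError("times and fluorescence must be 1-D and equal length")
        if self.times.size < 2:
            raise ValueError("need at least two readings")
        steps = np.diff(self.times)
        if not np.allclose(steps, steps[0]) or steps[0] <= 0:
            raise ValueError("times must be a uniform increasing grid")
        if self.fluorescence[0] <= 0:
            raise ValueError("initial fluorescence must be positive")


@dataclass(frozen=True)
class OracResult:
    auc: float
    net_auc: float
    trolox_eq: Optional[float] = None


def orac_normalize(sample: OracCurve, blank: OracCurve) -> OracCurve:
    """Scale a sample curve so its t=0 reading equals the blank's.

    Multiplies the whole curve by blank f(0) / sample f(0); the shape is
    preserved up to this scale factor.
    """
    if sample.times.shape != blank.times.shape or not np.allclose(sample.times, blank.times):
        raise ValueError("sample and blank must share the same time grid")
    factor = blank.fluorescence[0] / sample.fluorescence[0]
    return OracCurve(sample.sample_id, sample.concentration, sample.times.copy(),
                     sample.fluorescence * factor)


def orac_auc(curve: OracCurve) -> float:
    """Dimensionless decay area: Σ_i f_i / f_0 over all readings (t=0 included).

    The t=0 term contributes exactly 1, so a flat curve of n readings has
    AUC = n and complete immediate quenching gives AUC = 1.
    """
    f0 = curve.fluorescence[0]
    return float(np.sum(curve.fluorescence / f0))


def _slope(points: Sequence[tuple[float, float]]) -> float:
    arr = np.asarray(points, dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least two (concentration, net AUC) points")
    if np.allclose(arr[:, 0], arr[0, 0]):
        raise ValueError("singular regression: all concentrations equal")
    return float(stats.linregress(arr[:, 0], arr[:, 1]).slope)


def load_assay_panel() -> pd.DataFrame:
    """Reference antioxidant panel of the six green-tea extracts.

    One row per extract with measured ID50 (µg/mL) and TEAC for DPPH, ABTS
    and TBARS, the ORAC result (Trolox Eq µM), and the reported RACI (kept
    for ordering comparisons only). Indexed by sample id.
    """
    with resources.as_file(resources.files("teaphenol.data") / "assay_panel.csv") as p:
        return pd.read_csv(p, index_col="sample")


def orac_trolox_equivalents(
    sample_net_aucs: Sequence[tuple[float, float]],
    trolox_net_aucs: Sequence[tuple[float, float]],
) -> float:
    """Ratio of net-AUC-vs-concentration OLS slopes, sample over Trolox.

    Both regressions carry an intercept. The result is in Trolox concentration
    units per sample concentration unit.
    """
    slope_trolox = _slope(trolox_net_aucs)
    if slope_trolox <= 0:
        raise ValueError("Trolox regression slope must be positive")
    return _slope(sample_net_aucs) / slope_trolox
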