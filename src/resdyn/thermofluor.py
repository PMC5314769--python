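"""Thermal-shift (thermofluor) melting-curve analysis.

Pipeline: 5-point smoothing -> derivative melting temperature (Tm) ->
ΔTm against a control -> two-state unfolded fraction from linear
baselines -> van't Hoff analysis.

Thermodynamic model (two-state unfolding monitored by dye fluorescence):

    Keq = [unfolded]/[folded] = f/(1-f)
    ln Keq = (-ΔH/R)(1/T) + ΔS/R          (T in kelvin)
    ΔH = -R x slope of ln Keq vs 1/T
    ΔS = ΔH / Tm                          ("conformational entropy")

with R = 8.314 J/(mol K).  Tm is read from the maximum of the first
derivative of the smoothed curve (SYPRO-orange fluorescence rises on
unfolding), refined to sub-grid precision by quadratic interpolation —
which is how 0.1 °C precision comes out of a 1 °C gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

R_GAS = 8.314  # J/(mol K)
CELSIUS_OFFSET = 273.15


class NoTransitionError(ValueError):
    pass


class FitQualityError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass
class MeltCurve:
    """Fluorescence vs temperature on a strictly increasing °C grid."""

    temperature: np.ndarray
    fluorescence: np.ndarray
    label: str = ""
    replicate: int | None = None

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, float)
        self.fluorescence = np.asarray(self.fluorescence, float)
        if self.temperature.size != self.fluorescence.size:
            raise ValueError("temperature and fluorescence lengths differ")
        if self.temperature.size < 11:
            raise ValueError("melt curve needs at least 11 points")
        if not np.all(np.diff(self.temperature) > 0):
            raise ValueError("temperature grid must be strictly increasing")

    def __len__(self):
        return self.temperature.size


def smooth_curve(curve: MeltCurve, window: int = 5) -> MeltCurve:
    """Centered moving average; edges use shrinking symmetric windows.

    A symmetric average preserves linear segments exactly (including at the
    edges, where the window shrinks symmetrically rather than one-sidedly).
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    n = len(curve)
    if window > n:
        raise ValueError("window exceeds curve length")
    half = window // 2
    out = np.empty(n)
    f = curve.fluorescence
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = f[i - h : i + h + 1].mean()
    return MeltCurve(curve.temperature.copy(), out, curve.label, curve.replicate)


def _check_transition(f: np.ndarray) -> None:
    # noise scale from second differences (robust to the sigmoid itself)
    rise = np.ptp(f)
    noise = np.median(np.abs(np.diff(f, 2))) / np.sqrt(6) if f.size > 2 else 0.0
    if rise <= 0 or (noise > 0 and rise < 5 * noise):
        raise NoTransitionError("no clear unfolding transition in this curve")


def estimate_tm(curve: MeltCurve, smooth_window: int = 5,
                invert: bool = False) -> float:
    """Tm (°C) from the maximum of dF/dT of the smoothed curve.

    The peak grid point and its two neighbours define a parabola whose
    vertex is the reported Tm.  ``invert`` handles dye systems whose signal
    falls on unfolding (the minimum of the derivative is used).
    """
    sm = smooth_curve(curve, smooth_window) if smooth_window else curve
    _check_transition(sm.fluorescence)
    T = sm.temperature
    dF = np.gradient(sm.fluorescence, T)
    if invert:
        dF = -dF
    if dF.size < 3 or np.max(dF[1:-1]) <= 0:
        raise NoTransitionError("derivative has no interior positive peak")
    i = 1 + int(np.argmax(dF[1:-1]))
    # quadratic through (T[i-1], d-), (T[i], d0), (T[i+1], d+)
    coeffs = np.polyfit(T[i - 1 : i + 2], dF[i - 1 : i + 2], 2)
    if coeffs[0] >= 0:  # not concave; fall back to the grid point
        return float(T[i])
    vertex = -coeffs[1] / (2 * coeffs[0])
    if not (T[i - 1] <= vertex <= T[i + 1]):
        return float(T[i])
    return float(vertex)


def delta_tm(sample: MeltCurve, control: MeltCurve, smooth_window: int = 5) -> float:
    """Signed melting-point shift: Tm(sample) - Tm(control), °C."""
    return estimate_tm(sample, smooth_window) - estimate_tm(control, smooth_window)


@dataclass
class UnfoldedFraction:
    temperature: np.ndarray
    fraction: np.ndarray
    baseline_folded: tuple[float, float]    # (intercept, slope)
    baseline_unfolded: tuple[float, float]


def unfolded_fraction(curve: MeltCurve, baseline_frac: float = 0.15,
                      smooth_window: int = 0,
                      rollover_margin_c: float = 10.0) -> UnfoldedFraction:
    """Two-state unfolded fraction from linear pre/post-transition baselines.

    Baselines are fitted over the first and last ``baseline_frac`` of the
    grid.  If fluorescence rolls over after complete unfolding (dye release
    on aggregation), the upper baseline window is truncated at the
    fluorescence maximum, and never starts before Tm + ``rollover_margin_c``.
    f = (F - F_folded) / (F_unfolded - F_folded), clipped to (1e-6, 1-1e-6);
    any positive gain applied to the curve cancels in the normalisation.

    No smoothing is applied by default: the moving average broadens the
    transition and would bias the downstream van't Hoff slope low; set
    ``smooth_window`` (odd) for very noisy curves.
    """
    sm = smooth_curve(curve, smooth_window) if smooth_window else curve
    T, F = sm.temperature, sm.fluorescence
    n = len(sm)
    k = max(int(round(baseline_frac * n)), 2)
    tm = estimate_tm(curve, smooth_window)
    lo_idx = np.arange(k)
    # upper window: last k points, truncated at a rollover maximum if present
    i_max = int(np.argmax(F))
    amp = np.ptp(F)
    has_rollover = i_max < n - 1 and (F[i_max] - F[-1]) > 0.05 * amp
    end = i_max + 1 if has_rollover else n
    hi_start = max(end - k, int(np.searchsorted(T, tm + rollover_margin_c)))
    hi_idx = np.arange(hi_start, end)
    if hi_idx.size < 2:
        raise FitQualityError("upper baseline window too short")
    if T[lo_idx[-1]] >= tm or T[hi_idx[0]] <= tm:
        raise FitQualityError(
            "baseline windows overlap the unfolding transition; "
            "narrow baseline_frac or check the curve"
        )
    for idx, name in ((lo_idx, "lower"), (hi_idx, "upper")):
        res = stats.linregress(T[idx], F[idx])
        resid = F[idx] - (res.intercept + res.slope * T[idx])
        if np.std(resid) > 0.1 * amp:
            raise FitQualityError(f"{name} baseline fit is poor (transition inside window?)")
    lo = stats.linregress(T[lo_idx], F[lo_idx])
    hi = stats.linregress(T[hi_idx], F[hi_idx])
    f_f = lo.intercept + lo.slope * T
    f_u = hi.intercept + hi.slope * T
    span = f_u - f_f
    if np.any(span <= 0):
        raise FitQualityError("unfolded baseline not above folded baseline")
    f = np.clip((F - f_f) / span, 1e-6, 1 - 1e-6)
    return UnfoldedFraction(
        T.copy(), f, (lo.intercept, lo.slope), (hi.intercept, hi.slope)
    )


@dataclass
class VantHoffResult:
    """Results of the van't Hoff line fit; ΔS = ΔH/Tm holds by construction."""

    tm_c: float
    delta_h_kj: float            # kJ/mol
    delta_s_kj: float            # kJ/(mol K)
    slope: float                 # of ln Keq vs 1/T(K)
    intercept: float
    r_squared: float
    fit_window_c: tuple[float, float]
    n_points: int

    @property
    def tm_k(self) -> float:
        return self.tm_c + CELSIUS_OFFSET

    def summary(self) -> str:
        lines = [
            "van't Hoff analysis (two-state unfolding)",
            f"  Tm            = {self.tm_c:8.2f} °C ({self.tm_k:.2f} K)",
            f"  ΔH (van't Hoff) = {self.delta_h_kj:8.1f} kJ/mol",
            f"  ΔS = ΔH/Tm    = {self.delta_s_kj:8.4f} kJ/(mol K)",
            f"  ln Keq vs 1/T : slope {self.slope:.4g}, intercept {self.intercept:.4g}, "
            f"R² {self.r_squared:.5f}",
            f"  fit window    = {self.fit_window_c[0]:.1f}–{self.fit_window_c[1]:.1f} °C "
            f"({self.n_points} points)",
        ]
        return "\n".join(lines)


def vant_hoff_fit(fraction: UnfoldedFraction, band: tuple[float, float] = (0.1, 0.9),
                  tm_c: float | None = None) -> VantHoffResult:
    """Fit ln Keq = (-ΔH/R)(1/T) + ΔS/R over the fraction band.

    Keq = f/(1-f); the line is fitted on points with f inside ``band``
    (default 0.1–0.9, where the logit is well conditioned).  ΔH = -R*slope;
    Tm is where the fitted line crosses ln Keq = 0 unless supplied; ΔS is
    then ΔH/Tm(K).
    """
    f = fraction.fraction
    mask = (f >= band[0]) & (f <= band[1])
    if np.count_nonzero(mask) < 5:
        raise InsufficientDataError(
            f"only {np.count_nonzero(mask)} points with f in {band}; need >= 5"
        )
    T_k = fraction.temperature[mask] + CELSIUS_OFFSET
    y = np.log(f[mask] / (1 - f[mask]))
    res = stats.linregress(1.0 / T_k, y)
    delta_h = -R_GAS * res.slope  # J/mol
    if tm_c is None:
        if res.slope == 0:
            raise FitQualityError("zero slope; Tm undefined from the fit")
        tm_k = -res.slope / res.intercept
        tm_c = tm_k - CELSIUS_OFFSET
    tm_k = tm_c + CELSIUS_OFFSET
    delta_s = delta_h / tm_k
    tw = fraction.temperature[mask]
    return VantHoffResult(
        tm_c=float(tm_c),
        delta_h_kj=delta_h / 1000.0,
        delta_s_kj=delta_s / 1000.0,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        fit_window_c=(float(tw.min()), float(tw.max())),
        n_points=int(np.count_nonzero(mask)),
    )


def analyze_melt(curve: MeltCurve, control: MeltCurve | None = None,
                 smooth_window: int = 5, band=(0.1, 0.9)) -> dict:
    """One-stop report: Tm, optional ΔTm, and van't Hoff thermodynamics."""
    tm = estimate_tm(curve, smooth_window)
    report = {"label": curve.label, "tm_c": round(tm, 2)}
    if control is not None:
        report["control_tm_c"] = round(estimate_tm(control, smooth_window), 2)
        report["delta_tm_c"] = round(tm - report["control_tm_c"], 2)
    try:
        # fraction from the raw curve: smoothing is only for the derivative
        frac = unfolded_fraction(curve)
        vh = vant_hoff_fit(frac, band=band, tm_c=tm)
        report.update(
            delta_h_kj_mol=round(vh.delta_h_kj, 1),
            delta_s_kj_mol_k=round(vh.delta_s_kj, 4),
            vant_hoff_r_squared=round(vh.r_squared, 5),
        )
    except (FitQualityError, InsufficientDataError) as e:
        report["vant_hoff_error"] = str(e)
    return report


def average_replicates(curves: list[MeltCurve], label: str = "") -> MeltCurve:
    """Average replicate curves point-wise on their (identical) grid."""
    if not curves:
        raise ValueError("no curves to average")
    grid = curves[0].temperature
    for c in curves[1:]:
        if c.temperature.size != grid.size or not np.allclose(c.temperature, grid):
            raise ValueError("replicates must share a common temperature grid")
    F = np.mean([c.fluorescence for c in curves], axis=0)
    return MeltCurve(grid.copy(), F, label or curves[0].label)


def replicate_tm_spread(curves: list[MeltCurve], smooth_window: int = 5) -> dict:
    """Per-replicate Tm values with mean and standard deviation."""
    tms = [estimate_tm(c, smooth_window) for c in curves]
    return {
        "tm_values": tms,
        "mean": float(np.mean(tms)),
        "sd": float(np.std(tms, ddof=1)) if len(tms) > 1 else 0.0,
    }
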