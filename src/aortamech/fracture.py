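"""Notched fracture-toughness test analysis.

A matched pair of specimens with identical geometry is tested: one is
notched to half its width (0.5*W0) and pulled until a crack starts to
propagate — visible as the initial kink of its force-deformation curve at
the critical displacement L_c — while the other is pulled intact. The
fracture energy is the work the intact specimen stores between the
physiologic length L_p and L_c,

    Gamma = integral_{L_p}^{L_c} F dl / (W0 * T0),

optionally further normalized by the gauge length L0 to an energy density
(J/m^3), the convention used for reporting toughness here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .mechanics import ForceDisplacementCurve, SpecimenGeometry

Normalization = Literal["per_area", "per_volume"]


class NoKinkError(ValueError):
    """No slope-drop change point found; supply the critical displacement manually."""


class BoundsError(ValueError):
    """Integration bounds are degenerate or outside the measured curve."""


@dataclass(frozen=True)
class NotchedPair:
    """A notched/unnotched specimen pair sharing one geometry.

    ``notch_length`` is fixed by protocol at half the width. The critical
    displacement ``L_c`` may be supplied (manual reading of the kink) or
    left None to be detected from the notched curve.
    """

    notched_curve: ForceDisplacementCurve
    unnotched_curve: ForceDisplacementCurve
    geometry: SpecimenGeometry
    physiologic_length: float  # L_p, m (displacement at in vivo loading)
    critical_displacement: float | None = None  # L_c, m; manual override

    def __post_init__(self) -> None:
        if self.physiologic_length < 0:
            raise BoundsError("physiologic length must be non-negative")
        if (
            self.critical_displacement is not None
            and self.critical_displacement < self.physiologic_length
        ):
            raise BoundsError(
                f"L_c {self.critical_displacement:.6g} m must not be below "
                f"L_p {self.physiologic_length:.6g} m"
            )

    @property
    def notch_length(self) -> float:
        return 0.5 * self.geometry.W0


@dataclass(frozen=True)
class FractureResult:
    gamma: float  # J/m^2 or J/m^3 per `normalization`
    normalization: Normalization
    L_c: float  # m
    detection_mode: Literal["auto", "manual"]

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("fracture energy must be non-negative")


def _trailing_slopes(d: np.ndarray, f: np.ndarray, window: int) -> np.ndarray:
    """Least-squares slope of the `window` trailing points, per index.

    slopes[i] fits points i-window+1 .. i; entries before a full window are NaN.
    """
    n = d.size
    slopes = np.full(n, np.nan)
    for i in range(window - 1, n):
        x = d[i - window + 1 : i + 1]
        y = f[i - window + 1 : i + 1]
        xm, ym = x.mean(), y.mean()
        denom = np.sum((x - xm) ** 2)
        slopes[i] = np.sum((x - xm) * (y - ym)) / denom
    return slopes


def _hinge_sse(d: np.ndarray, f: np.ndarray, t: float, quadratic: bool) -> float:
    """SSE of a segmented fit with a slope break at t.

    Linear flavour: a + b*d + e*h with h = max(0, d - t). Quadratic flavour
    adds d^2 and h^2 terms, absorbing smooth stress-stiffening curvature on
    either side of the break so the breakpoint is not biased on curved
    records.
    """
    h = np.maximum(0.0, d - t)
    cols = [np.ones_like(d), d, h]
    if quadratic:
        cols += [d * d, h * h]
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, f, rcond=None)
    r = f - X @ beta
    return float(r @ r)


def _hinge_breakpoint(d: np.ndarray, f: np.ndarray, lo: int, hi: int,
                      model: str = "auto", n_sub: int = 8) -> float:
    """Breakpoint of a segmented least-squares fit on [lo, hi).

    The breakpoint is scanned on a sub-sample grid strictly inside the
    region (continuous in displacement, not snapped to a sample). With
    ``model='auto'`` both a broken-line and a segmented-quadratic fit are
    tried and the winner by BIC supplies the breakpoint — the quadratic
    only earns its extra terms when the record genuinely curves, while
    piecewise-linear records keep the tighter broken-line localization.
    """
    dd, ff = d[lo:hi], f[lo:hi]
    n = dd.size
    cands = np.concatenate(
        [np.linspace(a, b, n_sub, endpoint=False) for a, b in zip(dd[1:-2], dd[2:-1])]
    )
    flavours = {"linear": [False], "quadratic": [True], "auto": [False, True]}[model]
    best = []
    for quad in flavours:
        k_params = 6 if quad else 4
        sses = [_hinge_sse(dd, ff, t, quad) for t in cands]
        j = int(np.argmin(sses))
        bic = n * np.log(max(sses[j], 1e-300) / n) + k_params * np.log(n)
        best.append((bic, float(cands[j])))
    return min(best)[1]


def detect_critical_displacement(
    curve: ForceDisplacementCurve,
    slope_drop_fraction: float = 0.5,
    window: int = 5,
    model: Literal["auto", "linear", "quadratic"] = "auto",
    min_slope_fraction: float = 0.05,
    min_force_fraction: float = 0.05,
) -> float:
    """Displacement of the initial kink of a notched force-deformation curve.

    A trailing least-squares slope over ``window`` points is tracked along
    the curve; crack initiation is flagged at the first point where it falls
    below ``slope_drop_fraction`` of the running maximum trailing slope. The
    trailing window necessarily straddles the kink before the threshold
    trips, so the kink location is then refined by a local segmented
    least-squares fit around the trigger and the fitted breakpoint
    displacement is returned. ``model`` picks the refinement flavour:
    ``linear`` broken-line (tightest localization when the record is
    piecewise-linear), ``quadratic`` (unbiased on smoothly stiffening
    tissue records), or ``auto`` (BIC choice between the two, the
    default). Deterministic given its inputs.

    Raises :class:`NoKinkError` when no point qualifies (e.g. a straight
    curve); the caller must then supply L_c manually.
    """
    if not (0 < slope_drop_fraction < 1):
        raise ValueError("slope_drop_fraction must lie in (0, 1)")
    if window < 2:
        raise ValueError("window must be at least 2 points")
    d, f = curve.displacement, curve.force
    if d.size < 2 * window:
        raise ValueError(f"need at least {2 * window} points, got {d.size}")

    slopes = _trailing_slopes(d, f, window)
    # the trigger arms only once the toe of the curve is cleared: on
    # J-shaped tissue records the initial slopes (and forces) are
    # indistinguishable from noise, and an unguarded ratio test can fire in
    # that flat toe region — while a crack can only initiate under
    # substantial load
    arm_slope = min_slope_fraction * np.nanmax(slopes)
    arm_force = min_force_fraction * np.max(f)
    run_max = -np.inf
    for i in range(window - 1, d.size):
        armed = run_max >= arm_slope and f[i] >= arm_force
        if armed and slopes[i] < slope_drop_fraction * run_max:
            lo = max(0, i - 6 * window)
            hi = min(d.size, i + 3 * window)
            return _hinge_breakpoint(d, f, lo, hi, model)
        run_max = max(run_max, slopes[i])
    raise NoKinkError(
        "no trailing-slope drop below "
        f"{slope_drop_fraction:.2f} x running maximum; supply L_c manually"
    )


def critical_displacement(
    pair: NotchedPair,
    slope_drop_fraction: float = 0.5,
    window: int = 5,
) -> tuple[float, Literal["auto", "manual"]]:
    """L_c for a pair: the manual override if set, else detected from the notched curve."""
    if pair.critical_displacement is not None:
        return pair.critical_displacement, "manual"
    return (
        detect_critical_displacement(pair.notched_curve, slope_drop_fraction, window),
        "auto",
    )


def fracture_energy(
    pair: NotchedPair,
    normalization: Normalization = "per_volume",
    *,
    slope_drop_fraction: float = 0.5,
    window: int = 5,
) -> FractureResult:
    """Fracture energy of a notched/unnotched pair.

    Trapezoidal integral of the *unnotched* force over displacement from
    L_p to L_c, divided by the undeformed cross-section W0*T0 (``per_area``,
    the formula-literal J/m^2); ``per_volume`` (the reporting default)
    further divides by the gauge length L0, giving J/m^3.
    """
    L_c, mode = critical_displacement(pair, slope_drop_fraction, window)
    L_p = pair.physiologic_length
    if L_c < L_p:
        raise BoundsError(f"L_c {L_c:.6g} m below L_p {L_p:.6g} m")
    d, f = pair.unnotched_curve.displacement, pair.unnotched_curve.force
    if L_p < d[0] or L_c > d[-1]:
        raise BoundsError(
            f"integration bounds [{L_p:.6g}, {L_c:.6g}] m outside the unnotched "
            f"curve span [{d[0]:.6g}, {d[-1]:.6g}] m"
        )
    if L_c == L_p:
        work = 0.0
    else:
        inside = (d > L_p) & (d < L_c)
        dd = np.concatenate(([L_p], d[inside], [L_c]))
        ff = np.interp(dd, d, f)
        work = float(np.trapezoid(ff, dd))

    geom = pair.geometry
    gamma = work / (geom.W0 * geom.T0)
    if normalization == "per_volume":
        gamma /= geom.L0
    elif normalization != "per_area":
        raise ValueError(f"unknown normalization {normalization!r}")
    return FractureResult(gamma=gamma, normalization=normalization, L_c=L_c, detection_mode=mode)
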