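"""Fv/Fm-versus-temperature response curves and heat-tolerance thresholds.

The temperature response of the dark-acclimated maximum quantum yield of
photosystem II (Fv/Fm) is modelled with a negative-exponential decay

    y(T) = theta_a * (1 - exp(-(theta_b + theta_c * T)))

where ``theta_a`` is the unstressed asymptote, ``theta_b`` a location
constant and ``theta_c`` (< 0 for a declining curve) the decay parameter.
Three thresholds summarise a fitted curve:

* ``Tcrit`` — temperature at which the slope of the curve reaches 15% of its
  steepest value over the fitted temperature domain (onset of impairment);
* ``T50`` / ``T95`` — temperatures causing a 50% / 95% reduction of Fv/Fm
  relative to the unstressed control value.

All three have closed forms for this model (see :func:`compute_tcrit` and
:func:`compute_reduction_threshold`); fitting is nonlinear least squares
with multi-start initialisation, and uncertainties come from a leaf-level
bootstrap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

THRESHOLD_KINDS = ("Tcrit", "T50", "T95")

#: slope fraction defining Tcrit (15% of the steepest slope in the domain)
TCRIT_SLOPE_FRACTION = 0.15

#: fallback unstressed Fv/Fm when a group has no control measurements
DEFAULT_REFERENCE_FVFM = 0.803

# decay-parameter grid for multi-start initialisation (per degree C)
_THETA_C_STARTS = (-0.05, -0.10, -0.15, -0.25, -0.40, -0.60, -0.90, -1.40, -2.0)

# box constraints keep the optimiser on the declining branch
_LOWER = np.array([1e-3, -100.0, -12.0])
_UPPER = np.array([2.0, 800.0, -1e-5])


@dataclass
class ResponseCurve:
    """Fitted decay-curve parameters plus fit diagnostics for one group."""

    theta_a: float
    theta_b: float
    theta_c: float
    t_low: float
    t_high: float
    resid_sd: float
    n_obs: int
    converged: bool
    message: str = ""

    @property
    def thetas(self) -> tuple[float, float, float]:
        return (self.theta_a, self.theta_b, self.theta_c)


@dataclass
class ThresholdEstimate:
    """Point and bootstrap estimates of one heat-tolerance threshold."""

    kind: str
    point: float
    boot_mean: float
    boot_se: float
    n_boot_success: int
    n_boot: int
    reference_fvfm: float
    reliable: bool = True


def eq1(temperature, theta_a: float, theta_b: float, theta_c: float):
    """Evaluate the decay model at ``temperature`` (vectorised)."""
    t = np.asarray(temperature, dtype=float)
    z = np.clip(theta_b + theta_c * t, -700.0, 700.0)
    out = theta_a * (1.0 - np.exp(-z))
    return out if out.ndim else float(out)


def eq1_predict(curve: ResponseCurve, temperature):
    """Predicted Fv/Fm of a fitted curve at ``temperature``."""
    return eq1(temperature, *curve.thetas)


def eq1_slope(temperature, theta_a: float, theta_b: float, theta_c: float):
    """dy/dT of the decay model (negative for a declining curve)."""
    t = np.asarray(temperature, dtype=float)
    z = np.clip(theta_b + theta_c * t, -700.0, 700.0)
    out = theta_a * theta_c * np.exp(-z)
    return out if out.ndim else float(out)


def _fitting_arrays(
    observations: pd.DataFrame,
    include_controls: bool = True,
    control_temperature: float = 22.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble (temperature, fvfm) arrays, appending per-leaf ambient controls."""
    t = observations["temperature"].to_numpy(dtype=float)
    y = observations["fvfm"].to_numpy(dtype=float)
    if include_controls and "control_fvfm" in observations:
        ctrl = observations["control_fvfm"].to_numpy(dtype=float)
        ok = np.isfinite(ctrl)
        if ok.any():
            t = np.concatenate([t, np.full(ok.sum(), control_temperature)])
            y = np.concatenate([y, ctrl[ok]])
    return t, y


def group_reference_fvfm(observations: pd.DataFrame, fallback: float = DEFAULT_REFERENCE_FVFM) -> float:
    """Unstressed reference Fv/Fm for a group: mean of the leaf controls.

    Falls back to the published control value when no controls are present.
    """
    if "control_fvfm" in observations:
        ctrl = observations["control_fvfm"].to_numpy(dtype=float)
        ctrl = ctrl[np.isfinite(ctrl)]
        if ctrl.size:
            return float(ctrl.mean())
    return float(fallback)


def _fit_from_start(t: np.ndarray, y: np.ndarray, x0: np.ndarray, xtol: float, max_nfev: int):
    # Fv/Fm is physically non-negative and collapsed leaves record 0, so
    # residuals are taken against the zero-clamped curve; the raw model would
    # otherwise go negative past the collapse point and bias the fit.
    def resid(theta):
        return np.maximum(eq1(t, *theta), 0.0) - y

    x0 = np.clip(x0, _LOWER + 1e-9, _UPPER - 1e-9)
    try:
        res = least_squares(
            resid, x0, bounds=(_LOWER, _UPPER), xtol=xtol, ftol=xtol, gtol=None,
            max_nfev=max_nfev,
        )
    except Exception:  # pragma: no cover - pathological optimiser failure
        return None
    if not res.success or not np.all(np.isfinite(res.x)):
        return None
    return res


def fit_response_curve(
    observations: pd.DataFrame,
    include_controls: bool = True,
    control_temperature: float = 22.5,
    xtol: float = 1e-8,
    max_nfev: int = 500,
    _warm_start: Sequence[float] | None = None,
) -> ResponseCurve:
    """Fit the decay model to one species-site group by nonlinear least squares.

    Initialisation is multi-start: the asymptote starts at the mean control
    Fv/Fm (or the maximum observed value), and for each decay-parameter start
    on a fixed grid, ``theta_b`` is back-solved so the curve crosses half the
    starting asymptote near the empirical half-decline temperature.  The best
    converged start by residual sum of squares wins.  ``_warm_start`` is used
    by the bootstrap to seed replicate refits from the full-data solution
    (multi-start is the fallback when the warm start fails).

    Returns an unfittable (``converged=False``) result, never a silent
    default, when the group violates the preconditions (fewer than 5
    observations, fewer than 3 distinct temperatures, no decline, or no
    near-control observation at the top of the curve) or no start converges.
    """
    t, y = _fitting_arrays(observations, include_controls, control_temperature)
    n = t.size

    def unfit(msg: str) -> ResponseCurve:
        return ResponseCurve(
            np.nan, np.nan, np.nan,
            t_low=float(t.min()) if n else np.nan,
            t_high=float(t.max()) if n else np.nan,
            resid_sd=np.nan, n_obs=int(n), converged=False, message=msg,
        )

    if n < 5:
        return unfit(f"too few observations ({n} < 5)")
    if np.unique(np.round(t, 6)).size < 3:
        return unfit("fewer than 3 distinct temperatures")
    y_top = float(np.max(y))
    if y_top - float(np.min(y)) < 0.05:
        return unfit("no decline in Fv/Fm (decay parameter not identifiable)")
    ref = group_reference_fvfm(observations)
    if y_top < 0.5 * ref:
        return unfit("no near-control observation at the top of the curve")

    theta_a0 = ref if np.isfinite(ref) and ref > 0 else y_top

    starts: list[np.ndarray] = []
    if _warm_start is not None:
        starts.append(np.asarray(_warm_start, dtype=float))
    else:
        # empirical half-decline temperature for back-solving theta_b
        half = 0.5 * theta_a0
        order = np.argsort(t)
        t_half = float(t[order][np.argmin(np.abs(y[order] - half))])
        for c0 in _THETA_C_STARTS:
            b0 = np.log(2.0) - c0 * t_half
            starts.append(np.array([theta_a0, b0, c0]))

    best = None
    for x0 in starts:
        res = _fit_from_start(t, y, x0, xtol, max_nfev)
        if res is None:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None and _warm_start is not None:
        # fall back to full multi-start
        return fit_response_curve(
            observations, include_controls, control_temperature, xtol, max_nfev,
        )
    if best is None:
        return unfit("no start converged")

    a, b, c = (float(v) for v in best.x)
    if not (a > 0 and c < 0):
        return unfit(f"fit left the declining branch (theta_a={a:.3g}, theta_c={c:.3g})")
    dof = max(n - 3, 1)
    resid_sd = float(np.sqrt(2.0 * best.cost / dof))
    return ResponseCurve(
        a, b, c,
        t_low=float(t.min()), t_high=float(t.max()),
        resid_sd=resid_sd, n_obs=int(n), converged=True, message="ok",
    )


def compute_tcrit(curve: ResponseCurve, slope_fraction: float = TCRIT_SLOPE_FRACTION) -> float:
    """Temperature where the curve's slope reaches ``slope_fraction`` of its steepest value.

    The slope magnitude |theta_a*theta_c|*exp(-(theta_b+theta_c*T)) grows
    monotonically in T for a declining curve, so the steepest slope over the
    fit domain sits at its upper edge ``t_high``; the threshold has the
    closed form ``t_high + ln(slope_fraction)/|theta_c|``.  A value below the
    domain's lower edge means the curve is too shallow within the domain and
    is flagged with a warning (the value is still returned).
    """
    if not curve.converged:
        raise ValueError("Tcrit undefined for an unfitted curve")
    tcrit = curve.t_high + float(np.log(slope_fraction)) / abs(curve.theta_c)
    if tcrit < curve.t_low:
        warnings.warn(
            f"Tcrit {tcrit:.2f}C falls below the fitted domain "
            f"[{curve.t_low:.1f}, {curve.t_high:.1f}]C (curve too shallow)",
            stacklevel=2,
        )
    return tcrit


def compute_reduction_threshold(
    curve: ResponseCurve, fraction: float, reference: float
) -> float:
    """Temperature causing a ``fraction`` reduction of Fv/Fm below ``reference``.

    Solves ``theta_a*(1 - exp(-(theta_b + theta_c*T))) = (1-fraction)*reference``
    in closed form.  Undefined (NaN) when the target value is not reached by
    the curve, i.e. when it is at or above the asymptote.
    """
    if not curve.converged:
        raise ValueError("reduction threshold undefined for an unfitted curve")
    c = (1.0 - fraction) * reference
    if not (0.0 < c < curve.theta_a):
        return float("nan")
    return -(curve.theta_b + float(np.log(1.0 - c / curve.theta_a))) / curve.theta_c


def thresholds_from_curve(
    curve: ResponseCurve, reference: float
) -> dict[str, float]:
    """All three thresholds of a fitted curve (NaN where undefined)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tcrit = compute_tcrit(curve)
    return {
        "Tcrit": tcrit,
        "T50": compute_reduction_threshold(curve, 0.5, reference),
        "T95": compute_reduction_threshold(curve, 0.95, reference),
    }


def bootstrap_thresholds(
    observations: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    reference: float | None = None,
    include_controls: bool = True,
    control_temperature: float = 22.5,
    stratify_by_temperature: bool = False,
) -> tuple[ResponseCurve, dict[str, ThresholdEstimate]]:
    """Leaf-level bootstrap of Tcrit/T50/T95 for one species-site group.

    Rows are resampled with replacement (same n; optionally stratified within
    target-temperature levels), the curve is refitted for each replicate
    (warm-started from the full-data solution) and all three thresholds are
    recomputed.  Replicates that fail to converge or yield an undefined
    threshold are excluded from that threshold's mean/SE, never substituted.
    Estimates with fewer than 50% successful replicates are flagged
    unreliable.
    """
    full = fit_response_curve(
        observations, include_controls=include_controls,
        control_temperature=control_temperature,
    )
    if reference is None:
        reference = group_reference_fvfm(observations)
    if not full.converged:
        raise ValueError(f"group unfittable: {full.message}")
    points = thresholds_from_curve(full, reference)

    rng = np.random.default_rng(seed)
    n = len(observations)
    if stratify_by_temperature:
        strata = [
            np.flatnonzero(observations["temperature"].round(0).to_numpy() == lvl)
            for lvl in np.unique(observations["temperature"].round(0).to_numpy())
        ]
    draws: dict[str, list[float]] = {k: [] for k in THRESHOLD_KINDS}
    for _ in range(n_boot):
        if stratify_by_temperature:
            idx = np.concatenate([s[rng.integers(0, s.size, s.size)] for s in strata])
        else:
            idx = rng.integers(0, n, n)
        boot = observations.iloc[idx]
        curve = fit_response_curve(
            boot, include_controls=include_controls,
            control_temperature=control_temperature, _warm_start=full.thetas,
        )
        if not curve.converged:
            continue
        # Tcrit's slope domain is the group's measured range, a per-group
        # convention that stays fixed across resamples
        curve.t_low, curve.t_high = full.t_low, full.t_high
        vals = thresholds_from_curve(curve, reference)
        for k, v in vals.items():
            if np.isfinite(v):
                draws[k].append(v)

    estimates: dict[str, ThresholdEstimate] = {}
    for k in THRESHOLD_KINDS:
        arr = np.asarray(draws[k], dtype=float)
        ok = arr.size
        est = ThresholdEstimate(
            kind=k,
            point=points[k],
            boot_mean=float(arr.mean()) if ok else float("nan"),
            boot_se=float(arr.std(ddof=1)) if ok > 1 else (0.0 if ok else float("nan")),
            n_boot_success=int(ok),
            n_boot=int(n_boot),
            reference_fvfm=float(reference),
            reliable=bool(ok >= 0.5 * n_boot),
        )
        if not est.reliable:
            logger.warning("bootstrap for %s succeeded in only %d/%d replicates", k, ok, n_boot)
        estimates[k] = est
    return full, estimates


def fit_all_groups(
    observations: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    reference_policy: str = "group_control",
    fixed_reference: float = DEFAULT_REFERENCE_FVFM,
    include_controls: bool = True,
    control_temperature: float = 22.5,
    stratify_by_temperature: bool = False,
) -> pd.DataFrame:
    """Fit and bootstrap every species x site x protocol group of a table.

    Groups are processed in sorted key order with per-group random streams
    spawned from ``seed``, so re-runs are bit-identical and independent of
    input row order.  Unfittable groups yield a flagged row (``converged``
    False) rather than aborting the run.

    ``reference_policy`` selects the unstressed value the 50%/95% reductions
    are measured against: ``"group_control"`` (mean of the group's leaf
    controls, the default) or ``"fixed"`` (``fixed_reference``).
    """
    if observations.empty:
        raise ValueError("empty observation table")
    if reference_policy not in ("group_control", "fixed"):
        raise ValueError(f"unknown reference policy {reference_policy!r}")
    if "protocol" not in observations:
        observations = observations.assign(protocol="direct")

    keys = sorted(
        observations.groupby(["species", "site", "protocol"], sort=True).groups
    )
    streams = np.random.SeedSequence(seed).spawn(len(keys))
    grouped = observations.groupby(["species", "site", "protocol"], sort=True)

    rows = []
    for (key, stream) in zip(keys, streams):
        # sort rows so resampling is invariant to input row order
        group = grouped.get_group(key)
        group = group.sort_values(list(group.columns)).reset_index(drop=True)
        species, site, protocol = key
        ref = (
            group_reference_fvfm(group, fixed_reference)
            if reference_policy == "group_control"
            else float(fixed_reference)
        )
        row: dict[str, object] = {
            "species": species, "site": site, "protocol": protocol,
            "n_obs": len(group), "reference_fvfm": ref,
        }
        try:
            curve, ests = bootstrap_thresholds(
                group, n_boot=n_boot, seed=stream, reference=ref,
                include_controls=include_controls,
                control_temperature=control_temperature,
                stratify_by_temperature=stratify_by_temperature,
            )
        except ValueError as exc:
            logger.warning("group %s/%s/%s unfittable: %s", species, site, protocol, exc)
            row.update({"converged": False, "message": str(exc)})
            rows.append(row)
            continue
        row.update(
            {
                "converged": True, "message": curve.message,
                "theta_a": curve.theta_a, "theta_b": curve.theta_b,
                "theta_c": curve.theta_c,
                "t_low": curve.t_low, "t_high": curve.t_high,
                "resid_sd": curve.resid_sd,
            }
        )
        for kind, est in ests.items():
            row[f"{kind}_point"] = est.point
            row[f"{kind}_boot_mean"] = est.boot_mean
            row[f"{kind}_boot_se"] = est.boot_se
            row[f"{kind}_n_success"] = est.n_boot_success
            row[f"{kind}_reliable"] = est.reliable
        logger.info("fitted %s/%s/%s (n=%d)", species, site, protocol, len(group))
        rows.append(row)
    return pd.DataFrame(rows)
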