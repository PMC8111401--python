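"""Non-compartmental AUC analysis for sparse batch (serial-sampling) designs.

Plasma concentrations are dose-normalised to a 300 µg reference dose, the
AUC(0-tlast) is the linear trapezoid over the arithmetic per-time-point
means, and uncertainty comes from bootstrap-t resampling in which the
resampling unit is the animal within its time-point batch (most animals
contribute a single plasma sample, so time points behave as independent
batches).  The headline contrast is the irradiated/control AUC ratio over
the first 24 h.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .data_etl import ObservationRecord, correct_records

__all__ = [
    "MeanProfile",
    "AucEstimate",
    "AucRatio",
    "normalize",
    "mean_profile",
    "auc_tlast",
    "bootstrap_t_ci",
    "auc_ratio",
]

REFERENCE_DOSE_UG = 300.0


@dataclass(frozen=True)
class MeanProfile:
    """Arithmetic-mean dose-normalised concentration per sampling time."""

    times: np.ndarray
    means: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.means) != len(t) or len(self.counts) != len(t):
            raise ValueError("times, means and counts must be aligned")
        if np.any(np.asarray(self.counts) < 1):
            raise ValueError("each time point needs at least one animal")


@dataclass(frozen=True)
class AucEstimate:
    """Trapezoidal AUC with a bootstrap-t confidence interval."""

    auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.auc <= self.ci_high:
            raise ValueError("interval must bracket the point estimate")


@dataclass(frozen=True)
class AucRatio:
    """Irradiated/control AUC ratio with bootstrap CI and p-value."""

    ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    auc_irradiated: AucEstimate
    auc_control: AucEstimate


def normalize(
    records: Sequence[ObservationRecord],
    reference_dose_ug: float = REFERENCE_DOSE_UG,
) -> list[ObservationRecord]:
    """Scale each record's value to the reference administered dose.

    Under linear kinetics, concentration is proportional to dose, so values
    times ``reference/dose`` put all dose arms on a common scale.  Zero-dose
    (vehicle) records cannot be normalised and raise.
    """
    out = []
    for r in records:
        if r.dose_ug <= 0:
            raise ValueError(
                f"cannot dose-normalise record of animal {r.animal_id!r} "
                "with zero dose"
            )
        out.append(replace(r, value=r.value * reference_dose_ug / r.dose_ug))
    return out


def _batches(records: Sequence[ObservationRecord]) -> tuple[np.ndarray, list[np.ndarray]]:
    """Group plasma values by sampling time (the batch structure)."""
    by_time: dict[float, list[float]] = {}
    for r in records:
        by_time.setdefault(r.time_h, []).append(r.value)
    times = np.array(sorted(by_time))
    values = [np.asarray(by_time[t]) for t in times]
    return times, values


def mean_profile(records: Sequence[ObservationRecord]) -> MeanProfile:
    """Arithmetic-mean profile of (already corrected and normalised) plasma
    records, one mean per distinct sampling time."""
    plasma = [r for r in records if r.compartment == "plasma"]
    if not plasma:
        raise ValueError("no plasma records")
    times, values = _batches(plasma)
    return MeanProfile(
        times=times,
        means=np.array([v.mean() for v in values]),
        counts=np.array([len(v) for v in values]),
    )


def auc_tlast(profile: MeanProfile) -> float:
    """Linear trapezoidal AUC over the profile's time span."""
    if len(profile.times) < 2:
        raise ValueError("AUC needs at least two time points")
    return float(np.trapezoid(profile.means, profile.times))


def _trapezoid_weights(times: np.ndarray) -> np.ndarray:
    w = np.zeros_like(times)
    w[:-1] += 0.5 * np.diff(times)
    w[1:] += 0.5 * np.diff(times)
    return w


def _auc_and_se(times: np.ndarray, values: list[np.ndarray]) -> tuple[float, float]:
    """Trapezoid AUC of the batch means and its plug-in standard error.

    Time-point means are treated as independent (the batch design: nearly
    all animals contribute one sample); batches of a single animal
    contribute no variance estimate.
    """
    w = _trapezoid_weights(times)
    means = np.array([v.mean() for v in values])
    var = np.array([v.var(ddof=1) / len(v) if len(v) > 1 else 0.0 for v in values])
    return float(w @ means), float(np.sqrt(w**2 @ var))


def _prepare(records: Sequence[ObservationRecord], tlast: float) -> tuple[np.ndarray, list[np.ndarray]]:
    # gavage plasma only (the exposure summary of the oral arms); pre-dose
    # (t = 0) samples stay in, their mean anchors the first trapezoid
    recs = correct_records(records)
    recs = [
        r for r in recs
        if r.compartment == "plasma" and r.route == "gavage"
        and r.dose_ug > 0 and 0 <= r.time_h <= tlast
    ]
    if not recs:
        raise ValueError("no usable plasma records in the requested window")
    recs = normalize(recs)
    return _batches(recs)


def bootstrap_t_ci(
    dataset: Sequence[ObservationRecord],
    B: int = 2000,
    seed: int = 0,
    tlast: float = 24.0,
    alpha: float = 0.05,
) -> AucEstimate:
    """Bootstrap-t interval for the dose-normalised AUC(0-tlast).

    Animals are resampled with replacement within each time-point batch;
    each replicate's AUC is studentised by its own plug-in SE and the
    resulting t quantiles calibrate the interval around the point estimate.
    Fully reproducible from ``seed``.  Batches with a single animal cannot
    be studentised and are warned about: they contribute their mean but no
    variance.
    """
    if B < 199:
        raise ValueError("B must be >= 199 for quantile stability")
    times, values = _prepare(dataset, tlast)
    if len(times) < 2:
        raise ValueError("AUC needs at least two time points")
    singletons = [float(t) for t, v in zip(times, values) if len(v) == 1]
    if singletons:
        warnings.warn(
            f"time point(s) {singletons} have a single animal and cannot be "
            "studentised; they contribute no variance to the interval",
            stacklevel=2,
        )
    auc_hat, se_hat = _auc_and_se(times, values)
    if se_hat == 0.0:
        return AucEstimate(auc=auc_hat, ci_low=auc_hat, ci_high=auc_hat,
                           n_boot=B, seed=seed)

    rng = np.random.default_rng(seed)
    tstats = _bootstrap_tstats(times, values, auc_hat, B, rng)
    qlo, qhi = np.nanquantile(tstats, [alpha / 2, 1 - alpha / 2])
    return AucEstimate(
        auc=auc_hat,
        ci_low=min(float(auc_hat - qhi * se_hat), auc_hat),
        ci_high=max(float(auc_hat - qlo * se_hat), auc_hat),
        n_boot=B,
        seed=seed,
    )


def _bootstrap_replicates(
    times: np.ndarray, values: list[np.ndarray], B: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised batch resampling: (B,) AUC* and (B,) SE* arrays."""
    w = _trapezoid_weights(times)
    auc_b = np.zeros(B)
    var_b = np.zeros(B)
    for wt, v in zip(w, values):
        n = len(v)
        draw = v[rng.integers(0, n, size=(B, n))]
        m = draw.mean(axis=1)
        auc_b += wt * m
        if n > 1:
            var_b += wt**2 * draw.var(axis=1, ddof=1) / n
    return auc_b, np.sqrt(var_b)


def _bootstrap_tstats(
    times: np.ndarray,
    values: list[np.ndarray],
    auc_hat: float,
    B: int,
    rng: np.random.Generator,
) -> np.ndarray:
    auc_b, se_b = _bootstrap_replicates(times, values, B, rng)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(se_b > 0, (auc_b - auc_hat) / se_b, np.nan)


def auc_ratio(
    dataset: Sequence[ObservationRecord],
    B: int = 2000,
    seed: int = 0,
    tlast: float = 24.0,
    alpha: float = 0.05,
) -> AucRatio:
    """Irradiated/control ratio of dose-normalised AUC(0-tlast).

    The CI is a bootstrap-t interval on the log ratio (delta-method SE from
    the two groups' plug-in SEs); the p-value tests log-ratio = 0 against
    the studentised bootstrap distribution.
    """
    groups = {}
    for g in ("irradiated", "control"):
        sub = [r for r in dataset if r.group == g]
        if not sub:
            raise ValueError(f"no records for group {g!r}")
        groups[g] = _prepare(sub, tlast)
    t_irr, v_irr = groups["irradiated"]
    t_ctl, v_ctl = groups["control"]
    if len(set(t_irr) & set(t_ctl)) < 2:
        raise ValueError("groups share fewer than two sampling times")

    # a ratio of AUCs over different windows is meaningless: truncate both
    # groups to the overlap of their sampled time spans
    t_lo = max(t_irr.min(), t_ctl.min())
    t_hi = min(t_irr.max(), t_ctl.max())
    if (t_irr.min(), t_irr.max()) != (t_ctl.min(), t_ctl.max()):
        warnings.warn(
            f"group time spans differ; AUCs compared over [{t_lo}, {t_hi}] h",
            stacklevel=2,
        )

        def _trunc(t, v):
            keep = (t >= t_lo) & (t <= t_hi)
            return t[keep], [vi for vi, k in zip(v, keep) if k]

        t_irr, v_irr = _trunc(t_irr, v_irr)
        t_ctl, v_ctl = _trunc(t_ctl, v_ctl)
        if len(t_irr) < 2 or len(t_ctl) < 2:
            raise ValueError("groups share fewer than two sampling times")

    rng = np.random.default_rng(seed)
    est = {}
    for key, (t, v) in (("irradiated", (t_irr, v_irr)), ("control", (t_ctl, v_ctl))):
        a, se = _auc_and_se(t, v)
        est[key] = (a, se)

    (a_i, se_i), (a_c, se_c) = est["irradiated"], est["control"]
    log_ratio = np.log(a_i / a_c)
    se_log = float(np.sqrt((se_i / a_i) ** 2 + (se_c / a_c) ** 2))

    auc_bi, se_bi = _bootstrap_replicates(t_irr, v_irr, B, rng)
    auc_bc, se_bc = _bootstrap_replicates(t_ctl, v_ctl, B, rng)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_rb = np.log(auc_bi / auc_bc)
        se_log_b = np.sqrt((se_bi / auc_bi) ** 2 + (se_bc / auc_bc) ** 2)
        t_b = (log_rb - log_ratio) / se_log_b
    t_b = t_b[np.isfinite(t_b)]

    if se_log == 0.0 or len(t_b) == 0:
        ci_low = ci_high = float(np.exp(log_ratio))
        p = 1.0 if log_ratio == 0 else 0.0
    else:
        qlo, qhi = np.quantile(t_b, [alpha / 2, 1 - alpha / 2])
        ci_low = float(np.exp(log_ratio - qhi * se_log))
        ci_high = float(np.exp(log_ratio - qlo * se_log))
        t0 = log_ratio / se_log
        p = float((1.0 + np.sum(np.abs(t_b) >= abs(t0))) / (len(t_b) + 1.0))

    def _as_estimate(a: float, se: float, t: np.ndarray, v: list[np.ndarray]) -> AucEstimate:
        tb = _bootstrap_tstats(t, v, a, B, np.random.default_rng(seed + 1))
        tb = tb[np.isfinite(tb)]
        if se == 0.0 or len(tb) == 0:
            return AucEstimate(a, a, a, B, seed)
        ql, qh = np.quantile(tb, [alpha / 2, 1 - alpha / 2])
        return AucEstimate(
            a, min(float(a - qh * se), a), max(float(a - ql * se), a), B, seed
        )

    return AucRatio(
        ratio=float(np.exp(log_ratio)),
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
        auc_irradiated=_as_estimate(a_i, se_i, t_irr, v_irr),
        auc_control=_as_estimate(a_c, se_c, t_ctl, v_ctl),
    )
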