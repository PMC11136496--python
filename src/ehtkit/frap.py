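"""FRAP junctional-recycling analysis: trace assembly, normalization, fitting.

A FRAP recording is acquired in five steps: a reference z-stack, a 30 s
prebleach time lapse at 1 Hz, the bleach pulse, a 3 min fast-recovery time
lapse at 1 Hz, and a 7 min slow-recovery series of small z-stacks at one
stack per 20 s.  The assembled trace is background-subtracted, normalized to
the prebleach mean, scaled so the bleach floor sits at 0, and fitted with a
single-exponential recovery F(t) = A (1 - exp(-t tau)).  A is the mobile
fraction of the bleached pool, T_half = ln(2)/tau the half-recovery time,
and the early slope (first 30 s, ordinary least squares) a model-free speed
of recovery.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from ehtkit import stats as stats_core
from ehtkit.exceptions import (
    AssemblyError,
    ConfigurationError,
    FitFailed,
    NoBleachDetected,
    NonPositivePrebleach,
    WindowError,
)

__all__ = [
    "PhaseDesign",
    "FrapTrace",
    "NormalizedTrace",
    "FrapFit",
    "assemble_trace",
    "normalize_trace",
    "fit_recovery",
    "early_slope",
    "summarize_groups",
    "group_mean_curves",
]

PHASES = ("prebleach", "fast", "slow")

JUNCTION_TYPES = (
    "EC-EC bi",
    "EC-EC-EC tri",
    "HE-EC",
    "HE-EC-EC",
    "HE-HE-EC",
    "pol+-EC",
    "pol--EC",
)

# fit bounds: mobile fraction may overshoot 1 with noise; tau in 1/s
A_BOUNDS = (0.0, 1.5)
TAU_BOUNDS = (1e-5, 1.0)


@dataclass(frozen=True)
class PhaseDesign:
    """Acquisition timing of the three intensity phases (durations in s)."""

    prebleach_duration: float = 30.0
    prebleach_interval: float = 1.0
    fast_duration: float = 180.0
    fast_interval: float = 1.0
    slow_duration: float = 420.0
    slow_interval: float = 20.0

    def __post_init__(self):
        for name in (
            "prebleach_duration",
            "prebleach_interval",
            "fast_duration",
            "fast_interval",
            "slow_duration",
            "slow_interval",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    def times(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sample times (s) per phase; t = 0 at the bleach pulse.

        Prebleach samples at -duration .. -interval; fast samples start at
        one interval after the bleach; slow samples follow the fast phase.
        The default design yields 30 prebleach, 180 fast and 21 slow samples.
        """
        n_pre = int(round(self.prebleach_duration / self.prebleach_interval))
        pre = -self.prebleach_duration + self.prebleach_interval * np.arange(n_pre)
        n_fast = int(round(self.fast_duration / self.fast_interval))
        fast = self.fast_interval * (1 + np.arange(n_fast))
        n_slow = int(round(self.slow_duration / self.slow_interval))
        slow = fast[-1] + self.slow_interval * np.arange(1, n_slow + 1)
        return pre, fast, slow


@dataclass
class FrapTrace:
    """Assembled multi-phase recording on one unified time base."""

    times: np.ndarray  # s, strictly increasing, t = 0 at bleach
    i_roi: np.ndarray
    i_background: np.ndarray
    phases: np.ndarray  # str array over PHASES
    junction_type: str = "EC-EC bi"
    condition: str = "control"
    drift_flagged: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.i_roi = np.asarray(self.i_roi, dtype=float)
        self.i_background = np.asarray(self.i_background, dtype=float)
        self.phases = np.asarray(self.phases, dtype=object)
        n = self.times.size
        if not (self.i_roi.size == self.i_background.size == self.phases.size == n):
            raise AssemblyError("times, intensities and phases must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise AssemblyError("timestamps must be strictly increasing")
        if int((self.phases == "prebleach").sum()) < 3:
            raise AssemblyError("at least 3 prebleach samples required")


@dataclass
class NormalizedTrace:
    """Post-bleach trace after the three-step normalization chain.

    ``i_bg_norm = i_roi - i_background``; ``i_normalized`` divides the
    post-bleach values by the prebleach mean of ``i_bg_norm``; ``i_fsn``
    rescales so the post-bleach minimum maps to 0 and the prebleach level
    to 1.  Prebleach samples are excluded from fitting.
    """

    times: np.ndarray  # post-bleach times (s)
    i_fsn: np.ndarray
    i_normalized: np.ndarray
    floor: float  # min of i_normalized over post-bleach samples
    prebleach_mean: float
    junction_type: str = "EC-EC bi"
    condition: str = "control"
    drift_flagged: bool = False


@dataclass
class FrapFit:
    """Fitted single-exponential recovery F(t) = A (1 - exp(-t tau))."""

    A: float  # mobile fraction (amplitude of recovery)
    tau: float  # growth-rate constant, 1/s
    t_half: float  # ln(2)/tau, s
    residual_rms: float
    converged: bool
    n_samples: int
    early_slope: float | None = field(default=None)
    junction_type: str = "EC-EC bi"
    condition: str = "control"

    def summary(self) -> str:
        lines = [
            "Single-exponential FRAP recovery fit",
            f"  group               : {self.junction_type} / {self.condition}",
            f"  A (mobile fraction) : {self.A:.4f}",
            f"  tau                 : {self.tau:.5g} 1/s",
            f"  T_half              : {self.t_half:.3f} s",
            f"  residual RMS        : {self.residual_rms:.4g}",
            f"  samples             : {self.n_samples}",
            f"  converged           : {self.converged}",
        ]
        if self.early_slope is not None:
            lines.insert(5, f"  early slope (30 s)  : {self.early_slope:.5g} 1/s")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# assembly and normalization
# ---------------------------------------------------------------------------

def assemble_trace(
    phase_recordings: dict,
    junction_type: str = "EC-EC bi",
    condition: str = "control",
    drift_flagged: bool = False,
) -> FrapTrace:
    """Join per-phase recordings into one trace with t = 0 at the bleach.

    ``phase_recordings`` maps each phase name in ``PHASES`` to a dict (or
    3-tuple) with ``times``, ``roi`` and ``background`` arrays.  Prebleach
    times must be negative, post-bleach positive, and the fast and slow
    phases must not overlap in time.  Drift-flagged recordings are kept but
    the slow phase is dropped so only early recovery is analyzed.
    """
    missing = [p for p in PHASES if p not in phase_recordings]
    if missing:
        raise AssemblyError(f"missing phase recordings: {missing}")

    parts = []
    for phase in PHASES:
        rec = phase_recordings[phase]
        if isinstance(rec, dict):
            t, roi, bg = rec["times"], rec["roi"], rec["background"]
        else:
            t, roi, bg = rec
        t = np.asarray(t, dtype=float)
        if phase == "prebleach" and np.any(t >= 0):
            raise AssemblyError("prebleach times must be negative (t = 0 at bleach)")
        if phase != "prebleach" and np.any(t <= 0):
            raise AssemblyError(f"{phase} times must be positive")
        parts.append((t, np.asarray(roi, float), np.asarray(bg, float), phase))

    if parts[1][0].size and parts[2][0].size and parts[2][0].min() <= parts[1][0].max():
        raise AssemblyError("fast and slow phase timestamps overlap")

    if drift_flagged:
        parts = parts[:2]
        warnings.warn(
            "drift-flagged recording: slow phase truncated, trace kept for early recovery"
        )

    times = np.concatenate([p[0] for p in parts])
    roi = np.concatenate([p[1] for p in parts])
    bg = np.concatenate([p[2] for p in parts])
    phases = np.concatenate([np.full(p[0].size, p[3], dtype=object) for p in parts])
    return FrapTrace(
        times=times,
        i_roi=roi,
        i_background=bg,
        phases=phases,
        junction_type=junction_type,
        condition=condition,
        drift_flagged=drift_flagged,
    )


def normalize_trace(trace: FrapTrace) -> NormalizedTrace:
    """Apply the normalization chain and return the post-bleach scaled trace.

    Chain: background subtraction, division of the post-bleach signal by the
    mean background-subtracted prebleach intensity, then full-scale
    normalization ``(I_norm - min) / (1 - min)`` with the minimum taken over
    post-bleach samples only (prebleach noise must not set the scale floor).
    The chain is invariant to common positive scaling of ROI and background
    and to common additive offsets.
    """
    i_bg_norm = trace.i_roi - trace.i_background
    pre_mask = trace.phases == "prebleach"
    pre_mean = float(i_bg_norm[pre_mask].mean())
    if pre_mean <= 0:
        raise NonPositivePrebleach(
            f"background-subtracted prebleach mean is {pre_mean:.4g}; cannot normalize"
        )
    post_mask = ~pre_mask
    i_normalized = i_bg_norm[post_mask] / pre_mean
    floor = float(i_normalized.min())
    if floor >= 1.0:
        raise NoBleachDetected("post-bleach intensity never drops below the prebleach level")
    i_fsn = (i_normalized - floor) / (1.0 - floor)
    return NormalizedTrace(
        times=trace.times[post_mask],
        i_fsn=i_fsn,
        i_normalized=i_normalized,
        floor=floor,
        prebleach_mean=pre_mean,
        junction_type=trace.junction_type,
        condition=trace.condition,
        drift_flagged=trace.drift_flagged,
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _profiled_amplitude(t: np.ndarray, y: np.ndarray, tau: float) -> tuple[float, float]:
    """Closed-form LS amplitude for fixed tau (model is linear in A)."""
    g = 1.0 - np.exp(-t * tau)
    denom = float(g @ g)
    if denom == 0:
        return 0.0, float(y @ y)
    a = float(np.clip((y @ g) / denom, *A_BOUNDS))
    r = y - a * g
    return a, float(r @ r)


def fit_recovery(
    norm: NormalizedTrace,
    n_tau_starts: int = 40,
    compute_early_slope: bool = True,
) -> FrapFit:
    """Least-squares fit of F(t) = A (1 - exp(-t tau)) to the scaled trace.

    The amplitude is profiled out in closed form (the model is linear in A
    for fixed tau), so the multistart search reduces to a 1-D scan of tau
    over a log-spaced grid spanning the tau bounds, followed by a bounded
    (A, tau) polish.  ``T_half = ln(0.5)/(-tau)``.
    """
    t = np.asarray(norm.times, dtype=float)
    y = np.asarray(norm.i_fsn, dtype=float)
    if t.size < 10:
        raise WindowError(f"need >= 10 post-bleach samples to fit, got {t.size}")

    taus = np.geomspace(TAU_BOUNDS[0], TAU_BOUNDS[1], n_tau_starts)
    best = None
    for tau in taus:
        a, sse = _profiled_amplitude(t, y, tau)
        if best is None or sse < best[2]:
            best = (a, tau, sse)
    a0, tau0, sse0 = best
    if not np.isfinite(sse0):
        raise FitFailed("no converged start for the recovery fit")

    # variable-projection polish: exact 1-D minimization of the profiled SSE
    converged = True
    a_hat, tau_hat, sse = a0, tau0, sse0
    i0 = int(np.argmin(np.abs(taus - tau0)))
    lo = taus[max(i0 - 1, 0)]
    hi = taus[min(i0 + 1, len(taus) - 1)]
    try:
        res = optimize.minimize_scalar(
            lambda lt: _profiled_amplitude(t, y, math.exp(lt))[1],
            bounds=(math.log(lo), math.log(hi)),
            method="bounded",
            options={"xatol": 1e-12},
        )
        tau_p = float(math.exp(res.x))
        a_p, sse_p = _profiled_amplitude(t, y, tau_p)
        if sse_p <= sse0 + 1e-12:
            a_hat, tau_hat, sse = a_p, tau_p, sse_p
        converged = bool(res.success)
    except (RuntimeError, ValueError):
        converged = False  # grid solution kept

    slope = None
    if compute_early_slope:
        try:
            slope = early_slope(norm)
        except WindowError:
            slope = None

    return FrapFit(
        A=a_hat,
        tau=tau_hat,
        t_half=math.log(2.0) / tau_hat,
        residual_rms=math.sqrt(sse / t.size),
        converged=converged,
        n_samples=int(t.size),
        early_slope=slope,
        junction_type=norm.junction_type,
        condition=norm.condition,
    )


def early_slope(norm: NormalizedTrace, window_s: float = 30.0) -> float:
    """OLS slope of I_fsn vs t over the first ``window_s`` seconds post bleach."""
    mask = (norm.times >= 0) & (norm.times <= window_s)
    if int(mask.sum()) < 3:
        raise WindowError(
            f"need >= 3 samples within [0, {window_s}] s, got {int(mask.sum())}"
        )
    slope, _ = np.polyfit(norm.times[mask], norm.i_fsn[mask], 1)
    return float(slope)


# ---------------------------------------------------------------------------
# group summaries
# ---------------------------------------------------------------------------

def summarize_groups(fits: list[FrapFit]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group medians and pairwise rank-sum tests over junction type x condition.

    Returns ``(summary, tests)``: per-group medians of A, T_half and early
    slope with group sizes, and pairwise two-sided Wilcoxon rank-sum
    p-values for each metric.  Pairs involving a single-observation group
    are marked not-applicable (NaN p).
    """
    if not fits:
        return (
            pd.DataFrame(columns=["junction_type", "condition", "n", "A", "t_half", "early_slope"]),
            pd.DataFrame(columns=["metric", "group_a", "group_b", "statistic", "pvalue", "method"]),
        )
    df = pd.DataFrame(
        {
            "junction_type": [f.junction_type for f in fits],
            "condition": [f.condition for f in fits],
            "A": [f.A for f in fits],
            "t_half": [f.t_half for f in fits],
            "early_slope": [f.early_slope for f in fits],
        }
    )
    summary = (
        df.groupby(["junction_type", "condition"])
        .agg(
            n=("A", "size"),
            A=("A", "median"),
            t_half=("t_half", "median"),
            early_slope=("early_slope", "median"),
        )
        .reset_index()
    )

    groups = dict(tuple(df.groupby(["junction_type", "condition"])))
    keys = list(groups)
    rows = []
    for metric in ("A", "t_half", "early_slope"):
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                ka, kb = keys[i], keys[j]
                xa = groups[ka][metric].dropna().to_numpy(dtype=float)
                xb = groups[kb][metric].dropna().to_numpy(dtype=float)
                if xa.size < 2 or xb.size < 2:
                    rows.append(
                        {
                            "metric": metric,
                            "group_a": "/".join(ka),
                            "group_b": "/".join(kb),
                            "statistic": np.nan,
                            "pvalue": np.nan,
                            "method": "not-applicable",
                        }
                    )
                    continue
                res = stats_core.wilcoxon_rank_sum(xa, xb)
                rows.append(
                    {
                        "metric": metric,
                        "group_a": "/".join(ka),
                        "group_b": "/".join(kb),
                        "statistic": res.statistic,
                        "pvalue": res.pvalue,
                        "method": res.method,
                    }
                )
    return summary, pd.DataFrame(rows)


def group_mean_curves(traces: list[NormalizedTrace]) -> pd.DataFrame:
    """Mean I_fsn recovery curve per (junction type, condition) group.

    Traces in a group must share the same post-bleach time base.
    """
    rows = []
    by_group: dict = {}
    for tr in traces:
        by_group.setdefault((tr.junction_type, tr.condition), []).append(tr)
    for (jt, cond), members in by_group.items():
        t0 = members[0].times
        for m in members[1:]:
            if m.times.size != t0.size or not np.allclose(m.times, t0):
                raise ConfigurationError("traces in a group must share a time base")
        mean_curve = np.mean([m.i_fsn for m in members], axis=0)
        for t, v in zip(t0, mean_curve):
            rows.append({"junction_type": jt, "condition": cond, "time_s": t, "i_fsn_mean": v})
    return pd.DataFrame(rows)
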