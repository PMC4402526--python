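"""Replication-trace analysis: velocities, distributions, pauses, rates.

The analysis chain mirrors the standard single-molecule workflow: the
nucleotide-versus-time series is differentiated with a 50-point sliding
linear fit; instantaneous velocities are histogrammed at 5 nt/s and fitted
with a two-Gaussian mixture (an active peak and a zero-velocity pause
peak); pauses are scored as sub-threshold runs longer than a minimum
duration, with the threshold taken midway between the two mixture means;
average rates are slope fits with or without the pause intervals excised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ReplicationTrace",
    "VelocityDistribution",
    "PauseSet",
    "InsufficientDataError",
    "instantaneous_velocity",
    "velocity_distribution",
    "detect_pauses",
    "average_rate",
]


class InsufficientDataError(ValueError):
    """Series too short (or empty after exclusion) for the requested fit."""


@dataclass
class ReplicationTrace:
    """Uniformly sampled tether record: time (s), delta_x (nm), force (pN).

    ``force`` is signed (aiding positive) and may be constant-valued or
    per-sample (ramp experiments).  ``annotations`` optionally carries
    ground truth from the simulator: pause intervals, a detachment flag and
    the generating configuration.
    """

    time: np.ndarray
    delta_x: np.ndarray
    force: np.ndarray
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.delta_x = np.asarray(self.delta_x, dtype=float)
        force = np.asarray(self.force, dtype=float)
        if force.ndim == 0:
            force = np.full_like(self.time, float(force))
        self.force = force
        if not (self.time.size == self.delta_x.size == self.force.size):
            raise ValueError("time, delta_x and force must have equal length")
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if np.ptp(dt) > 0.01 * dt.mean():
                raise ValueError("sampling must be uniform to 1%")

    @property
    def sample_rate(self) -> float:
        if self.time.size < 2:
            raise InsufficientDataError("need >= 2 samples")
        return 1.0 / float(np.mean(np.diff(self.time)))


@dataclass
class VelocityDistribution:
    """Histogram of instantaneous velocities plus a two-Gaussian fit.

    ``means``, ``sds`` and ``weights`` are ordered (zero peak, positive
    peak); weights are the mixture fractions and sum to 1.  ``converged``
    is False when the mixture fit fell back to a single component.
    """

    bin_centers: np.ndarray
    counts: np.ndarray
    means: tuple
    sds: tuple
    weights: tuple
    converged: bool = True

    @property
    def positive_mean(self) -> float:
        return self.means[1]

    @property
    def zero_mean(self) -> float:
        return self.means[0]


@dataclass
class PauseSet:
    """Detected pause intervals and the associated average rates."""

    intervals: list
    density: float
    with_pauses_rate: float
    without_pauses_rate: float
    threshold: float = float("nan")

    @property
    def n_pauses(self) -> int:
        return len(self.intervals)

    def total_duration(self) -> float:
        return float(sum(e - s for s, e in self.intervals))


# ---------------------------------------------------------------------------


def instantaneous_velocity(nt_series, sample_rate: float,
                           window_points: int = 50) -> np.ndarray:
    """Sliding-window least-squares slope of the nucleotide count (nt/s).

    Centered linear fit over ``window_points`` consecutive samples; output
    length is ``len(nt_series) - window_points + 1``.
    """
    y = np.asarray(nt_series, dtype=float)
    w = int(window_points)
    if w < 2:
        raise ValueError("window_points must be >= 2")
    if y.size <= w:
        raise InsufficientDataError(
            f"series of {y.size} points shorter than window {w}")
    # slope = sum(c_i * y_i) with centered integer abscissa
    x = np.arange(w) - (w - 1) / 2.0
    coef = x / np.sum(x * x)
    return np.convolve(y, coef[::-1], mode="valid") * sample_rate


def _two_gauss(x, a1, mu1, s1, a2, mu2, s2):
    return (a1 * np.exp(-0.5 * ((x - mu1) / s1) ** 2)
            + a2 * np.exp(-0.5 * ((x - mu2) / s2) ** 2))


def velocity_distribution(v_series, bin_width: float = 5.0,
                          positive_min: float = 10.0) -> VelocityDistribution:
    """Histogram + two-Gaussian mixture fit of instantaneous velocities.

    One component is initialized at zero (pauses), the other at the robust
    positive mode (histogram maximum above ``positive_min`` nt/s).  On fit
    failure a single-Gaussian fallback is returned with ``converged=False``.
    """
    v = np.asarray(v_series, dtype=float)
    if v.size < 10:
        raise InsufficientDataError("need >= 10 velocity samples")
    lo = np.floor(v.min() / bin_width) * bin_width
    hi = np.ceil(v.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(v, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    pos = centers > positive_min
    if pos.any() and counts[pos].max() > 0:
        mu2_0 = float(centers[pos][np.argmax(counts[pos])])
        a2_0 = float(counts[pos].max())
    else:
        mu2_0 = max(float(np.percentile(v, 75)), positive_min + bin_width)
        a2_0 = max(float(counts.max()), 1.0)
    near0 = np.abs(centers) <= 2 * bin_width
    a1_0 = float(counts[near0].max()) if near0.any() else 1.0
    p0 = [max(a1_0, 1e-3), 0.0, bin_width, a2_0, mu2_0, 2 * bin_width]
    lower = [0, -1.5 * bin_width, bin_width / 10, 0, positive_min,
             bin_width / 10]
    upper = [np.inf, 1.5 * bin_width, 4 * bin_width, np.inf, np.inf,
             50 * bin_width]
    try:
        popt, _ = curve_fit(_two_gauss, centers, counts, p0=p0,
                            bounds=(lower, upper), maxfev=20000)
        a1, mu1, s1, a2, mu2, s2 = popt
        w1, w2 = a1 * s1, a2 * s2
        tot = w1 + w2
        return VelocityDistribution(
            bin_centers=centers, counts=counts,
            means=(float(mu1), float(mu2)),
            sds=(float(s1), float(s2)),
            weights=(float(w1 / tot), float(w2 / tot)),
        )
    except (RuntimeError, ValueError):
        mu, sd = float(np.mean(v)), float(np.std(v) + 1e-12)
        return VelocityDistribution(
            bin_centers=centers, counts=counts,
            means=(mu, mu), sds=(sd, sd), weights=(0.0, 1.0),
            converged=False,
        )


def _slope(t, y):
    t = t - t.mean()
    denom = np.sum(t * t)
    if denom == 0:
        raise InsufficientDataError("degenerate time axis")
    return float(np.sum(t * (y - y.mean())) / denom)


def average_rate(nt_series, sample_rate: float,
                 exclude: PauseSet | None = None) -> float:
    """Least-squares slope of nucleotides vs time (nt/s).

    With ``exclude``, samples inside the pause intervals are removed and
    the time axis compressed so the remaining active segments are fitted as
    one contiguous record.
    """
    y = np.asarray(nt_series, dtype=float)
    if y.size < 2:
        raise InsufficientDataError("need >= 2 samples")
    t = np.arange(y.size) / sample_rate
    if exclude is None or not exclude.intervals:
        return _slope(t, y)
    active = np.ones(y.size, dtype=bool)
    for s, e in exclude.intervals:
        active &= ~((t >= s) & (t <= e))
    if active.sum() < 2:
        raise InsufficientDataError("no active samples left after exclusion")
    t_act = np.cumsum(active) / sample_rate  # compressed time
    return _slope(t_act[active], y[active])


def detect_pauses(nt_series, sample_rate: float, min_duration: float = 0.4,
                  v_threshold: float | None = None,
                  window_points: int = 50) -> PauseSet:
    """Score pauses as sub-threshold runs of the instantaneous velocity.

    The threshold defaults to the midpoint of the two fitted mixture means;
    if the mixture fit does not converge an explicit ``v_threshold`` is
    required.  Returns the pause intervals (seconds, in trace time), the
    pause density per 100 nt, and the average rates with and without the
    pause intervals.
    """
    y = np.asarray(nt_series, dtype=float)
    v = instantaneous_velocity(y, sample_rate, window_points)
    if v_threshold is None:
        dist = velocity_distribution(v)
        if not dist.converged:
            raise InsufficientDataError(
                "mixture fit failed; pass an explicit v_threshold")
        v_threshold = 0.5 * (dist.zero_mean + dist.positive_mean)

    below = np.abs(v) < v_threshold
    # run-length encode
    intervals = []
    offset = (window_points - 1) / 2.0  # window center index offset
    i = 0
    n = below.size
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            start = (i + offset) / sample_rate
            end = (j + offset) / sample_rate
            if end - start >= min_duration:
                intervals.append((float(start), float(end)))
            i = j + 1
        else:
            i += 1

    with_rate = average_rate(y, sample_rate)
    total_nt = abs(y[-1] - y[0])
    density = 100.0 * len(intervals) / total_nt if total_nt > 0 else 0.0
    pset = PauseSet(intervals=intervals, density=density,
                    with_pauses_rate=with_rate,
                    without_pauses_rate=with_rate, threshold=float(v_threshold))
    if intervals:
        pset.without_pauses_rate = average_rate(y, sample_rate, exclude=pset)
    return pset
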