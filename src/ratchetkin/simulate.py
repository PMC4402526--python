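"""Stochastic generation of replication traces and force-velocity data.

Single-nucleotide stepping through the Brownian-ratchet cycle is simulated
with the Gillespie algorithm over the three states {pre-translocated free,
post-translocated free, dNTP-bound}; each completed cycle incorporates one
nucleotide.  The event log is sampled at the instrument rate (60 Hz),
converted to a tether-length change through the DNA elasticity model, and
degraded with Gaussian measurement noise and off-pathway, load-independent
pauses (Poisson arrivals, exponential durations).  Two load schedules are
supported: constant force (force feedback) and a force ramp (no feedback:
the load builds as the tether shortens against a fixed trap, ending in a
flagged detachment when the smoothed active velocity falls below the
empirical detachment criterion).

Force-velocity tables are generated directly from the closed-form ratchet
velocity with Gaussian relative noise, emulating per-condition replicate
averaging (records carry SEM = sd/sqrt(n)).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .kinetics import (
    KBT_22C,
    InvalidParameterError,
    MMCoefficients,
    RatchetRates,
    bell_rate,
    velocity_model3,
)
from .polymer import PolymerParams, conversion_strand, extension_per_nt
from .traces import ReplicationTrace

__all__ = [
    "SimConfig",
    "EventLog",
    "simulate_cycle",
    "synthesize_trace",
    "synthesize_fv_dataset",
    "DEFAULT_FV_FORCES",
    "DEFAULT_FV_DNTPS",
    "RECOVERY_FORCES",
]

#: Default force-velocity grid (pN): hindering -30 to aiding +20, step 5.
DEFAULT_FV_FORCES = tuple(float(f) for f in range(-30, 25, 5))
#: Default dNTP levels (uM), as in the titration experiments.
DEFAULT_FV_DNTPS = (5.0, 10.0, 50.0, 100.0, 200.0, 500.0)
#: 7-force design used for parameter-recovery studies.
RECOVERY_FORCES = (-30.0, -25.0, -20.0, -15.0, -10.0, -5.0, 20.0)

_PRE, _POST, _BOUND = 0, 1, 2


@dataclass
class EventLog:
    """Continuous-time trajectory of the incorporation cycle.

    ``times[i]`` is when the system *entered* ``states[i]`` at position
    ``positions[i]`` (nucleotides advanced, including the +-1 nt
    translocation offset).  ``completed`` counts incorporated nucleotides;
    ``stalled`` flags a run cut off by the event cap rather than by
    reaching the target length.
    """

    times: np.ndarray
    states: np.ndarray
    positions: np.ndarray
    completed: int
    stalled: bool = False

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    def mean_rate(self) -> float:
        """Mean stepping rate over the whole log (nt/s)."""
        if self.duration == 0:
            return 0.0
        return float(self.positions[-1]) / self.duration

    def dwell_fractions(self) -> dict:
        """Fraction of time spent in each state (pre, post, bound)."""
        dt = np.diff(self.times)
        tot = dt.sum()
        out = {}
        for name, code in (("pre", _PRE), ("post", _POST), ("bound", _BOUND)):
            out[name] = float(dt[self.states[:-1] == code].sum() / tot)
        return out


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a synthetic replication experiment.

    Defaults reproduce the study conditions: 60 Hz sampling, 2 nm
    measurement noise, a 229 nt single-stranded stretch followed by a
    3487 bp duplex, load-independent off-pathway pauses, and a 7 nt/s
    detachment criterion.  ``force`` is signed (aiding positive); in ramp
    mode it is the starting load and the trap stiffness converts tether
    shortening into additional hindering load.
    """

    rates: RatchetRates = field(default_factory=RatchetRates)
    dNTP: float = 500.0
    schedule: str = "constant"  # "constant" | "ramp"
    force: float = -10.0
    trap_stiffness: float = 0.1  # pN/nm, ramp mode
    template_ss_nt: int = 229
    template_ds_bp: int = 3487
    replication_mode: str = "strand_displacement"
    sample_rate: float = 60.0
    noise_sd: float = 2.0
    pause_entry_rate: float = 0.05  # 1/s
    pause_mean_duration: float = 1.0  # s
    v_detach: float = 7.0
    seed: int = 0
    n_nucleotides: int | None = None
    max_duration: float = 600.0
    kBT: float = KBT_22C
    polymer: PolymerParams = field(default_factory=PolymerParams)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise InvalidParameterError("sample_rate must be positive")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.pause_entry_rate < 0 or self.pause_mean_duration < 0:
            raise InvalidParameterError("pause parameters must be >= 0")
        if self.schedule not in ("constant", "ramp"):
            raise InvalidParameterError(f"unknown schedule {self.schedule!r}")
        if self.replication_mode not in ("strand_displacement",
                                         "primer_extension"):
            raise InvalidParameterError(
                f"unknown replication mode {self.replication_mode!r}")
        if self.dNTP < 0:
            raise InvalidParameterError("dNTP must be >= 0")

    @property
    def geometry(self) -> str:
        return "opposing" if self.force < 0 else "aiding"

    @property
    def template_limit(self) -> int:
        if self.replication_mode == "primer_extension":
            return self.template_ss_nt
        return self.template_ds_bp

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def simulate_cycle(rates: RatchetRates, F: float, dNTP: float,
                   n_nucleotides: int, seed=None, kBT: float = KBT_22C,
                   max_events: int | None = None) -> EventLog:
    """Gillespie simulation of the ratchet cycle at fixed load.

    Exponential waiting times with the Bell-modulated propensities; the
    mechanical position advances by one nucleotide at each forward
    translocation (and retreats at each backward one); a completed cycle
    leaves the position unchanged since translocation precedes binding.
    Stops at ``n_nucleotides`` advanced, or earlier at the event cap (the
    partial log is returned with ``stalled=True``).
    """
    if n_nucleotides < 1:
        raise InvalidParameterError("n_nucleotides must be >= 1")
    rng = np.random.default_rng(seed)
    kT = bell_rate(rates.k_T0, rates.d_T, F, kBT)
    kmT = bell_rate(rates.k_mT0, -rates.d_mT, F, kBT)
    kon = rates.k_on * dNTP
    if max_events is None:
        max_events = 400 * n_nucleotides + 100_000

    times = [0.0]
    states = [_PRE]
    positions = [0]
    t, state, completed, offset = 0.0, _PRE, 0, 0
    for _ in range(max_events):
        if state == _PRE:
            rate_tot = kT
            t += rng.exponential(1.0 / rate_tot)
            state, offset = _POST, 1
        elif state == _POST:
            rate_tot = kmT + kon
            if rate_tot <= 0:
                return EventLog(np.array(times), np.array(states),
                                np.array(positions), completed, stalled=True)
            t += rng.exponential(1.0 / rate_tot)
            if rng.random() < kmT / rate_tot:
                state, offset = _PRE, 0
            else:
                state = _BOUND
        else:  # _BOUND
            rate_tot = rates.k_off + rates.k_cat
            t += rng.exponential(1.0 / rate_tot)
            if rates.k_off > 0 and rng.random() < rates.k_off / rate_tot:
                state = _POST
            else:
                state, offset = _PRE, 0
                completed += 1
        times.append(t)
        states.append(state)
        positions.append(completed + offset)
        if completed + offset >= n_nucleotides:
            return EventLog(np.array(times), np.array(states),
                            np.array(positions), completed)
    return EventLog(np.array(times), np.array(states),
                    np.array(positions), completed, stalled=True)


def _draw_pauses(rng, active_duration: float, entry_rate: float,
                 mean_duration: float):
    """Poisson pause arrivals on the active-time axis -> wall intervals.

    Returns (wall_starts, durations); wall time inserts each pause's
    duration at its arrival point.
    """
    if entry_rate <= 0 or mean_duration <= 0:
        return np.empty(0), np.empty(0)
    arrivals = []
    t = rng.exponential(1.0 / entry_rate)
    while t < active_duration:
        arrivals.append(t)
        t += rng.exponential(1.0 / entry_rate)
    arrivals = np.asarray(arrivals)
    durations = rng.exponential(mean_duration, size=arrivals.size)
    wall_starts = arrivals + np.concatenate(([0.0], np.cumsum(durations[:-1])))
    return wall_starts, durations


def _active_time(t_wall, wall_starts, durations):
    """Map wall-clock sample times to active (pause-excised) time."""
    if wall_starts.size == 0:
        return np.asarray(t_wall, dtype=float)
    cum = np.concatenate(([0.0], np.cumsum(durations)))
    idx = np.searchsorted(wall_starts, t_wall, side="right")
    tau = np.asarray(t_wall, dtype=float) - cum[idx]
    # inside pause idx-1: freeze at the pause's activation point
    last = np.clip(idx - 1, 0, None)
    in_pause = (idx > 0) & (t_wall < wall_starts[last] + durations[last])
    frozen = wall_starts[last] - cum[last]
    return np.where(in_pause, frozen, tau)


def synthesize_trace(config: SimConfig) -> ReplicationTrace:
    """Generate one noisy replication trace from a SimConfig.

    Deterministic given the config (including seed).  Ground truth (pause
    intervals, true nucleotide series, detachment flag, config) is attached
    under ``trace.annotations``.
    """
    if config.schedule == "ramp":
        return _synthesize_ramp_trace(config)
    rng = np.random.default_rng(config.seed)
    n_nt = config.n_nucleotides or config.template_limit
    log = simulate_cycle(config.rates, config.force, config.dNTP, n_nt,
                         seed=rng, kBT=config.kBT)
    strand = conversion_strand(config.replication_mode, config.geometry)
    spacing = extension_per_nt(abs(config.force), strand, config.polymer,
                               config.kBT)
    sign = -1.0 if config.geometry == "opposing" else 1.0

    wall_starts, durations = _draw_pauses(
        rng, log.duration, config.pause_entry_rate, config.pause_mean_duration)
    total = min(log.duration + durations.sum(), config.max_duration)
    t = np.arange(0.0, total, 1.0 / config.sample_rate)
    tau = np.clip(_active_time(t, wall_starts, durations), 0.0, log.duration)
    pos = log.positions[
        np.clip(np.searchsorted(log.times, tau, side="right") - 1, 0, None)]
    delta_x = sign * pos * spacing
    if config.noise_sd > 0:
        delta_x = delta_x + rng.normal(0.0, config.noise_sd, size=t.size)

    pauses = [(float(s), float(min(s + d, t[-1] if t.size else s)))
              for s, d in zip(wall_starts, durations) if s < total]
    return ReplicationTrace(
        time=t, delta_x=delta_x,
        force=np.full(t.size, float(config.force)),
        annotations={
            "pauses": pauses,
            "detached": False,
            "true_nt": pos.astype(float),
            "config": config.to_dict(),
        },
    )


def _synthesize_ramp_trace(config: SimConfig) -> ReplicationTrace:
    """No-feedback (force ramp) trace ending in a flagged detachment.

    The load starts at ``config.force`` (hindering) and grows as the trap
    converts tether shortening into force.  Detachment is declared when the
    stepping velocity, smoothed over 2 s of *active* (pause-free) time,
    first falls below ``v_detach``; the smoothing uses the noise-free
    stepping record so the termination reflects the enzyme, not the
    measurement noise.
    """
    if config.force >= 0:
        raise InvalidParameterError("ramp schedule expects a hindering "
                                    "(negative) starting force")
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.sample_rate
    strand = conversion_strand(config.replication_mode, "opposing")
    n_window = max(int(round(2.0 * config.sample_rate)), 2)

    kon = config.rates.k_on * config.dNTP
    state, offset, completed = _PRE, 0, 0
    F = float(config.force)
    dx_true = 0.0
    t_list, x_list, f_list = [], [], []
    pause_left = 0.0
    next_pause = (rng.exponential(1.0 / config.pause_entry_rate)
                  if config.pause_entry_rate > 0 else np.inf)
    active_t = 0.0
    pauses, pause_open = [], None
    window = []  # (active_time, position) of recent active samples
    detached = False
    n_max = int(config.max_duration * config.sample_rate)
    limit = config.n_nucleotides or config.template_limit

    for i in range(n_max):
        t_now = i * dt
        if pause_left > 0:
            pause_left = max(0.0, pause_left - dt)
            if pause_left == 0 and pause_open is not None:
                pauses.append((pause_open, t_now))
                pause_open = None
        else:
            if active_t >= next_pause:
                pause_left = rng.exponential(config.pause_mean_duration)
                pause_open = t_now
                next_pause = active_t + rng.exponential(
                    1.0 / config.pause_entry_rate)
            else:
                # Gillespie within this sample interval at the current load
                kT = bell_rate(config.rates.k_T0, config.rates.d_T, F,
                               config.kBT)
                kmT = bell_rate(config.rates.k_mT0, -config.rates.d_mT, F,
                                config.kBT)
                t_in = 0.0
                while True:
                    if state == _PRE:
                        rate_tot = kT
                    elif state == _POST:
                        rate_tot = kmT + kon
                    else:
                        rate_tot = config.rates.k_off + config.rates.k_cat
                    if rate_tot <= 0:
                        break
                    t_in += rng.exponential(1.0 / rate_tot)
                    if t_in > dt:
                        break
                    if state == _PRE:
                        state, offset = _POST, 1
                        dx_true -= extension_per_nt(abs(F), strand,
                                                    config.polymer, config.kBT)
                    elif state == _POST:
                        if rng.random() < kmT / rate_tot:
                            state, offset = _PRE, 0
                            dx_true += extension_per_nt(
                                abs(F), strand, config.polymer, config.kBT)
                        else:
                            state = _BOUND
                    else:
                        if (config.rates.k_off > 0 and rng.random()
                                < config.rates.k_off / rate_tot):
                            state = _POST
                        else:
                            state, offset = _PRE, 0
                            completed += 1
                active_t += dt
                window.append((active_t, completed + offset))
                if len(window) > n_window:
                    window.pop(0)
                F = float(config.force) + config.trap_stiffness * dx_true

        noise = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
        t_list.append(t_now)
        x_list.append(dx_true + noise)
        f_list.append(F)

        if len(window) == n_window:
            (t0, p0), (t1, p1) = window[0], window[-1]
            if t1 > t0 and (p1 - p0) / (t1 - t0) < config.v_detach:
                detached = True
                break
        if completed + offset >= limit:
            break

    if pause_open is not None:
        pauses.append((pause_open, t_list[-1]))
    return ReplicationTrace(
        time=np.asarray(t_list), delta_x=np.asarray(x_list),
        force=np.asarray(f_list),
        annotations={
            "pauses": pauses,
            "detached": detached,
            "detachment_force": abs(F) if detached else None,
            "config": config.to_dict(),
        },
    )


def synthesize_fv_dataset(coeffs: MMCoefficients = MMCoefficients(),
                          forces=DEFAULT_FV_FORCES, dNTPs=DEFAULT_FV_DNTPS,
                          rel_noise: float = 0.08, n_replicates: int = 8,
                          seed=None, kBT: float = KBT_22C,
                          velocity_fn=None) -> pd.DataFrame:
    """Force-velocity table drawn around the closed-form ratchet velocity.

    Each (force, dNTP) cell averages ``n_replicates`` Gaussian draws with
    relative SD ``rel_noise``; the record carries the replicate mean and
    SEM = sd/sqrt(n).  With ``rel_noise=0`` the table lies exactly on the
    closed form (SEM 0, meaning unweighted fits downstream).  Pass
    ``velocity_fn(F, dNTP) -> nt/s`` to generate under an alternative
    model (e.g. one of the power-stroke variants) instead of the ratchet
    closed form.
    """
    forces = np.asarray(forces, dtype=float)
    dNTPs = np.asarray(dNTPs, dtype=float)
    if forces.size == 0 or dNTPs.size == 0:
        raise InvalidParameterError("force and dNTP grids must be non-empty")
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    if velocity_fn is None:
        velocity_fn = lambda F, C: velocity_model3(F, C, coeffs, kBT)
    rows = []
    for F in forces:
        for C in dNTPs:
            v_true = velocity_fn(F, C)
            if rel_noise > 0:
                draws = rng.normal(v_true, rel_noise * v_true,
                                   size=n_replicates)
                v, sem = draws.mean(), draws.std(ddof=1) / np.sqrt(n_replicates)
            else:
                v, sem = v_true, 0.0
            rows.append((F, C, v, sem, n_replicates))
    return pd.DataFrame(rows, columns=["force_pN", "dntp_uM",
                                       "velocity_nt_s", "sem_nt_s", "n"])
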