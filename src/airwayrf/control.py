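"""Target temperature profile and PID voltage controller.

The generator commands a set-point that ramps linearly to the hold
temperature over the ramp period and then stays constant, and updates
the drive voltage every 50 ms from the temperature error using

    V(t) = kp * e(t) + ki * integral(e) + kd * de/dt

with e = T_target - T_measured.  The default gains (kp = 20 V/C,
ki = 60 V/(C s), kd = 0) make it effectively a PI controller; the
derivative path is retained but, if ever enabled, acts on the
measurement rather than the error to avoid set-point kick.  The output
is clamped and the integral is frozen while the clamp is active
(conditional-integration anti-windup), which keeps the 1e-6 s startup
transient from winding up the integrator.  The output is held
piecewise-constant between updates (zero-order hold).

By default the simulation evaluates the control law continuously — at
every solver step — mirroring a control expression living inside the
transient solve; the generator's 50 ms cadence remains the telemetry
sampling interval and is available as a strict zero-order-hold mode
(``cadence="interval"``), in which updates are only accepted at
multiples of the update interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class TargetProfile:
    """Set-point curve: linear ramp then constant hold (deg C, s)."""

    T_start: float = 41.0
    T_hold: float = 65.0
    ramp_duration: float = 0.5
    total_duration: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.ramp_duration <= self.total_duration:
            raise ValueError("need 0 < ramp_duration <= total_duration")


def target_temperature(t: float, profile: TargetProfile) -> float:
    """Commanded temperature at time t within the activation window."""
    eps = 1e-9
    if t < -eps or t > profile.total_duration + eps:
        raise ValueError(
            f"t={t} outside activation window [0, {profile.total_duration}]"
        )
    if t >= profile.ramp_duration:
        return profile.T_hold
    frac = max(t, 0.0) / profile.ramp_duration
    return profile.T_start + frac * (profile.T_hold - profile.T_start)


@dataclass
class ControllerState:
    """PID gains, clamp, cadence, and integrator memory."""

    kp: float = 20.0
    ki: float = 60.0
    kd: float = 0.0
    update_interval: float = 0.05
    v_min: float = 0.0
    v_max: float = 50.0
    integral: float = 0.0
    prev_error: float | None = None
    prev_measured: float | None = None
    prev_time: float | None = None


class PIDController:
    """Discrete PID on the zero-order-hold cadence of the RF generator.

    Logs (t, target, measured, error, P, I, D, output) per update.
    """

    def __init__(self, state: ControllerState, profile: TargetProfile,
                 enforce_cadence: bool = True, log_updates: bool = True):
        self.state = state
        self.profile = profile
        self.enforce_cadence = enforce_cadence
        self.log_updates = log_updates
        self.log: list[dict] = []

    def update(self, T_measured: float, t: float) -> float:
        s = self.state
        ratio = t / s.update_interval
        if self.enforce_cadence and abs(ratio - round(ratio)) > 1e-6:
            raise ValueError(
                f"controller called at t={t}, not a multiple of the "
                f"{s.update_interval} s update interval"
            )
        if s.prev_time is not None and t <= s.prev_time:
            raise ValueError("controller time must be strictly increasing")

        e = target_temperature(t, self.profile) - T_measured
        if s.prev_time is None:
            integral_trial = s.integral
            d_term = 0.0
        else:
            dt = t - s.prev_time
            integral_trial = s.integral + 0.5 * (e + s.prev_error) * dt
            # Derivative on measurement (sign flipped) to avoid set-point kick.
            d_term = -s.kd * (T_measured - s.prev_measured) / dt

        raw = s.kp * e + s.ki * integral_trial + d_term
        if raw > s.v_max and e > 0:
            integral_trial = s.integral  # freeze while saturated high
            raw = s.kp * e + s.ki * integral_trial + d_term
        elif raw < s.v_min and e < 0:
            integral_trial = s.integral  # freeze while saturated low
            raw = s.kp * e + s.ki * integral_trial + d_term
        out = float(np.clip(raw, s.v_min, s.v_max))

        s.integral = integral_trial
        s.prev_error = e
        s.prev_measured = T_measured
        s.prev_time = t
        if not self.log_updates:
            return out
        self.log.append({
            "t_s": t,
            "target_C": target_temperature(t, self.profile),
            "measured_C": T_measured,
            "error_C": e,
            "p_term_V": s.kp * e,
            "i_term_V": s.ki * s.integral,
            "d_term_V": d_term,
            "output_V": out,
        })
        return out


def pid_update(state: ControllerState, T_measured: float, t: float,
               profile: TargetProfile) -> float:
    """One controller update on an externally held state (functional form)."""
    return PIDController(state, profile).update(T_measured, t)
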