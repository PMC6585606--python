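"""Two-site stochastic activation dynamics for limb selection.

The model describes the choice between the preferred (P) and nonpreferred
(NP) hand for a unimanual grasp as a competition between two neural sites
coupled by asymmetric mutual inhibition:

    tau * du_P/dt  = -u_P  + h - c_P  * sigma(u_NP) + I_P  + n * xi_P(t)
    tau * du_NP/dt = -u_NP + h - c_NP * sigma(u_P)  + I_NP + n * xi_NP(t)

``h`` is the resting level to which activation decays without input,
``sigma`` a logistic nonlinearity of steepness ``beta``, and ``I`` the total
(sensory + memory) input to each site.  Handedness is carried by the
inhibition asymmetry ``c_P < c_NP``: the preferred site inhibits its rival
more strongly than it is inhibited itself.  ``xi`` are independent
standard-normal fluctuations of strength ``n``.

Trials are integrated with a forward Euler scheme from the resting state;
the limb whose site is more active at the end of the trial is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "PREFERRED",
    "NONPREFERRED",
    "NOISE_DIALECTS",
    "ModelParameters",
    "ActivationState",
    "Trajectory",
    "TrialOutcome",
    "IntegrationDivergedError",
    "sigmoid",
    "drift",
    "euler_step",
    "simulate_trial",
    "simulate_trials_batch",
    "select_limb",
]

PREFERRED: Literal["P"] = "P"
NONPREFERRED: Literal["NP"] = "NP"

#: Recognised noise-injection schemes for the Euler update.
#:
#: ``sqrt-dt`` (default): du = (dt/tau)*drift + n*sqrt(dt)*xi — the
#: diffusion-consistent Euler–Maruyama scaling, with the noise term entering
#: the rate of change directly rather than through the relaxation factor.
#: ``per-step``: du = (dt/tau)*(drift + n*xi) — a literal per-step reading of
#: the model equation, in which the effective noise shrinks linearly with dt.
NOISE_DIALECTS = ("sqrt-dt", "per-step")


class IntegrationDivergedError(RuntimeError):
    """Raised when an activation becomes non-finite during integration."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"activation became non-finite at Euler step {step}")


@dataclass(frozen=True)
class ModelParameters:
    """Dynamical constants of the two-site system.

    Parameters
    ----------
    c_p, c_np
        Inhibition strengths onto the preferred / nonpreferred site.
        Handedness requires ``c_p < c_np``; both must be nonnegative.
    noise_strength
        Amplitude ``n`` of the additive fluctuations (activation units).
    tau
        Relaxation time constant, in model time units.
    h
        Resting level (activation units).
    beta
        Steepness of the logistic inhibition nonlinearity.
    dt
        Euler step, in model time units.  One model time unit maps to 0.1 s,
        so the default 400 steps of 0.05 span a 2-s selection process.
    n_steps
        Number of Euler steps per trial.
    noise_dialect
        One of :data:`NOISE_DIALECTS`.
    """

    c_p: float
    c_np: float
    noise_strength: float
    tau: float = 3.0
    h: float = -2.0
    beta: float = 2.0
    dt: float = 0.05
    n_steps: int = 400
    noise_dialect: str = "sqrt-dt"

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")
        if self.noise_strength < 0:
            raise ValueError(f"noise_strength must be >= 0, got {self.noise_strength}")
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if self.c_p < 0 or self.c_np < 0:
            raise ValueError("inhibition strengths must be nonnegative")
        if self.noise_dialect not in NOISE_DIALECTS:
            raise ValueError(
                f"unknown noise dialect {self.noise_dialect!r}; "
                f"expected one of {NOISE_DIALECTS}"
            )

    def replace(self, **changes) -> "ModelParameters":
        return replace(self, **changes)


class ActivationState(NamedTuple):
    """Instantaneous activation of the two sites."""

    u_p: float
    u_np: float


@dataclass(frozen=True)
class Trajectory:
    """Record of one trial's integration: n_steps + 1 states."""

    times: np.ndarray
    u_p: np.ndarray
    u_np: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.u_p) == len(self.u_np)):
            raise ValueError("trajectory arrays must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def states(self) -> list[ActivationState]:
        return [ActivationState(p, q) for p, q in zip(self.u_p, self.u_np)]

    @property
    def final_state(self) -> ActivationState:
        return ActivationState(float(self.u_p[-1]), float(self.u_np[-1]))

    def to_frame(self) -> pd.DataFrame:
        """Tidy representation with columns step, time, u_P, u_NP."""
        return pd.DataFrame(
            {
                "step": np.arange(len(self.times)),
                "time": self.times,
                "u_P": self.u_p,
                "u_NP": self.u_np,
            }
        )


@dataclass(frozen=True)
class TrialOutcome:
    """Selection read out from the final state of one trial."""

    selected: str  # PREFERRED or NONPREFERRED
    final_state: ActivationState
    tie_broken: bool = False


def sigmoid(u, beta: float = 2.0):
    """Logistic nonlinearity ``1 / (1 + exp(-beta * u))``.

    Strictly increasing, maps the real line onto (0, 1) with
    ``sigmoid(0) == 0.5``.  Accepts scalars or arrays.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    # scipy.special.expit is equivalent; the explicit form keeps the single
    # nonlinearity of the model visible and overflow-safe via clipping.
    x = np.clip(np.multiply(beta, u), -500.0, 500.0)
    return 1.0 / (1.0 + np.exp(-x))


def drift(state: ActivationState, params: ModelParameters,
          drive_p: float, drive_np: float) -> tuple[float, float]:
    """Deterministic time-derivatives (du_P/dt, du_NP/dt) at ``state``."""
    u_p, u_np = state
    du_p = (-u_p + params.h - params.c_p * sigmoid(u_np, params.beta) + drive_p) / params.tau
    du_np = (-u_np + params.h - params.c_np * sigmoid(u_p, params.beta) + drive_np) / params.tau
    return float(du_p), float(du_np)


def _noise_scale(params: ModelParameters) -> float:
    """Per-step standard deviation of the additive noise increment."""
    if params.noise_dialect == "sqrt-dt":
        return params.noise_strength * np.sqrt(params.dt)
    # per-step: noise treated as part of the bracket, scaled like the drift
    return params.noise_strength * params.dt / params.tau


def euler_step(u_p, u_np, params: ModelParameters,
               drive_p, drive_np, xi_p, xi_np):
    """One forward Euler update; vectorises over leading array dimensions."""
    a = params.dt / params.tau
    s = _noise_scale(params)
    new_p = u_p + a * (-u_p + params.h - params.c_p * sigmoid(u_np, params.beta) + drive_p) + s * xi_p
    new_np = u_np + a * (-u_np + params.h - params.c_np * sigmoid(u_p, params.beta) + drive_np) + s * xi_np
    return new_p, new_np


def select_limb(final_state: ActivationState,
                rng: np.random.Generator) -> tuple[str, bool]:
    """Read out the selected limb: argmax of final activation.

    An exact tie is broken by a fair draw from ``rng`` and flagged.
    """
    u_p, u_np = final_state
    if not (np.isfinite(u_p) and np.isfinite(u_np)):
        raise ValueError("final activations must be finite")
    if u_p > u_np:
        return PREFERRED, False
    if u_np > u_p:
        return NONPREFERRED, False
    return (PREFERRED if rng.uniform() < 0.5 else NONPREFERRED), True


def simulate_trial(params: ModelParameters, drive_p: float, drive_np: float,
                   rng: np.random.Generator) -> tuple[TrialOutcome, Trajectory]:
    """Integrate one trial from rest and read out the selected limb.

    Both sites start at the resting level ``h``; the drives are constant for
    the whole trial.  Noise is drawn as one standard-normal pair per step
    (consumed from ``rng`` in step order), so identical generator states give
    identical trajectories.  Noise draws are consumed even when
    ``noise_strength == 0`` to keep the stream position independent of the
    noise level.
    """
    n = params.n_steps
    u_p = np.empty(n + 1)
    u_np = np.empty(n + 1)
    u_p[0] = u_np[0] = params.h
    xi = rng.standard_normal((n, 2))
    for k in range(n):
        u_p[k + 1], u_np[k + 1] = euler_step(
            u_p[k], u_np[k], params, drive_p, drive_np, xi[k, 0], xi[k, 1]
        )
        if not (np.isfinite(u_p[k + 1]) and np.isfinite(u_np[k + 1])):
            raise IntegrationDivergedError(k + 1)
    times = np.arange(n + 1) * params.dt
    traj = Trajectory(times=times, u_p=u_p, u_np=u_np)
    selected, tie = select_limb(traj.final_state, rng)
    return TrialOutcome(selected=selected, final_state=traj.final_state,
                        tie_broken=tie), traj


def simulate_trials_batch(params: ModelParameters,
                          drive_p: np.ndarray, drive_np: np.ndarray,
                          xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integrate one trial for a whole cohort in lockstep.

    Parameters
    ----------
    drive_p, drive_np
        Arrays of shape ``(m,)`` with each participant's constant drives.
    xi
        Pre-drawn noise of shape ``(m, n_steps, 2)``; row ``i`` must come
        from participant ``i``'s own generator, drawn exactly as
        ``rng.standard_normal((n_steps, 2))``, so that batch results are
        bit-identical to the scalar :func:`simulate_trial` path.

    Returns
    -------
    (u_p, u_np)
        Final activations, each of shape ``(m,)``.
    """
    m = len(drive_p)
    if xi.shape != (m, params.n_steps, 2):
        raise ValueError(f"xi has shape {xi.shape}, expected {(m, params.n_steps, 2)}")
    u_p = np.full(m, params.h, dtype=float)
    u_np = np.full(m, params.h, dtype=float)
    for k in range(params.n_steps):
        u_p, u_np = euler_step(u_p, u_np, params, drive_p, drive_np,
                               xi[:, k, 0], xi[:, k, 1])
        if not (np.all(np.isfinite(u_p)) and np.all(np.isfinite(u_np))):
            raise IntegrationDivergedError(k + 1)
    return u_p, u_np
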