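"""Single-cell adapted FitzHugh-Nagumo model of the cAMP relay circuit.

The cell is a two-variable excitable system: an activator A (proxy for
cytosolic cAMP) with cubic positive feedback f(A) = A - A^3/3, and a slower
repressor R providing negative feedback.  Extracellular cAMP enters through
a logarithmic pre-processing module I(x) = a*log(1 + x/Kd) (natural log; a
fold-change sensor), so the cell responds to relative, not absolute,
concentration changes:

    dA/dt = A - A^3/3 - R + I([cAMP]_ex) + eta(t)
    dR/dt = epsilon * (A - gamma*R + c0)

with Gaussian white noise <eta(t) eta(t')> = sigma^2 delta(t-t').  In the
absence of external cAMP the unique fixed point is stable and the cell is
excitable; a sufficiently large constant drive destabilizes it through a
supercritical Hopf bifurcation and the cell oscillates.

Stochastic trajectories are integrated with the Euler-Maruyama scheme
(state += drift*dt + sigma*sqrt(dt)*xi) at a default step dt = 0.005.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _kernels
from .params import CellParams, SimConfig
from .stimulus import StimulusProtocol, constant_protocol

__all__ = [
    "CellTrace",
    "IntegrationError",
    "input_signal",
    "drift_field",
    "nullclines",
    "fixed_points",
    "hopf_threshold",
    "simulate_cell",
]

_NOISE_MODE = {"activator": _kernels.NOISE_ACTIVATOR,
               "external": _kernels.NOISE_EXTERNAL,
               "none": _kernels.NOISE_NONE}


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""

    def __init__(self, t: float):
        self.t = t
        super().__init__(f"integration diverged (non-finite state) at t={t:g}")


@dataclass(frozen=True)
class CellTrace:
    """Uniformly sampled activator/repressor trajectory of one cell."""

    times: np.ndarray
    A: np.ndarray
    R: np.ndarray
    input: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.A) == len(self.R) == len(self.input) == n):
            raise ValueError("times, A, R, input must have equal length")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def window(self, t_start: float, t_stop: float | None = None) -> "CellTrace":
        """Restrict to times in [t_start, t_stop]."""
        t_stop = self.times[-1] if t_stop is None else t_stop
        m = (self.times >= t_start - 1e-12) & (self.times <= t_stop + 1e-12)
        return CellTrace(self.times[m], self.A[m], self.R[m], self.input[m])

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"time": self.times, "A": self.A, "R": self.R,
                             "input": self.input})

    def save_csv(self, path, params: CellParams | None = None,
                 config: SimConfig | None = None) -> None:
        """Write the trace as CSV with a JSON sidecar for the parameters."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        side = {}
        if params is not None:
            side["cell_params"] = params.asdict()
        if config is not None:
            side["sim_config"] = config.asdict()
        if side:
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps(side, indent=2))

    @classmethod
    def load_csv(cls, path) -> "CellTrace":
        import pandas as pd
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(), df["A"].to_numpy(),
                   df["R"].to_numpy(), df["input"].to_numpy())


def input_signal(camp_ext, params: CellParams):
    """Logarithmic input pre-processing I(x) = a * ln(1 + x/Kd).

    Monotone nondecreasing in the concentration and zero at zero; Kd is the
    response threshold and a the response magnitude.  Accepts scalars or
    arrays; negative concentrations raise ValueError.
    """
    x = np.asarray(camp_ext, dtype=float)
    if np.any(x < 0):
        raise ValueError("extracellular cAMP concentration must be >= 0")
    out = params.a * np.log1p(x / params.Kd)
    return float(out) if np.isscalar(camp_ext) else out

def drift_field(A, R, drive, params: CellParams):
    """Deterministic part (dA/dt, dR/dt) of the Langevin system."""
    A = np.asarray(A, dtype=float)
    R = np.asarray(R, dtype=float)
    dA = A - A**3 / 3.0 - R + drive
    dR = params.epsilon * (A - params.gamma * R + params.c0)
    if np.isscalar(dA) or dA.ndim == 0:
        return float(dA), float(dR)
    return dA, dR


def nullclines(params: CellParams, drive: float, A_grid):
    """R values on the activator and repressor nullclines over A_grid.

    Activator nullcline (dA/dt = 0): R = A - A^3/3 + drive (S-shaped; shifts
    vertically with the drive).  Repressor nullcline (dR/dt = 0):
    R = (A + c0)/gamma (drive-independent).
    """
    A = np.asarray(A_grid, dtype=float)
    R_on_A = A - A**3 / 3.0 + drive
    R_on_R = (A + params.c0) / params.gamma
    return R_on_A, R_on_R


def _jacobian_classify(A_star: float, params: CellParams) -> str:
    # J = [[1 - A*^2, -1], [eps, -eps*gamma]]
    tr = (1.0 - A_star**2) - params.epsilon * params.gamma
    det = params.epsilon * (1.0 - params.gamma + params.gamma * A_star**2)
    return "stable" if (tr < 0 and det > 0) else "unstable"


def fixed_points(params: CellParams, drive: float):
    """All real fixed points (A*, R*, classification) at constant drive.

    Equating nullclines gives the depressed cubic
        A^3 + 3*(1-gamma)/gamma * A + 3*(c0 - gamma*drive)/gamma = 0;
    each real root is classified stable/unstable from the Jacobian
    [[1 - A*^2, -1], [eps, -eps*gamma]] (stable iff trace < 0 and det > 0).
    """
    g, c0 = params.gamma, params.c0
    coeffs = [1.0, 0.0, 3.0 * (1.0 - g) / g, 3.0 * (c0 - g * drive) / g]
    roots = np.roots(coeffs)
    out = []
    for r in sorted(roots, key=lambda z: z.real):
        if abs(r.imag) < 1e-9:
            A_star = float(r.real)
            R_star = (A_star + c0) / g
            out.append((A_star, R_star, _jacobian_classify(A_star, params)))
    return out


def hopf_threshold(params: CellParams) -> float:
    """Critical constant drive at which the resting fixed point loses
    stability (supercritical Hopf).

    The trace of the Jacobian vanishes at A*^2 = 1 - eps*gamma; the branch
    reached from the resting state (A* < 0) gives
        A*_c   = -sqrt(1 - eps*gamma)
        drive_c = (A*_c + c0)/gamma - A*_c + A*_c^3/3.
    Requires eps*gamma < 1, else no Hopf occurs on the real branch.
    """
    eg = params.epsilon * params.gamma
    if eg >= 1.0:
        raise ValueError(
            f"no Hopf bifurcation: epsilon*gamma = {eg:g} >= 1")
    A_c = -np.sqrt(1.0 - eg)
    return float((A_c + params.c0) / params.gamma - A_c + A_c**3 / 3.0)


def resting_state(params: CellParams, drive: float = 0.0) -> tuple[float, float]:
    """The (A*, R*) fixed point with the most negative A (the resting branch)."""
    fps = fixed_points(params, drive)
    if not fps:
        raise RuntimeError("no real fixed point found")
    A_star, R_star, _ = fps[0]
    return A_star, R_star


def simulate_cell(params: CellParams,
                  protocol: StimulusProtocol | float,
                  config: SimConfig,
                  initial_state: tuple[float, float] | None = None) -> CellTrace:
    """Euler-Maruyama trajectory of one cell under a stimulus protocol.

    `protocol` may be a StimulusProtocol or a constant concentration.
    Initial conditions default to uniform draws A, R in [-2, 2] ("random
    initial conditions"); pass `initial_state` to override (e.g. the resting
    fixed point for deterministic runs).  Identical seed and inputs give a
    bitwise-identical trace.  The recorded grid is decimated by
    config.record_stride.
    """
    if not isinstance(protocol, StimulusProtocol):
        protocol = constant_protocol(float(protocol), config.t_end)
    if protocol.t_end < config.t_end - 1e-9:
        raise ValueError(
            f"protocol ends at {protocol.t_end} before t_end={config.t_end}")

    stride = config.record_stride
    n_steps = int(round(config.t_end / config.dt))
    n_steps = ((n_steps + stride - 1) // stride) * stride  # uniform grid

    rng = np.random.default_rng(config.seed)
    if initial_state is None:
        A0, R0 = rng.uniform(-2.0, 2.0, size=2)
    else:
        A0, R0 = map(float, initial_state)

    t_steps = np.arange(n_steps) * config.dt
    camp = protocol.values(t_steps)
    mode = _NOISE_MODE[params.noise_source]
    if params.sigma > 0 and mode != _kernels.NOISE_NONE:
        noise = rng.standard_normal(n_steps)
    else:
        noise = np.zeros(n_steps)
        mode = _kernels.NOISE_NONE

    A_rec, R_rec, in_rec, fail = _kernels.integrate_cell(
        A0, R0, camp, config.dt, n_steps, stride,
        params.epsilon, params.gamma, params.c0, params.a, params.Kd,
        params.sigma, mode, noise)
    if fail >= 0:
        raise IntegrationError(fail * config.dt)

    times = np.arange(len(A_rec)) * config.dt_record
    return CellTrace(times, A_rec, R_rec, in_rec)
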