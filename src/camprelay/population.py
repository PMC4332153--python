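"""Mean-field population model: N cells coupled through shared extracellular cAMP.

Each cell i follows the single-cell adapted FHN equations with its own
noise realization, driven by the common external field [cAMP]_ex:

    dA_i/dt = A_i - A_i^3/3 - R_i + a*log(1 + [cAMP]_ex/Kd_i) + eta_i
    dR_i/dt = epsilon*(A_i - gamma*R_i + c0)
    d[cAMP]_ex/dt = alpha_f + rho*alpha0 + (rho*S/N) * sum_i Theta(A_i)
                    - D*[cAMP]_ex,       D = J + alpha_pde*rho

where Theta is the Heaviside function (1 for A_i > 0, else 0): cells secrete
a large cAMP pulse at rate S while their activator is excited, on top of a
basal leakage alpha0; alpha_f is an externally imposed inflow source rate
and the field is diluted by flow J and degraded by secreted
phosphodiesterase at alpha_pde*rho.  The model is well mixed (no spatial
structure).  The field is clipped at zero each step (negative excursions
can arise only under the external-noise variant).

The Langevin system of 2N+1 equations is integrated with Euler-Maruyama;
one seeded Generator draws initial conditions and then the noise matrix
(cell-major), so a seed fully determines the trajectory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _kernels
from .model import IntegrationError
from .params import CellParams, PopulationParams, SimConfig
from .stimulus import StimulusProtocol

__all__ = [
    "EnsembleTrace",
    "secretion_fraction",
    "quasi_steady_external",
    "sample_heterogeneous_kd",
    "simulate_population",
]


@dataclass(frozen=True)
class EnsembleTrace:
    """Recorded ensemble trajectory: per-cell states plus the shared field.

    A and R have shape (N, n_times); camp_ext is the shared external-cAMP
    time series; mean_A the population-averaged activator.
    """

    times: np.ndarray
    A: np.ndarray
    R: np.ndarray
    camp_ext: np.ndarray

    def __post_init__(self) -> None:
        if self.A.shape != self.R.shape:
            raise ValueError("A and R must have the same shape")
        if self.A.shape[1] != len(self.times) or len(self.camp_ext) != len(self.times):
            raise ValueError("inconsistent trace shapes")

    @property
    def N(self) -> int:
        return self.A.shape[0]

    @property
    def mean_A(self) -> np.ndarray:
        return self.A.mean(axis=0)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def window(self, t_start: float, t_stop: float | None = None) -> "EnsembleTrace":
        t_stop = self.times[-1] if t_stop is None else t_stop
        m = (self.times >= t_start - 1e-12) & (self.times <= t_stop + 1e-12)
        return EnsembleTrace(self.times[m], self.A[:, m], self.R[:, m],
                             self.camp_ext[m])

    def save_csv(self, path, per_cell: bool = False,
                 metadata: dict | None = None) -> None:
        """CSV of times, mean_A, camp_ext (plus per-cell columns on request),
        with a JSON parameter sidecar."""
        import pandas as pd
        path = Path(path)
        data = {"time": self.times, "mean_A": self.mean_A,
                "camp_ext": self.camp_ext}
        if per_cell:
            for i in range(self.N):
                data[f"A_{i}"] = self.A[i]
        pd.DataFrame(data).to_csv(path, index=False)
        if metadata is not None:
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps(metadata, indent=2))


def secretion_fraction(A_values) -> float:
    """Fraction of cells currently excited: (1/N) * sum_i Theta(A_i).

    Theta is the strict Heaviside function: Theta(x) = 1 if x > 0, else 0
    (in particular Theta(0) = 0).
    """
    A = np.asarray(A_values, dtype=float)
    if A.size == 0:
        raise ValueError("empty activator snapshot")
    if not np.all(np.isfinite(A)):
        raise ValueError("non-finite activator values")
    return float(np.count_nonzero(A > 0.0) / A.size)


def quasi_steady_external(pop_params: PopulationParams, theta_bar: float) -> float:
    """Quasi-steady external cAMP at mean secretion fraction theta_bar.

    For fast field dynamics (large D) the external cAMP slaves to
        (alpha_f + rho*alpha0 + rho*S*theta_bar) / D.
    At theta_bar = 0 and alpha_pde*rho << J this reduces to the
    background-cAMP axis value (alpha_f + rho*alpha0)/J.
    """
    D = pop_params.D
    if D <= 0:
        raise ZeroDivisionError("D = J + alpha_pde*rho must be > 0 for a "
                                "quasi-steady state")
    p = pop_params
    return (p.alpha_f + p.rho * p.alpha0 + p.rho * p.S * theta_bar) / D


def sample_heterogeneous_kd(pop_params: PopulationParams, seed) -> np.ndarray:
    """Per-cell Kd draws from the configured lognormal (median, shape).

    The lognormal is parameterized so its median equals the configured
    median exactly; shape is the standard deviation of log Kd.
    """
    dist = pop_params.kd_distribution
    if dist.kind != "lognormal":
        raise ValueError("kd_distribution must be lognormal to sample")
    if dist.median <= 0 or dist.shape < 0:
        raise ValueError("lognormal median must be > 0 and shape >= 0")
    rng = np.random.default_rng(seed)
    return dist.median * np.exp(dist.shape * rng.standard_normal(pop_params.N))


def simulate_population(cell_params: CellParams,
                        pop_params: PopulationParams,
                        protocol: StimulusProtocol | float | None,
                        config: SimConfig,
                        initial_state: tuple | None = None) -> EnsembleTrace:
    """Euler-Maruyama co-integration of the 2N+1 coupled equations.

    `protocol`, if given, modulates the inflow source rate alpha_f over
    time (a StimulusProtocol evaluated in alpha_f units, or a constant);
    None uses the constant pop_params.alpha_f.  Per-cell noise terms are
    independent (<eta_i eta_j> = sigma^2 delta_ij); with
    noise_source="external" a single noise term enters the field equation
    instead and per-cell noise is removed.  `initial_state` may be
    (A0 (N,), R0 (N,), camp0) to override the random initialization.
    """
    N = pop_params.N
    stride = config.record_stride
    n_steps = int(round(config.t_end / config.dt))
    n_steps = ((n_steps + stride - 1) // stride) * stride

    t_steps = np.arange(n_steps) * config.dt
    if protocol is None:
        alpha_f_t = np.full(n_steps, pop_params.alpha_f)
    elif isinstance(protocol, StimulusProtocol):
        if protocol.t_end < config.t_end - 1e-9:
            raise ValueError("protocol shorter than simulation")
        alpha_f_t = protocol.values(t_steps)
    else:
        alpha_f_t = np.full(n_steps, float(protocol))

    if pop_params.kd_distribution.kind == "lognormal":
        # heterogeneity seed derives from the run seed
        kd = sample_heterogeneous_kd(pop_params,
                                     np.random.SeedSequence([config.seed, 1]))
    else:
        kd = np.full(N, cell_params.Kd)

    rng = np.random.default_rng(config.seed)
    if initial_state is None:
        A0 = rng.uniform(-2.0, 2.0, size=N)
        R0 = rng.uniform(-2.0, 2.0, size=N)
        camp0 = 0.0
    else:
        A0, R0, camp0 = initial_state
        A0 = np.array(A0, dtype=float).copy()
        R0 = np.array(R0, dtype=float).copy()

    mode = {"activator": _kernels.NOISE_ACTIVATOR,
            "external": _kernels.NOISE_EXTERNAL,
            "none": _kernels.NOISE_NONE}[cell_params.noise_source]
    if cell_params.sigma == 0:
        mode = _kernels.NOISE_NONE
    kd_uniform = bool(np.all(kd == kd[0]))
    scale = cell_params.sigma * np.sqrt(config.dt)

    n_rec = n_steps // stride + 1
    A_rec = np.empty((n_rec, N))
    R_rec = np.empty((n_rec, N))
    camp_rec = np.empty(n_rec)
    A_cur, R_cur = A0.astype(float), R0.astype(float)
    camp = float(camp0)

    # noise drawn in bounded slabs (step-major, then cell-major)
    chunk = 50000 - (50000 % stride)
    fail = -1
    for k0 in range(0, n_steps, chunk):
        n_chunk = min(chunk, n_steps - k0)
        if mode == _kernels.NOISE_ACTIVATOR:
            noise = scale * rng.standard_normal((n_chunk, N),
                                                dtype=np.float32)
        elif mode == _kernels.NOISE_EXTERNAL:
            noise = scale * rng.standard_normal((n_chunk, 1),
                                                dtype=np.float32)
        else:
            noise = np.zeros((1, 1))
        fail, camp = _kernels.integrate_population_chunk(
            A_cur, R_cur, camp, alpha_f_t[k0:k0 + n_chunk], noise,
            config.dt, k0, n_chunk, stride, cell_params.epsilon,
            cell_params.gamma, cell_params.c0, cell_params.a,
            kd.astype(float), kd_uniform, mode, pop_params.rho,
            pop_params.alpha0, pop_params.S, pop_params.D,
            A_rec, R_rec, camp_rec)
        if fail >= 0:
            raise IntegrationError(fail * config.dt)
    # final state
    A_rec[-1] = A_cur
    R_rec[-1] = R_cur
    camp_rec[-1] = camp
    if not (np.all(np.isfinite(A_cur)) and np.all(np.isfinite(R_cur))
            and np.isfinite(camp)):
        raise IntegrationError(n_steps * config.dt)

    times = np.arange(n_rec) * config.dt_record
    return EnsembleTrace(times, A_rec.T.copy(), R_rec.T.copy(), camp_rec)
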