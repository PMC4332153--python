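"""Parameter containers for the single-cell and population cAMP-relay models.

All defaults are the single parameter set used for every simulation in the
study this package reproduces: a FitzHugh-Nagumo (FHN) activator/repressor
pair driven by a logarithmically pre-processed extracellular-cAMP input,
optionally coupled through a shared well-mixed extracellular field.

Units are dimensionless model units throughout: one model time unit "T"
corresponds (by convention, configurable in the stimulus presets) to one
experimental minute, and one model concentration unit to one nanomolar.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

NoiseSource = Literal["activator", "external", "none"]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class CellParams:
    """Single-cell adapted-FHN parameters.

    Attributes
    ----------
    epsilon : float
        Timescale ratio tau_A/tau_R between activator and repressor; controls
        excitability. Default 0.1.
    gamma : float
        Repressor degradation rate. Default 0.5.
    c0 : float
        Offset of the repressor nullcline R = (A + c0)/gamma; sets the resting
        repressor level in the absence of external cAMP. Default 1.2.
    a : float
        Magnitude of the logarithmic input response I(x) = a*log(1 + x/Kd).
        Default 0.058.
    Kd : float
        Threshold concentration of the cAMP response (model concentration
        units). Default 1e-5.
    sigma : float
        Langevin noise strength: <eta(t) eta(t')> = sigma^2 delta(t-t').
        Default 0.15.
    noise_source : {"activator", "external", "none"}
        Where the noise term enters.  "activator" (default) puts eta in the
        activator equation; "external" puts it in the shared extracellular
        cAMP field (population model only); "none" disables it.
    """

    epsilon: float = 0.1
    gamma: float = 0.5
    c0: float = 1.2
    a: float = 0.058
    Kd: float = 1e-5
    sigma: float = 0.15
    noise_source: NoiseSource = "activator"

    def __post_init__(self) -> None:
        _require(self.epsilon > 0, f"epsilon must be > 0, got {self.epsilon}")
        _require(self.gamma > 0, f"gamma must be > 0, got {self.gamma}")
        _require(self.Kd > 0, f"Kd must be > 0, got {self.Kd}")
        _require(self.sigma >= 0, f"sigma must be >= 0, got {self.sigma}")
        _require(
            self.noise_source in ("activator", "external", "none"),
            f"unknown noise_source {self.noise_source!r}",
        )

    def asdict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SimConfig:
    """Integration settings for the Euler-Maruyama solver.

    dt is the integration step (default 0.005); t_equil is the initial
    window discarded before statistics; record_stride decimates the stored
    trace (statistics are computed on the decimated grid).
    """

    dt: float = 0.005
    t_end: float = 100.0
    t_equil: float = 0.0
    seed: int = 0
    record_stride: int = 10

    def __post_init__(self) -> None:
        _require(self.dt > 0, f"dt must be > 0, got {self.dt}")
        _require(
            0 <= self.t_equil < self.t_end,
            f"need 0 <= t_equil < t_end, got t_equil={self.t_equil}, t_end={self.t_end}",
        )
        _require(self.record_stride >= 1, "record_stride must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))

    @property
    def dt_record(self) -> float:
        return self.dt * self.record_stride

    def asdict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class KdDistribution:
    """Per-cell cAMP-threshold heterogeneity.

    kind="fixed" gives every cell the shared Kd; kind="lognormal" draws each
    cell's Kd from a lognormal with the given median and shape (sigma of the
    underlying normal).
    """

    kind: Literal["fixed", "lognormal"] = "fixed"
    median: float = 1e-5
    shape: float = 0.0

    def __post_init__(self) -> None:
        _require(self.kind in ("fixed", "lognormal"), f"unknown kind {self.kind!r}")
        if self.kind == "lognormal":
            _require(self.median > 0, "lognormal median must be > 0")
            _require(self.shape >= 0, "lognormal shape must be >= 0")


@dataclass(frozen=True)
class PopulationParams:
    """Parameters of the shared extracellular-cAMP field coupling N cells.

    The field obeys
        d[cAMP]_ex/dt = alpha_f + rho*alpha0 + (rho*S/N) * sum_i Theta(A_i)
                        - D*[cAMP]_ex,
    with degradation D = J + alpha_pde*rho (recomputed, never stored).

    alpha_f is the external inflow source rate, alpha0 the basal per-cell
    cAMP secretion rate, S the spike-driven release rate, rho the cell
    density by volume and J the flow/dilution rate.  All are dimensionless
    model units (the experimental mapping, e.g. 1 ML = 6,600 cells/mm^2, is
    documentation only).
    """

    N: int = 100
    rho: float = 1.0
    J: float = 10.0
    alpha_f: float = 0.0
    alpha0: float = 800.0
    alpha_pde: float = 1e3
    S: float = 1e6
    kd_distribution: KdDistribution = field(default_factory=KdDistribution)

    def __post_init__(self) -> None:
        _require(self.N >= 1, f"N must be >= 1, got {self.N}")
        for name in ("rho", "J", "alpha_f", "alpha0", "alpha_pde", "S"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")

    @property
    def D(self) -> float:
        """Total extracellular degradation rate J + alpha_pde*rho."""
        return self.J + self.alpha_pde * self.rho

    @property
    def background_camp(self) -> float:
        """Background-cAMP axis value (alpha_f + rho*alpha0)/J."""
        return (self.alpha_f + self.rho * self.alpha0) / self.J

    @property
    def firing_induced_camp(self) -> float:
        """Firing-induced-cAMP axis value rho*S/J."""
        return self.rho * self.S / self.J

    def asdict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class FretParams:
    """Forward-model constants for synthetic three-channel FRET traces.

    alpha is the relative acceptor fluorescence signal (acceptor
    cross-excitation bleedthrough into the FRET channel), beta the donor
    bleedthrough.  E_high/E_low are the sensor's FRET efficiencies in the
    unbound (high-FRET) and cAMP-bound (low-FRET) configurations; gamma_ext
    is the relative donor/acceptor extinction (named to avoid collision with
    the repressor degradation rate).
    """

    alpha: float = 0.054
    beta: float = 0.906
    E_high: float = 0.50
    E_low: float = 0.05
    gamma_ext: float = 0.5
    donor_baseline: float = 1000.0
    acceptor_baseline: float = 800.0
    donor_bleach_rate: float = 0.0
    acceptor_bleach_rate: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        _require(0 <= self.alpha < 1, f"need 0 <= alpha < 1, got {self.alpha}")
        _require(0 < self.beta <= 1, f"need 0 < beta <= 1, got {self.beta}")
        _require(self.donor_bleach_rate >= 0, "bleach rates must be >= 0")
        _require(self.acceptor_bleach_rate >= 0, "bleach rates must be >= 0")
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")
        _require(0 <= self.E_low < self.E_high <= 1, "need 0 <= E_low < E_high <= 1")
        _require(self.gamma_ext > 0, "gamma_ext must be > 0")
        _require(self.donor_baseline > 0 and self.acceptor_baseline > 0,
                 "channel baselines must be > 0")

    def asdict(self) -> dict:
        return asdict(self)
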