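"""Synthetic three-channel FRET traces and the E*f_DA/gamma readout.

The Epac1camps sensor sits in a high-FRET configuration when unbound and a
low-FRET configuration when bound to cAMP, so a cytosolic cAMP spike
appears as a transient *drop* in FRET efficiency; -E*f_DA/gamma (baseline
subtracted) is therefore used as the FRET intensity so that spikes are
positive excursions.

Three per-timepoint intensities are modeled (already cell-averaged; image
segmentation is out of scope): the donor channel F_D, the direct-acceptor
channel F_A and the FRET (donor-excitation, acceptor-emission) channel F_F.
The readout

    E*f_DA/gamma_ext = (F_F - beta*F_D - alpha*F_A) / F_A

removes donor bleedthrough (beta) and acceptor cross-excitation (alpha)
from the FRET channel and normalizes by the direct acceptor signal, which
cancels any photobleaching common to all channels.  The forward generator
below is the exact algebraic inverse of this formula in the noiseless,
unbleached limit, so correctness is a round-trip identity.  Photobleaching
is modeled as per-channel exponential gain decay (donor rate on F_D,
acceptor rate on F_A, their mean on F_F): equal rates leave the readout
exactly invariant, unequal rates distort it (a documented limitation of
the method).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .metrics import SpikeTrain, detect_spikes
from .params import FretParams

__all__ = [
    "FretChannels",
    "activator_to_fda",
    "generate_fret_channels",
    "fret_efficiency",
    "normalize_and_threshold",
    "SINGLE_CELL_MIN_HEIGHT",
    "POPULATION_MIN_HEIGHT",
]

#: minimum spike heights, in FRET signal units, for a spike to be counted
SINGLE_CELL_MIN_HEIGHT = 0.25
POPULATION_MIN_HEIGHT = 0.3


@dataclass(frozen=True)
class FretChannels:
    """Cell-averaged intensities of the three FRET imaging channels.

    ground_truth_fda (synthetic traces only) is the underlying bound
    fraction of the sensor, in [0, 1].
    """

    times: np.ndarray
    F_donor: np.ndarray
    F_acceptor: np.ndarray
    F_fret: np.ndarray
    ground_truth_fda: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("F_donor", "F_acceptor", "F_fret"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValueError("channel lengths must match times")
            if np.any(arr < 0):
                raise ValueError(f"negative intensities in {name}")
        if self.ground_truth_fda is not None and len(self.ground_truth_fda) != n:
            raise ValueError("ground_truth_fda length must match times")

    def to_frame(self):
        import pandas as pd
        data = {"time": self.times, "F_donor": self.F_donor,
                "F_acceptor": self.F_acceptor, "F_fret": self.F_fret}
        if self.ground_truth_fda is not None:
            data["fda_truth"] = self.ground_truth_fda
        return pd.DataFrame(data)

    def save_csv(self, path, params: FretParams | None = None) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if params is not None:
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps({"fret_params": params.asdict()}, indent=2))

    @classmethod
    def load_csv(cls, path) -> "FretChannels":
        import pandas as pd
        df = pd.read_csv(path)
        fda = df["fda_truth"].to_numpy() if "fda_truth" in df else None
        return cls(df["time"].to_numpy(), df["F_donor"].to_numpy(),
                   df["F_acceptor"].to_numpy(), df["F_fret"].to_numpy(), fda)


def activator_to_fda(A, A_rest: float = -2.0, A_peak: float = 2.2) -> np.ndarray:
    """Affine map from an activator trace to a sensor bound fraction.

    The resting activator maps near 0 (little cAMP bound) and the spike
    peak near 1; output is clipped to [0, 1].
    """
    A = np.asarray(A, dtype=float)
    return np.clip((A - A_rest) / (A_peak - A_rest), 0.0, 1.0)


def _effective_efficiency(fda: np.ndarray, params: FretParams) -> np.ndarray:
    # bound sensor = low FRET: efficiency falls linearly with bound fraction
    return params.E_high - (params.E_high - params.E_low) * fda


def generate_fret_channels(times, ground_truth_fda, params: FretParams,
                           seed: int = 0) -> FretChannels:
    """Forward model producing three-channel intensities from a bound
    fraction time series.

    With E(t) the effective FRET efficiency (affine, decreasing in fda):
      F_D = B_D * (1 - E)            * exp(-k_D t)
      F_A = B_A                      * exp(-k_A t)
      F_F = (B_A*E/gamma_ext + beta*F_D' + alpha*F_A') * exp(-(k_D+k_A)t/2)
    where the primed bleedthrough terms use unbleached intensities, so the
    whole FRET channel bleaches at the mean rate.  Seeded additive Gaussian
    noise (sd = noise_sd) is applied per channel and clipped at 0.
    Applying fret_efficiency with the same alpha/beta and zero noise and
    bleach recovers E/gamma_ext, an affine image of fda, exactly.
    """
    times = np.asarray(times, dtype=float)
    fda = np.asarray(ground_truth_fda, dtype=float)
    if np.any(fda < 0) or np.any(fda > 1):
        raise ValueError("ground-truth bound fraction must lie in [0, 1]")
    E = _effective_efficiency(fda, params)

    F_D0 = params.donor_baseline * (1.0 - E)
    F_A0 = np.full_like(times, params.acceptor_baseline)
    sensitized = params.acceptor_baseline * E / params.gamma_ext
    F_F0 = sensitized + params.beta * F_D0 + params.alpha * F_A0

    b_D = np.exp(-params.donor_bleach_rate * times)
    b_A = np.exp(-params.acceptor_bleach_rate * times)
    b_F = np.exp(-(params.donor_bleach_rate + params.acceptor_bleach_rate)
                 * times / 2.0)

    rng = np.random.default_rng(seed)
    chans = []
    for base, bleach in ((F_D0, b_D), (F_A0, b_A), (F_F0, b_F)):
        noisy = base * bleach
        if params.noise_sd > 0:
            noisy = noisy + params.noise_sd * rng.standard_normal(len(times))
        chans.append(np.clip(noisy, 0.0, None))
    return FretChannels(times, chans[0], chans[1], chans[2], fda)


def fret_efficiency(channels: FretChannels, params: FretParams) -> np.ndarray:
    """Bleedthrough-corrected FRET readout E*f_DA/gamma_ext per timepoint.

        (F_fret - beta*F_donor - alpha*F_acceptor) / F_acceptor

    Timepoints with non-positive acceptor intensity are undefined (NaN),
    reported rather than fatal.
    """
    F_A = np.asarray(channels.F_acceptor, dtype=float)
    numer = (np.asarray(channels.F_fret, dtype=float)
             - params.beta * np.asarray(channels.F_donor, dtype=float)
             - params.alpha * F_A)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(F_A > 0, numer / np.where(F_A > 0, F_A, 1.0), np.nan)
    return out


def normalize_and_threshold(times, efd_trace, baseline_window: tuple[float, float],
                            spike_min_height: float = SINGLE_CELL_MIN_HEIGHT):
    """Convert an E*f_DA/gamma trace into the FRET-signal convention and
    detect spikes.

    The signal is -efd minus its baseline-window mean (0 is the baseline
    value; cAMP binding lowers FRET, so spikes are positive); spikes must
    reach `spike_min_height` FRET signal units above baseline (0.25 default
    for single cells, 0.3 for population means).  Returns
    (normalized signal, SpikeTrain).
    """
    times = np.asarray(times, dtype=float)
    efd = np.asarray(efd_trace, dtype=float)
    m = (times >= baseline_window[0]) & (times <= baseline_window[1])
    if not m.any():
        raise ValueError("empty baseline window")
    signal = -efd - np.nanmean(-efd[m])
    spikes = detect_spikes(times, signal, baseline=0.0,
                           min_height=spike_min_height)
    return signal, spikes
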