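"""Trace statistics: spike detection, firing rates, widths, periods,
entrainment quality, bootstrap errors and unit calibration.

Conventions (shared by simulated activator traces and normalized FRET
signals): a spike is one contiguous excursion of the signal above the
baseline (0 for activator traces), with its time taken at the excursion
maximum; excursions shorter than a few samples are treated as noise
crossings and ignored.  Firing rates are spike counts divided by the
observation window; the ensemble single-cell rate is the mean of per-cell
rates, while the population rate counts excursions of the population-mean
signal (which vanishes for incoherent populations).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.signal import get_window
from scipy.stats import pearsonr

from .stimulus import StimulusProtocol

__all__ = [
    "SpikeTrain",
    "detect_spikes",
    "firing_rate",
    "mean_cell_rate",
    "ensemble_cell_rate",
    "population_firing_rate",
    "spike_width",
    "oscillation_period",
    "ensemble_period",
    "entrainment_quality",
    "bootstrap_ci",
    "std_increase",
    "calibrate_units",
]

#: minimum excursion length, in samples, for a spike (suppresses
#: single-sample noise crossings)
MIN_EXCURSION_SAMPLES = 5

#: fraction of the excursion peak (above baseline) defining the "initial
#: rise" time used for spike widths
RISE_FRACTION = 0.05

#: Fisher-style periodogram significance margin: the peak must exceed
#: (ln(m) + PEAK_SIGNIFICANCE_MARGIN) times the mean periodogram level,
#: where m is the number of independent frequencies.  For white noise the
#: periodogram ordinates are ~exponential, so the largest of m of them is
#: ~ln(m) times the mean; the margin puts the false-alarm rate near
#: exp(-margin) regardless of trace length.
PEAK_SIGNIFICANCE_MARGIN = 4.0


@dataclass(frozen=True)
class SpikeTrain:
    """Detected spikes: peak times, peak heights and excursion bounds."""

    spike_times: np.ndarray
    spike_heights: np.ndarray
    excursion_bounds: np.ndarray  # (n_spikes, 2) rise/fall times

    def __post_init__(self) -> None:
        if len(self.spike_times) > 1 and np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.spike_times)


def _excursions(values: np.ndarray, baseline: float) -> list[tuple[int, int]]:
    """Index ranges [i0, i1] of contiguous runs with values > baseline."""
    above = values > baseline
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]])
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(values) - 1)
    return list(zip(starts, ends))


def detect_spikes(times, values, baseline: float = 0.0,
                  min_height: float = 0.0,
                  min_samples: int = MIN_EXCURSION_SAMPLES) -> SpikeTrain:
    """One spike per contiguous excursion of `values` above `baseline`.

    The spike time is the time of the excursion maximum (one spike per
    excursion, robust to noise-induced double peaks); excursions whose peak
    stays below baseline + min_height, or shorter than `min_samples`
    samples, are discarded.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("trace too short for spike detection (< 3 samples)")
    t_spk, h_spk, bounds = [], [], []
    for i0, i1 in _excursions(values, baseline):
        if i1 - i0 + 1 < min_samples:
            continue
        seg = values[i0:i1 + 1]
        peak = int(np.argmax(seg))
        if seg[peak] < baseline + min_height:
            continue
        t_spk.append(times[i0 + peak])
        h_spk.append(seg[peak])
        bounds.append((times[i0], times[i1]))
    return SpikeTrain(np.asarray(t_spk), np.asarray(h_spk),
                      np.asarray(bounds).reshape(-1, 2))


def firing_rate(spiketrain: SpikeTrain, duration: float) -> float:
    """Spike count divided by the observation window."""
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    return len(spiketrain) / duration


def mean_cell_rate(rates: Sequence[float]) -> float:
    """Ensemble single-cell firing rate: population mean of per-cell rates."""
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0:
        raise ValueError("no per-cell rates given")
    return float(rates.mean())


def ensemble_cell_rate(ensemble, t_equil: float = 0.0,
                       min_height: float = 0.0) -> float:
    """Single-cell firing rate of an EnsembleTrace over [t_equil, end]."""
    w = ensemble.window(t_equil)
    duration = w.times[-1] - w.times[0]
    rates = [firing_rate(detect_spikes(w.times, w.A[i], min_height=min_height),
                         duration)
             for i in range(w.N)]
    return mean_cell_rate(rates)


def population_firing_rate(ensemble, t_equil: float = 0.0,
                           min_height: float = 0.0) -> float:
    """Synchronous-firing rate: spikes of the population-mean activator.

    Desynchronized single-cell spiking leaves the mean activator below
    baseline, so the population rate vanishes for incoherent populations.
    """
    w = ensemble.window(t_equil)
    duration = w.times[-1] - w.times[0]
    spikes = detect_spikes(w.times, w.mean_A, min_height=min_height)
    return firing_rate(spikes, duration)


def spike_width(times, values, stimulus_onset: float, baseline: float = 0.0,
                rise_fraction: float = RISE_FRACTION) -> float:
    """Width of the first post-onset excursion above `baseline`.

    Width = (time of return to baseline) - (time of initial rise), where
    the initial rise is the first crossing above
    baseline + rise_fraction*(peak - baseline).  Returns NaN (not-a-spike
    sentinel, distinct from 0) when no excursion follows the onset or the
    trace never returns to baseline.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    for i0, i1 in _excursions(values, baseline):
        if i1 - i0 + 1 < MIN_EXCURSION_SAMPLES:
            continue
        if times[i1] < stimulus_onset:
            continue
        seg = values[i0:i1 + 1]
        peak = seg.max()
        thresh = baseline + rise_fraction * (peak - baseline)
        risers = np.flatnonzero(seg >= thresh)
        t_rise = times[i0 + risers[0]]
        if t_rise < stimulus_onset:
            # excursion already under way at onset; not a response
            continue
        if i1 == len(values) - 1 and values[i1] > baseline:
            return np.nan  # never returned to baseline before record end
        return times[i1] - t_rise
    return np.nan


def _periodogram(values: np.ndarray, dt: float):
    x = values - values.mean()
    w = get_window("hann", len(x))
    n_fft = 4 * len(x)  # zero-pad for peak interpolation
    spec = np.abs(np.fft.rfft(x * w, n=n_fft)) ** 2
    freqs = np.fft.rfftfreq(n_fft, d=dt)
    return freqs[1:], spec[1:]  # exclude the DC bin


def oscillation_period(times, values,
                       significance: float = PEAK_SIGNIFICANCE_MARGIN) -> float:
    """Period of the dominant Fourier component of a detrended trace.

    Hann-windowed periodogram, zero-padded 4x, DC bin excluded; the peak
    must pass a Fisher-style test (exceed (ln m + significance) times the
    mean ordinate, m = number of independent frequencies), else the period
    is undefined and NaN is returned (a white-noise trace has no period).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(values) < 8 or np.ptp(values) == 0:
        return np.nan
    freqs, spec = _periodogram(values, times[1] - times[0])
    k = int(np.argmax(spec))
    m = max(len(values) // 2, 2)
    if spec[k] < (np.log(m) + significance) * spec.mean() or freqs[k] == 0:
        return np.nan
    return float(1.0 / freqs[k])


def ensemble_period(times, values_list, n_boot: int = 2000, seed: int = 0):
    """Mean per-trace Fourier period with a bootstrap CI across traces.

    Periods are computed per trace and averaged (traces with no significant
    spectral peak are dropped); the CI resamples traces.  Returns
    (mean_period, (lo, hi)); all-NaN input gives (nan, (nan, nan)).
    """
    periods = np.asarray([oscillation_period(times, v) for v in values_list])
    periods = periods[np.isfinite(periods)]
    if periods.size == 0:
        return np.nan, (np.nan, np.nan)
    if periods.size == 1:
        return float(periods[0]), (float(periods[0]), float(periods[0]))
    est, ci = bootstrap_ci(periods, n_boot=n_boot, seed=seed)
    return est, ci


def entrainment_quality(times, values, protocol: StimulusProtocol) -> float:
    """Mean Pearson correlation between the first-period response and each
    subsequent period-aligned response window.

    Windows are one protocol period long, aligned to pulse onsets.  A
    perfectly periodic response scores 1; uncorrelated responses score ~0.
    Raises ValueError naming the window if any window has zero variance.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    onsets = protocol.pulse_onsets()
    if len(onsets) < 2:
        raise ValueError("protocol must contain a pulse train with >= 2 pulses")
    period = float(np.diff(onsets)[0])
    dt = times[1] - times[0]
    n_win = int(round(period / dt))
    windows = []
    for t0 in onsets:
        i0 = int(round((t0 - times[0]) / dt))
        if i0 < 0 or i0 + n_win > len(values):
            break
        windows.append(values[i0:i0 + n_win])
    if len(windows) < 2:
        raise ValueError("trace does not cover at least two pulse windows")
    ref = windows[0]
    corrs = []
    for k, w in enumerate(windows[1:], start=1):
        if np.ptp(ref) == 0 or np.ptp(w) == 0:
            raise ValueError(f"zero variance in entrainment window {k}")
        corrs.append(pearsonr(ref, w).statistic)
    return float(np.mean(corrs))


def bootstrap_ci(samples, statistic: Callable = np.mean, n_boot: int = 2000,
                 seed: int = 0, ci: float = 95.0):
    """Case-resampling percentile bootstrap of `statistic`.

    Returns (point estimate, (lo, hi)) with the (2.5, 97.5) percentile
    interval for the default 95% level.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples to bootstrap")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, samples.size, size=(n_boot, samples.size))
    reps = np.asarray([statistic(samples[row]) for row in idx])
    half = (100.0 - ci) / 2.0
    lo, hi = np.percentile(reps, [half, 100.0 - half])
    return float(statistic(samples)), (float(lo), float(hi))


def std_increase(traces_by_condition: Mapping[str, np.ndarray],
                 times, window: tuple[float, float], reference: str,
                 n_boot: int = 2000, seed: int = 0) -> dict:
    """Relative increase of single-cell temporal variability per condition.

    For each condition (per-cell trace matrix, shape (n_cells, n_times)),
    computes the mean over cells of the within-window standard deviation of
    each cell's trace, normalized to the same quantity for the `reference`
    condition.  Returns {condition: (ratio, (lo, hi))} with bootstrap CIs
    resampling cells.
    """
    if reference not in traces_by_condition:
        raise KeyError(f"reference condition {reference!r} missing")
    times = np.asarray(times, dtype=float)
    m = (times >= window[0]) & (times <= window[1])
    if not m.any():
        raise ValueError("empty analysis window")

    def cell_stds(mat: np.ndarray) -> np.ndarray:
        mat = np.asarray(mat, dtype=float)
        if mat.ndim != 2 or mat.shape[0] == 0:
            raise ValueError("condition needs a (n_cells, n_times) matrix")
        return mat[:, m].std(axis=1, ddof=1)

    ref_stds = cell_stds(traces_by_condition[reference])
    ref_mean = ref_stds.mean()
    rng = np.random.default_rng(seed)
    out = {}
    for cond, mat in traces_by_condition.items():
        stds = cell_stds(mat)
        ratio = stds.mean() / ref_mean
        reps = np.empty(n_boot)
        for b in range(n_boot):
            s = stds[rng.integers(0, stds.size, size=stds.size)]
            r = ref_stds[rng.integers(0, ref_stds.size, size=ref_stds.size)]
            reps[b] = s.mean() / r.mean()
        lo, hi = np.percentile(reps, [2.5, 97.5])
        out[cond] = (float(ratio), (float(lo), float(hi)))
    return out


def calibrate_units(cell_params, config=None, n_amplitude_runs: int = 20,
                    seed: int = 0):
    """Model time and amplitude unit calibration.

    T (the model time unit) is the average minimum oscillation period: the
    minimum over a supra-threshold drive scan of the mean inter-spike
    interval of a deterministic single cell.  The amplitude unit is the mean
    spike height (peak activator minus pre-stimulus baseline) of noisy
    responses to the 1 nM preset step, averaged over seeded runs.
    """
    from dataclasses import replace
    from .model import hopf_threshold, resting_state, simulate_cell
    from .params import SimConfig
    from .stimulus import preset

    if config is None:
        config = SimConfig(t_end=400.0, t_equil=100.0)
    drive_c = hopf_threshold(cell_params)
    det = replace(cell_params, sigma=0.0)
    drives = drive_c * np.linspace(1.05, 3.0, 12)
    best = np.inf
    found = False
    for d in drives:
        camp = cell_params.Kd * np.expm1(d / cell_params.a)
        trace = simulate_cell(det, camp, config,
                              initial_state=resting_state(det, 0.0))
        w = trace.window(config.t_equil)
        spikes = detect_spikes(w.times, w.A)
        if len(spikes) >= 3:
            found = True
            isi = float(np.mean(np.diff(spikes.spike_times)))
            best = min(best, isi)
    if not found:
        raise RuntimeError("no oscillatory drive found in calibration scan")

    from .stimulus import TIME_UNITS_PER_MIN
    proto = preset("step-1nM", t_end=20.0)
    onset = 5.0 * TIME_UNITS_PER_MIN
    heights = []
    rest = resting_state(cell_params, 0.0)
    for k in range(n_amplitude_runs):
        cfg = SimConfig(t_end=proto.t_end, seed=(int(seed) * 10007 + k) % 2**31)
        tr = simulate_cell(cell_params, proto, cfg, initial_state=rest)
        pre = tr.A[tr.times < onset].mean()
        post = tr.window(onset, onset + 10.0 * TIME_UNITS_PER_MIN)
        heights.append(post.A.max() - pre)
    return float(best), float(np.mean(heights))
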