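"""Neural-coding characterization of a single NLIF neuron.

Activity is the number of spikes in a fixed observation window (30 ms by
default).  The neuronal response function G[I_in] maps constant input
current to activity; a one-dimensional stimulus s (bar orientation, in
degrees) drives the neuron through a Gaussian stimulus-to-current map
I(s) = I_max exp(-(s - s_pref)^2 / (2 sigma_s^2)), so the noise-free
tuning curve is G[I(s)].  Under event-driven switching noise the spike
count becomes a random variable; its variance-mean scaling, the
inter-spike-interval distribution and the spike autocorrelation together
classify the noise as Poisson-like.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .circuit import DEFAULT_DT, SpikeTrain, raw_run
from .noise import NoiseSpec, certainly_silent, noise_free_reference, noisy_activity
from .params import NeuronCircuitParams

__all__ = [
    "StimulusMap",
    "TuningCurve",
    "ActivityStatistics",
    "ISIDistribution",
    "Correlogram",
    "ACTIVITY_WINDOW",
    "response_function",
    "firing_threshold",
    "tuning_curve",
    "noisy_tuning_curve",
    "variance_mean_statistics",
    "power_law_fit",
    "isi_fit",
    "spike_autocorrelation",
    "default_stimuli",
]

#: default activity observation window [s]
ACTIVITY_WINDOW = 30e-3


@dataclass(frozen=True)
class StimulusMap:
    """Gaussian stimulus-to-current map (stimulus in degrees, current in A)."""

    i_max: float = 1e-6
    s_pref: float = 0.0
    sigma_s: float = 30.0

    def __post_init__(self) -> None:
        if self.sigma_s <= 0:
            raise ValueError("sigma_s must be positive")

    def current(self, s) -> np.ndarray | float:
        s = np.asarray(s, dtype=float)
        out = self.i_max * np.exp(-((s - self.s_pref) ** 2)
                                  / (2.0 * self.sigma_s**2))
        return float(out) if out.ndim == 0 else out


@dataclass
class TuningCurve:
    stimuli: np.ndarray
    mean_activity: np.ndarray
    sd_activity: np.ndarray
    trials: int

    def __post_init__(self) -> None:
        if np.any(self.mean_activity < 0):
            raise ValueError("activities must be >= 0")

    def active_half_width(self, threshold: float = 1.0) -> float:
        """Largest |s - 0| (degrees) with mean activity >= threshold."""
        nz = np.abs(self.stimuli)[self.mean_activity >= threshold]
        return float(nz.max()) if nz.size else 0.0


@dataclass
class ActivityStatistics:
    """Mean/variance of activity per drive level and the power-law fit
    log(variance) = B log(mean) + log(A)."""

    i_in: np.ndarray
    mean_activity: np.ndarray
    variance: np.ndarray
    scaling_exponent: float
    scaling_prefactor: float
    fit_residual: float
    fitted_mask: np.ndarray


@dataclass
class ISIDistribution:
    isis: np.ndarray
    gamma_fit: tuple[float, float, float]  # (shape, scale, loglik)
    exp_fit: tuple[float, float]           # (rate, loglik)

    @property
    def gamma_beats_exponential(self) -> bool:
        return self.gamma_fit[2] > self.exp_fit[1]


@dataclass
class Correlogram:
    lags: np.ndarray
    values: np.ndarray  # pair fraction per bin


def response_function(
    params: NeuronCircuitParams,
    i_in_grid: np.ndarray,
    window: float = ACTIVITY_WINDOW,
    dt: float = DEFAULT_DT,
) -> np.ndarray:
    """Noise-free activity per constant input current (the G function)."""
    i_in_grid = np.asarray(i_in_grid, dtype=float)
    out = np.zeros(i_in_grid.size, dtype=int)
    for j, i_in in enumerate(i_in_grid):
        res = raw_run(params, float(i_in), window, dt)
        out[j] = int(np.count_nonzero(res.spike_times <= window))
    return out


def firing_threshold(
    params: NeuronCircuitParams,
    window: float = ACTIVITY_WINDOW,
    resolution: float = 0.01e-6,
    search_range: tuple[float, float] = (0.0, 1.0e-6),
    dt: float = DEFAULT_DT,
) -> float:
    """Smallest constant current producing >= 1 spike, by bisection.

    Raises if the upper end of ``search_range`` does not spike.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    lo, hi = search_range

    def spikes(i_in: float) -> bool:
        return len(raw_run(params, i_in, window, dt).spike_times) >= 1

    if not spikes(hi):
        raise ValueError(
            f"no spiking anywhere in the search range (up to {hi:g} A)")
    if spikes(lo):
        return lo
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if spikes(mid):
            hi = mid
        else:
            lo = mid
    return hi


def default_stimuli(step: float = 2.0, half_range: float = 90.0) -> np.ndarray:
    """Single-neuron stimulus grid: [-90, 90] degrees at 2-degree steps."""
    return np.arange(-half_range, half_range + step / 2, step)


def tuning_curve(
    params: NeuronCircuitParams,
    smap: StimulusMap,
    stimuli: np.ndarray | None = None,
    window: float = ACTIVITY_WINDOW,
    dt: float = DEFAULT_DT,
) -> TuningCurve:
    """Noise-free tuning curve: activity at I(s) for each stimulus."""
    stimuli = default_stimuli() if stimuli is None else np.asarray(stimuli, float)
    acts = response_function(params, smap.current(stimuli), window, dt)
    return TuningCurve(stimuli=stimuli, mean_activity=acts.astype(float),
                       sd_activity=np.zeros_like(stimuli, dtype=float), trials=1)


def noisy_tuning_curve(
    params: NeuronCircuitParams,
    smap: StimulusMap,
    stimuli: np.ndarray | None = None,
    noise: NoiseSpec | None = None,
    trials: int = 100,
    seed: int = 0,
    window: float = ACTIVITY_WINDOW,
    dt: float = DEFAULT_DT,
) -> TuningCurve:
    """Per-stimulus mean/sd of activity over seeded noisy trials.

    The noise model for tuning statistics varies the resistances only;
    a NoiseSpec with threshold-voltage deviations is rejected.  Stimuli
    whose noise-free simulation has no switching events are
    deterministically silent (the pre-event transient is unaffected by
    event-driven noise) and are not re-simulated per trial.
    """
    if noise is None:
        noise = NoiseSpec()
    if noise.dev_v_on > 0 or noise.dev_v_off > 0:
        raise ValueError("tuning statistics vary r_on/r_off only")
    stimuli = default_stimuli() if stimuli is None else np.asarray(stimuli, float)
    mean = np.zeros(stimuli.size)
    sd = np.zeros(stimuli.size)
    for j, s in enumerate(stimuli):
        i_in = float(smap.current(s))
        if not noise.is_noisy:
            ref = noise_free_reference(params, i_in, window, dt)
            mean[j] = ref.n_spikes
            continue
        if certainly_silent(params, noise, i_in, window, dt):
            continue
        stim_seed = int(np.random.SeedSequence((seed, j)).generate_state(1)[0]
                        % 2**31)
        counts = noisy_activity(params, noise, i_in, trials, stim_seed,
                                duration=window, dt=dt)["counts"]
        mean[j] = counts.mean()
        sd[j] = counts.std(ddof=1) if trials > 1 else 0.0
    return TuningCurve(stimuli=stimuli, mean_activity=mean, sd_activity=sd,
                       trials=trials)


def variance_mean_statistics(
    params: NeuronCircuitParams,
    noise: NoiseSpec,
    i_in_set: np.ndarray,
    trials: int = 100,
    window: float = ACTIVITY_WINDOW,
    seed: int = 0,
    dt: float = DEFAULT_DT,
    saturation_fraction: float | None = 0.8,
) -> ActivityStatistics:
    """Variance-mean scaling of activity across drive levels.

    The exponent B is the least-squares slope of log variance on log mean.
    Mean activity saturates at a ceiling set by the capacitor charging and
    discharging times (the integration time per spike), where the power
    law no longer holds; points whose mean exceeds ``saturation_fraction``
    of the grid maximum are therefore excluded from the fit by default.
    Pass ``saturation_fraction=None`` to fit every point with positive
    mean and variance.  A Poisson process gives B = 1 with A = 1.
    """
    i_in_set = np.asarray(i_in_set, dtype=float)
    if i_in_set.size < 2:
        raise ValueError("need at least two drive levels")
    if trials < 2:
        raise ValueError("need at least two trials per level")
    means = np.zeros(i_in_set.size)
    varis = np.zeros(i_in_set.size)
    for j, i_in in enumerate(i_in_set):
        point_seed = int(np.random.SeedSequence((seed, j)).generate_state(1)[0]
                         % 2**31)
        counts = noisy_activity(params, noise, float(i_in), trials, point_seed,
                                duration=window, dt=dt)["counts"]
        means[j] = counts.mean()
        varis[j] = counts.var(ddof=1)
    slope, prefactor, resid, mask = power_law_fit(means, varis,
                                                  saturation_fraction)
    return ActivityStatistics(
        i_in=i_in_set, mean_activity=means, variance=varis,
        scaling_exponent=slope, scaling_prefactor=prefactor,
        fit_residual=resid, fitted_mask=mask,
    )


def power_law_fit(means: np.ndarray, variances: np.ndarray,
                  saturation_fraction: float | None = 0.8
                  ) -> tuple[float, float, float, np.ndarray]:
    """Least-squares fit of log variance on log mean.

    Returns (exponent B, prefactor A, rms residual, fitted mask).  Points
    with non-positive mean or variance are excluded; points whose mean
    exceeds ``saturation_fraction`` of the largest mean are treated as
    ceiling-limited and excluded too (None disables this).
    """
    means = np.asarray(means, dtype=float)
    variances = np.asarray(variances, dtype=float)
    mask = (means > 0) & (variances > 0)
    if saturation_fraction is not None and mask.any():
        mask &= means < saturation_fraction * means.max()
    if np.count_nonzero(mask) < 2:
        raise ValueError("degenerate activity statistics: too few usable points")
    x, y = np.log(means[mask]), np.log(variances[mask])
    slope, intercept = np.polyfit(x, y, 1)
    resid = float(np.sqrt(np.mean((y - (slope * x + intercept)) ** 2)))
    return float(slope), float(np.exp(intercept)), resid, mask


def isi_fit(spike_trains: list[SpikeTrain], min_isis: int = 50) -> ISIDistribution:
    """Maximum-likelihood Gamma and Exponential fits to pooled ISIs.

    A Gamma shape above one reflects the effective refractory time set by
    the recharging of C1; for exponential-like ISIs the fitted shape is
    close to one and the two log-likelihoods coincide.
    """
    isis = np.concatenate([t.isis() for t in spike_trains]) if spike_trains \
        else np.empty(0)
    isis = isis[isis > 0]
    if isis.size < min_isis:
        raise ValueError(f"need at least {min_isis} ISIs, got {isis.size}")
    shape, _, scale = stats.gamma.fit(isis, floc=0)
    gamma_ll = float(np.sum(stats.gamma.logpdf(isis, shape, scale=scale)))
    _, exp_scale = stats.expon.fit(isis, floc=0)
    exp_ll = float(np.sum(stats.expon.logpdf(isis, scale=exp_scale)))
    return ISIDistribution(
        isis=isis,
        gamma_fit=(float(shape), float(scale), gamma_ll),
        exp_fit=(1.0 / float(exp_scale), exp_ll),
    )


def spike_autocorrelation(train: SpikeTrain, bin_width: float,
                          max_lag: float) -> Correlogram:
    """Histogram of all pairwise spike-time differences within +/- max_lag.

    Self-pairs are included, so the zero-lag bin is always populated; the
    values are fractions of the total pair count in range.  For
    uncorrelated (Poisson-like) trains the histogram is flat beyond the
    zero-lag bin.
    """
    t = train.spike_times
    if t.size < 2:
        raise ValueError("need at least two spikes")
    n_bins = 2 * int(np.ceil(max_lag / bin_width)) + 1
    edges = (np.arange(n_bins + 1) - n_bins / 2) * bin_width
    diffs = (t[None, :] - t[:, None]).ravel()
    # keep full coverage of the outermost bins so they are not half-empty
    diffs = diffs[np.abs(diffs) <= edges[-1]]
    hist, _ = np.histogram(diffs, bins=edges)
    lags = 0.5 * (edges[:-1] + edges[1:])
    return Correlogram(lags=lags, values=hist / diffs.size)
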