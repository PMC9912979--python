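"""Synthetic fNIRS datasets: event trains, HRF responses, AR noise, channel GLM.

Data are simulated by adding stimulation to autoregressive channel noise.  The
gaps between consecutive stimuli are exponentially distributed; the
hemodynamic response to a stimulus is the canonical double-gamma HRF,
peak-normalized so an isolated event attains exactly the configured HbO peak
(7 uM by default) and HbR peak (-2 uM).  The time-resolved channel signal is

    s_c(t) = [X (beta_true * h(t) + xi(t))]_c + e_c(t)

with h(t) the unit-peak HRF-convolved event regressor, xi(t) optional smooth
image-space physiological noise (off by default), and e_c(t) stationary AR
noise scaled to the requested SNR.  Because the reconstruction targets a
static effect image, each dataset is reduced to an effect-level measurement
(y, C_nu) by a channel-wise AR-prewhitened GLM before inversion.

Unstated study conditions use fixed defaults declared here: mean ISI 15 s,
scan duration 300 s, sampling rate 4 Hz, AR(3) noise with coefficients
(0.5, 0.2, 0.1), SNR 5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter
from scipy.stats import gamma as gamma_dist
from statsmodels.regression.linear_model import yule_walker
from statsmodels.tsa.arima_process import ArmaProcess

from .optics import ChannelData, ConfigurationError, SensitivityModel
from .parcels import Parcellation

__all__ = [
    "StimulusDesign",
    "SimScenario",
    "Dataset",
    "generate_stimulus_train",
    "canonical_hrf",
    "hrf_response",
    "simulate_timeseries",
    "channel_glm",
    "scenario_batch",
]

DEFAULT_MEAN_ISI = 15.0     # s
DEFAULT_DURATION = 300.0    # s
DEFAULT_RATE = 4.0          # Hz
DEFAULT_AR = (0.5, 0.2, 0.1)
DEFAULT_SNR = 5.0
DEFAULT_PEAK_HBO = 7.0      # uM
DEFAULT_PEAK_HBR = -2.0     # uM

#: variance floor for effect estimates from (near-)noiseless fits
VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class StimulusDesign:
    """Event onsets (s) within a scan of fixed duration and sampling rate."""

    onsets: np.ndarray
    mean_isi: float
    duration: float
    rate: float

    def __post_init__(self):
        onsets = np.asarray(self.onsets, dtype=float)
        if onsets.size and (np.any(np.diff(onsets) <= 0) or onsets[0] < 0
                            or onsets[-1] >= self.duration):
            raise ConfigurationError("onsets must be strictly increasing in [0, duration)")
        object.__setattr__(self, "onsets", onsets)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.rate))

    @property
    def n_events(self) -> int:
        return self.onsets.size


@dataclass(frozen=True)
class SimScenario:
    """Ground truth and noise settings for one simulated dataset."""

    beta_true: np.ndarray               # (P,) uM, zero outside the active group
    active_label: str | None = None
    peak_hbo: float = DEFAULT_PEAK_HBO  # uM
    peak_hbr: float = DEFAULT_PEAK_HBR  # uM
    ar_coeffs: tuple = DEFAULT_AR
    snr: float = DEFAULT_SNR
    noise_sd: float | None = None       # overrides SNR-derived channel noise SD
    xi_scale: float = 0.0               # image-space physiological noise SD (uM)
    xi_length: float = 2.0              # its spatial correlation length, in voxels
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "beta_true", np.asarray(self.beta_true, dtype=float))

    @classmethod
    def from_parcellation(
        cls,
        model: SensitivityModel,
        parcellation: Parcellation,
        active_label: str | None,
        **kwargs,
    ) -> "SimScenario":
        """True image with the configured peaks on every voxel of one group."""
        peak_hbo = kwargs.pop("peak_hbo", DEFAULT_PEAK_HBO)
        peak_hbr = kwargs.pop("peak_hbr", DEFAULT_PEAK_HBR)
        V = model.n_voxels
        beta = np.zeros(2 * V)
        if active_label is not None:
            g = list(parcellation.labels).index(active_label)
            voxels = parcellation.groups[g]
            beta[voxels] = peak_hbo
            beta[V + voxels] = peak_hbr
        return cls(beta_true=beta, active_label=active_label,
                   peak_hbo=peak_hbo, peak_hbr=peak_hbr, **kwargs)


@dataclass(frozen=True)
class Dataset:
    """Simulated channel time series plus its effect-level reduction inputs."""

    timeseries: np.ndarray        # (T, N) channel courses
    regressor: np.ndarray         # (T,) unit-peak HRF-convolved event train
    design: StimulusDesign
    scenario: SimScenario
    noise_sd: float               # realized per-channel AR noise SD

    @property
    def n_channels(self) -> int:
        return self.timeseries.shape[1]


# ---------------------------------------------------------------------------
# stimulus and response
# ---------------------------------------------------------------------------

def generate_stimulus_train(
    mean_isi: float = DEFAULT_MEAN_ISI,
    duration: float = DEFAULT_DURATION,
    rate: float = DEFAULT_RATE,
    seed: int | np.random.Generator = 0,
) -> StimulusDesign:
    """Event train with i.i.d. exponential inter-stimulus gaps, truncated at duration."""
    if mean_isi <= 0:
        raise ConfigurationError("mean inter-stimulus interval must be positive")
    rng = np.random.default_rng(seed)
    onsets = []
    t = rng.exponential(mean_isi)
    while t < duration:
        onsets.append(t)
        t += rng.exponential(mean_isi)
    if duration < mean_isi:
        warnings.warn("scan shorter than one mean gap; stimulus train may be empty")
    return StimulusDesign(
        onsets=np.asarray(onsets), mean_isi=mean_isi, duration=duration, rate=rate
    )


def canonical_hrf(t: np.ndarray, peak_time: float = 6.0, undershoot_time: float = 16.0,
                  undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at times ``t`` (not normalized)."""
    t = np.asarray(t, dtype=float)
    h = gamma_dist.pdf(t, peak_time) - undershoot_ratio * gamma_dist.pdf(t, undershoot_time)
    return np.where(t >= 0, h, 0.0)


def _unit_regressor(design: StimulusDesign) -> np.ndarray:
    """Event train convolved with the HRF, scaled so one isolated event peaks at 1."""
    T = design.n_frames
    dt = 1.0 / design.rate
    kernel = canonical_hrf(np.arange(0, 32.0, dt))
    peak = kernel.max()
    if peak <= 0:
        raise ConfigurationError("degenerate HRF kernel")
    kernel = kernel / peak
    train = np.zeros(T)
    frames = np.round(design.onsets * design.rate).astype(int)
    np.add.at(train, frames[frames < T], 1.0)
    return np.convolve(train, kernel)[:T]


def hrf_response(
    design: StimulusDesign,
    peak_hbo: float = DEFAULT_PEAK_HBO,
    peak_hbr: float = DEFAULT_PEAK_HBR,
):
    """Noiseless HbO and HbR time courses for the given event train.

    An isolated event attains exactly ``peak_hbo`` at the HbO maximum and
    ``peak_hbr`` at the HbR extremum; overlapping events superpose linearly.
    """
    u = _unit_regressor(design)
    return peak_hbo * u, peak_hbr * u


# ---------------------------------------------------------------------------
# time-series simulation
# ---------------------------------------------------------------------------

def _ar_process(ar_coeffs) -> ArmaProcess:
    proc = ArmaProcess(np.r_[1.0, -np.asarray(ar_coeffs, dtype=float)], [1.0])
    if not proc.isstationary:
        raise ConfigurationError(f"AR coefficients {tuple(ar_coeffs)} are non-stationary")
    return proc


def _ar_noise(rng, ar_coeffs, shape, target_sd):
    """Stationary AR noise with per-channel marginal SD ``target_sd``."""
    proc = _ar_process(ar_coeffs)
    stat_sd = float(np.sqrt(proc.acovf(1)[0]))  # process SD for unit innovations
    innov = rng.standard_normal(shape)
    noise = lfilter([1.0], np.r_[1.0, -np.asarray(ar_coeffs, dtype=float)], innov, axis=0)
    return noise * (target_sd / stat_sd)


def _xi_field(rng, model, scale, length_vox):
    """Zero-mean Gaussian image-space noise, exponential spatial correlation."""
    coords = model.grid.coordinates
    ell = length_vox * model.grid.spacing
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    K = np.exp(-dist / ell)
    L = np.linalg.cholesky(K + 1e-10 * np.eye(len(coords)))
    z = L @ rng.standard_normal((len(coords), 2))
    return scale * z.T.ravel()  # (P,), HbO block then HbR block


def simulate_timeseries(
    scenario: SimScenario,
    model: SensitivityModel,
    design: StimulusDesign,
) -> Dataset:
    """Project the true image through the forward model and add AR noise.

    SNR is defined as the peak channel signal amplitude over the noise SD on
    the most sensitive channel; for noise-only scenarios (zero signal) an
    explicit ``noise_sd`` must be provided.  Fully reproducible: all
    randomness comes from ``scenario.seed``.
    """
    if scenario.beta_true.size != model.n_coefficients:
        raise ConfigurationError("beta_true length does not match the model")
    rng = np.random.default_rng(scenario.seed)
    u = _unit_regressor(design)
    T, N = u.size, model.n_channels

    signal = np.outer(u, model.jacobian @ scenario.beta_true)   # (T, N)
    if scenario.xi_scale > 0:
        xi = _xi_field(rng, model, scenario.xi_scale, scenario.xi_length)
        signal = signal + np.outer(u, model.jacobian @ xi)

    if scenario.noise_sd is not None:
        sd = float(scenario.noise_sd)
    else:
        peak = float(np.abs(signal).max())
        if peak <= 0:
            raise ConfigurationError(
                "noise-only scenario requires an explicit noise_sd (SNR is undefined)"
            )
        sd = peak / scenario.snr

    ts = signal + (_ar_noise(rng, scenario.ar_coeffs, (T, N), sd) if sd > 0 else 0.0)
    return Dataset(timeseries=ts, regressor=u, design=design,
                   scenario=scenario, noise_sd=sd)


# ---------------------------------------------------------------------------
# channel GLM reduction
# ---------------------------------------------------------------------------

def channel_glm(dataset: Dataset, ar_order: int | None = None,
                noise_only_ok: bool = False) -> ChannelData:
    """Reduce a dataset to effect level: per-channel AR-prewhitened least squares.

    Each channel course is regressed on the unit-peak HRF regressor (plus an
    intercept); residual autocorrelation is fit by Yule-Walker at the
    scenario's AR order, both sides are prewhitened, and the fit is repeated.
    ``y`` stacks the effect estimates in the model's channel order; ``C_nu``
    is the diagonal matrix of effect-estimate variances (floored at 1e-12).
    """
    u = dataset.regressor
    if dataset.design.n_events < 2 and not noise_only_ok:
        raise ConfigurationError(
            "need at least 2 events (or noise_only_ok=True) for a stable effect fit"
        )
    if np.ptp(u) <= 0:
        raise ConfigurationError("rank-deficient design: constant regressor")
    order = len(dataset.scenario.ar_coeffs) if ar_order is None else ar_order
    Z = np.column_stack([u, np.ones_like(u)])
    T = u.size

    effects = np.empty(dataset.n_channels)
    variances = np.empty(dataset.n_channels)
    for c in range(dataset.n_channels):
        yc = dataset.timeseries[:, c]
        coef, *_ = np.linalg.lstsq(Z, yc, rcond=None)
        resid = yc - Z @ coef
        rvar = float(resid @ resid) / max(T - Z.shape[1], 1)
        if order > 0 and rvar > VAR_FLOOR:
            rho, _ = yule_walker(resid, order=order, method="mle")
            wfilt = np.r_[1.0, -rho]
            Zw = lfilter(wfilt, [1.0], Z, axis=0)
            yw = lfilter(wfilt, [1.0], yc)
        else:
            Zw, yw = Z, yc
        gram_inv = np.linalg.inv(Zw.T @ Zw)
        coef = gram_inv @ (Zw.T @ yw)
        resid_w = yw - Zw @ coef
        s2 = float(resid_w @ resid_w) / max(T - Z.shape[1], 1)
        effects[c] = coef[0]
        variances[c] = max(s2 * gram_inv[0, 0], VAR_FLOOR)

    return ChannelData(y=effects, cov=np.diag(variances))


# ---------------------------------------------------------------------------
# study batches
# ---------------------------------------------------------------------------

def scenario_batch(
    model: SensitivityModel,
    parcellation: Parcellation,
    active_labels,
    n_active: int,
    n_noise: int,
    seed: int = 0,
    **scenario_kwargs,
):
    """Replicate the simulation-study design: per active region, ``n_active``
    activity datasets plus ``n_noise`` matched noise-only datasets.

    Noise-only scenarios reuse the channel-noise SD implied by their region's
    activity signal at the configured SNR, so active and null datasets share a
    noise level.  Returns a list of (label-or-None, SimScenario); seeds are
    spawned deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    out = []
    snr = scenario_kwargs.get("snr", DEFAULT_SNR)
    for label in active_labels:
        ref = SimScenario.from_parcellation(model, parcellation, label, **scenario_kwargs)
        peak = float(np.abs(model.jacobian @ ref.beta_true).max())
        sd = peak / snr
        children = ss.spawn(n_active + n_noise)
        for k in range(n_active):
            out.append((label, replace(ref, seed=children[k].generate_state(1)[0] % 2**31)))
        null = SimScenario.from_parcellation(
            model, parcellation, None, **{**scenario_kwargs, "noise_sd": sd}
        )
        for k in range(n_noise):
            out.append(
                (None, replace(null, seed=children[n_active + k].generate_state(1)[0] % 2**31))
            )
    return out
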