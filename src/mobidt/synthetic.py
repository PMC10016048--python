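"""Synthetic cohort generator for the dual-task (Go/NoGo + treadmill) design.

Emulates the three data streams of the experiment so every downstream stage
can be exercised without access to recorded data:

* behavioral event tables -- blocks of 240 trials, 13% NoGo (a NoGo is a
  repeat of the immediately preceding image), fixed 1017-ms SOA, responses
  drawn from a truncated-normal RT distribution with configurable hit and
  false-alarm rates;
* quasi-periodic 3D heel-marker traces at 360 samples/s with controllable
  stride-to-stride jitter;
* ERP epoch sets on the 64-channel montage built from N2/P3/ERN/PMP
  component templates plus spatially correlated 1/f noise, with injectable
  walking-minus-sitting amplitude deltas.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidConfigError, TooShortError, UnknownChannelError
from .montage import angular_distance, channel_indices, get_biosemi64

__all__ = [
    "ErpTemplate",
    "NoiseSpec",
    "GaitTrace",
    "EpochSet",
    "gen_trial_sequence",
    "gen_responses",
    "gen_gait_trace",
    "gen_epoch_set",
    "default_templates",
]

GAIT_SAMPLE_RATE = 360.0  # motion-capture frame rate, frames/s


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# behavioral stream
# ---------------------------------------------------------------------------

def gen_trial_sequence(
    n_trials: int,
    nogo_fraction: float,
    soa_ms: float = 1017.0,
    seed=None,
    block_id: int = 0,
    motor_condition: str = "sitting",
) -> pd.DataFrame:
    """Generate one block of Go/NoGo trials.

    A NoGo trial is a repeat of the immediately preceding image, so the first
    trial of a block is always Go and no two NoGo trials are adjacent (a
    second immediate repeat would be ambiguous).  NoGo positions are drawn
    uniformly at random among the admissible (non-adjacent, non-initial)
    position sets.  Onsets fall at ``k * soa_ms``.
    """
    if n_trials < 2:
        raise InvalidConfigError("need at least 2 trials per block")
    if not 0.0 < nogo_fraction < 1.0:
        raise InvalidConfigError("nogo_fraction must be strictly inside (0, 1)")
    n_nogo = int(round(n_trials * nogo_fraction))
    if n_nogo < 1:
        raise InvalidConfigError("nogo_fraction too small: rounds to zero NoGo trials")
    # positions 1..n-1 with no two adjacent; feasibility bound
    if n_nogo > (n_trials - 1 + 1) // 2:
        raise InvalidConfigError("nogo_fraction too large for non-adjacent placement")
    rng = _rng(seed)
    # classic bijection: k non-adjacent slots among m = n_trials-1 candidates
    m = n_trials - 1
    base = np.sort(rng.choice(m - n_nogo + 1, size=n_nogo, replace=False))
    nogo_pos = 1 + base + np.arange(n_nogo)

    trial_type = np.full(n_trials, "go", dtype=object)
    trial_type[nogo_pos] = "nogo"
    image_id = np.empty(n_trials, dtype=int)
    next_img = 0
    for i in range(n_trials):
        if trial_type[i] == "go":
            image_id[i] = next_img
            next_img += 1
        else:
            image_id[i] = image_id[i - 1]
    return pd.DataFrame(
        {
            "block": block_id,
            "trial_idx": np.arange(n_trials),
            "onset_ms": np.arange(n_trials) * float(soa_ms),
            "trial_type": trial_type,
            "image_id": image_id,
            "motor_condition": motor_condition,
            "response_ms": np.nan,
        }
    )


def gen_responses(
    trials: pd.DataFrame,
    hit_rate: float,
    fa_rate: float,
    rt_mean_ms: float,
    rt_sd_ms: float,
    rt_floor_ms: float = 100.0,
    seed=None,
) -> pd.DataFrame:
    """Attach button-press latencies to a trial sequence.

    Go trials receive a response with probability ``hit_rate``, NoGo trials
    with probability ``fa_rate``.  Latencies are truncated-normal
    (floor ``rt_floor_ms``) relative to stimulus onset.
    """
    for name, v in [("hit_rate", hit_rate), ("fa_rate", fa_rate)]:
        if not 0.0 <= v <= 1.0:
            raise InvalidConfigError(f"{name} must lie in [0, 1]")
    if rt_mean_ms <= 0 or rt_sd_ms <= 0 or rt_floor_ms <= 0:
        raise InvalidConfigError("RT parameters must be positive")
    rng = _rng(seed)
    out = trials.copy()
    n = len(out)
    u = rng.random(n)
    a = (rt_floor_ms - rt_mean_ms) / rt_sd_ms
    rts = sps.truncnorm.rvs(a, np.inf, loc=rt_mean_ms, scale=rt_sd_ms, size=n, random_state=rng)
    is_go = (out["trial_type"] == "go").to_numpy()
    respond = np.where(is_go, u < hit_rate, u < fa_rate)
    out["response_ms"] = np.where(respond, rts, np.nan)
    return out


# ---------------------------------------------------------------------------
# gait stream
# ---------------------------------------------------------------------------

@dataclass
class GaitTrace:
    """3D heel-marker trajectory of one foot on the treadmill.

    Axes: X lateral, Y vertical, Z fore-aft (parallel to the belt), meters.
    """

    foot: str
    sample_rate: float
    t: np.ndarray
    xyz: np.ndarray  # (n, 3)

    def __post_init__(self):
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise InvalidConfigError("xyz must be (n, 3)")
        if len(self.t) != len(self.xyz):
            raise InvalidConfigError("t and xyz lengths differ")


def _heel_template(phase: np.ndarray) -> np.ndarray:
    """Template heel path over one stride (phase in [0, 1), Z peak at 0.5).

    Fore-aft: ~1.1-m peak-to-trough sweep (stance drift back, swing forward);
    vertical: double bump from heel-off and mid-swing; lateral: small sway.
    """
    x = 0.02 * np.sin(2 * np.pi * phase)
    y = 0.06 * (1 - np.cos(4 * np.pi * phase)) + 0.02 * np.sin(2 * np.pi * phase)
    z = -0.55 * np.cos(2 * np.pi * phase) + 0.08 * np.cos(4 * np.pi * phase)
    return np.column_stack([x, y, z])


def gen_gait_trace(
    duration_s: float,
    stride_period_s: float = 1.1,
    jitter_m: float = 0.0,
    foot: str = "left",
    seed=None,
    sample_rate: float = GAIT_SAMPLE_RATE,
) -> GaitTrace:
    """Generate a quasi-periodic heel trace with controllable stride jitter.

    Each stride is the template path plus a smooth random displacement field
    with pointwise standard deviation ``jitter_m`` per axis, plus a small
    random within-stride time warp that scales with the same knob.  With
    ``jitter_m = 0`` every stride is sample-identical.
    """
    if stride_period_s <= 0:
        raise InvalidConfigError("stride_period_s must be positive")
    if duration_s < 3 * stride_period_s:
        raise TooShortError("trace must cover at least 3 stride periods")
    rng = _rng(seed)
    n_per = int(round(stride_period_s * sample_rate))
    n_cycles = int(np.floor(duration_s * sample_rate / n_per))
    phase = np.arange(n_per) / n_per

    n_harm = 4
    coeff_sd = jitter_m / np.sqrt(2.0 * n_harm)  # pointwise SD == jitter_m
    warp_sd = 0.3 * jitter_m  # phase units; heuristic coupling, 0 at jitter 0
    chunks = []
    for _ in range(n_cycles):
        if jitter_m > 0:
            w = np.clip(rng.normal(0.0, warp_sd), -0.2, 0.2)
            ph0 = rng.uniform(0, 2 * np.pi)
            p = (phase + w * np.sin(2 * np.pi * phase + ph0) / (2 * np.pi)) % 1.0
        else:
            p = phase
        cyc = _heel_template(p)
        if jitter_m > 0:
            h = np.arange(1, n_harm + 1)[:, None]
            arg = 2 * np.pi * h * phase[None, :]
            a = rng.normal(0.0, coeff_sd, size=(n_harm, 3))
            b = rng.normal(0.0, coeff_sd, size=(n_harm, 3))
            disp = np.einsum("hp,hd->pd", np.sin(arg), a) + np.einsum(
                "hp,hd->pd", np.cos(arg), b
            )
            cyc = cyc + disp
        chunks.append(cyc)
    xyz = np.concatenate(chunks, axis=0)
    t = np.arange(len(xyz)) / sample_rate
    return GaitTrace(foot=foot, sample_rate=sample_rate, t=t, xyz=xyz)


# ---------------------------------------------------------------------------
# EEG stream
# ---------------------------------------------------------------------------

@dataclass
class ErpTemplate:
    """One ERP component template on the 64-channel montage.

    The time course is a raised cosine confined to ``window_ms`` (peak at the
    window centre unless ``peak_latency_ms`` is given); the scalp projection
    is a Gaussian in great-circle distance around ``peak_channel``.
    """

    name: str
    amplitude_uv: float
    window_ms: tuple[float, float]
    peak_channel: str = "Cz"
    scalp_sigma_rad: float = 0.7
    peak_latency_ms: float | None = None

    def time_course(self, times_ms: np.ndarray) -> np.ndarray:
        lo, hi = self.window_ms
        if hi <= lo:
            raise InvalidConfigError(f"{self.name}: empty latency window")
        centre = self.peak_latency_ms if self.peak_latency_ms is not None else 0.5 * (lo + hi)
        width = hi - lo
        inside = (times_ms >= lo) & (times_ms <= hi)
        tc = np.zeros_like(times_ms, dtype=float)
        tc[inside] = 0.5 * (1 + np.cos(2 * np.pi * (times_ms[inside] - centre) / width))
        return self.amplitude_uv * tc

    def scalp_weighting(self, ch_names: list[str], positions: np.ndarray) -> np.ndarray:
        idx = channel_indices(ch_names, [self.peak_channel])[0]
        dist = angular_distance(positions)[idx]
        return np.exp(-0.5 * (dist / self.scalp_sigma_rad) ** 2)

    def project(self, ch_names, positions, times_ms) -> np.ndarray:
        """channels x time contribution of this component, microvolts."""
        return np.outer(self.scalp_weighting(ch_names, positions), self.time_course(times_ms))


def default_templates(lock: str) -> list[ErpTemplate]:
    """Canonical component set per epoch lock.

    Stimulus-locked (correct rejections): frontocentral N2 in [200, 350] ms
    and centroparietal P3 in [350, 600] ms.  Response-locked (false alarms):
    frontocentral ERN in [-50, 100] ms and a central premovement positivity
    in [-210, -50] ms.
    """
    if lock == "stimulus_onset":
        return [
            ErpTemplate("N2", -4.0, (200.0, 350.0), peak_channel="FCz"),
            ErpTemplate("P3", 8.0, (350.0, 600.0), peak_channel="CPz"),
        ]
    if lock == "response_onset":
        return [
            ErpTemplate("ERN", -6.0, (-50.0, 100.0), peak_channel="FCz", peak_latency_ms=50.0),
            ErpTemplate("PMP", 4.0, (-210.0, -50.0), peak_channel="Cz"),
        ]
    raise InvalidConfigError(f"unknown lock {lock!r}")


@dataclass
class NoiseSpec:
    """Additive noise model for synthetic epochs.

    Pink (1/f^exponent) and white components, in microvolts of pointwise SD,
    mixed across channels with a Gaussian spatial kernel of width
    ``spatial_sigma_rad`` on the scalp sphere (rows renormalised so the
    per-channel SD is preserved).
    """

    pink_sd_uv: float = 6.0
    white_sd_uv: float = 4.0
    exponent: float = 1.0
    spatial_sigma_rad: float = 0.6


@dataclass
class EpochSet:
    """Epochs x channels x time voltage array with montage and labels."""

    data: np.ndarray  # (n_epochs, n_channels, n_times), microvolts
    ch_names: list[str]
    positions: np.ndarray  # (n_channels, 3), unit sphere
    sfreq: float
    times_ms: np.ndarray
    lock: str  # stimulus_onset | response_onset
    cognitive: str  # correct_rejection | false_alarm
    motor: str  # sitting | walking

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


@dataclass
class ErpWaveform:
    """Condition-mean ERP: channels x time, with the epoch count averaged."""

    data: np.ndarray  # (n_channels, n_times), microvolts
    ch_names: list[str]
    times_ms: np.ndarray
    n_epochs: int
    lock: str
    cognitive: str
    motor: str


def _pink_noise(rng, shape, exponent, sfreq):
    """1/f^exponent noise along the last axis, unit pointwise SD."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal(shape[:-1] + (len(freqs),))
            + 1j * rng.standard_normal(shape[:-1] + (len(freqs),))) * scale
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _spatial_mixer(positions: np.ndarray, sigma_rad: float) -> np.ndarray:
    """Row-normalised Gaussian smoothing kernel over electrodes."""
    k = np.exp(-0.5 * (angular_distance(positions) / sigma_rad) ** 2)
    return k / np.linalg.norm(k, axis=1, keepdims=True)


def epoch_times(lock: str, sfreq: float) -> np.ndarray:
    """Epoch time vector (ms): [-200, 800] stimulus-locked, [-500, 500] response-locked."""
    lo, hi = (-200.0, 800.0) if lock == "stimulus_onset" else (-500.0, 500.0)
    n = int(round((hi - lo) / 1000.0 * sfreq)) + 1
    return lo + np.arange(n) * 1000.0 / sfreq


def gen_epoch_set(
    templates: list[ErpTemplate],
    n_epochs: int,
    lock: str,
    cognitive: str,
    motor: str = "sitting",
    effects: list[tuple[str, list[str], tuple[float, float], float]] | None = None,
    noise: NoiseSpec | None = None,
    sfreq: float = 512.0,
    seed=None,
    ch_names: list[str] | None = None,
    positions: np.ndarray | None = None,
) -> EpochSet:
    """Generate an epoch set: component templates + injected deltas + noise.

    ``effects`` entries are ``(name, electrodes, (lo_ms, hi_ms), delta_uv)``;
    each adds a flat ``delta_uv`` offset on the listed electrodes inside the
    latency window, so the condition mean recovers the injection exactly when
    the noise is switched off.
    """
    if n_epochs < 1:
        raise InvalidConfigError("n_epochs must be >= 1")
    if ch_names is None or positions is None:
        ch_names, positions = get_biosemi64()
    if len(ch_names) != len(positions):
        raise InvalidConfigError("ch_names and positions disagree")
    times = epoch_times(lock, sfreq)
    for tpl in templates:
        if tpl.window_ms[0] < times[0] or tpl.window_ms[1] > times[-1]:
            raise InvalidConfigError(f"template {tpl.name} window outside epoch bounds")

    base = np.zeros((len(ch_names), len(times)))
    for tpl in templates:
        base += tpl.project(ch_names, positions, times)
    if effects:
        for name, electrodes, (lo, hi), delta in effects:
            idx = channel_indices(ch_names, list(electrodes))
            tmask = (times >= lo) & (times <= hi)
            base[np.ix_(idx, tmask)] += delta

    rng = _rng(seed)
    data = np.broadcast_to(base, (n_epochs,) + base.shape).copy()
    if noise is not None and (noise.pink_sd_uv > 0 or noise.white_sd_uv > 0):
        shape = (n_epochs, len(ch_names), len(times))
        nz = np.zeros(shape)
        if noise.pink_sd_uv > 0:
            nz += noise.pink_sd_uv * _pink_noise(rng, shape, noise.exponent, sfreq)
        if noise.white_sd_uv > 0:
            nz += noise.white_sd_uv * rng.standard_normal(shape)
        mixer = _spatial_mixer(positions, noise.spatial_sigma_rad)
        data += np.einsum("cd,edt->ect", mixer, nz)
    return EpochSet(
        data=data,
        ch_names=list(ch_names),
        positions=positions,
        sfreq=sfreq,
        times_ms=times,
        lock=lock,
        cognitive=cognitive,
        motor=motor,
    )
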