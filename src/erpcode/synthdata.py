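"""Seeded synthetic oddball-EEG datasets.

Emulates a two-stimulus visual oddball recording: every trial is a fixed
600 ms epoch (100 ms pre-stimulus baseline, 500 ms post-stimulus) sampled at
250 Hz, containing band-limited background EEG noise plus an evoked late
positive deflection (a P300-like Gaussian bump) that is strong in rare
*target* trials and weak in frequent *standard* trials.  The default task
uses the canonical 40-target / 95-standard split of a 135-trial session.

Everything is driven by a single integer seed; identical parameters and seed
yield a bit-identical dataset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Trial, EpochSet, bandpass_filter, _design_sos

_SD_CACHE: dict = {}


def _filtfilt_output_sd(fs: float, band: tuple[float, float]) -> float:
    """Long-run std of unit-variance white noise after the forward-backward
    band-pass: sqrt of the mean squared magnitude response |H|^4 over the
    frequency axis (white input PSD is flat)."""
    key = (fs, band)
    if key not in _SD_CACHE:
        from scipy import signal as _signal
        _, h = _signal.sosfreqz(_design_sos(fs, band[0], band[1]), worN=8192)
        _SD_CACHE[key] = float(np.sqrt(np.mean(np.abs(h) ** 4)))
    return _SD_CACHE[key]

__all__ = [
    "TaskDesign",
    "ERPTemplate",
    "NoiseModel",
    "SyntheticDataset",
    "make_design",
    "oddball_design",
    "scalp_gains",
    "default_target_template",
    "default_standard_template",
    "generate_dataset",
    "inject_artifact",
    "save_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class TaskDesign:
    """Geometry of an oddball session: trial counts, timing, channel count."""

    n_trials: int
    target_fraction: float
    n_target: int
    n_standard: int
    fs: float
    pre_ms: float
    post_ms: float
    n_channels: int
    trial_len: int

    @property
    def pre_samples(self) -> int:
        return int(round(self.pre_ms * self.fs / 1000.0))

    @property
    def post_samples(self) -> int:
        return int(round(self.post_ms * self.fs / 1000.0))


@dataclass(frozen=True)
class ERPTemplate:
    """A unimodal evoked component: Gaussian bump in time, scaled per channel.

    ``width_ms`` is the full width at half maximum of the bump;
    ``channel_gains`` (in [0, 1], one per channel) model the scalp projection.
    Optional per-trial jitter emulates trial-to-trial amplitude and latency
    variability; both default to zero.
    """

    component_label: str = "P300"
    peak_latency_ms: float = 300.0
    amplitude_uV: float = 10.0
    width_ms: float = 80.0
    channel_gains: tuple[float, ...] | None = None
    amplitude_jitter_uV: float = 0.0
    latency_jitter_ms: float = 0.0

    def waveform(self, design: TaskDesign,
                 amplitude_uV: float | None = None,
                 peak_latency_ms: float | None = None) -> np.ndarray:
        """Render the bump on the epoch time axis -> (trial_len, n_channels)."""
        amp = self.amplitude_uV if amplitude_uV is None else amplitude_uV
        lat = self.peak_latency_ms if peak_latency_ms is None else peak_latency_ms
        if not (0.0 < self.peak_latency_ms <= design.post_ms):
            raise ValueError(
                f"peak latency {self.peak_latency_ms} ms outside the "
                f"(0, {design.post_ms}] ms post-stimulus window")
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")
        t_ms = (np.arange(design.trial_len) - design.pre_samples) / design.fs * 1000.0
        sigma_ms = self.width_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # FWHM -> sd
        bump = amp * np.exp(-0.5 * ((t_ms - lat) / sigma_ms) ** 2)
        gains = (np.ones(design.n_channels) if self.channel_gains is None
                 else np.asarray(self.channel_gains, dtype=float))
        if gains.shape != (design.n_channels,):
            raise ValueError("channel_gains length must equal n_channels")
        return bump[:, None] * gains[None, :]


@dataclass(frozen=True)
class NoiseModel:
    """Background EEG noise: Gaussian, optionally shaped to the 0.3-30 Hz band.

    ``spectral_shape`` is ``"white"`` or ``"band"`` (white noise band-pass
    filtered to ``band`` and rescaled so its empirical standard deviation is
    ``sd_uV``).
    """

    sd_uV: float = 10.0
    spectral_shape: str = "band"
    band: tuple[float, float] = (0.3, 30.0)

    def __post_init__(self):
        if self.sd_uV < 0:
            raise ValueError("sd_uV must be non-negative")
        if self.spectral_shape not in ("white", "band"):
            raise ValueError(f"unknown spectral_shape {self.spectral_shape!r}")

    def realize(self, rng: np.random.Generator, n_samples: int,
                n_channels: int, fs: float) -> np.ndarray:
        if self.sd_uV == 0:
            return np.zeros((n_samples, n_channels))
        if self.spectral_shape == "white":
            return self.sd_uV * rng.standard_normal((n_samples, n_channels))
        # Filter a padded realization and keep the central window so the
        # segment is stationary, and scale by the filter's long-run output
        # sd (not the realized one: dividing by a per-trial sd estimated
        # from ~30 effective dof would inflate cross-trial variance).
        pad = int(round(2 * fs))
        white = rng.standard_normal((n_samples + 2 * pad, n_channels))
        shaped = bandpass_filter(white, fs, low=self.band[0],
                                 high=self.band[1])
        segment = shaped[pad:pad + n_samples]
        return self.sd_uV * segment / _filtfilt_output_sd(fs, self.band)


@dataclass
class SyntheticDataset:
    trials: list[Trial]
    labels: list[str]
    design: TaskDesign
    provenance: dict = field(default_factory=dict)

    def to_epochset(self) -> EpochSet:
        return EpochSet(
            trials=list(self.trials),
            channel_ids=[f"ch{j:02d}" for j in range(self.design.n_channels)],
            reference="single-electrode",
        )


def make_design(n_trials: int, target_fraction: float, fs: float,
                pre_ms: float, post_ms: float, n_channels: int,
                n_target: int | None = None,
                n_standard: int | None = None) -> TaskDesign:
    """Build a :class:`TaskDesign`.

    ``n_target`` defaults to ``floor(n_trials * target_fraction + 0.5)``;
    explicit ``n_target``/``n_standard`` counts override the fraction (the
    canonical session states 40/95 although 135 x 0.30 = 40.5).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must lie in [0, 1]")
    if fs <= 0:
        raise ValueError("fs must be positive")
    raw_len = (pre_ms + post_ms) * fs / 1000.0
    trial_len = int(round(raw_len))
    if abs(raw_len - trial_len) > 1e-9 or trial_len <= 0:
        raise ValueError(
            f"(pre_ms + post_ms) * fs must give an integral positive sample "
            f"count, got {raw_len}")
    if n_target is None and n_standard is None:
        n_target = int(np.floor(n_trials * target_fraction + 0.5))
        n_standard = n_trials - n_target
    elif n_target is None:
        n_target = n_trials - n_standard
    elif n_standard is None:
        n_standard = n_trials - n_target
    if n_target + n_standard != n_trials or min(n_target, n_standard) < 0:
        raise ValueError("n_target + n_standard must equal n_trials")
    return TaskDesign(n_trials=n_trials, target_fraction=target_fraction,
                      n_target=n_target, n_standard=n_standard, fs=fs,
                      pre_ms=pre_ms, post_ms=post_ms, n_channels=n_channels,
                      trial_len=trial_len)


def scalp_gains(n_channels: int, peak: float = 0.7, width: float = 0.25,
                floor: float = 0.0) -> tuple[float, ...]:
    """Focal parietal-peaked channel gain profile in [0, 1].

    Channels are laid out on a line from frontal (0) to occipital (1); the
    gain is a Gaussian centred at ``peak`` (default: parietal, where the
    late positive deflection is maximal) with spatial ``width`` and a
    ``floor`` reached far from the peak.  A focal topography keeps the
    evoked component visible after average referencing, which removes any
    channel-common signal.
    """
    if n_channels == 1:
        return (1.0,)
    pos = np.linspace(0.0, 1.0, n_channels)
    g = floor + (1.0 - floor) * np.exp(-0.5 * ((pos - peak) / width) ** 2)
    return tuple(float(v) for v in g)


def oddball_design(n_channels: int = 8) -> TaskDesign:
    """The canonical 135-trial session: 40 targets, 95 standards, 250 Hz,
    600 ms epochs with a 100 ms baseline."""
    return make_design(135, 0.30, 250.0, 100.0, 500.0, n_channels,
                       n_target=40, n_standard=95)


def default_target_template() -> ERPTemplate:
    return ERPTemplate("P300", peak_latency_ms=300.0, amplitude_uV=10.0,
                       width_ms=80.0)


def default_standard_template() -> ERPTemplate:
    # "relatively low" evoked response to the frequent stimulus; the 5:1
    # amplitude ratio is a simulation choice, not a measured quantity.
    return ERPTemplate("P300", peak_latency_ms=300.0, amplitude_uV=2.0,
                       width_ms=80.0)


def generate_dataset(design: TaskDesign,
                     target_template: ERPTemplate | None = None,
                     standard_template: ERPTemplate | None = None,
                     noise: NoiseModel | None = None,
                     seed: int = 0) -> SyntheticDataset:
    """Simulate one subject's session.

    Each trial is an independent noise realization plus the label-appropriate
    evoked template; label order is a seed-determined permutation.  One
    top-level seed is split deterministically per trial, so the same call is
    bit-identical and remains aligned trial-by-trial when only the templates
    or only the noise change (superposition).
    """
    target_template = target_template or default_target_template()
    standard_template = standard_template or default_standard_template()
    noise = noise or NoiseModel()

    labels = np.array(["target"] * design.n_target +
                      ["standard"] * design.n_standard)
    order_rng = np.random.default_rng(np.random.SeedSequence(seed))
    labels = labels[order_rng.permutation(design.n_trials)]

    child_seeds = np.random.SeedSequence(seed).spawn(design.n_trials + 1)[1:]
    trials: list[Trial] = []
    for i, (label, ss) in enumerate(zip(labels, child_seeds)):
        rng = np.random.default_rng(ss)
        template = target_template if label == "target" else standard_template
        amp = template.amplitude_uV
        lat = template.peak_latency_ms
        if template.amplitude_jitter_uV > 0:
            amp = amp + template.amplitude_jitter_uV * rng.standard_normal()
        if template.latency_jitter_ms > 0:
            lat = lat + template.latency_jitter_ms * rng.standard_normal()
        evoked = template.waveform(design, amplitude_uV=amp, peak_latency_ms=lat)
        background = noise.realize(rng, design.trial_len, design.n_channels,
                                   design.fs)
        trials.append(Trial(samples=background + evoked, fs=design.fs,
                            pre_samples=design.pre_samples, label=str(label),
                            trial_id=f"trial{i:03d}"))
    provenance = {
        "seed": int(seed),
        "design": dataclasses.asdict(design),
        "target_template": dataclasses.asdict(target_template),
        "standard_template": dataclasses.asdict(standard_template),
        "noise": dataclasses.asdict(noise),
    }
    return SyntheticDataset(trials=trials, labels=[str(l) for l in labels],
                            design=design, provenance=provenance)


def inject_artifact(trial: Trial, amplitude_uV: float,
                    kind: str = "blink", at_sample: int | None = None,
                    width_samples: int = 10, channel: int = 0) -> Trial:
    """Return a copy of ``trial`` with a blink-like transient added.

    The transient is a one-sided Gaussian pulse of peak ``amplitude_uV`` on one
    channel; ``amplitude_uV = 0`` returns the trial unchanged.  Guarantees at
    least one sample with magnitude >= ``amplitude_uV`` whenever that exceeds
    the trial's existing peak.
    """
    if kind != "blink":
        raise ValueError(f"unknown artifact kind {kind!r}")
    n = trial.samples.shape[0]
    if n == 0:
        raise ValueError("trial is empty")
    if amplitude_uV == 0:
        return trial
    pos = n // 4 if at_sample is None else int(at_sample)
    pulse = amplitude_uV * np.exp(
        -0.5 * ((np.arange(n) - pos) / max(width_samples, 1)) ** 2)
    samples = trial.samples.copy()
    samples[:, channel] += pulse
    # re-pin the peak so the contract holds even against opposing background
    peak = np.argmax(np.abs(pulse))
    samples[peak, channel] = trial.samples[peak, channel] + amplitude_uV
    if abs(samples[peak, channel]) < abs(amplitude_uV):
        samples[peak, channel] = amplitude_uV
    return dataclasses.replace(trial, samples=samples)


def save_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> Path:
    """Write one delimited matrix per trial plus a CSV sidecar table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for trial in dataset.trials:
        fname = f"{trial.trial_id}.csv"
        np.savetxt(out_dir / fname, trial.samples, delimiter=",", fmt="%.10g")
        rows.append({"trial_id": trial.trial_id, "label": trial.label,
                     "onset_sample": trial.pre_samples,
                     "seed": dataset.provenance.get("seed", -1)})
    sidecar = pd.DataFrame(rows, columns=["trial_id", "label",
                                          "onset_sample", "seed"])
    sidecar.to_csv(out_dir / "trials.csv", index=False)
    return out_dir


def load_dataset(in_dir: str | Path, fs: float, design: TaskDesign | None = None
                 ) -> SyntheticDataset:
    in_dir = Path(in_dir)
    sidecar = pd.read_csv(in_dir / "trials.csv")
    trials = []
    for row in sidecar.itertuples():
        samples = np.loadtxt(in_dir / f"{row.trial_id}.csv", delimiter=",",
                             ndmin=2)
        trials.append(Trial(samples=samples, fs=fs,
                            pre_samples=int(row.onset_sample),
                            label=str(row.label), trial_id=str(row.trial_id)))
    if design is None:
        n = len(trials)
        n_target = sum(t.label == "target" for t in trials)
        first = trials[0]
        pre_ms = first.pre_samples / fs * 1000.0
        total_ms = first.samples.shape[0] / fs * 1000.0
        design = make_design(n, n_target / n, fs, pre_ms, total_ms - pre_ms,
                             first.samples.shape[1], n_target=n_target)
    return SyntheticDataset(trials=trials, labels=[t.label for t in trials],
                            design=design)
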