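"""Physics-driven synthesis of chunked interferogram pure-shift FIDs.

Interferogram-mode pure-shift acquisition assembles the free induction decay
(FID) chunk by chunk: each increment of the pseudo-2D experiment contributes a
short contiguous block of time-domain points, and concatenating the chunks
yields a decoupled FID whose Fourier transform shows one Lorentzian singlet
per chemical shift.  Non-uniform sampling (NUS) omits whole chunks to shorten
the experiment; Fourier transforming the chunk-zeroed FID produces
undersampling artifacts that a reconstruction method must remove.

This module simulates that pipeline: Lorentzian singlet parameter draws,
ideal FID synthesis, chunk-wise undersampling schedules, complex Gaussian
noise, and the (undersampled noisy input, ideal noiseless label) spectrum
pairs used for supervised training.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "PeakParams",
    "PeakSet",
    "AcquisitionParams",
    "Fid",
    "NUSSchedule",
    "Spectrum1D",
    "TrainingPair",
    "SimConfig",
    "sample_peak_set",
    "synthesize_fid",
    "make_nus_schedule",
    "apply_nus",
    "add_noise",
    "fid_to_spectrum",
    "make_training_pair",
    "generate_dataset",
    "Dataset",
]


class ConfigurationError(ValueError):
    """Raised when simulator configuration ranges are empty or inconsistent."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakParams:
    """One Lorentzian singlet.

    Parameters
    ----------
    freq_hz : float
        Offset frequency within the spectral window (Hz); must satisfy
        ``|freq_hz| < spectral_width / 2``.
    amplitude : float
        Relative intensity, > 0 (unitless).
    lw_hz : float
        Full linewidth at half height of the Lorentzian (Hz), >= 0.
    phase_rad : float
        Zero-order phase (radians).
    """

    freq_hz: float
    amplitude: float
    lw_hz: float = 1.0
    phase_rad: float = 0.0

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError(f"amplitude must be > 0, got {self.amplitude}")
        if self.lw_hz < 0:
            raise ValueError(f"lw_hz must be >= 0, got {self.lw_hz}")


@dataclass(frozen=True)
class PeakSet:
    """Ordered collection of Lorentzian singlets defining a ground truth."""

    peaks: tuple[PeakParams, ...]

    def __post_init__(self) -> None:
        if len(self.peaks) == 0:
            raise ValueError("PeakSet must contain at least one peak")
        object.__setattr__(self, "peaks", tuple(self.peaks))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[PeakParams]:
        return iter(self.peaks)

    @property
    def dynamic_range(self) -> float:
        amps = [p.amplitude for p in self.peaks]
        return max(amps) / min(amps)


@dataclass(frozen=True)
class AcquisitionParams:
    """Chunked acquisition geometry.

    The measured FID holds ``n_chunks`` chunks of ``chunk_len`` complex points
    at dwell ``1 / spectral_width_hz``; spectra are computed on ``n_ft`` points
    after zero filling.  Defaults correspond to 93 chunks of 64 points
    (5952 measured points) zero-filled to 8192.
    """

    spectral_width_hz: float = 4000.0
    chunk_len: int = 64
    n_chunks: int = 93
    n_ft: int = 8192

    def __post_init__(self) -> None:
        if self.spectral_width_hz <= 0:
            raise ValueError("spectral_width_hz must be positive")
        if min(self.chunk_len, self.n_chunks, self.n_ft) < 1:
            raise ValueError("chunk_len, n_chunks, n_ft must be positive integers")
        if self.chunk_len * self.n_chunks > self.n_ft:
            raise ValueError(
                f"chunk_len*n_chunks = {self.chunk_len * self.n_chunks} exceeds "
                f"n_ft = {self.n_ft}"
            )

    @property
    def dwell_s(self) -> float:
        return 1.0 / self.spectral_width_hz

    @property
    def n_samples(self) -> int:
        return self.chunk_len * self.n_chunks

    @property
    def hz_per_bin(self) -> float:
        return self.spectral_width_hz / self.n_ft

    def chunk_slice(self, c: int) -> slice:
        """Half-open sample interval of chunk ``c`` (0-based)."""
        return slice(c * self.chunk_len, (c + 1) * self.chunk_len)


@dataclass(frozen=True)
class Fid:
    """Uniformly sampled complex time-domain signal with chunk geometry."""

    samples: np.ndarray
    acq: AcquisitionParams

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.complex128)
        if samples.ndim != 1 or samples.size != self.acq.n_samples:
            raise ValueError(
                f"expected {self.acq.n_samples} samples, got shape {samples.shape}"
            )
        if not np.all(np.isfinite(samples)):
            raise ValueError("FID contains non-finite samples")
        object.__setattr__(self, "samples", samples)


@dataclass(frozen=True)
class NUSSchedule:
    """Strictly increasing sampled-chunk indices out of ``n_chunks``."""

    sampled: tuple[int, ...]
    n_chunks: int

    def __post_init__(self) -> None:
        sampled = tuple(int(i) for i in self.sampled)
        if not 1 <= len(sampled) <= self.n_chunks:
            raise ValueError("schedule must sample between 1 and n_chunks chunks")
        if any(b <= a for a, b in zip(sampled, sampled[1:])):
            raise ValueError("sampled indices must be strictly increasing")
        if sampled[0] < 0 or sampled[-1] >= self.n_chunks:
            raise ValueError("sampled indices out of range")
        object.__setattr__(self, "sampled", sampled)

    @property
    def nus_level(self) -> float:
        """Sampled fraction of chunks (the NUS level)."""
        return len(self.sampled) / self.n_chunks

    @property
    def acceleration(self) -> float:
        """Experimental speed-up factor: n_chunks / sampled chunks."""
        return self.n_chunks / len(self.sampled)

    def sample_mask(self, chunk_len: int) -> np.ndarray:
        """Boolean per-sample mask: True inside sampled chunks."""
        mask = np.zeros(self.n_chunks, dtype=bool)
        mask[list(self.sampled)] = True
        return np.repeat(mask, chunk_len)


@dataclass(frozen=True)
class Spectrum1D:
    """Real frequency-domain vector with axis and normalization metadata.

    ``norm_factor`` is the maximum absolute value of the real part prior to
    unit-max normalization; 0 flags an all-zero spectrum that was left as-is.
    """

    values: np.ndarray
    axis_hz: np.ndarray
    norm_factor: float = 1.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        axis = np.asarray(self.axis_hz, dtype=np.float64)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("spectrum must be a non-empty 1-D vector")
        if axis.shape != values.shape:
            raise ValueError("axis_hz must match values in length")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "axis_hz", axis)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class TrainingPair:
    """(undersampled noisy input, ideal noiseless label) spectrum pair."""

    input: Spectrum1D
    label: Spectrum1D
    schedule: NUSSchedule
    peaks: PeakSet
    sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.input) != len(self.label):
            raise ValueError("input and label must share n_ft")


# ---------------------------------------------------------------------------
# simulator configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Ranges of the random peak-set and noise distributions.

    Defaults emulate the training regime of the reference experiments:
    3-25 singlets per spectrum, frequencies uniform over the central 90% of
    the window with >= 2 bins separation, amplitudes log-uniform over a 50x
    dynamic range, linewidths 1-6 Hz, in-phase signals, and time-domain
    complex Gaussian noise with a standard deviation up to 5% of the
    strongest FID point.
    """

    acq: AcquisitionParams = field(default_factory=AcquisitionParams)
    n_peaks_range: tuple[int, int] = (3, 25)
    freq_window_fraction: float = 0.9
    min_separation_bins: int = 2
    amp_range: tuple[float, float] = (0.02, 1.0)
    lw_range_hz: tuple[float, float] = (1.0, 6.0)
    phase_range_rad: tuple[float, float] = (0.0, 0.0)
    sigma_rel_range: tuple[float, float] = (0.0, 0.05)

    def __post_init__(self) -> None:
        lo, hi = self.n_peaks_range
        if not (1 <= lo <= hi):
            raise ConfigurationError(f"invalid n_peaks_range {self.n_peaks_range}")
        if not (0 < self.freq_window_fraction <= 1):
            raise ConfigurationError("freq_window_fraction must be in (0, 1]")
        for name in ("amp_range", "lw_range_hz", "phase_range_rad", "sigma_rel_range"):
            a, b = getattr(self, name)
            if b < a:
                raise ConfigurationError(f"empty range {name} = {(a, b)}")
        if self.amp_range[0] <= 0:
            raise ConfigurationError("amplitudes must be positive")
        if self.lw_range_hz[0] < 0 or self.sigma_rel_range[0] < 0:
            raise ConfigurationError("linewidths and noise levels must be >= 0")

    @property
    def dynamic_range_cap(self) -> float:
        return self.amp_range[1] / self.amp_range[0]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "acq" in d and isinstance(d["acq"], dict):
            d["acq"] = AcquisitionParams(**d["acq"])
        for key, val in list(d.items()):
            if isinstance(val, list):
                d[key] = tuple(val)
        return cls(**d)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def sample_peak_set(rng: np.random.Generator, config: SimConfig) -> PeakSet:
    """Draw a random ``PeakSet`` from the configured distributions.

    Frequencies are drawn uniformly over the central
    ``freq_window_fraction`` of the spectral window and redrawn until every
    pair is separated by at least ``min_separation_bins`` spectral bins;
    amplitudes are log-uniform so the configured dynamic-range cap holds by
    construction.
    """
    acq = config.acq
    lo, hi = config.n_peaks_range
    n_peaks = int(rng.integers(lo, hi + 1))
    half = 0.5 * config.freq_window_fraction * acq.spectral_width_hz
    min_sep_hz = config.min_separation_bins * acq.hz_per_bin

    freqs: list[float] = []
    attempts = 0
    while len(freqs) < n_peaks:
        f = float(rng.uniform(-half, half))
        if all(abs(f - g) >= min_sep_hz for g in freqs):
            freqs.append(f)
        attempts += 1
        if attempts > 1000 * n_peaks:
            raise ConfigurationError(
                "cannot place peaks with the requested minimum separation"
            )

    log_lo, log_hi = np.log(config.amp_range[0]), np.log(config.amp_range[1])
    amps = np.exp(rng.uniform(log_lo, log_hi, size=n_peaks))
    lws = rng.uniform(*config.lw_range_hz, size=n_peaks)
    phases = rng.uniform(*config.phase_range_rad, size=n_peaks)

    return PeakSet(
        tuple(
            PeakParams(freq_hz=f, amplitude=float(a), lw_hz=float(w), phase_rad=float(p))
            for f, a, w, p in zip(freqs, amps, lws, phases)
        )
    )


def synthesize_fid(peaks: PeakSet, acq: AcquisitionParams) -> Fid:
    """Synthesize the ideal chunked pure-shift FID.

    The signal is a sum of exponentially damped complex sinusoids sampled at
    the dwell time ``1/spectral_width_hz``::

        s(t_k) = sum_j A_j exp(i (2 pi f_j t_k + phi_j)) exp(-pi lw_j t_k)

    where ``lw_j`` is the full Lorentzian linewidth at half height, so the
    decay rate is ``pi * lw_j``.  Concatenated chunks of an ideal singlet
    spectrum form exactly this continuous decaying sinusoid.
    """
    t = np.arange(acq.n_samples) * acq.dwell_s
    s = np.zeros(acq.n_samples, dtype=np.complex128)
    for p in peaks:
        s += p.amplitude * np.exp(
            1j * (2.0 * np.pi * p.freq_hz * t + p.phase_rad) - np.pi * p.lw_hz * t
        )
    return Fid(samples=s, acq=acq)


def make_nus_schedule(
    n_chunks: int,
    n_keep: int,
    rng: np.random.Generator,
    scheme: str = "first+random",
) -> NUSSchedule:
    """Draw a chunk sampling schedule.

    ``scheme`` is ``"random"`` (uniform without replacement) or
    ``"first+random"`` (chunk 0 always sampled — it anchors the overall
    spectrum intensity — plus uniform random chunks).
    """
    if not 1 <= n_keep <= n_chunks:
        raise ValueError(f"n_keep = {n_keep} out of range [1, {n_chunks}]")
    if scheme == "random":
        idx = rng.choice(n_chunks, size=n_keep, replace=False)
    elif scheme == "first+random":
        rest = rng.choice(n_chunks - 1, size=n_keep - 1, replace=False) + 1
        idx = np.concatenate(([0], rest))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return NUSSchedule(sampled=tuple(sorted(int(i) for i in idx)), n_chunks=n_chunks)


def apply_nus(fid: Fid, schedule: NUSSchedule) -> Fid:
    """Zero every sample outside the sampled chunks."""
    if schedule.n_chunks != fid.acq.n_chunks:
        raise ValueError(
            f"schedule has {schedule.n_chunks} chunks, FID has {fid.acq.n_chunks}"
        )
    mask = schedule.sample_mask(fid.acq.chunk_len)
    return Fid(samples=np.where(mask, fid.samples, 0.0 + 0.0j), acq=fid.acq)


def add_noise(fid: Fid, sigma: float, rng: np.random.Generator) -> Fid:
    """Add i.i.d. Gaussian noise of standard deviation ``sigma`` to both
    quadratures (real and imaginary parts) of every sample."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return fid
    n = fid.samples.size
    noise = rng.normal(0.0, sigma, size=n) + 1j * rng.normal(0.0, sigma, size=n)
    return Fid(samples=fid.samples + noise, acq=fid.acq)


def fid_to_spectrum(fid: Fid, n_ft: int | None = None) -> Spectrum1D:
    """Zero-fill, Fourier transform, center, take the real part, normalize.

    The spectrum is the real part of the centered DFT of the zero-filled FID,
    scaled to unit maximum absolute value; the scale is kept in
    ``norm_factor`` (0 for an all-zero signal, which is returned unscaled).
    """
    if n_ft is None:
        n_ft = fid.acq.n_ft
    if n_ft < fid.samples.size:
        raise ValueError(f"n_ft = {n_ft} smaller than FID length {fid.samples.size}")
    spec = np.fft.fftshift(np.fft.fft(fid.samples, n=n_ft)).real
    axis = np.fft.fftshift(np.fft.fftfreq(n_ft, d=fid.acq.dwell_s))
    norm = float(np.max(np.abs(spec)))
    if norm > 0:
        spec = spec / norm
    return Spectrum1D(values=spec, axis_hz=axis, norm_factor=norm)


def make_training_pair(
    peaks: PeakSet,
    acq: AcquisitionParams,
    schedule: NUSSchedule,
    sigma: float,
    rng: np.random.Generator,
    seed: int | None = None,
) -> TrainingPair:
    """Build one supervised pair.

    The input is the spectrum of the noisy, chunk-undersampled FID; the label
    is the spectrum of the same peak set with full sampling and no noise.
    Both are unit-max normalized independently.
    """
    fid = synthesize_fid(peaks, acq)
    noisy = add_noise(fid, sigma, rng)
    nus = apply_nus(noisy, schedule)
    return TrainingPair(
        input=fid_to_spectrum(nus),
        label=fid_to_spectrum(fid),
        schedule=schedule,
        peaks=peaks,
        sigma=sigma,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """In-memory collection of training pairs as dense matrices."""

    inputs: np.ndarray      # (n, n_ft) float32
    labels: np.ndarray      # (n, n_ft) float32
    pairs: list[TrainingPair]
    config: SimConfig
    seed: int

    def __len__(self) -> int:
        return self.inputs.shape[0]


def generate_dataset(
    n: int,
    config: SimConfig,
    seed: int,
    n_keep: int = 15,
    scheme: str = "first+random",
    n_keep_choices: Sequence[int] | None = None,
) -> Dataset:
    """Generate ``n`` reproducible training pairs.

    Each pair draws its own peak set, schedule (with ``n_keep`` sampled
    chunks, or one of ``n_keep_choices`` when mixed NUS levels are wanted),
    and relative noise level; everything derives from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    acq = config.acq
    root = np.random.SeedSequence(seed)
    pairs: list[TrainingPair] = []
    inputs = np.empty((n, acq.n_ft), dtype=np.float32)
    labels = np.empty((n, acq.n_ft), dtype=np.float32)
    for i, child in enumerate(root.spawn(n)):
        rng = np.random.default_rng(child)
        peaks = sample_peak_set(rng, config)
        keep = n_keep if n_keep_choices is None else int(rng.choice(list(n_keep_choices)))
        schedule = make_nus_schedule(acq.n_chunks, keep, rng, scheme)
        fid_peak = synthesize_fid(peaks, acq)
        sigma = float(rng.uniform(*config.sigma_rel_range)) * float(
            np.max(np.abs(fid_peak.samples))
        )
        pair = make_training_pair(peaks, acq, schedule, sigma, rng, seed=i)
        pairs.append(pair)
        inputs[i] = pair.input.values
        labels[i] = pair.label.values
    return Dataset(inputs=inputs, labels=labels, pairs=pairs, config=config, seed=seed)
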