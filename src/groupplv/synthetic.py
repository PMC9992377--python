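r"""Synthetic multichannel EEG with controllable pairwise phase synchrony.

The generator emulates the shape of the DEAP preprocessed release —
32 channels, 128 Hz, 63-s trials (3-s pre-stimulus baseline + 60 s of
stimulus), four rhythm bands, continuous 1-9 ratings — while giving
every pairwise phase relationship a closed-form expected PLV, so the
whole pipeline is testable without the real download.

Signal model
------------
Channel :math:`i` is a sum over bands of phase-modulated tones plus
white noise:

.. math::

   x_i(t) = \sum_b A_b \sin\!\big(2\pi (f_b + \delta_{g_b(i)}) t
            + \psi_{g_b(i)}(t) + \varepsilon_i(t)\big) + \eta_i(t)

* :math:`g_b(i)` — the synchrony community of channel *i* in band *b*
  (a partition of the montage, possibly condition-dependent).
* :math:`\psi_c(t)` — a community phase shared by all members: a random
  walk (default step 0.05 rad/sample) so the tones wander slowly instead
  of being strictly periodic.
* :math:`\delta_c` — a per-community carrier detuning on a grid of
  ``detune_step`` Hz (default 1.0).  Distinct communities differ by an
  integer number of cycles per 3-s analysis window, so their relative
  phase sweeps full cycles and the cross-community PLV baseline is ~0.
* :math:`\varepsilon_i(t)` — per-channel wrapped-Gaussian phase jitter,
  an AR(1) process with stationary standard deviation ``jitter_sd`` and
  correlation time 16 samples (125 ms).  The slow correlation keeps the
  jitter sidebands inside the narrowest (4-Hz-wide) band so the
  band-pass filter does not strip the jitter back out.

For a within-community pair with jitter s.d. :math:`s_i, s_j` the
phase difference is :math:`\varepsilon_i - \varepsilon_j`, a Gaussian
with variance :math:`s_i^2 + s_j^2`, hence the expected PLV has the
closed form :math:`\exp(-(s_i^2+s_j^2)/2)` — the recovery target used
throughout the tests.

Conditions ("high" / "low" emotional state) alternate by video index;
each condition draws its four ratings from a Gaussian (s.d. 1) around
its ``rating_means`` entry, clipped to [1, 9].  By default the two
conditions differ only in gamma-band jitter (strong vs. negligible
gamma synchrony), mirroring the empirical finding that high-frequency
synchrony carries the discriminative signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import lfilter

from .io import Recording, write_participant_archive
from .montage import DEFAULT_MONTAGE, Montage
from .preprocess import BandSpec

__all__ = [
    "SynthBand",
    "SynthConfig",
    "SynthGroundTruth",
    "simulate_recording",
    "simulate_participant",
    "write_synthetic_corpus",
    "theoretical_plv",
    "ground_truth",
]

#: AR(1) correlation time of the phase jitter, in samples (125 ms at 128 Hz).
JITTER_TAU_SAMPLES = 16.0


@dataclass(frozen=True)
class SynthBand:
    """One oscillatory component: a rhythm band plus its carrier tone."""

    name: str
    low: float
    high: float
    carrier: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not self.low <= self.carrier <= self.high:
            raise ValueError(f"carrier {self.carrier} outside band [{self.low}, {self.high}]")

    @property
    def band(self) -> BandSpec:
        return BandSpec(self.name, self.low, self.high)


#: Carriers default to band centres so each tone stays inside one rhythm.
DEFAULT_SYNTH_BANDS: tuple[SynthBand, ...] = (
    SynthBand("theta", 4.0, 8.0, 6.0),
    SynthBand("alpha", 8.0, 13.0, 10.5),
    SynthBand("beta", 13.0, 30.0, 21.5),
    SynthBand("gamma", 30.0, 45.0, 37.5),
)


def _default_communities(n_channels: int) -> tuple[tuple[int, ...], ...]:
    half = n_channels // 2
    return (tuple(range(half)), tuple(range(half, n_channels)))


@dataclass
class SynthConfig:
    """Parameters of the simulated cohort.

    ``communities`` maps condition -> band name -> partition of channel
    indices; ``jitter_sd`` maps condition -> band name -> per-channel
    jitter standard deviation in radians.  Scalar / partial inputs are
    broadcast in ``__post_init__``.
    """

    n_participants: int = 32
    n_videos: int = 40
    n_channels: int = 32
    fs: float = 128.0
    duration: float = 63.0
    bands: tuple[SynthBand, ...] = DEFAULT_SYNTH_BANDS
    conditions: tuple[str, ...] = ("high", "low")
    communities: Mapping | None = None
    jitter_sd: float | Mapping = 0.3
    noise_sd: float = 0.1
    phase_step: float = 0.05  # community random-walk step, rad/sample
    detune_step: float = 1.0  # Hz between community carriers
    rating_means: Mapping[str, float] = field(
        default_factory=lambda: {"high": 6.5, "low": 2.5}
    )
    rating_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 2 * max(b.high for b in self.bands):
            raise ValueError("fs must exceed twice the highest band edge")
        n = self.duration * self.fs
        if not np.isclose(n, round(n)):
            raise ValueError("duration * fs must be an integer sample count")
        for cond, mu in self.rating_means.items():
            if not 1.0 <= mu <= 9.0:
                raise ValueError(f"rating mean for {cond!r} outside [1, 9]")

        band_names = [b.name for b in self.bands]
        default_part = _default_communities(self.n_channels)
        # normalize communities -> {condition: {band: partition}}
        comm: dict[str, dict[str, tuple[tuple[int, ...], ...]]] = {}
        for cond in self.conditions:
            comm[cond] = {}
            for bn in band_names:
                part = default_part
                if self.communities is not None:
                    spec = self.communities
                    if cond in spec:
                        spec = spec[cond]
                    if isinstance(spec, Mapping) and bn in spec:
                        part = spec[bn]
                    elif not isinstance(spec, Mapping):
                        part = spec
                comm[cond][bn] = tuple(tuple(int(c) for c in grp) for grp in part)
                flat = [c for grp in comm[cond][bn] for c in grp]
                if sorted(flat) != list(range(self.n_channels)):
                    raise ValueError(
                        f"communities for ({cond}, {bn}) must partition "
                        f"all {self.n_channels} channels"
                    )
        self.communities = comm

        # normalize jitter_sd -> {condition: {band: (n_channels,) array}}
        jit: dict[str, dict[str, np.ndarray]] = {}
        for cond in self.conditions:
            jit[cond] = {}
            for bn in band_names:
                val = self.jitter_sd
                if isinstance(val, Mapping):
                    val = val.get(cond, val) if cond in val else val
                if isinstance(val, Mapping):
                    val = val.get(bn, 0.0)
                arr = np.broadcast_to(np.asarray(val, dtype=float), (self.n_channels,)).copy()
                if np.any(arr < 0):
                    raise ValueError("jitter_sd must be non-negative")
                jit[cond][bn] = arr
        self.jitter_sd = jit

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    def condition_of(self, video: int) -> str:
        """Condition assignment alternates deterministically by video index."""
        return self.conditions[video % len(self.conditions)]

    def band(self, name: str) -> SynthBand:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(f"unknown band {name!r}")


def separable_gamma_config(**overrides) -> SynthConfig:
    """A two-condition world whose only difference is gamma-band synchrony.

    High-condition channels lock tightly within each gamma community
    (jitter 0.2 rad); low-condition gamma jitter (2.5 rad) washes the
    locking out.  The other three bands are identical across conditions.
    """
    jitter = {
        "high": {"theta": 0.3, "alpha": 0.3, "beta": 0.3, "gamma": 0.2},
        "low": {"theta": 0.3, "alpha": 0.3, "beta": 0.3, "gamma": 2.5},
    }
    overrides.setdefault("jitter_sd", jitter)
    return SynthConfig(**overrides)


def _ar1_jitter(rng: np.random.Generator, sd: np.ndarray, n: int) -> np.ndarray:
    """(channels, n) stationary AR(1) phase jitter with marginal s.d. ``sd``."""
    rho = np.exp(-1.0 / JITTER_TAU_SAMPLES)
    w = rng.standard_normal((sd.size, n))
    x0 = rng.standard_normal(sd.size)  # stationary start, unit variance
    innov = np.sqrt(1.0 - rho**2) * w
    innov[:, 0] = 0.0
    x = lfilter([1.0], [1.0, -rho], innov, axis=-1, zi=(rho * x0)[:, None])[0]
    x[:, 0] = x0
    return sd[:, None] * x


def _community_detunes(n_communities: int, step: float) -> np.ndarray:
    """Symmetric grid of carrier offsets, ``step`` Hz apart, centred on 0."""
    k = np.arange(n_communities, dtype=float)
    return (k - (n_communities - 1) / 2.0) * step


def simulate_recording(config: SynthConfig, participant: int, video: int) -> Recording:
    """Simulate one trial (channels x samples) plus its four ratings.

    Deterministic in (config.seed, participant, video): the same triple
    always yields bit-identical output.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(participant), int(video)])
    )
    cond = config.condition_of(video)
    n = config.n_samples
    t = np.arange(n) / config.fs
    x = np.zeros((config.n_channels, n))

    for sb in config.bands:
        part = config.communities[cond][sb.name]
        detunes = _community_detunes(len(part), config.detune_step)
        jitter = _ar1_jitter(rng, config.jitter_sd[cond][sb.name], n)
        for grp, df in zip(part, detunes):
            steps = rng.standard_normal(n) * config.phase_step
            steps[0] = rng.uniform(-np.pi, np.pi) / 1.0  # initial phase
            psi = np.cumsum(steps)
            carrier = 2.0 * np.pi * (sb.carrier + df) * t + psi
            idx = np.asarray(grp)
            x[idx] += sb.amplitude * np.sin(carrier[None, :] + jitter[idx])

    if config.noise_sd > 0:
        x += config.noise_sd * rng.standard_normal(x.shape)

    mu = config.rating_means[cond]
    ratings = np.clip(rng.normal(mu, config.rating_sd, size=4), 1.0, 9.0)
    montage = DEFAULT_MONTAGE if config.n_channels == DEFAULT_MONTAGE.n_channels else Montage(
        tuple(f"ch{i:02d}" for i in range(config.n_channels))
    )
    return Recording(
        participant=participant, video=video, signals=x,
        fs=config.fs, ratings=ratings, montage=montage,
    )


def simulate_participant(config: SynthConfig, participant: int) -> list[Recording]:
    """All trials of one participant."""
    return [simulate_recording(config, participant, v) for v in range(config.n_videos)]


def write_synthetic_corpus(config: SynthConfig, directory: str | Path) -> list[Path]:
    """Write the whole cohort as per-participant ``.npz`` archives
    (``s01.npz`` ... ), interchangeable with real archives downstream."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for p in range(config.n_participants):
        recs = simulate_participant(config, p)
        paths.append(write_participant_archive(directory / f"s{p + 1:02d}.npz", recs))
    return paths


def theoretical_plv(config: SynthConfig, band: str | SynthBand, condition: str):
    """Expected PLV matrix implied by the jitter model.

    Within-community entries are ``exp(-(s_i^2 + s_j^2) / 2)``; pairs in
    different communities sweep full relative-phase cycles per window and
    get the baseline 0; the diagonal is 1.
    """
    from .connectivity import PLVMatrix  # local import to avoid a cycle

    if condition not in config.conditions:
        raise KeyError(f"unknown condition {condition!r}")
    name = band if isinstance(band, str) else band.name
    sd = config.jitter_sd[condition][name]
    part = config.communities[condition][name]
    m = np.zeros((config.n_channels, config.n_channels))
    for grp in part:
        idx = np.asarray(grp)
        s2 = sd[idx] ** 2
        m[np.ix_(idx, idx)] = np.exp(-(s2[:, None] + s2[None, :]) / 2.0)
    np.fill_diagonal(m, 1.0)
    sb = config.band(name)
    return PLVMatrix(values=m, band=sb.band, level="individual",
                     description=f"theoretical, condition={condition}")


@dataclass(frozen=True)
class SynthGroundTruth:
    """Expected PLV matrices and the condition of every trial."""

    expected_plv: dict  # (condition, band name) -> PLVMatrix
    condition: dict  # (participant, video) -> condition label


def ground_truth(config: SynthConfig) -> SynthGroundTruth:
    expected = {
        (cond, sb.name): theoretical_plv(config, sb.name, cond)
        for cond in config.conditions
        for sb in config.bands
    }
    cond = {
        (p, v): config.condition_of(v)
        for p in range(config.n_participants)
        for v in range(config.n_videos)
    }
    return SynthGroundTruth(expected_plv=expected, condition=cond)
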