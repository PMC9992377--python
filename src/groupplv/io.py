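"""Reading per-participant trial archives and assembling labeled datasets.

Archive dialects
----------------
One file per participant, holding two arrays:

``data``
    ``videos x channels x samples`` float array.  The DEAP preprocessed
    release stores 40 x 40 x 8064 (the first 32 channels are EEG, the
    rest peripheral and dropped on read); the synthetic writer stores
    exactly 32 EEG channels.
``labels``
    ``videos x 4`` self-ratings on a 1-9 scale, columns ordered
    valence, arousal, dominance, liking.

Two containers are supported: ``.npz`` (written by this package's
synthetic generator; open, no pickling) and ``.dat`` (the published
DEAP preprocessed-Python pickle of a dict with the same two keys).

Labels
------
A continuous rating is binarized at 4.5: strictly greater is "high",
everything else (including exactly 4.5) is "low".  Group-level matrices
are labeled by averaging the rating across participants for the video
and thresholding the mean.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .montage import DEFAULT_MONTAGE, Montage

if TYPE_CHECKING:  # pragma: no cover
    from .connectivity import PLVMatrix
    from .preprocess import BandSpec

__all__ = [
    "RATING_DIMENSIONS",
    "Recording",
    "LabeledDataset",
    "read_participant_archive",
    "write_participant_archive",
    "binarize_rating",
    "group_label",
    "assemble_dataset",
]

#: Column order of the rating block.
RATING_DIMENSIONS: tuple[str, ...] = ("valence", "arousal", "dominance", "liking")

RATING_THRESHOLD = 4.5


@dataclass(frozen=True)
class Recording:
    """One participant watching one video: multichannel EEG plus ratings."""

    participant: int
    video: int
    signals: np.ndarray  # channels x samples
    fs: float
    ratings: np.ndarray  # (4,) valence, arousal, dominance, liking in [1, 9]
    montage: Montage = DEFAULT_MONTAGE

    def __post_init__(self) -> None:
        if self.signals.ndim != 2:
            raise ValueError("signals must be a channels x samples matrix")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        r = np.asarray(self.ratings, dtype=float)
        if r.shape != (4,):
            raise ValueError("ratings must hold exactly 4 values")
        if np.any(r < 1.0) or np.any(r > 9.0):
            raise ValueError("ratings must lie in [1, 9]")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals must be finite")

    def rating(self, dimension: str) -> float:
        """Rating for one of valence / arousal / dominance / liking."""
        return float(np.asarray(self.ratings)[RATING_DIMENSIONS.index(dimension)])

    @property
    def duration(self) -> float:
        return self.signals.shape[1] / self.fs


def read_participant_archive(
    path: str | Path,
    *,
    participant: int | None = None,
    fs: float = 128.0,
    montage: Montage = DEFAULT_MONTAGE,
) -> list[Recording]:
    """Load all trials of one participant.

    Parameters
    ----------
    path
        ``.npz`` (open container) or ``.dat`` (DEAP pickle) archive.
    participant
        Index stored in each Recording; parsed from a trailing integer in
        the file stem (``s01`` -> 0) when omitted.
    fs
        Sampling rate of the stored signals (DEAP preprocessed: 128 Hz).

    Returns
    -------
    list of Recording, one per video, EEG channels only.
    """
    path = Path(path)
    if participant is None:
        digits = "".join(c for c in path.stem if c.isdigit())
        participant = int(digits) - 1 if digits else 0
    if path.suffix == ".dat":
        with open(path, "rb") as fh:
            blob = pickle.load(fh, encoding="latin1")
        data, labels = np.asarray(blob["data"]), np.asarray(blob["labels"])
    else:
        with np.load(path) as npz:
            if "data" not in npz or "labels" not in npz:
                raise ValueError(f"{path}: archive must contain 'data' and 'labels'")
            data, labels = npz["data"], npz["labels"]

    if data.ndim != 3:
        raise ValueError(f"{path}: data must be videos x channels x samples")
    n_videos, n_channels, _ = data.shape
    if labels.shape != (n_videos, 4):
        raise ValueError(f"{path}: labels must be videos x 4, got {labels.shape}")
    n_eeg = montage.n_channels
    if n_channels < n_eeg:
        raise ValueError(f"{path}: expected >= {n_eeg} channels, got {n_channels}")

    return [
        Recording(
            participant=participant,
            video=v,
            signals=np.asarray(data[v, :n_eeg], dtype=float),
            fs=fs,
            ratings=np.asarray(labels[v], dtype=float),
            montage=montage,
        )
        for v in range(n_videos)
    ]


def write_participant_archive(path: str | Path, recordings: Sequence[Recording]) -> Path:
    """Write one participant's trials to an ``.npz`` archive (see module docs)."""
    if not recordings:
        raise ValueError("no recordings to write")
    path = Path(path).with_suffix(".npz")
    data = np.stack([r.signals for r in recordings])
    labels = np.stack([np.asarray(r.ratings, dtype=float) for r in recordings])
    np.savez(path, data=data, labels=labels)
    return path


def binarize_rating(rating: float) -> str:
    """Map a 1-9 rating to "high" (strictly above 4.5) or "low"."""
    if not 1.0 <= rating <= 9.0:
        raise ValueError(f"rating {rating} outside [1, 9]")
    return "high" if rating > RATING_THRESHOLD else "low"


def group_label(ratings: Sequence[float]) -> str:
    """Label for a group-level matrix: mean rating across participants,
    then the same strict 4.5 threshold."""
    if len(ratings) == 0:
        raise ValueError("group_label requires at least one rating")
    return binarize_rating(float(np.mean(ratings)))


@dataclass
class LabeledDataset:
    """(matrix, binary label) pairs for one target dimension at one level."""

    matrices: list["PLVMatrix"]
    labels: list[str]
    dimension: str  # arousal | valence
    level: str  # individual | group
    band: "BandSpec"

    def __post_init__(self) -> None:
        if len(self.matrices) != len(self.labels):
            raise ValueError("matrices and labels length mismatch")
        bad = set(self.labels) - {"high", "low"}
        if bad:
            raise ValueError(f"non-binary labels: {bad}")
        shapes = {m.values.shape for m in self.matrices}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent matrix shapes: {shapes}")

    def __len__(self) -> int:
        return len(self.matrices)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stacked matrix values (n, c, c) and 0/1 labels (1 = high)."""
        x = np.stack([m.values for m in self.matrices])
        y = np.array([1 if lab == "high" else 0 for lab in self.labels])
        return x, y

    def subset(self, idx: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(
            matrices=[self.matrices[i] for i in idx],
            labels=[self.labels[i] for i in idx],
            dimension=self.dimension,
            level=self.level,
            band=self.band,
        )


def assemble_dataset(
    matrices: Sequence["PLVMatrix"],
    ratings: dict,
    dimension: str,
    level: str,
) -> LabeledDataset:
    """Attach binary labels to connectivity matrices via their provenance.

    Parameters
    ----------
    matrices
        PLV matrices of one band, all at the same level.
    ratings
        individual level: ``{(participant, video): rating}``;
        group level: ``{video: [rating per participant]}``.
    dimension
        "arousal" or "valence" (which rating column fed ``ratings``).
    level
        "individual" or "group".
    """
    if dimension not in ("arousal", "valence"):
        raise ValueError(f"unknown dimension {dimension!r}")
    labels: list[str] = []
    for m in matrices:
        if level == "individual":
            key = (m.participant, m.video)
            if key not in ratings:
                raise KeyError(f"no rating for participant/video {key}")
            labels.append(binarize_rating(ratings[key]))
        elif level == "group":
            if m.video not in ratings:
                raise KeyError(f"no ratings for video {m.video}")
            labels.append(group_label(ratings[m.video]))
        else:
            raise ValueError(f"unknown level {level!r}")
    band = matrices[0].band if matrices else None
    return LabeledDataset(
        matrices=list(matrices), labels=labels,
        dimension=dimension, level=level, band=band,
    )
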