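"""End-to-end orchestration: recordings -> PLV matrices -> labeled datasets.

Pure plumbing around the science modules.  For a cohort of P
participants and V videos with 60 s of usable signal cut into twenty
3-s windows, each band yields P*V*20 individual matrices and V*20
group matrices (32 participants, 40 videos: 25600 and 800).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .connectivity import PLVMatrix, group_average, plv_matrix
from .io import LabeledDataset, Recording, assemble_dataset, read_participant_archive
from .preprocess import BAND_BY_NAME, BandSpec, segments_from_recording

__all__ = [
    "extract_individual_matrices",
    "extract_group_matrices",
    "ratings_table",
    "build_datasets",
    "load_corpus",
]


def load_corpus(directory: str | Path, pattern: str = "s*") -> list[list[Recording]]:
    """Read every per-participant archive in a directory (sorted order)."""
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir()
                   if p.match(pattern) and p.suffix in (".npz", ".dat"))
    if not paths:
        raise FileNotFoundError(f"no participant archives under {directory}")
    return [read_participant_archive(p, participant=i) for i, p in enumerate(paths)]


def extract_individual_matrices(
    recordings: Iterable[Recording],
    band: BandSpec | str,
    *,
    baseline_seconds: float = 3.0,
    seg_seconds: float = 3.0,
    filter_whole: bool = False,
) -> list[PLVMatrix]:
    """One PLV matrix per (recording, segment) for one band."""
    if isinstance(band, str):
        band = BAND_BY_NAME[band]
    out: list[PLVMatrix] = []
    for rec in recordings:
        for seg in segments_from_recording(
            rec, band, baseline_seconds=baseline_seconds,
            seg_seconds=seg_seconds, filter_whole=filter_whole,
        ):
            out.append(plv_matrix(seg))
    return out


def extract_group_matrices(matrices: Sequence[PLVMatrix]) -> list[PLVMatrix]:
    """Average individual matrices across participants per (video, segment)."""
    buckets: dict[tuple[int, int], list[PLVMatrix]] = {}
    for m in matrices:
        buckets.setdefault((m.video, m.segment), []).append(m)
    return [group_average(v) for _, v in sorted(buckets.items())]


def ratings_table(corpus: Sequence[Sequence[Recording]], dimension: str) -> dict:
    """Rating lookups for labeling.

    Returns ``(individual, group)``: ``{(participant, video): rating}``
    and ``{video: [rating per participant]}``.
    """
    individual = {}
    group: dict[int, list[float]] = {}
    for recs in corpus:
        for r in recs:
            individual[(r.participant, r.video)] = r.rating(dimension)
            group.setdefault(r.video, []).append(r.rating(dimension))
    return individual, group


def build_datasets(
    corpus: Sequence[Sequence[Recording]],
    band: BandSpec | str,
    dimension: str,
    *,
    baseline_seconds: float = 3.0,
    seg_seconds: float = 3.0,
) -> tuple[LabeledDataset, LabeledDataset]:
    """(individual, group) labeled datasets for one band and dimension."""
    all_recordings = [r for recs in corpus for r in recs]
    indiv = extract_individual_matrices(
        all_recordings, band,
        baseline_seconds=baseline_seconds, seg_seconds=seg_seconds,
    )
    grp = extract_group_matrices(indiv)
    ind_ratings, grp_ratings = ratings_table(corpus, dimension)
    ds_ind = assemble_dataset(indiv, ind_ratings, dimension, "individual")
    ds_grp = assemble_dataset(grp, grp_ratings, dimension, "group")
    return ds_ind, ds_grp
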