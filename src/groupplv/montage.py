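"""Electrode montage for the 32-channel 10-20 layout used by DEAP.

The channel ordering below is the DEAP "Geneva" ordering of the 32 EEG
electrodes.  Every adjacency matrix produced by this package indexes its
rows and columns in this order, so matrix images are directly comparable
across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The 32 EEG channels of the DEAP preprocessed release, in file order.
DEAP_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "C4",
    "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2", "Cz",
)


@dataclass(frozen=True)
class Montage:
    """Ordered set of scalp electrode names.

    Fixes the channel index <-> name correspondence for all signal arrays
    and connectivity matrices in the package.
    """

    channels: tuple[str, ...] = DEAP_CHANNELS

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("montage channel names must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def index(self, name: str) -> int:
        """Index of an electrode by name."""
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None

    def name(self, index: int) -> str:
        return self.channels[index]


#: Default montage instance shared across the package.
DEFAULT_MONTAGE = Montage()
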