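"""Core containers: multichannel iEEG recordings and seizure annotations.

A :class:`Recording` holds a channels x time sample matrix together with the
sampling rate and a per-channel role label.  Roles distinguish electrodes on
the epileptogenic zone (``focal``) from distant electrodes (``remote``); the
detector combines three focal channels with one remote channel, so at least
four channels (3 focal + 1 remote) are needed for detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FOCAL = "focal"
REMOTE = "remote"
_VALID_ROLES = (FOCAL, REMOTE)


@dataclass
class Recording:
    """Multichannel iEEG signal.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal samples, nominally in microvolts.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        One name per channel.
    roles : list of str
        Per-channel role, each ``"focal"`` or ``"remote"``.
    patient_id : str
        Free-form identifier carried through reports.
    """

    samples: np.ndarray
    fs: float
    labels: list[str]
    roles: list[str]
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        n_ch = self.samples.shape[0]
        if len(self.labels) != n_ch or len(self.roles) != n_ch:
            raise ValueError(
                f"labels ({len(self.labels)}) and roles ({len(self.roles)}) "
                f"must match the number of channels ({n_ch})"
            )
        for role in self.roles:
            if role not in _VALID_ROLES:
                raise ValueError(f"unknown channel role {role!r}; expected one of {_VALID_ROLES}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    def focal_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == FOCAL]

    def remote_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == REMOTE]

    def copy(self) -> "Recording":
        return Recording(
            samples=self.samples.copy(),
            fs=self.fs,
            labels=list(self.labels),
            roles=list(self.roles),
            patient_id=self.patient_id,
        )


@dataclass(frozen=True, order=True)
class Annotation:
    """Expert-style seizure annotation: [onset, offset) in seconds."""

    onset: float
    offset: float

    def __post_init__(self) -> None:
        if not 0 <= self.onset < self.offset:
            raise ValueError(f"need 0 <= onset < offset, got [{self.onset}, {self.offset}]")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def check_annotations(annotations: list[Annotation]) -> list[Annotation]:
    """Return annotations sorted by onset; raise if any pair overlaps."""
    anns = sorted(annotations)
    for a, b in zip(anns, anns[1:]):
        if b.onset < a.offset:
            raise ValueError(f"overlapping annotations: {a} and {b}")
    return anns
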