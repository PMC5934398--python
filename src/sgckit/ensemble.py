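"""Trial-segmented multichannel time-series container.

A :class:`TrialEnsemble` is the unit of resampling throughout the package:
``data`` is a ``(n_trials, n_channels, n_samples)`` float array, each channel
is assigned to a ``lower`` or ``higher`` area, and each trial carries a
condition label (``"none"`` for unlabeled data).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

VALID_AREAS = ("lower", "higher")


class EnsembleError(ValueError):
    """Raised when an ensemble violates its structural invariants."""


@dataclass
class TrialEnsemble:
    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    areas: dict[str, str]
    conditions: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise EnsembleError(
                f"data must be (trials, channels, samples), got shape {self.data.shape}"
            )
        self.channel_labels = list(self.channel_labels)
        if self.conditions is None:
            self.conditions = np.array(["none"] * self.n_trials, dtype=object)
        else:
            self.conditions = np.asarray(self.conditions, dtype=object)
        self.validate()

    # -- structural invariants -------------------------------------------------
    def validate(self) -> None:
        n_trials, n_channels, _ = self.data.shape
        if not np.all(np.isfinite(self.data)):
            raise EnsembleError("ensemble data contains non-finite values")
        if len(self.channel_labels) != n_channels:
            raise EnsembleError(
                f"{len(self.channel_labels)} labels for {n_channels} channels"
            )
        if len(set(self.channel_labels)) != n_channels:
            raise EnsembleError("channel labels must be unique")
        missing = [c for c in self.channel_labels if c not in self.areas]
        if missing:
            raise EnsembleError(f"channels without an area assignment: {missing}")
        bad = {c: a for c, a in self.areas.items() if a not in VALID_AREAS}
        if bad:
            raise EnsembleError(f"invalid areas (must be lower/higher): {bad}")
        if len(self.conditions) != n_trials:
            raise EnsembleError(
                f"{len(self.conditions)} condition labels for {n_trials} trials"
            )
        if self.sampling_rate <= 0:
            raise EnsembleError(f"sampling_rate must be > 0, got {self.sampling_rate}")

    # -- basic views -----------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def nyquist(self) -> float:
        return self.sampling_rate / 2.0

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None

    def area_of(self, label: str) -> str:
        return self.areas[label]

    def lower_channels(self) -> list[str]:
        return [c for c in self.channel_labels if self.areas[c] == "lower"]

    def higher_channels(self) -> list[str]:
        return [c for c in self.channel_labels if self.areas[c] == "higher"]

    def condition_names(self) -> list[str]:
        names = [c for c in dict.fromkeys(self.conditions) if c != "none"]
        return names

    # -- subsetting ------------------------------------------------------------
    def channel_data(self, labels: Sequence[str]) -> np.ndarray:
        idx = [self.channel_index(c) for c in labels]
        return self.data[:, idx, :]

    def subset_channels(self, labels: Sequence[str]) -> "TrialEnsemble":
        idx = [self.channel_index(c) for c in labels]
        return TrialEnsemble(
            data=self.data[:, idx, :].copy(),
            sampling_rate=self.sampling_rate,
            channel_labels=list(labels),
            areas={c: self.areas[c] for c in labels},
            conditions=self.conditions.copy(),
        )

    def select_trials(self, index: np.ndarray) -> "TrialEnsemble":
        index = np.asarray(index)
        return TrialEnsemble(
            data=self.data[index].copy(),
            sampling_rate=self.sampling_rate,
            channel_labels=list(self.channel_labels),
            areas=dict(self.areas),
            conditions=self.conditions[index].copy(),
        )

    def condition_trials(self, condition: str) -> np.ndarray:
        return np.flatnonzero(self.conditions == condition)

    def time_reversed(self) -> "TrialEnsemble":
        """Flip samples within each trial (used by the time-reversal control)."""
        return replace_data(self, self.data[:, :, ::-1].copy())

    def __eq__(self, other: object) -> bool:  # bit-for-bit equality
        if not isinstance(other, TrialEnsemble):
            return NotImplemented
        return (
            np.array_equal(self.data, other.data)
            and self.sampling_rate == other.sampling_rate
            and self.channel_labels == other.channel_labels
            and self.areas == other.areas
            and np.array_equal(self.conditions, other.conditions)
        )


def replace_data(ensemble: TrialEnsemble, data: np.ndarray) -> TrialEnsemble:
    """Return a copy of *ensemble* with ``data`` swapped out, metadata shared."""
    return TrialEnsemble(
        data=data,
        sampling_rate=ensemble.sampling_rate,
        channel_labels=list(ensemble.channel_labels),
        areas=dict(ensemble.areas),
        conditions=ensemble.conditions.copy(),
    )
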