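"""Shared containers and exception types."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(ValueError):
    """Input is formally valid but statistically degenerate (e.g. constant)."""


class EmptyAlignmentError(ValueError):
    """No usable events remained for peri-event alignment."""


class AlignmentError(ValueError):
    """Traces that must share a session clock do not."""


class DependencyError(RuntimeError):
    """A pipeline stage is missing the output of an upstream stage."""


class DataError(ValueError):
    """A data file could not be parsed or failed validation."""


class NoSolutionError(RuntimeError):
    """An iterative search exhausted its bounds without a solution."""


@dataclass
class TraceSet:
    """Per-neuron fluorescence traces with coordinates and plane identity.

    Attributes
    ----------
    traces : (n_neurons, n_samples) float array, arbitrary fluorescence units.
    coords : (n_neurons, 2) float array, micrometres in the imaging plane.
    plane : (n_neurons,) int array, focal-plane index per neuron.
    rate : sampling rate in Hz (effective per-plane rate).
    neuron_ids : (n_neurons,) int array of stable neuron identifiers.
    """

    traces: np.ndarray
    coords: np.ndarray
    plane: np.ndarray
    rate: float
    neuron_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.plane = np.asarray(self.plane, dtype=int)
        if self.traces.ndim != 2:
            raise InvalidArgumentError("traces must be 2-D (neurons x time)")
        n = self.traces.shape[0]
        if self.coords.shape != (n, 2):
            raise InvalidArgumentError("coords must have shape (n_neurons, 2)")
        if self.plane.shape != (n,):
            raise InvalidArgumentError("plane must have shape (n_neurons,)")
        if not self.rate > 0:
            raise InvalidArgumentError("rate must be positive")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(n)
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=int)
        if self.neuron_ids.shape != (n,):
            raise InvalidArgumentError("neuron_ids must have shape (n_neurons,)")

    @property
    def n_neurons(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def subset(self, keep: np.ndarray) -> "TraceSet":
        """Return a new TraceSet restricted to the given row indices."""
        keep = np.asarray(keep)
        return TraceSet(
            traces=self.traces[keep],
            coords=self.coords[keep],
            plane=self.plane[keep],
            rate=self.rate,
            neuron_ids=self.neuron_ids[keep],
        )


@dataclass
class EventSeries:
    """Deconvolved event times and sigma-normalised amplitudes, long format.

    ``table`` has columns ``neuron`` (int), ``time_s`` (float) and
    ``amplitude_sigma`` (float, multiples of the whole-trace fluorescence SD).
    """

    table: pd.DataFrame

    COLUMNS = ("neuron", "time_s", "amplitude_sigma")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise DataError(f"event table missing columns: {missing}")
        if len(self.table) and (self.table["amplitude_sigma"] <= 0).any():
            raise DataError("event amplitudes must be strictly positive")

    @classmethod
    def empty(cls) -> "EventSeries":
        return cls(pd.DataFrame({c: pd.Series(dtype=float) for c in cls.COLUMNS}))

    @classmethod
    def from_arrays(cls, neuron, time_s, amplitude_sigma) -> "EventSeries":
        return cls(
            pd.DataFrame(
                {
                    "neuron": np.asarray(neuron, dtype=int),
                    "time_s": np.asarray(time_s, dtype=float),
                    "amplitude_sigma": np.asarray(amplitude_sigma, dtype=float),
                }
            )
        )

    def for_neuron(self, neuron: int) -> pd.DataFrame:
        return self.table[self.table["neuron"] == neuron]

    def __len__(self) -> int:
        return len(self.table)
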