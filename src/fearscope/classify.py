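"""Event-aligned responder classification on Z-scored traces.

Responder calls use the time-averaged Z in a fixed post-event window:
footshock (US) events use [0, 1) s with threshold 1.0; tone-beep and
movement-ON events use [0, 0.5) s with threshold 0.2.  Tone beeps followed
by a movement transition, and movement transitions preceded by a tone, are
excluded before alignment.  Cross-plane duplicate cells (< 20 um apart,
Z-trace correlation > 0.7) are removed, keeping the brighter member.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from fearscope.core import (
    EmptyAlignmentError,
    InvalidArgumentError,
    TraceSet,
)
from fearscope.deconvolution import zscore_trace

EVENT_KINDS = ("US", "CS_beep", "movON_CS", "movON_noCS")

#: (analysis window length s, mean-Z threshold) per event kind
CLASSIFICATION_RULES: dict[str, tuple[float, float]] = {
    "US": (1.0, 1.0),
    "CS_beep": (0.5, 0.2),
    "movON_CS": (0.5, 0.2),
    "movON_noCS": (0.5, 0.2),
}

DEFAULT_WINDOW = (-2.0, 4.0)  # stored peri-event window, s
EXCLUSION_WINDOW = 0.5  # s, confound-trial rejection
DUPLICATE_DISTANCE_UM = 20.0
DUPLICATE_CORRELATION = 0.7


@dataclass
class AlignedResponse:
    """Average peri-event Z-score trace for one neuron and event kind."""

    neuron: int
    event_kind: str
    window_times: np.ndarray  # s relative to event onset
    mean_z: np.ndarray
    n_events: int
    n_dropped: int = 0

    def mean_window_z(self, window_length: float) -> float:
        """Time-averaged Z over [0, window_length) seconds post-onset."""
        mask = (self.window_times >= 0.0) & (self.window_times < window_length)
        return float(self.mean_z[mask].mean())


def align_events(
    ztraces: np.ndarray,
    rate: float,
    event_times: np.ndarray,
    event_kind: str = "US",
    window: tuple[float, float] = DEFAULT_WINDOW,
    neuron_ids: np.ndarray | None = None,
) -> list[AlignedResponse]:
    """Average peri-event snippets of Z traces for every neuron.

    Events whose window would cross either trace edge are dropped (and
    counted in ``n_dropped``).  Raises :class:`EmptyAlignmentError` when no
    usable event remains.
    """
    ztraces = np.atleast_2d(np.asarray(ztraces, dtype=float))
    event_times = np.asarray(event_times, dtype=float)
    if not np.isfinite(window).all() or window[0] >= window[1]:
        raise InvalidArgumentError("window must be a finite (lo, hi) pair")
    n_neurons, n_samples = ztraces.shape
    if neuron_ids is None:
        neuron_ids = np.arange(n_neurons)

    n_pre = int(round(-window[0] * rate))
    n_post = int(round(window[1] * rate))
    onsets = np.rint(event_times * rate).astype(int)
    usable = (onsets - n_pre >= 0) & (onsets + n_post <= n_samples)
    n_dropped = int((~usable).sum())
    onsets = onsets[usable]
    if onsets.size == 0:
        raise EmptyAlignmentError(f"no usable {event_kind} events for alignment")

    window_times = np.arange(-n_pre, n_post) / rate
    # gather all snippets at once: (events, window) index matrix
    idx = onsets[:, None] + np.arange(-n_pre, n_post)[None, :]
    out = []
    for i in range(n_neurons):
        snippets = ztraces[i][idx]
        out.append(
            AlignedResponse(
                neuron=int(neuron_ids[i]),
                event_kind=event_kind,
                window_times=window_times,
                mean_z=snippets.mean(axis=0),
                n_events=onsets.size,
                n_dropped=n_dropped,
            )
        )
    return out


def classify_responders(
    aligned: Iterable[AlignedResponse],
    day: str = "",
    rules: Mapping[str, tuple[float, float]] = CLASSIFICATION_RULES,
) -> pd.DataFrame:
    """Responder table from aligned responses.

    Returns a DataFrame with columns ``neuron, day, kind, mean_window_z,
    responder``; the flag is exactly ``mean_window_z > threshold`` with the
    kind-specific window and threshold.
    """
    rows = []
    for resp in aligned:
        if resp.event_kind not in rules:
            raise InvalidArgumentError(f"no rule for event kind {resp.event_kind!r}")
        window_length, threshold = rules[resp.event_kind]
        mz = resp.mean_window_z(window_length)
        rows.append(
            {
                "neuron": resp.neuron,
                "day": day,
                "kind": resp.event_kind,
                "mean_window_z": mz,
                "responder": bool(mz > threshold),
                "n_events": resp.n_events,
            }
        )
    return pd.DataFrame(rows)


def exclude_confounded(
    beep_times: np.ndarray,
    movement_on_times: np.ndarray,
    exclusion_window: float = EXCLUSION_WINDOW,
) -> tuple[np.ndarray, np.ndarray, dict[str, float]]:
    """Drop confounded trials before alignment.

    A beep with a movement-ON within ``[0, w]`` after it is removed from the
    tone analysis; a movement-ON with a beep within ``[-w, 0]`` before it is
    removed from the movement analysis.  Returns the cleaned arrays and the
    excluded fractions.
    """
    if exclusion_window < 0:
        raise InvalidArgumentError("exclusion window must be >= 0")
    beeps = np.sort(np.asarray(beep_times, dtype=float))
    movons = np.sort(np.asarray(movement_on_times, dtype=float))

    if movons.size and beeps.size:
        # nearest movement-ON at or after each beep
        pos = np.searchsorted(movons, beeps, side="left")
        has_next = pos < movons.size
        beep_bad = np.zeros(beeps.size, dtype=bool)
        beep_bad[has_next] = (
            movons[pos[has_next]] - beeps[has_next]
        ) <= exclusion_window
        # nearest beep at or before each movement-ON
        pos2 = np.searchsorted(beeps, movons, side="right") - 1
        has_prev = pos2 >= 0
        movon_bad = np.zeros(movons.size, dtype=bool)
        movon_bad[has_prev] = (
            movons[has_prev] - beeps[pos2[has_prev]]
        ) <= exclusion_window
    else:
        beep_bad = np.zeros(beeps.size, dtype=bool)
        movon_bad = np.zeros(movons.size, dtype=bool)

    fractions = {
        "beeps": float(beep_bad.mean()) if beeps.size else 0.0,
        "movons": float(movon_bad.mean()) if movons.size else 0.0,
    }
    return beeps[~beep_bad], movons[~movon_bad], fractions


def remove_duplicates(
    traceset: TraceSet,
    max_distance_um: float = DUPLICATE_DISTANCE_UM,
    min_correlation: float = DUPLICATE_CORRELATION,
) -> tuple[TraceSet, np.ndarray]:
    """Remove cross-plane duplicate cells.

    For every pair of cells on *different* focal planes whose centres are
    closer than ``max_distance_um`` and whose Z-score traces correlate above
    ``min_correlation``, the member with the lower mean fluorescence is
    removed; removal iterates until no violating pair remains.  Returns the
    deduplicated TraceSet and the removed neuron ids.
    """
    n = traceset.n_neurons
    z = np.empty_like(traceset.traces)
    const = np.zeros(n, dtype=bool)
    for i in range(n):
        sd = traceset.traces[i].std(ddof=1)
        if sd == 0:
            const[i] = True
            z[i] = 0.0
        else:
            z[i] = (traceset.traces[i] - traceset.traces[i].mean()) / sd
    mean_f = traceset.traces.mean(axis=1)

    d2 = np.sum(
        (traceset.coords[:, None, :] - traceset.coords[None, :, :]) ** 2, axis=-1
    )
    cross_plane = traceset.plane[:, None] != traceset.plane[None, :]
    close = (d2 < max_distance_um**2) & cross_plane
    np.fill_diagonal(close, False)

    alive = np.ones(n, dtype=bool)
    while True:
        violation = None
        ii, jj = np.nonzero(np.triu(close, 1))
        for i, j in zip(ii, jj):
            if not (alive[i] and alive[j]) or const[i] or const[j]:
                continue
            r = float(np.dot(z[i], z[j]) / (z.shape[1] - 1))
            if r > min_correlation:
                violation = (i, j)
                break
        if violation is None:
            break
        i, j = violation
        drop = i if mean_f[i] < mean_f[j] else j
        alive[drop] = False

    removed_ids = traceset.neuron_ids[~alive]
    return traceset.subset(np.flatnonzero(alive)), removed_ids
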