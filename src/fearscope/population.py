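"""Pooled cell maps, responder overlaps and day-by-day fractions."""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from fearscope.core import InvalidArgumentError

OVERLAP_KINDS = ("CS_beep", "movON", "US")


def build_cell_map(
    per_animal_coords: Mapping[str, np.ndarray],
    lens_centers: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Pool cells across animals into lens-centred coordinates.

    Each cell's coordinate becomes ``raw - lens_center`` for its animal.
    Returns a DataFrame (animal, cell, x_um, y_um).
    """
    rows = []
    for animal, coords in per_animal_coords.items():
        if animal not in lens_centers:
            raise InvalidArgumentError(f"missing lens center for animal {animal!r}")
        center = np.asarray(lens_centers[animal], dtype=float)
        coords = np.asarray(coords, dtype=float)
        if not np.isfinite(coords).all():
            raise InvalidArgumentError("non-finite cell coordinates")
        rel = coords - center
        for cell, (x, y) in enumerate(rel):
            rows.append({"animal": animal, "cell": cell, "x_um": x, "y_um": y})
    return pd.DataFrame(rows, columns=["animal", "cell", "x_um", "y_um"])


def overlap_counts(
    responder_table: pd.DataFrame, day: str, kinds: Sequence[str] = OVERLAP_KINDS
) -> dict[str, int]:
    """Venn region counts for the responder sets of one day.

    ``kinds`` may use the pseudo-kind ``movON`` which unions the CS and
    no-CS movement-ON calls.  Footshock ('US') overlaps are only defined on
    the training day.  Region keys are '+'-joined kind names, plus 'none';
    the region counts partition the set of neurons present that day.
    """
    sub = responder_table[responder_table["day"] == day]
    if sub.empty:
        raise InvalidArgumentError(f"responder table has no rows for day {day!r}")
    if "US" in kinds and day != "training":
        raise InvalidArgumentError("footshock overlaps are training-day only")

    sets: dict[str, set[int]] = {}
    for kind in kinds:
        if kind == "movON":
            mask = sub["kind"].isin(["movON_CS", "movON_noCS"])
        else:
            mask = sub["kind"] == kind
        flagged = sub[mask & sub["responder"]]
        sets[kind] = set(flagged["neuron"].tolist())

    universe = set(sub["neuron"].tolist())
    counts: dict[str, int] = {}
    for r in range(len(kinds), 0, -1):
        for combo in combinations(kinds, r):
            inside = set(universe)
            for kind in combo:
                inside &= sets[kind]
            for kind in kinds:
                if kind not in combo:
                    inside -= sets[kind]
            counts["+".join(combo)] = len(inside)
    in_any = set()
    for s in sets.values():
        in_any |= s
    counts["none"] = len(universe - in_any)
    return counts


def fractions_by_day(responder_table: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions of responders per day and event kind."""
    rows = []
    for (day, kind), grp in responder_table.groupby(["day", "kind"], sort=True):
        n_resp = int(grp["responder"].sum())
        total = int(len(grp))
        rows.append(
            {
                "day": day,
                "kind": kind,
                "n_responders": n_resp,
                "n_total": total,
                "fraction": n_resp / total if total else np.nan,
                "percent": 100.0 * n_resp / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows)
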