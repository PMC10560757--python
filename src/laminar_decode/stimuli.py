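"""Stimulus condition tables for grating and natural-image sessions.

Two families of visual-stimulus protocols are modelled:

* Allen-style sessions: drifting gratings with 8 directions crossed with
  5 temporal frequencies (1, 2, 4, 8, 15 Hz), ~75 repeats per condition,
  and a 119-image natural-scene session.
* Stringer-style sessions: 32 grating directions at 11.25 deg spacing at a
  single temporal frequency, or 32 natural images, 70-120 repeats.

A :class:`StimulusSet` is the condition table every downstream container
(response tensors, decoders, tuning metrics) is paired with.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "StimulusCondition",
    "StimulusSet",
    "make_stimulus_set",
    "PRESETS",
]


@dataclass(frozen=True)
class StimulusCondition:
    """One stimulus condition: either a grating (direction [+ TF]) or an image."""

    condition_id: int
    direction_deg: Optional[float] = None
    temporal_frequency_hz: Optional[float] = None
    image_id: Optional[int] = None

    def __post_init__(self) -> None:
        is_grating = self.direction_deg is not None
        is_image = self.image_id is not None
        if is_grating == is_image:
            raise ValueError(
                "exactly one of direction_deg or image_id must be set "
                f"(got direction_deg={self.direction_deg}, image_id={self.image_id})"
            )
        if self.temporal_frequency_hz is not None:
            if not is_grating:
                raise ValueError("temporal_frequency_hz only applies to gratings")
            if self.temporal_frequency_hz <= 0:
                raise ValueError("temporal_frequency_hz must be positive")
        if is_grating and not (0.0 <= self.direction_deg < 360.0):
            raise ValueError(f"direction_deg must lie in [0, 360): {self.direction_deg}")


@dataclass(frozen=True)
class StimulusSet:
    """An ordered condition table plus the per-condition repeat count."""

    task_kind: str  # "grating" | "image"
    conditions: tuple[StimulusCondition, ...]
    n_repeats: int

    def __post_init__(self) -> None:
        if self.task_kind not in ("grating", "image"):
            raise ValueError(f"unknown task_kind: {self.task_kind!r}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be a positive integer")
        if not self.conditions:
            raise ValueError("condition table is empty")
        ids = [c.condition_id for c in self.conditions]
        if len(set(ids)) != len(ids):
            raise ValueError("condition identifiers must be unique")
        object.__setattr__(self, "conditions", tuple(self.conditions))

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def condition_ids(self) -> list[int]:
        return [c.condition_id for c in self.conditions]

    def directions(self) -> list[float]:
        """Distinct grating directions in table order."""
        if self.task_kind != "grating":
            raise ValueError("directions() only applies to grating tasks")
        seen: dict[float, None] = {}
        for c in self.conditions:
            seen.setdefault(c.direction_deg, None)
        return list(seen)

    def temporal_frequencies(self) -> list[float]:
        """Distinct temporal frequencies in table order (empty if untracked)."""
        if self.task_kind != "grating":
            raise ValueError("temporal_frequencies() only applies to grating tasks")
        seen: dict[float, None] = {}
        for c in self.conditions:
            if c.temporal_frequency_hz is not None:
                seen.setdefault(c.temporal_frequency_hz, None)
        return list(seen)

    def find_grating(self, direction_deg: float, temporal_frequency_hz: Optional[float]) -> int:
        """Return the condition_id matching (direction, TF); raises if absent."""
        for c in self.conditions:
            if c.direction_deg is None:
                continue
            if abs(((c.direction_deg - direction_deg) + 180.0) % 360.0 - 180.0) > 1e-9:
                continue
            if temporal_frequency_hz is None and c.temporal_frequency_hz is None:
                return c.condition_id
            if (
                temporal_frequency_hz is not None
                and c.temporal_frequency_hz is not None
                and abs(c.temporal_frequency_hz - temporal_frequency_hz) < 1e-9
            ):
                return c.condition_id
        raise KeyError(
            f"no condition with direction {direction_deg} deg, TF {temporal_frequency_hz} Hz"
        )

    def to_dict(self) -> dict:
        return {
            "task_kind": self.task_kind,
            "n_repeats": self.n_repeats,
            "conditions": [
                {
                    "condition_id": c.condition_id,
                    "direction_deg": c.direction_deg,
                    "temporal_frequency_hz": c.temporal_frequency_hz,
                    "image_id": c.image_id,
                }
                for c in self.conditions
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StimulusSet":
        conds = tuple(
            StimulusCondition(
                condition_id=int(c["condition_id"]),
                direction_deg=c.get("direction_deg"),
                temporal_frequency_hz=c.get("temporal_frequency_hz"),
                image_id=c.get("image_id"),
            )
            for c in d["conditions"]
        )
        return cls(task_kind=d["task_kind"], conditions=conds, n_repeats=int(d["n_repeats"]))


def _grating_set(
    n_directions: int,
    temporal_frequencies_hz: Optional[Sequence[float]],
    n_repeats: int,
) -> StimulusSet:
    if n_directions <= 0:
        raise ValueError("n_directions must be positive")
    step = 360.0 / n_directions
    directions = [i * step for i in range(n_directions)]
    conds = []
    cid = 0
    tfs: Iterable[Optional[float]] = (
        temporal_frequencies_hz if temporal_frequencies_hz else [None]
    )
    for tf in tfs:
        for d in directions:
            conds.append(
                StimulusCondition(condition_id=cid, direction_deg=d, temporal_frequency_hz=tf)
            )
            cid += 1
    return StimulusSet(task_kind="grating", conditions=tuple(conds), n_repeats=n_repeats)


def _image_set(n_images: int, n_repeats: int) -> StimulusSet:
    if n_images <= 0:
        raise ValueError("n_images must be positive")
    conds = tuple(
        StimulusCondition(condition_id=i, image_id=i) for i in range(n_images)
    )
    return StimulusSet(task_kind="image", conditions=conds, n_repeats=n_repeats)


# Preset defaults mirror the two public-dataset protocols the pipeline emulates.
PRESETS: dict[str, dict] = {
    "allen-dg": dict(
        kind="grating",
        n_directions=8,
        temporal_frequencies_hz=(1.0, 2.0, 4.0, 8.0, 15.0),
        n_repeats=75,
    ),
    "allen-ni": dict(kind="image", n_images=119, n_repeats=75),
    "stringer-dg": dict(
        kind="grating",
        n_directions=32,
        temporal_frequencies_hz=(2.0,),
        n_repeats=90,
    ),
    "stringer-ni": dict(kind="image", n_images=32, n_repeats=90),
}


def make_stimulus_set(preset: str, overrides: Optional[Mapping] = None) -> StimulusSet:
    """Build a condition table from a named preset (or fully custom parameters).

    Parameters
    ----------
    preset
        One of ``allen-dg``, ``allen-ni``, ``stringer-dg``, ``stringer-ni`` or
        ``custom``.  ``custom`` requires ``overrides`` to carry either
        ``n_directions`` (grating) or ``n_images`` (image) plus ``n_repeats``.
    overrides
        Optional parameter map overriding the preset's defaults; recognised
        keys: ``n_directions``, ``temporal_frequencies_hz``, ``n_images``,
        ``n_repeats``.
    """
    overrides = dict(overrides or {})
    if preset == "custom":
        if "n_directions" in overrides:
            params = dict(kind="grating", temporal_frequencies_hz=None, n_repeats=10)
        elif "n_images" in overrides:
            params = dict(kind="image", n_repeats=10)
        else:
            raise ValueError("custom preset needs n_directions or n_images")
    elif preset in PRESETS:
        params = dict(PRESETS[preset])
    else:
        raise ValueError(f"unknown stimulus preset: {preset!r}")
    params.update(overrides)

    n_repeats = int(params["n_repeats"])
    if n_repeats <= 0:
        raise ValueError("n_repeats must be positive")
    if params["kind"] == "grating":
        return _grating_set(
            int(params["n_directions"]), params.get("temporal_frequencies_hz"), n_repeats
        )
    return _image_set(int(params["n_images"]), n_repeats)
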