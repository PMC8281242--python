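"""Trail-Making-Test stimulus layouts.

A layout is 25 non-overlapping encircled stimuli placed pseudo-randomly on the
display, in linking order: part A labels them "1".."25"; part B alternates
numbers 1-13 with letters A-L (1, A, 2, B, ..., L, 13). Trial variants are
derived from a base geometry by a 180-degree rotation and/or by swapping the
label set between parts, both of which preserve all inter-item distances so
the motor demands of the variants are identical.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Stimulus",
    "StimulusLayout",
    "PlacementError",
    "part_labels",
    "generate_layout",
    "rotate_layout",
    "swap_label_set",
]

N_ITEMS = 25


class PlacementError(RuntimeError):
    """Rejection sampling failed to place all stimuli."""


@dataclass(frozen=True)
class Stimulus:
    label: str
    x: float
    y: float
    r: float


@dataclass(frozen=True)
class StimulusLayout:
    items: tuple[Stimulus, ...]
    width: float
    height: float
    part: str  # "A" or "B"
    variant_id: int

    def path_length(self) -> float:
        xy = np.array([(s.x, s.y) for s in self.items])
        return float(np.sum(np.hypot(*np.diff(xy, axis=0).T)))


def part_labels(part: str) -> list[str]:
    if part == "A":
        return [str(i) for i in range(1, N_ITEMS + 1)]
    if part == "B":
        labels = []
        for i, letter in zip(range(1, 13), string.ascii_uppercase):
            labels += [str(i), letter]
        labels.append("13")
        return labels
    raise ValueError(f"unknown part {part!r}")


def _sample_geometry(
    rng: np.random.Generator,
    width: float,
    height: float,
    radius: float,
    gap: float,
    max_tries: int,
    step_range: tuple[float, float] = (90.0, 340.0),
) -> np.ndarray:
    """Sequential placement: each item lands a bounded distance from its
    sequence predecessor, as in the standard test sheet, so link path lengths
    are a few hundred pixels rather than display-scale jumps."""
    tries = 0
    while True:
        pts: list[tuple[float, float]] = []
        stuck = 0
        while len(pts) < N_ITEMS:
            if tries >= max_tries:
                raise PlacementError(
                    f"could not place {N_ITEMS} circles of radius {radius} "
                    f"in {width}x{height} after {max_tries} tries"
                )
            tries += 1
            if not pts:
                x = rng.uniform(radius, width - radius)
                y = rng.uniform(radius, height - radius)
            else:
                d = rng.uniform(*step_range)
                ang = rng.uniform(0.0, 2 * np.pi)
                x = pts[-1][0] + d * np.cos(ang)
                y = pts[-1][1] + d * np.sin(ang)
            in_bounds = radius <= x <= width - radius and radius <= y <= height - radius
            clear = all(
                np.hypot(x - px, y - py) >= 2 * radius + gap for px, py in pts
            )
            if in_bounds and clear:
                pts.append((x, y))
                stuck = 0
            else:
                stuck += 1
                if stuck > 200:  # walk cornered itself; restart the layout
                    break
        if len(pts) == N_ITEMS:
            return np.array(pts)


def generate_layout(
    part: str,
    variant_id: int = 0,
    seed: int = 0,
    width: float = 1280.0,
    height: float = 1024.0,
    radius: float = 28.0,
    gap: float = 12.0,
    max_tries: int = 20000,
) -> StimulusLayout:
    """Deterministically generate a layout variant.

    The base geometry depends only on ``seed`` (not on ``part``), so the A and
    B versions built from one seed share identical coordinates and therefore
    identical link path lengths. Bit 0 of ``variant_id`` applies the
    180-degree rotation (x, y) -> (width - x, height - y).
    """
    rng = np.random.default_rng(seed)
    xy = _sample_geometry(rng, width, height, radius, gap, max_tries)
    if variant_id & 1:
        xy = np.column_stack([width - xy[:, 0], height - xy[:, 1]])
    labels = part_labels(part)
    items = tuple(
        Stimulus(lbl, float(x), float(y), radius) for lbl, (x, y) in zip(labels, xy)
    )
    return StimulusLayout(items, width, height, part, variant_id)


def rotate_layout(layout: StimulusLayout) -> StimulusLayout:
    """180-degree rotation about the display center; an involution."""
    items = tuple(
        replace(s, x=layout.width - s.x, y=layout.height - s.y) for s in layout.items
    )
    return replace(layout, items=items, variant_id=layout.variant_id ^ 1)


def swap_label_set(layout: StimulusLayout) -> StimulusLayout:
    """Swap number-only and number-letter labels; coordinates unchanged."""
    other = "B" if layout.part == "A" else "A"
    labels = part_labels(other)
    items = tuple(replace(s, label=lbl) for s, lbl in zip(layout.items, labels))
    return replace(layout, items=items, part=other, variant_id=layout.variant_id ^ 2)
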