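"""Per-bone, per-side binary instance masks and the binary-mask bridge.

On an infant AP pelvic radiograph three bones are outlined per side: the
ilium (upper), the ischium-pubis complex ("middle" bone), and the femur
(lower).  ``InstanceMasks`` holds one strictly binary raster per
(bone, side) pair.  ``render_binary_mask`` flattens them into the single
0/255 foreground image that bridges the segmentation stage and the
landmark-detection stage of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ShapeMismatchError

__all__ = ["BONES", "SIDES", "InstanceMasks", "render_binary_mask"]

BONES = ("ilium", "middle", "femur")
SIDES = ("right", "left")


@dataclass
class InstanceMasks:
    """Binary masks keyed by (bone, side); all share the image shape."""

    shape: tuple[int, int]
    parts: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for key, m in list(self.parts.items()):
            self.parts[key] = self._validate(key, m)

    def _validate(self, key, m) -> np.ndarray:
        bone, side = key
        if bone not in BONES or side not in SIDES:
            raise ValueError(f"unknown mask key {key!r}")
        m = np.asarray(m)
        if m.shape != tuple(self.shape):
            raise ShapeMismatchError(f"mask {key} shape {m.shape} != image shape {self.shape}")
        m = m.astype(bool)
        return m

    def set(self, bone: str, side: str, mask: np.ndarray) -> None:
        self.parts[(bone, side)] = self._validate((bone, side), mask)

    def get(self, bone: str, side: str) -> np.ndarray | None:
        return self.parts.get((bone, side))

    def has(self, bone: str, side: str) -> bool:
        return (bone, side) in self.parts

    def union(self) -> np.ndarray:
        """Boolean union of all masks (all-False when empty)."""
        out = np.zeros(self.shape, dtype=bool)
        for m in self.parts.values():
            out |= m
        return out


def render_binary_mask(masks: InstanceMasks) -> np.ndarray:
    """Single-channel uint8 image: 255 where any mask is set, 0 elsewhere.

    Idempotent in the sense that re-rendering masks derived from the
    output reproduces the output.
    """
    return np.where(masks.union(), 255, 0).astype(np.uint8)
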