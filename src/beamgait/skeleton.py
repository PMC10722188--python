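"""Feature-point skeleton configuration.

A mouse posture is tracked as a fixed set of named feature points organised
into body-part groups.  The default configuration uses 18 points: 3 on the
head (ear tips and nose tip), 4 along the torso, 7 along the tail, and one
per foot.  Point order is significant: it fixes the component layout of
every downstream speed vector (x1, y1[, z1], x2, ...).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

__all__ = ["FeaturePointConfig", "default_config", "FOOT_LABELS", "AXES"]

#: canonical foot labels, front/rear x left/right
FOOT_LABELS = ("front-left", "front-right", "rear-left", "rear-right")

#: axis names per dimensionality
AXES = {2: ("x", "y"), 3: ("x", "y", "z")}

DEFAULT_GROUPS = {
    "head": ("left-ear-tip", "right-ear-tip", "nose-tip"),
    "body": ("body-1", "body-2", "body-3", "body-4"),
    "tail": ("tail-1", "tail-2", "tail-3", "tail-4", "tail-5", "tail-6", "tail-7"),
    "feet": FOOT_LABELS,
}


@dataclass(frozen=True)
class FeaturePointConfig:
    """Ordered grouping of named feature points.

    Parameters
    ----------
    groups
        Ordered mapping ``group name -> tuple of point names``.  Point names
        must be unique across groups.  The flattened point order defines the
        component layout used by all downstream modules.
    """

    groups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {g: tuple(p) for g, p in DEFAULT_GROUPS.items()}
    )

    def __post_init__(self) -> None:
        names = [p for pts in self.groups.values() for p in pts]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate point names across groups: {dup}")
        if not names:
            raise ValueError("configuration has no feature points")

    @property
    def point_names(self) -> tuple[str, ...]:
        return tuple(p for pts in self.groups.values() for p in pts)

    @property
    def n_points(self) -> int:
        return len(self.point_names)

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(self.groups)

    def group_of(self, point: str) -> str:
        for g, pts in self.groups.items():
            if point in pts:
                return g
        raise KeyError(point)

    def point_indices(self, group: str) -> list[int]:
        """Indices of a group's points in the flattened point order."""
        names = self.point_names
        return [names.index(p) for p in self.groups[group]]

    def component_names(self, dims: int) -> list[str]:
        """Names of the stacked speed/coordinate components, ``point_axis``."""
        return [f"{p}_{a}" for p in self.point_names for a in AXES[dims]]

    def component_indices(
        self, group: str, dims: int, axes: str | None = None
    ) -> list[int]:
        """Component indices of ``group`` in the stacked layout.

        ``axes`` restricts to a subset of axis letters, e.g. ``"xy"``.
        """
        letters = AXES[dims] if axes is None else tuple(axes)
        out = []
        for i in self.point_indices(group):
            for a_idx, a in enumerate(AXES[dims]):
                if a in letters:
                    out.append(i * dims + a_idx)
        return out

    def config_hash(self) -> str:
        canon = ";".join(f"{g}:{','.join(p)}" for g, p in self.groups.items())
        return hashlib.sha1(canon.encode()).hexdigest()[:12]


def default_config() -> FeaturePointConfig:
    """The 18-point head/body/tail/feet configuration (3/4/7/4 split)."""
    return FeaturePointConfig()
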