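"""Skeleton conventions for the 8-key-point larval zebrafish pose model.

Every downstream computation (center of mass, tail angle, heading,
inter-eye distance, egocentric alignment) refers to key-points by role
through a :class:`SkeletonSpec`, so alternative key-point orderings from
other tracking pipelines can be mapped in without touching the analysis
code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

N_KEYPOINTS = 8

#: Roles that must be present in every skeleton.
REQUIRED_ROLES = ("snout", "eye_left", "eye_right", "center", "caudal_fin")

#: Default anatomical ordering, rostral to caudal, eyes after the snout.
DEFAULT_ORDER = (
    "snout",
    "eye_left",
    "eye_right",
    "rostral_trunk",
    "center",
    "caudal_trunk",
    "mid_tail",
    "caudal_fin",
)


@dataclass(frozen=True)
class SkeletonSpec:
    """Mapping from key-point index (0-7) to anatomical role.

    Parameters
    ----------
    order
        Tuple of 8 role names. Must contain the roles in
        :data:`REQUIRED_ROLES`; the 6 non-eye roles form the body
        midline used for the center of mass.
    """

    order: tuple[str, ...] = field(default=DEFAULT_ORDER)

    def __post_init__(self) -> None:
        if len(self.order) != N_KEYPOINTS:
            raise ValueError(f"skeleton needs exactly {N_KEYPOINTS} key-points, got {len(self.order)}")
        if len(set(self.order)) != N_KEYPOINTS:
            raise ValueError("duplicate key-point roles in skeleton")
        missing = [r for r in REQUIRED_ROLES if r not in self.order]
        if missing:
            raise ValueError(f"skeleton missing required roles: {missing}")

    def index(self, role: str) -> int:
        return self.order.index(role)

    @property
    def snout(self) -> int:
        return self.index("snout")

    @property
    def eye_left(self) -> int:
        return self.index("eye_left")

    @property
    def eye_right(self) -> int:
        return self.index("eye_right")

    @property
    def center(self) -> int:
        return self.index("center")

    @property
    def caudal_fin(self) -> int:
        return self.index("caudal_fin")

    @property
    def midline_indices(self) -> tuple[int, ...]:
        """Indices of the 6 non-eye key-points, in skeleton order.

        The eyes are excluded because they sit lateral of the midline and
        bias the center of mass toward the head.
        """
        eyes = {self.eye_left, self.eye_right}
        idx = tuple(i for i in range(N_KEYPOINTS) if i not in eyes)
        assert len(idx) == 6
        return idx


DEFAULT_SKELETON = SkeletonSpec()
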