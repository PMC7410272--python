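"""Subject-scaled upper-limb models, virtual amputation and prosthesis substitution.

The limb is a proximal-to-distal chain of rigid segments attached to the
humeral long axis: upper arm (intact) or residual humerus quarters + pylon +
pyramid adapter (prosthetic), followed by forearm and hand.  Geometry is kept
as arc length along the chain; 3-D placement (which depends on the locked
elbow flexion angle) is resolved by :mod:`oiload.inverse_dynamics`.

Units are SI throughout: kg, m, kg.m^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

from oiload.errors import InvalidInputError, StateError

# Segment mass fractions of body mass (Dempster-style coefficients).
UPPER_ARM_MASS_FRACTION = 0.028
FOREARM_MASS_FRACTION = 0.016
HAND_MASS_FRACTION = 0.006

# Default COM offsets, fraction of segment length from the proximal end.
INTACT_UPPER_ARM_COM_OFFSET = 0.43
INTACT_FOREARM_COM_OFFSET = 0.43
INTACT_HAND_COM_OFFSET = 0.50
PROSTHETIC_COM_OFFSET = 0.45  # proximal of mid-segment

# Forearm length as a fraction of stature (used when not measured directly).
FOREARM_LENGTH_STATURE_RATIO = 0.146

PYLON_RADIUS = 0.015  # m
DEFAULT_PYLON_LINEAR_DENSITY = 1.0  # kg/m
DEFAULT_ADAPTER_MASS = 0.10  # kg

STUDY_AMPUTATION_LEVELS = (0.25, 0.50, 0.75)

PROSTHESIS_CATEGORIES = (
    "body_powered",
    "myoelectric_hook",
    "myoelectric_hand",
    "advanced",
)


@dataclass(frozen=True)
class SubjectAnthropometry:
    """Body dimensions of one (simulated) subject."""

    body_mass: float  # kg
    stature: float  # m
    upper_arm_length: float  # m, shoulder joint center to elbow joint center
    elbow_width: float  # m
    wrist_width: float  # m
    hand_length: float  # m
    sex_label: str = "unspecified"

    def __post_init__(self) -> None:
        for name in ("body_mass", "stature", "upper_arm_length", "elbow_width",
                     "wrist_width", "hand_length"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be strictly positive")
        if not self.upper_arm_length < self.stature:
            raise InvalidInputError("upper_arm_length must be less than stature")

    @property
    def forearm_length(self) -> float:
        return FOREARM_LENGTH_STATURE_RATIO * self.stature


@dataclass(frozen=True)
class SegmentInertialParams:
    """One rigid segment of the limb chain.

    ``proximal_offset`` is arc length from the shoulder along the chain path.
    ``com_offset`` is the dimensionless COM position from the proximal end.
    ``principal_inertia`` is (transverse, transverse, axial) about the COM with
    the third principal axis along the segment axis (uniform solid cylinder).
    """

    name: str
    role: str  # upper_arm | humerus_quarter | pylon | adapter | forearm | hand
    mass: float
    length: float
    com_offset: float
    transverse_radius: float
    proximal_offset: float
    distal_of_plane: bool = False

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise InvalidInputError(f"segment {self.name}: mass must be >= 0")
        if not 0.0 <= self.com_offset <= 1.0:
            raise InvalidInputError(
                f"segment {self.name}: com_offset must lie in [0, 1]")
        if self.length < 0 or self.transverse_radius < 0:
            raise InvalidInputError(
                f"segment {self.name}: lengths must be >= 0")

    @property
    def principal_inertia(self) -> np.ndarray:
        m, length, r = self.mass, self.length, self.transverse_radius
        transverse = m * (3.0 * r * r + length * length) / 12.0
        axial = 0.5 * m * r * r
        return np.array([transverse, transverse, axial])

    @property
    def com_arc_position(self) -> float:
        return self.proximal_offset + self.com_offset * self.length

    @property
    def distal_offset(self) -> float:
        return self.proximal_offset + self.length


@dataclass(frozen=True)
class ProsthesisSpec:
    """Mass/geometry of one prosthetic arm category."""

    category: str
    elbow_width: float  # m
    forearm_mass: float  # kg (includes integrated elbow components)
    wrist_width: float  # m
    hand_mass: float  # kg
    hand_length: float  # m
    forearm_com_offset: float = PROSTHETIC_COM_OFFSET
    hand_com_offset: float = PROSTHETIC_COM_OFFSET

    def __post_init__(self) -> None:
        if not 0.0 <= self.forearm_com_offset <= 1.0:
            raise InvalidInputError("forearm_com_offset must lie in [0, 1]")
        if not 0.0 <= self.hand_com_offset <= 1.0:
            raise InvalidInputError("hand_com_offset must lie in [0, 1]")

    @property
    def distal_mass(self) -> float:
        """Forearm + hand mass, excluding connector hardware."""
        return self.forearm_mass + self.hand_mass

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "elbow_width": self.elbow_width,
            "forearm_mass": self.forearm_mass,
            "wrist_width": self.wrist_width,
            "hand_mass": self.hand_mass,
            "hand_length": self.hand_length,
            "forearm_com_offset": self.forearm_com_offset,
            "hand_com_offset": self.hand_com_offset,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProsthesisSpec":
        return cls(**d)


@dataclass(frozen=True)
class AmputationConfig:
    """Virtual amputation plane and connector hardware parameters."""

    level: float  # fraction of upper_arm_length from the shoulder
    pylon_linear_density: float = DEFAULT_PYLON_LINEAR_DENSITY  # kg/m
    adapter_mass: float = DEFAULT_ADAPTER_MASS  # kg
    allow_nonstudy_level: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise InvalidInputError("amputation level must lie in (0, 1)")
        if not self.allow_nonstudy_level and not any(
                abs(self.level - lv) < 1e-12 for lv in STUDY_AMPUTATION_LEVELS):
            raise InvalidInputError(
                f"level {self.level} is not one of {STUDY_AMPUTATION_LEVELS}; "
                "set allow_nonstudy_level=True to override")
        if self.pylon_linear_density < 0 or self.adapter_mass < 0:
            raise InvalidInputError("connector masses/densities must be >= 0")


@dataclass(frozen=True)
class LimbModel:
    """Ordered proximal-to-distal chain of rigid segments.

    The humeral long-axis convention points proximally (distal -> proximal);
    ``interface_position`` is arc length along the humeral axis from the
    shoulder.  ``handheld_mass`` is a point mass carried at the hand COM,
    shifted ``handheld_offset`` m further distal along the hand axis.
    """

    segments: tuple[SegmentInertialParams, ...]
    upper_arm_length: float
    elbow_width: float
    wrist_width: float
    variant: str  # intact | prosthetic
    interface_position: float | None = None
    handheld_mass: float = 0.0
    handheld_offset: float = 0.0
    prosthesis_category: str | None = None
    amputation_level: float | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("intact", "prosthetic"):
            raise InvalidInputError(f"unknown variant {self.variant!r}")
        if self.handheld_mass < 0:
            raise InvalidInputError("handheld_mass must be >= 0")

    # -- chain queries ----------------------------------------------------

    @property
    def total_mass(self) -> float:
        return sum(s.mass for s in self.segments) + self.handheld_mass

    def segments_distal_of(self, arc_position: float) -> tuple[SegmentInertialParams, ...]:
        """Segments whose proximal end lies at/beyond ``arc_position``."""
        return tuple(s for s in self.segments
                     if s.proximal_offset >= arc_position - 1e-12)

    @property
    def distal_segments(self) -> tuple[SegmentInertialParams, ...]:
        if self.interface_position is None:
            raise StateError("model has no interface plane")
        return self.segments_distal_of(self.interface_position)

    @property
    def distal_mass(self) -> float:
        return sum(s.mass for s in self.distal_segments) + self.handheld_mass

    @property
    def forearm_length(self) -> float:
        for s in self.segments:
            if s.role == "forearm":
                return s.length
        raise StateError("model has no forearm segment")

    @property
    def hand_com_arc_position(self) -> float:
        for s in self.segments:
            if s.role == "hand":
                return s.com_arc_position
        raise StateError("model has no hand segment")

    def with_handheld(self, mass: float, offset: float = 0.0) -> "LimbModel":
        if mass < 0:
            raise InvalidInputError("handheld mass must be >= 0")
        return replace(self, handheld_mass=mass, handheld_offset=offset)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "segments": [{
                "name": s.name, "role": s.role, "mass": s.mass,
                "length": s.length, "com_offset": s.com_offset,
                "transverse_radius": s.transverse_radius,
                "proximal_offset": s.proximal_offset,
                "distal_of_plane": s.distal_of_plane,
            } for s in self.segments],
            "upper_arm_length": self.upper_arm_length,
            "elbow_width": self.elbow_width,
            "wrist_width": self.wrist_width,
            "variant": self.variant,
            "interface_position": self.interface_position,
            "handheld_mass": self.handheld_mass,
            "handheld_offset": self.handheld_offset,
            "prosthesis_category": self.prosthesis_category,
            "amputation_level": self.amputation_level,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "LimbModel":
        segs = tuple(SegmentInertialParams(**sd) for sd in d["segments"])
        rest = {k: v for k, v in d.items() if k != "segments"}
        return cls(segments=segs, **rest)

    @classmethod
    def from_json(cls, path) -> "LimbModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def anthropometric_segment_masses(body_mass: float) -> tuple[float, float, float]:
    """Segment masses (upper arm, forearm, hand) from body mass.

    Fixed mass fractions: 0.028, 0.016 and 0.006 of body mass respectively.
    """
    if not body_mass > 0:
        raise InvalidInputError("body_mass must be strictly positive")
    return (UPPER_ARM_MASS_FRACTION * body_mass,
            FOREARM_MASS_FRACTION * body_mass,
            HAND_MASS_FRACTION * body_mass)


def build_intact_model(subject: SubjectAnthropometry) -> LimbModel:
    """Three-segment intact arm (upper arm, forearm, hand) for one subject."""
    ua_mass, fa_mass, hd_mass = anthropometric_segment_masses(subject.body_mass)
    L_ua = subject.upper_arm_length
    L_fa = subject.forearm_length
    segments = (
        SegmentInertialParams(
            name="upper_arm", role="upper_arm", mass=ua_mass, length=L_ua,
            com_offset=INTACT_UPPER_ARM_COM_OFFSET,
            transverse_radius=subject.elbow_width / 2.0, proximal_offset=0.0),
        SegmentInertialParams(
            name="forearm", role="forearm", mass=fa_mass, length=L_fa,
            com_offset=INTACT_FOREARM_COM_OFFSET,
            transverse_radius=subject.wrist_width / 2.0, proximal_offset=L_ua),
        SegmentInertialParams(
            name="hand", role="hand", mass=hd_mass, length=subject.hand_length,
            com_offset=INTACT_HAND_COM_OFFSET,
            transverse_radius=subject.wrist_width / 2.0,
            proximal_offset=L_ua + L_fa),
    )
    return LimbModel(segments=segments, upper_arm_length=L_ua,
                     elbow_width=subject.elbow_width,
                     wrist_width=subject.wrist_width, variant="intact")


def apply_virtual_amputation(model: LimbModel, cfg: AmputationConfig) -> LimbModel:
    """Split the upper arm into equal-mass quarters and set the interface plane.

    The upper arm is replaced by four contiguous quarter-segments of equal
    mass (uniform density); a quarter straddling the plane is split at the
    plane so residual mass is exactly ``level x upper-arm mass``.  Segments
    distal of the plane are retained (for the intact-comparison model) but
    flagged ``distal_of_plane`` for prosthetic substitution.  Total mass is
    conserved.
    """
    if model.variant != "intact":
        raise InvalidInputError("virtual amputation requires an intact model")
    upper = next(s for s in model.segments if s.role == "upper_arm")
    L = upper.length
    plane = cfg.level * L
    density = upper.mass / L

    # quarter boundaries plus the plane itself (dedup keeps quarters contiguous)
    bounds = sorted({0.0, 0.25 * L, 0.50 * L, 0.75 * L, L, plane})
    quarters = []
    for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        if b - a <= 1e-15:
            continue
        quarters.append(SegmentInertialParams(
            name=f"humerus_q{i + 1}", role="humerus_quarter",
            mass=density * (b - a), length=b - a, com_offset=0.5,
            transverse_radius=upper.transverse_radius, proximal_offset=a,
            distal_of_plane=a >= plane - 1e-12))

    rest = tuple(replace(s, distal_of_plane=True)
                 for s in model.segments if s.role != "upper_arm")
    return replace(model, segments=tuple(quarters) + rest,
                   interface_position=plane, amputation_level=cfg.level)


def attach_prosthesis(amputated: LimbModel, spec: ProsthesisSpec,
                      cfg: AmputationConfig) -> LimbModel:
    """Replace everything distal of the interface plane with a prosthesis.

    A pylon spans interface plane -> elbow for the 25 % and 50 % levels
    (length ``(1 - level) x upper_arm_length``, mass ``density x length``,
    COM at mid-length on the long axis); at the 75 % level no pylon is
    modelled and the arm joins via the pyramid adapter alone.  The adapter is
    a point mass at the interface plane.  Prosthetic forearm and hand carry
    the category's masses and geometry; elbow/wrist widths are replaced by
    the spec values.
    """
    if amputated.interface_position is None:
        raise StateError("model has no interface plane; amputate first")
    plane = amputated.interface_position
    L_ua = amputated.upper_arm_length
    residual = tuple(s for s in amputated.segments if not s.distal_of_plane)

    chain = [SegmentInertialParams(
        name="pyramid_adapter", role="adapter", mass=cfg.adapter_mass,
        length=0.0, com_offset=0.0, transverse_radius=0.0,
        proximal_offset=plane)]
    if cfg.level < 0.75 - 1e-12:
        pylon_length = L_ua - plane
        chain.append(SegmentInertialParams(
            name="pylon", role="pylon",
            mass=cfg.pylon_linear_density * pylon_length, length=pylon_length,
            com_offset=0.5, transverse_radius=PYLON_RADIUS,
            proximal_offset=plane))

    # the prosthetic forearm keeps the subject's elbow-to-wrist length
    L_fa = amputated.forearm_length
    chain.append(SegmentInertialParams(
        name="prosthetic_forearm", role="forearm", mass=spec.forearm_mass,
        length=L_fa, com_offset=spec.forearm_com_offset,
        transverse_radius=spec.wrist_width / 2.0, proximal_offset=L_ua))
    chain.append(SegmentInertialParams(
        name="prosthetic_hand", role="hand", mass=spec.hand_mass,
        length=spec.hand_length, com_offset=spec.hand_com_offset,
        transverse_radius=spec.wrist_width / 2.0, proximal_offset=L_ua + L_fa))

    return replace(amputated, segments=residual + tuple(chain),
                   variant="prosthetic", elbow_width=spec.elbow_width,
                   wrist_width=spec.wrist_width,
                   prosthesis_category=spec.category)


def _load_preset_file() -> dict:
    text = resources.files("oiload.data").joinpath(
        "prosthesis_presets.yaml").read_text()
    return yaml.safe_load(text)


def prosthesis_preset(category: str) -> ProsthesisSpec:
    """Spec for one of the four study prosthesis categories (shipped presets)."""
    presets = _load_preset_file()["presets"]
    if category not in presets:
        raise InvalidInputError(
            f"unknown prosthesis category {category!r}; "
            f"expected one of {sorted(presets)}")
    return ProsthesisSpec(category=category, **presets[category])


def build_prosthetic_model(subject: SubjectAnthropometry, category: str,
                           cfg: AmputationConfig) -> LimbModel:
    """Convenience: intact -> amputated -> prosthetic in one call."""
    return attach_prosthesis(
        apply_virtual_amputation(build_intact_model(subject), cfg),
        prosthesis_preset(category), cfg)
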