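"""Single-trial sensitivity of peak loads to distal mass and COM placement.

Perturbs forearm/hand masses by a factor k and shifts their COMs
proximally/distally, re-runs the load pipeline on identical kinematics, and
reports perturbed/baseline peak ratios per modality.  "50 % proximal/distal"
is interpreted as +/-50 % of the COM's distance from the proximal joint
(the alternative - a fraction of segment length - is available via ``mode``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from oiload.errors import InvalidInputError
from oiload.inverse_dynamics import loads_for_trial
from oiload.limb_model import LimbModel
from oiload.load_stats import MODALITIES, extract_peaks
from oiload.motion_synth import MotionTrial

DISTAL_ROLES = ("forearm", "hand")


@dataclass(frozen=True)
class SensitivityResult:
    perturbation: str  # "mass_scale" | "com_shift"
    value: float  # k for mass_scale; signed s for com_shift (distal positive)
    modality: str
    peak_ratio: float  # perturbed / baseline
    activity: str = ""

    def __post_init__(self) -> None:
        if not self.peak_ratio > 0:
            raise InvalidInputError("peak_ratio must be > 0")


def scale_distal_masses(model: LimbModel, k: float,
                        include_handheld: bool = False,
                        include_connectors: bool = False) -> LimbModel:
    """Scale forearm and hand masses by k; pylon/adapter untouched by default.

    ``include_connectors`` additionally scales pylon/adapter/residual-bone
    segments distal of the interface (used by the exact-linearity check);
    ``include_handheld`` scales a carried mass too.
    """
    if not k > 0:
        raise InvalidInputError("mass scale factor must be > 0")
    plane = model.interface_position
    segs = []
    for s in model.segments:
        scale = s.role in DISTAL_ROLES
        if include_connectors and plane is not None:
            scale = scale or s.proximal_offset >= plane - 1e-12
        segs.append(replace(s, mass=k * s.mass) if scale else s)
    hh = model.handheld_mass * k if include_handheld else model.handheld_mass
    return replace(model, segments=tuple(segs), handheld_mass=hh)


def shift_coms(model: LimbModel, s: float,
               mode: str = "fraction_of_com_distance") -> LimbModel:
    """Shift forearm/hand COMs distally (s > 0) or proximally (s < 0).

    Default mode rescales each COM's distance from the proximal joint by
    (1 + s); ``mode='fraction_of_length'`` instead adds ``s`` to the offset.
    Offsets leaving [0, 1] raise.
    """
    if mode not in ("fraction_of_com_distance", "fraction_of_length"):
        raise InvalidInputError(f"unknown COM shift mode {mode!r}")
    segs = []
    for seg in model.segments:
        if seg.role not in DISTAL_ROLES:
            segs.append(seg)
            continue
        if mode == "fraction_of_com_distance":
            new_offset = seg.com_offset * (1.0 + s)
        else:
            new_offset = seg.com_offset + s
        if not 0.0 <= new_offset <= 1.0:
            raise InvalidInputError(
                f"COM shift s={s} moves segment {seg.name} offset to "
                f"{new_offset:.3f}, outside [0, 1]")
        segs.append(replace(seg, com_offset=new_offset))
    return replace(model, segments=tuple(segs))


def _peaks(trial: MotionTrial, model: LimbModel, filter_cutoff,
           axial_convention: str):
    loads = loads_for_trial(trial, model, filter_cutoff=filter_cutoff)
    return extract_peaks(loads, axial_convention=axial_convention)


def sensitivity_report(trial: MotionTrial, model: LimbModel,
                       mass_scales=(0.5, 1.5), com_shifts=(-0.5, 0.5),
                       include_handheld: bool = False,
                       filter_cutoff: float | None = 6.0,
                       axial_convention: str = "tensile",
                       com_mode: str = "fraction_of_com_distance",
                       ) -> list[SensitivityResult]:
    """Peak-load ratios for each perturbation, on one trial's kinematics."""
    baseline = _peaks(trial, model, filter_cutoff, axial_convention)
    results = []
    perturbed_models = [
        ("mass_scale", k, scale_distal_masses(model, k,
                                              include_handheld=include_handheld))
        for k in mass_scales
    ] + [
        ("com_shift", s, shift_coms(model, s, mode=com_mode))
        for s in com_shifts
    ]
    for kind, value, pm in perturbed_models:
        peaks = _peaks(trial, pm, filter_cutoff, axial_convention)
        for modality in MODALITIES:
            results.append(SensitivityResult(
                perturbation=kind, value=value, modality=modality,
                peak_ratio=peaks.value(modality) / baseline.value(modality),
                activity=trial.activity))
    return results
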