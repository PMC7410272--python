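"""Published bone-implant failure thresholds and exceedance flagging.

Thresholds are time-zero cadaveric yield/ultimate-failure loads per modality,
shipped as a versioned data file.  Modelled 25 %/75 % amputation levels map to
the tested proximal (30 %)/distal (65 %) counterparts.  The default policy is
conservative for the patient: loads are compared against the lower bound of
each published range.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml

from oiload.errors import ConfigurationError, InvalidInputError
from oiload.load_stats import MODALITIES, PeakLoads


@dataclass(frozen=True)
class FailureEnvelope:
    """Yield / ultimate thresholds for one modality x level x screw condition.

    Moments in N.m, forces in N.  ``yield_lo``/``yield_hi`` may be absent when
    the source only reports ultimate failure.
    """

    modality: str
    level: str  # proximal | distal | unspecified
    screws: str  # with | without | unspecified
    ultimate_lo: float
    ultimate_hi: float
    yield_lo: float | None = None
    yield_hi: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise InvalidInputError(f"unknown modality {self.modality!r}")
        if self.level not in ("proximal", "distal", "unspecified"):
            raise InvalidInputError(f"unknown level {self.level!r}")
        if self.screws not in ("with", "without", "unspecified"):
            raise InvalidInputError(f"unknown screws value {self.screws!r}")
        if not 0 < self.ultimate_lo <= self.ultimate_hi:
            raise InvalidInputError("ultimate bounds must be ordered, > 0")
        if self.yield_lo is not None:
            if self.yield_hi is None:
                raise InvalidInputError("yield_hi missing")
            if not 0 < self.yield_lo <= self.yield_hi <= self.ultimate_hi:
                raise InvalidInputError(
                    "need 0 < yield_lo <= yield_hi <= ultimate_hi")
            if not self.yield_lo <= self.ultimate_lo:
                raise InvalidInputError("need yield_lo <= ultimate_lo")


@dataclass(frozen=True)
class ExceedanceFlag:
    """Comparison of one peak load against one envelope."""

    activity: str
    model_variant: str
    level: float
    modality: str
    load: float
    exceeds_yield: bool
    exceeds_ultimate: bool
    yield_margin: float | None  # threshold / load
    ultimate_margin: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.exceeds_ultimate and self.yield_margin is not None:
            # ultimate exceedance implies yield exceedance when yield <= ultimate
            if not self.exceeds_yield and self.yield_margin >= 1.0 \
                    and self.ultimate_margin < self.yield_margin:
                raise InvalidInputError(
                    "inconsistent flags: ultimate exceeded but not yield")


def load_envelope_presets() -> list[FailureEnvelope]:
    """All shipped failure-threshold presets (validated at load)."""
    text = resources.files("oiload.data").joinpath(
        "failure_envelopes.yaml").read_text()
    raw = yaml.safe_load(text)
    envelopes = []
    for entry in raw["envelopes"]:
        entry = {k: v for k, v in entry.items() if k != "ultimate_sd"}
        envelopes.append(FailureEnvelope(**entry))
    return envelopes


def load_reported_peaks() -> pd.DataFrame:
    """Reference table of reported peak mean +/- SD loads per condition.

    Columns: model_variant, level, modality, activity, mean, sd.  Used as a
    published input for failure-margin arithmetic and exceedance reports.
    """
    text = resources.files("oiload.data").joinpath(
        "reported_peaks.csv").read_text()
    return pd.read_csv(io.StringIO(text))


def map_level(model_level: float) -> str:
    """Map a modelled amputation fraction to its tested anatomical level.

    Only 25 % (-> proximal, tested at 30 %) and 75 % (-> distal, tested at
    65 %) have published counterparts; 50 % raises.
    """
    if abs(model_level - 0.25) < 1e-9:
        return "proximal"
    if abs(model_level - 0.75) < 1e-9:
        return "distal"
    raise InvalidInputError(
        f"no tested anatomical counterpart for level {model_level}")


def select_envelope(envelopes: list[FailureEnvelope], modality: str,
                    level: str, screws: str = "unspecified"
                    ) -> FailureEnvelope:
    """Most specific envelope matching modality/level/screws.

    Exact level/screws matches outrank 'unspecified' entries.
    """
    best = None
    best_score = -1
    for env in envelopes:
        if env.modality != modality:
            continue
        if env.level not in (level, "unspecified"):
            continue
        if env.screws not in (screws, "unspecified"):
            continue
        score = (env.level == level) * 2 + (env.screws == screws)
        if score > best_score:
            best, best_score = env, score
    if best is None:
        raise ConfigurationError(
            f"no failure envelope for modality={modality!r} level={level!r} "
            f"screws={screws!r}")
    return best


def exceedance(peaks: list[PeakLoads],
               envelopes: list[FailureEnvelope] | None = None,
               policy: str = "conservative", screws: str = "unspecified",
               skip_unmapped: bool = True) -> list[ExceedanceFlag]:
    """Flag peak loads that exceed yield / ultimate failure thresholds.

    ``policy='conservative'`` compares against the lower bound of each range
    (worst case for the patient); ``'optimistic'`` uses the upper bound.
    Peaks at levels without a tested counterpart (50 %) are skipped unless
    ``skip_unmapped=False``.  Margins are threshold / load ratios.
    """
    if envelopes is None:
        envelopes = load_envelope_presets()
    if policy not in ("conservative", "optimistic"):
        raise InvalidInputError(f"unknown policy {policy!r}")
    lo = policy == "conservative"
    flags = []
    for peak in peaks:
        try:
            anatomical = map_level(peak.level)
        except InvalidInputError:
            if skip_unmapped:
                continue
            raise
        for modality in MODALITIES:
            env = select_envelope(envelopes, modality, anatomical, screws)
            load = peak.value(modality)
            ult_thr = env.ultimate_lo if lo else env.ultimate_hi
            yld_thr = None if env.yield_lo is None else (
                env.yield_lo if lo else env.yield_hi)
            positive = load > 0
            flags.append(ExceedanceFlag(
                activity=peak.activity, model_variant=peak.model_variant,
                level=peak.level, modality=modality, load=load,
                exceeds_yield=(yld_thr is not None and positive
                               and load > yld_thr),
                exceeds_ultimate=positive and load > ult_thr,
                yield_margin=(yld_thr / load
                              if yld_thr is not None and positive else None),
                ultimate_margin=(ult_thr / load if positive else float("inf")),
                source=env.source))
    return flags


def exceedance_report(flags: list[ExceedanceFlag]) -> pd.DataFrame:
    return pd.DataFrame([{
        "activity": f.activity, "model_variant": f.model_variant,
        "level": f.level, "modality": f.modality, "load": f.load,
        "exceeds_yield": f.exceeds_yield,
        "exceeds_ultimate": f.exceeds_ultimate,
        "yield_margin": f.yield_margin, "ultimate_margin": f.ultimate_margin,
        "source": f.source,
    } for f in flags])
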