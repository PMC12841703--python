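"""The PRE-ECV additive points score.

Eight clinical and ultrasonographic predictors, each carrying 0, 1 or 2
points, are summed into a total score between 0 and 13 that ranks the
chance of a successful external cephalic version (ECV) at term:

========================  =============================  ======
factor                    condition                      points
========================  =============================  ======
parity                    multiparous                    2
fetal presentation        transverse                     2
                          complete breech                1
                          frank breech                   0
non-engagement            presenting part not engaged    2
palpable fetal head       head palpable abdominally      2
estimated fetal weight    >= 10th percentile             1
maximum vertical pocket   >= 4 cm                        1
placental location        posterior wall                 1
tocolysis                 given before the attempt       2
========================  =============================  ======

The weights are fixed by design (level-A evidence factors carry 2 points,
level-B factors 1 point); nothing in this module is refitted from data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum

from .errors import ValidationError

__all__ = [
    "Parity",
    "Presentation",
    "PredictorProfile",
    "ScoreResult",
    "FACTOR_NAMES",
    "compute_score",
    "score_bounds",
    "all_profiles",
]


class Parity(str, Enum):
    MULTIPAROUS = "multiparous"
    NULLIPAROUS = "nulliparous"


class Presentation(str, Enum):
    TRANSVERSE = "transverse"
    COMPLETE_BREECH = "complete_breech"
    FRANK_BREECH = "frank_breech"


#: Fixed factor names used as keys of :attr:`ScoreResult.breakdown`.
#: These strings are part of the public contract.
FACTOR_NAMES = (
    "parity",
    "fetal_presentation",
    "non_engagement",
    "palpable_fetal_head",
    "efw",
    "mvp",
    "placental_location",
    "tocolysis",
)

_PRESENTATION_POINTS = {
    Presentation.TRANSVERSE: 2,
    Presentation.COMPLETE_BREECH: 1,
    Presentation.FRANK_BREECH: 0,
}


@dataclass(frozen=True)
class PredictorProfile:
    """One patient's predictor values, assessed immediately before the ECV.

    Every field must be set; a missing value is an input error, not a state.
    ``engaged`` is True when the presenting part is engaged in the pelvis
    (engagement itself scores 0 -- the score rewards *non*-engagement).
    ``efw_ge_10th_percentile`` and ``mvp_ge_4cm`` are dichotomised upstream
    by the caller: an EFW percentile below 10 and an MVP below 4.0 cm are
    the low (0-point) states.  Placental location is dichotomised to
    posterior wall vs anything else.
    """

    parity: Parity
    presentation: Presentation
    engaged: bool
    palpable_head: bool
    efw_ge_10th_percentile: bool
    mvp_ge_4cm: bool
    placenta_posterior: bool
    tocolysis: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "parity", _coerce_enum("parity", self.parity, Parity))
        object.__setattr__(
            self, "presentation", _coerce_enum("presentation", self.presentation, Presentation)
        )
        for name in (
            "engaged",
            "palpable_head",
            "efw_ge_10th_percentile",
            "mvp_ge_4cm",
            "placenta_posterior",
            "tocolysis",
        ):
            value = getattr(self, name)
            if not isinstance(value, bool):
                raise ValidationError(
                    f"field '{name}' must be a bool, got {value!r}"
                )


def _coerce_enum(field: str, value, enum_cls):
    if isinstance(value, enum_cls):
        return value
    try:
        return enum_cls(value)
    except ValueError:
        allowed = ", ".join(m.value for m in enum_cls)
        raise ValidationError(
            f"field '{field}' must be one of {{{allowed}}}, got {value!r}"
        ) from None


@dataclass(frozen=True)
class ScoreResult:
    """Total score and its per-factor breakdown (exactly 8 entries)."""

    total: int
    breakdown: dict[str, int]


def compute_score(profile: PredictorProfile) -> ScoreResult:
    """Compute the additive PRE-ECV score for one predictor profile.

    Returns a :class:`ScoreResult` whose ``total`` is the sum of the
    per-factor points and always lies in [0, 13].

    Raises
    ------
    ValidationError
        If any field is unset or outside its enumeration (raised at
        profile construction; re-raised here for non-profile inputs).
    """
    if not isinstance(profile, PredictorProfile):
        raise ValidationError(f"expected a PredictorProfile, got {type(profile).__name__}")
    breakdown = {
        "parity": 2 if profile.parity is Parity.MULTIPAROUS else 0,
        "fetal_presentation": _PRESENTATION_POINTS[profile.presentation],
        "non_engagement": 0 if profile.engaged else 2,
        "palpable_fetal_head": 2 if profile.palpable_head else 0,
        "efw": 1 if profile.efw_ge_10th_percentile else 0,
        "mvp": 1 if profile.mvp_ge_4cm else 0,
        "placental_location": 1 if profile.placenta_posterior else 0,
        "tocolysis": 2 if profile.tocolysis else 0,
    }
    return ScoreResult(total=sum(breakdown.values()), breakdown=breakdown)


def all_profiles() -> list[PredictorProfile]:
    """Enumerate all 2^7 x 3 = 384 admissible predictor profiles."""
    profiles = []
    bools = (False, True)
    for parity, pres, eng, palp, efw, mvp, post, toco in itertools.product(
        Parity, Presentation, bools, bools, bools, bools, bools, bools
    ):
        profiles.append(
            PredictorProfile(parity, pres, eng, palp, efw, mvp, post, toco)
        )
    return profiles


def score_bounds() -> tuple[int, int]:
    """Analytic (min, max) achievable totals, found by scoring the two
    extreme profiles through :func:`compute_score` rather than hard-coding."""
    worst = PredictorProfile(
        parity=Parity.NULLIPAROUS,
        presentation=Presentation.FRANK_BREECH,
        engaged=True,
        palpable_head=False,
        efw_ge_10th_percentile=False,
        mvp_ge_4cm=False,
        placenta_posterior=False,
        tocolysis=False,
    )
    best = PredictorProfile(
        parity=Parity.MULTIPAROUS,
        presentation=Presentation.TRANSVERSE,
        engaged=False,
        palpable_head=True,
        efw_ge_10th_percentile=True,
        mvp_ge_4cm=True,
        placenta_posterior=True,
        tocolysis=True,
    )
    return compute_score(worst).total, compute_score(best).total
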