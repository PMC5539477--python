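"""Activity vocabulary shared by every stage of the pipeline.

Six activities are modelled: sitting (SI), standing (ST), walking (WK),
ascending stairs/incline (AS), running (RU) and post-exercise rest (REST).
Recognition is a five-class problem (REST looks like SI to an accelerometer
and is excluded); energy-expenditure estimation uses all six, split into a
static category {SI, ST, REST} and a dynamic category {WK, AS, RU}.
"""

from __future__ import annotations

import enum


class Activity(str, enum.Enum):
    SI = "SI"
    ST = "ST"
    WK = "WK"
    AS = "AS"
    RU = "RU"
    REST = "REST"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def is_static(self) -> bool:
        return self in STATIC_ACTIVITIES

    @property
    def is_dynamic(self) -> bool:
        return self in DYNAMIC_ACTIVITIES


#: Classes used by the activity-recognition task (REST excluded).
RECOGNITION_ACTIVITIES: tuple[Activity, ...] = (
    Activity.SI,
    Activity.ST,
    Activity.WK,
    Activity.RU,
    Activity.AS,
)

#: Little or no net body movement.
STATIC_ACTIVITIES: frozenset[Activity] = frozenset(
    {Activity.SI, Activity.ST, Activity.REST}
)

#: Locomotion with sustained movement.
DYNAMIC_ACTIVITIES: frozenset[Activity] = frozenset(
    {Activity.WK, Activity.AS, Activity.RU}
)

ALL_ACTIVITIES: tuple[Activity, ...] = tuple(Activity)


def as_activity(value: "Activity | str") -> Activity:
    """Coerce a string code (e.g. ``"WK"``) to an :class:`Activity`."""
    if isinstance(value, Activity):
        return value
    try:
        return Activity(str(value).upper())
    except ValueError as exc:
        raise ValueError(
            f"unknown activity code {value!r}; expected one of "
            f"{[a.value for a in Activity]}"
        ) from exc
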