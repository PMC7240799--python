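"""Domain types and deterministic encodings for the treatment MDP.

A patient's condition at a decision epoch is summarised by six categorical
attributes — age band, disease-history count, complication flag, western
diagnosis, TCM syndrome type, and neurological-impairment level — and
serialised as a six-digit state code such as ``"200112"``.  A treatment
choice for one epoch is a three-bit action code over (rehabilitation,
Chinese herbal decoction, acupuncture), e.g. ``"101"``.  Rewards are
impairment-score improvements (before minus after) on the 0–29 scale, so
positive rewards mean the patient got better.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass
from typing import Iterator

SCORE_MIN = 0
SCORE_MAX = 29

#: score recorded for a patient whose outcome is death
DEATH_SCORE = 29

#: closed score interval covered by each impairment level
LEVEL_BOUNDS: dict[int, tuple[int, int]] = {
    1: (0, 2),
    2: (3, 5),
    3: (6, 12),
    4: (13, 19),
    5: (20, 29),
}

#: valid categories per state attribute, in state-code digit order i1..i6
ATTRIBUTE_DOMAINS: dict[str, tuple[int, ...]] = {
    "age_band": (1, 2, 3),          # 18-45 / 46-65 / >=66 years
    "history": (0, 1, 2),           # none / one / at least two prior diseases
    "complication": (0, 1),         # none / at least one
    "diagnosis": (1, 2),            # ischaemic / haemorrhagic
    "syndrome": (1, 2, 3, 4, 5),    # TCM syndrome differentiation
    "level": (1, 2, 3, 4, 5),       # graded impairment score
}

STATE_FIELDS: tuple[str, ...] = tuple(ATTRIBUTE_DOMAINS)

ACTION_FIELDS: tuple[str, ...] = ("a1", "a2", "a3")

#: the full 8-member action set, in the conventional inventory order
ACTION_CODES: tuple[str, ...] = (
    "111", "110", "101", "100", "011", "010", "001", "000",
)

MILD = "mild"
MODERATE_TO_SEVERE = "moderate_to_severe"
SEVERITY_BANDS: tuple[str, str] = (MILD, MODERATE_TO_SEVERE)


def _as_int(value, name: str) -> int:
    """Coerce an integer-like value, rejecting floats and other types."""
    if isinstance(value, bool):
        raise TypeError(f"{name} must be an integer, got bool")
    try:
        return operator.index(value)
    except TypeError:
        raise TypeError(f"{name} must be an integer, got {value!r}") from None


def check_score(score, name: str = "score") -> int:
    """Validate an impairment score and return it as a plain int."""
    value = _as_int(score, name)
    if not SCORE_MIN <= value <= SCORE_MAX:
        raise ValueError(
            f"{name} must lie in {SCORE_MIN}..{SCORE_MAX}, got {value}"
        )
    return value


def grade_score(score) -> int:
    """Map an impairment score (0–29) to its level 1..5.

    The five closed intervals 0–2, 3–5, 6–12, 13–19 and 20–29 partition
    the score range.
    """
    value = check_score(score)
    for level, (lo, hi) in LEVEL_BOUNDS.items():
        if lo <= value <= hi:
            return level
    raise AssertionError("unreachable: level intervals cover 0..29")


def severity_band(level) -> str:
    """Collapse a level 1..5 into ``mild`` (1–2) or ``moderate_to_severe`` (3–5)."""
    value = _as_int(level, "level")
    if value not in ATTRIBUTE_DOMAINS["level"]:
        raise ValueError(f"level must be one of 1..5, got {value}")
    return MILD if value <= 2 else MODERATE_TO_SEVERE


@dataclass(frozen=True, order=True)
class PatientAttributes:
    """One patient's state attributes, the decoded form of a state code."""

    age_band: int
    history: int
    complication: int
    diagnosis: int
    syndrome: int
    level: int

    def __post_init__(self):
        for name in STATE_FIELDS:
            value = _as_int(getattr(self, name), name)
            object.__setattr__(self, name, value)
            if value not in ATTRIBUTE_DOMAINS[name]:
                raise ValueError(
                    f"{name} must be one of {ATTRIBUTE_DOMAINS[name]}, got {value}"
                )

    def as_tuple(self) -> tuple[int, int, int, int, int, int]:
        return tuple(getattr(self, name) for name in STATE_FIELDS)

    @property
    def band(self) -> str:
        return severity_band(self.level)


def encode_state(attrs: PatientAttributes) -> str:
    """Serialise attributes to the six-digit state code, digits in i1..i6 order."""
    if not isinstance(attrs, PatientAttributes):
        attrs = PatientAttributes(*attrs)
    return "".join(str(d) for d in attrs.as_tuple())


def decode_state(code: str) -> PatientAttributes:
    """Parse a six-digit state code back into :class:`PatientAttributes`."""
    if not isinstance(code, str):
        raise ValueError(f"state code must be a string, got {code!r}")
    if len(code) != 6 or not code.isdigit():
        raise ValueError(f"state code must be six digits, got {code!r}")
    try:
        return PatientAttributes(*(int(c) for c in code))
    except ValueError as exc:
        raise ValueError(f"invalid state code {code!r}: {exc}") from None


def encode_action(rehab, herbal, acupuncture) -> str:
    """Serialise the three treatment flags to a three-bit action code a1a2a3."""
    bits = []
    for name, flag in zip(ACTION_FIELDS, (rehab, herbal, acupuncture)):
        value = _as_int(flag, name)
        if value not in (0, 1):
            raise ValueError(f"{name} must be 0 or 1, got {value}")
        bits.append(str(value))
    return "".join(bits)


def decode_action(code: str) -> tuple[int, int, int]:
    """Parse a three-bit action code into its (a1, a2, a3) flags."""
    if not isinstance(code, str) or code not in ACTION_CODES:
        raise ValueError(f"action code must be one of {ACTION_CODES}, got {code!r}")
    return tuple(int(c) for c in code)


def compute_reward(score_before, score_after) -> int:
    """Reward of one epoch: score before minus score after (positive = improved)."""
    before = check_score(score_before, "score_before")
    after = check_score(score_after, "score_after")
    return before - after


def iter_states() -> Iterator[str]:
    """Enumerate all 900 syntactically valid state codes in lexicographic order."""
    def rec(prefix: str, fields: tuple[str, ...]) -> Iterator[str]:
        if not fields:
            yield prefix
            return
        for cat in ATTRIBUTE_DOMAINS[fields[0]]:
            yield from rec(prefix + str(cat), fields[1:])

    yield from rec("", STATE_FIELDS)
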