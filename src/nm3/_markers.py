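"""Typed sentinels for quantities that are undefined or unscorable.

A near-miss-to-harm ratio with zero harm events, or a learning yield with an
empty denominator, is *undefined* — not infinite, not zero, not an error.
These sentinels let such results flow through reports and serializers
without being mistaken for numbers.
"""

from __future__ import annotations


class _Marker:
    __slots__ = ("_label",)

    def __init__(self, label: str) -> None:
        self._label = label

    def __repr__(self) -> str:
        return self._label

    def __bool__(self) -> bool:
        return False

    def __deepcopy__(self, memo):  # singletons survive copying
        return self

    def __copy__(self):
        return self


#: Result of a division whose denominator is zero (e.g. ratio with no harm events).
UNDEFINED = _Marker("undefined")

#: Result of scoring an event that carries no severity class.
UNSCORED = _Marker("unscored")


def is_undefined(value: object) -> bool:
    return value is UNDEFINED


def is_unscored(value: object) -> bool:
    return value is UNSCORED
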