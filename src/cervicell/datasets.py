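"""Bundled reference data.

``load_grading_example`` returns the detected-versus-reviewed grade
assignments for the published 34-cell clinical evaluation set that the
grading rules were validated on (sample ids 1-34).  Exact-match accuracy on
this set is 26/34.
"""

from __future__ import annotations

from .decision import Grade

__all__ = ["load_grading_example"]

_DETECTED = {
    Grade.LSIL: (5, 17, 18, 19, 20, 21, 22, 31, 32, 33),
    Grade.HSIL: (1, 3, 6, 7, 8, 11, 12, 13, 15, 16, 26, 30),
    Grade.SCC: (2, 4, 9, 10, 14, 23, 24, 25, 27, 28, 29, 34),
}

_ACTUAL = {
    Grade.LSIL: (17, 18, 19, 20, 21, 22, 30, 31, 32, 33),
    Grade.HSIL: tuple(range(1, 17)),
    Grade.SCC: (23, 24, 25, 26, 27, 28, 29, 34),
}


def load_grading_example() -> tuple[dict[int, Grade], dict[int, Grade]]:
    """Return ``(detected, actual)`` grade maps keyed by sample id."""
    detected = {sid: g for g, ids in _DETECTED.items() for sid in ids}
    actual = {sid: g for g, ids in _ACTUAL.items() for sid in ids}
    assert set(detected) == set(actual) == set(range(1, 35))
    return detected, actual
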