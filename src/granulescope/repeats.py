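"""Tandem-repeat composition arithmetic for low-complexity protein domains.

AlgP, the histone-H1-like DNA-binding protein of *P. aeruginosa*, carries a
C-terminal domain dominated by tandem "KPAA" repeats and close variants.
The contiguous repeat region is described by a composition — how many copies
of each repeat unit it contains — and its length is the sum of copy counts
times unit lengths.
"""

from __future__ import annotations

from collections.abc import Mapping

#: Composition of the contiguous KPAA-repeat region of the AlgP C-terminal
#: domain: 25 perfect KPAA repeats interspersed with 7 KPVA, 4 KTAAA, one
#: KPAV, and two single-alanine spacers.  Two further KPAA repeats fall
#: outside this contiguous region and are not part of the composition.
ALGP_REPEAT_COMPOSITION: dict[str, int] = {
    "KPAA": 25,
    "KPVA": 7,
    "KTAAA": 4,
    "KPAV": 1,
    "A": 2,
}


def repeat_region_length(composition: Mapping[str, int]) -> int:
    """Total amino-acid length of a tandem-repeat region.

    Parameters
    ----------
    composition
        Mapping from repeat-unit sequence (one-letter amino-acid codes) to
        its copy number.

    Returns
    -------
    int
        Sum over units of ``copies * len(unit)``.

    Examples
    --------
    >>> repeat_region_length({"KPAA": 2, "A": 1})
    9
    >>> repeat_region_length(ALGP_REPEAT_COMPOSITION)
    154
    """
    for unit, copies in composition.items():
        if not unit:
            raise ValueError("empty repeat unit")
        if copies < 0:
            raise ValueError(f"negative copy number for unit {unit!r}")
    return sum(copies * len(unit) for unit, copies in composition.items())


def count_repeat_units(sequence: str, unit: str) -> int:
    """Count non-overlapping occurrences of a repeat unit in a sequence."""
    if not unit:
        raise ValueError("empty repeat unit")
    return sequence.upper().count(unit.upper())
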