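"""Rule-based surrogate of the visual read: diffuse-uptake grade and group A/B/C.

The grade compares a bone-marrow reference SUV (iliac/lumbar surrogate)
against liver uptake; the group combines focal-lesion count and grade:

* A — no focal lesions and negative/mild diffuse uptake (below liver);
* B — 1-3 focal lesions and/or moderate diffuse uptake (> 1.1 x liver);
* C — > 3 focal lesions and/or intense diffuse uptake (> 2 x liver).

Boundary resolution: marrow uptake in ``(1.0, 1.1] x liver`` falls in a gap
between the printed bins and is graded ``negative_mild`` here (configurable
via ``moderate_factor``).
"""

from __future__ import annotations

from bmquant.refinement import LesionComponent

__all__ = ["GRADES", "GROUPS", "grade_diffuse", "assign_group", "count_focal_surrogate"]

GRADES = ("negative_mild", "moderate", "intense")
GROUPS = ("A", "B", "C")


def grade_diffuse(
    bm_suv: float,
    liver_suv: float,
    moderate_factor: float = 1.1,
    intense_factor: float = 2.0,
) -> str:
    """Grade diffuse marrow uptake against the liver reference."""
    if liver_suv <= 0:
        raise ValueError("liver reference SUV must be > 0")
    if bm_suv > intense_factor * liver_suv:
        return "intense"
    if bm_suv > moderate_factor * liver_suv:
        return "moderate"
    return "negative_mild"


def assign_group(n_focal: int, grade: str) -> str:
    """Combine focal-lesion count and diffuse grade into group A, B or C."""
    if n_focal < 0:
        raise ValueError("focal lesion count must be >= 0")
    if grade not in GRADES:
        raise ValueError(f"unknown grade {grade!r}; expected one of {GRADES}")
    if n_focal > 3 or grade == "intense":
        return "C"
    if n_focal >= 1 or grade == "moderate":
        return "B"
    return "A"


def count_focal_surrogate(components: list[LesionComponent]) -> int:
    """Number of surviving refined components, standing in for the visual lesion count."""
    return len(components)
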