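"""Neck Type assignment and morphology inference.

Four neck architectures (Types) are defined by which Type-specific
connection families a phage carries: Type 1 (SPP1-like: Ad1, Hc1, Tc1,
plus Ne1 and the gpW adaptor replacement), Type 2 (T4-like: Ad2, Hc2,
Tc2), Type 3 (P22-like: Ad3, Hc3) and Type 4 (Phi29-like: Ad4). The
morphological family then follows from the Type and the presence of a
contractile sheath: Type 1 phages are Siphoviridae (no sheath) or
Myoviridae (sheath); Type 2 are Myoviridae; Types 3 and 4 are
Podoviridae.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

from .detection import NECK_CLASSES_BY_TYPE, DetectionTable, ProteinClass

__all__ = ["NeckAssignment", "assign_neck_type", "infer_morphology"]

#: minimum number of detected connection proteins required to classify
MIN_EVIDENCE = {1: 2, 2: 2, 3: 1, 4: 1}

#: classes expected per Type for the completeness display (Type 1
#: includes Ne1: the canonical module is Ad1-Hc1-Ne1-Tc1)
EXPECTED_CLASSES = {
    1: (ProteinClass.Ad1, ProteinClass.Hc1, ProteinClass.Ne1, ProteinClass.Tc1),
    2: NECK_CLASSES_BY_TYPE[2],
    3: NECK_CLASSES_BY_TYPE[3],
    4: NECK_CLASSES_BY_TYPE[4],
}

TYPE1_LIKE = "type1_like"
UNASSIGNED = "unassigned"


@dataclass
class NeckAssignment:
    """Type and morphology assignment for one phage."""

    phage_id: str
    neck_type: Union[int, str]  # 1-4, "type1_like" or "unassigned"
    evidence: list[tuple[ProteinClass, str, float]] = field(default_factory=list)
    morphology: str = "undetermined"
    completeness: float = 0.0
    diagnostics: list[str] = field(default_factory=list)

    @property
    def classified(self) -> bool:
        return isinstance(self.neck_type, int)


def _evidence_for_type(
    classes: dict[ProteinClass, "DetectionEntry"],  # noqa: F821
    neck_type: int,
) -> list[ProteinClass]:
    """Connection classes counting toward the Type's evidence minimum.

    gpW fills the Ad1 slot for Type 1 evidence counting; Ne1 counts
    toward the completeness display but not toward the minimum (the
    minimum-evidence rule predates Ne1's inclusion in the module).
    """
    present = [c for c in NECK_CLASSES_BY_TYPE[neck_type] if c in classes]
    if neck_type == 1 and ProteinClass.Ad1 not in classes and ProteinClass.gpW in classes:
        present.append(ProteinClass.gpW)
    return present


def assign_neck_type(detections: DetectionTable, phage_id: str) -> NeckAssignment:
    """Assign a neck Type from the detected connection classes of one phage.

    The Type with the most detected Type-specific classes wins, subject
    to the minimum-evidence rule (at least two connection proteins for
    Types 1 and 2, one for Types 3 and 4). A phage whose only Type 1
    evidence is an Ad1 is reported ``type1_like`` (recognized but not
    clusterable). Evidence spread over several Types is resolved by
    majority; a tie yields ``unassigned`` with a diagnostic.
    """
    classes = detections.classes_of(phage_id)
    assignment = NeckAssignment(phage_id, UNASSIGNED)

    counts: dict[int, list[ProteinClass]] = {
        t: _evidence_for_type(classes, t) for t in NECK_CLASSES_BY_TYPE
    }
    candidates = {t: ev for t, ev in counts.items() if ev}
    if not candidates:
        assignment.diagnostics.append("no head-to-tail connection protein detected")
        return assignment

    best_n = max(len(ev) for ev in candidates.values())
    leaders = sorted(t for t, ev in candidates.items() if len(ev) == best_n)
    if len(leaders) > 1:
        assignment.diagnostics.append(
            f"conflicting Type evidence (tie between Types {leaders}); "
            "majority rule could not decide — left unassigned "
            "(precedence between co-occurring Types is a heuristic)"
        )
        return assignment
    neck_type = leaders[0]
    if len(candidates) > 1:
        others = {t: [str(c) for c in ev] for t, ev in candidates.items() if t != neck_type}
        assignment.diagnostics.append(
            f"evidence from multiple Types {others}; assigned Type "
            f"{neck_type} by majority (heuristic rule)"
        )

    evidence_classes = counts[neck_type]
    if len(evidence_classes) < MIN_EVIDENCE[neck_type]:
        if neck_type == 1 and evidence_classes == [ProteinClass.Ad1]:
            assignment.neck_type = TYPE1_LIKE
            assignment.diagnostics.append(
                "only an Ad1 component identified: Type 1-like, not clusterable"
            )
        else:
            assignment.diagnostics.append(
                f"insufficient evidence for Type {neck_type}: "
                f"{len(evidence_classes)} < {MIN_EVIDENCE[neck_type]} "
                "connection proteins"
            )
            return assignment
    else:
        assignment.neck_type = neck_type

    display = list(evidence_classes)
    if neck_type == 1 and ProteinClass.Ne1 in classes:
        display.append(ProteinClass.Ne1)
    assignment.evidence = [
        (c, classes[c].protein_id, classes[c].probability) for c in display
    ]
    expected = EXPECTED_CLASSES[neck_type]
    n_slots = sum(
        1 for c in expected
        if c in classes or (c is ProteinClass.Ad1 and ProteinClass.gpW in classes)
    )
    assignment.completeness = n_slots / len(expected)
    return assignment


def infer_morphology(
    assignment: NeckAssignment, has_sheath: bool
) -> NeckAssignment:
    """Deduce the morphological family from the Type and sheath presence.

    Type 1 with a sheath is Myoviridae, without one Siphoviridae; Type 2
    is Myoviridae; Types 3 and 4 are Podoviridae (a detected sheath there
    is contradictory and is reported as a diagnostic, morphology stays
    Podoviridae). Unassigned phages are undetermined.
    """
    t = assignment.neck_type
    if t == 1 or t == TYPE1_LIKE:
        assignment.morphology = "Myoviridae" if has_sheath else "Siphoviridae"
    elif t == 2:
        assignment.morphology = "Myoviridae"
    elif t in (3, 4):
        assignment.morphology = "Podoviridae"
        if has_sheath:
            assignment.diagnostics.append(
                f"contradiction: Type {t} (Podoviridae) phage with a "
                "detected Sheath protein"
            )
    else:
        assignment.morphology = "undetermined"
    return assignment
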