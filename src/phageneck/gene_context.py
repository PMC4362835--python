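"""Gene-context learning and the context-constrained relaxed search.

Head-to-tail connection genes sit at strongly conserved relative
positions in phage genomes. This module first *learns* those positions
from the strictly detected proteins (per neck Type, the mean and standard
deviation of the signed inter-gene distance for every ordered class
pair; the tolerated distance is mean + 2*SD), then re-runs the iterative
homology expansion at a relaxed probability threshold (70%) and accepts a
candidate only when its genomic position is consistent with the tolerated
distance matrix relative to every already-detected partner.

Two special detections complete the Type 1 picture: the lambda-like gpW
adaptor replacement (95% threshold plus a fixed positional window) and
the Ne1 superfamily (strict-probability anywhere, or relaxed probability
strictly between Hc1 and Tc1). Proteins whose profiles were built from
fewer than 5 sequences are never auto-accepted; when they occupy the
canonical position of a missing class they are flagged for human review.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import sqrt
from pathlib import Path
from typing import Mapping, Optional, Union

import yaml

from .detection import (
    NECK_CLASSES_BY_TYPE,
    DetectionEntry,
    DetectionTable,
    ExpansionResult,
    ProteinClass,
    SeedSet,
    iterative_expand,
)
from .genome_io import PhageGenome, intergene_distance
from .homology import HomologyProvider, ProfileMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "PairStats",
    "DistanceModel",
    "learn_distance_model",
    "constrained_relaxed_search",
    "detect_gpW",
    "detect_ne1",
    "FlaggedCandidate",
    "flag_low_support_candidates",
    "dump_distance_model",
    "load_distance_model",
]

#: profiles with fewer source sequences than this are "low support"
LOW_SUPPORT_CUTOFF = 5


@dataclass(frozen=True)
class PairStats:
    """Distance statistics for one ordered class pair."""

    mean: float
    sd: float
    tolerated: float  # mean + 2*sd, kept real-valued
    n_observations: int

    def __post_init__(self) -> None:
        if self.n_observations < 1:
            raise ValueError("n_observations must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class DistanceModel:
    """Learned inter-gene distance model for one neck Type.

    ``pairs`` holds statistics for ordered class pairs in canonical gene
    order (earlier class first), so means are positive for canonical
    arrangements. Pairs never observed together are absent.
    """

    neck_type: int
    pairs: dict[tuple[ProteinClass, ProteinClass], PairStats] = field(default_factory=dict)

    def stats(self, a: ProteinClass, b: ProteinClass) -> Optional[PairStats]:
        """Stats for the (a, b) pair in canonical order, if learned."""
        return self.pairs.get((a, b))

    @property
    def classes(self) -> tuple[ProteinClass, ...]:
        return NECK_CLASSES_BY_TYPE[self.neck_type]

    def canonical_index(self, cls: ProteinClass) -> int:
        return self.classes.index(cls)


def _ordered_pairs(neck_type: int):
    classes = NECK_CLASSES_BY_TYPE[neck_type]
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            yield a, b


def learn_distance_model(
    detections: DetectionTable,
    genomes: Mapping[str, PhageGenome],
    neck_type: int,
) -> DistanceModel:
    """Learn mean/SD/tolerated inter-gene distances from strict detections.

    For each ordered class pair of the Type, the signed rank distance is
    collected over every genome carrying both detections; the tolerated
    distance is mean + 2*SD (sample SD, ddof=1; a single observation
    gives SD 0 so tolerated equals the mean). A pair observed in no
    genome is skipped with a warning.
    """
    if neck_type not in NECK_CLASSES_BY_TYPE:
        raise ValueError(f"unknown neck type {neck_type}")
    model = DistanceModel(neck_type)
    for a, b in _ordered_pairs(neck_type):
        dists: list[int] = []
        for phage_id, genome in genomes.items():
            ea, eb = detections.get(phage_id, a), detections.get(phage_id, b)
            if ea is None or eb is None:
                continue
            dists.append(intergene_distance(genome, ea.protein_id, eb.protein_id))
        if not dists:
            logger.warning(
                "no genome carries both %s and %s; (%s,%s) constraint unavailable",
                a, b, a, b,
            )
            continue
        n = len(dists)
        mean = sum(dists) / n
        sd = 0.0 if n == 1 else sqrt(sum((d - mean) ** 2 for d in dists) / (n - 1))
        model.pairs[(a, b)] = PairStats(mean, sd, mean + 2 * sd, n)
    return model


def _position_consistent(
    genome: PhageGenome,
    candidate_protein: str,
    candidate_cls: ProteinClass,
    partners: Mapping[ProteinClass, DetectionEntry],
    model: DistanceModel,
    require_sign: bool = True,
) -> bool:
    """True when the candidate satisfies every available pairwise constraint.

    For each detected partner, the signed distance (in canonical pair
    order) must be positive (canonical direction, unless ``require_sign``
    is off) and of magnitude at most the tolerated distance.
    """
    i_cand = model.canonical_index(candidate_cls)
    checked = 0
    for p_cls, p_entry in partners.items():
        if p_cls == candidate_cls or p_cls not in model.classes:
            continue
        i_part = model.canonical_index(p_cls)
        if i_part < i_cand:
            key, d = (p_cls, candidate_cls), intergene_distance(
                genome, p_entry.protein_id, candidate_protein)
        else:
            key, d = (candidate_cls, p_cls), intergene_distance(
                genome, candidate_protein, p_entry.protein_id)
        stats = model.pairs.get(key)
        if stats is None:
            continue  # pair never learned: constraint unavailable
        if require_sign and d <= 0:
            return False
        if abs(d) > stats.tolerated:
            return False
        checked += 1
    return checked > 0


def constrained_relaxed_search(
    seeds: SeedSet,
    provider: HomologyProvider,
    model: DistanceModel,
    detections: DetectionTable,
    genomes: Mapping[str, PhageGenome],
    relaxed_threshold: float = 70.0,
    strict_threshold: float = 90.0,
    require_sign: bool = True,
) -> DetectionTable:
    """Relaxed-threshold expansion gated by the tolerated distance matrix.

    The iterative expansion is repeated at ``relaxed_threshold`` for the
    model's connection classes; a new candidate is accepted only if, for
    every already-detected partner class in the same phage, its signed
    inter-gene distance is canonical in direction and within the
    tolerated distance. Phages with no strict anchor cannot validate a
    candidate, which is then rejected and logged. Accepted entries carry
    round ``relaxed70``. Returns the updated table (mutated in place).
    """
    if relaxed_threshold >= strict_threshold:
        raise ValueError("relaxed threshold must be below the strict threshold")
    protein_to_phage = {
        pid: g.phage_id for g in genomes.values() for pid in g.protein_ids
    }
    classes = [c for c in model.classes if c in seeds.classes()]
    expanded = iterative_expand(
        seeds, provider, relaxed_threshold, classes=classes, strict_seeds=False
    )
    for cls in classes:
        res = expanded.get(cls)
        if res is None:
            continue
        for pid in sorted(res.members):
            prob = res.members[pid]
            phage_id = protein_to_phage.get(pid)
            if phage_id is None:
                continue
            existing = detections.classes_of(phage_id)
            if any(e.protein_id == pid for e in existing.values()):
                continue  # already detected (possibly under another class)
            partners = {
                c: e for c, e in existing.items()
                if c in model.classes and c != cls
            }
            if not partners:
                detections.diagnostics.append(
                    f"relaxed candidate {pid} ({cls}, {prob:.1f}%) in "
                    f"{phage_id} rejected: no strict anchor to validate against"
                )
                continue
            genome = genomes[phage_id]
            if _position_consistent(genome, pid, cls, partners, model, require_sign):
                detections.add(
                    phage_id, cls,
                    DetectionEntry(pid, prob, "relaxed70", res.chains.get(pid, ())),
                )
            else:
                detections.diagnostics.append(
                    f"relaxed candidate {pid} ({cls}, {prob:.1f}%) in "
                    f"{phage_id} rejected: position inconsistent with the "
                    "tolerated distance matrix"
                )
    return detections


def detect_gpW(
    provider: HomologyProvider,
    detections: DetectionTable,
    genomes: Mapping[str, PhageGenome],
    seeds: SeedSet,
    gpw_threshold: float = 95.0,
    hc1_window: tuple[int, int] = (6, 7),
    tc1_distance: int = 9,
    tc1_tolerance: int = 1,
) -> DetectionTable:
    """Detect the lambda-like gpW adaptor replacement.

    Applies only to phages carrying Hc1 and Tc1 but no Ad1. A gpW-family
    hit at >= 95% probability is accepted when the candidate lies 6 to 7
    genes upstream of Hc1 and 9 (+/- 1) genes upstream of Tc1. The phage
    remains Type 1: gpW occupies the adaptor slot.
    """
    targets = [
        pid for pid in detections.phages()
        if detections.has(pid, ProteinClass.Hc1)
        and detections.has(pid, ProteinClass.Tc1)
        and not detections.has(pid, ProteinClass.Ad1)
        and not detections.has(pid, ProteinClass.gpW)
    ]
    if not targets:
        return detections
    expanded = iterative_expand(
        seeds, provider, gpw_threshold,
        classes=[ProteinClass.gpW], strict_seeds=False,
    )
    res = expanded.get(ProteinClass.gpW)
    if res is None:
        return detections
    protein_to_phage = {
        pid: g.phage_id for g in genomes.values() for pid in g.protein_ids
    }
    lo, hi = hc1_window
    for pid in sorted(res.members):
        phage_id = protein_to_phage.get(pid)
        if phage_id not in targets:
            continue
        genome = genomes[phage_id]
        hc1 = detections.get(phage_id, ProteinClass.Hc1).protein_id
        tc1 = detections.get(phage_id, ProteinClass.Tc1).protein_id
        d_hc1 = intergene_distance(genome, pid, hc1)
        d_tc1 = intergene_distance(genome, pid, tc1)
        if lo <= d_hc1 <= hi and abs(d_tc1 - tc1_distance) <= tc1_tolerance:
            detections.add(
                phage_id, ProteinClass.gpW,
                DetectionEntry(pid, res.members[pid], "gpw95",
                               res.chains.get(pid, ())),
            )
        else:
            detections.diagnostics.append(
                f"gpW candidate {pid} in {phage_id} rejected: distances "
                f"to Hc1 ({d_hc1}) / Tc1 ({d_tc1}) outside the canonical "
                f"window ({lo}-{hi} / {tc1_distance}+/-{tc1_tolerance})"
            )
    return detections


def detect_ne1(
    provider: HomologyProvider,
    detections: DetectionTable,
    genomes: Mapping[str, PhageGenome],
    seeds: SeedSet,
    strict_threshold: float = 90.0,
    relaxed_threshold: float = 70.0,
) -> DetectionTable:
    """Detect the Ne1 (SPP1 gp16.1-like) neck gene of Type 1 phages.

    Eligible phages carry at least one Type 1 connection class. An Ne1
    homolog is accepted at strict probability regardless of position, or
    at relaxed probability when its gene lies strictly between the Hc1
    and Tc1 genes (the canonical Ad1-Hc1-Ne1-Tc1 slot).
    """
    expanded = iterative_expand(
        seeds, provider, relaxed_threshold,
        classes=[ProteinClass.Ne1], strict_seeds=False,
    )
    res = expanded.get(ProteinClass.Ne1)
    if res is None:
        return detections
    protein_to_phage = {
        pid: g.phage_id for g in genomes.values() for pid in g.protein_ids
    }
    type1_classes = (ProteinClass.Ad1, ProteinClass.Hc1,
                     ProteinClass.Tc1, ProteinClass.gpW)
    for pid in sorted(res.members):
        prob = res.members[pid]
        phage_id = protein_to_phage.get(pid)
        if phage_id is None:
            continue
        existing = detections.classes_of(phage_id)
        if not any(c in existing for c in type1_classes):
            continue  # not a Type 1(-assignable) phage
        if any(e.protein_id == pid for e in existing.values()):
            continue
        if prob >= strict_threshold:
            detections.add(
                phage_id, ProteinClass.Ne1,
                DetectionEntry(pid, prob, "strict90", res.chains.get(pid, ())),
            )
            continue
        hc1, tc1 = existing.get(ProteinClass.Hc1), existing.get(ProteinClass.Tc1)
        if hc1 is None or tc1 is None:
            continue
        genome = genomes[phage_id]
        rank = genome.rank_of(pid)
        lo = genome.rank_of(hc1.protein_id)
        hi = genome.rank_of(tc1.protein_id)
        if lo > hi:
            lo, hi = hi, lo
        if lo < rank < hi:
            detections.add(
                phage_id, ProteinClass.Ne1,
                DetectionEntry(pid, prob, "relaxed70", res.chains.get(pid, ())),
            )
        else:
            detections.diagnostics.append(
                f"Ne1 candidate {pid} ({prob:.1f}%) in {phage_id} rejected: "
                f"rank {rank} not strictly between Hc1 and Tc1"
            )
    return detections


@dataclass(frozen=True)
class FlaggedCandidate:
    """A low-support protein at the canonical position of a missing class.

    Never auto-accepted: surfaced for human review only (round
    ``flagged``).
    """

    phage_id: str
    cls: ProteinClass
    protein_id: str
    n_aligned_sequences: int


def flag_low_support_candidates(
    metadata: Mapping[str, ProfileMetadata],
    model: DistanceModel,
    detections: DetectionTable,
    genomes: Mapping[str, PhageGenome],
    require_sign: bool = True,
) -> list[FlaggedCandidate]:
    """Flag low-support proteins occupying the slot of a missing class.

    For phages of the model's Type lacking exactly one connection class,
    any undetected protein whose profile was built from fewer than 5
    source sequences and whose rank is consistent with the tolerated
    matrix for the missing class is flagged for manual review.
    """
    flagged: list[FlaggedCandidate] = []
    for phage_id in detections.phages():
        existing = detections.classes_of(phage_id)
        present = [c for c in model.classes if c in existing]
        missing = [c for c in model.classes if c not in existing]
        if len(missing) != 1 or not present:
            continue
        miss = missing[0]
        if miss is ProteinClass.Ad1 and ProteinClass.gpW in existing:
            continue  # adaptor slot already filled by gpW
        genome = genomes[phage_id]
        detected_ids = {e.protein_id for e in existing.values()}
        partners = {c: existing[c] for c in present}
        for protein in genome.proteins:
            pid = protein.protein_id
            if pid in detected_ids:
                continue
            meta = metadata.get(pid)
            if meta is None or meta.n_aligned_sequences >= LOW_SUPPORT_CUTOFF:
                continue
            if _position_consistent(genome, pid, miss, partners, model, require_sign):
                flagged.append(
                    FlaggedCandidate(phage_id, miss, pid, meta.n_aligned_sequences)
                )
                detections.diagnostics.append(
                    f"low-support candidate {pid} flagged as possible {miss} "
                    f"in {phage_id} (profile built from "
                    f"{meta.n_aligned_sequences} sequences); needs review"
                )
    return flagged


def dump_distance_model(
    models: Union[DistanceModel, list[DistanceModel]],
    path: Union[str, Path],
) -> None:
    """Serialize one or several distance models to YAML."""
    if isinstance(models, DistanceModel):
        models = [models]
    doc = {}
    for m in models:
        doc[f"type{m.neck_type}"] = {
            f"{a}-{b}": {
                "mean": float(s.mean),
                "sd": float(s.sd),
                "tolerated": float(s.tolerated),
                "n": int(s.n_observations),
            }
            for (a, b), s in m.pairs.items()
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_distance_model(path: Union[str, Path]) -> dict[int, DistanceModel]:
    """Load distance models from YAML, keyed by neck Type."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    out: dict[int, DistanceModel] = {}
    for key, pairs in doc.items():
        neck_type = int(key.removeprefix("type"))
        model = DistanceModel(neck_type)
        for pair_key, s in (pairs or {}).items():
            a, b = pair_key.split("-")
            model.pairs[(ProteinClass(a), ProteinClass(b))] = PairStats(
                float(s["mean"]), float(s["sd"]), float(s["tolerated"]), int(s["n"])
            )
        out[neck_type] = model
    return out
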