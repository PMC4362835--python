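"""Iterative remote-homology expansion from reference seeds.

The first detection pass starts from functionally characterized reference
proteins (the seed set) and expands each protein class by breadth-first
transitive closure over profile-profile hits at a strict probability
threshold (90% by default): every newly accepted protein is re-used as a
probe until a fixed point. Head and tail classes (MCP, TermL, Portal,
MTP, Sheath) are detected with this strict pass only; the relaxed,
gene-context-constrained pass for the head-to-tail connection classes
lives in :mod:`phageneck.gene_context`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from .homology import HomologyProvider

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinClass",
    "SeedSet",
    "DEFAULT_SEEDS",
    "DetectionEntry",
    "DetectionTable",
    "ExpansionResult",
    "iterative_expand",
    "resolve_class_conflicts",
    "NECK_CLASSES_BY_TYPE",
    "STRICT_ONLY_CLASSES",
    "CONNECTION_CLASSES",
]


class ProteinClass(str, Enum):
    """The protein superfamilies of the head-neck-tail module.

    Nine module superfamilies — head: major capsid protein and large
    terminase; neck: Portal plus the adaptor (Ad), head-closure (Hc),
    tail-completion (Tc) and Ne1 connection families; tail: major tail
    protein and sheath. The Ad/Hc/Tc families are refined into
    Type-specific subclasses (suffix 1-4 for SPP1-, T4-, P22- and
    Phi29-like necks), and gpW is the lambda-like adaptor replacement.
    """

    MCP = "MCP"
    TermL = "TermL"
    Portal = "Portal"
    MTP = "MTP"
    Sheath = "Sheath"
    Ad1 = "Ad1"
    Hc1 = "Hc1"
    Tc1 = "Tc1"
    Ne1 = "Ne1"
    gpW = "gpW"
    Ad2 = "Ad2"
    Hc2 = "Hc2"
    Tc2 = "Tc2"
    Ad3 = "Ad3"
    Hc3 = "Hc3"
    Ad4 = "Ad4"

    def __str__(self) -> str:  # keep TSV output plain
        return self.value


#: strict-pass-only classes (no relaxed/context pass)
STRICT_ONLY_CLASSES = frozenset(
    {ProteinClass.MCP, ProteinClass.TermL, ProteinClass.Portal,
     ProteinClass.MTP, ProteinClass.Sheath}
)

#: head-to-tail connection classes, by neck Type
NECK_CLASSES_BY_TYPE: dict[int, tuple[ProteinClass, ...]] = {
    1: (ProteinClass.Ad1, ProteinClass.Hc1, ProteinClass.Tc1),
    2: (ProteinClass.Ad2, ProteinClass.Hc2, ProteinClass.Tc2),
    3: (ProteinClass.Ad3, ProteinClass.Hc3),
    4: (ProteinClass.Ad4,),
}

#: every class subject to the single-copy control
CONNECTION_CLASSES = frozenset(
    c for classes in NECK_CLASSES_BY_TYPE.values() for c in classes
) | {ProteinClass.Ne1, ProteinClass.gpW}


@dataclass(frozen=True)
class SeedSet:
    """Mapping from protein class to reference seed protein ids.

    Every class must have at least one seed and no protein may seed two
    classes.
    """

    seeds: Mapping[ProteinClass, tuple[str, ...]]

    def __post_init__(self) -> None:
        seen: dict[str, ProteinClass] = {}
        for cls, ids in self.seeds.items():
            if not ids:
                raise ValueError(f"class {cls} has no seeds")
            for pid in ids:
                if pid in seen:
                    raise ValueError(
                        f"protein {pid!r} seeds both {seen[pid]} and {cls}"
                    )
                seen[pid] = cls

    def __getitem__(self, cls: ProteinClass) -> tuple[str, ...]:
        return tuple(self.seeds[cls])

    def classes(self) -> list[ProteinClass]:
        return list(self.seeds)

    def restrict(self, classes: Iterable[ProteinClass]) -> "SeedSet":
        keep = set(classes)
        return SeedSet({c: ids for c, ids in self.seeds.items() if c in keep})


#: default seeds: the functionally characterized reference proteins of
#: SPP1, lambda, HK97, T4, P22 and Phi29 (head-to-tail connection) plus
#: the structure-based head/tail seeds
DEFAULT_SEEDS = SeedSet({
    ProteinClass.MCP: ("HK97_gp5", "T4_gp23"),
    ProteinClass.TermL: ("SPP1_gp2", "T4_gp17"),
    ProteinClass.Portal: ("SPP1_gp6", "P22_gp1", "Phi29_gp10"),
    ProteinClass.MTP: ("Lambda_gpV", "T4_gp19"),
    ProteinClass.Sheath: ("T4_gp18", "PhiKZ_sheath"),
    ProteinClass.Ad1: ("SPP1_gp15", "HK97_gp6"),
    ProteinClass.Hc1: ("SPP1_gp16",),
    ProteinClass.Tc1: ("SPP1_gp17",),
    ProteinClass.Ne1: ("SPP1_gp16.1",),
    ProteinClass.gpW: ("Lambda_gpW",),
    ProteinClass.Ad2: ("T4_gp13",),
    ProteinClass.Hc2: ("T4_gp14",),
    ProteinClass.Tc2: ("T4_gp15",),
    ProteinClass.Ad3: ("P22_gp4",),
    ProteinClass.Hc3: ("P22_gp10",),
    ProteinClass.Ad4: ("Phi29_gp11",),
})


@dataclass
class DetectionEntry:
    """Accepted protein for one (phage, class) cell."""

    protein_id: str
    probability: float
    round: str  # strict90 | relaxed70 | flagged
    chain: tuple[str, ...] = ()


@dataclass
class DetectionTable:
    """Per-phage, per-class detection results with provenance.

    At most one accepted protein per (phage, class); inserting a second
    candidate keeps the higher probability and, for connection classes,
    records a single-copy-control diagnostic.
    """

    entries: dict[tuple[str, ProteinClass], DetectionEntry] = field(default_factory=dict)
    diagnostics: list[str] = field(default_factory=list)

    def add(self, phage_id: str, cls: ProteinClass, entry: DetectionEntry) -> bool:
        """Insert; returns True if the entry now occupies the cell."""
        key = (phage_id, cls)
        prev = self.entries.get(key)
        if prev is None:
            self.entries[key] = entry
            return True
        if prev.protein_id == entry.protein_id:
            if entry.probability > prev.probability:
                self.entries[key] = entry
            return True
        if cls in CONNECTION_CLASSES:
            self.diagnostics.append(
                f"multiple {cls} in {phage_id}: {prev.protein_id} "
                f"({prev.probability:.1f}) vs {entry.protein_id} "
                f"({entry.probability:.1f}); keeping best "
                "(single-copy control violation)"
            )
        if (entry.probability, prev.protein_id) > (prev.probability, entry.protein_id):
            self.entries[key] = entry
            return True
        return False

    def get(self, phage_id: str, cls: ProteinClass) -> Optional[DetectionEntry]:
        return self.entries.get((phage_id, cls))

    def has(self, phage_id: str, cls: ProteinClass) -> bool:
        return (phage_id, cls) in self.entries

    def classes_of(self, phage_id: str) -> dict[ProteinClass, DetectionEntry]:
        return {
            cls: e for (pid, cls), e in self.entries.items() if pid == phage_id
        }

    def phages(self) -> list[str]:
        return sorted({pid for pid, _ in self.entries})

    def copy(self) -> "DetectionTable":
        return DetectionTable(dict(self.entries), list(self.diagnostics))

    def to_frame(self):
        import pandas as pd

        rows = [
            (pid, str(cls), e.protein_id, round(e.probability, 2), e.round,
             ";".join(e.chain))
            for (pid, cls), e in sorted(
                self.entries.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))
            )
        ]
        return pd.DataFrame(
            rows,
            columns=["phage_id", "class", "protein_id", "probability",
                     "round", "chain"],
        )


@dataclass
class ExpansionResult:
    """Per-class closure of the hit graph above a threshold.

    ``members`` maps each accepted protein to its accepting probability
    (maximum over probes that reached it; seeds carry 100) and
    ``chains`` to the probe path from a seed.
    """

    cls: ProteinClass
    members: dict[str, float]
    chains: dict[str, tuple[str, ...]]
    seeds_used: tuple[str, ...]


def _expand_one_class(
    cls: ProteinClass,
    seed_ids: Sequence[str],
    provider: HomologyProvider,
    threshold: float,
    strict_seeds: bool,
) -> Optional[ExpansionResult]:
    universe = provider.universe
    present = [s for s in seed_ids if s in universe]
    for s in seed_ids:
        if s not in universe:
            logger.warning("seed %s of class %s absent from hit universe; skipped", s, cls)
    if not present:
        msg = f"all seeds of class {cls} absent from the hit universe"
        if strict_seeds:
            raise ValueError(msg)
        logger.warning(msg)
        return None

    members: set[str] = set(present)
    chains: dict[str, tuple[str, ...]] = {s: () for s in present}
    frontier = sorted(present)
    while frontier:
        discovered: dict[str, str] = {}
        for probe in frontier:
            for hit in provider.hits_for(probe, threshold):
                t = hit.target_id
                if t in members:
                    continue
                # deterministic parent: highest probability, then lexicographic
                prev = discovered.get(t)
                if prev is None:
                    discovered[t] = probe
                else:
                    prev_prob = provider.hit(prev, t).probability
                    if hit.probability > prev_prob or (
                        hit.probability == prev_prob and probe < prev
                    ):
                        discovered[t] = probe
        for t in sorted(discovered):
            parent = discovered[t]
            members.add(t)
            chains[t] = chains[parent] + (parent,)
        frontier = sorted(discovered)

    # accepting probability: max over in-edges from any member (order-free)
    probs: dict[str, float] = {}
    for pid in members:
        if pid in present:
            probs[pid] = 100.0
            continue
        best = 0.0
        for m in members:
            if m == pid:
                continue
            h = provider.hit(m, pid)
            if h is not None and h.probability >= threshold:
                best = max(best, h.probability)
        probs[pid] = best
    return ExpansionResult(cls, probs, chains, tuple(present))


def iterative_expand(
    seeds: SeedSet,
    provider: HomologyProvider,
    threshold: float = 90.0,
    classes: Optional[Iterable[ProteinClass]] = None,
    strict_seeds: bool = True,
) -> dict[ProteinClass, ExpansionResult]:
    """Breadth-first transitive closure over hits >= ``threshold``, per class.

    Each class expands independently from its seeds; newly accepted
    proteins are queued as probes until a fixed point. Set membership is
    the transitive closure of the thresholded hit graph, so it does not
    depend on probe dequeue order. With ``strict_seeds`` (default), a
    class whose seeds are all absent from the provider's universe raises;
    otherwise it is skipped with a warning.
    """
    if not 0.0 < threshold <= 100.0:
        raise ValueError(f"threshold must be in (0,100], got {threshold}")
    wanted = list(classes) if classes is not None else seeds.classes()
    results: dict[ProteinClass, ExpansionResult] = {}
    for cls in wanted:
        res = _expand_one_class(cls, seeds[cls], provider, threshold, strict_seeds)
        if res is not None:
            results[cls] = res
    return results


def resolve_class_conflicts(
    per_class: Mapping[ProteinClass, ExpansionResult],
    protein_to_phage: Mapping[str, str],
    round_label: str = "strict90",
    table: Optional[DetectionTable] = None,
) -> DetectionTable:
    """Turn per-class expansion sets into a per-phage detection table.

    A protein claimed by two or more classes goes to the class with the
    highest accepting probability (tie: lexicographically first class
    label, with a diagnostic). Within one phage, a class keeps a single
    protein (highest probability); extra claims on a connection class are
    logged as single-copy-control violations. Proteins not mapped to any
    phage (e.g. external reference seeds) are ignored.
    """
    claims: dict[str, list[tuple[ProteinClass, float, tuple[str, ...]]]] = {}
    for cls, res in per_class.items():
        for pid, prob in res.members.items():
            claims.setdefault(pid, []).append((cls, prob, res.chains.get(pid, ())))

    out = table if table is not None else DetectionTable()
    for pid in sorted(claims):
        cands = claims[pid]
        cands.sort(key=lambda c: (-c[1], str(c[0])))
        cls, prob, chain = cands[0]
        if len(cands) > 1 and any(c[1] == prob and c[0] != cls for c in cands[1:]):
            out.diagnostics.append(
                f"protein {pid} claimed by multiple classes at probability "
                f"{prob:.1f}; assigned to {cls} (lexicographic tie-break)"
            )
        elif len(cands) > 1:
            out.diagnostics.append(
                f"protein {pid} claimed by {len(cands)} classes; assigned to "
                f"{cls} (highest probability {prob:.1f})"
            )
        phage = protein_to_phage.get(pid)
        if phage is None:
            continue
        out.add(phage, cls, DetectionEntry(pid, prob, round_label, chain))
    return out
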