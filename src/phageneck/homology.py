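"""Access to profile-profile comparison evidence.

All similarity evidence seen by the detection and scoring stages flows
through a :class:`HomologyProvider`: an indexed, symmetrizable store of
(query, target, probability %, identity %) hits. Providers can be loaded
from a tab-separated all-vs-all hit table or filled from parsed
profile-profile search reports (HHR dialect). Probabilities are kept on
the 0-100 percent scale throughout, matching the thresholds the method
uses (90, 70, 95); they are never renormalized to [0, 1].
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HomologyHit",
    "ProfileMetadata",
    "HomologyProvider",
    "load_hit_table",
    "dump_hit_table",
    "parse_search_report",
    "symmetrize",
]


@dataclass(frozen=True)
class HomologyHit:
    """One profile-profile comparison result.

    ``probability`` is the profile-HMM homology confidence in percent;
    ``identity`` the percent sequence identity of the underlying
    alignment. ``identity_missing`` marks hits whose report carried no
    identity figure: identity is then 0 for scoring but the flag is
    surfaced in reports.
    """

    query_id: str
    target_id: str
    probability: float
    identity: float
    identity_missing: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 100.0:
            raise ValueError(
                f"probability out of [0,100] for hit "
                f"{self.query_id!r}->{self.target_id!r}: {self.probability}"
            )
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(
                f"identity out of [0,100] for hit "
                f"{self.query_id!r}->{self.target_id!r}: {self.identity}"
            )


@dataclass(frozen=True)
class ProfileMetadata:
    """Provenance of a profile: how many homologs its source alignment held.

    Profiles built from fewer than 5 source sequences are too weak for
    reliable profile-profile detection and are only ever *flagged* by the
    gene-context stage, never auto-accepted.
    """

    profile_id: str
    n_aligned_sequences: int

    def __post_init__(self) -> None:
        if self.n_aligned_sequences < 1:
            raise ValueError("n_aligned_sequences must be >= 1")


class HomologyProvider:
    """Indexed store of homology hits.

    ``hits_for(query, min_probability)`` returns every stored hit from
    ``query`` with probability >= the floor, deterministically ordered by
    descending probability then target id. Self-hits are dropped on
    insertion; duplicate (query, target) pairs keep the maximum
    probability (the expansion step only cares about crossing thresholds).
    """

    def __init__(self, hits: Iterable[HomologyHit] = ()):
        self._hits: dict[str, dict[str, HomologyHit]] = {}
        self.n_duplicates = 0
        self.n_self_hits = 0
        for h in hits:
            self.add(h)

    def add(self, hit: HomologyHit) -> None:
        if hit.query_id == hit.target_id:
            self.n_self_hits += 1
            return
        bucket = self._hits.setdefault(hit.query_id, {})
        prev = bucket.get(hit.target_id)
        if prev is not None:
            self.n_duplicates += 1
            if hit.probability <= prev.probability:
                return
            logger.warning(
                "duplicate hit %s->%s: keeping max probability %.2f over %.2f",
                hit.query_id, hit.target_id, hit.probability, prev.probability,
            )
        bucket[hit.target_id] = hit

    def hits_for(self, query_id: str, min_probability: float = 0.0) -> list[HomologyHit]:
        bucket = self._hits.get(query_id, {})
        out = [h for h in bucket.values() if h.probability >= min_probability]
        out.sort(key=lambda h: (-h.probability, h.target_id))
        return out

    def hit(self, query_id: str, target_id: str) -> Optional[HomologyHit]:
        """Directed lookup; ``None`` when the pair was never compared."""
        return self._hits.get(query_id, {}).get(target_id)

    def best_mutual_hit(self, a: str, b: str) -> Optional[HomologyHit]:
        """Hit between ``a`` and ``b`` in the direction with higher probability."""
        fwd, rev = self.hit(a, b), self.hit(b, a)
        if fwd is None:
            return rev
        if rev is None or fwd.probability >= rev.probability:
            return fwd
        return rev

    def __iter__(self):
        for query in sorted(self._hits):
            for target in sorted(self._hits[query]):
                yield self._hits[query][target]

    def __len__(self) -> int:
        return sum(len(b) for b in self._hits.values())

    @property
    def query_ids(self) -> list[str]:
        return sorted(self._hits)

    @property
    def universe(self) -> set[str]:
        ids = set(self._hits)
        for bucket in self._hits.values():
            ids.update(bucket)
        return ids


def load_hit_table(path: Union[str, Path]) -> HomologyProvider:
    """Load a TSV hit table (columns query_id, target_id, probability, identity).

    Malformed rows (missing fields, non-numeric values) are counted,
    logged and skipped; an out-of-range probability is an error naming
    the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["query_id", "target_id", "probability", "identity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"hit table {path} lacks columns {missing}")
    provider = HomologyProvider()
    n_malformed = 0
    for row in df.itertuples(index=True):
        try:
            prob = float(row.probability)
            ident = float(row.identity)
        except (TypeError, ValueError):
            n_malformed += 1
            continue
        if pd.isna(row.query_id) or pd.isna(row.target_id):
            n_malformed += 1
            continue
        if not 0.0 <= prob <= 100.0:
            raise ValueError(
                f"probability {prob} out of [0,100] at row {row.Index + 2} "
                f"of {path} ({row.query_id} -> {row.target_id})"
            )
        provider.add(
            HomologyHit(str(row.query_id), str(row.target_id), prob, ident)
        )
    if n_malformed:
        logger.warning("%d malformed rows skipped in %s", n_malformed, path)
    provider.n_malformed = n_malformed
    return provider


def dump_hit_table(provider: HomologyProvider, path: Union[str, Path]) -> None:
    """Write the provider back to TSV (two-decimal probabilities/identities)."""
    rows = [
        (h.query_id, h.target_id, f"{h.probability:.2f}", f"{h.identity:.2f}")
        for h in provider
    ]
    pd.DataFrame(
        rows, columns=["query_id", "target_id", "probability", "identity"]
    ).to_csv(path, sep="\t", index=False)


# --- HHR-dialect report parsing ------------------------------------------

_SUMMARY_HEADER = re.compile(r"^\s*No\s+Hit\s+Prob\b")
_SUMMARY_LINE = re.compile(r"^\s*(\d+)\s+(\S+)")
_ALIGN_BLOCK = re.compile(r"^No\s+(\d+)\s*$")
_PROBAB = re.compile(r"Probab=([\d.]+)")
_IDENTITIES = re.compile(r"Identities=([\d.]+)%")


def parse_search_report(text: str) -> list[HomologyHit]:
    """Parse a profile-profile search report (HHR dialect) into hits.

    The report must carry a ``Query`` header and a hit summary block
    (``No Hit ... Prob ...``); per-hit alignment blocks (``No i`` /
    ``>id`` / ``Probab=.. Identities=..%``) supply the identity when
    present. A hit without any identity figure is returned flagged with
    identity 0. Hits are returned in report order.
    """
    query_id = None
    for line in text.splitlines():
        if line.startswith("Query"):
            parts = line.split()
            if len(parts) < 2:
                raise ValueError("unparseable report header: Query line has no id")
            query_id = parts[1]
            break
    if query_id is None:
        raise ValueError("unparseable report header: no 'Query' line found")

    lines = text.splitlines()
    # summary block: ordered (rank, target) with the Prob column
    order: list[tuple[int, str, float]] = []
    in_summary = False
    for line in lines:
        if _SUMMARY_HEADER.match(line):
            in_summary = True
            continue
        if in_summary:
            m = _SUMMARY_LINE.match(line)
            if not m:
                break  # summary ends at first non-hit line
            rank, target = int(m.group(1)), m.group(2)
            # trailing numeric fields: Prob E-value P-value Score SS Cols
            # Query-HMM Template-HMM (cols); Prob is 9th from the end
            toks = line.split()
            try:
                prob = float(toks[-9])
            except (IndexError, ValueError):
                raise ValueError(
                    f"unparseable summary line for hit {rank}: {line!r}"
                ) from None
            order.append((rank, target, prob))

    # alignment blocks: refine probability, supply identity
    details: dict[int, tuple[Optional[float], Optional[float]]] = {}
    current: Optional[int] = None
    for line in lines:
        m = _ALIGN_BLOCK.match(line)
        if m:
            current = int(m.group(1))
            details.setdefault(current, (None, None))
            continue
        if current is not None:
            pm, im = _PROBAB.search(line), _IDENTITIES.search(line)
            if pm or im:
                prob, ident = details[current]
                if pm:
                    prob = float(pm.group(1))
                if im:
                    ident = float(im.group(1))
                details[current] = (prob, ident)

    if not order and details:
        order = [
            (rank, f"hit_{rank}", details[rank][0] or 0.0)
            for rank in sorted(details)
        ]

    hits = []
    for rank, target, prob in order:
        block_prob, ident = details.get(rank, (None, None))
        if block_prob is not None:
            prob = block_prob
        if ident is None:
            hits.append(HomologyHit(query_id, target, prob, 0.0, identity_missing=True))
        else:
            hits.append(HomologyHit(query_id, target, prob, ident))
    return hits


def symmetrize(provider: HomologyProvider) -> HomologyProvider:
    """Return a provider where P(a,b) = P(b,a) = max of the two directions.

    The identity carried by each direction is the one from the direction
    achieving the maximal probability; pairs present in one direction only
    are mirrored. Idempotent.
    """
    out = HomologyProvider()
    seen: set[tuple[str, str]] = set()
    for h in provider:
        key = (min(h.query_id, h.target_id), max(h.query_id, h.target_id))
        if key in seen:
            continue
        seen.add(key)
        best = provider.best_mutual_hit(h.query_id, h.target_id)
        out.add(best)
        out.add(
            replace(best, query_id=best.target_id, target_id=best.query_id)
        )
    return out
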