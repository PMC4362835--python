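"""Ground-truthed synthetic universes for exercising every pipeline stage.

The generator emits ordered phage proteomes with Type-specific neck
arrangements (Type 1: Ad1-Hc1-Ne1-Tc1; Type 2: Ad2-Hc2-Tc2; Type 3:
Ad3-x-Hc3; Type 4: Ad4) embedded among decoy genes, together with a
noisy all-vs-all homology hit table, profile metadata and the ground
truth (true class per protein, true Type and planted cluster per phage).

The default distributions emulate the regime the method was designed
for: within-family profile-profile probabilities above the strict
threshold (U(90,100), refined to U(97,100) within a planted cluster and
U(90,95) across clusters of the same Type), a configurable fraction of
neck proteins only detectable at the relaxed threshold (U(70,89)),
threshold-straddling decoy hits at non-canonical genome positions to
exercise the gene-context filter, and sequence identities that decay
with planted-cluster distance (same cluster U(25,60); different cluster
U(10,25), matching the 10-20% identity regime typical between remote
homologs). Sequences themselves are random amino-acid strings of
class-typical lengths: homology evidence flows through the hit table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .detection import DEFAULT_SEEDS, NECK_CLASSES_BY_TYPE, ProteinClass, SeedSet
from .genome_io import PhageGenome, ProteinRecord, write_ordered_proteome
from .homology import HomologyHit, HomologyProvider, ProfileMetadata, dump_hit_table

__all__ = [
    "UniverseConfig",
    "GroundTruth",
    "Universe",
    "generate_universe",
    "generate_worked_examples",
    "WORKED_EXAMPLE_TRUTH",
]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: class-typical sequence length ranges (residues); Ne1 spans 56-231
_LENGTHS: dict[Optional[ProteinClass], tuple[int, int]] = {
    ProteinClass.MCP: (280, 450),
    ProteinClass.TermL: (400, 600),
    ProteinClass.Portal: (400, 700),
    ProteinClass.MTP: (150, 250),
    ProteinClass.Sheath: (400, 600),
    ProteinClass.Ad1: (90, 130),
    ProteinClass.Hc1: (100, 140),
    ProteinClass.Tc1: (100, 160),
    ProteinClass.Ne1: (56, 231),
    ProteinClass.gpW: (60, 80),
    ProteinClass.Ad2: (250, 310),
    ProteinClass.Hc2: (230, 290),
    ProteinClass.Tc2: (250, 290),
    ProteinClass.Ad3: (140, 180),
    ProteinClass.Hc3: (400, 500),
    ProteinClass.Ad4: (260, 310),
    None: (80, 300),  # decoys
}

_HEAD_CLASSES = (ProteinClass.TermL, ProteinClass.Portal, ProteinClass.MCP)


@dataclass(frozen=True)
class UniverseConfig:
    """Conditions of a synthetic universe.

    ``n_phages`` and ``n_clusters`` are per neck Type; arrangement
    templates are canonical unless ``type1_extra_gap`` inserts extra
    decoy genes between Ne1 and Tc1 (``("constant", k)`` or
    ``("poisson", lam)``). All probability/identity distributions are
    uniform ranges on the percent scale.
    """

    n_phages: dict[int, int] = field(
        default_factory=lambda: {1: 16, 2: 4, 3: 6, 4: 2}
    )
    n_clusters: dict[int, int] = field(
        default_factory=lambda: {1: 4, 2: 1, 3: 2, 4: 1}
    )
    decoy_genes: tuple[int, int] = (15, 30)
    within_cluster_prob: tuple[float, float] = (97.0, 100.0)
    cross_cluster_prob: tuple[float, float] = (90.0, 95.0)
    seed_link_prob: tuple[float, float] = (92.0, 100.0)
    relaxed_prob: tuple[float, float] = (70.0, 89.0)
    cross_family_prob: tuple[float, float] = (5.0, 50.0)
    within_cluster_identity: tuple[float, float] = (25.0, 60.0)
    cross_cluster_identity: tuple[float, float] = (10.0, 25.0)
    noise_identity: tuple[float, float] = (1.0, 15.0)
    relaxed_fraction: float = 0.15
    decoy_hit_fraction: float = 0.3
    noise_hits_per_phage: int = 2
    low_support_fraction: float = 0.05
    type1_extra_gap: tuple[str, float] = ("constant", 0)
    include_ne1: bool = True
    sheath_fraction_type1: float = 0.3
    gpw_fraction_type1: float = 0.0

    def __post_init__(self) -> None:
        for t, n in self.n_phages.items():
            k = self.n_clusters.get(t, 1)
            if k > n:
                raise ValueError(
                    f"Type {t}: {k} clusters requested for only {n} phages"
                )
        for rng_pair in (
            self.within_cluster_prob, self.cross_cluster_prob,
            self.seed_link_prob, self.relaxed_prob, self.cross_family_prob,
            self.within_cluster_identity, self.cross_cluster_identity,
            self.noise_identity,
        ):
            lo, hi = rng_pair
            if not (0.0 <= lo <= hi <= 100.0):
                raise ValueError(f"distribution bounds {rng_pair} not in [0,100]")


@dataclass
class GroundTruth:
    """What the generator planted, for downstream scoring."""

    protein_class: dict[str, ProteinClass] = field(default_factory=dict)
    phage_type: dict[str, int] = field(default_factory=dict)
    phage_cluster: dict[str, int] = field(default_factory=dict)
    demoted: set[str] = field(default_factory=set)  # relaxed-only members
    decoy_with_hits: set[str] = field(default_factory=set)
    has_sheath: dict[str, bool] = field(default_factory=dict)


@dataclass
class Universe:
    """A generated universe: genomes, homology evidence, metadata, truth."""

    genomes: dict[str, PhageGenome]
    provider: HomologyProvider
    metadata: dict[str, ProfileMetadata]
    truth: GroundTruth
    config: UniverseConfig
    seed: int

    def write(self, outdir: Union[str, Path]) -> None:
        """Emit the universe in the formats the pipeline consumes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta_dir = outdir / "genomes"
        fasta_dir.mkdir(exist_ok=True)
        for pid, genome in sorted(self.genomes.items()):
            write_ordered_proteome(genome, fasta_dir / f"{pid}.fasta")
        dump_hit_table(self.provider, outdir / "hits.tsv")
        meta = {
            pid: int(m.n_aligned_sequences)
            for pid, m in sorted(self.metadata.items())
        }
        (outdir / "profile_metadata.yaml").write_text(yaml.safe_dump(meta))
        truth_doc = {
            "protein_class": {
                k: str(v) for k, v in sorted(self.truth.protein_class.items())
            },
            "phage_type": dict(sorted(self.truth.phage_type.items())),
            "phage_cluster": dict(sorted(self.truth.phage_cluster.items())),
            "demoted": sorted(self.truth.demoted),
            "decoy_with_hits": sorted(self.truth.decoy_with_hits),
            "has_sheath": dict(sorted(self.truth.has_sheath.items())),
        }
        (outdir / "ground_truth.yaml").write_text(yaml.safe_dump(truth_doc))


def _random_seq(rng: np.random.Generator, cls: Optional[ProteinClass]) -> str:
    lo, hi = _LENGTHS[cls]
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(_AA, size=n))


def _neck_slots(
    neck_type: int, cfg: UniverseConfig, rng: np.random.Generator, gpw: bool
) -> list[Optional[ProteinClass]]:
    if neck_type == 1:
        kind, param = cfg.type1_extra_gap
        if kind == "constant":
            extra = int(param)
        elif kind == "poisson":
            extra = int(rng.poisson(param))
        else:
            raise ValueError(f"unknown gap distribution {kind!r}")
        x_slot: list[Optional[ProteinClass]] = (
            [ProteinClass.Ne1] if cfg.include_ne1 else [None]
        )
        tail = x_slot + [None] * extra + [ProteinClass.Tc1]
        if gpw:
            # gpW 6 genes upstream of Hc1 and 9 upstream of Tc1
            return [ProteinClass.gpW] + [None] * 5 + [ProteinClass.Hc1,
                    ProteinClass.Ne1, None, ProteinClass.Tc1]
        return [ProteinClass.Ad1, ProteinClass.Hc1] + tail
    if neck_type == 2:
        return [ProteinClass.Ad2, ProteinClass.Hc2, ProteinClass.Tc2]
    if neck_type == 3:
        return [ProteinClass.Ad3, None, ProteinClass.Hc3]
    if neck_type == 4:
        return [ProteinClass.Ad4]
    raise ValueError(f"unknown neck type {neck_type}")


def _uniform(rng: np.random.Generator, bounds: tuple[float, float]) -> float:
    return float(np.round(rng.uniform(*bounds), 2))


def generate_universe(
    config: UniverseConfig, seed: int, seeds: SeedSet = DEFAULT_SEEDS
) -> Universe:
    """Generate a deterministic ground-truthed universe for a seed.

    Every stochastic draw derives from the single ``seed``; two calls
    with the same config and seed produce identical output.
    """
    rng = np.random.default_rng(seed)
    truth = GroundTruth()
    genomes: dict[str, PhageGenome] = {}
    families: dict[ProteinClass, list[tuple[str, str]]] = {c: [] for c in ProteinClass}
    decoys_by_phage: dict[str, list[str]] = {}
    neck_ranks: dict[str, list[int]] = {}

    # --- genomes -----------------------------------------------------
    for neck_type in sorted(config.n_phages):
        n = config.n_phages[neck_type]
        k = config.n_clusters.get(neck_type, 1)
        for i in range(n):
            phage_id = f"T{neck_type}P{i:03d}"
            cluster = i % k + 1
            has_sheath = neck_type == 2 or (
                neck_type == 1 and rng.random() < config.sheath_fraction_type1
            )
            gpw = neck_type == 1 and rng.random() < config.gpw_fraction_type1
            neck = _neck_slots(neck_type, config, rng, gpw)
            tail: list[Optional[ProteinClass]] = [ProteinClass.MTP]
            if has_sheath:
                tail.append(ProteinClass.Sheath)
            n_decoys = int(rng.integers(*config.decoy_genes))
            parts = rng.multinomial(n_decoys, [0.25, 0.25, 0.25, 0.25])
            slots: list[Optional[ProteinClass]] = (
                [None] * parts[0] + list(_HEAD_CLASSES) + [None] * parts[1]
                + neck + [None] * parts[2] + tail + [None] * parts[3]
            )
            proteins, decoy_ids, nranks = [], [], []
            for rank, cls in enumerate(slots, start=1):
                pid = f"{phage_id}_p{rank:03d}"
                proteins.append(ProteinRecord(pid, phage_id, rank, _random_seq(rng, cls)))
                if cls is None:
                    decoy_ids.append(pid)
                else:
                    truth.protein_class[pid] = cls
                    families[cls].append((pid, phage_id))
                    if cls in NECK_CLASSES_BY_TYPE.get(neck_type, ()):
                        nranks.append(rank)
                    if cls in (ProteinClass.Ne1, ProteinClass.gpW):
                        nranks.append(rank)
            genomes[phage_id] = PhageGenome(phage_id, proteins)
            truth.phage_type[phage_id] = neck_type
            truth.phage_cluster[phage_id] = cluster
            truth.has_sheath[phage_id] = has_sheath
            decoys_by_phage[phage_id] = decoy_ids
            neck_ranks[phage_id] = nranks

    # demote a fraction of Ad/Hc/Tc members to relaxed-only detectability
    connection = {c for cs in NECK_CLASSES_BY_TYPE.values() for c in cs}
    for cls in sorted(connection, key=str):
        for pid, _ in families[cls]:
            if rng.random() < config.relaxed_fraction:
                truth.demoted.add(pid)

    # --- hit table ---------------------------------------------------
    provider = HomologyProvider()

    def emit(a: str, b: str, prob: float, ident: float) -> None:
        provider.add(HomologyHit(a, b, prob, ident))
        provider.add(HomologyHit(b, a, prob, ident))

    for cls in sorted(families, key=str):
        members = families[cls]
        if not members:
            continue
        seed_ids = list(seeds[cls]) if cls in seeds.classes() else []
        pool: list[tuple[str, Optional[str]]] = (
            [(s, None) for s in seed_ids] + [(p, ph) for p, ph in members]
        )
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                a, pa = pool[i]
                b, pb = pool[j]
                if a in truth.demoted or b in truth.demoted:
                    prob = _uniform(rng, config.relaxed_prob)
                    ident = _uniform(rng, config.cross_cluster_identity)
                elif pa is None or pb is None:
                    prob = _uniform(rng, config.seed_link_prob)
                    ident = _uniform(rng, config.cross_cluster_identity)
                else:
                    same = (
                        truth.phage_type[pa] == truth.phage_type[pb]
                        and truth.phage_cluster[pa] == truth.phage_cluster[pb]
                    )
                    if same:
                        prob = _uniform(rng, config.within_cluster_prob)
                        ident = _uniform(rng, config.within_cluster_identity)
                    else:
                        prob = _uniform(rng, config.cross_cluster_prob)
                        ident = _uniform(rng, config.cross_cluster_identity)
                emit(a, b, prob, ident)

    # threshold-straddling decoys at non-canonical positions
    for phage_id in sorted(decoys_by_phage):
        if rng.random() >= config.decoy_hit_fraction:
            continue
        genome = genomes[phage_id]
        nranks = neck_ranks[phage_id]
        eligible = [
            pid for pid in decoys_by_phage[phage_id]
            if all(abs(genome.rank_of(pid) - r) > 6 for r in nranks)
        ]
        if not eligible:
            continue
        decoy = eligible[int(rng.integers(len(eligible)))]
        neck_classes = NECK_CLASSES_BY_TYPE[truth.phage_type[phage_id]]
        cls = neck_classes[int(rng.integers(len(neck_classes)))]
        partners = [p for p, _ in families[cls][:2]] + list(seeds[cls])[:1]
        for partner in partners:
            emit(decoy, partner,
                 _uniform(rng, config.relaxed_prob),
                 _uniform(rng, config.noise_identity))
        truth.decoy_with_hits.add(decoy)

    # sub-threshold cross-family noise
    all_true = sorted(truth.protein_class)
    for phage_id in sorted(genomes):
        for _ in range(config.noise_hits_per_phage):
            a = all_true[int(rng.integers(len(all_true)))]
            b = all_true[int(rng.integers(len(all_true)))]
            if a == b or truth.protein_class[a] == truth.protein_class[b]:
                continue
            emit(a, b,
                 _uniform(rng, config.cross_family_prob),
                 _uniform(rng, config.noise_identity))

    # --- profile metadata -------------------------------------------
    metadata: dict[str, ProfileMetadata] = {}
    all_ids = sorted(
        set(truth.protein_class)
        | {d for ds in decoys_by_phage.values() for d in ds}
        | {s for cls in seeds.classes() for s in seeds[cls]}
    )
    for pid in all_ids:
        if rng.random() < config.low_support_fraction:
            n_seqs = int(rng.integers(1, 5))
        else:
            n_seqs = int(rng.integers(10, 101))
        metadata[pid] = ProfileMetadata(pid, n_seqs)

    return Universe(genomes, provider, metadata, truth, config, seed)


def generate_planted_similarity(
    block_sizes: list[int],
    seed: int,
    within: tuple[float, float] = (90.0, 100.0),
    between: tuple[float, float] = (20.0, 50.0),
):
    """Block-structured similarity matrix with known cluster labels.

    Cells within a planted block draw from ``within``, cells across
    blocks from ``between``; the diagonal is maximal (110). Returns
    ``(SimilarityMatrix, labels)`` with labels 1..K by block.
    """
    from .similarity import MAX_SCORE, SimilarityMatrix

    rng = np.random.default_rng(seed)
    labels: dict[str, int] = {}
    ids: list[str] = []
    for k, size in enumerate(block_sizes, start=1):
        for i in range(size):
            pid = f"B{k:02d}P{i:03d}"
            ids.append(pid)
            labels[pid] = k
    n = len(ids)
    scores = np.full((n, n), np.nan)
    np.fill_diagonal(scores, MAX_SCORE)
    for i in range(n):
        for j in range(i + 1, n):
            bounds = within if labels[ids[i]] == labels[ids[j]] else between
            scores[i, j] = scores[j, i] = float(rng.uniform(*bounds))
    counts = np.full((n, n), 1, dtype=int)
    return SimilarityMatrix(ids, scores, counts), labels


# --- worked examples: the six reference phages ------------------------

#: expected (neck type, morphology) of each worked-example fixture
WORKED_EXAMPLE_TRUTH: dict[str, tuple[int, str]] = {
    "SPP1": (1, "Siphoviridae"),
    "Lambda": (1, "Siphoviridae"),
    "HK97": (1, "Siphoviridae"),
    "T4": (2, "Myoviridae"),
    "P22": (3, "Podoviridae"),
    "Phi29": (4, "Podoviridae"),
}


def generate_worked_examples() -> Universe:
    """Minimal fixtures for the six reference phages.

    Each genome carries its documented head-neck-tail composition at the
    canonical gene order (SPP1: Ad1-Hc1-Ne1-Tc1; Lambda: gpW six genes
    upstream of Hc1 and nine upstream of Tc1, no Ad1; HK97:
    Ad1-Hc1-x-Tc1; T4: consecutive Ad2-Hc2-Tc2 plus a sheath; P22:
    Ad3-x-Hc3; Phi29: Ad4 only). Reference proteins that *are* default
    seeds appear under their seed ids; the others are linked to their
    seeds by fixed high-probability hits. Deterministic.
    """
    rng = np.random.default_rng(0)  # cosmetic sequences only
    truth = GroundTruth()
    provider = HomologyProvider()
    genomes: dict[str, PhageGenome] = {}

    def emit(a: str, b: str, prob: float, ident: float) -> None:
        provider.add(HomologyHit(a, b, prob, ident))
        provider.add(HomologyHit(b, a, prob, ident))

    # layout: ordered (protein_id, class or None); hit: member -> seed
    layouts: dict[str, list[tuple[str, Optional[ProteinClass]]]] = {
        "SPP1": [
            ("SPP1_gp2", ProteinClass.TermL),
            ("SPP1_gp6", ProteinClass.Portal),
            ("SPP1_gp13", ProteinClass.MCP),
            ("SPP1_gp15", ProteinClass.Ad1),
            ("SPP1_gp16", ProteinClass.Hc1),
            ("SPP1_gp16.1", ProteinClass.Ne1),
            ("SPP1_gp17", ProteinClass.Tc1),
            ("SPP1_gp17.1", ProteinClass.MTP),
        ],
        "Lambda": [
            ("Lambda_gpA", ProteinClass.TermL),
            ("Lambda_gpB", ProteinClass.Portal),
            ("Lambda_gpE", ProteinClass.MCP),
            ("Lambda_gpW", ProteinClass.gpW),
            ("Lambda_orf1", None),
            ("Lambda_orf2", None),
            ("Lambda_orf3", None),
            ("Lambda_orf4", None),
            ("Lambda_orf5", None),
            ("Lambda_gpFII", ProteinClass.Hc1),
            ("Lambda_gpZ", ProteinClass.Ne1),
            ("Lambda_orf6", None),
            ("Lambda_gpU", ProteinClass.Tc1),
            ("Lambda_gpV", ProteinClass.MTP),
        ],
        "HK97": [
            ("HK97_gp2", ProteinClass.TermL),
            ("HK97_gp3", ProteinClass.Portal),
            ("HK97_gp5", ProteinClass.MCP),
            ("HK97_gp6", ProteinClass.Ad1),
            ("HK97_gp7", ProteinClass.Hc1),
            ("HK97_orf1", None),
            ("HK97_gp9", ProteinClass.Tc1),
            ("HK97_gp11", ProteinClass.MTP),
        ],
        "T4": [
            ("T4_gp17", ProteinClass.TermL),
            ("T4_gp20", ProteinClass.Portal),
            ("T4_gp23", ProteinClass.MCP),
            ("T4_gp13", ProteinClass.Ad2),
            ("T4_gp14", ProteinClass.Hc2),
            ("T4_gp15", ProteinClass.Tc2),
            ("T4_gp18", ProteinClass.Sheath),
            ("T4_gp19", ProteinClass.MTP),
        ],
        "P22": [
            ("P22_gp2", ProteinClass.TermL),
            ("P22_gp1", ProteinClass.Portal),
            ("P22_gp5", ProteinClass.MCP),
            ("P22_gp4", ProteinClass.Ad3),
            ("P22_orf1", None),
            ("P22_gp10", ProteinClass.Hc3),
        ],
        "Phi29": [
            ("Phi29_gp10", ProteinClass.Portal),
            ("Phi29_gp8", ProteinClass.MCP),
            ("Phi29_gp11", ProteinClass.Ad4),
        ],
    }
    sheath = {"T4": True}
    seed_ids = {s for cls in DEFAULT_SEEDS.classes() for s in DEFAULT_SEEDS[cls]}

    for phage_id, layout in layouts.items():
        proteins = []
        for rank, (pid, cls) in enumerate(layout, start=1):
            proteins.append(ProteinRecord(pid, phage_id, rank, _random_seq(rng, cls)))
            if cls is not None:
                truth.protein_class[pid] = cls
                if pid in seed_ids:
                    # the reference protein itself: its own family profile
                    # sits in the reference collection
                    emit(pid, f"{pid}_refprofile", 100.0, 100.0)
                else:
                    # deterministic member->seed link above the strict
                    # threshold (Ne1 homologs are mostly seen above 95%)
                    seed = DEFAULT_SEEDS[cls][0]
                    prob = 97.0 if cls is ProteinClass.Ne1 else 95.0
                    emit(pid, seed, prob, 28.0)
        genomes[phage_id] = PhageGenome(phage_id, proteins)
        truth.phage_type[phage_id] = WORKED_EXAMPLE_TRUTH[phage_id][0]
        truth.phage_cluster[phage_id] = 1
        truth.has_sheath[phage_id] = sheath.get(phage_id, False)

    metadata = {
        pid: ProfileMetadata(pid, 50)
        for g in genomes.values() for pid in g.protein_ids
    }
    return Universe(genomes, provider, metadata, truth, UniverseConfig(), 0)
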