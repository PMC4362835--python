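"""End-to-end orchestration: build a reference classification, classify queries.

``run_build_reference`` runs the four-step method over a corpus —
strict iterative expansion from the seeds, inter-gene distance learning,
the context-constrained relaxed pass (plus the gpW and Ne1 special
detections and low-support flagging), Type/morphology assignment, then
per-Type similarity matrices, WPGMA trees and cluster labels — and
serializes everything as one versioned reference bundle.

``run_classify`` maps a single query genome onto such a bundle: detects
its module components, assigns Type and morphology, checks its neck
gene spacing against the learned tolerated distances, places it in the
nearest reference cluster and reports the most similar reference
proteins. Exit status 3 marks the unclassifiable (non-tailed) outcome:
no head-to-tail connection protein detected.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import yaml

from .detection import (
    DEFAULT_SEEDS,
    NECK_CLASSES_BY_TYPE,
    STRICT_ONLY_CLASSES,
    DetectionEntry,
    DetectionTable,
    ProteinClass,
    SeedSet,
    iterative_expand,
    resolve_class_conflicts,
)
from .gene_context import (
    DistanceModel,
    FlaggedCandidate,
    constrained_relaxed_search,
    detect_gpW,
    detect_ne1,
    dump_distance_model,
    flag_low_support_candidates,
    learn_distance_model,
    load_distance_model,
)
from .genome_io import PhageGenome, intergene_distance
from .homology import HomologyProvider, ProfileMetadata, symmetrize
from .neck_typing import NeckAssignment, assign_neck_type, infer_morphology
from .similarity import (
    SimilarityMatrix,
    assign_cluster,
    build_similarity_matrix,
    wpgma_tree,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ReferenceBundle",
    "ClassifyResult",
    "detect_all",
    "run_build_reference",
    "run_classify",
    "EXIT_OK",
    "EXIT_UNCLASSIFIABLE",
]

EXIT_OK = 0
EXIT_UNCLASSIFIABLE = 3

BUNDLE_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and switches of one pipeline run."""

    strict_threshold: float = 90.0
    relaxed_threshold: float = 70.0
    gpw_threshold: float = 95.0
    components: str = "all"
    require_sign: bool = True
    symmetrize: bool = True
    tree_distance: str = "rows"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.relaxed_threshold < self.strict_threshold <= 100.0:
            raise ValueError(
                "need 0 < relaxed_threshold < strict_threshold <= 100, got "
                f"{self.relaxed_threshold} / {self.strict_threshold}"
            )

    def hash(self) -> str:
        """Stable digest of the thresholds; guards bundle compatibility."""
        doc = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:12]


def detect_all(
    genomes: Mapping[str, PhageGenome],
    provider: HomologyProvider,
    metadata: Optional[Mapping[str, ProfileMetadata]] = None,
    config: RunConfig = RunConfig(),
    seeds: SeedSet = DEFAULT_SEEDS,
    models: Optional[dict[int, DistanceModel]] = None,
) -> tuple[DetectionTable, dict[int, DistanceModel], list[FlaggedCandidate]]:
    """Full detection over a genome set.

    Strict expansion for head/tail and Ad/Hc/Tc classes, distance-model
    learning per Type (skipped when pre-learned ``models`` are given,
    e.g. at classify time), the context-constrained relaxed pass, the
    gpW and Ne1 rules, and low-support flagging (when profile metadata
    is available).
    """
    if config.symmetrize:
        provider = symmetrize(provider)
    protein_to_phage = {
        pid: g.phage_id for g in genomes.values() for pid in g.protein_ids
    }
    strict_classes = [
        c for c in seeds.classes()
        if c in STRICT_ONLY_CLASSES
        or any(c in cs for cs in NECK_CLASSES_BY_TYPE.values())
    ]
    expanded = iterative_expand(
        seeds, provider, config.strict_threshold,
        classes=strict_classes, strict_seeds=False,
    )
    table = resolve_class_conflicts(expanded, protein_to_phage, "strict90")

    if models is None:
        models = {}
        for neck_type in sorted(NECK_CLASSES_BY_TYPE):
            if len(NECK_CLASSES_BY_TYPE[neck_type]) < 2:
                models[neck_type] = DistanceModel(neck_type)
                continue
            models[neck_type] = learn_distance_model(table, genomes, neck_type)

    for neck_type in sorted(models):
        if models[neck_type].pairs:
            constrained_relaxed_search(
                seeds, provider, models[neck_type], table, genomes,
                config.relaxed_threshold, config.strict_threshold,
                config.require_sign,
            )
    detect_gpW(provider, table, genomes, seeds, config.gpw_threshold)
    detect_ne1(provider, table, genomes, seeds,
               config.strict_threshold, config.relaxed_threshold)

    flags: list[FlaggedCandidate] = []
    if metadata:
        for neck_type in sorted(models):
            if models[neck_type].pairs:
                flags.extend(
                    flag_low_support_candidates(
                        metadata, models[neck_type], table, genomes,
                        config.require_sign,
                    )
                )
    return table, models, flags


def _assignments_for(
    table: DetectionTable, phage_ids
) -> dict[str, NeckAssignment]:
    out = {}
    for pid in sorted(phage_ids):
        a = assign_neck_type(table, pid)
        infer_morphology(a, table.has(pid, ProteinClass.Sheath))
        out[pid] = a
    return out


@dataclass
class ReferenceBundle:
    """A versioned reference classification, reusable for query placement."""

    config: RunConfig
    detections: DetectionTable
    models: dict[int, DistanceModel]
    assignments: dict[str, NeckAssignment]
    matrices: dict[int, SimilarityMatrix] = field(default_factory=dict)
    trees: dict[int, str] = field(default_factory=dict)  # newick per Type
    cluster_labels: dict[int, dict[str, int]] = field(default_factory=dict)
    flags: list[FlaggedCandidate] = field(default_factory=list)

    def save(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "version": BUNDLE_VERSION,
            "config": asdict(self.config),
            "config_hash": self.config.hash(),
            "types": sorted(self.trees),
        }
        (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
        self.detections.to_frame().to_csv(outdir / "detections.tsv", sep="\t", index=False)
        dump_distance_model(
            [m for m in self.models.values() if m.pairs], outdir / "distance_models.yaml"
        )
        rows = [
            {
                "phage_id": a.phage_id,
                "neck_type": a.neck_type,
                "morphology": a.morphology,
                "completeness": round(a.completeness, 3),
                "evidence": ";".join(f"{c}:{p}:{prob:.1f}" for c, p, prob in a.evidence),
            }
            for a in self.assignments.values()
        ]
        import pandas as pd

        pd.DataFrame(rows).to_csv(outdir / "assignments.tsv", sep="\t", index=False)
        for t, matrix in self.matrices.items():
            matrix.to_frame().to_csv(outdir / f"matrix_type{t}.tsv", sep="\t")
        for t, newick in self.trees.items():
            (outdir / f"tree_type{t}.nwk").write_text(newick + "\n")
        for t, labels in self.cluster_labels.items():
            pd.DataFrame(
                sorted(labels.items()), columns=["phage_id", "cluster"]
            ).to_csv(outdir / f"clusters_type{t}.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, indir: Union[str, Path]) -> "ReferenceBundle":
        import pandas as pd

        indir = Path(indir)
        manifest = yaml.safe_load((indir / "manifest.yaml").read_text())
        config = RunConfig(**manifest["config"])
        if manifest.get("config_hash") != config.hash():
            raise ValueError(
                f"bundle at {indir} has a corrupted or incompatible config hash"
            )
        table = DetectionTable()
        df = pd.read_csv(indir / "detections.tsv", sep="\t")
        for _, row in df.iterrows():
            chain = (
                tuple(str(row["chain"]).split(";"))
                if isinstance(row["chain"], str) and row["chain"]
                else ()
            )
            table.add(
                str(row["phage_id"]), ProteinClass(row["class"]),
                DetectionEntry(
                    str(row["protein_id"]), float(row["probability"]),
                    str(row["round"]), chain,
                ),
            )
        models_path = indir / "distance_models.yaml"
        models = load_distance_model(models_path) if models_path.exists() else {}
        for t in NECK_CLASSES_BY_TYPE:
            models.setdefault(t, DistanceModel(t))
        assignments = _assignments_for(table, table.phages())
        labels: dict[int, dict[str, int]] = {}
        trees: dict[int, str] = {}
        for t in manifest.get("types", []):
            lpath = indir / f"clusters_type{t}.tsv"
            if lpath.exists():
                ldf = pd.read_csv(lpath, sep="\t")
                labels[int(t)] = dict(zip(ldf.phage_id, (int(c) for c in ldf.cluster)))
            tpath = indir / f"tree_type{t}.nwk"
            if tpath.exists():
                trees[int(t)] = tpath.read_text().strip()
        return cls(config, table, models, assignments,
                   matrices={}, trees=trees, cluster_labels=labels)


def run_build_reference(
    genomes: Mapping[str, PhageGenome],
    provider: HomologyProvider,
    metadata: Optional[Mapping[str, ProfileMetadata]] = None,
    config: RunConfig = RunConfig(),
    seeds: SeedSet = DEFAULT_SEEDS,
    n_clusters: Optional[Mapping[int, int]] = None,
) -> ReferenceBundle:
    """Build a reference classification over a corpus.

    Per Type with at least two classified phages, the similarity matrix
    and WPGMA tree are built and clusters are cut — at the requested
    count per Type when ``n_clusters`` provides one (reproducing a known
    classification), by the largest-height-gap heuristic otherwise.
    """
    table, models, flags = detect_all(genomes, provider, metadata, config, seeds)
    assignments = _assignments_for(table, genomes.keys())
    bundle = ReferenceBundle(config, table, models, assignments, flags=flags)

    search_provider = symmetrize(provider) if config.symmetrize else provider
    for neck_type in sorted(NECK_CLASSES_BY_TYPE):
        members = sorted(
            pid for pid, a in assignments.items() if a.neck_type == neck_type
        )
        if len(members) < 2:
            continue
        matrix = build_similarity_matrix(
            members, table, search_provider, config.components
        )
        tree = wpgma_tree(matrix, distance=config.tree_distance)
        if n_clusters and neck_type in n_clusters:
            labels = tree.cut_k(n_clusters[neck_type])
        else:
            labels = tree.cut_largest_gap()
        bundle.matrices[neck_type] = matrix
        bundle.trees[neck_type] = tree.to_newick()
        bundle.cluster_labels[neck_type] = labels
    return bundle


@dataclass
class ClassifyResult:
    """Report bundle for one query phage."""

    phage_id: str
    assignment: NeckAssignment
    gene_map: list[tuple[int, str, str, float]]  # rank, protein, class, prob
    distance_warnings: list[str]
    cluster: Optional[int] = None
    cluster_means: dict[int, float] = field(default_factory=dict)
    nearest: list[dict] = field(default_factory=list)
    reference_tree: Optional[str] = None
    exit_code: int = EXIT_OK

    def write(self, outdir: Union[str, Path]) -> None:
        import pandas as pd

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            self.gene_map, columns=["rank", "protein_id", "class", "probability"]
        ).to_csv(outdir / "gene_map.tsv", sep="\t", index=False)
        report = {
            "phage_id": self.phage_id,
            "neck_type": self.assignment.neck_type,
            "morphology": self.assignment.morphology,
            "completeness": round(self.assignment.completeness, 3),
            "evidence": [
                {"class": str(c), "protein_id": p, "probability": prob}
                for c, p, prob in self.assignment.evidence
            ],
            "cluster": self.cluster,
            "cluster_means": {str(k): round(v, 2) for k, v in self.cluster_means.items()},
            "diagnostics": self.assignment.diagnostics,
            "distance_warnings": self.distance_warnings,
            "exit_code": self.exit_code,
        }
        (outdir / "assignment.json").write_text(json.dumps(report, indent=2) + "\n")
        if self.nearest:
            pd.DataFrame(self.nearest).to_csv(
                outdir / "nearest_reference.tsv", sep="\t", index=False
            )
        if self.reference_tree:
            (outdir / "reference_tree.nwk").write_text(self.reference_tree + "\n")
        (outdir / "warnings.txt").write_text(
            "".join(w + "\n" for w in self.distance_warnings)
        )


def _distance_warnings(
    genome: PhageGenome,
    table: DetectionTable,
    assignment: NeckAssignment,
    models: Mapping[int, DistanceModel],
) -> list[str]:
    """Flag unusual neck gene spacing relative to the learned model."""
    if not isinstance(assignment.neck_type, int):
        return []
    model = models.get(assignment.neck_type)
    if model is None or not model.pairs:
        return []
    classes = table.classes_of(genome.phage_id)
    out = []
    for (a, b), stats in sorted(model.pairs.items(), key=lambda kv: str(kv[0])):
        ea, eb = classes.get(a), classes.get(b)
        if ea is None or eb is None:
            continue
        d = intergene_distance(genome, ea.protein_id, eb.protein_id)
        if d <= 0 or abs(d) > stats.tolerated:
            out.append(
                f"unusual inter-gene distance ({a},{b}) = {d}: expected "
                f"{stats.mean:.1f} +/- 2*{stats.sd:.1f} (tolerated "
                f"{stats.tolerated:.1f})"
            )
    return out


def run_classify(
    genome: PhageGenome,
    provider: HomologyProvider,
    config: RunConfig = RunConfig(),
    reference: Optional[ReferenceBundle] = None,
    seeds: SeedSet = DEFAULT_SEEDS,
) -> ClassifyResult:
    """Detect, type and place one query genome.

    The provider must hold the query-vs-reference comparison results.
    Without a reference bundle only the strict pass and the positional
    gpW/Ne1 rules run (no learned distance model is available for the
    relaxed pass) and no cluster placement is reported.
    """
    genomes = {genome.phage_id: genome}
    models = reference.models if reference is not None else {
        t: DistanceModel(t) for t in NECK_CLASSES_BY_TYPE
    }
    table, _, _ = detect_all(
        genomes, provider, None, config, seeds, models=models
    )
    assignment = assign_neck_type(table, genome.phage_id)
    infer_morphology(assignment, table.has(genome.phage_id, ProteinClass.Sheath))

    detected = table.classes_of(genome.phage_id)
    by_protein = {e.protein_id: (c, e.probability) for c, e in detected.items()}
    gene_map = [
        (
            p.rank,
            p.protein_id,
            str(by_protein[p.protein_id][0]) if p.protein_id in by_protein else "-",
            round(by_protein[p.protein_id][1], 1) if p.protein_id in by_protein else 0.0,
        )
        for p in genome.proteins
    ]

    result = ClassifyResult(
        genome.phage_id, assignment, gene_map,
        _distance_warnings(genome, table, assignment, models),
    )
    has_connection = any(c not in STRICT_ONLY_CLASSES for c in detected)
    if not has_connection:
        result.exit_code = EXIT_UNCLASSIFIABLE
        assignment.diagnostics.append("no head-to-tail connection detected")
        return result

    if reference is not None and isinstance(assignment.neck_type, int):
        labels = reference.cluster_labels.get(assignment.neck_type)
        if labels:
            merged = reference.detections.copy()
            for (pid, cls), e in table.entries.items():
                merged.add(pid, cls, e)
            search_provider = symmetrize(provider) if config.symmetrize else provider
            cluster, means, warn = assign_cluster(
                genome.phage_id, merged, search_provider, labels,
                config.components,
            )
            result.cluster = cluster
            result.cluster_means = means
            result.distance_warnings.extend(warn)
            result.reference_tree = reference.trees.get(assignment.neck_type)
            result.nearest = _nearest_reference(
                table, reference.detections, provider, genome.phage_id
            )
    return result


def _nearest_reference(
    query_table: DetectionTable,
    ref_table: DetectionTable,
    provider: HomologyProvider,
    phage_id: str,
    top: int = 3,
) -> list[dict]:
    """Most similar reference proteins per detected query component."""
    ref_index = {
        e.protein_id: (pid, cls)
        for (pid, cls), e in ref_table.entries.items()
    }
    rows = []
    for cls, entry in sorted(query_table.classes_of(phage_id).items(), key=lambda kv: str(kv[0])):
        hits = [
            h for h in provider.hits_for(entry.protein_id)
            if h.target_id in ref_index
        ][:top]
        for h in hits:
            ref_phage, ref_cls = ref_index[h.target_id]
            rows.append({
                "query_protein": entry.protein_id,
                "query_class": str(cls),
                "reference_protein": h.target_id,
                "reference_phage": ref_phage,
                "reference_class": str(ref_cls),
                "probability": round(h.probability, 1),
                "identity": round(h.identity, 1),
            })
    return rows
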