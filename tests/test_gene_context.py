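"""Distance-model learning and the context-constrained relaxed pass."""

from math import sqrt

import numpy as np
import pytest

from phageneck.detection import (
    DetectionEntry,
    DetectionTable,
    ProteinClass,
    SeedSet,
)
from phageneck.gene_context import (
    DistanceModel,
    PairStats,
    constrained_relaxed_search,
    detect_gpW,
    detect_ne1,
    dump_distance_model,
    flag_low_support_candidates,
    learn_distance_model,
    load_distance_model,
)
from phageneck.genome_io import PhageGenome, ProteinRecord
from phageneck.homology import HomologyHit, HomologyProvider, ProfileMetadata
from phageneck.pipeline import detect_all
from phageneck.synthetic import UniverseConfig, generate_universe

AD1, HC1, TC1 = ProteinClass.Ad1, ProteinClass.Hc1, ProteinClass.Tc1


def _genome(phage_id, n, placed):
    """Genome of n decoys with class proteins placed at given ranks.

    placed: {rank: protein_id}; remaining ranks become decoys.
    """
    proteins = []
    for rank in range(1, n + 1):
        pid = placed.get(rank, f"{phage_id}_d{rank:02d}")
        proteins.append(ProteinRecord(pid, phage_id, rank, "M" * 50))
    return PhageGenome(phage_id, proteins)


def _table(entries):
    """entries: (phage, cls, protein, prob)"""
    t = DetectionTable()
    for phage, cls, pid, prob in entries:
        t.add(phage, cls, DetectionEntry(pid, prob, "strict90"))
    return t


def _both(a, b, prob, ident=10.0):
    return [HomologyHit(a, b, prob, ident), HomologyHit(b, a, prob, ident)]


class TestLearnDistanceModel:
    def test_canonical_type1_means(self):
        genomes, rows = {}, []
        for i, offset in enumerate([3, 5, 8]):
            pid = f"g{i}"
            placed = {offset: f"{pid}_ad1", offset + 1: f"{pid}_hc1",
                      offset + 3: f"{pid}_tc1"}
            genomes[pid] = _genome(pid, 15, placed)
            rows += [(pid, AD1, f"{pid}_ad1", 95.0),
                     (pid, HC1, f"{pid}_hc1", 95.0),
                     (pid, TC1, f"{pid}_tc1", 95.0)]
        model = learn_distance_model(_table(rows), genomes, 1)
        assert model.stats(AD1, HC1).mean == 1.0
        assert model.stats(HC1, TC1).mean == 2.0
        assert model.stats(AD1, TC1).mean == 3.0
        for pair in [(AD1, HC1), (HC1, TC1), (AD1, TC1)]:
            assert model.stats(*pair).sd == 0.0
            assert model.stats(*pair).tolerated == model.stats(*pair).mean

    def test_single_genome_gives_sd_zero(self):
        g = _genome("p", 10, {2: "ad1", 3: "hc1", 5: "tc1"})
        t = _table([("p", AD1, "ad1", 95.0), ("p", HC1, "hc1", 95.0),
                    ("p", TC1, "tc1", 95.0)])
        model = learn_distance_model(t, {"p": g}, 1)
        s = model.stats(AD1, HC1)
        assert (s.mean, s.sd, s.tolerated, s.n_observations) == (1.0, 0.0, 1.0, 1)

    def test_two_observations_sample_sd(self):
        # distances {1, 3} -> mean 2, sample sd sqrt(2), tolerated 2+2*sqrt(2)
        g1 = _genome("p1", 10, {2: "a1", 3: "h1"})
        g2 = _genome("p2", 10, {2: "a2", 5: "h2"})
        t = _table([("p1", AD1, "a1", 95.0), ("p1", HC1, "h1", 95.0),
                    ("p2", AD1, "a2", 95.0), ("p2", HC1, "h2", 95.0)])
        model = learn_distance_model(t, {"p1": g1, "p2": g2}, 1)
        s = model.stats(AD1, HC1)
        assert s.mean == 2.0
        assert s.sd == pytest.approx(sqrt(2))
        assert s.tolerated == pytest.approx(2 + 2 * sqrt(2))

    @pytest.mark.parametrize("seed", range(5))
    def test_against_numpy_statistics_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genomes, rows, gaps = {}, [], []
        for i in range(12):
            pid = f"p{i}"
            gap = int(rng.integers(1, 6))
            gaps.append(gap)
            genomes[pid] = _genome(pid, 15, {2: f"{pid}a", 2 + gap: f"{pid}h"})
            rows += [(pid, AD1, f"{pid}a", 95.0), (pid, HC1, f"{pid}h", 95.0)]
        s = learn_distance_model(_table(rows), genomes, 1).stats(AD1, HC1)
        assert s.mean == pytest.approx(np.mean(gaps))
        assert s.sd == pytest.approx(np.std(gaps, ddof=1))
        assert s.tolerated == pytest.approx(np.mean(gaps) + 2 * np.std(gaps, ddof=1))

    def test_unobserved_pair_skipped(self):
        g = _genome("p", 10, {2: "ad1"})
        model = learn_distance_model(_table([("p", AD1, "ad1", 95.0)]), {"p": g}, 1)
        assert model.stats(AD1, HC1) is None

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError, match="neck type"):
            learn_distance_model(DetectionTable(), {}, 9)


def _relaxed_setup(tc1_rank, prob=75.0):
    """One phage with strict Hc1 anchor and one relaxed Tc1 candidate."""
    placed = {3: "hc1", tc1_rank: "cand"}
    genome = _genome("p", 14, placed)
    table = _table([("p", HC1, "hc1", 95.0)])
    seeds = SeedSet({TC1: ("seed_tc1",)})
    provider = HomologyProvider(_both("seed_tc1", "cand", prob))
    model = DistanceModel(1, {(HC1, TC1): PairStats(2.0, 1.0, 4.0, 5)})
    return seeds, provider, model, table, {"p": genome}


class TestConstrainedRelaxedSearch:
    def test_candidate_at_tolerated_boundary_accepted(self):
        seeds, provider, model, table, genomes = _relaxed_setup(tc1_rank=7)
        constrained_relaxed_search(seeds, provider, model, table, genomes)
        e = table.get("p", TC1)
        assert e is not None and e.protein_id == "cand" and e.round == "relaxed70"

    def test_candidate_beyond_tolerated_rejected(self):
        seeds, provider, model, table, genomes = _relaxed_setup(tc1_rank=9)  # d=6 > 4
        constrained_relaxed_search(seeds, provider, model, table, genomes)
        assert table.get("p", TC1) is None
        assert any("inconsistent" in d for d in table.diagnostics)

    def test_wrong_sign_rejected(self):
        seeds, provider, model, table, genomes = _relaxed_setup(tc1_rank=1)  # upstream
        constrained_relaxed_search(seeds, provider, model, table, genomes)
        assert table.get("p", TC1) is None

    def test_wrong_sign_accepted_when_sign_check_off(self):
        seeds, provider, model, table, genomes = _relaxed_setup(tc1_rank=1)  # |d|=2 <= 4
        constrained_relaxed_search(
            seeds, provider, model, table, genomes, require_sign=False
        )
        assert table.get("p", TC1) is not None

    def test_below_relaxed_threshold_never_surfaces(self):
        seeds, provider, model, table, genomes = _relaxed_setup(tc1_rank=5, prob=65.0)
        constrained_relaxed_search(seeds, provider, model, table, genomes)
        assert table.get("p", TC1) is None

    def test_no_strict_anchor_rejected_and_logged(self):
        seeds, provider, model, table, genomes = _relaxed_setup(tc1_rank=5)
        empty = DetectionTable()
        constrained_relaxed_search(seeds, provider, model, empty, genomes)
        assert empty.get("p", TC1) is None
        assert any("no strict anchor" in d for d in empty.diagnostics)

    def test_relaxed_must_be_below_strict(self):
        seeds, provider, model, table, genomes = _relaxed_setup(tc1_rank=5)
        with pytest.raises(ValueError, match="below"):
            constrained_relaxed_search(
                seeds, provider, model, table, genomes, relaxed_threshold=95.0
            )


class TestGpW:
    def _setup(self, prob, gpw_rank=4, with_ad1=False):
        placed = {gpw_rank + 6: "hc1", gpw_rank + 9: "tc1", gpw_rank: "w"}
        rows = [("p", HC1, "hc1", 95.0), ("p", TC1, "tc1", 95.0)]
        if with_ad1:
            placed[gpw_rank + 5] = "ad1"
            rows.append(("p", AD1, "ad1", 95.0))
        genome = _genome("p", 16, placed)
        seeds = SeedSet({ProteinClass.gpW: ("seed_w",)})
        provider = HomologyProvider(_both("seed_w", "w", prob))
        return seeds, provider, _table(rows), {"p": genome}

    def test_canonical_gpw_accepted(self):
        seeds, provider, table, genomes = self._setup(96.0)
        detect_gpW(provider, table, genomes, seeds)
        e = table.get("p", ProteinClass.gpW)
        assert e is not None and e.protein_id == "w"

    def test_below_95_rejected(self):
        seeds, provider, table, genomes = self._setup(80.0)
        detect_gpW(provider, table, genomes, seeds)
        assert table.get("p", ProteinClass.gpW) is None

    def test_skipped_when_ad1_present(self):
        seeds, provider, table, genomes = self._setup(96.0, with_ad1=True)
        detect_gpW(provider, table, genomes, seeds)
        assert table.get("p", ProteinClass.gpW) is None

    def test_off_window_rejected_with_diagnostic(self):
        # gpW only 3 genes upstream of Hc1
        placed = {4: "w", 7: "hc1", 10: "tc1"}
        genome = _genome("p", 16, placed)
        table = _table([("p", HC1, "hc1", 95.0), ("p", TC1, "tc1", 95.0)])
        seeds = SeedSet({ProteinClass.gpW: ("seed_w",)})
        provider = HomologyProvider(_both("seed_w", "w", 97.0))
        detect_gpW(provider, table, {"p": genome}, seeds)
        assert table.get("p", ProteinClass.gpW) is None
        assert any("gpW candidate" in d for d in table.diagnostics)


class TestNe1:
    def _setup(self, prob, ne1_rank):
        placed = {4: "hc1", 8: "tc1", ne1_rank: "ne"}
        genome = _genome("p", 12, placed)
        table = _table([("p", HC1, "hc1", 95.0), ("p", TC1, "tc1", 95.0)])
        seeds = SeedSet({ProteinClass.Ne1: ("seed_ne",)})
        provider = HomologyProvider(_both("seed_ne", "ne", prob))
        return seeds, provider, table, {"p": genome}

    def test_strict_probability_accepted_anywhere(self):
        seeds, provider, table, genomes = self._setup(97.0, ne1_rank=11)
        detect_ne1(provider, table, genomes, seeds)
        assert table.get("p", ProteinClass.Ne1).protein_id == "ne"

    def test_relaxed_inside_hc1_tc1_interval_accepted(self):
        seeds, provider, table, genomes = self._setup(75.0, ne1_rank=6)
        detect_ne1(provider, table, genomes, seeds)
        e = table.get("p", ProteinClass.Ne1)
        assert e is not None and e.round == "relaxed70"

    def test_relaxed_outside_interval_rejected(self):
        seeds, provider, table, genomes = self._setup(75.0, ne1_rank=10)
        detect_ne1(provider, table, genomes, seeds)
        assert table.get("p", ProteinClass.Ne1) is None
        assert any("Ne1 candidate" in d for d in table.diagnostics)

    def test_non_type1_phage_ignored(self):
        seeds, provider, table, genomes = self._setup(97.0, ne1_rank=6)
        other = _table([("p", ProteinClass.Ad3, "hc1", 95.0)])
        detect_ne1(provider, other, genomes, seeds)
        assert other.get("p", ProteinClass.Ne1) is None


class TestLowSupportFlagging:
    def _setup(self, n_aligned, cand_rank=6):
        # Tc1 missing; candidate sits at the canonical slot
        placed = {3: "ad1", 4: "hc1", cand_rank: "cand"}
        genome = _genome("p", 12, placed)
        table = _table([("p", AD1, "ad1", 95.0), ("p", HC1, "hc1", 95.0)])
        model = DistanceModel(1, {
            (AD1, HC1): PairStats(1.0, 0.5, 2.0, 9),
            (AD1, TC1): PairStats(3.0, 1.0, 5.0, 9),
            (HC1, TC1): PairStats(2.0, 1.0, 4.0, 9),
        })
        metadata = {"cand": ProfileMetadata("cand", n_aligned)}
        return metadata, model, table, {"p": genome}

    def test_low_support_candidate_flagged_not_accepted(self):
        metadata, model, table, genomes = self._setup(3)
        flagged = flag_low_support_candidates(metadata, model, table, genomes)
        assert len(flagged) == 1
        f = flagged[0]
        assert (f.cls, f.protein_id, f.n_aligned_sequences) == (TC1, "cand", 3)
        assert table.get("p", TC1) is None  # never auto-accepted

    def test_boundary_five_sequences_not_flagged(self):
        metadata, model, table, genomes = self._setup(5)
        assert flag_low_support_candidates(metadata, model, table, genomes) == []

    def test_no_missing_class_gives_empty_list(self):
        metadata, model, table, genomes = self._setup(3)
        table.add("p", TC1, DetectionEntry("tc1_real", 95.0, "strict90"))
        assert flag_low_support_candidates(metadata, model, table, genomes) == []

    def test_off_position_candidate_not_flagged(self):
        metadata, model, table, genomes = self._setup(3, cand_rank=12)
        assert flag_low_support_candidates(metadata, model, table, genomes) == []


class TestModelSerialization:
    def test_yaml_round_trip(self, tmp_path):
        model = DistanceModel(1, {
            (AD1, HC1): PairStats(1.0, 0.5, 2.0, 42),
            (HC1, TC1): PairStats(2.0, 1.0, 4.0, 40),
        })
        path = tmp_path / "model.yaml"
        dump_distance_model(model, path)
        loaded = load_distance_model(path)[1]
        assert loaded.pairs == model.pairs


class TestUniverseProperties:
    def test_decoys_at_non_canonical_positions_all_rejected(self):
        """Threshold-straddling decoys must never pass the context filter."""
        for seed in (2, 3, 4):
            cfg = UniverseConfig(decoy_hit_fraction=1.0)
            u = generate_universe(cfg, seed=seed)
            table, _, _ = detect_all(u.genomes, u.provider, u.metadata)
            detected = {e.protein_id for e in table.entries.values()}
            assert u.truth.decoy_with_hits, "generator planted no decoys"
            assert not (detected & u.truth.decoy_with_hits)

    def test_single_copy_invariant_after_all_passes(self, default_universe,
                                                    default_detections):
        table, _, _ = default_detections
        # table structure enforces one protein per (phage, class); verify
        # no protein occupies two classes either
        seen = {}
        for (phage, cls), e in table.entries.items():
            assert e.protein_id not in seen, (
                f"{e.protein_id} assigned to {seen[e.protein_id]} and {cls}"
            )
            seen[e.protein_id] = cls

    def test_relearning_on_augmented_detections_is_stable(self, default_universe,
                                                          default_detections):
        """Relearned tolerated distances stay within 2*SD of the strict ones."""
        u = default_universe
        table, models, _ = default_detections
        for neck_type in (1, 2, 3):
            relearned = learn_distance_model(table, u.genomes, neck_type)
            for pair, s0 in models[neck_type].pairs.items():
                s1 = relearned.stats(*pair)
                assert s1 is not None
                assert s1.tolerated >= s0.tolerated - 2 * s0.sd
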