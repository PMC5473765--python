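import numpy as np
import pytest

from retrochrono import synth
from retrochrono.abundance import (
    LTRLibrary,
    LTRRepresentative,
    annotate_homologous_copies,
    build_ltr_library,
    depth_profile,
    family_sequence_lengths,
    genome_mean_depth_from_reads,
    map_reads,
    validate_depth_proxy,
)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def mutate(seq, n_subs, rng):
    out = list(seq)
    for i in rng.choice(len(seq), size=n_subs, replace=False):
        out[i] = "ACGT"[("ACGT".index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def library_of(*entries):
    return LTRLibrary(
        representatives=[
            LTRRepresentative(name=n, family_id=f, sequence=s, collapsed=[n])
            for n, f, s in entries
        ],
        dedupe_identity=0.95,
        min_length=150,
    )


class TestBuildLibrary:
    def test_pair_above_cutoff_collapses(self):
        rng = np.random.default_rng(1)
        ltr = random_seq(rng, 1000)
        similar = mutate(ltr, 40, rng)  # identity 0.96
        lib = build_ltr_library([("a", "f", ltr), ("b", "f", similar)])
        assert len(lib) == 1
        assert sorted(lib.representatives[0].collapsed) == ["a", "b"]

    def test_pair_below_cutoff_kept_separate(self):
        rng = np.random.default_rng(2)
        ltr = random_seq(rng, 1000)
        diverged = mutate(ltr, 100, rng)  # identity 0.90
        lib = build_ltr_library([("a", "f", ltr), ("b", "f", diverged)])
        assert len(lib) == 2

    def test_short_ltr_excluded(self):
        rng = np.random.default_rng(3)
        lib = build_ltr_library(
            [("short", "f", random_seq(rng, 140)), ("ok", "f", random_seq(rng, 200))]
        )
        assert len(lib) == 1
        assert lib.representatives[0].name == "ok"
        assert lib.n_dropped_short == 1

    def test_idempotent_under_duplicates(self):
        rng = np.random.default_rng(4)
        ltr = random_seq(rng, 500)
        once = build_ltr_library([("a", "f", ltr)])
        twice = build_ltr_library([("a", "f", ltr), ("a2", "f", ltr)])
        assert len(once) == len(twice) == 1
        assert once.representatives[0].sequence == twice.representatives[0].sequence

    def test_identity_over_shorter_sequence(self):
        rng = np.random.default_rng(5)
        long_seq = random_seq(rng, 1000)
        prefix = long_seq[:300]  # identical over its whole (shorter) length
        lib = build_ltr_library([("long", "f", long_seq), ("short", "f", prefix)])
        assert len(lib) == 1


class TestMapReads:
    def test_exact_substring_weight_one(self):
        rng = np.random.default_rng(6)
        rep = random_seq(rng, 500)
        lib = library_of(("r1", "f", rep))
        hits = map_reads([rep[100:200]], lib)
        assert len(hits[0]) == 1
        placement = hits[0][0]
        assert placement.weight == 1.0
        assert placement.position == 100
        assert placement.mismatches == 0

    def test_read_in_two_representatives_half_weight(self):
        rng = np.random.default_rng(7)
        shared = random_seq(rng, 200)
        rep_a = shared + random_seq(rng, 300)
        rep_b = shared + random_seq(rng, 300)
        lib = library_of(("a", "f1", rep_a), ("b", "f2", rep_b))
        hits = map_reads([shared[50:150]], lib)
        assert len(hits[0]) == 2
        assert all(p.weight == pytest.approx(0.5) for p in hits[0])

    def test_weights_always_sum_to_one(self):
        spec = synth.FamilySpec(family_id="f", ltr_length=400, internal_length=800,
                                copy_number=5, age_distribution=0.0)
        genome = synth.build_genome([spec], 60_000, seed=8)
        reads = synth.simulate_reads(genome, coverage=2, seed=9)
        el = genome.truth[0]
        ltr = genome.sequence[slice(*el.realized_coords["ltr5"])]
        lib = library_of(("r", "f", ltr))
        for placements in map_reads(reads, lib):
            if placements:
                assert sum(p.weight for p in placements) == pytest.approx(1.0)

    def test_too_many_mismatches_unmapped(self):
        rng = np.random.default_rng(10)
        rep = random_seq(rng, 400)
        read = list(rep[100:200])
        for i in (10, 30, 50, 70, 90):  # 5 mismatches > 2 per 100 bp
            read[i] = "ACGT"[("ACGT".index(read[i]) + 1) % 4]
        lib = library_of(("r", "f", rep))
        assert map_reads(["".join(read)], lib) == [[]]

    def test_reverse_complement_reads_map(self):
        from retrochrono.ioutils import revcomp

        rng = np.random.default_rng(11)
        rep = random_seq(rng, 400)
        lib = library_of(("r", "f", rep))
        hits = map_reads([revcomp(rep[50:150])], lib)
        assert len(hits[0]) == 1
        assert hits[0][0].strand == "-"


class TestDepthProfile:
    def test_single_copy_depth_near_one(self):
        spec = synth.FamilySpec(family_id="f", ltr_length=400, internal_length=800,
                                copy_number=1, solo_fraction=1.0)
        genome = synth.build_genome([spec], 120_000, seed=12)
        reads = synth.simulate_reads(genome, coverage=5, seed=13)
        el = genome.truth[0]
        ltr = genome.sequence[slice(*el.realized_coords["ltr5"])]
        lib = library_of(("r", "f", ltr))
        profile = depth_profile(
            map_reads(reads, lib), lib,
            genome_mean_depth_from_reads(reads, len(genome.sequence)),
        )
        assert profile.normalized_depth[0] == pytest.approx(1.0, abs=0.15)

    def test_ten_copies_depth_near_ten(self):
        # ten identical planted LTR copies (solo form: one LTR each)
        spec = synth.FamilySpec(family_id="f", ltr_length=1000, internal_length=800,
                                copy_number=10, solo_fraction=1.0)
        genome = synth.build_genome([spec], 120_000, seed=14)
        reads = synth.simulate_reads(genome, coverage=5, seed=15)
        el = genome.truth[0]
        ltr = genome.sequence[slice(*el.realized_coords["ltr5"])]
        lib = library_of(("r", "f", ltr))
        profile = depth_profile(
            map_reads(reads, lib), lib,
            genome_mean_depth_from_reads(reads, len(genome.sequence)),
        )
        assert profile.normalized_depth[0] == pytest.approx(10.0, rel=0.15)

    def test_zero_mapped_reads_zero_depth(self):
        rng = np.random.default_rng(16)
        lib = library_of(("r", "f", random_seq(rng, 300)))
        profile = depth_profile([[]], lib, genome_mean_depth=5.0)
        assert profile.normalized_depth[0] == 0.0
        assert profile.family_depth["f"] == 0.0

    def test_zero_mean_depth_rejected(self):
        lib = library_of(("r", "f", "ACGT" * 100))
        with pytest.raises(ValueError):
            depth_profile([], lib, genome_mean_depth=0.0)


class TestAnnotateHomologs:
    def _genome_with_solo_and_fragment(self):
        specs = [
            synth.FamilySpec(family_id="solo", ltr_length=400, internal_length=800,
                             copy_number=1, solo_fraction=1.0, age_distribution=1e5),
            synth.FamilySpec(family_id="frag", ltr_length=400, internal_length=2000,
                             copy_number=1, fragment_fraction=1.0,
                             age_distribution=1e5),
        ]
        return synth.build_genome(specs, 120_000, seed=18)

    def test_planted_solo_annotated(self):
        genome = self._genome_with_solo_and_fragment()
        solo = next(e for e in genome.truth if e.state == "solo_ltr")
        ltr = genome.sequence[slice(*solo.realized_coords["ltr5"])]
        lib = library_of(("solo_rep", "solo", ltr))
        records = annotate_homologous_copies(genome.sequence, lib, [])
        solo_hits = [r for r in records if r.attributes["label"] == "solo_ltr"]
        assert len(solo_hits) == 1
        s, e = solo.span
        assert abs(solo_hits[0].start - 1 - s) <= 10
        assert abs(solo_hits[0].end - e) <= 10

    def test_planted_fragment_annotated(self):
        genome = self._genome_with_solo_and_fragment()
        frag = next(e for e in genome.truth if e.state == "fragment")
        spec = synth.FamilySpec(family_id="frag", ltr_length=400,
                                internal_length=2000, copy_number=1)
        # the family's ancestral LTR, rebuilt deterministically
        ltr0, _ = synth._ancestral_family(spec, 18)
        lib = library_of(("frag_rep", "frag", ltr0.tobytes().decode()))
        records = annotate_homologous_copies(genome.sequence, lib, [])
        frag_hits = [
            r for r in records
            if r.attributes["family"] == "frag"
            and r.start - 1 < frag.span[1] and r.end > frag.span[0]
        ]
        assert frag_hits
        assert all(r.attributes["label"] == "fragment" for r in frag_hits)

    def test_family_without_copies_no_annotation(self):
        rng = np.random.default_rng(19)
        genome = synth.build_genome([], 50_000, seed=20)
        lib = library_of(("ghost", "ghost", random_seq(rng, 400)))
        assert annotate_homologous_copies(genome.sequence, lib, []) == []

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            annotate_homologous_copies("ACGT" * 100, library_of(), [])

    def test_family_sequence_lengths(self):
        genome = self._genome_with_solo_and_fragment()
        solo = next(e for e in genome.truth if e.state == "solo_ltr")
        ltr = genome.sequence[slice(*solo.realized_coords["ltr5"])]
        lib = library_of(("solo_rep", "solo", ltr))
        records = annotate_homologous_copies(genome.sequence, lib, [])
        totals = family_sequence_lengths(records)
        assert totals["solo"] >= 380


class TestDepthProxyValidation:
    def test_perfectly_proportional(self):
        counts = {"a": 1, "b": 2, "c": 3, "d": 4}
        depths = {k: 2.0 * v for k, v in counts.items()}
        report = validate_depth_proxy(depths, counts)
        assert report.r == pytest.approx(1.0)
        assert report.valid

    def test_anti_proportional(self):
        counts = {"a": 1, "b": 2, "c": 3, "d": 4}
        depths = {k: 10.0 - v for k, v in counts.items()}
        assert validate_depth_proxy(depths, counts).r == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        report = validate_depth_proxy(
            {"a": 1.0, "b": 1.0, "c": 1.0}, {"a": 1, "b": 2, "c": 3}
        )
        assert not report.valid

    def test_too_few_families(self):
        with pytest.raises(ValueError):
            validate_depth_proxy({"a": 1.0, "b": 2.0}, {"a": 1, "b": 2})
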