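"""Four-step variant validation, artifact classification and statistics."""

import itertools

import pytest

from tagmux.coverage import coverage_probability
from tagmux.design import AmpliconDesign
from tagmux.validate import (
    ArtifactCall,
    Genotype,
    PoolDataset,
    SampleObservations,
    assemble_genotypes,
    classify_artifact,
    detect_chimera,
    pool_statistics,
    replicate_concordance,
    step1_filter,
    step2_depth_filter,
    step3_frequency_filter,
    step4_artifact_screen,
    validate_pool,
)

L = 171
V1 = "A" * L
V2 = "C" * L
V3 = "G" * L


def pool_of(samples, pool="A", raw=None):
    sobs = [SampleObservations(sid, "sp", m, dict(counts)) for sid, m, counts in samples]
    total = sum(sum(c.values()) for *_, c in samples)
    return PoolDataset(pool, raw if raw is not None else total, sobs)


@pytest.fixture
def design():
    return AmpliconDesign()


class TestStep1:
    def test_pool_singleton_removed(self, design):
        pool = pool_of([("Sa", 2, {V1: 2, V2: 1})])
        out, report = step1_filter(pool, design)
        assert out.sample("Sa").counts == {V1: 2}
        assert report.removed_sequences == 1
        assert report.input_sequences == report.removed_sequences + report.retained_sequences

    def test_singleton_scope_is_pool_wide(self, design):
        # V2 is unique within each sample but occurs twice in the pool
        pool = pool_of([("Sa", 2, {V1: 3, V2: 1}), ("Sb", 2, {V2: 1})])
        out, _ = step1_filter(pool, design)
        assert V2 in out.sample("Sa").counts
        assert V2 in out.sample("Sb").counts

    def test_frameshift_lengths(self, design):
        seq168, seq170 = "A" * 168, "A" * 170
        pool = pool_of([("Sa", 2, {V1: 2, seq168: 2, seq170: 2})])
        out, report = step1_filter(pool, design, drop_singletons=False)
        kept = set(out.sample("Sa").counts)
        assert kept == {V1, seq168}  # -3 is in-frame, -1 is not
        assert ("Sa", seq170, "frameshift") in report.removals

    def test_singleton_filter_can_be_relaxed(self, design):
        pool = pool_of([("Sa", 2, {V1: 2, V2: 1})])
        out, _ = step1_filter(pool, design, drop_singletons=False)
        assert out.sample("Sa").counts == {V1: 2, V2: 1}


class TestStep2:
    @pytest.mark.parametrize(
        "m, n_i, kept",
        [(2, 18, False), (2, 19, True), (4, 45, False), (4, 46, True)],
    )
    def test_depth_boundaries(self, m, n_i, kept):
        pool = pool_of([("Sa", m, {V1: n_i})])
        out, _ = step2_depth_filter(pool, r=3, alpha=1e-3)
        assert (len(out.samples) == 1) is kept


class TestStep3:
    def test_low_frequency_variant_removed(self):
        pool = pool_of([("Sa", 2, {V1: 98, V2: 2})])  # F = 2% < 4%
        out, report = step3_frequency_filter(pool, t2=0.04)
        assert set(out.sample("Sa").counts) == {V1}
        assert report.removed_sequences == 2

    def test_balanced_heterozygote_untouched(self):
        pool = pool_of([("Sa", 2, {V1: 50, V2: 50})])
        out, _ = step3_frequency_filter(pool)
        assert out.sample("Sa").counts == {V1: 50, V2: 50}

    def test_boundary_is_strict(self):
        # exactly 4% is NOT below the threshold
        pool = pool_of([("Sa", 2, {V1: 96, V2: 4})])
        out, _ = step3_frequency_filter(pool, t2=0.04)
        assert set(out.sample("Sa").counts) == {V1, V2}

    def test_removals_are_simultaneous(self):
        # both minor variants are judged against the same initial N_i = 77:
        # V3 at 3/77 = 3.9% goes too, even though removing V2 first would
        # have lifted it to exactly 4% (iterative recomputation would keep it)
        pool = pool_of([("Sa", 2, {V1: 72, V2: 2, V3: 3})])
        out, _ = step3_frequency_filter(pool, t2=0.04)
        assert set(out.sample("Sa").counts) == {V1}

    def test_t2_validation(self):
        with pytest.raises(ValueError):
            step3_frequency_filter(pool_of([("Sa", 2, {V1: 10})]), t2=1.5)


def brute_force_chimera(candidate, parents):
    """All (P, Q, k) with candidate = P[:k] + Q[k:], by direct search."""
    hits = []
    for p, q in itertools.permutations(parents, 2):
        if len(p) != len(candidate) or len(q) != len(candidate):
            continue
        for k in range(1, len(candidate)):
            if candidate == p[:k] + q[k:]:
                hits.append((p, q, k))
    return hits


class TestDetectChimera:
    def test_direct_composition(self):
        call = detect_chimera("AAATTT", ["AAAAAA", "TTTTTT"])
        assert call.artifact_class == "chimera"
        assert call.parents == ("AAAAAA", "TTTTTT")
        assert call.breakpoints == (3, 3)

    def test_candidate_equal_to_parent_is_never_chimeric(self):
        assert detect_chimera("AAAAAA", ["AAAAAA", "TTTTTT"]) is None

    def test_breakpoint_interval_matches_brute_force(self):
        cand, parents = "ACGTAC", ["ACGTTT", "GGGTAC"]
        call = detect_chimera(cand, parents)
        hits = brute_force_chimera(cand, parents)
        ks = sorted(k for p, q, k in hits if (p, q) == call.parents)
        assert call is not None
        assert (call.breakpoints[0], call.breakpoints[1]) == (min(ks), max(ks))

    def test_fewer_than_two_parents(self):
        assert detect_chimera("AATT", ["AAAA"]) is None

    def test_agrees_with_brute_force_on_short_sequences(self):
        import random

        rnd = random.Random(7)
        for _ in range(300):
            n = rnd.randint(2, 12)
            parents = list({
                "".join(rnd.choice("AT") for _ in range(n)) for _ in range(3)
            })
            cand = "".join(rnd.choice("AT") for _ in range(n))
            call = detect_chimera(cand, parents)
            hits = brute_force_chimera(cand, [p for p in parents if p != cand])
            if cand in parents:
                assert call is None
            elif call is None:
                assert hits == []
            else:
                assert hits != []
                p, q = call.parents
                ks = [k for pp, qq, k in hits if (pp, qq) == (p, q)]
                assert call.breakpoints == (min(ks), max(ks))


class TestStep4:
    def test_chimera_removed_and_parents_kept(self):
        a = "AAAA" + "C" * (L - 4)
        b = "TTTT" + "G" * (L - 4)
        crossover = a[:80] + b[80:]
        pool = pool_of([("Sa", 2, {a: 46, b: 46, crossover: 8})])
        out, report, calls = step4_artifact_screen(pool)
        assert set(out.sample("Sa").counts) == {a, b}
        assert any(c.artifact_class == "chimera" for c in calls)

    def test_without_references_only_chimera_screen_runs(self):
        off_target = "T" * L
        pool = pool_of([("Sa", 2, {V1: 40, off_target: 20})])
        out, _, calls = step4_artifact_screen(pool, nontarget_refs=None)
        assert set(out.sample("Sa").counts) == {V1, off_target}

    def test_pseudogene_removed_with_references(self):
        allele_a = V1
        allele_b = V1[:-6] + "CCCCCC"
        pseudo = "T" * L
        pool = pool_of([("Sa", 2, {allele_a: 40, allele_b: 30, pseudo: 20})])
        out, _, calls = step4_artifact_screen(pool, nontarget_refs=[pseudo])
        assert set(out.sample("Sa").counts) == {allele_a, allele_b}
        assert any(c.artifact_class == "other_gene" for c in calls)

    def test_sample_eliminated_when_depth_falls_below_t1(self):
        a = "AAAA" + "C" * (L - 4)
        b = "TTTT" + "G" * (L - 4)
        crossover = a[:80] + b[80:]
        # exactly T1 sequences; losing the chimeric one drops below
        pool = pool_of([("Sa", 2, {a: 9, b: 9, crossover: 1})])
        out, report, _ = step4_artifact_screen(pool)
        assert out.samples == []
        assert any("post-screen depth" in why for *_, why in report.removals)


class TestGenotypes:
    def test_heterozygote_confidence(self):
        pool = pool_of([("Sa", 2, {V1: 36, V2: 26})])
        (g,) = assemble_genotypes(pool)
        assert g.variants == {V1, V2}
        assert g.zygosity == "heterozygous/multi"
        assert g.confidence == pytest.approx(coverage_probability(3, 2, 62))
        assert g.confidence > 0.999999

    def test_homozygous_like(self):
        pool = pool_of([("Sa", 2, {V1: 40})])
        (g,) = assemble_genotypes(pool)
        assert g.zygosity == "homozygous-like"
        assert not g.flagged_excess_variants

    def test_excess_variants_flagged_not_truncated(self):
        pool = pool_of([("Sa", 2, {V1: 20, V2: 20, V3: 20})])
        (g,) = assemble_genotypes(pool)
        assert len(g.variants) == 3
        assert g.flagged_excess_variants


class TestClassifyArtifact:
    def test_substitution(self):
        rejected = "C" + V1[1:]
        call = classify_artifact(rejected, [V1])
        assert call.artifact_class == "substitution"

    def test_insertion_and_deletion(self):
        assert classify_artifact(V1 + "G", [V1]).artifact_class == "insertion"
        assert classify_artifact(V1[:-2], [V1]).artifact_class == "deletion"

    def test_chimera_takes_precedence(self):
        a = "AAAACCCC"
        b = "TTTTGGGG"
        composite = a[:4] + b[4:]  # 4 mismatches to each parent
        call = classify_artifact(composite, [a, b])
        assert call.artifact_class == "chimera"

    def test_other_gene_and_unknown(self):
        far = "T" * L
        assert classify_artifact(far, [V1], nontarget_refs=[far]).artifact_class == "other_gene"
        assert classify_artifact(far, [V1]).artifact_class == "unknown"

    def test_requires_accepted_variants(self):
        with pytest.raises(ValueError):
            classify_artifact(V1, [])


class TestPoolStatistics:
    def test_toy_pool(self):
        pool = pool_of([("S1", 2, {V1: 3, V2: 2}), ("S2", 2, {V1: 4})], raw=9)
        stats = pool_statistics(pool)
        assert (stats["R"], stats["N"], stats["A"]) == (9, 9, 2)
        assert stats["N_j"][V1] == 7
        f = stats["frequencies"]
        s1v1 = f.query("sample == 'S1' and variant == @V1")["F_ij"].iloc[0]
        assert s1v1 == pytest.approx(0.6)

    def test_empty_pool(self):
        stats = pool_statistics(PoolDataset("A", 0, []))
        assert (stats["R"], stats["N"], stats["A"]) == (0, 0, 0)

    def test_frequencies_sum_to_one_per_sample(self):
        pool = pool_of([("S1", 2, {V1: 3, V2: 2, V3: 5}), ("S2", 4, {V2: 7, V3: 1})])
        f = pool_statistics(pool)["frequencies"]
        sums = f.groupby("sample")["F_ij"].sum()
        assert all(abs(s - 1.0) < 1e-12 for s in sums)


class TestReplicateConcordance:
    @staticmethod
    def genotype(sid, variants, status="genotyped"):
        return Genotype(sid, "sp", 2, frozenset(variants), 40, 1.0, status)

    def test_sixty_three_of_sixty_six_rounds_to_95(self):
        gts, pairs = [], []
        for i in range(66):
            a, b = f"A{i}", f"B{i}"
            variants = [V1, V2] if i >= 3 else [V1]  # 3 discordant pairs
            gts.append(self.genotype(a, [V1, V2]))
            gts.append(self.genotype(b, variants))
            pairs.append((a, b))
        rep = replicate_concordance(gts, pairs)
        assert (rep.pairs_genotyped, rep.concordant) == (66, 63)
        assert rep.percent == 95

    def test_identical_pair_concordant(self):
        gts = [self.genotype("a", [V1, V2]), self.genotype("b", [V2, V1])]
        rep = replicate_concordance(gts, [("a", "b")])
        assert rep.concordant == 1

    def test_strict_subset_is_allelic_dropout(self):
        gts = [self.genotype("a", [V1, V2]), self.genotype("b", [V1])]
        rep = replicate_concordance(gts, [("a", "b")])
        assert rep.discordant == [("a", "b", "allelic_dropout")]

    def test_ungenotyped_member_excluded(self):
        gts = [self.genotype("a", [V1]), self.genotype("b", [], status="insufficient_depth")]
        rep = replicate_concordance(gts, [("a", "b")])
        assert rep.pairs_genotyped == 0

    def test_unknown_sample_id(self):
        with pytest.raises(ValueError, match="unknown sample"):
            replicate_concordance([self.genotype("a", [V1])], [("a", "zzz")])


class TestPipelineInvariants:
    def test_steps_shrink_and_balance(self, design):
        from tagmux.demux import demultiplex_pool
        from tagmux.simulate import DepthModel, SimConfig, SpeciesSpec, simulate

        cfg = SimConfig(
            seed=11,
            species=[SpeciesSpec("sp", m=2, allele_pool_size=12)],
            samples_per_species=25,
            depth=DepthModel(mean=60, shape=5, min_depth=19),
        )
        truth = simulate(cfg)
        res = demultiplex_pool(
            truth.reads, truth.sheet, cfg.design, truth.forward_tags, truth.reverse_tags, "A"
        )
        pool = PoolDataset.from_demux(res, truth.sheet)
        stages = [pool]
        p1, r1 = step1_filter(pool, design)
        p2, r2 = step2_depth_filter(p1)
        p3, r3 = step3_frequency_filter(p2)
        p4, r4, _ = step4_artifact_screen(p3, truth.off_target_pool)
        stages += [p1, p2, p3, p4]
        for before, after, rep in zip(stages, stages[1:], (r1, r2, r3, r4)):
            assert after.N <= before.N
            assert rep.input_sequences == rep.removed_sequences + rep.retained_sequences
            assert rep.retained_sequences == after.N
            before_variants = set(before.variant_counts)
            assert set(after.variant_counts) <= before_variants
        # post-step-3: every retained F_ij >= T2
        for s in p3.samples:
            assert all(c / s.n_i >= 0.04 for c in s.counts.values())
        # post-step-4: every surviving sample at or above T1
        for s in p4.samples:
            assert s.n_i >= 19

    def test_validate_pool_records_eliminated_samples(self, design):
        pool = pool_of([("Sa", 2, {V1: 50, V2: 40}), ("Sb", 2, {V1: 5, V2: 5})])
        result = validate_pool(pool, design, drop_singletons=False)
        by_id = {g.sample: g for g in result.genotypes}
        assert by_id["Sa"].status == "genotyped"
        assert by_id["Sb"].status == "insufficient_depth"
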