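import numpy as np
import pytest

from glyloop import (
    DomainPartition,
    GeneratorParams,
    IndexStyle,
    central_unknown_fraction,
    degrade_with_unknowns,
    detect_gly_loops,
    generate_duplicate_pair,
    generate_loricrin_protein,
    loop_profile,
    permutation_test,
    polymorphic_columns,
)
from glyloop.records import PROTEIN_ALPHABET


class TestGenerateProtein:
    def test_same_seed_identical(self):
        params = GeneratorParams(seed=13)
        r1, _ = generate_loricrin_protein(params)
        r2, _ = generate_loricrin_protein(params)
        assert r1.residues == r2.residues

    def test_different_seeds_differ(self):
        r1, _ = generate_loricrin_protein(GeneratorParams(seed=1))
        r2, _ = generate_loricrin_protein(GeneratorParams(seed=2))
        assert r1.residues != r2.residues

    @pytest.mark.parametrize("style", list(IndexStyle))
    def test_planted_loops_recovered(self, style):
        params = GeneratorParams(
            n_loops=10, loop_size_sampler=("uniform", 4, 8), index_style=style, seed=31
        )
        rec, truth = generate_loricrin_protein(params)
        a, b = truth.central_span
        loops = detect_gly_loops(rec.residues[a:b])
        assert [(a + lp.start, a + lp.end, lp.size) for lp in loops] == truth.planted_loops

    def test_full_sequence_detection_matches_truth(self):
        # termini are engineered not to contribute loops of their own
        params = GeneratorParams(n_loops=12, seed=17)
        rec, truth = generate_loricrin_protein(params)
        loops = detect_gly_loops(rec.residues)
        assert [(lp.start, lp.end, lp.size) for lp in loops] == truth.planted_loops

    def test_no_loops(self):
        params = GeneratorParams(n_loops=0, seed=3)
        rec, truth = generate_loricrin_protein(params)
        a, b = truth.central_span
        assert detect_gly_loops(rec.residues[a:b]) == []

    def test_alphabet_and_truth_invariants(self):
        params = GeneratorParams(n_loops=15, seed=23)
        rec, truth = generate_loricrin_protein(params)
        assert set(rec.residues) <= PROTEIN_ALPHABET
        a, b = truth.central_span
        assert 0 <= a <= b <= len(rec)
        prev_end = a
        for start, end, size in truth.planted_loops:
            assert a <= start < end <= b
            assert end - start == size
            assert start >= prev_end
            prev_end = end

    def test_fixed_sampler_cycles_sizes(self):
        params = GeneratorParams(n_loops=4, loop_size_sampler=("fixed", [5, 9]), seed=2)
        _, truth = generate_loricrin_protein(params)
        assert [s for _, _, s in truth.planted_loops] == [5, 9, 5, 9]

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GeneratorParams(loop_size_sampler=("uniform", 0, 4))
        with pytest.raises(ValueError):
            GeneratorParams(loop_alphabet_weights=(0, 0, 0, 0))
        with pytest.raises(ValueError):
            GeneratorParams(n_loops=-1)


class TestDegrade:
    def test_zero_fraction_identity(self):
        rec, truth = generate_loricrin_protein(GeneratorParams(seed=5))
        assert degrade_with_unknowns(rec, 0.0, "anywhere", seed=1).residues == rec.residues

    def test_central_only_hits_target(self):
        rec, truth = generate_loricrin_protein(
            GeneratorParams(n_loops=10, loop_size_sampler=("uniform", 6, 12), seed=6)
        )
        deg = degrade_with_unknowns(rec, 0.30, "central_only", seed=2, truth=truth)
        a, b = truth.central_span
        part = DomainPartition(a=a, b=b, length=len(rec))
        assert abs(central_unknown_fraction(deg, part) - 0.30) <= 1.0 / (b - a)
        # nothing outside the central span was touched
        assert "X" not in deg.residues[:a] and "X" not in deg.residues[b:]

    def test_spacer_degradation_preserves_profile(self):
        for seed in range(5):
            rec, truth = generate_loricrin_protein(
                GeneratorParams(n_loops=10, loop_size_sampler=("uniform", 5, 10), seed=seed)
            )
            if not truth.spacer_positions:
                continue
            deg = degrade_with_unknowns(rec, 0.5, "spacers_only", seed=seed, truth=truth)
            a, b = truth.central_span
            clean = loop_profile(detect_gly_loops(rec.residues[a:b]))
            degraded = loop_profile(detect_gly_loops(deg.residues[a:b]))
            assert degraded == clean

    def test_deterministic(self):
        rec, truth = generate_loricrin_protein(GeneratorParams(seed=8))
        d1 = degrade_with_unknowns(rec, 0.4, "central_only", seed=3, truth=truth)
        d2 = degrade_with_unknowns(rec, 0.4, "central_only", seed=3, truth=truth)
        assert d1.residues == d2.residues

    def test_invalid_fraction(self):
        rec, truth = generate_loricrin_protein(GeneratorParams(seed=8))
        with pytest.raises(ValueError):
            degrade_with_unknowns(rec, 1.0, "anywhere", seed=1)

    def test_empty_region_raises(self):
        rec, truth = generate_loricrin_protein(GeneratorParams(n_loops=1, seed=9))
        truth.spacer_positions = []
        with pytest.raises(ValueError, match="achievable"):
            degrade_with_unknowns(rec, 0.5, "spacers_only", seed=1, truth=truth)


class TestDuplicatePair:
    def test_zero_divergence_identical(self):
        grp, truth = generate_duplicate_pair(GeneratorParams(seed=4), divergence=0.0, seed=1)
        assert grp.rows[0] == grp.rows[1]
        assert polymorphic_columns(grp) == []

    def test_divergence_within_binomial_bounds(self):
        diffs = []
        n = None
        for rep in range(100):
            grp, _ = generate_duplicate_pair(
                GeneratorParams(n_loops=6, seed=rep), divergence=0.2, seed=1000 + rep
            )
            n = grp.length
            d = sum(a != b for a, b in zip(grp.rows[0], grp.rows[1])) / n
            diffs.append(d)
        # substitutions may be masked by none here (no Ns), so the observed
        # fraction is binomial(n, 0.2) per replicate
        mean = np.mean(diffs)
        sd = np.sqrt(0.2 * 0.8 / n) / np.sqrt(100)
        assert abs(mean - 0.2) < 3 * np.sqrt(0.2 * 0.8 / n)

    def test_planted_tract_is_homogenized(self):
        grp, truth = generate_duplicate_pair(
            GeneratorParams(n_loops=8, seed=10), divergence=0.3, tract=(0.4, 60), seed=11
        )
        ts, te = truth.planted_tract
        assert grp.rows[0][ts:te] == grp.rows[1][ts:te]

    def test_tract_too_long_rejected(self):
        with pytest.raises(ValueError):
            generate_duplicate_pair(
                GeneratorParams(n_loops=2, seed=1), divergence=0.1, tract=(0.9, 10_000), seed=2
            )

    def test_invalid_divergence(self):
        with pytest.raises(ValueError):
            generate_duplicate_pair(GeneratorParams(seed=1), divergence=0.8, seed=1)

    def test_cds_length_is_three_times_protein(self):
        params = GeneratorParams(n_loops=5, seed=12)
        rec, _ = generate_loricrin_protein(params, record_id="dup")
        grp, _ = generate_duplicate_pair(params, divergence=0.1, seed=13)
        assert grp.length == 3 * len(rec)


class TestPipelineSmoke:
    def test_end_to_end_under_budget(self):
        import time

        from glyloop import (
            DefectFlags,
            assess,
            composition_vector,
            partition_domains,
        )
        from glyloop.compstats import UnknownFractionError

        t0 = time.time()
        assessed = kept = 0
        for i in range(50):
            params = GeneratorParams(
                n_loops=8, loop_size_sampler=("uniform", 6, 12), seed=i
            )
            rec, truth = generate_loricrin_protein(params, record_id=f"rec{i}")
            deg = degrade_with_unknowns(
                rec, 0.05 * (i % 4), "central_only", seed=i, truth=truth
            )
            part = partition_domains(deg)
            a, b = part.central
            loops = detect_gly_loops(deg.residues[a:b])
            assess(deg, part, loops, DefectFlags(), len(rec))
            assessed += 1
            try:
                composition_vector(deg)
                kept += 1
            except UnknownFractionError:
                pass
        grp, _ = generate_duplicate_pair(params, divergence=0.2, tract=(0.3, 90), seed=99)
        frags = permutation_test(grp, n_permutations=300, seed=7, mismatch_penalty=8.0)
        assert assessed == 50
        assert 0 < kept <= 50
        assert frags[0].p_value is not None
        assert time.time() - t0 < 60
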