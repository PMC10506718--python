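"""Profile scoring, pairwise alignment, E-value calibration, expansion."""

import numpy as np
import pytest
from _helpers import naive_local_affine

from nemamp.io_formats import AMINO_ACIDS, ProteinRecord, SeedSet
from nemamp.seq_search import (
    align_local,
    align_score,
    build_profile,
    calibrate_evalue,
    calibrate_pairwise,
    iterative_expand,
    random_background_sequence,
    reciprocal_top5,
    score_profile,
    score_profile_full,
    shuffle_sequence,
)


def make_seed(rows, group="Cecropin"):
    recs = tuple(
        ProteinRecord(id=f"s{i}", sequence=r.replace("-", "")) for i, r in enumerate(rows)
    )
    return SeedSet(group=group, sequences=recs, alignment=tuple(rows))


class TestBuildProfile:
    def test_identical_ungapped_seeds_give_one_state_per_column(self):
        model = build_profile(make_seed(["MKVLHEAGAW"] * 3))
        assert model.n_states == 10
        argmax = [AMINO_ACIDS[int(np.argmax(e[:20]))] for e in model.emissions]
        assert "".join(argmax) == "MKVLHEAGAW"

    def test_majority_gap_column_is_not_a_match_state(self):
        rows = ["MKVL-EAGAW", "MKVL-EAGAW", "MKVLHEAGAW"]
        model = build_profile(make_seed(rows))
        assert model.n_states == 9  # the 2/3-gap column is dropped

    def test_single_sequence_seed_is_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_profile(make_seed(["MKVLHEAGAW"]))


class TestScoreProfile:
    def test_training_sequence_beats_its_shuffles(self, seed_sets, rng):
        seed = seed_sets[0]
        model = build_profile(seed)
        target = seed.sequences[0].sequence
        own = score_profile(model, target)
        shuffled = [
            score_profile(model, shuffle_sequence(target, rng)) for _ in range(100)
        ]
        assert own > max(shuffled)

    def test_every_seed_beats_the_shuffle_null_95th_percentile(self, seed_sets, rng):
        for seed in seed_sets:
            model = build_profile(seed)
            for rec in seed.sequences:
                null = [
                    score_profile(model, shuffle_sequence(rec.sequence, rng))
                    for _ in range(40)
                ]
                assert score_profile(model, rec.sequence) > np.percentile(null, 95)

    def test_all_x_sequence_scores_zero(self, seed_sets):
        model = build_profile(seed_sets[0])
        assert score_profile(model, "X" * 80) == 0.0

    def test_score_is_local_under_random_flanks(self, seed_sets, rng):
        model = build_profile(seed_sets[0])
        core = seed_sets[0].sequences[0].sequence
        base = score_profile(model, core)
        flank = random_background_sequence(100, rng)
        flanked = score_profile(model, flank + core + flank)
        assert flanked >= base - 1e-9  # flanks can only add, never lose the core
        assert abs(flanked - base) <= 0.5

    def test_full_traceback_agrees_with_fast_score(self, seed_sets, rng):
        model = build_profile(seed_sets[1])
        for rec in seed_sets[1].sequences:
            fast = score_profile(model, rec.sequence)
            full, (tstart, tend), n_states = score_profile_full(model, rec.sequence)
            assert abs(fast - full) < 1e-6
            assert 0 <= tstart < tend <= rec.length
            assert 1 <= n_states <= model.n_states


class TestEvalueCalibration:
    def test_evalue_strictly_decreasing_in_score(self, seed_sets, rng):
        model = build_profile(seed_sets[0])
        cal = calibrate_evalue(model, 10_000, rng)
        scores = np.linspace(0, 50, 20)
        evs = [cal.evalue(s) for s in scores]
        assert all(a > b for a, b in zip(evs, evs[1:]))

    def test_evalue_linear_in_db_size(self, seed_sets, rng):
        model = build_profile(seed_sets[0])
        cal = calibrate_evalue(model, 10_000, rng)
        assert cal.evalue(20.0, 20_000) == pytest.approx(2 * cal.evalue(20.0, 10_000))

    def test_median_decoy_score_has_half_tail_evalue(self, seed_sets):
        """At the empirical decoy-median score the fitted model should
        predict about half the decoys as chance hits (factor 2)."""
        model = build_profile(seed_sets[1])
        cal = calibrate_evalue(model, 200 * 150, np.random.default_rng(1))
        fresh = np.random.default_rng(2)
        scores = [
            score_profile(model, random_background_sequence(150, fresh))
            for _ in range(200)
        ]
        e_at_median = cal.evalue(float(np.median(scores)))
        assert 50 <= e_at_median <= 200  # expected 100 = 200 * 0.5

    def test_degenerate_score_variance_is_an_error(self, seed_sets, rng):
        model = build_profile(seed_sets[0])
        dead = type(model)(
            group=model.group,
            emissions=np.full_like(model.emissions, -100.0),
            match_columns=model.match_columns,
        )
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_evalue(dead, 1000, rng)


class TestAlignLocal:
    def test_self_alignment_sums_diagonal_blosum62(self):
        # H8+E5+A4+G6+A4+W11+G6+H8+E5+E5 = 62
        assert align_local("HEAGAWGHEE", "HEAGAWGHEE").score == 62

    def test_empty_sequence_scores_zero(self):
        assert align_local("", "HEAGAWGHEE").score == 0
        assert align_local("HEAG", "").score == 0

    def test_score_is_symmetric(self, rng):
        for _ in range(20):
            a = random_background_sequence(int(rng.integers(5, 40)), rng)
            b = random_background_sequence(int(rng.integers(5, 40)), rng)
            assert align_score(a, b) == align_score(b, a)

    def test_equals_naive_dp_oracle_on_random_pairs(self, rng):
        """Exact integer score equality against the independent Gotoh
        dynamic-programming oracle on 100 random pairs (length <= 40)."""
        for _ in range(100):
            a = random_background_sequence(int(rng.integers(1, 41)), rng)
            b = random_background_sequence(int(rng.integers(1, 41)), rng)
            assert align_local(a, b).score == naive_local_affine(a, b)

    def test_intervals_cover_the_aligned_region(self):
        aln = align_local("MMMMHEAGAWGHEEKKK", "HEAGAWGHEE")
        assert aln.a_interval == (4, 14)
        assert aln.b_interval == (0, 10)


class TestIterativeExpand:
    @staticmethod
    def _db(ids_seqs):
        return [ProteinRecord(id=i, sequence=s) for i, s in ids_seqs]

    def test_transitive_chain_found_in_two_rounds(self):
        db = self._db([("a", "MA"), ("b", "MC"), ("c", "MD"), ("z", "ME")])
        sim = {"a": {"b"}, "b": {"a", "c"}, "c": {"b"}, "z": set()}
        got, rounds, converged = iterative_expand(
            {"a"}, db, accept=lambda r: True,
            search_fn=lambda q, _db: sim[q.id], max_rounds=10,
        )
        assert got == {"a", "b", "c"}
        assert rounds == 2 and converged

    def test_no_acceptable_hits_is_a_fixed_point(self):
        db = self._db([("a", "MA"), ("b", "MC")])
        got, rounds, converged = iterative_expand(
            {"a"}, db, accept=lambda r: False,
            search_fn=lambda q, _db: {"b"}, max_rounds=10,
        )
        assert got == {"a"} and rounds == 0 and converged

    def test_result_independent_of_database_order(self, rng):
        pairs = [(f"p{i}", "M" + "ACDEFGHIKL"[i % 10] * 3) for i in range(12)]
        sim = {f"p{i}": {f"p{(i + 1) % 12}"} for i in range(12)}
        db = self._db(pairs)
        runs = []
        for _ in range(3):
            perm = list(db)
            rng.shuffle(perm)
            got, _, _ = iterative_expand(
                {"p0"}, perm, accept=lambda r: int(r.id[1:]) < 6,
                search_fn=lambda q, _db: sim[q.id], max_rounds=20,
            )
            runs.append(got)
        assert runs[0] == runs[1] == runs[2]

    def test_idempotent_at_fixed_point(self):
        db = self._db([("a", "MA"), ("b", "MC"), ("c", "MD")])
        sim = {"a": {"b"}, "b": {"c"}, "c": set()}
        got1, _, _ = iterative_expand(
            {"a"}, db, lambda r: True, lambda q, _db: sim[q.id], 10
        )
        got2, rounds2, _ = iterative_expand(
            got1, db, lambda r: True, lambda q, _db: sim[q.id], 10
        )
        assert got2 == got1 and rounds2 == 0

    def test_max_rounds_exhaustion_is_flagged(self):
        db = self._db([(f"p{i}", "MA") for i in range(6)])
        sim = {f"p{i}": {f"p{i + 1}"} for i in range(5)}
        sim["p5"] = set()
        got, rounds, converged = iterative_expand(
            {"p0"}, db, lambda r: True, lambda q, _db: sim[q.id], max_rounds=2
        )
        assert rounds == 2 and not converged


class TestReciprocalTop5:
    @pytest.fixture()
    def cal(self):
        return calibrate_pairwise(np.random.default_rng(9))

    def test_identical_to_known_grsp_passes(self, cal, rng):
        g = "GG".join("YNQFS") + "GGYGGN" * 8
        refs = [ProteinRecord(id="grsp1", sequence=g)] + [
            ProteinRecord(id=f"other{i}", sequence=random_background_sequence(80, rng))
            for i in range(6)
        ]
        cand = ProteinRecord(id="cand", sequence=g)
        assert reciprocal_top5(cand, refs, {"grsp1"}, cal)

    def test_five_better_non_grsp_hits_fail(self, cal, rng):
        fam = random_background_sequence(90, rng)
        refs = [
            ProteinRecord(id=f"fam{i}", sequence=fam) for i in range(5)
        ] + [ProteinRecord(id="grsp1", sequence="GGYGGN" * 12)]
        cand = ProteinRecord(id="cand", sequence=fam)
        assert not reciprocal_top5(cand, refs, {"grsp1"}, cal)

    def test_all_grsp_reference_of_five_always_passes(self, cal, rng):
        refs = [
            ProteinRecord(id=f"g{i}", sequence="GGYGGN" * (8 + i)) for i in range(5)
        ]
        cand = ProteinRecord(id="cand", sequence=random_background_sequence(60, rng))
        assert reciprocal_top5(cand, refs, {f"g{i}" for i in range(5)}, cal)

    def test_empty_reference_db_is_an_error(self, cal):
        with pytest.raises(ValueError):
            reciprocal_top5(ProteinRecord(id="c", sequence="MA"), [], set(), cal)
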