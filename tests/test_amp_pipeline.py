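"""End-to-end pipeline behaviour: rules, determinism, expansion, rescan."""

import numpy as np
import pytest

from nemamp.amp_pipeline import (
    PipelineConfig,
    relatives_rescan,
    rule_cecropin,
    rule_grsp,
    rule_motif_group,
    run_pipeline,
)
from nemamp.io_formats import AMP_GROUPS, ProteinRecord, read_candidates, write_candidates
from nemamp.seq_search import calibrate_pairwise
from nemamp.synthetic_data import (
    SimConfig,
    default_grsp_reference,
    default_seed_sets,
    generate_study,
    make_decoy,
    plant_amp,
)


@pytest.fixture(scope="module")
def small_result(small_study, seed_sets, motifs):
    return run_pipeline(
        small_study.all_proteins(),
        seed_sets,
        motifs=motifs,
        domains=small_study.domains,
        config=PipelineConfig(seed=11),
    )


@pytest.fixture(scope="module")
def pairwise_cal():
    return calibrate_pairwise(np.random.default_rng(2))


class TestGroupRules:
    def test_cecropin_needs_evalue_and_coverage(self):
        cfg = PipelineConfig()
        assert rule_cecropin(1e-5, 0.9, cfg)
        assert not rule_cecropin(0.02, 0.9, cfg)       # E too high
        assert not rule_cecropin(0.009, 0.2, cfg)      # coverage too low

    def test_motif_rule_accepts_planted_rejects_wrong_spacing(self, motifs, rng):
        rec, _ = plant_amp("Diapausin", None, rng)
        ok, evidence = rule_motif_group(rec, "Diapausin", motifs)
        assert ok and evidence["matches"]
        dec, _ = make_decoy("cys_rich_wrong_spacing", rng)
        assert not rule_motif_group(dec, "Diapausin", motifs)[0]

    def test_nemapore_extra_domain_exclusion(self, motifs, rng):
        rec, _ = make_decoy("saplip_extra_domain", rng)
        ok, evidence = rule_motif_group(
            rec, "Nemapore", motifs, extra_domains={"SaposinB", "Kunitz"}
        )
        assert not ok and evidence["excluded_by_domains"] == ["Kunitz"]
        # the same protein without the extra annotation is acceptable
        assert rule_motif_group(rec, "Nemapore", motifs, extra_domains={"SaposinB"})[0]

    def test_grsp_rule_accepts_planted_and_rejects_no_sp(self, rng, pairwise_cal):
        refs, known = default_grsp_reference()
        rec, _ = plant_amp("GRSP", None, rng)
        ok, checks = rule_grsp(rec, refs, known, pairwise_cal)
        assert ok, checks
        dec, _ = make_decoy("glycine_rich_no_sp", rng)
        ok2, checks2 = rule_grsp(dec, refs, known, pairwise_cal)
        assert not ok2 and not checks2["grsp_signal_peptide"]

    def test_grsp_rule_rejects_250aa_glycine_rich(self, rng, pairwise_cal):
        refs, known = default_grsp_reference()
        dec, _ = make_decoy("glycine_rich_long", rng)
        ok, checks = rule_grsp(dec, refs, known, pairwise_cal)
        assert not ok and not checks["grsp_length"]
        assert checks["grsp_signal_peptide"] and checks["grsp_glycine"]


class TestRunPipeline:
    def test_empty_proteome_is_an_error(self, seed_sets, motifs):
        with pytest.raises(ValueError):
            run_pipeline([], seed_sets, motifs=motifs)

    def test_recovers_planted_and_rejects_decoys(self, small_study, small_result):
        ids = small_result.ids_by_group()
        truth = small_study.truth_by_id()
        for g in AMP_GROUPS:
            planted = {t.id for t in small_study.truth if t.planted_group == g}
            assert planted <= ids[g], f"{g}: planted AMP missed"
        all_found = set().union(*ids.values())
        decoy_hits = {
            i for i in all_found if truth[i].planted_group not in AMP_GROUPS
        }
        assert len(decoy_hits) <= 0.1 * len(all_found)

    def test_rerun_is_deterministic(self, small_study, seed_sets, motifs, small_result):
        again = run_pipeline(
            small_study.all_proteins(), seed_sets, motifs=motifs,
            domains=small_study.domains, config=PipelineConfig(seed=11),
        )
        rows_a = [c.to_row() for c in small_result.candidates]
        rows_b = [c.to_row() for c in again.candidates]
        assert rows_a == rows_b

    def test_tightening_the_e_gate_never_adds_candidates(
        self, small_study, seed_sets, motifs
    ):
        loose = run_pipeline(
            small_study.all_proteins(), seed_sets, motifs=motifs,
            domains=small_study.domains,
            config=PipelineConfig(seed=11, e_gate=0.01),
        )
        tight = run_pipeline(
            small_study.all_proteins(), seed_sets, motifs=motifs,
            domains=small_study.domains,
            config=PipelineConfig(seed=11, e_gate=0.001),
        )
        loose_ids = loose.ids_by_group()
        tight_ids = tight.ids_by_group()
        for g in ("Cecropin", "Diapausin", "CSab", "Nemapore"):
            assert tight_ids[g] <= loose_ids[g]

    def test_corpus_without_diapausins_yields_none(self, seed_sets, motifs):
        cfg = SimConfig(
            seed=19, n_genomes=1, n_decoys_per_genome=60,
            planted_per_group={g: 4 for g in AMP_GROUPS if g != "Diapausin"},
        )
        study = generate_study(cfg)
        res = run_pipeline(
            study.all_proteins(), seed_sets, motifs=motifs,
            domains=study.domains, config=PipelineConfig(seed=19),
        )
        assert res.ids_by_group()["Diapausin"] == set()

    def test_report_carries_audit_and_checksum(self, small_result):
        assert small_result.report["audit_pass"] is True
        assert small_result.report["motif_checksum"]
        assert small_result.report["config"]["e_gate"] == 0.01

    def test_incomplete_candidates_are_retained_flagged(
        self, seed_sets, motifs
    ):
        cfg = SimConfig(
            seed=23, n_genomes=1, n_decoys_per_genome=40,
            planted_per_group={"Diapausin": 6}, truncate_fraction=1.0,
        )
        study = generate_study(cfg)
        res = run_pipeline(
            study.all_proteins(), seed_sets, motifs=motifs,
            domains=study.domains, config=PipelineConfig(seed=23),
        )
        dia = res.by_group("Diapausin")
        assert dia, "truncated Diapausins should still be found via their motif"
        assert all(not c.complete for c in dia)


class TestCandidateTable:
    def test_tsv_roundtrip_preserves_fields(self, small_result, tmp_path):
        path = tmp_path / "cands.tsv"
        write_candidates(small_result.candidates, path)
        df = read_candidates(path)
        assert len(df) == len(small_result.candidates)
        by_id_group = {
            (c.record.id, c.group): c for c in small_result.candidates
        }
        for row in df.itertuples(index=False):
            c = by_id_group[(row.id, row.group)]
            assert row.complete == c.complete
            assert row.n_saposin_domains == c.n_saposin_domains
            assert row.sp_cleavage == (c.maturation.sp_cleavage or 0)
            assert row.mature_seq == c.maturation.mature_seq

    def test_motif_span_serialized_1based(self, small_result, tmp_path):
        cand = next(c for c in small_result.candidates if c.motif_matches)
        row = cand.to_row()
        first = cand.motif_matches[0]
        assert row["motif_span"] == f"{first.start + 1}-{first.end}"


class TestRelativesRescan:
    def test_rescue_and_confirmed_null(self, small_study, small_result, seed_sets, motifs):
        rng = np.random.default_rng(31)
        rescued_rec, _ = plant_amp("Diapausin", None, rng, record_id="g99_dia", genome_id="g99")
        filler = [
            make_decoy("random", rng, record_id=f"g99_dec{i}", genome_id="g99")[0]
            for i in range(10)
        ]
        null_genome = [
            make_decoy("random", rng, record_id=f"g98_dec{i}", genome_id="g98")[0]
            for i in range(10)
        ]
        proteomes = {
            gid: [r for r in small_study.proteomes[gid]]
            for gid in small_study.proteomes
        }
        proteomes["g99"] = [rescued_rec] + filler
        proteomes["g98"] = null_genome
        n_before = len(small_result.candidates)
        flags = relatives_rescan(
            small_result, proteomes,
            neighbor_map={"g99": ["g01", "g02"], "g98": ["g01", "g02"]},
            motifs=motifs, domains=small_study.domains,
            config=PipelineConfig(seed=11),
        )
        assert flags["g99"]["Diapausin"] == "rescued"
        assert flags["g98"]["Diapausin"] == "confirmed_null"
        rescued = [c for c in small_result.candidates if c.rescued]
        assert any(c.record.id == "g99_dia" for c in rescued)
        # rescued hits still had to pass the motif rule: nothing from the
        # all-decoy genome was admitted
        assert not any(c.record.genome_id == "g98" for c in rescued)
        assert len(small_result.candidates) > n_before
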