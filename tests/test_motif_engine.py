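"""Cysteine-array matching, its brute-force oracle, and CSab calls."""

import numpy as np
import pytest

from nemamp.motif_engine import (
    MotifDefinition,
    brute_force_motif_oracle,
    classify_csab,
    count_saposin_domains,
    csab_arrays,
    default_motifs,
    find_motif,
    load_motifs,
    motif_checksum,
)
from nemamp.synthetic_data import plant_amp


def build_array(spacers, pre="NNN", post="NNN", fill="A"):
    """Sequence with cysteines at exactly the given spacings."""
    return pre + "C" + "C".join(fill * s for s in spacers) + "C" + post


class TestFindMotif:
    def test_planted_diapausin_has_one_six_cysteine_match(self, motifs, rng):
        rec, _ = plant_amp("Diapausin", None, rng)
        matches = find_motif(rec.sequence, motifs["Diapausin"])
        assert len(matches) == 1
        assert len(matches[0].positions) == 6

    def test_tandem_arrays_give_two_matches(self, motifs):
        dia = motifs["Diapausin"]
        spacers = [(lo + hi) // 2 for lo, hi in dia.spacers]
        one = build_array(spacers, pre="", post="")
        seq = "NNN" + one + "A" * 20 + one + "NNN"  # twelve cysteines in total
        matches = find_motif(seq, dia)
        assert len(matches) == 2

    def test_spacer_one_below_minimum_gives_no_match(self, motifs):
        dia = motifs["Diapausin"]
        spacers = [(lo + hi) // 2 for lo, hi in dia.spacers]
        spacers[2] = dia.spacers[2][0] - 1
        assert find_motif(build_array(spacers), dia) == []

    def test_spacer_windows_may_not_contain_cysteine(self, motifs):
        dia = motifs["Diapausin"]
        spacers = [(lo + hi) // 2 for lo, hi in dia.spacers]
        seq = build_array(spacers)
        # replace the middle of the third spacer with a cysteine: the run
        # of consecutive cysteines is broken, so the array cannot match
        cys = [i for i, aa in enumerate(seq) if aa == "C"]
        mid = (cys[2] + cys[3]) // 2
        broken = seq[:mid] + "C" + seq[mid + 1:]
        assert find_motif(broken, dia) == []

    def test_x_cannot_stand_for_a_cysteine(self, motifs):
        dia = motifs["Diapausin"]
        spacers = [(lo + hi) // 2 for lo, hi in dia.spacers]
        seq = build_array(spacers)
        first_c = seq.index("C")
        assert find_motif(seq[:first_c] + "X" + seq[first_c + 1:], dia) == []

    def test_x_inside_spacer_is_allowed(self, motifs):
        dia = motifs["Diapausin"]
        spacers = [(lo + hi) // 2 for lo, hi in dia.spacers]
        seq = build_array(spacers, fill="X")
        assert len(find_motif(seq, dia)) == 1


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_sequences(self, motifs, rng):
        """The scanning matcher equals exhaustive enumeration + greedy
        reduction on 500 seeded sequences (length <= 120, <= 20 Cys).
        Half the corpus has near-array cysteine runs planted (spacers
        drawn one residue beyond each bound) so both genuine matches and
        near-misses are exercised."""
        defs = list(motifs.values())
        alphabet = list("ADEFGHIKLMNPQRSTVWY")  # background without C
        n_with_match = 0
        for i in range(500):
            m = defs[i % len(defs)]
            seq = "".join(rng.choice(alphabet, size=int(rng.integers(8, 20))))
            if i % 2:
                spacers = [
                    int(rng.integers(max(0, lo - 1), hi + 2)) for lo, hi in m.spacers
                ]
                seq += "C" + "C".join(
                    "".join(rng.choice(alphabet, size=s)) for s in spacers
                ) + "C"
            seq += "".join(rng.choice(alphabet, size=int(rng.integers(4, 15))))
            seq = seq[:120]
            if seq.count("C") > 20:
                continue
            got = find_motif(seq, m)
            want = brute_force_motif_oracle(seq, m)
            assert [g.positions for g in got] == [w.positions for w in want]
            n_with_match += bool(got)
        assert n_with_match > 20  # the comparison must exercise real matches

    def test_oracle_on_zero_cysteines(self, motifs):
        assert brute_force_motif_oracle("A" * 50, motifs["Diapausin"]) == []

    def test_exact_minimum_spacers_match(self, motifs):
        dia = motifs["Diapausin"]
        seq = build_array([lo for lo, _ in dia.spacers])
        assert len(find_motif(seq, dia)) == 1
        assert len(brute_force_motif_oracle(seq, dia)) == 1

    def test_guard_on_cysteine_count(self, motifs):
        with pytest.raises(ValueError, match="guard"):
            brute_force_motif_oracle("C" * 30, motifs["Diapausin"])


class TestMatchValidation:
    def test_reported_matches_revalidate(self, motifs, rng):
        rec, _ = plant_amp("Nemapore", None, rng, n_domains=3)
        for m in find_motif(rec.sequence, motifs["SaposinB"]):
            m.validate(rec.sequence, motifs["SaposinB"])


class TestClassifyCsab:
    @pytest.mark.parametrize(
        "subgroup,n_cys",
        [("MND", 8), ("TID", 6), ("Macin", 10), ("Drosomycin", 8), ("MND_6Cys", 6)],
    )
    def test_planted_subgroups_classify_uniquely(self, motifs, subgroup, n_cys):
        rng = np.random.default_rng(3)
        for _ in range(10):
            rec, _ = plant_amp("CSab", subgroup, rng)
            call = classify_csab(rec.sequence, csab_arrays(motifs))
            assert call.subgroup == subgroup
            assert len(call.match.positions) == n_cys

    def test_no_cysteines_gives_no_call(self, motifs):
        call = classify_csab("MKLA" * 20, csab_arrays(motifs))
        assert call.subgroup is None and not call.is_ambiguous

    def test_ambiguity_is_reported_never_tie_broken(self, motifs):
        """A sequence carrying two different reference arrays in tandem
        matches both and must be reported as ambiguous."""
        mnd = motifs["MND"]
        tid = motifs["TID"]
        part1 = build_array([(lo + hi) // 2 for lo, hi in mnd.spacers], post="")
        part2 = build_array([(lo + hi) // 2 for lo, hi in tid.spacers], pre="")
        call = classify_csab(part1 + "A" * 30 + part2, csab_arrays(motifs))
        assert call.is_ambiguous
        assert set(call.ambiguous) == {"MND", "TID"}


class TestSaposinCounting:
    def test_single_domain(self, motifs, rng):
        rec, _ = plant_amp("Nemapore", None, rng, n_domains=1)
        assert count_saposin_domains(rec.sequence, motifs["SaposinB"]) == 1

    def test_seven_domain_concatemer(self, motifs, rng):
        rec, truth = plant_amp("Nemapore", None, rng, n_domains=7)
        assert truth.n_saposin_domains == 7
        assert count_saposin_domains(rec.sequence, motifs["SaposinB"]) == 7

    def test_scattered_cysteines_count_zero(self, motifs):
        seq = "AAC" + "A" * 30 + "C" + "A" * 17 + "C" + "A" * 40 + "CC"
        assert count_saposin_domains(seq, motifs["SaposinB"]) == 0


class TestDefinitions:
    def test_packaged_arrays_have_expected_cysteine_counts(self, motifs):
        expected = {
            "Diapausin": 6, "MND": 8, "TID": 6, "Macin": 10,
            "Drosomycin": 8, "MND_6Cys": 6, "SaposinB": 6,
        }
        assert {n: m.n_cys for n, m in motifs.items()} == expected

    def test_checksum_is_stable_and_content_sensitive(self, motifs):
        again = default_motifs()
        assert motif_checksum(motifs) == motif_checksum(again)
        tweaked = dict(motifs)
        d = motifs["Diapausin"]
        tweaked["Diapausin"] = MotifDefinition(
            name="Diapausin", n_cys=d.n_cys,
            spacers=tuple((lo, hi + 1) for lo, hi in d.spacers),
            connectivity=d.connectivity,
        )
        assert motif_checksum(tweaked) != motif_checksum(motifs)

    def test_invalid_definition_rejected(self):
        with pytest.raises(ValueError):
            MotifDefinition(name="bad", n_cys=3, spacers=((2, 1), (0, 3)))
        with pytest.raises(ValueError):
            MotifDefinition(
                name="bad", n_cys=4, spacers=((0, 1),) * 3,
                connectivity=((1, 2), (2, 3)),  # index 2 reused
            )

    def test_load_motifs_from_file_roundtrip(self, motifs, tmp_path):
        import json

        payload = {
            "motifs": [
                {
                    "name": m.name, "n_cys": m.n_cys,
                    "spacers": [list(s) for s in m.spacers],
                    "connectivity": [list(c) for c in m.connectivity],
                }
                for m in motifs.values()
            ]
        }
        p = tmp_path / "motifs.json"
        p.write_text(json.dumps(payload))
        assert motif_checksum(load_motifs(p)) == motif_checksum(motifs)
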