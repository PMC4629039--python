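import numpy as np
import pytest

import edlib

from fdsw import (
    AlphabetError,
    FiltrationConfig,
    ProteinSequence,
    ValidationError,
    apply_fdfs,
    build_index,
    ed_bound,
    frequency_distance,
    frequency_vector,
    generate_database,
    random_protein,
)
from fdsw.seqdb import DEFAULT_ALPHABET
from .conftest import random_seq


class TestFrequencyVector:
    def test_empty_sequence(self):
        fv = frequency_vector("")
        assert fv.length == 0
        assert (fv.counts == 0).all()

    def test_direct_counting(self):
        fv = frequency_vector("AAC")
        assert fv["A"] == 2 and fv["C"] == 1 and fv["D"] == 0
        assert fv.length == 3

    def test_order_invariance(self, rng):
        s = random_seq(rng, 50)
        perm = "".join(rng.permutation(list(s)))
        assert frequency_vector(s) == frequency_vector(perm)

    def test_out_of_alphabet_residue(self):
        with pytest.raises(AlphabetError, match="position 2"):
            frequency_vector("A1C")


class TestFrequencyDistance:
    def test_identical_vectors_zero_under_both(self):
        fv = frequency_vector("ACDWY")
        assert frequency_distance(fv, fv, "max_signed_sums") == 0
        assert frequency_distance(fv, fv, "l1") == 0

    def test_single_substitution(self):
        fu, fv = frequency_vector("AAAA"), frequency_vector("AAAC")
        assert frequency_distance(fu, fv, "max_signed_sums") == 1
        assert frequency_distance(fu, fv, "l1") == 2

    def test_anagrams_are_indistinguishable(self):
        assert frequency_distance(
            frequency_vector("AC"), frequency_vector("CA")
        ) == 0

    def test_symmetry(self, rng):
        fu = frequency_vector(random_seq(rng, 30))
        fv = frequency_vector(random_seq(rng, 45))
        for definition in ("max_signed_sums", "l1"):
            assert frequency_distance(fu, fv, definition) == \
                frequency_distance(fv, fu, definition)

    def test_alphabet_mismatch(self):
        fu = frequency_vector("AC", alphabet="AC")
        fv = frequency_vector("AC")
        with pytest.raises(AlphabetError):
            frequency_distance(fu, fv)

    def test_unknown_definition(self):
        fv = frequency_vector("AC")
        with pytest.raises(ValidationError):
            frequency_distance(fv, fv, "hamming")

    def test_l1_overshoots_edit_distance(self):
        """The L1 form counts one substitution twice, so it is not a
        valid edit-distance lower bound — why max_signed_sums is the
        default."""
        fu, fv = frequency_vector("ACDE"), frequency_vector("ACDF")
        assert frequency_distance(fu, fv, "l1") == 2  # but ED is 1


class TestEdBound:
    def test_decile_arithmetic(self):
        assert ed_bound(1028, 0.90) == 102

    def test_extremes(self):
        assert ed_bound(100, 1.0) == 0
        assert ed_bound(100, 0.0) == 100

    def test_float_artifact_guard(self):
        # (1 - 0.9) * 1030 is 102.999... in binary floating point
        assert ed_bound(1030, 0.90) == 103

    def test_monotone_in_threshold(self):
        bounds = [ed_bound(517, t / 100) for t in range(0, 101, 5)]
        assert bounds == sorted(bounds, reverse=True)

    def test_threshold_out_of_range(self):
        with pytest.raises(ValidationError):
            ed_bound(100, 1.5)
        with pytest.raises(ValidationError):
            ed_bound(100, -0.1)


def _substituted(query, t, rng, alphabet=DEFAULT_ALPHABET):
    """t point substitutions at distinct positions, any different residue."""
    residues = list(query)
    for pos in rng.choice(len(query), size=t, replace=False):
        pool = alphabet.replace(residues[pos], "")
        residues[pos] = pool[int(rng.integers(len(pool)))]
    return "".join(residues)


class TestApplyFdfs:
    def _db(self, seqs):
        return build_index(seqs)

    def test_longer_sequences_are_exempt(self, rng):
        query = random_protein(100, rng)
        longer = ProteinSequence("long", random_seq(rng, 150))
        db = self._db([longer])
        res = apply_fdfs(frequency_vector(query.residues), 100, db,
                         FiltrationConfig(0.99))
        (rec,) = res.records
        assert rec.selected and rec.reason == "length_exempt"
        assert rec.fd is None

    def test_query_against_itself_always_selected(self, rng):
        query = random_protein(80, rng)
        db = self._db([ProteinSequence("self", query.residues)])
        for theta in (0.0, 0.5, 1.0):
            res = apply_fdfs(frequency_vector(query.residues), 80, db,
                             FiltrationConfig(theta))
            (rec,) = res.records
            assert rec.selected and rec.fd == 0

    def test_equal_length_sequences_are_filtered_not_exempt(self, rng):
        query = random_protein(60, rng)
        other = ProteinSequence("far", "W" * 60)
        res = apply_fdfs(frequency_vector(query.residues), 60,
                         self._db([other]), FiltrationConfig(0.9))
        (rec,) = res.records
        assert rec.reason in ("fd_pass", "fd_reject")
        assert not rec.selected  # all-W is nowhere near a random query

    def test_threshold_zero_selects_everything(self, rng):
        query = random_protein(50, rng)
        db = self._db(generate_database(query, 50, rng))
        res = apply_fdfs(frequency_vector(query.residues), 50, db,
                         FiltrationConfig(0.0))
        assert res.ratio == 100.0

    def test_threshold_one_selects_only_fd_zero_and_exempt(self, rng):
        query = random_protein(50, rng)
        seqs = generate_database(query, 50, rng) + [
            ProteinSequence("long", random_seq(rng, 70))
        ]
        db = self._db(seqs)
        res = apply_fdfs(frequency_vector(query.residues), 50, db,
                         FiltrationConfig(1.0))
        for rec in res.records:
            assert rec.selected == (rec.fd == 0 or rec.reason == "length_exempt")

    def test_length_exempt_count(self, rng):
        query = random_protein(60, rng)
        seqs = [
            ProteinSequence(f"s{i}", random_seq(rng, int(rng.integers(30, 90))))
            for i in range(100)
        ]
        db = self._db(seqs)
        res = apply_fdfs(frequency_vector(query.residues), 60, db,
                         FiltrationConfig(0.8))
        n_exempt = sum(r.reason == "length_exempt" for r in res.records)
        assert n_exempt == sum(len(s) > 60 for s in seqs)

    def test_preserves_database_order(self, rng):
        query = random_protein(40, rng)
        db = self._db(generate_database(query, 30, rng))
        res = apply_fdfs(frequency_vector(query.residues), 40, db,
                         FiltrationConfig(0.5))
        assert [r.id for r in res.records] == [s.id for s in db.entries]

    def test_empty_database(self, rng, caplog):
        query = random_protein(40, rng)
        res = apply_fdfs(frequency_vector(query.residues), 40,
                         self._db([]), FiltrationConfig(0.5))
        assert res.ratio == 0.0 and res.records == []

    def test_report_tsv(self, rng, tmp_path):
        query = random_protein(50, rng)
        seqs = generate_database(query, 10, rng) + [
            ProteinSequence("long", random_seq(rng, 80))
        ]
        res = apply_fdfs(frequency_vector(query.residues), 50,
                         self._db(seqs), FiltrationConfig(0.9))
        out = tmp_path / "report.tsv"
        res.to_tsv(out)
        lines = out.read_text().splitlines()
        assert lines[0] == "seq_id\tlength\tfd\tselected\treason"
        assert len(lines) == len(seqs) + 1
        na_rows = [l for l in lines[1:] if "\tNA\t" in l]
        assert len(na_rows) == 1 and na_rows[0].endswith("length_exempt")


class TestLowerBoundAndLosslessness:
    """FD(max_signed_sums) <= Hamming distance t and <= true edit
    distance; hence equal-length sequences at identity >= theta are
    never rejected at threshold theta."""

    def test_fd_bounded_by_t_and_edit_distance(self, rng):
        query = random_protein(100, rng)
        qfv = frequency_vector(query.residues)
        for _ in range(400):
            t = int(rng.integers(0, 101))
            mutant = _substituted(query.residues, t, rng)
            fd = frequency_distance(qfv, frequency_vector(mutant))
            ed = edlib.align(query.residues, mutant)["editDistance"]
            assert fd <= t
            assert fd <= ed

    def test_no_false_negatives_at_threshold(self, rng):
        theta = 0.9
        query = random_protein(100, rng)
        qfv = frequency_vector(query.residues)
        bound = ed_bound(100, theta)
        cfg = FiltrationConfig(theta)
        seqs = []
        for i in range(700):
            t = int(rng.integers(0, 101))
            seqs.append(
                ProteinSequence(f"m{t}_{i}", _substituted(query.residues, t, rng))
            )
        db = build_index(seqs)
        res = apply_fdfs(qfv, 100, db, cfg)
        by_id = {r.id: r for r in res.records}
        for seq in seqs:
            hamming = sum(a != b for a, b in zip(query.residues, seq.residues))
            identity = 1 - hamming / 100
            if identity >= theta:
                assert by_id[seq.id].selected, (
                    f"{seq.id}: identity {identity} rejected"
                )

    def test_ratio_monotone_in_threshold(self, rng):
        query = random_protein(60, rng)
        db = build_index(generate_database(query, 200, rng))
        qfv = frequency_vector(query.residues)
        ratios = [
            apply_fdfs(qfv, 60, db, FiltrationConfig(t / 20)).ratio
            for t in range(21)
        ]
        assert all(a >= b for a, b in zip(ratios, ratios[1:]))
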