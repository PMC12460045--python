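"""RPKM / RUSCG / geometric mean / GAM / CV / TPM / CPM arithmetic."""

from __future__ import annotations

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uscgam.abundance import (
    AbundanceError,
    cpm,
    cv,
    family_ruscg,
    gam,
    gene_rg,
    geometric_mean,
    rpkm,
    tpm,
)
from uscgam.alignment import AlignmentHit
from uscgam.sequence_stats import SampleReadStats

from conftest import make_uscg_db


def hit_to(subject, slen, q):
    return AlignmentHit(
        query_id=q, subject_id=subject, percent_identity=97.0, alignment_length=40,
        evalue=1e-12, bitscore=80.0, query_coverage=95.0, subject_length_aa=slen,
    )


class TestRpkm:
    @pytest.mark.parametrize(
        "mrc,trc,length,expected",
        [(10, 1_000_000, 1_000, 10.0), (0, 10, 10, 0.0),
         (25, 5_000_000, 500, 10.0)],
    )
    def test_examples(self, mrc, trc, length, expected):
        assert rpkm(mrc, trc, length) == pytest.approx(expected)

    def test_zero_denominators_rejected(self):
        with pytest.raises(AbundanceError):
            rpkm(1, 0, 100)
        with pytest.raises(AbundanceError):
            rpkm(1, 100, 0)

    @given(mrc=st.integers(0, 10**6), trc=st.integers(1, 10**8),
           length=st.integers(1, 10**5))
    @settings(max_examples=100, derandomize=True)
    def test_linear_in_mrc_inverse_in_trc(self, mrc, trc, length):
        base = rpkm(mrc, trc, length)
        assert rpkm(2 * mrc, trc, length) == pytest.approx(2 * base)
        assert rpkm(mrc, 2 * trc, length) == pytest.approx(base / 2)


class TestFamilyRuscg:
    def test_single_reference_tally(self):
        # 6 hits to a 100-aa reference at TRC 1e6: 6e9 / (1e6 * 300) = 20
        db = make_uscg_db({name: 100 for name in make_uscg_db().family_names})
        stats = SampleReadStats(sample_id="s", trc=1_000_000, n_discarded_short=0)
        hits = [hit_to("USCG_S7", 100, f"r{i}") for i in range(6)]
        profile = family_ruscg(hits, db, stats)
        assert profile.ruscg["S7"] == pytest.approx(20.0)

    def test_family_without_hits_is_zero(self, uscg_db):
        stats = SampleReadStats(sample_id="s", trc=1_000_000, n_discarded_short=0)
        profile = family_ruscg([], uscg_db, stats)
        assert all(v == 0.0 for v in profile.ruscg.values())

    def test_multi_reference_family_sums_per_subject_rpkm(self):
        # two members of one family: 100 aa with 3 hits (10.0) + 200 aa with
        # 3 hits (5.0) -> RUSCG 15.0; brute-force per-subject tally oracle
        db = make_uscg_db()
        fam = db.families[0]
        extra = "USCG_extra"
        fam.member_seq_ids.append(extra)
        db.seq_lengths_aa["USCG_" + fam.family_name] = 100
        db.seq_lengths_aa[extra] = 200
        db.seq_to_family[extra] = fam.family_name
        stats = SampleReadStats(sample_id="s", trc=1_000_000, n_discarded_short=0)
        hits = [hit_to("USCG_" + fam.family_name, 100, f"a{i}") for i in range(3)]
        hits += [hit_to(extra, 200, f"b{i}") for i in range(3)]
        profile = family_ruscg(hits, db, stats)
        # independent oracle: tally per subject, then RPKM, then sum
        per_subject = {}
        for h in hits:
            per_subject[h.subject_id] = per_subject.get(h.subject_id, 0) + 1
        expected = sum(
            n * 1e9 / (stats.trc * db.seq_lengths_aa[s] * 3)
            for s, n in per_subject.items()
        )
        assert expected == pytest.approx(15.0)
        assert profile.ruscg[fam.family_name] == pytest.approx(expected)

    def test_unknown_subject_rejected(self, uscg_db):
        stats = SampleReadStats(sample_id="s", trc=1_000, n_discarded_short=0)
        with pytest.raises(Exception, match="mystery"):
            family_ruscg([hit_to("mystery", 50, "r0")], uscg_db, stats)


class TestGeometricMean:
    def test_constant_vector_is_identity(self):
        assert geometric_mean([3.5] * 14) == pytest.approx(3.5)

    def test_two_values(self):
        assert geometric_mean([1.0, 4.0]) == pytest.approx(2.0)

    def test_zero_under_na_policy(self):
        vals = [0.0] + [5.0] * 13
        assert math.isnan(geometric_mean(vals, zero_policy="na"))

    def test_zero_under_error_policy(self):
        with pytest.raises(AbundanceError):
            geometric_mean([0.0, 5.0], zero_policy="error")

    def test_zero_under_pseudocount_policy(self):
        got = geometric_mean([0.0, 4.0], zero_policy="pseudocount", pseudocount=1.0)
        assert got == pytest.approx(2.0)

    def test_empty_and_negative_rejected(self):
        with pytest.raises(AbundanceError):
            geometric_mean([])
        with pytest.raises(AbundanceError):
            geometric_mean([1.0, -2.0])

    @given(st.lists(st.floats(1e-6, 1e6), min_size=14, max_size=14))
    @settings(max_examples=200, derandomize=True)
    def test_bounded_by_extremes_and_below_arithmetic_mean(self, vals):
        g = geometric_mean(vals)
        assert min(vals) * (1 - 1e-12) <= g <= max(vals) * (1 + 1e-12)
        assert g <= sum(vals) / len(vals) * (1 + 1e-12)

    @given(st.lists(st.floats(1e-3, 1e3), min_size=14, max_size=14),
           st.randoms(use_true_random=False))
    @settings(max_examples=100, derandomize=True)
    def test_log_space_matches_naive_product_and_permutation(self, vals, rnd):
        naive = math.prod(vals) ** (1.0 / len(vals))
        assert geometric_mean(vals) == pytest.approx(naive, rel=1e-10)
        shuffled = list(vals)
        rnd.shuffle(shuffled)
        assert geometric_mean(shuffled) == pytest.approx(geometric_mean(vals), rel=1e-12)


class TestGam:
    @pytest.mark.parametrize("rg,mruscg,expected", [(5.0, 10.0, 50.0), (0.0, 7.0, 0.0)])
    def test_examples(self, rg, mruscg, expected):
        assert gam(rg, mruscg) == pytest.approx(expected)

    def test_na_propagation(self):
        assert math.isnan(gam(5.0, float("nan")))
        assert math.isnan(gam(5.0, 0.0))

    def test_uscg_scored_as_gene_gives_100_percent(self):
        # if every family has the same RUSCG x, MRUSCG = x and a "gene" with
        # RG = x sits at exactly one copy per genome
        x = 17.3
        mruscg = geometric_mean([x] * 14)
        assert gam(x, mruscg) == pytest.approx(100.0)


class TestCv:
    def test_constant_is_zero(self):
        assert cv([4.2] * 14) == pytest.approx(0.0)

    def test_closed_form_pair(self):
        assert cv([1.0, 3.0]) == pytest.approx(math.sqrt(2) / 2)

    def test_population_sd_variant(self):
        assert cv([1.0, 3.0], use_sample_sd=False) == pytest.approx(0.5)

    def test_n_below_two_rejected(self):
        with pytest.raises(AbundanceError):
            cv([1.0])

    def test_nonpositive_mean_is_na(self):
        assert math.isnan(cv([0.0, 0.0]))


class TestTpmCpm:
    def test_single_gene_gets_the_million(self):
        assert tpm({"g": 7}, {"g": 500})["g"] == pytest.approx(1e6)
        assert cpm({"g": 7})["g"] == pytest.approx(1e6)

    def test_equal_counts_equal_lengths_split_evenly(self):
        out = tpm({"a": 5, "b": 5}, {"a": 300, "b": 300})
        assert out["a"] == pytest.approx(5e5) and out["b"] == pytest.approx(5e5)
        out = cpm({"a": 1, "b": 1, "c": 1, "d": 1})
        assert all(v == pytest.approx(2.5e5) for v in out.values())

    def test_all_zero_rejected(self):
        with pytest.raises(AbundanceError):
            tpm({"a": 0}, {"a": 100})
        with pytest.raises(AbundanceError):
            cpm({"a": 0})

    def test_mismatched_keys_rejected(self):
        with pytest.raises(AbundanceError):
            tpm({"a": 1}, {"b": 100})

    def test_tpm_sums_to_one_million_on_random_tables(self):
        rng = random.Random(3)
        for _ in range(50):
            n = rng.randrange(1, 40)
            counts = {f"g{i}": rng.randrange(0, 1000) for i in range(n)}
            counts[f"g{rng.randrange(n)}"] = rng.randrange(1, 1000)  # >=1 positive
            lengths = {g: rng.randrange(100, 5000) for g in counts}
            total = sum(tpm(counts, lengths).values())
            assert total == pytest.approx(1e6, rel=1e-6)


def test_gene_rg_grouping_and_passthrough_equivalence():
    stats = SampleReadStats(sample_id="s", trc=2_000_000, n_discarded_short=0)
    # 12 hits to one 200-aa subject: 12e9 / (2e6 * 600) = 10
    hits = [hit_to("geneA|ref1", 200, f"r{i}") for i in range(12)]
    out = gene_rg(hits, {"geneA|ref1": 200}, stats)
    assert out == {"geneA": pytest.approx(10.0)}
    # two subjects of one gene sum
    hits += [hit_to("geneA|ref2", 100, f"x{i}") for i in range(3)]
    out = gene_rg(hits, {"geneA|ref1": 200, "geneA|ref2": 100}, stats)
    assert out["geneA"] == pytest.approx(10.0 + 3 * 1e9 / (2_000_000 * 300))

    with pytest.raises(AbundanceError, match="no known length"):
        gene_rg([hit_to("orphan", 50, "r0")], {}, stats)
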