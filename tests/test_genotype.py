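"""Length rules, consensus calling, phasing and diploid genotype calls."""

import math
import random

import numpy as np
import pytest

import zfarray as z
from zfarray.genotype import (
    NO_CALL,
    LengthFrequencyTable,
    PhaseResult,
    phase_equal_length,
)


def _table(freqs: dict[int, float], total: int = 1000) -> LengthFrequencyTable:
    return LengthFrequencyTable({k: max(1, round(v * total)) for k, v in freqs.items()})


class TestLengthRules:
    @pytest.mark.parametrize(
        "freqs,rule,lengths",
        [
            ({13: 1.0}, 1, (13, 13)),
            ({13: 0.40, 14: 0.35, 15: 0.25}, 2, (13, 14)),
            ({14: 0.50, 13: 0.22, 12: 0.08, 15: 0.08, 11: 0.07, 10: 0.05}, 3, (14, 13)),
            ({13: 0.72, 12: 0.20, 14: 0.08}, 4, (13, 13)),
            # f_i/f_j exactly 3 escapes both rule 3 (<3) and rule 4 (>3)
            ({13: 0.72, 12: 0.24, 14: 0.04}, 5, (13, 13)),
        ],
    )
    def test_rule_rows(self, freqs, rule, lengths):
        call = z.infer_lengths(_table(freqs))
        assert call.rule == rule
        assert call.hap_lengths == lengths

    def test_no_call_when_no_rule_fires(self):
        call = z.infer_lengths(_table({13: 0.40, 12: 0.25, 14: 0.20, 11: 0.15}))
        assert call is NO_CALL or call.rule is None

    def test_two_lengths_treats_fk_as_zero(self):
        # f_j/f_k = +inf > 2, so rule 3 can fire with only two lengths
        call = z.infer_lengths(LengthFrequencyTable({14: 50, 13: 20}))
        assert call.rule == 3 and call.hap_lengths == (14, 13)

    def test_tie_breaks_toward_smaller_length(self):
        t = LengthFrequencyTable({14: 40, 13: 40, 12: 20})
        (li, _), (lj, _), _ = t.top_freqs()
        assert (li, lj) == (13, 14)

    def test_tracer_equivalence_random_tables(self):
        """infer_lengths matches an independent rule-by-rule tracer."""

        def tracer(counts: dict[int, int]):
            total = sum(counts.values())
            ranked = sorted(counts, key=lambda L: (-counts[L], L))
            f = [counts[L] / total for L in ranked]
            i = ranked[0]
            if len(ranked) == 1:
                return 1, (i, i)
            j = ranked[1]
            fi, fj = f[0], f[1]
            fk = f[2] if len(ranked) > 2 else 0.0
            if fi + fj >= 0.7 and fi / fj < 2:
                return 2, (i, j)
            if fi + fj >= 0.7 and fi / fj < 3 and (fk == 0 or fj / fk > 2):
                return 3, (i, j)
            if fi + fj >= 0.7 and fi / fj > 3:
                return 4, (i, i)
            if fi >= 0.7:
                return 5, (i, i)
            return None, None

        rng = random.Random(12345)
        for _ in range(2000):
            n_lengths = rng.randint(1, 6)
            counts = {}
            for _ in range(n_lengths):
                counts[rng.randint(8, 20)] = rng.randint(1, 200)
            table = LengthFrequencyTable(counts)
            call = z.infer_lengths(table)
            rule, lengths = tracer(counts)
            assert (call.rule, call.hap_lengths) == (rule, lengths)


class TestCoverageGate:
    @pytest.mark.parametrize("n,expected", [(99, False), (100, True), (0, False)])
    def test_boundary(self, n, expected):
        obs = [
            z.ArrayObservation(f"r{i}", "", ("A" * 84,), 1.0, 1.0, "+")
            for i in range(n)
        ]
        assert z.coverage_gate(obs) is expected


class TestConsensus:
    def test_identical_sequences(self):
        prof = z.build_consensus(["ACGTACGT"] * 10)
        assert prof.consensus == "ACGTACGT"
        assert np.all(prof.f_c == 1.0)

    def test_seven_three_split(self):
        seqs = ["A"] * 7 + ["C"] * 3
        prof = z.build_consensus(seqs)
        assert prof.consensus == "A"
        assert prof.f_c[0] == pytest.approx(0.7)

    def test_ns_excluded_from_denominator(self):
        seqs = ["A"] * 4 + ["C"] * 4 + ["N"] * 2
        prof = z.build_consensus(seqs)
        assert prof.f_c[0] == pytest.approx(0.5)  # denominator 8, not 10

    def test_all_n_position_flagged(self):
        prof = z.build_consensus(["N", "N"])
        assert prof.consensus == "N"
        assert math.isnan(prof.f_c[0])


class TestPhasing:
    def _mix(self, s1, s2, n1, n2):
        return [s1] * n1 + [s2] * n2

    def test_balanced_het_recovered(self):
        s1 = "A" * 30
        s2 = "A" * 10 + "C" + "A" * 9 + "G" + "A" * 8 + "T"
        res = phase_equal_length(self._mix(s1, s2, 25, 25))
        assert res.status == "het"
        assert set(res.consensi) == {s1, s2}
        assert sorted(res.supports) == [25, 25]

    def test_all_identical_is_hom(self):
        res = phase_equal_length(["ACGT" * 5] * 40)
        assert res.status == "hom"
        assert res.consensi == ("ACGT" * 5,)

    def test_stray_error_cluster_ignored(self):
        """A small third cluster of error sequences does not displace the
        two true haplotype clusters."""
        s1 = "A" * 40
        s2 = "A" * 20 + "C" * 20
        noise = "G" * 40
        seqs = [s1] * 24 + [s2] * 24 + [noise] * 2
        res = phase_equal_length(seqs)
        assert res.status == "het"
        assert set(res.consensi) == {s1, s2}

    def test_duplicated_single_allele_matches_hom_path(self):
        """Feeding the het machinery duplicated single-allele data gives the
        same answer as the hom path."""
        allele = "ACGT" * 21
        res = phase_equal_length([allele] * 60)
        assert res.status == "hom" and res.consensi[0] == allele


class TestCallGenotype:
    def _obs_from(self, catalog, pair, n, seed, **em_kwargs):
        em = z.ErrorModel(**em_kwargs) if em_kwargs else z.ERROR_FREE
        reads, _ = z.simulate_reads("i", pair, n, error_model=em, seed=seed,
                                    with_barcodes=False)
        obs, _ = z.extract_all(reads, z.FlankAnchors(), catalog)
        return obs

    def test_unequal_het_recovers_both_named_alleles(self, sim_catalog):
        byn = {a.n_zf: a for a in sim_catalog.alleles.values()}
        lens = sorted(byn)
        a, b = byn[lens[0]], byn[lens[-1]]
        assert a.n_zf != b.n_zf
        obs = self._obs_from(sim_catalog, (a.dna, b.dna), 200, seed=21)
        g = z.call_genotype("i", obs, sim_catalog)
        assert g.qc_pass and g.zygosity == "het_unequal_length"
        assert {c.name for c in g.alleles} == {a.name, b.name}

    def test_hom_individual(self, sim_catalog):
        a = list(sim_catalog.alleles.values())[0]
        obs = self._obs_from(sim_catalog, (a.dna, a.dna), 150, seed=22)
        g = z.call_genotype("i", obs, sim_catalog)
        assert g.qc_pass and g.zygosity == "hom"
        assert g.alleles[0].dna == g.alleles[1].dna == a.dna

    def test_single_nucleotide_het_with_errors(self, sim_catalog):
        """Equal-length alleles differing by one nucleotide are phased apart
        at 150x even with 1% substitution error."""
        a = list(sim_catalog.alleles.values())[0]
        # silent single-base variant of one finger -> new equal-length allele
        pos = 53  # third base of a serine codon in the scaffold
        other = "T" if a.dna[pos] != "T" else "C"
        b_dna = a.dna[:pos] + other + a.dna[pos + 1 :]
        assert sum(x != y for x, y in zip(a.dna, b_dna)) == 1
        obs = self._obs_from(sim_catalog, (a.dna, b_dna), 150, seed=23,
                             substitution=0.01, insertion=0.0, deletion=0.0,
                             slippage=0.0, truncation=0.0)
        g = z.call_genotype("i", obs, sim_catalog)
        assert g.qc_pass and g.zygosity == "het_equal_length"
        assert set(g.allele_dnas) == {a.dna, b_dna}

    def test_coverage_gate_failure_reported(self, sim_catalog):
        a = list(sim_catalog.alleles.values())[0]
        obs = self._obs_from(sim_catalog, (a.dna, a.dna), 50, seed=24)
        g = z.call_genotype("i", obs, sim_catalog)
        assert not g.qc_pass and g.qc_reason == "insufficient_coverage"


class TestMergePlatformCalls:
    def _geno(self, ind, dnas, zyg="hom", qc=True):
        from zfarray.genotype import AlleleCall, DiploidGenotype, LengthCall

        return DiploidGenotype(
            individual=ind,
            alleles=tuple(AlleleCall(dna=d, name=d[:4], support=10, qc_pass=qc) for d in dnas),
            zygosity=zyg,
            length_call=LengthCall(rule=1, hap_lengths=(1, 1)),
            qc_pass=qc,
        )

    def test_identical_pairs_concordant(self):
        g1 = self._geno("i", ["AAAA" * 21, "CCCC" * 21], "het_equal_length")
        g2 = self._geno("i", ["CCCC" * 21, "AAAA" * 21], "het_equal_length")
        _, rec = z.merge_platform_calls(g1, g2)
        assert rec.concordant and rec.category == "het_equal"

    def test_one_shared_allele_flagged(self):
        g1 = self._geno("i", ["AAAA" * 21, "CCCC" * 21], "het_equal_length")
        g2 = self._geno("i", ["AAAA" * 21, "GGGG" * 21], "het_equal_length")
        _, rec = z.merge_platform_calls(g1, g2)
        assert not rec.concordant and rec.shared_allele

    def test_fully_discordant(self):
        g1 = self._geno("i", ["AAAA" * 21] * 2)
        g2 = self._geno("i", ["GGGG" * 21] * 2)
        _, rec = z.merge_platform_calls(g1, g2)
        assert not rec.concordant and not rec.shared_allele
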