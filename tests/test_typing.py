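"""A/C-type classification, contact residues and cohort statistics."""

import itertools

import pytest

import zfarray as z
from zfarray.genotype import AlleleCall, DiploidGenotype, LengthCall


def _geno(ind, dna1, dna2, qc=True):
    return DiploidGenotype(
        individual=ind,
        alleles=(
            AlleleCall(dna=dna1, name=dna1[:6], support=10, qc_pass=qc),
            AlleleCall(dna=dna2, name=dna2[:6], support=10, qc_pass=qc),
        ),
        zygosity="hom" if dna1 == dna2 else "het_equal_length",
        length_call=LengthCall(rule=1, hap_lengths=(1, 1)),
        qc_pass=qc,
    )


class TestContactProfile:
    def test_identical_fingers_identical_tokens(self, sim_catalog):
        code = list(sim_catalog.fingers)[0]
        allele = sim_catalog.new_allele([code] * 6)
        prof = z.contact_profile(allele)
        assert len(prof.triplets) == 6
        assert len(set(prof.triplets)) == 1
        assert all(len(t) == 3 for t in prof.triplets)

    def test_profile_depends_only_on_codes(self, sim_catalog):
        codes = list(sim_catalog.fingers)[:4]
        a1 = sim_catalog.new_allele(codes)
        a2 = z.Allele(name="copy", zf_codes=list(codes),
                      dna=sim_catalog.build_dna(codes), provenance="synthetic")
        assert z.contact_profile(a1).triplets == z.contact_profile(a2).triplets

    def test_single_aa_variant_differs_in_at_most_one_token(self, typed_catalog):
        """An allele differing from the reference by one amino acid (like the
        B allele vs A) changes at most one contact token."""
        catalog, ref_a, _ = typed_catalog
        ref = catalog.alleles[ref_a]
        # substitute one finger's contact residue
        from zfarray.simulate import _CONTACT_AA_POOL_A, _finger_dna
        import random

        rng = random.Random(0)
        prof_ref = z.contact_profile(ref)
        new_token = None
        for cand in itertools.product(_CONTACT_AA_POOL_A, repeat=3):
            tok = "".join(cand)
            if sum(a != b for a, b in zip(tok, prof_ref.triplets[2])) == 1:
                new_token = tok
                break
        dna = _finger_dna(new_token, rng)
        if catalog.finger_by_dna(dna) is None:
            catalog.add_finger(z.ZincFinger(code="xx", dna=dna, is_novel=True))
        codes = list(ref.zf_codes)
        codes[2] = catalog.finger_by_dna(dna).code
        variant = z.Allele(name="Bv", zf_codes=codes,
                           dna=catalog.build_dna(codes), provenance="synthetic")
        diff = sum(
            a != b
            for a, b in zip(prof_ref.triplets, z.contact_profile(variant).triplets)
        )
        assert diff <= 1


class TestClassifyType:
    def test_reflexive(self, typed_catalog):
        catalog, ref_a, ref_c = typed_catalog
        a, c = catalog.alleles[ref_a], catalog.alleles[ref_c]
        sa = z.classify_type(a, a, c)
        sc = z.classify_type(c, a, c)
        assert sa.sim_A == pytest.approx(1.0) and sa.label == "A-type"
        assert sc.sim_C == pytest.approx(1.0) and sc.label == "C-type"

    def test_label_stable_under_code_renaming(self, typed_catalog):
        """Classification depends on residues only, not on ZF codes."""
        catalog, ref_a, ref_c = typed_catalog
        a, c = catalog.alleles[ref_a], catalog.alleles[ref_c]
        some = next(al for al in catalog.alleles.values() if al.name not in (ref_a, ref_c))
        renamed = z.Allele(name="renamed", zf_codes=["q"] * some.n_zf,
                           dna=some.dna, provenance="synthetic")
        s1 = z.classify_type(some, a, c)
        s2 = z.classify_type(renamed, a, c)
        assert (s1.sim_A, s1.sim_C, s1.label) == (s2.sim_A, s2.sim_C, s2.label)

    def test_family_members_recover_their_label(self, typed_catalog):
        catalog, ref_a, ref_c = typed_catalog
        scores = z.label_catalog(catalog, ref_a, ref_c)
        for name, allele in catalog.alleles.items():
            assert scores[name].label == allele.type_label


class TestLengthStats:
    def test_toy_medians(self, typed_catalog):
        catalog, ref_a, ref_c = typed_catalog
        alleles = []
        for i, n in enumerate([13, 13, 13]):
            al = z.Allele(name=f"ga{i}", zf_codes=["x"] * n,
                          dna=catalog.alleles[ref_a].dna[:84] * n,
                          provenance="synthetic", type_label="A-type")
            alleles.append(al)
        for i, n in enumerate([15, 15]):
            al = z.Allele(name=f"gc{i}", zf_codes=["x"] * n,
                          dna=catalog.alleles[ref_c].dna[:84] * n,
                          provenance="synthetic", type_label="C-type")
            alleles.append(al)
        stats = z.length_stats(alleles)
        assert stats["median_A"] == 13 and stats["median_C"] == 15

    def test_identical_groups_p_near_one(self, typed_catalog):
        catalog, ref_a, ref_c = typed_catalog
        unit = catalog.alleles[ref_a].dna[:84]
        alleles = []
        for i, lab in enumerate(["A-type"] * 5 + ["C-type"] * 5):
            alleles.append(
                z.Allele(name=f"e{i}", zf_codes=["x"] * 13, dna=unit * 13,
                         provenance="synthetic", type_label=lab)
            )
        stats = z.length_stats(alleles)
        assert stats["p_value"] == pytest.approx(1.0, abs=0.05)

    def test_empty_group_errors(self, typed_catalog):
        catalog, ref_a, _ = typed_catalog
        unit = catalog.alleles[ref_a].dna[:84]
        only_a = [z.Allele(name="x", zf_codes=["x"] * 3, dna=unit * 3,
                           provenance="synthetic", type_label="A-type")]
        with pytest.raises(ValueError):
            z.length_stats(only_a)


class TestFrequencies:
    def test_all_hom_single_allele(self):
        A = "AAAA" * 21
        recs = z.allele_frequencies({"pop": [_geno(f"i{k}", A, A) for k in range(10)]})
        assert len(recs) == 1
        assert recs[0].count == 20 and recs[0].frequency == 1.0

    def test_toy_counts(self):
        A, C = "AAAA" * 21, "CCCC" * 21
        genos = [_geno(f"i{k}", A, A) for k in range(3)] + [_geno("i3", A, C)]
        recs = z.allele_frequencies({"pop": genos})
        by = {r.allele: r for r in recs}
        assert by[A[:6]].frequency == pytest.approx(7 / 8)
        assert by[C[:6]].frequency == pytest.approx(1 / 8)

    def test_frequencies_sum_to_one_and_cis_bracket(self):
        A, C, G = "AAAA" * 21, "CCCC" * 21, "GGGG" * 21
        genos = [_geno("a", A, C), _geno("b", C, G), _geno("c", G, G), _geno("d", A, A)]
        recs = z.allele_frequencies({"p": genos})
        assert sum(r.frequency for r in recs) == pytest.approx(1.0)
        for r in recs:
            assert r.ci99[0] <= r.frequency <= r.ci99[1]

    def test_qc_failed_individuals_excluded(self):
        A = "AAAA" * 21
        genos = [_geno("a", A, A), _geno("b", A, A, qc=False)]
        recs = z.allele_frequencies({"p": genos})
        assert recs[0].count == 2


class TestHeterozygosity:
    def test_extremes_and_fraction(self):
        A, C = "AAAA" * 21, "CCCC" * 21
        hom = {"p": [_geno(f"h{k}", A, A) for k in range(4)]}
        het = {"p": [_geno(f"e{k}", A, C) for k in range(4)]}
        mix = {"p": [_geno("a", A, C), _geno("b", A, C), _geno("c", A, C), _geno("d", A, A)]}
        assert z.heterozygosity(hom)["p"] == 0.0
        assert z.heterozygosity(het)["p"] == 1.0
        assert z.heterozygosity(mix)["p"] == 0.75


class TestTrio:
    A, B, C, L = "AAAA" * 21, "TTTT" * 21, "CCCC" * 21, "GGGG" * 21

    def test_simple_consistent(self):
        ok, phase = z.trio_concordance(
            _geno("c", self.A, self.C), _geno("m", self.A, self.A),
            _geno("f", self.C, self.L)
        )
        assert ok and phase == (self.A, self.C)

    def test_inconsistent(self):
        ok, _ = z.trio_concordance(
            _geno("c", self.B, self.B), _geno("m", self.A, self.C),
            _geno("f", self.A, self.C)
        )
        assert not ok

    def test_hom_child_consistent(self):
        ok, _ = z.trio_concordance(
            _geno("c", self.A, self.A), _geno("m", self.A, self.C),
            _geno("f", self.A, self.B)
        )
        assert ok

    def test_matches_brute_force_enumeration(self):
        """trio_concordance equals exhaustive checking of the four parental
        assignments over random allele draws."""
        import random

        pool = [self.A, self.B, self.C, self.L]
        rng = random.Random(99)
        for _ in range(300):
            c = [rng.choice(pool), rng.choice(pool)]
            m = [rng.choice(pool), rng.choice(pool)]
            f = [rng.choice(pool), rng.choice(pool)]
            expected = any(
                (c[o] in m) and (c[1 - o] in f) for o in (0, 1)
            )
            got, _ = z.trio_concordance(
                _geno("c", *c), _geno("m", *m), _geno("f", *f)
            )
            assert got == expected


class TestCompareSets:
    def test_identical_sets_full_concordance(self):
        A, C = "AAAA" * 21, "CCCC" * 21
        s = {f"i{k}": _geno(f"i{k}", A, C) for k in range(5)}
        res = z.compare_genotype_sets(s, dict(s))
        assert res["overall_pct"] == 100.0

    def test_disjoint_calls_zero(self):
        A, C, G = "AAAA" * 21, "CCCC" * 21, "GGGG" * 21
        s1 = {"i": _geno("i", A, A)}
        s2 = {"i": _geno("i", C, G)}
        res = z.compare_genotype_sets(s1, s2)
        assert res["overall_pct"] == 0.0
        assert res["discordant"][0]["shared_allele"] is False

    def test_448_of_461_rounds_to_97_2(self):
        A, C = "AAAA" * 21, "CCCC" * 21
        s1, s2 = {}, {}
        for k in range(461):
            s1[f"i{k}"] = _geno(f"i{k}", A, A)
            s2[f"i{k}"] = _geno(f"i{k}", A, A) if k < 448 else _geno(f"i{k}", A, C)
        res = z.compare_genotype_sets(s1, s2)
        assert res["n_concordant"] == 448
        assert round(res["overall_pct"], 1) == 97.2
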