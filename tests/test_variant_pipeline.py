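"""Filtering cascade, triage, carrier summaries and reference comparison."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from germex import variant_pipeline as vp
from germex.io import load_gene_list
from germex.synthetic_data import generate_headline_fixture


def _call(sample="S1", chrom="1", pos=100, t_alt=10, t_tot=30, n_alt=10,
          n_tot=30, zyg="het"):
    return {"sample_id": sample, "chrom": chrom, "pos": pos, "ref": "G",
            "alt": "A", "tumor_alt": t_alt, "tumor_total": t_tot,
            "normal_alt": n_alt, "normal_total": n_tot, "zygosity": zyg}


class TestReadSupportFilter:
    @pytest.mark.parametrize("t_alt,t_tot,n_alt,n_tot,kept", [
        (4, 20, 8, 20, False),    # tumor alt below 5
        (10, 60, 10, 30, False),  # tumor VAF 0.1667 < 0.2
        (5, 25, 5, 25, True),     # boundary VAF 0.2 and alt 5 inclusive
        (8, 20, 0, 0, False),     # zero normal depth rejects
    ])
    def test_threshold_semantics(self, t_alt, t_tot, n_alt, n_tot, kept):
        calls = pd.DataFrame([_call(t_alt=t_alt, t_tot=t_tot,
                                    n_alt=n_alt, n_tot=n_tot)])
        retained, rejected = vp.filter_read_support(calls)
        assert (len(retained) == 1) is kept
        if not kept:
            assert rejected["reason"].iloc[0]

    def test_rejections_carry_reason_codes(self):
        calls = pd.DataFrame([_call(t_alt=4, t_tot=20),
                              _call(sample="S2", t_alt=10, t_tot=60)])
        _, rejected = vp.filter_read_support(calls)
        assert set(rejected["reason"]) == {"tumor_alt_below_5",
                                           "tumor_vaf_below_0.2"}


class TestAcmgRecall:
    def test_recall_path_ignores_vaf_and_respects_gene_list(self, toy_variants):
        toy_variants.loc[0, "gene"] = "RYR1"  # ACMG non-cancer gene
        calls = pd.DataFrame([
            _call(chrom="1", t_alt=5, t_tot=50, n_alt=1, n_tot=50),  # VAF 0.1
            _call(sample="S2", chrom="2", pos=200, t_alt=5, t_tot=50,
                  n_alt=1, n_tot=50),  # same counts, non-listed gene
        ])
        recalled = vp.filter_acmg_recall(calls, toy_variants)
        assert list(recalled["sample_id"]) == ["S1"]

    def test_union_deduplicates(self, toy_variants):
        toy_variants.loc[0, "gene"] = "RYR1"
        call = _call(t_alt=30, t_tot=60, n_alt=30, n_tot=60)
        calls = pd.DataFrame([call])
        retained, _ = vp.filter_read_support(calls)
        recalled = vp.filter_acmg_recall(calls, toy_variants)
        merged = vp.union_calls(retained, recalled)
        assert len(merged) == 1

    def test_empty_gene_set_rejected(self, toy_variants):
        with pytest.raises(ValueError):
            vp.filter_acmg_recall(pd.DataFrame([_call()]), toy_variants, set())


class TestNonCancerTriage:
    def _variants(self, gene="MPO", traits="Myeloperoxidase deficiency"):
        return pd.DataFrame([{
            "chrom": "1", "pos": 100, "ref": "G", "alt": "A",
            "build": "GRCh37", "gene": gene, "function_class": "missense",
            "traits": traits, "classification": "P", "inheritance": "AR",
            "af": 1e-5}])

    def test_cancer_gene_excluded(self):
        retained, excluded = vp.filter_non_cancer(self._variants(gene="BRCA1"))
        assert len(retained) == 0
        assert excluded["reason"].iloc[0] == "gene_on_cancer_list"

    def test_benign_gene_and_trait_retained(self):
        retained, _ = vp.filter_non_cancer(self._variants())
        assert len(retained) == 1

    @pytest.mark.parametrize("trait,kept", [
        ("Melanoma, cutaneous malignant", False),  # -oma token
        ("Glaucoma 1", True),                      # exception list
        ("Malignant tumor of breast", False),      # cancer term
        ("Neoplasia of the colon", False),
        ("Multiple glaucomas observed", True),     # plural exception
    ])
    def test_trait_rules(self, trait, kept):
        retained, _ = vp.filter_non_cancer(self._variants(traits=trait))
        assert (len(retained) == 1) is kept

    def test_filter_order_independence(self, small_cohort):
        tables, _ = small_cohort
        calls, variants = tables["calls"], tables["variants"]
        keep_first, _ = vp.filter_read_support(calls)
        nc_then, _ = vp.filter_non_cancer(variants)
        keys_a = set(vp._vkey(keep_first)) & set(vp._vkey(nc_then))
        nc_first, _ = vp.filter_non_cancer(variants)
        keep_then, _ = vp.filter_read_support(calls)
        keys_b = set(vp._vkey(nc_first)) & set(vp._vkey(keep_then))
        assert keys_a == keys_b


class TestSelectNcPlp:
    def test_keeps_only_p_and_lp(self, toy_variants):
        toy_variants.loc[1, "classification"] = "VUS"
        plp, summary = vp.select_nc_plp(toy_variants)
        assert set(plp["classification"]) == {"P"}
        assert summary["n_unique_variants"] == 1

    def test_empty_input(self):
        plp, summary = vp.select_nc_plp(pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "gene", "classification"]))
        assert len(plp) == 0 and summary["n_unique_variants"] == 0

    def test_headline_counts(self):
        fx = generate_headline_fixture("nc_plp_counts")
        _, summary = vp.select_nc_plp(fx["variants"], fx["calls"])
        assert summary == {"n_unique_variants": 753, "n_genes": 363,
                           "n_sample_variants": 2920}


class TestCarrierSummaries:
    def test_headline_overall_and_inheritance(self):
        fx = generate_headline_fixture("carriers_overall")
        s = vp.summarize_carriers(fx["calls"], fx["variants"], fx["samples"])
        assert s.overall == {"carriers": 2505, "n": 10389, "pct": 24.11}
        pi = s.per_inheritance.set_index("inheritance")["pct"]
        assert pi["AD"] == 2.07 and pi["AR"] == 22.02
        pa = s.per_ancestry.set_index("ancestry")["pct"]
        assert pa["EUR"] == 26.75 and pa["AFR"] == 12.98
        assert pa["EAS"] == 11.66 and pa["AMR_LATINX"] == 15.08

    def test_headline_per_gene_frequency(self):
        fx = generate_headline_fixture("spg7_eur")
        s = vp.summarize_carriers(fx["calls"], fx["variants"], fx["samples"])
        eur = s.per_gene[(s.per_gene["gene"] == "SPG7")
                         & (s.per_gene["ancestry"] == "EUR")]
        assert eur["carriers_ancestry"].iloc[0] == 100
        assert eur["pct_ancestry"].iloc[0] == 1.21

    def test_zero_carriers(self, toy_variants):
        samples = pd.DataFrame([{"sample_id": "S1", "ancestry": "EUR",
                                 "age": 60, "sex": "female",
                                 "cancer_type": "CT00", "tumor_purity": 0.5,
                                 "pc1": 0, "pc2": 0}])
        s = vp.summarize_carriers(
            pd.DataFrame(columns=list(_call().keys())), toy_variants, samples)
        assert s.overall["carriers"] == 0 and s.overall["pct"] == 0.0

    def test_referential_integrity_enforced(self, toy_variants):
        samples = pd.DataFrame([{"sample_id": "S1", "ancestry": "EUR",
                                 "age": 60, "sex": "female",
                                 "cancer_type": "CT00", "tumor_purity": 0.5,
                                 "pc1": 0, "pc2": 0}])
        bad = pd.DataFrame([_call(chrom="9", pos=999)])
        with pytest.raises(vp.ReferentialIntegrityError):
            vp.summarize_carriers(bad, toy_variants, samples)

    def test_ancestry_partition_sums_to_overall(self, small_cohort):
        tables, _ = small_cohort
        plp, _ = vp.select_nc_plp(tables["variants"])
        keys = set(vp._vkey(plp))
        calls = tables["calls"][vp._vkey(tables["calls"]).isin(keys)]
        s = vp.summarize_carriers(calls, plp, tables["samples"])
        assert s.per_ancestry["carriers"].sum() == s.overall["carriers"]
        # per-gene carrier counts never exceed the overall count
        assert (s.per_gene["carriers"] <= s.overall["carriers"]).all()


class TestPopulationSpecific:
    def _summary(self, ancestries):
        fx = generate_headline_fixture("carriers_overall")
        samples = fx["samples"]
        ids = {a: samples[samples["ancestry"] == a]["sample_id"].iloc[0]
               for a in ancestries}
        calls = pd.DataFrame([_call(sample=ids[a], chrom="1", pos=1000)
                              for a in ancestries])
        return vp.summarize_carriers(calls, fx["variants"], samples)

    def test_single_ancestry_flagged(self):
        flags = vp.flag_population_specific(self._summary(["EAS"]))
        assert list(flags["ancestry"]) == ["EAS"]

    @pytest.mark.parametrize("ancestries", [["EUR", "AFR"], ["EUR", "MIX"],
                                            ["MIX"]])
    def test_mixed_or_multi_ancestry_not_flagged(self, ancestries):
        flags = vp.flag_population_specific(self._summary(ancestries))
        assert len(flags) == 0


class TestReferenceComparison:
    def _summary_and_ref(self, cohort_ac=2, n_eur=100, ref_ac=10, ref_an=1000):
        samples = pd.DataFrame([
            {"sample_id": f"S{i}", "ancestry": "EUR", "age": 60,
             "sex": "female", "cancer_type": "CT00", "tumor_purity": 0.5,
             "pc1": 0, "pc2": 0} for i in range(n_eur)])
        variants = pd.DataFrame([{
            "chrom": "1", "pos": 100, "ref": "G", "alt": "A",
            "build": "GRCh37", "gene": "GENE_A", "function_class": "missense",
            "traits": "", "classification": "P", "inheritance": "AR",
            "af": 1e-5}])
        calls = pd.DataFrame([_call(sample=f"S{i}") for i in range(cohort_ac)])
        summary = vp.summarize_carriers(calls, variants, samples)
        ref = pd.DataFrame([
            {"chrom": "1", "pos": 100, "ref": "G", "alt": "A",
             "build": "GRCh37", "population": "NFE",
             "allele_count": ref_ac, "allele_number": ref_an}])
        return summary, ref

    def test_proportional_table_gives_p_one(self):
        summary, ref = self._summary_and_ref(cohort_ac=2, n_eur=100,
                                             ref_ac=10, ref_an=1000)
        per_variant, _ = vp.compare_to_reference(summary, ref)
        assert per_variant["p"].iloc[0] == pytest.approx(1.0)
        assert per_variant["cohort_an"].iloc[0] == 200  # 2 alleles per sample

    def test_fisher_matches_enumeration(self):
        summary, ref = self._summary_and_ref(cohort_ac=3, n_eur=50,
                                             ref_ac=0, ref_an=1000)
        per_variant, _ = vp.compare_to_reference(summary, ref)
        expected = scipy.stats.fisher_exact(
            [[3, 97], [0, 1000]], alternative="two-sided")[1]
        assert per_variant["p"].iloc[0] == pytest.approx(expected, rel=1e-7)

    def test_eur_pools_nfe_and_fin(self):
        summary, ref = self._summary_and_ref()
        fin = ref.copy()
        fin["population"] = "FIN"
        both = pd.concat([ref, fin], ignore_index=True)
        per_variant, _ = vp.compare_to_reference(summary, both)
        assert per_variant["ref_an"].iloc[0] == 2000

    def test_perfect_frequency_agreement_gives_r_one(self, small_cohort):
        tables, _ = small_cohort
        plp, _ = vp.select_nc_plp(tables["variants"])
        keys = set(vp._vkey(plp))
        calls = tables["calls"][vp._vkey(tables["calls"]).isin(keys)]
        summary = vp.summarize_carriers(calls, plp, tables["samples"])
        # reference exactly proportional to the cohort: AC = dose, AN = 2n
        vc = summary.variant_carriers
        eur = vc[vc["ancestry"] == "EUR"]
        dose = eur.groupby("key")["sample_id"].nunique()
        n_eur = int(summary.ancestry_sizes["EUR"])
        rows = []
        for key, d in dose.items():
            chrom, pos, ref_a, alt_a = key.split(":")
            rows.append({"chrom": chrom, "pos": int(pos), "ref": ref_a,
                         "alt": alt_a, "build": "GRCh37", "population": "NFE",
                         "allele_count": int(d) * 10,
                         "allele_number": 2 * n_eur * 10})
        per_variant, per_pop = vp.compare_to_reference(
            summary, pd.DataFrame(rows))
        eur_row = per_pop[per_pop["ancestry"] == "EUR"]
        assert eur_row["pearson_r"].iloc[0] == pytest.approx(1.0)
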