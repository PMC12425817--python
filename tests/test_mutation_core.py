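"""Caller integration, the four SNV filters, indel filters, burden, frequencies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from mutscape import mutation_core as mc


def _rec(sample="S1", chrom="chr1", pos=100, ref="C", alt="T", **kw):
    base = dict(
        sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
        variant_class="SNV", gene="G1", consequence="missense", nonsilent=True,
        callers="", t_alt=20, t_ref=80, n_alt=0, n_ref=100,
        alt_fwd=10, alt_rev=10, ref_fwd=40, ref_rev=40,
        site_bq=34.0, flank_bq=34.0, alt_mq=60.0, context="ACA", hp_run=np.nan,
    )
    base.update(kw)
    return base


class TestIntegrateCallers:
    def test_variant_in_all_four_sets_yields_one_record(self):
        call_sets = {c: pd.DataFrame([_rec()]) for c in mc.CALLERS}
        merged = mc.integrate_callers(call_sets)
        assert len(merged) == 1
        assert set(merged.loc[0, "callers"].split(",")) == set(mc.CALLERS)

    def test_min_support_threshold_drops_singletons(self):
        call_sets = {
            "strelka": pd.DataFrame([_rec(pos=100), _rec(pos=200)]),
            "muse": pd.DataFrame([_rec(pos=100)]),
            "vardict": pd.DataFrame(columns=mc.MAF_COLUMNS),
            "mutect": pd.DataFrame(columns=mc.MAF_COLUMNS),
        }
        merged = mc.integrate_callers(call_sets, min_support=2)
        assert list(merged["pos"]) == [100]

    def test_conflicting_ref_alleles_raise(self):
        call_sets = {
            "strelka": pd.DataFrame([_rec(ref="C", alt="A")]),
            "muse": pd.DataFrame([_rec(ref="G", alt="A")]),
        }
        with pytest.raises(mc.DataError):
            mc.integrate_callers(call_sets)

    @given(
        hst.lists(
            hst.tuples(hst.integers(0, 2), hst.integers(100, 110)),
            min_size=0, max_size=25,
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_union_size_matches_brute_force(self, assignments):
        names = ["strelka", "muse", "vardict"]
        sets = {n: [] for n in names}
        for caller_i, pos in assignments:
            sets[names[caller_i]].append(_rec(pos=pos))
        call_sets = {
            n: pd.DataFrame(rows) if rows else pd.DataFrame(columns=mc.MAF_COLUMNS)
            for n, rows in sets.items()
        }
        merged = mc.integrate_callers(call_sets)
        brute = set()
        for n, rows in sets.items():
            for r in rows:
                brute.add((r["sample_id"], r["chrom"], r["pos"], r["ref"], r["alt"]))
        assert len(merged) == len(brute)


class TestFilterSnvs:
    def test_clean_record_passes(self):
        dec = mc.filter_snvs(pd.DataFrame([_rec()]))
        assert bool(dec.loc[0, "passed"]) and dec.loc[0, "reasons"] == ""

    def test_nonsignificant_normal_contingency_fails(self):
        # two-sided Fisher on [[20,80],[10,90]] is 0.0734 >= 0.05
        dec = mc.filter_snvs(pd.DataFrame([_rec(n_alt=10, n_ref=90)]))
        assert dec.loc[0, "reasons"] == "normal_evidence"

    def test_significant_normal_contingency_passes(self):
        dec = mc.filter_snvs(pd.DataFrame([_rec(t_alt=40, t_ref=60, n_alt=1, n_ref=199)]))
        assert bool(dec.loc[0, "passed"])

    def test_one_strand_with_significant_bias_fails(self):
        dec = mc.filter_snvs(
            pd.DataFrame([_rec(t_alt=15, alt_fwd=15, alt_rev=0, ref_fwd=50, ref_rev=50)])
        )
        assert dec.loc[0, "reasons"] == "strand_bias"

    def test_one_strand_few_reads_not_significant_passes(self):
        dec = mc.filter_snvs(
            pd.DataFrame([_rec(t_alt=2, alt_fwd=2, alt_rev=0, ref_fwd=50, ref_rev=50)])
        )
        assert bool(dec.loc[0, "passed"])

    def test_base_quality_drop_and_poor_mapping_accumulate(self):
        dec = mc.filter_snvs(
            pd.DataFrame([_rec(site_bq=20.0, flank_bq=34.0, alt_mq=5.0)])
        )
        assert dec.loc[0, "reasons"] == "base_quality_drop,poor_mapping"

    def test_missing_strand_counts_unevaluable(self):
        dec = mc.filter_snvs(pd.DataFrame([_rec(alt_fwd=np.nan)]))
        assert not dec.loc[0, "evaluable"]
        assert pd.isna(dec.loc[0, "passed"])

    def test_filtering_is_idempotent(self, small_bundle):
        merged = mc.integrate_callers(small_bundle.caller_calls)
        passed, _ = mc.apply_filters(merged)
        passed2, dec2 = mc.apply_filters(passed)
        assert len(passed2) == len(passed)
        assert (dec2["passed"] == True).all()  # noqa: E712


class TestFilterIndels:
    def test_one_bp_insertion_in_long_homopolymer_rejected(self):
        rec = _rec(ref="-", alt="A", variant_class="insertion", hp_run=7)
        dec = mc.filter_indels(pd.DataFrame([rec]))
        assert dec.loc[0, "reasons"] == "homopolymer"

    def test_clean_five_bp_deletion_passes(self):
        rec = _rec(ref="ACGTA", alt="-", variant_class="deletion", hp_run=2)
        dec = mc.filter_indels(pd.DataFrame([rec]))
        assert bool(dec.loc[0, "passed"])

    def test_labeled_fixture_decisions_match(self):
        rows, labels = [], []
        for i in range(10):
            rows.append(_rec(pos=i, ref="-", alt="T", variant_class="insertion", hp_run=8))
            labels.append(False)
        for i in range(10, 20):
            rows.append(_rec(pos=i, ref="AC", alt="-", variant_class="deletion", hp_run=1))
            labels.append(True)
        dec = mc.filter_indels(pd.DataFrame(rows))
        assert list(dec["passed"]) == labels


class TestBurden:
    def test_default_library_size_division(self):
        recs = pd.DataFrame([_rec(pos=i) for i in range(95)])
        out = mc.mutation_burden(recs)
        assert out.loc[0, "snvs_per_mb"] == pytest.approx(95 / 73.499)
        assert not out.loc[0, "hypermutated"]

    def test_exact_boundary_strict_vs_inclusive(self):
        recs = pd.DataFrame([_rec(pos=i) for i in range(735)])
        strict = mc.mutation_burden(recs, target_size_mb=73.5)
        assert strict.loc[0, "snvs_per_mb"] == pytest.approx(10.0)
        assert not strict.loc[0, "hypermutated"]
        inclusive = mc.mutation_burden(recs, target_size_mb=73.5, strict=False)
        assert inclusive.loc[0, "hypermutated"]

    def test_no_mutations_zero_burden(self):
        out = mc.mutation_burden(pd.DataFrame(columns=mc.MAF_COLUMNS), samples=["S1"])
        assert out.loc[0, "snv_count"] == 0 and not out.loc[0, "hypermutated"]

    def test_invalid_target_size(self):
        with pytest.raises(ValueError):
            mc.mutation_burden(pd.DataFrame(columns=mc.MAF_COLUMNS), target_size_mb=0)


class TestGeneFrequency:
    def test_ten_of_462_is_two_percent(self):
        recs = pd.DataFrame([_rec(sample=f"S{i}", gene="PIK3CA") for i in range(10)])
        out = mc.gene_frequency(recs, n_samples=462, min_frequency=0.02)
        assert out.loc[0, "frequency"] == pytest.approx(10 / 462)
        assert len(out) == 1

    def test_sample_counts_once_per_gene(self):
        recs = pd.DataFrame([_rec(pos=p, gene="TP53") for p in (1, 2, 3)])
        out = mc.gene_frequency(recs, n_samples=10)
        assert out.loc[0, "mutated_samples"] == 1

    def test_planted_frequencies_recovered(self, small_bundle):
        truth = small_bundle.truth["planted_gene_counts"]
        out = mc.gene_frequency(
            small_bundle.truth_mutations, n_samples=len(small_bundle.patients)
        ).set_index("gene")
        for gene, count in truth.items():
            assert out.loc[gene, "mutated_samples"] == count


class TestSummarizeClasses:
    @pytest.mark.parametrize(
        "counts, pct_snv, pct_indel",
        [
            ({"total": 39103, "snv": 36059, "indel": 2690}, 92, 7),
            ({"snv": 10, "indel": 0}, 100, 0),
        ],
    )
    def test_integer_rounded_percentages(self, counts, pct_snv, pct_indel):
        out = mc.summarize_classes(counts)
        assert out["pct_snv"] == pct_snv and out["pct_indel"] == pct_indel

    def test_empty_input_zeros(self):
        assert mc.summarize_classes(pd.DataFrame(columns=mc.MAF_COLUMNS))["total"] == 0


class TestVcfReader:
    VCF = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=249250621>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=SB,Number=4,Type=Integer,Description="Strand bias components">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL
chr1\t100\t.\tC\tT\t.\tPASS\t.\tGT:AD:SB\t0/1:80,20:40,40,10,10\t0/0:100,0:50,50,0,0
chr1\t200\t.\tAT\tA\t.\tPASS\t.\tGT:AD\t0/1:90,10\t0/0:95,0
"""

    def test_minimal_somatic_vcf_round_trip(self, tmp_path):
        path = tmp_path / "calls.vcf"
        path.write_text(self.VCF)
        df = mc.read_vcf(path, "TUMOR", "NORMAL", sample_id="S1")
        assert list(df["variant_class"]) == ["SNV", "deletion"]
        snv = df.iloc[0]
        assert (snv["t_alt"], snv["t_ref"], snv["n_alt"]) == (20, 80, 0)
        assert (snv["alt_fwd"], snv["alt_rev"]) == (10, 10)
        dec = mc.filter_snvs(df[df["variant_class"] == "SNV"])
        assert bool(dec.loc[0, "passed"])
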