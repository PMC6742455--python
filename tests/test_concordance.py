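"""Group-specific peaks, allele frequencies, and the compatibility rule."""

import pytest

from mesnp.concordance import (
    CandidateMeSnp,
    SampleGroup,
    candidate_table,
    concordance_filter,
    count_with_min_called,
    enumerate_genotype_states,
    group_allele_frequencies,
    group_specific_peaks,
    methylation_compatibility,
    qtl_overlap,
)
from mesnp.core import CpGContext, MeSnpClass, MeSnpRecord
from mesnp.genomic_io import HET, HOM_ALT, HOM_REF, MISSING, GenomicInterval


def make_group(name, peaks_per_sample):
    sids = [f"{name}_{i}" for i in range(len(peaks_per_sample))]
    return SampleGroup(
        name=name, sample_ids=sids,
        peak_sets={sid: peaks for sid, peaks in zip(sids, peaks_per_sample)},
    )


PEAK = GenomicInterval("chr1", 100, 300)


class TestGroupSpecificPeaks:
    def test_three_of_four_with_absent_other_group_emitted(self):
        a = make_group("A", [[PEAK], [PEAK], [PEAK], []])
        b = make_group("B", [[], [], [], []])
        (region,) = group_specific_peaks(a, b, min_present=3)
        assert (region.chrom, region.start, region.end, region.label) == (
            "chr1", 100, 300, "A",
        )

    def test_two_of_four_not_emitted(self):
        a = make_group("A", [[PEAK], [PEAK], [], []])
        b = make_group("B", [[], [], [], []])
        assert group_specific_peaks(a, b, min_present=3) == []

    def test_any_other_group_presence_vetoes(self):
        a = make_group("A", [[PEAK]] * 4)
        b = make_group("B", [[GenomicInterval("chr1", 299, 400)], [], [], []])
        assert group_specific_peaks(a, b, min_present=3) == []

    def test_intersection_of_staggered_peaks(self):
        a = make_group(
            "A",
            [
                [GenomicInterval("chr1", 100, 300)],
                [GenomicInterval("chr1", 150, 350)],
                [GenomicInterval("chr1", 120, 280)],
                [],
            ],
        )
        b = make_group("B", [[], [], [], []])
        (region,) = group_specific_peaks(a, b, min_present=3)
        assert (region.start, region.end) == (150, 280)

    def test_union_mode_spans_supporting_peaks(self):
        a = make_group(
            "A",
            [
                [GenomicInterval("chr1", 100, 300)],
                [GenomicInterval("chr1", 150, 350)],
                [GenomicInterval("chr1", 120, 280)],
                [],
            ],
        )
        b = make_group("B", [[], [], [], []])
        (region,) = group_specific_peaks(a, b, min_present=3, mode="union")
        assert (region.start, region.end) == (100, 350)

    def test_antisymmetric(self):
        a = make_group("A", [[PEAK]] * 4)
        b = make_group("B", [[PEAK]] * 4)
        regions = group_specific_peaks(a, b, min_present=3)
        assert regions == []  # both groups present -> specific to neither

    def test_min_present_monotonicity(self):
        a = make_group("A", [[PEAK], [PEAK], [PEAK], []])
        b = make_group("B", [[], [], [], []])
        n_by_k = [
            len(group_specific_peaks(a, b, min_present=k)) for k in (1, 2, 3, 4)
        ]
        assert n_by_k == sorted(n_by_k, reverse=True)

    def test_min_present_exceeding_group_size_rejected(self):
        a = make_group("A", [[PEAK]] * 2)
        b = make_group("B", [[PEAK]] * 2)
        with pytest.raises(ValueError):
            group_specific_peaks(a, b, min_present=3)


class TestEnumeration:
    def test_four_samples_four_states(self):
        assert enumerate_genotype_states(4, 4) == 256

    def test_single_sample(self):
        assert enumerate_genotype_states(1, 4) == 4

    def test_min_called_enumeration(self):
        # 3^4 all-called + 4 * 3^3 exactly-one-missing
        assert count_with_min_called(4, 3) == 189
        assert count_with_min_called(4, 0) == 256
        assert count_with_min_called(4, 4) == 81


class TestAlleleFrequencies:
    def test_worked_example_missing_genotype(self):
        """Three hom-ref + one missing vs three het + one missing -> |delta|=0.5."""
        r = group_allele_frequencies(
            [HOM_REF, HOM_REF, HOM_REF, MISSING],
            [HET, HET, HET, MISSING],
            name_g1="HFE", name_g2="LFE",
        )
        assert r.af_g1 == pytest.approx(0 / 6)
        assert r.af_g2 == pytest.approx(3 / 6)
        assert r.abs_delta == pytest.approx(0.5)
        assert (r.n_called_g1, r.n_called_g2) == (3, 3)

    def test_worked_example_full_calls(self):
        """7/8 alt alleles vs 1/8 -> delta 0.75."""
        r = group_allele_frequencies(
            [HOM_ALT, HET, HOM_ALT, HOM_ALT],
            [HOM_REF, HOM_REF, HOM_REF, HET],
        )
        assert r.af_g1 == pytest.approx(7 / 8)
        assert r.af_g2 == pytest.approx(1 / 8)
        assert r.delta == pytest.approx(0.75)

    def test_identical_groups_zero_delta(self):
        gts = [HET, HOM_REF, HOM_ALT, HET]
        r = group_allele_frequencies(gts, list(gts))
        assert r.delta == 0.0

    def test_sample_order_invariance(self):
        g1 = [HOM_ALT, HET, MISSING, HOM_REF]
        r1 = group_allele_frequencies(g1, [HET] * 4)
        r2 = group_allele_frequencies(list(reversed(g1)), [HET] * 4)
        assert r1.af_g1 == r2.af_g1 and r1.n_called_g1 == r2.n_called_g1

    def test_all_missing_group_uncallable(self):
        r = group_allele_frequencies([MISSING] * 4, [HET] * 4)
        assert not r.callable
        assert r.delta is None

    def test_group_label_swap_negates_delta(self):
        g1 = [HOM_ALT] * 4
        g2 = [HOM_REF, HOM_REF, HET, HOM_REF]
        r = group_allele_frequencies(g1, g2, "X", "Y")
        rs = group_allele_frequencies(g2, g1, "Y", "X")
        assert rs.delta == pytest.approx(-r.delta)
        assert rs.abs_delta == pytest.approx(r.abs_delta)


class TestConcordanceFilter:
    def _result(self, af1, af2, n1=3, n2=3):
        from mesnp.concordance import GroupAFResult

        return GroupAFResult("A", "B", af1, af2, n1, n2)

    def test_threshold_boundary(self):
        assert concordance_filter(self._result(0.5, 0.0)) == (True, None)
        passed, reason = concordance_filter(self._result(0.49, 0.0))
        assert not passed and reason == "insufficient_delta"

    def test_insufficient_calls(self):
        passed, reason = concordance_filter(self._result(1.0, 0.0, n1=2))
        assert not passed and reason == "insufficient_calls"


def _mesnp(cls, ref="C", alt="T"):
    ctx = {"ref": ref, "alt": alt}
    return MeSnpRecord(
        chrom="chr1", pos=150, ref_allele=ref, alt_allele=alt,
        context=CpGContext("A", ref, alt, "G"), mesnp_class=cls, rsid="rs1",
    )


class TestCompatibility:
    def _result(self, af_hfe, af_lfe):
        from mesnp.concordance import GroupAFResult

        return GroupAFResult("HFE", "LFE", af_hfe, af_lfe, 4, 4)

    def test_create_alt_high_in_hyper_group_compatible(self):
        rec = _mesnp(MeSnpClass.CREATE, ref="T", alt="C")
        assert methylation_compatibility(rec, self._result(0.875, 0.125), "HFE") is True

    def test_create_alt_high_in_hypo_group_incompatible(self):
        rec = _mesnp(MeSnpClass.CREATE, ref="A", alt="G")
        # peak in LFE but the CpG-creating alt allele is commoner in HFE
        assert methylation_compatibility(rec, self._result(0.5, 0.0), "LFE") is False

    def test_destroy_ref_high_in_hyper_group_compatible(self):
        rec = _mesnp(MeSnpClass.DESTROY)
        # alt (MSD) at 0 in hyper group -> ref (MSC) at 1 there
        assert methylation_compatibility(rec, self._result(0.0, 0.5), "HFE") is True

    def test_tie_is_incompatible(self):
        rec = _mesnp(MeSnpClass.CREATE)
        assert methylation_compatibility(rec, self._result(0.5, 0.5), "HFE") is False

    def test_displace_indeterminate(self):
        rec = _mesnp(MeSnpClass.DISPLACE, ref="G", alt="C")
        assert methylation_compatibility(rec, self._result(1.0, 0.0), "HFE") is None

    def test_hyper_group_swap_consistency(self):
        """Swapping which group is hypermethylated flips the conclusion."""
        rec = _mesnp(MeSnpClass.CREATE)
        r = self._result(0.9, 0.1)
        assert methylation_compatibility(rec, r, "HFE") is True
        assert methylation_compatibility(rec, r, "LFE") is False


class TestQtlOverlapAndTable:
    def _candidate(self, cls, compatible, pos=150):
        from mesnp.concordance import GroupAFResult

        rec = _mesnp(cls)
        rec = MeSnpRecord(
            chrom="chr1", pos=pos, ref_allele="C", alt_allele="T",
            context=rec.context, mesnp_class=cls, rsid=f"rs{pos}",
        )
        return CandidateMeSnp(
            tissue="SI", record=rec,
            dmr=GenomicInterval("chr1", 100, 300, label="HFE"),
            af_result=GroupAFResult("HFE", "LFE", 1.0, 0.0, 4, 4),
            compatible=compatible,
        )

    def test_qtl_hits_filled_by_half_open_rule(self):
        cands = [self._candidate(MeSnpClass.CREATE, True, pos=150)]
        qtls = [
            GenomicInterval("chr1", 100, 200, "feed_efficiency"),
            GenomicInterval("chr1", 149, 160, "efficiency_of_gain"),
            GenomicInterval("chr2", 0, 1000, "other_trait"),
        ]
        (cand,) = qtl_overlap(cands, qtls)
        assert cand.qtl_hits == ["efficiency_of_gain", "feed_efficiency"]

    def test_no_qtls_on_chrom_empty_hits(self):
        cands = [self._candidate(MeSnpClass.CREATE, True)]
        (cand,) = qtl_overlap(cands, [GenomicInterval("chr9", 0, 10, "t")])
        assert cand.qtl_hits == []

    def test_table_sections(self):
        cands = (
            [self._candidate(MeSnpClass.CREATE, True, pos=100 + i) for i in range(7)]
            + [self._candidate(MeSnpClass.DESTROY, False, pos=200 + i) for i in range(5)]
            + [self._candidate(MeSnpClass.DISPLACE, None, pos=250)]
        )
        table = candidate_table(cands)
        counts = table["section"].value_counts()
        assert counts["compatible"] == 7
        assert counts["incompatible"] == 5
        assert counts["indeterminate"] == 1

    def test_empty_input_header_only(self):
        table = candidate_table([])
        assert table.empty and "section" in table.columns
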