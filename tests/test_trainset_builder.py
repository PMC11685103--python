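import math

import pytest

from mretarget.errors import DataError
from mretarget.site_scanner import CandidateSite, SiteCategory
from mretarget.trainset_builder import (
    ChimeraRecord,
    LibraryInfo,
    PeakRecord,
    PerturbationRecord,
    filter_chimeras,
    filter_peaks,
    label_sites,
)


def _site(mirna="m1", gene="g1", tid="t1", start=100):
    return CandidateSite(
        mirna_id=mirna, transcript_id=tid, gene_id=gene, region="UTR3",
        match_start=start, match_end=start + 7, anchor=start + 7,
        category=SiteCategory.SEVENMER_M8,
        paired_mirna_positions=frozenset(range(2, 9)),
    )


def _peak(tid="t1", start=90, end=120, score=0.8, lib="L1"):
    return PeakRecord(transcript_id=tid, start=start, end=end, score=score,
                      library_id=lib)


def _pert(gene="g1", lfc=-1.0, fdr=0.01, exp="E1",
          direction="down_on_transfection"):
    return PerturbationRecord(gene_id=gene, log2_fc=lfc, fdr=fdr,
                              direction_expected=direction, experiment_id=exp,
                              tissue="liver")


TISSUE_MAP = [LibraryInfo("L1", "E1", "AGO"), LibraryInfo("BG", "E1", "BACKGROUND")]


class TestFilterPeaks:
    def test_above_threshold_kept(self):
        assert filter_peaks([_peak(score=0.6)]) == [_peak(score=0.6)]

    def test_exact_threshold_dropped(self):
        assert filter_peaks([_peak(score=0.5)]) == []

    def test_empty(self):
        assert filter_peaks([]) == []


class TestFilterChimeras:
    def test_kept(self):
        r = ChimeraRecord("m1", "t1", 0, 30, mfe=-5.0, chimeric_reads=3)
        assert filter_chimeras([r]) == [r]

    def test_zero_mfe_dropped(self):
        r = ChimeraRecord("m1", "t1", 0, 30, mfe=0.0, chimeric_reads=5)
        assert filter_chimeras([r]) == []

    def test_single_read_dropped(self):
        r = ChimeraRecord("m1", "t1", 0, 30, mfe=-2.0, chimeric_reads=1)
        assert filter_chimeras([r]) == []

    def test_idempotent(self):
        recs = [
            ChimeraRecord("m", "t", 0, 10, mfe=-1.0, chimeric_reads=2),
            ChimeraRecord("m", "t", 5, 15, mfe=-0.1, chimeric_reads=1),
            ChimeraRecord("m", "t", 9, 29, mfe=1.0, chimeric_reads=9),
        ]
        once = filter_chimeras(recs)
        assert filter_chimeras(once) == once


class TestLabelSites:
    def test_positive_rule(self):
        # in peak, gene down 2-fold on transfection, FDR 0.01 -> positive
        out = label_sites([_site()], [_peak()], [_pert(lfc=-1.0)], TISSUE_MAP)
        assert out == [(_site(), 1)]

    def test_fold_change_threshold_is_1_5(self):
        # |log2FC| = 0.3 < log2(1.5) = 0.585 -> fails the positive rule
        out = label_sites([_site()], [_peak()], [_pert(lfc=-0.3)], TISSUE_MAP)
        assert out == []  # in a peak but unresponsive: unlabeled

    def test_negative_no_peak_no_response(self):
        out = label_sites([_site(start=500)], [_peak()], [_pert(lfc=-0.05)], TISSUE_MAP)
        assert out == [(_site(start=500), 0)]

    def test_background_peak_negative(self):
        bg = _peak(start=90, end=120, lib="BG")
        out = label_sites([_site()], [bg], [_pert(lfc=-2.0)], TISSUE_MAP)
        assert out == [(_site(), 0)]

    def test_fdr_gate(self):
        out = label_sites([_site()], [_peak()], [_pert(lfc=-2.0, fdr=0.2)], TISSUE_MAP)
        assert out == []

    def test_fdr_absent_is_permitted(self):
        out = label_sites([_site()], [_peak()], [_pert(lfc=-2.0, fdr=None)], TISSUE_MAP)
        assert out == [(_site(), 1)]

    def test_knockdown_direction(self):
        pert = _pert(lfc=+1.0, direction="up_on_knockdown")
        out = label_sites([_site()], [_peak()], [pert], TISSUE_MAP)
        assert out == [(_site(), 1)]

    def test_missing_library_mapping(self):
        with pytest.raises(DataError, match="missing from the tissue map"):
            label_sites([_site()], [_peak(lib="unknown")], [_pert()], TISSUE_MAP)

    def test_interaction_exclusivity(self):
        s_pos = _site(start=100)  # in peak, responsive -> positive
        s_other = _site(start=500)  # same pair, would be negative by rule (b)
        pert_both = [_pert(lfc=-1.0)]
        out = label_sites([s_pos, s_other], [_peak()], pert_both, TISSUE_MAP)
        labels = {(s.match_start): l for s, l in out}
        assert labels == {100: 1}  # the negative candidate of a positive pair is dropped

    def test_golden_ten_row_fixture(self):
        """Hand-assigned labels on a 10-site fixture, byte-identical."""
        sites = [
            _site(gene="g1", start=100),  # peak + down 2x: positive
            _site(gene="g2", start=100),  # peak + down 1.4x only: unlabeled
            _site(gene="g3", start=100),  # peak + FDR 0.5: unlabeled
            _site(gene="g4", start=100),  # peak + up (wrong direction): unlabeled
            _site(gene="g5", start=500),  # no peak + |lfc|<0.1: negative
            _site(gene="g6", start=500),  # no peak + lfc -0.3: unlabeled
            _site(gene="g7", start=100),  # background peak: negative
            _site(gene="g8", start=100),  # peak + down exactly 1.5x: positive
            _site(gene="g9", start=500),  # no peak, no perturbation record: unlabeled
            _site(gene="g10", start=100), # peak + knockdown up 2x: positive
        ]
        perts = [
            _pert("g1", lfc=-1.0),
            _pert("g2", lfc=-0.49),
            _pert("g3", lfc=-2.0, fdr=0.5),
            _pert("g4", lfc=+2.0),
            _pert("g5", lfc=0.05),
            _pert("g6", lfc=-0.3),
            _pert("g7", lfc=-2.0),
            _pert("g8", lfc=-math.log2(1.5)),
            _pert("g10", lfc=+2.0, direction="up_on_knockdown"),
        ]
        # g7's site overlaps only the background peak: move others' transcript
        sites[6] = _site(gene="g7", tid="t_bg", start=100)
        peaks = [
            _peak(tid="t1", start=90, end=120, lib="L1"),
            _peak(tid="t_bg", start=90, end=120, lib="BG"),
        ]
        out = label_sites(sites, peaks, perts, TISSUE_MAP)
        got = {(s.gene_id): l for s, l in out}
        assert got == {"g1": 1, "g5": 0, "g7": 0, "g8": 1, "g10": 1}

    def test_no_pair_in_both_classes(self):
        sites = [_site(start=100), _site(start=500), _site(gene="g2", start=500)]
        out = label_sites(sites, [_peak()], [_pert("g1", -1.0), _pert("g2", 0.0)],
                          TISSUE_MAP)
        by_pair = {}
        for s, l in out:
            by_pair.setdefault((s.mirna_id, s.gene_id), set()).add(l)
        assert all(len(v) == 1 for v in by_pair.values())


class TestRecordValidation:
    def test_bad_direction(self):
        with pytest.raises(DataError, match="direction"):
            PerturbationRecord("g", 0.0, "sideways", "E1")

    def test_bad_fdr(self):
        with pytest.raises(DataError, match="FDR"):
            _pert(fdr=1.5)

    def test_negative_peak_score(self):
        with pytest.raises(DataError, match="score"):
            _peak(score=-0.1)

    def test_negative_reads(self):
        with pytest.raises(DataError, match="read count"):
            ChimeraRecord("m", "t", 0, 10, mfe=-1.0, chimeric_reads=-1)
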