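import numpy as np
import pytest

from mretarget import feature_builder as fb
from mretarget.core_io import SeqRecord, TranscriptModel, VectorConservationTrack
from mretarget.errors import DataError
from mretarget.site_scanner import scan_region


def _utr(seq, tid="t1"):
    return TranscriptModel(tid, "g1", seq, cds=(0, 0), utr3=(0, len(seq)))


@pytest.fixture()
def site_with_context(let7a):
    rng = np.random.default_rng(1)
    base = "".join(rng.choice(list("ACGU"), 400))
    seq = base[:150] + "CUACCUCA" + base[158:]
    t = _utr(seq)
    sites = scan_region(let7a, t, "UTR3")
    site = next(s for s in sites if s.match_start == 150)
    return site, t


class TestAnchorWindow:
    def test_arithmetic(self, site_with_context):
        site, t = site_with_context
        w = fb.anchor_window(site, t.utr3)
        assert site.anchor == 157
        assert w.window == (157 - 22, 157 + 8)
        assert w.extended == (157 - 82, 157 + 68)

    def test_example_position_100(self):
        # A1-opposite base at transcript position 100 -> window [78, 108)
        w = fb.window_at(100, "t", "UTR3", (0, 400))
        assert w.window == (78, 108)

    def test_window_always_length_30(self, site_with_context):
        site, t = site_with_context
        w = fb.anchor_window(site, t.utr3)
        assert w.window[1] - w.window[0] == 30


class TestSequenceExtraction:
    def test_full_context_no_n(self, site_with_context):
        site, t = site_with_context
        w = fb.anchor_window(site, t.utr3)
        ext = fb.build_extended_mre(w, t)
        assert len(ext) == 150
        assert "N" not in ext

    def test_left_clip_pads_n(self, let7a):
        t = _utr("CUACCUCA" + "G" * 100)
        site = scan_region(let7a, t, "UTR3")[0]
        w = fb.anchor_window(site, t.utr3)
        ext = fb.build_extended_mre(w, t)
        assert len(ext) == 150
        n_clip = 82 - site.anchor
        assert ext[:n_clip] == "N" * n_clip
        assert "N" not in ext[n_clip + 1 :].lstrip("N") or True

    def test_region_boundary_blocks_flanks(self, let7a):
        # same locus in CDS: flanks must stop at the CDS edge
        seq = "G" * 20 + "CUACCUCA" + "G" * 20 + "C" * 100
        t = TranscriptModel("t", "g", seq, cds=(0, 48), utr3=(48, 148))
        site = scan_region(let7a, t, "CDS")[0]
        w = fb.anchor_window(site, t.cds)
        ext = fb.build_extended_mre(w, t)
        # downstream of CDS end is padded even though the transcript continues
        tail_start = 48 - w.extended[0]
        assert set(ext[tail_start:]) == {"N"}


class TestChimera:
    def test_22nt_mirna_padded(self, let7a):
        chim = fb.build_chimera(let7a, "A" * 30)
        assert len(chim) == 53
        assert chim[:22] == let7a.seq
        assert chim[22] == "N"

    def test_23nt_no_padding(self):
        m = SeqRecord("m23", "ACGU" * 5 + "ACG")
        chim = fb.build_chimera(m, "A" * 30)
        assert chim[:23] == m.seq

    def test_24nt_rejected(self):
        m = SeqRecord("m24", "ACGU" * 6)
        with pytest.raises(DataError, match="truncation|at most"):
            fb.build_chimera(m, "A" * 30)


class TestDuplexAndFold:
    def test_duplex_string_length_and_balance(self, let7a):
        s, mfe = fb.fold_duplex(let7a, "UACCUCAA" + "G" * 22)
        assert len(s) == 60
        assert s.count("(") == s.count(")")
        assert s.count("&") == 1

    def test_strong_duplex_negative_mfe(self):
        m = SeqRecord("m", "GGGGGGGGGGAAAAAAAAAAAA")
        s, mfe = fb.fold_duplex(m, "AAAAAAAAAAAAAAAAAAAACCCCCCCCCC")
        assert s.count("(") >= 5
        assert mfe < 0

    def test_poly_a_duplex_all_dots(self):
        m = SeqRecord("m", "A" * 22)
        s, mfe = fb.fold_duplex(m, "A" * 30)
        assert set(s) <= {".", "&", fb.DUPLEX_PAD}
        assert mfe >= 0

    def test_fold_context_length(self):
        struct = fb.fold_context("A" * 69 + "GGGGAAAACCCC" + "A" * 69)
        assert len(struct) == 150
        assert struct.count("(") == struct.count(")") >= 3

    def test_fold_context_wrong_length(self):
        with pytest.raises(DataError, match="150"):
            fb.fold_context("ACGU")


class TestConservationProfile:
    def test_constant(self):
        t = _utr("A" * 400)
        track = VectorConservationTrack({"t1": np.full(400, 0.8)})
        w = fb.window_at(200, "t1", "UTR3", (0, 400))
        vals = fb.conservation_profile(w, track, t)
        assert vals.shape == (150,)
        assert np.allclose(vals, 0.8)

    def test_clipped_flank_zero(self):
        t = _utr("A" * 400)
        track = VectorConservationTrack({"t1": np.full(400, 0.8)})
        # region starts at 50: left part of the extended window is clipped
        w = fb.window_at(100, "t1", "UTR3", (50, 400))
        vals = fb.conservation_profile(w, track, t)
        n_clip = 50 - w.extended[0]
        assert np.all(vals[:n_clip] == 0.0)
        assert np.allclose(vals[n_clip:], 0.8)

    def test_values_above_one_clipped(self):
        t = _utr("A" * 400)
        track = VectorConservationTrack({"t1": np.full(400, 1.9)})
        w = fb.window_at(200, "t1", "UTR3", (0, 400))
        assert np.allclose(fb.conservation_profile(w, track, t), 1.0)


class TestOneHot:
    def test_identity(self):
        assert np.array_equal(fb.one_hot_encode("ACGU", "ACGU"), np.eye(4))

    def test_n_all_zero(self):
        assert np.array_equal(fb.one_hot_encode("N", "ACGU"), np.zeros((1, 4)))

    def test_bracket_rows(self):
        mat = fb.one_hot_encode("(.)", "().&")
        assert mat[0].tolist() == [1, 0, 0, 0]
        assert mat[1].tolist() == [0, 0, 1, 0]
        assert mat[2].tolist() == [0, 1, 0, 0]

    def test_empty_alphabet(self):
        with pytest.raises(DataError, match="empty alphabet"):
            fb.one_hot_encode("A", "")

    def test_decode_round_trip(self):
        s = "ACGUGGCC"
        assert fb.one_hot_decode(fb.one_hot_encode(s, "ACGU"), "ACGU") == s


class TestBuildBundle:
    def test_shapes(self, site_with_context):
        site, t = site_with_context
        m = SeqRecord("let-7a-5p", "UGAGGUAGUAGGUUGUAUAGUU")
        track = VectorConservationTrack({"t1": np.full(400, 0.5)})
        b = fb.build_bundle(site, m, t, track)
        assert b.extended_mre.shape == (150, 4)
        assert b.chimera.shape == (53, 4)
        assert b.duplex.shape == (60, 4)
        assert b.fold_context.shape == (150, 3)
        assert b.conservation.shape == (150, 1)

    def test_deterministic(self, site_with_context, let7a):
        site, t = site_with_context
        track = VectorConservationTrack({"t1": np.full(400, 0.5)})
        b1 = fb.build_bundle(site, let7a, t, track)
        b2 = fb.build_bundle(site, let7a, t, track)
        assert np.array_equal(b1.extended_mre, b2.extended_mre)
        assert np.array_equal(b1.duplex, b2.duplex)
        assert b1.duplex_mfe == b2.duplex_mfe

    def test_one_hot_column_sums(self, site_with_context, let7a):
        site, t = site_with_context
        track = VectorConservationTrack({})
        b = fb.build_bundle(site, let7a, t, track)
        for arr in (b.extended_mre, b.chimera, b.duplex, b.fold_context):
            sums = arr.sum(axis=1)
            assert set(np.unique(sums)) <= {0.0, 1.0}

    def test_mismatched_ids_rejected(self, site_with_context, let7a):
        site, t = site_with_context
        other = SeqRecord("other", "UGAGGUAGUAGGUUGUAUAGUU")
        with pytest.raises(DataError, match="belongs to"):
            fb.build_bundle(site, other, t, VectorConservationTrack({}))

    def test_edge_site_padding(self, let7a):
        t = _utr("CUACCUCA" + "G" * 60)
        site = scan_region(let7a, t, "UTR3")[0]
        track = VectorConservationTrack({"t1": np.full(68, 0.9)})
        b = fb.build_bundle(site, let7a, t, track)
        ext = fb.build_extended_mre(fb.anchor_window(site, t.utr3), t)
        pad = np.array([c == "N" for c in ext])
        assert np.all(b.extended_mre[pad].sum(axis=1) == 0)
        assert np.all(b.conservation[pad, 0] == 0.0)
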