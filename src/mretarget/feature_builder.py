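"""Encoding of candidate sites into the five tensors the site scorer consumes.

For every site a 30-nt window is anchored so that the target base opposite
miRNA position 1 sits at window offset 22 (22 nt upstream for 3'
supplementary pairing, 7 nt downstream), flanked by 60 nt on each side.
Windows and flanks are clipped at the annotated region boundary and
N-padded, so a CDS site never borrows 3' UTR context and vice versa.

Bundle layout (shapes fixed):

==============  =========  =========================================
extended_mre    (150, 4)   one-hot A/C/G/U; N and padding all-zero
chimera         (53, 4)    miRNA padded to 23 nt + 30-nt window
duplex          (60, 4)    dot-bracket over '(', ')', '.', '&'
fold_context    (150, 3)   dot-bracket over '(', ')', '.'
conservation    (150, 1)   floats in [0, 1]; padding = 0.0
==============  =========  =========================================

plus the scalar duplex minimum free energy (kcal/mol).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from mretarget import rna_fold
from mretarget.core_io import ConservationTrack, SeqRecord, TranscriptModel, read_conservation
from mretarget.errors import DataError
from mretarget.site_scanner import CandidateSite

WINDOW_LEN = 30
FLANK_LEN = 60
EXTENDED_LEN = WINDOW_LEN + 2 * FLANK_LEN  # 150
MIRNA_SLOT = 23
CHIMERA_LEN = MIRNA_SLOT + WINDOW_LEN  # 53
DUPLEX_LEN = 60
ANCHOR_OFFSET = 22  # window offset of the base opposite miRNA position 1

NUC_ALPHABET = "ACGU"
DUPLEX_ALPHABET = "().&"
FOLD_ALPHABET = "()."
DUPLEX_PAD = "_"  # encodes to an all-zero one-hot row

BUNDLE_SHAPES = {
    "mre": (EXTENDED_LEN, 4),
    "chimera": (CHIMERA_LEN, 4),
    "duplex": (DUPLEX_LEN, 4),
    "fold": (EXTENDED_LEN, 3),
    "conservation": (EXTENDED_LEN, 1),
}


@dataclass(frozen=True)
class MreWindow:
    """A 30-nt site window plus region bounds used for clipping."""

    transcript_id: str
    region: str
    region_bounds: tuple[int, int]
    window: tuple[int, int]  # [start, end), length 30; may overhang the region

    @property
    def upflank(self) -> tuple[int, int]:
        return (self.window[0] - FLANK_LEN, self.window[0])

    @property
    def downflank(self) -> tuple[int, int]:
        return (self.window[1], self.window[1] + FLANK_LEN)

    @property
    def extended(self) -> tuple[int, int]:
        return (self.window[0] - FLANK_LEN, self.window[1] + FLANK_LEN)


@dataclass(frozen=True)
class FeatureBundle:
    """The five encoded inputs for one candidate site."""

    extended_mre: np.ndarray
    chimera: np.ndarray
    duplex: np.ndarray
    fold_context: np.ndarray
    conservation: np.ndarray
    duplex_mfe: float

    def __post_init__(self) -> None:
        for name, arr, shape in (
            ("extended_mre", self.extended_mre, BUNDLE_SHAPES["mre"]),
            ("chimera", self.chimera, BUNDLE_SHAPES["chimera"]),
            ("duplex", self.duplex, BUNDLE_SHAPES["duplex"]),
            ("fold_context", self.fold_context, BUNDLE_SHAPES["fold"]),
            ("conservation", self.conservation, BUNDLE_SHAPES["conservation"]),
        ):
            if arr.shape != shape:
                raise DataError(f"feature {name} has shape {arr.shape}, expected {shape}")


def anchor_window(site: CandidateSite, region_bounds: tuple[int, int]) -> MreWindow:
    """Place the 30-nt window so the site anchor lands at offset 22."""
    ws = site.anchor - ANCHOR_OFFSET
    return MreWindow(
        transcript_id=site.transcript_id,
        region=site.region,
        region_bounds=region_bounds,
        window=(ws, ws + WINDOW_LEN),
    )


def window_at(anchor: int, transcript_id: str, region: str, region_bounds) -> MreWindow:
    """Window for a bare anchor position (used for scanner-negative loci)."""
    ws = anchor - ANCHOR_OFFSET
    return MreWindow(transcript_id, region, tuple(region_bounds), (ws, ws + WINDOW_LEN))


def _extract(seq: str, bounds: tuple[int, int], start: int, end: int) -> str:
    """Region-clipped subsequence with N padding outside [lo, hi)."""
    lo, hi = bounds
    return "".join(seq[i] if lo <= i < hi else "N" for i in range(start, end))


def window_sequence(window: MreWindow, transcript: TranscriptModel) -> str:
    return _extract(transcript.seq, window.region_bounds, *window.window)


def build_extended_mre(window: MreWindow, transcript: TranscriptModel) -> str:
    """upflank(60) + window(30) + downflank(60) = 150 symbols."""
    s = _extract(transcript.seq, window.region_bounds, *window.extended)
    assert len(s) == EXTENDED_LEN
    return s


def build_chimera(mirna: SeqRecord, window_seq: str) -> str:
    """miRNA right-padded with N to 23 nt, then the 30-nt window."""
    if len(mirna.seq) > MIRNA_SLOT:
        raise DataError(
            f"miRNA {mirna.id!r} is {len(mirna.seq)} nt; the chimera slot holds "
            f"at most {MIRNA_SLOT} nt and silent truncation is refused"
        )
    if len(window_seq) != WINDOW_LEN:
        raise DataError(f"chimera window must be {WINDOW_LEN} nt, got {len(window_seq)}")
    return mirna.seq + "N" * (MIRNA_SLOT - len(mirna.seq)) + window_seq


def fold_duplex(mirna: SeqRecord, window_seq: str) -> tuple[str, float]:
    """Co-fold miRNA vs window; serialize as miRNA-structure & window-structure.

    The two dot-bracket strings are joined by '&' and right-padded with
    ``DUPLEX_PAD`` to exactly 60 symbols.  N is folded as A; the encoded
    sequences elsewhere keep their Ns.
    """
    if len(window_seq) != WINDOW_LEN:
        raise DataError(f"duplex window must be {WINDOW_LEN} nt, got {len(window_seq)}")
    qs, ts, mfe, _pairs = rna_fold.fold_duplex(mirna.seq, window_seq)
    s = qs + "&" + ts
    if len(s) > DUPLEX_LEN:
        raise DataError(
            f"duplex string of length {len(s)} exceeds {DUPLEX_LEN}; miRNA too long"
        )
    return s + DUPLEX_PAD * (DUPLEX_LEN - len(s)), float(mfe)


def fold_context(extended: str) -> str:
    """Single-sequence MFE structure of the 150-nt extended window."""
    if len(extended) != EXTENDED_LEN:
        raise DataError(f"fold_context expects {EXTENDED_LEN} symbols, got {len(extended)}")
    struct, _energy = rna_fold.fold_single(extended)
    return struct


def conservation_profile(
    window: MreWindow, track: ConservationTrack, transcript: TranscriptModel
) -> np.ndarray:
    """Per-base conservation for the 150-nt extended window.

    Positions clipped away by the region boundary (or the transcript end)
    contribute 0.0; everything else is the track value clipped to [0, 1].
    """
    start, end = window.extended
    vals = read_conservation(track, transcript, start, end)
    lo, hi = window.region_bounds
    idx = np.arange(start, end)
    vals[(idx < lo) | (idx >= hi)] = 0.0
    return vals


def one_hot_encode(s: str, alphabet: str) -> np.ndarray:
    """len(s) x len(alphabet) one-hot matrix; unknown symbols -> all-zero row."""
    if not alphabet:
        raise DataError("one_hot_encode: empty alphabet")
    index = {c: i for i, c in enumerate(alphabet)}
    mat = np.zeros((len(s), len(alphabet)), dtype=np.float32)
    for i, c in enumerate(s):
        j = index.get(c)
        if j is not None:
            mat[i, j] = 1.0
    return mat


def one_hot_decode(mat: np.ndarray, alphabet: str, unknown: str = "N") -> str:
    out = []
    for row in mat:
        if row.sum() == 0:
            out.append(unknown)
        else:
            out.append(alphabet[int(np.argmax(row))])
    return "".join(out)


def build_bundle_at(
    anchor: int,
    region: str,
    mirna: SeqRecord,
    transcript: TranscriptModel,
    track: ConservationTrack,
) -> FeatureBundle:
    """Encode the locus at ``anchor`` in ``region`` (site or negative locus)."""
    bounds = transcript.region_interval(region)
    window = window_at(anchor, transcript.transcript_id, region, bounds)
    wseq = window_sequence(window, transcript)
    extended = build_extended_mre(window, transcript)
    chim = build_chimera(mirna, wseq)
    dup_str, mfe = fold_duplex(mirna, wseq)
    ctx = fold_context(extended)
    cons = conservation_profile(window, track, transcript)
    return FeatureBundle(
        extended_mre=one_hot_encode(extended, NUC_ALPHABET),
        chimera=one_hot_encode(chim, NUC_ALPHABET),
        duplex=one_hot_encode(dup_str, DUPLEX_ALPHABET),
        fold_context=one_hot_encode(ctx, FOLD_ALPHABET),
        conservation=cons.reshape(-1, 1).astype(np.float32),
        duplex_mfe=mfe,
    )


def build_bundle(
    site: CandidateSite,
    mirna: SeqRecord,
    transcript: TranscriptModel,
    track: ConservationTrack,
) -> FeatureBundle:
    """Compose the full feature bundle for one candidate site."""
    if site.mirna_id != mirna.id:
        raise DataError(f"site belongs to {site.mirna_id!r}, got miRNA {mirna.id!r}")
    if site.transcript_id != transcript.transcript_id:
        raise DataError(
            f"site belongs to {site.transcript_id!r}, got transcript "
            f"{transcript.transcript_id!r}"
        )
    return build_bundle_at(site.anchor, site.region, mirna, transcript, track)


def bundles_to_arrays(bundles: Sequence[FeatureBundle]) -> dict[str, np.ndarray]:
    """Stack bundles into the per-branch batch arrays the model consumes."""
    return {
        "mre": np.stack([b.extended_mre for b in bundles]),
        "chimera": np.stack([b.chimera for b in bundles]),
        "duplex": np.stack([b.duplex for b in bundles]),
        "fold": np.stack([b.fold_context for b in bundles]),
        "conservation": np.stack([b.conservation for b in bundles]),
    }
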