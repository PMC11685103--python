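"""Sequence, region-annotation, and conservation-track input handling.

All coordinates are 0-based half-open transcript coordinates.  Sequences
are normalized to the RNA alphabet ``{A, C, G, U, N}`` on ingest: lowercase
is uppercased, ``T`` becomes ``U``, anything else becomes ``N``.

Conservation can come from two kinds of sources:

* a per-transcript score vector (TSV; the self-contained path), or
* a genome-anchored bigWig plus a transcript->genome ``chrom_map``
  (requires the optional ``pyBigWig`` dependency).

Missing data (gaps in the track, positions outside the transcript) maps to
``missing_value`` (default 0.0, i.e. least conserved); all returned scores
are clipped to [0, 1].
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO

from mretarget.errors import ConfigurationError, DataError

RNA_ALPHABET = "ACGUN"
_NON_RNA = re.compile(r"[^ACGUN]")


def normalize_seq(seq: str) -> str:
    """Uppercase, convert T->U, and map every other symbol to N."""
    s = seq.upper().replace("T", "U")
    return _NON_RNA.sub("N", s)


@dataclass(frozen=True)
class SeqRecord:
    """A named RNA sequence over {A, C, G, U, N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise DataError("sequence record with empty id")
        if not self.seq:
            raise DataError(f"sequence record {self.id!r} has empty sequence")
        bad = set(self.seq) - set(RNA_ALPHABET)
        if bad:
            raise DataError(
                f"sequence record {self.id!r} contains non-RNA symbols {sorted(bad)}; "
                "use normalize_seq() on ingest"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript sequence with its CDS and 3' UTR intervals.

    ``cds`` and ``utr3`` are 0-based half-open intervals in transcript
    coordinates; either may be empty (start == end).  ``chrom_map`` is an
    optional list of ``(t_start, t_end, chrom, g_start, strand)`` blocks
    used only for genome-anchored conservation lookup.
    """

    transcript_id: str
    gene_id: str
    seq: str
    cds: tuple[int, int]
    utr3: tuple[int, int]
    appris_label: Optional[str] = None
    chrom_map: Optional[tuple] = None

    def __post_init__(self) -> None:
        n = len(self.seq)
        for name, (lo, hi) in (("cds", self.cds), ("utr3", self.utr3)):
            if not (0 <= lo <= hi <= n):
                raise DataError(
                    f"transcript {self.transcript_id!r}: {name} interval "
                    f"[{lo}, {hi}) outside sequence of length {n}"
                )
        c0, c1 = self.cds
        u0, u1 = self.utr3
        if c1 > c0 and u1 > u0:
            if u0 < c1:
                raise DataError(
                    f"transcript {self.transcript_id!r}: 3' UTR [{u0}, {u1}) must "
                    f"start at or after CDS end {c1} and not overlap it"
                )

    def region_interval(self, region: str) -> tuple[int, int]:
        if region == "UTR3":
            return self.utr3
        if region == "CDS":
            return self.cds
        raise DataError(f"unknown region {region!r}; expected 'UTR3' or 'CDS'")

    def __len__(self) -> int:
        return len(self.seq)


REGIONS = ("UTR3", "CDS")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[SeqRecord]:
    """Read a FASTA file into normalized :class:`SeqRecord` objects.

    Rejects empty files, text before the first header (reported with its
    line number), duplicate ids, and empty sequences.
    """
    with open(path) as fh:
        lines = fh.readlines()
    first_content = next(
        ((i, ln) for i, ln in enumerate(lines, start=1) if ln.strip()), None
    )
    if first_content is None:
        raise DataError(f"{path}: empty FASTA file")
    if not first_content[1].lstrip().startswith(">"):
        raise DataError(
            f"{path}: malformed FASTA, line {first_content[0]} is not a header"
        )

    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DataError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = normalize_seq(str(rec.seq))
        if not seq:
            raise DataError(f"{path}: record {rec.id!r} has empty sequence")
        records.append(SeqRecord(id=rec.id, seq=seq))
    return records


def write_fasta(records: Iterable[SeqRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Region annotation table
# ---------------------------------------------------------------------------

REGION_TSV_COLUMNS = (
    "transcript_id",
    "gene_id",
    "cds_start",
    "cds_end",
    "utr3_start",
    "utr3_end",
)


def read_regions(path, records: Sequence[SeqRecord]) -> list[TranscriptModel]:
    """Join a region-annotation TSV with transcript sequences.

    Required columns: transcript_id, gene_id, cds_start, cds_end,
    utr3_start, utr3_end; optional column: appris.
    """
    import pandas as pd

    table = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "gene_id": str})
    missing = [c for c in REGION_TSV_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"{path}: region table missing columns {missing}")
    by_id = {r.id: r for r in records}
    out = []
    for row in table.itertuples(index=False):
        tid = row.transcript_id
        if tid not in by_id:
            raise DataError(f"{path}: transcript {tid!r} has no sequence")
        appris = getattr(row, "appris", None)
        if appris is not None and (appris != appris or appris == ""):  # NaN/blank
            appris = None
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=row.gene_id,
                seq=by_id[tid].seq,
                cds=(int(row.cds_start), int(row.cds_end)),
                utr3=(int(row.utr3_start), int(row.utr3_end)),
                appris_label=appris,
            )
        )
    return out


def write_regions(transcripts: Iterable[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(REGION_TSV_COLUMNS + ("appris",)) + "\n")
        for t in transcripts:
            fh.write(
                f"{t.transcript_id}\t{t.gene_id}\t{t.cds[0]}\t{t.cds[1]}\t"
                f"{t.utr3[0]}\t{t.utr3[1]}\t{t.appris_label or ''}\n"
            )


# ---------------------------------------------------------------------------
# Conservation
# ---------------------------------------------------------------------------

class ConservationTrack:
    """Base class: per-base conservation scores in [0, 1]."""

    missing_value: float = 0.0

    def transcript_values(self, transcript: TranscriptModel, lo: int, hi: int) -> np.ndarray:
        """Scores for in-bounds interval [lo, hi) of the transcript."""
        raise NotImplementedError


class VectorConservationTrack(ConservationTrack):
    """In-memory per-transcript score vectors (the download-free path)."""

    def __init__(self, vectors: Mapping[str, np.ndarray], missing_value: float = 0.0):
        self.vectors = {k: np.asarray(v, dtype=float) for k, v in vectors.items()}
        self.missing_value = missing_value

    def transcript_values(self, transcript, lo, hi):
        vec = self.vectors.get(transcript.transcript_id)
        if vec is None:
            return np.full(hi - lo, self.missing_value)
        if len(vec) < len(transcript.seq):
            raise DataError(
                f"conservation vector for {transcript.transcript_id!r} has length "
                f"{len(vec)} < transcript length {len(transcript.seq)}"
            )
        return vec[lo:hi].astype(float)


class BigWigConservationTrack(ConservationTrack):
    """Genome-anchored bigWig source; requires pyBigWig and a chrom_map."""

    def __init__(self, path, missing_value: float = 0.0):
        try:
            import pyBigWig  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise DataError(
                "bigWig conservation requested but pyBigWig is not installed; "
                "supply a per-transcript conservation TSV instead"
            ) from exc
        try:
            self._bw = pyBigWig.open(str(path))
        except Exception as exc:  # pragma: no cover
            raise DataError(f"cannot open bigWig {path}: {exc}") from exc
        self.missing_value = missing_value

    def transcript_values(self, transcript, lo, hi):  # pragma: no cover - needs bigWig
        if transcript.chrom_map is None:
            raise ConfigurationError(
                f"transcript {transcript.transcript_id!r} lacks a chrom_map; "
                "required for bigWig conservation lookup"
            )
        out = np.full(hi - lo, self.missing_value)
        for t_start, t_end, chrom, g_start, strand in transcript.chrom_map:
            a, b = max(lo, t_start), min(hi, t_end)
            if a >= b:
                continue
            if strand == "+":
                vals = self._bw.values(chrom, g_start + (a - t_start), g_start + (b - t_start))
            else:
                g_hi = g_start + (t_end - a)
                g_lo = g_start + (t_end - b)
                vals = self._bw.values(chrom, g_lo, g_hi)[::-1]
            vals = np.asarray(vals, dtype=float)
            vals[np.isnan(vals)] = self.missing_value
            out[a - lo : b - lo] = vals
        return out


def read_conservation(
    track: ConservationTrack, transcript: TranscriptModel, start: int, end: int
) -> np.ndarray:
    """Per-base scores for [start, end); the interval may overhang the transcript.

    Out-of-transcript positions and track gaps yield ``track.missing_value``;
    everything is clipped to [0, 1].  Output length always equals end - start.
    """
    if end < start:
        raise DataError(f"invalid conservation interval [{start}, {end})")
    n = len(transcript.seq)
    out = np.full(end - start, track.missing_value, dtype=float)
    lo, hi = max(start, 0), min(end, n)
    if lo < hi:
        vals = np.asarray(track.transcript_values(transcript, lo, hi), dtype=float)
        if len(vals) != hi - lo:
            raise DataError("conservation source returned wrong-length vector")
        vals = np.where(np.isnan(vals), track.missing_value, vals)
        out[lo - start : hi - start] = vals
    return np.clip(out, 0.0, 1.0)


def read_conservation_tsv(path, missing_value: float = 0.0) -> VectorConservationTrack:
    """Read per-transcript conservation vectors.

    Format: TSV with columns ``transcript_id`` and ``scores`` where scores
    is a comma-separated list of floats, one per transcript base.
    """
    import pandas as pd

    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("transcript_id", "scores"):
        if col not in table.columns:
            raise DataError(f"{path}: conservation table missing column {col!r}")
    vectors = {}
    for row in table.itertuples(index=False):
        vectors[row.transcript_id] = np.fromstring(row.scores, sep=",")
    return VectorConservationTrack(vectors, missing_value=missing_value)


def write_conservation_tsv(vectors: Mapping[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tscores\n")
        for tid, vec in vectors.items():
            fh.write(tid + "\t" + ",".join(f"{v:.4f}" for v in np.asarray(vec)) + "\n")


# ---------------------------------------------------------------------------
# Principal-transcript selection
# ---------------------------------------------------------------------------

_APPRIS_RE = re.compile(r"^(PRINCIPAL|ALTERNATIVE):(\d+)$")


def _appris_rank(label: Optional[str]) -> tuple[int, int]:
    """Sort key: PRINCIPAL:1 best, then PRINCIPAL:n, ALTERNATIVE:n, unlabeled."""
    if label:
        m = _APPRIS_RE.match(label.strip())
        if m:
            cls = 0 if m.group(1) == "PRINCIPAL" else 1
            return (cls, int(m.group(2)))
    return (2, 0)


def select_principal_transcript(candidates: Sequence[TranscriptModel]) -> TranscriptModel:
    """Pick one transcript per gene: best APPRIS label, then longest 3' UTR,
    then lexicographically smallest transcript_id.  Order-independent."""
    if not candidates:
        raise DataError("select_principal_transcript: empty candidate list")
    genes = {t.gene_id for t in candidates}
    if len(genes) != 1:
        raise DataError(
            f"select_principal_transcript: mixed gene ids {sorted(genes)}"
        )

    def key(t: TranscriptModel):
        utr_len = t.utr3[1] - t.utr3[0]
        return (*_appris_rank(t.appris_label), -utr_len, t.transcript_id)

    return min(candidates, key=key)
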