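"""Exhaustive enumeration of candidate miRNA binding sites.

Every position of a transcript region is tested against the supported site
categories; the scan is exact (complete by construction) rather than a
heuristic alignment.

Geometry.  miRNA positions are 1-based from the 5' end.  Pairing is
antiparallel: if the target position opposite miRNA position 1 (the
"anchor") is ``a``, then miRNA position ``p`` faces target index
``a - (p - 1)``.  Category definitions, in precedence order:

* 9mer      - Watson-Crick (WC) pairing of miRNA 2-10
* 8mer      - WC pairing of 2-8 plus an A at the anchor
* 7mer-m8   - WC pairing of 2-8
* 7mer-A1   - WC pairing of 2-7 plus an A at the anchor
* 6mer      - WC pairing of 2-7
* centered      - contiguous WC pairing covering miRNA 4-14 (>= 11 pairs),
                  no canonical seed category at the anchor
* compensatory  - seed 2-7 with exactly one non-WC position (mismatch or
                  G:U wobble) rescued by >= 4 contiguous WC pairs within
                  miRNA 13-17, no canonical category at the anchor

One site is kept per anchor (strongest category); a final pass also keeps a
single strongest site per match_start so output tuples are unique.  Sites
never cross the annotated region boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from mretarget.core_io import SeqRecord, TranscriptModel
from mretarget.errors import DataError

MIN_MIRNA_LEN = 17

_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {("G", "U"), ("U", "G")}


class SiteCategory(Enum):
    NINEMER = "9mer"
    EIGHTMER = "8mer"
    SEVENMER_M8 = "7mer-m8"
    SEVENMER_A1 = "7mer-A1"
    SIXMER = "6mer"
    CENTERED = "centered"
    COMPENSATORY = "compensatory"


#: Lower value = stronger category.
PRECEDENCE = {cat: i for i, cat in enumerate(SiteCategory)}


@dataclass(frozen=True)
class CandidateSite:
    """One putative miRNA binding site within a single transcript region."""

    mirna_id: str
    transcript_id: str
    gene_id: str
    region: str  # 'UTR3' or 'CDS'
    match_start: int
    match_end: int
    anchor: int  # target index opposite miRNA position 1
    category: SiteCategory
    paired_mirna_positions: frozenset[int]
    wobble_positions: frozenset[int] = frozenset()


def revcomp_match(mirna_sub: str, target_sub: str, allow_wobble: bool = False) -> list[str]:
    """Antiparallel per-position pairing report.

    ``mirna_sub`` is read 5'->3' and compared against ``target_sub`` read
    3'->5'.  Returns one symbol per miRNA position: ``'W'`` for a
    Watson-Crick pair, ``'G'`` for a G:U wobble (only when
    ``allow_wobble``), ``'.'`` otherwise.
    """
    if len(mirna_sub) != len(target_sub):
        raise DataError(
            f"revcomp_match: unequal lengths {len(mirna_sub)} vs {len(target_sub)}"
        )
    n = len(mirna_sub)
    report = []
    for i in range(n):
        m, t = mirna_sub[i], target_sub[n - 1 - i]
        if _WC.get(m) == t:
            report.append("W")
        elif allow_wobble and (m, t) in _WOBBLE:
            report.append("G")
        else:
            report.append(".")
    return report


def _classify_anchor(m: str, t: str, a: int, lo: int, hi: int):
    """Strongest category at anchor ``a`` within region [lo, hi), or None.

    Returns (category, match_start, match_end, paired, wobble).
    """

    def wc(p: int) -> bool:
        i = a - (p - 1)
        return lo <= i < hi and _WC.get(m[p - 1]) == t[i]

    # -- canonical seed categories ------------------------------------------
    if wc(2) and wc(3) and wc(4) and wc(5) and wc(6) and wc(7):
        if wc(8):
            if wc(9) and wc(10):
                return (SiteCategory.NINEMER, a - 9, a, frozenset(range(2, 11)), frozenset())
            if a < hi and t[a] == "A":
                return (SiteCategory.EIGHTMER, a - 7, a + 1, frozenset(range(2, 9)), frozenset())
            return (SiteCategory.SEVENMER_M8, a - 7, a, frozenset(range(2, 9)), frozenset())
        if a < hi and t[a] == "A":
            return (SiteCategory.SEVENMER_A1, a - 6, a + 1, frozenset(range(2, 8)), frozenset())
        return (SiteCategory.SIXMER, a - 6, a, frozenset(range(2, 8)), frozenset())

    # -- centered: contiguous WC pairing covering miRNA 4-14 ----------------
    if all(wc(p) for p in range(4, 15)):
        pmin, pmax = 4, 14
        while pmin > 1 and wc(pmin - 1):
            pmin -= 1
        while pmax < len(m) and wc(pmax + 1):
            pmax += 1
        return (
            SiteCategory.CENTERED,
            a - pmax + 1,
            a - pmin + 2,
            frozenset(range(pmin, pmax + 1)),
            frozenset(),
        )

    # -- 3' compensatory ----------------------------------------------------
    if a - 6 >= lo and a <= hi:
        seed_wc = []
        off = []
        for p in range(2, 8):
            if wc(p):
                seed_wc.append(p)
            else:
                off.append(p)
        if len(off) == 1:
            runs = _wc_runs(m, t, a, lo, hi, 13, 17)
            run = next((r for r in runs if len(r) >= 4), None)
            if run is not None:
                p_off = off[0]
                tb = t[a - (p_off - 1)]
                wob = frozenset({p_off}) if (m[p_off - 1], tb) in _WOBBLE else frozenset()
                return (
                    SiteCategory.COMPENSATORY,
                    a - 6,
                    a,
                    frozenset(seed_wc) | frozenset(run),
                    wob,
                )
    return None


def _wc_runs(m, t, a, lo, hi, p_from, p_to):
    """Maximal runs of WC-paired miRNA positions within [p_from, p_to]."""
    runs, cur = [], []
    for p in range(p_from, min(p_to, len(m)) + 1):
        i = a - (p - 1)
        if lo <= i < hi and _WC.get(m[p - 1]) == t[i]:
            cur.append(p)
        else:
            if cur:
                runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    runs.sort(key=len, reverse=True)
    return runs


def scan_region(mirna: SeqRecord, transcript: TranscriptModel, region: str) -> list[CandidateSite]:
    """All candidate sites for one miRNA in one transcript region.

    One site per anchor (precedence dedup), then one per match_start;
    sorted by (match_start, precedence).
    """
    if len(mirna.seq) < MIN_MIRNA_LEN:
        raise DataError(
            f"miRNA {mirna.id!r} is {len(mirna.seq)} nt; minimum is {MIN_MIRNA_LEN}"
        )
    lo, hi = transcript.region_interval(region)
    m, t = mirna.seq, transcript.seq
    found: list[CandidateSite] = []
    # Anchors up to hi+2 matter: centered sites pair only miRNA 4-14, whose
    # target footprint [a-13, a-2) can still sit inside the region there.
    for a in range(lo + 6, hi + 3):
        hit = _classify_anchor(m, t, a, lo, hi)
        if hit is None:
            continue
        cat, ms, me, paired, wob = hit
        found.append(
            CandidateSite(
                mirna_id=mirna.id,
                transcript_id=transcript.transcript_id,
                gene_id=transcript.gene_id,
                region=region,
                match_start=ms,
                match_end=me,
                anchor=a,
                category=cat,
                paired_mirna_positions=paired,
                wobble_positions=wob,
            )
        )
    return dedup_by_match_start(found)


def dedup_by_match_start(sites: list[CandidateSite]) -> list[CandidateSite]:
    """Keep the strongest site per match_start (ties: smallest anchor)."""
    best: dict[int, CandidateSite] = {}
    for s in sites:
        cur = best.get(s.match_start)
        if cur is None or (PRECEDENCE[s.category], s.anchor) < (PRECEDENCE[cur.category], cur.anchor):
            best[s.match_start] = s
    return sorted(best.values(), key=lambda s: (s.match_start, PRECEDENCE[s.category]))


def scan_transcript(mirna: SeqRecord, transcript: TranscriptModel) -> list[CandidateSite]:
    """Union of per-region scans; windows are clipped per region so sites
    never span the CDS / 3' UTR boundary."""
    if transcript.cds[1] == transcript.cds[0] and transcript.utr3[1] == transcript.utr3[0]:
        raise DataError(
            f"transcript {transcript.transcript_id!r} has no annotated region"
        )
    sites: list[CandidateSite] = []
    for region in ("UTR3", "CDS"):
        lo, hi = transcript.region_interval(region)
        if hi > lo:
            sites.extend(scan_region(mirna, transcript, region))
    return sites
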