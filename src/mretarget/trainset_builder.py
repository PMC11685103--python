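"""Labeling rules that turn experiment tables into training labels.

Consumes tabular outputs of upstream processing (peak calling, differential
expression, chimera calling) and applies the retention/labeling thresholds:

* peaks: keep score > 0.5 (strict);
* chimeras: keep minimum free energy < 0 kcal/mol AND > 1 chimeric read;
* sites: POSITIVE when overlapping a retained AGO peak from a
  tissue-matched library whose gene responds in the expected direction with
  |fold change| >= 1.5 (|log2FC| >= log2(1.5)), FDR < 0.05 where present;
  NEGATIVE when inside a background (non-AGO) peak, or when the gene is
  non-responsive (|log2FC| < 0.1) and the site overlaps no retained AGO
  peak.  No (miRNA, gene) pair ever contributes to both classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from mretarget.errors import DataError
from mretarget.site_scanner import CandidateSite

LOG2_FOLD_THRESHOLD = math.log2(1.5)
NO_RESPONSE_BAND = 0.1  # |log2FC| below this counts as non-responsive
FDR_THRESHOLD = 0.05
PEAK_SCORE_THRESHOLD = 0.5

DIRECTIONS = ("down_on_transfection", "up_on_knockdown")


@dataclass(frozen=True)
class PeakRecord:
    """An enriched region on a transcript from one CLIP library."""

    transcript_id: str
    start: int
    end: int
    score: float
    library_id: str

    def __post_init__(self) -> None:
        if self.score < 0:
            raise DataError(f"peak score {self.score} < 0")
        if self.end <= self.start:
            raise DataError(f"empty peak interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class PerturbationRecord:
    """Differential-expression result for one gene in one experiment."""

    gene_id: str
    log2_fc: float
    direction_expected: str
    experiment_id: str
    tissue: str = ""
    fdr: Optional[float] = None
    mirna_id: Optional[str] = None  # None = applies to every miRNA

    def __post_init__(self) -> None:
        if self.direction_expected not in DIRECTIONS:
            raise DataError(
                f"unknown direction {self.direction_expected!r}; expected one of {DIRECTIONS}"
            )
        if self.fdr is not None and not 0 <= self.fdr <= 1:
            raise DataError(f"FDR {self.fdr} outside [0, 1]")


@dataclass(frozen=True)
class ChimeraRecord:
    """One miRNA-target chimeric fragment."""

    mirna_id: str
    transcript_id: str
    start: int
    end: int
    mfe: float
    chimeric_reads: int

    def __post_init__(self) -> None:
        if self.chimeric_reads < 0:
            raise DataError(f"negative chimeric read count {self.chimeric_reads}")


@dataclass(frozen=True)
class LibraryInfo:
    """Tissue-map entry linking a CLIP library to its matched experiment."""

    library_id: str
    experiment_id: str
    kind: str = "AGO"  # 'AGO' or 'BACKGROUND'

    def __post_init__(self) -> None:
        if self.kind not in ("AGO", "BACKGROUND"):
            raise DataError(f"unknown library kind {self.kind!r}")


def filter_peaks(peaks: Sequence[PeakRecord], min_score: float = PEAK_SCORE_THRESHOLD):
    """Strict score filter: keep peaks with score > min_score."""
    return [p for p in peaks if p.score > min_score]


def filter_chimeras(records: Sequence[ChimeraRecord]) -> list[ChimeraRecord]:
    """Keep chimeras with mfe < 0 kcal/mol and more than one supporting read.

    Idempotent: applying the filter twice equals applying it once.
    """
    return [r for r in records if r.mfe < 0 and r.chimeric_reads > 1]


def _overlaps(site: CandidateSite, peak: PeakRecord) -> bool:
    return (
        site.transcript_id == peak.transcript_id
        and site.match_start < peak.end
        and peak.start < site.match_end
    )


def _responds(rec: PerturbationRecord) -> bool:
    """Gene responds in the expected direction at >= 1.5-fold, FDR-gated."""
    if rec.fdr is not None and not rec.fdr < FDR_THRESHOLD:
        return False
    if rec.direction_expected == "down_on_transfection":
        return rec.log2_fc <= -LOG2_FOLD_THRESHOLD
    return rec.log2_fc >= LOG2_FOLD_THRESHOLD


def _non_responsive(rec: PerturbationRecord) -> bool:
    return abs(rec.log2_fc) < NO_RESPONSE_BAND


def label_sites(
    sites: Sequence[CandidateSite],
    peaks: Sequence[PeakRecord],
    perturbations: Sequence[PerturbationRecord],
    tissue_map: Sequence[LibraryInfo],
) -> list[tuple[CandidateSite, int]]:
    """Assign 1/0 labels to candidate sites; unlabeled sites are dropped.

    ``peaks`` must already be score-filtered.  Every peak library must
    appear in ``tissue_map``; a missing mapping raises.  Interaction-level
    exclusivity is enforced: once any site marks a (miRNA, gene) pair
    positive, no site of that pair can be labeled negative.
    """
    lib_by_id = {l.library_id: l for l in tissue_map}
    for p in peaks:
        if p.library_id not in lib_by_id:
            raise DataError(
                f"peak library {p.library_id!r} missing from the tissue map"
            )

    # (experiment_id, gene_id[, mirna]) -> perturbation record
    pert_index: dict[tuple, PerturbationRecord] = {}
    for rec in perturbations:
        pert_index[(rec.experiment_id, rec.gene_id, rec.mirna_id)] = rec

    def matched_record(experiment_id: str, site: CandidateSite):
        rec = pert_index.get((experiment_id, site.gene_id, site.mirna_id))
        if rec is None:
            rec = pert_index.get((experiment_id, site.gene_id, None))
        return rec

    ago_peaks = [p for p in peaks if lib_by_id[p.library_id].kind == "AGO"]
    bg_peaks = [p for p in peaks if lib_by_id[p.library_id].kind == "BACKGROUND"]

    provisional: list[tuple[CandidateSite, int]] = []
    positive_pairs: set[tuple[str, str]] = set()
    for site in sites:
        label = None
        overlapping_ago = [p for p in ago_peaks if _overlaps(site, p)]
        for p in overlapping_ago:
            rec = matched_record(lib_by_id[p.library_id].experiment_id, site)
            if rec is not None and _responds(rec):
                label = 1
                break
        if label is None:
            if any(_overlaps(site, p) for p in bg_peaks):
                label = 0
            elif not overlapping_ago:
                recs = [
                    matched_record(l.experiment_id, site)
                    for l in tissue_map
                    if l.kind == "AGO"
                ]
                if any(r is not None and _non_responsive(r) for r in recs):
                    label = 0
        if label is None:
            continue
        if label == 1:
            positive_pairs.add((site.mirna_id, site.gene_id))
        provisional.append((site, label))

    return [
        (site, label)
        for site, label in provisional
        if label == 1 or (site.mirna_id, site.gene_id) not in positive_pairs
    ]
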