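"""Self-contained synthetic fixtures with the statistical structure the
model assumes: transcripts with planted binding sites of known category,
positive/negative feature bundles (positives carry real planted pairing plus
elevated conservation; duplex and folding branches receive genuinely
computed structures), and interaction-level max-score distributions.

Everything is reproducible from ``(config, seed)`` and every planted site
is verified against the scanner before it enters a dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from mretarget import feature_builder, site_scanner
from mretarget.core_io import SeqRecord, TranscriptModel, VectorConservationTrack
from mretarget.errors import DataError
from mretarget.site_scanner import CandidateSite, SiteCategory
from mretarget.trainset_builder import PerturbationRecord

_BASES = np.array(list("ACGU"))
_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
# A mismatch partner that is neither the WC nor the wobble partner.
_MISMATCH = {"A": "C", "C": "A", "G": "G", "U": "C"}

DEFAULT_CATEGORY_PROPORTIONS = {
    "8mer": 0.30,
    "7mer-m8": 0.25,
    "7mer-A1": 0.20,
    "6mer": 0.15,
    "9mer": 0.04,
    "centered": 0.03,
    "compensatory": 0.03,
}


@dataclass(frozen=True)
class SimConfig:
    n_transcripts: int = 50
    transcript_length_range: tuple[int, int] = (300, 1500)
    gc_content: float = 0.5
    n_mirnas: int = 10
    n_pos: int = 200
    n_neg: int = 200
    planted_categories: dict = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROPORTIONS)
    )
    conservation_signal: tuple[float, float, float] = (0.7, 0.3, 0.15)
    region: str = "UTR3"
    mirna_length: int = 22
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.transcript_length_range
        if lo < 120 or hi < lo:
            raise DataError(
                f"degenerate transcript length range ({lo}, {hi}); minimum is 120"
            )
        if not 0 < self.gc_content < 1:
            raise DataError(f"gc_content {self.gc_content} outside (0, 1)")
        total = sum(self.planted_categories.values())
        if abs(total - 1.0) > 1e-6:
            raise DataError(f"category proportions sum to {total}, expected 1")
        mean_pos, mean_neg, sd = self.conservation_signal
        for v in (mean_pos, mean_neg):
            if not 0 <= v <= 1:
                raise DataError(f"conservation mean {v} outside [0, 1]")
        if sd <= 0:
            raise DataError("conservation noise sd must be positive")


def random_rna(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=length, p=probs))


def generate_mirnas(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> list[SeqRecord]:
    rng = rng or np.random.default_rng(cfg.seed)
    return [
        SeqRecord(id=f"mir-{i + 1:03d}", seq=random_rna(rng, cfg.mirna_length, cfg.gc_content))
        for i in range(cfg.n_mirnas)
    ]


def _make_transcript(rng, cfg, tid: str, gene: str) -> TranscriptModel:
    lo, hi = cfg.transcript_length_range
    length = int(rng.integers(lo, hi + 1))
    seq = random_rna(rng, length, cfg.gc_content)
    split = int(length * 0.6)  # CDS = first 60%, 3' UTR = remainder
    return TranscriptModel(
        transcript_id=tid, gene_id=gene, seq=seq, cds=(0, split), utr3=(split, length)
    )


def generate_transcriptome(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> list[TranscriptModel]:
    """i.i.d. transcripts at the configured GC content, 60/40 CDS/UTR split."""
    rng = rng or np.random.default_rng(cfg.seed)
    return [
        _make_transcript(rng, cfg, f"T{i + 1:05d}", f"G{i + 1:05d}")
        for i in range(cfg.n_transcripts)
    ]


# ---------------------------------------------------------------------------
# Site planting
# ---------------------------------------------------------------------------

def _site_assignments(mirna_seq: str, category: str, anchor: int) -> dict[int, str]:
    """Target base assignments that realize ``category`` at ``anchor``,
    including guard bases that block any stronger category at the locus."""
    m = mirna_seq

    def tidx(p: int) -> int:
        return anchor - (p - 1)

    def wc_at(p: int) -> tuple[int, str]:
        return tidx(p), _WC[m[p - 1]]

    def guard_at(p: int) -> tuple[int, str]:
        return tidx(p), _MISMATCH[m[p - 1]]

    a: dict[int, str] = {}
    if category == "6mer":
        a.update(dict(wc_at(p) for p in range(2, 8)))
        a[anchor] = "C"  # block 7mer-A1
        a.update([guard_at(8)])  # block 7mer-m8
    elif category == "7mer-A1":
        a.update(dict(wc_at(p) for p in range(2, 8)))
        a[anchor] = "A"
        a.update([guard_at(8)])  # block 8mer
    elif category == "7mer-m8":
        a.update(dict(wc_at(p) for p in range(2, 9)))
        a[anchor] = "C"  # block 8mer
        a.update([guard_at(9)])  # block 9mer
    elif category == "8mer":
        a.update(dict(wc_at(p) for p in range(2, 9)))
        a[anchor] = "A"
        a.update([guard_at(9)])  # block 9mer
    elif category == "9mer":
        a.update(dict(wc_at(p) for p in range(2, 11)))
    elif category == "centered":
        a.update(dict(wc_at(p) for p in range(4, 15)))
        a.update([guard_at(2), guard_at(3)])  # block canonical and compensatory
    elif category == "compensatory":
        for p in (2, 3, 4, 6, 7):
            a.update([wc_at(p)])
        a.update([guard_at(5)])  # the single seed mismatch
        a.update(dict(wc_at(p) for p in range(13, 18)))
    else:
        raise DataError(f"unknown site category {category!r}")
    return a


def plant_site(
    transcript: TranscriptModel,
    mirna: SeqRecord,
    category: str,
    region: str,
    anchor: int,
    occupied: Optional[Sequence[tuple[int, int]]] = None,
) -> tuple[TranscriptModel, dict]:
    """Write the exact target subsequence realizing ``category`` at ``anchor``.

    Returns the modified transcript and a ground-truth record.  Raises when
    the site footprint leaves the region or overlaps ``occupied`` intervals
    (previously planted sites).
    """
    lo, hi = transcript.region_interval(region)
    assignments = _site_assignments(mirna.seq, category, anchor)
    foot_lo, foot_hi = min(assignments), max(assignments) + 1
    if foot_lo < lo or foot_hi > hi:
        raise DataError(
            f"planted {category} at anchor {anchor} spills outside region "
            f"[{lo}, {hi}) (footprint [{foot_lo}, {foot_hi}))"
        )
    for (olo, ohi) in occupied or ():
        if foot_lo < ohi and olo < foot_hi:
            raise DataError(
                f"planted site footprint [{foot_lo}, {foot_hi}) overlaps an "
                f"existing planted site [{olo}, {ohi})"
            )
    seq = list(transcript.seq)
    for idx, base in assignments.items():
        seq[idx] = base
    new_t = TranscriptModel(
        transcript_id=transcript.transcript_id,
        gene_id=transcript.gene_id,
        seq="".join(seq),
        cds=transcript.cds,
        utr3=transcript.utr3,
        appris_label=transcript.appris_label,
        chrom_map=transcript.chrom_map,
    )
    truth = {
        "mirna_id": mirna.id,
        "transcript_id": transcript.transcript_id,
        "gene_id": transcript.gene_id,
        "region": region,
        "anchor": anchor,
        "category": category,
        "footprint_start": foot_lo,
        "footprint_end": foot_hi,
    }
    return new_t, truth


def _recovered(mirna, transcript, region, anchor, category) -> bool:
    sites = site_scanner.scan_region(mirna, transcript, region)
    return any(s.anchor == anchor and s.category.value == category for s in sites)


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

@dataclass
class MreDataset:
    bundles: list
    arrays: dict
    labels: np.ndarray
    truth: pd.DataFrame
    transcripts: list[TranscriptModel]
    mirnas: list[SeqRecord]
    track: VectorConservationTrack


def _conservation_vector(rng, length: int, mean: float, sd: float) -> np.ndarray:
    # One class-conditional level per site (transcript), small per-base jitter:
    # the class overlap comes from the site-level draw, as configured.
    level = rng.normal(mean, sd)
    return np.clip(rng.normal(level, 0.05, size=length), 0.0, 1.0)


def generate_mre_dataset(cfg: SimConfig, max_retries: int = 20) -> MreDataset:
    """Planted-site MRE dataset: ``n_pos`` positives (scanner-verified planted
    sites, elevated conservation) and ``n_neg`` negatives (scanner-verified
    site-free loci, background conservation), with encoded bundles.
    """
    rng = np.random.default_rng(cfg.seed)
    mirnas = generate_mirnas(cfg, rng)
    mean_pos, mean_neg, sd = cfg.conservation_signal
    categories = list(cfg.planted_categories)
    probs = np.array([cfg.planted_categories[c] for c in categories], dtype=float)
    probs /= probs.sum()

    bundles, rows, transcripts = [], [], []
    track = VectorConservationTrack({})
    vectors = track.vectors  # filled incrementally as transcripts are created

    for i in range(cfg.n_pos):
        category = str(rng.choice(categories, p=probs))
        mirna = mirnas[int(rng.integers(len(mirnas)))]
        for attempt in range(max_retries):
            t = _make_transcript(rng, cfg, f"TP{i + 1:05d}", f"GP{i + 1:05d}")
            lo, hi = t.region_interval(cfg.region)
            if hi - lo < 40:
                continue
            anchor = int(rng.integers(lo + 20, hi - 2))
            try:
                planted, truth = plant_site(t, mirna, category, cfg.region, anchor)
            except DataError:
                continue
            if _recovered(mirna, planted, cfg.region, anchor, category):
                break
        else:
            raise DataError(
                f"could not place a {category} site after {max_retries} retries"
            )
        vectors[planted.transcript_id] = _conservation_vector(rng, len(planted.seq), mean_pos, sd)
        bundles.append(
            feature_builder.build_bundle_at(anchor, cfg.region, mirna, planted, track)
        )
        truth["label"] = 1
        rows.append(truth)
        transcripts.append(planted)

    for i in range(cfg.n_neg):
        mirna = mirnas[int(rng.integers(len(mirnas)))]
        for attempt in range(max_retries):
            t = _make_transcript(rng, cfg, f"TN{i + 1:05d}", f"GN{i + 1:05d}")
            lo, hi = t.region_interval(cfg.region)
            if hi - lo < 40:
                continue
            if site_scanner.scan_region(mirna, t, cfg.region):
                continue  # region must be site-free for this miRNA
            anchor = int(rng.integers(lo + 20, hi - 2))
            break
        else:
            raise DataError(f"could not build a site-free negative after {max_retries} retries")
        vectors[t.transcript_id] = _conservation_vector(rng, len(t.seq), mean_neg, sd)
        bundles.append(feature_builder.build_bundle_at(anchor, cfg.region, mirna, t, track))
        rows.append(
            {
                "mirna_id": mirna.id,
                "transcript_id": t.transcript_id,
                "gene_id": t.gene_id,
                "region": cfg.region,
                "anchor": anchor,
                "category": "none",
                "footprint_start": -1,
                "footprint_end": -1,
                "label": 0,
            }
        )
        transcripts.append(t)

    labels = np.array([r["label"] for r in rows], dtype=int)
    return MreDataset(
        bundles=bundles,
        arrays=feature_builder.bundles_to_arrays(bundles),
        labels=labels,
        truth=pd.DataFrame(rows),
        transcripts=transcripts,
        mirnas=mirnas,
        track=track,
    )


def generate_interaction_dataset(
    n_pos: int = 1000,
    n_neg: int = 1000,
    pos_beta: tuple[float, float] = (5.0, 2.0),
    neg_beta: tuple[float, float] = (2.0, 5.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Interaction-level max-score features: positives draw both region
    maxima from Beta(5, 2), negatives from Beta(2, 5) (defaults)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_pos + n_neg):
        a, b = pos_beta if i < n_pos else neg_beta
        rows.append(
            {
                "mirna_id": f"mir-{i % 50:03d}",
                "gene_id": f"G{i:05d}",
                "max_utr3_score": float(rng.beta(a, b)),
                "max_cds_score": float(rng.beta(a, b)),
                "n_utr3_sites": 1,
                "n_cds_sites": 1,
            }
        )
    labels = np.array([1] * n_pos + [0] * n_neg, dtype=int)
    return pd.DataFrame(rows), labels


def generate_perturbation_fixture(
    targets: Sequence[str],
    nontargets: Sequence[str],
    effect: float,
    seed: int = 0,
    direction: str = "down_on_transfection",
    sd: float = 0.5,
    experiment_id: str = "sim-exp",
    tissue: str = "sim-tissue",
) -> list[PerturbationRecord]:
    """Perturbation table: targets shifted by ``effect`` in the expected
    direction (down for transfection, up for knockdown), non-targets null."""
    if effect < 0:
        raise DataError("effect must be non-negative; direction sets its sign")
    rng = np.random.default_rng(seed)
    shift = -effect if direction == "down_on_transfection" else effect
    records = []
    for g in targets:
        records.append(
            PerturbationRecord(
                gene_id=g, log2_fc=float(rng.normal(shift, sd)),
                direction_expected=direction, experiment_id=experiment_id, tissue=tissue,
            )
        )
    for g in nontargets:
        records.append(
            PerturbationRecord(
                gene_id=g, log2_fc=float(rng.normal(0.0, sd)),
                direction_expected=direction, experiment_id=experiment_id, tissue=tissue,
            )
        )
    return records
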