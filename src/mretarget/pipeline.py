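"""End-to-end prediction: scan -> featurize -> score sites per region ->
aggregate -> score interactions -> write the prediction table.

Output schema (TSV, tab-delimited, header row, 0-based half-open
coordinates): one header row per interaction with the site columns empty,
followed by one row per retained site (site score above the configured
threshold).  Genes without any candidate site are absent.  Outputs are
written to a temporary path and promoted atomically.
"""

from __future__ import annotations

import logging
import os
import tempfile
from typing import Optional

import numpy as np

from mretarget import core_io, feature_builder, gene_meta, mre_model, site_scanner
from mretarget.config import RunConfig
from mretarget.errors import DataError, ModelError

log = logging.getLogger("mretarget")

PREDICTION_COLUMNS = (
    "mirna_id", "gene_id", "transcript_id", "interaction_score",
    "max_utr3_score", "max_cds_score", "region", "start", "end",
    "category", "mre_score",
)


def atomic_write(path: str, text: str) -> None:
    """Write to a temp file in the destination directory, then rename."""
    d = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", suffix=".part")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def load_inputs(cfg: RunConfig):
    cfg.require("mirna_fasta", "transcript_fasta", "regions_tsv")
    mirnas = core_io.read_fasta(cfg.mirna_fasta)
    seqs = core_io.read_fasta(cfg.transcript_fasta)
    transcripts = core_io.read_regions(cfg.regions_tsv, seqs)
    if cfg.conservation_tsv:
        track = core_io.read_conservation_tsv(cfg.conservation_tsv)
    elif cfg.conservation_bigwig:
        track = core_io.BigWigConservationTrack(cfg.conservation_bigwig)
    else:
        track = core_io.VectorConservationTrack({})
        log.warning("no conservation source supplied; using all-missing track")
    return mirnas, transcripts, track


def run_predict(cfg: RunConfig, out_path: str, meta=None) -> int:
    """Execute the full pipeline; returns the number of rows written."""
    cfg.require("utr3_model_dir", "cds_model_dir")
    mirnas, transcripts, track = load_inputs(cfg)
    models = {
        "UTR3": mre_model.load_model(cfg.utr3_model_dir),
        "CDS": mre_model.load_model(cfg.cds_model_dir),
    }
    if meta is None:
        if cfg.meta_model_path is None:
            raise ModelError("no meta model supplied (meta_model_path)")
        meta = load_meta(cfg.meta_model_path)

    log.info("scanning %d transcripts x %d miRNAs", len(transcripts), len(mirnas))
    scored: list[tuple[site_scanner.CandidateSite, float]] = []
    for region in ("UTR3", "CDS"):
        region_sites = []
        for t in transcripts:
            lo, hi = t.region_interval(region)
            if hi <= lo:
                continue
            for m in mirnas:
                region_sites.extend(site_scanner.scan_region(m, t, region))
        if not region_sites:
            continue
        if models[region] is None:
            raise ModelError(f"no trained model for annotated region {region}")
        log.info("region %s: %d candidate sites", region, len(region_sites))
        t_by_id = {t.transcript_id: t for t in transcripts}
        m_by_id = {m.id: m for m in mirnas}
        bundles = [
            feature_builder.build_bundle(s, m_by_id[s.mirna_id], t_by_id[s.transcript_id], track)
            for s in region_sites
        ]
        scores = mre_model.score_mres(models[region], feature_builder.bundles_to_arrays(bundles))
        scored.extend(zip(region_sites, [float(s) for s in scores]))

    features = gene_meta.aggregate_mre_scores(scored)
    if not features:
        atomic_write(out_path, "\t".join(PREDICTION_COLUMNS) + "\n")
        return 0
    probs = gene_meta.score_interactions(meta, gene_meta.features_frame(features))

    gene_tid = {}
    for t in transcripts:
        gene_tid[t.gene_id] = t.transcript_id
    by_pair: dict[tuple[str, str], list] = {}
    for site, score in scored:
        by_pair.setdefault((site.mirna_id, site.gene_id), []).append((site, score))

    lines = ["\t".join(PREDICTION_COLUMNS)]
    n_rows = 0
    for feat, prob in zip(features, probs):
        key = (feat.mirna_id, feat.gene_id)
        tid = gene_tid.get(feat.gene_id, "")
        base = (
            f"{feat.mirna_id}\t{feat.gene_id}\t{tid}\t{prob:.6f}\t"
            f"{feat.max_utr3_score:.6f}\t{feat.max_cds_score:.6f}"
        )
        lines.append(base + "\t\t\t\t\t")
        n_rows += 1
        for site, score in sorted(by_pair[key], key=lambda p: (p[0].region, p[0].match_start)):
            if score > cfg.site_threshold:
                lines.append(
                    base
                    + f"\t{site.region}\t{site.match_start}\t{site.match_end}"
                    + f"\t{site.category.value}\t{score:.6f}"
                )
                n_rows += 1
    atomic_write(out_path, "\n".join(lines) + "\n")
    log.info("wrote %d rows to %s", n_rows, out_path)
    return n_rows


# -- meta model persistence (joblib-free, plain pickle of sklearn model) ----

def save_meta(meta: gene_meta.TrainedMeta, path: str) -> None:
    import pickle

    with open(path, "wb") as fh:
        pickle.dump(meta, fh)


def load_meta(path: str) -> gene_meta.TrainedMeta:
    import pickle

    if not os.path.exists(path):
        raise ModelError(f"meta model {path} not found")
    with open(path, "rb") as fh:
        return pickle.load(fh)
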