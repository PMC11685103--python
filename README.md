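# mretarget

Two-layer miRNA target prediction as a tested library and CLI.

**Layer 1 (site level).** Transcript regions (3′ UTR and CDS, handled by
separate models) are scanned exhaustively for candidate miRNA binding
sites: canonical 6mer/7mer-A1/7mer-m8/8mer/9mer seed matches, centered
sites (≥11 contiguous pairs covering miRNA positions 4–14), and
3′-compensatory sites (one imperfect seed position rescued by ≥4
contiguous pairs in miRNA positions 13–17). Each site is encoded as five
tensors — the 150-nt extended sequence (30-nt window + 60-nt flanks), the
53-nt miRNA–site chimera, the 60-symbol dot-bracket duplex structure, the
150-symbol folding context, and the 150-value conservation profile — and
scored by a five-branch CNN-GRU network (NumPy implementation, no deep
learning framework required).

**Layer 2 (gene level).** The per-region maximum site scores of every
(miRNA, gene) pair feed a gradient-boosted meta-learner (scikit-learn)
that classifies the interaction, evaluated with stratified 5-fold CV.

Also included: the labeling rule engine for building training sets from
CLIP peaks, perturbation DE tables and chimera tables; a synthetic-data
module that plants scanner-verifiable sites; and an evaluation module
(rank AUC, AUPRC, Youden thresholds, rank-sum/KS functional-efficacy
tests).

RNA structures come from an in-repo nearest-neighbor thermodynamic model
(`rna_fold`, numba-accelerated): a duplex co-fold with Turner-style
stacking energies and a single-strand MFE fold. Conservation can be a
per-transcript TSV (self-contained path) or a bigWig + transcript→genome
map (requires the optional `pyBigWig`).

## CLI

```sh
mretarget simulate  --out-dir sim --seed 7 --n-pos 200 --n-neg 200
mretarget scan      --mirna-fasta sim/mirnas.fasta --transcript-fasta sim/transcripts.fasta \
                    --regions sim/regions.tsv --out sites.tsv
mretarget featurize --sites sites.tsv --mirna-fasta sim/mirnas.fasta \
                    --transcript-fasta sim/transcripts.fasta --regions sim/regions.tsv \
                    --conservation sim/conservation.tsv --out features.npz
mretarget train-mre --features sim/features.npz --region UTR3 --seed 7 \
                    --epochs 16 --learning-rate 1e-3 --out-dir utr3_model
mretarget train-meta --features interactions.tsv --seed 7 --out meta.pkl
mretarget predict   --mirna-fasta ... --transcript-fasta ... --regions ... \
                    --conservation ... --utr3-model utr3_model --cds-model cds_model \
                    --meta-model meta.pkl --out predictions.tsv
mretarget evaluate  --predictions predictions.tsv --labels labels.tsv --out metrics.json
```

Exit codes: 0 success, 2 usage, 3 data error, 4 model error. A YAML config
(`--config`) can supply any `predict` option; CLI flags override it and
unknown keys are rejected. All coordinates are 0-based half-open.

Input formats: FASTA (sequences; `T`→`U`, unknown symbols→`N` on ingest); a
region TSV (`transcript_id, gene_id, cds_start, cds_end, utr3_start,
utr3_end[, appris]`); a conservation TSV (`transcript_id, scores` with
comma-separated per-base values in [0, 1]).

The prediction TSV has one row per interaction (site columns empty)
followed by one row per retained site (`region, start, end, category,
mre_score`), sharing the interaction columns (`mirna_id, gene_id,
transcript_id, interaction_score, max_utr3_score, max_cds_score`).

## Model defaults

Per branch: stacked strided valid 1-D convolutions (filters/strides
(35,50)/(2,3) for the sequence branch, (16,32,62)/(2,3,4) for chimera and
duplex, (35,50)/(4,5) for folding, (20,40,60)/(3,4,5) for conservation),
max-pool 2 after every convolution except the last, a 24-unit GRU with
dropout 0.1, then dense layers 90→55→35 (leaky ReLU, batch norm, dropout
0.1) to a sigmoid output. Training: Adam, binary cross-entropy, up to 200
epochs with early stopping (patience 15) at learning rate 1e-4 by default
(the synthetic acceptance runs use 1e-3 and ≤16 epochs to converge at desk
scale). Meta-learner: 200 trees, depth 3, learning rate 0.1.
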