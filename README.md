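# m6amnet

Prediction of m6Am (N6,2′-O-dimethyladenosine) sites from 41-nt RNA windows
centered on an adenosine in a BCA context (B ∈ {C, G, U}).

The package provides:

- **Sequence encoders** (`m6amnet.encoding`): one-hot (4 channels), nucleotide
  chemical property (3 binary channels: ring structure, chemical
  functionality, hydrogen-bond strength) and nucleotide density / accumulated
  nucleotide frequency (1 channel), fused channel-wise into a 41 × 8 matrix.
- **Benchmark construction** (`m6amnet.dataset`): window extraction from a
  reference FASTA with strand handling, BCA-center filtering, greedy
  redundancy removal at an identity threshold (internal backend, or
  `cd-hit-est` when the binary is available), 1:1 negative sampling, random
  stratified train/test splits and chromosome-level hold-out plans.
- **Base classifier** (`m6amnet.model`): a multi-head self-attention
  front-end feeding two parallel branches — a two-layer CNN with max pooling
  and a BiLSTM with a ReLU fully connected layer — concatenated into a
  two-layer softmax prediction head with dropout. Trained with Adam,
  cross-entropy and early stopping on validation accuracy. Ablation flags
  (`no_attention`, `cnn_only`, `bilstm_only`) remove components.
- **Ensemble** (`m6amnet.ensemble`): hyper-parameter grid search, selection
  of the top-3 members by validation accuracy and soft-voting (probability
  averaging) aggregation; hard majority voting behind a flag.
- **Evaluation** (`m6amnet.evaluation`): Sn/Sp/ACC/MCC, rank-based AUROC,
  average-precision AUPR, repeated stratified k-fold cross-validation and
  per-chromosome hold-out evaluation.
- **Synthetic data** (`m6amnet.simulate`): planted-motif window datasets
  with controllable class signal (mixing fraction λ), matched background
  negatives, pseudo-chromosome labels and closed-form background motif
  collision rates.

The neural network runs on a small NumPy reverse-mode autodiff engine
(`m6amnet.nn`) — no deep-learning framework is required.

## CLI

One umbrella executable with subcommands; every run writes a
`run_config.yaml` snapshot next to its outputs and is deterministic under
`--seed`.

```bash
# generate a synthetic planted-motif dataset (FASTA + TSV + spec YAML)
m6amnet simulate --n-per-class 500 --signal-strength 0.9 --seed 1 --out runs/data

# build a benchmark from a reference FASTA and a site list (BED6 or TSV)
m6amnet build-data --fasta genome.fasta --sites sites.tsv --out runs/bench --seed 1

# hyper-parameter search + top-3 soft-voting ensemble checkpoint
m6amnet train --dataset runs/data/dataset.fasta --out runs/ckpt \
    --grid-size 6 --top-k 3 --max-epochs 20 --seed 1

# score 41-nt FASTA records
m6amnet predict --checkpoint runs/ckpt --fasta query.fasta --out runs/pred

# evaluate: direct test run, repeated CV, or chromosome hold-out
m6amnet evaluate --dataset runs/data/dataset.fasta --out runs/eval \
    --protocol test --checkpoint runs/ckpt

# export encoded matrices for inspection
m6amnet encode --fasta query.fasta --out runs/enc
```

Checkpoint layout: a directory with `member_<i>/` (each holding
`weights.npz` + a self-describing `spec.json`) and `manifest.json`
(member order, validation accuracies, aggregation rule, threshold).

## Notes

- Sequences are normalized on read: T→U, lowercase uppercased; ambiguity
  codes (N) are rejected, and windows containing them are dropped with a
  logged count during dataset construction.
- Positions are 0-based (BED-style) on input; minus-strand sites are
  reverse-complemented so windows read 5′→3′ with the candidate A centered.
- Channel order is fixed (one-hot A,C,G,U; NCP ring/functionality/bond;
  fusion one_hot ‖ ncp ‖ nd) so saved models are portable.
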