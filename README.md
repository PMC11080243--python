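# egolink

Multi-label prediction of protein–protein interaction (PPI) types with a
graph neural network that fuses **global** graph features (a GIN encoder
over the whole PPI network) with **local** features (a shared "kernel" GIN
run over every protein's k-hop egonet, with members gated by their encoded
hop distance to the center). Class imbalance across the seven interaction
categories (Reaction, Binding, Ptmod, Activation, Inhibition, Catalysis,
Expression) is handled by an asymmetric focal-style loss with a probability
margin. Evaluation supports Random, BFS and DFS edge partitions; the
traversal-based partitions concentrate test edges around newly discovered
proteins to simulate prediction for unseen proteins.

Everything (including the neural network and its reverse-mode autodiff)
runs on NumPy — no deep-learning framework required.

## Input formats

* **Interaction table** (STRING-actions-like, TSV or CSV, header optional):
  columns `item_id_a`, `item_id_b`, `mode`, where mode is one of the seven
  category names (case-insensitive). Duplicate and reversed pairs merge
  into one undirected multi-label edge.
* **Feature table**: `protein_id` followed by a fixed-length numeric vector
  per row (TSV/CSV).
* **FASTA** (optional): used by the baseline sequence encoder
  (`egolink.seqfeat.encode_sequences_baseline`), a deterministic 13-dim
  residue-class encoding pooled by a width-3 convolution.

## CLI

```bash
egolink synth --preset easy --seed 1 --out runs/fixture     # synthetic data
egolink stats runs/fixture/interactions.tsv                 # category table
egolink split runs/fixture/interactions.tsv --scheme bfs --fraction 0.2 \
    --seed 1 --out runs/split.tsv
egolink train runs/fixture/interactions.tsv \
    --features runs/fixture/features.tsv --split-file runs/split.tsv \
    --hidden-dim 64 --epochs 200 --seed 1 --out runs/exp1
egolink eval runs/fixture/interactions.tsv \
    --features runs/fixture/features.tsv \
    --checkpoint runs/exp1/checkpoint.npz --split-file runs/split.tsv
egolink embed runs/fixture/interactions.tsv \
    --features runs/fixture/features.tsv \
    --checkpoint runs/exp1/checkpoint.npz --out runs/embeddings.tsv
```

Every `train`/`synth` run writes a `config.json` snapshot first, so any
result directory is reproducible from its snapshot and seed.

## Library layout

| module | contents |
|---|---|
| `egolink.graph` | `ProteinGraph`, interaction/feature table I/O, category statistics |
| `egolink.egonet` | k-hop egonet extraction, intra-subgraph distance matrices, batched layout |
| `egolink.model` | global GIN encoder, distance-gated ego-subgraph encoder, fusion, edge head |
| `egolink.losses` | asymmetric loss (`asl`), `focal`, `bce` |
| `egolink.split` | random / BFS / DFS edge partitions |
| `egolink.metrics` | confusion counts, micro/macro/weighted P/R/F1, per-category accuracy |
| `egolink.training` | Adam loop, early stopping, LR decay, checkpointing, evaluation |
| `egolink.synthetic` | seeded stochastic-block-model generator with planted category rules |
| `egolink.autodiff` / `egolink.nn` | minimal NumPy autodiff + layers |

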