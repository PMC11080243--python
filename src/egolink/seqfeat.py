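"""Baseline sequence encoder: 13-dim per-residue class encoding pooled by a
width-3 convolution and a linear map to the configured output dimension.

Each residue is encoded as two concatenated one-hots: a 5-class
co-occurrence grouping and an 8-class electrostatic/hydrophobic grouping
(the classical conjoint-triad classes plus a catch-all for non-standard
letters). The class table is shipped as data and can be overridden. The
convolution/linear weights are fixed random projections drawn from the
seed, so the encoder is deterministic and training-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["SeqEncoderConfig", "ResidueClassTable", "encode_sequences_baseline",
           "read_fasta", "encode_sequence"]

# 5 co-occurrence classes: small/polar, aliphatic-hydrophobic, aromatic,
# acidic+amide, basic. Index 0 doubles as the catch-all class.
DEFAULT_COOCCURRENCE = {
    **{aa: 0 for aa in "GAST"},
    **{aa: 1 for aa in "CVILPM"},
    **{aa: 2 for aa in "FYW"},
    **{aa: 3 for aa in "DENQ"},
    **{aa: 4 for aa in "RKH"},
}

# 7 conjoint-triad electrostatic/hydrophobic classes + catch-all (index 7)
DEFAULT_ELECTRO_HYDRO = {
    **{aa: 0 for aa in "AGV"},
    **{aa: 1 for aa in "ILFP"},
    **{aa: 2 for aa in "YMTS"},
    **{aa: 3 for aa in "HNQW"},
    **{aa: 4 for aa in "RK"},
    **{aa: 5 for aa in "DE"},
    **{aa: 6 for aa in "C"},
}

N_COOC = 5
N_EH = 8
RESIDUE_DIM = N_COOC + N_EH  # 13


@dataclass(frozen=True)
class ResidueClassTable:
    cooccurrence: dict = field(default_factory=lambda: dict(DEFAULT_COOCCURRENCE))
    electro_hydro: dict = field(default_factory=lambda: dict(DEFAULT_ELECTRO_HYDRO))

    def encode(self, residue: str) -> np.ndarray:
        """13-dim two-hot vector; unknown letters map to catch-all classes."""
        vec = np.zeros(RESIDUE_DIM)
        vec[self.cooccurrence.get(residue, 0)] = 1.0
        vec[N_COOC + self.electro_hydro.get(residue, N_EH - 1)] = 1.0
        return vec


@dataclass(frozen=True)
class SeqEncoderConfig:
    output_dim: int = 64
    conv_channels: int = 32
    seed: int = 0
    table: ResidueClassTable = field(default_factory=ResidueClassTable)


def make_weights(config: SeqEncoderConfig) -> tuple[np.ndarray, np.ndarray]:
    """(conv kernel (3, 13, channels), linear map (channels, output_dim))."""
    rng = np.random.default_rng(config.seed)
    kernel = rng.normal(0.0, 1.0 / np.sqrt(3 * RESIDUE_DIM),
                        size=(3, RESIDUE_DIM, config.conv_channels))
    linear = rng.normal(0.0, 1.0 / np.sqrt(config.conv_channels),
                        size=(config.conv_channels, config.output_dim))
    return kernel, linear


def encode_sequence(seq: str, config: SeqEncoderConfig,
                    weights: tuple[np.ndarray, np.ndarray] | None = None
                    ) -> np.ndarray:
    """Encode one sequence to a length-`output_dim` vector."""
    if not seq:
        raise ValueError("empty sequence")
    kernel, linear = weights if weights is not None else make_weights(config)
    onehot = np.stack([config.table.encode(aa) for aa in seq.upper()])
    # width-3 convolution with edge padding, then ReLU and mean pooling
    padded = np.pad(onehot, ((1, 1), (0, 0)))
    conv = (padded[:-2] @ kernel[0] + padded[1:-1] @ kernel[1]
            + padded[2:] @ kernel[2])
    pooled = np.maximum(conv, 0.0).mean(axis=0)
    return pooled @ linear


def read_fasta(path: str | Path) -> dict[str, str]:
    path = Path(path)
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                records[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        else:
            if name is None:
                raise ValueError(f"{path}: not FASTA (sequence before header)")
            chunks.append(line)
    if name is not None:
        records[name] = "".join(chunks)
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def encode_sequences_baseline(fasta: str | Path,
                              config: SeqEncoderConfig = SeqEncoderConfig(),
                              out_path: str | Path | None = None):
    """Encode every FASTA record; optionally write a feature TSV.

    Returns (ids, matrix) where matrix is len(ids) x output_dim.
    """
    records = read_fasta(fasta)
    weights = make_weights(config)
    ids = list(records.keys())
    X = np.stack([encode_sequence(records[i], config, weights) for i in ids])
    if out_path is not None:
        with Path(out_path).open("w") as fh:
            fh.write("protein_id\t"
                     + "\t".join(f"f{i}" for i in range(config.output_dim)) + "\n")
            for pid, row in zip(ids, X):
                fh.write(pid + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")
    return ids, X
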