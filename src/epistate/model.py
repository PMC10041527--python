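"""Two-tailed network: CNN sequence tail + linear cell-state tail + MLP heads.

The sequence tail reduces a one-hot 4 x 1,000 window to a fixed-size
embedding through convolution blocks and a global max pool.  The cell-state
tail is a linear map from the one-hot cell-type vector, i.e. a learned
embedding matrix whose row n is the latent representation of cell type n.
The head concatenates the two embeddings and emits one value per epigenetic
feature, for every requested cell type, re-using the sequence embedding
across cells.

Two head variants exist.  The single head predicts the target t[n, k]
directly.  The split head predicts the across-cell mean profile M[k]
(sequence-only) and the cell-specific deviation D[n, k] separately, with the
combined prediction t[n, k] = M[k] + D[n, k]; this decomposition reflects
that sequence explains far more target variance than cell identity does.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._autograd import Tensor, concat, conv1d, maxpool1d, set_guided

DEFAULT_CONV_SPEC = ((64, 8, 4), (128, 8, 4), (256, 8, 1))


@dataclass
class ModelConfig:
    n_cells: int
    n_features: int
    emb_length: int = 32
    seq_embedding_size: int | None = None  # default: channels of last conv block
    head_depth: int = 8
    head_width: int = 512
    head_variant: str = "single"  # or "split_MD"
    task: str = "qualitative"  # or "quantitative"
    conv_spec: tuple = DEFAULT_CONV_SPEC
    conv_bias_init: float = -0.5
    input_length: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.emb_length < 1 or self.head_depth < 1:
            raise ValueError("emb_length and head_depth must be >= 1")
        if self.head_variant not in ("single", "split_MD"):
            raise ValueError("head_variant must be 'single' or 'split_MD'")
        if self.task not in ("qualitative", "quantitative"):
            raise ValueError("task must be 'qualitative' or 'quantitative'")
        if self.head_variant == "split_MD" and self.task != "quantitative":
            raise ValueError("the split M/D head is a quantitative-task variant")


def _mlp_params(rng, sizes):
    layers = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        w = Tensor(rng.normal(0, np.sqrt(2.0 / fan_in), (fan_in, fan_out)), requires_grad=True)
        b = Tensor(np.zeros(fan_out), requires_grad=True)
        layers.append((w, b))
    return layers


def _mlp_forward(layers, x: Tensor) -> Tensor:
    for i, (w, b) in enumerate(layers):
        x = x @ w + b
        if i < len(layers) - 1:
            x = x.relu()
    return x


class Network:
    """Parameter container + forward passes (the ModelState)."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        L = config.input_length
        c_in = 4
        self.conv_layers = []
        for channels, kernel, pool in config.conv_spec:
            L = L - kernel + 1
            if L <= 0:
                raise ValueError(
                    f"conv_spec incompatible with {config.input_length}-bp input: "
                    f"length fell to {L} at block with kernel {kernel}"
                )
            w = Tensor(
                rng.normal(0, np.sqrt(2.0 / (c_in * kernel)), (channels, c_in, kernel)),
                requires_grad=True,
            )
            # negative bias init keeps ReLU activations sparse, so the global
            # max pool reflects genuine motif matches instead of the extreme
            # value of background activations — without it the sequence tail
            # sits on a long plateau before any filter becomes selective
            b = Tensor(np.full(channels, float(config.conv_bias_init)), requires_grad=True)
            self.conv_layers.append((w, b, pool))
            L = L // pool if pool > 1 else L
            if L <= 0:
                raise ValueError(
                    f"conv_spec incompatible with input: length 0 after pool {pool}"
                )
            c_in = channels
        self.seq_dim = config.seq_embedding_size or c_in
        if self.seq_dim != c_in:
            self.seq_proj = _mlp_params(rng, [c_in, self.seq_dim])
        else:
            self.seq_proj = None

        # unit-scale init keeps cell embeddings commensurate with the ReLU
        # sequence features, so the head's bilinear interaction gets usable
        # gradient from the first steps
        self.cell_embedding = Tensor(
            rng.normal(0, 1.0, (config.n_cells, config.emb_length)), requires_grad=True
        )

        widths = [config.head_width] * (config.head_depth - 1)
        if config.head_variant == "single":
            self.head = _mlp_params(
                rng, [self.seq_dim + config.emb_length, *widths, config.n_features]
            )
            self.head_M = self.head_D = None
        else:
            self.head = None
            self.head_M = _mlp_params(rng, [self.seq_dim, *widths, config.n_features])
            self.head_D = _mlp_params(
                rng, [self.seq_dim + config.emb_length, *widths, config.n_features]
            )

    # ------------------------------------------------------------------

    @property
    def parameters(self) -> list:
        params = []
        for w, b, _ in self.conv_layers:
            params += [w, b]
        for group in (self.seq_proj, self.head, self.head_M, self.head_D):
            if group:
                for w, b in group:
                    params += [w, b]
        params.append(self.cell_embedding)
        return params

    def sequence_embedding(self, x: Tensor) -> Tensor:
        """(B, 4, L) one-hot input -> (B, seq_dim) embedding."""
        h = x
        for w, b, pool in self.conv_layers:
            h = conv1d(h, w, b).relu()
            if pool > 1:
                h = maxpool1d(h, pool)
        e = h.max(axis=2)  # global max pool over positions
        if self.seq_proj is not None:
            e = _mlp_forward(self.seq_proj, e).relu()
        return e

    def _pair_input(self, seq_emb: Tensor, cell_idx: np.ndarray) -> Tensor:
        B = seq_emb.shape[0]
        N = len(cell_idx)
        cell_emb = self.cell_embedding[cell_idx]  # (N, E)
        s = seq_emb.reshape(B, 1, self.seq_dim).broadcast_to((B, N, self.seq_dim))
        c = cell_emb.reshape(1, N, self.config.emb_length).broadcast_to(
            (B, N, self.config.emb_length)
        )
        return concat([s, c], axis=2)

    def forward(self, x: Tensor, cell_idx=None) -> Tensor:
        """Predictions of shape (B, |cells|, n_features).

        The sequence embedding is computed once per window and shared across
        all requested cell types.  Qualitative task: sigmoid probabilities.
        """
        cell_idx = self._check_cells(cell_idx)
        if self.config.head_variant == "split_MD":
            m, d = self.forward_split(x, cell_idx)
            B, N = d.shape[0], d.shape[1]
            return m.reshape(B, 1, self.config.n_features).broadcast_to(d.shape) + d
        seq_emb = self.sequence_embedding(x)
        pair = self._pair_input(seq_emb, cell_idx)
        B, N = pair.shape[0], pair.shape[1]
        out = _mlp_forward(self.head, pair.reshape(B * N, pair.shape[2]))
        out = out.reshape(B, N, self.config.n_features)
        if self.config.task == "qualitative":
            out = out.sigmoid()
        return out

    def forward_split(self, x: Tensor, cell_idx=None) -> tuple:
        """(M, D): M (B, n_features) depends on sequence only; D (B, N, n_features)."""
        if self.config.head_variant != "split_MD":
            raise ValueError("forward_split requires head_variant='split_MD'")
        cell_idx = self._check_cells(cell_idx)
        seq_emb = self.sequence_embedding(x)
        m = _mlp_forward(self.head_M, seq_emb)
        pair = self._pair_input(seq_emb, cell_idx)
        B, N = pair.shape[0], pair.shape[1]
        d = _mlp_forward(self.head_D, pair.reshape(B * N, pair.shape[2]))
        d = d.reshape(B, N, self.config.n_features)
        return m, d

    def _check_cells(self, cell_idx) -> np.ndarray:
        if cell_idx is None:
            return np.arange(self.config.n_cells)
        cell_idx = np.asarray(cell_idx, dtype=int)
        if cell_idx.size and (cell_idx.min() < 0 or cell_idx.max() >= self.config.n_cells):
            raise ValueError("unknown cell index")
        return cell_idx

    def get_cell_embeddings(self) -> np.ndarray:
        """Embedding matrix, row n = latent representation of cell type n."""
        return self.cell_embedding.data.copy()

    def input_saliency(
        self, seq: np.ndarray, cell: int, feature: int, guided: bool = True
    ) -> np.ndarray:
        """Per-position input-gradient magnitude for one (cell, feature) output.

        Gradient of the selected output w.r.t. the one-hot input, absolute
        value, max-reduced over the 4 nucleotide channels.  `guided` clamps
        negative intermediate gradients at ReLUs (guided backpropagation).
        """
        x = Tensor(np.asarray(seq)[None, :, :], requires_grad=True)
        out = self.forward(x, np.array([cell]))
        set_guided(guided)
        try:
            out[0, 0, feature].backward()
        finally:
            set_guided(False)
        return np.abs(x.grad[0]).max(axis=0)

    # ---- persistence --------------------------------------------------

    def state_blobs(self) -> dict:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters)}

    def save(self, path) -> None:
        cfg = asdict(self.config)
        cfg["conv_spec"] = [list(t) for t in cfg["conv_spec"]]
        np.savez(path, __config__=json.dumps(cfg), **self.state_blobs())

    @classmethod
    def load(cls, path) -> "Network":
        with np.load(path, allow_pickle=False) as z:
            cfg = json.loads(str(z["__config__"]))
            cfg["conv_spec"] = tuple(tuple(t) for t in cfg["conv_spec"])
            net = cls(ModelConfig(**cfg))
            for i, p in enumerate(net.parameters):
                p.data[...] = z[f"p{i}"]
        return net


# ---------------------------------------------------------------------------
# spec-surface convenience functions


def build_model(config: ModelConfig) -> Network:
    return Network(config)


def forward(net: Network, seq: np.ndarray, cells=None) -> np.ndarray:
    """Batched forward pass on raw numpy input; returns (B, |cells|, n_features)."""
    seq = np.asarray(seq)
    if seq.ndim == 2:
        seq = seq[None]
    return net.forward(Tensor(seq), cells).data


def forward_split(net: Network, seq: np.ndarray, cells=None) -> tuple:
    seq = np.asarray(seq)
    if seq.ndim == 2:
        seq = seq[None]
    m, d = net.forward_split(Tensor(seq), cells)
    combined = m.data[:, None, :] + d.data
    return m.data, d.data, combined


def get_cell_embeddings(net: Network) -> np.ndarray:
    return net.get_cell_embeddings()


def input_saliency(net: Network, seq, cell: int, feature: int, guided: bool = True):
    return net.input_saliency(np.asarray(seq), cell, feature, guided=guided)


def export_embeddings_tsv(net: Network, cells: list, path) -> None:
    import pandas as pd

    emb = net.get_cell_embeddings()
    df = pd.DataFrame(emb, index=cells, columns=[f"dim{i}" for i in range(emb.shape[1])])
    df.to_csv(path, sep="\t", index_label="cell_id")
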