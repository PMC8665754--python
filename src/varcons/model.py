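"""Recurrent pathogenicity network.

Architecture: three bidirectional LSTM encoders independently process the
wild-type, mutant and conservation-profile matrices into per-residue
features. Per residue, wild-type and profile features are concatenated
(likewise mutant and profile), each concatenated sequence runs through a
second LSTM of which only the final state is kept, and the two branch
vectors are joined into the extracted feature vector. Task-specific
classifier heads (two fully connected layers, dropout after the first,
2-way softmax) sit on top of the shared extractor; with the optional
85-dimensional substitution-feature branch, the extracted vector and the
feature vector each pass a separate linear layer with sigmoid activation
before concatenation. End-user scores always come from the clinical head.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .curation import CANONICAL_AA
from .featurize import SNVBOX_DIM, FeatureDataset

__all__ = [
    "ModelConfig",
    "PathogenicityScore",
    "Model",
    "make_model",
    "extract_features",
    "classify",
    "multitask_forward",
]

TASKS = ("clinical", "conservation")


@dataclass(frozen=True)
class ModelConfig:
    lstm_hidden: int = 64
    fc_hidden: int = 64
    dropout_rate: float = 0.3
    use_snvbox: bool = False
    heads: tuple[str, ...] = ("clinical", "conservation")
    bidirectional_second: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if not self.heads:
            raise ValueError("at least one classifier head is required")
        for h in self.heads:
            if h not in TASKS:
                raise ValueError(f"unknown head {h!r}")

    @property
    def extracted_dim(self) -> int:
        per_branch = self.lstm_hidden * (2 if self.bidirectional_second else 1)
        return 2 * per_branch


@dataclass(frozen=True)
class PathogenicityScore:
    p_pathogenic: float
    p_benign: float

    def __post_init__(self) -> None:
        if abs(self.p_pathogenic + self.p_benign - 1.0) > 1e-6:
            raise ValueError("probabilities must sum to 1")


# ---------------------------------------------------------------------------
# Parameter construction


def _uniform(rng, shape, k):
    return rng.uniform(-k, k, size=shape).astype(np.float32)


#: Gate-bias initialization: the forget gate opens (+3) and the input gate
#: closes (-3) so each LSTM starts with a memory horizon comparable to the
#: window length and integrates per-residue features across the window
#: instead of only the most recent steps (chrono-style initialization).
GATE_BIAS = 3.0


def _lstm_params(rng, name, d_in, hidden, params, input_scale=None):
    k = 1.0 / np.sqrt(hidden)
    kx = k if input_scale is None else input_scale
    params[f"{name}_Wx"] = Tensor(_uniform(rng, (d_in, 4 * hidden), kx), requires_grad=True)
    params[f"{name}_Wh"] = Tensor(_uniform(rng, (hidden, 4 * hidden), k), requires_grad=True)
    b = np.zeros((1, 4 * hidden), dtype=np.float32)
    b[0, :hidden] = -GATE_BIAS
    b[0, hidden:2 * hidden] = GATE_BIAS
    params[f"{name}_b"] = Tensor(b, requires_grad=True)


def _linear_params(rng, name, d_in, d_out, params):
    k = 1.0 / np.sqrt(d_in)
    params[f"{name}_W"] = Tensor(_uniform(rng, (d_in, d_out), k), requires_grad=True)
    params[f"{name}_b"] = Tensor(np.zeros((1, d_out), dtype=np.float32), requires_grad=True)


def init_params(cfg: ModelConfig) -> dict[str, Tensor]:
    rng = np.random.default_rng(cfg.seed)
    H = cfg.lstm_hidden
    params: dict[str, Tensor] = {}
    # First-stage input projections use unit-scale init: the inputs are
    # one-hot or frequency rows of unit norm, so unit-scale projections
    # yield diverse nonlinear per-residue features from the first step.
    for name in ("wt", "mut", "msa"):
        for direction in ("f", "b"):
            _lstm_params(rng, f"enc_{name}_{direction}", 20, H, params,
                         input_scale=1.0)
    second_dirs = ("f", "b") if cfg.bidirectional_second else ("f",)
    for branch in ("wt", "mut"):
        for direction in second_dirs:
            _lstm_params(rng, f"sec_{branch}_{direction}", 4 * H, H, params)
    for task in cfg.heads:
        if cfg.use_snvbox:
            _linear_params(rng, f"head_{task}_ext", cfg.extracted_dim, cfg.fc_hidden, params)
            _linear_params(rng, f"head_{task}_snv", SNVBOX_DIM, cfg.fc_hidden, params)
            fc1_in = 2 * cfg.fc_hidden
        else:
            fc1_in = cfg.extracted_dim
        _linear_params(rng, f"head_{task}_fc1", fc1_in, cfg.fc_hidden, params)
        _linear_params(rng, f"head_{task}_fc2", cfg.fc_hidden, 2, params)
    return params


# ---------------------------------------------------------------------------
# Forward passes


def _linear(x: Tensor, params, name) -> Tensor:
    return ad.matmul(x, params[f"{name}_W"]) + params[f"{name}_b"]


def _lstm_pass(xs: list[Tensor], params, name, hidden: int) -> list[Tensor]:
    Wx, Wh, b = params[f"{name}_Wx"], params[f"{name}_Wh"], params[f"{name}_b"]
    B = xs[0].data.shape[0]
    h = Tensor(np.zeros((B, hidden), dtype=np.float32))
    c = Tensor(np.zeros((B, hidden), dtype=np.float32))
    H = hidden
    out: list[Tensor] = []
    for x in xs:
        z = ad.matmul(x, Wx) + ad.matmul(h, Wh) + b
        i = ad.sigmoid(z.cols(0, H))
        f = ad.sigmoid(z.cols(H, 2 * H))
        g = ad.tanh(z.cols(2 * H, 3 * H))
        o = ad.sigmoid(z.cols(3 * H, 4 * H))
        c = f * c + i * g
        h = o * ad.tanh(c)
        out.append(h)
    return out


def _bilstm(xs: list[Tensor], params, name, hidden: int) -> list[Tensor]:
    fwd = _lstm_pass(xs, params, f"{name}_f", hidden)
    bwd = _lstm_pass(xs[::-1], params, f"{name}_b", hidden)[::-1]
    return [ad.concat([f, b]) for f, b in zip(fwd, bwd)]


def extract_features(
    wt: np.ndarray, mut: np.ndarray, msa: np.ndarray,
    params: dict[str, Tensor], cfg: ModelConfig,
) -> Tensor:
    """Shared feature extractor: (B, L, 20) triple -> (B, extracted_dim).

    Deterministic given parameters; the second-stage LSTM keeps only its
    final state per branch.
    """
    if not (wt.shape == mut.shape == msa.shape):
        raise ValueError("wt/mut/msa batches must share one shape")
    L = wt.shape[1]
    H = cfg.lstm_hidden
    xs = {
        "wt": [Tensor(wt[:, t, :]) for t in range(L)],
        "mut": [Tensor(mut[:, t, :]) for t in range(L)],
        "msa": [Tensor(msa[:, t, :]) for t in range(L)],
    }
    enc = {name: _bilstm(seq, params, f"enc_{name}", H) for name, seq in xs.items()}
    branch_out: list[Tensor] = []
    for branch in ("wt", "mut"):
        merged = [ad.concat([enc[branch][t], enc["msa"][t]]) for t in range(L)]
        last = _lstm_pass(merged, params, f"sec_{branch}_f", H)[-1]
        if cfg.bidirectional_second:
            last_b = _lstm_pass(merged[::-1], params, f"sec_{branch}_b", H)[-1]
            last = ad.concat([last, last_b])
        branch_out.append(last)
    return ad.concat(branch_out)


def classify(
    extracted: Tensor,
    snvbox: np.ndarray | None,
    params: dict[str, Tensor],
    cfg: ModelConfig,
    task: str = "clinical",
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Task head: extracted features (+ optional 85-vector) -> logits (B, 2).

    Dropout is applied after the first fully connected layer during
    training only; inference is deterministic.
    """
    if task not in cfg.heads:
        raise ValueError(f"model has no {task!r} head")
    if cfg.use_snvbox:
        if snvbox is None:
            raise ValueError("snvbox-enabled head requires a feature matrix "
                             "(zero-filled rows are valid for missing variants)")
        e = ad.sigmoid(_linear(extracted, params, f"head_{task}_ext"))
        s = ad.sigmoid(_linear(Tensor(snvbox), params, f"head_{task}_snv"))
        x = ad.concat([e, s])
    else:
        if snvbox is not None and np.any(np.asarray(snvbox)):
            raise ValueError("snvbox features supplied to a model configured "
                             "without the snvbox branch")
        x = extracted
    h1 = ad.relu(_linear(x, params, f"head_{task}_fc1"))
    if train:
        h1 = ad.dropout(h1, cfg.dropout_rate, rng or np.random.default_rng(), train)
    return _linear(h1, params, f"head_{task}_fc2")


# ---------------------------------------------------------------------------
# Model container


@dataclass
class Model:
    cfg: ModelConfig
    params: dict[str, Tensor]
    window_length: int
    alphabet: str = CANONICAL_AA
    meta: dict = field(default_factory=dict)

    def forward_logits(
        self, wt, mut, msa, snvbox=None, task: str = "clinical",
        train: bool = False, rng=None,
    ) -> Tensor:
        extracted = extract_features(wt, mut, msa, self.params, self.cfg)
        return classify(extracted, snvbox, self.params, self.cfg, task, train, rng)

    def predict_proba(
        self, ds: FeatureDataset, task: str = "clinical", batch_size: int = 256
    ) -> np.ndarray:
        """P(pathogenic) for every example, from the requested head."""
        if ds.window_length != self.window_length:
            raise ValueError(
                f"dataset featurized at L={ds.window_length}, model expects "
                f"L={self.window_length}"
            )
        out = np.empty(len(ds), dtype=np.float64)
        for start in range(0, len(ds), batch_size):
            sl = slice(start, min(start + batch_size, len(ds)))
            logits = self.forward_logits(
                ds.wt[sl], ds.mut[sl], ds.msa[sl],
                ds.snvbox[sl] if self.cfg.use_snvbox else None, task=task,
            )
            out[sl] = ad.softmax(logits.data)[:, 1]
        return out

    def score_one(self, wt, mut, msa, snvbox=None, task="clinical") -> PathogenicityScore:
        logits = self.forward_logits(wt[None], mut[None], msa[None],
                                     None if snvbox is None else snvbox[None],
                                     task=task)
        p = ad.softmax(logits.data)[0]
        return PathogenicityScore(float(p[1]), float(p[0]))

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "config": asdict(self.cfg),
            "window_length": self.window_length,
            "alphabet": self.alphabet,
            "extra": self.meta,
        }
        arrays = {k: t.data for k, t in self.params.items()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "Model":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            cfg_d = meta["config"]
            cfg_d["heads"] = tuple(cfg_d["heads"])
            cfg = ModelConfig(**cfg_d)
            params = {
                k: Tensor(z[k], requires_grad=True)
                for k in z.files if k != "__meta__"
            }
        return cls(cfg, params, meta["window_length"], meta["alphabet"],
                   meta.get("extra", {}))


def make_model(cfg: ModelConfig, window_length: int,
               alphabet: str = CANONICAL_AA) -> Model:
    """Freshly initialised model (seeded by ``cfg.seed``)."""
    return Model(cfg, init_params(cfg), window_length, alphabet,
                 meta={"init_seed": cfg.seed})


def multitask_forward(model: Model, wt, mut, msa, snvbox=None,
                      task: str = "clinical") -> np.ndarray:
    """Scores from the shared extractor routed through one task head."""
    logits = model.forward_logits(wt, mut, msa, snvbox, task=task)
    return ad.softmax(logits.data)[:, 1]
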