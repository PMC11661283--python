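"""Attention-MIL deep Cox model on patch-embedding bags.

Architecture: each patch embedding is linearly projected to ``proj_dim``
(default 256) with ReLU and dropout; a multi-head self-attention layer with a
Nyström low-rank approximation (landmark tokens = segment means, iterative
Moore-Penrose pseudo-inverse of the landmark kernel) mixes information across
patches, with a residual connection; average pooling over patches yields a
slide-level feature, and a linear head maps it to a scalar log-partial-hazard
risk.

Training minimizes the average negative log partial likelihood (Breslow risk
sets). Bags are scored one at a time — subsampling ``patches_per_bag_train``
patches without replacement when a bag is larger — and risks are accumulated
over ``accumulation_size`` patients before each loss evaluation and Adam
update, since the partial likelihood is defined across patients. An internal
event-stratified validation split drives a reduce-on-plateau learning-rate
schedule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, stack
from .cohort_io import EmbeddingBag, RiskVector, SurvivalOutcome

logger = logging.getLogger(__name__)


@dataclass
class MILNetConfig:
    input_dim: int
    proj_dim: int = 256
    dropout: float = 0.25
    n_heads: int = 8
    n_landmarks: int = 256
    pinv_iterations: int = 18

    def __post_init__(self) -> None:
        if self.proj_dim % self.n_heads:
            raise ValueError("proj_dim must be divisible by n_heads")
        if self.n_landmarks < 1:
            raise ValueError("n_landmarks must be >= 1")


@dataclass
class TrainConfig:
    lr: float = 1e-3
    epochs: int = 100
    patches_per_bag_train: int = 4096
    plateau_patience: int = 5
    plateau_gamma: float = 0.1
    accumulation_size: int = 32
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.accumulation_size < 2:
            raise ValueError("accumulation_size must be >= 2 (risk sets span patients)")
        if min(self.lr, self.epochs, self.patches_per_bag_train, self.plateau_patience,
               self.plateau_gamma, self.val_fraction) <= 0:
            raise ValueError("training hyper-parameters must be positive")


def init_params(cfg: MILNetConfig, seed: int = 0) -> dict[str, np.ndarray]:
    """Scaled-normal initialization of all trainable arrays."""
    rng = np.random.default_rng(seed)
    d, h = cfg.input_dim, cfg.proj_dim

    def w(shape, fan_in):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

    return {
        "W_proj": w((d, h), d), "b_proj": np.zeros(h),
        "W_q": w((h, h), h), "W_k": w((h, h), h), "W_v": w((h, h), h),
        "W_o": w((h, h), h),
        "W_head": w((h, 1), h), "b_head": np.zeros(1),
    }


# ---------------------------------------------------------------------------
# Nyström attention


def _segment_mean_matrix(n: int, m: int) -> np.ndarray:
    """(m x n) averaging matrix mapping tokens to m contiguous-segment means."""
    bounds = np.linspace(0, n, m + 1).round().astype(int)
    S = np.zeros((m, n))
    for i in range(m):
        lo, hi = bounds[i], max(bounds[i + 1], bounds[i] + 1)
        S[i, lo:hi] = 1.0 / (hi - lo)
    return S


def _iterative_pinv(A: Tensor, iters: int) -> Tensor:
    """Newton-Schulz style iteration converging to the Moore-Penrose
    pseudo-inverse of the (m x m) landmark kernel."""
    m = A.shape[-1]
    I = Tensor(np.eye(m))
    a = A.data
    scale = 1.0 / (np.abs(a).sum(axis=-1).max() * np.abs(a).sum(axis=-2).max())
    Z = A.transpose_last() * scale  # init scale treated as a constant
    for _ in range(iters):
        AZ = A @ Z
        Z = Z @ (13.0 * I - AZ @ (15.0 * I - AZ @ (7.0 * I - AZ))) * 0.25
    return Z


def _exact_attention(q: Tensor, k: Tensor, v: Tensor, scale: float) -> Tensor:
    attn = ((q @ k.transpose_last()) * scale).softmax(axis=-1)
    return attn @ v


def nystrom_attention(tokens: Tensor, params: dict, cfg: MILNetConfig) -> Tensor:
    """Multi-head self-attention over an (n x proj_dim) token matrix.

    When n < n_landmarks the exact softmax attention is used; otherwise the
    n x n kernel is approximated with landmark tokens (contiguous segment
    means), two small softmax kernels, and an iteratively approximated
    pseudo-inverse of the landmark-landmark kernel.
    """
    n, h = tokens.shape
    H, dh = cfg.n_heads, cfg.proj_dim // cfg.n_heads
    q = (tokens @ Tensor._lift(params["W_q"])).reshape(n, H, dh).swapaxes(0, 1)
    k = (tokens @ Tensor._lift(params["W_k"])).reshape(n, H, dh).swapaxes(0, 1)
    v = (tokens @ Tensor._lift(params["W_v"])).reshape(n, H, dh).swapaxes(0, 1)
    scale = 1.0 / np.sqrt(dh)
    m = min(cfg.n_landmarks, n)
    if n < cfg.n_landmarks:
        out = _exact_attention(q, k, v, scale)
    else:
        S = Tensor(_segment_mean_matrix(n, m))
        q_l = S @ q  # (H, m, dh) landmark queries
        k_l = S @ k
        F = ((q @ k_l.transpose_last()) * scale).softmax(axis=-1)      # n x m
        A = ((q_l @ k_l.transpose_last()) * scale).softmax(axis=-1)    # m x m
        B = ((q_l @ k.transpose_last()) * scale).softmax(axis=-1)      # m x n
        out = F @ (_iterative_pinv(A, cfg.pinv_iterations) @ (B @ v))
    merged = out.swapaxes(0, 1).reshape(n, cfg.proj_dim)
    return merged @ Tensor._lift(params["W_o"])


# ---------------------------------------------------------------------------
# Forward pass and loss


def forward_bag(params: dict, vectors: np.ndarray, cfg: MILNetConfig,
                train: bool = False, rng: np.random.Generator | None = None,
                as_tensor: bool = False):
    """Score one bag: project -> ReLU -> dropout (train) -> attention with a
    residual connection -> mean-pool over patches -> linear head -> scalar."""
    if vectors.shape[1] != cfg.input_dim:
        raise ValueError(f"bag dimension {vectors.shape[1]} != model input_dim {cfg.input_dim}")
    x = Tensor(np.asarray(vectors, float))
    p = {k: (v if isinstance(v, Tensor) else v) for k, v in params.items()}
    h = (x @ Tensor._lift(p["W_proj"])) + Tensor._lift(p["b_proj"])
    h = h.relu()
    if train and cfg.dropout > 0:
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        mask = (rng.random(h.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
        h = h * Tensor(mask)
    h = h + nystrom_attention(h, p, cfg)
    pooled = h.mean(axis=0)
    risk = (pooled.reshape(1, -1) @ Tensor._lift(p["W_head"])).reshape(()) + \
        Tensor._lift(p["b_head"]).reshape(())
    if as_tensor:
        return risk
    return float(risk.data)


def cox_nlpl_loss(risks: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Average negative log partial likelihood (Breslow risk sets):
    -(1/n_events) * sum_{i: event} [ r_i - log sum_{j: t_j >= t_i} exp(r_j) ]."""
    risks = np.asarray(risks, float)
    time = np.asarray(time, float)
    event = np.asarray(event, float).astype(bool)
    if event.sum() == 0:
        raise ValueError("partial likelihood undefined with zero events in the batch")
    at_risk = time[None, :] >= time[event][:, None]  # one row per event
    mx = risks.max()
    log_den = mx + np.log((at_risk * np.exp(risks - mx)[None, :]).sum(axis=1))
    return float(-(risks[event] - log_den).mean())


def cox_nlpl_grad(risks: np.ndarray, time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Analytic gradient of :func:`cox_nlpl_loss` with respect to the risks."""
    risks = np.asarray(risks, float)
    time = np.asarray(time, float)
    event = np.asarray(event, float).astype(bool)
    n_ev = int(event.sum())
    if n_ev == 0:
        raise ValueError("partial likelihood undefined with zero events in the batch")
    at_risk = time[None, :] >= time[event][:, None]
    w = np.exp(risks)
    den = (at_risk * w[None, :]).sum(axis=1)
    grad = -(event.astype(float) - (at_risk / den[:, None]).sum(axis=0) * w)
    return grad / n_ev


def _nlpl_tensor(risks: Tensor, time: np.ndarray, event: np.ndarray) -> Tensor:
    event = np.asarray(event, float).astype(bool)
    at_risk = Tensor((np.asarray(time)[None, :] >= np.asarray(time)[event][:, None]).astype(float))
    e = Tensor(event.astype(float))
    log_den = (at_risk @ risks.exp().reshape(-1, 1)).log().reshape(-1)
    return -((risks * e).sum() - log_den.sum()) * (1.0 / event.sum())


# ---------------------------------------------------------------------------
# Training


@dataclass
class DeepRiskModel:
    params: dict[str, np.ndarray]
    net_cfg: MILNetConfig
    train_cfg: TrainConfig | None = None
    history: dict[str, list[float]] = field(default_factory=dict)

    def risk(self, bag: EmbeddingBag | np.ndarray) -> float:
        vec = bag.vectors if isinstance(bag, EmbeddingBag) else bag
        return forward_bag(self.params, vec, self.net_cfg, train=False)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        sidecar = {"net_cfg": asdict(self.net_cfg),
                   "train_cfg": asdict(self.train_cfg) if self.train_cfg else None,
                   "history": self.history}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "DeepRiskModel":
        path = Path(path)
        params = dict(np.load(path.with_suffix(".npz")))
        meta = json.loads(path.with_suffix(".json").read_text())
        tc = TrainConfig(**meta["train_cfg"]) if meta["train_cfg"] else None
        return cls(params, MILNetConfig(**meta["net_cfg"]), tc, meta["history"])


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


def _stratified_split(ids, events, val_fraction, rng):
    """Event-stratified train/validation split of patient ids."""
    ids = np.asarray(ids)
    events = np.asarray(events, float).astype(bool)
    val = []
    for mask in (events, ~events):
        grp = ids[mask]
        k = max(1, round(val_fraction * len(grp))) if len(grp) else 0
        if len(grp):
            val.extend(rng.permutation(grp)[:k].tolist())
    val_set = set(val)
    train = [p for p in ids if p not in val_set]
    return train, sorted(val_set)


def train_deep_cph(bags: dict[str, EmbeddingBag], outcome: SurvivalOutcome,
                   net_cfg: MILNetConfig, train_cfg: TrainConfig) -> DeepRiskModel:
    """Train the MIL risk network; reproducible under ``train_cfg.seed``."""
    pids = [p for p in outcome.patient_ids if p in bags]
    out = outcome.subset(pids)
    if out.event.sum() == 0:
        raise ValueError("training data contain no events")
    if len(pids) < train_cfg.accumulation_size:
        raise ValueError("need at least accumulation_size patients")
    rng = np.random.default_rng(train_cfg.seed)
    train_ids, val_ids = _stratified_split(pids, out.event, train_cfg.val_fraction, rng)
    t_of = dict(zip(out.patient_ids, out.time))
    e_of = dict(zip(out.patient_ids, out.event))
    if sum(e_of[p] for p in train_ids) == 0 or sum(e_of[p] for p in val_ids) == 0:
        raise ValueError("train/validation split left one side without events")

    params = init_params(net_cfg, seed=int(rng.integers(2**31)))
    opt = _Adam(params, train_cfg.lr)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": [], "lr": []}
    best_val = np.inf
    stall = 0

    def batch_loss_and_grads(batch: list[str]) -> float | None:
        times = np.array([t_of[p] for p in batch])
        events = np.array([e_of[p] for p in batch])
        if events.sum() == 0:
            return None
        tensors = {k: Tensor(v, requires_grad=True) for k, v in params.items()}
        risks = []
        for p in batch:
            vec = bags[p].vectors
            if vec.shape[0] > train_cfg.patches_per_bag_train:
                sel = rng.choice(vec.shape[0], train_cfg.patches_per_bag_train, replace=False)
                vec = vec[sel]
            risks.append(forward_bag(tensors, vec, net_cfg, train=True, rng=rng, as_tensor=True))
        loss = _nlpl_tensor(stack(risks), times, events)
        loss.backward()
        opt.step(params, {k: t.grad for k, t in tensors.items() if t.grad is not None})
        return float(loss.data)

    def full_loss(id_list: list[str]) -> float:
        risks = np.array([forward_bag(params, bags[p].vectors, net_cfg) for p in id_list])
        return cox_nlpl_loss(risks,
                             np.array([t_of[p] for p in id_list]),
                             np.array([e_of[p] for p in id_list]))

    for epoch in range(train_cfg.epochs):
        order = rng.permutation(train_ids)
        losses = []
        for i in range(0, len(order), train_cfg.accumulation_size):
            batch = list(order[i:i + train_cfg.accumulation_size])
            if len(batch) < 2:
                continue  # a singleton cannot form a risk set
            val = batch_loss_and_grads(batch)
            if val is None:
                logger.debug("epoch %d: skipped event-free batch", epoch)
                continue
            losses.append(val)
        val_loss = full_loss(val_ids)
        history["train_loss"].append(float(np.mean(losses)) if losses else np.nan)
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            stall = 0
        else:
            stall += 1
            if stall >= train_cfg.plateau_patience:
                opt.lr *= train_cfg.plateau_gamma
                stall = 0
                logger.info("epoch %d: plateau, lr -> %.2e", epoch, opt.lr)

    # validation C-index of the final model, reused as the modality's p_val
    from .survival_metrics import harrell_cindex
    val_risks = np.array([forward_bag(params, bags[p].vectors, net_cfg) for p in val_ids])
    try:
        val_c = harrell_cindex(val_risks, np.array([t_of[p] for p in val_ids]),
                               np.array([e_of[p] for p in val_ids])).point
    except ValueError:
        val_c = 0.5
    history["val_cindex"] = [val_c]
    history["val_ids"] = list(val_ids)  # type: ignore[list-item]
    return DeepRiskModel(params, net_cfg, train_cfg, history)


def predict_bag_risk(model: DeepRiskModel, bags: dict[str, EmbeddingBag],
                     endpoint: str = "", modality: str = "wsi") -> RiskVector:
    """Deterministic eval-mode risk per patient using every patch in the bag."""
    pids = sorted(bags)
    scores = np.array([model.risk(bags[p]) for p in pids])
    return RiskVector(pids, scores, modality, endpoint)
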