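"""Residual multilayer network and the two-phase training procedure.

The network maps a feature row (rescaled environmental predictors plus
the two circular seasonal coordinates) to one raw score per taxon: an
input affine layer to the hidden width, ``n_blocks`` residual blocks

    block(x) = x + Lin2(Dropout(ReLU(Lin1(x)))),

and an output affine layer. Forward, backward, and the SGD-with-momentum
optimizer are implemented directly in numpy; a single seeded generator
drives initialization, dropout, and batch sampling, so training is
bit-reproducible on one thread.

Training runs in two phases: first with taxonomically balanced sampling
(records drawn with probability proportional to 1 / n_s, upsampling rare
taxa with replacement), then with unmodified sampling probabilities.
The learning rate is halved when the epoch-mean training loss plateaus,
and phase 2 stops early on a held-out validation slice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .grids import ScalingSpec
from .losses import (
    cross_entropy_value_and_grad,
    lambda_ndcg_value_and_grad,
)

__all__ = [
    "NetworkConfig",
    "TrainingConfig",
    "ResidualMLP",
    "ModelState",
    "build_network",
    "train_two_phase",
    "save_model",
    "load_model",
]


@dataclass
class NetworkConfig:
    n_inputs: int
    n_outputs: int
    width: int = 380
    n_blocks: int = 4
    dropout: float = 0.2
    preactivation: bool = False

    def __post_init__(self):
        if min(self.n_inputs, self.n_outputs, self.width, self.n_blocks) < 1:
            raise ValueError("widths and block count must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


@dataclass
class TrainingConfig:
    loss: str = "cel"  # "cel" | "ndcg"
    ndcg_rank_cap: int = 500
    include_self_pair: bool = True
    phase1_epochs: int = 50
    phase2_max_epochs: int = 100
    early_stop_patience: int = 5
    lr_phase1: float = 1e-2
    lr_phase2: float = 5e-3
    momentum: float = 0.9
    batch_size: int = 250
    plateau_factor: float = 0.5
    plateau_patience: int = 3
    plateau_min_improve: float = 1e-3  # relative improvement below this counts as flat
    min_lr: float = 1e-5
    seed: int = 0

    def __post_init__(self):
        if self.loss not in ("cel", "ndcg"):
            raise ValueError("loss must be 'cel' or 'ndcg'")
        if self.phase1_epochs < 0 or self.phase2_max_epochs < 0:
            raise ValueError("epoch counts must be nonnegative")
        if self.batch_size < 1:
            raise ValueError("batch size must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")


def _relu(x):
    return np.maximum(x, 0.0)


class ResidualMLP:
    """Plain-numpy residual MLP with explicit forward/backward passes."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.params: dict[str, np.ndarray] = {}

        def init(name, fan_in, shape):
            bound = 1.0 / np.sqrt(fan_in)
            self.params[name] = rng.uniform(-bound, bound, size=shape)

        init("W_in", c.n_inputs, (c.n_inputs, c.width))
        init("b_in", c.n_inputs, (c.width,))
        for k in range(c.n_blocks):
            init(f"W1_{k}", c.width, (c.width, c.width))
            init(f"b1_{k}", c.width, (c.width,))
            init(f"W2_{k}", c.width, (c.width, c.width))
            init(f"b2_{k}", c.width, (c.width,))
        init("W_out", c.width, (c.width, c.n_outputs))
        init("b_out", c.width, (c.n_outputs,))

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    def forward(self, X, training: bool = False, rng=None):
        """Raw scores for a (batch, n_inputs) matrix.

        In training mode dropout masks are drawn from ``rng``; in eval
        mode dropout is disabled and the output is deterministic.
        """
        X = np.asarray(X, dtype=float)
        p = self.params
        c = self.config
        cache = {"X": X, "blocks": []}
        h = X @ p["W_in"] + p["b_in"]
        cache["h_in"] = h
        for k in range(c.n_blocks):
            u = _relu(h) if c.preactivation else h
            a = u @ p[f"W1_{k}"] + p[f"b1_{k}"]
            r = _relu(a)
            if training and c.dropout > 0.0:
                if rng is None:
                    raise ValueError("training-mode forward needs an rng")
                mask = (rng.random(r.shape) >= c.dropout) / (1.0 - c.dropout)
            else:
                mask = None
            d = r * mask if mask is not None else r
            z = d @ p[f"W2_{k}"] + p[f"b2_{k}"]
            cache["blocks"].append(
                {"h": h, "u": u, "a": a, "d": d, "mask": mask}
            )
            h = h + z
        cache["h_out"] = h
        scores = h @ p["W_out"] + p["b_out"]
        if training:
            self._cache = cache
        return scores

    def backward(self, dscores) -> dict:
        """Gradients of the loss w.r.t. every parameter.

        ``dscores`` is dL/dscores from the loss; requires a preceding
        training-mode forward pass.
        """
        p = self.params
        c = self.config
        cache = self._cache
        grads = {}
        grads["W_out"] = cache["h_out"].T @ dscores
        grads["b_out"] = dscores.sum(axis=0)
        dh = dscores @ p["W_out"].T
        for k in reversed(range(c.n_blocks)):
            blk = cache["blocks"][k]
            dz = dh  # residual: dL/dz = dL/dh_next, dL/dh += passthrough
            grads[f"W2_{k}"] = blk["d"].T @ dz
            grads[f"b2_{k}"] = dz.sum(axis=0)
            dd = dz @ p[f"W2_{k}"].T
            if blk["mask"] is not None:
                dd = dd * blk["mask"]
            da = dd * (blk["a"] > 0)
            grads[f"W1_{k}"] = blk["u"].T @ da
            grads[f"b1_{k}"] = da.sum(axis=0)
            du = da @ p[f"W1_{k}"].T
            if c.preactivation:
                du = du * (blk["h"] > 0)
            dh = dh + du
        grads["W_in"] = cache["X"].T @ dh
        grads["b_in"] = dh.sum(axis=0)
        return grads


class _SGDMomentum:
    def __init__(self, params: dict, momentum: float):
        self.momentum = momentum
        self.velocity = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict, lr: float):
        for k in params:
            v = self.velocity[k]
            v *= self.momentum
            v += grads[k]
            params[k] -= lr * v


@dataclass
class ModelState:
    """Trained network plus everything needed to reproduce predictions."""

    network: ResidualMLP
    taxa: list
    scaling: ScalingSpec | None = None
    year_length: float = 365.25
    season_phase: float = 0.0
    training_log: list = field(default_factory=list)
    seed: int = 0

    @property
    def config(self) -> NetworkConfig:
        return self.network.config

    def predict_scores(self, features: np.ndarray) -> np.ndarray:
        return self.network.forward(features, training=False)


def build_network(config: NetworkConfig, seed: int = 0, taxa=None) -> ModelState:
    """Seeded network construction; taxa default to index labels."""
    net = ResidualMLP(config, seed=seed)
    if taxa is None:
        taxa = [str(i) for i in range(config.n_outputs)]
    if len(taxa) != config.n_outputs:
        raise ValueError("taxa list must match the output width")
    return ModelState(network=net, taxa=list(taxa), seed=seed)


def _loss_and_grad(cfg: TrainingConfig, scores, labels, n_taxa):
    if cfg.loss == "cel":
        return cross_entropy_value_and_grad(scores, labels)
    n = min(cfg.ndcg_rank_cap, n_taxa)
    return lambda_ndcg_value_and_grad(
        scores, labels, n=n, include_self_pair=cfg.include_self_pair
    )


def _epoch(model, opt, X, y, order, cfg, lr, rng, n_taxa):
    losses = []
    for start in range(0, len(order), cfg.batch_size):
        idx = order[start : start + cfg.batch_size]
        scores = model.network.forward(X[idx], training=True, rng=rng)
        loss, dscores = _loss_and_grad(cfg, scores, y[idx], n_taxa)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss ({loss}) — diverged; lower the "
                "learning rate or inspect the input features"
            )
        grads = model.network.backward(dscores)
        opt.step(model.network.params, grads, lr)
        losses.append(loss)
    return float(np.mean(losses))


def _eval_loss(model, cfg, X, y, n_taxa, batch=4096):
    total, count = 0.0, 0
    for start in range(0, len(X), batch):
        scores = model.network.forward(X[start : start + batch])
        loss, _ = _loss_and_grad(cfg, scores, y[start : start + batch], n_taxa)
        total += loss * len(scores)
        count += len(scores)
    return total / max(count, 1)


def train_two_phase(
    model: ModelState,
    features: np.ndarray,
    labels: np.ndarray,
    config: TrainingConfig,
    val_features: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
) -> ModelState:
    """Train in two phases and append per-epoch records to the model log.

    ``features`` are rescaled predictor rows (env + seasonal), ``labels``
    integer taxon indices. Phase 1 draws records with probability
    proportional to 1 / n_s (taxonomically balanced, with replacement,
    epoch size = training-set size); phase 2 visits each record once per
    epoch in random order and stops early when the validation loss has
    not improved for ``early_stop_patience`` epochs (best weights are
    restored). Without a validation slice, phase 2 runs a fixed
    ``phase2_max_epochs``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(X) == 0:
        raise ValueError("empty training set")
    if val_features is not None and len(val_features) == 0:
        val_features = val_labels = None
    n_taxa = model.config.n_outputs
    rng = np.random.default_rng(config.seed)
    opt = _SGDMomentum(model.network.params, config.momentum)

    counts = np.bincount(y, minlength=n_taxa).astype(float)
    inv = np.where(counts[y] > 0, 1.0 / counts[y], 0.0)
    balanced_p = inv / inv.sum()

    def run_phase(name, epochs, lr0, sampler, early_stop):
        lr = lr0
        best = np.inf
        since_best_plateau = 0
        best_val = np.inf
        since_best_val = 0
        best_params = None
        for epoch in range(epochs):
            order = sampler()
            mean_loss = _epoch(model, opt, X, y, order, config, lr, rng, n_taxa)
            record = {
                "phase": name,
                "epoch": epoch,
                "loss": mean_loss,
                "lr": lr,
            }
            # an epoch counts as progress only if it beats the best loss by
            # a relative margin; otherwise the schedule anneals the lr
            if mean_loss < best * (1.0 - config.plateau_min_improve):
                best = mean_loss
                since_best_plateau = 0
            else:
                best = min(best, mean_loss)
                since_best_plateau += 1
                if since_best_plateau >= config.plateau_patience:
                    lr = max(lr * config.plateau_factor, config.min_lr)
                    since_best_plateau = 0
            if early_stop:
                val_loss = _eval_loss(model, config, val_features, val_labels, n_taxa)
                record["val_loss"] = val_loss
                if val_loss < best_val - 1e-12:
                    best_val = val_loss
                    since_best_val = 0
                    best_params = {
                        k: v.copy() for k, v in model.network.params.items()
                    }
                else:
                    since_best_val += 1
            model.training_log.append(record)
            if early_stop and since_best_val >= config.early_stop_patience:
                break
        if early_stop and best_params is not None:
            model.network.params = best_params

    n = len(X)
    run_phase(
        "balanced",
        config.phase1_epochs,
        config.lr_phase1,
        lambda: rng.choice(n, size=n, replace=True, p=balanced_p),
        early_stop=False,
    )
    use_val = val_features is not None and val_labels is not None
    run_phase(
        "natural",
        config.phase2_max_epochs,
        config.lr_phase2,
        lambda: rng.permutation(n),
        early_stop=use_val,
    )
    return model


def save_model(path, model: ModelState) -> None:
    """Single-file artifact: weight arrays + JSON header (bit-exact)."""
    header = {
        "network_config": asdict(model.config),
        "taxa": model.taxa,
        "scaling": model.scaling.to_dict() if model.scaling else None,
        "year_length": model.year_length,
        "season_phase": model.season_phase,
        "training_log": model.training_log,
        "seed": model.seed,
    }
    arrays = {f"param__{k}": v for k, v in model.network.params.items()}
    arrays["header"] = np.array(json.dumps(header))
    np.savez_compressed(path, **arrays)


def load_model(path) -> ModelState:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        params = {
            k[len("param__"):]: z[k] for k in z.files if k.startswith("param__")
        }
    config = NetworkConfig(**header["network_config"])
    net = ResidualMLP(config, seed=0)
    for k in net.params:
        net.params[k] = params[k]
    scaling = (
        ScalingSpec.from_dict(header["scaling"]) if header["scaling"] else None
    )
    return ModelState(
        network=net,
        taxa=header["taxa"],
        scaling=scaling,
        year_length=header["year_length"],
        season_phase=header["season_phase"],
        training_log=header["training_log"],
        seed=header["seed"],
    )
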