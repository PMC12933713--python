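"""Geometric deep learning on a learned soft polar grid.

Each geodesic patch is mapped onto a grid of 12 Gaussian kernels (3 radial x
4 angular bins) acting as soft, overlapping pixels in geodesic polar
coordinates; the kernel centers and widths are themselves learnable.  Three
such convolutional layers — each applying the soft-grid map at several
evenly spaced angular offsets, a linear filter, and a maximum over the
offsets (angular max pooling, which removes the arbitrariness of each
patch's random reference axis) — feed a small fully connected head that
emits a per-vertex interfacial-binding-site score in (0, 1).

Training follows the per-protein-batch recipe: Adam on a sigmoid
cross-entropy loss over all positive vertices plus an equal-size random
subsample of negatives (fresh each epoch), with a checkpoint kept whenever
the mean per-protein validation ROC AUC improves.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from surfibs import _autodiff as ad
from surfibs._autodiff import Tensor
from surfibs.evaluation import roc_auc
from surfibs.features import FEATURE_NAMES
from surfibs.geodesy import Patch

EPS = 1e-8

FEATURE_PRESETS = {
    "geom": ("shape_index", "ddc"),
    "chem": ("hydropathy", "electrostatics", "hbond"),
    "all": FEATURE_NAMES,
}


# ---------------------------------------------------------------------------
# packed patch tensors
# ---------------------------------------------------------------------------

@dataclass
class ProteinData:
    """All patches of one protein, packed for the network."""

    protein_id: str
    rho: np.ndarray  # (V, M)
    theta: np.ndarray  # (V, M)
    mask: np.ndarray  # (V, M) float 0/1
    members: np.ndarray  # (V, M) int
    features: np.ndarray  # (V, M, 5)
    labels: np.ndarray | None = None  # (V,) binary
    group: str = ""

    @property
    def n_vertices(self) -> int:
        return self.rho.shape[0]


def pack_patches(
    patches: list[Patch], protein_id: str = "", labels: np.ndarray | None = None,
    group: str = "", dtype=np.float32,
) -> ProteinData:
    rho = np.stack([p.rho for p in patches]).astype(dtype)
    theta = np.stack([p.theta for p in patches]).astype(dtype)
    mask = np.stack([p.mask for p in patches]).astype(dtype)
    members = np.stack([p.members for p in patches])
    feats = np.stack([p.features for p in patches]).astype(dtype)
    return ProteinData(protein_id, rho, theta, mask, members, feats,
                       labels=None if labels is None else np.asarray(labels),
                       group=group)


def mask_features(dataset: list[ProteinData], keep) -> list[ProteinData]:
    """Zero every feature column not in ``keep`` (name set or preset name)."""
    if isinstance(keep, str):
        keep = FEATURE_PRESETS[keep]
    keep = set(keep)
    if not keep:
        raise ValueError("keep set must be nonempty")
    unknown = keep - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown feature names: {sorted(unknown)}")
    cols = [i for i, n in enumerate(FEATURE_NAMES) if n not in keep]
    out = []
    for p in dataset:
        feats = p.features.copy()
        feats[:, :, cols] = 0.0
        out.append(ProteinData(p.protein_id, p.rho, p.theta, p.mask, p.members,
                               feats, p.labels, p.group))
    return out


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    n_radial: int = 3
    n_angular: int = 4
    radius: float = 9.0  # Angstrom, geodesic patch radius
    n_channels: int = 16
    n_rotations: int = 4
    n_features: int = 5
    head_widths: tuple = (8,)
    seed: int = 0


@dataclass
class TrainConfig:
    epochs: int = 50
    learning_rate: float = 1e-3
    seed: int = 0
    validation_fraction: float = 0.10
    patience: int | None = 10  # epochs without val improvement before stopping
    min_delta: float = 1e-3  # improvement below this does not reset patience
    verbose: bool = False

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _inv_softplus(y: float) -> float:
    return float(np.log(np.expm1(y)))


class SoftGridModel:
    """Learnable soft-polar-grid network: 3 conv blocks + MLP head."""

    FORMAT_VERSION = 1

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.params: dict[str, Tensor] = {}
        self.frozen: set[str] = set()
        self.n_conv_layers = 0
        rng = np.random.default_rng(self.config.seed)
        c = self.config
        for layer in range(3):
            cin = c.n_features if layer == 0 else c.n_channels
            self._add_conv_layer(rng, cin, c.n_channels)
        self._init_head(rng, c.head_widths)

    # -- construction ------------------------------------------------------

    def _add_conv_layer(self, rng, cin: int, cout: int) -> None:
        c = self.config
        i = self.n_conv_layers
        nb = c.n_radial * c.n_angular
        # kernel centers on a regular polar lattice, widths = half bin spacing
        drho = c.radius / c.n_radial
        mu_rho = np.repeat((np.arange(c.n_radial) + 0.5) * drho, c.n_angular)
        mu_theta = np.tile(np.arange(c.n_angular) * 2 * np.pi / c.n_angular, c.n_radial)
        self._param(f"conv{i}.mu_rho", mu_rho)
        self._param(f"conv{i}.sigma_rho_raw", np.full(nb, _inv_softplus(drho / 2)))
        self._param(f"conv{i}.mu_theta", mu_theta)
        self._param(f"conv{i}.sigma_theta_raw",
                    np.full(nb, _inv_softplus(np.pi / c.n_angular)))
        scale = np.sqrt(2.0 / (nb * cin + cout))
        self._param(f"conv{i}.W", rng.normal(0.0, scale, size=(nb * cin, cout)))
        self._param(f"conv{i}.b", np.zeros(cout))
        self.n_conv_layers += 1

    def _init_head(self, rng, widths) -> None:
        # drop any existing head parameters first
        for k in [k for k in self.params if k.startswith("head")]:
            del self.params[k]
            self.frozen.discard(k)
        self.head_widths = tuple(widths)
        dims = [self.config.n_channels, *widths, 1]
        for j in range(len(dims) - 1):
            scale = np.sqrt(2.0 / (dims[j] + dims[j + 1]))
            self._param(f"head{j}.W", rng.normal(0.0, scale, size=(dims[j], dims[j + 1])))
            self._param(f"head{j}.b", np.zeros(dims[j + 1]))

    def _param(self, name: str, value: np.ndarray) -> None:
        self.params[name] = Tensor(np.asarray(value, dtype=np.float32), requires_grad=True)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def trainable_parameters(self) -> list[Tensor]:
        return [t for n, t in self.params.items() if n not in self.frozen]

    def frozen_manifest(self) -> dict[str, bool]:
        return {n: (n in self.frozen) for n in sorted(self.params)}

    # -- forward -----------------------------------------------------------

    def _grid_weights(self, layer: int, rho: np.ndarray, theta: np.ndarray,
                      mask: np.ndarray) -> Tensor:
        """Soft-grid kernel weights at all rotation offsets, (R, V, M, B).

        Fused op: the Gaussian in (rho, theta) is evaluated in one numpy
        pass and differentiated analytically with respect to the four
        kernel-parameter vectors, so the graph retains only the weight
        array itself rather than every intermediate.
        """
        c = self.config
        mu_r = self.params[f"conv{layer}.mu_rho"]
        sraw_r = self.params[f"conv{layer}.sigma_rho_raw"]
        mu_t = self.params[f"conv{layer}.mu_theta"]
        sraw_t = self.params[f"conv{layer}.sigma_theta_raw"]
        sig_r = np.logaddexp(0.0, sraw_r.data).astype(rho.dtype)
        sig_t = np.logaddexp(0.0, sraw_t.data).astype(rho.dtype)
        offsets = (2 * np.pi * np.arange(c.n_rotations) / c.n_rotations).astype(theta.dtype)

        dr = rho[:, :, None] - mu_r.data  # (V, M, B)
        dt = theta[None, :, :, None] + offsets[:, None, None, None] - mu_t.data
        dt -= (2 * np.pi) * np.floor(dt / (2 * np.pi) + 0.5)  # wrap to [-pi, pi)
        dt = dt.astype(theta.dtype, copy=False)  # (R, V, M, B)
        w = np.exp(-0.5 * (dr / sig_r) ** 2 - 0.5 * (dt / sig_t) ** 2) \
            * mask[:, :, None]

        req = any(t.requires_grad for t in (mu_r, sraw_r, mu_t, sraw_t))

        def backward(g):
            gw = g * w  # (R, V, M, B)
            gw_r = gw.sum(axis=0)  # (V, M, B)
            out = []
            if mu_r.requires_grad:
                out.append((mu_r, (gw_r * dr).sum(axis=(0, 1)) / sig_r**2))
            if sraw_r.requires_grad:
                d_sig = (gw_r * dr**2).sum(axis=(0, 1)) / sig_r**3
                out.append((sraw_r, d_sig / (1.0 + np.exp(-sraw_r.data))))
            if mu_t.requires_grad:
                out.append((mu_t, (gw * dt).sum(axis=(0, 1, 2)) / sig_t**2))
            if sraw_t.requires_grad:
                d_sig = (gw * dt**2).sum(axis=(0, 1, 2)) / sig_t**3
                out.append((sraw_t, d_sig / (1.0 + np.exp(-sraw_t.data))))
            return out

        return Tensor(w, req, (mu_r, sraw_r, mu_t, sraw_t), backward if req else None)

    def _conv_block(self, layer: int, x_members: Tensor, data: ProteinData) -> Tensor:
        """x_members: (V, M, Cin) member features -> (V, Cout)."""
        c = self.config
        V, M, cin = x_members.shape
        nb = c.n_radial * c.n_angular
        R = c.n_rotations
        w = self._grid_weights(layer, data.rho, data.theta, data.mask)
        numer = ad.einsum("rvmb,vmf->rvbf", w, x_members)
        denom = ad.tsum(w, axis=2) + EPS  # (R, V, nb)
        g = numer * ad.power(ad.reshape(denom, (R, V, nb, 1)), -1.0)
        flat = ad.reshape(g, (R * V, nb * cin))
        pre = flat @ self.params[f"conv{layer}.W"] + self.params[f"conv{layer}.b"]
        pre = ad.reshape(pre, (R, V, c.n_channels))
        return ad.relu(ad.tmax(pre, axis=0))  # angular max pooling

    def forward_t(self, data: ProteinData, features_tensor: Tensor | None = None) -> Tensor:
        """Per-vertex IBS logits as an autodiff Tensor, shape (V,)."""
        x = features_tensor if features_tensor is not None else Tensor(data.features)
        h = self._conv_block(0, x, data)
        for layer in range(1, self.n_conv_layers):
            gathered = ad.gather(h, data.members)  # (V, M, C)
            gathered = gathered * Tensor(data.mask[:, :, None])
            h = self._conv_block(layer, gathered, data)
        j = 0
        while f"head{j}.W" in self.params:
            h = h @ self.params[f"head{j}.W"] + self.params[f"head{j}.b"]
            if f"head{j + 1}.W" in self.params:
                h = ad.relu(h)
            j += 1
        return ad.reshape(h, (data.n_vertices,))

    def predict(self, data: ProteinData) -> np.ndarray:
        """Per-vertex IBS scores in (0, 1)."""
        return ad.sigmoid(self.forward_t(data)).data.astype(np.float64)

    def soft_grid_map(self, data: ProteinData, layer: int = 0,
                      rotation_offset: float = 0.0) -> np.ndarray:
        """Normalized soft-grid activations at one angular offset, (V, B, F).

        bin(v, b, f) = sum_m mask w_b(rho, theta + offset) x_f / (sum_m mask w_b + eps).
        """
        g = lambda name: self.params[f"conv{layer}.{name}"].data.astype(np.float64)
        sig_r = np.logaddexp(0.0, g("sigma_rho_raw"))
        sig_t = np.logaddexp(0.0, g("sigma_theta_raw"))
        rho = data.rho[:, :, None].astype(np.float64)
        theta = data.theta[:, :, None].astype(np.float64) + rotation_offset
        dt = theta - g("mu_theta")
        dt -= 2 * np.pi * np.floor(dt / (2 * np.pi) + 0.5)
        w = np.exp(-((rho - g("mu_rho")) ** 2) / (2 * sig_r**2) - dt**2 / (2 * sig_t**2))
        w = w * data.mask[:, :, None]
        numer = np.einsum("vmb,vmf->vbf", w, data.features.astype(np.float64))
        denom = w.sum(axis=1) + EPS
        return numer / denom[:, :, None]

    # -- surgery -----------------------------------------------------------

    def copy(self) -> "SoftGridModel":
        return copy.deepcopy(self)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: t.data.copy() for n, t in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for n, v in state.items():
            self.params[n] = Tensor(np.asarray(v, dtype=np.float32), requires_grad=True)

    def save(self, path) -> None:
        meta = {
            "format_version": self.FORMAT_VERSION,
            "config": asdict(self.config),
            "head_widths": list(self.head_widths),
            "n_conv_layers": self.n_conv_layers,
            "frozen": sorted(self.frozen),
        }
        arrays = {n.replace(".", "__"): t.data for n, t in self.params.items()}
        np.savez(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "SoftGridModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            arrays = {k.replace("__", "."): z[k] for k in z.files if k != "__meta__"}
        cfg = meta["config"]
        cfg["head_widths"] = tuple(cfg["head_widths"])
        model = cls(ModelConfig(**cfg))
        model.n_conv_layers = meta["n_conv_layers"]
        model.head_widths = tuple(meta["head_widths"])
        model.params = {}
        for n, v in arrays.items():
            model.params[n] = Tensor(v, requires_grad=True)
        model.frozen = set(meta["frozen"])
        return model


def transfer_surgery(pretrained: SoftGridModel, strategy: str) -> SoftGridModel:
    """Adapt a pretrained model to a new task.

    opt1: freeze all conv layers and replace the head with a deeper fully
    connected stack of widths 128/64/4/2 (then the sigmoid output unit).
    opt2: freeze the conv layers, append three fresh trainable conv layers
    and a fresh head; only the new parameters train.
    """
    model = pretrained.copy()
    rng = np.random.default_rng(model.config.seed + 1)
    conv_names = {n for n in model.params if n.startswith("conv")}
    if strategy == "opt1":
        model.frozen |= conv_names
        model._init_head(rng, (128, 64, 4, 2))
    elif strategy == "opt2":
        model.frozen |= conv_names
        c = model.config.n_channels
        for _ in range(3):
            model._add_conv_layer(rng, c, c)
        model._init_head(rng, model.config.head_widths)
    else:
        raise ValueError(f"unknown transfer strategy {strategy!r} (use 'opt1' or 'opt2')")
    return model


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _balanced_indices(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    neg_sub = rng.choice(neg, size=min(len(pos), len(neg)), replace=False)
    return np.r_[pos, neg_sub]


def train(
    dataset: list[ProteinData],
    config: TrainConfig | None = None,
    model: SoftGridModel | None = None,
    model_config: ModelConfig | None = None,
) -> tuple[SoftGridModel, list[dict]]:
    """Train on per-protein batches with balanced negative subsampling.

    Returns the checkpointed model (best mean per-protein validation ROC
    AUC) and a history of per-epoch train loss and validation AUC.
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)

    usable = []
    for p in dataset:
        if p.labels is None:
            raise ValueError(f"protein {p.protein_id} has no labels")
        if len(np.unique(p.labels)) < 2:
            warnings.warn(f"protein {p.protein_id} has single-class labels; excluded")
            continue
        usable.append(p)
    if len(usable) < 2:
        raise ValueError("need at least 2 usable proteins (train + validation)")

    order = rng.permutation(len(usable))
    n_val = max(1, int(round(config.validation_fraction * len(usable))))
    val_set = [usable[i] for i in order[:n_val]]
    train_set = [usable[i] for i in order[n_val:]]

    if model is None:
        model = SoftGridModel(model_config or ModelConfig(seed=config.seed))
    opt = ad.Adam(model.trainable_parameters(), lr=config.learning_rate)

    best_auc = -np.inf
    best_state = model.state_dict()
    history: list[dict] = []
    stall = 0
    for epoch in range(1, config.epochs + 1):
        losses = []
        for i in rng.permutation(len(train_set)):
            p = train_set[i]
            sel = _balanced_indices(p.labels, rng)
            logits = model.forward_t(p)
            loss = ad.mean(ad.sigmoid_cross_entropy(ad.take(logits, sel), p.labels[sel]))
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        per_protein = [roc_auc(model.predict(p), p.labels) for p in val_set]
        val_auc = float(np.mean(per_protein))
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_mean_roc_auc": val_auc,
                        "val_median_roc_auc": float(np.median(per_protein))})
        if config.verbose:
            print(f"epoch {epoch:3d}  loss {np.mean(losses):.4f}  val ROC AUC {val_auc:.4f}")
        improved_enough = val_auc > best_auc + config.min_delta
        if val_auc > best_auc:
            best_auc = val_auc
            best_state = model.state_dict()
        if improved_enough:
            stall = 0
        else:
            stall += 1
            if config.patience is not None and stall >= config.patience:
                break
    model.load_state_dict(best_state)
    model.validation_ids = [p.protein_id for p in val_set]
    return model, history
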