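"""The multi-headed convolutional peptide classifier.

One convolutional group per active sequence representation: two stacked
stride-1 valid convolutions with ReLU and dropout (no pooling — the inputs
are short fixed-length windows, so the stacked kernels' effective receptive
field already spans any plantable motif).  The groups' outputs are
flattened, concatenated, recombined by one or two dense ReLU layers with
dropout, and classified by a two-unit softmax head.  All branches and the
recombination layers are trained jointly by Adam on the cross-entropy loss
with an L2 penalty on convolutional and dense weights.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from . import nn
from .encoders import DEFAULT_K, REPRESENTATIONS, WIDTHS, resolve_combination


@dataclass(frozen=True)
class ConvGroupConfig:
    """Hyperparameters of one two-layer convolutional group."""

    conv1_filters: int = 10
    conv1_kernel: int = 4
    conv1_dropout: float = 0.8
    conv2_filters: int = 8
    conv2_kernel: int = 3
    conv2_dropout: float = 0.7

    def __post_init__(self) -> None:
        for kern in (self.conv1_kernel, self.conv2_kernel):
            if kern < 1:
                raise ValueError("kernel lengths must be >= 1")
        for rate in (self.conv1_dropout, self.conv2_dropout):
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"dropout rate {rate} outside [0, 1)")


@dataclass(frozen=True)
class ModelConfig:
    """Full architecture + training hyperparameter set.

    ``dense_layers`` lists (units, dropout) of the recombination stack — one
    layer in the ACP-740 profile, two in the ACP-500 profile.  Training
    defaults (learning rate, batch size, epoch budget, patience, L2 weight)
    are documented package defaults; the published configuration fixes only
    the architecture, dropout rates and the optimizer family.
    """

    k: int = DEFAULT_K
    combination: tuple[str, ...] = REPRESENTATIONS
    groups: tuple[ConvGroupConfig, ...] = (ConvGroupConfig(),)
    dense_layers: tuple[tuple[int, float], ...] = ((8, 0.7),)
    l2_lambda: float = 1e-3
    learning_rate: float = 3e-3
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        combo = resolve_combination(self.combination)
        object.__setattr__(self, "combination", combo)
        groups = tuple(self.groups)
        if len(groups) != len(combo):
            if len(set(groups)) == 1:
                # one shared profile (or copies of it) -> one branch per representation
                groups = (groups[0],) * len(combo)
            else:
                raise ValueError(
                    f"{len(groups)} distinct conv groups for {len(combo)} "
                    "active representations"
                )
        object.__setattr__(self, "groups", groups)
        if not self.dense_layers:
            raise ValueError("dense_layers must be non-empty")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        for grp in groups:
            if grp.conv1_kernel > self.k:
                raise ValueError(
                    f"conv1 kernel {grp.conv1_kernel} longer than input rows k={self.k}"
                )
            if grp.conv2_kernel > self.k - grp.conv1_kernel + 1:
                raise ValueError(
                    f"conv2 kernel {grp.conv2_kernel} longer than conv1 output "
                    f"({self.k - grp.conv1_kernel + 1} rows)"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["combination"] = list(self.combination)
        d["groups"] = [asdict(g) for g in self.groups]
        d["dense_layers"] = [list(t) for t in self.dense_layers]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        d = dict(d)
        if "groups" in d:
            d["groups"] = tuple(ConvGroupConfig(**g) for g in d["groups"])
        if "dense_layers" in d:
            d["dense_layers"] = tuple((int(u), float(p)) for u, p in d["dense_layers"])
        if "combination" in d:
            d["combination"] = tuple(d["combination"])
        return cls(**d)


#: Published hyperparameter profiles (per benchmark family).
PRESETS = {
    "acp740": dict(
        groups=(
            ConvGroupConfig(
                conv1_filters=10, conv1_kernel=4, conv1_dropout=0.8,
                conv2_filters=8, conv2_kernel=3, conv2_dropout=0.7,
            ),
        ),
        dense_layers=((8, 0.7),),
        k=DEFAULT_K,
    ),
    "acp500": dict(
        groups=(
            ConvGroupConfig(
                conv1_filters=16, conv1_kernel=3, conv1_dropout=0.7,
                conv2_filters=8, conv2_kernel=3, conv2_dropout=0.5,
            ),
        ),
        dense_layers=((16, 0.6), (8, 0.5)),
        k=DEFAULT_K,
    ),
}


def preset_config(name: str, **overrides) -> ModelConfig:
    """Return the published hyperparameter profile ``acp740`` or ``acp500``."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {sorted(PRESETS)}"
        ) from None
    return ModelConfig(**{**base, **overrides})


def effective_receptive_field(
    kernel_lengths: Sequence[int], strides: Optional[Sequence[int]] = None
) -> int:
    """Rows of the input influencing one unit of the final stacked conv layer.

    For valid convolutions the receptive field grows by (kernel-1) x jump per
    layer, where jump is the product of earlier strides; with all strides 1
    this reduces to 1 + sum(kernel - 1).
    """
    kernels = list(kernel_lengths)
    if not kernels:
        raise ValueError("kernel_lengths must be non-empty")
    strides = [1] * len(kernels) if strides is None else list(strides)
    if len(strides) != len(kernels):
        raise ValueError("kernel_lengths and strides must have equal length")
    if any(v < 1 for v in kernels + strides):
        raise ValueError("kernel lengths and strides must be >= 1")
    rf, jump = 1, 1
    for kern, stride in zip(kernels, strides):
        rf += (kern - 1) * jump
        jump *= stride
    return rf


class MHCNN:
    """Multi-headed CNN over up to three peptide representations.

    Use :func:`build_mhcnn` (or the constructor) to create an untrained
    model, :meth:`fit` to train, :meth:`predict_proba` /
    :meth:`predict_label` for inference.
    """

    def __init__(self, config: ModelConfig) -> None:
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.history: dict[str, list[float]] = {}
        self._build()

    def _build(self) -> None:
        cfg = self.config
        self.branches: list[list[nn.Layer]] = []
        concat_width = 0
        for rep, grp in zip(cfg.combination, cfg.groups):
            in_ch = WIDTHS[rep]
            layers: list[nn.Layer] = [
                nn.Conv1D(in_ch, grp.conv1_filters, grp.conv1_kernel, self.rng),
                nn.ReLU(),
                nn.Dropout(grp.conv1_dropout, self.rng),
                nn.Conv1D(grp.conv1_filters, grp.conv2_filters, grp.conv2_kernel, self.rng),
                nn.ReLU(),
                nn.Dropout(grp.conv2_dropout, self.rng),
                nn.Flatten(),
            ]
            out_len = cfg.k - grp.conv1_kernel - grp.conv2_kernel + 2
            concat_width += out_len * grp.conv2_filters
            self.branches.append(layers)
        self._branch_widths = []
        for rep, grp in zip(cfg.combination, cfg.groups):
            out_len = cfg.k - grp.conv1_kernel - grp.conv2_kernel + 2
            self._branch_widths.append(out_len * grp.conv2_filters)
        self.head: list[nn.Layer] = []
        n_in = concat_width
        for units, drop in cfg.dense_layers:
            self.head += [
                nn.Dense(n_in, units, self.rng),
                nn.ReLU(),
                nn.Dropout(drop, self.rng),
            ]
            n_in = units
        self.head.append(nn.Dense(n_in, 2, self.rng))  # softmax applied in loss/infer

    # -- plumbing ---------------------------------------------------------

    def _all_layers(self) -> list[nn.Layer]:
        return [l for branch in self.branches for l in branch] + self.head

    def _params(self) -> list[np.ndarray]:
        return [p for l in self._all_layers() for p in l.params]

    def _grads(self) -> list[np.ndarray]:
        return [g for l in self._all_layers() for g in l.grads]

    def count_parameters(self) -> int:
        """Total trainable scalar parameters."""
        return sum(l.n_params() for l in self._all_layers())

    def _check_stacks(self, stacks: Mapping[str, np.ndarray]) -> list[np.ndarray]:
        xs = []
        n = None
        for rep in self.config.combination:
            if rep not in stacks:
                raise ValueError(f"missing stack for representation {rep}")
            x = np.asarray(stacks[rep], dtype=float)
            if x.ndim != 3 or x.shape[1] != self.config.k or x.shape[2] != WIDTHS[rep]:
                raise ValueError(
                    f"{rep} stack has shape {x.shape}, expected "
                    f"(n, {self.config.k}, {WIDTHS[rep]})"
                )
            if n is None:
                n = x.shape[0]
            elif x.shape[0] != n:
                raise ValueError("representation stacks are misaligned in length")
            xs.append(x)
        return xs

    def _forward(self, xs: list[np.ndarray], train: bool) -> np.ndarray:
        outs = []
        for branch, x in zip(self.branches, xs):
            h = x
            for layer in branch:
                h = layer.forward(h, train)
            outs.append(h)
        h = np.concatenate(outs, axis=1)
        for layer in self.head:
            h = layer.forward(h, train)
        return h  # logits

    def _backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.head):
            d = layer.backward(d)
        start = 0
        for branch, width in zip(self.branches, self._branch_widths):
            db = d[:, start : start + width]
            start += width
            for layer in reversed(branch):
                db = layer.backward(db)

    def _apply_l2(self) -> None:
        lam = self.config.l2_lambda
        if lam == 0:
            return
        for layer in self._all_layers():
            for i in layer.l2_params():
                layer.grads[i] += 2.0 * lam * layer.params[i]

    # -- training ---------------------------------------------------------

    def fit(
        self,
        stacks: Mapping[str, np.ndarray],
        labels: np.ndarray,
        validation: Optional[tuple[Mapping[str, np.ndarray], np.ndarray]] = None,
        validation_fraction: float = 0.1,
        verbose: bool = False,
    ) -> "MHCNN":
        """Train with Adam + early stopping on validation loss.

        If no explicit validation set is given, a stratified
        ``validation_fraction`` of the training data is held out (seeded).
        The parameters from the best-validation-loss epoch are restored at
        the end.
        """
        xs = self._check_stacks(stacks)
        y = np.asarray(labels, dtype=int)
        if xs[0].shape[0] != len(y):
            raise ValueError("labels misaligned with encoded stacks")
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError(
                f"training labels must contain both classes, got {classes.tolist()}"
            )
        if validation is None:
            tr_idx, va_idx = _stratified_split(y, validation_fraction, self.rng)
            xs_tr = [x[tr_idx] for x in xs]
            y_tr = y[tr_idx]
            xs_va = [x[va_idx] for x in xs]
            y_va = y[va_idx]
        else:
            xs_tr, y_tr = xs, y
            xs_va = self._check_stacks(validation[0])
            y_va = np.asarray(validation[1], dtype=int)

        cfg = self.config
        optimizer = nn.Adam(self._params(), lr=cfg.learning_rate)
        self.history = {
            "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [],
        }
        best_loss = np.inf
        best_params = None
        best_epoch = -1
        wait = 0
        n = len(y_tr)
        for epoch in range(cfg.max_epochs):
            order = self.rng.permutation(n)
            ep_loss, ep_correct = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb = [x[idx] for x in xs_tr]
                yb = y_tr[idx]
                logits = self._forward(xb, train=True)
                probs = nn.softmax(logits)
                loss = nn.cross_entropy(probs, yb)
                ep_loss += loss * len(idx)
                ep_correct += int(np.sum(np.argmax(probs, axis=1) == yb))
                dlogits = probs.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits /= len(yb)
                self._backward(dlogits)
                self._apply_l2()
                optimizer.step(self._grads())
            val_probs = self._predict_proba_arrays(xs_va)
            val_loss = nn.cross_entropy(val_probs, y_va)
            val_acc = float(np.mean(np.argmax(val_probs, axis=1) == y_va))
            self.history["train_loss"].append(ep_loss / n)
            self.history["train_acc"].append(ep_correct / n)
            self.history["val_loss"].append(val_loss)
            self.history["val_acc"].append(val_acc)
            if verbose:  # pragma: no cover - logging only
                print(
                    f"epoch {epoch + 1:3d}  loss {ep_loss / n:.4f} "
                    f"acc {ep_correct / n:.3f}  val_loss {val_loss:.4f} "
                    f"val_acc {val_acc:.3f}"
                )
            if val_loss < best_loss - 1e-12:
                best_loss = val_loss
                best_params = [p.copy() for p in self._params()]
                best_epoch = epoch
                wait = 0
            else:
                wait += 1
                if wait >= cfg.patience:
                    break
        if best_params is not None:
            for p, bp in zip(self._params(), best_params):
                p[...] = bp
        self.best_epoch = best_epoch
        return self

    # -- inference --------------------------------------------------------

    def _predict_proba_arrays(self, xs: list[np.ndarray]) -> np.ndarray:
        return nn.softmax(self._forward(xs, train=False))

    def predict_proba(self, stacks: Mapping[str, np.ndarray]) -> np.ndarray:
        """(n, 2) class probabilities, column 0 = negative, column 1 = positive."""
        return self._predict_proba_arrays(self._check_stacks(stacks))

    def predict_label(self, stacks: Mapping[str, np.ndarray]) -> np.ndarray:
        return predict_label(self.predict_proba(stacks))

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Save as a directory archive: weights.npz + human-readable config.json."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {f"p{i}": p for i, p in enumerate(self._params())}
        np.savez_compressed(path / "weights.npz", **arrays)
        (path / "config.json").write_text(
            json.dumps(self.config.to_dict(), indent=2) + "\n"
        )

    @classmethod
    def load(cls, path: str | Path) -> "MHCNN":
        path = Path(path)
        config = ModelConfig.from_dict(json.loads((path / "config.json").read_text()))
        model = cls(config)
        with np.load(path / "weights.npz") as data:
            params = model._params()
            if len(data.files) != len(params):
                raise ValueError("archive does not match the configured architecture")
            for i, p in enumerate(params):
                saved = data[f"p{i}"]
                if saved.shape != p.shape:
                    raise ValueError(f"parameter {i} shape mismatch")
                p[...] = saved
        return model


def _stratified_split(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified holdout; at least one record per class held out."""
    hold: list[int] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_hold = max(1, int(round(fraction * len(idx))))
        hold.extend(idx[:n_hold].tolist())
    hold_arr = np.sort(np.array(hold))
    mask = np.ones(len(y), dtype=bool)
    mask[hold_arr] = False
    return np.flatnonzero(mask), hold_arr


def build_mhcnn(config: ModelConfig) -> MHCNN:
    """Build an untrained multi-headed CNN from ``config``."""
    return MHCNN(config)


def train(
    model: MHCNN,
    stacks: Mapping[str, np.ndarray],
    labels: np.ndarray,
    validation=None,
    validation_fraction: float = 0.1,
    verbose: bool = False,
) -> MHCNN:
    """Functional wrapper around :meth:`MHCNN.fit`."""
    return model.fit(stacks, labels, validation, validation_fraction, verbose)


def predict_label(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Label 1 iff positive-class probability strictly exceeds ``threshold``.

    An exact tie at the threshold is resolved to the negative class
    (conservative positive calls).
    """
    probs = np.asarray(probabilities, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 2:
        raise ValueError("expected (n, 2) probability pairs")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability pairs must sum to 1")
    return (probs[:, 1] > threshold).astype(int)
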