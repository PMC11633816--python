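"""Small 2D U-net learner backend (optional, requires torch).

Honours the same contract as :class:`segsense.learners.GaussianPixelLearner`
and the configuration knobs of the harness: encoder/decoder depth, initial
filter count, ReLU activations, He-normal initialization, 3x3 kernels,
per-layer dropout, an optional batch-normalization stage, the optimizer
family, learning rate, batch size, and a SoftMax output head.

torch is imported lazily; installing ``segsense[torch]`` enables this
backend, everything else in the package runs without it.
"""

from __future__ import annotations

import numpy as np

__all__ = ["UNetLearner"]


def _require_torch():
    try:
        import torch  # noqa: F401
        import torch.nn as nn  # noqa: F401
    except ImportError as exc:  # pragma: no cover - depends on optional extra
        raise ImportError(
            "the U-net backend requires torch; install segsense[torch] or use "
            "segsense.learners.GaussianPixelLearner"
        ) from exc
    import torch
    import torch.nn as nn
    return torch, nn


class UNetLearner:
    """U-net backend satisfying the harness learner contract."""

    def __init__(self, config, n_classes: int, seed: int = 0) -> None:
        torch, nn = _require_torch()
        values = getattr(config, "values", config)
        static = getattr(config, "static", None)
        torch.manual_seed(seed)
        depth = getattr(static, "unet_depth", 4) if static else 4
        filters = getattr(static, "initial_filters", 32) if static else 32
        self.batch_size = getattr(static, "batch_size", 16) if static else 16
        self.n_classes = n_classes
        self.net = self._build(nn, n_classes, depth, filters,
                               float(values.get("dropout", 0.0)),
                               bool(values.get("batch_normalization", False)))
        self._init_weights(nn)
        self.optimizer = self._make_optimizer(
            torch, str(values.get("optimizer", "adam")).lower(),
            float(values.get("learning_rate", 1e-3)))
        self.loss_name = str(values.get("loss_function", "Dice"))
        self.loss_values = values

    def _build(self, nn, n_classes, depth, filters, dropout, batch_norm):
        def block(cin, cout):
            layers = [nn.Conv2d(cin, cout, 3, padding=1)]
            if batch_norm:
                layers.append(nn.BatchNorm2d(cout))
            layers.append(nn.ReLU(inplace=True))
            if dropout > 0:
                layers.append(nn.Dropout2d(dropout))
            return nn.Sequential(*layers)

        class UNet(nn.Module):
            def __init__(self):
                super().__init__()
                self.downs = nn.ModuleList()
                self.ups = nn.ModuleList()
                self.pool = nn.MaxPool2d(2)
                cin = 1
                chans = []
                for d in range(depth):
                    cout = filters * 2**d
                    self.downs.append(block(cin, cout))
                    chans.append(cout)
                    cin = cout
                self.bottom = block(cin, cin * 2)
                cin = cin * 2
                for cout in reversed(chans):
                    self.ups.append(nn.ModuleList([
                        nn.ConvTranspose2d(cin, cout, 2, stride=2),
                        block(cout * 2, cout),
                    ]))
                    cin = cout
                self.head = nn.Conv2d(cin, n_classes, 1)

            def forward(self, x):
                skips = []
                for down in self.downs:
                    x = down(x)
                    skips.append(x)
                    x = self.pool(x)
                x = self.bottom(x)
                import torch as _t
                for (up, conv), skip in zip(self.ups, reversed(skips)):
                    x = up(x)
                    x = conv(_t.cat([x, skip], dim=1))
                return self.head(x)

        return UNet()

    def _init_weights(self, nn) -> None:
        for m in self.net.modules():
            if isinstance(m, (nn.Conv2d, nn.ConvTranspose2d)):
                nn.init.kaiming_normal_(m.weight, nonlinearity="relu")
                if m.bias is not None:
                    nn.init.zeros_(m.bias)

    def _make_optimizer(self, torch, name, lr):
        opts = {
            "adam": lambda p: torch.optim.Adam(p, lr=lr),
            "weighted_adam": lambda p: torch.optim.AdamW(p, lr=lr),
            "rmsprop": lambda p: torch.optim.RMSprop(p, lr=lr),
            "sgd": lambda p: torch.optim.SGD(p, lr=lr),
            "adagrad": lambda p: torch.optim.Adagrad(p, lr=lr),
        }
        if name not in opts:
            raise ValueError(f"unknown optimizer {name!r}")
        return opts[name](self.net.parameters())

    def fit_epoch(self, patches) -> None:
        torch, _ = _require_torch()
        from segsense.losses import LossParams, get_loss

        params = LossParams(**{k: self.loss_values[k]
                               for k in ("beta", "w_cce", "gamma")
                               if k in self.loss_values})
        loss_fn = get_loss(self.loss_name)
        self.net.train()
        x = torch.tensor(np.stack([p.image_window for p in patches]),
                         dtype=torch.float32)[:, None]
        y = torch.tensor(np.stack([p.label_window for p in patches]),
                         dtype=torch.int64)
        for i in range(0, len(patches), self.batch_size):
            xb, yb = x[i:i + self.batch_size], y[i:i + self.batch_size]
            self.optimizer.zero_grad()
            logits = self.net(xb)
            probs = torch.softmax(logits, dim=1)
            onehot = torch.nn.functional.one_hot(yb, self.n_classes).permute(0, 3, 1, 2)
            # numpy losses define the objective; autograd needs the torch mirror
            loss = _torch_loss(loss_fn, probs, onehot.float(), params)
            loss.backward()
            self.optimizer.step()

    def predict(self, images: np.ndarray) -> np.ndarray:
        torch, _ = _require_torch()
        self.net.eval()
        with torch.no_grad():
            x = torch.tensor(np.asarray(images), dtype=torch.float32)[:, None]
            probs = torch.softmax(self.net(x), dim=1)
        return probs.permute(0, 2, 3, 1).numpy().astype(np.float64)


def _torch_loss(loss_fn, probs, onehot, params):
    """Torch re-expression of the registry losses (soft-confusion family)."""
    import torch

    from segsense import losses as L

    p = probs.permute(0, 2, 3, 1).reshape(-1, probs.shape[1])
    t = onehot.permute(0, 2, 3, 1).reshape(-1, probs.shape[1])
    tp = (p * t).sum(0)
    fp = (p * (1 - t)).sum(0)
    fn = ((1 - p) * t).sum(0)
    e = params.epsilon
    if loss_fn is L.dice_loss:
        return 1 - ((2 * tp + e) / (2 * tp + fp + fn + e)).mean()
    if loss_fn is L.jaccard_loss:
        return 1 - ((tp + e) / (tp + fp + fn + e)).mean()
    if loss_fn is L.focal_tversky_loss:
        ti = (tp + e) / (tp + params.alpha_tversky * fp + params.beta_tversky * fn + e)
        return ((1 - ti) ** params.gamma).mean()
    if loss_fn is L.rf_loss:
        b2 = params.beta**2
        return 1 - (((1 + b2) * tp + e) / ((1 + b2) * tp + b2 * fn + fp + e)).mean()
    if loss_fn is L.combo_loss:
        cce = -(t * torch.log(p + e)).sum(1).mean()
        dice = 1 - ((2 * tp + e) / (2 * tp + fp + fn + e)).mean()
        return params.w_cce * cce + (1 - params.w_cce) * dice
    raise ValueError("unsupported loss for the torch backend")
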