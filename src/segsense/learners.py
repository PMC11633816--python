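"""Pluggable learners for the grid-search harness.

A learner receives a concrete trial configuration and training patches and
exposes two methods::

    fit_epoch(patches)   # one pass of parameter refinement
    predict(images)      # (S, H, W) -> (S, H, W, K) SoftMax-like probabilities

Two backends exist.  :class:`GaussianPixelLearner` (here) is a
framework-free per-pixel Gaussian class-conditional intensity classifier
refined once per epoch; it lets the entire pipeline, test suite, and
sensitivity analysis run on CPU in seconds with no deep-learning dependency.
:mod:`segsense.unet` provides a small U-net honouring the same contract for
users with torch installed.

How the Gaussian learner maps hyperparameters onto its update (documented in
the methods note):

* ``learning_rate`` and ``optimizer`` set the per-epoch step size with which
  the running class statistics move toward the current empirical estimates,
  so low rates genuinely under-converge within a short epoch budget;
* ``batch_normalization`` toggles per-patient intensity standardization
  (features are z-scored against the source volume's statistics, at training
  and at prediction).  Because real — and phantom — cohorts carry per-patient
  global intensity offsets, this normalization is load-bearing, not cosmetic;
* ``dropout`` discards that fraction of training pixels each epoch
  (a regularization analog with deliberately small effect);
* ``augmentation`` is handled upstream by the harness (augmented patches are
  simply what the learner is fed).
"""

from __future__ import annotations

import numpy as np

from segsense.ingest import Patch

__all__ = ["GaussianPixelLearner", "OPTIMIZER_GAINS"]

#: relative step-size gain per optimizer name (adaptive optimizers step fuller)
OPTIMIZER_GAINS = {
    "adam": 1.0,
    "weighted_adam": 1.0,
    "rmsprop": 0.9,
    "adagrad": 0.7,
    "sgd": 0.5,
}

_VAR_FLOOR = 1e-6


class GaussianPixelLearner:
    """Per-pixel Gaussian class-conditional intensity classifier.

    Maintains running per-class intensity mean/variance and class priors;
    each epoch moves them toward the empirical statistics of the training
    pixels by a step size derived from the learning rate and optimizer.
    Prediction applies Bayes' rule pixelwise and normalizes the class
    log-likelihoods with a SoftMax, yielding a probabilistic output map.
    """

    def __init__(self, config, n_classes: int, seed: int = 0) -> None:
        values = getattr(config, "values", config)
        self.n_classes = n_classes
        self.lr = float(values.get("learning_rate", 0.01))
        self.optimizer = str(values.get("optimizer", "adam")).lower()
        if self.optimizer not in OPTIMIZER_GAINS:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        self.batch_norm = bool(values.get("batch_normalization", False))
        self.dropout = float(values.get("dropout", 0.0))
        self.rng = np.random.default_rng(np.random.SeedSequence((seed, 0x6A55)))
        self.mu: np.ndarray | None = None
        self.var: np.ndarray | None = None
        self.log_prior = np.full(n_classes, -np.log(n_classes))

    @property
    def step_size(self) -> float:
        """Per-epoch step toward the empirical statistics, in (0, 1]."""
        return float(np.clip(self.lr * 100.0 * OPTIMIZER_GAINS[self.optimizer], 0.05, 1.0))

    # -- feature extraction -------------------------------------------------

    def _normalize_stack(self, images: np.ndarray) -> np.ndarray:
        sd = images.std()
        return (images - images.mean()) / (sd if sd > 0 else 1.0)

    def _training_features(self, patches: list[Patch]) -> tuple[np.ndarray, np.ndarray]:
        feats, labels = [], []
        if self.batch_norm:
            by_patient: dict[str, list[Patch]] = {}
            for p in patches:
                by_patient.setdefault(p.provenance[0], []).append(p)
            for group in by_patient.values():
                x = np.concatenate([p.image_window.ravel() for p in group])
                m, s = x.mean(), x.std()
                s = s if s > 0 else 1.0
                feats.append((x - m) / s)
                labels.append(np.concatenate([p.label_window.ravel() for p in group]))
        else:
            feats = [p.image_window.ravel() for p in patches]
            labels = [p.label_window.ravel() for p in patches]
        return np.concatenate(feats), np.concatenate(labels)

    # -- contract ------------------------------------------------------------

    def fit_epoch(self, patches: list[Patch]) -> None:
        """One refinement pass over the training patches."""
        if not patches:
            raise ValueError("no training patches")
        x, y = self._training_features(patches)
        if self.dropout > 0:
            keep = self.rng.random(x.size) >= self.dropout
            x, y = x[keep], y[keep]
        if self.mu is None:
            # small seeded perturbation of the global statistics (random-init
            # analog; 0.1 SD keeps initialization a minor, not dominant, axis)
            gm, gs = x.mean(), max(x.std(), np.sqrt(_VAR_FLOOR))
            self.mu = gm + self.rng.normal(0.0, 0.1, self.n_classes) * gs
            self.var = np.full(self.n_classes, gs**2)

        eta = self.step_size
        counts = np.bincount(y, minlength=self.n_classes).astype(float)
        for c in range(self.n_classes):
            if counts[c] == 0:
                continue  # class absent this epoch; keep running estimate
            xc = x[y == c]
            self.mu[c] += eta * (xc.mean() - self.mu[c])
            self.var[c] += eta * (max(xc.var(), _VAR_FLOOR) - self.var[c])
        present = counts > 0
        prior = counts / counts.sum()
        new_log_prior = self.log_prior.copy()
        new_log_prior[present] = np.log(prior[present])
        self.log_prior += eta * (new_log_prior - self.log_prior)

    def predict(self, images: np.ndarray) -> np.ndarray:
        """SoftMax class probabilities for a slice stack, shape (..., K)."""
        if self.mu is None:
            raise RuntimeError("predict() before any fit_epoch()")
        images = np.asarray(images, dtype=np.float64)
        x = self._normalize_stack(images) if self.batch_norm else images
        sd = np.sqrt(self.var)
        z = (x[..., None] - self.mu) / sd
        loglik = -0.5 * z**2 - np.log(sd) + self.log_prior
        loglik -= loglik.max(axis=-1, keepdims=True)
        probs = np.exp(loglik)
        probs /= probs.sum(axis=-1, keepdims=True)
        return probs
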