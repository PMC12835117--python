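"""Scikit-learn-style estimator wrapping the adversarial diffusion translator.

``DiffusionEnhancer`` is the package's top-level interface: ``fit`` on
paired (low-field, high-field) volumes, ``transform`` new low-field
volumes into high-field-like ones.  It composes with scikit-learn model
selection (``get_params`` / ``set_params`` / ``clone``); fitted state
lives in trailing-underscore attributes.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .inference import enhance_volume
from .io import VolumePair
from .training import TrainConfig, make_2p5d_stacks, train_on_stacks

__all__ = ["DiffusionEnhancer"]


class DiffusionEnhancer(BaseEstimator, TransformerMixin):
    """Few-step conditional adversarial diffusion volume-to-volume translator.

    Parameters mirror the training configuration: a T-step (default 4)
    variance-preserving diffusion chain with rate range
    ``(beta_min, beta_max)``, an x0-predicting 2.5D generator conditioned
    on ``k_adjacent`` neighbouring slices and a 256-d latent code, and a
    time-conditioned discriminator; Adam with the (0.5, 0.9) momentum
    pair, generator/discriminator learning rates 1.5e-4 / 1e-4, and an
    L1 data term weighted by ``lambda1 = 0.5``.

    Examples
    --------
    >>> enh = DiffusionEnhancer(base_channels=16, max_steps=200, random_state=0)
    >>> enh.fit(low_field_volumes, high_field_volumes)   # doctest: +SKIP
    >>> restored = enh.transform(low_field_volumes[:1])  # doctest: +SKIP
    """

    def __init__(self, T=4, beta_min=0.1, beta_max=20.0, k_adjacent=3,
                 base_channels=32, depth=3, z_dim=256, lambda1=0.5,
                 lr_generator=1.5e-4, lr_discriminator=1e-4,
                 adam_beta1=0.5, adam_beta2=0.9, batch_size=4, epochs=1,
                 max_steps=None, fixed_z=False, random_state=0):
        self.T = T
        self.beta_min = beta_min
        self.beta_max = beta_max
        self.k_adjacent = k_adjacent
        self.base_channels = base_channels
        self.depth = depth
        self.z_dim = z_dim
        self.lambda1 = lambda1
        self.lr_generator = lr_generator
        self.lr_discriminator = lr_discriminator
        self.adam_beta1 = adam_beta1
        self.adam_beta2 = adam_beta2
        self.batch_size = batch_size
        self.epochs = epochs
        self.max_steps = max_steps
        self.fixed_z = fixed_z
        self.random_state = random_state

    def _config(self) -> TrainConfig:
        return TrainConfig(
            lr_generator=self.lr_generator, lr_discriminator=self.lr_discriminator,
            adam_beta1=self.adam_beta1, adam_beta2=self.adam_beta2,
            lambda1=self.lambda1, T=self.T, beta_min=self.beta_min,
            beta_max=self.beta_max, batch_size=self.batch_size, epochs=self.epochs,
            max_steps=self.max_steps, k_adjacent=self.k_adjacent,
            base_channels=self.base_channels, depth=self.depth, z_dim=self.z_dim,
            seed=0 if self.random_state is None else int(self.random_state),
        )

    @staticmethod
    def _as_volumes(X) -> list:
        vols = [np.asarray(v, dtype=np.float32) for v in X]
        for v in vols:
            if v.ndim != 3:
                raise ValueError(f"each sample must be a 3D volume, got shape {v.shape}")
            if v.shape != vols[0].shape:
                raise ValueError("all volumes must share a grid")
        return vols

    def fit(self, X, y, masks=None):
        """Train on paired volumes: X conditioning (low-field), y targets.

        Both are sequences of co-registered 3D arrays on a [0, 1] scale.
        """
        X = self._as_volumes(X)
        y = self._as_volumes(y)
        if len(X) != len(y):
            raise ValueError(f"X and y lengths differ: {len(X)} vs {len(y)}")
        if X[0].shape != y[0].shape:
            raise ValueError("conditioning and target grids differ")
        cfg = self._config()
        stacks = []
        for i, (cond, tgt) in enumerate(zip(X, y)):
            mask = np.asarray(masks[i], bool) if masks is not None else np.ones(cond.shape, bool)
            pair = VolumePair(conditioning=cond, target=tgt, spacing=(1.0, 1.0, 1.0),
                              contrast="", brain_mask=mask, subject_id=f"sample-{i}")
            stacks.extend(make_2p5d_stacks(pair, cfg.k_adjacent))
        G, D, _, _, _, step, hist, _ = train_on_stacks(stacks, cfg)
        self.generator_ = G
        self.discriminator_ = D
        self.schedule_ = cfg.schedule()
        self.loss_history_ = hist
        self.n_steps_ = int(step)
        return self

    def transform(self, X, seed: int | None = None):
        """Enhance conditioning volumes; returns an array of the same shape."""
        if not hasattr(self, "generator_"):
            raise AttributeError("DiffusionEnhancer is not fitted yet; call fit first")
        X = self._as_volumes(X)
        base = int(self.random_state or 0) if seed is None else int(seed)
        out = []
        for i, vol in enumerate(X):
            res = enhance_volume(vol, self.generator_, self.schedule_,
                                 seed=base + i, fixed_z=self.fixed_z)
            out.append(res.enhanced)
        return np.stack(out)

    def predict(self, X, seed: int | None = None):
        return self.transform(X, seed=seed)
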