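"""Scikit-learn style estimator wrapping the network and training loop.

``CellImageClassifier`` follows the sklearn estimator contract — keyword
constructor that only stores parameters, ``fit(X, y)`` returning ``self``,
fitted attributes with a trailing underscore, ``predict`` /
``predict_proba`` / ``score`` — so it composes with sklearn model selection
and pipelines operating on (n, H, W, 3) image arrays.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .config import ModelConfig
from .data import LabeledImageSet
from .network import DDRNet, count_parameters
from .train import TrainConfig, train_model


class CellImageClassifier(ClassifierMixin, BaseEstimator):
    """Dilated-residual attention classifier for single-cell images.

    Parameters mirror the architecture and training recipe; defaults are
    the published configuration.  ``X`` is an (n, H, W, 3) float array with
    values in [0, 1]; ``y`` is any label vector (mapped through
    ``classes_``).

    Examples
    --------
    >>> from wbcnet.synth import SyntheticCellSpec, generate_synthetic_cells
    >>> ds = generate_synthetic_cells(SyntheticCellSpec(canvas=56), 10)
    >>> clf = CellImageClassifier(stem_channels=8, drdb_branch_width=8,
    ...                           glfeb_widths=(8, 16, 8), gn_groups=4,
    ...                           head_channels=8, epochs=5)
    >>> clf.fit(ds.images, ds.labels).score(ds.images, ds.labels)  # doctest: +SKIP
    """

    def __init__(self, *, stem_channels: int = 32, drdb_branch_width: int = 64,
                 drdb_dilations: tuple = (1, 2, 4), drdb_depth: int = 1,
                 glfeb_widths: tuple = (64, 128, 64), gn_groups: int = 32,
                 dropout_rate: float = 0.20, head: str = "softmax",
                 head_channels: int = 64, csab_kernel: int = 5,
                 attention_fc_reduction: int = 8,
                 attention_dual_pool: bool = False,
                 use_drdb: bool = True, use_glfeb: bool = True,
                 use_csab: bool = True,
                 learning_rate: float = 0.01, epochs: int = 30,
                 batch_size: int = 32, val_frac: float = 0.0,
                 seed: int = 0):
        self.stem_channels = stem_channels
        self.drdb_branch_width = drdb_branch_width
        self.drdb_dilations = drdb_dilations
        self.drdb_depth = drdb_depth
        self.glfeb_widths = glfeb_widths
        self.gn_groups = gn_groups
        self.dropout_rate = dropout_rate
        self.head = head
        self.head_channels = head_channels
        self.csab_kernel = csab_kernel
        self.attention_fc_reduction = attention_fc_reduction
        self.attention_dual_pool = attention_dual_pool
        self.use_drdb = use_drdb
        self.use_glfeb = use_glfeb
        self.use_csab = use_csab
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.val_frac = val_frac
        self.seed = seed

    # -- sklearn API ------------------------------------------------------
    def _model_config(self, input_size) -> ModelConfig:
        return ModelConfig(
            input_size=input_size, stem_channels=self.stem_channels,
            drdb_branch_width=self.drdb_branch_width,
            drdb_dilations=self.drdb_dilations, drdb_depth=self.drdb_depth,
            glfeb_widths=self.glfeb_widths, gn_groups=self.gn_groups,
            dropout_rate=self.dropout_rate,
            num_classes=len(self.classes_), head=self.head,
            head_channels=self.head_channels, csab_kernel=self.csab_kernel,
            attention_fc_reduction=self.attention_fc_reduction,
            attention_dual_pool=self.attention_dual_pool, seed=self.seed)

    def fit(self, X, y) -> "CellImageClassifier":
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError(f"X must be (n, H, W, 3), got shape {X.shape}")
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        cfg = self._model_config((X.shape[1], X.shape[2], 3))
        self.net_ = DDRNet(cfg, use_drdb=self.use_drdb,
                           use_glfeb=self.use_glfeb, use_csab=self.use_csab)
        class_names = tuple(str(c) for c in self.classes_)
        data = LabeledImageSet(X, y_idx, class_names)
        if self.val_frac > 0:
            # stratified val carve-out from the training data
            rng = np.random.default_rng(self.seed)
            split = np.array(["train"] * len(X), dtype=object)
            for k in range(len(self.classes_)):
                idx = np.where(y_idx == k)[0]
                n_val = max(1, int(round(self.val_frac * len(idx))))
                split[rng.permutation(idx)[:n_val]] = "val"
            data.split = split.astype(str)
        tcfg = TrainConfig(learning_rate=self.learning_rate,
                           epochs=self.epochs, batch_size=self.batch_size,
                           seed=self.seed)
        _, self.history_ = train_model(self.net_, data, tcfg)
        self.n_params_ = count_parameters(self.net_)
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        X = np.asarray(X, dtype=np.float32)
        self.net_.eval()
        out = []
        for start in range(0, len(X), 64):
            out.append(self.net_.predict_proba(X[start:start + 64]))
        return np.concatenate(out)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)]
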