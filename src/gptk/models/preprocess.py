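"""Per-training-fold preprocessing carried by fitted models.

Responses are z-scored on the training fold before KRR/SVR fitting and
predictions are transformed back; features optionally pass through a PCA
rotation fitted on the same training fold.  Keeping these constants on the
model is what makes prediction on new individuals leak-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..kernels import PCAState, transform_pca


@dataclass
class Preprocess:
    pca: PCAState | None = None
    y_mean: float = 0.0
    y_std: float = 1.0

    @classmethod
    def fit(cls, X: np.ndarray, y: np.ndarray, pca: PCAState | None = None) -> "Preprocess":
        y = np.asarray(y, dtype=float)
        std = float(np.std(y))
        if std == 0.0:
            std = 1.0  # constant response: shift only
        return cls(pca=pca, y_mean=float(np.mean(y)), y_std=std)

    def transform_X(self, X: np.ndarray) -> np.ndarray:
        return X if self.pca is None else transform_pca(X, self.pca)

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.y_mean) / self.y_std

    def inverse_y(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.y_std + self.y_mean
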