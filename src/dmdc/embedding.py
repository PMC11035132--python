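"""Takens time-delay embedding.

A scalar series ``x`` of length ``L`` becomes the point cloud whose row ``i``
is ``(x[i], x[i+lag], ..., x[i+(m-1)*lag])``; with ``m`` generic delays the
embedded trajectory has the topology of the underlying attractor.  For a
composite filter condition the two filtered streams of the same epoch are
embedded separately and concatenated column-wise (both are causally related
measurements of the same dynamic), giving ``2m`` columns over identical rows.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .store import Epoch

__all__ = ["DelayEmbedding", "delay_embed", "EmbeddingError"]


class EmbeddingError(ValueError):
    """Signal too short for the requested delay structure."""


def _embed_array(x: np.ndarray, n_delays: int, lag: int) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    span = (n_delays - 1) * lag
    n_points = len(x) - span
    if n_points < 1:
        raise EmbeddingError(
            f"signal length {len(x)} too short for {n_delays} delays at lag "
            f"{lag}; need at least {span + 1} samples"
        )
    idx = np.arange(n_points)[:, None] + lag * np.arange(n_delays)[None, :]
    return x[idx]


class DelayEmbedding(TransformerMixin, BaseEstimator):
    """Delay-coordinate map as a scikit-learn transformer.

    Parameters
    ----------
    n_delays : int, default 8
        Number of delay coordinates per stream.
    lag : int, default 1
        Delay between coordinates, in samples.  Consecutive delays (lag 1)
        follow the diffusion-mapped-delay-coordinate lineage; the lag is a
        documented knob, not an auto-tuned quantity.
    """

    def __init__(self, n_delays: int = 8, lag: int = 1):
        self.n_delays = n_delays
        self.lag = lag

    def _validate(self) -> None:
        if self.n_delays < 2:
            raise EmbeddingError(f"n_delays must be >= 2, got {self.n_delays}")
        if self.lag < 1:
            raise EmbeddingError(f"lag must be >= 1, got {self.lag}")

    def fit(self, X, y=None):  # noqa: D102 - stateless; kept for API symmetry
        self._validate()
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        """Embed an epoch, a pair of epochs, an array, or a list of streams."""
        self._validate()
        streams: list[np.ndarray]
        if isinstance(X, Epoch):
            streams = [X.samples]
        elif isinstance(X, (tuple, list)) and all(isinstance(e, Epoch) for e in X):
            lengths = {len(e) for e in X}
            rates = {e.fs for e in X}
            if len(lengths) > 1 or len(rates) > 1:
                raise EmbeddingError("composite streams need equal lengths and fs")
            streams = [e.samples for e in X]
        else:
            arr = np.asarray(X, dtype=float)
            streams = [arr] if arr.ndim == 1 else [c for c in arr.T]
        blocks = [_embed_array(s, self.n_delays, self.lag) for s in streams]
        return np.hstack(blocks)

    def fit_transform(self, X, y=None, **kwargs) -> np.ndarray:
        return self.fit(X).transform(X)


def delay_embed(epoch_or_pair, n_delays: int = 8, lag: int = 1) -> np.ndarray:
    """Functional form of :class:`DelayEmbedding`."""
    return DelayEmbedding(n_delays=n_delays, lag=lag).fit_transform(epoch_or_pair)
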