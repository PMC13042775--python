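"""Spillover compensation and image cleaning for imaging mass cytometry data.

Mass-cytometry channels leak into each other because metal isotope stocks are
not perfectly pure: a fraction of the signal acquired for channel *i* is
observed in channel *j*.  The leakage is summarised by a square spillover
matrix ``S`` with ``S[i, j]`` = fraction of channel *i* signal observed in
channel *j* (row convention: ``observed = true @ S``; diagonal 1).
Compensation solves, for every cell (or pixel) row ``y``, the nonnegative
least-squares problem ``argmin_{x >= 0} ||x S - y||^2``, which removes the
crosstalk without producing negative expression values.

Raw images additionally carry two kinds of acquisition artifacts that are
removed before quantification: isolated "hot" pixels (single-pixel spikes
from detector noise) and antibody aggregates, which appear as minuscule very
bright connected components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import nnls

__all__ = [
    "SpilloverMatrix",
    "compensate_spillover",
    "clean_image",
    "estimate_spillover",
]


@dataclass(frozen=True)
class SpilloverMatrix:
    """Square channel-spillover matrix.

    ``S[i, j]`` is the fraction of channel ``channels[i]`` signal observed in
    channel ``channels[j]``; the diagonal is 1 and off-diagonal entries lie in
    ``[0, 1)``.  The row convention ``observed = true @ S`` is fixed and is
    also documented in the CSV header written by :meth:`to_csv`.
    """

    channels: tuple[str, ...]
    S: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "channels", tuple(self.channels))
        n = len(self.channels)
        if S.shape != (n, n):
            raise ValueError(f"spillover matrix shape {S.shape} does not match {n} channels")
        if not np.allclose(np.diag(S), 1.0):
            raise ValueError("spillover matrix diagonal must be 1")
        off = S[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < 0 or off.max() >= 1):
            raise ValueError("off-diagonal spillover fractions must lie in [0, 1)")

    @classmethod
    def identity(cls, channels) -> "SpilloverMatrix":
        channels = tuple(channels)
        return cls(channels=channels, S=np.eye(len(channels)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=list(self.channels), columns=list(self.channels))

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# spillover matrix, convention: observed = true @ S "
                     "(rows = emitting channel)\n")
            self.to_frame().to_csv(fh, index_label="channel")

    @classmethod
    def from_csv(cls, path) -> "SpilloverMatrix":
        df = pd.read_csv(path, comment="#", index_col=0)
        return cls(channels=tuple(df.columns), S=df.to_numpy(dtype=float))


def compensate_spillover(observed: pd.DataFrame, sm: SpilloverMatrix) -> pd.DataFrame:
    """Remove channel crosstalk from per-cell (or per-pixel) expression rows.

    For each row ``y`` returns ``argmin_{x >= 0} ||x S - y||^2`` solved by
    nonnegative least squares.  Channel order of the output matches the input.

    Parameters
    ----------
    observed
        Rows = cells (or pixels), columns = channel names.  The column set
        must equal ``sm.channels`` (any order).
    sm
        The measured spillover matrix.
    """
    if set(observed.columns) != set(sm.channels):
        missing = set(sm.channels) ^ set(observed.columns)
        raise ValueError(f"channel mismatch between expression and spillover matrix: {sorted(missing)}")
    cols = list(observed.columns)
    # reorder S to the observed column order
    order = [sm.channels.index(c) for c in cols]
    S = sm.S[np.ix_(order, order)]
    Y = observed.to_numpy(dtype=float)
    if np.allclose(S, np.eye(S.shape[0])):
        return observed.copy()

    # x S = y  <=>  S.T x.T = y.T ; try the fast unconstrained solve first and
    # fall back to NNLS only for rows where nonnegativity binds.
    A = S.T
    X = np.linalg.solve(A, Y.T).T
    bad = np.where((X < -1e-9).any(axis=1))[0]
    for i in bad:
        X[i], _ = nnls(A, Y[i])
    np.clip(X, 0.0, None, out=X)
    return pd.DataFrame(X, index=observed.index, columns=cols)


def estimate_spillover(controls: dict[str, pd.DataFrame], channels) -> SpilloverMatrix:
    """Estimate a spillover matrix from single-stained control acquisitions.

    ``controls[c]`` holds expression rows acquired with only channel ``c``
    stained.  The spillover from ``c`` into ``d`` is estimated as the median
    per-row ratio ``d / c`` over rows with positive signal in ``c``.  This is
    a convenience helper, not a validated estimation stage.
    """
    channels = tuple(channels)
    n = len(channels)
    S = np.eye(n)
    for i, c in enumerate(channels):
        if c not in controls:
            continue
        df = controls[c]
        src = df[c].to_numpy(dtype=float)
        ok = src > 0
        if not ok.any():
            continue
        for j, d in enumerate(channels):
            if d == c:
                continue
            ratio = float(np.median(df[d].to_numpy(dtype=float)[ok] / src[ok]))
            S[i, j] = min(max(ratio, 0.0), np.nextafter(1.0, 0.0))
    return SpilloverMatrix(channels=channels, S=S)


def clean_image(
    image: np.ndarray,
    hot_kernel: int = 3,
    hot_factor: float = 5.0,
    agg_quantile: float = 0.999,
    agg_max_px: int = 25,
) -> np.ndarray:
    """Remove hot pixels and small antibody aggregates from a multichannel image.

    Hot pixels (value exceeding ``hot_factor`` times the ``hot_kernel`` x
    ``hot_kernel`` neighborhood median) are replaced by that median.
    Connected components of pixels above the ``agg_quantile`` intensity whose
    size is at most ``agg_max_px`` are treated as antibody aggregates and set
    to the local background (the neighborhood median).  No pixel is ever
    raised above its original value.

    ``image`` may be 2-D (one channel) or 3-D with channels on axis 0.
    """
    if hot_kernel % 2 != 1 or hot_kernel < 1:
        raise ValueError("hot_kernel must be a positive odd window size")
    if agg_max_px < 1:
        raise ValueError("agg_max_px must be >= 1")
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        return _clean_channel(img, hot_kernel, hot_factor, agg_quantile, agg_max_px)
    if img.ndim == 3:
        return np.stack(
            [_clean_channel(ch, hot_kernel, hot_factor, agg_quantile, agg_max_px) for ch in img]
        )
    raise ValueError("image must be 2-D per channel (2-D or channels-first 3-D array)")


def _clean_channel(img, hot_kernel, hot_factor, agg_quantile, agg_max_px):
    med = ndimage.median_filter(img, size=hot_kernel)
    out = img.copy()

    hot = img > hot_factor * med
    out[hot] = med[hot]

    thresh = np.quantile(img, agg_quantile)
    bright = img > thresh
    if bright.any() and thresh > 0:
        lab, n = ndimage.label(bright)
        if n:
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
            small = np.isin(lab, np.nonzero(sizes <= agg_max_px)[0] + 1)
            # local background estimated with the bright pixels masked out, so
            # an aggregate cannot dominate its own neighborhood median
            masked = np.where(bright, np.median(img), img)
            bg = ndimage.median_filter(masked, size=hot_kernel)
            out[small] = bg[small]

    return np.minimum(out, img)
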