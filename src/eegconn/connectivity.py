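"""Debiased weighted phase lag index (dwPLI) connectivity.

The dwPLI quantifies consistent non-zero-lag phase coupling between two
signals from the imaginary part of their cross-spectrum across epochs,
with a small-sample bias correction.  Because purely instantaneous
(zero-lag) mixing — volume conduction at the scalp — contributes only to
the real part of the cross-spectrum, the estimator is insensitive to it.

With ``I_k`` the imaginary cross-spectrum at epoch ``k``::

    dwPLI = [ (sum_k I_k)^2 - sum_k I_k^2 ] / [ (sum_k |I_k|)^2 - sum_k I_k^2 ]

The estimate is signed per frequency bin; band values average the signed
per-bin estimates over the band's bins and then take the absolute value,
yielding weights in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .spectral import BandDefinition, CrossSpectralDensity

__all__ = [
    "ConnectivityMatrix",
    "DwpliEstimate",
    "dwpli_per_bin",
    "band_dwpli",
    "summarize_dwpli",
]


@dataclass
class ConnectivityMatrix:
    """Per-band symmetric dwPLI weight matrix with zero diagonal."""

    band: str
    labels: list[str]
    weights: np.ndarray  # (n, n), in [0, 1]
    n_epochs_used: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.labels)
        if self.weights.shape != (n, n):
            raise ValueError("weights shape must match label count")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weights must be symmetric")


class DwpliEstimate(NamedTuple):
    value: float
    degenerate: bool


def _dwpli_from_imag(imag: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Debiased WPLI from imaginary cross-spectra, epochs on axis 0.

    Returns (estimate, degenerate_mask); degenerate bins — all imaginary
    parts exactly zero, i.e. no measurable lagged coupling — report 0.
    """
    s = imag.sum(axis=0)
    s2 = (imag ** 2).sum(axis=0)
    sa = np.abs(imag).sum(axis=0)
    num = s ** 2 - s2
    den = sa ** 2 - s2
    degenerate = den == 0
    est = np.divide(num, den, out=np.zeros_like(num), where=~degenerate)
    return est, degenerate


def dwpli_per_bin(csd: CrossSpectralDensity, pair: tuple[int, int],
                  bin_index: int) -> DwpliEstimate:
    """Signed dwPLI for one channel pair at one frequency bin."""
    if csd.n_epochs < 2:
        raise ValueError("dwPLI requires at least 2 epochs")
    i, j = pair
    imag = np.imag(csd.pair(i, j)[:, bin_index])
    est, degenerate = _dwpli_from_imag(imag)
    return DwpliEstimate(float(est), bool(degenerate))


def band_dwpli(csd: CrossSpectralDensity, band: BandDefinition,
               abs_per_bin: bool = False) -> ConnectivityMatrix:
    """dwPLI matrix for one band: all channel pairs, band bins averaged.

    The signed per-bin estimates are averaged over the band's bins and the
    absolute value of that average is returned (``abs_per_bin=False``,
    default).  Taking absolute values per bin before averaging
    (``abs_per_bin=True``) is offered for comparison but inflates the null
    level, since independent signals then no longer average toward zero.
    """
    if csd.n_epochs < 2:
        raise ValueError("dwPLI requires at least 2 epochs")
    bins = np.flatnonzero(band.contains(csd.freqs))
    if bins.size == 0:
        raise ValueError(
            f"band {band.name} [{band.f_lo}, {band.f_hi}] contains no bins "
            f"at resolution {csd.df:.4f} Hz"
        )
    n = csd.n_channels
    acc = np.zeros((n, n))
    for b in bins:
        imag = np.imag(csd.at_bin(int(b)))
        est, _ = _dwpli_from_imag(imag)
        acc += np.abs(est) if abs_per_bin else est
    weights = np.abs(acc / bins.size)
    weights = (weights + weights.T) / 2.0
    np.fill_diagonal(weights, 0.0)
    return ConnectivityMatrix(band.name, list(csd.channel_labels), weights,
                              csd.n_epochs)


def summarize_dwpli(matrix: ConnectivityMatrix) -> float:
    """Per-subject per-band scalar: mean of the off-diagonal upper triangle."""
    n = matrix.weights.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(matrix.weights[iu].mean())
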