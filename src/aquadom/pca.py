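"""PCA with the preprocessing used for EIS Bode-phase spectra.

The bilinear model D = T P^T + E is fit by SVD of the mean-centered or
autoscaled matrix: deterministic and exact at these problem sizes. The
per-component explained variance is sigma_i^2 / sum sigma^2 * 100 over
all components of the preprocessed matrix; a deterministic sign
convention (largest-magnitude loading entry positive) keeps results
stable across runs and platforms.

EIS spectra enter as rows of a sample-major, replicate-minor design
matrix on a common 500-point log10-spaced frequency grid between 0.1 Hz
and 20 kHz, optionally smoothed per-row with a 0th-order, 15-point
Savitzky-Golay filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import EISSpectrum, ValidationError

__all__ = [
    "PCAModel",
    "savitzky_golay",
    "assemble_eis_matrix",
    "fit_pca",
    "average_replicate_scores",
]


@dataclass
class PCAModel:
    """Scores, loadings and variance decomposition of a PCA fit."""

    preprocessing: str              # "center" or "autoscale"
    means: np.ndarray
    scales: np.ndarray              # ones under plain centering
    T: np.ndarray                   # nr x nc_kept scores
    P: np.ndarray                   # nv x nc_kept orthonormal loadings
    explained: np.ndarray           # percent per kept component
    explained_all: np.ndarray       # percent per possible component
    row_labels: Optional[list] = None

    @property
    def total_explained(self) -> float:
        return float(self.explained.sum())

    def reconstruct(self) -> np.ndarray:
        """Back-transformed reconstruction from the kept components."""
        return (self.T @ self.P.T) * self.scales + self.means

    def to_dict(self) -> dict:
        return {
            "preprocessing": self.preprocessing,
            "explained": self.explained.tolist(),
            "total_explained": self.total_explained,
            "scores": self.T.tolist(),
            "loadings": self.P.tolist(),
            "row_labels": self.row_labels,
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)


def savitzky_golay(signal, order: int = 0, window: int = 15) -> np.ndarray:
    """Savitzky-Golay smoothing with symmetrically shrinking edge windows.

    At each point a polynomial of the given order is least-squares fit
    over a centered window; near the edges the window shrinks
    symmetrically so it always stays centered (order 0 is therefore a
    centered moving average everywhere).
    """
    signal = np.asarray(signal, dtype=float).ravel()
    if window % 2 == 0:
        raise ValidationError("window must be odd")
    if window <= order:
        raise ValidationError("window must exceed the polynomial order")
    if signal.size < window:
        raise ValidationError("signal shorter than the smoothing window")
    half = window // 2
    out = np.empty_like(signal)
    n = signal.size
    for i in range(n):
        h = min(half, i, n - 1 - i)
        seg = signal[i - h : i + h + 1]
        deg = min(order, seg.size - 1)
        if deg == 0:
            out[i] = seg.mean()
        else:
            x = np.arange(-h, h + 1, dtype=float)
            coeffs = np.polynomial.polynomial.polyfit(x, seg, deg)
            out[i] = coeffs[0]  # polynomial value at the window center
    return out


def eis_target_grid(fmin: float = 0.1, fmax: float = 20000.0, n: int = 500) -> np.ndarray:
    """Common log10-spaced frequency grid for the EIS design matrix."""
    return np.logspace(np.log10(fmin), np.log10(fmax), n)


def assemble_eis_matrix(
    spectra: Sequence[EISSpectrum],
    fmin: float = 0.1,
    fmax: float = 20000.0,
    n_points: int = 500,
    smooth: bool = False,
    sg_order: int = 0,
    sg_window: int = 15,
):
    """Stack Bode-phase spectra into a (samples*replicates) x n_points matrix.

    Rows are ordered sample-major (order of first appearance) then by
    replicate number. Phases are linearly interpolated in log10(f) onto
    the common grid; a spectrum not covering [fmin, fmax] is an error.

    Returns ``(matrix, row_labels, freq_grid)`` with labels of the form
    ``"<sample_id>_<replicate>"``.
    """
    target = eis_target_grid(fmin, fmax, n_points)
    log_t = np.log10(target)
    sample_order: list = []
    for s in spectra:
        if s.sample_id not in sample_order:
            sample_order.append(s.sample_id)
    ordered = sorted(
        spectra, key=lambda s: (sample_order.index(s.sample_id), s.replicate)
    )
    rows, labels = [], []
    rtol = 1e-9
    for s in ordered:
        if s.freq_grid.min() > fmin * (1 + rtol) or s.freq_grid.max() < fmax * (1 - rtol):
            raise ValidationError(
                f"EIS spectrum of {s.sample_id!r} (replicate {s.replicate}) does "
                f"not cover [{fmin:g}, {fmax:g}] Hz"
            )
        phase = np.interp(log_t, np.log10(s.freq_grid), s.phase)
        if smooth:
            phase = savitzky_golay(phase, order=sg_order, window=sg_window)
        rows.append(phase)
        labels.append(f"{s.sample_id}_{s.replicate}")
    return np.vstack(rows), labels, target


def fit_pca(
    D: np.ndarray,
    preprocessing: str = "center",
    nc_kept: int = 2,
    row_labels: Optional[list] = None,
) -> PCAModel:
    """Fit the PCA bilinear model by SVD of the preprocessed matrix.

    ``preprocessing`` is ``"center"`` (column mean-centering) or
    ``"autoscale"`` (centering plus division by the n-1 column standard
    deviation; a zero-variance column is an error).
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] < 2:
        raise ValidationError("D must be a matrix with at least 2 rows")
    nr, nv = D.shape
    means = D.mean(axis=0)
    if preprocessing == "center":
        scales = np.ones(nv)
    elif preprocessing == "autoscale":
        scales = D.std(axis=0, ddof=1)
        zero = np.flatnonzero(scales == 0)
        if zero.size:
            raise ValidationError(
                f"autoscaling impossible: zero-variance columns {zero.tolist()}"
            )
    else:
        raise ValidationError("preprocessing must be 'center' or 'autoscale'")
    X = (D - means) / scales
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0:
        raise ValidationError("preprocessed matrix is identically zero")
    explained_all = 100.0 * s**2 / total
    nc_kept = int(min(nc_kept, s.size))
    T = U[:, :nc_kept] * s[:nc_kept]
    P = Vt[:nc_kept].T
    # sign convention: the largest-magnitude entry of each loading is positive
    for c in range(nc_kept):
        j = np.argmax(np.abs(P[:, c]))
        if P[j, c] < 0:
            P[:, c] = -P[:, c]
            T[:, c] = -T[:, c]
    return PCAModel(
        preprocessing=preprocessing, means=means, scales=scales,
        T=T, P=P, explained=explained_all[:nc_kept],
        explained_all=explained_all,
        row_labels=list(row_labels) if row_labels is not None else None,
    )


def average_replicate_scores(
    model: PCAModel, row_labels: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Average score rows across replicates of the same sample.

    Row labels of the form ``"<sample>_<replicate>"`` are grouped by
    sample; a bare label is its own group. An unpaired replicate is used
    as-is with a warning. Returns a DataFrame (samples x components, in
    order of first appearance).
    """
    labels = list(row_labels) if row_labels is not None else model.row_labels
    if labels is None:
        raise ValidationError("row labels are required to pair replicates")
    if len(labels) != model.T.shape[0]:
        raise ValidationError("label count does not match score rows")
    sample_of = [lbl.rsplit("_", 1)[0] if "_" in lbl else lbl for lbl in labels]
    order: list = []
    for sid in sample_of:
        if sid not in order:
            order.append(sid)
    rows = {}
    counts = {}
    for sid in order:
        sel = [i for i, s_ in enumerate(sample_of) if s_ == sid]
        counts[sid] = len(sel)
        rows[sid] = model.T[sel].mean(axis=0)
    if len(set(counts.values())) > 1:
        import warnings

        singles = [s_ for s_, c_ in counts.items() if c_ == min(counts.values())]
        warnings.warn(
            f"unpaired replicates for {singles}; single values used", stacklevel=2
        )
    cols = [f"pc{c + 1}" for c in range(model.T.shape[1])]
    return pd.DataFrame([rows[s_] for s_ in order], index=order, columns=cols)
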