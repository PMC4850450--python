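"""Channel-by-channel Pearson correlation matrices (functional connectivity).

A network node is an fNIRS channel; an edge weight is the Pearson correlation
between two channels' analysis time series.  By default the analysis series
is the per-trial normalized epochs concatenated across trials of one case;
the run-averaged epoch can be used instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import EpochSet

__all__ = ["CorrelationMatrix", "pearson_matrix", "group_average"]

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Symmetric channel × channel Pearson matrix (diagonal 1)."""

    labels: list[str]
    values: np.ndarray
    n_samples_used: int
    subject_id: str
    case: str
    group: str

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def validate(self) -> None:
        v = self.values
        if v.shape != (self.n_channels, self.n_channels):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("diagonal must be 1")
        if np.any(v < -1 - 1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("entries must lie in [-1, 1]")


def correlation_from_series(x: np.ndarray) -> np.ndarray:
    """Pearson matrix of a channels × samples array.

    Zero-variance channels get 0 off-diagonal (with a warning) instead of
    NaN; the diagonal is always exactly 1.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a channels x samples array with >= 2 channels")
    if x.shape[1] < 3:
        raise ValueError("need at least 3 time samples")
    sd = x.std(axis=1)
    flat = sd == 0
    if flat.any():
        logger.warning(
            "%d zero-variance channel(s); their correlations are set to 0",
            int(flat.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(x)
    r[flat, :] = 0.0
    r[:, flat] = 0.0
    np.fill_diagonal(r, 1.0)
    np.clip(r, -1.0, 1.0, out=r)
    return (r + r.T) / 2.0


def pearson_matrix(epoch_set: EpochSet, use_average: bool = False) -> CorrelationMatrix:
    """Correlation matrix of one subject/case.

    ``use_average=False`` (default) correlates the normalized epochs
    concatenated across trials; ``use_average=True`` correlates the
    run-averaged epoch instead.
    """
    if use_average:
        if epoch_set.averaged is None:
            raise ValueError("EpochSet has no run average; call normalize_and_average")
        series = epoch_set.averaged
    else:
        if epoch_set.n_trials == 0:
            raise ValueError("EpochSet has zero epochs")
        # (trials, channels, samples) -> (channels, trials * samples)
        e = epoch_set.epochs
        series = e.transpose(1, 0, 2).reshape(e.shape[1], -1)
    values = correlation_from_series(series)
    return CorrelationMatrix(
        labels=list(epoch_set.channels),
        values=values,
        n_samples_used=series.shape[1],
        subject_id=epoch_set.subject_id,
        case=epoch_set.case,
        group=epoch_set.group,
    )


def group_average(matrices: list[CorrelationMatrix]) -> CorrelationMatrix:
    """Element-wise mean of per-subject correlation matrices.

    Plain arithmetic averaging of the coefficients (a Fisher-z option is the
    caller's job if wanted: average ``np.arctanh`` transforms externally).
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels:
            raise ValueError("all matrices must share the same channel labels")
    values = np.mean([m.values for m in matrices], axis=0)
    np.fill_diagonal(values, 1.0)
    return CorrelationMatrix(
        labels=list(labels),
        values=values,
        n_samples_used=int(np.mean([m.n_samples_used for m in matrices])),
        subject_id="group-average",
        case=matrices[0].case,
        group=matrices[0].group,
    )
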