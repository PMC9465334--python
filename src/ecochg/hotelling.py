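"""One-sample Hotelling's T² detector on time-voltage means (TVMs).

Each epoch of a preprocessed recording is reduced to Q "time-voltage
means" — mean voltages over Q contiguous windows partitioning the
measurement window — giving an N x Q matrix V.  A one-sample Hotelling's
T² test against the zero vector asks whether the ensemble's mean TVM
vector differs from noise (band-passed noise has zero expectation).

Rows of V are the condensation epochs stacked with the *sign-flipped*
rarefaction epochs: the cochlear microphonic inverts with stimulus
polarity, so flipping RAR aligns the CM across all rows, doubles N (so Q
can be swept up to 195 with 100 epochs per polarity while keeping the
sample covariance nonsingular), and leaves the no-CM null mean at zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .preprocess import PreprocessedRecording
from .types import Recording

__all__ = [
    "TVMMatrix",
    "HotellingResult",
    "QTuningResult",
    "build_tvm",
    "hotelling_t2",
    "tune_q",
    "DEFAULT_Q",
    "DEFAULT_Q_GRID",
]

logger = logging.getLogger(__name__)

#: Per-frequency Q defaults: the accuracy-optimal values found on the
#: clinical training data.
DEFAULT_Q: dict[int, int] = {250: 90, 500: 80, 750: 100, 1000: 85, 1500: 105, 2000: 100}

#: Q sweep used for tuning: 5, 10, ..., 195.
DEFAULT_Q_GRID: tuple[int, ...] = tuple(range(5, 196, 5))


@dataclass
class TVMMatrix:
    """N x Q matrix of time-voltage means plus its window bounds."""

    V: np.ndarray
    window_bounds: list[tuple[int, int]]

    @property
    def N(self) -> int:
        return self.V.shape[0]

    @property
    def Q(self) -> int:
        return self.V.shape[1]


@dataclass
class HotellingResult:
    """Hotelling's T² test outcome."""

    t2: float
    f_stat: float
    dof: tuple[int, int]
    p_value: float
    alpha: float = 0.01
    detected: bool = False


@dataclass
class QTuningResult:
    """Accuracy-optimal Q per stimulus frequency plus the full curves."""

    optimal_q: dict[int, int]
    accuracy_curves: dict[int, dict[int, float]] = field(default_factory=dict)


def _stacked_epochs(rec: PreprocessedRecording | Recording) -> np.ndarray:
    return np.vstack([rec.con.samples, -rec.rar.samples])


def build_tvm(rec: PreprocessedRecording | Recording, q: int) -> TVMMatrix:
    """Build the N x Q time-voltage-mean matrix for one recording.

    Accepts the output of :func:`ecochg.preprocess.preprocess_recording`
    (recommended) or a raw :class:`Recording` assumed already clean.
    Window boundaries are ``round(j * T / Q)``: every sample belongs to
    exactly one window.
    """
    if q < 1:
        raise ValueError(f"Q must be >= 1, got {q}")
    return build_tvm_from_array(_stacked_epochs(rec), q)


def hotelling_t2(
    V: TVMMatrix | np.ndarray,
    mu0: np.ndarray | None = None,
    alpha: float = 0.01,
) -> HotellingResult:
    """One-sample Hotelling's T² test of the mean TVM vector against mu0.

    T² = N (x̄ - μ0)' S⁻¹ (x̄ - μ0) with S the unbiased sample covariance;
    F = T² (N - Q) / (Q (N - 1)) is referred to F(Q, N - Q) and the upper
    tail taken as the p-value.  mu0 defaults to the zero vector (noise).
    """
    v = V.V if isinstance(V, TVMMatrix) else np.asarray(V, float)
    if v.ndim == 1:
        v = v[:, None]
    n, q = v.shape
    if n <= q:
        raise ValueError(f"need N > Q, got N={n}, Q={q}")
    mu0 = np.zeros(q) if mu0 is None else np.asarray(mu0, float)
    diff = v.mean(axis=0) - mu0
    s = np.cov(v, rowvar=False).reshape(q, q)
    try:
        c, low = linalg.cho_factor(s)
        t2 = float(n * diff @ linalg.cho_solve((c, low), diff))
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            f"singular TVM covariance (Q={q}, N={n}); use a smaller Q"
        ) from exc
    f_stat = t2 * (n - q) / (q * (n - 1))
    p = float(stats.f.sf(f_stat, q, n - q))
    return HotellingResult(
        t2=t2, f_stat=f_stat, dof=(q, n - q), p_value=p,
        alpha=alpha, detected=p < alpha,
    )


def tune_q(
    training: list[tuple[PreprocessedRecording | Recording, bool]],
    alpha: float = 0.01,
    grid: tuple[int, ...] = DEFAULT_Q_GRID,
) -> QTuningResult:
    """Pick the accuracy-optimal Q per stimulus frequency on labelled data.

    For each frequency, every Q in ``grid`` is scored by the accuracy of
    the decision ``p < alpha`` against the labels; ties break toward the
    smallest Q (fewer parameters, more error degrees of freedom).  Grid
    values exceeding N - 1 or the sample count are skipped with a warning.
    """
    by_freq: dict[int, list[tuple[PreprocessedRecording | Recording, bool]]] = {}
    for rec, label in training:
        freq = int(rec.stimulus.frequency)
        by_freq.setdefault(freq, []).append((rec, bool(label)))

    optimal: dict[int, int] = {}
    curves: dict[int, dict[int, float]] = {}
    for freq, items in by_freq.items():
        labels = np.array([lab for _, lab in items])
        if labels.all() or not labels.any():
            raise ValueError(f"{freq} Hz training set contains a single class")
        # p-values per (recording, Q); the stacked matrix is reused across Q
        stacked = [_stacked_epochs(rec) for rec, _ in items]
        n_min = min(x.shape[0] for x in stacked)
        t_min = min(x.shape[1] for x in stacked)
        usable = [q for q in grid if q <= n_min - 1 and q <= t_min]
        skipped = sorted(set(grid) - set(usable))
        if skipped:
            warnings.warn(
                f"{freq} Hz: skipping Q values {skipped} exceeding N-1={n_min - 1} "
                f"or the sample count {t_min}"
            )
        if not usable:
            raise ValueError(f"{freq} Hz: no usable Q in the grid")
        curve: dict[int, float] = {}
        for q in usable:
            dec = np.array(
                [hotelling_t2(build_tvm_from_array(x, q)).p_value < alpha for x in stacked]
            )
            curve[q] = float(np.mean(dec == labels))
        best = min((q for q in usable), key=lambda q: (-curve[q], q))
        optimal[freq] = best
        curves[freq] = curve
    return QTuningResult(optimal_q=optimal, accuracy_curves=curves)


def build_tvm_from_array(x: np.ndarray, q: int) -> TVMMatrix:
    """TVM matrix from an already-stacked epoch array (epochs x samples)."""
    n, t = x.shape
    if q > n - 1:
        raise ValueError(f"Q = {q} exceeds the cap N - 1 = {n - 1}")
    if q > t:
        raise ValueError(f"Q = {q} exceeds the sample count {t}")
    bounds = np.round(np.arange(q + 1) * t / q).astype(int)
    v = np.add.reduceat(x, bounds[:-1], axis=1) / np.diff(bounds)
    return TVMMatrix(V=v, window_bounds=list(zip(bounds[:-1], bounds[1:])))
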