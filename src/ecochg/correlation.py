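"""Split-buffer correlation detector.

A reproducible response correlates with itself: each polarity's epochs are
split at random into two equal buffers, the buffers are averaged, and the
Pearson correlation of the two buffer means is computed (CORR CON, CORR
RAR).  Their mean, averaged over 100 random re-splits, is the final
correlation coefficient — near 1 for a clear response, near 0 for noise.
A logistic regression on the coefficient turns it into a detection
probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import PreprocessedRecording
from .types import Recording

__all__ = [
    "CorrelationResult",
    "CorrLogistic",
    "corr_buffer_split",
    "fit_corr_classifier",
]

logger = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    """Outcome of the repeated buffer-split correlation."""

    corr_con: float
    corr_rar: float
    corr_coeff: float
    n_repetitions: int
    probability: float | None = None
    detected: bool | None = None


@dataclass
class CorrLogistic:
    """Logistic model mapping a correlation coefficient to P(response).

    ``perfect_separation`` marks the midpoint-threshold fallback used when
    the two classes do not overlap (the ML slope diverges there).
    """

    intercept: float
    slope: float
    perfect_separation: bool = False
    threshold_probability: float = 0.5

    def predict_proba(self, coeff) -> np.ndarray:
        z = self.intercept + self.slope * np.asarray(coeff, float)
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, coeff) -> np.ndarray:
        return self.predict_proba(coeff) >= self.threshold_probability


def _split_means(x: np.ndarray, rng: np.random.Generator, n_rep: int) -> tuple[np.ndarray, np.ndarray]:
    """Buffer means for all repetitions at once: (n_rep, T) each."""
    n = x.shape[0]
    use = n - (n % 2)  # odd counts: one random epoch left out per repetition
    half = use // 2
    order = np.argsort(rng.random((n_rep, n)), axis=1)  # random permutations
    b1 = x[order[:, :half]].mean(axis=1)
    b2 = x[order[:, half:use]].mean(axis=1)
    return b1, b2


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(ac, axis=1) * np.linalg.norm(bc, axis=1)
    num = np.einsum("ij,ij->i", ac, bc)
    r = np.zeros(a.shape[0])
    ok = denom > 0
    if not ok.all():
        logger.warning("%d zero-variance buffer means; r set to 0", (~ok).sum())
    r[ok] = num[ok] / denom[ok]
    return r


def corr_buffer_split(
    rec: PreprocessedRecording | Recording,
    n_repetitions: int = 100,
    seed: int | np.random.Generator | None = None,
    model: CorrLogistic | None = None,
) -> CorrelationResult:
    """Repeated random buffer-split correlation for one recording.

    Per repetition the CON epochs are split into buffers 1/2 and the RAR
    epochs into buffers 3/4; CORR = (r(b1,b2) + r(b3,b4)) / 2, and
    ``corr_coeff`` is its mean over repetitions.  Deterministic given
    ``seed``.  If ``model`` is given, its probability and decision are
    attached.
    """
    con, rar = rec.con.samples, rec.rar.samples
    if con.shape[0] < 4 or rar.shape[0] < 4:
        raise ValueError("need at least 4 epochs per polarity")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r_con = _rowwise_pearson(*_split_means(con, rng, n_repetitions))
    r_rar = _rowwise_pearson(*_split_means(rar, rng, n_repetitions))
    corr = (r_con + r_rar) / 2.0
    result = CorrelationResult(
        corr_con=float(r_con.mean()),
        corr_rar=float(r_rar.mean()),
        corr_coeff=float(corr.mean()),
        n_repetitions=n_repetitions,
    )
    if model is not None:
        p = float(model.predict_proba(result.corr_coeff))
        result.probability = p
        result.detected = p >= model.threshold_probability
    return result


def fit_corr_classifier(coeffs, labels) -> CorrLogistic:
    """Maximum-likelihood logistic regression of label on corr_coeff.

    Falls back to a midpoint threshold (steep logistic centred between the
    classes, flagged via ``perfect_separation``) when the classes are
    perfectly separated and the ML estimate does not exist.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    x = np.asarray(coeffs, float)
    y = np.asarray(labels).astype(float)
    if y.min() == y.max():
        raise ValueError("both classes must be present to fit the classifier")

    # orient so positives sit above negatives, then test for separation
    direction = 1.0 if x[y == 1].mean() >= x[y == 0].mean() else -1.0
    xd = direction * x
    lo, hi = xd[y == 0].max(), xd[y == 1].min()
    if lo >= hi:  # overlapping classes: the ML estimate exists
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
            if np.isfinite(fit.params).all() and np.abs(fit.params).max() < 1e6:
                return CorrLogistic(
                    intercept=float(fit.params[0]), slope=float(fit.params[1])
                )
        except (PerfectSeparationError, np.linalg.LinAlgError):
            pass
    logger.warning("perfect separation in corr classifier; midpoint threshold used")
    mid = (lo + hi) / 2.0
    gap = max(hi - lo, 1e-12)
    slope = 20.0 / gap
    return CorrLogistic(
        intercept=-direction * slope * mid,
        slope=direction * slope,
        perfect_separation=True,
    )
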