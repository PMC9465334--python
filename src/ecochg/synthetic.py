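"""Synthetic ECochG recordings with known ground truth.

The cochlear microphonic is modelled as a gated pure tone at the stimulus
frequency that inverts with stimulus polarity: condensation epochs carry
``+s(t)`` and rarefaction epochs ``-s(t)``, both plus additive white
Gaussian noise.  Optional defects emulate what preprocessing must handle:
low-frequency baseline wander, buffer-stitching step artifacts, and runs of
outlier epochs (movement/interference bursts).

SNR throughout refers to the plus-minus (±) averaging estimate on the DIF
epoch ensemble, i.e. the signal power of the averaged response relative to
the residual noise power of that average — the scale on which clinical
ECochG SNRs of roughly 2-6 dB are reported.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import EpochMatrix, Polarity, Recording, StimulusSpec, ThresholdCategory

__all__ = [
    "SynthesisParams",
    "cm_waveform",
    "synth_recording",
    "synth_dataset",
    "inject_artifacts",
    "amplitude_for_snr",
    "realized_snr",
    "CLINICAL_SNR_DB",
]

#: Mean ± SNR (dB) of clinical recordings by stimulus frequency and level
#: category (supra-, near-, sub-threshold); used as default dataset targets.
CLINICAL_SNR_DB: dict[int, dict[str, float]] = {
    250: {"supra": 2.68, "near": 2.32, "sub": 2.28},
    500: {"supra": 4.41, "near": 2.62, "sub": 2.37},
    750: {"supra": 4.20, "near": 2.80, "sub": 2.41},
    1000: {"supra": 5.64, "near": 2.95, "sub": 2.38},
    1500: {"supra": 3.98, "near": 2.40, "sub": 2.30},
    2000: {"supra": 4.24, "near": 2.40, "sub": 2.42},
}

DEFAULT_SAMPLING_RATE = 20_000.0


@dataclass
class SynthesisParams:
    """Parameters of one synthetic recording.

    ``cm_amplitude`` is the peak amplitude of the injected CM tone in µV;
    zero means a noise-only recording.  ``cm_onset_delay`` defaults to the
    stimulus recording delay (1 ms).  ``outlier_fraction`` epochs per
    polarity are replaced by uncorrelated noise, in one contiguous block.
    """

    stimulus: StimulusSpec
    cm_amplitude: float = 1.0
    cm_onset_delay: float | None = None
    noise_sd: float = 1.0
    baseline_wander_amplitude: float = 0.0
    baseline_wander_frequency: float = 15.0
    outlier_fraction: float = 0.0
    stitching_artifact: bool = False
    stitching_sample: int | None = None
    stitching_amplitude: float = 50.0
    n_epochs: int = 100
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_epochs < 4:
            raise ValueError(f"n_epochs must be >= 4, got {self.n_epochs}")
        if not 0.0 <= self.outlier_fraction <= 0.5:
            raise ValueError("outlier_fraction must lie in [0, 0.5]")
        if self.cm_amplitude < 0:
            raise ValueError("cm_amplitude must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.cm_onset_delay is None:
            self.cm_onset_delay = self.stimulus.recording_delay
        if (self.cm_onset_delay + self.stimulus.stimulus_duration
                > self.stimulus.measurement_window + 1e-9):
            raise ValueError(
                "cm_onset_delay + stimulus_duration exceeds the measurement window"
            )


def cm_waveform(
    stimulus: StimulusSpec,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    amplitude: float = 1.0,
    onset_delay: float | None = None,
    ramp_ms: float = 1.0,
) -> np.ndarray:
    """Deterministic CM template: a gated sine with raised-cosine ramps.

    Returns one epoch's worth of samples (µV).  The tone runs from
    ``onset_delay`` for ``stimulus_duration`` ms with ``ramp_ms`` on/off
    ramps inside the gate.
    """
    if onset_delay is None:
        onset_delay = stimulus.recording_delay
    n = stimulus.n_samples(sampling_rate)
    t = np.arange(n) / sampling_rate * 1e3  # ms
    dur = stimulus.stimulus_duration
    ramp = min(ramp_ms, dur / 2.0)
    rel = t - onset_delay
    env = np.zeros(n)
    inside = (rel >= 0) & (rel <= dur)
    env[inside] = 1.0
    if ramp > 0:
        up = inside & (rel < ramp)
        env[up] = 0.5 * (1 - np.cos(np.pi * rel[up] / ramp))
        down = inside & (rel > dur - ramp)
        env[down] = 0.5 * (1 - np.cos(np.pi * (dur - rel[down]) / ramp))
    return amplitude * env * np.sin(2 * np.pi * stimulus.frequency * rel * 1e-3)


def _noise(rng: np.random.Generator, params: SynthesisParams, shape: tuple) -> np.ndarray:
    out = rng.normal(0.0, params.noise_sd, size=shape) if params.noise_sd > 0 else np.zeros(shape)
    if params.baseline_wander_amplitude > 0:
        n_ep, n_s = shape
        t = np.arange(n_s) / params.sampling_rate
        phases = rng.uniform(0, 2 * np.pi, size=(n_ep, 1))
        out = out + params.baseline_wander_amplitude * np.sin(
            2 * np.pi * params.baseline_wander_frequency * t[None, :] + phases
        )
    return out


def synth_recording(
    params: SynthesisParams,
    rng: np.random.Generator | None = None,
    recording_id: str = "",
) -> Recording:
    """Generate one recording; deterministic for a fixed seed.

    CON epochs are ``s(t) + noise`` and RAR epochs ``-s(t) + noise``, so the
    DIF mean recovers ``s(t)`` and the SUM mean cancels it.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate
    n = params.stimulus.n_samples(fs)
    s = cm_waveform(params.stimulus, fs, params.cm_amplitude, params.cm_onset_delay)

    con = s[None, :] + _noise(rng, params, (params.n_epochs, n))
    rar = -s[None, :] + _noise(rng, params, (params.n_epochs, n))

    if params.outlier_fraction > 0:
        k = int(round(params.outlier_fraction * params.n_epochs))
        for mat in (con, rar):
            start = int(rng.integers(0, params.n_epochs - k + 1))
            mat[start:start + k] = _noise(rng, params, (k, n))

    if params.stitching_artifact:
        idx = params.stitching_sample if params.stitching_sample is not None else n // 2
        if not 0 <= idx < n:
            raise ValueError(f"stitching_sample {idx} out of range [0, {n})")
        con[:, idx:] += params.stitching_amplitude
        rar[:, idx:] += params.stitching_amplitude

    return Recording(
        con=EpochMatrix(con, fs, Polarity.CON),
        rar=EpochMatrix(rar, fs, Polarity.RAR),
        stimulus=params.stimulus,
        recording_id=recording_id,
        ground_truth=params.cm_amplitude > 0,
    )


def amplitude_for_snr(
    stimulus: StimulusSpec,
    target_snr_db: float,
    noise_sd: float = 1.0,
    n_epochs: int = 100,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    onset_delay: float | None = None,
    tol_db: float = 1e-4,
) -> float:
    """CM amplitude (µV) whose expected ± SNR on the DIF ensemble hits a target.

    The DIF epoch noise variance is ``noise_sd**2 / 2`` (two independent
    polarities averaged with weight 1/2), so the averaged response carries
    noise power ``noise_sd**2 / (2 n)`` and the expected ± SNR of a template
    with mean-square ``m`` at amplitude ``a`` is
    ``10 log10(a^2 m 2 n / noise_sd^2)``.  Solved by bisection on ``a``.
    """
    u = cm_waveform(stimulus, sampling_rate, 1.0, onset_delay)
    m = float(np.mean(u**2))
    if m <= 0 or noise_sd <= 0:
        raise ValueError(
            "SNR target unreachable: zero-power template or zero noise "
            f"(template mean-square {m}, noise_sd {noise_sd})"
        )
    noise_power = noise_sd**2 / (2 * n_epochs)

    def snr_db(a: float) -> float:
        return 10 * np.log10(a**2 * m / noise_power)

    lo, hi = 1e-9 * noise_sd, 1e6 * noise_sd
    if not snr_db(lo) < target_snr_db < snr_db(hi):
        raise ValueError(f"SNR target {target_snr_db} dB outside the reachable range")
    while snr_db(hi) - snr_db(lo) > tol_db:
        mid = np.sqrt(lo * hi)  # bisect in log-amplitude: SNR is linear there
        if snr_db(mid) < target_snr_db:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def realized_snr(rec: Recording) -> float:
    """± SNR (dB) of the raw DIF epoch ensemble of a recording.

    This is the scale :func:`amplitude_for_snr` calibrates against —
    measured on the generated epochs before any filtering.  The objective
    band-pass (100 Hz - 5 kHz) later removes roughly half the white-noise
    power, so pipeline SNR estimates read about 3 dB above this value.
    """
    from .preprocess import snr_plus_minus

    return snr_plus_minus((rec.con.samples - rec.rar.samples) / 2.0)


def synth_dataset(
    recipe: dict,
    seed: int | None = None,
) -> tuple[list[Recording], pd.DataFrame]:
    """Generate a labelled dataset from a recipe.

    The recipe maps the clinical study design — frequencies crossed with
    supra/near/sub-threshold level categories and target ± SNRs — onto the
    generator.  Schema::

        cells:                      # one entry per dataset cell
          - frequency: 500
            category: supra         # supra | near | sub | noise
            n: 10
            snr_db: 4.41            # omit (or category noise) for no signal
        noise_sd: 1.0               # optional globals
        n_epochs: 100
        sampling_rate: 20000.0
        outlier_fraction: 0.0

    Returns the recordings plus a label/manifest table with a single
    consensus rater ``truth`` whose round-1 labels are the ground truth.
    """
    if "cells" not in recipe:
        raise ValueError("recipe must contain a 'cells' list")
    rng = np.random.default_rng(seed)
    noise_sd = float(recipe.get("noise_sd", 1.0))
    n_epochs = int(recipe.get("n_epochs", 100))
    fs = float(recipe.get("sampling_rate", DEFAULT_SAMPLING_RATE))
    outlier_fraction = float(recipe.get("outlier_fraction", 0.0))

    recordings: list[Recording] = []
    rows = []
    idx = 0
    for cell in recipe["cells"]:
        freq = int(cell["frequency"])
        category = str(cell.get("category", "supra"))
        n_rec = int(cell["n"])
        snr_db = cell.get("snr_db", None)
        noise_only = category == "noise" or snr_db is None
        stim_cat = (
            ThresholdCategory(category)
            if category in ("supra", "near", "sub")
            else ThresholdCategory.SUB
        )
        stim = StimulusSpec(frequency=freq, threshold_category=stim_cat)
        if noise_only:
            amp = 0.0
        else:
            amp = amplitude_for_snr(stim, float(snr_db), noise_sd, n_epochs, fs)
        for _ in range(n_rec):
            rid = f"syn-{freq:04d}-{category}-{idx:05d}"
            params = SynthesisParams(
                stimulus=stim,
                cm_amplitude=amp,
                noise_sd=noise_sd,
                n_epochs=n_epochs,
                sampling_rate=fs,
                outlier_fraction=outlier_fraction,
            )
            rec = synth_recording(params, rng=rng, recording_id=rid)
            recordings.append(rec)
            rows.append(
                {
                    "recording_id": rid,
                    "frequency": freq,
                    "category": category,
                    "target_snr_db": np.nan if noise_only else float(snr_db),
                    "realized_snr_db": realized_snr(rec),
                    "cm_amplitude": amp,
                    "ground_truth": rec.ground_truth,
                    "rater_id": "truth",
                    "round": 1,
                    "response_present": rec.ground_truth,
                }
            )
            idx += 1
    return recordings, pd.DataFrame(rows)


def inject_artifacts(
    rec: Recording,
    kind: str,
    *,
    amplitude: float = 50.0,
    sample_index: int | None = None,
    fraction: float = 0.1,
    mode: str = "sign_flip",
    contiguous: bool = True,
    seed: int | None = None,
) -> Recording:
    """Return a copy of ``rec`` with a controlled defect injected.

    kind='stitching'
        Adds a step of ``amplitude`` µV at ``sample_index`` (default: window
        midpoint) to every epoch of both polarities.
    kind='outlier_epochs'
        Replaces ``round(fraction * n_epochs)`` epochs per polarity.  With
        ``mode='sign_flip'`` the chosen epochs are negated (anti-correlated
        with the ensemble mean — the defect the exclusion rule targets);
        with ``mode='noise'`` they become fresh noise of matching variance.
        ``contiguous=True`` places them in one block (random start), the
        realistic burst pattern.
    """
    rng = np.random.default_rng(seed)
    con = rec.con.samples.copy()
    rar = rec.rar.samples.copy()
    n_ep, n_s = con.shape

    if kind == "stitching":
        idx = n_s // 2 if sample_index is None else int(sample_index)
        if not 0 <= idx < n_s:
            raise ValueError(f"sample_index {idx} out of range [0, {n_s})")
        con[:, idx:] += amplitude
        rar[:, idx:] += amplitude
        extra = {"injected_stitching_index": idx, "injected_stitching_amplitude": amplitude}
    elif kind == "outlier_epochs":
        k = int(round(fraction * n_ep))
        if contiguous:
            start = int(rng.integers(0, n_ep - k + 1)) if k < n_ep else 0
            idxs = np.arange(start, start + k)
        else:
            idxs = rng.choice(n_ep, size=k, replace=False)
        for mat in (con, rar):
            if mode == "sign_flip":
                mat[idxs] = -mat[idxs]
            elif mode == "noise":
                sd = float(np.std(mat))
                mat[idxs] = rng.normal(0.0, sd, size=(k, n_s))
            else:
                raise ValueError(f"unknown outlier mode {mode!r}")
        extra = {"injected_outlier_indices": np.asarray(idxs), "injected_outlier_mode": mode}
    else:
        raise ValueError(f"unknown artifact kind {kind!r}")

    out = Recording(
        con=rec.con.replace(con),
        rar=rec.rar.replace(rar),
        stimulus=rec.stimulus,
        recording_id=rec.recording_id,
        electrode=rec.electrode,
        timing=rec.timing,
        ground_truth=rec.ground_truth,
        extra_attrs={**rec.extra_attrs},
    )
    out.extra_attrs.update(extra)
    return out
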