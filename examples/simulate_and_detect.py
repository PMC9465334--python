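"""Generate one synthetic ECochG recording and run both statistical detectors.

A 500 Hz cochlear-microphonic response is injected at a raw-DIF SNR of
4.4 dB (a typical supra-threshold recording); a noise-only control is
generated alongside.  Both are preprocessed and passed to the Hotelling
T² and buffer-split correlation detectors.
"""

import numpy as np

from ecochg import (
    DEFAULT_Q,
    StimulusSpec,
    SynthesisParams,
    amplitude_for_snr,
    build_tvm,
    corr_buffer_split,
    hotelling_t2,
    preprocess_recording,
    synth_recording,
)

stim = StimulusSpec(frequency=500)
amp = amplitude_for_snr(stim, target_snr_db=4.41)
rng = np.random.default_rng(1)

for name, amplitude in [("CM response (4.41 dB)", amp), ("noise only", 0.0)]:
    rec = synth_recording(SynthesisParams(stimulus=stim, cm_amplitude=amplitude), rng=rng)
    pre = preprocess_recording(rec)
    ht = hotelling_t2(build_tvm(pre, DEFAULT_Q[500]), alpha=0.01)
    corr = corr_buffer_split(pre, n_repetitions=100, seed=0)
    print(f"{name}:")
    print(f"  +/- SNR after preprocessing : {pre.derived.snr_dB:6.2f} dB "
          f"({pre.derived.n_excluded} epochs excluded)")
    print(f"  Hotelling T2 (Q=80)         : T2={ht.t2:8.1f}  p={ht.p_value:.3g}  "
          f"detected={ht.detected}")
    print(f"  buffer-split correlation    : corr_coeff={corr.corr_coeff:+.3f}")

# A detected response shows p << 0.01 and a correlation coefficient well
# above zero; the noise control shows a large p and a coefficient near 0.
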