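"""Condition a tremor recording and screen its spectral phenotype.

Generates a 1-minute synthetic postural acceleration recording (6 Hz
tremor over broadband noise) plus a weighted twin with a 2 Hz downward
peak shift, then runs the analysis chain: 0.5-40 Hz zero-phase
band-pass, RMS amplitude, disjoint-segments power spectrum (12 x 5 s
windows, 0.2 Hz resolution) and the load-shift origin classifier.
"""

import numpy as np

from tremorlab.signals import (
    bandpass_tremor, classify_origin, disjoint_spectrum, postural_rms,
)
from tremorlab.synth import TremorGenSpec, generate_tremor_pair

spec = TremorGenSpec(amplitude=0.15, frequency=6.0, freq_shift_weighted=2.0,
                     noise_sd=0.02, seed=3)
unweighted, weighted = generate_tremor_pair(spec)

rms = postural_rms(bandpass_tremor(unweighted), unweighted.fs)
sp_u = disjoint_spectrum(unweighted.samples, unweighted.fs)
sp_w = disjoint_spectrum(weighted.samples, weighted.fs)

print(f"postural RMS:        {rms:.4f} m/s^2 "
      f"(generated: {spec.amplitude / np.sqrt(2):.4f} + noise)")
print(f"spectrum:            {sp_u.n_segments} segments, "
      f"{sp_u.resolution:.1f} Hz resolution")
print(f"peak unweighted:     {sp_u.band_peak():.1f} Hz")
print(f"peak weighted:       {sp_w.band_peak():.1f} Hz")
print(f"origin class:        {classify_origin(sp_u, sp_w)}")

# A dominant peak that slows under inertial loading marks
# mechanical-reflex (non-central) tremor — the screening phenotype used
# to exclude enhanced physiological tremor from an ET cohort.
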