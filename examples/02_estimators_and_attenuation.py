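"""Compare zero-phase-inclusive and -exclusive estimators on a known lag.

Two noiseless 10 Hz signals offset by 0.3 rad: coherence and PLV report the
full interdependence, while the imaginary part of coherency -- built to
suppress zero-lag leakage artefact -- attenuates this genuine near-zero-lag
interaction by ~70%, the |sin(lag)| law that motivates the penalisation
scale.
"""

import warnings

import numpy as np

from zerolag import RegionTimeSeries, analytic_signal, imgcoh_attenuation, welch_csd
from zerolag.connectivity import (coherence_matrix, imag_coherency_matrix,
                                  phase_delay_matrix, plv_matrix, wpli_matrix)

fs = 250.0
t = np.arange(0, 20, 1 / fs)
phi = 0.3
pair = RegionTimeSeries(np.vstack([np.cos(2 * np.pi * 10 * t),
                                   np.cos(2 * np.pi * 10 * t - phi)]),
                        fs, band="alpha")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    csd = welch_csd(pair)
    coh = coherence_matrix(csd, "alpha").weights[0, 1]
    img = imag_coherency_matrix(csd, "alpha").weights[0, 1]
    wpli = wpli_matrix(csd, "alpha").weights[0, 1]
    analytic = analytic_signal(pair)
    plv = plv_matrix(analytic).weights[0, 1]
    tau = phase_delay_matrix(analytic).tau[0, 1]

print(f"planted lag: {phi} rad; measured mean phase delay: {tau:.3f} rad")
print(f"coherence        = {coh:.4f}   (inclusive: full strength)")
print(f"PLV              = {plv:.4f}   (inclusive: full strength)")
print(f"imag. coherency  = {img:.4f}   (exclusive: = coh * |sin lag|)")
print(f"wPLI             = {wpli:.4f}   (exclusive: sign-consistent Im only)")
print(f"measured ImgCoh reduction: {100 * (1 - img / coh):.1f}%  "
      f"(analytic 100*(1-|sin phi|) = {imgcoh_attenuation(phi):.1f}%)")
print("\nAt near-zero lags the exclusive estimators penalise genuine "
      "synchrony, not just artefact -- the core trade-off this package "
      "quantifies.")
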