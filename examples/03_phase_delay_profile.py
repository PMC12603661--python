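"""Map near-zero phase-delay connectivity against Euclidean distance.

Signal leakage produces artefactual zero-lag coupling that decays with
distance; genuine zero-phase synchrony does not.  Pooling pair delays
across participants into distance bins and finding where the near-zero
proportion stops varying with distance locates the range where leakage is
negligible.  Here leakage is simulated in isolation (mixing width 20 mm)
so the detected knee reflects the mixing kernel alone.
"""

import warnings

from zerolag import (SyntheticCohortSpec, analytic_signal, bandpass_filter,
                     leakage_negligible_distance, proportion_vs_distance)
from zerolag.connectivity import phase_delay_matrix
from zerolag.synthetic import (make_geometry, make_structural_connectome,
                               simulate_epoch)

geometry = make_geometry(68, seed=1)
spec = SyntheticCohortSpec(leakage_sigma=20.0, coupling_strength=0.0,
                           homotopic_gain=0.0, zero_lag_fraction=0.0)
taus = []
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for p in range(12):
        connectome = make_structural_connectome(geometry, seed=100 + p)
        epoch = simulate_epoch(geometry, connectome, spec, band="alpha",
                               seed=900 + p)
        filtered = bandpass_filter(epoch, "alpha")
        taus.append(phase_delay_matrix(analytic_signal(filtered)).tau)

    profile = proportion_vs_distance(taus, geometry, bin_width_mm=10.0)
    plateau = leakage_negligible_distance(profile)

print("distance bin (mm)   near-zero proportion   pairs")
for lo, hi, pr, c in zip(profile.bin_edges[:-1], profile.bin_edges[1:],
                         profile.proportion, profile.counts):
    bar = "#" * int(40 * pr) if pr == pr else ""
    print(f"  {lo:5.0f}-{hi:3.0f}          {pr:6.3f}  {bar:<40s} {c}")
print(f"\nleakage negligible beyond: {plateau.distance_mm:.0f} mm")
print("Below that distance the near-zero proportion is inflated by the "
      "mixing; beyond it the profile sits flat at the chance level "
      "(19.1% of the circle lies within 0.3 rad of 0 or pi).")
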