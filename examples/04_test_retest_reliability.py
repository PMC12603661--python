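"""Edgewise test-retest reliability of matched estimator pairs.

Each participant contributes two epochs with identical coupling but
independent noise.  Edgewise ICC(2,1) quantifies absolute agreement of each
connection across the two epochs; homotopic (mirror-image, callosally
coupled) edges carry stable zero-lag synchrony, so inclusive estimators are
far more reliable there than their zero-phase-exclusive counterparts.
"""

import warnings

import numpy as np

from zerolag import SyntheticCohortSpec, reliability_by_band, simulate_cohort

spec = SyntheticCohortSpec(n_regions=16, n_participants=12,
                           epoch_seconds=10.0, seed=42)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    cohort = simulate_cohort(spec)
    results, summary = reliability_by_band(cohort, bands=("alpha",))

hp = cohort.geometry.homotopic_pairs()
hi = [p[0] for p in hp]
hj = [p[1] for p in hp]

print(summary.round(3).to_string(index=False))
print("\nmedian ICC on homotopic edges only:")
for r in results:
    kind = "inclusive" if r.method in ("coherence", "plv", "aec") else "exclusive"
    print(f"  {r.method:10s} ({kind})  {np.nanmedian(r.icc[hi, hj]):.3f}")
print("\nZero-phase-exclusive estimators suppress the stable homotopic "
      "zero-lag coupling, so the individual differences they measure there "
      "are mostly noise -- reliability collapses.")
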