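"""Structure-function concordance and the transmission-time mediation chain.

Stronger structural connections transmit faster (tract length / HMOA, a
conduction-speed proxy), so their functional phase delays sit closer to
zero -- exactly the delays zero-phase-exclusive estimators penalise.  This
script recovers that causal chain from simulated epochs: per-participant
concordance of each estimator with log streamline counts, the correlation
between phase-delay penalisation and streamline count, and a bootstrap
mediation of count -> transmission time -> penalisation.
"""

import warnings

import numpy as np

from zerolag import (SyntheticCohortSpec, analytic_signal, bandpass_filter,
                     mediation_bootstrap, penalisation_structure_correlation,
                     penalisation_value, simulate_cohort,
                     structure_function_concordance, transmission_time_proxy)
from zerolag.connectivity import build_matrices, phase_delay_matrix

spec = SyntheticCohortSpec(n_regions=68, n_participants=10,
                           epoch_seconds=10.0, seed=42)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    cohort = simulate_cohort(spec)

    iu = np.triu_indices(68, k=1)
    conc = {"coherence": [], "wpli": []}
    pen_rhos, x_all, m_all, y_all = [], [], [], []
    for p in range(cohort.n_participants):
        conn = cohort.connectomes[p]
        out, tau = build_matrices(cohort.epochs[p][0], "alpha",
                                  ("coherence", "wpli"))
        for method in conc:
            conc[method].append(structure_function_concordance(
                out[method].weights, conn.norm_log_count))
        pen = penalisation_value(tau.tau)
        pen_rhos.append(penalisation_structure_correlation(
            pen, conn.streamline_count))
        proxy = transmission_time_proxy(conn.median_length, conn.median_hmoa)
        sel = conn.connected[iu]
        x_all.append(conn.norm_log_count[iu][sel])
        m_all.append(proxy[iu][sel])
        y_all.append(pen[iu][sel])

    med = mediation_bootstrap(np.concatenate(x_all), np.concatenate(m_all),
                              np.concatenate(y_all), n_boot=1000, seed=0)

print("structure-function concordance (mean Spearman rho, alpha band):")
print(f"  coherence (inclusive): {np.mean(conc['coherence']):+.3f}")
print(f"  wPLI      (exclusive): {np.mean(conc['wpli']):+.3f}")
print(f"\npenalisation ~ streamline count: mean rho = {np.mean(pen_rhos):+.3f}")
print("\nmediation of count -> transmission-time proxy -> penalisation:")
print(f"  total effect c       = {med.c:+.3f}")
print(f"  direct effect c'     = {med.c_prime:+.3f}")
print(f"  indirect effect a*b  = {med.indirect:+.3f} "
      f"[95% CI {med.ci_low:+.3f}, {med.ci_high:+.3f}]")
print(f"  proportion mediated  = {med.proportion_mediated:.3f}")
print("\nA positive indirect effect with a CI excluding zero recovers the "
      "planted chain: strong tracts -> quick transmission -> near-zero "
      "delays -> penalised by exclusive estimators.")
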