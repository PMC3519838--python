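"""Inspect the spectral multiplier and MMI detection on one run.

The multiplier m estimates, from the top-k singular values of the data
matrix and the first-iteration objective, how far the optimal MSE lies
below MSE_1.  The first iteration whose MSE comes within an epsilon-band
of that estimate is MMI — the point where per-cluster stability checking
switches on.
"""

import warnings

from mmkmeans import (
    AlgoConfig,
    MixtureSpec,
    compute_multiplier,
    detect_mmi,
    generate_mixture,
    run_mmkmeans,
)

data, _ = generate_mixture(MixtureSpec(n=5000, d=50, k_true=10, seed=10))
config = AlgoConfig(k=10, seed=10)

with warnings.catch_warnings():
    warnings.simplefilter("ignore", UserWarning)
    partition, centroids, trace, mmi_state, records = run_mmkmeans(data, config)

mse1 = trace.records[0].mse
estimate = compute_multiplier(data, k=10, sse1=mse1 * data.n)
print(f"MSE_1 = {mse1:.2f}")
print(f"multiplier m = {estimate.m:.4f}  (spectral bound / first-iteration SSE)")
print(f"estimated optimal MSE = m * MSE_1 = {estimate.mse_l_est:.2f}")
print(f"final MSE = {trace.records[-1].mse:.2f}")
print(f"MMI detected online:  {mmi_state.mmi}")
print(f"MMI from trace rescan: {detect_mmi(trace, estimate, config).mmi}")
if records:
    stable = records[-1].stable
    print(f"clusters frozen at termination: {int(stable.sum())} of {config.k}")
# The offline rescan always reproduces the online detection.  When MMI
# fires, later iterations freeze stable clusters and skip their points'
# assignment scans, which is where the method saves distance evaluations.
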