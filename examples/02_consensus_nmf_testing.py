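"""Consensus NMF clustering and the beta likelihood-ratio test on one gene.

Works directly on a normalized APA proportion matrix (sites x replicates):
a gene with a real usage shift and a null gene are factorized 100 times
each, their co-clustering consensus matrices printed, and differential APA
tested via beta models of the pair frequencies.
"""

import numpy as np

from apadiff.betalrt import lrt_test
from apadiff.nmf import consensus_matrix, stability_score

prior = np.array([0, 0, 0, 1, 1, 1])  # 3 control, 3 treated replicates

# gene with a clear proximal shift: distal usage 0.9 -> 0.5 in treated
shifted = np.array([
    [0.10, 0.12, 0.08, 0.50, 0.52, 0.48],   # proximal site
    [0.90, 0.88, 0.92, 0.50, 0.48, 0.52],   # distal site
])
# null gene: all six replicates share the same usage, small jitter
rng = np.random.default_rng(0)
null = np.abs(np.array([[0.3], [0.7]]) + rng.normal(0, 0.02, (2, 6)))

for name, V in (("shifted gene", shifted), ("null gene", null)):
    cm = consensus_matrix(V, prior, ni=100, base_seed=1)
    res = lrt_test(cm, name)
    print(f"{name}: consensus matrix (upper triangle = co-clustering freq)")
    print(np.round(cm.cm, 2))
    print(f"  stability score = {stability_score(cm):.3f}  "
          f"(1 = every run reproduces the design, 0.5 = chance)")
    print(f"  LRT = {res.lrt_stat:.2f}, p = {res.p_value:.2e}")
    print()

print(
    "For the shifted gene, same-condition replicate pairs co-cluster in\n"
    "(nearly) every NMF run while cross-condition pairs rarely do, so the\n"
    "partitioned beta model fits far better than the pooled null and the\n"
    "LRT is large.  For the null gene the pair frequencies are homogeneous\n"
    "and the test finds nothing."
)
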