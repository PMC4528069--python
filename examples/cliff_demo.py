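"""The cliff test: a 5'-end pile-up versus a scattered truncation tail.

Constructs two clusters of 5' read start positions — one from a
transcript whose clones reach the true transcription start (a sharp
pile-up at coordinate 0), one from a 5'-truncated long mRNA (uniform
premature-termination ends only) — and scores both.
"""
import numpy as np

from fullorf.cliff import cliff_score
from fullorf.model import Cluster, PipelineConfig
from fullorf.simulate import (
    simulate_truncated_end_positions,
    simulate_tss_end_positions,
)

rng = np.random.default_rng(1)
config = PipelineConfig()

tss_ends = simulate_tss_end_positions(rng, transcript_len=1200, n_ends=40)
tss = cliff_score(
    Cluster(cluster_id="with_tss", consensus="A" * 1200,
            five_prime_end_positions=tss_ends),
    config,
)
trunc_ends = simulate_truncated_end_positions(rng, span=2300, n_ends=40)
trunc = cliff_score(
    Cluster(cluster_id="truncated", consensus="A" * 3000,
            five_prime_end_positions=trunc_ends),
    config,
)

for result in (tss, trunc):
    print(f"cluster {result.cluster_id}:")
    print(f"  Z={result.Z} peak window x={result.x}  "
          f"N100={result.N100} N1000={result.N1000}")
    if result.score and result.score > 0:
        print(f"  S_peak={result.S_peak:.3f} S_steep={result.S_steep:.3f} "
              f"score={result.score:.1f}  TSS estimate={result.tss_estimate}")
    else:
        print(f"  score={result.score}  (peak fraction below the "
              "cluster-size threshold)")
    verdict = "5'-complete" if result.passes else "not verified"
    print(f"  passes (score >= {config.cliff_min_score:g}): "
          f"{result.passes} -> {verdict}\n")
print("A score >= 10 is treated like an upstream in-frame stop codon:")
print("evidence that the cluster consensus contains the mRNA 5' end.")
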