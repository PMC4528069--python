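"""The cliff algorithm: transcription-start detection from 5' end pile-ups.

Reverse transcription runs 3'->5' and can terminate prematurely anywhere,
but never runs past the mRNA 5' end. A cluster containing the true start
of transcription therefore shows an abrupt spatial concentration — a
"cliff" — of 5' read start positions, whereas a 5'-truncated cluster shows
only a scattered tail. The test quantifies this with two sub-scores:

* ``S_peak`` — the fraction of 5' ends in the densest 100 bp window among
  all 5' ends in the 1 kb region starting at that window, gated by a
  cluster-size-dependent threshold 1/3 + (2/3)·e^(−log(Z−4)) that decays
  from 1.0 at the minimum eligible size Z=5 to 1/3 for very large clusters.
* ``S_steep`` — 2^(−1/m_steep), where m_steep (ends/bp) is the steepest
  gradient over any run of Nsteep consecutive 5' end positions inside the
  peak window; a perfectly coincident pile-up has m_steep = ∞ and scores 1.

The overall cliff score is S_peak × S_steep × 100; clusters scoring at or
above a configured minimum (default 10) are treated as if an upstream stop
codon verified the 5' end of the ORF.
"""
from __future__ import annotations

import math
from typing import Optional, Sequence

from .model import CliffResult, Cluster, PipelineConfig


def _decay(Z: int, log_base: float = 0.0) -> float:
    """e^(−log(Z−4)) with configurable log base (0 => natural log)."""
    if Z < 5:
        raise ValueError(f"cluster size Z={Z} below the minimum of 5")
    arg = Z - 4
    if log_base and log_base != math.e:
        return math.exp(-math.log(arg, log_base))
    return 1.0 / arg


def peak_threshold(Z: int, log_base: float = 0.0) -> float:
    """Minimum N100/N1000 for a cluster of Z 5' ends to qualify.

    Equals 1.0 at Z=5 and decays to 1/3 for very large clusters.
    """
    return 1.0 / 3.0 + (2.0 / 3.0) * _decay(Z, log_base)


def steep_count(Z: int, N1000: int, N100: int, log_base: float = 0.0) -> int:
    """Number of consecutive 5' ends used to measure cliff steepness.

    ceil(N1000 · (1/5 + (4/5)·e^(−log(Z−4)))), floored at 2 (a gradient
    needs at least two points) and capped at N100 so the run fits inside
    the peak window.
    """
    frac = 1.0 / 5.0 + (4.0 / 5.0) * _decay(Z, log_base)
    # tolerance keeps the ceiling from rounding up the vanishing decay
    # remainder at the asymptote (e.g. 100 x 0.20000001 must stay 20)
    n = max(2, math.ceil(N1000 * frac - 1e-6))
    return min(n, N100) if N100 >= 1 else n


def find_peak_window(
    end_positions: Sequence[int],
    window_bp: int = 100,
    step_bp: int = 50,
    scan_limit: Optional[int] = None,
) -> tuple[int, int]:
    """Start x of the 100 bp window holding the most 5' ends, and its count.

    The window slides in step_bp steps from position 0; ties break toward
    the smallest x. With ``scan_limit`` set, only window starts strictly
    below it are considered (the transcription start is sought in the 5'
    region of the cluster; a dense knot of premature-termination ends deep
    in the cluster body is not a TSS candidate).
    """
    if not end_positions:
        raise ValueError("no 5' end positions")
    positions = sorted(end_positions)
    last = positions[-1] if scan_limit is None else min(positions[-1], scan_limit - 1)
    best_x, best_n = 0, 0
    x = 0
    while x <= last:
        n = _count_in(positions, x, x + window_bp)
        if n > best_n:
            best_x, best_n = x, n
        x += step_bp
    return best_x, best_n


def count_region(
    end_positions: Sequence[int], x: int, region_bp: int = 1000
) -> int:
    """Number of 5' ends in the 1 kb region [x, x+region_bp)."""
    return _count_in(sorted(end_positions), x, x + region_bp)


def _count_in(sorted_positions: Sequence[int], lo: int, hi: int) -> int:
    import bisect

    return bisect.bisect_left(sorted_positions, hi) - bisect.bisect_left(
        sorted_positions, lo
    )


def steepest_gradient(
    window_positions: Sequence[int], Nsteep: int
) -> tuple[float, int]:
    """Steepest gradient over runs of Nsteep consecutive sorted positions.

    m_i = Nsteep / Δx_i with Δx_i the span of the i-th run; coincident
    positions give m = ∞. Ties between runs break toward the most 5' run,
    whose first position is the TSS estimate.
    """
    positions = sorted(window_positions)
    if len(positions) < Nsteep:
        raise ValueError(
            f"need at least Nsteep={Nsteep} positions, got {len(positions)}"
        )
    best_m = -1.0
    best_tss = positions[0]
    for i in range(len(positions) - Nsteep + 1):
        dx = positions[i + Nsteep - 1] - positions[i]
        m = math.inf if dx == 0 else Nsteep / dx
        if m > best_m:
            best_m = m
            best_tss = positions[i]
    return best_m, best_tss


def cliff_score(
    cluster: Cluster, config: Optional[PipelineConfig] = None
) -> CliffResult:
    """Run the full cliff computation for one cluster.

    Clusters with fewer than ``min_5p_ends`` sense-orientation 5' read
    starts are ineligible. Eligible clusters failing the size-dependent
    peak threshold score 0. The 1 kb region includes the peak window and
    is truncated at the consensus end, so S_peak <= 1 always.
    """
    config = config or PipelineConfig()
    ends = sorted(cluster.five_prime_end_positions)
    Z = len(ends)
    result = CliffResult(cluster_id=cluster.cluster_id, Z=Z, eligible=False)
    if Z < config.min_5p_ends:
        return result
    result.eligible = True
    x, N100 = find_peak_window(
        ends, config.window_bp, config.step_bp, scan_limit=config.region_bp
    )
    region = config.region_bp
    if cluster.consensus:
        region = min(region, max(1, len(cluster.consensus) - x))
    N1000 = count_region(ends, x, region)
    result.x, result.N100, result.N1000 = x, N100, N1000
    threshold = peak_threshold(Z, config.cliff_log_base)
    s_peak = N100 / N1000 if N1000 else 0.0
    if s_peak < threshold:
        result.score = 0.0
        result.passes = False
        return result
    Nsteep = steep_count(Z, N1000, N100, config.cliff_log_base)
    window = [p for p in ends if x <= p < x + config.window_bp]
    m_steep, tss = steepest_gradient(window, Nsteep)
    s_steep = 1.0 if math.isinf(m_steep) else math.exp(-math.log(2) / m_steep)
    result.Nsteep = Nsteep
    result.m_steep = m_steep
    result.S_peak = s_peak
    result.S_steep = s_steep
    result.score = s_peak * s_steep * 100.0
    result.tss_estimate = tss
    result.passes = result.score >= config.cliff_min_score
    return result
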