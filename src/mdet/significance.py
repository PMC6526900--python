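"""The motif-discovery driver: frequencies, null distribution, z-scores.

For each subgraph size k from 3 up to the configured maximum, the frequent
patterns of the target network are found with the frequency-pruned census,
the same census is run on N degree-preserving randomized networks, and each
frequent pattern's over-representation is scored as

    z = (f_real - mean(f_null)) / sd(f_null)

with the sample standard deviation.  A pattern is flagged unique when its
z-score reaches the uniqueness threshold; an empirical p-value
(1 + #{f_null >= f_real}) / (N + 1) is reported alongside but selection uses
the z-score only.  A pattern never reached by the census of a randomized
network contributes frequency 0 for that replicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

from .census import run_census
from .frequency import EXACT_MIS_LIMIT
from .graph import Graph
from .null_model import null_ensemble
from .tree import make_root


@dataclass
class Config:
    """Run parameters.

    ``freq_threshold`` below 1 is a fraction of the vertex count (rounded
    up); at 1 or above it is an absolute F2 count.  Defaults are the
    standard operating point: uniqueness threshold 2, frequency threshold
    5% of the number of nodes, 100 randomized networks.
    """

    k_max: int = 5
    freq_threshold: float = 0.05
    z_threshold: float = 2.0
    n_random: int = 100
    swaps_per_edge: float = 10.0
    seed: int = 0
    propagate: Literal["full", "disjoint"] = "disjoint"
    strict_threshold: bool = False
    exact_mis_limit: int = EXACT_MIS_LIMIT

    def __post_init__(self) -> None:
        if self.k_max < 3:
            raise ValueError("k_max must be >= 3")
        if self.n_random < 1:
            raise ValueError("n_random must be >= 1")
        if self.freq_threshold <= 0:
            raise ValueError("freq_threshold must be positive")
        if self.propagate not in ("full", "disjoint"):
            raise ValueError("propagate must be 'full' or 'disjoint'")

    def resolve_frequency(self, g: Graph) -> int:
        """The integer F2 threshold for a concrete network."""
        if self.freq_threshold < 1:
            return max(1, math.ceil(self.freq_threshold * g.n))
        return int(self.freq_threshold)


@dataclass
class MotifResult:
    """One frequent pattern's frequencies and significance."""

    canon_string: str
    k: int
    n_edges: int
    f_real: int
    null_freqs: list[int] = field(repr=False)
    f_bar_random: float = 0.0
    sigma_random: float = 0.0
    z: float = 0.0
    p: float = 1.0
    is_unique: bool = False


def z_score(f_real: float, null_freqs: list[int | float]) -> float:
    """Z-score of the real frequency against the null sample.

    Sample standard deviation (n-1 denominator).  When the null sample has
    zero spread: +inf above the mean, 0 at it, -inf below.
    """
    if not null_freqs:
        raise ValueError("null_freqs must be non-empty")
    n = len(null_freqs)
    mean = sum(null_freqs) / n
    if n > 1:
        var = sum((x - mean) ** 2 for x in null_freqs) / (n - 1)
        sd = math.sqrt(var)
    else:
        sd = 0.0
    if sd == 0.0:
        if f_real > mean:
            return math.inf
        if f_real < mean:
            return -math.inf
        return 0.0
    return (f_real - mean) / sd


def empirical_p(f_real: float, null_freqs: list[int | float]) -> float:
    return (1 + sum(1 for x in null_freqs if x >= f_real)) / (len(null_freqs) + 1)


def calculate_subgraph_frequency(
    g: Graph, k: int, F: int, config: Config | None = None
) -> list[tuple[str, int]]:
    """Frequent size-k patterns of ``g``: canonical strings with their F2
    counts, for patterns whose count passes the threshold ``F``."""
    cfg = config or Config(k_max=k)
    records = run_census(
        make_root(k),
        g,
        k,
        F,
        propagate=cfg.propagate,
        strict_threshold=cfg.strict_threshold,
        exact_mis_limit=cfg.exact_mis_limit,
    )
    passes = (lambda f2: f2 > F) if cfg.strict_threshold else (lambda f2: f2 >= F)
    return [
        (rec.node.canon_string, rec.f2) for rec in records if passes(rec.f2)
    ]


def find_motifs(g: Graph, config: Config) -> list[MotifResult]:
    """Full discovery run: frequent patterns of every size 3..k_max, null
    distributions from degree-preserving randomizations, z-scores.

    Deterministic for a fixed (network, config): replicate seeds derive from
    ``config.seed`` and the subgraph size.  Results are sorted by
    (k, descending z, canonical string).
    """
    F = config.resolve_frequency(g)
    results: list[MotifResult] = []

    def passes(f2: int) -> bool:
        return f2 > F if config.strict_threshold else f2 >= F

    for k in range(3, config.k_max + 1):
        records = run_census(
            make_root(k),
            g,
            k,
            F,
            propagate=config.propagate,
            strict_threshold=config.strict_threshold,
            exact_mis_limit=config.exact_mis_limit,
        )
        frequent = [rec for rec in records if passes(rec.f2)]
        if not frequent:
            continue
        nulls = null_ensemble(
            g, config.n_random, config.swaps_per_edge, seed=(config.seed * 31 + k) % 2**31
        )
        null_counts: list[dict[str, int]] = []
        for g_rand in nulls:
            rnd = run_census(
                make_root(k),
                g_rand,
                k,
                F,
                propagate=config.propagate,
                strict_threshold=config.strict_threshold,
                exact_mis_limit=config.exact_mis_limit,
            )
            null_counts.append({rec.node.canon_string: rec.f2 for rec in rnd})
        for rec in frequent:
            cs = rec.node.canon_string
            freqs = [nc.get(cs, 0) for nc in null_counts]
            z = z_score(rec.f2, freqs)
            mean = sum(freqs) / len(freqs)
            sd = 0.0
            if len(freqs) > 1:
                sd = math.sqrt(
                    sum((x - mean) ** 2 for x in freqs) / (len(freqs) - 1)
                )
            results.append(
                MotifResult(
                    canon_string=cs,
                    k=k,
                    n_edges=rec.node.n_edges,
                    f_real=rec.f2,
                    null_freqs=freqs,
                    f_bar_random=mean,
                    sigma_random=sd,
                    z=z,
                    p=empirical_p(rec.f2, freqs),
                    is_unique=z >= config.z_threshold,
                )
            )
    results.sort(key=lambda r: (r.k, -r.z, r.canon_string))
    return results
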