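"""Random signed-network ensembles and the attractor-count experiments.

Networks are drawn Erdos-Renyi style: every ordered pair (i, j) —
including i = j — independently carries an edge with probability
p = <k>/N, and each edge is inhibitory (-1) with probability ``r``,
activating (+1) otherwise.  The diagonal is not special-cased: self-edges
follow the same two-point sign distribution as every other edge.

The ensemble harness enumerates the singleton attractors of each sample
and records the attractor count NS together with search-effort counters.
Branch expansions (``nodes_expanded``) serve as the hardware-independent
cost measure; wall-clock seconds are logged per sample but are never the
quantity of interest.  Sampling is reproducible: each sample's generator
is seeded from (root seed, sample index), so results do not depend on
iteration order.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attractor_search import enumerate_singleton_attractors
from .network_model import SignedNetwork

__all__ = ["EnsembleConfig", "EnsembleResult", "sample_network", "run_ensemble"]


@dataclass(frozen=True)
class EnsembleConfig:
    """Parameters of a random-network ensemble.

    n_nodes
        Network size N.
    k_avg
        Average degree <k>; the edge probability is p = <k>/N.
    r
        Probability that an edge is inhibitory, in [0, 1].
    n_samples
        Number of networks to draw (M).
    seed
        Root seed; sample ``m`` uses the stream (seed, m).
    """

    n_nodes: int
    k_avg: float
    r: float
    n_samples: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(
                f"edge probability p = k_avg/N = {self.p:.3g} must lie in [0, 1]"
            )
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"inhibitory probability r = {self.r} must lie in [0, 1]")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    @property
    def p(self) -> float:
        return self.k_avg / self.n_nodes


def sample_network(cfg: EnsembleConfig, index: int = 0) -> SignedNetwork:
    """Draw sample ``index`` of the ensemble (deterministic in (seed, index))."""
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, index)))
    n = cfg.n_nodes
    mask = rng.random((n, n)) < cfg.p
    signs = np.where(rng.random((n, n)) < cfg.r, -1, 1).astype(np.int8)
    return SignedNetwork(a=(mask * signs).astype(np.int8))


@dataclass
class EnsembleResult:
    """Per-sample records plus attractor-count aggregates.

    ``records`` has one row per sample with columns ``sample``,
    ``n_attractors`` (NS), ``nodes_expanded``, ``seconds`` and
    ``capped``.  Aggregates (avS / MinS / MaxS, mean seconds) are
    computed over all samples; capped samples — whose NS is a lower
    bound — are flagged in the records and counted in ``n_capped``
    rather than dropped.
    """

    config: EnsembleConfig
    records: pd.DataFrame = field(repr=False)

    @property
    def av_s(self) -> float:
        return float(self.records["n_attractors"].mean())

    @property
    def min_s(self) -> int:
        return int(self.records["n_attractors"].min())

    @property
    def max_s(self) -> int:
        return int(self.records["n_attractors"].max())

    @property
    def av_seconds(self) -> float:
        return float(self.records["seconds"].mean())

    @property
    def n_capped(self) -> int:
        return int(self.records["capped"].sum())

    def summary(self) -> dict:
        return {
            "N": self.config.n_nodes,
            "k_avg": self.config.k_avg,
            "r": self.config.r,
            "M": self.config.n_samples,
            "avS": self.av_s,
            "MinS": self.min_s,
            "MaxS": self.max_s,
            "av_seconds": self.av_seconds,
            "n_capped": self.n_capped,
        }


def run_ensemble(
    cfg: EnsembleConfig,
    max_attractors: int | None = 1_000_000,
    progress: bool = False,
) -> EnsembleResult:
    """Enumerate singleton attractors for every sample of the ensemble.

    ``max_attractors`` is a per-sample guard: sparse networks can have
    astronomically many fixed points (an edgeless network has 2^N), so a
    sample hitting the cap is flagged ``capped`` and its NS reported as
    the (lower-bound) count reached.
    """
    iterator = range(cfg.n_samples)
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm

            iterator = tqdm(iterator, desc="ensemble")
        except ImportError:
            pass
    rows = []
    for m in iterator:
        net = sample_network(cfg, m)
        t0 = time.perf_counter()
        attractors, stats = enumerate_singleton_attractors(net, max_attractors)
        elapsed = time.perf_counter() - t0
        rows.append(
            {
                "sample": m,
                "n_attractors": len(attractors),
                "nodes_expanded": stats.nodes_expanded,
                "seconds": elapsed,
                "capped": stats.capped,
            }
        )
    return EnsembleResult(config=cfg, records=pd.DataFrame(rows))
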