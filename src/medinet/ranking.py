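"""Per-sample bidirectional diffusion scores, ranks, and cohort aggregation."""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ParameterError, PipelineError, ValidationError
from .events import SampleEvents
from .network import DiffusionOperator

__all__ = [
    "SampleScore",
    "MediatorRanking",
    "sample_scores",
    "rank_genes",
    "aggregate_ranks",
    "select_top_fraction",
]

log = logging.getLogger(__name__)

COMBINE_METHODS = ("product", "sum", "forward_only")
AGGREGATE_METHODS = ("median", "mean", "sum")


@dataclass(frozen=True)
class SampleScore:
    """Forward/backward diffusion means and the combined per-node score."""

    sample: str
    f: np.ndarray  # forward score (mean of F_fwd rows at upstream events)
    b: np.ndarray  # backward score (mean of F_rev rows at downstream events)
    c: np.ndarray  # combined score
    r: np.ndarray  # ranks of c, 1 = best, ties averaged


def sample_scores(
    ffwd: DiffusionOperator,
    frev: DiffusionOperator,
    events: SampleEvents,
    combine: str = "product",
) -> SampleScore:
    """Score every node of the network for one sample.

    f is the mean forward-diffusion row over upstream events; b the mean
    reverse-diffusion row over downstream events. The combined score demands
    both signals by default (element-wise product).
    """
    if combine not in COMBINE_METHODS:
        raise ParameterError(f"unknown combination method {combine!r}")
    if not events.scoreable:
        raise ValidationError(f"sample {events.sample} has empty event sets")
    nodes = ffwd.nodes
    index = {n: k for k, n in enumerate(nodes)}
    up = [index[n] for n in sorted(events.upstream)]
    down = [index[n] for n in sorted(events.downstream)]
    f = ffwd.rows_mean(up)
    b = frev.rows_mean(down)
    if combine == "product":
        c = f * b
    elif combine == "sum":
        c = f + b
    else:
        c = f.copy()
    return SampleScore(events.sample, f, b, c, rank_genes(c))


def rank_genes(c: np.ndarray) -> np.ndarray:
    """Descending-score ranks (1 = best); ties get the average spanned rank."""
    c = np.asarray(c, dtype=float)
    if np.isnan(c).any():
        raise ParameterError("scores contain NaN")
    return rankdata(-c, method="average")


@dataclass(frozen=True)
class MediatorRanking:
    """Cohort-level aggregation of per-sample rank vectors."""

    nodes: tuple[str, ...]
    R: np.ndarray  # aggregated rank statistic per node (smaller = better)
    mean_score: np.ndarray  # mean combined score, used to break ties
    order: tuple[str, ...]  # total cohort ordering, best first
    method: str
    n_samples: int

    def rank_table(self) -> pd.DataFrame:
        pos = {n: k for k, n in enumerate(self.order)}
        return pd.DataFrame(
            {
                "gene": self.nodes,
                "aggregated_rank": self.R,
                "mean_score": self.mean_score,
                "cohort_position": [pos[n] + 1 for n in self.nodes],
            }
        ).sort_values("cohort_position", ignore_index=True)


def aggregate_ranks(
    scores: Sequence[SampleScore],
    nodes: tuple[str, ...],
    method: str = "median",
) -> MediatorRanking:
    """Aggregate per-sample rank vectors into one cohort ranking.

    Ties in the aggregated statistic are broken by mean combined score
    (descending), then node id.
    """
    if method not in AGGREGATE_METHODS:
        raise ParameterError(f"unknown aggregation method {method!r}")
    if len(scores) == 0:
        raise PipelineError("no scoreable samples to aggregate")
    mat = np.vstack([s.r for s in scores])
    if mat.shape[1] != len(nodes):
        raise ValidationError("rank vectors do not match the node set")
    if method == "median":
        agg = np.median(mat, axis=0)
    elif method == "mean":
        agg = mat.mean(axis=0)
    else:
        agg = mat.sum(axis=0)
    mean_score = np.vstack([s.c for s in scores]).mean(axis=0)
    order = sorted(range(len(nodes)), key=lambda k: (agg[k], -mean_score[k], nodes[k]))
    return MediatorRanking(
        tuple(nodes),
        agg,
        mean_score,
        tuple(nodes[k] for k in order),
        method,
        len(scores),
    )


def select_top_fraction(
    ranking: MediatorRanking,
    fraction: float = 0.05,
    qvalues: Mapping[str, float] | None = None,
    q_alpha: float = 0.05,
) -> list[str]:
    """Top ceil(fraction * N) nodes of the cohort order, FDR-filtered.

    Nodes with q > ``q_alpha`` are dropped from the candidate set; the cohort
    order of the survivors is preserved.
    """
    if not (0.0 < fraction <= 1.0):
        raise ParameterError(f"fraction must lie in (0, 1], got {fraction}")
    n_top = math.ceil(fraction * len(ranking.nodes))
    candidates = list(ranking.order[:n_top])
    if qvalues is None:
        return candidates
    return [g for g in candidates if qvalues.get(g, 1.0) <= q_alpha]
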