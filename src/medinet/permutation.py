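"""Permutation null model, empirical p-values, and BH FDR correction."""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import GenerationError, ParameterError, ValidationError
from .events import SampleEvents
from .network import DiffusionOperator, DirectedNetwork
from .ranking import MediatorRanking, aggregate_ranks, sample_scores

__all__ = [
    "PermutationResult",
    "permute_events",
    "empirical_pvalues",
    "bh_fdr",
    "run_permutation_test",
]

log = logging.getLogger(__name__)


def _draw(rng: np.random.Generator, pool: np.ndarray, size: int) -> np.ndarray:
    if size > pool.size:
        raise GenerationError(
            f"cannot draw {size} labels from {pool.size} eligible nodes"
        )
    if size == 0:
        return np.empty(0, dtype=int)
    return rng.choice(pool, size=size, replace=False)


def permute_events(
    events: SampleEvents, net: DirectedNetwork, rng: np.random.Generator
) -> SampleEvents:
    """Relabel each event category onto uniform random eligible nodes.

    Mutated genes and downstream genes are redrawn among gene nodes, DE
    miRNAs among miRNA nodes; category sizes are preserved exactly.
    """
    genes = net.gene_indices()
    mirnas = net.mirna_indices()
    mut = _draw(rng, genes, len(events.mutated_genes))
    mir = _draw(rng, mirnas, len(events.de_mirnas))
    down = _draw(rng, genes, len(events.downstream))
    return SampleEvents(
        events.sample,
        frozenset(net.nodes[k] for k in mut),
        frozenset(net.nodes[k] for k in mir),
        frozenset(net.nodes[k] for k in down),
    )


def empirical_pvalues(
    observed: np.ndarray, null_runs: Sequence[np.ndarray]
) -> np.ndarray:
    """Pseudocount empirical p per node: (1 + #{null <= observed}) / (1 + n).

    Both statistics are aggregated ranks, so smaller is better and a null run
    beats the observation when its value is less than or equal.
    """
    if len(null_runs) == 0:
        raise ParameterError("at least one null run is required")
    observed = np.asarray(observed, dtype=float)
    exceed = np.zeros(observed.shape[0], dtype=int)
    for run in null_runs:
        run = np.asarray(run, dtype=float)
        if run.shape != observed.shape:
            raise ValidationError("null run does not match the observed node set")
        exceed += run <= observed
    return (1.0 + exceed) / (1.0 + len(null_runs))


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p must be a non-empty 1-d vector")
    if np.any((p <= 0) | (p > 1)) or np.isnan(p).any():
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(adjusted, 1.0)
    return q


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of the event-relabeling permutation test."""

    nodes: tuple[str, ...]
    n_perm: int
    exceed_counts: np.ndarray
    p_emp: np.ndarray
    q: np.ndarray
    seed: int

    def qvalues(self) -> dict[str, float]:
        return dict(zip(self.nodes, self.q))


def run_permutation_test(
    ffwd: DiffusionOperator,
    frev: DiffusionOperator,
    events_list: Sequence[SampleEvents],
    observed: MediatorRanking,
    net: DirectedNetwork,
    n_perm: int = 10_000,
    seed: int = 0,
    combine: str = "product",
    method: str = "median",
    progress_every: int = 100,
) -> PermutationResult:
    """Recompute the cohort ranking under event relabeling ``n_perm`` times.

    Diffusion operators are reused across permutations; only the event sets
    change. The result is bit-reproducible for a given seed.
    """
    if n_perm < 1:
        raise ParameterError(f"n_perm must be >= 1, got {n_perm}")
    rng = np.random.default_rng(seed)
    scoreable = [ev for ev in events_list if ev.scoreable]
    exceed = np.zeros(len(observed.nodes), dtype=int)
    for rep in range(n_perm):
        null_scores = []
        for ev in scoreable:
            perm = permute_events(ev, net, rng)
            assert len(perm.mutated_genes) == len(ev.mutated_genes)
            assert len(perm.de_mirnas) == len(ev.de_mirnas)
            assert len(perm.downstream) == len(ev.downstream)
            null_scores.append(sample_scores(ffwd, frev, perm, combine))
        null_rank = aggregate_ranks(null_scores, observed.nodes, method)
        exceed += null_rank.R <= observed.R
        if progress_every and (rep + 1) % progress_every == 0:
            log.info("permutation %d / %d", rep + 1, n_perm)
    p_emp = (1.0 + exceed) / (1.0 + n_perm)
    return PermutationResult(
        observed.nodes, n_perm, exceed, p_emp, bh_fdr(p_emp), seed
    )
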