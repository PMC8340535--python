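"""End-to-end orchestration: tables -> events -> diffusion -> ranking -> FDR."""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import PipelineError
from .events import (
    DifferentialTable,
    MutationRecord,
    SampleEvents,
    build_sample_events,
    collapse_phosphosites,
    combine_downstream,
    filter_somatic_variants,
)
from .network import (
    DiffusionOperator,
    DirectedNetwork,
    insulated_diffusion,
    largest_scc,
    row_normalize,
)
from .permutation import PermutationResult, run_permutation_test
from .ranking import (
    MediatorRanking,
    aggregate_ranks,
    sample_scores,
    select_top_fraction,
)

__all__ = ["PipelineResult", "prepare_events", "run_pipeline", "write_results"]

log = logging.getLogger(__name__)

_EMPTY = DifferentialTable(
    "protein", "_empty", pd.DataFrame(columns=["feature", "log2fc", "padj", "detected"])
)


@dataclass(frozen=True)
class PipelineResult:
    network: DirectedNetwork  # the SCC actually scored
    events: list[SampleEvents]
    ranking: MediatorRanking
    permutation: PermutationResult | None
    mediators: list[str]
    config: RunConfig


def prepare_events(
    net: DirectedNetwork,
    mutations: dict[str, list[MutationRecord]],
    tables: dict[str, dict[str, DifferentialTable]],
    cfg: RunConfig,
) -> list[SampleEvents]:
    """Filter variants, merge downstream layers, and build per-sample events."""
    events = []
    for sample in sorted(tables):
        layers = tables[sample]
        mrna = layers["mrna"]
        mirna = layers["mirna"]
        protein = layers.get("protein", _EMPTY)
        phospho = layers.get("phosphosite")
        if phospho is not None and len(phospho.data):
            phos_sig = collapse_phosphosites(phospho, cfg.alpha)
            phos_det = set(phospho.data["gene"].astype(str).str.strip())
        else:
            phos_sig, phos_det = set(), set()
        downstream = combine_downstream(mrna, protein, phos_sig, phos_det, cfg.alpha)
        kept = filter_somatic_variants(mutations.get(sample, []))
        events.append(
            build_sample_events(kept, mirna, downstream, sample, net, cfg.alpha)
        )
    return events


def run_pipeline(
    net: DirectedNetwork,
    mutations: dict[str, list[MutationRecord]],
    tables: dict[str, dict[str, DifferentialTable]],
    cfg: RunConfig,
) -> PipelineResult:
    """Score, rank, aggregate and (optionally) permutation-test a cohort.

    Set ``cfg.n_perm = 0`` to skip the permutation test; the mediator set is
    then the unfiltered top fraction.
    """
    scc = largest_scc(net)
    if scc.n_nodes < 2:
        raise PipelineError("largest SCC has fewer than 2 nodes; nothing to score")
    w_fwd = row_normalize(scc, cfg.normalization)
    w_rev = row_normalize(scc.reverse(), cfg.normalization)
    f_fwd = insulated_diffusion(w_fwd, cfg.beta)
    f_rev = insulated_diffusion(w_rev, cfg.beta)

    events = prepare_events(scc, mutations, tables, cfg)
    scoreable = [ev for ev in events if ev.scoreable]
    if not scoreable:
        raise PipelineError("no scoreable samples in the cohort")
    if len(scoreable) < len(events):
        log.warning("%d samples dropped as unscoreable", len(events) - len(scoreable))

    scores = [sample_scores(f_fwd, f_rev, ev, cfg.combine) for ev in scoreable]
    ranking = aggregate_ranks(scores, scc.nodes, cfg.aggregation)

    perm = None
    qvalues = None
    if cfg.n_perm > 0:
        perm = run_permutation_test(
            f_fwd,
            f_rev,
            scoreable,
            ranking,
            scc,
            n_perm=cfg.n_perm,
            seed=cfg.seed,
            combine=cfg.combine,
            method=cfg.aggregation,
        )
        qvalues = perm.qvalues()
    mediators = select_top_fraction(ranking, cfg.fraction, qvalues, cfg.q_alpha)
    return PipelineResult(scc, events, ranking, perm, mediators, cfg)


def dysregulation_matrix(
    mediators: list[str],
    tables: dict[str, dict[str, DifferentialTable]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per (gene, sample, layer) +1/-1/0 display matrix for the mediator list."""
    samples = sorted(tables)
    cols = {}
    for sample in samples:
        layers = tables[sample]
        for layer in ("mrna", "protein", "phosphosite"):
            table = layers.get(layer)
            signs = {}
            if table is not None and len(table.data):
                d = table.data
                sig = d[d["detected"].astype(bool) & (d["padj"] < alpha)]
                key = "gene" if layer == "phosphosite" else "feature"
                for _, row in sig.iterrows():
                    g = str(row[key]).strip()
                    signs[g] = 1 if row["log2fc"] > 0 else -1
            cols[(layer, sample)] = [signs.get(g, 0) for g in mediators]
    out = pd.DataFrame(cols, index=mediators)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["layer", "sample"])
    return out


def write_results(
    result: PipelineResult,
    tables: dict[str, dict[str, DifferentialTable]],
    out_dir: str | Path,
) -> None:
    """Write ranking TSV, mediator TSV, display matrix, and a JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nodes = result.ranking.nodes
    up_count = {n: 0 for n in nodes}
    down_count = {n: 0 for n in nodes}
    for ev in result.events:
        for n in ev.upstream:
            up_count[n] += 1
        for n in ev.downstream:
            down_count[n] += 1
    perm = result.permutation
    p_emp = dict(zip(nodes, perm.p_emp)) if perm else {}
    q = perm.qvalues() if perm else {}
    table = result.ranking.rank_table()
    table["p_emp"] = [p_emp.get(g, np.nan) for g in table["gene"]]
    table["q"] = [q.get(g, np.nan) for g in table["gene"]]
    table["n_samples_up"] = [up_count[g] for g in table["gene"]]
    table["n_samples_down"] = [down_count[g] for g in table["gene"]]
    table.to_csv(out / "ranking.tsv", sep="\t", index=False)
    table[table["gene"].isin(set(result.mediators))].to_csv(
        out / "mediators.tsv", sep="\t", index=False
    )
    if result.mediators:
        dysregulation_matrix(result.mediators, tables, result.config.alpha).to_csv(
            out / "mediator_matrix.tsv", sep="\t"
        )
    summary = {
        "n_nodes": len(nodes),
        "n_samples": result.ranking.n_samples,
        "n_mediators": len(result.mediators),
        "mediators": result.mediators,
        "n_perm": perm.n_perm if perm else 0,
        "seed": result.config.seed,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "config.yaml").write_text(result.config.to_yaml())
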