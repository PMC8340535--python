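"""Synthetic multi-omics cohorts with planted mediators and full ground truth.

The generator plants mediator genes whose <=2-hop in-neighborhood receives the
upstream events (shared driver mutations, DE miRNAs) and whose <=2-hop
out-neighborhood receives the downstream events, so convergence through the
mediators is topological, not label-assigned. A configurable fraction of
events is placed uniformly at random as noise.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import GenerationError, ParameterError, ValidationError
from .events import DifferentialTable, MutationRecord
from .network import DirectedNetwork, largest_scc
from .ranking import MediatorRanking

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_network",
    "simulate_cohort",
    "recovery_metrics",
    "write_cohort",
    "load_cohort",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Generator knobs. Scales default to ~1/4 of the study's per-sample counts."""

    n_samples: int = 12
    n_genes: int = 2000
    n_mirnas: int = 80
    mean_degree: float = 6.0
    n_planted_mediators: int = 10
    n_shared_drivers: int = 2
    passengers_per_sample: int = 13
    de_mirna_per_sample: int = 27
    downstream_per_sample: int = 250
    noise_fraction: float = 0.3
    beta: float = 0.4
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self):
        counts = {
            "n_samples": self.n_samples,
            "n_genes": self.n_genes,
            "n_mirnas": self.n_mirnas,
            "n_planted_mediators": self.n_planted_mediators,
            "n_shared_drivers": self.n_shared_drivers,
            "passengers_per_sample": self.passengers_per_sample,
            "de_mirna_per_sample": self.de_mirna_per_sample,
            "downstream_per_sample": self.downstream_per_sample,
        }
        for name, v in counts.items():
            if v < 0:
                raise ParameterError(f"{name} must be non-negative, got {v}")
        if not (0.0 <= self.noise_fraction <= 1.0):
            raise ParameterError("noise_fraction must lie in [0, 1]")
        if not (0.0 < self.beta <= 1.0):
            raise ParameterError("beta must lie in (0, 1]")
        if self.seed is None:
            raise ParameterError("seed is mandatory")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth serialized alongside a generated cohort."""

    mediators: tuple[str, ...]
    drivers: tuple[str, ...]
    upstream: Mapping[str, tuple[str, ...]]
    downstream: Mapping[str, tuple[str, ...]]
    config: dict

    def __post_init__(self):
        if set(self.mediators) & set(self.drivers):
            raise ValidationError("planted mediators must be disjoint from drivers")

    def to_json(self) -> str:
        return json.dumps(
            {
                "mediators": list(self.mediators),
                "drivers": list(self.drivers),
                "upstream": {k: list(v) for k, v in self.upstream.items()},
                "downstream": {k: list(v) for k, v in self.downstream.items()},
                "config": self.config,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            tuple(d["mediators"]),
            tuple(d["drivers"]),
            {k: tuple(v) for k, v in d["upstream"].items()},
            {k: tuple(v) for k, v in d["downstream"].items()},
            d["config"],
        )


def _gene_name(k: int) -> str:
    return f"G{k:05d}"


def _mirna_name(k: int) -> str:
    return f"miR-{k + 1:04d}"


def generate_network(cfg: SimulationConfig, max_attempts: int = 10) -> DirectedNetwork:
    """Random directed gene graph with miRNA nodes wired into its giant SCC.

    Gene-gene edges follow a directed Erdos-Renyi model with the configured
    mean out-degree; each miRNA receives one incoming edge and sends several
    outgoing edges into the SCC so it survives SCC reduction.
    """
    for attempt in range(max_attempts):
        rng = np.random.default_rng((cfg.seed, 0, attempt))
        n = cfg.n_genes
        p = min(1.0, cfg.mean_degree / max(n - 1, 1))
        adj = rng.random((n, n)) < p
        np.fill_diagonal(adj, False)
        genes = [_gene_name(k) for k in range(n)]
        pairs = [
            (genes[i], genes[j], "regulation") for i, j in zip(*np.nonzero(adj))
        ]
        gene_net = DirectedNetwork.from_edge_list(pairs) if pairs else None
        if gene_net is None:
            continue
        scc_nodes = set(largest_scc(gene_net).nodes)
        if len(scc_nodes) < 0.9 * n:
            log.info(
                "attempt %d: SCC holds %d / %d genes, retrying", attempt, len(scc_nodes), n
            )
            continue
        scc_list = sorted(scc_nodes)
        for k in range(cfg.n_mirnas):
            m = _mirna_name(k)
            n_targets = int(rng.integers(2, 6))
            targets = rng.choice(len(scc_list), size=min(n_targets, len(scc_list)), replace=False)
            for t in targets:
                pairs.append((m, scc_list[t], "mirna_target"))
            src = int(rng.integers(len(scc_list)))
            pairs.append((scc_list[src], m, "regulation"))
        return DirectedNetwork.from_edge_list(pairs)
    raise GenerationError(
        f"could not grow an SCC covering 90% of {cfg.n_genes} genes in {max_attempts} attempts"
    )


def _two_hop(adj: sp.csr_matrix) -> sp.csr_matrix:
    """Reachability within one or two forward hops (diagonal removed)."""
    a = (adj > 0).astype(np.int32)
    r = ((a + a @ a) > 0).tolil()
    r.setdiag(False)
    r = r.tocsr()
    r.eliminate_zeros()
    return r


def _padj(rng: np.random.Generator, significant: bool, alpha: float) -> float:
    if significant:
        return float(rng.uniform(1e-8, alpha * 0.8))
    return float(rng.uniform(alpha, 1.0))


def simulate_cohort(
    net: DirectedNetwork, cfg: SimulationConfig
) -> tuple[dict[str, list[MutationRecord]], dict[str, dict[str, DifferentialTable]], SyntheticTruth]:
    """Emit per-sample mutation and differential tables plus ground truth.

    Returns ``(mutations, tables, truth)`` where ``mutations[sample]`` is a
    record list and ``tables[sample][layer]`` a :class:`DifferentialTable`.
    """
    rng = np.random.default_rng((cfg.seed, 1))
    scc = largest_scc(net)
    nodes = scc.nodes
    gene_idx = scc.gene_indices()
    mirna_idx = scc.mirna_indices()
    if cfg.n_planted_mediators > gene_idx.size:
        raise GenerationError("more planted mediators requested than SCC genes")

    adj = scc.adjacency()
    a1 = (adj > 0).tocsr()
    fwd2 = _two_hop(adj)
    rev1 = (adj.T > 0).tocsr()
    rev2 = _two_hop(adj.T.tocsr())

    mirna_set = set(mirna_idx.tolist())
    gene_set = set(gene_idx.tolist())

    # mediators need a real in- and out-neighborhood for planting
    eligible = [
        k
        for k in gene_idx
        if len(set(a1[k].indices) & gene_set) >= 3
        and len(set(rev1[k].indices) & mirna_set) >= 1
    ]
    if len(eligible) < cfg.n_planted_mediators:
        raise GenerationError(
            f"only {len(eligible)} genes have neighborhoods large enough for planting"
        )
    mediators = sorted(
        rng.choice(eligible, size=cfg.n_planted_mediators, replace=False).tolist()
    )
    med_set = set(mediators)

    # one- and two-hop event pools per mediator (one-hop carries most signal)
    down1 = {m: sorted(set(a1[m].indices) & gene_set - med_set) for m in mediators}
    down2 = {m: sorted(set(fwd2[m].indices) & gene_set - med_set) for m in mediators}
    mir1 = {m: sorted(set(rev1[m].indices) & mirna_set) for m in mediators}
    mir2 = {m: sorted(set(rev2[m].indices) & mirna_set) for m in mediators}

    # shared drivers: greedy cover of mediators reachable within two hops
    upstream_pool = sorted(
        set().union(*(set(rev2[m].indices) for m in mediators)) & gene_set - med_set
    )
    if cfg.n_shared_drivers > len(upstream_pool):
        raise GenerationError(
            f"upstream neighborhood too small for {cfg.n_shared_drivers} shared drivers"
        )
    coverage = {g: set(fwd2[g].indices) & med_set for g in upstream_pool}
    drivers: list[int] = []
    uncovered = set(mediators)
    for _ in range(cfg.n_shared_drivers):
        best = max(
            upstream_pool,
            key=lambda g: (len(coverage[g] & uncovered), len(coverage[g]), -g),
        )
        drivers.append(best)
        uncovered -= coverage[best]
        upstream_pool = [g for g in upstream_pool if g != best]
    drivers = sorted(drivers)

    # private passengers: disjoint across samples, never drivers or mediators
    passenger_pool = sorted(gene_set - set(drivers) - set(mediators))
    need = cfg.passengers_per_sample * cfg.n_samples
    if need > len(passenger_pool):
        raise GenerationError("not enough genes for disjoint private passengers")
    passenger_draw = rng.choice(passenger_pool, size=need, replace=False)

    samples = [f"S{j + 1:02d}" for j in range(cfg.n_samples)]
    mutations: dict[str, list[MutationRecord]] = {}
    tables: dict[str, dict[str, DifferentialTable]] = {}
    truth_up: dict[str, tuple[str, ...]] = {}
    truth_down: dict[str, tuple[str, ...]] = {}

    all_gene_names = [nodes[k] for k in gene_idx]
    all_mirna_names = [nodes[k] for k in mirna_idx]

    def planted_draw(pool1, pool2, full_pool, size):
        """(1-noise)*size events drawn round-robin from each mediator's own
        neighborhood (one-hop preferred), the rest uniform noise."""
        n_signal = int(round((1.0 - cfg.noise_fraction) * size))
        queues = []
        for m in mediators:
            q1, q2 = list(pool1[m]), [x for x in pool2[m] if x not in set(pool1[m])]
            rng.shuffle(q1)
            rng.shuffle(q2)
            queues.append(q1 + q2)
        picked: set[int] = set()
        progress = True
        while len(picked) < n_signal and progress:
            progress = False
            for q in queues:
                while q:
                    x = q.pop(0)
                    if x not in picked:
                        picked.add(x)
                        progress = True
                        break
                if len(picked) >= n_signal:
                    break
        remainder = sorted(set(full_pool) - picked)
        n_noise = min(size - len(picked), len(remainder))
        if n_noise > 0:
            picked |= set(rng.choice(remainder, size=n_noise, replace=False).tolist())
        return sorted(picked)

    for j, sample in enumerate(samples):
        passengers = passenger_draw[
            j * cfg.passengers_per_sample : (j + 1) * cfg.passengers_per_sample
        ].tolist()
        mutated = sorted(drivers + passengers)
        de_mir = planted_draw(mir1, mir2, mirna_idx.tolist(), cfg.de_mirna_per_sample)
        down = planted_draw(down1, down2, sorted(gene_set - med_set), cfg.downstream_per_sample)

        mutations[sample] = [
            MutationRecord(
                tumor_sample=sample,
                normal_sample=f"{sample}_normal",
                chrom=str(int(rng.integers(1, 20))),
                pos=int(rng.integers(1, 150_000_000)),
                ref="C",
                alt="A",
                gene=nodes[g],
                effect="frameshift_variant" if g in drivers else "missense_variant",
                depth_tumor=int(rng.integers(40, 150)),
                vaf_tumor=float(rng.uniform(0.10, 0.45)),
                depth_normal=int(rng.integers(10, 100)),
                vaf_normal=0.0,
                pon_count=0,
            )
            for g in mutated
        ]

        # miRNA layer: every miRNA detected, events significant
        de_mir_names = {nodes[k] for k in de_mir}
        mir_rows = [
            {
                "feature": name,
                "log2fc": float(rng.normal(0, 1)) + (2.0 if name in de_mir_names else 0.0),
                "padj": _padj(rng, name in de_mir_names, cfg.alpha),
                "detected": True,
            }
            for name in all_mirna_names
        ]

        # downstream layers: each event gene is expressed through one route
        down_names = {nodes[k] for k in down}
        routes = {
            g: ("protein", "phospho", "rna")[int(rng.choice(3, p=(0.4, 0.2, 0.4)))]
            for g in down_names
        }
        rna_rows, prot_rows, phos_rows = [], [], []
        for name in all_gene_names:
            route = routes.get(name)
            rna_sig = route == "rna"
            rna_rows.append(
                {
                    "feature": name,
                    "log2fc": float(rng.normal(0, 1)) + (2.5 if rna_sig else 0.0),
                    "padj": _padj(rng, rna_sig, cfg.alpha),
                    "detected": True,
                }
            )
            if route == "protein":
                prot_rows.append(
                    {
                        "feature": name,
                        "log2fc": float(rng.normal(2.0, 0.5)),
                        "padj": _padj(rng, True, cfg.alpha),
                        "detected": True,
                    }
                )
            elif route is None and rng.random() < 0.3:
                # detected but unchanged protein (must not enter downstream)
                prot_rows.append(
                    {
                        "feature": name,
                        "log2fc": float(rng.normal(0, 0.3)),
                        "padj": _padj(rng, False, cfg.alpha),
                        "detected": True,
                    }
                )
            if route == "phospho":
                n_sites = int(rng.integers(1, 6))
                sig_site = int(rng.integers(n_sites))
                for s in range(n_sites):
                    phos_rows.append(
                        {
                            "feature": f"{name}_S{s + 1}",
                            "gene": name,
                            "log2fc": float(rng.normal(0, 1))
                            + (2.0 if s == sig_site else 0.0),
                            "padj": _padj(rng, s == sig_site, cfg.alpha),
                            "detected": True,
                        }
                    )
        phos_cols = ["feature", "gene", "log2fc", "padj", "detected"]
        tables[sample] = {
            "mrna": DifferentialTable("mrna", sample, pd.DataFrame(rna_rows)),
            "mirna": DifferentialTable("mirna", sample, pd.DataFrame(mir_rows)),
            "protein": DifferentialTable(
                "protein",
                sample,
                pd.DataFrame(prot_rows, columns=["feature", "log2fc", "padj", "detected"]),
            ),
            "phosphosite": DifferentialTable(
                "phosphosite", sample, pd.DataFrame(phos_rows, columns=phos_cols)
            ),
        }
        truth_up[sample] = tuple(sorted({nodes[g] for g in mutated} | de_mir_names))
        truth_down[sample] = tuple(sorted(down_names))

    truth = SyntheticTruth(
        tuple(nodes[m] for m in mediators),
        tuple(nodes[d] for d in drivers),
        truth_up,
        truth_down,
        cfg.to_dict(),
    )
    return mutations, tables, truth


def recovery_metrics(
    ranking: MediatorRanking,
    truth: SyntheticTruth,
    selected: list[str] | None = None,
    fraction: float = 0.05,
) -> dict[str, float]:
    """Recall/precision of the selected set plus rank-based AUROC.

    ``selected`` defaults to the unfiltered top ``fraction`` of the cohort
    order. AUROC is computed from the aggregated rank statistic with planted
    mediators as positives.
    """
    planted = [g for g in truth.mediators if g in set(ranking.nodes)]
    if not planted:
        raise ValidationError("no planted mediator overlaps the ranked node set")
    if selected is None:
        import math

        selected = list(ranking.order[: math.ceil(fraction * len(ranking.nodes))])
    sel = set(selected)
    hit = len(sel & set(planted))
    position = {g: k + 1 for k, g in enumerate(ranking.order)}
    med_rank = float(np.median([position[g] for g in planted]))

    # AUROC via the rank-sum (Mann-Whitney) identity on -R
    from scipy.stats import rankdata

    scores = -np.asarray(ranking.R, dtype=float)
    labels = np.array([g in set(planted) for g in ranking.nodes])
    ranks = rankdata(scores)
    n1, n0 = labels.sum(), (~labels).sum()
    auroc = (ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    return {
        "recall": hit / len(planted),
        "precision": hit / len(sel) if sel else 0.0,
        "median_planted_rank": med_rank,
        "auroc": float(auroc),
        "n_selected": float(len(sel)),
    }


# ---------------------------------------------------------------------------
# cohort (de)serialization: the same TSV dialects the readers consume
# ---------------------------------------------------------------------------

MUTATION_COLUMNS = [
    "tumor_sample",
    "normal_sample",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "effect",
    "depth_tumor",
    "vaf_tumor",
    "depth_normal",
    "vaf_normal",
    "pon_count",
]


def write_cohort(
    out_dir: str | Path,
    net: DirectedNetwork,
    mutations: dict[str, list[MutationRecord]],
    tables: dict[str, dict[str, DifferentialTable]],
    truth: SyntheticTruth,
) -> None:
    """Write network, mutation table, per-sample layer tables and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "network.tsv", "w") as f:
        f.write("source\ttarget\tdirected\ttype\n")
        for i, j, t in net.edges:
            f.write(f"{net.nodes[i]}\t{net.nodes[j]}\t1\t{t}\n")
    rows = []
    for sample in sorted(mutations):
        for r in mutations[sample]:
            rows.append(
                [
                    r.tumor_sample,
                    r.normal_sample,
                    r.chrom,
                    r.pos,
                    r.ref,
                    r.alt,
                    r.gene,
                    r.effect,
                    r.depth_tumor,
                    f"{100 * r.vaf_tumor:.2f}%",
                    r.depth_normal,
                    "" if r.vaf_normal is None else f"{100 * r.vaf_normal:.2f}%",
                    r.pon_count,
                ]
            )
    pd.DataFrame(rows, columns=MUTATION_COLUMNS).to_csv(
        out / "mutations.tsv", sep="\t", index=False
    )
    for sample, layers in tables.items():
        for layer, table in layers.items():
            table.data.to_csv(out / f"{sample}.{layer}.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(truth.to_json())


def load_cohort(
    cohort_dir: str | Path,
) -> tuple[DirectedNetwork, dict[str, list[MutationRecord]], dict[str, dict[str, DifferentialTable]], SyntheticTruth | None]:
    """Read back a cohort directory written by :func:`write_cohort`."""
    from .network import load_network
    from .reporting import parse_mutation_table

    d = Path(cohort_dir)
    net = load_network(d / "network.tsv")
    records, _, _ = parse_mutation_table(d / "mutations.tsv")
    mutations: dict[str, list[MutationRecord]] = {}
    for r in records:
        mutations.setdefault(r.tumor_sample, []).append(r)
    tables: dict[str, dict[str, DifferentialTable]] = {}
    for path in sorted(d.glob("*.tsv")):
        parts = path.stem.split(".")
        if len(parts) != 2 or parts[1] not in ("mrna", "mirna", "protein", "phosphosite"):
            continue
        sample, layer = parts
        df = pd.read_csv(path, sep="\t")
        df["detected"] = df["detected"].astype(bool)
        tables.setdefault(sample, {})[layer] = DifferentialTable(layer, sample, df)
    truth = None
    truth_path = d / "truth.json"
    if truth_path.exists():
        truth = SyntheticTruth.from_json(truth_path.read_text())
    return net, mutations, tables, truth
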