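"""Per-sample omics ingestion: variant filtering, layer merging, event sets."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import FormatError, ParameterError, ValidationError
from .network import DirectedNetwork

__all__ = [
    "MutationRecord",
    "DifferentialTable",
    "SampleEvents",
    "filter_somatic_variants",
    "collapse_phosphosites",
    "combine_downstream",
    "build_sample_events",
    "read_differential_table",
]

log = logging.getLogger(__name__)

LAYERS = ("mrna", "mirna", "protein", "phosphosite")


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant call in one tumor nodule.

    ``depth_normal``, ``vaf_normal`` and ``pon_count`` are optional; a missing
    value passes the corresponding filter.
    """

    tumor_sample: str
    normal_sample: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect: str
    depth_tumor: int
    vaf_tumor: float
    depth_normal: int | None = None
    vaf_normal: float | None = None
    pon_count: int | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.depth_tumor < 0 or (self.depth_normal or 0) < 0:
            raise ValidationError(f"negative read depth in record for {self.gene}")
        for v in (self.vaf_tumor, self.vaf_normal):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(f"VAF {v} outside [0, 1] for {self.gene}")

    @property
    def supporting_reads(self) -> int:
        """Reads supporting the alternative allele, round(depth * VAF)."""
        return round(self.depth_tumor * self.vaf_tumor)


def filter_somatic_variants(
    records: Iterable[MutationRecord],
    min_depth_tumor: int = 10,
    min_depth_normal: int = 5,
    min_supporting_reads: int = 3,
    min_vaf_ratio: float = 5.0,
    max_pon_count: int = 1,
) -> list[MutationRecord]:
    """Apply the somatic read-support filters, preserving input order.

    A record is retained when tumor depth >= 10, germline depth >= 5,
    supporting reads >= 3, tumor VAF >= 5x the normal VAF, and it is seen in
    fewer than two panel-of-normals samples. Missing optional fields pass
    their filter; a normal VAF of 0 passes the ratio filter.
    """
    kept = []
    n_in = 0
    for rec in records:
        n_in += 1
        if rec.depth_tumor < min_depth_tumor:
            continue
        if rec.depth_normal is not None and rec.depth_normal < min_depth_normal:
            continue
        if rec.supporting_reads < min_supporting_reads:
            continue
        if rec.vaf_normal is not None and rec.vaf_normal > 0:
            if rec.vaf_tumor < min_vaf_ratio * rec.vaf_normal:
                continue
        if rec.pon_count is not None and rec.pon_count > max_pon_count:
            continue
        kept.append(rec)
    log.info("variant filter: %d records in, %d retained", n_in, len(kept))
    return kept


@dataclass(frozen=True)
class DifferentialTable:
    """Per-sample differential calls for one omics layer.

    ``data`` has columns feature, log2fc, padj, detected (bool) and, for the
    phosphosite layer, gene (the parent gene symbol).
    """

    layer: str
    sample: str
    data: pd.DataFrame

    def __post_init__(self):
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}")
        required = {"feature", "log2fc", "padj", "detected"}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"differential table missing columns {sorted(missing)}")
        if self.layer == "phosphosite" and "gene" not in self.data.columns:
            raise ValidationError("phosphosite table requires a parent 'gene' column")
        det = self.data["detected"].astype(bool)
        if self.data.loc[det, "padj"].isna().any():
            raise ValidationError("detected rows must carry an adjusted p-value")
        if self.data["feature"].duplicated().any() and self.layer != "phosphosite":
            dup = self.data.loc[self.data["feature"].duplicated(), "feature"].iloc[0]
            raise ValidationError(f"duplicate feature {dup!r} in {self.layer} table")
        if self.layer == "phosphosite":
            blank = ~self.data["gene"].astype(str).str.strip().astype(bool)
            if blank.any():
                raise ValidationError("phosphosite row without parent gene symbol")

    def significant(self, alpha: float = 0.05) -> set[str]:
        """Features detected with adjusted p below ``alpha``."""
        d = self.data
        mask = d["detected"].astype(bool) & (d["padj"] < alpha)
        return set(d.loc[mask, "feature"].astype(str))

    def detected_features(self) -> set[str]:
        return set(self.data.loc[self.data["detected"].astype(bool), "feature"].astype(str))


def read_differential_table(path: str | Path, layer: str, sample: str) -> DifferentialTable:
    """Read a TSV ``feature<TAB>log2fc<TAB>padj<TAB>detected[<TAB>gene]`` table."""
    df = pd.read_csv(path, sep="\t", dtype={"feature": str, "gene": str})
    df.columns = [c.strip().lower() for c in df.columns]
    if "detected" in df.columns:
        df["detected"] = df["detected"].astype(str).str.strip().isin(
            ("1", "true", "True", "TRUE", "yes")
        )
    return DifferentialTable(layer, sample, df)


def collapse_phosphosites(table: DifferentialTable, alpha: float = 0.05) -> set[str]:
    """Genes with at least one significantly changed phosphosite."""
    if table.layer != "phosphosite":
        raise ValidationError(f"expected a phosphosite table, got {table.layer!r}")
    if not (0.0 < alpha < 1.0):
        raise ParameterError(f"alpha must lie in (0, 1), got {alpha}")
    d = table.data
    mask = d["detected"].astype(bool) & (d["padj"] < alpha)
    return set(d.loc[mask, "gene"].astype(str).str.strip())


def _gene_status(sig: bool, detected: bool) -> str:
    if sig:
        return "significant"
    return "insignificant" if detected else "not_detected"


def combine_downstream(
    rna: DifferentialTable,
    protein: DifferentialTable,
    phospho_significant: set[str],
    phospho_detected: set[str] | frozenset[str] = frozenset(),
    alpha: float = 0.05,
) -> set[str]:
    """Merge RNA / proteome / phosphoproteome calls into downstream genes.

    Per gene: if the protein-or-phospho level is significant the gene is
    taken; if that level is detected but insignificant the gene is dropped
    regardless of RNA; if it is not detected at all, a significant RNA call
    takes the gene.
    """
    rna_sig = rna.significant(alpha)
    rna_det = rna.detected_features()
    prot_sig = protein.significant(alpha)
    prot_det = protein.detected_features()
    pp_sig = prot_sig | set(phospho_significant)
    pp_det = prot_det | set(phospho_detected) | pp_sig

    out: set[str] = set()
    for gene in rna_det | pp_det:
        pp = _gene_status(gene in pp_sig, gene in pp_det)
        if pp == "significant":
            out.add(gene)
        elif pp == "not_detected" and gene in rna_sig:
            out.add(gene)
    return out


@dataclass(frozen=True)
class SampleEvents:
    """Per-sample upstream and downstream event sets, restricted to a network.

    Category sets (``mutated_genes``, ``de_mirnas``, ``downstream``) contain
    node ids as spelled in the network; ``provenance`` maps node -> layer tags.
    """

    sample: str
    mutated_genes: frozenset[str]
    de_mirnas: frozenset[str]
    downstream: frozenset[str]
    provenance: Mapping[str, frozenset[str]] = field(default_factory=dict)

    @property
    def upstream(self) -> frozenset[str]:
        return self.mutated_genes | self.de_mirnas

    @property
    def scoreable(self) -> bool:
        return bool(self.upstream) and bool(self.downstream)


def build_sample_events(
    mutations: Iterable[MutationRecord],
    mirna: DifferentialTable,
    downstream: set[str],
    sample: str,
    net: DirectedNetwork,
    alpha: float = 0.05,
) -> SampleEvents:
    """Intersect per-sample events with the network and record provenance.

    Events whose id is not a network node are counted and logged, not fatal.
    A sample with an empty upstream or downstream set after intersection is
    flagged unscoreable (``SampleEvents.scoreable`` is False).
    """

    def on_network(ids: Iterable[str]) -> set[str]:
        found = set()
        n_off = 0
        for x in ids:
            k = net.index_of(str(x))
            if k is None:
                n_off += 1
            else:
                found.add(net.nodes[k])
        if n_off:
            log.info("sample %s: %d events not on the network", sample, n_off)
        return found

    mut_genes = on_network(r.gene for r in mutations)
    de_mir = on_network(mirna.significant(alpha))
    down = on_network(downstream)

    prov: dict[str, set[str]] = {}
    for g in mut_genes:
        prov.setdefault(g, set()).add("mutation")
    for m in de_mir:
        prov.setdefault(m, set()).add("mirna")
    for g in down:
        prov.setdefault(g, set()).add("downstream")

    ev = SampleEvents(
        sample,
        frozenset(mut_genes),
        frozenset(de_mir),
        frozenset(down),
        {k: frozenset(v) for k, v in prov.items()},
    )
    if not ev.scoreable:
        log.warning("sample %s is unscoreable (empty event set after intersection)", sample)
    return ev
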