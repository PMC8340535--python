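"""Table readers and tally reproduction for the packaged study fixtures."""
from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import FormatError, ValidationError
from .events import MutationRecord

__all__ = [
    "fixture_path",
    "parse_mutation_table",
    "mouse_of",
    "private_gene_intersections",
    "summarize_events_per_sample",
    "single_layer_detectability",
]

log = logging.getLogger(__name__)

LAYER_LABELS = ("rna", "protein", "phosphosite", "mirna")


def fixture_path(name: str) -> Path:
    """Absolute path of a packaged data fixture."""
    return Path(resources.files("medinet.data") / name)


def _parse_vaf(value, line_no: int) -> float:
    """VAF given either as a '%'-suffixed string or a fraction in [0, 1]."""
    s = str(value).strip()
    try:
        if s.endswith("%"):
            return float(s[:-1]) / 100.0
        return float(s)
    except ValueError as exc:
        raise FormatError(f"line {line_no}: unparseable VAF {value!r}") from exc


def parse_mutation_table(
    path: str | Path,
) -> tuple[list[MutationRecord], dict[str, int], int]:
    """Read a somatic mutation TSV into records plus per-sample tallies.

    Required columns: tumor_sample, normal_sample, chrom, pos, ref, alt,
    gene, effect, depth_tumor, vaf_tumor. Optional: depth_normal,
    vaf_normal, pon_count. VAF columns may carry a '%' suffix.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    required = [
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
    ]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"mutation table missing required column {col!r}")

    def opt(row, col, cast):
        if col not in df.columns:
            return None
        raw = str(row[col]).strip()
        return cast(raw) if raw else None

    records: list[MutationRecord] = []
    for k, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            pos = int(float(row["pos"]))
        except ValueError as exc:
            raise FormatError(f"line {k}: unparseable position {row['pos']!r}") from exc
        vn = row.get("vaf_normal", "")
        records.append(
            MutationRecord(
                tumor_sample=row["tumor_sample"].strip(),
                normal_sample=row["normal_sample"].strip(),
                chrom=row["chrom"].strip(),
                pos=pos,
                ref=row["ref"].strip(),
                alt=row["alt"].strip(),
                gene=row["gene"].strip(),
                effect=row["effect"].strip(),
                depth_tumor=int(row["depth_tumor"]),
                vaf_tumor=_parse_vaf(row["vaf_tumor"], k),
                depth_normal=opt(row, "depth_normal", lambda s: int(float(s))),
                vaf_normal=None if not str(vn).strip() else _parse_vaf(vn, k),
                pon_count=opt(row, "pon_count", lambda s: int(float(s))),
            )
        )
    per_sample: dict[str, int] = {}
    for r in records:
        per_sample[r.tumor_sample] = per_sample.get(r.tumor_sample, 0) + 1
    log.info("parsed %d mutation records from %s", len(records), path)
    return records, per_sample, len(records)


def mouse_of(record: MutationRecord) -> str:
    """Animal id shared by the nodules of one mouse (normal-sample prefix)."""
    normal = record.normal_sample
    for suffix in ("muscle", "_normal"):
        if normal.endswith(suffix):
            return normal[: -len(suffix)]
    return normal


def private_gene_intersections(
    records: list[MutationRecord], exclude: set[str] = frozenset()
) -> dict[str, set[str]]:
    """Per mouse, genes mutated in every one of its nodules (drivers excluded)."""
    by_mouse: dict[str, dict[str, set[str]]] = {}
    excl = {g.casefold() for g in exclude}
    for r in records:
        if r.gene.casefold() in excl:
            continue
        by_mouse.setdefault(mouse_of(r), {}).setdefault(r.tumor_sample, set()).add(r.gene)
    return {
        mouse: set.intersection(*nodules.values()) if len(nodules) > 1 else set()
        for mouse, nodules in by_mouse.items()
    }


def summarize_events_per_sample(path: str | Path) -> dict[str, int]:
    """Per-layer mean of (up + down) counts over samples, rounded to integer.

    Expects a TSV with one row per sample and columns
    ``<layer>_down / <layer>_not / <layer>_up`` for each layer in
    rna, protein, phosphosite, mirna.
    """
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise FormatError("per-sample count table requires a 'sample' column")
    out: dict[str, int] = {}
    for layer in LAYER_LABELS:
        for col in (f"{layer}_down", f"{layer}_up"):
            if col not in df.columns:
                raise ValidationError(f"count table missing column {col!r}")
        mean = (df[f"{layer}_down"] + df[f"{layer}_up"]).mean()
        out[layer] = round(mean)
    return out


CATEGORIES = ("rna_only", "protein_only", "phospho_only", "multi", "none")


def single_layer_detectability(
    path: str | Path, mediators: list[str] | None = None
) -> tuple[dict[str, str], dict[str, int]]:
    """Classify each mediator by which single-layer analyses flag it.

    The table carries one row per mediator with columns rna_top5,
    protein_top5, phospho_top5 (non-empty = flagged). Returns the per-gene
    classification and category counts.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("gene", "rna_top5", "protein_top5", "phospho_top5"):
        if col not in df.columns:
            raise FormatError(f"flag table missing column {col!r}")
    flags = {
        str(row.gene).strip(): (
            bool(str(row.rna_top5).strip()),
            bool(str(row.protein_top5).strip()),
            bool(str(row.phospho_top5).strip()),
        )
        for row in df.itertuples(index=False)
    }
    if mediators is None:
        mediators = list(flags)
    classification: dict[str, str] = {}
    for gene in mediators:
        if gene not in flags:
            raise ValidationError(f"mediator {gene!r} absent from the flag table")
        rna, prot, phos = flags[gene]
        n = rna + prot + phos
        if n == 0:
            cls = "none"
        elif n > 1:
            cls = "multi"
        elif rna:
            cls = "rna_only"
        elif prot:
            cls = "protein_only"
        else:
            cls = "phospho_only"
        classification[gene] = cls
    counts = {c: sum(v == c for v in classification.values()) for c in CATEGORIES}
    return classification, counts
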