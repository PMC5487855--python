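"""Tabular readers/writers: annotation TSV, gene evidence, edge lists, GMT,
and long-format assay CSV.

Annotation TSV header (tab-separated)::

    chrom pos ref alt gene effect hgvs_c hgvs_p conserved is_indel
    tool_calls af_<DB> [af_<DB> ...] [extra columns...]

``tool_calls`` is a comma-separated vector over the configured tool ensemble;
frequency columns use the ``af_`` prefix with ``.`` for database absence.
Unknown columns are preserved verbatim in ``extras``.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .models import (
    AnnotationRecord,
    EdgeList,
    Effect,
    ExpressionLevel,
    FormatError,
    GeneEvidence,
    GeneSetCollection,
    ToolCall,
)

_CORE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "effect",
    "hgvs_c",
    "hgvs_p",
    "conserved",
    "is_indel",
    "tool_calls",
]

_MISSING = "."


def read_annotations(
    path: Union[str, Path], n_tools: int = 10
) -> list[AnnotationRecord]:
    """Read an annotation TSV; validates frequencies and tool-call length."""
    path = Path(path)
    records = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing_cols = [c for c in _CORE_COLUMNS if c not in header]
        if missing_cols:
            raise FormatError(f"{path}: missing columns {missing_cols}")
        freq_cols = [c for c in header if c.startswith("af_")]
        extra_cols = [
            c for c in header if c not in _CORE_COLUMNS and not c.startswith("af_")
        ]
        for lineno, row in enumerate(reader, start=2):
            db_freq: dict[str, Optional[float]] = {}
            for col in freq_cols:
                raw = (row[col] or "").strip()
                if raw in ("", _MISSING):
                    db_freq[col[3:]] = None
                else:
                    f = float(raw)
                    if not (0.0 <= f <= 1.0):
                        raise FormatError(
                            f"{path}:{lineno}: frequency {f} in {col} outside [0, 1]"
                        )
                    db_freq[col[3:]] = f
            calls_raw = [c for c in row["tool_calls"].split(",") if c]
            try:
                calls = [ToolCall(c) for c in calls_raw]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if len(calls) != n_tools:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_tools} tool calls, "
                    f"got {len(calls)}"
                )
            records.append(
                AnnotationRecord(
                    variant_key=(
                        row["chrom"],
                        int(row["pos"]),
                        row["ref"],
                        row["alt"],
                    ),
                    gene=row["gene"],
                    effect=Effect(row["effect"]),
                    hgvs_c=row["hgvs_c"],
                    hgvs_p=row["hgvs_p"],
                    db_frequencies=db_freq,
                    tool_calls=calls,
                    conserved_region=_parse_bool(row["conserved"], path, lineno),
                    is_indel=_parse_bool(row["is_indel"], path, lineno),
                    extras={c: row[c] for c in extra_cols},
                )
            )
    return records


def write_annotations(
    records: Sequence[AnnotationRecord], path: Union[str, Path]
) -> None:
    db_names = sorted({db for r in records for db in r.db_frequencies})
    extra_names = sorted({k for r in records for k in r.extras})
    header = _CORE_COLUMNS + [f"af_{db}" for db in db_names] + extra_names
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for r in sorted(records, key=lambda r: r.variant_key):
            chrom, pos, ref, alt = r.variant_key
            row = [
                chrom,
                pos,
                ref,
                alt,
                r.gene,
                r.effect.value,
                r.hgvs_c,
                r.hgvs_p,
                int(r.conserved_region),
                int(r.is_indel),
                ",".join(c.value for c in r.tool_calls),
            ]
            for db in db_names:
                f = r.db_frequencies.get(db)
                row.append(_MISSING if f is None else repr(f))
            row.extend(r.extras.get(k, "") for k in extra_names)
            writer.writerow(row)


def _parse_bool(raw: str, path, lineno: int) -> bool:
    v = raw.strip().lower()
    if v in ("1", "true", "yes"):
        return True
    if v in ("0", "false", "no"):
        return False
    raise FormatError(f"{path}:{lineno}: cannot parse boolean {raw!r}")


def read_gene_evidence(path: Union[str, Path]) -> dict[str, GeneEvidence]:
    """TSV with columns gene, disease_associations, tissue_expression,
    rvis_percentile.  Associations are comma-separated; tissue expression is
    ``tissue:level`` pairs separated by ``;``; ``.`` marks missing RVIS."""
    out: dict[str, GeneEvidence] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene", "disease_associations", "tissue_expression", "rvis_percentile"}
        if not required <= set(reader.fieldnames or []):
            raise FormatError(f"{path}: expected columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            gene = row["gene"]
            if gene in out:
                raise FormatError(f"{path}:{lineno}: duplicate gene {gene!r}")
            tissues: dict[str, ExpressionLevel] = {}
            raw_tissue = (row["tissue_expression"] or "").strip()
            if raw_tissue and raw_tissue != _MISSING:
                for pair in raw_tissue.split(";"):
                    tissue, _, level = pair.partition(":")
                    try:
                        tissues[tissue] = ExpressionLevel(level)
                    except ValueError:
                        raise FormatError(
                            f"{path}:{lineno}: unknown expression level {level!r}"
                        ) from None
            raw_rvis = (row["rvis_percentile"] or "").strip()
            rvis = None if raw_rvis in ("", _MISSING) else float(raw_rvis)
            assoc_raw = (row["disease_associations"] or "").strip()
            assoc = (
                frozenset(a for a in assoc_raw.split(",") if a)
                if assoc_raw not in ("", _MISSING)
                else frozenset()
            )
            out[gene] = GeneEvidence(
                gene=gene,
                disease_associations=assoc,
                tissue_expression=tissues,
                rvis_percentile=rvis,
            )
    return out


def write_gene_evidence(
    evidence: dict[str, GeneEvidence], path: Union[str, Path]
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["gene", "disease_associations", "tissue_expression", "rvis_percentile"]
        )
        for gene in sorted(evidence):
            ev = evidence[gene]
            writer.writerow(
                [
                    gene,
                    ",".join(sorted(ev.disease_associations)) or _MISSING,
                    ";".join(
                        f"{t}:{lvl.value}"
                        for t, lvl in sorted(ev.tissue_expression.items())
                    )
                    or _MISSING,
                    _MISSING if ev.rvis_percentile is None else repr(ev.rvis_percentile),
                ]
            )


def read_edge_list(path: Union[str, Path]) -> EdgeList:
    """Read a 2-3 column TSV of undirected edges (third column = evidence
    label).  Duplicate edges in either orientation collapse to one."""
    el = EdgeList()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                raise FormatError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(fields)}"
                )
            a, b = fields[0].strip(), fields[1].strip()
            label = fields[2].strip() if len(fields) == 3 else ""
            el.add(a, b, label)
    return el


def write_edge_list(edges: EdgeList, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for a, b, label in edges.pairs():
            fh.write(f"{a}\t{b}\t{label}\n")


def read_gmt(path: Union[str, Path]) -> GeneSetCollection:
    """GMT: set_name <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene"
                )
            coll.add(fields[0], [g for g in fields[2:] if g], fields[1])
    return coll


def write_gmt(collection: GeneSetCollection, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection):
            genes = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{collection.descriptions.get(name, '')}\t{genes}\n")


def read_contexts(path: Union[str, Path]) -> dict[tuple, str]:
    """Reference sequence contexts for indel sites, keyed by variant key.
    TSV columns: chrom, pos, ref, alt, context."""
    out: dict[tuple, str] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"chrom", "pos", "ref", "alt", "context"}
        if not required <= set(reader.fieldnames or []):
            raise FormatError(f"{path}: expected columns {sorted(required)}")
        for row in reader:
            out[(row["chrom"], int(row["pos"]), row["ref"], row["alt"])] = row[
                "context"
            ]
    return out


def write_contexts(contexts: dict, path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["chrom", "pos", "ref", "alt", "context"])
        for key in sorted(contexts):
            chrom, pos, ref, alt = key
            writer.writerow([chrom, pos, ref, alt, contexts[key]])


ASSAY_COLUMNS = ["assay", "group", "replicate", "target", "value"]


def read_assay_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Long-format assay table with columns assay, group, replicate, target,
    value.  Values must be numeric."""
    df = pd.read_csv(path, dtype={"group": str, "target": str})
    missing = [c for c in ASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df["value"].isna().any():
        raise FormatError(f"{path}: non-numeric or missing values in 'value'")
    df["value"] = df["value"].astype(float)
    return df


def write_assay_csv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df = df[ASSAY_COLUMNS + [c for c in df.columns if c not in ASSAY_COLUMNS]]
    df.sort_values(ASSAY_COLUMNS[:4]).to_csv(path, index=False)
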