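"""Readers and writers for the tabular formats the pipeline touches.

All files are plain TSV with a header row (GMT excepted, which follows the
standard three-plus-column convention). Readers validate strictly and fail
with the offending column or 1-based data-line number; they never silently
drop rows.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .models import (
    Component,
    ComponentSample,
    CopySegment,
    GeneModel,
    GeneSet,
    MutationRecord,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class FormatError(ValueError):
    """A file violated the expected tabular format."""


#: default column map for mutation tables (MAF-like TSV); a dialect maps
#: our canonical field names to the column headers present in the file.
DEFAULT_MUTATION_DIALECT: dict[str, str] = {
    "sample_id": "sample_id",
    "patient_id": "patient_id",
    "component": "component",
    "chrom": "chrom",
    "pos": "pos",
    "ref": "ref",
    "alt": "alt",
    "gene": "gene",
    "variant_class": "variant_class",
    "alt_count": "alt_count",
    "ref_count": "ref_count",
    "population_freq": "population_freq",
    "is_cancer_gene": "is_cancer_gene",
}

_OPTIONAL_MUTATION_FIELDS = ("population_freq", "is_cancer_gene")


def _read_tsv(path: PathLike) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: PathLike) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def _parse_int(value: str, column: str, line: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise FormatError(f"line {line}: non-integer {column} value {value!r}") from None


def _parse_float(value: str, column: str, line: int) -> Optional[float]:
    if value in ("", "NA", "nan", "None", "."):
        return None
    try:
        return float(value)
    except ValueError:
        raise FormatError(f"line {line}: non-numeric {column} value {value!r}") from None


def read_mutation_table(
    path: PathLike, dialect: Optional[Mapping[str, str]] = None
) -> list[MutationRecord]:
    """Read a MAF-like TSV of somatic calls.

    ``dialect`` maps canonical field names to the file's column headers;
    unknown columns are preserved on each record under ``annotations``.
    """
    dmap = dict(DEFAULT_MUTATION_DIALECT)
    if dialect:
        dmap.update(dialect)
    df = _read_tsv(path)
    required = [dmap[f] for f in dmap if f not in _OPTIONAL_MUTATION_FIELDS]
    _require_columns(df, required, path)
    known_cols = set(dmap.values())
    extra_cols = [c for c in df.columns if c not in known_cols]

    records: list[MutationRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        r = dict(zip(df.columns, row))
        pf = None
        if dmap["population_freq"] in df.columns:
            pf = _parse_float(r[dmap["population_freq"]], "population_freq", i)
        cancer = False
        if dmap["is_cancer_gene"] in df.columns:
            cancer = str(r[dmap["is_cancer_gene"]]).strip().lower() in ("true", "1", "yes")
        try:
            rec = MutationRecord(
                sample_id=r[dmap["sample_id"]],
                patient_id=r[dmap["patient_id"]],
                component=Component(r[dmap["component"]]),
                chrom=r[dmap["chrom"]],
                pos=_parse_int(r[dmap["pos"]], "pos", i),
                ref=r[dmap["ref"]],
                alt=r[dmap["alt"]],
                gene=r[dmap["gene"]],
                variant_class=r[dmap["variant_class"]],
                alt_count=_parse_int(r[dmap["alt_count"]], "alt_count", i),
                ref_count=_parse_int(r[dmap["ref_count"]], "ref_count", i),
                population_freq=pf,
                is_cancer_gene=cancer,
                annotations={c: r[c] for c in extra_cols},
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from exc
        records.append(rec)
    logger.info("read %d mutation records from %s", len(records), path)
    return records


def write_mutation_table(records: Sequence[MutationRecord], path: PathLike) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "patient_id": r.patient_id,
                "component": r.component.value,
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "gene": r.gene,
                "variant_class": r.variant_class,
                "alt_count": r.alt_count,
                "ref_count": r.ref_count,
                "population_freq": "" if r.population_freq is None else repr(r.population_freq),
                "is_cancer_gene": str(r.is_cancer_gene),
                **r.annotations,
            }
        )
    pd.DataFrame(rows, columns=list(DEFAULT_MUTATION_DIALECT) + sorted(
        {k for r in records for k in r.annotations}
    )).to_csv(path, sep="\t", index=False)


def read_seg(path: PathLike) -> list[CopySegment]:
    """Read a SEG-dialect TSV extended with allele-specific copy number.

    Segments are returned sorted by (sample, chrom, start); overlapping
    segments within one sample are rejected.
    """
    df = _read_tsv(path)
    _require_columns(df, ["sample_id", "chrom", "start", "end", "log2_ratio"], path)
    segs: list[tuple[int, CopySegment]] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        r = dict(zip(df.columns, row))
        try:
            seg = CopySegment(
                sample_id=r["sample_id"],
                chrom=r["chrom"],
                start=_parse_int(r["start"], "start", i),
                end=_parse_int(r["end"], "end", i),
                log2_ratio=float(_parse_float(r["log2_ratio"], "log2_ratio", i) or 0.0),
                major_cn=_parse_int(r.get("major_cn", "1") or "1", "major_cn", i),
                minor_cn=_parse_int(r.get("minor_cn", "1") or "1", "minor_cn", i),
                segment_ccf=_parse_float(r.get("segment_ccf", ""), "segment_ccf", i)
                if "segment_ccf" in df.columns
                else None,
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from exc
        segs.append((i, seg))

    def _chrom_order(c: str):
        return (0, int(c)) if c.isdigit() else (1, c)

    segs.sort(key=lambda t: (t[1].sample_id, _chrom_order(t[1].chrom), t[1].start))
    for (la, a), (lb, b) in zip(segs, segs[1:]):
        if a.sample_id == b.sample_id and a.chrom == b.chrom and b.start <= a.end:
            raise FormatError(
                f"{path}: overlapping segments in sample {a.sample_id} "
                f"(lines {la} and {lb}: {a.chrom}:{a.start}-{a.end} vs {b.chrom}:{b.start}-{b.end})"
            )
    logger.info("read %d segments from %s", len(segs), path)
    return [s for _, s in segs]


def write_seg(segments: Sequence[CopySegment], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "log2_ratio": repr(s.log2_ratio),
                "major_cn": s.major_cn,
                "minor_cn": s.minor_cn,
                "segment_ccf": "" if s.segment_ccf is None else repr(s.segment_ccf),
            }
            for s in segments
        ]
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path: PathLike) -> list[GeneSet]:
    """Read gene sets in standard GMT (name, description, genes...)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {i}: GMT line has {len(fields)} field(s), need >= 3")
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise FormatError(f"{path}: line {i}: gene set {fields[0]!r} has no genes")
            sets.append(GeneSet(name=fields[0], genes=frozenset(genes)))
    return sets


def write_gmt(gene_sets: Sequence[GeneSet], path: PathLike) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, "na", *sorted(gs.genes)]) + "\n")


def read_metadata(path: PathLike) -> list[ComponentSample]:
    df = _read_tsv(path)
    _require_columns(df, ["sample_id", "patient_id", "component", "purity", "ploidy"], path)
    samples = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        r = dict(zip(df.columns, row))
        try:
            samples.append(
                ComponentSample(
                    sample_id=r["sample_id"],
                    patient_id=r["patient_id"],
                    component=Component(r["component"]),
                    purity=float(r["purity"]),
                    ploidy=float(r["ploidy"]),
                    capture_size_mb=float(r.get("capture_size_mb", "53") or "53"),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from exc
    return samples


def write_metadata(samples: Sequence[ComponentSample], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "patient_id": s.patient_id,
                "component": s.component.value,
                "purity": repr(s.purity),
                "ploidy": repr(s.ploidy),
                "capture_size_mb": repr(s.capture_size_mb),
            }
            for s in samples
        ]
    ).to_csv(path, sep="\t", index=False)


def read_gene_model(path: PathLike) -> list[GeneModel]:
    """Gene-model BED-like TSV: gene, chrom, start, end, arm (1-based inclusive)."""
    df = _read_tsv(path)
    _require_columns(df, ["gene", "chrom", "start", "end"], path)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        r = dict(zip(df.columns, row))
        if r["gene"] in seen:
            raise FormatError(f"{path}: line {i}: duplicate gene {r['gene']!r}")
        seen.add(r["gene"])
        try:
            genes.append(
                GeneModel(
                    gene=r["gene"],
                    chrom=r["chrom"],
                    start=_parse_int(r["start"], "start", i),
                    end=_parse_int(r["end"], "end", i),
                    arm=r.get("arm", "q") or "q",
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from exc
    return genes


def write_gene_model(genes: Sequence[GeneModel], path: PathLike) -> None:
    pd.DataFrame(
        [
            {"gene": g.gene, "chrom": g.chrom, "start": g.start, "end": g.end, "arm": g.arm}
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


def read_expression(path: PathLike) -> pd.DataFrame:
    """Expression matrix TSV, genes x samples, first column the gene name."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene rows: {dupes[:5]}")
    if df.isna().any().any():
        raise FormatError(f"{path}: missing values in expression matrix")
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        raise FormatError(f"{path}: non-numeric expression values")
    return df


def write_expression(expr: pd.DataFrame, path: PathLike) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")
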