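"""Readers and writers for the on-disk formats.

Formats
-------
* Enhancers: BED4 plus one activity column per cell type, with a header row
  naming the cell types (``chrom  start  end  id  CT01  CT02 ...``).
* Expression: TSV matrix, genes in rows, cell types in the header.
* Genes: BED6 (``chrom  txStart  txEnd  id  score  strand``); the TSS is
  txStart on the ``+`` strand and txEnd on the ``-`` strand.
* Interactions: BEDPE (``chrom1 start1 end1 chrom2 start2 end2 [name score]``).
* Predictions: TSV with enhancer coordinates, ids, TSS, cell type, the six
  feature values and the prediction score.

All coordinates are 0-based half-open internally; 1-based sources are
converted at this boundary (see ``read_gene_annotation``).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .core import Enhancer, Gene, GenomicInterval, InteractionRecord

logger = logging.getLogger(__name__)

#: Fixed feature column order used in all tabular model I/O.
FEATURE_ORDER = ("EGC", "GS", "DIS", "EWS", "GWS", "WEEC")

PREDICTION_COLUMNS = (
    "chrom",
    "enh_start",
    "enh_end",
    "enhancer_id",
    "gene_id",
    "tss",
    "cell_type",
    *FEATURE_ORDER,
    "score",
)


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line number."""


def _fields(line: str) -> list[str]:
    return line.rstrip("\n").split("\t")


def read_enhancer_bed(path: str | Path, cell_types: list[str] | None = None) -> list[Enhancer]:
    """Read an enhancer BED file with per-cell-type activity score columns.

    The first row is a header whose columns 5+ name the cell types. If
    ``cell_types`` is given it must match the header names exactly.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}:1: empty header")
        header_cells = _fields(header)[4:]
        if not header_cells:
            raise ParseError(f"{path}:1: header has no cell-type columns")
        if cell_types is not None and list(cell_types) != header_cells:
            raise ValueError(
                "cell types do not match header: "
                f"expected {list(cell_types)}, file has {header_cells}"
            )
        enhancers: list[Enhancer] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = _fields(line)
            if len(fields) != 4 + len(header_cells):
                raise ParseError(
                    f"{path}:{lineno}: expected {4 + len(header_cells)} columns, "
                    f"got {len(fields)}"
                )
            chrom, start, end, eid = fields[:4]
            try:
                interval = GenomicInterval(chrom, int(start), int(end))
                scores = [float(v) for v in fields[4:]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if eid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate enhancer id {eid!r}")
            seen.add(eid)
            for cell, score in zip(header_cells, scores):
                if score < 0:
                    raise ParseError(
                        f"{path}:{lineno}: negative activity {score} for {cell}"
                    )
            enhancers.append(Enhancer(eid, interval, dict(zip(header_cells, scores))))
    return enhancers


def write_enhancer_bed(enhancers: list[Enhancer], path: str | Path, cell_types: list[str]) -> None:
    """Write enhancers in the header-scored BED dialect ``read_enhancer_bed`` reads."""
    with open(path, "w") as fh:
        fh.write("\t".join(["chrom", "start", "end", "id", *cell_types]) + "\n")
        for enh in enhancers:
            missing = [c for c in cell_types if c not in enh.activity]
            if missing:
                raise ValueError(f"enhancer {enh.id} lacks activity for {missing}")
            row = [
                enh.interval.chrom,
                str(enh.interval.start),
                str(enh.interval.end),
                enh.id,
                *(repr(enh.activity[c]) for c in cell_types),
            ]
            fh.write("\t".join(row) + "\n")


def read_expression_table(path: str | Path) -> dict[str, dict[str, float]]:
    """Read a gene x cell-type FPKM matrix into ``{gene: {cell: fpkm}}``.

    Missing or non-numeric cells and negative FPKM values are errors, not
    imputed: silent zeros would distort activity-expression correlations.
    """
    path = Path(path)
    with open(path) as fh:
        header = _fields(fh.readline())
        cells = header[1:]
        if not cells:
            raise ParseError(f"{path}:1: header has no cell-type columns")
        table: dict[str, dict[str, float]] = {}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = _fields(line)
            if len(fields) != 1 + len(cells):
                raise ParseError(
                    f"{path}:{lineno}: expected {1 + len(cells)} columns, got {len(fields)}"
                )
            gene = fields[0]
            if gene in table:
                raise ParseError(f"{path}:{lineno}: duplicate gene id {gene!r}")
            try:
                values = [float(v) for v in fields[1:]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric expression value") from exc
            for cell, value in zip(cells, values):
                if value < 0:
                    raise ParseError(f"{path}:{lineno}: negative FPKM {value} for {cell}")
            table[gene] = dict(zip(cells, values))
    return table


def write_expression_table(table: dict[str, dict[str, float]], path: str | Path, cell_types: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["gene_id", *cell_types]) + "\n")
        for gene, values in table.items():
            fh.write("\t".join([gene, *(repr(values[c]) for c in cell_types)]) + "\n")


def read_gene_annotation(path: str | Path, one_based: bool = False) -> list[Gene]:
    """Read gene annotation from a BED6-like file (expression left unset).

    TSS = txStart for ``+`` strand genes, txEnd for ``-`` strand genes.
    Set ``one_based=True`` for sources with 1-based inclusive starts (GFF-style
    coordinates); starts are shifted to the 0-based half-open convention.
    """
    path = Path(path)
    genes: list[Gene] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = _fields(line)
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 columns, got {len(fields)}")
            chrom, start, end, gid, _score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if one_based:
                start_i -= 1
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            if gid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene id {gid!r}")
            seen.add(gid)
            try:
                body = GenomicInterval(chrom, start_i, end_i)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            tss = start_i if strand == "+" else end_i
            genes.append(Gene(gid, chrom, tss, strand, body))
    return genes


def write_gene_annotation(genes: list[Gene], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in genes:
            fh.write(
                "\t".join(
                    [
                        gene.chrom,
                        str(gene.body.start),
                        str(gene.body.end),
                        gene.id,
                        "0",
                        gene.strand,
                    ]
                )
                + "\n"
            )


def read_bedpe(path: str | Path, cell_type: str, source: str = "ChIA-PET") -> list[InteractionRecord]:
    """Read interaction anchors from a BEDPE file.

    Inter-chromosomal records are dropped (the candidate pairs they could label
    are never built) and the dropped count is logged.
    """
    path = Path(path)
    records: list[InteractionRecord] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _fields(line)
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 columns, got {len(fields)}")
            chrom1, start1, end1, chrom2, start2, end2 = fields[:6]
            if chrom1 != chrom2:
                dropped += 1
                continue
            try:
                a1 = GenomicInterval(chrom1, int(start1), int(end1))
                a2 = GenomicInterval(chrom2, int(start2), int(end2))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(InteractionRecord(a1, a2, cell_type, source))
    if dropped:
        logger.warning("%s: dropped %d inter-chromosomal record(s)", path, dropped)
    return records


def write_bedpe(records: list[InteractionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                "\t".join(
                    [
                        rec.anchor1.chrom,
                        str(rec.anchor1.start),
                        str(rec.anchor1.end),
                        rec.anchor2.chrom,
                        str(rec.anchor2.start),
                        str(rec.anchor2.end),
                    ]
                )
                + "\n"
            )


def write_predictions(pairs: pd.DataFrame, path: str | Path) -> None:
    """Write scored candidate pairs as a deterministic TSV.

    ``pairs`` must carry all of ``PREDICTION_COLUMNS``; every score must be a
    number in [0, 1]. Rows are sorted by (chrom, enhancer start, gene id) so
    repeated runs produce byte-identical files.
    """
    missing = [c for c in PREDICTION_COLUMNS if c not in pairs.columns]
    if missing:
        raise ValueError(f"prediction table missing columns: {missing}")
    scores = pairs["score"]
    if scores.isna().any():
        raise ValueError("unscored pair in prediction output")
    if ((scores < 0) | (scores > 1)).any():
        bad = scores[(scores < 0) | (scores > 1)].iloc[0]
        raise ValueError(f"prediction score outside [0, 1]: {bad}")
    out = (
        pairs.loc[:, list(PREDICTION_COLUMNS)]
        .sort_values(["chrom", "enh_start", "gene_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    out.to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
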