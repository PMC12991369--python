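"""Readers and writers for the plain-text formats used by TraDIS pipelines.

Gene annotations come in as GFF3 (a configurable feature type, ``gene`` by
default) or BED3+ (0-based half-open, converted to 1-based inclusive on read).
Insertion sites come in as TRANSIT-style variableStep wiggle or as a two-column
TSV (``position``, ``read_count``).  Parsers are strict and report the line
number of the first offending record.
"""

from __future__ import annotations

import os

import pandas as pd

from .genome import GeneAnnotation, GeneSet, InsertionSiteSet

__all__ = [
    "load_annotation",
    "write_annotation",
    "load_insertions",
    "write_insertions",
    "read_truth",
    "write_truth",
]

_ANNOT_EXT = {".gff": "gff3", ".gff3": "gff3", ".bed": "bed"}
_IS_EXT = {".wig": "wig", ".tsv": "tsv", ".txt": "tsv", ".csv": "tsv"}


def _sniff(path, table, kind):
    ext = os.path.splitext(str(path))[1].lower()
    if ext in table:
        return table[ext]
    raise ValueError(f"cannot infer {kind} format from extension {ext!r}; pass format=")


def _parse_gff3_attributes(field: str) -> dict:
    out = {}
    for item in field.strip().split(";"):
        if "=" in item:
            key, value = item.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def load_annotation(path, format=None, feature_type="gene", genome_length=None) -> GeneSet:
    """Load gene intervals from a GFF3 or BED file into a :class:`GeneSet`.

    GFF3 keeps only records whose type column equals ``feature_type``; the
    gene identifier is taken from the ``locus_tag``, ``ID``, ``Name`` or
    ``gene`` attribute (first present).  BED start coordinates are shifted
    from 0-based half-open to 1-based inclusive.
    """
    fmt = format or _sniff(path, _ANNOT_EXT, "annotation")
    if fmt not in {"gff3", "bed"}:
        raise ValueError(f"unknown annotation format {fmt!r}")
    genes = []
    seen = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "gff3":
                    if len(fields) < 9:
                        raise ValueError("expected 9 tab-separated columns")
                    if fields[2] != feature_type:
                        continue
                    start, end = int(fields[3]), int(fields[4])
                    strand = fields[6] if fields[6] in {"+", "-"} else "."
                    attrs = _parse_gff3_attributes(fields[8])
                    gene_id = next(
                        (attrs[k] for k in ("locus_tag", "ID", "Name", "gene") if k in attrs),
                        None,
                    )
                    if gene_id is None:
                        raise ValueError("no ID/Name/locus_tag/gene attribute")
                else:
                    if len(fields) < 3:
                        raise ValueError("expected at least 3 tab-separated columns")
                    start, end = int(fields[1]) + 1, int(fields[2])
                    gene_id = fields[3] if len(fields) > 3 and fields[3] else f"gene_{lineno}"
                    strand = fields[5] if len(fields) > 5 and fields[5] in {"+", "-"} else "."
                if gene_id in seen:
                    raise ValueError(f"duplicate gene_id {gene_id!r}")
                seen.add(gene_id)
                genes.append(GeneAnnotation(gene_id, start, end, strand))
            except (ValueError, IndexError) as err:
                raise ValueError(f"{path}: malformed {fmt} record at line {lineno}: {err}") from None
    if not genes:
        raise ValueError(f"{path}: no gene features")
    return GeneSet.from_records(genes, genome_length=genome_length)


def write_annotation(genes: GeneSet, path, format=None) -> None:
    """Write a :class:`GeneSet` as GFF3 or BED (round-trips with the loader)."""
    fmt = format or _sniff(path, _ANNOT_EXT, "annotation")
    with open(path, "w") as fh:
        if fmt == "gff3":
            fh.write("##gff-version 3\n")
            for g in genes:
                fh.write(
                    "genome\tconnis\tgene\t"
                    f"{g.start}\t{g.end}\t.\t{g.strand if g.strand in '+-' else '.'}\t.\t"
                    f"ID={g.gene_id};locus_tag={g.gene_id}\n"
                )
        elif fmt == "bed":
            for g in genes:
                strand = g.strand if g.strand in "+-" else "."
                fh.write(f"genome\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{strand}\n")
        else:
            raise ValueError(f"unknown annotation format {fmt!r}")


def load_insertions(path, format=None, genome_length=None) -> InsertionSiteSet:
    """Load insertion positions and read counts from wiggle or TSV.

    ``genome_length`` must be supplied unless the wiggle header carries a
    ``genome_length=`` hint.  Duplicate positions have their reads summed.
    """
    fmt = format or _sniff(path, _IS_EXT, "insertion")
    positions, counts = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if fmt == "wig" and (line.startswith("variableStep") or line.startswith("track")):
                for token in line.split():
                    if token.startswith("genome_length="):
                        genome_length = int(token.split("=", 1)[1])
                continue
            fields = line.replace(",", "\t").split()
            if fields[0].lower() in {"position", "pos"}:  # TSV header row
                continue
            try:
                pos = int(fields[0])
                count = int(fields[1]) if len(fields) > 1 else 1
            except ValueError:
                raise ValueError(
                    f"{path}: non-integer position/count at line {lineno}: {line!r}"
                ) from None
            positions.append(pos)
            counts.append(count)
            if pos < 1 or (genome_length is not None and pos > genome_length):
                raise ValueError(
                    f"{path}: position {pos} at line {lineno} outside genome "
                    f"[1, {genome_length}]"
                )
    if genome_length is None:
        raise ValueError("genome_length is required (not found in file header)")
    return InsertionSiteSet(genome_length, positions, counts)


def write_insertions(iss: InsertionSiteSet, path, format=None) -> None:
    """Write an insertion-site set as variableStep wiggle or TSV."""
    fmt = format or _sniff(path, _IS_EXT, "insertion")
    with open(path, "w") as fh:
        if fmt == "wig":
            fh.write(f"variableStep chrom=genome genome_length={iss.genome_length}\n")
            for pos, count in zip(iss.positions, iss.counts):
                fh.write(f"{pos} {count}\n")
        elif fmt == "tsv":
            fh.write("position\tread_count\n")
            for pos, count in zip(iss.positions, iss.counts):
                fh.write(f"{pos}\t{count}\n")
        else:
            raise ValueError(f"unknown insertion format {fmt!r}")


def write_truth(truth: pd.Series, path) -> None:
    """Write ground-truth labels (index gene_id, values essential/non-essential)."""
    df = pd.DataFrame({"gene_id": truth.index, "label": truth.values})
    df.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "label": str})
    if not {"gene_id", "label"}.issubset(df.columns):
        raise ValueError(f"{path}: truth TSV needs columns gene_id, label")
    return pd.Series(df["label"].values, index=df["gene_id"].values, name="label")
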