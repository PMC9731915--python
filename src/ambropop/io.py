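"""Readers and writers for the pipeline's file formats.

VCF 4.2 (GT only), FASTA, and header-row TSV tables. Readers validate
container invariants and fail loudly rather than coercing; read/write
round-trips are semantic identities (VCF header cosmetics aside).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import (MISSING, AnnotationMap, ExpressionMatrix,
                        GenotypeMatrix, ResistanceCatalog, SamplePanel,
                        TranscriptCollection, ValidationError)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------- VCF

def read_vcf(path: str | Path, panel: SamplePanel | None = None) -> GenotypeMatrix:
    """Read biallelic GT calls into a dosage matrix.

    Multiallelic records are dropped (with a logged count) — the upstream
    study removed putative tri-allelic variants as paralog-misalignment
    artefacts. ``./.`` genotypes become missing. If ``panel`` is given the
    matrix is restricted to (and ordered by) the panel's samples; a panel
    sample absent from the VCF header is a configuration error.
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as e:
        raise ValidationError(f"cannot parse VCF {path}: {e}") from e
    header_samples = list(vf.header.samples)
    if panel is not None:
        missing = [s for s in panel.sample_ids if s not in header_samples]
        if missing:
            raise ValidationError(
                f"panel samples absent from VCF header: {missing}")
        samples = list(panel.sample_ids)
    else:
        samples = header_samples
    col = [header_samples.index(s) for s in samples]

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[list[int]] = []
    n_multi = 0
    for rec in vf:
        alleles = rec.alts or ()
        if len(alleles) != 1:
            n_multi += 1
            continue
        gts = []
        for sname in header_samples:
            gt = rec.samples[sname].get("GT")
            if gt is None or any(a is None for a in gt):
                gts.append(MISSING)
            else:
                gts.append(int(sum(gt)))
        chroms.append(rec.chrom)
        poss.append(rec.pos)
        refs.append(rec.ref)
        alts.append(alleles[0])
        rows.append([gts[c] for c in col])
    if n_multi:
        log.info("read_vcf: dropped %d multiallelic records", n_multi)
    loci = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    dosage = (np.array(rows, dtype=np.int8) if rows
              else np.empty((0, len(samples)), dtype=np.int8))
    return GenotypeMatrix(loci, samples, dosage)


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Emit a minimal VCF 4.2 with a GT-only FORMAT column."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(matrix.loci["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        for i, row in enumerate(matrix.loci.itertuples(index=False)):
            gts = "\t".join(_GT_CODE[int(d)] for d in matrix.dosage[i])
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t.\tGT\t{gts}\n")


# -------------------------------------------------------------------- FASTA

def read_fasta(path: str | Path, label: str = "reference") -> TranscriptCollection:
    """Read FASTA; names are the first whitespace token; sequences upper-cased."""
    entries: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in entries:
            raise ValidationError(f"duplicate FASTA name {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValidationError(f"empty sequence for {rec.id!r}")
        entries[rec.id] = seq
    return TranscriptCollection(entries, label=label)


def write_fasta(collection: TranscriptCollection, path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in collection.entries.items()]
    SeqIO.write(records, str(path), "fasta")


# ------------------------------------------------------------------- tables

def _read_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns.duplicated().any():
        raise ValidationError(f"{path}: duplicate column names")
    return df


def read_panel(path: str | Path) -> SamplePanel:
    df = _read_tsv(path)
    for col in ("latitude", "longitude"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    if "replicate_group" in df.columns:
        df["replicate_group"] = df["replicate_group"].replace("", pd.NA)
    return SamplePanel(df)


def write_panel(panel: SamplePanel, path: str | Path) -> None:
    panel.table.to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a transcripts x samples TPM table (first column = transcript id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate transcript row {dup!r}")
    arr = df.apply(pd.to_numeric, errors="coerce")
    bad = arr.isna() & df.notna()
    if bad.any().any():
        row = bad.any(axis=1).idxmax()
        raise ValidationError(f"non-numeric TPM in row {row!r}")
    if arr.isna().any().any():
        row = arr.isna().any(axis=1).idxmax()
        raise ValidationError(f"missing TPM in row {row!r}")
    return ExpressionMatrix(arr)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="transcript_id")


def read_annotation(path: str | Path, descriptions_path: str | Path | None = None
                    ) -> AnnotationMap:
    """Read transcript -> term mapping (columns transcript_id, term_id[, description])."""
    df = _read_tsv(path)
    terms: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    for row in df.itertuples(index=False):
        terms.setdefault(row.transcript_id, set()).add(row.term_id)
        if hasattr(row, "description"):
            desc[row.term_id] = row.description
    if descriptions_path is not None:
        ddf = _read_tsv(descriptions_path)
        desc.update(dict(zip(ddf["term_id"], ddf["description"])))
    all_terms = set().union(*terms.values()) if terms else set()
    for t in all_terms - set(desc):
        desc[t] = t  # fall back to the id itself
    return AnnotationMap(terms, desc)


def write_annotation(ann: AnnotationMap, path: str | Path) -> None:
    rows = [(tr, term, ann.descriptions.get(term, term))
            for tr, ts in sorted(ann.terms.items()) for term in sorted(ts)]
    pd.DataFrame(rows, columns=["transcript_id", "term_id", "description"]) \
        .to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path) -> ResistanceCatalog:
    df = _read_tsv(path)
    df["codon"] = pd.to_numeric(df["codon"], errors="raise").astype(int)
    return ResistanceCatalog(df)


def write_catalog(catalog: ResistanceCatalog, path: str | Path) -> None:
    catalog.table.to_csv(path, sep="\t", index=False)
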