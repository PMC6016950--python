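"""Interchange formats: minimal trio VCF, FASTA, TSV tables, config files.

Every table is tab-separated with a header row; missing values are written
as ``NA``.  VCF positions are 1-based on disk and converted to the package's
0-based convention at this boundary.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError
from .phasing import Genotype, VariantTrioCall

TRIO_SAMPLES = ("parent1", "parent2", "hybrid")
NA = "NA"


# ---------------------------------------------------------------------------
# TSV tables

def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", na_rep=NA, index=index)


def read_counts(path) -> pd.DataFrame:
    """Gene x sample integer count table (first column gene_id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_sample_info(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_allele_counts(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", na_rep=NA, index=False)


def read_allele_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA])
    for col in ("derived_count", "ancestral_count", "unassigned_count"):
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    return df


def read_lengths(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].rename("length")


def read_exon_table(path) -> dict[str, dict[str, list[tuple[int, int]]]]:
    """BED-like exon table: columns gene, isoform, start, end (0-based,
    half-open).  Returns gene -> isoform -> interval list."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "isoform", "start", "end"}
    if not required.issubset(df.columns):
        raise ParseError(f"exon table must have columns {sorted(required)}")
    out: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.gene, {}).setdefault(str(row.isoform), []).append(
            (int(row.start), int(row.end))
        )
    return out


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# minimal trio VCF

def _format_gt(gt: Genotype) -> str:
    if gt is None:
        return "./."
    return f"{gt[0]}/{gt[1]}"


def write_vcf(
    calls: Iterable[VariantTrioCall],
    path,
    sample_names: Sequence[str] = TRIO_SAMPLES,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write trio calls as a minimal VCF v4.2 (GT genotypes only).

    Contigs are transcript (gene) identifiers; internal 0-based positions
    become 1-based POS fields.
    """
    calls = list(calls)
    if contig_lengths is None:
        contig_lengths = {}
        for c in calls:
            contig_lengths[c.gene_id] = max(contig_lengths.get(c.gene_id, 0), c.pos + 1)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=regdiv\n")
        for contig in sorted(contig_lengths):
            fh.write(f"##contig=<ID={contig},length={contig_lengths[contig]}>\n")
        fh.write('##INFO=<ID=KIND,Number=1,Type=String,Description="Generator label">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        for c in sorted(calls, key=lambda c: (c.gene_id, c.pos)):
            info = f"KIND={c.kind}" if c.kind else "."
            fields = [
                c.gene_id,
                str(c.pos + 1),
                ".",
                c.ref,
                c.alt,
                ".",
                ".",
                info,
                "GT",
                _format_gt(c.gt_parent1),
                _format_gt(c.gt_parent2),
                _format_gt(c.gt_hybrid),
            ]
            fh.write("\t".join(fields) + "\n")


def _gt_from_record(sample) -> Genotype:
    alleles = sample.get("GT")
    if alleles is None or any(a is None for a in alleles):
        return None
    if len(alleles) == 1:
        return (int(alleles[0]), int(alleles[0]))
    return (int(alleles[0]), int(alleles[1]))


def read_vcf(path, sample_names: Sequence[str] = TRIO_SAMPLES) -> list[VariantTrioCall]:
    """Read trio calls from a VCF v4.2 file (GT subfield only).

    Positions are converted to 0-based.  Multiallelic records are retained
    (they are removed later by the informativeness filter).  A malformed data
    line raises :class:`ParseError` carrying its 1-based line number; a
    missing sample raises ``KeyError`` naming it.
    """
    import pysam

    with open(path) as fh:
        n_header = 0
        for line in fh:
            if line.startswith("#"):
                n_header += 1
            else:
                break

    with pysam.VariantFile(str(path)) as vcf:
        present = list(vcf.header.samples)
        for name in sample_names:
            if name not in present:
                raise KeyError(f"sample {name!r} missing from VCF (has {present})")
        calls: list[VariantTrioCall] = []
        n_records = 0
        iterator = iter(vcf)
        while True:
            try:
                rec = next(iterator)
            except StopIteration:
                break
            except Exception as exc:  # malformed data line
                raise ParseError(str(exc), line=n_header + n_records + 1) from exc
            n_records += 1
            try:
                kind = ""
                if "KIND" in vcf.header.info:
                    kind = rec.info.get("KIND", "") or ""
                if isinstance(kind, tuple):
                    kind = kind[0] if kind else ""
                calls.append(
                    VariantTrioCall(
                        gene_id=rec.chrom,
                        pos=rec.pos - 1,
                        ref=rec.ref,
                        alt=",".join(rec.alts) if rec.alts else ".",
                        gt_parent1=_gt_from_record(rec.samples[sample_names[0]]),
                        gt_parent2=_gt_from_record(rec.samples[sample_names[1]]),
                        gt_hybrid=_gt_from_record(rec.samples[sample_names[2]]),
                        kind=str(kind or ""),
                    )
                )
            except (ValueError, TypeError, IndexError) as exc:
                raise ParseError(str(exc), line=n_header + n_records) from exc
    return calls


# ---------------------------------------------------------------------------
# key = value config files

def read_config(path) -> dict[str, str]:
    """Parse a ``key = value`` config file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"expected 'key = value', got {raw.strip()!r}", line=i)
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def write_config(values: Mapping[str, object], path) -> None:
    with open(path, "w") as fh:
        for key, value in values.items():
            fh.write(f"{key} = {value}\n")


def ensure_dir(path) -> Path:
    p = Path(path)
    os.makedirs(p, exist_ok=True)
    return p
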