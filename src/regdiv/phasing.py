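"""Phasing of F1-hybrid reads onto per-allele pseudo-transcriptomes.

In an F1 hybrid between two populations, a read can be attributed to the
allele it came from only if it overlaps a site where the two parental alleles
differ.  This module builds, for each gene, the pair of predicted allele
sequences (a *pseudo-transcriptome*): the reference transcript with the
derived parent's allele substituted at every informative site on one copy and
the ancestral parent's allele on the other.  Reads are then assigned to the
unique allele they match exactly, mirroring a unique-mapping criterion: a
read counts toward an allele only if it overlaps at least one informative
site and is consistent with exactly one of the two allele sequences.

Conventions
-----------
* All coordinates are 0-based, half-open.  VCF input (1-based) is converted
  at the parser boundary (:mod:`regdiv.io`).
* Substitution variants only; records whose REF or ALT is not a single base
  are rejected with a warning at pseudo-transcriptome construction.
* ``parent1`` is the derived-population parent, ``parent2`` the ancestral one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataIntegrityError

Genotype = tuple[int, int] | None  # allele indices into [ref] + alts, or missing


@dataclass(frozen=True)
class VariantTrioCall:
    """One variant with unphased genotypes for both parents and their F1.

    ``alt`` may contain several comma-separated alleles; such multiallelic
    records are carried through parsing but never treated as informative.
    ``kind`` is a free-text provenance label (used by the simulator to mark
    decoy records); the informativeness filter ignores it.
    """

    gene_id: str
    pos: int  # 0-based transcript coordinate
    ref: str
    alt: str
    gt_parent1: Genotype
    gt_parent2: Genotype
    gt_hybrid: Genotype
    kind: str = ""

    @property
    def is_multiallelic(self) -> bool:
        return "," in self.alt

    def alleles(self) -> list[str]:
        return [self.ref] + self.alt.split(",")


@dataclass(frozen=True)
class PseudoTranscriptome:
    """Predicted sequence of each allele of one gene in one F1 hybrid."""

    gene_id: str
    derived_seq: str
    ancestral_seq: str
    informative_positions: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if len(self.derived_seq) != len(self.ancestral_seq):
            raise DataIntegrityError(
                f"{self.gene_id}: allele sequences differ in length "
                "(only substitution variants are supported)"
            )


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of a gene with all isoforms collapsed to one transcript."""

    gene_id: str
    isoforms: Mapping[str, tuple[tuple[int, int], ...]]
    collapsed: tuple[tuple[int, int], ...]

    @property
    def collapsed_length(self) -> int:
        return sum(end - start for start, end in self.collapsed)


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"invalid half-open interval [{s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def collapse_isoforms(
    gene_id: str, isoform_exons: Mapping[str, Iterable[tuple[int, int]]]
) -> GeneModel:
    """Collapse all isoforms of a gene into the union of their exon intervals.

    Parameters
    ----------
    isoform_exons
        Mapping of isoform name to its exon intervals (0-based, half-open).

    Returns
    -------
    GeneModel with ``collapsed`` equal to the sorted, non-overlapping union.
    """
    if not isoform_exons:
        raise ValueError(f"{gene_id}: no isoforms to collapse")
    isoforms = {
        name: tuple(sorted((int(s), int(e)) for s, e in exons))
        for name, exons in isoform_exons.items()
    }
    if any(len(ex) == 0 for ex in isoforms.values()):
        raise ValueError(f"{gene_id}: isoform with no exons")
    union = _merge_intervals(iv for exons in isoforms.values() for iv in exons)
    return GeneModel(gene_id=gene_id, isoforms=isoforms, collapsed=union)


def _is_hom(gt: Genotype) -> bool:
    return gt is not None and gt[0] == gt[1]


def _is_het(gt: Genotype) -> bool:
    return gt is not None and gt[0] != gt[1]


def is_informative(call: VariantTrioCall) -> bool:
    """A call is informative iff both parents are homozygous for different
    alleles and the F1 is heterozygous; multiallelic and missing-genotype
    records never qualify."""
    if call.is_multiallelic:
        return False
    if call.gt_parent1 is None or call.gt_parent2 is None or call.gt_hybrid is None:
        return False
    return (
        _is_hom(call.gt_parent1)
        and _is_hom(call.gt_parent2)
        and call.gt_parent1[0] != call.gt_parent2[0]
        and _is_het(call.gt_hybrid)
    )


def select_informative_variants(calls: Iterable[VariantTrioCall]) -> list[VariantTrioCall]:
    """Keep exactly the trio calls usable for allele assignment.

    Filtering is idempotent and silently drops non-qualifying records.
    """
    return [c for c in calls if is_informative(c)]


def build_pseudotranscriptome(
    gene_id: str,
    sequence: str,
    variants: Sequence[VariantTrioCall],
    derived_parent: str = "parent1",
) -> PseudoTranscriptome:
    """Substitute informative variants into a transcript to get both alleles.

    The derived-allele sequence carries the derived parent's homozygous allele
    at every informative position; the ancestral-allele sequence carries the
    other parent's.  Non-informative records are ignored; records with
    non-single-base alleles are skipped with a warning (substitutions only).

    Raises
    ------
    DataIntegrityError
        If a variant's REF base does not match ``sequence`` at its position.
    """
    if derived_parent not in ("parent1", "parent2"):
        raise ValueError("derived_parent must be 'parent1' or 'parent2'")
    derived = list(sequence)
    ancestral = list(sequence)
    positions: list[int] = []
    for call in variants:
        if not is_informative(call):
            continue
        alleles = call.alleles()
        if any(len(a) != 1 for a in alleles):
            warnings.warn(
                f"{gene_id}:{call.pos}: indel variant skipped (substitutions only)",
                stacklevel=2,
            )
            continue
        if not 0 <= call.pos < len(sequence):
            raise DataIntegrityError(f"{gene_id}:{call.pos}: position outside transcript")
        if sequence[call.pos].upper() != call.ref.upper():
            raise DataIntegrityError(
                f"{gene_id}:{call.pos}: REF {call.ref!r} does not match transcript "
                f"base {sequence[call.pos]!r}"
            )
        gt_derived = call.gt_parent1 if derived_parent == "parent1" else call.gt_parent2
        gt_ancestral = call.gt_parent2 if derived_parent == "parent1" else call.gt_parent1
        derived[call.pos] = alleles[gt_derived[0]]
        ancestral[call.pos] = alleles[gt_ancestral[0]]
        positions.append(call.pos)
    return PseudoTranscriptome(
        gene_id=gene_id,
        derived_seq="".join(derived),
        ancestral_seq="".join(ancestral),
        informative_positions=tuple(sorted(positions)),
    )


def _occurrences(haystack: str, needle: str) -> list[int]:
    out, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def assign_read(
    read: str, pseudo: PseudoTranscriptome
) -> str:
    """Assign a read to ``'derived'``, ``'ancestral'`` or ``'unassigned'``.

    The read is placed by exact-substring search over both allele sequences.
    It is assigned iff, across all candidate placements, it overlaps at least
    one informative position and matches exactly one allele there (and is
    consistent with that allele at every overlapped informative site — an
    exact substring match guarantees this).  Reads overlapping no informative
    site, matching both alleles, or supporting conflicting alleles at
    different placements are unassigned.
    """
    if not read:
        return "unassigned"
    positions = pseudo.informative_positions
    length = len(read)
    votes: set[str] = set()
    for allele, seq in (("derived", pseudo.derived_seq), ("ancestral", pseudo.ancestral_seq)):
        for start in _occurrences(seq, read):
            if any(start <= p < start + length for p in positions):
                votes.add(allele)
    if len(votes) == 1:
        return votes.pop()
    return "unassigned"


def count_allelic_reads(
    reads_by_replicate: Mapping[str, Iterable],
    pseudotranscriptomes: Mapping[str, PseudoTranscriptome],
) -> pd.DataFrame:
    """Count reads assigned to each allele, per gene and replicate.

    Parameters
    ----------
    reads_by_replicate
        Mapping of replicate name to an iterable of reads.  Each read must
        have ``gene_id`` and ``sequence`` attributes (e.g.
        :class:`regdiv.simulate.SimulatedRead`) or be a ``(gene_id, sequence)``
        pair.
    pseudotranscriptomes
        Per-gene allele sequence pairs.

    Returns
    -------
    Long-format table with columns ``gene_id, replicate, derived_count,
    ancestral_count, unassigned_count``.  Genes present in
    ``pseudotranscriptomes`` but receiving no reads in a replicate appear
    with zero counts, so downstream pooling sees every gene.
    """
    rows = []
    for replicate, reads in reads_by_replicate.items():
        counts: dict[str, list[int]] = {g: [0, 0, 0] for g in pseudotranscriptomes}
        for read in reads:
            if hasattr(read, "gene_id"):
                gene, seq = read.gene_id, read.sequence
            else:
                gene, seq = read
            pseudo = pseudotranscriptomes.get(gene)
            if pseudo is None:
                continue
            bucket = assign_read(seq, pseudo)
            idx = {"derived": 0, "ancestral": 1, "unassigned": 2}[bucket]
            counts[gene][idx] += 1
        for gene, (d, a, u) in counts.items():
            rows.append((gene, replicate, d, a, u))
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "replicate", "derived_count", "ancestral_count", "unassigned_count"],
    )
    return out.sort_values(["gene_id", "replicate"], ignore_index=True)
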