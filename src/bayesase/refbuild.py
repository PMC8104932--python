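"""Genotype-specific reference construction.

Alignment of F1 reads against the common reference is biased toward the
reference allele at every heterozygous site.  Building one reference per
parental line, with that line's SNP alleles substituted in, removes most of
this bias while preserving coordinates, so downstream feature intervals and
per-read positions remain comparable between the two parental genomes.

Only biallelic single-nucleotide substitutions are applied.  Indels,
multiallelic sites, heterozygous calls (evidence of error in an inbred
line), reference mismatches and records on unknown chromosomes are skipped
with a machine-readable reason and logged.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import pysam
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

_NUCLEOTIDES = frozenset("ACGT")

# skip reasons
REASON_INDEL = "indel"
REASON_MULTIALLELIC = "multiallelic"
REASON_REF_MISMATCH = "ref-mismatch"
REASON_UNKNOWN_CHROM = "unknown-chrom"
REASON_HET_CALL = "het-call"
REASON_NON_ACGT = "non-acgt"


@dataclass(frozen=True)
class VariantRecord:
    """A single VCF record attributed to one parental line.

    ``pos`` follows the VCF convention (1-based).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype_id: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"VCF positions are 1-based; got pos={self.pos}")


@dataclass
class SkippedVariant:
    record: VariantRecord
    reason: str


@dataclass
class GenotypeReference:
    """Per-line reference: same sequence names and lengths as the input."""

    genotype_id: str
    sequences: dict[str, str]
    applied_count: int = 0
    skipped_count: int = 0
    log: list[tuple[VariantRecord, str, str]] = field(default_factory=list)


def read_vcf(path: str | os.PathLike, genotype_id: str) -> list[VariantRecord]:
    """Read variants for one line from an (uncompressed or bgzipped) VCF.

    Only CHROM, POS, REF, ALT and the genotype call of the single sample (if
    a sample column is present) are consulted.  Heterozygous calls and
    records whose sample genotype carries no alternate allele are returned
    with ref==alt so that :func:`filter_variants` can classify them; simpler
    here is to filter them out directly with a het-call reason, which is what
    the caller receives via :func:`filter_variants`.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            # pick a single alt for representation; multiallelic records are
            # rejected later in filter_variants on the stored alt string
            alt = ",".join(alts) if alts else "."
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref or ".",
                    alt=alt,
                    genotype_id=genotype_id,
                )
            )
    return records


def _het_calls(path: str | os.PathLike) -> set[tuple[str, int]]:
    """Positions whose single-sample genotype is heterozygous."""
    het: set[tuple[str, int]] = set()
    with pysam.VariantFile(os.fspath(path)) as vcf:
        if not list(vcf.header.samples):
            return het
        sample = list(vcf.header.samples)[0]
        vcf.reset()
        for rec in vcf:
            gt = rec.samples[sample].get("GT")
            if gt is None:
                continue
            alleles = [a for a in gt if a is not None]
            if len(set(alleles)) > 1:
                het.add((rec.chrom, rec.pos))
    return het


def filter_variants(
    records: list[VariantRecord],
    reference: dict[str, str],
    het_positions: set[tuple[str, int]] | None = None,
) -> tuple[list[VariantRecord], list[SkippedVariant]]:
    """Keep biallelic SNPs consistent with the reference; skip the rest.

    Returns ``(kept, skipped)`` where each skipped entry carries a reason in
    {indel, multiallelic, ref-mismatch, unknown-chrom, het-call, non-acgt}.
    """
    het_positions = het_positions or set()
    kept: list[VariantRecord] = []
    skipped: list[SkippedVariant] = []
    for rec in records:
        if (rec.chrom, rec.pos) in het_positions:
            skipped.append(SkippedVariant(rec, REASON_HET_CALL))
            continue
        if "," in rec.alt:
            skipped.append(SkippedVariant(rec, REASON_MULTIALLELIC))
            continue
        if len(rec.ref) != 1 or len(rec.alt) != 1 or rec.alt in (".", "*"):
            skipped.append(SkippedVariant(rec, REASON_INDEL))
            continue
        if rec.ref.upper() not in _NUCLEOTIDES or rec.alt.upper() not in _NUCLEOTIDES:
            skipped.append(SkippedVariant(rec, REASON_NON_ACGT))
            continue
        if rec.chrom not in reference:
            logger.warning(
                "variant %s:%d refers to a chromosome absent from the reference",
                rec.chrom,
                rec.pos,
            )
            skipped.append(SkippedVariant(rec, REASON_UNKNOWN_CHROM))
            continue
        seq = reference[rec.chrom]
        if rec.pos > len(seq) or seq[rec.pos - 1].upper() != rec.ref.upper():
            skipped.append(SkippedVariant(rec, REASON_REF_MISMATCH))
            continue
        kept.append(rec)
    return kept, skipped


def build_genotype_reference(
    reference: dict[str, str],
    variants: list[VariantRecord],
    genotype_id: str,
    skipped: list[SkippedVariant] | None = None,
) -> GenotypeReference:
    """Substitute each kept SNP's alt base into the reference.

    SNP-only edits preserve sequence lengths, which licenses the shared
    coordinate system used by read counting.  Two variants at the same
    position with different alt alleles are a collision and an error.
    Substitution is case-insensitive on the reference (soft-masked bases
    accepted); the edited position is emitted uppercase.
    """
    seen: dict[tuple[str, int], str] = {}
    by_chrom: dict[str, list[VariantRecord]] = {}
    for v in variants:
        key = (v.chrom, v.pos)
        if key in seen and seen[key] != v.alt.upper():
            raise ValueError(
                f"conflicting variants at {v.chrom}:{v.pos}: "
                f"alt {seen[key]!r} vs {v.alt!r}"
            )
        seen[key] = v.alt.upper()
        by_chrom.setdefault(v.chrom, []).append(v)

    sequences: dict[str, str] = {}
    applied = 0
    for name, seq in reference.items():
        chars = list(seq)
        for v in by_chrom.get(name, []):
            if seq[v.pos - 1].upper() != v.ref.upper():
                raise ValueError(
                    f"variant {v.chrom}:{v.pos} ref {v.ref!r} does not match "
                    f"reference base {seq[v.pos - 1]!r}"
                )
            chars[v.pos - 1] = v.alt.upper()
            applied += 1
        sequences[name] = "".join(chars)

    out = GenotypeReference(
        genotype_id=genotype_id,
        sequences=sequences,
        applied_count=applied,
        skipped_count=len(skipped or []),
    )
    for v in variants:
        out.log.append((v, "applied", ""))
    for s in skipped or []:
        out.log.append((s.record, "skipped", s.reason))
    return out


def call_differences(
    original: dict[str, str], edited: dict[str, str]
) -> list[tuple[str, int, str, str]]:
    """List (chrom, pos, ref, alt) where the two sequence sets differ.

    The round-trip check for SNP application: differences between an edited
    genotype reference and its input recover exactly the applied variants.
    """
    diffs: list[tuple[str, int, str, str]] = []
    for name, seq in original.items():
        other = edited[name]
        if len(seq) != len(other):
            raise ValueError(f"length changed for {name}; SNP-only edits expected")
        for i, (a, b) in enumerate(zip(seq, other)):
            if a.upper() != b.upper():
                diffs.append((name, i + 1, a.upper(), b.upper()))
    return diffs


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load a (small) multi-FASTA into memory as name -> sequence."""
    fa = Fasta(os.fspath(path), as_raw=True, sequence_always_upper=False)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: dict[str, str], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_variant_log(ref: GenotypeReference, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tstatus\treason\n")
        for rec, status, reason in ref.log:
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.ref}\t{rec.alt}\t{status}\t{reason}\n")


def build_from_files(
    fasta_path: str | os.PathLike,
    vcf_path: str | os.PathLike,
    genotype_id: str,
    out_dir: str | os.PathLike,
) -> GenotypeReference:
    """File-level driver: FASTA + VCF -> <genotype_id>.fasta plus a TSV log."""
    reference = read_fasta(fasta_path)
    records = read_vcf(vcf_path, genotype_id)
    het = _het_calls(vcf_path)
    kept, skipped = filter_variants(records, reference, het)
    result = build_genotype_reference(reference, kept, genotype_id, skipped)
    os.makedirs(out_dir, exist_ok=True)
    write_fasta(result.sequences, os.path.join(out_dir, f"{genotype_id}.fasta"))
    write_variant_log(result, os.path.join(out_dir, f"{genotype_id}.variant_log.tsv"))
    return result
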