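"""Dual-alignment comparison and per-feature allele counting.

Each read of an F1 sample is aligned (upstream, e.g. with BWA-MEM) against
both parental genotype references.  Here the two alignment files are
compared read by read: a read mapping better to one genome is informative
for that allele, a read mapping equally well to both is ambiguous.  Counts
are accumulated per feature interval (BED), technical replicates are
summed, and features with few informative reads are flagged.

Equality of mapping quality is judged on the aligner's alignment-score tag
(AS) when present, falling back to MAPQ; a tie at the finest available
criterion is AMBIGUOUS.
"""

from __future__ import annotations

import enum
import os
from bisect import bisect_right
from dataclasses import dataclass, replace
from typing import Iterable, Iterator

import pandas as pd
import pysam

COUNT_COLUMNS = [
    "FEATURE_ID",
    "CROSS",
    "CONDITION",
    "REP",
    "COUNT_G1",
    "COUNT_G2",
    "COUNT_AMBIG",
    "FLAG_LOW_COVERAGE",
]


class Assignment(enum.Enum):
    ALLELE1 = "ALLELE1"
    ALLELE2 = "ALLELE2"
    AMBIGUOUS = "AMBIGUOUS"
    UNMAPPED = "UNMAPPED"


@dataclass(frozen=True)
class FeatureInterval:
    """A BED feature: 0-based half-open [start, end)."""

    feature_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"feature {self.feature_id}: start must be < end "
                f"({self.start} >= {self.end})"
            )


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    assignment: Assignment
    position: tuple[str, int] | None  # (chrom, leftmost 0-based) or None if unmapped
    score1: float | None = None
    score2: float | None = None


@dataclass(frozen=True)
class AlleleCountRecord:
    """Informative (x, y) and ambiguous (z) read counts for one unit."""

    feature_id: str
    cross_id: str
    condition_id: str
    rep_id: str
    x: int
    y: int
    z: int
    flag_low_coverage: int = 0

    def __post_init__(self) -> None:
        if min(self.x, self.y, self.z) < 0:
            raise ValueError("counts must be nonnegative")


@dataclass(frozen=True)
class _Aln:
    """The slice of an alignment record the classifier needs."""

    read_id: str
    chrom: str
    pos: int  # leftmost 0-based
    mapq: int
    score: float | None  # AS tag, if the aligner set one


def _score_key(aln: _Aln) -> float:
    return aln.score if aln.score is not None else float(aln.mapq)


def classify_read(aln1: _Aln | None, aln2: _Aln | None) -> ReadAssignment:
    """Assign a read to an allele from its best alignment in each genome.

    Mapped in one genome only -> that allele; in both -> the higher-scoring
    one, ties AMBIGUOUS; in neither -> UNMAPPED.
    """
    if aln1 is not None and aln2 is not None and aln1.read_id != aln2.read_id:
        raise ValueError(
            f"read identifiers differ between alignments: "
            f"{aln1.read_id!r} vs {aln2.read_id!r}"
        )
    if aln1 is None and aln2 is None:
        return ReadAssignment("" if aln1 is None else aln1.read_id, Assignment.UNMAPPED, None)
    if aln2 is None:
        assert aln1 is not None
        return ReadAssignment(
            aln1.read_id, Assignment.ALLELE1, (aln1.chrom, aln1.pos), score1=_score_key(aln1)
        )
    if aln1 is None:
        return ReadAssignment(
            aln2.read_id, Assignment.ALLELE2, (aln2.chrom, aln2.pos), score2=_score_key(aln2)
        )
    s1, s2 = _score_key(aln1), _score_key(aln2)
    if s1 > s2:
        assignment = Assignment.ALLELE1
        pos = (aln1.chrom, aln1.pos)
    elif s2 > s1:
        assignment = Assignment.ALLELE2
        pos = (aln2.chrom, aln2.pos)
    else:
        # equal scores: ambiguous; genome-1 coordinates are representative
        # (valid in the shared system because refbuild preserves coordinates)
        assignment = Assignment.AMBIGUOUS
        pos = (aln1.chrom, aln1.pos)
    return ReadAssignment(aln1.read_id, assignment, pos, score1=s1, score2=s2)


class _FeatureIndex:
    """Point lookup over non-overlapping half-open intervals per chromosome."""

    def __init__(self, features: Iterable[FeatureInterval]):
        by_chrom: dict[str, list[FeatureInterval]] = {}
        for f in features:
            by_chrom.setdefault(f.chrom, []).append(f)
        self._starts: dict[str, list[int]] = {}
        self._feats: dict[str, list[FeatureInterval]] = {}
        for chrom, feats in by_chrom.items():
            feats.sort(key=lambda f: (f.start, f.end))
            for a, b in zip(feats, feats[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping features on {chrom}: "
                        f"{a.feature_id} [{a.start},{a.end}) and "
                        f"{b.feature_id} [{b.start},{b.end})"
                    )
            self._starts[chrom] = [f.start for f in feats]
            self._feats[chrom] = feats

    def lookup(self, chrom: str, pos: int) -> FeatureInterval | None:
        starts = self._starts.get(chrom)
        if not starts:
            return None
        i = bisect_right(starts, pos) - 1
        if i < 0:
            return None
        f = self._feats[chrom][i]
        return f if pos < f.end else None


def count_by_feature(
    assignments: Iterable[ReadAssignment], features: list[FeatureInterval]
) -> dict[str, tuple[int, int, int]]:
    """Accumulate (x, y, z) per feature from classified reads.

    A read increments the single feature containing its leftmost aligned
    coordinate; reads outside every feature, and UNMAPPED reads, increment
    nothing.  Features without reads appear with (0, 0, 0).  Overlapping
    features are refused (ambiguous attribution would break the
    one-increment-per-read conservation the count model relies on).
    """
    ids = [f.feature_id for f in features]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValueError(f"duplicate feature_id in BED: {dup!r}")
    index = _FeatureIndex(features)
    counts: dict[str, list[int]] = {f.feature_id: [0, 0, 0] for f in features}
    for ra in assignments:
        if ra.assignment is Assignment.UNMAPPED or ra.position is None:
            continue
        feat = index.lookup(*ra.position)
        if feat is None:
            continue
        slot = {
            Assignment.ALLELE1: 0,
            Assignment.ALLELE2: 1,
            Assignment.AMBIGUOUS: 2,
        }[ra.assignment]
        counts[feat.feature_id][slot] += 1
    return {fid: tuple(c) for fid, c in counts.items()}  # type: ignore[misc]


def sum_technical_replicates(records: list[AlleleCountRecord]) -> AlleleCountRecord:
    """Elementwise sum of technical replicates of one feature/cross/condition."""
    if not records:
        raise ValueError("cannot sum an empty replicate list")
    first = records[0]
    for r in records[1:]:
        if (r.feature_id, r.cross_id, r.condition_id) != (
            first.feature_id,
            first.cross_id,
            first.condition_id,
        ):
            raise ValueError("technical replicates must share feature, cross and condition")
    return AlleleCountRecord(
        feature_id=first.feature_id,
        cross_id=first.cross_id,
        condition_id=first.condition_id,
        rep_id=first.rep_id,
        x=sum(r.x for r in records),
        y=sum(r.y for r in records),
        z=sum(r.z for r in records),
    )


def flag_coverage(record: AlleleCountRecord, threshold: int) -> AlleleCountRecord:
    """Flag a record whose informative coverage x + y falls below threshold."""
    if threshold < 0:
        raise ValueError("coverage threshold must be nonnegative")
    return replace(record, flag_low_coverage=int(record.x + record.y < threshold))


# ---------------------------------------------------------------------------
# SAM-level driver


def _best_primary_alignments(sam_path: str | os.PathLike) -> dict[str, _Aln]:
    """Best primary alignment per read name from a SAM/BAM file."""
    best: dict[str, _Aln] = {}
    with pysam.AlignmentFile(os.fspath(sam_path), check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            score = rec.get_tag("AS") if rec.has_tag("AS") else None
            aln = _Aln(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                pos=rec.reference_start,
                mapq=rec.mapping_quality,
                score=float(score) if score is not None else None,
            )
            prev = best.get(rec.query_name)
            if prev is None or _score_key(aln) > _score_key(prev):
                best[rec.query_name] = aln
    return best


def _all_read_names(sam_path: str | os.PathLike) -> set[str]:
    names: set[str] = set()
    with pysam.AlignmentFile(os.fspath(sam_path), check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary:
                continue
            names.add(rec.query_name)
    return names


def classify_sam_pair(
    sam1: str | os.PathLike, sam2: str | os.PathLike
) -> Iterator[ReadAssignment]:
    """Classify every read appearing in either alignment file."""
    best1 = _best_primary_alignments(sam1)
    best2 = _best_primary_alignments(sam2)
    names = _all_read_names(sam1) | _all_read_names(sam2)
    for name in sorted(names):
        a1, a2 = best1.get(name), best2.get(name)
        ra = classify_read(a1, a2)
        if ra.assignment is Assignment.UNMAPPED:
            yield ReadAssignment(name, Assignment.UNMAPPED, None)
        else:
            yield ra


def read_bed(path: str | os.PathLike) -> list[FeatureInterval]:
    """Parse a labeled BED file (chrom, start, end, name)."""
    feats: list[FeatureInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError("BED file must carry a feature label in column 4")
            feats.append(
                FeatureInterval(
                    feature_id=parts[3], chrom=parts[0], start=int(parts[1]), end=int(parts[2])
                )
            )
    return feats


def counts_to_frame(records: Iterable[AlleleCountRecord]) -> pd.DataFrame:
    rows = [
        (r.feature_id, r.cross_id, r.condition_id, r.rep_id, r.x, r.y, r.z, r.flag_low_coverage)
        for r in records
    ]
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def frame_to_counts(df: pd.DataFrame) -> list[AlleleCountRecord]:
    return [
        AlleleCountRecord(
            feature_id=str(r.FEATURE_ID),
            cross_id=str(r.CROSS),
            condition_id=str(r.CONDITION),
            rep_id=str(r.REP),
            x=int(r.COUNT_G1),
            y=int(r.COUNT_G2),
            z=int(r.COUNT_AMBIG),
            flag_low_coverage=int(r.FLAG_LOW_COVERAGE),
        )
        for r in df.itertuples(index=False)
    ]


def sam_compare(
    sam1: str | os.PathLike,
    sam2: str | os.PathLike,
    bed: str | os.PathLike,
    cross_id: str = "cross",
    condition_id: str = "cond",
    rep_id: str = "1",
    min_coverage: int = 0,
) -> pd.DataFrame:
    """Full per-sample pipeline: classify, count per feature, flag coverage."""
    features = read_bed(bed)
    counts = count_by_feature(list(classify_sam_pair(sam1, sam2)), features)
    records = []
    for f in features:
        x, y, z = counts[f.feature_id]
        rec = AlleleCountRecord(f.feature_id, cross_id, condition_id, rep_id, x, y, z)
        records.append(flag_coverage(rec, min_coverage))
    return counts_to_frame(records)
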