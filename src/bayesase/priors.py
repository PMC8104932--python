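"""Mapping-bias prior estimation.

The Bayesian model needs, per feature and condition, q1 — the probability
that a read originating from genome 1 maps better to genome 1 than to
genome 2 — and the analogous q2.  These encode mapping bias in the absence
of allelic imbalance and can be estimated from reads whose allelic origin
is known: reads simulated separately from each genotype reference, or
genomic DNA of the F1 where the true allele ratio is 1:1.

Estimates are point values plugged into the model as constants, clipped
into (EPS, 1 - EPS) to respect the open constraint 0 < q1, q2 < 1.

An "rna" mode is named as a possible source by the overall design but no
estimator is provided: RNA counts confound allelic imbalance with mapping
bias, so no unbiased moment estimator exists without outside information.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .alncount import AlleleCountRecord

logger = logging.getLogger(__name__)

EPS = 1e-3

PRIOR_COLUMNS = ["FEATURE_ID", "CONDITION", "Q1", "Q2", "SOURCE"]


@dataclass(frozen=True)
class PriorSpec:
    feature_id: str
    condition_id: str
    q1: float
    q2: float
    source: str  # dna | simulation | rna | default

    def __post_init__(self) -> None:
        if not (0.0 < self.q1 < 1.0 and 0.0 < self.q2 < 1.0):
            raise ValueError("q1 and q2 must lie strictly inside (0, 1)")


def clip_probability(p: float, eps: float = EPS) -> float:
    """Clip an estimate into [eps, 1 - eps]."""
    return min(max(p, eps), 1.0 - eps)


def estimate_priors_from_simulation(
    counts_g1_origin: tuple[int, int],
    counts_g2_origin: tuple[int, int],
    feature_id: str = "",
    condition_id: str = "",
) -> PriorSpec:
    """Direct proportion estimator from reads of known origin.

    ``counts_g1_origin`` is (number of genome-1-origin reads whose best
    alignment is to genome 1, total mapped genome-1-origin reads); the
    second pair analogously for genome 2.
    """
    (best1, total1), (best2, total2) = counts_g1_origin, counts_g2_origin
    if total1 <= 0 or total2 <= 0:
        raise ValueError("zero mapped reads; omit this feature and fall back to defaults")
    return PriorSpec(
        feature_id=feature_id,
        condition_id=condition_id,
        q1=clip_probability(best1 / total1),
        q2=clip_probability(best2 / total2),
        source="simulation",
    )


def estimate_priors_from_f1_dna(record: AlleleCountRecord) -> PriorSpec:
    """Method-of-moments estimator from F1 genomic DNA counts.

    In DNA the two alleles are present 1:1, so each read originates from
    allele g with probability 1/2 and is informative to genome g with
    probability q_g, else ambiguous.  Hence E[x] = N q1 / 2 and
    E[y] = N q2 / 2 with N = x + y + z, giving q1 = 2x/N and q2 = 2y/N.
    """
    n = record.x + record.y + record.z
    if n <= 0:
        raise ValueError("zero total reads; omit this feature and fall back to defaults")
    q1_raw, q2_raw = 2 * record.x / n, 2 * record.y / n
    if q1_raw > 1.0 or q2_raw > 1.0:
        logger.warning(
            "feature %s: moment estimate exceeds 1 (q1=%.3f, q2=%.3f); "
            "counts violate the generative model, clipping",
            record.feature_id,
            q1_raw,
            q2_raw,
        )
    return PriorSpec(
        feature_id=record.feature_id,
        condition_id=record.condition_id,
        q1=clip_probability(q1_raw),
        q2=clip_probability(q2_raw),
        source="dna",
    )


def default_priors(
    features: Sequence[str], condition_id: str = ""
) -> list[PriorSpec]:
    """Uninformative bias priors q1 = q2 = 0.5 for every feature."""
    return [
        PriorSpec(feature_id=f, condition_id=condition_id, q1=0.5, q2=0.5, source="default")
        for f in features
    ]


def merge_priors(
    defaults: Iterable[PriorSpec], measured: Iterable[PriorSpec]
) -> list[PriorSpec]:
    """Measured priors win over defaults per (feature, condition)."""
    merged: dict[tuple[str, str], PriorSpec] = {
        (p.feature_id, p.condition_id): p for p in defaults
    }
    for p in measured:
        merged[(p.feature_id, p.condition_id)] = p
    return list(merged.values())


def priors_to_frame(priors: Iterable[PriorSpec]) -> pd.DataFrame:
    rows = [(p.feature_id, p.condition_id, p.q1, p.q2, p.source) for p in priors]
    return pd.DataFrame(rows, columns=PRIOR_COLUMNS)


def frame_to_priors(df: pd.DataFrame) -> list[PriorSpec]:
    return [
        PriorSpec(
            feature_id=str(r.FEATURE_ID),
            condition_id=str(r.CONDITION),
            q1=float(r.Q1),
            q2=float(r.Q2),
            source=str(r.SOURCE),
        )
        for r in df.itertuples(index=False)
    ]


def estimate_from_dna_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Apply the F1-DNA estimator to every row of a count table."""
    from .alncount import frame_to_counts

    priors: list[PriorSpec] = []
    for rec in frame_to_counts(counts):
        if rec.x + rec.y + rec.z == 0:
            logger.warning("feature %s: no reads, prior omitted", rec.feature_id)
            continue
        priors.append(estimate_priors_from_f1_dna(rec))
    return priors_to_frame(priors)


def write_priors(priors: Iterable[PriorSpec], path: str | os.PathLike) -> None:
    priors_to_frame(priors).to_csv(path, sep="\t", index=False)


def read_priors(path: str | os.PathLike) -> list[PriorSpec]:
    return frame_to_priors(pd.read_csv(path, sep="\t"))
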