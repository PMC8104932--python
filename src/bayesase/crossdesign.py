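"""Testcross inference over a grid of F1 crosses.

Direct pairwise comparison of n alleles needs at least (n^2 - n)/2 crosses.
A testcross design crosses every nontester line to one common tester, so n
alleles can be compared with n crosses: if the allelic imbalance of
tester/nontester-A differs from that of tester/nontester-B (rejection of
the equal-imbalance null H3 between the two crosses), the two nontester
alleles are predicted to carry divergent cis-regulatory effects.  The
prediction can be validated in the direct cross of the two nontester lines
where available, and reciprocal crosses (A x B vs B x A) flag
parent-of-origin effects as rejections of H3 between reciprocals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class Cross:
    cross_id: str
    maternal: str
    paternal: str

    def __post_init__(self) -> None:
        if self.maternal == self.paternal:
            raise ValueError(f"cross {self.cross_id}: F1s need distinct parents")


@dataclass(frozen=True)
class CrossDesign:
    crosses: tuple[Cross, ...]

    def __post_init__(self) -> None:
        ids = [c.cross_id for c in self.crosses]
        if len(set(ids)) != len(ids):
            raise ValueError("cross_id values must be unique")

    @property
    def lines(self) -> set[str]:
        return {c.maternal for c in self.crosses} | {c.paternal for c in self.crosses}

    def find(self, maternal: str, paternal: str) -> Cross | None:
        for c in self.crosses:
            if c.maternal == maternal and c.paternal == paternal:
                return c
        return None


@dataclass(frozen=True)
class TestcrossTriple:
    """Two crosses sharing a tester in the same parental role."""

    __test__ = False  # not a test class, despite the name

    tester: str
    nontester_a: str
    nontester_b: str
    parental_role: str  # role of the tester: "maternal" | "paternal"
    cross_a: str
    cross_b: str

    def __post_init__(self) -> None:
        if self.nontester_a == self.nontester_b:
            raise ValueError("a testcross needs two distinct nontester lines")
        if self.parental_role not in ("maternal", "paternal"):
            raise ValueError("parental_role must be maternal or paternal")


@dataclass
class TestcrossReport:
    per_feature: pd.DataFrame  # FEATURE_ID, predicted_divergent, validated, poo
    n_total: int
    pct_validated_total: float | None
    n_poo: int
    pct_validated_poo: float | None


def design_size(n: int, design: str) -> int:
    """Crosses needed to compare n alleles: (n^2 - n)/2 directly, n by testcross."""
    if n < 2:
        raise ValueError("comparing alleles needs n >= 2")
    if design == "direct":
        return (n * n - n) // 2
    if design == "testcross":
        return n
    raise ValueError(f"unknown design {design!r}")


def enumerate_testcrosses(design: CrossDesign) -> list[TestcrossTriple]:
    """All triples (tester; nontester pair) sharing the tester's parental role.

    Each unordered nontester pair under one tester and one role yields
    exactly one triple; the two roles are enumerated separately because the
    testcross compares alleles of identical parental inheritance.
    """
    triples: list[TestcrossTriple] = []
    for role in ("maternal", "paternal"):
        by_tester: dict[str, list[Cross]] = {}
        for c in design.crosses:
            tester = c.maternal if role == "maternal" else c.paternal
            by_tester.setdefault(tester, []).append(c)
        for tester, crosses in sorted(by_tester.items()):
            crosses = sorted(crosses, key=lambda c: c.cross_id)
            for i in range(len(crosses)):
                for j in range(i + 1, len(crosses)):
                    ca, cb = crosses[i], crosses[j]
                    na = ca.paternal if role == "maternal" else ca.maternal
                    nb = cb.paternal if role == "maternal" else cb.maternal
                    if na == nb:
                        continue
                    triples.append(
                        TestcrossTriple(
                            tester=tester,
                            nontester_a=na,
                            nontester_b=nb,
                            parental_role=role,
                            cross_a=ca.cross_id,
                            cross_b=cb.cross_id,
                        )
                    )
    return triples


def reciprocal_pairs(design: CrossDesign) -> list[tuple[Cross, Cross]]:
    """Unordered pairs (A x B, B x A) present in the design."""
    pairs = []
    seen = set()
    for c in design.crosses:
        key = frozenset((c.maternal, c.paternal))
        if key in seen:
            continue
        other = design.find(c.paternal, c.maternal)
        if other is not None:
            pairs.append((c, other))
            seen.add(key)
    return pairs


def _fits_for(fits: pd.DataFrame, comparison_id: str) -> pd.DataFrame:
    sub = fits[fits["COMPARISON"].astype(str) == comparison_id]
    if sub.empty:
        raise KeyError(f"no fits for comparison {comparison_id!r}")
    return sub.set_index(fits.columns[0])  # FEATURE_ID


def predict_divergent(
    triple: TestcrossTriple,
    fits: pd.DataFrame,
    alpha: float = 0.05,
    comparison_id: str | None = None,
    low_coverage: set[str] | None = None,
) -> pd.Series:
    """Per-feature 0/1 prediction of divergent nontester alleles.

    A feature is predicted divergent when the equal-imbalance null between
    the triple's two crosses is rejected (ev_h3 < alpha) and the feature is
    not low-coverage flagged in either cross.
    """
    comp = comparison_id or f"{triple.cross_a}_vs_{triple.cross_b}"
    try:
        sub = _fits_for(fits, comp)
    except KeyError as err:
        raise KeyError(
            f"missing H3 comparison for testcross triple "
            f"({triple.tester}; {triple.nontester_a} vs {triple.nontester_b}, "
            f"{triple.parental_role}): {err}"
        ) from None
    pred = (sub["EV_H3"] < alpha).astype(int)
    if low_coverage:
        pred[pred.index.isin(low_coverage)] = 0
    pred.name = "predicted_divergent"
    return pred


def detect_poo(
    fits: pd.DataFrame,
    comparison_id: str,
    cross_pair: tuple[Cross, Cross],
    alpha: float = 0.05,
) -> pd.Series:
    """Parent-of-origin flags from a reciprocal-cross H3 comparison."""
    a, b = cross_pair
    if (a.maternal, a.paternal) != (b.paternal, b.maternal):
        raise ValueError(
            f"crosses {a.cross_id} and {b.cross_id} are not reciprocal "
            f"({a.maternal}x{a.paternal} vs {b.maternal}x{b.paternal})"
        )
    sub = _fits_for(fits, comparison_id)
    poo = (sub["EV_H3"] < alpha).astype(int)
    poo.name = "poo"
    return poo


def validate_predictions(
    predictions: pd.Series,
    direct_fits: Sequence[pd.DataFrame],
    poo_flags: pd.Series,
    alpha: float = 0.05,
    require_both: bool = False,
) -> TestcrossReport:
    """Validation of testcross predictions against the direct cross(es).

    A predicted feature is validated when allelic imbalance is detected
    (ev_h1 < alpha) in at least one direct reciprocal cross of the two
    nontester lines (both, if ``require_both``).  Aggregates follow the
    total / parent-of-origin split: counts of predictions and percentage
    validated, overall and within the POO-flagged subset.
    """
    if not direct_fits:
        raise ValueError("need at least one direct-cross fit table")
    calls = []
    for fits in direct_fits:
        sub = fits.set_index(fits.columns[0])
        calls.append((sub["EV_H1"] < alpha).astype(int))
    direct = pd.concat(calls, axis=1).fillna(0).astype(int)
    detected = direct.min(axis=1) if require_both else direct.max(axis=1)

    df = pd.DataFrame({"predicted_divergent": predictions})
    df["poo"] = poo_flags.reindex(df.index).fillna(0).astype(int)
    df["validated"] = 0
    predicted_idx = df.index[df["predicted_divergent"] == 1]
    df.loc[predicted_idx, "validated"] = detected.reindex(predicted_idx).fillna(0).astype(int)

    n_total = int(df["predicted_divergent"].sum())
    subset = df[df["predicted_divergent"] == 1]
    poo_subset = subset[subset["poo"] == 1]
    n_poo = len(poo_subset)
    pct_total = 100.0 * subset["validated"].mean() if n_total else None
    pct_poo = 100.0 * poo_subset["validated"].mean() if n_poo else None
    return TestcrossReport(
        per_feature=df.reset_index(names="FEATURE_ID"),
        n_total=n_total,
        pct_validated_total=pct_total,
        n_poo=n_poo,
        pct_validated_poo=pct_poo,
    )


def ai_percentage(
    fits: pd.DataFrame, alpha: float = 0.05, low_coverage: set[str] | None = None
) -> float:
    """Percentage of tested features showing allelic imbalance (ev_h1 < alpha)."""
    if fits.empty:
        raise ValueError("no fits to summarise")
    sub = fits.set_index(fits.columns[0])
    if low_coverage:
        sub = sub[~sub.index.isin(low_coverage)]
    if sub.empty:
        raise ValueError("all features are low-coverage flagged")
    return 100.0 * float((sub["EV_H1"] < alpha).mean())


def mcnemar_sex_difference(
    calls_male: Sequence[int] | pd.Series, calls_female: Sequence[int] | pd.Series
) -> tuple[int, int, float]:
    """Exact McNemar test of discordant detection between paired call sets.

    Returns (b, c, p) where b = #(male only), c = #(female only) and p is
    the two-sided exact binomial probability of b successes in b + c trials
    at rate 1/2.  No discordant pairs gives p = 1 (degenerate case).
    """
    m = np.asarray(calls_male, dtype=int)
    f = np.asarray(calls_female, dtype=int)
    if m.shape != f.shape:
        raise ValueError("call vectors must index the same features")
    b = int(np.sum((m == 1) & (f == 0)))
    c = int(np.sum((m == 0) & (f == 1)))
    if b + c == 0:
        return b, c, 1.0
    p = float(stats.binomtest(b, b + c, 0.5, alternative="two-sided").pvalue)
    return b, c, p


# ---------------------------------------------------------------------------
# TSV plumbing


def read_cross_design(path) -> CrossDesign:
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    crosses = tuple(
        Cross(
            cross_id=str(r[cols["cross_id"]]),
            maternal=str(r[cols["maternal"]]),
            paternal=str(r[cols["paternal"]]),
        )
        for _, r in df.iterrows()
    )
    return CrossDesign(crosses)


def ai_summary_table(
    fits_by_cross: dict[tuple[str, str], pd.DataFrame], alpha: float = 0.05
) -> pd.DataFrame:
    """Per-cross/condition percentages of features with allelic imbalance."""
    rows = [
        (cross, condition, ai_percentage(fits, alpha))
        for (cross, condition), fits in sorted(fits_by_cross.items())
    ]
    return pd.DataFrame(rows, columns=["CROSS", "CONDITION", "PCT_AI"])


def validation_summary_table(
    reports: dict[tuple[str, str], TestcrossReport]
) -> pd.DataFrame:
    """Aggregate validation rates, one row per (alleles compared, condition)."""
    rows = []
    for (alleles, condition), rep in sorted(reports.items()):
        rows.append(
            (
                alleles,
                condition,
                rep.n_total,
                rep.pct_validated_total if rep.pct_validated_total is not None else np.nan,
                rep.n_poo,
                rep.pct_validated_poo if rep.pct_validated_poo is not None else np.nan,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "ALLELES_COMPARED",
            "CONDITION",
            "N_TOTAL",
            "PCT_VALIDATED_TOTAL",
            "N_POO",
            "PCT_VALIDATED_POO",
        ],
    )
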