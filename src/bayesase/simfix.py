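"""Synthetic allele-specific data under the model's generative process.

Two levels of fixture are produced:

* count-level — :func:`simulate_counts` draws per-feature (x, y, z) tables
  for arbitrary cross designs at known theta, q1, q2, read depth and
  parent-of-origin effects, so the statistical layers can be calibrated
  against ground truth;
* read-level — :func:`make_toy_fixture` writes a tiny reference FASTA,
  per-line VCFs, a BED of features and a pair of synthesized SAM files
  (alignment records constructed directly, not produced by an aligner, so
  tests are bit-stable) in which every read's name carries its true origin.

Generative process per read: the read originates from allele 1 with
probability theta; an allele-g read is informative to genome g with
probability q_g and ambiguous otherwise.  An optional contamination rate
sends an informative read to the wrong genome, probing robustness to
cross-misassignment, which the default model (and the prior estimators)
assume absent.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from . import refbuild
from .alncount import COUNT_COLUMNS
from .bayes import SamplerConfig, fit_batch
from .crossdesign import Cross, CrossDesign

DEFAULT_CROSS = CrossDesign((Cross("AxB", "lineA", "lineB"),))


@dataclass
class SimScenario:
    """Everything that determines a simulated count table.

    ``theta`` maps (cross_id, condition_id) to a scalar or per-feature
    array; missing keys fall back to ``theta_default``.  ``poo_effect``
    adds a per-feature shift to theta in the named crosses (inject it in
    one member of a reciprocal pair to create a parent-of-origin signal).
    """

    n_features: int = 10
    theta_default: float = 0.5
    theta: dict[tuple[str, str], float | np.ndarray] = field(default_factory=dict)
    q1: float | np.ndarray = 0.9
    q2: float | np.ndarray = 0.9
    reads_per_feature: int = 500
    crosses: CrossDesign = DEFAULT_CROSS
    conditions: tuple[str, ...] = ("cond1",)
    replicates: int = 1
    poo_effect: dict[str, float | np.ndarray] = field(default_factory=dict)
    contamination: float = 0.0
    seed: int = 0

    @property
    def feature_ids(self) -> list[str]:
        return [f"gene{i:04d}" for i in range(self.n_features)]

    def theta_for(self, cross_id: str, condition_id: str) -> np.ndarray:
        base = self.theta.get((cross_id, condition_id), self.theta_default)
        th = np.broadcast_to(np.asarray(base, dtype=float), (self.n_features,)).copy()
        th += np.broadcast_to(
            np.asarray(self.poo_effect.get(cross_id, 0.0), dtype=float), (self.n_features,)
        )
        if np.any((th <= 0.0) | (th >= 1.0)):
            raise ValueError("theta (after parent-of-origin effects) must stay inside (0, 1)")
        return th


def simulate_counts(scenario: SimScenario) -> pd.DataFrame:
    """Draw an allele count table; the seed fully determines the output."""
    rng = np.random.default_rng(scenario.seed)
    q1 = np.broadcast_to(np.asarray(scenario.q1, float), (scenario.n_features,))
    q2 = np.broadcast_to(np.asarray(scenario.q2, float), (scenario.n_features,))
    rho = scenario.contamination
    rows = []
    for cross in scenario.crosses.crosses:
        for condition in scenario.conditions:
            th = scenario.theta_for(cross.cross_id, condition)
            p_x = th * q1 * (1 - rho) + (1 - th) * q2 * rho
            p_y = (1 - th) * q2 * (1 - rho) + th * q1 * rho
            p_z = 1.0 - p_x - p_y
            probs = np.stack([p_x, p_y, p_z], axis=1)
            for rep in range(1, scenario.replicates + 1):
                draws = rng.multinomial(scenario.reads_per_feature, probs)
                for fid, (x, y, z) in zip(scenario.feature_ids, draws):
                    rows.append(
                        (fid, cross.cross_id, condition, str(rep), int(x), int(y), int(z), 0)
                    )
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def naive_binomial_pvalues(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact two-sided binomial test of x successes in x+y trials at 1/2.

    The comparator that ignores mapping bias entirely; used to demonstrate
    the inflation of type-I error the bias priors exist to prevent.
    """
    x = np.asarray(x)
    n = x + np.asarray(y)
    lo = stats.binom.cdf(x, n, 0.5)
    hi = stats.binom.sf(x - 1, n, 0.5)
    return np.minimum(1.0, 2.0 * np.minimum(lo, hi))


def calibration_experiment(
    n_features: int,
    theta_grid: tuple[float, ...],
    q_grid: tuple[tuple[float, float], ...],
    n_reads_grid: tuple[int, ...],
    alpha: float = 0.05,
    seed: int = 0,
    config: SamplerConfig | None = None,
) -> pd.DataFrame:
    """Rejection rates of ev_h1 and ev_h3 over a grid of true parameters.

    For each grid cell, ``n_features`` features are simulated in two
    conditions at the same theta (so the H3 null always holds), fitted with
    the true priors, and the fraction of features with ev below alpha is
    reported with a binomial standard error.
    """
    if not (theta_grid and q_grid and n_reads_grid):
        raise ValueError("grids must be nonempty")
    rows = []
    cell_seed = np.random.default_rng(seed)
    for theta in theta_grid:
        for q1, q2 in q_grid:
            for n_reads in n_reads_grid:
                s = int(cell_seed.integers(2**31 - 1))
                scen = SimScenario(
                    n_features=n_features,
                    theta_default=theta,
                    q1=q1,
                    q2=q2,
                    reads_per_feature=n_reads,
                    conditions=("cond1", "cond2"),
                    seed=s,
                )
                counts = simulate_counts(scen)
                c1 = counts[counts.CONDITION == "cond1"].set_index("FEATURE_ID")
                c2 = counts[counts.CONDITION == "cond2"].set_index("FEATURE_ID")
                feats = scen.feature_ids
                cfg = dataclasses.replace(config or SamplerConfig(), seed=s)
                res = fit_batch(
                    c1.loc[feats, "COUNT_G1"].to_numpy(),
                    c1.loc[feats, "COUNT_G2"].to_numpy(),
                    np.full(n_features, q1),
                    np.full(n_features, q2),
                    c2.loc[feats, "COUNT_G1"].to_numpy(),
                    c2.loc[feats, "COUNT_G2"].to_numpy(),
                    np.full(n_features, q1),
                    np.full(n_features, q2),
                    config=cfg,
                )
                rate_h1 = float(np.mean(res["ev_h1"] < alpha))
                rate_h3 = float(np.mean(res["ev_h3"] < alpha))
                se = lambda r: float(np.sqrt(r * (1 - r) / n_features))  # noqa: E731
                rows.append(
                    (theta, q1, q2, n_reads, n_features, rate_h1, se(rate_h1), rate_h3, se(rate_h3))
                )
    return pd.DataFrame(
        rows,
        columns=[
            "theta",
            "q1",
            "q2",
            "n_reads",
            "n_features",
            "rate_h1",
            "se_h1",
            "rate_h3",
            "se_h3",
        ],
    )


# ---------------------------------------------------------------------------
# three-line reciprocal experiment (testcross + direct validation)


def _oriented(counts: pd.DataFrame, cross: Cross, genome1_line: str, feats: list[str]):
    """Per-feature (x, y) with x counting reads of ``genome1_line``.

    Count tables put the maternal allele in COUNT_G1; comparisons between
    crosses need a shared allele labelling (the tester for testcrosses, a
    fixed line for reciprocal pairs), so the swap x <-> y — which maps
    theta to 1 - theta — is applied here when the requested line is
    paternal.
    """
    sub = counts[counts.CROSS == cross.cross_id].set_index("FEATURE_ID")
    x = sub.loc[feats, "COUNT_G1"].to_numpy()
    y = sub.loc[feats, "COUNT_G2"].to_numpy()
    if genome1_line == cross.maternal:
        return x, y
    if genome1_line == cross.paternal:
        return y, x
    raise ValueError(f"line {genome1_line} is not a parent of cross {cross.cross_id}")


def three_line_experiment(
    n_null: int = 150,
    n_divergent: int = 100,
    n_poo: int = 30,
    fold: float = 1.5,
    poo_delta: float = 0.15,
    n_reads: int = 500,
    q: float = 0.9,
    alpha: float = 0.05,
    seed: int = 0,
    config: SamplerConfig | None = None,
) -> dict:
    """Simulate and analyse a full 3-line reciprocal design.

    Per-line cis effects: lines A and B have effect 1 everywhere; line C
    has effect ``fold`` at the divergent features.  In cross m x p the
    maternal-allele share is theta = a_m / (a_m + a_p), so divergent
    features separate the crosses A x B and A x C of the maternal-tester-A
    testcross, and show imbalance in the direct B/C crosses.  The first
    ``n_poo`` divergent features also receive a parent-of-origin shift
    (+``poo_delta`` on the maternal share of C x B only), detectable
    exclusively through the reciprocal comparison.

    Returns predictions, parent-of-origin flags, the validation report and
    the ground-truth masks.
    """
    import pandas as _pd

    from .crossdesign import (
        TestcrossTriple,
        predict_divergent,
        detect_poo,
        validate_predictions,
    )

    lines = ("A", "B", "C")
    crosses = CrossDesign(
        tuple(
            Cross(f"{m}x{p}", m, p) for m in lines for p in lines if m != p
        )
    )
    n_features = n_null + n_divergent
    effect_c = np.ones(n_features)
    divergent_truth = np.zeros(n_features, dtype=bool)
    divergent_truth[n_null:] = True
    effect_c[divergent_truth] = fold
    poo_truth = np.zeros(n_features, dtype=bool)
    poo_truth[n_null : n_null + n_poo] = True

    effects = {"A": np.ones(n_features), "B": np.ones(n_features), "C": effect_c}
    theta = {
        (c.cross_id, "cond1"): effects[c.maternal] / (effects[c.maternal] + effects[c.paternal])
        for c in crosses.crosses
    }
    scen = SimScenario(
        n_features=n_features,
        theta=theta,
        q1=q,
        q2=q,
        reads_per_feature=n_reads,
        crosses=crosses,
        poo_effect={"CxB": poo_delta * poo_truth},
        seed=seed,
    )
    counts = simulate_counts(scen)
    feats = scen.feature_ids
    config = config or SamplerConfig(seed=seed)
    qv = np.full(n_features, q)

    def _h3_fits(cross_a: Cross, cross_b: Cross, genome1: str, comp: str) -> _pd.DataFrame:
        xa, ya = _oriented(counts, cross_a, genome1, feats)
        xb, yb = _oriented(counts, cross_b, genome1, feats)
        res = fit_batch(xa, ya, qv, qv, xb, yb, qv, qv, config=config)
        return _pd.DataFrame(
            {
                "FEATURE_ID": feats,
                "COMPARISON": comp,
                "EV_H1": res["ev_h1"],
                "EV_H2": res["ev_h2"],
                "EV_H3": res["ev_h3"],
            }
        )

    def _h1_fits(cross: Cross, comp: str) -> _pd.DataFrame:
        x, y = _oriented(counts, cross, cross.maternal, feats)
        res = fit_batch(x, y, qv, qv, config=config)
        return _pd.DataFrame(
            {"FEATURE_ID": feats, "COMPARISON": comp, "EV_H1": res["ev_h1"]}
        )

    axb, axc = crosses.find("A", "B"), crosses.find("A", "C")
    bxc, cxb = crosses.find("B", "C"), crosses.find("C", "B")

    triple = TestcrossTriple(
        tester="A", nontester_a="B", nontester_b="C",
        parental_role="maternal", cross_a="AxB", cross_b="AxC",
    )
    testcross_fits = _h3_fits(axb, axc, "A", "AxB_vs_AxC")
    predictions = predict_divergent(triple, testcross_fits, alpha, comparison_id="AxB_vs_AxC")

    reciprocal_fits = _h3_fits(bxc, cxb, "B", "BxC_vs_CxB")
    poo_flags = detect_poo(reciprocal_fits, "BxC_vs_CxB", (bxc, cxb), alpha)

    direct = [_h1_fits(bxc, "BxC_direct"), _h1_fits(cxb, "CxB_direct")]
    report = validate_predictions(predictions, direct, poo_flags, alpha)

    return {
        "counts": counts,
        "feature_ids": feats,
        "predictions": predictions,
        "poo_flags": poo_flags,
        "report": report,
        "testcross_fits": testcross_fits,
        "reciprocal_fits": reciprocal_fits,
        "direct_fits": direct,
        "divergent_truth": divergent_truth,
        "poo_truth": poo_truth,
    }


# ---------------------------------------------------------------------------
# read-level toy fixture

_READ_LEN = 50


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _write_vcf(path, chrom_lengths, variants, sample: str) -> None:
    """Plain-text VCF v4.2 with one homozygous-alt sample column."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, ln in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for chrom, pos, ref, alt in variants:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t1/1\n")


@dataclass
class ToyFixture:
    """Paths and ground truth for the end-to-end read-level fixture."""

    out_dir: str
    reference_fasta: str
    vcf_by_line: dict[str, str]
    genotype_fastas: dict[str, str]
    bed: str
    sam1: str
    sam2: str
    design: str
    truth_counts: pd.DataFrame  # FEATURE_ID x truth (x, y, z)
    truth_path: str


def make_toy_fixture(seed: int, out_dir: str | os.PathLike) -> ToyFixture:
    """Write a complete miniature data set with known per-read truth.

    Two 1 kb chromosomes, one feature on each, two inbred lines with
    disjoint SNPs inside the features.  Reads are placed uniformly within
    features; informative reads receive a higher alignment score against
    their own parental genome, reads on SNP-free segments receive equal
    scores (truth AMBIGUOUS), a few reads are unmapped in both genomes and
    a few fall outside every feature.
    """
    rng = np.random.default_rng(seed)
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)

    chrom_lengths = {"chr1": 1000, "chr2": 1000}
    reference = {c: _random_sequence(rng, n) for c, n in chrom_lengths.items()}
    ref_path = os.path.join(out_dir, "reference.fasta")
    refbuild.write_fasta(reference, ref_path)

    features = [("gene1", "chr1", 100, 900), ("gene2", "chr2", 100, 900)]
    bed_path = os.path.join(out_dir, "features.bed")
    with open(bed_path, "w") as fh:
        for fid, chrom, start, end in features:
            fh.write(f"{chrom}\t{start}\t{end}\t{fid}\n")

    def _snv(chrom: str, pos: int) -> tuple[str, int, str, str]:
        ref_base = reference[chrom][pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref_base])
        return (chrom, pos, ref_base, str(alt))

    # disjoint SNP positions per line, all inside the features
    variants = {
        "lineA": [_snv("chr1", int(p)) for p in (150, 400, 700)]
        + [_snv("chr2", int(p)) for p in (200, 600)],
        "lineB": [_snv("chr1", int(p)) for p in (250, 550)]
        + [_snv("chr2", int(p)) for p in (300, 500, 800)],
    }
    vcf_by_line, genotype_fastas, genomes = {}, {}, {}
    for line, vs in variants.items():
        vcf_path = os.path.join(out_dir, f"{line}.vcf")
        _write_vcf(vcf_path, chrom_lengths, vs, line)
        vcf_by_line[line] = vcf_path
        recs = [refbuild.VariantRecord(c, p, r, a, line) for c, p, r, a in vs]
        kept, _ = refbuild.filter_variants(recs, reference)
        geno = refbuild.build_genotype_reference(reference, kept, line)
        fasta_path = os.path.join(out_dir, f"{line}.fasta")
        refbuild.write_fasta(geno.sequences, fasta_path)
        genotype_fastas[line] = fasta_path
        genomes[line] = geno.sequences

    # reads: truth category drawn per read; positions uniform in the feature
    truth_rows = []
    reads = []  # (name, chrom, pos0, truth)
    ridx = 0
    for fid, chrom, start, end in features:
        n_reads = 30
        cats = rng.choice(
            ["ALLELE1", "ALLELE2", "AMBIGUOUS"], size=n_reads, p=[0.45, 0.35, 0.20]
        )
        x = int(np.sum(cats == "ALLELE1"))
        y = int(np.sum(cats == "ALLELE2"))
        z = int(np.sum(cats == "AMBIGUOUS"))
        truth_rows.append((fid, x, y, z))
        for cat in cats:
            pos0 = int(rng.integers(start, end - _READ_LEN))
            reads.append((f"r{ridx:04d}|{fid}|{cat}", chrom, pos0, cat))
            ridx += 1
    # intergenic reads (dropped by counting) and unmapped reads
    for _ in range(3):
        reads.append((f"r{ridx:04d}|none|AMBIGUOUS", "chr1", int(rng.integers(0, 50)), "AMBIGUOUS"))
        ridx += 1
    unmapped_names = [f"r{ridx + k:04d}|none|UNMAPPED" for k in range(2)]
    ridx += 2

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": n} for c, n in chrom_lengths.items()],
    }
    sam_paths = {}
    for genome_idx, line in enumerate(["lineA", "lineB"], start=1):
        path = os.path.join(out_dir, f"sample_vs_{line}.sam")
        sam_paths[genome_idx] = path
        with pysam.AlignmentFile(path, "w", header=header) as sam:
            tid = {c: i for i, c in enumerate(chrom_lengths)}
            for name, chrom, pos0, cat in reads:
                a = pysam.AlignedSegment(sam.header)
                a.query_name = name
                a.query_sequence = genomes[line][chrom][pos0 : pos0 + _READ_LEN]
                a.reference_id = tid[chrom]
                a.reference_start = pos0
                a.mapping_quality = 60
                a.cigartuples = [(0, _READ_LEN)]
                if cat == "AMBIGUOUS":
                    score = 100
                elif (cat == "ALLELE1") == (genome_idx == 1):
                    score = 100  # own genome
                else:
                    score = 90
                a.set_tag("AS", score)
                sam.write(a)
            for name in unmapped_names:
                a = pysam.AlignedSegment(sam.header)
                a.query_name = name
                a.query_sequence = _random_sequence(rng, _READ_LEN)
                a.is_unmapped = True
                sam.write(a)

    design_path = os.path.join(out_dir, "cross_design.tsv")
    pd.DataFrame(
        [("AxB", "lineA", "lineB", "cond1", "1", sam_paths[1], sam_paths[2])],
        columns=["cross_id", "genotype1", "genotype2", "condition_id", "rep_id", "sam1", "sam2"],
    ).to_csv(design_path, sep="\t", index=False)

    truth = pd.DataFrame(truth_rows, columns=["FEATURE_ID", "COUNT_G1", "COUNT_G2", "COUNT_AMBIG"])
    truth_path = os.path.join(out_dir, "truth_counts.tsv")
    truth.to_csv(truth_path, sep="\t", index=False)

    return ToyFixture(
        out_dir=out_dir,
        reference_fasta=ref_path,
        vcf_by_line=vcf_by_line,
        genotype_fastas=genotype_fastas,
        bed=bed_path,
        sam1=sam_paths[1],
        sam2=sam_paths[2],
        design=design_path,
        truth_counts=truth,
        truth_path=truth_path,
    )
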