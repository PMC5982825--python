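"""Sex-specific linkage-map statistics.

Map length in centimorgans is 100 x (observed crossovers) / (meioses); the
female:male ratio of total map lengths quantifies heterochiasmy.  Ratios are
always computed from unrounded lengths (rounding the lengths first changes
the printed 2-dp ratio on several chromosomes).  The module also provides
the obligate-crossover binomial test, a coefficient-of-variation equality
test, folded-chromosome segment maps, cross-sex segment correlations and
per-arm recombination rates.
"""

from __future__ import annotations

import decimal
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

MEIOSES_BY_SEX = {"male": 30, "female": 24}  # emulated study design


def map_length_cM(n_cos: int, n_meioses: int) -> float:
    """Map length in centimorgans: 100 x COs / meioses."""
    if n_meioses <= 0:
        raise ValueError("n_meioses must be positive")
    return 100.0 * n_cos / n_meioses


def round_half_up(x: float, digits: int) -> float:
    """Decimal half-up rounding (report convention; float repr is half-even)."""
    q = decimal.Decimal(10) ** -digits
    return float(decimal.Decimal(repr(float(x))).quantize(
        q, rounding=decimal.ROUND_HALF_UP))


def load_reference_map_lengths() -> pd.DataFrame:
    """Published per-chromosome sex-specific map lengths (cM) from the
    stickleback interspecific-cross experiment the simulator emulates
    (30 male and 24 female meioses); used for worked examples and for
    reconstructing crossover counts."""
    with resources.files("xomap.data").joinpath(
            "stickleback_map_lengths.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chromosome": str})


def counts_from_lengths(length_cM, n_meioses: int) -> np.ndarray:
    """Invert map lengths to integer crossover counts."""
    return np.rint(np.asarray(length_cM, dtype=float) * n_meioses / 100.0).astype(int)


def map_table(counts: pd.DataFrame, meioses_by_sex: dict = None) -> pd.DataFrame:
    """Per-chromosome map lengths, female:male ratios and a totals row.

    ``counts`` columns: chromosome, female, male (crossover counts).  Adds
    ``female_cM``, ``male_cM``, ``ratio`` (unrounded lengths; NaN when the
    male count is 0) and appends a ``Total`` row of column sums.
    """
    meioses_by_sex = MEIOSES_BY_SEX if meioses_by_sex is None else meioses_by_sex
    out = counts.copy().reset_index(drop=True)
    out["female_cM"] = [map_length_cM(c, meioses_by_sex["female"]) for c in out.female]
    out["male_cM"] = [map_length_cM(c, meioses_by_sex["male"]) for c in out.male]
    # ratio of unrounded lengths; the integer-count form avoids float noise
    # at exact decimal ties (e.g. 17/24 vs 10/30 is exactly 2.125)
    denom = out.male.to_numpy() * meioses_by_sex["female"]
    numer = out.female.to_numpy() * meioses_by_sex["male"]
    out["ratio"] = np.where(denom > 0, numer / np.where(denom > 0, denom, 1),
                            np.nan)
    total = pd.DataFrame([{
        "chromosome": "Total",
        "female": out.female.sum(), "male": out.male.sum(),
        "female_cM": out.female_cM.sum(), "male_cM": out.male_cM.sum(),
        "ratio": out.female_cM.sum() / out.male_cM.sum()
                 if out.male_cM.sum() > 0 else np.nan,
    }])
    return pd.concat([out, total], ignore_index=True)


def per_chromosome_table(co_table: pd.DataFrame, meioses_by_sex: dict,
                         chrom_names) -> tuple:
    """Build the map table from retained crossover calls.

    Returns ``(table, summary)`` where summary holds mean COs per chromosome
    per meiosis for each sex and the Pearson r between the per-chromosome
    male and female map lengths (NaN when degenerate; r of identical columns
    is 1 by the underlying definition).
    """
    counts = pd.DataFrame({"chromosome": list(chrom_names)})
    for sex in ("female", "male"):
        sub = co_table[co_table.parent_sex == sex]
        per = sub.groupby("chrom").size()
        counts[sex] = [int(per.get(c, 0)) for c in chrom_names]
    table = map_table(counts, meioses_by_sex)
    body = table[table.chromosome != "Total"]
    n_chrom = len(body)
    with np.errstate(invalid="ignore"):
        r = (np.corrcoef(body.female_cM, body.male_cM)[0, 1]
             if body.female_cM.std() > 0 and body.male_cM.std() > 0 else np.nan)
    summary = {
        "mean_cos_per_chrom_male":
            body.male.sum() / (meioses_by_sex["male"] * n_chrom),
        "mean_cos_per_chrom_female":
            body.female.sum() / (meioses_by_sex["female"] * n_chrom),
        "pearson_r_lengths": float(r),
    }
    return table, summary


def obligate_co_probability(observed_cos: int, n_meioses: int) -> float:
    """P[X <= observed] with X ~ Binomial(n_meioses, 1/2).

    Under one obligate chiasma per chromosome per meiosis, each meiosis shows
    its crossover in the sampled gamete with probability 1/2; a low observed
    count is evidence against the assembly/phasing on that chromosome.
    """
    if not 0 <= observed_cos <= n_meioses:
        raise ValueError("observed_cos must be within [0, n_meioses]")
    return float(stats.binom.cdf(observed_cos, n_meioses, 0.5))


def cv_equality_test(counts_female, counts_male) -> tuple:
    """Coefficients of variation and the Feltz-Miller equality test.

    CV = sample SD (ddof=1) / mean.  The asymptotic Feltz-Miller chi-square
    statistic tests H0: equal CVs across the two samples.
    """
    out_cv = []
    for x in (counts_female, counts_male):
        x = np.asarray(x, dtype=float)
        if len(x) < 2:
            raise ValueError("need >= 2 individuals per sex")
        if x.mean() <= 0:
            raise ValueError("mean must be positive")
        out_cv.append(x.std(ddof=1) / x.mean())
    cv_f, cv_m = out_cv
    m = np.array([len(counts_female) - 1, len(counts_male) - 1], dtype=float)
    c = np.array([cv_f, cv_m])
    pooled = (m * c).sum() / m.sum()
    if pooled == 0:
        return cv_f, cv_m, 1.0
    stat = ((m * (c - pooled) ** 2) / (pooled ** 2 * (0.5 + pooled ** 2))).sum()
    p = float(stats.chi2.sf(stat, df=1))
    return cv_f, cv_m, p


def folded_coordinate(midpoint, length) -> float:
    """Relative distance from the nearest chromosome end, in [0, 1]."""
    midpoint = np.asarray(midpoint, dtype=float)
    return np.minimum(midpoint, length - midpoint) / (length / 2.0)


def fold_and_bin(co_table: pd.DataFrame, meta: dict, n_segments: int) -> dict:
    """Relative map length per folded-chromosome segment, per sex.

    The folded coordinate ``min(mid, L - mid) / (L/2)`` lands in [0, 1];
    segment index is ``floor(coord * n)`` with coordinate exactly 1 assigned
    to the last segment.  Relative length divides each segment's crossover
    count by the chromosome total for that sex (chromosomes with zero
    crossovers are omitted, the ratio being undefined).
    """
    if not 2 <= n_segments <= 20:
        raise ValueError("n_segments must be in [2, 20]")
    out = {}
    for sex in ("male", "female"):
        sub = co_table[co_table.parent_sex == sex]
        rows = []
        for chrom, grp in sub.groupby("chrom"):
            L = meta[chrom].length_bp
            coord = folded_coordinate(grp.midpoint.to_numpy(), L)
            seg = np.minimum((coord * n_segments).astype(int), n_segments - 1)
            total = len(grp)
            for s in range(n_segments):
                cnt = int((seg == s).sum())
                rows.append((chrom, s, cnt, cnt / total))
        out[sex] = pd.DataFrame(rows, columns=["chrom", "segment", "count",
                                               "rel_length"])
    return out


def sex_segment_correlation(seg_f: pd.DataFrame, seg_m: pd.DataFrame) -> tuple:
    """Pearson r and regression p between relative map lengths of the sexes.

    Chromosome segments present in both frames are pooled; returns (r, p),
    NaN when either side has zero variance.
    """
    merged = seg_f.merge(seg_m, on=["chrom", "segment"], suffixes=("_f", "_m"))
    x, y = merged.rel_length_f.to_numpy(), merged.rel_length_m.to_numpy()
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    res = stats.linregress(x, y)
    return float(res.rvalue), float(res.pvalue)


def segment_correlation_scan(co_table: pd.DataFrame, meta: dict,
                             scales=range(2, 21)) -> pd.DataFrame:
    """r and p at every folded-segmentation scale n."""
    rows = []
    for n in scales:
        segs = fold_and_bin(co_table, meta, n)
        r, p = sex_segment_correlation(segs["female"], segs["male"])
        rows.append((n, r, p))
    return pd.DataFrame(rows, columns=["n_segments", "r", "p"])


def arm_rates(co_table: pd.DataFrame, meta: dict,
              short_arm_max_fraction: float = 0.30) -> tuple:
    """Per-arm crossover rates and the pooled short-arm deficit test.

    Rates are COs/Mb by arm (midpoint side of the centromere); the deficit
    chi-square (1 df) pools autosomes whose short arm is below
    ``short_arm_max_fraction`` of the chromosome and compares observed
    short/long-arm counts with an expectation proportional to physical arm
    length.  Chromosomes without a centromere are excluded.  Returns
    ``(arm_table, test_by_sex)``; a sex with zero pooled crossovers reports
    ``None``.
    """
    rows = []
    for chrom, m in meta.items():
        if m.centromere_pos_bp is None:
            continue
        cen = m.centromere_pos_bp
        short_left = cen <= m.length_bp - cen
        for sex in ("male", "female"):
            sub = co_table[(co_table.parent_sex == sex) & (co_table.chrom == chrom)]
            n_left = int((sub.midpoint < cen).sum())
            n_right = len(sub) - n_left
            n_short, n_long = (n_left, n_right) if short_left else (n_right, n_left)
            rows.append((chrom, sex, m.short_arm_bp, m.long_arm_bp,
                         n_short, n_long,
                         n_short / (m.short_arm_bp / 1e6),
                         n_long / (m.long_arm_bp / 1e6),
                         m.is_sex_chromosome))
    arms = pd.DataFrame(rows, columns=[
        "chrom", "parent_sex", "short_arm_bp", "long_arm_bp",
        "n_short", "n_long", "rate_short_per_mb", "rate_long_per_mb",
        "is_sex_chromosome"])
    tests = {}
    pool = arms[(~arms.is_sex_chromosome)
                & (arms.short_arm_bp < short_arm_max_fraction
                   * (arms.short_arm_bp + arms.long_arm_bp))]
    for sex in ("male", "female"):
        sub = pool[pool.parent_sex == sex]
        o_short, o_long = sub.n_short.sum(), sub.n_long.sum()
        total = o_short + o_long
        if total == 0:
            tests[sex] = None
            continue
        frac_short = sub.short_arm_bp.sum() / (sub.short_arm_bp.sum()
                                               + sub.long_arm_bp.sum())
        e_short, e_long = total * frac_short, total * (1 - frac_short)
        chi2 = (o_short - e_short) ** 2 / e_short + (o_long - e_long) ** 2 / e_long
        tests[sex] = {"chi2": float(chi2),
                      "p": float(stats.chi2.sf(chi2, df=1)),
                      "observed_short": int(o_short),
                      "expected_short": float(e_short)}
    return arms, tests
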