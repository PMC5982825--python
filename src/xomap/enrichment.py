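"""Hotspot, feature-overlap and GC analyses of crossover intervals.

All Monte-Carlo nulls re-place the observed crossover intervals uniformly on
their own chromosomes, preserving interval lengths; p-values use the add-one
convention p = (1 + #{null >= observed}) / (n_sims + 1) so a Monte-Carlo p
is never exactly zero.  Hotspots are fixed-length windows tiled from
coordinate 0 that contain two or more crossovers (assigned by midpoint).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("xomap")


@dataclass
class PermutationResult:
    """Observed statistic against its Monte-Carlo null."""

    statistic: str
    observed: float
    n_sims: int
    null_median: float
    null_q025: float
    null_q975: float
    p_enrichment: float
    p_depletion: float
    seed: int
    null: np.ndarray | None = field(default=None, repr=False)

    @property
    def p_two_sided(self) -> float:
        return min(1.0, 2.0 * min(self.p_enrichment, self.p_depletion))


def _mc_pvalues(observed: float, null: np.ndarray):
    n = len(null)
    p_enr = (1 + np.sum(null >= observed)) / (n + 1)
    p_dep = (1 + np.sum(null <= observed)) / (n + 1)
    return float(p_enr), float(p_dep)


def _result(name, observed, null, seed, keep_null=False) -> PermutationResult:
    p_enr, p_dep = _mc_pvalues(observed, null)
    return PermutationResult(
        name, float(observed), len(null), float(np.median(null)),
        float(np.quantile(null, 0.025)), float(np.quantile(null, 0.975)),
        p_enr, p_dep, seed, null if keep_null else None)


# ---------------------------------------------------------------------------
# Hotspots
# ---------------------------------------------------------------------------

def _multi_window_fraction(windows_by_chrom) -> float:
    """Fraction of COs lying in windows holding >= 2 COs (one chromosome's
    window indices per list entry)."""
    total = hot = 0
    for w in windows_by_chrom:
        total += len(w)
        if len(w) < 2:
            continue
        w = np.sort(w)
        multi = np.zeros(len(w), dtype=bool)
        same = w[1:] == w[:-1]
        multi[1:] |= same
        multi[:-1] |= same
        hot += int(multi.sum())
    return hot / total if total else 0.0


def hotspot_fraction(co_table: pd.DataFrame, window_bp: int) -> float:
    """Fraction of crossovers falling in multi-crossover windows.

    Chromosomes are tiled with non-overlapping ``window_bp`` windows from
    position 0; each crossover is assigned by midpoint.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    groups = [np.asarray(g.midpoint // window_bp, dtype=np.int64)
              for _, g in co_table.groupby("chrom")]
    return _multi_window_fraction(groups)


def hotspot_permutation(co_table: pd.DataFrame, meta: dict, window_bp: int,
                        n_sims: int = 10_000, seed: int = 0,
                        keep_null: bool = False) -> PermutationResult:
    """Monte-Carlo null for the hotspot fraction.

    Each simulation re-places every observed interval uniformly on its own
    chromosome (start ~ U[0, L - length]) and recomputes the multi-window
    crossover fraction.
    """
    observed = hotspot_fraction(co_table, window_bp)
    rng = np.random.default_rng(seed)
    per_chrom = []
    for chrom, g in co_table.groupby("chrom"):
        L = meta[chrom].length_bp
        lengths = (g.right - g.left).to_numpy(dtype=float)
        if np.any(lengths > L):
            raise ValueError(f"interval longer than chromosome {chrom}")
        starts = rng.random((n_sims, len(g))) * (L - lengths)
        mids = starts + lengths / 2
        per_chrom.append((mids // window_bp).astype(np.int64))
    null = np.empty(n_sims)
    for s in range(n_sims):
        null[s] = _multi_window_fraction([w[s] for w in per_chrom])
    return _result(f"hotspot_fraction_{window_bp}bp", observed, null, seed,
                   keep_null)


# ---------------------------------------------------------------------------
# Feature overlap
# ---------------------------------------------------------------------------

def _overlap_any(starts_sorted, ends_sorted, a, b):
    """True where interval [a, b) overlaps >= 1 feature (vectorized over a/b).

    Features overlapping [a, b) = #{feature starts < b} - #{feature ends <= a}.
    """
    n_start = np.searchsorted(starts_sorted, b, side="left")
    n_end = np.searchsorted(ends_sorted, a, side="right")
    return (n_start - n_end) > 0


def overlap_fraction(intervals: pd.DataFrame, features: pd.DataFrame) -> float:
    """Fraction of [start, end) intervals overlapping >= 1 feature."""
    hits = total = 0
    feat = {c: (np.sort(g.start.to_numpy()), np.sort(g.end.to_numpy()))
            for c, g in features.groupby("chrom")}
    for chrom, g in intervals.groupby("chrom"):
        total += len(g)
        if chrom not in feat:
            continue
        s, e = feat[chrom]
        hits += int(_overlap_any(s, e, g.start.to_numpy(), g.end.to_numpy()).sum())
    return hits / total if total else 0.0


def _co_intervals_0based(co_table: pd.DataFrame) -> pd.DataFrame:
    """CO intervals as 0-based half-open [left-1, right)."""
    return pd.DataFrame({"chrom": co_table.chrom,
                         "start": co_table.left - 1,
                         "end": co_table.right})


def feature_overlap_permutation(co_table: pd.DataFrame, features: pd.DataFrame,
                                meta: dict, n_sims: int = 10_000, seed: int = 0,
                                statistic: str = "feature_overlap",
                                respect_end_buffer: int = 0,
                                keep_null: bool = False) -> PermutationResult:
    """Monte-Carlo test of crossover-interval overlap with a feature class.

    Overlap means any shared base (half-open arithmetic).  Null placements
    are uniform per chromosome; ``respect_end_buffer`` > 0 additionally keeps
    null midpoints away from chromosome ends, matching the caller's end
    rule.  Both enrichment and depletion p-values are reported.
    """
    intervals = _co_intervals_0based(co_table)
    observed = overlap_fraction(intervals, features)
    rng = np.random.default_rng(seed)
    feat = {c: (np.sort(g.start.to_numpy()), np.sort(g.end.to_numpy()))
            for c, g in features.groupby("chrom")}
    hit_counts = np.zeros(n_sims)
    total = 0
    for chrom, g in intervals.groupby("chrom"):
        L = meta[chrom].length_bp
        lengths = (g.end - g.start).to_numpy(dtype=float)
        lo = np.full(len(g), float(respect_end_buffer))
        hi = L - respect_end_buffer - lengths
        hi = np.maximum(hi, lo + 1e-9)
        starts = lo + rng.random((n_sims, len(g))) * (hi - lo)
        total += len(g)
        if chrom not in feat:
            continue
        s, e = feat[chrom]
        hits = _overlap_any(s, e, starts, starts + lengths)
        hit_counts += hits.sum(axis=1)
    null = hit_counts / total if total else hit_counts
    return _result(statistic, observed, null, seed, keep_null)


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------

def gc_of(seq: str) -> float:
    """GC fraction of a sequence, ignoring N (NaN if no ACGT bases)."""
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    return gc / (gc + at) if gc + at else float("nan")


def gc_analysis(co_table: pd.DataFrame, fasta_path, meta: dict,
                flank_bp: int = 250_000) -> tuple:
    """Per-interval GC against pooled 250-kb flank GC, with paired t-tests.

    Each crossover interval's GC is paired with the GC of its two flanking
    regions pooled (truncated at chromosome ends).  Intervals with no
    callable base are excluded.  Returns ``(per_interval_table,
    tests_by_sex)`` where tests hold the paired-t statistic, p-value and the
    mean interval/flank GC.
    """
    from pyfaidx import Fasta

    fasta = Fasta(str(fasta_path))
    rows = []
    for row in co_table.itertuples(index=False):
        L = meta[row.chrom].length_bp
        a, b = int(row.left) - 1, int(row.right)  # 0-based half-open
        seq = str(fasta[row.chrom][a:b])
        gc_int = gc_of(seq)
        left = str(fasta[row.chrom][max(0, a - flank_bp):a])
        right = str(fasta[row.chrom][b:min(L, b + flank_bp)])
        gc_fl = gc_of(left + right)
        if np.isnan(gc_int) or np.isnan(gc_fl):
            logger.info("gc_analysis: interval %s:%d-%d has no callable "
                        "bases; excluded", row.chrom, row.left, row.right)
            continue
        rows.append((row.chrom, row.parent_sex, row.left, row.right,
                     gc_int, gc_fl))
    table = pd.DataFrame(rows, columns=["chrom", "parent_sex", "left", "right",
                                        "gc_interval", "gc_flank"])
    tests = {}
    for sex in ("male", "female"):
        sub = table[table.parent_sex == sex]
        if len(sub) < 2:
            tests[sex] = None
            continue
        t, p = stats.ttest_rel(sub.gc_interval, sub.gc_flank)
        tests[sex] = {"t": float(t), "p": float(p),
                      "mean_gc_interval": float(sub.gc_interval.mean()),
                      "mean_gc_flank": float(sub.gc_flank.mean()),
                      "n": int(len(sub))}
    return table, tests
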