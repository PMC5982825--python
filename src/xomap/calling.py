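"""Crossover calling from sibling allele-sharing tracks.

For each parent, the two transmitted gametes are compared site by site: code
0 where both offspring inherited the same parental allele, 1 where they
differ.  A crossover in either gamete flips the code, so candidate crossovers
are changepoints of this binary track.  Candidates must then pass a window
validation (sharing mean moves from < ``lo`` to > ``hi`` across the
boundary, averaged over ``window_bp``) and two distance filters: pairs of
crossovers closer than ``min_separation`` are both removed (gene-conversion /
mapping-error look-alikes; with two gametes in play neither member can be
trusted individually), and crossovers within ``end_buffer`` of a chromosome
end are removed (changepoint accuracy degrades at series ends).

A crossover is never assigned to a specific gamete — only two gametes were
sampled from each parent, so a sharing transition identifies the meiosis
pair, not the recombinant chromatid.  Counting is per sibling pair per
parent throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .changepoint import penalized_changepoints
from .phasing import GametePair

logger = logging.getLogger("xomap")

CO_COLUMNS = ["chrom", "parent_sex", "parent_id", "pair_id",
              "left", "right", "midpoint", "resolution", "status"]

STATUS_VALID = "validated"
STATUS_PAIR = "removed_pair_rule"
STATUS_END = "removed_end_rule"
STATUS_WINDOW = "removed_validation"


@dataclass
class SharingTrack:
    """Binary allele-sharing codes over informative sites of one chromosome."""

    chrom: str
    pos: np.ndarray
    codes: np.ndarray

    def __post_init__(self):
        assert len(self.pos) == len(self.codes)
        if len(self.pos) > 1:
            assert np.all(np.diff(self.pos) > 0)


def sharing_track(pair: GametePair) -> SharingTrack:
    """XOR of the two siblings' transmitted alleles."""
    if len(pair.pos) == 0:
        return SharingTrack(pair.chrom, pair.pos, np.empty(0, dtype=np.int8))
    codes = (pair.son != pair.daughter).astype(np.int8)
    return SharingTrack(pair.chrom, pair.pos, codes)


def detect_changepoints(track: SharingTrack, beta: float = 3.0) -> np.ndarray:
    """Candidate transition indices (split before ``codes[j]``)."""
    if len(track.codes) < 2:
        return np.empty(0, dtype=np.int64)
    return penalized_changepoints(track.codes, beta=beta)


def validate_crossovers(candidates, track: SharingTrack,
                        window_bp: int = 100_000,
                        lo: float = 0.1, hi: float = 0.9):
    """Keep candidates whose flanking window means straddle (lo, hi).

    The left window covers sites within ``window_bp`` left of the last site
    before the boundary; the right window mirrors it.  Windows truncated by
    the track ends use whatever sites are available; a side with zero sites
    rejects the candidate.  Returns ``(kept, rejected)`` index arrays.
    """
    pos, codes = track.pos, track.codes
    csum = np.concatenate(([0], np.cumsum(codes)))
    kept, rejected = [], []
    for j in candidates:
        lpos, rpos = pos[j - 1], pos[j]
        lo_idx = np.searchsorted(pos, lpos - window_bp, side="left")
        hi_idx = np.searchsorted(pos, rpos + window_bp, side="right")
        n_left, n_right = j - lo_idx, hi_idx - j
        if n_left == 0 or n_right == 0:
            rejected.append(j)
            logger.info("candidate at %s:%d rejected: empty validation window",
                        track.chrom, (lpos + rpos) // 2)
            continue
        left_mean = (csum[j] - csum[lo_idx]) / n_left
        right_mean = (csum[hi_idx] - csum[j]) / n_right
        if (left_mean < lo and right_mean > hi) or (left_mean > hi and right_mean < lo):
            kept.append(j)
        else:
            rejected.append(j)
    return np.array(kept, dtype=np.int64), np.array(rejected, dtype=np.int64)


def _interval_rows(pair: GametePair, track: SharingTrack, indices, status):
    rows = []
    for j in indices:
        left, right = int(track.pos[j - 1]), int(track.pos[j])
        rows.append({
            "chrom": track.chrom, "parent_sex": pair.parent_sex,
            "parent_id": pair.parent_id, "pair_id": pair.pair_id,
            "left": left, "right": right, "midpoint": (left + right) / 2,
            "resolution": right - left, "status": status,
        })
    return rows


def filter_crossovers(co_table: pd.DataFrame, meta: dict,
                      min_separation: int = 400_000,
                      end_buffer: int = 400_000) -> pd.DataFrame:
    """Apply the pair-distance and chromosome-end filters to validated COs.

    Midpoint distances are used for both rules.  Any two validated COs of the
    same (parent, pair, chromosome) closer than ``min_separation`` are *both*
    removed; survivors with a midpoint within ``end_buffer`` of either
    chromosome end are removed.
    """
    co = co_table.copy()
    valid = co.status == STATUS_VALID
    for _, idx in co[valid].groupby(["parent_id", "pair_id", "chrom"]).groups.items():
        mids = co.loc[idx, "midpoint"].to_numpy()
        order = np.argsort(mids)
        mids_sorted = mids[order]
        close = np.zeros(len(mids), dtype=bool)
        gaps = np.diff(mids_sorted)
        close_sorted = np.zeros(len(mids), dtype=bool)
        close_sorted[:-1] |= gaps < min_separation
        close_sorted[1:] |= gaps < min_separation
        close[order] = close_sorted
        co.loc[np.asarray(idx)[close], "status"] = STATUS_PAIR
    still = co.status == STATUS_VALID
    lengths = co.chrom.map({k: m.length_bp for k, m in meta.items()})
    near_end = (co.midpoint < end_buffer) | (co.midpoint > lengths - end_buffer)
    co.loc[still & near_end, "status"] = STATUS_END
    return co


def call_crossovers(pairs, meta: dict, beta: float = 3.0,
                    window_bp: int = 100_000, lo: float = 0.1, hi: float = 0.9,
                    min_separation: int = 400_000,
                    end_buffer: int = 400_000) -> pd.DataFrame:
    """Run detection, validation and filtering over gamete pairs.

    Returns one row per candidate crossover with its final status; retained
    calls carry status ``'validated'``.
    """
    rows = []
    for pair in pairs:
        track = sharing_track(pair)
        cands = detect_changepoints(track, beta=beta)
        if len(cands) == 0:
            continue
        kept, rejected = validate_crossovers(cands, track, window_bp, lo, hi)
        rows += _interval_rows(pair, track, kept, STATUS_VALID)
        rows += _interval_rows(pair, track, rejected, STATUS_WINDOW)
    co = pd.DataFrame(rows, columns=CO_COLUMNS)
    if len(co):
        co = filter_crossovers(co, meta, min_separation, end_buffer)
        co = co.sort_values(["pair_id", "parent_sex", "chrom", "midpoint"],
                            kind="stable").reset_index(drop=True)
    n_kept = int((co.status == STATUS_VALID).sum()) if len(co) else 0
    logger.info("call_crossovers: %d candidates, %d retained", len(co), n_kept)
    return co


def retained(co_table: pd.DataFrame) -> pd.DataFrame:
    """Subset of calls that survived every filter."""
    if not len(co_table):
        return co_table
    return co_table[co_table.status == STATUS_VALID].reset_index(drop=True)


def multi_co_events(co_table: pd.DataFrame, min_count: int = 3) -> pd.DataFrame:
    """Chromosome/pair/parent combinations with >= ``min_count`` retained COs.

    Three or more sharing transitions on one chromosome in a sibling pair
    imply that at least one of the two gametes carried a double crossover
    (two transitions could still be one crossover in each gamete).
    """
    kept = retained(co_table)
    if not len(kept):
        return pd.DataFrame(columns=["parent_sex", "parent_id", "pair_id",
                                     "chrom", "n_cos"])
    counts = (kept.groupby(["parent_sex", "parent_id", "pair_id", "chrom"])
              .size().rename("n_cos").reset_index())
    return counts[counts.n_cos >= min_count].reset_index(drop=True)
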