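"""Transmission phasing of quartet genotypes.

Each offspring inherits one allele from each parent; at most sites the
assignment is forced by Mendelian consistency.  Phase is computed per site
independently — isolated errors are absorbed downstream by the changepoint
validation stage, not here.

A site enters a parent's gamete-pair track only when (a) it passes the GQ/TP
quality filters, (b) the transmitted alleles are uniquely determined for
*both* offspring, and (c) the focal parent is heterozygous (a homozygous
parent transmits the same allele from either haplotype, so the site carries
no crossover information for that parent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import MISSING, VariantTable

logger = logging.getLogger("xomap")

# per-site phase status codes
PHASED = 0
UNDETERMINED = 1
VIOLATION = 2
INCOMPLETE = 3  # missing genotype somewhere in the trio

#: TP score emitted for uniquely phased sites (mirrors the TP < 60 filter
#: semantics of externally phased VCFs)
TP_PHASED = 60


def phase_site(father_gt, mother_gt, offspring_gt):
    """Phase a single site for one offspring.

    Genotypes are unordered allele pairs (tuples over {0, 1}) or ``None`` for
    missing.  Returns ``(status, alleles)`` where status is one of
    :data:`PHASED`, :data:`UNDETERMINED`, :data:`VIOLATION`,
    :data:`INCOMPLETE` and ``alleles`` is ``(paternal, maternal)`` when
    phased, else ``None``.

    The assignment is found by testing every (paternal, maternal) allele pair
    drawn from the parents' genotypes against the offspring genotype; a
    unique survivor is a phase, none is a Mendelian violation, several is
    undetermined (e.g. all three individuals heterozygous).
    """
    if father_gt is None or mother_gt is None or offspring_gt is None:
        return INCOMPLETE, None
    target = tuple(sorted(offspring_gt))
    assignments = {(p, m)
                   for p in set(father_gt) for m in set(mother_gt)
                   if tuple(sorted((p, m))) == target}
    if not assignments:
        return VIOLATION, None
    if len(assignments) > 1:
        return UNDETERMINED, None
    return PHASED, assignments.pop()


def _phase_offspring_vec(gt: np.ndarray, off_idx: int):
    """Vectorized phase over all sites for one offspring (index 2 or 3).

    Returns (status, paternal, maternal) arrays; alleles are -1 when not
    phased.
    """
    fa, mo, of = gt[:, 0, :], gt[:, 1, :], gt[:, off_idx, :]
    a, b = of[:, 0].astype(np.int16), of[:, 1].astype(np.int16)
    incomplete = (fa == MISSING).any(1) | (mo == MISSING).any(1) | (of == MISSING).any(1)

    def has(parent, x):
        return (parent[:, 0] == x) | (parent[:, 1] == x)

    c1 = has(fa, a) & has(mo, b)          # paternal=a, maternal=b
    c2 = has(fa, b) & has(mo, a)          # paternal=b, maternal=a
    hom = a == b

    status = np.full(len(a), UNDETERMINED, dtype=np.int8)
    pat = np.full(len(a), -1, dtype=np.int8)
    mat = np.full(len(a), -1, dtype=np.int8)

    status[~c1 & ~c2] = VIOLATION
    only1 = c1 & (~c2 | hom)
    only2 = c2 & ~c1
    status[only1] = PHASED
    pat[only1], mat[only1] = a[only1], b[only1]
    status[only2] = PHASED
    pat[only2], mat[only2] = b[only2], a[only2]
    # both candidates viable and offspring het -> ambiguous
    amb = c1 & c2 & ~hom
    status[amb] = UNDETERMINED
    pat[amb] = mat[amb] = -1
    status[incomplete] = INCOMPLETE
    pat[incomplete] = mat[incomplete] = -1
    return status, pat, mat


@dataclass
class GametePair:
    """Transmitted alleles from one parent to both offspring, one chromosome.

    ``son`` / ``daughter`` hold the allele (0/1) the parent transmitted to
    each offspring at every included informative site.
    """

    parent_sex: str            # 'male' (father) or 'female' (mother)
    parent_id: str
    pair_id: str
    chrom: str
    pos: np.ndarray
    son: np.ndarray
    daughter: np.ndarray

    def __post_init__(self):
        assert len(self.pos) == len(self.son) == len(self.daughter)


def phase_quartet(table: VariantTable, min_gq: int = 999, min_tp: int = 60,
                  parent_ids=("father", "mother"), pair_id: str = "pair0"):
    """Phase a quartet into per-parent, per-chromosome gamete pairs.

    Sites are excluded when any individual's GQ is below ``min_gq``, when a
    TP field is present and below ``min_tp`` for any individual, when any
    genotype is missing, or when transmission is not uniquely determined for
    both offspring.  Returns ``(pairs, stats)`` where ``pairs`` is a list of
    :class:`GametePair` and ``stats`` counts sites per filtering outcome.
    """
    gq_ok = (table.gq >= min_gq).all(axis=1)
    tp_ok = np.ones(table.n_sites, dtype=bool) if table.tp is None \
        else (table.tp >= min_tp).all(axis=1)
    quality_ok = gq_ok & tp_ok

    s_status, s_pat, s_mat = _phase_offspring_vec(table.gt, 2)
    d_status, d_pat, d_mat = _phase_offspring_vec(table.gt, 3)
    both_phased = (s_status == PHASED) & (d_status == PHASED)
    violation = (s_status == VIOLATION) | (d_status == VIOLATION)

    usable = quality_ok & both_phased
    stats = {
        "n_sites": table.n_sites,
        "n_quality_fail": int((~quality_ok).sum()),
        "n_violation": int((quality_ok & violation).sum()),
        "n_undetermined": int((quality_ok & ~both_phased & ~violation).sum()),
        "n_phased_both": int(usable.sum()),
    }
    logger.info("phase_quartet(%s): %s", pair_id, stats)

    fa_het = table.gt[:, 0, 0] != table.gt[:, 0, 1]
    mo_het = table.gt[:, 1, 0] != table.gt[:, 1, 1]

    pairs = []
    for name in table.chroms():
        on_chrom = table.chrom == name
        for sex, pid, het, s_all, d_all in (
                ("male", parent_ids[0], fa_het, s_pat, d_pat),
                ("female", parent_ids[1], mo_het, s_mat, d_mat)):
            m = on_chrom & usable & het
            if not m.any():
                logger.warning("phase_quartet(%s): no informative sites for "
                               "%s on %s", pair_id, pid, name)
            pairs.append(GametePair(sex, pid, pair_id, name, table.pos[m],
                                    s_all[m].copy(), d_all[m].copy()))
    return pairs, stats


def emit_tp(table: VariantTable, min_gq: int = 999) -> np.ndarray:
    """Phasing-confidence analog for tables phased by this package.

    ``TP_PHASED`` for sites uniquely phased for the individual's trio with
    all GQ passing, else 0.  External VCFs carrying their own TP field are
    honored upstream and never overwritten.
    """
    s_status, _, _ = _phase_offspring_vec(table.gt, 2)
    d_status, _, _ = _phase_offspring_vec(table.gt, 3)
    ok = (table.gq >= min_gq).all(axis=1) & (s_status == PHASED) & (d_status == PHASED)
    return np.where(ok[:, None], TP_PHASED, 0).astype(np.int32) * np.ones((1, 4), dtype=np.int32)
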