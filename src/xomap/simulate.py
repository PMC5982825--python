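"""Synthetic interspecific-cross quartets with known meiotic crossovers.

The generator emulates the study design the caller targets: two highly
diverged parents crossed to produce a son and a daughter, sequenced as a
quartet.  Divergence between the parental genomes makes SNPs dense and
informative; each parent's two haplotypes are distinguishable wherever that
parent is heterozygous, so transmitted gametes can be reconstructed and
crossovers located between informative sites.

Meioses follow the obligate-crossover model: every chromosome receives one
chiasma per meiosis plus a Poisson number of extras, placed from a piecewise
density with a telomere-concentration term and a centromere-suppression term
and thinned to a hard-core minimum separation (a simple stand-in for
crossover interference).  Each chiasma involves two of the four chromatids,
so it appears in the single transmitted gamete with probability 1/2 —
observed crossovers per gamete average half the chiasma count.

Ground truth records every chiasma, every retained gamete breakpoint, and
the per-sibling-pair observable transitions (the symmetric difference of the
two gametes' breakpoints) with detectability flags mirroring the caller's
end-distance and pair-distance exclusion rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ChromosomeMeta, VariantTable, MISSING

GENOTYPES = np.array([[0, 0], [0, 1], [1, 1]], dtype=np.int8)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class MeiosisParams:
    """Sex-specific chiasma placement model.

    extra_co_rate
        Mean count of chiasmata beyond the obligate one (Poisson).
    telomere_fraction / telomere_weight
        The placement density is multiplied by ``1 + telomere_weight`` within
        the distal ``telomere_fraction`` of each chromosome end.
    centromere_radius_bp / centromere_suppression
        Density is multiplied by ``centromere_suppression`` (0 = total
        suppression) within the radius of the centromere, when one is known.
    interference_min_bp
        Hard-core minimum distance between chiasmata of one meiosis.
    """

    sex: str
    obligate_co: bool = True
    extra_co_rate: float = 0.0
    telomere_fraction: float = 0.15
    telomere_weight: float = 0.0
    centromere_radius_bp: int = 5_000_000
    centromere_suppression: float = 1.0
    interference_min_bp: int = 1_000_000

    @classmethod
    def male(cls) -> "MeiosisParams":
        """Strong telomere concentration, near-total centromere suppression."""
        return cls(sex="male", extra_co_rate=0.0, telomere_fraction=0.15,
                   telomere_weight=8.0, centromere_radius_bp=5_000_000,
                   centromere_suppression=0.05)

    @classmethod
    def female(cls) -> "MeiosisParams":
        """Near-uniform placement, mild centromere suppression, more COs."""
        return cls(sex="female", extra_co_rate=0.6, telomere_fraction=0.15,
                   telomere_weight=0.0, centromere_radius_bp=2_000_000,
                   centromere_suppression=0.5)


# ---------------------------------------------------------------------------
# Genome scaffold
# ---------------------------------------------------------------------------

def default_genome(n_chrom: int = 21, min_mb: float = 15.0, max_mb: float = 30.0):
    """Chromosome metadata emulating the 21-chromosome stickleback karyotype.

    Lengths descend from ``max_mb`` to ``min_mb``; most chromosomes are
    acrocentric (centromere at 20% of length) with every third metacentric
    (45%).  Analogs of chromosomes 2, 4 and 8 lack a centromere and analogs
    of 9 and 19 are flagged as sex chromosomes, so spatial analyses exercise
    the same exclusions as real data.
    """
    lengths = np.linspace(max_mb, min_mb, n_chrom) * 1e6
    metas = []
    for i, L in enumerate(lengths):
        name = f"chr{i + 1}"
        if name in ("chr2", "chr4", "chr8"):
            cen = None
        else:
            frac = 0.45 if i % 3 == 2 else 0.20
            cen = int(L * frac)
        metas.append(ChromosomeMeta(name, int(L), cen,
                                    is_sex_chromosome=name in ("chr9", "chr19")))
    return metas


@dataclass
class ParentalGenome:
    """Shared SNP scaffold plus both parents' haplotypes.

    ``site_class`` per site: 0 = father-informative (father het, mother hom
    ref), 1 = mother-informative, 2 = species-diagnostic (father hom alt,
    mother hom ref; phases the offspring but carries no within-parent
    haplotype signal).  Haplotype arrays have shape (2, n_sites).
    """

    meta: list
    positions: dict
    site_class: dict
    father_haps: dict
    mother_haps: dict

    def n_sites(self, chrom: str) -> int:
        return len(self.positions[chrom])


def simulate_parental_haplotypes(meta, snp_spacing_mean: float = 2500.0,
                                 informative_fraction: float = 1.0,
                                 seed=None, rng=None) -> ParentalGenome:
    """Draw SNP positions (Poisson process) and parental haplotypes.

    ``informative_fraction`` of sites are haplotype-informative, split evenly
    between the two parents; the rest are species-diagnostic.
    """
    if snp_spacing_mean <= 0:
        raise ValueError("snp_spacing_mean must be positive")
    if not 0 < informative_fraction <= 1:
        raise ValueError("informative_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed) if rng is None else rng
    positions, site_class, fhaps, mhaps = {}, {}, {}, {}
    for m in meta:
        n = rng.poisson(m.length_bp / snp_spacing_mean)
        if n == 0:
            raise ValueError(f"no SNPs drawn on {m.name}; lower snp_spacing_mean")
        pos = np.sort(rng.integers(1, m.length_bp + 1, size=n))
        pos = np.unique(pos)
        n = len(pos)
        u = rng.random(n)
        cls = np.full(n, 2, dtype=np.int8)
        cls[u < informative_fraction / 2] = 0
        cls[(u >= informative_fraction / 2) & (u < informative_fraction)] = 1
        fh = np.zeros((2, n), dtype=np.int8)
        mh = np.zeros((2, n), dtype=np.int8)
        # father het at his informative sites, alt-allele haplotype random
        which = rng.integers(0, 2, size=n)
        f_inf = cls == 0
        fh[which[f_inf], np.flatnonzero(f_inf)] = 1
        m_inf = cls == 1
        mh[which[m_inf], np.flatnonzero(m_inf)] = 1
        fh[:, cls == 2] = 1  # diagnostic: father hom alt, mother hom ref
        positions[m.name], site_class[m.name] = pos, cls
        fhaps[m.name], mhaps[m.name] = fh, mh
    return ParentalGenome(list(meta), positions, site_class, fhaps, mhaps)


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------

def _placement_density(L: float, centromere, params: MeiosisParams):
    """Piecewise-constant chiasma density: uniform base, telomere boost,
    centromere suppression; returned as (edges, normalized segment weights)."""
    cuts = {0.0, L}
    tf = params.telomere_fraction * L
    cuts |= {tf, L - tf}
    if centromere is not None and params.centromere_suppression < 1.0:
        cuts |= {max(0.0, centromere - params.centromere_radius_bp),
                 min(L, centromere + params.centromere_radius_bp)}
    edges = np.array(sorted(c for c in cuts if 0.0 <= c <= L))
    dens = np.ones(len(edges) - 1)
    centers = (edges[:-1] + edges[1:]) / 2
    distal = (centers < tf) | (centers > L - tf)
    dens[distal] *= 1.0 + params.telomere_weight
    if centromere is not None and params.centromere_suppression < 1.0:
        near_cen = np.abs(centers - centromere) < params.centromere_radius_bp
        dens[near_cen] *= params.centromere_suppression
    weights = dens * np.diff(edges)
    total = weights.sum()
    if total <= 0:  # degenerate (all mass suppressed): fall back to uniform
        weights = np.diff(edges)
        total = weights.sum()
    return edges, weights / total


def _sample_positions(n: int, edges, weights, rng) -> np.ndarray:
    seg = rng.choice(len(weights), size=n, p=weights)
    u = rng.random(n)
    return edges[seg] + u * (edges[seg + 1] - edges[seg])


def sample_chiasmata(meta: ChromosomeMeta, params: MeiosisParams, rng) -> np.ndarray:
    """Chiasma positions for one meiosis of one chromosome."""
    n = (1 if params.obligate_co else 0) + rng.poisson(params.extra_co_rate)
    if n == 0:
        return np.empty(0)
    edges, weights = _placement_density(meta.length_bp, meta.centromere_pos_bp, params)
    kept: list = []
    for _ in range(50 * n):  # hard-core thinning with bounded retries
        if len(kept) == n:
            break
        p = float(_sample_positions(1, edges, weights, rng)[0])
        if all(abs(p - q) >= params.interference_min_bp for q in kept):
            kept.append(p)
    return np.sort(np.array(kept))


def simulate_meiosis(haps: np.ndarray, positions: np.ndarray,
                     meta: ChromosomeMeta, params: MeiosisParams, rng):
    """One meiosis: returns (gamete alleles, chiasma positions, retained
    breakpoint positions).

    Each chiasma is carried by the sampled gamete with probability 1/2 (two
    of four chromatids); the gamete is a mosaic of the parent's haplotypes
    switching at the retained breakpoints, with a random starting haplotype.
    """
    chiasmata = sample_chiasmata(meta, params, rng)
    carried = rng.random(len(chiasmata)) < 0.5
    breakpoints = chiasmata[carried]
    start = rng.integers(0, 2)
    hap_idx = (start + np.searchsorted(breakpoints, positions)) % 2
    gamete = haps[hap_idx, np.arange(len(positions))]
    return gamete, chiasmata, breakpoints


# ---------------------------------------------------------------------------
# Quartets and truth
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Ground truth for simulated quartets.

    ``chiasmata`` rows: pair_id, parent_sex, offspring, chrom, pos, retained.
    ``transitions`` rows: pair_id, parent_sex, chrom, pos, detectable, reason
    — the observable sharing-track switch positions for each sibling pair,
    i.e. the symmetric difference of the two gametes' breakpoint sets.
    """

    chiasmata: pd.DataFrame
    transitions: pd.DataFrame


def _transition_flags(positions: np.ndarray, length: int,
                      min_separation: int, end_buffer: int):
    flags, reasons = [], []
    for i, p in enumerate(positions):
        others = np.delete(positions, i)
        if p < end_buffer or p > length - end_buffer:
            flags.append(False); reasons.append("end_rule")
        elif len(others) and np.min(np.abs(others - p)) < min_separation:
            flags.append(False); reasons.append("pair_rule")
        else:
            flags.append(True); reasons.append("")
    return flags, reasons


def simulate_quartet(genome: ParentalGenome, params_male: MeiosisParams,
                     params_female: MeiosisParams, rng, pair_id: str = "pair0",
                     min_separation: int = 400_000, end_buffer: int = 400_000):
    """Simulate one quartet: 4 meioses (2 per parent).

    Returns ``(chrom, pos, gt, truth, gametes)`` where ``gametes`` maps
    ``(sex, offspring)`` to the transmitted allele array per chromosome.
    """
    chi_rows, tr_rows = [], []
    gt_chunks, chrom_chunks, pos_chunks = [], [], []
    gametes_out: dict = {}
    for m in genome.meta:
        pos = genome.positions[m.name]
        gametes = {}
        bps = {}
        for sex, haps, params in (("male", genome.father_haps[m.name], params_male),
                                  ("female", genome.mother_haps[m.name], params_female)):
            for off in ("son", "daughter"):
                g, chias, kept = simulate_meiosis(haps, pos, m, params, rng)
                gametes[(sex, off)] = g
                gametes_out.setdefault((sex, off), {})[m.name] = g
                bps[(sex, off)] = kept
                for c in chias:
                    chi_rows.append((pair_id, sex, off, m.name, float(c),
                                     bool(c in kept)))
        for sex in ("male", "female"):
            trans = np.sort(np.concatenate([bps[(sex, "son")], bps[(sex, "daughter")]]))
            flags, reasons = _transition_flags(trans, m.length_bp,
                                              min_separation, end_buffer)
            for p, f, r in zip(trans, flags, reasons):
                tr_rows.append((pair_id, sex, m.name, float(p), f, r))
        n = len(pos)
        gt = np.empty((n, 4, 2), dtype=np.int8)
        fh, mh = genome.father_haps[m.name], genome.mother_haps[m.name]
        gt[:, 0, :] = np.sort(fh.T, axis=1)
        gt[:, 1, :] = np.sort(mh.T, axis=1)
        for j, off in ((2, "son"), (3, "daughter")):
            pair = np.stack([gametes[("male", off)], gametes[("female", off)]], axis=1)
            gt[:, j, :] = np.sort(pair, axis=1)
        gt_chunks.append(gt)
        chrom_chunks.append(np.full(n, m.name, dtype=object))
        pos_chunks.append(pos)
    gt = np.concatenate(gt_chunks)
    truth = SimTruth(
        pd.DataFrame(chi_rows, columns=["pair_id", "parent_sex", "offspring",
                                        "chrom", "pos", "retained"]),
        pd.DataFrame(tr_rows, columns=["pair_id", "parent_sex", "chrom", "pos",
                                       "detectable", "reason"]),
    )
    return (np.concatenate(chrom_chunks), np.concatenate(pos_chunks), gt,
            truth, gametes_out)


def emit_quartet_table(genome, gt, chrom, pos, rng, pair_index: int = 0,
                       error_rate: float = 0.0, missing_rate: float = 0.0,
                       gq_flag_prob: float = 0.5, max_gq: int = 999) -> VariantTable:
    """Apply genotyping error/missingness and package genotypes as a table.

    Symmetric errors replace a genotype with one of the other two genotype
    classes.  GQ is ``max_gq`` for clean genotypes; a perturbed genotype is
    flagged with a low GQ with probability ``gq_flag_prob`` (so the GQ filter
    removes some errors while the rest exercise the caller's noise
    handling).
    """
    if not (0 <= error_rate < 1 and 0 <= missing_rate < 1):
        raise ValueError("rates must be in [0, 1)")
    n = len(pos)
    gt = gt.copy()
    gq = np.full((n, 4), max_gq, dtype=np.int32)
    if error_rate > 0:
        err = rng.random((n, 4)) < error_rate
        idx = np.argwhere(err)
        for i, j in idx:
            current = tuple(sorted(gt[i, j]))
            choices = [g for g in range(3) if tuple(GENOTYPES[g]) != current]
            gt[i, j] = GENOTYPES[rng.choice(choices)]
        flag = err & (rng.random((n, 4)) < gq_flag_prob)
        gq[flag] = rng.integers(0, max_gq, size=int(flag.sum()))
    if missing_rate > 0:
        miss = rng.random((n, 4)) < missing_rate
        gt[miss] = MISSING
        gq[miss] = 0
    samples = (f"sire{pair_index}", f"dam{pair_index}",
               f"son{pair_index}", f"daughter{pair_index}")
    ref = np.full(n, "A", dtype=object)
    alt = np.full(n, "C", dtype=object)
    return VariantTable(samples, chrom, pos, ref, alt, gt, gq)


@dataclass
class SimulatedDataset:
    """A batch of quartets plus merged ground truth and usage flags."""

    meta: list
    tables: list
    truth: SimTruth
    use_mother: list = field(default_factory=list)

    @property
    def meioses_by_sex(self) -> dict:
        n_m = 2 * len(self.tables)
        n_f = 2 * sum(self.use_mother)
        return {"male": n_m, "female": n_f}


def simulate_dataset(meta=None, n_quartets: int = 15, n_female_used: int = 12,
                     params_male: MeiosisParams | None = None,
                     params_female: MeiosisParams | None = None,
                     snp_spacing_mean: float = 2500.0,
                     informative_fraction: float = 1.0,
                     error_rate: float = 1e-3, missing_rate: float = 0.0,
                     min_separation: int = 400_000, end_buffer: int = 400_000,
                     seed: int = 0) -> SimulatedDataset:
    """Simulate a full study: ``n_quartets`` quartets over one genome.

    Defaults mirror the emulated study design: 15 quartets (30 meioses per
    parent sex) with the mother's side of only 12 quartets analyzed (24
    female meioses; the study excluded pseudo-replicated female gametes),
    male placement telomere-concentrated and centromere-suppressed, female
    placement near-uniform with extra crossovers.
    """
    rng = np.random.default_rng(seed)
    meta = default_genome() if meta is None else meta
    params_male = MeiosisParams.male() if params_male is None else params_male
    params_female = MeiosisParams.female() if params_female is None else params_female
    genome = simulate_parental_haplotypes(meta, snp_spacing_mean,
                                          informative_fraction, rng=rng)
    tables, chi_frames, tr_frames, use_mother = [], [], [], []
    for q in range(n_quartets):
        pair_id = f"pair{q}"
        chrom, pos, gt, truth, _ = simulate_quartet(
            genome, params_male, params_female, rng, pair_id,
            min_separation, end_buffer)
        tables.append(emit_quartet_table(genome, gt, chrom, pos, rng, q,
                                         error_rate, missing_rate))
        chi_frames.append(truth.chiasmata)
        tr_frames.append(truth.transitions)
        use_mother.append(q < n_female_used)
    empty_chi = pd.DataFrame(columns=["pair_id", "parent_sex", "offspring",
                                      "chrom", "pos", "retained"])
    empty_tr = pd.DataFrame(columns=["pair_id", "parent_sex", "chrom", "pos",
                                     "detectable", "reason"])
    chia = pd.concat(chi_frames, ignore_index=True) if chi_frames else empty_chi
    trans = pd.concat(tr_frames, ignore_index=True) if tr_frames else empty_tr
    # drop truth for mother sides that are not analyzed
    unused = [f"pair{q}" for q in range(n_quartets) if q >= n_female_used]
    drop_c = (chia.parent_sex == "female") & chia.pair_id.isin(unused)
    drop_t = (trans.parent_sex == "female") & trans.pair_id.isin(unused)
    truth = SimTruth(chia[~drop_c].reset_index(drop=True),
                     trans[~drop_t].reset_index(drop=True))
    return SimulatedDataset(meta, tables, truth, use_mother)


# ---------------------------------------------------------------------------
# Recovery evaluation
# ---------------------------------------------------------------------------

def evaluate_recovery(co_table: pd.DataFrame, truth: SimTruth,
                      match_tol: int = 100_000) -> dict:
    """Compare retained crossover calls with detectable truth transitions.

    A truth transition is *recovered* when a retained call of the same
    (pair, parent, chromosome) has an interval containing it or a midpoint
    within ``match_tol``.  A retained call *contains truth* when its
    [left, right] interval covers some truth transition of its group (any
    detectability).  Returns recall over detectable transitions, the
    containment fraction over retained calls, and the counts.
    """
    from .calling import retained as _retained
    kept = _retained(co_table)
    groups = {}
    if len(kept):
        for key, sub in kept.groupby(["pair_id", "parent_sex", "chrom"]):
            groups[key] = (sub.left.to_numpy(), sub.right.to_numpy(),
                           sub.midpoint.to_numpy())
    det = truth.transitions[truth.transitions.detectable]
    n_rec = 0
    for row in det.itertuples(index=False):
        key = (row.pair_id, row.parent_sex, row.chrom)
        if key not in groups:
            continue
        left, right, mid = groups[key]
        if np.any((left <= row.pos) & (row.pos <= right)) \
                or np.any(np.abs(mid - row.pos) <= match_tol):
            n_rec += 1
    truth_by_group = {k: s.pos.to_numpy()
                      for k, s in truth.transitions.groupby(
                          ["pair_id", "parent_sex", "chrom"])}
    n_contain = 0
    for row in kept.itertuples(index=False):
        t = truth_by_group.get((row.pair_id, row.parent_sex, row.chrom))
        if t is not None and np.any((row.left <= t) & (t <= row.right)):
            n_contain += 1
    return {
        "n_detectable": int(len(det)),
        "n_retained": int(len(kept)),
        "recall": n_rec / len(det) if len(det) else float("nan"),
        "containment": n_contain / len(kept) if len(kept) else float("nan"),
    }


# ---------------------------------------------------------------------------
# Sequence synthesis for GC analyses
# ---------------------------------------------------------------------------

def write_synthetic_fasta(meta, path, base_gc: float = 0.445,
                          enriched_intervals=None, enriched_gc: float = 0.465,
                          seed: int = 0, line_width: int = 70) -> None:
    """Write a random genome FASTA with optional GC-enriched intervals.

    ``enriched_intervals`` is an iterable of (chrom, left, right) 1-based
    inclusive intervals whose GC probability is raised to ``enriched_gc`` —
    a synthetic planting device for exercising the interval-vs-flank GC
    statistics; real fine-scale GC structure is not modelled.
    """
    rng = np.random.default_rng(seed)
    letters = np.frombuffer(b"ATGC", dtype=np.uint8)
    with open(path, "w") as fh:
        for m in meta:
            L = m.length_bp
            gc = rng.random(L) < base_gc
            if enriched_intervals is not None:
                for chrom, left, right in enriched_intervals:
                    if chrom == m.name:
                        span = slice(max(0, int(left) - 1), min(L, int(right)))
                        n = span.stop - span.start
                        gc[span] = rng.random(n) < enriched_gc
            strand = rng.integers(0, 2, size=L)
            seq = letters[2 * gc.astype(np.uint8) + strand]
            fh.write(f">{m.name}\n")
            text = seq.tobytes().decode("ascii")
            for i in range(0, L, line_width):
                fh.write(text[i:i + line_width] + "\n")


def write_truth_tsv(truth: SimTruth, transitions_path, chiasmata_path=None) -> None:
    truth.transitions.to_csv(transitions_path, sep="\t", index=False)
    if chiasmata_path is not None:
        truth.chiasmata.to_csv(chiasmata_path, sep="\t", index=False)
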