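"""Telomere/centromere covariates, mixed-model AIC comparison, and FST*.

Crossover counts (or mean scaled FST) over chromosome segments are modelled
with Gaussian linear mixed models: distance covariates as fixed effects and
chromosome as a random intercept.  Centromere suppression is assumed to act
on *absolute* distance, so the centromere covariate is distance in Mb scaled
by the maximum arm length over the included chromosomes (a shared scale),
while the telomere covariate is relative distance scaled by half the
chromosome's own length.  Models are fit by full maximum likelihood — not
REML — so AIC is comparable across fixed-effect structures.

FST* is FST divided by the chromosome-mean FST, removing between-chromosome
level differences; its per-chromosome mean is exactly 1.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .maps import folded_coordinate

logger = logging.getLogger("xomap")

CO_MODELS = {
    "null": [],
    "telomere": ["d_telo"],
    "centromere": ["d_centro"],
    "both": ["d_telo", "d_centro"],
}

FST_MODELS = {
    "null": [],
    "center": ["d_center"],
    "centromere": ["d_centro"],
    "both": ["d_center", "d_centro"],
}


def _included(meta: dict, require_centromere: bool = True):
    out = {}
    for name, m in meta.items():
        if m.is_sex_chromosome:
            continue
        if require_centromere and m.centromere_pos_bp is None:
            logger.info("build_covariates: %s dropped (no centromere)", name)
            continue
        out[name] = m
    return out


def build_covariates(meta: dict, n_segments: int = 10,
                     scope: str = "whole") -> pd.DataFrame:
    """Segment-center distance covariates for each included chromosome.

    Columns: chrom, segment, start, end, center, d_telo (relative distance
    to the nearest end, scaled by half the chromosome length), d_centro_mb
    (absolute distance to the centromere in Mb), d_centro (the same scaled
    by the maximum arm length over included chromosomes), d_center (relative
    distance to the chromosome center).  ``scope='long_arm'`` segments only
    the centromere-to-telomere span of the long arm.  Sex chromosomes and
    chromosomes without a centromere are excluded.
    """
    if scope not in ("whole", "long_arm"):
        raise ValueError("scope must be 'whole' or 'long_arm'")
    included = _included(meta)
    if not included:
        raise ValueError("no chromosomes with centromeres to analyze")
    max_arm_mb = max(m.long_arm_bp for m in included.values()) / 1e6
    rows = []
    for name, m in sorted(included.items()):
        L, cen = m.length_bp, m.centromere_pos_bp
        if scope == "whole":
            lo, hi = 0.0, float(L)
        else:
            # long arm spans centromere -> farther telomere
            lo, hi = (cen, float(L)) if L - cen >= cen else (0.0, float(cen))
        edges = np.linspace(lo, hi, n_segments + 1)
        centers = (edges[:-1] + edges[1:]) / 2
        for s in range(n_segments):
            c = centers[s]
            rows.append({
                "chrom": name, "segment": s,
                "start": edges[s], "end": edges[s + 1], "center": c,
                "d_telo": float(folded_coordinate(c, L)),
                "d_centro_mb": abs(c - cen) / 1e6,
                "d_centro": (abs(c - cen) / 1e6) / max_arm_mb,
                "d_centro_rel": abs(c - cen) / L,
                "d_center": abs(c - L / 2) / (L / 2),
            })
    return pd.DataFrame(rows)


def count_cos_in_segments(co_table: pd.DataFrame, cov: pd.DataFrame,
                          sex: str | None = None) -> pd.DataFrame:
    """Attach crossover counts (midpoint within segment span) as ``n_co``."""
    out = cov.copy()
    sub = co_table if sex is None else co_table[co_table.parent_sex == sex]
    counts = np.zeros(len(out), dtype=int)
    for i, row in enumerate(out.itertuples(index=False)):
        on = sub[sub.chrom == row.chrom]
        counts[i] = int(((on.midpoint >= row.start)
                         & (on.midpoint < row.end)).sum())
    out["n_co"] = counts
    return out


def fit_model_ledger(df: pd.DataFrame, response: str,
                     models: dict | None = None,
                     group: str = "chrom") -> pd.DataFrame:
    """AIC ledger over candidate fixed-effect structures.

    Each candidate is a Gaussian mixed model with a random intercept per
    ``group``, fit by full ML.  ``k`` counts fixed effects plus the two
    variance parameters; AIC = 2k - 2 lnL; delta_aic is relative to the best
    converged model.  Models whose fit fails or is singular are flagged and
    excluded from the comparison.
    """
    models = CO_MODELS if models is None else models
    if df[group].nunique() < 2:
        raise ValueError("need >= 2 groups for a random-intercept model")
    rows = []
    for name, terms in models.items():
        exog = sm.add_constant(df[terms]) if terms else \
            pd.DataFrame({"const": np.ones(len(df))}, index=df.index)
        ok = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model = sm.MixedLM(df[response].astype(float), exog,
                                   groups=df[group])
                res = model.fit(reml=False)
                llf = float(res.llf)
                singular = not np.isfinite(llf)
            except Exception as exc:  # singular / failed fit
                logger.warning("fit_model_ledger: model %r failed: %s", name, exc)
                ok, llf, singular = False, np.nan, True
        k = exog.shape[1] + 2  # fixed effects + RE variance + residual variance
        aic = 2 * k - 2 * llf if ok and not singular else np.nan
        rows.append({"model": name, "terms": "+".join(terms) or "1",
                     "k": k, "loglik": llf, "aic": aic,
                     "converged": ok and not singular})
    ledger = pd.DataFrame(rows)
    best = ledger.loc[ledger.converged, "aic"].min()
    ledger["delta_aic"] = ledger.aic - best
    return ledger.sort_values("aic").reset_index(drop=True)


def best_model(ledger: pd.DataFrame) -> str:
    return str(ledger.loc[ledger.converged].iloc[0]["model"])


# ---------------------------------------------------------------------------
# FST scaling and recombination-differentiation correlation
# ---------------------------------------------------------------------------

def fst_star(fst_windows: pd.DataFrame) -> pd.DataFrame:
    """Scale each window's FST by its chromosome mean (column ``fst_star``).

    Chromosomes whose mean FST is zero or negative are excluded with a
    warning — the scale is undefined there.
    """
    out = []
    for chrom, grp in fst_windows.groupby("chrom", sort=False):
        mean = grp.fst.mean()
        if mean <= 0:
            logger.warning("fst_star: chromosome %s excluded "
                           "(mean FST %.3g <= 0)", chrom, mean)
            continue
        g = grp.copy()
        g["fst_star"] = g.fst / mean
        out.append(g)
    if not out:
        return fst_windows.iloc[0:0].assign(fst_star=[])
    return pd.concat(out, ignore_index=True)


def fst_star_by_folded_segment(fst: pd.DataFrame, meta: dict,
                               n_segments: int = 10) -> pd.DataFrame:
    """Mean FST* per folded-chromosome segment (pooled over chromosomes)."""
    rows = []
    for row in fst.itertuples(index=False):
        m = meta.get(row.chrom)
        if m is None:
            continue
        center = (row.start + row.end) / 2
        coord = float(folded_coordinate(center, m.length_bp))
        seg = min(int(coord * n_segments), n_segments - 1)
        rows.append((seg, row.fst_star))
    df = pd.DataFrame(rows, columns=["segment", "fst_star"])
    return df.groupby("segment").fst_star.mean().reset_index()


def recomb_differentiation_correlation(segment_recomb: pd.DataFrame,
                                       segment_fst: pd.DataFrame) -> tuple:
    """Pearson r and p between segment recombination and segment FST*.

    Inputs carry one row per folded segment: ``rel_length`` (mean relative
    map length) and ``fst_star``.  Returns (r, p); NaN on zero variance.
    """
    merged = segment_recomb.merge(segment_fst, on="segment")
    x, y = merged.rel_length.to_numpy(), merged.fst_star.to_numpy()
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def mean_rel_length_by_segment(segs: dict, n_segments: int = 10,
                               sexes=("male", "female")) -> pd.DataFrame:
    """Average relative map length per folded segment across chromosomes.

    ``segs`` is the output of :func:`xomap.maps.fold_and_bin`; averaging over
    the requested sexes gives the sex-averaged profile.
    """
    frames = []
    for sex in sexes:
        df = segs[sex]
        prof = df.groupby("segment").rel_length.mean()
        frames.append(prof.reindex(range(n_segments), fill_value=0.0))
    mean = sum(frames) / len(frames)
    return pd.DataFrame({"segment": mean.index, "rel_length": mean.to_numpy()})
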