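"""Genetic maps from called crossovers, and map-level comparisons.

Marker order is taken from physical positions (no multipoint
re-ordering); per adjacent-marker interval the recombination fraction
r = recombinant individuals / n is converted to centimorgans with the
Kosambi mapping function d = 25 ln((1+2r)/(1-2r)).

Between-population heterogeneity is assessed per interval with a 2x2
Pearson chi-squared test (1 df, no continuity correction) at 5%; at
chromosome and genome scale a Bonferroni threshold of 0.05 / (number of
intervals at that scale) is applied, and two populations are declared
different at a scale iff at least one interval is significant at that
corrected threshold. Letter groups summarize the pairwise decisions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDesignError, SchemaError, ValidationError, XoverError
from .io import GenotypeMatrix, MarkerMap
from .letters import compact_letters

log = logging.getLogger("xover")


def kosambi_cm(r):
    """Kosambi genetic distance in cM for recombination fraction r.

    d = 25 ln((1 + 2r) / (1 - 2r)); domain 0 <= r < 0.5.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise XoverError("Kosambi domain is 0 <= r < 0.5")
    out = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(out) if out.ndim == 0 else out


@dataclass
class GeneticMap:
    """Per-interval Kosambi map plus cumulative marker positions.

    ``intervals``: chrom, left_marker, right_marker, start, end, n_rec,
    n, r, cm, valid. ``marker_cm``: per marker cumulative cM along its
    chromosome. Intervals with r >= 0.5 are flagged invalid (cm NaN) and
    excluded from totals.
    """

    intervals: pd.DataFrame
    marker_cm: pd.DataFrame
    n_individuals: int

    @property
    def chrom_lengths_cm(self) -> pd.Series:
        valid = self.intervals[self.intervals["valid"]]
        return valid.groupby("chrom", sort=False)["cm"].sum()

    @property
    def total_cm(self) -> float:
        return float(self.intervals.loc[self.intervals["valid"], "cm"].sum())


def build_map(events: pd.DataFrame, genotypes: GenotypeMatrix,
              marker_map: MarkerMap) -> GeneticMap:
    """Per-interval r and Kosambi cM from called events."""
    n = genotypes.n_individuals
    intervals = marker_map.intervals().copy()
    if len(events):
        counts = (events.groupby(["chrom", "start"], sort=False)
                  .size().rename("n_rec"))
        intervals = intervals.merge(counts, left_on=["chrom", "start"],
                                    right_index=True, how="left")
        intervals["n_rec"] = intervals["n_rec"].fillna(0).astype(int)
    else:
        intervals["n_rec"] = 0
    intervals["n"] = n
    intervals["r"] = intervals["n_rec"] / n
    valid = intervals["r"] < 0.5
    if not valid.all():
        log.warning("build_map: %d interval(s) with r >= 0.5 flagged and "
                    "excluded from totals", int((~valid).sum()))
    intervals["valid"] = valid
    cm = np.full(len(intervals), np.nan)
    cm[valid.to_numpy()] = kosambi_cm(intervals.loc[valid, "r"].to_numpy())
    intervals["cm"] = cm
    # cumulative positions: invalid intervals contribute 0
    rows = []
    for chrom, sub in intervals.groupby("chrom", sort=False):
        step = np.nan_to_num(sub["cm"].to_numpy())
        cum = np.concatenate([[0.0], np.cumsum(step)])
        mk = list(sub["left_marker"]) + [sub["right_marker"].iloc[-1]]
        pos = list(sub["start"]) + [sub["end"].iloc[-1]]
        rows.append(pd.DataFrame({"marker": mk, "chrom": chrom,
                                  "pos_bp": pos, "cum_cm": cum}))
    marker_cm = pd.concat(rows, ignore_index=True)
    return GeneticMap(intervals, marker_cm, n)


@dataclass
class IntervalComparison:
    chrom: object
    start: int
    end: int
    table: tuple  # ((recA, nonrecA), (recB, nonrecB))
    chi2: float
    p_value: float
    significant: bool
    testable: bool


def _pearson_2x2(a_rec, a_non, b_rec, b_non):
    """Pearson chi-squared, 1 df, no continuity correction."""
    obs = np.array([[a_rec, a_non], [b_rec, b_non]], dtype=float)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        return np.nan, np.nan, False
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1)), True


def interval_heterogeneity_test(a_rec: int, n_a: int, b_rec: int, n_b: int,
                                interval=None,
                                alpha: float = 0.05) -> IntervalComparison:
    """2x2 chi-squared heterogeneity test for one shared interval."""
    chi2, p, testable = _pearson_2x2(a_rec, n_a - a_rec, b_rec, n_b - b_rec)
    chrom, start, end = interval if interval is not None else (None, -1, -1)
    return IntervalComparison(chrom, start, end,
                              ((a_rec, n_a - a_rec), (b_rec, n_b - b_rec)),
                              chi2, p, bool(testable and p < alpha), testable)


def interval_heterogeneity_tests(map_a: GeneticMap, map_b: GeneticMap,
                                 alpha: float = 0.05) -> pd.DataFrame:
    """All shared intervals of two populations mapped on one marker set."""
    a = map_a.intervals
    b = map_b.intervals
    if not (a["chrom"].tolist() == b["chrom"].tolist()
            and a["start"].tolist() == b["start"].tolist()):
        raise SchemaError("populations are not mapped on the same intervals")
    ra = a["n_rec"].to_numpy(dtype=float)
    rb = b["n_rec"].to_numpy(dtype=float)
    na = a["n"].to_numpy(dtype=float)
    nb = b["n"].to_numpy(dtype=float)
    # closed-form Pearson chi2 on [[ra, na-ra], [rb, nb-rb]]
    n_tot = na + nb
    col_rec = ra + rb
    col_non = n_tot - col_rec
    testable = (col_rec > 0) & (col_non > 0) & (na > 0) & (nb > 0)
    chi2 = np.full(len(ra), np.nan)
    num = n_tot * (ra * (nb - rb) - rb * (na - ra)) ** 2
    den = na * nb * col_rec * col_non
    chi2[testable] = num[testable] / den[testable]
    p = np.full(len(ra), np.nan)
    p[testable] = stats.chi2.sf(chi2[testable], df=1)
    return pd.DataFrame({
        "chrom": a["chrom"].to_numpy(), "start": a["start"].to_numpy(),
        "end": a["end"].to_numpy(),
        "n_rec_a": ra.astype(int), "n_rec_b": rb.astype(int),
        "chi2": chi2, "p_value": p,
        "significant": testable & (p < alpha), "testable": testable})


@dataclass
class MapLengthComparison:
    totals_cm: dict
    pairwise: pd.DataFrame  # pop_a, pop_b, scale, n_significant, threshold, differs
    genome_letters: dict
    chromosome_letters: dict  # chrom -> {pop: letters}


def maplength_comparison(populations: list,
                         alpha: float = 0.05) -> MapLengthComparison:
    """Pairwise map-length heterogeneity with Bonferroni-over-intervals.

    ``populations`` is a list of (name, GeneticMap) on one shared marker
    set. A pair differs at genome (chromosome) scale iff >= 1 interval is
    significant at alpha / n_intervals at that scale. Letters sort by
    total cM descending.
    """
    if len(populations) < 2:
        raise ValidationError("need >= 2 populations to compare")
    names = [nm for nm, _ in populations]
    maps = dict(populations)
    first = populations[0][1].intervals
    n_genome = len(first)
    chroms = list(first["chrom"].drop_duplicates())
    n_by_chrom = first.groupby("chrom", sort=False).size().to_dict()

    rows = []
    genome_diff = {}
    chrom_diff = {c: {} for c in chroms}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            tests = interval_heterogeneity_tests(maps[a], maps[b], alpha)
            thr_g = alpha / n_genome
            sig_g = int((tests["p_value"] < thr_g).sum())
            genome_diff[(a, b)] = sig_g >= 1
            rows.append((a, b, "genome", sig_g, thr_g, sig_g >= 1))
            for c in chroms:
                sub = tests[tests["chrom"] == c]
                thr_c = alpha / n_by_chrom[c]
                sig_c = int((sub["p_value"] < thr_c).sum())
                chrom_diff[c][(a, b)] = sig_c >= 1
                rows.append((a, b, str(c), sig_c, thr_c, sig_c >= 1))
    pairwise = pd.DataFrame(rows, columns=[
        "pop_a", "pop_b", "scale", "n_significant", "threshold", "differs"])

    def letters_for(diff, key=lambda nm: None):
        def differs(x, y):
            return diff.get((x, y), diff.get((y, x), False))
        order = sorted(names, key=key, reverse=True)
        return compact_letters(order, differs)

    genome_letters = letters_for(
        genome_diff, key=lambda nm: maps[nm].total_cm)
    chromosome_letters = {
        c: letters_for(chrom_diff[c],
                       key=lambda nm, c=c: maps[nm].chrom_lengths_cm.get(c, 0.0))
        for c in chroms}
    return MapLengthComparison(
        {nm: maps[nm].total_cm for nm in names}, pairwise,
        genome_letters, chromosome_letters)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float  # F-test p (== t-test p for simple OLS)
    n: int


def _ols(x, y) -> RegressionResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValidationError("regression needs >= 3 points")
    if np.allclose(x, x[0]):
        raise DegenerateDesignError("constant predictor")
    if np.allclose(y, y[0]):  # flat response: R^2 = 0 by convention
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, len(x))
    res = stats.linregress(x, y)
    return RegressionResult(float(res.slope), float(res.intercept),
                            float(res.rvalue ** 2), float(res.pvalue), len(x))


def regress_crossovers_vs_size(mean_crossovers_per_chrom,
                               covered_mbp) -> RegressionResult:
    """OLS of per-chromosome mean crossovers on marker-covered Mbp."""
    return _ols(covered_mbp, mean_crossovers_per_chrom)


def regress_rate_vs_centromere_distance(gmap: GeneticMap,
                                        marker_map: MarkerMap
                                        ) -> RegressionResult:
    """OLS of relative interval recombination rate (%) on relative
    distance to the nearest centromere edge (%).

    Rates are normalized so each chromosome's intervals sum to 100%;
    distance is |interval midpoint - nearest centromere edge| / arm
    length x 100 (0 inside the centromere).
    """
    if not marker_map.centromeres:
        raise ValidationError("centromere positions required")
    xs, ys = [], []
    for chrom, sub in gmap.intervals.groupby("chrom", sort=False):
        if chrom not in marker_map.centromeres:
            raise ValidationError(f"no centromere for chromosome {chrom}")
        cen_s, cen_e = marker_map.centromeres[chrom]
        clen = marker_map.chrom_length(chrom)
        tot = sub.loc[sub["valid"], "cm"].sum()
        if tot == 0:
            continue
        mids = ((sub["start"] + sub["end"]) / 2.0).to_numpy()
        rel_rate = 100.0 * np.nan_to_num(sub["cm"].to_numpy()) / tot
        rel_dist = np.empty(len(mids))
        for k, m in enumerate(mids):
            if m < cen_s:
                rel_dist[k] = 100.0 * (cen_s - m) / cen_s if cen_s else 0.0
            elif m > cen_e:
                arm = clen - cen_e
                rel_dist[k] = 100.0 * (m - cen_e) / arm if arm else 0.0
            else:
                rel_dist[k] = 0.0
        xs.append(rel_dist)
        ys.append(rel_rate)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if np.allclose(x, x[0]):
        raise DegenerateDesignError(
            "all intervals equidistant from the centromere")
    return _ols(x, y)
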