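"""Crossover interference via KL divergence from a shuffle null.

The data are the genetic distances between successive crossovers of one
gamete on one chromosome, expressed as fractions of that chromosome's
genetic length and binned into 10 equal bins (chromosomes pooled by
concatenating their distance lists — distances never span chromosomes).

The "no interference" reference Q is built by shuffling: per
chromosome, pool every crossover position across individuals, permute
the pooled multiset and redistribute it preserving each individual's
crossover count. This preserves the recombination landscape exactly
(same position multiset) while destroying within-gamete correlations.
Q is the binned distance distribution pooled over all shuffles; the
p-value compares KL(P, Q) with the KL(P_S, Q) of single shuffles S.

Interference strength across populations is ordered by bootstrap over
individuals, recomputing both P and a (shallower) shuffle null per
replicate, with Bonferroni-corrected pairwise reversal p-values and
compact letters, in direct analogy with the landscape ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import resolve_rng, substream
from .errors import ValidationError, XoverError
from .genmap import GeneticMap
from .landscape import (DEFAULT_BINS, BinnedDistribution, _ordering_from_bootstrap,
                        kl_divergence)

log = logging.getLogger("xover")


def crossover_genetic_positions(events: pd.DataFrame,
                                gmap: GeneticMap) -> pd.DataFrame:
    """Attach genetic (cM) and relative genetic positions to events.

    An event's genetic position is the cumulative cM of its left marker
    plus half its interval's Kosambi length (linear interpolation of the
    physical midpoint); relative position divides by the chromosome's
    total cM.
    """
    iv = gmap.intervals[["chrom", "start", "cm"]].rename(
        columns={"cm": "_iv_cm"})
    cum = gmap.marker_cm[["chrom", "pos_bp", "cum_cm"]].rename(
        columns={"pos_bp": "start", "cum_cm": "_left_cum"})
    ev = events.merge(iv, on=["chrom", "start"], how="left") \
               .merge(cum, on=["chrom", "start"], how="left")
    if ev["_left_cum"].isna().any():
        bad = ev.loc[ev["_left_cum"].isna(), ["chrom", "start"]]
        raise XoverError(
            f"event outside mapped span: {bad.head(3).to_dict('records')}")
    ev["cm"] = ev.pop("_left_cum") + np.nan_to_num(ev.pop("_iv_cm")) / 2.0
    totals = gmap.chrom_lengths_cm
    tot = ev["chrom"].map(totals).to_numpy(dtype=float)
    if np.any(tot == 0):
        raise XoverError("chromosome with zero genetic length in events")
    ev["rel_cm"] = ev["cm"] / tot
    return ev


@dataclass
class InterCrossoverSample:
    """Inter-crossover distances and the per-chromosome structures the
    shuffle null needs."""

    distances: np.ndarray  # pooled over chromosomes, fractions of cM length
    #: chrom -> (pooled positions, per-individual counts > 0)
    per_chrom: dict

    @property
    def n_distances(self) -> int:
        return len(self.distances)


def inter_crossover_distances(events_g: pd.DataFrame) -> InterCrossoverSample:
    """Distances between successive crossovers per individual-chromosome.

    ``events_g`` must carry ``rel_cm`` (see
    :func:`crossover_genetic_positions`). Units with < 2 crossovers
    contribute nothing; chromosomes are pooled by concatenation.
    """
    dists = []
    per_chrom = {}
    for chrom, sub in events_g.groupby("chrom", sort=False):
        counts = sub.groupby("individual", sort=False).size()
        pos_sorted = []
        for ind, ssub in sub.groupby("individual", sort=False):
            p = np.sort(ssub["rel_cm"].to_numpy())
            pos_sorted.append(p)
            if len(p) >= 2:
                dists.append(np.diff(p))
        per_chrom[chrom] = (np.concatenate(pos_sorted),
                            counts.to_numpy())
    distances = np.concatenate(dists) if dists else np.empty(0)
    return InterCrossoverSample(distances, per_chrom)


def _bin_rows(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Row-wise histogram of a (R, m) matrix of values in [0, 1]."""
    r, m = values.shape
    idx = np.clip((values * n_bins).astype(np.int64), 0, n_bins - 1)
    offs = idx + n_bins * np.arange(r)[:, None]
    return np.bincount(offs.ravel(), minlength=r * n_bins).reshape(r, n_bins)


def _shuffle_distance_hists(pos: np.ndarray, counts: np.ndarray,
                            n_shuffles: int, rng: np.random.Generator,
                            n_bins: int) -> np.ndarray:
    """(n_shuffles, n_bins) distance histograms of random reassignments.

    Each row permutes the pooled position multiset and redistributes it
    over individuals with the original per-individual counts.
    """
    m = len(pos)
    seg = np.repeat(np.arange(len(counts)), counts).astype(float)
    within = seg[1:] == seg[:-1]
    if not within.any():
        return np.zeros((n_shuffles, n_bins), dtype=np.int64)
    out = np.empty((n_shuffles, n_bins), dtype=np.int64)
    done = 0
    chunk = max(1, min(n_shuffles, 2_000_000 // max(m, 1)))
    while done < n_shuffles:
        r = min(chunk, n_shuffles - done)
        perm = np.argsort(rng.random((r, m)), axis=1)
        shuffled = pos[perm]
        # offset by 2*segment id: sorting groups by individual, sorted within
        s = np.sort(shuffled + 2.0 * seg, axis=1) - 2.0 * seg
        d = (s[:, 1:] - s[:, :-1])[:, within]
        out[done:done + r] = _bin_rows(d, n_bins)
        done += r
    return out


def shuffle_null(sample: InterCrossoverSample, n_shuffles: int = 10_000,
                 seed: int | None = None,
                 rng: np.random.Generator | None = None,
                 n_bins: int = DEFAULT_BINS):
    """Build the no-interference reference Q and per-shuffle histograms.

    Returns (Q, hists) where Q is the BinnedDistribution pooled over all
    shuffles and hists the (n_shuffles, n_bins) per-shuffle matrix.
    """
    rng = resolve_rng(rng, seed, "shuffle")
    hists = np.zeros((n_shuffles, n_bins), dtype=np.int64)
    for chrom, (pos, counts) in sample.per_chrom.items():
        hists += _shuffle_distance_hists(pos, counts, n_shuffles, rng,
                                         n_bins)
    q_counts = hists.sum(axis=0)
    if q_counts.sum() == 0:
        raise ValidationError(
            "shuffle null undefined: no individual has >= 2 crossovers")
    return BinnedDistribution(q_counts), hists


@dataclass
class InterferenceResult:
    kl: float
    p_value: float
    n_shuffles: int
    reference: BinnedDistribution
    n_distances: int


def _kl_rows_vs_q(hists: np.ndarray, q: np.ndarray) -> np.ndarray:
    tot = hists.sum(axis=1, keepdims=True).astype(float)
    ok = tot[:, 0] > 0
    p = np.zeros_like(hists, dtype=float)
    p[ok] = hists[ok] / tot[ok]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p / q), 0.0)
    vals = terms.sum(axis=1)
    vals[~ok] = np.nan
    return vals


def kl_to_no_interference(sample: InterCrossoverSample,
                          n_shuffles: int = 10_000,
                          seed: int | None = None,
                          rng: np.random.Generator | None = None,
                          n_bins: int = DEFAULT_BINS,
                          pseudocount: float | None = None
                          ) -> InterferenceResult:
    """KL(P, Q) of observed distances against the shuffle null, with the
    randomization p-value p = #{KL(P_S, Q) >= KL(P, Q)} / n_shuffles."""
    if sample.n_distances == 0:
        raise ValidationError("no inter-crossover distances in sample")
    rng = resolve_rng(rng, seed, "interference")
    q_dist, hists = shuffle_null(sample, n_shuffles, rng=rng, n_bins=n_bins)
    if pseudocount is not None:
        q_dist = q_dist.with_pseudocount(pseudocount)
    p_dist = _bin_rows(sample.distances[None, :], n_bins)[0]
    observed = kl_divergence(BinnedDistribution(p_dist), q_dist)
    q = q_dist.probabilities()
    null = _kl_rows_vs_q(hists, q)
    p_value = float(np.nanmean(null >= observed))
    return InterferenceResult(observed, p_value, n_shuffles, q_dist,
                              sample.n_distances)


def _resample_sample(events_g: pd.DataFrame, individuals,
                     rng: np.random.Generator) -> InterCrossoverSample:
    """Bootstrap individuals; rebuild the distance sample for the
    resampled population (duplicated individuals duplicate their sets)."""
    ids = list(individuals)
    n = len(ids)
    by_ind = {}
    for (ind, chrom), sub in events_g.groupby(["individual", "chrom"],
                                              sort=False):
        by_ind.setdefault(ind, {})[chrom] = np.sort(
            sub["rel_cm"].to_numpy())
    pick = rng.integers(0, n, size=n)
    dists = []
    pooled = {}
    counts = {}
    for k in pick:
        for chrom, p in by_ind.get(ids[k], {}).items():
            pooled.setdefault(chrom, []).append(p)
            counts.setdefault(chrom, []).append(len(p))
            if len(p) >= 2:
                dists.append(np.diff(p))
    per_chrom = {c: (np.concatenate(pooled[c]), np.asarray(counts[c]))
                 for c in pooled}
    distances = np.concatenate(dists) if dists else np.empty(0)
    return InterCrossoverSample(distances, per_chrom)


def interference_ordering_test(populations: list, n_bootstraps: int = 10_000,
                               shuffles_per_replicate: int = 100,
                               n_shuffles: int = 10_000, seed: int = 0,
                               n_bins: int = DEFAULT_BINS,
                               alpha: float = 0.05,
                               pseudocount: float | None = 0.5):
    """Order populations by interference strength (KL to no-interference).

    ``populations``: list of (name, events_g, individuals) where
    events_g carries ``rel_cm``. Observed KLs use ``n_shuffles``; each
    bootstrap replicate recomputes P and a shallower Q
    (``shuffles_per_replicate`` shuffles) on the resample. Replicate KLs
    use a pseudocount reference by default, since a shallow Q can leave
    bins empty.
    """
    if len(populations) < 2:
        raise ValidationError("ordering test needs >= 2 populations")
    observed = {}
    boot = {}
    for name, events_g, individuals in populations:
        sample = inter_crossover_distances(events_g)
        res = kl_to_no_interference(
            sample, n_shuffles, rng=substream(seed, "iord-obs", name),
            n_bins=n_bins)
        observed[name] = res.kl
        rng = substream(seed, "iord-boot", name)
        vals = np.empty(n_bootstraps)
        for b in range(n_bootstraps):
            while True:
                rs = _resample_sample(events_g, individuals, rng)
                if rs.n_distances > 0:
                    break
                log.info("interference ordering: redrew empty resample")
            q_dist, _ = shuffle_null(rs, shuffles_per_replicate, rng=rng,
                                     n_bins=n_bins)
            if pseudocount is not None:
                q_dist = q_dist.with_pseudocount(pseudocount)
            p_counts = _bin_rows(rs.distances[None, :], n_bins)[0]
            vals[b] = kl_divergence(BinnedDistribution(p_counts), q_dist)
        boot[name] = vals
    return _ordering_from_bootstrap(observed, boot, alpha)
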