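"""Binned crossover landscapes and KL divergence to flatness.

Each chromosome is segmented into 10 bins of identical physical size;
the landscape P is the binned distribution of crossover point positions
(interval midpoints, as physical fractions of chromosome length). The
divergence of P from the flat landscape Q_i = 1/10 is the natural-log
plug-in KL divergence sum_i P_i log(P_i / Q_i).

Inference:

* flatness p-value — randomize every crossover uniformly on [0, 1] and
  recompute KL; p = proportion of null KL >= observed;
* ordering test — bootstrap individuals (their full crossover sets
  travel with them), pair the i-th replicate of each population's
  independent stream, count order reversals k; raw p = k/B, Bonferroni
  over the pairs performed, compact letters at adjusted 5%;
* pairwise landscape KL — KL(P_A, Q_B) with a percentile bootstrap CI
  from joint resampling of both populations.

An occupied-P bin facing an empty-Q bin is an explicit infinite-KL
error, never silently capped; a 0.5-per-bin pseudocount is available as
an opt-in.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import resolve_rng, substream
from .errors import ValidationError, XoverError, InfiniteKLError
from .io import MarkerMap
from .letters import compact_letters

log = logging.getLogger("xover")

DEFAULT_BINS = 10
_CHUNK = 512  # rows per block in vectorized resampling loops


@dataclass
class BinnedDistribution:
    """Non-negative counts over equal-width bins on [0, 1]."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 1 or len(c) < 2:
            raise ValidationError("counts must be a 1-d vector of >= 2 bins")
        if np.any(c < 0):
            raise ValidationError("counts must be non-negative")
        self.counts = c

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def probabilities(self) -> np.ndarray:
        if self.total == 0:
            raise ValidationError("probabilities undefined: zero total count")
        return self.counts / self.total

    def with_pseudocount(self, pseudo: float = 0.5) -> "BinnedDistribution":
        return BinnedDistribution(self.counts + pseudo)


def bin_relative_positions(positions, n_bins: int = DEFAULT_BINS
                           ) -> BinnedDistribution:
    """Bin positions in [0, 1]; bin k is [k/n, (k+1)/n), last bin closed."""
    pos = np.asarray(positions, dtype=float)
    if len(pos) and (pos.min() < 0.0 or pos.max() > 1.0):
        raise XoverError("positions must lie in [0, 1]")
    idx = np.minimum((pos * n_bins).astype(np.int64), n_bins - 1)
    return BinnedDistribution(np.bincount(idx, minlength=n_bins))


def _probs(dist) -> np.ndarray:
    if isinstance(dist, BinnedDistribution):
        return dist.probabilities()
    p = np.asarray(dist, dtype=float)
    return p / p.sum()


def kl_divergence(p_dist, q_dist) -> float:
    """Plug-in KL(P, Q) in nats; 0 log 0 := 0; empty-Q/occupied-P raises."""
    p = _probs(p_dist)
    q = _probs(q_dist)
    if p.shape != q.shape:
        raise ValidationError("P and Q must have the same number of bins")
    mask = p > 0
    bad = mask & (q == 0)
    if bad.any():
        raise InfiniteKLError(np.nonzero(bad)[0])
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def relative_positions(events: pd.DataFrame, marker_map: MarkerMap,
                       chrom=None) -> np.ndarray:
    """Event midpoints as fractions of chromosome physical length."""
    ev = events if chrom is None else events[events["chrom"] == chrom]
    if not len(ev):
        return np.empty(0)
    lengths = ev["chrom"].map(marker_map.chrom_lengths).to_numpy(dtype=float)
    return ev["midpoint"].to_numpy(dtype=float) / lengths


def kl_to_flat(positions, n_bins: int = DEFAULT_BINS) -> float:
    """KL of the binned positions against the uniform landscape."""
    dist = bin_relative_positions(positions, n_bins)
    if dist.total == 0:
        raise ValidationError("KL to flat undefined with zero crossovers")
    return kl_divergence(dist, np.full(n_bins, 1.0 / n_bins))


def landscape_kl_report(events: pd.DataFrame, marker_map: MarkerMap,
                        n_bins: int = DEFAULT_BINS) -> dict:
    """KL to flat per chromosome plus the pooled value (None if a unit
    has no crossovers)."""
    out = {}
    for chrom in marker_map.chromosomes:
        pos = relative_positions(events, marker_map, chrom)
        out[chrom] = kl_to_flat(pos, n_bins) if len(pos) else None
    pooled = relative_positions(events, marker_map)
    out["pooled"] = kl_to_flat(pooled, n_bins) if len(pooled) else None
    return out


def _null_kl_flat(n_events: int, n_rand: int, n_bins: int,
                  rng: np.random.Generator) -> np.ndarray:
    """KL-to-flat of ``n_rand`` uniform redraws of n_events positions."""
    flat_log = math.log(n_bins)
    out = np.empty(n_rand)
    done = 0
    while done < n_rand:
        r = min(_CHUNK, n_rand - done)
        idx = rng.integers(0, n_bins, size=(r, n_events))
        offs = idx + n_bins * np.arange(r)[:, None]
        counts = np.bincount(offs.ravel(), minlength=r * n_bins) \
            .reshape(r, n_bins)
        p = counts / n_events
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * (np.log(np.where(p > 0, p, 1.0))
                                         + flat_log), 0.0)
        out[done:done + r] = terms.sum(axis=1)
        done += r
    return out


@dataclass
class KLFlatnessResult:
    kl: float
    p_value: float
    n_randomizations: int
    n_crossovers: int


def flatness_pvalue(positions, n_randomizations: int = 10_000,
                    seed: int | None = None,
                    rng: np.random.Generator | None = None,
                    n_bins: int = DEFAULT_BINS) -> KLFlatnessResult:
    """Randomization test of H0 "flat landscape".

    Each randomization repositions every crossover uniformly on [0, 1]
    (within its chromosome; relative coordinates make the chromosomes
    exchangeable) and recomputes KL to flat. p = (# null KL >=
    observed) / n_randomizations.
    """
    positions = np.asarray(positions, dtype=float)
    if len(positions) == 0:
        raise ValidationError("flatness test undefined with zero crossovers")
    rng = resolve_rng(rng, seed, "flatness")
    observed = kl_to_flat(positions, n_bins)
    # uniform position -> uniform bin index: draw bins directly
    null = _null_kl_flat(len(positions), n_randomizations, n_bins, rng)
    p = float(np.mean(null >= observed))
    return KLFlatnessResult(observed, p, n_randomizations, len(positions))


def individual_bin_counts(events: pd.DataFrame, marker_map: MarkerMap,
                          individuals, n_bins: int = DEFAULT_BINS,
                          chrom=None) -> np.ndarray:
    """(n_individuals, n_bins) landscape bin counts per individual.

    Individuals without crossovers appear as zero rows; they remain
    bootstrap units.
    """
    ev = events if chrom is None else events[events["chrom"] == chrom]
    if len(ev):
        lengths = ev["chrom"].map(marker_map.chrom_lengths) \
            .to_numpy(dtype=float)
        pos = ev["midpoint"].to_numpy(dtype=float) / lengths
    else:
        pos = np.empty(0)
    bins = np.minimum((pos * n_bins).astype(np.int64), n_bins - 1)
    ind_index = pd.Index(individuals)
    codes = ind_index.get_indexer(ev["individual"])
    if (codes < 0).any():
        raise ValidationError("event individual absent from population list")
    mat = np.zeros((len(ind_index), n_bins), dtype=np.int64)
    np.add.at(mat, (codes, bins), 1)
    return mat


def _kl_to_flat_rows(counts: np.ndarray) -> np.ndarray:
    """Row-wise KL to flat for a (R, n_bins) count matrix."""
    n_bins = counts.shape[1]
    tot = counts.sum(axis=1, keepdims=True).astype(float)
    p = counts / tot
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * (np.log(np.where(p > 0, p, 1.0))
                                     + math.log(n_bins)), 0.0)
    return terms.sum(axis=1)


def bootstrap_kl_to_flat(bin_counts: np.ndarray, n_bootstraps: int = 10_000,
                         seed: int | None = None,
                         rng: np.random.Generator | None = None
                         ) -> np.ndarray:
    """Bootstrap distribution of pooled KL-to-flat over individuals.

    Resamples the rows of ``bin_counts`` (individuals) with replacement;
    zero-crossover resamples are redrawn and the occurrence logged.
    """
    n = bin_counts.shape[0]
    if n < 2:
        raise ValidationError("bootstrap needs >= 2 individuals")
    rng = resolve_rng(rng, seed, "bootstrap-kl-flat")
    out = np.empty(n_bootstraps)
    done = 0
    n_redrawn = 0
    while done < n_bootstraps:
        r = min(_CHUNK, n_bootstraps - done)
        idx = rng.integers(0, n, size=(r, n))
        tot = bin_counts[idx].sum(axis=1)  # (r, n_bins)
        empty = tot.sum(axis=1) == 0
        while empty.any():
            n_redrawn += int(empty.sum())
            redo = rng.integers(0, n, size=(int(empty.sum()), n))
            tot[empty] = bin_counts[redo].sum(axis=1)
            empty = tot.sum(axis=1) == 0
        out[done:done + r] = _kl_to_flat_rows(tot)
        done += r
    if n_redrawn:
        log.info("bootstrap_kl_to_flat redrew %d zero-crossover resamples",
                 n_redrawn)
    return out


def bootstrap_statistic(events: pd.DataFrame, individuals, statistic,
                        n_bootstraps: int = 10_000,
                        seed: int | None = None,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Generic bootstrap over individuals: their full crossover sets
    travel with them; ``statistic(resampled_events, resampled_ids)``."""
    ids = list(individuals)
    n = len(ids)
    if n < 2:
        raise ValidationError("bootstrap needs >= 2 individuals")
    rng = resolve_rng(rng, seed, "bootstrap-statistic")
    by_ind = {i: sub for i, sub in events.groupby("individual", sort=False)}
    empty = events.iloc[0:0]
    out = np.empty(n_bootstraps)
    for b in range(n_bootstraps):
        pick = rng.integers(0, n, size=n)
        frames = [by_ind.get(ids[k], empty) for k in pick]
        res = pd.concat(frames, ignore_index=True) if frames else empty
        out[b] = statistic(res, [ids[k] for k in pick])
    return out


@dataclass
class OrderingResult:
    """Bootstrap ordering of populations by a KL statistic."""

    statistics: dict            # name -> observed KL
    bootstrap: dict             # name -> (B,) bootstrap values
    pairs: pd.DataFrame         # pop_a, pop_b, k, raw_p, adj_p, differs
    letters: dict               # name -> letter group(s)


def _ordering_from_bootstrap(observed: dict, boot: dict,
                             alpha: float = 0.05) -> OrderingResult:
    names = list(observed)
    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    diff = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            d_obs = observed[a] - observed[b]
            d_boot = boot[a] - boot[b]
            # replicates ordering opposite to the observed ordering
            k = int((d_boot < 0).sum() if d_obs >= 0 else (d_boot > 0).sum())
            raw = k / len(d_boot)
            adj = min(1.0, raw * n_pairs)
            diff[(a, b)] = adj < alpha
            rows.append((a, b, k, raw, adj, adj < alpha))
    pairs = pd.DataFrame(rows, columns=["pop_a", "pop_b", "k", "raw_p",
                                        "adj_p", "differs"])

    def differs(x, y):
        return diff.get((x, y), diff.get((y, x), False))

    order = sorted(names, key=lambda nm: observed[nm], reverse=True)
    return OrderingResult(observed, boot, pairs,
                          compact_letters(order, differs))


def ordering_test(populations: list, n_bootstraps: int = 10_000,
                  seed: int = 0, n_bins: int = DEFAULT_BINS,
                  alpha: float = 0.05) -> OrderingResult:
    """Order populations by KL-to-flat with paired-bootstrap p-values.

    ``populations``: list of (name, bin_counts) with bin_counts the
    per-individual landscape count matrix. Each population bootstraps
    from its own named substream of ``seed``; replicates are paired by
    index across populations.
    """
    if len(populations) < 2:
        raise ValidationError("ordering test needs >= 2 populations")
    observed = {}
    boot = {}
    for name, counts in populations:
        pooled = BinnedDistribution(counts.sum(axis=0))
        observed[name] = kl_divergence(pooled,
                                       np.full(n_bins, 1.0 / n_bins))
        boot[name] = bootstrap_kl_to_flat(
            counts, n_bootstraps, rng=substream(seed, "ordering", name))
    return _ordering_from_bootstrap(observed, boot, alpha)


@dataclass
class KLPairResult:
    kl: float
    ci: tuple
    n_bootstraps: int
    n_redrawn: int


def pairwise_landscape_kl(bin_counts_a: np.ndarray, bin_counts_b: np.ndarray,
                          n_bootstraps: int = 10_000, seed: int = 0,
                          alpha: float = 0.05) -> KLPairResult:
    """KL(P_A, Q_B) between two observed landscapes with bootstrap CI.

    Both populations are resampled jointly (replicates paired by index);
    replicates hitting an occupied-P/empty-Q bin are redrawn and
    counted. The CI is the (alpha/2, 1 - alpha/2) percentile interval.
    """
    p_a = BinnedDistribution(bin_counts_a.sum(axis=0))
    q_b = BinnedDistribution(bin_counts_b.sum(axis=0))
    point = kl_divergence(p_a, q_b)  # raises InfiniteKLError if empty-Q bin
    rng_a = substream(seed, "pairkl", "a")
    rng_b = substream(seed, "pairkl", "b")
    n_a, n_b = bin_counts_a.shape[0], bin_counts_b.shape[0]
    vals = np.empty(n_bootstraps)
    n_redrawn = 0
    for b in range(n_bootstraps):
        while True:
            ca = bin_counts_a[rng_a.integers(0, n_a, size=n_a)].sum(axis=0)
            cb = bin_counts_b[rng_b.integers(0, n_b, size=n_b)].sum(axis=0)
            if ca.sum() == 0 or cb.sum() == 0 or \
                    np.any((ca > 0) & (cb == 0)):
                n_redrawn += 1
                continue
            break
        pa = ca / ca.sum()
        qb = cb / cb.sum()
        m = pa > 0
        vals[b] = float(np.sum(pa[m] * np.log(pa[m] / qb[m])))
    if n_redrawn:
        log.info("pairwise_landscape_kl redrew %d degenerate resamples",
                 n_redrawn)
    ci = (float(np.quantile(vals, alpha / 2)),
          float(np.quantile(vals, 1 - alpha / 2)))
    return KLPairResult(point, ci, n_bootstraps, n_redrawn)
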