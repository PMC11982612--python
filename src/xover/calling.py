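"""Crossover calling from testcross genotypes and Table-style summaries.

A crossover is called wherever two adjacent markers carry different
parental states within one individual; the event is localized to the
marker interval (0-based half-open) and given a point position at the
interval's physical midpoint. This is the minimal crossover count
consistent with two-state data: an even number of exchanges inside one
interval is invisible.

Per-meiocyte means double the per-gamete totals, because a testcross
progeny reveals a single gamete of the meiosis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyPopulationError, SchemaError, ValidationError, XoverError
from .io import EVENT_COLUMNS, MISSING, GenotypeMatrix, MarkerMap

log = logging.getLogger("xover")


def check_mendelian_segregation(genotypes: GenotypeMatrix,
                                alpha: float = 0.05) -> pd.DataFrame:
    """Per-marker 1:1 segregation chi-squared test (1 df).

    Statistic (a - b)^2 / (a + b) on the counts of the two parental
    states, missing calls excluded. Markers with no scorable call are
    reported untestable. Returns a frame with columns marker, n_p1,
    n_p2, chi2, p_value, flagged, testable.
    """
    vals = genotypes.calls.to_numpy()
    a = (vals == 0).sum(axis=0).astype(float)
    b = (vals == 1).sum(axis=0).astype(float)
    tot = a + b
    testable = tot > 0
    chi2 = np.full(len(tot), np.nan)
    chi2[testable] = (a[testable] - b[testable]) ** 2 / tot[testable]
    p = np.full(len(tot), np.nan)
    p[testable] = stats.chi2.sf(chi2[testable], df=1)
    out = pd.DataFrame({
        "marker": genotypes.markers,
        "n_p1": a.astype(int), "n_p2": b.astype(int),
        "chi2": chi2, "p_value": p,
        "flagged": testable & (p < alpha),
        "testable": testable,
    })
    n_flag = int(out["flagged"].sum())
    if n_flag:
        log.info("mendelian_segregation flagged=%d of %d markers",
                 n_flag, len(out))
    return out


def drop_incomplete_individuals(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Discard every individual with at least one missing call."""
    complete = ~(genotypes.calls.to_numpy() == MISSING).any(axis=1)
    n_dropped = int((~complete).sum())
    if complete.sum() == 0:
        raise EmptyPopulationError("all individuals have missing data")
    log.info("drop_incomplete_individuals dropped=%d kept=%d",
             n_dropped, int(complete.sum()))
    if n_dropped == 0:
        return genotypes
    return GenotypeMatrix(genotypes.calls.loc[complete].copy())


def call_crossovers(genotypes: GenotypeMatrix,
                    marker_map: MarkerMap) -> pd.DataFrame:
    """Call one event per adjacent-marker state change per individual.

    Requires a complete matrix (run ``drop_incomplete_individuals``
    first). Returns the event frame with columns
    ``individual, chrom, left_marker, right_marker, start, end, midpoint``.
    """
    genotypes.check_aligned(marker_map)
    if (genotypes.calls.to_numpy() == MISSING).any():
        raise ValidationError("missing calls present; drop incomplete "
                              "individuals before calling")
    ids = np.asarray(genotypes.individuals, dtype=object)
    frames = []
    for chrom in marker_map.chromosomes:
        sub = marker_map.markers_for(chrom)
        cols = list(sub["marker"])
        vals = genotypes.calls[cols].to_numpy()
        pos = sub["pos_bp"].to_numpy()
        names = np.asarray(cols, dtype=object)
        changed = vals[:, 1:] != vals[:, :-1]
        ind_idx, int_idx = np.nonzero(changed)
        if len(ind_idx) == 0:
            continue
        start = pos[int_idx]
        end = pos[int_idx + 1]
        frames.append(pd.DataFrame({
            "individual": ids[ind_idx],
            "chrom": chrom,
            "left_marker": names[int_idx],
            "right_marker": names[int_idx + 1],
            "start": start, "end": end,
            "midpoint": (start + end) / 2.0,
        }))
    if not frames:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    events = pd.concat(frames, ignore_index=True)
    log.info("call_crossovers individuals=%d events=%d",
             len(ids), len(events))
    return events


@dataclass
class PopulationSummary:
    """Population-level crossover-rate summary.

    ``mean_per_meiocyte`` doubles the per-gamete mean; the frequency
    table counts individuals by per-chromosome crossover number (its
    rows sum to n_individuals for every chromosome).
    """

    n_individuals: int
    total_crossovers: int
    mean_per_meiocyte: float
    per_chrom_frequency: pd.DataFrame

    def rounded_mean(self) -> float:
        return round(self.mean_per_meiocyte, 1)


def summarize_population(events: pd.DataFrame,
                         n_individuals: int) -> PopulationSummary:
    """Table-style summary: total events and 2x total / n per meiocyte."""
    if n_individuals < 1:
        raise ValidationError("n_individuals must be >= 1")
    total = int(len(events))
    mean = 2.0 * total / n_individuals
    if total:
        per_ind = (events.groupby(["chrom", "individual"], sort=False)
                   .size())
        freq = (per_ind.groupby(level="chrom", sort=False)
                .value_counts().unstack(fill_value=0))
        freq.columns.name = "n_crossovers"
        # individuals with zero events on a chromosome
        if 0 not in freq.columns:
            freq[0] = 0
        freq[0] = n_individuals - freq.drop(columns=0).sum(axis=1)
        freq = freq[sorted(freq.columns)]
    else:
        freq = pd.DataFrame({0: []})
    return PopulationSummary(n_individuals, total, mean, freq)


def variation_explained(mean_test: float, mean_low: float,
                        mean_high: float) -> float:
    """Percent of the low-to-high crossover-rate span reached by a test
    genotype: 100 * (test - low) / (high - low), on unrounded means."""
    denom = mean_high - mean_low
    if denom == 0:
        raise XoverError("degenerate denominator: mean_high == mean_low")
    return 100.0 * (mean_test - mean_low) / denom


def zero_recombination_fraction(events: pd.DataFrame,
                                marker_map: MarkerMap) -> float:
    """Percent of marker-covered genome in intervals with zero events."""
    intervals = marker_map.intervals()
    width = (intervals["end"] - intervals["start"]).to_numpy(dtype=float)
    if len(events):
        hit_keys = set(zip(events["chrom"], events["start"]))
        hit = np.array([(c, s) in hit_keys for c, s
                        in zip(intervals["chrom"], intervals["start"])])
    else:
        hit = np.zeros(len(intervals), dtype=bool)
    return 100.0 * width[~hit].sum() / width.sum()
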