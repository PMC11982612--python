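"""Tables the pipeline reads and writes.

Three on-disk dialects, all plain TSV:

* marker map   — columns ``marker, chrom, pos_bp`` (+ optional
  ``chrom_length``, ``centromere_start``, ``centromere_end``);
* genotypes    — first column ``individual``, one column per marker, calls
  coded ``A`` / ``B`` (the two parental states of a testcross) and ``-``
  for missing;
* crossovers   — BED-style ``chrom, start, end, individual, left_marker,
  right_marker``.

All coordinates on disk and in memory are 0-based half-open (BED
convention). Internally genotype calls are int8: 0 (parent 1), 1
(parent 2), -1 (missing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

log = logging.getLogger("xover")

MISSING = -1
CALL_SYMBOLS = {"A": 0, "B": 1, "-": MISSING}
SYMBOL_OF_CALL = {v: k for k, v in CALL_SYMBOLS.items()}

#: column order of a crossover-event frame
EVENT_COLUMNS = ["individual", "chrom", "left_marker", "right_marker",
                 "start", "end", "midpoint"]


@dataclass
class MarkerMap:
    """Ordered physical SNP positions per chromosome.

    ``table`` has columns ``marker, chrom, pos_bp`` sorted by chromosome
    (order of first appearance) then position. ``chrom_lengths`` maps each
    chromosome to its physical length in bp (defaults to the last marker
    position when not supplied). ``centromeres`` optionally maps a
    chromosome to a (start, end) bp interval.
    """

    table: pd.DataFrame
    chrom_lengths: dict = field(default_factory=dict)
    centromeres: dict = field(default_factory=dict)

    def __post_init__(self):
        t = self.table
        required = {"marker", "chrom", "pos_bp"}
        if not required.issubset(t.columns):
            raise ValidationError(f"marker map needs columns {sorted(required)}")
        if t["marker"].duplicated().any():
            dupes = t.loc[t["marker"].duplicated(), "marker"].tolist()
            raise ValidationError(f"duplicated marker ids: {dupes}")
        if (t["pos_bp"] < 0).any():
            raise ValidationError("marker positions must be >= 0")
        # preserve chromosome order of first appearance, sort within
        order = {c: i for i, c in enumerate(t["chrom"].drop_duplicates())}
        t = t.sort_values(["chrom", "pos_bp"],
                          key=lambda s: s.map(order) if s.name == "chrom" else s,
                          kind="stable").reset_index(drop=True)
        for chrom, sub in t.groupby("chrom", sort=False):
            pos = sub["pos_bp"].to_numpy()
            if len(pos) < 2:
                raise ValidationError(f"chromosome {chrom} has < 2 markers")
            if not np.all(np.diff(pos) > 0):
                raise ValidationError(
                    f"marker positions not strictly increasing on {chrom}")
        self.table = t
        for chrom, sub in t.groupby("chrom", sort=False):
            length = self.chrom_lengths.get(chrom)
            last = int(sub["pos_bp"].iloc[-1])
            if length is None:
                self.chrom_lengths[chrom] = last
            elif last > length:
                raise ValidationError(
                    f"marker beyond chromosome length on {chrom}")

    @property
    def chromosomes(self) -> list:
        return list(self.table["chrom"].drop_duplicates())

    @property
    def marker_ids(self) -> list:
        return list(self.table["marker"])

    def __len__(self) -> int:
        return len(self.table)

    def markers_for(self, chrom) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]

    def chrom_length(self, chrom) -> int:
        return self.chrom_lengths[chrom]

    def intervals(self) -> pd.DataFrame:
        """Adjacent-marker intervals: chrom, left/right marker, start, end."""
        rows = []
        for chrom, sub in self.table.groupby("chrom", sort=False):
            m = sub["marker"].to_numpy()
            p = sub["pos_bp"].to_numpy()
            rows.append(pd.DataFrame({
                "chrom": chrom,
                "left_marker": m[:-1], "right_marker": m[1:],
                "start": p[:-1], "end": p[1:],
            }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class GenotypeMatrix:
    """Testcross calls, individuals x markers, aligned to a MarkerMap.

    ``calls`` is an int8 DataFrame indexed by individual id with one
    column per marker in map order; entries are 0/1 (parental state) or
    -1 (missing).
    """

    calls: pd.DataFrame

    def __post_init__(self):
        if self.calls.shape[0] == 0 or self.calls.shape[1] == 0:
            raise ValidationError("genotype matrix must be non-empty")
        if self.calls.index.duplicated().any():
            raise ValidationError("duplicated individual ids")
        self.calls = self.calls.astype(np.int8)

    @property
    def individuals(self) -> list:
        return list(self.calls.index)

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def markers(self) -> list:
        return list(self.calls.columns)

    def check_aligned(self, marker_map: MarkerMap) -> None:
        if self.markers != marker_map.marker_ids:
            raise SchemaError("genotype columns do not match marker map order")


def read_marker_map(path) -> MarkerMap:
    """Read and validate a marker-map TSV."""
    try:
        t = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # malformed file
        raise ParseError(f"cannot parse marker map {path}: {exc}") from exc
    for col in ("marker", "chrom", "pos_bp"):
        if col not in t.columns:
            raise ParseError(f"marker map {path} lacks column {col!r}")
    bad = t["pos_bp"].isna()
    if bad.any():
        raise ParseError(
            f"marker map {path}: malformed pos_bp at line {bad.idxmax() + 2}")
    t["pos_bp"] = t["pos_bp"].astype(np.int64)
    chrom_lengths = {}
    if "chrom_length" in t.columns:
        chrom_lengths = (t.dropna(subset=["chrom_length"])
                         .groupby("chrom", sort=False)["chrom_length"]
                         .first().astype(np.int64).to_dict())
    centromeres = {}
    if {"centromere_start", "centromere_end"}.issubset(t.columns):
        cen = t.dropna(subset=["centromere_start", "centromere_end"])
        for chrom, sub in cen.groupby("chrom", sort=False):
            centromeres[chrom] = (int(sub["centromere_start"].iloc[0]),
                                  int(sub["centromere_end"].iloc[0]))
    mm = MarkerMap(t[["marker", "chrom", "pos_bp"]].copy(),
                   chrom_lengths=chrom_lengths, centromeres=centromeres)
    log.info("read_marker_map path=%s markers=%d chromosomes=%d",
             path, len(mm), len(mm.chromosomes))
    return mm


def write_marker_map(marker_map: MarkerMap, path) -> None:
    t = marker_map.table.copy()
    t["chrom_length"] = t["chrom"].map(marker_map.chrom_lengths)
    if marker_map.centromeres:
        t["centromere_start"] = t["chrom"].map(
            {c: s for c, (s, _) in marker_map.centromeres.items()})
        t["centromere_end"] = t["chrom"].map(
            {c: e for c, (_, e) in marker_map.centromeres.items()})
    t.to_csv(path, sep="\t", index=False)


def read_genotypes(path, marker_map: MarkerMap) -> GenotypeMatrix:
    """Read a genotype TSV and align its columns to the map order."""
    try:
        t = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:
        raise ParseError(f"cannot parse genotypes {path}: {exc}") from exc
    if t.shape[1] < 2:
        raise ParseError(f"genotype file {path} has no marker columns")
    t = t.set_index(t.columns[0])
    unknown_cols = [c for c in t.columns if c not in set(marker_map.marker_ids)]
    if unknown_cols:
        raise SchemaError(
            f"genotype columns absent from marker map: {unknown_cols}")
    missing_cols = [m for m in marker_map.marker_ids if m not in t.columns]
    if missing_cols:
        raise SchemaError(f"genotype file lacks mapped markers: {missing_cols}")
    if list(t.columns) != marker_map.marker_ids:
        log.info("read_genotypes path=%s realigned columns to map order", path)
        t = t[marker_map.marker_ids]
    bad = ~t.isin(list(CALL_SYMBOLS)).to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"unknown call symbol {t.iat[i, j]!r} for individual "
            f"{t.index[i]!r} marker {t.columns[j]!r}")
    calls = t.map(CALL_SYMBOLS.get).astype(np.int8)
    gm = GenotypeMatrix(calls)
    log.info("read_genotypes path=%s individuals=%d markers=%d",
             path, gm.n_individuals, len(gm.markers))
    return gm


def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    sym = genotypes.calls.replace(SYMBOL_OF_CALL)
    sym.index.name = "individual"
    sym.to_csv(path, sep="\t")


def write_crossovers(events: pd.DataFrame, path) -> None:
    """Write events as BED-style TSV, sorted by chromosome then start.

    Coordinates are 0-based half-open; an empty event list yields a
    header-only file.
    """
    cols = ["chrom", "start", "end", "individual", "left_marker",
            "right_marker"]
    if len(events):
        out = events[cols].sort_values(["chrom", "start", "individual"],
                                       kind="stable")
    else:
        out = pd.DataFrame(columns=cols)
    out.to_csv(path, sep="\t", index=False)


def read_crossovers(path, marker_map: MarkerMap) -> pd.DataFrame:
    """Read a crossover BED back into the in-memory event frame."""
    try:
        t = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise ParseError(f"cannot parse crossovers {path}: {exc}") from exc
    t["midpoint"] = (t["start"] + t["end"]) / 2.0
    return t[EVENT_COLUMNS]
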