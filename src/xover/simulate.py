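"""Synthetic testcross meiosis with known truth.

Crossovers on a bivalent are generated by a stationary gamma renewal
process along genetic length: inter-event distances are i.i.d.
Gamma(shape=nu, mean=1/2 Morgan), so the bivalent forms 2 crossovers per
Morgan on average. ``nu = 1`` is the no-interference (Poisson) case;
larger ``nu`` spaces crossovers more evenly, emulating interference.
Stationarity comes from a burn-in origin 5 Morgans before the chromosome
start. A gamete keeps each bivalent crossover independently with
probability 1/2 (two of four chromatids), which is the Housworth–Stahl
style of thinning.

The crossover *landscape* (where along the physical axis crossovers
fall) is imposed by a Marey warp: piecewise-linear anchors mapping
physical fraction to cumulative genetic fraction. The ``"flat"`` preset
is the identity; ``"distal"`` concentrates genetic length near the
chromosome ends with a suppressed pericentromeric middle, the pattern
typical of large-genome crops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import resolve_rng
from .errors import InvalidModelError, ValidationError
from .io import GenotypeMatrix, MarkerMap

#: named Marey-warp anchor sets (physical fraction, genetic fraction)
MAREY_PRESETS = {
    "flat": ((0.0, 0.0), (1.0, 1.0)),
    "distal": ((0.0, 0.0), (0.25, 0.45), (0.5, 0.5), (0.75, 0.55),
               (1.0, 1.0)),
}

_BURN_IN_MORGANS = 5.0
_BIVALENT_RATE = 2.0  # crossovers per Morgan on the bivalent


@dataclass(frozen=True)
class ChromosomeModel:
    """Physical/genetic geometry of one simulated chromosome."""

    name: str
    physical_length: float
    genetic_length: float  # Morgans
    marey_anchors: tuple = MAREY_PRESETS["flat"]

    def __post_init__(self):
        if not np.isfinite(self.physical_length) or self.physical_length <= 0:
            raise InvalidModelError(f"{self.name}: physical_length must be > 0")
        if not np.isfinite(self.genetic_length) or self.genetic_length < 0:
            raise InvalidModelError(f"{self.name}: genetic_length must be >= 0")
        a = np.asarray(self.marey_anchors, dtype=float)
        if a.ndim != 2 or a.shape[1] != 2 or a.shape[0] < 2:
            raise InvalidModelError("anchors must be >= 2 (phys, gen) pairs")
        if not (np.allclose(a[0], (0, 0)) and np.allclose(a[-1], (1, 1))):
            raise InvalidModelError("anchors must start at (0,0), end at (1,1)")
        if np.any(np.diff(a[:, 0]) < 0) or np.any(np.diff(a[:, 1]) < 0):
            raise InvalidModelError("anchor coordinates must be non-decreasing")

    def _anchors(self) -> np.ndarray:
        return np.asarray(self.marey_anchors, dtype=float)

    def genetic_to_physical(self, g):
        """Physical bp of genetic position(s) g via the inverse Marey warp."""
        g = np.asarray(g, dtype=float)
        if np.any(g < 0) or np.any(g > self.genetic_length):
            raise InvalidModelError(
                f"{self.name}: genetic position outside [0, genetic_length]")
        a = self._anchors()
        gf = g / self.genetic_length if self.genetic_length > 0 else g * 0.0
        return np.interp(gf, a[:, 1], a[:, 0]) * self.physical_length

    def physical_to_genetic(self, x):
        """Genetic Morgans of physical position(s) x via the Marey warp."""
        x = np.asarray(x, dtype=float)
        if np.any(x < 0) or np.any(x > self.physical_length):
            raise InvalidModelError(
                f"{self.name}: physical position outside [0, physical_length]")
        a = self._anchors()
        return np.interp(x / self.physical_length, a[:, 0], a[:, 1]) \
            * self.genetic_length


@dataclass(frozen=True)
class SimulationConfig:
    chromosomes: tuple
    n_individuals: int
    interference_shape: float = 1.0  # gamma shape nu; 1 = no interference
    thinning_probability: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1:
            raise InvalidModelError("n_individuals must be >= 1")
        if self.interference_shape < 1:
            raise InvalidModelError("interference shape nu must be >= 1")
        if not 0.0 <= self.thinning_probability <= 1.0:
            raise InvalidModelError("thinning probability must be in [0, 1]")


@dataclass
class TrueGamete:
    """Ground truth for one simulated gamete."""

    #: chromosome name -> (genetic positions Morgans, physical positions bp)
    crossovers: dict = field(default_factory=dict)
    #: chromosome name -> founder parental state (0 or 1)
    founder: dict = field(default_factory=dict)


def sample_bivalent_crossovers(chrom: ChromosomeModel, nu: float,
                               rng: np.random.Generator) -> np.ndarray:
    """Genetic positions (Morgans) of crossovers on one bivalent.

    Stationary gamma renewal process: gaps ~ Gamma(nu, mean 1/(2 nu) * nu
    = 1/2 Morgan), burn-in from -5 Morgans, events kept in
    [0, genetic_length], sorted ascending.
    """
    if not np.isfinite(chrom.genetic_length) or chrom.genetic_length < 0:
        raise InvalidModelError("genetic_length must be finite and >= 0")
    if nu < 1:
        raise InvalidModelError("nu must be >= 1")
    L = chrom.genetic_length
    if L == 0:
        return np.empty(0)
    scale = 1.0 / (_BIVALENT_RATE * nu)
    t = -_BURN_IN_MORGANS
    chunks = []
    # expected number of gaps to cover burn-in + L, with head-room
    n_draw = max(16, int(_BIVALENT_RATE * (L + _BURN_IN_MORGANS) * 1.5) + 8)
    while t <= L:
        gaps = rng.gamma(nu, scale, size=n_draw)
        pos = t + np.cumsum(gaps)
        chunks.append(pos)
        t = pos[-1]
    pos = np.concatenate(chunks)
    return pos[(pos >= 0.0) & (pos <= L)]


def thin_to_gamete(bivalent_positions: np.ndarray, p: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Keep each bivalent crossover independently with probability p."""
    if not 0.0 <= p <= 1.0:
        raise InvalidModelError("thinning probability must be in [0, 1]")
    pos = np.asarray(bivalent_positions, dtype=float)
    if p == 1.0:
        return pos.copy()
    if p == 0.0 or len(pos) == 0:
        return np.empty(0)
    return pos[rng.random(len(pos)) < p]


def genetic_to_physical(chrom: ChromosomeModel, g):
    """Module-level convenience wrapper over the chromosome method."""
    return chrom.genetic_to_physical(g)


def simulate_population(config: SimulationConfig, markers: MarkerMap,
                        rng: np.random.Generator | None = None):
    """Simulate a testcross population; return (GenotypeMatrix, truths).

    Per gamete and chromosome: draw the founder parental state with
    probability 1/2, place crossovers by the gamma-renewal/thinning
    model, and call each marker as the state at its physical position
    (the state flips at every crossover). Fully deterministic given the
    config seed.
    """
    rng = resolve_rng(rng, config.seed, "simulate")
    chrom_by_name = {c.name: c for c in config.chromosomes}
    for c in config.chromosomes:
        sub = markers.markers_for(c.name)
        if len(sub) < 2:
            raise ValidationError(
                f"chromosome {c.name} needs >= 2 markers in the map")
        if sub["pos_bp"].iloc[-1] > c.physical_length:
            raise ValidationError(f"marker beyond {c.name} physical length")
    for chrom in markers.chromosomes:
        if chrom not in chrom_by_name:
            raise ValidationError(f"map chromosome {chrom} not simulated")

    n = config.n_individuals
    ids = [f"ind{i:04d}" for i in range(n)]
    truths = [TrueGamete() for _ in range(n)]
    call_blocks = []
    for c in config.chromosomes:
        mpos = markers.markers_for(c.name)["pos_bp"].to_numpy(dtype=float)
        block = np.empty((n, len(mpos)), dtype=np.int8)
        for i in range(n):
            biv = sample_bivalent_crossovers(c, config.interference_shape, rng)
            gam = thin_to_gamete(biv, config.thinning_probability, rng)
            phys = c.genetic_to_physical(gam)
            founder = int(rng.integers(2))
            # crossover at position x flips markers at pos >= x
            flips = np.searchsorted(phys, mpos, side="right")
            block[i] = (founder + flips) % 2
            truths[i].crossovers[c.name] = (gam, phys)
            truths[i].founder[c.name] = founder
        call_blocks.append(pd.DataFrame(
            block, index=ids, columns=markers.markers_for(c.name)["marker"]))
    calls = pd.concat(call_blocks, axis=1)[markers.marker_ids]
    return GenotypeMatrix(calls), truths


def true_crossover_table(truths, individuals=None) -> pd.DataFrame:
    """Flatten TrueGamete records to a BED-like frame of point positions."""
    rows = []
    for i, t in enumerate(truths):
        ind = individuals[i] if individuals is not None else f"ind{i:04d}"
        for chrom, (_, phys) in t.crossovers.items():
            for x in phys:
                rows.append((chrom, int(x), int(x) + 1, ind))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "individual"])


def default_chromosomes(n_chromosomes: int = 10, genetic_length: float = 1.0,
                        physical_length: float = 25e6,
                        preset: str = "flat") -> tuple:
    """A uniform karyotype; preset selects the Marey warp."""
    anchors = MAREY_PRESETS[preset]
    return tuple(
        ChromosomeModel(f"chr{i + 1:02d}", physical_length, genetic_length,
                        anchors)
        for i in range(n_chromosomes))


def uniform_marker_map(chromosomes, n_intervals: int = 16,
                       centromere_fraction: tuple | None = None) -> MarkerMap:
    """Evenly spaced markers per chromosome, ends included.

    ``n_intervals`` adjacent-marker intervals (so n_intervals + 1 markers)
    per chromosome. ``centromere_fraction`` optionally places a centromere
    at the given (start, end) fractions of each chromosome.
    """
    rows = []
    lengths = {}
    centromeres = {}
    for c in chromosomes:
        pos = np.linspace(0, c.physical_length, n_intervals + 1)
        pos = np.round(pos).astype(np.int64)
        for j, p in enumerate(pos):
            rows.append((f"{c.name}_m{j:03d}", c.name, p))
        lengths[c.name] = int(c.physical_length)
        if centromere_fraction is not None:
            s, e = centromere_fraction
            centromeres[c.name] = (int(s * c.physical_length),
                                   int(e * c.physical_length))
    table = pd.DataFrame(rows, columns=["marker", "chrom", "pos_bp"])
    return MarkerMap(table, chrom_lengths=lengths, centromeres=centromeres)
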