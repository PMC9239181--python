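"""Seeded synthetic-data generators with ground truth for every stage.

Three generators emulate the three input kinds the analysis consumes:

* :func:`simulate_psm` — multinomial spectral-count tables for a
  pellet/lysate enrichment screen with a designated truly-enriched subset;
* :func:`simulate_foci_cells` — cells with 1–4 long-axis fluorescent foci
  placed under even / uniform / fused models, with Gaussian localization
  noise and independent per-channel detection dropout;
* :func:`simulate_tem` — per-cell granule counts and lognormal diameters,
  with a volume-conserving pairwise fusion transformation that reproduces
  the "fewer, larger granules" phenotype.

All generators are bit-reproducible given (config, seed); substreams are
derived from the single config seed via :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from granulescope.foci import CellFoci, ideal_positions

__all__ = [
    "PsmSimConfig",
    "FociSimConfig",
    "TemSimConfig",
    "simulate_psm",
    "simulate_foci_cells",
    "simulate_tem",
    "draw_baseline_ppm",
]

PLACEMENT_MODES = ("even_equal_gap", "even_quarter", "uniform", "fused")


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsmSimConfig:
    """Configuration of the spectral-count simulator.

    ``baseline_ppm_dispersion`` is the lognormal sigma of the true lysate
    mass fractions (before normalization); ``enrichment_fold`` is the true
    pellet:lysate mass-fraction ratio of every protein in ``enriched_ids``;
    ``depth`` is the total PSM count per (replicate, fraction) sample.
    """

    n_proteins: int = 1000
    baseline_ppm_dispersion: float = 1.5
    enriched_ids: frozenset[int] = field(default_factory=frozenset)
    enrichment_fold: float = 8.0
    depth: int = 20_000
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.baseline_ppm_dispersion < 0:
            raise ValueError("baseline_ppm_dispersion must be >= 0")
        if self.enrichment_fold <= 0:
            raise ValueError("enrichment_fold must be > 0")
        bad = set(self.enriched_ids) - set(range(1, self.n_proteins + 1))
        if bad:
            raise ValueError(f"enriched_ids outside 1..n_proteins: {sorted(bad)}")
        object.__setattr__(self, "enriched_ids", frozenset(self.enriched_ids))


def _baseline_fractions(config: PsmSimConfig) -> np.ndarray:
    """True lysate mass fractions (sum to 1), deterministic in the seed."""
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([config.seed, 0]))
    )
    raw = rng.lognormal(mean=0.0, sigma=config.baseline_ppm_dispersion,
                        size=config.n_proteins)
    return raw / raw.sum()


def draw_baseline_ppm(config: PsmSimConfig) -> pd.Series:
    """True lysate abundances in ppm, indexed by protein id (1-based).

    Deterministic in ``config.seed`` and identical to the baseline used by
    :func:`simulate_psm` under the same config, so callers can inspect the
    baseline (e.g. to select which proteins to designate as enriched)
    before running the full simulation.
    """
    frac = _baseline_fractions(config)
    return pd.Series(frac * 1e6, index=pd.RangeIndex(1, config.n_proteins + 1,
                                                     name="protein_id"))


def simulate_psm(config: PsmSimConfig) -> tuple[pd.DataFrame, frozenset[int]]:
    """Simulate a pellet/lysate spectral-counting screen.

    Lysate mass fractions are lognormal (normalized); pellet fractions give
    each enriched protein exactly ``enrichment_fold`` times its lysate
    fraction, with the remaining proteins scaled by a common factor so the
    pellet fractions sum to 1 (their true ratio is therefore a common
    constant slightly below 1).  Each (replicate, fraction) sample is a
    multinomial draw of ``depth`` PSMs from the true fractions.

    Returns
    -------
    (table, truth)
        ``table`` is a long-format DataFrame with columns ``protein_id``,
        ``replicate``, ``fraction`` ("pellet"/"lysate"), ``psm_count``
        (zero-count rows omitted); ``truth`` is the enriched id set.
    """
    lysate = _baseline_fractions(config)
    pellet = lysate.copy()
    ids = np.arange(1, config.n_proteins + 1)
    enriched_mask = np.isin(ids, list(config.enriched_ids))
    enriched_mass = lysate[enriched_mask].sum()
    if config.enrichment_fold * enriched_mass >= 1.0:
        raise ValueError(
            "enrichment_fold * total enriched baseline mass must be < 1"
        )
    pellet[enriched_mask] *= config.enrichment_fold
    if enriched_mask.any() and not enriched_mask.all():
        scale = (1.0 - pellet[enriched_mask].sum()) / lysate[~enriched_mask].sum()
        pellet[~enriched_mask] *= scale
    pellet /= pellet.sum()  # guard rounding; a no-op to ~1e-16

    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([config.seed, 1]))
    )
    rows = []
    for replicate in range(1, config.n_replicates + 1):
        for fraction, p in (("pellet", pellet), ("lysate", lysate)):
            counts = rng.multinomial(config.depth, p)
            nonzero = counts > 0
            rows.append(pd.DataFrame({
                "protein_id": ids[nonzero],
                "replicate": replicate,
                "fraction": fraction,
                "psm_count": counts[nonzero],
            }))
    table = pd.concat(rows, ignore_index=True)
    return table, frozenset(config.enriched_ids)


# ---------------------------------------------------------------------------
# Foci-bearing cells
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FociSimConfig:
    """Configuration of the two-channel foci simulator.

    Cell lengths are lognormal in µm; ``foci_count_weights`` is the
    probability vector over true focus counts 0..4; ``noise_sd`` is the
    Gaussian localization error as a fraction of cell length; ``dropout``
    the per-channel, per-focus miss probability; in ``fused`` placement an
    adjacent pair of the even-spaced foci is merged with probability
    ``fuse_prob`` (merged focus at the pair midpoint).
    """

    n_cells: int = 500
    length_mu: float = 0.92   # ln(2.5 µm): typical starved P. aeruginosa
    length_sigma: float = 0.2
    foci_count_weights: tuple[float, ...] = (0.05, 0.30, 0.45, 0.15, 0.05)
    placement: str = "even_equal_gap"
    noise_sd: float = 0.02
    dropout: float = 0.1
    fuse_prob: float = 0.5
    channels: tuple[str, ...] = ("dapi", "mapple")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        w = np.asarray(self.foci_count_weights, dtype=float)
        if w.ndim != 1 or len(w) != 5 or (w < 0).any():
            raise ValueError("foci_count_weights must be 5 non-negative numbers")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("foci_count_weights must sum to 1")
        if self.placement not in PLACEMENT_MODES:
            raise ValueError(
                f"unknown placement {self.placement!r}; one of {PLACEMENT_MODES}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be in [0, 1]")
        if not 0.0 <= self.fuse_prob <= 1.0:
            raise ValueError("fuse_prob must be in [0, 1]")
        if self.length_sigma < 0:
            raise ValueError("length_sigma must be >= 0")
        if not self.channels:
            raise ValueError("at least one channel required")


def _true_positions(n: int, placement: str, fuse_prob: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Relative (0..1) true focus positions for one cell with n foci."""
    if n == 0:
        return np.empty(0)
    if placement == "even_equal_gap":
        return ideal_positions(n, "equal_gap")
    if placement == "even_quarter":
        return ideal_positions(n, "quarter")
    if placement == "uniform":
        return np.sort(rng.uniform(0.0, 1.0, size=n))
    # fused: start from equal-gap even spacing, merge one adjacent pair
    pos = ideal_positions(n, "equal_gap")
    if n >= 2 and rng.uniform() < fuse_prob:
        k = rng.integers(0, n - 1)
        merged = 0.5 * (pos[k] + pos[k + 1])
        pos = np.delete(pos, [k, k + 1])
        pos = np.sort(np.append(pos, merged))
    return pos


def simulate_foci_cells(config: FociSimConfig) -> list[CellFoci]:
    """Simulate foci-bearing cells with ground truth attached.

    Each returned :class:`~granulescope.foci.CellFoci` carries observed
    per-channel foci (absolute µm positions plus lognormal intensities) and
    a ``truth`` attribute with the true relative positions.  Observed
    positions are truth plus N(0, noise_sd·L) noise, clipped to the cell,
    and each focus is dropped independently per channel with probability
    ``dropout``.  Cells with zero observed foci are retained.
    """
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([config.seed, 2]))
    )
    weights = np.asarray(config.foci_count_weights, dtype=float)
    weights = weights / weights.sum()
    cells: list[CellFoci] = []
    for i in range(config.n_cells):
        length = float(rng.lognormal(config.length_mu, config.length_sigma))
        n_true = int(rng.choice(5, p=weights))
        truth_rel = _true_positions(n_true, config.placement,
                                    config.fuse_prob, rng)
        foci: dict[str, list[tuple[float, float]]] = {}
        for channel in config.channels:
            observed: list[tuple[float, float]] = []
            for r in truth_rel:
                if config.dropout > 0 and rng.uniform() < config.dropout:
                    continue
                pos = r * length
                if config.noise_sd > 0:
                    pos += rng.normal(0.0, config.noise_sd * length)
                pos = float(np.clip(pos, 0.0, length))
                intensity = float(rng.lognormal(0.0, 0.3))
                observed.append((pos, intensity))
            foci[channel] = sorted(observed)
        cells.append(CellFoci(cell_id=f"cell_{i:05d}", length=length,
                              foci=foci, truth=tuple(truth_rel)))
    return cells


# ---------------------------------------------------------------------------
# TEM granule tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TemSimConfig:
    """Configuration of the TEM granule simulator.

    Granule counts per cell are Poisson(``count_lambda``); diameters are
    lognormal in nm.  ``fusion_events_per_cell`` is the Poisson mean number
    of pairwise fusion events per cell; each event replaces two granules by
    one of equal total volume (d = (6V/π)^(1/3)), floored so a cell with
    ≥1 granule keeps ≥1.
    """

    n_cells: int = 300
    count_lambda: float = 3.0
    diam_mu: float = 5.0      # ln(148 nm): granules cluster near 150 nm
    diam_sigma: float = 0.3
    fusion_events_per_cell: float = 0.0
    group: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.count_lambda <= 0:
            raise ValueError("count_lambda must be > 0")
        if self.diam_sigma < 0:
            raise ValueError("diam_sigma must be >= 0")
        if self.fusion_events_per_cell < 0:
            raise ValueError("fusion_events_per_cell must be >= 0")


def fuse_granules(diameters: np.ndarray, n_events: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Apply ``n_events`` volume-conserving pairwise fusions.

    Each event picks two granules at random and replaces them with one of
    summed volume, d = (dᵢ³ + dⱼ³)^(1/3).  Events beyond
    ``len(diameters) - 1`` are ignored, so a non-empty cell never drops
    below one granule.  Untouched granules keep their diameters bitwise, so
    per-cell total volume is conserved to machine precision and the largest
    granule never shrinks.
    """
    d = np.sort(np.asarray(diameters, dtype=float))
    n_events = min(int(n_events), max(len(d) - 1, 0))
    for _ in range(n_events):
        i, j = rng.choice(len(d), size=2, replace=False)
        merged = (d[i] ** 3 + d[j] ** 3) ** (1.0 / 3.0)
        d = np.delete(d, [i, j])
        d = np.append(d, merged)
    return np.sort(d)


def simulate_tem(config: TemSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-cell granule diameter tables, pre- and post-fusion.

    Returns ``(granules, cells)``: ``granules`` has one row per granule with
    columns ``cell_id``, ``group``, ``diameter_nm`` (post-fusion observed
    diameters) and ``true_diameter_nm``-bearing companion rows are kept in
    the pre-fusion columns ``pre_fusion`` (pipe-joined) of ``cells``;
    ``cells`` has one row per cell (including zero-granule cells) with
    ``cell_id``, ``group``, ``count``, ``pre_fusion_count``.
    """
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([config.seed, 3]))
    )
    granule_rows = []
    cell_rows = []
    for i in range(config.n_cells):
        cell_id = f"{config.group}_{i:05d}"
        n = int(rng.poisson(config.count_lambda))
        pre = rng.lognormal(config.diam_mu, config.diam_sigma, size=n)
        n_events = int(rng.poisson(config.fusion_events_per_cell)) if \
            config.fusion_events_per_cell > 0 else 0
        post = fuse_granules(pre, n_events, rng) if n > 0 else pre
        for d in post:
            granule_rows.append((cell_id, config.group, float(d)))
        cell_rows.append((
            cell_id, config.group, len(post), n,
            "|".join(f"{d:.17g}" for d in np.sort(pre)),
        ))
    granules = pd.DataFrame(granule_rows,
                            columns=["cell_id", "group", "diameter_nm"])
    cells = pd.DataFrame(cell_rows, columns=[
        "cell_id", "group", "count", "pre_fusion_count", "pre_fusion",
    ])
    return granules, cells
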