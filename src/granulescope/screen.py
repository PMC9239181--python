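"""Spectral-counting enrichment screen for granule-associated proteins.

The screen compares a density-gradient granule "pellet" fraction against the
whole-cell "lysate".  A protein's abundance in one mass-spectrometry sample
is its PSM (peptide-spectrum match) count divided by the sample's total PSM
count, expressed in ppm (×10⁶); enrichment is the ratio of its
replicate-averaged pellet abundance to its lysate abundance.  Candidate
granule proteins are the abundant (≥5,000 ppm in the pellet), highly
enriched (≥8-fold) ones; because polyphosphate is a dense polyanion, a
further predicate flags candidates with net positive charge (> +5 at pH 7).
Ribosomal proteins pass these cutoffs spuriously (they extract readily under
the screen's salt conditions) and are excluded from candidate lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "ScreenConfig",
    "EnrichmentStatus",
    "compute_ppm",
    "average_replicates",
    "compute_enrichment",
    "net_charge",
    "simple_charge",
    "exclude_ribosomal",
    "classify",
    "run_screen",
    "EMBOSS_PKA",
]

FRACTIONS = ("pellet", "lysate")

#: EMBOSS-style pKa values for the ionizable groups used by
#: :func:`net_charge`.  Positive groups: N-terminus, K, R, H; negative:
#: C-terminus, D, E, C, Y.
EMBOSS_PKA: dict[str, float] = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "K": 10.8,
    "R": 12.5,
    "H": 6.5,
    "D": 3.9,
    "E": 4.1,
    "C": 8.5,
    "Y": 10.1,
}

_POSITIVE_GROUPS = ("K", "R", "H")
_NEGATIVE_GROUPS = ("D", "E", "C", "Y")

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


class EnrichmentStatus(str, Enum):
    """Detection status for proteins seen in only one fraction."""

    PELLET_ONLY = "pellet_only"
    LYSATE_ONLY = "lysate_only"


@dataclass(frozen=True)
class ScreenConfig:
    """Cutoffs and conventions of the enrichment screen.

    All cutoffs are inclusive (≥ for enrichment/abundance, > for charge,
    matching a strict "positively charged" predicate).  ``zero_fill``
    controls replicate averaging for proteins absent from a replicate:
    ``"zero"`` counts the absence as 0 ppm (absence is evidence of low
    abundance); ``"skip"`` averages only the replicates where the protein
    was seen.
    """

    enrichment_cutoff: float = 8.0
    abundance_cutoff_ppm: float = 5000.0
    charge_cutoff: float = 5.0
    pH: float = 7.0
    zero_fill: str = "zero"

    def __post_init__(self) -> None:
        if self.enrichment_cutoff <= 0:
            raise ValueError("enrichment_cutoff must be > 0")
        if self.abundance_cutoff_ppm <= 0:
            raise ValueError("abundance_cutoff_ppm must be > 0")
        if self.zero_fill not in ("zero", "skip"):
            raise ValueError("zero_fill must be 'zero' or 'skip'")


def _validate_psm(psm: pd.DataFrame) -> pd.DataFrame:
    required = {"protein_id", "replicate", "fraction", "psm_count"}
    missing = required - set(psm.columns)
    if missing:
        raise ValueError(f"PSM table missing columns: {sorted(missing)}")
    if (psm["psm_count"] < 0).any():
        raise ValueError("psm_count must be >= 0")
    bad_fraction = set(psm["fraction"]) - set(FRACTIONS)
    if bad_fraction:
        raise ValueError(f"unknown fraction labels: {sorted(bad_fraction)}")
    dupes = psm.duplicated(["protein_id", "replicate", "fraction"])
    if dupes.any():
        raise ValueError("duplicate (protein_id, replicate, fraction) rows")
    return psm


def compute_ppm(psm: pd.DataFrame) -> pd.DataFrame:
    """Per-sample spectral-count abundances in ppm.

    Within each (replicate, fraction) sample, a protein's ppm is its PSM
    count divided by the sample's total PSM count, times 10⁶; ppm therefore
    sums to exactly 10⁶ within every sample.

    Returns a DataFrame with columns ``protein_id``, ``replicate``,
    ``fraction``, ``ppm``.
    """
    psm = _validate_psm(psm)
    totals = psm.groupby(["replicate", "fraction"])["psm_count"].transform("sum")
    zero_samples = (
        psm.assign(total=totals)
        .groupby(["replicate", "fraction"])["total"].first()
    )
    bad = zero_samples[zero_samples == 0]
    if not bad.empty:
        raise ValueError(
            f"sample(s) with all-zero PSM counts: {list(bad.index)}"
        )
    out = psm[["protein_id", "replicate", "fraction"]].copy()
    out["ppm"] = 1e6 * psm["psm_count"] / totals
    return out


def average_replicates(
    abundances: pd.DataFrame,
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Replicate-averaged ppm per protein and fraction.

    Under ``zero_fill="zero"`` a protein absent from a replicate
    contributes 0 ppm to that replicate's mean (divide by the number of
    replicates in which the fraction was measured); under ``"skip"`` the
    mean runs only over replicates where the protein was detected.

    Returns a wide DataFrame indexed by ``protein_id`` with columns
    ``mean_pellet_ppm`` and ``mean_lysate_ppm`` (NaN when the protein was
    never seen in that fraction).
    """
    config = config or ScreenConfig()
    n_reps = abundances.groupby("fraction")["replicate"].nunique()
    sums = abundances.pivot_table(index="protein_id", columns="fraction",
                                  values="ppm", aggfunc="sum")
    counts = abundances.pivot_table(index="protein_id", columns="fraction",
                                    values="ppm", aggfunc="count")
    means = pd.DataFrame(index=sums.index)
    for fraction in FRACTIONS:
        if fraction not in sums.columns:
            means[f"mean_{fraction}_ppm"] = np.nan
            continue
        if config.zero_fill == "zero":
            means[f"mean_{fraction}_ppm"] = sums[fraction] / n_reps[fraction]
        else:
            means[f"mean_{fraction}_ppm"] = sums[fraction] / counts[fraction]
    means.index.name = "protein_id"
    # a protein never seen in a fraction has no row → NaN, not 0
    return means


def compute_enrichment(
    mean_pellet_ppm: float,
    mean_lysate_ppm: float,
) -> float | EnrichmentStatus:
    """Pellet:lysate abundance ratio, or a one-fraction status.

    Proteins detected only in the pellet or only in the lysate get the
    statuses ``pellet_only`` / ``lysate_only`` instead of a number; no
    pseudocount is applied.  Missing (NaN) means are treated as 0.
    """
    pellet = 0.0 if pd.isna(mean_pellet_ppm) else float(mean_pellet_ppm)
    lysate = 0.0 if pd.isna(mean_lysate_ppm) else float(mean_lysate_ppm)
    if pellet < 0 or lysate < 0:
        raise ValueError("mean ppm must be >= 0")
    if pellet == 0 and lysate == 0:
        raise ValueError("protein absent from both fractions")
    if lysate == 0:
        return EnrichmentStatus.PELLET_ONLY
    if pellet == 0:
        return EnrichmentStatus.LYSATE_ONLY
    return pellet / lysate


def net_charge(
    sequence: str,
    pH: float = 7.0,
    pka: dict[str, float] | None = None,
    on_nonstandard: str = "skip",
) -> float:
    """Henderson–Hasselbalch net charge of a protein at a given pH.

    Sums the fractional charge of every ionizable group: the N-terminus and
    each K, R, H contribute +1/(1+10^(pH−pKa)); the C-terminus and each D,
    E, C, Y contribute −1/(1+10^(pKa−pH)).  The default pKa set is
    EMBOSS-style (:data:`EMBOSS_PKA`); pass ``pka`` to override.

    ``on_nonstandard`` controls residues outside the 20 standard one-letter
    codes: ``"skip"`` ignores them with a warning, ``"error"`` raises.
    """
    pka = pka or EMBOSS_PKA
    sequence = sequence.upper().strip()
    if not sequence:
        raise ValueError("empty sequence")
    nonstandard = set(sequence) - _STANDARD_AA
    if nonstandard:
        if on_nonstandard == "error":
            raise ValueError(f"non-standard residues: {sorted(nonstandard)}")
        import warnings
        warnings.warn(f"skipping non-standard residues {sorted(nonstandard)}",
                      stacklevel=2)
        sequence = "".join(c for c in sequence if c in _STANDARD_AA)
        if not sequence:
            raise ValueError("no standard residues left")

    def pos(pka_value: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (pH - pka_value))

    def neg(pka_value: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pka_value - pH))

    charge = pos(pka["Nterm"]) + neg(pka["Cterm"])
    for residue in sequence:
        if residue in _POSITIVE_GROUPS:
            charge += pos(pka[residue])
        elif residue in _NEGATIVE_GROUPS:
            charge += neg(pka[residue])
    return charge


def simple_charge(sequence: str) -> int:
    """Integer charge estimate: (K + R) − (D + E) residue counts.

    The crude convention some protein databases print; provided alongside
    :func:`net_charge` because published "calculated charge" values do not
    always state their method.
    """
    sequence = sequence.upper()
    return (sequence.count("K") + sequence.count("R")
            - sequence.count("D") - sequence.count("E"))


def exclude_ribosomal(
    records: pd.DataFrame,
    annotations: pd.DataFrame,
) -> pd.DataFrame:
    """Flag ribosomal proteins; they stay in tables, never in candidates.

    ``annotations`` needs columns ``protein_id`` and ``is_ribosomal``;
    proteins without an annotation row are not excluded.
    """
    records = records.copy()
    if annotations.empty or "is_ribosomal" not in annotations.columns:
        records["excluded"] = False
        return records
    ribo = annotations.loc[
        annotations["is_ribosomal"].astype(bool), "protein_id"
    ]
    records["excluded"] = records.index.isin(set(ribo))
    return records


def classify(
    enrichment: float | EnrichmentStatus,
    mean_pellet_ppm: float,
    config: ScreenConfig | None = None,
) -> str:
    """Quadrant label of one protein in the enrichment–abundance plane.

    ``abundant_enriched`` needs enrichment ≥ cutoff AND pellet ppm ≥
    abundance cutoff (both inclusive); ``enriched_only`` / ``abundant_only``
    when exactly one holds, ``neither`` otherwise.  One-fraction statuses
    pass through as labels.
    """
    config = config or ScreenConfig()
    if isinstance(enrichment, EnrichmentStatus):
        return enrichment.value
    abundant = (not pd.isna(mean_pellet_ppm)
                and mean_pellet_ppm >= config.abundance_cutoff_ppm)
    enriched = enrichment >= config.enrichment_cutoff
    if abundant and enriched:
        return "abundant_enriched"
    if enriched:
        return "enriched_only"
    if abundant:
        return "abundant_only"
    return "neither"


def run_screen(
    psm: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Full screen: ppm → replicate means → enrichment → classification.

    Parameters
    ----------
    psm
        Long PSM table (``protein_id``, ``replicate``, ``fraction``,
        ``psm_count``).
    annotations
        Optional table with ``protein_id``, ``is_ribosomal`` and, for the
        charge predicate, either ``charge`` or ``sequence``.
    config
        Cutoffs; defaults to the screen's published values.

    Returns
    -------
    DataFrame indexed by ``protein_id`` with columns ``mean_pellet_ppm``,
    ``mean_lysate_ppm``, ``enrichment`` (NaN for one-fraction proteins),
    ``status`` (``ratio``/``pellet_only``/``lysate_only``), ``net_charge``
    (NaN when unknown), ``class_label``, ``charge_positive``, ``excluded``,
    and ``is_candidate`` (abundant_enriched, not excluded).
    """
    config = config or ScreenConfig()
    means = average_replicates(compute_ppm(psm), config)

    enrichment_values, statuses, labels = [], [], []
    for protein_id, row in means.iterrows():
        e = compute_enrichment(row["mean_pellet_ppm"], row["mean_lysate_ppm"])
        if isinstance(e, EnrichmentStatus):
            enrichment_values.append(math.nan)
            statuses.append(e.value)
        else:
            enrichment_values.append(e)
            statuses.append("ratio")
        labels.append(classify(e, row["mean_pellet_ppm"], config))
    out = means.fillna(0.0)
    out["enrichment"] = enrichment_values
    out["status"] = statuses
    out["class_label"] = labels

    charges = pd.Series(math.nan, index=out.index, dtype=float)
    if annotations is not None and not annotations.empty:
        annot = annotations.set_index("protein_id")
        if "charge" in annot.columns:
            given = annot["charge"].dropna()
            charges.loc[charges.index.intersection(given.index)] = given
        if "sequence" in annot.columns:
            have_seq = annot["sequence"].dropna()
            todo = charges[charges.isna()].index.intersection(have_seq.index)
            for pid in todo:
                charges.loc[pid] = net_charge(have_seq.loc[pid], config.pH)
    out["net_charge"] = charges
    out["charge_positive"] = charges > config.charge_cutoff

    out = exclude_ribosomal(
        out,
        annotations if annotations is not None else pd.DataFrame(),
    )
    out["is_candidate"] = (out["class_label"] == "abundant_enriched") & ~out["excluded"]
    return out.sort_values("enrichment", ascending=False)
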