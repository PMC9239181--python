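import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from granulescope.screen import (
    EMBOSS_PKA,
    EnrichmentStatus,
    ScreenConfig,
    average_replicates,
    classify,
    compute_enrichment,
    compute_ppm,
    exclude_ribosomal,
    net_charge,
    run_screen,
    simple_charge,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def oracle_charge(sequence: str, pH: float = 7.0) -> float:
    """Independent per-residue Henderson-Hasselbalch sum (count-based)."""
    seq = sequence.upper()
    total = 0.0
    # termini
    total += 1.0 / (1.0 + 10.0 ** (pH - EMBOSS_PKA["Nterm"]))
    total -= 1.0 / (1.0 + 10.0 ** (EMBOSS_PKA["Cterm"] - pH))
    for res, sign in [("K", 1), ("R", 1), ("H", 1),
                      ("D", -1), ("E", -1), ("C", -1), ("Y", -1)]:
        n = seq.count(res)
        if sign > 0:
            total += n / (1.0 + 10.0 ** (pH - EMBOSS_PKA[res]))
        else:
            total -= n / (1.0 + 10.0 ** (EMBOSS_PKA[res] - pH))
    return total


# ---------------------------------------------------------------------------
# ppm
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("counts, expected_ppm", [
    ({"A": 5, "B": 995}, {"A": 5_000.0, "B": 995_000.0}),
    ({"A": 7}, {"A": 1_000_000.0}),
    ({"A": 3, "B": 3}, {"A": 500_000.0, "B": 500_000.0}),
])
def test_compute_ppm_single_sample(counts, expected_ppm):
    psm = pd.DataFrame([
        (pid, 1, "pellet", n) for pid, n in counts.items()
    ], columns=["protein_id", "replicate", "fraction", "psm_count"])
    out = compute_ppm(psm).set_index("protein_id")["ppm"]
    for pid, ppm in expected_ppm.items():
        assert out[pid] == pytest.approx(ppm)


def test_compute_ppm_conserves_million_per_sample(small_psm):
    out = compute_ppm(small_psm)
    sums = out.groupby(["replicate", "fraction"])["ppm"].sum()
    assert np.allclose(sums, 1e6, rtol=1e-9)


def test_compute_ppm_rejects_all_zero_sample():
    psm = pd.DataFrame([("A", 1, "pellet", 0), ("B", 1, "pellet", 0)],
                       columns=["protein_id", "replicate", "fraction",
                                "psm_count"])
    with pytest.raises(ValueError, match="pellet"):
        compute_ppm(psm)


def test_compute_ppm_rejects_negative_and_duplicate_rows():
    cols = ["protein_id", "replicate", "fraction", "psm_count"]
    with pytest.raises(ValueError, match=">= 0"):
        compute_ppm(pd.DataFrame([("A", 1, "pellet", -1)], columns=cols))
    with pytest.raises(ValueError, match="duplicate"):
        compute_ppm(pd.DataFrame(
            [("A", 1, "pellet", 1), ("A", 1, "pellet", 2)], columns=cols))


# ---------------------------------------------------------------------------
# replicate averaging
# ---------------------------------------------------------------------------

def _abundances(ppm_by_replicate):
    return pd.DataFrame([
        ("P", replicate, "pellet", value)
        for replicate, value in ppm_by_replicate.items()
    ], columns=["protein_id", "replicate", "fraction", "ppm"])


def test_average_replicates_plain_mean():
    # protein must appear in all replicates for the plain mean
    records = _abundances({1: 4000.0, 2: 5000.0, 3: 6000.0})
    means = average_replicates(records)
    assert means.loc["P", "mean_pellet_ppm"] == pytest.approx(5000.0)


def test_average_replicates_zero_fill_vs_skip():
    # protein Q seen in 1 of 3 replicates at 3000 ppm; anchor protein A
    # fixes the number of replicates per fraction
    rows = [("A", r, "pellet", 1.0) for r in (1, 2, 3)]
    rows.append(("Q", 2, "pellet", 3000.0))
    records = pd.DataFrame(rows, columns=["protein_id", "replicate",
                                          "fraction", "ppm"])
    zero = average_replicates(records, ScreenConfig(zero_fill="zero"))
    skip = average_replicates(records, ScreenConfig(zero_fill="skip"))
    assert zero.loc["Q", "mean_pellet_ppm"] == pytest.approx(1000.0)
    assert skip.loc["Q", "mean_pellet_ppm"] == pytest.approx(3000.0)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("pellet, lysate, expected", [
    (40_000.0, 5_000.0, 8.0),
    (123.0, 123.0, 1.0),
    (200.0, 0.0, EnrichmentStatus.PELLET_ONLY),
    (0.0, 200.0, EnrichmentStatus.LYSATE_ONLY),
])
def test_compute_enrichment(pellet, lysate, expected):
    assert compute_enrichment(pellet, lysate) == expected


def test_compute_enrichment_rejects_double_zero():
    with pytest.raises(ValueError):
        compute_enrichment(0.0, 0.0)


def test_enrichment_scale_invariance(small_psm):
    """Multiplying all counts in a sample by a constant leaves ppm unchanged."""
    scaled = small_psm.copy()
    scaled["psm_count"] *= 10
    assert np.allclose(compute_ppm(small_psm)["ppm"],
                       compute_ppm(scaled)["ppm"])


# ---------------------------------------------------------------------------
# net charge
# ---------------------------------------------------------------------------

def test_net_charge_against_independent_oracle(rng):
    for _ in range(100):
        n = int(rng.integers(1, 200))
        seq = "".join(rng.choice(list(AA), size=n))
        assert net_charge(seq) == pytest.approx(oracle_charge(seq), abs=1e-9)


def test_net_charge_landmark_values():
    assert net_charge("KKKK") == pytest.approx(3.98, abs=0.1)
    assert abs(net_charge("G")) < 0.1
    assert net_charge("DDDD") < 0 < net_charge("KKKK")


def test_net_charge_nonstandard_residue_handling():
    with pytest.raises(ValueError):
        net_charge("KXK", on_nonstandard="error")
    with pytest.warns(UserWarning):
        skipped = net_charge("KXK", on_nonstandard="skip")
    assert skipped == pytest.approx(net_charge("KK"), abs=1e-12)


def test_simple_charge_counts_basic_minus_acidic():
    assert simple_charge("KKRRDDE") == 1
    assert simple_charge("AAAA") == 0


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("enrichment, ppm, expected", [
    (10.0, 6000.0, "abundant_enriched"),
    (8.0, 5000.0, "abundant_enriched"),   # cutoffs inclusive
    (100.0, 4999.0, "enriched_only"),
    (7.9, 6000.0, "abundant_only"),
    (1.0, 10.0, "neither"),
    (EnrichmentStatus.PELLET_ONLY, 9000.0, "pellet_only"),
])
def test_classify_quadrants(enrichment, ppm, expected):
    assert classify(enrichment, ppm) == expected


@given(
    e1=st.floats(0.01, 1000), e2=st.floats(0.01, 1000),
    p1=st.floats(1, 1e6), p2=st.floats(1, 1e6),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_classification_monotonicity(e1, e2, p1, p2):
    """Raising enrichment or pellet ppm never demotes the label."""
    rank = {"neither": 0, "abundant_only": 1, "enriched_only": 1,
            "abundant_enriched": 2}
    lo = classify(min(e1, e2), min(p1, p2))
    hi = classify(max(e1, e2), max(p1, p2))
    assert rank[hi] >= rank[lo]


def test_exclude_ribosomal_flags_but_keeps_rows():
    records = pd.DataFrame({"x": [1, 2]}, index=pd.Index(["P1", "P2"],
                                                         name="protein_id"))
    annot = pd.DataFrame({"protein_id": ["P1"], "is_ribosomal": [True]})
    out = exclude_ribosomal(records, annot)
    assert out["excluded"].tolist() == [True, False]
    assert len(out) == 2
    no_annot = exclude_ribosomal(records, pd.DataFrame())
    assert not no_annot["excluded"].any()


def test_run_screen_ribosomal_candidate_dropped(small_psm):
    """A ribosomal protein passing all cutoffs never reaches candidates."""
    annot = pd.DataFrame({
        "protein_id": ["P1", "P2"],
        "is_ribosomal": [True, False],
        "charge": [20.0, -4.0],
    })
    result = run_screen(small_psm, annot)
    # P1: pellet 800,000 ppm / lysate 100,000 ppm = 8, abundant + enriched
    assert result.loc["P1", "class_label"] == "abundant_enriched"
    assert bool(result.loc["P1", "excluded"])
    assert not bool(result.loc["P1", "is_candidate"])
    assert bool(result.loc["P1", "charge_positive"])
    assert result.loc["P1", "enrichment"] == pytest.approx(8.0)
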