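"""Shared fixtures: small synthetic studies reused across test modules."""

import pandas as pd
import pytest

from regdiv import cistrans, expression
from regdiv.simulate import SimulationParams, generate_effects


@pytest.fixture(scope="session")
def default_params() -> SimulationParams:
    return SimulationParams(seed=42)


def analyze_cross(params, truth=None, gtest_mode=cistrans.DEFAULT_GTEST_MODE):
    """Run the single-cross analysis path used throughout the tests.

    Simulates parental counts and hybrid allele counts from ``truth`` (or
    fresh effects), quantifies parental expression, and returns the
    regulatory divergence result together with the inputs.
    """
    from regdiv import simulate

    if truth is None:
        truth = generate_effects(params)
    counts, info = simulate.simulate_parental_counts(truth, params)
    hybrid = simulate.simulate_hybrid_allele_counts(truth, params)
    lengths = simulate.simulate_transcript_lengths(params)
    populations = info["population"]
    factors = expression.size_factors(counts)
    fpkm = expression.filter_low_expression(expression.compute_fpkm(counts, lengths, factors))
    parental_log2 = expression.parental_log_ratio(fpkm, populations, "derived", "ancestral")
    pooled = expression.pooled_normalized_counts(
        counts.loc[fpkm.index], populations, ("derived", "ancestral"), factors=factors
    )
    result = cistrans.estimate_regulation(
        hybrid, parental_log2, pooled, gtest_mode=gtest_mode
    )
    return {
        "truth": truth,
        "counts": counts,
        "sample_info": info,
        "hybrid": hybrid,
        "lengths": lengths,
        "fpkm": fpkm,
        "parental_log2": parental_log2,
        "pooled_parental": pooled,
        "result": result,
    }


@pytest.fixture(scope="session")
def small_cross():
    """An 800-gene cross under default study conditions."""
    return analyze_cross(SimulationParams(n_genes=800, seed=42))


@pytest.fixture()
def hand_allele_counts() -> pd.DataFrame:
    """Single-replicate allele count table exercising every filter."""
    rows = [
        ("keep_balanced", 100, 100),
        ("keep_skewed", 80, 20),
        ("low_total", 15, 5),  # total 20 -> removed ("20 or fewer")
        ("zero_allele", 21, 0),  # infinite ratio -> removed
        ("high_fold", 660, 10),  # 66-fold > 32 -> removed
        ("keep_boundary", 14, 7),  # total 21 -> kept
        ("keep_32fold", 640, 20),  # exactly 32-fold -> kept (strict >)
        ("keep_small", 11, 10),
        ("low_and_zero", 20, 0),  # both filters fire
        ("keep_big", 5000, 4800),
    ]
    return pd.DataFrame(
        [(g, "rep1", d, a) for g, d, a in rows],
        columns=["gene_id", "replicate", "derived_count", "ancestral_count"],
    )
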