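"""Reference values from the study design this pipeline emulates.

These printed summary numbers (enrollment bookkeeping, the severity-grid
p-values, the significant correlation cells, group metric means) serve as
inputs for calibration presets and for arithmetic/bookkeeping checks.  They
are never substituted for quantities the pipeline computes.
"""

from __future__ import annotations

__all__ = [
    "ENROLLED",
    "ANALYZED",
    "GROUP_MEANS",
    "SEVERITY_GRID",
    "SIGNIFICANT_CORRELATIONS",
    "N_CORRELATION_CELLS",
    "retention_pct",
    "count_significant_cells",
    "significant_fraction_pct",
]

# completed vs analyzed after technical/calibration exclusions
ENROLLED = {"asd": 136, "td": 41}
ANALYZED = {"asd": 121, "td": 40}

# group means of the five eye-movement metrics (asd, td)
GROUP_MEANS = {
    "total_valid_pct": (80.0, 89.2),
    "preference_bio_pct": (54.5, 61.9),
    "first_fix_bio_pct": (54.2, 52.7),
    "latency_bio_ms": (649.1, 521.3),
    "latency_nonbio_ms": (639.7, 530.9),
}

# Mean preference for biological motion (and chance-level p-value) per
# symptom subscale and severity tertile, as printed.  P-values shown as
# "< 10^-k" are stored as 10^-k; all values are rounded as printed.
# Cell order: (mild, moderate, severe), each (mean_pct, p).
SEVERITY_GRID: dict[str, tuple[tuple[float, float], ...]] = {
    "abi_core_asd_symptoms": ((53.7, 0.02), (54.8, 1e-4), (54.2, 0.01)),
    "abi_challenging_behavior": ((52.4, 0.12), (55.1, 1e-3), (55.4, 1e-4)),
    "abi_mental_health": ((52.3, 0.06), (54.4, 1e-3), (56.1, 1e-4)),
    "abi_restrictive_repetitive_behaviors": ((52.9, 0.05), (53.7, 0.01), (56.2, 1e-4)),
    "abi_self_regulation": ((52.5, 0.15), (54.4, 1e-3), (55.8, 1e-4)),
    "abi_social_communication": ((54.6, 0.01), (54.5, 1e-3), (53.6, 0.01)),
    "ados2_restricted_repetitive_behavior": ((53.8, 0.01), (54.4, 0.01), (55.2, 1e-4)),
    "ados2_social_affect": ((54.9, 0.01), (55.2, 1e-4), (53.3, 0.01)),
    "ados2_total": ((56.0, 1e-4), (53.2, 0.05), (54.2, 1e-3)),
    "abc_hyperactivity_noncompliance": ((53.2, 0.02), (54.7, 0.01), (55.5, 1e-4)),
    "abc_inappropriate_speech": ((53.3, 0.05), (53.9, 1e-3), (56.1, 1e-4)),
    "abc_irritability": ((51.7, 0.08), (56.2, 1e-4), (55.4, 1e-4)),
    "abc_lethargy_social_withdrawal": ((55.8, 1e-5), (53.6, 0.02), (54.0, 0.01)),
    "abc_stereotypic_behavior": ((53.6, 0.03), (53.6, 0.01), (56.2, 1e-5)),
    "casi_anx_total": ((54.9, 0.01), (54.2, 0.01), (54.4, 1e-3)),
    "rbsr_compulsive_behavior": ((53.0, 0.03), (55.7, 1e-3), (54.7, 1e-3)),
    "rbsr_ritualistic_behavior": ((52.5, 0.11), (54.4, 1e-3), (56.4, 1e-5)),
    "rbsr_restricted_behavior": ((53.7, 0.01), (53.8, 0.01), (55.9, 1e-4)),
    "rbsr_sameness_behavior": ((52.8, 0.08), (54.5, 1e-3), (56.1, 1e-4)),
    "rbsr_self_injurious_behavior": ((53.1, 0.02), (54.2, 0.02), (56.1, 1e-6)),
    "rbsr_stereotyped_behavior": ((54.5, 0.01), (52.8, 0.02), (56.1, 1e-5)),
    "rbsr_total": ((52.4, 0.15), (54.5, 1e-3), (56.5, 1e-5)),
    "srs2_social_awareness": ((54.2, 1e-3), (53.8, 0.01), (55.1, 1e-3)),
    "srs2_social_cognition": ((53.2, 0.01), (53.8, 0.01), (56.2, 1e-4)),
    "srs2_social_communication": ((54.0, 0.01), (54.4, 1e-3), (54.7, 1e-3)),
    "srs2_social_motivation": ((55.2, 1e-3), (53.6, 0.01), (54.3, 1e-3)),
    "srs2_restricted_interests_repetitive_behavior": ((52.5, 0.04), (54.7, 1e-3), (55.9, 1e-4)),
    "srs2_social_communication_interaction": ((53.1, 0.01), (54.6, 0.01), (55.4, 1e-4)),
    "srs2_total": ((53.0, 0.02), (54.3, 0.01), (55.8, 1e-4)),
}

# the metric-symptom partial correlations that reached significance
SIGNIFICANT_CORRELATIONS = [
    ("total_valid_pct", "ados2_restricted_repetitive_behavior", 0.192),
    ("preference_bio_pct", "abi_mental_health", 0.185),
    ("latency_nonbio_ms", "abc_stereotypic_behavior", -0.245),
    ("latency_nonbio_ms", "rbsr_restricted_behavior", -0.192),
    ("latency_nonbio_ms", "rbsr_stereotyped_behavior", -0.191),
]
N_CORRELATION_CELLS = 5 * 29


def retention_pct(analyzed: int, enrolled: int) -> float:
    """Percentage of completers retained after exclusions, to one decimal."""
    if enrolled <= 0:
        raise ValueError("enrolled must be positive")
    return round(100.0 * analyzed / enrolled, 1)


def count_significant_cells(grid=None, alpha: float = 0.05) -> tuple[int, int]:
    """Count severity-grid cells whose printed p-value reaches ``alpha``.

    Printed p-values are rounded to two decimals, so a printed value equal
    to ``alpha`` is counted as significant (it was below before rounding).
    """
    grid = grid if grid is not None else SEVERITY_GRID
    cells = [p for triples in grid.values() for (_, p) in triples]
    return sum(p <= alpha for p in cells), len(cells)


def significant_fraction_pct(n_significant: int, n_total: int) -> float:
    """Share of significant cells in a grid, as a percentage to one decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_significant / n_total, 1)
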