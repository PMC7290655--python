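"""Summary statistics of the original GPS-PBS release, as printed counts.

These constants record the predictor inventory and dataset coverage of the
published GPS-PBS service; the percentage helpers recompute the derived
fractions from the raw counts rather than storing them.
"""

from __future__ import annotations

#: Individual predictors shipped by the original service, per group and level.
PREDICTOR_COUNTS = {
    "pS/pT": {"family": 12, "cluster": 30},
    "pY": {"family": 4, "cluster": 92},
}

#: Curated benchmark: total known binding phosphosites and the human subset.
BENCHMARK_SITES = {"total": 4458, "human": 4110}

#: Large-scale annotation of the mammalian phosphoproteome: total known
#: p-sites, and the counts predicted as binding sites at the family level,
#: at the single-domain cluster level, by either, and as kinase substrates.
PHOSPHOPROTEOME = {
    "total_sites": 765_779,
    "family_level_pbs": 171_825,
    "cluster_level_pbs": 325_913,
    "any_level_pbs": 371_018,
    "kinase_substrate_sites": 638_909,
}


def percentage(part: float, total: float, digits: int = 2) -> float:
    """``part/total`` as a percentage rounded to the printed precision."""
    if total == 0:
        raise ZeroDivisionError("total is zero")
    return round(100.0 * part / total, digits)


def total_predictors(counts: dict | None = None) -> int:
    counts = counts or PREDICTOR_COUNTS
    return sum(v for group in counts.values() for v in group.values())


def group_predictor_percentage(group: str, counts: dict | None = None,
                               digits: int = 1) -> float:
    """Share of all individual predictors belonging to one group, in %."""
    counts = counts or PREDICTOR_COUNTS
    part = sum(counts[group].values())
    return percentage(part, total_predictors(counts), digits)
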