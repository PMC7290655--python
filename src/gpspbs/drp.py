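"""Doubly-regulated p-sites and PPBD x kinase-family association tests.

A doubly regulated p-site (DRP) is a phosphosite predicted both as a kinase
substrate and as a PPBD binding site.  Whether a PPBD family K and a kinase
family L co-occur on the same sites more often than chance is assessed by a
permutation test: the PPBD assignments stay fixed while the n_L substrate
sites of L are re-drawn uniformly from the site universe; the overlap count
x' is recorded per round.  Under this null x' is exactly hypergeometric,
which serves as the analytic cross-check.  Term enrichment of DRP sets uses
the upper-tail hypergeometric test on user-supplied annotation tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ROUNDS = 10_000


@dataclass
class SiteAnnotationTable:
    """Site universe plus per-family PPBD and kinase site subsets."""

    universe: list
    ppbd_sets: dict[str, set] = field(default_factory=dict)
    pk_sets: dict[str, set] = field(default_factory=dict)

    def __post_init__(self) -> None:
        uni = set(self.universe)
        if len(uni) != len(self.universe):
            raise ValueError("site universe contains duplicates")
        for label, groups in (("PPBD", self.ppbd_sets), ("PK", self.pk_sets)):
            for fam, members in groups.items():
                members = set(members)
                if not members <= uni:
                    raise ValueError(f"{label} family {fam!r} has sites "
                                     "outside the universe")
                groups[fam] = members

    @property
    def size(self) -> int:
        return len(self.universe)


def identify_drps(table: SiteAnnotationTable, ppbd_family: str,
                  pk_family: str) -> set:
    """Sites both bound by the PPBD family and phosphorylated by the kinase family."""
    if ppbd_family not in table.ppbd_sets:
        raise KeyError(f"unknown PPBD family {ppbd_family!r}")
    if pk_family not in table.pk_sets:
        raise KeyError(f"unknown PK family {pk_family!r}")
    return table.ppbd_sets[ppbd_family] & table.pk_sets[pk_family]


@dataclass
class PermutationResult:
    ppbd_family: str
    pk_family: str
    observed: int
    p_value: float
    mode: str
    rounds: int
    null_mean: float
    null_sd: float
    null_skew: float


def permutation_test(table: SiteAnnotationTable, ppbd_family: str,
                     pk_family: str, rounds: int = DEFAULT_ROUNDS,
                     seed: int = 0, mode: str = "empirical",
                     ) -> PermutationResult:
    """Upper-tail association test between one PPBD and one kinase family.

    Each round re-draws the kinase family's site set (size n_L preserved)
    uniformly without replacement from the universe and counts the overlap
    x' with the fixed PPBD site set.  The empirical p-value is the add-one
    smoothed proportion of rounds with x' >= x, so it is never exactly 0;
    the Gaussian mode instead fits a normal to the x' sample and reports its
    upper tail, with a warning when the sample is visibly skewed.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if mode not in ("empirical", "gaussian"):
        raise ValueError(f"unknown mode {mode!r}")
    drps = identify_drps(table, ppbd_family, pk_family)
    x = len(drps)
    t = table.size
    n_l = len(table.pk_sets[pk_family])
    if n_l > t:
        raise ValueError("kinase site set larger than the universe")
    ppbd_mask = np.isin(np.array(table.universe, dtype=object),
                        np.array(sorted(table.ppbd_sets[ppbd_family]), dtype=object))
    rng = np.random.default_rng(seed)
    null = np.empty(rounds, int)
    for r in range(rounds):
        draw = rng.choice(t, size=n_l, replace=False)
        null[r] = int(ppbd_mask[draw].sum())
    mean, sd = float(null.mean()), float(null.std(ddof=1)) if rounds > 1 else 0.0
    skew = float(stats.skew(null)) if rounds > 2 and sd > 0 else 0.0
    if mode == "empirical":
        p = (int(np.sum(null >= x)) + 1) / (rounds + 1)
    else:
        if abs(skew) >= 0.5:
            warnings.warn(
                f"null overlap sample is skewed (skew={skew:.2f}); the "
                "Gaussian p-value may be unreliable, prefer mode='empirical'",
                stacklevel=2)
        p = float(stats.norm.sf(x, loc=mean, scale=sd)) if sd > 0 else float(x <= mean)
    return PermutationResult(ppbd_family, pk_family, x, float(p), mode,
                             rounds, mean, sd, skew)


def associate_all(table: SiteAnnotationTable, rounds: int = DEFAULT_ROUNDS,
                  seed: int = 0, mode: str = "empirical",
                  alpha: float = 0.05, correction: str = "bonferroni",
                  ) -> pd.DataFrame:
    """Permutation tests over the full PPBD x PK family grid.

    Bonferroni control of the family-wise error rate is the default;
    ``correction="none"`` with an explicit raw ``alpha`` reproduces a raw
    cutoff analysis.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    rows = []
    pairs = [(k, l) for k in sorted(table.ppbd_sets) for l in sorted(table.pk_sets)]
    for i, (k, l) in enumerate(pairs):
        res = permutation_test(table, k, l, rounds=rounds, seed=seed + i, mode=mode)
        rows.append({"ppbd_family": k, "pk_family": l, "drps": res.observed,
                     "p_value": res.p_value, "null_mean": res.null_mean,
                     "null_sd": res.null_sd})
    df = pd.DataFrame(rows)
    n_tests = len(df)
    if correction == "bonferroni":
        df["p_adjusted"] = np.minimum(df["p_value"] * n_tests, 1.0)
        df["significant"] = df["p_adjusted"] < alpha
    else:
        df["p_adjusted"] = df["p_value"]
        df["significant"] = df["p_value"] < alpha
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)


def hypergeometric_enrichment(foreground, background, annotations: dict,
                              alpha: float = 0.01) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of annotation terms.

    Per term: p = P(X >= overlap) for X ~ Hypergeometric(|background|,
    |term in background|, |foreground|); fold enrichment is the foreground
    annotation rate over the background rate.  Terms passing ``alpha`` are
    flagged; all terms are returned for inspection.
    """
    foreground, background = set(foreground), set(background)
    if not foreground:
        raise ValueError("empty foreground set")
    if not foreground <= background:
        raise ValueError("foreground must be a subset of the background")
    n_bg, n_fg = len(background), len(foreground)
    rows = []
    for term in sorted(annotations):
        term_bg = set(annotations[term]) & background
        if not term_bg:
            continue
        overlap = len(term_bg & foreground)
        p = float(stats.hypergeom.sf(overlap - 1, n_bg, len(term_bg), n_fg))
        fold = (overlap / n_fg) / (len(term_bg) / n_bg)
        rows.append({"term": term, "overlap": overlap, "term_size": len(term_bg),
                     "fold_enrichment": fold, "p_value": p,
                     "significant": p < alpha})
    return pd.DataFrame(rows, columns=["term", "overlap", "term_size",
                                       "fold_enrichment", "p_value",
                                       "significant"]
                        ).sort_values("p_value", kind="stable").reset_index(drop=True)


def read_family_table(path) -> dict[str, set]:
    """Two-column TSV (site_id, family) into a family -> site-set map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set] = {}
    for site, fam in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(fam, set()).add(site)
    return out
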