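"""Family-level phylogenetic dispersion of paradox species.

Are the families containing naturalized-yet-threatened species clustered
on the family-level tree, or spread across it? Three standard
community-phylogenetics metrics are offered — the count of families
containing paradox species, the mean pairwise patristic distance among
them, and the mean nearest-taxon distance — each tested against a
permutation null that reshuffles the per-family paradox counts while
holding every family's naturalized-species count and the total paradox
count fixed (a multivariate hypergeometric draw). These metrics and the
null are this package's own reconstruction of a dispersion test at family
level; branch lengths default to 1 when the input tree lacks them.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .errors import InputError, ValidationError

METRICS = ("n_families_with_paradox", "mean_pairwise_distance",
           "nearest_taxon_distance")


@dataclass(frozen=True)
class DispersionTestResult:
    observed: float
    null_mean: float
    null_sd: float
    p_value: float
    n_permutations: int
    metric_name: str


def family_trait_table(family_counts: pd.DataFrame) -> pd.DataFrame:
    """Normalize a per-family count table to (family, n_naturalized,
    n_paradox, has_paradox)."""
    t = family_counts.rename(columns={"nNaturalized": "n_naturalized",
                                      "nParadox": "n_paradox"})
    need = {"family", "n_naturalized", "n_paradox"}
    if not need.issubset(t.columns):
        raise InputError(f"trait table needs columns {sorted(need)}")
    bad = t[t["n_paradox"] > t["n_naturalized"]]
    if len(bad):
        raise ValidationError("n_paradox exceeds n_naturalized",
                              bad["family"].tolist())
    t = t[["family", "n_naturalized", "n_paradox"]].copy()
    t["has_paradox"] = t["n_paradox"] > 0
    return t


def family_coverage_pct(trait: pd.DataFrame) -> float:
    """100 * #{families with paradox among those with naturalized species}."""
    trait = family_trait_table(trait)
    with_nat = trait[trait["n_naturalized"] > 0]
    if len(with_nat) == 0:
        raise InputError("no family has naturalized species")
    return 100.0 * int(with_nat["has_paradox"].sum()) / len(with_nat)


def _distance_matrix(tree: dendropy.Tree, families: list[str]) -> np.ndarray:
    for edge in tree.preorder_edge_iter():
        if edge.length is None and edge.head_node is not tree.seed_node:
            edge.length = 1.0
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = [f for f in families if f not in taxa]
    if missing:
        raise ValidationError("families absent from the tree", missing)
    n = len(families)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[families[i]],
                                                       taxa[families[j]])
    return D


def _metric_value(metric: str, present: np.ndarray, D: np.ndarray) -> float:
    idx = np.flatnonzero(present)
    if metric == "n_families_with_paradox":
        return float(len(idx))
    if len(idx) < 2:
        return np.nan
    sub = D[np.ix_(idx, idx)]
    if metric == "mean_pairwise_distance":
        iu = np.triu_indices(len(idx), 1)
        return float(sub[iu].mean())
    if metric == "nearest_taxon_distance":
        np.fill_diagonal(sub, np.inf)
        return float(sub.min(axis=1).mean())
    raise InputError(f"unknown metric {metric!r}; choose from {METRICS}")


def permutation_dispersion_test(tree, trait: pd.DataFrame,
                                metric: str = "mean_pairwise_distance",
                                n_permutations: int = 999,
                                seed: int = 0) -> DispersionTestResult:
    """Permutation test of phylogenetic dispersion for one metric.

    ``tree`` is a dendropy.Tree or a Newick string over family labels.
    The null redistributes the global paradox total over families by a
    multivariate hypergeometric draw with each family's naturalized count
    as its urn size, i.e. paradox species are placed at random among
    naturalized species irrespective of family identity. The p-value is
    two-sided: (1 + #{null <= obs or >= obs, smaller tail}) doubled and
    capped at 1, with the +1 including the observed value itself.
    """
    if metric not in METRICS:
        raise InputError(f"unknown metric {metric!r}; choose from {METRICS}")
    if n_permutations < 99:
        raise InputError("n_permutations must be >= 99")
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    trait = family_trait_table(trait)
    trait = trait[trait["n_naturalized"] > 0].reset_index(drop=True)
    families = trait["family"].tolist()
    D = _distance_matrix(tree, families) if metric != "n_families_with_paradox" \
        else np.zeros((len(families), len(families)))

    observed = _metric_value(metric, trait["has_paradox"].to_numpy(), D)
    rng = np.random.default_rng(seed)
    sizes = trait["n_naturalized"].to_numpy(int)
    total_paradox = int(trait["n_paradox"].sum())
    null = np.empty(n_permutations)
    for k in range(n_permutations):
        counts = rng.multivariate_hypergeometric(sizes, total_paradox)
        null[k] = _metric_value(metric, counts > 0, D)
    valid = np.isfinite(null)
    null_v = null[valid]
    if np.isnan(observed) or len(null_v) == 0:
        raise InputError("metric undefined: fewer than two paradox families")
    n_used = len(null_v)
    ge = int(np.sum(null_v >= observed))
    le = int(np.sum(null_v <= observed))
    p = min(1.0, 2.0 * (1 + min(ge, le)) / (1 + n_used))
    return DispersionTestResult(
        observed=float(observed), null_mean=float(null_v.mean()),
        null_sd=float(null_v.std(ddof=1)) if n_used > 1 else 0.0,
        p_value=p, n_permutations=n_used, metric_name=metric)
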