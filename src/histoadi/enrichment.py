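"""Gene-set enrichment: per-sample ssGSEA and preranked GSEA.

ssGSEA follows the weighted empirical-CDF construction: within a sample,
genes are ranked by expression (descending, ties broken by gene id) and
a set's enrichment score is the integrated difference between the
rank-weighted in-set ECDF (weights rank^alpha, alpha = 0.25) and the
unweighted out-of-set ECDF. Being rank-based, the score is invariant to
any strictly monotone transform of the sample's expression values.

Preranked GSEA computes the classical weighted running-sum statistic
(maximum deviation from zero) over a ranked gene list and assigns
significance by gene-label permutation with the add-one rule, so
permutation p-values are never exactly zero.

Group comparisons (high- vs low-ADI) run a per-row two-sided test
(Welch's t by default, Mann-Whitney U by flag) with Benjamini-Hochberg
adjustment across rows and conventional significance stars.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# gene sets (GMT)

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        name, _desc, *members = parts
        members = [m for m in members if m]
        if len(set(members)) != len(members):
            raise ValueError(f"gene set {name!r} has duplicate members")
        sets[name] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *members]) for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def filter_sets(
    sets: dict[str, list[str]], universe, min_size: int = 2
) -> dict[str, list[str]]:
    """Intersect sets with the expression universe; drop undersized sets."""
    universe = set(universe)
    kept: dict[str, list[str]] = {}
    for name, members in sets.items():
        overlap = [g for g in members if g in universe]
        if len(overlap) >= min_size:
            kept[name] = overlap
        else:
            warnings.warn(
                f"gene set {name!r} has {len(overlap)} gene(s) in the expression "
                f"universe (< {min_size}); skipped",
                stacklevel=2,
            )
    return kept


# ---------------------------------------------------------------------------
# ssGSEA

def _rank_order(values: pd.Series) -> np.ndarray:
    """Positions of genes ordered by descending value, gene id as tie-break."""
    frame = pd.DataFrame({"v": values.to_numpy(), "g": values.index})
    return frame.sort_values(["v", "g"], ascending=[False, True], kind="stable").index.to_numpy()


def ssgsea_score(
    sample: pd.Series, sets: dict[str, list[str]], alpha: float = 0.25
) -> pd.Series:
    """Single-sample enrichment scores for one expression column.

    Genes are ordered by descending expression (ties broken by gene id)
    and assigned rank weights N, N-1, ..., 1. For a set S the score is

        ES = sum_i [ P_in(i) - P_out(i) ]

    where P_in is the cumulative rank^alpha weight of set genes up to
    position i (normalized over the set) and P_out the cumulative count
    of non-set genes (normalized over the complement) -- the integrated
    difference of the two weighted ECDFs.
    """
    if sample.size < 2:
        raise ValueError("need at least 2 genes")
    if sample.index.has_duplicates:
        raise ValueError("duplicate gene ids in expression index")
    order = _rank_order(sample)
    genes_ordered = sample.index.to_numpy()[order]
    n = sample.size
    rank_weight = np.arange(n, 0, -1, dtype=float) ** alpha  # N^a ... 1^a

    scores: dict[str, float] = {}
    for name, members in sets.items():
        in_set = np.isin(genes_ordered, list(members))
        n_in = int(in_set.sum())
        if n_in < 2:
            warnings.warn(f"gene set {name!r}: <2 genes overlap the sample; skipped", stacklevel=2)
            continue
        if n_in == n:
            scores[name] = 0.0
            continue
        w = np.where(in_set, rank_weight, 0.0)
        p_in = np.cumsum(w) / w.sum()
        p_out = np.cumsum(~in_set) / (n - n_in)
        scores[name] = float(np.sum(p_in - p_out))
    return pd.Series(scores, name=sample.name)


def ssgsea(
    expression: pd.DataFrame,
    sets: dict[str, list[str]],
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """ssGSEA scores for every sample column; rows are gene sets.

    With ``normalize`` the whole matrix is divided by its score range
    (max - min), putting values on a comparable absolute scale.
    """
    sets = filter_sets(sets, expression.index)
    cols = [ssgsea_score(expression[c], sets, alpha=alpha) for c in expression.columns]
    matrix = pd.concat(cols, axis=1)
    matrix.columns = expression.columns
    if normalize and matrix.size:
        span = float(matrix.to_numpy().max() - matrix.to_numpy().min())
        if span > 0:
            matrix = matrix / span
    return matrix


# ---------------------------------------------------------------------------
# preranked GSEA

@dataclass
class GseaResult:
    set_name: str
    es: float
    p_value: float
    n_perm: int
    n_genes: int
    set_size: int

    @property
    def direction(self) -> int:
        return int(np.sign(self.es))


def _running_es(in_set: np.ndarray, weights: np.ndarray) -> float:
    """Signed max deviation of the GSEA running sum from zero."""
    n = in_set.size
    n_in = int(in_set.sum())
    hit = np.where(in_set, weights, 0.0)
    hit_total = hit.sum()
    if hit_total <= 0:  # all weights zero: hits step uniformly
        p_hit = np.cumsum(in_set) / n_in
    else:
        p_hit = np.cumsum(hit) / hit_total
    p_miss = np.cumsum(~in_set) / (n - n_in)
    running = p_hit - p_miss
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def preranked_gsea(
    ranked: pd.Series,
    gene_set,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> GseaResult:
    """Classical preranked GSEA for one gene set.

    ``ranked`` maps gene ids to a ranking statistic (sorted internally,
    descending, gene-id tie-break). Hits advance the running sum by
    |statistic|^weight (normalized), misses retreat it uniformly; the ES
    is the maximum deviation from zero, signed. The p-value permutes
    gene labels (random same-size sets), two-sided on |ES| with the
    add-one rule: p = (1 + #{|ES*| >= |ES|}) / (1 + n_perm).
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    if ranked.index.has_duplicates:
        raise ValueError("duplicate gene ids in ranked list")
    if not np.isfinite(ranked.to_numpy(dtype=float)).all():
        raise ValueError("ranking statistics must be finite")
    order = _rank_order(ranked)
    genes_ordered = ranked.index.to_numpy()[order]
    stats_ordered = ranked.to_numpy(dtype=float)[order]
    weights = np.abs(stats_ordered) ** weight

    in_set = np.isin(genes_ordered, list(gene_set))
    n_in = int(in_set.sum())
    n = in_set.size
    if n_in < 2 or n_in >= n:
        raise ValueError("gene set must overlap the universe with 2 <= |S| < N genes")

    es = _running_es(in_set, weights)

    rng = np.random.default_rng(np.random.SeedSequence([0x65EA, seed & 0x7FFFFFFF]))
    exceed = 0
    positions = np.arange(n)
    for _ in range(n_perm):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(positions, size=n_in, replace=False)] = True
        if abs(_running_es(perm, weights)) >= abs(es):
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return GseaResult(
        set_name=getattr(gene_set, "name", ""),
        es=es,
        p_value=float(p),
        n_perm=n_perm,
        n_genes=n,
        set_size=n_in,
    )


# ---------------------------------------------------------------------------
# group comparison

def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(
    matrix: pd.DataFrame,
    groups: pd.Series,
    test: str = "welch",
) -> pd.DataFrame:
    """Row-wise high- vs low-group comparison with BH adjustment.

    ``matrix`` has features (gene sets, immune scores) as rows and
    samples as columns; ``groups`` assigns each column "high" or "low".
    Returns a DataFrame with columns mean_high, mean_low, difference,
    statistic, p, q, stars. Constant rows get p = 1 with a warning.
    """
    groups = groups.reindex(matrix.columns)
    if groups.isna().any():
        raise ValueError("every sample column needs a group label")
    if not set(groups) <= {"high", "low"}:
        raise ValueError("group labels must be 'high' or 'low'")
    high = matrix.loc[:, groups == "high"].to_numpy(dtype=float)
    low = matrix.loc[:, groups == "low"].to_numpy(dtype=float)
    if high.shape[1] < 2 or low.shape[1] < 2:
        raise ValueError("both groups need at least 2 samples")
    if test not in ("welch", "mannwhitney"):
        raise ValueError(f"unknown test {test!r}")

    rows = []
    for i, name in enumerate(matrix.index):
        a, b = high[i], low[i]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            warnings.warn(f"row {name!r} is constant; p set to 1", stacklevel=2)
            stat, p = 0.0, 1.0
        elif test == "mannwhitney":
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            res = sps.ttest_ind(a, b, equal_var=False)
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "feature": name,
                "mean_high": float(a.mean()),
                "mean_low": float(b.mean()),
                "difference": float(a.mean() - b.mean()),
                "statistic": stat,
                "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["stars"] = [significance_stars(p) for p in out["p"]]
    return out
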