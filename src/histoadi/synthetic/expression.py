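"""Synthetic expression matrices with planted gene-set shifts.

Genes are baseline Normal(0, noise_sd); members of designated gene sets
get a constant mean shift added in the high-ADI samples. This is the
minimal world in which single-sample enrichment scoring and group
comparison have a known right answer: shifted sets should score higher
in the shifted group, unshifted sets should not separate the groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ExpressionSpec:
    """Generating parameters for one genes x samples matrix.

    ``gene_sets`` maps set names to gene-id lists (all ids must exist in
    the g0000... universe of size ``n_genes``); ``shifted_sets`` maps a
    subset of those names to the mean shift applied in high-ADI samples.
    ``group_labels`` optionally fixes the per-sample high/low labels;
    by default the first half of the samples is "high".
    """

    n_genes: int
    n_samples: int
    gene_sets: dict[str, list[str]] = field(default_factory=dict)
    shifted_sets: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    group_labels: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 1:
            raise ValueError("n_genes and n_samples must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        universe = set(gene_ids(self.n_genes))
        for name, members in self.gene_sets.items():
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {name!r} contains duplicate genes")
            missing = set(members) - universe
            if missing:
                raise ValueError(f"gene set {name!r} has genes outside the universe: {sorted(missing)[:3]}")
        unknown = set(self.shifted_sets) - set(self.gene_sets)
        if unknown:
            raise ValueError(f"shifted_sets refer to unknown sets: {sorted(unknown)}")
        if self.group_labels is not None:
            if len(self.group_labels) != self.n_samples:
                raise ValueError("group_labels length must equal n_samples")
            if not set(self.group_labels) <= {"high", "low"}:
                raise ValueError("group_labels must be 'high' or 'low'")


def gene_ids(n_genes: int) -> list[str]:
    """The canonical synthetic gene universe g0000 ... g{n-1}."""
    width = max(4, len(str(n_genes - 1)))
    return [f"g{i:0{width}d}" for i in range(n_genes)]


def make_gene_sets(
    n_genes: int, set_sizes: dict[str, int], seed: int = 0
) -> dict[str, list[str]]:
    """Draw disjoint random gene sets of the requested sizes."""
    if sum(set_sizes.values()) > n_genes:
        raise ValueError("gene sets do not fit in the universe")
    rng = np.random.default_rng(np.random.SeedSequence([0x6E5E, seed & 0x7FFFFFFF]))
    pool = list(gene_ids(n_genes))
    rng.shuffle(pool)
    sets: dict[str, list[str]] = {}
    start = 0
    for name, size in set_sizes.items():
        sets[name] = sorted(pool[start : start + size])
        start += size
    return sets


def generate_expression(spec: ExpressionSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a genes x samples matrix plus per-sample group labels.

    Returns ``(matrix, groups)`` where ``matrix`` is indexed by gene id
    with sample-id columns, and ``groups`` is a high/low Series aligned
    to the columns. Deterministic under the spec seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([0xE497, spec.seed & 0x7FFFFFFF]))
    genes = gene_ids(spec.n_genes)
    samples = [f"S{i:04d}" for i in range(spec.n_samples)]
    if spec.group_labels is None:
        half = spec.n_samples // 2
        labels = ["high"] * half + ["low"] * (spec.n_samples - half)
    else:
        labels = list(spec.group_labels)
    groups = pd.Series(labels, index=samples, name="group")

    values = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_samples))
    matrix = pd.DataFrame(values, index=genes, columns=samples)

    high_cols = groups[groups == "high"].index
    for name, shift in spec.shifted_sets.items():
        members = spec.gene_sets[name]
        matrix.loc[members, high_cols] += shift
    return matrix, groups
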