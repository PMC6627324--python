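"""Editing-frequency tables and group statistics.

The central statistic is the editing frequency of a gene in a species:
100 x (number of predicted sites in the gene's CDS) / (CDS length in nt).
Group comparisons use the Kruskal-Wallis rank test per gene, Dunn's
post-hoc z tests with Benjamini-Hochberg adjustment across group pairs,
and Pearson correlation of per-gene mean frequencies between groups.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .edit_predict import EditingProfile

__all__ = [
    "FrequencyTable",
    "GroupComparison",
    "CorrelationResult",
    "editing_frequency",
    "build_frequency_table",
    "kruskal_wallis",
    "dunn_posthoc",
    "benjamini_hochberg",
    "pearson_correlation",
    "group_scale_factor",
    "compare_groups_per_gene",
]


def editing_frequency(site_count: int, cds_length: int) -> float:
    """Percent of edited positions in a CDS: 100 * sites / length."""
    if cds_length <= 0:
        raise ValueError(f"cds_length must be positive, got {cds_length}")
    if not 0 <= site_count <= cds_length:
        raise ValueError(f"site_count {site_count} outside [0, {cds_length}]")
    return 100.0 * site_count / cds_length


@dataclass
class FrequencyTable:
    """Species x gene editing frequencies (%) with group labels.

    ``values`` holds NaN where a species lacks the gene (absent, not zero);
    ``lengths`` holds the per-species CDS length used as each denominator.
    """

    values: pd.DataFrame
    lengths: pd.DataFrame
    direction: str
    groups: dict[str, str] = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    def group_members(self, group: str) -> list[str]:
        return [s for s in self.species if self.groups.get(s) == group]

    def gene_values(self, gene: str, group: Optional[str] = None) -> np.ndarray:
        col = self.values[gene]
        if group is not None:
            col = col.loc[self.group_members(group)]
        return col.dropna().to_numpy()


def build_frequency_table(
    profile: EditingProfile,
    lengths: Mapping[tuple[str, str], int],
    direction: str,
    groups: Optional[Mapping[str, str]] = None,
) -> FrequencyTable:
    """Tabulate per-species per-gene editing frequencies for one direction.

    ``lengths`` maps (species, gene) to that species' own CDS length in nt.
    Cells for genes absent in a species remain NaN.
    """
    species = profile.species()
    genes = sorted({g for sp in species for g in profile.genes(sp)})
    values = pd.DataFrame(np.nan, index=species, columns=genes, dtype=float)
    lens = pd.DataFrame(np.nan, index=species, columns=genes, dtype=float)
    for sp in species:
        for gene in profile.genes(sp):
            key = (sp, gene)
            if key not in lengths:
                raise ValueError(f"CDS length missing for species {sp!r} gene {gene!r}")
            n = sum(1 for s in profile.sites_for(sp, gene) if s.direction == direction)
            values.loc[sp, gene] = editing_frequency(n, lengths[key])
            lens.loc[sp, gene] = lengths[key]
    return FrequencyTable(
        values=values,
        lengths=lens,
        direction=direction,
        groups=dict(groups or {}),
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; chi-square p on k-1 df.

    By convention, samples in which every observation is identical give
    H = 0, p = 1 (no rank information at all).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) == 0:
            raise ValueError("empty group")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, never below the raw p)."""
    return multipletests(pvalues, method="fdr_bh")[1]


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Dunn's pairwise rank tests after Kruskal-Wallis, BH-adjusted.

    For groups i, j the statistic is
    z = (Ri - Rj) / sqrt((N(N+1)/12 - T) (1/ni + 1/nj)) with mean ranks Ri,
    pooled tie correction T = sum(t^3 - t) / (12 (N - 1)), and a two-sided
    normal p-value; BH adjustment runs across the family of group pairs.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) == 0:
            raise ValueError("empty group")
    if labels is None:
        labels = [f"group{i+1}" for i in range(len(groups))]
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for arr in arrays:
        mean_ranks.append(ranks[start : start + len(arr)].mean())
        sizes.append(len(arr))
        start += len(arr)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        denom = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if denom == 0 else (mean_ranks[i] - mean_ranks[j]) / denom
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append((labels[i], labels[j], z, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])
    df["p_adj"] = benjamini_hochberg(df["p_raw"].to_numpy())
    return df


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r between two per-gene mean-frequency vectors, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input vector")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=len(x))


@dataclass
class GroupComparison:
    """Per-gene Kruskal-Wallis and Dunn results across species groups."""

    gene: str
    h: float
    p: float
    dunn: pd.DataFrame
    group_means: dict[str, float]
    group_se: dict[str, float]


def compare_groups_per_gene(
    table: FrequencyTable,
    groups: Optional[Sequence[str]] = None,
) -> list[GroupComparison]:
    """Kruskal-Wallis per gene across groups, with Dunn/BH post-hoc.

    Group means are unweighted means over the species of a group; the
    standard error is sd/sqrt(n). Genes with no rank variation anywhere are
    reported with H = 0, p = 1 rather than dropped.
    """
    if groups is None:
        groups = sorted(set(table.groups.values()))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    out = []
    for gene in table.genes:
        samples = [table.gene_values(gene, g) for g in groups]
        usable = [(g, s) for g, s in zip(groups, samples) if len(s) > 0]
        if len(usable) < 2:
            continue
        names = [g for g, _ in usable]
        vals = [s for _, s in usable]
        h, p = kruskal_wallis(vals)
        dunn = dunn_posthoc(vals, labels=names)
        means = {g: float(np.mean(s)) for g, s in usable}
        ses = {
            g: float(np.std(s, ddof=1) / math.sqrt(len(s))) if len(s) > 1 else float("nan")
            for g, s in usable
        }
        out.append(GroupComparison(gene=gene, h=h, p=p, dunn=dunn, group_means=means, group_se=ses))
    return out


def group_scale_factor(table: FrequencyTable, group_a: str, group_b: str) -> float:
    """Ratio of overall editing levels of two groups.

    A group's overall level is the unweighted mean over its species of
    (total sites across genes / total CDS length x 100); the factor is
    level(A) / level(B), so factor(A,B) * factor(B,A) = 1.
    """

    def overall_level(group: str) -> float:
        members = table.group_members(group)
        if not members:
            raise ValueError(f"group {group!r} has no species")
        levels = []
        for sp in members:
            freqs = table.values.loc[sp]
            lens = table.lengths.loc[sp]
            mask = freqs.notna()
            total_len = lens[mask].sum()
            total_sites = (freqs[mask] * lens[mask] / 100.0).sum()
            levels.append(100.0 * total_sites / total_len)
        return float(np.mean(levels))

    denom = overall_level(group_b)
    if denom == 0:
        raise ValueError(f"group {group_b!r} has zero overall editing level")
    return overall_level(group_a) / denom
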