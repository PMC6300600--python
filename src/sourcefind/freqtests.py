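"""Local-ancestry-conditioned allele-frequency differentiation tests.

Compares allele frequencies at index SNPs between two Native ancestry
components (e.g. Central Andes vs Mapuche) using admixed individuals:
individuals are selected by their genome-wide ancestry proportions
(>10% of the target component, <1% combined other Native, <1% East
Asian), and at each SNP only alleles lying on haplotype segments with
Native local ancestry are pooled into the frequency estimate.

Per-SNP differentiation uses a Welch two-sample t-test computed from the
Bernoulli summary statistics (frequency and haplotype count), with
Benjamini-Hochberg FDR control across SNPs.  Joint differentiation of a
set of index SNPs is assessed against a matched-SNP resampling null:
random sets of SNPs matched on haplotype counts (within 20) and
minor-allele frequency (within 1%) are drawn repeatedly, and the mean
-log p of the index set is ranked among the resampled sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .copying import ValidationError

__all__ = [
    "GroupSelection",
    "SNPAncestryFreq",
    "MatchedSetConfig",
    "select_individuals",
    "aggregate_group_frequencies",
    "welch_t_frequencies",
    "fdr_adjust",
    "build_matched_pools",
    "empirical_differentiation_p",
    "direction_consistency",
]


@dataclass(frozen=True)
class GroupSelection:
    """Ancestry thresholds defining one analysis group of individuals.

    ``group`` names the target ancestry column in the proportions table;
    ``other_native_groups`` the remaining Native columns whose combined
    proportion must stay below ``max_other_native``; ``east_asian_group``
    the column bounded by ``max_east_asian``.
    """

    group: str
    other_native_groups: tuple[str, ...] = ()
    east_asian_group: str | None = None
    min_target_ancestry: float = 0.10
    max_other_native: float = 0.01
    max_east_asian: float = 0.01

    def __post_init__(self) -> None:
        for thr in (self.min_target_ancestry, self.max_other_native, self.max_east_asian):
            if not 0.0 <= thr <= 1.0:
                raise ValidationError("selection thresholds must lie in [0, 1]")


@dataclass(frozen=True)
class SNPAncestryFreq:
    """Ancestry-conditioned allele frequency of one SNP in one group."""

    snp_id: str
    group: str
    allele_count: int
    n_haplotypes: int
    frequency: float  # NaN when no qualifying haplotypes

    @property
    def defined(self) -> bool:
        return self.n_haplotypes > 0


@dataclass(frozen=True)
class MatchedSetConfig:
    """Matching rules and sampling depth for the resampling null.

    Candidates for an index SNP must have both groups' haplotype counts
    within ``count_tolerance`` and the relevant group's minor-allele
    frequency within ``maf_tolerance`` of the index SNP (group A for set
    I, group B for set II).
    """

    count_tolerance: int = 20
    maf_tolerance: float = 0.01
    n_random_sets: int = 10_000
    set_size: int = 6
    match_on_group: Literal["A", "B"] = "A"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.count_tolerance < 0 or self.maf_tolerance < 0:
            raise ValidationError("matching tolerances must be >= 0")
        if self.set_size < 1 or self.n_random_sets < 1:
            raise ValidationError("set_size and n_random_sets must be >= 1")


def select_individuals(
    ancestry: pd.DataFrame, selection: GroupSelection
) -> list[str]:
    """Individuals passing the ancestry thresholds.

    ``ancestry`` is indexed by individual with one column per ancestry
    component (proportions).  Target ancestry must exceed
    ``min_target_ancestry`` strictly; the combined other-Native and the
    East-Asian proportions must fall strictly below their caps.
    """
    mask = ancestry[selection.group] > selection.min_target_ancestry
    if selection.other_native_groups:
        other = ancestry[list(selection.other_native_groups)].sum(axis=1)
        mask &= other < selection.max_other_native
    if selection.east_asian_group is not None:
        mask &= ancestry[selection.east_asian_group] < selection.max_east_asian
    return list(ancestry.index[mask])


def aggregate_group_frequencies(
    calls: pd.DataFrame,
    ancestry: pd.DataFrame,
    selection: GroupSelection,
    *,
    native_label: str = "Native",
) -> list[SNPAncestryFreq]:
    """Pool Native-ancestry alleles of selected individuals per SNP.

    ``calls`` has one row per haplotype per SNP with columns
    ``individual_id``, ``snp_id``, ``allele`` (0/1) and ``local_ancestry``;
    alleles on haplotypes whose local ancestry is not ``native_label`` are
    excluded from both numerator and denominator.  SNPs with zero
    qualifying haplotypes get frequency NaN (flagged via ``defined``).
    """
    required = {"individual_id", "snp_id", "allele", "local_ancestry"}
    missing = required - set(calls.columns)
    if missing:
        raise ValidationError(f"calls table missing columns: {sorted(missing)}")
    if not calls["allele"].isin([0, 1]).all():
        raise ValidationError("alleles must be coded 0/1")
    chosen = set(select_individuals(ancestry, selection))
    usable = calls[
        calls["individual_id"].isin(chosen)
        & (calls["local_ancestry"] == native_label)
    ]
    out: list[SNPAncestryFreq] = []
    grouped = usable.groupby("snp_id")["allele"].agg(["sum", "count"])
    for snp_id in sorted(calls["snp_id"].unique()):
        if snp_id in grouped.index:
            count = int(grouped.loc[snp_id, "sum"])
            n = int(grouped.loc[snp_id, "count"])
            freq = count / n
        else:
            count, n, freq = 0, 0, float("nan")
        out.append(SNPAncestryFreq(str(snp_id), selection.group, count, n, freq))
    return out


def welch_t_frequencies(
    freq_a: float, n_a: int, freq_b: float, n_b: int
) -> tuple[float, float, float]:
    """Welch two-sample t-test from Bernoulli summary statistics.

    Treats each group's alleles as n Bernoulli draws with the observed
    frequency: ``t = (fA - fB) / sqrt(fA(1-fA)/nA + fB(1-fB)/nB)`` with
    Welch-Satterthwaite degrees of freedom and a two-sided p from the t
    distribution.  Algebraically identical to running the unequal-variance
    t-test on the raw 0/1 allele vectors.
    """
    if n_a < 2 or n_b < 2:
        raise ValidationError("need at least two haplotypes per group")
    for f in (freq_a, freq_b):
        if not 0.0 <= f <= 1.0:
            raise ValidationError("frequencies must lie in [0, 1]")
    # per-group sample variances of 0/1 data (ddof=1, via the n/(n-1) factor)
    var_a = freq_a * (1.0 - freq_a) * n_a / (n_a - 1)
    var_b = freq_b * (1.0 - freq_b) * n_b / (n_b - 1)
    se2_a = var_a / n_a
    se2_b = var_b / n_b
    if se2_a + se2_b == 0.0:
        if freq_a == freq_b:
            return 0.0, float(n_a + n_b - 2), 1.0
        # monomorphic in both groups at different alleles: infinitely
        # separated under the Bernoulli model
        return math.copysign(math.inf, freq_a - freq_b), float(n_a + n_b - 2), 0.0
    t = (freq_a - freq_b) / math.sqrt(se2_a + se2_b)
    df = (se2_a + se2_b) ** 2 / (
        se2_a**2 / (n_a - 1) + se2_b**2 / (n_b - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def fdr_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValidationError("no p-values to adjust")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _required_columns(table: pd.DataFrame) -> None:
    required = {"snp_id", "n_a", "n_b", "freq_a", "freq_b", "maf_a", "maf_b"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"SNP summary table missing columns: {sorted(missing)}")


def build_matched_pools(
    index_snps: Sequence[str],
    genome_snps: pd.DataFrame,
    cfg: MatchedSetConfig,
) -> dict[str, dict[str, list[str]]]:
    """Per-index-SNP candidate pools matched on counts and MAF.

    ``genome_snps`` is a per-SNP summary (snp_id, n_a, n_b, freq_a,
    freq_b, maf_a, maf_b).  For each index SNP, pool "I" requires both
    groups' haplotype counts within ``count_tolerance`` and group-A MAF
    within ``maf_tolerance``; pool "II" uses the same count rule with
    group-B MAF.  Index SNPs are excluded from all pools.
    """
    _required_columns(genome_snps)
    table = genome_snps.set_index("snp_id", drop=False)
    for snp in index_snps:
        if snp not in table.index:
            raise ValidationError(f"index SNP {snp!r} missing from summary table")
    candidates = table[~table["snp_id"].isin(set(index_snps))]
    pools: dict[str, dict[str, list[str]]] = {}
    for snp in index_snps:
        row = table.loc[snp]
        count_ok = (
            ((candidates["n_a"] - row["n_a"]).abs() <= cfg.count_tolerance)
            & ((candidates["n_b"] - row["n_b"]).abs() <= cfg.count_tolerance)
        )
        set_i = candidates.loc[
            count_ok & ((candidates["maf_a"] - row["maf_a"]).abs() <= cfg.maf_tolerance),
            "snp_id",
        ].tolist()
        set_ii = candidates.loc[
            count_ok & ((candidates["maf_b"] - row["maf_b"]).abs() <= cfg.maf_tolerance),
            "snp_id",
        ].tolist()
        chosen = set_i if cfg.match_on_group == "A" else set_ii
        if not chosen:
            raise ValidationError(
                f"no matched candidates for index SNP {snp!r} "
                f"(set {'I' if cfg.match_on_group == 'A' else 'II'})"
            )
        pools[snp] = {"I": set_i, "II": set_ii}
    return pools


def _neglog_p(row: pd.Series) -> float:
    _, _, p = welch_t_frequencies(
        float(row["freq_a"]), int(row["n_a"]), float(row["freq_b"]), int(row["n_b"])
    )
    # cap so monomorphic-difference SNPs cannot dominate the set mean
    return -math.log(max(p, 1e-300))

def empirical_differentiation_p(
    index_snps: Sequence[str],
    pools: Mapping[str, Mapping[str, list[str]]],
    genome_snps: pd.DataFrame,
    cfg: MatchedSetConfig,
    rng: np.random.Generator,
    *,
    tail: Literal["ge", "le"] = "ge",
) -> tuple[float, float]:
    """Matched-SNP resampling p for joint differentiation of the index set.

    The statistic is the mean over index SNPs of -log p (Welch test).  For
    each of ``cfg.n_random_sets`` iterations one matched SNP per index SNP
    is drawn from its pool and the same statistic computed; the empirical
    p is ``(k + 1) / (n + 1)`` where ``k`` counts random sets at least as
    extreme.  ``tail="ge"`` (default) counts sets with statistic >= the
    observed one — the null sets being *more* differentiated; ``tail="le"``
    counts sets <= observed.  Returns ``(observed statistic, empirical p)``.
    """
    _required_columns(genome_snps)
    table = genome_snps.set_index("snp_id")
    pool_key = "I" if cfg.match_on_group == "A" else "II"
    pool_lists: list[np.ndarray] = []
    for snp in index_snps:
        ids = list(pools[snp][pool_key])
        if not ids:
            raise ValidationError(f"empty pool for index SNP {snp!r}")
        pool_lists.append(np.array([_neglog_p(table.loc[c]) for c in ids]))
    observed = float(np.mean([_neglog_p(table.loc[s]) for s in index_snps]))
    k = len(index_snps)
    draws = np.empty((cfg.n_random_sets, k))
    for j, stats_j in enumerate(pool_lists):
        draws[:, j] = stats_j[rng.integers(0, stats_j.size, size=cfg.n_random_sets)]
    null_stats = draws.mean(axis=1)
    if tail == "ge":
        exceed = int(np.sum(null_stats >= observed))
    elif tail == "le":
        exceed = int(np.sum(null_stats <= observed))
    else:
        raise ValidationError(f"unknown tail {tail!r}")
    return observed, (exceed + 1) / (cfg.n_random_sets + 1)


def direction_consistency(
    freq_a: Sequence[float],
    freq_b: Sequence[float],
    gwas_betas: Sequence[float],
    contrast_betas: Sequence[float],
) -> list[bool | None]:
    """Per-SNP sign agreement between frequency contrast and effect sizes.

    For each SNP: True when ``sign(fA - fB) * sign(gwas_beta)`` equals
    ``sign(contrast_beta)`` for the counted allele — i.e. the group in
    which the trait-increasing allele is commoner is the group whose
    ancestry contrast raises the trait.  ``None`` flags indeterminate SNPs
    (equal frequencies or a zero coefficient).
    """
    out: list[bool | None] = []
    for fa, fb, gw, ct in zip(freq_a, freq_b, gwas_betas, contrast_betas, strict=True):
        d = fa - fb
        if d == 0 or gw == 0 or ct == 0:
            out.append(None)
        else:
            out.append(math.copysign(1, d) * math.copysign(1, gw) == math.copysign(1, ct))
    return out
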