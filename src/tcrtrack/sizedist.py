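"""Clonal size-class analysis on depth-equalized repertoires.

Each library is downsized (sampled without replacement) to a fixed UMI
depth so that clonal-frequency classes are comparable across samples and
timepoints.  Clones are then binned as rare (a single UMI), small, medium
or large by clonal frequency, the UMI mass per class is summarized per
sample, and class fractions are compared across timepoints with ANOVA plus
Bonferroni-corrected pairwise tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import CloneCountTable


@dataclass(frozen=True)
class SizeClassSpec:
    """Size-class boundaries on clonal frequency (fractions, not %).

    rare: exactly one UMI (takes precedence; at depth 25,000 a singleton is
    a clonal frequency of 0.004%); small: below ``small_upper``; medium:
    ``[small_upper, medium_upper)``; large: >= ``medium_upper``.  Boundaries
    are half-open exactly as written: 0.1% <= c.f. < 0.5% is medium,
    c.f. >= 0.5% is large.
    """

    small_upper: float = 0.001   # 0.1 %
    medium_upper: float = 0.005  # 0.5 %

    @property
    def class_names(self) -> tuple[str, str, str, str]:
        return ("rare", "small", "medium", "large")


def downsize(
    counts: np.ndarray, depth: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Sample ``depth`` UMIs without replacement from one library column.

    Multivariate hypergeometric on the clone counts; clones drawn zero
    times simply have count 0 in the result.  Raises if the library is
    smaller than ``depth`` (no upsampling).
    """
    counts = np.asarray(counts)
    total = int(counts.sum())
    if total < depth:
        raise ValueError(f"library of {total} UMIs cannot be downsized to {depth}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if total == depth:
        return counts.copy()
    return rng.multivariate_hypergeometric(counts, depth)


def downsize_table(
    table: CloneCountTable, depth: int, seed: int = 0
) -> CloneCountTable:
    """Downsize every sample column of a table to a common depth."""
    rng = np.random.default_rng(seed)
    cols = [downsize(table.counts[:, j], depth, rng) for j in range(table.n_samples)]
    counts = np.column_stack(cols)
    present = counts.sum(axis=1) > 0
    return CloneCountTable(
        clones=[c for c, k in zip(table.clones, present) if k],
        samples=list(table.samples),
        counts=counts[present, :],
    )


def classify_sizes(
    counts: np.ndarray, depth: int, spec: SizeClassSpec = SizeClassSpec()
) -> pd.Series:
    """Size class per clone of one downsized column (zeros left unclassed)."""
    counts = np.asarray(counts)
    cf = counts / depth
    labels = np.full(len(counts), "", dtype=object)
    labels[(counts >= 2) & (cf < spec.small_upper)] = "small"
    labels[(cf >= spec.small_upper) & (cf < spec.medium_upper) & (counts >= 2)] = "medium"
    labels[(cf >= spec.medium_upper) & (counts >= 2)] = "large"
    labels[counts == 1] = "rare"  # structural rule, takes precedence
    return pd.Series(labels)


def class_fractions(
    counts: np.ndarray, depth: int, spec: SizeClassSpec = SizeClassSpec()
) -> dict[str, float]:
    """UMI-mass fraction of the repertoire occupied by each size class."""
    counts = np.asarray(counts)
    if counts.sum() != depth:
        raise ValueError("column must be downsized to the spec's depth first")
    labels = classify_sizes(counts, depth, spec)
    out = {}
    for name in spec.class_names:
        out[name] = float(counts[(labels == name).to_numpy()].sum() / depth)
    return out


def summarize_table(
    table: CloneCountTable, depth: int, spec: SizeClassSpec = SizeClassSpec(),
    seed: int = 0,
) -> pd.DataFrame:
    """Long summary (sample, timepoint, replicate, class, fraction) after
    downsizing each sample to ``depth``."""
    rng = np.random.default_rng(seed)
    rows = []
    for j, s in enumerate(table.samples):
        down = downsize(table.counts[:, j], depth, rng)
        for name, frac in class_fractions(down, depth, spec).items():
            rows.append(
                dict(sample_id=s.sample_id, timepoint=s.timepoint,
                     replicate=s.replicate, condition=s.condition,
                     size_class=name, fraction=frac)
            )
    return pd.DataFrame(rows)


def _anova_oneway(groups: list[np.ndarray]) -> tuple[float, float, str]:
    """One-way fixed-effects ANOVA with explicit degenerate-variance rules."""
    pooled = np.concatenate(groups)
    grand = pooled.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    # degenerate-variance rules, with a scale-aware numerical zero
    eps = 1e-12 * max(grand ** 2, 1e-30) * len(pooled)
    if ss_between <= eps:
        return 0.0, 1.0, "ok"
    if ss_within <= eps:
        return float("inf"), float("nan"), "zero within-group variance"
    f, p = stats.f_oneway(*groups)
    return float(f), float(p), "ok"


def compare_fractions(
    summary: pd.DataFrame,
    design: str = "one-way",
    group_col: str = "timepoint",
    second_factor: str = "condition",
) -> pd.DataFrame:
    """Per-class ANOVA across groups plus Bonferroni-adjusted pairwise tests.

    Pairwise p-values (two-sample t-tests) are multiplied by the number of
    pairwise comparisons C(k, 2) and capped at 1, mirroring Bonferroni's
    multiple-comparison post-test.
    """
    if design not in ("one-way", "two-way"):
        raise ValueError("design must be 'one-way' or 'two-way'")
    rows = []
    for size_class, sub in summary.groupby("size_class"):
        levels = sorted(sub[group_col].unique())
        if len(levels) < 2:
            raise ValueError("need >= 2 groups")
        groups = [
            sub.loc[sub[group_col] == lv, "fraction"].to_numpy() for lv in levels
        ]
        if any(len(g) < 2 for g in groups):
            raise ValueError("need >= 2 replicates per group")
        if design == "one-way":
            f, p, flag = _anova_oneway(groups)
        else:
            import statsmodels.formula.api as smf
            from statsmodels.stats.anova import anova_lm

            model = smf.ols(
                f"fraction ~ C({group_col}) + C({second_factor})", data=sub
            ).fit()
            tab = anova_lm(model, typ=2)
            f = float(tab.loc[f"C({group_col})", "F"])
            p = float(tab.loc[f"C({group_col})", "PR(>F)"])
            flag = "ok"
        rows.append(dict(size_class=size_class, contrast="omnibus",
                         F=f, p=p, p_bonferroni=np.nan, flag=flag))

        n_pairs = len(levels) * (len(levels) - 1) // 2
        for (i, a), (k, b) in itertools.combinations(enumerate(levels), 2):
            ga, gb = groups[i], groups[k]
            if ga.std(ddof=1) == 0 and gb.std(ddof=1) == 0:
                pp = 1.0 if np.isclose(ga.mean(), gb.mean()) else 0.0
                flag_p = "zero within-group variance"
            else:
                _, pp = stats.ttest_ind(ga, gb)
                flag_p = "ok"
            rows.append(
                dict(size_class=size_class, contrast=f"{a} vs {b}",
                     F=np.nan, p=float(pp),
                     p_bonferroni=min(1.0, float(pp) * n_pairs), flag=flag_p)
            )
    return pd.DataFrame(rows)
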