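"""Replicate-aware negative-binomial differential-expansion testing.

Implements the count-model workflow used for two-group clone-abundance
contrasts (pre- vs post-stimulation; bulk vs activation-marker-sorted):

* TMM (trimmed mean of M-values) library normalization,
* quantile adjustment of counts to a common effective library size,
* common negative-binomial dispersion by conditional maximum likelihood on
  the quantile-adjusted ("pseudo") counts,
* per-clone (tagwise) dispersion by weighted-likelihood shrinkage toward
  the common value,
* an exact two-sided NB test on the group sums, conditioning on the total
  (the conditional law is beta-binomial; the two-sided p sums all
  partitions no more probable than the observed one, capped at 1),
* Benjamini-Hochberg adjustment and classification into Differentially
  Over-/Under-/Not-Expanded (DOE/DUE/NDE) or Over-/Under-/Not-Represented
  (DOR/DUR/NDR) at the |fold change| > 1.5, adjusted p < 0.05 cut-offs.

The per-clone p-value depends only on the group sums, the replicate counts
per group and the dispersion; with dispersion -> 0 and balanced groups it
reduces exactly to the two-sided exact binomial test at 1/2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .model import CloneCountTable

logger = logging.getLogger(__name__)

PHI_MIN, PHI_MAX = 1e-6, 10.0
_REL_TIE = np.log1p(1e-7)  # relative tolerance when comparing partition pmfs

LABELS = {
    "expansion": dict(over="DOE", under="DUE", nde="NDE"),
    "representation": dict(over="DOR", under="DUR", nde="NDR"),
}
ND = "ND"


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------


def tmm_factors(
    counts: np.ndarray,
    lib_sizes: np.ndarray | None = None,
    log_ratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> np.ndarray:
    """Per-sample TMM normalization factors, rescaled to geometric mean 1.

    The reference sample is the one whose 75th-percentile scaled count is
    closest to the mean of those; each sample's factor is the
    precision-weighted mean of its log2 abundance ratios (M) against the
    reference after trimming the extreme 30% of M and 5% of A values,
    computed over clones nonzero in both samples.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a clones x samples matrix with >= 2 samples")
    lib = counts.sum(axis=0) if lib_sizes is None else np.asarray(lib_sizes, float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")

    scaled75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(scaled75 - scaled75.mean())))

    factors = np.ones(counts.shape[1])
    yr, nr = counts[:, ref], lib[ref]
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        y, n = counts[:, j], lib[j]
        keep = (y > 0) & (yr > 0)
        if keep.sum() < 2:
            logger.warning("TMM: sample %d shares <2 nonzero clones with reference; factor 1", j)
            continue
        obs, refp = y[keep] / n, yr[keep] / nr
        M = np.log2(obs / refp)
        A = 0.5 * np.log2(obs * refp)
        # asymptotic (delta-method) variance of M; weight = 1/variance
        v = (n - y[keep]) / (n * y[keep]) + (nr - yr[keep]) / (nr * yr[keep])

        m = len(M)
        lo_m = np.floor(m * log_ratio_trim) + 1
        hi_m = m + 1 - lo_m
        lo_a = np.floor(m * abundance_trim) + 1
        hi_a = m + 1 - lo_a
        rank_m = stats.rankdata(M)
        rank_a = stats.rankdata(A)
        kept = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not kept.any() or v[kept].min() <= 0:
            logger.warning("TMM: trimming left no usable clones for sample %d; factor 1", j)
            continue
        f = np.sum(M[kept] / v[kept]) / np.sum(1.0 / v[kept])
        factors[j] = 2.0 ** f
    return factors / np.exp(np.mean(np.log(factors)))


# ---------------------------------------------------------------------------
# quantile adjustment to a common library size
# ---------------------------------------------------------------------------


def q2qnbinom(
    x: np.ndarray, input_mean: np.ndarray, output_mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Quantile-map NB counts from one mean to another at fixed dispersion.

    Average of a normal and a gamma approximation to the NB quantile
    function, tail-matched on the side of the observation.
    """
    x = np.asarray(x, dtype=float)
    input_mean = np.broadcast_to(np.asarray(input_mean, float), x.shape).copy()
    output_mean = np.broadcast_to(np.asarray(output_mean, float), x.shape).copy()
    tiny = (input_mean < 1e-14) | (output_mean < 1e-14)
    input_mean[tiny] += 0.25
    output_mean[tiny] += 0.25

    ri = 1.0 + dispersion * input_mean
    vi = input_mean * ri
    ro = 1.0 + dispersion * output_mean
    vo = output_mean * ro

    # the normal map reduces to a linear standardization
    q1 = output_mean + np.sqrt(vo / vi) * (x - input_mean)

    shape_i, scale_i = input_mean / ri, ri
    shape_o, scale_o = output_mean / ro, ro
    upper = x >= input_mean
    q2 = np.empty_like(x)
    with np.errstate(all="ignore"):
        sf = stats.gamma.sf(x[upper], a=shape_i[upper], scale=scale_i[upper])
        q2[upper] = stats.gamma.isf(sf, a=shape_o[upper], scale=scale_o[upper])
        cdf = stats.gamma.cdf(x[~upper], a=shape_i[~upper], scale=scale_i[~upper])
        q2[~upper] = stats.gamma.ppf(cdf, a=shape_o[~upper], scale=scale_o[~upper])
    bad = ~np.isfinite(q2)
    q2[bad] = q1[bad]
    return np.clip((q1 + q2) / 2.0, 0.0, None)


def group_columns(groups: Sequence) -> dict:
    """Map group label -> column indices."""
    out: dict = {}
    for j, g in enumerate(groups):
        out.setdefault(g, []).append(j)
    return out


def quantile_adjust(
    counts: np.ndarray, groups: Sequence, eff_lib: np.ndarray, dispersion: float
) -> tuple[np.ndarray, float]:
    """Pseudo-counts at the common (geometric-mean) effective library size."""
    counts = np.asarray(counts, dtype=float)
    eff_lib = np.asarray(eff_lib, dtype=float)
    common = float(np.exp(np.mean(np.log(eff_lib))))
    pseudo = np.empty_like(counts)
    for cols in group_columns(groups).values():
        cols = np.asarray(cols)
        prop = counts[:, cols].sum(axis=1) / eff_lib[cols].sum()
        for j in cols:
            pseudo[:, j] = q2qnbinom(
                counts[:, j], prop * eff_lib[j], prop * common, dispersion
            )
    return pseudo, common


# ---------------------------------------------------------------------------
# dispersion estimation (conditional maximum likelihood)
# ---------------------------------------------------------------------------


def _conditional_loglik(
    pseudo: np.ndarray, group_cols: dict, phi: float
) -> np.ndarray:
    """Per-clone log-likelihood of phi conditional on the per-group totals.

    For a group of n replicates with counts y_i and total z:
    sum_i lnG(y_i + 1/phi) + lnG(n/phi) - lnG(z + n/phi) - n lnG(1/phi).
    """
    r = 1.0 / phi
    ll = np.zeros(pseudo.shape[0])
    for cols in group_cols.values():
        y = pseudo[:, cols]
        n = y.shape[1]
        z = y.sum(axis=1)
        ll += (
            gammaln(y + r).sum(axis=1)
            + gammaln(n * r)
            - gammaln(z + n * r)
            - n * gammaln(r)
        )
    return ll


def estimate_common_dispersion(
    counts: np.ndarray,
    groups: Sequence,
    eff_lib: np.ndarray | None = None,
    n_iter: int = 2,
) -> float:
    """Common NB dispersion by quantile-adjusted conditional ML (qCML).

    Counts are quantile-adjusted to the common library size, the summed
    conditional log-likelihood is maximized over phi in [1e-6, 10], and the
    adjustment is re-done at the updated phi (``n_iter`` refinements).
    """
    counts = np.asarray(counts, dtype=float)
    gc = group_columns(groups)
    if all(len(c) < 2 for c in gc.values()):
        raise ValueError(
            "no replication in any group: set the dispersion manually instead"
        )
    eff = counts.sum(axis=0) if eff_lib is None else np.asarray(eff_lib, float)

    phi = 0.1
    for _ in range(n_iter + 1):
        pseudo, _ = quantile_adjust(counts, groups, eff, phi)

        def neg(t: float) -> float:
            return -_conditional_loglik(pseudo, gc, float(np.exp(t))).sum()

        res = minimize_scalar(
            neg, bounds=(np.log(PHI_MIN), np.log(PHI_MAX)), method="bounded"
        )
        phi = float(np.exp(res.x))
    if phi <= PHI_MIN * 1.1:
        warnings.warn(
            "dispersion likelihood is maximized at the lower bound "
            "(little or no overdispersion information)",
            stacklevel=2,
        )
    return phi


def dispersion_grid(common_phi: float, points: int = 81) -> np.ndarray:
    grid = np.logspace(np.log10(PHI_MIN), np.log10(PHI_MAX), points)
    return np.unique(np.append(grid, common_phi))


def estimate_tagwise_dispersion(
    counts: np.ndarray,
    groups: Sequence,
    common_phi: float,
    prior_weight: float = 10.0,
    eff_lib: np.ndarray | None = None,
    grid_points: int = 81,
) -> np.ndarray:
    """Per-clone dispersion by weighted-likelihood shrinkage.

    Each clone maximizes its own conditional log-likelihood plus
    ``prior_weight`` times the average per-clone log-likelihood (whose
    maximum is the common dispersion): prior_weight -> infinity recovers the
    common value, prior_weight = 0 the per-clone ML estimate.
    """
    counts = np.asarray(counts, dtype=float)
    gc = group_columns(groups)
    eff = counts.sum(axis=0) if eff_lib is None else np.asarray(eff_lib, float)
    pseudo, _ = quantile_adjust(counts, groups, eff, common_phi)

    grid = dispersion_grid(common_phi, grid_points)
    cl = np.column_stack([_conditional_loglik(pseudo, gc, p) for p in grid])
    objective = cl + prior_weight * cl.mean(axis=0)[None, :]
    return grid[np.argmax(objective, axis=1)]


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------


def nb_exact_pvalue(z_a: int, z_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact p for group sums (z_a, z_b) under a common NB law.

    Conditional on z = z_a + z_b the partition is beta-binomial with sizes
    n_a/phi and n_b/phi (binomial with success probability n_a/(n_a+n_b) as
    phi -> 0).  p = sum of the probabilities of all partitions no more
    probable than the observed one (relative tie tolerance 1e-7), capped
    at 1.
    """
    if z_a < 0 or z_b < 0:
        raise ValueError("negative adjusted counts")
    z = z_a + z_b
    if z == 0:
        return 1.0
    a = np.arange(z + 1)
    if phi <= 1e-10:
        pr = n_a / (n_a + n_b)
        logpmf = (
            gammaln(z + 1) - gammaln(a + 1) - gammaln(z - a + 1)
            + a * np.log(pr) + (z - a) * np.log1p(-pr)
        )
    else:
        ra, rb = n_a / phi, n_b / phi
        logpmf = (
            gammaln(a + ra) - gammaln(a + 1) - gammaln(ra)
            + gammaln(z - a + rb) - gammaln(z - a + 1) - gammaln(rb)
        )
    logpmf = logpmf - logsumexp(logpmf)
    keep = logpmf <= logpmf[z_a] + _REL_TIE
    return float(min(1.0, np.exp(logsumexp(logpmf[keep]))))


def exact_test(
    counts_a: np.ndarray, counts_b: np.ndarray, phi: float | np.ndarray
) -> np.ndarray:
    """Vector of exact-test p-values for clones x replicate count blocks.

    ``counts_a``/``counts_b`` are (possibly quantile-adjusted) replicate
    counts per clone; group sums are rounded to the nearest integer for the
    exact partition summation.
    """
    counts_a = np.atleast_2d(np.asarray(counts_a, dtype=float))
    counts_b = np.atleast_2d(np.asarray(counts_b, dtype=float))
    if (counts_a < -1e-8).any() or (counts_b < -1e-8).any():
        raise ValueError("negative adjusted counts")
    n_a, n_b = counts_a.shape[1], counts_b.shape[1]
    z_a = np.rint(counts_a.sum(axis=1)).astype(int)
    z_b = np.rint(counts_b.sum(axis=1)).astype(int)
    phi_g = np.broadcast_to(np.asarray(phi, dtype=float), z_a.shape)
    return np.array(
        [nb_exact_pvalue(int(za), int(zb), n_a, n_b, float(p))
         for za, zb, p in zip(z_a, z_b, phi_g)]
    )


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# classification and reporting primitives
# ---------------------------------------------------------------------------


def classify(
    log2_fc: np.ndarray,
    adj_p: np.ndarray,
    fc_cut: float = 1.5,
    alpha: float = 0.05,
    contrast_kind: str = "expansion",
) -> np.ndarray:
    """DOE/DUE/NDE (or DOR/DUR/NDR) labels at strict cut-offs:
    over if log2FC > log2(fc_cut) and adjusted p < alpha, under if
    log2FC < -log2(fc_cut) and adjusted p < alpha, else not-differential."""
    names = LABELS[contrast_kind]
    cut = np.log2(fc_cut)
    log2_fc = np.asarray(log2_fc, dtype=float)
    adj_p = np.asarray(adj_p, dtype=float)
    out = np.full(log2_fc.shape, names["nde"], dtype=object)
    out[(log2_fc > cut) & (adj_p < alpha)] = names["over"]
    out[(log2_fc < -cut) & (adj_p < alpha)] = names["under"]
    return out


@dataclass(frozen=True)
class DiffExpConfig:
    fc_cut: float = 1.5
    alpha: float = 0.05
    prior_weight: float = 10.0
    prior_count: float = 0.5     # per group, for finite log2FC at zeros
    use_tagwise: bool = True


def differential_expansion(
    table: CloneCountTable,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    contrast_kind: str = "expansion",
    config: DiffExpConfig = DiffExpConfig(),
) -> pd.DataFrame:
    """Full two-group contrast (B vs A) on a clone-count table.

    The clone universe is every clone with at least one UMI in either
    group.  Returns one row per clone: ``clone_id``, ``log2_fc``,
    ``avg_log2_ucpm``, ``p``, ``adj_p``, ``label``.
    """
    wanted = list(samples_a) + list(samples_b)
    missing = set(wanted) - set(table.sample_ids)
    if missing:
        raise ValueError(f"unknown sample(s): {sorted(missing)}")
    sub = table.subset_samples(lambda s: s.sample_id in set(wanted))
    order = [sub.sample_ids.index(sid) for sid in wanted]
    counts = sub.counts[:, order].astype(float)
    lib = counts.sum(axis=0)
    groups = ["A"] * len(samples_a) + ["B"] * len(samples_b)

    factors = tmm_factors(counts, lib)
    eff = lib * factors

    phi = estimate_common_dispersion(counts, groups, eff)
    if config.use_tagwise:
        phi_g = estimate_tagwise_dispersion(
            counts, groups, phi, prior_weight=config.prior_weight, eff_lib=eff
        )
    else:
        phi_g = np.full(counts.shape[0], phi)

    pseudo, _ = quantile_adjust(counts, groups, eff, phi)
    a_cols = np.array([g == "A" for g in groups])
    p = exact_test(pseudo[:, a_cols], pseudo[:, ~a_cols], phi_g)
    adj = adjust_bh(p)

    z_a = counts[:, a_cols].sum(axis=1)
    z_b = counts[:, ~a_cols].sum(axis=1)
    la, lb = eff[a_cols].sum(), eff[~a_cols].sum()
    c = config.prior_count
    log2_fc = np.log2((z_b + c) / lb) - np.log2((z_a + c) / la)
    avg_log2_ucpm = np.log2(1e6 * (z_a + z_b + c) / (la + lb))
    labels = classify(log2_fc, adj, config.fc_cut, config.alpha, contrast_kind)

    return pd.DataFrame(
        dict(
            clone_id=sub.clone_ids,
            log2_fc=log2_fc,
            avg_log2_ucpm=avg_log2_ucpm,
            p=p,
            adj_p=adj,
            label=labels,
        )
    )


# ---------------------------------------------------------------------------
# cross-tables and overlaps
# ---------------------------------------------------------------------------


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass
class CrossTable:
    counts: pd.DataFrame        # rows: labels of contrast A (+ ND margin)
    row_percent: pd.DataFrame   # integer-rounded, half away from zero


def cross_tabulate(
    labels_a: pd.Series,
    labels_b: pd.Series,
    kind_a: str = "expansion",
    kind_b: str = "representation",
) -> CrossTable:
    """4x4 contingency of two contrasts' labels over the union universe.

    Clones absent from one contrast fall into its Not-Detected (ND) margin.
    Row percentages are reported as integers (half away from zero).
    """
    for s, name in ((labels_a, "labels_a"), (labels_b, "labels_b")):
        if s.index.duplicated().any():
            raise ValueError(f"duplicate clone ids in {name}")
    na, nb = LABELS[kind_a], LABELS[kind_b]
    rows = [na["over"], na["nde"], na["under"], ND]
    cols = [nb["over"], nb["nde"], nb["under"], ND]
    universe = labels_a.index.union(labels_b.index)
    a = labels_a.reindex(universe, fill_value=ND)
    b = labels_b.reindex(universe, fill_value=ND)
    counts = (
        pd.crosstab(a, b)
        .reindex(index=rows, columns=cols, fill_value=0)
        .rename_axis(index=kind_a, columns=kind_b)
    )
    totals = counts.sum(axis=1).replace(0, np.nan)
    pct = (counts.div(totals, axis=0) * 100.0).fillna(0.0)
    pct = pd.DataFrame(
        _round_half_away(pct.to_numpy()).astype(int), index=counts.index,
        columns=counts.columns,
    )
    return CrossTable(counts=counts, row_percent=pct)


def overlap_sets(sets: dict[str, set]) -> pd.DataFrame:
    """Venn-style exclusive region counts for two or more clone-id sets.

    One row per non-empty membership pattern; per-set totals over regions
    equal the set cardinalities.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    names = list(sets)
    universe = set().union(*sets.values())
    patterns: dict[tuple[bool, ...], int] = {}
    for x in universe:
        key = tuple(x in sets[n] for n in names)
        patterns[key] = patterns.get(key, 0) + 1
    rows = []
    for key in sorted(patterns, reverse=True):
        row = dict(zip(names, key))
        row["count"] = patterns[key]
        rows.append(row)
    return pd.DataFrame(rows)
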