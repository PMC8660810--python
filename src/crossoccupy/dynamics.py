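"""Time-course chromatin-accessibility analysis.

Fragments from the accessibility assay are filtered to the nucleosome-free
population (length < 100 bp, mapping quality > 30, both strict), counted over
regions, and normalized with median-of-ratios size factors. Differential
accessibility across timepoints is tested per region with a negative-binomial
likelihood-ratio test comparing per-timepoint means (full model) against a
common mean (reduced model), with a per-region method-of-moments dispersion
profiled once under the full model; p values come from a chi-squared reference
with T - 1 degrees of freedom and are BH-adjusted across regions. Significant
regions are k-means-clustered on z-scored replicate-averaged trajectories
(Lloyd's algorithm, best of ``nstart`` random restarts, R-style semantics).

The model/results split follows the statsmodels convention:
:class:`AccessibilityTimeCourse` holds the data, ``fit()`` returns a
:class:`TimeCourseResults` carrying estimates, diagnostics and ``summary()``,
and clustering hangs off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .core import GenomicInterval, ValidationError
from .stats import fisher_exact_two_sided, odds_ratio, wilcoxon_rank_sum

DEFAULT_TIMEPOINTS = (0, 6, 12, 18, 24)


@dataclass
class FragmentRecord:
    """An aligned fragment: interval plus mapping quality."""

    interval: GenomicInterval
    mapq: int

    def __post_init__(self) -> None:
        if self.mapq < 0:
            raise ValidationError("mapq must be >= 0")

    @property
    def length(self) -> int:
        return len(self.interval)


def filter_fragments(
    fragments: list[FragmentRecord], max_len: int = 100, min_mapq: int = 30
) -> list[FragmentRecord]:
    """Keep nucleosome-free, well-mapped fragments: length < ``max_len`` AND
    mapq > ``min_mapq`` (both bounds strict). Order is preserved."""
    return [f for f in fragments if f.length < max_len and f.mapq > min_mapq]


@dataclass
class CountMatrix:
    """Regions x samples non-negative integer counts with a sample sheet.

    ``counts``: DataFrame indexed by region id, one column per sample.
    ``samples``: DataFrame indexed by sample id with ``timepoint`` and
    ``replicate`` columns.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.isna().any().any():
            raise ValidationError("count matrix has missing cells")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        if not self.counts.index.is_unique:
            raise ValidationError("duplicate region ids")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValidationError(f"samples missing from sample sheet: {sorted(missing)}")
        self.samples = self.samples.loc[list(self.counts.columns)]

    @property
    def timepoints(self) -> list:
        return sorted(self.samples["timepoint"].unique().tolist())

    @property
    def region_ids(self) -> list[str]:
        return list(self.counts.index)


def region_id(iv: GenomicInterval) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}"


def count_matrix(
    fragments_per_sample: dict[str, list[FragmentRecord]],
    regions: list[GenomicInterval],
    samples: pd.DataFrame,
    exclusive: bool = False,
) -> CountMatrix:
    """Count fragments overlapping each region (>= 1 bp) per sample.

    By default a fragment spanning two regions counts toward both; with
    ``exclusive=True`` it is assigned only to the region of maximal overlap
    (ties to the leftmost region).
    """
    ids = [r.name or region_id(r) for r in regions]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate region ids")
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, r in enumerate(regions):
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end, i))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    data = {}
    for sample, frags in fragments_per_sample.items():
        col = np.zeros(len(regions), dtype=np.int64)
        for f in frags:
            items = by_chrom.get(f.interval.chrom)
            if not items:
                continue
            s, e = f.interval.start, f.interval.end
            hits = [
                (min(e, re_) - max(s, rs), rs, i)
                for rs, re_, i in items
                if rs < e and re_ > s
            ]
            if not hits:
                continue
            if exclusive:
                ov, _, i = max(hits, key=lambda h: (h[0], -h[1]))
                col[i] += 1
            else:
                for _, _, i in hits:
                    col[i] += 1
        data[sample] = col
    counts = pd.DataFrame(data, index=ids)
    return CountMatrix(counts=counts, samples=samples)


def size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    Per region with all-positive counts, the ratio of each sample's count to
    the region's geometric mean; the factor is the per-sample median of those
    ratios.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    y = df.to_numpy(dtype=float)
    positive = (y > 0).all(axis=1)
    if not positive.any():
        raise ValidationError(
            "no region with all-positive counts; use a pseudo-reference fallback"
        )
    yp = y[positive]
    log_geomean = np.log(yp).mean(axis=1)
    ratios = yp / np.exp(log_geomean)[:, None]
    return pd.Series(np.median(ratios, axis=0), index=df.columns, name="size_factor")


# ---------------------------------------------------------------------------
# negative-binomial likelihood-ratio test


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB2 log-likelihood, elementwise then summed over the last axis.

    ``mu`` broadcasts against ``y``; mu == 0 contributes 0 when y == 0 and
    -inf otherwise. Near-zero dispersion falls back to the Poisson limit.
    """
    y = np.asarray(y, dtype=float)
    mu = np.broadcast_to(mu, y.shape).astype(float)
    alpha = np.broadcast_to(alpha, y.shape).astype(float)
    out = np.full(y.shape, -np.inf)
    zero = mu <= 0
    out[zero & (y == 0)] = 0.0
    ok = ~zero
    poiss = ok & (alpha < 1e-10)
    if poiss.any():
        out[poiss] = y[poiss] * np.log(mu[poiss]) - mu[poiss] - gammaln(y[poiss] + 1)
    nb = ok & ~poiss
    if nb.any():
        r = 1.0 / alpha[nb]
        m, yy = mu[nb], y[nb]
        out[nb] = (
            gammaln(yy + r) - gammaln(r) - gammaln(yy + 1)
            + r * np.log(r / (r + m)) + yy * np.log(m / (r + m))
        )
    return out.sum(axis=-1)


def _nb_group_mle(y: np.ndarray, s: np.ndarray, alpha: np.ndarray, n_iter: int = 60) -> np.ndarray:
    """MLE of the group mean mu (one per row) for counts y with exposures s
    and fixed per-row dispersion alpha, by damped Newton on the score.

    y: (R, J); s: (J,) or (R, J); alpha: (R,). Rows with all-zero counts get 0.
    """
    y = np.asarray(y, dtype=float)
    s = np.broadcast_to(np.asarray(s, dtype=float), y.shape)
    a = np.asarray(alpha, dtype=float)[:, None]
    mu = y.sum(axis=1) / s.sum(axis=1)
    active = mu > 0
    mu_a = mu[active]
    y_a, s_a, al = y[active], s[active], a[active]
    for _ in range(n_iter):
        denom = 1.0 + al * mu_a[:, None] * s_a
        score = (y_a / mu_a[:, None] - s_a * (1.0 + al * y_a) / denom).sum(axis=1)
        hess = (-y_a / mu_a[:, None] ** 2 + s_a**2 * al * (1.0 + al * y_a) / denom**2).sum(axis=1)
        step = np.where(hess < 0, -score / hess, 0.0)
        new = mu_a + step
        # keep the iterate positive; fall back to halving toward the old value
        bad = new <= 0
        new[bad] = mu_a[bad] / 2.0
        if np.max(np.abs(new - mu_a) / np.maximum(mu_a, 1e-12)) < 1e-12:
            mu_a = new
            break
        mu_a = new
    mu[active] = mu_a
    return mu


def _moment_dispersion(
    y: np.ndarray, s: np.ndarray, groups: list[np.ndarray], floor: float = 1e-8
) -> np.ndarray:
    """Per-region method-of-moments dispersion profiled under the full model.

    Works on the normalized scale q = y / s. For each timepoint group,
    Var(q) = mu * mean(1/s) + alpha * mu^2; pooling unbiased within-group
    variances v_t over timepoints gives
    alpha = sum_t (v_t - qbar_t * c_t) / sum_t qbar_t^2, floored.
    Unbiased (ddof=1) group variances keep the estimator centered despite one
    fitted mean per group.
    """
    q = y / s
    num = np.zeros(y.shape[0])
    den = np.zeros(y.shape[0])
    for g in groups:
        if len(g) < 2:
            continue
        qg = q[:, g]
        qbar = qg.mean(axis=1)
        v = qg.var(axis=1, ddof=1)
        c = np.mean(1.0 / s[g]) if s.ndim == 1 else (1.0 / s[:, g]).mean(axis=1)
        num += v - qbar * c
        den += qbar**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, 0.0)
    # pooled (all-region) moment estimate: the stable central dispersion
    pooled = num.sum() / den.sum() if den.sum() > 0 else 0.0
    return np.maximum(alpha, floor), max(pooled, floor)


@dataclass
class TimeCourseResults:
    """Per-region LRT results with BH-adjusted p values.

    ``table`` columns: lrt_stat, df, pvalue, padj, dispersion, all_zero.
    """

    table: pd.DataFrame
    size_factors: pd.Series
    timepoints: list
    model: "AccessibilityTimeCourse"
    normalized_means: pd.DataFrame = field(repr=False, default=None)

    def significant(self, fdr: float = 0.05) -> list[str]:
        return list(self.table.index[self.table["padj"] < fdr])

    def summary(self) -> str:
        n = len(self.table)
        nsig = int((self.table["padj"] < 0.05).sum())
        lines = [
            "Time-course differential accessibility (NB likelihood-ratio test)",
            f"regions: {n}   timepoints: {self.timepoints}   df: {len(self.timepoints) - 1}",
            f"size factors: "
            + ", ".join(f"{s}={v:.3f}" for s, v in self.size_factors.items()),
            f"significant at BH FDR 0.05: {nsig} ({100 * nsig / max(n, 1):.1f}%)",
            f"median dispersion: {self.table['dispersion'].median():.4f}",
        ]
        return "\n".join(lines)

    def trajectories(self, regions: list[str] | None = None, zscore: bool = True) -> pd.DataFrame:
        """Replicate-averaged normalized count trajectories (regions x timepoints),
        z-scored per region by default (constant rows become zeros)."""
        return self.model.trajectories(regions=regions, zscore=zscore)

    def cluster(
        self,
        k: int = 6,
        nstart: int = 25,
        max_iter: int = 1000,
        seed: int = 0,
        fdr: float = 0.05,
        zscore: bool = True,
    ) -> "TrajectoryClustering":
        """k-means clustering of the significant regions' trajectories."""
        regions = self.significant(fdr)
        traj = self.trajectories(regions=regions, zscore=zscore)
        return cluster_trajectories(
            traj, k=k, nstart=nstart, max_iter=max_iter, seed=seed
        )


class AccessibilityTimeCourse:
    """Negative-binomial time-course model of per-region accessibility counts.

    Parameters
    ----------
    data : CountMatrix
        Regions x samples counts with a sample sheet mapping samples to
        timepoints and replicates.
    """

    def __init__(self, data: CountMatrix):
        self.data = data
        tps = data.timepoints
        if len(tps) < 2:
            raise ValidationError("need >= 2 timepoints")
        self.timepoints = tps
        self._groups = [
            np.flatnonzero((data.samples["timepoint"] == t).to_numpy()) for t in tps
        ]
        self._sf = size_factors(data)

    @classmethod
    def from_dataframes(cls, counts: pd.DataFrame, samples: pd.DataFrame):
        return cls(CountMatrix(counts=counts.astype(int), samples=samples))

    def trajectories(self, regions=None, zscore: bool = True) -> pd.DataFrame:
        y = self.data.counts.to_numpy(dtype=float)
        q = y / self._sf.to_numpy()
        cols = []
        for g in self._groups:
            cols.append(q[:, g].mean(axis=1))
        traj = pd.DataFrame(
            np.column_stack(cols), index=self.data.counts.index, columns=self.timepoints
        )
        if regions is not None:
            traj = traj.loc[regions]
        if zscore:
            vals = traj.to_numpy()
            mean = vals.mean(axis=1, keepdims=True)
            sd = vals.std(axis=1, keepdims=True)
            z = np.where(sd > 0, (vals - mean) / np.where(sd > 0, sd, 1.0), 0.0)
            traj = pd.DataFrame(z, index=traj.index, columns=traj.columns)
        return traj

    def fit(
        self,
        dispersion_floor: float = 1e-8,
        dispersion_mode: str = "max",
        fixed_dispersion: float | None = None,
    ) -> TimeCourseResults:
        """Fit full (per-timepoint mean) and reduced (common mean) NB models per
        region and return the likelihood-ratio test results.

        ``dispersion_mode`` selects the per-region dispersion plugged into both
        fits: ``'max'`` (default) takes the maximum of the per-region moment
        estimate and the pooled all-region estimate — the conservative rule of
        the original count-model packages, which keeps the chi-squared
        reference calibrated with few replicates; ``'per-region'`` and
        ``'pooled'`` use one source alone.
        """
        if dispersion_mode not in ("max", "per-region", "pooled"):
            raise ValidationError("dispersion_mode must be max, per-region or pooled")
        y = self.data.counts.to_numpy(dtype=float)
        s = self._sf.to_numpy()
        groups = self._groups
        if fixed_dispersion is not None:
            alpha = np.full(y.shape[0], max(fixed_dispersion, dispersion_floor))
            return self._lrt(y, s, groups, alpha)
        alpha_region, alpha_pooled = _moment_dispersion(y, s, groups, floor=dispersion_floor)
        if dispersion_mode == "per-region":
            alpha = alpha_region
        elif dispersion_mode == "pooled":
            alpha = np.full(y.shape[0], alpha_pooled)
        else:
            alpha = np.maximum(alpha_region, alpha_pooled)
        return self._lrt(y, s, groups, alpha)

    def _lrt(self, y, s, groups, alpha) -> TimeCourseResults:
        ll_full = np.zeros(y.shape[0])
        mu_full = np.zeros((y.shape[0], len(groups)))
        for gi, g in enumerate(groups):
            mu_g = _nb_group_mle(y[:, g], s[g], alpha)
            mu_full[:, gi] = mu_g
            ll_full += _nb_loglik(y[:, g], mu_g[:, None] * s[g], alpha[:, None])
        mu_red = _nb_group_mle(y, s, alpha)
        ll_red = _nb_loglik(y, mu_red[:, None] * s, alpha[:, None])

        stat = 2.0 * (ll_full - ll_red)
        stat = np.where(stat < 0, np.where(stat > -1e-8, 0.0, stat), stat)
        if (stat < 0).any():
            raise RuntimeError("LRT statistic negative beyond tolerance")
        df = len(groups) - 1
        pvals = sps.chi2.sf(stat, df)
        all_zero = (y == 0).all(axis=1)
        pvals = np.where(all_zero, 1.0, pvals)
        stat = np.where(all_zero, 0.0, stat)
        padj = multipletests(pvals, method="fdr_bh")[1]
        table = pd.DataFrame(
            {
                "lrt_stat": stat,
                "df": df,
                "pvalue": pvals,
                "padj": padj,
                "dispersion": alpha,
                "all_zero": all_zero,
            },
            index=self.data.counts.index,
        )
        means = pd.DataFrame(mu_full, index=self.data.counts.index, columns=self.timepoints)
        return TimeCourseResults(
            table=table, size_factors=self._sf, timepoints=self.timepoints,
            model=self, normalized_means=means,
        )


def nb_lrt(
    counts: CountMatrix,
    dispersion_floor: float = 1e-8,
    dispersion_mode: str = "max",
    fixed_dispersion: float | None = None,
) -> TimeCourseResults:
    """Functional wrapper: fit the NB time-course LRT on a count matrix."""
    return AccessibilityTimeCourse(counts).fit(
        dispersion_floor=dispersion_floor,
        dispersion_mode=dispersion_mode,
        fixed_dispersion=fixed_dispersion,
    )


# ---------------------------------------------------------------------------
# k-means trajectory clustering


@dataclass
class TrajectoryClustering:
    """Per-region cluster labels (1..k), centroids and within-cluster SS."""

    labels: pd.Series
    centroids: np.ndarray
    within_ss: float
    k: int
    nstart: int
    seed: int
    timepoints: list

    def cluster_regions(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])


def _lloyd(X: np.ndarray, k: int, max_iter: int, rng: np.random.Generator):
    uniq = np.unique(X, axis=0)
    init_idx = rng.choice(len(uniq), size=k, replace=False)
    centroids = uniq[init_idx].copy()
    prev_ss = np.inf
    labels = np.zeros(len(X), dtype=int)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        ss = d2[np.arange(len(X)), labels].sum()
        assert ss <= prev_ss + 1e-9, "k-means objective increased"
        new_centroids = centroids.copy()
        for j in range(k):
            members = X[labels == j]
            if len(members):
                new_centroids[j] = members.mean(axis=0)
            else:
                # re-seed an empty cluster at the point farthest from its centroid
                far = d2[np.arange(len(X)), labels].argmax()
                new_centroids[j] = X[far]
        if np.allclose(new_centroids, centroids):
            prev_ss = ss
            break
        centroids = new_centroids
        prev_ss = ss
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    ss = d2[np.arange(len(X)), labels].sum()
    return labels, centroids, float(ss)


def kmeans(X: np.ndarray, k: int, nstart: int = 25, max_iter: int = 1000, seed: int = 0):
    """Best-of-``nstart`` Lloyd's k-means with distinct-point initialization.

    Returns (labels 0..k-1, centroids, within-cluster SS). Deterministic given
    the seed.
    """
    X = np.asarray(X, dtype=float)
    if len(np.unique(X, axis=0)) < k:
        raise ValidationError("k exceeds the number of distinct points")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(nstart):
        labels, centroids, ss = _lloyd(X, k, max_iter, rng)
        if best is None or ss < best[2]:
            best = (labels, centroids, ss)
    return best


def cluster_trajectories(
    trajectories: pd.DataFrame,
    k: int = 6,
    nstart: int = 25,
    max_iter: int = 1000,
    seed: int = 0,
) -> TrajectoryClustering:
    """k-means over per-region trajectory vectors (rows are regions, columns
    timepoints; callers normally pass z-scored replicate-averaged counts)."""
    X = trajectories.to_numpy(dtype=float)
    labels, centroids, ss = kmeans(X, k=k, nstart=nstart, max_iter=max_iter, seed=seed)
    return TrajectoryClustering(
        labels=pd.Series(labels + 1, index=trajectories.index, name="cluster"),
        centroids=centroids, within_ss=ss, k=k, nstart=nstart, seed=seed,
        timepoints=list(trajectories.columns),
    )


# ---------------------------------------------------------------------------
# downstream comparisons


def cluster_binding_enrichment(
    clustering: TrajectoryClustering, bound_flags: pd.Series
) -> dict:
    """Test whether decreasing-accessibility clusters are enriched for bound regions.

    Clusters are grouped by the sign of (mean of the last two centroid
    timepoints - mean of the first two); the 2x2 Fisher test compares bound
    fractions between decreasing and increasing groups.
    """
    missing = set(clustering.labels.index) - set(bound_flags.index)
    if missing:
        raise ValidationError("bound_flags missing for some clustered regions")
    trend = clustering.centroids[:, -2:].mean(axis=1) - clustering.centroids[:, :2].mean(axis=1)
    decreasing_clusters = {j + 1 for j in range(clustering.k) if trend[j] < 0}
    group = clustering.labels.map(lambda c: "decreasing" if c in decreasing_clusters else "increasing")
    flags = bound_flags.loc[clustering.labels.index].astype(bool)
    n_dec, n_inc = (group == "decreasing").sum(), (group == "increasing").sum()
    if n_dec == 0 or n_inc == 0:
        raise ValidationError("a trend group is empty")
    a = int((flags & (group == "decreasing")).sum())
    c = int((flags & (group == "increasing")).sum())
    b, d = int(n_dec - a), int(n_inc - c)
    return {
        "fraction_decreasing": a / n_dec,
        "fraction_increasing": c / n_inc,
        "odds_ratio": odds_ratio(a, b, c, d),
        "pvalue": fisher_exact_two_sided(a, b, c, d),
        "decreasing_clusters": sorted(decreasing_clusters),
        "group": group,
    }


def motif_stratified_decay(
    trajectories: pd.DataFrame, motif_flags: pd.Series
) -> pd.DataFrame:
    """Per-timepoint rank-sum comparison of accessibility between motif-containing
    and motif-lacking regions, with box-plot summary statistics.

    Returns a tidy frame: one row per (timepoint, stratum) with median, Q1, Q3
    and 1.5 IQR whisker bounds, plus the two-sided Wilcoxon p per timepoint.
    """
    flags = motif_flags.loc[trajectories.index].astype(bool)
    if flags.all() or (~flags).all():
        raise ValidationError("both motif strata must be non-empty")
    rows = []
    for tp in trajectories.columns:
        with_m = trajectories.loc[flags, tp].to_numpy()
        without = trajectories.loc[~flags, tp].to_numpy()
        _, p = wilcoxon_rank_sum(with_m, without, mode="auto")
        for name, vals in (("with_motif", with_m), ("without_motif", without)):
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            lo = vals[vals >= q1 - 1.5 * iqr].min()
            hi = vals[vals <= q3 + 1.5 * iqr].max()
            rows.append(
                {
                    "timepoint": tp, "stratum": name, "n": len(vals), "median": med,
                    "q1": q1, "q3": q3, "whisker_low": lo, "whisker_high": hi, "pvalue": p,
                }
            )
    return pd.DataFrame(rows)
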