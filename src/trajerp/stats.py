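"""Inferential statistics for the 2x2 within-subject ERP design.

Two model classes follow the familiar model/results pattern:

* :class:`RepeatedMeasures2x2` -- the omnibus repeated-measures ANOVA
  with factors expectation (predictable / unpredictable) and shape
  status (cued / non-cued), with partial eta squared, Cousineau-Morey
  within-subject confidence intervals and Cook's-distance screening.
* :class:`ClusterPermutationTest` -- the temporal cluster test on
  per-subject subtraction waveforms: pointwise one-sample t-tests, a
  cluster-forming height threshold, summed-t cluster values, and a
  sign-flip permutation null of maximal pseudo-cluster values whose
  95th percentile gives the family-wise corrected significance
  criterion.

With two-level factors each within-subject effect's F statistic equals
the square of the paired t test on the corresponding per-subject
contrast scores, which the implementation exploits directly: each
effect is tested against its own subject-by-effect error term, and
sphericity holds automatically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

CONDITION_ORDER = (
    "predictable_cued",
    "predictable_noncued",
    "unpredictable_cued",
    "unpredictable_noncued",
)

EFFECTS = ("expectation", "shape_status", "interaction")

#: contrast weights over CONDITION_ORDER producing per-subject effect
#: scores on the scale of condition-mean differences
_CONTRASTS = {
    # (unpredictable mean) - (predictable mean)
    "expectation": np.array([-0.5, -0.5, 0.5, 0.5]),
    # (cued mean) - (non-cued mean)
    "shape_status": np.array([0.5, -0.5, 0.5, -0.5]),
    # difference of differences
    "interaction": np.array([1.0, -1.0, -1.0, 1.0]),
}


class DegenerateDataError(ValueError):
    pass


def as_cell_matrix(data: pd.DataFrame) -> pd.DataFrame:
    """Validate and order a subjects x 4-condition cell matrix.

    Accepts a wide DataFrame (index subjects, columns the four condition
    names). Requires complete cases and at least two subjects.
    """
    missing = [c for c in CONDITION_ORDER if c not in data.columns]
    if missing:
        raise ValueError(f"cell matrix missing condition columns {missing}")
    m = data.loc[:, list(CONDITION_ORDER)].astype(float)
    if m.isna().any().any():
        raise ValueError("cell matrix contains missing cells; complete cases only")
    if len(m) < 2:
        raise DegenerateDataError("need at least 2 subjects")
    return m


# ---------------------------------------------------------------------------
# repeated-measures ANOVA

@dataclass
class RM2x2Results:
    """Fitted 2x2 repeated-measures ANOVA."""

    anova_table: pd.DataFrame          # index: effect; F, df1, df2, p, partial eta sq
    cell_means: pd.Series
    cell_sems: pd.Series
    marginal_means: dict
    n_subjects: int
    data: pd.DataFrame = field(repr=False)

    def cousineau_morey_ci(self, alpha: float = 0.05) -> pd.Series:
        return cousineau_morey_ci(self.data, alpha=alpha)

    def cooks_distance(self, contrast: str = "mean") -> pd.DataFrame:
        return cooks_distance(self.data, contrast=contrast)

    def summary(self) -> str:
        lines = [
            f"Repeated-measures 2x2 ANOVA (n = {self.n_subjects} subjects)",
            "",
            self.anova_table.to_string(
                float_format=lambda v: f"{v:.4f}", justify="right"
            ),
            "",
            "Cell means (uV):",
        ]
        ci = self.cousineau_morey_ci()
        for cond in CONDITION_ORDER:
            lines.append(
                f"  {cond:<24s} {self.cell_means[cond]: .3f}"
                f"  (SE {self.cell_sems[cond]:.3f},"
                f" 95% CM-CI +-{ci[cond]:.3f})"
            )
        return "\n".join(lines)


class RepeatedMeasures2x2:
    """2x2 within-subject ANOVA on a subjects x conditions cell matrix.

    Parameters
    ----------
    data : DataFrame
        Wide cell matrix: one row per subject, one column per condition
        (the four ``{predictable,unpredictable}_{cued,noncued}`` names).
    """

    def __init__(self, data: pd.DataFrame):
        self.data = as_cell_matrix(data)

    @classmethod
    def from_component_table(
        cls, table: pd.DataFrame, measure: str
    ) -> "RepeatedMeasures2x2":
        from .erp_measures import measure_cell_matrix

        return cls(measure_cell_matrix(table, measure))

    def fit(self) -> RM2x2Results:
        m = self.data.to_numpy()
        n = m.shape[0]
        rows = []
        for effect in EFFECTS:
            scores = m @ _CONTRASTS[effect]
            mean = scores.mean()
            sd = scores.std(ddof=1)
            if sd == 0.0:
                if mean == 0.0:
                    f = 0.0
                else:
                    warnings.warn(
                        f"zero error variance for effect {effect}; F is infinite"
                    )
                    f = np.inf
            else:
                t = mean / (sd / np.sqrt(n))
                f = t * t
            df2 = n - 1
            p = float(sst.f.sf(f, 1, df2)) if np.isfinite(f) else 0.0
            eta = f / (f + df2) if np.isfinite(f) else 1.0
            rows.append(
                dict(effect=effect, F=float(f), df1=1, df2=df2, p=p,
                     partial_eta_sq=float(eta))
            )
        table = pd.DataFrame(rows).set_index("effect")
        cell_means = self.data.mean()
        cell_sems = self.data.std(ddof=1) / np.sqrt(n)
        marginals = {
            "predictable": float(
                self.data[["predictable_cued", "predictable_noncued"]]
                .to_numpy().mean()
            ),
            "unpredictable": float(
                self.data[["unpredictable_cued", "unpredictable_noncued"]]
                .to_numpy().mean()
            ),
            "cued": float(
                self.data[["predictable_cued", "unpredictable_cued"]]
                .to_numpy().mean()
            ),
            "noncued": float(
                self.data[["predictable_noncued", "unpredictable_noncued"]]
                .to_numpy().mean()
            ),
        }
        return RM2x2Results(
            anova_table=table,
            cell_means=cell_means,
            cell_sems=cell_sems,
            marginal_means=marginals,
            n_subjects=n,
            data=self.data,
        )


def rm_anova_2x2(data: pd.DataFrame) -> RM2x2Results:
    """Functional wrapper around :class:`RepeatedMeasures2x2`."""
    return RepeatedMeasures2x2(data).fit()


def cousineau_morey_ci(data: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Within-subject CI half-widths per cell (Cousineau-Morey).

    Subject-centre the data (subtract each subject's mean, add the grand
    mean), take the per-cell SE of the centred scores times the critical
    t (df = n-1), and apply the Morey bias correction sqrt(J/(J-1)) with
    J the number of cells.  Invariant to adding any subject-specific
    constant to all of a subject's cells.
    """
    m = as_cell_matrix(data)
    n, j = m.shape
    centred = m.sub(m.mean(axis=1), axis=0) + m.to_numpy().mean()
    sem = centred.std(ddof=1) / np.sqrt(n)
    tcrit = sst.t.ppf(1.0 - alpha / 2.0, n - 1)
    return sem * tcrit * np.sqrt(j / (j - 1.0))


def cooks_distance(data: pd.DataFrame, contrast: str = "mean") -> pd.DataFrame:
    """Per-subject Cook's distances for outlier screening.

    The default model regresses each subject's cell mean on an intercept
    only; ``contrast`` may instead name one of the within-subject effects
    ('expectation', 'shape_status', 'interaction'), screening on that
    subject-level effect score.  Distances above the 4/n heuristic are
    flagged; nothing is auto-excluded.
    """
    m = as_cell_matrix(data)
    n = len(m)
    if n <= 2:
        raise DegenerateDataError("Cook's distance needs more than 2 subjects")
    if contrast == "mean":
        y = m.to_numpy().mean(axis=1)
    elif contrast in _CONTRASTS:
        y = m.to_numpy() @ _CONTRASTS[contrast]
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    # intercept-only OLS: leverage 1/n, closed-form Cook's distance
    resid = y - y.mean()
    dof = n - 1
    mse = float(resid @ resid) / dof
    h = 1.0 / n
    with np.errstate(divide="ignore", invalid="ignore"):
        d = resid**2 / (1 * mse) * h / (1 - h) ** 2
    d = np.where(mse == 0.0, 0.0, d)
    return pd.DataFrame(
        {"cooks_d": d, "flagged": d > 4.0 / n}, index=m.index
    )


# ---------------------------------------------------------------------------
# pointwise t and temporal clusters

def pointwise_t(diff_waves: np.ndarray) -> np.ndarray:
    """One-sample t against zero at each timepoint; rows are subjects.

    Zero-variance timepoints yield t = +-inf (or 0 for the fully
    degenerate 0/0 case), with a warning.
    """
    x = np.asarray(diff_waves, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (n_subjects >= 2, n_times) array")
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    bad = sd == 0.0
    if bad.any():
        warnings.warn("zero between-subject variance at some timepoints")
        t = np.where(bad & (mean == 0.0), 0.0, t)
    return t


@dataclass(frozen=True)
class Cluster:
    start_idx: int
    end_idx: int       # inclusive
    start_ms: float
    end_ms: float
    summed_t: float

    @property
    def n_samples(self) -> int:
        return self.end_idx - self.start_idx + 1


def form_clusters(
    t_series: np.ndarray,
    height_threshold: float,
    times_ms: np.ndarray | None = None,
    min_length: int = 1,
) -> list[Cluster]:
    """Maximal runs of consecutive samples with |t| above the threshold
    and constant sign; each cluster's value is the sum of its t-values.
    Runs shorter than ``min_length`` samples are discarded (default:
    singletons are valid clusters)."""
    if height_threshold <= 0:
        raise ValueError("height threshold must be positive")
    t = np.asarray(t_series, float)
    if times_ms is None:
        times_ms = np.arange(len(t), dtype=float)
    supra = np.abs(t) > height_threshold
    sign = np.sign(t)
    clusters: list[Cluster] = []
    start = None
    for i in range(len(t) + 1):
        open_run = start is not None
        if i < len(t) and supra[i] and (not open_run or sign[i] == sign[start]):
            if not open_run:
                start = i
            continue
        if open_run:
            end = i - 1
            if end - start + 1 >= min_length:
                clusters.append(
                    Cluster(
                        start_idx=start,
                        end_idx=end,
                        start_ms=float(times_ms[start]),
                        end_ms=float(times_ms[end]),
                        summed_t=float(t[start : end + 1].sum()),
                    )
                )
            start = None
            if i < len(t) and supra[i]:   # sign flip starts a new run
                start = i
    return clusters


def _max_cluster_stats(
    tmat: np.ndarray, height_threshold: float, min_length: int = 1
) -> np.ndarray:
    """|largest summed-t pseudo-cluster| per row of a (n_perm, n_time)
    t matrix; 0 where a row has no supra-threshold cluster.  Vectorised
    over permutations via run-boundary bookkeeping."""
    p, t_len = tmat.shape
    flat = tmat.ravel()
    mask = np.abs(flat) > height_threshold
    if not mask.any():
        return np.zeros(p)
    sign = np.sign(flat)
    prev_mask = np.empty_like(mask)
    prev_mask[0] = False
    prev_mask[1:] = mask[:-1]
    prev_sign = np.empty_like(sign)
    prev_sign[0] = 0.0
    prev_sign[1:] = sign[:-1]
    new_row = np.zeros(p * t_len, dtype=bool)
    new_row[::t_len] = True
    starts = mask & (~prev_mask | (sign != prev_sign) | new_row)
    idx = np.flatnonzero(starts)
    sums = np.add.reduceat(np.where(mask, flat, 0.0), idx)
    if min_length > 1:
        lengths = np.add.reduceat(mask.astype(np.int64), idx)
        keep = lengths >= min_length
        idx, sums = idx[keep], sums[keep]
        if idx.size == 0:
            return np.zeros(p)
    out = np.zeros(p)
    np.maximum.at(out, idx // t_len, np.abs(sums))
    return out


def _t_for_flips(x: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t-series for every sign-flip pattern at once.

    ``x`` is (n_subjects, n_times), ``signs`` (n_perm, n_subjects) of
    +-1.  Per-subject sign flips leave each subject's squared values
    unchanged, so only the permuted means need a matrix product.
    """
    n = x.shape[0]
    ssq = (x * x).sum(axis=0)                        # (n_times,)
    means = signs @ x / n                            # (n_perm, n_times)
    var = (ssq - n * means**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n)
    return np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)


def signflip_null(
    diff_waves: np.ndarray,
    n_perm: int,
    height_threshold: float,
    seed: int | np.random.Generator = 0,
    min_length: int = 1,
    exhaustive: bool = False,
) -> np.ndarray:
    """Null distribution of maximal |summed-t| pseudo-cluster values.

    Each permutation flips every subject's whole subtraction waveform
    independently with probability one half (flips identical to the
    observed labelling included), recomputes the pointwise t-series and
    its clusters, and records the absolute value of the largest cluster
    value (0 if none).  With ``exhaustive=True`` all 2**n sign patterns
    are enumerated instead (n <= 20).
    """
    x = np.asarray(diff_waves, float)
    n = x.shape[0]
    if exhaustive:
        if n > 20:
            raise ValueError("exhaustive enumeration limited to n <= 20 subjects")
        codes = np.arange(2**n, dtype=np.int64)
        bits = (codes[:, None] >> np.arange(n)[None, :]) & 1
        signs = bits * 2.0 - 1.0
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null = np.empty(len(signs))
    block = 2048   # bound the (block x n_times) intermediates
    for i in range(0, len(signs), block):
        t = _t_for_flips(x, signs[i : i + block])
        null[i : i + block] = _max_cluster_stats(t, height_threshold, min_length)
    return null


# ---------------------------------------------------------------------------
# the full cluster test

@dataclass
class ClusterPermutationResults:
    """Observed clusters against the sign-flip max-statistic null."""

    t_series: np.ndarray
    times_ms: np.ndarray
    height_threshold: float
    clusters: pd.DataFrame       # start_ms, end_ms, n_samples, summed_t, p, significant
    null_distribution: np.ndarray
    percentile_95: float
    alpha: float
    n_subjects: int
    n_perm: int

    @property
    def any_significant(self) -> bool:
        return bool(self.clusters["significant"].any()) if len(self.clusters) else False

    def summary(self) -> str:
        lines = [
            f"Temporal cluster permutation test "
            f"(n = {self.n_subjects}, {self.n_perm} permutations)",
            f"height threshold |t({self.n_subjects - 1})| > "
            f"{self.height_threshold:.4f}",
            f"null 95th percentile of max |summed t| = {self.percentile_95:.2f}",
        ]
        if len(self.clusters) == 0:
            lines.append("no clusters exceeded the height threshold")
        else:
            lines.append(
                self.clusters.to_string(
                    float_format=lambda v: f"{v:.4g}", index=False
                )
            )
        return "\n".join(lines)


class ClusterPermutationTest:
    """Sign-flip temporal cluster test on per-subject subtraction waveforms.

    Parameters
    ----------
    diff_waves : ndarray (n_subjects, n_times)
        One subtraction waveform per subject (e.g. unpredictable minus
        predictable), on a common time axis.
    times_ms : ndarray
        Time axis; the analysis is typically restricted to -100..500 ms
        around the final stimulus before construction.
    alpha : float
        Two-tailed alpha, both for the cluster-forming height threshold
        (critical t with df = n-1) and the 95th-percentile null criterion.
    n_perm : int
        Number of sign-flip permutations.
    height_threshold : float, optional
        Override the computed critical t.
    min_cluster_length : int
        Minimum run length in samples (default 1: singletons allowed; the
        max-statistic null makes them harmless).
    """

    def __init__(
        self,
        diff_waves: np.ndarray,
        times_ms: np.ndarray,
        alpha: float = 0.05,
        n_perm: int = 10_000,
        height_threshold: float | None = None,
        min_cluster_length: int = 1,
    ):
        self.x = np.asarray(diff_waves, float)
        if self.x.ndim != 2 or self.x.shape[0] < 2:
            raise ValueError("need a (n_subjects >= 2, n_times) array")
        self.times_ms = np.asarray(times_ms, float)
        if len(self.times_ms) != self.x.shape[1]:
            raise ValueError("time axis length mismatch")
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        self.alpha = alpha
        self.n_perm = n_perm
        n = self.x.shape[0]
        self.height_threshold = (
            float(sst.t.ppf(1.0 - alpha / 2.0, n - 1))
            if height_threshold is None
            else float(height_threshold)
        )
        self.min_cluster_length = min_cluster_length

    def fit(self, seed: int = 0, exhaustive: bool = False) -> ClusterPermutationResults:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t_obs = pointwise_t(self.x)
        observed = form_clusters(
            t_obs, self.height_threshold, self.times_ms, self.min_cluster_length
        )
        null = signflip_null(
            self.x,
            self.n_perm,
            self.height_threshold,
            seed=seed,
            min_length=self.min_cluster_length,
            exhaustive=exhaustive,
        )
        n_null = len(null)
        pct95 = float(np.percentile(null, 95))
        rows = []
        for c in observed:
            stat = abs(c.summed_t)
            p = (1.0 + float((null >= stat).sum())) / (1.0 + n_null)
            rows.append(
                dict(
                    start_ms=c.start_ms,
                    end_ms=c.end_ms,
                    n_samples=c.n_samples,
                    summed_t=c.summed_t,
                    p=p,
                    significant=stat > pct95,
                )
            )
        clusters = pd.DataFrame(
            rows,
            columns=["start_ms", "end_ms", "n_samples", "summed_t", "p", "significant"],
        )
        return ClusterPermutationResults(
            t_series=t_obs,
            times_ms=self.times_ms,
            height_threshold=self.height_threshold,
            clusters=clusters,
            null_distribution=null,
            percentile_95=pct95,
            alpha=self.alpha,
            n_subjects=self.x.shape[0],
            n_perm=n_null,
        )


def cluster_test(
    diff_waves: np.ndarray,
    times_ms: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
    **kwargs,
) -> ClusterPermutationResults:
    """Functional wrapper around :class:`ClusterPermutationTest`."""
    return ClusterPermutationTest(
        diff_waves, times_ms, alpha=alpha, n_perm=n_perm, **kwargs
    ).fit(seed=seed)
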