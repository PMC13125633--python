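"""The study-level statistical layer.

Four pieces: (i) Spearman correlation of each metric with mean expert
ratings, with a plain Bonferroni multiplicity correction (0.05 / 17
rounds to the 0.003 threshold the study design uses); (ii) inter-rater
reliability as the two-way random-effects absolute-agreement intraclass
correlation, for single raters (ICC(2,1)) and for the rater average
(ICC(2,k)); (iii) descriptive medians / IQRs; and (iv) the Group x Stage
learning contrasts.

The contrasts deliberately replace a Bayesian multivariate skew-normal
model with a participant-level cluster bootstrap of the same
difference-in-differences estimands: participants are resampled with
replacement within group, keeping all their exercises and stages, and
per replicate the three Stage contrasts of the group means are formed.
Estimates are the observed contrasts; uncertainty is the percentile 95%
interval; ``prob`` is the bootstrap probability that the contrast
exceeds zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError

__all__ = [
    "RatingMatrix",
    "ContrastResult",
    "ALWAYS_INCLUDE_DEFAULT",
    "spearman",
    "bonferroni_threshold",
    "select_metrics",
    "correlate_metrics",
    "icc",
    "median_iqr",
    "group_stage_contrasts",
    "rating_contrasts",
    "CONTRAST_LABELS",
]

#: Metrics the study adds to the correlation-selected set regardless of
#: significance (shoulder ROM, the three variability metrics, timing and
#: phase shift).
ALWAYS_INCLUDE_DEFAULT = ("m3", "m10", "m11", "m12", "m13", "m17")

CONTRAST_LABELS = (
    "(AV S1 - AV S2) - (AVE S1 - AVE S2)",
    "(AV S2 - AV S3) - (AVE S2 - AVE S3)",
    "(AV S1 - AV S3) - (AVE S1 - AVE S3)",
)


@dataclass
class RatingMatrix:
    """Ordinal 1-7 expert ratings, raters x videos.

    ``scores`` has shape (n_raters, n_videos); ``video_meta`` is a
    DataFrame indexed like ``videos`` with participant / group /
    exercise / stage columns.
    """

    raters: list[str]
    videos: list[str]
    scores: np.ndarray
    video_meta: pd.DataFrame | None = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.raters), len(self.videos)):
            raise ParameterError("scores must have shape (n_raters, n_videos)")
        valid = np.isin(self.scores, np.arange(1, 8))
        if not valid.all():
            raise ParameterError("scores must be ordinal integers 1-7")

    def mean_per_video(self) -> pd.Series:
        """Mean expert rating per video, the correlation target."""
        return pd.Series(self.scores.mean(axis=0), index=self.videos)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "RatingMatrix":
        """Build from a tidy table with columns video_id, participant,
        group, exercise, stage, rater, score."""
        pivot = table.pivot_table(index="rater", columns="video_id",
                                  values="score", aggfunc="first")
        meta = (table.drop_duplicates("video_id")
                .set_index("video_id")[["participant", "group", "exercise", "stage"]]
                .loc[list(pivot.columns)])
        return cls(list(pivot.index.astype(str)), list(pivot.columns.astype(str)),
                   pivot.to_numpy(), meta)

    def to_table(self) -> pd.DataFrame:
        rows = []
        for r, rater in enumerate(self.raters):
            for v, video in enumerate(self.videos):
                row = {"video_id": video, "rater": rater,
                       "score": int(self.scores[r, v])}
                if self.video_meta is not None:
                    row.update(self.video_meta.loc[video].to_dict())
                rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class ContrastResult:
    """One bootstrap difference-in-differences contrast."""

    label: str
    estimate: float
    ci_low: float
    ci_high: float
    prob: float
    low_precision: bool = False

    def __post_init__(self):
        if np.isfinite(self.estimate):
            if not (self.ci_low <= self.estimate + 1e-12
                    and self.estimate - 1e-12 <= self.ci_high):
                raise ParameterError("estimate must lie inside its CI")
            if not 0.0 <= self.prob <= 1.0:
                raise ParameterError("prob must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Correlation layer
# ---------------------------------------------------------------------------


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with pairwise deletion of undefined values.

    Average ranks for ties; two-sided p from the t approximation.
    Requires >= 4 complete pairs; an all-tied vector yields a NaN marker.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 4:
        raise ParameterError("spearman needs >= 4 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, _ = sps.spearmanr(x, y)
    n = len(x)
    # two-sided p via the t approximation (documented convention)
    if abs(rho) >= 1.0:
        return float(rho), 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return float(rho), float(p)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance level alpha / m."""
    if m < 1:
        raise ParameterError("m must be >= 1")
    return alpha / m


def select_metrics(
    correlations: dict[str, tuple[float, float]],
    threshold: float,
    always_include: tuple[str, ...] = (),
) -> list[str]:
    """Metric ids with p < threshold, unioned with ``always_include``,
    in metric order."""
    retained = {mid for mid, (_, p) in correlations.items()
                if np.isfinite(p) and p < threshold}
    retained |= set(always_include)
    order = {mid: i for i, mid in enumerate(correlations)}
    return sorted(retained, key=lambda mid: order.get(mid, len(order)))


def correlate_metrics(
    metric_table: pd.DataFrame,
    ratings: RatingMatrix,
    alpha: float = 0.05,
    always_include: tuple[str, ...] = ALWAYS_INCLUDE_DEFAULT,
) -> pd.DataFrame:
    """Per-metric Spearman correlation with mean expert ratings.

    ``metric_table`` is tidy (participant, group, exercise, stage,
    metric, value); videos are joined on participant/exercise/stage.
    Returns a DataFrame (metric, rho, p, retained).
    """
    mean_ratings = ratings.mean_per_video()
    meta = ratings.video_meta
    if meta is None:
        raise ParameterError("ratings carry no video metadata to join on")
    key = meta.assign(rating=mean_ratings).reset_index()
    merged = metric_table.merge(
        key, on=["participant", "group", "exercise", "stage"], how="inner")
    metric_ids = [m for m in metric_table["metric"].unique()]
    rows = []
    corrs: dict[str, tuple[float, float]] = {}
    for mid in metric_ids:
        sub = merged[merged["metric"] == mid]
        rho, p = spearman(sub["value"].to_numpy(), sub["rating"].to_numpy())
        corrs[mid] = (rho, p)
        rows.append({"metric": mid, "rho": rho, "p": p})
    threshold = bonferroni_threshold(alpha, len(metric_ids))
    retained = set(select_metrics(corrs, threshold, always_include))
    out = pd.DataFrame(rows)
    out["retained"] = out["metric"].isin(retained)
    return out


# ---------------------------------------------------------------------------
# Inter-rater reliability
# ---------------------------------------------------------------------------


def icc(ratings: RatingMatrix, alpha: float = 0.05):
    """Two-way random-effects absolute-agreement intraclass correlation.

    Returns ``(icc_single, icc_average, ci_single, ci_average)``:
    ICC(2,1), ICC(2,k), and their F-based confidence intervals (McGraw &
    Wong), for a complete raters x videos score matrix.
    """
    scores = ratings.scores.T  # subjects (videos) x raters
    n, k = scores.shape
    if n < 2 or k < 2:
        raise ParameterError("icc needs >= 2 videos and >= 2 raters")
    grand = scores.mean()
    row_means = scores.mean(axis=1)
    col_means = scores.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((scores - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))

    icc1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    icck = (msr - mse) / (msr + (msc - mse) / n)

    if 1 - icc1 < 1e-12:  # perfect agreement: degenerate F interval
        return float(icc1), float(icck), (1.0, 1.0), (1.0, 1.0)

    # Satterthwaite df for the absolute-agreement interval
    a = (k * icc1) / (n * (1 - icc1))
    b = 1 + (k * icc1 * (n - 1)) / (n * (1 - icc1))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_lo = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_up = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lo1 = n * (msr - f_lo * mse) / (
        f_lo * (k * msc + (k * n - k - n) * mse) + n * msr)
    up1 = n * (f_up * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_up * msr)
    sb = lambda r: k * r / (1 + (k - 1) * r)  # Spearman-Brown
    return (
        float(icc1),
        float(icck),
        (float(lo1), float(up1)),
        (float(sb(lo1)), float(sb(up1))),
    )


def median_iqr(values) -> tuple[float, float]:
    """Median and interquartile range (linear-interpolation quantiles).

    The even-n median is the mean of the two central order statistics.
    """
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        raise ParameterError("median_iqr needs a non-empty sample")
    q1, q3 = np.percentile(x, [25, 75], method="linear")
    return float(np.median(x)), float(q3 - q1)


# ---------------------------------------------------------------------------
# Group x Stage contrasts
# ---------------------------------------------------------------------------


def _cell_matrix(table: pd.DataFrame, stages: tuple[str, ...]):
    """Participant x stage mean matrix (exercises averaged) per group."""
    out = {}
    for group, sub in table.groupby("group"):
        pivot = sub.pivot_table(index="participant", columns="stage",
                                values="value", aggfunc="mean", dropna=False)
        pivot = pivot.reindex(columns=list(stages))
        out[group] = pivot
    return out


def _bootstrap_contrasts(
    table: pd.DataFrame,
    n_boot: int,
    rng: np.random.Generator,
    stages: tuple[str, ...] = ("S1", "S2", "S3"),
) -> dict[str, ContrastResult]:
    cells = _cell_matrix(table, stages)
    if set(cells) != {"AV", "AVE"}:
        raise ParameterError("contrasts need both an AV and an AVE group")
    means = {}
    boots = {}
    for group, pivot in cells.items():
        vals = pivot.to_numpy()  # participants x stages
        n_part = vals.shape[0]
        if n_part < 2:
            raise ParameterError(f"group {group} has fewer than 2 participants")
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
            means[group] = np.nanmean(vals, axis=0)
            idx = rng.integers(0, n_part, size=(n_boot, n_part))
            boots[group] = np.nanmean(vals[idx], axis=1)  # n_boot x stages

    def diffs(stage_means):  # stage_means: (..., 3) ordered S1 S2 S3
        return np.stack(
            [
                (stage_means[..., 0] - stage_means[..., 1]),
                (stage_means[..., 1] - stage_means[..., 2]),
                (stage_means[..., 0] - stage_means[..., 2]),
            ],
            axis=-1,
        )

    obs = diffs(means["AV"][None, :])[0] - diffs(means["AVE"][None, :])[0]
    rep = diffs(boots["AV"]) - diffs(boots["AVE"])
    out = {}
    for j, label in enumerate(CONTRAST_LABELS):
        col = rep[:, j]
        col = col[np.isfinite(col)]
        if not np.isfinite(obs[j]) or len(col) == 0:
            out[label] = ContrastResult(label, float("nan"), float("nan"),
                                        float("nan"), float("nan"))
            continue
        lo, hi = np.percentile(col, [2.5, 97.5])
        lo, hi = min(lo, obs[j]), max(hi, obs[j])
        out[label] = ContrastResult(
            label,
            float(obs[j]),
            float(lo),
            float(hi),
            float(np.mean(col > 0)),
            low_precision=n_boot < 1000,
        )
    return out


def group_stage_contrasts(
    metric_table: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Difference-in-differences contrasts of the Group x Stage means,
    per metric, via participant-level cluster bootstrap.

    ``metric_table`` is tidy with columns participant, group, exercise,
    stage, metric, value (NaN = undefined, excluded by nan-mean).
    Returns a DataFrame (metric, contrast, estimate, ci_low, ci_high,
    prob).
    """
    if n_boot < 1:
        raise ParameterError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for mid in metric_table["metric"].unique():
        sub = metric_table[metric_table["metric"] == mid]
        results = _bootstrap_contrasts(sub, n_boot, rng)
        for label, res in results.items():
            rows.append({"metric": mid, "contrast": label,
                         "estimate": res.estimate, "ci_low": res.ci_low,
                         "ci_high": res.ci_high, "prob": res.prob})
    return pd.DataFrame(rows)


RATING_CONTRAST_LABELS = (
    "AV S1 - AVE S1",
    "AV S1 - AV S3",
    "AVE S1 - AVE S3",
    "AV S3 - AVE S3",
    "(AV S1 - AV S3) - (AVE S1 - AVE S3)",
)


def rating_contrasts(
    ratings: RatingMatrix,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Cluster-bootstrap contrasts of per-video mean expert ratings.

    Mirrors the expert-panel contrast table: the two within-group
    baseline-recall changes, the two between-group stage differences,
    and the Group x Stage interaction.
    """
    if ratings.video_meta is None:
        raise ParameterError("ratings carry no video metadata")
    if n_boot < 1:
        raise ParameterError("n_boot must be >= 1")
    table = ratings.video_meta.copy()
    table["value"] = ratings.mean_per_video()
    rng = np.random.default_rng(seed)

    cells = _cell_matrix(table, ("S1", "S3"))
    if set(cells) != {"AV", "AVE"}:
        raise ParameterError("contrasts need both an AV and an AVE group")
    means, boots = {}, {}
    for group, pivot in cells.items():
        vals = pivot.to_numpy()
        if vals.shape[0] < 2:
            raise ParameterError(f"group {group} has fewer than 2 participants")
        means[group] = np.nanmean(vals, axis=0)
        idx = rng.integers(0, vals.shape[0], size=(n_boot, vals.shape[0]))
        boots[group] = np.nanmean(vals[idx], axis=1)

    def all_contrasts(av, ave):  # (..., 2) stage means ordered S1 S3
        return np.stack(
            [
                av[..., 0] - ave[..., 0],
                av[..., 0] - av[..., 1],
                ave[..., 0] - ave[..., 1],
                av[..., 1] - ave[..., 1],
                (av[..., 0] - av[..., 1]) - (ave[..., 0] - ave[..., 1]),
            ],
            axis=-1,
        )

    obs = all_contrasts(means["AV"][None, :], means["AVE"][None, :])[0]
    rep = all_contrasts(boots["AV"], boots["AVE"])
    rows = []
    for j, label in enumerate(RATING_CONTRAST_LABELS):
        col = rep[:, j]
        col = col[np.isfinite(col)]
        lo, hi = np.percentile(col, [2.5, 97.5])
        lo, hi = min(lo, obs[j]), max(hi, obs[j])
        rows.append({"contrast": label, "estimate": float(obs[j]),
                     "ci_low": float(lo), "ci_high": float(hi),
                     "prob": float(np.mean(col > 0))})
    return pd.DataFrame(rows)
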