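"""Perceptual-contrast analysis of paired post-adaptation ratings.

Perceptual contrast is a shift of a stimulus's evaluation away from the
evaluation of the preceding adaptor stimuli. Each evaluation image receives
a mean rating after adaptation to the most-beautiful adaptors and one after
the least-beautiful adaptors; the contrast is their difference

    contrast = mean_after_beautiful - mean_after_least,

so a positive value means the image was rated less beautiful (higher
number) after beautiful adaptors — the headline direction of the effect.
The effect is tested with a paired t-test across the pooled unique
evaluation images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ClusterSolution
from .ratings import RatingMatrix

logger = logging.getLogger(__name__)


@dataclass
class ContrastTestResult:
    t: float
    df: int
    p: float
    paired_correlation: float
    mean_difference: float
    degenerate: bool = False

    def summary(self) -> str:
        flag = " [degenerate: zero variance of differences]" if self.degenerate else ""
        return (
            f"paired t-test across {self.df + 1} images: mean contrast = "
            f"{self.mean_difference:+.4f}, R = {self.paired_correlation:.3f}, "
            f"t({self.df}) = {self.t:.3f}, p = {self.p:.3g}{flag}"
        )


def compute_contrast(
    after_beautiful: RatingMatrix,
    after_least: RatingMatrix,
    sol: ClusterSolution,
) -> pd.DataFrame:
    """Per (cluster, image) condition means and their difference.

    For each cluster, each evaluation image's rating is pooled over the
    cluster's participants who rated it in both conditions; images present
    in only one condition are excluded with a warning. Columns:
    ``cluster, image_id, mean_after_beautiful, mean_after_least, contrast``.
    """
    if after_beautiful.phase != "after_beautiful" or after_least.phase != "after_least":
        raise ValueError("matrices must carry phases after_beautiful / after_least")
    all_imgs = after_beautiful.ratings.columns.union(after_least.ratings.columns)
    rows = []
    for c in sorted(sol.assignment.unique()):
        members = sol.assignment.index[sol.assignment == c]
        mb = after_beautiful.ratings.reindex(index=members, columns=all_imgs)
        ml = after_least.ratings.reindex(index=members, columns=all_imgs)
        nb, nl = mb.notna().sum(axis=0), ml.notna().sum(axis=0)
        one_sided = (nb > 0) ^ (nl > 0)
        for img in all_imgs[one_sided]:
            logger.warning("image %r in cluster %s rated in only one condition; excluded", img, c)
        both = (nb > 0) & (nl > 0)
        bm, lm = mb.mean(axis=0)[both], ml.mean(axis=0)[both]
        for img in bm.index:
            rows.append(
                {
                    "cluster": int(c),
                    "image_id": img,
                    "mean_after_beautiful": float(bm[img]),
                    "mean_after_least": float(lm[img]),
                    "contrast": float(bm[img] - lm[img]),
                }
            )
    return pd.DataFrame(rows, columns=["cluster", "image_id", "mean_after_beautiful", "mean_after_least", "contrast"])


def _paired_t(b: np.ndarray, l: np.ndarray) -> ContrastTestResult:
    n = len(b)
    diff = b - l
    mean_diff = float(diff.mean())
    if np.allclose(diff.std(ddof=1), 0):
        return ContrastTestResult(
            t=float("inf") if mean_diff != 0 else 0.0,
            df=n - 1,
            p=float("nan") if mean_diff != 0 else 1.0,
            paired_correlation=float(np.corrcoef(b, l)[0, 1]) if b.std() > 0 and l.std() > 0 else float("nan"),
            mean_difference=mean_diff,
            degenerate=mean_diff != 0,
        )
    t, p = stats.ttest_rel(b, l)
    r = float(np.corrcoef(b, l)[0, 1]) if b.std() > 0 and l.std() > 0 else float("nan")
    return ContrastTestResult(
        t=float(t), df=n - 1, p=float(p), paired_correlation=r, mean_difference=mean_diff
    )


def paired_contrast_test(table: pd.DataFrame) -> ContrastTestResult:
    """Paired t-test of the contrast across the pooled unique evaluation images.

    Images evaluated by several clusters are averaged within image across
    clusters first, so each unique image contributes one pair; df is the
    number of unique images minus one. Also reports the Pearson correlation
    between the two condition vectors.
    """
    pooled = table.groupby("image_id")[["mean_after_beautiful", "mean_after_least"]].mean()
    if len(pooled) < 3:
        raise ValueError("need at least 3 images rated in both conditions")
    return _paired_t(
        pooled["mean_after_beautiful"].to_numpy(), pooled["mean_after_least"].to_numpy()
    )


def per_cluster_contrast_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Condition means +- SD and paired test per cluster.

    Clusters with fewer than 2 evaluation images are excluded with a
    warning. ``inverted`` flags clusters whose mean contrast opposes the
    sign of the majority of clusters (the anomalous-cluster phenomenon).
    """
    rows = []
    for c, sub in table.groupby("cluster"):
        if len(sub) < 2:
            logger.warning("cluster %s has <2 evaluation images; excluded from summary", c)
            continue
        res = _paired_t(sub["mean_after_beautiful"].to_numpy(), sub["mean_after_least"].to_numpy())
        rows.append(
            {
                "cluster": int(c),
                "n_images": len(sub),
                "mean_after_beautiful": float(sub["mean_after_beautiful"].mean()),
                "sd_after_beautiful": float(sub["mean_after_beautiful"].std(ddof=1)),
                "mean_after_least": float(sub["mean_after_least"].mean()),
                "sd_after_least": float(sub["mean_after_least"].std(ddof=1)),
                "mean_contrast": res.mean_difference,
                "t": res.t,
                "df": res.df,
                "p": res.p,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    majority_sign = np.sign(np.sign(out["mean_contrast"]).sum())
    out["inverted"] = (np.sign(out["mean_contrast"]) == -majority_sign) & (majority_sign != 0)
    return out
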