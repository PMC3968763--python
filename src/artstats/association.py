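"""Associations between image statistics and beauty ratings / contrast.

Three layers, mirroring standard practice in empirical aesthetics:

* per-cluster Spearman rank correlations between cluster-mean beauty
  ratings and each image property (raw p-values plus Holm-adjusted ones);
* multivariate OLS across images with z-scored response and predictors
  (standardized betas);
* a linear mixed model over (image, cluster) observations with cluster as
  fixed factor, image properties as covariates, cluster x property
  interactions, and a random intercept per image.

Sign convention: ratings use 1 = most beautiful, so a POSITIVE correlation
means images with more of the property were rated LESS beautiful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .features import FEATURE_COLUMNS, HUE_COLUMNS

logger = logging.getLogger(__name__)

#: Properties entered in the mixed model (PHOG + hue/saturation/value + aspect ratio).
MIXED_MODEL_PROPERTIES = [
    "self_similarity",
    "complexity",
    "anisotropy",
    "birkhoff",
    "hsv_hue",
    "hsv_saturation",
    "hsv_value",
    "aspect_ratio",
]

COLLINEARITY_CONDITION_THRESHOLD = 1e6


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def spearman_table(
    cluster_means: pd.DataFrame,
    features: pd.DataFrame,
    properties: list[str] | None = None,
    cluster_label_suffix: str | None = None,
    include_average: bool = True,
) -> pd.DataFrame:
    """Tie-corrected Spearman rho per cluster x property.

    ``cluster_means`` is clusters x images (raw 1-4 scale); ``features``
    is indexed by image id. Cluster labels follow the "c/k" scheme when
    ``cluster_label_suffix`` (the k) is given. An "average evaluation" row
    over the grand-mean rating is appended when ``include_average``.
    Constant properties yield NaN rho flagged in the ``flag`` column.
    """
    if properties is None:
        properties = FEATURE_COLUMNS
    imgs = [i for i in cluster_means.columns if i in features.index]
    if len(imgs) < 5:
        raise ValueError("need at least 5 images common to ratings and features")
    feats = features.loc[imgs]
    rows = []

    def _rows_for(label: str, ratings: np.ndarray) -> None:
        for prop in properties:
            x = feats[prop].to_numpy(dtype=float)
            flag = ""
            if np.isnan(x).any():
                keep = ~np.isnan(x)
                x_use, y_use = x[keep], ratings[keep]
                flag = f"dropped_{int((~keep).sum())}_missing"
            else:
                x_use, y_use = x, ratings
            if np.allclose(x_use.std(), 0):
                rho, p, flag = float("nan"), float("nan"), "constant_property"
            else:
                rho, p = _spearman(x_use, y_use)
            rows.append({"cluster": label, "property": prop, "rho": rho, "p": p, "flag": flag})

    for c in cluster_means.index:
        label = f"{int(c) + 1}/{cluster_label_suffix}" if cluster_label_suffix else str(c)
        _rows_for(label, cluster_means.loc[c, imgs].to_numpy(dtype=float))
    if include_average:
        _rows_for("average evaluation", cluster_means[imgs].mean(axis=0).to_numpy(dtype=float))
    out = pd.DataFrame(rows)
    # Holm adjustment within each cluster row-block, mirroring per-cluster reporting
    out["p_holm"] = np.nan
    for label, idx in out.groupby("cluster").groups.items():
        pvals = out.loc[idx, "p"]
        mask = pvals.notna()
        if mask.any():
            out.loc[pvals.index[mask], "p_holm"] = multipletests(pvals[mask], method="holm")[1]
    return out


@dataclass
class RegressionResult:
    response: str
    params: pd.Series  # standardized betas (no intercept)
    pvalues: pd.Series
    r_squared: float
    n: int
    condition_number: float
    collinear: bool
    n_dropped: int = 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"standardized_beta": self.params, "p": self.pvalues})


def regression_standardized(
    response: pd.Series,
    features: pd.DataFrame,
    predictors: list[str],
    response_name: str = "response",
) -> RegressionResult:
    """OLS across images after z-scoring response and each predictor.

    Images with missing predictor values are dropped (count logged).
    A condition number above 1e6 triggers a collinearity warning; the
    coefficients are still reported.
    """
    data = features.loc[response.index, predictors].copy()
    data[response_name] = response
    n0 = len(data)
    data = data.dropna()
    n_dropped = n0 - len(data)
    if n_dropped:
        logger.warning("dropping %d images with missing values from regression", n_dropped)
    constant = [p for p in predictors if np.allclose(data[p].std(ddof=1), 0)]
    if constant:
        logger.warning("dropping constant predictors (undefined standardized beta): %s", constant)
    used = [p for p in predictors if p not in constant]
    if not used:
        raise ValueError("no non-constant predictors")
    z = (data[used + [response_name]] - data[used + [response_name]].mean()) / data[
        used + [response_name]
    ].std(ddof=1)
    X = sm.add_constant(z[used].to_numpy())
    fit = sm.OLS(z[response_name].to_numpy(), X).fit()
    cond = float(np.linalg.cond(X))
    collinear = cond > COLLINEARITY_CONDITION_THRESHOLD
    if collinear:
        logger.warning("collinear predictors (condition number %.3g)", cond)
    params = pd.Series(fit.params[1:], index=used).reindex(predictors)
    pvals = pd.Series(fit.pvalues[1:], index=used).reindex(predictors)
    return RegressionResult(
        response=response_name,
        params=params,
        pvalues=pvals,
        r_squared=float(fit.rsquared),
        n=len(data),
        condition_number=cond,
        collinear=collinear,
        n_dropped=n_dropped,
    )


def quadratic_complexity_probe(response: pd.Series, features: pd.DataFrame) -> RegressionResult:
    """Inverted-U probe: rating ~ complexity + complexity^2 (both z-scored)."""
    feats = features.loc[response.index, ["complexity"]].copy()
    feats["complexity_sq"] = feats["complexity"] ** 2
    return regression_standardized(
        response, feats, ["complexity", "complexity_sq"], response_name="rating"
    )


@dataclass
class MixedModelResult:
    interaction_tests: pd.DataFrame  # property -> F (Wald chi2/df), df, p
    cluster_slopes: pd.DataFrame  # per (cluster, property) regression coefficient + p
    converged: bool
    singular: bool
    n_obs: int
    group_var: float

    def summary(self) -> pd.DataFrame:
        return self.interaction_tests


def mixed_model_cluster_interaction(
    cluster_means: pd.DataFrame,
    features: pd.DataFrame,
    properties: list[str] | None = None,
) -> MixedModelResult:
    """Linear mixed model over (image, cluster) observations.

    Dependent: cluster-mean beauty rating. Fixed: cluster membership,
    image-property covariates and their cluster x property interactions.
    Random: an intercept per image (the only grouping factor). For each
    property the cluster x property interaction is tested with a Wald test
    (chi2 with k-1 df, reported on the F = chi2/df scale); per-cluster
    regression coefficients (base slope + interaction) are reported with
    Wald p-values. A singular or non-converged fit is reported in the
    result, never silently replaced.
    """
    if properties is None:
        properties = [p for p in MIXED_MODEL_PROPERTIES if p in features.columns]
    if cluster_means.shape[0] < 2:
        raise ValueError("need at least 2 clusters")
    imgs = [i for i in cluster_means.columns if i in features.index]
    feats = features.loc[imgs, properties]
    keep = feats.dropna().index
    if len(keep) < len(imgs):
        logger.warning("dropping %d images with missing properties from mixed model", len(imgs) - len(keep))
    constant = [p for p in properties if np.allclose(feats.loc[keep, p].std(ddof=1), 0)]
    if constant:
        logger.warning("dropping constant properties from mixed model: %s", constant)
        properties = [p for p in properties if p not in constant]
    feats = feats[properties]
    # z-score covariates so slopes are comparable across properties
    z = (feats.loc[keep] - feats.loc[keep].mean()) / feats.loc[keep].std(ddof=1)
    long = []
    for c in cluster_means.index:
        for img in keep:
            long.append({"image": str(img), "cluster": f"c{int(c)}", "rating": cluster_means.loc[c, img]})
    df = pd.DataFrame(long).set_index("image")
    df = df.join(z.rename(index=str)).reset_index()
    rhs = " + ".join(f"C(cluster)*{p}" for p in properties)
    model = smf.mixedlm(f"rating ~ {rhs}", df, groups=df["image"])
    import warnings as _warnings

    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        fit = model.fit(reml=True)
    singular = any("singular" in str(w.message).lower() for w in caught)
    clusters = sorted(cluster_means.index)
    names = list(fit.model.exog_names)
    k = len(clusters)

    inter_rows = []
    slope_rows = []
    cov = fit.cov_params().iloc[: len(names), : len(names)].to_numpy()
    beta = fit.params.iloc[: len(names)].to_numpy()
    for prop in properties:
        inter_names = [n for n in names if n.endswith(f":{prop}") or (":" in n and n.split(":")[-1] == prop)]
        # Wald chi2 over the k-1 interaction contrasts
        R = np.zeros((len(inter_names), len(names)))
        for r, n_ in enumerate(inter_names):
            R[r, names.index(n_)] = 1.0
        if len(inter_names):
            rb = R @ beta
            rcov = R @ cov @ R.T
            try:
                chi2 = float(rb @ np.linalg.solve(rcov, rb))
            except np.linalg.LinAlgError:
                chi2 = float("nan")
            dfn = len(inter_names)
            F = chi2 / dfn
            p = float(stats.chi2.sf(chi2, dfn)) if np.isfinite(chi2) else float("nan")
        else:
            F, dfn, p = float("nan"), 0, float("nan")
        inter_rows.append({"property": prop, "F": F, "df": dfn, "p": p})
        base_idx = names.index(prop)
        for ci, c in enumerate(clusters):
            contrast = np.zeros(len(names))
            contrast[base_idx] = 1.0
            iname = f"C(cluster)[T.c{int(c)}]:{prop}"
            if iname in names:
                contrast[names.index(iname)] = 1.0
            rc = float(contrast @ beta)
            se = float(np.sqrt(contrast @ cov @ contrast))
            zstat = rc / se if se > 0 else float("nan")
            slope_rows.append(
                {
                    "cluster": int(c),
                    "property": prop,
                    "rc": rc,
                    "se": se,
                    "p": float(2 * stats.norm.sf(abs(zstat))) if np.isfinite(zstat) else float("nan"),
                }
            )
    return MixedModelResult(
        interaction_tests=pd.DataFrame(inter_rows).set_index("property"),
        cluster_slopes=pd.DataFrame(slope_rows),
        converged=bool(fit.converged),
        singular=singular,
        n_obs=len(df),
        group_var=float(fit.cov_re.iloc[0, 0]) if fit.cov_re.size else float("nan"),
    )


def hue_group_analysis(
    features: pd.DataFrame,
    cluster_means: pd.DataFrame,
) -> pd.DataFrame:
    """Spearman association of each 60-degree hue-sector pixel fraction with ratings.

    Hue is circular, so instead of correlating the raw hue channel, the
    fraction of pixels in each of the six color ranges (red, yellow, green,
    cyan, blue, magenta) is correlated with the cluster-mean ratings; p is
    Holm-corrected across the six sectors within each cluster. Sectors with
    (near-)constant fractions — e.g. an all-grayscale collection — are
    flagged degenerate.
    """
    imgs = [i for i in cluster_means.columns if i in features.index]
    feats = features.loc[imgs]
    rows = []
    for c in cluster_means.index:
        y = cluster_means.loc[c, imgs].to_numpy(dtype=float)
        sector_stats = []
        for col in HUE_COLUMNS:
            x = feats[col].to_numpy(dtype=float)
            if np.allclose(x.std(), 0):
                sector_stats.append((col, float("nan"), float("nan"), True))
            else:
                rho, p = _spearman(x, y)
                sector_stats.append((col, rho, p, False))
        pvals = [s[2] for s in sector_stats if not s[3]]
        adj_iter = iter(multipletests(pvals, method="holm")[1]) if pvals else iter([])
        for col, rho, p, degen in sector_stats:
            rows.append(
                {
                    "cluster": int(c),
                    "sector": col.removeprefix("hue_"),
                    "rho": rho,
                    "p": p,
                    "p_holm": float("nan") if degen else float(next(adj_iter)),
                    "degenerate": degen,
                }
            )
    return pd.DataFrame(rows)
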