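"""Phenotype curation: encoding, outlier trimming, upright means, trait cliques.

Raw per-upright observations are curated in a fixed order: rows flagged as
rotten are dropped, then observations are tested as regression outliers
(externally studentized residuals from a least-squares fit of the trait on
population, genotype and year, Bonferroni-adjusted, worst observation
removed and the model refit until none is significant), then values beyond
a hard standard-deviation cut are culled. Analysis units are the means over
the (up to ten) sampled uprights per genotype-year. Trait relationships are
summarized by Pearson correlations computed within year and averaged, with
complete-linkage hierarchical clustering on 1 - |r| cut at 0.6; only
non-singleton clusters ("trait cliques") are reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats

DEFAULT_ORDINAL = {"very low": 0, "low": 1, "medium": 2, "high": 3, "very high": 4}


def encode_categorical(raw: pd.DataFrame, encoding: dict[str, dict],
                       shape_trait: str = "UBS") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map categorical trait labels to numeric values.

    ``encoding`` maps trait name -> {category label -> numeric value}. The
    berry-shape trait is not encoded: its rows are split off unchanged for
    the chimera pipeline. Traits not named in ``encoding`` are assumed
    numeric already. Unknown categories are a hard error listing the labels.

    Returns ``(numeric_table, shape_table)``.
    """
    shape_rows = raw[raw["trait"] == shape_trait].copy()
    out = raw[raw["trait"] != shape_trait].copy()
    for trait, mapping in encoding.items():
        if trait == shape_trait:
            continue
        sel = out["trait"] == trait
        vals = out.loc[sel, "value"]
        unknown = sorted(set(vals) - set(mapping))
        if unknown:
            raise ValueError(f"trait {trait!r}: unmapped categories {unknown}")
        out.loc[sel, "value"] = vals.map(mapping)
    out["value"] = pd.to_numeric(out["value"], errors="raise")
    return out, shape_rows


def _factor_design(df: pd.DataFrame) -> np.ndarray:
    """Intercept + treatment dummies for population, genotype and year."""
    blocks = [np.ones((len(df), 1))]
    for c in ("population", "genotype", "year"):
        if c in df.columns and df[c].nunique() > 1:
            d = pd.get_dummies(df[c], drop_first=True, dtype=float)
            blocks.append(d.to_numpy())
    return np.hstack(blocks)


def _externally_studentized(X: np.ndarray, y: np.ndarray):
    """Externally studentized residuals and residual df for a least-squares fit.

    Closed form via leverages: t_i = r_i / (s_(i) sqrt(1-h_i)) with
    s_(i)² the leave-one-out residual variance — no refitting needed.
    Returns None if the model is rank deficient to the point of df < 2.
    """
    Q, R = np.linalg.qr(X)
    keep = np.abs(np.diag(R)) > 1e-9 * max(1.0, np.abs(R).max())
    if not keep.all():
        Q = np.linalg.qr(X[:, keep])[0]
    n, p = len(y), Q.shape[1]
    df = n - p
    if df < 2:
        return None
    r = y - Q @ (Q.T @ y)
    h = np.clip((Q ** 2).sum(axis=1), 0.0, 1.0 - 1e-12)
    sse = float(r @ r)
    s2_loo = np.clip((sse - r ** 2 / (1.0 - h)) / (df - 1), 1e-300, None)
    t = r / np.sqrt(s2_loo * (1.0 - h))
    pvals = 2.0 * stats.t.sf(np.abs(t), df=df - 1)
    return t, np.minimum(pvals * n, 1.0)


def _studentized_trim(df: pd.DataFrame, alpha: float, log: list) -> pd.DataFrame:
    """Iterated worst-outlier removal by Bonferroni-adjusted studentized residuals."""
    work = df.copy()
    while len(work) >= 10:
        res = _externally_studentized(_factor_design(work),
                                      work["value"].to_numpy(dtype=float))
        if res is None:
            log.append(("<fit>", "rank_deficient", np.nan, np.nan))
            break
        t, bonf = res
        k = int(np.argmin(bonf))
        if bonf[k] < alpha:
            idx = work.index[k]
            log.append((idx, "studentized", float(t[k]), float(bonf[k])))
            work = work.drop(index=idx)
        else:
            break
    return work


def trim_outliers(tbl: pd.DataFrame, alpha: float = 0.05,
                  sd_cut: float = 3.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Curate a long phenotype table; returns ``(clean_table, removal_log)``.

    Order per trait: rot-flagged rows out first, then the iterated
    studentized-residual test at Bonferroni ``alpha``, then the hard
    ``sd_cut``-standard-deviation cut around the trait mean. Zero-variance
    traits pass through the SD step untouched.
    """
    log: list[tuple] = []
    pieces = []
    for trait, grp in tbl.groupby("trait", sort=False):
        work = grp
        if "rot_flag" in work.columns:
            rotten = work.index[work["rot_flag"].fillna(False).astype(bool)]
            for idx in rotten:
                log.append((idx, "rotten", np.nan, np.nan))
            work = work.drop(index=rotten)
        if len(work) >= 10:
            work = _studentized_trim(work, alpha, log)
        sd = work["value"].std(ddof=1)
        if sd and np.isfinite(sd) and sd > 0:
            z = (work["value"] - work["value"].mean()).abs() / sd
            cut = work.index[z > sd_cut]
            for idx in cut:
                log.append((idx, "sd_cut", float(z[idx]), np.nan))
            work = work.drop(index=cut)
        pieces.append(work)
    clean = pd.concat(pieces) if pieces else tbl.iloc[0:0]
    log_df = pd.DataFrame(log, columns=["row_id", "rule", "statistic", "p"])
    return clean, log_df


def upright_means(tbl: pd.DataFrame) -> pd.DataFrame:
    """Mean value over available uprights per (genotype, year, trait), with counts."""
    keys = [c for c in ("population", "genotype", "year", "trait") if c in tbl.columns]
    out = (tbl.groupby(keys, sort=False)["value"]
           .agg(value="mean", n_uprights="count")
           .reset_index())
    return out


def correlation_cliques(means: pd.DataFrame, cut_height: float = 0.6,
                        linkage_method: str = "complete"):
    """Year-averaged Pearson correlations, p-values, and non-singleton trait clusters.

    Correlations are computed on the genotype × trait matrix within each
    year and averaged across years. p-values use the t statistic of the
    averaged correlation at the mean per-year sample size. Clustering is
    hierarchical agglomerative on distance ``1 - |r̄|``, cut at
    ``cut_height``; traits with zero variance (correlation undefined) are
    excluded and logged.

    Returns ``(rbar, pvals, clusters, dropped)`` where ``clusters`` maps
    cluster id -> trait list (non-singletons only).
    """
    traits = sorted(means["trait"].unique())
    if len(traits) < 3:
        raise ValueError("need at least 3 traits")
    dropped = []
    mats, ns = [], []
    for _, grp in means.groupby("year"):
        wide = grp.pivot_table(index="genotype", columns="trait", values="value")
        mats.append(wide.corr(method="pearson", min_periods=3))
        ns.append(len(wide))
    rbar = pd.concat(mats).groupby(level=0).mean()
    rbar = rbar.reindex(index=traits, columns=traits)
    constant = [t for t in traits if rbar.drop(columns=t).loc[t].isna().all()]
    for t in constant:
        dropped.append((t, "constant_or_missing"))
    keep = [t for t in traits if t not in constant]
    if len(keep) < 3:
        raise ValueError("fewer than 3 traits with defined correlations")
    rbar = rbar.loc[keep, keep]
    np.fill_diagonal(rbar.values, 1.0)

    n_eff = max(float(np.mean(ns)), 4.0)
    r = rbar.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n_eff - 2) / np.clip(1 - r ** 2, 1e-12, None))
    pvals = pd.DataFrame(2 * stats.t.sf(np.abs(tstat), df=n_eff - 2),
                         index=keep, columns=keep)
    np.fill_diagonal(pvals.values, 0.0)

    dist = 1.0 - np.abs(r)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    link = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    labels = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    clusters = {}
    for cid in np.unique(labels):
        members = [keep[i] for i in np.flatnonzero(labels == cid)]
        if len(members) > 1:
            clusters[int(cid)] = members
    return rbar, pvals, clusters, dropped
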