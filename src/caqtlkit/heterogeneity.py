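"""Cross-cell-type caQTL heterogeneity, effect sharing and pi1 statistics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NormalizedCountMatrix",
    "vst_normalize",
    "interaction_test",
    "nested_f_test",
    "effect_correlation",
    "pi1_sharing",
]


@dataclass
class NormalizedCountMatrix:
    """Variance-stabilized accessibility, peaks x (sample, cell type) columns."""

    values: np.ndarray  # (n_peaks, n_columns)
    peak_ids: list[str]
    samples: list[str]  # per column
    cell_types: list[str]  # per column
    size_factors: np.ndarray
    meta: pd.DataFrame | None = None  # optional per-column age/sex etc.


def vst_normalize(
    totals_by_celltype: dict[str, np.ndarray],
    peak_ids: list[str],
    sample_ids: list[str],
    meta: pd.DataFrame | None = None,
) -> NormalizedCountMatrix:
    """Median-of-ratios size factors followed by log2(count/sf + 1).

    Columns are all (sample, cell type) combinations. Columns with no
    overlap with the geometric-mean reference fall back to a total-count
    ratio.
    """
    mats = [np.asarray(totals_by_celltype[ct], dtype=float).T for ct in totals_by_celltype]
    counts = np.concatenate(mats, axis=1)  # peaks x columns
    if counts.size == 0 or counts.sum() == 0:
        raise ValueError("all-zero count matrix cannot be normalized")
    samples, cts = [], []
    for ct in totals_by_celltype:
        samples.extend(sample_ids)
        cts.extend([ct] * len(sample_ids))

    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    ref_ok = np.isfinite(logc).all(axis=1)
    sf = np.empty(counts.shape[1])
    if ref_ok.any():
        log_geo = logc[ref_ok].mean(axis=1)
        ratios = counts[ref_ok] / np.exp(log_geo)[:, None]
        sf = np.median(ratios, axis=0)
    else:
        sf[:] = 0.0
    bad = ~np.isfinite(sf) | (sf <= 0)
    if bad.any():
        tot = counts.sum(axis=0)
        sf[bad] = tot[bad] / max(tot.mean(), 1e-12)
    values = np.log2(counts / sf[None, :] + 1.0)
    return NormalizedCountMatrix(
        values=values, peak_ids=list(peak_ids), samples=samples,
        cell_types=cts, size_factors=sf, meta=meta,
    )


def nested_f_test(y: np.ndarray, X_full: np.ndarray, X_reduced: np.ndarray):
    """F statistic and p-value comparing nested least-squares models."""
    def rss_rank(X):
        beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid), rank

    rss_f, rank_f = rss_rank(X_full)
    rss_r, rank_r = rss_rank(X_reduced)
    df_num = rank_f - rank_r
    df_den = len(y) - rank_f
    if df_num <= 0 or df_den <= 0:
        return np.nan, np.nan
    f = ((rss_r - rss_f) / df_num) / (rss_f / df_den)
    f = max(f, 0.0)
    return f, float(stats.f.sf(f, df_num, df_den))


def interaction_test(
    norm: NormalizedCountMatrix,
    dosage_by_sample: dict[str, np.ndarray],
    pairs: pd.DataFrame,  # columns peak_id, variant_id
    covariates: np.ndarray | None = None,
    fdr: float = 0.10,
) -> pd.DataFrame:
    """ANOVA of genotype x cell-type interaction per caQTL lead pair.

    Full model: value ~ genotype + celltype + genotype:celltype + covariates;
    reduced drops the interaction. ``dosage_by_sample`` maps variant id to a
    per-sample dosage vector aligned with the sample ids used by ``norm``.
    """
    sample_index = {s: i for i, s in enumerate(dict.fromkeys(norm.samples))}
    ct_index = {c: i for i, c in enumerate(dict.fromkeys(norm.cell_types))}
    if len(ct_index) < 2:
        raise ValueError("interaction test needs >= 2 cell types")
    peak_row = {p: i for i, p in enumerate(norm.peak_ids)}

    n_col = norm.values.shape[1]
    ct_dummies = np.zeros((n_col, len(ct_index) - 1))
    for j, ct in enumerate(norm.cell_types):
        k = ct_index[ct]
        if k > 0:
            ct_dummies[j, k - 1] = 1.0
    samp_of_col = np.array([sample_index[s] for s in norm.samples])

    rows = []
    for pr in pairs.itertuples():
        if pr.peak_id not in peak_row or pr.variant_id not in dosage_by_sample:
            continue
        y = norm.values[peak_row[pr.peak_id]]
        geno = np.asarray(dosage_by_sample[pr.variant_id], dtype=float)[samp_of_col]
        inter = geno[:, None] * ct_dummies
        base = [np.ones(n_col), geno[:, None], ct_dummies]
        if covariates is not None:
            base.append(np.asarray(covariates, dtype=float))
        X_red = np.column_stack([np.atleast_2d(b.T).T if b.ndim == 1 else b for b in base])
        X_full = np.column_stack([X_red, inter])
        if np.linalg.matrix_rank(X_full) >= len(y):
            warnings.warn(f"rank-deficient design for {pr.peak_id}/{pr.variant_id}; skipped")
            continue
        f, p = nested_f_test(y, X_full, X_red)
        if np.isnan(f):
            warnings.warn(f"degenerate design for {pr.peak_id}/{pr.variant_id}; skipped")
            continue
        rows.append({"peak_id": pr.peak_id, "variant_id": pr.variant_id,
                     "f_stat": f, "p_value": p})
    out = pd.DataFrame(rows, columns=["peak_id", "variant_id", "f_stat", "p_value"])
    if len(out):
        from caqtlkit.caqtl import bh_qvalues

        out["fdr"] = bh_qvalues(out["p_value"].to_numpy())
        out["heterogeneous"] = out["fdr"] < fdr
    return out


def effect_correlation(
    results_by_celltype: dict[str, pd.DataFrame], min_shared: int = 3
) -> pd.DataFrame:
    """Pairwise Spearman correlation of allelic effects (pi) across cell types.

    Per pair, restricted to peak-variant pairs significant in at least one of
    the two cell types; fewer than ``min_shared`` shared pairs -> NaN.
    """
    cts = list(results_by_celltype)
    mat = pd.DataFrame(np.eye(len(cts)), index=cts, columns=cts)
    indexed = {
        ct: df.set_index(["peak_id", "variant_id"])
        for ct, df in results_by_celltype.items()
    }
    for i, a in enumerate(cts):
        for b in cts[i + 1:]:
            da, db = indexed[a], indexed[b]
            shared = da.index.intersection(db.index)
            sig = (
                da.loc[shared, "significant"].to_numpy(dtype=bool)
                | db.loc[shared, "significant"].to_numpy(dtype=bool)
            )
            shared = shared[sig]
            if len(shared) < min_shared:
                r = np.nan
            else:
                r = stats.spearmanr(
                    da.loc[shared, "pi_hat"], db.loc[shared, "pi_hat"]
                ).statistic
            mat.loc[a, b] = mat.loc[b, a] = r
    return mat


def pi1_sharing(
    pvals: np.ndarray,
    n_boot: int = 100,
    lambdas: np.ndarray | None = None,
    seed: int = 0,
) -> float:
    """Storey bootstrap estimate of pi1 = 1 - pi0 from replication p-values.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over a lambda grid;
    the bootstrap picks the lambda minimizing estimated MSE against the
    10th percentile of the plug-in pi0(lambda) curve (Storey's "bootstrap"
    method; the quantile rather than the minimum tempers the bias from
    high-lambda variance).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("pi1_sharing needs at least one p-value")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = p.size
    pi0_l = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
    min_pi0 = np.quantile(pi0_l, 0.1)
    rng = np.random.default_rng(seed)
    mse = np.zeros(len(lambdas))
    for _ in range(n_boot):
        pb = rng.choice(p, size=m, replace=True)
        pi0_b = np.array([(pb > lam).sum() / (m * (1 - lam)) for lam in lambdas])
        mse += (pi0_b - min_pi0) ** 2
    pi0 = pi0_l[int(np.argmin(mse))]
    return float(np.clip(1.0 - pi0, 0.0, 1.0))
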