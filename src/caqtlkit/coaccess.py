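"""Single-cell co-accessibility: cell aggregation, distance-penalized
sparse partial correlations, link filtering, promoter annotation, and
caQTL-to-promoter effect propagation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "CoaccessLink",
    "PromoterAnnotation",
    "aggregate_cells",
    "coaccessibility_scores",
    "filter_links",
    "annotate_promoters",
    "link_caqtls_to_promoters",
    "promoter_effect_test",
    "interaction_overlap_enrichment",
    "graphical_lasso_matrix_penalty",
]


@dataclass
class CoaccessLink:
    peak_a: str
    peak_b: str
    score: float
    distance: int
    n_samples_replicated: int
    link_class: str  # distal-promoter | promoter-promoter | distal-distal


@dataclass
class PromoterAnnotation:
    """peak id -> promoter/distal label with associated TSS gene ids."""

    labels: dict[str, str]
    genes: dict[str, list[str]]

    def is_promoter(self, peak_id: str) -> bool:
        return self.labels.get(peak_id) == "promoter"


def aggregate_cells(
    matrix: np.ndarray,
    embedding: np.ndarray,
    k: int = 30,
    seed: int = 0,
    max_overlap: float = 0.8,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Sum cells into bins of k nearest neighbors in the embedding.

    Seed cells are visited in a seeded random order; a seed is rejected if
    its k-neighborhood shares more than ``max_overlap`` of its members with
    an already-accepted bin. Returns (bin x peak matrix, member indices).
    """
    n_cells = matrix.shape[0]
    if k > n_cells:
        raise ValueError(f"k={k} exceeds number of cells ({n_cells})")
    if n_cells == 0:
        return np.zeros((0, matrix.shape[1])), []
    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_cells)
    bins, members = [], []
    accepted: list[set] = []
    for seed_cell in order:
        mem = set(idx[seed_cell])
        if any(len(mem & prev) > max_overlap * k for prev in accepted):
            continue
        accepted.append(mem)
        members.append(idx[seed_cell])
        bins.append(matrix[idx[seed_cell]].sum(axis=0))
    return np.asarray(bins, dtype=float), members


def _glasso_core(S, penalty, max_iter, tol):  # pragma: no cover - numba twin below
    p = S.shape[0]
    W = S.copy() + 1e-8 * np.eye(p)
    betas = np.zeros((p, p))
    for _ in range(max_iter):
        max_change = 0.0
        for j in range(p):
            idx = np.empty(p - 1, dtype=np.int64)
            k = 0
            for i in range(p):
                if i != j:
                    idx[k] = i
                    k += 1
            W11 = W[idx][:, idx].copy()
            s12 = S[idx, j].copy()
            rho = penalty[idx, j].copy()
            beta = betas[idx, j].copy()
            for _inner in range(100):
                delta = 0.0
                for i in range(p - 1):
                    r = s12[i] - W11[i] @ beta + W11[i, i] * beta[i]
                    new = np.sign(r) * max(abs(r) - rho[i], 0.0) / W11[i, i]
                    delta = max(delta, abs(new - beta[i]))
                    beta[i] = new
                if delta < tol * 0.1:
                    break
            w12 = W11 @ beta
            for k2 in range(p - 1):
                change = abs(W[idx[k2], j] - w12[k2])
                max_change = max(max_change, change)
                W[idx[k2], j] = w12[k2]
                W[j, idx[k2]] = w12[k2]
                betas[idx[k2], j] = beta[k2]
        if max_change < tol:
            break
    theta = np.zeros((p, p))
    for j in range(p):
        denom = W[j, j]
        for k2 in range(p):
            if k2 != j:
                denom -= W[k2, j] * betas[k2, j]
        theta[j, j] = 1.0 / denom
        for k2 in range(p):
            if k2 != j:
                theta[k2, j] = -betas[k2, j] * theta[j, j]
    return (theta + theta.T) / 2.0


try:  # JIT-compile the block coordinate descent when numba is available
    from numba import njit

    _glasso_jit = njit(cache=True)(_glasso_core)
except Exception:  # pragma: no cover
    _glasso_jit = _glasso_core


def graphical_lasso_matrix_penalty(
    S: np.ndarray,
    penalty: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> np.ndarray:
    """L1-penalized inverse covariance with an entry-wise penalty matrix.

    Block coordinate descent (Friedman et al.); ``penalty`` is symmetric
    with zero diagonal. Returns the precision matrix. With penalty -> 0
    this converges to inv(S).
    """
    S = np.ascontiguousarray(S, dtype=np.float64)
    penalty = np.ascontiguousarray(penalty, dtype=np.float64)
    return _glasso_jit(S, penalty, max_iter, tol)


def _partial_correlations(theta: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(theta))
    rho = -theta / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return rho


def coaccessibility_scores(
    bins: np.ndarray,
    peaks: pd.DataFrame,  # chrom, start, end, peak_id; sorted by coordinate
    window_bp: int = 1_000_000,
    penalty: float = 8.0,
    stride_bp: int | None = None,
) -> pd.DataFrame:
    """Distance-penalized partial correlations between peaks.

    Bin counts are standardized per peak within each overlapping genomic
    window (span ``window_bp``, stride half of it); the precision matrix is
    estimated with an L1 penalty scaled by pair distance,
    penalty * d_ij / window_bp. A pair's score is the mean partial
    correlation over windows containing both peaks.
    """
    stride = stride_bp or window_bp // 2
    mids = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    peak_ids = peaks["peak_id"].to_numpy()
    chroms = peaks["chrom"].to_numpy()

    acc: dict[tuple[str, str], list[float]] = {}
    for ch in pd.unique(chroms):
        on = np.flatnonzero(chroms == ch)
        if on.size < 2:
            continue
        lo, hi = mids[on].min(), mids[on].max()
        w0 = lo - (lo % stride)
        starts = np.arange(w0 - stride, hi + 1, stride)
        for ws in starts:
            sel = on[(mids[on] >= ws) & (mids[on] < ws + window_bp)]
            if sel.size < 2:
                continue
            X = bins[:, sel]
            sd = X.std(axis=0)
            keep = sd > 0
            sel = sel[keep]
            if sel.size < 2:
                continue
            Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
            S = Z.T @ Z / max(len(Z) - 1, 1)
            d = np.abs(mids[sel][:, None] - mids[sel][None, :])
            P = penalty * d / window_bp
            np.fill_diagonal(P, 0.0)
            theta = graphical_lasso_matrix_penalty(S, P)
            rho = _partial_correlations(theta)
            for i in range(sel.size):
                for j in range(i + 1, sel.size):
                    key = (peak_ids[sel[i]], peak_ids[sel[j]])
                    acc.setdefault(key, []).append(rho[i, j])
    rows = [
        {"peak_a": a, "peak_b": b, "score": float(np.mean(v))}
        for (a, b), v in acc.items()
    ]
    return pd.DataFrame(rows, columns=["peak_a", "peak_b", "score"])


def _pair_distance(peaks: pd.DataFrame) -> dict[str, int]:
    mids = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    return dict(zip(peaks["peak_id"], mids))


def filter_links(
    scores: pd.DataFrame,
    peaks: pd.DataFrame,
    per_sample_scores: dict[str, pd.DataFrame] | None = None,
    threshold: float = 0.05,
    min_distance: int = 10_000,
    min_replication: int = 4,
    annotation: "PromoterAnnotation | None" = None,
) -> pd.DataFrame:
    """Apply the co-accessibility gates.

    Keeps pairs with pooled score > threshold, midpoint distance >
    min_distance, and per-sample score > threshold in >= min_replication
    samples (skipped when no per-sample scores are given).
    """
    mid = _pair_distance(peaks)
    rep_count: dict[tuple[str, str], int] = {}
    if per_sample_scores:
        for df in per_sample_scores.values():
            ok = df[df["score"] > threshold]
            for row in ok.itertuples():
                key = (row.peak_a, row.peak_b)
                rep_count[key] = rep_count.get(key, 0) + 1

    rows = []
    for row in scores.itertuples():
        if row.score <= threshold:
            continue
        dist = abs(mid[row.peak_a] - mid[row.peak_b])
        if dist <= min_distance:
            continue
        n_rep = rep_count.get((row.peak_a, row.peak_b), 0)
        if per_sample_scores is not None and n_rep < min_replication:
            continue
        if annotation is not None:
            pa = annotation.is_promoter(row.peak_a)
            pb = annotation.is_promoter(row.peak_b)
            cls = ("promoter-promoter" if pa and pb
                   else "distal-distal" if not pa and not pb
                   else "distal-promoter")
        else:
            cls = "unknown"
        rows.append(
            {"peak_a": row.peak_a, "peak_b": row.peak_b, "score": row.score,
             "distance": int(dist), "n_samples_replicated": n_rep,
             "link_class": cls}
        )
    return pd.DataFrame(
        rows, columns=["peak_a", "peak_b", "score", "distance",
                       "n_samples_replicated", "link_class"],
    )


def annotate_promoters(
    peaks: pd.DataFrame, tss: pd.DataFrame, window: int = 2_000
) -> PromoterAnnotation:
    """Label peaks promoter/distal by TSS proximity.

    A peak is a promoter iff its interval intersects [tss - window,
    tss + window); peaks hitting several genes' windows carry all gene ids.
    """
    for df, nm in ((peaks, "peaks"), (tss, "tss")):
        if (df["start"] >= df["end"]).any():
            raise ValueError(f"malformed intervals in {nm}: start >= end")
    labels, genes = {}, {}
    for pk in peaks.itertuples():
        hits = tss[
            (tss["chrom"] == pk.chrom)
            & (tss["start"] - window < pk.end)
            & (tss["start"] + window > pk.start)
        ]
        if len(hits):
            labels[pk.peak_id] = "promoter"
            genes[pk.peak_id] = list(hits["gene"])
        else:
            labels[pk.peak_id] = "distal"
            genes[pk.peak_id] = []
    return PromoterAnnotation(labels=labels, genes=genes)


def link_caqtls_to_promoters(
    caqtl_peaks: list[str],
    links: pd.DataFrame,
    annotation: PromoterAnnotation,
) -> pd.DataFrame:
    """Classify each caQTL peak by its promoter linkage.

    Classes: promoter-direct (caQTL inside a promoter peak),
    distal-linked (distal peak co-accessible with >= 1 promoter),
    promoter-promoter-linked, or unlinked.
    """
    partner: dict[str, list[str]] = {}
    for row in links.itertuples():
        partner.setdefault(row.peak_a, []).append(row.peak_b)
        partner.setdefault(row.peak_b, []).append(row.peak_a)
    rows = []
    for pk in caqtl_peaks:
        prom_partners = [q for q in partner.get(pk, []) if annotation.is_promoter(q)]
        genes = sorted({g for q in prom_partners for g in annotation.genes.get(q, [])})
        if annotation.is_promoter(pk):
            cls = "promoter-promoter-linked" if prom_partners else "promoter-direct"
        else:
            cls = "distal-linked" if prom_partners else "unlinked"
        rows.append(
            {"peak_id": pk, "link_class": cls,
             "n_linked_promoters": len(prom_partners),
             "linked_genes": ",".join(genes)}
        )
    return pd.DataFrame(rows)


def promoter_effect_test(
    caqtl_leads: pd.DataFrame,  # peak_id, variant_id, variant_idx, pi_hat
    links: pd.DataFrame,
    annotation: PromoterAnnotation,
    tensor,
    genotypes,
    cell_type: str,
    fdr: float = 0.20,
    n_permutations: int = 2,
    min_distance: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Test caQTL lead variants against linked promoter peak accessibility.

    Uses the population-only model (the lead generally sits outside the
    promoter peak). Significance via permutation empirical FDR at ``fdr``;
    the effect correlation is Pearson r between pi on the caQTL peak and pi
    on the best-associated linked promoter at > ``min_distance``.
    """
    from caqtlkit.caqtl import bh_qvalues, empirical_fdr, fit_population_only

    totals = tensor.totals[cell_type]
    offsets = tensor.offsets[cell_type]
    peak_col = {pid: i for i, pid in enumerate(tensor.peaks["peak_id"])}
    mid = _pair_distance(tensor.peaks)
    partner: dict[str, list[str]] = {}
    for row in links.itertuples():
        partner.setdefault(row.peak_a, []).append(row.peak_b)
        partner.setdefault(row.peak_b, []).append(row.peak_a)

    tests = []
    for lead in caqtl_leads.itertuples():
        proms = [q for q in partner.get(lead.peak_id, []) if annotation.is_promoter(q)]
        for q in proms:
            if q not in peak_col:
                continue
            tests.append((lead, q))
    if not tests:
        return pd.DataFrame(), {"pearson_r": np.nan, "n_pairs": 0}

    def run(dosage_mat):
        out = []
        for lead, q in tests:
            res = fit_population_only(
                totals[:, peak_col[q]], dosage_mat[:, lead.variant_idx], offsets,
                peak_id=q, variant_id=lead.variant_id,
            )
            out.append(res)
        return out

    real = run(genotypes.dosage)
    q_real = bh_qvalues(np.array([r.lrt_p for r in real]))
    rng = np.random.default_rng(seed)
    perm_q = []
    for _ in range(n_permutations):
        perm = rng.permutation(genotypes.dosage.shape[0])
        pr = run(genotypes.dosage[perm])
        perm_q.append(bh_qvalues(np.array([r.lrt_p for r in pr])))
    threshold, sig = empirical_fdr(q_real, perm_q, alpha=fdr)

    rows = []
    for (lead, prom), res, qv, s in zip(tests, real, q_real, sig):
        rows.append(
            {"caqtl_peak": lead.peak_id, "variant_id": lead.variant_id,
             "promoter_peak": prom, "pi_caqtl": lead.pi_hat,
             "pi_promoter": res.pi_hat, "p_value": res.lrt_p, "q": qv,
             "significant": bool(s),
             "distance": int(abs(mid[lead.peak_id] - mid[prom]))}
        )
    table = pd.DataFrame(rows)

    # best-associated promoter per caQTL, distance-gated
    far = table[table["distance"] > min_distance]
    best = far.loc[far.groupby("caqtl_peak")["p_value"].idxmin()] if len(far) else far
    info: dict = {"threshold": threshold, "n_pairs": len(table)}
    if len(best) >= 3 and best["pi_caqtl"].std() > 1e-12 and best["pi_promoter"].std() > 1e-12:
        info["pearson_r"] = float(stats.pearsonr(best["pi_caqtl"], best["pi_promoter"]).statistic)
    else:
        import warnings

        warnings.warn("effect correlation not estimable (too few pairs or zero variance)")
        info["pearson_r"] = np.nan
    bins = [(10_000, 50_000), (50_000, 100_000), (100_000, 200_000),
            (200_000, 350_000), (350_000, 1_000_000)]
    by_bin = {}
    for lo, hi in bins:
        sub = best[(best["distance"] > lo) & (best["distance"] <= hi)] if len(best) else best
        if len(sub) >= 3 and sub["pi_caqtl"].std() > 1e-12 and sub["pi_promoter"].std() > 1e-12:
            by_bin[f"{lo//1000}-{hi//1000}kb"] = float(
                stats.pearsonr(sub["pi_caqtl"], sub["pi_promoter"]).statistic
            )
        else:
            by_bin[f"{lo//1000}-{hi//1000}kb"] = np.nan
    info["pearson_r_by_distance"] = by_bin
    return table, info


def _anchors_match(s1, e1, s2, e2, max_gap):
    return s1 < e2 + max_gap and s2 < e1 + max_gap


def interaction_overlap_enrichment(
    candidate_pairs: pd.DataFrame,  # peak_a, peak_b, called (bool)
    peaks: pd.DataFrame,
    loops: pd.DataFrame,  # chrom_a, start_a, end_a, chrom_b, start_b, end_b
    max_gap: int = 1_000,
) -> dict:
    """Fisher enrichment of called links among loop-supported candidate pairs.

    Candidates must already be restricted to pairs with >= 1 anchor near a
    bait; a pair is loop-supported when both peaks match the two loop
    anchors within ``max_gap``. Zero-cell tables use Haldane correction.
    """
    if len(candidate_pairs) == 0:
        return {"evaluable": False, "odds_ratio": np.nan, "p_value": np.nan}
    coords = peaks.set_index("peak_id")

    def supported(pa: str, pb: str) -> bool:
        a, b = coords.loc[pa], coords.loc[pb]
        for lp in loops.itertuples():
            fwd = (
                a["chrom"] == lp.chrom_a and b["chrom"] == lp.chrom_b
                and _anchors_match(a["start"], a["end"], lp.start_a, lp.end_a, max_gap)
                and _anchors_match(b["start"], b["end"], lp.start_b, lp.end_b, max_gap)
            )
            rev = (
                a["chrom"] == lp.chrom_b and b["chrom"] == lp.chrom_a
                and _anchors_match(a["start"], a["end"], lp.start_b, lp.end_b, max_gap)
                and _anchors_match(b["start"], b["end"], lp.start_a, lp.end_a, max_gap)
            )
            if fwd or rev:
                return True
        return False

    sup = np.array([supported(r.peak_a, r.peak_b) for r in candidate_pairs.itertuples()])
    called = candidate_pairs["called"].to_numpy(dtype=bool)
    table = np.array([
        [int((called & sup).sum()), int((called & ~sup).sum())],
        [int((~called & sup).sum()), int((~called & ~sup).sum())],
    ])
    _, p = stats.fisher_exact(table, alternative="greater")
    if (table == 0).any():
        t = table + 0.5  # Haldane-Anscombe
        odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
        capped = True
    else:
        odds = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
        capped = False
    return {"evaluable": True, "odds_ratio": float(odds), "p_value": float(p),
            "table": table, "haldane_corrected": capped}
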