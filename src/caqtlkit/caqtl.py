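"""Joint population + allelic caQTL mapping.

For one peak-variant pair the model couples a negative-binomial likelihood
on total fragment counts with a beta-binomial likelihood on allele-specific
read counts at heterozygous samples, both driven by a single cis allelic
effect pi:

    total_j  ~ NB(mean = s_j * lam * exp(c_j @ gamma) * [(2-g_j)(1-pi) + g_j*pi],
                  dispersion phi)
    alt_j    ~ BB(depth_j, mean = p', overdispersion theta)   [g_j = 1 only]
    p  = pi(1-psi) / (pi(1-psi) + (1-pi)psi)
    p' = p(1-2*delta) + delta

psi is the reference-mapping bias (0.5 = none) and delta the allele-flip
error rate. Significance is a 1-df likelihood-ratio test of pi = 0.5;
genome-wide control uses q-values compared against genotype-permuted reruns
(empirical FDR).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import digamma, gammaln

from caqtlkit.types import CohortGenotypes, PeakCountTensor

__all__ = [
    "CaQtlResult",
    "filter_testable",
    "fit_joint_model",
    "fit_population_only",
    "adjust_within_peak",
    "bh_qvalues",
    "empirical_fdr",
    "qc_filter",
    "genotype_class_diagnostics",
    "map_caqtl",
]

_EPS = 1e-3
_BOUNDS = {
    "pi": (_EPS, 1.0 - _EPS),
    "psi": (_EPS, 1.0 - _EPS),
    "delta": (0.0, 0.45),
    "loglam": (-12.0, 20.0),
    "logphi": (-8.0, 6.0),
    "logtheta": (-8.0, 6.0),
}


@dataclass
class CaQtlResult:
    """Fitted association for one peak-variant pair."""

    peak_id: str
    variant_id: str
    position: int
    pi_hat: float
    psi_hat: float
    delta_hat: float
    lambda_hat: float
    phi_hat: float
    theta_hat: float
    loglik: float
    loglik_null: float
    lrt_p: float
    n_het: int
    n_classes: int
    converged: bool
    adj_p: float = np.nan
    q: float = np.nan
    lead: bool = False
    qc_pass: bool = True
    significant: bool = False


def _layout(has_bb: bool, fit_pi: bool, n_cov: int) -> list[str]:
    names = ["pi"] if fit_pi else []
    if has_bb:
        names += ["psi", "delta"]
    names += ["loglam", "logphi"]
    if has_bb:
        names += ["logtheta"]
    names += [f"gamma{k}" for k in range(n_cov)]
    return names


def _nll_grad(vals: dict, y, logs, g, C, a, r, has_bb, psi_prior=0.0):
    """Negative joint log-likelihood and gradient w.r.t. every parameter.

    Constant terms that do not depend on parameters (binomial coefficients,
    gammaln(y+1)) are kept for the NB so absolute log-likelihoods are
    comparable with external evaluations; BB drops log C(d, a).

    ``psi_prior`` > 1 adds a symmetric Beta(c, c) log-prior on the
    reference-bias psi. Without it psi is unidentifiable from a single
    variant's allelic counts under the null (it absorbs any imbalance), and
    the allelic component would contribute no association power.
    """
    pi = vals["pi"]
    loglam, logphi = vals["loglam"], vals["logphi"]
    gamma = vals.get("gamma")
    n = y.shape[0]

    m = (2.0 - g) * (1.0 - pi) + g * pi
    eta = logs + loglam
    if gamma is not None and gamma.size:
        eta = eta + C @ gamma
    ebase = np.exp(eta)
    mu = ebase * m
    alpha = float(np.exp(-logphi))

    am = alpha + mu
    log_am = np.log(am)
    y_am = (y + alpha) / am
    ll = (
        (gammaln(y + alpha) - gammaln(y + 1)).sum()
        - n * gammaln(alpha)
        + alpha * (n * np.log(alpha) - log_am.sum())
        + (y * (np.log(mu) - log_am)).sum()
    )
    t1 = y / mu - y_am  # d ll / d mu
    t1mu = t1 * mu
    grad = {
        "pi": float((t1 * ebase * (2.0 * g - 2.0)).sum()),
        "loglam": float(t1mu.sum()),
    }
    dl_da = (
        digamma(y + alpha).sum() - n * digamma(alpha)
        + n * np.log(alpha) - log_am.sum() + n - y_am.sum()
    )
    grad["logphi"] = float(dl_da * (-alpha))
    if gamma is not None and gamma.size:
        grad["gamma"] = t1mu @ C

    if has_bb:
        psi, delta = vals["psi"], vals["delta"]
        theta = float(np.exp(vals["logtheta"]))
        qq = 1.0 - psi
        D = pi * qq + (1.0 - pi) * psi
        p = pi * qq / D
        pp = p * (1.0 - 2.0 * delta) + delta
        A = pp / theta
        B = (1.0 - pp) / theta
        d = a + r
        n_bb = len(a)
        dg_dAB = digamma(d + A + B)
        ll += (
            (gammaln(a + A) + gammaln(r + B) - gammaln(d + A + B)).sum()
            + n_bb * (gammaln(A + B) - gammaln(A) - gammaln(B))
        )
        gA = float(digamma(a + A).sum() - dg_dAB.sum()
                   - n_bb * (digamma(A) - digamma(A + B)))
        gB = float(digamma(r + B).sum() - dg_dAB.sum()
                   - n_bb * (digamma(B) - digamma(A + B)))
        dl_dpp = (gA - gB) / theta
        dp_dpi = qq * psi / D**2
        dp_dpsi = -pi * (1.0 - pi) / D**2
        grad["pi"] += dl_dpp * (1.0 - 2.0 * delta) * dp_dpi
        grad["psi"] = dl_dpp * (1.0 - 2.0 * delta) * dp_dpsi
        grad["delta"] = dl_dpp * (1.0 - 2.0 * p)
        grad["logtheta"] = gA * (-A) + gB * (-B)
        if psi_prior > 1.0:
            c1 = psi_prior - 1.0
            ll += c1 * (np.log(psi) + np.log(1.0 - psi))
            grad["psi"] += c1 * (1.0 / psi - 1.0 / (1.0 - psi))
    return -ll, grad


def _make_objective(y, logs, g, C, a, r, has_bb, names, fixed, psi_prior=0.0):
    # precompute slot mapping once; the closure is the optimizer hot path
    fixed_scalar = {k: v for k, v in fixed.items() if not k.startswith("gamma")}
    gamma_fixed = {int(k[5:]): v for k, v in fixed.items() if k.startswith("gamma")}
    free_scalar = [(i, nm) for i, nm in enumerate(names) if not nm.startswith("gamma")]
    free_gamma = [(i, int(nm[5:])) for i, nm in enumerate(names) if nm.startswith("gamma")]
    gamma_slots = sorted(set(gamma_fixed) | {gi for _, gi in free_gamma})
    n_free = len(names)

    def fun(x):
        vals = dict(fixed_scalar)
        for i, nm in free_scalar:
            vals[nm] = x[i]
        if gamma_slots:
            gd = dict(gamma_fixed)
            for i, gi in free_gamma:
                gd[gi] = x[i]
            vals["gamma"] = np.array([gd[k] for k in gamma_slots])
        else:
            vals["gamma"] = None
        nll, grad = _nll_grad(vals, y, logs, g, C, a, r, has_bb, psi_prior)
        gvec = np.empty(n_free)
        for i, nm in free_scalar:
            gvec[i] = -grad[nm]
        for i, gi in free_gamma:
            gvec[i] = -grad["gamma"][gamma_slots.index(gi)]
        return nll, gvec

    return fun


def _optimize(fun, x0, bounds):
    res = optimize.minimize(
        fun, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 300},
    )
    return res


def _fit(y, s, g, C, a, r, *, fit_pi, has_bb, fixed=None, pi_starts=(0.5,),
         warm=None, psi_prior=0.0):
    """Maximize the (joint or population-only) likelihood.

    Returns (loglik, estimates dict, converged).
    """
    fixed = dict(fixed or {})
    if not fit_pi:
        fixed.setdefault("pi", 0.5)
    n_cov = C.shape[1] if C is not None else 0
    names = [nm for nm in _layout(has_bb, fit_pi, n_cov) if nm not in fixed]
    logs = np.log(s)

    # moment-based starting values (fixed starting point of the contract,
    # with lam from the observed mean so the optimizer starts in range)
    lam0 = max(float(np.mean(y / s)), 1e-6)
    start = {
        "pi": 0.5, "psi": 0.5, "delta": 0.01,
        "loglam": float(np.log(lam0)), "logphi": float(np.log(0.1)),
        "logtheta": float(np.log(0.1)),
    }
    if warm:
        start.update({k: v for k, v in warm.items() if not k.startswith("pi")})
    for k in range(n_cov):
        start[f"gamma{k}"] = warm.get(f"gamma{k}", 0.0) if warm else 0.0

    fun = _make_objective(y, logs, g, C, a, r, has_bb, names, fixed, psi_prior)
    bounds = [_BOUNDS.get(nm, (-15.0, 15.0)) for nm in names]
    best = None
    starts = pi_starts if ("pi" in names) else (None,)
    for p0 in starts:
        st = dict(start)
        if p0 is not None:
            st["pi"] = float(np.clip(p0, _EPS, 1 - _EPS))
        x0 = np.array([st[nm] for nm in names])
        res = _optimize(fun, x0, bounds)
        if best is None or res.fun < best.fun:
            best = res
    vals = dict(fixed)
    for nm, v in zip(names, best.x):
        vals[nm] = float(v)
    return -float(best.fun), vals, bool(best.success)


def _moment_pi(y, s, g, a, r):
    """Quick starting value for pi from genotype-group means / allelic ratio."""
    yn = y / s
    has0, has2 = (g == 0).any(), (g == 2).any()
    if has0 and has2:
        m0, m2 = yn[g == 0].mean(), yn[g == 2].mean()
        if m0 + m2 > 0:
            return float(np.clip(m2 / (m0 + m2), 0.02, 0.98))
    if len(a):
        tot = float(np.sum(a) + np.sum(r))
        if tot > 0:
            return float(np.clip(np.sum(a) / tot, 0.02, 0.98))
    return 0.5


def fit_joint_model(
    totals: np.ndarray,
    allelic: tuple[np.ndarray, np.ndarray, np.ndarray] | None,
    dosage: np.ndarray,
    offsets: np.ndarray,
    covariates: np.ndarray | None = None,
    *,
    peak_id: str = "",
    variant_id: str = "",
    position: int = 0,
    population_only: bool = False,
    fix: dict | None = None,
    psi_prior: float = 30.0,
) -> CaQtlResult:
    """Fit the joint NB + BB model for one peak-variant pair.

    ``allelic`` is (sample_index, ref_count, alt_count) arrays; records for
    samples not heterozygous under ``dosage`` are ignored. ``fix`` pins
    named parameters (e.g. {"delta": 0.0}) during both fits. ``psi_prior``
    is the concentration of a symmetric Beta regularizer on the
    reference-bias psi (0 disables it); it keeps psi identifiable so the
    allelic counts contribute power, and is applied identically to the null
    and alternative fits.
    """
    y = np.asarray(totals, dtype=float)
    s = np.asarray(offsets, dtype=float)
    g = np.asarray(dosage, dtype=float)
    if (s <= 0).any():
        raise ValueError("offsets must be positive")
    C = np.asarray(covariates, dtype=float) if covariates is not None else None

    if allelic is not None and not population_only:
        idx, ref_c, alt_c = (np.asarray(v) for v in allelic)
        het = g[idx] == 1
        idx, ref_c, alt_c = idx[het], ref_c[het].astype(float), alt_c[het].astype(float)
    else:
        idx = np.array([], dtype=int)
        ref_c = alt_c = np.array([], dtype=float)
    has_bb = len(idx) > 0
    n_het = int((g == 1).sum())
    n_classes = int(len(np.unique(g)))

    try:
        pp = psi_prior if has_bb else 0.0
        ll0, vals0, ok0 = _fit(y, s, g, C, alt_c, ref_c, fit_pi=False,
                               has_bb=has_bb, fixed=fix, psi_prior=pp)
        pi0 = _moment_pi(y, s, g, alt_c, ref_c)
        ll1, vals1, ok1 = _fit(y, s, g, C, alt_c, ref_c, fit_pi=True,
                               has_bb=has_bb, fixed=fix, pi_starts=(pi0,),
                               warm=vals0, psi_prior=pp)
        if ll1 < ll0 - 1e-8 and abs(pi0 - 0.5) > 1e-6:
            # retry from the null start if the moment start underperformed
            ll1b, vals1b, ok1b = _fit(y, s, g, C, alt_c, ref_c, fit_pi=True,
                                      has_bb=has_bb, fixed=fix,
                                      pi_starts=(0.5,), warm=vals0, psi_prior=pp)
            if ll1b > ll1:
                ll1, vals1, ok1 = ll1b, vals1b, ok1b
        converged = ok0 and ok1
    except (FloatingPointError, ValueError):
        converged = False
        ll0 = ll1 = np.nan
        vals1 = {"pi": 0.5, "psi": 0.5, "delta": 0.0,
                 "loglam": 0.0, "logphi": 0.0, "logtheta": 0.0}

    if converged and ll1 < ll0 - 1e-6:
        # alternative must nest the null; fall back to the null optimum
        ll1 = ll0
        vals1 = dict(vals1, pi=0.5)
    lrt = max(0.0, 2.0 * (ll1 - ll0)) if converged else 0.0
    lrt_p = float(stats.chi2.sf(lrt, df=1)) if converged else 1.0

    return CaQtlResult(
        peak_id=peak_id,
        variant_id=variant_id,
        position=position,
        pi_hat=float(vals1.get("pi", 0.5)),
        psi_hat=float(vals1.get("psi", 0.5)),
        delta_hat=float(vals1.get("delta", 0.0)),
        lambda_hat=float(np.exp(vals1.get("loglam", 0.0))),
        phi_hat=float(np.exp(vals1.get("logphi", 0.0))),
        theta_hat=float(np.exp(vals1.get("logtheta", np.log(0.1)))) if has_bb else np.nan,
        loglik=float(ll1),
        loglik_null=float(ll0),
        lrt_p=lrt_p,
        n_het=n_het,
        n_classes=n_classes,
        converged=converged,
        qc_pass=converged,
    )


def fit_population_only(totals, dosage, offsets, covariates=None, **kw) -> CaQtlResult:
    """Joint model with the beta-binomial (allelic) component dropped."""
    return fit_joint_model(totals, None, dosage, offsets, covariates,
                           population_only=True, **kw)


def filter_testable(
    tensor: PeakCountTensor,
    genotypes: CohortGenotypes,
    cell_type: str,
    window_bp: int = 10_000,
    min_mean: float = 5.0,
    min_het: int = 2,
) -> pd.DataFrame:
    """Peak-variant pairs eligible for testing.

    Keeps pairs where the peak's mean count exceeds ``min_mean``, the
    variant lies inside the peak itself or inside another peak overlapping
    peak +/- ``window_bp``, and >= ``min_het`` samples are heterozygous.
    """
    peaks = tensor.peaks.reset_index(drop=True)
    if cell_type not in tensor.totals or len(peaks) == 0:
        return pd.DataFrame(columns=["peak_id", "variant_id", "position"])
    mean_depth = tensor.totals[cell_type].mean(axis=0)
    het = (genotypes.dosage == 1).sum(axis=0)
    pos0 = genotypes.positions - 1  # to 0-based

    # containing peak per variant
    var_peak = np.full(genotypes.n_variants, -1)
    for k in range(len(peaks)):
        inside = (
            (genotypes.chrom == peaks["chrom"].iloc[k])
            & (pos0 >= peaks["start"].iloc[k])
            & (pos0 < peaks["end"].iloc[k])
        )
        var_peak[inside & (var_peak < 0)] = k

    rows = []
    for k in range(len(peaks)):
        if mean_depth[k] <= min_mean:
            continue
        lo = peaks["start"].iloc[k] - window_bp
        hi = peaks["end"].iloc[k] + window_bp
        near = [
            j for j in range(len(peaks))
            if peaks["chrom"].iloc[j] == peaks["chrom"].iloc[k]
            and peaks["start"].iloc[j] < hi and peaks["end"].iloc[j] > lo
        ]
        ok_peak = np.isin(var_peak, near) & (var_peak >= 0)
        cand = np.flatnonzero(ok_peak & (het >= min_het)
                              & (genotypes.chrom == peaks["chrom"].iloc[k]))
        for v in cand:
            rows.append((peaks["peak_id"].iloc[k], genotypes.variant_ids[v],
                         int(genotypes.positions[v]), int(v)))
    return pd.DataFrame(rows, columns=["peak_id", "variant_id", "position", "variant_idx"])


def adjust_within_peak(results: list[CaQtlResult], m_eff: int | None = None) -> list[CaQtlResult]:
    """Bonferroni-adjust p-values within one peak and flag the lead variant.

    ``m_eff`` overrides the default count of tested variants. The lead is
    the minimum adjusted p, ties broken by smaller raw p then position.
    """
    if not results:
        raise ValueError("adjust_within_peak needs >= 1 result")
    m = m_eff if m_eff is not None else len(results)
    out = [replace(r, adj_p=min(1.0, r.lrt_p * m), lead=False) for r in results]
    lead = min(range(len(out)),
               key=lambda i: (out[i].adj_p, out[i].lrt_p, out[i].position))
    out[lead] = replace(out[lead], lead=True)
    return out


def effective_test_count(dosage_sub: np.ndarray, var_explained: float = 0.995) -> int:
    """Effective number of tests: PCs needed to explain 99.5% genotype variance."""
    if dosage_sub.shape[1] <= 1:
        return dosage_sub.shape[1]
    X = dosage_sub - dosage_sub.mean(axis=0)
    sd = X.std(axis=0)
    X = X[:, sd > 0] / sd[sd > 0]
    if X.shape[1] <= 1:
        return max(1, X.shape[1])
    ev = np.linalg.eigvalsh(np.cov(X, rowvar=False))[::-1]
    ev = np.maximum(ev, 0)
    frac = np.cumsum(ev) / ev.sum()
    return int(np.searchsorted(frac, var_explained) + 1)


def bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values (monotone step-up)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    q[order] = p[order] * m / (np.arange(m) + 1)
    q[order] = np.minimum.accumulate(q[order][::-1])[::-1]
    return np.minimum(q, 1.0)


def empirical_fdr(
    real_q: np.ndarray,
    permuted_q: list[np.ndarray],
    alpha: float = 0.10,
) -> tuple[float | None, np.ndarray]:
    """Empirical FDR threshold from genotype-permuted rerun q-values.

    FDR(t) = mean_k |{q in P_k : q <= t}| / max(1, |{q in R : q <= t}|);
    the threshold is the largest real q with FDR <= alpha.
    """
    if len(permuted_q) == 0:
        raise ValueError("at least one permutation is required")
    real_q = np.asarray(real_q, dtype=float)
    if real_q.size == 0:
        return None, np.zeros(0, dtype=bool)
    perms = [np.sort(np.asarray(p, dtype=float)) for p in permuted_q]
    thresholds = np.sort(np.unique(real_q))
    best = None
    sorted_real = np.sort(real_q)
    for t in thresholds:
        n_real = np.searchsorted(sorted_real, t, side="right")
        n_perm = np.mean([np.searchsorted(p, t, side="right") for p in perms])
        if n_perm / max(1, n_real) <= alpha:
            best = t
    if best is None:
        return None, np.zeros(real_q.shape, dtype=bool)
    return float(best), real_q <= best


def qc_filter(results: pd.DataFrame, psi_lo: float = 0.2, psi_hi: float = 0.8,
              delta_max: float = 0.1) -> pd.DataFrame:
    """Flag fits failing reference-bias or mapping-error QC.

    qc_pass requires psi_lo <= psi_hat <= psi_hi and delta_hat <= delta_max.
    """
    out = results.copy()
    out["qc_pass"] = (
        (out["psi_hat"] >= psi_lo)
        & (out["psi_hat"] <= psi_hi)
        & (out["delta_hat"] <= delta_max)
        & out["converged"]
    )
    return out


def genotype_class_diagnostics(leads: pd.DataFrame) -> dict:
    """Enrichment of significant caQTLs in 3-genotype vs 2-genotype variants.

    Fisher exact test on [[sig & 3-class, nonsig & 3-class],
    [sig & 2-class, nonsig & 2-class]]; 1-class variants are excluded.
    """
    df = leads[leads["n_classes"] >= 2]
    sig = df["significant"].to_numpy(dtype=bool)
    three = (df["n_classes"] == 3).to_numpy()
    table = np.array([
        [int((sig & three).sum()), int((~sig & three).sum())],
        [int((sig & ~three).sum()), int((~sig & ~three).sum())],
    ])
    if sig.sum() == 0:
        return {"table": table, "odds_ratio": np.nan, "p_value": np.nan,
                "evaluable": False}
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return {"table": table, "odds_ratio": float(odds), "p_value": float(p),
            "evaluable": True}


def _results_frame(results: list[CaQtlResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def _fit_all_pairs(pairs, tensor, genotypes, cell_type, dosage, covariates,
                   population_only, sample_perm=None):
    """Fit every pair, then Bonferroni-adjust per peak and pick leads.

    ``sample_perm`` applies a genotype permutation: sample j receives the
    genotype (and allelic record) of sample sample_perm[j], so LD and the
    allelic component are preserved while the genotype-to-total-count
    association is destroyed.
    """
    if sample_perm is not None:
        dosage = dosage[sample_perm]
        inv = np.empty(len(sample_perm), dtype=int)
        inv[sample_perm] = np.arange(len(sample_perm))
    totals = tensor.totals[cell_type]
    offsets = tensor.offsets.get(cell_type)
    if offsets is None:
        from caqtlkit.types import library_size_factors
        offsets = library_size_factors(totals)
    allelic_tab = tensor.allelic[cell_type].table if cell_type in tensor.allelic else None
    sample_pos = {sid: j for j, sid in enumerate(tensor.sample_ids)}
    peak_col = {pid: k for k, pid in enumerate(tensor.peaks["peak_id"])}

    allelic_by_var: dict[str, tuple] = {}
    if allelic_tab is not None and len(allelic_tab):
        for vid, grp in allelic_tab.groupby("variant_id"):
            idx = grp["sample"].map(sample_pos).to_numpy()
            if sample_perm is not None:
                idx = inv[idx]
            allelic_by_var[vid] = (
                idx,
                grp["ref_count"].to_numpy(),
                grp["alt_count"].to_numpy(),
            )

    by_peak: list[CaQtlResult] = []
    all_results: list[CaQtlResult] = []
    leads: list[CaQtlResult] = []
    for pid, grp in pairs.groupby("peak_id", sort=True):
        fits = []
        for row in grp.itertuples():
            al = allelic_by_var.get(row.variant_id)
            res = fit_joint_model(
                totals[:, peak_col[pid]],
                al,
                dosage[:, row.variant_idx],
                offsets,
                covariates,
                peak_id=pid,
                variant_id=row.variant_id,
                position=row.position,
                population_only=population_only,
            )
            fits.append(res)
        fits = adjust_within_peak(fits)
        all_results.extend(fits)
        leads.append(next(r for r in fits if r.lead))
    return all_results, leads


def map_caqtl(
    tensor: PeakCountTensor,
    genotypes: CohortGenotypes,
    cell_type: str,
    *,
    window_bp: int = 10_000,
    n_permutations: int = 2,
    alpha: float = 0.10,
    population_only: bool = False,
    covariates: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Full per-cell-type caQTL scan with permutation-based empirical FDR.

    Returns (results table for all tested pairs, info dict with the q-value
    threshold and per-permutation q-values). Permutations shuffle sample
    labels of the genotype matrix jointly across variants, preserving LD.
    """
    pairs = filter_testable(tensor, genotypes, cell_type, window_bp=window_bp)
    info = {"cell_type": cell_type, "alpha": alpha, "threshold": None,
            "n_pairs": len(pairs), "n_permutations": n_permutations}
    if len(pairs) == 0:
        return _results_frame([]), info

    dosage = genotypes.dosage
    all_results, leads = _fit_all_pairs(
        pairs, tensor, genotypes, cell_type, dosage, covariates, population_only
    )
    lead_q = bh_qvalues(np.array([r.adj_p for r in leads]))
    leads = [replace(r, q=q) for r, q in zip(leads, lead_q)]

    rng = np.random.default_rng(seed)
    perm_q = []
    for _ in range(n_permutations):
        perm = rng.permutation(dosage.shape[0])
        _, perm_leads = _fit_all_pairs(
            pairs, tensor, genotypes, cell_type, dosage, covariates,
            population_only, sample_perm=perm,
        )
        perm_q.append(bh_qvalues(np.array([r.adj_p for r in perm_leads])))

    threshold, sig = empirical_fdr(np.array([r.q for r in leads]), perm_q, alpha)
    leads = [replace(r, significant=bool(s)) for r, s in zip(leads, sig)]

    lead_map = {(r.peak_id, r.variant_id): r for r in leads}
    merged = []
    for r in all_results:
        lr = lead_map.get((r.peak_id, r.variant_id))
        merged.append(lr if (lr is not None and r.lead) else r)
    df = qc_filter(_results_frame(merged))
    info["threshold"] = threshold
    info["permuted_q"] = perm_q
    return df, info
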