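"""Enrichment of fine-mapped GWAS credible sets in caQTL peaks.

Annotates credible-set variants with per-cell-type caQTL status and tests
whether cumulative PPA inside caQTL peaks exceeds random draws of
equally-many background peaks (tested but non-significant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from caqtlkit.finemap import CredibleSet

__all__ = [
    "EnrichmentResult",
    "annotate_credible_variants",
    "cumulative_ppa_enrichment",
]


@dataclass
class EnrichmentResult:
    trait: str
    cell_type: str
    observed_stat: float
    null_stats: np.ndarray
    empirical_p: float
    log_or: float
    n_caqtl_peaks: int


def _variant_in_peaks(pos: np.ndarray, chrom: np.ndarray, peaks: pd.DataFrame) -> np.ndarray:
    """Peak id per variant (1-based variant positions, half-open peaks)."""
    out = np.array([None] * len(pos), dtype=object)
    p0 = np.asarray(pos) - 1
    for row in peaks.itertuples():
        hit = (chrom == row.chrom) & (p0 >= row.start) & (p0 < row.end)
        out[hit & (out == None)] = row.peak_id  # noqa: E711
    return out


def annotate_credible_variants(
    credible_sets: list[CredibleSet],
    caqtl_results: dict[str, pd.DataFrame],
    peaks: pd.DataFrame,
    summary: pd.DataFrame,  # variant_id, chrom, pos
    links_to_promoters: pd.DataFrame | None = None,  # peak_id, gene
    ppa_min: float = 0.01,
) -> pd.DataFrame:
    """Per credible variant: caQTL status per cell type, PPA, linked genes.

    A variant counts as a caQTL if it is a significant lead, or shares the
    lead's q-value, in a cell type. Returns one row per credible-set
    variant; ``filtered`` marks the PPA > ppa_min promoter-linked view.
    """
    per_ct_status = {}
    for ct, df in caqtl_results.items():
        leads = df[df["lead"] & df["significant"]]
        q_by_peak = dict(zip(leads["peak_id"], leads["q"]))
        status = set(zip(leads["peak_id"], leads["variant_id"]))
        # variants sharing the lead's q-value: same peak, same adjusted q
        for row in df.itertuples():
            qlead = q_by_peak.get(row.peak_id)
            if qlead is not None and np.isclose(row.adj_p, df[(df.peak_id == row.peak_id) & df.lead]["adj_p"].iloc[0]):
                status.add((row.peak_id, row.variant_id))
        per_ct_status[ct] = status

    gene_by_peak: dict[str, list[str]] = {}
    if links_to_promoters is not None:
        for row in links_to_promoters.itertuples():
            gene_by_peak.setdefault(row.peak_id, []).append(row.gene)

    pos_by_vid = summary.set_index("variant_id")
    rows = []
    for cs in credible_sets:
        for r in cs.table.itertuples():
            if r.variant_id not in pos_by_vid.index:
                continue
            rec = pos_by_vid.loc[r.variant_id]
            peak = _variant_in_peaks(
                np.array([rec["pos"]]), np.array([rec["chrom"]]), peaks
            )[0]
            ct_hits = [
                ct for ct, status in per_ct_status.items()
                if peak is not None and (peak, r.variant_id) in status
            ]
            genes = gene_by_peak.get(peak, []) if peak is not None else []
            rows.append(
                {
                    "signal_id": cs.signal_id,
                    "variant_id": r.variant_id,
                    "ppa": r.ppa,
                    "peak_id": peak,
                    "tested": peak is not None,
                    "caqtl_cell_types": ",".join(ct_hits),
                    "is_caqtl": bool(ct_hits),
                    "linked_genes": ",".join(genes),
                    "filtered": bool(ct_hits) and r.ppa > ppa_min and bool(genes),
                }
            )
    return pd.DataFrame(rows)


def cumulative_ppa_enrichment(
    credible_sets: list[CredibleSet],
    summary: pd.DataFrame,  # variant_id, chrom, pos
    caqtl_peaks: list[str],
    background_peaks: list[str],
    peaks: pd.DataFrame,
    n_draws: int = 1000,
    seed: int = 0,
    trait: str = "trait",
    cell_type: str = "",
) -> EnrichmentResult:
    """Cumulative credible-set PPA in caQTL peaks vs random background peaks.

    Each null draw samples ``len(caqtl_peaks)`` peaks without replacement
    from the background and recomputes the statistic;
    empirical_p = (1 + #{null >= observed}) / (n_draws + 1).
    """
    caqtl_set = set(caqtl_peaks)
    bg = [p for p in background_peaks if p not in caqtl_set]
    if len(bg) < len(caqtl_set):
        raise ValueError("background smaller than the caQTL peak set")

    pos_by_vid = summary.set_index("variant_id")
    var_peaks, var_ppa = [], []
    for cs in credible_sets:
        for r in cs.table.itertuples():
            if r.variant_id not in pos_by_vid.index:
                continue
            rec = pos_by_vid.loc[r.variant_id]
            pk = _variant_in_peaks(np.array([rec["pos"]]), np.array([rec["chrom"]]), peaks)[0]
            if pk is not None:
                var_peaks.append(pk)
                var_ppa.append(float(r.ppa))
    var_peaks = np.array(var_peaks, dtype=object)
    var_ppa = np.array(var_ppa, dtype=float)

    def stat(peak_set: set) -> float:
        if var_peaks.size == 0:
            return 0.0
        mask = np.array([p in peak_set for p in var_peaks])
        return float(var_ppa[mask].sum())

    observed = stat(caqtl_set)
    rng = np.random.default_rng(seed)
    null = np.empty(n_draws)
    bg_arr = np.array(bg, dtype=object)
    for i in range(n_draws):
        draw = rng.choice(bg_arr, size=len(caqtl_set), replace=False)
        null[i] = stat(set(draw))
    if observed == 0.0:
        emp_p = 1.0
    else:
        emp_p = (1.0 + float((null >= observed).sum())) / (n_draws + 1.0)
    mean_null = float(null.mean())
    log_or = float(np.log(observed / mean_null)) if mean_null > 0 and observed > 0 else np.nan
    return EnrichmentResult(
        trait=trait, cell_type=cell_type, observed_stat=observed,
        null_stats=null, empirical_p=emp_p, log_or=log_or,
        n_caqtl_peaks=len(caqtl_set),
    )
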