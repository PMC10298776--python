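"""Synthetic cohort generator for the caQTL pipeline.

Emits genotypes with founder-haplotype LD blocks, per-cell-type peak count
matrices with allele-specific read counts, single-cell peak matrices with a
low-dimensional embedding, and GWAS summary statistics — together with a
ground-truth ledger of every planted effect so recovery can be scored.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from caqtlkit.types import AllelicCounts, CohortGenotypes, PeakCountTensor

__all__ = [
    "SimConfig",
    "GroundTruth",
    "make_peaks",
    "simulate_genotypes",
    "make_ground_truth",
    "simulate_peak_counts",
    "simulate_single_cells",
    "simulate_gwas",
    "het_allelic_fraction",
]

_BASES = np.array(["A", "C", "G", "T"])


def het_allelic_fraction(pi: float, psi: float, delta: float) -> float:
    """Expected ALT-read fraction at a heterozygous sample.

    ``pi`` is the allelic effect (0.5 = none), ``psi`` the expected
    REF-read fraction under no effect (0.5 = unbiased), ``delta`` the
    probability that a read's allele assignment is flipped by error.
    """
    p = pi * (1.0 - psi) / (pi * (1.0 - psi) + (1.0 - pi) * psi)
    return p * (1.0 - 2.0 * delta) + delta


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    ``cell_types`` maps label -> relative abundance weight (must sum to 1).
    """

    n_samples: int = 10
    n_variants: int = 300
    n_peaks: int = 100
    ld_block_size: int = 5
    maf_range: tuple[float, float] = (0.1, 0.5)
    cell_types: dict[str, float] = field(
        default_factory=lambda: {"Tcell": 0.4, "Mono": 0.3, "Bcell": 0.2, "NK": 0.1}
    )
    mean_depth_per_peak: float = 100.0
    frac_caqtl_peaks: float = 0.2
    pi_effect_range: tuple[float, float] = (0.65, 0.85)
    psi_range: tuple[float, float] = (0.45, 0.55)
    delta_range: tuple[float, float] = (0.0, 0.02)
    nb_dispersion: float = 0.1
    bb_overdispersion: float = 0.02
    n_cells_per_sample: int = 200
    coaccess_module_size: int = 2
    n_coaccess_modules: int = 5
    gwas_n: int = 50_000
    gwas_beta: float = 0.04
    n_gwas_signals: int = 4
    peak_width: int = 400
    peak_spacing: int = 5_000
    n_chroms: int = 4
    # fraction of a peak's reads that overlap a variant and are allele-informative
    informative_fraction: float = 0.2
    promoter_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_variants", "n_peaks", "ld_block_size",
                     "n_cells_per_sample", "coaccess_module_size", "gwas_n"):
            if getattr(self, name) < 0 or (name != "n_cells_per_sample" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        lo, hi = self.pi_effect_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("pi_effect_range must lie within (0, 1)")
        lo, hi = self.delta_range
        if not (0.0 <= lo <= hi < 0.5):
            raise ValueError("delta_range must lie within [0, 0.5)")
        total = sum(self.cell_types.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("cell-type abundance weights must sum to 1")
        if self.nb_dispersion <= 0 or self.bb_overdispersion < 0:
            raise ValueError("dispersions must be positive")


@dataclass
class GroundTruth:
    """Ledger of everything the generator planted."""

    peaks: pd.DataFrame  # chrom, start, end, peak_id, lam, psi, delta
    caqtl: pd.DataFrame  # peak_id, variant_id, pi, psi, delta, cell_types
    coaccess_modules: list[list[str]]
    gwas_causals: pd.DataFrame  # signal_id, variant_id, beta
    promoter_peaks: list[str]
    tss: pd.DataFrame  # chrom, start, end, gene

    def caqtl_peak_ids(self) -> set[str]:
        return set(self.caqtl["peak_id"])


def make_peaks(config: SimConfig) -> pd.DataFrame:
    """Evenly spaced non-overlapping peak intervals (0-based half-open).

    Peaks are split into ``n_chroms`` contiguous chromosome batches with
    coordinates restarting per chromosome, so independent GWAS signals can
    live on separate chromosomes.
    """
    n_chroms = max(1, min(config.n_chroms, config.n_peaks))
    per = int(np.ceil(config.n_peaks / n_chroms))
    chroms, starts = [], []
    for i in range(config.n_peaks):
        chroms.append(f"chr{1 + i // per}")
        starts.append(1_000 + config.peak_spacing * (i % per))
    return pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": np.asarray(starts) + config.peak_width,
            "peak_id": [f"peak{i:05d}" for i in range(config.n_peaks)],
        }
    )


def _founder_subset(weights: np.ndarray, target: float, rng: np.random.Generator):
    """Non-trivial founder subset whose weight sum best matches target."""
    n = len(weights)
    best, best_err = None, np.inf
    idx = list(range(n))
    for r in range(1, n):
        for sub in itertools.combinations(idx, r):
            s = weights[list(sub)].sum()
            err = abs(s - target)
            if err < best_err - 1e-12 or (abs(err - best_err) < 1e-12 and rng.random() < 0.5):
                best, best_err = sub, err
    return list(best)


def simulate_genotypes(config: SimConfig, peaks: pd.DataFrame | None = None) -> CohortGenotypes:
    """Draw cohort genotypes organised in founder-haplotype LD blocks.

    Within a block every haplotype is a copy of one of 2–4 founder
    haplotypes (high pairwise r²); blocks are independent. Variants are
    placed inside peak intervals so the cis-window filter finds them.
    """
    if config.n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng([config.seed, 11])
    if peaks is None:
        peaks = make_peaks(config)

    n_var, n_hap = config.n_variants, 2 * config.n_samples
    # spread variants across peaks; positions unique and increasing per chrom
    peak_idx = np.arange(n_var) % len(peaks)
    peak_idx.sort()
    var_chrom = peaks["chrom"].to_numpy()[peak_idx]
    positions = np.empty(n_var, dtype=np.int64)
    n_in_peak: dict[int, int] = {}
    for i, pk in enumerate(peak_idx):
        lo = int(peaks["start"].iloc[pk])
        hi = int(peaks["end"].iloc[pk])
        k = n_in_peak.get(pk, 0)
        n_in_peak[pk] = k + 1
        positions[i] = min(lo + 1 + 3 * k, hi - 1)  # 0-based, inside the peak

    ref_idx = rng.integers(0, 4, size=n_var)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_var)) % 4

    hap = np.zeros((n_hap, n_var), dtype=np.int8)
    target_maf = np.empty(n_var)
    start = 0
    while start < n_var:
        stop = min(start + config.ld_block_size, n_var)
        # LD blocks never span chromosomes
        while stop < n_var and var_chrom[stop - 1] != var_chrom[start]:
            stop -= 1
        for v in range(start + 1, stop):
            if var_chrom[v] != var_chrom[start]:
                stop = v
                break
        n_founders = int(rng.integers(2, 5))
        w = rng.dirichlet(np.ones(n_founders))
        founder_of_hap = rng.choice(n_founders, size=n_hap, p=w)
        for v in range(start, stop):
            maf = rng.uniform(*config.maf_range)
            sub = _founder_subset(w, maf, rng)
            carrier = np.zeros(n_founders, dtype=np.int8)
            carrier[sub] = 1
            hap[:, v] = carrier[founder_of_hap]
            af = w[sub].sum()
            target_maf[v] = min(af, 1.0 - af)
        start = stop

    phase = hap.reshape(config.n_samples, 2, n_var).transpose(0, 2, 1)
    dosage = phase.sum(axis=2)
    return CohortGenotypes(
        chrom=var_chrom.astype(object),
        positions=positions + 1,
        ref=_BASES[ref_idx],
        alt=_BASES[alt_idx],
        dosage=dosage,
        variant_ids=np.array([f"var{i:05d}" for i in range(n_var)]),
        sample_ids=[f"S{j:02d}" for j in range(config.n_samples)],
        phase=phase,
        target_maf=target_maf,
    )


def variant_peak_map(genotypes: CohortGenotypes, peaks: pd.DataFrame) -> pd.Series:
    """Map variant_id -> peak_id for variants inside a peak (0-based logic)."""
    out = {}
    starts = peaks["start"].to_numpy()
    ends = peaks["end"].to_numpy()
    chroms = peaks["chrom"].to_numpy()
    pos0 = genotypes.positions - 1
    for i, vid in enumerate(genotypes.variant_ids):
        hit = (chroms == genotypes.chrom[i]) & (starts <= pos0[i]) & (pos0[i] < ends)
        j = np.flatnonzero(hit)
        if j.size:
            out[vid] = peaks["peak_id"].iloc[j[0]]
    return pd.Series(out, dtype=object)


def make_ground_truth(
    genotypes: CohortGenotypes,
    config: SimConfig,
    peaks: pd.DataFrame | None = None,
    effect_cell_types: list[str] | None = None,
) -> GroundTruth:
    """Plant caQTL effects, co-accessibility modules, promoters and GWAS causals.

    ``effect_cell_types``: cell types in which planted caQTLs act
    (default: all — fully shared effects).
    """
    rng = np.random.default_rng([config.seed, 23])
    if peaks is None:
        peaks = make_peaks(config)
    peaks = peaks.copy()

    lam = rng.gamma(shape=4.0, scale=config.mean_depth_per_peak / 4.0, size=len(peaks))
    peaks["lam"] = np.maximum(lam, 1.0)
    peaks["psi"] = rng.uniform(*config.psi_range, size=len(peaks))
    peaks["delta"] = rng.uniform(*config.delta_range, size=len(peaks))

    vp = variant_peak_map(genotypes, peaks)
    het_counts = (genotypes.dosage == 1).sum(axis=0)
    het_by_vid = dict(zip(genotypes.variant_ids, het_counts))
    # candidate causal per peak: an inside variant heterozygous in >=2 samples
    candidates: dict[str, list[str]] = {}
    for vid, pid in vp.items():
        if het_by_vid.get(vid, 0) >= 2:
            candidates.setdefault(pid, []).append(vid)

    eligible = [p for p in peaks["peak_id"] if p in candidates]
    n_caqtl = int(round(config.frac_caqtl_peaks * len(peaks)))
    n_caqtl = min(n_caqtl, len(eligible))
    chosen = list(rng.choice(eligible, size=n_caqtl, replace=False)) if n_caqtl else []

    cts = effect_cell_types if effect_cell_types is not None else list(config.cell_types)
    rows = []
    pk = peaks.set_index("peak_id")
    for pid in chosen:
        vid = candidates[pid][int(rng.integers(len(candidates[pid])))]
        pi = rng.uniform(*config.pi_effect_range)
        if rng.random() < 0.5:
            pi = 1.0 - pi
        rows.append(
            {
                "peak_id": pid,
                "variant_id": vid,
                "pi": pi,
                "psi": float(pk.loc[pid, "psi"]),
                "delta": float(pk.loc[pid, "delta"]),
                "cell_types": ",".join(cts),
            }
        )
    caqtl = pd.DataFrame(rows, columns=["peak_id", "variant_id", "pi", "psi", "delta", "cell_types"])

    # co-accessibility modules: peaks >10 kb apart but within 1 Mb
    stride = max(int(np.ceil(12_000 / config.peak_spacing)), 1)
    modules: list[list[str]] = []
    used: set[int] = set()
    cursor = 0
    for _ in range(config.n_coaccess_modules):
        members = [cursor + k * stride for k in range(config.coaccess_module_size)]
        if members[-1] >= len(peaks):
            break
        modules.append([peaks["peak_id"].iloc[m] for m in members])
        used.update(members)
        cursor = members[-1] + stride
    # promoters: a fixed fraction of peaks gets a TSS at its midpoint
    n_prom = int(round(config.promoter_fraction * len(peaks)))
    prom_idx = np.sort(rng.choice(len(peaks), size=n_prom, replace=False)) if n_prom else np.array([], int)
    promoter_peaks = [peaks["peak_id"].iloc[i] for i in prom_idx]
    mid = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    tss = pd.DataFrame(
        {
            "chrom": peaks["chrom"].iloc[prom_idx].to_numpy(),
            "start": mid[prom_idx],
            "end": mid[prom_idx] + 1,
            "gene": [f"gene{i:04d}" for i in range(len(prom_idx))],
        }
    )

    # GWAS causal variants sit inside caQTL peaks, one signal per chromosome
    peak_chrom = dict(zip(peaks["peak_id"], peaks["chrom"]))
    by_chrom: dict[str, list[str]] = {}
    for r in caqtl.itertuples():
        by_chrom.setdefault(peak_chrom[r.peak_id], []).append(r.variant_id)
    gwas_vids = []
    for ch in sorted(by_chrom):
        if len(gwas_vids) >= config.n_gwas_signals:
            break
        pool = by_chrom[ch]
        gwas_vids.append(pool[int(rng.integers(len(pool)))])
    gwas = pd.DataFrame(
        {
            "signal_id": [f"signal{i}" for i in range(len(gwas_vids))],
            "variant_id": gwas_vids,
            "beta": config.gwas_beta * np.where(rng.random(len(gwas_vids)) < 0.5, 1.0, -1.0),
        }
    )
    return GroundTruth(
        peaks=peaks,
        caqtl=caqtl,
        coaccess_modules=modules,
        gwas_causals=gwas,
        promoter_peaks=promoter_peaks,
        tss=tss,
    )


def _sample_nb(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Negative binomial with Var = mu + phi*mu^2 via Gamma-Poisson mixing."""
    if phi <= 0:
        return rng.poisson(mu)
    shape = 1.0 / phi
    rate = rng.gamma(shape, mu * phi)
    return rng.poisson(rate)


def _sample_bb(rng: np.random.Generator, d: np.ndarray, p: float, theta: float) -> np.ndarray:
    """Beta-binomial alt counts with mean p and overdispersion theta."""
    d = np.asarray(d)
    if theta <= 0:
        return rng.binomial(d, p)
    probs = rng.beta(p / theta, (1.0 - p) / theta, size=d.shape)
    return rng.binomial(d, probs)


def simulate_peak_counts(
    genotypes: CohortGenotypes,
    truth: GroundTruth,
    config: SimConfig,
) -> PeakCountTensor:
    """Draw per-cell-type totals and allelic counts under the planted model.

    Totals: NB with mean s_j * lam * [(2-g)(1-pi) + g*pi] (dispersion phi).
    Allelic counts at heterozygous samples: the allele-informative depth is
    Binomial(total, informative_fraction); ALT reads are beta-binomial with
    mean p' = p(1-2*delta) + delta, p = pi(1-psi)/(pi(1-psi)+(1-pi)psi).
    """
    if "lam" not in truth.peaks.columns or truth.peaks["lam"].isna().any():
        raise ValueError("every peak needs an assigned baseline accessibility lam")
    rng = np.random.default_rng([config.seed, 37])
    peaks = truth.peaks
    n_s, n_p = genotypes.n_samples, len(peaks)
    s = np.exp(rng.normal(0.0, 0.25, size=n_s))  # library-size factors

    causal_by_peak = dict(zip(truth.caqtl["peak_id"], truth.caqtl["variant_id"]))
    pi_by_peak = dict(zip(truth.caqtl["peak_id"], truth.caqtl["pi"]))
    cts_by_peak = {
        r.peak_id: set(r.cell_types.split(",")) for r in truth.caqtl.itertuples()
    }
    vid_col = dict(zip(genotypes.variant_ids, range(genotypes.n_variants)))
    vp = variant_peak_map(genotypes, peaks)
    variants_in_peak: dict[str, list[str]] = {}
    for vid, pid in vp.items():
        variants_in_peak.setdefault(pid, []).append(vid)

    weights = config.cell_types
    mean_w = np.mean(list(weights.values()))
    totals: dict[str, np.ndarray] = {}
    allelic: dict[str, AllelicCounts] = {}
    offsets: dict[str, np.ndarray] = {}
    phi, theta, f_inf = config.nb_dispersion, config.bb_overdispersion, config.informative_fraction

    for ct, w in weights.items():
        y = np.zeros((n_s, n_p), dtype=np.int64)
        rows = []
        scale = w / mean_w
        for k in range(n_p):
            pid = peaks["peak_id"].iloc[k]
            lam = float(peaks["lam"].iloc[k]) * scale
            psi = float(peaks["psi"].iloc[k])
            delta = float(peaks["delta"].iloc[k])
            pi_eff = 0.5
            causal = causal_by_peak.get(pid)
            if causal is not None and ct in cts_by_peak[pid]:
                pi_eff = pi_by_peak[pid]
            if causal is not None:
                g = genotypes.dosage[:, vid_col[causal]]
            else:
                g = np.ones(n_s, dtype=np.int8)  # multiplier = 1 at pi 0.5
            m = (2.0 - g) * (1.0 - pi_eff) + g * pi_eff
            if causal is None:
                m = np.ones(n_s)
            y[:, k] = _sample_nb(rng, s * lam * m, phi)
            # allelic counts at every variant inside the peak (het samples only)
            for vid in variants_in_peak.get(pid, []):
                gv = genotypes.dosage[:, vid_col[vid]]
                het = np.flatnonzero(gv == 1)
                if het.size == 0:
                    continue
                pi_here = pi_eff if vid == causal else 0.5
                p_alt = het_allelic_fraction(pi_here, psi, delta)
                d = rng.binomial(y[het, k], f_inf)
                alt = _sample_bb(rng, d, p_alt, theta)
                for jj, dd, aa in zip(het, d, alt):
                    if dd > 0:
                        rows.append(
                            (vid, genotypes.sample_ids[jj], int(dd - aa), int(aa))
                        )
        totals[ct] = y
        allelic[ct] = AllelicCounts(
            pd.DataFrame(rows, columns=["variant_id", "sample", "ref_count", "alt_count"])
        )
        offsets[ct] = s.copy()

    return PeakCountTensor(
        peaks=peaks[["chrom", "start", "end", "peak_id"]].copy(),
        sample_ids=list(genotypes.sample_ids),
        totals=totals,
        allelic=allelic,
        offsets=offsets,
    )


def simulate_single_cells(
    truth: GroundTruth, config: SimConfig
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Per-cell Poisson peak counts with module-shared latent activity.

    Returns (counts cell x peak, embedding cell x 2, labels with sample and
    cell_type columns). Peaks in a co-accessibility module share a latent
    per-cell factor, inducing positive cross-peak correlation.
    """
    peak_ids = list(truth.peaks["peak_id"])
    known = set(peak_ids)
    for mod in truth.coaccess_modules:
        unknown = [p for p in mod if p not in known]
        if unknown:
            raise ValueError(f"co-accessibility module references unknown peaks: {unknown}")
    rng = np.random.default_rng([config.seed, 53])
    n_p = len(peak_ids)
    lam = truth.peaks["lam"].to_numpy(dtype=float)
    base = lam / lam.mean() * 0.5  # mean ~0.5 fragments per peak per cell

    cells = []
    ct_names = list(config.cell_types)
    ct_w = np.array(list(config.cell_types.values()))
    for j in range(config.n_samples):
        ct_idx = rng.choice(len(ct_names), size=config.n_cells_per_sample, p=ct_w)
        for t in ct_idx:
            cells.append((f"S{j:02d}", j, ct_names[t], t))
    labels = pd.DataFrame(cells, columns=["sample", "sample_idx", "cell_type", "ct_idx"])
    n_c = len(labels)
    counts = np.zeros((n_c, n_p), dtype=np.int32)
    embedding = np.zeros((n_c, 2))
    if n_c == 0:
        return counts, embedding, labels[["sample", "cell_type"]]

    depth = np.exp(rng.normal(0.0, 0.3, size=n_c))
    rate = depth[:, None] * base[None, :]
    col_of = {p: i for i, p in enumerate(peak_ids)}
    module_factor = np.ones((n_c, n_p))
    for mod in truth.coaccess_modules:
        z = rng.gamma(1.0, 1.0, size=n_c)  # mean-1 exponential activity
        for p in mod:
            module_factor[:, col_of[p]] = z
    counts = rng.poisson(rate * module_factor).astype(np.int32)

    embedding[:, 0] = 8.0 * labels["ct_idx"].to_numpy() + rng.normal(0, 1.0, n_c)
    embedding[:, 1] = 3.0 * labels["sample_idx"].to_numpy() + rng.normal(0, 1.0, n_c)
    return counts, embedding, labels[["sample", "cell_type"]].copy()


def simulate_gwas(
    genotypes: CohortGenotypes, truth: GroundTruth, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GWAS summary statistics with planted causal variants.

    Marginal beta at variant v is r_vc * (sd_c / sd_v) * beta_c plus
    Gaussian noise with sd SE = 1/sqrt(2 N maf (1-maf)); the sd ratio keeps
    the per-variant z-scores consistent with a single causal variant (a
    proxy can never have higher expected |z| than the causal itself), and
    the noise is correlated across variants with the panel LD matrix, as
    marginal estimates from one GWAS sample are. Returns (summary table,
    index table).
    """
    rng = np.random.default_rng([config.seed, 71])
    af = genotypes.allele_frequency()
    maf = np.minimum(af, 1.0 - af)
    dos = genotypes.dosage.astype(float)
    sd = dos.std(axis=0)
    n_v = genotypes.n_variants
    se = np.empty(n_v)
    poly = maf > 0
    se[poly] = 1.0 / np.sqrt(2.0 * config.gwas_n * maf[poly] * (1.0 - maf[poly]))
    se[~poly] = np.nan

    col_of = dict(zip(genotypes.variant_ids, range(n_v)))
    beta_mean = np.zeros(n_v)
    for row in truth.gwas_causals.itertuples():
        c = col_of[row.variant_id]
        if sd[c] == 0:
            raise ValueError(f"causal variant {row.variant_id} is monomorphic")
        z = (dos - dos.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        r = z.T @ z[:, c] / len(dos)
        r[sd == 0] = 0.0
        # true LD with other chromosomes is zero; the finite panel's
        # spurious cross-chromosome correlations must not leak effects
        r[genotypes.chrom != genotypes.chrom[c]] = 0.0
        beta_mean += r * row.beta * sd[c] / np.where(sd > 0, sd, 1.0)

    # LD-correlated noise: z-noise ~ MVN(0, R) per chromosome
    noise = np.zeros(n_v)
    eps = rng.standard_normal(n_v)
    z_all = (dos - dos.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    for ch in pd.unique(genotypes.chrom):
        idx = np.flatnonzero((genotypes.chrom == ch) & poly)
        if idx.size == 0:
            continue
        R = z_all[:, idx].T @ z_all[:, idx] / len(dos)
        L = np.linalg.cholesky(R + 1e-6 * np.eye(idx.size))
        noise[idx] = L @ eps[idx]
    beta = beta_mean + np.where(poly, se, 0.0) * noise

    summary = pd.DataFrame(
        {
            "variant_id": genotypes.variant_ids,
            "chrom": genotypes.chrom,
            "pos": genotypes.positions,
            "ref": genotypes.ref,
            "alt": genotypes.alt,
            "beta": beta,
            "se": se,
        }
    )
    summary = summary[poly].reset_index(drop=True)

    # per planted signal, the index variant is the max |z| within +/- 2.5 Mb
    idx_rows = []
    zscore = (summary["beta"] / summary["se"]).abs()
    for row in truth.gwas_causals.itertuples():
        c = col_of[row.variant_id]
        cpos = int(genotypes.positions[c])
        near = ((summary["pos"] - cpos).abs() <= 2_500_000) & (
            summary["chrom"] == genotypes.chrom[c]
        )
        best = summary[near].loc[zscore[near].idxmax()]
        idx_rows.append(
            {"signal_id": row.signal_id, "index_variant": best["variant_id"],
             "causal_variant": row.variant_id}
        )
    return summary, pd.DataFrame(idx_rows)
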