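"""End-to-end orchestration: simulate -> map-caqtl -> heterogeneity ->
coaccess -> finemap -> enrich -> motif -> report.

Each stage reads its inputs from and writes its outputs to one run
directory; a manifest records every parameter and output hash so reruns
with the same configuration are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from caqtlkit import caqtl as cq
from caqtlkit import coaccess as ca
from caqtlkit import finemap as fm
from caqtlkit import heterogeneity as het
from caqtlkit import io as kio
from caqtlkit import motif as mt
from caqtlkit import synthdata as sd
from caqtlkit import traitenrich as te

log = logging.getLogger("caqtlkit")

STAGES = ["simulate", "map-caqtl", "heterogeneity", "coaccess", "finemap",
          "enrich", "motif"]

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Pipeline configuration with the printed defaults.

    Defaults: cis window 10 kb, FDR 0.10, k = 30 neighbors, co-accessibility
    threshold 0.05 at > 10 kb with >= 4-sample replication, aBF prior
    W = 0.04, LD r2 > 0.1 within +/- 2.5 Mb, 99% credible sets, 1,000
    background draws, motif p < 5e-4.
    """

    outdir: str = "caqtlkit_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    window_bp: int = 10_000
    fdr: float = 0.10
    n_permutations: int = 2
    population_only: bool = False
    coaccess_k: int = 30
    coaccess_window: int = 1_000_000
    coaccess_threshold: float = 0.05
    coaccess_min_dist: int = 10_000
    coaccess_min_rep: int = 4
    coaccess_penalty: float = 8.0
    finemap_w: float = 0.04
    finemap_r2_min: float = 0.1
    finemap_window: int = 2_500_000
    credible_level: float = 0.99
    enrich_draws: int = 1000
    motif_p_threshold: float = 5e-4
    motif_strong_delta: float = 0.15

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        if not (0 < self.fdr < 1) or not (0 < self.credible_level <= 1):
            raise ValueError("fdr and credible_level must lie in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def sim_config(self) -> sd.SimConfig:
        return sd.SimConfig(seed=self.seed, **self.sim)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing {path.name}: run the '{stage}' stage first"
        )
    return path


def _write_df(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def stage_simulate(config: RunConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim_config()
    genotypes = sd.simulate_genotypes(sim)
    truth = sd.make_ground_truth(genotypes, sim)
    tensor = sd.simulate_peak_counts(genotypes, truth, sim)
    counts_sc, embedding, labels = sd.simulate_single_cells(truth, sim)
    summary, index_tab = sd.simulate_gwas(genotypes, truth, sim)

    kio.write_vcf(genotypes, out / "genotypes.vcf")
    kio.write_bed(truth.peaks[["chrom", "start", "end", "peak_id"]], out / "peaks.bed")
    kio.write_bed(truth.tss, out / "tss.bed")
    kio.write_tensor(tensor, out)
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    mmwrite(str(out / "sc_counts.mtx"), csr_matrix(counts_sc))
    _write_df(pd.DataFrame(embedding, columns=["dim1", "dim2"]), out / "sc_embedding.tsv")
    _write_df(labels, out / "sc_cells.tsv")
    _write_df(summary, out / "gwas.tsv")
    _write_df(index_tab, out / "gwas_index.tsv")
    kio.write_json(
        {
            "caqtl": truth.caqtl.to_dict(orient="records"),
            "coaccess_modules": truth.coaccess_modules,
            "gwas_causals": truth.gwas_causals.to_dict(orient="records"),
            "promoter_peaks": truth.promoter_peaks,
            "cell_types": list(sim.cell_types),
            "peak_lam": truth.peaks["lam"].tolist(),
        },
        out / "truth.json",
    )


def _load_common(config: RunConfig):
    out = Path(config.outdir)
    peaks = kio.read_bed(_require(out / "peaks.bed", "simulate"), names=["peak_id"])
    genotypes = kio.read_vcf(_require(out / "genotypes.vcf", "simulate"))
    truth = json.loads((out / "truth.json").read_text())
    tensor = kio.read_tensor(out, peaks, truth["cell_types"])
    return out, peaks, genotypes, truth, tensor


def stage_map_caqtl(config: RunConfig) -> None:
    out, _peaks, genotypes, truth, tensor = _load_common(config)
    for ct in truth["cell_types"]:
        results, info = cq.map_caqtl(
            tensor, genotypes, ct, window_bp=config.window_bp,
            n_permutations=config.n_permutations, alpha=config.fdr,
            population_only=config.population_only, seed=config.seed,
        )
        _write_df(results, out / f"caqtl.{ct}.tsv")
        kio.write_json(
            {k: v for k, v in info.items() if k != "permuted_q"},
            out / f"caqtl.{ct}.info.json",
        )


def _load_caqtl(config: RunConfig, truth) -> dict[str, pd.DataFrame]:
    out = Path(config.outdir)
    results = {}
    for ct in truth["cell_types"]:
        path = _require(out / f"caqtl.{ct}.tsv", "map-caqtl")
        results[ct] = pd.read_csv(path, sep="\t")
    return results


def stage_heterogeneity(config: RunConfig) -> None:
    out, _peaks, genotypes, truth, tensor = _load_common(config)
    results = _load_caqtl(config, truth)
    norm = het.vst_normalize(
        tensor.totals, list(tensor.peaks["peak_id"]), tensor.sample_ids
    )
    sig_pairs = pd.concat(
        [df[df["lead"] & df["significant"]][["peak_id", "variant_id"]]
         for df in results.values()]
    ).drop_duplicates()
    vid_idx = {v: i for i, v in enumerate(genotypes.variant_ids)}
    dosage_by_sample = {
        v: genotypes.dosage[:, vid_idx[v]] for v in sig_pairs["variant_id"]
        if v in vid_idx
    }
    if len(sig_pairs):
        inter = het.interaction_test(norm, dosage_by_sample, sig_pairs, fdr=config.fdr)
    else:
        inter = pd.DataFrame(columns=["peak_id", "variant_id", "f_stat", "p_value"])
    _write_df(inter, out / "heterogeneity.tsv")
    corr = het.effect_correlation(results)
    corr.to_csv(out / "effect_correlation.tsv", sep="\t", float_format=_FLOAT_FMT)

    # pi1 sharing of every cell type's leads evaluated in every other
    rows = []
    cts = list(results)
    for a in cts:
        da = results[a]
        disc = da[da["lead"] & da["significant"]].set_index(["peak_id", "variant_id"])
        for b in cts:
            if a == b:
                continue
            db = results[b]
            rep = db.set_index(["peak_id", "variant_id"])
            shared = disc.index.intersection(rep.index)
            if len(shared) < 5:
                continue
            pi1 = het.pi1_sharing(rep.loc[shared, "lrt_p"].to_numpy(), seed=config.seed)
            rows.append({"discovery": a, "replication": b, "n": len(shared), "pi1": pi1})
    _write_df(pd.DataFrame(rows, columns=["discovery", "replication", "n", "pi1"]),
              out / "pi1.tsv")


def stage_coaccess(config: RunConfig) -> None:
    out, peaks, genotypes, truth, tensor = _load_common(config)
    from scipy.io import mmread

    counts_sc = np.asarray(mmread(str(_require(out / "sc_counts.mtx", "simulate"))).todense())
    embedding = pd.read_csv(out / "sc_embedding.tsv", sep="\t").to_numpy()
    labels = pd.read_csv(out / "sc_cells.tsv", sep="\t")
    k = min(config.coaccess_k, max(len(labels), 1))
    bins, _ = ca.aggregate_cells(counts_sc, embedding, k=k, seed=config.seed)
    scores = ca.coaccessibility_scores(
        bins, peaks, window_bp=config.coaccess_window, penalty=config.coaccess_penalty
    )
    per_sample = {}
    for sample, rows in labels.groupby("sample"):
        sel = rows.index.to_numpy()
        ks = min(k, len(sel))
        if ks < 2:
            continue
        b_s, _ = ca.aggregate_cells(counts_sc[sel], embedding[sel], k=ks, seed=config.seed)
        per_sample[sample] = ca.coaccessibility_scores(
            b_s, peaks, window_bp=config.coaccess_window, penalty=config.coaccess_penalty
        )
    tss = kio.read_bed(out / "tss.bed", names=["gene"])
    annotation = ca.annotate_promoters(peaks, tss)
    links = ca.filter_links(
        scores, peaks, per_sample, threshold=config.coaccess_threshold,
        min_distance=config.coaccess_min_dist,
        min_replication=config.coaccess_min_rep, annotation=annotation,
    )
    _write_df(scores, out / "coaccess_scores.tsv")
    _write_df(links, out / "links.tsv")

    results = _load_caqtl(config, truth)
    class_rows, gene_rows = [], []
    for ct, df in results.items():
        sig = df[df["lead"] & df["significant"]]
        classes = ca.link_caqtls_to_promoters(list(sig["peak_id"]), links, annotation)
        classes.insert(0, "cell_type", ct)
        class_rows.append(classes)
        for row in classes.itertuples():
            for g in (row.linked_genes.split(",") if row.linked_genes else []):
                gene_rows.append({"cell_type": ct, "peak_id": row.peak_id, "gene": g})
    _write_df(
        pd.concat(class_rows, ignore_index=True) if class_rows else pd.DataFrame(),
        out / "caqtl_link_classes.tsv",
    )
    _write_df(pd.DataFrame(gene_rows, columns=["cell_type", "peak_id", "gene"]),
              out / "caqtl_linked_genes.tsv")


def stage_finemap(config: RunConfig) -> None:
    out, _peaks, genotypes, truth, _tensor = _load_common(config)
    summary = pd.read_csv(_require(out / "gwas.tsv", "simulate"), sep="\t")
    index_tab = pd.read_csv(out / "gwas_index.tsv", sep="\t")
    sets = fm.finemap_signals(
        summary, index_tab, genotypes, W=config.finemap_w,
        r2_min=config.finemap_r2_min, window_bp=config.finemap_window,
        level=config.credible_level,
    )
    frames = []
    for cs in sets:
        t = cs.table.copy()
        t.insert(0, "signal_id", cs.signal_id)
        frames.append(t)
    _write_df(pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(),
              out / "credible_sets.tsv")


def stage_enrich(config: RunConfig) -> None:
    out, peaks, genotypes, truth, tensor = _load_common(config)
    summary = pd.read_csv(out / "gwas.tsv", sep="\t")
    cred = pd.read_csv(_require(out / "credible_sets.tsv", "finemap"), sep="\t")
    results = _load_caqtl(config, truth)
    sets = [
        fm.CredibleSet(sig, grp.drop(columns=["signal_id"]).reset_index(drop=True))
        for sig, grp in cred.groupby("signal_id")
    ]
    rows = []
    for ct, df in results.items():
        leads = df[df["lead"]]
        caqtl_peaks = list(leads.loc[leads["significant"], "peak_id"])
        background = list(leads.loc[~leads["significant"], "peak_id"])
        if not caqtl_peaks or len(background) < len(caqtl_peaks):
            continue
        res = te.cumulative_ppa_enrichment(
            sets, summary, caqtl_peaks, background, peaks,
            n_draws=config.enrich_draws, seed=config.seed, trait="synthetic",
            cell_type=ct,
        )
        rows.append(
            {"trait": res.trait, "cell_type": ct, "observed": res.observed_stat,
             "null_mean": float(res.null_stats.mean()),
             "empirical_p": res.empirical_p, "log_or": res.log_or}
        )
    _write_df(pd.DataFrame(rows, columns=["trait", "cell_type", "observed",
                                          "null_mean", "empirical_p", "log_or"]),
              out / "enrichment.tsv")

    gene_path = out / "caqtl_linked_genes.tsv"
    link_genes = None
    if gene_path.exists():
        lg = pd.read_csv(gene_path, sep="\t")
        link_genes = lg[["peak_id", "gene"]] if len(lg) else None
    annot = te.annotate_credible_variants(sets, results, peaks, summary, link_genes)
    _write_df(annot, out / "credible_caqtl_annotation.tsv")


def stage_motif(config: RunConfig) -> None:
    out, _peaks, genotypes, truth, _tensor = _load_common(config)
    results = _load_caqtl(config, truth)
    pwms = mt.bundled_pwms()
    max_len = max(p.length for p in pwms)
    rng = np.random.default_rng([config.seed, 97])
    bases = np.array(list("ACGT"))

    tested: set[str] = set()
    caqtl_vars: set[str] = set()
    for df in results.values():
        tested.update(df["variant_id"])
        sig = df[df["lead"] & df["significant"]]
        caqtl_vars.update(sig["variant_id"])
    vid_idx = {v: i for i, v in enumerate(genotypes.variant_ids)}

    calls = []
    for vid in sorted(tested):
        i = vid_idx[vid]
        flank = rng.choice(bases, size=2 * (max_len - 1) + 1)
        flank[max_len - 1] = genotypes.ref[i]
        context = "".join(flank)
        for pwm in pwms:
            call = mt.allelic_disruption(
                vid, context, max_len - 1, genotypes.ref[i], genotypes.alt[i],
                pwm, p_threshold=config.motif_p_threshold,
                strong_delta=config.motif_strong_delta,
            )
            calls.append(call.__dict__)
    disruptions = pd.DataFrame(calls)
    _write_df(disruptions, out / "motif_disruptions.tsv")
    if len(disruptions) and caqtl_vars:
        table, global_fisher = mt.motif_enrichment(disruptions, caqtl_vars, tested)
        _write_df(table, out / "motif_enrichment.tsv")
        kio.write_json(global_fisher, out / "motif_global.json")


_STAGE_FN = {
    "simulate": stage_simulate,
    "map-caqtl": stage_map_caqtl,
    "heterogeneity": stage_heterogeneity,
    "coaccess": stage_coaccess,
    "finemap": stage_finemap,
    "enrich": stage_enrich,
    "motif": stage_motif,
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages in dependency order and write a manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        log.info("stage %s started", stage)
        _STAGE_FN[stage](config)
        timings[stage] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done in %.1fs", stage, timings[stage])
    manifest = {
        "config": asdict(config),
        "stage_seconds": timings,
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    kio.write_json(manifest, out / "manifest.json")
    return manifest
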