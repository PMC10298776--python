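"""Readers and writers for the pipeline's on-disk formats.

Internal coordinates are 0-based half-open; VCF positions are 1-based and
converted on read/write. The VCF dialect is deliberately strict: diploid,
biallelic single-nucleotide variants with GT fields only.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from caqtlkit.types import AllelicCounts, CohortGenotypes, PeakCountTensor

__all__ = [
    "VcfParseError",
    "read_vcf",
    "write_vcf",
    "read_bed",
    "write_bed",
    "write_tensor",
    "read_tensor",
]


class VcfParseError(ValueError):
    """Malformed VCF input; carries the offending 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


_GT_DOSAGE = {"0": 0, "1": 1}


def read_vcf(path: str | Path) -> CohortGenotypes:
    """Read a minimal biallelic-SNV VCF into a genotype matrix.

    Missing GT ('./.') excludes the sample for that variant (dosage -1);
    multi-allelic or non-SNV records are rejected with the line number.
    """
    chroms, positions, refs, alts, vids, rows = [], [], [], [], [], []
    samples: list[str] | None = None
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if fields[:9] != ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL",
                                  "FILTER", "INFO", "FORMAT"]:
                    raise VcfParseError("unexpected header columns", ln)
                samples = fields[9:]
                continue
            if samples is None:
                raise VcfParseError("record before #CHROM header", ln)
            fields = line.split("\t")
            if len(fields) != 9 + len(samples):
                raise VcfParseError(
                    f"expected {9 + len(samples)} columns, got {len(fields)}", ln
                )
            chrom, pos, vid, ref, alt, _qual, _filt, _info, fmt = fields[:9]
            if "," in alt:
                raise VcfParseError("multi-allelic records are not supported", ln)
            if len(ref) != 1 or len(alt) != 1 or ref == alt:
                raise VcfParseError(f"not a biallelic SNV: {ref}>{alt}", ln)
            if fmt.split(":")[0] != "GT":
                raise VcfParseError("first FORMAT key must be GT", ln)
            try:
                positions.append(int(pos))
            except ValueError:
                raise VcfParseError(f"bad POS {pos!r}", ln) from None
            dos = []
            for cell in fields[9:]:
                gt = cell.split(":")[0].replace("|", "/")
                parts = gt.split("/")
                if "." in parts:
                    dos.append(-1)
                    continue
                try:
                    dos.append(sum(_GT_DOSAGE[p] for p in parts))
                except KeyError:
                    raise VcfParseError(f"bad genotype {gt!r}", ln) from None
            chroms.append(chrom)
            refs.append(ref)
            alts.append(alt)
            vids.append(vid if vid != "." else f"{chrom}:{pos}")
            rows.append(dos)
    if samples is None:
        raise VcfParseError("no #CHROM header found", 1)
    dosage = np.array(rows, dtype=np.int8).T if rows else np.zeros((len(samples), 0), np.int8)
    return CohortGenotypes(
        chrom=np.array(chroms),
        positions=np.array(positions, dtype=np.int64),
        ref=np.array(refs),
        alt=np.array(alts),
        dosage=dosage,
        variant_ids=np.array(vids),
        sample_ids=list(samples),
    )


def write_vcf(genotypes: CohortGenotypes, path: str | Path) -> None:
    """Write genotypes as a minimal CHROM/POS/ID/REF/ALT + GT VCF."""
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.sample_ids) + "\n")
        for v in range(genotypes.n_variants):
            gts = "\t".join(gt_of[int(d)] for d in genotypes.dosage[:, v])
            fh.write(
                f"{genotypes.chrom[v]}\t{genotypes.positions[v]}\t"
                f"{genotypes.variant_ids[v]}\t{genotypes.ref[v]}\t"
                f"{genotypes.alt[v]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_bed(path: str | Path, names: list[str] | None = None) -> pd.DataFrame:
    """Read BED3+ (0-based half-open), returned stably sorted by coordinate."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end"]
    extra = names or [f"col{i}" for i in range(3, df.shape[1])]
    df.columns = cols + list(extra[: df.shape[1] - 3])
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0]
        raise ValueError(f"BED record {bad}: start >= end")
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def write_tensor(tensor: PeakCountTensor, outdir: str | Path) -> None:
    """Write counts, allelic counts and offsets as per-cell-type TSVs."""
    outdir = Path(outdir)
    for ct in tensor.cell_types:
        counts = pd.DataFrame(
            tensor.totals[ct].T, index=tensor.peaks["peak_id"],
            columns=tensor.sample_ids,
        )
        counts.to_csv(outdir / f"counts.{ct}.tsv", sep="\t", index_label="peak_id")
        tensor.allelic[ct].table.to_csv(outdir / f"allelic.{ct}.tsv", sep="\t", index=False)
    off = pd.DataFrame({ct: tensor.offsets[ct] for ct in tensor.cell_types},
                       index=tensor.sample_ids)
    off.to_csv(outdir / "offsets.tsv", sep="\t", index_label="sample")


def read_tensor(outdir: str | Path, peaks: pd.DataFrame,
                cell_types: list[str]) -> PeakCountTensor:
    outdir = Path(outdir)
    totals, allelic, offsets = {}, {}, {}
    sample_ids: list[str] = []
    off = pd.read_csv(outdir / "offsets.tsv", sep="\t", index_col="sample")
    sample_ids = list(off.index)
    for ct in cell_types:
        counts = pd.read_csv(outdir / f"counts.{ct}.tsv", sep="\t", index_col="peak_id")
        counts = counts.reindex(peaks["peak_id"])
        totals[ct] = counts[sample_ids].to_numpy().T
        allelic[ct] = AllelicCounts(pd.read_csv(outdir / f"allelic.{ct}.tsv", sep="\t"))
        offsets[ct] = off[ct].to_numpy()
    return PeakCountTensor(
        peaks=peaks[["chrom", "start", "end", "peak_id"]].reset_index(drop=True),
        sample_ids=sample_ids, totals=totals, allelic=allelic, offsets=offsets,
    )


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
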