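"""Allelic TF-motif disruption scoring and per-motif caQTL enrichment.

PWMs are log-odds matrices (bits) built from position frequency matrices;
score tail probabilities come from an exact dynamic-programming convolution
of the per-position score distributions under a background base model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Pwm",
    "DisruptionCall",
    "read_jaspar",
    "build_pwm",
    "exact_score_pvalue",
    "allelic_disruption",
    "motif_enrichment",
    "BUNDLED_PFMS",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
UNIFORM_BG = np.full(4, 0.25)


@dataclass
class Pwm:
    """Position weight matrix in bits, columns ordered A, C, G, T."""

    motif_id: str
    tf_name: str
    matrix: np.ndarray  # (length, 4) log-odds
    background: np.ndarray

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def score_range(self) -> tuple[float, float]:
        return float(self.matrix.min(axis=1).sum()), float(self.matrix.max(axis=1).sum())

    def score(self, seq: str) -> float:
        """Log-odds score of one exact-length sequence."""
        if len(seq) != self.length:
            raise ValueError("sequence length must equal motif length")
        return float(sum(self.matrix[i, _BASE_INDEX[b]] for i, b in enumerate(seq.upper())))


@dataclass
class DisruptionCall:
    variant_id: str
    motif_id: str
    best_score_ref: float
    best_score_alt: float
    best_p_ref: float
    best_p_alt: float
    delta: float  # |score_ref - score_alt| scaled by attainable range
    effect: str  # none | weak | strong


def read_jaspar(text: str) -> dict[str, np.ndarray]:
    """Parse JASPAR-style PFM text (`>id name` header, then A/C/G/T rows).

    Returns motif id -> (length x 4) count matrix with columns A, C, G, T.
    """
    pfms: dict[str, np.ndarray] = {}
    name, rows = None, []
    for line in text.strip().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None and rows:
                pfms[name] = np.array(rows, dtype=float).T
            name = line[1:].split()[0]
            rows = []
        else:
            parts = line.replace("[", " ").replace("]", " ").split()
            if parts and parts[0] in "ACGT":
                parts = parts[1:]
            rows.append([float(x) for x in parts])
    if name is not None and rows:
        pfms[name] = np.array(rows, dtype=float).T
    return pfms


def build_pwm(
    pfm: np.ndarray,
    background: np.ndarray | None = None,
    pseudocount: float = 0.8,
    motif_id: str = "motif",
    tf_name: str = "",
) -> Pwm:
    """Counts -> log2 odds: log2(((n + pc*bg) / (colsum + pc)) / bg)."""
    pfm = np.asarray(pfm, dtype=float)
    if pfm.ndim != 2 or pfm.shape[1] != 4 or pfm.shape[0] == 0:
        raise ValueError("PFM must be a non-empty (length x 4) matrix")
    if (pfm < 0).any() or not (pfm.sum(axis=1) > 0).any():
        raise ValueError("PFM must be non-negative with at least one positive column")
    bg = UNIFORM_BG if background is None else np.asarray(background, dtype=float)
    colsum = pfm.sum(axis=1, keepdims=True)
    prob = (pfm + pseudocount * bg[None, :]) / (colsum + pseudocount)
    return Pwm(motif_id, tf_name, np.log2(prob / bg[None, :]), bg)


_DIST_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def score_distribution(
    pwm: Pwm, background: np.ndarray | None = None, resolution: float = 1e-3
) -> tuple[np.ndarray, np.ndarray]:
    """Exact discretized score distribution: (grid of scores, tail P(S >= s)).

    Convolves per-position score distributions by four shifted adds per
    position (each position contributes only four score values); results
    are cached per (matrix, background, resolution).
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    bg = pwm.background if background is None else np.asarray(background, dtype=float)
    key = (pwm.matrix.tobytes(), bg.tobytes(), resolution)
    hit = _DIST_CACHE.get(key)
    if hit is not None:
        return hit
    q = np.round(pwm.matrix / resolution).astype(np.int64)
    offset = q.min(axis=1)
    qn = q - offset[:, None]  # non-negative integer scores per position
    dist = np.array([1.0])
    for i in range(pwm.length):
        width = dist.size + qn[i].max()
        nxt = np.zeros(width)
        for b in range(4):
            nxt[qn[i, b]:qn[i, b] + dist.size] += bg[b] * dist
        dist = nxt
    grid = (np.arange(dist.size) + offset.sum()) * resolution
    tail = np.cumsum(dist[::-1])[::-1]
    _DIST_CACHE[key] = (grid, tail)
    return grid, tail


def exact_score_pvalue(
    pwm: Pwm,
    score: float,
    background: np.ndarray | None = None,
    resolution: float = 1e-3,
) -> float:
    """P(S >= score) for a random background sequence, by exact convolution.

    Exact on the discretized score scale: per-position scores are rounded
    to ``resolution`` bits and the query score is rounded to the same grid,
    so the result equals brute-force enumeration with rounded scores
    (absolute error vs the continuous distribution <= length*resolution/2).
    """
    grid, tail = score_distribution(pwm, background, resolution)
    base = int(np.round(grid[0] / resolution))
    idx = int(np.round(score / resolution)) - base
    if idx <= 0:
        return 1.0
    if idx >= tail.size:
        return 0.0
    return float(tail[idx])


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _best_window_score(pwm: Pwm, seq: str, var_pos: int) -> float:
    """Best score over windows covering var_pos, both strands."""
    L = pwm.length
    best = -np.inf
    for start in range(max(0, var_pos - L + 1), min(len(seq) - L, var_pos) + 1):
        window = seq[start:start + L]
        best = max(best, pwm.score(window), pwm.score(_revcomp(window)))
    return best


def allelic_disruption(
    variant_id: str,
    context_sequence: str,
    variant_offset: int,
    ref: str,
    alt: str,
    pwm: Pwm,
    p_threshold: float = 5e-4,
    strong_delta: float = 0.15,
    weak_delta: float = 0.05,
) -> DisruptionCall:
    """Classify allelic motif disruption at a variant.

    ``context_sequence`` must carry the REF base at ``variant_offset`` and
    cover all motif windows overlapping it. An allele is "bound" if its
    best score has exact p < ``p_threshold``; effect is strong when exactly
    one allele is bound and the range-scaled score difference >=
    ``strong_delta``, weak when both are bound and the difference >=
    ``weak_delta``.
    """
    seq = context_sequence.upper()
    if seq[variant_offset] != ref.upper():
        raise ValueError(
            f"context base {seq[variant_offset]!r} does not match ref allele {ref!r}"
        )
    seq_alt = seq[:variant_offset] + alt.upper() + seq[variant_offset + 1:]
    s_ref = _best_window_score(pwm, seq, variant_offset)
    s_alt = _best_window_score(pwm, seq_alt, variant_offset)
    p_ref = exact_score_pvalue(pwm, s_ref)
    p_alt = exact_score_pvalue(pwm, s_alt)
    lo, hi = pwm.score_range
    delta = abs(s_ref - s_alt) / max(hi - lo, 1e-12)
    bound_ref, bound_alt = p_ref < p_threshold, p_alt < p_threshold
    if bound_ref != bound_alt and delta >= strong_delta:
        effect = "strong"
    elif bound_ref and bound_alt and delta >= weak_delta:
        effect = "weak"
    elif (bound_ref or bound_alt) and delta >= strong_delta:
        effect = "weak"
    else:
        effect = "none"
    return DisruptionCall(
        variant_id=variant_id, motif_id=pwm.motif_id,
        best_score_ref=s_ref, best_score_alt=s_alt,
        best_p_ref=p_ref, best_p_alt=p_alt, delta=delta, effect=effect,
    )


def motif_enrichment(
    disruptions: pd.DataFrame,  # variant_id, motif_id, effect
    caqtl_variants: set[str],
    tested_variants: set[str],
    fdr: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Per-motif one-tailed binomial enrichment of strong disruptions in caQTLs.

    Background rate p0 is the motif's strong-disruption frequency among all
    tested variants; p = P(X >= k), X ~ Binomial(n_caqtl, p0). Also returns
    a global any-motif Fisher exact enrichment.
    """
    if not caqtl_variants <= tested_variants:
        raise ValueError("caQTL variants must be a subset of tested variants")
    strong = disruptions[disruptions["effect"] == "strong"]
    n_tested = len(tested_variants)
    n_caqtl = len(caqtl_variants)

    rows = []
    for motif_id, grp in strong.groupby("motif_id"):
        hit_vars = set(grp["variant_id"]) & tested_variants
        k = len(hit_vars & caqtl_variants)
        m = len(hit_vars)
        p0 = m / n_tested if n_tested else 0.0
        if p0 == 0.0:
            p = 1.0 / (n_caqtl + 1) if k > 0 else 1.0
            flagged = k > 0
        else:
            p = float(stats.binom.sf(k - 1, n_caqtl, p0))
            flagged = False
        expected = n_caqtl * p0
        rows.append(
            {
                "motif_id": motif_id, "n_caqtl_disrupting": k,
                "n_tested_disrupting": m, "background_rate": p0,
                "enrichment": (k / expected) if expected > 0 else np.nan,
                "p_value": p, "zero_background_flag": flagged,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        from caqtlkit.caqtl import bh_qvalues

        table["fdr"] = bh_qvalues(table["p_value"].to_numpy())
        table["significant"] = table["fdr"] < fdr

    any_disrupt = set(strong["variant_id"]) & tested_variants
    a = len(any_disrupt & caqtl_variants)
    b = n_caqtl - a
    c = len(any_disrupt) - a
    d = (n_tested - n_caqtl) - c
    odds, p_global = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return table, {"odds_ratio": float(odds), "p_value": float(p_global),
                   "table": [[a, b], [c, d]]}


# Toy PFMs standing in for a motif database: ETS-, IRF-, SPI1-, RUNX- and
# CEBP-like consensus cores padded with weakly informative flanks.
BUNDLED_PFMS_TEXT = """
>ETS_like ETS1
A  [ 4  2 60  2  1  2 10 ]
C  [ 30 2  2  2  1  2 20 ]
G  [ 16 90  2 90 96 2 20 ]
T  [ 50 6 36  6  2 94 50 ]
>IRF_like IRF4
A  [ 70  70  2  2  4 70 70  2 ]
C  [ 10  10  4 90  4 10 10  4 ]
G  [ 10  10 90  4  4 10 10 90 ]
T  [ 10  10  4  4 88 10 10  4 ]
>SPI1_like SPI1
A  [ 40  60  2 95  2  2 20 ]
C  [ 20  10  2  1  1  2 30 ]
G  [ 20  20 94  2 95 94 30 ]
T  [ 20  10  2  2  2  2 20 ]
>RUNX_like RUNX3
A  [ 10  2 70  2  2  6 ]
C  [ 60 90  4  2 90  8 ]
G  [ 10  4  4 94  4 80 ]
T  [ 20  4 22  2  4  6 ]
>CEBP_like CEBPB
A  [ 2 90  2  2  2 70 90 ]
C  [ 6  4  2 90  2 10  4 ]
G  [ 6  4  2  4 90 10  2 ]
T  [ 86 2 94  4  6 10  4 ]
"""

BUNDLED_PFMS = read_jaspar(BUNDLED_PFMS_TEXT)


def bundled_pwms(pseudocount: float = 0.8) -> list[Pwm]:
    """The toy motif set as ready-to-scan PWMs."""
    return [
        build_pwm(pfm, pseudocount=pseudocount, motif_id=mid, tf_name=mid)
        for mid, pfm in BUNDLED_PFMS.items()
    ]
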