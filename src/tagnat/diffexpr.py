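"""Nonparametric differential expression via M/D noise dominance.

For each transcript the signal between conditions S and F is summarized by
two statistics computed from the condition means (arithmetic mean of
replicate TPM):

* ``M`` — the log2 ratio ``log2((mean_S + k) / (mean_F + k))`` with a small
  pseudo-abundance ``k`` guarding against zeros;
* ``D`` — the absolute difference ``|mean_S - mean_F|``.

The null ("noise") distribution of (|M|, D) is built empirically from all
within-condition replicate pairs, pooled across every transcript, so that
with 3+3 replicates each transcript contributes C(3,2)+C(3,2) = 6 pairs.
A transcript's probability of differential expression is the fraction of
noise pairs its signal strictly dominates (|M_sig| > |M_noise| and
D_sig > D_noise).  A probability of 0.8 means the change is 4 times more
likely to be signal than noise (odds p/(1-p)).  Note this probability is a
noise-dominance score, not a false-discovery-rate q-value, even though DGE
reports often label it "q".

Significant calls additionally require |M| >= 1 and the TPM of the lower
expressed condition >= 1.  Genes (sense layer) and natural antisense
transcripts (antisense layer) are called by the identical procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .quantify import StrandedExpressionMatrix

#: default pseudo-abundance (TPM) inside the log ratio
DEFAULT_K = 0.5


@dataclass
class DeRecord:
    transcript_id: str
    layer: str  # "sense" (DEG) | "antisense" (NAT)
    mean_tpm_S: float
    mean_tpm_F: float
    M: float
    D: float
    probability: float
    direction: str = "none"  # "up_in_S" | "down_in_S"
    significant: bool = False


@dataclass
class NoiseDistribution:
    abs_m: np.ndarray
    d: np.ndarray
    sample_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return int(self.abs_m.size)


@dataclass
class SignificantSet:
    degs_up: list[DeRecord]
    degs_down: list[DeRecord]
    nats_up: list[DeRecord]
    nats_down: list[DeRecord]
    min_abs_m: float
    min_prob: float
    min_tpm_low: float

    @property
    def total(self) -> int:
        return (
            len(self.degs_up) + len(self.degs_down) + len(self.nats_up) + len(self.nats_down)
        )


def noiseq_signal(mean_s: float, mean_f: float, k: float = DEFAULT_K) -> tuple[float, float]:
    """(M, D) between two condition means at pseudo-abundance ``k``."""
    if mean_s < 0 or mean_f < 0:
        raise ValueError("condition means must be >= 0")
    if k <= 0:
        raise ValueError("pseudo-abundance k must be > 0")
    m = math.log2((mean_s + k) / (mean_f + k))
    d = abs(mean_s - mean_f)
    return m, d


def build_noise(
    expr: pd.DataFrame, design: dict[str, str], k: float = DEFAULT_K
) -> NoiseDistribution:
    """Pool (|M|, D) over all within-group replicate pairs and all transcripts.

    ``expr`` is a transcripts x samples TPM frame; ``design`` maps
    sample_id -> group label.  At least one group needs >= 2 replicates.
    """
    pairs: list[tuple[str, str]] = []
    groups: dict[str, list[str]] = {}
    for s in expr.columns:
        groups.setdefault(design[s], []).append(s)
    for members in groups.values():
        pairs.extend(combinations(members, 2))
    if not pairs:
        raise ValueError("need at least one group with >= 2 replicates to estimate noise")
    abs_m_parts = []
    d_parts = []
    vals = expr.to_numpy(dtype=float)
    col = {s: i for i, s in enumerate(expr.columns)}
    for a, b in pairs:
        x, y = vals[:, col[a]], vals[:, col[b]]
        abs_m_parts.append(np.abs(np.log2((x + k) / (y + k))))
        d_parts.append(np.abs(x - y))
    return NoiseDistribution(
        abs_m=np.concatenate(abs_m_parts), d=np.concatenate(d_parts), sample_pairs=pairs
    )


def de_probability(signal: tuple[float, float], noise: NoiseDistribution) -> float:
    """Fraction of noise pairs strictly dominated by the signal pair."""
    if noise.size == 0:
        raise ValueError("empty noise pool; need replicated samples")
    m, d = signal
    dominated = (abs(m) > noise.abs_m) & (d > noise.d)
    return float(dominated.sum()) / noise.size


def _probabilities(
    abs_m_sig: np.ndarray, d_sig: np.ndarray, noise: NoiseDistribution, chunk: int = 512
) -> np.ndarray:
    """Vectorized dominance probabilities for many signals."""
    out = np.empty(abs_m_sig.size, dtype=float)
    for i in range(0, abs_m_sig.size, chunk):
        ms = abs_m_sig[i : i + chunk, None]
        ds = d_sig[i : i + chunk, None]
        out[i : i + chunk] = (
            ((ms > noise.abs_m[None, :]) & (ds > noise.d[None, :])).sum(axis=1) / noise.size
        )
    return out


def run_noiseq(
    expr: pd.DataFrame,
    design: dict[str, str],
    layer: str,
    k: float = DEFAULT_K,
    noise: NoiseDistribution | None = None,
) -> list[DeRecord]:
    """Score every transcript of one layer; groups are labelled S and F."""
    s_cols = [s for s in expr.columns if design[s] == "S"]
    f_cols = [s for s in expr.columns if design[s] == "F"]
    if not s_cols or not f_cols:
        raise ValueError("design must contain both groups S and F")
    if noise is None:
        noise = build_noise(expr, design, k=k)
    mean_s = expr[s_cols].mean(axis=1).to_numpy()
    mean_f = expr[f_cols].mean(axis=1).to_numpy()
    m = np.log2((mean_s + k) / (mean_f + k))
    d = np.abs(mean_s - mean_f)
    prob = _probabilities(np.abs(m), d, noise)
    records = []
    for i, tid in enumerate(expr.index):
        records.append(
            DeRecord(
                transcript_id=str(tid),
                layer=layer,
                mean_tpm_S=float(mean_s[i]),
                mean_tpm_F=float(mean_f[i]),
                M=float(m[i]),
                D=float(d[i]),
                probability=float(prob[i]),
                direction="up_in_S" if m[i] >= 0 else "down_in_S",
            )
        )
    return records


def run_differential(
    matrix: StrandedExpressionMatrix,
    design: dict[str, str],
    k: float = DEFAULT_K,
) -> list[DeRecord]:
    """DE scoring on both strand layers with layer-specific noise pools."""
    records = []
    for layer in ("sense", "antisense"):
        expr = matrix.layer(layer, tpm=True)
        records.extend(run_noiseq(expr, design, layer=layer, k=k))
    return records


def odds_from_probability(p: float) -> float:
    """Odds p/(1-p) that a change is signal rather than noise."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("probability must be in [0,1]")
    if p == 1.0:
        return math.inf
    return p / (1.0 - p)


def call_significant(
    records: list[DeRecord],
    min_abs_m: float = 1.0,
    min_prob: float = 0.8,
    min_tpm_low: float = 1.0,
) -> SignificantSet:
    """Apply the significance filter and partition by layer and direction.

    A record passes when |M| >= ``min_abs_m``, probability >= ``min_prob``
    and the lower of the two condition means >= ``min_tpm_low``.  Output
    lists are ordered by |M| descending.
    """
    out = SignificantSet([], [], [], [], min_abs_m, min_prob, min_tpm_low)
    for r in records:
        ok = (
            abs(r.M) >= min_abs_m
            and r.probability >= min_prob
            and min(r.mean_tpm_S, r.mean_tpm_F) >= min_tpm_low
        )
        r.significant = ok
        r.direction = "up_in_S" if r.M >= 0 else "down_in_S"
        if not ok:
            continue
        if r.layer == "sense":
            (out.degs_up if r.M >= 0 else out.degs_down).append(r)
        else:
            (out.nats_up if r.M >= 0 else out.nats_down).append(r)
    for lst in (out.degs_up, out.degs_down, out.nats_up, out.nats_down):
        lst.sort(key=lambda r: -abs(r.M))
    return out


def ddct_fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the delta-delta-Ct method: 2^-ΔΔCt."""
    for v in (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0**-ddct


def records_to_frame(records: list[DeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "layer": [r.layer for r in records],
            "transcript_id": [r.transcript_id for r in records],
            "mean_tpm_S": [r.mean_tpm_S for r in records],
            "mean_tpm_F": [r.mean_tpm_F for r in records],
            "log2_ratio": [r.M for r in records],
            "D": [r.D for r in records],
            "probability": [r.probability for r in records],
            "direction": [r.direction for r in records],
            "significant": [r.significant for r in records],
        }
    )
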