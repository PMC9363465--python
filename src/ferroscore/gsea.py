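"""Pre-ranked gene-set enrichment analysis with a gene-permutation null.

Takes the differential tables produced by the matched analysis (mRNA or
methylation layers), ranks features by a signed significance metric, and
runs the weighted Kolmogorov-Smirnov enrichment walk against a GMT
collection.  Significance comes from permuting gene labels: random sets of
the same size are drawn from the ranked list, the null ES distribution is
shared across sets of equal size, NES normalizes by the mean |null ES| of
matching sign, and p-values carry a +1 pseudo-count so they are never
exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GeneSetCollection
from .stats import bh_fdr

log = logging.getLogger(__name__)


def rank_metric(diff: pd.DataFrame) -> pd.DataFrame:
    """Signed significance ranking from a differential table.

    score = sign(effect) * -log10(max(p, 1e-300)); sorted descending, ties
    broken by |effect| descending then feature id ascending.
    """
    if len(diff) == 0:
        raise ValueError("empty differential table")
    if diff["feature"].duplicated().any():
        raise ValueError("duplicate features in differential table")
    d = diff.dropna(subset=["p", "effect"]).copy()
    if len(d) == 0:
        raise ValueError("no feature with a finite p-value and effect")
    score = np.sign(d["effect"]) * -np.log10(np.maximum(d["p"], 1e-300))
    d = d.assign(score=score, abs_effect=d["effect"].abs())
    d = d.sort_values(
        ["score", "abs_effect", "feature"], ascending=[False, False, True]
    )
    return d[["feature", "score"]].reset_index(drop=True)


def gsea_es(
    ranked: pd.DataFrame,
    gene_set,
    weight: float = 1.0,
    return_walk: bool = False,
):
    """Weighted KS enrichment score of one gene set on a ranked list.

    Hit steps are proportional to |score|^weight normalized over the set;
    miss steps are uniform 1/(N - |S|).  The ES is the running-difference
    extreme of larger magnitude (positive on ties).
    """
    features = ranked["feature"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    n = len(features)
    in_set = np.isin(features, list(gene_set))
    m = int(in_set.sum())
    if m == 0:
        raise ValueError("gene set has no member in the ranked list")
    if m == n:
        walk = np.cumsum(np.abs(scores) ** weight)
        walk = walk / walk[-1]
        return (1.0, walk) if return_walk else 1.0

    w = np.abs(scores) ** weight
    w_in = np.where(in_set, w, 0.0)
    total = w_in.sum()
    if total == 0:
        w_in = in_set.astype(float)  # all-zero scores: fall back to uniform hits
        total = w_in.sum()
    p_hit = np.cumsum(w_in) / total
    p_miss = np.cumsum(~in_set) / (n - m)
    walk = p_hit - p_miss
    hi, lo = walk.max(), walk.min()
    es = float(hi if hi >= -lo else lo)
    return (es, walk) if return_walk else es


def leading_edge(ranked: pd.DataFrame, gene_set, weight: float = 1.0) -> list[str]:
    """Set members up to (positive ES) or after (negative ES) the walk extreme."""
    es, walk = gsea_es(ranked, gene_set, weight, return_walk=True)
    features = ranked["feature"].to_numpy()
    in_set = np.isin(features, list(gene_set))
    if es >= 0:
        cut = int(np.argmax(walk))
        mask = np.zeros(len(features), dtype=bool)
        mask[: cut + 1] = True
    else:
        cut = int(np.argmin(walk))
        mask = np.zeros(len(features), dtype=bool)
        mask[cut:] = True
    return [f for f in features[mask & in_set]]


def _null_es(scores: np.ndarray, size: int, nperm: int, weight: float,
             rng: np.random.Generator) -> np.ndarray:
    """Null ES for random sets of ``size`` genes, vectorized over permutations.

    Uses the closed form of the walk extremes: with sorted hit positions
    p_1<..<p_m and cumulative hit weights W_j, the running difference peaks
    at hit positions (W_j/W_m - (p_j - j)/(N - m)) and troughs just before
    them (W_{j-1}/W_m - (p_j - j)/(N - m) - adjustment), so only hit
    positions need evaluating.
    """
    n = len(scores)
    w = np.abs(scores) ** weight
    # nperm x size random positions without replacement
    pos = np.argsort(rng.random((nperm, n)), axis=1)[:, :size]
    pos.sort(axis=1)
    wh = w[pos]
    wsum = wh.sum(axis=1, keepdims=True)
    wsum = np.where(wsum == 0, 1.0, wsum)
    cum = np.cumsum(wh, axis=1) / wsum
    j = np.arange(1, size + 1)
    miss_at = (pos + 1 - j) / (n - size)          # misses accumulated before hit j
    peaks = cum - miss_at                          # walk just after hit j
    prev = np.concatenate([np.zeros((nperm, 1)), cum[:, :-1]], axis=1)
    troughs = prev - miss_at                       # walk just before hit j
    hi = peaks.max(axis=1)
    lo = np.minimum(troughs.min(axis=1), 0.0)      # walk ends at 0
    return np.where(hi >= -lo, hi, lo)


@dataclass
class GSEAResult:
    set_name: str
    es: float
    nes: float
    p: float
    q: float
    size: int
    leading_edge: list[str]
    direction: str  # high_fps | low_fps


def gsea_significance(
    ranked: pd.DataFrame,
    collection: GeneSetCollection,
    weight: float = 1.0,
    nperm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run the enrichment walk for every set and assess significance.

    Gene-label permutation null per set-size class; NES = ES / mean(|null
    ES| of the same sign); two-sided empirical p with a +1 pseudo-count;
    q = BH-FDR across the collection.  Deterministic given ``seed``.
    """
    if nperm < 100:
        raise ValueError("nperm must be >= 100")
    rng = np.random.default_rng(seed)
    features = set(ranked["feature"])
    scores = ranked["score"].to_numpy(dtype=float)

    sets: list[tuple[str, list[str], int]] = []
    for name, genes in collection.items():
        present = [g for g in genes if g in features]
        if not present or len(present) >= len(features):
            log.info("skipping gene set %r (%d of %d genes in ranking)",
                     name, len(present), len(features))
            continue
        sets.append((name, present, len(present)))

    null_cache: dict[int, np.ndarray] = {}
    for size in sorted({s for _, _, s in sets}):
        null_cache[size] = _null_es(scores, size, nperm, weight, rng)

    rows = []
    for name, present, size in sets:
        es = gsea_es(ranked, present, weight)
        null = null_cache[size]
        p = (1.0 + np.sum(np.abs(null) >= abs(es))) / (1.0 + nperm)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = np.abs(same_sign).mean() if same_sign.size else np.abs(null).mean()
        nes = es / denom if denom > 0 else 0.0
        rows.append(
            {
                "set_name": name,
                "es": es,
                "nes": nes,
                "p": float(p),
                "size": size,
                "leading_edge": ",".join(leading_edge(ranked, present, weight)),
                "direction": "high_fps" if es >= 0 else "low_fps",
            }
        )
    if not rows:
        raise ValueError("no gene set overlapped the ranked list")
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    out.attrs["nperm"] = nperm
    out.attrs["seed"] = seed
    out.attrs["weight"] = weight
    return out[["set_name", "es", "nes", "p", "q", "size", "direction", "leading_edge"]]
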