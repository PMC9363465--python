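"""Single-sample gene-set scoring and the ferroptosis score (FPS).

The FPS contrasts the per-sample enrichment of pro-ferroptosis genes with
that of anti-ferroptosis genes::

    FPS(sample) = ES(pro genes) - ES(anti genes)

where ES is a rank-weighted single-sample enrichment walk: genes are ranked
by descending expression within the sample, in-set genes contribute rank
weights r^alpha (normalized over the set), out-of-set genes uniform steps,
and the ES is the sum of the running difference over all positions.  The
same code path scores bulk samples, single cells and spatial spots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FerroptosisSignature, GeneSetCollection, OmicsMatrix
from .stats import _rankdata

log = logging.getLogger(__name__)


@dataclass
class ScoreTable:
    """Per-sample FPS results.

    ``data`` columns: es_pro, es_anti, fps, fps_z, group (high/low/NA),
    indexed by sample id.  ``fps = es_pro - es_anti`` exactly; ``fps_z`` is
    the cohort z-score of fps.
    """

    data: pd.DataFrame
    method: str = "ssgsea"
    alpha: float = 0.25

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def fps(self) -> pd.Series:
        return self.data["fps"]

    @property
    def groups(self) -> pd.Series:
        return self.data["group"]

    def high_samples(self) -> list[str]:
        return list(self.data.index[self.data["group"] == "high"])

    def low_samples(self) -> list[str]:
        return list(self.data.index[self.data["group"] == "low"])


def ssgsea_es(values: pd.Series, gene_set, alpha: float = 0.25) -> float:
    """Single-sample enrichment score for one sample.

    Parameters
    ----------
    values
        Per-gene expression for one sample (index = gene ids).  NaNs are
        dropped before ranking.
    gene_set
        Iterable of gene ids.
    alpha
        Rank-weight exponent; 0 gives a pure rank walk.

    Genes are ordered by descending value; ties share an average rank used
    for the weights, while the walk order among ties is fixed by gene id so
    the score is deterministic.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    values = values.dropna()
    if not np.isfinite(values.to_numpy(dtype=float)).all():
        raise ValueError("expression values must be finite")
    n = len(values)
    genes = values.index
    in_set = np.asarray(genes.isin(set(gene_set)))
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError("gene set has no measured member")
    if n_in == n:
        raise ValueError("gene set covers every measured gene; ES undefined")

    vals = values.to_numpy(dtype=float)
    # descending ranks with average ties: top gene has rank weight n
    ranks = n + 1 - _rankdata(vals)
    # deterministic walk order: descending value, gene id breaks ties
    order = np.lexsort((np.asarray(genes), -vals))
    r_sorted = ranks[order]
    in_sorted = in_set[order]

    weights = r_sorted**alpha
    w_in = np.where(in_sorted, weights, 0.0)
    p_in = np.cumsum(w_in) / w_in.sum()
    p_out = np.cumsum(np.where(in_sorted, 0.0, 1.0)) / (n - n_in)
    return float(np.sum(p_in - p_out))


def compute_fps(
    matrix: OmicsMatrix,
    signature: FerroptosisSignature,
    alpha: float = 0.25,
    method: str = "ssgsea",
    max_missing_frac: float = 0.5,
) -> ScoreTable:
    """Score every sample (or cell) of ``matrix`` with the FPS model.

    ``method='ssgsea'`` (default) takes the difference of enrichment walks;
    ``method='zmean'`` takes mean cohort z-score of pro genes minus mean
    z-score of anti genes.  Samples missing more than ``max_missing_frac``
    of the signature genes keep their score but are flagged group=NA.
    """
    if method not in ("ssgsea", "zmean"):
        raise ValueError(f"unknown FPS method {method!r}")
    df = matrix.data
    pro = [g for g in signature.pro_genes if g in df.index]
    anti = [g for g in signature.anti_genes if g in df.index]
    if not pro or not anti:
        raise ValueError(
            f"signature coverage too low: {len(pro)} pro / {len(anti)} anti "
            "genes measured"
        )

    sig_genes = list(signature.pro_genes) + list(signature.anti_genes)
    measured = df.reindex(sig_genes)
    low_cov = (measured.isna().mean(axis=0) > max_missing_frac)
    if low_cov.any():
        log.warning(
            "%d sample(s) missing >%.0f%% of signature genes; group set to NA",
            int(low_cov.sum()), 100 * max_missing_frac,
        )

    if method == "ssgsea":
        es_pro = df.apply(lambda col: ssgsea_es(col, pro, alpha), axis=0)
        es_anti = df.apply(lambda col: ssgsea_es(col, anti, alpha), axis=0)
    else:
        z = df.loc[pro + anti].sub(df.loc[pro + anti].mean(axis=1), axis=0)
        sd = df.loc[pro + anti].std(axis=1, ddof=0).replace(0.0, np.nan)
        z = z.div(sd, axis=0)
        es_pro = z.loc[pro].mean(axis=0)
        es_anti = z.loc[anti].mean(axis=0)

    fps = es_pro - es_anti
    if len(fps) < 2 or fps.std(ddof=0) == 0:
        log.warning("fps_z undefined for a cohort of %d sample(s)", len(fps))
        fps_z = pd.Series(np.nan, index=fps.index)
    else:
        fps_z = (fps - fps.mean()) / fps.std(ddof=0)

    out = pd.DataFrame(
        {
            "es_pro": es_pro,
            "es_anti": es_anti,
            "fps": fps,
            "fps_z": fps_z,
            "group": "NA",
        }
    )
    out.attrs["low_coverage"] = list(out.index[low_cov.reindex(out.index, fill_value=False)])
    return ScoreTable(out, method=method, alpha=alpha)


def dichotomize(scores: ScoreTable, rule: str = "median", q: float = 0.5) -> ScoreTable:
    """Split scored samples into high/low FPS groups.

    Median rule: fps > median -> high, fps <= median -> low (samples exactly
    at the median go low).  ``rule='quantile'`` splits at the ``q``-quantile
    analogously.  Samples flagged low-coverage stay NA.
    """
    data = scores.data.copy()
    fps = data["fps"].dropna()
    if len(fps) < 2:
        raise ValueError("need at least 2 scored samples to dichotomize")
    if fps.nunique() == 1:
        raise ValueError("all scores identical; no high/low split exists")
    if rule == "median":
        cut = float(fps.median())
    elif rule == "quantile":
        if not 0.0 < q < 1.0:
            raise ValueError("quantile must lie in (0, 1)")
        cut = float(fps.quantile(q))
    else:
        raise ValueError(f"unknown dichotomization rule {rule!r}")
    group = pd.Series(
        np.where(data["fps"] > cut, "high", "low"), index=data.index
    )
    group[data["fps"].isna()] = "NA"
    for s in data.attrs.get("low_coverage", scores.data.attrs.get("low_coverage", [])):
        group[s] = "NA"
    data["group"] = group
    data.attrs.update(scores.data.attrs)
    data.attrs["cutoff"] = cut
    return ScoreTable(data, method=scores.method, alpha=scores.alpha)


def score_gene_sets(
    matrix: OmicsMatrix,
    collection: GeneSetCollection,
    alpha: float = 0.25,
) -> pd.DataFrame:
    """Enrichment score of every gene set for every sample.

    Returns a sets x samples DataFrame.  Sets with no measured gene are
    skipped with a log message.
    """
    rows = {}
    measured = set(matrix.data.index)
    for name, genes in collection.items():
        present = [g for g in genes if g in measured]
        if not present or len(present) == len(measured):
            log.info("skipping gene set %r (coverage %d/%d measured genes)",
                     name, len(present), len(measured))
            continue
        rows[name] = matrix.data.apply(
            lambda col: ssgsea_es(col, present, alpha), axis=0
        )
    if not rows:
        raise ValueError("no gene set could be scored on this matrix")
    return pd.DataFrame(rows).T
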