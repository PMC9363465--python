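"""Immunotherapy-response and immunogenicity association analysis.

High- vs low-FPS groups are compared on checkpoint-blockade response rates
(2x2 chi-square with Yates correction), survival (Kaplan-Meier + log-rank),
and continuous immune features (Spearman with the FPS, Wilcoxon between
groups).  Two canonical immune scores are provided:

* CYT (cytolytic activity): geometric mean of GZMA and PRF1 abundance on
  the linear scale.
* GEP (T-cell-inflamed gene expression profile): weighted mean of an
  18-gene panel on the log scale, uniform weights by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources as _ilres

import numpy as np
import pandas as pd

from .containers import ClinicalTable, OmicsMatrix
from .scoring import ScoreTable
from .stats import (
    TestResult,
    bh_fdr,
    chisq_2x2,
    km_estimate,
    logrank_test,
    spearman,
    wilcoxon_ranksum,
)

log = logging.getLogger(__name__)


@dataclass
class ResponseSummary:
    n_high: int
    n_low: int
    responders_high: int
    responders_low: int
    proportion_high: float
    proportion_low: float
    chi2: float
    p: float

    def contingency(self) -> tuple[int, int, int, int]:
        return (
            self.responders_high,
            self.n_high - self.responders_high,
            self.responders_low,
            self.n_low - self.responders_low,
        )


def response_analysis(groups: pd.Series, response: pd.Series,
                      yates: bool = True) -> ResponseSummary:
    """Responder-rate contingency analysis of high vs low FPS groups."""
    df = pd.DataFrame({"group": groups, "response": response}).dropna()
    df = df[(df["group"].isin(["high", "low"])) & (df["response"].isin(["R", "NR"]))]
    n_high = int((df["group"] == "high").sum())
    n_low = int((df["group"] == "low").sum())
    if n_high == 0 or n_low == 0:
        raise ValueError("both FPS groups must contain labelled samples")
    r_high = int(((df["group"] == "high") & (df["response"] == "R")).sum())
    r_low = int(((df["group"] == "low") & (df["response"] == "R")).sum())
    test = chisq_2x2(r_high, n_high - r_high, r_low, n_low - r_low, yates=yates)
    return ResponseSummary(
        n_high=n_high,
        n_low=n_low,
        responders_high=r_high,
        responders_low=r_low,
        proportion_high=r_high / n_high,
        proportion_low=r_low / n_low,
        chi2=test.statistic,
        p=test.p_value,
    )


def survival_split(
    scores: ScoreTable,
    clinical: ClinicalTable,
    endpoint: str = "PFS",
) -> dict:
    """Kaplan-Meier curves and log-rank test between high and low FPS groups."""
    time, event = clinical.survival(endpoint)
    groups = scores.groups.reindex(time.index)
    keep = groups.isin(["high", "low"])
    if keep.sum() < 0.5 * len(scores.data):
        raise ValueError(
            f"{endpoint} endpoint available for fewer than half the scored samples"
        )
    time, event, groups = time[keep], event[keep], groups[keep]
    curves = {}
    for g in ("high", "low"):
        t, e = time[groups == g], event[groups == g]
        if len(t) and e.sum() == 0:
            log.warning("group %r is fully censored for %s", g, endpoint)
        curves[g] = km_estimate(t, e)
    test = logrank_test(time, event, (groups == "high").astype(int))
    med_h = curves["high"].median_survival()
    med_l = curves["low"].median_survival()
    direction = "high" if med_h > med_l else ("low" if med_l > med_h else "tie")
    return {
        "km_high": curves["high"],
        "km_low": curves["low"],
        "test": test,
        "longer_survival_group": direction,
        "endpoint": endpoint.upper(),
    }


def cyt_score(
    expr: OmicsMatrix,
    genes: tuple[str, str] = ("GZMA", "PRF1"),
    pseudocount: float = 1.0,
) -> pd.Series:
    """Cytolytic activity: geometric mean of the two effector transcripts.

    Expression is assumed log2(x+1)-scale and is un-logged internally;
    CYT = sqrt((a + pc)(b + pc)) on the linear scale.
    """
    missing = [g for g in genes if g not in expr.data.index]
    if missing:
        raise ValueError(f"CYT genes absent from matrix: {missing}")
    linear = np.power(2.0, expr.data.loc[list(genes)].astype(float)) - 1.0
    if (linear < 0).any().any():
        raise ValueError("negative un-logged abundance; CYT expects log2(x+1) input")
    prod = (linear.iloc[0] + pseudocount) * (linear.iloc[1] + pseudocount)
    return np.sqrt(prod).rename("cyt")


def _default_gep_panel() -> pd.DataFrame:
    with _ilres.files("ferroscore.resources").joinpath("gep18.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def gep_score(
    expr: OmicsMatrix,
    panel: list[str] | None = None,
    weights: dict[str, float] | None = None,
    min_coverage: float = 0.8,
) -> pd.Series:
    """T-cell-inflamed GEP: weighted mean of panel genes on the log scale.

    Defaults to the 18-gene inflamed-tumor panel with uniform weights;
    weights are renormalized over the measured subset.  Fails if fewer than
    ``min_coverage`` of the panel genes are measured.
    """
    if panel is None:
        table = _default_gep_panel()
        panel = table["gene"].tolist()
        if weights is None:
            weights = dict(zip(table["gene"], table["weight"]))
    if weights is None:
        weights = {g: 1.0 for g in panel}
    measured = [g for g in panel if g in expr.data.index]
    coverage = len(measured) / len(panel)
    if coverage < min_coverage:
        missing = sorted(set(panel) - set(measured))
        raise ValueError(
            f"GEP panel coverage {coverage:.0%} below {min_coverage:.0%}; "
            f"missing genes: {missing}"
        )
    w = np.array([weights.get(g, 1.0) for g in measured], dtype=float)
    w = w / w.sum()
    vals = expr.data.loc[measured].astype(float)
    return vals.mul(w, axis=0).sum(axis=0).rename("gep")


def association_report(
    scores: ScoreTable,
    features: pd.DataFrame,
    min_overlap: int = 3,
) -> pd.DataFrame:
    """Associate each immune feature with the FPS.

    ``features`` is a samples x features frame (BCR/TCR richness, TIL
    fraction, PDL1, GEP, CYT, ...).  Per feature: Spearman rho against the
    FPS and a two-sided Wilcoxon rank-sum between high and low groups, each
    BH-adjusted across features.
    """
    fps = scores.fps
    groups = scores.groups
    rows = []
    for col in features.columns:
        joined = pd.concat([fps, features[col]], axis=1, join="inner").dropna()
        if len(joined) < min_overlap:
            log.warning("feature %r skipped: only %d overlapping samples",
                        col, len(joined))
            continue
        sp = spearman(joined.iloc[:, 0], joined.iloc[:, 1])
        hi = joined.index.intersection(groups.index[groups == "high"])
        lo = joined.index.intersection(groups.index[groups == "low"])
        if len(hi) and len(lo):
            wx = wilcoxon_ranksum(joined.loc[hi, col], joined.loc[lo, col])
            p_wx = wx.p_value
        else:
            p_wx = np.nan
        rows.append(
            {
                "feature": col,
                "n": len(joined),
                "rho": sp.statistic,
                "p_spearman": sp.p_value,
                "p_wilcoxon_high_vs_low": p_wx,
            }
        )
    if not rows:
        raise ValueError("no feature had enough overlapping samples")
    out = pd.DataFrame(rows)
    out["q_spearman"] = bh_fdr(out["p_spearman"].to_numpy())
    ok = out["p_wilcoxon_high_vs_low"].notna()
    out["q_wilcoxon"] = np.nan
    if ok.any():
        out.loc[ok, "q_wilcoxon"] = bh_fdr(out.loc[ok, "p_wilcoxon_high_vs_low"])
    return out
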