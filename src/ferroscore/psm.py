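"""Propensity-score-matched differential feature identification.

Comparing molecular features between high- and low-FPS tumors naively is
confounded by clinical structure (tumor purity, stage, age ...) that
correlates with both group membership and the molecular readouts.  This
module controls that confounding the way observational studies do:

1. fit a logistic propensity model P(high | covariates);
2. greedily match each high-FPS sample to its nearest low-FPS neighbour on
   the logit-propensity scale, within a caliper, without replacement;
3. check covariate balance via standardized mean differences (SMD);
4. test each feature between the matched groups (two-sided Wilcoxon
   rank-sum) with per-layer Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import OmicsMatrix
from .stats import bh_fdr, wilcoxon_ranksum

log = logging.getLogger(__name__)


@dataclass
class PropensityFit:
    propensity: pd.Series
    beta: np.ndarray
    feature_names: list[str]
    log_likelihood: float
    converged: bool
    n_iter: int
    separated: bool = False
    dropped: list[str] = field(default_factory=list)


@dataclass
class MatchResult:
    propensity: pd.Series
    pairs: list[tuple[str, str]]          # (high sample, low sample)
    caliper: float                         # logit scale
    unmatched: list[str]
    balance: pd.DataFrame | None = None    # per-covariate smd_before/after

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def matched_samples(self) -> tuple[list[str], list[str]]:
        return [h for h, _ in self.pairs], [l for _, l in self.pairs]


def encode_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode categorical columns (drop-first), keep numerics."""
    parts = []
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float))
        else:
            dummies = pd.get_dummies(s.astype("category"), prefix=col, drop_first=True)
            parts.append(dummies.astype(float))
    return pd.concat(parts, axis=1)


def fit_propensity(
    covariates: pd.DataFrame,
    group: pd.Series,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> PropensityFit:
    """Logistic-regression propensity model fitted by IRLS.

    ``group`` holds 1/True for the treated (high-FPS) samples.  Constant
    covariates are dropped with a log message.  Perfect separation is
    flagged and propensities clipped to [1e-6, 1 - 1e-6] rather than
    silently returning degenerate scores.
    """
    covariates = encode_covariates(covariates)
    y = group.reindex(covariates.index).astype(float).to_numpy()
    if covariates.isna().any().any() or np.isnan(y).any():
        raise ValueError("covariates and group must be complete (no NaN)")
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 samples in each group")

    dropped = [c for c in covariates.columns if covariates[c].nunique() <= 1]
    if dropped:
        log.warning("dropping constant covariate(s): %s", dropped)
        covariates = covariates.drop(columns=dropped)

    X = np.column_stack([np.ones(len(y)), covariates.to_numpy(dtype=float)])
    beta = np.zeros(X.shape[1])
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    logl = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = np.clip(mu * (1 - mu), 1e-12, None)
        z = eta + (y - mu) / w
        wx = X * w[:, None]
        try:
            new_beta = np.linalg.solve(X.T @ wx, wx.T @ z)
        except np.linalg.LinAlgError:
            break
        new_eta = np.clip(X @ new_beta, -500, 500)
        new_mu = 1.0 / (1.0 + np.exp(-new_eta))
        new_mu = np.clip(new_mu, 1e-15, 1 - 1e-15)
        new_logl = float(np.sum(y * np.log(new_mu) + (1 - y) * np.log(1 - new_mu)))
        beta, eta, mu = new_beta, new_eta, new_mu
        if abs(new_logl - logl) < tol:
            logl = new_logl
            converged = True
            break
        logl = new_logl

    fitted = 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -500, 500)))
    # perfect separation: fitted probabilities pinned to the labels
    separated = bool(np.all(np.abs(fitted - y) < 1e-4)) and covariates.shape[1] > 0
    if separated:
        log.warning(
            "propensity model is perfectly separated; scores clipped — "
            "matched estimates are unreliable"
        )
    propensity = pd.Series(
        np.clip(fitted, 1e-6, 1 - 1e-6), index=covariates.index, name="propensity"
    )
    return PropensityFit(
        propensity=propensity,
        beta=beta,
        feature_names=["intercept", *covariates.columns],
        log_likelihood=logl,
        converged=converged,
        n_iter=it,
        separated=separated,
        dropped=dropped,
    )


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def match_nearest(
    propensity: pd.Series,
    group: pd.Series,
    ratio: int = 1,
    caliper_sd: float = 0.2,
    replacement: bool = False,
    seed: int | None = None,
) -> MatchResult:
    """Greedy 1:ratio nearest-neighbour matching on the logit-propensity scale.

    The caliper is ``caliper_sd`` times the pooled (across groups) SD of the
    logit propensity.  Treated samples are processed in descending
    propensity order; distance ties between candidate controls are broken
    by lexicographic sample id.  Deterministic for fixed inputs (``seed``
    is accepted for interface symmetry but no randomness is used).
    """
    group = group.reindex(propensity.index)
    treated = propensity.index[group.astype(bool)]
    control = propensity.index[~group.astype(bool)]
    if len(treated) == 0 or len(control) == 0:
        raise ValueError("both groups must be non-empty")

    lp = pd.Series(_logit(propensity.to_numpy(dtype=float)), index=propensity.index)
    var_t = lp[treated].var(ddof=1) if len(treated) > 1 else 0.0
    var_c = lp[control].var(ddof=1) if len(control) > 1 else 0.0
    pooled_sd = math.sqrt(0.5 * (var_t + var_c))
    caliper = caliper_sd * pooled_sd

    # descending propensity, lexicographic id on ties
    t_order = sorted(treated, key=lambda s: (-propensity[s], s))
    available = set(control)
    pairs: list[tuple[str, str]] = []
    unmatched: list[str] = []
    for t in t_order:
        matched_here = 0
        for _ in range(max(ratio, 1)):
            pool = available if not replacement else set(control)
            if not pool:
                break
            cands = sorted(pool, key=lambda c: (abs(lp[c] - lp[t]), c))
            best = cands[0]
            if abs(lp[best] - lp[t]) <= caliper + 1e-12:
                pairs.append((t, best))
                if not replacement:
                    available.discard(best)
                matched_here += 1
            else:
                break
        if matched_here == 0:
            unmatched.append(t)
    if not pairs:
        raise ValueError(
            "no matched pairs formed; consider relaxing the caliper "
            f"(current caliper {caliper:.4g} on the logit scale)"
        )
    unmatched += sorted(set(control) - {c for _, c in pairs})
    return MatchResult(
        propensity=propensity, pairs=pairs, caliper=caliper, unmatched=unmatched
    )


def balance_smd(
    covariates: pd.DataFrame,
    group: pd.Series,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Standardized mean differences before and after matching.

    SMD = (mean_high - mean_low) / pooled SD, where the pooled SD is taken
    over the full (pre-match) cohort so before/after values share a scale.
    Binary 0/1 columns reduce to the proportion difference over the pooled
    binary SD.  Zero pooled SD yields SMD = 0 with a warning.
    """
    covariates = encode_covariates(covariates)
    group = group.reindex(covariates.index).astype(bool)
    rows = {}
    high_m, low_m = ([], [])
    if pairs:
        high_m = [h for h, _ in pairs]
        low_m = [l for _, l in pairs]
    for col in covariates.columns:
        s = covariates[col].astype(float)
        sd = math.sqrt(0.5 * (s[group].var(ddof=1) + s[~group].var(ddof=1)))
        if sd == 0 or not np.isfinite(sd):
            log.warning("zero pooled SD for covariate %r; SMD set to 0", col)
            rows[col] = (0.0, 0.0 if pairs else np.nan)
            continue
        before = (s[group].mean() - s[~group].mean()) / sd
        after = np.nan
        if pairs:
            after = (s[high_m].mean() - s[low_m].mean()) / sd
        rows[col] = (before, after)
    return pd.DataFrame(rows, index=["smd_before", "smd_after"]).T


def differential_features(
    layer: OmicsMatrix,
    pairs: list[tuple[str, str]],
    test: str = "wilcoxon",
    q_threshold: float = 0.05,
    effect_threshold: float = 0.0,
    paired: bool = False,
) -> pd.DataFrame:
    """Per-feature differential testing between matched high and low samples.

    Effect size is mean(high) - mean(low): a log2 fold change for
    mRNA/miRNA/protein layers, a delta-beta for methylation.  Two-sided
    Wilcoxon rank-sum p-values are BH-adjusted within the layer; a feature
    is significant iff q < ``q_threshold`` and |effect| >= ``effect_threshold``.
    ``paired=True`` switches to the Wilcoxon signed-rank test on pair
    differences (normal approximation).
    """
    if test != "wilcoxon":
        raise ValueError(f"unknown test {test!r}")
    if len(pairs) < 3:
        raise ValueError("need at least 3 matched pairs for differential testing")
    high_ids = [h for h, _ in pairs]
    low_ids = [l for _, l in pairs]
    missing = [s for s in high_ids + low_ids if s not in layer.data.columns]
    if missing:
        raise ValueError(f"matched samples absent from layer: {missing[:5]}")

    H = layer.data[high_ids].to_numpy(dtype=float)
    L = layer.data[low_ids].to_numpy(dtype=float)
    feats = layer.feature_ids
    effects = np.empty(len(feats))
    pvals = np.empty(len(feats))
    n_dropped = 0
    for i in range(len(feats)):
        h = H[i][~np.isnan(H[i])]
        l = L[i][~np.isnan(L[i])]
        n_dropped += (len(high_ids) - h.size) + (len(low_ids) - l.size)
        if h.size == 0 or l.size == 0:
            effects[i], pvals[i] = np.nan, np.nan
            continue
        effects[i] = h.mean() - l.mean()
        both = np.concatenate([h, l])
        if np.unique(both).size == 1:
            pvals[i] = 1.0
            effects[i] = 0.0
            continue
        if paired and h.size == l.size:
            pvals[i] = _signed_rank_p(h - l)
        else:
            pvals[i] = wilcoxon_ranksum(h, l).p_value
    if n_dropped:
        log.info("dropped %d missing values across features during testing", n_dropped)

    ok = ~np.isnan(pvals)
    q = np.full(len(feats), np.nan)
    if ok.any():
        q[ok] = bh_fdr(pvals[ok])
    effect_col = "delta_beta" if layer.layer == "methylation" else "log2fc"
    out = pd.DataFrame(
        {
            "feature": feats,
            "layer": layer.layer,
            "effect": effects,
            "p": pvals,
            "q": q,
            "direction": np.where(effects > 0, "up_in_high", "up_in_low"),
            "significant": ok
            & (q < q_threshold)
            & (np.abs(effects) >= effect_threshold),
        }
    )
    out.attrs["effect_measure"] = effect_col
    out.attrs["n_pairs"] = len(pairs)
    return out


def _signed_rank_p(diffs: np.ndarray) -> float:
    """Wilcoxon signed-rank test, normal approximation with tie correction."""
    from .stats import _rankdata
    from scipy import stats as _dist

    d = diffs[diffs != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = _rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (counts**3 - counts).sum() / 48.0
    if var <= 0:
        return 1.0
    z = (abs(w_plus - mu) - 0.5) / math.sqrt(var)
    return float(min(2.0 * _dist.norm.sf(max(z, 0.0)), 1.0))


def extract_gene_panel(results: pd.DataFrame, panel: list[str]) -> pd.DataFrame:
    """Restrict a differential table to a gene panel (e.g. actionable genes).

    Panel genes absent from the tested features are reported with
    ``tested=False`` so the caller can see what the layer never measured.
    """
    if not panel:
        raise ValueError("empty gene panel")
    panel = [str(g).strip() for g in panel]
    indexed = results.set_index("feature")
    rows = []
    for g in panel:
        if g in indexed.index:
            r = indexed.loc[g]
            rows.append(
                {
                    "feature": g, "tested": True, "effect": r["effect"],
                    "p": r["p"], "q": r["q"], "direction": r["direction"],
                    "significant": bool(r["significant"]),
                }
            )
        else:
            rows.append(
                {
                    "feature": g, "tested": False, "effect": np.nan,
                    "p": np.nan, "q": np.nan, "direction": "NA",
                    "significant": False,
                }
            )
    return pd.DataFrame(rows)
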