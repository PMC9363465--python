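"""Outcome-based screening of candidate ferroptosis genes.

Starting from a curated annotation of candidate genes (role: pro- or
anti-ferroptosis, a FerrDB-style export), each gene is tested for overall-
survival association — either a log-rank test on the median split of its
expression or a univariate Cox fit on the continuous value — and genes
passing the p threshold form the FerroptosisSignature.  Roles are taken
from the annotation and never inferred from hazard direction; the hazard
direction is reported for audit.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ClinicalTable, FerroptosisSignature, OmicsMatrix
from .stats import bh_fdr, cox_ph, logrank_test

log = logging.getLogger(__name__)


class ScreeningError(ValueError):
    """Raised when screening cannot produce a valid signature."""

    def __init__(self, message: str, report: pd.DataFrame | None = None):
        super().__init__(message)
        self.report = report


def screen_frgs(
    expr: OmicsMatrix,
    clinical: ClinicalTable,
    candidates: pd.DataFrame,
    threshold: float = 0.05,
    method: str = "logrank_median",
    adjust: str | None = None,
) -> tuple[FerroptosisSignature, pd.DataFrame]:
    """Screen annotated candidates down to outcome-associated genes.

    Parameters
    ----------
    candidates
        DataFrame with columns ``gene`` and ``role`` (pro/anti).
    threshold
        Keep genes with p (or BH q if ``adjust='bh'``) below this value.
    method
        ``logrank_median``: median-split the gene, log-rank on OS.
        ``cox_continuous``: univariate Cox on the continuous expression.

    Returns the assembled signature and a per-gene report (gene, role,
    screen_p, hazard_direction, kept, reason).  Screening is order-invariant
    over the candidate list.
    """
    if method not in ("logrank_median", "cox_continuous"):
        raise ValueError(f"unknown screening method {method!r}")
    if candidates.empty:
        raise ValueError("candidate list is empty")
    bad_roles = set(candidates["role"]) - {"pro", "anti"}
    if bad_roles:
        raise ValueError(f"unknown candidate roles: {sorted(bad_roles)}")
    time, event = clinical.survival("OS")
    samples = [s for s in expr.sample_ids if s in time.index]
    if len(samples) < 10:
        raise ValueError(f"need >=10 samples with OS data, have {len(samples)}")
    time = time[samples]
    event = event[samples]

    rows = []
    for _, cand in candidates.sort_values("gene", kind="mergesort").iterrows():
        gene, role = str(cand["gene"]).strip(), cand["role"]
        if gene not in expr.data.index:
            rows.append((gene, role, np.nan, "NA", False, "unmeasured"))
            continue
        vals = expr.data.loc[gene, samples].astype(float)
        if vals.isna().any():
            keep_mask = vals.notna()
            v, t, e = vals[keep_mask], time[keep_mask], event[keep_mask]
        else:
            v, t, e = vals, time, event
        if v.nunique() <= 1:
            rows.append((gene, role, np.nan, "NA", False, "constant"))
            continue
        try:
            if method == "logrank_median":
                high = (v > v.median()).astype(int)
                if high.nunique() < 2:
                    rows.append((gene, role, np.nan, "NA", False, "degenerate_split"))
                    continue
                res = logrank_test(t, e, high)
                p = res.p_value
                # direction from the group with longer observed survival
                direction = _median_direction(t, e, high)
            else:
                fit = cox_ph(t, e, v.to_numpy())
                if not fit.converged:
                    rows.append((gene, role, np.nan, "NA", False, "non_converged"))
                    continue
                p = float(fit.p[0])
                direction = "protective" if fit.beta[0] < 0 else "adverse"
        except ValueError as exc:
            rows.append((gene, role, np.nan, "NA", False, f"test_error:{exc}"))
            continue
        rows.append((gene, role, p, direction, False, ""))

    report = pd.DataFrame(
        rows, columns=["gene", "role", "screen_p", "hazard_direction", "kept", "reason"]
    )
    tested = report["screen_p"].notna()
    crit = report["screen_p"].copy()
    if adjust == "bh" and tested.any():
        crit[tested] = bh_fdr(report.loc[tested, "screen_p"].to_numpy())
        report["screen_q"] = crit
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    report.loc[tested & (crit < threshold), "kept"] = True
    report.loc[~report["kept"] & (report["reason"] == ""), "reason"] = "p_above_threshold"

    pro = report.loc[report["kept"] & (report["role"] == "pro"), "gene"].tolist()
    anti = report.loc[report["kept"] & (report["role"] == "anti"), "gene"].tolist()
    if not pro or not anti:
        raise ScreeningError(
            f"screening kept {len(pro)} pro and {len(anti)} anti genes; "
            "a signature needs both roles",
            report=report,
        )
    provenance = (
        f"screen method={method} threshold={threshold} adjust={adjust} "
        f"n_samples={len(samples)} n_candidates={len(candidates)}"
    )
    return FerroptosisSignature(tuple(pro), tuple(anti), provenance), report


def _median_direction(time, event, high) -> str:
    from .stats import km_estimate

    km_h = km_estimate(time[high == 1], event[high == 1])
    km_l = km_estimate(time[high == 0], event[high == 0])
    mh, ml = km_h.median_survival(), km_l.median_survival()
    if mh == ml:
        return "NA"
    return "protective" if mh > ml else "adverse"


def rank_scores_by_cox(
    score_stack: pd.DataFrame,
    clinical: ClinicalTable,
    endpoint: str = "OS",
) -> pd.DataFrame:
    """Rank gene-set scores by univariate Cox association with survival.

    ``score_stack`` is a sets x samples frame (e.g. the FPS alongside the
    50 cancer-hallmark scores).  Each row is z-scaled across samples and
    fed to a univariate Cox fit; the result is sorted by p ascending, ties
    by |z| descending; non-converged fits sort last and are flagged.
    """
    time, event = clinical.survival(endpoint)
    samples = [s for s in score_stack.columns if s in time.index]
    if len(samples) < 3:
        raise ValueError("too few samples shared between scores and clinical data")
    time, event = time[samples], event[samples]
    rows = []
    for name, vals in score_stack[samples].iterrows():
        v = vals.astype(float)
        sd = v.std(ddof=0)
        if sd == 0 or v.isna().any():
            rows.append((name, np.nan, np.nan, np.nan, np.nan, False))
            continue
        z = (v - v.mean()) / sd
        fit = cox_ph(time, event, z.to_numpy())
        rows.append(
            (
                name,
                float(fit.beta[0]),
                float(fit.hazard_ratio[0]),
                float(fit.z[0]),
                float(fit.p[0]),
                fit.converged,
            )
        )
    out = pd.DataFrame(
        rows, columns=["set", "beta", "hazard_ratio", "z", "p", "converged"]
    )
    out["abs_z"] = out["z"].abs()
    out = out.sort_values(
        ["converged", "p", "abs_z", "set"],
        ascending=[False, True, False, True],
        kind="mergesort",
    ).drop(columns="abs_z")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)
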