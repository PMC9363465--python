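"""Synthetic multi-omics cohort generator with full ground truth.

The generator encodes the statistical structure the analysis assumes:

* a latent per-sample ferroptosis activity f ~ N(0, 1);
* a clinical confounder c = rho*f + sqrt(1-rho^2)*eps correlated with both
  group membership and molecular features (surfaced as tumor purity and
  stage covariates);
* signature genes loading +loading_strength (pro) or -loading_strength
  (anti) on f; planted differential features loading on f in each layer;
  confounder-only features loading on c alone;
* methylation passed through a logistic squash so beta values stay in (0,1);
* exponential survival with log-hazard decreasing in f; Bernoulli
  checkpoint-blockade response increasing in f.

Every random draw flows from one seeded generator, so a (config, seed)
pair regenerates the cohort byte-identically, and the returned truth
object records every planted element for acceptance-style checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import ClinicalTable, FerroptosisSignature, OmicsMatrix

# E[f | f > median] - E[f | f < median] for standard-normal f; converts a
# loading on f into the expected high-vs-low group mean difference.
_MEDIAN_SPLIT_GAP = 2.0 * math.sqrt(2.0 / math.pi)

_IMMUNE_GENES = (
    "GZMA", "PRF1",  # cytolytic activity
    "CCL5", "CD27", "CD274", "CD276", "CD8A", "CMKLR1", "CXCL9", "CXCR6",
    "HLA-DQA1", "HLA-DRB1", "HLA-E", "IDO1", "LAG3", "NKG7", "PDCD1LG2",
    "PSMB10", "STAT1", "TIGIT",  # T-cell-inflamed GEP panel
)


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic cohort.

    Effects are in units of the feature noise SD: ``planted_effect`` is the
    expected high-vs-low group mean difference of a planted feature, and
    ``loading_strength`` the per-SD-of-f shift of a signature gene.
    """

    n_samples: int = 200
    n_features: dict = field(
        default_factory=lambda: {
            "mrna": 500, "mirna": 120, "methylation": 300, "protein": 100
        }
    )
    n_pro: int = 16
    n_anti: int = 16
    loading_strength: float = 1.0
    confounder_strength: float = 0.5       # corr(f, c)
    n_planted_up: dict = field(default_factory=dict)    # per layer, default 0
    n_planted_down: dict = field(default_factory=dict)
    n_confounded: dict = field(default_factory=dict)    # c-only null features
    planted_effect: float = 1.5            # group mean diff, noise-SD units
    confounded_effect: float = 1.5         # c loading of confounder-only features
    noise_sd: float = 1.0
    baseline_hazard: float = 1.0 / 700.0   # per day; median OS ~ 485 days at f=0
    hazard_beta: float = 0.7               # protective effect of f on log-hazard
    censor_rate: float = 0.3
    response_slope: float = 1.5            # logistic slope of P(responder) on f
    pfs_response_hr: float = 0.4           # PFS hazard ratio of responders
    expression_baseline: float = 6.0       # log2-scale mean of expression layers
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_pro", "n_anti"):
            if getattr(self, name) < 0:
                raise ValueError(f"invalid config field {name}: must be >= 0")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("invalid config field censor_rate: must be in [0, 1)")
        if not -1.0 <= self.confounder_strength <= 1.0:
            raise ValueError(
                "invalid config field confounder_strength: must be in [-1, 1]"
            )
        if self.n_pro + self.n_anti > self.n_features.get("mrna", 0):
            raise ValueError(
                "invalid config field n_pro/n_anti: signature larger than mrna layer"
            )
        if self.noise_sd <= 0:
            raise ValueError("invalid config field noise_sd: must be > 0")
        if self.baseline_hazard <= 0:
            raise ValueError("invalid config field baseline_hazard: must be > 0")


@dataclass
class SyntheticCohort:
    layers: dict[str, OmicsMatrix]
    clinical: ClinicalTable
    latent: pd.Series                      # true ferroptosis activity f
    confounder: pd.Series                  # true confounder c
    signature: FerroptosisSignature | None  # None when no signature genes planted
    planted: pd.DataFrame                  # layer, feature, kind, loading
    config: SimulationConfig

    def planted_features(self, layer: str, kinds=("up", "down")) -> list[str]:
        mask = (self.planted["layer"] == layer) & self.planted["kind"].isin(kinds)
        return self.planted.loc[mask, "feature"].tolist()


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one cohort under the configured generative model."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(n)]

    f = rng.normal(size=n)
    rho = config.confounder_strength
    c = rho * f + math.sqrt(max(1.0 - rho**2, 0.0)) * rng.normal(size=n)

    planted_rows = []
    layers: dict[str, OmicsMatrix] = {}
    pro_genes = tuple(f"PRO{i:02d}" for i in range(config.n_pro))
    anti_genes = tuple(f"ANTI{i:02d}" for i in range(config.n_anti))
    planted_loading = (
        config.planted_effect * config.noise_sd / _MEDIAN_SPLIT_GAP
    )

    for layer, n_feat in config.n_features.items():
        n_up = config.n_planted_up.get(layer, 0)
        n_dn = config.n_planted_down.get(layer, 0)
        n_cf = config.n_confounded.get(layer, 0)
        names: list[str] = []
        lam = np.zeros(0)
        gam = np.zeros(0)

        def block(prefix, count, lam_val, gam_val):
            nonlocal lam, gam
            ids = [f"{layer}_{prefix}{i:03d}" for i in range(count)]
            names.extend(ids)
            lam = np.concatenate([lam, np.full(count, lam_val)])
            gam = np.concatenate([gam, np.full(count, gam_val)])
            return ids

        if layer == "mrna":
            names.extend(pro_genes)
            lam = np.concatenate([lam, np.full(config.n_pro, config.loading_strength)])
            gam = np.concatenate([gam, np.zeros(config.n_pro)])
            names.extend(anti_genes)
            lam = np.concatenate([lam, np.full(config.n_anti, -config.loading_strength)])
            gam = np.concatenate([gam, np.zeros(config.n_anti)])
        up_ids = block("up", n_up, planted_loading, 0.0)
        dn_ids = block("dn", n_dn, -planted_loading, 0.0)
        cf_loading = config.confounded_effect * config.noise_sd / _MEDIAN_SPLIT_GAP
        cf_ids = block("cf", n_cf, 0.0, cf_loading)
        n_null = n_feat - len(names)
        if n_null < 0:
            raise ValueError(
                f"invalid config field n_features[{layer}]: smaller than the "
                "planted + signature blocks"
            )
        null_ids = block("null", n_null, 0.0, 0.0)
        if layer == "mrna" and len(null_ids) >= len(_IMMUNE_GENES):
            # name trailing null genes after canonical immune markers so the
            # CYT/GEP stage runs on synthetic cohorts (they carry no signal)
            for k, g in enumerate(_IMMUNE_GENES, start=1):
                names[len(names) - k] = g

        values = (
            lam[:, None] * f[None, :]
            + gam[:, None] * c[None, :]
            + rng.normal(scale=config.noise_sd, size=(len(names), n))
        )
        if layer == "methylation":
            values = _sigmoid(values)
        else:
            values = values + config.expression_baseline
        df = pd.DataFrame(values, index=names, columns=samples)
        layers[layer] = OmicsMatrix(df, layer)

        for ids, kind in ((up_ids, "up"), (dn_ids, "down"), (cf_ids, "confounded")):
            loading = {"up": planted_loading, "down": -planted_loading,
                       "confounded": cf_loading}[kind]
            planted_rows += [
                {"layer": layer, "feature": fid, "kind": kind, "loading": loading}
                for fid in ids
            ]
    for g in pro_genes:
        planted_rows.append(
            {"layer": "mrna", "feature": g, "kind": "signature_pro",
             "loading": config.loading_strength}
        )
    for g in anti_genes:
        planted_rows.append(
            {"layer": "mrna", "feature": g, "kind": "signature_anti",
             "loading": -config.loading_strength}
        )

    # survival: exponential with log-hazard = log(h0) - hazard_beta * f
    rate = config.baseline_hazard * np.exp(-config.hazard_beta * f)
    os_time = rng.exponential(1.0 / rate)
    censored = rng.random(n) < config.censor_rate
    os_obs = np.where(censored, os_time * rng.random(n), os_time)
    os_event = (~censored).astype(int)

    # checkpoint-blockade response increasing in f
    p_resp = _sigmoid(config.response_slope * f)
    resp = np.where(rng.random(n) < p_resp, "R", "NR")

    # PFS: responders progress slower
    pfs_rate = (
        2.0 * config.baseline_hazard
        * np.exp(-config.hazard_beta * f)
        * np.where(resp == "R", config.pfs_response_hr, 1.0)
    )
    pfs_time = rng.exponential(1.0 / pfs_rate)
    pfs_cens = rng.random(n) < config.censor_rate
    pfs_obs = np.where(pfs_cens, pfs_time * rng.random(n), pfs_time)
    pfs_event = (~pfs_cens).astype(int)

    purity = _sigmoid(c)
    stage_latent = 0.8 * c + 0.6 * rng.normal(size=n)
    stage = pd.qcut(stage_latent, 4, labels=["I", "II", "III", "IV"]).astype(str)
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "os_time": np.round(os_obs, 3),
                "os_event": os_event,
                "pfs_time": np.round(pfs_obs, 3),
                "pfs_event": pfs_event,
                "response": resp,
                "age": np.round(rng.normal(60, 10, n), 1),
                "gender": rng.choice(["M", "F"], n),
                "stage": stage,
                "tumor_purity": np.round(purity, 4),
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )
    signature = None
    if pro_genes and anti_genes:
        signature = FerroptosisSignature(
            pro_genes, anti_genes,
            provenance=f"simulated, loading={config.loading_strength}, seed={config.seed}",
        )
    return SyntheticCohort(
        layers=layers,
        clinical=clinical,
        latent=pd.Series(f, index=samples, name="latent_activity"),
        confounder=pd.Series(c, index=samples, name="confounder"),
        signature=signature,
        planted=pd.DataFrame(
            planted_rows, columns=["layer", "feature", "kind", "loading"]
        ),
        config=config,
    )


def generate_icb_cohort(
    config: SimulationConfig,
    n: int = 62,
    n_responders: int = 33,
) -> SyntheticCohort:
    """Cohort conditioned to an exact responder count.

    Mirrors an anti-PD-1-treated cohort of fixed size: the marginal model
    of :func:`generate_cohort` is drawn, then the response labels are
    re-drawn conditioned on the exact responder count — an intercept is
    calibrated so the expected count matches, and Bernoulli vectors are
    rejection-sampled until the realized count is exact, which preserves
    the response-activity coupling.  PFS is re-drawn so progression stays
    coupled to the realized response labels.
    """
    if not 0 <= n_responders <= n:
        raise ValueError(f"infeasible counts: {n_responders} responders of {n}")
    cfg = replace(config, n_samples=n)
    cohort = generate_cohort(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 62]))
    f = cohort.latent.to_numpy()
    if n_responders == 0:
        resp = np.full(n, "NR")
    elif n_responders == n:
        resp = np.full(n, "R")
    else:
        # calibrate intercept a so sum sigmoid(a + slope*f) = n_responders
        lo_a, hi_a = -50.0, 50.0
        for _ in range(200):
            a = 0.5 * (lo_a + hi_a)
            if _sigmoid(a + cfg.response_slope * f).sum() < n_responders:
                lo_a = a
            else:
                hi_a = a
        p = _sigmoid(a + cfg.response_slope * f)
        for _ in range(100_000):
            draw = rng.random(n) < p
            if draw.sum() == n_responders:
                break
        else:  # pragma: no cover - astronomically unlikely after calibration
            order = np.argsort(-p)
            draw = np.zeros(n, bool)
            draw[order[:n_responders]] = True
        resp = np.where(draw, "R", "NR")
    clin = cohort.clinical.data.copy()
    clin["response"] = resp
    pfs_rate = (
        2.0 * cfg.baseline_hazard
        * np.exp(-cfg.hazard_beta * f)
        * np.where(resp == "R", cfg.pfs_response_hr, 1.0)
    )
    pfs_time = rng.exponential(1.0 / pfs_rate)
    pfs_cens = rng.random(n) < cfg.censor_rate
    clin["pfs_time"] = np.round(np.where(pfs_cens, pfs_time * rng.random(n), pfs_time), 3)
    clin["pfs_event"] = (~pfs_cens).astype(int)
    return replace(cohort, clinical=ClinicalTable(clin))


def generate_confounded_pair(
    config: SimulationConfig,
) -> tuple[pd.Series, SyntheticCohort]:
    """Confounding stress-test cohort plus naive group labels.

    The cohort's planted null features load on the confounder only, so a
    naive high-vs-low comparison is biased while a matched comparison is
    calibrated.  The returned groups are the median split of the latent
    activity (the population the score split estimates).
    """
    import warnings

    if config.confounder_strength == 0:
        warnings.warn("confounder_strength is 0; there is no confounding to remove")
    cfg = config
    if not any(cfg.n_confounded.values()):
        cfg = replace(
            config, n_confounded={layer: 50 for layer in config.n_features}
        )
    cohort = generate_cohort(cfg)
    f = cohort.latent
    groups = pd.Series(
        np.where(f > f.median(), "high", "low"), index=f.index, name="group"
    )
    return groups, cohort
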