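"""Synthetic two-timepoint cohorts with known ground truth.

The study population this emulates is a small school cohort: children and
their adult family members assessed at the start and end of a school
year.  Every generated table uses exactly the formats the scoring modules
consume, and the generator's ground truth is rich enough to check every
pipeline stage analytically:

* **Diet.**  Each subject has a latent diet quality ``T ~ N(0, latent_sd)``
  and a time-specific value ``Q_t = T + delta_t`` with
  ``delta_t ~ N(0, sigma_within)`` (test-retest variability).  Item-level
  consumption propensity is ``w_i * Q_t + b + eps_i`` where healthy items
  load positively (``w_i = +item_loading``), sugary drinks and
  red/processed meat negatively, neutral items not at all; ``b`` is a
  per-subject over/under-reporting bias shared by every item and
  ``eps_i`` is item noise drawn once per subject (so a noiseless retest,
  ``sigma_within = 0``, reproduces baseline responses exactly).
  Propensities are discretized into the dialect's ordinal categories by
  fixed thresholds chosen so every category keeps >=5% mass at defaults.

* **Likert scales.**  One-factor model per construct:
  ``x_j = lambda * F + sqrt(1 - lambda^2) * e_j`` cut into 4 categories.
  ``lambda`` is *calibrated numerically* (bivariate-normal cell
  probabilities + bisection) so the observed Pearson inter-item
  correlation of the discretized items equals ``target_interitem_r``;
  hence the population alpha of a k-item scale is the closed form
  ``k r / (1 + (k-1) r)`` and parameter recovery can be asserted exactly.
  The self-efficacy factor (the child reference construct) carries the
  programmed correlation ``rho`` with the child's latent diet quality;
  the tendency-to-choose factor is independent of it.

* **Adult references.**  FFQ F&V servings and the obesogenic index are
  linear-Gaussian in the standardized time-specific diet quality with
  programmed correlation ``+rho`` / ``-rho`` (then floored at 0
  servings), anchored to realistic scales (FFQ mean 3.0 / SD 1.8
  servings/d; obesogenic mean 2.5 / SD 1.7 per week).

The continuous ``retest`` table carries ``Q_t`` itself, so
``SD(diff)/sqrt(2)`` recovers ``sigma_within`` and reference-vs-latent
correlations recover ``rho`` without ordinal attenuation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .adult_reference_measures import OBESOGENIC_ITEMS
from .food_registry import (
    FoodRegistry,
    TIMEPOINTS,
    default_dialects,
    default_registry,
)
from .psychosocial_scoring import ScaleDefinition, default_scales


class SyntheticConfigError(ValueError):
    pass


#: Fixed discretization thresholds (propensity scale) per dialect, chosen
#: so every ordinal category retains >=5% marginal mass at default config.
DEFAULT_CHILD_THRESHOLDS = (-1.0, 0.3, 1.2)
DEFAULT_ADULT_THRESHOLDS = (-1.3, -0.5, 0.4, 1.2)
DEFAULT_LIKERT_THRESHOLDS = (-1.0, 0.0, 1.0)

#: Fixed shares of total FFQ F&V servings across the included items
#: (anchored to FFQ fruits ~2.0 and vegetables ~1.0 servings/d at a
#: total of 3.0).
FFQ_SHARES = {
    "ffq_juice": 0.25,
    "ffq_fruit": 5.0 / 12.0,
    "ffq_salad": 0.10,
    "ffq_other_potatoes": 0.05,
    "ffq_beans": 1.0 / 12.0,
    "ffq_other_veg": 0.10,
}

FFQ_MEAN, FFQ_SD = 3.0, 1.8
OBESOGENIC_MEAN, OBESOGENIC_SD = 2.5, 1.7


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a generated cohort.

    Defaults mirror the feasibility-study design: 25 children and 18
    adults at baseline, with 72% / 67% completing follow-up.
    """

    n_children: int = 25
    n_adults: int = 18
    seed: int = 0
    #: follow-up completion fraction per role (subjects beyond this
    #: fraction have no follow-up records)
    completion_children: float = 18 / 25
    completion_adults: float = 12 / 18
    latent_sd: float = 1.0
    reporting_bias_sd: float = 0.3
    item_loading: float = 0.8
    target_interitem_r: float = 0.3
    sigma_within: float = 0.5
    rho_index_reference: float = 0.5
    child_thresholds: tuple[float, ...] = DEFAULT_CHILD_THRESHOLDS
    adult_thresholds: tuple[float, ...] = DEFAULT_ADULT_THRESHOLDS
    likert_thresholds: tuple[float, ...] = DEFAULT_LIKERT_THRESHOLDS

    def __post_init__(self) -> None:
        for name in ("n_children", "n_adults"):
            if getattr(self, name) < 0:
                raise SyntheticConfigError(f"{name} must be >= 0")
        for name in ("latent_sd", "reporting_bias_sd", "sigma_within"):
            if getattr(self, name) < 0:
                raise SyntheticConfigError(f"{name} must be >= 0 (an SD)")
        if not (0 <= self.target_interitem_r < 1):
            raise SyntheticConfigError("target_interitem_r must be in [0, 1)")
        if not (-1 < self.rho_index_reference < 1):
            raise SyntheticConfigError("rho_index_reference must be in (-1, 1)")
        for name in ("completion_children", "completion_adults"):
            if not (0 <= getattr(self, name) <= 1):
                raise SyntheticConfigError(f"{name} must be in [0, 1]")


@dataclass
class SyntheticCohort:
    """All generated tables plus the ground truth behind them."""

    responses: pd.DataFrame  # picture-sort long format
    likert: pd.DataFrame  # child psychosocial long format
    adult_survey: pd.DataFrame  # FFQ + obesogenic long format
    retest: pd.DataFrame  # subject_id, role, timepoint, diet_quality (Q_t)
    ground_truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the CSV/JSON files the scoring modules read."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "responses": outdir / "responses.csv",
            "likert": outdir / "likert.csv",
            "adult_survey": outdir / "adult_survey.csv",
            "retest": outdir / "retest.csv",
            "ground_truth": outdir / "ground_truth.json",
        }
        self.responses.to_csv(paths["responses"], index=False)
        self.likert.to_csv(paths["likert"], index=False)
        self.adult_survey.to_csv(paths["adult_survey"], index=False)
        self.retest.to_csv(paths["retest"], index=False)
        gt = dict(self.ground_truth)
        gt["subjects"] = gt["subjects"].to_dict(orient="records")
        with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
            json.dump(gt, fh, indent=1, default=float)
            fh.write("\n")
        return paths


# ---------------------------------------------------------------------------
# Analytic oracles

def analytic_alpha(k: int, rbar: float) -> float:
    """Population Cronbach alpha of k exchangeable items with mean
    inter-item correlation rbar:  k*rbar / (1 + (k-1)*rbar)."""
    if k < 2:
        raise SyntheticConfigError("k must be >= 2")
    if not (0 <= rbar < 1):
        raise SyntheticConfigError("rbar must be in [0, 1)")
    return k * rbar / (1 + (k - 1) * rbar)


def discretized_correlation(rho: float, thresholds: tuple[float, ...]) -> float:
    """Pearson correlation of two standard normals with latent
    correlation ``rho`` after both are cut at ``thresholds`` into ordinal
    codes 1..K."""
    if rho == 0:
        return 0.0
    cuts = np.array([-8.0, *thresholds, 8.0])
    codes = np.arange(1, len(cuts))
    marg = np.diff(stats.norm.cdf(cuts))
    mu = float((codes * marg).sum())
    var = float((codes**2 * marg).sum() - mu**2)
    mvn = stats.multivariate_normal(mean=[0.0, 0.0],
                                    cov=[[1.0, rho], [rho, 1.0]])
    grid = np.array([(a, b) for a in cuts for b in cuts])
    cdf = mvn.cdf(grid).reshape(len(cuts), len(cuts))
    cell = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
    exy = float((np.outer(codes, codes) * cell).sum())
    return (exy - mu**2) / var


_CALIBRATION_CACHE: dict[tuple, float] = {}


def calibrate_latent_correlation(
    target_r: float, thresholds: tuple[float, ...]
) -> float:
    """Latent bivariate-normal correlation whose discretized Pearson
    correlation equals ``target_r`` (bisection to 1e-6)."""
    if target_r == 0:
        return 0.0
    key = (round(target_r, 10), tuple(thresholds))
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    lo, hi = 0.0, 0.9995
    if discretized_correlation(hi, thresholds) < target_r:
        raise SyntheticConfigError(
            f"target_interitem_r={target_r} not attainable after "
            "discretization at these thresholds"
        )
    for _ in range(40):
        mid = (lo + hi) / 2
        if discretized_correlation(mid, thresholds) < target_r:
            lo = mid
        else:
            hi = mid
    _CALIBRATION_CACHE[key] = (lo + hi) / 2
    return _CALIBRATION_CACHE[key]


def one_factor_likert(
    n: int,
    k: int,
    rbar: float,
    rng: np.random.Generator,
    thresholds: tuple[float, ...] = DEFAULT_LIKERT_THRESHOLDS,
    discretize: bool = True,
) -> np.ndarray:
    """n x k one-factor item matrix with inter-item correlation rbar.

    ``discretize=False`` returns the continuous items (latent correlation
    exactly rbar); ``discretize=True`` cuts into 1..K codes using the
    calibrated latent correlation so the *observed* correlation is rbar.
    """
    rho = calibrate_latent_correlation(rbar, thresholds) if discretize else rbar
    lam = np.sqrt(rho)
    f = rng.standard_normal(n)
    e = rng.standard_normal((n, k))
    x = lam * f[:, None] + np.sqrt(1 - lam**2) * e
    if not discretize:
        return x
    return np.searchsorted(np.asarray(thresholds), x).astype(int) + 1


# ---------------------------------------------------------------------------
# Cohort generation

def _item_weights(registry: FoodRegistry, loading: float) -> pd.Series:
    reg = registry.to_frame()
    w = np.where(
        reg["healthy"], loading,
        np.where(reg["ahei_component"].isin(["ssb_juice", "red_processed_meat"]),
                 -loading, 0.0),
    )
    return pd.Series(w, index=reg["item_id"].to_numpy())


def _picture_sort_block(
    subject_ids: np.ndarray,
    role: str,
    q: Mapping[str, np.ndarray],  # timepoint -> per-subject Q_t
    followup_mask: np.ndarray,
    bias: np.ndarray,
    items: list[str],
    weights: np.ndarray,
    thresholds: tuple[float, ...],
    categories: tuple[str, ...],
    rng: np.random.Generator,
) -> pd.DataFrame:
    n, k = len(subject_ids), len(items)
    eps = rng.standard_normal((n, k))  # shared across timepoints
    frames = []
    for tp in TIMEPOINTS:
        prop = np.outer(q[tp], weights) + bias[:, None] + eps
        idx = np.searchsorted(np.asarray(thresholds), prop)
        labels = np.asarray(categories, dtype=object)[idx]
        keep = np.ones(n, dtype=bool) if tp == "baseline" else followup_mask
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(subject_ids[keep], k),
                    "role": role,
                    "timepoint": tp,
                    "item_id": np.tile(np.asarray(items, dtype=object),
                                       int(keep.sum())),
                    "response": labels[keep].ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_cohort(config: SyntheticConfig | None = None) -> SyntheticCohort:
    """Generate a fully reproducible two-timepoint child + adult cohort."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    registry = default_registry()
    dialects = default_dialects()
    scales = default_scales()

    child_ids = np.array([f"C{i:04d}" for i in range(1, config.n_children + 1)])
    adult_ids = np.array([f"A{i:04d}" for i in range(1, config.n_adults + 1)])

    def latents(n: int):
        t = rng.normal(0.0, config.latent_sd, n)
        b = rng.normal(0.0, config.reporting_bias_sd, n)
        q = {
            tp: t + rng.normal(0.0, config.sigma_within, n)
            for tp in TIMEPOINTS
        }
        return t, b, q

    child_t, child_b, child_q = latents(config.n_children)
    adult_t, adult_b, adult_q = latents(config.n_adults)

    n_child_fu = int(round(config.completion_children * config.n_children))
    n_adult_fu = int(round(config.completion_adults * config.n_adults))
    child_fu = np.arange(config.n_children) < n_child_fu
    adult_fu = np.arange(config.n_adults) < n_adult_fu

    weights_all = _item_weights(registry, config.item_loading)
    child_items = [it.item_id for it in registry if not it.is_alcohol]
    adult_items = [it.item_id for it in registry]

    resp_child = _picture_sort_block(
        child_ids, "child", child_q, child_fu, child_b,
        child_items, weights_all[child_items].to_numpy(),
        config.child_thresholds, dialects["child"].categories, rng,
    )
    resp_adult = _picture_sort_block(
        adult_ids, "adult", adult_q, adult_fu, adult_b,
        adult_items, weights_all[adult_items].to_numpy(),
        config.adult_thresholds, dialects["adult"].categories, rng,
    )
    responses = pd.concat([resp_child, resp_adult], ignore_index=True)

    # --- child Likert scales: one factor per construct -------------------
    constructs = {
        "tendency": [i for i in _construct_items(scales, "tc_")],
        "self_efficacy": [i for i in _construct_items(scales, "se_")],
    }
    likert_rows = []
    n = config.n_children
    # self-efficacy is the child reference measure: its factor carries the
    # programmed correlation with latent diet quality; the tendency factor
    # is independent (mirroring its weak observed convergent validity)
    rho_c = config.rho_index_reference
    z_child = (
        child_t / config.latent_sd if config.latent_sd > 0 else np.zeros(n)
    )
    factor = {
        "tendency": rng.standard_normal(n),
        "self_efficacy": rho_c * z_child
        + np.sqrt(1 - rho_c**2) * rng.standard_normal(n),
    }
    rho_latent = calibrate_latent_correlation(
        config.target_interitem_r, config.likert_thresholds
    ) if config.target_interitem_r > 0 else 0.0
    lam = np.sqrt(rho_latent)
    for tp in TIMEPOINTS:
        keep = np.ones(n, dtype=bool) if tp == "baseline" else child_fu
        for construct, items in constructs.items():
            k = len(items)
            e = rng.standard_normal((n, k))
            x = lam * factor[construct][:, None] + np.sqrt(1 - lam**2) * e
            codes = np.searchsorted(
                np.asarray(config.likert_thresholds), x
            ).astype(int) + 1
            likert_rows.append(
                pd.DataFrame(
                    {
                        "subject_id": np.repeat(child_ids[keep], k),
                        "timepoint": tp,
                        "item_id": np.tile(np.asarray(items, dtype=object),
                                           int(keep.sum())),
                        "response": codes[keep].ravel(),
                    }
                )
            )
    likert = pd.concat(likert_rows, ignore_index=True)

    # --- adult reference measures ----------------------------------------
    rho = config.rho_index_reference
    q_sd = float(np.sqrt(config.latent_sd**2 + config.sigma_within**2))
    survey_rows = []
    for tp in TIMEPOINTS:
        keep = adult_fu if tp == "followup" else np.ones(config.n_adults, bool)
        z = adult_q[tp] / q_sd if q_sd > 0 else np.zeros(config.n_adults)
        u = rng.standard_normal(config.n_adults)
        v = rng.standard_normal(config.n_adults)
        ffq_total = np.maximum(
            0.0, FFQ_MEAN + FFQ_SD * (rho * z + np.sqrt(1 - rho**2) * u)
        )
        fries = np.abs(rng.normal(0.0, 0.25, config.n_adults))
        obes_mean = np.maximum(
            0.0,
            OBESOGENIC_MEAN
            + OBESOGENIC_SD * (-rho * z + np.sqrt(1 - rho**2) * v),
        )
        obes_items = np.maximum(
            0.0, obes_mean[:, None] + rng.normal(0.0, 0.3, (config.n_adults, 3))
        )
        for j, sid in enumerate(adult_ids):
            if not keep[j]:
                continue
            for item, share in FFQ_SHARES.items():
                survey_rows.append((sid, tp, "ffq", item, share * ffq_total[j]))
            survey_rows.append((sid, tp, "ffq", "ffq_fries", fries[j]))
            for m, item in enumerate(OBESOGENIC_ITEMS):
                survey_rows.append((sid, tp, "obesogenic", item, obes_items[j, m]))
    adult_survey = pd.DataFrame(
        survey_rows,
        columns=["subject_id", "timepoint", "measure", "item_id", "value"],
    )

    # --- ground truth ------------------------------------------------------
    retest_rows = []
    for ids, role, q, keep_fu in (
        (child_ids, "child", child_q, child_fu),
        (adult_ids, "adult", adult_q, adult_fu),
    ):
        for tp in TIMEPOINTS:
            keep = np.ones(len(ids), bool) if tp == "baseline" else keep_fu
            retest_rows.append(
                pd.DataFrame(
                    {
                        "subject_id": ids[keep],
                        "role": role,
                        "timepoint": tp,
                        "diet_quality": q[tp][keep],
                    }
                )
            )
    retest = pd.concat(retest_rows, ignore_index=True)

    subjects = pd.concat(
        [
            pd.DataFrame(
                {"subject_id": child_ids, "role": "child",
                 "latent": child_t, "reporting_bias": child_b,
                 "completes_followup": child_fu}
            ),
            pd.DataFrame(
                {"subject_id": adult_ids, "role": "adult",
                 "latent": adult_t, "reporting_bias": adult_b,
                 "completes_followup": adult_fu}
            ),
        ],
        ignore_index=True,
    )
    ground_truth = {
        "subjects": subjects,
        "analytic_alphas": {
            sid: analytic_alpha(len(sd.item_ids), config.target_interitem_r)
            for sid, sd in scales.items()
        },
        "sigma_within": config.sigma_within,
        "rho_index_reference": config.rho_index_reference,
        "latent_sd": config.latent_sd,
        "config": asdict(config),
    }
    return SyntheticCohort(
        responses=responses,
        likert=likert,
        adult_survey=adult_survey,
        retest=retest,
        ground_truth=ground_truth,
    )


def _construct_items(scales: Mapping[str, ScaleDefinition], prefix: str) -> list[str]:
    seen: list[str] = []
    for sd in scales.values():
        for item in sd.item_ids:
            if item.startswith(prefix) and item not in seen:
                seen.append(item)
    return seen


__all__ = [
    "DEFAULT_ADULT_THRESHOLDS",
    "DEFAULT_CHILD_THRESHOLDS",
    "DEFAULT_LIKERT_THRESHOLDS",
    "FFQ_SHARES",
    "SyntheticCohort",
    "SyntheticConfig",
    "SyntheticConfigError",
    "analytic_alpha",
    "calibrate_latent_correlation",
    "discretized_correlation",
    "generate_cohort",
    "one_factor_likert",
]
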