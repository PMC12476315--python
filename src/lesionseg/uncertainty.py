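"""Monte Carlo Dropout inference and pixel-wise uncertainty estimation.

With dropout kept active at prediction time, T stochastic forward passes
through the network approximate sampling from the posterior predictive
distribution.  The binary sigmoid output is materialised as a two-class
distribution (p, 1−p) so all estimators share one code path.  Four
pixel-wise maps are computed (log base 2 throughout, so entropies are in
bits):

* confidence          C   = max_c  p̄(c),        p̄ = mean over the T passes
* predictive entropy  H   = −Σ_c p̄(c) log₂ p̄(c)           (total uncertainty)
* mutual information  MI  = H(p̄) − mean_t H(p_t)       (epistemic component)
* EPKL                    = mean over ordered pass pairs of KL(p_i ‖ p_j)

Per-image means of the four maps are min–max normalised across an
evaluation cohort and combined into the aggregate score

    U_tot = α·C − β·H + γ·MI − δ·EPKL,   (α, β, γ, δ) = (0.4, 0.2, 0.2, 0.2),

used to rank images for review.  Note the sign pattern is kept exactly as
printed: the confidence term *raises* the score, so ranking direction is a
configuration choice recorded with the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .architectures import MetaUNet, images_to_batch
from .data_model import LesionSample

_EPS = 1e-12
DEFAULT_WEIGHTS = (0.4, 0.2, 0.2, 0.2)
MEASURES = ("C", "H", "MI", "EPKL")


@dataclass
class PredictionEnsemble:
    """T stochastic per-pixel class-probability maps for one image."""

    probs: np.ndarray  # (T, H, W, n_classes)
    sample_id: str = ""
    seed: int | None = None

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 4:
            raise ValueError("probs must be (T, H, W, n_classes)")
        if p.min() < -1e-9 or p.max() > 1 + 1e-9:
            raise ValueError("probabilities must lie in [0, 1]")
        sums = p.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("per-pixel class probabilities must sum to 1")
        self.probs = p

    @property
    def T(self) -> int:
        return self.probs.shape[0]

    @property
    def mean_probs(self) -> np.ndarray:
        return self.probs.mean(axis=0)


def ensemble_from_binary(prob_maps: np.ndarray, sample_id: str = "",
                         seed: int | None = None) -> PredictionEnsemble:
    """Materialise T (H, W) lesion-probability maps as 2-class ensembles."""
    p = np.asarray(prob_maps, dtype=float)
    return PredictionEnsemble(np.stack([p, 1.0 - p], axis=-1), sample_id, seed)


def mcd_predict(model: MetaUNet, sample: LesionSample, T: int = 10,
                seed: int = 0) -> PredictionEnsemble:
    """T forward passes with dropout sampling active; seeded and reproducible."""
    if not model.cfg.bayesian:
        raise ValueError(
            "model was built with bayesian=False; rebuild the configuration "
            "with bayesian=True (dropout after each conv block) to enable "
            "Monte Carlo Dropout inference")
    imgs, _, meta = images_to_batch([sample])
    meta_arg = meta if model.cfg.fusion_strategy != "none" else None
    rng = np.random.default_rng(seed)
    maps = []
    for _ in range(T):
        out = model.forward(imgs, meta_arg, stochastic=True, rng=rng)
        maps.append(out.data[0, 0])
    return ensemble_from_binary(np.stack(maps), sample.id, seed)


# ---------------------------------------------------------------------
# pixel-wise estimators
# ---------------------------------------------------------------------

def _entropy(p: np.ndarray) -> np.ndarray:
    """−Σ_c p log₂ p along the trailing class axis."""
    return -(p * np.log2(np.clip(p, _EPS, None))).sum(axis=-1)


def confidence_map(ensemble: PredictionEnsemble) -> np.ndarray:
    """C = max_c of the pass-averaged class probabilities."""
    return ensemble.mean_probs.max(axis=-1)


def entropy_map(ensemble: PredictionEnsemble) -> np.ndarray:
    """Predictive entropy of the pass-averaged distribution, in bits."""
    return _entropy(ensemble.mean_probs)


def mutual_information_map(ensemble: PredictionEnsemble) -> np.ndarray:
    """MI = H(mean) − mean per-pass H: the disagreement (epistemic) part."""
    if ensemble.T < 2:
        raise ValueError("mutual information needs T >= 2 passes")
    return _entropy(ensemble.mean_probs) - _entropy(ensemble.probs).mean(axis=0)


def epkl_map(ensemble: PredictionEnsemble, variant: str = "pairwise") -> np.ndarray:
    """Expected pairwise KL divergence among the T predicted distributions.

    ``variant="pairwise"`` (default) averages KL(p_i ‖ p_j) over ordered
    pairs i ≠ j; ``variant="to_mean"`` instead averages KL(p_i ‖ p̄) against
    the ensemble mean.
    """
    if ensemble.T < 2:
        raise ValueError("EPKL needs T >= 2 passes")
    p = np.clip(ensemble.probs, _EPS, None)
    logp = np.log2(p)
    if variant == "to_mean":
        pbar = np.clip(ensemble.mean_probs, _EPS, None)
        kl = (p * (logp - np.log2(pbar)[None])).sum(axis=-1)
        return kl.mean(axis=0)
    if variant != "pairwise":
        raise ValueError(f"unknown EPKL variant {variant!r}")
    T = ensemble.T
    total = np.zeros(p.shape[1:-1])
    for i in range(T):
        for j in range(T):
            if i == j:
                continue
            total += (p[i] * (logp[i] - logp[j])).sum(axis=-1)
    return total / (T * (T - 1))


# ---------------------------------------------------------------------
# cohort-level aggregation
# ---------------------------------------------------------------------

@dataclass
class UncertaintyReport:
    """Per-image uncertainty maps, their means and the aggregate score."""

    sample_id: str
    maps: dict = field(repr=False, default_factory=dict)   # name -> 2-D array
    means: dict = field(default_factory=dict)              # name -> float
    normalized: dict = field(default_factory=dict)
    u_tot: float = np.nan
    weights: tuple = DEFAULT_WEIGHTS
    cohort_id: str = ""


def image_report(ensemble: PredictionEnsemble,
                 epkl_variant: str = "pairwise") -> UncertaintyReport:
    maps = {
        "C": confidence_map(ensemble),
        "H": entropy_map(ensemble),
        "MI": mutual_information_map(ensemble),
        "EPKL": epkl_map(ensemble, epkl_variant),
    }
    means = {k: float(v.mean()) for k, v in maps.items()}
    return UncertaintyReport(ensemble.sample_id, maps=maps, means=means)


def normalize_measures(per_image_means: pd.DataFrame) -> pd.DataFrame:
    """Min–max normalise each measure column across the cohort to [0, 1].

    A degenerate cohort (max == min, including a single image) maps to 0.
    """
    if len(per_image_means) == 0:
        raise ValueError("empty cohort")
    out = per_image_means.copy()
    for col in out.columns:
        lo, hi = out[col].min(), out[col].max()
        out[col] = 0.0 if hi == lo else (out[col] - lo) / (hi - lo)
    return out


def aggregate_score(norm_c, norm_h, norm_mi, norm_epkl,
                    alpha: float = 0.4, beta: float = 0.2,
                    gamma: float = 0.2, delta: float = 0.2):
    """U_tot = α·C − β·H + γ·MI − δ·EPKL on normalised per-image means."""
    if min(alpha, beta, gamma, delta) < 0:
        raise ValueError("aggregation weights must be non-negative")
    return (alpha * np.asarray(norm_c) - beta * np.asarray(norm_h)
            + gamma * np.asarray(norm_mi) - delta * np.asarray(norm_epkl))


def cohort_report(reports: list[UncertaintyReport], cohort_id: str,
                  weights: tuple = DEFAULT_WEIGHTS) -> pd.DataFrame:
    """Normalise per-image means across the cohort and attach U_tot.

    Returns a DataFrame indexed by image id with columns mean_*/norm_*/u_tot;
    the cohort identity is stored on every row to block cross-cohort ranking.
    """
    means = pd.DataFrame({m: [r.means[m] for r in reports] for m in MEASURES},
                         index=[r.sample_id for r in reports])
    norm = normalize_measures(means)
    u = aggregate_score(norm["C"], norm["H"], norm["MI"], norm["EPKL"], *weights)
    df = pd.DataFrame(index=means.index)
    for m in MEASURES:
        df[f"mean_{m}"] = means[m]
    for m in MEASURES:
        df[f"norm_{m}"] = norm[m]
    df["u_tot"] = u
    df["cohort_id"] = cohort_id
    for r, (_, row) in zip(reports, df.iterrows()):
        r.normalized = {m: float(row[f"norm_{m}"]) for m in MEASURES}
        r.u_tot = float(row["u_tot"])
        r.weights = weights
        r.cohort_id = cohort_id
    return df


def rank_by_uncertainty(report_df: pd.DataFrame, k: int | None = None,
                        descending: bool = True) -> list[str]:
    """Image ids sorted by U_tot (ties broken lexicographically by id)."""
    if "cohort_id" in report_df.columns and report_df["cohort_id"].nunique() > 1:
        raise ValueError("cannot rank across different cohort normalisations")
    order = report_df.assign(_id=report_df.index.astype(str)).sort_values(
        ["u_tot", "_id"], ascending=[not descending, True])
    ids = list(order.index.astype(str))
    return ids if k is None else ids[:k]


def model_cohort_report(model: MetaUNet, samples: list[LesionSample],
                        cohort_id: str, T: int = 10, seed: int = 0,
                        epkl_variant: str = "pairwise") -> pd.DataFrame:
    """Run MCD over a cohort and return the normalised uncertainty table."""
    seeds = np.random.SeedSequence(seed).generate_state(len(samples)) % (2 ** 31)
    reports = [image_report(mcd_predict(model, s, T=T, seed=int(si)), epkl_variant)
               for s, si in zip(samples, seeds)]
    return cohort_report(reports, cohort_id)
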