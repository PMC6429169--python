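"""Simulation-study evaluation: phenotype-prediction AIC, SNP retrieval.

Two questions are asked of every simulated replicate. First, how well do
the fitted latent scores predict the binary phenotype, measured by the AIC
of a logistic regression and compared against four reference feature sets
(m principal components of the regions, all regions, all SNPs plus
regions, all SNPs). Second, how well is the set of true-effect SNPs
recovered, measured by ROC AUC over per-SNP importance scores from four
rankings: the SEM path p values combined by max-then-min ("SEM max") or by
Fisher's method then min ("SEM Fisher"), and plain univariate /
multivariate logistic regression of the phenotype on the SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import PCA

from .inference import LatentScores, bartlett_scores, robust_adjust
from .model import FitError, fit_sem
from .simulate import SimulationConfig, simulate_dataset, swap_region_links

AIC_MODELS = ("fitted_latents", "pcs_regions", "all_regions", "all_snps_regions", "all_snps")
AUC_METHODS = ("sem_max", "sem_fisher", "multivariate_logistic", "univariate_logistic")

class SeparationError(RuntimeError):
    """Logistic fit failed due to (quasi-)perfect separation."""


class StudyError(RuntimeError):
    """Too many replicates of a simulation study failed."""


@dataclass
class LogisticFit:
    coefficients: np.ndarray   # intercept first
    pvalues: np.ndarray        # Wald p per coefficient (intercept first)
    aic: float
    loglik: float


def logistic_fit_aic(features: np.ndarray, y: np.ndarray) -> LogisticFit:
    """ML logistic regression with intercept; AIC = 2(k+1) - 2 loglik.

    ``features`` may have zero columns (null model). Perfect or
    quasi-perfect separation raises :class:`SeparationError` rather than
    returning meaningless estimates.
    """
    y = np.asarray(y, dtype=float)
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[:, None]
    n, k = features.shape
    if len(np.unique(y)) < 2:
        raise SeparationError("phenotype has a single class")
    if n <= k + 1:
        raise ValueError(f"need n > k+1 (n={n}, k={k})")
    X = np.hstack([np.ones((n, 1)), features])
    # IRLS, as in R's glm: quasi-perfect prediction of individual samples
    # is tolerated; only complete separation (deviance ~ 0) is an error.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        except sm.tools.sm_exceptions.PerfectSeparationError as e:
            raise SeparationError(str(e)) from e
        except np.linalg.LinAlgError as e:
            raise SeparationError(f"singular system in logistic fit: {e}") from e
    if res.llf > -1e-6:
        raise SeparationError("complete separation: the log-likelihood is zero")
    return LogisticFit(
        coefficients=res.params, pvalues=res.pvalues,
        aic=float(res.aic), loglik=float(res.llf),
    )


def compare_models_aic(dataset, scores: LatentScores) -> dict:
    """AIC of five phenotype-prediction logistic models on one replicate.

    Feature sets: the fitted latent scores; the first m principal
    components of the centred+scaled regions; all regions; all SNPs and
    regions; all SNPs. Regions/SNPs enter centred (regions also scaled).
    """
    y = dataset.y
    x_std = _center_scale(dataset.x)
    g_c = dataset.g - dataset.g.mean(axis=0)
    m = scores.values.shape[1]
    pcs = PCA(n_components=m).fit_transform(x_std)
    feature_sets = {
        "fitted_latents": scores.values,
        "pcs_regions": pcs,
        "all_regions": x_std,
        "all_snps_regions": np.hstack([g_c, x_std]),
        "all_snps": g_c,
    }
    return {name: logistic_fit_aic(f, y).aic for name, f in feature_sets.items()}


def _center_scale(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=0)
    return xc / xc.std(axis=0)


def combine_snp_scores(pA: np.ndarray, pL: np.ndarray, method: str = "max") -> np.ndarray:
    """Per-SNP importance scores from the two p values along each path.

    The path from SNP j to the phenotype through latent l carries the
    robust p value pA[l, j] (SNP -> latent) and the logistic p value pL[l]
    (latent -> phenotype).

    method "max": score_j = min over latents of max(pA[l, j], pL[l]).
    method "fisher": per latent, combine the pair with Fisher's statistic
    -2(ln pA + ln pL) against chi-square with 4 df, then take the min over
    latents. Lower scores mean stronger evidence.
    """
    pA = np.asarray(pA, dtype=float)
    pL = np.asarray(pL, dtype=float)
    if pA.ndim != 2 or pL.shape != (pA.shape[0],):
        raise ValueError("pA must be m x p and pL length m")
    if np.any(pA > 1) or np.any(pL > 1) or np.any(pA < 0) or np.any(pL < 0):
        raise ValueError("p values must lie in [0, 1]")
    tiny = np.finfo(float).tiny
    if np.any(pA == 0) or np.any(pL == 0):
        warnings.warn("zero p values clamped to the smallest positive float", stacklevel=2)
    pA = np.clip(pA, tiny, 1.0)
    pL = np.clip(pL, tiny, 1.0)
    if method == "max":
        per_latent = np.maximum(pA, pL[:, None])
    elif method == "fisher":
        stat = -2.0 * (np.log(pA) + np.log(pL)[:, None])
        per_latent = stats.chi2.sf(stat, df=4)
    else:
        raise ValueError(f"unknown method {method!r}")
    return per_latent.min(axis=0)


def baseline_snp_pvalues(g: np.ndarray, y: np.ndarray, mode: str = "univariate") -> np.ndarray:
    """GWAS-style logistic p values for each SNP.

    "univariate": a separate logistic regression per SNP; "multivariate":
    one joint logistic regression on all SNPs, per-coefficient Wald p.
    Separation is flagged per SNP (univariate, that SNP's p is NaN) or for
    the whole model (multivariate, raises).
    """
    g = np.asarray(g, dtype=float)
    if mode == "univariate":
        out = np.empty(g.shape[1])
        for j in range(g.shape[1]):
            try:
                out[j] = logistic_fit_aic(g[:, [j]], y).pvalues[1]
            except SeparationError:
                out[j] = np.nan
        return out
    if mode == "multivariate":
        return logistic_fit_aic(g, y).pvalues[1:]
    raise ValueError(f"unknown mode {mode!r}")


def retrieval_auc(scores: np.ndarray, true_effect: np.ndarray) -> float:
    """ROC AUC for SNP retrieval; lower score = stronger evidence.

    Rank formulation of the threshold sweep, with the standard tie
    correction: AUC = P(score_true < score_false) + 0.5 P(tie).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(true_effect, dtype=bool)
    n_t, n_f = truth.sum(), (~truth).sum()
    if n_t == 0 or n_f == 0:
        raise ValueError("need at least one true-effect and one null SNP")
    ranks = stats.rankdata(scores)          # ascending, ties averaged
    u_true_larger = ranks[truth].sum() - n_t * (n_t + 1) / 2.0
    return float(1.0 - u_true_larger / (n_t * n_f))


def latent_phenotype_pvalues(scores: LatentScores, y: np.ndarray) -> np.ndarray:
    """Wald p per latent from a joint logistic regression of y on all scores."""
    return logistic_fit_aic(scores.values, y).pvalues[1:]


@dataclass
class EvaluationResult:
    """Tidy per-replicate AIC and AUC tables plus failure bookkeeping."""

    aic: pd.DataFrame            # columns: replicate, [sweep cols], model, aic
    auc: pd.DataFrame            # columns: replicate, [sweep cols], method, auc
    failures: list               # (replicate, reason)
    n_replicates: int
    config: SimulationConfig

    def mean_aic(self) -> pd.Series:
        return self.aic.groupby("model")["aic"].mean().reindex(list(AIC_MODELS))

    def mean_auc(self) -> pd.Series:
        return self.auc.groupby("method")["auc"].mean().reindex(list(AUC_METHODS))

    def summary(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "n_failed": len(self.failures),
            "mean_aic": self.mean_aic().to_dict(),
            "mean_auc": self.mean_auc().to_dict(),
        }


def evaluate_replicate(config: SimulationConfig, seed) -> tuple:
    """Simulate, fit, and score one replicate.

    Returns (aic_record, auc_record): the five-model AIC dict and the
    four-method AUC dict. The SEM is fitted with the misspecified grouping
    when ``config.n_swaps`` > 0; the data are always generated from the
    true grouping.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    rng = np.random.default_rng(ss)
    ds = simulate_dataset(config, seed=rng)
    fit_spec = ds.spec
    if config.n_swaps:
        fit_spec = swap_region_links(ds.spec, config.n_swaps, seed=rng)

    g_c = ds.g - ds.g.mean(axis=0)
    x_std = _center_scale(ds.x)
    fit = fit_sem(g_c, x_std, fit_spec, seed=int(rng.integers(2**31)))
    if not fit.converged:
        raise FitError("SEM fit did not converge")
    fit = robust_adjust(fit, g_c, x_std)
    scores = bartlett_scores(fit, x_std)

    aic_record = compare_models_aic(ds, scores)

    pA = fit.snp_weight_pvalues()
    pL = latent_phenotype_pvalues(scores, ds.y)
    truth = ds.true_effect_mask()
    auc_record = {
        "sem_max": retrieval_auc(combine_snp_scores(pA, pL, "max"), truth),
        "sem_fisher": retrieval_auc(combine_snp_scores(pA, pL, "fisher"), truth),
        "multivariate_logistic": retrieval_auc(
            baseline_snp_pvalues(ds.g, ds.y, "multivariate"), truth
        ),
        "univariate_logistic": retrieval_auc(
            baseline_snp_pvalues(ds.g, ds.y, "univariate"), truth
        ),
    }
    return aic_record, auc_record


def run_simulation_study(
    config: SimulationConfig,
    n_replicates: int = 100,
    seed: int = 0,
    sweep: dict | None = None,
    max_failure_rate: float = 0.2,
) -> EvaluationResult:
    """Run the full simulation study, optionally over a parameter sweep.

    ``sweep`` maps one config field name to a list of values; each cell of
    the sweep runs ``n_replicates`` replicates. Every replicate gets a
    child seed derived from ``seed`` and a counter, so any single
    replicate can be re-run in isolation. Replicates that fail (SEM
    non-convergence, separation in a logistic fit) are recorded with the
    reason and excluded from the tables; if more than
    ``max_failure_rate`` of all replicates fail, the study errors out.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if sweep is not None and len(sweep) != 1:
        raise ValueError("sweep must map exactly one parameter to its values")
    cells = [(None, None, config)]
    if sweep is not None:
        (param, values), = sweep.items()
        cells = [(param, v, config.replace(**{param: v})) for v in values]

    aic_rows, auc_rows, failures = [], [], []
    counter = 0
    for param, value, cfg in cells:
        for rep in range(n_replicates):
            child = np.random.SeedSequence(entropy=seed, spawn_key=(counter,))
            counter += 1
            tags = {} if param is None else {param: value}
            try:
                aic_record, auc_record = evaluate_replicate(cfg, child)
            except (FitError, SeparationError, StudyError, ValueError) as e:
                failures.append({"replicate": rep, **tags, "reason": str(e)})
                continue
            for model, v in aic_record.items():
                aic_rows.append({"replicate": rep, **tags, "model": model, "aic": v})
            for method, v in auc_record.items():
                auc_rows.append({"replicate": rep, **tags, "method": method, "auc": v})

    total = n_replicates * len(cells)
    if len(failures) > max_failure_rate * total:
        raise StudyError(
            f"{len(failures)} of {total} replicates failed "
            f"(limit {max_failure_rate:.0%}); first reason: {failures[0]['reason']}"
        )
    return EvaluationResult(
        aic=pd.DataFrame(aic_rows),
        auc=pd.DataFrame(auc_rows),
        failures=failures,
        n_replicates=n_replicates,
        config=config,
    )
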