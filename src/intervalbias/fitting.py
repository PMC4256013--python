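"""Maximum-likelihood fitting of observer models to trial blocks.

Each block (80 trials) is fitted independently.  The free parameters are
the observer noise sigma (all families) and, for the response-bias
family, the additive bias beta.  Sigma is optimised on a log scale to
enforce positivity.  Optimisation uses Powell's derivative-free
direction-set method from multiple random starting points drawn from
Normal(0, 10) in the fitted-parameter space, and the best local optimum
is kept.  Models are compared per block by the Bayesian information
criterion, BIC = k ln n − 2 lnL (lower is better).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import ndtr

from .observers import ContractionWeights, ModelTag, empty_memory, update_memory
from .protocols import Block

__all__ = [
    "PROB_CLIP_EPS",
    "FitResult",
    "ModelComparison",
    "block_log_likelihood",
    "fit_block",
    "bic",
    "compare_models_across_blocks",
]

#: Per-trial response probabilities are clipped to [eps, 1-eps] before
#: taking logs, keeping block likelihoods finite for degenerate parameters.
PROB_CLIP_EPS = 1e-12

_N_FREE_PARAMS = {
    ModelTag.NAIVE: 1,
    ModelTag.MEMORY_TRACE: 1,
    ModelTag.RESPONSE_BIAS: 2,
}


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting one model family to one block."""

    model_tag: ModelTag
    sigma: float
    beta: Optional[float]
    log_likelihood: float
    bic: float
    n_trials: int
    n_free_params: int
    n_starts: int
    best_start_index: int
    converged: bool
    block_id: object = None


def _check_fittable(model_tag: ModelTag) -> int:
    if model_tag not in _N_FREE_PARAMS:
        raise ValueError(
            f"{model_tag} is not fitted per block; fittable families are "
            f"{sorted(m.value for m in _N_FREE_PARAMS)}"
        )
    return _N_FREE_PARAMS[model_tag]


def _signed_drives(
    model_tag: ModelTag, block: Block, weights: Optional[ContractionWeights]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial decision variable and response sign.

    The drive D_t depends only on the stimulus sequence, so it is computed
    once per block; the log-likelihood of any (sigma, beta) is then
    sum_t log Phi(s_t (D_t / sigma + beta)) with s_t = +1 for an observed
    "first higher" response and −1 otherwise.  Memory is rebuilt
    sequentially from the block's own stimuli.
    """
    drives = np.empty(len(block.trials))
    signs = np.empty(len(block.trials))
    if model_tag is ModelTag.MEMORY_TRACE:
        if weights is None:
            raise ValueError("memory-trace fitting requires weights")
        mem = empty_memory(weights.k)
        for i, t in enumerate(block.trials):
            if t.response_first_higher is None:
                raise ValueError(f"trial {t.index} has no recorded response")
            drives[i] = weights.drive(mem, t.x1, t.x2)
            signs[i] = 1.0 if t.response_first_higher else -1.0
            mem = update_memory(mem, t.x1)
    else:
        for i, t in enumerate(block.trials):
            if t.response_first_higher is None:
                raise ValueError(f"trial {t.index} has no recorded response")
            drives[i] = t.x1 - t.x2
            signs[i] = 1.0 if t.response_first_higher else -1.0
    return drives, signs


def _neg_log_likelihood(
    theta: np.ndarray, drives: np.ndarray, signs: np.ndarray, has_beta: bool
) -> float:
    sigma = math.exp(max(min(float(theta[0]), 700.0), -700.0))
    beta = float(theta[1]) if has_beta else 0.0
    with np.errstate(over="ignore"):
        p = ndtr(signs * (drives / sigma + beta))
    p = np.clip(p, PROB_CLIP_EPS, 1.0 - PROB_CLIP_EPS)
    return -float(np.sum(np.log(p)))


def block_log_likelihood(
    model_tag: ModelTag,
    sigma: float,
    block: Block,
    weights: Optional[ContractionWeights] = None,
    beta: float = 0.0,
) -> float:
    """Log-likelihood (nats) of a block's observed responses under a model.

    Probabilities are clipped to [PROB_CLIP_EPS, 1 − PROB_CLIP_EPS].
    """
    _check_fittable(model_tag)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    drives, signs = _signed_drives(model_tag, block, weights)
    has_beta = model_tag is ModelTag.RESPONSE_BIAS
    theta = np.array([math.log(sigma), beta]) if has_beta else np.array([math.log(sigma)])
    return -_neg_log_likelihood(theta, drives, signs, has_beta)


def bic(log_likelihood: float, n_free_params: int, n_trials: int) -> float:
    """Bayesian information criterion, k ln(n) − 2 lnL."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return n_free_params * math.log(n_trials) - 2.0 * log_likelihood


def fit_block(
    model_tag: ModelTag,
    block: Block,
    weights: Optional[ContractionWeights] = None,
    n_starts: int = 100,
    start_sd: float = 10.0,
    rng: Optional[np.random.Generator] = None,
) -> FitResult:
    """Fit one model family to one block by multistart maximum likelihood.

    Starting points are drawn from Normal(0, start_sd) in the fitted
    space (log sigma, and beta where applicable); each start is refined
    with Powell's method and the best optimum is returned.  With a fixed
    ``rng`` state the result is bit-reproducible, and the first start of a
    larger multistart equals the single start of a smaller one drawn from
    the same generator state.
    """
    n_free = _check_fittable(model_tag)
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    drives, signs = _signed_drives(model_tag, block, weights)
    has_beta = model_tag is ModelTag.RESPONSE_BIAS
    ndim = 2 if has_beta else 1
    starts = rng.normal(0.0, start_sd, size=(n_starts, ndim))

    best_fun = math.inf
    best_x: Optional[np.ndarray] = None
    best_idx = -1
    any_converged = False
    for i, x0 in enumerate(starts):
        res = optimize.minimize(
            _neg_log_likelihood,
            x0,
            args=(drives, signs, has_beta),
            method="Powell",
            options={"xtol": 1e-8, "ftol": 1e-10},
        )
        if res.success:
            any_converged = True
        if np.isfinite(res.fun) and res.fun < best_fun:
            best_fun = float(res.fun)
            best_x = np.atleast_1d(res.x)
            best_idx = i
    if best_x is None:
        raise RuntimeError(
            f"fit failed: none of {n_starts} starts produced a finite "
            f"likelihood for {model_tag} on block {block.block_id!r}"
        )

    sigma = math.exp(float(best_x[0]))
    beta = float(best_x[1]) if has_beta else None
    ll = -best_fun
    n_trials = len(block.trials)
    return FitResult(
        model_tag=model_tag,
        sigma=sigma,
        beta=beta,
        log_likelihood=ll,
        bic=bic(ll, n_free, n_trials),
        n_trials=n_trials,
        n_free_params=n_free,
        n_starts=n_starts,
        best_start_index=best_idx,
        converged=any_converged,
    )


@dataclass(frozen=True)
class ModelComparison:
    """Paired per-block comparison of two fitted model families (A vs B)."""

    n_blocks: int
    bic_diff: np.ndarray  # BIC_A − BIC_B per block
    win_fraction_a: float
    t_stat: float
    p_value: float
    compared_on: str  # "bic" or "log_likelihood"
    pearson_r: Optional[float] = None
    pearson_p: Optional[float] = None
    spearman_rho: Optional[float] = None
    spearman_p: Optional[float] = None
    correlation_degenerate: bool = False


def compare_models_across_blocks(
    fits_a: Sequence[FitResult],
    fits_b: Sequence[FitResult],
    bias_magnitudes: Optional[Sequence[float]] = None,
) -> ModelComparison:
    """Compare two model families fitted to the same blocks.

    Wins are counted per block: when the families have the same number of
    free parameters the higher log-likelihood wins, otherwise the lower
    BIC wins; exact ties score 0.5 each.  The paired t-test is run on the
    per-block comparison criterion.  If per-block interval-bias
    magnitudes are supplied, Pearson and Spearman correlations of the BIC
    difference against them are reported; a constant input is flagged as
    degenerate rather than propagating NaN.
    """
    if len(fits_a) != len(fits_b) or len(fits_a) == 0:
        raise ValueError("fits_a and fits_b must be non-empty and paired")
    for fa, fb in zip(fits_a, fits_b):
        if fa.n_trials != fb.n_trials:
            raise ValueError("paired fits must come from identical blocks")
        if fa.block_id is not None and fb.block_id is not None:
            if fa.block_id != fb.block_id:
                raise ValueError(
                    f"unpaired fits: block {fa.block_id!r} vs {fb.block_id!r}"
                )

    same_k = all(
        fa.n_free_params == fb.n_free_params for fa, fb in zip(fits_a, fits_b)
    )
    if same_k:
        crit_a = np.array([-f.log_likelihood for f in fits_a])
        crit_b = np.array([-f.log_likelihood for f in fits_b])
        compared_on = "log_likelihood"
    else:
        crit_a = np.array([f.bic for f in fits_a])
        crit_b = np.array([f.bic for f in fits_b])
        compared_on = "bic"

    wins = np.where(crit_a < crit_b, 1.0, np.where(crit_a > crit_b, 0.0, 0.5))
    bic_diff = np.array([fa.bic - fb.bic for fa, fb in zip(fits_a, fits_b)])

    diff = crit_a - crit_b
    if np.allclose(diff.std(ddof=1) if len(diff) > 1 else 0.0, 0.0):
        t_stat, p_value = (0.0, 1.0) if np.allclose(diff, 0.0) else (math.nan, math.nan)
    else:
        t_stat, p_value = stats.ttest_rel(crit_a, crit_b)

    pearson_r = pearson_p = spearman_rho = spearman_p = None
    degenerate = False
    if bias_magnitudes is not None:
        mags = np.asarray(bias_magnitudes, dtype=float)
        if len(mags) != len(fits_a):
            raise ValueError("bias_magnitudes must pair with the fits")
        if np.ptp(mags) == 0.0 or np.ptp(bic_diff) == 0.0:
            degenerate = True
        else:
            pr = stats.pearsonr(bic_diff, mags)
            sr = stats.spearmanr(bic_diff, mags)
            pearson_r, pearson_p = float(pr.statistic), float(pr.pvalue)
            spearman_rho, spearman_p = float(sr.statistic), float(sr.pvalue)

    return ModelComparison(
        n_blocks=len(fits_a),
        bic_diff=bic_diff,
        win_fraction_a=float(wins.mean()),
        t_stat=float(t_stat),
        p_value=float(p_value),
        compared_on=compared_on,
        pearson_r=pearson_r,
        pearson_p=pearson_p,
        spearman_rho=spearman_rho,
        spearman_p=spearman_p,
        correlation_degenerate=degenerate,
    )
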