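"""Univariate Gaussian mixture decomposition by EM with BIC model selection.

Log2 expression distributions are modelled as finite mixtures of K normal
components, either with component-specific variances (family ``V``) or a
single shared variance (family ``E``). For each candidate (K, family) the
likelihood is maximized by expectation-maximization; the number of
components and the variance family are then selected by the Bayesian
information criterion in the maximize convention, BIC = 2*loglik - p*ln(n),
where p = 3K-1 for family V and 2K for family E.

Initialization is deterministic: component k starts at the (k-0.5)/K sample
quantile with equal weights and the sample variance, which makes fits
independent of input order and reproducible without a seed. Optional seeded
jittered restarts can be layered on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from fungiflow.quantify import ExpressionVector

_LOG_2PI = np.log(2.0 * np.pi)

FAMILIES = ("E", "V")


@dataclass(frozen=True)
class FitConfig:
    """EM and model-selection settings.

    k_range is inclusive; tol is a relative log-likelihood change; the
    variance floor is a fraction of the sample variance and guards against
    singular collapse of a component onto a single point.
    """

    k_min: int = 1
    k_max: int = 9
    families: tuple[str, ...] = ("E", "V")
    tol: float = 1e-8
    max_iter: int = 1000
    variance_floor_frac: float = 1e-6
    n_starts: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("k_range must be a nonempty range with k_min >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if not self.families or any(f not in FAMILIES for f in self.families):
            raise ValueError(f"families must be a nonempty subset of {FAMILIES}")

    @property
    def k_values(self) -> range:
        return range(self.k_min, self.k_max + 1)


@dataclass
class MixtureModel:
    """A fitted K-component univariate normal mixture."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    family: str
    loglik: float
    n: int
    converged: bool = True
    n_iter: int = 0
    degenerate: bool = False
    collapsed: bool = False
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    bic: float = field(init=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        k = len(self.weights)
        if not (len(self.means) == len(self.variances) == k) or k < 1:
            raise ValueError("weights, means, variances must share a length K >= 1")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1 within 1e-12")
        if (self.weights <= 0).any() or (self.weights > 1).any():
            raise ValueError("weights must lie in (0, 1]")
        if (self.variances <= 0).any():
            raise ValueError("variances must be positive")
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.family == "E" and not np.allclose(self.variances, self.variances[0]):
            raise ValueError("family E requires equal variances")
        self.bic = 2.0 * self.loglik - self.n_params * np.log(self.n)

    @property
    def K(self) -> int:
        return len(self.weights)

    @property
    def n_params(self) -> int:
        return 3 * self.K - 1 if self.family == "V" else 2 * self.K

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "family": self.family,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "loglik": self.loglik,
            "bic": self.bic,
            "n": self.n,
            "n_params": self.n_params,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "degenerate": self.degenerate,
            "collapsed": self.collapsed,
        }


def _as_array(values: ExpressionVector | Sequence[float] | np.ndarray) -> np.ndarray:
    if isinstance(values, ExpressionVector):
        x = values.to_numpy()
    else:
        x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expression values must be one-dimensional")
    if not np.isfinite(x).all():
        raise ValueError("expression values must be finite")
    return x


def _log_component_densities(x: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    # shape (n, K): log N(x_i; mu_k, sigma_k^2)
    diff = x[:, None] - means[None, :]
    return -0.5 * (_LOG_2PI + np.log(variances)[None, :] + diff * diff / variances[None, :])


def loglik(
    values: ExpressionVector | Sequence[float] | np.ndarray, model: MixtureModel
) -> float:
    """Mixture log-likelihood, computed in log space (log-sum-exp)."""
    x = _as_array(values)
    log_dens = _log_component_densities(x, model.means, model.variances)
    return float(logsumexp(log_dens + np.log(model.weights)[None, :], axis=1).sum())


def responsibilities(
    values: ExpressionVector | Sequence[float] | np.ndarray, model: MixtureModel
) -> np.ndarray:
    """Posterior component membership probabilities, rows summing to 1."""
    x = _as_array(values)
    log_r = _log_component_densities(x, model.means, model.variances) + np.log(model.weights)
    log_r -= logsumexp(log_r, axis=1, keepdims=True)
    return np.exp(log_r)


def _quantile_init(x: np.ndarray, K: int) -> np.ndarray:
    probs = (np.arange(1, K + 1) - 0.5) / K
    return np.quantile(x, probs)


def _em_once(
    x: np.ndarray,
    K: int,
    family: str,
    config: FitConfig,
    init_means: np.ndarray,
) -> MixtureModel:
    n = x.size
    sample_var = float(np.var(x))
    floor = max(config.variance_floor_frac * sample_var, 1e-300)

    # all-equal input: np.var of a constant vector can be ~1e-32 rather
    # than exactly zero, so compare against numerical noise, not zero
    if sample_var < 1e-20 * (1.0 + float(np.mean(x)) ** 2):
        # Degenerate data: every value identical. Report a single component
        # at the floor variance rather than a -inf likelihood.
        model = MixtureModel(
            weights=np.ones(1),
            means=np.array([x[0]]),
            variances=np.array([max(floor, 1e-12)]),
            family=family,
            loglik=float(n * (-0.5 * (_LOG_2PI + np.log(max(floor, 1e-12))))),
            n=n,
            converged=True,
            degenerate=True,
        )
        return model

    weights = np.full(K, 1.0 / K)
    means = init_means.astype(float).copy()
    variances = np.full(K, sample_var)

    trace: list[float] = []
    prev_ll = -np.inf
    prev_prev_ll = -np.inf
    floor_events = 0
    converged = False
    collapsed = False
    n_iter = 0

    xcol = x[:, None]
    for n_iter in range(1, config.max_iter + 1):
        # E-step, fused: r holds log densities, then responsibilities
        r = xcol - means[None, :]
        np.square(r, out=r)
        r *= -0.5 / variances[None, :]
        r += np.log(weights) - 0.5 * (_LOG_2PI + np.log(variances))
        shift = r.max(axis=1)
        np.subtract(r, shift[:, None], out=r)
        np.exp(r, out=r)
        norm = r.sum(axis=1)
        ll = float(np.log(norm).sum() + shift.sum())
        trace.append(ll)
        r /= norm[:, None]

        nk = np.maximum(r.sum(axis=0), 1e-300)
        weights = nk / n
        means = r.T @ x / nk
        diff2 = xcol - means[None, :]
        np.square(diff2, out=diff2)
        diff2 *= r
        if family == "V":
            variances = diff2.sum(axis=0) / nk
        else:
            variances = np.full(K, float(diff2.sum() / n))

        if (variances < floor).any():
            floor_events += 1
            variances = np.maximum(variances, floor)
            if floor_events >= 2:
                collapsed = True  # persistent collapse: flag and exclude from selection
                break

        scale = config.tol * (1.0 + abs(ll))
        if np.isfinite(prev_ll):
            delta = ll - prev_ll
            if abs(delta) <= scale:
                converged = True
                break
            # Aitken acceleration: in the geometric slow-creep regime the
            # asymptotic log-likelihood can be extrapolated; stop once the
            # projected remaining gain is below tolerance.
            if np.isfinite(prev_prev_ll):
                denom = prev_ll - prev_prev_ll
                if denom > 0:
                    rate = delta / denom
                    if 0.0 < rate < 1.0 and delta / (1.0 - rate) - delta <= scale:
                        converged = True
                        break
        prev_prev_ll = prev_ll
        prev_ll = ll

    final_ll = float(
        logsumexp(
            _log_component_densities(x, means, variances) + np.log(weights), axis=1
        ).sum()
    )
    trace.append(final_ll)
    return MixtureModel(
        weights=weights,
        means=means,
        variances=variances,
        family=family,
        loglik=final_ll,
        n=n,
        converged=converged,
        n_iter=n_iter,
        collapsed=collapsed,
        loglik_trace=np.asarray(trace),
    )


def em_fit(
    values: ExpressionVector | Sequence[float] | np.ndarray,
    K: int,
    family: str = "V",
    config: FitConfig | None = None,
) -> MixtureModel:
    """Fit a K-component mixture of the given variance family by EM.

    Starts from deterministic quantile initialization; with
    ``config.n_starts > 0`` additional seeded jittered starts are tried and
    the best converged fit by log-likelihood is returned.
    """
    config = config or FitConfig()
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    x = _as_array(values)
    if x.size < K:
        raise ValueError(f"need at least K={K} data points, got {x.size}")

    base_init = _quantile_init(x, K)
    candidates = [_em_once(x, K, family, config, base_init)]
    if config.n_starts > 0:
        rng = np.random.default_rng(config.seed)
        spread = float(np.std(x)) or 1.0
        for _ in range(config.n_starts):
            jitter = rng.normal(0.0, 0.25 * spread, size=K)
            candidates.append(_em_once(x, K, family, config, base_init + jitter))
    usable = [m for m in candidates if not m.collapsed] or candidates
    return max(usable, key=lambda m: m.loglik)


def bic(model: MixtureModel) -> float:
    """BIC in the maximize convention: 2*loglik - n_params*ln(n)."""
    return 2.0 * model.loglik - model.n_params * np.log(model.n)


def select_model(
    values: ExpressionVector | Sequence[float] | np.ndarray,
    config: FitConfig | None = None,
) -> tuple[MixtureModel, pd.DataFrame]:
    """Fit every (K, family) in the config and pick the argmax-BIC model.

    Returns the best model and the full BIC table for reporting. Fits that
    failed to converge (variance collapse) are listed but excluded from the
    selection. Ties break toward smaller K, then family E.
    """
    config = config or FitConfig()
    x = _as_array(values)
    if x.size == 0:
        raise ValueError("cannot select a model for an empty expression vector")

    rows = []
    models: list[MixtureModel] = []
    for K in config.k_values:
        if x.size < K:
            continue
        for family in config.families:
            model = em_fit(x, K, family, config)
            models.append(model)
            rows.append(
                {
                    "K": K,
                    "family": family,
                    "loglik": model.loglik,
                    "bic": model.bic,
                    "n_params": model.n_params,
                    "converged": model.converged,
                    "collapsed": model.collapsed,
                    "n_iter": model.n_iter,
                }
            )
    table = pd.DataFrame(rows)
    eligible = [m for m in models if not m.collapsed]
    if not eligible:
        raise RuntimeError("all mixture fits failed (every fit collapsed)")
    # tie-breaking: smaller K first, then family E
    eligible.sort(key=lambda m: (-m.bic, m.K, 0 if m.family == "E" else 1))
    best = eligible[0]
    return best, table


def mixture_density(
    model: MixtureModel, grid: Sequence[float] | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Total mixture density and per-component curves on a grid.

    Returns ``(total, components)`` with ``components`` of shape (K, len(grid));
    the component curves are weighted, so they sum to the total pointwise.
    """
    g = np.asarray(grid, dtype=float)
    if not np.isfinite(g).all():
        raise ValueError("grid must be finite")
    log_dens = _log_component_densities(g, model.means, model.variances)
    components = (model.weights[None, :] * np.exp(log_dens)).T
    return components.sum(axis=0), components
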