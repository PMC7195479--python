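"""Model-free integration kernels: logistic regression, shape labels, psychometrics.

The integration kernel of an observer is estimated by logistic regression of
choice (1 = left) on the 20 signed click indicators:

    logit p(left, trial k) = sum_i beta_i^click * dC_ki + beta^bias

The per-click weights beta_i^click are the empirical integration kernel;
beta^bias captures an overall side preference.  A deterministic heuristic
sorts kernels into the four phenotypes — primacy, bump, flat, recency —
by comparing early / middle / late segment means against a flatness
threshold proportional to the overall mean weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.optimize import minimize

from .task import Dataset

DEFAULT_EARLY_WINDOW = (1, 5)    # clicks 1-5 (1-based, inclusive)
DEFAULT_MIDDLE_WINDOW = (8, 13)
DEFAULT_LATE_WINDOW = (16, 20)
DEFAULT_FLATNESS_FRACTION = 0.15


class SeparationError(RuntimeError):
    """Raised when the logistic fit diverges (perfectly separated data)."""


@dataclass(frozen=True)
class KernelEstimate:
    """Fitted per-click regression weights with uncertainties."""

    beta_click: np.ndarray
    beta_bias: float
    standard_errors: np.ndarray  # length n_clicks + 1; last entry is the bias
    converged: bool
    n_trials: int
    participant_id: str = "p0"

    @property
    def click_standard_errors(self) -> np.ndarray:
        return self.standard_errors[:-1]


@dataclass(frozen=True)
class KernelShape:
    """A kernel phenotype label plus the contrasts that produced it."""

    label: str
    evidence: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PsychometricCurve:
    """Observed p(left) as a function of the signed click difference."""

    delta_levels: np.ndarray
    p_left: np.ndarray
    n_per_level: np.ndarray
    sigmoid_fit: dict | None = None


def fit_logistic_kernel(
    dataset: Dataset,
    ridge: float = 0.0,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> KernelEstimate:
    """Maximum-(penalized-)likelihood logistic kernel via Newton/IRLS.

    The design matrix is the (n_trials, n_clicks) signed click matrix plus an
    intercept column.  ``ridge`` adds an L2 penalty on the click weights
    (never the intercept); the default 0 is appropriate for the large
    synthetic samples used here, and a small positive value (1e-3) resolves
    perfect separation.  Standard errors come from the observed (penalized)
    information at the optimum.
    """
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    if len(dataset) < 50:
        raise ValueError("need at least 50 trials with choices")
    y = dataset.choices_binary()
    S = dataset.signs_matrix()
    n, p = S.shape
    X = np.column_stack([S, np.ones(n)])
    pen = np.append(np.full(p, ridge), 0.0)

    beta = np.zeros(p + 1)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        score = X.T @ (y - mu) - pen * beta
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X + np.diag(pen)
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError as err:
            raise SeparationError(
                "logistic kernel fit failed (singular information); the data "
                "may be perfectly separated — retry with ridge > 0"
            ) from err
        beta = beta + step
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e3:
            raise SeparationError(
                "logistic kernel fit diverged; the data may be perfectly "
                "separated — retry with ridge > 0 (e.g. 1e-3)"
            )
    if not converged:
        raise SeparationError(
            "logistic kernel fit did not converge in "
            f"{max_iter} iterations — retry with ridge > 0"
        )
    if ridge == 0.0:
        # every choice on the fitted side of the hyperplane proves the data
        # are perfectly separated: the unpenalized MLE does not exist
        margins = (2.0 * y - 1.0) * (X @ beta)
        if np.all(margins > 0):
            raise SeparationError(
                "data are perfectly separated (all margins positive); the "
                "unpenalized maximum-likelihood kernel does not exist — "
                "retry with ridge > 0 (e.g. 1e-3)"
            )

    mu = expit(X @ beta)
    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X + np.diag(pen)
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    pid = dataset.trials[0].participant_id if dataset.trials else "p0"
    return KernelEstimate(
        beta_click=beta[:-1],
        beta_bias=float(beta[-1]),
        standard_errors=se,
        converged=True,
        n_trials=n,
        participant_id=pid,
    )


def _window_slice(window: tuple[int, int]) -> slice:
    lo, hi = window
    return slice(lo - 1, hi)


def classify_profile(
    beta: np.ndarray,
    flatness_fraction: float = DEFAULT_FLATNESS_FRACTION,
    early_window: tuple[int, int] = DEFAULT_EARLY_WINDOW,
    middle_window: tuple[int, int] = DEFAULT_MIDDLE_WINDOW,
    late_window: tuple[int, int] = DEFAULT_LATE_WINDOW,
) -> KernelShape:
    """Deterministic shape rule on a weight profile.

    With e, m, l the early/middle/late segment means, g the overall mean and
    theta = flatness_fraction * |g|:

    - flat    if max(|e-m|, |m-l|, |e-l|) <= theta
    - bump    elif m > e + theta and m > l + theta
    - primacy elif e > l + theta
    - recency elif l > e + theta
    - flat    otherwise (fallback)

    The rule is scale-invariant for positive rescalings of beta, so analytic
    kernels can be classified on the (area*K + mu) scale without knowing
    sigma.
    """
    beta = np.asarray(beta, dtype=float)
    e = float(beta[_window_slice(early_window)].mean())
    m = float(beta[_window_slice(middle_window)].mean())
    l = float(beta[_window_slice(late_window)].mean())
    g = float(beta.mean())
    theta = flatness_fraction * abs(g)
    evidence = {"early": e, "middle": m, "late": l, "mean": g, "theta": theta}

    if max(abs(e - m), abs(m - l), abs(e - l)) <= theta:
        label = "flat"
    elif m > e + theta and m > l + theta:
        label = "bump"
    elif e > l + theta:
        label = "primacy"
    elif l > e + theta:
        label = "recency"
    else:
        label = "flat"
    return KernelShape(label=label, evidence=evidence)


def classify_kernel_shape(
    estimate: KernelEstimate,
    flatness_fraction: float = DEFAULT_FLATNESS_FRACTION,
    **windows,
) -> KernelShape:
    """Classify a fitted kernel estimate into one of the four phenotypes."""
    if not estimate.converged:
        raise ValueError("cannot classify a non-converged kernel estimate")
    return classify_profile(estimate.beta_click, flatness_fraction, **windows)


def psychometric_curve(
    dataset: Dataset,
    probabilities: np.ndarray | None = None,
    fit_sigmoid: bool = False,
) -> PsychometricCurve:
    """p(left) as a function of the click difference #left - #right.

    If ``probabilities`` is given (one model-predicted p(left) per trial) it
    is averaged per difficulty level instead of the recorded choices, which
    reproduces the model-predicted curve with the identical procedure.
    """
    signs = dataset.signs_matrix()
    delta = signs.sum(axis=1).astype(int)
    if probabilities is None:
        resp = dataset.choices_binary()
    else:
        resp = np.asarray(probabilities, dtype=float)
        if resp.shape != (len(dataset),):
            raise ValueError("probabilities must have one entry per trial")
    levels = np.unique(delta)
    p_left = np.array([resp[delta == lv].mean() for lv in levels])
    n_per = np.array([(delta == lv).sum() for lv in levels])

    sig = None
    if fit_sigmoid:
        y = resp
        x = delta.astype(float)

        def nll(theta):
            slope, mid = theta
            p = expit(slope * (x - mid))
            p = np.clip(p, 1e-10, 1 - 1e-10)
            return -np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))

        res = minimize(nll, x0=np.array([0.5, 0.0]), method="Nelder-Mead")
        sig = {"slope": float(res.x[0]), "midpoint": float(res.x[1])}

    return PsychometricCurve(levels, p_left, n_per, sig)


def cohort_mean_kernel(
    estimates: list[KernelEstimate],
) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted across-participant mean profile and s.e.m. per click."""
    if len(estimates) < 2:
        raise ValueError("need at least 2 kernel estimates")
    lengths = {len(e.beta_click) for e in estimates}
    if len(lengths) != 1:
        raise ValueError("kernel estimates have mixed numbers of clicks")
    B = np.array([e.beta_click for e in estimates])
    mean = B.mean(axis=0)
    sem = B.std(axis=0, ddof=1) / np.sqrt(B.shape[0])
    return mean, sem
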