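"""Dynamic divisive normalization as an evidence-accumulation model.

Two excitatory pools R_left and R_right receive the left- and right-ear
clicks; an inhibitory unit G pools their total activity (with weight
omega_I) and divisively scales the input drive:

    tau_R dR_i/dt = -R_i + C_i / (1 + G)
    tau_G dG/dt   = -G + omega_I * (R_left + R_right)

The click train is the signed evidence stream Delta-C(t) = C_left - C_right,
which takes value +1 or -1 throughout each 50-ms slot; numerically each click
is applied as a punctate impulse carrying its slot's evidence mass
a = inter-click interval (seconds).  The decision variable is
delta = R_left - R_right.  Because the delta subsystem is linear, delta at
the decision time T is an explicit weighted sum of the signed clicks:

    delta(T) = sum_i a * K(T, t_i) * sign_i,
    K(T, t') = (1/tau_R) * exp(-(T - t')/tau_R) / (1 + G(t'-))

K is the model's integration kernel: the weight a click at time t' carries in
the final decision.  Its shape (primacy / bump / flat / recency) is set by
the balance between the leak rate 1/tau_R and the inhibition rate 1/tau_G.

Choice is read out through a logistic rule with decision noise sigma, a flat
kernel offset mu, and a side bias:

    logit p(left) = (sum_i (a * K(T, t_i) + mu) * sign_i) / sigma + bias

At a click the corresponding R unit jumps by a/(tau_R * (1 + G(t-))) with G
evaluated just before the impulse; G itself is continuous across clicks.
(Folding the click mass a into the per-click weight is an exact
reparameterization of mu and sigma.)
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import expit

from .task import ClickTrain, Dataset, TaskProtocol

#: Probabilities are clipped to [PROB_CLIP, 1 - PROB_CLIP] before taking logs.
PROB_CLIP = 1e-10


@dataclass(frozen=True)
class DivNormParams:
    """The six free parameters of the divisive-normalization observer.

    tau_R, tau_G are in seconds; omega_I, sigma, mu, bias are dimensionless.
    """

    tau_R: float
    tau_G: float
    omega_I: float
    sigma: float = 1.0
    mu: float = 0.0
    bias: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_R <= 0 or self.tau_G <= 0:
            raise ValueError("tau_R and tau_G must be > 0")
        if self.omega_I < 0:
            raise ValueError("omega_I must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    def to_dict(self) -> dict:
        return {
            "tau_R": self.tau_R,
            "tau_G": self.tau_G,
            "omega_I": self.omega_I,
            "sigma": self.sigma,
            "mu": self.mu,
            "bias": self.bias,
        }


@dataclass(frozen=True)
class Trajectory:
    """Simulated time courses of the two R units, G, and delta."""

    time_grid: np.ndarray
    R_left: np.ndarray
    R_right: np.ndarray
    G: np.ndarray

    @property
    def delta(self) -> np.ndarray:
        return self.R_left - self.R_right

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.time_grid,
                "R_left": self.R_left,
                "R_right": self.R_right,
                "G": self.G,
                "delta": self.delta,
            }
        )


@dataclass(frozen=True)
class KernelWeights:
    """Analytic per-click kernel values K(T, t_i) plus the offset mu.

    ``per_click_K`` holds the kernel *function* values K(T, t_i) (units 1/s);
    a click's weight in the decision variable is ``click_area * K + mu``,
    where ``click_area`` is the evidence mass each click carries (seconds).
    """

    per_click_K: np.ndarray
    mu: float
    decision_time: float
    click_area: float = 1.0

    @property
    def per_click_weight(self) -> np.ndarray:
        """Effective logit weight per click before noise: area*K + mu."""
        return self.click_area * self.per_click_K + self.mu


def _infer_click_area(times: np.ndarray, duration: float) -> float:
    """Evidence mass per click: the slot width of the click grid.

    For a multi-click train this is the smallest inter-click gap (the slot
    width, 0.05 s under the default protocol); a single click spans the whole
    stimulus.
    """
    times = np.asarray(times, dtype=float)
    if times.size > 1:
        return float(np.min(np.diff(times)))
    return float(duration)


def static_normalization(u, S: float) -> np.ndarray:
    """Static divisive normalization f_i = u_i / (S + sum_j u_j)."""
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or S < 0:
        raise ValueError("inputs and S must be nonnegative")
    denom = S + u.sum()
    if denom == 0:
        raise ZeroDivisionError("S + sum(u) must be > 0")
    return u / denom


def _segment_nodes(a: float, b: float, dt: float) -> int:
    """Number of equal RK4 substeps covering [a, b] with step <= dt."""
    return max(1, int(np.ceil((b - a) / dt - 1e-12)))


def simulate_dynamics(
    params: DivNormParams, train: ClickTrain, dt: float = 1e-3
) -> Trajectory:
    """Integrate the full (R_left, R_right, G) system for one click train.

    Between clicks the smooth system is advanced with classical fixed-step
    RK4; the grid contains every click time exactly, and at a click the
    corresponding R unit jumps by a/(tau_R * (1 + G)) — a is the click's
    evidence mass (the slot width) and G is taken just before the impulse.
    Values stored at click nodes are post-jump.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    times = np.asarray(train.times, dtype=float)
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("click times must be strictly increasing")
    if times.size:
        min_gap = min(np.min(np.diff(times)), train.duration - times[-1]) if times.size > 1 else train.duration - times[-1]
        if dt > min_gap + 1e-12:
            raise ValueError("dt must not exceed the inter-click spacing")

    tau_R, tau_G, w = params.tau_R, params.tau_G, params.omega_I
    area = _infer_click_area(times, train.duration)

    grid = [0.0]
    RL = [0.0]
    RR = [0.0]
    GG = [0.0]
    rl = rr = g = 0.0
    t = 0.0

    events = list(times)
    boundaries = events + [train.duration]

    def rk4_advance(rl, rr, g, h):
        def deriv(x, y, z):
            return (-x / tau_R, -y / tau_R, (w * (x + y) - z) / tau_G)

        k1 = deriv(rl, rr, g)
        k2 = deriv(rl + 0.5 * h * k1[0], rr + 0.5 * h * k1[1], g + 0.5 * h * k1[2])
        k3 = deriv(rl + 0.5 * h * k2[0], rr + 0.5 * h * k2[1], g + 0.5 * h * k2[2])
        k4 = deriv(rl + h * k3[0], rr + h * k3[1], g + h * k3[2])
        rl += h / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        rr += h / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        g += h / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        return rl, rr, g

    ev = 0
    for b in boundaries:
        # impulse at the segment start if it is a click time
        if ev < len(events) and abs(t - events[ev]) < 1e-12:
            jump = area / (tau_R * (1.0 + g))
            if train.signs[ev] > 0:
                rl += jump
            else:
                rr += jump
            RL[-1], RR[-1], GG[-1] = rl, rr, g
            ev += 1
        if b <= t + 1e-15:
            continue
        n_sub = _segment_nodes(t, b, dt)
        h = (b - t) / n_sub
        for j in range(n_sub):
            rl, rr, g = rk4_advance(rl, rr, g, h)
            t_node = t + (j + 1) * h
            grid.append(t_node)
            RL.append(rl)
            RR.append(rr)
            GG.append(g)
        t = b

    return Trajectory(
        np.asarray(grid), np.asarray(RL), np.asarray(RR), np.asarray(GG)
    )


def _integrate_gain_scalar(
    tau_R: float,
    tau_G: float,
    omega_I: float,
    times: tuple,
    duration: float,
    dt: float,
    area: float,
    record: bool = False,
):
    """RK4 on the reduced (A, G) system, A = R_left + R_right.

    The total drive is one impulse of mass ``area`` per click time regardless
    of side, so A and G are shared by every train with the same timing.
    Returns the G value just before each click (and, if ``record``, the full
    grid).  Scalar arithmetic keeps this fast enough for the inner fitting
    loop.
    """
    a = g = 0.0
    t = 0.0
    g_pre = []
    grid = [0.0] if record else None
    AA = [0.0] if record else None
    GG = [0.0] if record else None

    boundaries = list(times) + [duration]
    ev = 0
    for b in boundaries:
        if ev < len(times) and abs(t - times[ev]) < 1e-12:
            g_pre.append(g)
            a += area / (tau_R * (1.0 + g))
            if record:
                AA[-1] = a
            ev += 1
        if b <= t + 1e-15:
            continue
        n_sub = _segment_nodes(t, b, dt)
        h = (b - t) / n_sub
        h2 = 0.5 * h
        for j in range(n_sub):
            k1a = -a / tau_R
            k1g = (omega_I * a - g) / tau_G
            a2 = a + h2 * k1a
            g2 = g + h2 * k1g
            k2a = -a2 / tau_R
            k2g = (omega_I * a2 - g2) / tau_G
            a3 = a + h2 * k2a
            g3 = g + h2 * k2g
            k3a = -a3 / tau_R
            k3g = (omega_I * a3 - g3) / tau_G
            a4 = a + h * k3a
            g4 = g + h * k3g
            k4a = -a4 / tau_R
            k4g = (omega_I * a4 - g4) / tau_G
            a += h / 6.0 * (k1a + 2 * k2a + 2 * k3a + k4a)
            g += h / 6.0 * (k1g + 2 * k2g + 2 * k3g + k4g)
            if record:
                grid.append(t + (j + 1) * h)
                AA.append(a)
                GG.append(g)
        t = b

    if record:
        return np.asarray(g_pre), np.asarray(grid), np.asarray(AA), np.asarray(GG)
    return np.asarray(g_pre)


@lru_cache(maxsize=8192)
def _kernel_values_cached(
    tau_R: float,
    tau_G: float,
    omega_I: float,
    times: tuple,
    duration: float,
    dt: float,
) -> tuple:
    area = _infer_click_area(np.asarray(times), duration)
    g_pre = _integrate_gain_scalar(
        tau_R, tau_G, omega_I, times, duration, dt, area
    )
    t_arr = np.asarray(times)
    K = (1.0 / tau_R) * np.exp(-(duration - t_arr) / tau_R) / (1.0 + g_pre)
    return tuple(K)


def gain_trajectory(
    params: DivNormParams, protocol: TaskProtocol, dt: float = 1e-3
):
    """The G(t) time course shared by all trains under a fixed-grid protocol.

    Because every slot receives exactly one click on one side or the other,
    the total excitatory drive — and hence G — is identical across trains.
    Integrated with the same RK4 stepper as :func:`simulate_dynamics`, so the
    two agree to rounding error.
    """
    if not isinstance(protocol, TaskProtocol):
        raise TypeError("gain_trajectory requires a fixed-grid TaskProtocol")
    times = tuple(float(t) for t in protocol.click_times)
    area = _infer_click_area(np.asarray(times), protocol.stimulus_duration)
    _, grid, _, G = _integrate_gain_scalar(
        params.tau_R, params.tau_G, params.omega_I, times,
        protocol.stimulus_duration, dt, area, record=True,
    )
    return grid, G


def kernel_weights(
    params: DivNormParams, train: ClickTrain, dt: float = 1e-3
) -> KernelWeights:
    """Analytic integration-kernel values K(T, t_i) for one train's timing.

    G is evaluated just before each click's own impulse.  Results are cached
    per (tau_R, tau_G, omega_I, timing), so repeated likelihood evaluations
    over a fixed protocol reuse the same gain integration.
    """
    times = tuple(float(t) for t in train.times)
    K = _kernel_values_cached(
        params.tau_R, params.tau_G, params.omega_I, times, train.duration, dt
    )
    return KernelWeights(
        np.asarray(K),
        params.mu,
        train.duration,
        _infer_click_area(train.times, train.duration),
    )


def decision_variable(
    params: DivNormParams, train: ClickTrain, dt: float = 1e-3
) -> float:
    """delta'(T) = sum_i (a * K(T, t_i) + mu) * sign_i."""
    kw = kernel_weights(params, train, dt)
    return float(np.dot(kw.per_click_weight, train.signs))


def choice_probability(
    params: DivNormParams, train: ClickTrain, dt: float = 1e-3
) -> float:
    """p(left) = logistic(delta'(T) / sigma + bias)."""
    dp = decision_variable(params, train, dt)
    return float(expit(dp / params.sigma + params.bias))


def choice_probability_matrix(
    params: DivNormParams,
    signs: np.ndarray,
    times: np.ndarray,
    duration: float,
    dt: float = 1e-3,
) -> np.ndarray:
    """Vectorized p(left) for an (n_trials, n_clicks) signed click matrix."""
    K = np.asarray(
        _kernel_values_cached(
            params.tau_R,
            params.tau_G,
            params.omega_I,
            tuple(float(t) for t in times),
            duration,
            dt,
        )
    )
    area = _infer_click_area(np.asarray(times), duration)
    eta = signs @ (area * K + params.mu) / params.sigma + params.bias
    return expit(eta)


def log_likelihood(
    params: DivNormParams, dataset: Dataset, dt: float = 1e-3
) -> float:
    """Bernoulli log likelihood of the recorded choices under the model.

    Choice probabilities are clipped to [1e-10, 1 - 1e-10] before logs so
    the result stays finite for extreme parameters.
    """
    d = dataset.choices_binary()
    signs = dataset.signs_matrix()
    p = choice_probability_matrix(
        params,
        signs,
        dataset.protocol.click_times,
        dataset.protocol.stimulus_duration,
        dt,
    )
    p = np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP)
    return float(np.sum(d * np.log(p) + (1.0 - d) * np.log1p(-p)))


class DivNormObserver:
    """A callable observer mapping a ClickTrain to p(left).

    Suitable for :func:`clicknorm.task.simulate_choices`; kernel values are
    cached per click timing, so per-trial calls are cheap under a fixed
    protocol.
    """

    def __init__(
        self, params: DivNormParams, protocol: TaskProtocol | None = None,
        dt: float = 1e-3,
    ):
        self.params = params
        self.protocol = protocol
        self.dt = dt

    def __call__(self, train: ClickTrain) -> float:
        return choice_probability(self.params, train, self.dt)

    def p_left_matrix(self, signs: np.ndarray) -> np.ndarray:
        if self.protocol is None:
            raise ValueError("protocol required for matrix evaluation")
        return choice_probability_matrix(
            self.params,
            signs,
            self.protocol.click_times,
            self.protocol.stimulus_duration,
            self.dt,
        )
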