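"""Drift-diffusion-family benchmark observers: DDM, LCA, and the bounded
adaptive accumulator of Brunton et al.

All three accumulate the signed clicks (+1 left, -1 right) in a scalar
decision variable a:

    da = (lam * a + C(t)) dt + sigma_a dW

- basic DDM:  lam = 0, no bound.  The integration kernel is flat.
- LCA:        lam free.  lam < 0 leaks memory (recency), lam > 0 amplifies
  early evidence (primacy).  Without a bound, a(T) is Gaussian and the choice
  probability has a closed form.
- Brunton model: adds a sticky absorbing bound B (evidence after the bound is
  crossed is ignored) and per-side sensory adaptation: each click's impact is
  multiplied by an adaptation state that is scaled by phi after every click
  on that side and relaxes back to 1 with time constant tau_phi.  Choice
  probability comes from propagating the accumulator density between clicks
  with the exact Ornstein-Uhlenbeck transition kernel on a grid with
  absorbing boundaries.

The decision is read out at stimulus end T by comparing a(T) (or the
absorbed side) with the bias threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.special import ndtr  # standard normal CDF, vectorized
from scipy import sparse

from .task import ClickTrain, Dataset


@dataclass(frozen=True)
class LCAParams:
    """Leaky/unstable accumulator: da = (lam*a + C)dt + sigma_a dW."""

    lam: float
    sigma_a: float
    bias: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_a <= 0:
            raise ValueError("sigma_a must be > 0")

    def to_dict(self) -> dict:
        return {"lam": self.lam, "sigma_a": self.sigma_a, "bias": self.bias}


@dataclass(frozen=True)
class BruntonParams:
    """Six-parameter bounded adaptive accumulator."""

    sigma_a: float
    lam: float
    B: float
    phi: float
    tau_phi: float
    bias: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_a <= 0:
            raise ValueError("sigma_a must be > 0")
        if self.B <= 0:
            raise ValueError("bound B must be > 0")
        if self.phi <= 0 or self.tau_phi <= 0:
            raise ValueError("phi and tau_phi must be > 0")
        if abs(self.bias) >= self.B:
            raise ValueError("|bias| must be < B")

    def to_dict(self) -> dict:
        return {
            "sigma_a": self.sigma_a,
            "lam": self.lam,
            "B": self.B,
            "phi": self.phi,
            "tau_phi": self.tau_phi,
            "bias": self.bias,
        }


@dataclass
class DensityGrid:
    """Accumulator probability mass on a uniform grid over [-B, +B].

    ``masses[i]`` is the probability mass in the cell centred on
    ``a_values[i]``; ``absorbed_left``/``absorbed_right`` hold the mass
    committed at the +B / -B bound.
    """

    a_values: np.ndarray
    masses: np.ndarray
    absorbed_left: float = 0.0
    absorbed_right: float = 0.0

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum() + self.absorbed_left + self.absorbed_right)


def make_density_grid(B: float, n_nodes: int = 501) -> DensityGrid:
    """Point mass at a = 0 on a symmetric grid (n_nodes must be odd)."""
    if n_nodes < 201:
        raise ValueError("need at least 201 grid nodes")
    if n_nodes % 2 == 0:
        raise ValueError("n_nodes must be odd so that a = 0 is a node")
    a = np.linspace(-B, B, n_nodes)
    m = np.zeros(n_nodes)
    m[n_nodes // 2] = 1.0
    return DensityGrid(a, m)


# --- closed-form LCA -------------------------------------------------------

def _lca_variance(lam: float, sigma_a: float, T: float) -> float:
    if lam == 0.0:
        return sigma_a**2 * T
    return sigma_a**2 * (np.exp(2.0 * lam * T) - 1.0) / (2.0 * lam)


def lca_mean_weights(lam: float, times: np.ndarray, T: float) -> np.ndarray:
    """Contribution e^{lam (T - t_i)} of a unit click to the mean of a(T)."""
    return np.exp(lam * (T - np.asarray(times, dtype=float)))


def lca_choice_probability(params: LCAParams, train: ClickTrain) -> float:
    """Exact p(left) for the unbounded accumulator.

    a(T) is Gaussian with mean sum_i sign_i e^{lam (T - t_i)} and variance
    sigma_a^2 (e^{2 lam T} - 1) / (2 lam); p(left) = P(a(T) > bias).
    """
    T = train.duration
    m = float(np.dot(train.signs, lca_mean_weights(params.lam, train.times, T)))
    v = _lca_variance(params.lam, params.sigma_a, T)
    return float(ndtr((m - params.bias) / np.sqrt(v)))


def lca_choice_probability_matrix(
    params: LCAParams, signs: np.ndarray, times: np.ndarray, T: float
) -> np.ndarray:
    w = lca_mean_weights(params.lam, times, T)
    m = signs @ w
    v = _lca_variance(params.lam, params.sigma_a, T)
    return ndtr((m - params.bias) / np.sqrt(v))


def ddm_choice_probability(sigma_a: float, bias: float, train: ClickTrain) -> float:
    """Basic drift-diffusion model: the lam = 0 special case of the LCA."""
    return lca_choice_probability(LCAParams(0.0, sigma_a, bias), train)


# --- sensory adaptation ----------------------------------------------------

def adaptation_magnitudes(
    train: ClickTrain, phi: float, tau_phi: float
) -> np.ndarray:
    """Effective magnitude of each click under per-side sensory adaptation.

    Each side keeps an adaptation state starting at 1.  A click's magnitude
    is the state at its onset; immediately after, the state is multiplied by
    phi, and between same-side clicks it relaxes towards 1 as
    d(state)/dt = (1 - state)/tau_phi.  Clicks on the other side are
    unaffected.
    """
    if phi <= 0 or tau_phi <= 0:
        raise ValueError("phi and tau_phi must be > 0")
    times = np.asarray(train.times, dtype=float)
    signs = np.asarray(train.signs)
    mags = np.empty(len(times))
    for side in (1, -1):
        state = 1.0
        t_prev = None
        for i in np.flatnonzero(signs == side):
            if t_prev is not None:
                gap = times[i] - t_prev
                state = 1.0 - (1.0 - state) * np.exp(-gap / tau_phi)
            mags[i] = state
            state = phi * state
            t_prev = times[i]
    return mags


# --- Fokker-Planck density propagation -------------------------------------

@lru_cache(maxsize=256)
def _ou_propagator(
    lam: float, sigma_a: float, dt: float, B: float, n_nodes: int
):
    """One-step transition operator for the OU-type drift-diffusion step.

    Each source cell's mass is moved to mean x*e^{lam dt} and spread with the
    exact Gaussian transition standard deviation, integrated over destination
    cells; mass beyond +B / -B is absorbed.  Columns sum to one, so mass is
    conserved to rounding error.  Returns (sparse matrix M, absorb_left
    vector, absorb_right vector) with p_new = M @ p.
    """
    x = np.linspace(-B, B, n_nodes)
    dx = x[1] - x[0]
    s_true = np.sqrt(_lca_variance(lam, sigma_a, dt))
    if lam != 0.0 and s_true < dx / 2.0:
        min_dt = dt * (dx / (2.0 * s_true)) ** 2
        raise ValueError(
            "transition kernel narrower than half a grid cell with nonzero "
            f"drift; increase dt to >= {min_dt:.3g} s or use a coarser grid"
        )
    # Sheppard correction: representing each cell's mass at its centre adds
    # dx^2/12 of variance per step, so the kernel is narrowed to compensate.
    s = float(np.sqrt(max(s_true**2 - dx**2 / 12.0, 0.0)))
    c = x * np.exp(lam * dt)

    half_width = max(8.0 * s, dx)
    kmax = int(np.ceil(half_width / dx)) + 1
    offsets = np.arange(-kmax, kmax + 1)
    idx = np.arange(n_nodes)

    # band of destination cells around each source's shifted mean
    ci = np.clip(np.rint((c + B) / dx).astype(int), 0, n_nodes - 1)
    rows = ci[:, None] + offsets[None, :]
    valid = (rows >= 0) & (rows < n_nodes)
    rows_c = np.clip(rows, 0, n_nodes - 1)
    # cell edges (outermost cells are half-width, truncated at the bounds)
    lo = np.maximum(x[rows_c] - dx / 2.0, -B)
    hi = np.minimum(x[rows_c] + dx / 2.0, B)

    if s > 0:
        frac = (ndtr((hi - c[:, None]) / s) - ndtr((lo - c[:, None]) / s)) * valid
        abs_left = 1.0 - ndtr((B - c) / s)
        abs_right = ndtr((-B - c) / s)
        # in-bound mass outside the band goes to the band's extreme cells
        top_i = np.minimum(ci + kmax, n_nodes - 1)
        bot_i = np.maximum(ci - kmax, 0)
        top_edge = np.minimum(x[top_i] + dx / 2.0, B)
        bot_edge = np.maximum(x[bot_i] - dx / 2.0, -B)
        frac[idx, kmax + top_i - ci] += ndtr((B - c) / s) - ndtr(
            (top_edge - c) / s
        )
        frac[idx, kmax + bot_i - ci] += ndtr((bot_edge - c) / s) - ndtr(
            (-B - c) / s
        )
    else:  # degenerate: all mass at the shifted mean
        frac = ((hi >= c[:, None]) & (lo < c[:, None])).astype(float) * valid
        abs_left = (c > B).astype(float)
        abs_right = (c < -B).astype(float)

    if s > 0:
        # Brownian-bridge correction: paths from x to y inside the bounds may
        # still have crossed a bound within the step; crossing probability
        # exp(-2 (B-x)(B-y) / s^2) for the top bound (mirror for the bottom).
        x_dst = x[rows_c]
        with np.errstate(under="ignore"):
            p_top = np.exp(
                -2.0
                * np.maximum(B - x[:, None], 0.0)
                * np.maximum(B - x_dst, 0.0)
                / s_true**2
            )
            p_bot = np.exp(
                -2.0
                * np.maximum(B + x[:, None], 0.0)
                * np.maximum(B + x_dst, 0.0)
                / s_true**2
            )
        crossed = np.clip(p_top + p_bot, 0.0, 1.0)
        abs_left = abs_left + (frac * p_top).sum(axis=1)
        abs_right = abs_right + (frac * np.minimum(p_bot, 1.0 - p_top)).sum(axis=1)
        frac = frac * (1.0 - crossed)

    cols = np.repeat(idx, len(offsets))
    M = sparse.csr_matrix(
        (frac.ravel(), (rows_c.ravel(), cols)), shape=(n_nodes, n_nodes)
    )
    return M, abs_left, abs_right


def fokker_planck_step(
    grid: DensityGrid, lam: float, sigma_a: float, dt: float
) -> DensityGrid:
    """Advance the density one time step under drift lam*a and diffusion.

    Uses the exact Ornstein-Uhlenbeck transition kernel integrated over grid
    cells, with absorbing boundaries at +-B.  Raises a configuration error,
    with the admissible bound, if the one-step kernel is too narrow to
    resolve a nonzero drift on this grid.
    """
    B = float(grid.a_values[-1])
    n = len(grid.a_values)
    M, aL, aR = _ou_propagator(float(lam), float(sigma_a), float(dt), B, n)
    masses = M @ grid.masses
    return DensityGrid(
        grid.a_values,
        masses,
        grid.absorbed_left + float(aL @ grid.masses),
        grid.absorbed_right + float(aR @ grid.masses),
    )


def apply_click(grid: DensityGrid, delta: float) -> DensityGrid:
    """Shift the interior mass by a click's signed magnitude.

    Linear re-binning onto the grid; mass pushed beyond a bound is absorbed
    on that side (the sticky-bound semantics: it never returns).
    """
    x = grid.a_values
    dx = x[1] - x[0]
    n = len(x)
    f = delta / dx
    i0 = int(np.floor(f))
    w_hi = f - i0
    new = np.zeros(n)
    aL = grid.absorbed_left
    aR = grid.absorbed_right

    for shift, w in ((i0, 1.0 - w_hi), (i0 + 1, w_hi)):
        if w == 0.0:
            continue
        src = np.arange(n)
        dst = src + shift
        inside = (dst >= 0) & (dst < n)
        np.add.at(new, dst[inside], w * grid.masses[src[inside]])
        aL += w * grid.masses[src[dst >= n]].sum()
        aR += w * grid.masses[src[dst < 0]].sum()
    return DensityGrid(x, new, aL, aR)


def _mass_above(grid: DensityGrid, threshold: float) -> float:
    """Interior mass above a threshold, splitting the straddled cell linearly
    (a node exactly at the threshold contributes half its cell)."""
    x = grid.a_values
    dx = x[1] - x[0]
    hi_edges = x + dx / 2.0
    lo_edges = x - dx / 2.0
    fraction = np.clip((hi_edges - threshold) / dx, 0.0, 1.0)
    # cells fully below contribute 0, fully above contribute 1
    fraction[lo_edges >= threshold] = 1.0
    fraction[hi_edges <= threshold] = 0.0
    return float(np.dot(fraction, grid.masses))


def brunton_choice_probability(
    params: BruntonParams,
    train: ClickTrain,
    n_nodes: int = 501,
    dt: float = 0.0125,
) -> float:
    """p(left) for the bounded adaptive accumulator by density propagation.

    Clicks shift the density by their adapted magnitudes; between clicks the
    density diffuses (and drifts, if lam != 0) with absorbing bounds at +-B.
    At T, p(left) = mass absorbed at +B plus interior mass above the bias.
    """
    grid = make_density_grid(params.B, n_nodes)
    mags = adaptation_magnitudes(train, params.phi, params.tau_phi)
    times = np.asarray(train.times, dtype=float)
    signs = np.asarray(train.signs, dtype=float)

    t = 0.0
    events = list(zip(times, signs * mags)) + [(train.duration, None)]
    for t_ev, delta in events:
        gap = t_ev - t
        if gap > 1e-12:
            n_sub = max(1, int(np.ceil(gap / dt - 1e-12)))
            h = gap / n_sub
            for _ in range(n_sub):
                grid = fokker_planck_step(grid, params.lam, params.sigma_a, h)
        if delta is not None:
            grid = apply_click(grid, float(delta))
        t = t_ev

    return grid.absorbed_left + _mass_above(grid, params.bias)


def lca_bounded_choice_probability(
    params: LCAParams,
    B: float,
    train: ClickTrain,
    n_nodes: int = 501,
    dt: float = 0.0125,
) -> float:
    """LCA with a sticky bound: the Brunton model with adaptation switched off."""
    bp = BruntonParams(
        sigma_a=params.sigma_a,
        lam=params.lam,
        B=B,
        phi=1.0,
        tau_phi=1.0,
        bias=params.bias,
    )
    return brunton_choice_probability(bp, train, n_nodes, dt)


# --- likelihoods -----------------------------------------------------------

def benchmark_log_likelihood(
    model_tag: str,
    params,
    dataset: Dataset,
    **solver_options,
) -> float:
    """Bernoulli log likelihood of a dataset under a benchmark observer.

    ``model_tag`` is one of ``ddm``, ``lca``, ``lca_bound`` (needs ``B`` in
    the solver options), ``brunton``.  Probabilities are clipped to
    [1e-10, 1 - 1e-10] as in the divisive-normalization likelihood.
    """
    from .divnorm import PROB_CLIP

    d = dataset.choices_binary()
    proto = dataset.protocol
    signs = dataset.signs_matrix()
    if model_tag in ("ddm", "lca"):
        p = lca_choice_probability_matrix(
            params, signs, proto.click_times, proto.stimulus_duration
        )
    elif model_tag == "lca_bound":
        B = solver_options.pop("B")
        p = np.array(
            [
                lca_bounded_choice_probability(
                    params, B, t.train, **solver_options
                )
                for t in dataset.trials
            ]
        )
    elif model_tag == "brunton":
        p = np.array(
            [
                brunton_choice_probability(params, t.train, **solver_options)
                for t in dataset.trials
            ]
        )
    else:
        raise ValueError(f"unknown model tag {model_tag!r}")
    p = np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP)
    return float(np.sum(d * np.log(p) + (1.0 - d) * np.log1p(-p)))
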