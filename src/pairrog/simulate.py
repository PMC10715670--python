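"""Generative sampling from the pairwise RoG and synthetic experiment designs.

Presets named after the simulation experiments they emulate:

``fig1``
    Moment-validation draws at the pair-parameter level: mu_N ~ U[0, 100],
    mu_D ~ U[0.5, 1.5], sigma_N^2 = mu_N^beta_N, sigma_D^2 = 0.001 mu_D^beta_D
    with beta ~ U[1, 1.5], rho_N, rho_D ~ U[-0.5, 0.5], additive-noise variance
    10% of the numerator-path response variance, rho_eta = 0.
``fig2``
    Contrast-tuning draws: R_max ~ U[5, 50], epsilon ~ U[10, 100],
    alpha ~ U[0.1, 1], beta ~ U[1, 2], no residual noise; the coupling
    correlations are set per experiment.
``fig3``
    As ``fig2`` but with rho_N, rho_D ~ U[-0.9, 0.9] (inference experiments).
``fig4``
    Single-trial-normalization experiments: R_max ~ U[10, 100],
    epsilon ~ U[15, 25], alpha ~ U[0.1, 1], beta ~ U[1, 1.5], no residual
    noise; rho_N, rho_D ~ U[-0.9, 0.9] unless set explicitly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import PairParams, ValidityWarning
from .dataset import Dataset
from .tuning import ContrastTuning, MarginalTuning, build_pair_params

__all__ = [
    "ParameterGrid",
    "sample_trials",
    "generate_parameter_grid",
    "generate_dataset",
    "generate_fluorescence_fixture",
    "PRESET_CONTRASTS",
    "FRAMES_PER_TRIAL",
]

#: Default stimulus sets by preset (contrast percent).
PRESET_CONTRASTS = {
    "fig2": (6.25, 12.5, 25.0, 50.0, 100.0),
    "fig3": (6.25, 12.5, 25.0, 50.0, 100.0),
    "fig4": (6.25, 12.5, 25.0, 50.0, 100.0),
}

FRAMES_PER_TRIAL = 24


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _bvn(rng: np.random.Generator, mu, sigma, rho, T: int) -> np.ndarray:
    """Draw T samples from a bivariate normal given per-neuron mean/SD and
    correlation. Shapes broadcast: mu, sigma (..., 2), rho (...,).
    Returns (..., T, 2)."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    rho = np.asarray(rho, dtype=float)
    base = np.broadcast_shapes(mu.shape[:-1], sigma.shape[:-1], rho.shape)
    z = rng.standard_normal(base + (T, 2))
    x1 = mu[..., None, 0] + sigma[..., None, 0] * z[..., 0]
    x2 = mu[..., None, 1] + sigma[..., None, 1] * (
        rho[..., None] * z[..., 0] + np.sqrt(1.0 - rho[..., None] ** 2) * z[..., 1]
    )
    return np.stack([x1, x2], axis=-1)


def sample_trials(params: PairParams, T: int, seed, return_latents: bool = False):
    """Draw ``T`` i.i.d. trials R = N/D + eta from the generative model.

    N and D are sampled from their bivariate Gaussians (independent of each
    other), eta from its own.  Trials where a sampled denominator is <= 0 are
    still computed (the ratio is then unreliable) but counted and warned about.
    With ``return_latents`` the sampled (D1, D2) draws are returned alongside,
    for ground-truth evaluation of single-trial normalization estimators.

    Deterministic given an integer ``seed``; a Generator may be passed instead.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = _rng(seed)
    N = _bvn(rng, params.mu_N, params.sigma_N, params.rho_N, T)
    D = _bvn(rng, params.mu_D, params.sigma_D, params.rho_D, T)
    eta = _bvn(rng, params.mu_eta, params.sigma_eta, params.rho_eta, T)
    n_bad = int(np.count_nonzero(np.any(D <= 0, axis=-1)))
    if n_bad:
        warnings.warn(
            f"{n_bad}/{T} trials sampled a denominator <= 0; ratios for those "
            "trials are outside the model's validity regime",
            ValidityWarning,
            stacklevel=2,
        )
    R = N / D + eta
    if return_latents:
        return R, D
    return R


@dataclass
class ParameterGrid:
    """Named collection of parameter draws for a simulation experiment.

    ``draws`` holds :class:`ContrastTuning` objects for the contrast-tuned
    presets (fig2/fig3/fig4) and :class:`PairParams` objects for the
    pair-level moment-validation preset (fig1).
    """

    preset: str
    seed: int
    draws: list = field(default_factory=list)
    contrasts: tuple = ()

    def __len__(self) -> int:
        return len(self.draws)


def _draw_fig1_params(rng: np.random.Generator) -> PairParams:
    mu_N = rng.uniform(0.0, 100.0, size=2)
    mu_D = rng.uniform(0.5, 1.5, size=2)
    beta_N = rng.uniform(1.0, 1.5, size=2)
    beta_D = rng.uniform(1.0, 1.5, size=2)
    sigma_N = np.sqrt(1.0 * mu_N**beta_N)
    sigma_D = np.sqrt(0.001 * mu_D**beta_D)
    # Additive noise carries 10% of the numerator-path response variance.
    sigma_eta = np.sqrt(0.1 * sigma_N**2 / mu_D**2)
    rho_N = rng.uniform(-0.5, 0.5)
    rho_D = rng.uniform(-0.5, 0.5)
    return PairParams(
        mu_N=mu_N, mu_D=mu_D, sigma_N=sigma_N, sigma_D=sigma_D,
        rho_N=rho_N, rho_D=rho_D, mu_eta=np.zeros(2), sigma_eta=sigma_eta,
        rho_eta=0.0,
    )


_TUNING_RANGES = {
    "fig2": {"r_max": (5.0, 50.0), "epsilon": (10.0, 100.0),
             "alpha": (0.1, 1.0), "beta": (1.0, 2.0)},
    "fig3": {"r_max": (5.0, 50.0), "epsilon": (10.0, 100.0),
             "alpha": (0.1, 1.0), "beta": (1.0, 2.0)},
    "fig4": {"r_max": (10.0, 100.0), "epsilon": (15.0, 25.0),
             "alpha": (0.1, 1.0), "beta": (1.0, 1.5)},
}


def _draw_marginal(rng: np.random.Generator, ranges: dict) -> MarginalTuning:
    return MarginalTuning(
        r_max=rng.uniform(*ranges["r_max"]),
        epsilon=rng.uniform(*ranges["epsilon"]),
        alpha_n=rng.uniform(*ranges["alpha"]),
        beta_n=rng.uniform(*ranges["beta"]),
        alpha_d=rng.uniform(*ranges["alpha"]),
        beta_d=rng.uniform(*ranges["beta"]),
        r0=0.0,
        sigma_eta=0.0,
    )


def generate_parameter_grid(preset: str, n_pairs: int, seed: int,
                            rho: tuple | None = None) -> ParameterGrid:
    """Draw ``n_pairs`` parameter sets for the named preset.

    ``rho`` optionally fixes (rho_N, rho_D) for every draw (the fig2-style
    experiments sweep explicit combinations); otherwise the preset's own rule
    applies: fig2 defaults to (0, 0), fig3/fig4 draw both uniformly from
    [-0.9, 0.9], and fig1 draws from [-0.5, 0.5].
    """
    rng = _rng(seed)
    if preset == "fig1":
        if rho is not None:
            raise ValueError("preset fig1 draws rho internally")
        draws = [_draw_fig1_params(rng) for _ in range(n_pairs)]
        return ParameterGrid(preset=preset, seed=seed, draws=draws, contrasts=())
    if preset not in _TUNING_RANGES:
        raise ValueError(f"unknown preset {preset!r}; choose from fig1, fig2, fig3, fig4")
    ranges = _TUNING_RANGES[preset]
    draws = []
    for _ in range(n_pairs):
        n1 = _draw_marginal(rng, ranges)
        n2 = _draw_marginal(rng, ranges)
        if rho is not None:
            rho_n, rho_d = float(rho[0]), float(rho[1])
        elif preset in ("fig3", "fig4"):
            rho_n = rng.uniform(-0.9, 0.9)
            rho_d = rng.uniform(-0.9, 0.9)
        else:
            rho_n = rho_d = 0.0
        draws.append(ContrastTuning(neuron1=n1, neuron2=n2,
                                    rho_n=rho_n, rho_d=rho_d, rho_eta=0.0))
    return ParameterGrid(preset=preset, seed=seed, draws=draws,
                         contrasts=PRESET_CONTRASTS[preset])


def generate_dataset(grid: ParameterGrid, contrasts=None, T: int = 100,
                     seed: int = 0, record_latents: bool = False):
    """Simulate a :class:`Dataset` with ``T`` trials per (pair, contrast).

    Returns ``(dataset, truth)`` where ``truth`` is a JSON-serializable record
    of the generating parameters per pair, optionally including the latent
    normalization draws (``truth["latents"][pair_id][str(contrast)]``).
    """
    if grid.preset == "fig1":
        raise ValueError("preset fig1 has no contrast dimension; use sample_trials directly")
    if contrasts is None:
        contrasts = grid.contrasts
    contrasts = [float(c) for c in contrasts]
    rng = _rng(seed)
    rows = []
    truth: dict = {"preset": grid.preset, "seed": grid.seed, "contrasts": contrasts,
                   "pairs": {}, "latents": {} if record_latents else None}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ValidityWarning)
        for pid, tun in enumerate(grid.draws):
            truth["pairs"][str(pid)] = tun.to_dict()
            if record_latents:
                truth["latents"][str(pid)] = {}
            for c in contrasts:
                params = build_pair_params(tun, c)
                out = sample_trials(params, T, rng, return_latents=record_latents)
                R, D = out if record_latents else (out, None)
                if record_latents:
                    truth["latents"][str(pid)][str(c)] = D.tolist()
                for t in range(T):
                    rows.append((pid, c, t, R[t, 0], R[t, 1]))
    frame = pd.DataFrame(rows, columns=["pair_id", "stimulus", "trial", "r1", "r2"])
    return Dataset(frame), truth


def write_ground_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh)


# ---------------------------------------------------------------------------
# Frame-wise fluorescence fixture for the preprocessing path
# ---------------------------------------------------------------------------

def generate_fluorescence_fixture(n_cells: int, contrasts, trials_per_contrast: int,
                                  seed: int, n_blank_trials: int | None = None,
                                  baseline: float = 100.0, frame_noise_sd: float = 1.0,
                                  amplitudes: dict | None = None):
    """Synthetic 24-frame fluorescence traces with known ground truth.

    Trial layout mirrors a contrast-detection imaging protocol: 4 pre-stimulus
    blank frames, 3 stimulus frames, 17 post-stimulus frames.  The evoked bump
    spans frames 6-9 (1-based; stimulus frames plus one frame of indicator
    lag), scaled so that a noiseless trace yields Delta-F/F exactly equal to
    the generating amplitude.  Blank trials (``stimulus == "blank"``) carry no
    bump and provide the spontaneous statistics for the inclusion criterion.

    ``amplitudes`` may plant exact per-cell response amplitudes as
    ``{cell_id: {contrast: amp}}``; otherwise amplitudes follow a
    hyperbolic-ratio contrast response with per-cell random maximum.

    Returns ``(traces, truth)``: a wide table with columns
    ``cell_id, trial, stimulus, f01..f24`` and a ground-truth table with the
    generating amplitude per (cell, stimulus).
    """
    if n_cells < 1 or trials_per_contrast < 1:
        raise ValueError("counts must be >= 1")
    rng = _rng(seed)
    contrasts = [float(c) for c in contrasts]
    if n_blank_trials is None:
        n_blank_trials = trials_per_contrast
    evoked_frames = np.arange(5, 9)          # 0-based frames 6..9 (1-based)
    rows, truth_rows = [], []
    for cell in range(n_cells):
        if amplitudes is not None and cell in amplitudes:
            amp_by_c = {c: float(amplitudes[cell][c]) for c in contrasts}
        else:
            amp_max = rng.uniform(0.1, 0.6)
            eps = rng.uniform(10.0, 50.0)
            amp_by_c = {c: amp_max * c**2 / (eps**2 + c**2) for c in contrasts}
        stim_seq = [(c, amp_by_c[c]) for c in contrasts for _ in range(trials_per_contrast)]
        stim_seq += [("blank", 0.0) for _ in range(n_blank_trials)]
        for c, amp in amp_by_c.items():
            truth_rows.append({"cell_id": cell, "stimulus": c, "amplitude": amp})
        truth_rows.append({"cell_id": cell, "stimulus": "blank", "amplitude": 0.0})
        for trial, (stim, amp) in enumerate(stim_seq):
            trace = np.full(FRAMES_PER_TRIAL, baseline)
            trace[evoked_frames] += baseline * amp
            trace += frame_noise_sd * rng.standard_normal(FRAMES_PER_TRIAL)
            rows.append([cell, trial, stim] + trace.tolist())
    cols = ["cell_id", "trial", "stimulus"] + [f"f{i:02d}" for i in range(1, FRAMES_PER_TRIAL + 1)]
    traces = pd.DataFrame(rows, columns=cols)
    return traces, pd.DataFrame(truth_rows)
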