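"""Seeded Euler-Maruyama simulation of the Langevin dynamics.

The stochastic differential equation integrated here is

    dx_i = D1_i(x) dt + sqrt(D2_ii(x)) dW_i,

i.e. the noise intensity equals the diffusion coefficient itself.  With this
convention the exactly discretised linear process reproduces the VAR(1)
residual covariance of :mod:`resgc.var_map` (scalar check: an OU process
relaxing at rate p with diffusivity sigma^2 has lag-h residual variance
sigma^2 (1 - e^{-2h}) / (2p)).

Euler steps may exit [-1, 1]^2, where the follower diffusivity can lose
positivity; states are clipped back to the closed square after every step.
For the default group sizes the diffusivities are O(1e-4..1e-2) and boundary
contact is measure-negligible.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model_core import ModelParams, _require_finite_mu

__all__ = [
    "SimConfig",
    "Trajectory",
    "simulate_sde",
    "empirical_moments",
    "make_fixture",
    "load_fixture",
    "simulate_var1",
    "seed_for",
]

_NOISE_CHUNK = 262_144  # normals drawn per chunk; bounds memory for long runs


def seed_for(master_seed: int, stream_index: int) -> np.random.SeedSequence:
    """Deterministic per-stream seed: child ``SeedSequence([master, index])``.

    Used to give every mu value its own reproducible noise stream in
    multi-coupling runs, independent of execution order.
    """
    return np.random.SeedSequence([int(master_seed), int(stream_index)])


@dataclass(frozen=True)
class SimConfig:
    """Integration and observation protocol.

    ``dt_sim`` is the Euler step, ``delta_t`` the observation interval (an
    integer multiple of ``dt_sim``), ``n_obs`` the retained observations
    after discarding ``burn_in`` observations.
    """

    delta_t: float
    n_obs: int
    seed: int
    dt_sim: float | None = None
    burn_in: int | None = None
    x0: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.delta_t > 0:
            raise ValueError(f"delta_t must be > 0, got {self.delta_t}")
        if self.dt_sim is None:
            object.__setattr__(self, "dt_sim", self.delta_t / 10.0)
        if not self.dt_sim > 0:
            raise ValueError(f"dt_sim must be > 0, got {self.dt_sim}")
        ratio = self.delta_t / self.dt_sim
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError(
                f"delta_t/dt_sim = {ratio} must be a positive integer"
            )
        if self.n_obs < 1:
            raise ValueError("n_obs must be >= 1")
        if self.burn_in is not None and self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if not (-1 <= self.x0[0] <= 1 and -1 <= self.x0[1] <= 1):
            raise ValueError(f"x0 = {self.x0} outside [-1, 1]^2")

    @property
    def thin(self) -> int:
        return int(round(self.delta_t / self.dt_sim))

    def resolved_burn_in(self, params: ModelParams) -> int:
        """Default burn-in: 10 relaxation times, expressed in observations."""
        if self.burn_in is not None:
            return self.burn_in
        return int(math.ceil(10.0 / (params.p * self.delta_t)))


@dataclass
class Trajectory:
    """Subsampled states at spacing ``delta_t`` with full provenance."""

    t: np.ndarray
    x: np.ndarray  # shape (n_obs, 2)
    params: ModelParams
    config: SimConfig

    @property
    def x1(self) -> np.ndarray:
        return self.x[:, 0]

    @property
    def x2(self) -> np.ndarray:
        return self.x[:, 1]

    def __len__(self) -> int:
        return self.x.shape[0]


def simulate_sde(params: ModelParams, config: SimConfig) -> Trajectory:
    """Integrate the Langevin dynamics and subsample to ``delta_t``.

    Identical (params, config) including seed give a bit-identical
    trajectory.  Raises on numerical blow-up, naming the offending step.
    """
    _require_finite_mu(params)
    p, mu, n1, n2 = params.p, params.mu, params.n1, params.n2
    dt = config.dt_sim
    sq_dt = math.sqrt(dt)
    thin = config.thin
    burn = config.resolved_burn_in(params)
    n_steps = (config.n_obs + burn) * thin

    rng = np.random.default_rng(config.seed)
    x1, x2 = float(config.x0[0]), float(config.x0[1])
    out = np.empty((config.n_obs, 2))
    i_obs = 0
    step = 0
    c1 = p / n1
    c2 = p / n2
    while step < n_steps:
        m = min(_NOISE_CHUNK, n_steps - step)
        z = rng.standard_normal((m, 2))
        z1 = z[:, 0].tolist()
        z2 = z[:, 1].tolist()
        for k in range(m):
            d11 = c1 * (2.0 - x1)
            d22 = c2 * (2.0 + x2 + 2.0 * mu * (1.0 - x1 * x2))
            x1 += -p * (x1 - 0.5) * dt + math.sqrt(d11) * sq_dt * z1[k]
            x2 += (
                -p * (x2 + 0.5 + mu * (x2 - x1)) * dt
                + math.sqrt(d22) * sq_dt * z2[k]
            )
            # clip to the closed square; D22 may lose positivity outside
            if x1 > 1.0:
                x1 = 1.0
            elif x1 < -1.0:
                x1 = -1.0
            if x2 > 1.0:
                x2 = 1.0
            elif x2 < -1.0:
                x2 = -1.0
            step += 1
            if step % thin == 0:
                idx = step // thin - 1
                if idx >= burn:
                    out[idx - burn, 0] = x1
                    out[idx - burn, 1] = x2
                    i_obs = idx - burn + 1
        if not (math.isfinite(x1) and math.isfinite(x2)):
            raise RuntimeError(f"non-finite state at integration step {step}")
    assert i_obs == config.n_obs
    t = (burn + 1 + np.arange(config.n_obs)) * config.delta_t
    return Trajectory(t=t, x=out, params=params, config=config)


def empirical_moments(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Sample mean vector and 2x2 covariance of the retained states."""
    if len(traj) < 2:
        raise ValueError("need at least 2 observations")
    mean = traj.x.mean(axis=0)
    cov = np.cov(traj.x, rowvar=False)
    return mean, 0.5 * (cov + cov.T)


def simulate_var1(model, n_obs: int, seed, intercept=(0.0, 0.0),
                  burn_in: int = 100) -> np.ndarray:
    """Exact sampling of a bivariate VAR(1) (used for synthetic benchmarks).

    ``model`` is a :class:`resgc.var_map.VAR1Model`; residuals are Gaussian
    with covariance ``model.Sigma``; returns an (n_obs, 2) array.
    """
    rng = np.random.default_rng(seed)
    A = model.transition
    L = np.linalg.cholesky(model.Sigma + 1e-300 * np.eye(2))
    nu = np.asarray(intercept, dtype=float)
    mean = np.linalg.solve(np.eye(2) - A, nu)
    z = rng.standard_normal((n_obs + burn_in, 2)) @ L.T
    x = mean.copy()
    out = np.empty((n_obs, 2))
    for k in range(n_obs + burn_in):
        x = nu + A @ x + z[k]
        if k >= burn_in:
            out[k - burn_in] = x
    return out


def _format_float(v: float) -> str:
    return format(v, ".12g")


def make_fixture(params: ModelParams, config: SimConfig, out_dir) -> dict:
    """Write a trajectory CSV plus a JSON manifest (seed, params, moments).

    Regenerating with the manifest's seed reproduces the CSV bit-identically;
    the manifest stores the CSV's SHA-256 so a round trip is checkable.
    Returns the manifest dict.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out_dir}: {exc}") from exc
    traj = simulate_sde(params, config)
    csv_path = out_dir / "trajectory.csv"
    lines = ["t,x1,x2"]
    for ti, (a, b) in zip(traj.t, traj.x):
        lines.append(f"{_format_float(ti)},{_format_float(a)},{_format_float(b)}")
    csv_text = "\n".join(lines) + "\n"
    csv_path.write_text(csv_text)
    mean, cov = empirical_moments(traj)
    manifest = {
        "params": {"p": params.p, "n1": params.n1, "n2": params.n2,
                   "mu": params.mu},
        "config": {
            "delta_t": config.delta_t,
            "dt_sim": config.dt_sim,
            "n_obs": config.n_obs,
            "burn_in": config.resolved_burn_in(params),
            "seed": config.seed,
            "x0": list(config.x0),
        },
        "moments": {"mean": mean.tolist(), "cov": cov.tolist()},
        "csv_sha256": hashlib.sha256(csv_text.encode()).hexdigest(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def load_fixture(out_dir) -> tuple[np.ndarray, dict]:
    """Read back a fixture directory: (t,x1,x2 array, manifest)."""
    out_dir = Path(out_dir)
    try:
        manifest = json.loads((out_dir / "manifest.json").read_text())
        data = np.loadtxt(out_dir / "trajectory.csv", delimiter=",", skiprows=1)
    except OSError as exc:
        raise OSError(f"cannot read fixture in {out_dir}: {exc}") from exc
    return data, manifest
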