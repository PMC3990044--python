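"""Wright–Fisher style coevolution of host and parasite genotype frequencies.

Discrete, non-overlapping generations.  Each generation applies, in order:

1. **selection** — fitness is mean-field: a host of genotype ``i`` meets the
   parasite population in proportion to its frequencies, so
   ``w_h[i] = (1 - s_h * sum_j q_j alpha_ij) * (1 - tau_h)**r_i`` and a
   parasite is penalized for failing to infect,
   ``w_p[j] = (1 - s_p * sum_i p_i (1 - alpha_ij)) * (1 - tau_p)**v_j``;
2. **mutation** — symmetric among the ``K`` genotypes,
   ``p_i' = (1 - mu) p_i + mu (1 - p_i) / (K - 1)``;
3. **drift** (optional) — one multinomial draw of ``N`` individuals per
   species.

Matching-alleles interactions under this recursion generate negative
frequency-dependent selection: common host genotypes are preferentially
infected, rare parasite genotypes find few matching hosts, and genotype
frequencies cycle (the Red Queen regime).  With strong selection the cycles
carry genotypes close to fixation and back.

This module doubles as the study's synthetic-data generator; the
cross-infection experiment samples its trajectories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from gxglink.infection_models import InfectionMatrix

__all__ = [
    "SimulationParams",
    "PopulationState",
    "TrajectoryRecord",
    "fitness_vectors",
    "step",
    "run_simulation",
]

#: negative frequencies larger than this (in magnitude) are treated as errors
RENORM_TOL = 1e-12

#: magnitude of the seeded perturbation applied to the uniform initial state
INIT_PERTURBATION = 0.01


@dataclass
class SimulationParams:
    """Parameters of one coevolution run.

    ``s_h`` is the host fitness cost of being infected, ``s_p`` the parasite
    cost of failing to infect, and ``tau_h`` / ``tau_p`` the per-level costs
    of resistance / virulence (GFG only; no effect when the matrix carries
    zero cost exponents).  ``selection=False`` sets all fitness effects of
    infection to zero — the no-coevolution control.  ``drift=False`` runs
    the deterministic recursion.
    """

    model: InfectionMatrix
    N: int = 100_000
    mu: float = 1e-5
    s_h: float = 0.67
    s_p: float = 0.69
    tau_h: float = 0.0
    tau_p: float = 0.0
    generations: int = 1000
    seed: int = 0
    drift: bool = True
    selection: bool = True

    def __post_init__(self) -> None:
        if self.model.n_host != self.model.n_parasite:
            raise ValueError("coevolution requires a square infection matrix")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for name in ("mu", "s_h", "s_p", "tau_h", "tau_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @property
    def K(self) -> int:
        return self.model.n_host

    def to_dict(self) -> dict:
        """JSON-serializable echo of the parameters (for sidecars/manifests)."""
        return {
            "model": self.model.model_name,
            "model_params": {
                k: np.asarray(v).tolist() if isinstance(v, np.ndarray) else v
                for k, v in self.model.params.items()
            },
            "K": self.K,
            "N": self.N,
            "mu": self.mu,
            "s_h": self.s_h,
            "s_p": self.s_p,
            "tau_h": self.tau_h,
            "tau_p": self.tau_p,
            "generations": self.generations,
            "seed": int(self.seed),
            "drift": self.drift,
            "selection": self.selection,
        }


@dataclass
class PopulationState:
    """Host (``p``) and parasite (``q``) genotype frequencies at one generation."""

    generation: int
    p: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        for name, vec in (("p", self.p), ("q", self.q)):
            if vec.ndim != 1:
                raise ValueError(f"{name} must be a vector")
            if np.any(vec < 0.0):
                raise ValueError(f"{name} has negative entries")
            if abs(vec.sum() - 1.0) > 1e-8:
                raise ValueError(f"{name} must sum to 1")


@dataclass
class TrajectoryRecord:
    """Full frequency time series of one run (generation 0 .. generations)."""

    params: SimulationParams
    host_freqs: np.ndarray  # (generations + 1, K)
    parasite_freqs: np.ndarray

    @property
    def n_generations(self) -> int:
        return self.host_freqs.shape[0] - 1

    def state(self, t: int) -> PopulationState:
        return PopulationState(t, self.host_freqs[t], self.parasite_freqs[t])

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: columns generation, species, genotype, frequency."""
        T, K = self.host_freqs.shape
        gens = np.repeat(np.arange(T), K)
        genos = np.tile(np.arange(K), T)
        frames = []
        for species, freqs in (("host", self.host_freqs), ("parasite", self.parasite_freqs)):
            frames.append(
                pd.DataFrame(
                    {
                        "generation": gens,
                        "species": species,
                        "genotype": genos,
                        "frequency": freqs.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path: str | Path, write_params: bool = True) -> None:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        if write_params:
            sidecar = path.with_suffix(".params.json")
            sidecar.write_text(json.dumps(self.params.to_dict(), indent=2))


def fitness_vectors(
    state: PopulationState, params: SimulationParams
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-field host and parasite fitness vectors at the current state.

    With ``selection=False`` both vectors are all ones (fitness effects of
    infection set to zero).
    """
    K = params.K
    if not params.selection:
        return np.ones(K), np.ones(K)
    A = params.model.alpha
    infection_risk = A @ state.q  # P(host i is infected by a random parasite)
    w_h = (1.0 - params.s_h * infection_risk) * (1.0 - params.tau_h) ** params.model.host_cost_exponents
    failure_risk = (1.0 - A).T @ state.p  # P(parasite j fails on a random host)
    w_p = (1.0 - params.s_p * failure_risk) * (1.0 - params.tau_p) ** params.model.parasite_cost_exponents
    assert np.all(w_h >= 0.0) and np.all(w_p >= 0.0), "negative fitness"
    return w_h, w_p


def _mutate(x: np.ndarray, mu: float, K: int) -> np.ndarray:
    # symmetric mutation kernel: every genotype mutates to each other
    # genotype with probability mu / (K - 1)
    return (1.0 - mu) * x + mu * (1.0 - x) / (K - 1)


def _renormalize(x: np.ndarray) -> np.ndarray:
    if np.any(x < -RENORM_TOL):
        raise FloatingPointError("frequency fell below -tolerance")
    x = np.clip(x, 0.0, None)
    return x / x.sum()


def step(
    state: PopulationState, params: SimulationParams, rng: np.random.Generator
) -> PopulationState:
    """Advance one generation: selection, then mutation, then optional drift."""
    p, q = state.p, state.q
    if params.selection:
        w_h, w_p = fitness_vectors(state, params)
        p = p * w_h
        p = p / p.sum()
        q = q * w_p
        q = q / q.sum()
    if params.mu > 0.0:
        p = _mutate(p, params.mu, params.K)
        q = _mutate(q, params.mu, params.K)
    if params.drift:
        p = rng.multinomial(params.N, _renormalize(p)) / params.N
        q = rng.multinomial(params.N, _renormalize(q)) / params.N
    else:
        p = _renormalize(p)
        q = _renormalize(q)
    return PopulationState(state.generation + 1, p, q)


def _perturbed_uniform(K: int, rng: np.random.Generator) -> np.ndarray:
    delta = rng.uniform(-INIT_PERTURBATION, INIT_PERTURBATION, size=K)
    delta -= delta.mean()
    x = np.clip(np.full(K, 1.0 / K) + delta, 0.0, None)
    return x / x.sum()


def run_simulation(
    params: SimulationParams, initial_state: PopulationState | None = None
) -> TrajectoryRecord:
    """Run the full recursion; deterministic given ``params.seed``.

    The default initial state is uniform frequencies plus a small seeded
    perturbation (magnitude 0.01) so that deterministic runs leave the
    unstable symmetric equilibrium.
    """
    rng = np.random.default_rng(params.seed)
    K = params.K
    if initial_state is None:
        state = PopulationState(0, _perturbed_uniform(K, rng), _perturbed_uniform(K, rng))
    else:
        state = replace(initial_state, generation=0)
    P = np.empty((params.generations + 1, K))
    Q = np.empty((params.generations + 1, K))
    P[0], Q[0] = state.p, state.q
    for t in range(1, params.generations + 1):
        state = step(state, params, rng)
        P[t], Q[t] = state.p, state.q
    return TrajectoryRecord(params, P, Q)
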