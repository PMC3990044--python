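"""Functional genotype-by-genotype (G×G) infection models.

The unit of description is the *infection matrix* ``alpha``: entry
``alpha[i, j]`` is the probability that parasite genotype ``j`` infects host
genotype ``i`` on contact.  A model is *functionally* G×G when ``alpha``
cannot be written as a host effect plus a parasite effect; the classic
single-locus infection-genetics models are provided:

``MA``
    matching alleles — a parasite infects only the host genotype it matches
    (identity matrix).
``IMA``
    inverse matching alleles — a molecular match triggers host recognition
    and defense, so infection succeeds everywhere *except* the diagonal.
``GFG``
    gene-for-gene, nested multi-level convention: hosts carry resistance
    levels ``r_i = 0..K-1``, parasites virulence levels ``v_j = 0..K-1``,
    and infection succeeds iff ``v_j >= r_i``.  Carrying level ``x`` costs a
    factor ``(1 - tau)**x`` of fitness (used by the simulator).
``CONST`` / ``ADDITIVE``
    no-interaction controls: a constant matrix, and a clamped additive
    matrix ``clip(beta_i + gamma_j, 0, 1)`` with no interaction term on the
    probability scale.

The module also provides the frequency-weighted two-way decomposition of an
infection matrix into grand mean, main effects and interaction residuals.
This is the population-level quantity that a factorial cross-infection
experiment estimates ("statistical G×G") and serves as the analytic oracle
for the variance-partitioning module: the same functional model yields a
large or a vanishing interaction variance depending only on how even the
genotype frequencies are.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "MODEL_NAMES",
    "InfectionMatrix",
    "AlphaDecomposition",
    "build_infection_matrix",
    "register_model",
    "interaction_variance_components",
]

#: tolerance for "frequencies sum to one" checks
FREQ_ATOL = 1e-8


@dataclass
class InfectionMatrix:
    """Infection probabilities for every host × parasite genotype pair.

    Attributes
    ----------
    alpha
        ``(K_h, K_p)`` matrix, rows = host genotypes, columns = parasite
        genotypes, entries in ``[0, 1]``.
    model_name
        Label of the generating model (``MA``, ``IMA``, ``GFG``, ``CONST``,
        ``ADDITIVE`` or a custom registered name).
    host_cost_exponents, parasite_cost_exponents
        Integer cost levels ``r_i`` / ``v_j`` (all zero outside GFG); the
        simulator applies multiplicative fitness costs ``(1-tau)**level``.
    params
        Model-specific coefficients used to build the matrix, kept for
        serialization.
    """

    alpha: np.ndarray
    model_name: str
    host_cost_exponents: np.ndarray | None = None
    parasite_cost_exponents: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alpha = np.array(self.alpha, dtype=float)
        if self.alpha.ndim != 2:
            raise ValueError("alpha must be a 2-D matrix")
        if np.any(self.alpha < 0.0) or np.any(self.alpha > 1.0):
            raise ValueError("infection probabilities must lie in [0, 1]")
        if self.host_cost_exponents is None:
            self.host_cost_exponents = np.zeros(self.n_host, dtype=int)
        if self.parasite_cost_exponents is None:
            self.parasite_cost_exponents = np.zeros(self.n_parasite, dtype=int)
        self.host_cost_exponents = np.asarray(self.host_cost_exponents, dtype=int)
        self.parasite_cost_exponents = np.asarray(self.parasite_cost_exponents, dtype=int)
        if self.host_cost_exponents.shape != (self.n_host,):
            raise ValueError("host_cost_exponents must have one entry per host genotype")
        if self.parasite_cost_exponents.shape != (self.n_parasite,):
            raise ValueError("parasite_cost_exponents must have one entry per parasite genotype")

    @property
    def n_host(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_parasite(self) -> int:
        return self.alpha.shape[1]

    # -- serialization -----------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write alpha as CSV: header = parasite labels, first column = hosts."""
        df = pd.DataFrame(
            self.alpha,
            index=[f"H{i}" for i in range(self.n_host)],
            columns=[f"P{j}" for j in range(self.n_parasite)],
        )
        df.to_csv(path, index_label="host")

    @classmethod
    def from_csv(cls, path: str | Path, model_name: str = "CUSTOM") -> "InfectionMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), model_name)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "model_name": self.model_name,
            "K_host": self.n_host,
            "K_parasite": self.n_parasite,
            "params": {k: np.asarray(v).tolist() if isinstance(v, np.ndarray) else v
                       for k, v in self.params.items()},
            "alpha": self.alpha.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "InfectionMatrix":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        name = payload["model_name"]
        if name in _REGISTRY and payload["K_host"] == payload["K_parasite"]:
            return build_infection_matrix(name, payload["K_host"], **payload.get("params", {}))
        return cls(np.asarray(payload["alpha"], dtype=float), name,
                   params=payload.get("params", {}))


# -- model registry --------------------------------------------------------

ModelBuilder = Callable[[int, dict], InfectionMatrix]
_REGISTRY: dict[str, ModelBuilder] = {}


def register_model(name: str) -> Callable[[ModelBuilder], ModelBuilder]:
    """Register a builder so alternative matrix conventions can be dropped in."""

    def decorate(fn: ModelBuilder) -> ModelBuilder:
        _REGISTRY[name] = fn
        return fn

    return decorate


def build_infection_matrix(model_name: str, K: int, **params) -> InfectionMatrix:
    """Build the infection matrix for a named model with ``K`` genotypes.

    Parameters
    ----------
    model_name
        One of :data:`MODEL_NAMES` (or a custom registered label).
    K
        Number of genotypes per species (``K >= 2``).
    **params
        Model-specific coefficients: ``c`` for CONST (default 0.5), ``beta``
        and ``gamma`` vectors of length ``K`` for ADDITIVE.
    """
    if model_name not in _REGISTRY:
        raise ValueError(
            f"unknown model {model_name!r}; valid labels are: "
            + ", ".join(sorted(_REGISTRY))
        )
    if int(K) < 2:
        raise ValueError("K must be at least 2")
    return _REGISTRY[model_name](int(K), params)


@register_model("MA")
def _build_ma(K: int, params: dict) -> InfectionMatrix:
    return InfectionMatrix(np.eye(K), "MA")


@register_model("IMA")
def _build_ima(K: int, params: dict) -> InfectionMatrix:
    return InfectionMatrix(1.0 - np.eye(K), "IMA")


@register_model("GFG")
def _build_gfg(K: int, params: dict) -> InfectionMatrix:
    # nested convention: infection iff parasite virulence >= host resistance
    levels = np.arange(K)
    alpha = (levels[None, :] >= levels[:, None]).astype(float)
    return InfectionMatrix(
        alpha, "GFG", host_cost_exponents=levels, parasite_cost_exponents=levels
    )


@register_model("CONST")
def _build_const(K: int, params: dict) -> InfectionMatrix:
    c = float(params.get("c", 0.5))
    if not 0.0 <= c <= 1.0:
        raise ValueError("CONST level c must lie in [0, 1]")
    return InfectionMatrix(np.full((K, K), c), "CONST", params={"c": c})


@register_model("ADDITIVE")
def _build_additive(K: int, params: dict) -> InfectionMatrix:
    beta = params.get("beta")
    gamma = params.get("gamma")
    if beta is None or gamma is None:
        raise ValueError("ADDITIVE requires beta and gamma vectors of length K")
    beta = np.asarray(beta, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if beta.shape != (K,) or gamma.shape != (K,):
        raise ValueError("beta and gamma must each have length K")
    alpha = np.clip(beta[:, None] + gamma[None, :], 0.0, 1.0)
    return InfectionMatrix(alpha, "ADDITIVE", params={"beta": beta, "gamma": gamma})


MODEL_NAMES: tuple[str, ...] = tuple(_REGISTRY)


# -- frequency-weighted decomposition --------------------------------------


@dataclass
class AlphaDecomposition:
    """Exact two-way decomposition of alpha under genotype frequencies (p, q).

    ``alpha_ij = grand_mean + host_effects[i] + parasite_effects[j] +
    interaction_effects[i, j]`` holds exactly, with the effects centred so
    that ``sum_i p_i a_i = 0`` and ``sum_j q_j b_j = 0``.  The variances are
    the frequency-weighted second moments of the corresponding effects.
    """

    grand_mean: float
    host_effects: np.ndarray
    parasite_effects: np.ndarray
    interaction_effects: np.ndarray
    var_host: float
    var_parasite: float
    var_interaction: float


def _check_frequencies(vec: np.ndarray, n: int, name: str) -> np.ndarray:
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (n,):
        raise ValueError(f"{name} must have length {n}")
    if np.any(vec < 0.0) or abs(vec.sum() - 1.0) > FREQ_ATOL:
        raise ValueError(f"{name} must be non-negative and sum to 1")
    return vec


def interaction_variance_components(
    alpha: InfectionMatrix | np.ndarray, p: np.ndarray, q: np.ndarray
) -> AlphaDecomposition:
    """Frequency-weighted two-way decomposition of an infection matrix.

    With host frequencies ``p`` and parasite frequencies ``q``::

        mu   = sum_ij p_i q_j alpha_ij
        a_i  = sum_j q_j alpha_ij - mu
        b_j  = sum_i p_i alpha_ij - mu
        e_ij = alpha_ij - mu - a_i - b_j

    and the returned variances are ``sum_i p_i a_i**2``,
    ``sum_j q_j b_j**2`` and ``sum_ij p_i q_j e_ij**2``.  The interaction
    variance is the population-level "statistical G×G" that an ideal
    infinite cross-infection experiment would measure on the probability
    scale.
    """
    A = alpha.alpha if isinstance(alpha, InfectionMatrix) else np.asarray(alpha, float)
    p = _check_frequencies(p, A.shape[0], "p")
    q = _check_frequencies(q, A.shape[1], "q")
    mu = float(p @ A @ q)
    a = A @ q - mu
    b = A.T @ p - mu
    e = A - mu - a[:, None] - b[None, :]
    return AlphaDecomposition(
        grand_mean=mu,
        host_effects=a,
        parasite_effects=b,
        interaction_effects=e,
        var_host=float(p @ a**2),
        var_parasite=float(q @ b**2),
        var_interaction=float(p @ (e**2) @ q),
    )
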