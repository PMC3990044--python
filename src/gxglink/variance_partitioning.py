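"""Two-way random-effects ANOVA for cross-infection tables.

The response is the per-cell infection count ``y[g, h, r]`` (0..trials); a
per-trial binary response is available via ``response="binary"``.  Host and
parasite isolates are random factors — two isolates that happen to share a
latent genotype are still distinct levels, because the empiricist cannot
know.  The balanced crossed design gives the classic sums of squares and
the method-of-moments (expected-mean-squares) solutions::

    sigma2_error    = MS_E
    sigma2_gxg      = (MS_AB - MS_E) / n
    sigma2_host     = (MS_A - MS_AB) / (b * n)
    sigma2_parasite = (MS_B - MS_AB) / (a * n)

with ``a``/``b`` the isolate counts and ``n`` the replicate count.
Negative solutions are truncated to zero (standard practice; the
pre-truncation values are retained in ``raw``).  A REML estimator over the
same balanced strata is offered as a cross-check: for balanced data it
coincides with the EMS solutions whenever those are non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from gxglink.cross_infection_experiment import CrossInfectionTable, ExperimentDesign
from gxglink.infection_models import InfectionMatrix, interaction_variance_components

__all__ = [
    "VarianceComponents",
    "anova_decompose",
    "expected_components",
    "component_timeseries",
]

_STRATA = ("host", "parasite", "gxg", "error")


@dataclass
class VarianceComponents:
    """Estimated variance components for one cross-infection experiment."""

    sigma2_host: float
    sigma2_parasite: float
    sigma2_gxg: float
    sigma2_error: float
    mean_squares: dict = field(default_factory=dict)
    df: dict = field(default_factory=dict)
    method: str = "EMS"
    raw: dict = field(default_factory=dict)  # pre-truncation solutions
    generation: int | None = None

    def __post_init__(self) -> None:
        for name in ("sigma2_host", "sigma2_parasite", "sigma2_gxg", "sigma2_error"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be non-negative after truncation")

    def as_row(self) -> dict:
        row = {"generation": self.generation, "method": self.method}
        for s in _STRATA:
            row[f"sigma2_{s}"] = getattr(self, f"sigma2_{s}")
        for s in _STRATA:
            row[f"ms_{s}"] = self.mean_squares.get(s, np.nan)
            row[f"df_{s}"] = self.df.get(s, np.nan)
            row[f"raw_sigma2_{s}"] = self.raw.get(s, np.nan)
        return row


def _balanced_two_way(y: np.ndarray) -> tuple[dict, dict, dict]:
    """Sums of squares, degrees of freedom and mean squares for a balanced
    two-way layout ``y`` of shape (a, b, n)."""
    a, b, n = y.shape
    grand = y.mean()
    cell = y.mean(axis=2)
    row = cell.mean(axis=1)
    col = cell.mean(axis=0)
    ss = {
        "host": b * n * float(((row - grand) ** 2).sum()),
        "parasite": a * n * float(((col - grand) ** 2).sum()),
        "gxg": n * float(
            ((cell - row[:, None] - col[None, :] + grand) ** 2).sum()
        ),
        "error": float(((y - cell[:, :, None]) ** 2).sum()),
    }
    dfs = {
        "host": a - 1,
        "parasite": b - 1,
        "gxg": (a - 1) * (b - 1),
        "error": a * b * (n - 1),
    }
    ms = {s: ss[s] / dfs[s] for s in _STRATA}
    return ss, dfs, ms


def _ems_solutions(ms: dict, a: int, b: int, n: int) -> dict:
    return {
        "error": ms["error"],
        "gxg": (ms["gxg"] - ms["error"]) / n,
        "host": (ms["host"] - ms["gxg"]) / (b * n),
        "parasite": (ms["parasite"] - ms["gxg"]) / (a * n),
    }


def _reml_solutions(ss: dict, dfs: dict, a: int, b: int, n: int, start: dict) -> dict:
    """REML for the balanced crossed random model via its stratum likelihood.

    The four mean-square strata are independent scaled chi-squares with
    scales (stratum variances)::

        lam_A  = s2e + n s2ab + n b s2a
        lam_B  = s2e + n s2ab + n a s2b
        lam_AB = s2e + n s2ab
        lam_E  = s2e

    so the restricted log-likelihood is, up to a constant,
    ``-1/2 sum_s (df_s log lam_s + SS_s / lam_s)``.
    """

    def lams(theta: np.ndarray) -> np.ndarray:
        s2a, s2b, s2ab, s2e = theta
        return np.array(
            [
                s2e + n * s2ab + n * b * s2a,
                s2e + n * s2ab + n * a * s2b,
                s2e + n * s2ab,
                s2e,
            ]
        )

    ss_vec = np.array([ss["host"], ss["parasite"], ss["gxg"], ss["error"]])
    df_vec = np.array([dfs["host"], dfs["parasite"], dfs["gxg"], dfs["error"]], float)

    def neg_loglik(theta: np.ndarray) -> float:
        lam = lams(theta)
        if np.any(lam <= 0):
            return np.inf
        return float((df_vec * np.log(lam) + ss_vec / lam).sum())

    x0 = np.array([max(start[s], 1e-8) for s in ("host", "parasite", "gxg", "error")])
    res = optimize.minimize(
        neg_loglik,
        x0,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * 3 + [(1e-12, None)],
    )
    s2a, s2b, s2ab, s2e = res.x
    return {"host": s2a, "parasite": s2b, "gxg": s2ab, "error": s2e}


def _table_response(table: CrossInfectionTable, response: str) -> np.ndarray:
    if response == "count":
        return table.counts.astype(float)
    if response == "binary":
        # expand each replicate's count into trials_per_cell 0/1 outcomes;
        # ordering within a replicate is immaterial for sums of squares
        t = table.design.trials_per_cell
        G, H, R = table.counts.shape
        y = (np.arange(t)[None, None, None, :] < table.counts[..., None]).astype(float)
        return y.reshape(G, H, R * t)
    raise ValueError("response must be 'count' or 'binary'")


def anova_decompose(
    data: CrossInfectionTable | np.ndarray,
    method: str = "EMS",
    response: str = "count",
) -> VarianceComponents:
    """Partition a balanced factorial table into variance components.

    ``data`` may be a :class:`CrossInfectionTable` or a raw ``(a, b, n)``
    response array (useful for non-infection fixtures).  ``method`` is
    ``"EMS"`` (default, closed form) or ``"REML"``.
    """
    generation = None
    if isinstance(data, CrossInfectionTable):
        y = _table_response(data, response)
        generation = data.generation
    else:
        y = np.asarray(data, dtype=float)
        if y.ndim != 3:
            raise ValueError("response array must be (a, b, n)")
    a, b, n = y.shape
    if n < 2:
        raise ValueError("at least two replicates are required to estimate the error stratum")
    ss, dfs, ms = _balanced_two_way(y)
    raw = _ems_solutions(ms, a, b, n)
    if method == "EMS":
        comps = {s: max(v, 0.0) for s, v in raw.items()}
    elif method == "REML":
        comps = _reml_solutions(ss, dfs, a, b, n, {s: max(v, 0.0) for s, v in raw.items()})
    else:
        raise ValueError("method must be 'EMS' or 'REML'")
    return VarianceComponents(
        sigma2_host=comps["host"],
        sigma2_parasite=comps["parasite"],
        sigma2_gxg=comps["gxg"],
        sigma2_error=comps["error"],
        mean_squares=ms,
        df=dfs,
        method=method,
        raw=raw,
        generation=generation,
    )


def expected_components(
    alpha: InfectionMatrix | np.ndarray,
    p: np.ndarray,
    q: np.ndarray,
    design: ExperimentDesign,
    response: str = "count",
) -> VarianceComponents:
    """Infinite-sample expectation of the ANOVA components.

    Isolate genotypes are i.i.d. draws from (p, q), so isolate effects are
    i.i.d. copies of the frequency-weighted effects of the error-adjusted
    matrix ``alpha' = alpha (1 - 2 eps) + eps``; on the count scale cell
    means are ``t * pi'``, hence the factor ``t**2`` on the between-cell
    components, and the within-cell (error) component is the mean binomial
    variance ``t * E[pi' (1 - pi')]`` (``E[...]`` for binary).
    """
    A = alpha.alpha if isinstance(alpha, InfectionMatrix) else np.asarray(alpha, float)
    eps = design.error_rate
    A_eff = A * (1.0 - 2.0 * eps) + eps
    dec = interaction_variance_components(A_eff, p, q)
    t = design.trials_per_cell
    scale = float(t**2) if response == "count" else 1.0
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    mean_bernoulli_var = float(p @ (A_eff * (1.0 - A_eff)) @ q)
    err = t * mean_bernoulli_var if response == "count" else mean_bernoulli_var
    return VarianceComponents(
        sigma2_host=scale * dec.var_host,
        sigma2_parasite=scale * dec.var_parasite,
        sigma2_gxg=scale * dec.var_interaction,
        sigma2_error=err,
        method="expected",
    )


def component_timeseries(
    tables: Sequence[CrossInfectionTable] | Iterable[CrossInfectionTable],
    method: str = "EMS",
    response: str = "count",
) -> pd.DataFrame:
    """One :class:`VarianceComponents` row per experiment, CSV-writable."""
    tables = list(tables)
    if not tables:
        raise ValueError("no tables supplied")
    rows = [anova_decompose(t, method=method, response=response).as_row() for t in tables]
    return pd.DataFrame(rows)
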