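"""Model-based inference of functional G×G from cross-infection tables.

Rather than partitioning variance, confront the table with candidate
infection models directly.  Each host isolate ``g`` carries a latent
genotype ``z_g ~ f`` and each parasite isolate ``h`` a latent ``z_h ~ g``;
given the genotypes, replicate counts are independent binomials with
per-trial probability ``pi'_ij = alpha_ij (1 - 2 eps) + eps`` — the
candidate matrix entry pushed away from 0/1 by the assay error rate
``eps``.  The marginal likelihood of a table sums over all joint genotype
assignments:

    L(f, g) = sum_z [ prod_g f_{z_g} * prod_h g_{z_h}
                      * prod_{g,h,r} Binom(y_ghr; t, pi'_{z_g z_h}) ]

Genotype frequencies (and the number of genotypes, by comparing fits across
``K``) are estimated from nothing but the cross-infection data; candidate
models are ranked by AIC, with likelihood-ratio tests for the few genuinely
nested pairs.

Exact evaluation is exponential in the isolate count, so it is guarded and
reserved for small instances (where it is also the oracle for tests).
:func:`fit_model` uses a mean-field EM: host-margin and parasite-margin
genotype posteriors are updated alternately (a variational approximation —
rows and columns couple, so the exact E-step is itself intractable), with
the frequency vectors re-estimated from the posteriors each sweep.  Each
sweep is a coordinate ascent on the evidence lower bound (ELBO), asserted
monotone.  Inside the enumeration guard the fit is polished against the
exact likelihood and the exact value reported; outside it, the ELBO is
reported and flagged (``exact=False``).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from gxglink.cross_infection_experiment import CrossInfectionTable
from gxglink.infection_models import FREQ_ATOL, build_infection_matrix

__all__ = [
    "ENUMERATION_GUARD",
    "FunctionalModelHypothesis",
    "FitResult",
    "ModelComparisonResult",
    "log_likelihood_exact",
    "fit_model",
    "compare_models",
    "NESTED_PAIRS",
]

#: exact enumeration allowed while K ** (n_hosts + n_parasites) stays below this
ENUMERATION_GUARD = 10_000_000

# sentinel for log(0) so that impossible outcomes stay finite in tensors
_NEG = -1e15

#: pairs (poor, rich) for which the poor model is a boundary case of the rich
#: one, so a chi-square LRT reference is meaningful.  CONST is representable
#: by ADDITIVE (beta_i = c, gamma_j = 0); MA/IMA/GFG cannot represent a
#: non-degenerate constant matrix, so they are compared to CONST by AIC only.
NESTED_PAIRS: frozenset[tuple[str, str]] = frozenset({("CONST", "ADDITIVE")})


@dataclass
class FunctionalModelHypothesis:
    """A candidate functional model with (estimated) genotype frequencies."""

    model_name: str
    K: int
    host_freqs: np.ndarray
    parasite_freqs: np.ndarray
    epsilon: float = 0.01
    matrix_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.host_freqs = np.asarray(self.host_freqs, dtype=float)
        self.parasite_freqs = np.asarray(self.parasite_freqs, dtype=float)
        for name, vec in (("host_freqs", self.host_freqs),
                          ("parasite_freqs", self.parasite_freqs)):
            if vec.shape != (self.K,):
                raise ValueError(f"{name} must have length K={self.K}")
            if np.any(vec < 0.0) or abs(vec.sum() - 1.0) > FREQ_ATOL:
                raise ValueError(f"{name} must lie on the simplex")
        if not 0.0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must lie in [0, 0.5)")

    def matrix(self) -> np.ndarray:
        """The K×K infection matrix implied by the hypothesis."""
        if self.model_name == "CONST":
            return np.full((self.K, self.K), float(self.matrix_params.get("c", 0.5)))
        if self.K == 1:
            # degenerate single-genotype cases of the structured models
            value = {"MA": 1.0, "IMA": 0.0, "GFG": 1.0}.get(self.model_name)
            if value is None:
                raise ValueError(f"K=1 undefined for model {self.model_name!r}")
            return np.full((1, 1), value)
        return build_infection_matrix(self.model_name, self.K, **self.matrix_params).alpha


@dataclass
class FitResult:
    """Outcome of fitting one hypothesis to one table."""

    hypothesis: FunctionalModelHypothesis
    log_likelihood: float
    n_params: int
    elbo: float
    exact: bool  # True when log_likelihood is the exact marginal likelihood
    converged: bool
    n_iter: int
    host_posteriors: np.ndarray  # (n_host_isolates, K)
    parasite_posteriors: np.ndarray

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.log_likelihood


@dataclass
class ModelComparisonResult:
    """AIC ranking of candidate functional models on one table."""

    fits: list[FitResult]
    table: pd.DataFrame
    selected: str
    selected_index: int
    lrt: list[dict]

    def to_json_dict(self) -> dict:
        return {
            "selected": self.selected,
            "models": self.table.to_dict(orient="records"),
            "lrt": self.lrt,
        }


# -- shared pieces ---------------------------------------------------------


def _effective_matrix(alpha: np.ndarray, eps: float) -> np.ndarray:
    return alpha * (1.0 - 2.0 * eps) + eps


def _cell_loglik(table: CrossInfectionTable, alpha: np.ndarray, eps: float) -> np.ndarray:
    """``C[g, h, i, j] = sum_r log P(y_ghr | host genotype i, parasite j)``.

    Impossible outcomes (only reachable when ``eps = 0``) contribute the
    finite sentinel ``_NEG`` instead of ``-inf`` so tensor algebra stays
    NaN-free; callers detect contradiction by magnitude.
    """
    t = table.design.trials_per_cell
    pi = _effective_matrix(alpha, eps)
    ys = np.arange(t + 1)
    with np.errstate(divide="ignore"):
        lp = stats.binom.logpmf(ys[:, None, None], t, pi[None, :, :])
    lp = np.where(np.isfinite(lp), lp, _NEG)
    hist = (table.counts[..., None] == ys).sum(axis=2)  # (G, H, t+1)
    return np.einsum("ghy,yij->ghij", hist, lp)


def _softmax_rows(logw: np.ndarray) -> np.ndarray:
    w = np.exp(logw - logw.max(axis=1, keepdims=True))
    return w / w.sum(axis=1, keepdims=True)


def _safe_log(x: np.ndarray) -> np.ndarray:
    return np.log(np.clip(x, 1e-300, None))


# -- exact likelihood ------------------------------------------------------


def log_likelihood_exact(table: CrossInfectionTable, hyp: FunctionalModelHypothesis) -> float:
    """Exact marginal log-likelihood by enumeration over latent genotypes.

    Conditioning on a full assignment of the (say) parasite margin makes
    host isolates independent, so the sum enumerates only the smaller
    margin: cost ``K**min(G, H) * G * H * K``.  Returns ``-inf`` (with a
    warning) when the data are impossible under the hypothesis, which can
    only happen at ``epsilon = 0``.
    """
    G, H = table.n_host_isolates, table.n_parasite_isolates
    K = hyp.K
    if K ** (G + H) > ENUMERATION_GUARD:
        raise ValueError(
            f"enumeration over K**(G+H) = {K}**{G + H} latent assignments exceeds "
            f"the guard ({ENUMERATION_GUARD:g}); use fit_model instead"
        )
    C = _cell_loglik(table, hyp.matrix(), hyp.epsilon)
    log_f = _safe_log(hyp.host_freqs)
    log_g = _safe_log(hyp.parasite_freqs)
    if G < H:  # enumerate hosts instead
        C = C.transpose(1, 0, 3, 2)
        G, H = H, G
        log_f, log_g = log_g, log_f
    idx = np.arange(H)
    terms = []
    for z in itertools.product(range(K), repeat=H):
        zz = np.asarray(z)
        # advanced indexing on axes 1 and 3 -> (H, G, K); sum out the margin
        per_host = C[:, idx, :, zz].sum(axis=0)  # (G, K)
        ll = float(log_g[zz].sum() + logsumexp(log_f[None, :] + per_host, axis=1).sum())
        terms.append(ll)
    ll = float(logsumexp(terms))
    if ll < -1e12:
        warnings.warn(
            "data are impossible under the hypothesis (epsilon = 0 with "
            "contradictory counts); returning -inf"
        )
        return float("-inf")
    return ll


# -- mean-field EM ---------------------------------------------------------


def _elbo(r, s, f, g, C):
    data = float(np.einsum("gi,hj,ghij->", r, s, C))
    prior = float((r * _safe_log(f)[None, :]).sum())
    prior += float((s * _safe_log(g)[None, :]).sum())
    entropy = -float((r * _safe_log(r)).sum()) - float((s * _safe_log(s)).sum())
    return data + prior + entropy


def _mean_field_em(C, K, f0, g0, max_iter, tol, s0=None):
    """Alternating posterior / frequency updates; returns (f, g, r, s, elbo, it, conv)."""
    G, H = C.shape[0], C.shape[1]
    f, g = f0.copy(), g0.copy()
    s = np.tile(g, (H, 1)) if s0 is None else np.asarray(s0, float)
    r = np.tile(f, (G, 1))
    elbo_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        r = _softmax_rows(_safe_log(f)[None, :] + np.einsum("hj,ghij->gi", s, C))
        s = _softmax_rows(_safe_log(g)[None, :] + np.einsum("gi,ghij->hj", r, C))
        f = r.mean(axis=0)
        g = s.mean(axis=0)
        elbo = _elbo(r, s, f, g, C)
        # coordinate ascent: the bound must not decrease
        assert elbo >= elbo_prev - 1e-6 * max(1.0, abs(elbo_prev)), "EM objective decreased"
        if elbo - elbo_prev < tol:
            converged = True
            break
        elbo_prev = elbo
    return f, g, r, s, elbo, it, converged


def _fit_const(table: CrossInfectionTable, K: int, eps: float) -> FitResult:
    # under a constant matrix the latent genotypes are irrelevant and the
    # MLE of the single infection probability is closed-form
    t = table.design.trials_per_cell
    total = table.counts.sum()
    n_trials = table.counts.size * t
    p_hat = total / n_trials
    c = float(np.clip((p_hat - eps) / (1.0 - 2.0 * eps), 0.0, 1.0))
    pi = c * (1.0 - 2.0 * eps) + eps
    with np.errstate(divide="ignore"):
        ll = float(stats.binom.logpmf(table.counts, t, pi).sum())
    uniform = np.full(K, 1.0 / K)
    hyp = FunctionalModelHypothesis("CONST", K, uniform, uniform, eps, {"c": c})
    return FitResult(
        hypothesis=hyp,
        log_likelihood=ll,
        n_params=1,
        elbo=ll,
        exact=True,
        converged=True,
        n_iter=1,
        host_posteriors=np.tile(uniform, (table.n_host_isolates, 1)),
        parasite_posteriors=np.tile(uniform, (table.n_parasite_isolates, 1)),
    )


def _polish_exact(table, model_name, K, eps, matrix_params, f, g):
    """Nelder-Mead on the exact log-likelihood in softmax coordinates."""

    def unpack(x):
        fu = np.exp(np.append(x[: K - 1], 0.0))
        gu = np.exp(np.append(x[K - 1 :], 0.0))
        return fu / fu.sum(), gu / gu.sum()

    def nll(x):
        ff, gg = unpack(x)
        hyp = FunctionalModelHypothesis(model_name, K, ff, gg, eps, matrix_params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return -log_likelihood_exact(table, hyp)

    fc = np.clip(f, 1e-8, None)
    gc = np.clip(g, 1e-8, None)
    x0 = np.concatenate([np.log(fc[:-1] / fc[-1]), np.log(gc[:-1] / gc[-1])])
    res = optimize.minimize(
        nll, x0, method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 4000},
    )
    ff, gg = unpack(res.x)
    return ff, gg, -float(res.fun)


def fit_model(
    table: CrossInfectionTable,
    model_name: str,
    K: int,
    *,
    epsilon: float = 0.01,
    estimate_epsilon: bool = False,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int = 0,
    matrix_params: Mapping | None = None,
    polish: bool = True,
) -> FitResult:
    """Maximize the table's likelihood over genotype frequencies.

    Restart 0 starts from uniform frequencies; the remaining restarts from
    seeded Dirichlet draws.  With ``estimate_epsilon=True`` the assay error
    rate is re-optimized (1-D, bounded) between EM passes.
    """
    matrix_params = dict(matrix_params or {})
    if model_name == "CONST":
        return _fit_const(table, K, epsilon)
    probe = FunctionalModelHypothesis(
        model_name, K, np.full(K, 1.0 / K), np.full(K, 1.0 / K), epsilon, matrix_params
    )
    alpha = probe.matrix()
    G, H = table.n_host_isolates, table.n_parasite_isolates
    rng = np.random.default_rng(seed)
    eps = float(epsilon)
    n_outer = 5 if estimate_epsilon else 1

    best = None
    C0 = _cell_loglik(table, alpha, eps)
    for restart in range(max(1, n_restarts)):
        f0 = np.full(K, 1.0 / K)
        g0 = np.full(K, 1.0 / K)
        if restart == 0:
            s0 = None  # deterministic uniform start
        else:
            # per-isolate random soft assignments break the label symmetry
            # that traps the uniform start in degenerate optima
            s0 = rng.dirichlet(np.ones(K), size=H)
            f0 = rng.dirichlet(np.ones(K))
            g0 = rng.dirichlet(np.ones(K))
        eps_r = eps
        C = C0
        f, g, r, s, elbo, iters, conv = _mean_field_em(C, K, f0, g0, max_iter, tol, s0=s0)
        for _ in range(n_outer - 1):
            def expected_ll(e):
                Ce = _cell_loglik(table, alpha, e)
                return -float(np.einsum("gi,hj,ghij->", r, s, Ce))

            opt = optimize.minimize_scalar(
                expected_ll, bounds=(1e-6, 0.4999), method="bounded"
            )
            if abs(opt.x - eps_r) < 1e-10:
                break
            eps_r = float(opt.x)
            C = _cell_loglik(table, alpha, eps_r)
            f, g, r, s, elbo, iters, conv = _mean_field_em(C, K, f, g, max_iter, tol)
        cand = (elbo, f, g, r, s, eps_r, iters, conv)
        if best is None or cand[0] > best[0]:
            best = cand

    elbo, f, g, r, s, eps_r, iters, conv = best
    n_params = 2 * (K - 1) + (1 if estimate_epsilon else 0)
    within_guard = K ** (G + H) <= ENUMERATION_GUARD
    if within_guard:
        hyp = FunctionalModelHypothesis(model_name, K, f, g, eps_r, matrix_params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ll_em = log_likelihood_exact(table, hyp)
        ll = ll_em
        if polish and K >= 2 and np.isfinite(ll_em):
            fp, gp, ll_p = _polish_exact(table, model_name, K, eps_r, matrix_params, f, g)
            if ll_p > ll:
                f, g, ll = fp, gp, ll_p
        exact = True
    else:
        ll = elbo
        exact = False
    if not conv:
        warnings.warn(
            f"EM did not converge within {max_iter} iterations; reporting best value found"
        )
    hyp = FunctionalModelHypothesis(model_name, K, f, g, eps_r, matrix_params)
    return FitResult(
        hypothesis=hyp,
        log_likelihood=float(ll),
        n_params=n_params,
        elbo=float(elbo),
        exact=exact,
        converged=conv,
        n_iter=iters,
        host_posteriors=r,
        parasite_posteriors=s,
    )


# -- model comparison ------------------------------------------------------


def _normalize_hypothesis_spec(h) -> dict:
    if isinstance(h, Mapping):
        spec = dict(h)
    elif isinstance(h, (tuple, list)) and len(h) == 2:
        spec = {"model_name": h[0], "K": int(h[1])}
    else:
        raise TypeError("hypothesis must be a (model_name, K) pair or a mapping")
    if "model_name" not in spec or "K" not in spec:
        raise ValueError("hypothesis spec needs 'model_name' and 'K'")
    return spec


def compare_models(
    table: CrossInfectionTable,
    hypotheses: Sequence,
    **fit_kwargs,
) -> ModelComparisonResult:
    """Fit every candidate hypothesis and rank by AIC.

    ``hypotheses`` is a sequence of ``(model_name, K)`` pairs or mappings
    with those keys (plus optional per-hypothesis ``epsilon``,
    ``matrix_params``, ``estimate_epsilon``).  The selected model has the
    lowest AIC; ties go to the fewer-parameter hypothesis, then to input
    order.  Likelihood-ratio statistics are reported for pairs flagged in
    :data:`NESTED_PAIRS`.
    """
    if len(hypotheses) < 2:
        raise ValueError("need at least two hypotheses to compare")
    fits = []
    for h in hypotheses:
        spec = _normalize_hypothesis_spec(h)
        kwargs = {**fit_kwargs, **{k: v for k, v in spec.items() if k not in ("model_name", "K")}}
        fits.append(fit_model(table, spec["model_name"], spec["K"], **kwargs))
    rows = [
        {
            "model": fit.hypothesis.model_name,
            "K": fit.hypothesis.K,
            "log_likelihood": fit.log_likelihood,
            "n_params": fit.n_params,
            "aic": fit.aic,
            "exact": fit.exact,
        }
        for fit in fits
    ]
    df = pd.DataFrame(rows)
    aics = df["aic"].to_numpy()
    best_aic = aics.min()
    candidates = [i for i in range(len(fits)) if aics[i] <= best_aic + 1e-9]
    candidates.sort(key=lambda i: (fits[i].n_params, i))
    sel = candidates[0]
    lrt = []
    for i, j in itertools.permutations(range(len(fits)), 2):
        pair = (fits[i].hypothesis.model_name, fits[j].hypothesis.model_name)
        if pair in NESTED_PAIRS:
            stat = max(0.0, 2.0 * (fits[j].log_likelihood - fits[i].log_likelihood))
            ddf = fits[j].n_params - fits[i].n_params
            lrt.append(
                {
                    "null": pair[0],
                    "alternative": pair[1],
                    "statistic": stat,
                    "df": ddf,
                    "p_value": float(stats.chi2.sf(stat, ddf)) if ddf > 0 else np.nan,
                }
            )
    return ModelComparisonResult(
        fits=fits,
        table=df,
        selected=fits[sel].hypothesis.model_name,
        selected_index=sel,
        lrt=lrt,
    )


def posteriors_to_dataframe(fit: FitResult) -> pd.DataFrame:
    """Per-isolate posterior genotype assignments, CSV-writable."""
    rows = []
    for species, post in (("host", fit.host_posteriors), ("parasite", fit.parasite_posteriors)):
        for isolate, probs in enumerate(post):
            for genotype, prob in enumerate(probs):
                rows.append(
                    {
                        "species": species,
                        "isolate": isolate,
                        "genotype": genotype,
                        "posterior": float(prob),
                    }
                )
    return pd.DataFrame(rows)
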