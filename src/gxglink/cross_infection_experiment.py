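"""Simulated reciprocal cross-infection experiments.

The empiricist's view of a coevolving population: sample isolates from each
species, challenge every host × parasite pair ``trials_per_cell`` times in
each of ``replicates`` independent factorial repeats, and record per-cell
infection counts.  Isolate genotypes are latent to the analyst; the table
keeps them only so simulation studies can validate inference.

Isolates are drawn with replacement from the genotype frequency
distribution (the infinite-population approximation of picking ~30
individuals from a population of 100,000).  Each trial outcome is Bernoulli
with probability ``pi' = alpha_ij (1 - eps) + (1 - alpha_ij) eps`` — the
matrix entry for the pair's genotypes, flipped with assay error rate
``eps``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gxglink.coevolution_simulator import PopulationState, TrajectoryRecord
from gxglink.infection_models import InfectionMatrix

__all__ = [
    "ExperimentDesign",
    "CrossInfectionTable",
    "sample_isolates",
    "run_cross_infection",
    "longitudinal_survey",
]


@dataclass
class ExperimentDesign:
    """Sampling design of one factorial cross-infection study."""

    n_isolates_host: int = 30
    n_isolates_parasite: int = 30
    trials_per_cell: int = 5
    replicates: int = 5
    sampling_interval: int = 20
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_isolates_host", "n_isolates_parasite", "trials_per_cell",
                     "replicates", "sampling_interval"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")


@dataclass
class CrossInfectionTable:
    """Infection counts ``y[g, h, r]`` for a complete factorial design.

    ``counts`` has shape ``(n_host_isolates, n_parasite_isolates,
    replicates)`` with entries in ``0..trials_per_cell``.  The latent
    genotype vectors are ``None`` for tables read from user CSVs.
    """

    counts: np.ndarray
    design: ExperimentDesign
    host_genotypes: np.ndarray | None = None
    parasite_genotypes: np.ndarray | None = None
    generation: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be (hosts, parasites, replicates)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(int)
        if self.counts.min() < 0 or self.counts.max() > self.design.trials_per_cell:
            raise ValueError("counts must lie in 0..trials_per_cell")
        if self.counts.shape[2] != self.design.replicates:
            raise ValueError("replicate axis does not match design.replicates")

    @property
    def n_host_isolates(self) -> int:
        return self.counts.shape[0]

    @property
    def n_parasite_isolates(self) -> int:
        return self.counts.shape[1]

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[2]

    # -- I/O ---------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        G, H, R = self.counts.shape
        g, h, r = np.meshgrid(np.arange(G), np.arange(H), np.arange(R), indexing="ij")
        return pd.DataFrame(
            {
                "host_isolate": g.ravel(),
                "parasite_isolate": h.ravel(),
                "replicate": r.ravel(),
                "infections": self.counts.ravel(),
                "trials": self.design.trials_per_cell,
            }
        )

    def to_csv(self, path: str | Path, truth_path: str | Path | None = None) -> None:
        """Write the analyst-visible table; latent genotypes (the simulation
        truth) go to a separate CSV that inference code never reads."""
        self.to_dataframe().to_csv(path, index=False)
        if truth_path is not None:
            if self.host_genotypes is None or self.parasite_genotypes is None:
                raise ValueError("no latent genotypes to write")
            truth = pd.concat(
                [
                    pd.DataFrame({"species": "host",
                                  "isolate": np.arange(self.n_host_isolates),
                                  "genotype": self.host_genotypes}),
                    pd.DataFrame({"species": "parasite",
                                  "isolate": np.arange(self.n_parasite_isolates),
                                  "genotype": self.parasite_genotypes}),
                ],
                ignore_index=True,
            )
            truth.to_csv(truth_path, index=False)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, design: ExperimentDesign | None = None, generation: int = 0
    ) -> "CrossInfectionTable":
        required = {"host_isolate", "parasite_isolate", "replicate", "infections", "trials"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"table is missing columns: {sorted(missing)}")
        trials = df["trials"].unique()
        if len(trials) != 1:
            raise ValueError("trials must be constant across cells")
        hosts = np.sort(df["host_isolate"].unique())
        paras = np.sort(df["parasite_isolate"].unique())
        reps = np.sort(df["replicate"].unique())
        G, H, R = len(hosts), len(paras), len(reps)
        if len(df) != G * H * R:
            raise ValueError("table is not a complete balanced factorial")
        if design is None:
            design = ExperimentDesign(
                n_isolates_host=G,
                n_isolates_parasite=H,
                trials_per_cell=int(trials[0]),
                replicates=R,
            )
        pivot = df.set_index(["host_isolate", "parasite_isolate", "replicate"])
        if pivot.index.has_duplicates:
            raise ValueError("duplicate (host, parasite, replicate) rows")
        counts = (
            pivot["infections"]
            .unstack(["parasite_isolate", "replicate"])  # may raise on holes
            .to_numpy()
            .reshape(G, H, R)
        )
        if np.isnan(counts).any():
            raise ValueError("table is not a complete balanced factorial")
        return cls(counts.astype(int), design, generation=generation)

    @classmethod
    def from_csv(cls, path: str | Path, design: ExperimentDesign | None = None) -> "CrossInfectionTable":
        return cls.from_dataframe(pd.read_csv(path), design=design)


def sample_isolates(
    state: PopulationState | np.ndarray,
    n: int,
    rng: np.random.Generator,
    species: str = "host",
) -> np.ndarray:
    """Draw ``n`` isolate genotypes from the genotype frequency distribution.

    ``state`` may be a :class:`PopulationState` (then ``species`` selects the
    ``p`` or ``q`` vector) or a bare frequency vector.  Sampling is with
    replacement: picking tens of isolates from a population of 10^5 is
    indistinguishable from i.i.d. draws.
    """
    if isinstance(state, PopulationState):
        freqs = state.p if species == "host" else state.q
    else:
        freqs = np.asarray(state, dtype=float)
    return rng.choice(len(freqs), size=n, p=freqs)


def run_cross_infection(
    host_isolates: np.ndarray,
    parasite_isolates: np.ndarray,
    alpha: InfectionMatrix | np.ndarray,
    design: ExperimentDesign,
    rng: np.random.Generator,
    generation: int = 0,
) -> CrossInfectionTable:
    """Binomial infection counts for every isolate pair and replicate."""
    host_isolates = np.asarray(host_isolates, dtype=int)
    parasite_isolates = np.asarray(parasite_isolates, dtype=int)
    if host_isolates.size == 0 or parasite_isolates.size == 0:
        raise ValueError("isolate vectors must be non-empty")
    A = alpha.alpha if isinstance(alpha, InfectionMatrix) else np.asarray(alpha, float)
    pi = A[np.ix_(host_isolates, parasite_isolates)]
    eps = design.error_rate
    pi_eff = pi * (1.0 - eps) + (1.0 - pi) * eps
    counts = rng.binomial(
        design.trials_per_cell,
        pi_eff[:, :, None],
        size=(len(host_isolates), len(parasite_isolates), design.replicates),
    )
    return CrossInfectionTable(
        counts,
        design,
        host_genotypes=host_isolates,
        parasite_genotypes=parasite_isolates,
        generation=generation,
    )


def longitudinal_survey(
    trajectory: TrajectoryRecord,
    design: ExperimentDesign,
    rng: np.random.Generator,
) -> list[CrossInfectionTable]:
    """One cross-infection experiment every ``sampling_interval`` generations.

    Experiments are taken at generations ``0, interval, 2*interval, ...``
    (inclusive endpoints), each with fresh isolate samples and fresh
    binomial draws.
    """
    T = trajectory.n_generations
    if design.sampling_interval > T:
        raise ValueError(
            f"sampling interval {design.sampling_interval} exceeds trajectory length {T}"
        )
    tables = []
    for t in range(0, T + 1, design.sampling_interval):
        state = trajectory.state(t)
        hosts = sample_isolates(state.p, design.n_isolates_host, rng)
        paras = sample_isolates(state.q, design.n_isolates_parasite, rng)
        tables.append(
            run_cross_infection(
                hosts, paras, trajectory.params.model, design, rng, generation=t
            )
        )
    return tables
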