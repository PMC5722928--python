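"""ABC rejection inference of subclone fitness and arising time.

Given an observed (mutant frequency, mixing score) pair measured on a
lesion, parameters (fitness ratio, arising population size) are drawn
from uniform priors, one growth realization is simulated per draw, the
same two summary statistics are computed with the shared quadrat
scheme, and draws whose Euclidean distance to the observation is below
the threshold epsilon are accepted into the posterior. The reported
point estimate is the center of the modal bin of a 2D histogram of the
accepted draws (arising size binned on a log scale), matching the
maximal-posterior-probability reporting convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .metrics import CloneMap, QuadratSpec, SummaryPair, summarize
from .simulator import (
    Mechanics,
    SimParams,
    default_quadrat_side,
    run,
)

__all__ = [
    "PriorSpec",
    "AbcResult",
    "euclidean_distance",
    "abc_rejection",
    "map_estimate",
    "classify_regime",
    "SELECTION_ANCHORS",
]

#: Canonical fitness-ratio anchors and their selection-regime labels.
SELECTION_ANCHORS = ((1.0, "neutral"), (1.75, "weak"), (3.0, "intermediate"), (8.0, "strong"))


@dataclass
class PriorSpec:
    """Uniform priors over the two inferred parameters, plus the fixed
    nuisance settings shared by every simulated draw.

    ``fitness_ratio`` is sampled uniformly on the closed interval.
    ``arise_size`` is sampled log-uniformly on its closed integer
    interval: the underlying inferred quantity is the clone's arrival
    *time*, and since the population grows exponentially a uniform
    prior on arrival time is log-uniform in the population size at
    arrival. (This also matches the log-scale binning of the
    posterior mode.) The simulated tumor size, mechanics and death
    rate are held fixed across draws.
    """

    fitness_ratio_range: tuple = (1.0, 10.0)
    arise_size_range: tuple = (10, 2000)
    final_size: int = 2500
    mechanics: Mechanics = Mechanics.PUSHING
    death_rate: float = 0.0
    quadrat_side: Optional[int] = None

    def validate(self) -> None:
        flo, fhi = self.fitness_ratio_range
        alo, ahi = self.arise_size_range
        if not (1.0 <= flo < fhi):
            raise ValueError(f"bad fitness_ratio_range {self.fitness_ratio_range}")
        if not (2 <= alo < ahi < self.final_size):
            raise ValueError(
                f"need 2 <= arise lo < hi < final_size, got "
                f"{self.arise_size_range} with final_size={self.final_size}"
            )

    def resolved_quadrat_side(self) -> int:
        if self.quadrat_side is not None:
            return int(self.quadrat_side)
        return default_quadrat_side(self.final_size)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mechanics"] = self.mechanics.value
        d["quadrat_side"] = self.resolved_quadrat_side()
        return d


@dataclass
class AbcResult:
    """Outcome of an ABC rejection run.

    ``draws`` has one row per draw: fitness_ratio, arise_size,
    frequency, entropy, distance, accepted, extinct (extinct
    realizations have NaN summaries and are always rejected).
    """

    draws: pd.DataFrame
    epsilon: float
    observed: SummaryPair
    priors: PriorSpec
    seed: int
    status: str = "ok"
    map_estimate: Optional[tuple] = None

    @property
    def accepted(self) -> pd.DataFrame:
        return self.draws[self.draws["accepted"]]

    @property
    def acceptance_rate(self) -> float:
        return float(self.draws["accepted"].mean()) if len(self.draws) else 0.0

    @property
    def n_extinct(self) -> int:
        return int(self.draws["extinct"].sum())

    def summary_dict(self) -> dict:
        d = {
            "status": self.status,
            "epsilon": self.epsilon,
            "seed": self.seed,
            "n_draws": int(len(self.draws)),
            "n_accepted": int(self.draws["accepted"].sum()),
            "n_extinct": self.n_extinct,
            "acceptance_rate": self.acceptance_rate,
            "observed": {"frequency": self.observed.frequency, "entropy": self.observed.entropy},
            "priors": self.priors.to_dict(),
        }
        if self.map_estimate is not None:
            d["map_estimate"] = {
                "fitness_ratio": self.map_estimate[0],
                "arise_size": self.map_estimate[1],
            }
            sel, timing = classify_regime(self.map_estimate, self.priors)
            d["regime"] = {"selection": sel, "timing": timing}
        return d


def euclidean_distance(observed: SummaryPair, simulated: SummaryPair) -> float:
    """Euclidean distance between two (frequency, mixing) pairs.

    No re-weighting: both components already live on [0, 1]."""
    df = observed.frequency - simulated.frequency
    de = observed.entropy - simulated.entropy
    return float(np.hypot(df, de))


def abc_rejection(
    observed: SummaryPair,
    priors: PriorSpec,
    n_draws: int,
    epsilon: float = 0.05,
    seed: int = 0,
    progress: bool = False,
) -> AbcResult:
    """ABC rejection sampling against the spatial growth simulator.

    One realization is simulated per parameter draw; acceptance is the
    strict inequality distance < epsilon. Extinct realizations (only
    possible under EMPTY_ONLY mechanics) count as rejected draws.
    Fully reproducible from ``seed``: each draw's parameters and
    realization come from an independent child stream, so results do
    not depend on evaluation order and replaying the first k draws
    reproduces them exactly.
    """
    priors.validate()
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    root = np.random.SeedSequence(seed)
    flo, fhi = priors.fitness_ratio_range
    alo, ahi = priors.arise_size_range
    sim_seeds = root.spawn(n_draws)
    qside = priors.resolved_quadrat_side()
    spec = QuadratSpec(quadrat_side=qside)

    iterator = range(n_draws)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="abc", unit="draw")

    rows = []
    for i in iterator:
        rng = np.random.default_rng(sim_seeds[i])
        fitness = float(rng.uniform(flo, fhi))
        arise = int(np.clip(round(10 ** rng.uniform(np.log10(alo), np.log10(ahi))), alo, ahi))
        params = SimParams(
            fitness_ratio=fitness,
            arise_size=arise,
            final_size=priors.final_size,
            death_rate=priors.death_rate,
            mechanics=priors.mechanics,
        )
        state, _ = run(params, rng=rng, quadrat_side=qside)
        if state.extinct:
            rows.append((fitness, arise, np.nan, np.nan, np.inf, False, True))
            continue
        pair = summarize(CloneMap(state.grid), spec)
        dist = euclidean_distance(observed, pair)
        rows.append((fitness, arise, pair.frequency, pair.entropy, dist, dist < epsilon, False))

    draws = pd.DataFrame(
        rows,
        columns=["fitness_ratio", "arise_size", "frequency", "entropy", "distance", "accepted", "extinct"],
    )
    result = AbcResult(draws=draws, epsilon=epsilon, observed=observed, priors=priors, seed=seed)
    if not draws["accepted"].any():
        result.status = "empty_posterior"
    else:
        result.map_estimate = map_estimate(result)
    return result


def map_estimate(result: AbcResult, bins: int = 10) -> tuple:
    """Maximum-posterior parameters via the modal 2D histogram bin.

    Accepted draws are histogrammed on a ``bins x bins`` grid over the
    prior support, with arising size on a log scale. The center of the
    modal bin is returned (geometric center on the log axis). Ties are
    broken toward the smaller fitness ratio, then the smaller arising
    size.
    """
    acc = result.accepted
    if len(acc) == 0:
        raise ValueError("empty posterior: no accepted draws")
    flo, fhi = result.priors.fitness_ratio_range
    alo, ahi = result.priors.arise_size_range
    f_edges = np.linspace(flo, fhi, bins + 1)
    a_edges = np.logspace(np.log10(alo), np.log10(ahi), bins + 1)
    h, _, _ = np.histogram2d(
        acc["fitness_ratio"], acc["arise_size"], bins=[f_edges, a_edges]
    )
    # first maximum in (fitness asc, arise asc) raster order = documented tie-break
    i, j = np.unravel_index(int(np.argmax(h)), h.shape)
    f_hat = 0.5 * (f_edges[i] + f_edges[i + 1])
    a_hat = float(np.sqrt(a_edges[j] * a_edges[j + 1]))
    return (float(f_hat), a_hat)


def classify_regime(estimate: tuple, priors: PriorSpec) -> tuple:
    """Label an estimate as (selection regime, timing).

    The fitness ratio maps to the nearest canonical anchor
    (1 -> neutral, 1.75 -> weak, 3.0 -> intermediate, 8.0 -> strong;
    ties toward the lower anchor). The arising size is 'early' below
    the geometric midpoint of its prior range, 'late' at or above it.
    """
    f_hat, a_hat = estimate
    anchors = np.array([a for a, _ in SELECTION_ANCHORS])
    labels = [lab for _, lab in SELECTION_ANCHORS]
    selection = labels[int(np.argmin(np.abs(anchors - f_hat)))]
    alo, ahi = priors.arise_size_range
    midpoint = np.sqrt(alo * ahi)
    timing = "early" if a_hat < midpoint else "late"
    return selection, timing
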