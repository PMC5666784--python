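"""Seeded generator of replica compound collections and enumerated screens.

Real enrichment benchmarking starts from a screened collection (here
emulating a 1364-compound diversity set with 19 experimentally confirmed
kinase inhibitors, 4 of them potent) and the rank lists that commercial
docking / shape-similarity engines produce over its *enumerated* 3D library.
Neither the collection's rank lists nor the screening engines are
redistributable, so this module generates collections, activity tables and
score lists with the statistical structure that the downstream evaluation
assumes:

* a latent lognormal "molecular size" per parent compound;
* uneven state enumeration — per-parent state counts of 1 + Poisson with a
  size-dependent mean (lambda0 * size**gamma), giving a median of a few
  states but an upper tail into the hundreds, as protonation/tautomer/
  stereoisomer expansion does on real diverse collections;
* class-separated Gaussian scores: active parents shifted by ``score_sep``
  inactive-SD units toward the better end, with independent per-state noise;
* a configurable bulk artifact (``rho_bulk``): large inactive compounds are
  simultaneously penalized in score and rich in states, so their many states
  pile up at the bottom of the redundant list.  This is the mechanism by
  which the redundant treatment inflates every enrichment metric relative
  to the no-duplicates treatment; at ``rho_bulk = 0`` the inflation vanishes
  by construction (state multiplicity independent of score).

All draws come from one seed via deterministic per-stage child streams:
identical (config, seed) reproduces every output byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .ranking import (
    DIRECTIONS,
    LIGAND_BASED,
    LOWER_BETTER,
    STRUCTURE_BASED,
    ActivityTable,
    RankedScreen,
)

__all__ = [
    "SimulationConfig",
    "SyntheticCollection",
    "generate_collection",
    "enumerate_states",
    "simulate_screen",
    "simulate_pipeline",
]

#: Kinase panel of the replica activity table; the first entry is primary.
KINASES = ("CK1d/e", "GSK3a/b", "CDK5/p25", "DYRK1a")
PRIMARY_KINASE = KINASES[0]

#: Residual-activity brackets (percent) per class: potent actives bracket
#: the strongest printed hits, moderate actives fill the rest of the
#: threshold window, inactives lie strictly above it.
POTENT_BRACKET = (5.0, 25.0)
MODERATE_BRACKET = (25.0, 40.0)
INACTIVE_BRACKET = (40.0, 100.0)
ACTIVE_THRESHOLD = 40.0

#: Size penalty (inactive-SD units per standardized log-size) applied to
#: inactive parents at rho_bulk = 1.
BULK_PENALTY_SCALE = 2.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic screening campaign.

    Defaults replicate the study conditions the evaluation is designed for:
    a 1364-parent collection with 19 actives (4 potent), heavy-tailed state
    enumeration, and docking-like class separation.
    """

    n_parents: int = 1364
    n_active: int = 19
    n_potent: int = 4
    size_log_mean: float = 0.0
    size_log_sd: float = 0.6
    state_rate: float = 4.0  # lambda0
    multiplicity_size_exponent: float = 2.5  # gamma
    score_sep: float = 1.5  # Delta, in inactive score SDs
    state_noise_sd: float = 0.05
    rho_bulk: float = 0.5
    direction: str = LOWER_BETTER
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_parents <= 0:
            raise ParameterError(f"n_parents must be positive, got {self.n_parents}")
        if not 0 <= self.n_potent <= self.n_active <= self.n_parents:
            raise ParameterError(
                "need 0 <= n_potent <= n_active <= n_parents, got "
                f"{self.n_potent}/{self.n_active}/{self.n_parents}"
            )
        if self.size_log_sd < 0 or self.state_rate < 0 or self.state_noise_sd < 0:
            raise ParameterError("scale parameters must be nonnegative")
        if self.multiplicity_size_exponent < 0:
            raise ParameterError("multiplicity_size_exponent must be >= 0")
        if not self.score_sep > 0:
            raise ParameterError(f"score_sep must be > 0, got {self.score_sep}")
        if not 0.0 <= self.rho_bulk <= 1.0:
            raise ParameterError(f"rho_bulk must lie in [0, 1], got {self.rho_bulk}")
        if self.direction not in DIRECTIONS:
            raise ParameterError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )

    def rng(self, stage: int) -> np.random.Generator:
        """Deterministic child stream for a pipeline stage (0 = collection,
        1 = state enumeration, 2 = scores)."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stage,))
        )

    def to_dict(self) -> dict:
        return {
            "n_parents": self.n_parents,
            "n_active": self.n_active,
            "n_potent": self.n_potent,
            "size_log_mean": self.size_log_mean,
            "size_log_sd": self.size_log_sd,
            "state_rate": self.state_rate,
            "multiplicity_size_exponent": self.multiplicity_size_exponent,
            "score_sep": self.score_sep,
            "state_noise_sd": self.state_noise_sd,
            "rho_bulk": self.rho_bulk,
            "direction": self.direction,
            "seed": self.seed,
        }


@dataclass
class SyntheticCollection:
    """A generated compound collection with ground truth and activity table.

    ``parents`` columns: parent_id, latent_size, is_active, is_potent, plus
    one residual-activity column (percent) per kinase in :data:`KINASES`.
    """

    parents: pd.DataFrame
    config: SimulationConfig

    @property
    def n_parents(self) -> int:
        return len(self.parents)

    def activity_table(self, threshold_pct: float = ACTIVE_THRESHOLD) -> ActivityTable:
        rows = self.parents.set_index("parent_id")[list(KINASES)].copy()
        rows.index.name = "compound_id"
        return ActivityTable(rows=rows, primary_kinase=PRIMARY_KINASE, threshold_pct=threshold_pct)

    def active_ids(self) -> list[str]:
        return list(self.parents.loc[self.parents["is_active"], "parent_id"])

    def potent_ids(self) -> list[str]:
        return list(self.parents.loc[self.parents["is_potent"], "parent_id"])


def _uniform_open(rng: np.random.Generator, low: float, high: float, size: int) -> np.ndarray:
    # uniform on (low, high): nudge the lower edge so class brackets never
    # collide with the inclusive activity threshold
    return rng.uniform(np.nextafter(low, high), high, size=size)


def generate_collection(config: SimulationConfig) -> SyntheticCollection:
    """Generate a replica collection with an exact active/potent census.

    Exactly ``n_active`` parents receive a primary-kinase residual at or
    below the 40% threshold; ``n_potent`` of those are potent (residual in
    [5, 25], bracketing the strongest confirmed hits), the remaining actives
    fall in (25, 40], and inactives in (40, 100].  Off-target kinase
    residuals are uninformative draws in (25, 100].  Latent molecular size
    is lognormal and independent of the activity class.
    """
    rng = config.rng(0)
    m = config.n_parents
    width = max(4, len(str(m)))
    parent_ids = np.array([f"C{i + 1:0{width}d}" for i in range(m)], dtype=object)
    latent_size = rng.lognormal(config.size_log_mean, config.size_log_sd, size=m)

    order = rng.permutation(m)
    is_active = np.zeros(m, dtype=bool)
    is_potent = np.zeros(m, dtype=bool)
    is_active[order[: config.n_active]] = True
    is_potent[order[: config.n_potent]] = True

    primary = np.empty(m, dtype=float)
    primary[is_potent] = rng.uniform(*POTENT_BRACKET, size=config.n_potent)
    moderate = is_active & ~is_potent
    primary[moderate] = _uniform_open(
        rng, *MODERATE_BRACKET, size=int(moderate.sum())
    )
    primary[~is_active] = _uniform_open(
        rng, *INACTIVE_BRACKET, size=m - config.n_active
    )

    df = pd.DataFrame(
        {
            "parent_id": parent_ids,
            "latent_size": latent_size,
            "is_active": is_active,
            "is_potent": is_potent,
            PRIMARY_KINASE: primary,
        }
    )
    for kinase in KINASES[1:]:
        df[kinase] = rng.uniform(25.0, 100.0, size=m)
    return SyntheticCollection(parents=df, config=config)


def enumerate_states(
    collection: SyntheticCollection, config: SimulationConfig | None = None
) -> pd.DataFrame:
    """Expand each parent into its enumerated states (uneven expansion).

    Per-parent state count is 1 + Poisson(lambda0 * size**gamma): every
    parent keeps at least one state, counts grow with molecular size, and
    the lognormal size tail produces the heavy upper tail of real
    enumeration.  Returns a DataFrame with columns state_id, parent_id,
    latent_size, is_active (scores are assigned by :func:`simulate_screen`).
    """
    config = config or collection.config
    rng = config.rng(1)
    size = collection.parents["latent_size"].to_numpy()
    lam = config.state_rate * size**config.multiplicity_size_exponent
    counts = 1 + rng.poisson(lam)

    parent_ids = collection.parents["parent_id"].to_numpy(dtype=object)
    rep = np.repeat(np.arange(collection.n_parents), counts)
    state_index = np.concatenate([np.arange(1, c + 1) for c in counts])
    states = pd.DataFrame(
        {
            "state_id": [
                f"{parent_ids[i]}_s{j}" for i, j in zip(rep, state_index)
            ],
            "parent_id": parent_ids[rep],
            "latent_size": size[rep],
            "is_active": collection.parents["is_active"].to_numpy()[rep],
        }
    )
    return states


def simulate_screen(
    states: pd.DataFrame,
    collection: SyntheticCollection,
    config: SimulationConfig | None = None,
    screen_type: str | None = None,
    template_id: str = "synthetic",
    name: str = "",
) -> RankedScreen:
    """Score every enumerated state and return the sorted screen.

    On the internal higher-is-better scale, each parent's mean score is a
    class mean (actives at +``score_sep``, inactives at 0) plus a standard
    normal between-parent term; inactive parents additionally receive a bulk
    penalty of ``-rho_bulk * BULK_PENALTY_SCALE * z`` where z is the
    standardized log molecular size — the knob coupling state multiplicity
    to poor scores.  State scores add independent Gaussian noise
    (``state_noise_sd``).  Emitted scores are negated for lower-is-better
    screens so that docking-like lists look docking-like.
    """
    config = config or collection.config
    rng = config.rng(2)
    par = collection.parents
    m = len(par)
    is_active = par["is_active"].to_numpy()
    z = (np.log(par["latent_size"].to_numpy()) - config.size_log_mean) / max(
        config.size_log_sd, 1e-12
    )
    parent_mean = rng.normal(0.0, 1.0, size=m)
    parent_mean[is_active] += config.score_sep
    parent_mean[~is_active] -= config.rho_bulk * BULK_PENALTY_SCALE * z[~is_active]

    mean_by_parent = dict(zip(par["parent_id"], parent_mean))
    mu = np.fromiter(
        (mean_by_parent[p] for p in states["parent_id"]), dtype=float, count=len(states)
    )
    internal = mu + rng.normal(0.0, config.state_noise_sd, size=len(states))
    emitted = -internal if config.direction == LOWER_BETTER else internal

    if screen_type is None:
        screen_type = (
            STRUCTURE_BASED if config.direction == LOWER_BETTER else LIGAND_BASED
        )
    frame = pd.DataFrame(
        {
            "state_id": states["state_id"].to_numpy(),
            "parent_id": states["parent_id"].to_numpy(),
            "score": emitted,
        }
    )
    return RankedScreen.from_frame(
        frame,
        direction=config.direction,
        screen_type=screen_type,
        template_id=template_id,
        name=name or f"synthetic_{screen_type}_{config.seed}",
    )


def simulate_pipeline(
    config: SimulationConfig,
    template_id: str = "synthetic",
    name: str = "",
) -> tuple[SyntheticCollection, pd.DataFrame, RankedScreen]:
    """Collection -> enumerated states -> scored screen, in one call."""
    collection = generate_collection(config)
    states = enumerate_states(collection, config)
    screen = simulate_screen(states, collection, config, template_id=template_id, name=name)
    return collection, states, screen
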