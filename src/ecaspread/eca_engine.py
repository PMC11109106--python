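"""Exact elementary-cellular-automaton (ECA) machinery.

An ECA is a one-dimensional binary automaton: each cell's next state is a
fixed Boolean function of itself and its two nearest neighbours.  The 256
possible functions are indexed 0-255 in Wolfram numbering, where bit
``b = 4*left + 2*centre + 1*right`` of the rule number gives the output for
neighbourhood ``(left, centre, right)``.

Only the 128 *even* rules — those mapping the all-zero neighbourhood to 0 —
are biologically admissible for a presence/absence spreading model: absence
cannot spontaneously become presence.  All downstream machinery therefore
refuses odd rules.

The lattice is flat, not periodic: a constant virtual 0 flanks both ends of
the array (zero padding), so presence never wraps around.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .rasterization import GridSpec, PresenceImage

__all__ = [
    "ECARule",
    "SimConfig",
    "PerRuleIntensity",
    "rule_outputs",
    "even_rules",
    "step",
    "step_batch",
    "evolve",
    "flatten",
    "unflatten",
    "random_state",
    "simulate_presence_counts",
    "per_rule_intensity",
    "all_rule_intensities",
    "consistent_rules",
]

N_RULES = 256
N_EVEN_RULES = 128


@dataclass(frozen=True)
class ECARule:
    """One Wolfram-numbered ECA rule.

    Attributes
    ----------
    number : int
        Rule number in [0, 255].
    table : numpy.ndarray
        Length-8 uint8 lookup table; ``table[4*l + 2*c + r]`` is the next
        state of a cell with neighbourhood ``(l, c, r)``.
    """

    number: int
    table: np.ndarray

    def __post_init__(self) -> None:
        if not 0 <= self.number <= 255:
            raise ValueError(f"rule number must be in [0, 255], got {self.number}")

    @property
    def is_even(self) -> bool:
        """True if the all-zero neighbourhood maps to 0 (number is even)."""
        return self.number % 2 == 0

    def __hash__(self) -> int:
        return hash(self.number)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ECARule):
            return self.number == other.number
        return NotImplemented


def rule_outputs(number: int) -> ECARule:
    """Expand a Wolfram rule number into its neighbourhood lookup table."""
    if not isinstance(number, (int, np.integer)) or isinstance(number, bool):
        raise TypeError(f"rule number must be an integer, got {number!r}")
    if not 0 <= number <= 255:
        raise ValueError(f"rule number must be in [0, 255], got {number}")
    table = (number >> np.arange(8)) & 1
    return ECARule(number=int(number), table=table.astype(np.uint8))


def even_rules() -> list[ECARule]:
    """The 128 even rules, ascending by number.

    Even rules fix the all-zero state: no cell can turn on without at least
    one occupied neighbour, the admissibility condition for a presence-only
    spreading model.
    """
    return [rule_outputs(n) for n in range(0, N_RULES, 2)]


def _as_rule(rule: int | ECARule) -> ECARule:
    return rule if isinstance(rule, ECARule) else rule_outputs(rule)


def _require_even(rule: ECARule) -> ECARule:
    if not rule.is_even:
        raise ValueError(
            f"rule {rule.number} is odd (maps empty neighbourhood to presence); "
            "only even rules are admissible"
        )
    return rule


def step(state: np.ndarray, rule: int | ECARule) -> np.ndarray:
    """Apply one ECA update to a 1-D binary state with zero boundaries.

    Cells at virtual positions -1 and n are held at 0, so the state never
    grows past the array ends.
    """
    rule = _as_rule(rule)
    s = np.asarray(state, dtype=np.uint8)
    if s.ndim != 1:
        raise ValueError(f"state must be 1-D, got shape {s.shape}")
    left = np.concatenate(([0], s[:-1]))
    right = np.concatenate((s[1:], [0]))
    return rule.table[4 * left + 2 * s + right]


def step_batch(states: np.ndarray, rule: int | ECARule) -> np.ndarray:
    """Apply one ECA update to each row of a (batch, n) array of states."""
    rule = _as_rule(rule)
    s = np.asarray(states, dtype=np.uint8)
    if s.ndim != 2:
        raise ValueError(f"states must be 2-D, got shape {s.shape}")
    zeros = np.zeros((s.shape[0], 1), dtype=np.uint8)
    left = np.concatenate((zeros, s[:, :-1]), axis=1)
    right = np.concatenate((s[:, 1:], zeros), axis=1)
    return rule.table[4 * left + 2 * s + right]


def evolve(state: np.ndarray, rule: int | ECARule, n_steps: int) -> list[np.ndarray]:
    """Return the trajectory [state, step(state), ...] of length n_steps + 1."""
    rule = _as_rule(rule)
    traj = [np.asarray(state, dtype=np.uint8).copy()]
    for _ in range(n_steps):
        traj.append(step(traj[-1], rule))
    return traj


def flatten(image: PresenceImage) -> np.ndarray:
    """Reshape a 2-D presence image to the 1-D ECA state, row-major."""
    return np.ascontiguousarray(image.grid, dtype=np.uint8).reshape(-1)


def unflatten(state: np.ndarray, gridspec: GridSpec) -> PresenceImage:
    """Reshape a 1-D ECA state back to a presence image on ``gridspec``."""
    s = np.asarray(state, dtype=np.uint8)
    expected = gridspec.ny * gridspec.nx
    if s.size != expected:
        raise ValueError(
            f"state has {s.size} cells but gridspec is "
            f"{gridspec.ny}x{gridspec.nx} = {expected}"
        )
    return PresenceImage(grid=s.reshape(gridspec.ny, gridspec.nx), gridspec=gridspec)


def random_state(
    n_cells: int, n_ones: int, rng: np.random.Generator
) -> np.ndarray:
    """A length-``n_cells`` binary state with exactly ``n_ones`` cells set,
    positions drawn uniformly without replacement."""
    if not 0 <= n_ones <= n_cells:
        raise ValueError(f"n_ones must be in [0, {n_cells}], got {n_ones}")
    state = np.zeros(n_cells, dtype=np.uint8)
    idx = rng.choice(n_cells, size=n_ones, replace=False)
    state[idx] = 1
    return state


@dataclass(frozen=True)
class SimConfig:
    """Monte-Carlo protocol for per-rule presence-count simulation.

    Defaults are the study protocol: 100 of 400 cells seeded at random,
    evolved for 400 generations, averaged over 10 repetitions.
    """

    n_cells: int = 400
    n_initial_ones: int = 100
    generations: int = 400
    repetitions: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_initial_ones <= self.n_cells:
            raise ValueError(
                f"n_initial_ones must be in [0, {self.n_cells}], "
                f"got {self.n_initial_ones}"
            )
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass(frozen=True)
class PerRuleIntensity:
    """Per-rule spreading summary.

    ``mean_presence`` is the expected count of occupied cells averaged over
    generations 1..G; ``intensity`` divides it by the initial count (so the
    identity rule 204 scores exactly 1); ``convergent_mean`` averages the
    final quarter of generations, i.e. the plateau.
    """

    rule: int
    mean_presence: float
    intensity: float
    convergent_mean: float


def simulate_presence_counts(
    rule: int | ECARule, config: SimConfig = SimConfig()
) -> np.ndarray:
    """Expected presence count per generation under one even rule.

    Entry ``g`` (0-based) is the count of 1s after ``g + 1`` updates,
    averaged over ``config.repetitions`` independent random initialisations.
    Each repetition uses its own RNG substream spawned from ``config.seed``,
    so the result is reproducible bit-for-bit.
    """
    rule = _require_even(_as_rule(rule))
    children = np.random.SeedSequence(config.seed).spawn(config.repetitions)
    states = np.empty((config.repetitions, config.n_cells), dtype=np.uint8)
    for i, child in enumerate(children):
        states[i] = random_state(
            config.n_cells, config.n_initial_ones, np.random.default_rng(child)
        )
    counts = np.empty((config.generations, config.repetitions))
    for g in range(config.generations):
        states = step_batch(states, rule)
        counts[g] = states.sum(axis=1)
    return counts.mean(axis=1)


def per_rule_intensity(
    rule: int | ECARule, config: SimConfig = SimConfig()
) -> PerRuleIntensity:
    """Summarise one rule's simulated spreading into a PerRuleIntensity."""
    rule = _require_even(_as_rule(rule))
    counts = simulate_presence_counts(rule, config)
    mean_presence = float(counts.mean())
    tail = max(1, config.generations // 4)
    return PerRuleIntensity(
        rule=rule.number,
        mean_presence=mean_presence,
        intensity=mean_presence / config.n_initial_ones,
        convergent_mean=float(counts[-tail:].mean()),
    )


def all_rule_intensities(
    config: SimConfig = SimConfig(),
) -> dict[int, PerRuleIntensity]:
    """Per-rule intensities for all 128 even rules, keyed by rule number.

    Every rule shares the same protocol and seed, so each rule sees the same
    ensemble of initial conditions.
    """
    return {r.number: per_rule_intensity(r, config) for r in even_rules()}


def _observed_transitions(
    before: np.ndarray, after: np.ndarray
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Per-neighbourhood evidence from one observed transition.

    Returns (present mask over the 8 neighbourhoods, required output bit per
    present neighbourhood, consistent flag).  ``consistent`` is False when the
    same neighbourhood is observed mapping to both 0 and 1, in which case no
    rule whatsoever can explain the pair.
    """
    left = np.concatenate(([0], before[:-1]))
    right = np.concatenate((before[1:], [0]))
    idx = 4 * left + 2 * before + right
    ones = np.bincount(idx, weights=after, minlength=8)
    total = np.bincount(idx, minlength=8)
    present = total > 0
    consistent = bool(np.all((ones == 0) | (ones == total)))
    required = (ones > 0).astype(np.uint8)
    return present, required, consistent


def consistent_rules(
    pair: tuple[PresenceImage | np.ndarray, PresenceImage | np.ndarray],
) -> set[int]:
    """Exact decoder: the even rules that map the first image to the second.

    For each of the 8 neighbourhoods that actually occurs in the first state,
    the second state pins down the rule's output bit; a rule is consistent
    iff it matches every observed bit.  The set may be empty (real occurrence
    data need not follow any rule) and is the full 128 for the all-zero pair.
    """
    first, second = pair
    a = flatten(first) if isinstance(first, PresenceImage) else np.asarray(
        first, dtype=np.uint8
    )
    b = flatten(second) if isinstance(second, PresenceImage) else np.asarray(
        second, dtype=np.uint8
    )
    if a.shape != b.shape:
        raise ValueError(f"pair shape mismatch: {a.shape} vs {b.shape}")
    present, required, consistent = _observed_transitions(a, b)
    if not consistent:
        return set()
    numbers = np.arange(0, N_RULES, 2)
    bits = (numbers[:, None] >> np.arange(8)) & 1  # (128, 8)
    ok = np.all((bits == required) | ~present, axis=1)
    return set(int(n) for n in numbers[ok])


def intensities_to_frame(intensities: dict[int, PerRuleIntensity]):
    """Tabulate a rule → PerRuleIntensity map as a pandas DataFrame."""
    import pandas as pd

    rows = [dataclasses.asdict(v) for _, v in sorted(intensities.items())]
    return pd.DataFrame(rows, columns=["rule", "mean_presence", "intensity", "convergent_mean"])
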