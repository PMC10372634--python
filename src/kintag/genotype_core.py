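"""Genotype space, population state, parameters, and the mechanical
lifecycle steps (free recombination, symmetric mutation, bookkeeping).

The model tracks an infinite haploid population over four loci:

* ``Resist``  -- a tag locus that also determines parasite susceptibility
  (``L_resist`` alleles),
* ``Neutral`` -- a tag locus with no role outside recognition
  (``L_neutral`` alleles),
* ``Choice``  -- two alleles selecting which tag locus is consulted when
  deciding whether a social partner "matches" (``USE_RESIST`` /
  ``USE_NEUTRAL``),
* ``Trait``   -- two alleles controlling conditional helping
  (``DEFECT`` / ``HELP``).

A population is a frequency vector over the ``L_resist * L_neutral * 4``
genotypes (a point on the simplex).  All deterministic dynamics operate on
this vector; the 4-D view ``freqs.reshape(space.shape)`` has axes ordered
(resist, neutral, choice, trait).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "AX_RESIST",
    "AX_NEUTRAL",
    "AX_CHOICE",
    "AX_TRAIT",
    "USE_RESIST",
    "USE_NEUTRAL",
    "DEFECT",
    "HELP",
    "ModelParams",
    "GenotypeSpace",
    "PopulationState",
    "ResistHistory",
    "InitSpec",
    "build_space",
    "initialize_population",
    "recombine_free",
    "recombine_free_bruteforce",
    "mutate",
    "allele_frequencies",
]

# Axis order of the 4-D genotype-frequency table.
AX_RESIST, AX_NEUTRAL, AX_CHOICE, AX_TRAIT = 0, 1, 2, 3

# Choice alleles.
USE_RESIST, USE_NEUTRAL = 0, 1
# Trait alleles.
DEFECT, HELP = 0, 1

#: entries more negative than this are treated as logic errors rather than
#: floating-point round-off (see ``_clean_simplex``).
NEGATIVE_TOL = 1e-15

SIMPLEX_TOL = 1e-9


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class ModelParams:
    """All lifecycle parameters plus run controls.

    Defaults follow the standard figure settings: viscosity 0.25, help
    benefit 0.3, help cost 0.1, ten tags per locus, Trait/Choice mutation
    rates 1e-3.
    """

    theta: float = 0.25      # population viscosity: P(encounter a clone)
    b: float = 0.3           # fecundity benefit received by a helped partner
    c: float = 0.1           # fecundity cost of helping
    d: float = 0.5           # parasite virulence (fecundity loss if infected)
    lag: int = 0             # parasite adaptation delay, in host generations
    alpha: float = 0.0       # reassociation probability after tag mismatch
    L_resist: int = 10
    L_neutral: int = 10
    L_max: int = 10          # genetic constraint: max tags per locus
    mu_trait: float = 1e-3
    mu_choice: float = 1e-3
    max_generations: int = 200_000
    fixed_point_tol: float = 1e-10
    cycle_window: int = 1000
    seed: int = 0            # used only for initial-state perturbations

    def __post_init__(self) -> None:
        for name in ("theta", "alpha", "d", "mu_trait", "mu_choice"):
            _check_prob(name, getattr(self, name))
        if self.b < 0 or self.c < 0:
            raise ValueError("b and c must be nonnegative")
        if not isinstance(self.lag, (int, np.integer)) or self.lag < 0:
            raise ValueError(f"lag must be a nonnegative integer, got {self.lag!r}")
        for name in ("L_resist", "L_neutral"):
            L = getattr(self, name)
            if not isinstance(L, (int, np.integer)) or L < 1:
                raise ValueError(f"{name} must be a positive integer, got {L!r}")
            if L > self.L_max:
                raise ValueError(f"{name}={L} exceeds the genetic constraint L_max={self.L_max}")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if self.fixed_point_tol <= 0:
            raise ValueError("fixed_point_tol must be positive")
        if self.cycle_window < 1:
            raise ValueError("cycle_window must be >= 1")

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GenotypeSpace:
    """Bijective index map between four-locus genotypes and 0..G-1."""

    L_resist: int
    L_neutral: int

    @property
    def shape(self) -> Tuple[int, int, int, int]:
        return (self.L_resist, self.L_neutral, 2, 2)

    @property
    def size(self) -> int:
        return self.L_resist * self.L_neutral * 4

    # G is the conventional symbol for the number of genotypes.
    G = size

    def encode(self, resist, neutral, choice, trait):
        """Map genotype 4-tuple(s) to linear index/indices."""
        return np.ravel_multi_index((resist, neutral, choice, trait), self.shape)

    def decode(self, index):
        """Map linear index/indices back to (resist, neutral, choice, trait)."""
        return np.unravel_index(index, self.shape)


def build_space(L_resist: int, L_neutral: int) -> GenotypeSpace:
    """Construct the genotype space for given tag-locus sizes."""
    for name, L in (("L_resist", L_resist), ("L_neutral", L_neutral)):
        if not isinstance(L, (int, np.integer)) or L < 1:
            raise ValueError(f"{name} must be a positive integer, got {L!r}")
    return GenotypeSpace(int(L_resist), int(L_neutral))


@dataclass
class PopulationState:
    """Genotype-frequency distribution at a given generation."""

    freqs: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float).reshape(-1)

    def validate(self) -> None:
        if abs(self.freqs.sum() - 1.0) > 1e-12:
            raise ValueError(f"frequencies sum to {self.freqs.sum()!r}, not 1")
        if np.any(self.freqs < 0):
            raise ValueError("negative genotype frequency")

    def table(self, space: GenotypeSpace) -> np.ndarray:
        """4-D view (resist, neutral, choice, trait) of the frequencies."""
        return self.freqs.reshape(space.shape)

    def copy(self) -> "PopulationState":
        return PopulationState(self.freqs.copy(), self.generation)


class ResistHistory:
    """Ring buffer of past Resist allele-frequency vectors, newest last.

    The buffer keeps at most ``lag + 1`` census vectors: the current one
    plus enough history to look ``lag`` generations back.  During warm-up
    (fewer than ``lag`` recorded generations) lookups fall back on the
    oldest stored vector, i.e. the initial state.
    """

    def __init__(self, initial: np.ndarray, lag: int):
        if not isinstance(lag, (int, np.integer)) or lag < 0:
            raise ValueError(f"lag must be a nonnegative integer, got {lag!r}")
        self.lag = int(lag)
        self.buffer: deque = deque(maxlen=self.lag + 1)
        self.append(initial)

    def append(self, vec: np.ndarray) -> None:
        vec = np.asarray(vec, dtype=float)
        if abs(vec.sum() - 1.0) > 1e-12:
            raise ValueError(f"Resist frequency vector sums to {vec.sum()!r}, not 1")
        self.buffer.append(vec)

    def copy(self) -> "ResistHistory":
        new = ResistHistory.__new__(ResistHistory)
        new.lag = self.lag
        new.buffer = deque(self.buffer, maxlen=self.lag + 1)
        return new

    def __len__(self) -> int:
        return len(self.buffer)

    def __getitem__(self, i):
        return self.buffer[i]


@dataclass(frozen=True)
class InitSpec:
    """Initial-frequency specification: a product measure over the four
    loci plus a seeded multiplicative perturbation of magnitude ``epsilon``.

    ``p0`` is the initial HELP frequency, ``q0`` the initial USE_RESIST
    frequency.  ``resist_freqs``/``neutral_freqs`` default to uniform.
    """

    p0: float = 0.5
    q0: float = 0.5
    resist_freqs: Optional[Sequence[float]] = None
    neutral_freqs: Optional[Sequence[float]] = None
    epsilon: float = 1e-3

    def __post_init__(self) -> None:
        _check_prob("p0", self.p0)
        _check_prob("q0", self.q0)
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")


def _tag_marginal(freqs: Optional[Sequence[float]], L: int, name: str) -> np.ndarray:
    if freqs is None:
        return np.full(L, 1.0 / L)
    vec = np.asarray(freqs, dtype=float)
    if vec.shape != (L,):
        raise ValueError(f"{name} must have length {L}, got shape {vec.shape}")
    if np.any(vec < 0) or abs(vec.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must be a probability vector")
    return vec / vec.sum()


def initialize_population(space: GenotypeSpace, init: InitSpec, seed: int) -> PopulationState:
    """Build the initial state: product measure over loci with a seeded
    multiplicative perturbation, renormalized onto the simplex.

    The perfectly symmetric product state is an (unstable) fixed point of
    the deterministic recursion; the perturbation breaks the symmetry so
    positive frequency dependence is visible.
    """
    xr = _tag_marginal(init.resist_freqs, space.L_resist, "resist_freqs")
    xn = _tag_marginal(init.neutral_freqs, space.L_neutral, "neutral_freqs")
    xc = np.array([init.q0, 1.0 - init.q0])
    xt = np.array([1.0 - init.p0, init.p0])
    f = np.einsum("i,j,k,l->ijkl", xr, xn, xc, xt)
    if init.epsilon > 0:
        positive = f[f > 0]
        if positive.size and init.epsilon >= positive.min():
            raise ValueError(
                f"perturbation epsilon={init.epsilon} is not small relative to the "
                f"smallest product frequency {positive.min():.3g}"
            )
        rng = np.random.default_rng(seed)
        f = f * (1.0 + rng.uniform(-init.epsilon, init.epsilon, size=f.shape))
        f /= f.sum()
    state = PopulationState(f.reshape(-1), generation=0)
    state.validate()
    return state


def _check_simplex(freqs: np.ndarray, tol: float = SIMPLEX_TOL) -> None:
    if abs(freqs.sum() - 1.0) > tol:
        raise ValueError(f"input off the simplex: sum={freqs.sum()!r}")
    if np.any(freqs < -tol):
        raise ValueError("input has negative frequencies")


def _clean_simplex(freqs: np.ndarray) -> np.ndarray:
    """Clip round-off negatives in (-1e-15, 0) to zero and renormalize.

    Anything below -1e-15 signals a logic bug and raises.
    """
    if np.any(freqs < -NEGATIVE_TOL):
        raise FloatingPointError(
            f"frequency {freqs.min()!r} below -{NEGATIVE_TOL}: not round-off noise"
        )
    out = np.where(freqs < 0, 0.0, freqs)
    return out / out.sum()


# The 16 inheritance masks of free recombination.  For mask m, the child
# takes the loci with bit 0 from parent 1 and the loci with bit 1 from
# parent 2; with random mating each mask carries weight 1/16 and the
# contribution factorizes into two joint marginals.
_MASKS: list = []
for _m in range(16):
    _from_p2 = tuple(ax for ax in range(4) if (_m >> ax) & 1)
    _from_p1 = tuple(ax for ax in range(4) if not (_m >> ax) & 1)
    _MASKS.append((_from_p1, _from_p2))


def recombine_free(freqs: np.ndarray, space: GenotypeSpace) -> np.ndarray:
    """One round of random mating with free recombination (r = 1/2
    between every pair of the four loci).

    Uses the 16-mask marginal decomposition, O(16 G) per call: the child
    distribution is the average over inheritance masks of the product of
    the two complementary joint marginals.  Single-locus allele
    frequencies are preserved exactly and every pairwise linkage
    disequilibrium is halved.
    """
    freqs = np.asarray(freqs, dtype=float).reshape(-1)
    _check_simplex(freqs)
    f = freqs.reshape(space.shape)
    out = np.zeros_like(f)
    for from_p1, from_p2 in _MASKS:
        if not from_p2:           # whole genome from parent 1
            out += f
        elif not from_p1:         # whole genome from parent 2
            out += f
        else:
            m1 = f.sum(axis=from_p2, keepdims=True)
            m2 = f.sum(axis=from_p1, keepdims=True)
            out += m1 * m2
    out /= 16.0
    return out.reshape(-1)


def recombine_free_bruteforce(freqs: np.ndarray, space: GenotypeSpace) -> np.ndarray:
    """Reference implementation: O(G^2 * 16) sum over ordered parent
    pairs and inheritance masks.  Retained as an independent oracle for
    :func:`recombine_free`; only practical for small spaces.
    """
    freqs = np.asarray(freqs, dtype=float).reshape(-1)
    _check_simplex(freqs)
    G = space.size
    coords = np.array(space.decode(np.arange(G)))  # (4, G)
    pair_w = np.outer(freqs, freqs)                # (G, G) parent1 x parent2
    out = np.zeros(G)
    for from_p1, from_p2 in _MASKS:
        child = [None] * 4
        for ax in range(4):
            if ax in from_p1:
                child[ax] = coords[ax][:, None] * np.ones(G, dtype=int)[None, :]
            else:
                child[ax] = np.ones(G, dtype=int)[:, None] * coords[ax][None, :]
        idx = np.ravel_multi_index(tuple(child), space.shape)
        np.add.at(out, idx.reshape(-1), pair_w.reshape(-1) / 16.0)
    return out


def mutate(freqs: np.ndarray, mu_trait: float, mu_choice: float,
           space: GenotypeSpace) -> np.ndarray:
    """Independent symmetric two-allele mutation at Trait then Choice.

    Each allele flips to the alternative with its locus rate; tag loci
    are untouched (the lifecycle names mutation only at Trait and Choice).
    """
    _check_prob("mu_trait", mu_trait)
    _check_prob("mu_choice", mu_choice)
    freqs = np.asarray(freqs, dtype=float).reshape(-1)
    _check_simplex(freqs)
    f = freqs.reshape(space.shape)
    f = (1.0 - mu_trait) * f + mu_trait * f[:, :, :, ::-1]
    f = (1.0 - mu_choice) * f + mu_choice * f[:, :, ::-1, :]
    return f.reshape(-1)


def allele_frequencies(freqs: np.ndarray, space: GenotypeSpace, axis: int) -> np.ndarray:
    """Single-locus marginal allele frequencies along the given axis."""
    f = np.asarray(freqs, dtype=float).reshape(space.shape)
    other = tuple(ax for ax in range(4) if ax != axis)
    return f.sum(axis=other)
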