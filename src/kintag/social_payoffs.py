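"""Social encounters, per-genotype social payoffs, and tag relatedness.

Each generation every individual searches the viscous population for a
partner.  An encounter is a clone with probability ``theta`` and a random
nonrelative otherwise.  The focal individual compares tags at its *own*
chosen recognition locus; on a mismatch it reassociates with probability
``alpha`` and retries.  The resulting per-generation match probability for
an individual whose chosen tag has population frequency ``X`` is

    P(X) = (theta + (1 - theta) X) / (1 - alpha (1 - X)(1 - theta)).

A matched focal carrying the HELP allele pays fecundity cost ``c`` and its
realized partner receives benefit ``b``.  Benefit allocation is
donor-centric: conditional on matching, the partner is the donor's clone
with probability theta / (theta + (1-theta) X) and otherwise a uniform
draw among carriers of the donor's chosen tag.  This bookkeeping balances
the help budget exactly: population-mean benefit received equals
(b/c) times population-mean cost paid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np

from .genotype_core import (
    DEFECT,
    HELP,
    USE_NEUTRAL,
    USE_RESIST,
    GenotypeSpace,
    ModelParams,
    PopulationState,
    _check_prob,
)

__all__ = [
    "SocialSummary",
    "p_interact",
    "social_payoff_vector",
    "relatedness_rtag",
    "hamilton_check",
]

ArrayLike = Union[float, np.ndarray]


def p_interact(X: ArrayLike, theta: float, alpha: float) -> ArrayLike:
    """Generational probability of finding a tag-matched partner.

    Equals ``theta + (1 - theta) X`` when ``alpha = 0`` (single
    encounter), and 1 when ``alpha = 1`` provided ``X > 0`` or
    ``theta > 0`` (unlimited reassociation guarantees an eventual match).
    """
    _check_prob("theta", theta)
    _check_prob("alpha", alpha)
    X = np.asarray(X, dtype=float)
    if np.any(X < 0) or np.any(X > 1):
        raise ValueError("tag frequency X must lie in [0, 1]")
    num = theta + (1.0 - theta) * X
    den = 1.0 - alpha * (1.0 - X) * (1.0 - theta)
    # den == 0 only at alpha=1, theta=0, X=0, where num == 0 too: an
    # individual whose tag nobody carries never matches.
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out if out.ndim else float(out)


@dataclass
class SocialSummary:
    """Per-genotype social bookkeeping (flat arrays of length G).

    ``B`` is expected benefit received in fecundity units (b times the
    expected number of help events received); ``C`` is expected cost paid
    (c times the match probability for helpers).  ``p_resist``/
    ``p_neutral`` are per-tag helper fractions (NaN for absent tags).
    """

    P: np.ndarray
    B: np.ndarray
    C: np.ndarray
    p_resist: np.ndarray
    p_neutral: np.ndarray
    p_bar: float


def social_payoff_vector(
    state: PopulationState, params: ModelParams, space: GenotypeSpace
) -> Tuple[np.ndarray, SocialSummary]:
    """Expected social fecundity payoff 1 - C_g + B_g for every genotype.

    The focal pays the cost whenever it perceives a match at its own
    chosen locus; it receives help whenever some donor's search lands on
    it, which depends on the focal's tags but not on the focal's Choice
    allele.
    """
    state.validate()
    f = state.table(space)
    theta, alpha, b, c = params.theta, params.alpha, params.b, params.c

    x_r = f.sum(axis=(1, 2, 3))
    x_n = f.sum(axis=(0, 2, 3))
    P_r = np.asarray(p_interact(x_r, theta, alpha))
    P_n = np.asarray(p_interact(x_n, theta, alpha))

    # Conditional clone share of a realized match: theta / (theta + (1-theta) X).
    def clone_share(x):
        den = theta + (1.0 - theta) * x
        return np.where(den > 0, theta / np.where(den > 0, den, 1.0), 1.0)

    cs_r, cs_n = clone_share(x_r), clone_share(x_n)

    shape = space.shape
    Xg = np.empty(shape)
    Pg = np.empty(shape)
    CSg = np.empty(shape)
    Xg[:, :, USE_RESIST, :] = x_r[:, None, None]
    Xg[:, :, USE_NEUTRAL, :] = x_n[None, :, None]
    Pg[:, :, USE_RESIST, :] = P_r[:, None, None]
    Pg[:, :, USE_NEUTRAL, :] = P_n[None, :, None]
    CSg[:, :, USE_RESIST, :] = cs_r[:, None, None]
    CSg[:, :, USE_NEUTRAL, :] = cs_n[None, :, None]

    h = np.array([0.0, 1.0])  # HELP indicator along the trait axis

    # Donor flux landing on nonrelative tag-sharers, per tag of each locus.
    # Donors choosing Resist spread (1 - clone share) of their donations
    # uniformly over the mass X of carriers of their Resist tag.
    helpmass_r = f[:, :, USE_RESIST, HELP].sum(axis=1)   # by resist tag
    helpmass_n = f[:, :, USE_NEUTRAL, HELP].sum(axis=0)  # by neutral tag
    with np.errstate(invalid="ignore", divide="ignore"):
        flux_r = np.where(x_r > 0, helpmass_r * P_r * (1.0 - cs_r) / np.where(x_r > 0, x_r, 1.0), 0.0)
        flux_n = np.where(x_n > 0, helpmass_n * P_n * (1.0 - cs_n) / np.where(x_n > 0, x_n, 1.0), 0.0)

    events_received = (
        h[None, None, None, :] * Pg * CSg          # from one's own clone donor
        + flux_r[:, None, None, None]              # from Resist-choosing donors
        + flux_n[None, :, None, None]              # from Neutral-choosing donors
    )
    B = b * events_received
    C = c * h[None, None, None, :] * Pg
    payoff = 1.0 - C + B
    if np.any(payoff < 0):
        raise ValueError(
            "negative social payoff: parameters outside the model's fecundity assumptions"
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        p_resist = np.where(x_r > 0, f[:, :, :, HELP].sum(axis=(1, 2)) / np.where(x_r > 0, x_r, 1.0), np.nan)
        p_neutral = np.where(x_n > 0, f[:, :, :, HELP].sum(axis=(0, 2)) / np.where(x_n > 0, x_n, 1.0), np.nan)
    p_bar = float(f[:, :, :, HELP].sum())

    summary = SocialSummary(
        P=Pg.reshape(-1),
        B=B.reshape(-1),
        C=C.reshape(-1),
        p_resist=p_resist,
        p_neutral=p_neutral,
        p_bar=p_bar,
    )
    return payoff.reshape(-1), summary


def relatedness_rtag(X: ArrayLike, p: ArrayLike, p_bar: float, theta: float) -> ArrayLike:
    """Relatedness between an actor and its tag-matched interactant:

        R_tag = [ (theta + (1-theta) X p) / (theta + (1-theta) X) - p_bar ]
                / (1 - p_bar)

    With ``p = p_bar`` it decreases monotonically in the tag frequency X,
    from 1 in the rare-tag limit down to ``theta`` at fixation.
    """
    _check_prob("theta", theta)
    X = np.asarray(X, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(X <= 0) or np.any(X > 1):
        raise ValueError("tag frequency X must lie in (0, 1]")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("tag helper fraction p must lie in [0, 1]")
    if not (0.0 <= p_bar < 1.0):
        raise ValueError("p_bar must lie in [0, 1); R_tag is undefined at p_bar = 1")
    partner_p = (theta + (1.0 - theta) * X * p) / (theta + (1.0 - theta) * X)
    out = (partner_p - p_bar) / (1.0 - p_bar)
    return out if out.ndim else float(out)


def hamilton_check(R: float, b: float, c: float) -> bool:
    """True iff conditional helping is favored: R * b > c (strict)."""
    if b < 0 or c < 0:
        raise ValueError("b and c must be nonnegative")
    return bool(R * b > c)
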