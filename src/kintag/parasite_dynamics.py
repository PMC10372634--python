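"""Lagged frequency-dependent parasite selection.

Parasites evolve to exploit the Resist allele that was most common
``lag`` host generations ago.  An individual carrying Resist allele i
suffers an expected fecundity loss of ``d * Z_i`` where ``Z`` is the
Resist allele-frequency vector recorded ``lag`` generations back
(``lag = 0`` means parasites track current frequencies perfectly).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .genotype_core import (
    AX_RESIST,
    GenotypeSpace,
    ModelParams,
    PopulationState,
    ResistHistory,
    allele_frequencies,
    build_space,
)

__all__ = [
    "lagged_frequencies",
    "parasite_payoff_vector",
    "susceptibility",
]


def lagged_frequencies(history: ResistHistory, lag: int) -> np.ndarray:
    """Resist allele frequencies recorded ``lag`` generations before the
    newest census.  During warm-up (history shorter than ``lag``) the
    oldest stored vector (the initial state) is returned.
    """
    if not isinstance(lag, (int, np.integer)) or lag < 0:
        raise ValueError(f"lag must be a nonnegative integer, got {lag!r}")
    if len(history) == 0:
        raise ValueError("history is empty")
    idx = len(history) - 1 - lag
    return history[max(idx, 0)]


def parasite_payoff_vector(
    state: PopulationState,
    history: ResistHistory,
    params: ModelParams,
    space: GenotypeSpace,
) -> np.ndarray:
    """Per-genotype fecundity multiplier 1 - d * Z[resist allele].

    With d = 0 the parasite stage is the identity on fitness.
    """
    Z = np.asarray(lagged_frequencies(history, params.lag), dtype=float)
    if Z.shape != (space.L_resist,):
        raise ValueError(
            f"history vectors have length {Z.shape}, expected ({space.L_resist},)"
        )
    mult = 1.0 - params.d * Z
    out = np.broadcast_to(mult[:, None, None, None], space.shape)
    return out.reshape(-1).copy()


def susceptibility(
    state: PopulationState,
    history: ResistHistory,
    lag: int,
    space: Optional[GenotypeSpace] = None,
) -> float:
    """Population-average generational infection probability,
    ``sum_i x_i(t) * Z_i`` with x the current Resist frequencies and Z
    the lagged ones.

    With lag = 0 this is the Simpson concentration ``sum_i x_i^2``,
    which the uniform tag distribution minimizes at 1/L_resist.  The
    statistic is invariant under relabeling of Resist alleles.
    """
    Z = np.asarray(lagged_frequencies(history, lag), dtype=float)
    if space is None:
        L_resist = Z.shape[0]
        G = state.freqs.size
        if G % (4 * L_resist):
            raise ValueError("state size incompatible with history vector length")
        space = build_space(L_resist, G // (4 * L_resist))
    x_r = allele_frequencies(state.freqs, space, AX_RESIST)
    return float(np.dot(x_r, Z))
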