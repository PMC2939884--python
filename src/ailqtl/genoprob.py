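"""Conditional genotype-class probabilities along the mapped region.

Haley-Knott regression needs, at every scan position, the probability of
each genotype class (AA, AB, BB) given the observed flanking markers. In an
intercross the two transmitted gametes are independent two-state Markov
chains along the chromosome, so the class probabilities at a position p
flanked by informative markers L and R follow from the standard two-locus
transition matrix with recombination fractions r(L,p) and r(p,R).

Recombination fractions are Haldane-transformed from cM distances (cM =
Mb x rate) after multiplying the distance by an AIL map-expansion factor.
The default expansion is t/2 for generation t -- the expected inflation of
the realized recombination fraction after t-2 additional generations of
intercrossing -- because the cohort's scan treats G10 data with F2
machinery on an expanded map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .formats import GeneticMap, GenotypeMatrix
from .synthdata import haldane_recombination_fraction

logger = logging.getLogger(__name__)

__all__ = ["GenoProbGrid", "conditional_probabilities", "ail_expansion"]


def ail_expansion(n_generations: int) -> float:
    """Standard AIL map-expansion multiplier, t/2 for generation t."""
    if n_generations < 2:
        raise ValueError("n_generations must be >= 2")
    return n_generations / 2.0


@dataclass(frozen=True)
class GenoProbGrid:
    """Individuals x positions x 3 genotype-class probabilities."""

    ids: tuple[str, ...]
    positions: np.ndarray  # Mb
    probs: np.ndarray  # (n, m, 3), rows sum to 1
    step: float  # 0 means markers-only grid
    markers: tuple[str, ...] | None = None  # names where positions are markers

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, float)
        object.__setattr__(self, "probs", p)
        object.__setattr__(
            self, "positions", np.asarray(self.positions, float)
        )
        if p.shape != (len(self.ids), self.positions.size, 3):
            raise ValueError("probability grid shape mismatch")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    def dosage(self) -> tuple[np.ndarray, np.ndarray]:
        """Additive and dominance regressors per individual and position.

        a = P(BB) - P(AA) in [-1, 1]; d = P(AB).
        """
        a = self.probs[:, :, 2] - self.probs[:, :, 0]
        d = self.probs[:, :, 1]
        return a, d

    def subset(self, rows: np.ndarray) -> "GenoProbGrid":
        """Row-select (or bootstrap-resample) individuals."""
        rows = np.asarray(rows)
        return GenoProbGrid(
            ids=tuple(np.asarray(self.ids, object)[rows]),
            positions=self.positions,
            probs=self.probs[rows],
            step=self.step,
            markers=self.markers,
        )


def _transition(r: np.ndarray) -> np.ndarray:
    """F2 genotype transition matrices, shape (..., 3, 3).

    Entry [g, h] is P(genotype h at the second locus | g at the first) for
    recombination fraction r; the two gametes recombine independently.
    """
    r = np.asarray(r, float)
    s = 1.0 - r
    T = np.empty(r.shape + (3, 3))
    T[..., 0, 0] = s * s
    T[..., 0, 1] = 2 * r * s
    T[..., 0, 2] = r * r
    T[..., 1, 0] = r * s
    T[..., 1, 1] = s * s + r * r
    T[..., 1, 2] = r * s
    T[..., 2, 0] = r * r
    T[..., 2, 1] = 2 * r * s
    T[..., 2, 2] = s * s
    return T


_PRIOR = np.array([0.25, 0.5, 0.25])


def conditional_probabilities(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    step: float = 0.0,
    expansion: float = 1.0,
    cm_per_mb: float = 1.0,
) -> GenoProbGrid:
    """Genotype-class probabilities at markers (and optional pseudo-positions).

    Parameters
    ----------
    step
        Pseudo-position spacing in Mb; 0 (default) evaluates at the marker
        positions only, matching marker-anchored LOD curves.
    expansion
        AIL map-expansion multiplier (>= 1) applied to inter-marker cM
        distances before the Haldane transform; use
        :func:`ail_expansion` for a generation-t cohort.

    Positions beyond the terminal informative markers condition on the
    single nearest marker; individuals with no informative marker at all
    receive the intercross prior (1/4, 1/2, 1/4) with a logged warning.
    """
    if step < 0:
        raise ValueError("step must be >= 0")
    if expansion < 1:
        raise ValueError("expansion must be >= 1")
    genotypes.require_map(gmap)

    G = genotypes.codes()  # (n, M), -1 = missing
    n, M = G.shape
    mpos = gmap.pos_mb

    if step > 0:
        grid = [mpos[0]]
        while grid[-1] + step < mpos[-1] - 1e-12:
            grid.append(grid[-1] + step)
        positions = np.unique(np.concatenate([np.asarray(grid), mpos]))
    else:
        positions = mpos.copy()
    marker_names = None
    if step == 0:
        marker_names = tuple(gmap.markers)

    all_missing = (G < 0).all(axis=1)
    if all_missing.any():
        logger.warning(
            "%d individual(s) with all markers missing: using the (1/4,1/2,1/4)"
            " prior", int(all_missing.sum())
        )

    informative = G >= 0
    probs = np.empty((n, positions.size, 3))
    idx = np.arange(n)

    for j, p in enumerate(positions):
        left_markers = np.nonzero(mpos <= p + 1e-12)[0]
        right_markers = np.nonzero(mpos >= p - 1e-12)[0]

        # nearest informative flank on each side, per individual
        if left_markers.size:
            lm = informative[:, left_markers]
            has_l = lm.any(axis=1)
            # last True column
            li = left_markers[
                lm.shape[1] - 1 - np.argmax(lm[:, ::-1], axis=1)
            ]
        else:
            has_l = np.zeros(n, bool)
            li = np.zeros(n, int)
        if right_markers.size:
            rm = informative[:, right_markers]
            has_r = rm.any(axis=1)
            ri = right_markers[np.argmax(rm, axis=1)]
        else:
            has_r = np.zeros(n, bool)
            ri = np.zeros(n, int)

        rL = haldane_recombination_fraction(
            (p - mpos[li]) * cm_per_mb * expansion
        )
        rR = haldane_recombination_fraction(
            (mpos[ri] - p) * cm_per_mb * expansion
        )
        TL = _transition(rL)  # (n, 3, 3)
        TR = _transition(rR)
        gL = np.where(has_l, G[idx, li], 0)
        gR = np.where(has_r, G[idx, ri], 0)

        w = np.ones((n, 3))
        w = np.where(has_l[:, None], TL[idx, gL, :], w)
        w = np.where(has_r[:, None], w * TR[idx, :, gR], w)
        neither = ~(has_l | has_r)
        w[neither] = _PRIOR
        probs[:, j, :] = w / w.sum(axis=1, keepdims=True)

    return GenoProbGrid(
        ids=tuple(genotypes.ids),
        positions=positions,
        probs=probs,
        step=step,
        markers=marker_names,
    )
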