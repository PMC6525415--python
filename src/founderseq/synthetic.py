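"""Synthetic recombinant panels with known ground truth.

Two generators:

* :func:`simulate_recombinants` — a planted-founder panel: ``d`` founder
  strings are drawn i.i.d. uniform over ``sigma`` symbols; each of ``m``
  rows is a mosaic of the founders with crossovers restricted to a shared
  grid of breakpoints spaced ``>= g`` columns apart (all rows switch at the
  same column positions, mirroring the segmentation model where crossovers
  align).  Optional point mutations replace a cell's symbol with a uniformly
  chosen different one.  With zero mutations and any segment length bound
  ``L <= g``, the minimum segmentation of the panel needs at most ``d``
  founders, which gives the ground truth the recovery tests rely on.
* :func:`random_matrix` — an unconstrained i.i.d. uniform panel for
  oracle-equivalence sweeps.

A single seeded :class:`numpy.random.Generator` drives all randomness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msa_io import RecombinantMatrix

__all__ = ["PlantedPanel", "simulate_recombinants", "random_matrix"]

# Characters used to decode integer panels; supports sigma up to 8, far more
# than the biological alphabets this emulates.
_SYMBOLS = "ACGTEFHI"


@dataclass
class PlantedPanel:
    """A recombinant panel plus the ground truth it was generated from."""

    matrix: RecombinantMatrix
    founders: list[str]
    founder_choices: list[list[int]]  # per row, founder index per grid segment
    true_breakpoints: list[list[int]]  # per row, 1-based start of each switch
    grid: list[int]  # 1-based first columns of grid segments (grid[0] == 1)
    mutation_rate: float
    seed: int | None

    @property
    def d(self) -> int:
        return len(self.founders)


def _grid_starts(n: int, g: int) -> list[int]:
    """Shared segment starts: every ``g`` columns, last segment >= g long."""
    starts = [1]
    pos = 1 + g
    while n - pos + 1 >= g:
        starts.append(pos)
        pos += g
    return starts


def simulate_recombinants(
    d: int,
    m: int,
    n: int,
    grid_spacing: int,
    mutation_rate: float = 0.0,
    sigma: int = 4,
    seed: int | None = None,
    jitter: int = 0,
) -> PlantedPanel:
    """Generate a planted-founder panel (see module docstring).

    Parameters
    ----------
    d, m, n
        Number of founders, rows, and columns.
    grid_spacing
        Minimum spacing ``g`` between shared breakpoints; every grid segment
        has length at least ``g``.
    mutation_rate
        Per-cell probability of replacing the symbol with a different one.
    jitter
        If positive, each row's breakpoints are independently shifted by up
        to ``jitter`` columns (stress-testing only; breaks the shared-grid
        guarantee the recovery bound relies on).
    """
    if d < 1 or m < 1 or n < 1:
        raise ValueError("d, m and n must be positive")
    if grid_spacing < 1 or grid_spacing > n:
        raise ValueError("grid_spacing must lie in [1, n]")
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must lie in [0, 1]")
    if sigma < 1 or sigma > len(_SYMBOLS):
        raise ValueError(f"sigma must lie in [1, {len(_SYMBOLS)}]")
    rng = np.random.default_rng(seed)
    founder_codes = rng.integers(0, sigma, size=(d, n))
    grid = _grid_starts(n, grid_spacing)
    codes = np.empty((m, n), dtype=np.int64)
    founder_choices: list[list[int]] = []
    true_breakpoints: list[list[int]] = []
    for i in range(m):
        choices = rng.integers(0, d, size=len(grid)).tolist()
        starts = list(grid)
        if jitter > 0:
            for t in range(1, len(starts)):
                lo = max(starts[t - 1] + 1, starts[t] - jitter)
                hi = min(n, starts[t] + jitter)
                starts[t] = int(rng.integers(lo, hi + 1))
            starts = sorted(set(starts))
        bps = []
        for t, start in enumerate(starts):
            end = starts[t + 1] - 1 if t + 1 < len(starts) else n
            codes[i, start - 1 : end] = founder_codes[choices[min(t, len(choices) - 1)], start - 1 : end]
            if t > 0 and choices[min(t, len(choices) - 1)] != choices[min(t - 1, len(choices) - 1)]:
                bps.append(start)
        founder_choices.append(choices)
        true_breakpoints.append(bps)
    if mutation_rate > 0:
        mask = rng.random(size=codes.shape) < mutation_rate
        if sigma > 1:
            shifts = rng.integers(1, sigma, size=codes.shape)
            codes = np.where(mask, (codes + shifts) % sigma, codes)
    alphabet = list(_SYMBOLS[:sigma])
    mat = RecombinantMatrix(
        codes=codes,
        alphabet=alphabet,
        names=[f"rec{i + 1}" for i in range(m)],
    )
    founders = ["".join(alphabet[c] for c in row) for row in founder_codes]
    return PlantedPanel(
        matrix=mat,
        founders=founders,
        founder_choices=founder_choices,
        true_breakpoints=true_breakpoints,
        grid=grid,
        mutation_rate=mutation_rate,
        seed=seed,
    )


def random_matrix(
    m: int, n: int, sigma: int = 4, seed: int | None = None
) -> RecombinantMatrix:
    """Unconstrained i.i.d. uniform panel over ``sigma`` symbols."""
    if m < 1 or n < 1:
        raise ValueError("m and n must be positive")
    if sigma < 1 or sigma > len(_SYMBOLS):
        raise ValueError(f"sigma must lie in [1, {len(_SYMBOLS)}]")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, sigma, size=(m, n))
    return RecombinantMatrix(
        codes=codes,
        alphabet=list(_SYMBOLS[:sigma]),
        names=[f"rec{i + 1}" for i in range(m)],
    )
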