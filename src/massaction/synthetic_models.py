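"""Randomized synthetic reaction-based models for testing and scaling.

The generator emulates the benchmark conditions used to exercise
large-scale mass-action simulators: M reactions over N species, each
reaction with one or two reactant molecules and one or two product
molecules (same or different species), no null reactions (a reaction
whose product row equals its reactant row), and every species covered
by at least one reaction.  Initial concentrations are drawn uniformly
in [0, 1) and kinetic constants log-uniformly in [1e-8, 1), i.e.
log10(k) ~ Uniform[-8, 0).  The time horizon defaults to t_max = 50
with sampling instants at regular intervals.

A single seeded pseudo-random generator governs the whole model, so
generation is bit-reproducible; the seed is recorded in the model
metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_io import ReactionModel

__all__ = ["GeneratorSpec", "GenerationError", "generate_random_model"]


class GenerationError(ValueError):
    """The requested model cannot be generated (infeasible spec)."""


@dataclass
class GeneratorSpec:
    """Parameters of the random-model generator.

    ``conc_low``/``conc_high`` bound the uniform initial-concentration
    draw; ``logk_low``/``logk_high`` are base-10 exponents bounding the
    log-uniform kinetic-constant draw.
    """

    n_reactions: int
    n_species: int
    seed: int = 0
    conc_low: float = 0.0
    conc_high: float = 1.0
    logk_low: float = -8.0
    logk_high: float = 0.0
    max_reactants: int = 2
    max_products: int = 2
    t_max: float = 50.0
    n_samples: int = 10

    def validated(self) -> "GeneratorSpec":
        if self.n_reactions < 1 or self.n_species < 1:
            raise GenerationError("M and N must be >= 1")
        if not (self.conc_low < self.conc_high):
            raise GenerationError("empty concentration range")
        if not (self.logk_low < self.logk_high):
            raise GenerationError("empty kinetic-constant range")
        if self.max_reactants != 2 or self.max_products != 2:
            raise GenerationError("only 1-2 reactants/products supported")
        if self.t_max <= 0 or self.n_samples < 2:
            raise GenerationError("need t_max > 0 and n_samples >= 2")
        return self


def generate_random_model(spec: GeneratorSpec) -> ReactionModel:
    """Draw a random reaction-based model satisfying every invariant.

    Reactions are built by sampling the reactant count r in {1, 2} and
    the product count p in {1, 2} uniformly, then species uniformly
    with replacement (so dimerizations 2A are possible); null
    reactions are resampled.  A post-pass re-wires products so that
    every species appears in at least one reaction; if the species
    cannot all be covered (e.g. far more species than reaction slots)
    a :class:`GenerationError` is raised.
    """
    spec = spec.validated()
    M, N = spec.n_reactions, spec.n_species
    if (spec.max_reactants + spec.max_products) * M < N:
        # each reaction mentions at most 4 species units
        raise GenerationError(f"{M} reactions cannot cover {N} species")
    rng = np.random.default_rng(spec.seed)

    A = np.zeros((M, N), dtype=np.int64)
    B = np.zeros((M, N), dtype=np.int64)
    for i in range(M):
        for _ in range(1000):
            a_row = np.zeros(N, dtype=np.int64)
            b_row = np.zeros(N, dtype=np.int64)
            for j in rng.integers(0, N, size=rng.integers(1, 3)):
                a_row[j] += 1
            for j in rng.integers(0, N, size=rng.integers(1, 3)):
                b_row[j] += 1
            if not np.array_equal(a_row, b_row):
                break
        else:  # pragma: no cover - requires a pathological spec
            raise GenerationError(f"could not draw a non-null reaction {i}")
        A[i] = a_row
        B[i] = b_row

    _cover_all_species(A, B, rng)

    X0 = spec.conc_low + (spec.conc_high - spec.conc_low) * rng.random(N)
    log10k = spec.logk_low + (spec.logk_high - spec.logk_low) * rng.random(M)
    K = 10.0 ** log10k
    times = np.linspace(0.0, spec.t_max, spec.n_samples)

    return ReactionModel(
        reactant_matrix=A,
        product_matrix=B,
        kinetic_constants=K,
        initial_state=X0,
        sampling_times=times,
        metadata={"generator_seed": spec.seed},
    )


def _cover_all_species(A: np.ndarray, B: np.ndarray, rng) -> None:
    """Make every species a product of some reaction if it is uncovered.

    Each uncovered species is added to the product side of a randomly
    chosen reaction: into a free product slot when one exists (a
    reaction with a single product unit), otherwise by displacing a
    product unit whose species keeps at least one other occurrence.
    Edits that would create a null reaction are discarded.
    """
    M, N = A.shape
    units = A.sum(axis=0) + B.sum(axis=0)  # occurrence units per species
    uncovered = [int(j) for j in np.nonzero(units == 0)[0]]
    attempts = 0
    max_attempts = 500 * max(len(uncovered), 1)
    while uncovered:
        if attempts > max_attempts:
            raise GenerationError(
                f"could not cover {len(uncovered)} species after "
                f"{attempts} re-wiring attempts"
            )
        attempts += 1
        s = uncovered[-1]
        i = int(rng.integers(0, M))
        if B[i].sum() < 2:  # free product slot
            B[i, s] += 1
            if np.array_equal(A[i], B[i]):
                B[i, s] -= 1
                continue
            units[s] += 1
            uncovered.pop()
            continue
        prods = np.nonzero(B[i])[0]
        d = int(rng.choice(prods))
        if units[d] < 2:
            continue
        B[i, d] -= 1
        B[i, s] += 1
        if np.array_equal(A[i], B[i]):
            B[i, d] += 1
            B[i, s] -= 1
            continue
        units[d] -= 1
        units[s] += 1
        uncovered.pop()
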