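"""Compressed sparse encoding of mass-action ODE systems.

Under mass-action kinetics the network

    R_i :  sum_j a_ij S_j  --k_i-->  sum_j b_ij S_j

induces the polynomial ODE system

    dX/dt = H (K o X^A),      H = (B - A)^T,

where ``o`` is the entry-by-entry product and ``X^A`` is the
vector-matrix exponentiation: component i of ``X^A`` is the monomial
``prod_j X_j^{a_ij}``.  Because at most two reactant molecules are
admitted per reaction, A and H are sparse; this module stores only
their non-zero entries:

* ``vh_entries`` -- one quadruple per non-zero ``h_ji``:
  ``(species j, monomial row, signed coefficient h_ji, kinetic index)``.
  The monomial row indexes ``oa_offsets``; under plain mass action it
  equals the reaction index, as does the kinetic index, but the two
  fields are kept distinct in the layout.
* ``oh_offsets`` -- per species, the ``(first, last)`` *inclusive* span
  of its rows in ``vh_entries`` (an empty span has ``last = first - 1``).
* ``va_entries`` -- one pair per non-zero ``a_ij``:
  ``(reactant species, exponent)`` with exponent in {1, 2}; a
  dimerization reactant 2A is a single entry with exponent 2.
* ``oa_offsets`` -- per monomial row, the ``(first, last)`` inclusive
  span of its reactant factors in ``va_entries``.

Entries are ordered deterministically: ``vh_entries`` species-major and
by ascending reaction within a species; ``va_entries`` by reaction and
ascending species.  ``compact_mode`` additionally enforces that every
stored index fits in 16 bits (limit 65,536), the capacity of the
short-integer storage layout this encoding mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_io import ReactionModel

__all__ = [
    "CompressedODESystem",
    "CapacityError",
    "INDEX_LIMIT",
    "build_encoding",
    "evaluate_derivatives",
    "evaluate_jacobian",
    "encoding_table",
]

#: largest index representable with 16-bit storage
INDEX_LIMIT = 65536


class CapacityError(ValueError):
    """System too large for the 16-bit compact index layout."""


@dataclass
class CompressedODESystem:
    """Sparse monomial encoding of a mass-action ODE system."""

    n_species: int
    n_reactions: int
    vh_species: np.ndarray  #: (L_H,) species index j of each quadruple
    vh_row: np.ndarray  #: (L_H,) monomial row (into oa_offsets)
    vh_coeff: np.ndarray  #: (L_H,) signed coefficient h_ji (float)
    vh_kidx: np.ndarray  #: (L_H,) kinetic-constant index
    oh_first: np.ndarray  #: (N,) span start into vh_entries
    oh_last: np.ndarray  #: (N,) span end, inclusive; empty: first - 1
    va_species: np.ndarray  #: (L_A,) reactant species index
    va_exp: np.ndarray  #: (L_A,) exponent a_ij in {1, 2}
    oa_first: np.ndarray  #: (M,) span start into va_entries
    oa_last: np.ndarray  #: (M,) span end, inclusive
    constants: np.ndarray  #: (M,) copy of K (frozen at build time)
    compact_mode: bool = False

    # evaluation caches, derived from the fields above
    _vh_scale: np.ndarray = field(default=None, repr=False)  # h_ji * k
    _sq_index: np.ndarray = field(default=None, repr=False)  # va rows with exp 2
    _mono_reduce_idx: np.ndarray = field(default=None, repr=False)
    _empty_mono: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self._vh_scale = self.vh_coeff * self.constants[self.vh_kidx]
        self._sq_index = np.nonzero(self.va_exp == 2)[0]
        # guard against empty reactant spans (zero-order reactions in
        # permissive mode): reduceat cannot express empty segments
        empty = self.oa_last < self.oa_first
        self._empty_mono = np.nonzero(empty)[0]
        idx = self.oa_first.astype(np.intp)
        if self._empty_mono.size:
            idx = np.minimum(idx, max(len(self.va_species) - 1, 0))
        self._mono_reduce_idx = idx

    # -- spec-shaped tuple views ------------------------------------------

    @property
    def vh_entries(self) -> list[tuple[int, int, float, int]]:
        return list(
            zip(
                self.vh_species.tolist(),
                self.vh_row.tolist(),
                self.vh_coeff.tolist(),
                self.vh_kidx.tolist(),
            )
        )

    @property
    def oh_offsets(self) -> list[tuple[int, int]]:
        return list(zip(self.oh_first.tolist(), self.oh_last.tolist()))

    @property
    def va_entries(self) -> list[tuple[int, int]]:
        return list(zip(self.va_species.tolist(), self.va_exp.tolist()))

    @property
    def oa_offsets(self) -> list[tuple[int, int]]:
        return list(zip(self.oa_first.tolist(), self.oa_last.tolist()))

    def dense_h(self) -> np.ndarray:
        """Rebuild the dense N x M matrix H = (B - A)^T from the entries."""
        H = np.zeros((self.n_species, self.n_reactions))
        H[self.vh_species, self.vh_kidx] += self.vh_coeff
        return H


def build_encoding(
    model: ReactionModel, compact_mode: bool = False
) -> CompressedODESystem:
    """Compress the stoichiometry of ``model`` into monomial structures.

    For each species j, the resulting span in ``oh_offsets`` enumerates
    exactly the monomials of its ODE — one per reaction with
    ``h_ji != 0`` — each carrying the monomial's signed coefficient,
    its reactant factors and its kinetic constant.  With
    ``compact_mode`` the 16-bit index capacity (65,536) is enforced and
    exceeding it raises :class:`CapacityError`.
    """
    A = np.asarray(model.reactant_matrix)
    B = np.asarray(model.product_matrix)
    M, N = A.shape
    H = (B - A).T  # N x M

    # V_H: species-major, ascending reaction index within each species
    hj, hi = np.nonzero(H)
    vh_species = hj.astype(np.int64)
    vh_row = hi.astype(np.int64)  # monomial row == reaction index
    vh_coeff = H[hj, hi].astype(float)
    vh_kidx = hi.astype(np.int64)
    counts_h = np.bincount(vh_species, minlength=N)
    oh_last = np.cumsum(counts_h) - 1
    oh_first = oh_last - counts_h + 1

    # V_A: reaction-major, ascending species index within each reaction
    ai, aj = np.nonzero(A)
    va_species = aj.astype(np.int64)
    va_exp = A[ai, aj].astype(np.int64)
    counts_a = np.bincount(ai, minlength=M)
    oa_last = np.cumsum(counts_a) - 1
    oa_first = oa_last - counts_a + 1

    if compact_mode:
        for what, size in (
            ("species", N),
            ("reactions", M),
            ("V_H entries", len(vh_species)),
            ("V_A entries", len(va_species)),
        ):
            if size > INDEX_LIMIT:
                raise CapacityError(
                    f"compact 16-bit indices support at most {INDEX_LIMIT} "
                    f"{what}; got {size}"
                )

    return CompressedODESystem(
        n_species=N,
        n_reactions=M,
        vh_species=vh_species,
        vh_row=vh_row,
        vh_coeff=vh_coeff,
        vh_kidx=vh_kidx,
        oh_first=oh_first,
        oh_last=oh_last,
        va_species=va_species,
        va_exp=va_exp,
        oa_first=oa_first,
        oa_last=oa_last,
        constants=np.asarray(model.kinetic_constants, dtype=float).copy(),
        compact_mode=compact_mode,
    )


def _monomials(system: CompressedODESystem, X: np.ndarray) -> np.ndarray:
    """Reactant products prod_j X_j^{a_ij}, one per monomial row (no k)."""
    factors = X[system.va_species]
    sq = system._sq_index
    if sq.size:
        factors[sq] *= factors[sq]  # exponent-2 factors; fancy copy is safe
    if not factors.size:
        return np.ones(system.n_reactions)
    mono = np.multiply.reduceat(factors, system._mono_reduce_idx)
    if system._empty_mono.size:
        mono[system._empty_mono] = 1.0
    return mono


def evaluate_derivatives(system: CompressedODESystem, X) -> np.ndarray:
    """Right-hand side f(X) of the encoded ODE system.

    ``f_j = sum over the monomials of species j of
    h_ji * k_i * prod_r X_r^{a_ir}``.
    """
    X = np.asarray(X, dtype=float)
    if X.shape != (system.n_species,):
        raise ValueError(
            f"state length {X.shape} does not match N = {system.n_species}"
        )
    mono = _monomials(system, X)
    contrib = system._vh_scale * mono[system.vh_row]
    return np.bincount(
        system.vh_species, weights=contrib, minlength=system.n_species
    )


def evaluate_jacobian(system: CompressedODESystem, X) -> np.ndarray:
    """Exact Jacobian J[j, r] = d f_j / d X_r.

    Each monomial is differentiated symbolically: an exponent-1 factor
    is dropped, an exponent-2 factor X_r^2 contributes 2 X_r.  No
    numerical differencing is involved.
    """
    X = np.asarray(X, dtype=float)
    if X.shape != (system.n_species,):
        raise ValueError(
            f"state length {X.shape} does not match N = {system.n_species}"
        )
    N, M = system.n_species, system.n_reactions
    # per-monomial gradients: list of (species r, d mono / d X_r)
    grads: list[list[tuple[int, float]]] = []
    for i in range(M):
        s0, s1 = int(system.oa_first[i]), int(system.oa_last[i])
        if s1 < s0:
            grads.append([])
        elif s1 == s0:
            r = int(system.va_species[s0])
            if system.va_exp[s0] == 1:
                grads.append([(r, 1.0)])
            else:  # X_r^2
                grads.append([(r, 2.0 * X[r])])
        else:  # two distinct exponent-1 factors
            r1 = int(system.va_species[s0])
            r2 = int(system.va_species[s1])
            grads.append([(r1, X[r2]), (r2, X[r1])])

    J = np.zeros((N, N))
    for j, i, scale in zip(
        system.vh_species.tolist(),
        system.vh_row.tolist(),
        system._vh_scale.tolist(),
    ):
        for r, g in grads[i]:
            J[j, r] += scale * g
    return J


def encoding_table(system: CompressedODESystem) -> str:
    """Human-readable dump of the compressed structures (debugging aid)."""
    lines = ["# V_H (species, monomial row, coefficient, kinetic index)"]
    for row in system.vh_entries:
        lines.append("  ".join(str(x) for x in row))
    lines.append("# O_H (first, last)")
    for row in system.oh_offsets:
        lines.append("  ".join(str(x) for x in row))
    lines.append("# V_A (species, exponent)")
    for row in system.va_entries:
        lines.append("  ".join(str(x) for x in row))
    lines.append("# O_A (first, last)")
    for row in system.oa_offsets:
        lines.append("  ".join(str(x) for x in row))
    lines.append("# K")
    lines.extend(repr(k) for k in system.constants.tolist())
    return "\n".join(lines) + "\n"
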