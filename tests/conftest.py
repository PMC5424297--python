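import numpy as np
import pytest

from massaction import GeneratorSpec, ReactionModel, generate_random_model


@pytest.fixture
def worked_model() -> ReactionModel:
    """Two-reaction association/dissociation model X1 + X2 <-> X3.

    R1: X1 + X2 -(k1)-> X3 and R2: X3 -(k2)-> X1 + X2 with k = (2, 3),
    X0 = (1, 0.5, 2); the ODE of X1 is -k1*X1*X2 + k2*X3.
    """
    return ReactionModel(
        reactant_matrix=[[1, 1, 0], [0, 0, 1]],
        product_matrix=[[0, 0, 1], [1, 1, 0]],
        kinetic_constants=[2.0, 3.0],
        initial_state=[1.0, 0.5, 2.0],
        sampling_times=[0.0, 50.0],
    )


@pytest.fixture
def reversible_pair() -> ReactionModel:
    """Closed isomerization A <-> B with k1 = k2 = 1, X0 = (1, 0)."""
    return ReactionModel(
        reactant_matrix=[[1, 0], [0, 1]],
        product_matrix=[[0, 1], [1, 0]],
        kinetic_constants=[1.0, 1.0],
        initial_state=[1.0, 0.0],
        sampling_times=np.linspace(0.0, 50.0, 11),
    )


@pytest.fixture
def random_model_factory():
    """Seeded random models of a given size (the benchmark conditions)."""

    def make(seed: int, m: int = 16, n: int = 16, **kwargs) -> ReactionModel:
        return generate_random_model(
            GeneratorSpec(n_reactions=m, n_species=n, seed=seed, **kwargs)
        )

    return make


def dense_rhs(model: ReactionModel):
    """Independent dense evaluation of dX/dt = (B - A)^T [K o X^A].

    Brute-force route: explicit matrices, entry-by-entry product and
    vector-matrix exponentiation, used as the oracle for the compressed
    encoding.
    """
    A = np.asarray(model.reactant_matrix, dtype=float)
    H = (np.asarray(model.product_matrix, dtype=float) - A).T
    K = np.asarray(model.kinetic_constants, dtype=float)

    def f(X: np.ndarray) -> np.ndarray:
        xa = np.prod(np.asarray(X, dtype=float)[np.newaxis, :] ** A, axis=1)
        return H @ (K * xa)

    return f


def central_difference_jacobian(f, X: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of a vector field f at X."""
    X = np.asarray(X, dtype=float)
    n = X.size
    J = np.empty((n, n))
    for r in range(n):
        xp = X.copy()
        xm = X.copy()
        xp[r] += h
        xm[r] -= h
        J[:, r] = (f(xp) - f(xm)) / (2.0 * h)
    return J
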