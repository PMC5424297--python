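"""Plain-text input/output for reaction-based models.

A model is a directory of whitespace-separated text files mirroring the
stoichiometric-matrix form of a mass-action reaction system

    R_i :  sum_j a_ij S_j  --k_i-->  sum_j b_ij S_j ,   i = 1..M

with M reactions over N species:

``left_side``
    the M x N reactant stoichiometry matrix A (``a_ij``), one reaction
    per row, species in column order;
``right_side``
    the M x N product stoichiometry matrix B (``b_ij``);
``c_vector``
    the M kinetic constants, one per line;
``M_0``
    the N initial concentrations (single row, or one per line);
``t_vector``
    the sampling time instants, strictly increasing, the last one being
    the simulation horizon t_max;
``cs_vector`` (optional)
    0-based indices of the species whose trajectory should be recorded;
``species_names`` (optional)
    one label per species.

Lines starting with ``#`` are comments and blank lines are ignored in
every file.  Indices are 0-based everywhere; the species order is the
column order of ``left_side``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ReactionModel",
    "Violation",
    "ModelIOError",
    "parse_model",
    "validate_model",
    "write_model",
    "write_timeseries",
    "read_timeseries",
    "REQUIRED_FILES",
]

REQUIRED_FILES = ("left_side", "right_side", "c_vector", "M_0", "t_vector")

#: float format preserving full double precision across a write/read cycle
_FLOAT_FMT = "%.17g"


class ModelIOError(ValueError):
    """Raised for unreadable, malformed or invalid model files."""


@dataclass
class ReactionModel:
    """A mass-action reaction network with its simulation inputs.

    Only first- and second-order reactions are admitted: every row of
    the reactant matrix must sum to 1 or 2 (at most two reactant
    molecules, of the same or of different species).
    """

    reactant_matrix: np.ndarray  #: (M, N) non-negative integers a_ij
    product_matrix: np.ndarray  #: (M, N) non-negative integers b_ij
    kinetic_constants: np.ndarray  #: (M,) positive reals k_i
    initial_state: np.ndarray  #: (N,) non-negative concentrations
    sampling_times: np.ndarray  #: strictly increasing, last = t_max
    species_names: list[str] | None = None
    recorded_species: np.ndarray | None = None  #: optional cs_vector hint
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.reactant_matrix = np.atleast_2d(np.asarray(self.reactant_matrix))
        self.product_matrix = np.atleast_2d(np.asarray(self.product_matrix))
        self.kinetic_constants = np.asarray(self.kinetic_constants, dtype=float)
        self.initial_state = np.asarray(self.initial_state, dtype=float)
        self.sampling_times = np.asarray(self.sampling_times, dtype=float)
        if self.recorded_species is not None:
            self.recorded_species = np.asarray(self.recorded_species, dtype=int)

    @property
    def n_reactions(self) -> int:
        return self.reactant_matrix.shape[0]

    @property
    def n_species(self) -> int:
        return self.reactant_matrix.shape[1]

    @property
    def t_max(self) -> float:
        return float(self.sampling_times[-1])

    def species_labels(self) -> list[str]:
        if self.species_names is not None:
            return list(self.species_names)
        return [f"S{j}" for j in range(self.n_species)]


@dataclass(frozen=True)
class Violation:
    """One validation failure; violations are data, not exceptions."""

    rule: str
    reaction: int | None = None
    species: int | None = None
    detail: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = []
        if self.reaction is not None:
            where.append(f"reaction {self.reaction}")
        if self.species is not None:
            where.append(f"species {self.species}")
        loc = f" ({', '.join(where)})" if where else ""
        msg = f"{self.rule}{loc}"
        return f"{msg}: {self.detail}" if self.detail else msg


def validate_model(
    model: ReactionModel, allow_zero_order: bool = False
) -> list[Violation]:
    """Check every structural invariant of a reaction-based model.

    Returns an empty list iff the model is valid.  ``allow_zero_order``
    relaxes the first/second-order restriction so that source reactions
    (empty left-hand side) are admitted.
    """
    v: list[Violation] = []
    A, B = model.reactant_matrix, model.product_matrix
    if A.ndim != 2 or A.shape[0] < 1 or A.shape[1] < 1:
        v.append(Violation("empty stoichiometry", detail=f"A has shape {A.shape}"))
        return v
    M, N = A.shape
    if B.shape != (M, N):
        v.append(
            Violation(
                "shape mismatch", detail=f"left_side {A.shape} vs right_side {B.shape}"
            )
        )
        return v
    if model.kinetic_constants.shape != (M,):
        v.append(
            Violation(
                "shape mismatch",
                detail=f"{model.kinetic_constants.size} kinetic constants for "
                f"{M} reactions",
            )
        )
    if model.initial_state.shape != (N,):
        v.append(
            Violation(
                "shape mismatch",
                detail=f"{model.initial_state.size} initial concentrations for "
                f"{N} species",
            )
        )
    for name, mat in (("left_side", A), ("right_side", B)):
        if not np.issubdtype(mat.dtype, np.integer):
            v.append(
                Violation(
                    "non-integer stoichiometry", detail=f"{name} is {mat.dtype}"
                )
            )
        elif np.any(mat < 0):
            i, j = np.argwhere(mat < 0)[0]
            v.append(
                Violation(
                    "negative stoichiometric coefficient",
                    reaction=int(i),
                    species=int(j),
                    detail=name,
                )
            )
    if np.issubdtype(A.dtype, np.integer):
        order = A.sum(axis=1)
        low = 0 if allow_zero_order else 1
        for i in np.nonzero(order > 2)[0]:
            v.append(
                Violation(
                    "reaction order > 2",
                    reaction=int(i),
                    detail=f"{int(order[i])} reactant molecules",
                )
            )
        for i in np.nonzero(order < low)[0]:
            v.append(Violation("zero-order reaction", reaction=int(i)))
    if model.kinetic_constants.shape == (M,):
        for i in np.nonzero(~(model.kinetic_constants > 0))[0]:
            v.append(
                Violation(
                    "non-positive kinetic constant",
                    reaction=int(i),
                    detail=f"k = {model.kinetic_constants[i]!r}",
                )
            )
    if model.initial_state.shape == (N,):
        for j in np.nonzero(~(model.initial_state >= 0))[0]:
            v.append(
                Violation(
                    "negative initial concentration",
                    species=int(j),
                    detail=f"X0 = {model.initial_state[j]!r}",
                )
            )
    t = model.sampling_times
    if t.ndim != 1 or t.size < 1:
        v.append(Violation("empty sampling times"))
    else:
        if not np.all(np.isfinite(t)) or t[0] < 0:
            v.append(Violation("invalid sampling times", detail=repr(t)))
        if np.any(np.diff(t) <= 0):
            v.append(Violation("sampling times not strictly increasing"))
    if model.species_names is not None and len(model.species_names) != N:
        v.append(
            Violation(
                "shape mismatch",
                detail=f"{len(model.species_names)} species names for {N} species",
            )
        )
    if model.recorded_species is not None and model.recorded_species.size:
        r = model.recorded_species
        if r.min() < 0 or r.max() >= N:
            v.append(Violation("recorded species index out of range"))
    return v


# ---------------------------------------------------------------------------
# reading


def _data_lines(path: Path) -> list[str]:
    lines = []
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            lines.append(line)
    return lines


def _parse_tokens(tokens: Sequence[str], path: Path, dtype) -> np.ndarray:
    try:
        return np.array([dtype(tok) for tok in tokens], dtype=dtype)
    except ValueError as exc:
        raise ModelIOError(f"non-numeric token in {path.name}: {exc}") from None


def _read_matrix(path: Path, dtype=int) -> np.ndarray:
    rows = []
    width = None
    for line in _data_lines(path):
        row = _parse_tokens(line.split(), path, dtype)
        if width is None:
            width = row.size
        elif row.size != width:
            raise ModelIOError(
                f"ragged rows in {path.name}: expected {width} columns, "
                f"got {row.size}"
            )
        rows.append(row)
    if not rows:
        raise ModelIOError(f"no reactions: {path.name} is empty")
    return np.vstack(rows)


def _read_vector(path: Path, dtype=float) -> np.ndarray:
    tokens: list[str] = []
    for line in _data_lines(path):
        tokens.extend(line.split())
    return _parse_tokens(tokens, path, dtype)


def parse_model(model_dir: str | Path, allow_zero_order: bool = False) -> ReactionModel:
    """Read a reaction-based model from its directory of text files.

    The numbers of reactions and species are inferred from
    ``left_side``.  Raises :class:`ModelIOError` on missing files,
    dimension mismatches, non-numeric tokens or invariant violations.
    """
    model_dir = Path(model_dir)
    if not model_dir.is_dir():
        raise ModelIOError(f"model directory not found: {model_dir}")
    for name in REQUIRED_FILES:
        if not (model_dir / name).is_file():
            raise ModelIOError(f"missing model file: {model_dir / name}")

    A = _read_matrix(model_dir / "left_side")
    B = _read_matrix(model_dir / "right_side")
    K = _read_vector(model_dir / "c_vector")
    X0 = _read_vector(model_dir / "M_0")
    times = _read_vector(model_dir / "t_vector")

    names = None
    names_path = model_dir / "species_names"
    if names_path.is_file():
        names = _data_lines(names_path)
    recorded = None
    cs_path = model_dir / "cs_vector"
    if cs_path.is_file():
        recorded = _read_vector(cs_path, dtype=int)

    model = ReactionModel(
        reactant_matrix=A,
        product_matrix=B,
        kinetic_constants=K,
        initial_state=X0,
        sampling_times=times,
        species_names=names,
        recorded_species=recorded,
    )
    violations = validate_model(model, allow_zero_order=allow_zero_order)
    if violations:
        raise ModelIOError(
            f"invalid model in {model_dir}: "
            + "; ".join(str(x) for x in violations)
        )
    return model


# ---------------------------------------------------------------------------
# writing


def write_model(model: ReactionModel, out_dir: str | Path) -> Path:
    """Write a model in the text dialect read by :func:`parse_model`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savetxt(out_dir / "left_side", model.reactant_matrix, fmt="%d")
    np.savetxt(out_dir / "right_side", model.product_matrix, fmt="%d")
    np.savetxt(out_dir / "c_vector", model.kinetic_constants, fmt=_FLOAT_FMT)
    np.savetxt(
        out_dir / "M_0", model.initial_state[np.newaxis, :], fmt=_FLOAT_FMT
    )
    np.savetxt(out_dir / "t_vector", model.sampling_times, fmt=_FLOAT_FMT)
    if model.species_names is not None:
        (out_dir / "species_names").write_text(
            "\n".join(model.species_names) + "\n"
        )
    if model.recorded_species is not None:
        np.savetxt(out_dir / "cs_vector", model.recorded_species, fmt="%d")
    if model.metadata:
        meta = "".join(f"# {k} = {v}\n" for k, v in sorted(model.metadata.items()))
        (out_dir / "metadata").write_text(meta)
    return out_dir


def write_timeseries(result, path: str | Path) -> Path:
    """Write a simulated time series as a TSV file.

    ``result`` is any object with ``times`` (T,), ``states`` (T, S) and
    ``species_labels`` attributes (normally a ``SimulationResult``).
    The header row is ``time`` followed by the species labels; values
    keep full double precision so that the file round-trips bit for bit.
    """
    times = np.asarray(result.times, dtype=float)
    states = np.atleast_2d(np.asarray(result.states, dtype=float))
    if times.size == 0:
        raise ValueError("cannot write an empty time series")
    if states.shape[0] != times.size:
        raise ValueError("times/states row mismatch")
    labels = list(result.species_labels)
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(["time"] + labels) + "\n")
        for t, row in zip(times, states):
            fields = [_FLOAT_FMT % t] + [_FLOAT_FMT % x for x in row]
            fh.write("\t".join(fields) + "\n")
    return path


def read_timeseries(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read a TSV time series back; returns (times, states, labels)."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "time":
            raise ModelIOError(f"{path}: not a time-series file")
        labels = header[1:]
        data = np.loadtxt(fh, ndmin=2)
    if data.shape[1] != len(labels) + 1:
        raise ModelIOError(f"{path}: column count does not match header")
    return data[:, 0], data[:, 1:], labels
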