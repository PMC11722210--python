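"""Mass-action reaction networks and deterministic evolution of cell populations.

A :class:`ReactionNetwork` holds an ordered species list and a set of
elementary reactions with mass-action kinetics.  Each reaction rate constant is
either fixed at construction or refers to one of three freely varying
parameters ``theta_1..theta_3``.  Conserved moieties (integer left-null
vectors of the stoichiometry matrix, e.g. total Syk across free and complexed
forms) are derived at construction and used as integration sanity checks.

Cell-to-cell variability enters only through initial conditions (extrinsic
noise): every cell follows the same deterministic ODE
``dx/dt = sum_r nu_r * k_r * prod_s x_s^{alpha_rs}`` independently of every
other cell, so a population is integrated as one large block-diagonal system.

The default network is a minimal six-species NK-cell signalling model
(Syk, Vav1, Syk:Vav1, pVav1, SHP1, SHP1:pVav1) with three free rates and
three rates fixed at 0.12, 0.14 and 0.05 1/s; alternative topologies can be
loaded from a YAML description via :func:`load_network`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from .errors import ConfigError, DataError, NumericalError

__all__ = [
    "Species",
    "RateRef",
    "Reaction",
    "ReactionNetwork",
    "RateVector",
    "CandidateModel",
    "build_minimal_nk_network",
    "default_candidates",
    "mass_action_rhs",
    "evolve_cells",
    "resolve_rates",
    "load_network",
    "DEFAULT_SPECIES",
    "FIXED_RATES",
]

#: Species order of the minimal NK-cell model; matches the column order of the
#: lognormal initial-condition parameters used throughout the package.
DEFAULT_SPECIES = ("Syk", "Vav1", "SykVav1", "pVav1", "SHP1", "SHP1pVav1")

#: The three fixed rate constants of the minimal model (1/s).
FIXED_RATES = (0.12, 0.14, 0.05)

#: Number of free rate parameters in the full model.
N_FREE_SLOTS = 3

# Negative integrator undershoot within this many absolute tolerances of zero
# is clipped to zero; anything more negative is treated as a failure.
_UNDERSHOOT_ATOL_FACTOR = 100.0


@dataclass(frozen=True)
class Species:
    """A chemical species: a unique name and its 0-based column index."""

    name: str
    index: int


@dataclass(frozen=True)
class RateRef:
    """Reference to a reaction's rate constant.

    Either ``fixed`` with a nonnegative ``value`` (units 1/s for unimolecular,
    1/(abundance*s) for bimolecular reactions), or ``free`` with a 1-based
    ``param_index`` into the free-parameter vector theta.
    """

    kind: str  # "fixed" | "free"
    value: float | None = None
    param_index: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "fixed":
            if self.value is None or not (self.value >= 0):
                raise DataError(f"fixed rate constant must be >= 0, got {self.value!r}")
        elif self.kind == "free":
            if self.param_index is None or not (1 <= self.param_index <= N_FREE_SLOTS):
                raise DataError(
                    f"free rate must reference a parameter index in 1..{N_FREE_SLOTS}, "
                    f"got {self.param_index!r}"
                )
        else:
            raise DataError(f"rate kind must be 'fixed' or 'free', got {self.kind!r}")

    @classmethod
    def fixed(cls, value: float) -> "RateRef":
        return cls(kind="fixed", value=float(value))

    @classmethod
    def free(cls, param_index: int) -> "RateRef":
        return cls(kind="free", param_index=int(param_index))


@dataclass(frozen=True)
class Reaction:
    """An elementary reaction with integer stoichiometry and one rate constant."""

    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate: RateRef

    def __post_init__(self) -> None:
        if not self.reactants and not self.products:
            raise DataError("a reaction needs at least one reactant or product")
        for side in (self.reactants, self.products):
            for name, coeff in side.items():
                if not (isinstance(coeff, (int, np.integer)) and coeff >= 1):
                    raise DataError(
                        f"stoichiometric coefficient for {name!r} must be a positive "
                        f"integer, got {coeff!r}"
                    )


@dataclass(frozen=True)
class RateVector:
    """The full rate triple (theta_1, theta_2, theta_3), all strictly positive."""

    theta: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.theta) != N_FREE_SLOTS:
            raise DataError(f"RateVector needs {N_FREE_SLOTS} entries, got {len(self.theta)}")
        if not all(np.isfinite(t) and t > 0 for t in self.theta):
            raise DataError(f"rate parameters must be finite and > 0, got {self.theta}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.theta, dtype=float)

    def __iter__(self):
        return iter(self.theta)

    def __getitem__(self, i: int) -> float:
        return self.theta[i]


def _as_rate_vector(rates: "RateVector | Sequence[float]") -> RateVector:
    if isinstance(rates, RateVector):
        return rates
    return RateVector(tuple(float(r) for r in rates))


class ReactionNetwork:
    """An ordered species list plus mass-action reactions.

    Stoichiometry matrices and an integer basis of conserved moieties are
    precomputed at construction.  The net stoichiometry matrix ``S`` has shape
    (n_species, n_reactions); a conserved moiety is an integer vector ``v``
    with ``v @ S == 0``.
    """

    def __init__(self, species_names: Sequence[str], reactions: Sequence[Reaction]):
        if len(set(species_names)) != len(species_names):
            raise DataError("species names must be unique")
        self.species: list[Species] = [Species(n, i) for i, n in enumerate(species_names)]
        self._index = {s.name: s.index for s in self.species}
        self.reactions: list[Reaction] = list(reactions)
        n, m = len(self.species), len(self.reactions)
        if m == 0:
            raise DataError("a network needs at least one reaction")

        reactant = np.zeros((m, n), dtype=np.int64)
        net = np.zeros((m, n), dtype=np.int64)
        for r, rx in enumerate(self.reactions):
            for name, coeff in rx.reactants.items():
                if name not in self._index:
                    raise DataError(f"reaction {r} references unknown species {name!r}")
                reactant[r, self._index[name]] += coeff
                net[r, self._index[name]] -= coeff
            for name, coeff in rx.products.items():
                if name not in self._index:
                    raise DataError(f"reaction {r} references unknown species {name!r}")
                net[r, self._index[name]] += coeff
        self._reactant_orders = reactant  # (m, n)
        self._net = net  # (m, n); S = net.T
        # flat index lists: species indices repeated per stoichiometric count,
        # one list per reaction, used for fast flux products
        self._reactant_lists: list[list[int]] = [
            [j for j in range(n) for _ in range(reactant[r, j])] for r in range(m)
        ]
        self.conserved_moieties: list[np.ndarray] = _integer_left_null_basis(net)

    # -- basic introspection ------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def stoichiometry(self) -> np.ndarray:
        """Net stoichiometry matrix S, shape (n_species, n_reactions)."""
        return self._net.T.copy()

    @property
    def free_param_indices(self) -> set[int]:
        return {
            rx.rate.param_index for rx in self.reactions if rx.rate.kind == "free"
        }

    @property
    def fixed_rate_values(self) -> list[float]:
        return [rx.rate.value for rx in self.reactions if rx.rate.kind == "fixed"]

    def species_index(self, name: str) -> int:
        return self._index[name]

    # -- kinetics -----------------------------------------------------------
    def rate_constants(self, rates: "RateVector | Sequence[float]") -> np.ndarray:
        """Resolve the per-reaction rate constants for a full parameter triple."""
        rv = _as_rate_vector(rates)
        k = np.empty(len(self.reactions), dtype=float)
        for r, rx in enumerate(self.reactions):
            k[r] = rx.rate.value if rx.rate.kind == "fixed" else rv[rx.rate.param_index - 1]
        return k

    def _deriv(self, states: np.ndarray, k: np.ndarray) -> np.ndarray:
        """Mass-action time derivative for a batch of states, shape (N, n)."""
        N = states.shape[0]
        flux = np.empty((N, len(self.reactions)))
        for r, idxs in enumerate(self._reactant_lists):
            f = np.full(N, k[r])
            for j in idxs:
                f = f * states[:, j]
            flux[:, r] = f
        return flux @ self._net


def _integer_left_null_basis(net: np.ndarray) -> list[np.ndarray]:
    """Integer basis of {v : net @ v = 0}, i.e. conserved moieties of S = net.T.

    Exact rational Gaussian elimination; vectors are scaled to coprime
    integers with the first nonzero entry positive.
    """
    m, n = net.shape
    rows = [[Fraction(int(x)) for x in row] for row in net]
    pivots: list[tuple[int, int]] = []
    r = 0
    for c in range(n):
        pivot = next((i for i in range(r, m) if rows[i][c] != 0), None)
        if pivot is None:
            continue
        rows[r], rows[pivot] = rows[pivot], rows[r]
        pv = rows[r][c]
        rows[r] = [x / pv for x in rows[r]]
        for i in range(m):
            if i != r and rows[i][c] != 0:
                f = rows[i][c]
                rows[i] = [a - f * b for a, b in zip(rows[i], rows[r])]
        pivots.append((r, c))
        r += 1
        if r == m:
            break
    pivot_cols = {c for _, c in pivots}
    basis: list[np.ndarray] = []
    for free_c in range(n):
        if free_c in pivot_cols:
            continue
        v = [Fraction(0)] * n
        v[free_c] = Fraction(1)
        for pr, pc in pivots:
            v[pc] = -rows[pr][free_c]
        denom = math.lcm(*(f.denominator for f in v))
        ints = np.array([int(f * denom) for f in v], dtype=np.int64)
        g = math.gcd(*(abs(int(x)) for x in ints if x != 0))
        ints //= max(g, 1)
        first = next(x for x in ints if x != 0)
        if first < 0:
            ints = -ints
        basis.append(ints)
    return _prefer_nonnegative(basis)


def _prefer_nonnegative(basis: list[np.ndarray]) -> list[np.ndarray]:
    """Reduce a moiety basis toward nonnegative vectors (e.g. totals of a
    protein across its free and complexed forms) by pairwise combinations."""

    def score(v: np.ndarray) -> tuple[int, int]:
        return int(np.sum(v < 0)), int(np.sum(np.abs(v)))

    def normalize(v: np.ndarray) -> np.ndarray:
        g = math.gcd(*(abs(int(x)) for x in v if x != 0))
        v = v // max(g, 1)
        if next((x for x in v if x != 0), 1) < 0:
            v = -v
        return v

    basis = [v.copy() for v in basis]
    for _ in range(10):
        improved = False
        for i in range(len(basis)):
            for j in range(len(basis)):
                if i == j:
                    continue
                for c in (1, -1):
                    cand = normalize(basis[i] + c * basis[j])
                    if np.any(cand != 0) and score(cand) < score(basis[i]):
                        basis[i] = cand
                        improved = True
        if not improved:
            break
    return basis


# ---------------------------------------------------------------------------
# Default minimal NK-cell network and the nested candidate models
# ---------------------------------------------------------------------------

def build_minimal_nk_network() -> ReactionNetwork:
    """The minimal six-species NK-cell signalling network.

    Reactions (free rates theta_1..theta_3, fixed rates in 1/s):

    ====  =============================  ==========
    R1    Syk + Vav1 -> Syk:Vav1         theta_1
    R2    Syk:Vav1 -> Syk + Vav1         0.12
    R3    Syk:Vav1 -> Syk + pVav1        theta_2
    R4    SHP1 + pVav1 -> SHP1:pVav1     theta_3
    R5    SHP1:pVav1 -> SHP1 + pVav1     0.14
    R6    SHP1:pVav1 -> SHP1 + Vav1      0.05
    ====  =============================  ==========

    The kinase Syk binds Vav1 and phosphorylates it; the phosphatase SHP1
    binds phosphorylated Vav1 and dephosphorylates it.  Conserved moieties:
    total Syk, total SHP1 and the total Vav1 moiety
    (Vav1 + pVav1 + Syk:Vav1 + SHP1:pVav1).
    """
    s = DEFAULT_SPECIES
    reactions = [
        Reaction({s[0]: 1, s[1]: 1}, {s[2]: 1}, RateRef.free(1)),
        Reaction({s[2]: 1}, {s[0]: 1, s[1]: 1}, RateRef.fixed(FIXED_RATES[0])),
        Reaction({s[2]: 1}, {s[0]: 1, s[3]: 1}, RateRef.free(2)),
        Reaction({s[4]: 1, s[3]: 1}, {s[5]: 1}, RateRef.free(3)),
        Reaction({s[5]: 1}, {s[4]: 1, s[3]: 1}, RateRef.fixed(FIXED_RATES[1])),
        Reaction({s[5]: 1}, {s[4]: 1, s[1]: 1}, RateRef.fixed(FIXED_RATES[2])),
    ]
    return ReactionNetwork(s, reactions)


@dataclass(frozen=True)
class CandidateModel:
    """A candidate ODE model: a network plus a free-parameter constraint map.

    The three default candidates are nested: model 1 enforces
    ``theta_2 = 9*theta_1`` and ``theta_3 = 2*theta_1`` (one free parameter),
    model 2 enforces ``theta_2 = 9*theta_1`` (two free), model 3 leaves all
    three rates free.
    """

    id: int
    network: ReactionNetwork
    n_free: int
    constraint_map: Callable[[np.ndarray], tuple[float, ...]] = field(compare=False)

    def resolve_rates(self, free_params: Sequence[float]) -> RateVector:
        return resolve_rates(self, free_params)

    def admits(self, rates: "RateVector | Sequence[float]", rtol: float = 1e-9) -> bool:
        """Whether a full rate triple lies on this model's constraint manifold."""
        rv = _as_rate_vector(rates).as_array()
        free = self.reduce_rates(rv)
        resolved = self.resolve_rates(free).as_array()
        return bool(np.allclose(resolved, rv, rtol=rtol, atol=0.0))

    def reduce_rates(self, rates: "RateVector | Sequence[float]") -> np.ndarray:
        """Project a full rate triple onto this model's free parameters."""
        rv = _as_rate_vector(rates).as_array()
        if self.n_free == 1:
            return rv[[0]]
        if self.n_free == 2:
            return rv[[0, 2]]
        return rv.copy()


def resolve_rates(model: CandidateModel, free_params: Sequence[float]) -> RateVector:
    """Apply a candidate's constraint map to its free parameters.

    Raises :class:`DataError` on a wrong-length or nonpositive input.
    """
    fp = np.asarray(free_params, dtype=float).ravel()
    if fp.shape[0] != model.n_free:
        raise DataError(
            f"model {model.id} expects {model.n_free} free parameter(s), got {fp.shape[0]}"
        )
    if not np.all(np.isfinite(fp) & (fp > 0)):
        raise DataError(f"free parameters must be finite and > 0, got {fp}")
    return RateVector(tuple(float(t) for t in model.constraint_map(fp)))


def default_candidates(network: ReactionNetwork | None = None) -> list[CandidateModel]:
    """The three nested candidate models sharing one network topology."""
    net = network if network is not None else build_minimal_nk_network()
    return [
        CandidateModel(1, net, 1, lambda p: (p[0], 9.0 * p[0], 2.0 * p[0])),
        CandidateModel(2, net, 2, lambda p: (p[0], 9.0 * p[0], p[1])),
        CandidateModel(3, net, 3, lambda p: (p[0], p[1], p[2])),
    ]


# ---------------------------------------------------------------------------
# Kinetics and integration
# ---------------------------------------------------------------------------

def mass_action_rhs(
    network: ReactionNetwork,
    rates: "RateVector | Sequence[float]",
    state: Sequence[float],
) -> np.ndarray:
    """Mass-action time derivative at one state (abundance/s).

    ``state`` must be a nonnegative vector of length ``n_species``.
    """
    x = np.asarray(state, dtype=float).ravel()
    if x.shape[0] != network.n_species:
        raise DataError(
            f"state length {x.shape[0]} != number of species {network.n_species}"
        )
    if np.any(x < 0):
        raise DataError("state entries must be nonnegative")
    k = network.rate_constants(rates)
    return network._deriv(x[None, :], k)[0]


class _RhsBudgetExceeded(Exception):
    pass


def evolve_cells(
    network: ReactionNetwork,
    rates: "RateVector | Sequence[float]",
    initial_states: np.ndarray,
    t: float,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "batch",
    max_rhs_evals: int | None = None,
    stiff_fallback: bool = True,
) -> np.ndarray:
    """Evolve a population of cells to time ``t`` under the deterministic ODEs.

    ``initial_states`` is an (N, n_species) strictly positive matrix; row j of
    the result is the ODE solution at ``t`` started from row j.  Cells are
    independent, so by default all are integrated together as one flattened
    system with a high-order explicit Runge-Kutta method (DOP853); a stiff
    per-cell path (``method="stiff"``, LSODA) is available and is also the
    automatic fallback when the batch integration fails.

    Small negative undershoots (within ``100*atol`` of zero) are clipped to 0
    with a warning; larger negatives raise :class:`NumericalError`.

    ``max_rhs_evals`` bounds the work of the batch integrator; exceeding it
    raises :class:`NumericalError` when ``stiff_fallback`` is off (an
    optimizer screening implausible, very stiff trial rates uses this to
    fail fast) and otherwise triggers the per-cell stiff path.
    """
    X0 = np.asarray(initial_states, dtype=float)
    if X0.ndim != 2 or X0.shape[1] != network.n_species:
        raise DataError(
            f"initial_states must be (N, {network.n_species}), got {X0.shape}"
        )
    if not np.all(np.isfinite(X0) & (X0 > 0)):
        raise DataError("initial states must be finite and strictly positive")
    if not (np.isfinite(t) and t >= 0):
        raise DataError(f"time t must be >= 0, got {t}")
    if t == 0:
        return X0.copy()

    k = network.rate_constants(rates)
    if method == "batch":
        out = _evolve_batch(network, k, X0, t, rtol, atol, max_rhs_evals)
        if out is None:  # fall back to the robust per-cell path
            if not stiff_fallback:
                raise NumericalError(
                    "batch ODE integration failed or exceeded its evaluation "
                    f"budget at rates {np.asarray(k)}"
                )
            out = _evolve_per_cell(network, k, X0, t, rtol, atol)
    elif method == "stiff":
        out = _evolve_per_cell(network, k, X0, t, rtol, atol)
    else:
        raise ConfigError(f"unknown integration method {method!r}")
    return _clip_undershoot(out, atol)


def _evolve_batch(network, k, X0, t, rtol, atol, max_rhs_evals=None) -> np.ndarray | None:
    N, n = X0.shape
    budget = [max_rhs_evals] if max_rhs_evals is not None else None

    def rhs(_t, y):
        if budget is not None:
            budget[0] -= 1
            if budget[0] < 0:
                raise _RhsBudgetExceeded
        return network._deriv(y.reshape(N, n), k).ravel()

    try:
        sol = solve_ivp(
            rhs, (0.0, t), X0.ravel(), method="DOP853", rtol=rtol, atol=atol,
            t_eval=(t,), dense_output=False,
        )
    except _RhsBudgetExceeded:
        return None
    if not sol.success:
        return None
    return sol.y[:, -1].reshape(N, n)


def _evolve_per_cell(network, k, X0, t, rtol, atol) -> np.ndarray:
    N, n = X0.shape
    out = np.empty_like(X0)

    def rhs(_t, y):
        return network._deriv(y[None, :], k)[0]

    for j in range(N):
        sol = solve_ivp(
            rhs, (0.0, t), X0[j], method="LSODA", rtol=rtol, atol=atol, t_eval=(t,)
        )
        if not sol.success:
            raise NumericalError(
                f"ODE integration failed for cell row {j}: {sol.message}"
            )
        out[j] = sol.y[:, -1]
    return out


def _clip_undershoot(out: np.ndarray, atol: float) -> np.ndarray:
    floor = -_UNDERSHOOT_ATOL_FACTOR * atol
    if np.any(out < floor):
        rows = np.unique(np.where(out < floor)[0])
        raise NumericalError(
            f"integration produced negative abundances below tolerance in cell "
            f"row(s) {rows.tolist()[:5]} (min {out.min():.3e})"
        )
    neg = out < 0
    if np.any(neg):
        warnings.warn(
            "clipped small negative integrator undershoot to 0", RuntimeWarning,
            stacklevel=2,
        )
        out = np.where(neg, 0.0, out)
    return out


# ---------------------------------------------------------------------------
# Network config files
# ---------------------------------------------------------------------------

def _parse_side(text: str) -> dict[str, int]:
    side: dict[str, int] = {}
    text = text.strip()
    if not text or text == "0":
        return side
    for term in text.split("+"):
        parts = term.strip().split()
        if len(parts) == 1:
            name, coeff = parts[0], 1
        elif len(parts) == 2:
            coeff, name = int(parts[0]), parts[1]
        else:
            raise ConfigError(f"cannot parse reaction term {term!r}")
        side[name] = side.get(name, 0) + coeff
    return side


def _parse_reaction_string(text: str) -> Reaction:
    """Parse ``"A + 2 B -> C @ fixed:0.12"`` / ``"... @ free:2"``."""
    try:
        body, rate_text = text.rsplit("@", 1)
        lhs, rhs = body.split("->")
        kind, value = rate_text.strip().split(":")
    except ValueError as exc:
        raise ConfigError(f"malformed reaction string {text!r}") from exc
    kind = kind.strip().lower()
    if kind == "fixed":
        rate = RateRef.fixed(float(value))
    elif kind == "free":
        rate = RateRef.free(int(value))
    else:
        raise ConfigError(f"rate kind must be fixed|free in {text!r}")
    return Reaction(_parse_side(lhs), _parse_side(rhs), rate)


def load_network(path) -> ReactionNetwork:
    """Load a network from a YAML file.

    Schema::

        species: [Syk, Vav1, SykVav1, pVav1, SHP1, SHP1pVav1]
        reactions:
          - "Syk + Vav1 -> SykVav1 @ free:1"
          - "SykVav1 -> Syk + Vav1 @ fixed:0.12"
        conserved:            # optional explicit checks, verified on load
          - {Syk: 1, SykVav1: 1}

    Any ``conserved`` entries are verified to annihilate the net stoichiometry
    matrix; a violation raises :class:`ConfigError`.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "species" not in doc or "reactions" not in doc:
        raise ConfigError(f"network file {path} must define 'species' and 'reactions'")
    try:
        net = ReactionNetwork(
            [str(s) for s in doc["species"]],
            [_parse_reaction_string(str(r)) for r in doc["reactions"]],
        )
    except DataError as exc:
        raise ConfigError(f"invalid network in {path}: {exc}") from exc
    for entry in doc.get("conserved", []) or []:
        v = np.zeros(net.n_species, dtype=np.int64)
        for name, coeff in entry.items():
            v[net.species_index(name)] = int(coeff)
        if np.any(v @ net.stoichiometry != 0):
            raise ConfigError(
                f"declared conserved moiety {entry!r} is not conserved by the network"
            )
    return net
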