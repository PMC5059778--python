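"""NK fitness landscapes over binary strings.

The task environment is Kauffman's NK model: a solution is a length-``N``
binary vector, and the payoff contribution of each locus depends on its own
state and the states of ``K`` other, randomly chosen loci.  ``K`` tunes
ruggedness: ``K=0`` gives a single-peaked (generically) landscape where
one-bit hill climbing always reaches the global optimum, while large ``K``
produces many local optima.

Raw payoffs (means of uniform contributions) are normalised by the landscape
maximum and raised to a power (default 8), which stretches the payoff
distribution so that most solutions are mediocre and only a few are very
good.  The full table of 2^N transformed payoffs is precomputed at
construction, so the simulation loop reduces to array lookups keyed by the
integer encoding of a genotype (bit ``i`` of the index is locus ``i``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["NKLandscape", "generate_landscape", "bits_to_index", "index_to_bits"]

#: maximum N for which the 2^N payoff cache is considered feasible
MAX_CACHED_N = 20

#: exponent of the monotone payoff transform
DEFAULT_EXPONENT = 8


def bits_to_index(bits: np.ndarray) -> int:
    """Pack a binary genotype vector into its integer code (locus i -> bit i)."""
    bits = np.asarray(bits)
    return int((bits.astype(np.int64) << np.arange(bits.size, dtype=np.int64)).sum())


def index_to_bits(index: int, n: int) -> np.ndarray:
    """Unpack an integer genotype code into a length-``n`` 0/1 vector."""
    return (index >> np.arange(n, dtype=np.int64)) & 1


@dataclass
class NKLandscape:
    """An NK landscape with fully enumerated payoff caches.

    Parameters
    ----------
    N : int
        Number of binary components per solution.
    K : int
        Number of other loci each locus' contribution depends on
        (``0 <= K < N``).
    interaction_map : (N, K) int array
        For each locus, the ``K`` distinct other loci it depends on.
    contribution_tables : (N, 2**(K+1)) float array
        Per-locus payoff contributions in [0, 1], indexed by the packed joint
        state (own bit is the lowest bit, partner bits follow in
        ``interaction_map`` order).
    seed : int or None
        RNG seed the landscape was generated from (metadata only).
    exponent : float
        Power applied to the normalised payoff.
    """

    N: int
    K: int
    interaction_map: np.ndarray
    contribution_tables: np.ndarray
    seed: int | None = None
    exponent: float = DEFAULT_EXPONENT

    raw_cache: np.ndarray = field(init=False, repr=False)
    payoff_cache: np.ndarray = field(init=False, repr=False)
    max_raw_payoff: float = field(init=False)

    def __post_init__(self) -> None:
        self._validate()
        self._build_caches()

    # ------------------------------------------------------------------ setup

    def _validate(self) -> None:
        if not (0 <= self.K < self.N):
            raise ValueError(f"require 0 <= K < N, got N={self.N}, K={self.K}")
        if self.N > MAX_CACHED_N:
            raise ValueError(
                f"N={self.N} exceeds the full-enumeration limit ({MAX_CACHED_N}); "
                "the 2^N payoff cache would be infeasible"
            )
        self.interaction_map = np.asarray(self.interaction_map, dtype=np.int64).reshape(
            self.N, self.K
        )
        self.contribution_tables = np.asarray(self.contribution_tables, dtype=np.float64)
        if self.contribution_tables.shape != (self.N, 2 ** (self.K + 1)):
            raise ValueError(
                "contribution_tables must have shape (N, 2**(K+1)), got "
                f"{self.contribution_tables.shape}"
            )
        for i in range(self.N):
            partners = self.interaction_map[i]
            if i in partners or len(set(partners.tolist())) != self.K:
                raise ValueError(f"locus {i}: partners must be {self.K} distinct loci != {i}")
        if self.contribution_tables.min() < 0.0 or self.contribution_tables.max() > 1.0:
            raise ValueError("contribution values must lie in [0, 1]")

    def _build_caches(self) -> None:
        codes = np.arange(2**self.N, dtype=np.int64)
        bits = ((codes[:, None] >> np.arange(self.N, dtype=np.int64)) & 1).astype(np.int64)
        raw = np.zeros(2**self.N, dtype=np.float64)
        weights = 1 << np.arange(self.K + 1, dtype=np.int64)
        for i in range(self.N):
            cols = np.concatenate(([i], self.interaction_map[i]))
            state = bits[:, cols] @ weights
            raw += self.contribution_tables[i, state]
        raw /= self.N
        self.raw_cache = raw
        self.max_raw_payoff = float(raw.max())
        if self.max_raw_payoff <= 0.0:
            raise ValueError("degenerate landscape: maximum raw payoff is 0")
        self.payoff_cache = (raw / self.max_raw_payoff) ** self.exponent

    # ------------------------------------------------------------- evaluation

    def _check_genotype(self, g: np.ndarray) -> np.ndarray:
        g = np.asarray(g)
        if g.shape != (self.N,):
            raise ValueError(f"genotype must have length N={self.N}, got shape {g.shape}")
        if not np.isin(g, (0, 1)).all():
            raise ValueError("genotype entries must be 0 or 1")
        return g.astype(np.int64)

    def raw_payoff(self, g: np.ndarray) -> float:
        """Mean of the per-locus contributions, evaluated directly from the tables."""
        g = self._check_genotype(g)
        total = 0.0
        weights = 1 << np.arange(self.K + 1, dtype=np.int64)
        for i in range(self.N):
            state = int(np.concatenate(([g[i]], g[self.interaction_map[i]])) @ weights)
            total += self.contribution_tables[i, state]
        return total / self.N

    def transformed_payoff(self, g: np.ndarray) -> float:
        """Normalised raw payoff raised to ``exponent``; 1.0 iff g is a global optimum."""
        return (self.raw_payoff(g) / self.max_raw_payoff) ** self.exponent

    def payoff_of_index(self, code: int) -> float:
        """Cached transformed payoff of an integer-encoded genotype."""
        return float(self.payoff_cache[code])

    def count_local_optima(self) -> int:
        """Number of genotypes strictly better than all N one-bit neighbours."""
        codes = np.arange(2**self.N, dtype=np.int64)
        is_opt = np.ones(2**self.N, dtype=bool)
        for b in range(self.N):
            is_opt &= self.raw_cache > self.raw_cache[codes ^ (1 << b)]
        return int(is_opt.sum())

    # -------------------------------------------------------------------- I/O

    def to_json(self, path) -> None:
        """Serialise the defining data (not the caches) to a JSON file."""
        payload = {
            "N": self.N,
            "K": self.K,
            "seed": self.seed,
            "exponent": self.exponent,
            "interaction_map": self.interaction_map.tolist(),
            "contribution_tables": self.contribution_tables.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "NKLandscape":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            N=payload["N"],
            K=payload["K"],
            interaction_map=np.array(payload["interaction_map"], dtype=np.int64).reshape(
                payload["N"], payload["K"]
            ),
            contribution_tables=np.array(payload["contribution_tables"], dtype=np.float64),
            seed=payload["seed"],
            exponent=payload["exponent"],
        )

    # ------------------------------------------------------------- generation

    @classmethod
    def generate(cls, N: int, K: int, seed: int, exponent: float = DEFAULT_EXPONENT) -> "NKLandscape":
        """Draw a random landscape: i.i.d. U(0,1) contributions, uniform partners."""
        if not (0 <= K < N):
            raise ValueError(f"require 0 <= K < N, got N={N}, K={K}")
        if N > MAX_CACHED_N:
            raise ValueError(f"N={N} exceeds the full-enumeration limit ({MAX_CACHED_N})")
        rng = np.random.default_rng(seed)
        interaction_map = np.empty((N, K), dtype=np.int64)
        for i in range(N):
            others = np.delete(np.arange(N, dtype=np.int64), i)
            interaction_map[i] = rng.choice(others, size=K, replace=False)
        tables = rng.random((N, 2 ** (K + 1)))
        return cls(
            N=N,
            K=K,
            interaction_map=interaction_map,
            contribution_tables=tables,
            seed=seed,
            exponent=exponent,
        )


def generate_landscape(N: int, K: int, seed: int, exponent: float = DEFAULT_EXPONENT) -> NKLandscape:
    """Functional alias for :meth:`NKLandscape.generate`."""
    return NKLandscape.generate(N, K, seed, exponent=exponent)
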