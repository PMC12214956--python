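"""Binary linear block codes for tag payloads.

The default code is the extended binary Golay code, a [24, 12] code with
minimum distance 8 and therefore a guaranteed correction radius of
``floor((8 - 1) / 2) = 3`` bit errors.  A 12-bit identifier (the *dataword*)
is multiplied by a systematic generator matrix ``G = [I | B]`` over GF(2) to
produce the 24-bit *codeword* that is physically embodied as a tag; decoding
is brute-force nearest-neighbour search over all 2^12 codewords, which is
exact and fast at this size.

Any systematic generator matrix can be supplied instead, e.g. an identity
code on 25 bits for raw-pattern experiments on a full 5x5 ticket.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations, product
from pathlib import Path

import numpy as np

__all__ = [
    "LinearCode",
    "DecodeResult",
    "default_code",
    "identity_code",
]

# Quadratic residues mod 11; the bordered circulant over their complement
# yields the standard extended-Golay B block.
_QR11 = frozenset({1, 3, 4, 5, 9})


def _golay_b() -> np.ndarray:
    B = np.zeros((12, 12), dtype=np.uint8)
    B[0, 1:] = 1
    B[1:, 0] = 1
    for i in range(11):
        for j in range(11):
            B[1 + i, 1 + j] = 0 if (j - i) % 11 in _QR11 else 1
    return B


@dataclass(frozen=True)
class DecodeResult:
    """Outcome of nearest-neighbour decoding of a received n-bit vector."""

    dataword: np.ndarray
    distance: int
    ambiguous: bool
    guaranteed: bool

    def __post_init__(self):  # guaranteed decoding is by definition unambiguous
        if self.guaranteed and self.ambiguous:
            raise ValueError("a guaranteed decode cannot be ambiguous")


@dataclass
class LinearCode:
    """Systematic binary [n, k] block code defined by G = [I | B].

    Parameters
    ----------
    G : (k, n) uint8 array
        Generator matrix over GF(2); the first k columns must form the
        identity so that codewords carry the dataword verbatim.
    """

    G: np.ndarray
    _codebook: np.ndarray | None = field(default=None, repr=False, compare=False)
    _d_min: int | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=np.uint8) % 2
        k, n = self.G.shape
        if k > n:
            raise ValueError(f"generator matrix is {k}x{n}; need k <= n")
        if not np.array_equal(self.G[:, :k], np.eye(k, dtype=np.uint8)):
            raise ValueError("generator matrix is not in systematic form [I | B]")

    @property
    def k(self) -> int:
        return self.G.shape[0]

    @property
    def n(self) -> int:
        return self.G.shape[1]

    @property
    def is_rate_one(self) -> bool:
        """G = I: codewords are the raw messages (no redundancy)."""
        return self.n == self.k

    @property
    def codebook(self) -> np.ndarray:
        """All 2^k codewords, row i encoding the k-bit binary expansion of i."""
        if self._codebook is None:
            if self.k > 20:
                raise MemoryError(
                    f"refusing to enumerate 2^{self.k} codewords; k too large"
                )
            msgs = np.array(list(product([0, 1], repeat=self.k)), dtype=np.uint8)
            self._codebook = msgs @ self.G % 2
        return self._codebook

    def encode(self, dataword) -> np.ndarray:
        d = _as_bits(dataword, self.k, "dataword")
        return d @ self.G % 2

    def minimum_distance(self) -> int:
        """Exhaustive minimum nonzero codeword weight (= d_min for a linear code)."""
        if self._d_min is None:
            if self.is_rate_one:
                self._d_min = 1  # unit-weight messages are codewords
            else:
                w = self.codebook.sum(axis=1)
                self._d_min = int(w[w > 0].min()) if len(w) > 1 else self.n
        return self._d_min

    def correction_radius(self) -> int:
        return (self.minimum_distance() - 1) // 2

    def decode(self, received) -> DecodeResult:
        """Brute-force nearest-neighbour decode of an n-bit received vector.

        Scans all 2^k codewords; ties are reported as ``ambiguous`` and broken
        toward the lowest dataword index so that decoding stays deterministic.
        """
        r = _as_bits(received, self.n, "received vector")
        if self.is_rate_one:  # every vector is a codeword; no search needed
            return DecodeResult(r.copy(), 0, False, True)
        dists = (self.codebook ^ r).sum(axis=1)
        best = int(dists.min())
        idx = int(dists.argmin())
        ambiguous = int((dists == best).sum()) > 1
        dataword = np.array(
            [(idx >> (self.k - 1 - i)) & 1 for i in range(self.k)], dtype=np.uint8
        )
        guaranteed = best <= self.correction_radius() and not ambiguous
        return DecodeResult(dataword, best, ambiguous, guaranteed)

    def verify_radius(self, t: int, n_datawords: int = 20, rng=None) -> bool:
        """Audit that every error of weight <= t is corrected.

        Exhaustive over error patterns of weight ``t`` for a sample of
        datawords (all datawords if ``2^k <= n_datawords``).  Returns False as
        soon as one pattern decodes wrongly or without guarantee.
        """
        if t < 0:
            raise ValueError("t must be >= 0")
        if t == 0:
            return True
        rng = np.random.default_rng(rng)
        if 2**self.k <= n_datawords:
            datawords = list(product([0, 1], repeat=self.k))
        else:
            datawords = rng.integers(0, 2, size=(n_datawords, self.k))
        for d in datawords:
            d = np.asarray(d, dtype=np.uint8)
            c = self.encode(d)
            for pos in combinations(range(self.n), t):
                r = c.copy()
                r[list(pos)] ^= 1
                res = self.decode(r)
                if not res.guaranteed or not np.array_equal(res.dataword, d):
                    return False
        return True

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "k": self.k,
            "n": self.n,
            "rows": [int("".join(map(str, row)), 2) for row in self.G],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "LinearCode":
        if isinstance(source, Path) or (
            isinstance(source, str) and "{" not in source
        ):
            source = Path(source).read_text()
        payload = json.loads(source)
        k, n = payload["k"], payload["n"]
        G = np.array(
            [[(row >> (n - 1 - j)) & 1 for j in range(n)] for row in payload["rows"]],
            dtype=np.uint8,
        )
        if len(G) != k:
            raise ValueError("row count does not match k")
        return cls(G)


def _as_bits(v, length: int, what: str) -> np.ndarray:
    if isinstance(v, str):
        v = [int(ch) for ch in v]
    a = np.asarray(v, dtype=np.uint8)
    if a.ndim != 1 or len(a) != length:
        raise ValueError(f"{what} must have exactly {length} bits, got shape {a.shape}")
    if not np.all((a == 0) | (a == 1)):
        raise ValueError(f"{what} entries must be 0/1")
    return a


def default_code() -> LinearCode:
    """The extended binary Golay [24, 12, 8] code in systematic form.

    The minimum distance is re-derived by exhaustive enumeration rather than
    trusted as a constant; construction bugs therefore fail loudly here.
    """
    code = LinearCode(np.hstack([np.eye(12, dtype=np.uint8), _golay_b()]))
    d = code.minimum_distance()
    if d != 8:
        raise AssertionError(f"Golay construction broken: d_min={d}, expected 8")
    return code


def identity_code(n: int) -> LinearCode:
    """Trivial rate-1 code (G = I): raw n-bit patterns with no redundancy."""
    return LinearCode(np.eye(n, dtype=np.uint8))
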