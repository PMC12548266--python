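"""Optimal-matching (OM) edit distances between daily state sequences.

The dissimilarity between two fish is the minimum total cost of
transforming one daily sequence into the other using substitutions and
indels, under a geographic cost model:

* substituting a state for itself costs 0, for an *adjacent*
  habitat/region 1, and for a non-adjacent one 2;
* a constant indel cost of 1 (half the maximum substitution cost, so an
  indel is never cheaper than the substitution it could replace);
* a left-missing day (MISSING) substituted against any observed state
  costs 2, which pins sequences to calendar time: shifting a late-starting
  sequence left is never cheaper than paying for its missing prefix.
  MISSING against MISSING costs 0.

Trailing VOID runs (days after a fish's final detection) are stripped
before the computation and excluded entirely.  Raw distances are
normalized by the longer sequence length (Abbott's "maxlength"
normalization) so dissimilarity does not merely reflect differences in
sequence length; normalized values lie in [0, 2].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequences import MISSING, VOID, DailyStateSequence


@dataclass(frozen=True)
class CostModel:
    """Substitution/indel cost structure over an observed-state alphabet.

    ``states`` is the alphabet plus the MISSING sentinel (last);
    ``matrix`` the symmetric substitution-cost matrix over ``states``.
    """

    alphabet: tuple[str, ...]
    states: tuple[str, ...]
    matrix: np.ndarray
    indel: float = 1.0
    missing_cost: float = 2.0

    def index(self, label: str) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise KeyError(f"state {label!r} not in cost model alphabet") from None

    def cost(self, a: str, b: str) -> float:
        return float(self.matrix[self.index(a), self.index(b)])

    def encode(self, labels) -> np.ndarray:
        lut = {s: i for i, s in enumerate(self.states)}
        try:
            return np.fromiter((lut[x] for x in labels), dtype=np.intp, count=len(labels))
        except KeyError as e:
            raise KeyError(f"state {e.args[0]!r} not in cost model alphabet") from None


def _normalize_adjacency(alphabet, adjacency) -> set[frozenset]:
    pairs: set[frozenset] = set()
    if isinstance(adjacency, dict):
        for a, nbrs in adjacency.items():
            for b in nbrs:
                if a not in adjacency.get(b, ()):  # type: ignore[arg-type]
                    raise ValueError(f"asymmetric adjacency: {a!r}~{b!r}")
                pairs.add(frozenset((a, b)))
    else:
        for a, b in adjacency:
            pairs.add(frozenset((a, b)))
    known = set(alphabet)
    for p in pairs:
        if not p <= known:
            raise ValueError(f"adjacency references unknown states: {sorted(p - known)}")
    return pairs


def build_cost_matrix(
    alphabet,
    adjacency,
    indel: float = 1.0,
    missing_cost: float = 2.0,
) -> CostModel:
    """Geographic cost model: 0 same, 1 adjacent, 2 non-adjacent.

    ``adjacency`` is an edge list of label pairs (or a symmetric mapping
    label -> neighbors).  The MISSING sentinel gets ``missing_cost``
    against every observed state and 0 against itself.
    """
    alphabet = tuple(alphabet)
    if MISSING in alphabet or VOID in alphabet:
        raise ValueError("alphabet must not contain the MISSING/VOID sentinels")
    pairs = _normalize_adjacency(alphabet, adjacency)
    states = alphabet + (MISSING,)
    k = len(states)
    m = np.full((k, k), 2.0)
    np.fill_diagonal(m, 0.0)
    for i, a in enumerate(alphabet):
        for j, b in enumerate(alphabet):
            if i != j and frozenset((a, b)) in pairs:
                m[i, j] = 1.0
    m[-1, :-1] = missing_cost
    m[:-1, -1] = missing_cost
    m[-1, -1] = 0.0
    return CostModel(alphabet, states, m, float(indel), float(missing_cost))


def _as_labels(seq) -> np.ndarray:
    if isinstance(seq, DailyStateSequence):
        seq = seq.strip_void().states
    arr = np.asarray(seq, dtype=object)
    n = len(arr)
    while n > 0 and arr[n - 1] == VOID:
        n -= 1
    arr = arr[:n]
    if (arr == VOID).any():
        raise ValueError("VOID states are only allowed as a trailing run")
    return arr


def _om_raw(x: np.ndarray, y: np.ndarray, S: np.ndarray, indel: float) -> float:
    """Full-table edit-distance DP, vectorized one row at a time.

    The left-neighbor (insertion) dependency is resolved with a running
    minimum: D[i, j] = min_k<=j (cand[k] + (j - k) * indel), where cand
    holds the diagonal/top candidates.
    """
    n, m = len(x), len(y)
    jj = np.arange(m + 1)
    ramp = jj * indel
    prev = ramp.astype(float).copy()
    cand = np.empty(m + 1)
    for i in range(1, n + 1):
        cand[0] = i * indel
        np.minimum(prev[:-1] + S[x[i - 1], y], prev[1:] + indel, out=cand[1:])
        t = cand - ramp
        np.minimum.accumulate(t, out=t)
        prev = t + ramp
    return float(prev[m])


def om_distance(a, b, cost: CostModel) -> tuple[float, float]:
    """Raw and normalized OM distance between two sequences.

    Accepts :class:`DailyStateSequence` objects or plain label vectors;
    trailing VOID runs are stripped first.  Normalized distance is
    raw / max(len(a), len(b)).
    """
    la, lb = _as_labels(a), _as_labels(b)
    if len(la) == 0 or len(lb) == 0:
        raise ValueError("empty sequence after VOID stripping")
    x, y = cost.encode(la), cost.encode(lb)
    raw = _om_raw(x, y, cost.matrix, cost.indel)
    return raw, raw / max(len(x), len(y))


@dataclass
class DissimilarityMatrix:
    """Symmetric matrix of normalized pairwise OM distances."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        if (self.values < -1e-12).any():
            raise ValueError("dissimilarity matrix must be non-negative")

    def __len__(self) -> int:
        return len(self.ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DissimilarityMatrix":
        return cls(tuple(str(i) for i in df.index), df.to_numpy(dtype=float))


def dissimilarity_matrix(sequences, cost: CostModel) -> DissimilarityMatrix:
    """All-pairs normalized OM distances.

    ``sequences`` is a mapping id -> sequence or a list of
    :class:`DailyStateSequence`.  Byte-identical sequences are deduplicated
    before the quadratic DP (a pure optimization; results are unchanged).
    """
    if isinstance(sequences, dict):
        items = [(str(k), v) for k, v in sequences.items()]
    else:
        items = [(s.fish_id, s) for s in sequences]
    if len(items) < 2:
        raise ValueError("need at least two sequences")
    ids = [k for k, _ in items]
    encoded = []
    for _, s in items:
        labels = _as_labels(s)
        if len(labels) == 0:
            raise ValueError("empty sequence after VOID stripping")
        encoded.append(cost.encode(labels))
    keys = [e.tobytes() for e in encoded]
    uniq: dict[bytes, int] = {}
    for k in keys:
        uniq.setdefault(k, len(uniq))
    reps = [None] * len(uniq)
    for e, k in zip(encoded, keys):
        reps[uniq[k]] = e
    u = len(uniq)
    ud = np.zeros((u, u))
    for i in range(u):
        for j in range(i + 1, u):
            raw = _om_raw(reps[i], reps[j], cost.matrix, cost.indel)
            ud[i, j] = ud[j, i] = raw / max(len(reps[i]), len(reps[j]))
    gi = np.array([uniq[k] for k in keys])
    values = ud[np.ix_(gi, gi)]
    np.fill_diagonal(values, 0.0)
    return DissimilarityMatrix(tuple(ids), values)
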