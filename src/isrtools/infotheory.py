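"""Context-tree-weighting entropy rates and spike-train mutual information.

Spike trains are binarized in ``b`` = 25 ms bins (1 = at least one spike).
The entropy rate of a binned train is estimated with the context tree
weighting (CTW) algorithm: a depth-``D`` suffix tree whose nodes carry
Krichevsky-Trofimov (KT) estimators, mixed with weight 1/2 between each
node's own KT estimate and the product of its children, which yields the
coding probability of the sequence under a Bayesian mixture over all
tree sources of depth <= D.  The mutual information rate between an input
and an output train is the plug-in combination

    MI = H(X) + H(Y) - H(X, Y)

with the joint sequence encoded over the 4-symbol product alphabet.  The
default depth D = 40 bins corresponds to a 1 s context window.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .integrator import SpikeTrain

__all__ = [
    "BinnedTrain",
    "MIEstimate",
    "bin_spike_train",
    "ContextTree",
    "ctw_entropy_rate",
    "mi_rate",
]

_LOG_HALF = math.log(0.5)


@dataclass
class BinnedTrain:
    """Binary (0/1) spike-count sequence at bin size ``b`` ms."""

    bin_ms: float
    seq: np.ndarray
    duration_ms: float

    def __post_init__(self) -> None:
        self.seq = np.asarray(self.seq, dtype=np.int64)
        if len(self.seq) != int(self.duration_ms / self.bin_ms):
            raise ValueError("sequence length must be floor(duration/bin)")


def bin_spike_train(spikes: SpikeTrain, bin_ms: float = 25.0,
                    T_ms: Optional[float] = None) -> BinnedTrain:
    """Binarize a spike train into left-closed right-open bins [kb, (k+1)b)."""
    if T_ms is None:
        T_ms = spikes.duration_ms
    nb = int(T_ms / bin_ms)
    seq = np.zeros(nb, dtype=np.int64)
    idx = (spikes.times_ms / bin_ms).astype(int)
    idx = idx[(idx >= 0) & (idx < nb)]
    seq[idx] = 1
    return BinnedTrain(bin_ms=bin_ms, seq=seq, duration_ms=nb * bin_ms)


class ContextTree:
    """Sequential m-ary KT context-tree-weighting coder (log domain).

    Nodes are stored sparsely in a dict keyed by (depth, context-code); each
    node holds its symbol counts, log KT probability, log weighted
    probability and the log product of its updated children.
    """

    def __init__(self, depth: int, alphabet: int):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        if alphabet < 2:
            raise ValueError("alphabet must have >= 2 symbols")
        self.D = depth
        self.m = alphabet
        self.n = 0
        # node: [counts list, logPe, logPw, log product of children Pw]
        self._nodes: dict = {}

    @property
    def log2_prob(self) -> float:
        """log2 of the weighted coding probability of everything seen."""
        root = self._nodes.get((0, 0))
        return (root[2] / math.log(2)) if root else 0.0

    def update(self, sym: int, ctx: Sequence[int]) -> None:
        """Process one symbol given its context (ctx[0] = most recent)."""
        D, m, nodes = self.D, self.m, self._nodes
        path = []
        key = 0
        for d in range(D + 1):
            path.append((d, key))
            if d < D:
                key = key * m + ctx[d] + 1  # bijective base-m numeration
        child_old = 0.0
        child_new = 0.0
        for d in range(D, -1, -1):
            nd = nodes.get(path[d])
            if nd is None:
                nd = [[0] * m, 0.0, 0.0, 0.0]
                nodes[path[d]] = nd
            cnts = nd[0]
            total = 0
            for c in cnts:
                total += c
            pe = (cnts[sym] + 0.5) / (total + 0.5 * m)
            logPe = nd[1] + math.log(pe)
            cnts[sym] += 1
            if d == D:
                logPw = logPe
            else:
                logPch = nd[3] + (child_new - child_old)
                nd[3] = logPch
                hi = logPe if logPe > logPch else logPch
                logPw = _LOG_HALF + hi + math.log(
                    math.exp(logPe - hi) + math.exp(logPch - hi))
            child_old = nd[2]
            child_new = logPw
            nd[1] = logPe
            nd[2] = logPw
        self.n += 1

    def feed(self, seq: np.ndarray) -> None:
        """Process a whole sequence (initial context padded with zeros)."""
        ctx = [0] * self.D
        for s in seq:
            s = int(s)
            self.update(s, ctx)
            ctx.insert(0, s)
            ctx.pop()

    def entropy_rate(self) -> float:
        """Code length per symbol, bits."""
        if self.n == 0:
            raise ValueError("no symbols processed")
        return -self.log2_prob / self.n


def ctw_entropy_rate(seq: np.ndarray, depth: int = 40,
                     alphabet: Optional[int] = None) -> float:
    """CTW entropy-rate estimate of a symbol sequence in bits/symbol."""
    seq = np.asarray(seq, dtype=np.int64)
    if alphabet is None:
        alphabet = max(2, int(seq.max()) + 1)
    if seq.min() < 0 or seq.max() >= alphabet:
        raise ValueError("symbols must lie in [0, alphabet)")
    if len(seq) < 10 * depth:
        warnings.warn(
            f"sequence length {len(seq)} < 10*depth; estimate may be "
            "strongly biased", stacklevel=2)
    tree = ContextTree(depth, alphabet)
    tree.feed(seq)
    return tree.entropy_rate()


@dataclass
class MIEstimate:
    """Mutual information rate between binned input and output trains."""

    mi_bits_per_bin: float
    mi_bits_per_s: float
    H_X: float
    H_Y: float
    H_XY: float
    repeats: int
    per_repeat: np.ndarray

    @property
    def mi_clipped(self) -> float:
        """Summary value with small negative estimates clipped at zero."""
        return max(0.0, self.mi_bits_per_s)


def mi_rate(inp: BinnedTrain, out: BinnedTrain, depth: int = 40,
            repeats: int = 1) -> MIEstimate:
    """Plug-in CTW mutual information rate MI = H(X) + H(Y) - H(X,Y).

    The joint sequence is coded over the 4-symbol product alphabet.  With
    ``repeats`` > 1 the sequence pair is additionally split into that many
    contiguous blocks whose per-block estimates give a spread; the headline
    value always uses the full sequences.
    """
    if inp.bin_ms != out.bin_ms:
        raise ValueError("input and output must use the same bin size")
    if len(inp.seq) != len(out.seq):
        raise ValueError("input and output must have the same duration")
    x = inp.seq
    y = out.seq
    joint = 2 * x + y

    def _mi_block(xs, ys, js) -> tuple:
        hx = ctw_entropy_rate(xs, depth, 2)
        hy = ctw_entropy_rate(ys, depth, 2)
        hxy = ctw_entropy_rate(js, depth, 4)
        return hx, hy, hx + hy - hxy

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hx, hy, mi = _mi_block(x, y, joint)
        per = []
        if repeats > 1:
            for blk in range(repeats):
                sl = slice(blk * len(x) // repeats,
                           (blk + 1) * len(x) // repeats)
                per.append(_mi_block(x[sl], y[sl], joint[sl])[2])
    per = np.asarray(per if per else [mi])
    return MIEstimate(
        mi_bits_per_bin=mi,
        mi_bits_per_s=mi / (inp.bin_ms / 1000.0),
        H_X=hx, H_Y=hy, H_XY=hx + hy - mi,
        repeats=repeats, per_repeat=per,
    )
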