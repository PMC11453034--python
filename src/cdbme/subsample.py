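"""Integer-weight sub-ensembles drawn from refined weights.

After refinement, compact final models are built by drawing small
sub-ensembles (multisets of conformers, sizes 5-200) with replacement
from the refined weights, so important conformers appear with integer
multiplicity.  For each candidate size several replica draws are made;
their chi2 deviations are averaged and compared against the chi2 of the
concatenation of all replicas.  The final size is the smallest one for
which (i) going to the next size no longer improves the mean chi2
considerably and (ii) replica means agree with the concatenated ensemble
within their uncertainty.

Sampling is implemented as categorical draws with replacement, which is
equivalent in law to rejection sampling (propose a conformer uniformly,
accept with probability w_j / max(w)).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

from .core import ObservableBlock, normalize_weights
from .refine import chi2_block

__all__ = [
    "DEFAULT_SIZES",
    "DEFAULT_REPLICAS",
    "SubEnsemble",
    "SizeTable",
    "draw_subensemble",
    "evaluate_sizes",
    "select_final",
]

#: candidate sub-ensemble sizes
DEFAULT_SIZES = (5, 10, 20, 50, 100, 200)
#: replica draws per size
DEFAULT_REPLICAS = 5


@dataclass(frozen=True)
class SubEnsemble:
    """A multiset of conformer indices with integer multiplicities."""

    size: int
    members: tuple  # (conformer_index, multiplicity) pairs, index-sorted
    replica_id: int
    seed: int

    def __post_init__(self):
        total = sum(m for _, m in self.members)
        if total != self.size or any(m < 1 for _, m in self.members):
            raise ValueError("multiplicities must be positive and sum to size")

    def weight_vector(self, n_conformers: int) -> np.ndarray:
        """Uniform-within-draw weights: multiplicity / size per conformer."""
        w = np.zeros(n_conformers)
        for idx, mult in self.members:
            w[idx] = mult / self.size
        return w


def draw_subensemble(w: npt.ArrayLike, size: int, seed: int) -> SubEnsemble:
    """Draw ``size`` conformers with replacement, P(j) = w_j per draw."""
    if size < 1:
        raise ValueError("size must be >= 1")
    w = normalize_weights(w)
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(w), size=size, replace=True, p=w)
    members = tuple(sorted(Counter(draws.tolist()).items()))
    return SubEnsemble(size=size, members=members, replica_id=0, seed=int(seed))


@dataclass(frozen=True)
class SizeTable:
    """Replica chi2 statistics per candidate size.

    ``mean_chi2[s][k]`` / ``sem_chi2[s][k]`` are the replica mean and
    standard error of block k's chi2 at size index s;
    ``concat_chi2[s][k]`` is the chi2 of the concatenated replicas.
    """

    sizes: tuple
    mean_chi2: np.ndarray
    sem_chi2: np.ndarray
    concat_chi2: np.ndarray
    replica_chi2: np.ndarray = field(repr=False)  # (n_sizes, replicas, blocks)
    subensembles: tuple = field(repr=False)  # tuple of tuples of SubEnsemble
    concatenated: tuple = field(repr=False)  # one SubEnsemble per size


def evaluate_sizes(
    blocks: list[ObservableBlock],
    w: npt.ArrayLike,
    sizes=DEFAULT_SIZES,
    replicas: int = DEFAULT_REPLICAS,
    seed: int = 0,
) -> SizeTable:
    """Draw replica sub-ensembles per size and tabulate their chi2.

    Each replica is an independent draw; within a draw the members get
    uniform (integer-multiplicity) weights.  Replica statistics are mean
    and standard error (n-1 variance) over replicas; the concatenated
    ensemble is the multiset union of the replicas.
    """
    sizes = tuple(int(s) for s in sizes)
    if not sizes:
        raise ValueError("sizes must be nonempty")
    if replicas < 2:
        raise ValueError("need at least two replicas")
    w = normalize_weights(w)
    n = len(w)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(sizes) * replicas) % (2**31)

    all_subs, all_concat = [], []
    rep_chi2 = np.empty((len(sizes), replicas, len(blocks)))
    concat_chi2 = np.empty((len(sizes), len(blocks)))
    for si, size in enumerate(sizes):
        reps = []
        pooled: Counter = Counter()
        for r in range(replicas):
            sub_seed = int(child_seeds[si * replicas + r])
            sub = draw_subensemble(w, size, sub_seed)
            sub = SubEnsemble(sub.size, sub.members, replica_id=r, seed=sub_seed)
            reps.append(sub)
            pooled.update(dict(sub.members))
            wv = sub.weight_vector(n)
            rep_chi2[si, r] = [chi2_block(b, wv) for b in blocks]
        concat = SubEnsemble(
            size=size * replicas,
            members=tuple(sorted(pooled.items())),
            replica_id=-1,
            seed=int(seed),
        )
        all_concat.append(concat)
        wv = concat.weight_vector(n)
        concat_chi2[si] = [chi2_block(b, wv) for b in blocks]
        all_subs.append(tuple(reps))

    mean = rep_chi2.mean(axis=1)
    sem = rep_chi2.std(axis=1, ddof=1) / np.sqrt(replicas)
    return SizeTable(
        sizes=sizes,
        mean_chi2=mean,
        sem_chi2=sem,
        concat_chi2=concat_chi2,
        replica_chi2=rep_chi2,
        subensembles=tuple(all_subs),
        concatenated=tuple(all_concat),
    )


def select_final(
    table: SizeTable, improve_tol: float = 0.05, agree_tol: float = 1.0
):
    """Choose the smallest adequate sub-ensemble size.

    A size qualifies when, for every block, (i) the relative mean-chi2
    improvement to the next larger size is below ``improve_tol`` and
    (ii) the replica mean agrees with the concatenated-ensemble chi2
    within ``agree_tol`` standard errors.  If no size qualifies the
    largest size is returned with a warning.

    Returns
    -------
    (size, subensembles)
        The chosen size and its replica :class:`SubEnsemble` draws (the
        first replica is the representative single-draw model).
    """
    if len(table.sizes) < 2:
        raise ValueError("size table must cover at least two sizes")
    n_sizes = len(table.sizes)
    for si in range(n_sizes):
        if si < n_sizes - 1:
            cur, nxt = table.mean_chi2[si], table.mean_chi2[si + 1]
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = np.where(cur > 0, (cur - nxt) / cur, 0.0)
            if np.any(rel >= improve_tol):
                continue
        agree = np.abs(table.mean_chi2[si] - table.concat_chi2[si]) <= (
            agree_tol * table.sem_chi2[si] + 1e-12
        )
        if np.all(agree):
            return table.sizes[si], table.subensembles[si]
    warnings.warn(
        "no sub-ensemble size met the plateau/agreement criteria; "
        "returning the largest size",
        RuntimeWarning,
        stacklevel=2,
    )
    return table.sizes[-1], table.subensembles[-1]
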