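"""Pairwise gene-set statistics: hypergeometric overlap tail and the
AUC / average-precision recovery of a terminal set from a diffusion ranking.

AUC here is the Mann-Whitney statistic of terminal vs non-terminal ranks
(identical to the trapezoidal ROC area under midrank tie handling); AP is

    AP = (1/k) * sum_{i=1..k} i / rank_i

over the k terminal genes sorted by ascending rank.  Both are summary
statistics of network proximity, not calibrated probabilities: AUC is
confounded by terminal-set centrality and AP by terminal-set size, which is
why the combiner receives sizes and centralities as additional features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

from .diffusion import DiffusionParams, DiffusionProfile, diffuse, rank_genes
from .network import GeneNetwork, GeneSet

__all__ = [
    "OverlapStat",
    "RecoveryScore",
    "hypergeometric_tail",
    "overlap_stat",
    "auc_recovery",
    "ap_recovery",
    "recovery_from_ranking",
    "reflective_scores",
]

Ranking = Sequence[tuple[str, float]]  # (gene, midrank), best rank = 1


def rankdata_midrank(x) -> np.ndarray:
    """Ascending midranks (ties share the mean of the ranks they span)."""
    from scipy.stats import rankdata

    return rankdata(np.asarray(x), method="average")


@dataclass(frozen=True)
class OverlapStat:
    """Hypergeometric overlap test: k of n query genes hit an m-gene pathway
    in a universe of N known genes; p = P(overlap >= k)."""

    N: int
    m: int
    n: int
    k: int
    p: float


@dataclass(frozen=True)
class RecoveryScore:
    """AUC/AP recovery of a terminal set, with the terminal count used."""

    auc: float
    ap: float
    k_terminal: int

    @property
    def ap_per_gene(self) -> float:
        """Size-normalized AP (diagnostic only; not a combiner feature)."""
        return self.ap / self.k_terminal


def hypergeometric_tail(N: int, m: int, n: int, k: int) -> float:
    """Upper tail P(x >= k) of the hypergeometric(N, m, n) overlap count.

    Computed via the survival function (log-space internally), so small
    tails are stable.  k = 0 returns exactly 1.
    """
    if not (0 <= k <= min(n, m) <= N) or n > N or m > N or min(n, m) < 0:
        raise ValueError(f"invalid hypergeometric arguments N={N}, m={m}, n={n}, k={k}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, m, n))


def overlap_stat(net: GeneNetwork, query: GeneSet, pathway: GeneSet) -> OverlapStat:
    """Hypergeometric test on the network universe (N = network genes; set
    sizes counted after restriction to the network)."""
    q = query.in_network(net)
    p_ = pathway.in_network(net)
    N = net.n_genes
    m, n, k = len(p_), len(q), len(q & p_)
    return OverlapStat(N=N, m=m, n=n, k=k, p=hypergeometric_tail(N, m, n, k))


def _terminal_ranks(ranking: Ranking, terminal: Iterable[str]) -> np.ndarray:
    tset = set(terminal)
    return np.asarray(sorted(r for g, r in ranking if g in tset))


def auc_recovery(ranking: Ranking, terminal: GeneSet | Iterable[str]) -> float:
    """ROC area of terminal-gene recovery over a midranked gene list.

    Equals the fraction of (terminal, non-terminal) pairs ordered correctly,
    ties counted 1/2 (Mann-Whitney U / (n1*n2)).
    """
    members = terminal.members if isinstance(terminal, GeneSet) else set(terminal)
    if not ranking:
        raise ValueError("empty ranking")
    r1 = _terminal_ranks(ranking, members)
    n1 = r1.size
    n2 = len(ranking) - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("AUC undefined: terminal covers none or all of the ranking")
    u = n1 * n2 - (r1.sum() - n1 * (n1 + 1) / 2.0)
    return float(u / (n1 * n2))


def ap_recovery(ranking: Ranking, terminal: GeneSet | Iterable[str]) -> float:
    """Average precision (1/k) sum_i i/rank_i over terminal genes by rank."""
    members = terminal.members if isinstance(terminal, GeneSet) else set(terminal)
    r = _terminal_ranks(ranking, members)
    if r.size == 0:
        raise ValueError("AP undefined: no terminal gene in the ranking")
    i = np.arange(1, r.size + 1)
    return float(np.mean(i / r))


def recovery_from_ranking(ranking: Ranking, terminal: Iterable[str]) -> RecoveryScore:
    members = set(terminal)
    return RecoveryScore(
        auc=auc_recovery(ranking, members),
        ap=ap_recovery(ranking, members),
        k_terminal=len(_terminal_ranks(ranking, members)),
    )


def _directional(net: GeneNetwork, seed: GeneSet, terminal: GeneSet,
                 params: DiffusionParams, profile: DiffusionProfile | None = None) -> RecoveryScore:
    prof = profile if profile is not None else diffuse(net, seed, params)
    term_net = terminal.in_network(net)
    # Seed genes that are not themselves terminal candidates are removed from
    # the ranking; shared genes stay in and take the top ranks they earn.
    drop = frozenset(seed.in_network(net) - term_net)
    ranking = rank_genes(prof, exclude=drop)
    return recovery_from_ranking(ranking, term_net)


def reflective_scores(
    net: GeneNetwork,
    a: GeneSet,
    b: GeneSet,
    params: DiffusionParams | None = None,
    profiles: tuple[DiffusionProfile | None, DiffusionProfile | None] = (None, None),
) -> tuple[RecoveryScore, RecoveryScore]:
    """Diffuse each set in turn as the seed and score recovery of the other.

    Returns (forward, reverse) = (seed a / terminal b, seed b / terminal a).
    ``profiles`` lets callers pass precomputed diffusion profiles for a and b
    (a cache point for library-scale scoring).
    """
    params = params or DiffusionParams()
    fwd = _directional(net, a, b, params, profiles[0])
    rev = _directional(net, b, a, params, profiles[1])
    return fwd, rev
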