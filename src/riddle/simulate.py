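"""Synthetic worlds: planted-module networks and the simulated test regimes
used for training and benchmarking without any external downloads.

The generator produces a weighted planted-partition graph — modules of
genes wired densely inside (edge probability p_in) and sparsely to the rest
of the graph (p_out), with log-normal edge weights — plus a pool of
background genes attached at the between-module rate.  On top of the world
sit the three simulated test regimes: two independent half-size draws from
a module (overlap allowed), a random disjoint split into halves, and an
asymmetric disjoint split standing in for annotation-time splits (the
hardest case: the smaller, later-annotated side is the query).  A
centrality-binned randomizer provides size- and centrality-matched random
sets for null comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    CombinerModel,
    FeatureVector,
    RiddleConfig,
    compute_features,
    ras_score,
)
from .diffusion import DiffusionProfile
from .network import GeneNetwork, GeneSet
from .scoring import rankdata_midrank  # re-exported helper

logger = logging.getLogger(__name__)

__all__ = [
    "WorldParams",
    "SyntheticWorld",
    "SubsetPair",
    "CorpusConfig",
    "synthetic_network",
    "overlapping_subsets",
    "disjoint_halves",
    "timesplit_like",
    "centrality_matched_random_set",
    "make_training_corpus",
    "corpus_features",
    "benchmark_recovery",
    "confound_survey",
]


@dataclass(frozen=True)
class WorldParams:
    """Planted-partition generator settings.

    Defaults (30 modules x 25 genes, 500 background genes, p_in = 0.25,
    p_out = 0.01, log-normal weights) give a minutes-scale world whose
    modules are recoverable but not trivially separable.
    """

    n_modules: int = 30
    module_size: int = 25
    p_in: float = 0.25
    p_out: float = 0.01
    n_background: int = 500
    weight_mu: float = 0.0
    weight_sigma: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError("require p_in > p_out >= 0")
        if self.module_size < 4:
            raise ValueError("module_size must be >= 4")
        if self.n_modules < 1 or self.n_background < 0:
            raise ValueError("invalid world sizes")


@dataclass(frozen=True)
class SyntheticWorld:
    """A generated network plus its ground-truth modules."""

    network: GeneNetwork
    modules: tuple[GeneSet, ...]
    params: WorldParams
    seed: int

    def module_by_id(self, mid: str) -> GeneSet:
        for m in self.modules:
            if m.id == mid:
                return m
        raise KeyError(mid)


@dataclass(frozen=True)
class SubsetPair:
    """A (query, known) subset pair drawn from a source module."""

    source_id: str
    regime: str  # overlap | disjoint | timesplit
    query: GeneSet
    known: GeneSet
    matched: bool = True


def synthetic_network(params: WorldParams | None = None, seed: int = 0) -> SyntheticWorld:
    """Planted-partition world: pure function of (params, seed)."""
    params = params or WorldParams()
    rng = np.random.default_rng(seed)
    n_mod_genes = params.n_modules * params.module_size
    n = n_mod_genes + params.n_background
    width = len(str(params.n_modules))
    gwidth = len(str(max(params.module_size, params.n_background)))
    names: list[str] = []
    membership = np.full(n, -1)
    for m in range(params.n_modules):
        for g in range(params.module_size):
            names.append(f"M{m + 1:0{width}d}G{g + 1:0{gwidth}d}")
            membership[m * params.module_size + g] = m
    for g in range(params.n_background):
        names.append(f"BG{g + 1:0{gwidth}d}")

    # Bernoulli trials over the upper triangle, rate by module co-membership
    iu, ju = np.triu_indices(n, k=1)
    same = (membership[iu] == membership[ju]) & (membership[iu] >= 0)
    prob = np.where(same, params.p_in, params.p_out)
    hit = rng.random(iu.size) < prob
    ei, ej = iu[hit], ju[hit]
    weights = rng.lognormal(params.weight_mu, params.weight_sigma, ei.size)

    edges = [(names[i], names[j], float(w)) for i, j, w in zip(ei, ej, weights)]
    net = GeneNetwork(edges, extra_genes=names)
    modules = tuple(
        GeneSet(
            id=f"M{m + 1:0{width}d}",
            name=f"planted module {m + 1}",
            members=frozenset(
                names[m * params.module_size + g] for g in range(params.module_size)
            ),
        )
        for m in range(params.n_modules)
    )
    logger.info(
        "synthetic world: %d genes, %d edges, %d modules",
        net.n_genes, net.n_edges, len(modules),
    )
    return SyntheticWorld(network=net, modules=modules, params=params, seed=seed)


# ---------------------------------------------------------------------------
# subset regimes
# ---------------------------------------------------------------------------


def _draw(rng: np.random.Generator, members: Sequence[str], size: int) -> frozenset[str]:
    return frozenset(rng.choice(np.asarray(members), size=size, replace=False))


def overlapping_subsets(module: GeneSet, frac: float = 0.5,
                        rng: np.random.Generator | None = None) -> SubsetPair:
    """Two independent draws of ceil(frac*n) distinct genes; the two subsets
    may overlap each other."""
    rng = rng or np.random.default_rng()
    if len(module) < 4:
        raise ValueError("module must have >= 4 genes")
    members = sorted(module.members)
    size = int(np.ceil(frac * len(members)))
    q = _draw(rng, members, size)
    k = _draw(rng, members, size)
    return SubsetPair(
        source_id=module.id,
        regime="overlap",
        query=GeneSet(id=f"{module.id}.oq", name="overlap query", members=q),
        known=GeneSet(id=f"{module.id}.ok", name="overlap known", members=k),
    )


def disjoint_halves(module: GeneSet, rng: np.random.Generator | None = None) -> SubsetPair:
    """Random partition into two halves: disjoint, sizes differ by <= 1,
    union recovers the module."""
    rng = rng or np.random.default_rng()
    if len(module) < 2:
        raise ValueError("module must have >= 2 genes")
    members = np.asarray(sorted(module.members))
    perm = rng.permutation(members)
    half = len(members) // 2
    q, k = frozenset(perm[:half]), frozenset(perm[half:])
    return SubsetPair(
        source_id=module.id,
        regime="disjoint",
        query=GeneSet(id=f"{module.id}.dq", name="disjoint query", members=q),
        known=GeneSet(id=f"{module.id}.dk", name="disjoint known", members=k),
    )


def timesplit_like(module: GeneSet, frac_known: float = 0.7,
                   rng: np.random.Generator | None = None) -> SubsetPair:
    """Asymmetric disjoint split emulating an annotation-time split: the
    larger side plays the long-known set, the smaller the newly-added query."""
    rng = rng or np.random.default_rng()
    if len(module) < 3:
        raise ValueError("module must have >= 3 genes")
    members = np.asarray(sorted(module.members))
    perm = rng.permutation(members)
    n_known = max(1, int(round(frac_known * len(members))))
    n_known = min(n_known, len(members) - 1)
    k, q = frozenset(perm[:n_known]), frozenset(perm[n_known:])
    return SubsetPair(
        source_id=module.id,
        regime="timesplit",
        query=GeneSet(id=f"{module.id}.tq", name="timesplit query", members=q),
        known=GeneSet(id=f"{module.id}.tk", name="timesplit known", members=k),
    )


_REGIMES = {
    "overlap": lambda mod, rng: overlapping_subsets(mod, rng=rng),
    "disjoint": lambda mod, rng: disjoint_halves(mod, rng=rng),
    "timesplit": lambda mod, rng: timesplit_like(mod, rng=rng),
}


def centrality_matched_random_set(
    net: GeneNetwork,
    template: GeneSet,
    n_bins: int = 10,
    rng: np.random.Generator | None = None,
    set_id: str | None = None,
) -> GeneSet:
    """Random gene set matching the template's size and centrality profile.

    Network genes are binned into n_bins equal-width centrality bins; each
    in-network template member is replaced by a uniform draw from its bin
    (deduplicated by redraw, falling back to the nearest non-empty bin)."""
    rng = rng or np.random.default_rng()
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    deg = net.degree_vector()
    members = net.indices_of(template.members)
    if members.size == 0:
        raise ValueError(f"template {template.id!r} has no gene in the network")
    lo, hi = float(deg.min()), float(deg.max())
    edges_ = np.linspace(lo, hi, n_bins + 1)
    bin_of = np.clip(np.searchsorted(edges_, deg, side="right") - 1, 0, n_bins - 1)
    pools = [np.flatnonzero(bin_of == b) for b in range(n_bins)]

    chosen: set[int] = set()
    for idx in members:
        b = int(bin_of[idx])
        pool = pools[b]
        avail = np.setdiff1d(pool, np.fromiter(chosen, dtype=np.intp, count=len(chosen)))
        if avail.size == 0:
            # nearest non-empty bin with unused genes
            for off in range(1, n_bins):
                for b2 in (b - off, b + off):
                    if 0 <= b2 < n_bins:
                        avail = np.setdiff1d(
                            pools[b2], np.fromiter(chosen, dtype=np.intp, count=len(chosen))
                        )
                        if avail.size:
                            logger.info("bin %d exhausted; drew from bin %d", b, b2)
                            break
                if avail.size:
                    break
        if avail.size == 0:
            raise ValueError("network too small to draw a matched set")
        chosen.add(int(rng.choice(avail)))
    return GeneSet(
        id=set_id or f"rand.{template.id}",
        name=f"centrality-matched random of {template.id}",
        members=frozenset(net.genes[i] for i in chosen),
    )


# ---------------------------------------------------------------------------
# training corpus
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorpusConfig:
    """Training-corpus recipe: positives are matched overlap + disjoint
    pairs per module; negatives are mismatched known subsets per query plus
    random sets of varying size paired with real module sets."""

    mismatches_per_query: int = 10
    n_random_negatives: int = 30
    random_size_range: tuple[int, int] = (5, 50)
    regimes: tuple[str, ...] = ("overlap", "disjoint")


def make_training_corpus(
    world: SyntheticWorld,
    cfg: CorpusConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[SubsetPair], list[SubsetPair]]:
    """Labelled (positives, negatives) subset pairs over the world."""
    cfg = cfg or CorpusConfig()
    rng = rng or np.random.default_rng()
    if len(world.modules) < 5:
        raise ValueError("need >= 5 modules for a training corpus")

    positives: list[SubsetPair] = []
    knowns_by_module: dict[str, list[GeneSet]] = {}
    for mod in world.modules:
        for regime in cfg.regimes:
            pair = _REGIMES[regime](mod, rng)
            positives.append(pair)
            knowns_by_module.setdefault(mod.id, []).append(pair.known)

    negatives: list[SubsetPair] = []
    module_ids = [m.id for m in world.modules]
    for pair in positives:
        others = [mid for mid in module_ids if mid != pair.source_id]
        pool = [k for mid in others for k in knowns_by_module[mid]]
        picks = rng.choice(len(pool), size=min(cfg.mismatches_per_query, len(pool)),
                           replace=False)
        for i in picks:
            negatives.append(
                SubsetPair(
                    source_id=pair.source_id,
                    regime=pair.regime,
                    query=pair.query,
                    known=pool[int(i)],
                    matched=False,
                )
            )

    # random sets of varying size paired with a real module set
    genes = np.asarray(world.network.genes)
    lo, hi = cfg.random_size_range
    for j in range(cfg.n_random_negatives):
        size = int(rng.integers(lo, hi + 1))
        rand = GeneSet(
            id=f"rand{j + 1:03d}",
            name="random negative set",
            members=frozenset(rng.choice(genes, size=size, replace=False)),
        )
        mod = world.modules[int(rng.integers(len(world.modules)))]
        negatives.append(
            SubsetPair(source_id=mod.id, regime="random", query=rand, known=mod,
                       matched=False)
        )
    return positives, negatives


def corpus_features(
    world: SyntheticWorld,
    pairs: Iterable[SubsetPair],
    cfg: RiddleConfig | None = None,
    profile_cache: dict[frozenset[str], DiffusionProfile] | None = None,
) -> list[FeatureVector]:
    """Feature vectors for a list of subset pairs (shared diffusion cache)."""
    cfg = cfg or RiddleConfig()
    cache = profile_cache if profile_cache is not None else {}
    return [
        compute_features(world.network, p.query, p.known, cfg, profile_cache=cache)
        for p in pairs
    ]


# ---------------------------------------------------------------------------
# benchmark
# ---------------------------------------------------------------------------

#: candidate orderings per method; sign +1 means higher is better
_METHOD_KEYS = {
    "riddle": None,  # RAS, filled per pair
    "hypergeometric": ("log_p_hg", -1),
    "le": ("log_p_le_rev", -1),
    "rd_auc": ("auc_rev", +1),
    "rd_ap": ("ap_rev", +1),
}


def rank_of_match(scores: np.ndarray, match_index: int) -> float:
    """Midrank of the matching candidate under descending-score ranking."""
    ranks = rankdata_midrank(-scores)
    return float(ranks[match_index])


def benchmark_recovery(
    world: SyntheticWorld,
    model: CombinerModel,
    regime: str,
    rng: np.random.Generator | None = None,
    cfg: RiddleConfig | None = None,
) -> pd.DataFrame:
    """Subset-matching benchmark for one regime.

    Each module is split into a query and a known subset; every query is
    scored against the pooled known subsets by RAS and by the component
    baselines (hypergeometric p, reverse LE p, reverse RD-AUC, reverse
    RD-AP).  A query counts as matched when its own module's known subset is
    the unique top candidate (midrank exactly 1); ties — e.g. the all-ones
    hypergeometric p column in the disjoint regime — therefore never yield a
    perfect match.  Returns one row per method with the fraction matched and
    the mean reciprocal (mid)rank.
    """
    if regime not in _REGIMES:
        raise ValueError(f"unknown regime {regime!r}")
    rng = rng or np.random.default_rng()
    cfg = cfg or RiddleConfig()
    pairs = [_REGIMES[regime](mod, rng) for mod in world.modules]
    knowns = [p.known for p in pairs]

    cache: dict[frozenset[str], DiffusionProfile] = {}
    per_method_ranks: dict[str, list[float]] = {m: [] for m in _METHOD_KEYS}
    for qi, pair in enumerate(pairs):
        fvs = [
            compute_features(world.network, pair.query, kn, cfg, profile_cache=cache)
            for kn in knowns
        ]
        for method, key in _METHOD_KEYS.items():
            if method == "riddle":
                scores = np.asarray([ras_score(model, fv) for fv in fvs])
            else:
                attr, sign = key
                scores = sign * np.asarray([getattr(fv, attr) for fv in fvs])
            per_method_ranks[method].append(rank_of_match(scores, qi))

    rows = []
    for method, ranks in per_method_ranks.items():
        r = np.asarray(ranks)
        rows.append(
            {
                "regime": regime,
                "method": method,
                "n_modules": r.size,
                "fraction_matched": float((r == 1.0).mean()),
                "mean_reciprocal_rank": float((1.0 / r).mean()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# confound survey
# ---------------------------------------------------------------------------


def confound_survey(
    world: SyntheticWorld,
    n_trials: int = 120,
    seed_size: int = 15,
    size_range: tuple[int, int] = (5, 100),
    n_bins: int = 10,
    rng: np.random.Generator | None = None,
    cfg: RiddleConfig | None = None,
) -> pd.DataFrame:
    """Recovery scores of random terminal sets from random seed sets.

    Per trial, a uniform random seed set diffuses over the network and a
    random terminal set is scored by AUC and AP.  Terminal sets alternate
    between (a) uniform draws of varying size — exposing the AP-vs-size
    confound — and (b) fixed-size draws from a single equal-width centrality
    bin — exposing the AUC-vs-centrality confound.  Columns: trial kind,
    terminal size/centrality, auc, ap.
    """
    from .diffusion import rank_genes, diffuse
    from .scoring import recovery_from_ranking

    rng = rng or np.random.default_rng()
    cfg = cfg or RiddleConfig()
    net = world.network
    genes = np.asarray(net.genes)
    deg = net.degree_vector()
    lo, hi = float(deg.min()), float(deg.max())
    bin_edges = np.linspace(lo, hi, n_bins + 1)
    bin_of = np.clip(np.searchsorted(bin_edges, deg, side="right") - 1, 0, n_bins - 1)
    pools = [np.flatnonzero(bin_of == b) for b in range(n_bins)]
    nonempty = [b for b, p in enumerate(pools) if p.size >= 25]

    rows = []
    for t in range(n_trials):
        seed_members = frozenset(rng.choice(genes, size=seed_size, replace=False))
        seed = GeneSet(id=f"seed{t}", name="random seed", members=seed_members)
        if t % 2 == 0:
            size = int(rng.integers(size_range[0], size_range[1] + 1))
            term_idx = rng.choice(net.n_genes, size=size, replace=False)
            kind = "size"
        else:
            b = int(rng.choice(np.asarray(nonempty)))
            term_idx = rng.choice(pools[b], size=20, replace=False)
            kind = "centrality"
        terminal = frozenset(genes[term_idx])
        prof = diffuse(net, seed, cfg.diffusion)
        ranking = rank_genes(prof, exclude=frozenset(seed_members - terminal))
        rec = recovery_from_ranking(ranking, terminal)
        rows.append(
            {
                "kind": kind,
                "terminal_size": len(terminal),
                "terminal_centrality": float(deg[term_idx].mean()),
                "auc": rec.auc,
                "ap": rec.ap,
            }
        )
    return pd.DataFrame(rows)
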