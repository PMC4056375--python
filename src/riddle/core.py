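"""The combiner layer: assemble the 13 per-pair features, train the
weighted RBF-SVM, emit the association score (RAS) with an empirical FDR,
and rank a pathway library against a query set.

The 13 features are the natural-log p-values of the hypergeometric test and
of the forward/reverse local-extension tests, forward/reverse diffusion AUC
and AP, the in-network query/pathway/overlap sizes, query and pathway
average centrality, and the fraction of query genes covered by the network.
The RAS is the signed decision value of the trained SVM; the empirical FDR
at a score s is N(s) / (N(s) + P(s)), where P and N are the fractions of
held-out positive and negative validation scores at or above s, each
distribution area-normalized to 1, made monotone by isotonic regression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
from sklearn.isotonic import IsotonicRegression
from sklearn.svm import SVC

from .diffusion import DiffusionParams, DiffusionProfile, diffuse
from .extension import DEFAULT_ALPHA, DEFAULT_BETA, le_pvalue
from .network import GeneNetwork, GeneSet, network_coverage, set_centrality
from .scoring import overlap_stat, reflective_scores

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "SvmParams",
    "RiddleConfig",
    "CombinerModel",
    "TrainReport",
    "RasResult",
    "compute_features",
    "train_combiner",
    "ras_score",
    "empirical_fdr",
    "FdrCurve",
    "rank_pathways",
    "write_results_tsv",
]

MODEL_VERSION = "riddle-combiner-1"
P_FLOOR = 1e-300  # p-values floored here before taking logs

FEATURE_NAMES = (
    "log_p_hg",
    "log_p_le_fwd",
    "log_p_le_rev",
    "auc_fwd",
    "auc_rev",
    "ap_fwd",
    "ap_rev",
    "query_size",
    "pathway_size",
    "overlap_size",
    "query_centrality",
    "pathway_centrality",
    "query_coverage",
)


@dataclass(frozen=True)
class FeatureVector:
    """The 13 per-pair features fed to the SVM combiner."""

    log_p_hg: float
    log_p_le_fwd: float
    log_p_le_rev: float
    auc_fwd: float
    auc_rev: float
    ap_fwd: float
    ap_rev: float
    query_size: int
    pathway_size: int
    overlap_size: int
    query_centrality: float
    pathway_centrality: float
    query_coverage: float

    def to_array(self) -> np.ndarray:
        return np.asarray([getattr(self, f) for f in FEATURE_NAMES], dtype=float)

    def __post_init__(self) -> None:
        arr = self.to_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite feature value")


@dataclass(frozen=True)
class SvmParams:
    """Combiner hyper-parameters.

    w1/w0 are the class weights of positive matches and negative matches
    (negatives are deliberately down-weighted since they vastly outnumber
    positives); C the soft-margin cost, e the termination tolerance, gamma
    the RBF kernel width.  frac_model/frac_cv give the modeling and
    cross-validation split fractions; the remainder is final validation.
    """

    w1: float = 1.0
    w0: float = 0.3
    C: float = 1e9
    e: float = 0.01
    gamma: float = 0.07
    frac_model: float = 0.25
    frac_cv: float = 0.25

    @property
    def tag(self) -> str:
        return (
            f"w1={self.w1:g},w0={self.w0:g},C={self.C:g},e={self.e:g},"
            f"gamma={self.gamma:g}"
        )


@dataclass(frozen=True)
class RiddleConfig:
    """Per-pair scoring configuration: diffusion and extension settings."""

    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    alpha: float = DEFAULT_ALPHA
    beta: int = DEFAULT_BETA


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------


def _log_p(p: float) -> float:
    return math.log(max(p, P_FLOOR))


def compute_features(
    net: GeneNetwork,
    query: GeneSet,
    pathway: GeneSet,
    cfg: RiddleConfig | None = None,
    profile_cache: dict[frozenset[str], DiffusionProfile] | None = None,
) -> FeatureVector:
    """All 13 features for one query-pathway pair.

    Forward direction = query as s1/seed, pathway as s2/terminal; reverse
    swaps the roles.  ``profile_cache`` (keyed by in-network seed members)
    lets library-scale callers reuse diffusion profiles across pairs.
    """
    cfg = cfg or RiddleConfig()
    q_net = query.in_network(net)
    p_net = pathway.in_network(net)
    if not q_net:
        raise ValueError(f"query set {query.id!r} has no gene in the network")
    if not p_net:
        raise ValueError(f"pathway set {pathway.id!r} has no gene in the network")

    hg = overlap_stat(net, query, pathway)
    p_le_fwd, _ = le_pvalue(net, query, pathway, cfg.alpha, cfg.beta)
    p_le_rev, _ = le_pvalue(net, pathway, query, cfg.alpha, cfg.beta)

    profiles: tuple[DiffusionProfile | None, DiffusionProfile | None] = (None, None)
    if profile_cache is not None:
        profiles = tuple(  # type: ignore[assignment]
            _cached_profile(net, s, key, cfg.diffusion, profile_cache)
            for s, key in ((query, q_net), (pathway, p_net))
        )
    fwd, rev = reflective_scores(net, query, pathway, cfg.diffusion, profiles)

    return FeatureVector(
        log_p_hg=_log_p(hg.p),
        log_p_le_fwd=_log_p(p_le_fwd),
        log_p_le_rev=_log_p(p_le_rev),
        auc_fwd=fwd.auc,
        auc_rev=rev.auc,
        ap_fwd=fwd.ap,
        ap_rev=rev.ap,
        query_size=hg.n,
        pathway_size=hg.m,
        overlap_size=hg.k,
        query_centrality=set_centrality(net, query),
        pathway_centrality=set_centrality(net, pathway),
        query_coverage=network_coverage(net, query),
    )


def _cached_profile(net, s, key, params, cache):
    prof = cache.get(key)
    if prof is None:
        prof = diffuse(net, s, params)
        cache[key] = prof
    return prof


# ---------------------------------------------------------------------------
# empirical FDR
# ---------------------------------------------------------------------------


class FdrCurve:
    """Monotone empirical FDR as a step function of the score.

    At each observed score s the raw ratio N(s) / (N(s) + P(s)) is computed
    from the area-normalized exceedance fractions of the negative and
    positive score distributions, then made non-increasing in s by isotonic
    regression (finite samples produce local inversions).  Above every
    observed score the FDR is 0; below, it is the value at the lowest score
    (0.5 when both distributions still have full mass).
    """

    def __init__(self, pos_scores: Sequence[float], neg_scores: Sequence[float]):
        pos = np.asarray(pos_scores, dtype=float)
        neg = np.asarray(neg_scores, dtype=float)
        if pos.size == 0 or neg.size == 0:
            raise ValueError("both score distributions must be non-empty")
        self.grid = np.unique(np.concatenate([pos, neg]))
        p_bar = np.array([(pos >= s).mean() for s in self.grid])
        n_bar = np.array([(neg >= s).mean() for s in self.grid])
        total = p_bar + n_bar
        raw = np.where(total > 0, n_bar / np.where(total > 0, total, 1.0), 0.0)
        iso = IsotonicRegression(increasing=False, y_min=0.0, y_max=1.0)
        self.values = iso.fit_transform(self.grid, raw)

    def __call__(self, s: float) -> float:
        # exceedance fractions only change at observed scores: evaluate at
        # the smallest grid point >= s
        i = int(np.searchsorted(self.grid, s, side="left"))
        if i >= self.grid.size:
            return 0.0
        return float(self.values[i])


def empirical_fdr(pos_scores: Sequence[float], neg_scores: Sequence[float], s: float) -> float:
    """Empirical FDR at score s from held-out positive/negative scores."""
    return FdrCurve(pos_scores, neg_scores)(s)


# ---------------------------------------------------------------------------
# training and scoring
# ---------------------------------------------------------------------------


@dataclass
class TrainReport:
    """Per-split sizes and accuracies plus the final-validation RAS
    distributions the empirical FDR is built from."""

    n_pos: int
    n_neg: int
    n_model: int
    n_cv: int
    n_validation: int
    accuracy_model: float
    accuracy_cv: float
    accuracy_validation: float
    validation_pos_scores: np.ndarray
    validation_neg_scores: np.ndarray


@dataclass
class CombinerModel:
    """Trained RBF-SVM combiner with its feature scaling and the validation
    score distributions needed to attach an empirical FDR to new scores."""

    version: str
    params: SvmParams
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    svc: SVC
    fdr_pos: np.ndarray
    fdr_neg: np.ndarray
    tag: str = ""
    _fdr_curve: FdrCurve | None = field(default=None, repr=False, compare=False)

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.feature_mean.size:
            raise ValueError(
                f"feature dimension mismatch: got {x.shape[1]}, expected {self.feature_mean.size}"
            )
        return (x - self.feature_mean) / self.feature_scale

    def decision(self, x: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(self.transform(x))

    @property
    def fdr_curve(self) -> FdrCurve:
        if self._fdr_curve is None:
            self._fdr_curve = FdrCurve(self.fdr_pos, self.fdr_neg)
        return self._fdr_curve

    def save(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "params": asdict(self.params),
            "feature_mean": self.feature_mean,
            "feature_scale": self.feature_scale,
            "svc": self.svc,
            "fdr_pos": self.fdr_pos,
            "fdr_neg": self.fdr_neg,
            "tag": self.tag,
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path: str | Path) -> "CombinerModel":
        payload = joblib.load(path)
        version = payload.get("version")
        if version != MODEL_VERSION:
            raise ValueError(
                f"model version mismatch: file has {version!r}, this build expects {MODEL_VERSION!r}"
            )
        return cls(
            version=version,
            params=SvmParams(**payload["params"]),
            feature_mean=payload["feature_mean"],
            feature_scale=payload["feature_scale"],
            svc=payload["svc"],
            fdr_pos=payload["fdr_pos"],
            fdr_neg=payload["fdr_neg"],
            tag=payload.get("tag", ""),
        )


def _as_matrix(fvs: Sequence[FeatureVector]) -> np.ndarray:
    x = np.vstack([fv.to_array() for fv in fvs])
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature value in training data")
    return x


def train_combiner(
    positives: Sequence[FeatureVector],
    negatives: Sequence[FeatureVector],
    params: SvmParams | None = None,
    seed: int = 0,
) -> tuple[CombinerModel, TrainReport]:
    """Train the weighted RBF-SVM on labelled feature vectors.

    The pooled data are split per class into modeling, cross-validation and
    final-validation subsets (default 25/25/50%).  Features are z-scored on
    the modeling split and the scaling is stored in the model so scoring is
    reproducible.  The final-validation decision-value distributions are
    retained for the empirical FDR.
    """
    params = params or SvmParams()
    if len(positives) < 20 or len(negatives) < 20:
        raise ValueError("need at least 20 examples per class")
    x_pos = _as_matrix(positives)
    x_neg = _as_matrix(negatives)

    rng = np.random.default_rng(seed)
    splits: dict[str, list[np.ndarray]] = {"model": [], "cv": [], "val": []}
    labels: dict[str, list[np.ndarray]] = {"model": [], "cv": [], "val": []}
    for x, y in ((x_pos, 1), (x_neg, 0)):
        perm = rng.permutation(x.shape[0])
        n_model = max(1, int(round(params.frac_model * x.shape[0])))
        n_cv = max(1, int(round(params.frac_cv * x.shape[0])))
        parts = {
            "model": x[perm[:n_model]],
            "cv": x[perm[n_model:n_model + n_cv]],
            "val": x[perm[n_model + n_cv:]],
        }
        for k, v in parts.items():
            splits[k].append(v)
            labels[k].append(np.full(v.shape[0], y))
    xs = {k: np.vstack(v) for k, v in splits.items()}
    ys = {k: np.concatenate(v) for k, v in labels.items()}

    mean = xs["model"].mean(axis=0)
    scale = xs["model"].std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)

    svc = SVC(
        kernel="rbf",
        C=params.C,
        gamma=params.gamma,
        tol=params.e,
        class_weight={1: params.w1, 0: params.w0},
    )
    svc.fit((xs["model"] - mean) / scale, ys["model"])

    model = CombinerModel(
        version=MODEL_VERSION,
        params=params,
        feature_mean=mean,
        feature_scale=scale,
        svc=svc,
        fdr_pos=np.empty(0),
        fdr_neg=np.empty(0),
        tag=params.tag,
    )
    acc = {k: float((svc.predict(model.transform(xs[k])) == ys[k]).mean()) for k in xs}
    val_scores = model.decision(xs["val"])
    model.fdr_pos = val_scores[ys["val"] == 1]
    model.fdr_neg = val_scores[ys["val"] == 0]

    report = TrainReport(
        n_pos=len(positives),
        n_neg=len(negatives),
        n_model=xs["model"].shape[0],
        n_cv=xs["cv"].shape[0],
        n_validation=xs["val"].shape[0],
        accuracy_model=acc["model"],
        accuracy_cv=acc["cv"],
        accuracy_validation=acc["val"],
        validation_pos_scores=model.fdr_pos,
        validation_neg_scores=model.fdr_neg,
    )
    return model, report


def ras_score(model: CombinerModel, fv: FeatureVector) -> float:
    """Signed SVM decision value for one feature vector (the RAS)."""
    return float(model.decision(fv.to_array())[0])


# ---------------------------------------------------------------------------
# library ranking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RasResult:
    """One query-pathway association: score, FDR, components, rank."""

    pathway_id: str
    ras: float
    fdr: float
    features: FeatureVector
    rank: int
    reciprocal_rank: float


def rank_pathways(
    net: GeneNetwork,
    model: CombinerModel,
    query: GeneSet,
    library: Iterable[GeneSet] | Mapping[str, GeneSet],
    cfg: RiddleConfig | None = None,
) -> list[RasResult]:
    """Score the query against every library set and rank by descending RAS
    (ties broken by pathway id).  Pathways with no in-network member are
    skipped with a log message."""
    cfg = cfg or RiddleConfig()
    if isinstance(library, Mapping):
        library = list(library.values())
    else:
        library = list(library)
    if not library:
        raise ValueError("pathway library is empty")

    cache: dict[frozenset[str], DiffusionProfile] = {}
    scored: list[tuple[str, float, FeatureVector]] = []
    for pw in library:
        if not pw.in_network(net):
            logger.warning("skipping pathway %r: no gene in the network", pw.id)
            continue
        fv = compute_features(net, query, pw, cfg, profile_cache=cache)
        scored.append((pw.id, ras_score(model, fv), fv))
    scored.sort(key=lambda t: (-t[1], t[0]))

    curve = model.fdr_curve
    return [
        RasResult(
            pathway_id=pid,
            ras=s,
            fdr=curve(s),
            features=fv,
            rank=i,
            reciprocal_rank=1.0 / i,
        )
        for i, (pid, s, fv) in enumerate(scored, start=1)
    ]


def write_results_tsv(results: Sequence[RasResult], path: str | Path,
                      header: Sequence[str] = ()) -> None:
    """Ranked results as TSV with component scores, '#'-prefixed header."""
    cols = [
        "pathway_id", "RAS", "FDR", "rank", "reciprocal_rank",
        "p_hg", "p_le_fwd", "p_le_rev", "auc_fwd", "auc_rev", "ap_fwd", "ap_rev",
        "overlap_size", "query_size", "pathway_size",
        "query_centrality", "pathway_centrality", "query_coverage",
    ]
    with Path(path).open("w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("\t".join(cols) + "\n")
        for r in results:
            f = r.features
            row = [
                r.pathway_id, f"{r.ras:.6g}", f"{r.fdr:.4g}", str(r.rank),
                f"{r.reciprocal_rank:.6g}",
                f"{math.exp(f.log_p_hg):.4g}", f"{math.exp(f.log_p_le_fwd):.4g}",
                f"{math.exp(f.log_p_le_rev):.4g}",
                f"{f.auc_fwd:.4f}", f"{f.auc_rev:.4f}", f"{f.ap_fwd:.4f}", f"{f.ap_rev:.4f}",
                str(f.overlap_size), str(f.query_size), str(f.pathway_size),
                f"{f.query_centrality:.4f}", f"{f.pathway_centrality:.4f}",
                f"{f.query_coverage:.4f}",
            ]
            fh.write("\t".join(row) + "\n")
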