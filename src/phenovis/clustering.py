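"""Per-date response vectors, clustering ensembles, and coassociation.

Each study date is summarized either as an **aggregate vector** (AV: one
component per section, the mean response in that section) or a **complete
vector** (CV: the schema-ordered concatenation of all question responses).
Dates are then clustered many times — with user-chosen k ("predefined") and
with k selected by silhouette ("natural") — and the ensemble is condensed
into a **coassociation matrix**: entry (i, j) is the fraction of partitions
placing dates i and j in the same cluster. Blocks of high coassociation mark
stretches of days with a shared behavioral regime; in relapse cases the
month before the event typically forms such a block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import silhouette_score

from .io import SurveySchema, SurveyTable, ValidationError


# ---------------------------------------------------------------------------
# Date vectors
# ---------------------------------------------------------------------------


def date_vectors(
    table: SurveyTable, kind: str = "AV", standardize: bool = False
) -> pd.DataFrame:
    """Dates x features matrix of AV or CV vectors for a complete one-patient
    table.

    AV columns follow schema section order; CV columns follow schema
    (section, question) order. Vectors are unstandardized by default —
    all components share the ordinal response scale — with an optional
    z-score mode.
    """
    if not table.is_complete:
        raise ValidationError("date vectors need a complete table; impute first")
    schema = table.schema
    if kind.upper() == "AV":
        out = (
            table.df.pivot_table(
                index="date", columns="section", values="response", aggfunc="mean"
            )
            .reindex(columns=list(schema.sections))
        )
    elif kind.upper() == "CV":
        wide = table.df.pivot_table(
            index="date",
            columns=["section", "question_id"],
            values="response",
            aggfunc="last",
        )
        cols = [
            (s, q) for s in schema.sections for q in schema.questions[s]
        ]
        out = wide.reindex(columns=pd.MultiIndex.from_tuples(cols))
        out.columns = [f"{s}:{q}" for s, q in cols]
    else:
        raise ValidationError(f"unknown vector kind {kind!r} (expected AV or CV)")
    if out.isna().any().any():
        raise ValidationError("incomplete date coverage across sections/questions")
    if standardize:
        sd = out.std(ddof=0).replace(0.0, 1.0)
        out = (out - out.mean()) / sd
    return out


def make_av(table: SurveyTable, date) -> np.ndarray:
    """Aggregate vector for one date: per-section mean responses."""
    day = pd.Timestamp(date).normalize()
    vecs = date_vectors(table, "AV")
    if day not in vecs.index:
        raise ValidationError(f"no responses on {day.date()}")
    return vecs.loc[day].to_numpy()


def make_cv(table: SurveyTable, date) -> np.ndarray:
    """Complete vector for one date: all responses, schema order."""
    day = pd.Timestamp(date).normalize()
    vecs = date_vectors(table, "CV")
    if day not in vecs.index:
        raise ValidationError(f"no responses on {day.date()}")
    return vecs.loc[day].to_numpy()


# ---------------------------------------------------------------------------
# Partitions
# ---------------------------------------------------------------------------


@dataclass
class Partition:
    """A clustering of dates; labels are meaningful only up to relabeling."""

    dates: pd.DatetimeIndex
    labels: np.ndarray
    method: str
    seed: int | None = None
    degenerate: bool = False

    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


def cluster_predefined(
    vectors: pd.DataFrame,
    k: int,
    method: str = "kmeans",
    seed: int = 0,
) -> Partition:
    """Cluster date vectors into a user-chosen number of clusters k.

    ``method`` is "kmeans" or "agglomerative" (Ward linkage). Euclidean
    distance throughout — the ordinal integer coding makes it the natural
    metric. Deterministic given ``seed``.
    """
    n = len(vectors)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > n:
        raise ValidationError(f"k={k} exceeds the {n} available dates")
    X = vectors.to_numpy(dtype=float)
    if method == "kmeans":
        model = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = model.fit_predict(X)
    elif method == "agglomerative":
        if k == n:
            labels = np.arange(n)
        else:
            labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)
    else:
        raise ValidationError(f"unknown clustering method {method!r}")
    return Partition(
        dates=pd.DatetimeIndex(vectors.index),
        labels=np.asarray(labels),
        method=f"{method}(k={k})",
        seed=seed,
    )


def cluster_natural(
    vectors: pd.DataFrame, k_max: int = 6, seed: int = 0
) -> Partition:
    """Let the data pick k: mean-silhouette argmax over k in [2, k_max] with
    a k-means base clusterer; silhouette ties break toward the smallest k.

    All-identical vectors have no cluster structure at all and return a
    single-cluster partition flagged degenerate.
    """
    n = len(vectors)
    X = vectors.to_numpy(dtype=float)
    if np.allclose(X, X[0]):
        return Partition(
            dates=pd.DatetimeIndex(vectors.index),
            labels=np.zeros(n, dtype=int),
            method="natural(degenerate)",
            seed=seed,
            degenerate=True,
        )
    if n < 4:
        raise ValidationError("natural clustering needs at least 4 dates")
    if k_max < 2:
        raise ValidationError("k_max must be >= 2")
    best_k, best_score, best_labels = None, -np.inf, None
    for k in range(2, min(k_max, n - 1) + 1):
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(X, labels)
        if score > best_score + 1e-12:  # strict improvement => smallest k wins ties
            best_k, best_score, best_labels = k, score, labels
    if best_labels is None:  # pragma: no cover - unreachable for non-identical X
        best_k, best_labels = 1, np.zeros(n, dtype=int)
    return Partition(
        dates=pd.DatetimeIndex(vectors.index),
        labels=np.asarray(best_labels),
        method=f"natural(k={best_k})",
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Ensemble + coassociation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnsembleConfig:
    """What goes into the clustering ensemble for one vector kind.

    The default mirrors a strength-in-numbers consensus: k-means and Ward
    agglomerative at several plausible k, plus silhouette-selected natural
    clustering, each restarted several times with distinct derived seeds.
    """

    strategies: tuple[str, ...] = ("predefined", "natural")
    methods: tuple[str, ...] = ("kmeans", "agglomerative")
    k_list: tuple[int, ...] = (2, 3, 4)
    k_max_natural: int = 6
    restarts: int = 5
    seed: int = 0


def build_ensemble(vectors: pd.DataFrame, config: EnsembleConfig) -> list[Partition]:
    """Run every configured (strategy, method, k) combination ``restarts``
    times with seeds derived deterministically from the master seed."""
    if not config.strategies:
        raise ValidationError("ensemble needs at least one strategy")
    jobs: list[tuple[str, str | None, int | None]] = []
    if "predefined" in config.strategies:
        n = len(vectors)
        for m in config.methods:
            for k in config.k_list:
                if 2 <= k <= n:
                    jobs.append(("predefined", m, k))
    if "natural" in config.strategies:
        jobs.append(("natural", None, None))
    if not jobs:
        raise ValidationError("ensemble config produced no jobs for this input")

    seeds = np.random.SeedSequence(config.seed).generate_state(
        len(jobs) * config.restarts
    )
    partitions = []
    for i, (strategy, method, k) in enumerate(jobs):
        for rep in range(config.restarts):
            s = int(seeds[i * config.restarts + rep] % (2**31))
            if strategy == "predefined":
                partitions.append(cluster_predefined(vectors, k, method, seed=s))
            else:
                partitions.append(
                    cluster_natural(vectors, k_max=config.k_max_natural, seed=s)
                )
    return partitions


def coassociation(partitions: list[Partition]) -> pd.DataFrame:
    """Consensus matrix: entry (i, j) = fraction of partitions in which dates
    i and j share a cluster. Symmetric with unit diagonal; entries are
    multiples of 1/E for an ensemble of E partitions."""
    if not partitions:
        raise ValidationError("coassociation needs at least one partition")
    dates = partitions[0].dates
    for p in partitions[1:]:
        if not p.dates.equals(dates):
            raise ValidationError("all partitions must cover the same date set")
    n = len(dates)
    acc = np.zeros((n, n))
    for p in partitions:
        same = p.labels[:, None] == p.labels[None, :]
        acc += same
    acc /= len(partitions)
    return pd.DataFrame(acc, index=dates, columns=dates)
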