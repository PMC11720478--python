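"""Target embeddings from response distributions, and projections.

The count-based route tabulates, for every target (used as a cue), the
distribution of responses it elicited — an N-targets x M-responses count
matrix.  Counts are reweighted with positive pointwise mutual information
(PPMI), which discounts globally frequent targets and responses, and
compressed with a truncated singular value decomposition; rows are
embedded as U_k S_k (the standard latent-semantic-analysis convention,
which preserves row dot products at full rank).

Alternatively, a pluggable :class:`EmbeddingProvider` maps each target
string to a fixed-dimension vector — the hook for sentence-transformer
style text-embedding models.  A deterministic :class:`HashEmbeddingProvider`
is included as a dependency-free stand-in with the same contract.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

from .errors import ConfigurationError, StateError, UsageError
from .study import AssociationStudy

logger = logging.getLogger(__name__)

EMBED_METHODS = ("ppmi-svd", "external")
PROJECTION_METHODS = ("pca", "mds", "umap")


@dataclass
class CountMatrix:
    """Target-by-response co-occurrence counts with cached margins."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray  # (N, M) non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise UsageError("count matrix shape does not match its labels")
        if (self.counts < 0).any():
            raise UsageError("counts must be non-negative")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.row_labels, columns=self.col_labels
        )


@dataclass
class EmbeddingMatrix:
    """N x k real vectors per target with provenance metadata."""

    labels: list[str]
    vectors: np.ndarray
    method: str = "ppmi-svd"
    seed: int | None = None
    provider: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.labels):
            raise UsageError("embedding needs one vector per target label")
        if not np.isfinite(self.vectors).all():
            raise UsageError("embedding vectors must be finite")

    @property
    def n_dim(self) -> int:
        return self.vectors.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.vectors,
            index=pd.Index(self.labels, name="target"),
            columns=[f"dim_{i + 1}" for i in range(self.n_dim)],
        )

    def to_csv(self, csv_path: str | Path, meta_path: str | Path) -> None:
        self.to_frame().to_csv(csv_path)
        meta = {
            "method": self.method,
            "n_dim": self.n_dim,
            "seed": self.seed,
            "provider": self.provider,
            **self.extra,
        }
        Path(meta_path).write_text(json.dumps(meta, indent=2), encoding="utf-8")

    @classmethod
    def from_csv(cls, csv_path: str | Path, meta_path: str | Path) -> "EmbeddingMatrix":
        frame = pd.read_csv(csv_path, index_col=0)
        meta = json.loads(Path(meta_path).read_text(encoding="utf-8"))
        extra = {
            k: v
            for k, v in meta.items()
            if k not in ("method", "n_dim", "seed", "provider")
        }
        return cls(
            labels=[str(x) for x in frame.index],
            vectors=frame.to_numpy(dtype=float),
            method=meta.get("method", "unknown"),
            seed=meta.get("seed"),
            provider=meta.get("provider"),
            extra=extra,
        )


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Contract for external text-embedding backends.

    ``embed`` must be deterministic within a provider instance: the same
    text always yields the same vector.
    """

    identifier: str

    def embed(self, texts: Sequence[str]) -> np.ndarray:  # pragma: no cover
        ...


class HashEmbeddingProvider:
    """Deterministic mock provider: hash-seeded Gaussian unit vectors.

    Each text is mapped to a fixed vector derived from the SHA-256 digest
    of the text (plus an instance salt), so results are reproducible
    across processes and platforms.  Useful for testing the external
    embedding path without network access; the vectors carry no semantics.
    """

    def __init__(self, n_dim: int = 16, salt: int = 0) -> None:
        if n_dim < 1:
            raise UsageError("n_dim must be >= 1")
        self.n_dim = n_dim
        self.salt = salt
        self.identifier = f"hash-gaussian-{n_dim}d-salt{salt}"

    def _vector(self, text: str) -> np.ndarray:
        digest = hashlib.sha256(f"{self.salt}|{text}".encode("utf-8")).digest()
        seed = int.from_bytes(digest[:4], "big")
        rng = np.random.default_rng(seed)
        vec = rng.standard_normal(self.n_dim)
        return vec / np.linalg.norm(vec)

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        return np.stack([self._vector(t) for t in texts])


def build_count_matrix(
    study: AssociationStudy, responses: pd.DataFrame | None = None
) -> CountMatrix:
    """Tabulate the response distribution of every target used as a cue.

    Requires targets drawn from cues only: when responses are part of the
    target set there is no further response level left to tabulate, and a
    response-based embedding is infeasible.
    """
    if study.targets is None:
        raise StateError("targets must be set before building a count matrix")
    if study.meta.get("targets_source", "cues") != "cues":
        raise UsageError(
            "response-based embeddings require targets drawn from cues only "
            f"(targets_source={study.meta.get('targets_source')!r}); there is "
            "no deeper response level to tabulate for response targets"
        )
    frame = study.responses if responses is None else responses
    targets = study.target_list()
    never_cued = sorted(set(targets) - set(frame["cue"]))
    if never_cued:
        shown = ", ".join(never_cued[:10])
        raise UsageError(
            f"{len(never_cued)} target(s) never occur as cues ({shown}...); "
            "cannot tabulate their response distributions"
        )
    return _count_matrix(frame, targets)


def _count_matrix(frame: pd.DataFrame, targets: Sequence[str]) -> CountMatrix:
    """Cross-tabulate cue x response restricted to target cues.

    Targets with zero response tokens are dropped with a warning (an
    all-zero row has no distributional information).
    """
    sub = frame[frame["cue"].isin(set(targets))]
    table = pd.crosstab(sub["cue"], sub["response"])
    kept = [t for t in targets if t in table.index and table.loc[t].sum() > 0]
    dropped = [t for t in targets if t not in kept]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} target(s) with no responses: "
            + ", ".join(dropped[:10]),
            stacklevel=2,
        )
    table = table.loc[kept]
    table = table.loc[:, table.sum(axis=0) > 0]
    return CountMatrix(
        row_labels=list(table.index),
        col_labels=list(table.columns),
        counts=table.to_numpy(dtype=float),
    )


def ppmi(counts: CountMatrix | np.ndarray, smoothing: float | None = None) -> np.ndarray:
    """Positive pointwise mutual information reweighting.

    cell(t, r) = max(0, ln[(n_tr * n_..)/(n_t. * n_.r)]); structural zeros
    stay zero.  ``smoothing`` optionally raises the context (column)
    distribution to a power alpha < 1 before normalization, damping the
    penalty on rare responses; default is plain PPMI.
    """
    if isinstance(counts, CountMatrix):
        matrix = counts.counts
    else:
        matrix = np.asarray(counts, dtype=float)
    total = matrix.sum()
    if total <= 0:
        raise UsageError("count matrix grand total must be positive")
    row = matrix.sum(axis=1, keepdims=True)
    col = matrix.sum(axis=0, keepdims=True)
    if smoothing is not None:
        col = col**smoothing
    col_p = col / col.sum()  # context probability (smoothed when requested)
    with np.errstate(divide="ignore", invalid="ignore"):
        # ln[ p(t,r) / (p(t) p(r)) ] = ln[ n_tr / (n_t. * p(r)) ]
        pmi = np.log(matrix / (row * col_p))
    pmi = np.where(matrix > 0, pmi, 0.0)
    return np.maximum(pmi, 0.0)


def svd_embed(
    weighted: np.ndarray,
    n_dim: int,
    labels: Sequence[str] | None = None,
) -> EmbeddingMatrix:
    """Embed rows as U_k S_k from the rank-k truncated SVD.

    Singular values are ordered descending, and each left singular
    vector's sign is fixed by forcing its largest-magnitude entry
    positive, so repeated runs produce identical matrices.  ``n_dim``
    larger than min(N, M) is capped with a warning.
    """
    weighted = np.asarray(weighted, dtype=float)
    n, m = weighted.shape
    if n_dim < 1:
        raise UsageError("n_dim must be >= 1")
    if n_dim > min(n, m):
        warnings.warn(
            f"n_dim={n_dim} exceeds min(N, M)={min(n, m)}; capping",
            stacklevel=2,
        )
        n_dim = min(n, m)
    u, s, _ = np.linalg.svd(weighted, full_matrices=False)
    u, s = u[:, :n_dim], s[:n_dim]
    # deterministic sign convention
    for k in range(n_dim):
        pivot = np.argmax(np.abs(u[:, k]))
        if u[pivot, k] < 0:
            u[:, k] = -u[:, k]
    if labels is None:
        labels = [str(i) for i in range(n)]
    return EmbeddingMatrix(
        labels=list(labels),
        vectors=u * s,
        method="ppmi-svd",
        extra={"singular_values": s.tolist()},
    )


def default_n_dim(n: int, m: int) -> int:
    return max(1, min(100, min(n, m) - 1))


def embed_targets(
    study: AssociationStudy,
    method: str = "ppmi-svd",
    n_dim: int | None = None,
    provider: EmbeddingProvider | None = None,
    seed: int | None = None,
    smoothing: float | None = None,
) -> AssociationStudy:
    """Attach an :class:`EmbeddingMatrix` for the study's targets."""
    if study.targets is None:
        raise StateError("targets must be set before embedding")
    if method not in EMBED_METHODS:
        raise UsageError(f"method must be one of {EMBED_METHODS}")
    out = study.copy()
    if method == "ppmi-svd":
        counts = build_count_matrix(out)
        weighted = ppmi(counts, smoothing=smoothing)
        k = n_dim or default_n_dim(*weighted.shape)
        embedding = svd_embed(weighted, k, labels=counts.row_labels)
        embedding.seed = seed
        embedding.extra["smoothing"] = smoothing
    else:
        if provider is None:
            raise ConfigurationError(
                "method='external' requires an EmbeddingProvider instance"
            )
        targets = out.target_list()
        rows = []
        for text in targets:
            try:
                vec = np.asarray(provider.embed([text]))[0]
            except Exception as exc:  # noqa: BLE001
                raise ConfigurationError(
                    f"embedding provider {provider.identifier!r} failed on "
                    f"target {text!r}: {exc}"
                ) from exc
            rows.append(vec)
        embedding = EmbeddingMatrix(
            labels=targets,
            vectors=np.stack(rows),
            method="external",
            seed=seed,
            provider=provider.identifier,
        )
        if n_dim is not None and n_dim != embedding.n_dim:
            raise UsageError(
                f"provider emits {embedding.n_dim}-d vectors; cannot honour "
                f"n_dim={n_dim}"
            )
    out.embedding = embedding
    return out


def _classical_mds(vectors: np.ndarray, n_dim: int) -> np.ndarray:
    """Torgerson scaling of cosine distances (deterministic).

    Double-centers the squared cosine-distance matrix and keeps the top
    eigenvectors scaled by sqrt(eigenvalue); identical input rows map to
    identical points.
    """
    from sklearn.metrics.pairwise import cosine_distances

    d = cosine_distances(vectors)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:n_dim]
    eigval = np.clip(eigval[order], 0, None)
    coords = eigvec[:, order] * np.sqrt(eigval)
    for k in range(coords.shape[1]):
        pivot = np.argmax(np.abs(coords[:, k]))
        if coords[pivot, k] < 0:
            coords[:, k] = -coords[:, k]
    return coords


def project_embedding(
    embedding: EmbeddingMatrix,
    method: str = "umap",
    n_dim: int = 2,
    seed: int | None = None,
    **kwargs,
) -> EmbeddingMatrix:
    """Project an embedding to low dimension (pca, mds, or umap).

    UMAP has stochastic components; pass ``seed`` for exact
    reproducibility.  PCA and the classical metric MDS used here are
    deterministic.
    """
    if method not in PROJECTION_METHODS:
        raise UsageError(f"method must be one of {PROJECTION_METHODS}")
    if n_dim >= embedding.n_dim and method != "pca":
        raise UsageError(
            f"projection n_dim={n_dim} must be below the embedding "
            f"dimensionality k={embedding.n_dim}"
        )
    x = embedding.vectors
    if method == "pca":
        from sklearn.decomposition import PCA

        coords = PCA(
            n_components=min(n_dim, min(x.shape)), svd_solver="full",
            random_state=seed,
        ).fit_transform(x)
    elif method == "mds":
        coords = _classical_mds(x, n_dim)
    else:
        import umap

        reducer = umap.UMAP(
            n_components=n_dim,
            random_state=seed if seed is not None else 42,
            **kwargs,
        )
        coords = np.asarray(reducer.fit_transform(x), dtype=float)
    return EmbeddingMatrix(
        labels=list(embedding.labels),
        vectors=coords,
        method="projection",
        seed=seed,
        provider=embedding.provider,
        extra={"projection": method, "source_method": embedding.method},
    )


def project_study(
    study: AssociationStudy,
    method: str = "umap",
    n_dim: int = 2,
    seed: int | None = None,
    **kwargs,
) -> AssociationStudy:
    """Replace the study's embedding with its low-dimensional projection."""
    if study.embedding is None:
        raise StateError("no embedding present; call embed_targets first")
    out = study.copy()
    out.embedding = project_embedding(
        study.embedding, method=method, n_dim=n_dim, seed=seed, **kwargs
    )
    return out
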