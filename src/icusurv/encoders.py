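"""Per-subject feature encoders.

Three text-feature families are supported, mirroring how radiology reports
can enter a survival model at increasing levels of abstraction:

* ``labels`` — the 14 binary finding indicators, passed through unchanged;
* ``transformer`` — average pooling of the per-token embedding matrix
  (m x d, d = 768 by default) into a single d-vector;
* ``gcn`` — a graph convolutional encoder over a concept graph whose nodes
  are the 14 findings: node features are initialised by a 1-D convolution
  over the token axis (one output channel per node, valid padding, mean
  aggregation over positions), then propagated through two layers

      H1 = ReLU(A_hat @ H0 @ W0 + b0)
      Z  = softmax(A_hat @ H1 @ W1 + b1)        (softmax per node row)

  with ``A_hat = D^{-1/2} (A + I) D^{-1/2}`` the symmetrically normalised
  self-looped adjacency, precomputed once.

The GCN parameters are frozen at (seeded) initialisation — the encoder is a
fixed feature extractor, like the pretrained language/image backbones it
stands in for; only the downstream fusion heads are trained.

Image features arrive as precomputed vectors (1024-dim by default) through an
:class:`EmbeddingProvider`; the bundled providers are a seeded synthetic one
and a file-backed one reading a cohort archive.  Extraction from real reports
or images is a third-party plug-in behind the same interface.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Protocol

import numpy as np

from . import findings
from .synthetic import CohortConfig, SubjectRecord, generate_embeddings

__all__ = [
    "ConceptGraph",
    "GCNParams",
    "default_concept_graph",
    "normalize_adjacency",
    "pool_token_embeddings",
    "init_node_features",
    "gcn_forward",
    "encode_text",
    "encode_saps_factors",
    "EmbeddingProvider",
    "SyntheticEmbeddingProvider",
    "FileBackedEmbeddingProvider",
    "SAPS_FACTOR_SCALING",
]


# ---------------------------------------------------------------------------
# concept graph


@dataclass
class ConceptGraph:
    """Undirected binary graph over the finding nodes.

    ``adjacency`` is symmetric with zero diagonal (self-loops are added
    during normalisation, not stored).
    """

    adjacency: np.ndarray
    node_names: list[str]

    def __post_init__(self):
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if A.shape[0] != len(self.node_names):
            raise ValueError("node_names length must match adjacency size")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if not np.all(np.isin(A, (0.0, 1.0))):
            raise ValueError("adjacency must be binary")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must have zero diagonal")
        self.adjacency = A

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @classmethod
    def from_json(cls, path: str | Path) -> "ConceptGraph":
        payload = json.loads(Path(path).read_text())
        return cls._from_payload(payload)

    @classmethod
    def _from_payload(cls, payload: dict) -> "ConceptGraph":
        nodes = list(payload["nodes"])
        n = len(nodes)
        A = np.zeros((n, n))
        for i, j in payload["edges"]:
            A[i, j] = A[j, i] = 1.0
        return cls(adjacency=A, node_names=nodes)

    def to_json(self, path: str | Path) -> None:
        edges = [
            [int(i), int(j)]
            for i, j in zip(*np.nonzero(np.triu(self.adjacency)))
        ]
        Path(path).write_text(
            json.dumps({"nodes": self.node_names, "edges": edges}, indent=2)
        )


def default_concept_graph() -> ConceptGraph:
    """The bundled 14-node finding hierarchy."""
    ref = resources.files("icusurv.data").joinpath("concept_graph.json")
    return ConceptGraph._from_payload(json.loads(ref.read_text()))


def normalize_adjacency(graph: ConceptGraph) -> np.ndarray:
    """A_hat = D^{-1/2} (A + I) D^{-1/2}, with D the self-looped degree matrix.

    Symmetric; eigenvalues lie in [-1, 1].  The input adjacency is never
    mutated; recomputation yields an identical matrix.
    """
    A_tilde = graph.adjacency + np.eye(graph.n_nodes)
    d = A_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return inv_sqrt[:, None] * A_tilde * inv_sqrt[None, :]


# ---------------------------------------------------------------------------
# token pooling and GCN


def pool_token_embeddings(tokens: np.ndarray) -> np.ndarray:
    """Column-wise mean of an m x d token-embedding matrix."""
    tokens = np.asarray(tokens, dtype=float)
    if tokens.ndim != 2 or tokens.shape[0] < 1:
        raise ValueError(f"expected a nonempty m x d matrix, got shape {tokens.shape}")
    if not np.all(np.isfinite(tokens)):
        raise ValueError("token embeddings contain non-finite entries")
    return tokens.mean(axis=0)


@dataclass
class GCNParams:
    """Frozen parameters of the GCN text encoder.

    ``conv_weights`` has shape (N, k): one length-k kernel per graph node,
    applied along the token axis (shared across embedding dimensions), so the
    node features keep the embedding width d.  ``W0``: (d, hidden_dim);
    ``W1``: (hidden_dim, output_dim).
    """

    conv_weights: np.ndarray
    W0: np.ndarray
    b0: np.ndarray
    W1: np.ndarray
    b1: np.ndarray

    @property
    def kernel_size(self) -> int:
        return self.conv_weights.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.conv_weights.shape[0]

    @property
    def hidden_dim(self) -> int:
        return self.W0.shape[1]

    @property
    def output_dim(self) -> int:
        return self.W1.shape[1]

    def __post_init__(self):
        if self.W0.shape[1] != self.W1.shape[0]:
            raise ValueError(
                f"W0 output dim {self.W0.shape[1]} != W1 input dim {self.W1.shape[0]}"
            )
        if self.b0.shape != (self.W0.shape[1],):
            raise ValueError("b0 shape inconsistent with W0")
        if self.b1.shape != (self.W1.shape[1],):
            raise ValueError("b1 shape inconsistent with W1")

    @classmethod
    def initialize(
        cls,
        *,
        n_nodes: int = findings.N_LABELS,
        embed_dim: int = 768,
        hidden_dim: int = 64,
        output_dim: int = 2,
        kernel_size: int = 3,
        seed: int = 0,
    ) -> "GCNParams":
        """Glorot-uniform seeded initialisation."""
        rng = np.random.default_rng([seed, 4201])

        def glorot(shape):
            limit = np.sqrt(6.0 / sum(shape))
            return rng.uniform(-limit, limit, size=shape)

        return cls(
            conv_weights=glorot((n_nodes, kernel_size)),
            W0=glorot((embed_dim, hidden_dim)),
            b0=np.zeros(hidden_dim),
            W1=glorot((hidden_dim, output_dim)),
            b1=np.zeros(output_dim),
        )


def init_node_features(tokens: np.ndarray, params: GCNParams) -> np.ndarray:
    """H0: one d-length feature row per graph node.

    Valid (unpadded) 1-D convolution of the token sequence with each node's
    kernel, then mean over the m - k + 1 positions, so every token
    contributes to every node's initial state.
    """
    tokens = np.asarray(tokens, dtype=float)
    m = tokens.shape[0]
    k = params.kernel_size
    if m < k:
        raise ValueError(
            f"report has {m} tokens but the convolution kernel needs k={k}; "
            "pad the token matrix or reduce kernel_size"
        )
    windows = np.lib.stride_tricks.sliding_window_view(tokens, k, axis=0)  # (m-k+1, d, k)
    h0 = np.einsum("pdk,ck->cd", windows, params.conv_weights) / (m - k + 1)
    return h0


def _softmax_rows(x: np.ndarray) -> np.ndarray:
    shifted = x - x.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def gcn_forward(h0: np.ndarray, a_hat: np.ndarray, params: GCNParams) -> np.ndarray:
    """Two-layer propagation: Z = softmax(A_hat @ ReLU(A_hat @ H0 @ W0 + b0) @ W1 + b1)."""
    h0 = np.asarray(h0, dtype=float)
    a_hat = np.asarray(a_hat, dtype=float)
    n = a_hat.shape[0]
    if a_hat.shape != (n, n):
        raise ValueError(f"A_hat must be square, got {a_hat.shape}")
    if h0.shape[0] != n:
        raise ValueError(f"H0 has {h0.shape[0]} rows but A_hat has {n} nodes")
    if h0.shape[1] != params.W0.shape[0]:
        raise ValueError(
            f"H0 feature dim {h0.shape[1]} != W0 input dim {params.W0.shape[0]}"
        )
    h1 = np.maximum(a_hat @ h0 @ params.W0 + params.b0, 0.0)
    return _softmax_rows(a_hat @ h1 @ params.W1 + params.b1)


# ---------------------------------------------------------------------------
# per-record encoding

TEXT_MODES = ("labels", "transformer", "gcn")


def encode_text(
    record: SubjectRecord,
    mode: str,
    *,
    gcn_params: GCNParams | None = None,
    a_hat: np.ndarray | None = None,
) -> np.ndarray:
    """Fixed-length text feature vector for one subject.

    ``labels`` passes the 14-vector through; ``transformer`` average-pools the
    token embeddings (length d); ``gcn`` runs the graph encoder and flattens
    Z row-major (length N * output_dim).
    """
    if mode == "labels":
        return np.asarray(record.labels, dtype=float)
    if record.token_embeddings is None:
        raise ValueError(f"mode {mode!r} requires token embeddings, record has none")
    if mode == "transformer":
        return pool_token_embeddings(record.token_embeddings)
    if mode == "gcn":
        if gcn_params is None or a_hat is None:
            raise ValueError("gcn mode requires gcn_params and a precomputed a_hat")
        h0 = init_node_features(record.token_embeddings, gcn_params)
        return gcn_forward(h0, a_hat, gcn_params).ravel()
    raise ValueError(f"unknown text mode {mode!r}; expected one of {TEXT_MODES}")


#: Reference (center, scale) used to standardise the continuous factors, plus
#: integer codes for the categoricals; fixed so encodings are portable.
SAPS_FACTOR_SCALING: dict[str, tuple[float, float]] = {
    "age": (65.0, 16.0),
    "heart_rate": (88.0, 20.0),
    "systolic_bp": (120.0, 23.0),
    "temperature": (37.0, 0.8),
    "pao2_fio2_ratio": (250.0, 80.0),
    "urine_output": (1900.0, 900.0),
    "bun": (28.0, 18.0),
    "sodium": (139.0, 4.7),
    "potassium": (4.1, 0.56),
    "bicarbonate": (24.0, 4.3),
    "bilirubin": (1.2, 1.5),
    "wbc": (10.6, 4.0),
    "gcs": (13.3, 2.6),
}

_CHRONIC_CODE = {"none": 0.0, "metastatic_cancer": 1.0, "hematologic_malignancy": 2.0, "aids": 3.0}
_ADMISSION_CODE = {"scheduled_surgical": 0.0, "medical": 1.0, "unscheduled_surgical": 2.0}


def encode_saps_factors(record: SubjectRecord) -> np.ndarray:
    """15-vector of standardised risk factors (model input for the saps head).

    Continuous factors are z-scored against fixed reference constants; a
    missing PaO2/FiO2 ratio (not ventilated) encodes as 0 (the reference
    value); the two categoricals enter as small integer codes.
    """
    f = record.risk_factors
    out = []
    for name, (center, scale) in SAPS_FACTOR_SCALING.items():
        value = getattr(f, name)
        out.append(0.0 if value is None else (float(value) - center) / scale)
    out.append(_CHRONIC_CODE[f.chronic_disease])
    out.append(_ADMISSION_CODE[f.admission_type])
    return np.array(out)


# ---------------------------------------------------------------------------
# embedding providers


class EmbeddingProvider(Protocol):
    """Maps a subject to its (token_embeddings, image_embedding) pair."""

    def get(self, record: SubjectRecord) -> tuple[np.ndarray, np.ndarray]: ...


class SyntheticEmbeddingProvider:
    """Seeded on-the-fly surrogate embeddings (default provider).

    Deterministic per subject: the draw is keyed by the cohort seed and a
    CRC of the subject identifier, so repeated calls agree.
    """

    def __init__(self, config: CohortConfig):
        self.config = config

    def get(self, record: SubjectRecord) -> tuple[np.ndarray, np.ndarray]:
        key = zlib.crc32(record.subject_id.encode()) & 0x7FFFFFFF
        rng = np.random.default_rng([self.config.seed, 7100, key])
        return generate_embeddings(record.labels, self.config, rng)


class FileBackedEmbeddingProvider:
    """Reads embeddings from a cohort archive written by ``save_cohort``."""

    def __init__(self, npz_path: str | Path):
        self._archive = np.load(Path(npz_path))

    def get(self, record: SubjectRecord) -> tuple[np.ndarray, np.ndarray]:
        sid = record.subject_id
        try:
            return self._archive[f"tok_{sid}"], self._archive[f"img_{sid}"]
        except KeyError as exc:
            raise KeyError(f"subject {sid!r} not in embedding archive") from exc
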