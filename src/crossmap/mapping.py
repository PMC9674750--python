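"""Linear zero-shot mapping from a language space onto a visual feature space.

The mapping is the matrix ``M`` minimising ``sum ||v - M'l||^2`` over
training pairs of word vectors ``l`` and (SVD-reduced) visual vectors ``v``
— a multivariate linear regression without intercept, so a predicted visual
vector for any word, including words outside the training set, is simply
``v_hat = l @ M``.

Two training regimes are supported.  In the *prototype* regime each label
contributes one pair, its mean image vector; in the *exemplar* regime each
label contributes ``k`` individual image vectors.  The visual side is
reduced by truncated SVD separately per regime before fitting.

The module exposes a statsmodels-flavoured surface: build a
:class:`CrossModalMapping` from a language space and an image inventory,
call :meth:`~CrossModalMapping.fit` and obtain a :class:`MappingModel`
results object that predicts, retrieves images, and serializes itself.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .inventory import ImageInventory, PrototypeSet, compute_prototypes, sample_exemplars
from .spaces import SvdReduction, VectorSpace, svd_reduce

__all__ = [
    "TrainingSet",
    "MappingModel",
    "CrossModalMapping",
    "build_training_set",
    "fit_mapping",
    "retrieve_image",
    "pick_random_control",
]

REGIMES = ("prototype", "exemplar")


@dataclass
class TrainingSet:
    """Aligned language/vision training pairs for one regime.

    ``language`` is ``(n, d_lang)``, ``vision`` is ``(n, d')`` (already
    SVD-reduced), ``labels`` gives the word for each pair.  The prototype
    regime has exactly one pair per label; the exemplar regime has ``k``.
    """

    labels: list[str]
    language: np.ndarray
    vision: np.ndarray
    regime: str

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        n = len(self.labels)
        if self.language.shape[0] != n or self.vision.shape[0] != n:
            raise ValueError("labels, language and vision must align")
        if self.regime == "prototype" and len(set(self.labels)) != n:
            raise ValueError("prototype regime requires one pair per label")

    @property
    def n_pairs(self) -> int:
        return len(self.labels)


def build_training_set(
    lang: VectorSpace,
    vis: ImageInventory | PrototypeSet,
    regime: str = "prototype",
    target_dim: int = 300,
    exemplar_k: int = 20,
    seed: int | None = None,
    normalize_language: bool = False,
) -> tuple[TrainingSet, SvdReduction]:
    """Assemble (word vector, reduced visual vector) pairs for one regime.

    The visual matrix is reduced to ``target_dim`` by truncated SVD,
    independently for each regime; language vectors are used as-is unless
    ``normalize_language`` rescales each to unit length (off by default:
    whether embeddings should be length-normalised before mapping is an
    open modelling choice).  Every visual label must exist in ``lang``.
    """
    if regime not in REGIMES:
        raise ValueError(f"regime must be one of {REGIMES}")

    if regime == "prototype":
        protos = vis if isinstance(vis, PrototypeSet) else compute_prototypes(vis)
        pair_labels = list(protos.labels)
        vis_matrix = protos.space.matrix
    else:
        if isinstance(vis, PrototypeSet):
            raise TypeError("exemplar regime requires an ImageInventory")
        ex = sample_exemplars(vis, k=exemplar_k, seed=seed)
        pair_labels = list(ex.labels)
        vis_matrix = ex.matrix

    missing = sorted(set(pair_labels) - set(lang.labels))
    if missing:
        raise KeyError(f"labels missing from the language space: {missing[:10]}"
                       + ("..." if len(missing) > 10 else ""))

    reduction = svd_reduce(vis_matrix, target_dim=target_dim)
    L = np.vstack([lang.vector(lab) for lab in pair_labels])
    if normalize_language:
        norms = np.linalg.norm(L, axis=1, keepdims=True)
        if np.any(norms == 0.0):
            raise ValueError("cannot normalize a zero language vector")
        L = L / norms
    return TrainingSet(pair_labels, L, reduction.reduced, regime), reduction


@dataclass
class MappingModel:
    """Fitted language-to-vision map: results object of :class:`CrossModalMapping`.

    ``M`` is ``(input_dim, output_dim)``; predictions are ``l @ M``.
    ``projection`` is the SVD reduction the visual training targets lived
    in, so new raw visual vectors can be projected into the model's space.
    """

    M: np.ndarray
    regime: str
    projection: SvdReduction | None
    training_labels: list[str]
    rank: int | None = None
    residual_sumsq: float | None = None
    n_pairs: int | None = None

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if not np.all(np.isfinite(self.M)):
            raise ValueError("M contains non-finite values")
        if not self.training_labels:
            raise ValueError("training_labels must be nonempty")

    @property
    def input_dim(self) -> int:
        return self.M.shape[0]

    @property
    def output_dim(self) -> int:
        return self.M.shape[1]

    def predict(self, l: np.ndarray) -> np.ndarray:
        """Predicted visual vector(s) ``v_hat = l @ M`` for 1-D or 2-D input."""
        l = np.asarray(l, dtype=float)
        if l.shape[-1] != self.input_dim:
            raise ValueError(
                f"language vector has dim {l.shape[-1]}, expected {self.input_dim}"
            )
        return l @ self.M

    def retrieve(
        self,
        l: np.ndarray,
        images: ImageInventory,
        prototypes: PrototypeSet | None = None,
        scheme: str | None = None,
    ) -> str:
        """Predict from ``l`` and retrieve the matching image id."""
        scheme = scheme or self.regime
        return retrieve_image(self.predict(l), images, prototypes, scheme)

    def summary(self) -> str:
        lines = [
            "Cross-modal linear mapping (least squares, no intercept)",
            "=" * 56,
            f"regime:           {self.regime}",
            f"input dim:        {self.input_dim}",
            f"output dim:       {self.output_dim}",
            f"training pairs:   {self.n_pairs if self.n_pairs is not None else len(self.training_labels)}",
            f"training labels:  {len(set(self.training_labels))}",
            f"solver rank:      {self.rank}",
        ]
        if self.residual_sumsq is not None:
            lines.append(f"residual SSQ:     {self.residual_sumsq:.6g}")
        return "\n".join(lines)

    # --- serialization: JSON manifest + TSV matrix payloads -------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "regime": self.regime,
            "input_dim": self.input_dim,
            "output_dim": self.output_dim,
            "rank": self.rank,
            "residual_sumsq": self.residual_sumsq,
            "n_pairs": self.n_pairs,
            "training_labels": self.training_labels,
            "singular_values": (
                self.projection.singular_values.tolist() if self.projection else None
            ),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
        np.savetxt(directory / "M.tsv", self.M, delimiter="\t", fmt="%.12g")
        if self.projection is not None:
            np.savetxt(
                directory / "projection.tsv",
                self.projection.projection,
                delimiter="\t",
                fmt="%.12g",
            )

    @classmethod
    def load(cls, directory: str | Path) -> "MappingModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        M = np.loadtxt(directory / "M.tsv", delimiter="\t", ndmin=2)
        projection = None
        proj_path = directory / "projection.tsv"
        if proj_path.exists():
            proj = np.loadtxt(proj_path, delimiter="\t", ndmin=2)
            sv = np.asarray(manifest.get("singular_values") or [])
            reduced = np.empty((0, proj.shape[1]))
            projection = SvdReduction(reduced, proj, sv)
        return cls(
            M,
            manifest["regime"],
            projection,
            list(manifest["training_labels"]),
            rank=manifest.get("rank"),
            residual_sumsq=manifest.get("residual_sumsq"),
            n_pairs=manifest.get("n_pairs"),
        )


class CrossModalMapping:
    """Model object: least-squares map from word vectors to visual vectors.

    Construct from an already-assembled :class:`TrainingSet` (plus its SVD
    reduction), or use :meth:`from_spaces` to build the training set from a
    language space and an image inventory directly.
    """

    def __init__(self, training_set: TrainingSet, projection: SvdReduction | None = None):
        self.training_set = training_set
        self.projection = projection

    @classmethod
    def from_spaces(
        cls,
        lang: VectorSpace,
        vis: ImageInventory | PrototypeSet,
        regime: str = "prototype",
        target_dim: int = 300,
        exemplar_k: int = 20,
        seed: int | None = None,
        normalize_language: bool = False,
    ) -> "CrossModalMapping":
        ts, reduction = build_training_set(
            lang, vis, regime=regime, target_dim=target_dim,
            exemplar_k=exemplar_k, seed=seed,
            normalize_language=normalize_language,
        )
        return cls(ts, reduction)

    def fit(self, ridge: float = 0.0, cutoff: float = 1e-10) -> MappingModel:
        """Estimate ``M`` by least squares (pseudoinverse, rank-revealing).

        ``ridge`` adds an L2 penalty ``ridge * ||M||^2`` (off by default;
        the plain model has neither intercept nor regularisation).
        ``cutoff`` is the relative singular-value cutoff of the solver.
        """
        ts = self.training_set
        L, V = ts.language, ts.vision
        if np.allclose(L, 0.0):
            raise np.linalg.LinAlgError("language matrix is identically zero")
        if ts.n_pairs < L.shape[1]:
            warnings.warn(
                f"fewer training pairs ({ts.n_pairs}) than input dimensions "
                f"({L.shape[1]}); the map is underdetermined",
                stacklevel=2,
            )
        if ridge > 0.0:
            d = L.shape[1]
            A = L.T @ L + ridge * np.eye(d)
            M = np.linalg.solve(A, L.T @ V)
            rank = d
        else:
            M, _, rank, _ = np.linalg.lstsq(L, V, rcond=cutoff)
        resid = float(np.sum((V - L @ M) ** 2))
        return MappingModel(
            M,
            ts.regime,
            self.projection,
            list(ts.labels),
            rank=int(rank),
            residual_sumsq=resid,
            n_pairs=ts.n_pairs,
        )


def fit_mapping(
    ts: TrainingSet,
    projection: SvdReduction | None = None,
    ridge: float = 0.0,
    cutoff: float = 1e-10,
) -> MappingModel:
    """Functional wrapper around :class:`CrossModalMapping` + ``fit``."""
    return CrossModalMapping(ts, projection).fit(ridge=ridge, cutoff=cutoff)


def _cosine_to_all(v: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    nv = np.linalg.norm(v)
    if nv == 0.0:
        raise ValueError("cannot retrieve with a zero prediction vector")
    norms = np.linalg.norm(matrix, axis=1)
    if np.any(norms == 0.0):
        raise ValueError("retrieval pool contains a zero vector")
    return (matrix @ v) / (norms * nv)


def retrieve_image(
    v_hat: np.ndarray,
    images: ImageInventory,
    prototypes: PrototypeSet | None = None,
    scheme: str = "exemplar",
) -> str:
    """Retrieve the image id matching a predicted visual vector.

    *exemplar* scheme: the image whose vector has maximal cosine to
    ``v_hat`` over the whole inventory.  *prototype* scheme: first find the
    prototype most similar to ``v_hat``, then within that label the image
    most similar to the *prototype* (not to ``v_hat``).  Both the images
    and the prototypes must live in the model's reduced space.  Ties are
    broken by lexicographic image id / label.
    """
    if len(images) == 0:
        raise ValueError("empty image inventory")
    v_hat = np.asarray(v_hat, dtype=float).ravel()
    if scheme == "exemplar":
        sims = _cosine_to_all(v_hat, images.matrix)
        order = sorted(range(len(images)), key=lambda i: (-sims[i], images.image_ids[i]))
        return images.image_ids[order[0]]
    if scheme == "prototype":
        if prototypes is None:
            raise ValueError("prototype scheme requires a PrototypeSet")
        psims = _cosine_to_all(v_hat, prototypes.space.matrix)
        order = sorted(
            range(len(prototypes.labels)),
            key=lambda i: (-psims[i], prototypes.labels[i]),
        )
        best_label = prototypes.labels[order[0]]
        proto_vec = prototypes.space.vector(best_label)
        rows = [i for i, lab in enumerate(images.labels) if lab == best_label]
        if not rows:
            raise ValueError(f"no images for retrieved label {best_label!r}")
        sims = _cosine_to_all(proto_vec, images.matrix[rows])
        ranked = sorted(
            range(len(rows)), key=lambda j: (-sims[j], images.image_ids[rows[j]])
        )
        return images.image_ids[rows[ranked[0]]]
    raise ValueError(f"unknown retrieval scheme {scheme!r}")


def pick_random_control(
    images: ImageInventory, exclude: set[str] | None = None, seed: int | None = None
) -> str:
    """Uniform seeded draw of an image id outside ``exclude``."""
    exclude = exclude or set()
    pool = sorted(set(images.image_ids) - set(exclude))
    if not pool:
        raise ValueError("no images left after exclusion")
    rng = np.random.default_rng(seed)
    return pool[int(rng.integers(len(pool)))]
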