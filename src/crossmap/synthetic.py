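"""Synthetic coupled language/vision worlds and simulated 2AFC responses.

The generator stands in for the large pre-trained resources the pipeline
normally consumes (a distributional word space, CNN image features, human
concreteness norms) so that every downstream operation can run and be
tested offline.  It emulates three structural facts about the real data:

* words vary in concreteness, and more concrete words sit closer — in
  cosine terms — to the visually grounded (training) part of the lexicon:
  the generator plants a target correlation ``rho`` between concreteness
  and mean training-item similarity (the real-data value is about 0.53);
* each training label owns a cloud of images whose feature vectors are a
  hidden linear transform of the word vector plus per-image Gaussian
  scatter, so the true language-to-vision map exists and is recoverable;
* binary 2AFC choices follow a logistic model with participant and item
  random intercepts, plus catch trials answered correctly with high
  probability.

What it does **not** emulate: heavy-tailed frequency effects on embedding
quality, polysemy, label noise, or any nonlinearity in the true
language-to-vision relation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inventory import ImageInventory
from .spaces import VectorSpace

__all__ = [
    "SyntheticWorldConfig",
    "SyntheticWorld",
    "ChoiceModelConfig",
    "generate_world",
    "simulate_trials",
]


@dataclass
class SyntheticWorldConfig:
    """Knobs of the synthetic world.

    ``concreteness_coupling`` is the target correlation between a word's
    concreteness rating and its mean cosine similarity to the training
    labels; ``noise_sd`` is the per-image feature scatter around the
    label's true (mapped) visual vector.
    """

    n_words: int = 1000
    lang_dim: int = 50
    vis_dim: int = 64
    n_training_labels: int = 200
    images_per_label: int = 25
    noise_sd: float = 0.5
    concreteness_coupling: float = 0.53
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.lang_dim < 2 or self.vis_dim < 2:
            raise ValueError("dimensions must be >= 2")
        if not 0.0 <= self.concreteness_coupling < 1.0:
            raise ValueError("concreteness_coupling must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_training_labels >= self.n_words:
            raise ValueError("need words outside the training set")
        if self.lang_dim < 8 and self.concreteness_coupling > 0.8:
            raise ValueError(
                "coupling this strong is not achievable at such low dimension"
            )


@dataclass
class SyntheticWorld:
    """Everything :func:`generate_world` produced, incl. the hidden map."""

    lang: VectorSpace
    inventory: ImageInventory
    norms: pd.DataFrame
    training_labels: list[str]
    planted_map: np.ndarray  # true (lang_dim, vis_dim) matrix M*
    config: SyntheticWorldConfig = field(repr=False, default=None)

    def __iter__(self):  # (lang, inventory, norms, training_labels)
        return iter((self.lang, self.inventory, self.norms, self.training_labels))


def generate_world(cfg: SyntheticWorldConfig) -> SyntheticWorld:
    """Generate a coupled language space, image inventory and norms table.

    Language vectors are unit-norm directions interpolated between a
    word-specific random direction and the centroid direction of the
    training labels, with interpolation weight increasing in a latent
    variable correlated ``rho`` with concreteness.  Image vectors are
    ``v = l @ M* + Normal(0, noise_sd)`` per image for a hidden planted
    ``M*`` (kept on the returned world for recovery tests).
    """
    rng = np.random.default_rng(cfg.seed)
    n, d = cfg.n_words, cfg.lang_dim
    words = [f"w{i:05d}" for i in range(n)]
    training = words[: cfg.n_training_labels]

    concreteness = rng.uniform(1.0, 5.0, size=n)
    c_std = (concreteness - concreteness.mean()) / concreteness.std()
    rho = cfg.concreteness_coupling
    z = rho * c_std + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)

    mu = rng.standard_normal(d)
    mu /= np.linalg.norm(mu)
    raw = rng.standard_normal((n, d))
    raw /= np.linalg.norm(raw, axis=1, keepdims=True)

    vectors = np.empty((n, d))
    is_training = np.zeros(n, dtype=bool)
    is_training[: cfg.n_training_labels] = True
    # training labels: a moderately tight cloud around the grounded centroid
    vectors[is_training] = mu + 0.9 * raw[is_training]
    # other words: pulled toward the centroid with weight increasing in z;
    # the near-linear weight map keeps corr(concreteness, mean training
    # similarity) close to the planted rho
    w = np.clip(0.42 + 0.16 * z[~is_training], 0.02, 0.9)
    vectors[~is_training] = (
        (1.0 - w)[:, None] * raw[~is_training] + w[:, None] * mu
    )
    vectors /= np.linalg.norm(vectors, axis=1, keepdims=True)
    lang = VectorSpace(words, vectors)

    planted = rng.standard_normal((d, cfg.vis_dim)) / np.sqrt(d)
    ids, labels, feats = [], [], []
    for lab in training:
        base = lang.vector(lab) @ planted
        imgs = base + cfg.noise_sd * rng.standard_normal(
            (cfg.images_per_label, cfg.vis_dim)
        )
        for j in range(cfg.images_per_label):
            ids.append(f"{lab}_img{j:03d}")
            labels.append(lab)
        feats.append(imgs)

    frequency = np.round(np.exp(rng.normal(6.2, 1.3, size=n))).astype(int)
    norms = pd.DataFrame(
        {
            "word": words,
            "concreteness": np.round(concreteness, 3),
            "frequency": frequency,
            "is_noun": rng.random(n) < 0.9,
            "known_proportion": np.round(rng.beta(40, 1.5, size=n), 3),
        }
    )
    # training labels behave like imageable nouns
    norms.loc[: cfg.n_training_labels - 1, "is_noun"] = True

    inventory = ImageInventory(
        ids,
        labels,
        np.vstack(feats) if feats else np.empty((0, cfg.vis_dim)),
        label_frequency=dict(zip(words, frequency.tolist())),
    )
    return SyntheticWorld(lang, inventory, norms, training, planted, cfg)


@dataclass
class ChoiceModelConfig:
    """Generative model of 2AFC choices (logistic, crossed intercepts).

    The linear predictor is ``b0 + bc*x_c + bn*x_n + bcn*x_c*x_n + u_p +
    u_i`` with participant and item intercepts drawn from centred normals
    with standard deviations ``tau_participant`` / ``tau_item``.
    """

    beta0: float = 0.0
    beta_concreteness: float = 1.09
    beta_neighbor: float = 0.8
    beta_interaction: float = 0.0
    tau_participant: float = 1.0
    tau_item: float = 1.0
    n_participants: int = 55
    n_catch: int = 10
    catch_error_rate: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.tau_participant < 0 or self.tau_item < 0:
            raise ValueError("random-intercept standard deviations must be >= 0")
        if not 0.0 <= self.catch_error_rate <= 1.0:
            raise ValueError("catch_error_rate must be a probability")


def _choice_covariates(items: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(x_c, x_n) per item: condition codes for the five-condition design
    (concrete 0/1; far/near/maximum -> 0/1/2), raw covariates otherwise."""
    if "condition" in items.columns:
        cond = items["condition"].astype(str)
        x_c = cond.str.startswith("concrete").to_numpy(dtype=float)
        level = cond.str.split("/").str[-1]
        x_n = level.map({"far": 0.0, "near": 1.0, "maximum": 2.0}).to_numpy(dtype=float)
        if np.any(np.isnan(x_n)):
            raise ValueError("unknown neighborhood level in condition column")
        return x_c, x_n
    return (
        items["concreteness"].to_numpy(dtype=float),
        items["mean_training_similarity"].to_numpy(dtype=float),
    )


def simulate_trials(
    items: pd.DataFrame, cfg: ChoiceModelConfig, include_latent: bool = False
) -> pd.DataFrame:
    """Simulate one response per participant x item, plus catch trials.

    Returns a long-format trial table with columns ``participant_id``,
    ``word``, the item covariates, ``chose_model_image``, ``is_catch`` and
    ``catch_correct`` (catch rows only).  With ``include_latent`` the drawn
    random intercepts and per-trial choice probabilities are included too
    (for checking the generator, not for analysis).
    """
    rng = np.random.default_rng(cfg.seed)
    items = items.reset_index(drop=True)
    x_c, x_n = _choice_covariates(items)
    u_p = cfg.tau_participant * rng.standard_normal(cfg.n_participants)
    u_i = cfg.tau_item * rng.standard_normal(len(items))
    eta_items = (
        cfg.beta0
        + cfg.beta_concreteness * x_c
        + cfg.beta_neighbor * x_n
        + cfg.beta_interaction * x_c * x_n
    )

    covar_cols = [
        c
        for c in ("condition", "concreteness", "mean_training_similarity", "list_id")
        if c in items.columns
    ]
    frames = []
    for p in range(cfg.n_participants):
        pid = f"p{p + 1:04d}"
        prob = 1.0 / (1.0 + np.exp(-(eta_items + u_p[p] + u_i)))
        resp = (rng.random(len(items)) < prob).astype(int)
        df = items[["word", *covar_cols]].copy()
        df.insert(0, "participant_id", pid)
        df["chose_model_image"] = resp
        df["is_catch"] = 0
        df["catch_correct"] = np.nan
        if include_latent:
            df["u_participant"] = u_p[p]
            df["u_item"] = u_i
            df["p_choose_model"] = prob
        frames.append(df)
        if cfg.n_catch:
            correct = (rng.random(cfg.n_catch) >= cfg.catch_error_rate).astype(int)
            catch = pd.DataFrame(
                {
                    "participant_id": pid,
                    "word": [f"catch{j:02d}" for j in range(cfg.n_catch)],
                    "chose_model_image": np.nan,
                    "is_catch": 1,
                    "catch_correct": correct,
                }
            )
            frames.append(catch)
    out = pd.concat(frames, ignore_index=True)
    return out
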